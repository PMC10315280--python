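"""Differential methylation over ortholog-pair features.

Feature-level methylation (one level per replicate per genomic feature per
context) is contrasted between two groups — the two genotypes at a matched
stage, or two stages within one genotype — with a two-sided equal-variance
Student t-test. The methylation change is reported as
``delta = mean(group B) - mean(group A)`` (B = FIL2 when contrasting
genotypes, so delta follows the "HAL2 subtracted from FIL2" convention).
Significance requires q < 0.01 and |delta| > 0.1; features where one group
shows zero methylation in every replicate while the other does not are
*degenerate* — no t-test is possible in a meaningful sense and the |delta|
threshold alone decides. A gene is a differentially methylated gene (DMG)
when at least one feature x context contrast is significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DivergescanError
from .stats import storey_qvalues


def contrast_feature(levels_a, levels_b) -> tuple[float, float, float]:
    """Equal-variance two-sample t-test between replicate level vectors.

    Returns ``(t, p, delta)`` with ``delta = mean(b) - mean(a)``. With fewer
    than two defined levels on either side, t and p are NaN (untestable).
    Zero pooled variance is handled as a limiting case: p = 1 when the means
    agree, p = 0 when they differ.
    """
    a = np.asarray(levels_a, float)
    b = np.asarray(levels_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan, float(np.mean(b) - np.mean(a)) if len(a) and len(b) else np.nan
    delta = float(b.mean() - a.mean())
    # exact-tie variance can come out as ~1e-34 in floating point
    if a.var(ddof=1) <= 1e-20 and b.var(ddof=1) <= 1e-20:
        if delta == 0:
            return 0.0, 1.0, delta
        return np.inf if delta > 0 else -np.inf, 0.0, delta
    t, p = sps.ttest_ind(b, a, equal_var=True)
    return float(t), float(p), delta


def is_degenerate(levels_a, levels_b) -> bool:
    """One group entirely unmethylated for the feature, the other not."""
    a = np.asarray(levels_a, float)
    b = np.asarray(levels_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        return False
    zero_a, zero_b = bool((a == 0).all()), bool((b == 0).all())
    return zero_a != zero_b


def contrast_groups(
    table: pd.DataFrame,
    design: pd.DataFrame,
    group_a: dict,
    group_b: dict,
    ortholog_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build per-(pair, feature, context) contrasts between two sample groups.

    ``table`` is a long feature-methylation table (columns ``gene_id,
    feature_kind, context, sample, mean_level, n_sites``). ``group_a`` and
    ``group_b`` select design rows, e.g. ``{"genotype": "HAL2", "stage":
    "D1"}`` vs ``{"genotype": "FIL2", "stage": "D1"}``. For genotype
    contrasts the two groups are measured against their own annotations and
    joined through the one-to-one ``ortholog_map`` (columns ``pair_id`` plus
    one gene-id column per genotype); intergenic regions join directly on
    their shared region ids. Stage contrasts within one genotype need no map.

    Only keys with replicate data on both sides yield a contrast. Returns
    columns ``pair_id, feature_kind, context, mean_a, mean_b, delta, t, p,
    degenerate, n_a, n_b``.
    """

    def _select(group: dict) -> list[str]:
        mask = pd.Series(True, index=design.index)
        for col, val in group.items():
            mask &= design[col] == val
        return design.loc[mask, "sample"].tolist()

    samples_a, samples_b = _select(group_a), _select(group_b)
    if not samples_a or not samples_b:
        raise DivergescanError("empty sample group in contrast")

    def _side(samples: list[str], genotype: str | None) -> pd.DataFrame:
        sub = table[table["sample"].isin(samples)].copy()
        if ortholog_map is not None and genotype is not None:
            mapping = ortholog_map.set_index(genotype)["pair_id"]
            if not mapping.index.is_unique or not mapping.is_unique:
                raise DivergescanError("ortholog map is not a bijection")
            mapped = sub["gene_id"].map(mapping)
            # intergenic and other unmapped region ids pass through unchanged
            sub["pair_id"] = mapped.fillna(sub["gene_id"])
        else:
            sub["pair_id"] = sub["gene_id"]
        return sub

    geno_a = group_a.get("genotype") if ortholog_map is not None else None
    geno_b = group_b.get("genotype") if ortholog_map is not None else None
    side_a = _side(samples_a, geno_a)
    side_b = _side(samples_b, geno_b)

    def _pivot(side: pd.DataFrame) -> pd.DataFrame:
        return side.pivot_table(
            index=["pair_id", "feature_kind", "context"],
            columns="sample",
            values="mean_level",
            aggfunc="first",
        )

    wide_a, wide_b = _pivot(side_a), _pivot(side_b)
    keys = wide_a.index.intersection(wide_b.index)
    rows = []
    for key in keys:
        la = wide_a.loc[key].to_numpy(float)
        lb = wide_b.loc[key].to_numpy(float)
        la, lb = la[~np.isnan(la)], lb[~np.isnan(lb)]
        if len(la) == 0 or len(lb) == 0:
            continue
        degenerate = is_degenerate(la, lb)
        if degenerate:
            t, p, delta = np.nan, np.nan, float(lb.mean() - la.mean())
        else:
            t, p, delta = contrast_feature(la, lb)
        rows.append(
            {
                "pair_id": key[0],
                "feature_kind": key[1],
                "context": key[2],
                "mean_a": float(la.mean()),
                "mean_b": float(lb.mean()),
                "delta": delta,
                "t": t,
                "p": p,
                "degenerate": degenerate,
                "n_a": len(la),
                "n_b": len(lb),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "feature_kind",
            "context",
            "mean_a",
            "mean_b",
            "delta",
            "t",
            "p",
            "degenerate",
            "n_a",
            "n_b",
        ],
    )


def call_dmgs(
    contrasts: pd.DataFrame,
    q_max: float = 0.01,
    delta_min: float = 0.1,
    family: str = "per_context_feature",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply q-value and delta thresholds and roll contrasts up to genes.

    q-values are computed within each context x feature-kind family by
    default (``family="pooled"`` pools all testable contrasts instead).
    A contrast is significant when ``q < q_max`` and ``|delta| > delta_min``,
    or when it is degenerate and ``|delta| > delta_min``.

    Returns ``(contrasts, dmg_table, direction_counts)``: the input with
    ``q`` and ``significant`` columns added; one row per gene with its
    significant features and the DMG flag; and per feature x context tallies
    of hyper- (delta > 0, i.e. higher in group B) and hypomethylated calls.
    """
    out = contrasts.copy()
    out["q"] = np.nan
    testable = ~out["degenerate"] & out["p"].notna()
    if family == "pooled":
        out.loc[testable, "q"] = storey_qvalues(out.loc[testable, "p"])
    elif family == "per_context_feature":
        for _, idx in out[testable].groupby(["context", "feature_kind"]).groups.items():
            out.loc[idx, "q"] = storey_qvalues(out.loc[idx, "p"])
    else:
        raise ValueError(f"unknown q-value family {family!r}")

    big = out["delta"].abs() > delta_min
    out["significant"] = (out["q"] < q_max) & big | (out["degenerate"] & big)

    sig = out[out["significant"]]
    dmg_rows = []
    for pair_id, grp in out.groupby("pair_id"):
        feats = grp[grp["significant"]]
        dmg_rows.append(
            {
                "pair_id": pair_id,
                "is_dmg": bool(len(feats)),
                "n_significant": int(len(feats)),
                "significant_features": ";".join(
                    f"{r.feature_kind}:{r.context}:{r.delta:+.3f}" for r in feats.itertuples()
                ),
            }
        )
    dmg_table = pd.DataFrame(dmg_rows, columns=["pair_id", "is_dmg", "n_significant", "significant_features"])

    direction = (
        sig.assign(direction=np.where(sig["delta"] > 0, "hyper_b", "hypo_b"))
        .groupby(["feature_kind", "context", "direction"])
        .size()
        .rename("n")
        .reset_index()
        if len(sig)
        else pd.DataFrame(columns=["feature_kind", "context", "direction", "n"])
    )
    return out, dmg_table, direction
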