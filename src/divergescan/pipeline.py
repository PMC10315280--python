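"""End-to-end orchestration and DEG/DMG/Ka-Ks integration.

``run_pipeline`` drives the whole analysis on a simulated study: genomes and
feature derivation, methylome quantification, DMR calling over ortholog
pairs, factorial expression testing with stage contrasts, divergence-pattern
clustering with GO enrichment, NG86 Ka/Ks, and the DMR-associated-DEG join.
The machine-readable run report records seeds, thresholds and all summary
counts, plus recovery metrics against the planted truth; identical
config + seed yields an identical report.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GENOTYPES, STAGES_METH, SimulationConfig, methylome_design
from .errors import DivergescanError
from .features import parse_gff3, derive_features, assign_sites
from .methylation import (
    conversion_rate,
    feature_levels,
    filter_min_coverage,
    global_levels,
    level_histogram,
    read_cx_report,
)
from .dmr import call_dmgs, contrast_groups
from .expression import (
    classify_predominance,
    cpm_filter,
    define_deg_set,
    estimate_size_factors,
    fit_and_test,
    stage_contrasts,
    vst_like_normalize,
)
from .clustering import fuzzy_cmeans, kmeans_cluster, min_centroid_distance_curve, standardize_profiles
from .enrichment import enrich
from .kaks import classify_selection, kaks_table
from .simulate import simulate_all


def quadrant(log2fc: float, delta: float) -> str:
    """Quadrant label from expression and methylation change signs.

    "hyper"/"hypo" refer to methylation in FIL2 relative to HAL2 and
    "up"/"down" to expression in the same orientation.
    """
    meth = "hyper" if delta > 0 else "hypo"
    expr = "up" if log2fc > 0 else "down"
    return f"{meth}-{expr}"


def dmr_associated_degs(
    deg_sets: dict[str, pd.DataFrame],
    dmg_contrasts: dict[str, pd.DataFrame],
    stage_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-matched inner join of stringent DEGs with significant DMG features.

    ``deg_sets`` maps stage -> stringent DEG contrast rows (``gene_id,
    log2fc`` per stage); ``dmg_contrasts`` maps stage -> significant
    methylation contrast rows (``pair_id, feature_kind, context, delta``).
    Returns the per-feature records and per-context/feature gene tallies
    (a gene counts once per context even when several of its features are
    differentially methylated).
    """
    if stage_map is None:
        stage_map = {s: s for s in deg_sets}
    records = []
    for deg_stage, dmg_stage in stage_map.items():
        if deg_stage not in deg_sets:
            raise DivergescanError(f"stage {deg_stage} missing from the DEG input")
        if dmg_stage not in dmg_contrasts:
            raise DivergescanError(f"stage {dmg_stage} missing from the DMG input")
        degs = deg_sets[deg_stage]
        dmgs = dmg_contrasts[dmg_stage]
        merged = degs.rename(columns={"gene_id": "pair_id"}).merge(
            dmgs[["pair_id", "feature_kind", "context", "delta"]], on="pair_id", how="inner"
        )
        for r in merged.itertuples():
            records.append(
                {
                    "pair_id": r.pair_id,
                    "stage": deg_stage,
                    "context": r.context,
                    "feature_kind": r.feature_kind,
                    "log2fc": r.log2fc,
                    "delta": r.delta,
                    "quadrant": quadrant(r.log2fc, r.delta),
                }
            )
    rec_df = pd.DataFrame(
        records,
        columns=["pair_id", "stage", "context", "feature_kind", "log2fc", "delta", "quadrant"],
    )
    if len(rec_df):
        counts = (
            rec_df.drop_duplicates(["pair_id", "stage", "context", "feature_kind"])
            .groupby(["stage", "context", "feature_kind"])["pair_id"]
            .nunique()
            .rename("n_genes")
            .reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["stage", "context", "feature_kind", "n_genes"])
    return rec_df, counts


def selection_overlay(
    records: pd.DataFrame, kaks: pd.DataFrame
) -> tuple[pd.DataFrame, float | None]:
    """Attach omega and selection class to DMR-associated DEG records.

    Left join on pair id; returns the annotated records and the fraction of
    distinct pairs with omega > 1 among those with a defined omega (``None``
    when no pair has one).
    """
    out = records.merge(kaks[["pair_id", "omega"]], on="pair_id", how="left")
    out["selection"] = out["omega"].map(classify_selection)
    defined = out.drop_duplicates("pair_id")["omega"].dropna()
    fraction = float((defined > 1).mean()) if len(defined) else None
    return out, fraction


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def read_chrom_lengths(gff_path: str | Path) -> dict[str, int]:
    """Chromosome lengths from ``##sequence-region`` GFF3 headers."""
    lengths = {}
    for line in Path(gff_path).read_text().splitlines():
        m = re.match(r"##sequence-region\s+(\S+)\s+(\d+)\s+(\d+)", line)
        if m:
            lengths[m.group(1)] = int(m.group(3))
    return lengths


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path,
    min_cov: int = 5,
    q_max_dmr: float = 0.01,
    delta_min: float = 0.1,
    alpha_expr: float = 0.01,
    fc_min: float = 1.5,
    c_range=range(2, 7),
) -> dict:
    """Run the full synthetic analysis and write outputs plus a JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "thresholds": {
            "min_cov": min_cov,
            "q_max_dmr": q_max_dmr,
            "delta_min": delta_min,
            "alpha_expr": alpha_expr,
            "fc_min": fc_min,
        },
    }

    # -- simulation --------------------------------------------------------
    sim_dir = outdir / "sim"
    manifest = simulate_all(config, sim_dir)
    ortholog_map = pd.read_csv(manifest["orthologs"], sep="\t", dtype=str)
    dmr_truth = pd.read_csv(manifest["dmr_truth"], sep="\t")
    deg_truth = pd.read_csv(manifest["deg_truth"], sep="\t")
    kaks_truth = pd.read_csv(manifest["kaks_truth"], sep="\t")

    # -- features (round-trip through the GFF3 files) -----------------------
    models, assignments = {}, {}
    for genotype in GENOTYPES:
        gff = manifest[f"gff_{genotype}"]
        models[genotype] = parse_gff3(gff)
        chrom_lengths = read_chrom_lengths(gff)
        feats = derive_features(models[genotype], chrom_lengths, config.promoter_len)
        assignments[genotype] = (feats, chrom_lengths)

    # -- methylome quantification -------------------------------------------
    design_meth = methylome_design(config)
    feat_tables = []
    global_rows = []
    for _, row in design_meth.iterrows():
        sample, genotype = row["sample"], row["genotype"]
        records = read_cx_report(sim_dir / "methylomes" / f"{sample}.CX_report.txt")
        records = filter_min_coverage(records, min_cov)
        feats, _ = assignments[genotype]
        positions = {
            c: g["pos"].to_numpy() - 1 for c, g in records.groupby("chrom")
        }
        assignment = assign_sites(feats, positions)
        feat_tables.append(feature_levels(records, assignment, sample))
        gl = global_levels(records).assign(sample=sample)
        global_rows.append(gl)
    feature_table = pd.concat(feat_tables, ignore_index=True)
    feature_table.to_csv(outdir / "feature_levels.tsv", sep="\t", index=False)
    global_table = pd.concat(global_rows, ignore_index=True)
    global_table.to_csv(outdir / "global_levels.tsv", sep="\t", index=False)
    report["global_methylation"] = {
        ctx: float(global_table[global_table["context"] == ctx]["mean_level"].mean())
        for ctx in sorted(global_table["context"].unique())
    }
    chloro = read_cx_report(manifest["chloroplast"])
    report["conversion_rate"] = conversion_rate(filter_min_coverage(chloro, 1))
    hist = level_histogram(
        filter_min_coverage(
            read_cx_report(sim_dir / "methylomes" / f"{design_meth['sample'].iloc[0]}.CX_report.txt"),
            min_cov,
        )
    )
    hist.to_csv(outdir / "level_histogram.tsv", sep="\t", index=False)

    # -- DMR calling ---------------------------------------------------------
    dmg_sig_by_stage: dict[str, pd.DataFrame] = {}
    dmr_summary = {}
    for stage in STAGES_METH:
        contrasts = contrast_groups(
            feature_table,
            design_meth,
            {"genotype": GENOTYPES[0], "stage": stage},
            {"genotype": GENOTYPES[1], "stage": stage},
            ortholog_map=ortholog_map,
        )
        contrasts, dmg_table, direction = call_dmgs(contrasts, q_max_dmr, delta_min)
        contrasts.to_csv(outdir / f"dmr_contrasts_{stage}.tsv", sep="\t", index=False)
        dmg_table.to_csv(outdir / f"dmg_{stage}.tsv", sep="\t", index=False)
        genic = contrasts[~contrasts["pair_id"].str.startswith("IG_")]
        dmg_sig_by_stage[stage] = genic[genic["significant"]]
        dmr_summary[stage] = {
            "n_contrasts": int(len(contrasts)),
            "n_significant": int(contrasts["significant"].sum()),
            "n_dmgs": int(
                dmg_table[~dmg_table["pair_id"].str.startswith("IG_")]["is_dmg"].sum()
            ),
        }
    report["dmr"] = dmr_summary

    # recovery vs planted truth at D1 (planting is constant across stages)
    sig = dmg_sig_by_stage[STAGES_METH[0]]
    truth_keys = set(map(tuple, dmr_truth[["pair_id", "feature_kind", "context"]].to_numpy()))
    called = set(map(tuple, sig[["pair_id", "feature_kind", "context"]].to_numpy()))
    tp = len(truth_keys & called)
    report["dmr_recovery"] = {
        "sensitivity": tp / len(truth_keys) if truth_keys else None,
        "fdr": (len(called) - tp) / len(called) if called else None,
        "n_planted": len(truth_keys),
        "n_called": len(called),
    }

    # -- expression divergence ----------------------------------------------
    counts = pd.read_csv(manifest["counts"], sep="\t", index_col=0)
    design_expr = pd.read_csv(manifest["design_expr"], sep="\t")
    counts = cpm_filter(counts)
    size_factors = estimate_size_factors(counts)
    fit = fit_and_test(counts, design_expr, size_factors, alpha_q=alpha_expr)
    fit.results.to_csv(outdir / "factorial_tests.tsv", sep="\t")
    contrasts = stage_contrasts(fit)
    contrasts.to_csv(outdir / "stage_contrasts.tsv", sep="\t", index=False)
    predominance = classify_predominance(contrasts, alpha_expr)
    predominance.to_csv(outdir / "predominance.tsv", sep="\t", header=True)
    deg_rows = define_deg_set(contrasts, q_max=alpha_expr, fc_min=fc_min)

    cat_counts = fit.results["category"].value_counts().to_dict()
    report["expression"] = {
        "n_tested": int(len(fit.results)),
        "n_divergent": int(fit.results["divergent"].sum()),
        "categories": {k: int(v) for k, v in sorted(cat_counts.items())},
        "predominance": {
            k: int(v) for k, v in sorted(predominance.value_counts().to_dict().items())
        },
        "n_stringent_deg_genes": int(deg_rows["gene_id"].nunique()),
    }
    truth_int = set(deg_truth.loc[deg_truth["effect"] == "interaction", "gene_id"]) & set(
        fit.results.index
    )
    called_int = set(fit.results.index[fit.results["category"] == "interaction"])
    null_genes = set(fit.results.index) - set(deg_truth["gene_id"])
    report["expression_recovery"] = {
        "interaction_sensitivity": (
            len(truth_int & called_int) / len(truth_int) if truth_int else None
        ),
        "null_divergent_rate": (
            float(fit.results.loc[sorted(null_genes), "divergent"].mean()) if null_genes else None
        ),
    }

    # -- clustering + enrichment --------------------------------------------
    normalized = vst_like_normalize(counts, size_factors)
    interaction_genes = fit.results.index[fit.results["category"] == "interaction"]
    report["clustering"] = None
    if len(interaction_genes) >= max(c_range) + 1:
        profiles = standardize_profiles(normalized.loc[interaction_genes], design_expr)
        curve, selected = min_centroid_distance_curve(profiles, c_range, seed=config.seed)
        curve.to_csv(outdir / "dmin_curve.tsv", sep="\t", index=False)
        fcm = fuzzy_cmeans(profiles.to_numpy(), selected, seed=config.seed)
        hard = kmeans_cluster(profiles, selected, seed=config.seed)
        pd.DataFrame(
            {"gene_id": profiles.index, "kmeans_cluster": hard}
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        report["clustering"] = {
            "selected_c": int(selected),
            "dmin_curve": curve["dmin"].round(6).tolist(),
            "fcm_converged": bool(fcm.converged),
            "cluster_sizes": pd.Series(hard).value_counts().sort_index().tolist(),
        }

        # synthetic annotation: one term per planted effect + random terms
        background = set(fit.results.index)
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(97,)))
        annotations = {
            f"EFFECT:{eff}": set(grp["gene_id"]) & background
            for eff, grp in deg_truth.groupby("effect")
        }
        bg_sorted = sorted(background)
        for i in range(5):
            annotations[f"RANDOM:{i}"] = set(
                rng.choice(bg_sorted, size=min(30, len(bg_sorted)), replace=False)
            )
        enr = enrich(set(interaction_genes), background, annotations)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report["enrichment"] = {
            "n_terms_tested": int(len(enr)),
            "significant_terms": enr.loc[enr["significant"], "term"].tolist(),
        }

    # -- Ka/Ks ---------------------------------------------------------------
    from .simulate import read_cds_pairs

    pairs = read_cds_pairs(manifest["cds_pairs"])
    kk = kaks_table(pairs)
    kk["selection"] = kk["omega"].map(classify_selection)
    kk.to_csv(outdir / "kaks.tsv", sep="\t", index=False)
    defined = kk["omega"].dropna()
    merged_truth = kk.merge(kaks_truth, on="pair_id")
    recovered = (
        merged_truth["Sd"] + merged_truth["Nd"]
        == merged_truth["planted_synonymous"] + merged_truth["planted_nonsynonymous"]
    )
    report["kaks"] = {
        "n_pairs": int(len(kk)),
        "n_defined_omega": int(len(defined)),
        "fraction_positive": float((defined > 1).mean()) if len(defined) else None,
        "mean_omega": float(defined.mean()) if len(defined) else None,
        "substitution_count_recovery": float(recovered.mean()),
    }

    # -- integration ---------------------------------------------------------
    deg_sets = {
        stage: deg_rows[deg_rows["stage"] == stage][["gene_id", "log2fc"]]
        for stage in STAGES_METH
    }
    records, tally = dmr_associated_degs(deg_sets, dmg_sig_by_stage)
    records, frac_pos = selection_overlay(records, kk)
    records.to_csv(outdir / "dmr_deg_records.tsv", sep="\t", index=False)
    tally.to_csv(outdir / "dmr_deg_counts.tsv", sep="\t", index=False)
    report["integration"] = {
        "n_records": int(len(records)),
        "n_genes_per_stage": {
            stage: int(records[records["stage"] == stage]["pair_id"].nunique())
            for stage in STAGES_METH
        },
        "fraction_positive_selection": frac_pos,
        "quadrants": {
            k: int(v) for k, v in sorted(records["quadrant"].value_counts().to_dict().items())
        },
    }

    report = _round_floats(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
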