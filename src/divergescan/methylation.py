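"""Cytosine-report parsing and methylation summaries.

Reads Bismark-style CX genome-wide cytosine reports (7 tab-separated columns:
chromosome, 1-based position, strand, methylated count, unmethylated count,
context, trinucleotide) and computes site-, feature-, window- and
metagene-level methylation statistics.

The regional methylation level is the *unweighted* mean of per-site
proportions ``n_meth / (n_meth + n_unmeth)`` over covered sites; a
pooled-count estimator (sum of methylated over sum of total reads) is
available behind a flag but is off by default. Symmetric CG positions on
opposite strands are kept as separate sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .config import CONTEXTS
from .errors import MissingDataError, ParseError

CX_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


@dataclass(frozen=True)
class CytosineSiteRecord:
    """One reference cytosine with its read support."""

    chrom: str
    pos: int  # 1-based, as in the report
    strand: str
    n_meth: int
    n_unmeth: int
    context: str
    trinucleotide: str

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        if self.coverage == 0:
            return float("nan")
        return self.n_meth / self.coverage


def parse_cx_report(path: str | Path) -> Iterator[CytosineSiteRecord]:
    """Stream records from a CX report, validating each line.

    Malformed rows raise :class:`ParseError` naming the line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 7:
                raise ParseError(
                    f"{path}, line {lineno}: expected 7 tab-separated columns, got {len(cols)}"
                )
            try:
                pos = int(cols[1])
                n_meth = int(cols[3])
                n_unmeth = int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: non-integer field") from exc
            if n_meth < 0 or n_unmeth < 0 or pos < 1:
                raise ParseError(f"{path}, line {lineno}: negative count or position")
            if cols[2] not in {"+", "-"}:
                raise ParseError(f"{path}, line {lineno}: invalid strand {cols[2]!r}")
            if cols[5] not in CONTEXTS:
                raise ParseError(f"{path}, line {lineno}: unknown context {cols[5]!r}")
            yield CytosineSiteRecord(cols[0], pos, cols[2], n_meth, n_unmeth, cols[5], cols[6])


def read_cx_report(path: str | Path) -> pd.DataFrame:
    """Load a whole CX report as a DataFrame (vectorized path).

    Column semantics match :func:`parse_cx_report`; an extra ``coverage``
    column is added. ``pos`` stays 1-based.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=CX_COLUMNS,
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "count_methylated": np.int64,
                "count_unmethylated": np.int64,
                "context": str,
                "trinucleotide": str,
            },
            header=None,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: malformed CX report ({exc})") from exc
    df["coverage"] = df["count_methylated"] + df["count_unmethylated"]
    return df


def filter_min_coverage(records: pd.DataFrame, min_cov: int = 5) -> pd.DataFrame:
    """Keep sites covered by at least ``min_cov`` reads (inclusive bound)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    cov = records["count_methylated"] + records["count_unmethylated"]
    return records.loc[cov >= min_cov].copy()


def site_levels(records: pd.DataFrame) -> pd.Series:
    """Per-site methylation proportion for covered sites."""
    cov = records["count_methylated"] + records["count_unmethylated"]
    with np.errstate(invalid="ignore"):
        return records["count_methylated"] / cov


def feature_levels(
    records: pd.DataFrame,
    assignment: pd.DataFrame,
    sample: str,
    min_sites: int = 1,
    pooled: bool = False,
) -> pd.DataFrame:
    """Aggregate coverage-filtered sites into per-feature methylation levels.

    ``assignment`` maps 0-based positions to (gene_id, feature_kind); report
    positions are 1-based and converted here. Returns a long table with
    columns ``gene_id, feature_kind, context, sample, mean_level, n_sites``;
    (gene, feature, context) combinations with fewer than ``min_sites``
    covered sites are omitted.

    With ``pooled=True`` the level is the read-weighted pooled estimate
    instead of the default unweighted mean of site proportions.
    """
    df = records.copy()
    df["pos0"] = df["pos"] - 1
    df["level"] = site_levels(df)
    merged = df.merge(
        assignment.rename(columns={"pos": "pos0"}),
        on=["chrom", "pos0"],
        how="inner",
    )
    if pooled:
        grouped = merged.groupby(["gene_id", "feature_kind", "context"], sort=True).agg(
            meth=("count_methylated", "sum"),
            total=("coverage", "sum"),
            n_sites=("level", "size"),
        )
        grouped["mean_level"] = grouped["meth"] / grouped["total"]
        out = grouped.reset_index()[["gene_id", "feature_kind", "context", "mean_level", "n_sites"]]
    else:
        grouped = merged.groupby(["gene_id", "feature_kind", "context"], sort=True).agg(
            mean_level=("level", "mean"), n_sites=("level", "size")
        )
        out = grouped.reset_index()
    out = out[out["n_sites"] >= min_sites].copy()
    out.insert(3, "sample", sample)
    return out.reset_index(drop=True)


def global_levels(records: pd.DataFrame) -> pd.DataFrame:
    """Per-context global summaries: mean site level and fraction methylated.

    Two readings of "proportion of methylated cytosines" are reported: the
    mean per-site methylation level (primary) and the fraction of sites with
    at least one methylated read.
    """
    if len(records) == 0:
        raise MissingDataError("no covered sites for global summary")
    df = records.copy()
    df["level"] = site_levels(df)
    out = df.groupby("context").agg(
        mean_level=("level", "mean"),
        frac_methylated=("count_methylated", lambda x: float((x > 0).mean())),
        n_sites=("level", "size"),
    )
    return out.reset_index()


def level_histogram(
    records: pd.DataFrame, cutpoints: tuple[float, float] = (0.2, 0.8)
) -> pd.DataFrame:
    """Fractions of sites in low/mid/high level bins per context.

    Bins are ``[0, low)``, ``[low, high]`` and ``(high, 1]``; fractions sum
    to 1 per context.
    """
    low, high = cutpoints
    df = records.copy()
    df["level"] = site_levels(df)
    rows = []
    for context, grp in df.groupby("context"):
        lv = grp["level"].to_numpy()
        n = len(lv)
        rows.append(
            {
                "context": context,
                "low": float((lv < low).sum() / n),
                "mid": float(((lv >= low) & (lv <= high)).sum() / n),
                "high": float((lv > high).sum() / n),
                "n_sites": n,
            }
        )
    return pd.DataFrame(rows)


def conversion_rate(chloroplast_records: pd.DataFrame) -> float:
    """Bisulfite conversion rate from an unmethylated chloroplast control.

    Rate = 1 - (total methylated reads / total reads) over covered sites.
    """
    if len(chloroplast_records) == 0:
        raise MissingDataError("empty chloroplast report")
    meth = int(chloroplast_records["count_methylated"].sum())
    total = int(
        chloroplast_records["count_methylated"].sum()
        + chloroplast_records["count_unmethylated"].sum()
    )
    if total == 0:
        raise MissingDataError("chloroplast report has no covered sites")
    return 1.0 - meth / total


def window_profiles(
    records: pd.DataFrame,
    gene_spans: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_bp: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile chromosomes into windows; methylation level vs gene density.

    ``gene_spans`` needs columns ``chrom, start, end`` (0-based half-open).
    Returns ``(windows, correlations)``: per-window unweighted mean site
    level per context and gene count (genes assigned by span midpoint), and
    the per-context Pearson r over windows with at least one covered site
    (NaN when undefined, e.g. zero variance or a single window).
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    df = records.copy()
    df["level"] = site_levels(df)
    df["window"] = (df["pos"] - 1) // window_bp

    gene_spans = gene_spans.copy()
    gene_spans["window"] = ((gene_spans["start"] + gene_spans["end"]) // 2) // window_bp

    rows = []
    for chrom, clen in sorted(chrom_lengths.items()):
        n_windows = int(np.ceil(clen / window_bp))
        counts = (
            gene_spans[gene_spans["chrom"] == chrom]
            .groupby("window")["start"]
            .size()
            .reindex(range(n_windows), fill_value=0)
        )
        sub = df[df["chrom"] == chrom]
        for context in CONTEXTS:
            lv = (
                sub[sub["context"] == context]
                .groupby("window")["level"]
                .agg(["mean", "size"])
                .reindex(range(n_windows))
            )
            for w in range(n_windows):
                rows.append(
                    {
                        "chrom": chrom,
                        "window": w,
                        "context": context,
                        "mean_level": lv["mean"].iloc[w],
                        "n_sites": 0 if np.isnan(lv["size"].iloc[w]) else int(lv["size"].iloc[w]),
                        "gene_count": int(counts.iloc[w]),
                    }
                )
    windows = pd.DataFrame(rows)

    corr_rows = []
    for context, grp in windows.groupby("context"):
        grp = grp[grp["n_sites"] >= 1]
        r = np.nan
        if len(grp) >= 2:
            x, y = grp["mean_level"].to_numpy(), grp["gene_count"].to_numpy(float)
            if np.std(x) > 0 and np.std(y) > 0:
                r = float(np.corrcoef(x, y)[0, 1])
        corr_rows.append({"context": context, "pearson_r": r, "n_windows": len(grp)})
    return windows, pd.DataFrame(corr_rows)


def expression_rank_groups(
    counts: pd.DataFrame, samples: list[str], n_groups: int = 6
) -> pd.Series:
    """Rank genes by expression in one genotype-stage cell.

    Rank 1 holds genes with zero total count across the given replicates;
    the remaining genes are split into ``n_groups - 1`` equal-size quantile
    groups of mean library-normalized count, rank 2 lowest to rank
    ``n_groups`` highest. Quantile ties are broken by gene id order.
    """
    sub = counts[samples]
    lib = sub.sum(axis=0).to_numpy(float)
    if (lib == 0).any():
        raise ValueError("zero library size in rank-group samples")
    cpm = (sub / lib * 1e6).mean(axis=1)
    total = sub.sum(axis=1)
    ranks = pd.Series(1, index=counts.index, name="rank", dtype=int)
    expressed = total[total > 0].index.tolist()
    # deterministic order: value then gene id
    expressed.sort(key=lambda g: (cpm[g], g))
    chunks = np.array_split(np.asarray(expressed, dtype=object), n_groups - 1)
    for i, chunk in enumerate(chunks):
        ranks.loc[list(chunk)] = i + 2
    return ranks


def metagene_profile(
    records: pd.DataFrame,
    models: list,
    rank_groups: pd.Series | dict,
    flank_bp: int = 2000,
    body_bins: int = 20,
    flank_bins: int = 20,
) -> pd.DataFrame:
    """Mean methylation over gene bodies and flanks, by expression group.

    The gene body is scaled to ``body_bins`` bins; each flank is split into
    ``flank_bins`` fixed-width bins. Bins are oriented 5' to 3' in transcript
    direction (upstream flank first, so a minus-strand gene's upstream flank
    lies genomically downstream). The group profile is the mean over genes of
    within-gene bin means.

    ``rank_groups`` maps gene_id -> group label; genes without a label are
    skipped. ``models`` is a list of :class:`~divergescan.features.GeneModel`.
    Returns columns ``group, context, bin, mean_level, n_genes``.
    """
    if isinstance(rank_groups, dict):
        rank_groups = pd.Series(rank_groups)
    df = records.copy()
    df["level"] = site_levels(df)
    df["pos0"] = df["pos"] - 1
    by_chrom = {c: g.sort_values("pos0") for c, g in df.groupby("chrom")}

    total_bins = body_bins + 2 * flank_bins
    flank_width = flank_bp / flank_bins
    per_gene = []  # (group, context, bin) -> per-gene mean rows
    for m in models:
        if m.gene_id not in rank_groups.index:
            continue
        group = rank_groups[m.gene_id]
        sub = by_chrom.get(m.chrom)
        if sub is None:
            continue
        pos = sub["pos0"].to_numpy()
        lo = np.searchsorted(pos, m.start - flank_bp, side="left")
        hi = np.searchsorted(pos, m.end + flank_bp, side="left")
        if hi <= lo:
            continue
        window = sub.iloc[lo:hi]
        p = window["pos0"].to_numpy()
        gene_len = m.end - m.start
        # bin index in transcript orientation
        upstream = p < m.start
        downstream = p >= m.end
        body = ~upstream & ~downstream
        bins = np.empty(len(p), dtype=int)
        bins[upstream] = np.minimum(
            flank_bins - 1, ((p[upstream] - (m.start - flank_bp)) // flank_width).astype(int)
        )
        bins[body] = flank_bins + np.minimum(
            body_bins - 1, ((p[body] - m.start) * body_bins // max(gene_len, 1)).astype(int)
        )
        bins[downstream] = flank_bins + body_bins + np.minimum(
            flank_bins - 1, ((p[downstream] - m.end) // flank_width).astype(int)
        )
        if m.strand == "-":
            bins = total_bins - 1 - bins
        gene_df = pd.DataFrame(
            {"context": window["context"].to_numpy(), "bin": bins, "level": window["level"].to_numpy()}
        )
        gmeans = gene_df.groupby(["context", "bin"])["level"].mean().reset_index()
        gmeans["group"] = group
        per_gene.append(gmeans)

    if not per_gene:
        return pd.DataFrame(columns=["group", "context", "bin", "mean_level", "n_genes"])
    allg = pd.concat(per_gene, ignore_index=True)
    out = allg.groupby(["group", "context", "bin"]).agg(
        mean_level=("level", "mean"), n_genes=("level", "size")
    )
    return out.reset_index()
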