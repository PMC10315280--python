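"""Global methylome profiles: context levels, histograms, conversion rate,
methylation vs gene density, and metagene profiles by expression rank.

Expects the synthetic study from 01_simulate_study.py.
"""

import pandas as pd

from _common import CONFIG, SIM_DIR, results_dir
from divergescan.config import GENOTYPES, methylome_design
from divergescan.features import parse_gff3
from divergescan.methylation import (
    conversion_rate,
    expression_rank_groups,
    filter_min_coverage,
    global_levels,
    level_histogram,
    metagene_profile,
    read_cx_report,
    window_profiles,
)

MIN_COV = 5


def main() -> None:
    out = results_dir("02_methylome")
    design = methylome_design(CONFIG)

    # global per-context levels across all 12 samples
    rows = []
    for sample in design["sample"]:
        records = filter_min_coverage(
            read_cx_report(SIM_DIR / "methylomes" / f"{sample}.CX_report.txt"), MIN_COV
        )
        rows.append(global_levels(records).assign(sample=sample))
    glob = pd.concat(rows, ignore_index=True)
    glob.to_csv(out / "global_levels.tsv", sep="\t", index=False)
    means = glob.groupby("context")["mean_level"].mean()
    print("mean methylation level per context (all samples):")
    print(means.round(4).to_string())

    # distribution of site levels for one representative sample
    sample0 = design["sample"].iloc[0]
    records = filter_min_coverage(
        read_cx_report(SIM_DIR / "methylomes" / f"{sample0}.CX_report.txt"), MIN_COV
    )
    hist = level_histogram(records)
    hist.to_csv(out / "level_histogram.tsv", sep="\t", index=False)

    # bisulfite conversion rate from the chloroplast control
    chloro = filter_min_coverage(read_cx_report(SIM_DIR / "chloroplast.CX_report.txt"), 1)
    rate = conversion_rate(chloro)
    print(f"bisulfite conversion rate: {100 * rate:.2f}%")

    # methylation level vs gene density in 10 kb windows
    models = parse_gff3(SIM_DIR / f"{GENOTYPES[0]}.gff3")
    from divergescan.pipeline import read_chrom_lengths

    lengths = read_chrom_lengths(SIM_DIR / f"{GENOTYPES[0]}.gff3")
    spans = pd.DataFrame(
        [{"chrom": m.chrom, "start": m.start, "end": m.end} for m in models]
    )
    windows, corr = window_profiles(records, spans, lengths, 10_000)
    windows.to_csv(out / "windows.tsv", sep="\t", index=False)
    corr.to_csv(out / "window_gene_density_correlation.tsv", sep="\t", index=False)
    print("methylation vs gene density (Pearson r):")
    print(corr.round(3).to_string(index=False))

    # metagene profiles by expression rank (HAL2, D1)
    counts = pd.read_csv(SIM_DIR / "counts.tsv", sep="\t", index_col=0)
    expr_design = pd.read_csv(SIM_DIR / "design_expr.tsv", sep="\t")
    d1_samples = expr_design.query("genotype == 'HAL2' and stage == 'D1'")["sample"].tolist()
    ranks_by_pair = expression_rank_groups(counts, d1_samples)
    omap = pd.read_csv(SIM_DIR / "orthologs.tsv", sep="\t").set_index("pair_id")
    ranks = ranks_by_pair.rename(index=omap[GENOTYPES[0]].to_dict()).map(lambda r: f"rank{r}")
    profile = metagene_profile(records, models, ranks)
    profile.to_csv(out / "metagene_by_rank.tsv", sep="\t", index=False)
    print(f"metagene profile: {profile['group'].nunique()} rank groups x "
          f"{profile['bin'].nunique()} bins x {profile['context'].nunique()} contexts")


if __name__ == "__main__":
    main()
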