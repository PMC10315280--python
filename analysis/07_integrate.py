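"""Join DEGs, DMGs and Ka/Ks into the DMR-associated DEG table.

Stage-matched inner join of the stringent DEG set with significant
methylation contrasts (D1 with D1, D4 with D4), quadrant classification
from the signs of expression and methylation change, and the positive-
selection overlay.
"""

import pandas as pd

from _common import results_dir
from divergescan.config import STAGES_METH
from divergescan.pipeline import dmr_associated_degs, selection_overlay


def main() -> None:
    out = results_dir("07_integration")
    degs = pd.read_csv(results_dir("04_expression") / "stringent_degs.tsv", sep="\t")
    kaks = pd.read_csv(results_dir("06_kaks") / "kaks.tsv", sep="\t")

    deg_sets, dmg_sets = {}, {}
    for stage in STAGES_METH:
        deg_sets[stage] = degs[degs["stage"] == stage][["gene_id", "log2fc"]]
        con = pd.read_csv(
            results_dir("03_dmr") / f"contrasts_genotype_{stage}.tsv", sep="\t"
        )
        sig = con[con["significant"] & ~con["pair_id"].str.startswith("IG_")]
        dmg_sets[stage] = sig

    records, tally = dmr_associated_degs(deg_sets, dmg_sets)
    records, frac_positive = selection_overlay(records, kaks)
    records.to_csv(out / "dmr_deg_records.tsv", sep="\t", index=False)
    tally.to_csv(out / "dmr_deg_counts.tsv", sep="\t", index=False)

    for stage in STAGES_METH:
        n_deg = deg_sets[stage]["gene_id"].nunique()
        n_joint = records.loc[records["stage"] == stage, "pair_id"].nunique()
        frac = 100 * n_joint / n_deg if n_deg else 0.0
        print(f"{stage}: {n_joint} of {n_deg} stringent DEGs are DMR-associated ({frac:.1f}%)")
    print("quadrants:", records["quadrant"].value_counts().to_dict())
    if frac_positive is not None:
        print(f"fraction of DMR-associated DEG pairs with omega > 1: {frac_positive:.3f}")
    else:
        print("no DMR-associated DEG pair has a defined omega")


if __name__ == "__main__":
    main()
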