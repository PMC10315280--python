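"""Cluster divergence profiles of interaction genes and test GO enrichment.

Standardizes the 8 genotype x stage cell means per interaction gene,
selects the fuzzy cluster number from the minimum-centroid-distance curve,
assigns hard k-means clusters, and runs hypergeometric enrichment of each
cluster against the tested-gene background using a synthetic annotation
built from the planted effect classes.
"""

import numpy as np
import pandas as pd

from _common import CONFIG, SIM_DIR, results_dir
from divergescan.clustering import (
    fuzzy_cmeans,
    kmeans_cluster,
    min_centroid_distance_curve,
    standardize_profiles,
)
from divergescan.enrichment import enrich
from divergescan.expression import cpm_filter, estimate_size_factors, vst_like_normalize


def main() -> None:
    out = results_dir("05_clusters")
    counts = cpm_filter(pd.read_csv(SIM_DIR / "counts.tsv", sep="\t", index_col=0))
    design = pd.read_csv(SIM_DIR / "design_expr.tsv", sep="\t")
    factorial = pd.read_csv(
        results_dir("04_expression") / "factorial_tests.tsv", sep="\t", index_col=0
    )
    normalized = vst_like_normalize(counts, estimate_size_factors(counts))

    interaction = factorial.index[factorial["category"] == "interaction"]
    profiles = standardize_profiles(normalized.loc[interaction], design)
    print(f"clustering {len(profiles)} interaction-gene profiles")

    c_max = min(8, max(2, len(profiles) - 1))
    curve, selected = min_centroid_distance_curve(profiles, range(2, c_max + 1), seed=CONFIG.seed)
    curve.to_csv(out / "dmin_curve.tsv", sep="\t", index=False)
    print(f"minimum centroid distance selects c = {selected}")

    fcm = fuzzy_cmeans(profiles.to_numpy(), selected, seed=CONFIG.seed)
    membership = pd.DataFrame(
        fcm.membership, index=profiles.index,
        columns=[f"cluster{i + 1}" for i in range(selected)],
    )
    membership.to_csv(out / "fcm_membership.tsv", sep="\t")
    hard = kmeans_cluster(profiles, selected, seed=CONFIG.seed)
    assignments = pd.DataFrame({"gene_id": profiles.index, "kmeans_cluster": hard})
    assignments.to_csv(out / "kmeans_clusters.tsv", sep="\t", index=False)
    print("k-means cluster sizes:", np.bincount(hard).tolist())

    # enrichment against the tested background with truth-derived terms
    truth = pd.read_csv(SIM_DIR / "deg_truth.tsv", sep="\t")
    background = set(factorial.index)
    annotations = {
        f"EFFECT:{eff}": set(grp["gene_id"]) & background
        for eff, grp in truth.groupby("effect")
    }
    rng = np.random.default_rng(CONFIG.seed)
    bg_sorted = sorted(background)
    for i in range(5):
        annotations[f"RANDOM:{i}"] = set(
            rng.choice(bg_sorted, size=min(30, len(bg_sorted)), replace=False)
        )
    rows = []
    for cluster in range(selected):
        study = set(assignments.loc[assignments["kmeans_cluster"] == cluster, "gene_id"])
        enr = enrich(study, background, annotations)
        rows.append(enr.assign(cluster=cluster + 1))
    enrichment = pd.concat(rows, ignore_index=True)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    sig = enrichment[enrichment["significant"]]
    print(f"significant terms across clusters: "
          f"{sig[['cluster', 'term']].to_records(index=False).tolist()}")


if __name__ == "__main__":
    main()
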