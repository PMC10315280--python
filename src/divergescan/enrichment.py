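"""Hypergeometric GO-term enrichment with Benjamini–Hochberg FDR control.

A study set (e.g. one expression cluster) is tested against an
expressed-gene background: for each term with K annotated background genes,
the upper-tail hypergeometric probability of observing at least the actual
overlap k in a study set of size n drawn from a background of size N. No
GO-graph propagation is applied; annotations are used as given.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats as sps

from .errors import DivergescanError
from .stats import bh_adjust


def read_annotations(path) -> dict[str, set]:
    """Read a two-column (gene, term) TSV into term -> gene-set form."""
    df = pd.read_csv(path, sep="\t", names=["gene", "term"], header=None, dtype=str)
    out: dict[str, set] = {}
    for term, grp in df.groupby("term"):
        out[term] = set(grp["gene"])
    return out


def enrich(
    study: set,
    background: set,
    annotations: dict[str, set],
    min_term_size: int = 2,
    fdr_max: float = 0.05,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``study`` within ``background``.

    Annotation sets are intersected with the background before testing;
    terms with fewer than ``min_term_size`` background genes are skipped.
    Returns one row per tested term with the overlap ``k``, term size ``K``,
    study size ``n``, background size ``N``, the upper-tail p-value, the BH
    FDR and a significance flag (FDR < ``fdr_max``), sorted by p.
    """
    study, background = set(study), set(background)
    if not study <= background:
        raise DivergescanError("study set is not a subset of the background")
    N, n = len(background), len(study)
    rows = []
    for term, genes in sorted(annotations.items()):
        term_genes = genes & background
        K = len(term_genes)
        if K < min_term_size:
            continue
        k = len(term_genes & study)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "term_name": (term_names or {}).get(term, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
            }
        )
    df = pd.DataFrame(rows, columns=["term", "term_name", "k", "K", "n", "N", "p"])
    if len(df):
        df["fdr"] = bh_adjust(df["p"])
        df["significant"] = df["fdr"] < fdr_max
        df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        df["fdr"] = []
        df["significant"] = []
    return df
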