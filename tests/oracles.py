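"""Independent brute-force oracles used to validate the implementations.

Each oracle is written from the definition, with no shared code with the
package: NG86 counting via explicit recursive enumeration of substitution
orderings and Biopython translation; hypergeometric enrichment by exhaustive
enumeration of all possible draws; feature methylation levels by a direct
loop over sites.
"""

from __future__ import annotations

import itertools
from math import comb

from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> float:
    """Synonymous site count of one codon (stops among targets count as
    non-synonymous)."""
    syn = 0
    for pos, nt in itertools.product(range(3), BASES):
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1:]
        if _aa(alt) == _aa(codon):
            syn += 1
    return syn / 3.0


def _paths(codon_a: str, codon_b: str):
    """Yield (sd, nd, hits_stop) for every ordering of the differing positions."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    for order in itertools.permutations(diffs):
        current, sd, nd, hit = codon_a, 0, 0, False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if _aa(nxt) == "*" and nxt != codon_b:
                hit = True
            if _aa(nxt) == _aa(current):
                sd += 1
            else:
                nd += 1
            current = nxt
        yield sd, nd, hit


def oracle_ng86(seq_a: str, seq_b: str):
    """NG86 counts and rates computed from first principles.

    Returns a dict with S_sites, N_sites, Sd, Nd, Ka, Ks (None when the
    Jukes-Cantor correction is undefined).
    """
    import math

    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    s_sites = sd = nd = 0.0
    used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3].upper(), seq_b[i:i + 3].upper()
        if set(ca + cb) - set(BASES):
            continue
        if _aa(ca) == "*" or _aa(cb) == "*":
            continue
        s_sites += (oracle_sites(ca) + oracle_sites(cb)) / 2.0
        paths = list(_paths(ca, cb))
        ok = [(s, n) for s, n, hit in paths if not hit] or [(s, n) for s, n, _ in paths]
        if ok:
            sd += sum(s for s, _ in ok) / len(ok)
            nd += sum(n for _, n in ok) / len(ok)
        used += 1
    n_sites = 3.0 * used - s_sites

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    return {
        "S_sites": s_sites,
        "N_sites": n_sites,
        "Sd": sd,
        "Nd": nd,
        "Ks": jc(ps),
        "Ka": jc(pn),
    }


def oracle_hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = list(range(N))
    annotated = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(annotated & set(draw)) >= k:
            hits += 1
    assert total == comb(N, n)
    return hits / total


def oracle_feature_level(site_meth, site_unmeth) -> float:
    """Unweighted mean of per-site methylation proportions."""
    props = [m / (m + u) for m, u in zip(site_meth, site_unmeth) if m + u > 0]
    return sum(props) / len(props)
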