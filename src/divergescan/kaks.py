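"""Nei–Gojobori (1986) Ka/Ks estimation for aligned CDS pairs.

For each codon the number of synonymous sites is the fraction of the three
possible single-nucleotide changes at each position that preserve the amino
acid (changes producing a stop codon count as non-synonymous sites, so that
synonymous + non-synonymous sites always sum to three per codon). Site counts
are averaged over the two sequences. For codons differing at several
positions, synonymous and non-synonymous difference counts are averaged with
equal weight over all substitution orderings; orderings passing through a
stop codon are excluded (and only if every ordering does are all retained).
Proportions are corrected with the Jukes–Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``; the correction is undefined for p >= 3/4 and
omega = Ka/Ks is undefined when Ks = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DivergescanError, MissingDataError

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        _CODON_TABLE[stop] = "*"


_build_codon_table()


def translate_codon(codon: str) -> str:
    """Amino acid (or ``*`` for stop) encoded by a codon."""
    return _CODON_TABLE[codon]


def _codon_site_counts(codon: str) -> float:
    """Synonymous site count of one codon (non-synonymous = 3 - this)."""
    aa = _CODON_TABLE[codon]
    syn = 0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if _CODON_TABLE[alt] == aa:
                syn += 1
    return syn / 3.0


def count_sites(seq: str) -> tuple[float, float]:
    """Total (synonymous, non-synonymous) site counts of one CDS."""
    s = 0.0
    n_codons = 0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if set(codon) - set("ACGT"):
            continue
        s += _codon_site_counts(codon)
        n_codons += 1
    return s, 3.0 * n_codons - s


def _codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, non-synonymous) differences between two codons."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if _CODON_TABLE[nxt] == "*" and nxt != codon_b:
                through_stop = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        paths.append((sd, nd, through_stop))
    valid = [(s, n) for s, n, bad in paths if not bad]
    if not valid:
        valid = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; ``None`` when the correction is undefined (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


@dataclass
class KaKsResult:
    """NG86 counts and rates for one aligned CDS pair."""

    pair_id: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    omega: float | None
    n_codons: int
    n_skipped_codons: int

    def to_dict(self) -> dict:
        return {
            "pair_id": self.pair_id,
            "S_sites": self.s_sites,
            "N_sites": self.n_sites,
            "Sd": self.sd,
            "Nd": self.nd,
            "pS": self.ps,
            "pN": self.pn,
            "Ks": self.ks,
            "Ka": self.ka,
            "omega": self.omega,
            "n_codons": self.n_codons,
            "n_skipped_codons": self.n_skipped_codons,
        }


def ng86(cds_a: str, cds_b: str, pair_id: str = "") -> KaKsResult:
    """NG86 Ka, Ks and omega for one aligned CDS pair.

    Sequences must be equal-length and a multiple of 3. Codons containing
    gaps or ambiguity characters in either sequence are skipped (the count is
    reported); internal stop codons raise an error naming the codon index.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise DivergescanError(
            f"pair {pair_id or '?'}: sequence lengths differ ({len(cds_a)} vs {len(cds_b)})"
        )
    if len(cds_a) % 3 != 0:
        raise DivergescanError(f"pair {pair_id or '?'}: length {len(cds_a)} not a multiple of 3")

    n_codons = len(cds_a) // 3
    s_a = s_n = 0.0
    sd = nd = 0.0
    used = skipped = 0
    for i in range(n_codons):
        ca, cb = cds_a[3 * i:3 * i + 3], cds_b[3 * i:3 * i + 3]
        if (set(ca) | set(cb)) - set("ACGT"):
            skipped += 1
            continue
        for name, codon in (("a", ca), ("b", cb)):
            if _CODON_TABLE[codon] == "*" and i < n_codons - 1:
                raise DivergescanError(
                    f"pair {pair_id or '?'}: internal stop codon at codon index {i} "
                    f"in sequence {name}"
                )
        if _CODON_TABLE[ca] == "*" or _CODON_TABLE[cb] == "*":
            # terminal stop codons contribute no sites
            skipped += 1
            continue
        s_a += _codon_site_counts(ca)
        s_n += _codon_site_counts(cb)
        d_s, d_n = _codon_differences(ca, cb)
        sd += d_s
        nd += d_n
        used += 1

    s_sites = (s_a + s_n) / 2.0
    n_sites = 3.0 * used - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps) if s_sites > 0 else None
    ka = jukes_cantor(pn) if n_sites > 0 else None
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return KaKsResult(
        pair_id=pair_id,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ks=ks,
        ka=ka,
        omega=omega,
        n_codons=used,
        n_skipped_codons=skipped,
    )


def kaks_table(pairs: dict[str, tuple[str, str]]) -> pd.DataFrame:
    """Run :func:`ng86` over a collection of pairs and tabulate the results."""
    return pd.DataFrame([ng86(a, b, pair_id=pid).to_dict() for pid, (a, b) in pairs.items()])


def classify_selection(omega: float | None) -> str:
    """Selection regime from omega: positive (>1), neutral (=1), purifying (<1)."""
    if omega is None or (isinstance(omega, float) and np.isnan(omega)):
        return "undefined"
    if omega > 1:
        return "positive"
    if omega < 1:
        return "purifying"
    return "neutral"


def compare_distributions(
    omegas_a, omegas_b, truncate_at: float = 5.0
) -> dict:
    """Two-sample KS comparison of omega distributions with per-set summaries.

    The mode is the argmax of a Gaussian KDE (Silverman bandwidth) over values
    truncated to ``[0, truncate_at]``. Requires at least 5 defined omegas per
    set.
    """
    a = np.asarray([w for w in omegas_a if w is not None and np.isfinite(w)], float)
    b = np.asarray([w for w in omegas_b if w is not None and np.isfinite(w)], float)
    if len(a) < 5 or len(b) < 5:
        raise MissingDataError("need >= 5 defined omegas per set")
    ks_stat, p = stats.ks_2samp(a, b, method="asymp")

    def _summary(x: np.ndarray) -> dict:
        t = x[(x >= 0) & (x <= truncate_at)]
        grid = np.linspace(0, min(truncate_at, t.max() + 1e-9), 512)
        if len(np.unique(t)) > 1:
            kde = stats.gaussian_kde(t)
            mode = float(grid[np.argmax(kde(grid))])
        else:
            mode = float(t[0])
        return {"mean": float(x.mean()), "median": float(np.median(x)), "mode": mode}

    return {
        "ks_stat": float(ks_stat),
        "p": float(p),
        "summary_a": _summary(a),
        "summary_b": _summary(b),
    }
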