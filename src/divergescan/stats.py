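"""Multiple-testing helpers: Storey q-values and Benjamini–Hochberg FDR."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaNs propagate)."""
    p = np.asarray(pvalues, float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Smoother-based estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a grid and
    smoothed with a cubic polynomial; the estimate is the smoothed value at
    the largest lambda, clipped to (0, 1].
    """
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return min(pi0, 1.0) if pi0 > 0 else 1.0


def storey_qvalues(pvalues, min_tests_for_pi0: int = 100) -> np.ndarray:
    """Storey q-values with a smoother-based pi0 estimate.

    Falls back to pi0 = 1 (then identical to Benjamini–Hochberg) when fewer
    than ``min_tests_for_pi0`` tests are supplied or the estimate exceeds 1.
    NaN p-values yield NaN q-values and do not enter the estimate.
    """
    p = np.asarray(pvalues, float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    pi0 = estimate_pi0(pv) if m >= min_tests_for_pi0 else 1.0
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[ok] = qv
    return out
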