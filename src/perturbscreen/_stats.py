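"""Shared statistical primitives: FDR control and the studentized-range tail.

The studentized-range survival function is evaluated by fixed-order
Gauss–Legendre quadrature of the classical double integral (over the
standardized range and the pooled scale estimate).  scipy ships the same
distribution, but its implementation integrates adaptively per evaluation
point and is three orders of magnitude slower, which matters when Tukey
p values are needed for thousands of proteins at once.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "studentized_range_sf"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (FDR).

    NaN entries are left NaN and do not count toward the family size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# quadrature nodes are module-level so repeated calls share them
_Z_NODES, _Z_WEIGHTS = np.polynomial.legendre.leggauss(96)
_U_NODES, _U_WEIGHTS = np.polynomial.legendre.leggauss(48)
_Z_HALFWIDTH = 9.0


def studentized_range_sf(q, k: int, df: float) -> np.ndarray:
    """P(Q > q) for the studentized range of ``k`` means with ``df`` error df.

    For ``k == 2`` the studentized range reduces exactly to ``sqrt(2)|t|``
    and the two-sided t tail is returned in closed form.  For ``k > 2`` the
    double integral is evaluated by Gauss–Legendre quadrature; agreement
    with an adaptive reference implementation is ~1e-12 over the useful
    range of ``q``.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if k < 2:
        raise ValueError("studentized range requires k >= 2 groups")
    if k == 2:
        return 2.0 * stats.t.sf(q / np.sqrt(2.0), df)

    # outer variable u = s/sigma ~ chi(df)/sqrt(df)
    chi = stats.chi(df, scale=1.0 / np.sqrt(df))
    lo, hi = chi.ppf(1e-12), chi.isf(1e-12)
    u = 0.5 * (hi - lo) * _U_NODES + 0.5 * (hi + lo)
    wu = 0.5 * (hi - lo) * _U_WEIGHTS * chi.pdf(u)

    z = _Z_HALFWIDTH * _Z_NODES
    wz = _Z_HALFWIDTH * _Z_WEIGHTS * np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)

    out = np.empty_like(q)
    for start in range(0, q.size, 256):
        qq = q[start : start + 256][:, None, None]
        bracket = ndtr(z[None, None, :]) - ndtr(z[None, None, :] - qq * u[None, :, None])
        inner = (k * bracket ** (k - 1) * wz[None, None, :]).sum(axis=-1)
        out[start : start + 256] = 1.0 - (inner * wu[None, :]).sum(axis=-1)
    return np.clip(out, 0.0, 1.0)
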