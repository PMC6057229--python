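"""Small statistical helpers shared by the analysis modules."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import StatisticsError


def paired_t_p(a: np.ndarray, b: np.ndarray, axis: int = 0) -> np.ndarray:
    """Two-sided paired t-test p-values along ``axis`` (pairs = that axis).

    Degenerate pairs are resolved deterministically instead of propagating
    NaN: when every paired difference is zero the evidence against the null
    is nil (p = 1); when the differences are a nonzero constant the paired t
    statistic diverges (p = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[axis]
    if n < 2:
        raise StatisticsError(f"paired t-test needs >= 2 pairs, got {n}")
    d = np.moveaxis(a - b, axis, 0)
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_sd = sd == 0
    p = np.where(zero_sd & (mean == 0), 1.0, p)
    p = np.where(zero_sd & (mean != 0), 0.0, p)
    return p


def fdr_bh(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a flat p-value array.

    Returns ``(reject, p_adjusted)`` with the input shape preserved.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return reject.reshape(p.shape), p_adj.reshape(p.shape)
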