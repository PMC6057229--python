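"""Topographic analysis of variance (TANOVA).

Pattern similarity between two condition topographies is the cosine of the
angle between them viewed as vectors in sensor space,

    cos(theta) = (A . B) / (|A| |B|),

with 1 for identical patterns and -1 for polarity-reversed patterns. Because
both vectors are normalised, the measure is blind to response magnitude: it
isolates *where* the field is distributed, not how strong it is.

Significance comes from a permutation null of the cosine built by one of
three label-shuffling strategies:

* **Strategy 1** — pool every trial of every subject, re-assign condition
  labels at random (preserving the original per-condition counts), average
  the pooled pseudo-conditions directly.
* **Strategy 2** — re-assign trial labels within each subject (preserving
  per-subject counts), average to subject pseudo-ERPs, then across subjects.
* **Strategy 3** — compute subject x condition ERPs once, then per shuffle
  swap (or not, with probability 1/2) the two labels within each subject and
  re-average across subjects. When the full set of 2^S assignments is no
  larger than the requested number of shuffles it is enumerated exactly.

The p-value is the rank of the observed cosine in the null: small cosine =
dissimilar patterns, so the test is one-tailed on the left. Monte-Carlo nulls
use the add-one rule p = (1 + #{null <= observed}) / (1 + N) so p is never 0;
exhaustive nulls use p = #{null <= observed} / N (the identity assignment is
in the null, so p >= 1/N). Ties count as extreme (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import fdr_bh
from .epochs import EpochsDataset, Topography, Window, subject_erp_array, window_means, windows
from .errors import (
    DegenerateTopographyError,
    ParameterError,
    StatisticsError,
    StructuralError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "angle_measure",
    "null_distribution",
    "tanova",
    "correct",
    "NullDistribution",
    "TanovaResult",
]

_NORM_TOL = 1e-300


def angle_measure(a, b, center: bool = True) -> float:
    """Cosine of the high-dimensional angle between two topographies.

    When ``center`` is true (default) both vectors are average-referenced
    first, which makes the measure independent of the recording reference.
    """
    if isinstance(a, Topography) and isinstance(b, Topography):
        if a.sensor_names != b.sensor_names:
            raise StructuralError("topographies have different sensor sets/orders")
        a, b = a.values, b.values
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StructuralError(f"mismatched topography shapes {a.shape} vs {b.shape}")
    if center:
        a = a - a.mean()
        b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na <= _NORM_TOL or nb <= _NORM_TOL:
        raise DegenerateTopographyError("zero-norm topography: angle undefined")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def _cosine_rows(a: np.ndarray, b: np.ndarray, center: bool) -> np.ndarray:
    """Cosine along the last axis for stacked topographies (NaN where degenerate)."""
    if center:
        a = a - a.mean(axis=-1, keepdims=True)
        b = b - b.mean(axis=-1, keepdims=True)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.einsum("...i,...i->...", a, b) / (na * nb)
    cos = np.where((na <= _NORM_TOL) | (nb <= _NORM_TOL), np.nan, cos)
    return np.clip(cos, -1.0, 1.0)


@dataclass
class NullDistribution:
    """Permutation null of the angle measure for one window."""

    strategy: int
    n_shuffles: int
    values: np.ndarray
    seed: int
    window: Window
    exact: bool = field(default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_shuffles:
            raise ParameterError("null distribution length does not match n_shuffles")


@dataclass
class TanovaResult:
    """Observed cosine and permutation p per window for one comparison."""

    comparison: tuple[str, str]
    strategy: int
    n_shuffles: int
    seed: int
    windows: list[Window]
    table: pd.DataFrame  # window_start, window_end, cosine, p [, significant]
    correction: str | None = None

    def correct(self, method: str, alpha: float = 0.05, min_duration_ms: float = 20.0) -> "TanovaResult":
        table = correct(self.table, method=method, alpha=alpha, min_duration_ms=min_duration_ms)
        return dc_replace(self, table=table, correction=method)


# --------------------------------------------------------------------------
# Null generation
# --------------------------------------------------------------------------

def _trial_window_means(
    view: EpochsDataset, comparison: Sequence[str], wins: Sequence[Window]
):
    """Per-trial window-mean topographies, stacked per subject and pooled.

    Returns (pooled X of shape (N, W, sensors), per-subject index slices,
    per-subject per-condition counts).
    """
    per_subject = []
    counts = []
    for subject in view.subjects:
        blocks = []
        cnt = []
        for condition in comparison:
            block = view.block(subject, condition)  # (trials, sensors, times)
            wm = np.stack(
                [block[:, :, w.start_idx : w.end_idx].mean(axis=2) for w in wins],
                axis=1,
            )  # (trials, windows, sensors)
            blocks.append(wm)
            cnt.append(block.shape[0])
        per_subject.append(np.concatenate(blocks, axis=0))
        counts.append(tuple(cnt))
    return per_subject, counts


def _chunked(n_shuffles: int, workers: int, compute_one):
    """Evaluate ``compute_one(i)`` for every pre-drawn shuffle index.

    Randomness is always drawn up front, so the result is identical whatever
    the worker count; workers only split the deterministic computation.
    """
    if workers <= 1:
        return np.stack([compute_one(i) for i in range(n_shuffles)])
    from joblib import Parallel, delayed

    rows = Parallel(n_jobs=workers, prefer="threads")(
        delayed(compute_one)(i) for i in range(n_shuffles)
    )
    return np.stack(rows)


def _null_strategy_1(
    view, comparison, wins, n_shuffles, rng, workers: int = 1
) -> np.ndarray:
    """Pooled-trial label shuffle; pseudo-condition ERPs average pooled trials."""
    per_subject, counts = _trial_window_means(view, comparison, wins)
    pooled = np.concatenate(per_subject, axis=0)  # (N, W, sensors)
    n_total = pooled.shape[0]
    n_a = sum(c[0] for c in counts)
    perms = np.stack([rng.permutation(n_total) for _ in range(n_shuffles)])

    def one(i: int) -> np.ndarray:
        perm = perms[i]
        a = pooled[perm[:n_a]].mean(axis=0)  # (W, sensors)
        b = pooled[perm[n_a:]].mean(axis=0)
        return _cosine_rows(a, b, center=True)

    return _chunked(n_shuffles, workers, one)


def _null_strategy_2(
    view, comparison, wins, n_shuffles, rng, workers: int = 1
) -> np.ndarray:
    """Within-subject trial label shuffle, subject-then-group averaging."""
    per_subject, counts = _trial_window_means(view, comparison, wins)
    n_sub = len(per_subject)
    perms = [
        np.stack([rng.permutation(x.shape[0]) for _ in range(n_shuffles)])
        for x in per_subject
    ]

    def one(i: int) -> np.ndarray:
        a_sum = 0.0
        b_sum = 0.0
        for s in range(n_sub):
            x = per_subject[s]
            n_a = counts[s][0]
            perm = perms[s][i]
            a_sum = a_sum + x[perm[:n_a]].mean(axis=0)
            b_sum = b_sum + x[perm[n_a:]].mean(axis=0)
        return _cosine_rows(a_sum / n_sub, b_sum / n_sub, center=True)

    return _chunked(n_shuffles, workers, one)


def _strategy3_flips(n_subjects: int, n_shuffles: int, rng) -> tuple[np.ndarray, bool]:
    """Flip matrix for Strategy 3: exhaustive when 2^S <= n_shuffles."""
    if n_subjects <= 30 and 2**n_subjects <= n_shuffles:
        codes = np.arange(2**n_subjects, dtype=np.int64)
        flips = (codes[:, None] >> np.arange(n_subjects)) & 1
        return flips.astype(bool), True
    return rng.integers(0, 2, size=(n_shuffles, n_subjects)).astype(bool), False


def _null_strategy_3(view, comparison, wins, n_shuffles, rng) -> tuple[np.ndarray, bool]:
    """ERP-level per-subject label swap; vectorised over shuffles."""
    erps = subject_erp_array(view, comparison)  # (2, S, sensors, times)
    wm = window_means(erps, wins)  # (2, S, W, sensors)
    n_sub = wm.shape[1]
    flips, exact = _strategy3_flips(n_sub, n_shuffles, rng)
    e_a, e_b = wm[0], wm[1]  # (S, W, sensors)
    mean_a = e_a.mean(axis=0)
    mean_b = e_b.mean(axis=0)
    delta = (e_b - e_a).reshape(n_sub, -1)  # (S, W*sensors)
    shift = (flips.astype(float) @ delta).reshape(flips.shape[0], *mean_a.shape) / n_sub
    a = mean_a[None] + shift
    b = mean_b[None] - shift
    return _cosine_rows(a, b, center=True), exact


def _compute_null(view, comparison, wins, strategy, n_shuffles, seed, workers: int = 1):
    """Null cosines for all windows: array (n_draws, n_windows), exact flag."""
    if n_shuffles < 1:
        raise ParameterError(f"n_shuffles must be >= 1, got {n_shuffles}")
    for label in comparison:
        if label not in view.conditions:
            raise StructuralError(f"condition {label!r} not in view")
    rng = np.random.default_rng(seed)
    if strategy == 1:
        return _null_strategy_1(view, comparison, wins, n_shuffles, rng, workers), False
    if strategy == 2:
        return _null_strategy_2(view, comparison, wins, n_shuffles, rng, workers), False
    if strategy == 3:
        return _null_strategy_3(view, comparison, wins, n_shuffles, rng)
    raise ParameterError(f"strategy must be 1, 2 or 3, got {strategy}")


def null_distribution(
    view: EpochsDataset,
    comparison: tuple[str, str],
    window: Window,
    strategy: int = 3,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Permutation null of the angle measure for one window."""
    values, exact = _compute_null(view, comparison, [window], strategy, n_shuffles, seed)
    values = values[:, 0]
    return NullDistribution(
        strategy=strategy,
        n_shuffles=values.size,
        values=values,
        seed=seed,
        window=window,
        exact=exact,
    )


def rank_p(observed: float, null_values: np.ndarray, exact: bool = False) -> float:
    """One-tailed (left) rank p-value of an observed cosine in its null.

    Ties count as extreme. Monte-Carlo nulls use the add-one convention; an
    exhaustively enumerated null contains the identity assignment, so the
    plain rank fraction is already bounded away from zero.
    """
    null_values = np.asarray(null_values, dtype=float)
    b = int(np.sum(null_values <= observed + 1e-12))
    if exact:
        return max(b, 1) / null_values.size
    return (1 + b) / (1 + null_values.size)


def tanova(
    view: EpochsDataset,
    comparison: tuple[str, str],
    window_ms: float,
    strategy: int = 3,
    n_shuffles: int = 1000,
    seed: int = 0,
    center: bool = True,
    workers: int = 1,
) -> TanovaResult:
    """Windowed TANOVA: observed cosine and permutation p per window.

    The observed cosine compares the window-mean topographies of the
    group-averaged ERPs (unweighted mean of subject ERPs) of the two
    conditions. One shared set of shuffles serves every window.
    """
    if len(view.subjects) < 2 and strategy == 3:
        raise StatisticsError("TANOVA Strategy 3 needs >= 2 subjects")
    wins = windows(view.times, window_ms, view.sampling_rate)
    erps = subject_erp_array(view, comparison)  # (2, S, sensors, times)
    group = erps.mean(axis=1)  # (2, sensors, times)
    wm = window_means(group, wins)  # (2, W, sensors)
    observed = _cosine_rows(wm[0], wm[1], center=center)  # (W,)

    null, exact = _compute_null(view, comparison, wins, strategy, n_shuffles, seed, workers)
    p = np.empty(len(wins))
    for wi in range(len(wins)):
        if np.isnan(observed[wi]) or np.isnan(null[:, wi]).any():
            p[wi] = np.nan
            logger.warning(
                "degenerate topography in window [%s, %s) ms; p set to missing",
                wins[wi].start_ms,
                wins[wi].end_ms,
            )
            continue
        p[wi] = rank_p(observed[wi], null[:, wi], exact=exact)
    table = pd.DataFrame(
        {
            "window_start": [w.start_ms for w in wins],
            "window_end": [w.end_ms for w in wins],
            "comparison": " vs ".join(comparison),
            "cosine": observed,
            "p": p,
        }
    )
    return TanovaResult(
        comparison=tuple(comparison),
        strategy=strategy,
        n_shuffles=null.shape[0],
        seed=seed,
        windows=wins,
        table=table,
    )


# --------------------------------------------------------------------------
# Temporal correction
# --------------------------------------------------------------------------

def correct(
    table: pd.DataFrame,
    method: str = "cluster",
    alpha: float = 0.05,
    min_duration_ms: float = 20.0,
) -> pd.DataFrame:
    """Correct a windowed p-value series for multiple comparisons over time.

    ``cluster`` keeps a window only if it lies in a maximal run of
    consecutive windows with p < alpha whose total duration exceeds
    ``min_duration_ms`` (strictly); it requires a uniform window grid.
    ``fdr_bh`` applies Benjamini-Hochberg across all windows.
    """
    if "p" not in table.columns:
        raise ParameterError("table must have a 'p' column")
    table = table.copy()
    p = table["p"].to_numpy(dtype=float)
    if method == "fdr_bh":
        finite = np.isfinite(p)
        reject = np.zeros_like(p, dtype=bool)
        p_adj = np.full_like(p, np.nan)
        if finite.any():
            reject[finite], p_adj[finite] = fdr_bh(p[finite], alpha=alpha)
        table["p_fdr"] = p_adj
        table["significant_corrected"] = reject
        return table
    if method != "cluster":
        raise ParameterError(f"method must be 'cluster' or 'fdr_bh', got {method!r}")

    lengths = (table["window_end"] - table["window_start"]).to_numpy(dtype=float)
    if np.max(lengths) - np.min(lengths) > 1e-6:
        raise StructuralError("cluster correction requires a uniform window grid")
    win_len = float(lengths[0])
    raw = np.where(np.isfinite(p), p < alpha, False)
    keep = np.zeros_like(raw)
    i = 0
    n = raw.size
    while i < n:
        if raw[i]:
            j = i
            while j < n and raw[j]:
                j += 1
            duration = (j - i) * win_len
            if duration - min_duration_ms > 1e-9:
                keep[i:j] = True
            i = j
        else:
            i += 1
    table["significant_corrected"] = keep
    return table
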