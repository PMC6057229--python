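"""Global field power (GFP): per-topography magnitude and its group dynamics.

GFP of a topography is the root mean square of its average-referenced sensor
values,

    GFP(U) = sqrt( (1/n) * sum_i (U_i - mean(U))^2 ),

a reference-free, magnitude-only summary of a topography. Because GFP is a
nonlinear transform, the GFP of a group-averaged ERP is *not* the average of
the individual GFPs; group summaries here therefore always average the
per-subject GFP series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import fdr_bh, paired_t_p
from .epochs import EpochsDataset, windows
from .errors import ParameterError, StatisticsError

__all__ = ["gfp_of_topography", "gfp_series", "gfp_compare", "GfpSeries"]


def gfp_of_topography(values: np.ndarray) -> float:
    """GFP of one topography (µV): RMS of the mean-referenced sensor values."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ParameterError("GFP needs a 1-D topography with >= 2 sensors")
    centered = values - values.mean()
    return float(np.sqrt(np.mean(centered**2)))


@dataclass
class GfpSeries:
    """Per-subject, per-condition GFP over time, plus group summaries.

    ``values`` has shape ``(subjects, conditions, times)``. The group mean and
    SEM are across subjects, never the GFP of the group ERP.
    """

    subjects: list[str]
    conditions: list[str]
    times: np.ndarray
    sampling_rate: float
    values: np.ndarray

    @property
    def group_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def group_sem(self) -> np.ndarray:
        n = self.values.shape[0]
        return self.values.std(axis=0, ddof=1) / np.sqrt(n)

    def subject_table(self) -> pd.DataFrame:
        rows = []
        for i, subject in enumerate(self.subjects):
            for j, condition in enumerate(self.conditions):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_ms": self.times,
                            "subject": subject,
                            "condition": condition,
                            "gfp_uV": self.values[i, j],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def group_table(self) -> pd.DataFrame:
        rows = []
        mean, sem = self.group_mean, self.group_sem
        for j, condition in enumerate(self.conditions):
            rows.append(
                pd.DataFrame(
                    {
                        "time_ms": self.times,
                        "condition": condition,
                        "gfp_mean_uV": mean[j],
                        "gfp_sem_uV": sem[j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def gfp_series(view: EpochsDataset, level: str = "subject") -> GfpSeries:
    """GFP over time for every (subject, condition) ERP.

    ``level='trial'`` computes GFP per single trial before averaging the GFP
    series over trials; the default computes GFP on the subject ERP, the
    quantity used for group statistics.
    """
    if level not in ("subject", "trial"):
        raise ParameterError(f"level must be 'subject' or 'trial', got {level!r}")
    n_sub, n_cond = len(view.subjects), len(view.conditions)
    values = np.empty((n_sub, n_cond, view.n_times))
    for i, subject in enumerate(view.subjects):
        for j, condition in enumerate(view.conditions):
            block = view.block(subject, condition)
            if level == "subject":
                erp = block.mean(axis=0)
                values[i, j] = np.sqrt(
                    np.mean((erp - erp.mean(axis=0, keepdims=True)) ** 2, axis=0)
                )
            else:
                centered = block - block.mean(axis=1, keepdims=True)
                values[i, j] = np.sqrt(np.mean(centered**2, axis=1)).mean(axis=0)
    return GfpSeries(
        subjects=list(view.subjects),
        conditions=list(view.conditions),
        times=view.times.copy(),
        sampling_rate=view.sampling_rate,
        values=values,
    )


def gfp_compare(
    series: GfpSeries,
    comparison: tuple[str, str],
    window_ms: float,
    stat: str = "mean",
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Windowed paired t-test on subject GFP between two conditions.

    Per window, each subject contributes the window mean (or peak) of its GFP
    series in each condition; a two-sided paired t-test across subjects gives
    one p-value per window. Uncorrected by default; ``fdr=True`` applies
    Benjamini-Hochberg across windows.
    """
    if stat not in ("mean", "peak"):
        raise ParameterError(f"stat must be 'mean' or 'peak', got {stat!r}")
    if series.values.shape[0] < 2:
        raise StatisticsError("gfp_compare needs >= 2 subjects")
    try:
        idx = [series.conditions.index(c) for c in comparison]
    except ValueError as exc:
        raise ParameterError(
            f"comparison {comparison} not among conditions {series.conditions}"
        ) from exc
    wins = windows(series.times, window_ms, series.sampling_rate)
    rows = []
    stats_ab = []
    for cond_idx in idx:
        per_window = []
        for w in wins:
            chunk = series.values[:, cond_idx, w.start_idx : w.end_idx]
            per_window.append(chunk.mean(axis=1) if stat == "mean" else chunk.max(axis=1))
        stats_ab.append(np.stack(per_window, axis=1))  # (subjects, windows)
    a, b = stats_ab
    p = paired_t_p(a, b, axis=0)
    diff = (a - b).mean(axis=0)
    table = pd.DataFrame(
        {
            "window_start": [w.start_ms for w in wins],
            "window_end": [w.end_ms for w in wins],
            "comparison": " vs ".join(comparison),
            "gfp_diff_uV": diff,
            "p": p,
        }
    )
    if fdr:
        reject, p_adj = fdr_bh(p, alpha=alpha)
        table["p_fdr"] = p_adj
        table["significant"] = reject
    else:
        table["significant"] = p < alpha
    return table
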