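"""Distribution of significant sensors: per-sensor paired tests over windows.

For a pair of conditions, every sensor is tested across subjects (paired
t-test on the within-window mean of each subject's ERP) in successive time
windows. The number of significant sensors per window summarises the spatial
extent of the effect over time. By default p-values are uncorrected — this
analysis is descriptive, akin to "p < 0.05 uncorrected" maps — with optional
Benjamini-Hochberg correction across sensors and windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import fdr_bh, paired_t_p
from .epochs import EpochsDataset, Window, subject_erp_array, window_means, windows
from .errors import StatisticsError, StructuralError

__all__ = ["sensor_tests", "significant_channels_count", "SensorSigMap"]


@dataclass
class SensorSigMap:
    """Per-window, per-sensor differences, p-values and significance flags."""

    comparison: tuple[str, str]
    alpha: float
    windows: list[Window]
    sensor_names: list[str]
    diff: np.ndarray  # (windows, sensors) mean over subjects of cond1 - cond2, µV
    p: np.ndarray  # (windows, sensors)
    significant: np.ndarray  # (windows, sensors) bool
    fdr: bool = field(default=False)

    @property
    def sig_count(self) -> np.ndarray:
        return self.significant.sum(axis=1).astype(int)

    def table(self) -> pd.DataFrame:
        rows = []
        for wi, w in enumerate(self.windows):
            rows.append(
                pd.DataFrame(
                    {
                        "window_start": w.start_ms,
                        "window_end": w.end_ms,
                        "sensor": self.sensor_names,
                        "diff_uV": self.diff[wi],
                        "p": self.p[wi],
                        "significant": self.significant[wi],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def counts_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": [w.start_ms for w in self.windows],
                "window_end": [w.end_ms for w in self.windows],
                "comparison": " vs ".join(self.comparison),
                "sig_count": self.sig_count,
            }
        )


def sensor_tests(
    view: EpochsDataset,
    comparison: tuple[str, str],
    window_ms: float,
    alpha: float = 0.05,
    fdr: bool = False,
) -> SensorSigMap:
    """Paired t-test per sensor per window between two conditions.

    Each subject contributes, per sensor and window, the mean of its ERP over
    the window samples; the test is two-sided across subjects. The reported
    difference is the subject-mean of (condition1 − condition2).
    """
    cond1, cond2 = comparison
    for label in comparison:
        if label not in view.conditions:
            raise StructuralError(
                f"condition {label!r} not in view conditions {view.conditions}"
            )
    if len(view.subjects) < 2:
        raise StatisticsError("sensor_tests needs >= 2 subjects")
    wins = windows(view.times, window_ms, view.sampling_rate)
    erps = subject_erp_array(view, [cond1, cond2])  # (2, subjects, sensors, times)
    wm = window_means(erps, wins)  # (2, subjects, windows, sensors)
    a, b = wm[0], wm[1]
    p = paired_t_p(a, b, axis=0)  # (windows, sensors)
    diff = (a - b).mean(axis=0)
    if fdr:
        significant, _ = fdr_bh(p, alpha=alpha)
    else:
        significant = p < alpha
    return SensorSigMap(
        comparison=(cond1, cond2),
        alpha=alpha,
        windows=wins,
        sensor_names=list(view.sensor_names),
        diff=diff,
        p=p,
        significant=significant,
        fdr=fdr,
    )


def significant_channels_count(sig_map: SensorSigMap) -> pd.DataFrame:
    """Number of significant sensors per window (the count-over-time series)."""
    return sig_map.counts_table()
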