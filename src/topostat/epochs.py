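"""Multi-subject epoched EEG: data model, HDF5 round trip, extraction, ERPs, windows.

The central container is :class:`EpochsDataset`: per (subject, condition) a
``trials x sensors x timepoints`` array of potentials in microvolts, with a
shared sensor axis and a shared, uniformly sampled time axis in milliseconds.
Analyses never see raw trials directly; they receive a view produced by
:func:`extract`, which restricts conditions and time range (half-open in ms)
and, by default, re-references every trial to the average across sensors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

from .errors import (
    ConditionNotFoundError,
    EpochsFormatError,
    ParameterError,
    StructuralError,
    TimeRangeError,
)

logger = logging.getLogger(__name__)

#: tolerance on the uniformity of the time axis, in ms
_TIME_STEP_TOL = 1e-9


def _round_half_away(x: np.ndarray | float) -> np.ndarray | int:
    """Round half away from zero (values here are always >= 0)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class AnalysisTarget:
    """Declarative description of what to analyse.

    Parameters
    ----------
    conditions
        Condition labels to keep, in order.
    comparisons
        Ordered pairs of labels; each pair is one "A vs B" contrast.
    time_range
        ``(start_ms, end_ms)``; analyses use the half-open slice
        ``[start_ms, end_ms)``.
    window_ms
        Window length for windowed analyses.
    """

    conditions: tuple[str, ...]
    comparisons: tuple[tuple[str, str], ...]
    time_range: tuple[float, float]
    window_ms: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(
            self, "comparisons", tuple(tuple(c) for c in self.comparisons)
        )
        object.__setattr__(self, "time_range", tuple(float(t) for t in self.time_range))
        for pair in self.comparisons:
            if len(pair) != 2:
                raise ParameterError(f"comparison must be a pair, got {pair!r}")
            for label in pair:
                if label not in self.conditions:
                    raise ParameterError(
                        f"comparison label {label!r} not among conditions "
                        f"{list(self.conditions)}"
                    )
        start, end = self.time_range
        if not start < end:
            raise ParameterError(f"time_range start must be < end, got {start}..{end}")
        if not self.window_ms > 0:
            raise ParameterError(f"window_ms must be > 0, got {self.window_ms}")

    @classmethod
    def from_json(cls, source: str | Path | Mapping) -> "AnalysisTarget":
        """Build a target from a JSON document (path, JSON string, or mapping)."""
        if isinstance(source, Mapping):
            doc = source
        else:
            text = Path(source).read_text() if Path(str(source)).exists() else str(source)
            doc = json.loads(text)
        try:
            return cls(
                conditions=tuple(doc["conditions"]),
                comparisons=tuple(tuple(p) for p in doc.get("comparisons", [])),
                time_range=tuple(doc["time_range"]),
                window_ms=float(doc["window_ms"]),
            )
        except KeyError as exc:  # missing required key
            raise EpochsFormatError(f"analysis target is missing key {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "comparisons": [list(p) for p in self.comparisons],
            "time_range": list(self.time_range),
            "window_ms": self.window_ms,
        }


@dataclass(frozen=True)
class Topography:
    """One vector of per-sensor values over a time window."""

    values: np.ndarray
    sensor_names: tuple[str, ...]
    condition: str = ""
    subject: str = ""
    window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sensor_names", tuple(self.sensor_names))
        if values.ndim != 1 or values.size != len(self.sensor_names):
            raise StructuralError(
                f"topography has {values.size} values for "
                f"{len(self.sensor_names)} sensors"
            )
        if not np.all(np.isfinite(values)):
            raise StructuralError("topography contains non-finite values")


@dataclass
class EpochsDataset:
    """Multi-subject epoched EEG with shared sensor and time axes.

    ``data`` maps ``(subject, condition)`` to a ``(trials, sensors, timepoints)``
    float array in microvolts. Trial counts may differ between blocks; the
    sensor and time axes may not.
    """

    subjects: list[str]
    conditions: list[str]
    data: dict[tuple[str, str], np.ndarray]
    sensor_names: list[str]
    times: np.ndarray
    sampling_rate: float
    average_referenced: bool = field(default=False)

    def __post_init__(self) -> None:
        self.subjects = [str(s) for s in self.subjects]
        self.conditions = [str(c) for c in self.conditions]
        self.sensor_names = [str(s) for s in self.sensor_names]
        self.times = np.asarray(self.times, dtype=float)
        self.sampling_rate = float(self.sampling_rate)
        self.validate()

    # -- basic geometry ----------------------------------------------------
    @property
    def n_sensors(self) -> int:
        return len(self.sensor_names)

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def time_step(self) -> float:
        return 1000.0 / self.sampling_rate

    def block(self, subject: str, condition: str) -> np.ndarray:
        try:
            return self.data[(subject, condition)]
        except KeyError:
            raise StructuralError(
                f"no data block for subject {subject!r}, condition {condition!r}"
            ) from None

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise EpochsFormatError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.times.ndim != 1 or self.times.size < 2:
            raise EpochsFormatError("times must be a vector with >= 2 entries")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise EpochsFormatError("times must be strictly increasing")
        if np.max(np.abs(steps - self.time_step)) > _TIME_STEP_TOL:
            raise EpochsFormatError(
                "times step is not uniform at 1000/sampling_rate "
                f"({self.time_step:.6f} ms) within {_TIME_STEP_TOL} ms"
            )
        for subject in self.subjects:
            for condition in self.conditions:
                if (subject, condition) not in self.data:
                    raise StructuralError(
                        f"missing block for subject {subject!r}, "
                        f"condition {condition!r}"
                    )
        for key, block in self.data.items():
            block = np.asarray(block, dtype=float)
            self.data[key] = block
            if block.ndim != 3:
                raise StructuralError(f"block {key} is not 3-axis (trials, sensors, times)")
            trials, sensors, timepoints = block.shape
            if trials < 1:
                raise StructuralError(f"block {key} has no trials")
            if sensors != self.n_sensors:
                raise StructuralError(
                    f"block {key} has {sensors} sensors, dataset has {self.n_sensors}"
                )
            if timepoints != self.n_times:
                raise StructuralError(
                    f"block {key} has {timepoints} timepoints, dataset has {self.n_times}"
                )


# --------------------------------------------------------------------------
# HDF5 container (contract: root attrs sampling_rate/times/sensor_names,
# one group per subject, one dataset per condition)
# --------------------------------------------------------------------------

def save_epochs(dataset: EpochsDataset, path: str | Path) -> Path:
    """Write an :class:`EpochsDataset` to the epochs HDF5 layout."""
    path = Path(path)
    with h5py.File(path, "w") as handle:
        handle.attrs["sampling_rate"] = float(dataset.sampling_rate)
        handle.attrs["times"] = dataset.times.astype(float)
        handle.attrs["sensor_names"] = np.array(dataset.sensor_names, dtype=object)
        for subject in dataset.subjects:
            group = handle.create_group(subject)
            for condition in dataset.conditions:
                group.create_dataset(
                    condition, data=dataset.block(subject, condition).astype(np.float64)
                )
    return path


def load_epochs(path: str | Path, format: str = "hdf5") -> EpochsDataset:
    """Load a validated :class:`EpochsDataset` from the epochs HDF5 layout."""
    if format != "hdf5":
        raise ParameterError(f"unsupported epochs format {format!r}")
    path = Path(path)
    if not path.exists():
        raise EpochsFormatError(f"epochs file not found: {path}")
    with h5py.File(path, "r") as handle:
        for attr in ("sampling_rate", "times", "sensor_names"):
            if attr not in handle.attrs:
                raise EpochsFormatError(f"epochs file is missing root attribute {attr!r}")
        sampling_rate = float(handle.attrs["sampling_rate"])
        times = np.asarray(handle.attrs["times"], dtype=float)
        sensor_names = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in handle.attrs["sensor_names"]
        ]
        subjects = list(handle.keys())
        if not subjects:
            raise EpochsFormatError("epochs file contains no subject groups")
        conditions: list[str] | None = None
        data: dict[tuple[str, str], np.ndarray] = {}
        for subject in subjects:
            group = handle[subject]
            labels = list(group.keys())
            if conditions is None:
                conditions = labels
            elif set(labels) != set(conditions):
                raise StructuralError(
                    f"subject {subject!r} has conditions {labels}, "
                    f"expected {conditions}"
                )
            for condition in conditions:
                data[(subject, condition)] = np.asarray(group[condition], dtype=float)
    return EpochsDataset(
        subjects=subjects,
        conditions=list(conditions or []),
        data=data,
        sensor_names=sensor_names,
        times=times,
        sampling_rate=sampling_rate,
    )


# --------------------------------------------------------------------------
# Extraction
# --------------------------------------------------------------------------

def _time_index(times: np.ndarray, sampling_rate: float, t_ms: float) -> int:
    """Map a time in ms to a sample index (round half away from zero)."""
    return int(_round_half_away((t_ms - times[0]) * sampling_rate / 1000.0))


def extract(
    dataset: EpochsDataset,
    target: AnalysisTarget,
    average_reference: bool = True,
    sensors: Sequence[str] | None = None,
) -> EpochsDataset:
    """Restrict a dataset to the target's conditions and time range.

    Time slicing is half-open ``[start_ms, end_ms)`` so adjacent windows
    partition exactly. When ``average_reference`` is true (the default) every
    trial is re-referenced to its mean across the retained sensors at each
    timepoint; sensor subsetting (``sensors``) is applied *before*
    re-referencing.
    """
    for label in target.conditions:
        if label not in dataset.conditions:
            raise ConditionNotFoundError(
                f"condition {label!r} not in dataset; available: {dataset.conditions}"
            )
    start_ms, end_ms = target.time_range
    lo = _time_index(dataset.times, dataset.sampling_rate, start_ms)
    hi = _time_index(dataset.times, dataset.sampling_rate, end_ms)
    hi = min(hi, dataset.n_times)
    if lo < 0 or lo >= hi:
        raise TimeRangeError(
            f"time_range {target.time_range} selects no samples in "
            f"[{dataset.times[0]}, {dataset.times[-1] + dataset.time_step}) ms"
        )

    if sensors is None:
        sensor_idx = np.arange(dataset.n_sensors)
        kept_names = list(dataset.sensor_names)
    else:
        missing = [s for s in sensors if s not in dataset.sensor_names]
        if missing:
            raise StructuralError(f"unknown sensors requested: {missing}")
        sensor_idx = np.array([dataset.sensor_names.index(s) for s in sensors])
        kept_names = list(sensors)

    # centering is idempotent; skip the redundant pass (and its float noise)
    # when the data is already average-referenced over this sensor set
    rereference = average_reference and not (
        dataset.average_referenced and sensors is None
    )
    data: dict[tuple[str, str], np.ndarray] = {}
    for subject in dataset.subjects:
        for condition in target.conditions:
            block = dataset.block(subject, condition)[:, sensor_idx, lo:hi]
            if rereference:
                block = block - block.mean(axis=1, keepdims=True)
            data[(subject, condition)] = np.ascontiguousarray(block)

    return EpochsDataset(
        subjects=list(dataset.subjects),
        conditions=list(target.conditions),
        data=data,
        sensor_names=kept_names,
        times=dataset.times[lo:hi].copy(),
        sampling_rate=dataset.sampling_rate,
        average_referenced=average_reference or dataset.average_referenced,
    )


# --------------------------------------------------------------------------
# ERPs
# --------------------------------------------------------------------------

def erp(view: EpochsDataset, level: str = "subject") -> dict:
    """Trial-averaged responses.

    ``level='subject'`` returns ``{(subject, condition): sensors x times}``:
    the mean over trials of each block. ``level='group'`` returns
    ``{condition: sensors x times}``: the unweighted mean over subjects of the
    subject-level ERPs (each subject counts once regardless of trial count).
    """
    subject_level = {
        key: block.mean(axis=0) for key, block in view.data.items()
    }
    if level == "subject":
        return subject_level
    if level == "group":
        return {
            condition: np.mean(
                [subject_level[(s, condition)] for s in view.subjects], axis=0
            )
            for condition in view.conditions
        }
    raise ParameterError(f"level must be 'subject' or 'group', got {level!r}")


def subject_erp_array(view: EpochsDataset, conditions: Sequence[str] | None = None) -> np.ndarray:
    """Subject ERPs as one array, shape (conditions, subjects, sensors, times)."""
    conditions = list(conditions or view.conditions)
    return np.stack(
        [
            np.stack([view.block(s, c).mean(axis=0) for s in view.subjects])
            for c in conditions
        ]
    )


# --------------------------------------------------------------------------
# Windowing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """One analysis window: nominal ms bounds plus the sample index range."""

    start_ms: float
    end_ms: float
    start_idx: int
    end_idx: int  # exclusive

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def length_ms(self) -> float:
        return self.end_ms - self.start_ms


def windows(times: np.ndarray, window_ms: float, sampling_rate: float | None = None) -> list[Window]:
    """Tile a time axis with half-open windows of ``window_ms``.

    Windows tile left to right. A trailing remainder shorter than half a
    window (in samples) is dropped; a longer remainder is kept as a short
    final window. Every sample belongs to at most one window.
    """
    times = np.asarray(times, dtype=float)
    if sampling_rate is None:
        sampling_rate = 1000.0 / float(np.median(np.diff(times)))
    n = times.size
    t0 = times[0]
    samples_per_window = window_ms * sampling_rate / 1000.0
    if samples_per_window < 1.0 - 1e-9:
        raise ParameterError(
            f"window_ms={window_ms} is shorter than one sample period "
            f"({1000.0 / sampling_rate:.6f} ms)"
        )
    out: list[Window] = []
    k = 0
    while True:
        s_idx = int(_round_half_away(k * window_ms * sampling_rate / 1000.0))
        e_idx = int(_round_half_away((k + 1) * window_ms * sampling_rate / 1000.0))
        if e_idx > n or s_idx >= n:
            break
        out.append(Window(t0 + k * window_ms, t0 + (k + 1) * window_ms, s_idx, e_idx))
        k += 1
    rem_start = out[-1].end_idx if out else 0
    remainder = n - rem_start
    if remainder > 0 and remainder >= samples_per_window / 2.0:
        out.append(
            Window(
                t0 + k * window_ms,
                t0 + n * 1000.0 / sampling_rate,
                rem_start,
                n,
            )
        )
    elif remainder > 0:
        logger.debug("dropping trailing remainder of %d samples", remainder)
    return out


def window_means(erps: np.ndarray, wins: Sequence[Window]) -> np.ndarray:
    """Window-mean along the last (time) axis; output gains a window axis.

    ``erps`` has shape ``(..., sensors, times)``; the result has shape
    ``(..., windows, sensors)``.
    """
    stacked = np.stack(
        [erps[..., w.start_idx : w.end_idx].mean(axis=-1) for w in wins], axis=-2
    )
    return stacked


def drop_missing_sensors(dataset: EpochsDataset, bad: Sequence[str]) -> EpochsDataset:
    """Exclude sensors everywhere (no imputation); logs what was dropped."""
    bad = set(bad)
    keep = [s for s in dataset.sensor_names if s not in bad]
    if len(keep) == len(dataset.sensor_names):
        return dataset
    logger.warning("dropping sensors from all subjects: %s", sorted(bad))
    idx = np.array([dataset.sensor_names.index(s) for s in keep])
    data = {k: v[:, idx, :] for k, v in dataset.data.items()}
    return replace(dataset, data=data, sensor_names=keep)
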