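"""Synthetic multi-subject epoched EEG with separable magnitude/pattern effects.

The generator emulates a multi-subject ERP study: each source is a fixed
spatial pattern (a centred unit vector over sensors, spatially smooth over a
ring layout) driven by an amplitude time course in microvolts. Condition
effects are injected inside an ``[onset, offset)`` window and come in two
dissociable kinds:

* ``magnitude_scale`` multiplies the source amplitude — the topography is
  unchanged, only its strength (what GFP detects);
* ``pattern_swap`` replaces the source pattern with an alternative unit
  pattern — the strength is unchanged, only its spatial distribution (what
  TANOVA detects). Because all patterns are centred unit vectors, a swap is
  GFP-matched by construction.

Between-subject variability perturbs each subject's patterns (jitter +
renormalisation); trial-level variability scales amplitudes per trial; white
sensor noise is added per sample. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .epochs import EpochsDataset
from .errors import ParameterError

__all__ = [
    "Source",
    "Effect",
    "NoiseSpec",
    "SimulationSpec",
    "simulate",
    "null_spec",
    "demo_spec",
    "spec_from_json",
    "half_sine_course",
    "smooth_ring_pattern",
    "orthogonal_pattern",
]


def half_sine_course(times: np.ndarray, onset_ms: float, offset_ms: float, peak_uV: float) -> np.ndarray:
    """Half-sine amplitude bump: 0 outside [onset, offset), peak in the middle."""
    times = np.asarray(times, dtype=float)
    course = np.zeros_like(times)
    inside = (times >= onset_ms) & (times < offset_ms)
    phase = (times[inside] - onset_ms) / (offset_ms - onset_ms)
    course[inside] = peak_uV * np.sin(np.pi * phase)
    return course


def smooth_ring_pattern(n_sensors: int, rng: np.random.Generator, smooth: int | None = None) -> np.ndarray:
    """Centred unit pattern: circularly smoothed white noise over a sensor ring."""
    if smooth is None:
        smooth = max(3, n_sensors // 8)
    raw = rng.standard_normal(n_sensors)
    kernel = np.ones(smooth) / smooth
    padded = np.concatenate([raw[-(smooth - 1) :], raw]) if smooth > 1 else raw
    smoothed = np.convolve(padded, kernel, mode="valid")
    smoothed = smoothed - smoothed.mean()
    norm = np.linalg.norm(smoothed)
    if norm == 0:  # vanishingly unlikely; retry deterministically
        return smooth_ring_pattern(n_sensors, rng, smooth)
    return smoothed / norm


def orthogonal_pattern(base: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A centred unit pattern orthogonal to ``base`` (and to the constant vector)."""
    base = np.asarray(base, dtype=float)
    candidate = smooth_ring_pattern(base.size, rng)
    candidate = candidate - np.dot(candidate, base) * base
    candidate = candidate - candidate.mean()
    norm = np.linalg.norm(candidate)
    if norm < 1e-9:
        return orthogonal_pattern(base, rng)
    return candidate / norm


@dataclass(frozen=True)
class Source:
    """One neural source: unit spatial pattern x amplitude time course (µV)."""

    pattern: np.ndarray
    time_course: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", np.asarray(self.pattern, dtype=float))
        object.__setattr__(self, "time_course", np.asarray(self.time_course, dtype=float))
        norm = np.linalg.norm(self.pattern)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ParameterError(f"source pattern must have unit norm, got {norm:.6f}")


@dataclass(frozen=True)
class Effect:
    """A condition-specific manipulation inside [onset_ms, offset_ms)."""

    kind: str  # 'magnitude_scale' | 'pattern_swap'
    condition: str
    onset_ms: float
    offset_ms: float
    scale: float | None = None
    alternate_pattern: np.ndarray | None = None
    source: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("magnitude_scale", "pattern_swap"):
            raise ParameterError(f"unknown effect kind {self.kind!r}")
        if not self.onset_ms < self.offset_ms:
            raise ParameterError("effect onset_ms must be < offset_ms")
        if self.kind == "magnitude_scale" and self.scale is None:
            raise ParameterError("magnitude_scale effect requires 'scale'")
        if self.kind == "pattern_swap":
            if self.alternate_pattern is None:
                raise ParameterError("pattern_swap effect requires 'alternate_pattern'")
            alt = np.asarray(self.alternate_pattern, dtype=float)
            object.__setattr__(self, "alternate_pattern", alt)
            if not np.isclose(np.linalg.norm(alt), 1.0, atol=1e-6):
                raise ParameterError("alternate_pattern must have unit norm")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise levels: per-sample sensor noise (µV), subject pattern jitter
    (relative to the unit pattern), and per-trial amplitude jitter (relative)."""

    sensor_sd: float = 1.0
    subject_pattern_jitter_sd: float = 0.2
    trial_amplitude_jitter_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in ("sensor_sd", "subject_pattern_jitter_sd", "trial_amplitude_jitter_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulated study."""

    n_subjects: int = 16
    n_sensors: int = 70
    n_trials: tuple[int, ...] = (60, 60)  # per condition
    conditions: tuple[str, ...] = ("A", "B")
    sampling_rate: float = 250.0
    epoch_ms: tuple[float, float] = (-200.0, 600.0)
    sources: tuple[Source, ...] = ()
    effects: tuple[Effect, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_trials", tuple(int(n) for n in self.n_trials))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "effects", tuple(self.effects))
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.n_sensors < 2:
            raise ParameterError("n_sensors must be >= 2")
        if len(self.n_trials) != len(self.conditions):
            raise ParameterError("n_trials must give one count per condition")
        if any(n < 1 for n in self.n_trials):
            raise ParameterError("every condition needs >= 1 trial")
        if not self.epoch_ms[0] < self.epoch_ms[1]:
            raise ParameterError("epoch_ms start must be < end")
        for src in self.sources:
            if src.pattern.size != self.n_sensors:
                raise ParameterError("source pattern length must equal n_sensors")
            if src.time_course.size != self.n_times:
                raise ParameterError(
                    f"time_course length {src.time_course.size} != epoch samples {self.n_times}"
                )
        for eff in self.effects:
            if eff.condition not in self.conditions:
                raise ParameterError(f"effect condition {eff.condition!r} unknown")
            if not (self.epoch_ms[0] <= eff.onset_ms < eff.offset_ms <= self.epoch_ms[1]):
                raise ParameterError("effect window must lie within the epoch")
            if not 0 <= eff.source < max(len(self.sources), 1):
                raise ParameterError(f"effect source index {eff.source} out of range")
            if eff.alternate_pattern is not None and eff.alternate_pattern.size != self.n_sensors:
                raise ParameterError("alternate_pattern length must equal n_sensors")

    @property
    def n_times(self) -> int:
        span = self.epoch_ms[1] - self.epoch_ms[0]
        return int(round(span * self.sampling_rate / 1000.0))

    @property
    def times(self) -> np.ndarray:
        return self.epoch_ms[0] + np.arange(self.n_times) * 1000.0 / self.sampling_rate


def null_spec(base: SimulationSpec) -> SimulationSpec:
    """Strip all condition effects, keeping structure and noise (the global null)."""
    return replace(base, effects=())


def _jitter_pattern(pattern: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return pattern
    jittered = pattern + sd * rng.standard_normal(pattern.size)
    jittered = jittered - jittered.mean()
    norm = np.linalg.norm(jittered)
    if norm < 1e-12:
        return pattern
    return jittered / norm


def simulate(spec: SimulationSpec) -> EpochsDataset:
    """Generate a fully valid :class:`EpochsDataset` from a spec.

    Per trial: signal(t) = sum_k a_k(t) * scale_k(t) * jittered_pattern_k(t)
    plus white sensor noise; effects modify amplitude or pattern only inside
    their window and only for their condition.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.times
    n_t = times.size
    subjects = [f"S{i + 1:02d}" for i in range(spec.n_subjects)]
    data: dict[tuple[str, str], np.ndarray] = {}

    # per-effect boolean time masks
    masks = [
        (times >= eff.onset_ms) & (times < eff.offset_ms) for eff in spec.effects
    ]

    for subject in subjects:
        # subject-level pattern jitter, one draw per source (and per swap target)
        base_patterns = [
            _jitter_pattern(src.pattern, spec.noise.subject_pattern_jitter_sd, rng)
            for src in spec.sources
        ]
        alt_patterns = {}
        for ei, eff in enumerate(spec.effects):
            if eff.kind == "pattern_swap":
                alt_patterns[ei] = _jitter_pattern(
                    eff.alternate_pattern, spec.noise.subject_pattern_jitter_sd, rng
                )
        for condition, n_trials in zip(spec.conditions, spec.n_trials):
            # condition-specific pattern/amplitude per source, time-resolved
            pat = [np.tile(p[:, None], (1, n_t)) for p in base_patterns]
            amp = [np.tile(src.time_course, (1,)) .copy() for src in spec.sources]
            for ei, eff in enumerate(spec.effects):
                if eff.condition != condition:
                    continue
                if eff.kind == "magnitude_scale":
                    amp[eff.source] = amp[eff.source].copy()
                    amp[eff.source][masks[ei]] *= eff.scale
                else:
                    pat[eff.source] = pat[eff.source].copy()
                    pat[eff.source][:, masks[ei]] = alt_patterns[ei][:, None]
            block = np.empty((n_trials, spec.n_sensors, n_t))
            for trial in range(n_trials):
                signal = np.zeros((spec.n_sensors, n_t))
                for k in range(len(spec.sources)):
                    jitter = 1.0 + spec.noise.trial_amplitude_jitter_sd * rng.standard_normal()
                    signal += pat[k] * (amp[k] * jitter)[None, :]
                noise = spec.noise.sensor_sd * rng.standard_normal((spec.n_sensors, n_t))
                block[trial] = signal + noise
            data[(subject, condition)] = block

    return EpochsDataset(
        subjects=subjects,
        conditions=list(spec.conditions),
        data=data,
        sensor_names=[f"E{i + 1:02d}" for i in range(spec.n_sensors)],
        times=times,
        sampling_rate=spec.sampling_rate,
    )


def spec_from_json(source) -> SimulationSpec:
    """Build a :class:`SimulationSpec` from a JSON document (path/str/mapping).

    Patterns may be explicit vectors, ``"random"`` (drawn from the spec seed),
    or — for a ``pattern_swap`` alternate — ``"orthogonal"`` to its source's
    pattern. Time courses may be explicit vectors or
    ``{"kind": "half_sine", "onset_ms": ..., "offset_ms": ..., "peak_uV": ...}``.
    """
    import json
    from pathlib import Path

    if isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
    seed = int(doc.get("seed", 0))
    n_sensors = int(doc.get("n_sensors", 70))
    sampling_rate = float(doc.get("sampling_rate", 250.0))
    epoch_ms = tuple(doc.get("epoch_ms", (-200.0, 600.0)))
    n_times = int(round((epoch_ms[1] - epoch_ms[0]) * sampling_rate / 1000.0))
    times = epoch_ms[0] + np.arange(n_times) * 1000.0 / sampling_rate
    rng = np.random.default_rng(seed + 982451653)

    sources = []
    for sdoc in doc.get("sources", []):
        pattern = sdoc.get("pattern", "random")
        if isinstance(pattern, str):
            if pattern != "random":
                raise ParameterError(f"unknown pattern spec {pattern!r}")
            pattern = smooth_ring_pattern(n_sensors, rng)
        course = sdoc["time_course"]
        if isinstance(course, dict):
            if course.get("kind") != "half_sine":
                raise ParameterError(f"unknown time_course kind {course.get('kind')!r}")
            course = half_sine_course(
                times, course["onset_ms"], course["offset_ms"], course["peak_uV"]
            )
        sources.append(Source(pattern=np.asarray(pattern, float), time_course=course))

    effects = []
    for edoc in doc.get("effects", []):
        alternate = edoc.get("alternate_pattern")
        src_idx = int(edoc.get("source", 0))
        if isinstance(alternate, str):
            if alternate != "orthogonal":
                raise ParameterError(f"unknown alternate_pattern spec {alternate!r}")
            alternate = orthogonal_pattern(sources[src_idx].pattern, rng)
        effects.append(
            Effect(
                kind=edoc["kind"],
                condition=edoc["condition"],
                onset_ms=float(edoc["onset_ms"]),
                offset_ms=float(edoc["offset_ms"]),
                scale=edoc.get("scale"),
                alternate_pattern=alternate,
                source=src_idx,
            )
        )

    noise_doc = doc.get("noise", {})
    return SimulationSpec(
        n_subjects=int(doc.get("n_subjects", 16)),
        n_sensors=n_sensors,
        n_trials=tuple(doc.get("n_trials", (60, 60))),
        conditions=tuple(doc.get("conditions", ("A", "B"))),
        sampling_rate=sampling_rate,
        epoch_ms=epoch_ms,
        sources=tuple(sources),
        effects=tuple(effects),
        noise=NoiseSpec(
            sensor_sd=float(noise_doc.get("sensor_sd", 1.0)),
            subject_pattern_jitter_sd=float(noise_doc.get("subject_pattern_jitter_sd", 0.2)),
            trial_amplitude_jitter_sd=float(noise_doc.get("trial_amplitude_jitter_sd", 0.2)),
        ),
        seed=seed,
    )


def demo_spec(
    kind: str = "null",
    n_subjects: int = 16,
    n_sensors: int = 70,
    n_trials: Sequence[int] = (60, 60),
    sampling_rate: float = 250.0,
    epoch_ms: tuple[float, float] = (-200.0, 600.0),
    onset_ms: float = 200.0,
    offset_ms: float = 500.0,
    scale: float = 1.5,
    peak_uV: float = 20.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> SimulationSpec:
    """A ready-made two-condition study spec.

    ``kind`` selects the injected effect in condition A: ``'null'`` (none),
    ``'magnitude'`` (amplitude x ``scale`` inside the effect window) or
    ``'pattern'`` (swap to an orthogonal, GFP-matched pattern). One half-sine
    source spans the post-stimulus epoch with ~ERP-scale amplitudes.
    """
    rng = np.random.default_rng(seed + 982451653)  # pattern draws, distinct from data noise
    pattern = smooth_ring_pattern(n_sensors, rng)
    times = epoch_ms[0] + np.arange(
        int(round((epoch_ms[1] - epoch_ms[0]) * sampling_rate / 1000.0))
    ) * 1000.0 / sampling_rate
    source = Source(
        pattern=pattern,
        time_course=half_sine_course(times, max(0.0, epoch_ms[0]), epoch_ms[1], peak_uV),
    )
    effects: tuple[Effect, ...] = ()
    if kind == "magnitude":
        effects = (
            Effect("magnitude_scale", "A", onset_ms, offset_ms, scale=scale),
        )
    elif kind == "pattern":
        effects = (
            Effect(
                "pattern_swap",
                "A",
                onset_ms,
                offset_ms,
                alternate_pattern=orthogonal_pattern(pattern, rng),
            ),
        )
    elif kind != "null":
        raise ParameterError(f"kind must be 'null', 'magnitude' or 'pattern', got {kind!r}")
    return SimulationSpec(
        n_subjects=n_subjects,
        n_sensors=n_sensors,
        n_trials=tuple(n_trials),
        conditions=("A", "B"),
        sampling_rate=sampling_rate,
        epoch_ms=epoch_ms,
        sources=(source,),
        effects=effects,
        noise=noise or NoiseSpec(),
        seed=seed,
    )
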