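"""Simulation studies validating the statistical guarantees of the toolbox.

These routines generate synthetic studies and measure, from scratch, the
operating characteristics the methods are supposed to have:

* :func:`type1_study` — per-window false-positive rates of all four analyses
  under the global null (both conditions drawn identically);
* :func:`dissociation_study` — the magnitude/pattern dissociation: GFP should
  detect magnitude-only effects and ignore GFP-matched pattern effects, TANOVA
  the reverse, and decoding should detect both;
* :func:`onset_study` — recovery of an injected effect onset by the first
  cluster-corrected significant window of TANOVA and decoding;
* :func:`determinism_check` — byte-identity of result tables across repeated
  runs with the same seed and different worker counts.

Study sizes follow the simulated-study conventions of the package: 16
subjects, 32 sensors, 40 trials per condition at 100 Hz, 100 ms analysis
windows (20 ms for onset recovery). See docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .classification import ClassificationConfig, classify
from .epochs import AnalysisTarget, extract
from .gfp import gfp_compare, gfp_series
from .sensors import sensor_tests
from .simulate import NoiseSpec, demo_spec, simulate
from .tanova import tanova

__all__ = ["type1_study", "dissociation_study", "onset_study", "determinism_check"]

_PAIR = ("A", "B")


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % 2**31]


def type1_study(
    n_datasets: int = 200,
    seed: int = 0,
    n_subjects: int = 16,
    n_sensors: int = 32,
    n_trials: int = 40,
    alpha: float = 0.05,
    n_shuffles: int = 1000,
    include_classify: bool = True,
) -> dict:
    """False-positive rates under the global null.

    Each dataset: two identically-distributed conditions, 0-300 ms at 100 Hz,
    analysed in 100 ms windows (decoding on the first window only, to keep the
    study tractable; its rejection rate is still a per-window rate). Returns
    per-window rejection rates with their Monte-Carlo standard errors.
    """
    seeds = _child_seeds(seed, n_datasets)
    sensor_fraction, gfp_rej, tan_rej, clf_rej = [], [], [], []
    target = AnalysisTarget(_PAIR, (_PAIR,), (0.0, 300.0), 100.0)
    clf_target = AnalysisTarget(_PAIR, (_PAIR,), (0.0, 100.0), 100.0)
    for i, s in enumerate(seeds):
        spec = demo_spec(
            "null",
            n_subjects=n_subjects,
            n_sensors=n_sensors,
            n_trials=(n_trials, n_trials),
            sampling_rate=100.0,
            epoch_ms=(0.0, 300.0),
            seed=s,
        )
        dataset = simulate(spec)
        view = extract(dataset, target)
        sig_map = sensor_tests(view, _PAIR, 100.0, alpha=alpha)
        sensor_fraction.append(sig_map.significant.mean(axis=1))
        series = gfp_series(view)
        gfp_rej.append(
            gfp_compare(series, _PAIR, 100.0, alpha=alpha)["p"].to_numpy() < alpha
        )
        tan = tanova(view, _PAIR, 100.0, strategy=3, n_shuffles=n_shuffles, seed=s + 1)
        tan_rej.append(tan.table["p"].to_numpy() < alpha)
        if include_classify:
            clf_view = extract(dataset, clf_target)
            config = ClassificationConfig(window_ms=100.0, seed=s + 2)
            res = classify(clf_view, _PAIR, config, n_permutations=2000)
            clf_rej.append(res.table["p"].to_numpy() < alpha)
    out = {
        "alpha": alpha,
        "n_datasets": n_datasets,
        "sensor_fraction": np.asarray(sensor_fraction),
        "gfp_reject": np.asarray(gfp_rej),
        "tanova_reject": np.asarray(tan_rej),
    }
    if include_classify:
        out["classify_reject"] = np.asarray(clf_rej)
    # summary: mean rate and MC standard error per method (pooled over windows)
    rates = {}
    rates["sensor"] = (
        float(out["sensor_fraction"].mean()),
        float(out["sensor_fraction"].mean(axis=1).std(ddof=1) / np.sqrt(n_datasets)),
    )
    for key, name in (("gfp_reject", "gfp"), ("tanova_reject", "tanova")):
        rate = float(out[key].mean())
        rates[name] = (rate, float(np.sqrt(alpha * (1 - alpha) / out[key].size)))
    if include_classify:
        rate = float(out["classify_reject"].mean())
        rates["classify"] = (rate, float(np.sqrt(alpha * (1 - alpha) / out["classify_reject"].size)))
    out["rates"] = rates
    return out


def dissociation_study(
    n_reps: int = 100,
    seed: int = 0,
    n_subjects: int = 16,
    n_sensors: int = 32,
    n_trials: int = 40,
    alpha: float = 0.05,
    scale: float = 1.5,
    n_shuffles: int = 1000,
) -> dict:
    """Magnitude/pattern dissociation rates.

    Per replicate and effect kind: 0-200 ms epoch at 100 Hz, effect injected
    in condition A over 100-200 ms; 100 ms windows, statistics taken in the
    effect window. Magnitude effects scale the source amplitude x ``scale``;
    pattern effects swap to an orthogonal, GFP-matched pattern.
    """
    seeds = _child_seeds(seed, n_reps)
    target = AnalysisTarget(_PAIR, (_PAIR,), (0.0, 200.0), 100.0)
    clf_target = AnalysisTarget(_PAIR, (_PAIR,), (100.0, 200.0), 100.0)
    reject: dict[str, list] = {
        "gfp_magnitude": [], "tanova_magnitude": [], "classify_magnitude": [],
        "gfp_pattern": [], "tanova_pattern": [], "classify_pattern": [],
    }
    for s in seeds:
        for kind in ("magnitude", "pattern"):
            spec = demo_spec(
                kind,
                n_subjects=n_subjects,
                n_sensors=n_sensors,
                n_trials=(n_trials, n_trials),
                sampling_rate=100.0,
                epoch_ms=(0.0, 200.0),
                onset_ms=100.0,
                offset_ms=200.0,
                scale=scale,
                seed=s,
            )
            dataset = simulate(spec)
            view = extract(dataset, target)
            series = gfp_series(view)
            p_gfp = gfp_compare(series, _PAIR, 100.0, alpha=alpha)["p"].to_numpy()[-1]
            tan = tanova(view, _PAIR, 100.0, strategy=3, n_shuffles=n_shuffles, seed=s + 1)
            p_tan = tan.table["p"].to_numpy()[-1]
            clf_view = extract(dataset, clf_target)
            config = ClassificationConfig(window_ms=100.0, seed=s + 2)
            p_clf = classify(clf_view, _PAIR, config, n_permutations=2000).table["p"].to_numpy()[0]
            reject[f"gfp_{kind}"].append(p_gfp < alpha)
            reject[f"tanova_{kind}"].append(p_tan < alpha)
            reject[f"classify_{kind}"].append(p_clf < alpha)
    out = {name: float(np.mean(flags)) for name, flags in reject.items()}
    out["n_reps"] = n_reps
    out["alpha"] = alpha
    return out


def onset_study(
    n_reps: int = 20,
    seed: int = 0,
    n_subjects: int = 16,
    n_sensors: int = 32,
    n_trials: int = 40,
    onset_ms: float = 100.0,
    window_ms: float = 20.0,
    alpha: float = 0.01,
    n_shuffles: int = 1000,
) -> dict:
    """Recovery of an injected effect onset from corrected p-series.

    Strong pattern effect (orthogonal swap, low noise) from ``onset_ms`` to
    the end of a 0-200 ms epoch; 20 ms windows, cluster correction with a
    20 ms minimum duration at alpha = 0.01. A replicate counts as a hit for a
    method when its first corrected-significant window starts within one
    window length of the injected onset.
    """
    seeds = _child_seeds(seed, n_reps)
    target = AnalysisTarget(_PAIR, (_PAIR,), (0.0, 200.0), window_ms)
    noise = NoiseSpec(sensor_sd=0.5, subject_pattern_jitter_sd=0.1, trial_amplitude_jitter_sd=0.1)
    hits = {"tanova": [], "classify": []}
    first = {"tanova": [], "classify": []}
    for s in seeds:
        spec = demo_spec(
            "pattern",
            n_subjects=n_subjects,
            n_sensors=n_sensors,
            n_trials=(n_trials, n_trials),
            sampling_rate=100.0,
            epoch_ms=(0.0, 200.0),
            onset_ms=onset_ms,
            offset_ms=200.0,
            noise=noise,
            seed=s,
        )
        view = extract(simulate(spec), target)
        tan = tanova(view, _PAIR, window_ms, strategy=3, n_shuffles=n_shuffles, seed=s + 1)
        tan = tan.correct("cluster", alpha=alpha, min_duration_ms=20.0)
        config = ClassificationConfig(window_ms=window_ms, seed=s + 2)
        clf = classify(view, _PAIR, config, n_permutations=2000)
        clf = clf.correct("cluster", alpha=alpha, min_duration_ms=20.0)
        for name, table in (("tanova", tan.table), ("classify", clf.table)):
            sig = table[table["significant_corrected"].astype(bool)]
            if sig.empty:
                first[name].append(np.nan)
                hits[name].append(False)
            else:
                start = float(sig["window_start"].iloc[0])
                first[name].append(start)
                hits[name].append(abs(start - onset_ms) <= window_ms + 1e-9)
    return {
        "n_reps": n_reps,
        "onset_ms": onset_ms,
        "window_ms": window_ms,
        "first_tanova": first["tanova"],
        "first_classify": first["classify"],
        "hit_rate_tanova": float(np.mean(hits["tanova"])),
        "hit_rate_classify": float(np.mean(hits["classify"])),
    }


def determinism_check(seed: int = 0) -> bool:
    """Same seed, repeated runs and different worker counts => identical tables."""
    import pandas as pd

    spec = demo_spec(
        "pattern",
        n_subjects=8,
        n_sensors=16,
        n_trials=(20, 20),
        sampling_rate=100.0,
        epoch_ms=(0.0, 200.0),
        onset_ms=100.0,
        offset_ms=200.0,
        seed=seed,
    )
    target = AnalysisTarget(_PAIR, (_PAIR,), (0.0, 200.0), 50.0)
    tables = []
    for workers in (1, 2, 1):
        view = extract(simulate(spec), target)
        res = tanova(view, _PAIR, 50.0, strategy=2, n_shuffles=200, seed=seed + 1, workers=workers)
        tables.append(res.table.to_csv(sep="\t", index=False))
        config = ClassificationConfig(window_ms=100.0, seed=seed + 2)
        clf_view = extract(simulate(spec), AnalysisTarget(_PAIR, (_PAIR,), (100.0, 200.0), 100.0))
        tables.append(classify(clf_view, _PAIR, config, n_permutations=500).table.to_csv(sep="\t", index=False))
    return tables[0] == tables[2] == tables[4] and tables[1] == tables[3] == tables[5]
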