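"""Sliding-window pattern classification with group-level permutation inference.

Per subject and time window, single trials are reduced to window-mean
topographies (one sample per trial, sensors as features) and a binary
classifier is scored by AUC over repeated stratified random train/test
splits. Per window, the subject scores are tested against the chance level
0.5 with a one-sided sign-flip permutation test. Decoding is sensitive to
both magnitude and pattern differences, complementing GFP (magnitude only)
and TANOVA (pattern only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler

from .epochs import EpochsDataset, Window, windows
from .errors import ParameterError, SampleSizeError, StatisticsError, StructuralError
from .tanova import correct as correct_pvalues

__all__ = [
    "ClassificationConfig",
    "ClassificationResult",
    "window_samples",
    "subject_score",
    "group_test",
    "classify",
]

_MIN_TRIALS_PER_CONDITION = 4


@dataclass(frozen=True)
class ClassificationConfig:
    """Decoding configuration.

    ``model`` is either ``"logistic_regression"`` (L2, C=1.0, features
    standardised on the training folds only) or any estimator exposing
    ``fit(X, y)`` plus ``decision_function`` or ``predict_proba``.
    """

    model: Any = "logistic_regression"
    window_ms: float = 5.0
    test_size: float = 0.3
    folds: int = 25
    score: str = "auc"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_size < 1.0:
            raise ParameterError(f"test_size must be in (0, 1), got {self.test_size}")
        if self.folds < 2:
            raise ParameterError(f"folds must be >= 2, got {self.folds}")
        if self.score != "auc":
            raise ParameterError(f"only 'auc' scoring is supported, got {self.score!r}")


@dataclass
class ClassificationResult:
    """Per-subject per-window AUC and per-window group p-values."""

    comparison: tuple[str, str]
    config: ClassificationConfig
    windows: list[Window]
    subjects: list[str]
    scores: np.ndarray  # (subjects, windows)
    table: pd.DataFrame  # window_start, window_end, mean_auc, p [, significant]
    n_permutations: int = 0
    correction: str | None = None

    def scores_table(self) -> pd.DataFrame:
        rows = []
        for si, subject in enumerate(self.subjects):
            rows.append(
                pd.DataFrame(
                    {
                        "window_start": [w.start_ms for w in self.windows],
                        "window_end": [w.end_ms for w in self.windows],
                        "subject": subject,
                        "auc": self.scores[si],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def correct(self, method: str, alpha: float = 0.05, min_duration_ms: float = 20.0) -> "ClassificationResult":
        from dataclasses import replace

        table = correct_pvalues(self.table, method=method, alpha=alpha, min_duration_ms=min_duration_ms)
        return replace(self, table=table, correction=method)


def window_samples(
    view: EpochsDataset,
    subject: str,
    comparison: tuple[str, str],
    window: Window,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled sample set for one subject and window.

    One sample per trial: the window-mean topography (sensors as features).
    Labels: 1 for the first condition of the pair, 0 for the second.
    """
    xs, ys = [], []
    for label_value, condition in ((1, comparison[0]), (0, comparison[1])):
        if condition not in view.conditions:
            raise StructuralError(f"condition {condition!r} not in view")
        block = view.block(subject, condition)
        if block.shape[0] < _MIN_TRIALS_PER_CONDITION:
            raise SampleSizeError(
                f"subject {subject!r}, window [{window.start_ms}, {window.end_ms}) ms: "
                f"condition {condition!r} has {block.shape[0]} trials "
                f"(need >= {_MIN_TRIALS_PER_CONDITION})"
            )
        wm = block[:, :, window.start_idx : window.end_idx].mean(axis=2)
        xs.append(wm)
        ys.append(np.full(wm.shape[0], label_value))
    return np.concatenate(xs, axis=0), np.concatenate(ys)


def _make_estimator(model: Any):
    if model == "logistic_regression":
        # liblinear solves the primal L2 problem deterministically and is the
        # fastest exact solver at these sample sizes (tens of trials)
        return LogisticRegression(C=1.0, solver="liblinear", random_state=0)
    if hasattr(model, "fit"):
        import copy

        return copy.deepcopy(model)
    raise ParameterError(f"unsupported model {model!r}")


def _positive_scores(estimator, x: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(x), dtype=float)
    if hasattr(estimator, "predict_proba"):
        return np.asarray(estimator.predict_proba(x), dtype=float)[:, 1]
    raise ParameterError("model must expose decision_function or predict_proba")


def subject_score(samples: tuple[np.ndarray, np.ndarray], config: ClassificationConfig) -> float:
    """Mean AUC over repeated stratified random splits for one sample set."""
    x, y = samples
    classes = np.unique(y)
    if classes.size != 2:
        raise ParameterError(f"need exactly 2 classes, got {classes.size}")
    splitter = StratifiedShuffleSplit(
        n_splits=config.folds, test_size=config.test_size, random_state=config.seed
    )
    aucs = []
    for train, test in splitter.split(x, y):
        scaler = StandardScaler().fit(x[train])
        estimator = _make_estimator(config.model)
        estimator.fit(scaler.transform(x[train]), y[train])
        scores = _positive_scores(estimator, scaler.transform(x[test]))
        aucs.append(roc_auc_score(y[test], scores))
    return float(np.mean(aucs))


def group_test(
    scores: np.ndarray,
    chance: float = 0.5,
    n_permutations: int = 10000,
    seed: int = 0,
) -> float:
    """One-sided sign-flip permutation test of mean(score) > chance.

    The statistic is the mean deviation from chance; the null flips each
    subject's deviation sign independently. All 2^S assignments are
    enumerated when feasible (p = #{null >= observed}/2^S, never 0 since the
    identity is in the null); otherwise Monte-Carlo sampling with the add-one
    rule p = (1 + #{null >= observed}) / (1 + N).
    """
    d = np.asarray(scores, dtype=float) - chance
    n_sub = d.size
    if n_sub < 2:
        raise StatisticsError("group_test needs >= 2 subjects")
    observed = d.mean()
    if n_sub <= 30 and 2**n_sub <= n_permutations:
        codes = np.arange(2**n_sub, dtype=np.int64)
        signs = 1.0 - 2.0 * ((codes[:, None] >> np.arange(n_sub)) & 1)
        null = signs @ d / n_sub
        b = int(np.sum(null >= observed - 1e-12))
        return max(b, 1) / null.size
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_sub))
    null = signs @ d / n_sub
    b = int(np.sum(null >= observed - 1e-12))
    return (1 + b) / (1 + n_permutations)


def classify(
    view: EpochsDataset,
    comparison: tuple[str, str],
    config: ClassificationConfig,
    n_permutations: int = 10000,
) -> ClassificationResult:
    """Sliding-window decoding with a group-level test vs chance per window."""
    wins = windows(view.times, config.window_ms, view.sampling_rate)
    n_sub = len(view.subjects)
    scores = np.empty((n_sub, len(wins)))
    root = np.random.SeedSequence(config.seed)
    split_seeds = root.spawn(n_sub * len(wins))
    perm_seeds = root.spawn(len(wins))
    for si, subject in enumerate(view.subjects):
        for wi, window in enumerate(wins):
            samples = window_samples(view, subject, comparison, window)
            state = int(split_seeds[si * len(wins) + wi].generate_state(1)[0] % 2**31)
            cfg = ClassificationConfig(
                model=config.model,
                window_ms=config.window_ms,
                test_size=config.test_size,
                folds=config.folds,
                score=config.score,
                seed=state,
            )
            scores[si, wi] = subject_score(samples, cfg)
    p = np.empty(len(wins))
    for wi in range(len(wins)):
        state = int(perm_seeds[wi].generate_state(1)[0] % 2**31)
        p[wi] = group_test(scores[:, wi], 0.5, n_permutations, seed=state)
    table = pd.DataFrame(
        {
            "window_start": [w.start_ms for w in wins],
            "window_end": [w.end_ms for w in wins],
            "comparison": " vs ".join(comparison),
            "mean_auc": scores.mean(axis=0),
            "p": p,
        }
    )
    return ClassificationResult(
        comparison=tuple(comparison),
        config=config,
        windows=wins,
        subjects=list(view.subjects),
        scores=scores,
        table=table,
        n_permutations=n_permutations,
    )
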