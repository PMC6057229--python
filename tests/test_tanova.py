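import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import topostat as ts
from topostat.errors import DegenerateTopographyError, StructuralError
from topostat.tanova import rank_p

from conftest import make_dataset


class TestAngleMeasure:
    def test_identical_patterns(self):
        v = np.array([1.0, 2.0, -3.0, 0.5])
        assert ts.angle_measure(v, v) == pytest.approx(1.0)

    def test_opposite_patterns(self):
        v = np.array([1.0, 2.0, -3.0, 0.5])
        assert ts.angle_measure(v, -v) == pytest.approx(-1.0)

    def test_hand_oracle_after_centering(self):
        # unit basis vectors in n=4: centered cosine is exactly -1/3
        a = np.array([1.0, 0.0, 0.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, 0.0])
        assert ts.angle_measure(a, b, center=True) == pytest.approx(-1.0 / 3.0, abs=1e-15)

    @given(
        v=arrays(float, 6, elements=st.floats(-10, 10)),
        lam=st.floats(0.01, 100),
    )
    def test_positive_scale_invariance(self, v, lam):
        w = v + np.arange(6)  # avoid exactly proportional/degenerate pairs
        if np.ptp(v) < 1e-6 or np.ptp(w) < 1e-6:
            return
        assert ts.angle_measure(v, lam * w) == pytest.approx(
            ts.angle_measure(v, w), rel=1e-9, abs=1e-9
        )

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert ts.angle_measure(a, b) == pytest.approx(ts.angle_measure(b, a))

    def test_zero_norm_rejected(self):
        with pytest.raises(DegenerateTopographyError):
            ts.angle_measure(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]), center=True)

    def test_mismatched_sensors_rejected(self):
        with pytest.raises(StructuralError):
            ts.angle_measure(np.ones(4), np.ones(5), center=False)


class TestRankP:
    def test_below_all_nulls(self):
        null = np.linspace(0.5, 1.0, 999)
        assert rank_p(0.0, null) == pytest.approx(1.0 / 1000.0)

    def test_at_null_maximum(self):
        null = np.linspace(-1.0, 1.0, 999)
        assert rank_p(1.0, null) == pytest.approx(1.0)

    def test_monotone_in_observed(self):
        null = np.random.default_rng(1).uniform(-1, 1, 500)
        ps = [rank_p(obs, null) for obs in np.linspace(-1, 1, 21)]
        assert all(p1 <= p2 for p1, p2 in zip(ps, ps[1:]))
        assert min(ps) > 0


class TestNullDistribution:
    def test_strategy3_two_subjects_matches_enumeration(self):
        view = make_dataset(n_subjects=2, n_trials=5, n_sensors=6, n_times=20, t0=0.0, seed=2)
        wins = ts.windows(view.times, 20.0, view.sampling_rate)
        null = ts.null_distribution(view, ("A", "B"), wins[0], strategy=3, n_shuffles=1000, seed=0)
        assert null.exact and null.n_shuffles == 4

        # independent brute force over the 2^2 label assignments
        erps = {
            (s, c): view.block(s, c).mean(axis=0)[:, wins[0].start_idx : wins[0].end_idx].mean(axis=1)
            for s in view.subjects
            for c in ("A", "B")
        }
        expected = []
        for flips in itertools.product([False, True], repeat=2):
            a = np.mean(
                [erps[(s, "B" if f else "A")] for s, f in zip(view.subjects, flips)], axis=0
            )
            b = np.mean(
                [erps[(s, "A" if f else "B")] for s, f in zip(view.subjects, flips)], axis=0
            )
            expected.append(ts.angle_measure(a, b, center=True))
        np.testing.assert_allclose(np.sort(null.values), np.sort(expected), atol=1e-12)

    def test_all_identical_trials_null_cosine_one(self):
        view = make_dataset(n_subjects=2, n_trials=3, n_sensors=5, n_times=10, t0=0.0)
        trial = np.arange(5.0)[:, None] * np.ones(10)
        for key in view.data:
            view.data[key] = np.stack([trial] * 3)
        wins = ts.windows(view.times, 10.0, view.sampling_rate)
        for strategy in (1, 2, 3):
            null = ts.null_distribution(view, ("A", "B"), wins[0], strategy=strategy,
                                        n_shuffles=50, seed=1)
            np.testing.assert_allclose(null.values, 1.0, atol=1e-12)

    def test_strategies_agree_on_null_data(self):
        """On balanced, fully exchangeable null data the three strategies
        estimate the same null: paired over replicate datasets, their null
        means are statistically indistinguishable (3 SEM).

        The comparison is across datasets because, within one dataset, the
        ERP-level null (Strategy 3) conditions on the subject ERPs while the
        trial-level nulls re-average trials; their means differ by quenched
        trial noise that no number of shuffles removes.
        """
        pairs = list(itertools.combinations((1, 2, 3), 2))
        diffs = {pair: [] for pair in pairs}
        for seed in range(20):
            view = make_dataset(n_subjects=8, n_trials=10, n_sensors=8,
                                n_times=10, t0=0.0, seed=100 + seed)
            win = ts.windows(view.times, 10.0, view.sampling_rate)[0]
            nulls = {
                s: ts.null_distribution(view, ("A", "B"), win, strategy=s,
                                        n_shuffles=200, seed=seed)
                for s in (1, 2, 3)
            }
            for s1, s2 in pairs:
                diffs[(s1, s2)].append(
                    nulls[s1].values.mean() - nulls[s2].values.mean()
                )
        for pair, d in diffs.items():
            d = np.asarray(d)
            sem = d.std(ddof=1) / np.sqrt(d.size)
            assert abs(d.mean()) <= 3 * sem, (pair, d.mean(), sem)


class TestTanova:
    def test_type_one_near_alpha_small_smoke(self, study_view):
        res = ts.tanova(study_view, ("A", "B"), 100.0, strategy=3, n_shuffles=500, seed=3)
        assert np.all((res.table["p"] > 0) & (res.table["p"] <= 1))

    def test_pattern_effect_detected_magnitude_not(self):
        p_pat, p_mag = [], []
        for seed in range(5):
            for kind, sink in (("pattern", p_pat), ("magnitude", p_mag)):
                spec = ts.demo_spec(kind, n_subjects=12, n_sensors=16, n_trials=(20, 20),
                                    sampling_rate=100.0, epoch_ms=(0.0, 200.0),
                                    onset_ms=100.0, offset_ms=200.0, seed=seed + 20)
                view = ts.extract(
                    ts.simulate(spec),
                    ts.AnalysisTarget(("A", "B"), (("A", "B"),), (0.0, 200.0), 100.0),
                )
                res = ts.tanova(view, ("A", "B"), 100.0, strategy=3, n_shuffles=1000, seed=seed)
                sink.append(res.table["p"].to_numpy()[-1])
        assert np.mean(np.array(p_pat) < 0.01) >= 0.8
        assert np.mean(np.array(p_mag) < 0.05) <= 0.4


class TestCorrect:
    def _series(self, p_values, window_ms=5.0):
        starts = np.arange(len(p_values)) * window_ms
        return pd.DataFrame(
            {
                "window_start": starts,
                "window_end": starts + window_ms,
                "p": p_values,
            }
        )

    def test_cluster_keeps_25ms_run_drops_15ms_run(self):
        p = np.ones(20)
        p[2:7] = 0.01  # 5 windows x 5 ms = 25 ms > 20 ms
        p[12:15] = 0.01  # 3 windows x 5 ms = 15 ms < 20 ms
        out = ts.correct(self._series(p), "cluster", alpha=0.05, min_duration_ms=20.0)
        sig = out["significant_corrected"].to_numpy()
        assert sig[2:7].all()
        assert not sig[12:15].any()
        assert not sig[:2].any() and not sig[7:12].any() and not sig[15:].any()

    def test_exactly_min_duration_not_kept(self):
        p = np.ones(10)
        p[0:4] = 0.01  # exactly 20 ms: "longer than" excludes it
        out = ts.correct(self._series(p), "cluster", alpha=0.05, min_duration_ms=20.0)
        assert not out["significant_corrected"].any()

    def test_all_p_one_nothing_significant(self):
        for method in ("cluster", "fdr_bh"):
            out = ts.correct(self._series(np.ones(8)), method, alpha=0.05)
            assert not out["significant_corrected"].any()

    def test_bh_hand_example(self):
        out = ts.correct(self._series([0.001, 0.02, 0.03, 0.9]), "fdr_bh", alpha=0.05)
        np.testing.assert_array_equal(
            out["significant_corrected"].to_numpy(), [True, True, True, False]
        )

    def test_cluster_requires_uniform_grid(self):
        table = self._series([0.01, 0.01, 0.01])
        table.loc[2, "window_end"] += 3.0
        with pytest.raises(StructuralError):
            ts.correct(table, "cluster")

    def test_corrected_subset_of_uncorrected(self, study_view):
        res = ts.tanova(study_view, ("A", "B"), 50.0, strategy=3, n_shuffles=200, seed=9)
        out = res.correct("cluster", alpha=0.5).table
        sig_corr = out["significant_corrected"].to_numpy()
        uncorr = out["p"].to_numpy() < 0.5
        assert np.all(uncorr[sig_corr])
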