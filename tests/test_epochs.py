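import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import topostat as ts
from topostat.errors import (
    ConditionNotFoundError,
    EpochsFormatError,
    ParameterError,
    TimeRangeError,
)

from conftest import make_dataset


class TestDatasetAndIO:
    def test_roundtrip_preserves_everything(self, small_dataset, tmp_path):
        path = ts.save_epochs(small_dataset, tmp_path / "epochs.h5")
        loaded = ts.load_epochs(path)
        assert loaded.subjects == small_dataset.subjects
        assert loaded.conditions == small_dataset.conditions
        assert loaded.sensor_names == small_dataset.sensor_names
        assert loaded.sampling_rate == small_dataset.sampling_rate
        np.testing.assert_allclose(loaded.times, small_dataset.times, atol=1e-6)
        for key, block in small_dataset.data.items():
            assert loaded.data[key].shape == (10, 4, 801)
            np.testing.assert_allclose(loaded.data[key], block, atol=1e-6)

    def test_missing_sampling_rate_is_format_error(self, small_dataset, tmp_path):
        import h5py

        path = ts.save_epochs(small_dataset, tmp_path / "epochs.h5")
        with h5py.File(path, "a") as handle:
            del handle.attrs["sampling_rate"]
        with pytest.raises(EpochsFormatError, match="sampling_rate"):
            ts.load_epochs(path)

    def test_nonuniform_times_rejected(self):
        with pytest.raises(EpochsFormatError):
            ts.EpochsDataset(
                subjects=["S01"],
                conditions=["A"],
                data={("S01", "A"): np.zeros((1, 2, 3))},
                sensor_names=["E1", "E2"],
                times=np.array([0.0, 1.0, 3.0]),
                sampling_rate=1000.0,
            )

    def test_inconsistent_sensor_axis_rejected(self):
        with pytest.raises(Exception):
            ts.EpochsDataset(
                subjects=["S01"],
                conditions=["A", "B"],
                data={
                    ("S01", "A"): np.zeros((2, 4, 5)),
                    ("S01", "B"): np.zeros((2, 3, 5)),
                },
                sensor_names=["E1", "E2", "E3", "E4"],
                times=np.arange(5.0),
                sampling_rate=1000.0,
            )


class TestExtract:
    def test_restricts_conditions_and_halfopen_time(self):
        dataset = make_dataset(conditions=("A", "B", "C"), n_times=801)
        target = ts.AnalysisTarget(("A", "B"), (("A", "B"),), (0.0, 600.0), 100.0)
        view = ts.extract(dataset, target)
        assert view.conditions == ["A", "B"]
        assert view.times[0] == 0.0
        assert view.times[-1] < 600.0
        assert view.n_times == 600

    def test_halfopen_count(self):
        dataset = make_dataset(n_times=801)
        target = ts.AnalysisTarget(("A",), (), (0.0, 100.0), 10.0)
        assert ts.extract(dataset, target).n_times == 100

    def test_unknown_condition_names_available(self, small_dataset):
        target = ts.AnalysisTarget(("D",), (), (0.0, 100.0), 10.0)
        with pytest.raises(ConditionNotFoundError, match="'D'"):
            ts.extract(small_dataset, target)

    def test_empty_slice_is_range_error(self, small_dataset):
        target = ts.AnalysisTarget(("A",), (), (700.0, 800.0), 10.0)
        with pytest.raises(TimeRangeError):
            ts.extract(small_dataset, target)

    def test_idempotent(self, small_dataset):
        target = ts.AnalysisTarget(("A", "B"), (), (0.0, 400.0), 50.0)
        once = ts.extract(small_dataset, target)
        target2 = ts.AnalysisTarget(("A", "B"), (), (0.0, 400.0), 50.0)
        twice = ts.extract(once, target2)
        for key in once.data:
            np.testing.assert_array_equal(once.data[key], twice.data[key])

    def test_average_reference_zero_means(self, small_dataset):
        target = ts.AnalysisTarget(("A",), (), (0.0, 100.0), 10.0)
        view = ts.extract(small_dataset, target, average_reference=True)
        block = view.block("S01", "A")
        np.testing.assert_allclose(block.mean(axis=1), 0.0, atol=1e-12)

    def test_target_json_roundtrip(self, tmp_path):
        doc = {
            "conditions": ["A", "B"],
            "comparisons": [["A", "B"]],
            "time_range": [0, 600],
            "window_ms": 5,
        }
        path = tmp_path / "target.json"
        import json

        path.write_text(json.dumps(doc))
        target = ts.AnalysisTarget.from_json(path)
        assert target.to_dict() == {
            "conditions": ["A", "B"],
            "comparisons": [["A", "B"]],
            "time_range": [0.0, 600.0],
            "window_ms": 5.0,
        }


class TestErp:
    def test_identical_trials_return_the_trial(self):
        dataset = make_dataset(n_subjects=1, conditions=("A",), n_trials=3, n_times=5)
        v = np.arange(4 * 5, dtype=float).reshape(4, 5)
        dataset.data[("S01", "A")] = np.stack([v, v, v])
        erps = ts.erp(dataset, "subject")
        np.testing.assert_array_equal(erps[("S01", "A")], v)

    def test_mean_of_two_trials(self):
        dataset = make_dataset(n_subjects=1, conditions=("A",), n_trials=2, n_times=5)
        dataset.data[("S01", "A")] = np.stack(
            [np.full((4, 5), 1.0), np.full((4, 5), 3.0)]
        )
        np.testing.assert_array_equal(
            ts.erp(dataset, "subject")[("S01", "A")], np.full((4, 5), 2.0)
        )

    def test_group_erp_is_unweighted_across_subjects(self):
        dataset = make_dataset(n_subjects=2, conditions=("A",), n_trials=1, n_times=5)
        u = np.full((4, 5), 1.0)
        w = np.full((4, 5), 5.0)
        dataset.data[("S01", "A")] = np.stack([u] * 9)  # 9 trials
        dataset.data[("S02", "A")] = np.stack([w] * 1)  # 1 trial
        group = ts.erp(dataset, "group")["A"]
        np.testing.assert_array_equal(group, (u + w) / 2)  # not (9u + w)/10
        weighted = (9 * u + 1 * w) / 10
        assert not np.allclose(group, weighted)

    def test_constant_map_recovered_exactly(self):
        dataset = make_dataset(n_subjects=4, conditions=("A",), n_trials=4, n_times=6)
        m = np.linspace(-1, 1, 4)[:, None] * np.ones(6)
        for s in dataset.subjects:
            dataset.data[(s, "A")] = np.stack([m] * 4)
        np.testing.assert_array_equal(ts.erp(dataset, "group")["A"], m)


class TestWindows:
    def test_exact_tiling(self):
        times = np.arange(600.0)
        wins = ts.windows(times, 100.0, 1000.0)
        assert len(wins) == 6
        assert all(w.n_samples == 100 for w in wins)

    def test_short_remainder_dropped(self):
        times = np.arange(601.0)
        wins = ts.windows(times, 100.0, 1000.0)
        assert len(wins) == 6
        assert wins[-1].end_idx == 600

    def test_long_remainder_kept(self):
        times = np.arange(650.0)
        wins = ts.windows(times, 100.0, 1000.0)
        assert len(wins) == 7
        assert wins[-1].n_samples == 50

    def test_1100hz_5ms_windows(self):
        rate = 1100.0
        n = int(round(600 * rate / 1000.0))
        times = np.arange(n) * 1000.0 / rate
        wins = ts.windows(times, 5.0, rate)
        sizes = {w.n_samples for w in wins}
        assert sizes <= {5, 6}
        # contiguous, disjoint, covering everything except a short remainder
        assert wins[0].start_idx == 0
        for prev, nxt in zip(wins, wins[1:]):
            assert prev.end_idx == nxt.start_idx
        assert n - wins[-1].end_idx < 5.0 * rate / 1000.0 / 2

    def test_subsample_window_rejected(self):
        with pytest.raises(ParameterError):
            ts.windows(np.arange(100.0), 0.5, 1000.0)

    @given(
        n=st.integers(20, 400),
        window_ms=st.floats(2.0, 120.0),
        rate=st.sampled_from([100.0, 250.0, 1000.0, 1100.0]),
    )
    def test_windows_disjoint_ordered(self, n, window_ms, rate):
        times = np.arange(n) * 1000.0 / rate
        if window_ms * rate / 1000.0 < 1:
            return
        wins = ts.windows(times, window_ms, rate)
        total = 0
        last_end = 0
        for w in wins:
            assert w.start_idx >= last_end
            assert w.end_idx > w.start_idx
            last_end = w.end_idx
            total += w.n_samples
        assert total <= n
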