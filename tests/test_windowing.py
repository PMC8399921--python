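"""(D, W, F) windowing, splitting and the sweep grid."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fieldfatigue as ff
from fieldfatigue.labels import FatigueLabelSeries
from fieldfatigue.prep import AlignedStreams
from fieldfatigue.windowing import (
    SplitSpec,
    hyperparameter_sweep,
    split_train_test,
    window_activity,
    window_count,
)


def make_streams(n, rate=250.0, seed=0):
    rng = np.random.default_rng(seed)
    return AlignedStreams(data=rng.uniform(0, 1, size=(n, 4)), rate_hz=rate)


def make_label(n, rate=250.0):
    return FatigueLabelSeries("LTLF", np.linspace(1, 0, n), rate_hz=rate)


class TestWindowCount:
    @pytest.mark.parametrize("n,w,d", [
        (1_534_500, 256, 5994),
        (2_662_750, 256, 10_401),
        (1_843_749, 256, 7202),
        (20_000, 128, 156),
        (128, 128, 1),
    ])
    def test_accounting(self, n, w, d):
        assert window_count(n, w) == d

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 700))
    def test_matches_brute_force_segmentation(self, n, w):
        x = np.empty(n)
        count = 0
        i = 0
        while i + w <= n:
            _ = x[i: i + w]
            count += 1
            i += w
        assert window_count(n, w) == count


class TestWindowActivity:
    def test_single_window_when_n_equals_w(self):
        streams = make_streams(256)
        label = make_label(256)
        seconds = np.arange(2)  # 2 s x 250 Hz >= 256... use first 256 samples
        ds = window_activity(streams, seconds, "walk", 256, label)
        assert len(ds) == 1
        assert ds.X.shape == (1, 256, 4)

    def test_window_label_is_mean_within_bounds(self):
        streams = make_streams(2500)
        label = make_label(2500)
        ds = window_activity(streams, np.arange(10), "run", 128, label)
        for i in range(len(ds)):
            lo = label.values[i * 128:(i + 1) * 128]
            assert lo.min() - 1e-12 <= ds.y[i] <= lo.max() + 1e-12
            assert ds.y[i] == pytest.approx(lo.mean())

    def test_nonadjacent_seconds_concatenated_in_time_order(self):
        streams = make_streams(5000)
        label = make_label(5000)
        seconds = np.array([0, 1, 8, 9])  # 1000 samples with a seam
        ds = window_activity(streams, seconds, "walk_up", 250, label)
        assert len(ds) == 4
        assert np.array_equal(ds.X[2], streams.data[2000:2250])
        strict = window_activity(streams, seconds, "walk_up", 250, label,
                                 strict_seams=True)
        assert len(strict) == 4  # seams align with window edges here

    def test_strict_seams_drops_partial_runs(self):
        streams = make_streams(5000)
        label = make_label(5000)
        seconds = np.array([0, 8])  # two 250-sample runs, W=400 spans the seam
        default = window_activity(streams, seconds, "walk", 400, label)
        assert len(default) == 1
        with pytest.raises(ValueError):
            window_activity(streams, seconds, "walk", 400, label, strict_seams=True)

    def test_missing_or_short_activity_rejected(self):
        streams = make_streams(1000)
        label = make_label(1000)
        with pytest.raises(ValueError):
            window_activity(streams, np.empty(0, int), "sit", 128, label)
        with pytest.raises(ValueError):
            window_activity(streams, np.arange(1), "sit", 512, label)


class TestSplit:
    def _ds(self, d=100):
        streams = make_streams(d * 128)
        label = make_label(d * 128)
        return window_activity(streams, np.arange(d * 128 // 250 + 1), "run", 128, label)

    def test_split_sizes(self):
        ds = self._ds()
        train, test = split_train_test(ds, SplitSpec(test_fraction=0.33, seed=0))
        assert len(test) == round(0.33 * len(ds))
        assert len(train) + len(test) == len(ds)

    def test_partition_and_determinism(self):
        ds = self._ds()
        t1 = split_train_test(ds, SplitSpec(seed=5))
        t2 = split_train_test(ds, SplitSpec(seed=5))
        o1 = np.sort(np.concatenate([t1[0].meta["order"], t1[1].meta["order"]]))
        assert np.array_equal(o1, np.arange(len(ds)))
        assert np.array_equal(t1[1].meta["order"], t2[1].meta["order"])
        assert not np.intersect1d(t1[0].meta["order"], t1[1].meta["order"]).size

    def test_blocked_split_is_contiguous_tail(self):
        ds = self._ds()
        train, test = split_train_test(ds, SplitSpec(seed=0, blocked=True))
        orders = test.meta["order"].to_numpy()
        assert np.array_equal(orders, np.arange(orders.min(), len(ds)))

    def test_too_small_dataset_rejected(self):
        streams = make_streams(500)
        label = make_label(500)
        ds = window_activity(streams, np.arange(2), "run", 250, label)
        with pytest.raises(ValueError):
            split_train_test(ds)


class TestSweep:
    def test_grid_enumerates_108_cells(self, session1):
        _, s, streams, timeline = session1
        label = ff.label_from_scores(
            s.test_scores, streams.length_n / streams.rate_hz, "LTLF"
        )
        table = hyperparameter_sweep(streams, timeline, label, dry_run=True)
        assert len(table) == 3 * 9 * 4 == 108
        ok = table[table["status"] == "ok"]
        assert (ok["n_windows"] == ok["n_samples"] // ok["width"]).all()

    def test_dry_run_grid_is_deterministic(self, session1):
        _, s, streams, timeline = session1
        label = ff.label_from_scores(
            s.test_scores, streams.length_n / streams.rate_hz, "LTLF"
        )
        a = hyperparameter_sweep(streams, timeline, label, dry_run=True)
        b = hyperparameter_sweep(streams, timeline, label, dry_run=True)
        assert a.equals(b)
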