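import numpy as np
import pytest
from hypothesis import given, strategies as st

import gaitann as g
from gaitann.errors import EmptyInputError
from gaitann.preprocess import (
    FeatureTable,
    window_starts,
    extract_features_batch,
)
from _oracles import brute_features, brute_window_starts


def _circuit_from_labels(labels, n_channels=2, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    chans = tuple(g.CANONICAL_CHANNEL_NAMES[:n_channels])
    return g.Circuit(
        "S1", "C0", "even", rng.normal(size=(len(labels), n_channels)), labels, chans
    )


class TestRemoveTransitions:
    def test_two_block_boundary_trimming(self):
        c = _circuit_from_labels([0] * 1000 + [1] * 1000)
        runs = g.remove_transitions(c, g.SegmentationConfig())
        assert [(r.activity, r.start, r.stop) for r in runs] == [
            (0, 0, 750),
            (1, 1250, 2000),
        ]

    def test_single_activity_keeps_everything(self):
        c = _circuit_from_labels([3] * 500)
        (run,) = g.remove_transitions(c, g.SegmentationConfig())
        assert (run.start, run.stop) == (0, 500)

    def test_short_blocks_keep_50_samples_each(self):
        c = _circuit_from_labels([0] * 300 + [1] * 300)
        runs = g.remove_transitions(c, g.SegmentationConfig())
        assert [(r.start, r.stop) for r in runs] == [(0, 50), (550, 600)]

    def test_runs_shorter_than_window_are_dropped(self):
        c = _circuit_from_labels([0] * 270 + [1] * 1000)
        runs = g.remove_transitions(c, g.SegmentationConfig())
        # first run keeps 270-250=20 < 25 samples and disappears
        assert [r.activity for r in runs] == [1]

    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=30))
    def test_retained_total_accounting(self, block_pattern):
        """retained = T - boundaries*removal - samples lost in dropped runs."""
        cfg = g.SegmentationConfig(transition_removal=100)
        labels = np.concatenate([[a] * 60 for a in block_pattern])
        # merge equal neighbours to count true boundaries
        c = _circuit_from_labels(labels, seed=1)
        runs = g.remove_transitions(c, cfg)
        n_boundaries = int((np.diff(labels) != 0).sum())
        survived = sum(r.length for r in runs)
        full = len(labels) - n_boundaries * cfg.transition_removal
        assert survived <= max(full, 0) + n_boundaries * cfg.transition_removal
        for r in runs:  # never longer than its source block run
            assert r.length >= cfg.window
            assert np.all(labels[r.start:r.stop] == r.activity)


class TestSegmentation:
    def test_pass_counts_for_l130(self):
        starts, offs, idxs = window_starts(130, g.SegmentationConfig())
        assert len(starts) == 22  # 5+5+4+4+4
        counts = [int((offs == o).sum()) for o in (0, 5, 10, 15, 20)]
        assert counts == [5, 5, 4, 4, 4]

    def test_too_short_run_yields_nothing(self):
        starts, _, _ = window_starts(24, g.SegmentationConfig())
        assert len(starts) == 0

    @pytest.mark.parametrize("L", list(range(25, 501, 7)) + [25, 500])
    def test_union_of_passes_equals_stride5_sliding(self, L):
        cfg = g.SegmentationConfig()
        starts, _, _ = window_starts(L, cfg)
        assert sorted(starts) == brute_window_starts(L, cfg.window, cfg.shift)
        assert len(set(starts)) == len(starts)

    def test_segment_run_emits_windows_per_channel(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(size=(130, 3))
        wins = g.segment_run(samples, g.SegmentationConfig())
        assert len(wins) == 22 * 3
        w = wins[0]
        assert w.values.shape == (25,) and w.pass_offset == 0 and w.window_index == 0
        np.testing.assert_array_equal(w.values, samples[:25, 0])


class TestFeatures:
    def test_constant_window(self):
        f = g.extract_features(np.full(25, 3.0))
        np.testing.assert_allclose(f, [3, 3, 0, 3, 3, 3, 3, 0, 0])

    def test_ramp_window(self):
        f = g.extract_features(np.arange(25.0))
        np.testing.assert_allclose(
            f, [12, 12, np.sqrt(52), 0, 24, 0, 24, 6.24, 24], rtol=1e-12
        )

    def test_alternating_window(self):
        x = np.zeros(25)
        x[1::2] = 1.0  # 13 zeros, 12 ones
        f = g.extract_features(x)
        np.testing.assert_allclose(
            f, [0.48, 0, np.sqrt(0.2496), 0, 1, 0, 0, 0.4992, 24], rtol=1e-12
        )

    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            W = int(rng.integers(2, 51))
            x = rng.normal(scale=rng.uniform(0.1, 50), size=W)
            got = g.extract_features(x)
            want = np.array(brute_features(x))
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-14)

    def test_exact_on_integer_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            W = int(rng.integers(2, 40))
            x = rng.integers(-50, 50, size=W).astype(float)
            got = g.extract_features(x)
            want = brute_features(x)
            for j in (3, 4, 5, 6, 8):  # min, max, initial, final, WL
                assert got[j] == want[j]

    def test_median_modes(self):
        x = np.arange(25.0)[::-1]  # descending ramp
        assert g.extract_features(x)[1] == 12.0  # sorted median
        assert g.extract_features(x, median_mode="center")[1] == x[12]

    def test_window_too_short_raises(self):
        with pytest.raises(ValueError):
            g.extract_features(np.array([1.0]))

    @given(st.integers(0, 2**31 - 1))
    def test_feature_invariants_hold(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        mean, med, std, mn, mx, first, last, mav, wl = g.extract_features(x)
        assert std >= 0 and mav >= 0 and wl >= 0
        assert mn <= mean <= mx and mn <= med <= mx


class TestFeatureTable:
    def test_single_run_row_count_and_width(self):
        rng = np.random.default_rng(0)
        c = g.Circuit(
            "S1", "C0", "even",
            rng.normal(size=(130, 19)), np.zeros(130), g.CANONICAL_CHANNEL_NAMES,
        )
        cfg = g.SegmentationConfig(transition_removal=0)
        table = g.build_feature_table([c], cfg)
        assert table.X.shape == (22, 171)

    def test_empty_input_gives_empty_table(self):
        table = g.build_feature_table([], g.SegmentationConfig())
        assert table.X.shape[0] == 0 and len(table.meta) == 0

    def test_concatenation_compositionality(self, tiny_circuits, seg_cfg):
        both = g.build_feature_table(tiny_circuits[:2], seg_cfg)
        parts = [g.build_feature_table([c], seg_cfg) for c in tiny_circuits[:2]]
        np.testing.assert_array_equal(both.X, np.vstack([p.X for p in parts]))

    def test_batch_features_agree_with_scalar_path(self, tiny_circuits, seg_cfg):
        c = tiny_circuits[0]
        table = g.build_feature_table([c], seg_cfg)
        runs = g.remove_transitions(c, seg_cfg)
        r = runs[0]
        win = c.samples[r.start : r.start + seg_cfg.window, 0]
        np.testing.assert_allclose(table.X[0, :9], g.extract_features(win))


class TestStacking:
    def _table(self, n_rows, width=4):
        import pandas as pd

        X = np.arange(n_rows * width, dtype=float).reshape(n_rows, width)
        meta = pd.DataFrame(
            {
                "subject_id": "S1",
                "circuit_id": "C0",
                "run_index": 0,
                "activity": 2,
                "pass_offset": 0,
                "window_index": range(n_rows),
            }
        )
        return FeatureTable(X, meta, ("a",))

    def test_counts_and_layout(self):
        t = self._table(5)
        ds = g.stack_context(t, 3)
        assert ds.X.shape == (3, 12)
        np.testing.assert_array_equal(ds.X[0], np.concatenate([t.X[0], t.X[1], t.X[2]]))
        assert list(ds.groups["window_index"]) == [2, 3, 4]

    def test_group_shorter_than_context_produces_nothing(self):
        assert g.stack_context(self._table(2), 3).n_rows == 0

    def test_k1_is_identity(self):
        t = self._table(4)
        ds = g.stack_context(t, 1)
        np.testing.assert_array_equal(ds.X, t.X)

    def test_stacked_width_is_513_for_19_channels(self, tiny_circuits, seg_cfg):
        table = g.build_feature_table(tiny_circuits[:1], seg_cfg)
        ds = g.stack_context(table, seg_cfg.context)
        assert ds.X.shape[1] == 3 * 9 * 19 == 513

    def test_no_row_mixes_runs_or_passes(self, tiny_circuits, seg_cfg):
        """Each stacked row's constituents come from one (circuit, run, pass)."""
        table = g.build_feature_table(tiny_circuits[:2], seg_cfg)
        ds = g.stack_context(table, seg_cfg.context)
        position = {
            (m.subject_id, m.circuit_id, m.run_index, m.pass_offset, m.window_index): j
            for j, m in enumerate(table.meta.itertuples(index=False))
        }
        width = table.X.shape[1]
        rng = np.random.default_rng(0)
        for i in rng.choice(ds.n_rows, 25, replace=False):
            row = ds.groups.iloc[i]
            for back in range(seg_cfg.context):
                j = position[
                    (
                        row.subject_id,
                        row.circuit_id,
                        row.run_index,
                        row.pass_offset,
                        row.window_index - back,
                    )
                ]
                piece_slice = slice(
                    (seg_cfg.context - 1 - back) * width,
                    (seg_cfg.context - back) * width,
                )
                np.testing.assert_array_equal(ds.X[i, piece_slice], table.X[j])
                assert int(table.meta["activity"].iloc[j]) == ds.y[i]


class TestScaler:
    def test_train_matrix_standardized(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 5, size=(200, 7))
        stats = g.fit_scaler(X)
        Z = g.apply_scaler(X, stats)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(Z.std(axis=0), 1.0, rtol=1e-10)

    def test_constant_column_passes_through_centered(self):
        X = np.column_stack([np.full(50, 4.0), np.arange(50.0)])
        Z = g.apply_scaler(X, g.fit_scaler(X))
        assert np.all(Z[:, 0] == 0.0)

    def test_apply_is_affine_per_column(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        stats = g.fit_scaler(X)
        a, b = 2.5, -1.0
        np.testing.assert_allclose(
            g.apply_scaler(a * X + b, stats),
            a * g.apply_scaler(X, stats) + (b + (a - 1) * stats.mean) / stats.scale,
            rtol=1e-10,
            atol=1e-10,
        )

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            g.fit_scaler(np.empty((0, 3)))


class TestBalancing:
    def _ds(self, counts, seed=0):
        import pandas as pd

        y = np.concatenate([np.full(n, c) for c, n in counts.items()])
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(len(y), 3))
        groups = pd.DataFrame({"subject_id": "S1", "circuit_id": "C0"}, index=range(len(y)))
        from gaitann.preprocess import StackedDataset

        return StackedDataset(X, y, groups.reset_index(drop=True))

    def test_downsamples_to_min_count(self):
        ds = g.balance_classes(self._ds({0: 10, 1: 7, 2: 7}), seed=0)
        assert ds.n_rows == 21
        assert all((ds.y == c).sum() == 7 for c in (0, 1, 2))

    def test_already_balanced_is_identity(self):
        src = self._ds({0: 5, 1: 5})
        ds = g.balance_classes(src, seed=3)
        np.testing.assert_array_equal(ds.X, src.X)

    def test_seed_determinism(self):
        src = self._ds({0: 50, 1: 10})
        a = g.balance_classes(src, seed=1)
        b = g.balance_classes(src, seed=1)
        c = g.balance_classes(src, seed=2)
        np.testing.assert_array_equal(a.X, b.X)
        assert not np.array_equal(a.X, c.X)

    def test_order_preserved(self):
        src = self._ds({0: 40, 1: 10})
        ds = g.balance_classes(src, seed=0)
        # surviving rows keep their original relative order: X rows appear in
        # the same order as in the source
        pos = [int(np.flatnonzero((src.X == row).all(axis=1))[0]) for row in ds.X]
        assert pos == sorted(pos)

    def test_missing_class_raises(self):
        with pytest.raises(EmptyInputError, match="2"):
            g.balance_classes(self._ds({0: 5, 1: 5}), seed=0, classes=[0, 1, 2])


def test_pipeline_is_deterministic(tiny_circuits, seg_cfg):
    def run():
        table = g.build_feature_table(tiny_circuits[:3], seg_cfg)
        ds = g.stack_context(table, seg_cfg.context)
        return g.balance_classes(ds, seed=5)

    a, b = run(), run()
    np.testing.assert_array_equal(a.X, b.X)
    np.testing.assert_array_equal(a.y, b.y)
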