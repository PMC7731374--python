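"""Feature-table IO, normalization, grouping, and Mann-Whitney selection."""

import numpy as np
import pandas as pd
import pytest

from asdvoice import features as ft
from asdvoice import generate_cohort, SyntheticCohortConfig


def _brute_force_u(x, y):
    """U as explicit pair counting: #(xi > yj) + 0.5 * #(xi == yj)."""
    x, y = np.asarray(x), np.asarray(y)
    return float((x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum())


def _write_table(path, n_features=88, n_rows=10, n_utts=2):
    rng = np.random.default_rng(5)
    rows = []
    per = n_rows // n_utts
    for u in range(n_utts):
        for _ in range(per):
            rows.append([f"u{u}", f"s{u}", "ASD" if u == 0 else "TD", u, 0.5,
                         *rng.standard_normal(n_features)])
    cols = ["utterance_id", "subject_id", "group", "vocal_label", "duration_s"] + \
           [f"f{i:03d}" for i in range(n_features)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


class TestLoadFeatureTable:
    def test_two_utterances_of_five_frames(self, tmp_path):
        path = _write_table(tmp_path / "t.csv")
        utts = ft.load_feature_table(path)
        assert [u.utterance_id for u in utts] == ["u0", "u1"]
        assert all(u.n_frames == 5 for u in utts)
        assert utts[0].group == "ASD" and utts[1].group == "TD"

    def test_missing_feature_column_is_schema_error(self, tmp_path):
        path = _write_table(tmp_path / "t.csv")
        df = pd.read_csv(path).drop(columns=["f087"])
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ft.SchemaError, match="f087"):
            ft.load_feature_table(tmp_path / "bad.csv")

    def test_extra_column_is_schema_error(self, tmp_path):
        path = _write_table(tmp_path / "t.csv")
        df = pd.read_csv(path)
        df["f088"] = 0.0
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ft.SchemaError, match="f088"):
            ft.load_feature_table(tmp_path / "bad.csv")

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = _write_table(tmp_path / "t.csv")
        df = pd.read_csv(path)
        df["f010"] = df["f010"].astype(object)
        df.loc[3, "f010"] = "oops"
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="row 3.*f010"):
            ft.load_feature_table(tmp_path / "bad.csv")

    def test_synthetic_cohort_roundtrip_is_lossless(self, tmp_path, tiny_cohort):
        utts, _ = tiny_cohort
        path = tmp_path / "cohort.csv"
        ft.write_feature_table(utts, path)
        reloaded = ft.load_feature_table(path)
        assert len(reloaded) == len(utts)
        for a, b in zip(utts, reloaded):
            assert a.utterance_id == b.utterance_id
            assert a.subject_id == b.subject_id
            assert a.group == b.group
            assert a.vocal_label == b.vocal_label
            assert a.duration_s == b.duration_s
            np.testing.assert_array_equal(a.frames, b.frames)


class TestNormalizer:
    def test_constant_column_falls_back_to_epsilon(self):
        frames = np.full((10, 2), 3.0)
        frames[:, 1] = np.arange(10)
        stats = ft.fit_normalizer(frames)
        assert stats.mean[0] == 3.0 and stats.sd[0] == 0.0
        out = ft.apply_normalizer(frames, stats)
        assert np.all(np.isfinite(out))
        # constant column maps to (x - mean) / epsilon = 0 exactly here
        assert np.all(out[:, 0] == 0.0)

    def test_two_point_population_sd(self):
        stats = ft.fit_normalizer(np.array([[0.0], [2.0]]))
        assert stats.mean[0] == 1.0
        assert stats.sd[0] == 1.0  # population convention, not sample (sqrt(2))

    def test_fit_then_apply_standardizes(self, rng):
        X = rng.standard_normal((1000, 88)) * rng.uniform(0.5, 4, 88) + rng.normal(0, 5, 88)
        out = ft.apply_normalizer(X, ft.fit_normalizer(X))
        assert np.abs(out.mean(axis=0)).max() < 1e-9
        assert np.abs(out.std(axis=0) - 1.0).max() < 1e-9

    def test_frozen_train_stats_leave_shifted_test_uncentered(self, rng):
        train = rng.standard_normal((500, 4))
        test = rng.standard_normal((500, 4)) + 2.0
        out = ft.apply_normalizer(test, ft.fit_normalizer(train))
        assert np.abs(out.mean(axis=0)).min() > 0.5  # shift survives

    def test_errors(self):
        with pytest.raises(ValueError):
            ft.fit_normalizer(np.empty((0, 3)))
        stats = ft.fit_normalizer(np.ones((2, 3)) * [[1, 2, 3], [3, 2, 1]])
        with pytest.raises(ValueError):
            ft.apply_normalizer(np.ones((5, 4)), stats)

    def test_json_roundtrip(self, tmp_path):
        stats = ft.fit_normalizer(np.random.default_rng(1).standard_normal((20, 5)))
        stats.to_json(tmp_path / "s.json")
        back = ft.NormStats.from_json(tmp_path / "s.json")
        np.testing.assert_array_equal(stats.mean, back.mean)
        np.testing.assert_array_equal(stats.sd, back.sd)


def _utt(n_frames, n_features=4):
    return ft.UtteranceFeatures(
        "u", "s", "ASD", 0,
        np.arange(n_frames * n_features, dtype=float).reshape(n_frames, n_features),
        1.0)


class TestGroupFrames:
    def test_remainder_dropped(self):
        g = ft.group_frames(_utt(12), group_size=5)
        assert g.n_windows == 2 and not g.too_short
        np.testing.assert_array_equal(g.windows.reshape(10, 4), _utt(12).frames[:10])

    def test_exact_window_is_identity(self):
        g = ft.group_frames(_utt(5))
        assert g.n_windows == 1
        np.testing.assert_array_equal(g.windows[0], _utt(5).frames)

    def test_short_utterance_flagged(self):
        g = ft.group_frames(_utt(3))
        assert g.n_windows == 0 and g.too_short

    @pytest.mark.parametrize("n_frames", range(1, 51))
    def test_window_count_is_floor(self, n_frames):
        assert ft.group_frames(_utt(n_frames)).n_windows == n_frames // 5

    def test_invalid_group_size(self):
        with pytest.raises(ValueError):
            ft.group_frames(_utt(5), group_size=0)


class TestMannWhitney:
    def test_fully_separated_samples(self):
        u, p = ft.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == _brute_force_u([1, 2, 3], [4, 5, 6]) == 0.0

    def test_identical_samples_give_half_pairs(self):
        x = [1.0, 2.0, 5.0, 5.0]
        u, p = ft.mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2
        all_same = ft.mann_whitney_u([2, 2, 2], [2, 2, 2])
        assert all_same == (4.5, 1.0)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ft.mann_whitney_u([], [1.0])

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(77)
        for _ in range(250):
            n, m = rng.integers(1, 9, 2)
            # small integer pool forces ties
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, m).astype(float)
            u, p = ft.mann_whitney_u(x, y)
            assert u == _brute_force_u(x, y)
            assert 0.0 <= p <= 1.0


class TestSelectFeatures:
    def test_planted_shift_recovered_exactly(self, rng):
        n = 500
        asd = rng.standard_normal((n, 88))
        td = rng.standard_normal((n, 88))
        asd[:, :10] += 2.0  # large location shift on features 0-9
        sel = ft.select_features(asd, td, k=10)
        assert sorted(sel.selected_indices) == list(range(10))

    def test_full_k_returns_permutation(self, rng):
        sel = ft.select_features(rng.standard_normal((30, 88)),
                                 rng.standard_normal((30, 88)), k=88)
        assert sorted(sel.selected_indices) == list(range(88))

    def test_identical_groups_tie_break_by_index(self):
        X = np.tile(np.arange(20.0)[:, None], (1, 88))
        sel = ft.select_features(X, X, k=5)
        assert sel.selected_indices == [0, 1, 2, 3, 4]

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError):
            ft.select_features(rng.standard_normal((5, 88)),
                               rng.standard_normal((5, 88)), k=89)

    def test_recovery_probability_at_delta_two(self):
        """Planted-set recovery >= 0.95 at delta=2 SD, 500 frames/group."""
        successes = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            asd = rng.standard_normal((500, 88))
            td = rng.standard_normal((500, 88))
            asd[:, :10] += 2.0
            sel = ft.select_features(asd, td, k=10)
            successes += sorted(sel.selected_indices) == list(range(10))
        assert successes >= 19
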