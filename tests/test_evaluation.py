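"""Confusion metrics against an independent oracle, grouped k-fold
splitting, imbalance resampling, and fold reports."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import precision_score, recall_score

from edgegan.errors import InvalidArgumentError
from edgegan.evaluation import (
    ConfusionCounts,
    confusion_from_labels,
    evaluate_folds,
    f1,
    kfold_by_group,
    precision,
    precision_flagged,
    resample_imbalance,
    sensitivity,
    sensitivity_flagged,
)
from edgegan.synthetic import TUMORLIKE, generate_tiles

from conftest import make_stub_registry


class TestConfusionMetrics:
    def test_simple_arithmetic(self):
        c = ConfusionCounts(tp=9, fp=1, fn=1, tn=9)
        assert precision(c) == pytest.approx(90.0)
        assert sensitivity(c) == pytest.approx(90.0)

    def test_degenerate_denominators_flagged(self):
        c = ConfusionCounts(tp=0, fp=0, fn=0, tn=5)
        assert precision_flagged(c) == (0.0, True)
        assert sensitivity_flagged(c) == (0.0, True)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)

    def test_random_tables_match_sklearn_oracle(self):
        """Formula-level agreement with an independent implementation on
        random confusion tables (reconstructed as label vectors)."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 40, 4))
            if tp + fp + fn + tn == 0:
                tp = 1
            y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
            c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
            assert precision(c) == pytest.approx(
                100 * precision_score(y_true, y_pred, zero_division=0), rel=1e-12)
            assert sensitivity(c) == pytest.approx(
                100 * recall_score(y_true, y_pred, zero_division=0), rel=1e-12)

    def test_confusion_from_labels(self):
        y_true = ["t", "t", "n", "n", "t"]
        y_pred = ["t", "n", "n", "t", "t"]
        c = confusion_from_labels(y_true, y_pred, positive_label="t")
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 1)


class TestF1:
    def test_zero_cases(self):
        assert f1(0.0, 0.0) == 0.0
        assert f1(0.0, 50.0) == 0.0

    @settings(deadline=None, max_examples=60)
    @given(st.floats(0.01, 100.0))
    def test_harmonic_mean_identity(self, x):
        assert f1(x, x) == pytest.approx(x, rel=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    def test_bounds_and_symmetry(self, p, s):
        v = f1(p, s)
        tol = 1e-9 * max(p, s)  # one-ulp slack on the harmonic-mean bound
        assert min(p, s) - tol <= v <= max(p, s) + tol
        assert v == pytest.approx(f1(s, p), rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            f1(101.0, 50.0)


class TestKFoldByGroup:
    def test_24_groups_4_folds_of_6(self):
        groups = [f"slide{i:02d}" for i in range(24)]
        split = kfold_by_group(groups, 4, seed=1)
        assert split.k == 4
        folds = [split.groups_in_fold(f) for f in range(4)]
        assert all(len(f) == 6 for f in folds)
        assert set().union(*map(set, folds)) == set(groups)
        for i in range(4):
            for j in range(i + 1, 4):
                assert not set(folds[i]) & set(folds[j])

    def test_leave_one_group_out(self):
        groups = ["a", "b", "c"]
        split = kfold_by_group(groups, 3, seed=0)
        assert sorted(len(split.groups_in_fold(f)) for f in range(3)) == [1, 1, 1]

    def test_tiles_follow_their_group(self):
        """No tile-level leakage: every tile's fold equals its slide's."""
        rng = np.random.default_rng(7)
        slide_of_tile = [f"s{rng.integers(0, 8)}" for _ in range(200)]
        split = kfold_by_group(slide_of_tile, 4, seed=2)
        for s in slide_of_tile:
            assert split.fold_of(s) == split.assignments[s]
        per_fold_slides = [set(split.groups_in_fold(f)) for f in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not per_fold_slides[i] & per_fold_slides[j]

    def test_k_exceeding_groups_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kfold_by_group(["a", "b"], 3)


class TestResampleImbalance:
    def test_one_tenth_rule(self):
        tiles = generate_tiles(TUMORLIKE, 400, 32)
        sub = resample_imbalance(tiles, majority_count=3000, ratio=0.1, seed=0)
        assert len(sub) == 300

    def test_ratio_one_is_identity_as_set(self):
        tiles = generate_tiles(TUMORLIKE, 10, 32)
        sub = resample_imbalance(tiles, majority_count=10, ratio=1.0, seed=3)
        assert {id(t) for t in sub} == {id(t) for t in tiles}

    def test_seeded_determinism(self):
        tiles = generate_tiles(TUMORLIKE, 50, 32)
        a = resample_imbalance(tiles, 100, 0.3, seed=5)
        b = resample_imbalance(tiles, 100, 0.3, seed=5)
        assert [id(t) for t in a] == [id(t) for t in b]

    def test_oversized_request_rejected(self):
        tiles = generate_tiles(TUMORLIKE, 5, 32)
        with pytest.raises(InvalidArgumentError):
            resample_imbalance(tiles, majority_count=100, ratio=0.5)


class TestEvaluateFolds:
    def _fold_tiles(self, n_folds=2, n_per_class=4):
        out = {}
        for f in range(n_folds):
            tiles = []
            for label in ("tumor", "stroma"):
                for t in generate_tiles(TUMORLIKE, n_per_class, 32):
                    t.label = label
                    tiles.append(t)
            out[f] = tiles
        return out

    def test_perfect_stub_scores_100_with_zero_sd(self, monkeypatch):
        import edgegan.evaluation as ev
        from edgegan.classify import ClassificationResult

        fold_tiles = self._fold_tiles()
        truth = {f: [t.label for t in tiles] for f, tiles in fold_tiles.items()}
        state = {"fold": 0}

        def perfect(registry, px, metric="mse"):
            labels = truth[state["fold"]]
            state["fold"] += 1
            return [ClassificationResult({lab: 0.0}, lab, metric, False) for lab in labels]

        monkeypatch.setattr("edgegan.classify.classify_tiles", perfect)
        registries = {f: make_stub_registry(32, {"tumor": lambda t: t, "stroma": lambda t: t})
                      for f in fold_tiles}
        report = ev.evaluate_folds(registries, fold_tiles)
        assert report.aggregate["f1"] == {"mean": 100.0, "sd": 0.0, "median": 100.0}

    def test_all_positive_stub_has_full_sensitivity_and_prevalence_precision(self, monkeypatch):
        from edgegan.classify import ClassificationResult
        import edgegan.evaluation as ev

        fold_tiles = self._fold_tiles(n_folds=1, n_per_class=5)

        def all_tumor(registry, px, metric="mse"):
            return [ClassificationResult({"tumor": 0.0}, "tumor", metric, False)
                    for _ in range(len(px))]

        monkeypatch.setattr("edgegan.classify.classify_tiles", all_tumor)
        registries = {0: make_stub_registry(32, {"tumor": lambda t: t, "stroma": lambda t: t})}
        report = ev.evaluate_folds(registries, fold_tiles, positive_label="tumor")
        assert report.per_fold[0]["sensitivity"] == 100.0
        assert report.per_fold[0]["precision"] == 50.0  # prevalence

    def test_aggregate_matches_hand_computation(self):
        from edgegan.evaluation import _agg

        vals = [90.0, 95.0, 100.0, 85.0]
        agg = _agg(vals)
        assert agg["mean"] == pytest.approx(92.5)
        assert agg["sd"] == pytest.approx(round(float(np.std(vals, ddof=1)), 2))
        assert agg["median"] == pytest.approx(92.5)

    def test_fold_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            evaluate_folds({0: None}, {1: []})
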