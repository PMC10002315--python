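"""Classifier stage: Youden cutoffs, confusion arithmetic, stratified CV
properties on synthetic feature tables, and the feature report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voicesym.classify import (
    ConfusionMatrix,
    confusion_stats,
    crossvalidate,
    feature_report,
    youden_cutoff,
)


def _exhaustive_youden(scores, labels):
    """Independent oracle: try every distinct cutoff, return max J."""
    best = -np.inf
    n_pos = np.sum(labels == 1)
    n_neg = np.sum(labels == 0)
    for t in np.concatenate([np.unique(scores), [np.min(scores) - 1, np.max(scores) + 1]]):
        pred = scores >= t
        j = np.sum(pred & (labels == 1)) / n_pos + np.sum(~pred & (labels == 0)) / n_neg - 1
        best = max(best, j)
    return best


def _j_at(scores, labels, t):
    pred = scores >= t
    return (
        np.sum(pred & (labels == 1)) / np.sum(labels == 1)
        + np.sum(~pred & (labels == 0)) / np.sum(labels == 0)
        - 1
    )


class TestYoudenCutoff:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        t = youden_cutoff(scores, labels)
        assert _j_at(scores, labels, t) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = 20
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                labels[0] = 1 - labels[0]
            scores = np.round(rng.uniform(0, 1, n), 2)  # duplicates likely
            t = youden_cutoff(scores, labels)
            assert _j_at(scores, labels, t) == pytest.approx(
                _exhaustive_youden(scores, labels)
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_optimality_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        labels = np.r_[np.zeros(2, int), np.ones(2, int), rng.integers(0, 2, n - 4)]
        scores = rng.normal(labels.astype(float), 1.0)
        t = youden_cutoff(scores, labels)
        assert _j_at(scores, labels, t) == pytest.approx(
            _exhaustive_youden(scores, labels)
        )


class TestConfusionStats:
    def test_pooled_study_matrix(self):
        m = ConfusionMatrix(tp=31, fn=6, fp=10, tn=30)
        s = confusion_stats(m)
        assert s["accuracy"] == pytest.approx(61 / 77)
        assert round(100 * s["accuracy"]) == 79
        assert s["sensitivity"] == pytest.approx(31 / 37)
        assert s["specificity"] == pytest.approx(30 / 40)

    def test_perfect_matrix(self):
        s = confusion_stats(ConfusionMatrix(tp=10, fn=0, fp=0, tn=12))
        assert s["sensitivity"] == s["specificity"] == s["accuracy"] == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_stats(ConfusionMatrix())

    def test_cellwise_addition(self):
        a = ConfusionMatrix(1, 2, 3, 4)
        b = ConfusionMatrix(5, 6, 7, 8)
        c = a + b
        assert (c.tp, c.fn, c.fp, c.tn) == (6, 8, 10, 12)
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fn=0, fp=0, tn=0)


def _gaussian_table(n_per_group=20, n_feat=30, shift=2.0, seed=0):
    """Synthetic feature table: first 3 features carry the group signal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_group, n_feat))
    X[:n_per_group, :3] += shift
    cols = [f"f{i}__mean__phrase{(i % 21) + 1:02d}" for i in range(n_feat)]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(2 * n_per_group)])
    labels = {f"S{i:03d}": (1 if i < n_per_group else 2) for i in range(2 * n_per_group)}
    return df, labels


class TestCrossvalidate:
    def test_fold_partition_and_conservation(self):
        df, labels = _gaussian_table()
        cv = crossvalidate(df, labels, seed=1)
        assert len(cv.fold_confusions) == 5
        assert cv.overall.total == len(df)
        summed = ConfusionMatrix()
        for m in cv.fold_confusions:
            summed = summed + m
        assert summed.as_dict() == cv.overall.as_dict()
        s = confusion_stats(cv.overall)
        assert cv.accuracy == pytest.approx(s["accuracy"])

    def test_signal_recovered(self):
        df, labels = _gaussian_table(shift=2.5)
        cv = crossvalidate(df, labels, seed=2)
        assert cv.accuracy >= 0.85

    def test_deterministic_given_seed(self):
        df, labels = _gaussian_table()
        a = crossvalidate(df, labels, seed=5)
        b = crossvalidate(df, labels, seed=5)
        assert a.fold_cutoffs == b.fold_cutoffs
        assert a.overall.as_dict() == b.overall.as_dict()

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(9)
        accs = []
        for seed in range(5):
            df, labels = _gaussian_table(shift=2.0, seed=seed)
            sids = list(labels)
            vals = rng.permutation([labels[s] for s in sids])
            shuffled = dict(zip(sids, vals.tolist()))
            if min(sum(1 for v in shuffled.values() if v == g) for g in (1, 2)) < 5:
                continue
            accs.append(crossvalidate(df, shuffled, seed=seed).accuracy)
        # binomial noise around 0.5 at n = 40: sd ~ 0.079
        assert abs(np.mean(accs) - 0.5) < 2 * 0.079 / np.sqrt(len(accs)) + 0.08

    def test_small_class_rejected(self):
        df, labels = _gaussian_table(n_per_group=4)
        with pytest.raises(ValueError):
            crossvalidate(df, labels, n_folds=5, seed=0)

    def test_missing_values_consumed_natively(self):
        df, labels = _gaussian_table()
        df.iloc[::3, 5] = np.nan
        cv = crossvalidate(df, labels, seed=3)
        assert cv.overall.total == len(df)


class TestFeatureReport:
    def test_planted_signal_ranked_first(self):
        rng = np.random.default_rng(4)
        n = 60
        X = rng.standard_normal((n, 10))
        labels_arr = (X[:, 7] > 0).astype(int)
        cols = [f"g{i}__std__phrase{i + 1:02d}" for i in range(10)]
        df = pd.DataFrame(X, columns=cols)
        df.insert(0, "subject_id", [f"S{i}" for i in range(n)])
        labels = {f"S{i}": (1 if labels_arr[i] else 2) for i in range(n)}
        cv = crossvalidate(df, labels, seed=0)
        rep = feature_report(cv)
        assert rep.iloc[0]["feature"] == "g7"
        assert rep.iloc[0]["statistic"] == "std"
        assert rep.iloc[0]["phrase"] == 8

    def test_constant_feature_never_reported(self):
        df, labels = _gaussian_table()
        df["const__mean__phrase01"] = 1.0
        cv = crossvalidate(df, labels, seed=1)
        rep = feature_report(cv)
        assert "const" not in set(rep["feature"])

    def test_entries_are_valid_registry_style_triples(self):
        df, labels = _gaussian_table()
        cv = crossvalidate(df, labels, seed=1)
        rep = feature_report(cv)
        valid_cols = set(df.columns) - {"subject_id"}
        for _, row in rep.iterrows():
            name = f"{row['feature']}__{row['statistic']}__phrase{row['phrase']:02d}"
            assert name in valid_cols
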