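import math

import numpy as np
import pytest

from betaface import (ScoredInterface, cross_dataset_eval, evaluate,
                      generate_scored_dataset, metrics, optimal_threshold,
                      quantile_threshold)


def scored(values, labels, name="f"):
    return [ScoredInterface(f"e{i}", name, float(v), l)
            for i, (v, l) in enumerate(zip(values, labels))]


def exhaustive_best_splits(values, labels):
    """O(n^2) oracle: MCC of every midpoint split in both directions."""
    import sklearn.metrics as skm
    v = np.asarray(values, dtype=float)
    y = np.asarray([l == "biological" for l in labels])
    s = np.unique(v)
    mids = (s[:-1] + s[1:]) / 2.0
    rows = []
    for t in mids:
        for direction in ("pos", "neg"):
            pred = v > t if direction == "pos" else v < t
            rows.append((t, direction, skm.matthews_corrcoef(y, pred)))
    return rows


class TestMetrics:
    def test_perfect_predictions(self):
        m = metrics([True, True, False, False], [True, True, False, False])
        assert (m.precision, m.recall, m.specificity, m.accuracy, m.mcc) == \
            (1, 1, 1, 1, 1)

    def test_all_positive_degenerate(self):
        m = metrics([True] * 10, [True] * 5 + [False] * 5)
        assert m.specificity == 0.0
        assert m.accuracy == 0.5
        assert m.mcc == 0.0  # zero-denominator convention

    def test_direct_formula_toy_confusion(self):
        pred = [True] * 8 + [True] * 2 + [False] * 7 + [False] * 3
        lab = [True] * 8 + [False] * 2 + [False] * 7 + [True] * 3
        m = metrics(pred, lab)
        assert (m.tp, m.fp, m.tn, m.fn) == (8, 2, 7, 3)
        assert m.mcc == pytest.approx((8 * 7 - 2 * 3) / math.sqrt(10 * 11 * 9 * 10))
        assert m.mcc == pytest.approx(0.5025, abs=5e-5)

    def test_matches_sklearn_mcc(self):
        import sklearn.metrics as skm
        rng = np.random.default_rng(0)
        for _ in range(20):
            pred = rng.random(50) > 0.5
            lab = rng.random(50) > 0.4
            assert metrics(pred, lab).mcc == pytest.approx(
                skm.matthews_corrcoef(lab, pred), abs=1e-12)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(1)
        pred = rng.random(80) > 0.5
        lab = rng.random(80) > 0.5
        m = metrics(pred, lab)
        P, N = lab.sum(), (~lab).sum()
        assert m.accuracy == pytest.approx(
            (m.recall * P + m.specificity * N) / (P + N))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            metrics([True], [True, False])


class TestOptimalThreshold:
    def test_separable_low_is_biological(self):
        data = scored([-5, -4, -3, 3, 4, 5] + [-6, -7, 6, 7],
                      ["biological"] * 3 + ["packing"] * 3
                      + ["biological"] * 2 + ["packing"] * 2)
        model = optimal_threshold(data)
        assert model.direction == "negative-is-biological"
        assert -3 < model.threshold < 3
        assert evaluate(model, data).mcc == 1.0

    def test_planted_gaussian_recovery(self):
        data = generate_scored_dataset(200, 200, -3.0, 3.0, 1.0, seed=77)
        model = optimal_threshold(data)
        assert abs(model.threshold - 0.0) <= 0.5
        assert model.direction == "negative-is-biological"
        test = generate_scored_dataset(200, 200, -3.0, 3.0, 1.0, seed=78)
        assert evaluate(model, test).mcc > 0.95

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_exhaustive_oracle(self, seed):
        """Top-decile split set and threshold equal a brute-force scan."""
        rng = np.random.default_rng(seed)
        v = np.round(rng.normal(0, 2, size=40), 2)
        labels = ["biological" if rng.random() < 0.5 else "packing"
                  for _ in range(40)]
        if len(set(labels)) < 2:
            labels[0] = "biological"
            labels[1] = "packing"
        data = scored(v, labels)
        model = optimal_threshold(data)
        rows = exhaustive_best_splits(v, labels)
        # per-split best MCC, oracle side
        best_by_split = {}
        for t, _, mcc in rows:
            best_by_split[t] = max(best_by_split.get(t, -2), mcc)
        splits = sorted(best_by_split)
        mccs = np.array([best_by_split[t] for t in splits])
        k = max(1, math.ceil(0.10 * len(splits)))
        cutoff = np.sort(mccs)[::-1][k - 1]
        kept = [t for t, m in best_by_split.items() if m >= cutoff - 1e-12]
        assert model.candidate_splits_used == sorted(model.candidate_splits_used)
        assert np.allclose(sorted(kept), sorted(model.candidate_splits_used))
        assert model.threshold == pytest.approx(np.mean(kept))

    def test_hand_written_overlapping_set(self):
        v = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
        labels = ["biological"] * 4 + ["packing", "biological"] + ["packing"] * 6
        data = scored(v, labels)
        model = optimal_threshold(data)
        rows = exhaustive_best_splits(v, labels)
        best = max(m for _, _, m in rows)
        got = evaluate(model, data).mcc
        # averaged-decile threshold cannot beat the best single split
        assert got <= best + 1e-12
        assert model.direction == "negative-is-biological"

    def test_monotone_transform_invariance(self):
        data = generate_scored_dataset(50, 50, -1.0, 1.0, 1.0, seed=5)
        test = generate_scored_dataset(50, 50, -1.0, 1.0, 1.0, seed=6)
        m1 = optimal_threshold(data)
        mcc1 = evaluate(m1, test).mcc

        def transform(x):
            return math.exp(0.5 * x) + 0.1 * x  # strictly increasing

        data_t = [ScoredInterface(s.entry_id, s.feature_name,
                                  transform(s.score), s.label) for s in data]
        test_t = [ScoredInterface(s.entry_id, s.feature_name,
                                  transform(s.score), s.label) for s in test]
        m2 = optimal_threshold(data_t)
        assert evaluate(m2, test_t).mcc == pytest.approx(mcc1, abs=1e-12)
        assert m2.direction == m1.direction
        assert len(m2.candidate_splits_used) == len(m1.candidate_splits_used)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            optimal_threshold(scored(range(12), ["biological"] * 12))

    def test_identical_scores_error(self):
        with pytest.raises(ValueError):
            optimal_threshold(scored([1.0] * 12,
                                     ["biological"] * 6 + ["packing"] * 6))

    def test_mixed_feature_names_rejected(self):
        data = scored(range(12), ["biological"] * 6 + ["packing"] * 6)
        data[0].feature_name = "other"
        with pytest.raises(ValueError, match="mixed"):
            optimal_threshold(data)


class TestQuantileThreshold:
    def test_linear_interpolation_quantile(self):
        data = scored(range(1, 101), ["biological"] * 100)
        model = quantile_threshold(data, q=0.25)
        assert model.threshold == pytest.approx(25.75)

    def test_all_equal(self):
        data = scored([7.0] * 10, ["biological"] * 10)
        assert quantile_threshold(data, 0.25).threshold == 7.0

    def test_median_of_three(self):
        data = scored([1, 2, 3], ["biological"] * 3)
        assert quantile_threshold(data, 0.5).threshold == 2.0

    def test_rejects_negatives(self):
        data = scored([1, 2, 3], ["biological", "packing", "biological"])
        with pytest.raises(ValueError):
            quantile_threshold(data, 0.25)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            quantile_threshold([], 0.25)


class TestCrossDatasetEval:
    def test_diagonal_is_perfect_on_separable(self):
        data = generate_scored_dataset(30, 30, -5.0, 5.0, 0.5, seed=9)
        table = cross_dataset_eval(data, {"self": data})
        assert table.loc[0, "mcc"] == 1.0

    def test_same_distribution_generalizes(self):
        tr = generate_scored_dataset(200, 200, -2.0, 2.0, 1.0, seed=10)
        te = generate_scored_dataset(200, 200, -2.0, 2.0, 1.0, seed=11)
        table = cross_dataset_eval(tr, {"train": tr, "test": te})
        diag = table.set_index("test").loc["train", "mcc"]
        off = table.set_index("test").loc["test", "mcc"]
        assert abs(diag - off) < 0.1

    def test_no_signal_gives_null_mcc(self):
        # equal class means: scores carry no information anywhere
        tr = generate_scored_dataset(100, 100, 0.0, 0.0, 1.0, seed=13)
        te = generate_scored_dataset(100, 100, 0.0, 0.0, 1.0, seed=14)
        table = cross_dataset_eval(tr, {"test": te})
        assert abs(table.loc[0, "mcc"]) < 0.15

    def test_permutation_null_mcc(self):
        """Shuffling the labels of an informative dataset destroys the
        score-label association, so a threshold trained and tested on the
        permuted data scores near zero."""
        rng = np.random.default_rng(12)
        full = generate_scored_dataset(200, 200, -2.0, 2.0, 1.0, seed=13)
        labels = [s.label for s in full]
        rng.shuffle(labels)
        null = [ScoredInterface(s.entry_id, s.feature_name, s.score, l)
                for s, l in zip(full, labels)]
        tr, te = null[::2], null[1::2]
        table = cross_dataset_eval(tr, {"test": te})
        assert abs(table.loc[0, "mcc"]) < 0.15

    def test_positives_only_train_uses_quantile(self):
        tr = generate_scored_dataset(100, 0, -2.0, 0.0, 1.0, seed=15)
        te = generate_scored_dataset(100, 100, -2.0, 2.0, 1.0, seed=16)
        table = cross_dataset_eval(tr, {"test": te})
        # fallback is the q = 0.25 quantile rule, not the MCC learner
        assert table.loc[0, "threshold"] == pytest.approx(
            np.quantile([s.score for s in tr], 0.25))
        # a quarter of positives sit below the cut: recall == q, no false
        # positives expected with well-separated classes
        assert table.loc[0, "recall"] == pytest.approx(0.25, abs=0.08)
        assert table.loc[0, "mcc"] > 0.2
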