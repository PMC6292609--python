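import numpy as np
import pandas as pd
import pytest

from netess import evaluation as ev

import oracles


def gaussian_classes(n=300, sep=6.0, pos_frac=0.2, seed=0):
    """Two spherical Gaussians, well separated when sep is large."""
    rng = np.random.default_rng(seed)
    n_pos = int(n * pos_frac)
    Xp = rng.standard_normal((n_pos, 4)) + sep
    Xn = rng.standard_normal((n - n_pos, 4))
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(n_pos, bool), np.zeros(n - n_pos, bool)])
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestUndersample:
    def test_balances_classes(self):
        y = np.r_[np.ones(10, bool), np.zeros(90, bool)]
        idx = ev.undersample_balanced(y, seed=1)
        assert len(idx) == 20
        assert y[idx].sum() == 10

    def test_balanced_input_is_identity(self):
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        assert ev.undersample_balanced(y, seed=0).tolist() == list(range(10))

    def test_seeds_vary_majority_subset(self):
        y = np.r_[np.ones(10, bool), np.zeros(90, bool)]
        a = ev.undersample_balanced(y, seed=1)
        b = ev.undersample_balanced(y, seed=2)
        assert a.tolist() != b.tolist()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.undersample_balanced(np.ones(5, bool), seed=0)


class TestComputeMetrics:
    def test_perfect_ordering(self):
        truth = np.r_[np.ones(3, bool), np.zeros(5, bool)]
        m = ev.compute_metrics(np.r_[[0.9, 0.8, 0.7], [0.3, 0.2, 0.1, 0.05, 0.0]], truth)
        assert m["auroc"] == 1.0
        assert m["auprc"] == 1.0

    def test_anti_ordering(self):
        truth = np.r_[np.ones(3, bool), np.zeros(3, bool)]
        m = ev.compute_metrics([0.1, 0.2, 0.3, 0.7, 0.8, 0.9], truth)
        assert m["auroc"] == 0.0

    def test_confusion_counts_at_threshold(self):
        # TP=8 FP=2 FN=4 -> precision 0.8, recall 2/3
        truth = np.r_[np.ones(12, bool), np.zeros(6, bool)]
        scores = np.r_[np.full(8, 0.9), np.full(4, 0.1), np.full(2, 0.9), np.full(4, 0.1)]
        m = ev.compute_metrics(scores, truth)
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(2 / 3)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            ev.compute_metrics([0.1, 0.9], [True, True])

    def test_auroc_matches_pair_counting(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 51))
            truth = rng.random(n) < 0.4
            if truth.all() or not truth.any():
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            got = ev.compute_metrics(scores, truth)["auroc"]
            assert got == pytest.approx(oracles.auroc_pairs(scores, truth), abs=1e-12)


class TestEvaluateUndersampled:
    def test_separable_classes_near_perfect(self):
        X, y = gaussian_classes(sep=6.0, seed=0)
        res = ev.evaluate_undersampled(X, y, reps=10, seed=0)
        assert np.mean(res.auroc) >= 0.99
        assert res.repetitions == 10

    def test_shuffled_labels_near_chance(self):
        X, y = gaussian_classes(sep=6.0, seed=1)
        rng = np.random.default_rng(1)
        res = ev.evaluate_undersampled(X, rng.permutation(y), reps=10, seed=1)
        assert abs(np.mean(res.auroc) - 0.5) <= 0.1

    def test_single_repetition(self):
        X, y = gaussian_classes(n=120, seed=2)
        res = ev.evaluate_undersampled(X, y, reps=1, seed=2)
        assert len(res.auroc) == len(res.precision) == 1

    def test_reproducible_given_seed(self):
        X, y = gaussian_classes(n=150, sep=2.0, seed=3)
        a = ev.evaluate_undersampled(X, y, reps=3, seed=7)
        b = ev.evaluate_undersampled(X, y, reps=3, seed=7)
        assert a.auroc == b.auroc
        assert a.precision == b.precision


class TestCompareZtest:
    def test_identical_lists_are_indistinguishable(self):
        a = ev.EvaluationResult(auroc=[0.8, 0.9, 0.85])
        z, p = ev.compare_ztest(a, a, "auroc")
        assert z == 0.0
        assert p == 0.5

    def test_closed_form_worked_example(self):
        rng = np.random.default_rng(0)

        def with_moments(mean, sd, n):
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1) * sd + mean
            return ev.EvaluationResult(auroc=list(x))

        a = with_moments(0.85, 0.01, 50)
        b = with_moments(0.80, 0.01, 50)
        z, p = ev.compare_ztest(a, b, "auroc")
        assert z == pytest.approx(25.0, abs=1e-9)
        assert p < 1e-100

    def test_direction(self):
        a = ev.EvaluationResult(auroc=[0.6, 0.61, 0.59])
        b = ev.EvaluationResult(auroc=[0.8, 0.81, 0.79])
        _, p = ev.compare_ztest(a, b, "auroc")
        assert p > 0.5

    def test_zero_variance_degenerate_cases(self):
        hi = ev.EvaluationResult(auroc=[0.9, 0.9])
        lo = ev.EvaluationResult(auroc=[0.8, 0.8])
        assert ev.compare_ztest(hi, lo, "auroc")[1] == 0.0
        assert ev.compare_ztest(lo, hi, "auroc")[1] == 1.0
        assert ev.compare_ztest(hi, hi, "auroc")[1] == 0.5

    def test_unequal_repetitions_rejected(self):
        a = ev.EvaluationResult(auroc=[0.8, 0.9])
        b = ev.EvaluationResult(auroc=[0.8])
        with pytest.raises(ValueError, match="repetition"):
            ev.compare_ztest(a, b, "auroc")


def stacked(parts):
    frames, ys = [], []
    for org, (X, y) in parts.items():
        idx = pd.MultiIndex.from_product(
            [[org], [f"g{i}" for i in range(len(y))]], names=["organism_id", "gene_id"]
        )
        frames.append(pd.DataFrame(X, index=idx))
        ys.append(pd.Series(y, index=idx))
    return pd.concat(frames), pd.concat(ys)


class TestLeaveOneSpeciesOut:
    def test_planted_signal_transfers(self):
        parts = {f"o{i}": gaussian_classes(n=150, sep=3.0, seed=i) for i in range(3)}
        X, y = stacked(parts)
        res = ev.leave_one_species_out(X, y, forest_trees=50, seed=0)
        assert set(res.organisms) == set(parts)
        assert (res.metric("auroc") > 0.5).all()

    def test_identical_organisms_score_identically(self):
        Xo, yo = gaussian_classes(n=120, sep=2.0, seed=5)
        X, y = stacked({"a": (Xo, yo), "b": (Xo.copy(), yo.copy())})
        res = ev.leave_one_species_out(X, y, forest_trees=30, seed=3)
        # same training data (the other, identical organism) up to undersampling
        assert res.metrics["a"]["auroc"] == pytest.approx(res.metrics["b"]["auroc"], abs=0.05)

    def test_single_organism_rejected(self):
        X, y = stacked({"only": gaussian_classes(n=60, seed=6)})
        with pytest.raises(ValueError, match="at least 2"):
            ev.leave_one_species_out(X, y, seed=0)

    def test_single_class_holdout_skips_rank_metrics(self):
        Xa, ya = gaussian_classes(n=80, seed=7)
        Xb, yb = gaussian_classes(n=80, seed=8)
        Xc = np.random.default_rng(7).standard_normal((40, 4))
        yc = np.zeros(40, bool)  # held-out organism with no essential gene
        X, y = stacked({"a": (Xa, ya), "b": (Xb, yb), "c": (Xc, yc)})
        res = ev.leave_one_species_out(X, y, forest_trees=20, seed=1)
        assert np.isnan(res.metrics["c"]["auroc"])
        assert not np.isnan(res.metrics["a"]["auroc"])
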