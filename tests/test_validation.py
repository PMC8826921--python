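"""Resampling machinery: metrics, inner component selection, MC-2CV,
balanced subsampling, external validation, leak checks."""

import copy

import numpy as np
import pytest

from metabofp.oplsda import fit_oplsda
from metabofp.validation import (
    CvConfig,
    StratificationError,
    balanced_subsample_cv,
    classification_metrics,
    external_validation,
    inner_component_selection,
    mc_2cv,
)

FAST_CV = dict(outer_repetitions=20, inner_repetitions=10, max_ortho=2)


def labelled_data(seed=0, n_pos=30, n_neg=30, p=40, signal=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_pos + n_neg, p))
    y = np.array(["dn2PD"] * n_pos + ["CTR"] * n_neg)
    X[:n_pos, :10] += signal
    return X, y


class TestClassificationMetrics:
    def test_confusion_worked_example(self):
        true = ["P"] * 3 + ["P"] + ["N"] * 2 + ["N"] * 2
        pred = ["P"] * 3 + ["N"] + ["N"] * 2 + ["P"] * 2
        acc, sens, spec = classification_metrics(true, pred, "P")
        assert (acc, sens, spec) == (0.625, 0.75, 0.5)

    def test_all_correct(self):
        y = ["P", "N", "P", "N"]
        assert classification_metrics(y, y, "P") == (1.0, 1.0, 1.0)

    def test_all_wrong(self):
        true = ["P", "N", "P", "N"]
        pred = ["N", "P", "N", "P"]
        assert classification_metrics(true, pred, "P") == (0.0, 0.0, 0.0)

    def test_absent_positive_class_raises(self):
        with pytest.raises(StratificationError):
            classification_metrics(["N", "N"], ["N", "N"], "P")


class TestInnerSelection:
    def test_result_always_in_candidate_range(self, rng):
        X, y = labelled_data(seed=1)
        cfg = CvConfig(seed=1, **FAST_CV)
        k = inner_component_selection(X, y, cfg, rng)
        assert 0 <= k <= cfg.max_ortho

    def test_planted_orthogonal_confound_selects_at_least_one(self):
        # a strong structured component orthogonal to class membership:
        # removing it should help, so selection should rarely pick 0
        hits = 0
        runs = 10
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            X, y = labelled_data(seed=seed, signal=0.35, p=60)
            confound = rng.standard_normal(len(y))
            confound -= confound.mean()
            coded = np.where(y == "dn2PD", 1.0, -1.0)
            confound -= coded * (confound @ coded) / (coded @ coded)
            direction = np.zeros(60)
            direction[10:40] = 1.0
            X = X + np.outer(confound, direction) * 3.0
            cfg = CvConfig(seed=seed, inner_repetitions=25, max_ortho=3)
            k = inner_component_selection(X, y, cfg, np.random.default_rng(seed))
            hits += int(k >= 1)
        assert hits / runs >= 0.8

    def test_tiny_class_raises(self, rng):
        X, y = labelled_data(n_pos=1, n_neg=10)
        with pytest.raises(StratificationError):
            inner_component_selection(X, y, CvConfig(**FAST_CV), rng)


class TestMc2cv:
    def test_null_data_accuracy_near_chance(self):
        X, y = labelled_data(seed=3, n_pos=30, n_neg=30, p=60)
        res = mc_2cv(X, y, CvConfig(seed=3, outer_repetitions=40,
                                    inner_repetitions=10, max_ortho=2))
        assert 0.40 <= res.summary["accuracy"]["mean"] <= 0.60

    def test_separated_classes_high_accuracy(self):
        X, y = labelled_data(seed=4, signal=3.0)
        res = mc_2cv(X, y, CvConfig(seed=4, **FAST_CV))
        assert res.summary["accuracy"]["mean"] >= 0.95

    def test_same_seed_reproducible(self):
        X, y = labelled_data(seed=5, signal=0.5)
        cfg = CvConfig(seed=9, **FAST_CV)
        r1, r2 = mc_2cv(X, y, cfg), mc_2cv(X, y, cfg)
        assert np.array_equal(r1.accuracy, r2.accuracy)
        assert np.array_equal(r1.chosen_n_ortho, r2.chosen_n_ortho)

    def test_metrics_bounded_and_ci_contains_mean(self):
        X, y = labelled_data(seed=6, signal=1.0)
        res = mc_2cv(X, y, CvConfig(seed=6, **FAST_CV))
        for v in (res.accuracy, res.sensitivity, res.specificity):
            assert np.all((v >= 0) & (v <= 1))
        s = res.summary["accuracy"]
        assert s["ci95_low"] <= s["mean"] <= s["ci95_high"]

    def test_single_class_raises(self):
        X, _ = labelled_data()
        with pytest.raises(StratificationError):
            mc_2cv(X, ["dn2PD"] * X.shape[0], CvConfig(**FAST_CV))


class TestBalancedSubsample:
    def test_equal_groups_match_mc2cv_within_ci(self):
        X, y = labelled_data(seed=7, signal=0.8)
        cfg = CvConfig(seed=7, outer_repetitions=30, inner_repetitions=10, max_ortho=2)
        a = mc_2cv(X, y, cfg).summary["accuracy"]
        b = balanced_subsample_cv(X, y, cfg, n_models=30).summary["accuracy"]
        assert a["ci95_low"] <= b["ci95_high"] and b["ci95_low"] <= a["ci95_high"]

    def test_unbalanced_groups_are_equalized(self, monkeypatch):
        X, y = labelled_data(seed=8, n_pos=60, n_neg=15, signal=0.5)
        seen = []
        import metabofp.validation as v

        orig = v._one_outer_repetition

        def spy(Xs, ys, cfg, rng):
            seen.append({g: int((ys == g).sum()) for g in np.unique(ys)})
            return orig(Xs, ys, cfg, rng)

        monkeypatch.setattr(v, "_one_outer_repetition", spy)
        balanced_subsample_cv(X, y, CvConfig(seed=8, inner_repetitions=5, max_ortho=1),
                              n_models=5)
        assert all(c == {"CTR": 15, "dn2PD": 15} for c in seen)

    def test_same_seed_reproducible(self):
        X, y = labelled_data(seed=9, n_pos=40, n_neg=25, signal=0.5)
        cfg = CvConfig(seed=10, inner_repetitions=5, max_ortho=1)
        r1 = balanced_subsample_cv(X, y, cfg, n_models=8)
        r2 = balanced_subsample_cv(X, y, cfg, n_models=8)
        assert np.array_equal(r1.accuracy, r2.accuracy)

    def test_tiny_minority_raises(self):
        X, y = labelled_data(n_pos=3, n_neg=30)
        with pytest.raises(StratificationError):
            balanced_subsample_cv(X, y, CvConfig(**FAST_CV))


class TestExternalValidation:
    def test_training_set_reproduces_in_sample_metrics(self):
        X, y = labelled_data(seed=11, signal=1.5)
        model = fit_oplsda(X, y, n_ortho=1, positive_class="dn2PD")
        from metabofp.oplsda import predict_oplsda

        _, pred = predict_oplsda(model, X)
        expect = classification_metrics(y, pred, "dn2PD")
        got = external_validation(model, X, y, "dn2PD")
        assert (got["accuracy"], got["sensitivity"], got["specificity"]) == expect

    def test_prediction_does_not_mutate_model(self):
        X, y = labelled_data(seed=12, signal=1.0)
        model = fit_oplsda(X, y, n_ortho=2, positive_class="dn2PD")
        before = copy.deepcopy(model)
        Xnew, ynew = labelled_data(seed=13, signal=1.0)
        external_validation(model, Xnew, ynew, "dn2PD")
        for attr in ("mean", "sd", "w", "p", "W_o", "P_o"):
            assert np.array_equal(getattr(model, attr), getattr(before, attr))
        assert model.q == before.q

    def test_generalization_from_same_process(self):
        # validation cohort drawn from the training generative process:
        # external accuracy should land inside the training CV interval most
        # of the time
        inside = 0
        runs = 5
        for seed in range(runs):
            X, y = labelled_data(seed=20 + seed, n_pos=40, n_neg=40, signal=0.9)
            cfg = CvConfig(seed=20 + seed, outer_repetitions=25,
                           inner_repetitions=10, max_ortho=2)
            cv = mc_2cv(X, y, cfg)
            model = fit_oplsda(X, y, n_ortho=1, positive_class="dn2PD")
            Xv, yv = labelled_data(seed=50 + seed, n_pos=75, n_neg=10, signal=0.9)
            ext = external_validation(model, Xv, yv, "dn2PD")
            s = cv.summary["accuracy"]
            if s["ci95_low"] - 0.05 <= ext["accuracy"] <= s["ci95_high"] + 0.05:
                inside += 1
        assert inside / runs >= 0.8
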