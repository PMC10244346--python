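import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from pscml.dose_model import (
    CLASSES,
    choose_duration,
    cross_batch_validate,
    delta_chir,
    deviation_scores,
    evaluate_classifier,
    label_doses,
    select_features_anova,
    train_dose_classifier,
)


def make_records(conc_fracs: dict[float, float], duration=24.0, n_per=4) -> pd.DataFrame:
    rows = []
    for c, frac in conc_fracs.items():
        for i in range(n_per):
            rows.append(
                {"well_id": f"w{c}-{i}", "chir_um": c, "chir_h": duration, "positive_fraction": frac}
            )
    return pd.DataFrame(rows)


class TestLabeling:
    def test_default_threshold_and_range(self):
        df = make_records({4.0: 0.1, 6.0: 0.4, 8.0: 0.25, 10.0: 0.1})
        lab = label_doses(df, 24.0)
        assert (lab.c1, lab.c2) == (6.0, 8.0)

    def test_low_class_signed_distance(self):
        df = make_records({4.0: 0.05, 6.0: 0.3, 8.0: 0.3})
        lab = label_doses(df, 24.0)
        assert lab.classes[4.0] == "low"
        assert lab.delta_chir[4.0] == -2.0

    def test_inside_range_has_zero_delta(self):
        df = make_records({6.0: 0.3, 7.0: 0.35, 8.0: 0.3})
        lab = label_doses(df, 24.0)
        assert lab.classes[7.0] == "optimal"
        assert lab.delta_chir[7.0] == 0.0

    def test_no_qualifying_concentration_is_an_error(self):
        df = make_records({4.0: 0.05, 6.0: 0.1})
        with pytest.raises(ValueError, match="no optimal range"):
            label_doses(df, 24.0)

    def test_delta_sign_matches_class_on_grid(self):
        c1, c2 = 5.0, 8.0
        for c in np.arange(1.0, 14.1, 0.5):
            d = delta_chir(c, c1, c2)
            if c < c1:
                assert d == c - c1 < 0
            elif c > c2:
                assert d == c - c2 > 0
            else:
                assert d == 0.0


class TestDeviationScore:
    def test_all_high_gives_one(self):
        res = deviation_scores(np.array(["high"] * 10), np.full(10, 8.0))
        assert res.scores[8.0] == 1.0

    def test_all_low_gives_minus_one(self):
        res = deviation_scores(np.array(["low"] * 10), np.full(10, 2.0))
        assert res.scores[2.0] == -1.0

    def test_all_optimal_gives_zero(self):
        res = deviation_scores(np.array(["optimal"] * 5), np.full(5, 6.0))
        assert res.scores[6.0] == 0.0

    def test_three_high_one_low_gives_half(self):
        preds = np.array(["high", "high", "high", "low"])
        res = deviation_scores(preds, np.full(4, 9.0))
        assert res.scores[9.0] == 0.5

    def test_bounds_exhaustive_small_n(self):
        for n in range(1, 7):
            for combo in itertools.product(CLASSES, repeat=n):
                res = deviation_scores(np.array(combo), np.full(n, 5.0))
                assert -1.0 <= res.scores[5.0] <= 1.0

    def test_empty_concentration_omitted(self):
        res = deviation_scores(np.array(["high"]), np.array([4.0]))
        assert 6.0 not in res.scores

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            deviation_scores(np.array(["high"]), np.array([4.0, 6.0]))


class TestClassifier:
    def _separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([CLASSES[i % 3] for i in range(n)])
        X = rng.standard_normal((n, 21)) * 0.3
        X[y == "low", 0] -= 4
        X[y == "high", 0] += 4
        return X, y

    def test_separable_three_class_training_accuracy(self):
        X, y = self._separable()
        model = train_dose_classifier(X, y)
        assert (model.predict(X) == y).mean() >= 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_dose_classifier(np.zeros((10, 21)), np.array(["low"] * 10))

    def test_balanced_weights_double_for_half_sized_class(self):
        from sklearn.utils.class_weight import compute_class_weight

        y = np.array(["a"] * 40 + ["b"] * 20)
        w = compute_class_weight("balanced", classes=np.array(["a", "b"]), y=y)
        assert w[1] / w[0] == pytest.approx(2.0)

    def test_elastic_net_preset_l1_ratio(self):
        from pscml.dose_model import REG_PRESETS

        assert REG_PRESETS["cross-batch"]["l1_ratio"] == 0.1
        assert REG_PRESETS["cross-batch"]["solver"] == "saga"


class TestFeatureSelection:
    def test_planted_signal_ranked_first(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1, 2], 30)
        X = rng.standard_normal((90, 21))
        X[:, 13] = y + 0.01 * rng.standard_normal(90)
        sel = select_features_anova(X, y, k=4)
        assert 13 in sel
        F_sel = select_features_anova(X, y, k=1)
        assert F_sel[0] == 13

    def test_k_equals_n_features_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 5))
        y = np.repeat([0, 1], 15)
        np.testing.assert_array_equal(select_features_anova(X, y, k=5), np.arange(5))

    def test_ties_break_toward_lower_index(self):
        y = np.repeat([0, 1], 10)
        base = np.concatenate([np.zeros(10), np.ones(10)])
        X = np.column_stack([base, base, base])  # identical F statistics
        assert select_features_anova(X, y, k=1)[0] == 0

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            select_features_anova(np.zeros((10, 3)), np.repeat([0, 1], 5), k=4)


class TestEvaluation:
    def test_perfect_predictions_score_one(self):
        X, y = TestClassifier()._separable(n=120, seed=3)
        model = train_dose_classifier(X, y)
        metrics = evaluate_classifier(model, X, y)
        if (model.predict(X) == y).all():
            for key in ("accuracy", "precision", "recall", "f1"):
                assert metrics[key] == 1.0
            assert metrics["auc"] == pytest.approx(1.0)

    def test_hand_worked_confusion_matrix(self):
        # y/pred constructed to a fixed 3x3 confusion matrix
        y = np.array(["low"] * 10 + ["optimal"] * 10 + ["high"] * 10)
        pred = np.array(
            ["low"] * 8 + ["optimal"] * 2  # low: 8 correct
            + ["optimal"] * 9 + ["high"] * 1  # optimal: 9 correct
            + ["high"] * 7 + ["low"] * 3  # high: 7 correct
        )

        class Stub:
            classes_ = np.array(["high", "low", "optimal"])

            def predict(self, X):
                return pred

            def predict_proba(self, X):
                onehot = np.zeros((len(pred), 3))
                for i, p in enumerate(pred):
                    onehot[i, list(self.classes_).index(p)] = 1.0
                return onehot

        m = evaluate_classifier(Stub(), np.zeros((30, 1)), y)
        assert m["accuracy"] == pytest.approx(24 / 30)
        # hand computation: precision per class then unweighted mean
        prec = np.mean([7 / 8, 8 / 11, 9 / 11])
        rec = np.mean([7 / 10, 8 / 10, 9 / 10])
        assert m["precision"] == pytest.approx(prec)
        assert m["recall"] == pytest.approx(rec)

    def test_random_predictions_near_chance(self):
        rng = np.random.default_rng(0)
        y = np.array([CLASSES[i % 3] for i in range(900)])

        class Rand:
            classes_ = np.array(CLASSES)

            def predict(self, X):
                return rng.choice(CLASSES, size=len(y))

            def predict_proba(self, X):
                p = rng.random((len(y), 3))
                return p / p.sum(1, keepdims=True)

        m = evaluate_classifier(Rand(), np.zeros((900, 1)), y)
        assert m["accuracy"] == pytest.approx(1 / 3, abs=0.06)


class TestCrossBatch:
    def _batch(self, batch_id, seed):
        # shared dose-response: features depend on delta_chir plus noise
        rng = np.random.default_rng(seed)
        rows = []
        for c, (cls, d) in {
            2.0: ("low", -4.0), 4.0: ("low", -2.0), 6.0: ("optimal", 0.0),
            8.0: ("high", 2.0), 10.0: ("high", 4.0),
        }.items():
            for i in range(8):
                feats = rng.standard_normal(6) * 0.3
                feats[2] += d  # one informative feature
                rows.append(
                    {"batch": batch_id, "chir_um": c, "dose_class": cls, "delta_chir": d,
                     **{f"f{j}": feats[j] for j in range(6)}}
                )
        return pd.DataFrame(rows)

    def test_two_batches_two_rounds_with_ids(self):
        tables = {"A": self._batch("A", 0), "B": self._batch("B", 1)}
        out, r = cross_batch_validate(tables, [f"f{j}" for j in range(6)], n_selected=3)
        assert set(out["batch"]) == {"A", "B"}
        assert len(out) == 10  # 5 concentrations per round

    def test_shared_dose_response_recovered(self):
        tables = {b: self._batch(b, i) for i, b in enumerate("ABC")}
        out, r = cross_batch_validate(tables, [f"f{j}" for j in range(6)], n_selected=2)
        assert r >= 0.8

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError, match="two batches"):
            cross_batch_validate({"A": self._batch("A", 0)}, ["f0"])


class TestDurationChoice:
    def test_score_closest_to_zero_wins(self):
        assert choose_duration({24.0: -0.6, 36.0: 0.1, 48.0: 0.7}) == 36.0

    def test_single_duration_returned(self):
        assert choose_duration({24.0: 0.9}) == 24.0

    def test_tie_breaks_to_shorter_duration(self):
        assert choose_duration({24.0: -0.2, 36.0: 0.2}) == 24.0
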