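"""Balancing, stratified splitting, CV training and one-vs-rest BA evaluation."""

import numpy as np
import pytest

from trapsense import classify, features, simulate
from trapsense.classify import LabeledDataset
from trapsense.types import TARGET_CLASSES, ClassLabel


def make_dataset(counts, d=5, seed=0):
    rng = np.random.default_rng(seed)
    feats, labels, temps = [], [], []
    for c, n in counts.items():
        feats.append(rng.normal(size=(n, d)))
        labels += [c.value] * n
        temps += [23.0] * n
    return LabeledDataset(np.vstack(feats), np.array(labels), np.array(temps))


class TestBalance:
    def test_undersamples_to_minority_count(self):
        data = make_dataset(dict(zip(TARGET_CLASSES, [100, 200, 300, 400])))
        bal = classify.balance_by_undersampling(data, rng_seed=0)
        assert all(v == 100 for v in bal.class_counts().values())

    def test_already_balanced_keeps_rows(self):
        data = make_dataset(dict(zip(TARGET_CLASSES, [50, 50, 50, 50])))
        bal = classify.balance_by_undersampling(data, rng_seed=0)
        assert sorted(map(tuple, bal.features)) == sorted(map(tuple, data.features))

    def test_deterministic_subset(self):
        data = make_dataset(dict(zip(TARGET_CLASSES, [3, 5, 7, 9])))
        a = classify.balance_by_undersampling(data, rng_seed=3)
        b = classify.balance_by_undersampling(data, rng_seed=3)
        np.testing.assert_array_equal(a.features, b.features)

    def test_empty_class_names_offender(self):
        data = make_dataset(dict(zip(TARGET_CLASSES[:3], [5, 5, 5])))
        with pytest.raises(ValueError, match="CULEX_M"):
            classify.balance_by_undersampling(data, rng_seed=0)


class TestSplit:
    def test_stratified_counts_and_disjointness(self):
        data = make_dataset({c: 60 for c in TARGET_CLASSES}, seed=1)
        train, test = classify.split_test_set(data, 40, rng_seed=2)
        assert test.class_counts() == {c.value: 10 for c in TARGET_CLASSES}
        assert len(train) + len(test) == len(data)
        train_rows = {tuple(r) for r in train.features}
        test_rows = {tuple(r) for r in test.features}
        assert not train_rows & test_rows

    def test_zero_test(self):
        data = make_dataset({c: 10 for c in TARGET_CLASSES})
        train, test = classify.split_test_set(data, 0, rng_seed=0)
        assert len(test) == 0 and len(train) == len(data)

    def test_bad_sizes_rejected(self):
        data = make_dataset({c: 10 for c in TARGET_CLASSES})
        with pytest.raises(ValueError):
            classify.split_test_set(data, 41, rng_seed=0)  # not divisible by 4
        with pytest.raises(ValueError):
            classify.split_test_set(data, 400, rng_seed=0)  # too large


class TestBalancedAccuracyFormula:
    def test_perfect_predictions(self):
        y = np.repeat([c.value for c in TARGET_CLASSES], 5)
        assert classify.mean_balanced_accuracy(y, y) == 100.0

    def test_two_class_reduction_by_hand(self):
        # confusion [[9,1],[2,8]]: class-1 Se=0.9, Sp=0.8 -> BA 85%
        y_true = np.array(["AEDES_F"] * 10 + ["AEDES_M"] * 10)
        y_pred = np.array(
            ["AEDES_F"] * 9 + ["AEDES_M"] + ["AEDES_F"] * 2 + ["AEDES_M"] * 8
        )
        cm = classify._confusion(y_true, y_pred)
        per_class, _ = classify._ovr_ba_from_confusion(cm)
        assert per_class["AEDES_F"] == pytest.approx(85.0)
        assert per_class["AEDES_M"] == pytest.approx(85.0)

    def test_ba_invariant_to_other_class_row_order(self, small_model, small_split):
        _, test = small_split
        report = classify.evaluate_classifier(small_model, test)
        perm = np.random.default_rng(0).permutation(len(test))
        shuffled = test.take(perm)
        report2 = classify.evaluate_classifier(small_model, shuffled)
        assert report.per_class_ba == report2.per_class_ba


class TestTraining:
    def test_degenerate_features_rejected(self):
        data = make_dataset({c: 20 for c in TARGET_CLASSES})
        data.features[:] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            classify.train_classifier(data)

    def test_well_separated_classes_reach_high_cv_ba(self):
        # disjoint f0 ranges guarantee separability by construction
        from trapsense.types import WingbeatParams

        params = {
            c: WingbeatParams(250.0 + 180.0 * i, f0_sd=10.0)
            for i, c in enumerate(TARGET_CLASSES)
        }
        params[ClassLabel.NON_TARGET] = WingbeatParams(150.0)
        recs = simulate.simulate_lab_dataset(
            {(c, 23.0): 40 for c in TARGET_CLASSES},
            invalid_fraction=0.0, rng_seed=21, params=params,
        )
        table = features.extract_feature_table(recs)
        data = LabeledDataset(
            features.feature_matrix(table),
            table["label"].to_numpy(),
            table["temperature"].to_numpy(float),
        )
        model = classify.train_classifier(
            data, grid=[{"max_depth": 3, "learning_rate": 0.3}], rng_seed=0
        )
        assert model.cv_results[0]["cv_ba"] >= 95.0

    def test_permuted_labels_score_at_chance(self, small_split):
        train, _ = small_split
        rng = np.random.default_rng(5)
        permuted = LabeledDataset(
            train.features, rng.permutation(train.labels), train.temperature
        )
        model = classify.train_classifier(
            permuted, grid=[{"max_depth": 3, "learning_rate": 0.3}], rng_seed=0
        )
        assert abs(model.cv_results[0]["cv_ba"] - 50.0) <= 5.0

    def test_same_seed_same_folds_and_predictions(self, small_split):
        train, test = small_split
        grid = [{"max_depth": 3, "learning_rate": 0.3}]
        m1 = classify.train_classifier(train, grid=grid, rng_seed=7)
        m2 = classify.train_classifier(train, grid=grid, rng_seed=7)
        np.testing.assert_array_equal(m1.fold_assignment, m2.fold_assignment)
        np.testing.assert_array_equal(
            m1.predict(test.features), m2.predict(test.features)
        )


class TestEvaluation:
    def test_confusion_conserves_test_rows(self, small_model, small_split):
        _, test = small_split
        report = classify.evaluate_classifier(small_model, test)
        assert report.confusion.sum() == len(test)
        np.testing.assert_array_equal(
            report.confusion.sum(axis=1),
            [test.class_counts()[c.value] for c in TARGET_CLASSES],
        )

    def test_separable_test_ba(self, small_model, small_split):
        _, test = small_split
        report = classify.evaluate_classifier(small_model, test)
        assert report.mean_ba >= 85.0  # small-sample bound; lab-scale is tighter

    def test_missing_class_flagged(self, small_model, small_split):
        _, test = small_split
        keep = test.labels != ClassLabel.AEDES_F.value
        sub = test.take(np.flatnonzero(keep))
        report = classify.evaluate_classifier(small_model, sub)
        assert report.undefined_classes == [ClassLabel.AEDES_F.value]
        assert ClassLabel.AEDES_F.value not in report.per_class_ba


class TestRobustnessProperties:
    def small_run(self, f0_sd_scale, seed):
        base = simulate.default_wingbeat_params()
        params = {
            label: type(p)(
                p.f0_base,
                temp_coeff=p.temp_coeff,
                n_harmonics=p.n_harmonics,
                harmonic_decay=p.harmonic_decay,
                f0_sd=p.f0_sd * f0_sd_scale,
            )
            for label, p in base.items()
        }
        recs = simulate.simulate_lab_dataset(
            {(c, 23.0): 60 for c in TARGET_CLASSES},
            invalid_fraction=0.0, rng_seed=seed, params=params,
        )
        table = features.extract_feature_table(recs)
        data = LabeledDataset(
            features.feature_matrix(table),
            table["label"].to_numpy(),
            table["temperature"].to_numpy(float),
        )
        train, test = classify.split_test_set(data, 40, rng_seed=seed)
        model = classify.train_classifier(
            train, grid=[{"max_depth": 3, "learning_rate": 0.3}], rng_seed=0
        )
        return classify.evaluate_classifier(model, test).mean_ba

    def test_more_class_overlap_never_helps(self):
        # widen the between-individual f0 spread over a 3-point grid
        bas = [np.mean([self.small_run(s, seed) for seed in (1, 2)])
               for s in (0.5, 2.0, 4.0)]
        margin = 4.0  # Monte-Carlo slack at this sample size
        assert bas[0] >= bas[1] - margin
        assert bas[1] >= bas[2] - margin
        assert bas[0] > bas[2]

    def test_cross_temperature_model_matches_per_temperature_models(self):
        recs = simulate.simulate_lab_dataset(50, invalid_fraction=0.0, rng_seed=11)
        table = features.extract_feature_table(recs)
        data = LabeledDataset(
            features.feature_matrix(table),
            table["label"].to_numpy(),
            table["temperature"].to_numpy(float),
        )
        grid = [{"max_depth": 3, "learning_rate": 0.3}]
        train, test = classify.split_test_set(data, 160, rng_seed=0)
        full_model = classify.train_classifier(train, grid=grid, rng_seed=0)
        for temp in (18.0, 23.0, 28.0):
            tr_idx = np.flatnonzero(train.temperature == temp)
            te_idx = np.flatnonzero(test.temperature == temp)
            sub_test = test.take(te_idx)
            per_temp = classify.train_classifier(
                train.take(tr_idx), grid=grid, rng_seed=0
            )
            ba_full = classify.evaluate_classifier(full_model, sub_test).mean_ba
            ba_temp = classify.evaluate_classifier(per_temp, sub_test).mean_ba
            assert ba_full >= ba_temp - 5.0
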