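"""Pre-index aggregation, leakage guards, predictor fitting and importance."""

import numpy as np
import pandas as pd
import pytest

from progsub import io as pio
from progsub import predict
from progsub.predict import PreIndexFeatures


@pytest.fixture(scope="module")
def pre_index(small_synth):
    gt = small_synth.ground_truth
    index_dates = dict(zip(gt["patient_id"], gt["first_mci_date"]))
    return predict.aggregate_pre_index(small_synth.cohort, index_dates,
                                       small_synth.code_maps)


class TestAggregation:
    def test_or_rule_and_post_index_exclusion(self):
        demo = pd.DataFrame({"patient_id": ["p1"],
                             "birth_date": [pd.Timestamp("1940-01-01")],
                             "sex": ["F"], "race_ethnicity": ["NHW"]})
        dx = pd.DataFrame({
            "patient_id": ["p1"] * 3,
            "date": pd.to_datetime(["2014-01-01", "2014-06-01",
                                    "2015-06-02"]),
            "code": ["A", "B", "C"], "code_system": ["X"] * 3})
        empty_rx = dx.iloc[:0].copy()
        vt = pd.DataFrame(columns=["patient_id", "date", "bmi", "systolic",
                                   "diastolic", "smoking"])
        cohort = pio.Cohort(demo, dx, empty_rx, vt)
        maps = {"diagnosis": pio.CodeMap("ICD", {"A": "PA", "B": "PB",
                                                 "C": "PC"}),
                "drug": pio.CodeMap("RX", {})}
        out = predict.aggregate_pre_index(
            cohort, {"p1": pd.Timestamp("2015-06-01")}, maps)
        x = dict(zip(out.feature_names, out.X[0]))
        assert x["dx:PA"] == 1 and x["dx:PB"] == 1   # OR over windows
        assert x["dx:PC"] == 0                       # dated after index

    def test_erasing_post_index_rows_changes_nothing(self, small_synth,
                                                     pre_index):
        gt = small_synth.ground_truth
        index_dates = dict(zip(gt["patient_id"], gt["first_mci_date"]))
        cohort = small_synth.cohort

        def truncate(df):
            idx = df["patient_id"].map(index_dates)
            return df[df["date"] <= idx]

        erased = pio.Cohort(cohort.demographics, truncate(cohort.diagnoses),
                            truncate(cohort.drugs), truncate(cohort.vitals))
        out2 = predict.aggregate_pre_index(erased, index_dates,
                                           small_synth.code_maps)
        assert out2.patient_ids == pre_index.patient_ids
        assert np.array_equal(out2.X, pre_index.X)

    def test_patient_without_pre_index_data_excluded(self, small_synth):
        gt = small_synth.ground_truth
        index_dates = {gt["patient_id"].iloc[0]:
                       pd.Timestamp("1990-01-01")}  # before any record
        out = predict.aggregate_pre_index(small_synth.cohort, index_dates,
                                          small_synth.code_maps)
        assert out.patient_ids == []


class TestResampling:
    def test_oversample_balances_up(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([0] * 25 + [1] * 5)
        Xo, yo = predict.oversample(X, y, rng)
        counts = np.bincount(yo)
        assert counts[0] == counts[1] == 25

    def test_undersample_balances_down(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([0] * 25 + [1] * 5)
        Xu, yu = predict.undersample(X, y, rng)
        counts = np.bincount(yu)
        assert counts[0] == counts[1] == 5


class TestPredictors:
    def test_no_signal_auroc_near_half(self, rng):
        X = (rng.random((240, 12)) < 0.3).astype(float)
        y = rng.integers(0, 2, size=240)
        feats = PreIndexFeatures([f"p{i}" for i in range(240)], X,
                                 [f"f{j}" for j in range(12)])
        reports = predict.fit_predictors(feats, y, models=("ridge",),
                                         seed=0, n_trials=2)
        assert abs(reports[("ridge", "none")].test_auroc - 0.5) < 0.15

    def test_deterministic_label_reaches_high_auroc(self, rng):
        X = (rng.random((200, 10)) < 0.5).astype(float)
        y = X[:, 3].astype(int)
        feats = PreIndexFeatures([f"p{i}" for i in range(200)], X,
                                 [f"f{j}" for j in range(10)])
        reports = predict.fit_predictors(
            feats, y, models=("logistic", "gradient_boosting"),
            resampling=("none", "oversample"), seed=0, n_trials=3)
        for rep in reports.values():
            assert rep.test_auroc > 0.95

    def test_resampling_inside_folds_does_not_inflate_cv(self, rng):
        """CV AUROC with in-fold oversampling stays close to the held-out
        AUROC, unlike oversampling before the split which duplicates
        samples across folds."""
        from sklearn.model_selection import StratifiedKFold

        n = 600
        X = rng.normal(size=(n, 8))
        w = rng.normal(size=8) * 0.35
        y = (X @ w + rng.normal(scale=2.0, size=n) > 1.5).astype(int)
        feats = PreIndexFeatures([f"p{i}" for i in range(n)], X,
                                 [f"f{j}" for j in range(8)])
        reports = predict.fit_predictors(feats, y,
                                         models=("gradient_boosting",),
                                         resampling=("oversample",),
                                         seed=1, n_trials=3)
        rep = reports[("gradient_boosting", "oversample")]
        assert abs(rep.cv_auroc - rep.test_auroc) < 0.12

        # leaky variant: oversample the whole set, then cross-validate;
        # duplicated minority rows cross fold boundaries and get memorized
        Xo, yo = predict.oversample(X, y, rng)
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        leaky = []
        for tr, va in skf.split(Xo, yo):
            model = predict._make_model(
                "gradient_boosting",
                {"n_estimators": 100, "max_depth": 4}, 0)
            model.fit(Xo[tr], yo[tr])
            leaky.append(predict.macro_auroc(model, Xo[va], yo[va], [0, 1]))
        assert np.mean(leaky) > rep.cv_auroc + 0.05  # visible inflation

    def test_single_class_rejected(self, rng):
        feats = PreIndexFeatures(["p0", "p1"], np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            predict.fit_predictors(feats, np.zeros(2, dtype=int))


class TestImportance:
    def _planted(self, rng, n=200):
        X = (rng.random((n, 8)) < 0.5).astype(float)
        X[:, 7] = 0.0  # dead feature
        y = X[:, 2].astype(int)
        feats = PreIndexFeatures([f"p{i}" for i in range(n)], X,
                                 [f"f{j}" for j in range(8)])
        return feats, y

    def test_informative_feature_ranks_first_dead_feature_last(self, rng):
        feats, y = self._planted(rng)
        model = predict._make_model("logistic", {}, 0)
        model.fit(feats.X, y)
        table = predict.importance(model, feats, y, n_repeats=10, seed=0)
        assert table.iloc[0]["feature"] == "f2"
        dead = table[table["feature"] == "f7"]["importance"].iloc[0]
        assert abs(dead) < 1e-9

    def test_same_seed_identical_ranking(self, rng):
        feats, y = self._planted(rng)
        model = predict._make_model("ridge", {"C": 1.0}, 0)
        model.fit(feats.X, y)
        a = predict.importance(model, feats, y, n_repeats=5, seed=3)
        b = predict.importance(model, feats, y, n_repeats=5, seed=3)
        assert list(a["feature"]) == list(b["feature"])
        assert np.allclose(a["importance"], b["importance"])

    def test_unknown_method_rejected(self, rng):
        feats, y = self._planted(rng)
        model = predict._make_model("logistic", {}, 0)
        model.fit(feats.X, y)
        with pytest.raises(ValueError):
            predict.importance(model, feats, y, method="nope")
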