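"""Subphenotype predictability from pre-index information.

The index date is each patient's first MCI diagnosis. A cross-sectional
binary vector aggregates everything recorded strictly up to and including
the index date (OR over the feature bits of the pre-index record;
demographics evaluated at the index date); nothing after the index date may
influence the features, which a standing erasure test enforces. Linear
models (logistic, lasso, ridge, elastic net) and gradient boosting then
predict cluster membership with seeded random hyperparameter search under
5-fold cross-validation, optional random over/under-sampling applied inside
training folds only, and permutation-based feature importance (mean macro
AUROC drop over repeated shuffles); SHAP values are produced instead when
the optional shap package is installed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import label_binarize

from .featurize import FeaturizedCohort, age_bin, build_feature_space
from .io import Cohort


@dataclass
class PreIndexFeatures:
    """Cross-sectional pre-index design matrix with subphenotype targets."""

    patient_ids: list
    X: np.ndarray
    feature_names: list

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "patient_id", self.patient_ids)
        return df


def aggregate_pre_index(cohort: Cohort, index_dates: dict,
                        code_maps: dict, feature_space=None,
                        thresholds=None) -> PreIndexFeatures:
    """Aggregate each patient's record up to the index date into one vector.

    Code and vital bits are OR-ed over all encounters with date <= index
    date; age is binned at the index date. Patients with no pre-index
    encounter are excluded.
    """
    from .featurize import discretize_vitals

    if feature_space is None:
        feature_space = build_feature_space(cohort, code_maps)
    name_to_idx = {n: i for i, n in enumerate(feature_space.names)}
    ids, rows = [], []
    for pid, index_date in index_dates.items():
        records = [r for r in cohort.records_for(pid) if r.date <= index_date]
        if not records:
            continue
        x = np.zeros(feature_space.n_features, dtype=np.uint8)
        demo = cohort.demographics_for(pid)
        age = (index_date - demo["birth_date"]).days / 365.25
        x[name_to_idx[age_bin(age)]] = 1
        for key in (f"sex:{demo['sex']}", f"race:{demo['race_ethnicity']}"):
            if key in name_to_idx:
                x[name_to_idx[key]] = 1
        for rec in records:
            for code in rec.diagnosis_codes:
                x[name_to_idx[f"dx:{code_maps['diagnosis'].apply(code)}"]] = 1
            for code in rec.drug_codes:
                x[name_to_idx[f"rx:{code_maps['drug'].apply(code)}"]] = 1
            if rec.vitals:
                for cat in discretize_vitals(
                        bmi=rec.vitals.get("bmi"),
                        systolic=rec.vitals.get("systolic"),
                        diastolic=rec.vitals.get("diastolic"),
                        smoking=rec.vitals.get("smoking"),
                        thresholds=thresholds):
                    x[name_to_idx[cat]] = 1
        ids.append(pid)
        rows.append(x)
    return PreIndexFeatures(patient_ids=ids, X=np.asarray(rows),
                            feature_names=list(feature_space.names))


def pre_index_from_featurized(cohort: Cohort, feat: FeaturizedCohort,
                              code_maps: dict) -> PreIndexFeatures:
    return aggregate_pre_index(cohort, feat.index_dates, code_maps,
                               feature_space=feat.feature_space)


# ---------------------------------------------------------------------------
# resampling and model search


def oversample(X, y, rng) -> tuple:
    """Random oversampling of minority classes to the majority size."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        idx.append(members)
        if len(members) < n_max:
            idx.append(rng.choice(members, n_max - len(members),
                                  replace=True))
    idx = np.concatenate(idx)
    return X[idx], y[idx]


def undersample(X, y, rng) -> tuple:
    """Random undersampling of majority classes to the minority size."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    idx = np.concatenate([rng.choice(np.flatnonzero(y == c), n_min,
                                     replace=False) for c in classes])
    return X[idx], y[idx]


_RESAMPLERS = {"none": None, "oversample": oversample,
               "undersample": undersample}


def _make_model(name: str, params: dict, seed: int):
    common = dict(max_iter=2000, random_state=seed)
    if name == "logistic":
        return LogisticRegression(C=np.inf, **common)
    if name == "lasso":
        return LogisticRegression(solver="saga", l1_ratio=1.0,
                                  C=params.get("C", 1.0), **common)
    if name == "ridge":
        return LogisticRegression(C=params.get("C", 1.0), **common)
    if name == "elastic_net":
        return LogisticRegression(solver="saga",
                                  C=params.get("C", 1.0),
                                  l1_ratio=params.get("l1_ratio", 0.5),
                                  **common)
    if name == "gradient_boosting":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth", 3),
            learning_rate=params.get("learning_rate", 0.1),
            subsample=params.get("subsample", 1.0),
            random_state=seed, n_jobs=1, verbosity=0,
            eval_metric="mlogloss")
    raise ValueError(f"unknown model '{name}'")


_SEARCH_SPACE = {
    "logistic": {},
    "lasso": {"C": [0.01, 0.1, 1.0, 10.0]},
    "ridge": {"C": [0.01, 0.1, 1.0, 10.0]},
    "elastic_net": {"C": [0.01, 0.1, 1.0, 10.0],
                    "l1_ratio": [0.2, 0.5, 0.8]},
    "gradient_boosting": {"n_estimators": [50, 100, 200],
                          "max_depth": [2, 3, 4],
                          "learning_rate": [0.05, 0.1, 0.3],
                          "subsample": [0.7, 1.0]},
}


def _sample_params(space: dict, rng) -> dict:
    return {k: v[rng.integers(len(v))] for k, v in space.items()}


def macro_auroc(model, X, y, classes) -> float:
    probs = model.predict_proba(X)
    if len(classes) == 2:
        return float(roc_auc_score(y, probs[:, 1]))
    Y = label_binarize(y, classes=classes)
    present = Y.sum(axis=0) > 0
    return float(roc_auc_score(Y[:, present], probs[:, present],
                               average="macro"))


def _cv_score(name, params, X, y, resampler, seed, n_folds=5) -> float:
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    rng = np.random.default_rng(seed)
    for tr, va in skf.split(X, y):
        Xtr, ytr = X[tr], y[tr]
        if resampler is not None:  # resampling inside the training fold only
            Xtr, ytr = resampler(Xtr, ytr, rng)
        model = _make_model(name, params, seed)
        model.fit(Xtr, ytr)
        scores.append(macro_auroc(model, X[va], y[va], classes))
    return float(np.mean(scores))


@dataclass
class FitReport:
    model_name: str
    resampling: str
    best_params: dict
    cv_auroc: float
    test_auroc: float
    test_metrics: pd.DataFrame
    model: object


def fit_predictors(features: PreIndexFeatures, labels,
                   models=("logistic", "lasso", "ridge", "elastic_net",
                           "gradient_boosting"),
                   resampling=("none",), seed: int = 0, n_trials: int = 20,
                   test_frac: float = 0.25) -> dict:
    """Tune, fit and evaluate subphenotype predictors.

    Hyperparameters are tuned by seeded random search over a declared grid
    with 5-fold CV macro AUROC on the training split only; resampling is
    applied inside folds. Returns {(model, resampling): FitReport} with
    held-out one-vs-rest metrics.
    """
    X = np.asarray(features.X, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    small = min(np.bincount(np.searchsorted(classes, y)))
    if small < 5:
        import warnings

        warnings.warn(f"smallest class has {small} members; "
                      "stratification degraded")
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_frac, random_state=seed,
        stratify=y if small >= 2 else None)
    reports = {}
    for name in models:
        space = _SEARCH_SPACE[name]
        for rs_name in resampling:
            resampler = _RESAMPLERS[rs_name]
            rng = np.random.default_rng(seed)
            n_combo = int(np.prod([len(v) for v in space.values()])) \
                if space else 1
            trials = min(n_trials, n_combo)
            best_params, best_score = {}, -np.inf
            for _ in range(max(trials, 1)):
                params = _sample_params(space, rng)
                score = _cv_score(name, params, Xtr, ytr, resampler, seed)
                if score > best_score:
                    best_score, best_params = score, params
            Xfit, yfit = Xtr, ytr
            if resampler is not None:
                Xfit, yfit = resampler(Xfit, yfit,
                                       np.random.default_rng(seed))
            model = _make_model(name, best_params, seed)
            model.fit(Xfit, yfit)
            test_auroc = macro_auroc(model, Xte, yte, classes)
            pred = model.predict(Xte)
            rows = []
            for c in classes:
                pos, ppos = yte == c, pred == c
                tp = (pos & ppos).sum()
                fn = (pos & ~ppos).sum()
                fp = (~pos & ppos).sum()
                tn = (~pos & ~ppos).sum()
                rows.append({
                    "class": c,
                    "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                    "specificity": tn / (tn + fp) if tn + fp else np.nan,
                    "precision": tp / (tp + fp) if tp + fp else np.nan,
                })
            reports[(name, rs_name)] = FitReport(
                model_name=name, resampling=rs_name, best_params=best_params,
                cv_auroc=best_score, test_auroc=test_auroc,
                test_metrics=pd.DataFrame(rows), model=model)
    return reports


def importance(model, features: PreIndexFeatures, labels,
               method: str = "permutation", n_repeats: int = 20,
               seed: int = 0) -> pd.DataFrame:
    """Ranked feature importances.

    ``permutation`` (the core method): mean macro-AUROC drop over
    ``n_repeats`` shuffles of each column. ``shap``: mean |SHAP| per feature,
    available only when the optional shap package is installed.
    """
    X = np.asarray(features.X, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if method == "shap":
        try:
            import shap
        except ImportError as err:
            raise ImportError("shap is not installed; use "
                              "method='permutation'") from err
        explainer = shap.Explainer(model, X)
        vals = np.abs(explainer(X).values)
        imp = vals.mean(axis=tuple(range(1, vals.ndim)) if vals.ndim > 2
                        else 0)
        imp = np.atleast_1d(np.asarray(imp)).ravel()[:X.shape[1]]
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        base = macro_auroc(model, X, y, classes)
        imp = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            drops = []
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                drops.append(base - macro_auroc(model, Xp, y, classes))
            imp[j] = np.mean(drops)
    else:
        raise ValueError("method must be 'permutation' or 'shap'")
    out = pd.DataFrame({"feature": features.feature_names,
                        "importance": imp})
    return out.sort_values("importance", ascending=False,
                           kind="stable").reset_index(drop=True)
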