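"""Train/test splitting, cross-validated classifier fitting, evaluation,
and imputation of missing location codes.

Four multinomial classifier families are supported — L1-penalized
(lasso) multinomial logistic regression, one-vs-rest linear SVM with Platt
scaling, a single-hidden-layer feed-forward network, and gradient-boosted
trees — each selected over a small hyperparameter grid by 5-fold
cross-validated accuracy (macro one-vs-rest AUC breaking ties) and refit on
the full training set.  The grid runner evaluates every family on every
predictor construction and flags the best cell, which is then applied to
records with missing location codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .records import LOCATION_CLASSES, RecordSet
from .text import FeatureMatrix

logger = logging.getLogger(__name__)

CLASS_INDEX = {c: i for i, c in enumerate(LOCATION_CLASSES)}

FAMILIES = ("lasso_multinomial", "svm_multiclass", "feedforward_nn",
            "gradient_boosted_trees")

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "lasso_multinomial": [{"C": 0.3}, {"C": 1.0}, {"C": 3.0}],
    "svm_multiclass": [{"C": 0.3}, {"C": 1.0}],
    "feedforward_nn": [{"hidden": 32, "alpha": 1e-4}],
    "gradient_boosted_trees": [{"max_depth": 3, "n_estimators": 100}],
}


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    seed: int = 0
    stratified: bool = False

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ModelSpec:
    family: str
    grid: list[dict] = field(default_factory=list)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.grid:
            self.grid = [dict(g) for g in DEFAULT_GRIDS[self.family]]
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def split_sizes(n: int, train_fraction: float) -> tuple[int, int]:
    """(train, test) sizes: round(f·n) and the remainder."""
    n_train = round(train_fraction * n)
    return n_train, n - n_train


def split_train_test(nonmissing: RecordSet, spec: SplitSpec
                     ) -> tuple[RecordSet, RecordSet]:
    """Simple random 70/30 split of the labeled records, deterministic
    given the seed.  Stratified-by-class splitting is available via the
    spec but is off by default."""
    df = nonmissing.records
    n = len(df)
    n_train, _ = split_sizes(n, spec.train_fraction)
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        train_idx: list[int] = []
        for cls, grp in df.groupby("location4", sort=True):
            k = round(spec.train_fraction * len(grp))
            train_idx.extend(rng.choice(grp.index.to_numpy(), size=k, replace=False))
        # adjust to the exact global size with random extras/removals
        pool = np.setdiff1d(df.index.to_numpy(), np.asarray(train_idx))
        while len(train_idx) < n_train:
            pick = rng.choice(pool); train_idx.append(pick)
            pool = pool[pool != pick]
        train_mask = df.index.isin(train_idx[:n_train])
    else:
        perm = rng.permutation(n)
        train_mask = np.zeros(n, dtype=bool)
        train_mask[perm[:n_train]] = True
    train = RecordSet(df.loc[train_mask].reset_index(drop=True),
                      provenance=f"{nonmissing.provenance} [train]")
    test = RecordSet(df.loc[~train_mask].reset_index(drop=True),
                     provenance=f"{nonmissing.provenance} [test]")
    return train, test


def _make_estimator(family: str, params: dict, seed: int):
    if family == "lasso_multinomial":
        return LogisticRegression(penalty="l1", solver="saga",
                                  tol=params.get("tol", 1e-4),
                                  max_iter=params.get("max_iter", 2000),
                                  C=params.get("C", 1.0),
                                  random_state=seed)
    if family == "svm_multiclass":
        base = LinearSVC(C=params.get("C", 1.0), random_state=seed,
                         max_iter=5000)
        return CalibratedClassifierCV(base, method="sigmoid", cv=3)
    if family == "feedforward_nn":
        return MLPClassifier(hidden_layer_sizes=(params.get("hidden", 32),),
                             alpha=params.get("alpha", 1e-4),
                             learning_rate_init=params.get(
                                 "learning_rate_init", 0.01),
                             early_stopping=True, n_iter_no_change=20,
                             max_iter=params.get("max_iter", 500),
                             random_state=seed)
    if family == "gradient_boosted_trees":
        return XGBClassifier(n_estimators=params.get("n_estimators", 100),
                             max_depth=params.get("max_depth", 3),
                             learning_rate=params.get("learning_rate", 0.3),
                             objective="multi:softprob", num_class=4,
                             random_state=seed, n_jobs=1, verbosity=0)
    raise ValueError(family)


def _encode(labels) -> np.ndarray:
    return np.asarray([CLASS_INDEX[c] for c in labels], dtype=int)


def _macro_ovr_auc(y_codes: np.ndarray, proba: np.ndarray) -> float:
    """Macro average of the one-vs-rest ROC areas over classes present."""
    aucs = []
    for c in range(len(LOCATION_CLASSES)):
        pos = y_codes == c
        if 0 < pos.sum() < len(y_codes):
            aucs.append(roc_auc_score(pos, proba[:, c]))
    return float(np.mean(aucs)) if aucs else float("nan")


@dataclass
class FittedModel:
    """A refit classifier with its CV trace and feature schema."""

    estimator: object
    family: str
    feature_names: tuple[str, ...]
    feature_construction: str
    best_params: dict
    cv_results: list[dict]
    seed: int

    def _check(self, fm: FeatureMatrix) -> None:
        if fm.feature_names != self.feature_names:
            raise ValueError("feature columns do not match training columns")

    def predict_proba(self, fm: FeatureMatrix) -> np.ndarray:
        """(n, 4) class probabilities in the fixed reporting order."""
        self._check(fm)
        proba = np.asarray(self.estimator.predict_proba(fm.values),
                           dtype=float)
        # training requires all 4 classes, so columns are codes 0..3
        sums = proba.sum(axis=1)
        # float32 backends (boosted trees) carry ~1e-7 rounding
        if np.abs(sums - 1.0).max() > 1e-5:
            raise AssertionError("probabilities do not sum to 1")
        return proba / sums[:, None]

    def predict(self, fm: FeatureMatrix) -> np.ndarray:
        """Argmax labels; ties break to the earlier class in the fixed
        order HOME, STREET, PUBLIC, OTHER."""
        codes = np.argmax(self.predict_proba(fm), axis=1)
        return np.asarray(LOCATION_CLASSES, dtype=object)[codes]

    def linear_coefficients(self) -> pd.DataFrame:
        """Per-class linear coefficients over named features (sparse
        multinomial models only)."""
        if self.family != "lasso_multinomial":
            raise ValueError(f"{self.family} does not expose per-class linear "
                             "coefficients")
        if self.feature_construction == "embedding":
            raise ValueError("embedding features are not word-attributable")
        coef = self.estimator.coef_
        return pd.DataFrame(coef, index=list(LOCATION_CLASSES),
                            columns=list(self.feature_names))


def fit_classifier(features: FeatureMatrix, labels, spec: ModelSpec
                   ) -> FittedModel:
    """Select hyperparameters by k-fold CV accuracy (AUC tie-break) and
    refit on the full training set."""
    y = _encode(labels)
    if len(y) != features.shape[0]:
        raise ValueError("labels do not align with feature rows")
    present = set(y.tolist())
    if present != {0, 1, 2, 3}:
        absent = [LOCATION_CLASSES[c] for c in sorted({0, 1, 2, 3} - present)]
        raise ValueError(f"class(es) absent from training labels: {absent}")

    X = features.values
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                         random_state=spec.seed)
    cv_results = []
    for params in spec.grid:
        accs, aucs = [], []
        for tr, va in cv.split(np.zeros(len(y)), y):
            est = _make_estimator(spec.family, params, spec.seed)
            est.fit(X[tr], y[tr])
            proba = est.predict_proba(X[va])
            accs.append(float((np.argmax(proba, axis=1) == y[va]).mean()))
            aucs.append(_macro_ovr_auc(y[va], proba))
        cv_results.append({"params": dict(params),
                           "cv_accuracy": float(np.mean(accs)),
                           "cv_auc": float(np.nanmean(aucs))})
    best = max(range(len(cv_results)),
               key=lambda i: (cv_results[i]["cv_accuracy"],
                              cv_results[i]["cv_auc"], -i))
    best_params = cv_results[best]["params"]
    final = _make_estimator(spec.family, best_params, spec.seed)
    final.fit(X, y)
    logger.info("fit %s on %s features: best %s (cv acc %.3f)", spec.family,
                features.construction, best_params,
                cv_results[best]["cv_accuracy"])
    return FittedModel(final, spec.family, features.feature_names,
                       features.construction, best_params, cv_results,
                       spec.seed)


@dataclass
class EvalReport:
    """Out-of-sample performance of one (model, feature set) cell.

    All metrics derive from the 4×4 confusion matrix (true × predicted in
    the fixed class order) except AUC, which comes from the class
    probabilities as the macro one-vs-rest ROC area.
    """

    confusion: np.ndarray
    precision: dict[str, float]
    recall: dict[str, float]
    accuracy: float
    auc: float
    model_label: str = ""
    feature_set_label: str = ""

    def __post_init__(self):
        conf = self.confusion
        total = conf.sum()
        assert conf.shape == (4, 4)
        assert np.isclose(self.accuracy, np.trace(conf) / total)
        for i, c in enumerate(LOCATION_CLASSES):
            col = conf[:, i].sum()
            row = conf[i, :].sum()
            assert np.isclose(self.precision[c], conf[i, i] / col if col else 0.0)
            assert np.isclose(self.recall[c], conf[i, i] / row if row else 0.0)

    def to_row(self) -> dict:
        row = {"model": self.model_label, "feature_set": self.feature_set_label}
        row.update({f"precision_{c}": self.precision[c] for c in LOCATION_CLASSES})
        row.update({f"recall_{c}": self.recall[c] for c in LOCATION_CLASSES})
        row["accuracy"] = self.accuracy
        row["auc"] = self.auc
        return row


def evaluate(model: FittedModel, test_features: FeatureMatrix, test_labels,
             model_label: str = "", feature_set_label: str = "") -> EvalReport:
    """Score a fitted model on held-out records."""
    y = _encode(test_labels)
    proba = model.predict_proba(test_features)
    pred = np.argmax(proba, axis=1)
    conf = np.zeros((4, 4), dtype=int)
    np.add.at(conf, (y, pred), 1)
    total = conf.sum()
    precision = {}
    recall = {}
    for i, c in enumerate(LOCATION_CLASSES):
        col = conf[:, i].sum()
        row = conf[i, :].sum()
        if col == 0:
            logger.warning("class %s never predicted; precision set to 0", c)
        precision[c] = float(conf[i, i] / col) if col else 0.0
        recall[c] = float(conf[i, i] / row) if row else 0.0
    return EvalReport(conf, precision, recall,
                      accuracy=float(np.trace(conf) / total),
                      auc=_macro_ovr_auc(y, proba),
                      model_label=model_label,
                      feature_set_label=feature_set_label)


@dataclass
class GridResult:
    reports: dict[tuple[str, str], EvalReport]
    models: dict[tuple[str, str], FittedModel]
    best_key: tuple[str, str]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.reports.values()])


def run_model_grid(feature_bundles: dict[str, tuple[FeatureMatrix, FeatureMatrix]],
                   train_labels, test_labels,
                   model_specs: list[ModelSpec]) -> GridResult:
    """Fit every model family on every predictor construction.

    ``feature_bundles`` maps a feature-set label (e.g. ``"shared:tfidf"``)
    to its (train, test) matrices built from the same record split.  The
    best cell is the one with highest test accuracy, AUC breaking ties.
    """
    ids = {tuple(fm_tr.record_ids) for fm_tr, _ in feature_bundles.values()}
    if len(ids) != 1:
        raise ValueError("feature bundles were not built from the same split")
    reports: dict[tuple[str, str], EvalReport] = {}
    models: dict[tuple[str, str], FittedModel] = {}
    for fs_label, (fm_train, fm_test) in feature_bundles.items():
        for spec in model_specs:
            key = (spec.family, fs_label)
            model = fit_classifier(fm_train, train_labels, spec)
            reports[key] = evaluate(model, fm_test, test_labels,
                                    model_label=spec.family,
                                    feature_set_label=fs_label)
            models[key] = model
    best_key = max(reports, key=lambda k: (reports[k].accuracy, reports[k].auc))
    return GridResult(reports, models, best_key)


def predict_missing(model: FittedModel, missing_features: FeatureMatrix
                    ) -> pd.DataFrame:
    """Classify records with missing location codes.

    Returns one row per record: record_id, predicted class, and the
    four class probabilities.  The predicted-class distribution is logged.
    """
    if missing_features.shape[0] == 0:
        return pd.DataFrame(columns=["record_id", "predicted",
                                     *[f"p_{c}" for c in LOCATION_CLASSES]])
    proba = model.predict_proba(missing_features)
    pred = np.asarray(LOCATION_CLASSES, dtype=object)[np.argmax(proba, axis=1)]
    out = pd.DataFrame({"record_id": list(missing_features.record_ids),
                        "predicted": pred})
    for i, c in enumerate(LOCATION_CLASSES):
        out[f"p_{c}"] = proba[:, i]
    shares = out["predicted"].value_counts(normalize=True)
    logger.info("predicted class shares: %s",
                {c: round(float(shares.get(c, 0.0)), 3) for c in LOCATION_CLASSES})
    return out
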