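"""Machine-learning false-positive filtration of pooled variant calls.

Calls are labelled by membership of their normalized key in a gold-standard
truth set for the same pool, features are the caller's technical annotations,
and per-variant-type classifiers (logistic regression for SNVs and random
forest for indels by default; gradient boosting and a supervised Gaussian
mixture are also available) are trained with repeated nested cross-validation:
hyperparameters are selected on inner folds only, out-of-fold probabilities
are recorded for every row in every repetition, and the final model is refit
on the full table. Two probability thresholds are calibrated from the
out-of-fold probabilities: one maximizing F1 and one targeting 99% sensitivity.

The central object is :class:`PoolVariantFilter`, a scikit-learn compatible
estimator (``fit``/``predict_proba``/``get_params``) whose fitted attributes
carry the calibrated thresholds and the nested-CV report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .pinpoint import PoolCallSet
from .variants import INDEL, SNV, AnnotatedCall, VariantKey

__all__ = [
    "DEFAULT_FEATURES",
    "CVSpec",
    "GaussianMixtureClassifier",
    "PoolVariantFilter",
    "FilterModel",
    "label_calls",
    "prune_correlated",
    "mrmr_select",
    "train_nested_cv",
    "calibrate_thresholds",
    "apply_filter",
    "hard_filter",
    "default_hard_filters",
    "load_hard_filters",
    "save_model",
    "load_model",
]

DEFAULT_FEATURES = [
    "QD",
    "FS",
    "MQ",
    "SOR",
    "MQRankSum",
    "ReadPosRankSum",
    "BaseQRankSum",
    "DP",
    "AF",
    "QUAL",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class CVSpec:
    """Repeated nested cross-validation layout: 5 x (10 outer, 5 inner)."""

    repetitions: int = 5
    outer_folds: int = 10
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if min(self.repetitions, self.outer_folds, self.inner_folds) < 1:
            raise ValueError("CV spec fields must be >= 1")


# ---------------------------------------------------------------------------
# labeling and feature selection
# ---------------------------------------------------------------------------

def label_calls(
    pool_calls: PoolCallSet,
    truth_pool_set: set,
    features: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One labelled row per emitted call.

    Label is 1 iff the call's key is in the truth set built for the same pool
    membership. Truth variants absent from the calls produce no rows — false
    negatives are not training samples. Missing feature values are NaN.
    """
    feats = list(features) if features is not None else list(DEFAULT_FEATURES)
    rows = []
    for key in sorted(pool_calls.calls):
        call = pool_calls.calls[key]
        row: dict = {
            "call_id": f"{pool_calls.pool_id}:{key.chrom}:{key.pos}:{key.ref}:{key.alt}",
            "pool_id": pool_calls.pool_id,
            "chrom": key.chrom,
            "pos": key.pos,
            "ref": key.ref,
            "alt": key.alt,
            "vtype": key.vtype,
            "label": int(key in truth_pool_set),
        }
        for f in feats:
            v = call.annotations.get(f)
            row[f] = np.nan if v is None else float(v)
        rows.append(row)
    cols = ["call_id", "pool_id", "chrom", "pos", "ref", "alt", "vtype", "label"] + feats
    return pd.DataFrame(rows, columns=cols)


def feature_columns(table: pd.DataFrame) -> list[str]:
    meta = {"call_id", "pool_id", "chrom", "pos", "ref", "alt", "vtype", "label"}
    return [c for c in table.columns if c not in meta]


def prune_correlated(
    table: pd.DataFrame,
    r_threshold: float = 0.9,
    features: Optional[Sequence[str]] = None,
) -> list[str]:
    """Greedy removal of highly correlated features.

    Among pairs with ``|Pearson r| >= r_threshold`` (computed on complete
    cases), the alphabetically later feature of the first offending pair is
    dropped; repeat until no pair exceeds the threshold. Constant features are
    excluded up front with a warning.
    """
    feats = sorted(features if features is not None else feature_columns(table))
    sub = table[feats].dropna()
    constant = [f for f in feats if sub[f].nunique() <= 1]
    if constant:
        warnings.warn(f"excluding constant feature(s): {constant}", stacklevel=2)
        feats = [f for f in feats if f not in constant]
    keep = list(feats)
    while len(keep) >= 2:
        corr = sub[keep].corr().abs()
        offender = None
        for i, a in enumerate(keep):
            for b in keep[i + 1 :]:
                if corr.loc[a, b] >= r_threshold:
                    offender = b  # later in alphabetical order (keep is sorted)
                    break
            if offender:
                break
        if offender is None:
            break
        keep.remove(offender)
    return keep


def _relevance_f(table: pd.DataFrame, feature: str) -> float:
    """ANOVA F statistic of one feature against the binary label (complete cases)."""
    sub = table[[feature, "label"]].dropna()
    g0 = sub.loc[sub["label"] == 0, feature].to_numpy()
    g1 = sub.loc[sub["label"] == 1, feature].to_numpy()
    if len(g0) < 2 or len(g1) < 2:
        return 0.0
    f, _ = stats.f_oneway(g0, g1)
    return 0.0 if np.isnan(f) else float(f)


def mrmr_select(
    table: pd.DataFrame,
    k: int,
    features: Optional[Sequence[str]] = None,
) -> list[str]:
    """Minimum-redundancy maximum-relevance forward selection (FCQ variant).

    Greedy: the next feature maximizes ``F(feature, label) / mean |Pearson r|``
    with the already selected features (relevance quotient); the first feature
    is the one with the highest F statistic. Deterministic; ties break
    alphabetically.
    """
    if k <= 0:
        return []
    feats = sorted(features if features is not None else feature_columns(table))
    if k > len(feats):
        raise ValueError(f"k={k} exceeds available features ({len(feats)})")
    relevance = {f: _relevance_f(table, f) for f in feats}
    corr = table[feats].corr().abs().fillna(0.0)
    selected: list[str] = []
    remaining = list(feats)
    while len(selected) < k and remaining:
        if not selected:
            scores = {f: relevance[f] for f in remaining}
        else:
            scores = {}
            for f in remaining:
                redundancy = max(float(np.mean([corr.loc[f, s] for s in selected])), 1e-12)
                scores[f] = relevance[f] / redundancy
        best = max(remaining, key=lambda f: (scores[f], [-ord(ch) for ch in f]))
        selected.append(best)
        remaining.remove(best)
    return selected


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

class GaussianMixtureClassifier(BaseEstimator, ClassifierMixin):
    """Supervised wrapper around per-class Gaussian mixtures.

    Fits one mixture per class and classifies via Bayes' rule with equal
    class priors (the class-weighting analogue for generative models).
    """

    def __init__(self, n_components: int = 2, covariance_type: str = "full",
                 reg_covar: float = 1e-4, random_state: int = 0):
        self.n_components = n_components
        self.covariance_type = covariance_type
        self.reg_covar = reg_covar
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("GaussianMixtureClassifier needs both classes present")
        self.mixtures_ = {}
        for cls in self.classes_:
            Xc = X[y == cls]
            n_comp = min(self.n_components, len(Xc))
            gm = GaussianMixture(
                n_components=n_comp,
                covariance_type=self.covariance_type,
                reg_covar=self.reg_covar,
                random_state=self.random_state,
            )
            gm.fit(Xc)
            self.mixtures_[cls] = gm
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "mixtures_")
        X = np.asarray(X, dtype=float)
        logp = np.column_stack(
            [self.mixtures_[cls].score_samples(X) for cls in self.classes_]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class BalancedXGBClassifier(XGBClassifier):
    """Gradient boosting with class weighting derived from the fit data.

    ``scale_pos_weight`` is set to the negative/positive ratio at fit time,
    the boosting analogue of ``class_weight="balanced"``.
    """

    def fit(self, X, y, **kwargs):
        y = np.asarray(y)
        pos = max(int((y == 1).sum()), 1)
        self.set_params(scale_pos_weight=int((y == 0).sum()) / pos)
        return super().fit(X, y, **kwargs)


def _base_pipeline(family: str, random_state: int) -> Pipeline:
    """Imputation (training-median) + scaling + classifier for one family."""
    steps = [("impute", SimpleImputer(strategy="median"))]
    if family == "lr":
        steps += [
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000, class_weight="balanced",
                                       random_state=random_state)),
        ]
    elif family == "rf":
        steps += [
            ("clf", RandomForestClassifier(n_estimators=100, class_weight="balanced",
                                           random_state=random_state, n_jobs=1)),
        ]
    elif family == "xgb":
        steps += [
            ("clf", BalancedXGBClassifier(n_estimators=100, eval_metric="logloss",
                                          random_state=random_state, n_jobs=1)),
        ]
    elif family == "gmm":
        steps += [
            ("scale", StandardScaler()),
            ("clf", GaussianMixtureClassifier(random_state=random_state)),
        ]
    else:
        raise ValueError(f"unknown model family {family!r} (lr, rf, xgb, gmm)")
    return Pipeline(steps)


DEFAULT_PARAM_GRIDS: dict[str, dict[str, list]] = {
    "lr": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "rf": {"clf__max_depth": [None, 8]},
    "xgb": {"clf__max_depth": [3, 6], "clf__learning_rate": [0.1, 0.3]},
    "gmm": {"clf__n_components": [1, 2, 4]},
}


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def calibrate_thresholds(
    probabilities: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """Calibrate the dual decision thresholds from out-of-fold probabilities.

    Candidates are the unique probability values; a call passes when its
    probability is >= the threshold. ``t_f1`` maximizes F1 (ties broken toward
    the smallest threshold, favouring sensitivity); ``t_s99`` is the largest
    candidate retaining sensitivity >= 0.99, falling back to the smallest
    probability (pass-all) when none does.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if probs.ndim != 1 or len(probs) != len(y):
        raise ValueError("probabilities and labels must be 1-D and equal length")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        if not np.any(y == 1):
            raise ValueError("threshold calibration needs at least one positive label")
        # all labels positive: any threshold has precision 1; keep everything
        t = float(np.min(probs))
        return t, t
    candidates = np.unique(probs)
    n_pos = int(np.sum(y == 1))
    best_f1, t_f1 = -1.0, float(candidates[0])
    t_s99 = None
    for t in candidates:
        passed = probs >= t
        tp = int(np.sum(passed & (y == 1)))
        fp = int(np.sum(passed & (y == 0)))
        fn = n_pos - tp
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        if f1 > best_f1:  # strict: ties keep the smaller threshold
            best_f1, t_f1 = f1, float(t)
        sens = tp / n_pos
        if sens >= 0.99:
            t_s99 = float(t)  # candidates ascend; last qualifying is largest
    if t_s99 is None:
        t_s99 = float(np.min(probs))
    return t_f1, t_s99


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class PoolVariantFilter(BaseEstimator, ClassifierMixin):
    """Nested-CV-trained false-positive filter for one variant type.

    scikit-learn estimator: ``fit(X, y)`` runs repeated nested cross-validation
    (hyperparameters chosen on inner folds only), records out-of-fold
    probabilities for every row in every repetition, refits the final pipeline
    on the full table with inner-CV-chosen hyperparameters, and calibrates the
    two decision thresholds from the out-of-fold probabilities.

    Parameters
    ----------
    family : {"lr", "rf", "xgb", "gmm"}
        Classifier family. The shipped pipeline default is logistic
        regression for SNVs and random forest for indels.
    vtype : {"SNV", "INDEL"}
        Variant-type scope; informational, used by :func:`apply_filter`.
    repetitions, outer_folds, inner_folds : int
        Nested CV layout (default 5 x 10 x 5).
    param_grid : dict or None
        Hyperparameter grid (pipeline step syntax, e.g. ``clf__C``); defaults
        to a small documented grid per family.
    scoring : str
        Inner-fold selection score (default ``"f1"``).

    Attributes
    ----------
    pipeline_ : fitted sklearn Pipeline (imputer + scaler + classifier)
    t_f1_, t_s99_ : calibrated probability thresholds
    oof_ : DataFrame of out-of-fold probabilities (repetition, fold, row, label)
    n_outer_models_ : number of outer models trained (= repetitions x outer folds)
    best_params_ : hyperparameters of the final refit
    feature_names_ : column order the model expects
    """

    def __init__(
        self,
        family: str = "lr",
        vtype: str = SNV,
        repetitions: int = 5,
        outer_folds: int = 10,
        inner_folds: int = 5,
        param_grid: Optional[dict] = None,
        scoring: str = "f1",
        random_state: int = 0,
    ):
        self.family = family
        self.vtype = vtype
        self.repetitions = repetitions
        self.outer_folds = outer_folds
        self.inner_folds = inner_folds
        self.param_grid = param_grid
        self.scoring = scoring
        self.random_state = random_state

    def _grid(self) -> dict:
        return self.param_grid if self.param_grid is not None else DEFAULT_PARAM_GRIDS[self.family]

    def fit(self, X, y):
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training table must contain both labels (0 and 1)")
        if counts.min() < self.outer_folds:
            raise ValueError(
                f"minority class has {counts.min()} rows, fewer than "
                f"{self.outer_folds} outer folds: stratified folds would be "
                "single-class; provide more data or a smaller CV spec"
            )
        if len(X) < self.outer_folds * 2:
            raise ValueError("table must have at least outer_folds * 2 rows")
        self.feature_names_ = list(X.columns)
        self.classes_ = classes
        grid = self._grid()
        oof_rows = []
        n_models = 0
        for rep in range(self.repetitions):
            outer = StratifiedKFold(
                n_splits=self.outer_folds, shuffle=True,
                random_state=self.random_state + 1000 * rep,
            )
            for fold, (tr, te) in enumerate(outer.split(X, y)):
                gs = self._grid_search(rep * 7919 + fold)
                gs.fit(X.iloc[tr], y[tr])
                n_models += 1
                prob = gs.predict_proba(X.iloc[te])[:, 1]
                for row, p in zip(te, prob):
                    oof_rows.append(
                        {"repetition": rep, "fold": fold, "row": int(row),
                         "prob": float(p), "label": int(y[row])}
                    )
        self.oof_ = pd.DataFrame(oof_rows)
        self.n_outer_models_ = n_models
        final = self._grid_search(self.repetitions * 7919)
        final.fit(X, y)
        self.best_params_ = final.best_params_
        self.pipeline_ = final.best_estimator_
        self.t_f1_, self.t_s99_ = calibrate_thresholds(
            self.oof_["prob"].to_numpy(), self.oof_["label"].to_numpy()
        )
        return self

    def _grid_search(self, seed_offset: int) -> GridSearchCV:
        pipe = _base_pipeline(self.family, self.random_state + seed_offset)
        inner = StratifiedKFold(
            n_splits=self.inner_folds, shuffle=True,
            random_state=self.random_state + seed_offset,
        )
        return GridSearchCV(pipe, self._grid(), scoring=self.scoring, cv=inner,
                            n_jobs=1, refit=True)

    def _check_X(self, X) -> pd.DataFrame:
        check_is_fitted(self, "pipeline_")
        X = pd.DataFrame(X)
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        return X[self.feature_names_]

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(self._check_X(X))

    def predict(self, X, threshold_mode: str = "F1"):
        """Pass/fail at a calibrated threshold (``"F1"`` or ``"S99"``)."""
        t = self.threshold(threshold_mode)
        return (self.predict_proba(X)[:, 1] >= t).astype(int)

    def threshold(self, mode: str) -> float:
        check_is_fitted(self, "t_f1_")
        if mode.upper() == "F1":
            return self.t_f1_
        if mode.upper() == "S99":
            return self.t_s99_
        raise ValueError(f"unknown threshold mode {mode!r} (F1 or S99)")

    def oof_auroc(self) -> float:
        """Mean out-of-fold AUROC across repetitions."""
        from sklearn.metrics import roc_auc_score

        check_is_fitted(self, "oof_")
        return float(
            self.oof_.groupby("repetition")
            .apply(lambda d: roc_auc_score(d["label"], d["prob"]), include_groups=False)
            .mean()
        )


@dataclass
class FilterModel:
    """A trained, serializable per-variant-type filter with metadata."""

    vtype: str
    family: str
    estimator: PoolVariantFilter
    features: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def t_f1(self) -> float:
        return self.estimator.t_f1_

    @property
    def t_s99(self) -> float:
        return self.estimator.t_s99_

    def predict_proba_calls(self, calls: Iterable[AnnotatedCall]) -> np.ndarray:
        rows = [
            {f: (np.nan if c.annotations.get(f) is None else float(c.annotations.get(f)))
             for f in self.features}
            for c in calls
        ]
        X = pd.DataFrame(rows, columns=self.features)
        return self.estimator.predict_proba(X)[:, 1]


def save_model(model: FilterModel, path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> FilterModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version}")
    return payload["model"]


def train_nested_cv(
    table: pd.DataFrame,
    family: str,
    cv: CVSpec = CVSpec(),
    seed: int = 0,
    features: Optional[Sequence[str]] = None,
    param_grid: Optional[dict] = None,
    vtype: Optional[str] = None,
) -> tuple[pd.DataFrame, FilterModel]:
    """Train one per-variant-type filter from a labelled call table.

    Returns ``(oof_report, model)`` where the report holds the out-of-fold
    probability of every row in every repetition and the model is refit on the
    full table with inner-CV-chosen hyperparameters and carries the two
    calibrated thresholds.
    """
    feats = list(features) if features is not None else feature_columns(table)
    vt = vtype or (table["vtype"].iloc[0] if "vtype" in table.columns else SNV)
    est = PoolVariantFilter(
        family=family,
        vtype=vt,
        repetitions=cv.repetitions,
        outer_folds=cv.outer_folds,
        inner_folds=cv.inner_folds,
        param_grid=param_grid,
        random_state=seed,
    )
    est.fit(table[feats], table["label"].to_numpy())
    model = FilterModel(
        vtype=vt,
        family=family,
        estimator=est,
        features=feats,
        metadata={
            "seed": seed,
            "cv": {"repetitions": cv.repetitions, "outer_folds": cv.outer_folds,
                   "inner_folds": cv.inner_folds},
            "n_rows": int(len(table)),
            "best_params": est.best_params_,
        },
    )
    return est.oof_.copy(), model


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def apply_filter(
    calls: PoolCallSet,
    snv_model: Optional[FilterModel],
    indel_model: Optional[FilterModel],
    threshold_mode: str = "F1",
) -> tuple[PoolCallSet, pd.DataFrame]:
    """Route calls by variant type through the matching model.

    A call passes iff its predicted probability is >= the selected calibrated
    threshold. Calls whose variant type has no model pass unchanged with a
    warning. Returns the filtered call set and a per-call probability sidecar.
    """
    models = {}
    if snv_model is not None:
        if snv_model.vtype != SNV:
            raise ValueError(f"snv_model has scope {snv_model.vtype}, expected SNV")
        models[SNV] = snv_model
    if indel_model is not None:
        if indel_model.vtype != INDEL:
            raise ValueError(f"indel_model has scope {indel_model.vtype}, expected INDEL")
        models[INDEL] = indel_model

    by_vtype: dict[str, list[VariantKey]] = {SNV: [], INDEL: []}
    for key in sorted(calls.calls):
        by_vtype[key.vtype].append(key)

    passed: dict[VariantKey, AnnotatedCall] = {}
    sidecar_rows = []
    for vtype, keys in by_vtype.items():
        if not keys:
            continue
        model = models.get(vtype)
        if model is None:
            warnings.warn(
                f"no {vtype} model provided; {len(keys)} {vtype} call(s) pass unchanged",
                stacklevel=2,
            )
            for k in keys:
                passed[k] = calls.calls[k]
                sidecar_rows.append(
                    {"pool_id": calls.pool_id, "chrom": k.chrom, "pos": k.pos,
                     "ref": k.ref, "alt": k.alt, "vtype": vtype,
                     "prob": np.nan, "passed": True}
                )
            continue
        threshold = model.t_f1 if threshold_mode.upper() == "F1" else (
            model.t_s99 if threshold_mode.upper() == "S99" else None)
        if threshold is None:
            raise ValueError(f"unknown threshold mode {threshold_mode!r}")
        probs = model.predict_proba_calls(calls.calls[k] for k in keys)
        for k, p in zip(keys, probs):
            ok = bool(p >= threshold)
            if ok:
                passed[k] = calls.calls[k]
            sidecar_rows.append(
                {"pool_id": calls.pool_id, "chrom": k.chrom, "pos": k.pos,
                 "ref": k.ref, "alt": k.alt, "vtype": vtype,
                 "prob": float(p), "passed": ok}
            )
    filtered = PoolCallSet(calls.pool_id, calls.axis, calls.index, passed)
    return filtered, pd.DataFrame(sidecar_rows)


# community-standard germline hard-filter cutoffs (an external convention)
_DEFAULT_HARD_FILTERS: dict[str, dict[str, tuple[str, float]]] = {
    SNV: {
        "QD": ("<", 2.0),
        "FS": (">", 60.0),
        "MQ": ("<", 40.0),
        "MQRankSum": ("<", -12.5),
        "ReadPosRankSum": ("<", -8.0),
        "SOR": (">", 3.0),
    },
    INDEL: {
        "QD": ("<", 2.0),
        "FS": (">", 200.0),
        "ReadPosRankSum": ("<", -20.0),
        "SOR": (">", 10.0),
    },
}


def default_hard_filters() -> dict[str, dict[str, tuple[str, float]]]:
    """A fresh copy of the default hard-filter threshold tables."""
    return {vt: dict(rules) for vt, rules in _DEFAULT_HARD_FILTERS.items()}


def load_hard_filters(path) -> dict[str, dict[str, tuple[str, float]]]:
    """Load threshold tables from the editable YAML config format."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, dict[str, tuple[str, float]]] = {}
    for vt, rules in raw.items():
        out[vt.upper()] = {
            ann: (str(spec["comparator"]), float(spec["cutoff"]))
            for ann, spec in rules.items()
        }
    return out


def hard_filter(
    calls: PoolCallSet,
    thresholds: Optional[Mapping[str, Mapping[str, tuple[str, float]]]] = None,
) -> PoolCallSet:
    """Fixed per-annotation cutoff filtering.

    A call fails when any populated annotation violates its rule (``"<"``:
    fail if value < cutoff; ``">"``: fail if value > cutoff). Missing
    annotations never fail a call.
    """
    tables = thresholds if thresholds is not None else _DEFAULT_HARD_FILTERS
    for vt in tables:
        for ann, (cmp_, _) in tables[vt].items():
            if cmp_ not in ("<", ">"):
                raise ValueError(f"unknown comparator {cmp_!r} for {vt}/{ann}")
    passed: dict[VariantKey, AnnotatedCall] = {}
    for key, call in calls.calls.items():
        rules = tables.get(key.vtype, {})
        ok = True
        for ann, (cmp_, cutoff) in rules.items():
            v = call.annotations.get(ann)
            if v is None:
                continue
            if (cmp_ == "<" and v < cutoff) or (cmp_ == ">" and v > cutoff):
                ok = False
                break
        if ok:
            passed[key] = call
    return PoolCallSet(calls.pool_id, calls.axis, calls.index, passed)
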