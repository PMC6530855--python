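"""Cross-validated recognition of questionnaire severity from gait features.

Regression models predict the GAD-7 or PHQ-9 total; accuracy is the Pearson
correlation r between pooled out-of-fold predictions and the questionnaire
scores, with its p-value from the usual t transform.  Classification models
detect, per PHQ-9 item, the symptomatic group (item score 1-3) versus the
non-symptomatic group (score 0); precision, recall and F-measure of the
symptomatic class are computed from the pooled out-of-fold confusion
counts.  Ten-fold cross-validation throughout, with seeded fold shuffling,
optionally run separately on the male and female strata.

Model roster (regression): SLR, single-predictor least squares on the one
feature with the smallest training residual; LR, ordinary least squares
with a tiny ridge term (1e-8) so the n < p selected matrix stays solvable;
eSVR / nSVR, RBF-kernel support vector regression (C=1, epsilon=0.1 /
nu=0.5); GP, Gaussian-process regression with an RBF kernel plus a white
noise term, hyperparameters by marginal-likelihood optimization.
Classification: SL, logistic regression; KStarSurrogate, an
inverse-distance-weighted 5-nearest-neighbour stand-in for the entropic
K-Star learner; CSVC, RBF-kernel C-SVC (C=1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC, SVR, NuSVR

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

STRATA = ("all", "male", "female")
REGRESSION_MODELS = ("SLR", "LR", "eSVR", "nSVR", "GP")
CLASSIFICATION_MODELS = ("SL", "KStarSurrogate", "CSVC")

SelectorFn = Callable[[np.ndarray, pd.MultiIndex, np.ndarray], np.ndarray]


class TooFewCases(RuntimeError):
    """A stratum lacks enough cases of one class to cross-validate."""


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings."""

    n_folds: int = 10
    rng_seed: int = 0
    stratum: str = "all"
    nested_selection: bool = False
    pooled: bool = True  #: single r over pooled out-of-fold predictions

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")


@dataclass(frozen=True)
class EvalResult:
    """Predictive accuracy of one model on one stratum."""

    model_name: str
    stratum: str
    kind: str  # "regression" | "classification"
    n: int
    pearson_r: Optional[float] = None
    p_value: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    f_measure: Optional[float] = None
    n_symptomatic: Optional[int] = None
    predictions: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    targets: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.pearson_r is not None and not -1.0 - 1e-9 <= self.pearson_r <= 1.0 + 1e-9:
            raise ValueError(f"pearson_r out of [-1, 1]: {self.pearson_r}")
        for name in ("precision", "recall", "f_measure"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")


class _SingleFeatureRegressor:
    """SLR: least squares on the single feature minimizing training SSE."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SingleFeatureRegressor":
        y = np.asarray(y, dtype=float)
        if np.unique(y).size < 2:
            logger.warning("SLR: degenerate fold with <2 distinct target values")
            self.feature_, self.slope_, self.intercept_ = None, 0.0, float(y.mean())
            return self
        xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sxx = (xc**2).sum(axis=0)
        sxy = xc.T @ yc
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        # SSE of each single-feature fit; constant features fall back to the mean
        sse = (yc**2).sum() - slope * sxy
        j = int(np.argmin(sse))
        self.feature_ = j
        self.slope_ = float(slope[j])
        self.intercept_ = float(y.mean() - self.slope_ * X[:, j].mean())
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.feature_ is None:
            return np.full(X.shape[0], self.intercept_)
        return self.intercept_ + self.slope_ * X[:, self.feature_]


def _make_regressor(model_name: str):
    if model_name == "SLR":
        return _SingleFeatureRegressor()
    if model_name == "LR":
        return Ridge(alpha=1e-8)
    if model_name == "eSVR":
        return SVR(kernel="rbf", C=1.0, epsilon=0.1, gamma="scale")
    if model_name == "nSVR":
        return NuSVR(kernel="rbf", C=1.0, nu=0.5, gamma="scale")
    if model_name == "GP":
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            length_scale=10.0, length_scale_bounds=(1e-2, 1e4)
        ) + WhiteKernel(noise_level=1.0, noise_level_bounds=(1e-6, 1e3))
        return GaussianProcessRegressor(kernel=kernel, normalize_y=True)
    raise ValueError(f"unknown regression model {model_name!r}; choose from {REGRESSION_MODELS}")


def _make_classifier(model_name: str):
    if model_name == "SL":
        return LogisticRegression(max_iter=2000, C=1.0)
    if model_name == "KStarSurrogate":
        return KNeighborsClassifier(n_neighbors=5, weights="distance")
    if model_name == "CSVC":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    raise ValueError(
        f"unknown classification model {model_name!r}; choose from {CLASSIFICATION_MODELS}"
    )


def binarize_item(item_scores: Sequence[int]) -> np.ndarray:
    """PHQ-9 item scores 0-3 -> labels: 0 non-symptomatic, 1-3 symptomatic."""
    scores = np.asarray(item_scores)
    if not np.isin(scores, (0, 1, 2, 3)).all():
        raise ValueError("item scores must lie in {0, 1, 2, 3}")
    return (scores > 0).astype(int)


def _shuffled_folds(n: int, n_folds: int, rng_seed: int) -> list[np.ndarray]:
    if n < n_folds:
        raise ValueError(f"cannot make {n_folds} folds from {n} subjects")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    return [fold for fold in np.array_split(order, n_folds)]


def _stratified_folds(labels: np.ndarray, n_folds: int, rng_seed: int) -> list[np.ndarray]:
    """Class-stratified folds so each training set keeps both classes."""
    rng = np.random.default_rng(rng_seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == cls))
        for part, fold in zip(np.array_split(members, n_folds), folds):
            fold.extend(part.tolist())
    return [np.array(sorted(f), dtype=int) for f in folds]


def _fold_predictions(
    X: np.ndarray,
    columns: pd.MultiIndex,
    y: np.ndarray,
    folds: list[np.ndarray],
    make_model: Callable[[], object],
    selector: Optional[SelectorFn],
    nested: bool,
) -> np.ndarray:
    n = X.shape[0]
    if selector is not None and not nested:
        cols = selector(X, columns, y)
        X = X[:, cols]
        columns = columns[cols]
        selector = None
    preds = np.empty(n, dtype=float)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        Xtr, Xte = X[train], X[fold]
        if selector is not None:
            cols = selector(Xtr, columns, y[train])
            Xtr, Xte = Xtr[:, cols], Xte[:, cols]
        model = make_model()
        model.fit(Xtr, y[train])
        preds[fold] = model.predict(Xte)
    return preds


def pearson_accuracy(predictions: np.ndarray, targets: np.ndarray) -> tuple[float, float]:
    """Pearson r between predictions and observed scores, with its p-value.

    A zero-variance prediction vector (e.g. a mean-only model) yields r = 0
    with p = 1 rather than NaN.
    """
    if np.std(predictions) == 0 or np.std(targets) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(predictions, targets)
    return float(r), float(p)


def cross_validate_regression(
    features: FeatureMatrix,
    target: Sequence[float],
    model_name: str,
    config: CVConfig,
    selector: Optional[SelectorFn] = None,
) -> EvalResult:
    """10-fold CV of one regression model; accuracy = pooled-prediction r.

    ``selector`` (from :func:`gaitmood.features.make_selector`) reduces the
    feature set by target correlation.  With ``config.nested_selection`` it
    is re-fit inside every training fold; otherwise it is applied once to
    the full sample before folding, replicating the published order at the
    cost of selection leakage.
    """
    X = features.values
    y = np.asarray(target, dtype=float)
    if y.shape != (X.shape[0],):
        raise ValueError("target length must equal the number of subjects")
    folds = _shuffled_folds(X.shape[0], config.n_folds, config.rng_seed)
    preds = _fold_predictions(
        X, features.data.columns, y, folds,
        lambda: _make_regressor(model_name), selector, config.nested_selection,
    )
    if config.pooled:
        r, p = pearson_accuracy(preds, y)
    else:
        per_fold = [pearson_accuracy(preds[f], y[f]) for f in folds]
        r = float(np.mean([v for v, _ in per_fold]))
        p = float(np.nan)
    return EvalResult(
        model_name=model_name,
        stratum=config.stratum,
        kind="regression",
        n=X.shape[0],
        pearson_r=r,
        p_value=p,
        predictions=preds,
        targets=y,
    )


def confusion_counts(labels: np.ndarray, preds: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) for the symptomatic (positive = 1) class."""
    labels = np.asarray(labels, dtype=int)
    preds = np.asarray(preds, dtype=int)
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    return tp, fp, fn, tn


def precision_recall_f(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def cross_validate_classification(
    features: FeatureMatrix,
    labels: Sequence[int],
    model_name: str,
    config: CVConfig,
    selector: Optional[SelectorFn] = None,
) -> EvalResult:
    """10-fold CV of one symptomatic/non-symptomatic classifier.

    Folds are class-stratified so every training set contains both
    classes.  Raises :class:`TooFewCases` when either class has fewer
    members than there are folds (the PHQ-9 suicidality item typically
    triggers this).
    """
    X = features.values
    y = np.asarray(labels, dtype=int)
    if y.shape != (X.shape[0],):
        raise ValueError("label length must equal the number of subjects")
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.n_folds:
        raise TooFewCases(
            f"minority class has {counts.min()} cases; "
            f"need at least {config.n_folds} for {config.n_folds}-fold CV"
        )
    folds = _stratified_folds(y, config.n_folds, config.rng_seed)
    preds = _fold_predictions(
        X, features.data.columns, y.astype(float), folds,
        lambda: _make_classifier(model_name), selector, config.nested_selection,
    ).astype(int)
    tp, fp, fn, _ = confusion_counts(y, preds)
    precision, recall, f = precision_recall_f(tp, fp, fn)
    return EvalResult(
        model_name=model_name,
        stratum=config.stratum,
        kind="classification",
        n=X.shape[0],
        precision=precision,
        recall=recall,
        f_measure=f,
        n_symptomatic=int(counts[1]),
        predictions=preds,
        targets=y,
    )


def permutation_pvalue(
    predictions: np.ndarray,
    targets: np.ndarray,
    n_permutations: int = 10000,
    rng_seed: int = 0,
) -> float:
    """One-sided permutation p-value for r > 0 between predictions and targets."""
    preds = np.asarray(predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    r_obs, _ = pearson_accuracy(preds, y)
    rng = np.random.default_rng(rng_seed)
    pc = preds - preds.mean()
    denom_p = np.sqrt((pc**2).sum())
    exceed = 0
    perms = np.empty((n_permutations, y.size))
    for i in range(n_permutations):
        perms[i] = rng.permutation(y)
    yc = perms - perms.mean(axis=1, keepdims=True)
    denom_y = np.sqrt((yc**2).sum(axis=1))
    r_null = (yc @ pc) / (denom_p * denom_y)
    exceed = int(np.sum(r_null >= r_obs))
    return (1 + exceed) / (n_permutations + 1)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _stratum_mask(genders: pd.Series, stratum: str) -> np.ndarray:
    if stratum == "all":
        return np.ones(len(genders), dtype=bool)
    return (genders == stratum).to_numpy()


def run_study(
    raw_features: FeatureMatrix,
    subjects: pd.DataFrame,
    config: CVConfig,
    selector: Optional[SelectorFn] = None,
    regression_models: Sequence[str] = REGRESSION_MODELS,
    classification_models: Sequence[str] = CLASSIFICATION_MODELS,
    strata: Sequence[str] = STRATA,
) -> dict[str, pd.DataFrame]:
    """The full evaluation: severity regression and per-item classification.

    ``raw_features`` is the z-scored 4608-column matrix; feature selection
    is re-run per target and per stratum (and per fold when
    ``config.nested_selection``).  Returns long-format tables:
    ``regression`` (target x stratum x model -> r, p, stars, n) and
    ``classification`` (item x stratum x model -> precision/recall/F, with
    a note marking strata where symptomatic cases are too few).
    """
    from .features import make_selector

    if selector is None:
        selector = make_selector()
    subjects = subjects.set_index("subject_id").loc[raw_features.subject_ids]
    genders = subjects["gender"]

    reg_rows = []
    for target_name in ("gad7", "phq9"):
        scores = pd.to_numeric(subjects[target_name], errors="coerce")
        usable = scores.notna().to_numpy()
        for stratum in strata:
            mask = usable & _stratum_mask(genders, stratum)
            if mask.sum() < config.n_folds:
                logger.warning("skipping %s/%s: only %d subjects", target_name, stratum, mask.sum())
                continue
            fm = FeatureMatrix(raw_features.data.loc[mask], normalized=raw_features.normalized)
            y = scores[mask].to_numpy(dtype=float)
            for model_name in regression_models:
                res = cross_validate_regression(
                    fm, y, model_name, replace(config, stratum=stratum), selector
                )
                reg_rows.append(
                    {
                        "target": target_name,
                        "stratum": stratum,
                        "model": model_name,
                        "n": res.n,
                        "r": res.pearson_r,
                        "p": res.p_value,
                        "stars": significance_stars(res.p_value),
                    }
                )

    cls_rows = []
    item_cols = [c for c in subjects.columns if c.startswith("phq9_item")]
    for item_col in item_cols:
        scores = pd.to_numeric(subjects[item_col], errors="coerce")
        usable = scores.notna().to_numpy()
        for stratum in strata:
            mask = usable & _stratum_mask(genders, stratum)
            base = {"item": item_col, "stratum": stratum}
            for model_name in classification_models:
                row = dict(base, model=model_name, n=int(mask.sum()))
                if mask.sum() < config.n_folds:
                    row.update(precision=np.nan, recall=np.nan, f=np.nan,
                               note="too few subjects")
                    cls_rows.append(row)
                    continue
                fm = FeatureMatrix(
                    raw_features.data.loc[mask], normalized=raw_features.normalized
                )
                labels = binarize_item(scores[mask].astype(int).to_numpy())
                try:
                    res = cross_validate_classification(
                        fm, labels, model_name, replace(config, stratum=stratum), selector
                    )
                except TooFewCases:
                    row.update(precision=np.nan, recall=np.nan, f=np.nan,
                               note="no valid results (too few symptomatic cases)")
                else:
                    row.update(
                        precision=res.precision, recall=res.recall, f=res.f_measure,
                        n_symptomatic=res.n_symptomatic, note="",
                    )
                cls_rows.append(row)

    return {
        "regression": pd.DataFrame(reg_rows),
        "classification": pd.DataFrame(cls_rows),
    }
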