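"""Imbalanced-classification evaluation harness.

The design mirrors a clinical screening evaluation on a rare outcome:
stratified 5-fold outer cross-validation; within each training portion the
minority (suicidal) class is doubled with SMOTE, hyper-parameters are tuned
by grid search over an inner stratified 5-fold CV targeting ROC AUC, the
winning model is refit and the held-out fold scored.  Out-of-fold probability
scores are pooled over all samples; the report contains the pooled AUC with a
DeLong 95% CI and a two-sided p-value against AUC = 0.5, plus the seven
confusion-derived metrics (accuracy, sensitivity, specificity, PPV, NPV, F1)
at a probability threshold.

Orientation: the positive class for sensitivity/PPV defaults to the majority
NON-SUICIDAL class — the orientation under which the published metric panel
is arithmetically self-consistent — and can be flipped to the suicidal class
for clinical use via ``CVConfig.positive_class``.

Classifier backends (logistic regression, RBF-kernel SVM, gradient boosting,
random forest, decision tree) are scikit-learn estimators behind a
fit/predict-probability contract; folds, SMOTE, grid search, AUC inference
and all metrics are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CVConfig",
    "SmoteConfig",
    "ClassifierSpec",
    "MetricsReport",
    "DegenerateFoldWarning",
    "stratified_folds",
    "smote_oversample",
    "grid_search",
    "cross_validate",
    "auc_with_inference",
    "confusion_metrics",
    "counts_from_rates",
    "MODEL_FAMILIES",
    "default_spec",
]


class DegenerateFoldWarning(UserWarning):
    """An inner fold contained a single class and was skipped."""


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation settings."""

    outer_folds: int = 5
    inner_folds: int = 5
    threshold: float = 0.5
    positive_class: str = "non_suicidal"   # or "suicidal"
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.positive_class not in ("suicidal", "non_suicidal"):
            raise ValueError("positive_class must be 'suicidal' or 'non_suicidal'")


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE settings: the minority class is multiplied by
    ``minority_multiplier`` (2 = doubled) by interpolating toward one of the
    ``k`` nearest minority neighbors."""

    minority_multiplier: float = 2.0
    k: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.minority_multiplier < 1:
            raise ValueError("minority_multiplier must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class MetricsReport:
    """Pooled out-of-fold evaluation results."""

    auc: float
    auc_ci: Tuple[float, float]
    auc_p: float
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    f1: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = "non_suicidal"
    best_params: tuple = ()

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1], "auc_p": self.auc_p,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
            "f1": self.f1, "tp": self.tp, "fp": self.fp, "tn": self.tn,
            "fn": self.fn, "positive_class": self.positive_class,
        }


@dataclass(frozen=True)
class ClassifierSpec:
    """A model family plus its hyper-parameter grid (named candidate lists;
    declaration order is the tie-breaking order)."""

    family: str
    grid: Dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; "
                f"choose from {sorted(MODEL_FAMILIES)}"
            )
        for k, v in self.grid.items():
            if len(v) == 0:
                raise ValueError(f"grid entry {k!r} is empty")

    def grid_points(self) -> List[dict]:
        if not self.grid:
            return [{}]
        names = list(self.grid)
        return [dict(zip(names, combo)) for combo in product(*self.grid.values())]

    def build(self, params: dict, seed: int):
        return _build_estimator(self.family, params, seed)


def _build_estimator(family: str, params: dict, seed: int):
    if family == "logistic_regression":
        est = LogisticRegression(max_iter=2000, **params)
    elif family == "svm_rbf":
        est = SVC(kernel="rbf", probability=True, random_state=seed, **params)
    elif family == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=seed, **params)
    elif family == "random_forest":
        est = RandomForestClassifier(random_state=seed, **params)
    elif family == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed, **params)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(family)
    return make_pipeline(StandardScaler(), est)


#: default hyper-parameter grids per model family
MODEL_FAMILIES: Dict[str, Dict[str, tuple]] = {
    "logistic_regression": {"C": (0.01, 0.1, 1.0, 10.0)},
    "svm_rbf": {"C": (0.1, 1.0, 10.0), "gamma": ("scale", 0.1)},
    "gradient_boosting": {"n_estimators": (50, 100), "max_depth": (2, 3)},
    "random_forest": {"n_estimators": (100,), "max_depth": (3, 5, None)},
    "decision_tree": {"max_depth": (2, 3, 5, None)},
}


def default_spec(family: str) -> ClassifierSpec:
    return ClassifierSpec(family=family, grid=dict(MODEL_FAMILIES[family]))


# ---------------------------------------------------------------------------
# Folds and SMOTE
# ---------------------------------------------------------------------------

def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per sample); per-fold
    class counts differ by at most 1 within each class."""
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot build {k} "
            "stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


def smote_oversample(
    X: np.ndarray, y: np.ndarray, cfg: SmoteConfig | None = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Synthetic Minority Over-sampling Technique.

    Each synthetic sample is ``x_i + u * (x_nn - x_i)`` with
    ``u ~ Uniform(0, 1)`` and ``x_nn`` one of the ``k`` nearest minority
    neighbors (Euclidean) of a minority sample ``x_i``.  Majority rows are
    untouched; synthetic rows are appended after the originals.
    """
    cfg = cfg or SmoteConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects a binary label vector")
    minority = classes[np.argmin(counts)]
    Xm = X[y == minority]
    n_min = len(Xm)
    if n_min <= cfg.k:
        raise ValueError(
            f"minority class has {n_min} samples but k={cfg.k} neighbors are "
            "required; use a smaller k"
        )
    n_new = int(round(n_min * (cfg.minority_multiplier - 1.0)))
    if n_new == 0:
        return X.copy(), y.copy()
    # pairwise distances within the minority class
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, : cfg.k]
    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, n_min, size=n_new)
    which_nn = rng.integers(0, cfg.k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    xi = Xm[base]
    xnn = Xm[nn_idx[base, which_nn]]
    synthetic = xi + u[:, None] * (xnn - xi)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# AUC with DeLong inference
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def auc_with_inference(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[float, Tuple[float, float], float]:
    """Mann-Whitney AUC (half credit for ties) with DeLong variance.

    Returns ``(auc, (ci_low, ci_high), p)`` where the CI is
    ``auc +/- 1.96*SE`` truncated to [0, 1] and ``p`` is the two-sided
    normal test of AUC = 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC requires both classes to be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    rank_pos = _midrank(pos)
    rank_neg = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[:m] - rank_pos) / n
    v01 = 1.0 - (all_ranks[m:] - rank_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return float(auc), ci, p


# ---------------------------------------------------------------------------
# Confusion-derived metric panel
# ---------------------------------------------------------------------------

def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> Dict[str, Optional[float]]:
    """Accuracy, sensitivity, specificity, PPV, NPV and F1 from confusion
    counts (fractions in [0, 1]; ``None`` where a denominator is zero)."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("confusion counts sum to zero")
    sens = _ratio(tp, tp + fn)
    ppv = _ratio(tp, tp + fp)
    if sens is not None and ppv is not None and (sens + ppv) > 0:
        f1 = 2 * ppv * sens / (ppv + sens)
    else:
        f1 = None
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": sens,
        "specificity": _ratio(tn, tn + fp),
        "ppv": ppv,
        "npv": _ratio(tn, tn + fn),
        "f1": f1,
    }


def counts_from_rates(
    sensitivity: float, specificity: float, n_positive: int, n_negative: int
) -> Tuple[int, int, int, int]:
    """Reconstruct integer confusion counts (tp, fp, tn, fn) from printed
    sensitivity/specificity (fractions) and the class sizes."""
    tp = int(round(sensitivity * n_positive))
    tn = int(round(specificity * n_negative))
    return tp, n_negative - tn, tn, n_positive - tp


# ---------------------------------------------------------------------------
# Grid search and nested cross-validation
# ---------------------------------------------------------------------------

def _inner_auc(spec, params, X, y, inner_folds, seed) -> float:
    folds = stratified_folds(y, inner_folds, seed)
    aucs = []
    for f in range(inner_folds):
        tr, va = folds != f, folds == f
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            warnings.warn(
                f"inner fold {f} is single-class and was skipped",
                DegenerateFoldWarning, stacklevel=3,
            )
            continue
        est = spec.build(params, seed)
        est.fit(X[tr], y[tr])
        p = est.predict_proba(X[va])[:, 1]
        auc, _, _ = auc_with_inference(p, y[va])
        aucs.append(auc)
    if not aucs:
        raise ValueError("all inner folds were degenerate")
    return float(np.mean(aucs))


def grid_search(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray,
    inner_folds: int = 5, seed: int = 0,
) -> dict:
    """Return the grid point maximizing mean inner-fold AUC (ties broken by
    grid declaration order)."""
    best_params, best_auc = None, -np.inf
    for params in spec.grid_points():
        mean_auc = _inner_auc(spec, params, X, y, inner_folds, seed)
        if mean_auc > best_auc:  # strict: first occurrence wins ties
            best_auc, best_params = mean_auc, params
    return best_params


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    cv: CVConfig | None = None,
    smote: SmoteConfig | None = None,
) -> MetricsReport:
    """Nested stratified cross-validation of one model family.

    ``y`` codes suicidal ideation as 1.  Per outer fold: SMOTE on the
    training portion only, grid search (inner CV) on the augmented training
    portion, refit, score the held-out fold.  Metrics are computed from the
    pooled out-of-fold scores, oriented by ``cv.positive_class``.
    """
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, cv.outer_folds, cv.seed)
    scores = np.full(len(y), np.nan)
    chosen = []
    for f in range(cv.outer_folds):
        tr, te = folds != f, folds == f
        Xtr, ytr = X[tr], y[tr]
        if smote is not None:
            fold_smote = SmoteConfig(
                minority_multiplier=smote.minority_multiplier,
                k=smote.k, seed=smote.seed + f,
            )
            Xtr, ytr = smote_oversample(Xtr, ytr, fold_smote)
        params = grid_search(spec, Xtr, ytr, cv.inner_folds, cv.seed + f)
        est = spec.build(params, cv.seed + f)
        est.fit(Xtr, ytr)
        scores[te] = est.predict_proba(X[te])[:, 1]  # P(suicidal)
        chosen.append(tuple(sorted(params.items())))
    assert not np.isnan(scores).any(), "every sample must be scored once"
    return metrics_from_scores(scores, y, cv, best_params=tuple(chosen))


def metrics_from_scores(
    scores: np.ndarray, y: np.ndarray, cv: CVConfig | None = None,
    best_params: tuple = (),
) -> MetricsReport:
    """Build the metric panel from pooled P(suicidal) scores and true labels."""
    cv = cv or CVConfig()
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if cv.positive_class == "non_suicidal":
        pos_scores, pos_y = 1.0 - scores, 1 - y
    else:
        pos_scores, pos_y = scores, y
    auc, ci, p = auc_with_inference(pos_scores, pos_y)
    pred = (pos_scores >= cv.threshold).astype(int)
    tp = int(np.sum((pred == 1) & (pos_y == 1)))
    fp = int(np.sum((pred == 1) & (pos_y == 0)))
    tn = int(np.sum((pred == 0) & (pos_y == 0)))
    fn = int(np.sum((pred == 0) & (pos_y == 1)))
    panel = confusion_metrics(tp, fp, tn, fn)
    return MetricsReport(
        auc=auc, auc_ci=ci, auc_p=p,
        accuracy=panel["accuracy"], sensitivity=panel["sensitivity"],
        specificity=panel["specificity"], ppv=panel["ppv"], npv=panel["npv"],
        f1=panel["f1"], tp=tp, fp=fp, tn=tn, fn=fn,
        positive_class=cv.positive_class, best_params=best_params,
    )
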