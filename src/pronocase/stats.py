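"""Crude and covariate-adjusted logistic-regression associations.

Each linguistic feature enters the model on its natural percentage scale, so
an odds ratio is "per one percentage-point increase" in the feature.  Models
are binomial logistic regressions fit by maximum likelihood; inference is
Wald-based and two-sided: OR = exp(b), 95% CI = exp(b +/- 1.96*SE),
p = 2*(1 - Phi(|b/SE|)).  Quasi-complete separation (which genuinely occurs
in cohorts where almost every suicidal participant is also depressed) yields
a warning attached to the fit rather than a refusal; an optional Firth-style
bias-reduction flag shrinks such fits.

Also provides the cohort demographic summary (group sizes, per-group feature
means/SDs, categorical percentages) used for the demographics table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "LogisticFit",
    "AssociationRow",
    "CohortSummary",
    "SeparationWarning",
    "fit_logistic",
    "crude_association",
    "adjusted_association",
    "depression_association",
    "covariate_screen",
    "cohort_summary",
    "association_report",
]

_Z95 = 1.96  # Wald 95% multiplier

#: |coefficient| beyond which a fit is flagged as (quasi-)separated
_SEPARATION_COEF = 15.0


class SeparationWarning(UserWarning):
    """Complete or quasi-complete separation detected in a logistic fit."""


@dataclass
class LogisticFit:
    """A fitted binomial logistic regression (Wald inference)."""

    terms: List[str]
    coef: np.ndarray          # log-odds scale
    se: np.ndarray
    log_likelihood: float
    converged: bool
    separation: bool = False
    n_obs: int = 0

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def conf_int(self) -> np.ndarray:
        lo = np.exp(self.coef - _Z95 * self.se)
        hi = np.exp(self.coef + _Z95 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.coef / self.se, np.inf * np.sign(self.coef))
        return 2.0 * sps.norm.sf(np.abs(z))

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        return {
            "coef": float(self.coef[i]),
            "se": float(self.se[i]),
            "or": float(self.odds_ratios[i]),
            "ci": (float(self.conf_int[i, 0]), float(self.conf_int[i, 1])),
            "p": float(self.p_values[i]),
        }


def _validate_design(X: np.ndarray, y: np.ndarray, terms: Sequence[str]) -> None:
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design matrix and outcome are misaligned")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            "outcome must contain both classes coded 0/1; "
            f"got values {classes.tolist()}"
        )
    for j, name in enumerate(terms):
        if name == "intercept":
            continue
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor {name!r} is constant")


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    terms: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    firth: bool = False,
) -> LogisticFit:
    """Maximum-likelihood binomial logistic regression.

    ``X`` must include the intercept column; ``terms`` names the columns.
    Separation is reported through the ``separation`` flag (and a
    :class:`SeparationWarning`), not an exception.  ``firth=True`` applies
    Jeffreys-prior (Firth) bias reduction, useful under separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if terms is None:
        terms = ["intercept"] + [f"x{j}" for j in range(1, X.shape[1])]
    terms = list(terms)
    _validate_design(X, y, terms)

    separated = False
    if firth:
        coef, cov, llf, converged = _fit_firth(X, y, tol, max_iter)
        se = np.sqrt(np.diag(cov))
    else:
        model = sm.Logit(y, X)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = model.fit(method="newton", tol=tol, maxiter=max_iter, disp=0)
            except Exception:
                res = model.fit(method="bfgs", gtol=tol, maxiter=max_iter, disp=0)
        separated = any(
            issubclass(w.category, (PerfectSeparationWarning, RuntimeWarning))
            for w in caught
        )
        coef = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
        llf = float(res.llf)
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged:
            # a drifting likelihood with exploding coefficients is the
            # signature of (quasi-)separation: report it, don't refuse
            if np.all(np.isfinite(coef)) and np.max(np.abs(coef)) > 5.0:
                separated = True
            else:
                raise RuntimeError(
                    f"logistic fit did not converge within {max_iter} iterations"
                )

    if np.any(np.abs(coef) > _SEPARATION_COEF) or not np.all(np.isfinite(se)):
        separated = True
    if separated:
        warnings.warn(
            "complete or quasi-complete separation detected; "
            "Wald intervals may be unstable",
            SeparationWarning,
            stacklevel=2,
        )
    return LogisticFit(
        terms=terms, coef=coef, se=se, log_likelihood=llf,
        converged=True, separation=separated, n_obs=len(y),
    )


def _fit_firth(X, y, tol, max_iter):
    """Newton iterations on the Firth-penalized likelihood."""
    n, p = X.shape
    beta = np.zeros(p)
    llf = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        XtW = X.T * W
        info = XtW @ X
        cov = np.linalg.pinv(info)
        # hat-diagonal adjustment h_i
        H = (X @ cov) * XtW.T
        h = H.sum(axis=1)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = cov @ score
        beta_new = beta + step
        llf = float(np.sum(y * eta - np.log1p(np.exp(eta)))) + 0.5 * float(
            np.linalg.slogdet(info)[1]
        )
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = (X.T * (mu * (1 - mu))) @ X
    return beta, np.linalg.pinv(info), llf, True


# ---------------------------------------------------------------------------
# Association rows (feature -> outcome)
# ---------------------------------------------------------------------------

@dataclass
class AssociationRow:
    """One table row: group descriptives plus OR (95% CI) and p for a feature."""

    feature: str
    overall_mean: float
    overall_sd: float
    group0_mean: float
    group0_sd: float
    group1_mean: float
    group1_sd: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    separation: bool = False
    covariates: tuple = ()


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")


def _association(
    feature: np.ndarray,
    outcome: np.ndarray,
    covariate_matrix: np.ndarray | None,
    covariate_names: Sequence[str],
    feature_name: str,
    firth: bool = False,
) -> AssociationRow:
    feature = np.asarray(feature, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    cols = [np.ones_like(feature), feature]
    names = ["intercept", feature_name]
    if covariate_matrix is not None:
        cols.extend(np.asarray(covariate_matrix, dtype=float).T)
        names.extend(covariate_names)
    X = np.column_stack(cols)
    fit = fit_logistic(X, outcome, terms=names, firth=firth)
    term = fit.term(feature_name)
    g0, g1 = feature[outcome == 0], feature[outcome == 1]
    return AssociationRow(
        feature=feature_name,
        overall_mean=float(np.mean(feature)), overall_sd=_sd(feature),
        group0_mean=float(np.mean(g0)) if len(g0) else float("nan"),
        group0_sd=_sd(g0),
        group1_mean=float(np.mean(g1)) if len(g1) else float("nan"),
        group1_sd=_sd(g1),
        odds_ratio=term["or"], ci_low=term["ci"][0], ci_high=term["ci"][1],
        p_value=term["p"], separation=fit.separation,
        covariates=tuple(covariate_names),
    )


def crude_association(
    feature: np.ndarray, outcome: np.ndarray, feature_name: str = "feature",
    firth: bool = False,
) -> AssociationRow:
    """Simple (one-predictor) logistic regression of the outcome on a feature."""
    return _association(feature, outcome, None, (), feature_name, firth)


def adjusted_association(
    feature: np.ndarray,
    outcome: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    current_depression: np.ndarray,
    feature_name: str = "feature",
    firth: bool = False,
) -> AssociationRow:
    """Feature -> suicidal-ideation model adjusted for age, gender and
    current depression."""
    Z = np.column_stack([age, gender, current_depression]).astype(float)
    return _association(
        feature, outcome, Z, ("age", "gender", "current_depression"),
        feature_name, firth,
    )


def depression_association(
    feature: np.ndarray,
    depression_outcome: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    lifetime_affective: np.ndarray,
    feature_name: str = "feature",
    firth: bool = False,
) -> AssociationRow:
    """Feature -> current-depression model adjusted for age, gender and
    lifetime affective-disorder diagnosis."""
    Z = np.column_stack([age, gender, lifetime_affective]).astype(float)
    return _association(
        feature, depression_outcome, Z, ("age", "gender", "lifetime_affective"),
        feature_name, firth,
    )


def covariate_screen(covariate: np.ndarray, outcome: np.ndarray,
                     name: str = "covariate") -> AssociationRow:
    """Single-covariate screen (e.g. age or gender against suicidal ideation)."""
    return crude_association(covariate, outcome, feature_name=name)


# ---------------------------------------------------------------------------
# Cohort summary (demographics table)
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Per-group demographic and feature descriptives.

    ``groups`` maps a group name ("suicidal" / "non_suicidal") to a dict with
    keys: n, age_mean, age_sd, and for each categorical variable a
    {level: (count, percent)} mapping; ``feature_stats`` maps group name to
    {feature: (mean, sd)}.  Display percentages are rounded to 2 decimals.
    """

    groups: Dict[str, dict]
    feature_stats: Dict[str, Dict[str, tuple]] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(g["n"] for g in self.groups.values())


def _cat_summary(values: Sequence, levels: Sequence) -> Dict[str, tuple]:
    n = len(values)
    out = {}
    for level in levels:
        c = sum(1 for v in values if v == level)
        out[str(level)] = (c, round(100.0 * c / n, 2) if n else 0.0)
    return out


def cohort_summary(
    records: Sequence, labels: Sequence, features: pd.DataFrame | None = None
) -> CohortSummary:
    """Summarize the cohort grouped by suicidal ideation.

    ``records`` are :class:`~pronocase.corpus_io.ParticipantRecord`s and
    ``labels`` the aligned :class:`~pronocase.corpus_io.Labels`.
    """
    if len(records) != len(labels):
        raise ValueError("records and labels are misaligned")
    groups: Dict[str, dict] = {}
    masks = {
        "suicidal": [lab.suicidal_ideation for lab in labels],
        "non_suicidal": [not lab.suicidal_ideation for lab in labels],
    }
    for gname, mask in masks.items():
        recs = [r for r, m in zip(records, mask) if m]
        labs = [lab for lab, m in zip(labels, mask) if m]
        ages = np.array([r.age for r in recs], dtype=float)
        groups[gname] = {
            "n": len(recs),
            "age_mean": float(np.mean(ages)) if len(recs) else float("nan"),
            "age_sd": _sd(ages) if len(recs) > 1 else None,
            "gender": _cat_summary([r.gender.value for r in recs],
                                   ["male", "female"]),
            "current_depression": _cat_summary(
                [lab.current_depression for lab in labs], [True, False]),
            "lifetime_affective": _cat_summary(
                [r.lifetime_affective for r in recs], [True, False]),
        }
    feature_stats: Dict[str, Dict[str, tuple]] = {}
    if features is not None:
        ids = [r.participant_id for r in records]
        aligned = features.loc[ids]
        for gname, mask in masks.items():
            sub = aligned.loc[np.asarray(mask, dtype=bool)]
            feature_stats[gname] = {
                col: (float(sub[col].mean()), float(sub[col].std(ddof=1)))
                for col in sub.columns if col != "token_total"
            }
    return CohortSummary(groups=groups, feature_stats=feature_stats)


def association_report(rows: Sequence[AssociationRow]) -> pd.DataFrame:
    """Association rows as a table mirroring the feature-association layout."""
    return pd.DataFrame([
        {
            "feature": r.feature,
            "overall_mean": r.overall_mean, "overall_sd": r.overall_sd,
            "non_suicidal_mean": r.group0_mean, "non_suicidal_sd": r.group0_sd,
            "suicidal_mean": r.group1_mean, "suicidal_sd": r.group1_sd,
            "odds_ratio": r.odds_ratio,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p_value": r.p_value,
            "separation": r.separation,
        }
        for r in rows
    ])
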