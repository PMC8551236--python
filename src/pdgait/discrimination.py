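"""Cohort discrimination: logistic model score, ROC/AUC, cutoffs, DeLong.

The AUC is the midrank (Mann-Whitney) estimator: the fraction of
patient-control pairs in which the patient scores higher, ties counted
one half. Confidence intervals and correlated-AUC contrasts use the
DeLong placement-value variance. Scores are oriented so that higher means
more PD-like before any ROC quantity is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import reference as ref
from .exceptions import DomainError

POSITIVE_LABEL = "PD"


def _split(scores, labels, positive=POSITIVE_LABEL):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == positive]
    neg = s[y != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise DomainError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels, positive: str = POSITIVE_LABEL) -> float:
    """Midrank AUC: P(case > control) + 0.5 P(tie)."""
    pos, neg = _split(scores, labels, positive)
    n1, n0 = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values for cases and controls."""
    v10 = np.empty(len(pos))
    v01 = np.empty(len(neg))
    order = np.sort(neg)
    v10 = (
        np.searchsorted(order, pos, side="left")
        + 0.5
        * (
            np.searchsorted(order, pos, side="right")
            - np.searchsorted(order, pos, side="left")
        )
    ) / len(neg)
    order_p = np.sort(pos)
    v01 = 1.0 - (
        np.searchsorted(order_p, neg, side="left")
        + 0.5
        * (
            np.searchsorted(order_p, neg, side="right")
            - np.searchsorted(order_p, neg, side="left")
        )
    ) / len(pos)
    return v10, v01


def delong_variance(scores, labels, positive: str = POSITIVE_LABEL) -> float:
    pos, neg = _split(scores, labels, positive)
    v10, v01 = _placements(pos, neg)
    s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    return float(s10 / len(pos) + s01 / len(neg))


def auc_ci_delong(
    scores, labels, alpha: float = 0.05, positive: str = POSITIVE_LABEL
) -> tuple[float, float]:
    """Normal-approximation DeLong CI, truncated to [0, 1].

    A zero placement variance (e.g. perfect separation) yields a
    degenerate point interval and a warning.
    """
    auc = roc_auc(scores, labels, positive)
    var = delong_variance(scores, labels, positive)
    if var <= 0:
        warnings.warn("degenerate DeLong CI: zero placement variance", stacklevel=2)
        return auc, auc
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def compare_aucs(
    score_table: pd.DataFrame, labels, positive: str = POSITIVE_LABEL
) -> tuple[float, float]:
    """DeLong test that k correlated AUCs (same subjects) are equal.

    Returns the chi-square statistic (df = rank of the contrast
    covariance, at most k - 1) and its p-value.
    """
    cols = list(score_table.columns)
    if len(cols) < 2:
        raise DomainError("need at least two score columns to compare")
    y = np.asarray(labels)
    if len(y) != len(score_table):
        raise DomainError("labels and scores must cover the same subjects")
    pos_mask = y == positive
    if pos_mask.all() or (~pos_mask).all():
        raise DomainError("both classes must be present")
    v10 = np.column_stack(
        [_placements(score_table[c].to_numpy()[pos_mask],
                     score_table[c].to_numpy()[~pos_mask])[0] for c in cols]
    )
    v01 = np.column_stack(
        [_placements(score_table[c].to_numpy()[pos_mask],
                     score_table[c].to_numpy()[~pos_mask])[1] for c in cols]
    )
    aucs = v10.mean(axis=0)
    s = np.cov(v10, rowvar=False) / v10.shape[0] + np.cov(v01, rowvar=False) / v01.shape[0]
    k = len(cols)
    contrast = np.hstack([np.ones((k - 1, 1)), -np.eye(k - 1)])
    diff = contrast @ aucs
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    cov = contrast @ np.atleast_2d(s) @ contrast.T
    df = np.linalg.matrix_rank(cov)
    if df == 0:
        return 0.0, 1.0
    chi2 = float(diff @ np.linalg.pinv(cov) @ diff)
    return chi2, float(stats.chi2.sf(chi2, df))


def best_cutoff(
    scores, labels, positive: str = POSITIVE_LABEL
) -> tuple[float, float, float, float]:
    """Youden-optimal threshold and its operating characteristics.

    Candidate cutoffs are the midpoints between adjacent distinct scores
    (plus outer sentinels); a subject is called positive when its score
    exceeds the cutoff. Ties in sensitivity + specificity break toward
    higher specificity, then toward the higher cutoff. Sensitivity,
    specificity and accuracy are returned in percent.
    """
    pos, neg = _split(scores, labels, positive)
    s = np.unique(np.concatenate([pos, neg]))
    mids = (s[:-1] + s[1:]) / 2 if len(s) > 1 else np.array([])
    candidates = np.concatenate([[s[0] - 1.0], mids, [s[-1] + 1.0]])
    best = None
    for c in candidates:
        sens = 100.0 * (pos > c).mean()
        spec = 100.0 * (neg <= c).mean()
        acc = 100.0 * ((pos > c).sum() + (neg <= c).sum()) / (len(pos) + len(neg))
        key = (sens + spec, spec, c)
        if best is None or key > best[0]:
            best = (key, (float(c), sens, spec, acc))
    return best[1]


def binormal_auc(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Closed-form AUC of two normal score distributions.

    Phi(|mean1 - mean2| / sqrt(sd1^2 + sd2^2)); the analytic counterpart
    of the empirical AUC when both cohorts are normal.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise DomainError("SDs must be > 0")
    return float(stats.norm.cdf(abs(mean1 - mean2) / np.hypot(sd1, sd2)))


def accuracy_band(auc: float) -> str:
    """Discriminative-accuracy band: high / moderate / low / chance.

    > 0.90 high; 0.70-0.90 moderate (closed at both ends); 0.50-0.70 low;
    below 0.50 a chance result.
    """
    if not 0 <= auc <= 1:
        raise DomainError(f"AUC must lie in [0, 1], got {auc}")
    if auc > 0.90:
        return "high"
    if auc >= 0.70:
        return "moderate"
    if auc >= 0.50:
        return "low"
    return "chance"


@dataclass
class LogisticGaitModel:
    """Logistic combination of the three factor scores into a model score."""

    intercept: float
    coefficients: pd.Series
    log_likelihood: float
    converged: bool
    separation: bool = False

    def linear_predictor(self, scores: pd.DataFrame) -> pd.Series:
        x = scores[list(self.coefficients.index)].astype(float)
        return self.intercept + x @ self.coefficients

    def predict_proba(self, scores: pd.DataFrame) -> pd.Series:
        """Fitted probability of PD membership — the model score."""
        eta = np.clip(self.linear_predictor(scores), -500, 500)
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=scores.index)


def fit_logistic(
    score_table: pd.DataFrame,
    labels,
    positive: str = POSITIVE_LABEL,
    columns: tuple[str, ...] = ref.FACTORS,
) -> LogisticGaitModel:
    """Maximum-likelihood logistic regression of cohort on factor scores.

    Complete separation is flagged (``separation=True``, ``converged``
    False) rather than raised; the returned coefficients are then the last
    iterate and should be interpreted with care.
    """
    cols = [c for c in columns if c in score_table.columns]
    if not cols:
        raise DomainError("no factor-score columns found")
    x = score_table[cols].astype(float)
    if x.isna().any().any():
        raise DomainError("missing factor scores")
    y = (np.asarray(labels) == positive).astype(float)
    if y.min() == y.max():
        raise DomainError("both classes must be present")
    exog = sm.add_constant(x, has_constant="add")
    model = sm.Logit(y, exog)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            separation = True
            res = model.fit(disp=0, method="bfgs", maxiter=500)
    params = res.params
    converged = bool(res.mle_retvals.get("converged", False)) and not separation
    if not separation and np.abs(params).max() > 50:
        separation = True  # quasi-separation: runaway coefficients
        converged = False
    return LogisticGaitModel(
        intercept=float(params["const"]),
        coefficients=params.drop("const"),
        log_likelihood=float(res.llf),
        converged=converged,
        separation=separation,
    )


@dataclass
class ROCResult:
    """One row of the discrimination report."""

    measure: str
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    band: str


def evaluate_measure(
    scores, labels, measure: str = "score", positive: str = POSITIVE_LABEL
) -> ROCResult:
    """AUC, DeLong 95% CI, Youden cutoff metrics and accuracy band."""
    auc = roc_auc(scores, labels, positive)
    lo, hi = auc_ci_delong(scores, labels, positive=positive)
    cut, sens, spec, acc = best_cutoff(scores, labels, positive)
    return ROCResult(measure, auc, lo, hi, cut, sens, spec, acc, accuracy_band(auc))


def discrimination_report(
    table: pd.DataFrame,
    labels,
    variable_columns: tuple[str, ...] = ref.GAIT_VARIABLES,
    factor_columns: tuple[str, ...] = ref.FACTORS,
    model_column: str | None = "gait_model",
    positive: str = POSITIVE_LABEL,
) -> pd.DataFrame:
    """Report of AUC / 95% CI / cutoff metrics for every measure.

    Raw variables are first oriented so higher = more impaired (gait speed
    is negated); factor and model scores are already oriented.
    """
    rows = []
    for v in variable_columns:
        oriented = ref.IMPAIRMENT_DIRECTION.get(v, 1) * table[v].astype(float)
        rows.append(evaluate_measure(oriented, labels, measure=v, positive=positive))
    for f in factor_columns:
        rows.append(
            evaluate_measure(table[f], labels, measure=f, positive=positive)
        )
    if model_column is not None and model_column in table.columns:
        rows.append(
            evaluate_measure(
                table[model_column], labels, measure="gait_model", positive=positive
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
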