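"""Three-factor gait model: EFA, 0.40 allocation, weighted-sum factor scores.

The factor scores follow the weighted sum score (WSS) recipe: each of the
eight variables is z-scored against a reference sample, and every factor's
score is the sum of the z-scores of its allocated variables, each signed by
its loading, with the factor's overall sign fixed so that greater gait
impairment (slower speed, longer times, larger CVs and asymmetries) always
increases the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import reference as ref
from .exceptions import DegenerateInputError, DomainError, InsufficientDataError

MIN_EFA_SUBJECTS = 50


@dataclass
class FactorLoadingMatrix:
    """Rotated variable-factor correlations with the allocation threshold."""

    loadings: pd.DataFrame  # variables x factors
    threshold: float = ref.LOADING_THRESHOLD
    method: str = "paf"
    rotation: str = "varimax"

    def __post_init__(self) -> None:
        if (self.loadings.abs() > 1 + 1e-8).any().any():
            raise DomainError("loadings must lie in [-1, 1]")

    @property
    def variables(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def factors(self) -> list[str]:
        return list(self.loadings.columns)


@dataclass
class ZScoreReference:
    """Per-variable mean and SD of the standardization sample."""

    means: pd.Series
    sds: pd.Series
    source: str = "pooled"  # "pooled" (HS + PD) or "hs"

    def __post_init__(self) -> None:
        if (self.sds <= 0).any():
            bad = self.sds[self.sds <= 0].index.tolist()
            raise DomainError(f"reference SDs must be > 0, offending: {bad}")

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        variables: tuple[str, ...] = ref.GAIT_VARIABLES,
        source: str = "pooled",
    ) -> "ZScoreReference":
        sub = table[list(variables)].astype(float)
        return cls(means=sub.mean(), sds=sub.std(ddof=1), source=source)

    def zscore(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = list(self.means.index)
        return (table[cols].astype(float) - self.means) / self.sds


def _varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Raw varimax rotation (orthogonal), SVD-based fixed point."""
    n, k = loadings.shape
    if k < 2:
        return loadings
    rot = np.eye(k)
    obj = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / n)
        )
        rot = u @ vt
        new_obj = s.sum()
        if new_obj < obj * (1 + tol):
            break
        obj = new_obj
    return loadings @ rot


def _principal_axis(
    corr: np.ndarray, n_factors: int, max_iter: int = 200, tol: float = 1e-6
) -> np.ndarray:
    """Iterated principal-axis factoring of a correlation matrix.

    Communalities start at squared multiple correlations and are updated
    from the retained eigenstructure until convergence.
    """
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError as err:
        raise DegenerateInputError("singular correlation matrix") from err
    h = 1.0 - 1.0 / np.diag(inv)  # SMC start
    h = np.clip(h, 0.0, 1.0)
    r = corr.copy()
    for _ in range(max_iter):
        np.fill_diagonal(r, h)
        vals, vecs = np.linalg.eigh(r)
        order = np.argsort(vals)[::-1][:n_factors]
        lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
        h_new = np.clip((lam**2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            break
        h = h_new
    np.fill_diagonal(r, h)
    vals, vecs = np.linalg.eigh(r)
    order = np.argsort(vals)[::-1][:n_factors]
    return vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))


def fit_efa(
    table: pd.DataFrame,
    n_factors: int = 3,
    variables: tuple[str, ...] = ref.GAIT_VARIABLES,
    method: str = "paf",
    rotation: str = "varimax",
    threshold: float = ref.LOADING_THRESHOLD,
) -> FactorLoadingMatrix:
    """Exploratory factor analysis of the eight gait variables.

    Default recipe: principal-axis extraction of ``n_factors`` factors from
    the Pearson correlation matrix, followed by varimax rotation. Row order
    of the input is irrelevant. Requires at least 50 complete subjects.
    """
    x = table[list(variables)].astype(float)
    if x.isna().any().any():
        raise DomainError("EFA input contains missing values")
    if len(x) < MIN_EFA_SUBJECTS:
        raise InsufficientDataError(
            f"EFA needs >= {MIN_EFA_SUBJECTS} subjects, got {len(x)}"
        )
    if method != "paf":
        raise ValueError(f"unknown extraction method {method!r}")
    corr = np.corrcoef(x.to_numpy(), rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise DegenerateInputError("correlation matrix not finite (constant variable?)")
    lam = _principal_axis(corr, n_factors)
    if rotation == "varimax":
        lam = _varimax(lam)
    elif rotation not in (None, "none"):
        raise ValueError(f"unknown rotation {rotation!r}")
    cols = [f"factor{i + 1}" for i in range(n_factors)]
    loadings = pd.DataFrame(
        np.clip(lam, -1.0, 1.0), index=list(variables), columns=cols
    )
    return FactorLoadingMatrix(
        loadings=loadings, threshold=threshold, method=method, rotation=rotation
    )


def align_to_reference(
    flm: FactorLoadingMatrix, template: pd.DataFrame | None = None
) -> FactorLoadingMatrix:
    """Rename/reorder fitted factors to the reference factor names.

    Factors are matched to template columns by maximal absolute Tucker
    congruence (solved as an assignment problem), and each matched factor
    is sign-flipped to agree with the template's direction. Only a
    relabelling: the rotated solution itself is unchanged.
    """
    if template is None:
        template = ref.reference_loadings()
    lam = flm.loadings
    if lam.shape[1] != template.shape[1]:
        raise DomainError("factor count differs from the template")
    a = lam.to_numpy()
    b = template.reindex(lam.index).to_numpy()
    norm_a = np.linalg.norm(a, axis=0)
    norm_b = np.linalg.norm(b, axis=0)
    cong = (a.T @ b) / np.outer(norm_a, norm_b)
    rows, cols = linear_sum_assignment(-np.abs(cong))
    out = {}
    for i, j in zip(rows, cols):
        sign = 1.0 if cong[i, j] >= 0 else -1.0
        out[template.columns[j]] = sign * lam.iloc[:, i]
    aligned = pd.DataFrame(out)[list(template.columns)]
    return FactorLoadingMatrix(
        loadings=aligned,
        threshold=flm.threshold,
        method=flm.method,
        rotation=flm.rotation,
    )


def allocate_variables(flm: FactorLoadingMatrix) -> dict[str, list[str]]:
    """Map each factor to the variables loading |r| >= threshold on it.

    A variable may be allocated to several factors (gait speed is, in the
    reference structure). A variable reaching the threshold on no factor
    triggers a warning and stays unallocated.
    """
    lam = flm.loadings
    allocation = {
        f: [v for v in lam.index if abs(lam.at[v, f]) >= flm.threshold]
        for f in lam.columns
    }
    allocated = {v for vs in allocation.values() for v in vs}
    for v in lam.index:
        if v not in allocated:
            warnings.warn(
                f"variable {v!r} loads below {flm.threshold} on every factor "
                "and is unallocated",
                stacklevel=2,
            )
    return allocation


def weighted_sum_scores(
    table: pd.DataFrame,
    allocation: dict[str, list[str]],
    reference: ZScoreReference,
    flm: FactorLoadingMatrix,
    weighting: str = "unit",
) -> pd.DataFrame:
    """WSS factor scores, one column per factor, higher = more impaired.

    Per factor: sum over allocated variables of sign(loading) x z, with
    unit weights by default (``weighting="loading"`` multiplies by
    |loading| instead). The factor's overall sign is then fixed from the
    known impairment direction of its variables.
    """
    if weighting not in ("unit", "loading"):
        raise ValueError(f"unknown weighting {weighting!r}")
    z = reference.zscore(table)
    scores = {}
    for factor, variables in allocation.items():
        if not variables:
            scores[factor] = pd.Series(np.nan, index=table.index)
            continue
        total = pd.Series(0.0, index=table.index)
        orient = 0.0
        for v in variables:
            lam = flm.loadings.at[v, factor]
            w = np.sign(lam) if weighting == "unit" else lam
            total = total + w * z[v]
            orient += np.sign(lam) * ref.IMPAIRMENT_DIRECTION[v]
        if orient < 0:
            total = -total
        elif orient == 0:
            warnings.warn(
                f"factor {factor!r}: impairment orientation ambiguous", stacklevel=2
            )
        scores[factor] = total
    return pd.DataFrame(scores, index=table.index)


def hs_referenced_zscore(value: float, hs_mean: float, hs_sd: float) -> float:
    """(value - HS mean) / HS SD — the radar-chart standardization."""
    if hs_sd <= 0:
        raise DomainError(f"HS SD must be > 0, got {hs_sd}")
    return (value - hs_mean) / hs_sd
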