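"""Stage-wise impairment: Cohen's effect sizes vs HS, bands, ANOVA layer.

Every measure (8 gait variables, 3 factor scores, 1 model score) is
compared between each modified H&Y stage group and the healthy cohort
with Cohen's d on the pooled SD, giving the 12 x 6 = 72-cell grid. The
sign is kept internally (gait speed runs negative in impaired groups) but
bands are assigned on the magnitude.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import reference as ref
from .exceptions import DomainError, InsufficientDataError

#: Band lower edges on |d|, closed on the left.
ES_BANDS: tuple[tuple[float, str], ...] = (
    (2.0, "huge"),
    (1.2, "very large"),
    (0.8, "large"),
    (0.5, "medium"),
    (0.2, "small"),
    (0.0, "none"),
)

GRID_MEASURES: tuple[str, ...] = ref.GAIT_VARIABLES + ref.FACTORS + ("gait_model",)


def pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("pooled SD needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise DomainError("SDs must be >= 0")
    return float(
        np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    )


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Magnitude of Cohen's d: |mean1 - mean2| / pooled SD."""
    sp = pooled_sd(sd1, n1, sd2, n2)
    diff = abs(mean1 - mean2)
    if sp == 0:
        if diff == 0:
            return 0.0
        raise DomainError("zero pooled SD with unequal means: d undefined")
    return float(diff / sp)


def classify_es(d: float) -> str:
    """Band of an effect size; negative input is banded on its magnitude."""
    m = abs(d)
    for edge, label in ES_BANDS:
        if m >= edge:
            return label
    raise AssertionError("unreachable")


@dataclass
class EffectSize:
    """A signed Cohen's d with its magnitude band."""

    value: float

    @property
    def magnitude(self) -> float:
        return abs(self.value)

    @property
    def band(self) -> str:
        return classify_es(self.value)


def effect_size_from_samples(x1, x2) -> EffectSize:
    """Signed d of sample 1 vs sample 2 (positive when mean1 > mean2)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    sp = pooled_sd(x1.std(ddof=1), len(x1), x2.std(ddof=1), len(x2))
    diff = x1.mean() - x2.mean()
    if sp == 0:
        if diff == 0:
            return EffectSize(0.0)
        raise DomainError("zero pooled SD with unequal means: d undefined")
    return EffectSize(float(diff / sp))


def build_grid(
    table: pd.DataFrame,
    measures: tuple[str, ...] = GRID_MEASURES,
    stage_col: str = "stage",
    hs_label: str = "HS",
    group_col: str = "group",
) -> pd.DataFrame:
    """Long-format measure x stage grid of effect sizes vs HS.

    One row per (measure, stage): signed d, magnitude, band, group sizes.
    An empty stage yields rows flagged ``missing`` so the grid always has
    len(measures) x 6 cells.
    """
    hs = table[table[group_col] == hs_label]
    if len(hs) < 2:
        raise InsufficientDataError("HS group needs >= 2 subjects")
    pwpd = table[table[group_col] != hs_label]
    rows = []
    for measure, stage in itertools.product(measures, ref.VALID_STAGES):
        grp = pwpd[pwpd[stage_col] == stage]
        if len(grp) < 2 or measure not in table.columns:
            rows.append(
                {
                    "measure": measure,
                    "stage": stage,
                    "d_signed": np.nan,
                    "d": np.nan,
                    "band": "missing",
                    "n_stage": len(grp),
                    "n_hs": len(hs),
                    "missing": True,
                }
            )
            continue
        es = effect_size_from_samples(grp[measure], hs[measure])
        rows.append(
            {
                "measure": measure,
                "stage": stage,
                "d_signed": es.value,
                "d": es.magnitude,
                "band": es.band,
                "n_stage": len(grp),
                "n_hs": len(hs),
                "missing": False,
            }
        )
    grid = pd.DataFrame(rows)
    if grid["missing"].any():
        empty = sorted(grid.loc[grid["missing"], "stage"].unique())
        warnings.warn(f"grid has missing cells for stages {empty}", stacklevel=2)
    return grid


def radar_zscores(
    table: pd.DataFrame,
    measures: tuple[str, ...] = GRID_MEASURES,
    stage_col: str = "stage",
    hs_label: str = "HS",
    group_col: str = "group",
) -> pd.DataFrame:
    """HS-referenced z-scores of stage means — the radar-chart export.

    z = (stage mean - HS mean) / HS SD per measure; the gait-speed z runs
    negative in impaired groups, all other measures positive.
    """
    hs = table[table[group_col] == hs_label]
    rows = []
    for measure in measures:
        mu, sd = hs[measure].mean(), hs[measure].std(ddof=1)
        if sd <= 0:
            raise DomainError(f"HS SD must be > 0 for {measure!r}")
        for stage in ref.VALID_STAGES:
            grp = table[(table[group_col] != hs_label) & (table[stage_col] == stage)]
            z = (grp[measure].mean() - mu) / sd if len(grp) else np.nan
            rows.append({"measure": measure, "stage": stage, "zscore": z})
    return pd.DataFrame(rows)


def anova_factor_scores(
    table: pd.DataFrame,
    factors: tuple[str, ...] = ref.FACTORS,
    group_col: str = "group",
    hs_label: str = "HS",
    alpha: float = 0.05,
    family: str = "vs_hs",
) -> dict[str, dict]:
    """One-way ANOVA per factor score plus Fisher LSD post hoc.

    Groups are HS and the stage groups. If the omnibus F is significant at
    ``alpha``, pairwise Fisher LSD t-tests (pooled within-group MSE,
    df = N - k) follow, Bonferroni-corrected over the comparison family:
    each stage vs HS (m = number of stages) by default, or all pairs with
    ``family="all_pairs"``.
    """
    if family not in ("vs_hs", "all_pairs"):
        raise ValueError(f"unknown family {family!r}")
    groups = list(dict.fromkeys(table[group_col]))
    if len(groups) < 2:
        raise DomainError("need at least two groups")
    out: dict[str, dict] = {}
    for factor in factors:
        samples = {g: table.loc[table[group_col] == g, factor].to_numpy() for g in groups}
        for g, x in samples.items():
            if len(x) < 2:
                raise InsufficientDataError(f"group {g!r} needs >= 2 subjects")
            if np.std(x) == 0:
                warnings.warn(f"group {g!r} has zero variance in {factor!r}",
                              stacklevel=2)
        f_stat, p = stats.f_oneway(*samples.values())
        n_total = sum(len(x) for x in samples.values())
        k = len(samples)
        mse = sum((len(x) - 1) * x.var(ddof=1) for x in samples.values()) / (
            n_total - k
        )
        df = n_total - k
        result = {"F": float(f_stat), "p": float(p), "posthoc": None}
        if p < alpha:
            if family == "vs_hs":
                pairs = [(g, hs_label) for g in groups if g != hs_label]
            else:
                pairs = list(itertools.combinations(groups, 2))
            m = len(pairs)
            rows = []
            for g1, g2 in pairs:
                x1, x2 = samples[g1], samples[g2]
                se = np.sqrt(mse * (1 / len(x1) + 1 / len(x2)))
                t = (x1.mean() - x2.mean()) / se if se > 0 else np.nan
                p_raw = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
                p_adj = min(1.0, p_raw * m) if np.isfinite(p_raw) else np.nan
                rows.append(
                    {
                        "group1": g1,
                        "group2": g2,
                        "diff": float(x1.mean() - x2.mean()),
                        "t": float(t),
                        "p_raw": float(p_raw),
                        "p_bonferroni": float(p_adj),
                        "significant": bool(p_adj < alpha),
                    }
                )
            result["posthoc"] = pd.DataFrame(rows)
        out[factor] = result
    return out
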