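"""Published reference values for the three-factor gait model.

This module is the single source of the canonical eight-variable set, the
published cohort summary statistics (means and SDs per variable for the
Parkinson and healthy cohorts), the modified Hoehn & Yahr stage composition
of the patient cohort, and the latent-structure template (variable-to-factor
loadings with the 0.40 allocation threshold) that the synthetic generator
and the factor model share.

Units follow the walkway convention: gait speed in cm/s, step and double
support time in s, coefficients of variation and asymmetry indices in %.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical order of the eight model variables.
GAIT_VARIABLES: tuple[str, ...] = (
    "gait_speed",
    "step_time",
    "double_support_time",
    "step_length_cv",
    "swing_time_cv",
    "step_velocity_cv",
    "step_time_asymmetry",
    "swing_time_asymmetry",
)

#: Human-readable labels (report output).
VARIABLE_LABELS: dict[str, str] = {
    "gait_speed": "Gait speed (cm/s)",
    "step_time": "Step time (s)",
    "double_support_time": "Double support time (s)",
    "step_length_cv": "Step length CV (%)",
    "swing_time_cv": "Swing time CV (%)",
    "step_velocity_cv": "Step velocity CV (%)",
    "step_time_asymmetry": "Step time asymmetry (%)",
    "swing_time_asymmetry": "Swing time asymmetry (%)",
}

#: Direction in which impairment moves each variable: -1 means lower values
#: are worse (only gait speed), +1 means higher values are worse.
IMPAIRMENT_DIRECTION: dict[str, int] = {
    "gait_speed": -1,
    "step_time": +1,
    "double_support_time": +1,
    "step_length_cv": +1,
    "swing_time_cv": +1,
    "step_velocity_cv": +1,
    "step_time_asymmetry": +1,
    "swing_time_asymmetry": +1,
}

FACTORS: tuple[str, ...] = ("pace_rhythm", "variability", "asymmetry")

#: Published factor allocation at the 0.40 threshold. Gait speed is shared
#: between pace/rhythm and variability.
REFERENCE_ALLOCATION: dict[str, tuple[str, ...]] = {
    "pace_rhythm": ("gait_speed", "step_time", "double_support_time"),
    "variability": (
        "step_velocity_cv",
        "step_length_cv",
        "swing_time_cv",
        "gait_speed",
    ),
    "asymmetry": ("step_time_asymmetry", "swing_time_asymmetry"),
}

LOADING_THRESHOLD: float = 0.40

#: Cohort summary statistics: per variable, (mean, SD) for each cohort.
#: Patient cohort N = 298, healthy cohort N = 84.
COHORT_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "gait_speed": {"PD": (100.05, 30.42), "HS": (122.29, 17.7)},
    "step_time": {"PD": (0.54, 0.10), "HS": (0.51, 0.05)},
    "double_support_time": {"PD": (0.32, 0.15), "HS": (0.26, 0.05)},
    "step_length_cv": {"PD": (4.73, 3.10), "HS": (2.89, 1.10)},
    "swing_time_cv": {"PD": (5.68, 2.91), "HS": (4.00, 1.66)},
    "step_velocity_cv": {"PD": (4.37, 2.89), "HS": (2.95, 1.24)},
    "step_time_asymmetry": {"PD": (4.27, 4.58), "HS": (2.16, 1.97)},
    "swing_time_asymmetry": {"PD": (5.22, 5.56), "HS": (2.65, 2.30)},
}

N_PD: int = 298
N_HS: int = 84

#: Modified H&Y stage composition of the published patient cohort.
STAGE_COUNTS: dict[float, int] = {1.0: 7, 1.5: 27, 2.0: 60, 2.5: 99, 3.0: 93, 4.0: 12}

#: Stages admitted by the model (stage 5, wheelchair-bound, is excluded).
VALID_STAGES: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0)

#: Screening flow of the two cohorts: (screened, excluded).
SCREENING_PD: tuple[int, int] = (359, 61)
SCREENING_HS: tuple[int, int] = (96, 12)

#: Severity multipliers applied to the HS -> PD mean offset to spread the
#: pooled patient cohort over stages. Chosen monotone with a stage-count
#: weighted average of ~1 so the stage mixture reproduces the pooled means.
STAGE_SEVERITY: dict[float, float] = {
    1.0: 0.30,
    1.5: 0.45,
    2.0: 0.65,
    2.5: 1.00,
    3.0: 1.30,
    4.0: 2.00,
}


def reference_loadings() -> pd.DataFrame:
    """Latent-structure template: 8 variables x 3 factors.

    Signs encode direction on the shared impairment axis (gait speed loads
    negatively: a higher latent severity lowers speed). Magnitudes are
    plausible strong loadings consistent with the published allocation; per
    variable the squared loadings sum to < 1 so a unique variance remains.
    """
    lam = pd.DataFrame(
        0.0, index=list(GAIT_VARIABLES), columns=list(FACTORS)
    )
    # the cross-loading is set so the population varimax solution keeps
    # gait speed above the 0.40 threshold on both factors
    lam.loc["gait_speed", "pace_rhythm"] = -0.65
    lam.loc["gait_speed", "variability"] = -0.55
    lam.loc["step_time", "pace_rhythm"] = 0.80
    lam.loc["double_support_time", "pace_rhythm"] = 0.75
    lam.loc["step_length_cv", "variability"] = 0.75
    lam.loc["swing_time_cv", "variability"] = 0.75
    lam.loc["step_velocity_cv", "variability"] = 0.75
    lam.loc["step_time_asymmetry", "asymmetry"] = 0.80
    lam.loc["swing_time_asymmetry", "asymmetry"] = 0.80
    return lam


def mean_stage(counts: dict[float, int] | None = None) -> float:
    """Count-weighted mean modified H&Y stage of a patient cohort."""
    if counts is None:
        counts = STAGE_COUNTS
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty stage counts")
    return sum(stage * k for stage, k in counts.items()) / n


def screening_exclusion_pct(screened: int, excluded: int) -> float:
    """Percentage of screened participants excluded at eligibility."""
    if screened <= 0 or not 0 <= excluded <= screened:
        raise ValueError("invalid screening counts")
    return 100.0 * excluded / screened


def cohort_means(group: str) -> pd.Series:
    return pd.Series({v: COHORT_SUMMARY[v][group][0] for v in GAIT_VARIABLES})


def cohort_sds(group: str) -> pd.Series:
    return pd.Series({v: COHORT_SUMMARY[v][group][1] for v in GAIT_VARIABLES})


def unique_sds(loadings: pd.DataFrame) -> pd.Series:
    """Unique (specific) SD per variable on the standardized scale.

    Completes each variable's variance to 1 given its factor loadings.
    """
    comm = (loadings**2).sum(axis=1)
    if (comm > 1).any():
        bad = comm[comm > 1].index.tolist()
        raise ValueError(f"communalities exceed 1 for {bad}")
    return np.sqrt(1.0 - comm)
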