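"""Derivation of the eight model variables from step-level walkway records.

A step-level table has one row per footfall interval with columns
``subject_id, trial, step, foot, step_time, swing_time, double_support_time,
step_length, step_velocity`` (times in s, lengths in cm, velocities in cm/s).
Trial 1 is a familiarisation trial and is always discarded; the variables
are computed per trial on trials 2-4 and then averaged.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .exceptions import DomainError, InsufficientDataError, SchemaError
from .reference import GAIT_VARIABLES

#: Trials entering the analysis; trial 1 is familiarisation.
ANALYSIS_TRIALS: tuple[int, ...] = (2, 3, 4)

STEP_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "trial",
    "step",
    "foot",
    "step_time",
    "swing_time",
    "double_support_time",
    "step_length",
    "step_velocity",
)


def coefficient_of_variation(values: Iterable[float]) -> float:
    """Coefficient of variation in percent: sample SD / mean x 100.

    Uses the sample SD (n-1 denominator). Requires at least two values and
    a strictly positive mean.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            f"CV needs at least 2 values, got {x.size}"
        )
    m = x.mean()
    if m <= 0:
        raise DomainError(f"CV undefined for non-positive mean ({m})")
    return float(x.std(ddof=1) / m * 100.0)


def asymmetry_index(left_mean: float, right_mean: float) -> float:
    """Log-ratio asymmetry in percent: 100 x |ln(left/right)|.

    Symmetric in its arguments and invariant to a common rescaling of both
    sides; both means must be strictly positive.
    """
    if left_mean <= 0 or right_mean <= 0:
        raise DomainError(
            f"asymmetry needs positive side means, got ({left_mean}, {right_mean})"
        )
    return float(100.0 * abs(np.log(left_mean / right_mean)))


def _trial_variables(trial: pd.DataFrame) -> dict[str, float]:
    """The eight variables for a single trial's steps."""
    feet = trial.groupby("foot")
    side_counts = feet.size()
    for side in ("left", "right"):
        if side_counts.get(side, 0) < 2:
            raise InsufficientDataError(
                f"trial {trial['trial'].iat[0]}: need >= 2 steps per foot, "
                f"got {side_counts.to_dict()}"
            )
    side_step_time = feet["step_time"].mean()
    side_swing_time = feet["swing_time"].mean()
    return {
        "gait_speed": trial["step_velocity"].mean(),
        "step_time": trial["step_time"].mean(),
        "double_support_time": trial["double_support_time"].mean(),
        "step_length_cv": coefficient_of_variation(trial["step_length"]),
        "swing_time_cv": coefficient_of_variation(trial["swing_time"]),
        "step_velocity_cv": coefficient_of_variation(trial["step_velocity"]),
        "step_time_asymmetry": asymmetry_index(
            side_step_time["left"], side_step_time["right"]
        ),
        "swing_time_asymmetry": asymmetry_index(
            side_swing_time["left"], side_swing_time["right"]
        ),
    }


def derive_variables(
    steps: pd.DataFrame, pool_trials: bool = False
) -> pd.Series:
    """Collapse one subject's step records into the eight-variable vector.

    Trial 1 rows are dropped. By default each variable is computed per
    trial (means over steps; CVs over that trial's steps; asymmetries from
    that trial's per-foot means) and the three per-trial values averaged.
    With ``pool_trials=True`` the steps of trials 2-4 are pooled into a
    single computation instead.
    """
    missing = [c for c in STEP_COLUMNS if c not in steps.columns and c != "subject_id"]
    if missing:
        raise SchemaError(f"step table missing required columns: {missing}")
    kept = steps[steps["trial"].isin(ANALYSIS_TRIALS)]
    present = set(kept["trial"].unique())
    absent = [t for t in ANALYSIS_TRIALS if t not in present]
    if absent:
        raise InsufficientDataError(f"missing analysis trials: {absent}")
    if pool_trials:
        pooled = kept.copy()
        pooled["trial"] = 0  # single pseudo-trial
        values = _trial_variables(pooled)
        return pd.Series(values, index=list(GAIT_VARIABLES), dtype=float)
    per_trial = pd.DataFrame(
        [_trial_variables(kept[kept["trial"] == t]) for t in ANALYSIS_TRIALS]
    )
    return per_trial.mean().reindex(list(GAIT_VARIABLES))


def derive_table(
    steps: pd.DataFrame,
    pool_trials: bool = False,
    carry_columns: Iterable[str] = ("group", "stage"),
) -> pd.DataFrame:
    """Per-subject eight-variable table from a multi-subject step table.

    ``carry_columns`` present in the input (e.g. cohort label, H&Y stage)
    are propagated unchanged; they must be constant within a subject.
    """
    if "subject_id" not in steps.columns:
        raise SchemaError("step table missing required columns: ['subject_id']")
    rows = []
    for sid, sub in steps.groupby("subject_id", sort=True):
        row = {"subject_id": sid}
        for col in carry_columns:
            if col in sub.columns:
                vals = sub[col].dropna().unique()
                if len(vals) > 1:
                    raise SchemaError(
                        f"column {col!r} not constant within subject {sid!r}"
                    )
                row[col] = vals[0] if len(vals) else np.nan
        row.update(derive_variables(sub, pool_trials=pool_trials))
        rows.append(row)
    return pd.DataFrame(rows)
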