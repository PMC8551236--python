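"""Synthetic gait cohorts with a three-latent-factor correlation structure.

The published dataset is not deposited, so this module generates cohorts
whose eight-variable marginals match configurable means/SDs (defaults: the
published cohort summary statistics) and whose correlation structure
follows a three-factor model. Subject-level sampling draws, per subject,
three standard-normal latent factor scores; each standardized variable is
``sum_k lambda_vk f_k + u_v eps_v`` and is then rescaled to the target mean
and SD and clipped at a small positive floor. Step-level sampling inverts
the derivation formulas so that the derived variables match the subject's
targets in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference as ref
from .exceptions import ConfigError, GenerationError

#: Swing time as a fraction of step time for generated steps (the swing
#: phase mean is not one of the eight targets; a fixed plausible ratio).
SWING_TO_STEP_RATIO: float = 0.75

#: Familiarisation effect: trial-1 means are shifted by this fraction.
FAMILIARISATION_SHIFT: float = 0.05

#: Default step-to-step noise (CV, %) for fields without a CV target.
TIMING_NOISE_CV: float = 2.0


@dataclass
class GroupSpec:
    """Targets for one cohort: sample size and per-variable mean/SD."""

    n: int
    means: dict[str, float]
    sds: dict[str, float]
    stage: float | None = None  # modified H&Y stage; None for HS

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigError(f"group size must be >= 2, got {self.n}")
        for v in ref.GAIT_VARIABLES:
            if v not in self.means or v not in self.sds:
                raise ConfigError(f"missing mean/SD for variable {v!r}")
            if self.sds[v] <= 0:
                raise ConfigError(f"SD for {v!r} must be > 0, got {self.sds[v]}")
            # gait speed, timings, CVs and asymmetries are all positive scales
            if self.means[v] <= 0:
                raise ConfigError(f"mean for {v!r} must be > 0, got {self.means[v]}")
        if self.stage is not None and self.stage not in ref.VALID_STAGES:
            raise ConfigError(
                f"stage must be one of {ref.VALID_STAGES}, got {self.stage}"
            )


@dataclass
class CohortConfig:
    """Full generator configuration.

    ``loadings`` is the 8x3 latent template on the standardized scale;
    ``unique_sd`` the per-variable specific-noise SD (default: completes
    each variable's standardized variance to 1). ``clip_floor`` is the
    positive floor as a fraction of the group mean (None disables
    clipping, giving exact normal marginals).
    """

    groups: dict[str, GroupSpec]
    loadings: pd.DataFrame = field(default_factory=ref.reference_loadings)
    unique_sd: pd.Series | None = None
    clip_floor: float | None = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.loadings = self.loadings.reindex(list(ref.GAIT_VARIABLES))
        if self.loadings.isna().any().any():
            raise ConfigError("loading template must cover all eight variables")
        if self.unique_sd is None:
            self.unique_sd = ref.unique_sds(self.loadings)
        else:
            self.unique_sd = pd.Series(self.unique_sd).reindex(
                list(ref.GAIT_VARIABLES)
            )
            if self.unique_sd.isna().any() or (self.unique_sd < 0).any():
                raise ConfigError("unique-noise SDs must be >= 0 for all variables")
        for spec in self.groups.values():
            spec.validate()

    def resolved_seed(self) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed)


def _table2_spec(group: str, n: int, stage: float | None = None) -> GroupSpec:
    return GroupSpec(
        n=n,
        means=ref.cohort_means(group).to_dict(),
        sds=ref.cohort_sds(group).to_dict(),
        stage=stage,
    )


def default_config_from_table2(
    n_pd: int = ref.N_PD, n_hs: int = ref.N_HS, seed: int = 0, **kwargs
) -> CohortConfig:
    """Two-group config with the published per-variable means and SDs."""
    return CohortConfig(
        groups={"PD": _table2_spec("PD", n_pd), "HS": _table2_spec("HS", n_hs)},
        seed=seed,
        **kwargs,
    )


def staged_config_from_table2(
    stage_counts: dict[float, int] | None = None, seed: int = 0, **kwargs
) -> CohortConfig:
    """HS plus six stage groups with a monotone severity gradient.

    Per-stage means interpolate between the HS and pooled-PD published
    means with the severity multipliers in ``reference.STAGE_SEVERITY``
    (count-weighted average ~1, so the stage mixture reproduces the pooled
    PD means); SDs interpolate the same way with a floor at half the HS SD.
    The gradient is illustrative: per-stage summary statistics were never
    published.
    """
    if stage_counts is None:
        stage_counts = dict(ref.STAGE_COUNTS)
    hs_mu, hs_sd = ref.cohort_means("HS"), ref.cohort_sds("HS")
    pd_mu, pd_sd = ref.cohort_means("PD"), ref.cohort_sds("PD")
    groups: dict[str, GroupSpec] = {"HS": _table2_spec("HS", ref.N_HS)}
    for stage, n in sorted(stage_counts.items()):
        s = ref.STAGE_SEVERITY[stage]
        mu = hs_mu + s * (pd_mu - hs_mu)
        sd = (hs_sd + s * (pd_sd - hs_sd)).clip(lower=0.5 * hs_sd)
        groups[f"PD_{stage:g}"] = GroupSpec(
            n=n, means=mu.to_dict(), sds=sd.to_dict(), stage=stage
        )
    return CohortConfig(groups=groups, seed=seed, **kwargs)


def sample_subjects(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw one row per subject: id, group, stage and the eight variables.

    Deterministic for a fixed config seed. Per-group sample means and SDs
    converge to the configured targets as n grows (exactly normal when
    ``clip_floor`` is None).
    """
    if rng is None:
        rng = np.random.default_rng(config.resolved_seed())
    lam = config.loadings.to_numpy()  # 8 x 3
    u = config.unique_sd.to_numpy()
    rows = []
    for label, spec in config.groups.items():
        f = rng.standard_normal((spec.n, lam.shape[1]))
        eps = rng.standard_normal((spec.n, lam.shape[0]))
        z = f @ lam.T + eps * u
        mu = np.array([spec.means[v] for v in ref.GAIT_VARIABLES])
        sd = np.array([spec.sds[v] for v in ref.GAIT_VARIABLES])
        x = mu + sd * z
        if config.clip_floor is not None:
            floor = config.clip_floor * np.maximum(mu, 0.0)
            x = np.maximum(x, floor)
        for i in range(spec.n):
            row = {
                "subject_id": f"{label}_{i:04d}",
                "group": label,
                "stage": spec.stage if spec.stage is not None else np.nan,
            }
            row.update(dict(zip(ref.GAIT_VARIABLES, x[i])))
            rows.append(row)
    return pd.DataFrame(rows)


def _side_means(center: float, asymmetry_pct: float) -> tuple[float, float]:
    """Left/right means with 100|ln(L/R)| equal to the target asymmetry.

    Multiplicative offsets e^(+-a/200) preserve the geometric mean and
    invert the log-ratio formula exactly.
    """
    if asymmetry_pct < 0 or not np.isfinite(asymmetry_pct):
        raise GenerationError(f"invalid asymmetry target {asymmetry_pct}")
    left = center * np.exp(asymmetry_pct / 200.0)
    right = center * np.exp(-asymmetry_pct / 200.0)
    if not (np.isfinite(left) and left > 0 and right > 0):
        raise GenerationError(
            f"asymmetry target {asymmetry_pct}% yields non-positive side mean"
        )
    return left, right


def _within_sd(total_cv_pct: float, center: float, side_means: tuple[float, float]) -> float:
    """Within-side step SD so the pooled per-trial CV hits its target.

    The pooled variance across both feet contains a between-side component
    from the asymmetry offset; the within-side noise is reduced to
    compensate (floored at 0 when the offset alone exceeds the target).
    """
    target_var = (total_cv_pct / 100.0 * center) ** 2
    m = np.mean(side_means)
    between = np.mean([(s - m) ** 2 for s in side_means])
    return float(np.sqrt(max(target_var - between, 0.0)))


def sample_steps(
    subject: pd.Series,
    steps_per_trial: int = 7,
    timing_noise_cv: float = TIMING_NOISE_CV,
    familiarisation_shift: float = FAMILIARISATION_SHIFT,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Four trials of alternating left/right steps for one subject.

    ``subject`` holds the eight variable targets (plus id/group columns).
    Steps carry per-step noise sized so the derived CVs match their
    targets, side means offset so the derived asymmetries match, and a
    trial-1 mean shift so the familiarisation-discard rule is observable.
    """
    if not 6 <= steps_per_trial <= 8:
        raise ConfigError(f"steps_per_trial must be in [6, 8], got {steps_per_trial}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    t_step = float(subject["step_time"])
    t_dst = float(subject["double_support_time"])
    v_mean = float(subject["gait_speed"])
    if min(t_step, t_dst, v_mean) <= 0:
        raise GenerationError("timing/speed targets must be positive")
    t_swing = SWING_TO_STEP_RATIO * t_step
    l_mean = v_mean * t_step  # step length consistent with speed and cadence

    st_sides = _side_means(t_step, float(subject["step_time_asymmetry"]))
    sw_sides = _side_means(t_swing, float(subject["swing_time_asymmetry"]))
    sw_within = _within_sd(float(subject["swing_time_cv"]), t_swing, sw_sides)
    st_within = timing_noise_cv / 100.0 * t_step
    records = []
    for trial in range(1, 5):
        shift = 1.0 + familiarisation_shift if trial == 1 else 1.0
        for step in range(1, steps_per_trial + 1):
            side = "left" if step % 2 == 1 else "right"
            idx = 0 if side == "left" else 1
            st = rng.normal(st_sides[idx] * shift, st_within * shift)
            sw = rng.normal(sw_sides[idx] * shift, sw_within * shift)
            dst = rng.normal(t_dst * shift, timing_noise_cv / 100.0 * t_dst * shift)
            ln = rng.normal(
                l_mean * shift, float(subject["step_length_cv"]) / 100.0 * l_mean * shift
            )
            vel = rng.normal(
                v_mean * shift, float(subject["step_velocity_cv"]) / 100.0 * v_mean * shift
            )
            records.append(
                {
                    "subject_id": subject.get("subject_id", "s0"),
                    "trial": trial,
                    "step": step,
                    "foot": side,
                    "step_time": max(st, 0.01 * t_step),
                    "swing_time": max(sw, 0.01 * t_swing),
                    "double_support_time": max(dst, 0.01 * t_dst),
                    "step_length": max(ln, 0.01 * l_mean),
                    "step_velocity": max(vel, 0.01 * v_mean),
                }
            )
    return pd.DataFrame(records)


def sample_cohort_steps(
    config: CohortConfig, steps_per_trial: int = 7, **step_kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject table plus a full step-level table for every subject.

    One root seed; each subject's step stream is an independent child of
    the config's seed sequence, so the output is reproducible and
    insensitive to subject order.
    """
    root = config.resolved_seed()
    children = root.spawn(2)
    subjects = sample_subjects(config, rng=np.random.default_rng(children[0]))
    step_seeds = children[1].spawn(len(subjects))
    frames = []
    for (_, row), ss in zip(subjects.iterrows(), step_seeds):
        steps = sample_steps(
            row,
            steps_per_trial=steps_per_trial,
            rng=np.random.default_rng(ss),
            **step_kwargs,
        )
        steps.insert(1, "group", row["group"])
        steps.insert(2, "stage", row["stage"])
        frames.append(steps)
    return subjects, pd.concat(frames, ignore_index=True)
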