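"""Shared fixtures: small deterministic cohorts and step tables."""

import numpy as np
import pandas as pd
import pytest

from pdgait import reference as ref
from pdgait import synthetic_cohort as sc
from pdgait.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def staged_bundle(tmp_path_factory):
    """One full pipeline run on the default staged synthetic cohort."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = PipelineConfig(seed=42, outdir=str(outdir))
    return run_pipeline(config)


@pytest.fixture(scope="session")
def small_subjects():
    """Two-group subject table, n = 150/60, fixed seed."""
    config = sc.default_config_from_table2(n_pd=150, n_hs=60, seed=7)
    return sc.sample_subjects(config)


@pytest.fixture()
def symmetric_steps():
    """Perfectly periodic, side-symmetric 4-trial step table."""
    rows = []
    for trial in range(1, 5):
        for step in range(1, 8):
            rows.append(
                {
                    "subject_id": "s1",
                    "trial": trial,
                    "step": step,
                    "foot": "left" if step % 2 else "right",
                    "step_time": 0.5,
                    "swing_time": 0.4,
                    "double_support_time": 0.25,
                    "step_length": 60.0,
                    "step_velocity": 120.0,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def pd_subject_row():
    """A subject at the published pooled-PD variable means."""
    row = {"subject_id": "pd0", "group": "PD"}
    row.update(ref.cohort_means("PD"))
    return pd.Series(row)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
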