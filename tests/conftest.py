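"""Shared fixtures: small synthetic cohorts and a session-scoped fitted model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from healthexpect import MultistateLogitModel
from healthexpect.markov import StepParams, TransitionCoefficients
from healthexpect.simulate import SimulationConfig, WaveSchedule, generate_cohort, recovery_true_model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def true_model_quarter():
    return recovery_true_model(0.25)


@pytest.fixture(scope="session")
def small_cohort(true_model_quarter):
    """A 600-person cohort with ground truth (quarter-year step)."""
    cfg = SimulationConfig(n=600, seed=7, true_model=true_model_quarter)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def fitted_model(true_model_quarter):
    """Model fitted to a 2,500-person synthetic cohort (loneliness covariate)."""
    cfg = SimulationConfig(n=2500, seed=11, true_model=true_model_quarter)
    _, truth = generate_cohort(cfg)
    model = MultistateLogitModel(h=0.25, covariates=("lonely",))
    model.fit(truth["episodes_adl"])
    return model


def homogeneous_coeffs(
    logits=(-2.0, -3.0, -1.5, -2.5), h: float = 1.0, age_cap: float = 110.0
) -> TransitionCoefficients:
    """Age-constant chain: handy for closed-form oracles."""
    coef = np.asarray(logits, dtype=float)[:, None]
    return TransitionCoefficients(
        coef=coef, covariates=(), step=StepParams(h=h, age_cap=age_cap), age_slope=False
    )


def episodes_frame(rows) -> pd.DataFrame:
    """Build an episode table from (age_start, state_start, elapsed, end_state) tuples."""
    recs = []
    for i, (age0, j, elapsed, k) in enumerate(rows):
        recs.append(
            dict(
                id=i,
                age_start=age0,
                state_start=j,
                elapsed=elapsed,
                end_state=k,
                death_age=age0 + elapsed if k == 3 else np.nan,
                lonely=0,
                weight=1.0,
            )
        )
    return pd.DataFrame(recs)
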