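"""Shared fixtures.

The scaled cohort runs (12 subjects, reduced epochs) are session-scoped:
they back both the end-to-end sanity tests and the learning/standardization
properties, and are built once per session.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from gaitpress import simulate as sim
from gaitpress.pipeline import (ExperimentConfig, run_closed_set,
                                run_open_set, simulate_and_preprocess)

# 20 CNN epochs: training on this cohort converges by ~epoch 20, so the
# scaled runs stop there instead of the full 50-epoch budget.
SCALED_CONFIG = ExperimentConfig(
    n_subjects=12,
    unit_steps_per_round=20,
    epochs=20,
    ae_epochs=40,
    unknown_subjects=(2, 7, 11),
    seed=1,
)

CONTROL_CONFIG = dataclasses.replace(
    SCALED_CONFIG, identical_templates=True, epochs=6, ae_epochs=20
)


@pytest.fixture(scope="session")
def small_cohort() -> list[sim.SubjectProfile]:
    return sim.generate_cohort(4, {3: 1, 4: 1, 7: 1, 10: 1}, seed=11)


@pytest.fixture(scope="session")
def quiet_walk(small_cohort) -> sim.PressureFrameSequence:
    """Noise- and anomaly-free 4-step walk."""
    return sim.simulate_walk(
        small_cohort[0], sim.WalkCondition(), n_steps=4,
        noise_sd=0.0, anomaly_rate=0.0, seed=5,
    )


@pytest.fixture(scope="session")
def scaled_run() -> dict:
    """Distinct-template 12-subject cohort: closed and open-set reports."""
    cfg = SCALED_CONFIG
    maps = simulate_and_preprocess(cfg)
    return {
        "config": cfg,
        "maps": maps,
        "closed": run_closed_set(cfg, maps),
        "open": run_open_set(cfg, maps),
    }


@pytest.fixture(scope="session")
def control_run() -> dict:
    """Identical-template control: identity should be unlearnable."""
    cfg = CONTROL_CONFIG
    maps = simulate_and_preprocess(cfg)
    return {
        "config": cfg,
        "maps": maps,
        "closed": run_closed_set(cfg, maps),
        "open": run_open_set(cfg, maps),
    }
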