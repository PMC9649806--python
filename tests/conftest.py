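import numpy as np
import pandas as pd
import pytest

from osteosim.experiment import (ExperimentConfig, apply_reading_noise,
                                 simulate_cohort)
from osteosim.frame import build_frame
from osteosim.synthetic import SubjectParams, build_prism_fixture, build_tibia

RECT_60x50 = [(-30.0, -25.0), (30.0, -25.0), (30.0, 25.0), (-30.0, 25.0)]
# anteromedial corner cut away and posterior side wider: a triangular-
# tending section like a proximal tibia (x<0 = medial, y>0 = anterior)
ASYM_POLY = [(-20.0, 14.0), (-34.0, -8.0), (-26.0, -24.0), (16.0, -26.0),
             (32.0, -12.0), (30.0, 14.0), (6.0, 22.0)]


@pytest.fixture(scope="session")
def default_params() -> SubjectParams:
    return SubjectParams("S01", 9.0, 10.3, 1.0, 74.0, 47.0, 41.0, 300.0,
                         shape_seed=7)


@pytest.fixture(scope="session")
def default_model(default_params):
    return build_tibia(default_params)


@pytest.fixture(scope="session")
def default_frame(default_model):
    frame, _ = build_frame(default_model)
    return frame


@pytest.fixture(scope="session")
def rect_prism():
    return build_prism_fixture(RECT_60x50, length=250.0, pts=9.0)


@pytest.fixture(scope="session")
def asym_prism():
    return build_prism_fixture(ASYM_POLY, length=250.0, pts=9.0)


@pytest.fixture(scope="session")
def full_experiment():
    """The full 30 x 13 default experiment at seed 1 (shared by the
    acceptance tests; ~1 minute)."""
    cfg = ExperimentConfig(seed=1)
    outcomes = simulate_cohort(cfg)
    table = apply_reading_noise(outcomes, cfg)
    return cfg, outcomes, table


def make_lmm_table(slope: float, tau: float = 0.3, sd: float = 0.3,
                   n: int = 30, rho: float = 0.0,
                   seed: int = 0) -> pd.DataFrame:
    """Self-generated mixed-model data for parameter-recovery tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n):
        b = rng.normal(0.0, tau)
        e = 0.0
        for a in range(0, 31, 5):
            e = rho * e + rng.normal(0.0, sd * np.sqrt(1.0 - rho ** 2))
            rows.append({"subject_id": f"S{s:02d}", "inclination_deg": a,
                         "pts_deg": 9.0 + b + slope * a + e,
                         "pts_change_deg": b + slope * a + e})
    return pd.DataFrame(rows)
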