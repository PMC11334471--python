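"""Shared fixtures: analytic pH curves and a small simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest

from backslop.io_formats import PHTimeCourse
from backslop.synthetic_data import Cohort, SimConfig, generate_cohort

FIVE_MIN_H = 1.0 / 12.0


def piecewise_curve(
    lag_h: float = 2.0,
    slope: float = -0.4,
    plateau: float = 4.3,
    ph0: float = 6.7,
    duration_h: float = 18.0,
    dt_h: float = FIVE_MIN_H,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    lineage_id: str = "L1",
    step: str = "F2",
) -> PHTimeCourse:
    """Flat at ph0 until the lag, linear drop at `slope`, flat at `plateau`."""
    t = np.arange(0.0, duration_h + dt_h / 2, dt_h)
    ph = np.clip(ph0 + slope * np.clip(t - lag_h, 0.0, None), plateau, ph0)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        ph = ph + rng.normal(0.0, noise_sd, ph.shape)
    return PHTimeCourse(lineage_id, step, t, np.clip(ph, 0.0, 14.0))


@pytest.fixture
def make_piecewise():
    return piecewise_curve


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Six lineages (two per archetype), default dynamics, fixed seed."""
    cfg = SimConfig(n_lineages=6, archetype_mix=(1 / 3, 1 / 3, 1 / 3), seed=123)
    return generate_cohort(cfg)
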