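"""Shared fixtures: down-scaled tissue runs reused across the suite.

All tissue fixtures use the toy-plane conventions (proportional probes,
stimulus charge-per-area preserved) at dt = 10 us unless a finer step is
required by the stability bound.
"""

import numpy as np
import pytest

from atriasim import (NumericsConfig, StimulusProtocol, TissueGeometry,
                      baseline_parameters, biomarkers_from_result,
                      conduction_velocity, get_drug, run_simulation,
                      toy_plane)


@pytest.fixture(scope="session")
def toy20():
    """Baseline 20x20 plane, 0% fibrosis, 2 beats."""
    bundle = toy_plane(20, 20, fraction=0.0, seed=0, n_pulses=2)
    result = run_simulation(bundle.geometry, protocol=bundle.protocol,
                            numerics=bundle.numerics)
    return bundle, result, biomarkers_from_result(result)


@pytest.fixture(scope="session")
def toy20_drug_runs(toy20):
    bundle, _, _ = toy20
    out = {}
    for name in ("sotalol", "amiodarone"):
        out[name] = run_simulation(bundle.geometry, drug=get_drug(name),
                                   protocol=bundle.protocol,
                                   numerics=bundle.numerics)
    return out


@pytest.fixture(scope="session")
def strip_cv_vs_diffusion():
    """CV on a 1D-like strip at D and 2D, same (finer) step for both."""
    from dataclasses import replace
    base = baseline_parameters()
    geom = TissueGeometry(nx=60, ny=3, fibrosis_fraction=0.0)
    proto = StimulusProtocol.scaled(60, n_pulses=2)
    num = NumericsConfig.for_diffusion(2.0 * base.diffusion)
    cvs = {}
    for mult in (1.0, 2.0):
        res = run_simulation(geom,
                             params=replace(base,
                                            diffusion=mult * base.diffusion),
                             protocol=proto, numerics=num)
        cvs[mult] = conduction_velocity(res)
    return cvs


@pytest.fixture(scope="session")
def toy20_cv_vs_dt(toy20):
    """CV on the 20x20 toy plane at dt = 10 us and dt = 5 us."""
    bundle, res10, bm10 = toy20
    res5 = run_simulation(bundle.geometry, protocol=bundle.protocol,
                          numerics=NumericsConfig(dt_us=5.0))
    return {10.0: bm10.cv, 5.0: conduction_velocity(res5)}


@pytest.fixture(scope="session")
def fibrosis_cv_by_seed():
    """Mean CV at 0% vs 5% fibrosis over 10 mask seeds (16x16 plane)."""
    proto = StimulusProtocol.scaled(16, n_pulses=2)
    cv0 = conduction_velocity(
        run_simulation(TissueGeometry(nx=16, ny=16), protocol=proto))
    cv5 = []
    for seed in range(10):
        g = TissueGeometry(nx=16, ny=16, fibrosis_fraction=0.05,
                           mask_seed=seed)
        cv5.append(conduction_velocity(run_simulation(g, protocol=proto)))
    return cv0, cv5


@pytest.fixture(scope="session")
def paced_cell_trace():
    """Isolated myocyte paced 4 beats at 1 Hz, full-resolution trace."""
    from atriasim import simulate_single_myocyte
    t, v, res = simulate_single_myocyte(
        protocol=StimulusProtocol(n_pulses=4, stim_cols=2, amplitude=20.0),
        numerics=NumericsConfig(record_stride=10),
        duration_ms=4000.0)
    return t, v, res
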