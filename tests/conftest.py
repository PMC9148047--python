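"""Shared fixtures: one coarse setup for fast unit checks and one
characterization-resolution pipeline reused by the slower end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coaxtherm import (
    ApplicatorGeometry,
    Controller,
    GridSpec,
    NoiseModel,
    PowerSchedule,
    ProbeLayout,
    RunControl,
    SourceSpec,
    ThermalModel,
    build_material_map,
    cooling_phase,
    run_transient,
    scale_loss,
)
from coaxtherm.study import (
    experiment_focus,
    experiment_steady_state,
    prototype_solution,
    run_sweep,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: coarse, fast grid for unit-level EM checks (padding shrunk accordingly)
FAST_GRID = GridSpec(fine_mm=2.0, device_mm=3.0, coarse_mm=12.0, min_layer_cells=1)
#: characterization resolution used by the end-to-end checks
CHAR_GRID = GridSpec(fine_mm=1.0, device_mm=2.0, coarse_mm=10.0)

PROBE_POINTS = ProbeLayout().as_dict()


@pytest.fixture(scope="session")
def fast_geometry():
    return ApplicatorGeometry.prototype(domain_padding=6.0)


@pytest.fixture(scope="session")
def fast_map(fast_geometry):
    return build_material_map(fast_geometry, FAST_GRID)


@pytest.fixture(scope="session")
def fast_solution(fast_map):
    from coaxtherm import run_fdtd

    return run_fdtd(fast_map, SourceSpec(), RunControl())


@pytest.fixture(scope="session")
def proto():
    """Prototype EM solve at characterization resolution (reused widely)."""
    return prototype_solution(grid=CHAR_GRID)


@pytest.fixture(scope="session")
def transient_runs(proto):
    """40-min heating at 2.5/3/3.6 W plus 10-min cooling for the 3.6 W case."""
    model = proto.model(21.5)
    runs = {}
    for level in (2.5, 3.0, 3.6):
        loss = scale_loss(proto.loss, level)
        series = run_transient(
            proto.map, loss, PowerSchedule.constant(level, 2400.0),
            probe_points=PROBE_POINTS, model=model,
        )
        if level == 3.6:
            series = cooling_phase(series, 600.0, model)
        runs[level] = series
    return runs


@pytest.fixture(scope="session")
def steady_run(proto):
    """Closed-loop 43 degC maintenance, 12 min."""
    return experiment_steady_state(proto, target_C=43.0, duration=720.0)


@pytest.fixture(scope="session")
def focus_run(proto):
    """5 W / 5 min heating-focus experiment with 3-min IR delay."""
    return experiment_focus(proto, power=5.0, heat_duration=300.0, delay=180.0,
                            noise=NoiseModel(seed=1))


@pytest.fixture(scope="session")
def sweep_table():
    """The 12-combination design sweep at sweep resolution."""
    return run_sweep(grid=GridSpec(fine_mm=1.0, device_mm=2.0, coarse_mm=10.0))
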