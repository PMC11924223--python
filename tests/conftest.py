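"""Shared fixtures: benchmark topologies and cached expensive runs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from evbkit import (
    DiabaticState,
    EVBTopology,
    SamplerParams,
    accumulate_fep,
    builtin_scenario,
    make_schedule,
    sample_all_windows,
)
from evbkit.pipeline import calibrate_scenario


def marcus_topology(
    dG0: float = 0.0,
    H: float = 0.0,
    f: float = 200.0,
    d: float = 1.0,
    temperature: float = 300.0,
) -> EVBTopology:
    """Two displaced equal-f harmonic diabats: lambda_reorg = f*d^2/2."""
    return EVBTopology(
        states=(
            DiabaticState(id="r", role="reactant", x0=0.0, f=f),
            DiabaticState(id="p", role="product", x0=d, f=f),
        ),
        alpha=(0.0, dG0),
        coupling=((0.0, H), (H, 0.0)),
        temperature=temperature,
    )


def scan_features(topology: EVBTopology, lo: float, hi: float, n: int = 40001):
    """Deterministic oracle: dense scan of the coupled ground surface.

    Returns (barrier, dG0) relative to the reactant-side minimum; None if
    the surface has fewer than two local minima.
    """
    from evbkit import adiabatic_ground

    xs = np.linspace(lo, hi, n)
    eg = adiabatic_ground(topology, xs, active=(0, 1))
    mins = [
        i for i in range(1, n - 1) if eg[i] < eg[i - 1] and eg[i] < eg[i + 1]
    ]
    if len(mins) < 2:
        return None
    i1, i2 = mins[0], mins[-1]
    bar = float(eg[i1 : i2 + 1].max())
    return bar - float(eg[i1]), float(eg[i2]) - float(eg[i1])


@pytest.fixture(scope="session")
def marcus_run():
    """One sampled replicate of the symmetric Marcus benchmark (H = 0)."""
    topo = marcus_topology()
    sched = make_schedule("dissociative", 101)
    trajs = sample_all_windows(topo, sched, SamplerParams(), master_seed=42)
    fep = accumulate_fep(trajs, sched, topo)
    return topo, sched, trajs, fep


@pytest.fixture(scope="session")
def water_diss_calibration():
    """Calibrated water dissociative reference (ensemble fit, n = 10)."""
    spec = builtin_scenario("water_dissociative")
    spec = dataclasses.replace(spec, master_seed=2026)
    return calibrate_scenario(spec)


@pytest.fixture(scope="session")
def water_assoc_calibration():
    """Calibrated water associative reference (ensemble fit, n = 10)."""
    spec = builtin_scenario("water_associative")
    spec = dataclasses.replace(spec, master_seed=2026)
    return calibrate_scenario(spec)
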