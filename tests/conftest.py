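"""Shared fixtures: materials, small systems, and session-scoped scenario
runs (the expensive coupled simulations are run once and interrogated by
many tests)."""

from __future__ import annotations

import numpy as np
import pytest

from rootflow3d.root_architecture import RootSystem
from rootflow3d.soil_hydraulics import default_materials


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def soil(materials):
    return materials["soil"]


@pytest.fixture
def single_segment_system():
    """One vertical 1 cm segment below the collar."""
    return RootSystem(
        pos=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -1.0]]),
        parent=[-1, 0], radius=[0.0, 0.05], order=[0, 0],
        t_s=[-np.inf, 0.0], branch=[-1, 0])


@pytest.fixture
def two_segment_chain():
    """Collar -> node1 -> node2 vertical chain, 1 cm segments."""
    return RootSystem(
        pos=np.array([[0, 0, 0], [0, 0, -1.0], [0, 0, -2.0]]),
        parent=[-1, 0, 1], radius=[0, 0.05, 0.04], order=[0, 0, 0],
        t_s=[-np.inf, 0.0, 1.0], branch=[-1, 0, 0])


def random_tree(rng: np.random.Generator, n_nodes: int) -> RootSystem:
    """Random collar-rooted tree with jittered geometry for solver tests."""
    parent = [-1]
    pos = [np.zeros(3)]
    for j in range(1, n_nodes):
        p = int(rng.integers(0, j))
        d = rng.normal(size=3)
        d[2] = -abs(d[2]) - 0.2
        d /= np.linalg.norm(d)
        step = rng.uniform(0.2, 1.0)
        pos.append(pos[p] + d * step)
        parent.append(p)
    n = n_nodes
    return RootSystem(
        pos=np.array(pos), parent=np.array(parent),
        radius=np.r_[0.0, rng.uniform(0.02, 0.1, n - 1)],
        order=np.r_[0, rng.integers(0, 2, n - 1)],
        t_s=np.r_[-np.inf, np.sort(rng.uniform(0, 10, n - 1))],
        branch=np.r_[-1, np.zeros(n - 1, int)])


@pytest.fixture(scope="session")
def reduced_runs():
    """CD / NC / SC coupled runs of the desk-scale virtual experiment
    (hydrostatic-equilibrium column, 10 days, 14x14x43 voxels).

    Session-scoped: these three simulations back the conservation,
    compartment-ledger, scenario-contrast and predawn analyses."""
    from rootflow3d.experiment import run_scenario
    from rootflow3d.synthetic import generate_reduced_experiment

    ve = generate_reduced_experiment("NoSplit", seed=3)
    return {
        "bundle": ve,
        "CD": run_scenario(ve.scenario("CD")),
        "NC": run_scenario(ve.scenario("NC")),
        "SC": run_scenario(ve.scenario("SC")),
    }
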