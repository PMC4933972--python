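"""Shared fixtures: docked dimers, membranes and Brownian runs are expensive
to build, so they are session-scoped and reused across test modules."""
import numpy as np
import pytest

from helixpack import lipids, synthetic


@pytest.fixture(scope="session")
def ideal_helix():
    return synthetic.build_ideal_helix()


@pytest.fixture(scope="session")
def dimer_fixtures():
    """The three interface-state fixtures, docked once at a fixed seed."""
    return {name: synthetic.build_dimer_fixture(name, seed=0)
            for name in synthetic.DIMER_STATES}


@pytest.fixture(scope="session")
def iso_mutant(dimer_fixtures):
    return synthetic.apply_mutation_A183I(dimer_fixtures["iso_parallel"])


@pytest.fixture(scope="session")
def brownian_run():
    """100 lipids, 5000 stored frames at 10 ps: the diffusion-recovery
    study condition.  Returns (centered trajectory, table, params)."""
    comp = synthetic.MembraneComposition({"PC": 0.5, "CL": 0.5})
    membrane, table = synthetic.build_membrane(comp, n_lipids=100,
                                               box_xy=110.0, seed=11)
    params = synthetic.BrownianParams(
        diffusion={"PC": 0.05, "CL": 0.03}, timestep=10.0, n_steps=5000,
        seed=12,
    )
    traj = synthetic.simulate_lipid_trajectory(membrane, table, params)
    centered = lipids.center_and_dewrap(traj, np.ones(traj.n_atoms, bool))
    return centered, table, params


@pytest.fixture(scope="session")
def enrichment_runs(dimer_fixtures):
    """Paired CL-biased / unbiased membrane runs around the dimer."""
    membrane, table = synthetic.build_membrane(n_lipids=200, box_xy=150.0,
                                               seed=21)
    protein = dimer_fixtures["intersected"].copy()
    protein.coords[:, :2] += 75.0
    out = {}
    for label, bias in (("unbiased", 0.0), ("biased", 0.02)):
        params = synthetic.BrownianParams(
            timestep=10.0, n_steps=1500, enrichment_bias={"CL": bias},
            seed=22,
        )
        traj = synthetic.simulate_lipid_trajectory(
            membrane, table, params, protein=protein, box_xy=150.0)
        out[label] = lipids.center_and_dewrap(traj, {"chain": ["A", "B"]})
    return out, table
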