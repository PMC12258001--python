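"""Shared fixtures: a small phantom and plans built once per session."""

import numpy as np
import pytest

import csgarc as cg


def make_simple_plan(energies, gantry_start=-180.0, resolution=10.0,
                     mu=1.0, configs=None):
    """Hand-built plan: one OFF config and one spot of ``mu`` MU per CP."""
    cps = []
    for i, e in enumerate(energies):
        cfg = configs[i] if configs else cg.off_config(f"cp{i}_off")
        mu_i = mu[i] if isinstance(mu, (list, tuple)) else mu
        cps.append(cg.ControlPoint(
            index=i, gantry_deg=gantry_start + i * resolution, energy_mev=e,
            spots=(cg.Spot(f"cp{i}_s0", 0.0, 0.0, mu_i, cfg.id),),
            configs=(cfg,),
        ))
    return cg.ArcPlan(control_points=tuple(cps), arc_resolution_deg=resolution)


@pytest.fixture(scope="session")
def machine():
    return cg.MachineModel()


@pytest.fixture(scope="session")
def phantom():
    return cg.make_phantom(cg.desk_scale_spec())


@pytest.fixture(scope="session")
def baseline_plan(phantom):
    """A small optimized arc plan shared by the dose/pipeline tests."""
    return cg.make_baseline_plan(phantom, n_positions=25, seed=7)


@pytest.fixture(scope="session")
def structural_plan(phantom):
    """Unoptimized (uniform-weight) plan for cheap structural checks."""
    return cg.make_baseline_plan(phantom, n_positions=13, seed=11,
                                 optimize=False)
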