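"""Shared fixtures; the heavy forward runs are session-scoped so unit and
acceptance tests reuse the same simulations."""

from __future__ import annotations

import numpy as np
import pytest

from osteofrac.fem import FEModel, LoadProgram, run_simulation
from osteofrac.geometry import build_strip
from osteofrac.materials import (
    PhaseFieldConfig,
    TissueParams,
    baseline_tissue_params,
)


@pytest.fixture(scope="session")
def baseline():
    return baseline_tissue_params()


def make_bar(E=15000.0, nu=0.3, Gc=0.35, ell=0.05, h=None, width=0.5, height=1.0):
    """Homogeneous plane-strain bar in vertical tension, lateral free."""
    h = h or ell / 4.0
    mat = TissueParams("matrix", E, nu, Gc)
    mesh = build_strip(width=width, height=height, h_fine=h, ell=ell)
    model = FEModel(
        mesh=mesh, tissues={"matrix": mat}, pf=PhaseFieldConfig(ell=ell), thickness=1.0
    )
    return model, mat


@pytest.fixture(scope="session")
def bar_strength_run():
    """Bar loaded past its homogeneous AT1 strength; shared by the analytic
    strength check and the energy-balance suite."""
    E, nu, Gc, ell = 15000.0, 0.3, 0.35, 0.05
    model, mat = make_bar(E, nu, Gc, ell)
    Eeff = E / (1.0 - nu**2)
    eps_c = np.sqrt(3.0 * Gc / (8.0 * ell * Eeff))
    program = LoadProgram(
        du_initial=eps_c / 200.0,
        u_max=1.25 * eps_c,
        max_steps=400,
        stop_force_fraction=0.5,
        record_every=20,
    )
    hist = run_simulation(model, program)
    return {
        "model": model,
        "history": hist,
        "E": E,
        "nu": nu,
        "Gc": Gc,
        "ell": ell,
        "area": 0.5,
    }


@pytest.fixture(scope="session")
def desk_screening_result():
    """The full 54-run screening design at the desk scale (minutes)."""
    from osteofrac.studies import run_screening_study

    design, outcomes, tables = run_screening_study()
    return design, outcomes, tables


@pytest.fixture(scope="session")
def closed_loop_result():
    """Noise-free pseudo-experiment at (0.36, 0.14) plus the full
    response-surface + calibration pipeline on the same microstructure."""
    from osteofrac.studies import (
        apply_factors,
        calibrate_toughness,
        desk_senb_preset,
        run_response_surface_study,
        senb_outcomes,
    )
    from osteofrac.synthetic import generate_pseudo_experiment

    preset = desk_senb_preset(seed=3)
    micro = preset.build_microstructure()
    mesh = preset.build_mesh(micro)

    def forward(params):
        out = senb_outcomes(apply_factors(params), preset, mesh, micro)
        return {
            "peak_force": out["peak_force"],
            "tortuosity": out["tortuosity"],
            "J_Ic": out["J_Ic"],
        }

    pseudo = generate_pseudo_experiment(
        forward, {"Gc_mat": 0.36, "Gc_cem": 0.14}, noise_cv=0.0, seed=1
    )
    design, outcomes, tables, surfaces = run_response_surface_study(preset)
    result = calibrate_toughness(surfaces, pseudo.observed, grid_step=0.01)
    return {
        "pseudo": pseudo,
        "design": design,
        "outcomes": outcomes,
        "tables": tables,
        "surfaces": surfaces,
        "calibration": result,
    }
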