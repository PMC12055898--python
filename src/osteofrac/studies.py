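"""Study orchestration: screening, response-surface and validation stages.

This module wires the pieces together the way the study design uses them:

* the six-factor screening on the notched single-osteon cell (outcomes:
  peak force with the canal-truncation rule, crack tortuosity in the
  horizontal convention, energy release per unit crack advance), followed
  by Type-II ANOVA variance shares;
* the four-factor response-surface stage on an SENB beam with an embedded
  synthetic microstructure window (outcomes: peak force, tortuosity in the
  vertical convention, J_Ic), linear surfaces in the matrix and
  cement-line toughness, and the normalised-absolute-error calibration;
* forward evaluation helpers shared by the command-line stages and the
  calibration-recovery tests.

Presets define the problem sizes actually run.  ``fine`` presets use the
reference resolution (1.25 um elements, ell = 2.5 um); ``desk`` presets
are geometrically identical but coarser (thicker cement line so it stays
resolved by two elements) so a full design fits in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .doe import (
    FactorSpec,
    anova_tss,
    box_behnken,
    calibrate,
    fit_response_surface,
    run_design,
)
from .fem import FEModel, LoadProgram, Mesh, SolverTolerances, run_simulation
from .geometry import (
    Microstructure,
    SENBSpec,
    SingleOsteonSpec,
    build_senb,
    build_single_osteon,
)
from .materials import PhaseFieldConfig, baseline_tissue_params
from .postprocess import (
    detect_canal_entry,
    energy_release_per_advance,
    extract_crack_path,
    peak_force,
    tortuosity,
    toughness,
)
from .synthetic import MicrostructureRecipe, generate_microstructure

__all__ = [
    "ScreeningPreset",
    "SENBPreset",
    "desk_screening_preset",
    "fine_screening_preset",
    "desk_senb_preset",
    "screening_factors",
    "response_surface_factors",
    "apply_factors",
    "screening_outcomes",
    "senb_outcomes",
    "run_screening_study",
    "run_response_surface_study",
]

SCREENING_FACTOR_NAMES = ("E_mat", "E_ost", "E_cem", "Gc_mat", "Gc_ost", "Gc_cem")
RESPONSE_FACTOR_NAMES = ("E_cem", "Gc_mat", "Gc_ost", "Gc_cem")


# ----------------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningPreset:
    """Single-osteon cell geometry + discretisation + load schedule."""

    spec: SingleOsteonSpec
    h_fine: float
    ell: float
    program: LoadProgram

    def build_mesh(self) -> Mesh:
        return build_single_osteon(self.spec, self.h_fine, ell=self.ell)


@dataclass(frozen=True)
class SENBPreset:
    """SENB beam + microstructure recipe + discretisation + load schedule."""

    spec: SENBSpec
    recipe: MicrostructureRecipe
    h_fine: float
    ell: float
    corridor_width: float
    program: LoadProgram

    def build_microstructure(self, seed: int | None = None) -> Microstructure:
        recipe = self.recipe if seed is None else replace(self.recipe, seed=seed)
        rx, ry = self.spec.window_half_axes
        cx, cy = self.spec.window_center
        kind = self.spec.window[0]
        region = (
            ("circle", cx, cy, rx) if kind == "circle" else ("ellipse", cx, cy, rx, ry)
        )
        return generate_microstructure(recipe, region)

    def build_mesh(self, micro: Microstructure) -> Mesh:
        return build_senb(
            self.spec,
            micro,
            self.h_fine,
            ell=self.ell,
            corridor_width=self.corridor_width,
        )


def fine_screening_preset() -> ScreeningPreset:
    """Reference-resolution screening cell (ell = 0.5 t_cem = 2.5 um)."""
    return ScreeningPreset(
        spec=SingleOsteonSpec(),
        h_fine=0.00125,
        ell=0.0025,
        program=LoadProgram(
            du_initial=5e-5,
            u_max=0.05,
            max_steps=2000,
            stop_force_fraction=0.05,
            stop_crack_fraction=0.92,
            record_every=5,
        ),
    )


def desk_screening_preset() -> ScreeningPreset:
    """Coarsened screening cell for batch designs on one CPU.

    Same 400 um cell, osteon and notch; the cement line is thickened to
    15 um so it stays two elements wide at h = 7.5 um with ell = 15 um.
    """
    return ScreeningPreset(
        spec=SingleOsteonSpec(t_cem=0.015),
        h_fine=0.0075,
        ell=0.015,
        program=LoadProgram(
            du_initial=2e-4,
            du_refined=5e-5,
            u_max=0.05,
            max_steps=600,
            stop_force_fraction=0.05,
            stop_crack_fraction=0.92,
            record_every=5,
        ),
    )


def desk_senb_preset(seed: int = 0) -> SENBPreset:
    """Reduced SENB model with a synthetic embedded-cell window.

    A quarter-scale beam (height 0.8 mm, span 3.2 mm = 4 h, notch depth
    0.34 mm, i.e. the a/h of the response-surface specimen) with scaled
    osteons so the window holds a few of them at a resolvable cement-line
    thickness.
    """
    return SENBPreset(
        spec=SENBSpec(L=3.2, h=0.8, a0=0.34, t=1.0, window=("circle", 0.22)),
        recipe=MicrostructureRecipe(
            target_fraction=0.45,
            r_out_mean=0.055,
            r_out_sd=0.008,
            canal_ratio=1.0 / 3.0,
            t_cem=0.016,
            min_gap=0.004,
            seed=seed,
            containment="canal",
        ),
        h_fine=0.008,
        ell=0.016,
        corridor_width=0.2,
        program=LoadProgram(
            du_initial=2e-4,
            du_refined=1e-4,
            u_max=0.12,
            max_steps=400,
            stop_force_fraction=0.05,
            stop_crack_fraction=0.5,
            record_every=5,
        ),
    )


# ----------------------------------------------------------------------------
# factors
# ----------------------------------------------------------------------------


def screening_factors(half_range: float = 0.2) -> list:
    """Six screening factors at +/-20% around the baseline parameters."""
    base = baseline_tissue_params()
    vals = {
        "E_mat": base["matrix"].E,
        "E_ost": base["osteon"].E,
        "E_cem": base["cement_line"].E,
        "Gc_mat": base["matrix"].Gc,
        "Gc_ost": base["osteon"].Gc,
        "Gc_cem": base["cement_line"].Gc,
    }
    return [FactorSpec(n, vals[n], half_range) for n in SCREENING_FACTOR_NAMES]


def response_surface_factors(half_range: float = 0.5) -> list:
    """Four response-surface factors at +/-50% around the baseline."""
    base = baseline_tissue_params()
    vals = {
        "E_cem": base["cement_line"].E,
        "Gc_mat": base["matrix"].Gc,
        "Gc_ost": base["osteon"].Gc,
        "Gc_cem": base["cement_line"].Gc,
    }
    return [FactorSpec(n, vals[n], half_range) for n in RESPONSE_FACTOR_NAMES]


def apply_factors(params: dict) -> dict:
    """Decode a factor-value dict into the three TissueParams objects."""
    base = baseline_tissue_params()
    out = {}
    out["matrix"] = base["matrix"].with_values(
        E=params.get("E_mat", base["matrix"].E),
        Gc=params.get("Gc_mat", base["matrix"].Gc),
    )
    out["osteon"] = base["osteon"].with_values(
        E=params.get("E_ost", base["osteon"].E),
        Gc=params.get("Gc_ost", base["osteon"].Gc),
    )
    out["cement_line"] = base["cement_line"].with_values(
        E=params.get("E_cem", base["cement_line"].E),
        Gc=params.get("Gc_cem", base["cement_line"].Gc),
    )
    return out


# ----------------------------------------------------------------------------
# forward outcome evaluation
# ----------------------------------------------------------------------------


def screening_outcomes(
    tissues: dict,
    preset: ScreeningPreset,
    mesh: Mesh | None = None,
    tolerances: SolverTolerances | None = None,
) -> dict:
    """Forward run of the screening cell and its three outcomes.

    Peak force and energy release use the canal-truncation rule; the
    tortuosity is skeleton length over projected horizontal crack length
    for the whole path (screening convention).
    """
    if mesh is None:
        mesh = preset.build_mesh()
    model = FEModel(
        mesh=mesh, tissues=tissues, pf=PhaseFieldConfig(ell=preset.ell), thickness=1.0
    )
    hist = run_simulation(model, preset.program, tolerances)
    if hist.failed or len(hist) == 0:
        raise RuntimeError("screening forward run did not converge")
    canal_step = detect_canal_entry(hist, mesh)
    force = peak_force(hist, canal_step)
    release = energy_release_per_advance(hist, canal_step)
    # prune skeleton spurs up to the damage-band width (in pixels)
    prune = int(round(4.0 * preset.ell / preset.h_fine))
    path = extract_crack_path(
        mesh, hist.meta["final_d"], valid_fraction=1.0, prune=prune
    )
    tort = tortuosity(path, mode="horizontal")
    return {
        "peak_force": force,
        "tortuosity": tort,
        "energy_release": release,
        "canal_step": -1 if canal_step is None else canal_step,
        "crack_length": float(hist.crack_length[-1]),
    }


def senb_outcomes(
    tissues: dict,
    preset: SENBPreset,
    mesh: Mesh | None = None,
    micro: Microstructure | None = None,
    tolerances: SolverTolerances | None = None,
) -> dict:
    """Forward run of the SENB model: peak force, tortuosity, J_Ic.

    Toughness follows the single-edge-bend K formula with the crack-length
    series of the run, converted to J with the matrix elastic constants;
    tortuosity uses the vertical convention in the 25% validity region.
    """
    if micro is None:
        micro = preset.build_microstructure()
    if mesh is None:
        mesh = preset.build_mesh(micro)
    model = FEModel(
        mesh=mesh,
        tissues=tissues,
        pf=PhaseFieldConfig(ell=preset.ell),
        thickness=preset.spec.t,
    )
    hist = run_simulation(model, preset.program, tolerances)
    if hist.failed or len(hist) == 0:
        raise RuntimeError("SENB forward run did not converge")
    canal_step = detect_canal_entry(hist, mesh, micro)
    force = peak_force(hist, canal_step)
    prune = int(round(4.0 * preset.ell / preset.h_fine))
    path = extract_crack_path(
        mesh, hist.meta["final_d"], valid_fraction=0.25, prune=prune
    )
    tort = tortuosity(path, mode="vertical")
    mat = tissues["matrix"]
    tough = toughness(hist, preset.spec, E=mat.E, nu=mat.nu, ell=preset.ell)
    return {
        "peak_force": force,
        "tortuosity": tort,
        "J_Ic": tough.J_Ic,
        "J_Pmax": tough.J_Pmax,
        "K_c": tough.K_c,
        "canal_step": -1 if canal_step is None else canal_step,
        "crack_length": float(hist.crack_length[-1]),
    }


def _memoised(evaluate):
    """Centre-point repeats of a deterministic model are identical; skip
    re-running exact duplicates within one design."""
    cache: dict = {}

    def wrapped(params: dict) -> dict:
        key = tuple(sorted((k, round(v, 12)) for k, v in params.items()))
        if key not in cache:
            cache[key] = evaluate(params)
        return cache[key]

    return wrapped


# ----------------------------------------------------------------------------
# study stages
# ----------------------------------------------------------------------------


def run_screening_study(
    preset: ScreeningPreset | None = None,
    n_center: int = 6,
    half_range: float = 0.2,
    cache_dir=None,
    tolerances: SolverTolerances | None = None,
):
    """Six-factor screening: 48 edge runs + centre repeats, main-effect
    Type-II ANOVA per outcome.

    Returns (design, outcome table, {outcome: AnovaTable}).
    """
    if preset is None:
        preset = desk_screening_preset()
    factors = screening_factors(half_range)
    design = box_behnken(factors, n_center=n_center)
    mesh = preset.build_mesh()

    def evaluate(params: dict) -> dict:
        return screening_outcomes(apply_factors(params), preset, mesh, tolerances)

    outcomes = run_design(design, _memoised(evaluate), cache_dir=cache_dir)
    tables = {
        name: anova_tss(design, outcomes[name].to_numpy(), interactions=False)
        for name in ("peak_force", "tortuosity", "energy_release")
    }
    return design, outcomes, tables


def run_response_surface_study(
    preset: SENBPreset | None = None,
    n_center: int = 3,
    half_range: float = 0.5,
    surface_factors: tuple = ("Gc_mat", "Gc_cem"),
    cache_dir=None,
    tolerances: SolverTolerances | None = None,
):
    """Four-factor response-surface stage on one SENB microstructure.

    Returns (design, outcome table, {outcome: AnovaTable} with pairwise
    interactions, {outcome: ResponseSurfaceModel} over ``surface_factors``).
    """
    if preset is None:
        preset = desk_senb_preset()
    factors = response_surface_factors(half_range)
    design = box_behnken(factors, n_center=n_center)
    micro = preset.build_microstructure()
    mesh = preset.build_mesh(micro)

    def evaluate(params: dict) -> dict:
        return senb_outcomes(apply_factors(params), preset, mesh, micro, tolerances)

    outcomes = run_design(design, _memoised(evaluate), cache_dir=cache_dir)
    tables = {
        name: anova_tss(design, outcomes[name].to_numpy(), interactions=True)
        for name in ("peak_force", "tortuosity", "J_Ic")
    }
    surfaces = fit_response_surface(
        design, outcomes, ["peak_force", "tortuosity", "J_Ic"], list(surface_factors)
    )
    return design, outcomes, tables, surfaces


def calibrate_toughness(surfaces: dict, targets: dict, grid_step: float = 0.01):
    """Grid calibration of (Gc_mat, Gc_cem) against an observed triple."""
    return calibrate(
        {k: surfaces[k] for k in ("peak_force", "tortuosity", "J_Ic")},
        {k: targets[k] for k in ("peak_force", "tortuosity", "J_Ic")},
        grid_step=grid_step,
    )
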