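"""Constitutive core of the AT1 phase-field fracture model.

Cortical bone is treated as a composite of three isotropic, linear-elastic
tissue classes -- interstitial matrix, osteon and cement line -- each with a
Young's modulus ``E`` (MPa), Poisson's ratio ``nu`` and critical energy
release rate ``Gc`` (N/mm).  Damage follows the first-order
Ambrosio--Tortorelli (AT1) regularisation: a quadratic degradation function
``g(d) = (1 - d)^2 + k`` acts on the stored energy, the tensile part of the
energy drives damage through a history field with the AT1 elastic threshold,
and the hydrostatic--deviatoric (Amor) split prevents crack growth in
compression.

All quantities use the mm-N-MPa unit system: lengths in mm, forces in N,
stresses and energy densities in MPa = N/mm^2, toughness in N/mm.
"""

from __future__ import annotations

import configparser
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "TISSUE_CLASSES",
    "TissueParams",
    "PhaseFieldConfig",
    "degradation",
    "split_energy",
    "amor_tensile_energy",
    "at1_history_threshold",
    "update_history",
    "at1_uniaxial_strength",
    "transition_crack_length",
    "baseline_tissue_params",
    "baseline_phase_field_config",
    "load_material_config",
]

#: Tissue classes of the composite; "elastic" marks regions outside the
#: phase-field window that deform with matrix stiffness but never damage.
TISSUE_CLASSES = ("matrix", "osteon", "cement_line")


@dataclass(frozen=True)
class TissueParams:
    """Elastic and fracture constants of one tissue class.

    Parameters
    ----------
    tissue_class : str
        One of ``matrix``, ``osteon``, ``cement_line`` (or ``elastic`` for
        the linear-elastic far field of an embedded-cell model).
    E : float
        Young's modulus in MPa.
    nu : float
        Poisson's ratio (0 < nu < 0.5).
    Gc : float
        Critical energy release rate in N/mm.
    """

    tissue_class: str
    E: float
    nu: float
    Gc: float

    def __post_init__(self) -> None:
        if self.E <= 0.0:
            raise ValueError(f"E must be positive, got {self.E}")
        if not 0.0 < self.nu < 0.5:
            raise ValueError(f"nu must lie in (0, 0.5), got {self.nu}")
        if self.Gc <= 0.0:
            raise ValueError(f"Gc must be positive, got {self.Gc}")

    @property
    def mu(self) -> float:
        """Shear modulus, MPa."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def lam(self) -> float:
        """First Lame constant, MPa."""
        return self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))

    @property
    def kappa2d(self) -> float:
        """Plane-strain (2D) bulk modulus ``kappa' = lambda + mu``, MPa.

        This is the modulus conjugate to the in-plane trace in the Amor
        split under plane strain.
        """
        return self.lam + self.mu

    def plane_strain_stiffness(self) -> np.ndarray:
        """3x3 plane-strain stiffness in Voigt order (xx, yy, xy).

        Engineering shear strain convention: ``sigma = C @ (exx, eyy, gxy)``.
        """
        lam, mu = self.lam, self.mu
        return np.array(
            [
                [lam + 2.0 * mu, lam, 0.0],
                [lam, lam + 2.0 * mu, 0.0],
                [0.0, 0.0, mu],
            ]
        )

    def with_values(self, **kwargs) -> "TissueParams":
        """Return a copy with some fields replaced (used by the DOE stages)."""
        data = {"tissue_class": self.tissue_class, "E": self.E, "nu": self.nu, "Gc": self.Gc}
        data.update(kwargs)
        return TissueParams(**data)


@dataclass(frozen=True)
class PhaseFieldConfig:
    """Regularisation settings of the phase-field model.

    Attributes
    ----------
    ell : float
        Regularisation length in mm; sets the damage-band width (~4 ell)
        and, through the AT1 strength relation, an effective strength.
    k_res : float
        Residual stiffness factor of the degradation function.
    damage_threshold_for_crack : float
        Contour level used when visualising / rasterising crack paths.
    """

    ell: float
    k_res: float = 1e-7
    damage_threshold_for_crack: float = 0.01

    def __post_init__(self) -> None:
        if self.ell <= 0.0:
            raise ValueError(f"ell must be positive, got {self.ell}")
        if not 0.0 < self.k_res <= 1e-3:
            raise ValueError(f"k_res must lie in (0, 1e-3], got {self.k_res}")
        if not 0.0 < self.damage_threshold_for_crack < 1.0:
            raise ValueError("damage_threshold_for_crack must lie in (0, 1)")


def degradation(d, k_res: float = 1e-7):
    """Quadratic degradation ``g(d) = (1 - d)^2 + k_res``.

    Accepts scalars or arrays.  Raises ``ValueError`` if any damage value
    lies outside [0, 1].
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0.0) or np.any(d > 1.0):
        raise ValueError("damage must lie in [0, 1]")
    out = (1.0 - d) ** 2 + k_res
    return out if out.ndim else float(out)


def split_energy(strain: np.ndarray, params: TissueParams) -> tuple[float, float]:
    """Hydrostatic-deviatoric (Amor) split of the strain energy density.

    ``psi_plus = (alpha/2) kappa' tr(eps)^2 + mu eps_dev : eps_dev`` with
    ``alpha = 1`` for dilatational states (tr > 0) and 0 otherwise;
    ``psi_minus`` holds the remaining compressive volumetric part.  Their
    sum equals the undamaged isotropic plane-strain energy density.

    Parameters
    ----------
    strain : (2, 2) array
        Symmetric in-plane strain tensor.
    params : TissueParams

    Returns
    -------
    (psi_plus, psi_minus) : tuple of float, MPa
    """
    eps = np.asarray(strain, dtype=float)
    if eps.shape != (2, 2):
        raise ValueError("strain must be a 2x2 tensor")
    if not math.isclose(eps[0, 1], eps[1, 0], rel_tol=0.0, abs_tol=1e-12 * max(1.0, abs(eps).max())):
        raise ValueError("strain tensor must be symmetric")
    tr = eps[0, 0] + eps[1, 1]
    dev = eps - 0.5 * tr * np.eye(2)
    dev2 = float(np.tensordot(dev, dev))
    kappa = params.kappa2d
    alpha = 1.0 if tr > 0.0 else 0.0
    psi_plus = 0.5 * alpha * kappa * tr**2 + params.mu * dev2
    psi_minus = 0.5 * (1.0 - alpha) * kappa * tr**2
    return psi_plus, psi_minus


def amor_tensile_energy(tr, dev2, kappa, mu):
    """Vectorised tensile (damage-driving) energy of the Amor split.

    Parameters are broadcastable arrays: in-plane trace ``tr``, squared
    deviator norm ``dev2 = eps_dev : eps_dev``, and the per-point moduli.
    """
    tr = np.asarray(tr, dtype=float)
    pos = tr > 0.0
    return 0.5 * kappa * np.where(pos, tr * tr, 0.0) + mu * dev2


def at1_history_threshold(Gc, ell):
    """AT1 elastic threshold ``H_min = 3 Gc / (16 ell)`` (MPa).

    Below this driving force the damage subproblem returns d = 0; clamping
    the history field at H_min prevents the negative damage values the AT1
    model would otherwise admit.
    """
    return 3.0 * np.asarray(Gc, dtype=float) / (16.0 * np.asarray(ell, dtype=float))


def update_history(H_prev, psi_plus, Gc, ell):
    """Irreversibility update ``H = max(H_prev, psi_plus, H_min)``.

    Works elementwise on arrays.  Negative inputs raise ``ValueError``.
    """
    H_prev = np.asarray(H_prev, dtype=float)
    psi_plus = np.asarray(psi_plus, dtype=float)
    if np.any(H_prev < 0.0) or np.any(psi_plus < 0.0):
        raise ValueError("history and driving energy must be non-negative")
    H_min = at1_history_threshold(Gc, ell)
    out = np.maximum(np.maximum(H_prev, psi_plus), H_min)
    return out if out.ndim else float(out)


def at1_uniaxial_strength(E: float, Gc: float, ell: float) -> float:
    """Effective uniaxial strength ``sigma_c = sqrt(3 E Gc / (8 ell))``.

    ``E`` is the modulus of the loading state considered (use
    ``E / (1 - nu^2)`` for a plane-strain bar free to contract laterally).
    """
    if E <= 0.0 or Gc <= 0.0 or ell <= 0.0:
        raise ValueError("E, Gc and ell must be positive")
    return math.sqrt(3.0 * E * Gc / (8.0 * ell))


def transition_crack_length(E: float, Gc: float, sigma_c: float) -> float:
    """Ductile-to-brittle transition crack length ``a_c = E Gc / (pi sigma_c^2)``.

    Flaws shorter than ``a_c`` fail by strength, longer ones by toughness.
    Substituting the AT1 strength gives ``a_c = 8 ell / (3 pi)`` identically.
    """
    if E <= 0.0 or Gc <= 0.0 or sigma_c <= 0.0:
        raise ValueError("E, Gc and sigma_c must be positive")
    return E * Gc / (math.pi * sigma_c**2)


def _parse_material_config(cp: configparser.ConfigParser):
    tissues: dict[str, TissueParams] = {}
    for name in TISSUE_CLASSES:
        if cp.has_section(name):
            sec = cp[name]
            tissues[name] = TissueParams(
                tissue_class=name,
                E=sec.getfloat("E"),
                nu=sec.getfloat("nu"),
                Gc=sec.getfloat("Gc"),
            )
    pf = None
    if cp.has_section("phase_field"):
        sec = cp["phase_field"]
        pf = PhaseFieldConfig(
            ell=sec.getfloat("ell"),
            k_res=sec.getfloat("k_res", fallback=1e-7),
            damage_threshold_for_crack=sec.getfloat(
                "damage_threshold_for_crack", fallback=0.01
            ),
        )
    return tissues, pf


def load_material_config(path: str | Path):
    """Read tissue parameters and phase-field settings from a config file.

    The format is flat INI-style text with one section per tissue class
    plus an optional ``[phase_field]`` section; see the packaged
    ``baseline_materials.cfg`` for the layout.

    Returns
    -------
    (tissues, pf_config) : dict[str, TissueParams], PhaseFieldConfig | None
    """
    cp = configparser.ConfigParser(inline_comment_prefixes=("#",))
    read = cp.read(Path(path))
    if not read:
        raise FileNotFoundError(path)
    return _parse_material_config(cp)


def _baseline_config() -> configparser.ConfigParser:
    cp = configparser.ConfigParser(inline_comment_prefixes=("#",))
    text = resources.files("osteofrac.data").joinpath("baseline_materials.cfg").read_text()
    cp.read_string(text)
    return cp


def baseline_tissue_params() -> dict[str, TissueParams]:
    """Baseline three-tissue parameter set (design centre point)."""
    tissues, _ = _parse_material_config(_baseline_config())
    return tissues


def baseline_phase_field_config() -> PhaseFieldConfig:
    """Packaged default regularisation (ell = 2.5 um, k = 1e-7)."""
    _, pf = _parse_material_config(_baseline_config())
    assert pf is not None
    return pf
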