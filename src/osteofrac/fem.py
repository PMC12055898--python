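"""2D plane-strain finite-element engine for hybrid AT1 phase-field fracture.

Discretisation: 4-node bilinear quadrilaterals with 2x2 Gauss quadrature for
both the displacement and the damage field; the history field lives at the
quadrature points.  The hybrid scheme degrades the full isotropic stiffness
``g(d) C`` in the equilibrium problem while only the Amor tensile energy
drives damage.  Each displacement-controlled load step is solved by
alternating minimisation (staggered iteration) between the linear
displacement problem and the linear AT1 damage problem, iterated until the
damage increment and the energy change fall below tolerance.

Units: mm-N-MPa throughout.  Forces and energies in recorded histories are
multiplied by the out-of-plane thickness (N and N*mm).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

OMEGA_MAX = 4.0

# SuperLU settings for the symmetric positive-definite systems we assemble
_SPD_LU = dict(
    permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0, options=dict(SymmetricMode=True)
)

from .materials import (
    PhaseFieldConfig,
    amor_tensile_energy,
    at1_history_threshold,
)

__all__ = [
    "Mesh",
    "DofState",
    "LoadProgram",
    "SolverTolerances",
    "SimulationHistory",
    "FEModel",
    "StaggeredSolver",
    "assemble_displacement_system",
    "solve_damage_subproblem",
    "run_simulation",
]

# ----------------------------------------------------------------------------
# quadrature / shape functions
# ----------------------------------------------------------------------------

_GP = np.array(
    [[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]]
) / np.sqrt(3.0)  # 2x2 Gauss points, weight 1 each


def _shape(xi: float, eta: float) -> np.ndarray:
    return 0.25 * np.array(
        [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta), (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
    )


def _shape_grad(xi: float, eta: float) -> np.ndarray:
    # rows: nodes, cols: d/dxi, d/deta
    return 0.25 * np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ]
    )


_N_GP = np.stack([_shape(*gp) for gp in _GP])  # (4gp, 4nodes)
_DN_GP = np.stack([_shape_grad(*gp) for gp in _GP])  # (4gp, 4nodes, 2)


# ----------------------------------------------------------------------------
# mesh and state containers
# ----------------------------------------------------------------------------


@dataclass
class Mesh:
    """Quad mesh with per-element tissue labels.

    Attributes
    ----------
    nodes : (n, 2) float array, mm
    elems : (m, 4) int array, counter-clockwise connectivity
    material_id : (m,) int array; codes index into ``material_names``
    material_names : dict mapping code -> tissue label ('matrix', 'osteon',
        'cement_line') or 'elastic' for the undamageable far field
    pf_active : (m,) bool array; phase-field damage lives only here
    node_sets : named node index arrays (boundaries, pins, notch mouth)
    metadata : free-form dict; builders store boundary conditions ('bc'),
        the CMOD node pair ('cmod'), ligament frame ('ligament') and the
        fine-mesh size ('h_fine') here
    """

    nodes: np.ndarray
    elems: np.ndarray
    material_id: np.ndarray
    material_names: dict
    pf_active: np.ndarray
    node_sets: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def edge_lengths(self) -> np.ndarray:
        """(m, 4) lengths of the four element edges."""
        xy = self.nodes[self.elems]  # (m,4,2)
        nxt = np.roll(xy, -1, axis=1)
        return np.linalg.norm(nxt - xy, axis=2)

    @property
    def h_min(self) -> float:
        """Smallest element edge inside the phase-field-active region."""
        if not self.pf_active.any():
            return float("nan")
        return float(self.edge_lengths()[self.pf_active].min())

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)

    def validate(self, ell: float | None = None) -> None:
        """Check Jacobian positivity and, if ``ell`` is given, h <= ell/2."""
        det = _element_data(self).detJw
        if np.any(det <= 0.0):
            raise ValueError("mesh contains elements with non-positive Jacobian")
        if ell is not None and self.pf_active.any():
            if self.h_min > ell / 2.0 + 1e-12:
                raise ValueError(
                    f"fine mesh too coarse for phase field: h_min={self.h_min:g} "
                    f"> ell/2={ell / 2.0:g}"
                )


@dataclass
class DofState:
    """Nodal displacement/damage fields plus quadrature-point history."""

    u: np.ndarray  # (2n,), mm
    d: np.ndarray  # (n,), damage in [0, 1]
    H: np.ndarray  # (m, 4), MPa; zero rows for elastic elements

    def copy(self) -> "DofState":
        return DofState(self.u.copy(), self.d.copy(), self.H.copy())


@dataclass
class LoadProgram:
    """Displacement-control schedule.

    ``du_initial`` is used until the first drop in load (force falling below
    ``drop_ratio`` times its running maximum), after which ``du_refined``
    applies.  The run stops at ``u_max``, after ``max_steps`` steps, or once
    the force has fallen below ``stop_force_fraction`` of the recorded peak
    with a propagating crack (severed specimen).
    """

    du_initial: float
    du_refined: float | None = None
    u_max: float = np.inf
    max_steps: int = 10000
    drop_ratio: float = 0.99
    stop_force_fraction: float = 0.02
    stop_crack_fraction: float | None = None
    record_every: int = 5

    def __post_init__(self) -> None:
        if self.du_initial <= 0.0:
            raise ValueError("du_initial must be positive")
        if self.du_refined is None:
            self.du_refined = self.du_initial
        if self.du_refined <= 0.0 or self.du_refined > self.du_initial:
            raise ValueError("need 0 < du_refined <= du_initial")


@dataclass
class SolverTolerances:
    tol_d: float = 1e-4  # max nodal damage change per sweep
    tol_E: float = 1e-6  # relative energy change per sweep
    max_sweeps: int = 200
    max_step_cuts: int = 4
    # reuse the stiffness factorisation while damage has drifted less than
    # this since it was computed; a fresh factorisation is always forced on
    # the sweep that confirms convergence, so accepted states are exact
    refactor_tol: float = 0.05
    # Aitken relaxation of the damage update (accelerates the staggered
    # fixed point without changing it); disable for plain alternating
    # minimisation with its guaranteed energy descent
    aitken: bool = True


@dataclass
class SimulationHistory:
    """Per-load-step record of a displacement-controlled simulation.

    Forces are in N (thickness included), energies in N*mm, lengths in mm.
    ``snapshots`` holds (step_index, nodal damage) pairs saved every
    ``record_every`` accepted steps plus the final state.
    """

    applied_u: np.ndarray
    force: np.ndarray
    cmod: np.ndarray
    strain_energy: np.ndarray
    dissipated_energy: np.ndarray
    crack_length: np.ndarray
    snapshots: list
    thickness: float = 1.0
    a0: float = 0.0
    failed: bool = False
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.applied_u)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "applied_u_mm": self.applied_u,
                "force_N": self.force,
                "cmod_mm": self.cmod,
                "strain_energy_Nmm": self.strain_energy,
                "dissipated_energy_Nmm": self.dissipated_energy,
                "crack_length_mm": self.crack_length,
            }
        )


# ----------------------------------------------------------------------------
# element precomputation
# ----------------------------------------------------------------------------


class _ElementData:
    """Per-element quadrature data shared by assembly routines."""

    def __init__(self, mesh: Mesh):
        xy = mesh.nodes[mesh.elems]  # (m,4,2)
        m = xy.shape[0]
        # Jacobian per gp: J = dN^T @ xy  -> (m,4gp,2,2)
        J = np.einsum("gna,mnb->mgab", _DN_GP, xy)
        det = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]  # (m,4)
        inv = np.empty_like(J)
        inv[..., 0, 0] = J[..., 1, 1]
        inv[..., 1, 1] = J[..., 0, 0]
        inv[..., 0, 1] = -J[..., 0, 1]
        inv[..., 1, 0] = -J[..., 1, 0]
        inv /= det[..., None, None]
        # dN/dx: (m, 4gp, 4nodes, 2); note J_{ab} = dx_b/dxi_a, so the
        # chain rule contracts with the transposed inverse
        dNdx = np.einsum("gna,mgba->mgnb", _DN_GP, inv)
        self.detJw = det  # 2x2 Gauss weights are 1
        self.dNdx = dNdx
        # strain-displacement matrix B (m,4gp,3,8); Voigt (exx, eyy, gxy)
        B = np.zeros((m, 4, 3, 8))
        B[:, :, 0, 0::2] = dNdx[..., 0]
        B[:, :, 1, 1::2] = dNdx[..., 1]
        B[:, :, 2, 0::2] = dNdx[..., 1]
        B[:, :, 2, 1::2] = dNdx[..., 0]
        self.B = B


def _csr_scatter_map(rows, cols, n):
    """Canonical CSR pattern + per-entry positions for repeated assembly."""
    pattern = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()
    pattern.sum_duplicates()
    keys = (
        np.repeat(np.arange(n, dtype=np.int64), np.diff(pattern.indptr)) * n
        + pattern.indices
    )
    pos = np.searchsorted(keys, rows.astype(np.int64) * n + cols)
    return pattern.indptr, pattern.indices, pos


# ----------------------------------------------------------------------------
# model
# ----------------------------------------------------------------------------


@dataclass
class FEModel:
    """Mesh + tissue parameters + regularisation + loading definition."""

    mesh: Mesh
    tissues: dict
    pf: PhaseFieldConfig
    thickness: float = 1.0

    def __post_init__(self) -> None:
        names = {
            self.mesh.material_names[i] for i in np.unique(self.mesh.material_id)
        }
        missing = {n for n in names if n != "elastic" and n not in self.tissues}
        if missing:
            raise ValueError(f"no TissueParams registered for {sorted(missing)}")
        if "elastic" in names and "elastic" not in self.tissues:
            # undamageable far field deforms with matrix stiffness
            self.tissues = dict(self.tissues)
            mat = self.tissues["matrix"]
            self.tissues["elastic"] = dataclasses.replace(mat, tissue_class="matrix")

    def element_tissue(self) -> list:
        return [self.mesh.material_names[i] for i in self.mesh.material_id]

    def initial_state(self) -> DofState:
        mesh = self.mesh
        H = np.zeros((mesh.n_elems, 4))
        names = self.element_tissue()
        Gc = np.array([self.tissues[n].Gc for n in names])
        Hmin = at1_history_threshold(Gc, self.pf.ell)
        H[mesh.pf_active] = Hmin[mesh.pf_active, None]
        return DofState(
            u=np.zeros(2 * mesh.n_nodes), d=np.zeros(mesh.n_nodes), H=H
        )


def _bc_dofs(mesh: Mesh):
    """Resolve the boundary-condition spec in metadata into dof arrays.

    Returns (constrained_dofs, pattern, control_dofs, direction) where
    ``pattern`` holds 1 on displacement-controlled dofs (scaled by the
    applied displacement) and 0 on fixed dofs.
    """
    bc = mesh.metadata.get("bc")
    if not bc:
        raise ValueError("mesh metadata has no 'bc' boundary-condition spec")
    axis_map = {"x": (0,), "y": (1,), "both": (0, 1)}
    con, pat, ctl = [], [], []
    direction = 1.0
    for item in bc:
        nodes = mesh.node_sets[item["set"]]
        values = item.get("values")  # optional per-node values, (n,) or (n, 2)
        for k, ax in enumerate(axis_map[item["axis"]]):
            dofs = 2 * np.asarray(nodes, dtype=np.int64) + ax
            if values is not None:
                v = np.asarray(values, dtype=float)
                vals = v[:, k] if v.ndim == 2 else v
            else:
                vals = None
            if item["kind"] == "fixed":
                con.append(dofs)
                pat.append(np.zeros(len(dofs)) if vals is None else vals)
            elif item["kind"] == "control":
                direction = float(item.get("direction", 1.0))
                con.append(dofs)
                pat.append(np.full(len(dofs), direction) if vals is None else vals)
                ctl.append(dofs)
            else:
                raise ValueError(f"unknown bc kind {item['kind']!r}")
    con = np.concatenate(con)
    pat = np.concatenate(pat)
    uniq, idx = np.unique(con, return_index=True)
    if len(uniq) != len(con):
        con, pat = uniq, pat[idx]
    ctl = np.concatenate(ctl) if ctl else np.array([], dtype=np.int64)
    return con, pat, ctl, direction


# ----------------------------------------------------------------------------
# staggered solver
# ----------------------------------------------------------------------------


class StaggeredSolver:
    """Alternating-minimisation solver for one :class:`FEModel`.

    Precomputes element stiffness contributions and sparse scatter maps once
    and reuses LU factorisations across sweeps whenever the damage field has
    not changed (the whole elastic phase costs one factorisation).
    """

    def __init__(self, model: FEModel, tol: SolverTolerances | None = None):
        self.model = model
        self.tol = tol or SolverTolerances()
        mesh = model.mesh
        self.mesh = mesh
        self.edata = _element_data(mesh)
        names = model.element_tissue()
        self.Gc = np.array([model.tissues[n].Gc for n in names])
        self.kappa = np.array([model.tissues[n].kappa2d for n in names])
        self.mu_arr = np.array([model.tissues[n].mu for n in names])
        C = np.stack([model.tissues[n].plane_strain_stiffness() for n in names])
        # per-gauss-point element stiffness, detJw included: (m,4,8,8)
        B, detJw = self.edata.B, self.edata.detJw
        self.Ke_gp = np.einsum("mgka,mkl,mglb,mg->mgab", B, C, B, detJw, optimize=True)

        # --- displacement system scatter maps -------------------------------
        n_u = 2 * mesh.n_nodes
        edofs = np.empty((mesh.n_elems, 8), dtype=np.int64)
        edofs[:, 0::2] = 2 * mesh.elems
        edofs[:, 1::2] = 2 * mesh.elems + 1
        self.edofs = edofs
        rows = np.repeat(edofs, 8, axis=1).ravel()
        cols = np.tile(edofs, (1, 8)).ravel()

        con, pat, ctl, direction = _bc_dofs(mesh)
        self.con_dofs, self.pattern, self.ctl_dofs, self.direction = con, pat, ctl, direction
        is_con = np.zeros(n_u, dtype=bool)
        is_con[con] = True
        self.free = np.flatnonzero(~is_con)
        idx_free = np.full(n_u, -1, dtype=np.int64)
        idx_free[self.free] = np.arange(len(self.free))
        idx_con = np.full(n_u, -1, dtype=np.int64)
        idx_con[con] = np.arange(len(con))
        rf, cf = idx_free[rows], idx_free[cols]
        rc, cc = idx_con[rows], idx_con[cols]
        self._sel_ff = (rf >= 0) & (cf >= 0)
        self._sel_fc = (rf >= 0) & (cc >= 0)
        self._sel_cc = (rc >= 0) & (cc >= 0)
        nf, nc = len(self.free), len(con)
        self._ff = _csr_scatter_map(rf[self._sel_ff], cf[self._sel_ff], nf)
        # rectangular blocks: build as coo each time (cheap relative to LU)
        self._fc_rows = rf[self._sel_fc]
        self._fc_cols = cc[self._sel_fc]
        self._cc_rows = rc[self._sel_cc]
        self._cc_cols = cc[self._sel_cc]
        self._nf, self._nc = nf, nc
        self._u_con_pattern = pat  # values on constrained dofs per unit applied u

        # --- damage system ---------------------------------------------------
        pf = mesh.pf_active
        self.pf_elems = np.flatnonzero(pf)
        pf_nodes = np.unique(mesh.elems[pf])
        self.pf_nodes = pf_nodes
        nd = len(pf_nodes)
        node_map = np.full(mesh.n_nodes, -1, dtype=np.int64)
        node_map[pf_nodes] = np.arange(nd)
        self.delems = node_map[mesh.elems[pf]]  # (mp,4) damage dof connectivity
        drows = np.repeat(self.delems, 4, axis=1).ravel()
        dcols = np.tile(self.delems, (1, 4)).ravel()
        self._dd = _csr_scatter_map(drows, dcols, nd)
        self._nd = nd
        # damage shape products per gp
        self._NN = np.einsum("ga,gb->gab", _N_GP, _N_GP)  # (4,4,4)
        dNdx = self.edata.dNdx[pf]  # (mp,4,4,2)
        self._GG = np.einsum("mgna,mgoa->mgno", dNdx, dNdx)  # (mp,4,4,4)
        self._detJw_pf = self.edata.detJw[pf]
        self._Gc_pf = self.Gc[pf]
        self._B_pf = self.edata.B[pf]
        self._Ke_gp_pf = self.Ke_gp[pf]
        self._Hmin_pf = at1_history_threshold(self._Gc_pf, model.pf.ell)

        # damage-side gradient stiffness (constant): 3 Gc ell / 4 * GG
        ell = model.pf.ell
        grad_e = (
            (0.75 * self._Gc_pf * ell)[:, None, None, None]
            * self._GG
            * self._detJw_pf[:, :, None, None]
        ).sum(axis=1)  # (mp,4,4)
        data = np.zeros(len(self._dd[1]))
        np.add.at(data, self._dd[2], grad_e.ravel())
        self._Kd_grad_data = data

        # control-dof positions within the constrained block (for reactions)
        idx_con_map = {int(dof): i for i, dof in enumerate(self.con_dofs)}
        self._ctl_sel = np.array(
            [idx_con_map[int(dof)] for dof in self.ctl_dofs], dtype=np.int64
        )

        self._lu = None
        self._d_at_factor = None
        self._last_solve_drift = 0.0
        self._Kfc = None
        self._Kcc = None
        self._last_H_pf = None
        self._last_d_sol = None

    # -- assembly -----------------------------------------------------------

    def _g_gp(self, d: np.ndarray) -> np.ndarray:
        """Degradation factor at gauss points; 1 on elastic elements."""
        d_gp = d[self.mesh.elems] @ _N_GP.T  # (m,4)
        g = (1.0 - d_gp) ** 2 + self.model.pf.k_res
        g[~self.mesh.pf_active] = 1.0
        return g

    def _factorise(self, d: np.ndarray) -> None:
        g = self._g_gp(d)
        ke = np.einsum("mg,mgab->mab", g, self.Ke_gp)
        vals = ke.ravel()  # matches the (row-slow, col-fast) scatter order
        indptr, indices, pos = self._ff
        data = np.zeros(len(indices))
        np.add.at(data, pos, vals[self._sel_ff])
        Kff = sp.csr_matrix((data, indices, indptr), shape=(self._nf, self._nf))
        self._Kfc = sp.coo_matrix(
            (vals[self._sel_fc], (self._fc_rows, self._fc_cols)),
            shape=(self._nf, self._nc),
        ).tocsr()
        self._Kcc = sp.coo_matrix(
            (vals[self._sel_cc], (self._cc_rows, self._cc_cols)),
            shape=(self._nc, self._nc),
        ).tocsr()
        self._lu = splu(Kff.tocsc(), **_SPD_LU)
        self._d_at_factor = d.copy()
        self._rhs_base = -(self._Kfc @ self._u_con_pattern)

    def solve_displacement(
        self, d: np.ndarray, u_applied: float, stale_tol: float = 0.0
    ) -> np.ndarray:
        """Equilibrium displacements for damage field ``d`` (full vector).

        With ``stale_tol > 0`` the cached stiffness factorisation is reused
        as long as ``d`` has drifted less than that amount since it was
        computed (used to cheapen intermediate staggered sweeps).
        """
        if self._lu is None:
            self._factorise(d)
            self._last_solve_drift = 0.0
        elif not np.array_equal(d, self._d_at_factor):
            drift = float(np.abs(d - self._d_at_factor).max())
            if drift > stale_tol:
                self._factorise(d)
                self._last_solve_drift = 0.0
            else:
                self._last_solve_drift = drift
        else:
            self._last_solve_drift = 0.0
        uf = self._lu.solve(self._rhs_base * u_applied)
        u = np.empty(2 * self.mesh.n_nodes)
        u[self.free] = uf
        u[self.con_dofs] = self._u_con_pattern * u_applied
        return u

    def reaction_force(self, u: np.ndarray) -> float:
        """Total reaction on the control boundary, N (thickness included),
        positive in the loading direction."""
        uf = u[self.free]
        uc = u[self.con_dofs]
        r_c = self._Kfc.T @ uf + self._Kcc @ uc
        return float(r_c[self._ctl_sel].sum()) * self.direction * self.model.thickness

    def strains_pf(self, u: np.ndarray) -> np.ndarray:
        """(mp, 4, 3) Voigt strains at gauss points of phase-field elements."""
        ue = u[self.edofs[self.pf_elems]]  # (mp,8)
        return np.einsum("mgkb,mb->mgk", self._B_pf, ue)

    def tensile_energy(self, u: np.ndarray) -> np.ndarray:
        eps = self.strains_pf(u)
        tr = eps[..., 0] + eps[..., 1]
        dev2 = 0.5 * (eps[..., 0] - eps[..., 1]) ** 2 + 0.5 * eps[..., 2] ** 2
        kap = self.kappa[self.pf_elems][:, None]
        mu = self.mu_arr[self.pf_elems][:, None]
        return amor_tensile_energy(tr, dev2, kap, mu)

    def solve_damage(self, H_pf: np.ndarray) -> np.ndarray:
        """Solve the linear AT1 damage problem for history ``H_pf`` (mp,4).

        Returns the full nodal damage vector (zeros outside the phase-field
        region).  Raises if the solution dips below -1e-8 anywhere, which
        indicates a missing history threshold.
        """
        if self._last_H_pf is not None and np.array_equal(H_pf, self._last_H_pf):
            return self._last_d_sol.copy()
        c = 3.0 * self._Gc_pf / (8.0 * self.model.pf.ell)  # (mp,)
        w = self._detJw_pf  # (mp,4)
        mass = np.einsum("mg,gab,mg->mab", 2.0 * H_pf, self._NN, w)
        data = self._Kd_grad_data.copy()
        np.add.at(data, self._dd[2], mass.ravel())
        rhs_gp = (2.0 * H_pf - c[:, None]) * w  # (mp,4)
        b = np.zeros(self._nd)
        np.add.at(b, self.delems.ravel(), (rhs_gp @ _N_GP).ravel())
        indptr, indices, _ = self._dd
        A = sp.csr_matrix((data, indices, indptr), shape=(self._nd, self._nd))
        dd = splu(A.tocsc(), **_SPD_LU).solve(b)
        if dd.min() < -1e-8:
            raise RuntimeError(
                f"damage solution reached {dd.min():.3e} < -1e-8: "
                "history threshold was not applied"
            )
        dd = np.clip(dd, 0.0, 1.0)
        d = np.zeros(self.mesh.n_nodes)
        d[self.pf_nodes] = dd
        self._last_H_pf = H_pf.copy()
        self._last_d_sol = d.copy()
        return d

    # -- energies -----------------------------------------------------------

    def elastic_energy(self, u: np.ndarray, d: np.ndarray) -> float:
        """Degraded stored energy, N*mm (thickness included)."""
        g = self._g_gp(d)
        ue = u[self.edofs]
        e_gp = 0.5 * np.einsum("mb,mgbc,mc->mg", ue, self.Ke_gp, ue)
        return float((g * e_gp).sum()) * self.model.thickness

    def fracture_energy(self, d: np.ndarray) -> float:
        """AT1 surface energy 3Gc/(8 ell) * (d + ell^2 |grad d|^2), N*mm."""
        ell = self.model.pf.ell
        de = d[self.mesh.elems[self.pf_elems]]  # (mp,4)
        d_gp = de @ _N_GP.T
        grad = np.einsum("mgna,mn->mga", self.edata.dNdx[self.pf_elems], de)
        grad2 = (grad**2).sum(axis=2)
        dens = (3.0 * self._Gc_pf[:, None] / (8.0 * ell)) * (d_gp + ell**2 * grad2)
        return float((dens * self._detJw_pf).sum()) * self.model.thickness

    # -- load stepping ------------------------------------------------------

    def solve_load_step(self, state: DofState, u_applied: float):
        """Staggered solve at prescribed displacement ``u_applied``.

        Mutates ``state`` in place on success.  Returns a report dict with
        convergence info and the reaction force.
        """
        tol = self.tol
        d = state.d
        H = state.H.copy()
        E_prev = None
        converged = False
        sweeps = 0
        r_prev = None
        omega = 1.0
        force_fresh = False
        for sweep in range(1, tol.max_sweeps + 1):
            sweeps = sweep
            u = self.solve_displacement(
                d, u_applied, stale_tol=0.0 if force_fresh else tol.refactor_tol
            )
            force_fresh = False
            solve_drift = self._last_solve_drift
            psi = self.tensile_energy(u)
            H_changed = bool(np.any(psi > H[self.pf_elems]))
            H_pf = np.maximum(H[self.pf_elems], psi)
            d_hat = self.solve_damage(H_pf)
            H[self.pf_elems] = H_pf
            r = d_hat - d
            delta_d = float(np.abs(r).max())
            if not H_changed and delta_d < tol.tol_d:
                # elastic sweep: nothing moved, equilibrium already consistent
                d = d_hat
                converged = True
                break
            # Aitken relaxation of the damage update (accelerates the
            # staggered fixed point; the converged state is unchanged)
            if tol.aitken and r_prev is not None:
                dr = r - r_prev
                denom = float(dr @ dr)
                if denom > 0.0:
                    omega = float(np.clip(-omega * (r_prev @ dr) / denom, 0.25, OMEGA_MAX))
            r_prev = r
            d = np.clip(d + omega * r, 0.0, 1.0)
            E = self.elastic_energy(u, d) + self.fracture_energy(d)
            if E_prev is not None:
                rel_dE = abs(E - E_prev) / max(abs(E), 1e-14)
            else:
                rel_dE = np.inf
            E_prev = E
            if delta_d < tol.tol_d and rel_dE < tol.tol_E:
                if solve_drift <= tol.tol_d:
                    converged = True
                    break
                # candidate convergence reached with a stale stiffness:
                # confirm with a fresh factorisation before accepting
                force_fresh = True
        if not converged:
            return {"converged": False, "sweeps": sweeps}
        # irreversibility across accepted steps (running max nodewise)
        d = np.maximum(d, state.d)
        u = self.solve_displacement(d, u_applied)
        force = self.reaction_force(u)
        state.u, state.d, state.H = u, d, H
        return {"converged": True, "sweeps": sweeps, "force": force}

    # -- full simulation ----------------------------------------------------

    def run(self, program: LoadProgram) -> SimulationHistory:
        """Run the displacement-control schedule, recording histories."""
        mesh = self.mesh
        model = self.model
        state = model.initial_state()
        lig = mesh.metadata.get("ligament", {})
        a0 = float(lig.get("a0", 0.0))
        axis = 0 if lig.get("axis", "x") == "x" else 1
        tip = lig.get("tip")
        cmod_spec = mesh.metadata.get("cmod")
        pf_node_coord = mesh.nodes[self.pf_nodes, axis]
        tip_coord = tip[axis] if tip is not None else 0.0

        rec = {k: [] for k in ("u", "P", "cmod", "Es", "Ed", "a")}
        snapshots: list = []
        u_applied = 0.0
        du = program.du_initial
        refined = False
        peak = 0.0
        a_run = a0
        failed = False
        step = 0
        while step < program.max_steps and u_applied < program.u_max:
            target = min(u_applied + du, program.u_max)
            cuts = 0
            cur_du = target - u_applied
            while True:
                backup = state.copy()
                rep = self.solve_load_step(state, u_applied + cur_du)
                if rep["converged"]:
                    break
                state = backup
                cuts += 1
                if cuts > self.tol.max_step_cuts:
                    failed = True
                    break
                cur_du *= 0.5
            if failed:
                break
            u_applied += cur_du
            step += 1
            P = rep["force"]
            cmod = 0.0
            if cmod_spec is not None:
                na, nb = cmod_spec["nodes"]
                ax = 0 if cmod_spec["axis"] == "x" else 1
                cmod = abs(state.u[2 * nb + ax] - state.u[2 * na + ax])
            damaged = state.d[self.pf_nodes] >= 0.95
            if damaged.any():
                ext = float(pf_node_coord[damaged].max() - tip_coord)
                a_run = max(a_run, a0 + max(0.0, ext))
            rec["u"].append(u_applied)
            rec["P"].append(P)
            rec["cmod"].append(cmod)
            rec["Es"].append(self.elastic_energy(state.u, state.d))
            rec["Ed"].append(self.fracture_energy(state.d))
            rec["a"].append(a_run)
            if step % program.record_every == 0:
                snapshots.append((step - 1, state.d.astype(np.float32).copy()))
            peak = max(peak, P)
            if not refined and peak > 0.0 and P < program.drop_ratio * peak:
                refined = True
                du = program.du_refined
            if (
                peak > 0.0
                and P < program.stop_force_fraction * peak
                and a_run > a0
            ):
                break
            if (
                program.stop_crack_fraction is not None
                and lig.get("length")
                and a_run - a0 >= program.stop_crack_fraction * lig["length"]
            ):
                break
        if not snapshots or snapshots[-1][0] != step - 1:
            snapshots.append((step - 1, state.d.astype(np.float32).copy()))
        hist = SimulationHistory(
            applied_u=np.array(rec["u"]),
            force=np.array(rec["P"]),
            cmod=np.array(rec["cmod"]),
            strain_energy=np.array(rec["Es"]),
            dissipated_energy=np.array(rec["Ed"]),
            crack_length=np.array(rec["a"]),
            snapshots=snapshots,
            thickness=model.thickness,
            a0=a0,
            failed=failed,
            meta={
                "final_d": state.d.copy(),
                "ligament": lig,
                "h_fine": mesh.metadata.get("h_fine"),
                "ell": model.pf.ell,
            },
        )
        return hist


def _element_data(mesh: Mesh) -> _ElementData:
    cache = mesh.metadata.get("_edata")
    if cache is None:
        cache = _ElementData(mesh)
        mesh.metadata["_edata"] = cache
    return cache


# ----------------------------------------------------------------------------
# module-level operation wrappers
# ----------------------------------------------------------------------------


def assemble_displacement_system(
    mesh: Mesh, state: DofState, tissues: dict, pf: PhaseFieldConfig, thickness: float = 1.0
):
    """Build a solver for the displacement subproblem (thin wrapper).

    Returns the :class:`StaggeredSolver`; call ``solve_displacement`` /
    ``reaction_force`` on it.  Raises if the boundary conditions leave the
    system singular.
    """
    model = FEModel(mesh=mesh, tissues=tissues, pf=pf, thickness=thickness)
    solver = StaggeredSolver(model)
    if len(solver.con_dofs) == 0:
        raise ValueError("no displacement constraints: system is singular")
    return solver


def solve_damage_subproblem(
    mesh: Mesh, H: np.ndarray, tissues: dict, pf: PhaseFieldConfig
) -> np.ndarray:
    """Solve the AT1 damage problem at fixed history field ``H`` (m, 4)."""
    model = FEModel(mesh=mesh, tissues=tissues, pf=pf)
    solver = StaggeredSolver(model)
    return solver.solve_damage(np.asarray(H, dtype=float)[solver.pf_elems])


def run_simulation(
    model: FEModel,
    program: LoadProgram,
    tolerances: SolverTolerances | None = None,
) -> SimulationHistory:
    """Displacement-controlled phase-field simulation (deterministic)."""
    solver = StaggeredSolver(model, tolerances)
    return solver.run(program)
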