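"""Model geometries: single-osteon cell, SENB beam, and microstructures.

Two canonical models are built here as structured, graded quad meshes:

* a square single-osteon cell (side 400 um) with a central osteon, cement
  annulus and Haversian canal, notched at mid-height and loaded in vertical
  tension -- the screening geometry;
* a single-edge notched bending (SENB) beam in three-point bend with an
  embedded microstructure window ahead of the notch; outside the window the
  material is linear elastic with matrix properties.

Conventions: mm everywhere; the SENB frame has its origin at the notch
mouth with y upward along the ligament; canals are meshed as holes (free
surfaces); notches are geometric slits made of duplicated node pairs;
tissue regions share nodes at their boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fem import Mesh

__all__ = [
    "SingleOsteonSpec",
    "SENBSpec",
    "Osteon",
    "Microstructure",
    "classify_point",
    "build_single_osteon",
    "build_senb",
    "graded_coords",
    "write_layout",
    "read_layout",
]

_MATERIAL_CODES = {"matrix": 0, "osteon": 1, "cement_line": 2, "elastic": 3}
_CODE_NAMES = {v: k for k, v in _MATERIAL_CODES.items()}


# ----------------------------------------------------------------------------
# specs and microstructure
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class SingleOsteonSpec:
    """Square cell with one centred osteon, notched at mid-height.

    Defaults follow the screening geometry: side 400 um, osteon outer
    radius 75 um, canal radius 25 um, cement line 5 um, notch 80 um.
    """

    s: float = 0.4
    r_o: float = 0.075
    r_i: float = 0.025
    t_cem: float = 0.005
    a_notch: float = 0.08

    def __post_init__(self) -> None:
        if not self.r_i < self.r_o:
            raise ValueError("canal radius must be smaller than osteon radius")
        if not self.r_o + self.t_cem < self.s / 2.0:
            raise ValueError("osteon plus cement line must fit inside the cell")
        if not self.a_notch < self.s / 2.0:
            raise ValueError("notch must end before the cell centre")


@dataclass(frozen=True)
class SENBSpec:
    """Three-point-bend beam with an embedded microstructure window.

    ``L`` is the support span (= 4 h for the K-factor expression to apply),
    ``h`` the beam height, ``a0`` the notch depth, ``t`` the out-of-plane
    thickness.  ``window`` is ('circle', r) or ('ellipse', rx, ry); the
    window is centred on the ligament, ``window_offset`` above the notch
    tip (default: half the vertical semi-axis, so the window straddles the
    tip region and extends up the ligament).
    """

    L: float = 16.0
    h: float = 4.0
    a0: float = 1.5
    t: float = 2.0
    window: tuple = ("circle", 0.9)
    window_offset: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.a0 < self.h:
            raise ValueError("notch depth must lie in (0, h)")
        kind = self.window[0]
        if kind not in ("circle", "ellipse"):
            raise ValueError(f"unknown window kind {kind!r}")
        cy, ry = self.window_center[1], self.window_half_axes[1]
        if cy + ry > self.h or cy - ry < 0.0:
            raise ValueError("window does not fit inside the beam above the notch")

    @property
    def window_half_axes(self) -> tuple[float, float]:
        if self.window[0] == "circle":
            return (self.window[1], self.window[1])
        return (self.window[1], self.window[2])

    @property
    def window_center(self) -> tuple[float, float]:
        off = self.window_offset
        if off is None:
            off = 0.5 * self.window_half_axes[1]
        return (0.0, self.a0 + off)

    def in_window(self, pts: np.ndarray) -> np.ndarray:
        rx, ry = self.window_half_axes
        cx, cy = self.window_center
        p = np.atleast_2d(pts)
        return ((p[:, 0] - cx) / rx) ** 2 + ((p[:, 1] - cy) / ry) ** 2 <= 1.0


@dataclass(frozen=True)
class Osteon:
    """One osteon: centre, outer (lamellar) radius and canal radius, mm."""

    x: float
    y: float
    r_out: float
    r_canal: float

    def __post_init__(self) -> None:
        if not 0.0 < self.r_canal < self.r_out:
            raise ValueError("need 0 < r_canal < r_out")


@dataclass
class Microstructure:
    """Parametric osteon/cement-line layout inside a region of interest.

    ``region`` describes the domain the layout lives in, e.g.
    ``('circle', cx, cy, r)``, ``('ellipse', cx, cy, rx, ry)`` or
    ``('rect', x0, y0, x1, y1)``; it is carried along for serialisation
    and feasibility checks, classification itself is purely geometric.
    """

    osteons: list = field(default_factory=list)
    t_cem: float = 0.005
    region: tuple | None = None

    def validate(self) -> None:
        """Non-overlap (cement annuli included) and canal containment."""
        for o in self.osteons:
            if not o.r_canal < o.r_out:
                raise ValueError("canal must lie strictly inside its osteon")
        n = len(self.osteons)
        if n > 1:
            c = np.array([[o.x, o.y] for o in self.osteons])
            r = np.array([o.r_out for o in self.osteons]) + self.t_cem
            dist = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
            lim = r[:, None] + r[None, :]
            np.fill_diagonal(dist, np.inf)
            if np.any(dist < lim - 1e-12):
                raise ValueError("osteons (including cement annuli) overlap")

    def classify(self, pts: np.ndarray) -> np.ndarray:
        """Tissue labels at points: 'canal', 'osteon', 'cement_line', 'matrix'."""
        p = np.atleast_2d(np.asarray(pts, dtype=float))
        labels = np.full(len(p), "matrix", dtype=object)
        if not self.osteons:
            return labels
        centers = np.array([[o.x, o.y] for o in self.osteons])
        r_out = np.array([o.r_out for o in self.osteons])
        r_can = np.array([o.r_canal for o in self.osteons])
        # distance of every point to every osteon centre (layouts are small)
        d = np.linalg.norm(p[:, None, :] - centers[None, :, :], axis=2)
        near = np.argmin(d - (r_out + self.t_cem)[None, :], axis=1)
        dn = d[np.arange(len(p)), near]
        ro, rc = r_out[near], r_can[near]
        labels[dn < ro + self.t_cem] = "cement_line"
        labels[dn < ro] = "osteon"
        labels[dn < rc] = "canal"
        return labels

    def osteonal_area_fraction(self, domain_area: float) -> float:
        """Whole-osteon disc area (canal included) over the domain area."""
        a = sum(math.pi * o.r_out**2 for o in self.osteons)
        return a / domain_area


def classify_point(micro: Microstructure, point) -> str:
    """Tissue label at a single point (canal/osteon/cement_line/matrix)."""
    return str(micro.classify(np.asarray(point, dtype=float))[0])


def single_osteon_microstructure(spec: SingleOsteonSpec) -> Microstructure:
    """The one-osteon layout of the screening cell (centred in the square)."""
    c = spec.s / 2.0
    return Microstructure(
        osteons=[Osteon(c, c, spec.r_o, spec.r_i)],
        t_cem=spec.t_cem,
        region=("rect", 0.0, 0.0, spec.s, spec.s),
    )


# ----------------------------------------------------------------------------
# graded structured meshing
# ----------------------------------------------------------------------------


def graded_coords(
    lo: float,
    hi: float,
    fine_lo: float,
    fine_hi: float,
    h_fine: float,
    growth: float = 1.35,
    h_max_ratio: float = 8.0,
) -> np.ndarray:
    """1D node coordinates: uniform ``h_fine`` in [fine_lo, fine_hi],
    geometrically coarsening (capped at ``h_max_ratio * h_fine``) outside.

    The fine interval is snapped to a whole number of cells; the coarse
    tails are rescaled to fit [lo, hi] exactly.
    """
    fine_lo = max(lo, fine_lo)
    fine_hi = min(hi, fine_hi)
    if fine_hi <= fine_lo:
        raise ValueError("empty fine interval")
    n_fine = max(1, round((fine_hi - fine_lo) / h_fine))
    fine = np.linspace(fine_lo, fine_hi, n_fine + 1)

    def tail(length: float) -> np.ndarray:
        if length <= 1e-12:
            return np.array([])
        steps = []
        h = h_fine
        total = 0.0
        while total < length:
            h = min(h * growth, h_fine * h_max_ratio)
            steps.append(h)
            total += h
        steps = np.array(steps) * (length / total)
        return np.cumsum(steps)

    left = fine_lo - tail(fine_lo - lo)[::-1]
    right = fine_hi + tail(hi - fine_hi)
    return np.unique(np.concatenate([left, fine, right]))


def _grid_mesh(x: np.ndarray, y: np.ndarray):
    """Tensor-product nodes and CCW quad connectivity."""
    nx, ny = len(x) - 1, len(y) - 1
    X, Y = np.meshgrid(x, y, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    iy, ix = np.divmod(np.arange(nx * ny), nx)
    n0 = iy * (nx + 1) + ix
    elems = np.column_stack([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])
    return nodes, elems


def _compact(nodes, elems, *node_index_arrays):
    """Drop nodes not referenced by any element; remap indices."""
    used = np.zeros(len(nodes), dtype=bool)
    used[elems.ravel()] = True
    new_idx = np.cumsum(used) - 1
    out_sets = []
    for arr in node_index_arrays:
        arr = np.asarray(arr, dtype=np.int64)
        keep = used[arr]
        out_sets.append(new_idx[arr[keep]])
    return nodes[used], new_idx[elems], out_sets, new_idx, used


def _cut_slit(nodes, elems, on_line, above, mouth_hint):
    """Duplicate nodes along a slit; elements on the ``above`` side of the
    line get the duplicates.  Returns updated arrays plus the mouth node
    pair (original, duplicate) nearest ``mouth_hint``."""
    slit_nodes = np.flatnonzero(on_line)
    if len(slit_nodes) == 0:
        raise ValueError("slit does not intersect any mesh node")
    n_old = len(nodes)
    dup = {n: n_old + i for i, n in enumerate(slit_nodes)}
    nodes = np.vstack([nodes, nodes[slit_nodes]])
    elems = elems.copy()
    el_above = np.flatnonzero(above)
    sub = elems[el_above]
    for old, new in dup.items():
        sub[sub == old] = new
    elems[el_above] = sub
    d_mouth = np.linalg.norm(nodes[slit_nodes] - np.asarray(mouth_hint), axis=1)
    mouth = slit_nodes[np.argmin(d_mouth)]
    return nodes, elems, (int(mouth), int(dup[mouth]))


# ----------------------------------------------------------------------------
# single-osteon model
# ----------------------------------------------------------------------------


def build_single_osteon(
    spec: SingleOsteonSpec,
    h_fine: float,
    ell: float | None = None,
    band_height: float | None = None,
    growth: float = 1.35,
) -> Mesh:
    """Mesh the notched single-osteon cell.

    The mesh is uniform ``h_fine`` in x and inside a horizontal band around
    mid-height (where the crack runs), geometrically coarsened above and
    below.  The canal is a hole, the notch a mid-height slit of length
    ``a_notch``, loaded by a prescribed vertical displacement on the top
    edge with the bottom edge vertically constrained.

    Raises if the cement line would be resolved by fewer than 2 elements.
    """
    if spec.t_cem < 2.0 * h_fine - 1e-12:
        raise ValueError(
            f"cement line ({spec.t_cem:g} mm) thinner than 2 elements at "
            f"h_fine={h_fine:g} mm"
        )
    s = spec.s
    yc = s / 2.0
    if band_height is None:
        margin = 4.0 * (ell if ell is not None else 2.0 * h_fine)
        band_height = 2.0 * (spec.r_o + spec.t_cem) + 2.0 * margin
    band_height = min(band_height, s)
    # snap band to an even number of fine cells so yc is a node line
    half = h_fine * max(1, round(band_height / (2.0 * h_fine)))
    x = np.linspace(0.0, s, round(s / h_fine) + 1)
    y = graded_coords(0.0, s, yc - half, yc + half, h_fine, growth)
    # make sure yc is exactly on the grid
    y[np.argmin(np.abs(y - yc))] = yc
    nodes, elems = _grid_mesh(x, y)

    micro = single_osteon_microstructure(spec)
    cent = nodes[elems].mean(axis=1)
    labels = micro.classify(cent)
    keep = labels != "canal"
    elems, labels, cent = elems[keep], labels[keep], cent[keep]

    # slit: nodes at y = yc strictly left of the tip
    tip_x = h_fine * round(spec.a_notch / h_fine)
    on_line = (np.abs(nodes[:, 1] - yc) < 1e-12) & (nodes[:, 0] < tip_x - h_fine / 2.0)
    above = cent[:, 1] > yc
    nodes, elems, mouth_pair = _cut_slit(nodes, elems, on_line, above, (0.0, yc))

    top = np.flatnonzero(np.abs(nodes[:, 1] - s) < 1e-12)
    bottom = np.flatnonzero(np.abs(nodes[:, 1]) < 1e-12)
    pin = bottom[np.argmin(nodes[bottom, 0])]
    nodes, elems, (top, bottom, pin_arr, mouth_arr), _, _ = _compact(
        nodes, elems, top, bottom, [pin], list(mouth_pair)
    )

    material_id = np.array([_MATERIAL_CODES[l] for l in labels])
    cent = nodes[elems].mean(axis=1)
    pf_active = np.abs(cent[:, 1] - yc) < half + 1e-12

    mesh = Mesh(
        nodes=nodes,
        elems=elems,
        material_id=material_id,
        material_names=dict(_CODE_NAMES),
        pf_active=pf_active,
        node_sets={
            "top": top,
            "bottom": bottom,
            "pin": pin_arr,
            "notch_mouth": mouth_arr,
        },
        metadata={
            "bc": [
                {"set": "bottom", "axis": "y", "kind": "fixed"},
                {"set": "pin", "axis": "x", "kind": "fixed"},
                {"set": "top", "axis": "y", "kind": "control", "direction": 1.0},
            ],
            "cmod": {"nodes": (int(mouth_arr[0]), int(mouth_arr[1])), "axis": "y"},
            "ligament": {
                "axis": "x",
                "tip": (tip_x, yc),
                "a0": tip_x,
                "length": s - tip_x,
            },
            "h_fine": h_fine,
            "band": (yc - half, yc + half),
            "domain": (0.0, 0.0, s, s),
            "micro": micro,
        },
    )
    return mesh


def build_strip(
    width: float,
    height: float,
    h_fine: float,
    a_notch: float = 0.0,
    ell: float | None = None,
    band_height: float | None = None,
    growth: float = 1.35,
    tissue: str = "matrix",
) -> Mesh:
    """Homogeneous rectangular strip in vertical tension, optionally with a
    mid-height edge slit (the channel-crack / uniaxial benchmarks).

    Bottom edge vertically constrained, one corner pinned horizontally, top
    edge displacement-controlled.  Uniform ``h_fine`` in x and in a band
    around mid-height, coarsened towards top and bottom.
    """
    yc = height / 2.0
    if band_height is None:
        band_height = min(height, 8.0 * (ell if ell is not None else 2.0 * h_fine))
    half = h_fine * max(1, round(min(band_height, height) / (2.0 * h_fine)))
    x = np.linspace(0.0, width, max(2, round(width / h_fine)) + 1)
    if 2.0 * half >= height - 1e-12:
        y = np.linspace(0.0, height, max(2, round(height / h_fine)) + 1)
    else:
        y = graded_coords(0.0, height, yc - half, yc + half, h_fine, growth)
    y[np.argmin(np.abs(y - yc))] = yc
    nodes, elems = _grid_mesh(x, y)

    mouth_pair = None
    tip_x = 0.0
    if a_notch > 0.0:
        tip_x = h_fine * round(a_notch / h_fine)
        cent = nodes[elems].mean(axis=1)
        on_line = (np.abs(nodes[:, 1] - yc) < 1e-12) & (
            nodes[:, 0] < tip_x - h_fine / 2.0
        )
        nodes, elems, mouth_pair = _cut_slit(
            nodes, elems, on_line, cent[:, 1] > yc, (0.0, yc)
        )

    top = np.flatnonzero(np.abs(nodes[:, 1] - height) < 1e-12)
    bottom = np.flatnonzero(np.abs(nodes[:, 1]) < 1e-12)
    pin = [bottom[np.argmin(nodes[bottom, 0])]]
    material_id = np.full(len(elems), _MATERIAL_CODES[tissue])
    cent = nodes[elems].mean(axis=1)
    pf_active = np.abs(cent[:, 1] - yc) <= half + 1e-12

    metadata = {
        "bc": [
            {"set": "bottom", "axis": "y", "kind": "fixed"},
            {"set": "pin", "axis": "x", "kind": "fixed"},
            {"set": "top", "axis": "y", "kind": "control", "direction": 1.0},
        ],
        "ligament": {
            "axis": "x",
            "tip": (tip_x, yc),
            "a0": tip_x,
            "length": width - tip_x,
        },
        "h_fine": h_fine,
        "band": (yc - half, yc + half),
        "domain": (0.0, 0.0, width, height),
    }
    node_sets = {"top": top, "bottom": bottom, "pin": np.asarray(pin)}
    if mouth_pair is not None:
        node_sets["notch_mouth"] = np.asarray(mouth_pair)
        metadata["cmod"] = {"nodes": mouth_pair, "axis": "y"}
    return Mesh(
        nodes=nodes,
        elems=elems,
        material_id=material_id,
        material_names=dict(_CODE_NAMES),
        pf_active=pf_active,
        node_sets=node_sets,
        metadata=metadata,
    )


# ----------------------------------------------------------------------------
# SENB model
# ----------------------------------------------------------------------------


def build_senb(
    spec: SENBSpec,
    micro: Microstructure | None,
    h_fine: float,
    ell: float | None = None,
    corridor_width: float = 0.6,
    fine_margin: float | None = None,
    fine_extent: float | None = None,
    growth: float = 1.35,
    h_max_ratio: float = 24.0,
) -> Mesh:
    """Mesh the three-point-bend beam with an embedded-cell window.

    Origin at the notch mouth, y upward along the ligament; the beam spans
    x in [-L/2, L/2], y in [0, h].  The mesh is fine inside a vertical
    corridor of width ``corridor_width`` above the notch, extending over
    the window; phase-field damage is active only inside the window, the
    rest of the beam is linear elastic with matrix properties.  Supports:
    pin at the lower-left corner, roller (vertical) at the lower-right
    corner; a prescribed downward displacement drives the top mid-span.
    """
    if micro is not None and micro.t_cem < 2.0 * h_fine - 1e-12:
        raise ValueError("cement line thinner than 2 elements at this h_fine")
    L, h, a0 = spec.L, spec.h, spec.a0
    cx, cy = spec.window_center
    rx, ry = spec.window_half_axes
    if fine_margin is None:
        fine_margin = 4.0 * (ell if ell is not None else 2.0 * h_fine)
    x_lo = max(-L / 2.0, -corridor_width / 2.0)
    x_hi = min(L / 2.0, corridor_width / 2.0)
    y_lo = max(0.0, min(a0 - fine_margin, cy - ry))
    y_hi = min(h, cy + ry + fine_margin)
    if fine_extent is not None:
        # limit the fine band to the stretch of ligament the crack will
        # actually traverse; window elements outside stay phase-field
        # active but coarser
        y_hi = min(y_hi, a0 + fine_extent)
        y_lo = max(0.0, a0 - fine_margin)
    x = graded_coords(-L / 2.0, L / 2.0, x_lo, x_hi, h_fine, growth, h_max_ratio)
    y = graded_coords(0.0, h, y_lo, y_hi, h_fine, growth, h_max_ratio)
    # exact node lines for the slit (x = 0) and key y stations
    x[np.argmin(np.abs(x))] = 0.0
    tip_y = y[np.argmin(np.abs(y - a0))]
    nodes, elems = _grid_mesh(x, y)

    cent = nodes[elems].mean(axis=1)
    in_win = spec.in_window(cent)
    labels = np.full(len(elems), "elastic", dtype=object)
    if micro is not None:
        labels[in_win] = micro.classify(cent[in_win])
    else:
        labels[in_win] = "matrix"
    keep = labels != "canal"
    elems, labels, cent, in_win = elems[keep], labels[keep], cent[keep], in_win[keep]

    on_line = (np.abs(nodes[:, 0]) < 1e-12) & (nodes[:, 1] < tip_y - 1e-12)
    # "above" for a vertical slit = elements to the right (x > 0)
    right = cent[:, 0] > 0.0
    nodes, elems, mouth_pair = _cut_slit(nodes, elems, on_line, right, (0.0, 0.0))

    support_l = [int(np.argmin(np.hypot(nodes[:, 0] + L / 2.0, nodes[:, 1])))]
    support_r = [int(np.argmin(np.hypot(nodes[:, 0] - L / 2.0, nodes[:, 1])))]
    load_top = [int(np.argmin(np.hypot(nodes[:, 0], nodes[:, 1] - h)))]
    nodes, elems, (sl, sr, lt, mouth_arr), _, _ = _compact(
        nodes, elems, support_l, support_r, load_top, list(mouth_pair)
    )

    material_id = np.array([_MATERIAL_CODES[l] for l in labels])
    cent = nodes[elems].mean(axis=1)
    pf_active = spec.in_window(cent) & (material_id != _MATERIAL_CODES["elastic"])

    mesh = Mesh(
        nodes=nodes,
        elems=elems,
        material_id=material_id,
        material_names=dict(_CODE_NAMES),
        pf_active=pf_active,
        node_sets={
            "support_left": sl,
            "support_right": sr,
            "load": lt,
            "notch_mouth": mouth_arr,
        },
        metadata={
            "bc": [
                {"set": "support_left", "axis": "both", "kind": "fixed"},
                {"set": "support_right", "axis": "y", "kind": "fixed"},
                {"set": "load", "axis": "y", "kind": "control", "direction": -1.0},
            ],
            "cmod": {"nodes": (int(mouth_arr[0]), int(mouth_arr[1])), "axis": "x"},
            "ligament": {
                "axis": "y",
                "tip": (0.0, tip_y),
                "a0": tip_y,
                "length": h - tip_y,
            },
            "h_fine": h_fine,
            "band": (x_lo, x_hi),
            "domain": (-L / 2.0, 0.0, L / 2.0, h),
            "micro": micro,
            "senb_spec": spec,
        },
    )
    return mesh


# ----------------------------------------------------------------------------
# layout serialisation (shared by traced and synthetic microstructures)
# ----------------------------------------------------------------------------


def write_layout(micro: Microstructure, path: str | Path) -> None:
    """Write a microstructure to the structured-text layout format.

    Plain text, mm units: a header with cement thickness and region, then
    one ``x y r_out r_canal`` line per osteon.
    """
    lines = ["# osteofrac microstructure layout v1 (units: mm)"]
    lines.append(f"t_cem = {micro.t_cem!r}")
    region = " ".join(str(v) for v in (micro.region or ()))
    lines.append(f"region = {region}")
    lines.append("# x y r_out r_canal")
    for o in micro.osteons:
        lines.append(f"{o.x!r} {o.y!r} {o.r_out!r} {o.r_canal!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_layout(path: str | Path) -> Microstructure:
    """Read a microstructure layout file written by :func:`write_layout`."""
    osteons = []
    t_cem = None
    region = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, val = (s.strip() for s in line.split("=", 1))
            if key == "t_cem":
                t_cem = float(val)
            elif key == "region" and val:
                parts = val.split()
                region = (parts[0], *map(float, parts[1:]))
            continue
        x, y, ro, rc = map(float, line.split())
        osteons.append(Osteon(x, y, ro, rc))
    if t_cem is None:
        raise ValueError(f"{path}: missing t_cem header")
    micro = Microstructure(osteons=osteons, t_cem=t_cem, region=region)
    micro.validate()
    return micro
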