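"""File I/O: VTK field snapshots, history CSV round-trips, run configs.

All writers use the mm-N-MPa unit system and say so in their headers.
Field snapshots are legacy-ASCII VTK unstructured grids (point data: u, d;
cell data: material id, max history per element) readable by standard mesh
viewers; step histories are CSV with unit-bearing column names that
round-trip bit-exactly through :func:`read_history`.
"""

from __future__ import annotations

import configparser
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fem import DofState, Mesh, SimulationHistory

__all__ = [
    "write_vtk",
    "write_fields",
    "write_history",
    "read_history",
    "RunConfig",
    "load_run_config",
    "write_manifest",
]


def write_vtk(
    mesh: Mesh,
    path: str | Path,
    point_data: dict | None = None,
    cell_data: dict | None = None,
    title: str = "osteofrac fields (units: mm, MPa)",
) -> None:
    """Write the mesh and fields as a legacy-ASCII VTK unstructured grid.

    ``point_data`` values are (n,) scalars or (n, 2) vectors (padded with
    a zero z-component); ``cell_data`` values are (m,) scalars.
    """
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_elems
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.10g} {y:.10g} 0")
    lines.append(f"CELLS {m} {5 * m}")
    for quad in mesh.elems:
        lines.append("4 " + " ".join(str(int(v)) for v in quad))
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["9"] * m)  # VTK_QUAD

    def _scalars(name, vals, fmt="{:.10g}"):
        out = [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
        out.extend(fmt.format(float(v)) for v in vals)
        return out

    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, vals in point_data.items():
            vals = np.asarray(vals)
            if vals.ndim == 2:
                lines.append(f"VECTORS {name} double")
                for vx, vy in vals:
                    lines.append(f"{vx:.10g} {vy:.10g} 0")
            else:
                lines.extend(_scalars(name, vals))
    if cell_data:
        lines.append(f"CELL_DATA {m}")
        for name, vals in cell_data.items():
            lines.extend(_scalars(name, vals))
    path.write_text("\n".join(lines) + "\n")


def write_fields(state: DofState, mesh: Mesh, path: str | Path) -> None:
    """Snapshot the displacement/damage state of a run as VTK."""
    if len(state.u) != 2 * mesh.n_nodes or len(state.d) != mesh.n_nodes:
        raise ValueError("state does not match mesh")
    write_vtk(
        mesh,
        path,
        point_data={"u": state.u.reshape(-1, 2), "d": state.d},
        cell_data={
            "material_id": mesh.material_id.astype(float),
            "H_max": state.H.max(axis=1),
        },
    )


_HISTORY_COLUMNS = {
    "applied_u_mm": "applied_u",
    "force_N": "force",
    "cmod_mm": "cmod",
    "strain_energy_Nmm": "strain_energy",
    "dissipated_energy_Nmm": "dissipated_energy",
    "crack_length_mm": "crack_length",
}


def write_history(history: SimulationHistory, path: str | Path) -> None:
    """Write a step history as CSV (units in the header names)."""
    if len(history) == 0:
        raise ValueError("refusing to write an empty history")
    df = pd.DataFrame(
        {col: getattr(history, attr) for col, attr in _HISTORY_COLUMNS.items()}
    )
    with open(path, "w") as fh:
        fh.write(
            f"# osteofrac history v1; thickness_mm={history.thickness!r}; "
            f"a0_mm={history.a0!r}; failed={history.failed}\n"
        )
        df.to_csv(fh, index=False, float_format="%.17g")


def read_history(path: str | Path) -> SimulationHistory:
    """Read a history CSV back into a :class:`SimulationHistory`.

    Arrays round-trip bit-exactly (17 significant digits); snapshots are
    not serialised here (field snapshots live in VTK files).
    """
    path = Path(path)
    header = path.open().readline()
    meta = {}
    if header.startswith("#"):
        for part in header.lstrip("#").split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    kwargs = {attr: df[col].to_numpy() for col, attr in _HISTORY_COLUMNS.items()}
    return SimulationHistory(
        snapshots=[],
        thickness=float(meta.get("thickness_mm", 1.0)),
        a0=float(meta.get("a0_mm", 0.0)),
        failed=meta.get("failed", "False") == "True",
        **kwargs,
    )


# ----------------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------------

_STAGES = ("simulate", "screen", "respsurf", "calibrate", "validate", "synth", "postprocess")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline stage.

    Mirrors the flat key = value config file: a ``[run]`` section naming
    the stage, seed, mesh scale and output directory, plus the sections
    owned by the other modules (tissue blocks, phase field, geometry,
    load program).
    """

    stage: str
    seed: int = 0
    mesh_scale: float = 1.0
    outdir: Path = Path("out")
    sections: dict = field(default_factory=dict)
    source: Path | None = None

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r}; expected one of {_STAGES}"
            )
        if self.mesh_scale <= 0.0:
            raise ValueError("mesh_scale must be positive")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a flat INI-style run config; errors name the offending field."""
    cp = configparser.ConfigParser(inline_comment_prefixes=("#",))
    if not cp.read(Path(path)):
        raise FileNotFoundError(path)
    if not cp.has_section("run"):
        raise ValueError(f"{path}: missing [run] section")
    run = cp["run"]
    if "stage" not in run:
        raise ValueError(f"{path}: [run] section missing 'stage'")
    sections = {s: dict(cp[s]) for s in cp.sections() if s != "run"}
    return RunConfig(
        stage=run["stage"],
        seed=run.getint("seed", fallback=0),
        mesh_scale=run.getfloat("mesh_scale", fallback=1.0),
        outdir=Path(run.get("outdir", "out")),
        sections=sections,
        source=Path(path),
    )


def write_manifest(
    outdir: str | Path, config: RunConfig, artifacts: list, t_start: float
) -> Path:
    """Write the run manifest (resolved config, seed, wall time, outputs)."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "osteofrac",
        "version": __version__,
        "stage": config.stage,
        "seed": config.seed,
        "mesh_scale": config.mesh_scale,
        "config_file": str(config.source) if config.source else None,
        "sections": config.sections,
        "artifacts": [str(a) for a in artifacts],
        "wall_time_s": round(time.time() - t_start, 3),
        "units": "mm-N-MPa",
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
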