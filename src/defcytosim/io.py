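"""Output writers: CSV tables, NPZ field dumps, legacy-VTK files, manifests.

VTK output uses the legacy ASCII format (structured points for fluid
fields, unstructured grid for the cell mesh) so snapshots open directly
in ParaView without extra dependencies.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import SimConfig
from .coupling import Trajectory
from .fluid import FluidGrid, FluidState
from .solid import CellMesh

__all__ = [
    "RunManifest",
    "write_trajectory_csv",
    "write_fields_npz",
    "write_fluid_vtk",
    "write_cell_vtk",
    "write_cell_csv",
]


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """One row per sample: t, x, y, V0, V1, DI, area, tau."""
    traj.to_dataframe().to_csv(path, index=False)


def write_fields_npz(state: FluidState, grid: FluidGrid, path) -> None:
    np.savez(
        path,
        u=state.u, v=state.v, p=state.p, t=np.array(state.t),
        h=np.array(grid.h), fluid=grid.fluid,
    )


def write_fluid_vtk(state: FluidState, grid: FluidGrid, path) -> None:
    """Cell-centered velocity/pressure as a legacy-VTK structured grid."""
    ny, nx = grid.ny, grid.nx
    uc = 0.5 * (state.u[:, :-1] + state.u[:, 1:])
    vc = 0.5 * (state.v[:-1, :] + state.v[1:, :])
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ndefcytosim fluid snapshot\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} 1\n")
        f.write(f"ORIGIN {grid.h / 2:g} {grid.h / 2:g} 0\n")
        f.write(f"SPACING {grid.h:g} {grid.h:g} {grid.h:g}\n")
        f.write(f"POINT_DATA {nx * ny}\n")
        f.write("SCALARS pressure double 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, state.p.ravel()[None], fmt="%.9g")
        f.write("VECTORS velocity double\n")
        vec = np.column_stack([uc.ravel(), vc.ravel(), np.zeros(nx * ny)])
        np.savetxt(f, vec, fmt="%.9g")


def write_cell_vtk(mesh: CellMesh, path) -> None:
    """Cell mesh as a legacy-VTK unstructured (triangle) grid."""
    n, m = mesh.n_nodes, len(mesh.triangles)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ndefcytosim cell mesh\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        pts = np.column_stack([mesh.cur_nodes, np.zeros(n)])
        np.savetxt(f, pts, fmt="%.9g")
        f.write(f"CELLS {m} {4 * m}\n")
        cells = np.column_stack([np.full(m, 3), mesh.triangles])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {m}\n")
        np.savetxt(f, np.full(m, 5)[None], fmt="%d")
        f.write(f"POINT_DATA {n}\nVECTORS velocity double\n")
        vel = np.column_stack([mesh.node_velocities, np.zeros(n)])
        np.savetxt(f, vel, fmt="%.9g")


def write_cell_csv(mesh: CellMesh, nodes_path, triangles_path) -> None:
    import pandas as pd
    pd.DataFrame({
        "x_ref": mesh.ref_nodes[:, 0], "y_ref": mesh.ref_nodes[:, 1],
        "x": mesh.cur_nodes[:, 0], "y": mesh.cur_nodes[:, 1],
        "vx": mesh.node_velocities[:, 0], "vy": mesh.node_velocities[:, 1],
    }).to_csv(nodes_path, index=False)
    pd.DataFrame(mesh.triangles, columns=["n0", "n1", "n2"]).to_csv(
        triangles_path, index=False)


@dataclass
class RunManifest:
    """Reproducibility record for one CLI invocation.

    The embedded config snapshot is sufficient to reproduce the run
    bit-identically (the pipeline itself is deterministic).
    """

    command: str
    config: dict
    started: float
    outputs: list = field(default_factory=list)
    finished: float = 0.0
    exit_status: int = 0
    version: str = __version__

    def add(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        """Atomic write (tmp + rename) at run end."""
        self.finished = time.time()
        path = Path(path)
        tmp = path.with_suffix(path.suffix + ".tmp")
        tmp.write_text(json.dumps({
            "command": self.command,
            "package_version": self.version,
            "config": self.config,
            "started_unix": self.started,
            "finished_unix": self.finished,
            "outputs": self.outputs,
            "exit_status": self.exit_status,
        }, indent=2, sort_keys=True) + "\n")
        os.replace(tmp, path)

    @classmethod
    def start(cls, command: str, config: SimConfig | dict) -> "RunManifest":
        cfg = config.to_dict() if isinstance(config, SimConfig) else dict(config)
        return cls(command=command, config=cfg, started=time.time())
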