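"""Plain-text exporters: legacy-VTK structured fields and tabular records.

The VTK writer emits ASCII ``STRUCTURED_POINTS`` legacy files (readable
by ParaView and pyvista) for 3D cell fields — matric potential, water
content, sink density, material and compartment maps.  Xylem solutions
export as per-segment tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rootflow3d.domain import SoilGrid, SoilState
from rootflow3d.doussan import XylemSolution
from rootflow3d.root_architecture import RootSystem

__all__ = ["write_vtk_state", "xylem_solution_table"]


def write_vtk_state(path, state: SoilState, fields=("psi", "theta", "sink")
                    ) -> None:
    """Write cell fields of a soil state as a legacy-VTK ASCII file."""
    g = state.grid
    arrays = {
        "psi": state.psi, "theta": state.theta, "sink": state.sink,
        "material": g.material_index.astype(float),
        "compartment": g.compartment.astype(float),
    }
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"soil state t={state.time:.6f} d\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {g.nx + 1} {g.ny + 1} {g.nz + 1}\n")
        f.write(f"ORIGIN {-g.nx * g.dx / 2} {-g.ny * g.dy / 2} "
                f"{-g.height}\n")
        f.write(f"SPACING {g.dx} {g.dy} {g.dz}\n")
        f.write(f"CELL_DATA {g.n_cells}\n")
        for name in fields:
            arr = arrays[name]
            # VTK expects x fastest, z slowest; flip z so k=0 is the bottom
            vals = np.transpose(arr[:, :, ::-1], (2, 1, 0)).ravel()
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, vals, fmt="%.6g")


def xylem_solution_table(system: RootSystem,
                         sol: XylemSolution) -> pd.DataFrame:
    """Per-segment record of a solved xylem state (one row per segment)."""
    j = system.seg_nodes()
    df = pd.DataFrame({
        "segment": j,
        "parent": system.parent[j],
        "x": system.pos[j, 0], "y": system.pos[j, 1], "z": system.pos[j, 2],
        "order": system.order[j],
        "t_s": system.t_s[j],
        "psi_x": sol.psi_x[j],
        "J_r": sol.J_r[j],
        "J_x": sol.J_x[j],
        "psi_s_int": sol.psi_s_int[j],
    })
    if sol.suf is not None:
        df["SUF"] = sol.suf[j]
    return df
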