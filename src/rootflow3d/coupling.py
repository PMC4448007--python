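"""Soil-root exchange: interface potentials, sink aggregation, coupled step.

The two flow problems communicate through (i) the soil-root interface
potential psi_s,int of every root segment, defined as the trilinear
(distance-weighted) interpolation of the soil potential at the segment
midpoint, and (ii) the sink density of every soil voxel,
``S_i = sum_k J_r,k / V`` over the segments inside it, so that
``sum_i S_i V = T_act`` holds exactly.

Segments that span several voxels are split at voxel-face planes when
the map is built; each sub-piece contributes its length fraction to the
voxel it lies in, which makes the sink attribution unambiguous.  The
interpolation stencil is restricted to soil voxels: weights on wall or
split-layer cells (hydraulically inert or frozen) are dropped and the
remainder renormalized; a sub-piece whose midpoint falls inside a layer
slab is snapped to the nearest soil cell in its column (roots merely
pierce the wax).

``coupled_step`` advances soil and root states together over one time
step with a fixed-point sweep (interface potentials -> xylem solve ->
sink -> Richards step), iterated until the interface potentials change
by less than a tolerance (default 1 hPa) or a sweep cap is reached; a
lagged (single-sweep) mode is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from rootflow3d.domain import SoilGrid, SoilState
from rootflow3d.doussan import XylemSolution, solve_xylem
from rootflow3d.richards import (
    RichardsConfig,
    RichardsWorkspace,
    richards_step,
)
from rootflow3d.root_architecture import RootSystem

__all__ = ["SegmentSoilMap", "interface_potentials", "sink_field",
           "coupled_step"]


def _split_points(a: np.ndarray, b: np.ndarray, grid: SoilGrid):
    """Parametric positions (0,1) where segment a->b crosses voxel faces."""
    ts = []
    x0 = -grid.nx * grid.dx / 2.0
    y0 = -grid.ny * grid.dy / 2.0
    for axis, (orig, d, nn) in enumerate([
            (x0, grid.dx, grid.nx), (y0, grid.dy, grid.ny),
            (0.0, -grid.dz, grid.nz)]):
        lo, hi = a[axis], b[axis]
        if lo == hi:
            continue
        i0 = (lo - orig) / d
        i1 = (hi - orig) / d
        for i in range(int(np.ceil(min(i0, i1) + 1e-12)),
                       int(np.floor(max(i0, i1) - 1e-12)) + 1):
            t = (orig + i * d - lo) / (hi - lo)
            if 1e-12 < t < 1.0 - 1e-12:
                ts.append(t)
    return sorted(ts)


class SegmentSoilMap:
    """Geometric coupling between a root system and a soil grid.

    Built once per (architecture, grid) pair — the full architecture's
    geometry is static; growth only activates segments.  Rows of the
    interpolation operator ``W`` (n_nodes x n_cells) sum to 1; columns of
    the deposition operator ``B`` (n_cells x n_nodes) sum to 1 per
    segment.  ``psi_s_int = W @ psi``; ``S = (B @ J_r) / V``.

    ``deposition='stencil'`` (default) deposits each sub-piece's radial
    flow onto the same trilinear stencil cells used to sense its
    interface potential (``B = W^T``); this sensing/deposition
    consistency gives the coupled fixed point a negative feedback (a
    drying cell is felt by exactly the segments that drain it) and is
    the cell-centered analog of nodal sink attribution on a
    vertex-centered grid.  ``deposition='enclosing'`` assigns the whole
    sub-piece flow to its enclosing voxel instead.
    """

    def __init__(self, grid: SoilGrid, system: RootSystem,
                 deposition: str = "stencil"):
        self.grid = grid
        self.system = system
        n = system.n_nodes
        soil_flat = grid.is_soil.ravel()
        xc, yc, zc = grid.cell_centers()
        x0 = xc[0] - grid.dx / 2.0 + grid.dx / 2.0  # first center
        rows_w, cols_w, vals_w = [], [], []
        rows_b, cols_b, vals_b = [], [], []

        nz = grid.nz
        soil_col = grid.is_soil  # (nx, ny, nz)

        def cell_of(p):
            i = int((p[0] + grid.nx * grid.dx / 2.0) / grid.dx)
            j = int((p[1] + grid.ny * grid.dy / 2.0) / grid.dy)
            k = int(-p[2] / grid.dz)
            if not (0 <= i < grid.nx and 0 <= j < grid.ny and 0 <= k < nz):
                raise ValueError(
                    f"root segment at {p} lies outside the soil grid")
            return i, j, k

        def snap_to_soil(i, j, k):
            if soil_col[i, j, k]:
                return i, j, k
            col = soil_col[i, j, :]
            if not col.any():
                raise ValueError(
                    f"root segment in column ({i},{j}) with no soil cells "
                    "(outside the cylinder)")
            ks = np.nonzero(col)[0]
            return i, j, int(ks[np.argmin(np.abs(ks - k))])

        def trilinear(p):
            """Soil-restricted trilinear weights at point p."""
            u = (p[0] - xc[0]) / grid.dx
            v = (p[1] - yc[0]) / grid.dy
            w = (zc[0] - p[2]) / grid.dz     # z decreasing with k
            iu = int(np.clip(np.floor(u), 0, grid.nx - 2))
            iv = int(np.clip(np.floor(v), 0, grid.ny - 2))
            iw = int(np.clip(np.floor(w), 0, nz - 2))
            fu = np.clip(u - iu, 0.0, 1.0)
            fv = np.clip(v - iv, 0.0, 1.0)
            fw = np.clip(w - iw, 0.0, 1.0)
            out = []
            for di, wu in ((0, 1 - fu), (1, fu)):
                for dj, wv in ((0, 1 - fv), (1, fv)):
                    for dk, ww in ((0, 1 - fw), (1, fw)):
                        wt = wu * wv * ww
                        if wt <= 0.0:
                            continue
                        ci, cj, ck = iu + di, iv + dj, iw + dk
                        if soil_col[ci, cj, ck]:
                            out.append(((ci * grid.ny + cj) * nz + ck, wt))
            tot = sum(w for _, w in out)
            if tot <= 0.0:
                ci, cj, ck = snap_to_soil(*cell_of(p))
                return [((ci * grid.ny + cj) * nz + ck, 1.0)]
            return [(c, w / tot) for c, w in out]

        L = system.lengths()
        for seg in range(1, n):
            a = system.pos[system.parent[seg]]
            b = system.pos[seg]
            ts = [0.0] + _split_points(a, b, grid) + [1.0]
            for t0, t1 in zip(ts[:-1], ts[1:]):
                frac = t1 - t0
                if frac <= 1e-12:
                    continue
                mid = a + ((t0 + t1) / 2.0) * (b - a)
                i0, j0, k0 = cell_of(mid)
                i, j, k = snap_to_soil(i0, j0, k0)
                flat = (i * grid.ny + j) * nz + k
                if deposition == "enclosing":
                    rows_b.append(flat)
                    cols_b.append(seg)
                    vals_b.append(frac)
                elif deposition != "stencil":
                    raise ValueError(
                        f"unknown deposition mode {deposition!r}")
                if k != k0:
                    # midpoint sat inside a layer slab: interpolate at the
                    # snapped soil cell's depth instead
                    pt = np.array([mid[0], mid[1], -(k + 0.5) * grid.dz])
                else:
                    pt = mid
                for c, w in trilinear(pt):
                    rows_w.append(seg)
                    cols_w.append(c)
                    vals_w.append(frac * w)

        nc = grid.n_cells
        self.deposition = deposition
        self.W = sp.csr_matrix((vals_w, (rows_w, cols_w)), shape=(n, nc))
        if deposition == "stencil":
            self.B = self.W.T.tocsr()
        else:
            self.B = sp.csr_matrix((vals_b, (rows_b, cols_b)),
                                   shape=(nc, n))

    def restrict(self, active: RootSystem):
        """(W, B) operators for an active subset carrying source_index."""
        idx = active.source_index
        if idx is None:
            idx = np.arange(active.n_nodes)
        return self.W[idx], self.B[:, idx]


def interface_potentials(state: SoilState, smap: SegmentSoilMap,
                         active: RootSystem | None = None) -> np.ndarray:
    """psi_s,int per segment [hPa] (indexed by node; entry 0 = collar)."""
    if active is None:
        return smap.W @ state.psi.ravel()
    W, _ = smap.restrict(active)
    return W @ state.psi.ravel()


def sink_field(J_r: np.ndarray, smap: SegmentSoilMap,
               active: RootSystem | None = None) -> np.ndarray:
    """Sink density S [d^-1] per voxel from the radial inflow field.

    ``sum_i S_i V`` equals ``sum_k J_r,k`` to machine precision.
    """
    if active is None:
        dep = smap.B @ J_r
    else:
        _, B = smap.restrict(active)
        dep = B @ J_r
    return (dep / smap.grid.cell_volume).reshape(smap.grid.shape)


def coupled_step(state: SoilState, system: RootSystem,
                 smap: SegmentSoilMap, kr: np.ndarray, kx: np.ndarray,
                 dt: float, collar_bc: tuple[str, float],
                 config: RichardsConfig | None = None,
                 workspace: RichardsWorkspace | None = None,
                 flux_plane_depths: tuple[float, ...] = (),
                 tol_interface: float = 1.0, max_sweeps: int = 5,
                 mode: str = "iterated", gravity: bool = True):
    """Advance soil + root states together over ``dt`` days.

    ``system`` is the *active* root system for this step (with
    ``source_index`` into the architecture the map was built for);
    ``kr``/``kx`` its per-node conductances.  Fixed-point sweep:
    interface potentials -> xylem solve -> sink field -> Richards step,
    repeated until psi_s,int moves less than ``tol_interface`` hPa
    between sweeps (max ``max_sweeps``); ``mode='lagged'`` performs a
    single sweep with the sink computed from the pre-step soil state.

    Returns ``(new_state, xylem_solution, diagnostics)``.
    """
    from rootflow3d.richards import RichardsStepError

    W, B = smap.restrict(system)
    psi_flat = state.psi.ravel()
    psi_int = W @ psi_flat
    sweeps = 1 if mode == "lagged" else max_sweeps
    new_state = None
    sol = None
    diag = None
    delta = 0.0
    for sweep in range(sweeps):
        sol = solve_xylem(system, kr, kx, psi_int, collar_bc,
                          gravity=gravity)
        S = (B @ sol.J_r / smap.grid.cell_volume).reshape(state.grid.shape)
        new_state, diag = richards_step(
            state, dt, S, config=config, workspace=workspace,
            flux_plane_depths=flux_plane_depths, max_substeps=16)
        psi_int_new = W @ new_state.psi.ravel()
        delta = float(np.max(np.abs(psi_int_new - psi_int))) \
            if len(psi_int) else 0.0
        psi_int = psi_int_new
        if mode == "lagged" or delta < tol_interface:
            break
    if mode != "lagged" and delta > 100.0 * tol_interface:
        # the frozen-sink assumption broke down inside this interval:
        # refuse the step so the caller refines and re-solves the xylem
        raise RichardsStepError(
            f"coupling sweep did not settle (interface moved {delta:.1f} "
            f"hPa) at t={state.time:.5f} d; shorten the coupling step",
            state)
    diag.coupling_sweeps = sweep + 1
    return new_state, sol, diag
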