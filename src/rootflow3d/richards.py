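"""Implicit 3D Richards solver on the voxel grid.

Mixed-form (water-content/pressure) backward-Euler scheme with modified
Picard linearization: per cell i and iterate m,

    V/dt [ C(psi^m)(psi^{m+1} - psi^m) + theta(psi^m) - theta^n ]
        = sum_faces T_f (H^{m+1}_nb - H^{m+1}_i)  -  S_i V  ,

with total head H = psi + z and face transmissibility
T_f = K_face * area / distance.  The mixed form makes the converged step
mass-conservative up to the linearization gap of the last iterate, which
is tracked explicitly in the step diagnostics.

Face conductivity is the arithmetic mean of the two cell K(psi) values
within homogeneous material, and the harmonic (series) mean across
material interfaces, so an impermeable layer (K = 0) blocks flow exactly
and a semi-conductive layer governs the face.

All outer boundaries are zero-flux.  A small specific storage
(Ss = 1e-6 cm^-1) keeps the system regular in saturated and impermeable
cells; its contribution is included in the mass ledger so conservation
statements remain exact.

The sink field S [d^-1] is an uptake density (>= 0 extracts water) and
must vanish outside soil voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from rootflow3d.domain import SoilGrid, SoilState
from rootflow3d.soil_hydraulics import (
    hydraulic_conductivity,
    water_capacity,
    water_content,
)

__all__ = ["RichardsConfig", "RichardsWorkspace", "richards_step",
           "internode_conductivity", "vertical_flux_across_plane"]

SS_COMPRESS = 1e-8   # cm^-1 specific storage regularization


@dataclass
class RichardsConfig:
    """Numerical settings of the implicit scheme."""

    dt_max: float = 0.02          # d
    dt_min: float = 1e-5          # d
    tol_psi: float = 0.5          # hPa, Picard increment tolerance
    tol_mass: float = 1e-3        # cm^3, per-step linearization-gap bound
    max_picard: int = 25
    conductivity_averaging: str = "arithmetic"  # within-material mode

    def __post_init__(self):
        if self.dt_min <= 0 or self.dt_max < self.dt_min:
            raise ValueError("need 0 < dt_min <= dt_max")
        if self.tol_psi <= 0 or self.tol_mass <= 0:
            raise ValueError("tolerances must be > 0")


class RichardsStepError(RuntimeError):
    """Raised when the step fails below the minimum time step; carries the
    last state for post-mortem inspection."""

    def __init__(self, msg, state):
        super().__init__(msg)
        self.state = state


@dataclass
class StepDiagnostics:
    picard_iterations: int = 0
    substeps: int = 0
    mass_error: float = 0.0            # cm^3, signed per-step ledger gap
    plane_flux_dt: dict = field(default_factory=dict)  # cm^3 per plane


class RichardsWorkspace:
    """Precomputed grid topology shared across steps (face index arrays)."""

    def __init__(self, grid: SoilGrid):
        self.grid = grid
        nx, ny, nz = grid.shape
        n = grid.n_cells
        idx = np.arange(n).reshape(grid.shape)
        faces = []
        for axis, (d, area) in enumerate([
                (grid.dx, grid.dy * grid.dz),
                (grid.dy, grid.dx * grid.dz),
                (grid.dz, grid.dx * grid.dy)]):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = slice(None, -1)
            sl_b[axis] = slice(1, None)
            a = idx[tuple(sl_a)].ravel()
            b = idx[tuple(sl_b)].ravel()
            faces.append((a, b, area / d))
        self.face_a = np.concatenate([f[0] for f in faces])
        self.face_b = np.concatenate([f[1] for f in faces])
        self.face_geom = np.concatenate(
            [np.full(len(f[0]), f[2]) for f in faces])
        mat = grid.material_index.ravel()
        self.same_mat = mat[self.face_a] == mat[self.face_b]
        self.mat_flat = mat
        self.z_flat = np.broadcast_to(
            grid.z_centers()[None, None, :], grid.shape).ravel().copy()
        # z-face bookkeeping: faces between slices k-1 and k live at z=-k*dz
        n_zfaces = nx * ny * (nz - 1)
        self.zface_start = len(self.face_a) - n_zfaces
        self.zface_k = np.broadcast_to(
            np.arange(1, nz)[None, None, :], (nx, ny, nz - 1)).ravel()
        self._plane_cache: dict[int, np.ndarray] = {}

    def plane_faces(self, k: int) -> np.ndarray:
        """Global face indices of the horizontal plane at z = -k*dz."""
        if k not in self._plane_cache:
            self._plane_cache[k] = (self.zface_start
                                    + np.nonzero(self.zface_k == k)[0])
        return self._plane_cache[k]

    def cell_K(self, psi_flat: np.ndarray) -> np.ndarray:
        K = np.zeros_like(psi_flat)
        for im, m in enumerate(self.grid.materials):
            mask = self.mat_flat == im
            if mask.any():
                K[mask] = hydraulic_conductivity(psi_flat[mask], m)
        return K

    def cell_theta(self, psi_flat: np.ndarray) -> np.ndarray:
        th = np.zeros_like(psi_flat)
        for im, m in enumerate(self.grid.materials):
            mask = self.mat_flat == im
            if mask.any():
                th[mask] = water_content(psi_flat[mask], m)
        return th

    def cell_capacity(self, psi_flat: np.ndarray) -> np.ndarray:
        c = np.zeros_like(psi_flat)
        for im, m in enumerate(self.grid.materials):
            mask = self.mat_flat == im
            if mask.any():
                c[mask] = water_capacity(psi_flat[mask], m)
        return c

    def face_transmissibility(self, K_cell: np.ndarray,
                              mode: str = "arithmetic") -> np.ndarray:
        Ka = K_cell[self.face_a]
        Kb = K_cell[self.face_b]
        if mode == "arithmetic":
            Kf = np.where(self.same_mat, 0.5 * (Ka + Kb), 0.0)
        elif mode == "geometric":
            Kf = np.where(self.same_mat, np.sqrt(Ka * Kb), 0.0)
        else:
            raise ValueError(f"unknown averaging mode {mode!r}")
        # material interfaces: series (harmonic) combination; 0 blocks flow
        inter = ~self.same_mat
        s = Ka[inter] + Kb[inter]
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(s > 0.0, 2.0 * Ka[inter] * Kb[inter] / s, 0.0)
        Kf[inter] = h
        return Kf * self.face_geom


def internode_conductivity(psi_a, psi_b, mat_a, mat_b,
                           mode: str = "arithmetic") -> float:
    """Face hydraulic conductivity [cm d^-1] between two adjacent cells.

    Arithmetic mean within one material; harmonic (series) combination
    across a material interface, so a zero-conductivity layer blocks the
    face exactly.
    """
    Ka = hydraulic_conductivity(psi_a, mat_a)
    Kb = hydraulic_conductivity(psi_b, mat_b)
    if mat_a is mat_b or mat_a == mat_b:
        if mode == "arithmetic":
            return 0.5 * (Ka + Kb)
        if mode == "geometric":
            return float(np.sqrt(Ka * Kb))
        raise ValueError(f"unknown averaging mode {mode!r}")
    s = Ka + Kb
    return 2.0 * Ka * Kb / s if s > 0.0 else 0.0


def _solve_spd(A: sp.csr_matrix, b: np.ndarray,
               x0: np.ndarray | None = None) -> np.ndarray | None:
    """Solve the SPD Picard system: warm-started Jacobi-preconditioned CG
    with a sparse-direct fallback (the step contract is residual-based,
    not method-based)."""
    d = A.diagonal()
    if np.any(d <= 0.0):
        return None
    inv_d = 1.0 / d
    M = spla.LinearOperator(A.shape, matvec=lambda x: x * inv_d)
    bnorm = float(np.linalg.norm(b))
    x, info = spla.cg(A, b, x0=x0, M=M, rtol=1e-11,
                      atol=1e-11 * max(bnorm, 1.0), maxiter=3000)
    if info == 0:
        return x
    return spla.spsolve(A, b)


def _single_step(ws: RichardsWorkspace, psi_n, theta_n, sink_flat, dt,
                 config: RichardsConfig, plane_ks):
    """One backward-Euler step of length dt; returns (psi, theta,
    iterations, mass_err, plane_fluxes) or None on non-convergence."""
    grid = ws.grid
    V = grid.cell_volume
    n = grid.n_cells
    psi_m = psi_n.copy()
    z = ws.z_flat
    rhs_sink = sink_flat * V

    for it in range(config.max_picard):
        K = ws.cell_K(psi_m)
        T = ws.face_transmissibility(K, config.conductivity_averaging)
        C = ws.cell_capacity(psi_m)
        theta_m = ws.cell_theta(psi_m)

        diag_t = (C + SS_COMPRESS) * V / dt
        rows = np.concatenate([ws.face_a, ws.face_b, ws.face_a, ws.face_b])
        cols = np.concatenate([ws.face_a, ws.face_b, ws.face_b, ws.face_a])
        vals = np.concatenate([T, T, -T, -T])
        A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        A = A + sp.diags(diag_t)
        grav = np.zeros(n)
        np.add.at(grav, ws.face_a, T * (z[ws.face_b] - z[ws.face_a]))
        np.add.at(grav, ws.face_b, T * (z[ws.face_a] - z[ws.face_b]))
        b = (diag_t * psi_m - (V / dt) * (theta_m - theta_n)
             + (SS_COMPRESS * V / dt) * (psi_n - psi_m)
             - rhs_sink + grav)
        psi_new = _solve_spd(A, b, x0=psi_m)
        if psi_new is None or not np.all(np.isfinite(psi_new)):
            return None
        delta = psi_new - psi_m
        # guard rails for stiff (near-residual) cells: cap the elementwise
        # update and damp late iterations; the converged fixed point is
        # unchanged, only the iteration path is stabilized
        np.clip(delta, -2000.0, 2000.0, out=delta)
        if it >= 8:
            delta *= 0.6
        psi_m = psi_m + delta
        # absolute tolerance, relaxed proportionally under high suction
        dpsi = float(np.max(np.abs(delta) / (1.0 + 1e-3 * np.abs(psi_m))))
        if dpsi < config.tol_psi:
            theta_new = ws.cell_theta(psi_m)
            # linearization gap of the accepted iterate (per-step ledger)
            gap = float(np.sum(
                V * (theta_new - theta_m - C * (psi_m - psi_new))))
            # conservative ledger: storage change vs sink extraction
            storage = float(np.sum(
                V * (theta_new - theta_n
                     + SS_COMPRESS * (psi_m - psi_n))))
            mass_err = storage + float(np.sum(rhs_sink)) * dt
            if abs(mass_err) > config.tol_mass and it + 1 < config.max_picard:
                continue   # tighten with another iteration
            # plane fluxes from the converged face transmissibilities
            plane_flux = {}
            H = psi_m + z
            for zp in plane_ks:
                k = int(round(zp / grid.dz))
                sel = ws.plane_faces(k)
                fa = ws.face_a[sel]
                fb = ws.face_b[sel]
                # face_a is the upper cell (smaller k): flux positive upward
                q_up = float(np.sum(T[sel] * (H[fb] - H[fa])))
                plane_flux[zp] = q_up * dt
            return psi_m, theta_new, it + 1, mass_err, plane_flux
    return None


def richards_step(state: SoilState, dt: float, sink: np.ndarray,
                  config: RichardsConfig | None = None,
                  workspace: RichardsWorkspace | None = None,
                  flux_plane_depths: tuple[float, ...] = (),
                  max_substeps: int | None = None
                  ) -> tuple[SoilState, StepDiagnostics]:
    """Advance the soil state by ``dt`` days under the sink field ``sink``.

    The target interval is integrated with internal sub-stepping: on
    Picard non-convergence the sub-step is halved, down to
    ``config.dt_min`` (below which the step aborts with the last state
    attached).  ``flux_plane_depths`` (cm below surface, on voxel-face
    planes) request the integrated upward Darcy flux across those planes
    during the step; diagnostics also carry the summed Picard iterations
    and the signed mass-ledger gap.  ``max_substeps`` bounds the internal
    sub-stepping: in coupled use the sink field is frozen during this
    call, so grinding through very many sub-steps would apply a stale
    sink — the caller should instead shorten its own step and refresh
    the sink.
    """
    config = config or RichardsConfig()
    ws = workspace or RichardsWorkspace(state.grid)
    grid = state.grid
    sink_flat = np.asarray(sink, float).ravel()
    if np.any(sink_flat[~grid.is_soil.ravel()] != 0.0):
        raise ValueError("sink must vanish outside soil voxels")
    for d in flux_plane_depths:
        if abs(round(d / grid.dz) - d / grid.dz) > 1e-9:
            raise ValueError(f"plane depth {d} is not on a voxel face")

    psi = state.psi.ravel().copy()
    theta = state.theta.ravel().copy()
    diag = StepDiagnostics()
    diag.plane_flux_dt = {d: 0.0 for d in flux_plane_depths}

    remaining = dt
    sub = dt
    while remaining > 1e-14:
        if max_substeps is not None and diag.substeps >= max_substeps:
            bad = SoilState(grid, psi.reshape(grid.shape),
                            theta.reshape(grid.shape),
                            sink_flat.reshape(grid.shape),
                            state.time + (dt - remaining))
            raise RichardsStepError(
                f"sub-step budget ({max_substeps}) exhausted at "
                f"t={bad.time:.5f} d; shorten the coupling step", bad)
        sub = min(sub, remaining)
        out = _single_step(ws, psi, theta, sink_flat, sub, config,
                           flux_plane_depths)
        if out is None:
            sub /= 2.0
            if sub < config.dt_min:
                bad = SoilState(grid, psi.reshape(grid.shape),
                                theta.reshape(grid.shape),
                                sink_flat.reshape(grid.shape),
                                state.time + (dt - remaining))
                raise RichardsStepError(
                    f"Picard iteration failed below dt_min="
                    f"{config.dt_min} d at t={bad.time:.5f} d", bad)
            continue
        psi, theta, iters, mass_err, plane_flux = out
        diag.picard_iterations += iters
        diag.substeps += 1
        diag.mass_error += mass_err
        for d, q in plane_flux.items():
            diag.plane_flux_dt[d] += q
        remaining -= sub
        if iters <= 3:
            sub *= 1.3

    new = SoilState(grid, psi.reshape(grid.shape),
                    theta.reshape(grid.shape),
                    sink_flat.reshape(grid.shape).copy(),
                    state.time + dt)
    return new, diag


def vertical_flux_across_plane(state: SoilState, z_plane: float,
                               workspace: RichardsWorkspace | None = None,
                               mode: str = "arithmetic") -> float:
    """Net instantaneous Darcy flux [cm^3 d^-1, positive upward] across
    the horizontal voxel-face plane at depth ``z_plane`` (cm below the
    surface, or negative z), evaluated from the current state's face
    conductivities.
    """
    grid = state.grid
    d = abs(float(z_plane))
    k = d / grid.dz
    if abs(round(k) - k) > 1e-9:
        raise ValueError(f"plane {z_plane} is not on a voxel face")
    k = int(round(k))
    if not (1 <= k <= grid.nz - 1):
        raise ValueError("plane outside the domain interior")
    ws = workspace or RichardsWorkspace(grid)
    psi = state.psi.ravel()
    K = ws.cell_K(psi)
    T = ws.face_transmissibility(K, mode)
    H = psi + ws.z_flat
    sel = ws.plane_faces(k)
    fa = ws.face_a[sel]
    fb = ws.face_b[sel]
    return float(np.sum(T[sel] * (H[fb] - H[fa])))
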