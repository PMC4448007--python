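"""Xylem water flow on the root network (Doussan-type resistor model).

Each segment j (parent node p -> distal node j) carries

* an axial conductance ``a_j = K_x,j / l_j`` [cm^3 d^-1 hPa^-1] between
  the xylem potentials of its two nodes, with the gravitational potential
  included:  J_x,j = a_j (H_j - H_p),  H = psi_x + z  (flow positive
  toward the collar), and
* a radial conductance ``kr_j = K*_r,j A_r,j`` [cm^3 d^-1 hPa^-1] between
  the soil-root interface potential psi_s,int,j and the xylem potential
  at the distal node:  J_r,j = kr_j (psi_s,int,j - psi_x,j)  (positive
  into the root).

Root nodes have no storage, so the per-node mass balance (axial in/out
plus radial inflow = 0) yields a symmetric positive-definite sparse
system for psi_x that is solved directly (the solver contract is a
relative residual below 1e-10; any consistent method qualifies).  The
collar (node 0) carries either a prescribed transpiration flux T_act or a
prescribed potential.

Derived collar-scale quantities: the standard uptake fraction SUF_j
(segment share of uptake under uniform soil potential, summing to 1),
the effective soil potential psi_s,eff = sum_j SUF_j psi_s,int,j, and the
root system conductance K_root = T_act / (psi_s,eff - psi_collar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from rootflow3d.root_architecture import RootSystem

__all__ = ["XylemSolution", "solve_xylem", "compute_suf",
           "compute_kroot_and_effective_potential"]


@dataclass
class XylemSolution:
    """Solved xylem state (arrays indexed by node; entry 0 = collar)."""

    psi_x: np.ndarray            # hPa
    J_r: np.ndarray              # cm^3 d^-1, positive into the root
    J_x: np.ndarray              # cm^3 d^-1, positive toward the collar
    psi_collar: float            # hPa
    T_act: float                 # cm^3 d^-1
    psi_s_int: np.ndarray        # hPa, interface potentials used
    suf: np.ndarray | None = None
    residual: float = 0.0

    @property
    def psi_s_eff(self) -> float:
        """SUF-weighted effective soil potential [hPa]."""
        if self.suf is None:
            raise ValueError("solution carries no SUF; compute_suf first")
        return float(np.dot(self.suf[1:], self.psi_s_int[1:]))


def _assemble(system: RootSystem, kr: np.ndarray, kx: np.ndarray,
              gravity: bool):
    n = system.n_nodes
    L = system.lengths()
    j = np.arange(1, n)
    p = system.parent[j]
    a = kx[j] / L[j]
    if np.any(~np.isfinite(a)) or np.any(a < 0):
        raise ValueError("invalid axial conductances")
    if np.any(a == 0.0):
        bad = j[a == 0.0]
        raise ValueError(
            f"zero axial conductance isolates the subtree at nodes "
            f"{bad[:5].tolist()}{'...' if len(bad) > 5 else ''}")
    rows = np.concatenate([j, p, j, p])
    cols = np.concatenate([j, p, p, j])
    vals = np.concatenate([a, a, -a, -a])
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    z = system.pos[:, 2] if gravity else np.zeros(n)
    grav = -lap @ z
    return lap, grav, a


def solve_xylem(system: RootSystem, kr: np.ndarray, kx: np.ndarray,
                psi_s_int: np.ndarray, collar_bc: tuple[str, float],
                gravity: bool = True) -> XylemSolution:
    """Solve xylem potentials and fluxes on the active root network.

    Parameters
    ----------
    system
        Connected, collar-rooted root system.
    kr, kx
        Per-node absolute radial conductance ``K*_r A_r``
        [cm^3 d^-1 hPa^-1] and axial conductance ``K_x``
        [cm^4 d^-1 hPa^-1] (entry 0 ignored).
    psi_s_int
        Soil-root interface potential per segment [hPa] (entry 0 ignored).
    collar_bc
        ``('flux', T_act)`` prescribes the transpiration stream leaving
        the collar [cm^3 d^-1]; ``('psi', value)`` prescribes the collar
        potential [hPa].
    gravity
        Include the gravitational term dz/dl in the axial flow (on by
        default; can be disabled for oracle tests and SUF).
    """
    n = system.n_nodes
    kr = np.asarray(kr, float)
    psi_s_int = np.asarray(psi_s_int, float)
    if n == 1:
        raise ValueError("system has no segments")
    if not np.any(kr[1:] > 0):
        raise ValueError("all radial conductances are zero: "
                         "system is hydraulically isolated from the soil")
    lap, grav, a = _assemble(system, kr, kx, gravity)
    diag_r = kr.copy()
    diag_r[0] = 0.0
    A = (lap + sp.diags(diag_r)).tocsr()
    b = diag_r * psi_s_int + grav

    mode, val = collar_bc
    if mode == "flux":
        b = b.copy()
        b[0] -= val
        psi = spla.spsolve(A, b)
        T_act = float(val)
    elif mode == "psi":
        psi = np.empty(n)
        psi[0] = val
        keep = np.arange(1, n)
        A11 = A[keep][:, keep]
        b1 = b[keep] - A[keep][:, [0]].toarray().ravel() * val
        psi[1:] = spla.spsolve(A11.tocsr(), b1)
        # recover the collar flux from the collar-row balance
        T_act = -float((A[0] @ psi).item() - b[0])
    else:
        raise ValueError(f"unknown collar bc mode {mode!r}")

    if not np.all(np.isfinite(psi)):
        raise ValueError("xylem solve produced non-finite potentials "
                         "(singular system)")
    res = float(np.linalg.norm(A @ psi - b)
                / max(np.linalg.norm(b), 1e-30))

    z = system.pos[:, 2] if gravity else np.zeros(n)
    H = psi + z
    J_r = diag_r * (psi_s_int - psi)
    J_r[0] = 0.0
    J_x = np.zeros(n)
    j = np.arange(1, n)
    J_x[j] = a * (H[j] - H[system.parent[j]])
    return XylemSolution(psi_x=psi, J_r=J_r, J_x=J_x,
                         psi_collar=float(psi[0]), T_act=T_act,
                         psi_s_int=psi_s_int, residual=res)


def compute_suf(system: RootSystem, kr: np.ndarray,
                kx: np.ndarray) -> np.ndarray:
    """Standard uptake fraction per segment (indexed by node, entry 0 = 0).

    Solved with uniform soil potential, unit collar demand and the
    gravitational term disabled (uniform *total* potential), so that
    SUF_j = J_r,j and sum_j SUF_j = 1 by collar mass balance.  SUF depends
    only on conductance ratios, not their absolute magnitude.
    """
    psi_s = np.zeros(system.n_nodes)
    sol = solve_xylem(system, kr, kx, psi_s, ("flux", 1.0), gravity=False)
    return sol.J_r


def compute_kroot_and_effective_potential(sol: XylemSolution):
    """(K_root, psi_s_eff) of a solved state carrying SUF.

    ``psi_s_eff`` is the SUF-weighted interface potential; ``K_root =
    T_act / (psi_s_eff - psi_collar)`` [cm^3 hPa^-1 d^-1] is undefined
    (None) at zero transpiration, where psi_s_eff = psi_collar.
    """
    psi_eff = sol.psi_s_eff
    if sol.T_act == 0.0:
        return None, psi_eff
    return sol.T_act / (psi_eff - sol.psi_collar), psi_eff
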