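"""Bimodal Mualem-van Genuchten soil hydraulic functions.

Water retention is described as a weighted sum of two van Genuchten
modalities (Durner-type bimodal curve),

    Se(h) = sum_i  w_i * [1 + (alpha_i * h)^n_i]^(-m_i),      h = |psi|,
    theta(psi) = theta_r + (theta_s - theta_r) * Se,

with ``m_i = 1 - 1/n_i`` and ``w_1 = 1 - w_2``.  Unsaturated conductivity
follows the Mualem capillary-bundle model evaluated in closed form for the
bimodal retention curve,

    K(psi) = Ks * Se^lambda *
             [ sum_i w_i alpha_i (1 - (1 - Se_i^(1/m_i))^m_i)
               / sum_i w_i alpha_i ]^2 .

The closed form is exact: for a single van Genuchten modality the Mualem
integral int_0^S dx / h(x) evaluates to ``alpha * (1 - (1 - S^(1/m))^m)``,
and the bimodal integral is the w_i-weighted sum of the per-modality
integrals (the quadrature oracle in the test suite confirms this).

Units: pressure heads are in hPa, treated as identical to cm of water
column (the < 2 % difference is ignored throughout); conductivities in
cm d^-1; water contents in cm^3 cm^-3.  ``psi <= 0`` is unsaturated;
``psi >= 0`` is treated as exactly saturated (no air-entry offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SoilMaterial",
    "water_content",
    "water_capacity",
    "hydraulic_conductivity",
    "psi_from_theta",
    "default_materials",
]


@dataclass(frozen=True)
class SoilMaterial:
    """Parameter set of one porous material (one row of the material table).

    Parameters
    ----------
    theta_r, theta_s
        Residual and saturated volumetric water content [cm^3 cm^-3].
    alpha1, n1
        Inverse air-entry [hPa^-1] and shape [-] of the first modality.
    w2, alpha2, n2
        Weight [-] and parameters of the second modality; ``w2 = 0``
        recovers the classic unimodal van Genuchten-Mualem model.
    lambda_tort
        Mualem tortuosity/connectivity exponent [-].
    Ks
        Saturated hydraulic conductivity [cm d^-1].  ``Ks = 0`` marks an
        impermeable material (container wall, sealed paraffin).
    """

    theta_r: float
    theta_s: float
    alpha1: float
    n1: float
    w2: float = 0.0
    alpha2: float = 1.0
    n2: float = 2.0
    lambda_tort: float = 0.5
    Ks: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ValueError(
                f"require 0 <= theta_r < theta_s <= 1, got "
                f"theta_r={self.theta_r}, theta_s={self.theta_s}"
            )
        if self.n1 <= 1.0:
            raise ValueError(f"n1 must be > 1, got {self.n1}")
        if not (0.0 <= self.w2 <= 1.0):
            raise ValueError(f"w2 must be in [0, 1], got {self.w2}")
        if self.w2 > 0.0 and self.n2 <= 1.0:
            raise ValueError(f"n2 must be > 1, got {self.n2}")
        if self.alpha1 <= 0.0 or (self.w2 > 0.0 and self.alpha2 <= 0.0):
            raise ValueError("alpha parameters must be > 0")
        if self.Ks < 0.0:
            raise ValueError(f"Ks must be >= 0, got {self.Ks}")

    @property
    def m1(self) -> float:
        return 1.0 - 1.0 / self.n1

    @property
    def m2(self) -> float:
        return 1.0 - 1.0 / self.n2

    @property
    def w1(self) -> float:
        return 1.0 - self.w2

    @classmethod
    def from_dict(cls, d: dict, name: str = "") -> "SoilMaterial":
        """Build from a config mapping with material-table column names.

        Accepted keys: ``theta_r, theta_s, alpha, n, w2, alpha2, n2,
        lambda, Ks`` (``alpha1/n1/lambda_tort`` are accepted as aliases).
        Missing second-modality keys imply a unimodal curve.
        """
        d = dict(d)
        return cls(
            theta_r=float(d["theta_r"]),
            theta_s=float(d["theta_s"]),
            alpha1=float(d.get("alpha", d.get("alpha1"))),
            n1=float(d.get("n", d.get("n1"))),
            w2=float(d.get("w2", 0.0) or 0.0),
            alpha2=float(d.get("alpha2", 1.0) or 1.0),
            n2=float(d.get("n2", 2.0) or 2.0),
            lambda_tort=float(d.get("lambda", d.get("lambda_tort", 0.5))),
            Ks=float(d.get("Ks", d.get("ks", 0.0))),
            name=name or d.get("name", ""),
        )


def default_materials(leaky_Ks: float = 0.001) -> dict[str, SoilMaterial]:
    """Reference material set of the split-root column experiments.

    ``soil`` is the quartz substrate (bimodal retention); ``wall`` is the
    impermeable container; ``paraffin_sealed`` / ``paraffin_leaky`` are the
    split-layer wax with zero resp. small (default 0.001 cm d^-1)
    saturated conductivity.
    """
    soil = SoilMaterial(0.01, 0.35, 0.05, 4.0, w2=0.35, alpha2=0.0033,
                        n2=1.3, lambda_tort=0.5, Ks=170.0, name="soil")
    wall = SoilMaterial(0.01, 0.35, 3e-6, 1.5, lambda_tort=0.5, Ks=0.0,
                        name="wall")
    sealed = SoilMaterial(0.01, 0.35, 3e-6, 1.5, lambda_tort=0.5, Ks=0.0,
                          name="paraffin_sealed")
    leaky = SoilMaterial(0.01, 0.35, 3e-6, 1.5, lambda_tort=0.5,
                         Ks=leaky_Ks, name="paraffin_leaky")
    return {"soil": soil, "wall": wall,
            "paraffin_sealed": sealed, "paraffin_leaky": leaky}


def _check_psi(psi: np.ndarray) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    if not np.all(np.isfinite(psi)):
        raise ValueError("matric potential must be finite")
    return psi


def _effective_saturations(psi: np.ndarray, mat: SoilMaterial):
    """Per-modality and composite effective saturation (vectorized)."""
    h = np.maximum(-psi, 0.0)
    se1 = (1.0 + (mat.alpha1 * h) ** mat.n1) ** (-mat.m1)
    if mat.w2 > 0.0:
        se2 = (1.0 + (mat.alpha2 * h) ** mat.n2) ** (-mat.m2)
    else:
        se2 = np.zeros_like(se1)
    se = mat.w1 * se1 + mat.w2 * se2
    return se1, se2, se


def water_content(psi, mat: SoilMaterial):
    """Volumetric water content theta(psi) [cm^3 cm^-3].

    ``psi`` may be scalar or array, in hPa (negative = unsaturated);
    ``psi >= 0`` returns ``theta_s`` exactly.
    """
    psi = _check_psi(psi)
    _, _, se = _effective_saturations(psi, mat)
    theta = mat.theta_r + (mat.theta_s - mat.theta_r) * se
    return theta if theta.ndim else float(theta)


def water_capacity(psi, mat: SoilMaterial):
    """Specific water capacity C = d(theta)/d(psi) [cm^3 cm^-3 hPa^-1].

    Analytic derivative of :func:`water_content`; zero on the saturated
    branch ``psi >= 0``.  Always >= 0.
    """
    psi = _check_psi(psi)
    h = np.maximum(-psi, 0.0)
    span = mat.theta_s - mat.theta_r

    def _cap(alpha, n, m):
        ah_n = (alpha * h) ** n
        # d/dh of (1 + (alpha h)^n)^(-m), then d(theta)/d(psi) = +dtheta/dh... sign:
        # theta decreases as h grows; C = dtheta/dpsi = dtheta/d(-h) = -dtheta/dh >= 0.
        with np.errstate(divide="ignore", invalid="ignore"):
            dse_dh = np.where(
                h > 0.0,
                m * n * alpha * (alpha * h) ** (n - 1.0)
                * (1.0 + ah_n) ** (-m - 1.0),
                0.0,
            )
        return dse_dh

    cap = mat.w1 * _cap(mat.alpha1, mat.n1, mat.m1)
    if mat.w2 > 0.0:
        cap = cap + mat.w2 * _cap(mat.alpha2, mat.n2, mat.m2)
    cap = span * cap
    cap = np.where(psi >= 0.0, 0.0, cap)
    return cap if cap.ndim else float(cap)


def hydraulic_conductivity(psi, mat: SoilMaterial):
    """Unsaturated hydraulic conductivity K(psi) [cm d^-1].

    Bimodal Mualem closed form (module docstring); ``K(psi >= 0) = Ks``,
    monotone non-decreasing in ``psi``.  A material with ``Ks = 0``
    returns exactly 0 for all ``psi``.
    """
    psi = _check_psi(psi)
    if mat.Ks == 0.0:
        out = np.zeros_like(psi)
        return out if out.ndim else 0.0
    se1, se2, se = _effective_saturations(psi, mat)
    denom = mat.w1 * mat.alpha1 + mat.w2 * mat.alpha2
    # 1 - (1 - Se_i^(1/m_i))^(m_i), guarded at Se_i = 1
    f1 = 1.0 - (np.maximum(1.0 - se1 ** (1.0 / mat.m1), 0.0)) ** mat.m1
    num = mat.w1 * mat.alpha1 * f1
    if mat.w2 > 0.0:
        f2 = 1.0 - (np.maximum(1.0 - se2 ** (1.0 / mat.m2), 0.0)) ** mat.m2
        num = num + mat.w2 * mat.alpha2 * f2
    k = mat.Ks * se ** mat.lambda_tort * (num / denom) ** 2
    k = np.where(psi >= 0.0, mat.Ks, k)
    return k if k.ndim else float(k)


def psi_from_theta(theta, mat: SoilMaterial):
    """Invert the retention curve: matric potential [hPa] at given theta.

    Valid for ``theta_r < theta <= theta_s``; ``theta = theta_s`` maps to
    0.  Inversion is by bracketed root finding on log-suction, accurate to
    better than 1e-9 in theta.
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    if np.any(theta_arr <= mat.theta_r) or np.any(theta_arr > mat.theta_s):
        raise ValueError(
            f"theta must lie in ({mat.theta_r}, {mat.theta_s}]"
        )
    out = np.empty_like(theta_arr)
    for i, th in enumerate(theta_arr):
        if th >= mat.theta_s:
            out[i] = 0.0
            continue
        se_target = (th - mat.theta_r) / (mat.theta_s - mat.theta_r)

        def f(log_h):
            _, _, se = _effective_saturations(
                np.asarray(-(10.0 ** log_h)), mat)
            return float(se) - se_target

        # bracket in log10(h): retention is strictly decreasing in h
        lo, hi = -8.0, 12.0
        while f(hi) > 0.0 and hi < 40.0:
            hi += 4.0
        log_h = brentq(f, lo, hi, xtol=1e-13, rtol=1e-14)
        out[i] = -(10.0 ** log_h)
    return out if np.asarray(theta).ndim else float(out[0])
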