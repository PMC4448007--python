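"""Data-reduction computations for the column experiments.

These are the calculations applied to the measured (or simulated
virtual) sensor series: leaf area from lamina dimensions, daily
transpiration from balance weights, compartment water depletion from
tensiometer readings via the retention curve, and the root-length
comparison between image-derived and destructively measured totals.

Conventions: 1 g of weight loss is 1 cm^3 of water (density 1);
evaporation is taken as zero (gravel-mulched surface, never rewetted)
except for the seed-compartment correction of the split setup, where the
initially applied 20 ml are assumed lost uniformly over the first 7
days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rootflow3d.soil_hydraulics import SoilMaterial, water_content

__all__ = ["leaf_area", "transpiration_from_weights",
           "depletion_from_tensiometer", "ct_length_discrepancy"]

SEED_COMPARTMENT_WATER = 20.0     # cm^3 applied at planting (split setup)
SEED_EVAPORATION_DAYS = 7


def leaf_area(L, W):
    """One-sided leaflet lamina area [cm^2] from length and width [cm],
    using the linear faba-bean model LA = 0.919 + 0.682 L W."""
    L = np.asarray(L, float)
    W = np.asarray(W, float)
    if np.any(L < 0) or np.any(W < 0):
        raise ValueError("lamina dimensions must be >= 0")
    out = 0.919 + 0.682 * L * W
    return out if out.ndim else float(out)


def transpiration_from_weights(weights, split_correction: bool = False
                               ) -> pd.Series:
    """Daily transpiration rates [cm^3 d^-1] from daily balance weights.

    ``weights`` is a Series indexed by day (or an array at daily
    cadence) of column weights [g]; the rate on day d is the weight
    difference w_{d-1} - w_d.  With ``split_correction`` the seed
    compartment's 20 ml, assumed to evaporate uniformly over days 1-7,
    are subtracted on those days.  Rates are floored at 0.  Missing days
    (NaN weights) yield NaN rates — gaps are flagged, not interpolated.
    """
    if isinstance(weights, pd.Series):
        days = np.asarray(weights.index, float)
        if np.any(np.diff(days) != 1.0):
            raise ValueError("weights must be at daily cadence; fill gaps "
                             "with NaN to flag them")
        w = weights.to_numpy(float)
        idx = weights.index[1:]
    else:
        w = np.asarray(weights, float)
        idx = pd.RangeIndex(1, len(w))
    rates = w[:-1] - w[1:]
    if split_correction:
        corr = SEED_COMPARTMENT_WATER / SEED_EVAPORATION_DAYS
        d = np.asarray(idx, float)
        rates = rates - np.where(d <= SEED_EVAPORATION_DAYS, corr, 0.0)
    rates = np.where(np.isnan(rates), np.nan, np.maximum(rates, 0.0))
    return pd.Series(rates, index=idx, name="transpiration")


def depletion_from_tensiometer(psi_series: pd.Series, volume: float,
                               mat: SoilMaterial,
                               bubble_time: float | None = None
                               ) -> pd.Series:
    """Cumulative water depletion [cm^3] of a compartment from its
    tensiometer series, assuming a uniform matric potential in the
    compartment and the substrate retention curve:

        depletion(t) = V * (theta(psi_0) - theta(psi_t)).

    Readings after ``bubble_time`` (tensiometer air entry) are dropped —
    no water-content change can be computed beyond it.  Positive
    readings are rejected as sensor faults.
    """
    psi = psi_series.astype(float)
    if (psi > 0).any():
        bad = psi.index[psi > 0][0]
        raise ValueError(f"positive tensiometer reading at t={bad}")
    if bubble_time is not None:
        psi = psi[psi.index <= bubble_time]
    theta = water_content(psi.to_numpy(), mat)
    depl = volume * (theta[0] - theta)
    return pd.Series(depl, index=psi.index, name="depletion")


def ct_length_discrepancy(length_ct: float, length_winrhizo: float) -> float:
    """Relative root-length discrepancy (destructive - image) /
    destructive, rounded to two decimals as reported."""
    if length_ct <= 0 or length_winrhizo <= 0:
        raise ValueError("lengths must be > 0")
    return round((length_winrhizo - length_ct) / length_winrhizo, 2)
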