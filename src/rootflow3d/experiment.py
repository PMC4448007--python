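"""Scenario definitions, simulation driver and derived analyses.

A :class:`Scenario` bundles the column geometry, split-layer
configuration, a (growing) root architecture, its hydraulic
parameterization, the transpiration forcing and the initial condition.
The three canonical layer configurations are

* ``CD`` — continuous domain, no layers (compartments are bookkeeping
  slabs only);
* ``NC`` — non-conductive layers (Ks = 0): compartments are sealed and
  per-compartment water-storage change equals root water uptake;
* ``SC`` — semi-conductive (leaky) layers, default Ks = 0.001 cm d^-1,
  overridable per layer (a mixed sealed/leaky configuration is one
  scenario with per-layer Ks values).

Transpiration forcing is a periodic day/night step function: the daily
volume is withdrawn at a constant rate during the photoperiod and flow
is zero at night, so predawn (end-of-night) collar potentials equal the
SUF-weighted effective soil potential.

:func:`run_scenario` replays root growth (segments activate at their
origination times), advances the coupled soil-root system, and records
virtual tensiometer readings (slice-mean matric potential at the
instrument depths), per-compartment water balances (uptake, storage
change, net flow through the bounding planes), collar potentials and
predawn values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from rootflow3d.coupling import SegmentSoilMap, coupled_step
from rootflow3d.domain import (
    SoilGrid,
    SoilState,
    build_cylinder_domain,
    hydrostatic_init,
    uniform_theta_init,
)
from rootflow3d.doussan import solve_xylem, compute_suf
from rootflow3d.richards import (
    RichardsConfig,
    RichardsStepError,
    RichardsWorkspace,
)
from rootflow3d.root_architecture import RootHydraulicTable, RootSystem
from rootflow3d.soil_hydraulics import SoilMaterial, default_materials

__all__ = [
    "Scenario", "RunResult", "transpiration_step_function", "run_scenario",
    "layer_mean_psi", "compartment_balance", "predawn_collar_potential",
    "sensitivity_suite", "delta_psi_pd", "recover_layer_conductivity",
]


# ---------------------------------------------------------------------------
# forcing
# ---------------------------------------------------------------------------

def transpiration_step_function(daily_rates, photoperiod_h: float = 14.0):
    """Day/night step-function forcing T_act(t) [cm^3 d^-1].

    ``daily_rates[d]`` is the volume transpired on day d [cm^3 d^-1,
    integrated over the day]; during the light phase (first
    ``photoperiod_h`` hours of each day) the instantaneous rate is
    ``rate / (photoperiod_h/24)``, at night it is zero, so the integral
    over any whole day equals that day's rate exactly.

    Returns ``(T, breakpoints)``: the callable and the sorted times at
    which the forcing switches (day boundaries and light-off instants).
    """
    rates = np.asarray(daily_rates, float)
    if np.any(rates < 0):
        raise ValueError("daily transpiration rates must be >= 0")
    if not (0.0 < photoperiod_h < 24.0):
        raise ValueError("photoperiod must be in (0, 24) hours")
    p = photoperiod_h / 24.0

    def T(t: float) -> float:
        d = int(np.floor(t))
        if d >= len(rates):
            d = len(rates) - 1
        if d < 0:
            return 0.0
        frac = t - np.floor(t)
        return float(rates[d] / p) if frac < p else 0.0

    nb = len(rates)
    breaks = np.unique(np.concatenate(
        [np.arange(nb + 1, dtype=float),
         np.arange(nb, dtype=float) + p]))
    return T, breaks


# ---------------------------------------------------------------------------
# scenario container
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """Full configuration of one virtual split-root simulation."""

    architecture: RootSystem
    daily_rates: np.ndarray
    duration: float
    name: str = "run"
    # geometry
    radius: float = 7.0
    height: float = 21.5
    dx: float = 0.5
    dy: float = 0.5
    dz: float = 0.25
    layer_depths: tuple[float, ...] = ()
    layer_thickness: float = 0.5
    layer_Ks: tuple[float, ...] = ()          # one per layer; 0 = sealed
    compartment_depths: tuple[float, ...] | None = None
    # materials / hydraulics
    materials: dict[str, SoilMaterial] | None = None
    hydraulic_table: RootHydraulicTable | None = None
    # forcing / ic
    photoperiod_h: float = 14.0
    init: tuple = ("hydrostatic", 0.0)
    # observation
    tensiometer_depths: tuple[float, ...] = (-1.5, -6.5, -11.5, -16.5)
    output_per_day: int = 4
    # numerics
    richards: RichardsConfig = field(default_factory=RichardsConfig)
    coupling_mode: str = "iterated"
    tol_interface: float = 1.0
    max_sweeps: int = 5

    def __post_init__(self):
        self.daily_rates = np.asarray(self.daily_rates, float)
        if self.layer_depths and not self.layer_Ks:
            self.layer_Ks = (0.0,) * len(self.layer_depths)
        if len(self.layer_Ks) != len(self.layer_depths):
            raise ValueError("need one layer Ks per layer depth")
        if any(k < 0 for k in self.layer_Ks):
            raise ValueError("layer Ks must be >= 0")

    def build_grid(self) -> SoilGrid:
        mats = self.materials or default_materials()
        layer_mats = tuple(
            replace(mats["paraffin_sealed"], Ks=k,
                    name=f"paraffin_{i}") for i, k in enumerate(self.layer_Ks))
        return build_cylinder_domain(
            radius=self.radius, height=self.height,
            dx=self.dx, dy=self.dy, dz=self.dz,
            soil=mats["soil"], wall=mats["wall"],
            layer_depths=self.layer_depths,
            layer_thickness=self.layer_thickness,
            layer_materials=layer_mats,
            compartment_depths=self.compartment_depths)

    def initial_state(self, grid: SoilGrid) -> SoilState:
        kind = self.init[0]
        if kind == "hydrostatic":
            return hydrostatic_init(grid, float(self.init[1]))
        if kind == "uniform_theta":
            return uniform_theta_init(grid, self.init[1])
        raise ValueError(f"unknown initial condition {kind!r}")


@dataclass
class RunResult:
    """Output time series of one scenario run."""

    scenario: Scenario
    tensiometer: pd.DataFrame     # index time [d], columns depth [cm]
    collar: pd.DataFrame          # time, T_act, psi_collar
    compartments: pd.DataFrame    # time x (comp, quantity) cumulative ledgers
    predawn: pd.DataFrame         # day, psi_pd
    cumulative_transpiration: float
    cumulative_mass_error: float
    final_state: SoilState
    initial_storage_per_comp: np.ndarray
    suf_final: np.ndarray | None = None

    def summary_table(self) -> pd.DataFrame:
        """Cumulative uptake and water depletion per compartment at the
        end of the run (depletion = storage decrease of the compartment)."""
        last = self.compartments.iloc[-1]
        comps = sorted({c for c, _ in self.compartments.columns})
        rows = []
        for c in comps:
            rwu = last[(c, "cum_rwu")]
            depl = self.initial_storage_per_comp[c] - last[(c, "storage")]
            rows.append({"compartment": c, "RWU": rwu,
                         "depletion": depl})
        df = pd.DataFrame(rows).set_index("compartment")
        df.loc["total"] = df.sum()
        return df


# ---------------------------------------------------------------------------
# analyses on states / results
# ---------------------------------------------------------------------------

def layer_mean_psi(state: SoilState, depths) -> np.ndarray:
    """Mean matric potential [hPa] of the soil voxels in the horizontal
    slice containing each depth (a virtual tensiometer).  A depth inside
    a split-layer slab (no soil voxels in the slice) is rejected."""
    grid = state.grid
    out = np.empty(len(depths))
    for i, d in enumerate(depths):
        k = grid.slice_index(d)
        mask = grid.is_soil[:, :, k]
        if not mask.any():
            raise ValueError(
                f"depth {d} lies inside a split-layer slab")
        out[i] = float(state.psi[:, :, k][mask].mean())
    return out


def predawn_collar_potential(result: RunResult, day: int) -> float:
    """Collar potential [hPa] at the end of the night before ``day``
    (equals the SUF-weighted effective soil potential, since T = 0)."""
    sel = result.predawn[result.predawn["day"] == day]
    if sel.empty:
        raise ValueError(f"no predawn record for day {day}")
    return float(sel["psi_pd"].iloc[0])


def compartment_balance(result: RunResult, comp: int) -> pd.DataFrame:
    """Cumulative ledger of one compartment: uptake, storage change, net
    inflow through the bounding planes, and the closure residual
    ``rwu - (dstorage_loss + inflow)`` (zero to mass tolerance)."""
    df = result.compartments
    rwu = df[(comp, "cum_rwu")]
    storage = df[(comp, "storage")]
    inflow = df[(comp, "cum_inflow")]
    dstor = result.initial_storage_per_comp[comp] - storage
    out = pd.DataFrame({
        "cum_rwu": rwu, "storage": storage,
        "cum_depletion": dstor, "cum_inflow": inflow,
        "closure": rwu - (dstor + inflow),
    })
    return out


def delta_psi_pd(result_a: RunResult, result_b: RunResult) -> pd.Series:
    """Daily difference of absolute predawn potentials
    ``|psi_pd(a)| - |psi_pd(b)|`` (antisymmetric in its arguments);
    requires matching day grids and is positive when scenario ``a``
    leaves the plant under more negative predawn potentials."""
    a = result_a.predawn.set_index("day")["psi_pd"]
    b = result_b.predawn.set_index("day")["psi_pd"]
    if not a.index.equals(b.index):
        raise ValueError("predawn day grids differ between runs")
    return a.abs() - b.abs()


def sensitivity_suite(system: RootSystem, table: RootHydraulicTable,
                      t: float, dz_bin: float = 0.25,
                      max_depth: float | None = None) -> pd.DataFrame:
    """SUF depth profiles for the four conductivity parameterizations.

    Modes: ``reference`` (constant K*_r, age-dependent K_x), ``1`` (both
    constant), ``2`` (age-dependent K*_r, constant K_x), ``3`` (both
    age-dependent).  The active system at time ``t`` is solved for SUF
    per mode, summed over depth bins of ``dz_bin`` cm; every profile
    sums to 1.
    """
    modes = {
        "reference": ("constant", "age"),
        "1": ("constant", "constant"),
        "2": ("age", "constant"),
        "3": ("age", "age"),
    }
    active = system.active_subset(t)
    depths = -active.midpoints()[:, 2]       # positive downward
    if max_depth is None:
        max_depth = float(np.ceil(depths[1:].max() / dz_bin) * dz_bin)
    edges = np.arange(0.0, max_depth + dz_bin / 2, dz_bin)
    out = {}
    for label, (kr_mode, kx_mode) in modes.items():
        tab = table.perturbed(kr_mode, kx_mode)
        kr, kx = tab.segment_conductivities(active, t)
        suf = compute_suf(active, kr, kx)
        hist, _ = np.histogram(depths[1:], bins=edges, weights=suf[1:])
        out[label] = hist
    idx = pd.Index(-(edges[:-1] + dz_bin / 2), name="depth")
    return pd.DataFrame(out, index=idx)


# ---------------------------------------------------------------------------
# the driver
# ---------------------------------------------------------------------------

def recover_layer_conductivity(bundle, observed: pd.DataFrame,
                               ks_grid=(1e-4, 1e-3, 1e-2),
                               precomputed: dict | None = None):
    """Estimate the split-layer conductivity from tensiometer series.

    Runs the bundle's leaky-layer scenario for each candidate Ks
    [cm d^-1] in ``ks_grid`` and compares the simulated virtual
    tensiometer series against ``observed`` (time-indexed, one column
    per tensiometer depth) by root-mean-square misfit over the common
    index.  Returns ``(ks_best, misfits)``.

    ``precomputed`` may map a candidate Ks to an existing
    :class:`RunResult` to avoid re-running it.
    """
    misfits = {}
    for ks in ks_grid:
        if precomputed is not None and ks in precomputed:
            res = precomputed[ks]
        else:
            res = run_scenario(bundle.scenario("SC", leaky_Ks=ks))
        sim = res.tensiometer.reindex(observed.index)[observed.columns]
        misfits[ks] = float(np.sqrt(np.nanmean(
            (sim.to_numpy() - observed.to_numpy()) ** 2)))
    best = min(misfits, key=misfits.get)
    return best, misfits


def _compartment_planes(grid: SoilGrid):
    """Per-compartment (top, bottom) bounding plane depths [cm, > 0],
    None for the outer surface / floor (no-flux)."""
    planes = []
    for c in range(grid.n_compartments):
        ks = np.nonzero(grid.compartment.any(axis=(0, 1))
                        & (grid.compartment == c).any(axis=(0, 1)))[0]
        ks = np.nonzero((grid.compartment == c).any(axis=(0, 1)))[0]
        top = ks.min() * grid.dz
        bot = (ks.max() + 1) * grid.dz
        planes.append((top if top > 1e-9 else None,
                       bot if bot < grid.height - 1e-9 else None))
    return planes


def run_scenario(scenario: Scenario, progress: bool = False) -> RunResult:
    """Run the full coupled simulation of one scenario.

    Growth is replayed from the architecture's origination times; the
    forcing switches between day rate and zero at the photoperiod
    boundaries; outputs are recorded ``output_per_day`` times per day and
    the predawn collar potential once per day boundary.
    """
    grid = scenario.build_grid()
    state = scenario.initial_state(grid)
    ws = RichardsWorkspace(grid)
    table = scenario.hydraulic_table
    if table is None:
        from rootflow3d.root_architecture import default_hydraulic_table
        table = default_hydraulic_table()
    system = scenario.architecture
    system.validate()
    smap = SegmentSoilMap(grid, system)

    T_of, force_breaks = transpiration_step_function(
        scenario.daily_rates, scenario.photoperiod_h)
    out_times = np.arange(0.0, scenario.duration + 1e-9,
                          1.0 / scenario.output_per_day)
    day_bounds = np.arange(1.0, scenario.duration + 1e-9, 1.0)
    breaks = np.unique(np.concatenate(
        [force_breaks, out_times, day_bounds, [scenario.duration]]))
    breaks = breaks[(breaks > 0) & (breaks <= scenario.duration + 1e-9)]

    planes = _compartment_planes(grid)
    plane_depths = tuple(sorted({p for pair in planes for p in pair
                                 if p is not None}))
    ncomp = grid.n_compartments
    comp_masks = [grid.compartment_mask(c) for c in range(ncomp)]
    V = grid.cell_volume

    init_storage = np.array([state.storage(m) for m in comp_masks])
    cum_rwu = np.zeros(ncomp)
    cum_inflow = np.zeros(ncomp)
    cum_T = 0.0
    cum_mass_err = 0.0

    tens_rows, collar_rows, comp_rows, predawn_rows = [], [], [], []
    last_sol = None

    def record_output(t):
        tens_rows.append([t] + list(
            layer_mean_psi(state, scenario.tensiometer_depths)))
        collar_rows.append({
            "time": t, "T_act": T_of(t),
            "psi_collar": last_sol.psi_collar if last_sol else np.nan})
        row = {}
        for c in range(ncomp):
            row[(c, "cum_rwu")] = cum_rwu[c]
            row[(c, "storage")] = state.storage(comp_masks[c])
            row[(c, "cum_inflow")] = cum_inflow[c]
        row["time"] = t
        comp_rows.append(row)

    def record_predawn(t):
        active = system.active_subset(t)
        if active.n_segments == 0:
            return
        kr, kx = table.segment_conductivities(active, t)
        W, _ = smap.restrict(active)
        psi_int = W @ state.psi.ravel()
        sol0 = solve_xylem(active, kr, kx, psi_int, ("flux", 0.0))
        predawn_rows.append({"day": int(round(t)),
                             "psi_pd": sol0.psi_collar})

    record_output(0.0)
    t = 0.0
    dt_couple = scenario.richards.dt_max   # outer (coupling) step size
    for t_next in breaks:
        while t < t_next - 1e-12:
            dt = min(dt_couple, t_next - t)
            active = system.active_subset(t)
            T_now = T_of(t)
            try:
                if active.n_segments == 0:
                    # no roots yet: no transpiration, pure redistribution
                    from rootflow3d.richards import richards_step
                    T_now = 0.0
                    state, diag = richards_step(
                        state, dt, np.zeros(grid.shape),
                        config=scenario.richards, workspace=ws,
                        flux_plane_depths=plane_depths)
                    sol = None
                else:
                    kr, kx = table.segment_conductivities(active, t)
                    state, sol, diag = coupled_step(
                        state, active, smap, kr, kx, dt, ("flux", T_now),
                        config=scenario.richards, workspace=ws,
                        flux_plane_depths=plane_depths,
                        tol_interface=scenario.tol_interface,
                        max_sweeps=scenario.max_sweeps,
                        mode=scenario.coupling_mode)
                    last_sol = sol
                    # per-compartment uptake from the accepted sink field
                    for c in range(ncomp):
                        cum_rwu[c] += float(
                            state.sink[comp_masks[c]].sum()) * V * dt
            except RichardsStepError:
                # soil too stiff for this coupling interval: refine so the
                # xylem feedback is re-evaluated more often
                if dt_couple <= 4 * scenario.richards.dt_min:
                    raise
                dt_couple = max(dt_couple / 2.0,
                                4 * scenario.richards.dt_min)
                continue
            cum_T += T_now * dt
            cum_mass_err += diag.mass_error
            for c, (top, bot) in enumerate(planes):
                q = 0.0
                if top is not None:
                    q -= diag.plane_flux_dt[top]     # upward = leaving
                if bot is not None:
                    q += diag.plane_flux_dt[bot]     # upward from below
                cum_inflow[c] += q
            t += dt
            if (diag.substeps <= 2
                    and dt_couple < scenario.richards.dt_max):
                dt_couple = min(dt_couple * 1.3, scenario.richards.dt_max)
        t = t_next
        if abs(t - round(t)) < 1e-9 and round(t) >= 1:
            record_predawn(t)
        if np.any(np.abs(out_times - t) < 1e-9):
            record_output(t)
        if progress:
            print(f"  t = {t:6.2f} d", end="\r")

    tens = pd.DataFrame(
        tens_rows, columns=["time"] + list(scenario.tensiometer_depths)
    ).set_index("time")
    collar = pd.DataFrame(collar_rows).set_index("time")
    comp = pd.DataFrame(comp_rows).set_index("time")
    comp.columns = pd.MultiIndex.from_tuples(
        [c if isinstance(c, tuple) else (c, "") for c in comp.columns])
    predawn = pd.DataFrame(predawn_rows,
                           columns=["day", "psi_pd"])

    suf_final = None
    active = system.active_subset(scenario.duration)
    if active.n_segments > 0:
        kr, kx = table.segment_conductivities(active, scenario.duration)
        suf_final = compute_suf(active, kr, kx)

    return RunResult(
        scenario=scenario, tensiometer=tens, collar=collar,
        compartments=comp[[c for c in comp.columns if c[1]]],
        predawn=predawn,
        cumulative_transpiration=cum_T,
        cumulative_mass_error=cum_mass_err,
        final_state=state,
        initial_storage_per_comp=init_storage,
        suf_final=suf_final,
    )
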