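"""Synthetic faba-bean-like root architectures, transpiration series and
bundled virtual experiments.

The generator emulates the structural statistics of young *Vicia faba*
root systems grown in the split-root columns: a taproot elongating
downward at 0.7 cm d^-1 with gravitropic jitter, first-order laterals
initiated behind the tip at a set density and emergence delay, optional
second-order laterals, segment discretization of 0.087 cm, and snapshot
export every 2 days.  Every segment carries an exact ground-truth
origination time, so snapshot-based growth-replay interpolation can be
validated against the truth.  All randomness derives from one seed.

What it does **not** emulate: root responses to soil state (growth is
prescribed, not mechanistic), root diameter tapering, inter-plant
variability structure beyond the seeded randomness, and the seed
compartment of the physical setup.

The transpiration generator produces a logistic rise toward a peak daily
rate (transpiration grows with leaf area) with an optional sharp decline
after a stress day, mimicking the observed shape of drying experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from rootflow3d.experiment import Scenario
from rootflow3d.root_architecture import (
    LATERAL1,
    LATERAL2,
    TAPROOT,
    RootHydraulicTable,
    RootSystem,
    default_hydraulic_table,
)

__all__ = ["GeneratorParams", "generate_architecture",
           "generate_transpiration", "generate_virtual_experiment",
           "generate_reduced_experiment", "VirtualExperiment"]


@dataclass
class GeneratorParams:
    """Structural parameters of the synthetic root system.

    Rates in cm d^-1, lengths/diameters in cm, densities in cm^-1,
    angles in degrees.  Defaults are anchored to the measured taproot
    elongation rate (0.7 cm d^-1), mean root diameter (1.06 mm), mean
    segment length (0.087 cm) and the 2-day scan interval; branching
    statistics are package choices (no published values exist for them).
    """

    taproot_rate: float = 0.7
    lateral_rate: float = 0.45
    lateral2_rate: float = 0.15
    branching_density: float = 2.0        # first-order laterals per cm
    branching_density2: float = 0.25      # second-order per cm of lateral
    branching_delay: float = 2.0          # d behind the passing tip
    insertion_angle_deg: float = 70.0     # from the parent axis
    insertion_angle_sd: float = 12.0
    taproot_diameter: float = 0.18        # taproot is coarser ...
    lateral_diameter: float = 0.095       # ... so the length-weighted mean
    lateral2_diameter: float = 0.05       # diameter is ~0.106 cm
    segment_length: float = 0.087
    snapshot_interval: float = 2.0        # d
    tropism_strength: float = 0.12        # rad jitter per segment
    gravitropism: float = 0.25            # pull toward vertical (taproot)
    lateral_gravitropism: float = 0.04
    max_lateral_length: float = 8.0
    max_lateral2_length: float = 1.5
    clip_radius: float = 6.5              # cm, keep roots inside
    clip_depth: float = 21.0
    seed: int = 0

    def __post_init__(self):
        for f in ("taproot_rate", "lateral_rate", "branching_density",
                  "taproot_diameter", "lateral_diameter", "segment_length"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


def _rotate_toward(d, target, w):
    out = (1 - w) * d + w * target
    n = np.linalg.norm(out)
    return out / n if n > 0 else target


def _jitter(d, rng, s):
    r = rng.normal(0.0, s, size=3)
    r -= np.dot(r, d) * d          # perpendicular component only
    out = d + r
    return out / np.linalg.norm(out)


def _insertion_direction(axis, rng, angle_deg, angle_sd):
    """Random direction at the given polar angle from ``axis``."""
    ang = np.deg2rad(rng.normal(angle_deg, angle_sd))
    ang = float(np.clip(ang, 0.1, np.pi - 0.1))
    # orthonormal frame around axis
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, a)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    phi = rng.uniform(0.0, 2 * np.pi)
    return (np.cos(ang) * a
            + np.sin(ang) * (np.cos(phi) * e1 + np.sin(phi) * e2))


@dataclass
class _Node:
    pos: np.ndarray
    parent: int
    radius: float
    order: int
    t_s: float
    branch: int


def generate_architecture(params: GeneratorParams | None = None,
                          duration: float = 20.0) -> RootSystem:
    """Grow a synthetic root system for ``duration`` days.

    The collar sits at the soil surface on the cylinder axis; the taproot
    tip reaches a depth of ``taproot_rate * duration`` (minus tropism
    shortfall, bounded by ``clip_depth``).  Nodes are ordered by
    origination time, so earlier snapshots are index prefixes:
    ``system.active_subset(t)`` replays growth, and
    ``snapshots = [system.active_subset(k * snapshot_interval) ...]``
    emulates the scan series.  Same seed, same architecture.
    """
    p = params or GeneratorParams()
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(p.seed)
    nodes: list[_Node] = [_Node(np.zeros(3), -1, 0.0, TAPROOT, -np.inf, -1)]
    next_branch = [0]
    clipped = False

    def grow_root(start_node: int, t0: float, direction, order: int,
                  rate: float, radius: float, max_len: float,
                  gravitropism: float):
        """Grow one root as a chain of segments; returns list of
        (node_index, t_s, position) for branching bookkeeping."""
        nonlocal clipped
        b = next_branch[0]
        next_branch[0] += 1
        d = np.asarray(direction, float)
        d /= np.linalg.norm(d)
        prev = start_node
        length = 0.0
        laid = []
        t = t0
        while length + p.segment_length <= max_len + 1e-12:
            t = t0 + (length + p.segment_length) / rate
            if t > duration:
                break
            d = _jitter(d, rng, p.tropism_strength)
            d = _rotate_toward(d, np.array([0.0, 0.0, -1.0]), gravitropism)
            pos = nodes[prev].pos + d * p.segment_length
            r_h = np.hypot(pos[0], pos[1])
            if r_h > p.clip_radius or pos[2] < -p.clip_depth or pos[2] > 0:
                clipped = True
                break
            j = len(nodes)
            nodes.append(_Node(pos, prev, radius, order, t, b))
            laid.append((j, t, length + p.segment_length))
            prev = j
            length += p.segment_length
        return laid

    # taproot
    tap = grow_root(0, 0.0, [0.0, 0.0, -1.0], TAPROOT, p.taproot_rate,
                    p.taproot_diameter / 2.0, p.taproot_rate * duration,
                    p.gravitropism)

    # first-order laterals along the taproot
    def lay_laterals(parent_chain, density, delay, order, rate, radius,
                     max_len, gravi, sub_density):
        spacing = 1.0 / density
        next_at = spacing * rng.uniform(0.5, 1.5)
        child_chains = []
        for (j, t_s, arc) in parent_chain:
            if arc < next_at:
                continue
            next_at += spacing * rng.uniform(0.7, 1.3)
            t_emerge = t_s + delay
            if t_emerge > duration:
                continue
            axis = nodes[j].pos - nodes[nodes[j].parent].pos
            d0 = _insertion_direction(axis, rng, p.insertion_angle_deg,
                                      p.insertion_angle_sd)
            chain = grow_root(j, t_emerge, d0, order, rate, radius,
                              max_len, gravi)
            if chain:
                child_chains.append(chain)
        return child_chains

    laterals = lay_laterals(tap, p.branching_density, p.branching_delay,
                            LATERAL1, p.lateral_rate,
                            p.lateral_diameter / 2.0,
                            p.max_lateral_length, p.lateral_gravitropism,
                            p.branching_density2)
    if p.branching_density2 > 0:
        for chain in laterals:
            lay_laterals(chain, p.branching_density2,
                         p.branching_delay * 1.5, LATERAL2,
                         p.lateral2_rate, p.lateral2_diameter / 2.0,
                         p.max_lateral2_length, p.lateral_gravitropism, 0.0)

    if clipped:
        warnings.warn("root growth clipped at the domain boundary",
                      stacklevel=2)

    rs = RootSystem(
        pos=np.array([n.pos for n in nodes]),
        parent=np.array([n.parent for n in nodes]),
        radius=np.array([n.radius for n in nodes]),
        order=np.array([n.order for n in nodes]),
        t_s=np.array([n.t_s for n in nodes]),
        branch=np.array([n.branch for n in nodes]),
    )
    rs = rs.sorted_by_ts()
    rs.validate()
    return rs


def generate_transpiration(duration: float, peak_rate: float = 24.0,
                           midpoint_day: float = 8.0,
                           steepness: float = 0.45,
                           decline_day: float | None = None,
                           decline_fraction: float = 0.35,
                           noise_sd: float = 0.0,
                           seed: int = 0) -> np.ndarray:
    """Daily transpiration rates [cm^3 d^-1] for days 0..duration-1.

    Logistic rise toward ``peak_rate`` (transpiration tracks leaf-area
    growth); after ``decline_day`` (stomatal closure under drought) the
    rate drops sharply, multiplying by ``decline_fraction`` per day down
    to 10 % of peak.  ``noise_sd`` adds seeded relative day-to-day
    scatter.  Rates are never negative.
    """
    if peak_rate <= 0:
        raise ValueError("peak rate must be > 0")
    days = np.arange(int(np.ceil(duration)))
    rates = peak_rate / (1.0 + np.exp(-steepness * (days - midpoint_day)))
    if decline_day is not None:
        past = days > decline_day
        fac = decline_fraction ** (days[past] - decline_day)
        rates[past] = np.maximum(rates[past] * fac, 0.1 * peak_rate)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rates = rates * np.exp(rng.normal(0.0, noise_sd, size=len(days)))
    return np.maximum(rates, 0.0)


@dataclass
class VirtualExperiment:
    """A consistent bundle (domain + architecture + forcing + initial
    condition) emulating one column experiment; ``scenario(kind)``
    instantiates the CD / NC / SC layer configuration on it."""

    setup: str                     # 'NoSplit' | 'Split'
    architecture: RootSystem
    daily_rates: np.ndarray
    hydraulic_table: RootHydraulicTable
    duration: float
    layer_depths: tuple[float, ...]
    tensiometer_depths: tuple[float, ...]
    init: tuple
    seed: int
    geometry: dict = field(default_factory=dict)

    def scenario(self, kind: str, leaky_Ks: float = 0.001,
                 layer_Ks: tuple[float, ...] | None = None,
                 **overrides) -> Scenario:
        """CD (no layers), NC (sealed layers) or SC (leaky layers,
        per-layer Ks overridable) scenario on this bundle."""
        kind = kind.upper()
        if kind == "CD":
            depths, ks = (), ()
            comp_depths = self.layer_depths
        elif kind == "NC":
            depths, ks = self.layer_depths, (0.0,) * len(self.layer_depths)
            comp_depths = None
        elif kind == "SC":
            depths = self.layer_depths
            ks = layer_Ks if layer_Ks is not None \
                else (leaky_Ks,) * len(depths)
            comp_depths = None
        else:
            raise ValueError(f"unknown scenario kind {kind!r}")
        return Scenario(
            architecture=self.architecture,
            daily_rates=self.daily_rates,
            duration=self.duration,
            name=f"{self.setup}-{kind}",
            layer_depths=depths, layer_Ks=ks,
            compartment_depths=comp_depths,
            hydraulic_table=self.hydraulic_table,
            init=self.init,
            tensiometer_depths=self.tensiometer_depths,
            **self.geometry, **overrides)


def generate_virtual_experiment(setup: str = "Split", seed: int = 0,
                                duration: float = 20.0,
                                params: GeneratorParams | None = None,
                                peak_rate: float = 24.0,
                                **geometry) -> VirtualExperiment:
    """Bundle a synthetic architecture, forcing and initial condition.

    ``setup='Split'``: three layers at 5/10/15 cm depth, tensiometers at
    -2.5/-7.5/-12.5/-17.5 cm, uniform initial water content 23.8 % per
    compartment.  ``setup='NoSplit'``: no layers, tensiometers at
    -1.5/-6.5/-11.5/-16.5 cm, hydrostatic initial condition with zero
    matric potential at the column base.  The same seed yields the same
    bundle; geometry keywords (dx, dz, radius, ...) pass through to the
    scenario.
    """
    p = params or GeneratorParams(seed=seed)
    if p.seed != seed:
        p = GeneratorParams(**{**p.__dict__, "seed": seed})
    arch = generate_architecture(p, duration=duration)
    rates = generate_transpiration(duration, peak_rate=peak_rate,
                                   noise_sd=0.05, seed=seed + 1)
    if setup == "Split":
        layers = (5.0, 10.0, 15.0)
        tens = (-2.5, -7.5, -12.5, -17.5)
        init = ("uniform_theta", 0.238)
    elif setup == "NoSplit":
        layers = (5.0, 10.0, 15.0)     # bookkeeping depths only (CD)
        tens = (-1.5, -6.5, -11.5, -16.5)
        init = ("hydrostatic", 0.0)
    else:
        raise ValueError(f"unknown setup {setup!r}")
    return VirtualExperiment(
        setup=setup, architecture=arch, daily_rates=rates,
        hydraulic_table=default_hydraulic_table(),
        duration=duration, layer_depths=layers,
        tensiometer_depths=tens, init=init, seed=seed,
        geometry=dict(geometry))


def generate_reduced_experiment(setup: str = "NoSplit",
                                seed: int = 0) -> VirtualExperiment:
    """Desk-scale virtual experiment for full scenario runs.

    The physical column experiments ran 30+ days on a
    0.5 x 0.5 x 0.25 cm grid; at desk scale the same drying regime is
    compressed into a 10-day window on a 1.0 x 1.0 x 0.5 cm voxel grid
    (14 x 14 x 43 cells): transpiration rises logistically to
    30 cm^3 d^-1 with midpoint at day 5, so cumulative demand
    (~135 cm^3) draws the rooted upper compartment well into the dry
    range within the window, as the full-length experiments did over a
    month.  Forcing day-to-day scatter and the root architecture derive
    from ``seed``.
    """
    ve = generate_virtual_experiment(setup, seed=seed, duration=10.0,
                                     dx=1.0, dy=1.0, dz=0.5)
    ve.daily_rates = generate_transpiration(
        10.0, peak_rate=30.0, midpoint_day=5.0, steepness=0.6,
        noise_sd=0.05, seed=seed + 1)
    return ve
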