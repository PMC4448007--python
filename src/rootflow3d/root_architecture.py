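"""Root system graph, growth replay and age-dependent hydraulics.

A root system is a tree of nodes rooted at the collar (node 0, placed at
the soil surface).  Every non-collar node j defines the segment from its
parent node to j, carrying a radius, a root order (0 = taproot,
1/2 = first-/second-order lateral), a branch id and an origination time
``t_s`` [d].  Origination times are non-decreasing along every path from
the collar, so the set of segments with ``t_s <= t`` is always a
connected, collar-rooted subtree: growth is replayed simply by masking.

Node ordering convention: nodes are sorted by ``t_s`` (parents before
children), so earlier snapshots of one growing system are index prefixes
of later ones.

Hydraulic parameterization: radial conductivity K*_r [cm d^-1 hPa^-1]
and axial conductance K_x = K*_x A_x [cm^4 d^-1 hPa^-1] are
piecewise-constant, right-continuous step functions of segment age,
separately per root type.  The reference set uses a constant
K*_r = 8.64e-4 cm d^-1 hPa^-1 and stepwise age-increasing K_x; for the
taproot the source data are banded by distance to the tip and converted
to age bands by dividing distances by the mean taproot elongation rate
(0.7 cm d^-1).  The numeric band values ship as an editable table (no
published numbers exist for them in this system): all results are
relative to this parameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RootSystem",
    "RootHydraulicTable",
    "default_hydraulic_table",
    "assign_origination_times",
    "read_architecture",
    "write_architecture",
]

TAPROOT, LATERAL1, LATERAL2 = 0, 1, 2


@dataclass
class RootSystem:
    """Tree of root nodes; node 0 is the collar, node j>0 carries the
    segment parent(j) -> j.

    Arrays are indexed by node; entries at index 0 (collar) are unused for
    segment quantities (radius, order, t_s hold placeholder values there).
    """

    pos: np.ndarray          # (N, 3) cm
    parent: np.ndarray       # (N,) int, -1 for collar
    radius: np.ndarray       # (N,) cm (segment radius)
    order: np.ndarray        # (N,) int root type
    t_s: np.ndarray          # (N,) d origination time
    branch: np.ndarray       # (N,) int id of the root (polyline) the node ends
    source_index: np.ndarray | None = None   # map into a parent system

    def __post_init__(self):
        self.pos = np.asarray(self.pos, float)
        self.parent = np.asarray(self.parent, np.int64)
        self.radius = np.asarray(self.radius, float)
        self.order = np.asarray(self.order, np.int64)
        self.t_s = np.asarray(self.t_s, float)
        self.branch = np.asarray(self.branch, np.int64)

    # -- basic geometry -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_segments(self) -> int:
        return self.n_nodes - 1

    def seg_nodes(self) -> np.ndarray:
        """Node indices that carry a segment (all but the collar)."""
        return np.arange(1, self.n_nodes)

    def lengths(self) -> np.ndarray:
        """Per-segment length l [cm], indexed by distal node (0 unused)."""
        d = self.pos - self.pos[np.maximum(self.parent, 0)]
        out = np.linalg.norm(d, axis=1)
        out[0] = 0.0
        return out

    def surface_areas(self) -> np.ndarray:
        """Lateral (exchange) surface A_r = 2 pi r l per segment [cm^2]."""
        return 2.0 * np.pi * self.radius * self.lengths()

    def cross_sections(self) -> np.ndarray:
        """Xylem cross-section A_x = pi r^2 per segment [cm^2]."""
        return np.pi * self.radius ** 2

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.pos + self.pos[np.maximum(self.parent, 0)])

    def total_length(self, t: float | None = None) -> float:
        L = self.lengths()
        if t is not None:
            L = L[1:][self.t_s[1:] <= t]
            return float(L.sum())
        return float(L[1:].sum())

    def distance_to_tip(self) -> np.ndarray:
        """Per-node path distance to the farthest descendant tip [cm]."""
        L = self.lengths()
        dist = np.zeros(self.n_nodes)
        # children are always after parents (t_s sorted), walk backwards
        for j in range(self.n_nodes - 1, 0, -1):
            p = self.parent[j]
            dist[p] = max(dist[p], dist[j] + L[j])
        return dist

    # -- validation / growth --------------------------------------------
    def validate(self) -> None:
        if self.parent[0] != -1:
            raise ValueError("node 0 must be the collar (parent -1)")
        if np.any(self.parent[1:] < 0) or np.any(
                self.parent[1:] >= np.arange(1, self.n_nodes)):
            raise ValueError(
                "parents must precede children (tree sorted by t_s)")
        L = self.lengths()
        if np.any(L[1:] <= 0):
            bad = int(np.nonzero(L[1:] <= 0)[0][0]) + 1
            raise ValueError(f"zero-length segment at node {bad}")
        if np.any(self.t_s[1:] < self.t_s[np.maximum(self.parent[1:], 0)]
                  - 1e-9):
            raise ValueError("t_s must be non-decreasing along root paths")

    def active_subset(self, t: float) -> "RootSystem":
        """Induced subtree of segments with origination time <= t.

        Because ``t_s`` is sorted and monotone along paths, the active
        nodes are an index prefix (plus the collar); the returned system
        keeps ``source_index`` into this one.
        """
        keep = np.ones(self.n_nodes, bool)
        keep[1:] = self.t_s[1:] <= t
        idx = np.nonzero(keep)[0]
        remap = -np.ones(self.n_nodes, np.int64)
        remap[idx] = np.arange(len(idx))
        par = self.parent[idx].copy()
        par[1:] = remap[par[1:]]
        if np.any(par[1:] < 0):
            raise ValueError("active subset is disconnected: t_s not "
                             "monotone along paths")
        return RootSystem(self.pos[idx], par, self.radius[idx],
                          self.order[idx], self.t_s[idx], self.branch[idx],
                          source_index=idx)

    def sorted_by_ts(self) -> "RootSystem":
        """Reindex nodes in order of t_s with parents before children."""
        key = np.stack([self.t_s, np.arange(self.n_nodes)], axis=1)
        order = np.lexsort((key[:, 1], key[:, 0]))
        # collar stays first
        order = np.concatenate(([0], order[order != 0]))
        remap = np.empty(self.n_nodes, np.int64)
        remap[order] = np.arange(self.n_nodes)
        par = self.parent[order].copy()
        par[1:] = remap[par[1:]]
        rs = RootSystem(self.pos[order], par, self.radius[order],
                        self.order[order], self.t_s[order],
                        self.branch[order])
        rs.validate()
        return rs


# ---------------------------------------------------------------------------
# growth-replay: origination times from paired snapshots
# ---------------------------------------------------------------------------

def assign_origination_times(old: RootSystem, new: RootSystem,
                             t_i: float, t_ip1: float) -> np.ndarray:
    """Interpolate origination times of segments grown between two snapshots.

    ``new`` must contain ``old`` as its index prefix (the snapshot
    convention of this package).  For each new segment s, the connection
    point c is its first ancestor node present in ``old``; with

        l_s      = path length from c to the proximal node of s,
        Delta l_s = longest new-growth path length from c through s,

    the origination time is ``t_s = t_i + (l_s / Delta l_s)(t_{i+1} - t_i)``
    -- linear interpolation of arc length versus time along each branch
    path.  The first segment at a connection point gets t_i; times are
    strictly below t_{i+1} and non-decreasing along every path.

    Returns the full t_s array for ``new`` (old entries unchanged).
    """
    n_old, n_new = old.n_nodes, new.n_nodes
    if n_new < n_old:
        raise ValueError("new snapshot smaller than old")
    if not np.allclose(new.pos[:n_old], old.pos, atol=1e-9):
        raise ValueError("old snapshot is not a prefix of the new one")
    t_s = new.t_s.copy()
    t_s[:n_old] = old.t_s
    if n_new == n_old:
        return t_s

    L = new.lengths()
    # path length from the connection point to each new node's distal end
    depth = np.zeros(n_new)
    for j in range(n_old, n_new):
        p = new.parent[j]
        depth[j] = (depth[p] if p >= n_old else 0.0) + L[j]
    # longest downstream path within new growth (per-branch reading)
    down = depth.copy()
    for j in range(n_new - 1, n_old - 1, -1):
        p = new.parent[j]
        if p >= n_old:
            down[p] = max(down[p], down[j])
    dt = t_ip1 - t_i
    for j in range(n_old, n_new):
        delta_l = down[j]                   # c -> farthest tip through j
        l_s = depth[j] - L[j]               # c -> proximal node of j
        if delta_l <= 0.0:
            raise ValueError(f"inconsistent snapshots: zero new length at "
                             f"node {j}")
        t_s[j] = t_i + (l_s / delta_l) * dt
    return t_s


# ---------------------------------------------------------------------------
# hydraulic parameter table
# ---------------------------------------------------------------------------

@dataclass
class RootHydraulicTable:
    """Age-banded radial conductivity and axial conductance per root type.

    ``kx_bands[type]`` and ``kr_bands[type]`` are (age_min, value) pairs
    sorted by age; the value applies from age_min (inclusive) to the next
    band start (right-continuous steps).  Ages past the last band clamp
    to the last band value (conductances plateau with maturity).

    ``kr_mode``: 'constant' uses ``kr_constant`` for every segment;
    'age' uses the per-type ``kr_bands``.  ``kx_mode``: 'age' uses
    ``kx_bands``; 'constant' uses the time-average of the age-dependent
    bands (see :meth:`mean_kx`).  ``taproot_age_from_distance`` converts a
    taproot segment's distance-to-tip to an age via ``elongation_rate``
    instead of using t - t_s.
    """

    kx_bands: dict[int, list[tuple[float, float]]]
    kr_bands: dict[int, list[tuple[float, float]]]
    kr_constant: float = 8.64e-4          # cm d^-1 hPa^-1
    kr_mode: str = "constant"             # 'constant' | 'age'
    kx_mode: str = "age"                  # 'age' | 'constant'
    elongation_rate: float = 0.7          # cm d^-1, taproot distance->age
    taproot_age_from_distance: bool = False

    @staticmethod
    def _lookup(bands: list[tuple[float, float]], ages: np.ndarray):
        starts = np.array([b[0] for b in bands])
        vals = np.array([b[1] for b in bands])
        idx = np.searchsorted(starts, ages, side="right") - 1
        idx = np.clip(idx, 0, len(bands) - 1)
        return vals[idx]

    def mean_kx(self, rtype: int, horizon: float | None = None) -> float:
        """Band-width-weighted (time-average) K_x over ages [0, horizon].

        The default horizon is the start of the last band plus the mean
        width of the earlier bands, so every band contributes with its
        width.  Used for the constant-K_x perturbation mode, defined as
        the arithmetic mean of the age-dependent values.
        """
        bands = self.kx_bands[rtype]
        starts = [b[0] for b in bands]
        vals = [b[1] for b in bands]
        if len(bands) == 1:
            return vals[0]
        if horizon is None:
            widths = np.diff(starts)
            horizon = starts[-1] + float(np.mean(widths))
        edges = starts + [horizon]
        w = np.diff(edges)
        return float(np.sum(w * np.array(vals)) / np.sum(w))

    def segment_conductivities(self, system: RootSystem, t: float):
        """(K*_r * A_r, K_x) per segment of ``system`` at time ``t``.

        Returns two arrays indexed by node (entry 0 zero): the absolute
        radial conductance [cm^3 d^-1 hPa^-1] and the axial conductance
        [cm^4 d^-1 hPa^-1].  Segment ages are ``t - t_s`` (clamped at 0);
        taproot ages may instead derive from distance to tip.
        """
        ages = np.maximum(t - system.t_s, 0.0)
        if self.taproot_age_from_distance:
            dist = system.distance_to_tip()
            tap = system.order == TAPROOT
            ages = np.where(tap, dist / self.elongation_rate, ages)

        kx = np.zeros(system.n_nodes)
        krs = np.zeros(system.n_nodes)
        for rtype in np.unique(system.order[1:]):
            m = system.order == rtype
            m[0] = False
            key = int(rtype) if int(rtype) in self.kx_bands else LATERAL1
            if self.kx_mode == "constant":
                kx[m] = self.mean_kx(key)
            else:
                kx[m] = self._lookup(self.kx_bands[key], ages[m])
            if self.kr_mode == "constant":
                krs[m] = self.kr_constant
            else:
                kkey = int(rtype) if int(rtype) in self.kr_bands else LATERAL1
                krs[m] = self._lookup(self.kr_bands[kkey], ages[m])
        kr_abs = krs * system.surface_areas()
        kr_abs[0] = 0.0
        kx[0] = 0.0
        return kr_abs, kx

    def perturbed(self, kr_mode: str, kx_mode: str) -> "RootHydraulicTable":
        """Copy with the given radial/axial modes (sensitivity suite)."""
        return replace(self, kr_mode=kr_mode, kx_mode=kx_mode)


def default_hydraulic_table() -> RootHydraulicTable:
    """Reference age-dependent parameter set.

    Axial conductances [cm^4 d^-1 hPa^-1] increase stepwise with segment
    age as xylem matures; taproot bands were converted from
    distance-to-tip bands via the 0.7 cm d^-1 elongation rate.  Radial
    conductivity is constant 8.64e-4 cm d^-1 hPa^-1 in the reference
    mode; the age-dependent radial bands (used only by the sensitivity
    modes) decrease with age as apoplastic barriers develop.  Band values
    are representative magnitudes for a young legume root system and are
    meant to be edited via config for other parameterizations.
    """
    kx = {
        TAPROOT: [(0.0, 1.0e-2), (3.6, 4.3e-2), (7.1, 1.7e-1),
                  (14.3, 4.3e-1)],
        LATERAL1: [(0.0, 1.0e-3), (3.0, 5.0e-3), (10.0, 1.7e-2)],
        LATERAL2: [(0.0, 5.0e-4), (3.0, 2.0e-3), (10.0, 5.0e-3)],
    }
    kr = {
        TAPROOT: [(0.0, 1.73e-3), (5.0, 8.64e-4), (15.0, 4.32e-4)],
        LATERAL1: [(0.0, 1.73e-3), (5.0, 8.64e-4), (15.0, 4.32e-4)],
        LATERAL2: [(0.0, 1.73e-3), (5.0, 8.64e-4), (15.0, 4.32e-4)],
    }
    return RootHydraulicTable(kx_bands=kx, kr_bands=kr)


# ---------------------------------------------------------------------------
# RSML-style XML I/O
# ---------------------------------------------------------------------------

def write_architecture(path, system: RootSystem) -> None:
    """Write a root system as RSML-style XML.

    Each root (branch) is a polyline of points; per-point functions carry
    the segment diameter [cm] and origination time [d] (point k holds the
    attributes of the segment ending at point k; the first point repeats
    the first segment's values).  Child roots start at their branching
    node on the parent root.
    """
    from lxml import etree

    system.validate()
    root_el = etree.Element("rsml", version="1.0")
    meta = etree.SubElement(root_el, "metadata")
    etree.SubElement(meta, "unit").text = "cm"
    scene = etree.SubElement(root_el, "scene")
    plant = etree.SubElement(scene, "plant")

    # nodes of each branch, in index order (= along the root)
    branches: dict[int, list[int]] = {}
    for j in range(1, system.n_nodes):
        branches.setdefault(int(system.branch[j]), []).append(j)
    # a branch's parent branch = branch of its first node's parent
    parent_branch = {}
    for b, nodes in branches.items():
        p = system.parent[nodes[0]]
        parent_branch[b] = int(system.branch[p]) if p > 0 else -1

    els: dict[int, "etree._Element"] = {}

    def emit(b: int, parent_el) -> None:
        nodes = branches[b]
        el = etree.SubElement(parent_el, "root", ID=str(b),
                              order=str(int(system.order[nodes[0]])))
        geom = etree.SubElement(el, "geometry")
        poly = etree.SubElement(geom, "polyline")
        first = int(system.parent[nodes[0]])
        pts = [first] + nodes
        for j in pts:
            etree.SubElement(poly, "point",
                             x=repr(float(system.pos[j, 0])),
                             y=repr(float(system.pos[j, 1])),
                             z=repr(float(system.pos[j, 2])))
        fns = etree.SubElement(el, "functions")
        for name, arr in (("diameter", 2.0 * system.radius),
                          ("emergence_time", system.t_s)):
            fn = etree.SubElement(fns, "function", name=name,
                                  domain="polyline")
            vals = [arr[nodes[0]]] + [arr[j] for j in nodes]
            for v in vals:
                etree.SubElement(fn, "sample", value=repr(float(v)))
        els[b] = el

    order_of = sorted(branches,
                      key=lambda b: (system.order[branches[b][0]], b))
    for b in order_of:
        pb = parent_branch[b]
        emit(b, plant if pb < 0 else els[pb])

    etree.ElementTree(root_el).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def read_architecture(path) -> RootSystem:
    """Read a root system written by :func:`write_architecture`.

    Reading is the inverse of writing: the graph and origination times are
    recovered exactly, coordinates to better than 1e-6 cm.  Disconnected
    child roots (no matching branch point on the parent), cycles or
    missing attributes raise a parse error naming the offending element.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    pos = [np.zeros(3)]
    parent = [-1]
    radius = [0.0]
    order = [0]
    t_s = [-np.inf]
    branch = [-1]

    def node_key(p):
        return tuple(np.round(p, 6))

    index_of: dict[tuple, int] = {}

    def parse_root(el, parent_branch_nodes):
        b = int(el.get("ID"))
        rt = int(el.get("order", "0"))
        pts = el.findall("./geometry/polyline/point")
        if not pts:
            raise ValueError(f"root {b}: missing polyline")
        coords = np.array([[float(p.get("x")), float(p.get("y")),
                            float(p.get("z"))] for p in pts])
        fns = {f.get("name"): [float(s.get("value"))
                               for s in f.findall("sample")]
               for f in el.findall("./functions/function")}
        for need in ("diameter", "emergence_time"):
            if need not in fns or len(fns[need]) != len(pts):
                raise ValueError(f"root {b}: missing or short function "
                                 f"'{need}'")
        # attach the first point to an existing node
        key0 = node_key(coords[0])
        if rt == 0 and not index_of:
            # taproot: first point is the collar
            pos[0] = coords[0]
            index_of[key0] = 0
        if key0 not in index_of:
            raise ValueError(
                f"root {b}: first point {coords[0]} does not coincide with "
                "any node of its parent root (orphan root)")
        prev = index_of[key0]
        my_nodes = [prev]
        for k in range(1, len(pts)):
            j = len(parent)
            pos.append(coords[k])
            parent.append(prev)
            radius.append(fns["diameter"][k] / 2.0)
            order.append(rt)
            t_s.append(fns["emergence_time"][k])
            branch.append(b)
            index_of[node_key(coords[k])] = j
            my_nodes.append(j)
            prev = j
        for child in el.findall("root"):
            parse_root(child, my_nodes)

    roots = tree.findall(".//plant/root")
    if not roots:
        raise ValueError("no roots in file")
    for r in roots:
        parse_root(r, None)

    t_s[0] = min(t_s[1:]) if len(t_s) > 1 else 0.0
    rs = RootSystem(np.array(pos), np.array(parent), np.array(radius),
                    np.array(order), np.array(t_s), np.array(branch))
    rs = rs.sorted_by_ts()
    rs.validate()
    return rs
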