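"""Voxelized cylindrical soil domain, compartments and initial states.

The soil column is a cylinder embedded in a rectangular voxel grid
(cell-centered).  Voxels whose center lies within the cylinder radius are
soil (or split-layer wax inside a layer slab); voxels outside are wall
material with zero hydraulic conductivity, i.e. internal no-flow cells.

Coordinates: z = 0 at the soil surface, negative downward; x and y are
centered on the cylinder axis.  Voxels are half-open boxes indexed
0-based; cell k in z spans [-(k+1)*dz, -k*dz] with center -(k+0.5)*dz.

Compartments partition the *soil* voxels into horizontal slabs bounded by
the split-layer depths (or explicit bookkeeping depths for a continuous
domain); wall and layer voxels carry compartment label -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rootflow3d.soil_hydraulics import (
    SoilMaterial,
    psi_from_theta,
    water_content,
)

__all__ = ["SoilGrid", "SoilState", "build_cylinder_domain",
           "hydrostatic_init", "uniform_theta_init"]


@dataclass
class SoilGrid:
    """Structured voxel grid with material map and compartment labels."""

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float
    materials: list[SoilMaterial]
    material_index: np.ndarray      # (nx, ny, nz) int, index into materials
    compartment: np.ndarray         # (nx, ny, nz) int, -1 = wall/layer
    soil_material: int = 0          # index of the plain-soil material

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def cell_volume(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def height(self) -> float:
        return self.nz * self.dz

    def cell_centers(self):
        """Coordinate vectors (x, y, z) of cell centers."""
        x = (np.arange(self.nx) + 0.5) * self.dx - self.nx * self.dx / 2.0
        y = (np.arange(self.ny) + 0.5) * self.dy - self.ny * self.dy / 2.0
        z = -(np.arange(self.nz) + 0.5) * self.dz
        return x, y, z

    def z_centers(self) -> np.ndarray:
        return self.cell_centers()[2]

    @property
    def is_soil(self) -> np.ndarray:
        return self.material_index == self.soil_material

    @property
    def n_compartments(self) -> int:
        return int(self.compartment.max()) + 1

    def compartment_mask(self, c: int) -> np.ndarray:
        return self.compartment == c

    def slice_index(self, depth: float) -> int:
        """z-slice index of the horizontal slice containing ``depth`` (cm,
        positive-down or negative-z accepted)."""
        d = abs(float(depth))
        k = int(d / self.dz)
        if not (0 <= k < self.nz):
            raise ValueError(f"depth {depth} outside domain of height "
                             f"{self.height}")
        return k


@dataclass
class SoilState:
    """Matric potential, water content and sink fields on a grid."""

    grid: SoilGrid
    psi: np.ndarray                 # (nx, ny, nz), hPa
    theta: np.ndarray               # (nx, ny, nz), cm^3 cm^-3
    sink: np.ndarray                # (nx, ny, nz), d^-1, uptake density >= 0
    time: float = 0.0               # d

    def copy(self) -> "SoilState":
        return SoilState(self.grid, self.psi.copy(), self.theta.copy(),
                         self.sink.copy(), self.time)

    def storage(self, mask: np.ndarray | None = None) -> float:
        """Water volume [cm^3] stored in ``mask`` (default: soil voxels)."""
        if mask is None:
            mask = self.grid.is_soil
        return float(self.theta[mask].sum() * self.grid.cell_volume)

    def refresh_theta(self) -> None:
        """Recompute theta from psi with the local material's retention."""
        for im, mat in enumerate(self.grid.materials):
            m = self.grid.material_index == im
            if m.any():
                self.theta[m] = water_content(self.psi[m], mat)


def _layer_slices(depth: float, thickness: float, dz: float, nz: int):
    """z-slice indices of a layer slab centered at ``depth`` below surface."""
    if thickness < dz - 1e-12:
        raise ValueError(
            f"layer thickness {thickness} cm thinner than dz={dz} cm "
            "cannot be represented on this grid")
    n_sl = max(1, int(round(thickness / dz)))
    k0 = int(np.floor((depth - thickness / 2.0) / dz + 0.5 + 1e-9))
    k0 = max(0, min(k0, nz - n_sl))
    return list(range(k0, k0 + n_sl))


def build_cylinder_domain(
    radius: float = 7.0,
    height: float = 21.5,
    dx: float = 0.5,
    dy: float = 0.5,
    dz: float = 0.25,
    soil: SoilMaterial | None = None,
    wall: SoilMaterial | None = None,
    layer_depths: tuple[float, ...] = (),
    layer_thickness: float = 0.5,
    layer_materials: tuple[SoilMaterial, ...] | SoilMaterial | None = None,
    compartment_depths: tuple[float, ...] | None = None,
) -> SoilGrid:
    """Build the cylindrical column approximated on a voxel grid.

    ``layer_depths`` place horizontal split-layer slabs (full cylinder
    cross-section, ``layer_thickness`` cm thick, centered at each depth
    below the surface).  ``layer_materials`` gives one material per layer
    (or a single material reused); layers are omitted entirely for a
    continuous domain.  ``compartment_depths`` default to the layer
    depths and bound the bookkeeping compartments; for a continuous
    domain they may be given explicitly.
    """
    from rootflow3d.soil_hydraulics import default_materials

    defaults = default_materials()
    soil = soil or defaults["soil"]
    wall = wall or defaults["wall"]
    if radius <= 0 or height <= 0:
        raise ValueError("radius and height must be > 0")
    for d in layer_depths:
        if not (0.0 < d < height):
            raise ValueError(f"layer depth {d} outside (0, {height})")

    nx = int(round(2 * radius / dx))
    ny = int(round(2 * radius / dy))
    nz = int(round(height / dz))

    materials: list[SoilMaterial] = [soil, wall]
    mat_idx = np.full((nx, ny, nz), 1, dtype=np.int32)   # wall by default

    x = (np.arange(nx) + 0.5) * dx - nx * dx / 2.0
    y = (np.arange(ny) + 0.5) * dy - ny * dy / 2.0
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    inside = r2 <= radius ** 2 + 1e-12
    mat_idx[inside, :] = 0

    # split-layer slabs
    if layer_depths:
        if layer_materials is None:
            layer_materials = (defaults["paraffin_sealed"],) * len(layer_depths)
        elif isinstance(layer_materials, SoilMaterial):
            layer_materials = (layer_materials,) * len(layer_depths)
        if len(layer_materials) != len(layer_depths):
            raise ValueError("need one layer material per layer depth")
        for depth, lm in zip(layer_depths, layer_materials):
            materials.append(lm)
            idx = len(materials) - 1
            for k in _layer_slices(depth, layer_thickness, dz, nz):
                sl = mat_idx[:, :, k]
                sl[sl == 0] = idx
                mat_idx[:, :, k] = sl

    # compartments: slabs of soil voxels between the boundary depths
    if compartment_depths is None:
        compartment_depths = tuple(layer_depths)
    bounds = [0.0] + sorted(compartment_depths) + [height]
    comp = np.full((nx, ny, nz), -1, dtype=np.int32)
    zc = -(np.arange(nz) + 0.5) * dz
    for ci in range(len(bounds) - 1):
        in_slab = (zc < -bounds[ci] + 1e-12) & (zc > -bounds[ci + 1] - 1e-12)
        for k in np.nonzero(in_slab)[0]:
            sl = comp[:, :, k]
            sl[mat_idx[:, :, k] == 0] = ci
            comp[:, :, k] = sl

    return SoilGrid(nx, ny, nz, dx, dy, dz, materials, mat_idx, comp)


def _blank_state(grid: SoilGrid) -> SoilState:
    z = np.zeros(grid.shape)
    return SoilState(grid, z.copy(), z.copy(), z.copy(), 0.0)


def hydrostatic_init(grid: SoilGrid, psi_bottom: float = 0.0) -> SoilState:
    """State at hydrostatic equilibrium: total potential psi + z constant.

    ``psi_bottom`` is the matric potential [hPa] at the domain bottom
    ``z = -height``; with psi_bottom = 0 the column is saturated at the
    base and the suction at the surface equals the column height in cm.
    """
    st = _blank_state(grid)
    z = grid.z_centers()
    z_bottom = -grid.height
    psi_z = psi_bottom - (z - z_bottom)          # psi + z = const
    st.psi[:, :, :] = psi_z[None, None, :]
    st.refresh_theta()
    return st


def uniform_theta_init(grid: SoilGrid, theta) -> SoilState:
    """State with uniform water content per compartment.

    ``theta`` is a scalar (all compartments equal) or a sequence with one
    value per compartment.  Layer and wall voxels receive the potential of
    the compartment above them (hydraulically inert, so the choice only
    fixes their inert storage).
    """
    nc = grid.n_compartments
    theta_arr = np.broadcast_to(np.atleast_1d(np.asarray(theta, float)),
                                (nc,))
    soil = grid.materials[grid.soil_material]
    psis = np.array([psi_from_theta(th, soil) for th in theta_arr])

    st = _blank_state(grid)
    for c in range(nc):
        st.psi[grid.compartment == c] = psis[c]
    # non-soil voxels: per z-slice, potential of the nearest compartment above
    zc = grid.z_centers()
    comp_top = np.full(grid.nz, 0, dtype=int)
    for k in range(grid.nz):
        labels = grid.compartment[:, :, k]
        lab = labels[labels >= 0]
        if lab.size:
            comp_top[k] = int(lab[0])
        else:
            comp_top[k] = comp_top[k - 1] if k > 0 else 0
    for k in range(grid.nz):
        sl = st.psi[:, :, k]
        sl[grid.compartment[:, :, k] < 0] = psis[comp_top[k]]
        st.psi[:, :, k] = sl
    st.refresh_theta()
    return st
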