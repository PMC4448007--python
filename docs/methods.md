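# Methods

`rootflow3d` simulates water flow in an unsaturated soil column coupled
to water flow inside a growing root system, for the geometry of
split-root column experiments: a PVC cylinder (radius 7 cm, height
21.5 cm) filled with a quartz substrate, optionally partitioned by thin
horizontal paraffin layers at 5, 10 and 15 cm depth, holding a single
faba bean whose transpiration is the only water loss.

## Soil water flow

Soil flow follows the Richards equation in mixed
(water-content/pressure) form,

    dtheta/dt = div( K(psi) grad(psi + z) ) - S,

with matric potential `psi` [hPa], water content `theta`
[cm^3 cm^-3], unsaturated conductivity `K(psi)` [cm d^-1] and a sink
density `S` [d^-1] representing root uptake (positive S extracts
water).  Pressure heads in hPa are treated as identical to cm of water
column (< 2 % error), so no unit conversions appear anywhere.

Retention and conductivity use the bimodal van Genuchten form (a
weighted sum of two modalities, weights `w1 = 1 - w2`) with a
Mualem-type conductivity evaluated in closed form:

    Se_i   = [1 + (alpha_i |psi|)^(n_i)]^(-m_i),     m_i = 1 - 1/n_i
    theta  = theta_r + (theta_s - theta_r) (w1 Se_1 + w2 Se_2)
    K      = Ks Se^lambda [ sum_i w_i alpha_i (1 - (1 - Se_i^(1/m_i))^(m_i))
                            / sum_i w_i alpha_i ]^2

The closed form is exact for this retention family (the per-modality
Mualem integral evaluates to `alpha_i [1 - (1 - Se^(1/m))^m]`); the test
suite verifies it against direct quadrature of the capillary-bundle
integral.  The substrate parameter set (theta_r 0.01, theta_s 0.35,
alpha 0.05 hPa^-1, n 4, w2 0.35, alpha2 0.0033 hPa^-1, n2 1.3, lambda
0.5, Ks 170 cm d^-1) reproduces the measured anchor points of the
retention curve (10.6 % at -431 hPa, 9.5 % at -745 hPa).  `psi >= 0` is
treated as exactly saturated, with no air-entry offset.  Setting
`w2 = 0` recovers the classic unimodal model exactly (wall and paraffin
materials use it with a near-flat retention curve).

### Discretization

The cylinder is embedded in a rectangular, cell-centered voxel grid
(default 0.5 x 0.5 x 0.25 cm; z = 0 at the surface, negative downward).
Voxels whose center lies outside the 7 cm radius are wall material with
`Ks = 0` — internal no-flow cells rather than excluded nodes.  Paraffin
layers are 0.5 cm thick slabs spanning the full cross-section (10x the
physical layer thickness, the original trade-off for tractable voxel
counts; the thickness is configurable).  Every outer boundary is
zero-flux: the experiment had a gravel-mulched, never-rewetted surface
and a sealed base, so transpiration is the only sink.

The implicit scheme is backward Euler with modified-Picard
linearization: each iteration solves a symmetric positive-definite
7-point system for `psi^(m+1)` using the analytic capacity
`C = dtheta/dpsi`, then the accepted step's mass ledger is evaluated
with the exact `theta(psi)`, so the tracked per-step error is the
linearization gap only (typically 1e-4 cm^3 per step; cumulative errors
stay one to two orders below the 0.5 % closure bound over a full run).
Face conductivity is the arithmetic mean of the two cell values within
one material and the harmonic (series) mean across a material
interface, so a sealed layer blocks its faces exactly and a leaky
layer's small K governs them.  A specific storage of 1e-8 cm^-1
regularizes saturated and impermeable cells; it is carried in the mass
ledger so conservation statements remain exact.

Numerical settings (all in `RichardsConfig`): time steps adapt within
[1e-5, 0.02] d, growing 1.3x after fast convergence and halving on
Picard failure; the Picard tolerance is 0.5 hPa on the increment
(relaxed proportionally above ~1000 hPa of suction) plus a 1e-3 cm^3
bound on the per-step ledger gap; iteration updates are capped at
2000 hPa and damped after eight iterations, which only alters the
iteration path, never the fixed point.  The linear solves use
Jacobi-preconditioned conjugate gradients warm-started from the
previous iterate, with a sparse-direct fallback.

## Root water flow

The root system is a tree of short segments rooted at the collar.  Each
segment couples to the soil through a radial conductance
`K*_r A_r` [cm^3 d^-1 hPa^-1] (lateral surface `A_r = 2 pi r l`) and to
its neighbors through an axial conductance `K_x / l`
[cm^3 d^-1 hPa^-1], with the gravitational head included in the axial
driving force.  Root nodes have no storage, so nodal mass balance gives
a sparse SPD system for the xylem potentials, solved directly.  The
collar carries either a prescribed transpiration flux (the default — a
day/night step function, matching the original forcing) or a prescribed
potential; an optional collar-potential limit is available but off by
default.

Derived quantities:

* **SUF** (standard uptake fraction): per-segment share of uptake under
  uniform soil potential and unit collar demand; computed with the
  gravity term disabled (i.e. uniform *total* potential) so that
  `sum SUF = 1` holds identically and the fractions depend only on
  conductance ratios, never on their absolute scale.
* **psi_s_eff** = `sum_j SUF_j psi_s_int_j`, the effective soil
  potential, and **K_root** = `T_act / (psi_s_eff - psi_collar)`, the
  whole-root-system conductance (undefined at zero transpiration, where
  `psi_collar = psi_s_eff` — the predawn identity).

Radial and axial conductivities are right-continuous step functions of
segment age, per root type, with ages past the last band clamped (the
source parameterizations plateau with maturity).  The reference mode
uses constant `K*_r = 8.64e-4 cm d^-1 hPa^-1` and age-increasing `K_x`;
taproot bands were converted from distance-to-tip to age by the
0.7 cm d^-1 elongation rate, and a distance-based lookup mode is also
provided.  **The numeric band values are an editable config table**:
the underlying lupin measurements exist only as published curves, so
the shipped values are representative magnitudes and every derived
result is relative to this parameterization.  The sensitivity suite
exercises the four combinations {constant, age-dependent} x
{K*_r, K_x}; the constant-K_x mode is the band-width-weighted time
average of the age-dependent values over one band-structure horizon.

## Coupling

Exchange happens through (i) the soil-root interface potential of each
segment — the trilinear (distance-weighted) interpolation of the soil
potential at the segment midpoint, segments being split at voxel-face
planes first — and (ii) the sink density summing radial inflows into
the voxel grid, normalized by voxel volume so that `sum S V = T_act`
exactly.  Two deposition modes exist: the default deposits each
sub-segment's flow onto the same trilinear stencil used for sensing
(`B = W^T`), the cell-centered analog of nodal sink attribution on a
vertex-centered grid; an enclosing-voxel mode assigns the whole flow to
the midpoint's voxel.  The default is not merely cosmetic: with
mismatched sensing and deposition a root-dense voxel can be overdrafted
without the segments that drain it ever feeling its dryness, and the
coupled problem loses its bounded fixed point (observed as potentials
running off toward -1e6 hPa).  Stencils are restricted to soil cells
(weights on wall/layer cells are dropped and renormalized), and
sub-segments inside a layer slab are snapped to the nearest soil cell
in their column — roots pierce the wax but exchange water with soil.

One coupled step runs the fixed-point sweep "interface potentials ->
xylem solve -> sink field -> Richards step" until the interface
potentials move less than 1 hPa (at most 5 sweeps); a lagged
single-sweep mode is available.  Because the sink is frozen inside each
Richards call, that call's internal sub-stepping is budgeted (16
sub-steps); when soil near roots becomes very dry the step is refused
and the scenario driver shortens the coupling interval instead, so the
xylem feedback is re-evaluated at the cadence the stiffness demands.

## Scenarios and analyses

A scenario = geometry + layer configuration (CD: none; NC: `Ks = 0`;
SC: leaky, default 0.001 cm d^-1, per-layer overridable, so the mixed
sealed/leaky configuration is expressible) + architecture + hydraulic
table + daily transpiration rates (14 h photoperiod by default) +
initial condition (hydrostatic from a base potential, or uniform water
content per compartment) + duration.  Growth is replayed by activating
segments at their origination times.  Outputs: virtual tensiometers
(slice-mean matric potential at the instrument depths; a point-probe
would sample a single voxel — the slice mean is the default because a
tensiometer cup integrates over its surroundings), per-compartment
ledgers (cumulative uptake, storage, net flow through the compartment's
bounding voxel-face planes, closing to the mass tolerance at every
output time), collar potential series, and predawn collar potentials
sampled at the last instant of each night (the day boundary).

Origination times for snapshot-derived architectures interpolate arc
length against time: a segment at new-growth path distance `l_s` from
its connection point, on a branch whose longest new path through it is
`Delta l_s`, originates at `t_i + (l_s / Delta l_s)(t_{i+1} - t_i)`.
For branched new growth the per-branch path reading is used (each
branch is mapped onto the window by its own extent); segments of roots
already growing at `t_i` are thereby recovered to within half a
snapshot interval, while a root first emerging inside a window can only
be placed within that window.

## Synthetic data

The generator emulates the structural statistics of the scanned root
systems: taproot elongation 0.7 cm d^-1 with gravitropic jitter,
first-order laterals at 2 cm^-1 density emerging 2 d behind the tip at
~70 degrees insertion, sparse second-order laterals, segment length
0.087 cm, snapshots every 2 d, and diameters (taproot 0.18 cm, laterals
0.095/0.05 cm) chosen so the length-weighted mean diameter is
~0.106 cm.  Branching statistics are package choices — no measured
values exist for them.  Transpiration series rise logistically toward a
peak (transpiration tracks leaf-area growth) with an optional sharp
post-stress decline and seeded day-to-day scatter.  The generator does
**not** emulate: root growth responses to soil state (growth is
prescribed), diameter tapering, the seed compartment of the physical
setup, or CT imaging artifacts.  Passing tests on these bundles
therefore validate the flow physics and bookkeeping under controlled
conditions; they do not certify agreement with any particular measured
root system.

### Desk-scale study conditions

Full-resolution month-long runs are unnecessary for verifying the
mechanisms, so the bundled study conditions
(`generate_reduced_experiment`) compress them: a 14 x 14 x 43 voxel
grid (1.0 x 1.0 x 0.5 cm cells), 10 simulated days, transpiration
rising logistically to 30 cm^3 d^-1 with midpoint at day 5 (cumulative
~135 cm^3), which draws the rooted top compartment well into the dry
range within the window as the physical experiments did over a month.
The scenario contrast in predawn potentials (SC vs CD) is evaluated on
the hydrostatic-equilibrium initial condition: a uniform-water-content
column is not at equilibrium, and its early gravity settling dries the
rooted topsoil in CD faster than uptake does, which would confound the
layer effect with the initial condition during the first days.

## Known limitations

* No rhizosphere (root-surface) resistance: the interface potential is
  the voxel-interpolated bulk value, so local dry-down around roots is
  resolved only at voxel scale.
* No root storage/capacitance, cavitation, or potential-dependent
  radial conductivity; no hysteresis or temperature dependence in the
  soil functions; no evaporation or infiltration boundary fluxes.
* The root hydraulic band values are representative, not measured;
  absolute collar potentials and K_root scale with them (SUF and the
  scenario contrasts depend only on ratios).
* Paraffin layers are 10x their physical thickness (as in the original
  trade-off), so layer storage and transit times are not physical;
  their hydraulic resistance is controlled by the layer Ks.
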