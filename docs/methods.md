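# Methods

## Physical model

A single cell transits a planar microchannel under pressure-driven flow.
The model is two-dimensional: for channels whose height and width are
comparable (here 20 um x 20 um), the in-plane deformation of a cell
carried along the mid-plane captures the dominant shape change, at a
small fraction of the cost of a 3D simulation.  The out-of-plane depth
enters only through the flow-rate conversion.

**Carrier fluid.** Incompressible Newtonian fluid (default density
1000 kg/m^3, viscosity 1-5 mPa.s), governed by the incompressible
Navier-Stokes equations in a fixed laboratory frame.  The advective term
is retained: at the top flow rate (100 uL/min, mean velocity 4.17 m/s)
the channel Reynolds number is of order 10^2.  Boundary conditions: a
fully developed (plane-Poiseuille) velocity profile at the inlet, static
pressure 0 Pa with zero velocity gradient at the outlet, no-slip on all
walls.  The volumetric flow rate Q prescribed in uL/min is converted to
the 2D mean velocity by dividing by the full 20 um x 20 um cross-section,
U = Q/(W*D); the inlet profile is imposed across the inlet reservoir with
the same 2D flux U*W.

**Cell.** An incompressible neo-Hookean solid with a parallel Newtonian
dashpot (Kelvin-Voigt arrangement), initially a circular disk of diameter
8-16 um released on the channel axis one diameter upstream of the
constriction entrance.  Incompressibility (nu = 1/2) fixes the shear
modulus at G = E/3.  The plane-strain strain-energy density per unit
reference area is

    W(F) = (G/2) (tr(F^T F) - 2 - 2 ln J) + (kappa/2) (J - 1)^2,

with J = det F and kappa = 100 G a near-incompressibility penalty chosen
so the solid needs no pressure unknown while the cell's area drifts by
well under 2% per transit (monitored).  For small strains this energy
gives the plane-strain incompressible uniaxial modulus 4G = 4E/3, which
is what the stiffness unit test asserts.  The solid is massless (the
fluid it displaces carries the inertia), the standard idealization for
neutrally buoyant cells.

**Kelvin-Voigt branch and relaxation time.** The dashpot is
parameterized by the retardation time tau_r, with eta_c = tau_r * G
derived, because the relaxation-time sweeps drive tau_r directly (0.04 to
0.64 ms).  Under a stress step the branch creeps as
eps(t) = (sigma0/E)(1 - e^(-t/tau_r)), the closed form used as a
verification oracle.  A direct cell-viscosity input is accepted as an
alternative; tau_r wins when both are given.  Note the two published
parameter ranges are mutually inconsistent (cell viscosity 1-5 mPa.s
versus tau_r = 0.04-0.64 ms, which implies eta_c = tau_r G = 0.02-0.32
Pa.s at G = 500 Pa); this package treats tau_r as primary and documents
the discrepancy rather than resolving it.

## Numerical method

**Fluid.** Finite-volume incremental-pressure projection method on a
staggered (MAC) grid, default spacing h = W/20 with a documented floor
of 16 cells across the channel.  Advection is explicit MUSCL
(minmod-limited second-order upwind): first-order upwind would
contribute a numerical viscosity of order rho |u| h / 2, which at
80-100 uL/min exceeds the physical viscosity and visibly biases the
flow-rate/viscosity comparisons.  Diffusion is implicit (backward
Euler) with a spatially variable viscosity field and a direct sparse
factorization, refreshed when the viscosity field changes; walls sit
half a spacing beyond the nearest velocity face and use the quadratic
one-sided stencil (exact for parabolic profiles).  The pressure Poisson
equation is factorized once per run and solved exactly each step, so
the discrete divergence is at round-off level.  The incremental form
matters: the non-incremental (Chorin) variant leaves an O(dt) numerical
boundary layer at the walls that dominated the profile error.  With
these choices the steady no-cell plane-Poiseuille solution is exact to
round-off; the convergence-order test therefore uses a quartic forced
profile with genuine O(h^2) truncation error (observed order ~2).

**Coupling.** Explicit immersed-boundary cycle with the 4-point
regularized delta kernel: nodal elastic forces are spread to the grid
(total force conserved to round-off), the fluid advances one step, node
velocities are interpolated back with the adjoint kernel, and nodes move
with them.  A fixed grid avoids remeshing at large deformation and makes
the conservation properties exactly testable.  The cell mesh is a
deterministic polar-ring triangulated disk (Delaunay on staggered rings)
with target edge min(h, d/10), so runs are bit-reproducible.

The Kelvin-Voigt dashpot is realized inside the fluid step: because the
immersed boundary moves with the local fluid velocity, the solid's
rate-of-strain equals the local fluid rate-of-strain, so the parallel
Newtonian branch is exactly a viscosity increment eta_c on the cell's
interior.  The momentum diffusion uses div(eta grad u) per velocity
component with eta = eta_fluid + eta_c inside the current contour
(rasterized at cell centers, arithmetic corner averaging); the
transpose-gradient part of the stress divergence is supported only on
the one-cell band where eta jumps and is neglected.  Treating the
dashpot implicitly this way is what keeps the scheme stable across the
whole tau_r range: spreading the Lagrangian viscous force explicitly is
unconditionally unstable at eta_c = 0.32 Pa.s for any affordable step.
The Lagrangian viscous-force assembly is still provided (and verified
against a hand-assembled single-element case) as part of the solid
module's API.

**Time step.** dt is fixed per run at the minimum of the advective CFL
bound (with a blockage allowance on the peak velocity) and an elastic
bound dt <= 0.5 ds sqrt(rho/kappa) (ds = solid mesh edge), the
wave-speed heuristic for explicit immersed elastic bodies; if a step
still trips the CFL guard the step size is halved deterministically.
Element inversion, node escape from the grid, or non-finite fields abort
a run with a diagnostic error; sweeps record such rows as failed and
continue.

**Measurement.** The deformation index is the long/short axis ratio of
the contour's inertia-equivalent ellipse (rotation-invariant; a
minimum-rotated-rectangle variant is available for sensitivity checks).
The steady DI of a run is the median over samples whose centroid lies in
the middle half of the straight channel.  V0 is the area-weighted mean
node velocity (centroid velocity); V1 is the mean streamwise fluid
velocity over the mid-channel cross-section; gamma = (V1 - V0)/a_p,
tau = gamma eta, F = tau * area/2 (per unit depth; multiply by the 20 um
depth for a 3D-equivalent force).  Because the cell rides the fast
channel axis, V0 typically exceeds V1 and gamma is negative; the sign is
reported as computed.

## Study conditions and defaults

Baseline: 20 um x 20 um channel; cell diameter 12 um (mid-range of the
8-16 um leukocyte span), E = 1500 Pa, tau_r = 0.04 ms; fluid 1 mPa.s,
1000 kg/m^3, 20 uL/min.  The published study does not state which values
were held fixed in each sweep; these baselines are this package's
declared choice, all inside the published ranges.  Channel length 200 um
with 60 um x 60 um entry/exit reservoirs is likewise a declared geometry
choice (the source figures show the outline but no dimensions).  Sweep
grids: flow 20:20:100 uL/min, viscosity 1:1:5 mPa.s, diameter 8:2:16 um,
E 1500:1500:7500 Pa, tau_r {0.04, 0.08, 0.16, 0.32, 0.64} ms (endpoints
published; geometric spacing ours).

**Rigid limit.** The rigid-cell check takes G -> 5x10^5 Pa while holding
the dashpot at the baseline cell's value (eta_c = 20 mPa.s) rather than
holding tau_r: scaling tau_r's dashpot with G (eta_c = tau_r G = 20 Pa.s)
probes a viscous-droplet limit instead, and its 2x10^4:1 interior
viscosity contrast leaves a spurious DI residual an order larger than
the elastic one.  With the fixed dashpot the measured residual is
DI - 1 ~ 4x10^-4.

## Problem sizes used by the test suite

The verification suite runs every check end-to-end at reduced problem
sizes chosen for turnaround: channel 100 um, reservoirs 40 um, grid
spacing W/16 for transit checks; the diameter sweep runs at W/20 (the
2 um lubrication film of a 16 um cell is the resolution-critical case);
the rigid-limit run shortens the channel to 60 um because its stable
time step is ~30x smaller.  The acceptance script runs the reference
configuration at the full geometry (200 um channel, 60 um reservoirs,
h = W/20).

**Grid sensitivity of the absolute DI.** The immersed-boundary kernel
smears the interface over ~4h, so the absolute deformation index
converges only at first order: at the baseline condition the steady DI
measures 1.270 (W/16), 1.233 (W/20) and 1.167 (W/32).  The factor
*trends* — monotonicity, curvature, the ordering of conditions — are
stable across these resolutions and are the quantity this package
treats as converged; absolute DI values should be read with a ~5-10%
discretization allowance.

## What the synthetic fixtures do and do not cover

The fixtures module generates analytic Poiseuille fields, contour
families (circle, ellipse, rounded triangle, noisy star) whose truth DI
is computed by an independent dense-raster moment integration, and
closed-form Kelvin-Voigt creep/recovery series.  They exercise every
measurement and oracle path without the FSI loop.  They do not emulate
real cytometry imagery: no pixelation, segmentation noise, or
out-of-plane effects, so passing fixture tests says nothing about image
processing robustness — only about the geometry and constitutive
bookkeeping.

## Known limitations

- 2D plane strain confines the cell more strongly than a real square
  duct (the fluid cannot bypass in the third dimension), so absolute
  deformation indices are larger than in a 3D or experimental setting;
  trends with each factor are the meaningful output.
- The immersed-boundary kernel smears the cell boundary over ~4h; at
  d = 16 um the 2 um wall film is at the resolution floor, and DI values
  there carry the largest discretization error.
- The flow-rate/viscosity "equivalence" (matched eta*Q product) holds
  only approximately in this model: at 80 uL/min the Reynolds number is
  ~67 and inertia adds deformation that the matched low-flow/high-
  viscosity condition lacks.  The measured relative DI difference is
  ~15-20%, and it shrinks with grid refinement but not below ~15% at
  affordable resolutions.
- Single cell, no adhesion, no membrane/cortex structure, no nucleus;
  Newtonian carrier only.
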