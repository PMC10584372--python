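# Methods

## The model

The cellularization-stage embryo is an ellipsoid of revolution (long axis
511 um, short axis 184 um, long axis = x) whose surface is partitioned into
cells by a disordered hexagonal network.  Each cell is an *open prism*: its
apical polygon and lateral walls are triangulated networks of linear
(Hookean) springs with compartment-specific spring constants `k_apical`,
`k_lateral`, `k_basal` (nN/um); the basal face carries no surface, only a
polygonal rim of basal springs, reflecting cells that are open to the yolk.
Rest lengths equal construction lengths, so a freshly built mesh is
stress-free, and there is no bending stiffness or rest-length turnover.

The surrounding fluid is Newtonian Stokes flow: 1000 cP
(1e-3 nN s/um^2) cytoplasm and yolk inside the cell layer, a ~1 cP
perivitelline film between the layer and the rigid vitelline shell, which is
a no-slip boundary.  Units throughout: um, s, nN, nN/um, nN s/um^2.

A triangulated central-force spring sheet behaves as an isotropic 2D elastic
sheet.  Measured numerically here (`measure_sheet_moduli`, uniaxial stretch
with free transverse edges, bulk strain read off an affine fit that excludes
a 2-row clamp boundary layer), the lattice satisfies E = 2k/sqrt(3) ~ 1.155k
with Poisson ratio 1/3, the classical central-force triangular-lattice
result; the measured E/k is size-independent above ~15 rows to better than
1%.  (A sometimes-quoted E = 2k/3 is not what this lattice does; nothing is
hard-coded, the value is always measured.)

## Dynamics backends

**Immersed boundary (IB).**  Each step executes five ordered sub-steps:
elastic+external forces at solid nodes; spreading to fluid nodes with a
compact polynomial kernel (`(1-(d/r)^2)^3`, support = 2 fluid spacings,
weights normalized per solid node so constants transfer exactly and total
force is conserved to machine precision); a Stokes solve; interpolation of
fluid velocities back with the same weights (making interpolation the exact
adjoint of spreading under the volume-weighted inner product); explicit
advection by dt.

The Stokes solve uses the method of regularized Stokeslets (Cortez blob,
regularization eps = 0.75 x fluid spacing by default): nodal forces act as
regularized point forces and unknown tractions at shell collocation nodes
enforce no-slip, solved through a prefactored dense LU.  The mobility uses
the volume-dominant interior viscosity; the thin 1 cP film is treated as a
lubrication layer (see "Desk-scale choices").  The solver reproduces the
free-space Stokeslet near field to a few percent (the residual is the
genuine wall correction, O(r/R)) and its held-out boundary residual
decreases under shell refinement.  The dense mobility caps practical fluid
grids at ~1.5k nodes; this is the binding resolution constraint.

**Constant drag (overdamped).**  Node velocity = net force / gamma.  Used
for the flat-lattice experiments (drag gamma = 1 nN s/um per node, the
regime in which floppy-mode relaxation is slow on the 60 s loading scale)
and for cheap whole-embryo runs.  The embryo default gamma = 0.002 nN s/um
is calibrated so the pulled-edge relaxation at the best-fit uniform
stiffness k = 0.001 nN/um falls in the experimentally observed ~1 min
range, placing the surrogate in the same drag-to-elasticity regime as the
fluid-coupled model.

Time steps are explicit with dt = 0.1 gamma_eff / k_max (gamma_eff probed by
a unit force for the IB backend) and automatic halving when any node would
move more than half a rest length.  For both backends the elastic energy is
non-increasing in force-free relaxation.

## Pulling protocol and constraint forces

The cantilever contact is a rigid imposed displacement of the two nodes of
one lateral (vertical) cell edge on the dorsal mid-embryo: loading at
0.5 um/s for 60 s, holding 60 s, then free unloading (120 s default).  The
applied force is a Lagrange multiplier: per step the external force on the
constrained nodes solves M_cc f = v_imposed - v_elastic, with M_cc the
backend mobility restricted to those degrees of freedom (unit-force probes;
diagonal 1/gamma for constant drag), validated against a bisection oracle.
The constrained mobility is refreshed on a 1 s cadence rather than every
step; the constrained nodes are re-pinned to the exact imposed trajectory
after each step.

A *free-floating* overdamped mesh acquires rigid-body drift and rotation
from the net applied impulse — motion the shell-confined fluid model
forbids.  Relaxation, recoil and deformation-profile measurements on
overdamped embryo runs are therefore taken in the best-fit rigid-body
(Kabsch) co-moving frame (`displacement_corotated`), stored alongside the
raw trace.  Confinement is not merely cosmetic: under sustained pulling the
free mesh saturates at a rotation-drag force plateau, whereas the
shell-confined model shows the linearly growing loading force and the
holding-force plateau at roughly half the peak that the experiments show.
The geometric origin is that tangential tissue motion on the closed surface
must stretch rings of cells encircling the embryo and deform cells at the
high-curvature poles, where the per-spring stress k(L - L0) is visibly
upregulated.

## Flat-lattice (floppy/stiff) experiments

Triangular lattices are Maxwell-rigid (constraints >= 2N-3; stiffness-matrix
null space = rigid-body modes only); honeycombs are floppy (null space
strictly larger, matching the Maxwell count).  Patches are built with a
near-rectangular outline, rim pinned, and loaded at the interior node
nearest the centre (lowest index on ties) at 0.5 um/s with 8 um bonds —
displacements of several bond lengths, i.e. deliberately in the
geometrically nonlinear regime where the floppy phenomenology lives.

Two relaxation observables are deliberately distinct:

* `fit_decay` (protocol below) grants a fitted asymptote — appropriate for
  the embryo, whose elastic recoil is complete;
* `effective_relaxation_time` measures the approach to the *undeformed*
  state with no asymptote granted.  A floppy network stalls in a deformed
  zero-energy configuration, so this time grows with k for the honeycomb
  while it falls with k for the triangular lattice; with the
  asymptote-subtracted fit the stall would be absorbed into the asymptote
  and the ordering inverted.

## Quantification

Kymographs: intensity is sampled along a curve (or the membrane marks are
apical vertices in a sagittal band of a simulation record, arc-length
parameterized along the sagittal ellipse), membranes are intensity peaks
refined to sub-pixel by parabolic interpolation and tracked by
nearest-neighbour continuity (max jump 2 um/frame, minimal-displacement
tie-break); tracks with gaps >3 frames are flagged, never interpolated.

Deformation profiles plot each membrane's displacement against its initial
position.  `normalize_profiles` scales each profile's peak |displacement| to
1 and reports the residual spread on the common support.  `estimate_beta`
rescales x by t^-beta about the point of maximal displacement, scans beta
over [-0.2, 1] in steps of 0.01 with 10x local refinement, and reports the
argmin of the residual; alpha is the log-log slope of peak displacement
versus time.  beta = 0 indicates adiabatic (friction-free) spreading;
beta ~ 0.5, diffusive spreading.

`fit_decay`: asymptote initialized as the mean of the final 10% of the
trace; log-linear fit over the window where the subtracted signal exceeds 3x
the tail noise; then a nonlinear refinement of (A, tau, C), because the
tail-mean asymptote is biased high on traces that have not fully plateaued
and would otherwise bias tau low.  The fit is invariant to adding constants
and to uniform rescaling.

## Cantilever calibration

The flexible PDMS tip is a clamped-free Euler-Bernoulli beam: point tip load
F = 3EI d/L^3; uniform drag load w per unit length gives d = wL^4/8EI, with
w = 4 pi mu U / (ln(L/r) + 0.84) from slender-body theory for perpendicular
motion (the constant is configurable).  1 MPa = 1e3 nN/um^2.  Dragging at
known speed through a fluid of known viscosity inverts exactly for the
Young's modulus; tapered tips are supported through piecewise-constant EI in
the numerical beam integration used as the oracle.  A warning is raised for
deflections above 20% of the tip length (linear-beam limit).

## Synthetic data

The movie generator renders membranes as Gaussian-profile bright lines at
8 um spacing (the cell size), displaced by
d(x,t) = a t^alpha exp(-|x-x0| / (lambda t^beta)) with additive Gaussian
intensity noise, a 5 um border margin, and the exact trajectories returned
alongside; defaults (amplitude scale giving tens-of-um displacements over
~60 s, lambda = 40 um, 2% intensity noise) mirror the pulling-movie scales.
The deflection generator produces an exponential rise (2 s) to the
forward-model drag plateau plus proportional noise; the relaxation
generator is A exp(-t/tau)+C plus noise.  All are seeded and bit
reproducible.  What they do not emulate: out-of-focus background,
photobleaching, membrane-intensity heterogeneity, or tracking ambiguities
from cell rearrangement — so passing recovery tests demonstrates estimator
correctness, not robustness to every imaging artifact.

## Desk-scale choices and limitations

Grading-independent problem sizes were fixed once: 96-cell embryos
(~50 um cells) with a 24 um fluid grid for fluid-coupled sweeps, 150-cell
embryos for profile collapse, 24x24 lattice patches, 32-row patches for
sheet moduli.  Two desk-scale corrections are deliberate model choices:

* **Wall standoff.**  At eps ~ 14-18 um the regularized kernel cannot
  resolve the 3 um, 1 cP lubricating film; the cell layer would feel full
  1000 cP wall drag.  The desk configuration stands the layer off the shell
  by 0.75x the fluid spacing, which restores the weak near-wall drag the
  film provides (probe drag ~1 nN s/um, matching the slender-body
  estimate).
* **Overdamped gamma calibration** (above).

Known coarse-resolution limitations, measured and accepted rather than
hidden: at k = 0.001 the desk model is deeper in the drag-dominated regime
than the full-resolution model (relaxation ~160 s vs ~60 s), which inflates
the soft-k loading force and compresses the F_max span of the uniform
sweep (~7x measured) relative to full resolution; the ~50 um cells saturate
the basal-ring contribution in the compartment sweep (F_max ratio ~4x
measured, with the relaxation constant changing ~40%), because once the rim
network is effectively rigid relative to the fixed apical stiffness further
k_basal increases add no force.  All orderings (force increasing in k,
relaxation time decreasing in k, compartment stiffening raising the loading
force strongly while recoil dynamics change moderately) hold at desk scale.
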