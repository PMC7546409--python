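# Methods

`pallisteer` models the volume of tissue activated (VTA) by a directional
deep-brain-stimulation (DBS) lead implanted in the internal globus pallidus
(GPi), with heterogeneous tissue conductivities. The pipeline has five
stages: a synthetic pallidal phantom, a parametric eight-contact lead, a
quasi-static volume-conductor solve, multicompartment myelinated-axon
activation, and direct bounding of action-potential initiation (API) sites
into a VTA that is partitioned against the anatomy. This note records the
model content, the defaults, and the numerical choices.

## Synthetic pallidal phantom

The phantom stands in for a segmented whole-head anatomical model at desk
scale. It is a 48 mm cube of grey matter at 0.4 mm voxels containing:

- an outer globus pallidus envelope (ellipsoid, semi-axes 10.5 x 6.0 x
  5.0 mm) whose interior splits into GPe tissue, a 1.0 mm medial medullary
  lamina shell, and a GPi ellipsoid (7.5 x 4.0 x 3.5 mm, ~440 mm3 — human
  GPi scale);
- an internal-capsule slab (3 mm thick, posteromedial to the pallidum) and
  an optic-tract cylinder (radius 1.25 mm) running directly ventral to the
  GPi — the two classic side-effect structures;
- a 2.4 mm CSF rim and a thin outermost "case" shell that serves as the
  distant return surface of monopolar stimulation (the stand-in for the
  epidermis of a whole-head model);

Geometry is analytic (`label_points`), so any grid resolution can be
rasterized consistently. Default conductivities (S/m): grey 0.275, white
0.126, CSF 1.654, lamina/capsule/optic tract as white matter, encapsulation
0.1, case 0.1; exterior air and lead insulation are perfect insulators
(sigma = 0). These are the low-frequency tissue values in common use for
DBS volume-conductor models; every entry is overridable per model. A
homogeneous control (`homogenize`) maps every internal tissue — including
the encapsulation — to one value (0.3 S/m by default), leaving electrode
metal and insulation untouched.

What the phantom does *not* emulate: real pallidal shape (the lamina here
is a closed shell, not only the inter-segment sheet), anisotropy, gyri/CSF
convexities near the target, and inter-subject variability. Passing the
sweep-level checks therefore demonstrates the *directional* physics of
configuration and spacing choices, not patient-level percentages.

## Directional lead

The lead follows the common 1-3-3-1 segmented layout: 1.27 mm shaft, 1.5 mm
contact rows (ring 1, segmented rows 2 and 3 with three 90-degree segments
separated by 30-degree gaps, ring 4), with an edge-to-edge inter-row gap of
either 1.5 or 0.5 mm — the two lead variants differ only in that gap.
Exact commercial contact dimensions are not public; these defaults are
configurable assumptions. A 0.5 mm encapsulation shell surrounds the whole
lead body. The implant pose is 23 degrees anterior (sagittal) and
11 degrees lateral (coronal), A-segments facing anterior; segment angles
run from anterior toward lateral, so segment B faces posterolaterally.
`place_at_target` translates the lead so the row-2 contact surface sits at
requested distances (default 2.25 mm lateral, 2.3 mm posterior) from the
GPi borders at a ventral height (30th percentile of the GPi z-extent),
via a damped fixed-point iteration on ray-cast border distances; achieved
distances are reported and must match within two voxels.

## Volume-conductor solve

The potential obeys the resistive quasi-static equation
div(sigma grad phi) = 0. The solve is purely resistive: the stimulus pulse
(60 us) is long compared with tissue charge relaxation, so the permittivity
tables are carried but unused — a documented limitation. Discretization is
cell-centered finite volumes with harmonic face averaging (the standard
scheme for discontinuous coefficients); cells with sigma = 0 are excluded
(internal Neumann boundaries), active contacts are Dirichlet surfaces
(cathodes at -V0, co-activated cathodes share one potential; anodes and the
case shell at 0), inactive metal contacts are merged into floating
equipotential unknowns, and the outer box is a natural zero-flux boundary.
Faces between two distinct conductors are treated as insulated: they only
arise when voxelization swallows the 30-degree insulation gap between
segments.

Graded resolution is approximated with a two-level composite: a coarse
solve over the whole phantom (1.2 mm), then a fine region-of-interest (ROI)
solve around the contacts (0.25 mm by default, 0.3 mm in the sweep). For
monopolar configurations the ROI boundary takes Dirichlet values
interpolated from the coarse solve (the return current leaves the ROI);
for bipolar configurations the loop closes between the rows, so the ROI is
closed with the natural Neumann boundary, which makes cathode and anode
fluxes balance to solver tolerance, and the coarse far field is level-
matched to the fine solve on the ROI skin (a constant shift carries no
current and no transmembrane drive). The linear systems are solved with
Jacobi-preconditioned conjugate gradients to relative/absolute residuals of
1e-8 / 1e-10.

From the fine solution the cathode flux (sum of face currents over the
cathode boundary, tissue faces only), the electrode-tissue-interface (ETI)
impedance Z = V/I, and the equivalent delivered current are computed.
Linearity makes rescaling to a target current exact; all amplitudes of a
configuration reuse one unit solve. Solver verification rests on two
closed-form oracles: the concentric-spheres conductor (phi =
V0 (1/r - 1/R)/(1/a - 1/R), I = 4 pi sigma a V0 / (1 - a/R), the
isolated-sphere expressions as R grows) and the image-source solution for a
point source near a planar conductivity jump, plus exact charge
conservation.

The homogeneous control cell is run voltage-matched to its heterogeneous
counterpart rather than current-matched, and its equivalent current is
reported in the results row. The activation-volume difference between the
two models is dominated by the encapsulation sheath, which the homogeneous
model replaces with bulk tissue; that difference expresses itself at
matched voltage (the homogeneous model then delivers more current through
the lower interface impedance), whereas matched-current scaling would
cancel most of it. This mirrors clinical voltage-controlled intuition and
is the package's deliberate design choice.

## Axon model and activation

Model axons are straight, 20 mm long, and lie on planes perpendicular to
the lead shaft, 0.5 mm apart, spanning the contact stack plus a 2 mm
margin; within a plane, parallel axons at 0.25 mm spacing over a 10 mm
extent, replicated at six orientations (0-150 degrees in 30-degree steps —
180 degrees duplicates 0 for straight fibers). Axons whose line pierces
the lead body or its encapsulation sheath are removed (scar tissue carries
no intact fibers). Fibers parallel to the lead are deliberately absent;
this is a known source of underestimation for bipolar settings.

Each axon is a double-cable myelinated fiber in the MRG tradition: nodes of
Ranvier carrying fast Na+, persistent Na+, slow K+ and leak channels
(3.0 / 0.01 / 0.08 / 0.007 S/cm2, 36 C rate constants), passive MYSA /
FLUT / STIN internodal sections under a myelin sheath, an explicit
periaxonal pathway, and diameter-dependent geometry interpolated from the
published tables (default 5.7 um, 0.5 mm internodal length, 41 nodes;
8.7 um and interpolated calibres supported — the source material quotes
both 5.7 um and 4.7 um in different places, and this package defaults to
the Methods-section value). The leak reversal is anchored at start-up so
the node rests exactly at -80 mV.

The stimulus is a rectangular cathodic phase (default 60 us) followed by a
charge-balanced exponential passive-discharge phase (500 us time
constant); a single pulse decides activation (the conventional VTA
criterion), 130 Hz trains are available. Extracellular potentials are
trilinearly interpolated at compartment centers (fine grid inside the ROI,
coarse outside) and applied as Ve(t) = profile x waveform(t).

Integration is a theta-scheme (Crank-Nicolson, theta = 0.5) on the coupled
axoplasmic/periaxonal block-tridiagonal system with Rush-Larsen gating in
a two-pass predictor-corrector (gates re-advanced with midpoint-voltage
rates), 2.5 us steps through the pulse window (first 300 us) and 12.5 us
afterwards, 2.5 ms horizon. A spatially uniform extracellular potential is
exactly neutral in this discretization. Activation requires a propagating
spike: 0 mV crossings at three consecutive nodes including an end node;
the API site is the node with the earliest crossing (ties by lower index).
Early exits: propagation confirmed at either axon end, or no crossing with
all nodes below -50 mV beyond 1 ms after the pulse. Axons whose profile
swing (max - min) is below 40 mV are recorded inactive without
integration; measured minimum activating swings exceed 119 mV across all
sweep cells (safety factor ~3), and the population evaluator warns if an
activated axon ever comes within a factor of two of the floor.

Threshold searches bisect the amplitude multiplier geometrically to 1%.
Halving both time steps moves thresholds by under 2% (measured ~1.3% at
the default step).

## VTA construction and partition

The VTA directly bounds the API sites (no center-node remapping; the
contrasted remapping variant is out of scope). Default bounding surface is
the 3D alpha-shape of the API set with alpha = 2 x the plane spacing
(2 x 0.5 mm): Delaunay tetrahedra with circumradius below alpha are kept
and their union voxelized at 0.25 mm on a grid aligned with the phantom
(so partition counts are exact). A convex-hull mode is available; hull
volumes are systematically larger (they fill concavities between
activation lobes), and any comparison states its mode. A deterministic
1e-6 mm jitter is applied before triangulation purely to break the exact
lattice degeneracy of the API sites, which otherwise makes point location
pathologically slow. Voxels containing an API site are always inside the
mask. Sub-volumes (inside GPi / lamina / inside GPe / outside GP) are
voxel counts against the phantom labels; the outside-GP share includes the
side-effect structures, whose overlap is also reported separately. The
axial asymmetry index is the fraction of VTA volume in the half-space
toward the mean cathode-segment azimuth.

## Sweep and reported statistics

The default sweep enumerates the study grid: configurations 1, 2a, 2b, 3,
4, 5 on the 1.5 mm lead and the vertical configurations 2b, 4, 5 on the
0.5 mm lead, each at 1 and 2 mA, plus one homogeneous control for
configuration 4 — 19 cells, one unit solve per unique
(configuration, spacing, tissue mode). Rows carry volumes, the four-way
percentage breakdown (2 decimals), impedance, equivalent current, and
asymmetry; the summary derives mean %-in-GPi of the vertical
configurations per spacing/amplitude, configuration 4 -> 5 shifts, and the
homogeneous-vs-heterogeneous volume difference. Everything is
deterministic: rerunning a sweep reproduces the CSV byte-for-byte (the
seed is recorded in the manifest for provenance; no stage draws random
numbers that affect results).

Problem sizes are desk-scale choices: ~0.3 mm ROI grids (about 3 x 10^5
unknowns per solve), 4600-5800 axons per cell, a 10 mm plane extent. At
these sizes the full sweep runs in about five minutes on one CPU.
Absolute volumes and percentages at desk scale are not comparable to a
~10^8-element production mesh on real anatomy; the sweep-level checks are
therefore directional (ordering) statements, which are robust to
resolution.

## Known limitations

- Resistive solve only; no tissue anisotropy; no frequency-dependent
  permittivity.
- Straight, perpendicular axons of a single calibre per run.
- The phantom's lamina is a closed shell around the GPi, so lateral VTA
  spill exits through "lamina" voxels that in real anatomy would already
  be GPe or capsule.
- The alpha-shape VTA is conservative between weakly-connected activation
  lobes; hull mode bounds from above.
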