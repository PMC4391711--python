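# Methods

`plaquesim` asks a controlled-imaging question: how do the voxel dimensions
of a 2D carotid MRI protocol — slice thickness and in-plane acquired voxel
size — bias the quantification of plaque components (lumen area, vessel wall
area, lipid-rich necrotic core area, minimum fibrous-cap thickness) and the
peak fibrous-cap stress computed from the segmentations?  Because the
question needs an exact ground truth, everything runs on synthetic 3D plaque
geometries with known contours; the pipeline is

synthetic geometry → virtual MRI → automated segmentation → measurement →
plane-strain FEA → error statistics.

## Synthetic plaque geometries

A plaque model is three cross-sections stacked at 1 mm axial spacing
(emulating histology sections), each with a lumen contour, an outer-wall
contour and one or two LRNC contours, aligned on the luminal centroid and
interpolated axially.

**Cross-section construction.**  The lumen is a harmonically perturbed
ellipse (harmonics 2–8, amplitude ≤ the `roughness` parameter, default
0.08) scaled so its polygon area hits the sampled target exactly.  The wall
ring adds an eccentric thickness profile (plaque burden concentrated on one
side) scaled so the annulus area matches its target.  Cores are crescents in
the wall ring: an angular window with a plateau of constant cap gap and
cosine-tapered shoulders, whose inner edge sits a prescribed gap outside the
lumen — that gap *is* the minimum fibrous-cap thickness, which makes the
cap-thickness distribution directly controllable.  The crescent keeps an
outer rim of ≥ 0.4 mm of wall tissue between core and outer boundary,
representing the media/adventitia that always separates a necrotic core from
the vessel exterior (without it, the simulated wall ring becomes invisible
at the wall/background contrast and no reader — human or surrogate — could
close the outer contour).

**Population calibration.**  Component targets are drawn from truncated
normal distributions with the emulated cohort's statistics: slice-averaged
lumen area 13.4 ± 6.6 mm² (range 5.8–24.9), wall area 38.6 ± 11.5 mm²
(25.2–57.4), LRNC area 15.8 ± 9.7 mm² (6.0–34.6), minimum cap thickness
0.27 ± 0.20 mm (0.10–0.67).  Core and wall area are resampled jointly when a
core could not geometrically fit its ring (LRNC ≤ 0.55 × wall).  With 64
models, the sample means of all three slice-averaged areas fall within 15 %
of the population targets (cohort-calibration test).

**Axial structure.**  The middle section carries the sampled parameters; the
outer knots jitter them (10 % fractional area jitter, 0.25 rad angular drift
of the core, cap gap only widening away from the middle so the sampled
minimum is attained inside the slab).  A secondary core, present in half the
models, either spans all three knots or tapers to near-zero area at the
outer knots — the tapering choice for cores present in only some sections is
ours, not inherited.  Contours with matched vertex parameterisation are
interpolated per-vertex with natural cubic splines in z; every generated
model is validated on a 41-point z grid (containment, simplicity,
positive cap gap), with bounded rejection sampling (explicit infeasibility
error when a specification cannot be met).

**In-vivo state.**  The emulated study pre-inflated histology geometries to
100 mmHg before imaging.  `inflate_to_invivo` implements this as per-section
plane-strain solves (2.5D), but the experiment default declares the
generated geometry "already in vivo" and skips the step: the voxel-size
question only needs the imaged geometry and its exact ground truth, and the
calibration targets above describe the imaged state.

## Virtual MRI

The acquisition isolates voxel-size effects; scan time, motion, imperfect
blood suppression and slice cross-talk are out of scope by design.

* **Signal model.**  Steady-state spin echo, `PD·(1−exp(−TR/T1))·exp(−TE/T2)`
  with TR/TE = 800/10 ms and T1 = 680 / 1220 / 1412 ms for fibrous tissue,
  LRNC and background muscle, all with T2 = 50 ms (contrast-enhanced values).
  Blood is identically zero (perfect black-blood suppression).  A full Bloch
  simulator would add nothing here: at TR ≫ TE with ideal non-selective
  pulses the sequence reduces to this closed form, which is exactly testable.
* **Slab averaging.**  A rectangular (uniform) slice profile: the
  high-resolution signal map is the unweighted average of ≥ 9 equispaced
  z-levels across the slab, each level painted by scan-conversion of the
  interpolated contours (background muscle disc of 0.9 × fov diameter; air
  outside it provides a signal-free noise region).  Oversampling is ≥ 4×
  the acquired voxel.
* **k-space.**  The map's DFT is truncated to the acquired matrix (low-pass
  partial-volume model) and zero-padded to the reconstruction matrix before
  the inverse transform and magnitude.  Conventions: DC at the matrix
  centre, even matrices, half-open fov with samples at `−fov/2 + i·fov/n` —
  with these, zero-padded and plain reconstructions agree exactly on the
  acquired lattice.
* **Protocols.**  fov 39.68 mm; acquired 64² (0.62 mm) or 128² (0.31 mm);
  reconstructed at twice the matrix (0.31 / 0.155 mm); slice thicknesses 2,
  1 and 0.5 mm with slabs [0,2], [0.5,1.5] and [0.75,1.25] mm — six
  protocols, voxel volumes 0.77 … 0.05 mm³ (16×).
* **Noise.**  Zero-mean complex Gaussian noise in k-space (Rician magnitude
  statistics — the standard MR convention; a `magnitude` flag emulates
  Gaussian-on-magnitude post-processing instead).  The k-space sigma is
  calibrated analytically so that noiseless-fibrous-signal over image-domain
  per-component sigma equals the configured SNR of 16.7.  `measure_snr`
  estimates sigma from a signal-free (air) region with the Rayleigh
  correction `sqrt(2−π/2)`.

## Reader surrogate

The emulated study used a blinded human reader; no surrogate can reproduce a
human's absolute accuracy, so the surrogate is built to make error *trends*
across protocols measurable and reproducible.  It is deterministic:

1. light Gaussian pre-smoothing (σ = 0.75 reconstructed voxels — the
   reader's visual averaging scales with the displayed pixel size, so every
   surrogate bias vanishes as the voxel size goes to zero);
2. subvoxel iso-contours (marching squares) at midpoint thresholds between
   known class signals: lumen at blood/LRNC midpoint, outer wall at
   background/fibrous midpoint, cores at LRNC/fibrous midpoint;
3. the lumen is the dark region nearest the image centre; the outer wall the
   largest contour enclosing it (with a morphological-closing fallback when
   a superficial core interrupts the bright ring);
4. core candidates are dark blobs within the wall annulus; a core fused with
   the lumen shadow (cap thinner than resolvable) is recovered by excluding
   a one-acquired-voxel guard band around the detected lumen — this guard is
   the surrogate's main mechanism of cap-thickness overestimation and scales
   with the in-plane voxel, as a reader's partial-volume floor does;
5. cores below 2 reconstructed voxels are discarded (a reader cannot call
   sub-voxel cores); contours are smoothed with a 5-point moving average.

Measurements: polygon (shoelace) areas, wall = outer − lumen, LRNC = union
area, minimum cap thickness = shortest lumen-contour-to-core distance.
Relative errors are signed, `(measured − truth)/truth`.

## Cap mechanics

2D plane-strain, incompressible neo-Hookean (`W = C/2 (I₁ − 3)`, C read as
the shear modulus; a `c1` convention flag treats the constants as C₁ with
μ = 2C₁).  C = 167 kPa (fibrous) and 1 kPa (LRNC).  Incompressibility by
volumetric penalty κ = 1000 × max C with selective reduced integration
(deviatoric at 2×2 Gauss points, volumetric at the element centre), which
avoids volumetric locking of low-order elements; |det F − 1| stays below
0.05 at systolic load.

**Meshing.**  A structured ring of bilinear quadrilaterals between lumen and
outer contours (radial sampling by angle about the lumen centroid, ray-cast
fallback for non-star-shaped contours), with a fine inner radial zone so the
thinnest cap spans ≥ 3 elements, and per-element tissue tags by
point-in-polygon of centroids.  Quadrilaterals rather than triangles because
constant-strain triangles cannot be selectively under-integrated and lock
under the penalty.  Material interfaces are tag-resolved, not
boundary-conforming; the cap-region refinement keeps the resulting area
error within a few percent (tested).

**Per-material volumetric rule.**  The centre-point volumetric rule leaves
the quad's hourglass mode unresisted wherever μ is small; in the 1 kPa core
the incompressibility coupling excites that mode violently (tangent
indefiniteness, volume leakage, slow pressure convergence).  Soft elements
(μ < 10 kPa) therefore integrate the volumetric penalty at the full 2×2
points — volumetric locking is irrelevant in a fluid-like core and full
integration suppresses the spurious modes exactly — while stiff elements
keep the locking-free centre-point rule.  Output pressures are filtered over
the structured neighbour stencil (the Q1/centre-point pair carries a
checkerboard pressure mode, as Q1-P0 does; displacements are unaffected).

**Solver.**  The loading is conservative — the follower pressure on the
closed lumen boundary derives from the potential −p × enclosed area — so
the solver is a damped Newton method on the total potential energy:
full Newton steps with a Levenberg-style diagonal damping that increases
until a step lowers the energy (the −ln J term is a natural barrier against
element inversion).  Near the solution damping vanishes and convergence is
quadratic; residual tolerance 1e−8 relative, 10 load increments with
adaptive halving.  Rigid-body modes are removed by a three-DOF minimal
constraint on the lumen ring; because the load is self-equilibrated the
constraint reactions vanish (tested to 1e−6 of the load scale).

**Prestress.**  Imaged geometries are already pressurised; initial stresses
are recovered with the backward incremental method: pressure is raised in
≥ 10 increments on the fixed imaged mesh, after each solve the total Cauchy
stress is absorbed as the initial stress of the (reset) imaged
configuration, and final fixed-point sweeps at full pressure continue until
the residual geometry drift is < 0.5 % of the lumen radius.  The initial
stress is split: its in-plane hydrostatic part is carried as a spatial
(Cauchy) field — exact under rotation, and leaving the incremental
stiffness of a hydrostatically stressed incompressible material unchanged,
so the compressed fluid-like core cannot destabilise the tangent — while
the deviatoric part co-rotates as a 2nd Piola–Kirchhoff field.  The
hydrostatic part of each absorbed stress is checkerboard-filtered (the
penalty pressure carries discrete null-space noise that would otherwise
random-walk over the increments); deviatoric components are not filtered.
A forward inflation / backward recovery round trip on a reference annulus
reproduces the forward peak stress within ~4 % (5 % tolerance), and the
increment count is converged there (10 vs 40 increments: 0.3 %).  Sections
with a soft core retain an O(10–20 %) increment-count sensitivity from the
soft-inclusion pressure path; both study arms use the same 10 increments.

**Peak cap stress.**  Maximum principal Cauchy stress of the 3×3 tensor
(plane-strain σ₃₃ = κ(J−1) + prestress included).  The through-thickness
stress profile of the cap is a steep boundary layer maximal at the lumen or
core face; element-centroid maxima sample it at mesh-dependent depths and
converge only first-order, so the reported peak extrapolates the last two
centroids of each radial fibrous run to the face (second-order at smooth
faces).  The lumen and outer contours are exactly meshed; core interfaces
are snapped to the nearest radial node level per column and faces at the
residual one-layer steps (artificial bi-material corners) are excluded from
the peak search.  On an exactly conforming reference — a concentric
three-layer vessel whose incompressible plane-strain solution is closed
form (u = C/r) — the extrapolated peak converges to the analytic value
within 3 % at practical resolutions; on stepped interfaces of general
cores the peak carries an O(10 %) resolution dependence, shared by both
study arms.  The search region is the cap band: fibrous elements within
twice the local cap gap of both the lumen and a core.  Without any core the
whole-wall peak is reported with a fallback flag; the whole-wall peak is
always reported alongside.  The ground truth
is 2.5D: per-section plane-strain solves on nz ≥ 5 sections, maximum over
sections — the same formulation as the segmentation side, so the comparison
isolates geometry errors (a full-3D truth would mix formulation and
voxel-size effects; the experiment exposes per-section values so the two
can be probed).

## Experiment and statistics

For each model × protocol: simulate → segment → measure → cap-stress FEA on
the segmentation (125 mmHg systolic with backward-incremental prestress).
Slab-matched ground truths: slice-averaged component areas (adaptive Simpson
in z, 1e−4 relative), slab-minimum cap gap over 21 sections, and the 2.5D
peak cap stress evaluated on a 9-point z grid shared across slabs (each
slab takes the maximum of its interior samples; the grid is chosen so the
thinnest slab still contains 3 samples).  Stage failures are recorded per
cell with the reason — never dropped — and the error table always contains
models × protocols × parameters entries.  Everything is deterministic under
the master seed (per-model seeds by seed-sequence splitting, per-cell noise
seeds derived arithmetically).

Statistics: per protocol × parameter mean ± sd, quartiles and 1.5×IQR
whiskers/outliers (the box-plot convention); two-sided paired Student's
t-tests of each protocol against the 2-mm and 1-mm slices of the same
in-plane size (textbook formula, n−1 df; zero-variance differences return a
NaN sentinel).  No multiple-testing correction by default (matching the
emulated analysis); a Holm flag is available.  `trend_checks` reports the
qualitative findings: error sign pattern (lumen/LRNC under-, wall/cap
over-estimated), cap-thickness improvement with finer in-plane voxels, and
peak-stress underestimation smallest at the finest voxel.

## Numerical and scaling choices

* FE mesh pitch: library default `target_h` 0.25 mm; the factorial
  experiment uses 0.35 mm so the full 8-model study fits a desktop budget.
  Both arms (ground truth and segmentation models) share the discretisation,
  so relative errors are compared consistently; peak stresses move by ≈ 5–8 %
  between these pitches.
* Prestress geometric drift: the library default demands < 0.5 % of the
  lumen radius; on thin-cap cohort sections the underlying fixed point
  creeps (contraction ≈ 0.95 per sweep), so the experiment accepts 2.5 %
  residual drift — a ≈ 2–5 % peak-stress effect, below the mesh-definition
  uncertainty and shared by both arms.
* Quadrature, interpolation and clipping tolerances are stated at the API:
  slice-average refinement 1e−4, interpolant knot fidelity < 1e−9 mm,
  contour I/O round-trip < 1e−6 mm.
* Degenerate inputs fail loudly: cap gap < 1e−3 mm refuses to mesh; an
  infeasible cohort specification raises after a bounded number of attempts.

## What a green test run does and does not establish

The generator emulates the *statistics* of a small histology-based cohort,
not real plaques: no calcification or haemorrhage, no bifurcation or vessel
angulation, smooth harmonic contours, homogeneous tissue classes, a
single shared T2, perfect blood suppression, no motion.  The reader
surrogate is deterministic thresholding, not a trained human: its absolute
error magnitudes differ from a reader's even though its partial-volume
mechanisms scale the same way with voxel size.  Green end-to-end tests
therefore establish that the *qualitative* voxel-size findings (which
component errors point which way, and which voxel dimension helps which
measurement) are reproduced on a calibrated synthetic cohort — not the
emulated study's numeric error percentages, which depend on its eight
unreleased specimens and its human reader.
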