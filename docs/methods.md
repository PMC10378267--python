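# Methods

`cristamorph` quantifies the inner-membrane architecture of mitochondria in
electron-tomographic slabs: how much crista membrane a mitochondrion packs
(crista density), how the cristae are shaped (lamellar plates, worm-like
tubes, transitional rows of small tubes, or mixtures), and the per-crista
geometry that controls diffusion-limited chemistry (surface-to-volume ratio,
junction openings, fenestrations).  Because the tomograms such analyses are
built on are not generally shareable, the package ships a synthetic phantom
generator with analytic ground truth, and every stage is validated by
recovery experiments on those phantoms.

## The phantom model

A phantom is a tomographic slab (default 250 nm thick; the analyses in this
repository use 200 nm to keep run times short) containing one mitochondrion:
a cylindrical outer membrane with its inner boundary membrane (IBM) 15 nm
inside, and cristae of one of four morphologies:

* **lamellar** — plate compartments whose two membranes sit 20 nm apart,
  spanning the slab, optionally fenestrated (20–80 nm holes through the
  plate) or locally swollen (a span of the plate widened by a separation
  multiplier, default 3×);
* **tubular** — worm-like tubes, 50–90 nm in diameter, generated as
  smoothed random walks with per-step turning bounded at 0.25 rad so the
  tube cannot self-intersect, with hemispherical end caps;
* **transitional** — parallel rows of small tubes (30–60 nm): mostly
  slab-spanning vertical tubes that read as circular cross-sections, plus a
  fraction of short in-plane tubes that read as elongated sections;
* **mixed** — two half-regions each populated with one morphology
  (lamellar/tubular by default).  The plate count of the lamellar half is
  thinned (and the tube walk kept near the central plane) so that the two
  halves contribute comparable traced membrane *length*, since plates
  intrinsically pack about twice the membrane of tubes — that packing gap
  is exactly what the density analyses measure.

Membranes are rendered as solid shells of finite thickness (default 6 nm)
centred on the compartment midsurface: stained bilayers image with finite
width, and marching cubes needs a two-sided density feature.  Plate
placement carries a sub-voxel jitter so that analytically flat faces do not
align with the voxel lattice (aligned faces would bias voxelized widths by
half a voxel; ground truth is translation invariant, so the jitter is
free).  Voxel intensity falls off linearly over one voxel at the shell
boundary (anti-aliasing).  `corrupt` applies Gaussian blur then additive
Gaussian noise; the generator's defaults are blur σ = 2 nm and noise
σ = 0.25 × membrane contrast, chosen as a plausible post-reconstruction
signal-to-noise for stained plastic sections.

Three output channels per phantom:

1. **Volume** — the noiseless membrane-density map (MRC-writable);
2. **ContourSet** — the intersection of the membrane midsurfaces with
   tomographic slices, emulating manual tracing.  Lamellar compartments
   intersect a slice in closed rounded-rectangle outlines — the classic
   *pair of parallel lines* plus end arcs — so trace length follows the
   pair-tracing convention throughout.  Plate outlines are exact (shapely
   polygon arithmetic); worm-tube outlines come from sub-pixel contouring of
   the analytic distance field on a 2× refined grid.  By default only the
   central slice is contoured (that is where all 2-D metrics are read);
   `contour_slices="all"` produces every slice.
3. **GroundTruth** — closed forms for the slab-clipped geometry: plate
   native area `2·L·h + 2·w·h − Σ 2π(d/2)² + Σ π·d·w` (faces, end rims,
   hole disks removed, hole rims added), capsule area `π·D·L + π·D²`,
   vertical-tube area `π·D·h`, per-slice trace lengths, and
   `A_MIT = π·a·b`, `V_MIT = π·a·b·h`.  Slab caps are excluded from
   "native" areas everywhere.

What the phantoms do **not** emulate: missing-wedge anisotropy, CTF,
stain-density variation between matrix and intracristal space, membrane
curvature fluctuations, organelle crowding, or branched cristae.  Passing
the recovery tests therefore demonstrates that the measurement chain is
unbiased on known geometry at realistic noise — not that segmentation of
real tomograms is solved.

## Volume conditioning

* **Rolling slice average** (window 3, truncated at the slab faces) mirrors
  the standard pre-tracing noise reduction.
* **Anisotropic diffusion**: Perona–Malik with exponential conductance
  `g(|∇I|) = exp(−(|∇I|/κ)²)`, explicit 6-neighbour scheme in conservative
  flux form (Neumann boundaries; the global mean is conserved to float
  precision).  Step size is capped at 0.25 with a default of 1/6, the 3-D
  stability limit of the explicit scheme.  Defaults: 5 iterations,
  κ = 0.1 (in intensity units; about 10 % of the membrane contrast).
  With κ → ∞ the scheme reduces to linear heat diffusion; the test suite
  checks it against Gaussian smoothing at the matched diffusion time.
* **Membrane enhancement**: multiscale Hessian filtration with the
  eigenvalues ordered |λ1| ≤ |λ2| ≤ |λ3|.  Two structure measures are
  provided, because cristae are both plates and tubes and published
  pipelines do not state which measure was used on which structure:
  *tubular* (classic vesselness: λ2 ≈ λ3 ≪ 0, λ1 ≈ 0) and *planar*
  (sheetness: λ3 ≪ 0, |λ1|, |λ2| small, using `a2/a3` and
  `sqrt(|λ1·λ2|)/a3` as the deviation terms).  The default is planar,
  since the membrane itself is locally a sheet in every crista class.
  Scales are physical (nm; default 3, 4.5, 6 nm — bracketing the half
  thickness of a 6 nm membrane) and converted to voxels internally.
  Sensitivity constants α = β = 0.5; the structure constant c defaults to
  half the maximal Hessian norm, recomputed per scale.  Eigenvalues come
  from the closed-form (Cardano) solution for symmetric 3×3 matrices,
  which is an order of magnitude faster than batched `eigvalsh` on
  multi-million-voxel grids.  Membranes are assumed bright; `polarity="dark"`
  inverts first (stained membranes are dark in TEM).

## Segmentation and compartment recovery

Thresholding defaults to Otsu on the enhanced volume (the interactive
threshold choice of semi-automated workflows is not reproducible; a fixed
threshold remains available), followed by one pass of binary closing to seal
pinholes.  Membrane components use 26-connectivity (thin membranes fragment
under 6-connectivity); cavities use the dual 6-connectivity.

Compartments are recovered by peeling the membrane topology from the
outside in: the complement component touching the lateral image border is
the exterior; the membrane adjacent to it is the outer membrane; the cavity
inside that is the intermembrane space; the next membrane inward is the
IBM; the largest cavity inside the IBM is the matrix; every remaining
enclosed cavity is one intracristal space.  Each intracristal space is
grown by half a membrane thickness (EDT-based) so its boundary lies on the
membrane *midsurface* — the same convention as the ground truth.  The
outermost z-slices lose membrane response to filter boundary effects and
would leak every compartment into the exterior, so the analysed slab is
trimmed by 3 slices per face (`z_trim`); all density metrics are intensive,
so the thinner slab introduces no systematic change.

Meshing runs marching cubes on the signed Euclidean distance field of each
binary component, smoothed by 0.7 voxel: the zero level set places the
boundary at sub-voxel precision and the smoothing removes the EDT
staircase, which would otherwise inflate curved-surface areas by several
percent (the cost is an edge-rounding deficit of order 0.4 voxel per unit
edge length — about 1 % on a 100-voxel cube).  Components reaching the
slab faces come out open; `seal_mesh` caps each boundary loop at a slab
face with a triangle fan wound against the directed boundary (so winding
stays consistent) and *tags the cap triangles*.  Sealing adds surface that
is not membrane, so all density and S/V metrics use the native
(cap-excluded) area; this is also why sealed-model areas overstate 2-D
estimates in practice.

## Morphometry

**2-D (per central slice, from contours):** profile area `A_MIT` by the
shoelace formula on the IBM outline; aspect ratio as the long/short side of
the minimum-area rotated rectangle (an explicit, rotation-invariant reading
of "longest/shortest dimension"; a maximal-Feret variant is available);
`L_CRIS` as the summed trace length of crista contours (pair-tracing);
`L_IM = L_CRIS + L_IBM` (the outer membrane is not part of the inner
membrane); densities `L_CRIS/A_MIT`, `L_IM/A_MIT` in µm⁻¹ and folding
`L_CRIS/L_IM`.

**3-D (per crista mesh):** native and cap areas; enclosed volume by the
divergence theorem (watertight meshes only; orientation is normalised and a
flipped mesh yields |V| with a warning); `S/V` from native area.  For long
tubes of diameter D the native S/V is exactly 4/D and for plate
compartments of separation D it tends to 2/D — tubes always sit above
plates at equal D, the geometric fact behind shape-dependent transport
rates.

**Junction openings** are detected on the unsealed crista mesh against the
IBM surface: where the crista solid was clipped at the IBM, the openings
are connected clusters of mesh faces whose vertices lie within
`contact_tol` (default 10 nm) of the IBM; for meshes left open there, the
boundary loops near the IBM serve instead.  Proximity is measured against
the IBM mesh vertices with a KD-tree (marching-cubes edge lengths are about
one voxel, far below the tolerance).  Each opening is sized by its maximal
chord and called a *slot* when the chord ratio of its minimum-area
rectangle reaches 2, else *round*; round openings outside ~15–40 nm and
slots beyond ~70 nm are flagged (logged), not rejected, since those bands
are empirical.  One opening = one junction (per-opening counting).

**Fenestrations** are through-holes in a lamellar sheet: topologically each
is a handle, so the count equals the genus from the Euler characteristic
(V − E + F = 2 − 2g) of the sealed mesh.  Geometrically each hole is
localized by projecting the sheet onto its own plane (smallest principal
axis = sheet normal), rasterizing the projected triangles at 1 nm, and
taking enclosed background components; a hole's width is the diameter of
its maximal inscribed circle (twice the peak distance transform).  Hole-rim
triangles project onto a ~1 px ring, so widths carry a ≲2 nm negative bias
— well inside the 10 % recovery tolerance.

## Classification

Morphology is scored per central slice as the fraction of crista membrane
length carrying each class signature:

* **Lam**: points whose nearest roughly antiparallel, laterally displaced
  neighbour sits 20 ± 8 nm away (membrane pairs), on segments with
  elongation ≥ 2.5 and ≥ 60 % of samples paired;
* **Tub**: closed sections whose local width — the median pair distance
  across the section, robust for curved worm outlines whose bounding box is
  much wider than the tube — lies in 45–95 nm;
* **Trans**: closed sections 25–65 nm wide arranged in *parallel rows*: a
  row is a dense collinear run of ≥ 3 section centroids (lateral tolerance
  20 nm, neighbour gaps ≤ 130 nm) and only counts when a second distinct
  row runs within 12° of it — requiring the parallel-row *pattern*
  suppresses chance collinearity in dense tubular profiles;
* **Mix**: the two top-scoring classes, compared against each other (the
  0.35 floor is taken on their pairwise fractions, because oblique and
  grazing sections carry no signature and dilute raw fractions), both
  present with raw score ≥ 0.15 and living in spatially disjoint regions
  (projected means separated by more than the summed projected spreads).
  The mixture test precedes single-class dominance: a half-lamellar profile
  must not be called Lam merely because plates pack more length.

Thresholds live in `ClassifyConfig` and are logged; human classification by
eye published no numbers, so these are explicit package defaults.  The same
rules run on traced contours or on a segmented central slice, which is
skeletonized into midline polylines (membrane bars become open lines, tube
rings closed loops — the primitives a human tracer would draw); in the
image route the envelope membranes are removed exactly when compartment
recovery is available, else by a convex-hull proximity filter.

Cell location is rule-based: interfibrillar if the profile outline comes
within 50 nm of a myofibril mask, else subsarcolemmal within 50 nm of the
sarcolemma, else other; interfibrillar takes precedence when both fire.
A mitochondrion is flagged *swollen* when any membrane-pair separation
profile exceeds twice the nominal 20 nm over at least a quarter of its
length; a segment must show some nominal pairing to contribute a profile at
all, so tube sections (which pair at their diameter) do not masquerade as
swollen plates.

## Statistics

Group comparisons use the pooled-variance Student t-test, two-tailed
(Welch available); sample SDs use n − 1; no multiple-testing correction is
applied (comparisons are reported as raw p-values).  The test suite checks
the p-value against direct numerical quadrature of the t density and the
null calibration over 2,000 seeded null pairs.  Contingency tables compute
their totals on demand so they cannot drift from the cells.

## Problem sizes and numerical choices

The benchmark studies run phantoms with 260–320 nm envelope semi-axes,
200 nm slabs and 2.5 nm voxels (recovery and classification), 2 nm voxels
for fenestration/junction geometry, and 1 nm voxels for the analytic-solid
and S/V-limit fixtures; these sizes were chosen so each study completes in
minutes on one CPU while keeping every structural scale (6 nm membranes,
20 nm pairs, 20–90 nm tubes and holes) at 2.4+ voxels.  Degenerate inputs
are handled explicitly: empty foregrounds raise with a histogram summary,
non-watertight meshes are rejected by volume/genus computations with a
pointer to `seal_mesh`, boundary loops not at a slab face are left open
with a warning, and single-observation classes report an undefined SD.

## Known limitations

* The compartment-recovery route requires topologically closed membrane
  shells after thresholding; at noise well above σ ≈ 0.5 × contrast, shell
  breaks merge compartments and cristae are lost rather than mismeasured.
* Junction detection assumes the crista solid is clipped at (or open
  within `contact_tol` of) the IBM; branched cristae sharing one junction
  row are counted per opening, not per neck.
* The worm-tube ground-truth area treats the capsule chain as a smooth
  tube (Pappus); at the curvature bound this is exact to well under 1 %,
  but tighter curvatures would need numerical integration.
* 3-D connectivity of tubular cristae is not tracked; the classifier works
  from 2-D sections, as its thresholds were designed for.
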