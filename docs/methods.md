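# Methods

`tractweave` reconstructs white-matter tracts from three consumed
inputs — an integer brain parcellation, a fiber-orientation-
distribution (fODF) field, and a declarative tract protocol — and
evaluates the robustness and reliability of the resulting tractogram
maps. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic phantoms do and do not show.

## Coordinate conventions

All geometry lives in world millimetres, RAS+ (+x right, +y anterior,
+z superior); volumes are reoriented to the closest RAS+ ordering on
load because the ROI operators ("anterior part", "axial slab") need a
fixed anatomical frame. Voxel indexing is 0-based and a world point
belongs to the half-open voxel cell `[edge, edge)`. Spatial
normalization (e.g. to a group template) is consumed as a
`SpatialTransform` — identity for phantoms, an affine or displacement
field when supplied; estimating registrations is explicitly out of
scope.

## Geometric ROI construction

Each tract protocol builds seed/target/exclude/include masks from named
parcellation labels through six deterministic operators: label-union
selection, bounding-extent axis splits, axial slabs referenced to a
landmark's z-midpoint, Gaussian dilation, a fixed-volume sphere between
two structures, and a coronal plane through a landmark's anterior edge.
Notable choices:

- **Axis splits.** The cutting plane sits at `fraction` of the mask's
  bounding extent measured from the end opposite the kept side, so the
  kept part spans `1 - fraction` (anterior half: `fraction=0.5`;
  posterior two-thirds: `fraction=1/3`). Voxels exactly on the plane
  belong to the kept side. The "anterior part of the brainstem" uses
  the global bounding-box midplane, not a per-slice split.
- **Gaussian dilation.** The binary mask is smoothed with an isotropic
  Gaussian of standard deviation `sigma_mm` (the protocol values
  1.5 mm/3.0 mm are read as sigma, not FWHM; configurable) and kept
  where the smoothed value reaches 0.3 x its maximum. The threshold is
  relative because an absolute cutoff cannot dilate small structures:
  a single voxel smoothed at sigma = 1.5 mm peaks near 0.02, so no
  absolute threshold in a useful range would retain anything. Relative
  thresholding preserves the superset property and monotonicity in
  sigma, and behaves sensibly for the 3-voxel lateral geniculate
  nucleus on a 2 mm grid.
- **Capsula-externa sphere.** Radius from the protocol volume
  (24 mm³ -> r = 1.79 mm; the value is configurable in the protocol
  file since a diameter reading cannot be excluded), centred at the
  midpoint of the two structure centroids and snapped to the nearest
  white-matter voxel, ties broken by lowest linear index for
  determinism. On a 2 mm grid this include region is a single voxel.
- **Frontal-aslant seed.** The supplementary and pre-supplementary
  motor cortex are one seed label; the vertical plane through the
  anterior-most y of the corpus-callosum (genu) landmark only bounds
  the seed anteriorly.
- The optic radiation's seeding cone axis ("laterally") is the world
  ±x direction toward the ipsilateral side, configurable per protocol.

Shipped protocol parameters (per tract): streamline counts
FAT 5000, IFOF 15000, SLF III 7000, AF/CST/OR 7500; fODF amplitude
cutoffs OR 10%, IFOF/CST 7%, AF 7.5%, SLF 8%, FAT 9% of the field's
global maximum amplitude; step 0.2 mm; curvature radius 1 mm; 10,000
propagation attempts per seed voxel. The published protocol assigns a
medium or high coherence-filter setting per tract without listing
which; the shipped files default every tract to medium (1e-3),
overridable per protocol.

## Probabilistic tracking

The fODF is a real even-order spherical-harmonic (SH) expansion per
voxel, default maximum order 8 (45 coefficients — "8 spherical
harmonic coefficients" is read as order 8, the conventional CSD
setting; the order is configurable). Amplitudes are evaluated by
trilinear interpolation of coefficient vectors and clamped at zero.

The tracker is a **first-order per-step sampler** sharing the contract
surface of path-integral samplers (iFOD2): fixed 0.2 mm steps grown
unidirectionally from a uniformly drawn position inside a uniformly
drawn seed voxel, each direction drawn with probability proportional to
the fODF amplitude inside the curvature cone
`2 arcsin(step / 2 radius)` = 11.478 degrees around the previous
direction (45-degree half-angle seed cone when the protocol specifies
one). Directions below `cutoff_fraction x global max amplitude` carry
zero probability (per-voxel-max referencing is available as an
option); if no admissible direction remains the walk dies. Acceptance
requires entering a target; entering an exclusion, leaving the field,
or exceeding 250 mm (default maximum length, configurable — the
protocol is silent) rejects; include regions are checked post hoc over
the whole polyline. The attempt budget is pooled:
10,000 x (number of seed voxels).

Sampling is implemented over a fixed quasi-uniform direction table
(4096-point Fibonacci sphere) with a precomputed SH basis and
precomputed per-direction cone-neighbour lists; a categorical draw
proportional to amplitude over the table is the discrete analogue of
rejection sampling from the continuous density, and on an isotropic
field the samples pass a chi-square uniformity test over octants. The
inner walk runs in a numba-compiled kernel when numba is importable,
with an equivalent pure-numpy fallback; each attempt consumes a fixed
block of `max_steps` uniforms from the generator so outputs are
bit-reproducible for a given seed.

One caveat found during validation: the *path-level* acceptance rate is
not monotone in the amplitude cutoff. Raising the cutoff restricts
sampling to strongly on-axis directions, so the walks that do start
wander less and can reach the target *more* often. What is monotone —
and what the tests assert — is the admissible direction set itself,
which shrinks as the cutoff rises.

## Fiber-to-bundle coherence filtering

Streamlines are lifted to position-orientation space: interior point i
pairs with the normalized central difference of its neighbours;
endpoints are dropped. The local score (LFBC) of a lifted point is the
mean kernel affinity to the lifted points of all *other* streamlines;
the relative score (RFBC) of a streamline is its weakest sliding-
window-mean LFBC (window 7 points) divided by the set-wide mean LFBC.
Filtering retains streamlines with RFBC >= epsilon; the published
settings are none, medium 1e-3, high 1e-1.

The kernel is a documented **separable surrogate** for hypo-elliptic
SE(3) diffusion kernels, for which no closed form is published:
`exp(-d^2 / 2 sigma_s^2) * exp(kappa ((t.u)^2 - 1))` with spatial
bandwidth sigma_s = 2 mm and orientation concentration kappa = 10 by
default. It preserves the defining structure — density in positions
*and* orientations, antipodally symmetric — and is pluggable behind one
interface. Normalizing RFBC by the set mean makes the thresholds
scale-free, since absolute densities depend on streamline count and
bandwidth; whether 1e-3/1e-1 are numerically comparable under the
original kernels is unknowable from the published description, so the
thresholds remain protocol-level parameters. Scoring is exact
(chunked all-pairs); the test oracle is a literal double loop.
Streamlines shorter than three points cannot be lifted and score 0.
Tracker output already has uniform 1-point-per-step spacing, which the
scoring assumes.

## Density, probability, and overlap maps

A tract density image counts distinct streamlines per voxel (each
streamline at most once, loops included); segments are supersampled at
a quarter of the smallest voxel edge, and a refinement test checks that
halving the spacing leaves the binarized map unchanged (an exact
integer line-walk is available behind the same interface). Binarization
applies K >= 1 (configurable `k_min`). Group probability maps average
nearest-neighbour-resampled binarized maps, so values are exact
multiples of 1/n; confidence thresholding at 5%/50%/90% produces nested
masks.

Dice overlap is `2 N(A and B) / (N(A) + N(B))` on voxel counts; two
empty masks score 1 with a degenerate flag so batch phantom runs do not
crash. Hold-out cross-validation splits n subjects into a small group
of `floor(ratio x n)` (at least 1) and its complement — floor
reproduces the published 13/123 split at n = 136, whose stated 13/129
is internally inconsistent with n = 136 — builds both groups'
probability maps, thresholds at the minimal confidence, and records
Dice per iteration (default ratio 0.10, 300 iterations, 5%
confidence). Repeated processing reports all C(R,2) pairwise Dice
values (45 for R = 10); test-retest warps session 2 through a consumed
coregistration before comparison. Box-whisker summaries use Tukey
1.5 IQR whiskers. The significance tests marked in the published
filtering comparison are unspecified there and are deliberately
omitted.

## Synthetic phantoms

The default parcellation phantom is a schematic two-hemisphere "brain"
of axis-aligned boxes on a 2 mm grid (60 x 72 x 54 voxels), containing
every structure the six protocols name, with voxel centres
mirror-symmetric about x = 0 so left/right structures are exact
reflections. One analytic bundle centerline per tract and hemisphere
connects seed to target along a low-curvature path avoiding that
tract's exclusions (the optic radiation hooks laterally before turning
posterior; the arcuate arches over the Sylvian region). The fODF field
places antipodal orientation lobes (`exp(kappa ((d.t)^2 - 1))`,
kappa = 12, projected to SH by least squares on a 400-direction
quadrature) along the tangents of centerlines within a 3 mm tube,
over an isotropic background of amplitude 0.03 — below every
protocol's cutoff, so walks that stray off a bundle die rather than
wander. Crossing bundles superpose naturally into multi-lobed voxels.

Cohorts apply small per-subject rigid+scale affines (defaults: 2 mm
translation SD, 2 degree rotation SD, 5% scale SD) about the volume
centre; the subject fODF is regenerated from the affinely transformed
centerlines — exact, avoiding SH reorientation — and the returned
subject-to-base transform is the closed-form inverse. Spurious
streamlines for filtering studies come in two severities, both placed
at random azimuths around the bundle so they vary between
realizations like real tracking noise: *grossly spurious* lines
oriented orthogonally to the bundle's mean direction at 5 sigma_s
transverse offset (coherence negligible by construction — any filter
setting removes them) and *mildly deviating* lines at 1.5 sigma_s
offset, 30 degrees oblique (RFBC of order 4e-3 under the default
kernel: kept by the medium setting, removed by the high one, the
borderline class the published filter-strength comparison
distinguishes). Both stay inside the field of view so they contaminate
density maps until filtered, and every generated streamline carries a
coherent/spurious ground-truth label.

**What the phantoms do not show.** Anatomy is boxes and tubes: no
gyral folding, no partial-volume effects, no realistic crossing
statistics, no scanner noise or distortion, and the "registration" is
an exactly known affine. Passing tests therefore validate the
computation — geometry operators, sampling contracts, scores, overlap
statistics — not anatomical accuracy on real data, and the absolute
Dice levels measured on phantoms are not comparable to values obtained
on patient or volunteer cohorts.

## Experiment design at desk scale

The four evaluation experiments run on phantom data sized for a
single-CPU desktop run, a deliberate scaling of the published cohort
design (136 subjects, thousands of streamlines per tract): repeated
processing uses 10 runs of 50 streamlines on the straight-bundle
phantom with 10% grossly spurious plus 10% mildly deviating
streamlines injected per run (emulating the severity spectrum of
tracking noise on real data — at this scale clean-phantom tracking
produces none, and filtering would have nothing to do); hold-out
validation uses a 20-subject jittered
cohort, 25 streamlines per subject, at the published ratio/iteration/
confidence settings. In the cohort experiments one fixed tracker seed
is shared across subjects so the measured variability is purely
anatomical; with zero jitter all subjects are bit-identical and every
hold-out split scores Dice 1 exactly. The streamline counts in the
shipped protocol files are the published ones; desk-scale runs override
them through `n_streamlines`.

## Known limitations

- The per-step sampler is not iFOD2; integrator differences mean
  per-streamline trajectories are not comparable to MRtrix output,
  though the evaluation framework is agnostic to the integrator.
- The surrogate coherence kernel preserves structure, not the exact
  SE(3) kernel values; RFBC thresholds may need retuning per kernel.
- Direction sampling is discrete over 4096 table directions (~2 degree
  resolution), below the 11.5-degree curvature cone but a quantization
  nonetheless.
- Dense displacement-field transforms have no closed-form inverse here;
  grid resampling requires the field estimated in the needed direction.
- Hold-out Dice multisets are only statistically, not exactly,
  invariant under subject relabeling: the random splits are drawn over
  subject indices.
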