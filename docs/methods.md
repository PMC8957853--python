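# Methods

## Synthetic cohort model

Each subject carries the four structures of interest — the three MGB
subdivisions (MGBv, MGBd, MGBm) and the LGB — as axis-aligned ellipsoids in
a common fresh-tissue reference frame, mirrored about the midsagittal plane
x = 0. The default geometry places the nuclei at their anatomical
coordinates (MGB medially near |x| = 15 mm, LGB laterally near |x| = 24 mm,
both at y ≈ −22…−30, z ≈ −4…−11 mm) with per-hemisphere volumes of
~26 / 60 / 47 mm³ for the MGB subdivisions and ~166 mm³ for the LGB — the
scale of shrinkage-corrected measurements in adult postmortem cohorts. The
ellipsoid shape is deliberate: its closed-form volume (4/3)πabc is the
oracle every estimator is validated against; realistic nucleus shapes would
add nothing to estimator validation.

Per subject the generator draws, from an independent child stream of the
master seed (so cohort prefixes are reproducible):

| quantity | distribution | default | why |
|---|---|---|---|
| volume scale s | lognormal, mean 1 | CV = 0.25 | yields the ~two-fold max/min volume ratio across 10 subjects seen in real cohorts; positive support |
| structure position jitter | N(0, σ²) per axis | σ = 0.3 mm | biological location variability; keeps the default geometry collision-free |
| shrinkage factor f | N(1.93, 0.06²), clipped ≥ 1 | — | histological volume shrinkage ≈ factor 2; per-brain values for typical cohorts are not published, so this is a model choice |
| brain volume | N(1.25·10⁶, (1.4·10⁵)²) mm³ | — | fresh adult brain scale, from fresh-weight ≈ volume |
| registration jitter | rotation σ 2°, scale σ 0.02, translation σ 1 mm | — | plausible affine registration spread |

The subject-to-reference transform composes the exact inverse-shrinkage
scaling f^(1/3) with the rigid+scale jitter; it is *known* (returned with
the metadata), replacing the nonlinear registration a real pipeline would
estimate. Biological variability (s, position jitter) is deliberately *not*
in the transform — it is what makes probability maps grade from 100% at the
core to 10% at the fringe. Rasterisation maps voxel centres through the
transform and tests the ellipsoid inequality in the fresh frame, so
rotation and anisotropic grids are handled without resampling. The grid
bounding box covers the fresh-frame geometry under the full shrinkage
contraction range plus 3–4 σ of every jitter; structures that leave it (or
overlap after jitter) raise errors naming the culprit.

Ground truth records the realised semi-axes and two analytic volumes per
structure × hemisphere: the raw in-tissue volume and the
shrinkage-corrected volume (raw × f) — the latter is what a perfect
Cavalieri-plus-correction pipeline recovers. Sex and hemisphere have no
true effect by default (null generator); multiplicative effect knobs exist
for power studies. `sample_volume_table` draws the same model without
rasterisation, which makes thousand-cohort statistical calibrations cheap.

**What the generator does not emulate:** real nucleus shapes and internal
lamination, section distortion/tears, staining variability, and nonlinear
registration error. Passing tests therefore demonstrate correctness of the
estimators under known affine geometry, not robustness to histological
artefacts.

## Sectioning and Cavalieri estimation

Sections are infinitesimally thin planes at multiples of the thickness T
along the slicing (anterior–posterior) axis; every k-th plane is sampled,
starting at a per-subject random offset in [0, k) — delineation-on-section
practice, and it keeps the estimator textbook-exact. Masks are extracted by
nearest-neighbour lookup; profile area is pixel count × pixel area. Empty
sampled planes are retained with zero area. With T equal to the grid pitch,
averaging the estimate over all k offsets reproduces the voxel-count
volume exactly (systematic-sampling unbiasedness; a unit test asserts it to
machine precision).

The real microtome design is T = 20 μm with every 15th section delineated
(d = 0.3 mm). Rasterising subject volumes at 20 μm axial pitch is
needlessly heavy for estimator validation, so the pipeline uses a 0.1 mm
elementary section (one synthetic section stands for five microtome
sections) sampled every 3rd — the same d = 0.3 mm lattice. In-plane
delineation resolution is a free parameter of real pipelines (vector traces
on 1 μm scans); the default raster is 0.25 mm, at which the corrected
Cavalieri estimates recover the analytic volumes with < 1% mean relative
error on the default cohort.

## Volumetry conventions

Shrinkage correction is one multiplicative volumetric factor per brain;
factors < 1 are rejected (they would deflate). Normalised volumes are
reported as raw fractions of brain volume; a `rescaled` mode multiplies by
the cohort-mean brain volume for readability (which convention published
statistics used is typically unstated — the default is the plain
proportion, and the permutation p-values are identical under any common
rescaling). Hemispheres are split at the world x = 0 plane.

## Permutation inference

The observed contrast is a difference of group means; the null is built by
random relabeling with group sizes preserved, vectorised in chunks of 10⁵.
The p-value uses the add-one estimator (1 + exceedances)/(1 + n_iter) —
standard Monte-Carlo practice that cannot return zero — and ties count as
exceedances (conservative). Sidedness: `two` (default, on |C|), `greater`
(the literal "observed contrast larger than 95% of the null" rule),
`less`, and `observed`. The production default of 10⁶ iterations is
configurable; the pipeline default config uses 10⁴, which resolves p at the
0.05 criterion to ±0.4% (3 Monte-Carlo SEs at p = 0.05) — adequate for the
synthetic studies here.

A statistical caveat documented on purpose: grouping the 2n per-hemisphere
values of n subjects and permuting them as if independent ignores the
within-subject correlation induced by the shared size factor. For the
hemisphere contrast this is conservative (subject effects cancel in the
observed contrast but inflate the null); for the sex contrast it is
anticonservative (each subject is counted twice). Both analysis units are
therefore exposed (`sex_unit: hemisphere | subject_sum`), a paired
sign-flip permutation is provided for within-subject contrasts, and the
type-I calibration study asserts the nominal 5% rate for the
independent-unit (per-subject) analysis, where exchangeability holds by
construction. The interaction contrast permutes sex labels across subjects
with hemisphere pairs kept intact, which is exchangeable under its null.

## Reconstruction and probability maps

Sparse stacks are rebuilt to a full volume (one plane per elementary
section) either by `block` fill — each sampled mask occupies the d-thick
slab it represents — or by `shape_based` interpolation: linear blending of
signed distance transforms of consecutive masks, thresholded at zero. Where
the structure ends (a nonempty section next to an empty one), the blend
would extinguish the structure immediately against the empty section's
unbounded distance, so those gaps fall back to block fill. Measured on
phantoms: both modes stay well under 1% volume error at d = 0.3 mm on a
3 mm-radius sphere; block is slightly *better* on centred convex bodies
(its alternating errors cancel, while linear SDF blending under-fills
concave radius profiles), whereas shape-based clearly wins in boundary
fidelity when cross-sections drift between sections (Dice 0.987 vs 0.968
on a tilted-cylinder phantom at k = 6). The pipeline default is
shape-based, chosen for boundary fidelity on oblique structures.

Transport into the reference grid is nearest-neighbour pull-back through
the inverse subject-to-reference affine — label identity is never blended.
The reference grid defaults to 1 mm isotropic (the resolution probabilistic
atlases are published at), covering the metathalamus region. Overlap maps
store exact per-voxel subject counts internally; integer percents
(round(100·count/n)) are derived only on access/export, so no rounding
accumulates. Centre of mass is the overlap-weighted mean world coordinate,
rounded to integer mm (a binarised variant weights every covered voxel
equally). Per-structure maps are independent; no cross-structure
arbitration of disputed voxels is attempted.

## Meshing

Marching cubes with the topology-consistent Lewiner case tables on the
binarised structure, padded by one background voxel — the extracted surface
is therefore closed and consistently oriented, which `mesh_volume`
(divergence-theorem sum of signed tetrahedra) requires and verifies.
"Smoothing along the normal direction" is implemented as: per iteration,
displace each vertex by step × the normal component of its
uniform-Laplacian vector (mean of neighbours minus vertex), along the
area-weighted vertex normal. Tangential drift is zero by construction, flat
regions are stationary, and a sphere shrinks radially by < 2% at the
default (10 iterations, step 0.1); volume drift on genus-0 phantoms stays
under 3%. The smoothing magnitude is a discrete mean-curvature estimate
normalised by the local neighbourhood scale; the exact operator used in
published atlas work is not specified anywhere we could follow, so this is
an explicit interpretation with parameters in the config. Shrinkage-
corrected mesh volumes multiply the enclosed volume by f (equivalent to
scaling the grid by f^(1/3) before extraction).

## Pipeline, determinism, problem sizes

One YAML config drives simulate → section → volumetry → stats → probability
maps → meshes. Every random stage consumes an explicit seed; reruns are
bit-identical and the manifest hashes every output. Stages are skipped on
rerun when their config section is unchanged and their outputs exist.
Default problem sizes — 10 subjects, 0.5 mm label grids, (0.25, 0.1, 0.25)
mm sectioning raster, 10⁴ permutation iterations, 0.25 mm meshing grid —
run the whole pipeline in well under a minute on one core and were chosen
as the smallest sizes at which discretisation error is negligible relative
to the 2% recovery criterion. The statistical calibration study uses 1000
analytic cohorts at 10⁴ iterations each.

## Known limitations

* Affine-only spatial model: no nonlinear registration, so probability-map
  spread reflects biological jitter only.
* The shrinkage factor is treated as known per brain; estimating it is a
  separate (upstream) problem, and no Gundersen-style coefficient-of-error
  estimate for the Cavalieri volumes is provided.
* Shape-based interpolation assumes one structure per mask and degrades to
  block fill at structure ends; branching topology between sections is not
  handled specially.
* Integer-mm centre-of-mass reporting quantises sub-millimetre effects.
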