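# Methods

## Pipeline model

The package operationalizes connectivity-based parcellation of the
entorhinal cortex (EC) into MEC/LEC homologues. Its input is, per
participant and seed region, a voxel-wise connectivity probability volume:
for each EC voxel, the fraction of probabilistic-tractography streamlines
seeded there that reached the seed region (presubiculum, dCA1pSub, RSC or
OFC). All analysis happens in a common world space (RAS millimetres,
voxel-center convention, 0-based indices); the anatomical axes live in an
`AxisFrame` because the posterior–anterior (PA) reference — the long axis of
the hippocampus — need not coincide with a template coordinate axis. By
default PA = +y, the medial–lateral (ML) axis is ±x per hemisphere
(pointing medial→lateral), and the interhemispheric midline is the plane
x = 0, with on-plane voxel centers assigned to the left hemisphere (a
deterministic measure-zero tie rule).

Participant level: each connectivity map is **normalized** by the maximum
probability of each hemisphere separately (so both hemispheres top out at
1; an all-zero hemisphere with nonempty EC support is treated as a failed
input, not silently passed through), **thresholded** at 0.01 with
inclusive-keep semantics (a value exactly 0.01 survives, matching common
neuroimaging tool behavior; the boundary case is measure-zero for float
data), and **hard-segmented**: a voxel is MEC where the MEC evidence
(presubiculum or RSC map, or their average in the combined approach)
strictly exceeds the LEC evidence (dCA1pSub/OFC) and is positive, LEC for
the converse, background where both are zero. A voxel suprathreshold in
exactly one map is labeled by that map.

Group level: the *normalized, pre-threshold* individual maps are averaged,
smoothed with a Gaussian kernel of 1 mm, thresholded at 0.01 and
hard-segmented. Averaging pre-threshold maps avoids double-thresholding;
the alternative order is runnable through the same functions and the choice
is recorded in each run's provenance JSON. Inter-participant variability
maps count, per voxel, how many participants assigned each label.

Quantification: per hemisphere, the centers of gravity (CoG) of the MEC and
LEC voxel sets are unweighted means of voxel-center world coordinates (hard
labels carry no weights; world rather than voxel coordinates, recorded in
output metadata). The border orientation is the acute angle between the
MEC→LEC CoG vector and the PA or per-hemisphere ML axis, computed through
|v·axis| so the labeling-dependent sign of the vector cannot matter, and
converted to a percentage by the linear map %= (1 − θ/90°)·100. Linearity
is adopted because it reproduces every internally consistent published
angle/percentage pair to one decimal (45.1°→49.9 %, 29.8°→66.9 %,
84.5°→6.1 %, …); two published cells (18.7 vs. recomputed 18.8 and 2.4 vs.
2.3) differ in the last decimal because the printed angles are themselves
rounded, and are excluded from exact checks. Hemispheres are summarized as
mean ± mean absolute deviation; for two values the MAD about the mean is
exactly |a − b|/2. Sizes are voxel counts over both hemispheres and the
size ratio is MEC/LEC (undefined, and reported as such, when LEC is empty).

## Synthetic cohort generator

The generator emulates the *structure* of the tractography outputs, not
tractography itself. Each hemisphere's EC mask is an elliptical disk in the
PA–ML plane extruded along the superior–inferior axis, mirror-symmetric
about the midline. Connectivity is an opposed pair of linear ramps over the
mask: maps for the MEC-defining seeds increase toward posterior(-medial),
maps for the LEC-defining seeds toward anterior(-lateral), along a direction
at angle `theta_true` from the PA axis in the PA–ML plane (0° = pure PA
gradient). The ramp spans `p_max/contrast` to `p_max` over the mask. Count
noise replaces each probability p with Binomial(n, p)/n at n = 250,000
samples per voxel, mirroring the streamline count of the emulated
tractography protocol; per-participant direction jitter is a normal rotation
(SD `subject_jitter_deg`) in the PA–ML plane. An optional per-seed-pair
angular offset lets the cortical seeds (RSC/OFC) carry a more PA-oriented
gradient than the hippocampal seeds, qualitatively reproducing the reported
seed-pair differences; it defaults to 0 and no quantitative claim is made.
One RNG stream per participant is spawned as
`SeedSequence(master_seed, spawn_key=(participant_index,))`, so cohorts are
bit-reproducible and stable under reordering.

Defaults: 35 participants (the emulated study size; the CLI's desk-scale
`run --simulate` uses 10 on a 48×64×48 grid at 1 mm for speed), EC extents
14×14×10 mm centered 15 mm lateral of the midline, `theta_true` 45° (a
border oriented toward both axes, the qualitative combined-approach
outcome), contrast 3, `p_max` 0.5, jitter 5°.

**Why the default EC cross-section is circular.** The border estimator is
the CoG-difference vector of the two halves of the mask. For a centrally
symmetric body cut through its centroid, that vector is parallel to the cut
normal only when the body is rotationally symmetric within the cut plane;
for an anisotropic cross-section it is biased toward the long axis (a
closed-form half-rectangle centroid shows an 8×20 mm slab at θ = 30° yields
a recovered angle near 4°). Ground-truth recovery is therefore only an
identity for a circular PA–ML cross-section, which the defaults use. The
extents remain configurable — including anisotropic ellipses and a
volume-preserving ML-shear "curvature" (default 0) that makes the mask more
EC-like — but with documented estimator bias. This is also a caveat for
real data: the CoG-vector orientation metric conflates gradient direction
with ROI shape anisotropy.

What the generator does *not* emulate: streamline propagation, path-length
and distance effects, exclusion masks, spatially correlated tractography
noise, registration error, or ROI segmentation error. Passing recovery
tests therefore validates the pipeline's arithmetic and geometry, not the
fidelity of probabilistic tractography.

## Numerical choices

- **Smoothing kernel**: "1 mm Gaussian" is interpreted as σ = 1 mm
  (`fwhm=True` selects the FWHM reading); the kernel is specified in mm and
  converted per axis via the voxel size. Boundaries are zero-padded; total
  mass is conserved to 1e−6 relative as long as the signal stays off the
  grid edge, which holds for EC-sized masks on the default grids and is
  tested. At the group level the smoothing halo that spills beyond the EC
  mask is clipped back to the mask before thresholding, so labels stay
  inside the EC.
- **Ties in hard segmentation**: equal positive evidence maps to background
  (conservative and symmetric; a `tie_rule="first"` flag reproduces
  first-map-wins tooling). Ties are detected with a relative tolerance of
  1e−9: analytically equal evidence (opposed ramps meeting on a lattice
  plane, e.g. at θ = 45° on an axis-aligned grid) is otherwise broken
  inconsistently by float rounding, handing an entire tie plane to one
  label and biasing the recovered angle by several degrees on small grids.
  `tie_rtol=0` restores exact comparison.
- **Analysis resolution**: validation of ground-truth recovery runs at
  0.5 mm isotropic (96×128×96), the resolution of the emulated study's
  reported label maps. At 1 mm, CoG discretization alone contributes up to
  ~6 percentage points of orientation error at oblique angles — the error
  is quantized and identical across noise seeds, identifying discretization
  rather than noise as the cause — so the desk-scale 1 mm grid is suitable
  for smoke runs, not for orientation benchmarking.
- **Normalization support**: the per-hemisphere maximum is taken over the
  EC-mask support when a mask is attached, else over nonzero voxels.

## Limitations

- The 0.01 threshold is adopted, not re-derived; its empirical origin
  involved artifacts (air voxels from EPI distortion) that the synthetic
  data does not contain.
- The binomial count model understates real tractography noise, which is
  spatially correlated and path-length dependent.
- Orientation percentages for the PA and ML axes need not sum to 100: the
  CoG vector generally has a superior–inferior component.
- Single-hemisphere analyses are supported but omit the two-hemisphere
  mean ± MAD summary.
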