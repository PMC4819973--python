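# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the usnav toolkit. Units are millimetres and milliseconds
throughout; all coordinate frames are right-handed.

## Rigid transforms and pose streams

A `RigidTransform` is a rotation–translation pair mapping points from a
named source frame into a named destination frame (`p' = R p + t`).
Frame labels are *checked*: composing transforms whose labels do not
chain raises an error rather than a warning, because a silently mixed-up
calibration chain (image → sensor → tracker → reference) is the single
most damaging class of bug in a navigation system. Empty labels act as
wildcards for ad-hoc computation.

Rotations are validated at construction (orthonormality within 1e-6,
det = +1) and re-projected onto SO(3) by polar decomposition whenever
numerical drift exceeds 1e-12, and proactively after composition chains
longer than 10 — float drift in long chains is bounded but not zero, and
the polar projection is the nearest rotation in Frobenius norm.

Pose streams interpolate translation linearly and rotation by
shortest-arc quaternion slerp (negating one quaternion when the dot
product is negative, lerp-with-renormalization below 1e-12 of parallel).
Tracker protocols rarely document an interpolation convention;
shortest-arc slerp is the standard choice and is exact at sample
timestamps. Interpolation outside the recorded time range raises an
error — extrapolated poses are never fabricated, and frames without
bracketing tracker data are dropped (with a logged count) rather than
guessed.

## Landmark and fast registration

Paired-point least squares uses the SVD (Kabsch/Arun) closed form on the
cross-covariance of centred point sets. The determinant sign guard
replaces the smallest singular direction when a reflection would
otherwise minimize the cost, so the result is always a proper rotation.
Degenerate inputs are rejected explicitly: fewer than three common
landmark names, or a moving set whose centred rank is below 2
(collinear points leave a rotation degree of freedom undetermined).

The fast method builds the minimal-angle rotation carrying the moving
reference axis onto the tool axis (Rodrigues form) and pins the single
landmark exactly. Anti-parallel axes admit infinitely many 180°
rotations; the implementation deterministically rotates about the
coordinate axis with the smallest component along the reference axis,
orthogonalized. The method is documented as a rough initializer, not an
accurate registration.

## Centerline ICP

Correspondences are orthogonal projections of moving points onto the
*segments* of the fixed polyline (closest point on the continuous path),
not onto its vertices — residuals are then independent of how densely
the fixed path happens to be sampled. Each iteration alternates
correspondence assignment with the closed-form rigid fit. Defaults:
`max_iter = 100`, rms-change tolerance `1e-6` mm, trimming disabled.

The recorded residual (rms point-to-polyline distance) is non-increasing
by construction: re-assignment can only shorten distances and the rigid
fit minimizes distance to the assigned points, and the loop terminates
keeping the previous estimate in the rare event (possible with trimming,
when the kept subset changes) that a step would increase it.

Worst-fraction trimming (drop the `trim_fraction` most distant
correspondences each iteration, keeping at least 3) makes the method
robust to partial overlap — e.g. an extracted centerline that covers only
the imaged window of a longer nominal wire.

The trajectory-to-airway variant registers tracked tip *positions* with
the same machinery but gates each candidate correspondence on the angle
between the tip's pointing axis (local +z of the tool by convention) and
the running direction of the matched centerline segment (mean of endpoint
tangents). The gate uses the signed direction — a scope cannot travel
against the flow of the branch it occupies — which is what
disambiguates geometrically similar branches; default `max_angle_deg =
60`. Tangents are computed by normalized central differences when the
centerline does not carry them. The position/orientation trade-off of
the original formulation is not published in detail; a hard angular gate
is this package's interpretation, chosen over a weighted cost because it
is parameter-light and its failure mode (no correspondences) is loud.

## Freehand 3D reconstruction (PNN)

The pixel-to-reference chain is
`p_ref = T_pose · T_cal · S(pixel)` with `S` the pixel-to-mm scaling in
the image plane (x lateral, y depth, z = x×y the plane normal). Sector
clipping removes pixels outside the lateral/angular width and depth
range before they enter the chain.

Compounding is pixel-nearest-neighbour with *averaging*: every unmasked
pixel is binned to its nearest voxel, and voxels accumulate the mean of
their contributions. Averaging (rather than last-write-wins) makes the
result invariant to frame order, which in turn makes reconstructions
reproducible across storage orders and parallelization strategies. The
volume's axes are aligned with the reference frame; the bounding box is
the tight bounds of the mapped pixels padded by one voxel; the origin is
the center of voxel (0,0,0). Default output spacing is the maximum
in-plane pixel spacing, which avoids systematic in-plane aliasing holes.

Holes — voxels without data but with at least one filled neighbour
within `hole_fill_radius` voxels (spherical neighbourhood, default 1) —
are filled with the mean of those neighbours in a single pass. The
`fill_mask` records pre-fill coverage. No sound-speed correction is
applied during reconstruction; a sound-speed scale factor exists only in
the simulator as an error source.

## NSA evaluation

The pipeline is: segment → thin → refine → register.

**Segmentation** keeps voxels at or above `threshold_fraction` (default
0.5) of the maximum intensity over the covered region, then retains the
largest 26-connected component. Hole-filled voxels qualify: a sweep
whose frame pitch beats against the voxel pitch routinely misses single
voxel planes, and excluding the (data-supported) hole-filled values
slits the wire tube along those planes, which measurably biases the
subsequent thinning. There is no published segmentation rule for this
procedure; a fractional-maximum threshold is robust to overall gain and
is the simplest rule that works in a water tank, where contrast is high.

**Centerline extraction** applies 3D topological thinning
(`skimage.morphology.skeletonize`) and converts the 26-connected
skeleton graph into ordered polylines, splitting paths at branch points
(degree > 2 voxels).

**Subvoxel refinement.** A binary skeleton lives on the voxel lattice
and can sit up to half a voxel off the true intensity ridge — and the
offset is *systematic* for a given geometry, not noise (measured on
simulated sweeps: a constant 0.07–0.1 mm at 0.2 mm spacing, up to
0.3–0.4 mm for axis-aligned wires whose true position falls between
voxel columns). Each skeleton point is therefore iterated (3 times) to
the intensity-weighted centroid of above-background voxels
(weights `I − 0.25·max`) within 0.5 mm. For a tube with a symmetric
intensity profile this converges onto the ridge at subvoxel precision;
it reduces the null-experiment error to ~0.02 mm. Radius 0.5 mm spans
the rendered wire half-width at the tested spacings; set
`refine_radius_mm = 0` to evaluate the raw skeleton.

**Registration and readout.** The refined points are registered to the
nominal wire model by ICP with 10% trimming — the "modified" element of
the published procedure is not specified; trimming is this package's
interpretation, and it also absorbs cross-region and window-edge
artifacts. The fixed side is the pair of exact nominal wire segments
(point-to-segment correspondence makes sampling below the nominal 0.1 mm
step unnecessary; the sampled representation is still used to build the
segments). The NSA is the magnitude of the displacement the registration
imposes **at the nominal cross point**, not the ICP translation
component alone, so that rotational misalignment is evaluated where the
accuracy matters. The displacement decomposes exactly in the scan-plane
basis: elevation (plane normal), azimuth (lateral), radial (depth).

**Error budget.** Independent error magnitudes combine as
`E = √Σeᵢ²`; reported values are rounded half-away-from-zero to one
decimal, matching how such budgets are conventionally tabulated.
`E` always lies between the largest component and the plain sum.

## The phantom simulator

The simulator emulates: a two-wire cross (default 40 mm arms, 90°
crossing, 1 mm wire diameter, 40 mm deep in the tank), a linear-array
probe (96×96 pixels at 0.2 mm/px from 30 mm depth — sized so phantom
volumes at 0.2 mm spacing stay near 100³ voxels), and linear sweep
trajectories in the four standard session conditions (probe motion along
vs. diagonal to the cross, front-to-back vs. back-to-front; 80 frames
over ±8 mm of travel, 20 Hz). Wires render with a Gaussian radial
profile (σ = wire radius in-plane; out-of-plane σ from a 1 mm
elevation beam FWHM), over a water background of 5 with additive
Gaussian noise (SD 2) on a 0–255 scale.

Injectable error sources:

- **calibration offset** — the probe model handed to the consumer
  carries `true_calibration ∘ offset` while frames are rendered with the
  true calibration: exactly the discrepancy a miscalibrated probe
  produces, and the dominant error source in practice;
- **tracking jitter** — independent white perturbations per pose sample
  (mm / degrees), matching the character of optical tracking noise
  (a random walk would model electromagnetic drift instead);
- **sound-speed scale** — echoes render at `scale ×` their true depth;
- **latency** — the reported pose stream's timestamps lag the motion.

All randomness flows through one `numpy` generator seeded per sweep, so
identical seeds reproduce every array bit-exactly.

What the simulator does *not* emulate — and what passing tests therefore
do not show about real hardware: speckle statistics, shadowing,
reverberation and refraction; tracking occlusion/dropout beyond MISSING
rows in pose files; probe calibration estimation itself (calibrations
are inputs); phantom manufacturing tolerances; and scanner/tracker frame
rates or latencies, which are hardware measurements outside the scope of
a synthetic harness. Simulated accuracy numbers characterize the
*geometric pipeline*, not any physical system.

## Problem sizes and tolerances in the shipped studies

The packaged acceptance studies use 12-acquisition sessions (3 repeats ×
4 conditions) and 20-run suites at 0.2 mm voxel spacing (volumes around
100³ voxels), with the null-experiment criterion set at one voxel
diagonal (0.346 mm) and calibration-offset recovery judged by mean
absolute error ≤ 0.3 mm over offsets drawn uniformly from 0.5–2.0 mm.
These sizes keep a full session under a minute on a single core while
leaving each stage's error contribution clearly resolvable above the
~0.02 mm pipeline floor.

## Known limitations

- Only rigid registration; no deformable correction, so tissue-shift
  error enters budgets as a component rather than being corrected.
- PNN with averaging blurs under strong frame overlap; no
  forward/backward compounding alternatives are provided.
- Volumes are axis-aligned in the reference frame (no oblique output
  grids).
- The thinning-based centerline extractor assumes tubular segmentations;
  sheet-like segmentations produce medial surfaces that the path walker
  will fragment.
- The external image-to-image registration hook is a documented
  subprocess contract (transform file in, 4×4 matrix out); no external
  tool is bundled or wrapped.
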