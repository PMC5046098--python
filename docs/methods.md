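# Methods

This note records the models, parameter choices, and numerical decisions
behind `vqmselect`, and what the synthetic validation does and does not show.

## Problem setting and assumptions

The package operates downstream of vessel segmentation and registration: its
inputs are, per cardiac phase, a 3D intensity volume and a coronary
centerline tree (polylines with per-point radius and detected branching
points) already co-registered into one index-space frame. Segmentation and
registration are explicitly out of scope; "projection" of a point between
phases is therefore the identity map, with an affine hook available when an
external transform must be applied.

All coordinates are continuous, 0-based index-space positions. Distance
thresholds quoted in voxels are evaluated as Euclidean distances in index
space, which matches how they are customarily stated even on anisotropic
acquisitions (0.625 mm slices vs 0.488 mm pixels); whether such thresholds
should instead be evaluated in mm is genuinely open, so the geometry keeps
spacing metadata and a caller can convert, but index space is the default
everywhere.

## Branching-point consolidation and branch matching

Parameters (`MatchingParams`), all in voxels unless a fraction:

| parameter | default | meaning |
|---|---|---|
| `d_consolidate` | 20 | minimum separation for a projected branching point to be kept as new |
| `theta` | 3 | maximum nearest-centerline distance for a point to count toward coverage |
| `coverage_min` | 0.70 | mutual coverage fraction required for a branch correspondence |
| `subset_coverage` | 0.90 | coverage above which a shorter same-phase branch is a redundant subset |
| `resample_step` | 1.0 | arc-length step of centerline resampling |

The defaults for `d_consolidate`, `theta`, and `coverage_min` are the
operating values of the published method. `subset_coverage` has no published
value; 0.90 removes truncated duplicates while tolerating small geometric
noise. Unit resampling makes "70% of the centerline voxels" well defined for
continuous polylines.

Decisions taken where the procedure is underdetermined:

* **Coverage denominator.** All resampled points of the source branch count
  in the denominator; points farther than θ from the target tree count
  *against* coverage. This is the stricter reading and penalizes partial
  overlaps; a `denominator="within_theta"` mode implements the laxer one.
* **Group merging.** Pairwise matches over all phase pairs are merged by
  transitive closure. If closure would put two branches of one phase into a
  group, the branch with the larger within-group mutual-coverage sum is
  kept and the other is demoted to a singleton, with a log entry —
  deterministic and auditable.
* **Ties.** Equal-length subset duplicates: the lexicographically smaller id
  survives. Plurality votes in coverage: most votes, then lexicographic id.
* **Snap tolerance.** Branching points snap onto the nearest centerline
  vertex within 2 voxels when splitting; farther points are rejected with a
  report rather than silently moved.

Nearest-centerline queries use a KD-tree; an exhaustive brute-force scan is
kept as the oracle in the tests and the two are checked for exact agreement
on random instances.

## CPR straightening

Cross-section orientation comes from a rotation-minimizing frame propagated
by the double-reflection method, with tangents from central differences and
the initial normal chosen as the coordinate axis least aligned with the
first tangent (so straight axis-aligned vessels straighten to exact axial
crops). Frenet frames were rejected because their normals flip at
inflection points, which would twist the straightened volume.

Resampling is trilinear. Default in-plane extent is ±3× the branch mean
radius at 0.5-voxel pitch, with an odd sample count so the centre voxel lies
exactly on the centerline. Out-of-volume samples take a configurable fill
value (default: the volume minimum) and are flagged in a mask; flagged
regions are excluded from quality measurement.

The VQM is evaluated in original volume space by default, using the frame
field directly — straightening is primarily a display format. Evaluation
inside the straightened volume is available (`straightened_branch_vqm`) and
agrees with the original-space value to well under 5% on gently curved
tubes; the residual difference is interpolation loss from resampling twice.

## Vessel quality measure

`CrossSectionSpec` defaults: 36 radii (10° pitch — the number of wall points
is not prescribed anywhere, 36 balances angular coverage against cost) and
8 samples per half-radius interval. Sampling uses the midpoint rule on
uniform subintervals of [r/2, r] (inside) and [r, 1.5r] (outside): neither
band samples the wall itself, so on an ideal binary cylinder every inside
sample reads the lumen and every outside sample the background, and the
measure evaluates to the lumen-background contrast exactly. The means of
the per-radius gradients and of the per-point radial gradients are plain
arithmetic means, reproducible from the stored profiles to 1e-9.

The sampling radius is constant along a branch and across the phases of a
correspondence group — chosen as the branch-mean radius of the group's
best-resolved member, defined here as the member with the longest recovered
centerline. A per-point radius would inject segmentation noise into a
measure meant to compare the *same* segment between phases; the constant
radius keeps the denominator of a true gradient a common factor that can be
dropped.

Radii whose samples leave the volume are dropped and the profile flagged
truncated; a branch with no usable point raises an error naming the branch.
Selection ties are broken by the clinical phase listing order (earliest
listed wins best, latest worst), purely for determinism.

Exact invariants, verified in tests: VQM is unchanged by adding a constant
to all intensities, and scales linearly with a multiplicative rescaling.

## Observer agreement

Each pairable correspondence group contributes one best/worst pair with a
seeded random left/right placement. Kappa is computed on the post-
randomization left/right choices, with the computer's "choice" being the
side holding its best-VQM image: computing on best/worst labels instead
would give the computer a degenerate marginal and an undefined kappa,
whereas the left/right construction matches the randomized display and
yields the published overall values. Overall percent agreement pools
per-case agreement counts (count-weighted); overall kappa is the unweighted
mean of per-case kappas — the pair of conventions that reproduces the
published overall rows from the published per-case rows. Percents are
reported rounded to integers and kappas to two decimals, as printed.

Landis–Koch bins: < 0 less than chance, (0, 0.20] slight, (0.20, 0.40]
fair, (0.40, 0.60] moderate, (0.60, 0.80] substantial, (0.80, 1] almost
perfect. A kappa of exactly 0 is binned as slight (the published bin table
starts at 0.01 and never exercises 0).

## Synthetic phantom

The generator emulates the degradations that matter to the method, each
independently controllable per phase:

* **Geometry**: cubic-spline tubes with constant radius (default 2.5
  voxels, a typical coronary lumen at sub-millimetre voxels), rasterized by
  distance-to-centerline thresholding with 2× supersampling to anti-alias
  the wall (the radial-gradient measure is sensitive to wall
  discretization; an exact binary mode exists for analytic tests).
* **Intensities**: lumen 400, background 50 CT-like units — roughly
  contrast-enhanced lumen vs myocardium.
* **Motion blur**: isotropic Gaussian, per phase; the blur ordering is the
  ground-truth quality ordering.
* **Noise**: additive Gaussian on the volume.
* **Jitter**: smooth displacement of the *exported* centerlines (drawn on
  sparse control points, spline-interpolated, rescaled so the realized RMS
  equals the requested sigma) — the image is rendered from the true
  geometry, so jitter models registration/tracking error.
* **Dropout**: each branch removed from a phase's exported tree with a
  per-phase probability; the vessel stays in the image, as with a real
  segmentation failure.

Everything derives from one seed through spawned substreams, so trees are
identical whether or not volumes are rendered.

Not modelled: physically realistic cardiac motion (blur here is isotropic
and global per phase), beam hardening, helical reconstruction artifacts,
calcified plaque, stenoses, contrast gradients along the vessel, or
anisotropic voxels in the default specs. Passing phantom tests therefore
shows the pipeline's logic and its tolerance to the modelled degradations —
not clinical performance, which the bundled observer study tables address
at the aggregate level only.

## Validation studies and problem sizes

* **Correspondence recovery**: 20 seeds of tree-only phantoms — 8 branches
  ≥ 12 voxels apart, 6 phases, jitter RMS 1.0 voxel, dropout 0.2 —
  scored by the mean Jaccard index between recovered and true groups
  (observed: 1.0; required: ≥ 0.95). Jitter differences between two phases
  rarely exceed θ = 3, so coverage stays above 70%.
* **Best-phase selection**: 200 independent single-vessel trials at 40³
  voxels, two phases (blur 0.5 vs 3.0), noise sigma 20 — success = the VQM
  picks the low-blur phase (observed: 100%; required: ≥ 95%).
* **Analytic cases**: uniform volume (VQM 0) and an ideal binary cylinder
  of radius 48 voxels (VQM exactly 400; the radius is large enough that no
  trilinear interpolation cell straddles the wall at the default sampling
  offsets).

These sizes run the full suite in well under a minute per study on one CPU;
they are the package's standing validation conditions, not tuned per run.

## Known limitations

* Branching-point detection from image data is not implemented (it belongs
  to the upstream segmentation); consolidation starts from detected points.
* The coverage rule can mismatch branches that run parallel closer than θ
  for most of their length; the phantom layouts keep vessels farther apart
  than that, as real coronary branches usually are beyond bifurcation
  regions.
* VQM measures wall sharpness only; contrast or smoothness descriptors are
  not implemented.
* Kappa confidence intervals and significance tests are out of scope; the
  statistics mirror what the evaluation design reports.
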