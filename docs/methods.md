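# Methods

## Problem setting

The pipeline consumes, per swallowing structure (ROI), an ordered sequence
of closed 2D contours in physical millimetre coordinates — one contour per
cine frame over at least one swallowing cycle — plus pixel-spacing and
frame-interval metadata. Images themselves are never read. Coordinates are
expected in a right-handed frame with +y superior and +x anterior; inputs
stored in pixel units are converted by pure scaling at read time (an
explicit `flip_y` option covers image-convention input where the row index
grows inferiorly).

## Contour registration

**Preprocessing.** Both contours of a frame pair are resampled to uniform
arc-length spacing equal to the in-plane pixel size (default 1 mm), with a
deterministic start vertex (lowest y, then lowest x) so runs are
bit-reproducible. A single isotropic unit-box scaling is computed from the
union bounding box of the pair, so source and target share one coordinate
frame and the anatomical axes are not distorted. The paper-gap choice of a
*shared* (per-pair) rather than per-set box is deliberate: per-set scaling
would shrink the apparent motion and break the AP/SI decomposition.

**Modified TPS-RPM.** Matching alternates softassign correspondence and a
regularized thin-plate-spline fit under deterministic annealing:

- Inner affinities: `exp(-d²/(2T))/T`. Outlier row and column: a Gaussian
  at the fixed initial temperature around the opposing set's centroid —
  the symmetric-outlier ("modified") treatment that lets spurious or
  unmatched points in *both* sets opt out. Sinkhorn normalization
  (alternating row/column, tolerance 1e-3, ≤ 30 sweeps) keeps inner row
  and column sums near 1.
- TPS update: each source point's virtual target is its
  correspondence-weighted mean of target points, weighted by its inner
  mass; points with mass < 1e-8 are dropped from the solve. The fit
  minimizes the weighted residual plus two annealed regularizers,
  `lam = lambda_init·T·K` on the bending energy and
  `lam_affine = lambda_affine_init·T·K` on `‖A − I‖²`. The affine anchor is
  essential: without it, the high-temperature phase (where every virtual
  target collapses toward the centroid) re-expands with an arbitrary
  orientation, and symmetric contours can be registered through a
  *reflection* that is invisible to any contour-distance metric while
  corrupting the interior displacement field.
- The solve parameterizes the warp coefficients in the QR null space of the
  polynomial basis, so the TPS side conditions (`Σw = 0`, zero first
  moment) hold exactly; one symmetric linear solve per iteration. At
  `lam = 0` the solve interpolates to ~1e-12.

**Schedule defaults** (all exposed via `AnnealingSchedule` and the YAML
config): `T_init` = mean squared source–target distance in the unit box;
`T_final` = 0.1 × (resampling spacing / box scale)²; cooling rate 0.93;
3 correspondence/transform alternations per temperature; `lambda_init` = 1;
`lambda_affine_init` = 0.01. The extra cooling decade in `T_final` (the 0.1
factor) matters: at a final temperature equal to the squared point spacing,
the correspondence is still fuzzy at the one-spacing scale and the weighted
means pull chords inward, leaving a curvature-dependent residual of a few
hundredths of a millimetre even for identical contours; one more decade
drives the identity residual to ~1e-10 mm. The outer loop runs the full
schedule with no early stopping, and the core contains no randomness, so
repeated runs are bit-identical.

**Back to millimetres.** The solved unit-box transform is conjugated by the
similarity in closed form. The kernel rescaling
`U(r/s) = U(r)/s² − (log s/s²)·r²` introduces a quadratic cross-term whose
non-affine part cancels exactly under the TPS side conditions, so the
mm-space map is again an analytic thin-plate spline — which is what makes
analytic transform *composition* (below) possible.

## Deformation fields and motion

A uniform grid (default 1 mm spacing, 2 mm margin, origin snapped down to a
spacing multiple) covers the ROI at its first contoured frame. Motion from
the initial frame to frame k composes the chain of consecutive-pair
transforms by analytic re-evaluation at the moved position — not by
resampling gridded vectors — so concatenation adds no interpolation error;
translations compose exactly. Grid points inside the initial contour
(boundary inclusive, via polygon containment; identical to the even-odd
rule for the simple polygons produced here) define the averaging mask.

Each in-ROI displacement vector is decomposed onto the SI and AP axes and
rectified: a vector contributes `max(v·ŝ, 0)` to superior and
`max(−v·ŝ, 0)` to inferior (likewise AP), so each point feeds only the
direction it actually moves. The ROI magnitude per direction is the mean
over in-ROI grid points; the per-direction maximum over frames is the
cycle summary. Rectify-then-average (rather than average-then-rectify) is
the chosen reading of per-direction averaging; the two agree for coherent
ROI motion and differ only for shearing ROIs.

## Validation

The error of one registration is the symmetric mean closest-point distance
between the deformed source contour and the reference target contour (mean
over each contour's vertices of the distance to the other's polyline,
directed means averaged). Closest-point rather than index-paired distance
is forced by resampling, which destroys vertex correspondence. Thresholds:
errors ≤ 1 mm are `ok` (the level almost all successful registrations
reach), ≤ 2 mm `suspect` (the level reachable for difficult cases after
manual tuning), larger `failed`; boundaries take the lower status. The
batch runner never aborts on a failure — it flags, logs, and continues.

## Synthetic data

The generator emulates the study conditions: 7 ROIs (pharyngeal
constrictor as a narrow 8:1 band, plus epiglottis, base of tongue,
geniohyoid, hyoid, soft palate, larynx as ellipses/harmonic blobs at
sagittally plausible positions), 22 frames by default at 160 ms, 1 mm
pixels, and per-direction amplitude defaults near the cohort means (e.g.
larynx superior 18.4 mm). A frame-k contour is the base shape pushed
through a two-phase displacement (sin² ramp to the superior/anterior
amplitudes at the peak frame, then an inferior/posterior return phase) plus
an optional low-order TPS perturbation, then per-vertex Gaussian jitter
(default 0.2 mm — the hand-contouring surrogate) and optional spurious
vertices. Base shapes are resampled to 2.5 mm vertex spacing before
animation so the jittered polygons stay simple. Ground-truth fields and
motion tables come from the analytic warp, before jitter.

What the generator does **not** emulate: real contour-shape change driven
by physiology (shapes deform only through the prescribed smooth warp),
correlated contouring errors, through-plane motion, and frame-to-frame
contour topology changes. Passing tests therefore demonstrate the
machinery's correctness and its error level under controlled deformation
and noise, not clinical accuracy on patient cines.

Registration test suites: the *smooth* family (ellipses/blobs, deformation
amplitude drawn up to 15 mm, jitter 0.2 mm) defines the typical-error
suite; the *hard* family (crescents and 5:1 elongated ellipses) the
worst-case suite. `reflex_pair` reproduces the narrow-contour failure mode:
a 44 × 2.5 mm strip displaced 18 mm along its short (AP) axis with a
cluster of spurious vertices from an adjacent structure on the target
frame. With clean geometry the side-swapped ("reflex") lock still occurs
for strips thinner than ~2 mm but its error plateaus near half the strip
width, below the suspect threshold; the contamination is what drives the
mis-lock to flaggable levels (1–3 mm across seeds).

## Known limitations

- **Closed-curve sliding (aperture problem).** A uniformly resampled closed
  contour matched to a deformed copy admits cyclic-shift solutions that are
  nearly perfect at the contour level while rotating the point
  correspondence; contamination or strong tangential warp components can
  make such a slid solution win. Contour-distance validation cannot see
  this, and tangential motion components are correspondingly less reliable
  than normal components. Scattered point clouds (no sliding continuum) do
  not show the effect: with 30% spurious points in both sets the matcher
  recovers ≥ 95% of true pairs.
- **Outlier-bin floor.** With the fixed-temperature outlier bins, perfectly
  matched points retain a few percent of outlier mass at convergence (the
  Sinkhorn equilibrium scales like √T_final); outlier mass is a relative,
  not absolute, indicator.
- Motion is measured from the first contoured frame, not aligned to
  physiologic events; left–right motion is out of scope (sagittal plane
  only); no automatic re-tuning of flagged registrations is attempted.

## Problem sizes

Default test and acceptance runs use contours of 60–160 resampled points,
8–22 frames per sequence, 50-case (smooth) and 20-case (hard) registration
suites, and small 2–7 ROI scenes; one pair registration takes on the order
of a second on one CPU.
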