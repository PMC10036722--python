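# Methods

## Scope and model

`rvspect` implements model-based segmentation of the right ventricle in
non-gated myocardial-perfusion SPECT. The central assumption is that in the
summed (time-averaged) study the RV mid-myocardial surface is well
approximated by a sphere: with LV sphericity index `x = a/b`, the ratio of
the septal-center-to-apex distance to the LV long axis is
`f/b = ½√(x² + 1)`, which evaluates to 1.11 (end-systole, x = 2) and 0.98
(end-diastole, x = 1.7) at population indices, and the mid-RV
eccentricity argument gives `m/d = ½·(c/d)` ≈ 0.9–1. Both ratios being near
unity justifies a sphere for the time-averaged study; a dilated RV violates
the assumption and is a known failure mode, which is why the pipeline is
*semiautomatic*: the LV bounding box and the RV sphere (center and radius)
are operator-adjustable inputs, realized here as function arguments and CLI
options so runs stay scriptable.

Coordinates: volumes are `data[x, y, z]` with voxel centers at integer
indices, physical position `index × spacing` (mm). After reorientation the
LV long axis lies on Z with the base toward +Z and the apex toward −Z; X
increases from the RV side toward the LV; Y runs anterior → inferior. All
model mathematics is in mm; masks are voxel-space booleans.

## Pipeline

**LV stage.** Optional rotation by a prior angle about Y (default 0°: the
synthetic data are generated short-axis). Initial cluster: binarize at 50%
of the maximum count inside the upper-right search region (configurable
fractions of the array extent, since orientation dialects vary), label with
26-connectivity, and keep the component with an LV-like volume (15–400 ml)
whose centroid lies in the region, scored by centrality and size. The
intra-patient threshold is the maximum of the average of 10×10 radial
profiles from the box center; it defines the final cluster to which the
first ellipsoid is fitted (9-parameter algebraic quadric, decomposed into
center/semi-axes/rotation; non-ellipsoid quadrics are rejected). The
iterative loop alternates 24×48 radial profiles from the ellipsoid center —
per profile the best myocardial point is the global maximum if it lies
within 2 voxels of the model surface, otherwise the nearest local maximum
within 3 voxels, with a floor of half the intra-patient threshold — with an
ellipsoid refit, until the center and every semi-axis move by less than
0.1 mm (cap 50; on hitting the cap a warning is issued and the last model is
used). The volume is then resampled so the long axis (apex sign resolved by
probing counts at the two poles: the closed apex carries counts) lies on Z.
Epicardial/endocardial surfaces are delineated on a 32×64 angular grid at
50% of each profile's peak with sub-sample linear interpolation; invalid
bins are filled from the model. The valve plane is found by scanning
circumferential mean counts on the mid-surface ellipse along the long axis:
the plateau is the median over the middle third of the axis and the valve
sits at the first basal crossing below 50% of the plateau (sub-plane
interpolation). `max_count`, the maximum count inside the LV myocardium
mask, is the global normalizer for the RV stage.

**RV stage.** All counts are divided by the LV maximum, and voxels inside
the LV epicardial surface dilated by one voxel are zeroed (prevents septal
bleed-through). The sphere is initialized from the LV model (see README).
Because a dilated RV can place the entire wall farther than one voxel from
the suggested surface — where no profile can pass the validity test — an
automated stand-in for the operator's drag adjustment scans radius
multipliers 0.7–2.2 of the suggested radius and keeps the radius that
maximizes the number of valid profiles; the suggested radius is kept
whenever it reaches half the best count. The iterative fit then alternates
48×96 profiles, validity selection (local maximum within one voxel of the
surface and above ¼ of the LV maximum, ties to the nearest), delineation at
the adaptive threshold `0.8·C_profile/(1 − 0.4(C_max − C_profile))` with
`C_max = 0.5`, far-off rejection (crossings more than two voxels from the
surface), and an algebraic least-squares sphere refit to the mid points,
until center and radius move < 0.1 mm (cap 50). Two additional point filters
stabilize the wedge-constrained fit: mid points whose profile meets the
valve plane within one voxel of the epicardial crossing are dropped (the
wall is truncated there and the delineation is partial-volume corrupted),
and a fit that wanders outside 0.3–2.5× the initial radius or more than six
voxels from the initial center raises the "RV not detectable" condition.
When the iteration cycles without meeting the tolerance (discrete point-set
changes can produce limit cycles), the iterate supported by the most
delineated points is returned. If fewer than four usable points ever remain,
the RV is declared not detectable; in scripted runs the operator-accept
fallback uses the initial sphere itself as the segmentation, which keeps
repeated acquisitions of a sub-threshold RV consistent with each other.

**Surface and masks.** A dense 120×320 delineation from the converged model
follows; a refreshed sphere is fitted to its usable mid points and every
epicardial/endocardial point failing the criteria is replaced by the
corresponding sphere point (radius ± half the nominal wall). The
mid-myocardial surface is a bivariate polynomial of total degree 5 in
(polar angle, azimuth unwrapped about the free-wall center), fitted by
damped (ridge-regularized) least squares to the measured mid points, with
the boundary condition that the surface meets the LV epicardial surface at
the septal junction enforced through constraint points of weight 100 at the
azimuthal edges of the free-wall domain (rays that miss the LV fall back to
the sphere radius). The polynomial applies over the fitted angular
rectangle; outside it (model-replaced regions, e.g. perfusion defects and
the poles, where azimuth degenerates) the refreshed sphere radius applies,
and the azimuthal span of the free wall is measured away from the poles.
The RV valve plane shares the LV valve plane's tilt in the vertical
long-axis view, is parallel to X in the horizontal long-axis view, and
passes through its intersection with the LV epicardial surface. Myocardium
mask: voxels within half the nominal wall (default 12.8 mm total, i.e. one
voxel each side — the apparent thickness is resolution-driven, the true wall
being sub-voxel) of the mid surface, on the apical side of the valve plane,
outside the LV. Cavity: voxels inside the endocardial surface
(mid − wall/2), apical of the valve, outside the LV epicardium (the septum
bounds the cavity); volume = voxel count × voxel volume.

**Quantification.** The polar map (default 18 polar × 36 azimuth sectors;
no standard resolution exists, both configurable) stores the maximum
LV-normalized count among myocardium voxels per angular sector from the
sphere center. Occupied azimuth columns form the free-wall arc, split into
equal thirds — anterior (−Y side), lateral, inferior (+Y side); the exact
angular boundaries are a design choice, equal thirds being the neutral one.
Maximal/average ratios are reported ×100; the decision cutoff of 30 on the
lateral maximal ratio is exposed as configuration, not hard-coded.

## Synthetic phantoms

The generator emulates *reconstructed* non-gated MPI volumes analytically
(64³ grid, 6.4 mm isotropic by default): an LV ellipsoidal shell (semi-axes
25/25/45 mm mid-surface, 10 mm wall, intensity 1) truncated by a valve
plane, a partial spherical RV shell (12.8 mm nominal wall at the apparent,
resolution-driven thickness; intensity fraction 0.2–0.6 of LV; 150°
azimuthal free-wall wrap) carved at the LV epicardium where the two abut, an
optional basal or apical RV defect (intensity multipliers 0.6 / 0.3 / 0.0
for mild / moderate / severe; the multipliers are a documented choice) and
an optional hepatic blob (1.5× LV) adjacent to the inferior wall. The LV
truncation sits at +0.3 of the long semi-axis basal of the center rather
than exactly at the center, so the valve plane is strictly basal of the
ellipsoid center as it is anatomically. Degradation chain: Gaussian blur at
9 mm FWHM (the system resolution), a Poisson draw scaled so the hottest LV
voxel has expectation 100 counts (summed-study statistics), and a 3D
zero-phase Butterworth low-pass, `|H| = 1/√(1 + (f/f_c)^(2n))` with order 5
and cutoff 0.5 cycles/voxel. Truth masks and the cavity volume come from the
pre-degradation geometry; the reported truth volume is a fine-sub-grid
(1.6 mm) integral of the continuous geometry, analogous to the
continuous-geometry chamber volumes an anthropomorphic phantom package
reports, with the voxelized-mask volume carried alongside (they agree to ~3%
when cut planes sit mid-voxel). The cohort sampler draws cavity volumes
uniformly on 40–220 ml (the RV mid radius is solved for each target by
bisection on the analytic volume), RV fractions uniformly on 0.2–0.6, LV
axes over 22–28 / 40–50 mm, and a defect with probability 1/3; per-phantom
seeds derive deterministically from the master seed.

What the phantoms do **not** emulate: projection-domain physics
(attenuation, scatter, collimator response, iterative-reconstruction
artifacts), anatomic shape variability (the RV shell is exactly spherical —
favourable to a spherical model), respiratory/cardiac motion, and
extra-cardiac background beyond a single hepatic blob. Passing phantom tests
therefore demonstrates internal correctness and noise robustness of the
algorithm, not clinical accuracy; clinical quantities reported for the
method on patient data (mean contour Dice 0.83, repeatability CR 13.57 ml,
ROC AUC 0.772 with sensitivity/specificity/accuracy 73.17/67.57/70.51 at the
cutoff of 30) depend on patient datasets and are *not* reproducible here;
the cohort-level phantom bounds checked by `scripts/acceptance.py` and the
test suite stand in for them.

## Numerical choices

- Radial profiles sample trilinearly every half voxel (3.2 mm default) with
  zero padding outside the grid; threshold crossings are localized
  sub-sample by linear interpolation.
- Sphere fits use the closed-form algebraic formulation (linear solve of
  `x²+y²+z²+Dx+Ey+Fz+G = 0`), deterministic and adequate at these noise
  levels; a brute-force geometric-residual grid minimizer exists only in the
  tests as an independent oracle. Ellipsoid fits use the 9-parameter
  algebraic quadric with centering/scaling for conditioning.
- Convergence tolerances are 0.1 mm on centers, radii and semi-axes (well
  below voxel scale), iteration caps 50.
- The mid-surface ridge damping is `1e-8 × mean diagonal` of the normal
  matrix — negligible bias, guards rank deficiency.
- There is no randomness anywhere in segmentation; identical inputs give
  bit-identical outputs. All stochasticity lives in the phantom generator,
  keyed by explicit seeds.
- Problem sizes used by the test suite and the acceptance script — a
  20-phantom cohort with one repeat acquisition each, and a four-phantom
  noiseless sweep of the 40–220 ml range — keep a full run to a few minutes
  on one CPU while exercising every stage end to end.

## Known limitations

- Sub-threshold RVs: at intensity fractions near the ¼-of-LV-max validity
  floor (≈ 0.2–0.25 after blur), few or no profiles validate; the
  segmentation falls back to the operator-accepted initial sphere, and
  cavity-volume accuracy degrades accordingly. This mirrors the clinical
  situation of an invisible RV and dominates the tails of the cohort
  accuracy and repeatability distributions.
- Voxelization: on hard-edged, blur-free shells the delineated mid surface
  carries angle-dependent partial-volume bias up to ~1 mm which the
  wedge-constrained sphere fit can amplify; at the smallest cavity sizes
  (~45 ml at 6.4 mm voxels) per-phantom volume errors can reach ~15–17%
  even without noise. Under the realistic blurred conditions the bias
  largely averages out.
- Dilated, strongly non-spherical RVs violate the model assumption; the
  plausibility gates will flag them as not detectable rather than return a
  poor sphere.
- The degree-5 surface cannot follow sharp local shape features; its
  parameterization (angles about the sphere center, azimuth unwrapped about
  the free-wall center) and the weight-100 junction constraints are design
  choices where no canonical construction exists.
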