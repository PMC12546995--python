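# Methods

`cranioguide` estimates where the 10-20/10-10/10-5 scalp positions lie on a
subject's head from nothing but camera-frame facial landmarks, so that
EEG/fNIRS headgear can be placed consistently without tape measures,
digitizers, or structural scans.  This note describes the model, its
assumptions, the synthetic data the package tests itself on, and the
numerical choices that were genuinely open.

## The model

### Cranial fiducials from a head surface

The five cranial reference points are the nasion (Nz), inion (Iz), left and
right preauricular points (LPA/RPA), and vertex (Cz).  Given Nz, LPA and RPA
on a triangulated scalp (millimeter coordinates), the remaining two are
constructed geometrically under the **three-point assumption** that Nz, Iz,
LPA and RPA are coplanar — an anthropometric regularity of human heads:

- **Iz** is the far intersection of the scalp with the ray from Nz through
  the LPA–RPA midpoint.  The near hit (the surface adjacent to Nz itself) is
  rejected by a minimum ray-parameter tolerance of 1e-9 mm, which also
  guards rays whose origin lies exactly on a mesh vertex.  Coplanarity holds
  by construction; the residual is checked to 1e-6 mm.
- **Cz** is the far scalp intersection of the ray cast from the LPA–RPA
  midpoint along the fiducial-plane normal `cross(Iz − Nz, RPA − LPA)`.  A
  scalar product of the two in-plane axes carries no directional
  information, so the cross product is the only construction that yields
  the superior axis; both orientations are cast and the hit farther from
  the plane wins (the superior side on any head-like surface), with the
  cross-product direction preferred on ties.  Whether the ray should start
  at the LPA–RPA midpoint, the Nz–Iz midpoint, or the plane centroid is not
  fixed by the convention; all three lie in the fiducial plane and the
  choice is exposed as `cz_origin` (default `ear-midpoint`).  On spheres the
  three agree exactly; on realistic heads the difference is absorbed by the
  plane normal.

The **five-point** mode accepts independently measured Iz and/or Cz
verbatim (checked to lie within 1 mm of the surface, configurable) and
constructs whatever is missing.

### 10-20 layout construction

The layout step is self-contained rather than delegated to an external
meshing toolbox, so it can be validated against closed forms.  The
construction follows the extended 10-5 convention:

1. the plane through Nz, Cz and Iz cuts the **sagittal arc**; labels sit at
   cumulative arc-length fractions (10% steps for 10-20, 5% for 10-5).  The
   50% point *redefines* Cz — the convention defines the vertex by arc
   fractions, so the incoming geometric Cz only seeds the cutting plane.
   The drift between the two definitions is logged.
2. the plane through LPA, the redefined Cz and RPA cuts the **coronal
   medial arc** (T7…C3…Cz…C4…T8).
3. the **circumferential ring** is cut by the least-squares plane through
   the four 10%-level anchors (Fpz, T7, Oz, T8) — on real heads the four
   are generally not exactly coplanar.  The closed contour is re-seamed at
   Fpz and oriented toward T7 (left side); lateral labels sit at fixed
   fractions of the ring circumference (odd numbers left, even right).
   T7/T8 themselves are owned by the coronal arc; Fpz/Oz by the sagittal
   arc.
4. **intermediate arcs** (F7–Fz–F8, FT7–FCz–FT8, …) are cut by the plane
   through their three anchors and subdivided at quarter fractions (10-20
   rows) or eighth fractions (10-10 rows).

The label/fraction/region catalogue is an editable JSON table shipped with
the package (81 labels: 21 at 10-20, 63 at 10-10, 81 at 10-5).  The 10-5
tier extends the midline and coronal lines to 5% steps; the ring and
intermediate rows deliberately stay at the 10-10 set — evaluation code
tolerates layouts with missing labels, and densities are strictly nested so
shared labels coincide bit-for-bit on the same mesh.  Anterior/posterior
region tags live in the catalogue; coronal-medial-line labels are tagged
`both` and count in both regional summaries.

### Frame conversion and the linear head map

Facial landmarks arrive in a detector-style **normalized camera frame**
(x, y in [0, 1] of the image, z a relative depth).  Two linear pieces
connect frames and faces to crania:

- **Per-view affine** `dst = A·src + b`, fitted by least squares on ten
  matched facial points (nasion, eye corners, nose tip, mouth corners,
  chin, forehead).  Ten pairs give 30 equations for 12 parameters; the fit
  is exact whenever a true affine relates the frames.  No outlier handling
  is applied — the correspondence points are curated, not detected.
- **Stacked linear head map**: for each target `c ∈ {Iz, LPA, RPA, Cz}` an
  affine regression from the flattened coordinates of Nf = 20 selected
  facial points (a row of length 3·Nf = 60) to the target's 3D position,
  `p_c = f·A_c + b_c`, fitted on all subject × view rows pooled — the
  subject's head is rigid, so one map serves every view.  The
  normal-equations (pseudo-inverse) form is the reference semantics; the
  implementation solves three ordinary least-squares problems per target
  via LAPACK, which is algebraically identical and numerically stabler.
  An optional ridge penalty (default 0, intercept unpenalized) guards
  degenerate designs; with ridge = 0 a rank-deficient design raises rather
  than silently returning a minimum-norm solution.

Nz is never regressed: each landmark convention designates one facial point
as the nasion (index 168, 0-based, in the 468-point camera convention;
index 0 in the synthetic convention) and it is copied verbatim.  Facial z
is used as-is; no depth rescaling is applied before regression.

The prediction is affine in landmark *coordinates*, not a rigid-motion
model: translating all inputs by `t` does not translate the outputs by `t`.
This is intentional — the map also absorbs the scale and pose variation of
the normalized frame.

### Atlas registration and tracking

Precomputed atlas layouts are carried onto the subject by a least-squares
affine fitted between the atlas cranial fiducials and the predicted ones,
applied to every layout entry.  The fit runs directly across frames (atlas
millimeters → subject normalized-camera); the affine absorbs the scale, so
no explicit unit conversion is needed.  All five fiducials always enter the
correspondence set: four coplanar points cannot determine a 3D affine, and
in three-point mode Nz/Iz/LPA/RPA are coplanar by construction, so Cz is
required to fix the out-of-plane component.  The three/five-point toggle
therefore records only how Iz was derived.

Per frame, the tracker runs: moving-average stabilization → cranial
prediction → registration refit (every frame; an interval cache is a
config option) → manual offset → orthographic projection to pixels
(`pixel = (x·w, y·h)`; out-of-frame labels are flagged, never dropped).
Frames with no detected face are skipped and leave the stabilizer buffer
untouched.  Averaging is applied to the facial landmarks before prediction;
since every downstream step is affine, averaging the outputs instead is
nearly equivalent and is available via `average="output"`.

The moving average over `w` frames reduces the marginal standard deviation
of i.i.d. landmark jitter by `1/√w` and introduces exactly `w` frames of
lag after a step change — both are asserted in the test suite.  Supported
windows are any positive integer; 1 (off) and {3, 5, 8, 10} are the
conventional choices.

## Synthetic data: what it emulates and what it does not

No real head-scan library ships with the package; a generator produces the
study populations:

- **Heads** are icosphere tessellations scaled by per-subject semi-axes
  drawn from Gaussian priors — x (depth) 95 ± 5 mm, y (width) 75 ± 4 mm,
  z (height) 92 ± 5 mm, truncated at ±3 sd — adult-head-like proportions.
- **Cranial truth** is the axis intersections snapped to the faceted
  surface; **facial truth** is 24 named points at fixed ellipsoidal
  angular positions over the anterior surface, index 0 being the nasion.
- **Per-subject facial variation**: each point's angular position is
  perturbed by a 3° Gaussian offset (≈5 mm on a 90 mm head), fixed per
  subject, never applied to the nasion point.  Real faces vary
  independently of gross head shape; without this the multi-subject design
  matrix would carry only three shape degrees of freedom per view and the
  stacked regression would be structurally rank-deficient — a property no
  real face population has.
- **Nine views**: yaw ∈ {−30°, 0°, +30°} × pitch ∈ {+20°, 0°, −20°}
  (left/center/right × top/middle/bottom).  Each view applies its rigid
  rotation, then scales the head bounding box isotropically into the unit
  square with a 10% margin — a stand-in for a detector's normalized output
  frame, whose true normalization is detector-defined and unrecoverable.
  The exact per-view affine is recorded so the frame-conversion fit can be
  checked against its generator.
- **Jitter** (i.i.d. Gaussian, normalized units) lands on facial landmarks
  only; cranial reference points stay exact, mirroring a pipeline whose
  cranial ground truth is curated rather than detected.

All generators are pure functions of (parameters, seed).

What passing tests on this population show: the estimator recovers exactly
identifiable models, degrades monotonically with input noise, is
insensitive to viewing angle, and reproduces every geometric construction
against analytic oracles.  What they do not show: accuracy on real heads.
Ellipsoids have no hair, no ears, no asymmetry, and no detector bias;
real-data errors are dominated by exactly those factors, concentrated at
the back of the head where facial landmarks carry the least information.
The synthetic study reproduces that spatial pattern qualitatively
(posterior > anterior error; Iz worst, LPA/RPA best) but its absolute
numbers are not comparable to camera-and-scan results.

## Numerical choices

- Ray–triangle intersection (Möller–Trumbore) and point-to-mesh closest
  point are brute-force and vectorized over all faces; head meshes here
  are ≤ ~20k triangles, for which an acceleration structure buys nothing.
  Barycentric tolerance 1e-9; self-hit rejection t > 1e-9 mm.
- Plane cuts use exact plane–edge crossings per triangle (via trimesh
  sectioning); duplicate contour points within 1e-9 mm are merged.  When a
  cut yields several components, the one nearest the query anchor wins,
  ties broken by larger total length — heads are near-convex, so this is
  expected never to trigger; meshes need not be watertight.
- Arc subdivision interpolates linearly within polyline segments;
  fractions 0/1 return the exact endpoints.  Sub-arc extraction projects
  the three guide points onto the contour and walks the traversal that
  passes nearest the middle point.
- Least squares everywhere is `numpy.linalg.lstsq` (SVD); rank checks use
  a relative 1e-9 tolerance on the centered design.
- With exactly five registration correspondences the affine (12 dof, 15
  equations) is generically determined; least squares is used uniformly
  and yields the minimum-norm solution on ties.
- Angles are degrees in configuration and radians internally; millimeters
  everywhere in head frames.

## Problem sizes

The shipped validation study uses 100 subjects × 9 views with 5-fold
subject-wise cross-validation at jitter σ ∈ {0, 0.005, 0.01}; the
registration study uses 50 training and 20 held-out subjects; stabilizer
statistics use 10,000 frames.  These sizes give stable medians (CV medians
reproduce across seeds within a few percent) while keeping the whole suite
fast on a single CPU.

## Known limitations

- The synthetic facial convention has 24 points; the 468-point camera
  convention is fully supported in the data model and the default
  20-point subset for it is documented, but no live detector is bundled —
  an adapter converting detector output to the stream format is the
  integration point, and it is deliberately outside the tested surface.
- Only the linear predictor is implemented.  Tree-ensemble and neural
  predictors fit the same interface (rows → per-target coefficients) and
  are left as an extension point; on moderate-sized head libraries the
  linear map is the stronger baseline.
- Registration commutes with layout construction only up to similarity
  transforms; under strongly anisotropic subject-atlas shape differences
  the fraction-defined positions and the affinely carried atlas positions
  genuinely differ — that residual is part of what the layout error
  reports measure, not a bug.
- Atlas construction from MRI, mesh repair, scalp-to-cortex projection,
  and GUI/camera handling are out of scope; atlas bundles and meshes are
  inputs.
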