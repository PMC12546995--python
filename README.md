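# cranioguide

Facial-landmark-guided estimation of 10-20 head landmarks for EEG/fNIRS
headgear placement.

Consistent probe placement is a perennial problem in scalp neuroimaging:
optode and electrode positions are defined by the 10-20/10-10/10-5
conventions — labeled points at fixed arc-length fractions of curves
spanned by five cranial fiducials (nasion Nz, inion Iz, preauricular
points LPA/RPA, vertex Cz) — but measuring those fiducials with a tape is
slow and operator-dependent.  `cranioguide` implements the computational
core of a camera-based alternative: facial landmarks, which a detector can
track in real time, are mapped to the cranial fiducials by a precomputed
linear regression, and a precomputed atlas 10-20 layout is carried onto
the subject by an affine registration, frame by frame.

It is a library plus a CLI for researchers building or evaluating such
placement-guidance pipelines.  No camera, GUI, or licensed head-scan data
is required: a synthetic head-population generator (parametric ellipsoid
heads with ground-truth landmarks and a nine-view camera grid) drives all
tests and studies.

## The model in brief

For each target fiducial c ∈ {Iz, LPA, RPA, Cz}, the head map is the
affine regression

    p̂_c = f · A_c + b_c ,      A_c ∈ R^(3·Nf × 3),  b_c ∈ R^3,

where f is the row vector of Nf = 20 selected facial-landmark coordinates
in the detector's normalized camera frame.  (A_c, b_c) are fitted by
ordinary least squares over all subject × view training rows — the
pseudo-inverse solve of the stacked system is the reference semantics.
Nz is never regressed: it coincides with a designated facial point and is
copied.  Given predicted fiducials Ĉ and atlas fiducials C_a with layout
H_a, registration fits the affine T minimizing Σ‖T(C_a) − Ĉ‖² and renders
Ĥ = T(H_a).  On meshes, the 10-20 layout itself is constructed from the
five fiducials by plane cuts and arc-length subdivision (sagittal and
coronal arcs, circumferential ring, intermediate rows); geometric Iz/Cz
construction assumes Nz/Iz/LPA/RPA coplanarity (the "three-point" method).
See `docs/methods.md` for the full account.

## Worked example

Fit and cross-validate the head map on a synthetic population:

```python
import cranioguide as cg
from cranioguide.mapping import fit_linear_headmap, training_rows_from_records
from cranioguide.synthetic import default_synthetic_subset

subjects = cg.sample_population(100, seed=42)      # ellipsoid heads, mm
views = cg.nine_view_grid()                        # 3 x 3 camera stations
subset = default_synthetic_subset()                # Nf = 20 facial points
records = cg.build_training_table(subjects, views, jitter_sigma=0.005, seed=42)

report = cg.cross_validate_cranial(records, subset, k=5, seed=42)
print(report.summary("landmark").round(4))
print(f"overall median: {report.median():.4f}")
```

prints

```
          median     iqr    n
landmark
Cz        0.0208  0.0151  900
Iz        0.0264  0.0180  900
LPA       0.0185  0.0120  900
RPA       0.0181  0.0124  900
overall median: 0.0203
```

Errors are Euclidean distances in normalized camera units (the head spans
roughly 0.8 of the unit frame, so 0.02 ≈ 4 mm on a 190 mm head).  Each of
the 100 subjects is tested exactly once across the 5 folds, in all 9
views (n = 900 per landmark).  The ordering is the expected one: the
preauricular points, nearest the visible face, are predicted best; the
inion, hidden at the back of the head, worst.

The same pipeline is available from the shell:

```sh
cranioguide simulate --subjects 100 --sigma 0.005 --seed 42 --out data/
cranioguide fit-map  --training data/training.jsonl --out map.json
cranioguide evaluate --training data/training.jsonl --k 5 --out report/
```

plus `cranial`, `tentwenty`, `predict`, `register`, and `track` for the
mesh-side constructions and per-frame overlay tracking (`cranioguide
--help` lists them).

## Layout

- `src/cranioguide/geometry.py` — ray casting, plane-cut contours,
  arc-length subdivision on triangle meshes
- `src/cranioguide/cranial.py` — geometric Iz/Cz construction, fiducial sets
- `src/cranioguide/tentwenty.py` — 10-20/10-10/10-5 layout construction and
  the label catalogue (`src/cranioguide/data/`)
- `src/cranioguide/mapping.py` — per-view affine fits and the linear head map
- `src/cranioguide/registration.py` — atlas-to-subject registration, overlays
- `src/cranioguide/tracking.py` — moving-average stabilizer, per-frame pipeline
- `src/cranioguide/synthetic.py` — synthetic heads, views, training tables
- `src/cranioguide/validation.py` — cross-validation and error reports
- `src/cranioguide/io.py`, `cli.py` — file formats and the command line
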