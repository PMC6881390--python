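# skullnav

Evaluation pipeline for navigated craniofacial (fronto-orbital advancement)
surgery: fiducial-based rigid registration with RMSE reporting,
navigation-accuracy assessment against an intraoperative surface scan,
craniometric outcome metrics, mesh post-processing, and a synthetic skull
phantom generator so the whole pipeline runs with no external data.

## What it does

- **`skullnav.geometry` / `skullnav.io`** — shared data model
  (`RigidTransform`, `LandmarkSet`, `TriangleMesh`) and readers/writers for
  STL (ASCII + binary, with vertex welding), OBJ (geometry only, fan
  triangulation), CSV landmarks (`label,x,y,z[,frame]`) and Slicer-style
  markup control-point files (RAS→LPS conversion on read/write). The
  internal convention is a right-handed LPS frame in millimetres.
- **`skullnav.registration`** — closed-form (SVD/Kabsch) rigid point-set
  registration by label correspondence, with per-fiducial residuals and
  RMSE; two-step session bookkeeping (one primary registration on guide
  landmarks, repeatable secondary registrations on bone pins under head
  motion); per-case and pooled summary tables (pooled secondary RMSE is
  weighted by repetition count).
- **`skullnav.surface`** — exact unsigned point-to-triangle-mesh distances
  (all Voronoi regions; KD-tree-pruned accelerated query identical to brute
  force), scan-to-navigation registration via pin fiducials, and per-region
  + pooled error summaries (mean, SD, type-7 quartiles, max).
- **`skullnav.craniometry`** — interfrontal angle (at the metopic-suture
  landmark, atan2 formulation) and transverse forehead width from LFL /
  RFL / MSL landmarks; absolute plan-vs-postop outcome errors and summary
  tables.
- **`skullnav.processing`** — uniform-Laplacian smoothing (defaults:
  10 iterations, relaxation 0.1; boundary vertices fixed) and hole filling
  by centroid fans.
- **`skullnav.phantom`** — deterministic synthetic cases: ellipsoidal
  cranial-vault surrogate, landmarks constructed to realize a requested
  angle/width exactly, guide/pin fiducials on the surface, Gaussian tracking
  noise, scheduled head-motion events, and a postoperative "scan" in its own
  frame.
- **`skullnav.cli`** — `skullnav` command with `simulate`, `register`,
  `evaluate`, `morphometry`, `smooth`, `fillholes` and `report`
  subcommands.

## CLI quick start

```sh
# generate a synthetic case (planned angle 130 deg, width 93 mm)
skullnav simulate --seed 7 --angle 130 --width 93 --out case7

# craniometric metrics for each stage
skullnav morphometry --case case7

# simulated navigation session scored against the case's surface scan
skullnav evaluate --case case7 --out case7-eval

# rigid registration of two landmark files
skullnav register --source guides_image.csv --target guides_tracker.csv

# mesh post-processing
skullnav smooth --input skull.stl --output smooth.stl --iterations 10 --relaxation 0.1
skullnav fillholes --input smooth.stl --output closed.stl

# full multi-case pipeline -> report.json, table1.csv, table2.csv, distances.csv
skullnav report --config config.json --out report/
```

A `report` config is a JSON object with a `seed`, an `options` block
(`quartile_convention`, `sd_convention`, `secondary_pooling`) and a `cases`
list whose entries are either `{"dir": "<case directory>"}` or an inline
`{"phantom": {...PhantomSpec fields...}}`.

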