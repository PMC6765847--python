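# stratavis

Visual-analytics toolkit for stratifying patients from multidimensional
clinical test data: radial-coordinate (RadVis) layouts in 2D and in a 3D
cylinder, patient-similarity graphs, k-means segmentation, and
parallel-coordinates multifiltering — plus a reproducible synthetic
generator for a five-stage dementia cohort scored on the 15-item S-IADL
(Seoul-Instrumental Activities of Daily Living) questionnaire.

It is written for clinical-informatics researchers who want the
segmentation machinery of an interactive EMR visualization tool as a
scriptable, testable batch library: every view is a deterministic function
of the data and a seed, and every interaction (brushing, cluster
segmentation, export) has a programmatic equivalent.

## The layout model

Each numeric variable *i* is a **dimensional anchor** — a point on a
circle in 2D, a vertical edge of a cylinder in 3D.  A record's value is
first placed per variable by linear interpolation between position bounds:

    Np(i) = (N(i) − Vmin(i)) / (Vmax(i) − Vmin(i)) · (Pmax(i) − Pmin(i)) + Pmin(i)

With the default bounds `Pmin = 0, Pmax = 1` this is the min–max-normalised
value `u_i ∈ [0, 1]`, the attraction weight of anchor *i*.  A record is
then drawn at the anchor-weighted barycenter

    (x, y) = Σᵢ uᵢ aᵢ / Σᵢ uᵢ

so the highest-valued variable pulls hardest.  In the 3D cylinder the
height is the mean normalised score, `z = H · mean(u)`: a record at the
minimum on every variable sits at the bottom-centre `(0, 0, 0)`, and two
records with proportional profiles — which a flat RadVis would overlap —
share `(x, y)` but separate in `z`.

Segmentation is Lloyd's k-means (assign to nearest centre by Euclidean
distance, recompute centre means, repeat until the centres stop moving),
with **Forgy** initialisation (k distinct data points, seeded) or
**Random** initialisation (k pivots drawn uniformly inside the cylinder).
Cluster recovery is scored with the adjusted Rand index (ARI).

## Worked example

```sh
stratavis simulate --n 300 --seed 7 --out cohort.csv
stratavis cluster --input cohort.csv --schema cohort.schema.yaml \
    --k 5 --init forgy --seed 1 --space feature --restarts 10 --out clusters.csv
```

prints

```
wrote 300 patients to cohort.csv
k=5 forgy clusters (sizes 0:63, 1:53, 2:58, 3:63, 4:63), inertia 68.0830 -> clusters.csv
```

The simulated cohort has five diagnosis stages (SMI, MCI, VCI, SVD, AD)
whose mean item scores step down from 2.8 to 0.4 on the 0–3 Likert scale,
so the five clusters line up with the stages almost perfectly: this draw
contains 63 AD / 57 MCI / 63 SMI / 62 SVD / 54 VCI patients, and the
cross-tabulation of cluster against stage is diagonal up to relabelling
with 2 of 300 patients misassigned.  `clusters.csv.summary.json` records
each cluster's mean/median item scores and stage composition.  The same
flow in Python:

```python
import stratavis as sv

table   = sv.generate_cohort(sv.default_separated_config(300, seed=7))
specs   = sv.select_variables(table, [f"item_{i:02d}" for i in range(1, 16)], "anchors")
anchors = sv.make_anchors(specs)          # 15-gon
u       = sv.normalize(table, specs)      # 300 x 15 in [0, 1]
points  = sv.layout_table(u, anchors, mode="radvis3d")
model   = sv.kmeans([[p.x, p.y, p.z] for p in points], k=5, init="forgy", seed=1)
```

`stratavis run --simulate-n 300 --seed 7 --k 5 --render --out-dir out/`
writes the whole bundle — cohort, layout, clusters, summaries, HTML
renders and a JSON manifest — and is byte-reproducible for a fixed seed.

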