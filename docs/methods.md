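# Methods

## The layout model

The package projects a patient × variable table into radial-coordinate
(RadVis) layouts.  Every numeric variable *i* carries declared bounds
`[v_min(i), v_max(i)]` and two position bounds `[p_min(i), p_max(i)]`
(defaults 0 and 1).  The per-variable placement is the linear map

    Np(i) = (N(i) − Vmin(i)) / (Vmax(i) − Vmin(i)) · (Pmax(i) − Pmin(i)) + Pmin(i),

which with the default position bounds reduces to min–max normalisation
`u_i ∈ [0, 1]`.  A value at the variable's minimum therefore contributes
`p_min` and at the maximum `p_max`, affinely in between.

**Combination rule (a design choice).**  The per-variable rule says where
one variable would put the record; it does not by itself say how the *n*
per-variable placements combine into one point.  This package combines
them as the classic RadVis weighted barycenter over the anchor positions,

    (x, y) = Σᵢ wᵢ aᵢ / Σᵢ wᵢ,   wᵢ = Np(i) on [0, 1],

and, for the cylindrical 3D variant, sets the height to the mean
normalised score, `z = H · mean(u)`.  This single rule realises all three
behaviours the layout is meant to have: a record near a variable's
maximum is pulled toward that anchor; a record at the minimum on every
variable receives no horizontal pull and sits at the bottom-centre
`(0, 0, 0)`; and the height orders records by their average value.  It
also gives the cylinder its purpose: two records with proportional weight
vectors coincide horizontally (barycentric weights are scale-invariant)
but separate in `z` by exactly the proportionality factor, so profiles a
flat 2D RadVis would overlap remain distinguishable.  Alternative force
laws (e.g. weighting by squared value) would preserve the boundary
behaviours but not the scale-invariance; we document the barycentric
reading as the package's interpretation and test its consequences
(convex-hull containment, permutation equivariance, z-monotonicity)
rather than treat it as the only possible one.

Anchors sit at equidistant angles, first anchor at 12 o'clock, clockwise
in input column order; defaults radius 1 and height 1.  These are
cosmetic conventions.  Degenerate cases are defined, not rejected: a
constant variable (v_min = v_max) contributes the neutral weight 0.5
everywhere (with a warning) so an uninformative column cannot drag every
record to the bottom-centre; an all-zero weight vector is placed exactly
at the centre; values outside the declared bounds are clamped with a
warning.  Rows with a missing value in any selected variable are excluded
from layouts and clustering and reported — the upstream registries this
emulates give no guidance on missingness, so exclusion plus reporting is
the conservative default.

## Similarity graph

The node-link view links patients whose normalised profiles are similar:
cosine, Pearson, or Spearman (Pearson on average-tied ranks), with an
edge for every pair at or above a threshold in [0, 1].  Negative
correlations are left raw; because the threshold range is non-negative
they simply never form edges.  Zero vectors have cosine similarity 0 by
convention (including to themselves); constant rows correlate 0 with
everything and 1 with themselves.  Placement uses the seeded
Fruchterman–Reingold spring layout from networkx with a fixed iteration
count — the variant is unspecified upstream, and force-directed placement
is only required to be deterministic under a fixed seed and to place
connected nodes closer than unconnected ones, both of which are tested.

## k-means segmentation

Lloyd iterations with Euclidean distance: assign each point to the
nearest centre (ties to the lowest index, for determinism), recompute
centres as member means, stop when no centre moves by more than 1e−9 or
after 300 sweeps.  The within-cluster sum of squares is non-increasing
across iterations and is asserted on every test run.  An empty cluster is
repaired by reseeding its centre at the point farthest from the dead
centre — deterministic, and keeps k clusters.

Initialisation: **Forgy** draws k distinct data points by seeded sampling
without replacement (the often-repeated claim that Forgy is inherently
deterministic is only true once the selection is fixed; here the seed
fixes it, making whole runs bit-identical).  **Random** draws k pivots
uniformly inside the data volume — uniformly inside the r × H cylinder
when clustering layout points (area-uniform radius `r√U`), else inside
the bounding box.

**Clustering space.**  Whether segmentation should run on the 3D layout
coordinates or on the full normalised feature vectors is genuinely
ambiguous — "nearby in the cylinder" and "similar test profile" differ
once 15 dimensions are projected to 3.  Both are provided
(`space="layout3d"` is the default, matching pivots placed "inside" the
layout; `space="feature"` clusters the 15-dimensional profiles).  Stage
*recovery* is measured in feature space: in layout space the five stage
bands are so well separated along z that Lloyd centres cannot migrate
between them, and a bad initial draw sticks in a merge/split local
optimum (best-of-5 seeds plateaus near ARI 0.77 at n = 500), whereas
feature space recovers the stages at ARI ≈ 0.94–0.99.

**Restart policy.**  A single Forgy draw rarely covers all five stages
(the chance that 5 uniform picks hit 5 equal groups once each is ≈ 4%),
and on well-separated data Lloyd cannot repair a bad draw.  The
recommended protocol, used by the acceptance script, is the module's
`restarts` option: 10 Forgy restarts with derived seeds, keeping the run
with the lowest objective — an unsupervised model choice that needs no
reference labels.  Across 40 generator seeds at n = 500 this never
dropped below ARI 0.94.  On arbitrary unstructured point sets, best-of-10
restarts does *not* always attain the globally optimal partition (there
exist 9-point instances where every Forgy start converges ~2% short of
the enumerated optimum); the tests therefore assert the universal lower
bound on random instances and exact optimality on instances with real
cluster structure.

## Multifilter

Each selected variable is a parallel axis: numeric axes span
`[v_min, v_max]`, categorical axes place their levels at equally spaced
positions in declared order.  A filter is a union of **closed** intervals
per numeric axis (endpoints inclusive, matching drag-selection intuition)
or a set of levels per categorical axis; axes combine conjunctively, and
an axis with no selection is unconstrained.  Overlapping intervals behave
as their union.  The implementation is vectorised but specified by a
brute-force per-row scan, against which it is property-tested on 1000
randomised tables.

## Synthetic cohort generator

The generator emulates the schema of a multi-site dementia registry:
per-patient diagnosis stage on the five-step ladder SMI → MCI → VCI →
SVD → AD, gender, age, years of education and a derived academic-
background band, and the 15 S-IADL daily-function items.  Items are
encoded 0–3 (higher = better function) so the scale minimum coincides
with score 0 and the normalised bottom of the cylinder; item scores are
drawn as `round(clip(Normal(mean[stage, item], sd), 0, 3))` — a
deliberately simple model whose two knobs (per-stage means, shared sd)
directly control stage separation.  All draws come from a single numpy
PCG64 generator, so a seed fixes the cohort bit-for-bit across platforms.

The default "separated" configuration uses stage mean 2.8 / 2.2 / 1.6 /
1.0 / 0.4 on every item with sd 0.25 and equal stage proportions: stages
one noise-sd apart after rounding, far enough for k-means to recover them
and close enough that single bad initialisations still fail visibly.
Age (uniform 55–90), education (uniform 0–18 years) and gender (60/40)
are plausible for a dementia registry but carry no signal by design.

What the generator does **not** emulate: item–item correlation structure
within a stage (real daily-function items correlate through common
physical/cognitive factors), age–stage or education–stage dependence,
missing entries, and within-stage heterogeneity of profiles (every item
shares one stage mean).  Passing recovery tests on this cohort therefore
shows the machinery is correct under its stated conditions, not that real
cohorts separate this cleanly — on real data the stages overlap heavily
and k segments of the layout need not match diagnosis at all.  The
negative composite display scores some questionnaire UIs print (−1 …
−17) have no defined mapping from the 15 items and are not modelled.

## Pipeline and rendering

The batch pipeline chains simulate/load → multifilter → layout → k-means
→ export, writing CSVs, a cluster summary JSON and a manifest that
records every parameter, seed, warning and output; identical config and
seed give byte-identical CSVs (coordinates are serialised at 12
significant digits).  A stage failure names the stage and removes partial
outputs.  Renders (3D scatter with labelled anchor edges, parallel
coordinates) are matplotlib figures exported as PNG or as HTML embedding
the SVG, and are decorative: a render failure downgrades to a warning and
never touches the data outputs.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so each check
exercises the contract it names: cohorts of 100–500 patients (5000 for
the multinomial check of stage draws), 1000-case randomised oracles for
the placement rule, the 2D layout and the multifilter, 500 proportional
pairs for overlap resolution, and exhaustive partition enumeration on 9-
or 10-point instances (≤ 3^10 partitions).  The full suite completes in
well under a minute.
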