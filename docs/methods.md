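# Methods

This note records the models, estimators, numerical conventions and
design choices behind `octava`, and what the synthetic-data tests do and
do not establish about clinical data.

## Imaging geometry

All operations assume a square en-face scan of a known physical field of
view (default 3 mm), so the scale is `fov_mm·1000/width_px` µm/px
(5.86 µm/px at 512 px). Coordinates are pixel-centered, origin top-left,
x right / y down; every physical output is in µm or mm². Region masks
follow the ETDRS convention scaled to a 3 mm scan: foveal circle of 1 mm
diameter, parafoveal annulus 1–3 mm, both image-centered; the FAZ search
region is a central 1.5 mm disk. All three diameters are configurable.

## Vessel enhancement and binarization

The enhancement is a 2-D oriented-flux filter. With v = ∇(G_σ∗I),
σ = 1 px, the flux matrix at scale r is

    Q_ij(x, r) = (1/N) Σ_k v_i(x + h_k) n_j(h_k),

where h_k runs over the pixel annulus |‖h‖ − r| < ½ and n = h/‖h‖. The
annulus kernels are applied by FFT correlation on a reflect-padded image
(pad ≥ r_max + 3σ), so a macula-centered scan has no edge artifacts and
a constant image yields an exactly zero response. Per scale the
vesselness is max(0, −λ_min(Q)); the response is the maximum over an
ascending scale set (default 1.5–10 px ≈ 9–60 µm radius), with the
argmax scale recorded per pixel. On synthetic bars the response is
rotation-equivariant to ~1e-15 and peaks at the scale matching the bar
half-width, verified against a dense-sampling flux integral.

Thresholding operates by default on the blend
`(1−w)·image + w·response/max(response)` with w = 0.5. The raw scale-max
response smears over the filter scale, and no global threshold on it
localizes boundaries better than Dice ≈ 0.85 on noise-free phantoms; the
blend keeps the image's sharp boundary while the vesselness term bridges
speckle dropout (at speckle variance 0.4 the blend reaches Dice ≈ 0.95
where image-only thresholding gives ≈ 0.88). Threshold choices: Otsu
(default, parameter-free), fixed, or quantile; the value used is logged.
Mask cleaning removes components below 30 px and fills holes below
20 px; it is idempotent and stands in for the manual mask editing of
clinical pipelines. Whether the study pipeline thresholded globally or
locally is not documented anywhere we could rely on; the global choice
plus the blend weight are exposed in `SegmentationConfig`.

## Skeleton, radii, graph

Thinning uses topology-preserving skeletonization; per-point radius is
the Euclidean distance transform at the skeleton minus half a pixel,
floored at half a pixel. The half-pixel term corrects the EDT's
center-to-center convention — the physical boundary lies beyond the last
foreground pixel center — and, paired with the rasterizer's 50 %-coverage
painting (a pixel is vessel when its center is within r of the
centerline), keeps tube-radius error within 0.5 px for widths 4–20 px.

Graph extraction uses 8-connectivity. Skeleton pixels with ≠ 2 neighbors
are node pixels; adjacent node pixels collapse to a single node at their
centroid (thinning produces junction clusters); maximal degree-2 chains
become segments carrying ordered points, radii, arc and chord lengths.
Closed rings with no node get an arbitrary anchor (lexicographically
first pixel) and appear as chord-0 self-loops, excluded from tortuosity.
Arc length is measured on a 5-px moving-average-smoothed copy of the
chain (endpoints pinned): the raw 8-connected step sum overestimates
smooth curves by up to ~8 % (staircase bias), while the smoothed measure
is exact on straight lines and within ~1 % on circles. Chord is the
endpoint distance; arc ≥ chord is enforced as an invariant.

Spur pruning removes terminal segments shorter than 10 µm (default;
below capillary diameter) whose far end is a junction, then dissolves
degree-2 nodes, iterating to a fixed point — hence idempotent. Crossing
artifacts (degree ≥ 4) stay in the graph but are excluded from
bifurcation-based metrics, which use degree-3 nodes only.

"Caliber" is read as diameter (2× radius); the large/small split applies
the 20 µm cut to segment mean caliber, large being strictly greater.
The split partitions segments exactly and conserves total arc length to
machine precision.

## Bifurcation metrics

At each degree-3 node the three incident segments get a local caliber
measured over the 25 % of points nearest the node, after skipping a
junction zone of one local radius (+2 px) where the merging vessels
contaminate each other. When the source mask is available the caliber in
that window is estimated as attributed vessel area per unit centerline
length (every mask pixel is assigned to its nearest skeleton point);
this is sub-pixel accurate, whereas windowed EDT means quantize to pixel
steps and visibly bias cube-law statistics on vessels thinner than
~3 px. Without a mask the EDT-window mean is used. The parent is the
largest-caliber incident segment, ties broken by longer arc then lower
segment id; the reported metrics are then

- KS score: two-sample Kolmogorov–Smirnov statistic between {r_p³} and
  {r_1³ + r_2³} (scipy, asymptotic mode; the statistic is exact). Cube
  values agreeing to 9 significant digits are snapped to ties first,
  because the generator's cube-sum identity holds only to machine
  precision and a 1-ulp difference would otherwise turn an exactly-
  Murray tree's score from 0 into 1/n. A minimum of 5 bifurcations is
  required, otherwise the metric is an explicit missing value.
- Symmetry ratio: mean of (smaller daughter caliber)/(larger daughter
  caliber), fixed to (0, 1] so the metric is scale-free; the raw
  branch₂/branch₁ convention leaves ordering undefined.

## FAZ detection

Background (¬mask, 4-connected — complementary to the 8-connected
foreground) is labeled; among components intersecting the central search
disk the largest by pixel area is the FAZ, converted by scale². The
component may extend beyond the search region. The rule presumes a
perfused surround: on a sparse mask the outer background wins, which is
why the scene generator closes the perifovea (below). For an all-false
mask the FAZ is the whole image's background component.

## Synthetic data

**Trees.** Binary recursive bifurcation in physical µm coordinates
(origin at field center), so one tree rasterizes consistently at any
resolution. Radii follow r_p^k = r_1^k + r_2^k exactly at exponent k
(default 3.0) with daughter ratio r_2/r_1 = symmetry (default 0.8,
jittered ±0.15 per bifurcation so radii are continuous rather than a
degenerate ladder). Tortuosity is a one-period sinusoidal displacement
(amplitude = 0.03 of branch length) with quadrature-exact arc length.
Branch angles (±32° at the root) shrink by 0.75 per level so each
subtree stays in its own sector; a deterministic collision check re-draws
directions (and eventually shortens branches) so branches never cross,
and raises `GeometryError` when the canvas or the FAZ exclusion disk
(default 300 µm radius; every branch keeps clearance radius + its own
caliber) cannot be respected. Default: 5 levels, root radius 20 µm
(caliber 40 µm, tapering to ~16 µm — the caliber range of a 3 mm
superficial-complex scan), root length 300 µm decaying by 0.75.

**Scenes.** Six trees radiate from just outside the FAZ, plus a thin
capillary ring sealing the FAZ at exactly its nominal radius and two
circular "arcade" vessels (0.65 and 1.0 mm) that close the perifoveal
region into cells smaller than the FAZ — a coarse stand-in for the
capillary mesh that makes the largest-pocket FAZ rule applicable.

**Rendering.** Clean signal (vessel 0.85 / background 0.15) ×
multiplicative gamma speckle (mean 1, configured relative variance) →
Gaussian blur → clip to [0, 1]. The source scans' noise model is not
documented; these parameters are ours and config-exposed.

**Cohorts.** Long-format table, two eyes × two visits per participant.
Phenotype and covariate marginals are plausible for a middle-aged OSA
cohort (age 50 ± 9, BMI 35 ± 6, pAHI 54 ± 25 clipped to ≥ 15 so only
moderate/severe cases occur, CPAP usage a 55/45 mixture of N(6.7, 0.9)
and N(3.0, 1.3) so both adherence classes are populated); they are
documented defaults, not fitted values. Configured outcomes are built as
outcome = Σ β·z(phenotype) + b + ε on the latent (pre-clipping) scale,
with the residual split so `within_participant_corr` is the fellow-eye
ICC; the generator calibrates to ±0.02 of the configured standardized β
over replicate cohorts. Follow-up changes are γ·z(usage) + clustered
noise at half the baseline SD.

## Statistics

GEE: Gaussian family, identity link, exchangeable working correlation
(fellow eyes are exchangeable; an independence run is available as a
sensitivity option), robust sandwich SEs, cluster = participant.
Outcome and continuous predictors are z-scored on the analysis sample
after listwise deletion for that model; binary covariates stay 0/1, so
group coefficients remain interpretable while continuous coefficients
are standardized. Each result carries n_eyes, n_participants and the
exclusion count (n_eyes + excluded = input rows). A minimum of 10
clusters is enforced. Non-finite estimates or robust SEs raise rather
than emitting silent NaNs.

Group comparisons: change = follow-up − baseline per eye; t-test when
both groups pass Shapiro–Wilk at α = 0.05 (a zero-variance group counts
as non-normal), else Mann-Whitney U; the test used is reported, and
degenerate cells (identical constant values, n < 3) come back as
explicit missing results. Adherence has two definitions in circulation —
mean usage ≥ 4 hr/night, and ≥ 4 hr on ≥ 80 % of nights — both are
emitted and the analysis selects one by config (mean is the default for
longitudinal grouping). OSA severity bins: mild 5–14, moderate 15–30
(closed upper bound), severe > 30 events/hr; values under 5 are flagged
subthreshold. Ordinal brain scores are modeled as continuous. No
multiple-comparison correction is applied anywhere, by design.

## Problem sizes used by tests and the acceptance script

Rasterized fixtures run at 512 px / 3 mm. Murray-deviation checks use
6-level trees (31 bifurcations) for the rasterized score — KS on a
15-bifurcation tree has granularity 1/15, too coarse near small
deviations — and 5-level trees for branching-count exactness, whose
calibers all stay above the ~2 px resolution floor. GEE calibration uses
200 replicate cohorts of 500 participants for both effect recovery and
null CI coverage. Infeasible tree seeds (GeometryError) are skipped in
order until the requested replicate count is reached.

## What passing tests do and do not show

The generators provide exact ground truth, so the tests establish that
the measurement chain is correct at the stated resolutions and that the
statistical layer recovers known effects under clustering. They do not
establish performance on clinical OCT-A: real scans add projection and
motion artifacts, capillary-scale vasculature below the resolution
floor, intensity inhomogeneity, and segmentation ambiguity that the
speckle model does not emulate. Radii below ~1.5 px remain unreliable at
512 px regardless of estimator; small-vessel radius and KS metrics on
clinical data inherit that limit.
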