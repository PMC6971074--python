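# Methods

This note records the models, defaults and design choices behind
`plexcell`, in the spirit of a pipeline methods supplement. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and data conventions

Images are `(channel, y, x)` arrays, 0-based, y-down; physical
coordinates are `index × pixel_size_um`. Label masks use 0 for
background and consecutive labels 1..K, each one 8-connected component.
Centroids are unweighted label centroids. The single-cell CSV is the
hub format: `cell_id, case_id, x_um, y_um, area_um2`, one mean-intensity
column per marker in panel order, with `cluster_id` / `cell_type`
appended downstream. CSVs are comma-separated UTF-8 with `.` decimals
and ≥ 6 significant digits, so write∘read is an identity to 1e-6
relative tolerance.

## Registration and autofluorescence

Staining rounds of one physical section differ by a rigid stage offset;
rotation and deformation are assumed negligible. Each round's DAPI is
matched to round 1 by phase cross-correlation at integer-pixel
resolution, and the inverse translation (zero-filled) is applied to all
channels of that round. The aligned stack keeps round-1 DAPI plus every
non-DAPI channel. On noise-free synthetic DAPI any integer shift up to
a quarter of the field is recovered exactly; at read-noise levels up to
~20% of signal, recovery is within ±1 px (both are tested).

Autofluorescence is modelled as one blank channel recorded without
primary antibody: each non-DAPI channel becomes
`max(0, channel − scale × AF)` with a global `scale` (default 1.0), and
the blank channel is dropped. No per-pixel spectral unmixing is
attempted. Subtraction is pixelwise monotone in `scale` and never
produces negative intensities.

## Dual-mask segmentation

Both masks share one recipe: Gaussian smoothing
(`smoothing_sigma_um = 1.0`), thresholding (Otsu by default, fixed value
available), 8-connected labeling, and removal of components below
`min_area_um2 = 12` (a conservative lower bound for a leukocyte
cross-section). The *nuclear* mask segments DAPI. The *targeted* mask
first rescales each leukocyte lineage channel (CD43/CD45/CD68/CD163,
intersected with the panel) by its own 99.9th percentile so that no
single bright stain dominates, combines them pixelwise (max by default;
sum available), and afterwards applies the digital fragment exclusion:
components with area below the floor or solidity below
`min_solidity = 0.5` are dropped. Solidity (area over convex-hull area)
is the operational criterion for "small dendritic-shaped cytoplasm
fragments": a thin star-shaped fragment scores ~0.2, a compact cell
~1.0. Exclusion is idempotent.

The two masks exist because chromatin-poor tissue macrophages do not
reach DAPI threshold contrast. The per-case yield ratio
(nuclear count / targeted count) quantifies this; on immune-only
synthetic tissue with 30% dim-DAPI macrophages it lands at ~0.7, and it
is strictly below 1 whenever dim phenotypes are present. On mixed
tumor/immune fields the nuclear count includes tumor nuclei and the
ratio can exceed 1 — the comparison is meaningful for the inflammatory
compartment, which is why phenotyping runs on the targeted mask.

Touching cells are not split (no watershed): the synthetic generator
guarantees non-overlap, and real pipelines should substitute their own
instance segmentation if cells touch. This is a known limitation.

## Quantification

Per-cell features are the mean intensity of every channel over the
label's pixels, the centroid and the pixel-count area. Means (not
medians) are used, with no per-cell background correction — background
is handled globally by the autofluorescence step. The masked intensity
mass is conserved: Σ cells (area_px × mean) equals the channel total
over the mask to 1e-6 relative.

## Normalization and phenoclustering

Each marker is clipped above its 99th percentile (robustness to
acquisition outliers), optionally arcsinh-transformed
(`x ↦ asinh(x / cofactor)`), and z-scored to mean 0, sd 1 (population
sd; constant columns become zeros with a warning). The positivity
threshold downstream is **0.5 normalized units**, per-marker
overridable. This works when each marker is bimodal over the analyzed
cells — true on real tissue (tumor plus infiltrate) and in the default
generator, which always includes a marker-negative tumor compartment.

Clustering is Phenograph-style: exact Euclidean kNN (k = 30, the usual
cytometry default), edges re-weighted by the Jaccard overlap of the two
endpoints' k-neighbor sets, then Louvain modularity optimization with a
fixed seed (networkx implementation; deterministic given the seed;
clusters relabeled 1..C by decreasing size). The one deliberate
departure from common defaults is the **resolution, 0.1**: at unit
resolution modularity shatters large homogeneous phenogroups into
arbitrary sub-communities (on two well-separated Gaussian blobs it
returns seven clusters), whereas the rule engine consumes lineage-level
groups. At 0.1 the algorithm recovers well-separated mixtures exactly
(tested: ARI ≥ 0.9, in practice ≈ 1.0, on the default ten-component
mixture at n = 5000 over three seeds). Raise the resolution to hunt
finer functional sub-states; the heatmap-style cluster-profile CSV is
the QC surface for that decision.

Cluster sizes matter: groups much smaller than k cannot form their own
kNN community and merge into neighbors. With the default abundances the
rarest type is 1% of all cells, so n ≳ 5000 keeps every type
recoverable; the README example at n = 1200 deliberately shows the
merging behavior.

## Rule-based classification

A cluster profile carries, per marker, the mean normalized expression
and the fraction of positive cells. A rule matches when every
`required_positive` marker is positive in **≥ 1/3** of the cluster's
cells and every `required_negative` marker in < 1/3; among matches the
highest priority wins, a priority tie raises an explicit error, and no
match yields `Unassigned` (tumor/stroma land there and are excluded
from composition percentages). The one-third fraction is fixed by the
published criterion; the intensity threshold is configuration.

The shipped nine-type rule table is a reconstruction from the published
phenotype descriptions, shipped as data (YAML) so users can replace it:
T helper (CD45+CD3+CD4+CD8−), cytotoxic T (CD45+CD3+CD8+CD4−), NK
(CD45+CD3−GranzymeB+Granulysin+), B (CD45+CD20+CD3−), TAM
(CD16+CD68+CD163+), histiocyte (CD163+CD16−), phagocyte
(CD68+CD163−CD16−), inflammatory monocyte (LYZ+VISTA+CD68−CD163−) and
undefined monocyte/macrophage (CD45+ with the above failing). The
priority ordering resolves the deliberate overlaps (e.g. every TAM
profile also satisfies the undefined-monomac rule).

The default synthetic panel is 16 markers — DAPI, CD45, CD3, CD4, CD8,
FOXP3, TCF7, PD1, CD20, CD16, CD68, CD163, LYZ, VISTA, GranzymeB,
Granulysin — the smallest set on which every shipped rule is
exercisable (NK and B gating alone require CD45, CD3, GranzymeB,
Granulysin and CD20).

## T-cell exhaustion state

Per case: lymphocyte density = (CD4 T + CD8 T + NK) / analyzed area.
Below `density_min = 60 /mm²` the case is *Deserted*. Otherwise the
PD1- and TCF7-positive fractions among CD8 T cells are compared to
`θ_hi = θ_lo = 0.33` (the same one-third criterion): PD1 ≥ θ and
TCF7 < θ ⇒ *acute* exhaustion; TCF7 ≥ θ and PD1 < θ ⇒ *chronic*;
both ≥ θ ⇒ *mixed*. Two edge cases are resolved by design so the rule
is a total partition: a dense infiltrate with **no CD8 cluster** and a
dense infiltrate with **both fractions low** are both called
*Deserted* — in either case there is no exhaustion phenotype to
classify, which operationally matches a "passer-by" infiltrate. The
published calls also reflect qualitative review; this rule is strictly
numeric.

## Neighborhood analysis

Neighbors are defined on centroid distance: a short range (distance ≤
100 µm, the submicroscopic scale) and a long annulus (100–250 µm, the
microscopic scale). For each ordered pair (A, B) the statistic is the
mean count of B neighbors per A cell. The null shuffles type labels
over fixed positions (`n_permutations = 1000` by default; calibration
runs use 199, which already resolves p at 0.005 granularity);
`p_enrich = (1 + #{null ≥ obs}) / (P + 1)` and symmetrically for
avoidance — the add-one convention keeps p ≥ 1/(P+1). Ties count as
extreme, which together with the integer-valued statistic makes the
test mildly conservative: over 100 CSR replicates the measured
rejection rate at nominal 0.05 stays ≤ 0.07 (typically 0.01–0.05).
Power is retained where it matters: a 10-µm co-ring pattern embedded in
background cells is detected at short range in ≥ 90% of replicates, and
hard-core avoidance at 120 µm is flagged as significant avoidance.
Pairs involving an absent type are reported as NA. No multiple-testing
correction is applied across pairs by default (apply Benjamini–Hochberg
downstream if needed). Note that a short-scale association is only
testable against the 100 µm radius if label-permutable background cells
are present; with two pure clustered types the statistic saturates.

## Cohort statistics

Core geometry is analytic: `n_cores × π (d/2)²`; two 2-mm cores give
6.28 mm² (≈ 40 HPF). Ages use the sample (n−1) standard deviation —
validated in the tests against the printed cohort values, which the
population sd does not reproduce. Percentages are rounded to integers
and means to one decimal **only** in report strings; raw precision is
kept everywhere else. TMN is tallied by leading stage token (pT1/pT2/
pT3; NA excluded); FIGO stages IIIB and IIIC are pooled as "IIIB/C" to
match the cohort's reporting buckets. The packaged 21-case table
transcribes the published clinicopathologic data; its semiquantitative
IHC grades (±/+/++/+++ with "het"/"weak" qualifiers) are carried
verbatim as strings and never computed on. One transcription note: the
table contains a 71-year-old patient while the cohort text prints the
range 34–69; the mean 51.2 and sd 11.8 only reproduce with 71, so the
printed range is treated as a typo and `age_max` is 71.

## What the generator does and does not emulate

Emulated: per-phenotype Gaussian marker expression truncated at zero
(sd 1.5 around positive mean 8.0, sd 0.3 around negative mean 0.5,
"spotty" 1.5 ± 0.8 — arbitrary units); dim-DAPI macrophages
(`dapi_intensity_factor` 0.2–0.3 for TAM/histiocyte/phagocyte); a
marker-negative tumor compartment (50% by default); hard-disk cell
placement (radius 3.5 µm lymphoid, 4.5 µm myeloid, 5 µm tumor; ≥ 4 µm
edge gap) under CSR, parent-cluster or pairwise-avoidance spatial
models; flat autofluorescence (level 1.0) plus zero-truncated Gaussian
read noise (sd 0.5); integer stage shifts per round; default tissue
cellularity 1500 cells/mm². Default immune composition mirrors a
macrophage-dominated sarcoma infiltrate (TAM 38%, histiocytes 20%,
lymphoid ~24% of the infiltrate); all numbers are repo-defined
synthetic choices, not measurements.

Not emulated: optics (PSF, illumination falloff), staining-cycle
antigen degradation, nuclear texture, touching/overlapping cells,
log-normal expression tails, within-type marker bimodality (a type's
cells share one mean, so e.g. a partially TCF7+ CD8 population must be
modelled as two phenotypes), and deformable tissue motion. Passing
tests therefore certify the analysis logic under clean geometry, not
performance on real microscopy.

Because expression noise is real detection physics, a lineage-positive
cell can legitimately draw an intensity below segmentation threshold
(~0.4% of single-marker cells); the exact-count recovery checks
therefore use zero expression variance — "bright" is unambiguous —
while keeping read noise, autofluorescence and round shifts active.
Yield-ratio and clustering checks use the full default noise.

## Problem sizes used by the test and acceptance runs

Chosen to keep the full suite under a minute on one CPU while leaving
every statistical check well-powered: segmentation/registration
recovery at n = 500 cells × 3 seeds; yield ratios at n = 300 × 3;
clustering ARI at n = 5000 × 3 seeds; composition recovery at
n = 10000 (multinomial SE ≤ 0.5 pp per type against the ±2 pp band);
neighborhood calibration at 100 CSR replicates × 199 permutations and
power at 20 replicates.
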