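# Methods

This note documents the models, scoring rules and numerical choices behind
`dcistme`, and what the synthetic generators do and do not emulate.

## Setting

Ductal carcinoma in situ (DCIS) is a neoplastic epithelial proliferation
confined within the mammary duct by the myoepithelial layer. The package
analyses the immune microenvironment of DCIS from *per-cell tables* — one
row per segmented cell with coordinates (μm), marker intensities and/or
boolean phenotype flags, a duct/stroma compartment label and a
normal/ADH/DCIS region assignment — together with per-region areas and
per-sample clinical records. Everything upstream (staining, imaging,
spectral unmixing, segmentation, region classification) is out of scope;
the synthetic generator stands in for those outputs.

Coordinates are micrometres with arbitrary origin, y increasing downward
(image convention). All spatial statistics are invariant to origin and
rigid motion, so the convention carries no analytic weight.

## Spatial statistics

**Morisita–Horn colocalization.** The field is tessellated into
non-overlapping pointy-top hexagons with 100 μm sides, anchored at the
bounding-box minimum of the two cell types being compared. With per-hex
counts a_i, b_i and totals A, B,

    MH = 2 Σ a_i b_i / [ (Σa_i²/A² + Σb_i²/B²) · A · B ]

ranges from 0 (the types never share a hexagon) to 1 (proportional counts
in every hexagon). MH is invariant to hexagon relabeling but not to the
tessellation anchor; the anchor is therefore deterministic (bounding-box
minimum), never random. Empty hexagons contribute nothing to any sum, so
tessellating the bounding box rather than the tissue outline is
immaterial.

**Cross nearest-neighbor distribution and SPS.** For reference type a and
target type b, G(r) is the empirical CDF of each a-cell's distance to its
nearest *distinct* b-cell (a cell positive for both types never counts as
its own neighbor; a distinct cell at the same coordinates is a legal
neighbor at distance 0). The Spatial Proximity Score is the exact area
under the G step function on [0, 20] μm — computed in closed form as
Σ max(0, 20 − d_i)/n, not on a grid, so there is no discretization
tolerance. SPS is directional: `Tum_T.SPS` averages over tumor cells
(reference) looking for T cells (target). The 20 μm radius is roughly two
lymphocyte diameters. No edge correction is applied by default: at
r ≤ 20 μm on mm-scale fields the boundary bias is negligible and the raw
estimator is exactly reproducible; `border_exclude` enables minus-sampling
if wanted.

**Distance from epithelium.** Mean distance from marker-positive cells to
the nearest αSMA+p63+ myoepithelial cell. For αSMA itself the numerator
population is αSMA+p63− so the layer is not measured against itself.

**Myoepithelial continuity.** Within each DCIS region holding ≥ 2
myoepithelial cells, nearest-neighbor distances among those cells are
computed (never across region boundaries); the per-sample raw value is the
cell-weighted mean over all contributing regions. Reverse scoring maps raw
distances to scores by `score = (cohort max + 1 μm) − raw`, so high score
= tightly spaced = intact layer. **The score is cohort-relative**: it
depends on the cohort maximum and is not comparable across cohorts; the
raw distances are what to archive.

**QC rule.** Any spatial feature computed from fewer than 5 reference or
5 target cells is reported with a QC flag, never suppressed (the
threshold is configurable). Undefined quantities (empty sets, zero
denominators) are NaN plus a `QCWarning`, not exceptions, so one bad
sample cannot halt a cohort run.

## Immune scoring

Gating is by explicit per-marker intensity thresholds (`intensity >
cutoff`, strict) plus derived boolean expressions evaluated in dependency
order. The original workflow used density-based automated gating whose
parameters are not recoverable; explicit thresholds are deterministic and
auditable. An automatic threshold (KDE valley between the two highest
modes of log intensity) is available but never the default.

* **TIL %** = 100 · |CD3+ ∪ CD20+| / all cells. The union counts
  CD3+CD20+ double positives once, so the fraction cannot exceed 100.
* **TPS** = 100 · PD-L1+ tumor / all tumor.
* **CPS** = 100 · (PD-L1+ tumor + PD-L1+ immune) / all tumor, with
  "immune" the configurable union of CD3+, CD20+, CD68+ (tumor-negative).
  CPS is **not capped** at 100: the defining formula has no cap, and a
  tumor-sparse, immune-rich sample can legitimately exceed it (clinical
  assays that cap are making a separate reporting choice). CPS ≥ TPS
  always holds.
* Densities divide population counts within a region class by that
  class's summed area in mm²; ratios are count ratios with NaN + QC flag
  on zero denominators.

## Synthetic tissue and cohorts

`simulate_tissue` draws non-overlapping circular ducts in a rectangular
field; each duct carries (i) a myoepithelial ring of regularly spaced
αSMA+p63+ cells (spacing `myoep_spacing`, default 15 μm) whose positions
are *independently vacated* with probability `gap_fraction`, and (ii)
pancytokeratin+ tumor cells as homogeneous Poisson inside the disk.
Vacancies are Bernoulli rather than one contiguous arc because scattered
vacancies lengthen nearest-neighbor distances monotonically in the rate —
the property the continuity score measures — whereas removing a single
contiguous arc leaves every surviving cell's neighbor spacing unchanged.
Immune populations (CD8+/CD8− T, Treg, B, macrophage) are Poisson in the
stroma; when `attraction_sigma` is set each immune cell is displaced
radially toward the nearest duct boundary by |N(0, σ)|, clipped at the
boundary — a tunable, monotone effect on SPS that leaves marginal counts
unchanged. PD-L1/PD-1 positivity is Bernoulli per cell. Optional
log-normal intensity mixtures (positive mode e², negative mode e⁰, log-SD
0.4) support gating tests.

Geometric defaults (duct radius 120 μm, tumor 4000 cells/mm², stromal
immune populations 100–400 cells/mm²) are histologically plausible orders
of magnitude, **not** estimates of any real cohort. The generator does not
simulate spectral bleed-through, segmentation error, image noise, or
irregular duct shapes; passing recovery tests therefore demonstrates that
the estimators respond correctly to planted structure, not that they are
robust to real imaging artifacts.

`simulate_cohort` draws per-sample tissue parameters from uniform ranges,
computes named features (any `<ref>_<target>.SPS`, `<a>_<b>.MHI`, `TIL`,
or continuity) with the *same* downstream code the analysis uses, z-scores
them across the cohort, and draws exponential event times with hazard
`baseline_hazard · exp(Σ coef · z)`, censored at `censor_time`. Default
baseline hazard 0.05/year with 10-year censoring gives ≈ 40% cumulative
recurrence, deliberately event-rich for recovery experiments. Recurrence
events are labelled invasive vs DCIS by an independent coin flip.

`simulate_planted_matrix` plants Gaussian clusters whose means differ by
`separation` noise-SDs on a random half of features, with
missing-completely-at-random cells — the substrate for clustering
recovery.

## Cohort statistics

**Associations.** Features vs binary clinical variables (HR, HER2,
comedonecrosis, palpability, pathologic mass) use the Wilcoxon rank-sum
test — exact p when both groups are ≤ 20 without ties, otherwise the
normal approximation with tie correction; grade uses Kruskal–Wallis. Raw
p values only, by design — no multiple-testing correction in the
association matrices, with 0.05 as the conventional display threshold.
Direction is the sign of the Hodges–Lehmann shift of the positive level.
Levels with < 3 samples flag the result rather than dropping it.

**Survival.** Biomarkers are dichotomized at the median (strictly above =
"high"; ties go low; a degenerate all-low split is flagged) and compared
with the standard two-group log-rank test. The any-recurrence endpoint
counts DCIS and invasive events; the invasive endpoint counts invasive
only, censoring DCIS recurrences at their event time (standard univariate
competing-event censoring; the alternative of excluding those samples is
not used). Combined biomarkers are truth-table indicators such as "low
SPS AND high T-cell infiltrate", with samples missing either marker
excluded.

**Consensus clustering.** Features are median-centered and scaled to unit
SD (n−1 denominator); sample distances are Euclidean on
pairwise-complete features with the R `dist` scaling (squared distance ×
p / n_shared), erroring on pairs with no shared feature and warning below
50% sharing. Each of `iterations` (default 1000; 100 is the documented
scaled-down mode) draws ⌈0.8 n⌉ samples without replacement and clusters
them with Ward linkage (applied to Euclidean distances, i.e. the ward.D2
convention); consensus(i,j) = co-clustering count / co-subsampling count.
Final labels per k come from average-linkage clustering of 1 − consensus.

**Choice of k.** For each k the area under the empirical CDF of
off-diagonal consensus values is computed exactly as 1 − mean(values);
Δ(k) is the relative area increase over k−1 (Δ(k_min) is the area
itself). Selected k = the largest k with Δ(k) above the threshold.
In simulations with balanced well-separated clusters, splitting genuine
consensus blocks yields Δ ≈ 0.4–0.5 while forcing an extra split inside a
homogeneous block yields Δ ≈ 0.05–0.1; the default threshold 0.2 sits
between the regimes. Limitation: the forced-split Δ scales with
cluster-size fractions (a 2-cluster cohort's forced third split can reach
Δ ≈ 0.25), so the full area/Δ table is always returned and the selection
is overridable. **Cluster characterization** is each-cluster-vs-rest
Wilcoxon with Benjamini–Hochberg correction over the full
cluster × feature family; singleton clusters are excluded with a warning.

## Genomics

Copy-number burden: per-segment states are gain if log2 ratio > 0.3, loss
if < −0.3 (strict inequalities — boundary values are neutral); burden
fractions are state lengths over total segmented length, with segment
length end − start + 1 (1-based inclusive SEG convention). The germline
filter keeps variants that are ClinVar Pathogenic/Likely-Pathogenic, at
VAF ≥ 0.15 (inclusive), in a fixed breast-cancer susceptibility gene
list; the two family stubs in the list (FANC, XRCC) match by prefix,
case-insensitively after whitespace stripping.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible.
Recovery experiments use deliberately small fields (≈ 0.1–2 mm², one or
two ducts, a few hundred cells per sample) so full sweeps — 50 seeds per
condition for the monotonicity checks, 120 simulated cohorts of n = 200
for the survival-power and type-I-error checks, 10 seeds of 75 × 12
matrices for clustering — complete in minutes on one core. The
statistical properties verified (oracle equality, Poisson limits,
monotone recovery, nominal error rates) do not depend on field size.

## Known limitations

* The continuity score's cohort-relativity (above) is inherited from its
  definition; cross-cohort comparisons need the raw distances.
* The MH index depends mildly on the tessellation anchor; only the
  anchoring rule, not the value, is canonical.
* Exact Wilcoxon enumeration is only engaged for tie-free groups ≤ 20;
  tied data always use the corrected normal approximation.
* The synthetic outcome model is exponential (constant hazard); it is a
  recovery substrate, not a model of DCIS natural history.
* Automated density-based gating of the original imaging workflow is not
  reproduced; threshold gating is a documented substitute.
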