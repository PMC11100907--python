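# dcistme

Spatial immune-microenvironment analysis for high-risk ductal carcinoma in
situ (DCIS), starting from per-cell multiplex-immunofluorescence coordinate
tables.

Only 15–45% of untreated DCIS lesions ever progress to invasive cancer,
and which ones will is poorly predicted by conventional pathology. One
place to look is the microenvironment: how immune cells position
themselves around tumor-filled ducts, and how intact the myoepithelial
layer that confines the lesion remains. This package implements that
analysis for anyone with segmented cell tables (from QuPath, HALO, inForm
or similar): spatial colocalization and proximity statistics, immune and
checkpoint scores, cohort subtype discovery, and recurrence association —
plus a synthetic-tissue generator so the whole pipeline is testable
without clinical images.

## What it computes

* **Morisita–Horn index (MH)** of two cell types counted over 100 μm
  hexagons: 0 = segregated, 1 = colocalized.
* **Spatial Proximity Score (SPS)**: area under the cross
  nearest-neighbor distribution G(r) for r ∈ [0, 20] μm. Directional —
  `Tum_T.SPS` scores T cells near tumor cells, `T_Tum.SPS` the reverse.
* **Myoepithelial continuity**: cohort-relative reverse scoring of the
  average nearest-neighbor distance among αSMA+/p63+ cells within DCIS
  regions (high = intact layer), plus per-marker distance from the
  epithelium.
* **Immune scores**: TIL % (CD3+ ∪ CD20+ over all cells), PD-L1 TPS and
  CPS, population fractions, densities (cells/mm²) and ratios.
* **Cohort statistics**: Wilcoxon / Kruskal–Wallis association matrices
  against clinical variables (raw p values), median-dichotomized
  Kaplan–Meier log-rank tests against recurrence endpoints, combined
  two-marker groups, and consensus clustering (Ward linkage, 80%
  subsampling, 1000 iterations) with CDF-area selection of the cluster
  number and BH-corrected cluster characterization.
* **Genomics**: copy-number burden from SEG tables (gain: log2 > 0.3,
  loss: log2 < −0.3) and ClinVar-based pathogenic germline-variant
  filtering (VAF ≥ 15%, breast-cancer susceptibility genes).

## Worked example

Simulate one tissue field with immune attraction toward the ducts, then
score it:

```python
import dcistme as d

cfg = d.TissueConfig(n_ducts=2, duct_radius=100.0, field_size=(800.0, 800.0),
                     tumor_intensity=0.003, immune_intensities={"T": 4e-4},
                     attraction_sigma=40.0, gap_fraction=0.2, seed=7)
cells, regions = d.simulate_tissue(cfg)

from dcistme.spatial import sps_pair, mh_pair
print(f"cells: {len(cells)}")
print(f"Tum_T.SPS: {sps_pair(cells, 'Tum', 'T'):.2f}")
print(f"Tum_T.MHI: {mh_pair(cells, 'Tum', 'T'):.3f}")
print(f"TIL: {d.til_fraction(cells):.1f}%")
raw = d.myoep_continuity_raw(cells, regions)
print(f"myoepithelial NN distance: {raw['S0']:.1f} um")
```

prints

```
cells: 473
Tum_T.SPS: 0.76
Tum_T.MHI: 0.268
TIL: 46.5%
myoepithelial NN distance: 16.3 um
```

Read: a tumor cell's G-curve accumulates 0.76 μm of area below 20 μm
(T cells are being pulled toward the ducts, but most tumor cells sit
deeper inside, so the directional score stays modest); tumor and T cells
share hexagons at MH 0.27; 46.5% of all cells are TILs; and the
myoepithelial ring cells sit 16.3 μm apart on average — the 15 μm nominal
spacing lengthened by the 20% vacancy rate. With `attraction_sigma=None`
the same field gives Tum_T.SPS = 0.24: the score responds to the planted
attraction.

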