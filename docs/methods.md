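# Methods

## Scope and data model

The package covers the computational chain of a single-cell SIP experiment:
(i) isotope-scale arithmetic and the label-mixing mass balance; (ii) the
CSIA-FAME methyl-carbon correction and treatment summaries; (iii) NanoSIMS
ion-count stack handling, coccoid-cell segmentation and per-ROI
quantification; (iv) per-cell and community fluxes; (v) the statistical
battery; (vi) a ground-truthed forward simulator. Wet-lab chemistry,
chromatogram processing, vendor raw-file parsing and instrumental dead-time/
QSA corrections are out of scope.

## Isotope arithmetic

Two systems are predefined: ¹³C/¹²C with the VPDB reference ratio 0.0112372
and ¹⁵N/¹⁴N with the atmospheric-N₂ ratio 0.0036765, giving natural
abundances of 1.1112 and 0.3663 atom%. Conversions between ratio, atom
percent and δ are exact inverses over their domains.

**Mixing convention.** The final atom percent of a spiked substrate pool is
the concentration-weighted average of the label and natural pools at the
*molecule* level: a singly-labeled substrate of 99 atom% isotopic purity is
treated as a 99 atom% pool. This is the convention under which the printed
final ratios of the modeled incubation design (33.5 / 86.9 / 28.1 atom% ¹³C
and 74.5 atom% ¹⁵N) are recovered; computed values land within 0.3–0.6 atom%
of the printed ones, the residual reflecting the unstated natural-abundance
convention of the original calculation. A position-averaged mode
(`position_averaged_atom_percent`) that books atom percent over all carbon
positions is provided for users who need whole-molecule atom fractions; it
deliberately diverges from the printed values and is off by default.

## CSIA-FAME correction

The methyl-carbon correction is applied on the δ scale by default,
`δ_FA = (δ_FAME − (1−f)·δ_MeOH)/f` with `f = X/(X+1)` and the methanol
default −37.9 ‰. δ-scale mixing is a linearization of atom-fraction mixing;
it is exact to first order and indistinguishable from the exact form below a
few hundred ‰. For heavily labeled SIP material (thousands of ‰) the exact
atom-fraction variant `correct_fame_delta_exact` is provided; it is off by
default to match the conventional workflow. The nomenclature parser accepts
the CX:Yn-Z dialects plus iso/anteiso, hydroxy (`-OH`), cyclopropane (`cy`)
and dimethyl (`9-10diMe CX`) variants; it is permissive about case and
whitespace but rejects unknown suffixes rather than guessing.

A small-sample caveat for the enrichment summary: with triplicates, a
3-vs-3 rank test's smallest attainable p-value (≈0.055 under the χ²
approximation, 0.1 under exact two-sided permutation) cannot clear a
Holm-adjusted α = 0.05, so pairwise letters can only separate treatments at
≥4–6 replicates. This is a property of rank tests, not of the
implementation; the summary still reports means, spreads and differences at
any replication level.

## NanoSIMS processing

Stacks hold integer counts per (channel, plane, row, col) with the five
detectors ¹²C⁻, ¹³C⁻, ¹²C¹⁴N⁻, ¹²C¹⁵N⁻, ³²S⁻; defaults mirror typical
acquisitions (256×256 raster over a 25×25 μm field, ~28 rescans, 1 ms
dwell). I/O is multi-page TIFF (channel-major plane order, JSON metadata in
the image description) or per-channel plain-text matrices with a sidecar
config. Coordinates are row-major, 0-based, pixel-center.

**Segmentation.** The original workflow drew ROIs manually in vendor
software; here cells are detected automatically from the plane-accumulated
¹²C¹⁴N⁻ image: Otsu threshold (fixed-value override available), hole
filling (sulfur globules appear as zero-emission holes inside cells and
belong to the cell), 4-connected components, then an area window derived
from the expected coccoid diameter (1.67 μm ± 50%) and a circularity floor
4πA/P² ≥ 0.6 that rejects rods and debris. An optional distance-transform
watershed splits touching cells. Imported label masks are accepted, so
manually drawn ROIs remain usable.

**Quantification.** Per-ROI ratios are ratios of summed counts over all
pixels and planes — the maximum-likelihood estimator under Poisson counting
and robust at low per-pixel counts — never means of per-pixel ratios.
Counting error per ratio is σ_R = R·√(1/N_rare + 1/N_abundant). δ values
are reported against the international standards and, when control ratios
are supplied, against the control mean (the default baseline for
enrichment). ROIs with zero abundant-isotope counts are flagged invalid and
excluded downstream. ³²S⁻ is carried through I/O but excluded from
quantification.

## Flux model

`r` below the control baseline (counting noise) is clamped to 0 and
flagged, so population means are not dragged negative; `r > 1` is rejected
as physically inconsistent. Mass conversion assumes one traced atom per
substrate molecule (molar mass 12 or 14), consistent with the
molecule-level mixing convention; a stoichiometric mode (2 C per acetate,
3 C per pyruvate) is available but off by default. `R_ini` defaults to the
mean over all valid control ROIs.

The chamber-flux helper converts an areal benthic-chamber flux to a
per-gram rate as flux·10⁻³/(10⁴·depth·density). Direct arithmetic on the
published chamber parameters (27.3 mgC·m⁻²·h⁻¹, 0.1 cm, 1 g/cm³) gives
2.73×10⁻⁵ gC·g⁻¹·h⁻¹; published rates quoted alongside such parameters can
embed further normalizations, so no equality with any particular published
figure is asserted.

## Statistics

The Van der Waerden statistic uses mid-ranks for ties (the convention is
rarely stated in applied work; mid-ranks keep the statistic well-defined and
monotone-invariant) and is referred to χ²_{k−1}, or to the exact
permutation distribution of the statistic when the total sample size is
small (≤10 by default, exhaustive enumeration). Pairwise post-hoc tests are
pairwise Van der Waerden with Holm adjustment; the compact letter display
uses the insert-absorb algorithm, so two groups share a letter iff their
adjusted p ≥ α. The ANCOVA slope-homogeneity test fits the full-interaction
linear model with a centered covariate and reports the Type-II F-test of
the group×covariate interaction (statsmodels OLS + anova_lm).

## Synthetic data

The simulator renders coccoid cells as discs with pixel-center containment
(exact-area ground truth), places them without overlap by rejection
sampling, and draws per-cell diameters from a Gaussian around 1.67 μm
(sd 0.12 μm, a realistic coccoid spread). Per-cell enrichment fractions come
from configurable distributions; the preset uses a zero-inflated
("bimodal") mixture — 70% active cells around r ≈ 0.06 in the light and
0.015 in the dark, the rest inactive — which reproduces both the
active/inactive heterogeneity seen in natural mats and per-cell fluxes
inside the observed 0–0.002 fgC·cell⁻¹·h⁻¹ range. Enrichment maps to
channel expectations by inverting the enrichment-fraction definition, and
counts are drawn independently Poisson per pixel, plane and channel — the
physics of ion counting; no detector dead time is modeled. The CN⁻ channels
carry the nitrogen signal only (¹³C¹⁴N⁻ is not a recorded channel). Sulfur
globules are zero-yield discs punched into cells across all channels.
Background emits a small fraction (5% default) of the in-cell yield at
natural abundance. Default yields (30 C⁻, 60 CN⁻ counts/pixel/plane) give
~10³–10⁴ accumulated rare-isotope counts per cell, i.e. percent-level ratio
precision.

What the simulator does *not* emulate: 3D mat structure, EPS matrix,
diatoms and other non-target morphotypes, beam drift, QSA. Passing
closure tests therefore demonstrates correctness of the estimators under
Poisson counting and the stated geometry, not robustness to every
instrumental artifact of real acquisitions.

The FAME generator plants per-treatment δ shifts plus Gaussian replicate
noise and emits ester values through the forward esterification mixing, so
recovering the truth requires inverting the methyl-carbon correction.

## Problem sizes and numerical choices

The end-to-end closure check uses 5 fields × 40 cells (200 cells) at
elevated yield (60 C⁻ counts/pixel/plane), where each cell accumulates
≳10⁴ rare-isotope counts; it recovers per-cell r with ~1% median relative
error and the cohort mean flux within a few percent. The Van der Waerden
type-I calibration uses 2000 null replicates of two groups of 20. Pipeline
tests run reduced rasters (96 px) and plane counts, chosen to exercise every
code path at interactive speeds. Seeds fan out from a single master seed via
`numpy.random.SeedSequence`; all tables are written as plain CSV/JSON.

## Known limitations

- Automatic segmentation is tuned for well-separated coccoid cells; dense
  microcolonies need `split_touching` and still undercount at high packing.
- The enrichment fraction assumes no isotopic fractionation on uptake and a
  constant substrate pool over the incubation.
- δ-scale FAME correction biases heavily enriched samples (use the exact
  mode there).
- Community extrapolation inherits the uncertainty of the cell density,
  BChl a:C and C-per-cell conversions; it is reported as a point estimate.
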