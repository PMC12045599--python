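# Methods

This note documents the models and procedures implemented in `invkit`, the
assumptions behind them, the parameters that matter, and what the synthetic
data do and do not emulate.

## Capture-assay quantification

**Masks.** The mitochondrial mask is segmented from the MitoTrap channel by
Gaussian smoothing (σ = 1 px) and an Otsu threshold, with objects under
10 px removed; a trained pixel classifier can be substituted by importing an
externally produced mask TIFF.  The "cytoplasm" ring is the mito mask
dilated eight times with a 3×3 (8-connected) structuring element, minus the
mito mask itself — the two regions are disjoint by construction.  Cells are
connected components of the dilated mask; coordinates are 0-based (row,
column) pixel indices.

**Measurement.** For each cell, channel and region,
`F_region = Σ max(pixel − background, 0)`; background defaults to the median
intensity outside the (padded) union of cell footprints, per channel, and
can be overridden.  `F_total = F_mito + F_cyto` holds exactly — it is an
identity of the measurement, not an approximation.

**Ratios and the responder filter.** Fixed-cell experiments report
`F_mito/F_total` (treated vs control cells); live experiments report
`F_post/F_pre` in the mito region per cell.  Cells with
`F_mito/F_cyto < 1` in the FKBP channel after treatment are non-responders
(capture failed) and are excluded from every summary; the inequality is
strict, ties are kept.  The filter is not applied to untreated reference
cells, where the rule is undefined.

**Cytoplasmic loss and pool size.** The relocalizable pool of a marker is
estimated as the relative decrease of its cytoplasmic fraction
`cf = F_cyto/F_total`: `loss% = 100·(cf_ref − cf_treated)/cf_ref`, computed
per replicate and averaged.  The **subset share** is the ratio of the
co-relocated loss of a marker to its maximal direct-capture loss; it is
scale invariant, clipped to [0, 1] for reporting, and ratios ≥ 0.9
(tolerance 0.1) are flagged as capture of the entire pool.  Shares are
rendered to the nearest ten percent, the precision the statistic supports.

**Registration.** Channel alignment is translation-only phase
cross-correlation (sub-pixel, upsampling ×10); the per-channel displacement
is reported and its inverse applied.  Flat channels yield zero shift with a
warning.

## Capture kinetics

Mitochondrial fluorescence traces are fitted with a delayed mono-exponential

    F(t) = F_base                                        t < t_on
    F(t) = F_plateau − (F_plateau − F_base)·e^{−(t−t_on)/τ}   t ≥ t_on

by trust-region least squares, initialized from the data (pre-onset mean,
mean of the last 10% of frames, time to half-rise / ln 2).  A fit is flagged
not converged when the fitted rise is below twice the pre-onset noise sd
(flat traces) or τ is unphysical.  Per-cell (τ_A, τ_B) pairs are compared by
a through-origin regression, `slope = Σxy/Σx²`, with the *uncentered*
R² = 1 − SSR/Σy²: the centered definition is ill-posed without an intercept
and can be negative.  On synthetic traces with noise at 5% of the rise, the
median relative τ error is below 10%, and the fit residual is never worse
than a brute-force (τ, plateau) grid search.

## Synthetic capture fields

The generator emulates the statistical structure of the capture experiments,
not their optics.

- **Geometry.** Each cell is a mitochondrial network (persistent random-walk
  filaments stamped with a disk, filament width ≈ 0.45 µm at the default
  65 nm pixels) whose 8-step dilation defines the measured cell footprint —
  the same footprint definition the pipeline uses.  With the default
  `mito_density = 0.3`, mitochondria occupy ~30% of the footprint, which is
  what makes an ATG9A-sized pool (~40%) pass the responder filter, as it
  does in real data: post-capture, `F_mito/F_cyto = (g + V)/(1 − g − V)`
  where g is the diffuse signal over the mito footprint and V the
  vesicle-bound fraction.
- **Signal bookkeeping.** `pool_fraction` is the relocalizable fraction of a
  marker's *cytoplasmic* signal (outside the mito footprint); the diffuse
  remainder overlays the whole cell, as cytosol does in projection.  With
  mito area fraction m, the vesicle-bound share of the total is
  `V = p(1−m)/(1−pm)`, which makes the pipeline's measured cytoplasmic loss
  equal p exactly in the noise-free limit — simulated losses are calibrated
  by construction, not by tuning.
- **Vesicles.** Sub-resolution (~35 nm) vesicles are rendered as
  unit-normalized Gaussian spots (σ = 1 px) at least 2 px from compartment
  boundaries, so rendered mass stays in the right compartment.  Channel A
  (INV marker) rides 148 vesicles per cell, channel B (ATG9A-like) 30, and
  with `overlap_fraction = 1` every B vesicle also carries A — so 30/148 ≈
  20.3% of A's vesicle-bound signal is co-capturable, the condition matching
  the measured 14.5/71.5 losses.  Default pools: 71.5% (A), 41% (B).
- **Capture.** Adding rapalog moves each vesicle carrying the FKBP-tagged
  marker to a random interior mitochondrial pixel at an exponentially
  distributed delay (mean τ = 20 s), reproducing bulk 1 − e^{−t/τ} kinetics
  while keeping per-vesicle bookkeeping; fixed pre/post pairs use the t = 0
  and t → ∞ states.  Total marker signal is conserved exactly at zero noise.
- **Noise.** Poisson(photon_scale·I)/photon_scale shot noise plus Gaussian
  read noise (sd 2 at a per-cell signal of 2×10⁵), chosen so per-pixel
  signal sits well above the clipping floor of background subtraction.

Not emulated: optical PSF rigor, photobleaching, cell motility, organelle
crowding, marker pools on other organelles.  Passing recovery tests
therefore shows the *pipeline arithmetic* is faithful under realistic noise
and segmentation error; it cannot certify behavior on real images with
heterogeneous expression or segmentation failure modes.

## Puncta and Golgi quantification

Stacks are rescaled to isotropic voxels (the smallest dimension, linear
interpolation), normalized to [0, 1], thresholded and labeled with
26-connectivity; components with volume ≤ 0.012 µm³ are discarded (strict
">") and per-cell counts and mean volumes reported.  The default threshold
is 0.5 of the dynamic range: for sparse, near-binary puncta Otsu's
class-balance assumption fails and biases volumes upward, while the
half-range threshold recovers the physical surface of a partial-volume
rendered blob; Otsu remains available (`threshold="otsu"`), as does an
explicit value.  Synthetic blobs are spheres rendered with partial-volume
antialiasing (3×3×3 sub-voxel coverage), and their half-maximum voxel-count
volumes match the requested physical volumes within one voxel shell.  The
default synthetic voxel size (0.04 µm xy, 0.10 µm z) is the scale at which
0.011 vs 0.013 µm³ blobs are resolvable — the precondition for exercising
the threshold rule.

TGN measurements normalize and segment the TGN channel (smooth + Otsu),
erode the mask by one pixel so boundary partial-volume pixels do not dilute
the measure, and report the mean intensity of the second channel inside the
mask per cell (raw mean; whether to background-subtract here is left to the
caller, and the default reports the raw value).

## Proteomics enrichment

Protein-group tables are read in the MaxQuant dialect (intensity columns by
prefix, `<condition>_R<replicate>` sample names, contaminant / reverse /
site-only flags, zero = missing).  Intensities are log2 transformed; missing
values are imputed per sample from `Normal(mean − 1.8·sd, (0.3·sd)²)` of the
observed values — the de-facto standard for left-censored LFQ missingness.
Enrichment per protein is the Welch (unequal-variance) two-sample t test on
log2 intensities with `log2FC = mean_A − mean_B`; classes follow the
four-color volcano convention (pink: FC > 2 and P < 0.05 — the enriched
set; red: FC > 2 only; blue: P < 0.05 only; gray: remainder), with the
fold-change gate strict and applied on the linear scale.  No multiple-testing
correction enters the class call (matching the raw P < 0.05 convention); a
Benjamini–Hochberg FDR column is emitted for reference.  Consolidation takes
the union of pink sets across named runs, keeps per-run provenance flags and
ranks by maximum fold enrichment; it is idempotent and order independent.

2×2 annotation and dataset-overlap tests use Pearson's chi-squared statistic
computed from the closed form `n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` without
continuity correction (the convention when the statistic itself is
reported); Yates correction is available by flag, and zero expected counts
are an error.  Rank correlation is Spearman's ρ with average ranks for ties
and the large-sample p approximation, requiring n ≥ 4.

The LFQ simulator spikes `n_enriched = 50` of 2000 proteins with a mean
log2 effect of 1.8 = 3 within-condition sd (sd 0.6, six replicates per
condition — two runs of three), draws base abundances from N(25, 2) log2,
and censors low intensities with a logistic dropout (midpoint 2.5 sd below
the mean abundance, ~2–3% missing entries).  At these design values both
enrichment gates pass comfortably for spiked proteins (expected recovery
≈ 95–97%) while the null p-value calibration is preserved.  Note that under
the null with `fc_cut = 1`, the expected pink rate is α/2 = 0.025, not α:
the class additionally requires a positive fold change.

## Replicate-aware reporting

Superplot summaries collapse per-cell values to per-replicate means before
any inference; two-way ANOVA (type II with interaction) and Tukey's HSD run
on replicate means, so n is the number of independent experiments.  A
dedicated test constructs a pseudo-replication scenario (large per-replicate
cell counts, replicate-level batch effects) where pooled-cell testing is
confidently wrong and the replicate-aware test correctly is not.

## Problem sizes and determinism

The end-to-end subset-share study simulates 12-cell fields for each of two
condition arms across three replicate seeds (~36–42 analysed responder cells
per arm), enough for the share's seed-to-seed spread to sit well inside
±0.05.  All generators take explicit integer seeds; identical seeds give
bit-identical images, tables and CSV outputs.  Derived per-stage seeds are
produced by hashing the base seed so stages are independently reproducible.

## Known limitations

- Threshold segmentation stands in for the trained pixel classifiers used
  interactively in the field; mask import is the escape hatch.
- The capture model is 2D and single-plane; 3D capture quantification and
  nuclear masking are out of scope.
- Pool-size inference assumes the reference condition is at steady state and
  that expression differences cancel in the cytoplasmic *fraction*.
- The exponential model is mono-exponential by design; diffusion-limited or
  multi-phase capture is not modelled.
- Real-data quantities that depend on unpublished raw data (absolute protein
  counts, specific chi-squared statistics, real-cell τ scatter) are outside
  what the synthetic recovery tests can certify.
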