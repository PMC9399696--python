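# Methods

## Overview

`xistmelt` determines mammalian sex from messenger RNA by analyzing the
melt curves of a duplex RT-qPCR that co-amplifies the X-inactivation
transcript (*XIST*, present only when ≥ 2 X chromosomes are present) and a
β-actin (*ACTB*) control. The analysis follows the standard
high-resolution-melt (HRM) workflow: derivative peak calling, two-baseline
normalization, difference curves against an automatically chosen reference,
shape clustering, anchor-based cluster labelling, and a majority-rule call
per sample, validated against DNA-based truth labels. Because the method is
developed and tested against simulation, the synthetic-data generator is a
first-class part of the package and its assumptions are documented here.

## Melt-curve model

A well's fluorescence is modelled as

    RFU(T) = gain · (b0 + b1·T) · (r + Σ_k a_k · θ(T; Tm_k, w_k)) + ε(T)

* θ(T) = 1/(1 + exp((T − Tm)/w)) is the two-state (helix/coil) fraction of
  amplicon *k* still double-stranded at temperature T. This is the simplest
  model producing the sigmoidal melt step and the −dF/dT peak at Tm that
  the analysis consumes; no nearest-neighbor thermodynamics is attempted.
* (b0 + b1·T) is the dye/background response; b1 < 0 (fluorescence of the
  saturating dye declines with temperature). Defaults b0 = 2600 RFU,
  b1 = −20 RFU/°C give instrument-scale signals.
* r = 0.05 is a non-melting residual fraction.
* `gain` is a per-well log-normal factor (σ = 0.1) reproducing
  well-to-well amplitude spread; ε is additive Gaussian noise with
  sd = 0.004 of the well's pre-melt amplitude.
* The temperature grid is 70–95 °C in 0.5 °C steps, the melt-step
  resolution of a typical real-time thermocycler.

Default product parameters: *ACTB* Tm 85.5 °C (abundance 1.0), *XIST*
Tm 84.0 °C (abundance 0.55), transition width 0.25 °C. The Tm values place
the two transitions where the assay observes them; the *XIST*:*ACTB*
abundance ratio is a calibration choice (the real relative signal strength
is not reported anywhere), set so the female shape difference is far above
the clustering threshold. The width deserves a note: with 0.5 °C sampling
and a 1.5 °C Tm spacing, transition widths ≳ 0.3 °C make the composite
−dF/dT of a duplex well monotone between the two Tms — i.e. no resolvable
XIST peak at all. Width 0.25 °C (a transition spanning ~1–1.5 °C, typical
of short amplicons in HRM practice) keeps both peaks resolvable, which is
the defining feature of the female profile.

### Failure modes and cohort structure

Samples carry an RNA yield drawn log-normally per cohort profile
(means 5.6, 55.0 and 71.4 ng µl⁻¹ for the pilot, optimized and
preservative-stored profiles, log-sd 0.5–0.6). Below the dropout threshold
(9 ng µl⁻¹) each well is exposed, in fixed order, to mutually exclusive
failure draws:

* non-amplification (p = 0.2) — flat baseline-only trace;
* a dominant primer-dimer product (p = 0.3) at Tm 78 °C, width 0.35 °C,
  abundance 0.7 with residual *ACTB* at 0.35 — dimer-dominant but with
  enough in-window melt amplitude that replicate dimer wells co-cluster,
  as aberrant wells do in practice;
* *XIST* dropout (p = 0.5, females only) — the transcript present but
  below detection, leaving a male-like *ACTB*-only profile. This is the
  mechanism behind the documented low-yield misidentification of females.

These rates are free parameters chosen to reproduce the qualitative
failure behavior of poorly extracted samples; they are not measured
quantities. ACTB heterozygosity is an individual-level trait (p = 0.10 per
sample, consistent across its replicates) splitting the control amplicon
into two sub-transitions 0.35 °C apart — enough to flatten the transition
centre (the "elevation-separating plateau") while keeping heterozygous
individuals inside the male/female primary clusters, which is how such
individuals behave in the assay. XXY karyotypes (off by default) express
*XIST* while their DNA-based label is male.

Determinism: per-well and per-sample seeds are derived from the master
seed by stable hashing of string labels, so plates reproduce bit-identically
and are insensitive to simulation order.

## HRM transforms

* **Derivative**: −dF/dT by Savitzky–Golay local cubic over 5 points.
  A quadratic over the same window is equivalent to a smoothed 2-point
  central difference and blurs the two duplex peaks into one shoulder;
  wider windows do the same. The window-5 cubic is the minimal filter that
  resolves 0.25 °C transitions 1.5 °C apart on a 0.5 °C grid.
* **Peak calling**: local maxima with prominence above 10% of the
  run-wide derivative maximum and ≥ 1 °C apart, refined by quadratic
  interpolation through the three nearest grid points. The run-wide floor
  (rather than per-trace) guarantees flat wells produce no peaks; 10%
  (rather than a smaller fraction) sits above the prominence of noise
  wiggles on the cubic derivative (≈1.9× the curve noise) while the true
  XIST peak carries ~13% prominence. Peaks are searched on the full grid,
  not only the analysis window, so low-temperature primer-dimer
  transitions remain measurable for outlier diagnosis.
* **Normalization**: straight lines are fitted to a pre-melt window
  (default 80–82.5 °C) and a post-melt window (default 88–92 °C); the
  curve is rescaled to (RFU − L)/(U − L) on the analysis window
  [82.5, 88] °C and clipped to [0, 1]. Baselines that cross inside the
  window raise a degenerate-baseline error (flat/non-amplified wells).
  The defaults keep the pre-melt window above the primer-dimer transition
  (so aberrant wells normalize and can be *clustered* as outliers rather
  than silently discarded) and use 6–9 grid points per fit: shorter
  windows make the extrapolated baselines noisy enough to inflate
  within-group shape spread several-fold. Normalization is idempotent to
  1e−6 when the windows sit in truly flat regions.
* **Reference selection**: the "typical" curve for difference plots is
  the medoid under the shape metric (ties broken by well id). On a
  majority-male plate the medoid lands in the male group, matching the
  behavior of instrument software that picks a male reference
  automatically.
* **Difference curves**: pointwise subtraction of the reference. A female
  well against a male reference shows a sharp negative excursion near the
  XIST Tm; male wells stay near zero.

## Clustering

The shape metric is the maximum absolute pointwise difference between two
normalized curves (dimensionless, in [0, 1]). Clustering is greedy
agglomerative with complete linkage: starting from singletons, the
qualifying pair of clusters with the smallest complete-linkage distance is
merged, where a pair qualifies only if that distance is ≤ θ_shape **and**
the cluster mean primary Tms differ by ≤ the Tm threshold. The curve-shape
sensitivity s (percent) maps linearly to θ_shape = θ_max·(1 − (s−1)/99)
with θ_max = 0.10, so the minimum sensitivity used by the assay (1%) gives
the broadest clusters — amplicon presence/absence separates groups
(female–male shape distance ≈ 0.3) while allele-level differences
(≈ 0.02) do not. The mapping is a documented stand-in for a proprietary
parameter, as is the merge semantics (merge allowed iff ΔTm ≤ threshold);
neither is asserted to be identical to any instrument's internals.
Complete linkage was chosen so one aberrant well cannot chain two sex
clusters together. Everything is deterministic: wells are processed in
sorted id order and ties break on (distance, smaller cluster id), so
partitions are invariant to input order. Clusters smaller than
`min_cluster_size` (default 3, one triplicate) are flagged outliers and
excluded downstream — primer-dimer wells end up here via the Tm
constraint (their 78 °C primary Tm can never merge with the 85.5 °C
primary clusters).

## Calling and validation

Wells failing QC (non-amplified flag, absent/late Cq, melt amplitude below
10% of baseline, degenerate baseline, or membership in an outlier cluster)
are excluded. Primary clusters are mapped to sexes by the anchor rule —
the cluster holding the majority of wells from known-female anchor samples
(e.g. individuals observed with a calf) is female, the rest male — with a
signature fallback for anchor-free runs (the cluster whose medoid shows a
secondary melt transition is female). If the two rules disagree, or
anchors split evenly, mapping aborts and calls become inconclusive rather
than guessed.

A sample is called female/male when ≥ 2/3 of its evaluable wells (QC-passing
wells in primary clusters; excluded wells count in neither numerator nor
denominator) sit in one sex-mapped cluster; otherwise inconclusive;
insufficient when no well survives. RNA yields below 9 ng µl⁻¹ attach an
advisory low-yield flag ("repeat extraction") that never alters the call.

Concordance against DNA-based labels counts exact female/male matches;
inconclusive and insufficient calls count as disagreement but are itemized.
Discordances are tagged mechanistically: call-female/DNA-male is an XXY
candidate (*XIST* expressed and Y-linked marker present in one
individual); call-male/DNA-female on a low-yield sample is suspected XIST
dropout.

## Problem sizes

The test suite and acceptance script run entirely on simulated data: a
69-sample triplicate cohort (207 wells) for the end-to-end concordance
check, 16–24 wells for cluster-structure and Tm-recovery checks, and
200 wells for the Tm-recovery error distribution. These sizes mirror the
validation-cohort scale of the assay while keeping a full run in seconds.

## What the simulation does and does not show

The generator reproduces the features the analysis depends on: two-state
melt steps at the documented temperatures, baseline slope, multiplicative
well gain, replicate structure, yield-dependent failure modes, anchors and
karyotype edge cases. It does not emulate instrument-specific artifacts
(optical crosstalk, spatial plate effects, dye redistribution during
melting), sequence-dependent melt-domain structure, or Cq-correlated melt
amplitude. Passing tests therefore demonstrate that the analysis correctly
recovers what this signal model encodes — not that every real plate will
cluster as cleanly; real aberrant chemistry can produce shapes the
simulator never generates, which is why the outlier flagging and the
conservative inconclusive/abort paths exist.

## Numerical choices and degenerate inputs

* Melt CSV serialization: temperatures at 2 decimals (exact on a 0.5 °C
  grid), RFU at 12 significant digits (round-trips to 1e−9).
* Cq model: Cq = intercept − slope·log10(template); computed Cq above the
  cycle cap (45) reports non-amplified; a negative Cq clamps to 0.
* Quadratic peak refinement is skipped at grid edges and when the
  three-point stencil is not concave.
* A plate where no well passes QC raises rather than emitting an empty
  report from `analyze_plate`; `write_outputs` however accepts empty call
  tables (a run can legitimately produce none).
* The empirical product-Tm formula is restricted to its validity range
  (length ≥ 40 bp, GC ∈ [0, 1], cation molarity > 0); in-silico PCR is
  exact-match only, by design — mismatch-tolerant genome-scale search is
  out of scope.

## Known limitations

* The sensitivity→threshold mapping, θ_max, and the dimer/dropout rates
  are calibrated stand-ins, stated in the run parameters and logged with
  every report, not measured constants.
* The anchor rule needs at least one correctly clustered anchor sample;
  single-sex plates without anchors rely entirely on the signature
  fallback.
* Sub-°C allele discrimination (true HRM genotyping) is explicitly a
  non-goal; the pipeline targets presence/absence duplex discrimination.
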