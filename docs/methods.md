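# Methods

## The assay and its statistical model

A single-cell barcode chip (SCBC) run yields, per microchamber, a
bright-field cell count and one raw fluorescence intensity per analyte of a
multiplexed antibody barcode (default panel size 11). The pipeline's
statistical assumptions are:

* **0-cell chambers measure background.** For each analyte (barcode stripe)
  and chip, the 0-cell intensities are modelled as Gaussian *N(μ, σ)*. A
  typical exemplar used throughout the tests is μ = 106 AU, σ = 16.2 AU.
  Backgrounds are fitted per analyte per chip — stripes differ in antibody
  chemistry and chips differ in processing — and never pooled across chips.
* **Secretion calling is a 2σ exceedance test.** A 1-cell chamber is called
  positive for analyte *j* when raw > μⱼ + 2σⱼ (strict inequality: ties are
  measure-zero on real data and a fixed rule keeps tests deterministic).
  Under a correct background model this leaves a per-analyte false-positive
  rate of q = 1 − Φ(2) ≈ 0.0228. Over an 11-plex panel the *familywise*
  null rate is 1 − (1 − q)¹¹ ≈ 0.22 — a property of the 2σ rule that any
  interpretation of "fraction of secreting cells" has to carry, and that the
  synthetic calibration (below) accounts for explicitly.
* **Rates are T₂-normalized.** Net signal max(raw − μ, 0) divided by the
  on-chip secretion window T₂ (hours) gives AU/hour, the unit on which
  conditions with different T₂ are compared and on which the pSI is defined.
  Zero-clamping keeps net signal and pSI non-negative; its cost is a small
  positive noise floor, E[max(N(0, σ), 0)]/T₂ = σ/(√(2π)·T₂) per analyte,
  which the calibration arithmetic includes. Whether reported intensities
  should be background-subtracted before entering the index is not
  universally fixed; clamped subtraction of μ is this package's documented
  default, and `compute_psi(use_rates=False)` provides the raw-AU view.
* **Only 1-cell chambers are single cells.** Chambers with ≥ 2 cells are
  retained for QC but never enter single-cell statistics.

## The polyfunctional strength index

The verbal definition — the fraction of cells secreting a certain number of
different proteins multiplied by the measured intensity of those proteins —
is operationalized exactly as

    psi_k    = (n_k / n) * mean_{cells with exactly k calls}
               ( sum_{called analytes} net_rate )          for k = 1..P,
    psi_total = sum_{k >= 1} psi_k,

with exact-k strata internally ("1, 2, 3 or more" pooling is a display
convention only) and psi_0 = 0. Two identities follow and are enforced by
tests: Σ_k psi_k = psi_total, and the per-analyte decomposition
(Σ_cells call_j · rate_j) / n sums to psi_total. The per-analyte *mean
rates* used for fold changes are ensemble means over **all** cells (called
or not), matching bulk "fold above background" language; medians are not
used (heavy-tailed rates would understate ensemble amplification).

## Background diagnostics and gradient correction

* **Estimation.** Moment estimates (sample mean, sd with ddof = 1) are the
  defaults; a least-squares Gaussian fit to the 20-bin histogram is computed
  alongside (the binned view is how such backgrounds are usually inspected)
  and agrees with the moments within 5% on Gaussian data. Minimum sample
  size: 30 usable (unsaturated) 0-cell chambers. Saturated background
  values are censored, not Gaussian, and are excluded.
* **KS diagnostic.** The one-sample Kolmogorov–Smirnov test against the
  fitted *N(μ, σ)* is reported per analyte. Because the parameters are
  estimated from the same sample, the test is anti-conservative (Lilliefors
  effect); `ks_p` is advisory — the pipeline logs a warning below 0.05 and
  never gates on it. Whether the test should run on raw values or on the
  20-bin histogram is left open by precedent; this implementation runs it
  on raw values and reports the histogram for inspection.
* **Gradient.** Some chips show a spatial background trend. The model is
  linear in the row index (column or either axis selectable), estimated by
  least squares on 0-cell chambers (≥ 30 chambers spanning ≥ 5 distinct
  rows), gated at slope-test p < 0.01, and — when significant — the centered
  trend slope·(row − mean row) is subtracted from *all* chambers: the
  gradient is a device property, so 1-cell chambers must move with it.
  Centering leaves μ unchanged in expectation, so secretor net rates are
  unbiased by inject + correct (verified in tests). Correction is
  idempotent: a second pass finds no significant residual slope. The gate
  may fire per analyte independently; a 1% type-I rate per analyte is
  accepted rather than forcing a chip-wide decision.

## The synthetic chip generator

What it emulates: chamber occupancy (explicit class counts, default
{0: 300, 1: 400, 2: 350, 3: 200}, or Poisson loading), per-stripe Gaussian
background with optional linear row gradient, detector saturation at
65535 AU, and a two-layer Bernoulli secretion model —

* a cell is a *secretor* with probability p (`secreting_fraction`);
* a secretor secretes analyte j independently with probability aⱼ
  (`analyte_activity`);
* each secreted analyte contributes a lognormal per-hour amplitude
  exp(m_j + 0.5·(k−1)·boost + s_j·Z) × T₂, where k is the cell's total
  number of secreted analytes. The boost (default +0.5 log-units per extra
  analyte, configurable) couples polyfunctionality to copy number —
  polyfunctional cells secrete the most;
* multi-cell chambers sum independent per-cell contributions (no on-chip
  interaction model is assumed).

What it does **not** emulate: cell aggregation/motility dynamics during
priming, mechanistic autocrine feedback, analyte–analyte signal crosstalk,
non-Gaussian background contamination, and the true (unknown) secretor
amplitude distribution — lognormal is an assumption, flagged in every
scenario's calibration notes. Passing round-trip tests therefore shows the
pipeline recovers what this model generates, not that real chips satisfy
the model.

### Calibration of named scenarios

Scenario parameters are chosen so the *measured* pipeline output matches the
headline values each scenario emulates, by closed-form inversion fixed at
scenario-definition time:

* **Secreting fractions.** With per-analyte false-positive rate q and
  near-certain detection of secreted analytes, a cell's call count K is
  Poisson-binomial with probabilities qⱼ = q (non-secretor) or
  cⱼ = aⱼ + (1 − aⱼ)q (secretor). Given a target measured fraction m at
  threshold k, p solves m = p·P(K ≥ k | sec) + (1 − p)·P(K ≥ k | null).
  At m = 0.23 with k = 1 this leaves p ≈ 0.008 — almost all of the 23% is
  the 11-plex familywise tail, which is exactly what a 2σ rule implies.
* **Mean-rate folds.** The expected mean net rate of analyte j over 1-cell
  chambers is r_j ≈ (1 − p aⱼ)·σ/(√(2π)·T₂) + p aⱼ·E[Aⱼ]·Bⱼ with
  E[Aⱼ] = exp(mⱼ + sⱼ²/2) and boost factor
  Bⱼ = Π_{i≠j}(1 − aᵢ + aᵢ·e^{boost}) (the probability-generating-function
  identity for E[e^{boost(K−1)} | j secreted]). Target folds are imposed by
  solving for mⱼ (IL2 in the OT1 scenario) or a global amplitude scale
  (human CD4) against the reference condition's r.

Scenarios: **OT1_tetramer** (T = 24 h; T₁ ∈ {0.2, 4, 16} h ⇒ T₂ ∈ {23.8,
20, 8} h; detectable fractions 0.23/0.43/0.60; IL2 folds 10×/20× vs 0.2 h;
the 0.2 h condition uses a chemokine-dominated activity profile — only
CCL3/CCL4 are appreciably active at very short priming). **human_CD8**
(T = 13 h; P(k ≥ 2) = 0.20 at T₁ = 0 and 0.55 at T₁ = 8 h). **human_CD4**
(T = 13 h; expected total-rate fold calibrated to 300, instantiating a
"> 200-fold" increase; the T₁ = 0 denominator is dominated by the stable
clamped-noise floor). **density_sweep** (qualitative: secretor fraction
0.15 vs 0.35 at 2×10⁵ vs 5×10⁵ cells/ml). The 16 h detectable fraction
(0.60) and the CD4 polyfunctional parameters have no printed counterpart
and are fixed, plausible choices documented here.

Seeding: all generation flows through `numpy.random.Generator`; cohort
chips use per-condition seeds derived as
`SeedSequence([master_seed, condition_index])`, so streams are independent
and every run is bitwise reproducible.

## Numerical and statistical choices

* Chamber tables serialize floats with `repr`, so read → write → read is
  bitwise exact.
* Degenerate inputs: zero-variance background, sub-minimum sample sizes,
  empty call tables, zero-denominator fold changes (reported as undefined,
  never infinite), single-row background layouts (insufficient span), and
  all-identical embedding inputs (zero embedding, one cluster) all raise or
  degrade explicitly rather than silently.
* PCA is preceded by log1p (heavy-tailed rates; switchable); clustering is
  k-means with a fixed `random_state` and user-specified cluster count (no
  automatic model selection is claimed).
* Null false-positive suites use a 5000 zero-cell / 1000 one-cell chip:
  with 300 background chambers the cutoff's estimation error would rival
  the binomial band of the 2.3%-tail check, while at 5000 it is negligible,
  making the test sharp at 3 binomial standard errors.
* Recovery suites run one chip per condition (400 single cells), the chip
  scale the default occupancy implies; the KS type-I suite uses 1000
  replicates of n = 300 and the bimodal-power suite 200 replicates. The
  IL2 fold estimator at this scale has a simulation sd of roughly 16% of
  its value (ratio of heavy-tailed means), centered on the calibrated 10×.

## Known limitations

* Saturated positives keep their clipped intensity (flagged); no censoring
  correction is applied, so rates and pSI are biased low wherever
  saturation is frequent.
* No AU → molecule-count conversion (no calibration curve is modelled).
* No bootstrap confidence intervals for pSI in this version.
* The KS diagnostic with estimated parameters is anti-conservative; treat
  `ks_p` as descriptive.
* Calibrated recoveries validate internal consistency on the generator's
  model of chip data; they are not evidence about any particular real
  dataset.
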