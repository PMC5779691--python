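# scbc — single-cell barcode chip secretomics

`scbc` analyzes multiplexed antibody-barcode immunoassays of proteins
secreted by single T cells. A single-cell barcode chip (SCBC) isolates cells
in ~1500 nanoliter microchambers, each patterned with an 11-plex antibody
barcode; after an on-chip secretion window T₂, each barcode stripe reports
one analyte's captured signal as a fluorescence intensity. The package takes
the *merged chamber table* (cell count + per-analyte intensity per chamber)
and produces single-cell secretion calls, polyfunctionality statistics and
cross-condition comparisons. It is written for labs running SCBC-style
microchamber secretomic assays — e.g. T-cell conditioning / adoptive cell
transfer studies that sweep a bulk priming period T₁ while holding the total
stimulation time T = T₁ + T₂ constant.

## Method

Per chip and analyte (barcode stripe):

1. **Background** — chambers with zero cells measure pure assay background.
   Their intensities are fitted as a Gaussian *N(μ, σ)* (moment estimates; a
   20-bin histogram least-squares fit is reported alongside), with a
   one-sample Kolmogorov–Smirnov diagnostic. A linear spatial gradient along
   the device rows is detected on the 0-cell chambers and, when significant
   (slope-test p < 0.01), subtracted chip-wide.
2. **Calling** — a single cell in a 1-cell chamber secretes analyte *j* if
   its raw intensity strictly exceeds the cutoff **μⱼ + 2σⱼ**. Net signal is
   max(raw − μⱼ, 0) and the secretion **rate** is net / T₂ (AU/hour), making
   conditions with different T₂ comparable. Saturated stripes are called
   positive and flagged.
3. **Polyfunctionality** — a cell's polyfunctionality *k* is its number of
   positive calls. With *n_k / n* the fraction of cells secreting exactly
   *k* proteins, the polyfunctional strength index per stratum is

   ψ_k = (n_k / n) · ⟨Σ_{called j} rate_j⟩_{cells with exactly k calls},
   ψ_total = Σ_{k≥1} ψ_k,

   with an exact per-analyte decomposition of ψ_total.
4. **Cohorts** — conditions are compared by secreting fractions
   (P(k ≥ 1), P(k ≥ 2)), ψ_total, per-analyte mean net rates and their fold
   changes, secretion composition, and a PCA + k-means embedding of the
   single-cell rate matrix.

Because raw SCBC datasets of this kind are typically not deposited, the
package ships a first-class synthetic chip generator
(`scbc.synthetic`) with calibrated cohort scenarios (`OT1_tetramer`,
`human_CD8`, `human_CD4`, `density_sweep`) whose *measured* pipeline outputs
match the headline values they emulate. See `docs/methods.md` for the model
and the calibration arithmetic.

## Worked example

```python
from scbc import analyze_cohort, fraction_secreting, generate_cohort, get_scenario

scenario = get_scenario("OT1_tetramer")          # murine CD8+ T1 sweep, T = 24 h
datasets = generate_cohort(scenario, seed=1)     # one chip per condition
calls, profiles, summary = analyze_cohort(datasets)

for table, profile in zip(calls, profiles):
    print(
        f"{table.condition.label:>8}: {table.n_cells} cells, "
        f"secreting >=1: {100 * fraction_secreting(table, 1):.1f}%, "
        f"pSI total: {profile.psi_total:.1f} AU/h"
    )
print(f"IL2 fold change (T1 0.2h -> 4h): {summary.fold('IL2', 'T1=0.2h', 'T1=4h'):.1f}")
```

prints

```
 T1=0.2h: 400 cells, secreting >=1: 23.2%, pSI total: 3.0 AU/h
   T1=4h: 400 cells, secreting >=1: 44.5%, pSI total: 125.9 AU/h
  T1=16h: 400 cells, secreting >=1: 59.5%, pSI total: 245.8 AU/h
IL2 fold change (T1 0.2h -> 4h): 9.9
```

Each chip contributes 400 single cells. After only 12 minutes of bulk
priming, 23% of cells show detectable secretion; 4 hours of priming roughly
doubles that fraction, multiplies the IL2 mean secretion rate ~10-fold, and
the total polyfunctional strength keeps rising through 16 hours — the
cell–cell-interaction conditioning effect the scenario is calibrated to.

The same pipeline is available from the shell:

```sh
scbc simulate --scenario OT1_tetramer --seed 1 --out chips/
scbc fit-background --in chips/T14h.csv --report background.csv
scbc call --in chips/T14h.csv --out calls.csv
scbc psi --calls calls.csv --out profile.csv
scbc compare --calls calls_a.csv --calls calls_b.csv --out summary.csv
scbc embed --calls calls.csv --components 2 --clusters 3 --seed 0 --out embedding.csv
```

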