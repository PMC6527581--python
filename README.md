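# ramanprobe

Analysis pipeline for **alkyne-probe Raman spectroscopy of carrier-protein
chain sequestration**.

Carrier proteins (CPs, e.g. acyl carrier proteins in fatty-acid and polyketide
synthases) tether biosynthetic intermediates on a 4′-phosphopantetheine
(Ppant) arm and can bury — *sequester* — the acyl chain inside their
hydrophobic cavity. A terminal-alkyne fatty-acid mimic loaded onto the Ppant
thiol reports on that burial: the C≡C stretching band (~2100 cm⁻¹, in the
spectrally transparent region) sits at **lower frequency when the probe is
solvated in water and shifts to higher frequency when it enters the
hydrophobic cavity**, while the lineshape reports the picosecond-resolved
distribution of environments. This package turns raw C≡C-region Raman
exposures into that biological readout, and verifies probe loading by
intact-protein mass arithmetic.

## What it computes

Given an exposure stack `I_k(ν)` (repeated 1-minute acquisitions on a shared
Raman-shift axis) and a free-probe reference spectrum `R(ν)`:

1. **Preprocess** — co-add exposures; fit the surrounding baseline region
   (2000–2300 cm⁻¹) with a 7th-degree polynomial after cutting a hole over the
   band (2100–2130 cm⁻¹); subtract it; scale the band maximum to 1.0.
2. **Peak statistics** — mode (grid argmax), windowed centroid
   ν̄ = Σ ν·max(I,0) / Σ max(I,0) over 2100–2130 cm⁻¹, and FWHM from
   interpolated half-maximum crossings.
3. **Two-state decomposition** — nonnegative least squares of
   `I(ν) ≈ a_aq·R(ν) + a_seq·R(c + (ν − c − Δ)/s)` over a bounded grid of
   shifts Δ (0–15 cm⁻¹) and width scales s, giving the sequestered fraction
   `f̂ = a_seq / (a_aq + a_seq)`.
4. **Classification** — an explicit decision rule on the centroid shift
   Δν̄ = ν̄_sample − ν̄_ref and f̂ yields `not_sequestered`, `partial`, or
   `sequestered`; thresholds are configurable and echoed in every result.
5. **Mass checks** — expected masses for apo/holo/acyl species
   (holo = apo + Ppant C₁₁H₂₁N₂O₆PS; acyl = holo + acid − H₂O for the C5/C8/C13
   alkyne acids) and ESI charge-series deconvolution
   (mass = z·(m/z − m_H⁺), charge assignment chosen to minimize the SD across
   consecutive peaks).

A synthetic-data generator produces two-state pseudo-Voigt bands on smooth
polynomial baselines with Poisson-like exposure noise and recorded ground
truth, so every stage is testable end to end.

## Worked example

```python
import ramanprobe as rp

suite = rp.scenario_suite(seed=7)          # f = 1 / 0 / 0.5 scenarios
for sc in suite:
    spec, fit = rp.preprocess_stack(sc.stack)
    ref = rp.ReferenceEntry.from_spectrum(rp.preprocess_stack(sc.reference)[0])
    result = rp.analyze_sample(spec, ref)
    stats = rp.summarize(spec)
    print(f"{sc.stack.sample_id}: mode={stats.mode:.1f} mean={stats.mean:.2f} "
          f"fwhm={stats.fwhm:.2f} d_mean={result.deltas.d_mean:+.2f} "
          f"f_hat={result.fraction:.2f} -> {result.label}")
```

prints

```
scenario_sequestered: mode=2124.0 mean=2123.34 fwhm=9.55 d_mean=+5.71 f_hat=0.99 -> sequestered
scenario_not_sequestered: mode=2118.0 mean=2117.63 fwhm=13.39 d_mean=+0.02 f_hat=0.00 -> not_sequestered
scenario_partial: mode=2123.0 mean=2120.04 fwhm=14.25 d_mean=+2.42 f_hat=0.50 -> partial
```

The fully sequestered sample's band moved +5.7 cm⁻¹ above the aqueous
reference and narrowed; the partial sample broadened (FWHM 14.25 vs 13.39)
and its centroid sits between the two environments, with a fitted sequestered
fraction of 0.50 against a ground truth of 0.5.

Mass verification of a C8-loaded construct:

```python
holo = rp.ProteinSpecies("EcACP", SEQ, "holo")
acyl = rp.ProteinSpecies("EcACP", SEQ, "acyl", probe="C8")
# holo mass 8979.77 Da, C8-acyl mass 9101.93 Da, shift +122.16 Da
series = rp.deconvolute_series(observed_mz)   # -> 9101.93 Da, SD ~1e-12
rp.verify_loading(acyl, series.mass)          # -> match
```

The same functionality is available from the shell:

```bash
ramanprobe simulate -f 0.5 --seed 1 --outdir sim/
ramanprobe process sim/sample.txt --out processed.txt
ramanprobe stats processed.txt
ramanprobe classify --sample processed.txt --reference reference_processed.txt
ramanprobe mass --sequence GG...G --state acyl --probe C8
ramanprobe deconv peaks.txt
ramanprobe run --seed 1 --outdir run/
```

sklearn-style estimators (`RamanPreprocessor`, `PeakStatsExtractor`,
`SequestrationClassifier`) expose the same chain for array-shaped workflows
and model selection; see `tests/test_estimators.py`.

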