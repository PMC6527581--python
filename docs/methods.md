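# Methods

## The measurement and the model

A terminal-alkyne fatty-acid mimic (4-pentynoic, 7-octynoic or 12-tridecynoic
acid — C5, C8, C13 by carbon count) is loaded enzymatically onto the
4′-phosphopantetheine arm of a carrier protein. The alkyne C≡C stretch near
2100 cm⁻¹ lies in a region free of protein and solvent bands, and its
frequency reports the probe's solvation: lower in water, higher in the
protein's hydrophobic cavity. Because the vibrational lineshape averages over
configurations interconverting faster than roughly 10 ps, the band shape
directly maps the population of environments: a rigid upward shift means the
chain is sequestered, an unshifted band means it is not, and a broadened band
covering both frequencies means partial sequestration. This package operates
entirely at that empirical level; it does not attempt physics-based lineshape
prediction (molecular-dynamics/fragment-potential spectral simulation) or
exchange-kinetics modeling.

The two-state band model used throughout is a pseudo-Voigt mixture

    I(ν) = A · [(1 − f) · V(ν; ν_aq, w_aq, η) + f · V(ν; ν_aq + Δ, w_seq, η)]

with V a unit-peak-height (1−η)·Gaussian + η·Lorentzian profile of FWHM w.
`f` is the fraction of the probe population in the sequestered environment —
a deliberate simplification: a continuum of environments is also summarized
by a single f, and results flag the two-state assumption implicitly by
reporting the fit residual.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| ν_aq | 2118 cm⁻¹ | aqueous band center |
| Δ (delta_seq) | +6 cm⁻¹ | sequestration shift (positive = hydrophobic) |
| w_aq / w_seq | 14 / 10 cm⁻¹ | component FWHM; the buried band is narrower (less inhomogeneous broadening) |
| η | 0.5 | Gaussian/Lorentzian mixing |
| amplitude | 1000 counts | band peak height |
| axis | 1950–2350 cm⁻¹, 1 cm⁻¹ step | covers the 2000–2300 analysis region with margin |
| n_exposures | 30 | co-addable 60 s acquisitions |
| noise | σ = noise_scale·√(mean counts), noise_scale = 1 | Gaussian approximation to CCD Poisson counting noise, independent per point and exposure |
| baseline | cubic, coefficients (220, −35, 25, −8) on the [−1,1] axis | smooth, strictly positive, exactly representable by the degree-7 fit |

These center/width values are synthetic working values chosen to be realistic
for an alkyne stretch analyzed in a 2100–2130 cm⁻¹ window; they are not
measurements of any specific probe/protein pair. With 30 co-added exposures
the per-point noise on the normalized spectrum is ≈0.6% of the peak — the
"high signal-to-noise" regime of a ~2 h accumulation.

Not emulated: instrument response and wavelength-dependent detector
efficiency, wavenumber-calibration error, motional-narrowing/exchange
lineshape physics, correlated (non-white) baseline drift between exposures.
Passing tests therefore demonstrate the correctness and stability of the
analysis chain under the stated noise model, not robustness to every
instrumental artifact of real spectra. Cosmic-ray spikes can be injected
(`cosmic_ray_rate`, default off) to exercise the despike step.

## Preprocessing

Exposures are co-added by the point-wise **mean** (default) rather than sum,
so noise scales stay comparable across different accumulation times; `sum` is
available. The baseline is established on 2000–2300 cm⁻¹ with a hole cut over
2100–2130 cm⁻¹ and fit with a seventh-degree polynomial by linear least
squares. Numerical choices:

* The fit axis is mapped to [−1, 1] over the baseline window before building
  the Vandermonde matrix. A raw-axis power basis at ν ≈ 2000–2300 raised to
  the 7th power has condition numbers around 10¹⁸; the mapping changes
  nothing mathematically. Rank deficiency after conditioning raises.
* Window endpoints are inclusive, and points exactly at 2100 or 2130 belong
  to the hole: excluded from the baseline fit, included in peak statistics.
  One convention had to be fixed; both windows are configurable.
* Post-subtraction negative intensities are preserved in the spectrum.
  Clipping before normalization would bias the centroid; the centroid clips
  negatives inside its weights only.
* Normalization divides by the maximum inside the peak window, so the band
  maximum is exactly 1.0; a non-positive window maximum (no detectable band)
  raises rather than producing a meaningless scale.
* Despiking (off by default, since it is not part of the faithful default
  chain) replaces points deviating from the cross-exposure median by more
  than z (default 8) robust SDs. The per-point MAD across a small number of
  exposures is itself noisy, so the MAD track is smoothed along the axis with
  a width-15 median filter before thresholding — counting-noise scale varies
  slowly with the signal; a single-point spike does not.

## Peak statistics

"Inspection" statistics are operationalized deterministically: the **mode**
is the grid argmax in the peak window with exact ties broken toward lower
wavenumber (logged); the **mean** is the intensity-weighted centroid over the
window; the **FWHM** walks outward from the mode to the first half-maximum
crossings and interpolates linearly, using the crossings nearest the mode so
distant noise-induced crossings cannot capture the width. Crossings may fall
outside the peak window but must lie inside the baseline window; a band still
above half maximum at the edge raises a truncation error. The |mode − mean| ≤
one grid step property of symmetric bands holds when the band's tails are
approximately balanced within the window; a wide Lorentzian centered near a
window edge genuinely violates it because the asymmetric clip drags the
centroid, which is a property of windowed centroids, not an implementation
artifact.

## Two-state decomposition and classification

The sample is modeled as a nonnegative combination of the processed reference
lineshape R(ν) and a copy of it shifted by Δ and width-scaled by s about the
reference mode:

    I(ν) ≈ a_aq·R(ν) + a_seq·R(c + (ν − c − Δ)/s),   f̂ = a_seq/(a_aq + a_seq)

solved by NNLS on a grid of Δ ∈ (0, 15] cm⁻¹ (step 0.25, bounded to prevent
aliasing onto baseline artifacts) and s ∈ [0.5, 1.3] (step 0.05). The width
scale is part of the default model, not an optional extra: the sequestered
band is narrower than the aqueous one, and with mismatched component widths a
rigid-shift fit systematically misattributes amplitude — under the default
generator it misses the true fraction by up to ≈0.25 at mid-range f, versus
≈0.02 with the width grid. Axes are reconciled by linear interpolation onto
the coarser axis.

Degenerate case: a sample identical to its reference makes (f, Δ)
unidentifiable at Δ→0. The fit therefore reports f̂ = 0 unless the best
two-component fit improves the single-component residual by more than 15%
(relative). Measured on the default generator, spurious improvement on f = 0
samples stays below ~9% while genuine two-state structure at f = 0.10 already
yields >60%, so the guard costs essentially no sensitivity.

Classification applies an explicit rule to the centroid shift d_mean and f̂:
`not_sequestered` if d_mean < θ_low and f̂ < f_lo; `sequestered` if
d_mean ≥ θ_high and f̂ > f_hi; `partial` otherwise. Defaults θ_low = 1.5,
θ_high = 3.0 cm⁻¹, f_lo = 0.25, f_hi = 0.75. These are package conventions
that make a visual judgment reproducible — they are not measured constants —
and every result echoes the thresholds it used. The conjunctive rule is
deliberately conservative: both the nonparametric shift and the model-based
fraction must agree before a confident call, everything else is `partial`.

## Mass verification

Expected masses: protein = residue-mass sum + H₂O (pyteomics tables, 20
standard residues only, invalid characters rejected by position); holo = apo
+ Ppant (C₁₁H₂₁N₂O₆PS, monoisotopic 340.0858 Da); acyl = holo + acid − H₂O.
Intact-protein comparisons default to **average** mass, since a deconvoluted
intact MW is an average-mass quantity; monoisotopic is supported everywhere.
N-terminal Met processing is not modeled and His-tag/vector residues are not
auto-appended — the input sequence is taken as the mature construct.

Charge-series deconvolution assumes consecutive, positively protonated
charge states of one species (higher charge at lower m/z). For each candidate
charge of the highest-m/z peak, per-peak neutral masses z·(m/z − 1.007276)
are computed and the assignment minimizing their standard deviation wins; the
reported mass is the per-peak mean. Two flags accompany the result: an
ambiguity flag when a competing assignment's SD is within 2× of the best, and
a warning when even the best SD exceeds a sanity bound (default 2 Da).

## Determinism and problem sizes

Every stochastic step derives from an explicit integer seed
(`numpy.random.default_rng`); identical configuration and seed reproduce
reports bitwise. The test suite and the acceptance script run on desk-scale
problems — 401-point spectra, 30 exposures, tens of replicates per scenario —
chosen because the estimators' errors are already well-resolved at that size
(fraction-recovery error ≈0.004 against a 0.05 budget).

## Known limitations

* The two-state model summarizes any environment distribution by one f;
  strongly multimodal or continuously graded environments are reported as
  partial with an elevated residual rather than resolved.
* The reference lineshape is taken as noiseless truth; reference noise
  propagates into f̂ (mitigated by co-adding reference exposures).
* FWHM is meaningful only for a single dominant band; resolved doublets
  report the width of the taller component's half-maximum interval.
* Windowed centroids are compressed when band tails leave the analysis
  window, so d_mean understates the true center shift for very broad bands.
* File support is deliberately plain-text XY/CSV; vendor binary formats and
  JCAMP-DX are out of scope (extension point in `ramanprobe.spectra`).
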