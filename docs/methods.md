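# Methods

## The focused mismatch-compression model

The simulator is phenomenological: it reproduces the *spectral* structure
of differential LFP (∂LFP) recordings under DBS, not the biophysics of
field generation. Four layers are composed:

**Brain layer.** All sources live on a high-rate "tissue" grid of
4220 Hz for 20 s (84,400 samples), ten times the device output rate. Two
neural sources feed the two recording electrodes: `x1` carries a
stationary 15 Hz sinusoid (amplitude 2·10⁻³ model units) plus 1/f
background; `x3` carries independent 1/f background only. The 1/f
components are synthesized by frequency-domain shaping of white Gaussian
noise (amplitude envelope ∝ f^(−1/2), DC dropped), normalized so each
realization's RMS equals the configured strength (1·10⁻³ by default), and
seeded per source from a single parent seed. The stimulation artifact is
a truncated Fourier series of `n_harmonics = 6` harmonics of
`f_T = 130` Hz; the device's over-range marker (ORM) is a constant
105.5 Hz tone. All model amplitudes are dimensionless model units; only
ratios enter any reported quantity.

**Lead layer.** Each electrode has a purely resistive impedance
(`Z1`, `Z3`); the channel's internal impedance is `Z_b = 10⁴` Ω. The
impedance mismatch `|Z1 − Z3|` controls how much stimulation survives
common-mode rejection.

**Amplifier layer.** An ideal differential stage (infinite CMRR)
computes `(x1 − x3) + min(1, |ΔZ|/Z_b)·S + ORM`. The leakage law is a
voltage-divider-style line through the single published calibration
point — 0.5 V leaked from 5 V at a "typical" 1000 Ω mismatch — and is
config-replaceable. The ORM is injected after the difference because it
is device-generated, hence never differenced away. The signal amplifier
is one of `linear` (`g1·g2·v`), `hard_clip`
(`g2·clamp(g1 v, ±clip_level)`), or `soft_clip` (`g2·tanh(g1 v)`,
the realistic gain-compression model); `g1 = g2 = 1`.

**ADC layer.** A plain 10-fold decimation (keep every 10th sample) to
422 Hz, deliberately without an anti-alias filter: undersampling the
residual artifact is the mechanism that folds its harmonics in-band. An
optional first-order 100 Hz low-pass (mirroring the device's analog
filter) can be enabled pre-decimation. Trailing samples not divisible by
the factor are truncated.

## Stimulation waveform: weights and phases

Two choices here were genuinely open, and both matter because the
waveform meets a nonlinearity.

*Harmonic weights.* The default roll-off is 1/k. The alternative
`"pulse"` rule uses the closed-form Fourier magnitudes of a 90 µs
biphasic rectangular pulse, |c_k| ∝ sin²(πk f_T τ)/k — but for so narrow
a pulse these *grow* almost linearly in k over k = 1..6, and at clinical
voltages the leaked artifact then drives the tanh into square-wave-like
saturation whose high-order products bury the low-order peak taxonomy.
With 1/k weights the leaked artifact at 6 V and 1000 Ω mismatch spans
roughly ±1.5 model volts, the mild-compression regime in which the
regenerated harmonics decay beyond the truncation order and the 66 Hz
alias of the 7th harmonic is the dominant intermodulation line — the
regime the analysis chain is designed to grade.

*Phases.* The harmonics are zero-phase **cosines**, i.e. the Fourier
series of an even-symmetric pulse. Phase alignment between harmonics
changes intermodulation amplitudes even though it leaves each tone's own
power untouched: with zero-phase sines, a coherence cancellation
suppresses precisely the 7th-order product (measured ~10 dB below the
8th in a direct FFT of `tanh(artifact)`), inverting the expected IMH
ordering. Cosine alignment restores the physically expected behavior of
a compressed pulse train: the first regenerated harmonic beyond the
truncation is the strongest, decaying monotonically with order.

## Spectral analysis

Welch PSD with the device's analysis settings: 844-sample
Blackman–Harris window, zero-padded to 1024 FFT bins, 0 % overlap,
density scaling, no detrending; powers reported as 10·log₁₀(Pxx). A 20 s
recording at 422 Hz yields exactly 10 averaged segments on a
422/1024 ≈ 0.412 Hz grid, which places the 105.5 Hz ORM exactly on
bin 256, and the named artifact frequencies 32/64/66 Hz within half a
bin of grid points.

Band powers aggregate logPSD bins over half-open windows `[lo, hi)`
(adjacent bands never double-count a bin); the DC bin is always
excluded, since the hardware's 0.5 Hz high-pass makes it meaningless.
Two band schemes are built in: the standard clinical set
(δ 1–4, θ 4–8, α 8–14, β 14–30, γ 30–50 Hz) and the artifact-avoiding
adjusted set (β* 14–20, γ* 40–50 Hz) that excludes every forecast
artifact frequency without extending any band.

Peak detection is candidate-based: a candidate is "found" when a local
maximum within ±1 bin exceeds the median of its ±2 Hz neighborhood by
6 dB (far below the ≥20 dB artifact excursions at the default
parameters). Requiring a local maximum rejects the mainlobe skirt of a
strong off-center neighbor — essential next to the 64 Hz line, whose
skirt otherwise registers at 66 Hz. With zero tolerance only the exact
bin is tested and the local-maximum condition is waived.

## Mitigation pipeline

On the logPSD, in order: (1) least-squares polynomial baseline of order
4, fit over 1–105 Hz against frequency in Hz on a linear axis and
subtracted everywhere; (2) band powers in the adjusted scheme;
(3) median aggregation. The fit range stops below the ORM so the marker
tone cannot steer the baseline; artifact bins are *not* masked — the
median and the adjusted windows absorb them. The fit uses a scaled
domain internally for conditioning and reports plain coefficients.

The pipeline stabilizes bands that host artifacts: across a 0–8 V sweep
at 1000 Ω mismatch, the γ-band spread shrinks versus the standard-band
mean (the 32 Hz alias sits inside standard γ). In bands that contain no
artifact the simulator's distortions are purely narrowband, so there is
little broad-spectrum variability to remove there and the unmasked
baseline — steered by artifact lines that stand ~100 dB above the noise
floor, a direct consequence of the six-orders-of-magnitude
stimulation-to-oscillation scaling — contributes jitter of its own. The
pipeline's benefit in such bands appears with broad-spectrum session
variability (gain changes, physiological drift), which this generator
deliberately does not emulate.

## Diagnostics

`GCr = P(64 Hz) − P(66 Hz)` in dB, each power the maximum within ±1 bin
of the target. Larger is less compressed; the ratio is invariant to any
constant dB offset. The defaults (64, 66) are configurable. ORM power is
read at the 105.5 Hz bin with a discernibility flag from the peak test;
because the injected tone never changes, falling ORM power tracks
compression and a lost peak flags saturation.

## Synthetic-experiment fixtures

The voltage sweep simulates one recording per amplitude
(0, 2–8 V by default, 20 s each), reusing the same noise seed across
conditions (paired design) so artifact effects are not confounded with
background realizations. The chronic series emulates post-implant
electrode dynamics: a bounded random walk of weekly impedance mismatch
with step std 150 Ω/week for the first 10 weeks and 20 Ω/week after,
clamped to the observed 0–600 Ω range, with one simulated recording per
week at fixed stimulation settings.

## What the generator does and does not emulate

It reproduces: the 1/f-plus-oscillation spectral shape, the
mismatch-gated artifact leakage, amplifier compression and its
intermodulation products, undersampling aliases, the constant marker
tone, and the two-phase impedance dynamics. It does not emulate:
capacitive electrode impedance, finite CMRR, quantization or amplifier
noise, phase-spectrum distortion, non-stationary oscillations,
session-to-session gain changes, powerline interference, or
device-specific artifacts unrelated to mismatch compression (e.g. the
22–25 Hz peaks seen in vivo). Tests passing on this generator therefore
validate the artifact arithmetic, the compression fingerprints and the
pipeline mechanics — not robustness to every distortion of real
recordings.

## Numerical choices and degenerate inputs

* All tones start at zero phase (cosine convention for the stimulation
  series, as above); generators are deterministic given their seed, and
  the two 1/f sources draw independent child seeds from the parent.
* Zero amplitudes produce exact zero arrays; a tone at or above Nyquist,
  a retained harmonic above the grid Nyquist, or a non-positive
  rate/duration raises a configuration error rather than silently
  aliasing or dropping terms.
* tanh boundedness is strict mathematically but saturates to exactly
  ±g2 in float64 beyond |g1·v| ≈ 19; below |g1·v| = 0.01 the soft clip
  matches the linear amplifier to 0.01 %.
* Welch requires at least one full segment; band power requires at least
  one in-band bin; the baseline fit requires at least order+1 bins in
  range.
* Problem sizes: every simulated condition is 20 s (8,440 output
  samples, 10 Welch segments); sweeps use 8 conditions and the
  across-seed diagnostics 4–6 seeds, sizes at which every reported
  quantity is stable to well under its decision margin.

## Known limitations

* The leakage law is a one-point calibration; real leakage depends on
  frequency-dependent (capacitive) impedance.
* The unmasked polynomial baseline is artifact-steered when artifact
  lines are extreme; masking or robust regression would decouple it but
  would depart from the plain fit-and-subtract pipeline this package
  models.
* GCr is a relative diagnostic; it is not calibrated to a physical
  compression percentage.
* Phase distortion of the compressed signal is not modeled or analyzed;
  all outputs are power-spectral.
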