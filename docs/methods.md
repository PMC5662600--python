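# Methods

`ieegpac` re-implements, as a tested reusable pipeline, the intracranial
analysis used to ask whether low-frequency rhythmic stimulation (sinusoidal
transcranial alternating current, tACS, at 0.75 or 1 Hz, or 50-ms acoustic
noise bursts at the same rates) entrains sleep rhythms.  The package covers
band decomposition, stimulation-artifact modeling, cycle-wise
phase-amplitude coupling (PAC) with a phase-randomization surrogate test,
sleep-event detection, pre/post power comparisons, and electrode-level
electric-field projection, and ships a synthetic iEEG generator that
provides ground truth for every stage.

## Signal model and conventions

All narrowband quantities come from a complex Morlet wavelet filter
parameterised by centre frequency `fc` and bandwidth `bw`.  **Bandwidth is
defined as the full width at half maximum (FWHM) of the wavelet's
frequency-domain magnitude response** (the Gaussian gain is 0.5 at
`fc ± bw/2`).  This makes the fast-spindle band (14, 7) cover 10.5–17.5 Hz
at half amplitude, cleanly split from the slow-spindle band (10, 5).  The
definition of "bandwidth" for a Morlet filter is genuinely open (passband
width vs wavelet sigma); FWHM was chosen and is flagged for sensitivity
analysis.  Canonical bands: fast spindle (14, 7), slow spindle / alpha
(10, 5), theta (7, 3.5), gamma (90, 40) = 70–110 Hz, slow oscillation
(1, 1) and (0.75, 0.75).

Phase convention, anchored package-wide: the instantaneous phase of
`cos(2π fc t)` is **0° at the signal peaks**, ±180° at the troughs.  For
slow oscillations 0° is the cortical upstate on most surface electrodes;
for tACS 0° is the positive (anodal) peak of the fitted stimulation
fundamental.  Filtering is FFT-based (spectrum × one-sided Gaussian),
reflect-padded by one wavelet support (4 temporal sigma) per side with the
pads discarded; samples within one support of an edge are exposed via
`edge_samples` so cycles overlapping them can be flagged.

## Stimulation-artifact model

During sinusoidal tACS the recorded artifact exceeds the neural signal more
than ten-fold.  It is modelled per channel and per stimulation block as
`dc + Σ_k a_k cos(2π k f0 t) + b_k sin(2π k f0 t)` with harmonics up to
40 Hz (`K = floor(40/f0)`).  Coefficients are linear least squares; the
base frequency is refined over `f0_init ± 1%` by a bounded derivative-free
1-D minimisation of residual variance (`scipy.optimize.minimize_scalar`,
bounded Brent — same search class as golden section with faster
convergence).  The search evaluates the objective on strided samples (still
> 4× the highest harmonic) and the final coefficients are solved on all
samples.  Fit quality is the residual-to-total variance ratio; blocks above
0.2 are flagged "poor removal" and excluded, mirroring the electrode-discard
practice for badly removed artifacts.  Whether one global `f0` or one per
channel should be fit is unstated in the source analysis; per-channel was
chosen and is recorded in the output metadata.  Trapezoidal stimulation
waveforms produce broadband artifacts outside this model class; the API
refuses to fit them and analysis proceeds on stimulation-free intervals
instead.

## Cycle-wise PAC

The modulation index is `r = |⟨A_HF(t) e^{i φ_LF(t)}⟩|`, the time average
pooled over all retained samples of all retained cycles (not per-cycle
means averaged).  `r` is reported unnormalised, in the amplitude's units;
a dimensionless companion `r/⟨A⟩` is reported for cross-channel comparison
(for a noise-free channel with envelope modulation depth `d`,
`r/⟨A⟩ = d/2`).  The preferred phase is the argument of the same average.

Cycles are segmented from the continuous LF phase (successive 360°
crossings of the unwrapped phase; a final cycle whose boundary falls within
one sample of the end counts as complete, so a 5-min block at 1 Hz yields
exactly 300 cycles and at 0.75 Hz exactly 225), or from trigger onsets with
cycle duration equal to the mean inter-stimulus interval (acoustic).

Cycle filters:

* **Outlier power**: a cycle is rejected when its mean HF power strictly
  exceeds `median + 2·IQR` of all cycle powers in that electrode (single
  pass; the threshold is not recomputed on the retained set).  The phrase
  "exceeds two times the interquartile range" is scale-ambiguous; the
  median-referenced reading is the default and the literal `power > 2·IQR`
  variant is available (`rule="2iqr"`).
* **Amplitude floor** (endogenous phase only): cycles whose *peak*
  SO-band envelope is below 50 µV are rejected.  Whether the floor applies
  to peak or mean amplitude is unstated; peak was chosen.

For endogenous phase (extracted from non-sinusoidal slow oscillations, so
non-uniform by construction) a rank-based **histogram equalization** maps
the sorted retained phases onto equally spaced points around the circle,
anchored at the smallest input phase (an already-uniform grid is a fixed
point; rank order is preserved).  A consequence worth knowing: the
equalization warps the phase coordinate wherever the retained-phase
distribution is asymmetric, so recovered preferred phases live in
equalized coordinates.  On synthetic ground truth the warp is ~10° for a
coupling injected at 40° and vanishes at the symmetric point 0°, where
parameter recovery is assessed.

## Surrogate test and its calibration

Significance is assessed by rotating the LF phase of each cycle by an
independent uniform draw, the *same* draw applied to every electrode for a
given cycle, repeated `n_shuffles = 10,000` times;
`p = max(#(r_surr ≥ r_obs), 1)/n_shuffles`, so the smallest attainable p is
exactly 1e-4.  Only the per-cycle complex sums are needed, which makes the
test a single matrix product.

The default shift range is the literal **[0°, 180°)**.  A quantitative
caveat discovered while validating the package: with half-circle shifts the
surrogates are mutually aligned but systematically rotated (E[e^{iδ}] =
2i/π ≠ 0) relative to the observed statistic, which inflates the surrogate
null and makes the test *conservative* — measured type-I error ≈ 0.005 at
α = 0.05 on an ideal rotation-symmetric null.  The full-circle
`shift_range_deg=360` option is exactly calibrated (measured ≈ 0.05) and is
what the calibration checks exercise; the default follows the original
design (fidelity over convention) and errs on the safe side.  A second
caveat: when the HF envelope varies slowly (spindle-band correlation time
~50 ms), per-cycle sums become mildly elliptical and even the calibrated
test runs slightly hot (~0.07); with fast envelopes (gamma band) it is
nominal.  Null simulations therefore use gamma-band envelopes.

Multiple comparisons: Benjamini–Hochberg FDR at q = 0.05 across electrodes
*within* one block; no correction across blocks (blocks measure
reliability) or bands (planned comparisons).  Cross-block consistency is
the fraction of electrodes significant in ≥ 2 blocks.  The Rayleigh test
(via `pingouin`) handles circular non-uniformity.

## Event detection

**Spindles**: band power (squared Morlet envelope) must cross 6× its
median; the event is grown to where power falls below a lower threshold
(mean + 1 SD of power; an absolute-1-SD variant exists), then filtered to
durations 0.2–2 s.  Events coinciding with broadband artifacts are
excluded: broadband power is 1–45 Hz (configurable) with the detection band
notched out — without the notch every strong genuine spindle lands in the
top decile of "broadband" power and self-excludes.  The exclusion statistic
is the event's *median* smoothed broadband power against the 90th
percentile of the whole-recording distribution; comparing the event
*maximum* against a per-sample percentile is statistically inconsistent
(any 1-s window max exceeds the sample 90th percentile with probability
~0.65), so the literal max-based variant is offered against a
window-maximum reference (`broadband_stat="max"`).  The event peak time is
the time of maximum band power (needed for phase preference).  On pure 1/f
noise the detector fires at ~2.8 events/min with default thresholds
(regression-tested at < 3/min).

**Slow waves**: negative-going zero crossings of the (0.75, 0.75) Hz
filtered trace, paired when separated by 0.5–2 s; the down-state is the
filtered-voltage minimum within the pair.  Events with down-states
shallower than 10 µV are discarded: the bandpass response of an isolated
wave rings at the microvolt scale beyond the wave, and those tail ripples
would otherwise pair into spurious events (set `min_down_state_uv=0` for
the literal crossing rule).

**Rate comparison**: stimulus-locked event-count histograms are compared
by chi-square against the baseline histogram shape (expected counts scaled
to the stimulation total), dof = bins − 1.

## Coupling metrics

* Spindle–gamma alignment: Pearson cross-correlation of the two amplitude
  envelopes at each lag (envelopes low-pass smoothed at 5 Hz to suppress
  carrier leakage); positive lag means the first series precedes the
  second.
* Pre/post power: multitaper (DPSS, time-bandwidth 3, 5 tapers —
  Chronux-style defaults) band power of 30-s segments; log-ratio with a
  jackknife CI across tapers and a t-test on the pooled taper variance.
* Post-stimulation phase coherence (trapezoidal protocol): each 10-s
  stimulation-free window is fit with a sinusoid over a 0.5–1.5 Hz grid
  (step 0.01 Hz, linear amplitude/phase solve); per-trial phase is
  referenced to the window start; coherence is the resultant length across
  trials, tested with Rayleigh.  Fits pinned at the frequency-range edge in
  > 50% of trials raise a warning.

## Field projection

The stimulation voltage at each electrode is the amplitude of a
least-squares sinusoid fit at the stimulation frequency; channels with
> 1% of samples at the digitiser extremes are flagged saturated and
excluded.  Each electrode pairs with its closest same-array neighbour
within 10 mm (grids/strips) or 5 mm (depth; Euclidean distance on the
implanted coordinates), and the projected field is |ΔV|/distance in V/m,
normalised to 1 mA.  Amplitude fitting loses sign, so amplitudes are signed
by their fitted phase relative to a stimulation reference (within 90° →
positive): anti-phase neighbours correctly sum their amplitudes.  The
projection captures only the field component along the pair axis and never
exceeds the true gradient magnitude.

## Synthetic data: what it emulates, and what it does not

Per channel (independent sub-streams spawned from one seed; identical
configs are bit-identical):

* **Slow oscillations as unitary events**: Hann-windowed cosine snippets
  of 1–2 cycles, frequency drawn per event from 0.5–4 Hz, ~15 events/min,
  ~200 µV peak over a 15 µV-RMS 1/f background.  The slow-wave spectrum is
  broadband with no narrow peak, and rhythmicity never outlasts two cycles
  — the reason continuous low-frequency stimulation aligns poorly with
  these irregular events.
* **Coupled spindle/gamma activity**: narrowband Gaussian noise whose
  envelope is gated to the events and multiplied by
  `1 + depth·cos(φ_event − preferred)`; between events a continuous
  background at half the burst envelope remains (sigma and gamma activity
  never vanish in real sleep EEG — this is also what makes median-based
  spindle thresholds meaningful).  A noise-free channel has normalised
  modulation index exactly `depth/2`.
* **tACS artifact**: cosine fundamental (0° at anodal peak) plus arbitrary
  harmonic coefficients, optional linear amplitude drift; **acoustic
  triggers**: exact 1/rate trains with optional Gaussian jitter; **outlier
  epochs**: broadband power × gain inside given intervals (voltage ×
  √gain).

Not emulated: volume conduction between channels, epileptiform discharges,
amplifier saturation waveform shape, respiration/cardiac rhythms, or sleep
staging dynamics.  Passing recovery tests therefore demonstrate that the
*pipeline arithmetic* is right under realistic SNR, not that the detectors
are clinically validated.

## Problem sizes used in the validation runs

Cycle accounting and detector checks run on 2–5-minute single-channel
signals.  Type-I calibration uses 200 null electrodes × 300 cycles with
2,000 shuffles (plus 50 × 100 electrode-sims for the FDR null at 1,000
shuffles).  Parameter recovery runs the full pipeline on 20 seeds × 2
channels of 40-minute recordings, truncating to a 300-retained-cycle
budget per channel — with a 5-minute endogenous block the 50 µV floor
retains only ~35–45 analyzable cycles, and detection of depth-0.5 coupling
is then underpowered in the same way 5-minute endogenous segments were in
the original study; the 300-cycle budget restores the intended operating
point.  The acceptance script uses 10 seeds for the recovery block to stay
well inside a desktop run.

## Known limitations

* The half-circle surrogate default is conservative (quantified above);
  power-sensitive applications should weigh `shift_range_deg=360`.
* Equalized preferred phases are coordinate-warped for asymmetric phase
  distributions (quantified above).
* The EDF writer is minimal (16-bit, 1-s records, integer sampling rates,
  truncates trailing sub-second samples); the HDF5 container is lossless
  and is the internal format.
* `time_frequency_response` requires epochs longer than the slowest
  wavelet (≈ 1.9 s at 5 Hz × 6 cycles) and equal epoch counts per
  condition (paired test).
* The chi-square event-rate comparison treats bins as independent;
  stimulus-locked events in adjacent bins are not.
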