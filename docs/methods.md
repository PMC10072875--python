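# Methods notes

This note records the models, parameter choices, numerical decisions and
known limitations behind each stage of the package. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal containers and conventions

Signals are stored as flat little-endian float64 binary plus a JSON
sidecar (format version, per-channel fs/t0/units/byte layout) — exact on
round trip and inspectable without the library. All times are seconds
from session start as 64-bit floats, sample indexing is 0-based, and
every window is half-open `[start, end)`. Trial tables are plain UTF-8
CSV with a mandatory header; session metadata rides in `#`-prefixed
comment lines so one file is self-contained.

## Spectral analysis

The CWT uses a complex Morlet with center frequency ω₀ = 6 rad (the
common default that balances time and frequency resolution near 8 Hz),
mapped onto PyWavelets' `cmor` parameterization (bandwidth 2, center
frequency ω₀/2π). The frequency grid is log-spaced, 48 voices over
1–100 Hz. Both are configurable. Power is the squared coefficient
modulus; scales are evaluated one at a time so memory stays at a single
complex row even for 10-minute records.

"Peak normalization" divides the spectrogram by its single global
maximum before the log₁₀ transform (a per-frequency-row variant sits
behind a flag); normalized values are floored at 1e-15 so silent bins
cannot produce −inf while the global maximum stays exactly 0. Edge
samples inside the cone of influence are retained; the e-folding margin
at the lowest frequency is reported in the spectrogram's params so
alignment code can warn when windows are too short.

ECoG synthesis and analysis run at 1 kHz. Nothing in the stack looks
above 100 Hz, so higher acquisition rates are assumed decimated upstream
(an anti-aliased `decimate` helper is provided).

## Seizure detection

The detector thresholds 7–10 Hz band power at median + k·MAD (default
k = 6). No published numeric threshold exists for this preparation;
an adaptive robust threshold was chosen deliberately so that detection is
invariant to amplitude scaling of the recording (asserted by test).
Sub-0.5 s gaps are merged before the duration rule so waxing–waning
discharges are not fragmented. The peak-frequency veto computes the
spectral argmax on *whitened* power (each frequency row divided by its
own temporal median): on raw power the 1/f background always places the
argmax at the lowest grid frequency and every event would be discarded,
while whitening attributes the peak to the event-specific elevation. A
detected event is accepted only if that peak lies in 7–10 Hz.

"Within 10 s of the trial" is anchored on the full trial interval
(initiation to choice) by default; a cue-anchored variant is selectable
because the two phrasings appear interchangeably in the field.

## Synthetic data

The generators are first-class, tested code; every one is a pure
function of (parameters, seed) and returns machine-readable ground
truth.

- **ECoG**: Gaussian noise shaped to a 1/f power spectrum, Butterworth
  band-limited to 0.1–100 Hz, RMS 100 µV. SWDs are Poisson-placed
  (default 0.3/min), duration uniform on 2–30 s, fundamental uniform on
  7–10 Hz, waveform = fundamental + half-weight 2nd harmonic + a sharp
  rectified-sinusoid "spike" component, 0.2 s cosine ramps. This
  reproduces the fundamental/harmonic spectral signature the detector
  keys on without claiming biophysical realism. Event amplitude defaults
  to 5× background RMS; no published amplitude ratio exists for this
  preparation, so the value is a stand-in exposed in config.
- **Sessions**: cue lengths and correct sides tiled to near-equal counts
  then shuffled; omission and correctness drawn per cue length from a
  psychometric table; log-normal reaction times with a slower median on
  incorrect trials; a 30 s timeout follows errors; optional
  port-perseveration probability.
- **Photometry**: 20 Hz dual wavelength. 470 = 100·(1 + transients) +
  motion + noise; 405 = 50 + motion + noise. Transients are peak-1
  rise/decay double exponentials (τ_rise 0.2 s, τ_decay 0.6 s, 0.1 s
  onset latency) so the stated amplitude is exactly the peak dF/F to
  recover. Motion is unit-SD low-passed (1 Hz) Gaussian noise shared
  across channels.
- **Laminar LFP**: a target CSD profile (sink −1, sources +0.5, alpha
  time course) is inverted by double cumulative summation across depth
  plus a random per-time linear ramp, so the CSD operator recovers the
  injected pattern to machine precision at zero noise. 10 sweeps per
  intensity, 100–500 µA.
- **IPSP trains**: 20 TTLs at 40 Hz over 0.5 s; each pulse releases
  independently with probability p, evoking a hyperpolarizing
  double-exponential IPSP (decay 8 ms, peak-normalized).
- **Noisy current**: 150 pA DC + 10 pA white Gaussian noise through a
  unit-area 3 ms alpha kernel and a 4th-order 100 Hz low-pass.
- **Spiking**: leaky integrate-and-fire (τ_m 20 ms, R 200 MΩ, rest
  −70 mV, threshold −50 mV, reset −60 mV, 2 ms refractory — chosen to
  give ~15–35 spikes per 0.5 s under the standard current; no cell model
  is prescribed by the experimental literature this emulates). Light
  inhibition is modeled as a per-threshold-crossing stochastic veto: with
  probability equal to the inhibition fraction the membrane is reset (the
  hyperpolarization) but no spike is emitted. A literal added conductance
  has no closed-form mapping from conductance to fractional spike
  reduction; the veto construction makes the expected reduction equal the
  requested fraction exactly, which is the property downstream analyses
  are validated against.

What the generators do *not* emulate: biophysical seizure generation,
bleaching or hemodynamics in photometry, electrode drift, correlated
channel noise, or any within-session nonstationarity. Passing tests
demonstrate the *analysis operators* are correct on signals with the
stated statistical structure, not that the structure matches any
particular recording rig.

## Photometry processing

The regression fit is closed-form least squares; the corrected trace is
sig − (a·ref + b) + mean(sig). Restoring the mean keeps the session
median positive and dF/F magnitudes comparable with uncorrected data
(the subtraction alone would center the trace near zero and break median
normalization). The dF/F median is taken over the whole session — a
sliding-window variant is a config flag but is not the default because a
single session-wide median is the simplest reading of the procedure and
the generators contain no bleaching to detrend.

`peak_amplitude` is baseline-subtracted (max over the cue window minus
the 1 s pre-cue baseline mean); the raw maximum is emitted alongside as
`peak_raw` since either convention appears in practice.

## CSD

Edge channels are dropped (no Vaknin padding by default) because the
quantified components live on interior channels; padding is available
behind a flag. Tissue conductivity is deliberately omitted so units are
V/mm². Component windows (channel range × latency × expected sign) are
configuration, not ground truth — published figures mark components
graphically, not numerically — and a sign-discordant extremum warns
rather than errors.

## Intracellular metrics

Spike detection is an upward threshold crossing (default 0 mV) with a
2 ms refractory. The spike-reduction denominator is the no-light count,
which bounds complete silencing at 100 %; the alternative reading
(light-count denominator) is emitted alongside because the verbal
formula is ambiguous. IPSP failures use |deflection| < 0.25 mV against a
2 ms pre-TTL baseline within a 25 ms half-open post-pulse window (40 Hz
pulses abut exactly); the absolute value makes the classification
insensitive to IPSP polarity at rest. The 2 ms baseline is the shortest
window that stays robust to the previous IPSP's decay at 25 ms spacing.

## Behavior

Accuracy excludes omissions from its denominator (omission rates are a
separate metric). Repetitive responding counts *disjoint* blocks of five
within each maximal same-port run — floor(L/5) — normalized by responded
trials; a sliding-window variant (L−4 per run) is available since
"blocks of five consecutive trials" admits both readings. Reaction time
defaults to the cue-offset anchor; the initiation anchor is selectable,
and no single definition is asserted as canonical. Omission trials count
toward the 100-trial session cap (all initiated trials count).

## Decoding

Features are 11 summary statistics (mean, median, SD, min, max, range,
skewness, kurtosis, linear slope, integral, time-to-peak) over each of
the baseline and cue windows; the list is config-overridable. The raw
trace min/max columns are exempt from min/max normalization.

SMOTE interpolates between a random minority point and one of its k = 5
nearest minority neighbors at a uniform random fraction; Tomek cleaning
then removes the majority member of every cross-class mutual-nearest-
neighbor pair. Both are implemented in-package on sklearn
nearest-neighbor queries.

Rebalancing happens **inside each training fold only**. Resampling
before cross-validation leaks synthetic copies of held-out minority
points into training and biases the null above chance; the leakage-safe
ordering is the default and is guarded by a dedicated property test
(shuffled labels must stay within [0.4, 0.6] mean AUC across 20 seeds).
The resample-then-CV ordering remains available behind a flag for
comparison. XGBoost hyperparameters beyond the stated 80 %/30 %
subsampling are depth 3, 200 rounds, learning rate 0.1 — conventional
defaults, exposed in config. The real-vs-null comparison is a rank-sum
test over per-fold AUCs.

## Pipeline and problem sizes

A single global seed fans out to per-stage child seeds via
`SeedSequence([seed, stage_id])`, so each stage reproduces independently
of execution order; outputs are hashed into the run manifest and a rerun
is byte-identical. The default demo sizes — 600 s of 1 kHz ECoG, 60
trials, 20 Hz photometry, 10 laminar sweeps per intensity, 5 IPSP and
spiking sweeps per condition — mirror one realistic session per modality
and keep a full run near ten seconds on one core; the validation suite
uses 10 ECoG sessions for detector sensitivity and 50 sweeps per release
probability for failure-rate calibration.

## Known limitations

- The SWD detector is validated on the generator's waveform family;
  electrographic artifacts (chewing, movement) are out of scope beyond
  the duration and peak-frequency rules.
- CSD assumes uniform spacing and ignores conductivity anisotropy; no
  iCSD/kernel-CSD inverse methods.
- The decoder exposes no per-cue-length hyperparameter retuning; subset
  runs reuse the global configuration.
- Statistical group inference (ANOVA families, post-hoc corrections) is
  left to general-purpose statistics packages.
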