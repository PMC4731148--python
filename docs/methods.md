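# Methods

This note documents the model, the numerical choices, and the synthetic
data the package is validated on, in enough detail to judge what the tests
do and do not establish.

## Signal model and preprocessing

Recordings are continuous multichannel potentials sampled at 1000 Hz (one
sample = one millisecond; 0-based indexing). Preprocessing follows the
standard clinical-ECoG recipe: common average re-referencing over the good
channels (bad channels are user-masked, excluded from the average, and
passed through untouched), then a 3rd-order Butterworth band-stop at
58–62 Hz. The notch is applied forward–backward by default so that it is
zero-phase: group delay would otherwise skew template timing. Whether the
original analysis filtered causally is unknowable from the filter name
alone, so `zero_phase` is a config switch. The amplifier's 0.15–200 Hz
passband is treated as a property of the data; the simulator band-limits
accordingly rather than the pipeline re-filtering.

## Broadband spectral change B(t)

The broadband estimate is a reconstruction of the spectral-decoupling
methodology:

1. **Dynamic spectrum.** Morlet-family wavelets (~7 cycles) at 1 Hz steps
   over 4–200 Hz, excluding 58–62, 118–122 and 178–182 Hz so that notch
   residue cannot dominate the decomposition. Wavelets are applied in the
   frequency domain (analytic signal), giving power at every millisecond.
2. **Normalization.** Power at each frequency is divided by its mean over
   time and log-transformed. This removes the static 1/f^χ profile;
   what remains is power *change*.
3. **Decoupling.** PCA across time samples of the normalized log spectra.
   The first principal spectral component (PSC 1) is, for data whose
   dominant variance is a multiplicative power-law shift, a near-flat
   loading across frequencies. Its sign is fixed so the mean loading above
   80 Hz is positive. Decoupling is fitted once per channel across the
   whole recording: it is ignorant of class labels and timepoint selection,
   so it is not cross-validated.
4. **Timecourse.** Each millisecond's spectrum is projected onto PSC 1.
   The score is rescaled by the mean PSC-1 loading before exponentiation:
   what is exponentiated is then the reconstructed *mean log-power change*
   across the spectrum, a multiplicative power factor of order g² during an
   event, rather than a raw score whose magnitude grows with the size of
   the frequency grid (and whose exponential overflows). The exponentiated
   trace is smoothed with a Gaussian (σ = 25 ms — small enough not to blur
   a ~300 ms response, large enough to stabilize the exponential) and
   z-scored per channel.

Every stage (grid, cycles, σ, normalization) is exposed in
`PipelineConfig`; the defaults above are the package's reconstruction of
the cited methodology, not verbatim constants.

## Template projection

Templates are stimulus-triggered averages on −199 < t′ ≤ 400 ms (600
samples, both bounds inclusive in sample arithmetic), re-centered by their
mean over −199 < t′ ≤ 50 ms (250 samples). The projection at time τ
multiplies the template against the signal window after subtracting an
instantaneous baseline m(τ) computed over τ−199…τ+50. The printed form of
the baseline in the source methodology is a plain sum, while its prose
calls it an average; the average (sum/250) is the default and
`baseline_as_sum` preserves the literal sum. The continuous projection
Γ(t) is computed by FFT cross-correlation plus a sliding-baseline
correction and is required (and tested) to match the definitional per-ms
loop to 1e-6 relative tolerance. Γ is undefined within 199 ms of the
record start and 400 ms of its end; the decoder assigns the null class
there.

Null ("o") training points are drawn 4 per inter-stimulus interval, at
least 100 ms from stimulus offset/onset and 50 ms from one another,
sampled uniformly over the constraint set with a per-fold seed. Features
are retained when r² > 0.05, where r² is the squared point-biserial
correlation between a template's projections at its own class's events and
at the null points — computed on training data only, per fold.

## Classification and event picking

Fisher LDA with shared covariance: class means plus a pooled within-class
covariance with a ridge of 1e-6·trace/d for invertibility. Posteriors are
the softmax of the usual linear discriminant scores, so the three-class
null identity Pr{o} = 1 − Pr{F} − Pr{H} holds by construction. Priors are
uniform by default: the 4-per-ISI sampling makes null points ~4× as
frequent as either class, and empirical priors would let that imbalance,
rather than the signal, push the fixed 0.51 peak threshold; the
alternative is available as `empirical_priors`. Exact posterior ties in
known-onset classification break toward "face", with a logged warning.

Spontaneous decoding smooths each class posterior with a σ = 80 ms
Gaussian (kernel truncated at ±4σ, renormalized at record edges), then
accepts strict local maxima exceeding 0.51 in descending peak order,
rejecting any candidate within 320 ms of an accepted prediction — a
deterministic, order-independent realization of "the larger posterior
wins". Plateaus (exactly equal consecutive values) take their first
sample. The peak marks the alignment time of the templates, i.e. the
implied stimulus onset, which is why prediction times are compared to
onsets directly.

## Evaluation

A prediction is correct iff an event of the same class lies within 160 ms;
matching is one-to-one, nearest pair first, so neither an event nor a
prediction can be counted twice (an `any-within-window` reading would
allow double counting; the strict mode is the default and the only one
used in the tests). The captured fraction (denominator: events) and the
false-positive rate (denominator: predictions) are deliberately different
ratios and need not sum to one. Cross-validation is leave-one-run-out over
the three temporally contiguous runs; pooled metrics are event-weighted.

The random-guess baseline emits one uniformly random-class guess every
320 ms at a uniform phase across each run's stimulus span. For the 800 ms
onset-to-onset schedule the analytic values are: per-guess correct
(320/800)/2 = 0.2, captured fraction 0.5, false-positive rate 0.8, mean
timing error 80 ms; the Monte-Carlo guesser is scored by the same
`score_predictions` path as the decoder and converges to these values.

The paired permutation comparison flips A/B labels within pairs (sign
flips of paired differences), two-sided, with the +1 finite-sample
correction for the Monte-Carlo version and an exact 2^n enumeration for
n ≤ 20.

The collision-time sweep re-runs only the event-picking stage at a range
of collision times on the stored smoothed posteriors and reports false and
correct prediction counts; on well-separated (800 ms) events the correct
count is invariant and the false count decays monotonically, showing the
collision rule does not inform the decoder about stimulus timing.

## Synthetic data: what it emulates, and what it does not

Each channel is an independent 1/f^χ background (χ = 2 by default, slope
exact over ~0.5–200 Hz by frequency-domain shaping, band-limited above
200 Hz, default RMS 15 µV) plus a 60 Hz sinusoid (5 µV). Events add a
class-specific ERP waveform and multiply the background amplitude by
√(1 + (g−1)·env(t)) under a raised-cosine envelope spanning 0–400 ms — a
genuinely multiplicative power change, invisible in the stimulus-triggered
average potential when ERPs are zero yet visible in band power (the
ERP/ERBB dissociation the decoder exploits, asserted by test).

Single-trial variability in the presets: per-event lognormal response
scaling (CV 0.2, drawn per channel) and a per-event latency shift
(SD 30 ms) shared across channels as a global processing delay — real
single-trial latencies at these cortical sites vary by tens of
milliseconds and co-vary across sites; fully independent per-channel
latency draws would de-align the joint posterior in a way real data do
not. With perfectly stereotyped trials (variability 0, the default for
`ChannelSpec` so exact-recovery tests are exact) the LDA class clouds
collapse, posterior excursions become needle-thin, and the fixed σ = 80 ms
smoothing keeps them below the 0.51 threshold: realistic trial variability
is a *requirement* for the published operating point, not a nuisance.

The `high-snr` preset has 8 channels — per class one ERP-selective site
(~45 µV polymorphic ERP), one broadband-selective site (g = 4), one mixed
site (25 µV, g = 2), plus two null channels. Splitting selectivity across
sites makes the two feature kinds genuinely complementary: either feature
set alone captures ~86% of events, together ~95%, and ERBB-alone timing is
worse than ERP-alone — the qualitative pattern the method is designed to
exhibit. A `low-snr` preset (amplitudes ×0.25, g = 2) exists for stress
testing and is not used in acceptance checks; `tiny` (3 runs × 10 events,
3 channels) keeps unit tests fast.

What the simulator does **not** emulate: spatially correlated noise across
electrodes (channels are independent; common-average referencing therefore
mixes a fraction of each channel's signal into the others — visible as
weak "leaked" features that the r² selection occasionally picks up),
epileptiform or movement artifacts, narrowband alpha/beta rhythms with
event-related desynchronization, non-stationary drift across runs, and
semantic/novelty modulation of response magnitude. Passing tests therefore
show the pipeline recovers its own generative assumptions at realistic
SNR; they do not certify performance on clinical recordings.

## Problem sizes and determinism

The acceptance-level experiments use the full study geometry (3 runs × 100
stimuli, 8 channels, ~249 s of 1 kHz data per dataset) for five generator
seeds; one dataset takes roughly half a minute end-to-end, dominated by
the 182-frequency wavelet transform (per-channel spectra are held as
float32 and processed one channel at a time). All randomness flows through
explicit integer seeds (`numpy.random.SeedSequence` spawning per channel),
and a fixed seed reproduces every table and report bit-for-bit.
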