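# Methods

## The model

A virtual listener judges each stimulus against an adaptive criterion.
The only percept is the spectral centroid (SC) of the excerpt, and on
trial *n* the response is *bright* iff

    SC[n] > α · med({SC[n−1−k], …, SC[n−1]}) + (1−α) · med({long-term reference SCs})

The short-term term is the median SC of the trials within the last *L*
seconds of **stimulus** time (inter-trial silences are not counted),
walking backward over whole previous trials; the current trial is never
part of its own window and at least trial *n−1* is always included.
The median (rather than a leaky integrator) is used because the SC
distribution of naturalistic excerpts is skewed.  With α = 1 the model
is purely short-term (ST), with α = 0 purely long-term (LT), with
α = 0.5 an equal ST+LT mixture.  A lapse rate flips the
criterion-indicated response on a small fraction of trials, modelling
inattention; ties (SC exactly equal to the criterion) count as *dull*
(the criterion uses a strict inequality; ties have measure zero in
practice).  The first trial has no history: by default the model emits
no response there and the trial is excluded from aggregation
(`first_trial_policy="chance"` substitutes a coin flip).

Two long-term references are exposed, because they answer different
questions: `session_median` (the median over all N SCs of the running
session) and `unprocessed_domain_median` (the median SC of the
unfiltered corpus of the stimulus domain, a fixed internal reference).
The standalone LT model uses the fixed reference; inside the mixture
the session median is the default.

### Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| α | ST weight in the mixture | 1.0 | the ST model is the best-performing variant |
| L | integration length (s of stimulus time) | 16 | minimizes RMS error in model selection |
| lapse_rate | probability of a contrary response | 0.05 | standard psychophysical lapse allowance |
| lt_mode | long-term reference | session_median | see above |
| first_trial_policy | trial-1 behaviour | skip | no history exists to compare with |

## Stimulus synthesis

The generators emulate the *spectral statistics* of naturalistic
corpora, nothing more.

**Music** — an octave-band-shaped noise bed (white noise whose rFFT is
weighted piecewise-constant over the geometric octave regions
88 Hz–22 kHz) plus 4–8 amplitude-modulated (2–8 Hz) harmonic tones with
log-uniform F0s in 80–880 Hz, mixed 12 dB below the bed.  Each
excerpt's octave profile is a fixed, pop-music-shaped target profile
plus Gaussian per-band offsets.  The offset scale is
`heterogeneity_db · √(π/2) · 1.13`: the first factor converts a mean
absolute deviation into a normal σ, and the 1.13 compensates the
shrinkage of realized offsets through the synthesis/measurement chain
(adjacent octave filters leak into one another), determined once by
regressing measured against target offsets.  With the default spread of
1.8 dB the corpus reproduces a mean absolute per-band deviation of
~1.8 dB from the corpus grand mean.  Excerpts are 1, 2, 4 or 8 s,
peak-normalized to −3 dBFS, with 50 ms raised-cosine fades.

**Speech** — a glottal-like pulse train (F0 ≈ 120 Hz for male-labelled,
≈ 210 Hz for female-labelled speakers, 2% period jitter) shaped in the
frequency domain by a −6 dB/oct source tilt above 500 Hz, three
speaker-specific formant-like log-frequency Gaussian bumps, and a
per-gender spectral balance shift (±1 dB/oct by default), plus a
−20 dB noise floor.  Durations are truncated-normal with mean 2.0 s,
SD 0.26 s, clipped to 1.4–2.8 s.

**Transfer functions** — smooth random log-magnitude curves (sums of
log-frequency Gaussian ripples) made minimum-phase by cepstral
reconstruction on a 4096-point FFT grid.  The device response equals
the open-ear response plus a shelf of +contrast/2 dB below 1 kHz,
cosine transition, −contrast/2 dB above 4 kHz (region means exact by
construction), plus device-only ripple confined to the 1–4 kHz
transition.  Default contrast 6 dB.

**What the generators do not emulate:** melodic/linguistic structure,
temporal envelopes of real music, room acoustics, loudness calibration,
or the exact selection statistics of any real corpus.  Tests that pass
on these stimuli therefore establish the mechanics of the pipeline and
the internal consistency of the model, not quantitative predictions for
human listeners.

## Colorations

*Slope filtering*: the excerpt is split by a 5th-order Butterworth
octave filterbank (centers 0.125–16 kHz, geometric edges c/√2…c√2, top
band capped at 0.999×Nyquist), each band weighted by
`slope × log2(center/1 kHz)` dB, and the bands summed.  Gains are held
at the boundary values outside 0.125–8 kHz, so the 16 kHz band receives
the 8 kHz gain.  Filtering is zero-phase (forward–backward) by default:
the squared Butterworth magnitudes are power-complementary at the band
edges, which keeps the slope-0 chain flat within ±1 dB over
0.125–8 kHz without phase compensation; causal single-pass filtering is
available via `mode="causal"`.  Band levels are RMS energies in dB from
the same filterbank.

*Morphing*: transfer functions are combined linearly in log-magnitude
and unwrapped phase (2π-jump unwrapping from DC); m = 0 reproduces the
device and m = 1 the open ear exactly, m outside [0, 1] extrapolates.
Excerpts are convolved with the morphed impulse response, truncated to
the input length, and re-normalized only if clipping would occur.

## Spectral centroid

A single FFT of the whole excerpt (no window), bin magnitudes below
−90 dBFS zeroed (full scale referenced so a full-scale sinusoid reads
≈ 0 dBFS: bin level = 20·log10(2|X_k|/N)), magnitudes pooled into 128
bands spaced uniformly on the ERB-number (Cam) scale between 25 Hz and
20 kHz (Glasberg–Moore mapping, Cam = 21.4·log10(1 + 0.00437 f)).  Each
bin is assigned wholly to the nearest band center on the Cam scale;
triangular split-weighting is available behind a flag.  Linear
magnitude (not power) is pooled.  The FFT length, windowing and ERB
range are package choices — they are not uniquely determined by the
task — and are kept fixed across all analyses.

## Experiment designs

- Exp. 1: 350 2-s targets per session, 50 at each slope of
  {−2, −1, −0.5, 0, +0.5, +1, +2} dB/oct, uniformly random order.
  Speech sessions forbid consecutive trials by the same speaker
  (shuffle with local repair, restart on failure).
- Exp. 2: 150 adaptor/target pairs; targets 2 s at slopes −1/0/+1
  (50 each), adaptors at ±1 dB/oct (75 each) with durations 1/2/4/8 s in
  counts {38, 38, 37, 37}.  Counts are balanced exactly by default
  (`balanced=False` gives the fully random variant).  Responses are
  collected on adaptors too; only targets are analysed.
- Exp. 3: the Exp. 1 design with every slope shifted by ±1 dB/oct in
  two separate sessions; the contexts share slopes {−1, 0, +1}.
- Exp. 4: 300 2-s targets, 50 per morph level; device context
  {−0.5, −0.25, 0, 0.25, 0.5, 0.75}, open-ear context
  {0.25, 0.5, 0.75, 1.0, 1.25, 1.5}.  The six-level grids are a package
  choice constrained by the stated range [−0.5, 1.5], the 50-per-level
  count, and the Exp.-3-style overlap structure.

No excerpt is presented twice within a session.  Trial indices are
1-based.

## Aggregation and evaluation

Previous-trial classes: sign of the previous slope (Exp. 1; a zero
previous slope belongs to neither class and the trial is excluded), the
preceding adaptor's slope (Exp. 2), below/above the session-mean
coloration (Exps. 3–4) — labelled by whether the preceding stimulation
was relatively *dull* or *bright*.  A relative variant (previous vs
current level) is not the default.  Cell p(bright) is the mean over
participants of per-participant proportions; CIs are percentile
bootstrap over participants (2000 resamples, seeded).  Empty grid cells
are reported with n_trials = 0 rather than dropped.

Inclusion: a participant is retained iff the gain in proportion-bright
between the two most extreme levels of a session, averaged over their
sessions, is at least 40 percentage points (Exps. 1/3) or 20 points
(Exp. 2); equality retains.  Exp. 4 has no separate morph-domain
convention, so the analogous extreme-level comparison with the 40-point
threshold is applied.

Model selection: for each L on the grid {4, 8, 16, 32, 64, 128, 256} s
the experiments are simulated with 50 virtual participants — each with
an independently randomized trial sequence and lapse stream — and
scored by the root of the unweighted mean of squared cell errors over
all cells of all experiments (per-experiment weighting available via
`pooling="experiments"`).  The same seed is used at every grid point
(common random numbers), so RMS differences across the grid reflect the
parameters alone.  The Pearson correlation between model and reference
cells is reported at the best L.

### Identifiability note

With the session-median long-term term inside the mixture, (α, L) lie
on a shallow ridge: the session median itself tracks a global context
shift, so lowering α while shortening L produces nearly the same cell
pattern (e.g. α = 0.5, L = 8 s is empirically indistinguishable from
α = 0.75, L = 16 s at 50 participants).  With the fixed
unprocessed-domain-median reference the context contrast scales with α
and the trial-by-trial contrast with L, and a joint grid search
recovers both cleanly; the parameter-recovery test runs in that
configuration.

## Numerical choices and degenerate inputs

- Silent excerpts are rejected wherever a log level or a centroid would
  be undefined; all-zero ERB spectra raise rather than return NaN.
- Morphing rejects mismatched FFT grids and (numerically) zero
  magnitude bins, naming the first offending bin.
- Logistic summaries flag complete/quasi-separation (statsmodels
  warning, runaway coefficients or non-finite standard errors) instead
  of raising; coefficients are then not interpretable.
- The simulated adaptation contrast at very long integration lengths is
  a difference of proportions with Monte-Carlo SE near 1 percentage
  point at the simulation sizes used (50–100 participants); tests of
  its decrease over L allow for exactly that noise on the tail of the
  grid.
- Simulation problem sizes throughout the test-suite (corpus of 360
  excerpts, 50–100 virtual participants, 2000 bootstrap resamples) are
  chosen to put binomial SEs well below the asserted effects.

## Known limitations

- The synthetic corpora share one fixed target profile; real corpora
  have genre/speaker structure that the homogeneity-selection step
  would actually bite on.
- The logistic summarizer is fixed-effects only; it checks signs and
  directions on simulated data and is not a substitute for a
  random-effects analysis of human data.
- The filterbank reconstruction is exact only in the zero-phase mode;
  the causal mode exhibits crossover ripple beyond ±1 dB.
- SC is computed once per excerpt (no time-varying track), and no
  loudness model weights the spectrum.
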