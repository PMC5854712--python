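# Methods

## The analysis in brief

`songfractal` quantifies multi-timescale ("multifractal") structure in a
song's amplitude envelope and attributes it to either note arrangement
or instance-level timing/intensity deviations. The chain is: envelope
extraction → note segmentation → pause zeroing → MFDFA → IAAFT surrogate
test per song → average-rhythm re-synthesis → paired contrast of
surrogate-test effect sizes.

## Envelope extraction and segmentation

The envelope is the windowed RMS of the waveform, 10 ms windows advanced
in 1 ms steps (a 1000 Hz envelope). RMS was chosen as the envelope
statistic; Hilbert magnitude would serve equally, but one definition
must be fixed. A partial final window is dropped rather than padded, to
avoid edge artifacts in the RMS.

Note boundaries come from the difference between a fast (λ = 50) and a
slow (λ = 5·10⁷) Hodrick–Prescott trend of the envelope: the fast trend
tracks notes, the slow trend the overall level, so their difference is a
band-pass that goes positive during notes. The HP solver is
statsmodels' standard pentadiagonal penalized-least-squares routine with
natural endpoints. Two practical guards were added after measuring the
raw zero-crossing rule on synthetic corpora:

- **Edge refinement.** The trend crossing drifts 15–35 ms into note
  attacks and decays. Each candidate run is therefore re-localized on
  the envelope itself, walking outward from the run's amplitude peak
  until the envelope falls below 5% of that peak. This brings boundary
  errors to ≤ 2 ms on synthetic corpora with ≥ 30 ms pauses. Set
  `edge_frac=0` to recover the raw crossing rule.
- **Run-peak guard.** The slow trend dips below zero near long silent
  stretches, which would promote silence (or noise floor) to notes; runs
  peaking below 5% of the global envelope maximum are discarded.

Intervals are half-open `[onset, offset)` in ms, 0-based. Between-note
pauses are set to exactly zero amplitude before analysis so pause noise
cannot contribute to measured multifractality (a `--keep-pause-noise`
toggle reruns the pipeline on raw envelopes).

## MFDFA

Defaults: q grid 0.1–5.0 in steps of 0.1 (strictly positive; negative-q
analysis is out of scope), 19 log-spaced integer scales spanning
[10, N/4] (log spacing equalizes leverage in the log-log fit), linear
(order-1) detrending, natural logs (the slope is base-invariant), and
both-ends windowing: ⌊N/s⌋ windows tiled from the start plus ⌊N/s⌋ from
the end, so trailing samples are used at every scale and all q-order
means run over 2⌊N/s⌋ windows. Windows with exactly zero residual
contribute 0^(q/2) = 0, which is well defined for q > 0. A constant
series, the only input whose fluctuation function vanishes at every
scale, is rejected as "zero-variance". The per-q fit returns slope,
intercept and R²; the spectrum width is max h(q) − min h(q) over the
grid (identical to using the extreme q values whenever h is monotone in
q).

## IAAFT surrogates and the significance test

Each iteration (i) imposes the original amplitude spectrum on the
current iterate's phases, (ii) restores the original value distribution
by rank-ordered replacement. Stopping: relative improvement of the
spectral discrepancy below 1e-6, first non-improving iteration, or 100
iterations, whichever comes first; the best iterate seen is returned,
so the recorded discrepancy trace is non-increasing. The ensemble
(default n = 100) uses independent reproducible sub-streams spawned
from one master seed. The 95% interval is the empirical percentile
interval of the surrogate widths (a Gaussian mean ± 1.96 SD option is
available); significance is two-sided exceedance, and the effect size is
the SD-distance (width − ensemble mean)/ensemble SD. Surrogates operate
on the whole zero-pause envelope, pauses included.

## Average-rhythm re-synthesis

Note instances are averaged per type: each instance's course is
linearly resampled to a common 100-point duration-normalized grid,
averaged pointwise, and rendered at the type's mean duration — so the
intensity course is averaged independently of duration, then the mean
duration is re-imposed. When all instances of a type share one sample
length (the zero-deviation case), the native-grid mean is used directly,
which makes re-synthesis reproduce zero-pause originals exactly rather
than to within resampling error. Pauses are averaged per ordered pair of
flanking note types, with mean and median variants (pause-duration
distributions can be skewed). Amplitudes keep their native units; no
normalization. The intensity-deviation statistic is the note's mean
amplitude (peak amplitude would be an alternative; the mean is the
simplest per-note scalar). A type or type pair missing from the
profiles is a hard error — it cannot occur when profiles are built from
the corpus being re-synthesized, which is the intended use.

## Synthetic data

Reference processes: seeded Gaussian white noise; fractional Gaussian
noise by circulant embedding of the exact autocovariance
γ(k) = ½(|k+1|^2H − 2|k|^2H + |k−1|^2H) (unit variance, eigenvalue
clipping only absorbs round-off); binomial multiplicative cascades of
2^levels samples, mass split (p, 1−p) with a fair seeded coin deciding
orientation per split, so the series is stochastic while h(q) =
1/q − log₂(pᑫ + (1−p)ᑫ)/q depends only on p.

Song corpora emulate a single bird's recording session: by default 24
songs over 5 note types, 8–20 notes per song, at a 1000 Hz envelope
rate. Note templates are piecewise-linear attack–sustain–decay shapes
(total durations ≈ 85–230 ms, peaks 0.40–0.92); base pause durations are
a deterministic function of the flanking type pair (40–130 ms, all
≥ 30 ms so segmentation stays trivially correct); syntax is a first-order
Markov chain mildly favouring cyclic type progressions (a fixed
sequence or custom transition matrix can be supplied). Deviation modes
and default magnitudes: `jitter` = i.i.d. Gaussian perturbation of note
durations (σ = 5 ms) and per-note amplitude scale (σ = 5%); `drift` = a
mean-centered tempo ramp of ±2 ms per transition plus an amplitude ramp
of ±0.8% per note, sign drawn per song (accelerando/ritardando,
crescendo/decrescendo analogs); `motif` = a fixed 4-note pattern of
duration (±10 ms) and amplitude (±5%) offsets repeating across the
song; `mixed` = drift + motif + jitter at 40% magnitude. Durations are
rounded to whole envelope samples, so the zero-deviation corpus is
bit-reproducible under re-synthesis; ground truth (true boundaries,
types, injected interval and amplitude deviations) is returned with the
songs.

What the generator does **not** emulate: within-note envelope texture
(every instance of a type is an exact affine copy of its template),
recording noise floors, amplitude ties broken by measurement noise, and
spectral content of any kind. Passing tests on these corpora validate
the pipeline's mechanics and its response to controlled deviation
structure — not its behavior on real recordings, whose envelopes are
continuous-valued and noisy.

## Problem sizes used by the validation suite

Chosen once as the package's own trade-off between statistical
resolution and turnaround: white-noise calibration 50 series of
n = 10 000 (q = 2 only); known-H recovery 50 series of n = 8192 per H;
cascade validation p = 0.7 with 13 levels; surrogate-test calibration
40 monofractal trials (fGn n = 2048, H cycling over 0.3/0.5/0.8) and 40
cascade trials, 100 surrogates each; the replicated average-rhythm
contrast 20 corpus seeds per deviation condition with 10 songs of 6–10
notes, 30 surrogates and mean pauses. A full-scale single study
(24 songs × 100 surrogates, both pause statistics) runs in a few
minutes on one CPU.

## Numerical notes and known limitations

- **Exact-tie degeneracy at small q.** Synthetic and re-synthesized
  envelopes contain exactly repeated values (stereotyped notes) and
  exact zeros (pauses). Windows whose profile is perfectly linear give
  F² = 0, and at q near 0.1 the q-order mean is dominated by the
  smallest residuals, so h(0.1) — and hence the width — is inflated by
  these degeneracies and is hypersensitive to them: a 1% perturbation of
  note amplitudes moves an IAAFT ensemble's mean width by several
  ensemble SDs, because rank replacement maps tie runs of the sorted
  values onto whole windows of the surrogate. Consequences measured on
  synthetic corpora: (i) pause zeroing is *not* width-neutral when the
  pauses held a noise floor, unlike what is expected for real
  continuous-valued recordings; (ii) *any* instance-level variation —
  including pure i.i.d. per-note amplitude jitter — separates a corpus
  from its stereotyped re-synthesis in the paired contrast, so the
  contrast's specificity against random amplitude jitter is poor in
  this synthetic regime (duration-only jitter behaves as expected:
  paired t ≈ 1.5, non-significant). Real envelopes, which are
  continuous-valued, do not have this tie structure.
- **IAAFT and heavy tails.** For binomial cascades the IAAFT spectral
  discrepancy plateaus near 0.33 regardless of iteration count: under
  the exact value-distribution constraint the spectrum cannot be
  matched. Because IAAFT preserves the distribution, it also preserves
  the distribution-driven share of a cascade's apparent width
  (surrogate widths ≈ 0.40 vs. original ≈ 0.45, while a plain shuffle
  null gives ≈ 0.31); the width-vs-IAAFT test therefore detects
  correlation-driven multifractality and deliberately discounts purely
  distributional multifractality — cascades are flagged only rarely.
  This is a property of the null model, not a defect of the estimator:
  the same h(q) estimates match the cascade's closed form within 0.05.
- The q = 2 both-ends estimator shows the usual mild small-scale DFA
  bias (white-noise mean ĥ ≈ 0.50 with seed scatter ≈ 0.02 at
  n = 10 000).
- fGn sample autocovariances sit slightly below γ(k) at H = 0.8 due to
  the long-range-dependence bias of sample-mean subtraction
  (≈ n^(2H−2)), not a generator error.
- Tie-breaking in rank replacement follows numpy's stable argsort;
  surrogate streams are spawned from a master seed via `SeedSequence`,
  so ensembles are reproducible bit-for-bit.
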