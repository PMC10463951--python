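# Methods

This note documents the models, rules and numerical choices behind each
module, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the underlying procedures left room.

## MUA detection (`elptools.mea`)

The chain emulates online slice-MEA acquisition: a *causal* second-order
Butterworth highpass at 200 Hz (zero-phase filtering is available behind
`zero_phase=True` but is not the default, because acquisition software
filters forward in time), a per-channel robust noise estimate, threshold
detection, and an activity criterion.

*Noise estimate.*  σ̂ = median(|x|)/0.6745.  The "standard deviation of the
noise" is deliberately not the sample SD: with spiking at 1–5 Hz the sample
SD is inflated by the spikes themselves, while the median absolute
deviation tracks the noise floor (tested: 100 inserted 10σ events in 2×10⁵
samples bias σ̂ by < 5% while the plain SD is visibly inflated).

*Detection.*  Events are |x| > 5σ̂ crossings.  Both polarities are used
because extracellular spikes are biphasic and acquisition conventions vary;
a 1 ms dead time merges the two phases of one waveform into a single event
whose time is the local extremum of the excursion.  Thresholding scales
with σ̂, so detection is exactly invariant to rescaling the voltage trace.
An all-zero channel yields σ̂ = 0 and raises a degenerate-threshold error
rather than detecting everything.

*Activity.*  A channel is active iff it has at least 100 spikes per 300 s,
pro-rated for other durations; exactly 100 spikes in 300 s is active (the
rule excludes channels with *fewer than* 100).  At the 50 kHz, 5-minute
scale the Gaussian false-positive rate at 5σ is ≈ 9 events per channel,
two orders of magnitude below the activity cut, so noise-only channels are
classified inactive with overwhelming margin.

*Electrode subsets.*  `rows_to_channels` maps electrode rows of a grid
layout (e.g. rows 2–3 of a 6×10 chip, the rows facing cortical layers 2/3)
to channel indices for `summarize_slice`.

## Calcium peak calling (`elptools.calcium`)

Traces are normalized to the per-neuron baseline mean (0–200 s); thresholds
are relative to that single scalar, not to a running baseline, which makes
calls invariant to any positive rescaling of the raw ratios.

Two conventions matter and are fixed here:

1. *"First peak"* is the maximum within the first qualifying
   supra-threshold run's excursion, not the global maximum, so a late large
   deflection cannot displace an earlier genuine response.
2. The *excursion* used for the peak and the AUC is bounded by baseline
   crossings (fold > 1), not by the rule threshold.  The AUC is the
   trapezoidal integral of max(fold − 1, 0) over the excursion extended one
   sample past each crossing, which makes a triangular excursion
   1 → 1.2 → 1 over 20 s integrate to exactly 2.0 fold·s on its own grid
   and is zero for non-responders.

Thresholds are strict (greater than 10%/20% above baseline); run length is
≥ 5 consecutive samples (10 s at the 2 s sampling interval).  The capsaicin
search window ends at 780 s so depolarization responses cannot be
mis-attributed; the KCl window is open on the left (time to peak strictly
> 780 s).

## IntelliCage features (`elptools.icage`)

*Binning.*  Half-open [t, t + 12 h) bins aligned to lights-on; a visit
belongs to the bin containing its start, and a start exactly on an edge
goes to the later bin.  Binned counts sum to stream totals by construction.

*IVI semantics.*  The inter-visit interval is end-to-start — the gap during
which the animal is outside any corner — matching the "re-entry" reading.
A fast re-entry requires the *same* corner and IVI strictly below 60 s
(an IVI of exactly 60 s does not count).

*Repetitiveness.*  "Early return" is operationalized as a fast re-entry
(IVI < 60 s).  The expected count comes from permuting the corner-label
sequence over the fixed timestamps (default 1000 shuffles, seeded), which
preserves per-corner visit counts and the empirical IVI distribution —
unequal corner preferences therefore do not masquerade as repetitiveness,
which an analytic 1/4 null could not guarantee.  The statistic is the log2
ratio; when either count is zero a 0.5 pseudo-count enters both numerator
and denominator and the row is flagged.  Units with < 2 visits are
undefined (NaN); units with < 10 visits are flagged `low_n`.

*Feature matrix.*  Per-day parameter values are averaged per task and over
the whole observation, giving exactly five values (FA, NP3c, PPL, PPLrev,
overall) per parameter per animal.  Implemented parameters: visits/h
(total, day, night), NP/visit, NP/h, licks/h, lick duration/h,
licks/visit, fraction of visits with ≥ 1 nosepoke, mean visit duration,
mean IVI, fast re-entries/h, correct-visit fraction, repetitiveness.
Two deviations from the per-day rule: repetitiveness is computed on each
task's whole stream because per-day fast-return counts are too sparse for a
stable log-ratio; and door-opening latency is not computed because the
documented visit schema stores nosepoke counts, not per-nosepoke
timestamps.

*Task geometry.*  The PPL-reversal corner is the diagonally opposite corner
of the PPL corner ({1↔3, 2↔4}); the NP3c correct set is every corner except
the animal's future PPLrev corner.  Correct-corner fractions are computed
for learning tasks only — during free adaptation no corner is "correct" and
FA visits are excluded rather than erroring.

## Group statistics (`elptools.stats`)

Student's pooled-variance t-test is the default two-group test (Welch
available behind a flag).  Mann–Whitney uses the exact null for tie-free
samples with n ≤ 12 and the tie-corrected normal approximation otherwise.

The mixed RM-ANOVA covers the standard behavioral design — one
between-subjects factor crossed with one within-subjects factor — for
complete balanced-within data; unbalanced *group* sizes are allowed,
missing cells are an error (time-course data are expected to be averaged
per day first, so completeness is the norm).  The between effect is tested
against subject-within-group variation, within and interaction against the
residual.  Sphericity is not corrected; the output table records this.
Degenerate all-equal data report F = 0 by convention.

Dunnett's many-to-one adjustment is evaluated by seeded Monte Carlo on the
joint multivariate-t null with the correlation structure induced by the
shared control (λⱼ = √(nⱼ/(nⱼ+n₀))), default 10⁵ draws, reporting the MC
standard error; this handles arbitrary k and group sizes without tables.
Adjusted p-values are floored at the raw p (multiplicity never helps) —
the same guard appears in the Šidák closed form against float round-off.

## Lipid screen (`elptools.lipids`)

t-tests run on log2 intensities by default (multiplicative noise is the
norm for area-ratio quantification); the raw-scale option exists.  Positive
log2 fold change means higher in the test group.  `range_norm_for_plots`
maps a vector to [0, 1] for per-species scatter insets.

## Synthetic data (`elptools.simulate`)

Defaults are the emulated study conditions: 60 electrodes × 300 s at
50 kHz; 2 s-sampled ratio traces with capsaicin at 200–220 s and KCl at
780–825 s; a 2-week FA, 2-week NP3c, 10-day PPL, 10-day PPLrev schedule
with 15 control and 16 ELP females (PPL corners assigned 4 mice per
corner); 15/16-sample lipid tables.

Generator conventions, chosen once where no value was prescribed:

* **Spike waveform** — a Hann-windowed single sine period
  (negative-then-positive, 1 ms), scaled to `spike_amplitude` × noise SD;
  the ground-truth time is the negative peak.  Its spectral content sits
  near 1 kHz, far above the 200 Hz cutoff, so filtering barely attenuates
  inserted spikes.
* **Calcium transients** — linear rise over the stimulus window to the
  configured fold, exponential decay (τ = 60 s capsaicin, 40 s KCl); with
  zero noise the trace maximum equals the configured fold exactly, which
  the rule-exactness tests exploit.  Default KCl responder fractions are
  the observed viability levels (0.902 control, 0.955 ELP).
* **Visit process** — an inhomogeneous Poisson process with
  piecewise-constant day/night rates (2 and 6 visits/h by default),
  realized by thinning; visit durations are exponential (mean 25 s) and a
  candidate start during an ongoing visit is dropped, so streams are
  non-overlapping by construction.  Piecewise rates were chosen over a
  continuous sinusoid (both shapes are plausible) because bin-level
  expectations stay analytic for testing.
* **Corner choice** — Markov: stay with probability `stay_probability`
  (0.25 control, 0.40 ELP), otherwise uniform over the other three corners;
  during learning tasks a logistic learned-correct-corner override (default
  asymptote 0.8, midpoint day 3) takes precedence with the learned
  probability.
* **Nosepokes** — negative binomial (means 2 vs 3, dispersion 4): real
  per-visit counts are over-dispersed and NP/visit is a headline contrast.
* **Licks** — Poisson per visit (25 vs 50), gated by the task's door rule:
  ad libitum in FA, first-nosepoke-opens in NP3c, first-correct-nosepoke in
  PPL/PPLrev.  Lick duration is lick count × a fixed per-lick duration
  (0.12 s), keeping rate ratios exact in expectation.
* **Lipids** — log-normal intensities (σ from the configured CV), base
  abundances spanning ~10 log2 units, a −1 log2 shift planted in 20 of 60
  species.  A third of the panel is affected to emulate broad class-level
  co-regulation (many sphingomyelin species moving together); it also
  keeps finite-seed FDR estimates informative about the procedure rather
  than dominated by small-count noise.

What the generators do **not** emulate: electrode cross-talk, slice drift
and non-Gaussian artifacts on MEA channels; photobleaching, dye saturation
and mechanical drift in imaging; social interaction between cage mates,
corner-specific hardware biases and learning-curve individuality beyond the
logistic; correlated lipid species and batch effects.  Passing tests
therefore demonstrate correctness of the computations under the stated
stochastic models, not robustness to every artifact of real acquisitions.

## Problem sizes and determinism

Test and acceptance runs use the study-scale regimes where they are cheap
(60 × 5-min channels, 15/16-animal cohorts, 1000-shuffle nulls, 10⁵-draw
Dunnett MC) and trimmed Monte-Carlo loop counts where only calibration is
probed (500–1000 ANOVA null replicates, 20–50 generator seeds); each test
states its sizes.  Every stochastic component takes an explicit seed;
`pipeline.child_seeds` fans one global seed into per-stage seeds via
`numpy.random.SeedSequence`, so stages are independently reproducible and
pipeline reruns are byte-identical.

## Known limitations

* MUA only: no spike sorting, unit isolation or LFP analysis.
* RM-ANOVA requires complete within-subject data; no imputation and no
  sphericity correction.
* The Mann–Whitney exact path is limited to small tie-free samples.
* The repetitiveness null conditions on the observed corner-visit counts;
  it does not model drifting corner preferences within a task.
* The visit CSV schema stores per-visit aggregates; analyses needing
  per-nosepoke timing (e.g. door-opening latency) are out of reach of the
  format.
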