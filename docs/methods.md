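# Methods

## The peak-range statistic

The core oscillation measure operates on non-overlapping 1 s epochs of
a single LFP channel. The channel is first high-pass filtered
(Chebyshev type II; rat: 6th order, 80 dB stopband, 2 Hz passband edge;
ferret: 4th order, 80 dB, 1 Hz) and 50 Hz notch filtered (14th-order
band-stop Chebyshev II, 60 dB, stopband 49–51 Hz), both applied
forward–backward so the cascade is zero phase. scipy's `cheby2` is
parameterised by the stopband corner, so the corner is located by
bisection until the single-pass magnitude crosses −3 dB at the
specified passband edge.

For each epoch the biased (divide-by-N) autocorrelation is computed by
FFT over the full lag range 0–1000 ms and normalised to 1 at lag zero.
A bank of reference autocorrelograms is built the same way from 1 s
sinusoids on the species grid (rat 4–14 Hz, ferret 2–14 Hz, 0.1 Hz
steps). The matched sinusoid minimises the Euclidean distance between
epoch and reference autocorrelograms, with each distance divided by the
Euclidean norm of its reference (an unnormalised variant is one line
away; the normalisation only reweights the comparison across
frequencies, and ties break toward the lower frequency). Because epoch
and bank use the same estimator on the same lag grid, the triangular
taper of the biased autocorrelation cancels when the epoch's first-peak
range is divided by the reference's.

The first peak and its two flanking troughs are located on the
*matched reference* (which is noiseless), and the data extremum is then
measured within ±¼ period of each reference lag — robust to a grid
mismatch of half a step while never latching onto distant structure.
Epochs whose matched frequency is so low that the second trough window
would leave the lag grid are flagged undefined rather than
extrapolated. The value is not clipped: noise can push it slightly
above 1 or below 0.

Calibration (recomputed by `scripts/acceptance.py` and the test suite):
noiseless in-band sinusoids score 1.00 ± 0.02 at every grid frequency;
white-noise epochs average below 0.1. The FFT autocorrelation is
checked against a direct O(N²) sum to 1e-10, and the peak-range
measurement against an independently written implementation to 1e-6.

## Peak-trough instantaneous theta

The theta trace (zero-lag Hamming-windowed-sinc FIR; rat 4–14 Hz,
order 0.5 s; ferret 2–8 Hz, order 1 s; order forced even so the group
delay is an integer) is scanned point by point for alternating extrema
whose excursion exceeds 0.25 × the median absolute value of the
filtered session ("median amplitude" is read as median absolute value;
a median-envelope reading would scale the threshold by ≈ 1.2 without
changing any test outcome at these SNRs). Masked samples split the
trace and extrema are never detected across the boundary; the first
extremum emitted in each segment is discarded because its approach side
was never verified — a segment can begin mid-cycle at a mask edge, and
keeping the seed extremum biases edge frequencies upward. Ties in
extremum value break toward the earlier sample.

Instantaneous frequency is the mean of the peak-interval and
trough-interval frequencies, each linearly interpolated between cycle
midpoints; amplitude is the mean of |peak| and |trough| held constant
within each half-cycle; power is amplitude²; phase is anchored at 0° on
peaks and 180° on troughs and interpolated linearly, so phase is exact
at extrema by construction. Samples outside the first/last extremum of
a segment are NaN. On pure sinusoids the estimator is exact to within
0.1 Hz across the band; a 4→10 Hz chirp is tracked within 0.11 Hz; a
Hilbert-transform oracle agrees to < 0.2 Hz median frequency and < 1°
median phase on narrowband inputs. Note the FIR transition band
(≈ 3.3/order_s Hz) rolls gain off near the band edges — a 6 Hz tone
passes the rat filter at ≈ 0.92, not 1.0 — which affects amplitude but
not frequency or phase estimates.

## Cleaning

Thresholds described as "the mode of the distribution" use the mode of
a Freedman–Diaconis histogram: deterministic, scale-aware, and robust
to heavy right tails. Channel exclusion drops channels whose theta-band
Welch PSD peak (Hanning window, nfft 4096, 50% overlap — the overlap is
a package choice) is below the species threshold (rat 4 dB, ferret
2 dB) or whose 50 Hz peak meets the theta peak (0 dB margin,
configurable). PSDs on masked data drop every Welch segment containing
a masked sample.

Amplitude artifacts: the across-channel mean absolute amplitude is
thresholded at 10 × its histogram mode; supra-threshold runs are masked
on all channels with a 10 ms guard, runs of exact zeros and samples at
the saturation rail get their own labels. Scratching/HVS removal
follows the four-step cortical-power protocol: per cortical channel a
zero-lag 6–13 Hz FIR (order 0.5 s) and Hilbert power, the median across
cortical channels, a threshold at 8 × the histogram mode of that median
power, and masking of supra-threshold sections on all channels. The
multiplier is the one free parameter of the protocol; 8 was fixed by
validating per-sample recall (≥ 0.95, in practice 1.0) and
false-positive rate (≤ 0.01) against the generator's ground truth —
genuine bursts sit orders of magnitude above the mode, so recall is
insensitive to the choice, while the upper tail of the quiescent power
distribution reaches ≈ 6 × its mode and a multiplier of 5 trips on it.
Scratch detection runs on the amplitude-cleaned signal (transients
would otherwise pollute the power distribution); power is unassessable
within half a filter order of masked data, and such gaps are bridged
only when the flanking assessable power is supra-threshold. Ferret
sessions carry no cortical channels and the step degrades to a warning
no-op.

Head tracking: frames are invalidated when an LED moves > 50 px/frame
relative to the last valid position or the LED separation leaves the
configured 30–50 px band (rig-dependent; exposed as a parameter, no
single default asserted); gaps < 660 ms are linearly interpolated,
longer gaps stay invalid; each coordinate is median filtered (width 5,
nearest-edge padding so constant tracks are fixed points). Head
position is the LED midpoint; speed is frame displacement × fps ÷
px_per_cm, with px_per_cm stored as explicit session metadata because
no universal pixel scale exists.

## Laminar profiling

Depth profiles restrict the peak-trough outputs to locomotion samples
(speed > 10 cm/s, at least 60 s) and report per-channel median power
(with IQR) and the circular mean phase offset to the top channel (0 by
definition). Stratum pyramidale is the power-minimising channel within
the zone where the unwrapped phase gradient first exceeds 20°/channel
sustained over 2 channels (both numbers are package choices for a
qualitative rule); SO and SR/SLM are assigned 200 µm above and 400 µm
below via the depth field. Probes without a co-occurring dip and shift
fall back to the highest-power channel as SO, with the method recorded.
Over 20 simulated probes with the cell layer placed uniformly across
channels 8–24 the assignment is exact in 20/20.

Speed regressions use 250 ms epoch *medians* (also for the ≥ 10 cm/s
exclusion), drop epochs above the 90th speed percentile, bin at 5 cm/s
and fit ordinary least squares to bin medians; bins need at least 10
epochs, since sparse-bin medians destabilise the slope t-test.
Per-channel significance applies a Bonferroni-corrected α
(0.05/32 ≈ 0.0016 for a 32-channel probe). At that operating threshold,
block-permutation of the speed labels fires in ≈ 0.4% of 1000
permutations; the small residual anti-conservatism reflects the few
degrees of freedom of the bin-median fit. The ripple power profile
(150–250 Hz RMS, a field-convention band) is a confirmation aid only
and never overrides the theta-based assignment.

## Trial epochs and behaviour

Hold = [stimulus onset − 1.05, onset − 0.05); Run = the 1 s before the
peripheral response; Reward = the earliest post-response 1 s window in
which *every* speed sample is below 5 cm/s ("consistently below" read
strictly; the search advances one speed sample at a time and invalid
speed samples disqualify a window). Trials that are aborted,
correction trials, or errors are excluded by default (errors can be
included behind a flag). Condition tables measure the peak range
directly on each window's samples per channel — trial windows are not
aligned to the 1 s epoch grid, so reusing grid epochs would misplace
the windows by up to half a second. Optional normalisation divides by
the session's median Run value per channel. Behavioural performance is
the proportion correct per session and modality, tested against chance
(1/n_choices) with a one-sample t-test across sessions; zero-variance
degenerate cases are flagged instead of reporting a p-value.

## Mixed-effects models

All group comparisons model the per-epoch peak range with fixed effects
plus nested random intercepts, fitted by REML through statsmodels
`MixedLM`; nesting such as species/subject/session is expressed as a
random intercept on the outermost factor plus variance components for
the concatenated inner levels. Reference levels: Run for trial epoch,
immobile for locomotor state, no-drug for drug condition, rat for
species (all recorded in the output). Fixed-effect p-values use the
Wald normal approximation, recorded as `wald-z` in every result;
statsmodels provides no Satterthwaite correction, and at the epoch
counts these tables carry (10³–10⁴ rows) the difference from
finite-df corrections is far below the reported precision. Null
simulations put the type-I rate of the interaction test at 0.048 over
500 fits. The interaction-then-split protocol (full model, then
per-stratum refits) is packaged as a single workflow that reports both
stages; Tukey-adjusted pairwise contrasts (studentized range with
residual df) are available for ≥ 3-level factors, with a pass-through
of the model p for 2-level factors. Non-convergence is flagged, never
silently simplified. Optimiser: L-BFGS, max 10⁴ iterations.

## The synthetic generator

The generator is the package's study-condition definition, not a
biophysical model. Defaults: 32 channels at 100 µm spacing, 1 kHz, and
per channel `x_c(t) = A_c(t)·w(φ(t) + φ_c) + LIA_c(t)` where `w` is a
sinusoid with asymmetric cycle warping (rise fraction 0.5 − 0.4·skew,
skew 0.3 when moving — the "sawtooth" waveform is only qualitative, so
harmonic content is made controllable), `φ' = 2π(f₀ + s·v(t))` with
rat f₀ = 7.5 Hz, s = 0.026 Hz/(cm/s) and ferret f₀ = 5.2 Hz,
s = 0.010, 1 Hz lower and skew 0 when the ferret is immobile. These
are generator conventions placed at the centre of the observed
cross-species ranges, not claims about the animals. Theta is gated by a
200 ms smoothed locomotion indicator: always off when a rat is
immobile; always on in the drug-free ferret; off during immobility in
atropine mode for either species. LIA is Gaussian 1/f^1.5 noise at
30 µV RMS per channel. The laminar amplitude profile (≈ 55 µV above
the cell layer, a dip to 22 µV at SP, rising to 110 µV below) and a
0→180° phase ramp over the three channels below SP mimic the canonical
depth structure; SR/SLM channels are multiplied by 1.3 inside Reward
windows (the reward enhancement has no published effect size; 1.3 is a
free generator parameter).

Behaviour: trials are hold (2.5–3.5 s in five steps, speed ≈ 1 cm/s),
a 0.3 s reaction, a run that ramps to a 25–32 cm/s plateau and
decelerates onto the response spout, and a 2–3 s reward dwell below
5 cm/s; between trials the animal wanders with a mean-reverting
(Ornstein–Uhlenbeck, τ = 1 s) meander over 0–25 cm/s so moderate
speeds are sampled in quasi-steady state — without this, speed–theta
regressions would see moderate speeds only inside 0.4 s ramps, where
cycle-averaged frequency estimates are dominated by the adjacent
plateau. Measured speed adds Gaussian jitter (SD 1 cm/s, clipped at
±3 SD and at zero). Artifacts are Poisson-placed broadband transients
(20 × the median absolute amplitude), 8–12 Hz bursts strongest on
cortical channels, zero runs and rail saturation, all with ground-truth
masks.

What the generator does *not* emulate: volume-conduction geometry and
CSD structure, spiking, respiration/sniffing coupling, gradual
electrode drift, theta–gamma coupling, and realistic artifact
morphology beyond the four stylised classes. Passing tests therefore
demonstrate that the estimators recover known signal structure under
the stated statistical conditions — not that they are robust to every
failure mode of real recordings.

## Problem sizes and determinism

Test and acceptance runs use 180–300 s sessions (tens of trials,
hundreds of 1 s epochs), 10-seed parameter-recovery ensembles, 500-fit
null calibrations and 20-probe layer ensembles; these sizes keep every
Monte-Carlo proportion's sampling error well inside the asserted
margins while the whole chain stays single-core friendly. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations produce
byte-identical sessions.

## Known limitations

- The peak range saturates near 1 for strongly periodic signals, so
  amplitude increases beyond clean periodicity (e.g. the Reward
  enhancement) compress into small peak-range increments.
- Frequencies below ≈ 1.5 Hz have no measurable first peak within the
  1 s lag grid and are flagged undefined.
- Wald-z p-values are anti-conservative for very small group counts
  (< ≈ 5 sessions); the effect estimates themselves are unaffected.
- The FIR band-edge roll-off biases amplitude (not frequency/phase)
  estimates for oscillations near the band edges.
- Layer assignment assumes the probe crosses the cell layer roughly
  perpendicular to the laminae, as the depth-profile rule presupposes.
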