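# Methods

## Analysis segments

All detections run on 30-s hypnogram epochs staged N2 or N3. An epoch is
dropped entirely when it overlaps an artifact or arousal event longer than
5 s (strictly; a 5.000 s event never excludes an epoch). Shorter events keep
their epoch but flag their own samples, which are then excluded from the
spindle percentile threshold and from band-power sums while remaining
available to event detection — this preserves contiguous waveforms while
keeping amplitude statistics uncontaminated. The epoch-level reading of the
exclusion rule is a design choice: excluding only the overlapped samples
would cut waves mid-flight at artifact edges. Sample indexing is 0-based with
half-open intervals; event times are seconds from recording start.

## Filtering

Band-pass filtering uses an odd-length Hamming-window FIR applied by
symmetric convolution, which cancels the group delay exactly (linear phase,
zero net shift). The designed cutoffs are nudged outward by 0.126 of the
transition width so the −3 dB points fall on the nominal band edges (a
Hamming FIR is −6 dB at its design cutoff); the spindle band is verified at
−3 ± 0.6 dB at 10 and 16 Hz. Transition width defaults to half the low edge,
clamped to [0.2, 2] Hz, giving ≈3300 taps for the 0.3–4 Hz SW band at
200 Hz. Signals shorter than the filter are reflect-padded.

## Slow-wave detection

On the 0.3–4 Hz signal, candidates are consecutive negative-then-positive
half-waves delimited by zero crossings: start = down-going crossing, mid =
up-going crossing, end = next down-going crossing, with crossing times
linearly interpolated between samples and exact-zero samples adopting the
preceding sample's sign. A candidate becomes a SW iff all four criteria hold:
peak-to-peak ≥ 70 µV and negative peak ≤ −37 µV for women (≥ 60.5 µV and
≤ −32 µV for men), negative-deflection duration within 125–1500 ms, positive
deflection ≤ 1000 ms. Only sex-specific thresholds are implemented (exposed
as configurable parameters); any age adaptation happens by passing different
criteria.

Transition frequency is 1/(2·Δt) with Δt the negative-to-positive peak
interval: the peak-to-peak interval is half a cycle, so the literal
reciprocal of Δt would double the frequency scale. The half-cycle convention
is the one consistent with a ~0.9 s symmetric slow-switcher wave having both
an overall frequency of ~1.1 Hz and a transition frequency of ~1.1 Hz.

## Switcher split

Pooled transition frequencies (pooling across subjects by default; a
per-subject option exists) are fitted with a two-component univariate
Gaussian mixture by EM (scikit-learn, tolerance 1e-8, ≤500 iterations,
initialised from the values below/above 1.2 Hz, seeded). The classification
threshold is the root of w₁N(μ₁,σ₁²) = w₂N(μ₂,σ₂²) strictly between the two
means, obtained from the quadratic in x after equating log-densities. A wave
exactly at the threshold is labelled fast (slow iff f_T < threshold);
the tie has measure zero and the rule is stable. With component means
1.1/2.0 Hz and any plausible spreads the density intersection falls at
1.3–1.45 Hz; the often-quoted "≈1.2 Hz" split is not recoverable from those
summary parameters alone, so correctness is asserted against the closed-form
intersection rather than a fixed 1.2 Hz value.

## Spindle detection

The raw channel is band-passed 10–16 Hz; the envelope is the modulus of the
analytic signal smoothed by a centred 0.1 s moving average. The window must
exceed one carrier cycle (77 ms at 13 Hz) and stay well under the minimum
spindle duration; 0.1 s was chosen over a longer window because a centred
average of width w advances the detected onset of a burst by up to w/2, which
at 0.2 s consumed most of the onset-accuracy budget. The threshold is the
75th percentile of the smoothed envelope over the artifact-free N2/N3 samples
of that channel and recording. Maximal supra-threshold runs of 0.5–3 s become
spindles; longer runs are discarded entirely (no truncation, no gap-merging),
as are runs touching the edge of a contiguous segment run.

The onset ("ignition") is the first supra-threshold sample of the run,
refined to the latest local envelope minimum preceding the run's peak when
that minimum lies within the lowest tenth of the run's excursion above
threshold. The refinement addresses a property of percentile thresholds: by
construction ~25 % of background samples are supra-threshold, so background
exceedances adjoining a burst regularly drag the run start 0.1–0.35 s into
the noise before the burst proper; the last low trough before the climb marks
where the burst actually ignites. For clean runs the refinement is a no-op.
One caveat of run-based duration gating: at very generous envelope SNR a
sub-0.5 s burst can smear past the gate through filter ringing; at realistic
SNR the run tracks the true burst duration.

## Coupling phase

A coincidence is a spindle whose onset lies within a SW's [start, end]. The
onset phase interpolates linearly in time between the five landmark anchors
(0, π/2, π, 3π/2, 2π); linearity within quarters is the simplest monotone
convention honouring the anchors, and an amplitude-based (arcsine) mapping
was rejected as noise-sensitive. The map is invertible, which is how the
generator places spindles at a requested phase. Per subject, the statistic
entering linear models is the arithmetic mean of cos(phase) per channel,
averaged over F3/Fz/F4 — matching a cosine-transformed variable in a linear
model, not the cosine of the circular mean. SWs with coincident landmarks are
excluded from phase assignment; SWs on one channel cannot overlap by
construction, so each spindle yields at most one coupling event.

## Circular statistics

The two-sample Watson U² is computed from the difference of cumulative
fractions along the pooled sorted circle,
U² = nm/N² [Σd_k² − (Σd_k)²/N]; ties crossing samples are resolved by
assigning each tied block its block-final cumulative difference (the circular
analogue of averaged ranks, with a logged warning). p-values use the
asymptotic series 2Σ(−1)^{k−1}exp(−2k²π²U²) for samples of at least 20, with
its theta-transform dual below U² = 0.06 where the alternating series loses
accuracy, and seeded label permutations otherwise (add-one estimator). The
asymptotic branch reproduces the classical 5 % point (U² = 0.187) and agrees
with a 9,999-permutation oracle within 0.02 in p at n = m = 20.

Uniformity of one sample is tested by drawing a uniform reference sample of
the same size over the same range and applying the two-sample test. A single
reference replicate reproduces the historical procedure exactly but makes p
itself random; the multi-replicate mode (report per-replicate results and
their median p) is recommended and is what the analysis drivers use.

## Band powers

Per 30-s epoch, band power is the Hann-tapered periodogram integrated over
the half-open band [lo, hi); slow-wave energy is the per-epoch delta-band
(0.5–4 Hz) power summed ("cumulated") across artifact-free N2/N3 epochs, with
sub-bands 0.5–1 and 1–4 Hz and their ratio. Epochs containing flagged samples
are dropped from the power summary. No per-night normalisation is applied —
total sleep time enters the statistical models as a covariate instead — so
only scale-invariant downstream claims (the ratio, model effects controlling
for TST) should be made across recordings of different length.

## Mixed models

The primary model is cos(coupling phase) ~ SW type × Centiloid + age + sex +
TST + SW-type mean duration with a random intercept per subject, one row per
subject × SW type. The random-intercept LMM is fitted in-package by REML,
profiling the variance ratio τ²/σ² (1-D bounded optimisation; per-group
Sherman–Morrison solves make every evaluation O(n)). Fixed effects and
variance components agree with statsmodels MixedLM to 1e-5 in the test suite;
the fixed-effect covariance equals the dense GLS expression exactly.

Denominator degrees of freedom use the Satterthwaite approximation:
df = 2(l'Cl)²/Var(l'Cl), with the variance-parameter covariance taken from
the numerically differentiated REML observed information. For a balanced
random-intercept design this closely tracks the Kenward–Roger correction;
the method is recorded in the fit metadata. Effect sizes are the semi-partial
R²β* = (q·F/ν)/(1 + q·F/ν). Per-type amyloid slopes are tested as contrasts
of the fitted model with Tukey adjustment via the studentized range (k = 2).
Cook's distances are leave-one-subject-out on the fixed effects at the
full-data variance estimates, flagged above 1. A boundary fit (τ² → 0) falls
back to the numerically identical fixed-effects solution with a logged
warning; sex is coded with female as reference, SW type with slow as
reference (so the Centiloid coefficient is the slow-switcher slope).

Memory scores: RM = P('old'|target) − P('old'|foil); relative decline =
(baseline − follow-up)/baseline, undefined at zero baseline. The overall
2-year change is a paired two-sided t test.

## Synthetic data

The generator's defaults are the study conditions the pipeline targets:
200 Hz frontal EEG; SW density 7/min of N2/N3 with 81 % slow switchers;
transition-frequency modes at 1.1 ± 0.05 and 2.0 ± 0.1 Hz; total durations
near 0.906 s (slow) and 0.671 s (fast); peak-to-peak amplitudes near
104.5/94 µV; spindle density 8.3/min with 12–14.5 Hz carriers of ~1 s;
coupling probabilities 0.22 (slow) and 0.34 (fast) with von Mises onset
phases (μ = 1.25π, κ = 4 on slow switchers; μ = 1.1π, κ = 1 on fast);
1/f background noise (α = 1) at 10 µV broadband RMS; cohorts of N = 100
(66 with follow-up), ages 50–70, 68 % women, lognormal Centiloid burden
(median ≈ 10), a slow-switcher-only cosine slope of −0.010 per Centiloid,
and a memory-decline slope of 0.4 per unit cosine with a mean relative
decline of 0.08 (Cohen's d ≈ 0.27 at n = 66).

SW waveforms are quarter-cosine segments through the five landmarks: flat at
the peaks, non-zero slope at the zero crossings. An earlier half-cosine
construction was abandoned because it is flat at the crossings as well,
making detected crossing times on noisy signals purely noise-determined —
no real SW leaves zero with zero slope. A small biphasic sub-criterion wiggle
closes each wave so the terminal down-going crossing exists even in
noise-free signals. Spindles are Tukey-windowed sinusoids; phase-targeted
spindles invert the five-landmark map, so their onset phase is exact to one
sample. All generators are pure functions of their seed.

What the generator does not emulate: continuous background delta activity
between SWs (gaps are 1/f noise, so the pre-wave zero crossing is ambiguous
in a way real EEG is not — SW event agreement is therefore scored at the
down-state peak), ocular/cardiac artifacts (mask handling is exercised with
synthetic mask events), sleep-cycle architecture, topographic differences
across frontal channels (the same events are injected on F3/Fz/F4), and any
dependence of memory scores on item-level task structure. Generated subject
mean cosines are deliberately not truncated at ±1 (~2 % overshoot marginally
under defaults): truncation would attenuate the injected slope that the
estimator-validity checks measure. Passing tests therefore demonstrate
correctness of the machinery under the stated statistical structure, not
detector performance on real polysomnography.

## Numerical choices and degenerate inputs

Simulation sizes in the shipped suite: detection recovery on one 10-min
recording per condition; switcher split on 5,000 mixture draws; Watson
calibration on 1,000 null permutations tests at n = m = 20; mixed-model
calibration on 1,000 null cohorts and 200 effect cohorts of N = 100.
Degenerate handling: empty N2/N3 selections are legal and yield empty event
lists (the pipeline raises, naming the stage); all-wake hypnograms make TST
percentages undefined and raise; zero baseline RM raises; identical paired
vectors give t = 0, p = 1; a collapsed mixture component (σ < 1e-4) raises
rather than returning a spurious threshold; EM needs ≥ 50 pooled values
spanning both sides of the 1.2 Hz initialisation split.
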