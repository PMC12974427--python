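# Methods

## Signal model

A track is one cell × one channel, uniformly sampled (default dt = 0.25 h,
which resolves a 4 h ultradian period with 16 samples per cycle) in hours
and linear arbitrary fluorescence units. Event annotations (mitoses,
S-phase onsets, release time) are real-valued hours; snapping to sample
indices happens only inside operations that need indices, with midpoint
ties broken toward the earlier sample.

## Detrending and band isolation

Detrending is centered moving-average subtraction with symmetric edge
truncation. It is linear, and its effect on a sinusoid has a closed form:
a moving average of width W passes period T with gain sinc(W/T), so the
residual keeps amplitude 1 − sinc(W/T). This closed form is what the test
suite checks the filter against (the discrete filter spans
2·round(W/2dt)+1 samples, and the tests use that effective width). The
long window (40 h) removes drift slower than the circadian band while
passing ~24 h components with gain ≈ 1.14; the short window (12 h) removes
circadian-level and slower components (gain 0.38 at 24 h, ≈ 1.08 at
6.5 h). Wavelets or Gaussian-process detrending would allow sharper bands
but have no closed-form oracle; the moving average was chosen deliberately
for testability and linearity. Z-scoring uses the population standard
deviation; zero-variance traces map to all-zeros rather than erroring so
degenerate control channels flow through the pipeline.

## Periodicity

The Lomb–Scargle periodogram is computed in "standard" normalization:
power at each frequency equals the variance fraction explained by a
least-squares sine+cosine fit to the mean-subtracted signal, evaluated in
closed form from the trig normal equations. Powers are therefore in
[0, 1] and comparable across traces. The frequency grid runs from
1/period_max to 1/period_min at 4× the natural resolution 1/span; exact
power ties break toward the longer period (stability on near-flat
spectra). Dominant-period search ranges are 15–35 h for circadian-isolated
and 3–10 h for ultradian-isolated traces; note 3–10 h deliberately
excludes the first harmonic (~11.7 h) of a ~23 h cycle-locked waveform.
Band powers average grid points inside the configured 20–30 h and 4–8 h
bands.

Cohort band-power comparison averages per-cell power at each in-band grid
frequency within replicate, then across replicates, and applies Welch's
two-sample t test over the per-frequency means — the per-frequency mean is
the unit of comparison, and no multiple-testing correction is applied. The
ACF pipeline uses the biased normalized autocorrelation; the period
candidate is the first local maximum after the first zero crossing and is
reported only if it exceeds 2/√N. The stricter "first maximum is the sole
candidate" rule was adopted after the alternative (scan until some maximum
clears the threshold) declared spurious periods on most white-noise
realizations.

## Cell cycle alignment

Segments run mitosis-to-mitosis; cycle lengths outside 6–80 h are flagged
but kept. Pseudo-time warping linearly interpolates each segment onto 101
equally spaced cycle fractions (n_bins = 100). Dip timing uses cells with
at least three annotated mitoses (their last three): the trace is
circadian-isolated, z-scored, and the daughter generation's interior
minimum is reported in hours before the final mitosis. Minima on segment
boundaries are excluded as mitotic-signal artifacts.

## Events and statistics

Peaks/dips come from prominence-filtered extremum search (default
prominence 0.5 z-units on z-scored band-isolated traces); merged event
lists are forced to alternate by keeping the more prominent of adjacent
same-kind events. The post-release dip is located on a 1 h moving-average
smoothed trace (timing robust to sample noise) between release and the
first mitosis, or within 15 h for non-dividing cells; the fold-change
statistic divides the intensity at release by the window minimum
(inclusive of the release sample, so folds are ≥ 1 by construction).
Coincidence classification uses a 1 h tolerance and is symmetric under
swapping the two event kinds. Intensity-level comparisons use per-cell
mean/max/min of raw traces and ratios of cohort medians.

## Synthetic cohorts

The generator emulates five regimes with one parameter set each
(`calibrate_defaults()`); every stochastic term derives from a single
integer seed via spawned per-cell generators, so identical calls are
byte-identical.

**Cycle-locked waveform.** Cycling cells follow
B·(1 + A_cc·w(u) + A_u·sin(2πt/T_u + φ)) + OU + ε, where u is the
fraction of the current mitosis-to-mitosis interval and w is a zero-mean
two-harmonic waveform, w(θ) ∝ −cos θ + 0.25·cos 2θ with θ = 2π(u − u_dip).
Its maximum (+1 after normalization) sits near both mitoses and its unique
interior minimum (−0.6) falls exactly at u_dip = 1 − L_dip/T, with the dip
lead L_dip drawn per cell from Uniform[10, 14] h. The second-harmonic
fraction 1/4 is the largest that keeps the minimum unique; the resulting
0.6 dip/peak asymmetry is what lets arrest raise the per-cell minimum
1.6-fold while the maximum moves only ~1.1-fold and the mean exactly
1.4-fold. Cycle lengths are lognormal (median 23.3 h, σ_log 0.15); cells
start at a uniform random cycle phase so the population is asynchronous.
25% of proliferative cells are spontaneously nondividing (SND) and follow
the arrested model, matching the observed ~75% division fraction in a
100 h window.

**Arrest.** No mitoses; level 1.4·B with a relatively enhanced
multiplicative ultradian term (amplitude 0.22, period Uniform[5.5, 7.5] h
per cell). The amplitude was fixed by one-time simulation search against
the printed max/min intensity ratios (~1.1/~1.6) while keeping arrested
ultradian dip amplitudes below proliferative G1/S dip amplitudes.

**Release.** Arrested signal until the release time, then a half-cosine
descent to (level)/(fold) at a per-cell dip time Uniform[8, 10] h
post-release — fold is lognormal with mean 2.2 — followed by a half-cosine
recovery into the first mitosis at release + max(reentry, dip + 2 h),
with reentry lognormal (median 19 h, σ_log 0.44; mode ≈ 18 h, ~85% within
30 h). The arrest-enhanced ultradian term decays exponentially (τ = 3 h)
after release and the weak cycling ultradian returns after the first
mitosis, so traces are continuous at release. The post-release S-phase
onset is the cell's realized biological trough (deterministic curve plus
the slow OU term, excluding measurement noise) + Normal(1.0, 1.6) h; with
the 1 h coincidence tolerance this yields the Φ(2/1.6) ≈ 0.89
dip-before-or-at-S-phase fraction. Subsequent generations follow the
proliferative model, with per-cycle S-phase onsets at dip + Normal(1.0,
1.6) h clipped strictly inside the cycle.

**Misexpression and the 24 h assay.** The exogenous channel is
E₀ + κ·(V₀ − endo(t)) plus its own noise (E₀ = 0.10·V₀, κ = 0.24): constant
before release, rising as endogenous HES1 falls — anti-phase, so the total
channel is flatter than the endogenous one. In the 24 h assay (both the
control arm without the exogenous channel and the Tet-positive arm),
division is gated mechanistically: a cell divides only if its measured
total trace falls below θ = 0.524 of its value at release within 15 h;
dividers draw reentry from the lognormal truncated to 24 h. θ, E₀ and κ
were frozen by one-time calibration so the assay yields ~75% (control) vs
~14% (misexpression) dividers; per-seed binomial scatter at 3 × 150 cells
is ±2 percentage points (1 SE).

**Noise.** White measurement noise (σ 1.5 a.u.) plus a stationary
Ornstein–Uhlenbeck process (σ 1.5 a.u., τ 3 h) for slow biological
variability, both on a baseline B = 100 a.u. Raw values are clipped at 0.
Co-channels (optional): CDK2 activity as Gaussian pulses peaking at each
S-phase onset; p21 high in G1 with a sigmoidal decline at dip +
Normal(1.5, 1.0) h, resetting at mitosis. The constitutive control
reporter is constant + 0.05 a.u./h drift + noise.

## What the generator does and does not emulate

It reproduces the population statistics the pipeline quantifies: band
structure, cycle locking, dip geometry and timing, arrest level shifts,
reentry timing, gated assay fractions. It does not model the underlying
delay-differential HES1 autorepression circuit, Notch coupling between
cells, cell death (the assay denominator is all simulated cells, whereas
live-imaging assays exclude dying cells), serum-response transients at media
change, mitotic signal loss, or segmentation/tracking artifacts. Passing
tests therefore certify the analysis pipeline and the calibrated
statistical structure — not any mechanistic claim about real traces.

## Problem sizes and numerics

Shipped analyses use ≤ 3 replicates × ≤ 150 cells at dt = 0.25 h over
96–168 h, sizes at which every stage (closed-form trig sums for the
periodogram, FFT autocorrelation, linear interpolation warps) completes in
seconds. Degenerate inputs are handled explicitly: constant traces have
zero periodogram power and z-score to zeros; monotone segments yield no
dip; cells lacking an event kind are excluded from phase pairing but
counted. Exact power ties break toward longer periods, exact prominence
ties toward earlier events.
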