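# Methods

This note documents the analytical conventions, parameter choices and
numerical decisions behind `placedyn`, in the order data flows through
the package.

## Signal processing

ΔF/F is (F − F₀)/F₀ with F₀ the 50th percentile (median) of a 25-s
moving window. The window is centred and truncated at the trace edges;
a centred window avoids the phase lag a trailing window would
introduce at field onset. F₀ must remain positive; a nonpositive
baseline raises rather than silently producing infinities.

Baseline noise is estimated from the ΔF/F samples *below* the
histogram mode: the mode is located by a coarse (100-bin) histogram
pass refined around the peak, and the noise s.d. is the RMS deviation
of the below-mode samples from the mode. Because calcium transients
are positive-going, the below-mode half of the distribution is
transient-free, making the estimate insensitive to activity level.
For a symmetric noise distribution the one-sided RMS equals the true
s.d. A constant trace returns 0 with a warning.

Only transients exceeding 3 × noise s.d. count as functional activity;
all other frames are zeroed before spatial averaging. No minimum
transient duration is imposed — the threshold alone defines
significance, which keeps the mask monotone in the threshold (the
3-s.d. mask is a superset of the 4-s.d. mask, a property the tests
assert).

Spatial maps divide the 180-cm belt into 50 bins of 3.6 cm. A frame
contributes to (lap, bin) only when the running speed exceeds
2 cm/s; bins never visited above that speed on a lap are *missing*
(NaN), not zero — zero would fabricate silence in unvisited bins and
bias spatial information. Frames belong to the lap in progress at
their timestamp; positions are 0-based cm in [0, 180), and all
track distances in the package are circular (the belt is a loop).

## Place-field criteria

A behavioral epoch is one contiguous block (12–18 laps) of a reward
condition. Within an epoch a cell has PF activity when all four hold:

1. **Information.** Skaggs-style spatial information of the epoch-mean
   activity, Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄) with occupancy weights pᵢ,
   exceeds the 95th percentile of a null built by circularly rotating
   each lap's binned activity by an independent random offset
   (n_shuffles = 1,000 by default; per-lap independent rotation keeps
   the per-lap activity structure while destroying spatial alignment).
2. **Peak gate.** A lap is PF-active iff it carries significant
   activity and its peak lies within 54 cm (15/50 bins, circular) of
   the epoch-average peak. Peak ties break to the lowest bin index for
   determinism.
3. **Onset.** The first 5-lap sliding window holding ≥ 3 active laps;
   the onset lap is the first *active* lap inside that window, so the
   onset is itself a lap with field activity.
4. **Reliability.** The active fraction of laps strictly after the
   onset lap is ≥ 0.40.

Criterion 1 is evaluated per epoch, and a cell-condition passes if any
of its epochs passes all four (the pooled-epoch alternative is noted
as ambiguous; per-epoch is the stricter reading and matches the
block-wise task structure). The reported PF location is the peak of
the lap-averaged activity over all passing epochs, reported at the bin
centre (bin × 3.6 + 1.8 cm). Multi-field decomposition is out of
scope: one location per cell-condition-day.

## Day-to-day stability

The signed day-to-day shift is the circular difference wrapped to
(−90, 90], negative meaning backward relative to running direction.
The shift distribution is fit with a Gaussian on a 5-cm histogram
(3 s.d. of that fit, ≈25 cm in the study, motivates the window below).

A **consistency chain** starts at a cell's first PF appearance (per
condition) and extends while the cell has a PF on *every* consecutive
day within ±30 cm (circular) of its first-day location; a missed day
or an excursion beyond the window ends the chain. Both reward
conditions produce independent chains for the same cell.
Classification uses two conventions: for counts, transient ≤ 2 days
vs sustained > 2 days; for group-property comparisons, transient =
1 day and sustained > 2 days with 2-day cells excluded to minimize
misclassification.

Cohort survivor counts are fit with
N(d) = A₁e^(−d/τ_fast) + A₂e^(−d/τ_slow) by bounded least squares
from three starting points, taus returned ordered; non-convergence
falls back to a single exponential and is flagged on the result.

### The memoryless-random expectation

The null against which the observed accumulation of past place cells
is judged is a memoryless process: every available neuron becomes a PC
each day with probability 0.3 (≈767/2,511) at a uniform location, and
a chain survives a day with probability 0.3 × (60/180) (PC again, and
within the ±30-cm window covering 60 of 180 cm). The published
recurrence for this expectation is terse and its expansion is not
unique, so `expected_random_past_pcs` exposes the choices as
parameters: cohort construction (first appearances, with availability
shrinking geometrically by previously recruited cells, vs a fixed-rate
cohort every day), the decrement rule, whether expectations are
propagated as whole-cell counts (round half to even, with a 1e-9
pre-round so exact .5 boundaries such as 753 × 0.1 are stable), and
whether the two reward conditions are summed. The documented default —
first-appearance cohorts, 60/180 jitter, integer propagation, both
conditions, days 2–7 — evaluates to 490 expected past place cells at
the study's numbers; the continuous expectation is 489.1. An
independent Monte-Carlo oracle (`simulate_random_past_pcs`) simulates
the binary process directly and is required by the tests to agree with
the continuous expectation within sampling error.

**Past/new counts** label a day-d PC "past" when any earlier day's
location lies within the window of its day-d location. The
**stability index** compares, for days d and d+2, the number of PCs
with |shift| < 20 cm against the upper 99% bound of 10,000 bootstrap
permutations of the day-(d+2) locations across cells, normalized by
the day-d PC count; fewer than 10 paired PCs yields NaN. The
permutation null was chosen because the source text specifies only "a
random distribution"; permuting locations preserves both days'
marginal location distributions.

## Discrimination and behavioral metrics

Cosine-similarity matrices l2-normalize each lap's binned activity
(zero-norm laps give zero similarity) and take the Gram matrix; the
population version first concatenates the cells' maps horizontally.
CDI/PDI average, over rows with nonzero norm, the mean within-condition
minus between-condition similarity, excluding the diagonal — including
self-similarity would report spurious discrimination for
context-identical activity. PF density uses 50 bins with a
uniform-redraw bootstrap (10,000 resamples, 99% CI); onset-lap
comparisons use the two-sided asymptotic KS test. Licking probability
per bin is the fraction of laps with ≥ 1 lick in the bin; selectivity
= (P_ant − P_rand)/P_ant with the anticipatory zone the three bins
before each lap's reward location and the random zone three bins
around the light cue, excluding any reward zone (configurable);
P_ant = 0 is undefined and returned as NaN.

## BTSP and plateau analysis

At the lap × bin level a Ca²⁺ event is a lap's peak significant ΔF/F
(the generator emits at most one field transient per lap, making the
lap peak the faithful equivalent of a contiguous-transient event). An
event is a putative BTSP induction when (1) its amplitude is in the
cell-session's top 20th percentile with a floor of 1 ΔF/F — the
percentile reference set is all of the cell's events in the session,
exposed as an option; (2) laps qualify for the remaining checks only
when their peak lies within 45 cm of the event peak; (3) at least 3 of
the 5 subsequent laps qualify; and (4) the mean COM of the qualifying
post-laps — activity-weighted circular mean over bins within ±45 cm of
the event peak — is shifted backward (< 0) relative to the event peak.
The first event per cell-session-condition drives the pre/post
statistics. The plateau threshold is the minimum amplitude among the
cell's detected BTSP events; events at or above it count as putative
plateau potentials, reported as a per-lap rate.

Field width is the full width at half maximum of each qualifying
post-lap's profile (half-max crossings located by linear interpolation
between bins), averaged over post-laps. Measuring on each lap rather
than on the pooled post-mean avoids convolving the backward drift into
the width. Two residual biases remain and are visible in the tests'
tolerances: bin quantization (±1.8 cm on the event peak location,
which is why the backward-shift criterion needs drift larger than half
a bin to be decidable on synthetic data), and a small pedestal the
running-median baseline absorbs when a wide field occupies a large
fraction of every lap, which narrows measured widths by roughly 10%
at the default synthetic duty cycle. The width–velocity regression is
ordinary least squares via statsmodels.

Membrane-potential plateau detection removes spikes (0.26 ms before to
3 ms after each upward crossing of dV/dt = 25 V/s), linearly
interpolates the gaps, then takes −35-mV threshold crossings;
crossings separated by < 150 ms (consecutive theta cycles) merge into
one event whose duration is the summed time above threshold, and
events are long-lasting when that total exceeds 150 ms. By default
only long-lasting plateaus are returned. The per-trial baseline
correction (5th-percentile spike threshold re-referenced to −50 mV) is
available but not applied to synthetic traces; no liquid-junction
correction is applied.

## Generative models

### Three-pool kinetics

k₁ + k₂ = −ln((2511 − day-1 total)/2511) per hour, split by the
fast/slow amplitude fractions of the cohort-decay fit; k₃ = 1/τ_fast,
k₄ = 1/τ_slow per day. The magnitudes (not the negative logs) are
used so the available pool depletes during activation. The amplitude
split is not printed in the source; the defaults (0.784/0.216 of the
767-cell day-1 total) are derived from the reported day-1 cohort
retention of ~35% on day 2 and ~6% on day 7 together with the printed
taus. Integration is forward Euler, dt = 0.01 h for 100 activation
steps (1 h on-track); the off-track phase runs 2,300 steps. The decay
clock advances one full nominal day per off-track phase
(`decay_days_per_phase = 1.0`): with k₃ defined as 1/τ_fast from a fit
at daily resolution, only a full day of decay per day reproduces those
taus when the model's own cohort counts are refit — the 23/24-day
alternative is available but breaks that self-consistency by a factor
24/23. Daily rescaling uses a = 1 − (T+S)/(expected daily total, 767)
applied to k₁ and b = 0.6·a applied to k₂; b's multiplier is the
model's only free parameter and `three_pool_fit_b` recovers it by grid
scan plus bounded scalar minimization of the mean squared error over
the 7 days × 2 pools. [A]+[T]+[S] is conserved to machine precision
(asserted in the tests).

### Cascade state model

Cells start 88% in unreliable state 0 and 12% in unreliable state 1
(a training effect). Parameters follow the printed formulas:
q_i = 0.5353·e^(−0.3327(i−1)) + 0.2912, α_i = 6.6259(1−q_i)²,
β_k = 0.4927·e^(−0.1289(k−1)) + 0.7032·e^(−1.1846(k−1)),
γ_l = (1 + min(l/6,1))/(1 − 0.5·min(l/6,1)) with l the days the
previous field was sustained (the cell's state count is used for l).
Transition indexing uses the *destination* state: recruitment from
resting state i uses α_{i+1}, and the post-activation decay draw uses
q at the newly reached state. With source-state indexing the printed
initialization yields far fewer day-1 PCs than the study's daily
count; destination indexing reproduces it, and both conventions sit
behind the `indexing` switch. α_i β_k is clamped to [0, 1) before the
(1 − αβ)^(1/N) root since the printed α exceeds 1 at high states and
β₁ > 1. β_k uses the printed average formula; the per-run count
controller the source alludes to is not implemented (the average
formula already holds daily counts nearly constant).

Salience uses δ = 1.7 inside the zones [30, 60] ∪ [120, 150] cm with
bins at x_j = j·L/N. Normalizations divide by 1 + (δ−1)s and
1 + (γ−1)f with s and f the *actual* fractions of bins inside the
salience zone and the ±30-cm history window, so the track averages of
Sal and Loc are exactly 1 (the printed Loc constant assumes the window
is exactly 1/3 of the track, which a 50-bin grid does not realize; the
printed constant is available via `printed_loc_normalization`). Cells
with no previous field have Loc ≡ 1. New field locations are drawn
from Pr(j) ∝ Sal(x_j)Loc(x_j).

The simulation is vectorized over cells via per-day lookup tables of
p and the location CDF indexed by (state, previous bin).
`cascade_enumerate` independently propagates the exact probability
distribution over (state, reliable flag, previous bin) through the
same daily two-phase update — an exhaustive Markov computation the
tests use as an oracle against the Monte-Carlo simulation at small n
(the enumeration mirrors the simulation's integer initial split, which
matters at n = 10).

### Progressive stabilization

Two branches only: no-PF and active-PF states i = 1, 2, …; recruitment
p₁ = 0.3186·β_k (same printed β_k), f = 1 for continuing cells, and
escape q_i = 0.67^i applied at the state reached after activation. A
single missed day resets stability entirely, which is what makes its
days-active distribution separable from the cascade model's.

Summaries (days-active distribution, reappearance probability after
exactly one missed day stratified by prior active days,
sustained/transient daily counts via the same chain rule as the data
analysis, PF density) are computed per replicate and reported as
mean ± s.e.m.; the source runs 1,000 replicates and that is the
config default.

## Synthetic data generator

The generator emulates the study's design: 2,511-cell scale (size is
a required argument; tests run tens to hundreds of cells), 7 days,
126 laps/session in 12–18-lap alternating blocks, RL1/RL2 rewards at
100/160 cm, cue at 40 cm, 30-Hz frames. Behavior: per-lap base speed
25 cm/s with 25% lap-to-lap variability (so the width–velocity
regression has leverage), a Gaussian slow-down (50% dip, 12-cm scale)
approaching the lap's reward, Bernoulli licking elevated (0.12/frame
vs 0.005) in the three-bin anticipatory zone. Cells: 30% day-1 PCs,
22% of them sustained; per-day survival 0.80 (sustained, matching
e^(−1/4.6)) vs 0.22 (transient, e^(−1/0.67)); 5%/day recruitment of
never-active cells; half the PCs are context-selective. Fields are
Gaussian bumps in ΔF/F: induction lap at 3.0 ΔF/F, subsequent laps
0.8 ΔF/F at 85% reliability, FWHM = 0.80·v_onset + 18.95 cm, backward
COM drift of 1 cm/lap with a 4-lap decay, sustained centres jittered
4 cm day to day (within the ±30-cm window), extra plateau-amplitude
events at 0.06/lap, white noise at 0.1 ΔF/F on raw fluorescence
F = 100(1 + ΔF/F). The ordinary-lap amplitude sits below the 1-ΔF/F
event floor so that plateau-scale events separate cleanly under the
minimum-of-BTSP-events threshold rule, while induction events exceed
both the floor and the 80th percentile by construction. The
lap-to-lap variability of transient cells has no published generative
model; reliability and survival are free parameters, not claims of
fidelity.

What the generator does *not* emulate: calcium-indicator kinetics
(each traversal paints the spatial tuning curve directly rather than
spike-driven transients — this inflates the within-lap duty cycle and
is the source of the ~10% width attenuation noted above), imaging
artifacts, motion, cross-day registration errors, theta phase
precession, and multi-field cells. Passing tests therefore certify
the analysis logic and its calibration on idealized fields, not
performance on raw microscope output.

Membrane-potential synthesis places specified plateau depolarizations
(to −28 mV, 2-ms edges kept below the spike dV/dt gate) and Poisson
spikes on a −62-mV baseline at 20 kHz; overlapping plateau
specifications raise.

Determinism: the cell plan uses one RNG stream derived from the seed,
and each session's behavior/noise uses a stream derived from
(seed, mouse, day), so identical seeds give bit-identical experiments.

## Problem sizes

Defaults in tests and examples use tens to a few hundred cells, 1–3
days and 30–40 laps — sizes at which every stage's behavior is already
fully exercised and parameter recovery is tight. The model
computations (cascade at 2,511 cells × 1,000 replicates, the
enumeration oracle, the three-pool refit) run at full study scale
throughout.
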