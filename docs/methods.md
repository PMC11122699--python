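# Methods

## Model

The shrinking spotlight model (SSP) treats flanker-task decisions as a
single-stage diffusion process whose drift is gated by spatial attention.
Five contiguous unit-width items sit on a one-dimensional axis — target at 0,
foils at ±1 and ±2 — and a zero-mean Gaussian "spotlight" assigns each item
the probability mass over its spatial extent.  The drift toward the correct
boundary is

v(t) = p · [w_target(t) + foil_sign · Σ w_foil(t)],

where foil_sign is +1 (congruent) or −1 (incongruent).  The spotlight's
standard deviation narrows linearly, sd(t) = max(sd_a − rd·t, sd_floor), so
foil interference decays and vanishes after the interference time sd_a/rd.
Evidence starts at 0 (no response bias), boundaries sit at ±A (the single
reported boundary value is interpreted as a symmetric separation from the
start point), and RT = T_er + first-passage time.  No across-trial
variability parameters are included.

### Units

Response times and T_er are in seconds at the model level (ms at the data
level); p is evidence per second; A is in evidence units.  The spotlight
clock runs in **milliseconds of decision time**: rd is sd units per ms, and
interference time is in ms.  This dual-clock convention is the only one under
which the conventional parameter scales are jointly coherent — non-decision
times near 0.3 s, boundary separations near 0.08 and drift rates near 0.5/s
produce realistic 300–700 ms response times, while interference times of
30–60 must resolve *within* a trial's first tens of milliseconds for the
model to produce its defining fast-error signature at all.  All group-level
conclusions the package computes (effect sizes, rank tests, recovery
correlations) are invariant to this choice.

## Simulation

Euler–Maruyama integration with dt = 1 ms and diffusion coefficient s = 0.1
(the conventional scaling of the diffusion-model literature), truncation
horizon 3 s.  Truncated trials are flagged, assigned the horizon RT and
accuracy 0, and are excluded from fit binning — mirroring the empirical miss
screen, which removes them anyway (their nominal RT exceeds 2000 ms).
sd_floor = 0.001 keeps the Gaussian mass computation defined after full
narrowing; foil weight at that width is negligible (< 1e-300).

The trial loop is JIT-compiled (numba) and reads from a pre-generated
standard-normal increment matrix; a pure-NumPy cumulative-sum implementation
is kept as a fallback and is cross-checked against the compiled path on
shared noise in the test suite.  Supplying one fixed noise matrix across
objective evaluations ("common random numbers") makes the G² surface
deterministic, which Nelder–Mead handles far better than a stochastic
objective; the same matrix is shared between conditions, which additionally
cancels simulation noise out of predicted condition differences.

## Fitting

Each condition's trials are partitioned jointly by response type and RT:
correct responses into quantile bins at cut points .1/.3/.5/.7/.9 of the
participant's own correct RTs, and errors into quantile bins of the error
RTs when a condition has at least 11 errors, else a single pooled error bin
(quantile estimates are unstable below roughly two observations per bin).
This joint binning carries the cumulative RT distributions of both response
types plus the accuracy mass — the same information as CDF-plus-CAF
objectives.  Predicted bin probabilities come from forward simulation
(default 25,000 trials per condition per evaluation), floored at
1/(2·n_sim) and renormalised so G² stays finite; the discrepancy is

G² = 2 Σ_c N_c Σ_bins p_obs ln(p_obs/p_pred),

with zero-observation bins contributing nothing.  Fit quality is summarised
by the binned BIC, G² + k·ln(N) with k = 5 free parameters and N the trial
count.

Optimisation is two-stage Nelder–Mead from the conventional start
(A = 0.05, T_er = 0.3, p = 0.4, rd = 0.05, sd_a = 1.5): a 1,000-evaluation
first stage and a 50,000-evaluation refinement from the stage-1 best.  The
stage-1 budget is interpreted as an evaluation budget from the single named
start; a config switch (`n_starts`) instead splits it across jittered
restarts.  Bounds (A ∈ (0, 0.5], T_er ∈ [0, min observed RT), p ∈ (0, 2],
sd_a ∈ (0, 5], rd ∈ (1e-5, 1]) are enforced by an additive penalty.  Because
the best Nelder–Mead vertex never worsens, stage-2 G² ≤ stage-1 G², and with
common random numbers the whole fit is reproducible from its seed.

### Recovery-study problem size

The library defaults above are expensive (minutes per participant).  The
parameter-recovery study and the acceptance script instead use
`RECOVERY_SETTINGS`: 4,000 simulated trials per condition per evaluation,
450 stage-1 evaluations split over a three-way jittered multistart, and
2,000 stage-2 evaluations.  These were chosen from a pilot of fit quality
against cost: the multistart eliminates occasional catastrophic basins for
extreme participants (very low boundaries), and matching the fitting horizon
to the generator's 3 s horizon removes a truncation bias for slow
participants.  Under these settings a 24–30 participant recovery run takes
a few minutes and yields Spearman correlations of roughly 0.7–0.9
(interference time) and 0.8–0.95 (A, p, T_er) between generating and
recovered values; interference time is the weakest because participants with
short interference or very high perceptual strength leave little of its
signature in 384 trials.

## Screening and distributional analyses

RTs below 150 ms are anticipations and above 2000 ms misses (strict
inequalities; the boundary values are retained), removed before analysis;
participants below 65% overall pre-screen accuracy are excluded (exactly 65%
is retained).  The CE uses mean correct RTs per condition — means rather
than medians so the CE feeds the t-based TOST machinery directly.
Conditional accuracy functions bin **all** responses by within-condition RT
quantiles (accuracy is defined over all responses); delta plots use correct
trials only, differencing per-decile mean RTs between conditions.  Group
curves are Vincentized (participant-level bin values averaged bin-wise), the
standard aggregation for these plots.  With equal-probability bins the mean
of a participant's decile differences equals their CE exactly, a consistency
the tests assert.

## Group statistics

- **Cohen's d**: pooled-SD standardized mean difference; CIs by the same
  bootstrap as the mean difference rather than the noncentral-t closed form,
  matching estimation-graphics practice.
- **Bootstrap**: within-group resampling, 5,000 resamples, BCa intervals by
  default (percentile by config), via `scipy.stats.bootstrap`.
- **TOST**: the equivalence region is stated in d units (default ±0.31) and
  converted to the raw scale with the pooled SD of the two observed samples
  (the documented convention of the standard equivalence-testing packages);
  each bound gets a one-sided Welch test and equivalence requires both to
  reject.  The two-sided Welch NHST is reported alongside.  The test suite
  cross-checks against statsmodels' independent implementation.
- **Mann–Whitney U**: exact null distribution for tie-free samples with
  n_x·n_y ≤ 400, otherwise the normal approximation with tie and continuity
  corrections (scipy).  The one-sided direction is stated explicitly in
  configuration (`greater_group`), never inferred from label order.
- **Power**: noncentral-t with ncp = d·√(n/2), df = 2n − 2.
- **Normality screen**: Shapiro–Wilk; used only to route the CE to t-based
  tests and fitted parameters to rank tests.

## Synthetic studies

The generator emulates a two-group study of 144 and 146 participants, 8
blocks × 48 trials (384 trials, 50% congruent).  Participant parameters are
drawn independently from normals truncated at the fitting bounds, centred on
the two groups' published summaries; sd_a is held at 1.5 and rd derived from
the drawn interference time (43.61 ± 28.04 vs 33.50 ± 15.99 ms).  Contaminant
trials replace simulated RTs at per-trial rates matching the reported
screening fractions (anticipations 0.28% vs 0.11%, misses 1.36% vs 0.28%),
with RTs uniform on 50–149 and 2001–3000 ms so the screen captures exactly
the injected trials.  A ground-truth table records every generating
parameter and contaminant count for recovery scoring.

What the generator does **not** emulate: block/practice effects, RT
autocorrelation, parameter correlations across participants (none are
published), questionnaire measures, and — because the SSP with conventional
diffusion scaling produces few errors at these parameter values — empirical
error *rates*: simulated accuracies run higher than real flanker data,
though the temporal structure of the errors (fast errors on incongruent
trials, shrinking error congruency effect across RT bins) is preserved.
Passing tests therefore demonstrate internal consistency of the pipeline and
qualitative fidelity of the model's signatures, not quantitative realism of
error frequencies.  One further documented quirk: the emulated design's
trial count is taken as 8 × 48 = 384, the only internally consistent reading
of the published block structure.

## Determinism

Every random draw descends from one master seed via
`numpy.random.SeedSequence` spawning: the study generator, each
participant's fit (noise matrix and multistart jitter) and the bootstrap
receive independent child streams.  Rerunning the pipeline with the same
configuration and seed produces byte-identical reports; the report echoes
the full configuration for audit.

## Known limitations

- Simulation-based likelihoods: G² carries Monte-Carlo error at finite
  n_sim; the floor-and-renormalise smoothing slightly biases probabilities
  in near-empty bins.
- Interference time is weakly identified for participants whose decisions
  outrun the spotlight (high p, short interference) — a data limit, not an
  optimiser limit.
- No hierarchical pooling: each participant is fit independently, so
  extreme participants get noisy estimates.
- The first-passage discretisation (1 ms Euler steps) slightly inflates
  boundary-crossing times relative to the continuous process.
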