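# flankerssp

Shrinking-spotlight modelling and distributional analysis of flanker-task
data.

In the flanker task, participants make a speeded judgement about a central
target flanked by foils that are congruent or incongruent with it.  The
*congruency effect* (CE) — the incongruent-minus-congruent difference in mean
correct response time — indexes interference from the foils, but it conflates
attentional suppression with response caution and general processing speed.
`flankerssp` is for researchers who want to separate those contributions by
fitting the **shrinking spotlight model** (SSP) to trial-level RT/accuracy
data, typically when comparing two groups (the package ships study
conditions emulating an autistic vs non-autistic adult comparison).

## The model

The SSP is a drift-diffusion account of flanker performance.  Evidence *x*
accumulates toward response boundaries at ±*A* from an unbiased start:

    dx = v(t) dt + s dW,        RT = T_er + first-passage time

with drift determined by a Gaussian attentional spotlight centred on the
target.  Each of the five unit-width items (target at 0, foils at ±1, ±2)
receives the spotlight mass over its extent, and

    v(t) = p · [ w_target(t) + sign · Σ w_foils(t) ]

with sign +1 on congruent and −1 on incongruent trials.  The spotlight's
standard deviation narrows linearly from *sd_a* at rate *rd*, so foil
interference dies out after the **interference time** *sd_a*/*rd* — the
model's key index of suppression efficiency.  Early in an incongruent trial
the drift can point at the wrong boundary, producing the classic fast-error
signature in conditional accuracy functions.

Free parameters per participant: boundary separation *A* (response caution),
non-decision time *T_er* (seconds), perceptual strength *p* (evidence/s),
spotlight width *sd_a*, and narrowing rate *rd* (sd units per ms of decision
time; interference time is therefore in ms).  Fitting minimises the
likelihood-ratio chi-square

    G² = 2 Σ_c N_c Σ_bins p_obs ln(p_obs / p_pred)

over per-condition RT-quantile bins of correct and error responses, with a
two-stage Nelder–Mead search (1,000-evaluation pass from conventional
starting values, then a 50,000-evaluation refinement) and fit quality
summarised by the binned BIC, G² + k·ln(N).

Around the model sit the pipeline stages: trial screening (RT < 150 ms and
> 2000 ms removed; participants below 65% accuracy excluded), per-participant
CEs, Vincentized conditional accuracy functions and delta plots, and the
group statistics — Welch-based TOST equivalence testing with bounds stated as
Cohen's d (default ±0.31), pooled-SD effect sizes with BCa bootstrap CIs,
one- and two-sided Mann–Whitney U tests, noncentral-t power, and a
Shapiro–Wilk normality screen.  A synthetic-data module generates complete
two-group studies with known ground truth, including anticipation and miss
contaminant trials, so every stage is testable without any data download.

## Worked example

```python
import dataclasses
from flankerssp import synth, preprocess, stats
from flankerssp.fitting import fit_participant, RECOVERY_SETTINGS

spec_a = dataclasses.replace(synth.AUTISTIC_LIKE, n_participants=30)
spec_b = dataclasses.replace(synth.NON_AUTISTIC_LIKE, n_participants=30)
trials, truth = synth.generate_study(spec_a, spec_b, seed=11)

trimmed, screen = preprocess.trim_trials(trials)
ce = preprocess.congruency_effects(trimmed)
x = ce.loc[ce.group == "autistic", "ce"].to_numpy()
y = ce.loc[ce.group == "non-autistic", "ce"].to_numpy()
res = stats.tost_equivalence(x, y, d_bounds=(-0.31, 0.31))

fit = fit_participant(trimmed[trimmed.participant == "A002"],
                      fit_settings=RECOVERY_SETTINGS, seed=1)
```

prints (via the obvious `print` calls):

```
screened 45 anticipations (0.20%) and 183 misses (0.79%) from 23040 trials
mean CE: autistic 33.1 ms, non-autistic 25.8 ms
TOST: t_lower = 2.81 (p = 0.003), t_upper = 0.41 (p = 0.658), equivalent = False
NHST: t(54.6) = 1.61, p = 0.113, d = 0.42
A002: fitted interference time 34.9 ms (generating value 36.6), G2 = 14.72, BIC = 44.42
```

Reading the output: the two groups were generated with mean interference
times of 43.6 vs 33.5 ms, and the longer-interference group indeed shows a
larger mean CE (33.1 vs 25.8 ms).  The TOST rejects the lower equivalence
bound but not the upper one, so equivalence cannot be concluded — the effect
may be as large as the upper bound — while the two-sided test at this small
n (30 per group) is not significant.  The single-participant fit recovers
the generating interference time to within a couple of ms.

The same pipeline is available from the shell:

```
flankerssp simulate --seed 1 --out-trials trials.csv --out-truth truth.csv
flankerssp fit trials.csv --out fits.csv --seed 1
flankerssp analyze trials.csv --outdir results --seed 1
flankerssp recover --n 20 --seed 1 --out recovery.csv
```

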