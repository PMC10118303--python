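# Methods

## Task model and session schedule

The package analyzes entry-event streams from a three-hole home-cage operant
task. A session lasts 90 h: acquisition over hours [0, 49) with the left hole
rewarded, reversal over hours [49, 90) with the right hole rewarded, under a
repeating 12-h light:12-h dark cycle whose first dark phase starts at hour 3
(dark phases [3, 15), [27, 39), [51, 63), [75, 87)). All hour windows are
half-open, 0-based from session start, and an event exactly on a phase
boundary belongs to the later phase. The dark onset of 3 h is the value under
which the conventional analysis windows — hours 3–12 of acquisition and
51–61 of reversal — coincide with the first ten hours of each phase's first
dark period; it is configurable, and changing it relabels light/dark flags
without ever changing counts.

## Criterion detection

An animal attains criterion at the first phase entry n (1-based) such that
the trailing `window` entries (default 30) contain at least
`threshold·window` correct choices (default 0.80, so 24/30 attains). The
window must be complete — no attainment before entry 30 — and the entry
counter resets at the scope's phase start, so acquisition performance never
leaks into the reversal criterion. Threshold comparison uses an absolute
slop of 1e-9 on the window count so exact fractions like 24/30 are never
lost to floating-point rounding. Non-attaining animals are censored: ETC is
recorded as their total phase entries (a lower bound) and HTC as the phase
end hour. HTC uses the session clock, not a phase-relative clock (matching
the convention in which acquisition attainment "under 40 h" is meaningful);
attainment curves are tabulated as right-continuous step functions with
censored animals in the risk set but never in the reached proportion.

## Learning indices

All indices are (correct − incorrect)/total over a chosen entry set and are
bounded in [−1, 1]. Zero-entry sets yield NaN, never 0 — a zero asserts
chance-symmetric performance that absent data cannot support — and NaN hours
are excluded from group averages rather than imputed. Initial learning rate
and cognitive flexibility are the windowed index over hours [3, 13) and
[51, 61) respectively; both windows are config-exposed. The windowed form
normalizes by entries (not time): an alternative time-normalized reading of
"derived from total entries during the first dark phase" was considered and
rejected because the entry-normalized index is the one whose cumulative and
hourly variants the task literature defines, keeping all three measures on
one scale. Extinction curves report per-hour percentages of left, middle,
and error (left + middle) entries over the same reversal window.

## Stratification

The young-reference cutoff is the upper bound of the two-sided 90%
confidence interval of the young mean reversal ETC, mean + t₀.₉₅,ₙ₋₁·SEM,
rounded **up** to the nearest 100 entries. This interpretation was chosen
because it reproduces the published operational cutoff from the published
young summary (813.03 + 1.6849·105.92 ≈ 991.5 → 1,000 entries); the CI
formula and rounding are not stated in the source, so a percentile
reference-interval method is available as an alternative
(`method="percentile"`). Ties go to impaired (intact is strictly `<`
cutoff), and censored animals are impaired by extension — in the original
cohort every aged animal eventually reached criterion, so this case only
arises in simulation or truncated sessions. z-scores use the sample SD
(ddof = 1) over the full tested cohort by default. The 3-D embedding
centers features, takes the top-2 principal axes by SVD with the
largest-magnitude loading of each axis forced positive (a deterministic
sign convention), and appends the behavioral z-score as the third axis.

## Group statistics

Log-rank and Gehan–Wilcoxon comparisons of criterion attainment are
delegated to lifelines' multivariate log-rank machinery, with the Wilcoxon
variant implemented as Gehan–Breslow (weights = number at risk), the common
default in the commercial packages this analysis family uses; Peto–Peto
weighting was not implemented. Tests are verified in the suite against
hand-computed risk-set arithmetic and 10,000-draw permutation nulls.
One-way ANOVA is computed from the explicit sum-of-squares decomposition so
the zero-within-variance degenerate case reports an infinite F with p → 0
and a flag; Tukey HSD uses the studentized-range distribution (scipy) and
Šidák adjustment is 1 − (1 − p)^m. Repeated-measures/mixed-effects fits are
out of scope: the pipeline exports long-format per-hour tables for use with
standard mixed-model software. OXPHOS coupling efficiency is 1 − GM/S on
antimycin-A-baseline-subtracted oxygen consumption rates; GM > S yields a
negative value that is returned with a warning, never clamped.

## Synthetic cohort generator

`simcage` emulates the study conditions so every stage is verifiable without
animal data. Entry timing is an inhomogeneous Poisson process with
piecewise-constant hourly rate — `rate_dark` = 120 and `rate_light` = 25
entries/h — realized per hour as a Poisson count with sorted uniform times,
which is distributionally identical to an exponential clock switching with
the light:dark cycle. The rates are chosen so a reversal phase (24 dark +
17 light hours ≈ 3,300 entries) comfortably contains the largest observed
ETC (~2,400 entries). Choice follows a three-alternative model:

    p_correct(n) = q_asym − (q_asym − q0)·exp(−n/τ_phase)

with n counting entries within the phase (reset at reversal) and q0 = 1/3
(chance). The residual error mass goes to the middle hole with probability
`beta_mid` during acquisition, and to the previously rewarded left hole with
probability `w_persev` during reversal — the simplest mechanism producing
perseverative errors and slow extinction in impaired animals.

Default phenotypes (label: q_asym, τ_acq, τ_rev, w_persev):

- young: 0.85, 350, 850, 0.50
- aged_intact: 0.85, 350, 800, 0.50
- aged_impaired: 0.80, 450, 3200, 0.65

q_asym and w_persev for the impaired phenotype encode its qualitative
signature (lower asymptote, most errors at the old hole); the τ values are
calibrated constants, set so cohort median reversal ETC lands within ±25% of
the published group means (813 young / 737 intact / 2,439 impaired) — they
are modelling choices, not measured quantities. Body-weight loss is Gaussian
per group with the published means (5.5/5.3/6.6%) and SD recovered from the
published SEMs; activity (distance moved) is drawn from one circadian
distribution shared by all phenotypes, since the study found no group
differences in movement; pellets dispense every `reward_every_n_correct`-th
correct entry (default 1 — the true reinforcement ratio is unstated and
config-exposed, as is the entry-rate magnitude). All randomness derives from
one master seed via spawned child sequences, so outputs are byte-identical
per (config, seed).

What the generator does **not** emulate: position/velocity within the cage
(only hourly distance), social or stress effects, satiety or motivation
drift, within-animal rate fluctuations beyond the two-level circadian
profile, and any realistic transcriptomic structure — the feature-matrix
helper produces Gaussian features with block mean-shifts only. Passing
tests therefore demonstrate the correctness of the analysis pipeline under
a plausible behavioral model, not fidelity of any particular mouse cohort.

## Problem sizes and numerical choices

The test suite exercises cohorts of 6–16 animals/group and 20-seed replicate
sweeps; the Monte-Carlo stratification check uses 2,000 replicate 35-animal
cohorts with per-animal SD recovered from summary SEM as SEM·√n and draws
floored at 30 entries (the minimum attainable ETC). These sizes give stable
medians and fraction estimates (Monte-Carlo SE of the impaired fraction
< 0.2 percentage points) while keeping any single check in seconds. Survival
tables break ties by pooling equal attainment values into one step;
classification is a pure per-animal function and hence order-independent.

## Known limitations

- The cutoff CI interpretation reproduces the published operational value
  but is unconfirmed by the source; use the percentile method to probe
  sensitivity.
- The learning model has no lapses, warm-up, or forgetting; ETC
  distributions are narrower than real cohorts at equal medians, so the
  simulated young reference yields a tighter (lower) cutoff than the
  published 1,000 entries — pipeline runs on simulated data report both the
  raw bound and the rounded cutoff they actually used.
- The Gehan–Wilcoxon variant is Breslow-weighted; results can differ from
  Peto–Peto on heavily censored data.
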