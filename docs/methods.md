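# Methods

## Session model and event processing

A session is an ordered stream of timestamped events — active and
inactive nose-pokes, licks, and sipper extensions/retractions — with
times in seconds from session start at millisecond precision
(`EventRecord`). Validation enforces sorted times within
`[0, duration]` and strict extend/retract alternation beginning with an
extend. Derived summaries:

- **Intake** in g/kg: `volume_mL × ethanol_vv × ρ / (weight_g / 1000)`
  with ethanol density ρ fixed at 0.789 g/mL. The weight used is the
  same-day session weight. Dry (conditioned-reinforcement) and
  water-only sessions have zero alcohol intake by definition.
- **Binned rates** use half-open bins `[i·w, (i+1)·w)`; an event exactly
  at the session end is assigned to the last bin so counts are always
  conserved. Default widths follow convention: 10 s for responses, 1 s
  for licks.
- **Cumulative records** start at (0, 0) and are extended to
  (duration, n) for plotting.
- **Lick microstructure** partitions licks into bursts: maximal runs
  whose consecutive interlick intervals are at or below a threshold,
  default 0.5 s. No standard threshold exists; it is a parameter. A
  lickometer debounce (collapse of events < 20 ms apart, the instrument
  chatter scale) is applied when reading real logs and disabled for
  simulated ones.
- **Lick calibration**: intake regressed on lick count by ordinary
  least squares. Because a session's intake is the sum of L roughly
  independent per-lick volumes, the residual variance grows with L;
  the reported slope standard error is therefore HC3
  heteroscedasticity-robust rather than classical. `slope_ci95()`
  gives the robust 95% interval. The fit refuses fewer than 3 pairs or
  a constant predictor.

### Acquisition state machine

Training proceeds magazine → criteria 1 (FR 1, 30 s access) →
criteria 2 (FR 1, 10 s) → discrimination (FR 5, 10 s), with all
acquisition sessions capped at 100 licks or one hour. Advancement:
magazine after the cap is reached once; criteria 1 and 2 after the cap
on two consecutive days; discrimination is acquired after two
consecutive sessions with discrimination index ≥ 0.70 *and* the cap
reached. Three consecutive failing sessions revert the animal one
phase; three reverts in total remove it. Two choices the protocol
leaves open are resolved as follows: magazine failures do not accrue
reverts (there is no previous phase), and consecutive-success windows
reset when a revert occurs. A discrimination index with zero total
responses is returned as NaN — distinct from 0 — and counts as a failed
session.

## Phenotyping

Scores are percents of the cohort mean of per-subject means (see
README). Numerical decisions:

- The normalization denominator is the mean of subject means, not the
  mean over all session values; the two coincide in balanced designs
  and the subject-mean form is robust to missing sessions (a subject
  uses the mean of whatever sessions it has; it is excluded, with a
  warning, only if a condition has no sessions at all).
- The published rules use strict inequalities in both directions, so a
  score of exactly 100 is formally unassigned. Ties resolve downward —
  100 is "not above average" — so quinine = 100 is not Compulsive and
  alcohol = 100 is Low. Compulsive is checked first because its rule
  carries no alcohol-score condition.
- Normalization is scale-invariant and permutation-equivariant, and
  each score column averages exactly 100; these are tested as
  invariants.
- Cohorts below 15 subjects trigger a warning (see stability below);
  below 2 the computation refuses to run.

## Subsampling stability

For each subsample size k, `iterations` subsets of k subjects are drawn
uniformly without replacement; normalization and labels are recomputed
within the subsample; and each sampled subject's label is compared to
its full-cohort label. The primary statistic is the per-subject
mismatch probability (disagreements pooled over subjects and
iterations); the per-iteration any-mismatch probability is reported
alongside, since the protocol literature does not pin down which is
meant. The Monte-Carlo standard error is the standard deviation of the
per-iteration mismatch fractions over √iterations.

Reproducibility: each (k, iteration) cell draws from its own RNG
substream spawned from the root seed, so curves are bit-identical for a
given seed and any cell can be recomputed in isolation.
`exact_mismatch` enumerates all C(N, k) subsets (bounded at 10⁶) and
serves as the oracle for the Monte-Carlo estimator at small N. At
k = N the subsample normalization equals the full normalization, so the
mismatch is exactly zero — a hard invariant.

`recommend_min_n` returns the smallest k from which the *entire tail*
of the curve stays at or below the tolerance (default 0.05, a
conventional choice; "highly stable" has no agreed quantification).
The recommendation is a property of the cohort analyzed: cohorts with
subjects near the 100% boundaries need more subjects than cleanly
separated ones, which is why the package also carries a conservative
default warning threshold of 15 subjects.

## Analyte screen

Spearman rank correlation (midranks for ties) per (region, analyte,
behavior metric) with pairwise-complete observations. Cells with fewer
than 5 complete pairs or a constant variable are reported but marked
not-computed. P-values are exact permutation values (full enumeration
of one rank vector) for n ≤ 10 and use the t approximation otherwise.
Stars are unadjusted, as conventional for exploratory screens of this
kind; `fdr=True` adds Benjamini–Hochberg adjusted values without
changing the stars. The default behavior metrics are the normalized
percent scores; raw g/kg columns can be passed instead via `metrics=`.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with one latent phenotype per subject. Defaults describe the reference
study design: 41 subjects at Low:High:Compulsive proportions 19:5:17,
one-hour FR-10 sessions with 10 s access windows, 15% (v/v) ethanol, 3
alcohol-only + 4 graded-quinine sessions in both the pre-binge and
phenotyping epochs, and a 14-day two-bottle binge epoch (two cycles of
2, 2, 2, 2, 4, 0, 0 hours of access).

Latent intake model (g/kg per session; values chosen as
mouse-realistic for 15% ethanol one-hour operant sessions):

- Pre-binge propensity: common N(1.0, 0.1) across phenotypes — limited
  early variance by design.
- Post-binge propensity: Low N(0.9, 0.18); High and Compulsive
  N(1.9, 0.25) — individual differences widen after binge experience,
  with High ≈ Compulsive for unpunished drinking.
- Quinine retention (fraction of unpunished intake kept at
  concentration c mM): logistic `floor + (1−floor)/(1+exp(slope·(c−c50)))`
  with floors 0.08 / 0.08 / 0.80 for Low / High / Compulsive — only the
  ordering (Compulsive flattest) is externally constrained; subject
  jitter scales suppression depth so the ordering holds at every tested
  concentration.
- Session-to-session noise: lognormal, CV 0.12.

Event-level rendering: pokes are homogeneous Poisson processes (the
active rate is targeted so the subject earns enough access windows for
its latent lick budget, with a vigor-scaled seeking floor); every
ratio-th poke made outside an open window extends the sipper; licks
occur only inside windows as bursts (ILI ≈ 0.12 s, ~11 licks per
burst); each lick carries an independent volume (default 1.5 µL,
CV 20% — mouse-typical; no published per-lick volume exists for this
task). Sessions truncate at the lick cap when one is set. The
summary-only mode (`include_events=False`) draws session intakes from
the identical latent model and synthesizes plausible counts; it is
~20× faster and is what the stability and recovery experiments use.

Analyte tables couple a fixed set of (region, analyte) cells — e.g.
dPAG GABA/glutamate/glutamine/aspartate to punished intake, monoamine
cells to unpunished intake — log-linearly to the standardized latent
drives with strength `analyte_coupling` (0 gives an exact null table);
remaining cells are pure lognormal noise, for 15 subjects by default.

What the generator does *not* emulate: within-session satiation
dynamics beyond a fixed budget, circadian or inter-day drift,
acquisition-phase learning curves (acquisition sessions are simulated
only schedule-wise, not learning-wise), sex differences, and any
pharmacokinetics. Passing tests therefore demonstrate correctness of
the analysis pipeline and recoverability of planted structure — not
that real cohorts will match any particular curve.

## Problem sizes and determinism

Validation experiments use: 1,000 random cohorts (n = 2–100) for the
normalization laws; 10,000 iterations against exhaustive enumeration at
N = 4–6 for the stability oracle; 100 simulated cohorts for phenotype
recovery (mean accuracy ≈ 97%); 100 calibration experiments of 30
sessions each for CI coverage; and 5 null cohorts (460 cells) for the
screen's false-positive calibration. All randomness descends from
explicit root seeds via `numpy` `SeedSequence` spawning; repeated runs
are bit-identical, and the CLI writes a provenance sidecar (config,
seed, version) next to every output file.

## Known limitations

- The minimum-n recommendation is noisy at the protocol's 100
  iterations (SE ≈ 0.007 near the tolerance) and cohort-dependent;
  cohorts containing borderline-compulsive subjects can need a few more
  subjects than cleanly separated ones.
- Exact screen p-values enumerate n! permutations and are practical
  only at n ≤ 10 (the default crossover).
- The event simulator's Poisson poke process does not reproduce the
  heterogeneous within-session tempo of real animals; it is the
  simplest process satisfying the schedule contracts.
- `read_event_log` accepts only the documented CSV schema; proprietary
  operant-chamber formats must be converted upstream.
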