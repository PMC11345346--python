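# Methods

`corrmem` models and analyzes a three-phase misinformation-correction
paradigm. Participants in two age groups (younger, older) study real and
fake news headlines whose veracity is initially unclear (Phase 1), then
read clearly real headlines that either affirm earlier real news or
correct earlier fake news, reporting when they detect a correction
(Phase 2). After a retention interval they retrieve the real-news detail
for each topic, rate belief in the retrieved detail (1–6), report whether
the topic had been corrected, and — only after a "yes" — try to identify
the fake detail (Phase 3). Each critical topic sits in one of three
conditions: affirmed real [Real 1×, Real 1×], corrected after one fake
exposure [Fake 1×, Real 1×], or corrected after three fake exposures
[Fake 3×, Real 1×].

## The dual-process multinomial processing tree

In the correction conditions the Phase-3 response falls in one of three
categories: the real detail, the previously seen fake detail, or a novel
fake foil. The tree maps recollection *Pr* and familiarity *Pf* to these
categories:

```
p_real  = Pr + (1−Pr)·Pf·0.5 + (1−Pr)·(1−Pf)·g_real
p_fake  =      (1−Pr)·Pf·0.5 + (1−Pr)·(1−Pf)·g_fake
p_novel =                      (1−Pr)·(1−Pf)·g_novel
```

Recollection retrieves the correction episode and yields the real
detail. If recollection fails, familiarity makes the two previously seen
details equally attractive (the 0.5 split is fixed, never estimated).
Without familiarity the response is a guess. Two readings of the guessing
branch are implemented because the verbal descriptions in the literature
are ambiguous between them: `UNIFORM_THIRDS` (default; the three
categories equiprobable, g = 1/3 each) and `SEQUENTIAL_HALVES` (two
successive 0.5 splits, g = 1/2, 1/4, 1/4). The two readings give
different likelihoods, so the choice is an explicit config option rather
than a silent default.

The tree is analytically invertible on its interior:
(1−Pr)(1−Pf) = p_novel/g_novel and (1−Pr)·Pf = 2(p_fake − p_novel),
giving the closed-form moment estimator used both as a fast point
estimate and as the independent oracle against which the Bayesian fit is
tested. Observed frequencies with p_fake < p_novel lie outside the
model's image and are clipped with a boundary flag; Pr = 1 leaves Pf
unidentified (flagged NaN).

## Hierarchical Bayesian fit

Each age group × correction condition cell is fit separately (matching
how group posteriors are conventionally tabulated; condition and age
effects are then computed on the posterior draws). Participant *i*
contributes multinomial counts over the three categories; the
probit-scale pair θᵢ = (Φ⁻¹(Prᵢ), Φ⁻¹(Pfᵢ)) follows a bivariate normal
N(μ, Σ) — the latent-trait formulation, chosen over independent-beta
hierarchies so the recollection–familiarity covariance is itself
estimated and its fit checkable.

Priors: μ ~ N(0, I) on the probit scale (implying a near-uniform prior
on each probability-scale group mean) and Σ ~ Inverse-Wishart(ν₀ = 4,
Ψ₀ = I), a weakly informative conjugate choice (prior mean I) standard
for latent-trait MPTs. Conjugacy buys exact Gibbs updates for μ and Σ;
only θᵢ needs Metropolis.

Sampler: Metropolis-within-Gibbs. Participant probits are updated
jointly by vectorized random-walk Metropolis with per-participant step
sizes adapted during warm-up toward ≈35% acceptance (adaptation stops
before retention, preserving detailed balance). μ and Σ are drawn from
their exact conditionals. Chains are independent and seeded
deterministically: identical spec + seed gives identical draws.

Default settings are desk-scale — 4 chains × 5,000 retained iterations
after 1,000 warm-up, no thinning — which on these 2-dimensional
participant blocks yields effective sample sizes in the hundreds to
thousands for group means within seconds per cell.
`HierarchicalSpec.paper_profile()` provides the long-run profile
(4 × 100,000 iterations, 20,000 adaptation, 2,000 burn-in, thin 5) for
final runs. Convergence is monitored with split-R̂ and ESS (arviz);
any R̂ ≥ 1.05 flags the fit prominently but summaries are still
returned. Group estimates are reported on the probability scale as
Φ(μ), the population median of each parameter.

An effect (condition difference, age difference) is *credible* when the
central 95% interval of the difference of group-level draws excludes
zero. Calibration of this rule is part of the acceptance suite: with a
true zero difference the flag fires at roughly the nominal 5% rate.

Boundary data (e.g. zero novel counts for every participant) are handled
by the hierarchy and the priors alone — no count padding.

### Posterior-predictive checks

Two discrepancies, checked per cell: **T1** compares observed mean
category frequencies with their expectation under each draw's
participant parameters; **T2** compares the across-participant
covariance matrix of category frequencies with its model expectation
(covariance of participant expected frequencies plus mean multinomial
noise). For each retained draw the same discrepancy is computed for a
simulated replicate; the posterior-predictive p is the proportion of
draws where the replicate discrepancy meets or exceeds the observed one.
Model-generated data give mid-range p (the check is conservative, as
usual for posterior-predictive p-values); data whose novel responses
outnumber fake responses — impossible under the tree — drive T1 to 0.

## Signal detection

Correction detection (Phase 2) and correction remembering (Phase 3) are
scored with equal-variance Gaussian SDT: yes-responses to corrections
are hits, yes-responses to affirmed real news are false alarms (the
shared noise distribution), d′ = z(H) − z(F), c = −(z(H) + z(F))/2.
Estimates are computed per participant, each correction condition
providing its own hit rate, and then summarized.

Extreme proportions are handled by the log-linear rule
(x + 0.5)/(n + 1), applied to all counts — not only at 0/1 — so the
estimator is continuous in the counts; the 1/(2n) substitution rule and
raw proportions are selectable alternatives, and raw rates are always
emitted alongside. The generative convention used by the simulator,
P(yes|signal) = Φ(d′/2 − c) and P(yes|noise) = Φ(−d′/2 − c), makes the
estimator its exact inverse, which the test suite verifies to 1e−9 on a
grid.

## Conditional pipeline

Conditional analyses restrict to correction trials whose correction was
detected in Phase 2 and compute a target proportion within strata of a
conditioning response: real-news retrieval by whether the fake detail
was also retrieved (within remembered-correction trials, because the
fake question is gated on a "yes"), and erroneous fake retrieval by
whether the correction was remembered. Each cell carries its observation
count and its weight (share of observations within age group ×
condition); with pooled aggregation the weighted conditional proportions
reconstruct the marginal exactly (law of total probability), which is
enforced by a 1,000-table property test. Cells under `min_n = 5`
observations are flagged sparse, never dropped. Aggregation order is a
switch: per-participant means (default, matching the SDT treatment) or
trial pooling; both are reported because plotted proportions in this
literature rarely state which was used.

Belief accuracy is the mean 1–6 accuracy rating for correctly retrieved
real details minus the mean rating for erroneously retrieved fake
details, overall and within the conditional strata. Uncertainty for all
descriptive quantities comes from a cluster bootstrap (resampling
participants with replacement, percentile intervals), since the
mixed-effects inferential models conventional in this literature are
out of scope here.

## The synthetic cohort generator

The generator's defaults are the deployed study conditions: 102
participants per age group, 45 critical topics rotated as three sets of
15 through the three conditions (three counterbalancing formats, each
topic serving each condition in exactly one format), 15 real-news
fillers interleaved with the repeated fake items in Phase 1 Block A, and
orderings with no more than three consecutive same-condition items in
any phase (checked exhaustively in tests). Equating of average list
position across conditions is not enforced, only the run-length bound; a
position-equating scheduler is a possible future feature.

Latent-process choices, each the exact inverse of an estimator above:

- **Ordinal ratings** are cumulative-probit: latent normal, unit
  residual sd, five ordered cutpoints (default −1.8, −0.8, 0, 0.8, 1.8,
  putting mean ratings in the 2.6–3.8 band observed empirically).
  Familiarity grows by 0.15 latent units per prior presentation; fake
  accuracy ratings grow by 0.06 per prior exposure (illusory truth);
  real news sits above fake news in accuracy mean. Magnitudes were
  chosen to match the *direction* and rough size of effects typical of
  this paradigm, not calibrated to reproduce any particular dataset.
- **Detection/remembering** follow the SDT convention above with
  participant-level offsets (sd 0.5 on d′, 0.3 on c). Default d′ values
  are probit transforms of realistic yes-rates (detection ≈
  1.7–2.0, remembering ≈ 1.15–1.55, higher after three exposures).
- **Phase-3 choices** are sampled from the tree with
  condition-specific participant parameters drawn from the probit
  hierarchy (group means typical of recognition versions of the
  paradigm:
  recollection ≈ 0.44–0.49; familiarity 0.61–0.73, higher with
  repetition and for younger adults; probit sd 0.6, correlation 0.3).

Three couplings tie the Phase-3 responses together, because without
them the paradigm's conditional signatures cannot arise from
participant-level parameters alone:

- recollection boosts the remember-question evidence
  (`remember_boost_recollected = 1.5`), so remembered corrections are
  enriched in recollection trials;
- choosing the fake detail as real *lowers* remember evidence by
  `remember_mask_per_exposure = 0.2` per prior fake exposure — strong
  fake familiarity both attracts the error and masks memory that the
  detail was corrected. This is what concentrates repetition-driven
  errors in the not-remembered stratum: with purely participant-level
  familiarity differences (0.03–0.10 on the probability scale) the
  exposure effect inside that stratum is ≈0.01 and sign-unstable across
  seeds;
- fake identification (gated on "yes") succeeds with probability 0.9 on
  recollection trials versus 0.5 otherwise, and is impossible when the
  fake detail was itself chosen as real.

Belief ratings use the cumulative-probit machinery with a higher latent
mean for real than fake choices and a recollection shift
(`belief_shift_recollected = 0.6`), producing positive belief accuracy
that is larger on recollection-linked strata.

What the generator does **not** emulate: real headline content and
topic-level idiosyncrasy (topics are exchangeable), pre-experimental
familiarity differences between topics, free-text recall (cued-recall
mode emits the same three pre-scored categories, pooling "other"
errors and omissions into the novel category), reaction times, dropout,
and any dependence of Phase-3 behavior on the retention interval (it is
emitted as metadata only). Passing recovery tests therefore shows that
the estimators invert the stated generative processes at realistic
sizes — not that real data satisfy those processes.

## Numerical and design notes

- Run-length-constrained orderings use rejection sampling with a retry
  bound; infeasible count/constraint combinations raise a configuration
  error rather than loop.
- The detection threshold is parameterized as λ = c + d̄′/2 with d̄′ the
  mean correction-condition sensitivity, so the single criterion value
  applies coherently when the two correction conditions differ in d′.
- Multinomial log-likelihoods treat 0·log 0 as 0; an impossible datum
  (positive count on a zero-probability category) yields −∞.
- MCMC chain seeds derive from `SeedSequence([seed, cell_index,
  chain])`; the sampler is deterministic given the spec.
- Moment-estimator initialization of the chains is jittered per chain so
  R̂ retains diagnostic power.
- Fits report problem sizes used by the suite — recovery at 100
  participants × 15 trials/condition, calibration at 100 replicates of
  40 participants — chosen as the smallest cohorts at which the
  effect sizes of interest (0.10 on the probability scale) are
  resolvable.

## Known limitations

- The guessing-branch ambiguity is resolved by configuration, not by
  model comparison; Bayes-factor comparison of the two readings is out
  of scope.
- The affirmed-real condition never enters the MPT (its "fake" options
  were never studied); it serves only as the SDT noise distribution and
  as a knowledge/guessing baseline in descriptive tables.
- The inverse-Wishart prior on Σ is mildly informative for very small
  groups (< ~10 participants); with realistic cohort sizes its influence
  on group means is negligible, but variance components at n < 20 should
  be read with the prior in mind.
- Cluster-bootstrap intervals are percentile intervals; no BCa
  correction.
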