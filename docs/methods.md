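# Methods

## Choice-set design

Object-case best-worst scaling shows each respondent b subsets ("tasks") of
the v attributes, k at a time. We use a balanced incomplete block design so
that aggregate counts are comparable: every attribute appears in exactly r
tasks and every unordered pair co-occurs in exactly λ tasks, with the
identities b·k = v·r and λ(v−1) = r(k−1). Construction is by cyclic
development of a known planar difference set — block i = {(d + i) mod v} —
which is deterministic and trivially auditable, rather than by stochastic
design search. For the seven-attribute survey this is (v, b, r, k, λ) =
(7, 7, 3, 3, 1), the Fano plane developed from {0, 1, 3} mod 7. A small
table of difference sets covers (7,3,1), (13,4,1), (11,5,2), (15,7,3) and
(21,5,1); any other parameter triple raises an explicit "no construction
available" error — there is never a silent fallback to an unbalanced
design.

Task order and within-task order are cyclic-development order with
ascending indices. No downstream statistic depends on either ordering
(asserted by a shuffle-invariance test on the likelihood). The default
attribute-to-index binding follows the conventional reporting order SCLH,
BCS, SCLS, STN, LS, SB, P and is configurable via a permutation.

The actual task compositions used in the original survey were not
published; any valid (7,7,3,3,1) design is statistically equivalent for
every statistic this package computes, because all counting quantities and
the likelihood depend only on the design's balance properties.

## Choice model

A respondent facing task S picks a (best, worst) pair of distinct
attributes. We model the pair jointly:

    P(b, w | S) = exp(u_b − u_w) / Σ_{i≠j∈S} exp(u_i − u_j),

a conditional logit over the k(k−1) ordered pairs, with one attribute's
utility pinned at zero for identification (utilities are only defined up to
an additive constant). The joint pair family — rather than a sequential
best-then-worst model — is used for both simulation and estimation; its
null log-likelihood for T tasks of size 3 is −T·ln 6, which matches the
reported null deviance of the original analysis exactly (−357·ln 6 =
−639.66), pinning the likelihood family the original software used. For
k = 3 a sequential model would have the same null value, so the discrimination
rests on this family being the standard treatment in the BWS literature; the
sequential variant is out of scope.

The default reference is the attribute with the lowest aggregate best-minus-
worst count (the least-important one), which keeps the remaining
coefficients positive in typical data; it can be overridden. Refitting
against a different reference shifts all utilities by a constant and leaves
fitted probabilities unchanged (tested).

## Estimation

The log-likelihood is globally concave in the coefficients. We maximise it
with BFGS from β = 0 using the analytic gradient (log-sum-exp stabilised),
gradient tolerance 1e−6, at most 500 iterations; the objective is
deterministic so no seed is involved. Responses are grouped by distinct
task composition, so one likelihood evaluation costs O(#unique tasks ·
k(k−1) · K) regardless of cohort size.

Classical standard errors are the square roots of the inverse observed
information. Robust standard errors use the sandwich estimator with scores
summed within cluster; the cluster is the **respondent** by default — the
natural dependence unit when each person answers seven tasks — with a
per-task (heteroskedasticity-only) option. A finite-sample factor
G/(G−1) for G clusters is applied. Whether the original analysis clustered
by respondent is not documented; both variants are available and on
well-specified independent data they agree within ~25% (tested).

Quasi-complete separation (an attribute always or never picked when shown)
drives its coefficient to ±∞; coefficients exceeding |10| are flagged and a
`DivergenceWarning` is raised instead of failing or staying silent.

Fit statistics: LL(0) = −T·ln(k(k−1)); McFadden pseudo-R² =
1 − LL(model)/LL(0); AIC = −2·LL + 2K; BIC = −2·LL + K·ln(T) with T the
number of tasks and K = v − 1 estimated parameters.

Wald p-values use the robust SEs with stars at 0.05 / 0.01 / 0.001 and an
"NS" marker otherwise. Subgroup analysis fits the model independently on
each category of a two-category demographic split, keeping the pooled
reference attribute.

## Counting statistics

Per attribute j with B_j best picks and W_j worst picks over T tasks:
BW_j = B_j − W_j (sums to zero over attributes by construction);
standard value BW_j/(N·r) on [−1, 1] (N respondents, r appearances);
square-root ratio √(B_j/W_j); relative importance 100·√(B_j/W_j)/max.
Published aggregate tables for this survey are reproduced by these
formulas, *not* by the min–max rescalings sometimes quoted alongside them;
the literal min–max columns are still emitted (`std_minmax`,
`relative_minmax`) for comparability. One published row (SB) is internally
inconsistent — its printed best-percentage, BW value and ratio cannot all
be derived from any single pair of integer counts, and the printed worst
percentages sum to 100.6% — so tests assert 2-d.p. agreement on the other
six attributes only and no agreement is forced for SB.

A zero worst count makes the ratio undefined; the default is a hard error,
with an opt-in +0.5 continuity correction to both counts that is recorded
in the summary's metadata. Counts reconstructed from printed (rounded)
percentages may miss exact best/worst conservation by a task or two; the
summariser warns and uses per-column totals as percentage bases. Ranks are
dense with ties sharing the smaller rank and a tie flag in metadata.
Rendered tables round half-away-from-zero to 2 d.p.; machine outputs keep
full precision.

## Synthetic cohort

The generator emulates the study conditions: 51 respondents × 7 tasks = 357
observations, demographic margins 18/33 (gender), 24/27 (age 18–40 / >40),
26/25 (≤10 / >10 years experience), 15/36 (college / professional), 19/32
(≤5000 / >5000 sows). Quota mode reproduces these counts exactly
(round(n·p) per category, remainder to the larger category, shuffled so
variables are independent); multinomial mode samples them. Only marginal
shares are known, so variables are generated independently; joint structure
can be injected by passing a custom roster.

Default generating utilities are the pooled conditional-logit point
estimates from the real cohort (1.744, 1.455, 0.811, 0.697, 0.485, 0.431,
0 for P). They are *illustrative* — a plausible scenario for testing
recovery — not ground truth about any population. Seeding uses one master
seed with a deterministic substream per respondent, so extending a cohort
never reshuffles existing respondents' choices.

What the simulator does **not** model: position bias, respondent fatigue or
inattention, within-respondent taste heterogeneity (a stratum shares one
utility vector), and correlation between demographic variables. Passing
tests on simulated data therefore demonstrate correctness of the estimator
under the assumed model, not robustness to those real-world features.

## Verification scale and determinism

Unit and property tests run on cohorts of 1–500 respondents. The parameter
recovery study uses 20 replicates of 500 respondents × 7 tasks (3,500 tasks
each): per-coefficient mean estimates land within ±0.1 of the generating
utilities and ~93% of the 120 robust 95% CIs cover the truth. A single
500-respondent replicate has empirical coefficient SDs of 0.03–0.07, so
individual estimates are within ±0.15 of truth but not reliably within
±0.1; assertions are therefore placed on replicate means and CI coverage.
Subgroup fits are exercised at the real category sizes (18 and 33
respondents). All randomness flows through numpy `SeedSequence`s derived
from explicit integer seeds; identical config and seed give byte-identical
pipeline outputs.

## Known limitations

- The original individual-level choice data were never deposited, so the
  published coefficient table serves only as a simulation scenario and
  formatting fixture; it is not a reproduction target.
- Only symmetric BIBDs from the built-in difference-set table are
  constructible; optimal-design search and partially balanced designs are
  out of scope.
- No latent-class, mixed-logit or hierarchical-Bayes extensions; preference
  heterogeneity is addressed only through the stratified subgroup fits.
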