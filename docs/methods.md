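# Methods

This note documents the statistical machinery `cardmatch` implements, the
choices that were genuinely open, and what the synthetic validation does —
and does not — establish.

## The matched design

**Estimand.** The pipeline targets the treatment effect in the matched
population: the largest treated/control subsets that can be made
comparable on observed covariates. Binary outcomes are reported as
marginal odds ratios from matched-group proportions (not conditional
within-pair ORs); continuous outcomes as matched-group mean differences.
All matched patients with a non-missing outcome value contribute
(available-case analysis), so the effective n differs across outcomes
when continuous outcomes are missing for some patients.

**Step 1 — cardinality matching.** One binary variable per patient;
maximize the number of selected treated patients subject to (a) equal
selected group sizes, (b) for each continuous covariate x with reference
SD σ, the linearized moment constraint −δσ·m ≤ Σₜxᵢaᵢ − Σ꜀xⱼaⱼ ≤ δσ·m
where m = Σₜaᵢ is the (variable) match size, and (c) for every level of
every nominal covariate, exactly equal selected counts in the two groups
(fine balance). Defaults: δ = 0.05; moment balance on age and income;
fine balance on sex, race/ethnicity, insurance and the three provider
indicators. The reference SD is the full pre-match sample SD (ddof = 1)
per covariate; a treated-sample reference is available via
`BalanceSpec.sd_reference`. A zero-SD covariate degenerates to exact mean
equality and is logged. The empty selection is always feasible, so for
δ > 0 a solve can return cardinality zero but never "infeasible".

The program is solved by HiGHS through `scipy.optimize.milp` with
presolve disabled — on these wide, shallow programs (a dozen rows,
thousands of binaries) root-node presolve costs far more than it saves,
and the LP relaxation is already tight. Solves are deterministic for a
fixed program; ties among optimal selections are inconsequential because
pairs are re-optimized downstream and the estimand is a group contrast.
Integrality tolerance 1e-6 is absorbed by the balance assertion's slack.

**Step 2 — optimal pairing.** Covariates (age, income, and
reference-coded indicators of the nominal covariates by default; the
logit propensity score alone as a config option) are replaced by midranks
over the pooled selected units. The distance between a treated and a
control patient is the Mahalanobis distance on ranks, with the rank
covariance matrix ridge-regularized by 1e-8·trace(S)/p on the diagonal;
all-constant rank columns are dropped with a warning. Using ranks bounds
the influence of outliers (income is heavy-tailed) and makes the distance
invariant to monotone transforms. A soft propensity caliper adds
`penalty_scale · max(0, |logitᵢ − logitⱼ| − w·SD(logit PS))` to each
entry; defaults w = 0.2 (the conventional caliper width) and
penalty_scale = 1000 × the mean unpenalized distance, large enough to
dominate pair choice without ever making the pairing infeasible. The 1:1
pairing minimizing the total penalized distance is found exactly with
`scipy.optimize.linear_sum_assignment`.

**Propensity model.** A main-effects maximum-likelihood logistic
regression of treatment on all eight patient/provider covariates
(reference levels: female, white, commercial insurance, non-faculty,
non-physician, female provider), fit by statsmodels Newton iterations
(cap 100, tolerance 1e-8). Complete or quasi-complete separation — common
in small cohorts where a rare insurance level lands entirely in one arm —
is detected (non-convergence, non-finite coefficients, or fitted logits
beyond ±30) and handled by a ridge-penalized IRLS fit (penalty 1e-4 on
squared non-intercept coefficients), which keeps every score strictly
inside (0, 1); the fit is then flagged `converged = False`. Because the
intercept is never penalized, the mean fitted score equals the treated
fraction in both paths.

**Balance diagnostics.** Standardized difference =
(mean_t − mean_c)/√((var_t + var_c)/2) with sample (ddof = 1) variances —
the matching-literature pooled-SD convention, used identically by the
diagnostic tables and the ILP assertion so the feasibility guarantee is
exact. Continuous covariates are compared by Welch's t test; each nominal
level by a level-vs-rest 2×2 chi-square without continuity correction,
falling back to Fisher's exact test when an expected count is below 5;
zero counts in both arms give p = 1. The Bonferroni family is all rows of
one table. Which tests produced the published tables this layout mimics
is not stated there; these are conventional choices, documented as ours.

**Design-aware bootstrap.** Per replicate, patients are resampled with
replacement within each arm (original arm sizes preserved) and the whole
design — propensity fit, ILP, pairing — is re-run before recomputing the
point estimates. This propagates the variability of propensity
estimation, subset selection and pairing into the SE, which resampling of
fixed pairs understates. SEs are SDs over replicates on the estimation
scale (log for ORs); CIs are normal-theory by default (percentile
available); p-values come from the normal approximation. Replicate seeds
are spawned from the master seed (`numpy.random.SeedSequence`), so results
are reproducible and independent of execution order. Replicates whose
match is empty are dropped; more than 10% dropped is a hard error.
Default B = 200. A zero cell in a matched 2×2 table gets the 0.5
continuity correction on all four cells and the estimate is flagged.

## The synthetic cohort generator

The generator emulates a primary-care EHR cohort aged 50+ in a US urban
academic health system. Marginals: age truncated-normal (mean 65, SD
10.5, minimum 50); income log-normal with mean $68,000 and SD $30,000
(non-negative and right-skewed, so the rank-based distance has real work
to do); sex 40% male; race 64.5% white / 27% black / 1.8% Hispanic / 6.7%
other; insurance 52.5% commercial / 6.2% Medicaid / 40.5% Medicare / 0.8%
none; provider faculty 32.5%, physician 76%, male 41%. Covariates are
drawn independently; cross-covariate correlation is a config extension,
not a default, because nothing downstream requires it.

Treatment (portal registration) follows a logistic model whose
coefficients give the confounding directions seen in real portal cohorts:
younger (−0.30/SD age), higher-income (+0.35/SD), white (non-white levels
−0.25 to −1.0), commercially insured (public/no insurance −0.55 to −1.1);
intercept 1.0 yields a realized treated fraction near 0.59. Binary
outcomes are Bernoulli with logit = baseline + covariate terms + τ·treated;
continuous outcomes are Gaussian with an additive treatment shift; the
composite prevention score is the row sum of the four behavior
indicators, 0–4 by construction. Systolic blood pressure and LDL are
missing completely at random (18% and 46%), chosen to emulate the unequal
effective n of continuous outcomes in real matched tables without
asserting a missingness mechanism.

Behavior outcomes load on income (+0.25/SD), age (+0.05/SD) and white
race (+0.40). Two deliberate consequences: (i) the crude flu-shot log-OR
is biased upward by roughly +0.10 because portal users are richer and
more often white; (ii) the marginal OR a balanced design estimates stays
within about 1% of the generating conditional OR, because the strongest
outcome covariate (race) is removed exactly by fine balance and the
continuous terms are modest — logistic odds ratios are not collapsible,
and larger covariate effects would open a visible gap between the
generating τ and any marginal estimand, making "parameter recovery"
ill-posed rather than hard.

Scenarios: `paper-like` (behavior ORs 1.5 / 1.15 / 1.5 / 1.0, chronic
effects null) and `global-null` (all effects null), both under confounded
assignment. Generation is bitwise-deterministic in (params, seed).

What passing tests show — and do not. Recovery and coverage results
demonstrate correctness of the machinery under MCAR missingness,
independent covariates, a correctly specified (main-effects logistic)
treatment model, and no unmeasured confounding. Real EHR data violate all
four in unknown degrees; the pipeline adjusts only for what it is given.

## Validation sizes and numerical details

Oracle tests: ILP optima equal exhaustive subset-pair enumeration on 20
instances of ≤ 12 units; assignment totals equal brute force over all 7!
permutations on 20 matrices; the propensity fit matches an independent
Newton–Raphson oracle to 1e-6; distances match a direct matrix-inverse
oracle to 1e-10. Stochastic suites (sizes chosen for a single-CPU desk
run): the balance guarantee on 20 cohorts of n = 2,000; parameter
recovery over 30 repetitions at n = 4,000 (matched flu OR within 3 Monte
Carlo SEs of 1.5, crude OR biased upward, chronic estimates centered on
null); bootstrap coverage under the global null over 25 repetitions at
n = 800 with B = 60, requiring ≥ 21/25 coverage per outcome — the
threshold was fixed in advance from binomial error (under true 95%
coverage, P(≤ 20 of 25) ≈ 0.002). Determinism is asserted byte-for-byte
on full pipeline artifact directories.

## Known limitations

- 1:1 matching without replacement only; no 1:k, full matching or
  network-flow generalizations.
- Complete-case covariates are assumed; only outcomes may be missing.
- No sensitivity analysis to unmeasured confounding.
- Marginal ORs are reported; users comparing against conditional
  (within-pair) analyses should expect noncollapsibility gaps when
  outcome-covariate effects are strong.
- The bootstrap is O(B × design cost); at n = 10,000 the exact assignment
  step dominates (~20 s per replicate), so desk-scale inference is more
  comfortable at n ≤ 4,000 or with the propensity-only distance option.
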