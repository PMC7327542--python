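# Methods

This note documents the models behind `nitrial`, the default constants and
why they were chosen, the numerical conventions, and what the synthetic
cohorts do and do not capture about real trials.

## Decision rule and scales

The canonical internal scale is the efficacy difference
Δ = p_E − p_C, where p_t is the success probability under treatment t.
Designs whose recorded outcome is an adverse event (`outcome_polarity =
"harm"`, e.g. death by day 30) are converted at the analysis boundary:
efficacy = 1 − risk, and a confounder's `outcome_coefficient` is always the
additive effect on the probability of the *recorded* event. Working on one
scale with one strict decision rule — claim non-inferiority iff the lower
confidence bound of Δ̂ exceeds −M — avoids sign errors; the harm-scale rule
(upper bound of the risk difference below M) is its exact negation.

Wald (normal-approximation) intervals are used for ITT and PP, at two-sided
level 1 − 2α with α the one-sided type-I level (default 0.025,
z₀.₉₇₅ = 1.959964). When an arm proportion is exactly 0 or 1, half a
success and half a failure are added *for the variance only*, so small
cohorts never produce zero-width intervals.

## Cohort generator

**Outcome model.** π_t(X) = p_t + Σ_j c_j (X_j − E[X_j]) with mean-centred
confounders, linear on the probability scale (not logistic). The linearity
is a deliberate design choice: mean-centring makes the *marginal* efficacy
under every treatment equal the design value exactly, with no recalibration,
which in turn makes the closed-form oracles below exact rather than
approximate. The cost is a range constraint — every attainable confounder
combination must keep every treatment's probability inside [0, 1] — which is
validated at construction and reported with the offending treatment and
bound. Confounder effects are treatment-independent (no
treatment-by-covariate interaction); see Limitations.

**Adherence model.** Per assigned arm,
P(adhere | X) = expit(α_arm + Σ_j δ_j,arm (X_j − E[X_j])). The intercept is
calibrated by Brent root finding so that the marginal adherence (averaged
over the confounder distribution by tensor-product quadrature:
64-point Gauss–Legendre per uniform confounder, exact two-point sums for
Bernoulli ones) matches the target to within 1e−9. With all δ = 0 the
intercept is the exact logit; a target of 1 bypasses the logistic entirely;
a target of 0 is rejected as a degenerate arm.

**Mechanics.** Allocation is exactly balanced (n per arm, no further
blocking), confounders are i.i.d., non-adherent participants
deterministically receive the opposite arm's treatment (crossover) or the
scenario's inferior alternative, and outcomes are drawn from the model of
the treatment actually received. Cohorts are byte-identical given the same
configuration and seed.

## Closed-form oracles

Because confounder effects are treatment-independent and linear, the
expected *observed* efficacy of an assigned arm is the simple adherence
mixture a·p_assigned + (1−a)·p_destination regardless of confounding
(`expected_arm_efficacies`). Two consequences used throughout:

* under symmetric crossover with adherence a in both arms, the expected ITT
  difference is (2a − 1)Δ — the dilution closed form;
* the probability of claiming non-inferiority is approximately
  Φ((Δ_exp + M)/se − z₁₋α) at the mixture efficacies
  (`claim_probability_oracle`), exact for the arm-level binomial model up to
  the normal approximation. At n = 400/arm the exact Wald size at the
  boundary is 0.0249 vs the nominal 0.025; at small n (≈150/arm) the exact
  size can deviate by ~0.3 percentage points, which is why oracle-agreement
  checks run at n = 400/arm.

The expected *per-protocol* arm efficacy is the adherence-weighted
quadrature average E[p(X)π(X)]/E[p(X)] (`expected_pp_efficacies`) — the
quantity the naive PP analysis estimates, and the oracle for its selection
bias.

## Estimators

* **ITT / PP**: difference of arm proportions (all randomised / adherent
  only), Wald CI.
* **IPW**: logistic regression of adherence on the confounder columns,
  fitted separately per assigned arm (arms may have different mechanisms)
  by IRLS (tolerance 1e−8, 100 iterations; separation flagged when a
  coefficient exceeds 30 in absolute value). Adherent participants are
  weighted by 1/p̂ and arm efficacies compared in Hájek (normalised) form.
  The CI is a within-arm nonparametric bootstrap percentile interval
  (default B = 1000, seeded, weight model refitted per replicate) — simpler
  to specify than a sandwich variance and robust to the two-stage
  estimation. Weight truncation at the 99th percentile is available but off
  by default. A fully adherent table falls back to weights of 1 (= PP).
* **Standardisation**: stratum-specific adherent-only arm efficacies
  averaged with weights equal to each stratum's share of the *full
  randomised cohort*; continuous confounders are discretised at quantile
  cut points computed once on the analysed table and held fixed across
  bootstrap replicates (refreshing them per replicate would churn empty
  cells without changing the estimand). Empty stratum-arm cells are errors
  naming the stratum.
* **IV**: Wald ratio (ITT outcome difference) / (first-stage difference in
  the probability of receiving the experimental treatment), standard error
  by the delta method with within-arm covariances. The delta method is
  adequate away from weak instruments, and weak instruments (first stage
  ≤ 0.01) are rejected outright, as are tables containing
  alternative-treatment rows (the instrument logic requires crossover-only
  non-adherence). Fieller-type intervals are not implemented.

At 100% adherence ITT, PP and IPW coincide exactly, IV equals ITT exactly
(its delta-method variance differs from the ITT binomial variance by the
n/(n−1) sample-covariance factor), and standardisation with a single
stratum equals PP.

## Operating characteristics

`run_oc` estimates, per scenario × method, the probability of claiming
non-inferiority, the mean estimate and its spread over R replicates. ITT on
non-confounded scenarios uses an arm-level binomial shortcut (draws arm
success counts directly at the mixture efficacies); ITT on confounded
scenarios and PP everywhere use a vectorised participant-level engine
(chunked to ~4M participant-cells); IPW, standardisation and IV run cohort
by cohort. Shortcut and participant-level routes are cross-validated in the
tests. Replicate substreams are derived from the master seed per method via
`SeedSequence.spawn`, so results are independent of which methods are
requested together. Estimator failures in a replicate are recorded and
excluded; ≥1% failures aborts the run.

`direction_matrix` compares each catalogue row's claim probability and mean
estimate against a fully adherent baseline with a tolerance of three pooled
Monte-Carlo standard errors and labels them higher / lower / same (estimates
additionally towards_0). The claim-probability labels are the primary
readout; estimate labels are informational because their reference point
(the baseline mean) is a convention.

## Scenario catalogue

Eighteen rows: {both, experiment, control} × {crossover, inferior
alternative} × {non-confounded, confounded-increase, confounded-decrease},
all with the experimental arm truly inferior by exactly the margin
(efficacies 0.5 vs 0.6 on a harm-polarity outcome, margin 0.10, n = 400/arm)
so that the fully adherent claim probability is the nominal 2.5%. Frozen
defaults, chosen once with the quadrature oracles so that every row's
qualitative direction is resolvable at R = 5000 and n = 400 (i.e. the
biases are several Monte-Carlo standard errors wide), then left alone:

* marginal adherence of each non-adherent arm: 0.9 (10% non-adherence, the
  regime in which ITT claim-probability inflation to ~8% is the headline
  hazard);
* alternative-treatment efficacy: 0.35 (inferior to both arms, and keeping
  all outcome probabilities in range given the confounder slope);
* confounded rows: one uniform [0,1] severity score with outcome
  coefficient +0.6 on the adverse event and adherence log-odds of
  magnitude 6.

Confounded rows share a single mechanism: severity raises the adverse-event
probability and *tilts treatment receipt toward the experimental treatment*
("increase" rows: raises adherence in the experimental arm and lowers it in
the control arm; "decrease" rows: the reverse). For crossover rows this is
the classic open-label story — severely ill patients end up on one
particular treatment. This unified tilt is what produces the coherent
pattern of per-protocol biases across all twelve confounded rows (increase
→ PP biased against the experimental arm → claim probability falls;
decrease → the reverse), while leaving every ITT expectation at its
mixture value. A symmetric "severity raises non-adherence in both arms"
mechanism would instead make the two arms' selection biases cancel for
both-arm scenarios and is deliberately not used.

## Power and sample size

Analytic: n/arm = ceil((z₁₋α + z_power)² (p_E(1−p_E) + p_C(1−p_C)) /
(M + Δ)²), no continuity correction — internal consistency with the Wald
test beats matching any one textbook. Rounding is per arm; a quoted trial
total is treated as sufficient if it is ≥ 2·n/arm. For the 60%/60%, 10%
margin, 80% power design this gives 377/arm (754 total). Simulated power
wraps `run_oc` with any scenario and method; `required_n` bisects the
simulated power on a doubling bracket (full adherence short-circuits to the
analytic value), accepting the smallest n within one Monte-Carlo standard
error of the target. Under crossover dilution the required n *falls* — the
diluted difference sits closer to zero than the truth — which is precisely
the hazard the toolkit exists to expose.

## Biocreep chain

Four consecutive trials with fixed comparator pairs (standard-of-care vs A,
A vs B, B vs C, C vs D), each new treatment 10 points less effective than
its comparator, all run at the same adherence with symmetric crossover, all
statistically independent; treatment k is accepted as the new standard iff
trials 1..k all claim non-inferiority (a winner-carries-forward semantics is
deliberately not implemented). The oracle is the running product of
per-trial claim probabilities. The default per-trial n uses the analytic
formula under the equal-efficacy planning assumption of the first pair
(142/arm for a 90%-efficacy standard) — the calculation at the *true*
efficacies is undefined because the true drop equals the margin. Chain
acceptance probabilities are monotone in non-adherence; at 70% adherence and
n = 400/arm the probability that treatment D (40 points worse than the
original standard) becomes the accepted standard reaches several percent.

## Worked example preset

Design: 800 participants (400/arm), short vs long treatment duration for
ventilator-associated pneumonia, outcome death by day 30, margin 0.10,
α = 0.025 one-sided; the short course is truly worse, Δ = −0.10 on the
efficacy scale (mortality 0.5 vs 0.4). The stated design quantities are the
sample size, power, efficacy and adherence levels; the generator's effect
sizes are this package's own frozen choices:

* severity ~ U(0,1): +0.5 on 30-day mortality; adherence log-odds −8 in the
  short-duration arm (severely ill patients are switched to the long
  course) and +8 in the long-duration arm (mildly ill control patients are
  switched to the short course);
* doctor ~ Bernoulli(0.5): −0.05 on mortality; adherence log-odds +1 / −1
  (one doctor prescribes the short course more readily);
* marginal adherence 0.75 in each arm ("overall adherence 75%" is read as
  the marginal rate across both arms, applied symmetrically since no
  asymmetry is specified), crossover destination.

With these constants the naive PP analysis is biased by ≈ +0.10 (the
quadrature oracle gives expected PP efficacies of ≈0.55 in both arms), so
PP claims non-inferiority of the truly-inferior short course in roughly
two-thirds of trials; IPW — whose adherence model is correctly specified
here — recovers Δ to within 0.01 at large n; the IV first stage is
2·0.75 − 1 = 0.5, roughly doubling the ITT standard error.

One qualitative limit is worth stating plainly: with Δ = −0.10 and overall
75% crossover adherence, the expected ITT estimate is pinned at
(2a − 1)Δ = −0.05 for *any* crossover pattern, so the ITT analysis claims
non-inferiority in only ≈30% of replicates at n = 800. A single trial can
therefore show every qualitative contrast at once (diluted ITT, PP masking
the harm, IPW/IV seeing it), and the report renders exactly that, but "ITT
claims while IPW does not" is not a near-certain event under these
conditions — the inflation is a probability statement, quantified by
`run_oc`, not a per-dataset guarantee.

## What the generator does and does not emulate

It emulates: balanced randomisation, binary endpoints, confounded and
non-confounded non-adherence with crossover or switch to an inferior
alternative, and calibrated marginal efficacies/adherence so closed forms
apply. It does not emulate: time-varying treatment or adherence, dropout
and censoring, measurement error in confounders, unmeasured confounding of
the adherence model (the IPW model is correctly specified by construction —
real trials are not so lucky, so passing recovery tests here show the
estimator works when its assumptions hold, not that they hold in practice),
treatment-effect heterogeneity, or cluster randomisation. Passing the
suite therefore validates the machinery and its mathematics, not the
benignity of non-adherence in any real trial.

## Numerical conventions

Gauss–Legendre quadrature with 64 nodes per continuous confounder;
adherence-intercept root finding on [−60, 60] with a 1e−9 residual check;
logistic fits via statsmodels GLM (IRLS); bootstrap percentile intervals at
(α, 1−α) with the point estimate clamped into its own interval (percentile
intervals on very small tables can otherwise exclude it); Monte-Carlo
tolerances of three standard errors throughout; all randomness flows from
`numpy.random.SeedSequence` substreams of a single master seed. Problem
sizes used by the test suite and acceptance script — R = 5000 for the
18-row direction matrix, R = 10,000 for scalar claim probabilities, five
cohorts of 20,000 participants for the large-n recovery check — keep the
whole run in the tens of seconds while leaving every assertion several
Monte-Carlo standard errors of headroom.
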