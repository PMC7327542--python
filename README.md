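# nitrial

Simulation and analysis of two-arm **non-inferiority trials with binary
outcomes under non-adherence**.

Non-inferiority trials ask whether a new treatment is *no worse* than the
standard of care by more than a pre-specified margin. Their Achilles heel is
non-adherence: when participants cross over to the opposite arm or take up
an alternative treatment, the observed arm difference is diluted, so the
standard intention-to-treat analysis becomes *more* likely to declare
non-inferiority of a truly inferior treatment — and the naive per-protocol
analysis, which drops non-adherent participants, can be confounded by
whatever drove the non-adherence (disease severity, physician preference).
`nitrial` is a toolkit for trial statisticians and methodologists to
quantify these effects: it generates participant-level cohorts with
configurable adherence mechanisms and confounding, analyses them with five
strategies, and measures the operating characteristics of each.

## The model

For arms $t \in \{E, C\}$ with true efficacies $p_E, p_C$ (success
probabilities; harm outcomes such as 30-day mortality are handled as
$1-\text{risk}$), margin $M > 0$ and one-sided level $\alpha$, the decision
rule compares the Wald interval for $\hat\Delta = \hat p_E - \hat p_C$
against $-M$: non-inferiority is claimed iff the lower confidence bound
exceeds $-M$ (equivalently, on the risk-difference scale, iff the upper
bound is below $M$).

Cohorts are generated with

* **outcome model** $\pi_t(X) = p_t + \sum_j \gamma_j (X_j - E[X_j])$,
  linear on the probability scale with mean-centred confounders, so the
  *marginal* efficacy under every treatment equals the design value exactly
  (this is what makes the closed-form oracles below exact);
* **adherence model** $P(\text{adhere} \mid \text{arm}, X) =
  \operatorname{logit}^{-1}(\alpha_{\text{arm}} + \sum_j \delta_{j,\text{arm}}
  (X_j - E[X_j]))$, with the intercept calibrated by root finding so the
  marginal adherence hits its target;
* non-adherent participants receive the opposite arm's treatment
  (**crossover**) or an inferior **alternative** treatment.

Analyses: **ITT**, naive **PP**, **IPW** (per-protocol reweighted by inverse
fitted adherence probabilities, Hájek form, bootstrap CI),
**standardisation** (stratified estimates averaged over the cohort's stratum
distribution), and **IV** (Wald ratio: ITT outcome difference divided by the
randomisation→treatment first stage, delta-method CI; valid for
crossover-only non-adherence).

Key closed forms used as oracles throughout the test suite: under symmetric
crossover with adherence $a$ the expected ITT difference is
$(2a-1)\Delta$, and the claim probability is
$\Phi\!\big((\Delta_{\text{exp}} + M)/\text{se} - z_{1-\alpha}\big)$ at the
mixture efficacies.

## Worked example

A hypothetical open-label trial compares a short (experimental) versus long
(control) duration of treatment for ventilator-associated pneumonia;
the outcome is death by day 30, the margin 10 percentage points, 800
participants, overall adherence 75%. Disease severity raises mortality and
pushes severely ill patients off the short course; the treating doctor
affects both prescribing and outcome. The short course is truly *worse* by
10 points.

```python
import nitrial as nt

report = nt.run_worked_example(seed=0)
print(nt.render_report(report))
```

```
Worked example: short vs long treatment duration, death by day 30
n = 800, margin = 10% (mortality difference), overall adherence = 72.0%

method mortality diff                 95% CI  non-inferior?
ITT            +0.098       (+0.029, +0.166)             no
PP             +0.043       (-0.038, +0.124)             no
IPW            +0.131       (+0.037, +0.223)             no
IV             +0.222       (+0.059, +0.384)             no

IV first stage (randomisation -> received): 0.440
IPW weights: min 1.00, max 8.59, effective n 399
```

Reading the numbers: the true mortality difference is +0.10. The ITT
estimate is diluted toward zero by the 25% crossover (its expectation is
+0.05); the naive PP estimate (+0.043 here) is biased *toward* apparent
non-inferiority because the mildly ill accumulate in the per-protocol
short-course group; IPW reweights the adherent participants by their inverse
fitted adherence probability and lands near the truth; the IV estimate is
unbiased but has the widest interval because the first stage is only 0.44.
With these draws no method claims non-inferiority, but over repeated trials
the naive analyses claim it far more often than 2.5% — that is what the
operating-characteristics engine measures:

```python
design = nt.catalog_design()                       # eff 0.5 vs 0.6, margin 0.10
(res,) = nt.run_oc(design, nt.ScenarioSpec.symmetric_crossover(0.9),
                   ("ITT",), R=10_000, seed=1)
print(res.prob_claim_ni)                           # ~0.082 vs nominal 0.025
```

The same machinery powers a scenario catalogue of 18 qualitative
non-adherence patterns (`nt.CATALOG_ROW_IDS`, `nt.direction_matrix`), an
analytic + simulation-based power calculator, and a biocreep chain that
tracks how the probability of ever-worse treatments becoming the accepted
standard grows as adherence falls.

## Command line

```sh
nitrial simulate --config trial.yaml --seed 7 --out cohort.csv
nitrial analyze  --input cohort.csv --config trial.yaml --methods itt,pp,ipw,iv
nitrial oc       --config trial.yaml --methods itt,pp -R 10000 --seed 1
nitrial power    --mode analytic --eff-experimental 0.6 --eff-control 0.6 --margin 0.1
nitrial biocreep --adherence 0.7 -R 10000 --seed 1
nitrial worked-example --seed 0
```

`nitrial power` above prints `"n_per_arm": 377, "n_total": 754` — the
minimal balanced sample size for 80% power at a 2.5% one-sided level when
both efficacies are 60% and the margin is 10 points. Every subcommand
records its resolved configuration and seed in the output, so runs are
reproducible bit for bit.

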