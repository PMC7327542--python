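"""Treatment-difference estimators and the non-inferiority decision rule.

All estimators return the efficacy difference ``eff_E - eff_C`` together
with a two-sided confidence interval at level ``1 - 2 * alpha_one_sided``
and the non-inferiority claim: non-inferiority is concluded iff the lower
confidence bound of the efficacy difference strictly exceeds ``-margin``
(equivalently, on the harm scale, iff the upper bound of the risk difference
is strictly below the margin).

Methods
-------
ITT   intention to treat: compare arms as randomised.
PP    naive per protocol: restrict to participants who received their
      assigned treatment.
IPW   per protocol reweighted by inverse estimated adherence probabilities
      (Hajek form), confidence interval by within-arm nonparametric
      bootstrap percentile.
STD   standardisation over confounder strata, weighted by each stratum's
      share of the full randomised cohort; bootstrap CI as for IPW.
IV    instrumental-variable (Wald) estimator: intention-to-treat outcome
      difference divided by the randomisation-to-treatment first stage,
      delta-method standard error.  Valid only for crossover non-adherence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import confounder_columns
from .design import ARMS, EstimationError, TrialDesign, ValidationError

__all__ = [
    "AnalysisResult",
    "WeightDiagnostics",
    "ni_decision",
    "itt_estimate",
    "pp_estimate",
    "ipw_estimate",
    "ipw_point_estimate",
    "standardisation_estimate",
    "iv_estimate",
]

_MAX_LOGISTIC_COEF = 30.0  # |coefficient| beyond this flags separation


@dataclass(frozen=True)
class AnalysisResult:
    """One estimator's verdict on one trial."""

    method: str
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_analyzed: int
    ni_claimed: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError(
                f"confidence interval ({self.ci_low}, {self.ci_high}) does not "
                f"contain the estimate {self.estimate}"
            )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "std_error": self.std_error,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "n_analyzed": self.n_analyzed,
            "ni_claimed": self.ni_claimed,
        }


@dataclass(frozen=True)
class WeightDiagnostics:
    """Diagnostics of the inverse-probability weights."""

    min_weight: float
    max_weight: float
    mean_weight: float
    effective_sample_size: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "min_weight": self.min_weight,
            "max_weight": self.max_weight,
            "mean_weight": self.mean_weight,
            "effective_sample_size": self.effective_sample_size,
            "converged": self.converged,
        }


def ni_decision(
    estimate: float,
    ci_low: float,
    ci_high: float,
    margin: float,
    polarity: str = "success",
) -> bool:
    """Apply the non-inferiority decision rule to a difference estimate.

    On the efficacy-difference scale non-inferiority is claimed iff
    ``ci_low > -margin`` (strict); on the harm (risk-difference) scale iff
    ``ci_high < margin``.  The two are equivalent under negation of the
    interval.
    """
    if margin <= 0:
        raise ValidationError(f"margin must be positive, got {margin}")
    if polarity == "success":
        return bool(ci_low > -margin)
    if polarity == "harm":
        return bool(ci_high < margin)
    raise ValidationError(f"polarity must be 'success' or 'harm', got {polarity!r}")


def _efficacy_outcome(table: pd.DataFrame, design: TrialDesign) -> np.ndarray:
    """Outcome on the success scale (harm outcomes are flipped)."""
    y = table["outcome"].to_numpy(dtype=float)
    return y if design.outcome_polarity == "success" else 1.0 - y


def _proportion_variance(successes: float, n: int) -> float:
    # 0.5-success/0.5-failure fudge for degenerate proportions (variance only)
    if successes in (0.0, float(n)):
        p = (successes + 0.5) / (n + 1.0)
    else:
        p = successes / n
    return p * (1.0 - p) / n


def _wald_difference(
    yE: np.ndarray, yC: np.ndarray, design: TrialDesign, method: str
) -> AnalysisResult:
    nE, nC = len(yE), len(yC)
    pE, pC = yE.mean(), yC.mean()
    estimate = pE - pC
    se = float(np.sqrt(_proportion_variance(yE.sum(), nE) + _proportion_variance(yC.sum(), nC)))
    z = stats.norm.ppf(1.0 - design.alpha_one_sided)
    lo, hi = estimate - z * se, estimate + z * se
    return AnalysisResult(
        method=method,
        estimate=float(estimate),
        std_error=se,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=design.ci_level,
        n_analyzed=nE + nC,
        ni_claimed=ni_decision(estimate, lo, hi, design.margin),
    )


def _split_arms(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out = {arm: table[table["assigned"] == arm] for arm in ARMS}
    for arm, sub in out.items():
        if len(sub) == 0:
            raise EstimationError(f"no participants assigned to the {arm} arm")
    return out


def itt_estimate(table: pd.DataFrame, design: TrialDesign) -> AnalysisResult:
    """Intention-to-treat estimate of the efficacy difference."""
    arms = _split_arms(table)
    y = {arm: _efficacy_outcome(sub, design) for arm, sub in arms.items()}
    return _wald_difference(y["experimental"], y["control"], design, "ITT")


def pp_estimate(table: pd.DataFrame, design: TrialDesign) -> AnalysisResult:
    """Naive per-protocol estimate restricted to adherent participants."""
    adherent = table[table["received"] == table["assigned"]]
    for arm in ARMS:
        if (adherent["assigned"] == arm).sum() < 2:
            raise EstimationError(
                f"per-protocol analysis needs at least 2 adherent participants in the {arm} arm"
            )
    arms = _split_arms(adherent)
    y = {arm: _efficacy_outcome(sub, design) for arm, sub in arms.items()}
    return _wald_difference(y["experimental"], y["control"], design, "PP")


def _fit_adherence_weights(
    arm_table: pd.DataFrame, columns: list[str], truncate: bool
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit P(adhere | X) by logistic regression within one assigned arm.

    Returns ``(adherent_mask, weights_for_adherent_rows, converged)``.
    Weights are 1 when the arm is fully adherent (documented fallback).
    """
    adheres = (arm_table["received"] == arm_table["assigned"]).to_numpy()
    if adheres.all():
        return adheres, np.ones(int(adheres.sum())), True
    X = sm.add_constant(arm_table[columns].to_numpy(dtype=float), has_constant="add")
    model = sm.GLM(adheres.astype(float), X, family=sm.families.Binomial())
    try:
        fit = model.fit(maxiter=100, tol=1e-8)
    except Exception as err:  # perfect separation raises inside IRLS
        raise EstimationError(f"adherence model failed to fit: {err}") from err
    if not fit.converged:
        raise EstimationError(
            f"adherence model did not converge in 100 IRLS iterations (params {fit.params})"
        )
    if np.abs(fit.params).max() > _MAX_LOGISTIC_COEF:
        raise EstimationError(
            f"adherence model shows separation (diverging coefficients {fit.params})"
        )
    p_hat = fit.predict(X)[adheres]
    weights = 1.0 / p_hat
    if truncate:
        weights = np.minimum(weights, np.quantile(weights, 0.99))
    return adheres, weights, True


def _hajek_difference(table: pd.DataFrame, design: TrialDesign, truncate: bool):
    """Point estimate and weights of the IPW per-protocol analysis."""
    columns = confounder_columns(table)
    if not columns:
        raise EstimationError("inverse probability weighting requires confounder columns")
    arms = _split_arms(table)
    means, weights_all, n_analyzed = {}, [], 0
    for arm, sub in arms.items():
        adheres, w, _ = _fit_adherence_weights(sub, columns, truncate)
        y = _efficacy_outcome(sub[adheres], design)
        if len(y) < 2:
            raise EstimationError(f"fewer than 2 adherent participants in the {arm} arm")
        means[arm] = float(np.sum(w * y) / np.sum(w))
        weights_all.append(w)
        n_analyzed += len(y)
    w = np.concatenate(weights_all)
    diagnostics = WeightDiagnostics(
        min_weight=float(w.min()),
        max_weight=float(w.max()),
        mean_weight=float(w.mean()),
        effective_sample_size=float(w.sum() ** 2 / np.sum(w**2)),
        converged=True,
    )
    return means["experimental"] - means["control"], n_analyzed, diagnostics


def ipw_point_estimate(
    table: pd.DataFrame, design: TrialDesign, truncate_weights: bool = False
) -> float:
    """IPW (Hajek) point estimate of the efficacy difference, no CI."""
    estimate, _, _ = _hajek_difference(table, design, truncate_weights)
    return estimate


def _bootstrap_ci(
    table: pd.DataFrame,
    design: TrialDesign,
    point_fn,
    bootstrap_reps: int,
    seed: int | None,
    method: str,
) -> tuple[float, float, float]:
    """Within-arm nonparametric bootstrap percentile CI for ``point_fn``."""
    rng = np.random.default_rng(seed)
    arm_indices = {arm: np.flatnonzero((table["assigned"] == arm).to_numpy()) for arm in ARMS}
    estimates, failures = [], 0
    for _ in range(bootstrap_reps):
        rows = np.concatenate(
            [rng.choice(idx, size=len(idx), replace=True) for idx in arm_indices.values()]
        )
        resampled = table.iloc[rows].reset_index(drop=True)
        try:
            estimates.append(point_fn(resampled))
        except EstimationError:
            failures += 1
    if failures > 0.1 * bootstrap_reps:
        raise EstimationError(
            f"{method} bootstrap failed in {failures}/{bootstrap_reps} replicates"
        )
    estimates = np.asarray(estimates)
    lo, hi = np.quantile(estimates, [design.alpha_one_sided, 1.0 - design.alpha_one_sided])
    return float(lo), float(hi), float(estimates.std(ddof=1))


def ipw_estimate(
    table: pd.DataFrame,
    design: TrialDesign,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    truncate_weights: bool = False,
) -> tuple[AnalysisResult, WeightDiagnostics]:
    """Inverse-probability-weighted per-protocol estimate with bootstrap CI.

    The adherence model is a logistic regression of adherence on the
    confounder columns, fitted separately per assigned arm; adherent
    participants are weighted by the reciprocal of their fitted adherence
    probability and arm efficacies are compared in Hajek (normalised) form.
    The CI is a within-arm nonparametric bootstrap percentile interval, with
    the weight model refitted in each replicate.
    """
    if bootstrap_reps < 1:
        raise ValidationError("bootstrap_reps must be >= 1")
    estimate, n_analyzed, diagnostics = _hajek_difference(table, design, truncate_weights)
    lo, hi, se = _bootstrap_ci(
        table,
        design,
        lambda t: _hajek_difference(t, design, truncate_weights)[0],
        bootstrap_reps,
        seed,
        "IPW",
    )
    lo, hi = min(lo, estimate), max(hi, estimate)
    result = AnalysisResult(
        method="IPW",
        estimate=float(estimate),
        std_error=se,
        ci_low=lo,
        ci_high=hi,
        ci_level=design.ci_level,
        n_analyzed=n_analyzed,
        ni_claimed=ni_decision(estimate, lo, hi, design.margin),
    )
    return result, diagnostics


def _stratum_labels(
    table: pd.DataFrame, strata_definition: dict, reference: pd.DataFrame
) -> pd.Series:
    """Combined stratum label per row.

    ``strata_definition`` maps a confounder column to ``None`` (use its
    discrete values) or to a list of quantile probabilities whose cut points
    (computed on ``reference``) discretise a continuous confounder.
    """
    if not strata_definition:
        raise ValidationError("strata_definition must name at least one confounder column")
    pieces = []
    for col, quantiles in strata_definition.items():
        if col not in table.columns:
            raise ValidationError(f"stratification column {col!r} is not in the table")
        if quantiles is None:
            pieces.append(table[col].astype(str))
        else:
            cuts = np.unique(np.quantile(reference[col].to_numpy(dtype=float), quantiles))
            edges = np.concatenate(([-np.inf], cuts, [np.inf]))
            binned = pd.cut(table[col], bins=edges, labels=False, include_lowest=True)
            pieces.append(col + "=q" + binned.astype(int).astype(str))
    labels = pieces[0].astype(str)
    for extra in pieces[1:]:
        labels = labels + "|" + extra.astype(str)
    return labels


def _standardised_difference(
    table: pd.DataFrame, design: TrialDesign, strata_definition: dict, reference: pd.DataFrame
) -> tuple[float, int]:
    labels = _stratum_labels(table, strata_definition, reference)
    shares = labels.value_counts(normalize=True)
    adherent = table["received"] == table["assigned"]
    risks = {arm: 0.0 for arm in ARMS}
    n_analyzed = int(adherent.sum())
    for stratum, share in shares.items():
        in_stratum = labels == stratum
        for arm in ARMS:
            cell = table[in_stratum & adherent & (table["assigned"] == arm)]
            if len(cell) == 0:
                raise EstimationError(
                    f"stratum {stratum!r} has no adherent participants in the {arm} arm"
                )
            risks[arm] += share * _efficacy_outcome(cell, design).mean()
    return risks["experimental"] - risks["control"], n_analyzed


def standardisation_estimate(
    table: pd.DataFrame,
    design: TrialDesign,
    strata_definition: dict,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> AnalysisResult:
    """Standardised (stratified, cohort-weighted) per-protocol estimate.

    Stratum-specific adherent-only arm efficacies are averaged with weights
    equal to each stratum's share of the full randomised cohort.  Continuous
    confounders are discretised at quantile cut points computed once on the
    analysed table and held fixed across bootstrap replicates.
    """
    if bootstrap_reps < 1:
        raise ValidationError("bootstrap_reps must be >= 1")
    estimate, n_analyzed = _standardised_difference(table, design, strata_definition, table)
    lo, hi, se = _bootstrap_ci(
        table,
        design,
        lambda t: _standardised_difference(t, design, strata_definition, table)[0],
        bootstrap_reps,
        seed,
        "STD",
    )
    lo, hi = min(lo, estimate), max(hi, estimate)
    return AnalysisResult(
        method="STD",
        estimate=float(estimate),
        std_error=se,
        ci_low=lo,
        ci_high=hi,
        ci_level=design.ci_level,
        n_analyzed=n_analyzed,
        ni_claimed=ni_decision(estimate, lo, hi, design.margin),
    )


def iv_estimate(table: pd.DataFrame, design: TrialDesign) -> AnalysisResult:
    """Instrumental-variable (Wald ratio) estimate with delta-method CI.

    Randomised assignment instruments the treatment actually received: the
    estimate is the intention-to-treat outcome difference divided by the
    first-stage difference in the probability of receiving the experimental
    treatment.  Requires crossover-only non-adherence (no rows received the
    alternative treatment) and a first stage above 0.01.
    """
    if (table["received"] == "alternative").any():
        raise EstimationError(
            "instrumental-variable estimation requires crossover-only non-adherence; "
            "rows received the alternative treatment"
        )
    arms = _split_arms(table)
    stats_by_arm = {}
    for arm, sub in arms.items():
        y = _efficacy_outcome(sub, design)
        d = (sub["received"] == "experimental").to_numpy(dtype=float)
        n = len(sub)
        cov = np.cov(y, d, ddof=1) if n > 1 else np.zeros((2, 2))
        stats_by_arm[arm] = (y.mean(), d.mean(), cov / n, n)
    (yE, dE, covE, nE) = stats_by_arm["experimental"]
    (yC, dC, covC, nC) = stats_by_arm["control"]
    first_stage = dE - dC
    if first_stage <= 0.01:
        raise EstimationError(
            f"weak instrument: first-stage difference {first_stage:.4f} <= 0.01"
        )
    estimate = (yE - yC) / first_stage
    var = (
        covE[0, 0] + covC[0, 0]
        + estimate**2 * (covE[1, 1] + covC[1, 1])
        - 2.0 * estimate * (covE[0, 1] + covC[0, 1])
    ) / first_stage**2
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1.0 - design.alpha_one_sided)
    lo, hi = estimate - z * se, estimate + z * se
    return AnalysisResult(
        method="IV",
        estimate=float(estimate),
        std_error=se,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=design.ci_level,
        n_analyzed=nE + nC,
        ni_claimed=ni_decision(estimate, lo, hi, design.margin),
    )
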