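"""Calibrated outcome and adherence models used by the cohort generator.

Outcome model: linear on the probability scale with mean-centred
confounders, ``pi_t(X) = eff_t + sum_j c_j (X_j - E[X_j])``, so the marginal
success probability under every treatment equals the design efficacy
exactly.  Adherence model: logistic in the mean-centred confounders with the
intercept calibrated by root finding so the marginal adherence matches the
scenario's target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .design import (
    ARMS,
    CalibrationError,
    ConfounderSpec,
    ScenarioSpec,
    TrialDesign,
    ValidationError,
)

__all__ = [
    "OutcomeModel",
    "AdherenceModel",
    "calibrate_outcome_model",
    "calibrate_adherence_model",
    "confounder_quadrature",
]

_QUAD_NODES = 64
_CALIBRATION_TOL = 1e-9


def confounder_quadrature(
    confounders: tuple[ConfounderSpec, ...], n_nodes: int = _QUAD_NODES
) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product quadrature grid over the joint confounder distribution.

    Returns ``(points, weights)`` with ``points`` of shape ``(M, k)`` and
    ``weights`` summing to 1; expectations over the (independent) confounder
    distribution are ``weights @ f(points)``.  Uniform confounders use
    Gauss-Legendre nodes, Bernoulli confounders their two support points.
    """
    if not confounders:
        return np.zeros((1, 0)), np.ones(1)
    axes_x, axes_w = [], []
    for c in confounders:
        if c.distribution == "uniform01":
            x, w = np.polynomial.legendre.leggauss(n_nodes)
            axes_x.append(0.5 * (x + 1.0))
            axes_w.append(0.5 * w)
        else:
            axes_x.append(np.array([0.0, 1.0]))
            axes_w.append(np.array([1.0 - c.q, c.q]))
    grids = np.meshgrid(*axes_x, indexing="ij")
    points = np.column_stack([g.ravel() for g in grids])
    weights = np.ones(points.shape[0])
    for wg in np.meshgrid(*axes_w, indexing="ij"):
        weights *= wg.ravel()
    return points, weights


@dataclass(frozen=True)
class OutcomeModel:
    """Per-treatment success-probability functions, exact in the marginals.

    ``efficacy_coefficients`` are on the *success* scale (harm-polarity
    designs negate the confounders' recorded-event coefficients at
    construction).
    """

    efficacies: dict
    confounders: tuple[ConfounderSpec, ...]
    efficacy_coefficients: np.ndarray
    outcome_polarity: str = "success"

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.confounders])

    def efficacy(self, treatment, X: np.ndarray) -> np.ndarray:
        """Success probability given treatment(s) and confounder values ``X (n, k)``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        shift = (X - self.means) @ self.efficacy_coefficients if len(self.confounders) else 0.0
        if isinstance(treatment, str):
            base = self.efficacies[treatment]
        else:
            base = np.array([self.efficacies[t] for t in treatment])
        return base + shift

    def event_probability(self, treatment, X: np.ndarray) -> np.ndarray:
        """Probability of the recorded outcome event (harm designs: 1 - efficacy)."""
        p = self.efficacy(treatment, X)
        return p if self.outcome_polarity == "success" else 1.0 - p


def calibrate_outcome_model(
    design: TrialDesign,
    confounders: tuple[ConfounderSpec, ...] = (),
    alternative_efficacy: float | None = None,
) -> OutcomeModel:
    """Build the mean-centred linear outcome model and check its range.

    Raises :class:`ValidationError` naming the offending treatment and bound
    if any attainable confounder combination pushes a probability outside
    ``[0, 1]``.
    """
    confounders = tuple(confounders)
    sign = 1.0 if design.outcome_polarity == "success" else -1.0
    coefs = np.array([sign * c.outcome_coefficient for c in confounders])
    efficacies = {
        "experimental": design.eff_experimental,
        "control": design.eff_control,
    }
    if alternative_efficacy is not None:
        efficacies["alternative"] = float(alternative_efficacy)
    means = np.array([c.mean for c in confounders])
    for treatment, eff in efficacies.items():
        lo, hi = eff, eff
        for c, coef, mu in zip(confounders, coefs, means):
            a, b = c.support
            vals = (coef * (a - mu), coef * (b - mu))
            lo += min(vals)
            hi += max(vals)
        if lo < -1e-12:
            raise ValidationError(
                f"outcome model for treatment {treatment!r} reaches probability {lo:.4f} < 0"
            )
        if hi > 1.0 + 1e-12:
            raise ValidationError(
                f"outcome model for treatment {treatment!r} reaches probability {hi:.4f} > 1"
            )
    return OutcomeModel(
        efficacies=efficacies,
        confounders=confounders,
        efficacy_coefficients=coefs,
        outcome_polarity=design.outcome_polarity,
    )


@dataclass(frozen=True)
class AdherenceModel:
    """Probability of adhering given assigned arm and confounders.

    ``P(adhere | X) = expit(intercept + sum_j delta_j (X_j - E[X_j]))``;
    a fully adherent arm bypasses the logistic and returns 1 for all X.
    """

    arm: str
    intercept: float
    coefficients: np.ndarray
    means: np.ndarray
    always_adheres: bool = False

    def prob(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        if self.always_adheres:
            return np.ones(n)
        if self.coefficients.size:
            eta = self.intercept + (X - self.means) @ self.coefficients
        else:
            eta = np.full(n, self.intercept)
        return expit(eta)


def calibrate_adherence_model(
    scenario: ScenarioSpec, arm: str, n_nodes: int = _QUAD_NODES
) -> AdherenceModel:
    """Calibrate the arm's logistic adherence intercept to the target marginal.

    With no confounder effects the intercept is the exact logit of the
    target; otherwise it is found by one-dimensional root finding so the
    quadrature average of the adherence probability matches the target to
    within 1e-9.
    """
    if arm not in ARMS:
        raise ValidationError(f"unknown arm {arm!r}; expected one of {ARMS}")
    target = scenario.adherence_marginal_by_arm[arm]
    if target <= 0.0:
        raise CalibrationError(f"degenerate arm {arm!r}: marginal adherence must be positive")
    confounders = scenario.confounders
    means = np.array([c.mean for c in confounders])
    deltas = np.array([c.adherence_coefficient_by_arm[arm] for c in confounders])
    if target == 1.0:
        return AdherenceModel(arm, np.inf, deltas, means, always_adheres=True)
    if not deltas.size or not deltas.any():
        return AdherenceModel(arm, float(logit(target)), deltas, means)

    points, weights = confounder_quadrature(confounders, n_nodes)
    eta_x = (points - means) @ deltas

    def marginal_minus_target(alpha: float) -> float:
        return float(weights @ expit(alpha + eta_x) - target)

    lo, hi = -60.0, 60.0
    try:
        alpha = brentq(marginal_minus_target, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    except ValueError as err:
        raise CalibrationError(
            f"adherence calibration failed for arm {arm!r} (target {target}, "
            f"coefficients {deltas.tolist()}): {err}"
        ) from err
    residual = marginal_minus_target(alpha)
    if abs(residual) > _CALIBRATION_TOL:
        raise CalibrationError(
            f"adherence calibration for arm {arm!r} left residual {residual:.2e} "
            f"(target {target}, intercept {alpha:.6f})"
        )
    return AdherenceModel(arm, float(alpha), deltas, means)
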