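"""Domain types for two-arm non-inferiority trials with non-adherence.

The canonical internal scale throughout the package is the *efficacy
difference* ``delta = eff_experimental - eff_control``: non-inferiority is
claimed when the lower confidence bound of the efficacy difference exceeds
``-margin``.  Designs whose recorded outcome is an adverse event (e.g. death
by day 30) declare ``outcome_polarity="harm"`` and are converted to the
efficacy scale at the analysis boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "ARMS",
    "TREATMENTS",
    "ValidationError",
    "CalibrationError",
    "EstimationError",
    "TrialDesign",
    "ConfounderSpec",
    "ScenarioSpec",
]

ARMS = ("experimental", "control")
TREATMENTS = ("experimental", "control", "alternative")


class ValidationError(ValueError):
    """A design, scenario or participant table violates its invariants."""


class CalibrationError(RuntimeError):
    """A model calibration step failed (e.g. root finding did not converge)."""


class EstimationError(RuntimeError):
    """An estimator could not produce a valid result on the given data."""


@dataclass(frozen=True)
class TrialDesign:
    """Fixed design of a two-arm non-inferiority trial with a binary outcome.

    Parameters
    ----------
    n_per_arm
        Number of participants randomised to each arm (exactly balanced
        allocation).
    eff_experimental, eff_control
        Marginal success probabilities ("efficacies") under the experimental
        and control treatments.  For harm-polarity outcomes these are
        ``1 - risk`` of the adverse event.
    margin
        Non-inferiority margin on the absolute efficacy-difference scale.
    alpha_one_sided
        One-sided type-I error level; the reported CI is two-sided at level
        ``1 - 2 * alpha_one_sided``.
    outcome_polarity
        ``"success"`` if the recorded outcome is the good event, ``"harm"``
        if it is the adverse event (converted internally to efficacy).
    """

    n_per_arm: int
    eff_experimental: float
    eff_control: float
    margin: float
    alpha_one_sided: float = 0.025
    outcome_polarity: str = "success"

    def __post_init__(self) -> None:
        if int(self.n_per_arm) != self.n_per_arm or self.n_per_arm < 2:
            raise ValidationError(f"n_per_arm must be an integer >= 2, got {self.n_per_arm}")
        for name in ("eff_experimental", "eff_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.margin < 1.0:
            raise ValidationError(f"margin must lie in (0, 1), got {self.margin}")
        if not 0.0 < self.alpha_one_sided < 0.5:
            raise ValidationError(
                f"alpha_one_sided must lie in (0, 0.5), got {self.alpha_one_sided}"
            )
        if self.outcome_polarity not in ("success", "harm"):
            raise ValidationError(
                f"outcome_polarity must be 'success' or 'harm', got {self.outcome_polarity!r}"
            )

    @property
    def true_difference(self) -> float:
        """True efficacy difference ``eff_experimental - eff_control``."""
        return self.eff_experimental - self.eff_control

    @property
    def ci_level(self) -> float:
        return 1.0 - 2.0 * self.alpha_one_sided

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_arm


def _as_arm_mapping(value, what: str) -> Mapping[str, float]:
    if not isinstance(value, Mapping):
        raise ValidationError(f"{what} must be a mapping over arms {ARMS}")
    extra = set(value) - set(ARMS)
    if extra:
        raise ValidationError(f"{what} has unknown arm labels {sorted(extra)}")
    full = {arm: float(value.get(arm, 0.0)) for arm in ARMS}
    return MappingProxyType(full)


@dataclass(frozen=True)
class ConfounderSpec:
    """A baseline covariate affecting both adherence and the outcome.

    ``outcome_coefficient`` is the additive effect of one unit of the
    mean-centred confounder on the probability of the *recorded* outcome
    event (so a positive coefficient increases the adverse-event probability
    in a harm-polarity design).  ``adherence_coefficient_by_arm`` gives the
    log-odds effect of one unit of the mean-centred confounder on adhering,
    separately per assigned arm.
    """

    name: str
    distribution: str = "uniform01"
    q: float | None = None
    outcome_coefficient: float = 0.0
    adherence_coefficient_by_arm: Mapping[str, float] = field(
        default_factory=lambda: {"experimental": 0.0, "control": 0.0}
    )

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValidationError("confounder name must be a non-empty string")
        if self.distribution not in ("uniform01", "bernoulli"):
            raise ValidationError(
                f"distribution must be 'uniform01' or 'bernoulli', got {self.distribution!r}"
            )
        if self.distribution == "bernoulli":
            if self.q is None or not 0.0 < self.q < 1.0:
                raise ValidationError(
                    f"bernoulli confounder {self.name!r} needs q in (0, 1), got {self.q}"
                )
        elif self.q is not None:
            raise ValidationError(f"q is only meaningful for bernoulli confounders ({self.name!r})")
        object.__setattr__(
            self,
            "adherence_coefficient_by_arm",
            _as_arm_mapping(self.adherence_coefficient_by_arm, f"adherence coefficients of {self.name!r}"),
        )

    @property
    def mean(self) -> float:
        return 0.5 if self.distribution == "uniform01" else float(self.q)

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, 1.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """Non-adherence mechanism for a trial: who deviates, to what, and why.

    ``nonadherent_arms`` lists the arms with marginal adherence below 1;
    their non-adherent participants receive either the opposite arm's
    treatment (``destination="crossover"``) or a third, inferior treatment
    (``destination="alternative"`` with ``alternative_efficacy``).
    Confounders, if any, shift both adherence (log-odds scale, per arm) and
    the outcome (probability scale).
    """

    name: str = "custom"
    nonadherent_arms: tuple[str, ...] = ()
    destination: str | None = None
    alternative_efficacy: float | None = None
    adherence_marginal_by_arm: Mapping[str, float] = field(
        default_factory=lambda: {"experimental": 1.0, "control": 1.0}
    )
    confounders: tuple[ConfounderSpec, ...] = ()

    def __post_init__(self) -> None:
        arms = tuple(self.nonadherent_arms)
        if len(set(arms)) != len(arms) or set(arms) - set(ARMS):
            raise ValidationError(f"nonadherent_arms must be a subset of {ARMS}, got {arms}")
        object.__setattr__(self, "nonadherent_arms", arms)
        object.__setattr__(self, "confounders", tuple(self.confounders))
        names = [c.name for c in self.confounders]
        if len(set(names)) != len(names):
            raise ValidationError(f"confounder names must be unique, got {names}")
        adherence = _as_arm_mapping(
            {arm: self.adherence_marginal_by_arm.get(arm, 1.0) for arm in ARMS},
            "adherence_marginal_by_arm",
        )
        object.__setattr__(self, "adherence_marginal_by_arm", adherence)
        for arm in ARMS:
            a = adherence[arm]
            if not 0.0 < a <= 1.0:
                raise ValidationError(f"marginal adherence of {arm} arm must be in (0, 1], got {a}")
            if arm not in arms and a != 1.0:
                raise ValidationError(
                    f"{arm} arm is not listed as non-adherent but has marginal adherence {a}"
                )
        if arms:
            if self.destination not in ("crossover", "alternative"):
                raise ValidationError(
                    "destination must be 'crossover' or 'alternative' when any arm is non-adherent"
                )
            if self.destination == "alternative":
                if self.alternative_efficacy is None or not 0.0 <= self.alternative_efficacy <= 1.0:
                    raise ValidationError(
                        "alternative_efficacy in [0, 1] is required when destination='alternative'"
                    )
            elif self.alternative_efficacy is not None:
                raise ValidationError("alternative_efficacy is only meaningful for destination='alternative'")

    @property
    def confounded(self) -> bool:
        return any(
            c.adherence_coefficient_by_arm[arm] != 0.0
            for c in self.confounders
            for arm in ARMS
        )

    def validate_against(self, design: TrialDesign) -> None:
        """Cross-check scenario parameters against a trial design."""
        if self.destination == "alternative":
            low = min(design.eff_experimental, design.eff_control)
            if self.alternative_efficacy >= low:
                raise ValidationError(
                    "alternative treatment must be inferior to both trial treatments: "
                    f"alternative_efficacy={self.alternative_efficacy} >= {low}"
                )

    @classmethod
    def full_adherence(cls, confounders: tuple[ConfounderSpec, ...] = ()) -> "ScenarioSpec":
        """Scenario in which every participant receives the assigned treatment."""
        return cls(name="full_adherence", confounders=confounders)

    @classmethod
    def symmetric_crossover(
        cls, adherence: float, confounders: tuple[ConfounderSpec, ...] = ()
    ) -> "ScenarioSpec":
        """Both arms non-adherent at the same marginal rate; deviators cross over."""
        if adherence == 1.0:
            return cls.full_adherence(confounders)
        return cls(
            name=f"symmetric_crossover_{adherence:g}",
            nonadherent_arms=ARMS,
            destination="crossover",
            adherence_marginal_by_arm={"experimental": adherence, "control": adherence},
            confounders=confounders,
        )
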