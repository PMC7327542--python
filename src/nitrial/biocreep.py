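"""Biocreep: consecutive non-inferiority trials with an eroding standard.

Simulates a fixed chain of trials — standard of care vs treatment A, A vs B,
B vs C, C vs D — in which each new treatment is truly less effective than
its comparator by a fixed decrement, every trial is run at the same
adherence level with symmetric crossover, and a treatment becomes the
accepted standard only if its own trial and all preceding trials claimed
non-inferiority.  The trials are statistically independent with fixed
comparator pairs, so the closed-form acceptance probabilities are running
products of per-trial claim probabilities.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .design import ScenarioSpec, TrialDesign, ValidationError
from .oc import claim_probability_oracle, expected_arm_efficacies
from .power import analytic_sample_size

__all__ = ["ChainConfig", "BiocreepResult", "run_chain", "chain_oracle"]


@dataclass(frozen=True)
class ChainConfig:
    """Configuration of a chain of consecutive non-inferiority trials."""

    initial_soc_efficacy: float = 0.9
    per_step_efficacy_drop: float = 0.10
    n_treatments: int = 4
    margin: float = 0.10
    alpha_one_sided: float = 0.025
    n_per_arm: int | None = None
    adherence: float = 1.0
    replicates: int = 10_000

    def __post_init__(self) -> None:
        if self.per_step_efficacy_drop <= 0:
            raise ValidationError("per_step_efficacy_drop must be positive")
        if self.n_treatments < 1:
            raise ValidationError("n_treatments must be >= 1")
        if not 0.0 < self.adherence <= 1.0:
            raise ValidationError(f"adherence must be in (0, 1], got {self.adherence}")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        effs = self.chain_efficacies
        if effs[-1] <= 0.0 or effs[0] >= 1.0:
            raise ValidationError(
                f"chain efficacies {np.round(effs, 4).tolist()} leave (0, 1)"
            )

    @property
    def chain_efficacies(self) -> np.ndarray:
        """True efficacies of [standard of care, treatment 1, 2, ...]."""
        return self.initial_soc_efficacy - self.per_step_efficacy_drop * np.arange(
            self.n_treatments + 1
        )

    @property
    def treatment_labels(self) -> tuple[str, ...]:
        return tuple(string.ascii_uppercase[: self.n_treatments])

    def resolved_n_per_arm(self) -> int:
        """Per-trial sample size; defaults to the analytic size of the first
        trial designed under the usual equal-efficacy planning assumption."""
        if self.n_per_arm is not None:
            return self.n_per_arm
        e = self.initial_soc_efficacy
        return analytic_sample_size(e, e, self.margin, self.alpha_one_sided, 0.8)

    def trial_designs(self) -> list[TrialDesign]:
        effs = self.chain_efficacies
        n = self.resolved_n_per_arm()
        return [
            TrialDesign(
                n_per_arm=n,
                eff_experimental=float(effs[k + 1]),
                eff_control=float(effs[k]),
                margin=self.margin,
                alpha_one_sided=self.alpha_one_sided,
            )
            for k in range(self.n_treatments)
        ]


@dataclass(frozen=True)
class BiocreepResult:
    """Per-treatment acceptance probabilities along the chain."""

    labels: tuple[str, ...]
    cumulative_prob: np.ndarray
    mc_std_error: np.ndarray
    per_trial_claim_prob: np.ndarray
    replicates: int

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "cumulative_prob": self.cumulative_prob.tolist(),
            "mc_std_error": self.mc_std_error.tolist(),
            "per_trial_claim_prob": self.per_trial_claim_prob.tolist(),
            "replicates": self.replicates,
        }


def _trial_scenario(config: ChainConfig) -> ScenarioSpec:
    return ScenarioSpec.symmetric_crossover(config.adherence)


def run_chain(config: ChainConfig, seed: int | None = None) -> BiocreepResult:
    """Monte-Carlo acceptance probabilities for each treatment in the chain.

    Each replicate simulates all trials independently (arm-level binomial
    draws at the crossover-mixture efficacies, Wald test per trial);
    treatment k is accepted as the new standard iff trials 1..k all claimed
    non-inferiority.
    """
    from .oc import _binomial_shortcut_itt  # shared engine

    rng = np.random.default_rng(seed)
    scenario = _trial_scenario(config)
    R = config.replicates
    claims = np.empty((R, config.n_treatments), dtype=bool)
    for k, design in enumerate(config.trial_designs()):
        _, c = _binomial_shortcut_itt(design, scenario, R, rng)
        claims[:, k] = c
    accepted = np.logical_and.accumulate(claims, axis=1)
    cumulative = accepted.mean(axis=0)
    return BiocreepResult(
        labels=config.treatment_labels,
        cumulative_prob=cumulative,
        mc_std_error=np.sqrt(cumulative * (1 - cumulative) / R),
        per_trial_claim_prob=claims.mean(axis=0),
        replicates=R,
    )


def chain_oracle(config: ChainConfig) -> np.ndarray:
    """Closed-form cumulative acceptance probabilities (independence product).

    Per-trial claim probabilities come from the normal-approximation oracle
    evaluated at each trial's crossover-mixture efficacies; the cumulative
    probability for treatment k is the running product.
    """
    scenario = _trial_scenario(config)
    probs = []
    for design in config.trial_designs():
        eE, eC = expected_arm_efficacies(design, scenario)
        probs.append(
            claim_probability_oracle(
                eE, eC, design.n_per_arm, design.margin, design.alpha_one_sided
            )
        )
    return np.cumprod(probs)
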