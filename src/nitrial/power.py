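"""Sample-size and power calculation for non-inferiority designs.

Analytic mode uses the standard normal-approximation formula for the
difference of two proportions (no continuity correction, matching the Wald
test used by the estimators); simulated mode wraps the Monte-Carlo
operating-characteristics engine so that any non-adherence scenario and
analysis method can be accounted for at the design stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .design import ScenarioSpec, TrialDesign, ValidationError
from .oc import run_oc

__all__ = ["PowerResult", "analytic_sample_size", "simulated_power", "required_n"]


@dataclass(frozen=True)
class PowerResult:
    """Power of a design, either analytic or Monte-Carlo."""

    mode: str
    n_per_arm: int
    power: float
    mc_std_error: float | None
    method: str
    replicates: int | None
    settings: dict

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_per_arm": self.n_per_arm,
            "power": self.power,
            "mc_std_error": self.mc_std_error,
            "method": self.method,
            "replicates": self.replicates,
            "settings": self.settings,
        }


def analytic_sample_size(
    eff_experimental: float,
    eff_control: float,
    margin: float,
    alpha: float = 0.025,
    power: float = 0.8,
) -> int:
    """Minimal per-arm sample size for the non-inferiority Wald test.

    ``n = ceil((z_{1-alpha} + z_{power})^2 (p_E(1-p_E) + p_C(1-p_C))
    / (margin + p_E - p_C)^2)``, rounded up per arm.
    """
    delta = eff_experimental - eff_control
    if margin + delta <= 0:
        raise ValidationError(
            f"margin not attainable: margin + true difference = {margin + delta:g} <= 0"
        )
    if not 0 < power < 1:
        raise ValidationError(f"power must lie in (0, 1), got {power}")
    z_alpha = stats.norm.ppf(1.0 - alpha)
    z_power = stats.norm.ppf(power)
    variance = eff_experimental * (1 - eff_experimental) + eff_control * (1 - eff_control)
    n = (z_alpha + z_power) ** 2 * variance / (margin + delta) ** 2
    return int(math.ceil(n - 1e-12))


def simulated_power(
    design: TrialDesign,
    scenario: ScenarioSpec,
    R: int = 5000,
    seed: int | None = None,
    method: str = "ITT",
) -> PowerResult:
    """Monte-Carlo probability of claiming non-inferiority for the design.

    Interpreted as power when the true difference lies inside the margin and
    as type-I error when it lies at or beyond it.
    """
    if R < 100:
        raise ValidationError("simulated power needs R >= 100")
    (res,) = run_oc(design, scenario, (method,), R=R, seed=seed)
    return PowerResult(
        mode="simulated",
        n_per_arm=design.n_per_arm,
        power=res.prob_claim_ni,
        mc_std_error=res.mc_std_error,
        method=res.method,
        replicates=R,
        settings={
            "eff_experimental": design.eff_experimental,
            "eff_control": design.eff_control,
            "margin": design.margin,
            "alpha_one_sided": design.alpha_one_sided,
            "scenario": scenario.name,
        },
    )


def required_n(
    design: TrialDesign,
    scenario: ScenarioSpec,
    power_target: float = 0.8,
    R: int = 2000,
    seed: int | None = None,
    method: str = "ITT",
    max_n: int = 1_000_000,
) -> int:
    """Smallest per-arm sample size reaching the target power.

    Under full adherence the analytic formula is returned directly; under
    non-adherence the power is simulated and bisected on a doubling bracket,
    accepting the smallest n whose simulated power is within one Monte-Carlo
    standard error of the target (power is monotone in n for all supported
    scenarios).
    """
    if not 0 < power_target < 1:
        raise ValidationError(f"power_target must lie in (0, 1), got {power_target}")
    analytic = analytic_sample_size(
        design.eff_experimental,
        design.eff_control,
        design.margin,
        design.alpha_one_sided,
        power_target,
    )
    if not scenario.nonadherent_arms:
        return analytic

    def power_at(n: int) -> float:
        d = replace(design, n_per_arm=n)
        sub = np.random.SeedSequence((0 if seed is None else seed, n))
        return simulated_power(d, scenario, R=R, seed=sub, method=method).power

    mc_se = math.sqrt(power_target * (1 - power_target) / R)
    threshold = power_target - mc_se

    lo, hi = 2, max(analytic, 2)
    while power_at(hi) < threshold:
        lo = hi
        hi *= 2
        if hi > max_n:
            raise ValidationError(f"required sample size exceeds {max_n} per arm")
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if power_at(mid) >= threshold:
            hi = mid
        else:
            lo = mid
    return hi
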