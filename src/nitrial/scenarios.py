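"""Catalogue of canonical non-adherence scenarios and the worked example.

The catalogue enumerates the 18 qualitative non-adherence patterns for a
trial whose experimental treatment is truly inferior by exactly the
non-inferiority margin: which arm(s) deviate, whether deviators cross over
to the opposite arm or take up an inferior third treatment, and whether a
prognostic confounder drives the deviation.  Row identifiers follow
``"<arm>/<destination>/<confounding>"`` with

* arm: ``both``, ``experiment``, ``control``
* destination: ``crossover``, ``inferior``
* confounding: ``nonconfounded``, ``confounded_increase``,
  ``confounded_decrease``

Confounded rows share a single mechanism: a uniform disease-severity score
raises the probability of the adverse outcome and *tilts treatment receipt
toward the experimental treatment* (``confounded_increase``) or away from it
(``confounded_decrease``).  For crossover rows this is literally "sicker
participants end up on the experimental treatment"; it is the one-parameter
mechanism under which intention-to-treat and per-protocol analyses move in
opposite, predictable directions.
"""

from __future__ import annotations

import pandas as pd

from .design import ARMS, ConfounderSpec, ScenarioSpec, TrialDesign, ValidationError
from .cohort import simulate_cohort

__all__ = [
    "CATALOG_ROW_IDS",
    "EXPECTED_CLAIM_DIRECTION",
    "catalog_design",
    "scenario_from_catalog",
    "worked_example_design",
    "worked_example_scenario",
    "worked_example_cohort",
]

# Frozen generator defaults for the catalogue (see docs/methods.md).
CATALOG_ADHERENCE = 0.9
CATALOG_ALTERNATIVE_EFFICACY = 0.35
CATALOG_OUTCOME_COEFFICIENT = 0.6   # on the adverse-event probability
CATALOG_ADHERENCE_LOG_ODDS = 6.0    # magnitude of the severity tilt

_ARM_SETS = {"both": ARMS, "experiment": ("experimental",), "control": ("control",)}
_DESTINATIONS = {"crossover": "crossover", "inferior": "alternative"}
_CONFOUNDING = ("nonconfounded", "confounded_increase", "confounded_decrease")

CATALOG_ROW_IDS = tuple(
    f"{arm}/{dest}/{conf}" for arm in _ARM_SETS for dest in _DESTINATIONS for conf in _CONFOUNDING
)

#: Expected direction of the probability of claiming non-inferiority,
#: relative to the fully adherent trial, for each catalogue row and method.
#: These are the qualitative operating characteristics the generator is
#: built to exhibit; :func:`nitrial.oc.direction_matrix` recovers them by
#: Monte Carlo.
EXPECTED_CLAIM_DIRECTION = {}
for _row in CATALOG_ROW_IDS:
    _arm, _dest, _conf = _row.split("/")
    _itt = "lower" if (_arm, _dest) == ("experiment", "inferior") else "higher"
    if _conf == "nonconfounded":
        _pp = "same"
    elif _conf == "confounded_increase":
        _pp = "lower"
    else:
        _pp = "higher"
    EXPECTED_CLAIM_DIRECTION[_row] = {"ITT": _itt, "PP": _pp}


def catalog_design(n_per_arm: int = 400) -> TrialDesign:
    """Reference design for the catalogue: the experimental treatment is
    truly inferior by exactly the 10% margin (efficacies 50% vs 60%), with a
    harm-polarity recorded outcome (treatment failure)."""
    return TrialDesign(
        n_per_arm=n_per_arm,
        eff_experimental=0.5,
        eff_control=0.6,
        margin=0.10,
        alpha_one_sided=0.025,
        outcome_polarity="harm",
    )


def scenario_from_catalog(row_id: str, design: TrialDesign | None = None) -> ScenarioSpec:
    """Return the :class:`ScenarioSpec` for one catalogue row.

    ``design`` is used only to cross-check that the inferior alternative is
    indeed inferior to both trial treatments.
    """
    parts = row_id.split("/")
    if len(parts) != 3 or parts[0] not in _ARM_SETS or parts[1] not in _DESTINATIONS \
            or parts[2] not in _CONFOUNDING:
        raise ValidationError(
            f"unknown catalogue row {row_id!r}; valid rows are: {', '.join(CATALOG_ROW_IDS)}"
        )
    arm_key, dest_key, conf_key = parts
    arms = _ARM_SETS[arm_key]
    destination = _DESTINATIONS[dest_key]

    confounders: tuple[ConfounderSpec, ...] = ()
    if conf_key != "nonconfounded":
        tilt = 1.0 if conf_key == "confounded_increase" else -1.0
        # Positive tilt: severity raises the probability of *receiving the
        # experimental treatment* in each non-adherent arm (i.e. raises
        # adherence in the experimental arm, lowers it in the control arm).
        coefs = {"experimental": 0.0, "control": 0.0}
        if "experimental" in arms:
            coefs["experimental"] = tilt * CATALOG_ADHERENCE_LOG_ODDS
        if "control" in arms:
            coefs["control"] = -tilt * CATALOG_ADHERENCE_LOG_ODDS
        confounders = (
            ConfounderSpec(
                name="severity",
                distribution="uniform01",
                outcome_coefficient=CATALOG_OUTCOME_COEFFICIENT,
                adherence_coefficient_by_arm=coefs,
            ),
        )

    scenario = ScenarioSpec(
        name=row_id,
        nonadherent_arms=arms,
        destination=destination,
        alternative_efficacy=CATALOG_ALTERNATIVE_EFFICACY if destination == "alternative" else None,
        adherence_marginal_by_arm={
            arm: (CATALOG_ADHERENCE if arm in arms else 1.0) for arm in ARMS
        },
        confounders=confounders,
    )
    if design is not None:
        scenario.validate_against(design)
    return scenario


# ---------------------------------------------------------------------------
# Worked example: short vs long duration treatment for ventilator-associated
# pneumonia, primary outcome death by day 30 (harm polarity).
# ---------------------------------------------------------------------------

#: Frozen preset constants (see docs/methods.md for rationale).
WORKED_EXAMPLE = {
    "n_per_arm": 400,
    "eff_experimental": 0.5,   # 30-day survival under short duration
    "eff_control": 0.6,        # 30-day survival under long duration
    "margin": 0.10,
    "alpha_one_sided": 0.025,
    "adherence": 0.75,         # marginal, each arm (overall 75%)
    "severity_outcome_coefficient": 0.5,
    "severity_adherence_log_odds": {"experimental": -8.0, "control": 8.0},
    "doctor_outcome_coefficient": -0.05,
    "doctor_adherence_log_odds": {"experimental": 1.0, "control": -1.0},
    "doctor_prevalence": 0.5,
}


def worked_example_design() -> TrialDesign:
    """Design of the hypothetical pneumonia trial: 800 participants, 10%
    margin, one-sided 2.5% alpha, true efficacy difference -0.10."""
    return TrialDesign(
        n_per_arm=WORKED_EXAMPLE["n_per_arm"],
        eff_experimental=WORKED_EXAMPLE["eff_experimental"],
        eff_control=WORKED_EXAMPLE["eff_control"],
        margin=WORKED_EXAMPLE["margin"],
        alpha_one_sided=WORKED_EXAMPLE["alpha_one_sided"],
        outcome_polarity="harm",
    )


def worked_example_scenario() -> ScenarioSpec:
    """Non-adherence mechanism of the worked example.

    Disease severity (uniform on [0, 1]) raises 30-day mortality and pushes
    severely ill patients off the short-duration (experimental) arm onto the
    long-duration treatment, while mildly ill control patients are switched
    to the short course; the treating doctor (Bernoulli 0.5) mildly affects
    both prescribing and outcome.  Marginal adherence is calibrated to 75%
    in each arm, so overall adherence is 75%.
    """
    we = WORKED_EXAMPLE
    severity = ConfounderSpec(
        name="severity",
        distribution="uniform01",
        outcome_coefficient=we["severity_outcome_coefficient"],
        adherence_coefficient_by_arm=we["severity_adherence_log_odds"],
    )
    doctor = ConfounderSpec(
        name="doctor",
        distribution="bernoulli",
        q=we["doctor_prevalence"],
        outcome_coefficient=we["doctor_outcome_coefficient"],
        adherence_coefficient_by_arm=we["doctor_adherence_log_odds"],
    )
    return ScenarioSpec(
        name="worked_example",
        nonadherent_arms=ARMS,
        destination="crossover",
        adherence_marginal_by_arm={"experimental": we["adherence"], "control": we["adherence"]},
        confounders=(severity, doctor),
    )


def worked_example_cohort(seed: int | None = None) -> pd.DataFrame:
    """Simulate one 800-participant cohort of the worked example."""
    return simulate_cohort(worked_example_design(), worked_example_scenario(), seed=seed)
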