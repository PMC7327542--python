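"""Participant-level cohort generation.

A cohort is a :class:`pandas.DataFrame` with columns
``id, assigned, received, <confounder columns...>, outcome`` — the
participant-table dialect shared by the readers/writers in
:mod:`nitrial.io` and by every estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ARMS, ScenarioSpec, TrialDesign, ValidationError
from .models import calibrate_adherence_model, calibrate_outcome_model

__all__ = [
    "RESERVED_COLUMNS",
    "simulate_cohort",
    "confounder_columns",
    "validate_participant_table",
]

RESERVED_COLUMNS = ("id", "assigned", "received", "outcome")

_OPPOSITE = {"experimental": "control", "control": "experimental"}


def confounder_columns(table: pd.DataFrame) -> list[str]:
    """Names of the confounder columns of a participant table."""
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


def _draw_confounders(rng: np.random.Generator, scenario: ScenarioSpec, n: int) -> np.ndarray:
    X = np.empty((n, len(scenario.confounders)))
    for j, c in enumerate(scenario.confounders):
        if c.distribution == "uniform01":
            X[:, j] = rng.uniform(0.0, 1.0, size=n)
        else:
            X[:, j] = rng.binomial(1, c.q, size=n)
    return X


def simulate_cohort(
    design: TrialDesign,
    scenario: ScenarioSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate one trial cohort under the design and non-adherence scenario.

    Exactly ``design.n_per_arm`` participants are allocated to each arm;
    confounders are drawn i.i.d.; adherence follows the arm's calibrated
    logistic model; non-adherent participants receive the opposite arm's
    treatment (crossover) or the inferior alternative; the binary outcome is
    drawn from the linear outcome model of the treatment actually received.
    Deterministic given ``seed``.
    """
    scenario.validate_against(design)
    if rng is None:
        rng = np.random.default_rng(seed)
    outcome_model = calibrate_outcome_model(
        design, scenario.confounders, alternative_efficacy=scenario.alternative_efficacy
    )
    adherence_models = {arm: calibrate_adherence_model(scenario, arm) for arm in ARMS}

    n = design.n_total
    X = _draw_confounders(rng, scenario, n)
    assigned = np.array(
        ["experimental"] * design.n_per_arm + ["control"] * design.n_per_arm, dtype=object
    )
    assigned = assigned[rng.permutation(n)]

    p_adhere = np.ones(n)
    for arm in ARMS:
        mask = assigned == arm
        p_adhere[mask] = adherence_models[arm].prob(X[mask])
    adheres = rng.uniform(size=n) < p_adhere

    received = assigned.copy()
    deviators = ~adheres
    if scenario.destination == "crossover":
        received[deviators] = np.where(
            assigned[deviators] == "experimental", "control", "experimental"
        )
    elif scenario.destination == "alternative":
        received[deviators] = "alternative"

    p_success = np.empty(n)
    for treatment in np.unique(received):
        mask = received == treatment
        p_success[mask] = outcome_model.efficacy(str(treatment), X[mask])
    success = rng.uniform(size=n) < p_success
    outcome = success if design.outcome_polarity == "success" else ~success

    data = {"id": np.arange(n), "assigned": assigned, "received": received}
    for j, c in enumerate(scenario.confounders):
        data[c.name] = X[:, j]
    data["outcome"] = outcome.astype(np.int8)
    return pd.DataFrame(data)


def validate_participant_table(
    table: pd.DataFrame,
    design: TrialDesign | None = None,
    scenario: ScenarioSpec | None = None,
) -> pd.DataFrame:
    """Check the participant-table contract, returning the table unchanged.

    Raises :class:`ValidationError` naming the offending row and column.
    """
    for col in RESERVED_COLUMNS:
        if col not in table.columns:
            raise ValidationError(f"participant table is missing required column {col!r}")
    bad = ~table["assigned"].isin(ARMS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"row {row}, column 'assigned': invalid value {table['assigned'].iloc[row]!r}"
        )
    valid_received = ARMS + ("alternative",)
    bad = ~table["received"].isin(valid_received)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"row {row}, column 'received': invalid value {table['received'].iloc[row]!r}"
        )
    bad = ~table["outcome"].isin((0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"row {row}, column 'outcome': value {table['outcome'].iloc[row]!r} is not binary"
        )
    if design is not None:
        counts = table["assigned"].value_counts()
        for arm in ARMS:
            if counts.get(arm, 0) != design.n_per_arm:
                raise ValidationError(
                    f"assigned counts must equal n_per_arm={design.n_per_arm} per arm; "
                    f"{arm} arm has {counts.get(arm, 0)}"
                )
    if scenario is not None and scenario.destination != "alternative":
        if (table["received"] == "alternative").any():
            raise ValidationError(
                "received='alternative' present but the scenario destination is not 'alternative'"
            )
    return table
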