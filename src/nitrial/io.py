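"""Readers, writers and configuration parsing.

Participant CSV dialect: columns ``id,assigned,received,<confounders...>,
outcome`` with ``assigned in {experimental, control}``, ``received in
{experimental, control, alternative}``, ``outcome in {0, 1}``; header
required, UTF-8.  Configuration files are YAML or JSON mappings whose keys
mirror :class:`~nitrial.design.TrialDesign` and
:class:`~nitrial.design.ScenarioSpec` field names.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import RESERVED_COLUMNS, validate_participant_table
from .design import ConfounderSpec, ScenarioSpec, TrialDesign, ValidationError

__all__ = [
    "read_participant_csv",
    "write_participant_csv",
    "load_config",
    "design_from_dict",
    "scenario_from_dict",
    "write_json",
]


def read_participant_csv(path) -> pd.DataFrame:
    """Read and validate a participant table from CSV."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"participant CSV not found: {path}")
    table = pd.read_csv(path, encoding="utf-8")
    for col in RESERVED_COLUMNS:
        if col not in table.columns:
            raise ValidationError(f"participant CSV {path} is missing column {col!r}")
    if not pd.api.types.is_numeric_dtype(table["outcome"]):
        raise ValidationError(f"participant CSV {path}: column 'outcome' must be numeric")
    return validate_participant_table(table)


def write_participant_csv(table: pd.DataFrame, path) -> None:
    """Write a participant table to CSV (round-trips losslessly)."""
    validate_participant_table(table)
    ordered = [c for c in RESERVED_COLUMNS if c != "outcome"]
    ordered += [c for c in table.columns if c not in RESERVED_COLUMNS] + ["outcome"]
    table[ordered].to_csv(path, index=False, encoding="utf-8")


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        config = json.loads(text)
    else:
        config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return config


_DESIGN_KEYS = (
    "n_per_arm",
    "eff_experimental",
    "eff_control",
    "margin",
    "alpha_one_sided",
    "outcome_polarity",
)


def design_from_dict(config: dict) -> TrialDesign:
    """Build a :class:`TrialDesign` from a config mapping (or its ``design`` block)."""
    block = config.get("design", config)
    kwargs = {k: block[k] for k in _DESIGN_KEYS if k in block}
    missing = [k for k in ("n_per_arm", "eff_experimental", "eff_control", "margin") if k not in kwargs]
    if missing:
        raise ValidationError(f"design config is missing required keys {missing}")
    return TrialDesign(**kwargs)


def scenario_from_dict(config: dict) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a config mapping (or its ``scenario`` block)."""
    block = config.get("scenario", config)
    confounders = tuple(
        ConfounderSpec(
            name=c["name"],
            distribution=c.get("distribution", "uniform01"),
            q=c.get("q"),
            outcome_coefficient=c.get("outcome_coefficient", 0.0),
            adherence_coefficient_by_arm=c.get(
                "adherence_coefficient_by_arm", {"experimental": 0.0, "control": 0.0}
            ),
        )
        for c in block.get("confounders", ())
    )
    return ScenarioSpec(
        name=block.get("name", "custom"),
        nonadherent_arms=tuple(block.get("nonadherent_arms", ())),
        destination=block.get("destination"),
        alternative_efficacy=block.get("alternative_efficacy"),
        adherence_marginal_by_arm=block.get(
            "adherence_marginal_by_arm", {"experimental": 1.0, "control": 1.0}
        ),
        confounders=confounders,
    )


def write_json(payload: dict, path=None) -> str:
    """Serialise a result payload to JSON (and optionally a file)."""
    text = json.dumps(payload, indent=2, sort_keys=False, default=_jsonify)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialise {type(obj)!r}")
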