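import pandas as pd
import pytest
from hypothesis import settings

import nitrial as nt

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog_design():
    """Reference inferior-by-the-margin design (eff 0.5 vs 0.6, margin 0.1)."""
    return nt.catalog_design()


@pytest.fixture(scope="session")
def success_design():
    """Equal-efficacy success-polarity design used for power checks."""
    return nt.TrialDesign(n_per_arm=400, eff_experimental=0.6, eff_control=0.6, margin=0.1)


@pytest.fixture(scope="session")
def full_adherence():
    return nt.ScenarioSpec.full_adherence()


def make_table(outcomes_by_arm, received=None, confounders=None):
    """Small hand-built participant table.

    ``outcomes_by_arm``: {"experimental": [...], "control": [...]};
    ``received`` optionally overrides the received column (same layout).
    """
    rows = []
    i = 0
    for arm in ("experimental", "control"):
        for j, y in enumerate(outcomes_by_arm[arm]):
            rec = received[arm][j] if received else arm
            row = {"id": i, "assigned": arm, "received": rec, "outcome": y}
            if confounders:
                for name, values in confounders.items():
                    row[name] = values[arm][j]
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def crossover_cohort(catalog_design):
    """One simulated symmetric-crossover cohort, reused across tests."""
    scenario = nt.ScenarioSpec.symmetric_crossover(0.8)
    return nt.simulate_cohort(catalog_design, scenario, seed=123)
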