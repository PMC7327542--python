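"""Estimators: identities, hand-computed oracles, and decision rule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nitrial as nt
from conftest import make_table


@pytest.fixture(scope="module")
def toy_design():
    return nt.TrialDesign(n_per_arm=4, eff_experimental=0.5, eff_control=0.6, margin=0.1)


class TestNiDecision:
    def test_worked_example_interval_is_not_noninferior(self):
        # mortality difference 0.114 (0.032, 0.195) against a 10% margin
        assert not nt.ni_decision(0.114, 0.032, 0.195, margin=0.10, polarity="harm")

    def test_boundary_is_strict(self):
        assert not nt.ni_decision(0.0, -0.1, 0.1, margin=0.10, polarity="success")

    def test_tight_interval_claims(self):
        assert nt.ni_decision(0.0, -0.01, 0.01, margin=0.10)

    @given(
        est=st.floats(-0.5, 0.5),
        half=st.floats(0.001, 0.4),
        margin=st.floats(0.01, 0.3),
    )
    def test_harm_scale_is_negation_of_efficacy_scale(self, est, half, margin):
        lo, hi = est - half, est + half
        assert nt.ni_decision(est, lo, hi, margin, "success") == nt.ni_decision(
            -est, -hi, -lo, margin, "harm"
        )


class TestIttPp:
    def test_itt_arithmetic(self, toy_design):
        table = make_table({"experimental": [1, 1, 0, 0], "control": [1, 1, 1, 0]})
        res = nt.itt_estimate(table, toy_design)
        assert res.estimate == pytest.approx(-0.25)
        assert res.n_analyzed == 8

    def test_pp_restricts_to_adherent_rows(self, toy_design):
        received = {
            "experimental": ["experimental", "experimental", "experimental", "control"],
            "control": ["control", "control", "control", "experimental"],
        }
        table = make_table({"experimental": [1, 1, 0, 0], "control": [1, 1, 1, 0]}, received)
        res = nt.pp_estimate(table, toy_design)
        assert res.n_analyzed == 6
        assert res.estimate == pytest.approx(2 / 3 - 1.0)

    def test_pp_equals_itt_at_full_adherence(self, catalog_design, full_adherence):
        table = nt.simulate_cohort(catalog_design, full_adherence, seed=21)
        itt = nt.itt_estimate(table, catalog_design)
        pp = nt.pp_estimate(table, catalog_design)
        assert pp.estimate == itt.estimate
        assert pp.ci_low == itt.ci_low and pp.ci_high == itt.ci_high

    def test_pp_needs_two_adherent_per_arm(self, toy_design):
        received = {
            "experimental": ["control"] * 4,
            "control": ["control"] * 4,
        }
        table = make_table({"experimental": [1, 0, 1, 0], "control": [1, 1, 0, 0]}, received)
        with pytest.raises(nt.EstimationError):
            nt.pp_estimate(table, toy_design)

    def test_ci_width_shrinks_with_n(self, full_adherence):
        widths = []
        for n in (200, 400, 800, 1600):
            design = nt.TrialDesign(n, 0.5, 0.6, 0.1)
            table = nt.simulate_cohort(design, full_adherence, seed=31)
            res = nt.itt_estimate(table, design)
            widths.append(res.ci_high - res.ci_low)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    @given(
        kE=st.integers(0, 12),
        kC=st.integers(0, 12),
    )
    def test_estimate_bounded_and_ci_contains_it(self, kE, kC):
        design = nt.TrialDesign(12, 0.5, 0.5, 0.1)
        table = make_table(
            {"experimental": [1] * kE + [0] * (12 - kE), "control": [1] * kC + [0] * (12 - kC)}
        )
        res = nt.itt_estimate(table, design)
        assert -1.0 <= res.estimate <= 1.0
        assert res.ci_low <= res.estimate <= res.ci_high
        assert res.std_error > 0  # degenerate proportions get a positive variance


def _saturated_ipw_table():
    """Binary confounder, adherence varying by level: the per-arm logistic
    fit is saturated, so the weights are known empirical reciprocals."""
    received = {
        # E arm: sev=0 -> 3/4 adhere, sev=1 -> 2/4 adhere
        "experimental": ["experimental"] * 3 + ["control"]
        + ["experimental"] * 2 + ["control"] * 2,
        # C arm: sev=0 -> 3/4 adhere, sev=1 -> 2/4 adhere
        "control": ["control"] * 3 + ["experimental"]
        + ["control"] * 2 + ["experimental"] * 2,
    }
    outcomes = {"experimental": [1, 1, 0, 1, 1, 0, 0, 0], "control": [1, 1, 0, 1, 0, 0, 1, 1]}
    sev = {"experimental": [0, 0, 0, 0, 1, 1, 1, 1], "control": [0, 0, 0, 0, 1, 1, 1, 1]}
    return make_table(outcomes, received, confounders={"severity": sev})


class TestIpw:
    def test_hand_computed_hajek_estimate(self):
        # weights 1/0.75 at sev=0 and 1/0.5 at sev=1 in both arms:
        # E arm Hajek mean = (4/3 * 2 + 2 * 1) / 8 = 7/12
        # C arm Hajek mean = (4/3 * 2 + 2 * 0) / 8 = 1/3
        design = nt.TrialDesign(8, 0.5, 0.6, 0.1)
        est = nt.ipw_point_estimate(_saturated_ipw_table(), design)
        assert est == pytest.approx(7 / 12 - 1 / 3, abs=1e-6)

    def test_full_adherence_equals_pp_exactly(self, catalog_design):
        scenario = nt.ScenarioSpec.full_adherence(
            confounders=(nt.ConfounderSpec(name="severity", outcome_coefficient=0.2),)
        )
        table = nt.simulate_cohort(catalog_design, scenario, seed=13)
        res, diag = nt.ipw_estimate(table, catalog_design, bootstrap_reps=50, seed=1)
        assert res.estimate == nt.pp_estimate(table, catalog_design).estimate
        assert diag.min_weight == diag.max_weight == 1.0

    def test_constant_adherence_probability_weights_cancel(self):
        # adherence 2/4 at both confounder levels -> fitted probability is
        # constant, so the Hajek estimate equals the naive PP estimate
        received = {
            "experimental": ["experimental", "control"] * 4,
            "control": ["control", "experimental"] * 4,
        }
        outcomes = {"experimental": [1, 0, 1, 1, 0, 0, 1, 0], "control": [1, 1, 0, 0, 1, 0, 1, 0]}
        sev = {"experimental": [0, 0, 0, 0, 1, 1, 1, 1], "control": [0, 0, 0, 0, 1, 1, 1, 1]}
        table = make_table(outcomes, received, confounders={"severity": sev})
        design = nt.TrialDesign(8, 0.5, 0.6, 0.1)
        est = nt.ipw_point_estimate(table, design)
        assert est == pytest.approx(nt.pp_estimate(table, design).estimate, abs=1e-9)

    def test_requires_confounder_columns(self, catalog_design):
        table = nt.simulate_cohort(
            catalog_design, nt.ScenarioSpec.symmetric_crossover(0.8), seed=3
        )
        with pytest.raises(nt.EstimationError):
            nt.ipw_point_estimate(table, catalog_design)

    def test_bootstrap_ci_reproducible_under_seed(self, catalog_design):
        scenario = nt.scenario_from_catalog("both/crossover/confounded_increase", catalog_design)
        table = nt.simulate_cohort(catalog_design, scenario, seed=19)
        a, _ = nt.ipw_estimate(table, catalog_design, bootstrap_reps=100, seed=7)
        b, _ = nt.ipw_estimate(table, catalog_design, bootstrap_reps=100, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_diagnostics_effective_sample_size(self, catalog_design):
        scenario = nt.scenario_from_catalog("both/crossover/confounded_increase", catalog_design)
        table = nt.simulate_cohort(catalog_design, scenario, seed=19)
        res, diag = nt.ipw_estimate(table, catalog_design, bootstrap_reps=50, seed=7)
        assert diag.min_weight >= 1.0
        assert diag.effective_sample_size <= res.n_analyzed


class TestStandardisation:
    def test_single_stratum_equals_pp(self, catalog_design):
        scenario = nt.scenario_from_catalog("both/crossover/confounded_increase", catalog_design)
        table = nt.simulate_cohort(catalog_design, scenario, seed=23)
        table["one"] = 1
        res = nt.standardisation_estimate(
            table, catalog_design, {"one": None}, bootstrap_reps=50, seed=1
        )
        assert res.estimate == pytest.approx(nt.pp_estimate(table, catalog_design).estimate)

    def test_two_strata_hand_computation(self):
        # stratum 0: E 8/10, C 6/10; stratum 1: E 2/10, C 4/10; equal shares
        outcomes = {
            "experimental": [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8,
            "control": [1] * 6 + [0] * 4 + [1] * 4 + [0] * 6,
        }
        site = {"experimental": [0] * 10 + [1] * 10, "control": [0] * 10 + [1] * 10}
        table = make_table(outcomes, confounders={"site": site})
        design = nt.TrialDesign(20, 0.5, 0.5, 0.1)
        res = nt.standardisation_estimate(table, design, {"site": None}, bootstrap_reps=50, seed=2)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_empty_stratum_arm_cell_names_stratum(self):
        outcomes = {"experimental": [1, 0, 1, 0], "control": [1, 0, 1, 0]}
        received = {
            "experimental": ["experimental"] * 4,
            "control": ["control", "control", "experimental", "experimental"],
        }
        site = {"experimental": [0, 0, 1, 1], "control": [0, 0, 1, 1]}
        table = make_table(outcomes, received, confounders={"site": site})
        design = nt.TrialDesign(4, 0.5, 0.5, 0.1)
        with pytest.raises(nt.EstimationError, match="1"):
            nt.standardisation_estimate(table, design, {"site": None}, bootstrap_reps=10, seed=0)

    def test_agrees_with_ipw_on_binary_confounder_at_scale(self):
        # both are consistent under a single binary confounder, so the point
        # estimates agree within bootstrap uncertainty at n = 20,000
        doctor = nt.ConfounderSpec(
            name="doctor",
            distribution="bernoulli",
            q=0.5,
            outcome_coefficient=0.2,
            adherence_coefficient_by_arm={"experimental": 2.0, "control": -2.0},
        )
        design = nt.TrialDesign(10_000, 0.5, 0.6, 0.1)
        scenario = nt.ScenarioSpec(
            nonadherent_arms=nt.ARMS,
            destination="crossover",
            adherence_marginal_by_arm={"experimental": 0.8, "control": 0.8},
            confounders=(doctor,),
        )
        table = nt.simulate_cohort(design, scenario, seed=29)
        ipw, _ = nt.ipw_estimate(table, design, bootstrap_reps=200, seed=5)
        std = nt.standardisation_estimate(
            table, design, {"doctor": None}, bootstrap_reps=200, seed=6
        )
        tol = 3 * np.sqrt(ipw.std_error**2 + std.std_error**2)
        assert abs(ipw.estimate - std.estimate) < tol


class TestIv:
    def test_wald_ratio_arithmetic(self):
        # ITT difference 0.10, first stage 0.60 -> 0.166667
        received = {
            "experimental": ["experimental"] * 8 + ["control"] * 2,
            "control": ["experimental"] * 2 + ["control"] * 8,
        }
        outcomes = {"experimental": [1] * 7 + [0] * 3, "control": [1] * 6 + [0] * 4}
        table = make_table(outcomes, received)
        design = nt.TrialDesign(10, 0.5, 0.5, 0.1)
        res = nt.iv_estimate(table, design)
        assert res.estimate == pytest.approx(0.1 / 0.6, abs=1e-9)

    def test_full_adherence_equals_itt(self, catalog_design, full_adherence):
        table = nt.simulate_cohort(catalog_design, full_adherence, seed=37)
        iv = nt.iv_estimate(table, catalog_design)
        itt = nt.itt_estimate(table, catalog_design)
        assert iv.estimate == pytest.approx(itt.estimate, abs=1e-12)

    def test_alternative_destination_rejected(self, catalog_design):
        scenario = nt.scenario_from_catalog("both/inferior/nonconfounded", catalog_design)
        table = nt.simulate_cohort(catalog_design, scenario, seed=41)
        with pytest.raises(nt.EstimationError, match="alternative"):
            nt.iv_estimate(table, catalog_design)

    def test_weak_instrument_rejected(self):
        received = {
            "experimental": ["experimental", "control"] * 5,
            "control": ["experimental", "control"] * 5,
        }
        outcomes = {"experimental": [1, 0] * 5, "control": [1, 1, 0, 0, 1, 0, 1, 0, 1, 0]}
        table = make_table(outcomes, received)
        design = nt.TrialDesign(10, 0.5, 0.5, 0.1)
        with pytest.raises(nt.EstimationError, match="weak"):
            nt.iv_estimate(table, design)

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_iv_variance_exceeds_itt_under_nonadherence(self, catalog_design, seed):
        scenario = nt.ScenarioSpec.symmetric_crossover(0.8)
        table = nt.simulate_cohort(catalog_design, scenario, seed=seed)
        assert nt.iv_estimate(table, catalog_design).std_error > nt.itt_estimate(
            table, catalog_design
        ).std_error


class TestHarmPolarity:
    def test_harm_outcome_is_negated_efficacy(self):
        # identical tables, opposite polarity: estimates are negatives
        outcomes = {"experimental": [1, 1, 0, 0], "control": [1, 0, 0, 0]}
        table = make_table(outcomes)
        d_success = nt.TrialDesign(4, 0.5, 0.5, 0.1, outcome_polarity="success")
        d_harm = nt.TrialDesign(4, 0.5, 0.5, 0.1, outcome_polarity="harm")
        assert nt.itt_estimate(table, d_harm).estimate == pytest.approx(
            -nt.itt_estimate(table, d_success).estimate
        )
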