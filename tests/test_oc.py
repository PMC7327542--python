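"""Operating characteristics: oracle agreement, directions, determinism."""

import numpy as np
import pytest
from scipy import stats

import nitrial as nt


class TestClaimProbabilityOracle:
    def test_boundary_design_gives_nominal_alpha(self):
        # true difference exactly at -margin: probability is Phi(-z) = alpha
        p = nt.claim_probability_oracle(0.5, 0.6, 400, 0.1, 0.025)
        assert p == pytest.approx(0.025, abs=1e-12)

    def test_ten_percent_crossover_mixture(self):
        # mixture efficacies 0.51 / 0.59: evaluates to ~0.0823
        p = nt.claim_probability_oracle(0.51, 0.59, 400, 0.1, 0.025)
        se = np.sqrt((0.51 * 0.49 + 0.59 * 0.41) / 400)
        expected = stats.norm.cdf(0.02 / se - stats.norm.ppf(0.975))
        assert p == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(0.0823, abs=5e-4)

    def test_consistency_limit(self):
        assert nt.claim_probability_oracle(0.55, 0.6, 10**7, 0.1, 0.025) > 0.999

    def test_degenerate_efficacy_rejected(self):
        with pytest.raises(nt.ValidationError):
            nt.claim_probability_oracle(1.0, 0.6, 400, 0.1)


class TestExpectedEfficacies:
    def test_mixture_under_crossover(self, catalog_design):
        s = nt.ScenarioSpec.symmetric_crossover(0.9)
        eE, eC = nt.expected_arm_efficacies(catalog_design, s)
        assert (eE, eC) == (pytest.approx(0.51), pytest.approx(0.59))

    def test_pp_efficacies_unbiased_without_confounding(self, catalog_design):
        s = nt.ScenarioSpec.symmetric_crossover(0.9)
        eE, eC = nt.expected_pp_efficacies(catalog_design, s)
        assert (eE, eC) == (pytest.approx(0.5), pytest.approx(0.6))

    def test_pp_efficacies_shift_under_confounding(self, catalog_design):
        s = nt.scenario_from_catalog("both/crossover/confounded_increase", catalog_design)
        eE, eC = nt.expected_pp_efficacies(catalog_design, s)
        assert eE < 0.5 and eC > 0.6  # selection against the experimental arm


class TestRunOc:
    def test_zero_replicates_rejected(self, catalog_design, full_adherence):
        with pytest.raises(nt.ValidationError):
            nt.run_oc(catalog_design, full_adherence, ("ITT",), R=0, seed=1)

    def test_unknown_method_rejected(self, catalog_design, full_adherence):
        with pytest.raises(nt.ValidationError):
            nt.run_oc(catalog_design, full_adherence, ("G-EST",), R=10, seed=1)

    def test_deterministic_given_seed(self, catalog_design):
        s = nt.scenario_from_catalog("both/crossover/confounded_increase", catalog_design)
        a = nt.run_oc(catalog_design, s, ("ITT", "PP"), R=500, seed=99)
        b = nt.run_oc(catalog_design, s, ("ITT", "PP"), R=500, seed=99)
        assert [r.to_dict() for r in a] == [r.to_dict() for r in b]

    def test_method_results_independent_of_requested_set(self, catalog_design):
        s = nt.scenario_from_catalog("both/crossover/confounded_increase", catalog_design)
        both = nt.run_oc(catalog_design, s, ("ITT", "PP"), R=300, seed=5)
        only_pp = nt.run_oc(catalog_design, s, ("PP",), R=300, seed=5)
        assert both[1].to_dict() == only_pp[0].to_dict()

    def test_shortcut_matches_participant_level_engine(self, catalog_design):
        # binomial-shortcut ITT and participant-level ITT are two routes to
        # the same distribution: claim probabilities agree within MC noise
        s = nt.ScenarioSpec.symmetric_crossover(0.9)
        (shortcut,) = nt.run_oc(catalog_design, s, ("ITT",), R=4000, seed=2)
        # PP request forces the participant-level engine; at 0.9 adherence the
        # ITT estimates differ between engines only through the route taken
        engine = nt.oc._participant_level_itt_pp(
            catalog_design, s, 4000, np.random.default_rng(3)
        )
        est, claims = engine["ITT"]
        pooled = np.sqrt(
            shortcut.prob_claim_ni * (1 - shortcut.prob_claim_ni) / 4000
            + claims.mean() * (1 - claims.mean()) / 4000
        )
        assert abs(shortcut.prob_claim_ni - claims.mean()) < 3 * pooled

    def test_mc_matches_oracle_under_full_adherence(self, catalog_design, full_adherence):
        (res,) = nt.run_oc(catalog_design, full_adherence, ("ITT",), R=10_000, seed=11)
        assert res.prob_claim_ni == pytest.approx(0.025, abs=3 * res.mc_std_error)

    def test_monotone_in_nonadherence_at_the_boundary(self, catalog_design):
        # true difference at -margin: claim probability rises as adherence
        # falls from 1.0 to 0.5 under symmetric crossover
        probs, ses = [], []
        for a in (1.0, 0.9, 0.8, 0.7, 0.6, 0.5):
            s = nt.ScenarioSpec.symmetric_crossover(a)
            (res,) = nt.run_oc(catalog_design, s, ("ITT",), R=5000, seed=int(a * 100))
            probs.append(res.prob_claim_ni)
            ses.append(res.mc_std_error)
        for k in range(len(probs) - 1):
            tol = 3 * np.sqrt(ses[k] ** 2 + ses[k + 1] ** 2)
            assert probs[k + 1] >= probs[k] - tol


class TestDirectionMatrix:
    def test_baseline_against_itself_is_all_same(self, catalog_design):
        # a fully adherent "row" cannot differ from the fully adherent baseline
        import nitrial.oc as oc_mod

        (itt_a,) = nt.run_oc(catalog_design, nt.ScenarioSpec.full_adherence(), ("ITT",), R=4000, seed=1)
        (itt_b,) = nt.run_oc(catalog_design, nt.ScenarioSpec.full_adherence(), ("ITT",), R=4000, seed=2)
        assert oc_mod._probability_label(itt_a, itt_b) == "same"
        assert oc_mod._estimate_label(itt_a, itt_b) == "same"

    def test_selected_rows_reproduce_expected_directions(self, catalog_design):
        rows = ("both/crossover/nonconfounded", "experiment/inferior/nonconfounded")
        dm = nt.direction_matrix(catalog_design, row_ids=rows, R=4000, seed=31)
        labels = {(r.row_id, r.method): r.prob_label for r in dm.itertuples()}
        assert labels[("both/crossover/nonconfounded", "ITT")] == "higher"
        assert labels[("both/crossover/nonconfounded", "PP")] == "same"
        assert labels[("experiment/inferior/nonconfounded", "ITT")] == "lower"
        assert labels[("experiment/inferior/nonconfounded", "PP")] == "same"

    def test_unknown_row_rejected(self, catalog_design):
        with pytest.raises(nt.ValidationError):
            nt.direction_matrix(catalog_design, row_ids=("nope",), R=10, seed=1)
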