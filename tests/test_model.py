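import numpy as np
import pytest

from orthocea import (
    BaselineConsistencyError,
    DiscountSpec,
    EFFECT_LONG_TERM,
    LongTermAssumptions,
    NegativeCostError,
    OutcomeProbabilities,
    SimplexViolationError,
    TreatmentArm,
    ValidationError,
    enumerate_pathways,
    evaluate_arm,
    expected_cost,
    expected_effect,
    validate_arm,
)
from orthocea.model import Pathway

from conftest import joint_distribution_cost, random_arm


class TestValidation:
    def test_quad_helix_row_is_valid(self, quad_helix):
        assert validate_arm(quad_helix) is quad_helix

    def test_simplex_violation(self):
        arm = TreatmentArm("bad", 100, OutcomeProbabilities(0.5, 0.5, 0.1))
        with pytest.raises(SimplexViolationError):
            validate_arm(arm)

    def test_baseline_with_imperfect_success(self):
        arm = TreatmentArm(
            "base",
            2501,
            OutcomeProbabilities(0.9, 0.0, 0.1),
            LongTermAssumptions(1.0, 0.0),
            is_baseline=True,
        )
        with pytest.raises(BaselineConsistencyError):
            validate_arm(arm)

    def test_negative_cost(self):
        arm = TreatmentArm("bad", -1, OutcomeProbabilities(1.0, 0.0, 0.0))
        with pytest.raises(NegativeCostError):
            validate_arm(arm)


class TestEnumeration:
    def test_baseline_single_pathway(self, baseline, timing):
        pathways = enumerate_pathways(baseline, timing, fixed_cost=baseline.initial_cost)
        assert len(pathways) == 1
        (p,) = pathways
        assert (p.probability, p.cost, p.effect) == (1.0, 2501.0, 1)

    def test_quad_helix_pathway_probabilities(self, quad_helix, timing):
        pathways = enumerate_pathways(quad_helix, timing, fixed_cost=2501)
        assert len(pathways) == 5
        probs = [p.probability for p in pathways]
        assert probs == pytest.approx(
            [0.821 * 0.75, 0.821 * 0.25, 0.087 * 0.5, 0.087 * 0.5, 0.092]
        )
        assert sum(probs) == pytest.approx(1.0, abs=1e-9)

    def test_rescue_pathways_carry_discounted_fixed_cost(self, quad_helix, timing):
        pathways = enumerate_pathways(quad_helix, timing, fixed_cost=2501)
        rescue = 2501 * 1.03**-5
        by_label = {p.label: p for p in pathways}
        assert by_label["success->stable"].cost == pytest.approx(1254)
        assert by_label["partial->stable"].cost == pytest.approx(1254)
        for label in ("success->relapse->fixed", "partial->failure->fixed", "failure->fixed"):
            assert by_label[label].cost == pytest.approx(1254 + rescue)

    def test_certain_failure_keeps_zero_probability_pathways(self, timing):
        arm = TreatmentArm("fails", 500, OutcomeProbabilities(0.0, 0.0, 1.0))
        pathways = enumerate_pathways(arm, timing, fixed_cost=1000)
        assert [p.probability for p in pathways] == [0, 0, 0, 0, 1]

    def test_effect_indicator_tracks_initial_success(self, quad_helix, timing):
        pathways = enumerate_pathways(quad_helix, timing, fixed_cost=2501)
        assert [p.effect for p in pathways] == [1, 1, 0, 0, 0]

    def test_long_term_effect_definition(self, quad_helix, timing):
        pathways = enumerate_pathways(
            quad_helix, timing, fixed_cost=2501, effect_definition=EFFECT_LONG_TERM
        )
        assert [p.effect for p in pathways] == [1, 0, 1, 0, 0]
        assert expected_effect(pathways) == pytest.approx(0.821 * 0.75 + 0.087 * 0.5)


class TestExpectedValues:
    def test_single_certain_pathway(self):
        assert expected_cost([Pathway("fixed", 1.0, 2501, 1)]) == 2501

    def test_symmetric_mean(self):
        pathways = [Pathway("a", 0.5, 100, 0), Pathway("b", 0.5, 300, 1)]
        assert expected_cost(pathways) == pytest.approx(200.0)

    def test_quad_helix_undiscounted_hand_sum(self, quad_helix):
        """With discount factor 1 the expected cost is the hand sum
        1254 + 0.34075 * 2501 = 2106.21575."""
        undiscounted = DiscountSpec(annual_rate=0.0)
        pathways = enumerate_pathways(quad_helix, undiscounted, fixed_cost=2501)
        assert expected_cost(pathways) == pytest.approx(2106.21575, abs=1e-9)

    @pytest.mark.parametrize(
        "name, effect", [("quad_helix", 0.82), ("activator", 0.56), ("extra_oral_traction", 0.57)]
    )
    def test_expected_effect_is_initial_success_rate(self, arms, timing, name, effect):
        arm = next(a for a in arms if a.name == name)
        pathways = enumerate_pathways(arm, timing, fixed_cost=2501)
        assert round(expected_effect(pathways), 2) == effect

    def test_zero_success_arm_has_zero_effect(self, timing):
        arm = TreatmentArm("none", 100, OutcomeProbabilities(0.0, 0.4, 0.6))
        assert expected_effect(enumerate_pathways(arm, timing, 1000)) == 0

    def test_empty_pathway_list_rejected(self):
        with pytest.raises(ValidationError):
            expected_cost([])
        with pytest.raises(ValidationError):
            expected_effect([])

    def test_unnormalised_pathways_rejected(self):
        with pytest.raises(SimplexViolationError):
            expected_cost([Pathway("a", 0.6, 100, 0)])


class TestProperties:
    def test_matches_joint_distribution_oracle_on_random_arms(self, timing):
        rng = np.random.default_rng(42)
        for _ in range(200):
            arm = random_arm(rng)
            fixed_cost = float(rng.uniform(0, 4000))
            ours = expected_cost(enumerate_pathways(arm, timing, fixed_cost))
            oracle = joint_distribution_cost(arm, timing, fixed_cost)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_monotone_in_fixed_cost(self, quad_helix, timing):
        costs = [
            expected_cost(enumerate_pathways(quad_helix, timing, fc))
            for fc in (0, 500, 1000, 2501, 5000)
        ]
        assert costs == sorted(costs)
        assert costs[0] < costs[-1]

    def test_monotone_in_failure_probability(self, timing):
        """Moving mass from success to failure (renormalised on the simplex)
        never decreases expected cost."""
        costs = []
        for p_fail in np.linspace(0, 0.9, 10):
            arm = TreatmentArm(
                "sweep", 1000, OutcomeProbabilities(0.9 - p_fail, 0.1, p_fail)
            )
            costs.append(expected_cost(enumerate_pathways(arm, timing, 2501)))
        assert costs == sorted(costs)

    def test_baseline_invariant_to_timing(self, baseline):
        for spec in (DiscountSpec(), DiscountSpec(0.0, 8, 0, 0), DiscountSpec(0.1, 20, 8, 3)):
            outcome = evaluate_arm(baseline, spec, fixed_cost=9999)
            assert outcome.expected_cost == baseline.initial_cost
            assert outcome.expected_effect == 1.0

    def test_pathway_probabilities_conserved_on_random_arms(self, timing):
        rng = np.random.default_rng(7)
        for _ in range(100):
            pathways = enumerate_pathways(random_arm(rng), timing, 2501)
            assert sum(p.probability for p in pathways) == pytest.approx(1.0, abs=1e-9)

    def test_expected_cost_within_pathway_cost_hull(self, arms, timing):
        for arm in arms:
            pathways = enumerate_pathways(arm, timing, 2501)
            value = expected_cost(pathways)
            costs = [p.cost for p in pathways]
            assert min(costs) <= value <= max(costs)
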