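"""Superefficiency ranking scores and the two-stage infeasibility fallback."""

import numpy as np
import pytest

from healthdea import (
    PolicyRecord,
    PolicyTable,
    cook_score,
    efficiency,
    split_outcomes,
    superefficiency,
)


def super_scores(table, matrix):
    return {
        name: superefficiency(matrix, o)
        for o, name in enumerate(table.names)
    }


class TestFeasibleSuperefficiency:
    def test_published_scores_interventions(self, interventions_table, interventions_matrix):
        results = super_scores(interventions_table, interventions_matrix)
        assert round(results["Measles vaccine"].score, 2) == 2.43
        assert round(results["Pneumococcal vaccine"].score, 2) == 2.84
        assert round(results["Tuberculosis treatment"].score, 2) == 1.79
        assert round(results["Caesarean section"].score, 2) == 1.51
        for name in ("Measles vaccine", "Pneumococcal vaccine", "Tuberculosis treatment"):
            assert results[name].cook is None

    def test_published_scores_cancer(self, cancer_table, cancer_matrix):
        results = super_scores(cancer_table, cancer_matrix)
        assert round(results["Universal public finance"].score, 2) == 2.12
        assert round(results["Task-shifting"].score, 2) == 11.07
        assert results["Task-shifting"].cook is None

    def test_narrative_scores_surgery(self, surgery_table, surgery_matrix):
        """The surgical-access example ranks UPF, then task-shifting, highest
        among the feasible programs; the all-three combination goes through
        the fallback."""
        results = super_scores(surgery_table, surgery_matrix)
        expected = {
            "Universal public finance": 5.84,
            "Task-shifting": 5.38,
            "Universal public finance + task-shifting": 1.98,
            "Universal public finance + vouchers": 1.76,
            "Task-shifting + vouchers": 0.67,
        }
        for name, score in expected.items():
            assert round(results[name].score, 2) == score, name
            assert results[name].cook is None
        combo = results["Universal public finance + task-shifting + vouchers"]
        assert combo.cook is not None and combo.cook.triggered

    def test_single_policy_is_non_comparable(self):
        table = PolicyTable([PolicyRecord("only", [1.0], [1.0])], ["cost"], ["effect"])
        res = superefficiency(split_outcomes(table), 0)
        assert res.status == "non-comparable"
        assert res.score == float("inf")


class TestCookFallback:
    def test_trigger_set_identity_interventions(self, interventions_table, interventions_matrix):
        """Exactly the two policies holding an unreachable column maximum
        (diarrhoea: impoverishment averted; pneumonia: deaths averted) fall
        back."""
        triggered = {
            name
            for name, res in super_scores(interventions_table, interventions_matrix).items()
            if res.cook is not None
        }
        assert triggered == {"Diarrhoea treatment", "Pneumonia treatment"}

    def test_diarrhoea_components(self, interventions_table, interventions_matrix):
        o = interventions_table.names.index("Diarrhoea treatment")
        cook = cook_score(interventions_matrix, o)
        assert cook.s_star == pytest.approx(23000 / 40000, abs=1e-6)
        assert cook.theta_star == pytest.approx(31000 / 50000, abs=1e-6)
        assert round(cook.score, 2) == 2.36

    def test_pneumonia_components(self, interventions_table, interventions_matrix):
        o = interventions_table.names.index("Pneumonia treatment")
        cook = cook_score(interventions_matrix, o)
        assert cook.s_star == pytest.approx(3600 / 4100, abs=1e-6)
        assert cook.theta_star == pytest.approx(50000 / 31000, abs=1e-6)
        assert round(cook.score, 2) == 2.75

    def test_mobile_surgical_unit_components(self, cancer_table, cancer_matrix):
        o = cancer_table.names.index("Mobile surgical unit")
        cook = cook_score(cancer_matrix, o)
        assert cook.s_star == pytest.approx(33.6 / 42.8, abs=1e-6)
        assert cook.theta_star == pytest.approx(25009 / 7047, abs=1e-6)
        assert round(cook.score, 2) == 4.82

    def test_triggered_scores_exceed_one(self, interventions_table, interventions_matrix):
        for res in super_scores(interventions_table, interventions_matrix).values():
            if res.cook is not None:
                assert res.cook.s_star < 1
                assert res.score > 1


class TestConsistencyWithStandardScores:
    @pytest.mark.parametrize(
        "fixture", ["surgery", "interventions", "cancer"]
    )
    def test_standard_equals_min_super_one(self, fixture, request):
        """θ_standard = min(superefficiency, 1) for feasible programs; an
        infeasible program implies the policy is on the frontier (θ = 1)."""
        matrix = request.getfixturevalue(f"{fixture}_matrix")
        for o in range(matrix.n_policies):
            std = efficiency(matrix, o).theta
            sup = superefficiency(matrix, o)
            if sup.cook is None:
                assert std == pytest.approx(min(sup.score, 1.0), abs=1e-6)
            else:
                assert std == pytest.approx(1.0, abs=1e-6)

    def test_removing_a_policy_never_decreases_other_scores(self, surgery_table):
        full_matrix = split_outcomes(surgery_table)
        full = {
            name: superefficiency(full_matrix, o).score
            for o, name in enumerate(surgery_table.names)
        }
        for drop in range(len(surgery_table)):
            kept = [p for i, p in enumerate(surgery_table.policies) if i != drop]
            sub = PolicyTable(
                kept, surgery_table.input_names, surgery_table.outcome_names
            )
            matrix = split_outcomes(sub)
            for o, p in enumerate(kept):
                if len(kept) < 2:
                    continue
                assert superefficiency(matrix, o).score >= full[p.name] - 1e-6
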