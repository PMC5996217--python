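"""Cost-effectiveness dominance, extended dominance and ICERs."""

import pytest

from healthdea import (
    PolicyRecord,
    PolicyTable,
    cea_frontier,
    find_dominated,
    icers,
)


def make_table(rows, scales=None):
    return PolicyTable(
        [PolicyRecord(n, [c], [e]) for n, c, e in rows],
        ["cost"],
        ["effect"],
        column_scales=scales,
    )


class TestDominance:
    def test_caesarean_dominated_by_measles(self, interventions_table):
        result = find_dominated(interventions_table, "govt_expenditure", "deaths_averted")
        entry = result["Caesarean section"]
        assert entry.status == "dominated"
        assert entry.dominated_by == "Measles vaccine"

    def test_upf_dominated_by_task_shifting(self, cancer_table):
        result = find_dominated(cancer_table, "cost", "deaths_averted")
        entry = result["Universal public finance"]
        assert entry.status == "dominated"
        assert entry.dominated_by == "Task-shifting"

    def test_single_policy_on_frontier_vs_do_nothing(self):
        result = cea_frontier(make_table([("only", 100.0, 4.0)]), "cost", "effect")
        entry = result["only"]
        assert entry.status == "on-frontier"
        assert entry.comparator == "do-nothing"
        assert entry.icer == pytest.approx(25.0)

    def test_identical_pair_later_row_loses(self):
        result = find_dominated(
            make_table([("first", 10.0, 5.0), ("second", 10.0, 5.0)]), "cost", "effect"
        )
        assert result["first"].status == "on-frontier"
        assert result["second"].status == "dominated"
        assert result["second"].dominated_by == "first"


class TestIcers:
    def test_interventions_frontier_ratios(self, interventions_table):
        """ICERs in actual dollars: cost columns are published in thousands."""
        result = cea_frontier(interventions_table, "govt_expenditure", "deaths_averted")
        assert round(result["Measles vaccine"].icer) == 292
        assert round(result["Pneumococcal vaccine"].icer) == 1160
        assert round(result["Tuberculosis treatment"].icer) == 6333
        assert round(result["Pneumonia treatment"].icer) == 16067
        dominated = {e.name for e in result.entries if e.status != "on-frontier"}
        assert dominated == {
            "Rotavirus vaccine",
            "Diarrhoea treatment",
            "Malaria treatment",
            "Caesarean section",
            "Hypertension treatment",
        }

    def test_cancer_frontier_extended_dominance(self, cancer_table):
        """UPF + task-shifting survives pairwise dominance but is skipped by
        a cheaper ICER path through the mobile surgical unit."""
        result = cea_frontier(cancer_table, "cost", "deaths_averted")
        assert round(result["Task-shifting"].icer) == 94
        assert result["Universal public finance + task-shifting"].status == "extended-dominated"
        assert round(result["Mobile surgical unit"].icer) == 170
        assert result["Mobile surgical unit"].comparator == "Task-shifting"

    def test_previous_survivor_convention(self, cancer_table):
        result = cea_frontier(
            cancer_table, "cost", "deaths_averted", comparator="previous-survivor"
        )
        assert round(result["Mobile surgical unit"].icer) == 99
        assert (
            result["Mobile surgical unit"].comparator
            == "Universal public finance + task-shifting"
        )

    @pytest.mark.parametrize("fixture", ["interventions", "cancer", "surgery"])
    def test_frontier_icers_strictly_increase(self, fixture, request):
        table = request.getfixturevalue(f"{fixture}_table")
        cost = table.input_names[0]
        result = cea_frontier(table, cost, "deaths_averted")
        ratios = [e.icer for e in result.frontier if e.icer is not None]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_scaling_costs_and_effects_scales_icers(self, cancer_table):
        base = cea_frontier(cancer_table, "cost", "deaths_averted")
        scaled_table = PolicyTable(
            [
                PolicyRecord(
                    p.name,
                    [v * 7.0 for v in p.inputs],
                    [p.outcomes[0] * 3.0, *p.outcomes[1:]],
                )
                for p in cancer_table.policies
            ],
            cancer_table.input_names,
            cancer_table.outcome_names,
        )
        scaled = cea_frontier(scaled_table, "cost", "deaths_averted")
        for e_base, e_scaled in zip(base.entries, scaled.entries):
            assert e_base.status == e_scaled.status
            if e_base.icer is not None:
                assert e_scaled.icer == pytest.approx(e_base.icer * 7.0 / 3.0)

    def test_zero_effect_cheapest_survivor_flagged(self):
        result = cea_frontier(
            make_table([("futile", 10.0, 0.0), ("works", 20.0, 5.0)]), "cost", "effect"
        )
        assert result["futile"].icer is None
        assert result["futile"].comparator == "undefined"
        assert result["works"].icer is not None

    def test_icers_requires_explicit_call_order(self, cancer_table):
        partial = find_dominated(cancer_table, "cost", "deaths_averted")
        assert not partial.icers_applied
        assert icers(partial).icers_applied
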