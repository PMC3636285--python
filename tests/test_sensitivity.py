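"""One-way sweeps, tornado ordering and uniform-scaling scenarios."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from neocea import (
    CostParameter,
    OneWayResult,
    REFERENCE_STRATEGY_COSTS,
    compute_icer,
    effectiveness,
    expected_cost_per_patient,
    one_way_sweep,
    scenario_analysis,
    tornado_order,
    write_one_way_csv,
    write_scenario_csv,
)


class TestOneWaySweep:
    def test_range_endpoints_and_result_count(self, params, profiles, table_1mo):
        results = one_way_sweep(params, *profiles, table_1mo)
        assert len(results) == len(params)
        by_name = {r.parameter_name: r for r in results}
        for p in params:
            r = by_name[p.name]
            assert r.low_value == pytest.approx(p.unit_cost * 0.25)
            assert r.high_value == pytest.approx(p.unit_cost * 1.75)
            assert not r.clamped_low

    def test_zero_range_fraction_gives_zero_widths(self, params, profiles, table_1mo):
        flat = tuple(dataclasses.replace(p, range_fraction=0.0) for p in params)
        results = one_way_sweep(flat, *profiles, table_1mo)
        assert all(r.width == 0.0 for r in results)

    def test_single_arm_parameter_width_from_linearity(self, params, profiles, table_1mo):
        """The nurse salary enters only the intervention arm, so its ICER
        span equals that arm's component span divided by the (rounded)
        effectiveness difference."""
        profile_if, profile_hf = profiles
        results = {r.parameter_name: r for r in one_way_sweep(params, *profiles, table_1mo)}
        component = expected_cost_per_patient(profile_if, params).component(
            "nurse_hourly_salary"
        )
        assert expected_cost_per_patient(profile_hf, params).component(
            "nurse_hourly_salary"
        ).amount == 0.0
        delta_e = 0.102  # 0.944 - 0.842 at reporting precision
        span = 2 * 0.75 * component.amount / delta_e
        assert results["nurse_hourly_salary"].width == pytest.approx(span, abs=0.2)

    def test_low_end_clamped_at_zero_and_flagged(self, profiles, table_1mo, params):
        wide = (dataclasses.replace(params[0], range_fraction=1.5),) + params[1:]
        results = {r.parameter_name: r for r in one_way_sweep(wide, *profiles, table_1mo)}
        assert results[params[0].name].low_value == 0.0
        assert results[params[0].name].clamped_low

    def test_anchored_sweep_shifts_published_totals(self, params, profiles, table_1mo):
        """Anchored costs move by exactly the modelled component delta."""
        anchored = one_way_sweep(
            params, *profiles, table_1mo, anchor_costs=REFERENCE_STRATEGY_COSTS
        )
        # at the high end of the ED-visit cost, both components rise:
        # intervention by (5/90) x 0.75 x 127.2, control by (18/114) x 0.75 x 127.2
        result = {r.parameter_name: r for r in anchored}["ed_visit"]
        c_if = REFERENCE_STRATEGY_COSTS[0] + (5 / 90) * 0.75 * 127.2
        c_hf = REFERENCE_STRATEGY_COSTS[1] + (18 / 114) * 0.75 * 127.2
        e_if = effectiveness(table_1mo.c, table_1mo.n_intervention)
        e_hf = effectiveness(table_1mo.a, table_1mo.n_control)
        assert result.icer_at_high == compute_icer(c_if, c_hf, e_if, e_hf).icer


class TestTornadoOrder:
    def _result(self, name, width):
        return OneWayResult(name, 0.0, 1.0, 0.0, width, width)

    def test_sorts_by_width_descending(self):
        results = [self._result(n, w) for n, w in [("a", 5.0), ("b", 9.0), ("c", 1.0)]]
        assert [r.width for r in tornado_order(results)] == [9.0, 5.0, 1.0]

    def test_ties_break_alphabetically(self):
        results = [self._result(n, 3.0) for n in ["zeta", "alpha", "mid"]]
        assert [r.parameter_name for r in tornado_order(results)] == [
            "alpha", "mid", "zeta",
        ]

    def test_empty_input_gives_empty_output(self):
        assert tornado_order([]) == ()

    @settings(max_examples=50, derandomize=True)
    @given(widths=st.lists(st.floats(0, 100), max_size=8))
    def test_is_a_permutation(self, widths):
        results = [self._result(f"p{i}", w) for i, w in enumerate(widths)]
        ordered = tornado_order(results)
        assert sorted(ordered, key=lambda r: r.parameter_name) == sorted(
            results, key=lambda r: r.parameter_name
        )

    def test_reference_sweep_has_a_total_order(self, params, profiles, table_1mo):
        ordered = tornado_order(one_way_sweep(params, *profiles, table_1mo))
        assert [r.width for r in ordered] == sorted(
            (r.width for r in ordered), reverse=True
        )


class TestScenarioAnalysis:
    def test_identity_factor_reproduces_base_case(self, params, profiles, table_1mo):
        scenario = scenario_analysis(params, 1.0, *profiles, table_1mo)
        e_if = effectiveness(table_1mo.c, table_1mo.n_intervention)
        e_hf = effectiveness(table_1mo.a, table_1mo.n_control)
        c_if = expected_cost_per_patient(profiles[0], params).total
        c_hf = expected_cost_per_patient(profiles[1], params).total
        assert scenario.cea == compute_icer(c_if, c_hf, e_if, e_hf)

    def test_upscaled_unit_costs_match_printed_column(self, params, profiles, table_1mo):
        scenario = scenario_analysis(params, 1.75, *profiles, table_1mo)
        from neocea import round_half_away

        scaled = dict(scenario.scaled_parameters)
        assert {name: round_half_away(cost, 1) for name, cost in scaled.items()} == {
            "ed_visit": 222.6,
            "hospital_visit": 149.5,
            "nurse_hourly_salary": 57.8,
            "transport": 52.5,
            "missed_work_hour": 26.3,
        }

    @pytest.mark.parametrize("factor", [0.4375, 1.75, 3.0])
    def test_icer_scales_with_factor_under_anchor(self, params, profiles, table_1mo, factor):
        base = scenario_analysis(
            params, 1.0, *profiles, table_1mo, anchor_costs=REFERENCE_STRATEGY_COSTS
        )
        scaled = scenario_analysis(
            params, factor, *profiles, table_1mo, anchor_costs=REFERENCE_STRATEGY_COSTS
        )
        assert scaled.icer == pytest.approx(factor * base.icer, abs=0.5)

    @pytest.mark.parametrize("factor", [0.0, -2.0])
    def test_nonpositive_factor_rejected(self, params, profiles, table_1mo, factor):
        with pytest.raises(ValueError):
            scenario_analysis(params, factor, *profiles, table_1mo)

    def test_scaled_parameters_invariant(self, params, profiles, table_1mo):
        scenario = scenario_analysis(params, 2.5, *profiles, table_1mo)
        base = {p.name: p.unit_cost for p in params}
        for name, cost in scenario.scaled_parameters:
            assert cost == pytest.approx(2.5 * base[name], abs=1e-9)


class TestCsvWriters:
    def test_headers_and_rows(self, tmp_path, params, profiles, table_1mo):
        results = one_way_sweep(params, *profiles, table_1mo)
        one_way_path = tmp_path / "one_way.csv"
        write_one_way_csv(results, one_way_path)
        header = one_way_path.read_text().splitlines()[0]
        assert header == "parameter,low,high,icer_low,icer_high,width"

        scenario_path = tmp_path / "scenario.csv"
        write_scenario_csv(
            [scenario_analysis(params, 1.75, *profiles, table_1mo)], scenario_path
        )
        lines = scenario_path.read_text().splitlines()
        assert lines[0] == "factor,cost_if,cost_hf,icer"
        assert lines[1].startswith("1.75,")
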