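import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifeyears import (
    AnalysisConfig,
    ApproximateDate,
    GeneratorSpec,
    LifeYearsModel,
    ScenarioTable,
    SubgroupSpec,
    TherapyScenario,
    ValidationFailure,
    acceleration_scenario,
    apply_treated_fraction,
    effective_duration,
    evaluate_portfolio,
    generate_registry,
    life_years_lost,
    life_years_per_acceleration_year,
    round_half_away,
)
from lifeyears.dates import duration_years

nonneg = st.floats(min_value=0, max_value=1e7, allow_nan=False, allow_infinity=False)
scale = st.floats(min_value=0, max_value=100, allow_nan=False, allow_infinity=False)


class TestPrimitives:
    @pytest.mark.parametrize(
        "gain,eligible,expected",
        [
            (0.17, 1_351_418, 229_741),  # erlotinib, worldwide
            (0.12, 693_900, 83_268),     # regorafenib, worldwide
            (0.0, 500_000, 0),
        ],
    )
    def test_per_year_examples(self, gain, eligible, expected):
        assert round_half_away(
            life_years_per_acceleration_year(gain, eligible)
        ) == expected

    def test_per_year_domain(self):
        with pytest.raises(ValueError):
            life_years_per_acceleration_year(-0.1, 100)
        with pytest.raises(ValueError):
            life_years_per_acceleration_year(0.1, -100)

    def test_life_years_lost_examples(self):
        # bevacizumab nonsquamous NSCLC, worldwide
        assert round_half_away(life_years_lost(162_170, 11.4)) == 1_848_738
        # erlotinib: the rounded-input product is 220,788, within 0.01% of
        # the published 220,790
        got = round_half_away(life_years_lost(25_975, 8.5))
        assert got == 220_788
        assert abs(got - 220_790) / 220_790 <= 1e-4
        assert life_years_lost(0, 12.3) == 0

    def test_scenario_examples(self):
        # the published worldwide extremes of the 5-year counterfactual
        assert round_half_away(acceleration_scenario(7_590, 6.8, 5)) == 13_662
        assert round_half_away(acceleration_scenario(263_682, 23.3, 5)) == 4_825_381
        assert acceleration_scenario(1000, 7.5, 7.5) == 0
        assert acceleration_scenario(1000, 7.5, 9.0) == 0  # clamps, not negative

    @given(L=nonneg, T=st.floats(0, 50, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_scenario_at_target_zero_equals_lost(self, L, T):
        assert acceleration_scenario(L, T, 0) == life_years_lost(L, T)

    def test_treated_fraction(self):
        assert apply_treated_fraction(123.0, 1.0) == 123.0
        assert apply_treated_fraction(123.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            apply_treated_fraction(1.0, 1.5)
        with pytest.raises(ValueError):
            apply_treated_fraction(1.0, -0.1)

    @given(gain=nonneg, E=nonneg, a=scale)
    @settings(max_examples=200, deadline=None)
    def test_bilinearity(self, gain, E, a):
        L = life_years_per_acceleration_year
        assert L(a * gain, E) == pytest.approx(a * L(gain, E), rel=1e-12, abs=1e-9)
        assert L(gain, a * E) == pytest.approx(a * L(gain, E), rel=1e-12, abs=1e-9)

    @given(L=nonneg, T=st.floats(0, 50, allow_nan=False),
           t1=st.floats(0, 60, allow_nan=False), t2=st.floats(0, 60, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_scenario_monotone_and_bounded(self, L, T, t1, t2):
        lo, hi = sorted((t1, t2))
        s_lo, s_hi = (acceleration_scenario(L, T, t) for t in (lo, hi))
        assert s_hi <= s_lo  # nonincreasing in the target interval
        assert s_lo <= life_years_lost(L, T)  # saved never exceeds lost


class TestAnalysisConfig:
    def test_defaults(self):
        cfg = AnalysisConfig()
        assert cfg.target_years == 5.0
        assert cfg.treated_fraction == 1.0
        assert cfg.regions == ("north_america", "worldwide")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"treated_fraction": 1.5},
            {"treated_fraction": -0.1},
            {"target_years": -1},
            {"regions": ()},
            {"regions": ("europe",)},
            {"median_convention": "weird"},
            {"rounding": "nearest"},
        ],
    )
    def test_invariants(self, kwargs):
        with pytest.raises(ValueError):
            AnalysisConfig(**kwargs)

    def test_from_mapping_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown config key"):
            AnalysisConfig.from_mapping({"target": 5})

    def test_from_mapping_defaults_and_overrides(self):
        cfg = AnalysisConfig.from_mapping({"target_years": 7, "regions": ["worldwide"]})
        assert cfg.target_years == 7
        assert cfg.regions == ("worldwide",)
        assert cfg.treated_fraction == 1.0


def naive_row(scenario, target_years, fraction, region):
    """Independent straight-line recomputation of one row's metrics."""
    if scenario.duration_override_years is not None:
        T = scenario.duration_override_years
    else:
        T = duration_years(scenario.discovery, scenario.approval)
    E = scenario.eligible_na if region == "north_america" else scenario.eligible_ww
    L = scenario.survival_gain_years * E * fraction
    return L, T, L * T, L * (T - target_years if T > target_years else 0.0)


class TestEvaluatePortfolio:
    def test_row_count_and_order(self, paper_table, paper_results):
        assert paper_results.n_scenarios == 27
        assert [r.key for r in paper_results.rows] == [s.key for s in paper_table]

    def test_refuses_invalid_registry(self):
        bad = TherapyScenario(
            drug="d", site="s", subgroup=SubgroupSpec("s", "all", 1.0),
            survival_gain_years=0.2, eligible_na=10, eligible_ww=100,
            discovery=ApproximateDate(2010, 1), approval=ApproximateDate(2001, 1),
        )
        with pytest.raises(ValidationFailure) as exc:
            evaluate_portfolio(ScenarioTable(rows=[bad]))
        assert exc.value.report.has_errors

    def test_empty_region_config_rejected(self):
        with pytest.raises(ValueError, match="no regions"):
            AnalysisConfig(regions=())

    @pytest.mark.parametrize("seed,n", [(3, 200), (11, 1000)])
    def test_oracle_equivalence_on_synthetic_registries(self, seed, n):
        """Every RowResult equals an independent naive recomputation."""
        table = generate_registry(GeneratorSpec(n_rows=n, seed=seed))
        cfg = AnalysisConfig(target_years=5, treated_fraction=0.7)
        res = evaluate_portfolio(table, cfg)
        for s, r in zip(table, res.rows):
            for region in cfg.regions:
                L, T, lyl, saved = naive_row(s, 5, 0.7, region)
                assert r.duration_years == pytest.approx(T, rel=1e-12)
                assert r.per_year[region] == pytest.approx(L, rel=1e-12)
                assert r.life_years_lost[region] == pytest.approx(lyl, rel=1e-12)
                assert r.scenario_saved[region] == pytest.approx(saved, rel=1e-12)

    def test_summaries_recomputable_from_rows(self, paper_results):
        from lifeyears import summarize

        for (metric, region), s in paper_results.summaries.items():
            if metric == "survival_gain":
                continue
            values = paper_results.metric(
                "duration" if metric == "duration" else metric,
                region if region != "all" else "worldwide",
            )
            assert summarize(values) == s

    def test_uptake_linearity(self, paper_table):
        full = evaluate_portfolio(paper_table, AnalysisConfig(treated_fraction=1.0))
        tenth = evaluate_portfolio(paper_table, AnalysisConfig(treated_fraction=0.1))
        for rf, rt in zip(full.rows, tenth.rows):
            for region in ("north_america", "worldwide"):
                assert rt.per_year[region] == pytest.approx(
                    0.1 * rf.per_year[region], rel=1e-12)
                assert rt.scenario_saved[region] == pytest.approx(
                    0.1 * rf.scenario_saved[region], rel=1e-12)

    def test_saved_bounded_by_lost_everywhere(self, paper_results):
        for r in paper_results.rows:
            for region in ("north_america", "worldwide"):
                assert r.scenario_saved[region] <= r.life_years_lost[region]
                assert math.isclose(
                    r.life_years_lost[region],
                    r.per_year[region] * r.duration_years,
                    rel_tol=1e-12,
                )

    def test_presentation_rounding_mode(self, paper_table):
        res = evaluate_portfolio(
            paper_table, AnalysisConfig(rounding="presentation-integer")
        )
        first = res.rows[0]
        assert first.per_year["worldwide"] == 229_741
        assert isinstance(first.per_year["worldwide"], int)

    def test_override_takes_precedence_over_dates(self):
        s = TherapyScenario(
            drug="d", site="s", subgroup=SubgroupSpec("s", "all", 1.0),
            survival_gain_years=0.2, eligible_na=10, eligible_ww=100,
            discovery=ApproximateDate(2000, 1), approval=ApproximateDate(2010, 1),
            duration_override_years=9.9,
        )
        assert effective_duration(s) == 9.9

    def test_from_dataframe_matches_registry(self, paper_table):
        model = LifeYearsModel.from_dataframe(paper_table.to_dataframe())
        assert model.table == paper_table
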