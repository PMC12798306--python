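"""Tax-benefit calculator: scale, UC, Basic Income interactions, Gini."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bisim import taxben
from bisim.taxben import (
    TaxBenParams, SchemeDefinition, Person, Household,
    equivalence_factor, baseline_net_income, apply_scheme,
    marginal_deduction_rate, weighted_gini, distributional_summary,
    compute_population, scheme_starter, scheme_intermediate, scheme_mis,
    WEEKS_PER_MONTH,
)
from bisim.synthetic import PopulationConfig, gen_cross_section


@pytest.mark.parametrize("ages,expected", [
    ([40], 1.0),
    ([40, 38, 8], 1.8),
    ([70, 68], 1.5),
    ([30, 15], 1.5),          # 14+ counts as an additional adult
    ([30, 5, 5, 5], 1.9),
])
def test_oecd_equivalence_scale(ages, expected):
    assert equivalence_factor(ages) == pytest.approx(expected)


def test_empty_household_rejected():
    with pytest.raises(ValueError):
        equivalence_factor([])


def test_uc_floor_for_zero_income_single_adult():
    params = TaxBenParams(uc_standard_allowances={"single": 400.0, "couple": 600.0})
    hh = Household(0, [Person(age=30)])
    assert baseline_net_income(hh, params) == pytest.approx(400.0)


def test_taper_exhausts_uc_at_high_earnings():
    params = TaxBenParams()
    hh = Household(0, [Person(age=40, earned_income=10_000.0)])
    net = baseline_net_income(hh, params)
    # remove earnings: only UC would remain; at high earnings UC must be 0
    res = taxben._net_income(hh, params, scheme=None, reform_tax=False)
    assert res["uc"] == 0.0
    assert net < 10_000.0  # taxes bite


def test_negative_income_rejected():
    with pytest.raises(ValueError, match="negative"):
        baseline_net_income(Household(0, [Person(30, earned_income=-1.0)]),
                            TaxBenParams())


def test_starter_scheme_household_payment():
    # couple (40, 35) + child aged 8 at £75+£75+£50 per week
    scheme = scheme_starter()
    hh = Household(0, [Person(40, 2500.0), Person(35, 1200.0), Person(8)])
    r = apply_scheme(hh, scheme, TaxBenParams())
    assert r.bi_received == pytest.approx(200.0 * WEEKS_PER_MONTH)


def test_pensioner_gains_bi_minus_state_pension():
    # single pensioner: £205/week BI replaces a £200/week State Pension
    params = TaxBenParams(state_pension=200.0)
    hh = Household(0, [Person(70)])
    r = apply_scheme(hh, scheme_starter(), params)
    gain = r.net_income_reform - r.net_income_base
    assert gain == pytest.approx(5.0 * WEEKS_PER_MONTH)


def test_mis_scheme_reduces_uc_pound_for_pound():
    # no disregard: UC falls by £1 for each £1 of BI until the floor at 0
    params = TaxBenParams(uc_standard_allowances={"single": 600.0, "couple": 900.0})
    hh = Household(0, [Person(30)])
    base = taxben._net_income(hh, params, None, False)
    assert base["uc"] == pytest.approx(600.0)
    small_bi = SchemeDefinition("tiny", 0.0, 23.0769230769, 0.0,
                                frozenset(), uc_bi_disregard=0.0)  # ~£100/month
    r = taxben._net_income(hh, params, small_bi, True)
    assert r["uc"] == pytest.approx(600.0 - r["bi"])
    big = scheme_mis()
    r3 = taxben._net_income(hh, params, big, True)
    assert r3["uc"] == 0.0


def test_uc_households_gain_at_least_the_disregard():
    # for baseline UC recipients, reform gain >= the BI disregard (schemes 1-2)
    cfg = PopulationConfig(n_households=400, seed=17)
    households, persons = gen_cross_section(cfg)
    params = TaxBenParams()
    for scheme in (scheme_starter(), scheme_intermediate()):
        for hh in taxben.households_from_frames(households, persons):
            base = taxben._net_income(hh, params, None, False)
            if base["uc"] <= 0:
                continue
            r = apply_scheme(hh, scheme, params)
            gain = r.net_income_reform - r.net_income_base
            assert gain >= scheme.uc_bi_disregard - 1e-9


def test_null_reform_reproduces_baseline_exactly():
    cfg = PopulationConfig(n_households=150, seed=23)
    households, persons = gen_cross_section(cfg)
    null = SchemeDefinition("null", 0.0, 0.0, 0.0, frozenset(), 0.0)
    res = compute_population(households, persons, null, TaxBenParams())
    assert np.allclose(res["net_income_base"], res["net_income_reform"])
    assert np.allclose(res["bi_received"], 0.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    earned=st.floats(0, 8000),
    ages=st.lists(st.integers(0, 85), min_size=1, max_size=5),
    lo=st.floats(0, 100), step=st.floats(0, 100),
)
def test_reform_income_monotone_in_bi_rates(earned, ages, lo, step):
    params = TaxBenParams()
    members = [Person(a, earned if i == 0 and a >= 18 else 0.0)
               for i, a in enumerate(ages)]
    hh = Household(0, members)
    s1 = SchemeDefinition("a", lo, lo, lo, frozenset({"child_benefit",
                                                      "state_pension"}), 10.0)
    s2 = SchemeDefinition("b", lo + step, lo + step, lo + step,
                          frozenset({"child_benefit", "state_pension"}), 10.0)
    r1 = apply_scheme(hh, s1, params)
    r2 = apply_scheme(hh, s2, params)
    assert r2.net_income_reform >= r1.net_income_reform - 1e-9


def test_equiv_income_identity():
    cfg = PopulationConfig(n_households=100, seed=29)
    households, persons = gen_cross_section(cfg)
    res = compute_population(households, persons, scheme_starter(), TaxBenParams())
    assert np.allclose(res["net_equiv_base"],
                       res["net_income_base"] / res["equiv_factor"])
    assert (res["equiv_factor"] >= 1.0).all()


def test_unknown_replaced_benefit_rejected():
    with pytest.raises(ValueError, match="unknown"):
        SchemeDefinition("bad", 0, 0, 0, frozenset({"housing_benefit"}), 0)


def test_mdr_zero_below_all_thresholds():
    params = TaxBenParams(uc_standard_allowances={"single": 0.0, "couple": 0.0})
    hh = Household(0, [Person(30, earned_income=200.0)])
    assert marginal_deduction_rate(hh, None, params, delta=50.0) == pytest.approx(0.0)


def test_mdr_equals_taper_on_uc_only():
    # earnings above the work allowance but below tax/NI thresholds
    params = TaxBenParams(uc_standard_allowances={"single": 800.0, "couple": 900.0})
    hh = Household(0, [Person(30, earned_income=600.0)])
    assert marginal_deduction_rate(hh, None, params, delta=50.0) == \
        pytest.approx(0.55)


def test_mdr_requires_an_earner():
    with pytest.raises(ValueError, match="earner"):
        marginal_deduction_rate(Household(0, [Person(30)]), None, TaxBenParams())


def test_funding_adjustment_raises_taxes_under_reform():
    params = TaxBenParams(funding_adjustment=5.0)
    hh = Household(0, [Person(40, earned_income=4000.0)])
    r = apply_scheme(hh, scheme_starter(), params)
    assert r.taxes_delta > 0


def test_partial_takeup_is_seeded_and_reduces_aggregate_uc():
    cfg = PopulationConfig(n_households=300, seed=31)
    households, persons = gen_cross_section(cfg)
    full = TaxBenParams(uc_takeup=1.0)
    partial = TaxBenParams(uc_takeup=0.5, uc_takeup_seed=1)
    res_full = compute_population(households, persons, scheme_starter(), full)
    res_half = compute_population(households, persons, scheme_starter(), partial)
    res_half2 = compute_population(households, persons, scheme_starter(), partial)
    assert res_half["net_income_base"].sum() < res_full["net_income_base"].sum()
    assert res_half.equals(res_half2)


def test_gini_zero_for_equal_incomes():
    assert weighted_gini([5.0] * 10, [1.0] * 10) == pytest.approx(0.0, abs=1e-12)


def test_gini_half_for_all_or_nothing_pair():
    assert weighted_gini([0.0, 7.0], [1.0, 1.0]) == pytest.approx(0.5)


def test_gini_matches_pairwise_oracle():
    rng = np.random.default_rng(0)
    x = rng.lognormal(7.0, 0.8, 200)
    w = rng.uniform(0.5, 2.0, 200)
    # brute-force mean absolute difference
    diff = np.abs(x[:, None] - x[None, :])
    oracle = (w[:, None] * w[None, :] * diff).sum() / (2 * w.sum()**2
                                                       * np.average(x, weights=w))
    assert weighted_gini(x, w) == pytest.approx(oracle, abs=1e-12)


def test_distributional_summary_contents(cross_section_small):
    households, persons = cross_section_small
    res = compute_population(households, persons, scheme_starter(), TaxBenParams())
    rep = distributional_summary(res, persons)
    assert 0.0 <= rep["gini_base"] < 1.0
    assert rep["gini_reform"] < rep["gini_base"]       # BI is redistributive
    # against the *baseline* poverty line, nobody is pushed into poverty
    # (the relative line itself moves with the median, so the headline rate
    # can rise even though every household gains)
    w = res["weight"].to_numpy()
    line = rep["poverty_line_base"]
    anchored_base = w[res["net_equiv_base"] < line].sum() / w.sum()
    anchored_reform = w[res["net_equiv_reform"] < line].sum() / w.sum()
    assert anchored_reform <= anchored_base + 1e-9
    assert 0.0 <= rep["poverty_rate_reform"] <= 1.0
    assert len(rep["quintiles"]) == 5
    assert rep["net_exchequer_cost_annual"] > 0
    total_weight = res["weight"].sum()
    assert sum(rep["winners_losers"].values()) == pytest.approx(total_weight)


def test_distributional_summary_rejects_bad_weights(cross_section_small):
    households, persons = cross_section_small
    res = compute_population(households, persons, scheme_starter(), TaxBenParams())
    res.loc[0, "weight"] = 0.0
    with pytest.raises(ValueError, match="weights"):
        distributional_summary(res)
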