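"""Score-change forecasts, baseline imputation and case counting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from bisim.health_impact import (
    HealthThresholds, CaseChangeReport, impute_baseline_scores,
    linear_predictor, predict_score_change, count_cases, cases_prevented,
    build_states,
)
from bisim.panel_model import (ModelSpec, CoefficientSet, CoefficientBundle,
                               fit_bundle)
from bisim.synthetic import (PopulationConfig, TrueHealthModel, gen_panel,
                             default_panel_mix)


def _toy_coeffs(beta_between=2.0, outcome="mcs", const=35.0):
    return CoefficientSet(
        outcome=outcome, income_transform="log",
        beta_within=1.0, beta_between=beta_between,
        control_coefficients={"const": const},
        design_info={"categorical": {}, "numeric": []},
    )


def _toy_bundle(bb_mcs=2.0, bb_pcs=1.5):
    return CoefficientBundle(mcs=_toy_coeffs(bb_mcs, "mcs"),
                             pcs=_toy_coeffs(bb_pcs, "pcs", const=38.0))


@pytest.fixture()
def population():
    rng = np.random.default_rng(5)
    n = 400
    return pd.DataFrame({
        "person_id": np.arange(n),
        "net_equiv_income": rng.lognormal(7.6, 0.5, n),
        "weight": np.full(n, 1000.0),
    })


def test_case_threshold_semantics():
    thr = HealthThresholds()
    w = np.ones(3)
    assert count_cases([45.6, 45.7, 40.0], thr.mcs_case_max, w) == 2.0
    assert count_cases([50.0, 50.1, 70.0], thr.pcs_case_max, w) == 1.0


def test_thresholds_validated():
    with pytest.raises(ValueError):
        HealthThresholds(mcs_case_max=0.0)


def test_zero_residual_sd_returns_linear_predictor(population):
    cs = _toy_coeffs()
    scores = impute_baseline_scores(population, cs, residual_sd=0.0, seed=1)
    pred = linear_predictor(population, cs)
    assert np.allclose(scores, np.clip(pred, 0, 100))


def test_imputation_is_seed_deterministic(population):
    cs = _toy_coeffs()
    a = impute_baseline_scores(population, cs, residual_sd=8.0, seed=3)
    b = impute_baseline_scores(population, cs, residual_sd=8.0, seed=3)
    c = impute_baseline_scores(population, cs, residual_sd=8.0, seed=4)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_missing_covariate_error_names_it(population):
    cs = _toy_coeffs()
    cs.design_info = {"categorical": {"region": ["England", "Wales"]},
                      "numeric": []}
    cs.control_coefficients["region[Wales]"] = 0.5
    with pytest.raises(KeyError, match="region"):
        impute_baseline_scores(population, cs, residual_sd=0.0, seed=0)


def test_case_share_matches_normal_cdf_oracle(population):
    # share(score <= thr) ~ mean_i Phi((thr - pred_i)/sd)
    cs = _toy_coeffs(const=33.0)
    sd = 6.0
    thr = 45.6
    scores = impute_baseline_scores(population, cs, residual_sd=sd, seed=11)
    share = (scores <= thr).mean()
    pred = linear_predictor(population, cs)
    expect = norm.cdf((thr - pred) / sd).mean()
    se = np.sqrt(expect * (1 - expect) / len(population))
    assert abs(share - expect) < 4 * se


def test_no_income_change_means_no_score_change():
    bundle = _toy_bundle()
    inc = np.array([500.0, 2000.0])
    d = predict_score_change(inc, inc, bundle)
    assert np.allclose(d["delta_mcs"], 0.0) and np.allclose(d["delta_pcs"], 0.0)


def test_income_doubling_arithmetic():
    bundle = _toy_bundle(bb_mcs=2.0)
    d = predict_score_change([1000.0], [2000.0], bundle)
    assert d["delta_mcs"][0] == pytest.approx(2.0 * np.log(2), rel=1e-12)


def test_score_change_sign_follows_income_direction():
    bundle = _toy_bundle()
    d = predict_score_change([800.0], [900.0], bundle)
    assert d["delta_mcs"][0] > 0 and d["delta_pcs"][0] > 0


def test_transform_mismatch_rejected():
    bundle = _toy_bundle()
    with pytest.raises(ValueError, match="transform"):
        predict_score_change([1.0], [2.0], bundle, transform="linear")


def _states(base_mcs, delta_mcs, weights, base_pcs=None, delta_pcs=None):
    n = len(base_mcs)
    base_pcs = base_pcs if base_pcs is not None else np.full(n, 55.0)
    delta_pcs = delta_pcs if delta_pcs is not None else np.zeros(n)
    df = pd.DataFrame({
        "person_id": np.arange(n), "scheme": "s",
        "income_base": np.full(n, 1000.0),
        "income_reform": np.full(n, 1100.0),
        "mcs_base": base_mcs, "pcs_base": base_pcs,
        "delta_mcs": delta_mcs, "delta_pcs": delta_pcs,
        "weight": weights, "income_transform": "log",
    })
    df["mcs_reform"] = df["mcs_base"] + df["delta_mcs"]
    df["pcs_reform"] = df["pcs_base"] + df["delta_pcs"]
    return df


def test_null_reform_prevents_no_cases():
    st = _states(np.array([40.0, 50.0]), np.zeros(2), np.ones(2))
    rep = cases_prevented(st, HealthThresholds(), "mcs")
    assert rep.cases_prevented == 0.0


def test_threshold_crossing_counts_weighted_person():
    st = _states(np.array([45.0]), np.array([1.0]), np.array([1000.0]))
    rep = cases_prevented(st, HealthThresholds(), "mcs")
    assert rep.cases_prevented == pytest.approx(1000.0)


def test_uniform_positive_delta_never_creates_cases():
    rng = np.random.default_rng(2)
    st = _states(rng.normal(48, 8, 300), np.full(300, 0.7),
                 rng.uniform(500, 1500, 300))
    rep = cases_prevented(st, HealthThresholds(), "mcs")
    assert rep.cases_prevented >= 0.0


def test_translation_invariance_of_prevented_counts():
    rng = np.random.default_rng(3)
    base = rng.normal(47, 6, 200)
    delta = rng.normal(0.5, 0.3, 200)
    w = rng.uniform(1, 2, 200)
    thr1 = HealthThresholds(mcs_case_max=45.6)
    thr2 = HealthThresholds(mcs_case_max=55.6)
    r1 = cases_prevented(_states(base, delta, w), thr1, "mcs")
    r2 = cases_prevented(_states(base + 10.0, delta, w), thr2, "mcs")
    assert r1.cases_prevented == pytest.approx(r2.cases_prevented)


def test_net_count_equals_transition_accounting():
    rng = np.random.default_rng(4)
    base = rng.normal(46, 5, 500)
    delta = rng.normal(0.0, 1.0, 500)  # some gain, some lose
    w = rng.uniform(1, 3, 500)
    thr = HealthThresholds()
    rep = cases_prevented(_states(base, delta, w), thr, "mcs")
    cured = w[(base <= thr.mcs_case_max) & (base + delta > thr.mcs_case_max)].sum()
    created = w[(base > thr.mcs_case_max) & (base + delta <= thr.mcs_case_max)].sum()
    assert rep.cases_prevented == pytest.approx(cured - created)


def test_ci_omitted_without_bootstrap():
    st = _states(np.array([45.0, 47.0]), np.array([1.0, 1.0]), np.ones(2))
    rep = cases_prevented(st, HealthThresholds(), "mcs", bootstrap_coeffs=None)
    assert rep.ci_lower is None and rep.ci_upper is None


def test_bootstrap_ci_brackets_prevented_count(panel_medium):
    bundle = fit_bundle(panel_medium, reps=100, seed=5)
    rng = np.random.default_rng(8)
    n = 500
    pop = pd.DataFrame({
        "person_id": np.arange(n),
        "net_equiv_income": rng.lognormal(7.5, 0.5, n),
        "sex": rng.choice(["female", "male"], n),
        "age_band": rng.choice(["25-34", "45-54", "65-74"], n),
        "education": rng.choice(["degree", "gcse"], n),
        "region": rng.choice(["England", "Wales"], n),
        "employment_status": rng.choice(["employed", "not_employed"], n),
        "weight": np.full(n, 100.0),
    })
    base = pop["net_equiv_income"].to_numpy()
    states = build_states(pop, bundle, base, base * 1.15,
                          residual_sd=8.0, seed=2, scheme="test")
    rep = cases_prevented(states, HealthThresholds(), "mcs",
                          bootstrap_coeffs=bundle.mcs.bootstrap_replicates())
    assert rep.ci_lower is not None
    assert rep.ci_lower <= rep.cases_prevented <= rep.ci_upper
    # reform score = base + delta exactly
    assert np.allclose(states["mcs_reform"],
                       states["mcs_base"] + states["delta_mcs"])
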