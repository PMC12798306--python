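"""Seeded synthetic survey data for the Basic Income health microsimulation.

The real study population comes from two licensed UK surveys: a household
cross-section (the microsimulation base, Family Resources Survey style) and a
12-wave balanced individual panel (Understanding Society style) used to
estimate the income-health model.  This module generates stand-ins for both
with a *known* income-health structure, so every downstream stage — the
tax-benefit calculator, the within-between estimator, the health-impact
forecast and the valuation — can be tested end to end without access to the
licensed microdata.

Two generators are provided:

``gen_cross_section``
    A household cross-section with demographics, gross incomes and grossing
    weights, calibrated to published marginal proportions (age/sex/region/
    tenure mix, mean adults and children per household).

``gen_panel``
    A person × wave panel of net equivalised household income and SF-12
    mental (MCS) and physical (PCS) component scores, generated from a linear
    within-between model with person random effects, so that the generating
    coefficients can be recovered by the estimator in :mod:`bisim.panel_model`.

All randomness flows through a single integer seed; identical configuration
and seed give byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PopulationConfig",
    "TrueHealthModel",
    "gen_cross_section",
    "gen_panel",
    "make_balanced",
    "default_cross_section_mix",
    "default_panel_mix",
    "AGE_BANDS",
    "age_band_of",
]


class ConfigurationError(ValueError):
    """Raised when a population configuration is internally inconsistent."""


# Shared categorical vocabularies.  Both surveys use the same band list so
# that coefficients estimated on the panel can be evaluated on the
# cross-section without any level remapping.
AGE_BANDS = ["18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+"]
_BAND_EDGES = [(18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 74), (75, 89)]
SEXES = ["female", "male"]
REGIONS = ["England", "Scotland", "Wales", "Northern Ireland"]
TENURES = ["own", "social_rent", "private_rent", "other"]
EDUCATION = ["degree", "other_higher", "a_level", "gcse", "other_qual", "none"]
EMPLOYMENT = ["employed", "not_employed"]


def age_band_of(age) -> np.ndarray:
    """Map adult ages (years) to the shared band labels."""
    age = np.asarray(age)
    idx = np.searchsorted([25, 35, 45, 55, 65, 75], age, side="right")
    return np.asarray(AGE_BANDS, dtype=object)[idx]


def default_cross_section_mix() -> dict:
    """Marginal mix for the household cross-section (microsimulation base).

    Age/sex/region/tenure proportions follow the published characteristics of
    the 2021-22 UK cross-section used for Basic Income microsimulation; the
    65+ share is split between 65-74 and 75+ so both surveys share one band
    vocabulary.  Household composition targets a mean of 1.78 adults (OECD
    14+ definition) and 0.33 children (0-13) per household.
    """
    return {
        "age_band": {
            "18-24": 0.0475, "25-34": 0.1245, "35-44": 0.1508,
            "45-54": 0.1565, "55-64": 0.1884, "65-74": 0.2223, "75+": 0.1100,
        },
        "sex": {"female": 0.468, "male": 0.532},
        "region": {
            "England": 0.7389, "Scotland": 0.1086,
            "Wales": 0.0488, "Northern Ireland": 0.1037,
        },
        "tenure": {"own": 0.7519, "social_rent": 0.0994,
                   "private_rent": 0.0641, "other": 0.0846},
        "education": {"degree": 0.3364, "other_higher": 0.1308, "a_level": 0.1609,
                      "gcse": 0.1748, "other_qual": 0.0514, "none": 0.1457},
        # mean 1.78 adults, 0.33 children per household
        "adults": {1: 0.34, 2: 0.56, 3: 0.08, 4: 0.02},
        "children": {0: 0.80, 1: 0.10, 2: 0.07, 3: 0.03},
        "employment_rate": 0.6424,  # of working-age adults; retired dominate 65+
    }


def default_panel_mix() -> dict:
    """Marginal mix for the balanced panel (longitudinal survey stand-in)."""
    mix = default_cross_section_mix()
    mix = dict(mix)
    mix["age_band"] = {
        "18-24": 0.0198, "25-34": 0.0951, "35-44": 0.1704, "45-54": 0.2221,
        "55-64": 0.2368, "65-74": 0.1925, "75+": 0.0633,
    }
    # The published balanced panel skews male (57.66%); exposed as config
    # rather than asserted as representative.
    mix["sex"] = {"female": 0.4234, "male": 0.5766}
    # published nation shares sum to 101.6% (rounding); renormalised here
    mix["region"] = {"England": 0.877 / 1.016, "Scotland": 0.076 / 1.016,
                     "Wales": 0.037 / 1.016, "Northern Ireland": 0.026 / 1.016}
    return mix


def _check_proportions(name: str, mapping: dict) -> None:
    total = float(sum(mapping.values()))
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(
            f"proportions for {name!r} sum to {total!r}, expected 1.0"
        )
    if any(v < 0 for v in mapping.values()):
        raise ConfigurationError(f"negative proportion in {name!r}")


@dataclass
class PopulationConfig:
    """Configuration for both synthetic survey generators.

    Parameters
    ----------
    n_households
        Number of sample households (cross-section) or panel persons
        (``gen_panel`` draws one panel member per household).
    n_waves
        Panel length; the study design uses 12 annual waves.
    seed
        Master seed; all generator randomness derives from it.
    demographic_mix
        Marginal categorical proportions; see :func:`default_cross_section_mix`.
    income_model
        ``log_mean``/``log_sd`` of the persistent (between-person) component
        of log monthly income, AR(1) ``persistence`` of the transitory
        deviation, and its stationary ``transitory_sd``.
    grossing_target
        Total adult (18+) population represented; adult weights are
        normalised to sum to this.
    attrition_rate
        Per-wave independent probability that a panel person misses a wave
        after wave 1 (the study controls for attrition but does not state its
        process; independence is the package's modelling choice).
    """

    n_households: int = 1000
    n_waves: int = 12
    seed: int = 0
    demographic_mix: dict = field(default_factory=default_cross_section_mix)
    income_model: dict = field(default_factory=lambda: {
        # anchored on mean net equivalised monthly income ~ £2,412 for the
        # panel: E[X] = exp(mu + (sd_b^2 + sd_t^2)/2)
        "log_mean": 7.618,
        "log_sd": 0.50,
        "persistence": 0.5,
        "transitory_sd": 0.30,
    })
    grossing_target: float = 5.3e7
    attrition_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_households < 1:
            raise ConfigurationError("n_households must be >= 1")
        if self.n_waves < 2:
            raise ConfigurationError("n_waves must be >= 2 (within component undefined)")
        for key in ("age_band", "sex", "region", "tenure", "education",
                    "adults", "children"):
            if key in self.demographic_mix:
                _check_proportions(key, self.demographic_mix[key])
        rho = self.income_model.get("persistence", 0.0)
        if not 0.0 <= rho <= 1.0:
            raise ConfigurationError("income persistence must be in [0, 1]")
        if not 0.0 <= self.attrition_rate < 1.0:
            raise ConfigurationError("attrition_rate must be in [0, 1)")
        if self.grossing_target <= 0:
            raise ConfigurationError("grossing_target must be positive")


@dataclass
class TrueHealthModel:
    """Known generating model linking transformed income to MCS/PCS scores.

    The score for person *i* at wave *t* is::

        y_it = intercept + beta_within * (x_it - xbar_i) + beta_between * xbar_i
               + controls + lag_coefficient * (y_{i,t-1} - E[y]) + alpha_i + e_it

    with ``x`` the transformed income (log by default, matching the
    estimator), ``xbar_i`` the person's *empirical* mean over the observed
    waves, ``alpha_i ~ N(0, sigma_individual^2)`` and
    ``e_it ~ N(0, sigma_resid^2)``.  Units: score points per unit of
    transformed income.
    """

    beta_between_mcs: float = 2.0
    beta_within_mcs: float = 1.0
    beta_between_pcs: float = 1.5
    beta_within_pcs: float = 0.8
    intercept_mcs: float = 34.0
    intercept_pcs: float = 38.0
    control_effects: dict = field(default_factory=lambda: {
        "sex": {"female": 0.0, "male": 0.6},
        "education": {"degree": 1.0, "other_higher": 0.6, "a_level": 0.4,
                      "gcse": 0.2, "other_qual": 0.0, "none": -0.5},
        "employment_status": {"employed": 0.8, "not_employed": 0.0},
    })
    sigma_individual: float = 6.0
    sigma_resid: float = 7.0
    lag_coefficient: float = 0.0
    income_transform: str = "log"

    def __post_init__(self) -> None:
        if self.sigma_individual < 0:
            raise ConfigurationError("sigma_individual must be >= 0")
        if self.sigma_resid <= 0:
            raise ConfigurationError("sigma_resid must be > 0")
        if abs(self.lag_coefficient) >= 1:
            raise ConfigurationError("|lag_coefficient| must be < 1")
        if self.income_transform not in ("log", "linear"):
            raise ConfigurationError("income_transform must be 'log' or 'linear'")


def _draw_cat(rng: np.random.Generator, mapping: dict, size: int) -> np.ndarray:
    keys = list(mapping.keys())
    p = np.asarray([mapping[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.asarray(keys, dtype=object)[idx]


def _age_in_band(rng: np.random.Generator, bands: np.ndarray) -> np.ndarray:
    lo = np.empty(len(bands), dtype=int)
    hi = np.empty(len(bands), dtype=int)
    for label, (a, b) in zip(AGE_BANDS, _BAND_EDGES):
        m = bands == label
        lo[m], hi[m] = a, b
    return rng.integers(lo, hi + 1)


def gen_cross_section(config: PopulationConfig):
    """Generate a seeded household cross-section.

    Returns
    -------
    (households, persons) : tuple of DataFrame
        ``households``: household_id, n_adults, n_children, region, tenure,
        equiv_factor, weight.  ``persons``: one row per member with
        demographics, gross monthly earned/unearned income and a grossing
        weight; adult weights sum to ``config.grossing_target``.
    """
    mix = config.demographic_mix
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_hh = config.n_households

    n_adults = _draw_cat(rng, mix["adults"], n_hh).astype(int)
    n_children = _draw_cat(rng, mix["children"], n_hh).astype(int)
    region = _draw_cat(rng, mix["region"], n_hh)
    tenure = _draw_cat(rng, mix["tenure"], n_hh)

    total_adults = int(n_adults.sum())
    total_children = int(n_children.sum())

    # Adults: the first adult's band is drawn from the configured mix; any
    # partner's age is local to the first adult's, preserving the marginal
    # approximately (marginal realism only — no joint census calibration).
    first_band = _draw_cat(rng, mix["age_band"], n_hh)
    first_age = _age_in_band(rng, first_band)
    hh_of_adult = np.repeat(np.arange(n_hh), n_adults)
    adult_rank = np.concatenate([np.arange(k) for k in n_adults])
    ages = np.empty(total_adults, dtype=int)
    ages[adult_rank == 0] = first_age
    extra = adult_rank > 0
    ages[extra] = np.clip(
        first_age[hh_of_adult[extra]] + rng.integers(-6, 7, size=int(extra.sum())),
        18, 89,
    )

    sex = _draw_cat(rng, mix["sex"], total_adults)
    education = _draw_cat(rng, mix["education"], total_adults)
    ethnicity = _draw_cat(rng, {
        "white": 0.9106, "mixed": 0.0097, "south_asian": 0.0361,
        "other_asian": 0.0107, "black": 0.0201, "other": 0.0128,
    }, total_adults)
    marital = _draw_cat(rng, {
        "single": 0.1768, "cohabiting": 0.1127, "married": 0.5450,
        "divorced": 0.0719, "widowed": 0.0716, "other": 0.0220,
    }, total_adults)

    pension_age = 65
    working_age = ages < pension_age
    employed = np.zeros(total_adults, dtype=bool)
    emp_rate = mix.get("employment_rate", 0.64)
    employed[working_age] = rng.random(int(working_age.sum())) < emp_rate
    # a small share of 65+ still works
    older = ~working_age
    employed[older] = rng.random(int(older.sum())) < 0.10
    employment_status = np.where(employed, "employed", "not_employed").astype(object)

    im = config.income_model
    earned = np.zeros(total_adults)
    earned[employed] = np.exp(rng.normal(im["log_mean"], im["log_sd"],
                                         int(employed.sum())))
    unearned = np.zeros(total_adults)
    has_unearned = rng.random(total_adults) < 0.10
    unearned[has_unearned] = np.exp(rng.normal(5.0, 0.8, int(has_unearned.sum())))

    weight = config.grossing_target / total_adults

    adults = pd.DataFrame({
        "household_id": hh_of_adult,
        "age": ages,
        "sex": sex,
        "ethnicity": ethnicity,
        "region": region[hh_of_adult],
        "marital_status": marital,
        "employment_status": employment_status,
        "education": education,
        "earned_income": earned,
        "unearned_income": unearned,
    })

    hh_of_child = np.repeat(np.arange(n_hh), n_children)
    children = pd.DataFrame({
        "household_id": hh_of_child,
        "age": rng.integers(0, 14, size=total_children),
        "sex": _draw_cat(rng, {"female": 0.5, "male": 0.5}, total_children),
        "ethnicity": "white",
        "region": region[hh_of_child],
        "marital_status": "child",
        "employment_status": "child",
        "education": "child",
        "earned_income": 0.0,
        "unearned_income": 0.0,
    })

    persons = pd.concat([adults, children], ignore_index=True)
    persons = persons.sort_values(
        ["household_id", "age"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    persons.insert(0, "person_id", np.arange(len(persons)))
    persons["weight"] = weight
    persons["age_band"] = "child"
    adult_mask = persons["age"].to_numpy() >= 18
    persons.loc[adult_mask, "age_band"] = age_band_of(
        persons.loc[adult_mask, "age"].to_numpy()
    )

    from .taxben import equivalence_factor  # late import, no cycle at module load
    equiv = persons.groupby("household_id")["age"].apply(
        lambda a: equivalence_factor(list(a))
    )
    households = pd.DataFrame({
        "household_id": np.arange(n_hh),
        "n_adults": n_adults,
        "n_children": n_children,
        "region": region,
        "tenure": tenure,
        "equiv_factor": equiv.to_numpy(),
        "weight": weight,
    })
    return households, persons


def _transform(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "log":
        return np.log(np.maximum(x, 1.0))
    return np.asarray(x, dtype=float)


def gen_panel(config: PopulationConfig, truth: TrueHealthModel,
              thresholds=None) -> pd.DataFrame:
    """Generate a person × wave panel with known income-health structure.

    One panel person is drawn per configured household.  Log income follows a
    person mean plus an AR(1) transitory deviation (distinct, controllable
    within/between variance shares); MCS/PCS follow the linear model of
    :class:`TrueHealthModel`.  Scores are clipped to the instrument range
    [0, 100] (clipping should be rare; monitored by tests).

    ``prior_case_mcs``/``prior_case_pcs`` are lagged case indicators
    (MCS <= 45.6, PCS <= 50 at the previous wave), seeded from an internal
    burn-in wave so wave 1 has a defined lag.

    If ``config.attrition_rate > 0`` the returned panel is unbalanced (waves
    after the first are dropped independently); use :func:`make_balanced`.
    """
    if config.n_waves < 2:
        raise ConfigurationError("n_waves must be >= 2")
    from .health_impact import HealthThresholds
    thr = thresholds or HealthThresholds()

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    n = config.n_households
    T = config.n_waves
    im = config.income_model
    mix = config.demographic_mix

    # income: person mean + AR(1) stationary transitory deviation
    m = rng.normal(im["log_mean"], im["log_sd"], size=n)
    rho = float(im["persistence"])
    sd_t = float(im["transitory_sd"])
    u = np.empty((n, T))
    u[:, 0] = rng.normal(0.0, sd_t, size=n)
    innov_sd = sd_t * np.sqrt(max(1.0 - rho**2, 0.0))
    for t in range(1, T):
        u[:, t] = rho * u[:, t - 1] + rng.normal(0.0, innov_sd, size=n)
    income = np.exp(m[:, None] + u)  # £/month net equivalised

    x = _transform(income, truth.income_transform)
    xbar = x.mean(axis=1, keepdims=True)           # empirical person mean
    x_within = x - xbar

    # time-invariant controls
    sex = _draw_cat(rng, mix["sex"], n)
    band = _draw_cat(rng, mix["age_band"], n)
    education = _draw_cat(rng, mix["education"], n)
    region = _draw_cat(rng, mix["region"], n)
    working_age = ~np.isin(band, ["65-74", "75+"])
    employed = working_age & (rng.random(n) < mix.get("employment_rate", 0.64))
    employment = np.where(employed, "employed", "not_employed").astype(object)
    controls = {"sex": sex, "age_band": band, "education": education,
                "region": region, "employment_status": employment}

    ctrl_effect = np.zeros(n)
    for col, effects in truth.control_effects.items():
        if col not in controls:
            continue
        vals = controls[col]
        ctrl_effect += np.asarray([effects.get(v, 0.0) for v in vals])

    alpha_mcs = rng.normal(0.0, truth.sigma_individual, size=n)
    alpha_pcs = rng.normal(0.0, truth.sigma_individual, size=n)

    def simulate(intercept, bw, bb, alpha):
        mean_pred = intercept + bb * xbar[:, 0] + ctrl_effect
        lam = truth.lag_coefficient
        y = np.empty((n, T))
        # burn-in wave for the lag / prior-case flags
        y_prev = (mean_pred + alpha
                  + rng.normal(0.0, truth.sigma_resid, size=n))
        y0 = y_prev.copy()
        for t in range(T):
            y[:, t] = (intercept + bw * x_within[:, t] + bb * xbar[:, 0]
                       + ctrl_effect + lam * (y_prev - mean_pred) + alpha
                       + rng.normal(0.0, truth.sigma_resid, size=n))
            y_prev = y[:, t]
        return y0, y

    mcs0, mcs = simulate(truth.intercept_mcs, truth.beta_within_mcs,
                         truth.beta_between_mcs, alpha_mcs)
    pcs0, pcs = simulate(truth.intercept_pcs, truth.beta_within_pcs,
                         truth.beta_between_pcs, alpha_pcs)
    mcs_lagged = np.concatenate([mcs0[:, None], mcs[:, :-1]], axis=1)
    pcs_lagged = np.concatenate([pcs0[:, None], pcs[:, :-1]], axis=1)

    panel = pd.DataFrame({
        "person_id": np.repeat(np.arange(n), T),
        "wave": np.tile(np.arange(1, T + 1), n),
        "net_equiv_income": income.ravel(),
        "mcs": np.clip(mcs, 0.0, 100.0).ravel(),
        "pcs": np.clip(pcs, 0.0, 100.0).ravel(),
        "sex": np.repeat(sex, T),
        "age_band": np.repeat(band, T),
        "education": np.repeat(education, T),
        "region": np.repeat(region, T),
        "employment_status": np.repeat(employment, T),
        "prior_case_mcs": (mcs_lagged <= thr.mcs_case_max).ravel(),
        "prior_case_pcs": (pcs_lagged <= thr.pcs_case_max).ravel(),
    })
    panel.attrs["truth"] = asdict(truth)
    panel.attrs["config_seed"] = config.seed

    if config.attrition_rate > 0:
        keep = rng.random(len(panel)) >= config.attrition_rate
        keep |= panel["wave"].to_numpy() == 1  # everyone present at wave 1
        panel = panel[keep].reset_index(drop=True)
    return panel


def make_balanced(panel: pd.DataFrame, n_waves: int | None = None) -> pd.DataFrame:
    """Keep only persons observed in every wave.

    An ``attrition_flag`` column is added (False for all retained persons,
    since by construction they have complete records) for schema
    compatibility with estimators that control for attrition exposure.
    Raises ``ValueError`` with count diagnostics if no person is complete.
    """
    waves = panel["wave"].unique()
    T = n_waves or len(waves)
    counts = panel.groupby("person_id")["wave"].nunique()
    complete = counts[counts == T].index
    out = panel[panel["person_id"].isin(complete)].copy()
    if out.empty:
        raise ValueError(
            f"balanced panel is empty: {len(counts)} persons, "
            f"0 with all {T} waves (max observed {counts.max() if len(counts) else 0})"
        )
    out["attrition_flag"] = False
    out = out.sort_values(["person_id", "wave"], kind="stable").reset_index(drop=True)
    out.attrs = dict(panel.attrs)
    out.attrs["n_dropped_persons"] = int(len(counts) - len(complete))
    return out


SCHEMA_VERSION = "1.0"


def save_tables(out_dir, tables: dict, ground_truth: dict | None = None) -> None:
    """Write tables as CSV and Parquet with a versioned JSON schema sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = {"schema_version": SCHEMA_VERSION, "tables": {}}
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
        df.to_parquet(out / f"{name}.parquet", index=False)
        schema["tables"][name] = {c: str(t) for c, t in df.dtypes.items()}
    (out / "schema.json").write_text(json.dumps(schema, indent=2))
    if ground_truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=2))
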