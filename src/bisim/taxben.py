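"""Stylised static UK tax-benefit calculator and Basic Income reforms.

Computes baseline and reform net household incomes for a survey population.
The baseline is a deliberately simplified stand-in for the UK system — one
income-tax schedule, one National Insurance schedule, Child Benefit, the
State Pension and Universal Credit (UC) with a single family-type allowance
table — parameterised by :class:`TaxBenParams`, not statute.

Basic Income (BI) reforms pay an unconditional amount per person by age band
(child / working-age adult / 65+), replace the non-means-tested benefits
(Child Benefit and the State Pension) one for one, and count BI as unearned
income in the UC means test, less a configurable disregard.  In the baseline
the replaced benefits are likewise counted as unearned income in the UC
means test; this is what makes the replacement exactly one-for-one for UC
recipients and guarantees that, with a positive disregard, UC-receiving
households gain at least the disregard.

All incomes are monthly £, before housing costs.  Weekly benefit rates are
converted at x 52/12.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxBenParams",
    "SchemeDefinition",
    "IncomeResult",
    "Person",
    "Household",
    "equivalence_factor",
    "schedule_amount",
    "baseline_net_income",
    "apply_scheme",
    "marginal_deduction_rate",
    "compute_population",
    "distributional_summary",
    "weighted_gini",
    "scheme_starter",
    "scheme_intermediate",
    "scheme_mis",
]

WEEKS_PER_MONTH = 52.0 / 12.0

KNOWN_BENEFITS = {"child_benefit", "state_pension"}


@dataclass
class TaxBenParams:
    """Parameters of the stylised baseline system.

    Schedules are lists of ``(annual threshold £, marginal rate)`` applied to
    the slice of annual income above each threshold (up to the next).
    UC amounts are £/month; ``uc_taper`` applies to net earnings above
    ``uc_earnings_disregard``; unearned income (including baseline Child
    Benefit / State Pension and, under reform, Basic Income net of its
    disregard) reduces UC £1 for £1.
    """

    income_tax_bands: list = field(default_factory=lambda: [
        (12_570.0, 0.20), (50_270.0, 0.40), (125_140.0, 0.45)])
    ni_bands: list = field(default_factory=lambda: [
        (12_570.0, 0.12), (50_270.0, 0.02)])
    child_benefit_first: float = 24.00        # £/week, first child
    child_benefit_subsequent: float = 15.90   # £/week, each further child
    state_pension: float = 185.15             # £/week per person >= pension_age
    pension_age: int = 65
    uc_standard_allowances: dict = field(default_factory=lambda: {
        "single": 334.91, "couple": 525.72})  # £/month
    uc_child_element: float = 244.58          # £/month per child
    uc_taper: float = 0.55
    uc_earnings_disregard: float = 300.0      # £/month work allowance
    uc_takeup: float = 1.0
    uc_takeup_seed: int = 0
    funding_adjustment: float | None = None   # percentage points on all IT rates

    def __post_init__(self) -> None:
        for name, sched in (("income_tax_bands", self.income_tax_bands),
                            ("ni_bands", self.ni_bands)):
            thresholds = [t for t, _ in sched]
            if thresholds != sorted(thresholds):
                raise ValueError(f"{name}: thresholds must be nondecreasing")
            if any(not 0.0 <= r <= 1.0 for _, r in sched):
                raise ValueError(f"{name}: rates must be in [0, 1]")
        if not 0.0 <= self.uc_taper <= 1.0:
            raise ValueError("uc_taper must be in [0, 1]")
        if not 0.0 <= self.uc_takeup <= 1.0:
            raise ValueError("uc_takeup must be in [0, 1]")


@dataclass(frozen=True)
class SchemeDefinition:
    """A Basic Income scheme: weekly rates by age band plus UC interaction."""

    name: str
    rate_child: float      # £/week, age < 18
    rate_adult: float      # £/week, 18 <= age < 65
    rate_65plus: float     # £/week, age >= 65
    replaces: frozenset = frozenset({"child_benefit", "state_pension"})
    uc_bi_disregard: float = 0.0  # £/month of BI ignored in the UC means test

    def __post_init__(self) -> None:
        if min(self.rate_child, self.rate_adult, self.rate_65plus) < 0:
            raise ValueError("BI rates must be >= 0")
        unknown = set(self.replaces) - KNOWN_BENEFITS
        if unknown:
            raise ValueError(f"unknown benefits in replaces: {sorted(unknown)}")

    def monthly_bi(self, ages: Iterable[float]) -> float:
        total = 0.0
        for age in ages:
            if age < 18:
                total += self.rate_child
            elif age < 65:
                total += self.rate_adult
            else:
                total += self.rate_65plus
        return total * WEEKS_PER_MONTH


def scheme_starter() -> SchemeDefinition:
    """Starter scheme: £50/child, £75/adult 18-64, £205/65+ per week."""
    return SchemeDefinition("scheme1", 50.0, 75.0, 205.0,
                            frozenset(KNOWN_BENEFITS), uc_bi_disregard=10.0)


def scheme_intermediate() -> SchemeDefinition:
    """Intermediate scheme: £75/child, £185/adult, £205/65+ per week."""
    return SchemeDefinition("scheme2", 75.0, 185.0, 205.0,
                            frozenset(KNOWN_BENEFITS), uc_bi_disregard=10.0)


def scheme_mis() -> SchemeDefinition:
    """Minimum Income Standard scheme: £100/child, £295/adult and 65+ per week.

    Payments are high enough that no UC disregard is needed.
    """
    return SchemeDefinition("scheme3", 100.0, 295.0, 295.0,
                            frozenset(KNOWN_BENEFITS), uc_bi_disregard=0.0)


DEFAULT_SCHEMES = (scheme_starter, scheme_intermediate, scheme_mis)


@dataclass(frozen=True)
class Person:
    age: float
    earned_income: float = 0.0    # £/month gross
    unearned_income: float = 0.0  # £/month


@dataclass
class Household:
    household_id: int
    members: list
    weight: float = 1.0

    @property
    def ages(self) -> list:
        return [m.age for m in self.members]


@dataclass
class IncomeResult:
    household_id: int
    net_income_base: float
    net_income_reform: float
    equiv_factor: float
    bi_received: float
    benefits_lost: float
    taxes_delta: float
    weight: float = 1.0

    @property
    def net_equiv_base(self) -> float:
        return self.net_income_base / self.equiv_factor

    @property
    def net_equiv_reform(self) -> float:
        return self.net_income_reform / self.equiv_factor


def equivalence_factor(ages: Sequence[float]) -> float:
    """OECD-modified equivalence scale.

    First member aged 14+ counts 1.0, each additional 14+ member 0.5, each
    member aged 0-13 counts 0.3.
    """
    if len(ages) == 0:
        raise ValueError("household has no members")
    adults = sum(1 for a in ages if a >= 14)
    children = len(ages) - adults
    if adults == 0:
        # degenerate child-only household: first member is the reference
        return max(1.0 * 0.3 + 0.3 * (children - 1), 0.3)
    return 1.0 + 0.5 * (adults - 1) + 0.3 * children


def schedule_amount(annual_income: float, bands: Sequence) -> float:
    """Tax due on annual income under a marginal-rate schedule."""
    tax = 0.0
    for i, (threshold, rate) in enumerate(bands):
        upper = bands[i + 1][0] if i + 1 < len(bands) else float("inf")
        if annual_income > threshold:
            tax += rate * (min(annual_income, upper) - threshold)
    return tax


def _adjusted_tax_bands(params: TaxBenParams) -> list:
    if params.funding_adjustment is None:
        return params.income_tax_bands
    pp = params.funding_adjustment / 100.0
    return [(t, min(r + pp, 1.0)) for t, r in params.income_tax_bands]


def _takeup_draw(params: TaxBenParams, household_id: int) -> bool:
    if params.uc_takeup >= 1.0:
        return True
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.uc_takeup_seed), int(household_id), 7]))
    return bool(rng.random() < params.uc_takeup)


def _net_income(hh: Household, params: TaxBenParams,
                scheme: SchemeDefinition | None,
                reform_tax: bool) -> dict:
    """Core calculator shared by baseline and reform passes."""
    tax_bands = _adjusted_tax_bands(params) if reform_tax else params.income_tax_bands
    net_earnings = 0.0
    gross_earned = 0.0
    unearned = 0.0
    tax_paid = 0.0
    n_children = 0
    n_pensioners = 0
    n_adults_18 = 0
    any_working_age_adult = False
    for p in hh.members:
        if p.earned_income < 0 or p.unearned_income < 0:
            raise ValueError("negative gross income")
        annual = p.earned_income * 12.0
        tax = schedule_amount(annual, tax_bands) / 12.0
        ni = schedule_amount(annual, params.ni_bands) / 12.0
        tax_paid += tax + ni
        net_earnings += p.earned_income - tax - ni
        gross_earned += p.earned_income
        unearned += p.unearned_income
        if p.age < 18:
            if p.age <= 13:
                n_children += 1
        else:
            n_adults_18 += 1
            if p.age >= params.pension_age:
                n_pensioners += 1
            else:
                any_working_age_adult = True

    # non-means-tested benefits
    child_benefit = 0.0
    if n_children >= 1:
        child_benefit = (params.child_benefit_first
                         + params.child_benefit_subsequent * (n_children - 1))
        child_benefit *= WEEKS_PER_MONTH
    state_pension = params.state_pension * WEEKS_PER_MONTH * n_pensioners

    bi = 0.0
    replaced = 0.0
    if scheme is not None:
        bi = scheme.monthly_bi(hh.ages)
        if "child_benefit" in scheme.replaces:
            replaced += child_benefit
            child_benefit = 0.0
        if "state_pension" in scheme.replaces:
            replaced += state_pension
            state_pension = 0.0

    # Universal Credit: households with at least one working-age adult.
    # All benefit income other than UC itself (CB, SP, and BI net of its
    # disregard under reform) counts as unearned income in the means test.
    uc = 0.0
    if any_working_age_adult:
        allowance = params.uc_standard_allowances[
            "single" if n_adults_18 == 1 else "couple"]
        allowance += params.uc_child_element * n_children
        tapered = params.uc_taper * max(0.0, net_earnings - params.uc_earnings_disregard)
        unearned_for_uc = unearned + child_benefit + state_pension
        if scheme is not None:
            unearned_for_uc += max(0.0, bi - scheme.uc_bi_disregard)
        uc = max(0.0, allowance - tapered - unearned_for_uc)
        if uc > 0 and not _takeup_draw(params, hh.household_id):
            uc = 0.0

    net = net_earnings + unearned + child_benefit + state_pension + uc + bi
    return {
        "net": net, "tax_paid": tax_paid, "uc": uc, "bi": bi,
        "replaced": replaced, "child_benefit": child_benefit,
        "state_pension": state_pension, "gross_earned": gross_earned,
    }


def baseline_net_income(hh: Household, params: TaxBenParams) -> float:
    """Net monthly household income under the stylised baseline system."""
    return _net_income(hh, params, scheme=None, reform_tax=False)["net"]


def apply_scheme(hh: Household, scheme: SchemeDefinition,
                 params: TaxBenParams) -> IncomeResult:
    """Net incomes for one household under baseline and a BI reform."""
    base = _net_income(hh, params, scheme=None, reform_tax=False)
    reform = _net_income(hh, params, scheme=scheme, reform_tax=True)
    return IncomeResult(
        household_id=hh.household_id,
        net_income_base=base["net"],
        net_income_reform=reform["net"],
        equiv_factor=equivalence_factor(hh.ages),
        bi_received=reform["bi"],
        benefits_lost=reform["replaced"] + (base["uc"] - reform["uc"]),
        taxes_delta=reform["tax_paid"] - base["tax_paid"],
        weight=hh.weight,
    )


def marginal_deduction_rate(hh: Household, scheme: SchemeDefinition | None,
                            params: TaxBenParams, delta: float = 100.0) -> float:
    """MDR = 1 - (change in net income / change in gross earnings).

    The reference earner is the member with the highest earned income; their
    gross monthly earnings are incremented by ``delta``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    earners = [i for i, p in enumerate(hh.members) if p.earned_income > 0]
    if not earners:
        raise ValueError("household has no earner")
    ref = max(earners, key=lambda i: hh.members[i].earned_income)
    net0 = _net_income(hh, params, scheme, reform_tax=scheme is not None)["net"]
    bumped = Household(
        hh.household_id,
        [replace(p, earned_income=p.earned_income + (delta if i == ref else 0.0))
         for i, p in enumerate(hh.members)],
        hh.weight,
    )
    net1 = _net_income(bumped, params, scheme, reform_tax=scheme is not None)["net"]
    return 1.0 - (net1 - net0) / delta


# ---------------------------------------------------------------------------
# population-level interface


def households_from_frames(households: pd.DataFrame,
                           persons: pd.DataFrame) -> list:
    """Build Household objects from the generated survey tables."""
    out = []
    weights = households.set_index("household_id")["weight"]
    for hh_id, grp in persons.groupby("household_id", sort=True):
        members = [Person(a, e, u) for a, e, u in zip(
            grp["age"], grp["earned_income"], grp["unearned_income"])]
        out.append(Household(int(hh_id), members, float(weights.loc[hh_id])))
    return out


def compute_population(households: pd.DataFrame, persons: pd.DataFrame,
                       scheme: SchemeDefinition,
                       params: TaxBenParams) -> pd.DataFrame:
    """Per-household IncomeResult table for a whole survey population."""
    rows = []
    for hh in households_from_frames(households, persons):
        r = apply_scheme(hh, scheme, params)
        rows.append({
            "household_id": r.household_id,
            "net_income_base": r.net_income_base,
            "net_income_reform": r.net_income_reform,
            "equiv_factor": r.equiv_factor,
            "net_equiv_base": r.net_equiv_base,
            "net_equiv_reform": r.net_equiv_reform,
            "bi_received": r.bi_received,
            "benefits_lost": r.benefits_lost,
            "taxes_delta": r.taxes_delta,
            "weight": r.weight,
        })
    return pd.DataFrame(rows)


def weighted_gini(values, weights) -> float:
    """Weighted Gini coefficient via the midpoint-rank formula.

    Algebraically identical to the pairwise mean-absolute-difference form
    G = sum_ij w_i w_j |x_i - x_j| / (2 W^2 mu).
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    W = w.sum()
    mu = (w * x).sum() / W
    if mu == 0:
        return 0.0
    c = np.cumsum(w) - 0.5 * w  # midpoint cumulative weight
    return float(2.0 * (w * x * c).sum() / (W**2 * mu) - 1.0)


def _weighted_quantile(x, w, q):
    order = np.argsort(x, kind="stable")
    x, w = np.asarray(x, float)[order], np.asarray(w, float)[order]
    cw = np.cumsum(w) - 0.5 * w
    return float(np.interp(q * w.sum(), cw, x))


GAIN_BANDS = [(-np.inf, -1.0, "loser"), (-1.0, 1.0, "no_change"),
              (1.0, 100.0, "gain_1_100"), (100.0, 500.0, "gain_100_500"),
              (500.0, np.inf, "gain_500_plus")]


def distributional_summary(results: pd.DataFrame,
                           persons: pd.DataFrame | None = None) -> dict:
    """Distributional report: Gini, quintile changes, winners/losers,
    poverty headcounts and aggregate exchequer cost.

    Poverty is the share of (weighted) households below 60% of the weighted
    median equivalised income under each system; if a persons table is
    supplied, child poverty (members aged 0-13) is reported too.
    """
    if len(results) < 2:
        raise ValueError("need at least two households")
    w = results["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    base = results["net_equiv_base"].to_numpy(dtype=float)
    reform = results["net_equiv_reform"].to_numpy(dtype=float)
    delta = results["net_income_reform"].to_numpy() - results["net_income_base"].to_numpy()

    report = {
        "gini_base": weighted_gini(base, w),
        "gini_reform": weighted_gini(reform, w),
    }

    # quintiles of baseline equivalised income
    qs = [_weighted_quantile(base, w, q) for q in (0.2, 0.4, 0.6, 0.8)]
    bins = np.digitize(base, qs)
    quintiles = []
    for k in range(5):
        m = bins == k
        mean_base = np.average(results["net_income_base"].to_numpy()[m], weights=w[m])
        mean_delta = np.average(delta[m], weights=w[m])
        quintiles.append({
            "quintile": k + 1,
            "mean_change_cash": float(mean_delta),
            "mean_change_pct": float(100.0 * mean_delta / mean_base),
        })
    report["quintiles"] = quintiles

    winners = {}
    for lo, hi, label in GAIN_BANDS:
        m = (delta > lo) & (delta <= hi) if np.isfinite(hi) else (delta > lo)
        winners[label] = float(w[m].sum())
    report["winners_losers"] = winners

    for tag, inc in (("base", base), ("reform", reform)):
        line = 0.6 * _weighted_quantile(inc, w, 0.5)
        report[f"poverty_line_{tag}"] = line
        report[f"poverty_rate_{tag}"] = float(w[inc < line].sum() / w.sum())
        if persons is not None:
            kids = persons[persons["age"] <= 13]
            kw = kids["weight"].to_numpy(dtype=float)
            hh_inc = dict(zip(results["household_id"], inc))
            kid_inc = kids["household_id"].map(hh_inc).to_numpy(dtype=float)
            report[f"child_poverty_rate_{tag}"] = (
                float(kw[kid_inc < line].sum() / kw.sum()) if kw.sum() else np.nan)

    # static annual exchequer cost: extra BI spend net of benefits withdrawn
    # and extra taxes, i.e. the aggregate net income gain
    report["net_exchequer_cost_annual"] = float((w * delta).sum() * 12.0)
    return report
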