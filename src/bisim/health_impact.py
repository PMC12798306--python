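"""From income changes to SF-12 score changes and cases prevented.

The cross-sectional microsimulation population carries no SF-12 scores, so
baseline MCS/PCS are imputed from the fitted income-health model's linear
predictor plus a seeded normal residual (an explicit, sensitivity-testable
bridge).  Score *changes* under a reform use only the "between" income
coefficient — a Basic Income is a permanent rather than transitory income
change, and the between component is the model's permanent-income slope::

    delta = beta_between * (f(income_reform) - f(income_base))

Cases use the standard SF-12 screening thresholds: depressive disorder if
MCS <= 45.6, clinically significant physical health problem if PCS <= 50.
"Prevented or postponed" is the net weighted annual case difference
(baseline cases minus reform cases).  Confidence intervals propagate only
coefficient uncertainty: prevented counts are recomputed under each
bootstrap replicate's between-coefficient with the imputation draws held
fixed, and percentile bounds taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_model import CoefficientSet, CoefficientBundle, transform_income

__all__ = [
    "HealthThresholds",
    "CaseChangeReport",
    "linear_predictor",
    "impute_baseline_scores",
    "predict_score_change",
    "count_cases",
    "cases_prevented",
    "build_states",
]

OUTCOME_LABELS = {"mcs": "depressive_disorder", "pcs": "physical_health_problem"}


@dataclass
class HealthThresholds:
    """Case thresholds on the SF-12 summary scores (score <= max is a case)."""

    mcs_case_max: float = 45.6
    pcs_case_max: float = 50.0

    def __post_init__(self) -> None:
        for v in (self.mcs_case_max, self.pcs_case_max):
            if not 0.0 < v < 100.0:
                raise ValueError("thresholds must lie in (0, 100)")

    def for_outcome(self, outcome: str) -> float:
        return self.mcs_case_max if outcome == "mcs" else self.pcs_case_max


@dataclass
class CaseChangeReport:
    scheme: str
    outcome: str  # "depressive_disorder" or "physical_health_problem"
    cases_base: float
    cases_reform: float
    ci_lower: float | None = None
    ci_upper: float | None = None

    @property
    def cases_prevented(self) -> float:
        return self.cases_base - self.cases_reform


def linear_predictor(population: pd.DataFrame, coeffs: CoefficientSet,
                     income_col: str = "net_equiv_income") -> np.ndarray:
    """Evaluate the fitted model's systematic part on a cross-section.

    ``x_between`` is the transformed income (a cross-section observes each
    person once, at their long-run income level, so ``x_within = 0``).
    Raises ``KeyError`` naming any covariate the model needs but the
    population lacks.
    """
    if income_col not in population.columns:
        raise KeyError(f"missing covariate: {income_col!r}")
    x = transform_income(population[income_col], coeffs.income_transform)
    pred = (coeffs.control_coefficients["const"]
            + coeffs.beta_between * x)
    for col, levels in coeffs.design_info.get("categorical", {}).items():
        if col not in population.columns:
            raise KeyError(f"missing covariate: {col!r}")
        s = population[col].astype(str)
        for lev in levels[1:]:
            name = f"{col}[{lev}]"
            if name in coeffs.control_coefficients:
                pred = pred + coeffs.control_coefficients[name] * (s == lev).to_numpy()
    for col in coeffs.design_info.get("numeric", []):
        if col not in population.columns:
            raise KeyError(f"missing covariate: {col!r}")
        pred = pred + (coeffs.control_coefficients[col]
                       * population[col].to_numpy(dtype=float))
    return np.asarray(pred, dtype=float)


def impute_baseline_scores(population: pd.DataFrame, coeffs: CoefficientSet,
                           residual_sd: float, seed: int,
                           income_col: str = "net_equiv_income") -> np.ndarray:
    """Baseline scores = linear predictor + seeded N(0, residual_sd²) draw.

    Clipped to the instrument range [0, 100].  Identical seeds give
    identical imputations; ``residual_sd = 0`` returns the predictor exactly.
    """
    if residual_sd < 0:
        raise ValueError("residual_sd must be >= 0")
    pred = linear_predictor(population, coeffs, income_col=income_col)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 0 if coeffs.outcome == "mcs" else 1, 53]))
    draw = rng.normal(0.0, residual_sd, size=len(pred)) if residual_sd > 0 else 0.0
    return np.clip(pred + draw, 0.0, 100.0)


def predict_score_change(income_base, income_reform,
                         coeffs: CoefficientBundle,
                         transform: str = "log") -> dict:
    """Permanent-income score changes for both outcomes.

    delta = beta_between * (f(income_reform) - f(income_base)), f the
    configured transform with a £1 floor.
    """
    for cs in (coeffs.mcs, coeffs.pcs):
        if cs.income_transform != transform:
            raise ValueError(
                f"transform mismatch: coefficients use {cs.income_transform!r}, "
                f"requested {transform!r}")
    base = np.asarray(income_base, dtype=float)
    reform = np.asarray(income_reform, dtype=float)
    if np.any(base < 0) or np.any(reform < 0):
        raise ValueError("incomes must be >= 0")
    dx = transform_income(reform, transform) - transform_income(base, transform)
    return {"delta_mcs": coeffs.mcs.beta_between * dx,
            "delta_pcs": coeffs.pcs.beta_between * dx}


def count_cases(scores, threshold_max: float, weights) -> float:
    """Weighted count of cases: sum of weights where score <= threshold."""
    scores = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if scores.shape != weights.shape:
        raise ValueError("scores and weights are not aligned")
    return float(weights[scores <= threshold_max].sum())


def build_states(population: pd.DataFrame, coeffs: CoefficientBundle,
                 income_base, income_reform, residual_sd: float, seed: int,
                 scheme: str = "") -> pd.DataFrame:
    """Per-person health-state table (the audit trail for one scheme).

    Baseline scores are imputed at baseline income; deltas use the between
    coefficients.  Reform score = base + delta exactly.
    """
    pop = population.copy()
    pop["net_equiv_income"] = np.asarray(income_base, dtype=float)
    mcs_base = impute_baseline_scores(pop, coeffs.mcs, residual_sd, seed)
    pcs_base = impute_baseline_scores(pop, coeffs.pcs, residual_sd, seed)
    deltas = predict_score_change(income_base, income_reform, coeffs,
                                  transform=coeffs.mcs.income_transform)
    out = pd.DataFrame({
        "person_id": population["person_id"].to_numpy(),
        "scheme": scheme,
        "income_base": np.asarray(income_base, dtype=float),
        "income_reform": np.asarray(income_reform, dtype=float),
        "mcs_base": mcs_base,
        "pcs_base": pcs_base,
        "delta_mcs": deltas["delta_mcs"],
        "delta_pcs": deltas["delta_pcs"],
        "weight": population["weight"].to_numpy(dtype=float),
    })
    out["mcs_reform"] = out["mcs_base"] + out["delta_mcs"]
    out["pcs_reform"] = out["pcs_base"] + out["delta_pcs"]
    out["income_transform"] = coeffs.mcs.income_transform
    return out


def cases_prevented(states: pd.DataFrame, thresholds: HealthThresholds,
                    outcome: str = "mcs",
                    bootstrap_coeffs: list | None = None,
                    scheme: str | None = None) -> CaseChangeReport:
    """Net weighted cases prevented, with optional bootstrap CI.

    The CI recomputes prevented cases under each bootstrap replicate's
    between-coefficient (rescaling the deltas), holding the imputed baseline
    scores — hence the imputation draws — fixed, and takes percentile
    bounds.  An empty/absent bootstrap list omits the CI.
    """
    thr = thresholds.for_outcome(outcome)
    base = states[f"{outcome}_base"].to_numpy(dtype=float)
    delta = states[f"delta_{outcome}"].to_numpy(dtype=float)
    w = states["weight"].to_numpy(dtype=float)
    cases_base = count_cases(base, thr, w)
    cases_reform = count_cases(base + delta, thr, w)

    ci_lo = ci_hi = None
    if bootstrap_coeffs:
        # deltas are linear in beta_between, so replicates rescale the
        # transformed-income change rather than refitting anything
        transform = (str(states["income_transform"].iloc[0])
                     if "income_transform" in states.columns else "log")
        dx = (transform_income(states["income_reform"], transform)
              - transform_income(states["income_base"], transform))
        prevented = []
        for cs in bootstrap_coeffs:
            beta = cs.beta_between if hasattr(cs, "beta_between") else float(cs)
            reform_scores = base + beta * dx
            prevented.append(cases_base - count_cases(reform_scores, thr, w))
        ci_lo = float(np.percentile(prevented, 2.5))
        ci_hi = float(np.percentile(prevented, 97.5))

    report = CaseChangeReport(
        scheme=scheme if scheme is not None else str(states["scheme"].iloc[0]),
        outcome=OUTCOME_LABELS[outcome],
        cases_base=cases_base,
        cases_reform=cases_reform,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
    )
    return report
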