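"""End-to-end orchestration: generate → taxben → fit → impact → value.

``run_pipeline`` executes the whole chain on synthetic (or user-supplied)
data and returns a :class:`ResultsBundle` whose tables mirror the study's
headline outputs: net cases prevented per scheme and outcome, QALYs gained
and their monetary value, years of life gained, cost savings under two
perspectives, and a distributional report per scheme.  Every stochastic
stage draws its own sub-seed from the master seed, recorded in the
manifest, so a bundle is exactly reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic, taxben, panel_model, health_impact, valuation

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "report",
           "person_level_incomes"]


@dataclass
class RunConfig:
    population: synthetic.PopulationConfig = field(
        default_factory=lambda: synthetic.PopulationConfig(n_households=1000))
    panel: synthetic.PopulationConfig = field(
        default_factory=lambda: synthetic.PopulationConfig(
            n_households=2000, demographic_mix=synthetic.default_panel_mix()))
    truth: synthetic.TrueHealthModel = field(
        default_factory=synthetic.TrueHealthModel)
    schemes: list = field(default_factory=lambda: [
        taxben.scheme_starter(), taxben.scheme_intermediate(), taxben.scheme_mis()])
    params: taxben.TaxBenParams = field(default_factory=taxben.TaxBenParams)
    spec_mcs: panel_model.ModelSpec = field(
        default_factory=lambda: panel_model.ModelSpec(outcome="mcs"))
    spec_pcs: panel_model.ModelSpec = field(
        default_factory=lambda: panel_model.ModelSpec(outcome="pcs"))
    bootstrap_reps: int = 1000
    thresholds: health_impact.HealthThresholds = field(
        default_factory=health_impact.HealthThresholds)
    valuation: valuation.ValuationConfig = field(
        default_factory=valuation.ValuationConfig)
    residual_sd: float = 9.0   # SF-12 score points, baseline imputation noise
    seed: int = 0

    def sub_seeds(self) -> dict:
        state = np.random.SeedSequence(self.seed).generate_state(4) % (2**31)
        return {"cross_section": int(state[0]), "panel": int(state[1]),
                "bootstrap": int(state[2]), "imputation": int(state[3])}

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, frozenset):
                return sorted(o)
            if isinstance(o, pd.DataFrame):
                return o.to_dict("records")
            return asdict(o)
        text = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    cases: pd.DataFrame          # scheme × outcome case-change table
    qalys: pd.DataFrame          # scheme-level QALYs and £ value
    ylg: pd.DataFrame            # scheme-level years of life gained
    savings: pd.DataFrame        # scheme-level cost savings, two perspectives
    distributional: pd.DataFrame # scheme-level inequality/poverty statistics
    coefficients: panel_model.CoefficientBundle
    manifest: dict

    def table_hashes(self) -> dict:
        out = {}
        for name in ("cases", "qalys", "ylg", "savings", "distributional"):
            df: pd.DataFrame = getattr(self, name)
            out[name] = hashlib.sha256(
                df.round(9).to_csv(index=False).encode()).hexdigest()
        return out


def person_level_incomes(results: pd.DataFrame,
                         persons: pd.DataFrame) -> pd.DataFrame:
    """Adult persons with their household's equivalised incomes attached."""
    adults = persons[persons["age"] >= 18].copy()
    merged = adults.merge(
        results[["household_id", "net_equiv_base", "net_equiv_reform"]],
        on="household_id", how="left")
    return merged


def _estimate_coefficients(config: RunConfig, seeds: dict,
                           cache_dir: Path | None):
    """Fit (or load from cache) the income-health coefficient bundle."""
    cache_file = None
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_file = cache_dir / f"coeffs_{config.config_hash()}.json"
        if cache_file.exists():
            return panel_model.CoefficientBundle.from_json(cache_file), True
    panel_cfg = synthetic.PopulationConfig(**{
        **asdict(config.panel), "seed": seeds["panel"]})
    panel = synthetic.gen_panel(panel_cfg, config.truth, config.thresholds)
    panel = synthetic.make_balanced(panel, n_waves=panel_cfg.n_waves)
    bundle = panel_model.fit_bundle(
        panel, config.spec_mcs, config.spec_pcs,
        reps=config.bootstrap_reps, seed=seeds["bootstrap"])
    if cache_file is not None:
        bundle.to_json(cache_file)
    return bundle, False


def run_pipeline(config: RunConfig, out_dir=None) -> ResultsBundle:
    """Run all stages in order and assemble the results bundle.

    ``out_dir`` (optional) enables stage caching keyed by the config hash
    (the bootstrap refits dominate runtime) and is where :func:`report`
    will write the result files.
    """
    seeds = config.sub_seeds()
    cache_dir = Path(out_dir) / "cache" if out_dir is not None else None

    # 1. base population
    pop_cfg = synthetic.PopulationConfig(**{
        **asdict(config.population), "seed": seeds["cross_section"]})
    households, persons = synthetic.gen_cross_section(pop_cfg)

    # 2. income-health coefficients (panel generation + estimation)
    coeffs, from_cache = _estimate_coefficients(config, seeds, cache_dir)
    boot_pairs = coeffs.bootstrap_pairs()

    cases_rows, qaly_rows, ylg_rows, savings_rows, dist_rows = [], [], [], [], []
    for scheme in config.schemes:
        # 3. tax-benefit microsimulation
        results = taxben.compute_population(households, persons, scheme,
                                            config.params)
        dist = taxben.distributional_summary(results, persons)
        dist_rows.append({
            "scheme": scheme.name,
            "gini_base": dist["gini_base"],
            "gini_reform": dist["gini_reform"],
            "poverty_rate_base": dist["poverty_rate_base"],
            "poverty_rate_reform": dist["poverty_rate_reform"],
            "child_poverty_rate_base": dist.get("child_poverty_rate_base"),
            "child_poverty_rate_reform": dist.get("child_poverty_rate_reform"),
            "net_exchequer_cost_annual": dist["net_exchequer_cost_annual"],
            "mean_gain_q1": dist["quintiles"][0]["mean_change_cash"],
            "mean_gain_q5": dist["quintiles"][4]["mean_change_cash"],
        })

        # 4. health impact (imputation seed shared across schemes so the
        # baseline health of each person is the same under every reform)
        adults = person_level_incomes(results, persons)
        states = health_impact.build_states(
            adults, coeffs,
            income_base=adults["net_equiv_base"].to_numpy(),
            income_reform=adults["net_equiv_reform"].to_numpy(),
            residual_sd=config.residual_sd, seed=seeds["imputation"],
            scheme=scheme.name)

        reports = {}
        for outcome in ("mcs", "pcs"):
            cs = getattr(coeffs, outcome)
            rep = health_impact.cases_prevented(
                states, config.thresholds, outcome=outcome,
                bootstrap_coeffs=cs.bootstrap_replicates() or None,
                scheme=scheme.name)
            reports[outcome] = rep
            cases_rows.append({
                "scheme": scheme.name, "outcome": rep.outcome,
                "cases_base": rep.cases_base, "cases_reform": rep.cases_reform,
                "cases_prevented": rep.cases_prevented,
                "ci_lower": rep.ci_lower, "ci_upper": rep.ci_upper,
            })

        # 5. valuation
        vcfg = config.valuation
        du = valuation.sf6d_delta(
            states["delta_mcs"], states["delta_pcs"], vcfg.crosswalk,
            base_mcs=states["mcs_base"], base_pcs=states["pcs_base"])
        w = states["weight"].to_numpy()
        q = valuation.qalys_gained(du, w)
        q_reps = []
        for pair in boot_pairs:
            deltas = health_impact.predict_score_change(
                states["income_base"], states["income_reform"], pair,
                transform=pair.mcs.income_transform)
            du_r = valuation.sf6d_delta(
                deltas["delta_mcs"], deltas["delta_pcs"], vcfg.crosswalk,
                base_mcs=states["mcs_base"], base_pcs=states["pcs_base"])
            q_reps.append(valuation.qalys_gained(du_r, w))
        q_lo = float(np.percentile(q_reps, 2.5)) if q_reps else None
        q_hi = float(np.percentile(q_reps, 97.5)) if q_reps else None
        money = valuation.monetise(q, vcfg.value_per_qaly,
                                   vcfg.green_book_multiplier)
        qaly_rows.append({
            "scheme": scheme.name, "qalys": q,
            "ci_lower": q_lo, "ci_upper": q_hi,
            "value_gbp": money["value_gbp"], "value_bn": money["value_bn"],
            "green_book_value_bn": money["green_book_value_bn"],
        })

        ylg = valuation.years_of_life_gained(
            du, adults["sex"], adults["age_band"], vcfg.ylg_multipliers, w)
        ylg_rows.append({
            "scheme": scheme.name, "ylg": ylg,
            "ci_lower": ylg * q_lo / q if q_reps and q else None,
            "ci_upper": ylg * q_hi / q if q_reps and q else None,
        })

        sav = valuation.cost_savings(reports["mcs"], vcfg.cost_model)
        savings_rows.append({"scheme": scheme.name, **sav})

    manifest = {
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "master_seed": config.seed,
        "coefficients_from_cache": from_cache,
        "n_households": int(len(households)),
        "n_persons": int(len(persons)),
        "grossing_target": config.population.grossing_target,
        "bootstrap_reps": config.bootstrap_reps,
        "beta_between_mcs": coeffs.mcs.beta_between,
        "beta_between_pcs": coeffs.pcs.beta_between,
    }
    return ResultsBundle(
        cases=pd.DataFrame(cases_rows),
        qalys=pd.DataFrame(qaly_rows),
        ylg=pd.DataFrame(ylg_rows),
        savings=pd.DataFrame(savings_rows),
        distributional=pd.DataFrame(dist_rows),
        coefficients=coeffs,
        manifest=manifest,
    )


def _check_ci_order(df: pd.DataFrame, central: str, lo: str, hi: str) -> None:
    sub = df.dropna(subset=[lo, hi])
    bad = sub[(sub[lo] > sub[central]) | (sub[central] > sub[hi])]
    if len(bad):
        raise ValueError(f"CI ordering violated in rows: {bad.index.tolist()}")


def report(bundle: ResultsBundle, out_dir) -> list:
    """Write the bundle as CSV tables, a manifest and a text summary.

    Validates the lower ≤ central ≤ upper invariant in every emitted row;
    re-reporting a saved bundle produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _check_ci_order(bundle.cases, "cases_prevented", "ci_lower", "ci_upper")
    _check_ci_order(bundle.qalys, "qalys", "ci_lower", "ci_upper")
    _check_ci_order(bundle.savings, "nhs_pss", "nhs_pss_ci_lower", "nhs_pss_ci_upper")

    written = []
    for name in ("cases", "qalys", "ylg", "savings", "distributional"):
        path = out / f"{name}.csv"
        getattr(bundle, name).to_csv(path, index=False)
        written.append(path)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
    written.append(out / "manifest.json")
    bundle.coefficients.to_json(out / "coefficients.json")
    written.append(out / "coefficients.json")

    lines = ["Basic Income health microsimulation — results summary", ""]
    for _, r in bundle.cases.iterrows():
        lines.append(
            f"{r['scheme']}: {r['outcome']}: {r['cases_prevented']:,.0f} "
            f"cases prevented/year"
            + (f" (95% CI {r['ci_lower']:,.0f}–{r['ci_upper']:,.0f})"
               if pd.notna(r["ci_lower"]) else ""))
    for _, r in bundle.qalys.iterrows():
        lines.append(f"{r['scheme']}: {r['qalys']:,.0f} QALYs/year, "
                     f"£{r['value_bn']:.2f}bn at £30,000/QALY")
    for _, r in bundle.savings.iterrows():
        lines.append(f"{r['scheme']}: NHS/PSS savings £{r['nhs_pss']/1e6:,.0f}m; "
                     f"total £{r['total']/1e6:,.0f}m per year")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    written.append(out / "summary.txt")
    return written
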