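"""Within-between (Mundlak) panel regression of health on income.

The model separates net equivalised household income into a person-mean
("between") component and a deviation-from-own-mean ("within") component::

    y_it = a + b_w * (x_it - xbar_i) + b_b * xbar_i + g' z_it + u_i + e_it

where ``x`` is log (or linear) income, ``z`` the controls and ``u_i`` a
person random intercept.  Both income components enter one equation, so the
random-effects fit of this equation is the textbook within-between
estimator.  The "between" coefficient captures the association of permanent
income differences with health and is the one carried forward by the
microsimulation; the "within" coefficient captures transitory income
variation.

Estimators
----------
``random_effects``
    Feasible GLS on the balanced panel via Swamy-Arora quasi-demeaning:
    variance components are estimated from pooled-OLS residuals, each
    variable is partially demeaned by ``theta`` and OLS is run on the
    transformed data.  Exact GLS on balanced panels and fast enough to refit
    thousands of times in the bootstrap.
``pooled_ols_clustered``
    Pooled OLS with person-clustered standard errors, used as a cross-check
    (point estimates agree with GLS in the noise-free limit and are equally
    consistent).

Confidence intervals come from a percentile bootstrap that resamples
*persons* (all their waves together), matching the study's clustered
resampling design, with 1,000 repetitions by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "CoefficientSet",
    "CoefficientBundle",
    "decompose_income",
    "fit_within_between",
    "bootstrap_ci",
    "fit_bundle",
]

DEFAULT_CONTROLS = ["sex", "age_band", "education", "region", "employment_status"]
INCOME_FLOOR = 1.0  # £/month floor before the log transform


class CollinearDesignError(ValueError):
    """Raised when the design matrix is rank deficient; names the columns."""


@dataclass
class ModelSpec:
    """Specification of one income-health regression."""

    outcome: str = "mcs"                      # "mcs" or "pcs"
    income_transform: str = "log"             # "log" or "linear"
    controls: list = field(default_factory=lambda: list(DEFAULT_CONTROLS))
    include_lagged_case: bool = False
    estimator: str = "random_effects"         # or "pooled_ols_clustered"

    def __post_init__(self) -> None:
        if self.outcome not in ("mcs", "pcs"):
            raise ValueError("outcome must be 'mcs' or 'pcs'")
        if self.income_transform not in ("log", "linear"):
            raise ValueError("income_transform must be 'log' or 'linear'")
        if self.estimator not in ("random_effects", "pooled_ols_clustered"):
            raise ValueError("unknown estimator")


@dataclass
class CoefficientSet:
    """Fitted coefficients for one outcome; the contract consumed downstream.

    ``control_coefficients`` includes the intercept under ``"const"``.
    ``design_info`` records the categorical levels used, so the linear
    predictor can be evaluated on a new population without refitting.
    """

    outcome: str
    income_transform: str
    beta_within: float
    beta_between: float
    control_coefficients: dict
    ci_lower: dict = field(default_factory=dict)
    ci_upper: dict = field(default_factory=dict)
    n_individuals: int = 0
    n_observations: int = 0
    bootstrap_reps: int = 0
    design_info: dict = field(default_factory=dict)
    clustered_se: dict = field(default_factory=dict)
    bootstrap_betas: list = field(default_factory=list)  # [(b_within, b_between)]

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CoefficientSet":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and \
            str(source).endswith(".json") else source
        return cls(**json.loads(text))

    def replicate(self, beta_within: float, beta_between: float) -> "CoefficientSet":
        """A copy carrying one bootstrap replicate's income coefficients."""
        out = CoefficientSet(**{**asdict(self),
                                "beta_within": beta_within,
                                "beta_between": beta_between})
        out.bootstrap_betas = []
        return out

    def bootstrap_replicates(self) -> list:
        return [self.replicate(bw, bb) for bw, bb in self.bootstrap_betas]


@dataclass
class CoefficientBundle:
    """Coefficient sets for both outcomes (MCS and PCS)."""

    mcs: CoefficientSet
    pcs: CoefficientSet

    def to_json(self, path=None) -> str:
        text = json.dumps({"mcs": json.loads(self.mcs.to_json()),
                           "pcs": json.loads(self.pcs.to_json())}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CoefficientBundle":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and \
            str(source).endswith(".json") else source
        d = json.loads(text)
        return cls(mcs=CoefficientSet(**d["mcs"]), pcs=CoefficientSet(**d["pcs"]))

    def bootstrap_pairs(self) -> list:
        """Paired per-replicate bundles (MCS and PCS replicate k together)."""
        n = min(len(self.mcs.bootstrap_betas), len(self.pcs.bootstrap_betas))
        return [CoefficientBundle(self.mcs.replicate(*self.mcs.bootstrap_betas[k]),
                                  self.pcs.replicate(*self.pcs.bootstrap_betas[k]))
                for k in range(n)]


def transform_income(income, kind: str) -> np.ndarray:
    x = np.asarray(income, dtype=float)
    if kind == "log":
        return np.log(np.maximum(x, INCOME_FLOOR))
    return x


def decompose_income(panel: pd.DataFrame, transform: str = "log") -> pd.DataFrame:
    """Add ``x``, ``x_between`` (person mean) and ``x_within`` columns.

    Requires a balanced panel (every person observed the same number of
    waves).  By construction the per-person mean of ``x_within`` is zero and
    ``x_between + x_within`` reconstructs the transformed series exactly.
    """
    counts = panel.groupby("person_id")["wave"].nunique()
    if counts.nunique() > 1 or counts.min() < 2:
        bad = counts[counts != counts.max()]
        raise ValueError(
            f"panel is not balanced: {len(bad)} persons with fewer waves "
            f"(e.g. {dict(bad.head(3))})"
        )
    out = panel.copy()
    out["x"] = transform_income(out["net_equiv_income"], transform)
    out["x_between"] = out.groupby("person_id")["x"].transform("mean")
    out["x_within"] = out["x"] - out["x_between"]
    return out


def _build_design(panel: pd.DataFrame, spec: ModelSpec):
    """Design matrix, outcome vector, person ids and design metadata."""
    df = panel
    if "x_within" not in df.columns:
        df = decompose_income(df, spec.income_transform)
    if spec.include_lagged_case:
        df = df[df["wave"] > df["wave"].min()]

    y = df[spec.outcome].to_numpy(dtype=float)
    cols = {"const": np.ones(len(df))}
    design_info: dict = {"categorical": {}, "numeric": []}

    if np.ptp(df["x_within"].to_numpy()) < 1e-12:
        # zero within-variance: the within coefficient is undefined
        x_within_dropped = True
    else:
        cols["x_within"] = df["x_within"].to_numpy(dtype=float)
        x_within_dropped = False
    cols["x_between"] = df["x_between"].to_numpy(dtype=float)

    for c in spec.controls:
        if c not in df.columns:
            raise KeyError(f"control column {c!r} missing from panel")
        s = df[c]
        if s.dtype == bool or np.issubdtype(s.dtype, np.number):
            cols[c] = s.to_numpy(dtype=float)
            design_info["numeric"].append(c)
        else:
            levels = sorted(s.astype(str).unique())
            design_info["categorical"][c] = levels
            for lev in levels[1:]:  # first level is the reference
                cols[f"{c}[{lev}]"] = (s.astype(str) == lev).to_numpy(dtype=float)

    if spec.include_lagged_case:
        lag_col = f"prior_case_{spec.outcome}"
        if lag_col not in df.columns:
            raise KeyError(f"lagged case column {lag_col!r} missing from panel")
        cols[lag_col] = df[lag_col].to_numpy(dtype=float)
        design_info["numeric"].append(lag_col)

    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    pid = df["person_id"].to_numpy()
    return X, y, pid, names, design_info, x_within_dropped


def _check_rank(X: np.ndarray, names: list) -> None:
    from scipy.linalg import qr
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        offending = sorted(names[j] for j in piv[r:])
        raise CollinearDesignError(
            f"design matrix is rank deficient; offending columns: {offending}"
        )


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _theta_swamy_arora(X, y, pid) -> float:
    """Quasi-demeaning weight from pooled-OLS residual variance components."""
    beta = _ols(X, y)
    e = y - X @ beta
    order = np.argsort(pid, kind="stable")
    e_o, pid_o = e[order], pid[order]
    _, start, count = np.unique(pid_o, return_index=True, return_counts=True)
    T = int(count[0])
    n = len(count)
    ebar = np.add.reduceat(e_o, start) / count
    within_ss = float((e_o**2).sum() - (count * ebar**2).sum())
    k = X.shape[1]
    sigma2_e = within_ss / max(len(y) - n - k + 1, 1)
    sigma2_1 = T * float((ebar**2).sum()) / max(n - k, 1)
    sigma2_a = max((sigma2_1 - sigma2_e) / T, 0.0)
    if sigma2_e <= 1e-12:
        return 0.0
    return 1.0 - np.sqrt(sigma2_e / (sigma2_e + T * sigma2_a))


def _quasi_demean(M: np.ndarray, pid: np.ndarray, theta: float) -> np.ndarray:
    """Partial within-transform y - theta*ybar_i; pid must be group-sorted."""
    if theta == 0.0:
        return M
    _, start, count = np.unique(pid, return_index=True, return_counts=True)
    sums = np.add.reduceat(M, start, axis=0)
    means = sums / count[:, None] if M.ndim == 2 else sums / count
    return M - theta * np.repeat(means, count, axis=0)


def _clustered_se(X, y, beta, pid) -> np.ndarray:
    """Person-clustered (CR1) standard errors for pooled OLS."""
    e = y - X @ beta
    XtX_inv = np.linalg.inv(X.T @ X)
    _, start = np.unique(pid, return_index=True)
    Xe = np.add.reduceat(X * e[:, None], start, axis=0)
    meat = Xe.T @ Xe
    n_clusters = Xe.shape[0]
    n, k = X.shape
    adj = (n_clusters / (n_clusters - 1)) * ((n - 1) / (n - k))
    V = adj * XtX_inv @ meat @ XtX_inv
    return np.sqrt(np.diag(V))


def fit_within_between(panel: pd.DataFrame, spec: ModelSpec) -> CoefficientSet:
    """Fit the within-between model; returns point estimates.

    Raises :class:`CollinearDesignError` naming offending columns on a rank
    deficient design.  If the panel has zero within-person income variance,
    ``beta_within`` is reported as NaN (undefined), not zero.
    """
    X, y, pid, names, design_info, wdropped = _build_design(panel, spec)
    _check_rank(X, names)
    order = np.argsort(pid, kind="stable")
    X, y, pid = X[order], y[order], pid[order]

    if spec.estimator == "random_effects":
        theta = _theta_swamy_arora(X, y, pid)
        Xs = _quasi_demean(X, pid, theta)
        ys = _quasi_demean(y[:, None], pid, theta)[:, 0]
        beta = _ols(Xs, ys)
        se = _clustered_se(Xs, ys, beta, pid)
    else:
        beta = _ols(X, y)
        se = _clustered_se(X, y, beta, pid)

    coefs = dict(zip(names, beta.astype(float)))
    ses = dict(zip(names, se.astype(float)))
    n_ind = int(pd.unique(pid).size)
    return CoefficientSet(
        outcome=spec.outcome,
        income_transform=spec.income_transform,
        beta_within=float("nan") if wdropped else coefs.pop("x_within"),
        beta_between=coefs.pop("x_between"),
        control_coefficients=coefs,
        n_individuals=n_ind,
        n_observations=len(y),
        design_info=design_info,
        clustered_se=ses,
    )


def bootstrap_ci(panel: pd.DataFrame, spec: ModelSpec, reps: int = 1000,
                 seed: int = 0) -> CoefficientSet:
    """Percentile-bootstrap 95% CIs, resampling persons with replacement.

    Individuals (all their waves together) are the resampling unit.  For the
    GLS estimator the variance-component weight ``theta`` is held at its
    full-sample estimate across replicates; each replicate then solves the
    (fixed-transform) normal equations assembled from per-person Gram blocks
    weighted by multinomial resampling counts — algebraically identical to
    refitting on the stacked resampled rows.  Replicates with a singular
    design are dropped and counted; more than 5% dropped is an error.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    point = fit_within_between(panel, spec)
    X, y, pid, names, _, wdropped = _build_design(panel, spec)
    order = np.argsort(pid, kind="stable")
    X, y, pid = X[order], y[order], pid[order]

    if spec.estimator == "random_effects":
        theta = _theta_swamy_arora(X, y, pid)
        X = _quasi_demean(X, pid, theta)
        y = _quasi_demean(y[:, None], pid, theta)[:, 0]

    _, start, count = np.unique(pid, return_index=True, return_counts=True)
    n = len(start)
    k = X.shape[1]
    # per-person Gram blocks
    G = np.empty((n, k, k))
    h = np.empty((n, k))
    for i, (s, c) in enumerate(zip(start, count)):
        Xi = X[s:s + c]
        G[i] = Xi.T @ Xi
        h[i] = Xi.T @ y[s:s + c]

    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    draws = np.zeros((reps, k))
    dropped = 0
    p = np.full(n, 1.0 / n)
    for r in range(reps):
        counts = rng.multinomial(n, p).astype(float)
        XtX = np.tensordot(counts, G, axes=1)
        Xty = counts @ h
        try:
            draws[r] = np.linalg.solve(XtX, Xty)
        except np.linalg.LinAlgError:
            draws[r] = np.nan
            dropped += 1
    if dropped > 0.05 * reps:
        raise RuntimeError(f"{dropped}/{reps} bootstrap replicates degenerate")

    valid = draws[~np.isnan(draws).any(axis=1)]
    lo = np.nanpercentile(valid, 2.5, axis=0)
    hi = np.nanpercentile(valid, 97.5, axis=0)
    ci_lower = dict(zip(names, lo.astype(float)))
    ci_upper = dict(zip(names, hi.astype(float)))

    iw = names.index("x_within") if not wdropped else None
    ib = names.index("x_between")
    point.ci_lower = {("beta_within" if k_ == "x_within" else
                       "beta_between" if k_ == "x_between" else k_): v
                      for k_, v in ci_lower.items()}
    point.ci_upper = {("beta_within" if k_ == "x_within" else
                       "beta_between" if k_ == "x_between" else k_): v
                      for k_, v in ci_upper.items()}
    point.bootstrap_reps = int(len(valid))
    point.bootstrap_betas = [
        (float(row[iw]) if iw is not None else float("nan"), float(row[ib]))
        for row in valid
    ]
    return point


def fit_bundle(panel: pd.DataFrame, spec_mcs: ModelSpec | None = None,
               spec_pcs: ModelSpec | None = None, reps: int = 1000,
               seed: int = 0) -> CoefficientBundle:
    """Fit both outcomes with bootstrap CIs; the pipeline's estimation stage."""
    spec_mcs = spec_mcs or ModelSpec(outcome="mcs")
    spec_pcs = spec_pcs or ModelSpec(outcome="pcs")
    return CoefficientBundle(
        mcs=bootstrap_ci(panel, spec_mcs, reps=reps, seed=seed),
        pcs=bootstrap_ci(panel, spec_pcs, reps=reps, seed=seed + 1),
    )
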