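"""Recursive path-model fitting for the six engagement scores (EMODEB).

EMODEB is a fixed 6-variable, 9-edge recursive path model (a linear Gaussian
DAG on observed variables, no latents): gaze toward activity (GAct) is
exogenous and drives lean toward activity (LTAct), reach out activity
(RoAct), and the three affect counterparts (GAct_gsup, LTAct_postsup,
RoAct_qogest).

Estimation minimizes the ML covariance-structure discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over edge coefficients and (log-)variances, with the sample covariance S on
the n-1 denominator and chi2 = (n-1) F_ML at the optimum. For a recursive
DAG with uncorrelated errors the likelihood factorizes over child-on-parents
regressions, so per-equation OLS is both the start value and an independent
oracle for the optimizer. Standard errors come from the inverse observed
information (2/(n-1) times the inverse Hessian of F_ML); standardized
estimates rescale by model-implied standard deviations.

Fit indices compare the model chi2/df to the independence null (all
covariances zero, variances free; df_null = p(p-1)/2):

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1)))
    NFI   = (chi2_null - chi2) / chi2_null
    CFI   = 1 - max(chi2 - df, 0) / max(chi2_null - df_null, chi2 - df, 0)
    RFI   = 1 - (chi2/df) / (chi2_null/df_null)
    PNFI  = (df / df_null) NFI

Multivariate outliers are removed before fitting by Mahalanobis distance
D^2 = (x - xbar)' S^-1 (x - xbar), dropping either the k farthest rows from
the centroid (default) or those above a chi-square quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    ConditioningError,
    DegeneracyError,
    OptimizationError,
    StructureError,
)
from .scores import SCORE_NAMES, ScoreTable

__all__ = [
    "PathModel",
    "SampleMoments",
    "SemFit",
    "FitIndices",
    "OutlierReport",
    "RegressionResult",
    "emodeb_model",
    "model_df",
    "sample_moments",
    "mahalanobis_filter",
    "fit_path_model",
    "fit_indices",
    "follow_up_regression",
]


@dataclass(frozen=True)
class PathModel:
    """A recursive (acyclic) path model on observed variables."""

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]  # (parent, child)
    exogenous: frozenset[str]

    def __post_init__(self) -> None:
        names = set(self.variables)
        for parent, child in self.edges:
            if parent not in names or child not in names:
                raise StructureError(f"edge ({parent}, {child}) uses unknown variable")
        for v in self.exogenous:
            if self.parents(v):
                raise StructureError(f"exogenous variable {v} has parents")
        endo = [v for v in self.variables if v not in self.exogenous]
        for v in endo:
            if not self.parents(v):
                raise StructureError(f"endogenous variable {v} has no parents")
        self.topological_order()  # raises on cycles

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.edges if c == v)

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if v not in self.exogenous)

    def topological_order(self) -> tuple[str, ...]:
        order: list[str] = []
        placed: set[str] = set()
        remaining = list(self.variables)
        while remaining:
            ready = [v for v in remaining if set(self.parents(v)) <= placed]
            if not ready:
                raise StructureError(f"path model contains a cycle among {remaining}")
            for v in ready:
                order.append(v)
                placed.add(v)
                remaining.remove(v)
        return tuple(order)


EMODEB_VARIABLES = SCORE_NAMES

_EMODEB_EDGES = (
    ("GAct", "LTAct"),
    ("LTAct", "RoAct"),
    ("GAct", "RoAct"),
    ("GAct", "GAct_gsup"),
    ("RoAct", "RoAct_qogest"),
    ("GAct_gsup", "LTAct_postsup"),
    ("LTAct_postsup", "RoAct_qogest"),
    ("GAct_gsup", "RoAct_qogest"),
    ("LTAct", "LTAct_postsup"),
)


def emodeb_model() -> PathModel:
    """The fixed 9-edge engagement path model with GAct exogenous."""
    return PathModel(
        variables=tuple(EMODEB_VARIABLES),
        edges=_EMODEB_EDGES,
        exogenous=frozenset({"GAct"}),
    )


def model_df(m: PathModel) -> int:
    """Degrees of freedom: covariance moments minus free parameters.

    Free parameters are the edge coefficients, one variance per exogenous
    variable, and one error variance per endogenous variable.
    """
    p = len(m.variables)
    moments = p * (p + 1) // 2
    free = len(m.edges) + len(m.exogenous) + len(m.endogenous)
    return moments - free


@dataclass
class SampleMoments:
    n: int
    variables: tuple[str, ...]
    means: np.ndarray
    cov: np.ndarray  # n-1 denominator


def _as_matrix(table, variables: Sequence[str]) -> tuple[np.ndarray, list]:
    if isinstance(table, ScoreTable):
        df = table.to_frame()
        keys = [(r.session_id, r.participant_id) for r in table.rows]
    elif isinstance(table, pd.DataFrame):
        df = table
        keys = list(df.index)
    else:
        raise TypeError("expected a ScoreTable or DataFrame")
    return df[list(variables)].to_numpy(dtype=float), keys


def sample_moments(table, variables: Sequence[str] = EMODEB_VARIABLES) -> SampleMoments:
    x, _ = _as_matrix(table, variables)
    n = x.shape[0]
    if n < 2:
        raise DegeneracyError("need at least two observations")
    return SampleMoments(
        n=n,
        variables=tuple(variables),
        means=x.mean(axis=0),
        cov=np.cov(x, rowvar=False, ddof=1),
    )


# ---------------------------------------------------------------------------
# Mahalanobis outlier exclusion
# ---------------------------------------------------------------------------


@dataclass
class OutlierReport:
    distances: "pd.Series"  # D^2 per row, indexed by (session, participant) key
    excluded_keys: list
    rule: str


def mahalanobis_filter(
    table: ScoreTable,
    k: int = 7,
    rule: str = "fixed_k",
    alpha: float = 0.05,
    variables: Sequence[str] = EMODEB_VARIABLES,
) -> tuple[ScoreTable, OutlierReport]:
    """Drop the farthest observations from the multivariate centroid.

    ``fixed_k`` removes the k largest squared distances (ties broken by key
    order); ``chi2_quantile`` removes rows with D^2 above the upper-alpha
    chi-square quantile on len(variables) degrees of freedom.
    """
    x, keys = _as_matrix(table, variables)
    n, p = x.shape
    if n <= p:
        raise DegeneracyError(f"need more rows ({n}) than variables ({p})")
    centered = x - x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    if np.linalg.cond(cov) > 1e12:
        raise ConditioningError("score covariance is (near-)singular")
    solve = np.linalg.solve(cov, centered.T)
    d2 = np.einsum("ij,ji->i", centered, solve)
    distances = pd.Series(d2, index=pd.Index(keys, tupleize_cols=False))

    if rule == "fixed_k":
        order = sorted(range(n), key=lambda i: (-d2[i], keys[i]))
        excluded_idx = set(order[:k])
    elif rule == "chi2_quantile":
        cut = stats.chi2.ppf(1.0 - alpha, df=p)
        excluded_idx = {i for i in range(n) if d2[i] > cut}
    else:
        raise ValueError(f"unknown rule {rule!r}")

    kept_rows = [table.rows[i] for i in range(n) if i not in excluded_idx]
    excluded_keys = [keys[i] for i in sorted(excluded_idx)]
    return (
        ScoreTable(rows=kept_rows),
        OutlierReport(distances=distances, excluded_keys=excluded_keys, rule=rule),
    )


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------


class FitIndices(NamedTuple):
    rmsea: float
    nfi: float
    cfi: float
    rfi: float
    pnfi: float


@dataclass
class SemFit:
    model: PathModel
    estimates: dict[tuple[str, str], float]
    std_estimates: dict[tuple[str, str], float]
    se: dict[tuple[str, str], float]
    cr: dict[tuple[str, str], float]
    p_edge: dict[tuple[str, str], float]
    resid_var: dict[str, float]
    exo_var: dict[str, float]
    chi2: float
    df: int
    p_model: float
    rmsea: float
    nfi: float
    cfi: float
    rfi: float
    pnfi: float
    n_used: int
    converged: bool
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "edges": [
                {
                    "path": f"{p} -> {c}",
                    "estimate": self.estimates[(p, c)],
                    "std_estimate": self.std_estimates[(p, c)],
                    "se": self.se[(p, c)],
                    "cr": self.cr[(p, c)],
                    "p": self.p_edge[(p, c)],
                }
                for p, c in self.model.edges
            ],
            "resid_var": self.resid_var,
            "exo_var": self.exo_var,
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p_model,
            "rmsea": self.rmsea,
            "nfi": self.nfi,
            "cfi": self.cfi,
            "rfi": self.rfi,
            "pnfi": self.pnfi,
            "n_used": self.n_used,
            "notes": self.notes,
        }


def _implied_cov(m: PathModel, coeffs: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Sigma(theta) = (I - B)^-1 Psi (I - B)^-T for the DAG parameterization."""
    p = len(m.variables)
    idx = {v: i for i, v in enumerate(m.variables)}
    B = np.zeros((p, p))
    for (parent, child), b in zip(m.edges, coeffs):
        B[idx[child], idx[parent]] = b
    psi = np.diag(variances)
    inv = np.linalg.inv(np.eye(p) - B)
    return inv @ psi @ inv.T


def _ols_start(m: PathModel, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-equation OLS coefficients and residual variances computed from S."""
    idx = {v: i for i, v in enumerate(m.variables)}
    coeffs = np.zeros(len(m.edges))
    variances = np.zeros(len(m.variables))
    for v in m.exogenous:
        variances[idx[v]] = S[idx[v], idx[v]]
    for v in m.endogenous:
        pa = [idx[p] for p in m.parents(v)]
        i = idx[v]
        b = np.linalg.solve(S[np.ix_(pa, pa)], S[pa, i])
        variances[i] = S[i, i] - S[pa, i] @ b
        for e, (parent, child) in enumerate(m.edges):
            if child == v:
                coeffs[e] = b[m.parents(v).index(parent)]
    return coeffs, variances


def _fml(S: np.ndarray, sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(np.linalg.solve(sigma, S)) - logdet_s - p)


def _num_grad(f, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _num_hess(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        for j in range(i, k):
            ej = np.zeros(k)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit_path_model(m: PathModel, table, variables: Sequence[str] | None = None) -> SemFit:
    """Maximum-likelihood fit of a recursive path model to score data.

    The optimization runs on the correlation-scaled covariance (F_ML is
    invariant under diagonal rescaling for this model class, and the DAG
    parameterization rescales along), with log-variance coordinates for
    positivity and per-equation OLS start values; estimates are mapped back
    to the original scale.
    """
    if variables is None:
        variables = m.variables
    if isinstance(table, SampleMoments):
        S_raw, n = table.cov, table.n
        if tuple(table.variables) != tuple(variables):
            raise StructureError("moment variables do not match the model")
    else:
        mom = sample_moments(table, variables)
        S_raw, n = mom.cov, mom.n
    p = len(variables)
    n_free = len(m.edges) + p
    if n <= n_free:
        raise DegeneracyError(f"n = {n} too small for {n_free} free parameters")
    eigvals = np.linalg.eigvalsh(S_raw)
    if eigvals.min() <= 1e-10 * max(eigvals.max(), 1.0):
        raise ConditioningError("sample covariance is not positive definite")

    d = np.sqrt(np.diag(S_raw))
    S = S_raw / np.outer(d, d)  # correlation-scaled; F_ML invariant
    n_edges = len(m.edges)

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return theta[:n_edges], np.exp(theta[n_edges:])

    def objective(theta: np.ndarray) -> float:
        coeffs, variances = unpack(theta)
        return _fml(S, _implied_cov(m, coeffs, variances))

    b0, v0 = _ols_start(m, S)
    if (v0 <= 0).any():
        raise ConditioningError("OLS start produced non-positive variances")
    theta0 = np.concatenate([b0, np.log(v0)])
    res = optimize.minimize(
        objective,
        theta0,
        jac=lambda t: _num_grad(objective, t),
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    theta = res.x if res.fun <= objective(theta0) else theta0
    grad_norm = float(np.linalg.norm(_num_grad(objective, theta)))
    converged = grad_norm < 1e-6
    if not converged and res.fun > objective(theta0) + 1e-8:
        raise OptimizationError(
            f"likelihood optimization failed (gradient norm {grad_norm:.2e})"
        )

    coeffs_std_scale, variances_std_scale = unpack(theta)
    fmin = objective(theta)
    chi2 = max((n - 1) * fmin, 0.0)
    df = model_df(m)
    p_model = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    # observed information: cov(theta) = 2/(n-1) H^-1 in the scaled space
    H = _num_hess(objective, theta)
    try:
        cov_theta = 2.0 / (n - 1) * np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError("information matrix is singular") from exc
    se_scaled = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))

    # map back to the original scale: b = b_std d_child / d_parent
    idx = {v: i for i, v in enumerate(variables)}
    estimates, se, cr, p_edge = {}, {}, {}, {}
    for e, (parent, child) in enumerate(m.edges):
        scale = d[idx[child]] / d[idx[parent]]
        estimates[(parent, child)] = float(coeffs_std_scale[e] * scale)
        se[(parent, child)] = float(se_scaled[e] * scale)
        if se[(parent, child)] > 0:
            cr[(parent, child)] = estimates[(parent, child)] / se[(parent, child)]
        else:
            cr[(parent, child)] = math.inf * np.sign(estimates[(parent, child)] or 1.0)
        p_edge[(parent, child)] = float(2.0 * stats.norm.sf(abs(cr[(parent, child)])))

    variances_raw = variances_std_scale * d**2
    sigma_raw = _implied_cov(
        m,
        np.array([estimates[e] for e in m.edges]),
        variances_raw,
    )
    sd_implied = np.sqrt(np.diag(sigma_raw))
    std_estimates = {
        (parent, child): float(
            estimates[(parent, child)] * sd_implied[idx[parent]] / sd_implied[idx[child]]
        )
        for parent, child in m.edges
    }
    resid_var = {v: float(variances_raw[idx[v]]) for v in m.endogenous}
    exo_var = {v: float(variances_raw[idx[v]]) for v in m.exogenous}

    # independence null: Sigma = diag(S); F_null = -ln|R|
    sign, logdet_R = np.linalg.slogdet(S)
    chi2_null = max(-(n - 1) * logdet_R, 0.0)
    df_null = p * (p - 1) // 2
    if df > 0:
        idxs = fit_indices(chi2, df, chi2_null, df_null, n)
    else:
        # saturated model: perfect fit by construction; RFI is undefined
        idxs = FitIndices(rmsea=0.0, nfi=1.0, cfi=1.0, rfi=float("nan"), pnfi=0.0)

    notes = [
        "unstandardized and standardized estimates both reported; "
        "PNFI uses the standard (df/df_null)*NFI parsimony ratio",
    ]
    return SemFit(
        model=m,
        estimates=estimates,
        std_estimates=std_estimates,
        se=se,
        cr=cr,
        p_edge=p_edge,
        resid_var=resid_var,
        exo_var=exo_var,
        chi2=chi2,
        df=df,
        p_model=p_model,
        rmsea=idxs.rmsea,
        nfi=idxs.nfi,
        cfi=idxs.cfi,
        rfi=idxs.rfi,
        pnfi=idxs.pnfi,
        n_used=n,
        converged=converged,
        notes=notes,
    )


def fit_indices(
    chi2: float, df: int, chi2_null: float, df_null: int, n: int
) -> FitIndices:
    """RMSEA and the incremental indices against the independence null."""
    if df <= 0 or df_null <= 0:
        raise DegeneracyError("df and df_null must be positive")
    if chi2_null <= 0:
        raise DegeneracyError("degenerate null model (chi2_null <= 0)")
    rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
    nfi = (chi2_null - chi2) / chi2_null
    denom = max(chi2_null - df_null, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    rfi = 1.0 - (chi2 / df) / (chi2_null / df_null)
    pnfi = (df / df_null) * nfi
    return FitIndices(rmsea=rmsea, nfi=nfi, cfi=cfi, rfi=rfi, pnfi=pnfi)


# ---------------------------------------------------------------------------
# follow-up simple regressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    beta_std: float
    t: float
    df: int
    p: float


def follow_up_regression(x: str, y: str, table) -> RegressionResult:
    """Standardized simple regression of y on x (beta = Pearson r, df = n - 2)."""
    data, _ = _as_matrix(table, (x, y))
    n = data.shape[0]
    if n < 3:
        raise DegeneracyError("need at least three observations")
    xv, yv = data[:, 0], data[:, 1]
    if np.std(xv, ddof=1) == 0:
        raise DegeneracyError(f"predictor {x!r} has zero variance")
    if np.std(yv, ddof=1) == 0:
        raise DegeneracyError(f"response {y!r} has zero variance")
    r = float(np.corrcoef(xv, yv)[0, 1])
    df = n - 2
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0:
        return RegressionResult(beta_std=r, t=math.inf * np.sign(r), df=df, p=0.0)
    t = r * math.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return RegressionResult(beta_std=r, t=t, df=df, p=p)
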