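"""Generalized linear mixed models with a single random intercept.

Every local model in the food-web SEM is either a Poisson regression with
a log sampling-effort offset or a binomial-logit regression of a bounded
score (percentage cover out of 100, seed index out of 5), in both cases
with a normally distributed random intercept for trapping trip to absorb
repeated-measures correlation.  The random effect is integrated out by a
Laplace approximation: for each trip level the scalar conditional mode is
found by Newton's method, and the marginal log-likelihood is

    l(beta, sigma) = sum_j [ l_j(b_j) - b_j^2 / (2 sigma^2) ]
                     - 1/2 sum_j log(1 + sigma^2 W_j),

where ``l_j`` is the conditional log-likelihood of trip ``j``, ``b_j`` its
conditional mode, and ``W_j`` the summed GLM working weight at the mode.
The ``log1p`` form is exact at the sigma = 0 boundary, where the model
collapses to an ordinary GLM; that limit is solved by this module's own
iteratively reweighted least squares (IRLS) routine, which also provides
starting values for the mixed fit.

Binomial responses here are grid-averaged scores, so non-integer
"successes" are accepted throughout (a quasi-likelihood reading; the
kernel and deviance formulas are unchanged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln, xlogy
from scipy.stats import norm

from .model_graph import NodeSpec

__all__ = [
    "FittedNode",
    "fit_node",
    "deviance_explained",
    "standardize_predictors",
    "RATE_RULES",
    "irls_glm",
]

#: derived rate column -> (count column, effort column, scale)
RATE_RULES = {
    "mulgara_per_100tn": ("mulgara", "trap_nights", 100.0),
    "rodents_per_100tn": ("rodents", "trap_nights", 100.0),
    "cat_per_cn": ("cat", "camera_nights", 1.0),
    "fox_per_cn": ("fox", "camera_nights", 1.0),
    "dingo_per_cn": ("dingo", "camera_nights", 1.0),
}

_SIGMA_SINGULAR = 1e-4


def standardize_predictors(spec: NodeSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Compute the effort-standardised rate columns a node's formula uses.

    Counts entering as predictors are converted to rates exactly as the
    model formulas write them: captures per 100 trap-nights, photographs
    per camera-night.  If the node flags z-transformation, its numeric
    predictor columns (interactions included, computed first) are centred
    and scaled to unit standard deviation.
    """
    out = data.copy()
    needed = set()
    for term in spec.predictors:
        needed.update(term.split(":"))
    for col in needed:
        if col in out.columns or col not in RATE_RULES:
            continue
        count_col, effort_col, scale = RATE_RULES[col]
        if count_col not in out.columns or effort_col not in out.columns:
            continue
        effort = out[effort_col].to_numpy(float)
        if np.any(effort <= 0):
            bad = int(np.sum(effort <= 0))
            raise ValueError(
                f"{bad} rows with non-positive {effort_col!r}; cannot "
                f"standardize {count_col!r} for effort"
            )
        out[col] = out[count_col].to_numpy(float) / effort * scale
    for term in spec.predictors:
        if ":" in term and term not in out.columns:
            a, b = term.split(":")
            out[term] = out[a].to_numpy(float) * out[b].to_numpy(float)
    if spec.z_transform_predictors:
        for term in spec.predictors:
            if term in spec.categorical:
                continue
            x = out[term].to_numpy(float)
            sd = np.nanstd(x, ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"cannot z-transform constant column {term!r}")
            out[term] = (x - np.nanmean(x)) / sd
    return out


@dataclass
class Design:
    """Assembled numeric design for one node fit."""

    X: np.ndarray
    y: np.ndarray            # counts, or binomial successes (may be non-integer)
    offset_log: np.ndarray   # log effort for Poisson nodes, zeros otherwise
    trials: np.ndarray       # binomial denominators per row (ones for Poisson)
    group_idx: np.ndarray
    n_groups: int
    columns: list[str]
    term_columns: dict[str, list[int]]
    family: str
    group_levels: np.ndarray
    z_stats: dict | None = None  # term -> (mean, sd) used for z-transform
    index: np.ndarray | None = None  # row labels kept after listwise deletion
    ll_const: float = 0.0  # data-only normalising constant of the loglik


def build_design(spec: NodeSpec, data: pd.DataFrame) -> Design:
    """Build the numeric design matrix for a node, listwise-dropping rows
    with missing values and expanding categorical terms into dummies.

    Z-transformation (red-fox node) is applied here, on the analysis rows
    that survive listwise deletion, so the recorded centring constants
    match the data the likelihood actually saw.
    """
    raw_spec = spec
    if spec.z_transform_predictors:
        spec_fields = dict(spec.__dict__)
        spec_fields["z_transform_predictors"] = False
        spec = NodeSpec(**spec_fields)
    data = standardize_predictors(spec, data)
    cols_needed = [spec.response, spec.random_factor]
    if spec.offset:
        cols_needed.append(spec.offset)
    for term in spec.predictors:
        cols_needed.append(term)
    missing = [c for c in cols_needed if c not in data.columns]
    if missing:
        raise KeyError(f"node {spec.name!r}: missing columns {missing}")
    sub = data[list(dict.fromkeys(cols_needed))]
    n_before = len(sub)
    sub = sub.dropna()
    n_drop = n_before - len(sub)
    if n_drop:
        warnings.warn(
            f"node {spec.name}: dropped {n_drop} rows with missing values",
            stacklevel=2,
        )
    if len(sub) == 0:
        raise ValueError(f"node {spec.name!r}: no complete rows")

    z_stats: dict[str, tuple[float, float]] | None = None
    if raw_spec.z_transform_predictors:
        sub = sub.copy()
        z_stats = {}
        for term in spec.predictors:
            if term in spec.categorical:
                continue
            x = sub[term].to_numpy(float)
            mean, sd = float(x.mean()), float(x.std(ddof=1))
            if sd == 0:
                raise ValueError(f"cannot z-transform constant column {term!r}")
            sub[term] = (x - mean) / sd
            z_stats[term] = (mean, sd)

    pieces = [np.ones(len(sub))]
    names = ["(Intercept)"]
    term_columns: dict[str, list[int]] = {}
    for term in spec.predictors:
        if term in spec.categorical:
            levels = np.sort(sub[term].unique())
            idxs = []
            for lev in levels[1:]:
                pieces.append((sub[term] == lev).to_numpy(float))
                idxs.append(len(names))
                names.append(f"{term}[{lev}]")
            term_columns[term] = idxs
        else:
            pieces.append(sub[term].to_numpy(float))
            term_columns[term] = [len(names)]
            names.append(term)
    X = np.column_stack(pieces)

    y = sub[spec.response].to_numpy(float)
    if spec.family == "poisson":
        effort = sub[spec.offset].to_numpy(float)
        if np.any(effort <= 0):
            raise ValueError(f"node {spec.name!r}: non-positive offset values")
        offset_log = np.log(effort)
        trials = np.ones(len(sub))
    else:
        m = float(spec.binomial_denominator)
        if np.any((y < 0) | (y > m)):
            raise ValueError(
                f"node {spec.name!r}: response outside [0, {m}]"
            )
        offset_log = np.zeros(len(sub))
        trials = np.full(len(sub), m)

    if spec.family == "poisson":
        ll_const = float(-np.sum(gammaln(y + 1.0)))
    else:
        m = trials
        ll_const = float(
            np.sum(gammaln(m + 1.0) - gammaln(y + 1.0) - gammaln(m - y + 1.0))
        )

    levels, group_idx = np.unique(sub[spec.random_factor].to_numpy(), return_inverse=True)
    return Design(
        X=X,
        y=y,
        offset_log=offset_log,
        trials=trials,
        group_idx=group_idx,
        n_groups=len(levels),
        columns=names,
        term_columns=term_columns,
        family=spec.family,
        group_levels=levels,
        z_stats=z_stats,
        index=sub.index.to_numpy(),
        ll_const=ll_const,
    )


# ---------------------------------------------------------------------------
# likelihood kernels


def _cond_loglik(family, y, trials, eta):
    if family == "poisson":
        return float(np.sum(y * eta - np.exp(eta)))
    return float(np.sum(y * eta - trials * np.logaddexp(0.0, eta)))


def _mu_and_weight(family, trials, eta):
    if family == "poisson":
        mu = np.exp(eta)
        return mu, mu
    p = expit(eta)
    return trials * p, trials * p * (1.0 - p)


def _conditional_modes(family, y, trials, eta0, group_idx, n_groups, sigma2):
    """Newton solve for the per-group random-effect modes (vectorised)."""
    b = np.zeros(n_groups)
    for _ in range(100):
        eta = eta0 + b[group_idx]
        mu, w = _mu_and_weight(family, trials, eta)
        grad = np.bincount(group_idx, weights=y - mu, minlength=n_groups) - b / sigma2
        hess = np.bincount(group_idx, weights=w, minlength=n_groups) + 1.0 / sigma2
        step = grad / hess
        np.clip(step, -4.0, 4.0, out=step)
        b += step
        if np.max(np.abs(step)) < 1e-11:
            break
    return b


def _laplace_loglik(beta, sigma, design: Design):
    eta0 = design.X @ beta + design.offset_log
    if sigma < 1e-8:
        return design.ll_const + _cond_loglik(design.family, design.y, design.trials, eta0)
    sigma2 = sigma * sigma
    b = _conditional_modes(
        design.family, design.y, design.trials, eta0,
        design.group_idx, design.n_groups, sigma2,
    )
    eta = eta0 + b[design.group_idx]
    ll = _cond_loglik(design.family, design.y, design.trials, eta)
    ll -= 0.5 * float(np.sum(b * b)) / sigma2
    _, w = _mu_and_weight(design.family, design.trials, eta)
    W = np.bincount(design.group_idx, weights=w, minlength=design.n_groups)
    ll -= 0.5 * float(np.sum(np.log1p(sigma2 * W)))
    return ll + design.ll_const


def irls_glm(design: Design, tol: float = 1e-12, max_iter: int = 100):
    """Plain GLM fit (no random effect) by iteratively reweighted least
    squares with the canonical link; converges quadratically."""
    X, y, off, m = design.X, design.y, design.offset_log, design.trials
    if design.family == "poisson":
        eta = np.log(y + 0.5) - 0  # includes implicit offset start
        eta = np.maximum(eta, off - 10)
    else:
        p0 = (y + 0.5) / (m + 1.0)
        eta = np.log(p0 / (1 - p0))
    beta = np.zeros(X.shape[1])
    last = -np.inf
    for _ in range(max_iter):
        mu, w = _mu_and_weight(design.family, m, eta)
        w = np.maximum(w, 1e-10)
        z = (eta - off) + (y - mu) / w
        beta, *_ = np.linalg.lstsq(np.sqrt(w)[:, None] * X, np.sqrt(w) * z, rcond=None)
        eta = X @ beta + off
        ll = _cond_loglik(design.family, y, m, eta)
        if abs(ll - last) < tol * (abs(ll) + 1.0):
            break
        last = ll
    mu, w = _mu_and_weight(design.family, m, eta)
    fisher = X.T @ (X * w[:, None])
    return beta, fisher


def _conditional_deviance(family, y, trials, eta):
    """Summed unit deviance at the conditional means (0*log 0 = 0)."""
    if family == "poisson":
        mu = np.exp(eta)
        return float(2.0 * np.sum(xlogy(y, y / mu) - (y - mu)))
    mu = trials * expit(eta)
    return float(
        2.0 * np.sum(xlogy(y, y / mu) + xlogy(trials - y, (trials - y) / (trials - mu)))
    )


@dataclass
class FittedNode:
    """Result of one local GLMM fit."""

    name: str
    spec: NodeSpec
    columns: list[str]
    term_columns: dict[str, list[int]]
    coefficients: np.ndarray
    cov: np.ndarray
    std_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    random_intercept_sd: float
    loglik: float
    deviance: float
    null_deviance: float
    n_obs: int
    n_groups: int
    converged: bool
    family: str
    # statistics of the fitting data needed for sweeps and projection
    col_means: np.ndarray = field(default=None)
    col_mins: np.ndarray = field(default=None)
    col_maxs: np.ndarray = field(default=None)
    response_obs: np.ndarray = field(default=None)  # natural (rate) scale
    mean_offset: float = 1.0
    z_scale: dict | None = None

    def coef(self, column: str) -> float:
        return float(self.coefficients[self.columns.index(column)])

    def predict_response(self, x: np.ndarray) -> np.ndarray:
        """Population-level (random effect = 0) prediction on the natural
        response scale: rate per effort unit for Poisson nodes, score in
        [0, denominator] for binomial nodes."""
        eta = np.atleast_2d(x) @ self.coefficients
        if self.family == "poisson":
            return np.exp(eta)
        return self.spec.binomial_denominator * expit(eta)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.columns,
                "estimate": self.coefficients,
                "std_error": self.std_errors,
                "z": self.z_values,
                "p_value": self.p_values,
            }
        )


def _hessian(fun, x, h=None):
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, float)
    p = len(x)
    if h is None:
        h = 1e-4 * np.maximum(np.abs(x), 1.0)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            if i == j:
                ei = np.zeros(p); ei[i] = h[i]
                H[i, i] = (fun(x + ei) - 2 * fun(x) + fun(x - ei)) / h[i] ** 2
            else:
                ei = np.zeros(p); ei[i] = h[i]
                ej = np.zeros(p); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def fit_node(
    spec: NodeSpec,
    data: pd.DataFrame,
    constrain_sd: float | None = None,
    sigma_start: float = 0.3,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FittedNode:
    """Fit one node's GLMM by maximum likelihood (Laplace approximation).

    The optimiser starts at the plain-GLM IRLS estimates and maximises the
    Laplace marginal likelihood jointly over the fixed effects and the
    random-intercept standard deviation (bounded at zero).  With
    ``constrain_sd=0`` the model is the plain GLM and is solved exactly by
    IRLS.  Fits that drive the standard deviation to the boundary are
    reported as singular (SD = 0) with a warning.
    """
    design = build_design(spec, data)
    if design.n_groups < 2:
        raise ValueError(f"node {spec.name!r}: <2 levels of {spec.random_factor!r}")
    z_scale = design.z_stats

    beta0, fisher0 = irls_glm(design)
    p = len(beta0)

    if constrain_sd is not None and constrain_sd == 0.0:
        beta, sigma = beta0, 0.0
        cov = np.linalg.pinv(fisher0)
        converged = True
        ll = _laplace_loglik(beta, 0.0, design)
    else:
        def neg(params):
            return -_laplace_loglik(params[:p], params[p], design)

        if constrain_sd is not None:
            def neg_beta(b):
                return -_laplace_loglik(b, constrain_sd, design)

            res = optimize.minimize(neg_beta, beta0, method="L-BFGS-B",
                                    options={"ftol": 1e-12, "gtol": 1e-9,
                                             "maxiter": max_iter})
            beta, sigma = res.x, float(constrain_sd)
            converged = bool(res.success)
        else:
            x0 = np.concatenate([beta0, [sigma_start]])
            bounds = [(None, None)] * p + [(0.0, None)]
            res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                    options={"ftol": 1e-12, "gtol": 1e-9,
                                             "maxiter": max_iter})
            beta, sigma = res.x[:p], float(res.x[p])
            converged = bool(res.success)
        if sigma < _SIGMA_SINGULAR and constrain_sd is None:
            warnings.warn(
                f"node {spec.name}: singular fit, random-intercept SD -> 0",
                stacklevel=2,
            )
            beta, fisher = irls_glm(design)
            sigma = 0.0
        ll = _laplace_loglik(beta, sigma, design)
        if sigma == 0.0:
            cov = np.linalg.pinv(irls_glm(design)[1])
        else:
            H = _hessian(lambda b: -_laplace_loglik(b, sigma, design), beta)
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
                converged = False

    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * norm.sf(np.abs(z))

    # marginal deviances: -2 x Laplace log-likelihood (constants included),
    # null = intercept + offset + random intercept refit on identical rows
    deviance = -2.0 * ll
    null_deviance = _null_deviance(spec, design, constrain_sd)

    # fitting-data statistics for sweeps / projection
    if design.family == "poisson":
        resp_obs = design.y / np.exp(design.offset_log)
    else:
        resp_obs = design.y

    return FittedNode(
        name=spec.name,
        spec=spec,
        columns=design.columns,
        term_columns=design.term_columns,
        coefficients=np.asarray(beta, float),
        cov=cov,
        std_errors=se,
        z_values=z,
        p_values=pvals,
        random_intercept_sd=float(sigma),
        loglik=float(ll),
        deviance=float(deviance),
        null_deviance=float(null_deviance),
        n_obs=len(design.y),
        n_groups=design.n_groups,
        converged=converged,
        family=design.family,
        col_means=design.X.mean(axis=0),
        col_mins=design.X.min(axis=0),
        col_maxs=design.X.max(axis=0),
        response_obs=resp_obs,
        mean_offset=float(np.exp(design.offset_log).mean()),
        z_scale=z_scale,
    )


def _null_deviance(spec: NodeSpec, design: Design, constrain_sd) -> float:
    """-2 x maximised Laplace log-likelihood of the intercept + offset +
    random-intercept null model, refitted on the identical rows."""
    null = Design(
        X=np.ones((len(design.y), 1)),
        y=design.y,
        offset_log=design.offset_log,
        trials=design.trials,
        group_idx=design.group_idx,
        n_groups=design.n_groups,
        columns=["(Intercept)"],
        term_columns={},
        family=design.family,
        group_levels=design.group_levels,
        ll_const=design.ll_const,
    )
    beta0, _ = irls_glm(null)
    if constrain_sd is not None and constrain_sd == 0.0:
        return -2.0 * _laplace_loglik(beta0, 0.0, null)

    def neg(params):
        return -_laplace_loglik(params[:1], params[1], null)

    res = optimize.minimize(
        neg, np.array([beta0[0], 0.3]), method="L-BFGS-B",
        bounds=[(None, None), (0.0, None)],
        options={"ftol": 1e-12, "gtol": 1e-9},
    )
    return 2.0 * float(res.fun)


def deviance_explained(fit: FittedNode) -> float:
    """Proportion of the null-model deviance removed by the fixed
    predictors: (null - fitted) / null, reported as a percentage in
    outputs.  Nesting of the null guarantees a value in [0, 1] up to
    optimiser tolerance; tiny negative noise is clipped."""
    if fit.null_deviance <= 0:
        raise ValueError(f"node {fit.name!r}: null deviance <= 0, metric undefined")
    val = (fit.null_deviance - fit.deviance) / fit.null_deviance
    if -1e-6 < val < 0.0:
        val = 0.0
    return float(val)
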