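"""Use-vs-availability inference: PCA, mixed logistic models, multimodel
averaging, spatial-autocorrelation control and the buffer-size sweep.

The modelling chain mirrors a classical resource-selection workflow:

1. land-cover compositions (closed, collinear percentages) are summarised
   by a covariance-matrix PCA into a few orthogonal habitat axes;
2. use (stopover) versus availability (random route point) is modelled by
   a binomial logit GLMM with a per-bird random intercept, fitted by
   maximum likelihood with an adaptive Gauss-Hermite approximation of the
   marginal likelihood;
3. all additive fixed-effect subsets are enumerated, ranked by AICc, and
   the dAICc < 2 subset is averaged with Akaike weights (full averaging,
   absent terms counted as zero, unconditional standard errors);
4. residual spatial autocorrelation is tested with Moran's I under
   inverse-distance weights and controlled by random subsampling until the
   permutation test is non-significant;
5. the analysis is run per availability replicate and the replicate
   averages pooled into a global model.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit
from scipy.stats import norm
from scipy.optimize import minimize

from .geo import haversine_km
from .habitat import CROPLAND_MOSAIC_LABELS, composition_columns

logger = logging.getLogger(__name__)

_SEPARATION_EFFECT = 12.0  # |beta| * SD(score) beyond this flags quasi-separation


# ---------------------------------------------------------------------------
# PCA on compositions


class RankError(ValueError):
    pass


@dataclass
class PCModel:
    """Covariance PCA of compositions expressed as fractions.

    ``loadings`` has one row per retained class column and one column per
    component, orthonormal; eigenvalues cover the full spectrum.
    """

    columns: list[str]
    means: np.ndarray
    loadings: np.ndarray  # (n_cols, k)
    eigenvalues: np.ndarray  # full spectrum, non-increasing
    variance_fractions: np.ndarray
    k: int
    scale: str = "fraction"
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def component_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.k)]

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.columns, columns=self.component_names)


def fit_pca(compositions: pd.DataFrame, k: int = 5, scale: str = "fraction") -> PCModel:
    """Eigen-decompose the covariance of composition columns.

    Percent columns are converted to fractions when ``scale='fraction'``
    (the default; eigenvalues are then on the scale of squared fractions).
    Zero-variance columns are dropped with a logged notice.  Loading signs
    follow a fixed convention: the largest-magnitude element of each
    component is positive.
    """
    cols = composition_columns(compositions)
    if not cols:
        raise ValueError("no composition columns found")
    X = compositions[cols].to_numpy(dtype=float)
    if scale == "fraction":
        X = X / 100.0
    elif scale != "percent":
        raise ValueError("scale must be 'fraction' or 'percent'")
    variances = X.var(axis=0, ddof=1)
    keep = variances > 1e-14
    dropped = [c for c, k_ in zip(cols, keep) if not k_]
    if dropped:
        logger.info("fit_pca: dropping zero-variance columns %s", dropped)
    cols = [c for c, k_ in zip(cols, keep) if k_]
    X = X[:, keep]
    if X.shape[0] < k + 1:
        raise RankError(f"need at least {k + 1} rows for {k} components, got {X.shape[0]}")
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals[0], 1e-30) * 1e-10))
    if k > rank:
        raise RankError(f"k={k} exceeds the covariance rank {rank}")
    # sign convention: largest-|.| element of each retained component positive
    load = evecs[:, :k].copy()
    for j in range(k):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    total = float(np.trace(cov))
    return PCModel(
        columns=cols,
        means=X.mean(axis=0),
        loadings=load,
        eigenvalues=evals,
        variance_fractions=evals / total if total > 0 else evals * 0.0,
        k=k,
        scale=scale,
        dropped_columns=dropped,
    )


def score(pc: PCModel, compositions: pd.DataFrame) -> pd.DataFrame:
    """Centred projection of compositions onto the retained components."""
    missing = [c for c in pc.columns if c not in compositions.columns]
    if missing:
        raise KeyError(f"composition table lacks columns {missing}")
    X = compositions[pc.columns].to_numpy(dtype=float)
    if pc.scale == "fraction":
        X = X / 100.0
    S = (X - pc.means) @ pc.loadings
    return pd.DataFrame(S, index=compositions.index, columns=pc.component_names)


def cropland_axis(pc: PCModel) -> tuple[str, float]:
    """Component most aligned with cropland/mosaic cover and its orientation.

    Returns (component name, sign) where sign * score increases with the
    summed cropland + cropland-mosaic loading.  Used to interpret which
    habitat axis a selection or duration effect acts on.
    """
    crop = np.array([1.0 if c in CROPLAND_MOSAIC_LABELS else 0.0 for c in pc.columns])
    proj = crop @ pc.loadings
    j = int(np.argmax(np.abs(proj)))
    return pc.component_names[j], float(np.sign(proj[j]) or 1.0)


# ---------------------------------------------------------------------------
# Binomial random-intercept GLMM (adaptive Gauss-Hermite)


class ConvergenceError(RuntimeError):
    def __init__(self, msg, terms=()):
        super().__init__(msg)
        self.terms = tuple(terms)


@dataclass
class GlmmFit:
    terms: tuple[str, ...]  # fixed-effect columns, intercept excluded
    beta: dict[str, float]  # includes "Intercept"
    se: dict[str, float]
    sigma_re: float  # random-intercept SD
    loglik: float
    k_params: int
    n_obs: int
    aicc: float
    converged: bool
    separation: bool
    fitted_prob: np.ndarray | None = None  # conditional on the bird modes
    group_modes: dict[str, float] | None = None

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def wald_p(self) -> dict[str, float]:
        out = {}
        for t, b in self.beta.items():
            s = self.se.get(t, np.nan)
            out[t] = 2.0 * norm.sf(abs(b) / s) if s and np.isfinite(s) and s > 0 else np.nan
        return out


def aicc(loglik: float, k: float, n: int) -> float:
    """Small-sample Akaike criterion -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


class _MarginalLoglik:
    """Adaptive Gauss-Hermite marginal log-likelihood of a logit GLMM.

    Data are sorted by group once; per-group sums use ``np.add.reduceat``
    so each evaluation is a handful of vectorised passes.
    """

    def __init__(self, y, X, groups, n_quad=15):
        order = np.argsort(groups, kind="stable")
        self.y = np.asarray(y, dtype=float)[order]
        self.X = np.asarray(X, dtype=float)[order]
        g = np.asarray(groups)[order]
        _, starts, counts = np.unique(g, return_index=True, return_counts=True)
        self.starts = starts
        self.n_groups = len(starts)
        self.group_of_row = np.repeat(np.arange(self.n_groups), counts)
        self.n = len(self.y)
        z, w = hermgauss(n_quad)
        self.z, self.logw = z, np.log(w)

    def _row_loglik(self, theta):
        # Bernoulli log-density, stable: y*theta - log(1 + e^theta)
        return self.y[:, None] * theta - np.logaddexp(0.0, theta)

    def _modes(self, eta, sigma):
        u = np.zeros(self.n_groups)
        for _ in range(25):
            theta = eta + sigma * u[self.group_of_row]
            mu = expit(theta)
            grad = sigma * np.add.reduceat(self.y - mu, self.starts) - u
            hess = -(sigma**2) * np.add.reduceat(mu * (1.0 - mu), self.starts) - 1.0
            step = grad / hess
            u = u - step
            if np.max(np.abs(grad)) < 1e-9:
                break
        theta = eta + sigma * u[self.group_of_row]
        mu = expit(theta)
        hess = -(sigma**2) * np.add.reduceat(mu * (1.0 - mu), self.starts) - 1.0
        return u, hess

    def loglik(self, beta, sigma, return_modes=False):
        eta = self.X @ beta
        u, hess = self._modes(eta, sigma)
        s = 1.0 / np.sqrt(-hess)
        # nodes: u_gj = m_g + sqrt(2) s_g z_j
        u_nodes = u[:, None] + math.sqrt(2.0) * s[:, None] * self.z[None, :]
        theta = eta[:, None] + sigma * u_nodes[self.group_of_row]
        rows = self._row_loglik(theta)
        gsum = np.add.reduceat(rows, self.starts, axis=0)
        h = gsum - 0.5 * u_nodes**2 - 0.5 * math.log(2.0 * math.pi)
        h_ref = h.max(axis=1, keepdims=True)
        integral = np.log(np.exp(h - h_ref + (self.z**2)[None, :] + self.logw[None, :]).sum(axis=1))
        ll = float(np.sum(h_ref[:, 0] + integral + 0.5 * math.log(2.0) + np.log(s)))
        if return_modes:
            return ll, u
        return ll

    def loglik_and_grad(self, beta, sigma):
        """Marginal loglik plus its gradient in (beta, sigma).

        The gradient of the marginal likelihood is the posterior
        expectation of the complete-data score; the posterior over the
        random effect is approximated with the same adaptive quadrature
        nodes, so objective and gradient stay mutually consistent up to
        the (second-order) dependence of the nodes on the parameters.
        """
        eta = self.X @ beta
        u, hess = self._modes(eta, sigma)
        s = 1.0 / np.sqrt(-hess)
        u_nodes = u[:, None] + math.sqrt(2.0) * s[:, None] * self.z[None, :]
        theta = eta[:, None] + sigma * u_nodes[self.group_of_row]
        rows = self._row_loglik(theta)
        gsum = np.add.reduceat(rows, self.starts, axis=0)
        h = gsum - 0.5 * u_nodes**2 - 0.5 * math.log(2.0 * math.pi)
        h_ref = h.max(axis=1, keepdims=True)
        expterm = np.exp(h - h_ref + (self.z**2)[None, :] + self.logw[None, :])
        denom = expterm.sum(axis=1, keepdims=True)
        ll = float(np.sum(h_ref[:, 0] + np.log(denom[:, 0]) + 0.5 * math.log(2.0) + np.log(s)))
        W = expterm / denom  # posterior node weights per group, rows sum to 1
        mu = expit(theta)  # (n, k)
        resid = self.y[:, None] - mu
        w_rows = W[self.group_of_row]
        grad_beta = self.X.T @ (w_rows * resid).sum(axis=1)
        grad_sigma = float(np.sum(w_rows * resid * u_nodes[self.group_of_row]))
        return ll, np.concatenate([grad_beta, [grad_sigma]])


def fit_glmm(
    table: pd.DataFrame,
    terms: tuple[str, ...] | list[str],
    response: str = "y",
    group: str = "bird_id",
    n_quad: int = 15,
    max_iter: int = 200,
    fix_sigma: float | None = None,
) -> GlmmFit:
    """ML fit of logit P(use) = b0 + sum_j b_j x_j + bird random intercept.

    A boundary fit with zero random-effect variance is legal and reduces
    to plain logistic regression.  ``fix_sigma`` pins the random-effect SD
    (useful for the reduction check); otherwise it is profiled over [0, 20].
    """
    terms = tuple(terms)
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    if n <= len(terms) + 3:
        raise ValueError(f"too few rows ({n}) for {len(terms)} terms")
    groups, group_codes = np.unique(table[group].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 birds for a random intercept")
    X = np.column_stack([np.ones(n)] + [table[t].to_numpy(dtype=float) for t in terms])
    p = X.shape[1]
    ml = _MarginalLoglik(y, X, group_codes, n_quad=n_quad)

    # start from a few IRLS steps of plain logistic regression
    beta0 = np.zeros(p)
    for _ in range(25):
        mu = expit(X @ beta0)
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
        try:
            delta = np.linalg.solve((X * W[:, None]).T @ X + 1e-8 * np.eye(p), X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        beta0 = beta0 + delta
        if np.max(np.abs(delta)) < 1e-8 or np.max(np.abs(X @ beta0)) > 40.0:
            break

    if fix_sigma is not None:
        def nll(params):
            ll, g = ml.loglik_and_grad(params, fix_sigma)
            return -ll, -g[:-1]

        res = minimize(nll, beta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-7})
        beta_hat, sigma_hat = res.x, fix_sigma
        ll = -res.fun
        ok = bool(res.success) or np.max(np.abs(res.jac)) < 1e-3
    else:
        def nll(params):
            ll, g = ml.loglik_and_grad(params[:-1], params[-1])
            return -ll, -g

        x0 = np.concatenate([beta0, [0.3]])
        res = minimize(
            nll,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(None, None)] * p + [(0.0, 20.0)],
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-7},
        )
        beta_hat, sigma_hat = res.x[:-1], abs(res.x[-1])
        ll = -res.fun
        ok = bool(res.success)
    if not ok and not np.all(np.isfinite(beta_hat)):
        raise ConvergenceError(f"GLMM fit failed for terms {terms}", terms)

    # quasi-separation check on the per-SD effect scale: a huge coefficient
    # on a tiny-variance score is a legitimate fit, a huge standardised
    # effect (or an intercept running away) is not
    col_sd = X.std(axis=0)
    col_sd[0] = 1.0  # intercept column
    separation = bool(np.max(np.abs(beta_hat) * col_sd) > _SEPARATION_EFFECT)

    # SEs from the numerical Hessian of the negative marginal loglik (beta block)
    se = _beta_se(ml, beta_hat, sigma_hat)

    k = p + 1  # fixed effects (incl. intercept) + random-intercept variance
    crit = aicc(ll, k, n)
    ll_final, u = ml.loglik(beta_hat, sigma_hat, return_modes=True)
    theta = ml.X @ beta_hat + sigma_hat * u[ml.group_of_row]
    fitted_sorted = expit(theta)
    # un-sort fitted values back to the input row order
    order = np.argsort(group_codes, kind="stable")
    fitted = np.empty(n)
    fitted[order] = fitted_sorted

    names = ("Intercept",) + terms
    return GlmmFit(
        terms=terms,
        beta={nm: float(b) for nm, b in zip(names, beta_hat)},
        se={nm: float(s) for nm, s in zip(names, se)},
        sigma_re=float(sigma_hat),
        loglik=float(ll),
        k_params=k,
        n_obs=n,
        aicc=float(crit),
        converged=ok,
        separation=separation,
        fitted_prob=fitted,
        group_modes={str(g): float(sigma_hat * ui) for g, ui in zip(groups, u)},
    )


def _beta_se(ml: _MarginalLoglik, beta: np.ndarray, sigma: float) -> np.ndarray:
    """Wald SEs from the observed information: central differences of the
    analytic score in the beta block (sigma held at its estimate)."""
    p = len(beta)
    h = 1e-5 * np.maximum(np.abs(beta), 1.0)
    H = np.zeros((p, p))
    for i in range(p):
        step = np.zeros(p)
        step[i] = h[i]
        _, gp = ml.loglik_and_grad(beta + step, sigma)
        _, gm = ml.loglik_and_grad(beta - step, sigma)
        H[i] = (gp[:p] - gm[:p]) / (2.0 * h[i])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)
    var = np.diag(cov)
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.where(var > 0, var, np.nan))


# ---------------------------------------------------------------------------
# All-subsets enumeration and Akaike-weight averaging


class AveragingError(RuntimeError):
    pass


@dataclass
class AveragedModel:
    terms: list[str]  # "Intercept" first, then every PC term
    beta: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    candidates: pd.DataFrame  # all fits: terms, aicc, delta_aicc, weight (0 outside subset)
    n_models_averaged: int
    partial: bool = False
    failures: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "beta": [self.beta[t] for t in self.terms],
             "se": [self.se[t] for t in self.terms], "p": [self.p[t] for t in self.terms]}
        )


def dredge_average(
    table: pd.DataFrame,
    pc_names: tuple[str, ...] | list[str] = ("PC1", "PC2", "PC3", "PC4", "PC5"),
    delta: float = 2.0,
    response: str = "y",
    group: str = "bird_id",
    n_quad: int = 15,
) -> AveragedModel:
    """Enumerate all additive subsets, rank by AICc, average the dAICc<delta set.

    Full (zero-substitution) averaging: a term absent from a candidate
    contributes beta = 0 with zero conditional variance.  Unconditional
    standard errors combine within-model variance and between-model spread;
    two-sided P-values are normal-approximation Wald tests.
    """
    pc_names = tuple(pc_names)
    fits: list[GlmmFit] = []
    labels: list[str] = []
    for r in range(len(pc_names) + 1):
        for subset in itertools.combinations(pc_names, r):
            try:
                fit = fit_glmm(table, subset, response=response, group=group, n_quad=n_quad)
            except (ConvergenceError, ValueError) as exc:
                logger.warning("dredge: subset %s failed: %s", subset, exc)
                continue
            if fit.separation:
                logger.warning("dredge: subset %s flagged for separation, excluded", subset)
                continue
            fits.append(fit)
            labels.append("+".join(subset) if subset else "(intercept)")
    if not fits:
        raise AveragingError("no candidate model converged")

    aiccs = np.array([f.aicc for f in fits])
    deltas = aiccs - aiccs.min()
    in_subset = deltas < delta
    raw_w = np.where(in_subset, np.exp(-deltas / 2.0), 0.0)
    weights = raw_w / raw_w.sum()

    all_terms = ["Intercept"] + list(pc_names)
    beta_bar, se_u, pvals = {}, {}, {}
    for t in all_terms:
        b = np.array([f.beta.get(t, 0.0) for f in fits])
        v = np.array([f.se.get(t, 0.0) ** 2 if t in f.beta else 0.0 for f in fits])
        bw = float(np.sum(weights * b))
        seu = float(np.sum(weights * np.sqrt(v + (b - bw) ** 2)))
        beta_bar[t] = bw
        se_u[t] = seu
        pvals[t] = float(2.0 * norm.sf(abs(bw) / seu)) if seu > 0 else (1.0 if bw == 0 else 0.0)

    cand = pd.DataFrame(
        {
            "model": labels,
            "k": [f.k_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "aicc": aiccs,
            "delta_aicc": deltas,
            "weight": weights,
        }
    ).sort_values("aicc", kind="stable").reset_index(drop=True)

    return AveragedModel(
        terms=all_terms,
        beta=beta_bar,
        se=se_u,
        p=pvals,
        candidates=cand,
        n_models_averaged=int(in_subset.sum()),
    )


# ---------------------------------------------------------------------------
# Moran's I and decorrelating subsampler


class UndefinedMoranError(ValueError):
    pass


class NonDecorrelatableError(RuntimeError):
    def __init__(self, msg, trace):
        super().__init__(msg)
        self.trace = trace


@dataclass
class MoranResult:
    observed_i: float
    expected_i: float
    p_value: float
    n: int
    scheme: str = "inverse_distance_km"


def moran_i(
    residuals: np.ndarray,
    lons: np.ndarray,
    lats: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> MoranResult:
    """Global Moran's I under inverse great-circle-distance weights.

    I = (n/S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with w_ii = 0; significance is a two-sided permutation test around the
    null expectation -1/(n-1).  Duplicate coordinates are jittered by
    1e-6 degrees with a notice.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(residuals, dtype=float)
    lons = np.asarray(lons, dtype=float).copy()
    lats = np.asarray(lats, dtype=float).copy()
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I needs n >= 3")
    coords = np.column_stack([lons, lats])
    _, first_idx, inv = np.unique(coords, axis=0, return_index=True, return_inverse=True)
    if len(first_idx) < n:
        logger.info("moran_i: jittering %d duplicate coordinates by 1e-6 deg", n - len(first_idx))
        dup = np.ones(n, dtype=bool)
        dup[first_idx] = False
        lons[dup] += rng.uniform(-1e-6, 1e-6, dup.sum())
        lats[dup] += rng.uniform(-1e-6, 1e-6, dup.sum())
    xc = x - x.mean()
    denom = float(np.sum(xc**2))
    if denom <= 0:
        raise UndefinedMoranError("residuals have zero variance")
    d = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    np.fill_diagonal(d, np.inf)
    d = np.maximum(d, 1e-9)
    W = 1.0 / d
    np.fill_diagonal(W, 0.0)
    s0 = float(W.sum())
    obs = float(n / s0 * (xc @ W @ xc) / denom)
    expected = -1.0 / (n - 1)

    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Xp = xc[perms]  # (n_perm, n)
    quad = np.einsum("pi,ij,pj->p", Xp, W, Xp, optimize=True)
    i_perm = n / s0 * quad / denom
    extreme = np.abs(i_perm - expected) >= np.abs(obs - expected) - 1e-15
    p = float((1 + int(extreme.sum())) / (n_perm + 1))
    return MoranResult(obs, expected, p, n)


def decorrelate_subsample(
    table: pd.DataFrame,
    pc_names: tuple[str, ...] | list[str] = ("PC1", "PC2", "PC3", "PC4", "PC5"),
    alpha: float = 0.05,
    drop_fraction: float = 0.1,
    max_iter: int = 50,
    rng: np.random.Generator | int | None = None,
    n_perm: int = 999,
    response: str = "y",
    group: str = "bird_id",
    n_quad: int = 15,
) -> tuple[pd.DataFrame, list[dict]]:
    """Randomly thin rows until model residuals show no spatial autocorrelation.

    Each iteration fits the full model, Moran-tests its conditional response
    residuals at the point coordinates, and if significant drops
    ``drop_fraction`` of rows stratified by bird.  Returns the first table
    achieving P > alpha together with the full iteration trace.
    """
    rng = np.random.default_rng(rng)
    df = table.reset_index(drop=True)
    trace: list[dict] = []
    for it in range(max_iter + 1):
        n_birds = df[group].nunique()
        if len(df) < 9 or n_birds < 3:
            raise NonDecorrelatableError(
                f"subsample too small to continue (n={len(df)}, birds={n_birds})", trace
            )
        fit = fit_glmm(df, tuple(pc_names), response=response, group=group, n_quad=n_quad)
        resid = df[response].to_numpy(dtype=float) - fit.fitted_prob
        mres = moran_i(resid, df["lon"].to_numpy(), df["lat"].to_numpy(), n_perm=n_perm, rng=rng)
        trace.append({"iteration": it, "n": len(df), "moran_i": mres.observed_i, "p": mres.p_value})
        if mres.p_value > alpha:
            return df, trace
        if it == max_iter:
            break
        # stratified thinning: proportional share per bird, at least one row total
        drop_idx: list[int] = []
        for _, idx in df.groupby(group).indices.items():
            k = int(round(drop_fraction * len(idx)))
            k = min(k, max(len(idx) - 1, 0))
            if k > 0:
                drop_idx.extend(rng.choice(idx, size=k, replace=False).tolist())
        if not drop_idx:
            pool = df.index.to_numpy()
            drop_idx = [int(rng.choice(pool))]
        df = df.drop(index=drop_idx).reset_index(drop=True)
    raise NonDecorrelatableError(f"Moran P <= {alpha} after {max_iter} subsampling rounds", trace)


# ---------------------------------------------------------------------------
# Replicate pipeline and buffer sweep


def pool_averaged_models(models: list[AveragedModel], failures: list[str] | None = None) -> AveragedModel:
    """Global model: unweighted per-term mean of replicate averages.

    SEs combine mean within-replicate variance and between-replicate spread,
    sqrt(mean(SE^2) + var(beta)); P from the normal approximation.
    """
    if not models:
        raise AveragingError("no replicate models to pool")
    terms = models[0].terms
    beta, se, p = {}, {}, {}
    for t in terms:
        b = np.array([m.beta[t] for m in models])
        s2 = np.array([m.se[t] ** 2 for m in models])
        bw = float(b.mean())
        between = float(b.var(ddof=1)) if len(b) > 1 else 0.0
        su = float(np.sqrt(s2.mean() + between))
        beta[t], se[t] = bw, su
        p[t] = float(2.0 * norm.sf(abs(bw) / su)) if su > 0 else (1.0 if bw == 0 else 0.0)
    cand = pd.concat([m.candidates.assign(replicate=i + 1) for i, m in enumerate(models)], ignore_index=True)
    return AveragedModel(
        terms=terms,
        beta=beta,
        se=se,
        p=p,
        candidates=cand,
        n_models_averaged=len(models),
        partial=bool(failures),
        failures=list(failures or ()),
    )


def replicate_pipeline(
    replicate_tables: list[pd.DataFrame],
    pc_names: tuple[str, ...] | list[str] = ("PC1", "PC2", "PC3", "PC4", "PC5"),
    delta: float = 2.0,
    alpha: float = 0.05,
    drop_fraction: float = 0.1,
    rng: np.random.Generator | int | None = None,
    n_perm: int = 999,
    n_quad: int = 15,
) -> tuple[list[AveragedModel | None], AveragedModel, list[list[dict]]]:
    """Decorrelate + dredge-average each replicate, then pool globally.

    Each replicate table needs columns y, bird_id, lon, lat and the PC
    scores.  Returns (per-replicate models, global model, Moran traces);
    a fatally failing replicate leaves None in its slot and marks the
    global model partial.
    """
    rng = np.random.default_rng(rng)
    models: list[AveragedModel | None] = []
    ok_models: list[AveragedModel] = []
    traces: list[list[dict]] = []
    failures: list[str] = []
    for i, tab in enumerate(replicate_tables, start=1):
        try:
            sub, trace = decorrelate_subsample(
                tab, pc_names, alpha=alpha, drop_fraction=drop_fraction, rng=rng,
                n_perm=n_perm, n_quad=n_quad,
            )
            avg = dredge_average(sub, pc_names, delta=delta, n_quad=n_quad)
        except (NonDecorrelatableError, AveragingError, ConvergenceError, ValueError) as exc:
            logger.warning("replicate %d failed: %s", i, exc)
            models.append(None)
            traces.append(getattr(exc, "trace", []))
            failures.append(f"replicate {i}: {exc}")
            continue
        models.append(avg)
        ok_models.append(avg)
        traces.append(trace)
    global_model = pool_averaged_models(ok_models, failures)
    return models, global_model, traces


def buffer_sweep_models(
    points: list[dict],
    raster,
    radii_m: list[float],
    k_pcs: int = 5,
    n_quad: int = 15,
) -> pd.DataFrame:
    """Refit the full five-PC GLMM at each metre buffer radius and rank by AICc.

    ``points`` are the replicate-1 use + availability points (see
    ``habitat.composition_table``).  Each radius gets a fresh composition
    extraction and a fresh PCA.  Output columns: radius_m, aicc,
    delta_aicc, deviance, sorted ascending by AICc; a radius whose fit
    fails is reported with NaNs and the error message.
    """
    from .habitat import composition_table  # local import to avoid cycle noise

    rows = []
    for radius in radii_m:
        try:
            comp = composition_table(points, raster, radius, unit="m")
            pc = fit_pca(comp, k=k_pcs)
            scores = score(pc, comp)
            tab = pd.concat(
                [comp[["point_id", "bird_id", "label", "lon", "lat"]].reset_index(drop=True),
                 scores.reset_index(drop=True)], axis=1
            )
            tab["y"] = (tab["label"] == "use").astype(float)
            fit = fit_glmm(tab, tuple(pc.component_names), n_quad=n_quad)
            rows.append({"radius_m": radius, "aicc": fit.aicc, "deviance": fit.deviance, "error": ""})
        except Exception as exc:  # noqa: BLE001 - sweep must not abort
            logger.warning("buffer sweep: radius %s failed: %s", radius, exc)
            rows.append({"radius_m": radius, "aicc": np.nan, "deviance": np.nan, "error": str(exc)})
    out = pd.DataFrame(rows)
    best = out["aicc"].min()
    out["delta_aicc"] = out["aicc"] - best
    out = out.sort_values("aicc", kind="stable", na_position="last").reset_index(drop=True)
    return out[["radius_m", "aicc", "delta_aicc", "deviance", "error"]]
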