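"""ABC rejection, GLM model choice and parameter posteriors.

The inference layer follows the ABC-GLM lineage: simulate a reference
table per model under the priors, standardize summary statistics robustly,
retain the k simulations closest to the observed statistics in Euclidean
distance, and post-process the retained set with a Gaussian linear model
(GLM) of statistics on parameters.  The GLM serves two purposes:

* model choice — the marginal density of the observed statistics under
  each model is estimated as the average GLM likelihood over the retained
  parameter draws; posteriors are proportional to prior x density;
* parameter estimation — retained draws are re-weighted by their GLM
  likelihood at the observed statistics and marginal posteriors are
  obtained by weighted kernel density estimation on a grid truncated to
  the prior support.

A multinomial-logistic model-choice fallback is available behind a flag.
Optionally statistics are first projected onto partial-least-squares (PLS)
components fitted per model (dimension reduction before retention for
parameter estimation; never for model choice, where statistics must be
shared across models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .coalsim import SampleConfig, simulate_stat_vector
from .popstats import stat_names as full_stat_names


class ABCError(ValueError):
    pass


# ---------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.lo, self.hi, size=size)

    @property
    def support(self) -> tuple[float, float]:
        return self.lo, self.hi


@dataclass(frozen=True)
class TruncNormal:
    mean: float
    sd: float
    lo: float = 0.0

    def sample(self, rng: np.random.Generator, size=None):
        x = rng.normal(self.mean, self.sd, size=size)
        bad = x <= self.lo
        while np.any(bad):
            x = np.where(bad, rng.normal(self.mean, self.sd, size=size), x)
            bad = x <= self.lo
        return x

    @property
    def support(self) -> tuple[float, float]:
        return max(self.lo, self.mean - 4 * self.sd), self.mean + 4 * self.sd


@dataclass
class PriorSpec:
    """Joint prior over the colonization-model parameters.

    Sizes, founder counts and the migration intensity are sampled on the
    log10 scale; colonization times in generations with the ordering
    constraint tau_HI > tau_WUS > tau_SP > tau_EUS enforced by rejection;
    the mutation rate has a truncated-normal prior reflecting the
    experimental estimate for D. melanogaster.
    """

    marginals: dict = field(default_factory=lambda: {
        "log10_N_ASIA": Uniform(4, 8),
        "log10_N_JP": Uniform(2, 6),
        "log10_N_HI": Uniform(2, 6),
        "log10_N_WUS": Uniform(2, 6),
        "log10_N_EUS": Uniform(2, 6),
        "log10_N_SP": Uniform(2, 6),
        "log10_f_HI": Uniform(0.6, 3),
        "log10_f_WUS": Uniform(0.6, 3),
        "log10_f_EUS": Uniform(0.6, 3),
        "log10_f_SP": Uniform(0.6, 3),
        "tau_HI": Uniform(100, 750),
        "tau_WUS": Uniform(10, 100),
        "tau_EUS": Uniform(10, 100),
        "tau_SP": Uniform(10, 100),
        "log10_Nm": Uniform(-2, 2),
        "mu": TruncNormal(3.46e-9, 0.28e-9),
    })

    @property
    def names(self) -> list[str]:
        return list(self.marginals)

    def support(self, name: str) -> tuple[float, float]:
        return self.marginals[name].support

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        """One draw satisfying the colonization-time ordering."""
        out = {k: float(d.sample(rng)) for k, d in self.marginals.items()}
        if {"tau_WUS", "tau_EUS", "tau_SP"} <= set(out):
            while not (out["tau_WUS"] > out["tau_SP"] > out["tau_EUS"]):
                for k in ("tau_WUS", "tau_EUS", "tau_SP"):
                    out[k] = float(self.marginals[k].sample(rng))
        return out

    def vector(self, draw: dict[str, float]) -> np.ndarray:
        return np.array([draw[n] for n in self.names])


def to_sim_params(draw: dict[str, float]) -> dict[str, float]:
    """Convert a prior draw (log10 scales) to natural-scale simulator input."""
    out: dict[str, float] = {}
    for k, v in draw.items():
        if k.startswith("log10_"):
            out[k[len("log10_"):]] = 10.0**v
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------
# reference tables


@dataclass
class ReferenceTable:
    """Simulated (parameters, statistics) records for one model."""

    model_id: str
    params: np.ndarray  # n_sims x n_params, prior (log10) scale
    stats: np.ndarray  # n_sims x n_stats
    param_names: list[str]
    stat_names: list[str]

    @property
    def n_sims(self) -> int:
        return self.params.shape[0]

    def stat_columns(self, subset) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.stat_names)}
        return self.stats[:, [idx[n] for n in subset]]


def build_reference_table(
    model_id: str,
    prior: PriorSpec,
    n_sims: int,
    config: SampleConfig,
    seed: int,
    missing_rate: float = 0.214,
) -> ReferenceTable:
    """Simulate ``n_sims`` datasets under the prior and summarize each.

    Statistics go through the same code path as observed data.
    """
    rng = np.random.default_rng(seed)
    names = full_stat_names(tuple(config.samples))
    P = np.empty((n_sims, len(prior.names)))
    S = np.empty((n_sims, len(names)))
    for i in range(n_sims):
        draw = prior.sample(rng)
        P[i] = prior.vector(draw)
        sv = simulate_stat_vector(model_id, to_sim_params(draw), config, rng, missing_rate)
        S[i] = sv.values
    return ReferenceTable(model_id, P, S, prior.names, names)


# ---------------------------------------------------------------------
# standardization + rejection


def robust_scale(stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median / MAD standardization constants (MAD -> SD -> 1 fallback)."""
    center = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - center), axis=0) * 1.4826
    sd = stats.std(axis=0)
    scale = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    return center, scale


@dataclass
class RetainedSet:
    indices: np.ndarray
    distances: np.ndarray  # non-decreasing
    center: np.ndarray
    scale: np.ndarray


def retain_nearest(
    stats: np.ndarray,
    observed: np.ndarray,
    k: int,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> RetainedSet:
    """k nearest rows by Euclidean distance in standardized statistic space.

    Ties are broken by row index (stable ordering).
    """
    if k > stats.shape[0]:
        raise ABCError(f"k={k} exceeds table size {stats.shape[0]}")
    if not np.all(np.isfinite(observed)):
        raise ABCError("observed statistics contain non-finite values")
    if center is None or scale is None:
        center, scale = robust_scale(stats)
    z = (stats - center) / scale
    zo = (observed - center) / scale
    d = np.sqrt(((z - zo) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    return RetainedSet(order, d[order], center, scale)


# ---------------------------------------------------------------------
# the Gaussian linear model


@dataclass
class GLMFit:
    intercept: np.ndarray  # (n_stats,)
    coef: np.ndarray  # (n_params, n_stats)
    chol: np.ndarray  # cholesky factor of residual covariance
    log_det: float

    def predict(self, theta: np.ndarray) -> np.ndarray:
        return self.intercept + theta @ self.coef

    def log_likelihood(self, s_obs: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Log N(s_obs; predict(theta_j), Sigma) for each row of theta."""
        resid = s_obs - self.predict(np.atleast_2d(theta))
        y = np.linalg.solve(self.chol, resid.T)  # whitened residuals
        d = s_obs.size
        return -0.5 * (y**2).sum(axis=0) - 0.5 * self.log_det - 0.5 * d * np.log(2 * np.pi)


def fit_glm(theta: np.ndarray, stats: np.ndarray, ridge: float = 1e-8) -> GLMFit:
    """OLS of statistics on parameters over the retained set.

    The residual covariance is regularized by a small ridge on the
    diagonal whenever it is (near-)singular.
    """
    n = theta.shape[0]
    X = np.column_stack([np.ones(n), theta])
    beta, *_ = np.linalg.lstsq(X, stats, rcond=None)
    resid = stats - X @ beta
    sigma = resid.T @ resid / max(1, n - X.shape[1])
    jitter = ridge * max(1.0, np.trace(sigma) / sigma.shape[0])
    for _ in range(12):
        try:
            chol = np.linalg.cholesky(sigma + jitter * np.eye(sigma.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter *= 10
    else:
        raise ABCError("residual covariance is irreparably singular")
    log_det = 2.0 * np.log(np.diag(chol)).sum()
    return GLMFit(beta[0], beta[1:], chol, log_det)


def glm_marginal_log_density(fit: GLMFit, s_obs: np.ndarray, theta: np.ndarray) -> float:
    """log of the GLM marginal density of s_obs: average likelihood over
    the retained parameter draws (Monte-Carlo integral over the truncated
    prior)."""
    ll = fit.log_likelihood(s_obs, theta)
    m = ll.max()
    return float(m + np.log(np.mean(np.exp(ll - m))))


# ---------------------------------------------------------------------
# model choice


@dataclass
class ModelPosterior:
    probabilities: dict[str, float]
    log_marginals: dict[str, float]
    retained: dict[str, RetainedSet]

    @property
    def best(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)


class ModelChoiceEngine:
    """Prepared model choice: statistics sliced and standardized once.

    Use this when evaluating many observed vectors (pods) against the same
    reference tables; ``model_posterior`` is a one-shot convenience over
    it.
    """

    def __init__(
        self,
        tables: dict[str, ReferenceTable],
        stat_subset: list[str] | tuple[str, ...],
        prior_prob: dict[str, float] | None = None,
    ) -> None:
        if len(tables) < 2:
            raise ABCError("model choice needs at least two models")
        self.models = list(tables)
        self.tables = tables
        self.stat_subset = list(stat_subset)
        self.prior_prob = prior_prob or {m: 1.0 / len(self.models) for m in self.models}
        self._stats = {m: tables[m].stat_columns(stat_subset) for m in self.models}
        self.center, self.scale = robust_scale(np.vstack(list(self._stats.values())))
        self._z = {m: (s - self.center) / self.scale for m, s in self._stats.items()}

    def posterior(self, observed: np.ndarray, k: int = 1000, method: str = "glm") -> ModelPosterior:
        """Posterior model probabilities for one observed vector.

        A *common* retention tolerance is used for all models: the radius
        enclosing the ``k x n_models`` pooled nearest simulations.  Each
        model's marginal density of the observed vector is its acceptance
        fraction times the GLM mixture density over its retained draws —
        the two factors of the ABC-GLM marginal likelihood — and the
        posterior is proportional to prior x density.
        ``method="logistic"`` switches to a multinomial-logistic estimate
        on per-model k-nearest retained sets.
        """
        if not np.all(np.isfinite(observed)):
            raise ABCError("observed statistics contain non-finite values")
        zobs = (observed - self.center) / self.scale
        retained: dict[str, RetainedSet] = {}

        if method == "logistic":
            from sklearn.linear_model import LogisticRegression

            X, y = [], []
            for mi, m in enumerate(self.models):
                ret = retain_nearest(self._stats[m], observed, k, self.center, self.scale)
                retained[m] = ret
                X.append(self._z[m][ret.indices])
                y.append(np.full(k, mi))
            clf = LogisticRegression(max_iter=2000).fit(np.vstack(X), np.concatenate(y))
            p = clf.predict_proba(zobs[None, :])[0]
            probs = {m: float(p[mi]) * self.prior_prob[m] for mi, m in enumerate(self.models)}
            tot = sum(probs.values())
            probs = {m: v / tot for m, v in probs.items()}
            return ModelPosterior(probs, {m: float("nan") for m in self.models}, retained)

        dists = {m: np.sqrt(((z - zobs) ** 2).sum(axis=1)) for m, z in self._z.items()}
        pooled = np.sort(np.concatenate(list(dists.values())))
        k_total = min(k * len(self.models), pooled.size)
        delta = pooled[k_total - 1]

        d = len(self.stat_subset)
        log_marg: dict[str, float] = {}
        for m in self.models:
            table = self.tables[m]
            inside = np.flatnonzero(dists[m] <= delta)
            order = inside[np.argsort(dists[m][inside], kind="stable")]
            retained[m] = RetainedSet(order, dists[m][order], self.center, self.scale)
            k_m = order.size
            if k_m == 0:
                log_marg[m] = -np.inf
                continue
            z = self._z[m][order]
            theta = table.params[order]
            if k_m >= max(30, theta.shape[1] + 2):
                fit = fit_glm(theta, z)
                log_mix = glm_marginal_log_density(fit, zobs, theta)
            else:
                # too few retained for a regression: intercept-only Gaussian
                mean = z.mean(axis=0)
                cov = np.cov(z, rowvar=False).reshape(d, d) if k_m > 1 else np.eye(d)
                cov = cov + 0.1 * np.eye(d)
                chol = np.linalg.cholesky(cov)
                y = np.linalg.solve(chol, zobs - mean)
                log_mix = float(
                    -0.5 * (y**2).sum() - np.log(np.diag(chol)).sum() - 0.5 * d * np.log(2 * np.pi)
                )
            log_marg[m] = np.log(k_m / table.n_sims) + log_mix
        mx = max(log_marg.values())
        if not np.isfinite(mx):
            probs = {m: self.prior_prob[m] for m in self.models}
        else:
            unnorm = {m: self.prior_prob[m] * np.exp(log_marg[m] - mx) for m in self.models}
            tot = sum(unnorm.values())
            probs = {m: float(v / tot) for m, v in unnorm.items()}
        return ModelPosterior(probs, log_marg, retained)


def model_posterior(
    tables: dict[str, ReferenceTable],
    observed: np.ndarray,
    stat_subset: list[str] | tuple[str, ...],
    k: int = 1000,
    prior_prob: dict[str, float] | None = None,
    method: str = "glm",
) -> ModelPosterior:
    """One-shot model choice; see ``ModelChoiceEngine.posterior``."""
    return ModelChoiceEngine(tables, stat_subset, prior_prob).posterior(observed, k, method)


# ---------------------------------------------------------------------
# PLS projection


@dataclass
class PLSProjection:
    pls: PLSRegression
    center: np.ndarray
    scale: np.ndarray
    n_components: int

    def transform(self, stats: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(stats) - self.center) / self.scale
        return self.pls.transform(z)


def pls_project(
    stats: np.ndarray,
    params: np.ndarray,
    n_components: int = 7,
) -> tuple[np.ndarray, PLSProjection]:
    """Fit PLS components maximizing covariance with the parameters.

    Returns the transformed statistics and the projection (applied
    identically to the observed vector later).
    """
    if stats.shape[1] < n_components:
        raise ABCError("fewer statistics than requested PLS components")
    center, scale = robust_scale(stats)
    z = (stats - center) / scale
    rank = np.linalg.matrix_rank(z - z.mean(axis=0))
    if rank < n_components:
        raise ABCError(f"statistic matrix rank {rank} below {n_components} components")
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(z, params)
    proj = PLSProjection(pls, center, scale, n_components)
    return proj.transform(stats), proj


# ---------------------------------------------------------------------
# parameter posteriors


@dataclass
class ParameterPosterior:
    """Marginal posterior densities per parameter on fixed grids."""

    param_names: list[str]
    grids: dict[str, np.ndarray]
    densities: dict[str, np.ndarray]

    def _cdf(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        g, d = self.grids[name], self.densities[name]
        cdf = np.cumsum(d)
        cdf /= cdf[-1]
        return g, cdf

    def quantile(self, name: str, q: float) -> float:
        g, cdf = self._cdf(name)
        return float(np.interp(q, cdf, g))

    def quantile_of(self, name: str, value: float) -> float:
        g, cdf = self._cdf(name)
        return float(np.interp(value, g, cdf))

    def mode(self, name: str) -> float:
        g, d = self.grids[name], self.densities[name]
        return float(g[np.argmax(d)])

    def mean(self, name: str) -> float:
        g, d = self.grids[name], self.densities[name]
        return float((g * d).sum() / d.sum())

    def hpd_level_of(self, name: str, value: float) -> float:
        """Mass of the smallest highest-density region containing ``value``."""
        g, d = self.grids[name], self.densities[name]
        dv = float(np.interp(value, g, d))
        mass = d.sum()
        return float(d[d >= dv].sum() / mass)

    def summary(self, name: str) -> dict[str, float]:
        return {
            "mode": self.mode(name),
            "mean": self.mean(name),
            "median": self.quantile(name, 0.5),
            "q5": self.quantile(name, 0.05),
            "q95": self.quantile(name, 0.95),
        }


def _weighted_kde(
    values: np.ndarray,
    weights: np.ndarray,
    grid: np.ndarray,
) -> np.ndarray:
    """Gaussian weighted KDE evaluated on a grid, truncated+renormalized."""
    w = weights / weights.sum()
    n_eff = 1.0 / (w**2).sum()
    mean = (w * values).sum()
    var = (w * (values - mean) ** 2).sum()
    sd = np.sqrt(max(var, 1e-300))
    span = grid[-1] - grid[0]
    h = max(1.06 * sd * n_eff ** (-1 / 5), 1e-3 * span)
    dens = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / h) ** 2) @ w
    dens /= np.trapezoid(dens, grid)
    return dens


def parameter_posterior(
    theta: np.ndarray,
    stats_retained: np.ndarray,
    observed: np.ndarray,
    prior: PriorSpec,
    grid_size: int = 512,
) -> ParameterPosterior:
    """GLM-adjusted marginal posteriors from a retained set.

    ``stats_retained``/``observed`` must live in the same (standardized or
    PLS) space.  Retained draws are weighted by the GLM likelihood of the
    observed statistics and smoothed per parameter on a grid over the
    prior support.
    """
    if theta.shape[0] < 10:
        raise ABCError("retained set too small for posterior estimation")
    fit = fit_glm(theta, stats_retained)
    ll = fit.log_likelihood(observed, theta)
    w = np.exp(ll - ll.max())
    if w.sum() <= 0 or not np.isfinite(w.sum()):
        raise ABCError("degenerate GLM weights")
    names = prior.names
    grids, dens = {}, {}
    for j, name in enumerate(names):
        lo, hi = prior.support(name)
        grid = np.linspace(lo, hi, grid_size)
        grids[name] = grid
        dens[name] = _weighted_kde(theta[:, j], w, grid)
    return ParameterPosterior(names, grids, dens)


def weight_posteriors(
    posteriors: dict[str, ParameterPosterior],
    model_probs: dict[str, float],
) -> ParameterPosterior:
    """Model-averaged posterior: mixture of per-model densities."""
    models = [m for m, p in model_probs.items() if p > 0]
    first = posteriors[models[0]]
    names = first.param_names
    grids = {n: first.grids[n] for n in names}
    dens = {}
    for n in names:
        acc = np.zeros_like(grids[n])
        for m in models:
            post = posteriors[m]
            if n not in post.densities:
                raise ABCError(f"parameter {n} absent from model {m} posterior")
            if not np.allclose(post.grids[n], grids[n]):
                raise ABCError("posterior grids differ between models")
            acc += model_probs[m] * post.densities[n]
        total = np.trapezoid(acc, grids[n])
        dens[n] = acc / total
    return ParameterPosterior(names, grids, dens)
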