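"""Goodness-of-fit and calibration machinery for the ABC pipeline.

Two families of checks live here.

*Fit of the observed data* — after retention, does the observed statistic
vector look like a typical draw from the retained cloud?  The observed
P value ranks the GLM marginal likelihood of the observed vector among
the retained simulations; the Tukey (half-space) depth measures its
multivariate centrality, approximated by random projections.

*Calibration of the inference* — pseudo-observed datasets (pods) with
known truth are pushed through the full pipeline: binned posterior
probability of the chosen model against the empirical fraction correct
(p_ABC vs p_empirical), posterior-quantile uniformity per parameter, and
HPD-coverage curves.  A greedy forward search over candidate summary
statistics, scored by model-choice power on pods, is also provided.

Everything works on a ``SimulationStudy``: a bundle of model ids, a prior
and a ``simulate(model, draw, rng) -> stats`` callable.  The colonization
study used throughout the package is built by ``colonization_study``; unit
tests use cheap synthetic studies with known answers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

from .abcfit import (
    ABCError,
    ModelChoiceEngine,
    ParameterPosterior,
    PriorSpec,
    ReferenceTable,
    RetainedSet,
    fit_glm,
    parameter_posterior,
    pls_project,
    retain_nearest,
    robust_scale,
    to_sim_params,
)
from .coalsim import SampleConfig, default_sample_config, simulate_stat_vector
from .popstats import stat_names as full_stat_names


# ---------------------------------------------------------------------
# simulation studies


@dataclass
class SimulationStudy:
    """A self-contained simulation experiment for calibration and power."""

    models: list[str]
    prior: PriorSpec
    simulate: Callable[[str, dict, np.random.Generator], np.ndarray]
    stat_names: list[str]

    def build_tables(self, n_sims: int, seed: int) -> dict[str, ReferenceTable]:
        """One reference table per model, ``n_sims`` rows each."""
        tables = {}
        ss = np.random.SeedSequence(seed)
        for model, child in zip(self.models, ss.spawn(len(self.models))):
            rng = np.random.default_rng(child)
            P = np.empty((n_sims, len(self.prior.names)))
            S = np.empty((n_sims, len(self.stat_names)))
            for i in range(n_sims):
                draw = self.prior.sample(rng)
                P[i] = self.prior.vector(draw)
                S[i] = self.simulate(model, draw, rng)
            tables[model] = ReferenceTable(model, P, S, self.prior.names, self.stat_names)
        return tables

    def draw_pods(
        self, n_pods: int, seed: int, models: list[str] | None = None
    ) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Pseudo-observed datasets cycled equally across models.

        Returns (true model per pod, true parameter matrix, stat matrix).
        """
        models = models or self.models
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        truth_m, truth_p, stats = [], [], []
        for i in range(n_pods):
            m = models[i % len(models)]
            draw = self.prior.sample(rng)
            truth_m.append(m)
            truth_p.append(self.prior.vector(draw))
            stats.append(self.simulate(m, draw, rng))
        return truth_m, np.array(truth_p), np.array(stats)


def colonization_study(
    config: SampleConfig | None = None,
    missing_rate: float = 0.214,
    prior: PriorSpec | None = None,
) -> SimulationStudy:
    """The three-model invasion study at the dataset shape of the survey
    (6 x 450 bp loci, five sampled regions, ~21% missing calls)."""
    config = config or default_sample_config()
    prior = prior or PriorSpec()

    def simulate(model: str, draw: dict, rng: np.random.Generator) -> np.ndarray:
        return simulate_stat_vector(model, to_sim_params(draw), config, rng, missing_rate).values

    return SimulationStudy(["M1", "M2", "M3"], prior, simulate, full_stat_names(tuple(config.samples)))


# ---------------------------------------------------------------------
# observed P value


def observed_p_value(
    retained_stats: np.ndarray,
    retained_theta: np.ndarray,
    observed: np.ndarray,
) -> float:
    """Fraction of retained simulations whose GLM marginal likelihood is
    <= that of the observed statistics.  Values near 0 flag misfit."""
    if retained_stats.shape[0] == 0:
        raise ABCError("empty retained set")
    fit = fit_glm(retained_theta, retained_stats)
    pred = fit.predict(retained_theta)  # k x d

    def mixture_log_density(points: np.ndarray) -> np.ndarray:
        resid = points[:, None, :] - pred[None, :, :]  # m x k x d
        y = np.einsum("ij,mkj->mki", np.linalg.inv(fit.chol), resid)
        ll = -0.5 * (y**2).sum(axis=2) - 0.5 * fit.log_det - 0.5 * points.shape[1] * np.log(2 * np.pi)
        mx = ll.max(axis=1, keepdims=True)
        return (mx[:, 0] + np.log(np.exp(ll - mx).mean(axis=1)))

    d_obs = mixture_log_density(observed[None, :])[0]
    d_sims = mixture_log_density(retained_stats)
    return float((d_sims <= d_obs).mean())


# ---------------------------------------------------------------------
# Tukey depth


def _random_directions(d: int, n_directions: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.standard_normal((d, n_directions))
    return u / np.linalg.norm(u, axis=0, keepdims=True)


def tukey_depth(
    point: np.ndarray,
    cloud: np.ndarray,
    n_directions: int = 10_000,
    rng: np.random.Generator | None = None,
    directions: np.ndarray | None = None,
) -> float:
    """Randomized half-space (Tukey) depth of ``point`` in ``cloud``.

    For each random unit direction u the fraction of cloud points in each
    closed half-space through the point is computed; the depth estimate is
    the minimum over directions.  It upper-bounds the exact depth and is
    deterministic given the generator state.
    """
    cloud = np.atleast_2d(cloud)
    if cloud.shape[0] < 2:
        raise ABCError("cloud must contain at least 2 points")
    if np.allclose(cloud.std(axis=0), 0):
        raise ABCError("zero-variance cloud; depth undefined")
    if directions is None:
        rng = rng or np.random.default_rng()
        directions = _random_directions(cloud.shape[1], n_directions, rng)
    proj = cloud @ directions  # k x n_dir
    proj_pt = point @ directions
    frac_le = (proj <= proj_pt + 1e-12).mean(axis=0)
    frac_ge = (proj >= proj_pt - 1e-12).mean(axis=0)
    return float(np.minimum(frac_le, frac_ge).min())


def tukey_p_value(
    observed: np.ndarray,
    cloud: np.ndarray,
    n_directions: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """(depth of observed, fraction of cloud points with strictly smaller
    depth) — the leave-one-in convention: the observed point is appended
    to the ensemble so its depth and the retained depths are computed on
    the same reference set, under one shared set of directions.  An
    observed point drawn from the cloud's own distribution then gets a
    uniform p-value."""
    cloud = np.atleast_2d(cloud)
    rng = rng or np.random.default_rng()
    directions = _random_directions(cloud.shape[1], n_directions, rng)
    ensemble = np.vstack([cloud, observed[None, :]])
    proj = ensemble @ directions
    k = ensemble.shape[0]
    rank_le = sps.rankdata(proj, method="max", axis=0) / k
    rank_ge = (k - sps.rankdata(proj, method="min", axis=0) + 1) / k
    depths = np.minimum(rank_le, rank_ge).min(axis=1)
    d_obs = depths[-1]
    return float(d_obs), float((depths[:-1] < d_obs).mean())


# ---------------------------------------------------------------------
# model-choice calibration (p_ABC vs p_empirical)


@dataclass
class CalibrationReport:
    """Binned p_ABC vs p_empirical for the chosen model over pods."""

    bin_edges: np.ndarray
    counts: np.ndarray
    p_abc_mean: np.ndarray  # mean posterior of the chosen model per bin
    p_empirical: np.ndarray  # fraction of pods whose choice was correct
    flagged: np.ndarray  # bins with fewer than min_count pods
    min_count: int = 20

    def slope(self) -> float:
        """Count-weighted least-squares slope of p_empirical on p_ABC."""
        ok = self.counts > 0
        w = self.counts[ok]
        x, y = self.p_abc_mean[ok], self.p_empirical[ok]
        xm = (w * x).sum() / w.sum()
        ym = (w * y).sum() / w.sum()
        return float((w * (x - xm) * (y - ym)).sum() / (w * (x - xm) ** 2).sum())

    def as_rows(self) -> list[dict]:
        return [
            {
                "bin_lo": float(self.bin_edges[i]),
                "bin_hi": float(self.bin_edges[i + 1]),
                "n": int(self.counts[i]),
                "p_abc": float(self.p_abc_mean[i]),
                "p_empirical": float(self.p_empirical[i]),
                "flagged": bool(self.flagged[i]),
            }
            for i in range(len(self.counts))
        ]


def calibrate_model_choice(
    study: SimulationStudy,
    n_sims: int,
    k: int,
    n_pods: int,
    seed: int,
    stat_subset: list[str] | None = None,
    n_bins: int = 10,
    tables: dict[str, ReferenceTable] | None = None,
    min_count: int = 20,
) -> CalibrationReport:
    """Push pods through model choice and compare posterior probability of
    the chosen model with the empirical fraction of correct choices.

    Bins with fewer than ``min_count`` pods are flagged, never dropped.
    """
    subset = stat_subset or study.stat_names
    if tables is None:
        tables = study.build_tables(n_sims, seed)
    truth_m, _, pod_stats = study.draw_pods(n_pods, seed + 1)
    idx = {n: i for i, n in enumerate(study.stat_names)}
    cols = [idx[n] for n in subset]

    engine = ModelChoiceEngine(tables, subset)
    p_best = np.empty(n_pods)
    correct = np.empty(n_pods, dtype=bool)
    for i in range(n_pods):
        post = engine.posterior(pod_stats[i, cols], k=k)
        p_best[i] = post.probabilities[post.best]
        correct[i] = post.best == truth_m[i]

    edges = np.linspace(0.0, 1.0 + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(p_best, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    p_abc = np.array([p_best[which == b].mean() if counts[b] else np.nan for b in range(n_bins)])
    p_emp = np.array([correct[which == b].mean() if counts[b] else np.nan for b in range(n_bins)])
    return CalibrationReport(edges, counts, p_abc, p_emp, counts < min_count, min_count)


# ---------------------------------------------------------------------
# posterior-quantile and HPD checks


@dataclass
class QuantileReport:
    """Per-parameter posterior quantiles of the truth over pods."""

    param_names: list[str]
    quantiles: np.ndarray  # n_pods x n_params
    hpd_levels: np.ndarray  # n_pods x n_params (mass of smallest HPD containing truth)

    def ks_pvalues(self) -> dict[str, float]:
        return {
            name: float(sps.kstest(self.quantiles[:, j], "uniform").pvalue)
            for j, name in enumerate(self.param_names)
        }

    def hpd_coverage(self, level: float) -> dict[str, float]:
        """Fraction of pods whose truth lies inside the x% HPD interval."""
        return {
            name: float((self.hpd_levels[:, j] <= level).mean())
            for j, name in enumerate(self.param_names)
        }


def posterior_quantile_check(
    study: SimulationStudy,
    model: str,
    n_sims: int,
    k: int,
    n_pods: int,
    seed: int,
    stat_subset: list[str] | None = None,
    use_pls: bool = False,
    n_components: int = 7,
    table: ReferenceTable | None = None,
) -> QuantileReport:
    """Uniformity check of posterior quantiles (and HPD levels) of the
    truth across pods drawn from the prior.

    If the marginal posteriors are unbiased, the quantile of the true
    parameter under its estimated posterior is uniform on [0, 1], and so
    is the mass of the smallest HPD region containing the truth.
    """
    subset = stat_subset or study.stat_names
    if table is None:
        table = study.build_tables(n_sims, seed)[model] if model in study.models else None
    if table is None:
        raise ABCError(f"unknown model {model!r}")
    idx = {n: i for i, n in enumerate(study.stat_names)}
    cols = [idx[n] for n in subset]
    stats = table.stats[:, cols]

    proj = None
    if use_pls:
        space, proj = pls_project(stats, table.params, n_components=n_components)
    else:
        space = stats

    truth_m, truth_p, pod_stats = study.draw_pods(n_pods, seed + 1, models=[model])
    q = np.empty((n_pods, len(study.prior.names)))
    hpd = np.empty_like(q)
    for i in range(n_pods):
        obs = pod_stats[i, cols]
        obs_space = proj.transform(obs)[0] if proj is not None else obs
        ret = retain_nearest(space, obs_space, k)
        z = (space[ret.indices] - ret.center) / ret.scale
        zo = (obs_space - ret.center) / ret.scale
        post = parameter_posterior(table.params[ret.indices], z, zo, study.prior)
        for j, name in enumerate(study.prior.names):
            q[i, j] = post.quantile_of(name, truth_p[i, j])
            hpd[i, j] = post.hpd_level_of(name, truth_p[i, j])
    return QuantileReport(list(study.prior.names), q, hpd)


# ---------------------------------------------------------------------
# power + greedy statistic selection


def model_choice_power_from_tables(
    tables: dict[str, ReferenceTable],
    pod_truth: list[str],
    pod_stats: np.ndarray,
    stat_subset: list[str] | tuple[str, ...],
    all_names: list[str],
    k: int,
) -> tuple[float, float]:
    """Fraction of pods whose true model attains the highest posterior,
    with its binomial standard error."""
    idx = {n: i for i, n in enumerate(all_names)}
    cols = [idx[n] for n in stat_subset]
    engine = ModelChoiceEngine(tables, stat_subset)
    hits = 0
    n = len(pod_truth)
    for i in range(n):
        post = engine.posterior(pod_stats[i, cols], k=k)
        hits += post.best == pod_truth[i]
    p = hits / n
    return p, float(np.sqrt(p * (1 - p) / n))


def select_statistics_greedy(
    study: SimulationStudy,
    candidate_stats: list[str],
    n_sims: int,
    n_pods: int,
    k: int,
    seed: int,
    max_stats: int | None = None,
) -> tuple[list[str], float]:
    """Greedy forward selection of summary statistics for model choice.

    All pairs are scored first; the best pair seeds the subset, then the
    statistic improving power the most is appended until no candidate
    improves it.  One reference table and one pod set are shared across
    all candidate subsets (common random numbers), so the search is
    deterministic given the seed.
    """
    if len(candidate_stats) < 2:
        raise ABCError("need at least two candidate statistics")
    tables = study.build_tables(n_sims, seed)
    truth, _, pods = study.draw_pods(n_pods, seed + 1)

    def power_of(subset: list[str]) -> float:
        return model_choice_power_from_tables(tables, truth, pods, subset, study.stat_names, k)[0]

    best_subset, best_power = None, -1.0
    for pair in itertools.combinations(candidate_stats, 2):
        p = power_of(list(pair))
        if p > best_power:
            best_subset, best_power = list(pair), p

    while max_stats is None or len(best_subset) < max_stats:
        best_cand, best_cand_power = None, best_power
        for cand in candidate_stats:
            if cand in best_subset:
                continue
            p = power_of(best_subset + [cand])
            if p > best_cand_power:
                best_cand, best_cand_power = cand, p
        if best_cand is None:
            break
        best_subset, best_power = best_subset + [best_cand], best_cand_power
    return best_subset, best_power
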