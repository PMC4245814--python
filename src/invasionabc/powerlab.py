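"""Power and information analyses for recent-invasion inference.

How much sequence data does it take to tell colonization histories apart?
This module measures model-choice power as a function of the number of
independent loci, fits the empirically logarithmic power curve and inverts
it for a target power; and quantifies the information content of a founder
event through the number of ancestral lineages L_A (diversity inherited
from the source) and the genealogy length since colonization G_L
(proportional to the expected number of new mutations), on grids over the
founder count f and colonization time tau.

The L_A / G_L machinery runs on the exact time-inhomogeneous coalescent in
``growthcoal``; model-choice power runs on the full ABC pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .coalsim import default_sample_config
from .growthcoal import GrowthScenario, simulate_lineages
from .popstats import SELECTED6
from .validate import (
    SimulationStudy,
    colonization_study,
    model_choice_power_from_tables,
)

DEFAULT_MU = 3.46e-9
DEFAULT_LOCUS_BP = 450

#: Example founder-event scenario pairs with matched expected numbers of
#: ancestral lineages E(L_A) but different colonization times/founder
#: counts (hence different E(G_L)).  Found by grid search at n = 25
#: samples and N_present = 10,000; pair A has the smallest E(L_A)
#: (~2.7), B an intermediate one (~11), C the largest (~20).
EXAMPLE_MATCHED_PAIRS: dict[str, tuple[GrowthScenario, GrowthScenario]] = {
    "A": (GrowthScenario(10_000.0, 130, 434), GrowthScenario(10_000.0, 40, 170)),
    "B": (GrowthScenario(10_000.0, 180, 78), GrowthScenario(10_000.0, 55, 29)),
    "C": (GrowthScenario(10_000.0, 1000, 50), GrowthScenario(10_000.0, 380, 25)),
}


# ---------------------------------------------------------------------
# model-choice power vs number of loci


def model_choice_power(
    n_loci: int,
    n_sims: int,
    n_pods: int,
    k: int,
    seed: int,
    stat_subset: tuple[str, ...] | list[str] = SELECTED6,
    locus_length: int = DEFAULT_LOCUS_BP,
    missing_rate: float = 0.214,
    study: SimulationStudy | None = None,
) -> tuple[float, float]:
    """Power to pick the true colonization model at a given locus count.

    Pods are drawn equally from the three models under the priors; power
    is the fraction whose true model attains the highest posterior, with
    its binomial SE.  One reference table per model is shared across all
    pods (common random numbers).
    """
    if n_loci < 1:
        raise ValueError("need at least one locus")
    if study is None:
        config = default_sample_config(n_loci=n_loci, locus_length=locus_length)
        study = colonization_study(config, missing_rate=missing_rate)
    tables = study.build_tables(n_sims, seed)
    truth, _, pods = study.draw_pods(n_pods, seed + 1)
    return model_choice_power_from_tables(tables, truth, pods, stat_subset, study.stat_names, k)


@dataclass
class PowerCurve:
    """Least-squares fit of power = a + b * log10(loci)."""

    loci_counts: np.ndarray
    power: np.ndarray
    se: np.ndarray
    a: float
    b: float

    def predict(self, loci: float) -> float:
        return self.a + self.b * np.log10(loci)

    def loci_for(self, target: float) -> tuple[float, bool]:
        """Loci needed for a target power; second element flags
        extrapolation beyond the largest fitted count (or an unreachable
        target when the fitted slope is non-positive -> inf)."""
        if self.b <= 1e-12:
            return float("inf"), True
        with np.errstate(over="ignore"):
            exponent = (target - self.a) / self.b
            loci = float(10.0**exponent) if exponent < 300 else float("inf")
        return loci, bool(loci > self.loci_counts.max())

    def sequence_requirement_mb(self, target: float, locus_length: int = DEFAULT_LOCUS_BP) -> float:
        loci, _ = self.loci_for(target)
        return loci * locus_length / 1e6


def fit_power_curve(loci_counts, power, se=None) -> PowerCurve:
    """Fit power against log10(number of loci)."""
    loci_counts = np.asarray(loci_counts, dtype=float)
    power = np.asarray(power, dtype=float)
    if loci_counts.size < 3:
        raise ValueError("need at least three points to fit the curve")
    if not (np.all(np.isfinite(loci_counts)) and np.all(np.isfinite(power))):
        raise ValueError("non-finite inputs to the power-curve fit")
    b, a = np.polyfit(np.log10(loci_counts), power, 1)
    se = np.zeros_like(power) if se is None else np.asarray(se, dtype=float)
    return PowerCurve(loci_counts, power, se, float(a), float(b))


# ---------------------------------------------------------------------
# ancestral lineages and genealogy length grids


@dataclass
class LineageGrid:
    """Monte-Carlo E(L_A) and E(G_L) over a (f, tau) grid."""

    f_values: np.ndarray
    tau_values: np.ndarray
    E_LA: np.ndarray  # len(f) x len(tau)
    se_LA: np.ndarray
    E_GL: np.ndarray
    se_GL: np.ndarray
    n: int
    N_present: float


def lineage_grid(
    f_values,
    tau_values,
    N_present: float = 10_000.0,
    n: int = 25,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> LineageGrid:
    """Expected ancestral lineages and genealogy length since colonization
    for every founder-count x colonization-time combination.

    The colonized population grows exponentially from f at tau to
    ``N_present`` now; the present size is held fixed so the grid isolates
    the founder event itself.
    """
    rng = rng or np.random.default_rng()
    f_values = np.asarray(f_values, dtype=float)
    tau_values = np.asarray(tau_values, dtype=float)
    shape = (f_values.size, tau_values.size)
    E_LA, se_LA = np.empty(shape), np.empty(shape)
    E_GL, se_GL = np.empty(shape), np.empty(shape)
    for i, f in enumerate(f_values):
        for j, tau in enumerate(tau_values):
            scen = GrowthScenario(N_present=N_present, f=f, tau=tau)
            La = np.empty(reps)
            Gl = np.empty(reps)
            for r in range(reps):
                traj = simulate_lineages(n, scen, rng)
                La[r], Gl[r] = traj.L_end, traj.length
            E_LA[i, j], se_LA[i, j] = La.mean(), La.std(ddof=1) / np.sqrt(reps)
            E_GL[i, j], se_GL[i, j] = Gl.mean(), Gl.std(ddof=1) / np.sqrt(reps)
    return LineageGrid(f_values, tau_values, E_LA, se_LA, E_GL, se_GL, n, N_present)


# ---------------------------------------------------------------------
# new-mutation count distributions


@dataclass
class MutationCountDistribution:
    counts: np.ndarray
    pmf: np.ndarray
    mean: float

    def __post_init__(self) -> None:
        total = self.pmf.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"pmf sums to {total}, not 1")


def new_mutation_pmf(
    scenario: GrowthScenario,
    l_loci: int,
    mu: float = DEFAULT_MU,
    locus_length: int = DEFAULT_LOCUS_BP,
    reps: int = 2000,
    n: int = 25,
    rng: np.random.Generator | None = None,
    tail: float = 1e-10,
) -> MutationCountDistribution:
    """Distribution of the number of new (post-colonization) mutations
    across ``l_loci`` independent loci.

    Per-locus genealogy lengths since colonization are simulated once;
    totals over loci are drawn by resampling sums from that pool, and the
    pmf is the resulting mixture of Poisson(mu * L * total) distributions.
    """
    if reps < 1000:
        raise ValueError("need at least 1000 replicates")
    rng = rng or np.random.default_rng()
    pool = np.array([simulate_lineages(n, scenario, rng).length for r in range(reps)])
    totals = pool[rng.integers(0, reps, size=(reps, l_loci))].sum(axis=1)
    lam = mu * locus_length * totals
    if np.all(lam == 0):
        return MutationCountDistribution(np.array([0]), np.array([1.0]), 0.0)
    kmax = int(sps.poisson.ppf(1 - tail, lam.max())) + 1
    counts = np.arange(kmax + 1)
    pmf = sps.poisson.pmf(counts[:, None], lam[None, :]).mean(axis=1)
    pmf = pmf / pmf.sum()
    return MutationCountDistribution(counts, pmf, float(lam.mean()))


def pmf_overlap(p: MutationCountDistribution | np.ndarray, q: MutationCountDistribution | np.ndarray) -> float:
    """Overlap sum_k min(p_k, q_k) of two pmfs on a shared integer support."""
    pv = p.pmf if isinstance(p, MutationCountDistribution) else np.asarray(p, dtype=float)
    qv = q.pmf if isinstance(q, MutationCountDistribution) else np.asarray(q, dtype=float)
    for v in (pv, qv):
        if not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise ValueError("pmf_overlap requires normalized inputs")
    m = max(pv.size, qv.size)
    pv = np.pad(pv, (0, m - pv.size))
    qv = np.pad(qv, (0, m - qv.size))
    return float(np.minimum(pv, qv).sum())


# ---------------------------------------------------------------------
# sample-size effects


def sample_size_gain(
    scenario: GrowthScenario,
    n1: int,
    n2: int,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Percent increase in expected genealogy length (hence expected
    mutations) when the sample grows from n1 to n2.

    For founder scenarios the length since colonization is used (the
    new-mutation budget); for constant-size scenarios the total tree
    length, whose closed form is the harmonic sum (see harmonic_gain).
    """
    if n2 <= n1:
        if n2 == n1:
            return 0.0
        raise ValueError("n2 must be >= n1")
    rng = rng or np.random.default_rng()
    L1 = np.mean([simulate_lineages(n1, scenario, rng).length for _ in range(reps)])
    L2 = np.mean([simulate_lineages(n2, scenario, rng).length for _ in range(reps)])
    return float(100.0 * (L2 / L1 - 1.0))


def harmonic_gain(n1: int, n2: int) -> float:
    """Exact percent increase in expected mutation count for a constant
    population: 100 * (H_{n2-1} / H_{n1-1} - 1), H the harmonic number."""
    if n1 < 2 or n2 < n1:
        raise ValueError("need n2 >= n1 >= 2")
    h1 = (1.0 / np.arange(1, n1)).sum()
    h2 = (1.0 / np.arange(1, n2)).sum()
    return float(100.0 * (h2 / h1 - 1.0))
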