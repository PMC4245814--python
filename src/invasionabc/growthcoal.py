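"""Coalescent times in exponentially growing or constant populations.

A small, exact, time-inhomogeneous coalescent simulator written directly
from the rate integral: with k lineages in a haploid
population of size N(t), the coalescence rate is C(k,2)/N(t) per
generation.  For a population founded by f individuals tau generations ago
that grew exponentially to present size N, the backwards-time size is
N(t) = N * exp(-r t) with r = ln(N/f)/tau on t in [0, tau), and f beyond.

Waiting times are drawn by inverting the cumulative rate, so no time
discretization is involved.  This module is deliberately independent of
the msprime-backed simulator: the two act as cross-checks on each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GrowthScenario:
    """A founder-event scenario: f founders at time tau, size N_present now.

    ``tau=None`` means a constant-size population of size ``N_present``
    (no founding event).
    """

    N_present: float = 10_000.0
    f: float | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        if (self.f is None) != (self.tau is None):
            raise ValueError("f and tau must be given together")
        if self.f is not None and self.f > self.N_present:
            raise ValueError("founder count cannot exceed present size")


@dataclass
class LineageTrajectory:
    """Coalescence record of one replicate.

    ``coal_times`` are the event times (generations before present) that
    occurred before ``t_stop``; ``L_end`` is the number of lineages left at
    ``t_stop``; ``length`` is the total branch length accumulated on
    [0, t_stop].
    """

    coal_times: np.ndarray
    L_end: int
    length: float


def _next_coal_time(t0: float, k: int, N0: float, r: float, rng: np.random.Generator) -> float:
    """Time of next coalescence given k lineages, N(t) = N0 * exp(-r t)."""
    rate0 = k * (k - 1) / 2.0 / N0
    e = rng.exponential()
    if r == 0.0:
        return t0 + e / rate0
    # integral of rate0*exp(r s) from t0 to t equals e
    return np.log(np.exp(r * t0) + e * r / rate0) / r


def simulate_lineages(
    n: int,
    scenario: GrowthScenario,
    rng: np.random.Generator,
    t_stop: float | None = None,
) -> LineageTrajectory:
    """Simulate coalescence times for ``n`` sampled lineages.

    If ``t_stop`` is None it defaults to the scenario's founding time tau
    (so ``L_end`` is the number of ancestral lineages L_A and ``length``
    the genealogy length since colonization G_L); for a constant scenario
    the default runs to the MRCA.
    """
    if n < 1:
        raise ValueError("need at least one lineage")
    tau = scenario.tau
    if t_stop is None:
        t_stop = tau if tau is not None else np.inf
    r = 0.0 if tau is None else np.log(scenario.N_present / scenario.f) / tau

    t = 0.0
    k = n
    times = []
    length = 0.0
    while k > 1:
        if tau is None or t < tau:
            t_next = _next_coal_time(t, k, scenario.N_present, r, rng)
            if tau is not None and t_next > tau:
                # no event before the founding time; re-draw in the f epoch
                length += k * (min(tau, t_stop) - t)
                if t_stop <= tau:
                    return LineageTrajectory(np.array(times), k, length)
                t = tau
                continue
        else:
            t_next = t + rng.exponential() / (k * (k - 1) / 2.0 / scenario.f)
        if t_next >= t_stop:
            length += k * (t_stop - t)
            return LineageTrajectory(np.array(times), k, length)
        length += k * (t_next - t)
        t = t_next
        times.append(t)
        k -= 1
    return LineageTrajectory(np.array(times), 1, length)


def mean_lineage_stats(
    n: int,
    scenario: GrowthScenario,
    reps: int,
    rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    """Monte-Carlo means (and standard errors) of L_A and G_L at tau."""
    if scenario.tau is None:
        raise ValueError("scenario has no founding time")
    La = np.empty(reps)
    Gl = np.empty(reps)
    for i in range(reps):
        traj = simulate_lineages(n, scenario, rng)
        La[i] = traj.L_end
        Gl[i] = traj.length
    return (
        float(La.mean()),
        float(La.std(ddof=1) / np.sqrt(reps)),
        float(Gl.mean()),
        float(Gl.std(ddof=1) / np.sqrt(reps)),
    )


def total_tree_length(n: int, scenario: GrowthScenario, rng: np.random.Generator) -> float:
    """Total branch length: since colonization for founder scenarios
    (new-mutation budget), to the MRCA for constant scenarios."""
    return simulate_lineages(n, scenario, rng).length


def t_mrca(n: int, N: float, rng: np.random.Generator) -> float:
    """Time to MRCA in a constant haploid population (closed-form check:
    E[T_MRCA] = 2N(1 - 1/n))."""
    traj = simulate_lineages(n, GrowthScenario(N_present=N), rng)
    return float(traj.coal_times[-1])
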