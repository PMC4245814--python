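"""Structured-coalescent simulation of native-range and colonization models.

Model vocabulary
----------------
Five geographic regions are sampled: JP (native range), HI, WUS, EUS and
SP, plus an unsampled source pool ASIA.  JP exchanges migrants with ASIA
symmetrically at intensity Nm (expected migrant lineages per generation)
throughout.  Each colonized region is founded by ``f`` individuals at time
``tau`` generations ago and grows exponentially to its present size ``N``.
The three colonization histories differ only in the source of the
founders:

* ``M1`` — HI, WUS, EUS and SP founded independently from ASIA;
* ``M2`` — as M1 but EUS founded from WUS;
* ``M3`` — as M1 but EUS and SP both founded from WUS.

Colonization times are constrained ``tau_HI > tau_WUS > tau_SP > tau_EUS``.
Five single-population models of the native range are also available for
goodness-of-fit comparisons on the JP sample alone.

Genealogies are generated with msprime (haploid samples, one
non-recombining tree per locus); mutations fall at rate mu per site per
generation onto discrete integer positions (a finite-sites binary model,
so the site count never exceeds the locus length).  All sizes are haploid
effective sizes and coalescence happens at rate C(k,2)/N per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .popstats import StatVector, stat_vector_from_matrix
from .seqdata import MISSING, REGIONS, LocusAlignment, MultiLocusDataset

COLONIZED = ("HI", "WUS", "EUS", "SP")

COLONIZATION_MODELS = ("M1", "M2", "M3")
NATIVE_MODELS = (
    "native-constant",
    "native-expgrowth",
    "native-instgrowth",
    "native-colonized",
    "native-structured",
)

#: Founding source of each colonized region, per model.
MODEL_SOURCES = {
    "M1": {"HI": "ASIA", "WUS": "ASIA", "EUS": "ASIA", "SP": "ASIA"},
    "M2": {"HI": "ASIA", "WUS": "ASIA", "EUS": "WUS", "SP": "ASIA"},
    "M3": {"HI": "ASIA", "WUS": "ASIA", "EUS": "WUS", "SP": "WUS"},
}


_BINARY = msprime.BinaryMutationModel()


class ModelError(ValueError):
    pass


@dataclass
class DemographyGraph:
    """A fully parameterized demographic model ready for simulation."""

    model_id: str
    N: dict[str, float]  # present haploid sizes per deme
    f: dict[str, float] = field(default_factory=dict)  # founder counts
    tau: dict[str, float] = field(default_factory=dict)  # founding times (generations)
    Nm: float = 0.0  # JP<->ASIA migration intensity
    mu: float = 3.46e-9  # per-site per-generation mutation rate

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ModelError("mutation rate must be positive")
        for d, n in self.N.items():
            if n <= 0:
                raise ModelError(f"non-positive size for {d}")
        # f may exceed N: the prior supports it, and the backwards size
        # trajectory simply declines instead of growing in that corner.
        for r, fv in self.f.items():
            if fv <= 0:
                raise ModelError(f"non-positive founder count for {r}")
        if self.model_id in COLONIZATION_MODELS:
            t = self.tau
            if not (t["HI"] > t["WUS"] > t["SP"] > t["EUS"]):
                raise ModelError(
                    "colonization times must satisfy tau_HI > tau_WUS > tau_SP > tau_EUS"
                )


def build_demography(model_id: str, params: dict[str, float]) -> DemographyGraph:
    """Assemble a DemographyGraph from a flat parameter dict.

    Colonization models take ``N_ASIA, N_JP, N_HI, N_WUS, N_EUS, N_SP,
    f_HI, f_WUS, f_EUS, f_SP, tau_HI, tau_WUS, tau_EUS, tau_SP, Nm, mu``.
    Native-range models take the subset they need (see the methods note).
    """
    mu = params.get("mu", 3.46e-9)
    if model_id in COLONIZATION_MODELS:
        return DemographyGraph(
            model_id,
            N={d: params[f"N_{d}"] for d in ("ASIA", "JP") + COLONIZED},
            f={r: params[f"f_{r}"] for r in COLONIZED},
            tau={r: params[f"tau_{r}"] for r in COLONIZED},
            Nm=params["Nm"],
            mu=mu,
        )
    if model_id == "native-constant":
        return DemographyGraph(model_id, N={"JP": params["N_JP"]}, mu=mu)
    if model_id in ("native-expgrowth", "native-instgrowth"):
        return DemographyGraph(
            model_id,
            N={"JP": params["N_JP"], "ANC": params["N_ANC"]},
            tau={"JP": params["t_growth"]},
            mu=mu,
        )
    if model_id == "native-colonized":
        return DemographyGraph(
            model_id,
            N={"JP": params["N_JP"], "ASIA": params["N_ASIA"]},
            f={"JP": params["f_JP"]},
            tau={"JP": params["tau_JP"]},
            mu=mu,
        )
    if model_id == "native-structured":
        return DemographyGraph(
            model_id,
            N={"JP": params["N_JP"], "ASIA": params["N_ASIA"]},
            Nm=params["Nm"],
            mu=mu,
        )
    raise ModelError(f"unknown model id {model_id!r}")


def to_msprime(graph: DemographyGraph) -> msprime.Demography:
    """Translate a DemographyGraph into an msprime Demography.

    Founded demes shrink exponentially backwards in time from N to f over
    tau, then their lineages move to the source deme (mass migration; the
    source stays active so JP<->ASIA migration runs at all times).
    """
    d = msprime.Demography()
    m = graph.model_id
    if m in COLONIZATION_MODELS:
        d.add_population(name="ASIA", initial_size=graph.N["ASIA"])
        d.add_population(name="JP", initial_size=graph.N["JP"])
        for r in COLONIZED:
            growth = np.log(graph.N[r] / graph.f[r]) / graph.tau[r]
            d.add_population(name=r, initial_size=graph.N[r], growth_rate=growth)
        if graph.Nm > 0:
            d.set_migration_rate("JP", "ASIA", graph.Nm / graph.N["JP"])
            d.set_migration_rate("ASIA", "JP", graph.Nm / graph.N["ASIA"])
        src = MODEL_SOURCES[m]
        for r in COLONIZED:
            d.add_mass_migration(time=graph.tau[r], source=r, dest=src[r], proportion=1.0)
            d.add_population_parameters_change(
                time=graph.tau[r], population=r, initial_size=graph.f[r], growth_rate=0
            )
        d.sort_events()
        return d
    if m == "native-constant":
        d.add_population(name="JP", initial_size=graph.N["JP"])
        return d
    if m == "native-expgrowth":
        t = graph.tau["JP"]
        growth = np.log(graph.N["JP"] / graph.N["ANC"]) / t
        d.add_population(name="JP", initial_size=graph.N["JP"], growth_rate=growth)
        d.add_population_parameters_change(
            time=t, population="JP", initial_size=graph.N["ANC"], growth_rate=0
        )
        return d
    if m == "native-instgrowth":
        d.add_population(name="JP", initial_size=graph.N["JP"])
        d.add_population_parameters_change(
            time=graph.tau["JP"], population="JP", initial_size=graph.N["ANC"]
        )
        return d
    if m == "native-colonized":
        d.add_population(name="ASIA", initial_size=graph.N["ASIA"])
        growth = np.log(graph.N["JP"] / graph.f["JP"]) / graph.tau["JP"]
        d.add_population(name="JP", initial_size=graph.N["JP"], growth_rate=growth)
        d.add_mass_migration(time=graph.tau["JP"], source="JP", dest="ASIA", proportion=1.0)
        d.add_population_parameters_change(
            time=graph.tau["JP"], population="JP", initial_size=graph.f["JP"], growth_rate=0
        )
        d.sort_events()
        return d
    if m == "native-structured":
        d.add_population(name="ASIA", initial_size=graph.N["ASIA"])
        d.add_population(name="JP", initial_size=graph.N["JP"])
        d.set_migration_rate("JP", "ASIA", graph.Nm / graph.N["JP"])
        d.set_migration_rate("ASIA", "JP", graph.Nm / graph.N["ASIA"])
        return d
    raise ModelError(f"unknown model id {m!r}")


# ---------------------------------------------------------------------
# sampling configuration


@dataclass
class SampleConfig:
    """Haploid sample counts per sampled deme plus the locus layout."""

    samples: dict[str, int]
    loci: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.samples.values()):
            raise ModelError("sample counts must be positive")
        if any(length <= 0 for _, length in self.loci):
            raise ModelError("locus lengths must be positive")

    @property
    def total_samples(self) -> int:
        return sum(self.samples.values())

    def region_slices(self) -> dict[str, np.ndarray]:
        out = {}
        start = 0
        for deme, n in self.samples.items():
            out[deme] = np.arange(start, start + n)
            start += n
        return out


def default_sample_config(
    n_loci: int = 6,
    locus_length: int = 450,
    samples: dict[str, int] | None = None,
) -> SampleConfig:
    """The study-shaped default: 6 x 450 bp loci, five sampled regions."""
    if samples is None:
        samples = {"JP": 20, "HI": 15, "WUS": 40, "EUS": 120, "SP": 15}
    loci = [(f"L{i+1}", locus_length) for i in range(n_loci)]
    return SampleConfig(samples, loci)


# ---------------------------------------------------------------------
# genealogies and derived quantities


@dataclass
class GenealogyStats:
    """One locus genealogy plus founder-event summaries.

    ``L_A[r]`` is the number of lineages of region r's sample not yet
    coalesced at r's founding time; ``G_L[r]`` the total branch length of
    r's sample genealogy more recent than that time.
    """

    tree_sequence: object
    L_A: dict[str, int]
    G_L: dict[str, float]


def lineage_stats_from_tree(tree, sample_nodes: np.ndarray, tau: float) -> tuple[int, float]:
    """(L_A, G_L) of a sample subset at time tau, from a tskit tree."""
    sample_set = set(int(s) for s in sample_nodes)
    ts = tree.tree_sequence
    time = ts.tables.nodes.time
    # ancestors of the subset
    tracked: set[int] = set()
    for s in sample_set:
        u = s
        while u != -1 and u not in tracked:
            tracked.add(u)
            u = tree.parent(u)
    L = 0
    G = 0.0
    for u in tracked:
        p = tree.parent(u)
        t_u = time[u]
        t_p = time[p] if p != -1 else np.inf
        if t_u < tau <= t_p:
            L += 1
        if p != -1:
            G += max(0.0, min(t_p, tau) - min(t_u, tau))
    return L, G


def simulate_genealogy(
    graph: DemographyGraph,
    config: SampleConfig,
    rng: np.random.Generator,
) -> list[GenealogyStats]:
    """One genealogy per locus, with L_A and G_L per founded region."""
    demog = to_msprime(graph)
    sample_sets = [msprime.SampleSet(n, population=d, ploidy=1) for d, n in config.samples.items()]
    slices = config.region_slices()
    out = []
    for _, length in config.loci:
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=demog,
            ploidy=1,
            sequence_length=length,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        tree = ts.first()
        LA: dict[str, int] = {}
        GL: dict[str, float] = {}
        for r, tau in graph.tau.items():
            if r in slices:
                nodes = ts.samples()[slices[r]]
                LA[r], GL[r] = lineage_stats_from_tree(tree, nodes, tau)
        out.append(GenealogyStats(ts, LA, GL))
    return out


def drop_mutations(
    genealogies: list[GenealogyStats],
    mu: float,
    locus_ids: list[str],
    rng: np.random.Generator,
) -> list[LocusAlignment]:
    """Sprinkle mutations (Poisson rate mu*L per unit branch length, one
    integer position per site) on each genealogy and return full-length
    per-locus alignments: monomorphic columns carry the reference allele,
    segregating columns sit at their simulated positions."""
    out = []
    for gs, locus_id in zip(genealogies, locus_ids):
        ts = gs.tree_sequence
        seg, positions = _mutate_to_matrix(ts, mu, rng, with_positions=True)
        L = int(ts.sequence_length)
        mat = np.zeros((seg.shape[0], L), dtype=np.int8)
        mat[:, positions] = seg
        out.append(LocusAlignment(locus_id, mat))
    return out


def _mutate_to_matrix(
    ts, mu: float, rng: np.random.Generator, with_positions: bool = False
):
    """Genotype matrix (individuals x segregating sites, int8 in {0,1})."""
    mts = msprime.sim_mutations(
        ts,
        rate=mu,
        random_seed=int(rng.integers(1, 2**31 - 1)),
        discrete_genome=True,
        model=_BINARY,
        record_provenance=False,
    )
    if mts.num_sites == 0:
        mat = np.zeros((mts.num_samples, 0), dtype=np.int8)
        return (mat, np.array([], dtype=int)) if with_positions else mat
    mat = mts.genotype_matrix().T.astype(np.int8)
    if with_positions:
        return mat, mts.tables.sites.position.astype(int)
    return mat


def apply_missing_mask(
    loci: list[LocusAlignment],
    rate: float,
    rng: np.random.Generator,
    mode: str = "iid",
) -> list[LocusAlignment]:
    """Overlay a missing-data mask: i.i.d. per cell, or whole-individual
    blocks per locus (PCR-dropout style)."""
    out = []
    for loc in loci:
        mat = loc.haplotypes.copy()
        if mat.size:
            if mode == "iid":
                mask = rng.random(mat.shape) < rate
            elif mode == "block":
                mask = np.zeros(mat.shape, dtype=bool)
                mask[rng.random(mat.shape[0]) < rate, :] = True
            else:
                raise ModelError(f"unknown missing-data mode {mode!r}")
            mat[mask] = MISSING
        out.append(LocusAlignment(loc.locus_id, mat, loc.noncoding.copy()))
    return out


def simulate_dataset(
    model_id: str,
    params: dict[str, float],
    config: SampleConfig,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    missing_mode: str = "iid",
) -> MultiLocusDataset:
    """Full dataset simulation: genealogies, mutations, optional missing mask.

    The true (model, parameters) record is kept in ``dataset.meta``.
    Deterministic for a given generator state.
    """
    graph = build_demography(model_id, params)
    genealogies = simulate_genealogy(graph, config, rng)
    loci = drop_mutations(genealogies, graph.mu, [lid for lid, _ in config.loci], rng)
    if missing_rate > 0:
        loci = apply_missing_mask(loci, missing_rate, rng, missing_mode)
    individuals = []
    pop_of = {}
    region_of = {}
    for deme, n in config.samples.items():
        region_of[deme] = deme
        for i in range(n):
            name = f"{deme}_{i:03d}"
            individuals.append(name)
            pop_of[name] = deme
    meta = {"model": model_id, "params": {k: float(v) for k, v in params.items()}}
    return MultiLocusDataset(loci, individuals, pop_of, region_of, meta)


# ---------------------------------------------------------------------
# fast path for reference-table construction


def simulate_stat_vector(
    model_id: str,
    params: dict[str, float],
    config: SampleConfig,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> StatVector:
    """Simulate one dataset and summarize it, without FASTA plumbing.

    Uses the same statistic code path as observed data
    (``stat_vector_from_matrix``): segregating columns are materialized,
    and the monomorphic remainder of every locus enters in compact form
    (per-region non-missing counts drawn from the missing model), so all
    per-site estimators see the full locus length.
    """
    graph = build_demography(model_id, params)
    demog = to_msprime(graph)
    sample_sets = [msprime.SampleSet(n, population=d, ploidy=1) for d, n in config.samples.items()]
    mats = []
    n_samp = config.total_samples
    total_bp = sum(length for _, length in config.loci)
    lengths = {length for _, length in config.loci}
    if len(lengths) == 1:
        # all loci equal length: one replicated ancestry call
        reps = msprime.sim_ancestry(
            samples=sample_sets,
            demography=demog,
            ploidy=1,
            sequence_length=lengths.pop(),
            num_replicates=len(config.loci),
            random_seed=int(rng.integers(1, 2**31 - 1)),
            record_provenance=False,
        )
        for ts in reps:
            mats.append(_mutate_to_matrix(ts, graph.mu, rng))
    else:
        for _, length in config.loci:
            ts = msprime.sim_ancestry(
                samples=sample_sets,
                demography=demog,
                ploidy=1,
                sequence_length=length,
                random_seed=int(rng.integers(1, 2**31 - 1)),
                record_provenance=False,
            )
            mats.append(_mutate_to_matrix(ts, graph.mu, rng))
    mat = np.concatenate(mats, axis=1) if mats else np.zeros((n_samp, 0), dtype=np.int8)
    if missing_rate > 0 and mat.size:
        mat = mat.copy()
        mat[rng.random(mat.shape) < missing_rate] = MISSING
    n_invariant = max(0, total_bp - mat.shape[1])
    slices = config.region_slices()
    invariant_counts = {
        r: rng.binomial(len(idx), 1.0 - missing_rate, size=n_invariant)
        for r, idx in slices.items()
    }
    return stat_vector_from_matrix(
        mat, slices, tuple(config.samples), invariant_counts=invariant_counts
    )
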