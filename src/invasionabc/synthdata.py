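"""Pseudo-observed datasets with the statistical shape of the survey.

The generator emulates the study design end to end: 6 independent
non-recombining X-linked loci of 450 bp, 12 populations grouped into the
five regions JP / HI / WUS / EUS / SP, per-region haploid sample sizes in
the tens to low hundreds, and ~21% of genotype calls missing.  Datasets
are produced by the structured-coalescent simulator under any of the
colonization models, so every downstream stage (statistics, ABC,
validation) can be exercised without any external sequence data.

Tiny hand-crafted fixtures with known statistic values are also bundled
for unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .abcfit import PriorSpec, to_sim_params
from .coalsim import SampleConfig, simulate_dataset
from .seqdata import MultiLocusDataset, LocusAlignment, encode_sequence

#: Per-region haploid sample sizes; the survey reports only a 7-24 range
#: per population per locus, so these defaults are configuration, not data.
DEFAULT_REGION_SAMPLES = {"JP": 20, "HI": 15, "WUS": 40, "EUS": 120, "SP": 15}

#: Populations per region (12 total, as in the survey's sampling map).
DEFAULT_POPS_PER_REGION = {"JP": 1, "HI": 1, "WUS": 2, "EUS": 7, "SP": 1}


@dataclass
class ShapeSpec:
    """Dataset-shape configuration for pseudo-observed data."""

    n_loci: int = 6
    locus_length: int = 450
    region_samples: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_REGION_SAMPLES))
    pops_per_region: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_POPS_PER_REGION))
    missing_rate: float = 0.214
    missing_mode: str = "iid"

    def __post_init__(self) -> None:
        for r, n in self.region_samples.items():
            if n < 2:
                raise ValueError(f"need at least 2 samples in region {r}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")

    def sample_config(self) -> SampleConfig:
        loci = [(f"L{i+1}", self.locus_length) for i in range(self.n_loci)]
        return SampleConfig(dict(self.region_samples), loci)


def _split_into_populations(ds: MultiLocusDataset, shape: ShapeSpec) -> MultiLocusDataset:
    """Re-label simulated region samples into populations within regions."""
    pop_of: dict[str, str] = {}
    region_of: dict[str, str] = {}
    for region, n in shape.region_samples.items():
        n_pops = shape.pops_per_region.get(region, 1)
        members = [ind for ind in ds.individuals if ds.region_of[ds.pop_of[ind]] == region]
        for j, ind in enumerate(members):
            pop = f"{region}{(j % n_pops) + 1}" if n_pops > 1 else region
            pop_of[ind] = pop
            region_of[pop] = region
    return MultiLocusDataset(ds.loci, list(ds.individuals), pop_of, region_of, dict(ds.meta))


def make_pseudo_observed(
    model_id: str,
    rng: np.random.Generator,
    params: dict[str, float] | None = None,
    prior: PriorSpec | None = None,
    shape: ShapeSpec | None = None,
) -> tuple[MultiLocusDataset, dict]:
    """Simulate one pseudo-observed dataset plus its truth record.

    Parameters are either given explicitly (natural scale) or drawn from
    the prior.  Deterministic for a given generator state.
    """
    shape = shape or ShapeSpec()
    if params is None:
        prior = prior or PriorSpec()
        draw = prior.sample(rng)
        params = to_sim_params(draw)
        truth = {"model": model_id, "draw": draw, "params": params}
    else:
        truth = {"model": model_id, "params": params}
    ds = simulate_dataset(
        model_id,
        params,
        shape.sample_config(),
        rng,
        missing_rate=shape.missing_rate,
        missing_mode=shape.missing_mode,
    )
    ds = _split_into_populations(ds, shape)
    ds.meta["truth"] = {"model": model_id, "params": {k: float(v) for k, v in params.items()}}
    return ds, truth


# ---------------------------------------------------------------------
# hand-crafted unit-test fixtures


def _tiny_dataset(seqs_by_pop: dict[str, list[str]], region_of: dict[str, str]) -> MultiLocusDataset:
    individuals, pop_of, rows = [], {}, []
    for pop, seqs in seqs_by_pop.items():
        for i, s in enumerate(seqs):
            name = f"{pop}_{i}"
            individuals.append(name)
            pop_of[name] = pop
            rows.append(encode_sequence(s))
    locus = LocusAlignment("toy", np.array(rows, dtype=np.int8))
    return MultiLocusDataset([locus], individuals, pop_of, region_of)


def make_toy_fixture(name: str) -> MultiLocusDataset:
    """Tiny alignments with pencil-and-paper statistic values.

    * ``pi_onethird`` — three 4-bp haplotypes with pi = 1/3;
    * ``pi_onethird_missing`` — same with one missing call at an
      invariant site (pi unchanged);
    * ``fst_one`` — two populations fixed for different alleles (Fst = 1);
    * ``monomorphic`` — no variation anywhere (S = 0);
    * ``hd_half`` — four haplotypes, two distinct with counts 3/1
      (unbiased Hd = 0.5).
    """
    if name == "pi_onethird":
        return _tiny_dataset({"P1": ["ACGT", "ACGA", "TCGA"]}, {"P1": "JP"})
    if name == "pi_onethird_missing":
        return _tiny_dataset({"P1": ["ACGT", "ANGA", "TCGA"]}, {"P1": "JP"})
    if name == "fst_one":
        return _tiny_dataset(
            {"A": ["AAAA", "AAAA"], "B": ["TTTT", "TTTT"]},
            {"A": "JP", "B": "SP"},
        )
    if name == "monomorphic":
        return _tiny_dataset({"P1": ["ACGT", "ACGT", "ACGT", "ACGT"]}, {"P1": "JP"})
    if name == "hd_half":
        return _tiny_dataset({"P1": ["ACGT", "ACGT", "ACGT", "TCGA"]}, {"P1": "JP"})
    raise KeyError(f"unknown fixture {name!r}")
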