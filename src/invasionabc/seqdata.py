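"""Data model and I/O for multi-population, multi-locus haplotype alignments.

The container mirrors the shape of a multi-locus Sanger resequencing study:
a handful of short, independent, non-recombining loci sequenced in haploid
(here: X-linked, male) individuals from several populations grouped into
geographic regions.  Missing genotypes are first-class citizens: an
individual that failed PCR at a locus is kept as an all-missing row so that
per-site sample sizes can vary freely.

Symbols are encoded as small integers: A,C,G,T -> 0..3, MISSING -> 4,
GAP -> 5.  Alignments produced by the coalescent simulator use the same
container with alleles 0/1; every statistic downstream only relies on
symbol equality, never on nucleotide identity.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

A, C, G, T = 0, 1, 2, 3
MISSING = 4
GAP = 5

_SYM2CODE = {"A": A, "C": C, "G": G, "T": T, "N": MISSING, "-": GAP, "?": MISSING}
_CODE2SYM = np.array(list("ACGTN-"))

#: IUPAC ambiguity codes mapped to MISSING (haploid data; ambiguity means
#: an unresolved base call, not heterozygosity).
_AMBIGUOUS = set("RYSWKMBDHV")

REGIONS = ("JP", "HI", "WUS", "EUS", "SP")


class SeqDataError(ValueError):
    """Raised on malformed or inconsistent input data."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to the internal int8 representation."""
    out = np.empty(len(seq), dtype=np.int8)
    n_ambig = 0
    for i, ch in enumerate(seq.upper()):
        code = _SYM2CODE.get(ch)
        if code is None:
            if ch in _AMBIGUOUS:
                code = MISSING
                n_ambig += 1
            else:
                raise SeqDataError(f"unknown symbol {ch!r} in sequence")
        out[i] = code
    if n_ambig:
        logger.warning("mapped %d IUPAC ambiguity codes to MISSING", n_ambig)
    return out


def decode_sequence(row: np.ndarray) -> str:
    return "".join(_CODE2SYM[np.clip(row, 0, 5)])


@dataclass
class LocusAlignment:
    """One locus: an (individuals x sites) matrix of symbol codes.

    ``site_class`` holds a per-site label, ``True`` meaning noncoding.
    """

    locus_id: str
    haplotypes: np.ndarray  # int8, individuals x sites
    noncoding: np.ndarray | None = None  # bool per site; None = all noncoding

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise SeqDataError("haplotypes must be 2-D (individuals x sites)")
        if self.noncoding is None:
            self.noncoding = np.ones(self.haplotypes.shape[1], dtype=bool)
        else:
            self.noncoding = np.asarray(self.noncoding, dtype=bool)
            if self.noncoding.shape[0] != self.haplotypes.shape[1]:
                raise SeqDataError(
                    f"site_class length {self.noncoding.shape[0]} != "
                    f"alignment width {self.haplotypes.shape[1]} at locus {self.locus_id}"
                )

    @property
    def length(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class GeoTable:
    """Population id -> (latitude, longitude) in decimal degrees."""

    coords: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for pop, (lat, lon) in self.coords.items():
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise SeqDataError(f"coordinates out of range for {pop}: {(lat, lon)}")

    def distance_matrix(self, pops: list[str]) -> np.ndarray:
        """Great-circle (haversine) distances in km between populations."""
        R = 6371.0
        lat = np.radians([self.coords[p][0] for p in pops])
        lon = np.radians([self.coords[p][1] for p in pops])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        return 2 * R * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class MultiLocusDataset:
    """An ordered collection of loci over a shared set of individuals."""

    loci: list[LocusAlignment]
    individuals: list[str]
    pop_of: dict[str, str]
    region_of: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for loc in self.loci:
            if loc.n_individuals != len(self.individuals):
                raise SeqDataError(
                    f"locus {loc.locus_id} has {loc.n_individuals} rows, "
                    f"expected {len(self.individuals)}"
                )
        for ind in self.individuals:
            if ind not in self.pop_of:
                raise SeqDataError(f"individual {ind!r} missing from popmap")
        for pop in set(self.pop_of.values()):
            if pop not in self.region_of:
                raise SeqDataError(f"population {pop!r} has no region assignment")

    # ---- basic views -------------------------------------------------

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.pop_of[ind], None)
        return list(seen)

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.populations:
            seen.setdefault(self.region_of[pop], None)
        return list(seen)

    def indices_of_population(self, pop: str) -> np.ndarray:
        return np.array([i for i, ind in enumerate(self.individuals) if self.pop_of[ind] == pop], dtype=int)

    def indices_of_region(self, region: str) -> np.ndarray:
        return np.array(
            [i for i, ind in enumerate(self.individuals) if self.region_of[self.pop_of[ind]] == region],
            dtype=int,
        )

    def concat(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated (individuals x total sites) matrix and noncoding mask."""
        mat = np.concatenate([loc.haplotypes for loc in self.loci], axis=1)
        nc = np.concatenate([loc.noncoding for loc in self.loci])
        return mat, nc

    @property
    def total_length(self) -> int:
        return sum(loc.length for loc in self.loci)


# ---------------------------------------------------------------------
# construction from files


def _read_popmap(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    pop_of: dict[str, str] = {}
    region_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SeqDataError(f"popmap line needs 3 tab-separated fields: {line!r}")
            ind, pop, region = parts
            pop_of[ind] = pop
            if pop in region_of and region_of[pop] != region:
                raise SeqDataError(f"population {pop!r} mapped to two regions")
            region_of[pop] = region
    return pop_of, region_of


def _read_annotation(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Annotation TSV: locus, start, end, class — 0-based half-open intervals."""
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            locus, start, end, cls = line.split("\t")
            if cls not in ("coding", "noncoding"):
                raise SeqDataError(f"unknown site class {cls!r}")
            out.setdefault(locus, []).append((int(start), int(end), cls))
    return out


def load_dataset(
    fasta_paths: dict[str, str | Path],
    popmap: str | Path,
    annotation: str | Path | None = None,
) -> MultiLocusDataset:
    """Load per-locus FASTA files plus a popmap into a dataset.

    Individuals listed in the popmap but absent from a locus FASTA are kept
    as all-MISSING rows for that locus (variable per-locus sample size).
    Sequence ids not present in the popmap are an error.
    """
    pop_of, region_of = _read_popmap(popmap)
    individuals = list(pop_of)
    idx = {ind: i for i, ind in enumerate(individuals)}
    ann = _read_annotation(annotation) if annotation else {}

    loci = []
    for locus_id, path in fasta_paths.items():
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise SeqDataError(f"no sequences in {path}")
        length = len(records[0].seq)
        mat = np.full((len(individuals), length), MISSING, dtype=np.int8)
        for rec in records:
            if rec.id not in idx:
                raise SeqDataError(f"sequence id {rec.id!r} not in popmap")
            if len(rec.seq) != length:
                raise SeqDataError(
                    f"length mismatch at locus {locus_id}: {rec.id} has "
                    f"{len(rec.seq)} bp, expected {length}"
                )
            mat[idx[rec.id]] = encode_sequence(str(rec.seq))
        noncoding = np.ones(length, dtype=bool)
        for start, end, cls in ann.get(locus_id, []):
            if not (0 <= start <= end <= length):
                raise SeqDataError(f"interval ({start},{end}) outside locus {locus_id}")
            if cls == "coding":
                noncoding[start:end] = False
        loci.append(LocusAlignment(locus_id, mat, noncoding))

    return MultiLocusDataset(loci, individuals, pop_of, region_of)


# ---------------------------------------------------------------------
# operations


def strip_gap_columns(ds: MultiLocusDataset) -> tuple[MultiLocusDataset, int]:
    """Drop every alignment column in which any individual has a gap.

    Returns the stripped dataset and the total number of columns removed
    across loci.  Idempotent.
    """
    removed = 0
    new_loci = []
    for loc in ds.loci:
        keep = ~(loc.haplotypes == GAP).any(axis=0)
        removed += int((~keep).sum())
        new_loci.append(LocusAlignment(loc.locus_id, loc.haplotypes[:, keep], loc.noncoding[keep]))
    out = MultiLocusDataset(new_loci, list(ds.individuals), dict(ds.pop_of), dict(ds.region_of), dict(ds.meta))
    return out, removed


def missing_fraction(ds: MultiLocusDataset) -> float:
    """Proportion of MISSING cells over individuals x total sites (gap-stripped)."""
    total = 0
    miss = 0
    for loc in ds.loci:
        if (loc.haplotypes == GAP).any():
            raise SeqDataError("dataset contains gaps; strip_gap_columns first")
        total += loc.haplotypes.size
        miss += int((loc.haplotypes == MISSING).sum())
    if total == 0:
        raise SeqDataError("empty dataset")
    return miss / total


# ---------------------------------------------------------------------
# bundle serialization (single JSON file used by all downstream stages)


def write_bundle(ds: MultiLocusDataset, path: str | Path) -> None:
    obj = {
        "individuals": ds.individuals,
        "pop_of": ds.pop_of,
        "region_of": ds.region_of,
        "meta": ds.meta,
        "loci": [
            {
                "locus_id": loc.locus_id,
                "sequences": [decode_sequence(row) for row in loc.haplotypes],
                "noncoding": "".join("1" if x else "0" for x in loc.noncoding),
            }
            for loc in ds.loci
        ],
    }
    Path(path).write_text(json.dumps(obj))


def read_bundle(path: str | Path) -> MultiLocusDataset:
    obj = json.loads(Path(path).read_text())
    loci = [
        LocusAlignment(
            d["locus_id"],
            np.array([encode_sequence(s) for s in d["sequences"]], dtype=np.int8),
            np.array([ch == "1" for ch in d["noncoding"]]),
        )
        for d in obj["loci"]
    ]
    return MultiLocusDataset(loci, obj["individuals"], obj["pop_of"], obj["region_of"], obj.get("meta", {}))


def read_geo_table(path: str | Path) -> GeoTable:
    coords = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pop, lat, lon = line.split("\t")
            coords[pop] = (float(lat), float(lon))
    return GeoTable(coords)
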