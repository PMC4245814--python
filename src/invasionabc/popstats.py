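"""Missing-data-aware diversity and differentiation statistics.

All estimators work site-wise on whatever alleles were actually observed:
a site enters an estimator only if enough non-missing alleles are present
(two for within-sample diversity, one per group for between-sample
comparisons, two per population for Fst).  This is the convention needed
for datasets where PCR dropout leaves ~20% of genotypes undetermined.

The summary-statistic vector used by the ABC stage is a fixed, named set of
67 statistics computed at the region level: per-region S, pi, prS, K_sd,
H_sd and Tajima's D; the same five single-sample summaries for the pooled
sample; log(S_i/S_JP) for the colonized regions; prS/S ratios; the mean and
SD of S and pi across regions; and pairwise between-region diversity and
AMOVA Fst.  Simulated and observed data go through the same code path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdata import GAP, MISSING, REGIONS, GeoTable, MultiLocusDataset

__all__ = [
    "DiversityEstimate",
    "SiteSummaries",
    "StatVector",
    "nucleotide_diversity",
    "bootstrap_se_and_delta_test",
    "haplotype_diversity",
    "haplotype_diversity_change",
    "haplotype_diversity_change_weighted",
    "site_summaries",
    "pairwise_fst",
    "fst_matrix",
    "FstMatrix",
    "amova",
    "mantel_test",
    "compute_stat_vector",
    "stat_names",
    "SELECTED6",
]

_N_ALLELES = 4  # symbol codes 0..3; MISSING(4)/GAP(5) never counted


class StatError(ValueError):
    pass


# ---------------------------------------------------------------------
# site-count primitives


def _site_counts(mat: np.ndarray) -> np.ndarray:
    """Per-site allele counts, shape (4, n_sites); MISSING/GAP excluded."""
    return np.stack([(mat == a).sum(axis=0) for a in range(_N_ALLELES)]).astype(np.float64)


def _pi_per_site(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site pairwise diversity and usability mask (n >= 2).

    For a site with n observed alleles and counts c_a, the per-site
    diversity is the fraction of mismatching pairs, 1 - sum C(c_a,2)/C(n,2)
    — identical to the unbiased per-site heterozygosity.
    """
    n = counts.sum(axis=0)
    usable = n >= 2
    match = (counts * (counts - 1)).sum(axis=0) / 2.0
    tot = n * (n - 1) / 2.0
    pi = np.zeros_like(n)
    pi[usable] = 1.0 - match[usable] / tot[usable]
    return pi, usable


def _select_matrix(ds: MultiLocusDataset, rows: np.ndarray, noncoding_only: bool) -> np.ndarray:
    mat, nc = ds.concat()
    if (mat == GAP).any():
        raise StatError("alignment contains gaps; strip_gap_columns first")
    mat = mat[rows]
    if noncoding_only:
        mat = mat[:, nc]
    return mat


def _rows_for(ds: MultiLocusDataset, group: str) -> np.ndarray:
    if group in ds.populations:
        return ds.indices_of_population(group)
    if group in ds.regions:
        return ds.indices_of_region(group)
    raise StatError(f"unknown population or region {group!r}")


# ---------------------------------------------------------------------
# nucleotide diversity


@dataclass
class DiversityEstimate:
    pi: float  # per-site proportion in [0, 1]
    se: float | None
    n_usable_sites: int

    @property
    def percent(self) -> float:
        return 100.0 * self.pi


def nucleotide_diversity(
    ds: MultiLocusDataset,
    pop: str,
    site_filter: str = "all",
    n_boot: int = 0,
    seed: int | None = None,
) -> DiversityEstimate:
    """Average pairwise diversity per site, excluding sites with <2 alleles.

    ``site_filter`` is ``"all"`` or ``"noncoding"``.  With ``n_boot > 0``
    a bootstrap-over-sites standard error is attached.
    """
    mat = _select_matrix(ds, _rows_for(ds, pop), site_filter == "noncoding")
    pi_site, usable = _pi_per_site(_site_counts(mat))
    if not usable.any():
        raise StatError(f"no usable sites for {pop}")
    pi = float(pi_site[usable].mean())
    se = None
    if n_boot:
        rng = np.random.default_rng(seed)
        vals = pi_site[usable]
        idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
        se = float(vals[idx].mean(axis=1).std(ddof=1))
    return DiversityEstimate(pi, se, int(usable.sum()))


def bootstrap_se_and_delta_test(
    ds: MultiLocusDataset,
    pop: str,
    ref_pop: str,
    n_boot: int = 1000,
    site_filter: str = "all",
    seed: int | None = None,
) -> tuple[float, float, float, float]:
    """Paired two-tailed bootstrap test for a difference in pi.

    Sites are resampled with replacement *jointly* for both samples (paired
    by site).  Returns ``(se_pop, se_ref, pct_change, p)`` where
    ``pct_change = 100 * (pi_pop - pi_ref) / pi_ref`` and ``p`` is the
    two-tailed fraction of bootstrap differences crossing zero
    (add-one rule, capped at 1).
    """
    if n_boot < 100:
        raise StatError("need at least 100 bootstrap replicates")
    matA = _select_matrix(ds, _rows_for(ds, pop), site_filter == "noncoding")
    matB = _select_matrix(ds, _rows_for(ds, ref_pop), site_filter == "noncoding")
    piA, usA = _pi_per_site(_site_counts(matA))
    piB, usB = _pi_per_site(_site_counts(matB))
    pA = piA[usA].mean()
    pB = piB[usB].mean()
    if pA == 0 and pB == 0:
        raise StatError("both samples are monomorphic; test is degenerate")

    rng = np.random.default_rng(seed)
    n_sites = piA.size
    idx = rng.integers(0, n_sites, size=(n_boot, n_sites))

    def _boot_mean(pi_site: np.ndarray, usable: np.ndarray) -> np.ndarray:
        vals = np.where(usable, pi_site, 0.0)[idx].sum(axis=1)
        cnt = usable.astype(float)[idx].sum(axis=1)
        return np.divide(vals, cnt, out=np.zeros(n_boot), where=cnt > 0)

    bA = _boot_mean(piA, usA)
    bB = _boot_mean(piB, usB)
    delta = bA - bB
    lo = int((delta <= 0).sum())
    hi = int((delta >= 0).sum())
    p = min(1.0, 2.0 * (min(lo, hi) + 1) / (n_boot + 1))
    pct = 100.0 * (pA - pB) / pB if pB > 0 else float("inf")
    return float(bA.std(ddof=1)), float(bB.std(ddof=1)), float(pct), p


# ---------------------------------------------------------------------
# haplotype diversity


def haplotype_diversity(rows: np.ndarray) -> float:
    """Unbiased haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2).

    ``rows`` is a complete (no MISSING) haplotype matrix.
    """
    n = rows.shape[0]
    if n < 2:
        raise StatError("need at least 2 complete haplotypes")
    _, counts = np.unique(rows, axis=0, return_counts=True)
    p2 = ((counts / n) ** 2).sum()
    return float(n / (n - 1) * (1.0 - p2))


def _complete_rows(ds: MultiLocusDataset, locus_id: str, pop: str) -> np.ndarray:
    loc = next((l for l in ds.loci if l.locus_id == locus_id), None)
    if loc is None:
        raise StatError(f"unknown locus {locus_id!r}")
    rows = loc.haplotypes[_rows_for(ds, pop)]
    complete = ~(rows == MISSING).any(axis=1)
    return rows[complete]


def haplotype_diversity_change(ds: MultiLocusDataset, locus_id: str, pop: str, ref_pop: str = "JP") -> float:
    """Relative change (Hd_pop - Hd_ref) / Hd_ref at one locus.

    Individuals with any MISSING call at the locus are excluded.
    """
    hd_pop = haplotype_diversity(_complete_rows(ds, locus_id, pop))
    hd_ref = haplotype_diversity(_complete_rows(ds, locus_id, ref_pop))
    if hd_ref == 0:
        raise StatError("reference haplotype diversity is zero")
    return (hd_pop - hd_ref) / hd_ref


def haplotype_diversity_change_weighted(ds: MultiLocusDataset, pop: str, ref_pop: str = "JP") -> float:
    """Average per-locus relative Hd change, weighted by locus length."""
    changes, weights = [], []
    for loc in ds.loci:
        try:
            changes.append(haplotype_diversity_change(ds, loc.locus_id, pop, ref_pop))
            weights.append(loc.length)
        except StatError:
            continue
    if not changes:
        raise StatError("no locus admits a haplotype-diversity comparison")
    return float(np.average(changes, weights=weights))


# ---------------------------------------------------------------------
# site summaries (S, prS, K_sd, H_sd, Tajima's D)


@dataclass
class SiteSummaries:
    S: int
    prS: int
    K_sd: float
    H_sd: float
    tajima_d: float | None  # None when S == 0 (undefined)


def _tajima_d(pi_sum: float, S: int, n: int) -> float | None:
    if S == 0 or n < 3:
        return None
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return float((pi_sum - S / a1) / np.sqrt(var))


def _summaries_from_counts(counts: np.ndarray, other_counts: np.ndarray | None) -> SiteSummaries:
    n = counts.sum(axis=0)
    pi_site, usable = _pi_per_site(counts)
    K = (counts > 0).sum(axis=0)
    seg = K >= 2
    S = int(seg.sum())
    # K_sd over all sites with at least one observed allele (monomorphic included)
    k_obs = K[n >= 1]
    K_sd = float(k_obs.std(ddof=0)) if k_obs.size else 0.0
    h_obs = pi_site[usable]
    H_sd = float(h_obs.std(ddof=0)) if h_obs.size else 0.0
    prS = 0
    if other_counts is not None:
        private = ((counts > 0) & (other_counts == 0)).any(axis=0)
        prS = int((seg & private).sum())
    nbar = int(round(n[usable].mean())) if usable.any() else 0
    D = _tajima_d(float(pi_site[usable].sum()), S, nbar)
    return SiteSummaries(S, prS, K_sd, H_sd, D)


def site_summaries(ds: MultiLocusDataset, group: str, site_filter: str = "all") -> SiteSummaries:
    """S, private S, K_sd, H_sd and Tajima's D for a population or region.

    Tajima's D uses the rounded mean per-site non-missing sample size in
    its constants (missing-data convention; see the methods note).  prS is
    the number of segregating sites carrying an allele absent from every
    other group at the same grouping level.
    """
    rows = _rows_for(ds, group)
    level_groups = ds.populations if group in ds.populations else ds.regions
    mat_all, nc = ds.concat()
    cols = nc if site_filter == "noncoding" else slice(None)
    counts = _site_counts(mat_all[rows][:, cols])
    others = [g for g in level_groups if g != group]
    other_rows = np.concatenate([_rows_for(ds, g) for g in others]) if others else None
    other_counts = _site_counts(mat_all[other_rows][:, cols]) if other_rows is not None else None
    return _summaries_from_counts(counts, other_counts)


# ---------------------------------------------------------------------
# AMOVA / Fst


def _amova_components(counts_by_group: list[np.ndarray], sizes: list[int]) -> tuple[float, float]:
    """Two-level haploid AMOVA variance components (among, within).

    ``counts_by_group`` are per-site allele counts restricted to qualifying
    sites.  Distances are pairwise mismatch counts over shared non-missing
    sites; the sums over pairs decompose site-wise, so everything is
    computed from counts.
    """
    P = len(counts_by_group)
    N = sum(sizes)
    ssd_w = 0.0
    for counts, n_p in zip(counts_by_group, sizes):
        n_s = counts.sum(axis=0)
        match = (counts * (counts - 1)).sum(axis=0) / 2.0
        pairs = n_s * (n_s - 1) / 2.0
        ssd_w += float((pairs - match).sum()) / n_p
    tot = np.sum(counts_by_group, axis=0)
    n_s = tot.sum(axis=0)
    match = (tot * (tot - 1)).sum(axis=0) / 2.0
    pairs = n_s * (n_s - 1) / 2.0
    ssd_t = float((pairs - match).sum()) / N
    ssd_a = ssd_t - ssd_w
    df_a, df_w = P - 1, N - P
    if df_w <= 0:
        raise StatError("AMOVA needs more individuals than groups")
    sigma_w = ssd_w / df_w
    n_c = (N - sum(s**2 for s in sizes) / N) / df_a
    sigma_a = (ssd_a / df_a - sigma_w) / n_c
    return sigma_a, sigma_w


def _fst_from_matrices(mats: list[np.ndarray]) -> float:
    """AMOVA Fst over groups, restricted to sites with >=2 sampled per group."""
    counts = [_site_counts(m) for m in mats]
    ok = np.ones(counts[0].shape[1], dtype=bool)
    for c in counts:
        ok &= c.sum(axis=0) >= 2
    if not ok.any():
        raise StatError("no site has >=2 sampled individuals in every group")
    counts = [c[:, ok] for c in counts]
    sigma_a, sigma_w = _amova_components(counts, [m.shape[0] for m in mats])
    tot = sigma_a + sigma_w
    if tot == 0:
        raise StatError("zero total variance; Fst undefined")
    return sigma_a / tot


def _permutation_p(mats: list[np.ndarray], observed: float, n_perm: int, rng: np.random.Generator) -> float:
    pooled = np.concatenate(mats, axis=0)
    sizes = [m.shape[0] for m in mats]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        parts, start = [], 0
        for s in sizes:
            parts.append(pooled[perm[start : start + s]])
            start += s
        try:
            if _fst_from_matrices(parts) >= observed:
                count += 1
        except StatError:
            continue
    return (count + 1) / (n_perm + 1)


def pairwise_fst(
    ds: MultiLocusDataset,
    popA: str,
    popB: str,
    n_perm: int = 1000,
    site_filter: str = "all",
    seed: int | None = None,
) -> tuple[float, float]:
    """Haploid AMOVA Fst between two samples plus a permutation p-value.

    Only sites with at least two sampled (non-missing) individuals in each
    sample qualify.  Negative estimates are retained.  The p-value is the
    add-one-corrected fraction of label permutations with Fst >= observed.
    """
    mats = [_select_matrix(ds, _rows_for(ds, g), site_filter == "noncoding") for g in (popA, popB)]
    fst = _fst_from_matrices(mats)
    p = _permutation_p(mats, fst, n_perm, np.random.default_rng(seed)) if n_perm else float("nan")
    return fst, p


def amova(
    ds: MultiLocusDataset,
    pops: list[str],
    n_perm: int = 1000,
    site_filter: str = "all",
    seed: int | None = None,
) -> dict:
    """Two-level AMOVA across several populations.

    Returns among/within variance components, Fst (= among fraction) and a
    permutation p-value for the among-population component.
    """
    if len(pops) < 2:
        raise StatError("AMOVA needs at least two populations")
    mats = [_select_matrix(ds, _rows_for(ds, p), site_filter == "noncoding") for p in pops]
    counts = [_site_counts(m) for m in mats]
    ok = np.ones(counts[0].shape[1], dtype=bool)
    for c in counts:
        ok &= c.sum(axis=0) >= 2
    if not ok.any():
        raise StatError("no qualifying sites")
    sigma_a, sigma_w = _amova_components([c[:, ok] for c in counts], [m.shape[0] for m in mats])
    fst = sigma_a / (sigma_a + sigma_w)
    p = _permutation_p(mats, fst, n_perm, np.random.default_rng(seed)) if n_perm else float("nan")
    return {"sigma_among": sigma_a, "sigma_within": sigma_w, "fst": fst, "p": p}


@dataclass
class FstMatrix:
    """Pairwise Fst over populations with permutation p-values."""

    pops: list[str]
    fst: np.ndarray  # symmetric, zero diagonal
    p: np.ndarray  # permutation p-values (nan on diagonal)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pop\t" + "\t".join(self.pops) + "\n")
            for i, a in enumerate(self.pops):
                row = "\t".join(f"{self.fst[i, j]:.4f}" for j in range(len(self.pops)))
                fh.write(f"{a}\t{row}\n")


def fst_matrix(
    ds: MultiLocusDataset,
    pops: list[str] | None = None,
    n_perm: int = 1000,
    site_filter: str = "all",
    seed: int | None = None,
) -> FstMatrix:
    """All pairwise Fst values among populations (or any groups)."""
    pops = pops or ds.populations
    k = len(pops)
    fst = np.zeros((k, k))
    p = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            f, pv = pairwise_fst(
                ds, pops[i], pops[j], n_perm=n_perm, site_filter=site_filter,
                seed=int(rng.integers(2**31 - 1)),
            )
            fst[i, j] = fst[j, i] = f
            p[i, j] = p[j, i] = pv
    return FstMatrix(pops, fst, p)


# ---------------------------------------------------------------------
# Mantel test


def mantel_test(
    fst: np.ndarray,
    pops: list[str],
    geo: GeoTable,
    transform: str = "identity",
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between genetic and great-circle distances.

    ``transform`` is ``identity``, ``neglog`` (-log Fst, defined for
    Fst > 0) or ``fst_ratio`` (Fst/(1-Fst), defined for Fst < 1); pairs
    where the transform is undefined are excluded.  One-tailed permutation
    p-value for a positive association, add-one rule.
    """
    fst = np.asarray(fst, dtype=float)
    k = len(pops)
    if fst.shape != (k, k):
        raise StatError("Fst matrix does not match population list")
    gd = geo.distance_matrix(pops)
    iu = np.triu_indices(k, 1)

    def _transform(m: np.ndarray) -> np.ndarray:
        if transform == "identity":
            return m
        if transform == "neglog":
            out = np.where(m > 0, -np.log(np.where(m > 0, m, 1.0)), np.nan)
            return out
        if transform == "fst_ratio":
            return np.where(m < 1, m / (1 - m), np.nan)
        raise StatError(f"unknown transform {transform!r}")

    tg = _transform(fst)
    x = tg[iu]
    y = gd[iu]
    valid = np.isfinite(x)
    if valid.sum() < 3:
        raise StatError("too few defined pairs for a Mantel test")
    x, yv = x[valid], y[valid]
    if x.std() == 0 or yv.std() == 0:
        raise StatError("zero variance in a distance matrix")
    r_obs = float(np.corrcoef(x, yv)[0, 1])

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        xp = tg[np.ix_(perm, perm)][iu]
        ok = np.isfinite(xp) & np.isfinite(y)
        if ok.sum() < 3 or xp[ok].std() == 0:
            continue
        if np.corrcoef(xp[ok], y[ok])[0, 1] >= r_obs:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------
# the 67-statistic ABC summary vector


def _region_pairs(regions: tuple[str, ...] = REGIONS) -> list[tuple[str, str]]:
    return list(itertools.combinations(regions, 2))


def stat_names(regions: tuple[str, ...] = REGIONS) -> list[str]:
    names = []
    for r in regions:
        names += [f"S_{r}", f"pi_{r}", f"prS_{r}", f"Ksd_{r}", f"Hsd_{r}", f"D_{r}"]
    names += ["S_pool", "pi_pool", "Ksd_pool", "Hsd_pool", "D_pool"]
    names += [f"logS_{r}" for r in regions if r != regions[0]]
    names += [f"prSratio_{r}" for r in regions if r != regions[0]]
    names += ["S_mean", "S_sd", "pi_mean", "pi_sd"]
    names += [f"piB_{a}_{b}" for a, b in _region_pairs(regions)]
    names += [f"fst_{a}_{b}" for a, b in _region_pairs(regions)]
    return names


SELECTED6 = (
    "fst_EUS_SP",
    "fst_WUS_EUS",
    "fst_HI_EUS",
    "fst_HI_SP",
    "prSratio_WUS",
    "prSratio_EUS",
)


@dataclass
class StatVector:
    """Named summary-statistic vector; undefined entries are imputed with 0
    and flagged False in ``defined``."""

    values: np.ndarray
    names: list[str]
    defined: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    def subset(self, names: tuple[str, ...] | list[str]) -> np.ndarray:
        index = {n: i for i, n in enumerate(self.names)}
        return self.values[[index[n] for n in names]]

    def __len__(self) -> int:
        return len(self.names)


def stat_vector_from_matrix(
    mat: np.ndarray,
    region_rows: dict[str, np.ndarray],
    regions: tuple[str, ...] = REGIONS,
    invariant_counts: dict[str, np.ndarray] | None = None,
) -> StatVector:
    """Compute the full region-level statistic vector from a symbol matrix.

    ``mat`` is (individuals x sites) with MISSING == 4; ``region_rows``
    maps each region to its row indices.  This is the single code path used
    for both observed bundles and simulated reference-table rows.

    ``invariant_counts`` optionally appends monomorphic sites in compact
    form: per region, an array of per-site non-missing sample counts for
    sites carrying only the reference allele.  Simulators that store only
    segregating columns use this to restore the full per-site layout
    without materializing the padded matrix; the appended columns flow
    through the identical counts-based estimators.
    """
    counts = {r: _site_counts(mat[region_rows[r]]) for r in regions}
    if invariant_counts is not None:
        for r in regions:
            inv = np.asarray(invariant_counts[r], dtype=np.float64)
            block = np.zeros((_N_ALLELES, inv.size))
            block[0] = inv
            counts[r] = np.concatenate([counts[r], block], axis=1)
    total = np.sum([counts[r] for r in regions], axis=0)

    vals: dict[str, float] = {}
    undef: set[str] = set()

    per_region: dict[str, SiteSummaries] = {}
    for r in regions:
        other = total - counts[r]
        summ = _summaries_from_counts(counts[r], other)
        per_region[r] = summ
        pi_site, usable = _pi_per_site(counts[r])
        pi = float(pi_site[usable].mean()) if usable.any() else 0.0
        if not usable.any():
            undef.add(f"pi_{r}")
        vals[f"S_{r}"] = summ.S
        vals[f"pi_{r}"] = pi
        vals[f"prS_{r}"] = summ.prS
        vals[f"Ksd_{r}"] = summ.K_sd
        vals[f"Hsd_{r}"] = summ.H_sd
        if summ.tajima_d is None:
            vals[f"D_{r}"] = 0.0
            undef.add(f"D_{r}")
        else:
            vals[f"D_{r}"] = summ.tajima_d

    pool = _summaries_from_counts(total, None)
    pi_site, usable = _pi_per_site(total)
    vals["S_pool"] = pool.S
    vals["pi_pool"] = float(pi_site[usable].mean()) if usable.any() else 0.0
    vals["Ksd_pool"] = pool.K_sd
    vals["Hsd_pool"] = pool.H_sd
    if pool.tajima_d is None:
        vals["D_pool"] = 0.0
        undef.add("D_pool")
    else:
        vals["D_pool"] = pool.tajima_d

    ref = regions[0]
    for r in regions[1:]:
        s_i, s_ref = per_region[r].S, per_region[ref].S
        if s_i > 0 and s_ref > 0:
            vals[f"logS_{r}"] = float(np.log(s_i / s_ref))
        else:
            vals[f"logS_{r}"] = 0.0
            undef.add(f"logS_{r}")
        if per_region[r].S > 0:
            vals[f"prSratio_{r}"] = per_region[r].prS / per_region[r].S
        else:
            vals[f"prSratio_{r}"] = 0.0
            undef.add(f"prSratio_{r}")

    s_arr = np.array([per_region[r].S for r in regions], dtype=float)
    pi_arr = np.array([vals[f"pi_{r}"] for r in regions])
    vals["S_mean"], vals["S_sd"] = float(s_arr.mean()), float(s_arr.std(ddof=0))
    vals["pi_mean"], vals["pi_sd"] = float(pi_arr.mean()), float(pi_arr.std(ddof=0))

    # sites monomorphic in the pooled sample contribute nothing to
    # mismatch sums, so pair statistics only touch pooled-segregating
    # columns (denominators still count every qualifying site)
    seg_pool = (total > 0).sum(axis=0) >= 2
    n_of = {r: counts[r].sum(axis=0) for r in regions}
    for a, b in _region_pairs(regions):
        na, nb = n_of[a], n_of[b]
        ok = (na >= 1) & (nb >= 1)
        if ok.any():
            sel = ok & seg_pool
            mismatch = 0.0
            if sel.any():
                pa = counts[a][:, sel] / na[sel]
                pb = counts[b][:, sel] / nb[sel]
                mismatch = float((1.0 - (pa * pb).sum(axis=0)).sum())
            vals[f"piB_{a}_{b}"] = mismatch / int(ok.sum())
        else:
            vals[f"piB_{a}_{b}"] = 0.0
            undef.add(f"piB_{a}_{b}")
        ok2 = (na >= 2) & (nb >= 2)
        if ok2.any():
            try:
                sel2 = ok2 & seg_pool
                sig_a, sig_w = _amova_components(
                    [counts[a][:, sel2], counts[b][:, sel2]],
                    [len(region_rows[a]), len(region_rows[b])],
                )
                tot_var = sig_a + sig_w
                if tot_var == 0:
                    raise StatError("zero variance")
                vals[f"fst_{a}_{b}"] = sig_a / tot_var
            except StatError:
                vals[f"fst_{a}_{b}"] = 0.0
                undef.add(f"fst_{a}_{b}")
        else:
            vals[f"fst_{a}_{b}"] = 0.0
            undef.add(f"fst_{a}_{b}")

    names = stat_names(regions)
    values = np.array([vals[n] for n in names])
    defined = np.array([n not in undef for n in names])
    return StatVector(values, names, defined)


def compute_stat_vector(ds: MultiLocusDataset, site_filter: str = "all") -> StatVector:
    """The full 67-statistic summary of a dataset at the region level."""
    missing = [r for r in REGIONS if r not in ds.regions]
    if missing:
        raise StatError(f"dataset lacks regions {missing}")
    mat, nc = ds.concat()
    if (mat == GAP).any():
        raise StatError("alignment contains gaps; strip_gap_columns first")
    if site_filter == "noncoding":
        mat = mat[:, nc]
    region_rows = {r: ds.indices_of_region(r) for r in REGIONS}
    return stat_vector_from_matrix(mat, region_rows)
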