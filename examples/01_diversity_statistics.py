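"""Diversity and differentiation statistics on a synthetic survey.

Generates one pseudo-observed dataset with the survey's shape (six 450-bp
X-linked loci, 12 populations in five regions, ~21% missing calls), then
computes nucleotide diversity with bootstrap errors, the change relative
to the native-range sample, haplotype-diversity change, pairwise Fst with
permutation p-values, and a Mantel test against geographic distance.
"""

import numpy as np

from invasionabc.popstats import (
    bootstrap_se_and_delta_test,
    haplotype_diversity_change_weighted,
    mantel_test,
    nucleotide_diversity,
    pairwise_fst,
)
from invasionabc.seqdata import GeoTable
from invasionabc.synthdata import make_pseudo_observed

from invasionabc.synthdata import ShapeSpec

# posterior-point parameters of the independent-colonizations history:
# a large structured native range, a strong founder event in SP (f ~ 10)
# and milder ones elsewhere
params = dict(
    N_ASIA=2.5e6, N_JP=2.5e5, N_HI=2e4, N_WUS=5e4, N_EUS=2e4, N_SP=1e4,
    f_HI=130.0, f_WUS=180.0, f_EUS=62.0, f_SP=10.0,
    tau_HI=434.0, tau_WUS=78.0, tau_SP=58.0, tau_EUS=29.0,
    Nm=0.6, mu=3.46e-9,
)
rng = np.random.default_rng(7)
# block missing mode: whole individuals drop out at a locus (PCR failure),
# so complete haplotypes remain for haplotype-level statistics
shape = ShapeSpec(missing_mode="block")
ds, truth = make_pseudo_observed("M1", rng, params=params, shape=shape)
print(f"dataset: {len(ds.individuals)} individuals, {ds.total_length} bp, "
      f"{len(ds.populations)} populations")

print("\nper-region nucleotide diversity (% per site, bootstrap SE):")
for region in ("JP", "HI", "WUS", "EUS", "SP"):
    est = nucleotide_diversity(ds, region, n_boot=500, seed=1)
    print(f"  {region:4s} pi = {est.percent:5.2f}%  [SE {100*est.se:.3f}]")

print("\nchange vs the native-range sample (paired bootstrap test):")
for region in ("HI", "WUS", "EUS", "SP"):
    _, _, pct, p = bootstrap_se_and_delta_test(ds, region, "JP", n_boot=500, seed=2)
    print(f"  {region:4s} {pct:+6.1f}%  (p = {p:.3f})")

print("\nhaplotype-diversity change vs JP (locus-size-weighted):")
for region in ("HI", "SP"):
    try:
        hd = haplotype_diversity_change_weighted(ds, region, ref_pop="JP")
        print(f"  {region:4s} {100*hd:+6.1f}%")
    except Exception as e:
        print(f"  {region:4s} not computable ({e})")

fst, p = pairwise_fst(ds, "JP", "SP", n_perm=200, seed=3)
print(f"\nFst(JP, SP) = {fst:.3f} (permutation p = {p:.3f})")

# Mantel test on region centroids with arbitrary example coordinates
regions = ["JP", "HI", "WUS", "EUS", "SP"]
geo = GeoTable({"JP": (33.8, 132.8), "HI": (22.1, -159.6), "WUS": (34.4, -119.7),
                "EUS": (35.9, -79.0), "SP": (41.4, 2.2)})
fsts = np.zeros((5, 5))
for i, a in enumerate(regions):
    for j in range(i + 1, 5):
        fsts[i, j] = fsts[j, i] = pairwise_fst(ds, a, regions[j], n_perm=0)[0]
r, p = mantel_test(fsts, regions, geo, n_perm=500, seed=4)
print(f"Mantel r = {r:+.3f} (one-tailed p = {p:.3f}) — isolation-by-distance "
      "is not expected under independent colonizations")
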