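"""Diversity/differentiation statistics against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invasionabc import popstats as ps
from invasionabc.seqdata import MISSING, GeoTable, LocusAlignment, MultiLocusDataset
from invasionabc.synthdata import make_toy_fixture


def _dataset(pop_seqs: dict[str, list[str]], regions=None):
    from invasionabc.seqdata import encode_sequence

    inds, pop_of, rows = [], {}, []
    for pop, seqs in pop_seqs.items():
        for i, s in enumerate(seqs):
            name = f"{pop}{i}"
            inds.append(name)
            pop_of[name] = pop
            rows.append(encode_sequence(s))
    region_of = regions or {p: p for p in pop_seqs}
    return MultiLocusDataset(
        [LocusAlignment("L", np.array(rows, dtype=np.int8))], inds, pop_of, region_of
    )


def brute_force_pi(seqs: list[str]) -> float:
    """Mean pairwise Hamming distance per site (complete data only)."""
    n, L = len(seqs), len(seqs[0])
    total = sum(
        sum(a != b for a, b in zip(s1, s2)) for s1, s2 in itertools.combinations(seqs, 2)
    )
    return total / (n * (n - 1) / 2) / L


class TestNucleotideDiversity:
    def test_worked_example_one_third(self, pi_onethird):
        est = ps.nucleotide_diversity(pi_onethird, "P1")
        assert est.pi == pytest.approx(1 / 3)
        assert est.n_usable_sites == 4

    def test_missing_at_invariant_site_leaves_pi_unchanged(self):
        ds = make_toy_fixture("pi_onethird_missing")
        assert ps.nucleotide_diversity(ds, "P1").pi == pytest.approx(1 / 3)

    def test_monomorphic_is_zero(self):
        ds = make_toy_fixture("monomorphic")
        assert ps.nucleotide_diversity(ds, "P1").pi == 0.0

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=6, max_size=6),
            min_size=2,
            max_size=8,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_mean_pairwise_hamming_on_complete_data(self, seqs):
        ds = _dataset({"P": seqs}, {"P": "JP"})
        est = ps.nucleotide_diversity(ds, "P")
        assert est.pi == pytest.approx(brute_force_pi(seqs))

    def test_invariant_to_row_order_and_duplication(self, rng):
        seqs = ["ACGTAC", "ACGAAC", "TCGATC", "ACGTTC"]
        n = len(seqs)
        base = ps.nucleotide_diversity(_dataset({"P": seqs}, {"P": "JP"}), "P").pi
        shuffled = ps.nucleotide_diversity(
            _dataset({"P": list(rng.permutation(seqs))}, {"P": "JP"}), "P"
        ).pi
        doubled = ps.nucleotide_diversity(_dataset({"P": seqs * 2}, {"P": "JP"}), "P").pi
        assert shuffled == pytest.approx(base)
        # pairwise diversity transforms by the exact small-sample factor
        # under duplication (pairs of identical copies enter the average);
        # the allele-frequency content is unchanged
        assert doubled == pytest.approx(base * 2 * (n - 1) / (2 * n - 1))

    def test_no_usable_sites_raises(self):
        ds = _dataset({"P": ["NN", "NN"]}, {"P": "JP"})
        with pytest.raises(ps.StatError):
            ps.nucleotide_diversity(ds, "P")


class TestBootstrapDeltaTest:
    def test_identical_population_pct_zero_p_one(self):
        seqs = ["ACGT", "ACGA", "TCGA"]
        ds = _dataset({"A": seqs, "B": seqs}, {"A": "JP", "B": "SP"})
        seA, seB, pct, p = ps.bootstrap_se_and_delta_test(ds, "A", "B", n_boot=500, seed=3)
        assert pct == pytest.approx(0.0)
        assert p == 1.0

    def test_pct_change_formula(self):
        # pi_A = 0.5 at both sites; pi_B = 0.5 at one site of four -> ratio 4
        a = ["AATT", "AATT", "TTAA", "TTAA"]
        b = ["AAAA", "AAAA", "TAAA", "TAAA"]
        ds = _dataset({"A": a, "B": b}, {"A": "JP", "B": "SP"})
        piA = ps.nucleotide_diversity(ds, "A").pi
        piB = ps.nucleotide_diversity(ds, "B").pi
        _, _, pct, _ = ps.bootstrap_se_and_delta_test(ds, "A", "B", n_boot=200, seed=1)
        assert pct == pytest.approx(100 * (piA - piB) / piB)

    def test_two_site_alignment_against_exhaustive_enumeration(self):
        # 2 sites: A is polymorphic only at site 0, B only at site 1.
        a = ["AT", "TT"]
        b = ["AA", "AT"]
        ds = _dataset({"A": a, "B": b}, {"A": "JP", "B": "SP"})
        # exhaustive bootstrap over site pairs (with replacement): resamples
        # {(0,0),(0,1),(1,0),(1,1)}; per-site pi: A=(1,0), B=(0,1)
        deltas = np.array(
            [
                np.mean([(1.0, 0.0)[s] for s in pair]) - np.mean([(0.0, 1.0)[s] for s in pair])
                for pair in itertools.product((0, 1), repeat=2)
            ]
        )
        assert (deltas <= 0).mean() == 0.75 and (deltas >= 0).mean() == 0.75
        expected = min(1.0, 2 * min((deltas <= 0).mean(), (deltas >= 0).mean()))
        # large-B bootstrap converges to the exhaustive enumeration (here p
        # saturates at 1: the resampled difference crosses zero constantly)
        _, _, _, p = ps.bootstrap_se_and_delta_test(ds, "A", "B", n_boot=20000, seed=5)
        assert expected == 1.0
        assert p == pytest.approx(expected, abs=0.02)


class TestHaplotypeDiversity:
    def test_unbiased_hd_three_one_split(self):
        ds = make_toy_fixture("hd_half")
        assert ps.haplotype_diversity(ds.loci[0].haplotypes) == pytest.approx(0.5)

    def test_change_zero_for_identical_pops(self):
        seqs = ["ACGT", "ACGA", "TCGA"]
        ds = _dataset({"JPp": seqs, "X": seqs}, {"JPp": "JP", "X": "SP"})
        assert ps.haplotype_diversity_change(ds, "L", "X", ref_pop="JPp") == pytest.approx(0.0)

    def test_change_formula_minus_half(self):
        ref = ["AAAA", "TTTT", "CCCC", "GGGG"]  # Hd = 4/3 * (1 - 4/16) = 1.0
        pop = ["AAAA", "AAAA", "AAAA", "TTTT"]  # Hd = 0.5
        ds = _dataset({"R": ref, "P": pop}, {"R": "JP", "P": "SP"})
        assert ps.haplotype_diversity_change(ds, "L", "P", ref_pop="R") == pytest.approx(-0.5)

    def test_missing_rows_excluded(self):
        ref = ["AAAA", "TTTT", "CCCC", "GGGG"]
        pop = ["AAAA", "AAAA", "AAAA", "TTTT", "NNNN"]
        ds = _dataset({"R": ref, "P": pop}, {"R": "JP", "P": "SP"})
        assert ps.haplotype_diversity_change(ds, "L", "P", ref_pop="R") == pytest.approx(-0.5)

    def test_zero_reference_raises(self):
        ds = _dataset({"R": ["AAAA", "AAAA"], "P": ["AAAA", "TTTT"]}, {"R": "JP", "P": "SP"})
        with pytest.raises(ps.StatError):
            ps.haplotype_diversity_change(ds, "L", "P", ref_pop="R")


class TestSiteSummaries:
    def test_monomorphic(self):
        ds = make_toy_fixture("monomorphic")
        s = ps.site_summaries(ds, "P1")
        assert s.S == 0 and s.K_sd == 0.0 and s.tajima_d is None

    def test_tajima_d_matches_textbook_formula_n4(self):
        # 4 sequences, one biallelic 2/2 site among 4 sites
        ds = _dataset({"P": ["AAAA", "AAAA", "TAAA", "TAAA"]}, {"P": "JP"})
        s = ps.site_summaries(ds, "P")
        assert s.S == 1
        n, S = 4, 1
        pi_sum = 4 / 6  # 2*2 mismatching pairs of 6 at the one site
        i = np.arange(1, n)
        a1 = (1 / i).sum()
        a2 = (1 / i**2).sum()
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert s.tajima_d == pytest.approx(expected)

    def test_private_segregating_sites(self):
        # site 0 segregates only in A with allele T unique to A
        ds = _dataset(
            {"A": ["TAAA", "AAAA"], "B": ["AAAA", "AAAA"]}, {"A": "JP", "B": "SP"}
        )
        assert ps.site_summaries(ds, "A").prS == 1
        assert ps.site_summaries(ds, "B").prS == 0

    def test_prs_bounded_by_pooled_s(self, small_sim_dataset):
        ds = small_sim_dataset
        pooled = ps.site_summaries(ds, ds.regions[0])  # S of one region <= pooled
        total_prs = sum(ps.site_summaries(ds, r).prS for r in ds.regions)
        sv = ps.compute_stat_vector(ds)
        s_pool = sv.as_series()["S_pool"]
        assert total_prs <= s_pool


def brute_force_amova_fst(mats):
    """AMOVA Fst from an explicit pairwise mismatch-distance matrix."""
    pooled = np.concatenate(mats, axis=0)
    sizes = [m.shape[0] for m in mats]
    counts = [np.stack([(m == a).sum(0) for a in range(4)]).astype(float) for m in mats]
    ok = np.ones(pooled.shape[1], dtype=bool)
    for c in counts:
        ok &= c.sum(0) >= 2
    pooled = pooled[:, ok]
    N = pooled.shape[0]
    P = len(mats)
    present = pooled != MISSING
    D = np.zeros((N, N))
    for a in range(N):
        for b in range(N):
            both = present[a] & present[b]
            D[a, b] = (pooled[a][both] != pooled[b][both]).sum()
    bounds = np.cumsum([0] + sizes)
    ssd_w = 0.0
    for p in range(P):
        lo, hi = bounds[p], bounds[p + 1]
        ssd_w += D[lo:hi, lo:hi][np.triu_indices(hi - lo, 1)].sum() / sizes[p]
    ssd_t = D[np.triu_indices(N, 1)].sum() / N
    ssd_a = ssd_t - ssd_w
    sigma_w = ssd_w / (N - P)
    n_c = (N - sum(s**2 for s in sizes) / N) / (P - 1)
    sigma_a = (ssd_a / (P - 1) - sigma_w) / n_c
    return sigma_a / (sigma_a + sigma_w)


class TestFst:
    def test_fixed_difference_is_one(self, fst_one):
        fst, _ = ps.pairwise_fst(fst_one, "A", "B", n_perm=0)
        assert fst == pytest.approx(1.0)

    def test_random_split_is_near_zero(self, rng):
        seqs = ["".join(rng.choice(list("AT"), 8)) for _ in range(16)]
        ds = _dataset({"A": seqs[:8], "B": seqs[8:]}, {"A": "JP", "B": "SP"})
        fst, p = ps.pairwise_fst(ds, "A", "B", n_perm=200, seed=0)
        assert abs(fst) < 0.25
        assert p > 0.05

    def test_matches_brute_force_distance_amova(self, rng):
        # crafted 2+2 haplotypes with distinct distances, plus a missing call
        seqs_a = ["AATTC", "AATAC"]
        seqs_b = ["TTAAG", "TTANG"]
        ds = _dataset({"A": seqs_a, "B": seqs_b}, {"A": "JP", "B": "SP"})
        fst, _ = ps.pairwise_fst(ds, "A", "B", n_perm=0)
        mats = [ds.loci[0].haplotypes[:2], ds.loci[0].haplotypes[2:]]
        assert fst == pytest.approx(brute_force_amova_fst(mats))

    def test_matches_brute_force_on_random_data_with_missing(self, rng):
        for _ in range(5):
            mat = rng.choice([0, 1, 2, MISSING], size=(9, 12), p=[0.4, 0.3, 0.1, 0.2]).astype(np.int8)
            mats = [mat[:4], mat[4:]]
            fst = ps._fst_from_matrices(mats)
            assert fst == pytest.approx(brute_force_amova_fst(mats))

    def test_permutation_p_uniform_under_null(self, rng):
        """Permutation p-values should be ~uniform when both samples come
        from the same pool (KS over 200 null datasets)."""
        pvals = []
        for i in range(200):
            mat = rng.choice([0, 1], size=(10, 10)).astype(np.int8)
            ds = MultiLocusDataset(
                [LocusAlignment("L", mat)],
                [f"i{k}" for k in range(10)],
                {f"i{k}": ("A" if k < 5 else "B") for k in range(10)},
                {"A": "JP", "B": "SP"},
            )
            try:
                _, p = ps.pairwise_fst(ds, "A", "B", n_perm=49, seed=1000 + i)
            except ps.StatError:
                continue
            pvals.append(p)
        from scipy import stats as sps

        # discrete add-one p-values: compare against uniform loosely
        assert sps.kstest(pvals, "uniform").pvalue > 0.005


class TestAmova:
    def test_multigroup_components(self, rng):
        seqs = {
            "A": ["AAAA", "AAAT"],
            "B": ["TTTT", "TTTA"],
            "C": ["AATT", "AATA"],
        }
        ds = _dataset(seqs, {p: "JP" for p in seqs})
        out = ps.amova(ds, ["A", "B", "C"], n_perm=100, seed=2)
        mats = [ds.loci[0].haplotypes[i : i + 2] for i in (0, 2, 4)]
        assert out["fst"] == pytest.approx(brute_force_amova_fst(mats))
        assert 0 <= out["p"] <= 1


def test_fst_matrix_symmetric_with_pvalues(fst_one):
    m = ps.fst_matrix(fst_one, n_perm=50, seed=1)
    assert m.pops == ["A", "B"]
    assert m.fst[0, 1] == m.fst[1, 0] == pytest.approx(1.0)
    assert np.isnan(m.p[0, 0]) and 0 < m.p[0, 1] <= 1
    assert m.fst[0, 0] == 0.0


class TestMantel:
    def _geo(self):
        return GeoTable({p: (float(i), 0.0) for i, p in enumerate("abcd")})

    def test_perfect_correlation(self):
        # 7 populations with irregular spacing: enough distinct label
        # permutations for the p-value to approach its floor
        pops = list("abcdefg")
        geo = GeoTable({p: (float(x), 0.0) for p, x in zip(pops, [0, 1, 3, 6, 10, 20, 35])})
        gd = geo.distance_matrix(pops)
        r, p = ps.mantel_test(gd / gd.max(), pops, geo, n_perm=200, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_constant_matrix_raises(self):
        with pytest.raises(ps.StatError):
            ps.mantel_test(np.full((4, 4), 0.3), list("abcd"), self._geo(), n_perm=10)

    def test_r_equals_direct_pearson(self, rng):
        fst = rng.random((4, 4))
        fst = (fst + fst.T) / 2
        np.fill_diagonal(fst, 0)
        geo = self._geo()
        r, _ = ps.mantel_test(fst, list("abcd"), geo, n_perm=10, seed=0)
        iu = np.triu_indices(4, 1)
        expected = np.corrcoef(fst[iu], geo.distance_matrix(list("abcd"))[iu])[0, 1]
        assert r == pytest.approx(expected)

    def test_transforms(self, rng):
        fst = np.array(
            [[0, 0.1, 0.2, 0.3], [0.1, 0, 0.15, 0.25], [0.2, 0.15, 0, 0.05], [0.3, 0.25, 0.05, 0]]
        )
        geo = self._geo()
        for tr in ("identity", "neglog", "fst_ratio"):
            r, p = ps.mantel_test(fst, list("abcd"), geo, transform=tr, n_perm=99, seed=1)
            assert np.isfinite(r) and 0 < p <= 1


class TestStatVector:
    def test_67_finite_values_on_simulated_data(self, small_sim_dataset):
        sv = ps.compute_stat_vector(small_sim_dataset)
        assert len(sv) == 67
        assert np.all(np.isfinite(sv.values))

    def test_selected6_matches_independent_recomputation(self, small_sim_dataset):
        ds = small_sim_dataset
        sv = ps.compute_stat_vector(ds).as_series()
        # Fst_HI_SP via the pairwise op at region level
        fst, _ = ps.pairwise_fst(ds, "HI", "SP", n_perm=0)
        assert sv["fst_HI_SP"] == pytest.approx(fst)
        # prS/S for WUS via site_summaries
        summ = ps.site_summaries(ds, "WUS")
        assert sv["prSratio_WUS"] == pytest.approx(summ.prS / summ.S)

    def test_degenerate_region_flagged_and_imputed(self):
        pops = {
            "JP": ["AATT", "AATA"],
            "HI": ["AAAA", "AAAA"],  # monomorphic -> S=0
            "WUS": ["AATT", "AATA"],
            "EUS": ["AATT", "AATA"],
            "SP": ["AATT", "AATA"],
        }
        ds = _dataset(pops, {p: p for p in pops})
        sv = ps.compute_stat_vector(ds)
        s = sv.as_series()
        names = sv.names
        assert s["logS_HI"] == 0.0
        assert not sv.defined[names.index("logS_HI")]
        assert not sv.defined[names.index("D_HI")]

    def test_missing_region_raises(self):
        ds = _dataset({"JP": ["AAT", "AAA"]}, {"JP": "JP"})
        with pytest.raises(ps.StatError, match="lacks regions"):
            ps.compute_stat_vector(ds)
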