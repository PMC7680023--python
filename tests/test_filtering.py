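import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holopop import simdata
from holopop.exceptions import DataError
from holopop.filtering import (
    FilterParams,
    filter_individuals,
    filter_sites_basic,
    filter_sites_secondary,
    hwe_exact_test,
    hwe_filter_by_pop,
    recode_low_depth,
    run_cascade,
    thin_one_snp_per_contig,
)
from holopop.formats import MISSING, PopulationMap

from conftest import make_matrix, popmap_for


class TestRecodeLowDepth:
    def test_boundary_strict(self):
        gm = make_matrix([[1, 1]], depth=[[4, 5]])
        out = recode_low_depth(gm, 5)
        assert out.calls[0].tolist() == [MISSING, 1]

    def test_zero_threshold_identity(self):
        gm = make_matrix([[1, 2]], depth=[[0, 0]])
        out = recode_low_depth(gm, 0)
        assert np.array_equal(out.calls, gm.calls)

    def test_missing_depth_errors(self):
        gm = make_matrix([[1]])
        with pytest.raises(DataError):
            recode_low_depth(gm, 5)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(-1, 3, size=(10, 50)).astype(np.int8)
        depth = rng.integers(0, 15, size=(10, 50))
        gm = make_matrix(calls, depth=depth)
        out = recode_low_depth(gm, 5)
        for i in range(10):
            for j in range(50):
                expected = MISSING if depth[i, j] < 5 else calls[i, j]
                assert out.calls[i, j] == expected


class TestSitesBasic:
    def test_mac_keep_threshold(self):
        # 30 individuals, 2 alt copies -> mac 2 -> removed; 3 copies kept
        calls = np.zeros((30, 2), dtype=int)
        calls[0, 0] = 1
        calls[1, 0] = 1
        calls[0, 1] = 1
        calls[1, 1] = 2
        gm = make_matrix(calls, qual=[100, 100])
        out = filter_sites_basic(gm, FilterParams())
        assert out.n_loci == 1
        assert out.locus_ids[0].startswith("c1")

    def test_qual_boundary_strict(self):
        calls = np.tile([0, 1, 1, 2], (2, 1)).T  # mac 4 on both loci
        gm = make_matrix(calls, qual=[30.0, 30.1])
        out = filter_sites_basic(gm, FilterParams(mac_min=0))
        assert out.n_loci == 1
        assert out.site_qual[0] == pytest.approx(30.1)

    def test_indel_removed(self):
        gm = make_matrix([[1], [1], [1]], qual=[100], ref=["AT"], alt=["A"])
        out = filter_sites_basic(gm, FilterParams(mac_min=0))
        assert out.n_loci == 0

    def test_multiallelic_removed(self):
        gm = make_matrix([[1], [1], [1]], qual=[100])
        gm.multiallelic[0] = True
        out = filter_sites_basic(gm, FilterParams(mac_min=0))
        assert out.n_loci == 0

    def test_literal_mac_mode_inverts(self):
        calls = np.zeros((30, 1), dtype=int)
        calls[:3, 0] = 1  # mac 3
        gm = make_matrix(calls, qual=[100])
        assert filter_sites_basic(gm, FilterParams()).n_loci == 1
        assert filter_sites_basic(gm, FilterParams(literal_mac=True)).n_loci == 0


class TestIndividuals:
    def test_boundary(self):
        calls = np.ones((2, 100), dtype=int)
        calls[0, :51] = MISSING  # 51% missing -> dropped
        calls[1, :50] = MISSING  # exactly 50% -> kept
        gm = make_matrix(calls)
        out = filter_individuals(gm, 0.50)
        assert out.samples == ["s1"]

    def test_rowwise_oracle(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([MISSING, 0, 1, 2], p=[0.4, 0.2, 0.2, 0.2], size=(15, 40))
        gm = make_matrix(calls)
        out = filter_individuals(gm, 0.5)
        expected = [
            s for i, s in enumerate(gm.samples)
            if (calls[i] == MISSING).mean() <= 0.5
        ]
        assert out.samples == expected

    def test_all_removed_errors(self):
        gm = make_matrix(np.full((3, 10), MISSING, dtype=int))
        with pytest.raises(DataError):
            filter_individuals(gm, 0.5)


class TestSitesSecondary:
    def test_missingness_boundary(self):
        calls = np.ones((10, 2), dtype=int)
        calls[:8, 0] = MISSING  # 80% missing -> removed
        calls[:7, 1] = MISSING  # 70% -> kept by missingness
        gm = make_matrix(calls, depth=np.full((10, 2), 20))
        out = filter_sites_secondary(gm, FilterParams(maf_min=0))
        assert out.n_loci == 1

    def test_maf_inclusive(self):
        # 10 ind, 1 alt copy = maf 0.05 -> kept; maf below -> needs more ind
        calls = np.zeros((10, 1), dtype=int)
        calls[0, 0] = 1
        gm = make_matrix(calls, depth=np.full((10, 1), 20))
        out = filter_sites_secondary(gm, FilterParams())
        assert out.n_loci == 1

    def test_mean_depth_boundary(self):
        calls = np.tile([0, 1], (2, 5)).T.reshape(10, 2)[:, :2]
        calls = np.tile([[0], [1]], (5, 2))
        depth = np.full((10, 2), 10)
        depth[:, 1] = 9  # mean 9.99... < 10
        gm = make_matrix(calls, depth=depth)
        out = filter_sites_secondary(gm, FilterParams(maf_min=0, site_missing_max=1.0))
        assert out.n_loci == 1


def hwe_brute_force(n_hom_ref, n_het, n_hom_alt):
    """Exact-rational enumeration over compatible heterozygote counts."""
    n = n_hom_ref + n_het + n_hom_alt
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    def prob(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (
            Fraction(math.factorial(n), math.factorial(hom_r) * math.factorial(h) * math.factorial(hom_c))
            * Fraction(2) ** h
            * Fraction(math.factorial(rare) * math.factorial(2 * n - rare), math.factorial(2 * n))
        )
    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    p_obs = probs[n_het]
    return float(min(sum(p for p in probs.values() if p <= p_obs), 1))


class TestHweExact:
    def test_monomorphic_p_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_enumeration_oracle_2_8_0(self):
        assert hwe_exact_test(2, 8, 0) == pytest.approx(hwe_brute_force(2, 8, 0))

    def test_all_het_more_extreme_than_hwe_proportions(self):
        p_allhet = hwe_exact_test(0, 10, 0)
        p_nohet = hwe_exact_test(5, 0, 5)
        assert p_nohet < p_allhet or p_allhet < p_nohet  # both extremes differ
        # the balanced all-het configuration is *less* improbable than
        # zero hets at the same allele counts
        assert p_nohet < p_allhet

    @given(
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(hwe_brute_force(a, b, c))


class TestHweFilterByPop:
    def test_in_hwe_kept(self):
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.5, size=(40, 20))
        gm = make_matrix(calls)
        pm = popmap_for(gm, 4)
        out = hwe_filter_by_pop(gm, pm, 0.01, 0.5)
        assert out.n_loci == 20

    def test_violating_everywhere_removed(self):
        # all heterozygotes in every population: strong HWE violation
        calls = np.ones((40, 1), dtype=int)
        gm = make_matrix(calls)
        pm = popmap_for(gm, 4)
        out = hwe_filter_by_pop(gm, pm, 0.01, 0.5)
        assert out.n_loci == 0

    def test_per_pop_oracle(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([MISSING, 0, 1, 2], p=[0.1, 0.2, 0.5, 0.2], size=(20, 30))
        gm = make_matrix(calls)
        pm = popmap_for(gm, 2)
        labels = pm.labels_for(gm.samples)
        out = hwe_filter_by_pop(gm, pm, 0.05, 0.5)
        kept = set(out.locus_ids)
        for l, lid in enumerate(gm.locus_ids):
            viol = tested = 0
            for pop in pm.populations(gm.samples):
                sub = calls[labels == pop, l]
                sub = sub[sub != MISSING]
                if len(sub) < 2:
                    continue
                tested += 1
                p = hwe_brute_force(
                    int((sub == 0).sum()), int((sub == 1).sum()), int((sub == 2).sum())
                )
                if p < 0.05:
                    viol += 1
            expected_keep = not (tested and viol / tested > 0.5)
            assert (lid in kept) == expected_keep


class TestThinning:
    def test_one_per_contig(self):
        gm = make_matrix(np.zeros((2, 5), dtype=int),
                         contigs=["a", "a", "a", "b", "b"])
        out = thin_one_snp_per_contig(gm, seed=1)
        assert out.n_loci == 2
        assert sorted(set(out.contigs)) == ["a", "b"]

    def test_identity_when_unique(self):
        gm = make_matrix(np.zeros((2, 3), dtype=int), contigs=["a", "b", "c"])
        out = thin_one_snp_per_contig(gm, seed=5)
        assert np.array_equal(out.locus_ids, gm.locus_ids)

    def test_deterministic_and_uniform(self):
        gm = make_matrix(np.zeros((2, 4), dtype=int), contigs=["a"] * 4)
        picks = {thin_one_snp_per_contig(gm, seed=s).positions[0] for s in range(40)}
        assert len(picks) == 4  # every SNP reachable
        a = thin_one_snp_per_contig(gm, seed=3)
        b = thin_one_snp_per_contig(gm, seed=3)
        assert np.array_equal(a.locus_ids, b.locus_ids)


def brute_force_cascade(calls, depth, qual, ref, alt, labels, params):
    """Independent predicate-by-predicate re-evaluation of the cascade."""
    calls = calls.copy().astype(int)
    calls[depth < params.depth_min_genotype] = MISSING
    n, L = calls.shape
    # sites basic
    keep = []
    for l in range(L):
        col = calls[:, l]
        ok = qual[l] > params.qual_min
        ok &= len(ref[l]) == 1 and len(alt[l]) == 1
        valid = col[col != MISSING]
        alt_c = valid.sum()
        mac = min(alt_c, 2 * len(valid) - alt_c)
        ok &= mac >= params.mac_min
        keep.append(ok)
    calls = calls[:, np.array(keep, dtype=bool)]
    depth = depth[:, np.array(keep, dtype=bool)]
    # individuals, two passes
    for thresh in (params.ind_missing_1, params.ind_missing_2):
        rows = [(calls[i] == MISSING).mean() <= thresh for i in range(calls.shape[0])]
        rows = np.array(rows, dtype=bool)
        calls, depth, labels = calls[rows], depth[rows], labels[rows]
    # sites secondary
    keep = []
    for l in range(calls.shape[1]):
        col = calls[:, l]
        valid = col[col != MISSING]
        miss_ok = (col == MISSING).mean() <= params.site_missing_max
        alt_c = valid.sum()
        total = 2 * len(valid)
        maf = min(alt_c, total - alt_c) / total if total else 0.0
        keep.append(miss_ok and maf >= params.maf_min
                    and depth[:, l].mean() >= params.mean_depth_min)
    calls = calls[:, np.array(keep, dtype=bool)]
    # hwe
    keep = []
    for l in range(calls.shape[1]):
        viol = tested = 0
        for pop in np.unique(labels):
            sub = calls[labels == pop, l]
            sub = sub[sub != MISSING]
            if len(sub) < 2:
                continue
            tested += 1
            p = hwe_brute_force(int((sub == 0).sum()), int((sub == 1).sum()),
                                int((sub == 2).sum()))
            if p < params.hwe_p_cutoff:
                viol += 1
        keep.append(not (tested and viol / tested > params.hwe_pop_fraction))
    return calls[:, np.array(keep, dtype=bool)]


class TestCascade:
    def _random_case(self, seed, n=16, L=60):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.05, 0.95, L)
        calls = rng.binomial(2, p, size=(n, L))
        miss = rng.random((n, L)) < rng.uniform(0.0, 0.3)
        calls = np.where(miss, MISSING, calls)
        depth = rng.integers(0, 30, size=(n, L))
        qual = rng.uniform(10, 100, L)
        gm = make_matrix(calls, depth=depth, qual=qual)
        pm = popmap_for(gm, 2)
        return gm, pm

    def test_oracle_equivalence_random_matrices(self):
        params = FilterParams()
        for seed in range(25):
            gm, pm = self._random_case(seed)
            try:
                out, report = run_cascade(gm, pm, params)
            except DataError:
                continue  # all individuals removed: oracle would too
            labels = pm.labels_for(gm.samples)
            expected = brute_force_cascade(
                gm.calls, gm.depth, gm.site_qual, gm.ref, gm.alt,
                labels.copy(), params
            )
            assert out.calls.shape == expected.shape
            assert np.array_equal(
                np.where(out.calls == MISSING, MISSING, out.calls), expected
            )

    def test_disabled_thresholds_identity(self):
        gm, pm = self._random_case(3)
        params = FilterParams(
            ind_missing_1=1.0, ind_missing_2=1.0, mac_min=0, qual_min=0,
            depth_min_genotype=0, site_missing_max=1.0, maf_min=0.0,
            mean_depth_min=0, hwe_p_cutoff=0.0, biallelic_only=False,
            drop_indels=False,
        )
        out, report = run_cascade(gm, pm, params)
        assert np.array_equal(out.calls, gm.calls)
        assert out.samples == gm.samples

    def test_report_monotone(self):
        gm, pm = self._random_case(4)
        _, report = run_cascade(gm, pm, FilterParams())
        df = report.to_frame()
        assert (df["sites_out"] <= df["sites_in"]).all()
        assert (df["individuals_out"] <= df["individuals_in"]).all()
        # steps are contiguous
        assert (df["sites_in"].iloc[1:].to_numpy()
                == df["sites_out"].iloc[:-1].to_numpy()).all()

    def test_idempotent(self):
        cfg = simdata.SimConfig(seed=21, n_neutral_loci=300, n_outlier_loci=0,
                                missing_rate=0.05)
        gm, _ = simdata.simulate_genotypes(cfg)
        pm = simdata._population_map_for(gm, cfg.resolved_labels())
        once, _ = run_cascade(gm, pm, FilterParams())
        twice, _ = run_cascade(once, pm, FilterParams())
        assert np.array_equal(once.calls, twice.calls)
        assert once.samples == twice.samples

    def test_sample_order_invariance(self):
        gm, pm = self._random_case(6)
        out1, _ = run_cascade(gm, pm, FilterParams())
        perm = np.random.default_rng(0).permutation(gm.n_samples)
        gm2 = gm.take_samples(perm)
        out2, _ = run_cascade(gm2, pm, FilterParams())
        assert set(out1.locus_ids) == set(out2.locus_ids)
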