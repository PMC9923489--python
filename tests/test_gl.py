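import numpy as np
import pytest
from scipy import stats

from holopop.gl import (
    GLMatrix,
    PileupCounts,
    clone_threshold,
    compute_genotype_likelihoods,
    estimate_site_frequencies,
    filter_dataset,
    ibs_distance_matrix,
    infer_site_alleles,
    prune_clones,
)
from tests.conftest import make_certain_gl


def make_pileup(counts, major=None, minor=None):
    counts = np.asarray(counts, dtype=int)
    S = counts.shape[0]
    return PileupCounts(
        counts=counts,
        major=np.zeros(S, dtype=int) if major is None else np.asarray(major),
        minor=np.ones(S, dtype=int) if minor is None else np.asarray(minor),
        positions=np.arange(S),
        sample_ids=[f"s{i}" for i in range(counts.shape[1])],
    )


class TestGenotypeLikelihoods:
    def test_zero_reads_are_flat_and_masked(self):
        p = make_pileup(np.zeros((2, 3, 4)))
        glm = compute_genotype_likelihoods(p, 0.01)
        assert np.all(glm.gl == 0.0)
        assert glm.mask.all()

    def test_matches_per_read_product_enumeration(self):
        # 3 reads of the minor allele: brute-force the per-read product
        counts = np.zeros((1, 1, 4), dtype=int)
        counts[0, 0, 1] = 3
        glm = compute_genotype_likelihoods(make_pileup(counts), 0.01)
        e = 0.01
        p_read_minor = {0: e / 3, 1: 0.5 * (1 - e) + 0.5 * e / 3, 2: 1 - e}
        raw = np.array([np.log10(p_read_minor[g] ** 3) for g in (0, 1, 2)])
        expected = raw - raw.max()
        np.testing.assert_allclose(glm.gl[0, 0], expected, atol=1e-12)

    def test_deep_major_coverage_calls_homozygote(self):
        counts = np.zeros((1, 1, 4), dtype=int)
        counts[0, 0, 0] = 100
        glm = compute_genotype_likelihoods(make_pileup(counts), 0.01)
        assert np.argmax(glm.gl[0, 0]) == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_pileup(np.full((1, 1, 4), -1))

    def test_invalid_error_rate(self):
        p = make_pileup(np.ones((1, 1, 4)))
        with pytest.raises(ValueError, match="error_rate"):
            compute_genotype_likelihoods(p, 0.7)


class TestFiltering:
    def _glm_with_depth(self, depth):
        depth = np.asarray(depth)
        S, N = depth.shape
        return GLMatrix(
            gl=np.zeros((S, N, 3)), mask=depth == 0,
            positions=np.arange(S), sample_ids=[f"s{i:02d}" for i in range(N)],
            depth=depth,
        )

    def test_discovery_site_boundary_inclusive(self):
        # exactly 40% of individuals covered at 3+ reads -> retained
        depth = np.zeros((1, 10), dtype=int)
        depth[0, :4] = 3
        glm = self._glm_with_depth(np.vstack([depth] * 3)[..., :])
        out, rep = filter_dataset(glm, "discovery")
        assert rep.sites_out == 3

    def test_discovery_keeps_floor_65_percent_of_individuals(self):
        depth = np.full((5, 20), 3)
        out, rep = filter_dataset(self._glm_with_depth(depth), "discovery")
        assert rep.individuals_out == 13  # floor(0.65 * 20)

    def test_fully_covered_sites_pass_through(self):
        depth = np.full((4, 10), 10)
        out, _ = filter_dataset(self._glm_with_depth(depth), "analysis")
        assert out.n_sites == 4
        assert out.n_individuals == 10

    def test_idempotent_per_stage(self):
        rng = np.random.default_rng(0)
        depth = rng.poisson(5, size=(50, 20))
        once, _ = filter_dataset(self._glm_with_depth(depth), "discovery")
        twice, rep = filter_dataset(once, "discovery")
        assert twice.n_sites == once.n_sites
        assert twice.n_individuals == once.n_individuals

    def test_all_filtered_raises(self):
        depth = np.zeros((3, 10), dtype=int)
        with pytest.raises(ValueError, match="filter"):
            filter_dataset(self._glm_with_depth(depth), "analysis")


class TestSiteAlleles:
    def test_monomorphic_site_excluded(self):
        glm = make_certain_gl(np.zeros((5, 20), dtype=int))
        info = infer_site_alleles(glm)
        assert not info.keep.any()

    def test_maf_matches_grid_search(self):
        rng = np.random.default_rng(3)
        geno = rng.binomial(2, 0.25, size=(30, 40))
        glm = make_certain_gl(geno)
        freq, _ = estimate_site_frequencies(glm)
        lik = glm.linear()
        for s in (0, 7, 19):
            grid = np.linspace(1e-4, 1 - 1e-4, 20001)
            prior = np.stack(
                [(1 - grid) ** 2, 2 * grid * (1 - grid), grid**2]
            )
            ll = (
                np.log(lik[s] @ prior).sum(axis=0)
            )
            assert abs(freq[s] - grid[np.argmax(ll)]) < 1e-4

    def test_low_maf_excluded_at_threshold(self):
        # one minor heterozygote among 25 diploids: frequency 0.02 < 0.05
        geno = np.zeros((4, 25), dtype=int)
        geno[:, 0] = 1
        glm = make_certain_gl(geno)
        info = infer_site_alleles(glm, maf_min=0.05, lrt_alpha=0.99)
        assert (info.maf < 0.05).all()
        assert not info.keep.any()


class TestIBS:
    def test_identical_individuals_distance_zero(self):
        geno = np.tile(np.array([[0], [2], [0], [2]]), (1, 3))
        glm = make_certain_gl(geno)
        d = ibs_distance_matrix(glm, seed=0, min_sites=1)
        np.testing.assert_allclose(d.dist, 0.0)

    def test_counting_oracle_17_of_100(self):
        # haploid-sampled calls differ at exactly 17 of 100 sites when the
        # two individuals are opposite homozygotes there
        geno = np.zeros((100, 2), dtype=int)
        geno[:17, 1] = 2
        glm = make_certain_gl(geno)
        d = ibs_distance_matrix(glm, seed=1, min_sites=1)
        assert d.dist[0, 1] == pytest.approx(0.17)
        assert d.n_sites[0, 1] == 100

    def test_symmetry_and_zero_diagonal(self, reads_5x):
        _, glm, _ = reads_5x
        sub = glm.subset(individuals=range(8))
        d = ibs_distance_matrix(sub, seed=2)
        np.testing.assert_allclose(d.dist, d.dist.T)
        np.testing.assert_allclose(np.diag(d.dist), 0.0)

    def test_no_joint_sites_is_nan(self):
        glm = make_certain_gl(np.zeros((4, 2), dtype=int))
        glm.mask[:, 0] = True
        glm.depth[:, 0] = 0
        d = ibs_distance_matrix(glm, seed=0)
        assert np.isnan(d.dist[0, 1])


class TestCloneDetection:
    def _dists(self, pairs):
        ids = sorted({s for p in pairs for s in p[:2]})
        n = len(ids)
        d = np.zeros((n, n))
        from holopop.gl import IBSMatrix

        m = IBSMatrix(dist=d, n_sites=np.full((n, n), 1000),
                      sample_ids=ids, min_sites=10)
        for a, b, val in pairs:
            i, j = ids.index(a), ids.index(b)
            d[i, j] = d[j, i] = val
        return m

    def test_equal_replicate_distances_give_that_value(self):
        m = self._dists([("a", "b", 0.1), ("c", "d", 0.1), ("e", "f", 0.1)])
        thr = clone_threshold(m, [("a", "b"), ("c", "d"), ("e", "f")])
        assert thr == pytest.approx(0.1)

    def test_t_based_upper_ci_matches_hand_computation(self):
        vals = [0.10, 0.12, 0.11, 0.13]
        pairs = [("a", "b", vals[0]), ("c", "d", vals[1]),
                 ("e", "f", vals[2]), ("g", "h", vals[3])]
        m = self._dists(pairs)
        thr = clone_threshold(m, [p[:2] for p in pairs])
        x = np.array(vals)
        expected = x.mean() + stats.t.ppf(0.975, 3) * x.std(ddof=1) / 2.0
        assert thr == pytest.approx(expected, abs=1e-12)

    def test_too_few_replicate_pairs_raise(self):
        m = self._dists([("a", "b", 0.1)])
        with pytest.raises(ValueError, match="replicate"):
            clone_threshold(m, [("a", "b")])

    def test_triangle_of_clones_keeps_one(self):
        m = self._dists([("a", "b", 0.01), ("a", "c", 0.01), ("b", "c", 0.01)])
        rep = prune_clones(m, 0.05)
        assert len(rep.kept) == 1
        assert rep.groups == [["a", "b", "c"]]

    def test_chain_collapses_by_transitive_closure(self):
        m = self._dists([("a", "b", 0.01), ("b", "c", 0.02), ("a", "c", 0.20)])
        rep = prune_clones(m, 0.05)
        assert len(rep.kept) == 1

    def test_no_clones_keeps_everyone(self):
        m = self._dists([("a", "b", 0.4), ("b", "c", 0.5), ("a", "c", 0.45)])
        rep = prune_clones(m, 0.05)
        assert sorted(rep.kept) == ["a", "b", "c"]
        assert rep.groups == []

    def test_highest_coverage_member_kept(self):
        m = self._dists([("a", "b", 0.01)])
        rep = prune_clones(m, 0.05, coverage={"a": 10, "b": 99})
        assert rep.kept == ["b"]
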