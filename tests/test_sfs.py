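import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holopop.sfs import (
    FoldedSFS,
    diversity_from_sfs,
    estimate_folded_sfs,
    fold_sfs,
    fst_from_counts,
    fst_from_sfs2d,
    joint_folded_sfs,
    project_sfs,
    sfs_from_genotypes,
)
from tests.conftest import make_certain_gl


class TestFolding:
    def test_fold_merges_complementary_counts(self):
        data = np.arange(9.0)  # 2n = 8
        folded, mask = fold_sfs(data)
        # count k merges with 2n - k; the central class stays
        np.testing.assert_allclose(folded[:4], data[:4] + data[8:4:-1])
        assert folded[4] == data[4]
        assert folded[5:].sum() == 0
        assert mask[5:].all()

    def test_fold_preserves_total(self):
        rng = np.random.default_rng(0)
        data = rng.random((7, 10))
        folded, _ = fold_sfs(data)
        assert folded.sum() == pytest.approx(data.sum())

    @given(st.integers(2, 12), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_fold_idempotent_and_total_preserving(self, n, seed):
        data = np.random.default_rng(seed).random(n + 1)
        once, _ = fold_sfs(data)
        twice, _ = fold_sfs(once)
        assert np.allclose(once, twice)
        assert once.sum() == pytest.approx(data.sum())

    def test_projection_preserves_total_and_matches_binomial_limit(self):
        # projecting a monomorphic-free spectrum halves sample size
        data = np.zeros(9)
        data[2] = 100.0  # 2 derived among 8
        proj = project_sfs(data, (4,))
        assert proj.sum() == pytest.approx(100.0)
        # hypergeometric expectation for 2 of 8 sampled down to 4
        from scipy.stats import hypergeom

        expected = hypergeom.pmf(np.arange(5), 8, 2, 4) * 100
        np.testing.assert_allclose(proj, expected, atol=1e-9)


class TestSfsEstimation:
    def test_certain_gls_reproduce_count_histogram(self):
        rng = np.random.default_rng(5)
        geno = rng.binomial(2, 0.3, size=(300, 6))
        glm = make_certain_gl(geno)
        est = estimate_folded_sfs(glm, fold=False)
        truth = sfs_from_genotypes(geno, fold=False)
        np.testing.assert_allclose(est.data, truth.data, atol=1e-4)

    def test_entries_sum_to_site_count(self, reads_5x):
        _, glm, _ = reads_5x
        sub = glm.subset(sites=range(500), individuals=range(6))
        est = estimate_folded_sfs(sub)
        assert est.n_sites == pytest.approx(500)

    def test_joint_certain_gls_match_2d_histogram(self):
        rng = np.random.default_rng(6)
        geno = rng.binomial(2, 0.3, size=(400, 8))
        glm = make_certain_gl(geno)
        est = joint_folded_sfs(glm, range(4), range(4, 8), fold=False)
        truth = np.zeros((9, 9))
        np.add.at(
            truth,
            (geno[:, :4].sum(1), geno[:, 4:].sum(1)),
            1.0,
        )
        np.testing.assert_allclose(est.data, truth, atol=1e-3)

    def test_joint_entry_sum_is_site_count(self, reads_5x):
        _, glm, _ = reads_5x
        sub = glm.subset(sites=range(400))
        est = joint_folded_sfs(sub, range(4), range(4, 8))
        assert est.data.sum() == pytest.approx(400)


class TestDiversity:
    def test_monomorphic_spectrum_gives_zero(self):
        sfs = FoldedSFS(np.array([50.0, 0, 0, 0, 0]), (4,), folded=False)
        d = diversity_from_sfs(sfs)
        assert d.pi == 0.0
        assert d.theta_w == 0.0

    def test_watterson_harmonic_arithmetic(self):
        # S = 7 segregating sites among 2n = 8 chromosomes, L = 100
        data = np.zeros(9)
        data[0] = 93
        data[1] = 7
        sfs = FoldedSFS(data, (8,), folded=False)
        d = diversity_from_sfs(sfs, n_sites=100)
        a_n = sum(1.0 / i for i in range(1, 8))
        assert d.theta_w == pytest.approx(7 / (a_n * 100))
        assert d.theta_w == pytest.approx(0.0269975, abs=1e-6)

    def test_pi_matches_pairwise_difference_oracle(self):
        rng = np.random.default_rng(9)
        geno = rng.binomial(2, 0.4, size=(10, 4))  # 10 sites, 4 diploids
        sfs = sfs_from_genotypes(geno)
        d = diversity_from_sfs(sfs)
        # brute force: average pairwise difference over all chromosome pairs
        haps = []
        for i in range(4):
            g = geno[:, i]
            h1 = (g >= 1).astype(int)
            h2 = (g == 2).astype(int)
            haps += [h1, h2]
        haps = np.array(haps)
        total = 0
        npairs = 0
        for i in range(8):
            for j in range(i + 1, 8):
                total += (haps[i] != haps[j]).sum()
                npairs += 1
        assert d.pi == pytest.approx(total / npairs / 10)


class TestFst:
    def test_identical_frequencies_near_zero(self):
        ac = np.array([5, 10, 3, 8])
        res = fst_from_counts(ac, 20, ac, 20, min_sites_per_window=1)
        assert res.fst_weighted < 0.05  # slightly negative is possible

    def test_fixed_differences_give_one(self):
        n = 10
        ac1 = np.full(50, n)
        ac2 = np.zeros(50, dtype=int)
        res = fst_from_counts(ac1, n, ac2, n, min_sites_per_window=1)
        assert res.fst_weighted == pytest.approx(1.0)

    def test_toy_table_matches_hand_computation(self):
        ac1 = np.array([3, 12, 7])
        ac2 = np.array([9, 2, 14])
        n1, n2 = 16, 18
        res = fst_from_counts(ac1, n1, ac2, n2, min_sites_per_window=1)
        p1, p2 = ac1 / n1, ac2 / n2
        num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert res.fst_weighted == pytest.approx(num.sum() / den.sum(),
                                                 abs=1e-12)

    def test_window_smaller_than_step_rejected(self):
        with pytest.raises(ValueError, match="window"):
            fst_from_counts(np.array([1]), 4, np.array([2]), 4,
                            window=5_000, step=10_000)

    def test_site_order_invariance(self):
        rng = np.random.default_rng(2)
        ac1 = rng.integers(0, 11, 200)
        ac2 = rng.integers(0, 11, 200)
        perm = rng.permutation(200)
        a = fst_from_counts(ac1, 10, ac2, 10).fst_weighted
        b = fst_from_counts(ac1[perm], 10, ac2[perm], 10).fst_weighted
        assert a == pytest.approx(b, abs=1e-14)

    def test_sfs2d_route_agrees_with_per_site_route(self):
        rng = np.random.default_rng(4)
        n1 = n2 = 10
        ac1 = rng.integers(0, n1 + 1, 500)
        ac2 = rng.integers(0, n2 + 1, 500)
        direct = fst_from_counts(ac1, n1, ac2, n2).fst_weighted
        joint = np.zeros((n1 + 1, n2 + 1))
        np.add.at(joint, (ac1, ac2), 1.0)
        via_sfs = fst_from_sfs2d(FoldedSFS(joint, (n1, n2), folded=False))
        assert via_sfs == pytest.approx(direct, abs=1e-12)

    def test_folding_does_not_change_fst(self):
        rng = np.random.default_rng(8)
        joint = rng.random((11, 11))
        unfolded = FoldedSFS(joint, (10, 10), folded=False)
        folded = unfolded.fold()
        assert fst_from_sfs2d(folded) == pytest.approx(
            fst_from_sfs2d(unfolded), abs=1e-12
        )
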