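import numpy as np
import pytest
from scipy import stats

from isletpop.core_io import GenotypeMatrix, MISSING
from isletpop.structure import (
    compare_groups,
    fst_hudson,
    fst_inbreeding_corrected,
    fst_naive_genotype,
    inbreeding_coefficient,
    lambda_gc,
    pca,
    predict_group_accuracy,
)
from isletpop.synthetic_data import SimConfig, gen_balding_nichols, null_split

from conftest import make_geno
from oracles import hudson_fst_bruteforce


class TestPca:
    def test_two_pops_separate_on_pc1(self, two_pop_cohort):
        g, info, _ = two_pop_cohort
        res = pca(g, k=4)
        labels = info.labels_for(g.samples)
        pc1 = res.scores[:, 0]
        # linear separability of the two labels on PC1
        thr = (pc1[labels == "pop1"].mean() + pc1[labels == "pop2"].mean()) / 2
        pred = np.where(pc1 > thr, "pop1", "pop2")
        acc = max((pred == labels).mean(), (pred != labels).mean())
        assert acc > 0.99

    def test_null_no_outlier_eigenvalue(self, panmictic_cohort):
        g, _, _ = panmictic_cohort
        res = pca(g, k=10)
        top = res.eigenvalues[:10]
        assert top[0] < 1.5 * np.median(top)

    def test_duplicated_samples_equal_scores(self):
        g, _, _ = gen_balding_nichols(SimConfig(seed=9, samples_per_pop=20, n_snps=500))
        dup = GenotypeMatrix(
            [f"{s}_a" for s in g.samples] + [f"{s}_b" for s in g.samples],
            g.variants,
            np.vstack([g.calls, g.calls]),
        )
        res = pca(dup, k=2)
        n = g.n_samples
        np.testing.assert_allclose(res.scores[:n, 0], res.scores[n:, 0], atol=1e-8)

    def test_eigenvalues_sorted(self, panmictic_cohort):
        g, _, _ = panmictic_cohort
        res = pca(g, k=5)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


class TestPredictGroupAccuracy:
    def test_random_labels_chance_accuracy(self):
        # large n keeps the in-sample refit inflation below the tolerance
        rng = np.random.default_rng(0)
        pcs = rng.normal(size=(720, 4))
        labels = np.repeat([f"g{i}" for i in range(6)], 120)
        out = predict_group_accuracy(pcs, labels, n_iter=30, seed=1)
        assert abs(out["mean"] - 1 / 6) < 0.03

    def test_separated_pops_high_accuracy(self, two_pop_cohort):
        g, info, _ = two_pop_cohort
        res = pca(g, k=4)
        labels = info.labels_for(g.samples)
        out = predict_group_accuracy(res.scores, labels, n_iter=10, seed=2)
        assert out["mean"] > 0.99

    def test_small_group_rejected(self):
        pcs = np.random.default_rng(1).normal(size=(5, 4))
        with pytest.raises(ValueError, match="g2"):
            predict_group_accuracy(pcs, ["g1"] * 4 + ["g2"], n_iter=2, seed=0)


class TestLambdaGc:
    def test_null_split_near_one(self, panmictic_cohort):
        g, _, _ = panmictic_cohort
        info = null_split(g, seed=5)
        lam = lambda_gc(g, info.labels_for(g.samples), "g1", "g2")
        assert 0.9 < lam < 1.1  # 20k SNPs; the acceptance run uses 100k

    def test_differentiated_pops_inflated(self):
        g, info, _ = gen_balding_nichols(
            SimConfig(seed=13, n_pops=2, samples_per_pop=100, n_snps=5000, fst=0.01)
        )
        lam = lambda_gc(g, info.labels_for(g.samples), "pop1", "pop2")
        assert lam > 1.2

    def test_identical_groups_degenerate_zero(self):
        calls = np.tile(np.array([[0], [1], [2], [0], [1], [2]], dtype=np.int8), (1, 120))
        g = make_geno(calls)
        labels = ["a", "a", "a", "b", "b", "b"]
        assert lambda_gc(g, labels, "a", "b") == 0.0

    def test_invariant_to_snp_permutation(self, panmictic_cohort):
        g, _, _ = panmictic_cohort
        info = null_split(g, seed=5)
        labels = info.labels_for(g.samples)
        perm = np.random.default_rng(2).permutation(g.n_variants)
        order = np.argsort(g.variants.pos[perm], kind="stable")
        gp = g.take_variants(perm[order])
        assert lambda_gc(g, labels, "g1", "g2") == pytest.approx(
            lambda_gc(gp, labels, "g1", "g2")
        )


class TestFstHudson:
    def test_equal_freqs_near_zero(self):
        rng = np.random.default_rng(0)
        calls = rng.binomial(2, 0.3, size=(400, 3000)).astype(np.int8)
        g = make_geno(calls)
        labels = np.array(["a"] * 200 + ["b"] * 200, dtype=object)
        res = fst_hudson(g, labels, "a", "b")
        assert abs(res.estimate) < 2e-3

    def test_fixed_difference_is_one(self):
        calls = np.vstack([np.full((50, 100), 2), np.zeros((50, 100))]).astype(np.int8)
        g = make_geno(calls)
        labels = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        res = fst_hudson(g, labels, "a", "b")
        assert res.estimate == pytest.approx(1.0)

    def test_parameter_recovery(self, two_pop_cohort):
        g, info, truth = two_pop_cohort
        res = fst_hudson(g, info.labels_for(g.samples), "pop1", "pop2")
        assert abs(res.estimate - 0.05) < 0.01
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_matches_bruteforce_accumulation(self, two_pop_cohort):
        g, info, _ = two_pop_cohort
        labels = info.labels_for(g.samples)
        sub = g.take_variants(np.arange(500))
        res = fst_hudson(sub, labels, "pop1", "pop2")
        oracle = hudson_fst_bruteforce(
            sub.calls[labels == "pop1"], sub.calls[labels == "pop2"]
        )
        assert res.estimate == pytest.approx(oracle, rel=1e-12)

    def test_symmetry_and_allele_swap_invariance(self, two_pop_cohort):
        g, info, _ = two_pop_cohort
        labels = info.labels_for(g.samples)
        sub = g.take_variants(np.arange(1000))
        a = fst_hudson(sub, labels, "pop1", "pop2").estimate
        b = fst_hudson(sub, labels, "pop2", "pop1").estimate
        assert a == pytest.approx(b, rel=1e-12)
        swapped = sub.calls.copy()
        swapped[:, ::2] = np.where(swapped[:, ::2] == MISSING, MISSING, 2 - swapped[:, ::2])
        gs = GenotypeMatrix(sub.samples, sub.variants, swapped)
        c = fst_hudson(gs, labels, "pop1", "pop2").estimate
        assert c == pytest.approx(a, rel=1e-12)

    def test_permutation_p_small_under_structure(self):
        g, info, _ = gen_balding_nichols(
            SimConfig(seed=21, n_pops=2, samples_per_pop=50, n_snps=2000, fst=0.02)
        )
        res = fst_hudson(g, info.labels_for(g.samples), "pop1", "pop2", n_perm=99, seed=0)
        assert res.p_value_label == "<0.0101"
        assert res.p_value == pytest.approx(1 / 100)

    def test_degenerate_denominator(self):
        calls = np.zeros((10, 5), dtype=np.int8)
        g = make_geno(calls)
        labels = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        with pytest.raises(ValueError, match="degenerate"):
            fst_hudson(g, labels, "a", "b")


class TestFstInbreedingCorrected:
    def test_agrees_with_hudson_without_inbreeding(self, two_pop_cohort):
        g, info, _ = two_pop_cohort
        labels = info.labels_for(g.samples)
        h = fst_hudson(g, labels, "pop1", "pop2")
        ic = fst_inbreeding_corrected(g, labels, "pop1", "pop2", seed=0)
        half_width = (h.ci_high - h.ci_low) / 2
        assert abs(ic.estimate - h.estimate) < 2 * half_width

    def test_robust_to_inbreeding_where_naive_is_not(self):
        g, info, _ = gen_balding_nichols(
            SimConfig(seed=23, n_pops=2, samples_per_pop=150, n_snps=30_000,
                      fst=0.0, inbreeding_f=0.3)
        )
        labels = info.labels_for(g.samples)
        ic = fst_inbreeding_corrected(g, labels, "pop1", "pop2", seed=1)
        naive = fst_naive_genotype(g, labels, "pop1", "pop2")
        assert abs(ic.estimate) < 5e-4
        assert naive > 1e-3
        assert naive > 3 * abs(ic.estimate)

    def test_copied_groups_near_zero(self):
        # literally copied samples violate the independent-sampling assumption
        # of any unbiased estimator, leaving an O(1/n) conditional deficit
        # (expected about -1/(2n)); the estimate must vanish at that rate
        n = 300
        g, _, _ = gen_balding_nichols(SimConfig(seed=24, samples_per_pop=n, n_snps=5000))
        dup = GenotypeMatrix(
            [f"{s}_a" for s in g.samples] + [f"{s}_b" for s in g.samples],
            g.variants,
            np.vstack([g.calls, g.calls]),
        )
        labels = np.array(["a"] * g.n_samples + ["b"] * g.n_samples, dtype=object)
        res = fst_inbreeding_corrected(dup, labels, "a", "b", seed=2)
        assert abs(res.estimate) < 1.0 / n


class TestInbreedingCoefficient:
    def test_all_homozygous_sample_is_one(self):
        rng = np.random.default_rng(3)
        calls = rng.binomial(2, 0.4, size=(30, 400)).astype(np.int8)
        calls[0] = np.where(calls[0] == 1, 2, calls[0])
        g = make_geno(calls)
        stats_ = inbreeding_coefficient(g)
        assert stats_[0].f_hat == pytest.approx(1.0)

    def test_parameter_recovery(self):
        g, _, _ = gen_balding_nichols(
            SimConfig(seed=25, samples_per_pop=60, n_snps=50_000, inbreeding_f=0.1)
        )
        vals = [s.f_hat for s in inbreeding_coefficient(g)]
        assert abs(np.mean(vals) - 0.1) < 0.02


class TestCompareGroups:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(500):
            v = rng.normal(size=60)
            labels = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
            out = compare_groups(v, labels, "a")
            pvals.append(float(out.loc[out["group"] == "b", "p_vs_reference"].iloc[0]))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_power_on_shifted_means(self):
        rng = np.random.default_rng(8)
        v = np.concatenate([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
        labels = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        out = compare_groups(v, labels, "a")
        assert float(out.loc[out["group"] == "b", "p_vs_reference"].iloc[0]) < 1e-6

    def test_self_comparison(self):
        v = np.arange(10.0)
        labels = np.array(["a"] * 10, dtype=object)
        out = compare_groups(v, labels, "a")
        assert float(out["p_vs_reference"].iloc[0]) == 1.0
        assert float(out["t_vs_reference"].iloc[0]) == 0.0
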