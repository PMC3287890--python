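"""Gene-level collapsing tests: collapse definitions, regression oracles,
permutation validity, and the batched engine's determinism."""

import itertools

import numpy as np
import pytest
from scipy import stats

from burdenset import (
    GeneMap,
    GenotypeMatrix,
    PermutationPlan,
    Step1Engine,
    cmc_collapse,
    cmc_test,
    run_step1,
    weighted_sum_collapse,
    weightsum1_test,
    weightsum2_test,
)
from burdenset.simulate import SimulationConfig, simulate_genotypes

from conftest import random_genotypes


def brute_force_ols_f(y, X):
    """Independent OLS oracle: normal equations solved by hand-rolled
    Gaussian elimination; joint F of all non-intercept terms."""
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    k = A.shape[1]
    M = (A.T @ A).tolist()
    b = (A.T @ y).tolist()
    for col in range(k):  # elimination with partial pivoting
        piv = max(range(col, k), key=lambda r: abs(M[r][col]))
        M[col], M[piv] = M[piv], M[col]
        b[col], b[piv] = b[piv], b[col]
        for r in range(col + 1, k):
            f = M[r][col] / M[col][col]
            for c in range(col, k):
                M[r][c] -= f * M[col][c]
            b[r] -= f * b[col]
    beta = [0.0] * k
    for r in range(k - 1, -1, -1):
        beta[r] = (b[r] - sum(M[r][c] * beta[c] for c in range(r + 1, k))) / M[r][r]
    resid = y - A @ np.array(beta)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    dfn = k - 1
    dfd = n - k
    F = ((tss - rss) / dfn) / (rss / dfd)
    return F, float(stats.f.sf(F, dfn, dfd))


class TestCollapse:
    def test_cmc_indicator_and_count(self):
        d = np.array([[0, 0], [1, 0], [0, 2]], dtype=float)
        g = GenotypeMatrix(d, list("abc"), ["r1", "r2"])
        ind = cmc_collapse(g, [0, 1], "indicator")
        cnt = cmc_collapse(g, [0, 1], "count")
        assert ind.values.tolist() == [0, 1, 1]
        assert cnt.values.tolist() == [0, 1, 2]

    def test_empty_rare_set_is_degenerate_zero(self, tiny_geno):
        c = cmc_collapse(tiny_geno, [], "indicator")
        assert c.degenerate and not c.values.any()

    def test_count_equals_indicator_for_single_copy_carriers(self, rng):
        # when every carrier has exactly one rare-allele copy the two agree
        d = (rng.random((40, 6)) < 0.05).astype(float)
        g = GenotypeMatrix(d, [f"s{i}" for i in range(40)], [f"v{j}" for j in range(6)])
        ind = cmc_collapse(g, range(6), "indicator")
        cnt = cmc_collapse(g, range(6), "count")
        carriers_single = (d.sum(axis=1) <= 1)
        assert np.array_equal(ind.values[carriers_single], cnt.values[carriers_single])

    def test_weighted_sum_weight_formula(self):
        # n=4 genotyped, m=1 minor copy: q=(1+1)/(8+2)=0.2, w=sqrt(4*.2*.8)=0.8
        d = np.array([[1.0], [0.0], [0.0], [0.0]])
        g = GenotypeMatrix(d, list("abcd"), ["v"])
        c = weighted_sum_collapse(g, [0])
        assert c.weights[0] == pytest.approx(0.8)
        assert c.values.tolist() == pytest.approx([1 / 0.8, 0, 0, 0])

    def test_weighted_sum_is_linear_in_columns(self, rng):
        g = random_genotypes(rng, 25, 1)
        dup = GenotypeMatrix(
            np.column_stack([g.dosages, g.dosages]), g.sample_ids, ["a", "b"]
        )
        one = weighted_sum_collapse(g, [0])
        two = weighted_sum_collapse(dup, [0, 1])
        assert np.allclose(two.values, 2 * one.values)
        assert two.values[np.all(dup.dosages == 0, axis=1)].tolist() == pytest.approx(
            [0.0] * int(np.all(dup.dosages == 0, axis=1).sum())
        )


class TestCmcRegression:
    def test_perfect_fit_drives_p_to_floor(self, rng):
        g = random_genotypes(rng, 30, 3)
        part_rare = [0]
        c = cmc_collapse(g, part_rare, "count")
        y = 2.0 + 3.0 * c.values
        res = cmc_test(y, c, [1, 2], g)
        assert res.p_analytic < 1e-12

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_brute_force_ols_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_genotypes(rng, 20, 4)
        c = cmc_collapse(g, [0], "indicator")
        y = rng.standard_normal(20)
        res = cmc_test(y, c, [1, 2, 3], g)
        X = np.column_stack([c.values, g.imputed()[:, [1, 2, 3]]])
        F, p = brute_force_ols_f(y, X)
        assert res.statistic == pytest.approx(F, abs=1e-8)
        assert res.p_analytic == pytest.approx(p, abs=1e-8)

    def test_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm

        g = random_genotypes(rng, 40, 3)
        c = cmc_collapse(g, [0], "count")
        y = rng.standard_normal(40)
        res = cmc_test(y, c, [1, 2], g)
        X = sm.add_constant(np.column_stack([c.values, g.imputed()[:, [1, 2]]]))
        fit = sm.OLS(y, X).fit()
        assert res.p_analytic == pytest.approx(fit.f_pvalue, abs=1e-10)

    def test_constant_design_gives_p_one(self):
        d = np.zeros((10, 2))
        g = GenotypeMatrix(d, [f"s{i}" for i in range(10)], ["a", "b"])
        c = cmc_collapse(g, [0], "indicator")
        res = cmc_test(np.arange(10.0), c, [1], g)
        assert res.p_analytic == 1.0 and res.degenerate

    def test_partial_f_option_tests_collapsed_term_only(self, rng):
        g = random_genotypes(rng, 50, 3)
        c = cmc_collapse(g, [0], "count")
        y = rng.standard_normal(50)
        joint = cmc_test(y, c, [1, 2], g, joint=True)
        partial = cmc_test(y, c, [1, 2], g, joint=False)
        assert partial.dfn == 1 and joint.dfn >= partial.dfn
        assert 0 < partial.p_analytic <= 1


class TestWeightSumTests:
    def test_exhaustive_permutation_equals_enumeration(self, rng):
        n = 5
        g = random_genotypes(rng, n, 2, maf_low=0.2)
        s = weighted_sum_collapse(g, [0, 1])
        y = rng.standard_normal(n)
        plan = PermutationPlan.exhaustive_plan(n)
        res = weightsum1_test(y, s, plan)
        # independent enumeration in exact rational arithmetic: collapsed
        # scores repeat across individuals, so mathematical ties are common
        # and must be counted as >= without floating round-off
        from fractions import Fraction

        sv = [Fraction(v) for v in s.values]
        yv = [Fraction(v) for v in y]
        sc = [v - sum(sv) / n for v in sv]
        yc = [v - sum(yv) / n for v in yv]
        t_obs = abs(sum(a * b for a, b in zip(sc, yc)))
        stats_all = [
            abs(sum(sc[i] * yc[p] for i, p in enumerate(perm)))
            for perm in itertools.permutations(range(n))
        ]
        # ties resolved at floating precision (statistics closer than
        # round-off count as >=; float inputs cannot distinguish them)
        tol = Fraction(1, 10**12) * t_obs
        p_exact = sum(t >= t_obs - tol for t in stats_all) / len(stats_all)
        assert res.p_permutation == pytest.approx(p_exact)

    def test_constant_phenotype_gives_p_one(self, rng):
        g = random_genotypes(rng, 8, 1, maf_low=0.3)
        s = weighted_sum_collapse(g, [0])
        res = weightsum1_test(np.ones(8), s, PermutationPlan.random(8, 99, 0))
        assert res.p_permutation == 1.0 and res.degenerate

    def test_maximal_statistic_hits_permutation_floor(self):
        rng = np.random.default_rng(3)
        y = np.sort(rng.standard_normal(30))
        from burdenset.collapse_tests import CollapsedVariable

        # s identical to y: the cross product is rearrangement-maximal
        s = CollapsedVariable(y.copy(), "weighted_sum", np.array([0]))
        res = weightsum1_test(y, s, PermutationPlan.random(30, 999, seed=11))
        assert res.p_permutation == pytest.approx(1 / 1000)

    def test_weightsum2_matches_brute_force_slope_test(self):
        rng = np.random.default_rng(7)
        g = random_genotypes(rng, 50, 2)
        s = weighted_sum_collapse(g, [0, 1])
        y = rng.standard_normal(50)
        res = weightsum2_test(y, s)
        F, p = brute_force_ols_f(y, s.values[:, None])
        assert res.p_analytic == pytest.approx(p, abs=1e-8)

    def test_weightsum2_degenerate_and_perfect(self, rng):
        g = random_genotypes(rng, 20, 1, maf_low=0.3)
        s = weighted_sum_collapse(g, [0])
        perfect = weightsum2_test(2.0 * s.values, s)
        assert perfect.p_analytic < 1e-12
        from burdenset.collapse_tests import CollapsedVariable

        const = CollapsedVariable(np.zeros(20), "weighted_sum", np.array([0]))
        assert weightsum2_test(rng.standard_normal(20), const).p_analytic == 1.0


class TestStep1Engine:
    def test_same_seed_is_bit_identical(self, rng):
        g = random_genotypes(rng, 40, 8, maf_low=0.005)
        gm = GeneMap({"GA": [0, 1, 2, 3], "GB": [4, 5, 6, 7]})
        y = rng.standard_normal(40)
        r1 = run_step1(g, gm, y, plan=PermutationPlan.random(40, 10, seed=5))
        r2 = run_step1(g, gm, y, plan=PermutationPlan.random(40, 10, seed=5))
        for t in r1.panels:
            assert np.array_equal(r1.panels[t].perm_scores, r2.panels[t].perm_scores)
            assert r1.panels[t].perm_scores.shape == (10, 2)
        assert r1.results.equals(r2.results)

    def test_zero_carrier_gene_flagged_p_one(self, rng):
        d = np.zeros((30, 2))
        d[:, 1] = (np.arange(30) < 10).astype(float)  # one common variant
        g = GenotypeMatrix(d, [f"s{i}" for i in range(30)], ["dead", "live"])
        gm = GeneMap({"Gdead": [0], "Glive": [1]})
        res = run_step1(g, gm, rng.standard_normal(30), plan=PermutationPlan.random(30, 19, 0))
        sub = res.results[res.results.gene == "Gdead"]
        assert (sub.p_permutation == 1.0).all() and sub.degenerate.all()

    def test_null_fpr_of_permutation_pvalues_is_nominal(self):
        # global null: permutation p-values must reject at ~alpha
        cfg = SimulationConfig(n_individuals=150, n_genes=400, seed=21)
        geno, gmap = simulate_genotypes(cfg)
        eng = Step1Engine(geno, gmap, tests=("CMC-1",))
        y = np.random.default_rng(4).standard_normal(150)
        res = eng.run(y, PermutationPlan.random(150, 199, seed=8))
        rate = (res.permutation_pvalues("CMC-1") < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 400)
        assert abs(rate - 0.05) < 3 * se

    def test_engine_matches_single_gene_functions(self, rng):
        # the batched path must reproduce the per-gene reference functions
        g = random_genotypes(rng, 35, 6, maf_low=0.004, maf_high=0.3)
        gm = GeneMap({"GA": [0, 1, 2], "GB": [3, 4, 5]})
        y = rng.standard_normal(35)
        plan = PermutationPlan.random(35, 49, seed=2)
        res = Step1Engine(g, gm, maf_threshold=0.05).run(y, plan)
        from burdenset.data_model import partition_variants

        for gene in ("GA", "GB"):
            part = partition_variants(g, gm, gene, 0.05)
            c = cmc_collapse(g, part.rare, "indicator")
            ref = cmc_test(y, c, part.common, g)
            got = res.results[(res.results.gene == gene) & (res.results.test == "CMC-1")]
            assert got.p_analytic.iloc[0] == pytest.approx(ref.p_analytic, rel=1e-10)
            poly = np.concatenate([part.rare, part.common])
            ws = weighted_sum_collapse(g, poly)
            ref2 = weightsum2_test(y, ws)
            got2 = res.results[(res.results.gene == gene) & (res.results.test == "WeightSum2")]
            assert got2.p_analytic.iloc[0] == pytest.approx(ref2.p_analytic, rel=1e-10)
            ref1 = weightsum1_test(y, ws, plan)
            got1 = res.results[(res.results.gene == gene) & (res.results.test == "WeightSum1")]
            assert got1.p_permutation.iloc[0] == pytest.approx(ref1.p_permutation)


def test_permutation_plan_validates_bijections():
    with pytest.raises(ValueError, match="bijection"):
        PermutationPlan(np.array([[0, 0, 1]]))
    plan = PermutationPlan.random(6, 5, seed=1)
    assert plan.n_permutations == 5 and plan.n_samples == 6
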