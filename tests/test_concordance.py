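import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gwasaudit as ga
from gwasaudit.sumstats import SumStatsError

from conftest import small_table


def clump_oracle(pvals: dict, ld: pd.DataFrame, p_thresh: float, r2_thresh: float):
    """Exhaustive-enumeration reference for greedy clumping: among all
    maximal pairwise-independent subsets of the significant SNPs, the
    greedy result is the one whose (p, snp_id)-sorted sequence is
    lexicographically smallest."""
    sig = sorted(s for s, p in pvals.items() if p < p_thresh)
    n = len(sig)
    if n == 0:
        return set()
    conflict_mat = ld.loc[sig, sig].to_numpy(float) >= r2_thresh
    np.fill_diagonal(conflict_mat, False)
    conflict = [sum(1 << j for j in range(n) if conflict_mat[i, j]) for i in range(n)]
    best = None
    for mask in range(1, 1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        if any(conflict[i] & mask for i in members):
            continue  # some pair is in LD
        if any(not (mask >> i & 1) and not (conflict[i] & mask) for i in range(n)):
            continue  # not maximal: another SNP could still be added
        key = tuple(sorted((pvals[sig[i]], sig[i]) for i in members))
        if best is None or key < best[0]:
            best = (key, {sig[i] for i in members})
    return best[1] if best else set()


def random_instance(rng, n_snps):
    """A random small LD matrix (r2 blocks of random strength) and p-values."""
    ids = [f"s{i}" for i in range(n_snps)]
    mat = np.zeros((n_snps, n_snps))
    for i in range(n_snps):
        for j in range(i):
            mat[i, j] = mat[j, i] = rng.uniform(0, 0.6) if rng.random() < 0.4 else 0.0
    np.fill_diagonal(mat, 1.0)
    ld = pd.DataFrame(mat, index=ids, columns=ids)
    pvals = dict(zip(ids, rng.uniform(1e-12, 1e-7, n_snps)))
    return ld, pvals


def pvals_to_sumstats(pvals):
    return ga.sumstats_from_pvalues(pd.Series(pvals))


class TestLdClump:
    def test_no_significant_snps_empty(self):
        ld, pvals = ga.simulate_ld_blocks(2, 3, 0.5)
        ss = ga.sumstats_from_pvalues(pvals * 1e6)  # nothing below 5e-8 now
        assert len(ga.ld_clump(ss, ld)) == 0

    def test_single_significant_snp(self):
        ld, pvals = ga.simulate_ld_blocks(1, 4, 0.5)
        pv = pvals.copy() * 1e6
        pv.iloc[0] = 1e-9
        leads = ga.ld_clump(ga.sumstats_from_pvalues(pv), ld)
        assert leads.snp_ids == [pv.index[0]]

    def test_two_blocks_give_per_block_minima(self):
        ids = [f"s{i}" for i in range(6)]
        mat = np.zeros((6, 6))
        mat[:3, :3] = 0.5
        mat[3:, 3:] = 0.5
        np.fill_diagonal(mat, 1.0)
        ld = pd.DataFrame(mat, index=ids, columns=ids)
        pvals = dict(zip(ids, [3e-10, 5e-10, 9e-10, 2e-10, 7e-10, 8e-10]))
        leads = ga.ld_clump(pvals_to_sumstats(pvals), ld)
        assert set(leads.snp_ids) == {"s3", "s0"}
        assert set(leads.snp_ids) == clump_oracle(pvals, ld, 5e-8, 0.1)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            ld, pvals = random_instance(rng, int(rng.integers(4, 11)))
            leads = ga.ld_clump(pvals_to_sumstats(pvals), ld)
            assert set(leads.snp_ids) == clump_oracle(pvals, ld, 5e-8, 0.1)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(7)
        ld, pvals = random_instance(rng, 8)
        ss = pvals_to_sumstats(pvals)
        shuffled = ga.SumStats(ss.table.sample(frac=1, random_state=1).reset_index(drop=True))
        assert ga.ld_clump(ss, ld).snp_ids == ga.ld_clump(shuffled, ld).snp_ids

    def test_asymmetric_matrix_rejected(self):
        ld, pvals = ga.simulate_ld_blocks(1, 3, 0.5)
        bad = ld.copy()
        bad.iloc[0, 1] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            ga.ld_clump(ga.sumstats_from_pvalues(pvals), bad)


class TestSignConcordance:
    def test_full_concordance_gives_p_one(self, strong_pair):
        full, _, _ = strong_pair
        subset = full.table["snp_id"].head(842).tolist()
        prop, p = ga.sign_concordance(full, full, subset)
        assert prop == 1.0 and p == 1.0

    def test_binomial_cdf_oracle(self):
        t = small_table(5)
        base = pd.concat([t.assign(snp_id=[f"c{j}_{s}" for s in t.snp_id]) for j in range(20)],
                         ignore_index=True)
        full = ga.SumStats(base)
        down_t = base.copy()
        flip = np.zeros(100, bool)
        flip[:5] = True  # 95 of 100 concordant
        down_t.loc[flip, ["beta", "z"]] = -down_t.loc[flip, ["beta", "z"]]
        _, p = ga.sign_concordance(full, ga.SumStats(down_t), base["snp_id"], p0=0.99)
        assert p == pytest.approx(stats.binom.cdf(95, 100, 0.99), rel=1e-12)

    def test_zero_betas_count_discordant(self):
        t = small_table(4)
        down_t = t.copy()
        down_t["beta"] = 0.0
        down_t["z"] = 0.0
        prop, _ = ga.sign_concordance(ga.SumStats(t), ga.SumStats(down_t), t["snp_id"])
        assert prop == 0.0

    def test_symmetric_under_joint_sign_flip(self):
        t = small_table(5)
        flipped = t.copy()
        flipped[["beta", "z"]] = -flipped[["beta", "z"]]
        a = ga.sign_concordance(ga.SumStats(t), ga.SumStats(t), t["snp_id"])
        b = ga.sign_concordance(ga.SumStats(flipped), ga.SumStats(flipped), t["snp_id"])
        assert a == b

    def test_empty_subset_rejected(self):
        ss = ga.SumStats(small_table(3))
        with pytest.raises(SumStatsError):
            ga.sign_concordance(ss, ss, [])


class TestDesignPower:
    def test_150_snps_power_claim(self):
        assert ga.design_power(150, 0.99, 0.95, 0.05) >= 0.80

    def test_size_bounded_by_level(self):
        # under the null the rejection probability cannot exceed alpha
        k = np.arange(151)
        cdf0 = stats.binom.cdf(k, 150, 0.99)
        k_star = k[cdf0 <= 0.05].max()
        assert stats.binom.cdf(k_star, 150, 0.99) <= 0.05

    def test_monotone_in_n_and_p_true(self):
        assert ga.design_power(10, 0.99, 0.95) < ga.design_power(150, 0.99, 0.95)
        grid_n = [50, 150, 400, 1000]
        powers = [ga.design_power(n, 0.99, 0.95) for n in grid_n]
        assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))
        powers_p = [ga.design_power(150, 0.99, p) for p in (0.90, 0.93, 0.96, 0.98)]
        assert all(a >= b - 1e-12 for a, b in zip(powers_p, powers_p[1:]))

    def test_no_rejection_region_returns_zero(self):
        # with p0 = 0.5 even zero successes out of one trial has null
        # probability 0.5 > alpha, so no rejection region exists
        with pytest.warns(UserWarning):
            assert ga.design_power(1, 0.5, 0.3) == 0.0


class TestOutliers:
    def test_identical_pair_no_flags(self):
        ss = ga.SumStats(small_table(5))
        flags, n = ga.outlier_flags(ss, ss)
        assert n == 0

    def test_arithmetic_bound(self):
        t = small_table(1, seed=1).iloc[:1].copy()
        t["beta"], t["se"] = 0.10, 0.05
        t["z"] = t["beta"] / t["se"]
        d = t.copy()
        d["beta"] = 0.21
        d["z"] = d["beta"] / d["se"]
        _, n = ga.outlier_flags(ga.SumStats(t), ga.SumStats(d))
        assert n == 1  # bound is 0.10 + 1.96*0.05 = 0.198
        d2 = t.copy()
        d2["beta"] = 0.19
        d2["z"] = d2["beta"] / d2["se"]
        _, n2 = ga.outlier_flags(ga.SumStats(t), ga.SumStats(d2))
        assert n2 == 0

    def test_matches_row_by_row_recheck(self, strong_pair):
        full, down, _ = strong_pair
        sub = full.table["snp_id"].head(500).tolist()
        fsub, dsub = full.subset(sub), down.subset(sub)
        flags, _ = ga.outlier_flags(fsub, dsub)
        q = stats.norm.ppf(0.975)
        for i in range(len(sub)):
            lo = fsub.table.loc[i, "beta"] - q * fsub.table.loc[i, "se"]
            hi = fsub.table.loc[i, "beta"] + q * fsub.table.loc[i, "se"]
            expected = int(not (lo <= dsub.table.loc[i, "beta"] <= hi))
            assert flags[i] == expected


class TestCoefficientRegression:
    def test_identity_pair(self):
        ss = ga.SumStats(small_table(5))
        ic, sl, ar2, p_i, p_s = ga.coefficient_regression(ss, ss, ss.table["snp_id"])
        assert abs(ic) < 1e-10 and sl == pytest.approx(1.0, abs=1e-10)
        assert ar2 == pytest.approx(1.0, abs=1e-10)

    def test_exact_attenuation_detected(self):
        t = small_table(5)
        big = pd.concat([t.assign(snp_id=[f"c{j}_{s}" for s in t.snp_id]) for j in range(4)],
                        ignore_index=True)
        d = big.copy()
        d["beta"] = 0.9 * d["beta"]
        d["z"] = d["beta"] / d["se"]
        _, sl, ar2, _, p_s = ga.coefficient_regression(ga.SumStats(big), ga.SumStats(d),
                                                       big["snp_id"])
        assert sl == pytest.approx(0.9, abs=1e-10)
        assert ar2 == pytest.approx(1.0, abs=1e-10)
        assert p_s < 0.05

    def test_noisy_attenuation_slope_recovered(self):
        rng = np.random.default_rng(4)
        n = 842
        beta_full = rng.uniform(0.01, 0.08, n)
        beta_down = 0.898 * beta_full + rng.normal(0, 0.002, n)
        se = np.full(n, 0.003)
        def tab(beta):
            from scipy import stats as st
            z = beta / se
            return ga.SumStats(pd.DataFrame({
                "snp_id": [f"rs{i}" for i in range(n)], "chrom": "1",
                "pos": np.arange(n), "a1": "A", "a2": "G", "beta": beta,
                "se": se, "z": z, "p": np.maximum(2 * st.norm.sf(np.abs(z)), 1e-300),
                "n": 1e6}))
        full, down = tab(beta_full), tab(beta_down)
        _, sl, _, _, _ = ga.coefficient_regression(full, down, full.table["snp_id"])
        res_se = 0.002 / (np.std(beta_full) * np.sqrt(n))
        assert abs(sl - 0.898) <= 2 * res_se

    def test_degenerate_regressor_rejected(self):
        t = small_table(5)
        t["beta"] = 0.02
        t["z"] = t["beta"] / t["se"]
        ss = ga.SumStats(t)
        with pytest.raises(SumStatsError, match="variance"):
            ga.coefficient_regression(ss, ss, t["snp_id"])
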