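"""Association machinery against independent oracles: exact HWE enumeration,
hand-applied QC rules, brute-force GLS, exact multivariable regression."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from octphen.assoc import (
    GENOME_WIDE_ALPHA,
    SummaryStats,
    VariantQCRule,
    cojo_select,
    correlated_groups,
    estimate_null_z_corr,
    genetic_correlation,
    genomic_lambda,
    gwas_linear,
    hwe_exact_test,
    mtag_analysis,
    mtag_meta,
    replication_concordance,
    round_sig,
    significance_regime,
    trunc_sig,
    variant_qc,
)
from octphen.simulate import BlockSpec, GenotypeBlock, simulate_ld_genotypes


def _hwe_oracle(het, homr, homc):
    """Exact enumeration with rational arithmetic (conditional on allele counts)."""
    n = het + homr + homc
    rare = 2 * homr + het
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        if hr < 0 or hc < 0:
            continue
        weights[h] = Fraction(2**h, 1) / (
            Fraction(math.factorial(hr)) * math.factorial(h) * math.factorial(hc)
        )
    total = sum(weights.values())
    return float(sum(w for w in weights.values() if w <= weights[het]) / total)


def _make_block(dosages, maf_like=True):
    d = np.asarray(dosages, float)
    m = d.shape[1]
    return GenotypeBlock(
        d, 1_000_000 + 5000 * np.arange(m), np.array(["1"] * m, dtype=object)
    )


class TestHweExact:
    @pytest.mark.parametrize(
        "het,homr,homc",
        [(57, 14, 29), (100, 5, 95), (0, 10, 90), (3, 1, 5), (21, 10, 69), (2, 0, 2)],
    )
    def test_matches_rational_enumeration(self, het, homr, homc):
        assert hwe_exact_test(het, homr, homc) == pytest.approx(
            _hwe_oracle(het, homr, homc), rel=1e-10
        )

    def test_perfect_hwe_counts_not_rejected(self):
        assert hwe_exact_test(500, 250, 250) > 0.9


class TestVariantQC:
    def test_low_maf_excluded_with_reason(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, [0.02, 0.3], (500, 2)).astype(float)
        block = _make_block(d)
        filtered, report = variant_qc(block)
        assert not report["pass"][0] and report["reason"][0] == "maf"
        assert filtered.n_variants == 1

    def test_perfect_hwe_variant_passes(self):
        d = np.concatenate([np.zeros(250), np.ones(500), np.full(250, 2.0)])
        block = _make_block(d[:, None])
        _, report = variant_qc(block)
        assert report["pass"][0]
        assert report["hwe_p"][0] > 0.9

    def test_toy_block_exactly_two_survive(self):
        """Hand-applied rules on five printed variants: MAF 0.04 fails, a 2%-
        missing common variant fails the 99% call-rate rule, gross HWE
        violation (400/100/500) fails, two clean variants pass."""
        rng = np.random.default_rng(1)
        n = 1000
        v_lowmaf = rng.binomial(2, 0.04, n).astype(float)
        v_pass1 = rng.binomial(2, 0.10, n).astype(float)
        v_missing = rng.binomial(2, 0.50, n).astype(float)
        v_missing[:20] = np.nan  # 2% missing
        v_hwe = np.concatenate([np.zeros(400), np.ones(100), np.full(500, 2.0)])
        v_pass2 = np.concatenate([np.zeros(360), np.ones(480), np.full(160, 2.0)])
        block = _make_block(np.column_stack([v_lowmaf, v_pass1, v_missing, v_hwe, v_pass2]))
        filtered, report = variant_qc(block)
        assert filtered.n_variants == 2
        assert list(report["reason"]) == ["maf", "", "call_rate", "hwe", ""]

    def test_region_exclusion(self):
        d = np.random.default_rng(2).binomial(2, 0.3, (400, 1)).astype(float)
        block = _make_block(d)
        rule = VariantQCRule(exclude_regions=[("1", 900_000, 1_100_000)])
        filtered, report = variant_qc(block, rule)
        assert filtered.n_variants == 0 and report["reason"][0] == "region"


class TestGwasLinear:
    def test_null_type_one_error_calibrated(self, rng):
        n, m = 1000, 1000
        block = _make_block(rng.binomial(2, 0.3, (n, m)).astype(float))
        y = rng.standard_normal(n)
        cov = rng.standard_normal((n, 5))
        ss = gwas_linear(y, block, cov)
        frac = float((ss.df["p"] < 0.05).mean())
        assert 0.036 <= frac <= 0.064  # binomial 99% band at m=1000

    def test_exact_linear_trait_recovers_beta_with_underflowed_p(self, rng):
        n = 300
        block = _make_block(rng.binomial(2, 0.4, (n, 1)).astype(float))
        y = 0.5 * block.dosages[:, 0]
        ss = gwas_linear(y, block, None)
        assert ss.df["beta"][0] == pytest.approx(0.5, abs=1e-10)
        assert ss.df["p"][0] == np.finfo(float).tiny  # clipped at minimum representable
        assert ss.df["neglog10_p"][0] > 300

    def test_planted_effect_reaches_genome_wide_significance(self, rng):
        """~3% variance explained at n=2000 is reliably genome-wide significant."""
        n = 2000
        g = rng.binomial(2, 0.3, (n, 1)).astype(float)
        var_g = g.var()
        beta = np.sqrt(0.03 / var_g)  # 3% of unit trait variance
        hits = 0
        for s in range(5):
            r2 = np.random.default_rng(s)
            y = beta * g[:, 0] + np.sqrt(0.97) * r2.standard_normal(n)
            ss = gwas_linear(y, _make_block(g), None)
            hits += ss.df["p"][0] < GENOME_WIDE_ALPHA
        assert hits >= 4

    def test_missing_dosage_complete_case(self, rng):
        n = 500
        d = rng.binomial(2, 0.3, (n, 2)).astype(float)
        d[:50, 0] = np.nan
        block = _make_block(d)
        y = rng.standard_normal(n)
        ss = gwas_linear(y, block, None)
        assert ss.df["n"][0] == 450 and ss.df["n"][1] == 500

    def test_beta_and_se_match_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 400
        d = rng.binomial(2, 0.3, (n, 3)).astype(float)
        cov = rng.standard_normal((n, 4))
        y = rng.standard_normal(n) + 0.2 * d[:, 1]
        ss = gwas_linear(y, _make_block(d), cov)
        for j in range(3):
            x = sm.add_constant(np.column_stack([d[:, j], cov]))
            fit = sm.OLS(y, x).fit()
            assert ss.df["beta"][j] == pytest.approx(fit.params[1], rel=1e-8)
            assert ss.df["se"][j] == pytest.approx(fit.bse[1], rel=1e-6)

    def test_too_few_subjects_rejected(self, rng):
        block = _make_block(rng.binomial(2, 0.3, (5, 1)).astype(float))
        with pytest.raises(ValueError, match="covariates"):
            gwas_linear(np.zeros(5), block, rng.standard_normal((5, 6)))


class TestGenomicLambda:
    def test_null_lambda_near_one(self, rng):
        z = rng.standard_normal(10_000)
        ss_like = z**2
        lam = genomic_lambda(ss_like)
        assert 0.95 <= lam <= 1.05

    def test_scale_equivariance(self, rng):
        chi2 = rng.chisquare(1, 5000)
        assert genomic_lambda(2 * chi2) == pytest.approx(2 * genomic_lambda(chi2))

    def test_all_p_half_gives_unit_lambda(self):
        z = np.full(500, stats.norm.isf(0.25))  # two-sided p = 0.5
        assert genomic_lambda(z**2) == pytest.approx(1.0, rel=1e-6)


def _ss_from_arrays(beta, se, start_pos=1_000_000, chrom="1", trait="t", flip=None):
    m = len(beta)
    z = np.asarray(beta) / np.asarray(se)
    ea = np.array(["G"] * m, dtype=object)
    oa = np.array(["A"] * m, dtype=object)
    if flip is not None:
        ea[flip], oa[flip] = "A", "G"
    df = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(m)],
            "chromosome": chrom,
            "position": start_pos + 5000 * np.arange(m),
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": 0.3,
            "beta": beta,
            "se": se,
            "p": np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0),
            "neglog10_p": -(np.log(2) + stats.norm.logsf(np.abs(z))) / np.log(10),
            "n": 1000,
        }
    )
    return SummaryStats(df, trait=trait)


class TestGeneticCorrelation:
    def test_self_correlation_is_one(self, rng):
        beta = rng.standard_normal(50) * 3
        ss = _ss_from_arrays(beta, np.full(50, 0.1))
        assert genetic_correlation(ss, ss, p_threshold=1.0) == pytest.approx(1.0)

    def test_allele_flip_negates_correlation(self, rng):
        beta = rng.standard_normal(50) * 3
        a = _ss_from_arrays(beta, np.full(50, 0.1))
        b = _ss_from_arrays(-beta, np.full(50, 0.1), flip=np.ones(50, bool))
        # b stores -beta on swapped alleles: aligned it is +beta, so r = +1
        assert genetic_correlation(a, b, p_threshold=1.0) == pytest.approx(1.0)
        c = _ss_from_arrays(beta, np.full(50, 0.1), flip=np.ones(50, bool))
        assert genetic_correlation(a, c, p_threshold=1.0) == pytest.approx(-1.0)

    def test_too_few_shared_significant_flagged(self, rng):
        beta = rng.standard_normal(10) * 0.01
        ss = _ss_from_arrays(beta, np.full(10, 1.0))
        with pytest.warns(UserWarning, match="fewer than 3"):
            assert np.isnan(genetic_correlation(ss, ss, p_threshold=1e-10))

    def test_groups_are_connected_components(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.95
        r[1, 2] = r[2, 1] = 0.92
        groups = correlated_groups(r, 0.9)
        assert [0, 1, 2] in groups and [3] in groups


class TestMtag:
    def test_singleton_group_is_identity(self, rng):
        z = rng.standard_normal((200, 1))
        zn, pn = mtag_meta(z, 0, np.eye(1))
        np.testing.assert_array_equal(zn, z[:, 0])

    def test_perfectly_correlated_identical_z_unchanged(self, rng):
        z0 = rng.standard_normal(300)
        z = np.column_stack([z0, z0])
        rho = np.ones((2, 2))
        sigma = np.ones((2, 2)) + 1e-9 * np.eye(2)
        zn, _ = mtag_meta(z, 0, rho, sigma)
        np.testing.assert_allclose(zn, z0, atol=1e-6)

    def test_matches_bruteforce_gls_on_simulated_arrays(self, rng):
        """Independent GLS oracle: per-variant weighted solve written from the
        normal equations, no shared code with the implementation."""
        n_var, t = 500, 3
        rho = np.array([[1.0, 0.95, 0.2], [0.95, 1.0, 0.25], [0.2, 0.25, 1.0]])
        sigma = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.1], [0.0, 0.1, 1.0]])
        z = rng.multivariate_normal(np.zeros(t), sigma, n_var)
        for target in range(t):
            zn, _ = mtag_meta(z, target, rho, sigma)
            # oracle: z_new = rho_t' Sigma^-1 z / sqrt(rho_t' Sigma^-1 rho_t)
            si = np.linalg.inv(sigma)
            num = z @ si @ rho[:, target]
            den = math.sqrt(rho[:, target] @ si @ sigma @ si @ rho[:, target])
            np.testing.assert_allclose(zn, num / den, rtol=1e-10)

    def test_mean_chisq_gain_at_shared_causal_variants(self, rng):
        """Two traits sharing causal variants with independent noise: the
        combined chi-square at causal variants matches the closed-form gain."""
        n_var = 4000
        causal = np.zeros(n_var, bool)
        causal[:200] = True
        mu = np.where(causal, 4.0, 0.0)
        rho_val = 0.95
        z1 = mu + rng.standard_normal(n_var)
        z2 = rho_val * mu + rng.standard_normal(n_var)
        z = np.column_stack([z1, z2])
        rho = np.array([[1.0, rho_val], [rho_val, 1.0]])
        zn, _ = mtag_meta(z, 0, rho, np.eye(2))
        # with Sigma = I, w = rho_t, z_new = (z1 + rho z2)/sqrt(1 + rho^2);
        # expected chi2 at causal = (mu(1 + rho^2))^2/(1+rho^2) + 1
        expected = (4.0 * (1 + rho_val**2)) ** 2 / (1 + rho_val**2) + 1
        observed = np.mean(zn[causal] ** 2)
        assert observed == pytest.approx(expected, rel=0.1)
        # never loses power at truly shared signals on average
        assert observed > np.mean(z1[causal] ** 2)

    def test_null_type_one_error_preserved(self, rng):
        z = rng.standard_normal((20000, 2))
        zn, pn = mtag_meta(z, 0, np.array([[1.0, 0.95], [0.95, 1.0]]), np.eye(2))
        assert np.mean(pn < 0.05) == pytest.approx(0.05, abs=0.01)

    def test_uncorrelated_groups_left_unchanged(self, rng):
        a = _ss_from_arrays(rng.standard_normal(300) * 0.05, np.full(300, 0.05), trait="a")
        b = _ss_from_arrays(rng.standard_normal(300) * 0.05, np.full(300, 0.05), trait="b")
        out = mtag_analysis([a, b], sig_threshold=1e-4)
        np.testing.assert_allclose(out[0].df["beta"], a.df["beta"])
        np.testing.assert_allclose(out[1].df["beta"], b.df["beta"])
        assert all(s.analysis == "mtag" for s in out)


class TestCojo:
    def _sim(self, rng, n=1500, m=12, ld=0.6, causal=(4,), beta=0.25):
        block = simulate_ld_genotypes(n, [BlockSpec(m, maf=0.3, ld_decay=ld)], rng)
        y = np.zeros(n)
        for c in causal:
            y += beta * block.dosages[:, c]
        y += np.random.default_rng(99).standard_normal(n)
        ss = gwas_linear(y, block, None)
        g = block.dosages
        r = np.corrcoef((g - g.mean(0)) / g.std(0), rowvar=False)
        return block, y, ss, r

    def test_zero_ld_selects_all_significant_with_marginal_betas(self, rng):
        block, y, ss, r = self._sim(rng, ld=0.0, causal=(1, 5, 9), beta=0.3)
        locus = cojo_select(ss, np.eye(12), threshold=5e-8)
        sig = ss.df[ss.df["p"] < 5e-8]
        assert set(locus.leads["variant_id"]) == set(sig["variant_id"])
        merged = locus.leads.merge(ss.df, on="variant_id")
        np.testing.assert_allclose(merged["beta_joint"], merged["beta"], rtol=1e-6)

    def test_perfect_ld_pair_selects_exactly_one(self, rng):
        n = 1500
        block = simulate_ld_genotypes(n, [BlockSpec(2, maf=0.3, ld_decay=1.0)], rng)
        y = 0.3 * block.dosages[:, 0] + np.random.default_rng(1).standard_normal(n)
        ss = gwas_linear(y, block, None)
        r = np.ones((2, 2))
        locus = cojo_select(ss, r, threshold=5e-8)
        assert len(locus.leads) == 1

    def test_conditional_p_matches_exact_regression(self, rng):
        """After selecting the top variant, remaining conditional p-values
        agree with exact two-variant multivariable regression within 10%
        (on the log10 scale)."""
        block, y, ss, r = self._sim(rng, causal=(4,), beta=0.3)
        import statsmodels.api as sm

        locus = cojo_select(ss, r, threshold=5e-8)
        lead_idx = int(np.flatnonzero(block.variant_ids == locus.leads["variant_id"].iloc[0])[0])
        z = ss.z
        r_sel = r[:, lead_idx]
        for j in range(block.n_variants):
            if j == lead_idx or abs(r_sel[j]) > 0.9:
                continue
            z_cond = (z[j] - r_sel[j] * z[lead_idx]) / math.sqrt(1 - r_sel[j] ** 2)
            x = sm.add_constant(block.dosages[:, [j, lead_idx]])
            fit = sm.OLS(y, x).fit()
            p_exact = fit.pvalues[1]
            p_approx = 2 * stats.norm.sf(abs(z_cond))
            if p_exact < 1e-30:
                continue
            assert math.log10(p_approx) == pytest.approx(math.log10(p_exact), rel=0.10, abs=0.15)

    def test_distant_variants_treated_as_unlinked(self, rng):
        """Same LD matrix, but positions > 10 Mb apart: both variants kept."""
        n = 2000
        block = simulate_ld_genotypes(n, [BlockSpec(2, maf=0.3, ld_decay=1.0)], rng)
        block.positions = np.array([1_000_000, 50_000_000])
        y = 0.3 * block.dosages[:, 0] + np.random.default_rng(2).standard_normal(n)
        ss = gwas_linear(y, block, None)
        locus = cojo_select(ss, np.ones((2, 2)), threshold=5e-8)
        assert len(locus.leads) == 2  # identical signal twice, no LD assumed


class TestSignificanceRegime:
    def test_study_wide_threshold_from_153_analyses(self):
        reg = significance_regime(153)
        assert reg.study_wide == pytest.approx(5e-8 / 153)
        assert trunc_sig(reg.study_wide) == pytest.approx(3.2e-10)
        assert round_sig(reg.study_wide) == pytest.approx(3.3e-10)

    def test_replication_threshold_from_118_loci(self):
        reg = significance_regime(153, n_discovery_loci=118)
        assert round_sig(reg.replication) == pytest.approx(8.5e-5)

    def test_single_test_returns_family_alpha(self):
        reg = significance_regime(1, n_discovery_loci=1, replication_family_alpha=0.01)
        assert reg.study_wide == 5e-8 and reg.replication == 0.01

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            significance_regime(0)


class TestReplication:
    def test_identical_stats_give_perfect_concordance(self, rng):
        ss = _ss_from_arrays(rng.standard_normal(30), np.full(30, 0.1))
        table, r, frac, p = replication_concordance(ss, ss)
        assert r == pytest.approx(1.0) and frac == 1.0 and p < 1e-6

    def test_negated_betas_give_minus_one(self, rng):
        beta = rng.standard_normal(30)
        a = _ss_from_arrays(beta, np.full(30, 0.1))
        b = _ss_from_arrays(-beta, np.full(30, 0.1))
        _, r, frac, _ = replication_concordance(a, b)
        assert r == pytest.approx(-1.0) and frac == 0.0

    def test_split_cohort_sign_agreement_at_true_loci(self):
        """75/25 split of one cohort with planted effects: lead-variant effect
        directions replicate almost always (ensemble over seeds)."""
        agree = []
        for seed in range(3):
            rng_l = np.random.default_rng(seed)
            n, m = 2000, 8
            block = simulate_ld_genotypes(n, [BlockSpec(m, maf=0.3, ld_decay=0.2)], seed)
            y = 0.25 * block.dosages[:, 2] - 0.25 * block.dosages[:, 6]
            y = y + rng_l.standard_normal(n)
            test = np.zeros(n, bool)
            test[rng_l.choice(n, n // 4, replace=False)] = True
            import dataclasses

            bd = dataclasses.replace(block, dosages=block.dosages[~test], causal_map=[])
            br = dataclasses.replace(block, dosages=block.dosages[test], causal_map=[])
            disc = gwas_linear(y[~test], bd, None)
            repl = gwas_linear(y[test], br, None)
            _, r, frac, _ = replication_concordance(disc, repl, ["1:1010000", "1:1030000"])
            agree.append(frac)
        assert np.mean(agree) > 0.95
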