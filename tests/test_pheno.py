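"""Correlation structure, PheWAS, dominance maps, inversion genotyping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from octphen.pheno import (
    call_inversion,
    correlation_structure,
    dominance_map,
    phewas_logistic,
)
from octphen.simulate import GenotypeBlock, simulate_inversion


class TestCorrelationStructure:
    def test_duplicated_embeddings_adjacent_with_unit_r(self, rng):
        x = rng.standard_normal((300, 5))
        x[:, 4] = x[:, 0]
        cs = correlation_structure(x)
        pos0 = list(cs.order).index(0)
        pos4 = list(cs.order).index(4)
        assert abs(pos0 - pos4) == 1  # clustering puts the twins side by side
        i, j = sorted([pos0, pos4])
        assert cs.direct_r[i, j] == pytest.approx(1.0)

    def test_independent_embeddings_small_offdiagonals(self, rng):
        x = rng.standard_normal((1000, 8))
        cs = correlation_structure(x)
        off = cs.direct_r[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.12  # Fisher bound at n=1000

    def test_order_is_valid_permutation_preserving_symmetry(self, rng):
        x = rng.standard_normal((200, 6))
        g = rng.uniform(-1, 1, (6, 6))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 1.0)
        cs = correlation_structure(x, genetic_r=g)
        assert sorted(cs.order) == list(range(6))
        np.testing.assert_allclose(cs.direct_r, cs.direct_r.T)
        np.testing.assert_allclose(np.diag(cs.direct_r), 1.0)
        np.testing.assert_allclose(np.diag(cs.genetic_r), 1.0)

    def test_constant_column_excluded_with_warning(self, rng):
        x = rng.standard_normal((100, 4))
        x[:, 2] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            cs = correlation_structure(x)
        assert 2 not in cs.order and cs.excluded == [2]

    def test_planted_factor_blocks_cluster_together(self, rng):
        """Two latent morphology factors: embeddings loading on the same
        factor form a block in the direct correlation matrix."""
        n = 800
        f1 = rng.standard_normal(n)
        f2 = rng.standard_normal(n)
        x = np.column_stack(
            [
                f1 + 0.3 * rng.standard_normal(n),
                f1 + 0.3 * rng.standard_normal(n),
                f2 + 0.3 * rng.standard_normal(n),
                f2 + 0.3 * rng.standard_normal(n),
            ]
        )
        cs = correlation_structure(x)
        order = list(cs.order)
        assert abs(order.index(0) - order.index(1)) == 1
        assert abs(order.index(2) - order.index(3)) == 1


def _cohort_with_codes(rng, n=2000, or_beta=0.0, predictor=None, recessive=False):
    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "age": rng.uniform(40, 70, n),
            "sex": rng.integers(0, 2, n),
            "height": rng.normal(170, 8, n),
            "weight": rng.normal(75, 10, n),
        }
    )
    if predictor is None:
        predictor = rng.standard_normal(n)
    for k, code in enumerate(["E11", "G40", "H40", "I25"]):
        x = (predictor >= 2) if recessive else predictor
        logit = -1.2 + (or_beta * np.asarray(x, float) if code == "H40" else 0.0)
        p = 1 / (1 + np.exp(-logit))
        cohort[f"{code}_status"] = rng.binomial(1, p)
        cohort[f"{code}_time"] = rng.uniform(1, 3650, n)
    return cohort, predictor


class TestPhewas:
    def test_null_predictor_no_bonferroni_hits(self, rng):
        hits = 0
        for seed in range(3):
            r = np.random.default_rng(seed)
            cohort, pred = _cohort_with_codes(r)
            res = phewas_logistic(pred, cohort)
            hits += int(res.table["significant"].sum())
        assert hits == 0

    def test_reduces_to_two_by_two_odds_ratio_without_covariates(self):
        """On a printed 2x2 table the logistic OR equals the hand-computed
        cross-product ratio."""
        # exposed cases 40, exposed controls 60; unexposed cases 20, controls 80
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [40, 60, 20, 80])
        y = np.repeat([1, 0, 1, 0], [40, 60, 20, 80])
        cohort = pd.DataFrame({"subject_id": range(200), "D01_status": y})
        res = phewas_logistic(x, cohort, min_cases=5, covariates=())
        expected_or = (40 * 80) / (60 * 20)
        assert res.table["odds_ratio"][0] == pytest.approx(expected_or, rel=1e-4)

    def test_min_cases_rule_scales_with_cohort(self, rng):
        cohort, pred = _cohort_with_codes(rng, n=1000)
        cohort["RARE_status"] = np.zeros(1000, int)
        cohort.loc[:3, "RARE_status"] = 1
        cohort["RARE_time"] = 100.0
        res = phewas_logistic(pred, cohort)
        assert "RARE" not in set(res.table["code"])
        assert res.min_cases == max(5, round(1000 * 1000 / 85000))

    def test_recessive_coding_beats_additive_for_recessive_effect(self):
        """A planted recessive disease effect yields stronger signal under
        the recessive model than the additive one, on average."""
        gains = []
        for seed in range(4):
            r = np.random.default_rng(seed + 10)
            gt = r.binomial(2, 0.45, 2500).astype(float)
            cohort, _ = _cohort_with_codes(r, n=2500, or_beta=0.8, predictor=gt, recessive=True)
            add = phewas_logistic(gt, cohort, coding="additive")
            rec = phewas_logistic(gt, cohort, coding="recessive")
            p_add = add.table.set_index("code").loc["H40", "p"]
            p_rec = rec.table.set_index("code").loc["H40", "p"]
            gains.append(np.log10(p_add) - np.log10(p_rec))
        assert np.mean(gains) > 0


class TestDominanceMap:
    @staticmethod
    def _maps(rng, gt, effect_het, effect_hom, n_px=16):
        n = gt.size
        base = rng.normal(40.0, 1.0, (n, n_px, n_px))
        bump = np.zeros((n_px, n_px))
        bump[4:12, 4:12] = 1.0
        eff = np.where(gt == 2, effect_hom, np.where(gt == 1, effect_het, 0.0))
        return base + eff[:, None, None] * bump

    def test_null_genotype_mask_nearly_empty(self, rng):
        gt = rng.binomial(2, 0.4, 400)
        maps = self._maps(rng, gt, 0.0, 0.0)
        dm = dominance_map(maps, gt, seed=1)
        assert dm.significance_mask.mean() < 0.12
        assert np.abs(dm.diff_hom).max() < 1.5

    def test_additive_effect_dominance_near_half(self, rng):
        gt = rng.binomial(2, 0.4, 600)
        maps = self._maps(rng, gt, 2.0, 4.0)  # het = hom/2
        dm = dominance_map(maps, gt, seed=2)
        assert 0.4 <= dm.dominance_index <= 0.6

    def test_recessive_effect_dominance_near_zero_and_het_flat(self, rng):
        gt = rng.binomial(2, 0.45, 800)
        maps = self._maps(rng, gt, 0.0, 5.0)
        dm = dominance_map(maps, gt, seed=3)
        assert -0.1 <= dm.dominance_index <= 0.15
        # the paracentral signal appears only in the hom-difference map
        assert np.abs(dm.diff_hom[dm.significance_mask]).mean() > 3.0
        assert np.abs(dm.diff_het[dm.significance_mask]).mean() < 1.0

    def test_shift_invariance_and_scale_equivariance(self, rng):
        gt = rng.binomial(2, 0.4, 600)
        maps = self._maps(rng, gt, 2.0, 4.0)
        d0 = dominance_map(maps, gt, seed=4).dominance_index
        d_shift = dominance_map(maps + 100.0, gt, seed=4).dominance_index
        d_scale = dominance_map(maps * 3.0, gt, seed=4).dominance_index
        assert d_shift == pytest.approx(d0, abs=1e-9)
        assert d_scale == pytest.approx(d0, abs=1e-9)

    def test_empty_class_returns_nan_with_maps(self, rng):
        gt = rng.binomial(1, 0.4, 200)  # no homozygotes
        maps = self._maps(rng, gt, 2.0, 4.0)
        with pytest.warns(UserWarning, match="class sizes"):
            dm = dominance_map(maps, gt, seed=5)
        assert np.isnan(dm.dominance_index)
        assert np.isfinite(dm.diff_het).all()


class TestCallInversion:
    def test_perfect_tags_recover_truth_exactly(self):
        inv = simulate_inversion(500, 6, 0.22, 1.0, seed=31)
        call = call_inversion(inv.tags, inv.tag_variants)
        assert np.array_equal(call.classes, inv.inversion_dosage.astype(int))
        assert call.inversion_freq == pytest.approx(
            inv.inversion_dosage.mean() / 2, abs=1e-12
        )

    def test_all_reference_cohort_degenerate_path(self):
        d = np.zeros((100, 3))
        block = GenotypeBlock(
            d, np.array([1, 2, 3]) * 1000, np.array(["17"] * 3, dtype=object)
        )
        with pytest.warns(UserWarning, match="degenerate"):
            call = call_inversion(block, [0, 1, 2])
        assert (call.classes == 0).all() and call.inversion_freq == 0.0

    def test_imperfect_tags_at_study_frequency(self):
        """r^2 = 0.9 tags, n = 2000, inversion frequency 0.22: accuracy > 0.95
        and frequency within +-0.02."""
        inv = simulate_inversion(2000, 8, 0.22, 0.9, seed=32)
        call = call_inversion(inv.tags, inv.tag_variants)
        acc = (call.classes == inv.inversion_dosage).mean()
        assert acc > 0.95
        assert abs(call.inversion_freq - 0.22) < 0.02

    def test_accuracy_monotone_in_tag_r2(self):
        accs = []
        for r2 in (0.5, 0.7, 0.9, 1.0):
            acc = []
            for seed in range(3):
                inv = simulate_inversion(1500, 6, 0.25, r2, seed=40 + seed)
                call = call_inversion(inv.tags, inv.tag_variants)
                acc.append((call.classes == inv.inversion_dosage).mean())
            accs.append(np.mean(acc))
        assert all(b >= a - 0.01 for a, b in zip(accs, accs[1:]))
        assert accs[-1] == pytest.approx(1.0)
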