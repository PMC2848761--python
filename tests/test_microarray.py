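"""Condensation, contrasts, FDR and ANOVA on the expression-array arm."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedqtl.microarray import (
    ExpressionMatrix,
    ProbeIntensityMatrix,
    TARGET_MEDIAN,
    bh_fdr,
    genotype_contrast,
    median_polish,
    median_polish_condense,
    quantile_normalize,
    stage_contrast,
    two_way_anova,
)


def _matrix(values, arrays=None, genotypes=None, stages=None):
    """Build a ProbeIntensityMatrix from a (probes x arrays) array for one
    probeset, with a minimal design."""
    values = np.asarray(values, dtype=float)
    n_probes, n_arrays = values.shape
    arrays = arrays or [f"a{i}" for i in range(n_arrays)]
    design = pd.DataFrame(
        {
            "genotype": genotypes or ["LoPro"] * n_arrays,
            "stage": stages or [1] * n_arrays,
            "replicate": range(1, n_arrays + 1),
        },
        index=pd.Index(arrays, name="array"),
    )
    index = pd.MultiIndex.from_product(
        [["ps1"], range(1, n_probes + 1)], names=["probeset", "probe"]
    )
    return ProbeIntensityMatrix(
        values=pd.DataFrame(values, index=index, columns=arrays), design=design
    )


class TestQuantileNormalize:
    def test_identical_arrays_are_a_fixed_point(self):
        m = _matrix(np.tile([[1.0], [5.0], [9.0]], (1, 4)))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_two_array_rank_mean_example(self):
        m = _matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_sorted_vectors_identical_after_normalization(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.lognormal(size=(50, 6)))
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for a in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, a]), ref)

    def test_single_array_is_an_error(self):
        with pytest.raises(ValueError, match="2 arrays"):
            quantile_normalize(_matrix([[1.0], [2.0]]))


class TestMedianPolish:
    def test_constant_matrix(self):
        overall, row, col, resid = median_polish(np.full((5, 4), 7.0))
        assert overall == pytest.approx(7.0)
        np.testing.assert_allclose(row, 0.0)
        np.testing.assert_allclose(col, 0.0)
        np.testing.assert_allclose(resid, 0.0)

    def test_exactly_additive_matrix_recovers_column_effects(self):
        rng = np.random.default_rng(5)
        row = rng.normal(size=11)
        col = rng.normal(size=6)
        row -= np.median(row)
        col -= np.median(col)
        x = 8.0 + row[:, None] + col[None, :]
        overall, r, c, resid = median_polish(x)
        np.testing.assert_allclose(overall + c, 8.0 + col, atol=1e-9)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_condense_constant_probeset(self):
        m = _matrix(np.full((11, 4), 64.0))
        expr = median_polish_condense(m)
        # one probeset: every value equals the rescaled constant, median 10000
        np.testing.assert_allclose(expr.values.to_numpy(), TARGET_MEDIAN)

    def test_global_median_is_ten_thousand(self, small_experiment):
        expr = median_polish_condense(
            quantile_normalize(small_experiment.probe_intensities)
        )
        assert np.median(expr.values.to_numpy()) == pytest.approx(TARGET_MEDIAN)
        assert (expr.values.to_numpy() > 0).all()

    def test_nonpositive_intensity_is_an_error(self):
        m = _matrix(np.full((3, 4), 2.0))
        m.values.iloc[0, 0] = 2.0  # keep constructor happy
        bad = m.values.copy()
        bad.iloc[0, 0] = -1.0
        m2 = ProbeIntensityMatrix.__new__(ProbeIntensityMatrix)
        m2.values, m2.design = bad, m.design
        with pytest.raises(ValueError):
            median_polish_condense(m2)


def _expr_from_log2(log2_values, design):
    lin = np.power(2.0, np.asarray(log2_values, dtype=float))
    values = pd.DataFrame(
        lin,
        index=pd.Index([f"ps{i}" for i in range(len(lin))], name="probeset"),
        columns=design.index,
    )
    return ExpressionMatrix(values=values, design=design)


def _design(genotypes, stages):
    n = len(genotypes)
    return pd.DataFrame(
        {"genotype": genotypes, "stage": stages, "replicate": range(n)},
        index=pd.Index([f"a{i}" for i in range(n)], name="array"),
    )


class TestGenotypeContrast:
    def test_identical_groups_ratio_one_not_significant(self):
        design = _design(["LoPro"] * 3 + ["HiPro"] * 3, [1] * 6)
        expr = _expr_from_log2([[5, 6, 7, 5, 6, 7]], design)
        res = genotype_contrast(expr)
        assert res.loc[0, "ratio"] == pytest.approx(1.0)
        assert not res.loc[0, "significant"]

    def test_t_statistic_matches_textbook_pooled_formula(self):
        design = _design(["LoPro"] * 3 + ["HiPro"] * 3, [1] * 6)
        expr = _expr_from_log2([[1, 2, 3, 4, 5, 6]], design)
        res = genotype_contrast(expr)
        # pooled variance of (1,2,3) vs (4,5,6): sp2 = 1, se = sqrt(2/3)
        t = (2.0 - 5.0) / np.sqrt(2.0 / 3.0)
        p_expected = 2 * stats.t.sf(abs(t), df=4)
        assert res.loc[0, "p"] == pytest.approx(p_expected)

    def test_ratio_is_invariant_to_global_rescale(self):
        design = _design(["LoPro"] * 3 + ["HiPro"] * 3, [1] * 6)
        expr = _expr_from_log2([[5, 5.2, 4.9, 3.1, 3.0, 2.8]], design)
        scaled = ExpressionMatrix(values=expr.values * 37.0, design=design)
        r1 = genotype_contrast(expr).loc[0, "ratio"]
        r2 = genotype_contrast(scaled).loc[0, "ratio"]
        assert r1 == pytest.approx(r2)

    def test_injected_genotype_fold_recovered(self, small_experiment):
        """All truth-DE probesets pass the 1.5-fold / 5% FDR screen."""
        from seedqtl import simulate_microarray

        cfg = small_experiment.config
        _, coords, _, _ = simulate_microarray(
            cfg, small_experiment.annotation, cfg.region,
            truth_de=small_experiment.truth_de,
        )
        ps2gene = dict(zip(coords["feature"], coords["gene"]))
        truth_ps = {
            p for p, g in ps2gene.items() if g in set(small_experiment.truth_de["gene"])
        }
        expr = median_polish_condense(
            quantile_normalize(small_experiment.probe_intensities)
        )
        res = genotype_contrast(expr)
        sig = set(res.loc[res["significant"], "probeset"])
        assert truth_ps <= sig

    def test_missing_genotype_is_an_error(self):
        design = _design(["LoPro"] * 4, [1] * 4)
        expr = _expr_from_log2([[1, 2, 3, 4]], design)
        with pytest.raises(ValueError):
            genotype_contrast(expr)


class TestStageContrast:
    def test_same_stage_gives_unit_ratios(self):
        design = _design(["LoPro"] * 6, [1, 1, 1, 2, 2, 2])
        expr = _expr_from_log2([[4, 5, 6, 7, 8, 9]], design)
        res = stage_contrast(expr, "LoPro", 1, 1)
        assert res.loc[0, "ratio"] == pytest.approx(1.0)
        assert not res["significant"].any()

    def test_stage_fold_direction(self):
        design = _design(["LoPro"] * 6, [1, 1, 1, 4, 4, 4])
        expr = _expr_from_log2([[3, 3, 3, 5, 5, 5]], design)
        res = stage_contrast(expr, "LoPro", 4, 1)
        assert res.loc[0, "ratio"] == pytest.approx(4.0)


class TestBhFdr:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_empty_input(self):
        assert len(bh_fdr([])) == 0

    def test_monotone_in_sorted_p_order(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestTwoWayAnova:
    def _design_2x4x3(self):
        genos, stages = [], []
        for g in ("LoPro", "HiPro"):
            for s in (1, 2, 3, 4):
                genos += [g] * 3
                stages += [s] * 3
        return _design(genos, stages)

    def test_pure_noise_genotype_p_roughly_uniform(self):
        rng = np.random.default_rng(2)
        design = self._design_2x4x3()
        expr = _expr_from_log2(rng.normal(8, 1, size=(2000, 24)), design)
        res = two_way_anova(expr)
        frac = (res["p_genotype"] < 0.05).mean()
        assert 0.03 < frac < 0.07

    def test_genotype_shift_dominates_stage(self):
        design = self._design_2x4x3()
        rng = np.random.default_rng(4)
        base = rng.normal(8, 0.1, size=(50, 24))
        base[:, design["genotype"].to_numpy() == "HiPro"] += 2.0
        res = two_way_anova(_expr_from_log2(base, design))
        assert (res["p_genotype"] < res["p_stage"]).all()

    def test_all_constant_probeset_gets_p_one(self):
        design = self._design_2x4x3()
        res = two_way_anova(_expr_from_log2(np.full((1, 24), 6.0), design))
        assert res.loc[0, "p_genotype"] == 1.0

    def test_unbalanced_design_is_an_error(self):
        design = self._design_2x4x3().iloc[:-1]
        expr = _expr_from_log2(np.random.default_rng(0).normal(size=(3, 23)), design)
        with pytest.raises(ValueError, match="nbalanced"):
            two_way_anova(expr)

    def test_matches_statsmodels_anova_lm(self):
        """Cross-check the direct sums-of-squares against an OLS fit."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        design = self._design_2x4x3()
        rng = np.random.default_rng(9)
        x = rng.normal(8, 1, size=(5, 24))
        res = two_way_anova(_expr_from_log2(x, design))
        for i in range(5):
            df = design.copy()
            df["y"] = x[i]
            fit = ols("y ~ C(genotype) * C(stage)", data=df).fit()
            tab = sm.stats.anova_lm(fit, typ=2)
            assert res.loc[i, "p_genotype"] == pytest.approx(
                tab.loc["C(genotype)", "PR(>F)"]
            )
            assert res.loc[i, "p_stage"] == pytest.approx(
                tab.loc["C(stage)", "PR(>F)"]
            )
            assert res.loc[i, "p_interaction"] == pytest.approx(
                tab.loc["C(genotype):C(stage)", "PR(>F)"]
            )
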