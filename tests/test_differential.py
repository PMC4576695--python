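"""Differential testing: normalization factors, dispersion shrinkage, Wald."""

import warnings

import numpy as np
import pandas as pd
import pytest

from fourc.decay import fit_decay
from fourc.differential import (call_differential, estimate_dispersions,
                                nb_wald_test, normalization_factors)
from fourc.vst import VSTParams, vst


def _nb(rng, mu, alpha, size=None):
    r = 1.0 / np.maximum(alpha, 1e-12)
    return rng.negative_binomial(r, r / (r + mu), size=size)


def _constant_fit(levels, d):
    """DecayFit whose per-sample curves are flat at the given v-levels."""
    v = pd.DataFrame({s: np.full(len(d), lvl) for s, lvl in levels.items()})
    return fit_decay(v, d, mode="symmetric")


@pytest.fixture(scope="module")
def flat_params():
    return VSTParams(a=0.0, b=0.05, size_factors=np.array([1.0, 1.0]))


class TestNormalizationFactors:
    def test_identical_fits_give_unit_factors(self, flat_params):
        d = pd.Series(np.geomspace(1e3, 1e6, 80))
        fit = _constant_fit({"s1": 6.0, "s2": 6.0}, d)
        n = normalization_factors(fit, d, flat_params)
        assert np.allclose(n.to_numpy(), 1.0, atol=1e-9)

    def test_back_transformed_ratio(self, flat_params):
        # per-sample flat curves back-transforming to counts 2 and 8 must
        # yield factors (0.5, 2.0) at every fragment
        d = pd.Series(np.geomspace(1e3, 1e6, 80))
        levels = {
            "s1": float(vst(2.0, flat_params, j=0)),
            "s2": float(vst(8.0, flat_params, j=1)),
        }
        fit = _constant_fit(levels, d)
        n = normalization_factors(fit, d, flat_params)
        assert np.allclose(n["s1"], 0.5, atol=1e-6)
        assert np.allclose(n["s2"], 2.0, atol=1e-6)

    def test_unit_geometric_mean_per_fragment(self, null_analysis, null_dataset):
        res = null_analysis
        n = normalization_factors(
            res.fit, res.distances.loc[res.tested], res.vst_params, index=res.tested
        )
        log_geo = np.log(n.to_numpy()).mean(axis=1)
        assert np.max(np.abs(log_geo)) < 1e-8

    def test_common_rescaling_cancels_exactly(self, flat_params):
        # the geometric-mean renormalization makes the absolute scale of the
        # back-transformed curve irrelevant
        d = pd.Series(np.geomspace(1e3, 1e6, 60))
        fit = _constant_fit({"s1": 5.0, "s2": 7.0}, d)
        n = normalization_factors(fit, d, flat_params)
        u = np.column_stack([
            np.asarray([2.0] * len(d)), np.asarray([8.0] * len(d))
        ])
        scaled = 7.3 * u
        renorm = lambda m: m / np.exp(np.log(m).mean(axis=1, keepdims=True))
        assert np.allclose(renorm(u), renorm(scaled))


@pytest.fixture(scope="module")
def balanced_design():
    samples = [f"{c}_{r}" for c in "AB" for r in (1, 2, 3)]
    cond = pd.Series([s[0] for s in samples], index=samples)
    return samples, cond


class TestDispersions:
    def test_recovery_of_constant_dispersion(self, balanced_design):
        samples, cond = balanced_design
        rng = np.random.default_rng(31)
        mu = np.exp(rng.uniform(np.log(50), np.log(5000), 1500))
        k = pd.DataFrame(_nb(rng, mu[:, None], 0.05, (1500, 6)), columns=samples)
        n = pd.DataFrame(1.0, index=k.index, columns=samples)
        disp = estimate_dispersions(k, n, cond)
        assert np.median(disp.final) == pytest.approx(0.05, rel=0.30)

    def test_shrinkage_toward_trend(self, balanced_design):
        samples, cond = balanced_design
        rng = np.random.default_rng(32)
        mu = np.exp(rng.uniform(np.log(50), np.log(5000), 800))
        k = pd.DataFrame(_nb(rng, mu[:, None], 0.05, (800, 6)), columns=samples)
        n = pd.DataFrame(1.0, index=k.index, columns=samples)
        disp = estimate_dispersions(k, n, cond)
        gap = np.abs(np.log(disp.mle) - np.log(disp.trend))
        outliers = gap > 1.0
        assert outliers.any()
        shrunk = np.abs(np.log(disp.final) - np.log(disp.trend))
        assert (shrunk[outliers] < gap[outliers]).all()

    def test_poisson_data_near_floor(self, balanced_design):
        samples, cond = balanced_design
        rng = np.random.default_rng(33)
        mu = np.exp(rng.uniform(np.log(50), np.log(5000), 800))
        k = pd.DataFrame(rng.poisson(mu[:, None], (800, 6)), columns=samples)
        n = pd.DataFrame(1.0, index=k.index, columns=samples)
        disp = estimate_dispersions(k, n, cond)
        # six replicates cannot resolve dispersion below their sampling
        # noise (~1e-4); "near the floor" means orders of magnitude below
        # any biologically meaningful overdispersion
        assert np.median(disp.final) < 1e-3


class TestWald:
    def test_identical_conditions_are_perfect_null(self, balanced_design):
        samples, cond = balanced_design
        rng = np.random.default_rng(34)
        half = rng.poisson(200, size=(300, 3))
        k = pd.DataFrame(np.hstack([half, half]), columns=samples)
        n = pd.DataFrame(1.0, index=k.index, columns=samples)
        res = nb_wald_test(k, n, cond, ("B", "A"))
        assert np.allclose(res.table["log2FoldChange"], 0.0, atol=1e-9)
        assert np.allclose(res.table["pvalue"].dropna(), 1.0, atol=1e-9)

    def test_label_swap_negates_lfc_and_keeps_p(self, balanced_design):
        samples, cond = balanced_design
        rng = np.random.default_rng(35)
        k = pd.DataFrame(rng.poisson(150, size=(200, 6)), columns=samples)
        n = pd.DataFrame(1.0, index=k.index, columns=samples)
        disp = estimate_dispersions(k, n, cond)
        fwd = nb_wald_test(k, n, cond, ("B", "A"), dispersions=disp).table
        rev = nb_wald_test(k, n, cond, ("A", "B"), dispersions=disp).table
        assert np.allclose(fwd["log2FoldChange"], -rev["log2FoldChange"], atol=1e-8)
        ok = fwd["pvalue"].notna()
        assert np.allclose(fwd.loc[ok, "pvalue"], rev.loc[ok, "pvalue"], atol=1e-10)

    def test_agrees_with_statsmodels_glm(self, balanced_design):
        """Independent cross-check of coefficients and Fisher-information SEs."""
        import statsmodels.api as sm

        samples, cond = balanced_design
        rng = np.random.default_rng(36)
        mu = np.array([120.0, 400.0, 90.0, 1000.0, 250.0])
        k = pd.DataFrame(_nb(rng, mu[:, None], 0.08, (5, 6)), columns=samples)
        n = pd.DataFrame(rng.uniform(0.5, 2.0, size=(5, 6)), columns=samples)
        n = n.div(np.exp(np.log(n).mean(axis=1)), axis=0)
        alpha = pd.Series(0.08, index=k.index)

        class _D:
            final = alpha

        res = nb_wald_test(k, n, cond, ("B", "A"), dispersions=_D()).table
        X = np.column_stack([np.ones(6), (cond == "B").astype(float)])
        for i in k.index:
            glm = sm.GLM(
                k.loc[i].to_numpy(),
                X,
                family=sm.families.NegativeBinomial(alpha=0.08),
                offset=np.log(n.loc[i].to_numpy()),
            ).fit()
            assert res.loc[i, "log2FoldChange"] == pytest.approx(
                glm.params[1] / np.log(2), rel=1e-4, abs=1e-6
            )
            assert res.loc[i, "lfcSE"] == pytest.approx(
                glm.bse[1] / np.log(2), rel=1e-3
            )

    def test_planted_fold_change_recovered(self, balanced_design):
        samples, cond = balanced_design
        rng = np.random.default_rng(37)
        mu = np.exp(rng.uniform(np.log(80), np.log(3000), 1000))
        effect = np.zeros(1000)
        changed = rng.choice(1000, 50, replace=False)
        effect[changed] = 2.0  # 4-fold
        mu_mat = mu[:, None] * np.exp2(
            effect[:, None] * (np.arange(6) >= 3)[None, :]
        )
        k = pd.DataFrame(_nb(rng, mu_mat, 0.05), columns=samples)
        n = pd.DataFrame(1.0, index=k.index, columns=samples)
        res = nb_wald_test(k, n, cond, ("B", "A"))
        lfc = res.table.loc[changed, "log2FoldChange"]
        assert lfc.mean() == pytest.approx(2.0, abs=0.2)

    def test_missing_contrast_level_errors(self, balanced_design):
        samples, cond = balanced_design
        k = pd.DataFrame(np.ones((30, 6)), columns=samples)
        n = pd.DataFrame(1.0, index=k.index, columns=samples)
        with pytest.raises(ValueError, match="not present"):
            nb_wald_test(k, n, cond, ("C", "A"))


class TestDifferentialCalls:
    def test_threshold_flags(self):
        tab = pd.DataFrame(
            {"padj": [0.005, 0.02, 0.5], "log2FoldChange": [1, 1, 1]},
            index=[0, 1, 2],
        )

        class _R:
            table = tab

        flags = call_differential(_R(), padj_thresh=0.01)
        assert flags["differential"].tolist() == [True, False, False]

    def test_cross_reference_with_interaction_calls(self):
        tab = pd.DataFrame(
            {"padj": [0.001, 0.001, 0.9], "log2FoldChange": [1, -1, 0]},
            index=[0, 1, 2],
        )

        class _R:
            table = tab

        calls = pd.DataFrame({"c1": [True, False, True]}, index=[0, 1, 2])
        flags = call_differential(_R(), padj_thresh=0.01, interaction_calls=calls)
        assert flags.loc[0, "label"] == "interaction+differential"
        assert flags.loc[1, "label"] == "differential"
        assert flags.loc[2, "label"] == ""

    def test_empty_results(self):
        class _R:
            table = pd.DataFrame({"padj": [], "log2FoldChange": []})

        flags = call_differential(_R())
        assert flags.empty or not flags["differential"].any()
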