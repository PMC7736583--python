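"""GRS, logistic fits, nested comparisons, association scans, LD."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from sccadmix.errors import DegenerateInputError, InvalidArgumentError
from sccadmix.pigment import predict_skin_probabilities
from sccadmix.riskmodels import (
    attenuation,
    compute_grs,
    conditional_association,
    fit_logistic,
    fit_model_sequence,
    ld_stats,
    likelihood_ratio_test,
    per_snp_association,
    site_stratum_mask,
    variance_explained,
)

from conftest import make_genotypes


def brute_force_logistic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct likelihood maximisation, independent of the IRLS route."""
    xc = np.column_stack([np.ones(len(y)), x])

    def nll(b):
        eta = xc @ b
        return np.sum(np.logaddexp(0.0, eta)) - y @ eta

    res = minimize(nll, np.zeros(xc.shape[1]), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 500})
    return res.x


class TestGRS:
    def test_zero_dosages_score_zero(self, small_study):
        design, _ = small_study
        g = make_genotypes(np.zeros((5, 16)), prefix="risk")
        g.variants["variant_id"] = design.snp_panel.risk_variant_ids
        grs = compute_grs(g, design.snp_panel, maf_min=0.0)
        assert np.allclose(grs.values, 0.0)

    def test_two_rare_risk_variants_excluded_leaving_14(self, admixed_study):
        design, s = admixed_study
        grs = compute_grs(s.genotypes, design.snp_panel)
        assert len(grs.variants_used) == 14
        assert not {"risk01", "risk02"} & set(grs.variants_used)

    def test_score_equals_dot_product_oracle(self, small_study, rng):
        design, s = small_study
        grs = compute_grs(s.genotypes, design.snp_panel)
        sub = design.snp_panel.table.set_index("variant_id").loc[grs.variants_used]
        dos = s.genotypes.effect_dosages(
            grs.variants_used, sub["effect_allele"].tolist()
        )
        oracle = np.array([row @ sub["weight"].to_numpy() for row in dos])
        # agreement to float summation-order precision
        assert np.allclose(grs.values, oracle, rtol=0.0, atol=1e-12)

    def test_unit_weights_give_integer_allele_counts(self, small_study):
        design, s = small_study
        grs = compute_grs(s.genotypes, design.snp_panel, weighted=False)
        assert np.array_equal(grs.values, np.round(grs.values))

    def test_constant_weights_scale_unweighted_score(self, small_study):
        design, s = small_study
        panel = design.snp_panel
        scaled = panel.table.copy()
        scaled.loc[scaled["role"] == "risk", "weight"] = 0.37
        from sccadmix.data import SNPPanel

        w = compute_grs(s.genotypes, SNPPanel(table=scaled), weighted=True)
        u = compute_grs(s.genotypes, panel, weighted=False)
        assert np.allclose(w.values, 0.37 * u.values, atol=1e-12)

    def test_cohort_concatenation_linearity(self, small_study):
        design, s = small_study
        g = s.genotypes
        half = g.n_samples // 2
        from sccadmix.data import GenotypeData

        g1 = GenotypeData(g.samples[:half], g.variants, g.dosages[:half])
        g2 = GenotypeData(g.samples[half:], g.variants, g.dosages[half:])
        # fix the scored variant set (filter off) so per-cohort MAF noise
        # cannot change which variants contribute
        full = compute_grs(g, design.snp_panel, maf_min=0.0)
        a = compute_grs(g1, design.snp_panel, maf_min=0.0)
        b = compute_grs(g2, design.snp_panel, maf_min=0.0)
        assert a.variants_used == b.variants_used == full.variants_used
        assert np.allclose(
            np.concatenate([a.values, b.values]), full.values, rtol=0.0, atol=1e-12
        )


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        fit = fit_logistic(pd.DataFrame(index=range(100)), y)
        assert fit.coef("const") == pytest.approx(np.log(1 / 3), abs=1e-6)

    def test_two_by_two_table_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 70 + [1.0] * 10 + [0.0] * 90)
        x = pd.DataFrame({"exposed": [1.0] * 100 + [0.0] * 100})
        fit = fit_logistic(x, y)
        assert fit.coef("exposed") == pytest.approx(
            np.log(30 * 90 / (70 * 10)), abs=1e-6
        )

    def test_matches_brute_force_maximiser(self, rng):
        for _ in range(5):
            x = rng.normal(size=(200, 3))
            lin = 0.2 + x @ np.array([0.5, -0.7, 0.3])
            y = (rng.random(200) < 1 / (1 + np.exp(-lin))).astype(float)
            fit = fit_logistic(pd.DataFrame(x, columns=["a", "b", "c"]), y)
            oracle = brute_force_logistic(x, y)
            assert np.abs(fit.params - oracle).max() < 1e-5

    def test_rank_deficiency_names_collinear_columns(self, rng):
        x = rng.normal(size=(50, 2))
        df = pd.DataFrame({"a": x[:, 0], "b": x[:, 1], "twice_a": 2 * x[:, 0]})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(InvalidArgumentError, match="twice_a|a"):
            fit_logistic(df, y)

    def test_perfect_separation_flagged_not_silent(self):
        x = pd.DataFrame({"x": np.arange(20.0)})
        y = (np.arange(20) >= 10).astype(float)
        fit = fit_logistic(x, y)
        assert not fit.converged
        assert fit.message != ""

    def test_covariate_rescaling_rescales_slope_inversely(self, rng):
        x = rng.normal(size=(300, 1))
        y = (rng.random(300) < 1 / (1 + np.exp(-x[:, 0]))).astype(float)
        f1 = fit_logistic(pd.DataFrame({"x": x[:, 0]}), y)
        f2 = fit_logistic(pd.DataFrame({"x": 10.0 * x[:, 0]}), y)
        assert f2.coef("x") == pytest.approx(f1.coef("x") / 10.0, rel=1e-6)

    def test_column_reordering_invariance(self, rng):
        x = rng.normal(size=(150, 2))
        y = (rng.random(150) < 0.4).astype(float)
        f1 = fit_logistic(pd.DataFrame({"a": x[:, 0], "b": x[:, 1]}), y)
        f2 = fit_logistic(pd.DataFrame({"b": x[:, 1], "a": x[:, 0]}), y)
        assert f1.coef("a") == pytest.approx(f2.coef("a"), abs=1e-10)
        assert f1.llf == pytest.approx(f2.llf, abs=1e-10)


class TestLikelihoodRatio:
    def test_identical_models_give_zero_statistic(self, rng):
        x = pd.DataFrame({"x": rng.normal(size=100)})
        y = (rng.random(100) < 0.5).astype(float)
        fit = fit_logistic(x, y)
        cmp_ = likelihood_ratio_test(fit, fit)
        assert cmp_.lr_statistic == 0.0
        assert cmp_.p_value == 1.0

    def test_statistic_matches_deviance_oracle(self, rng):
        x = rng.normal(size=(200, 2))
        y = (rng.random(200) < 1 / (1 + np.exp(-x[:, 0]))).astype(float)
        nested = fit_logistic(pd.DataFrame({"a": x[:, 0]}), y)
        full = fit_logistic(pd.DataFrame({"a": x[:, 0], "b": x[:, 1]}), y)
        cmp_ = likelihood_ratio_test(nested, full)

        def ll(xcols):
            b = brute_force_logistic(xcols, y)
            eta = np.column_stack([np.ones(200), xcols]) @ b
            return y @ eta - np.sum(np.logaddexp(0.0, eta))

        oracle = 2.0 * (ll(x) - ll(x[:, :1]))
        assert cmp_.lr_statistic == pytest.approx(oracle, abs=1e-6)

    def test_non_nested_models_rejected(self, rng):
        x = rng.normal(size=(100, 2))
        y = (rng.random(100) < 0.5).astype(float)
        f1 = fit_logistic(pd.DataFrame({"a": x[:, 0]}), y)
        f2 = fit_logistic(pd.DataFrame({"b": x[:, 1]}), y)
        with pytest.raises(InvalidArgumentError):
            likelihood_ratio_test(f1, f2)


class TestVarianceExplained:
    def test_pure_noise_block_adds_nothing(self, rng):
        n = 10_000
        y = (rng.random(n) < 0.3).astype(float)
        baseline = pd.DataFrame({"age": rng.normal(60, 10, n)})
        noise = pd.DataFrame({"z": rng.normal(size=n)})
        table = variance_explained(y, baseline, {"noise": noise})
        assert abs(table.increment("noise")) < 0.5

    def test_ancestry_block_r2_larger_in_admixed_than_cline_cohort(self):
        from sccadmix.ancestry import compute_pcs
        from sccadmix.simulate import default_study, simulate_study, with_effects

        increments = {}
        for kind, b_anc in [("admixed", 2.0), ("cline", 0.3)]:
            design = with_effects(
                default_study(kind, 2000, seed=47), ancestry=b_anc
            )
            s = simulate_study(design)
            n_pcs = 6 if kind == "admixed" else 10
            pcs = compute_pcs(s.genotypes, n_components=n_pcs)
            p = s.phenotypes
            baseline = pd.DataFrame(
                {"age": p["age"].astype(float), "sex": p["sex"].astype(float)}
            )
            blocks = {
                "ancestry": pd.DataFrame(
                    {f"PC{i + 1}": pcs.scores[:, i] for i in range(n_pcs)}
                )
            }
            table = variance_explained(p["cscc"].to_numpy(float), baseline, blocks)
            increments[kind] = table.increment("ancestry")
        assert increments["admixed"] > increments["cline"]

    def test_increments_telescope_exactly(self, rng):
        import statsmodels.api as sm

        n = 500
        y = (rng.random(n) < 0.3).astype(float)
        baseline = pd.DataFrame({"age": rng.normal(size=n)})
        blocks = {
            "b1": pd.DataFrame({"u": rng.normal(size=n)}),
            "b2": pd.DataFrame({"v": rng.normal(size=n), "w": rng.normal(size=n)}),
        }
        table = variance_explained(y, baseline, blocks)
        full = pd.concat([baseline] + list(blocks.values()), axis=1)
        total = sm.OLS(y, sm.add_constant(full.to_numpy())).fit().rsquared_adj
        base = sm.OLS(y, sm.add_constant(baseline.to_numpy())).fit().rsquared_adj
        assert table.table["adj_r2_increment_pct"].sum() == pytest.approx(
            100 * (total - base), abs=1e-9
        )


class TestAssociationScans:
    def _cohort(self, rng, n=600, m=8, effect_idx=0, beta=0.8):
        freqs = rng.uniform(0.2, 0.5, size=m)
        dos = rng.binomial(2, freqs, size=(n, m)).astype(float)
        lin = -1.5 + beta * dos[:, effect_idx]
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
        return make_genotypes(dos), y

    def test_bonferroni_threshold_uses_tested_count(self, rng):
        g, y = self._cohort(rng, m=30)
        res = per_snp_association(g, y, alpha_family=0.05)
        assert res.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 30)
        assert res.attrs["bonferroni_threshold"] == pytest.approx(0.0016667, abs=1e-7)

    def test_monomorphic_variants_skipped_with_warning(self, rng):
        g, y = self._cohort(rng, m=3)
        g.dosages[:, 1] = 0.0
        with pytest.warns(UserWarning, match="monomorphic"):
            res = per_snp_association(g, y)
        assert res.attrs["n_tested"] == 2

    def test_effect_direction_recovered(self, rng):
        hits = 0
        for _ in range(40):
            g, y = self._cohort(rng, n=400, beta=0.7)
            res = per_snp_association(g, y)
            hits += res.loc[res["variant_id"] == "v1", "beta"].iloc[0] > 0
        assert hits >= 38  # >= 95% of replicates

    def test_no_conditioning_reduces_to_marginal_scan(self, rng):
        g, y = self._cohort(rng)
        a = per_snp_association(g, y)
        b = conditional_association(g, y, None, [])
        pd.testing.assert_frame_equal(
            a.drop(columns="fully_conditioned"), b.drop(columns="fully_conditioned")
        )

    def test_identical_conditioning_variant_fully_conditioned(self, rng):
        g, y = self._cohort(rng)
        res = conditional_association(g, y, None, ["v1"], variant_ids=["v1", "v2"])
        row = res.set_index("variant_id").loc["v1"]
        assert row["fully_conditioned"]
        assert row["p"] == 1.0

    def test_perfect_ld_proxy_loses_signal_when_conditioned(self, rng):
        nonsig = 0
        for _ in range(20):
            g, y = self._cohort(rng, n=500, beta=0.8)
            # v9 is a near-perfect proxy of the causal v1 (a few discordances)
            proxy = g.dosages[:, 0].copy()
            flip = rng.choice(len(proxy), size=5, replace=False)
            proxy[flip] = rng.integers(0, 3, size=5)
            g2 = make_genotypes(np.column_stack([g.dosages, proxy]))
            res = conditional_association(g2, y, None, ["v1"], variant_ids=["v9"])
            nonsig += (not res["converged"].iloc[0]) or res["p"].iloc[0] > 0.05
        assert nonsig >= 19

    def test_independent_variant_effect_survives_conditioning(self, rng):
        g, y = self._cohort(rng, n=2000, beta=0.6, effect_idx=2)
        res = conditional_association(g, y, None, ["v5", "v6"], variant_ids=["v3"])
        row = res.iloc[0]
        assert abs(row["beta"] - 0.6) < 3 * row["se"]


class TestLD:
    def test_duplicated_variant_in_perfect_ld(self, rng):
        h = rng.integers(0, 2, size=200)
        res = ld_stats(h, h)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.d_prime == pytest.approx(1.0, abs=1e-12)

    def test_hand_built_haplotype_counts(self):
        a = np.repeat([1, 1, 0, 0], [40, 10, 10, 40])
        b = np.repeat([1, 0, 1, 0], [40, 10, 10, 40])
        res = ld_stats(a, b)
        assert res.d == pytest.approx(0.15, abs=1e-12)
        assert res.r2 == pytest.approx(0.36, abs=1e-12)
        assert res.d_prime == pytest.approx(0.6, abs=1e-12)

    def test_independent_variants_have_negligible_r2(self, rng):
        a = rng.integers(0, 2, size=10_000)
        b = rng.permutation(a)
        assert ld_stats(a, b).r2 < 0.01

    def test_monomorphic_input_undefined(self, rng):
        with pytest.raises(DegenerateInputError):
            ld_stats(np.ones(50), rng.integers(0, 2, size=50))


class TestModelSequence:
    def test_site_stratum_mask_excludes_both_site_cases(self, small_study):
        _, s = small_study
        p = s.phenotypes
        mask = site_stratum_mask(p, "sun_exposed")
        sel = p.loc[mask]
        assert (sel.loc[sel["cscc"] == 1, "site_class"] == "sun_exposed").all()
        assert (p["cscc"] == 0).sum() == (sel["cscc"] == 0).sum()

    def test_sequence_nests_and_attenuates(self, admixed_study):
        design, s = admixed_study
        from sccadmix.ancestry import compute_pcs
        from sccadmix.pigment import filter_polymorphic

        pcs = compute_pcs(s.genotypes, n_components=6)
        kept = filter_polymorphic(list(design.pigment_model.variant_ids), s.genotypes)
        probs = predict_skin_probabilities(
            s.genotypes, design.pigment_model.subset(kept)
        )
        grs = compute_grs(s.genotypes, design.snp_panel)
        fits = fit_model_sequence(s.phenotypes, pcs, probs, grs, group="admixed")
        assert [len(f.names) for f in fits.values()] == sorted(
            len(f.names) for f in fits.values()
        )
        assert all(f.converged for f in fits.values())
        # under the default (partly mediated) settings the ancestry term shrinks
        assert attenuation(fits["model1"], fits["model2"]) > 0.0
        cmp_ = likelihood_ratio_test(fits["model1"], fits["model4"])
        assert cmp_.df == 4
        assert cmp_.p_value < 0.05
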