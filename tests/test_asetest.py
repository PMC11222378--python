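"""Design encoding, allelic model fitting, classification rules."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from allelescope import asetest, glm


def simulate_allelic_counts(rng, design, log2fc_po=0.0, log2fc_ag=0.0,
                            mean=100.0, dispersion=0.1, n_features=1,
                            libsize=None):
    """NB allelic counts under the PO/AG model for a given design."""
    X = design[asetest.EFFECT_COLUMNS].to_numpy()
    beta = np.zeros(5)
    beta[1] = log2fc_po * np.log(2)
    beta[2] = log2fc_ag * np.log(2)
    eta = X @ beta
    mu = mean / 2 * np.exp(eta - eta.mean())
    r = 1 / dispersion
    return rng.negative_binomial(r, r / (r + mu), size=(n_features, len(X)))


def counts_to_frames(Y, design, features):
    """Split observation-matrix counts back into maternal/paternal tables."""
    mat, pat = {}, {}
    for j, (_, r) in enumerate(design.iterrows()):
        (mat if r["origin"] == "maternal" else pat)[r["sample_id"]] = Y[:, j]
    return (pd.DataFrame(mat, index=features), pd.DataFrame(pat, index=features))


class TestDesign:
    def test_balanced_reciprocal_full_rank(self, reciprocal_samples):
        design = asetest.build_design(reciprocal_samples)
        assert len(design) == 24
        X = design[["intercept", "po", "ag"]].to_numpy()
        assert np.linalg.matrix_rank(X) == 3

    def test_single_direction_collinear(self, reciprocal_samples):
        one = reciprocal_samples[reciprocal_samples["cross_direction"] == "DxL"]
        with pytest.raises(ValueError, match="collinear"):
            asetest.build_design(one)
        design = asetest.build_design(one, require_both_directions=False)
        X = design[["intercept", "po", "ag"]].to_numpy()
        assert np.linalg.matrix_rank(X) == 2

    def test_breed_consistent_with_origin(self, reciprocal_samples):
        design = asetest.build_design(reciprocal_samples)
        for _, r in design.iterrows():
            mb = asetest.maternal_breed(r["sample_id"][:3])
            if r["origin"] == "maternal":
                assert r["breed"] == mb
            else:
                assert r["breed"] != mb

    def test_encoding_invariants(self, reciprocal_samples):
        design = asetest.build_design(reciprocal_samples)
        # per sample: one maternal and one paternal observation, exactly one
        # of which carries the Duroc allele
        for _, grp in design.groupby("sample_id"):
            assert sorted(grp["origin"]) == ["maternal", "paternal"]
            assert sorted(grp["po"]) == [0.0, 1.0]
            assert grp["ag"].sum() == 1.0
            assert grp["mg"].nunique() == 1
        assert (design["ag"] == (design["breed"] == "Duroc")).all()


class TestFilter:
    def test_cpm_rule(self):
        counts = pd.DataFrame(
            np.array([[2000] * 6 + [0] * 6,      # CPM huge in exactly 6
                      [2000] * 5 + [0] * 7,      # only 5
                      [0] * 12]),
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(12)])
        counts.loc["filler"] = 1_000_000        # keeps library sizes nonzero
        keep = asetest.filter_expression(counts, cpm_min=1, n_min=6)
        assert "a" in keep and "b" not in keep and "c" not in keep


class TestCountGlm:
    def test_null_log2fc_near_zero(self, reciprocal_samples):
        rng = np.random.default_rng(0)
        design = asetest.build_design(reciprocal_samples)
        Y = simulate_allelic_counts(rng, design, n_features=60)
        mat, pat = counts_to_frames(Y, design, [f"g{i}" for i in range(60)])
        res = asetest.fit_count_glm(mat, pat, design)
        assert abs(res[res["effect"] == "POE"]["log2fc"].mean()) < 0.1
        # p-values roughly uniform: mean near 0.5
        assert 0.3 < res["pvalue"].mean() < 0.7

    def test_planted_poe_recovered_and_matches_irls_oracle(self, reciprocal_samples):
        """Maternal = 4x paternal in both directions: POE log2FC near -2
        (paternal/maternal), AGE null; coefficients equal statsmodels GLM."""
        rng = np.random.default_rng(1)
        design = asetest.build_design(reciprocal_samples)
        Y = simulate_allelic_counts(rng, design, log2fc_po=-2.0,
                                    mean=400, n_features=30)
        mat, pat = counts_to_frames(Y, design, [f"g{i}" for i in range(30)])
        res = asetest.fit_count_glm(mat, pat, design, dispersion=0.1)
        poe = res[res["effect"] == "POE"].set_index("feature_id")
        age = res[res["effect"] == "AGE"].set_index("feature_id")
        assert poe["log2fc"].mean() == pytest.approx(-2.0, abs=0.25)
        assert (poe["fdr"] < 0.05).all()
        assert (age["fdr"] < 0.05).mean() < 0.2
        # oracle: the same observations through statsmodels NB GLM
        X, cols = asetest.design_matrix(design)
        off = asetest.allelic_offsets(mat, pat, design)
        f = 0
        ref = sm.GLM(Y[f], X, family=sm.families.NegativeBinomial(alpha=0.1),
                     offset=off).fit(tol=1e-12)
        assert poe.iloc[f]["log2fc"] == pytest.approx(
            ref.params[cols.index("po")] / np.log(2), abs=1e-6)

    def test_planted_age_hits_age_not_poe(self, reciprocal_samples):
        rng = np.random.default_rng(2)
        design = asetest.build_design(reciprocal_samples)
        Y = simulate_allelic_counts(rng, design, log2fc_ag=2.0,
                                    mean=400, n_features=30)
        mat, pat = counts_to_frames(Y, design, [f"g{i}" for i in range(30)])
        res = asetest.fit_count_glm(mat, pat, design, dispersion=0.1)
        age = res[res["effect"] == "AGE"]
        poe = res[res["effect"] == "POE"]
        assert (age["fdr"] < 0.05).all()
        assert (poe["fdr"] < 0.05).mean() < 0.2

    def test_breed_relabel_flips_age_only(self, reciprocal_samples):
        """Swapping which breed is called Duroc flips AGE log2FC signs and
        leaves POE untouched."""
        rng = np.random.default_rng(3)
        design = asetest.build_design(reciprocal_samples)
        Y = simulate_allelic_counts(rng, design, log2fc_po=1.0, log2fc_ag=1.5,
                                    mean=300, n_features=10)
        mat, pat = counts_to_frames(Y, design, [f"g{i}" for i in range(10)])
        res = asetest.fit_count_glm(mat, pat, design, dispersion=0.1)
        flipped = reciprocal_samples.copy()
        flipped["cross_direction"] = flipped["cross_direction"].map(
            {"DxL": "LxD", "LxD": "DxL"})
        design2 = asetest.build_design(flipped)
        res2 = asetest.fit_count_glm(mat, pat, design2, dispersion=0.1)
        a1 = res[res["effect"] == "AGE"]["log2fc"].to_numpy()
        a2 = res2[res2["effect"] == "AGE"]["log2fc"].to_numpy()
        p1 = res[res["effect"] == "POE"]["log2fc"].to_numpy()
        p2 = res2[res2["effect"] == "POE"]["log2fc"].to_numpy()
        np.testing.assert_allclose(a1, -a2, atol=1e-6)
        np.testing.assert_allclose(p1, p2, atol=1e-6)


class TestBinomialGlm:
    def _tables(self, M, U, design):
        obs = [f"{r['sample_id']}.{r['origin']}" for _, r in design.iterrows()]
        return (pd.DataFrame(M, columns=obs), pd.DataFrame(U, columns=obs))

    def test_equal_methylation_null(self, reciprocal_samples):
        rng = np.random.default_rng(4)
        design = asetest.build_design(reciprocal_samples)
        n = len(design)
        M = rng.binomial(30, 0.5, (40, n))
        m, u = self._tables(M, 30 - M, design)
        res = asetest.fit_binomial_glm(m, u, design)
        assert res["log2fc"].abs().mean() < 0.5
        assert (res["fdr"] < 0.05).mean() < 0.1

    def test_separation_flagged_p_missing(self, reciprocal_samples):
        design = asetest.build_design(reciprocal_samples)
        po = design["po"].to_numpy()
        M = np.where(po == 0, 20, 0)[None, :]
        U = np.where(po == 0, 0, 20)[None, :]
        m, u = self._tables(M, U, design)
        res = asetest.fit_binomial_glm(m, u, design)
        assert res["separated"].all()
        assert res["pvalue"].isna().all()

    def test_planted_po_logodds_recovered(self, reciprocal_samples):
        """Planted PO log-odds of 1.5 at coverage 30, n=12 samples is
        recovered within +-0.3 (statsmodels cross-check included)."""
        rng = np.random.default_rng(5)
        design = asetest.build_design(reciprocal_samples)
        X = design[asetest.EFFECT_COLUMNS].to_numpy()
        beta = np.array([0.3, 1.5, 0.0, 0.0, 0.0])
        p = 1 / (1 + np.exp(-(X @ beta)))
        F = 40
        N = np.full((F, len(X)), 30)
        M = rng.binomial(N, p)
        m, u = self._tables(M, N - M, design)
        res = asetest.fit_binomial_glm(m, u, design)
        poe = res[res["effect"] == "POE"]
        coef = poe["log2fc"].to_numpy() * np.log(2)   # back to log-odds
        assert np.mean(np.abs(coef - 1.5) <= 0.3) >= 0.9
        ref = sm.GLM(np.column_stack([M[0], N[0] - M[0]]),
                     X, family=sm.families.Binomial()).fit(tol=1e-12)
        assert coef[0] == pytest.approx(ref.params[1], abs=1e-6)


class TestClassification:
    def _results(self, fid, log2fc, fdr, effect="POE", context="c1"):
        return pd.DataFrame([{"feature_id": fid, "effect": effect,
                              "log2fc": log2fc, "fdr": fdr,
                              "context": context}])

    def _folds(self, fid, fold_origin=5.0, fold_breed=5.0):
        return pd.DataFrame({"fold_origin": [fold_origin],
                             "fold_breed": [fold_breed],
                             "paternal_fraction": [0.5]}, index=[fid])

    def test_significant_high_fold_called(self):
        out = asetest.classify_ase(self._results("g", -1.0, 0.01),
                                   self._folds("g"), mode="rna")
        assert out.iloc[0]["class"] == "POE_maternal_biased"

    def test_fold_three_not_called_rna(self):
        out = asetest.classify_ase(self._results("g", -1.0, 0.01),
                                   self._folds("g", fold_origin=3.0),
                                   mode="rna")
        assert len(out) == 0

    def test_fold_gate_strict_above_four(self):
        out = asetest.classify_ase(self._results("g", 1.0, 0.01),
                                   self._folds("g", fold_origin=4.0),
                                   mode="rna")
        assert len(out) == 0   # exactly 4x does not satisfy "more than 4 times"

    def test_atac_gate_two_fold_inclusive(self):
        out = asetest.classify_ase(self._results("g", 1.1, 0.01),
                                   self._folds("g", fold_origin=2.0),
                                   mode="atac")
        assert out.iloc[0]["class"] == "POE_paternal_biased"

    def test_nonsignificant_not_called(self):
        out = asetest.classify_ase(self._results("g", 2.0, 0.2),
                                   self._folds("g"), mode="rna")
        assert len(out) == 0

    def test_cross_context_rescue(self):
        res = pd.concat([
            self._results("g", 1.2, 0.01, context="c1"),
            self._results("g", 1.1, 0.30, context="c2")])
        out = asetest.classify_ase(res, self._folds("g", fold_origin=3.0),
                                   mode="rna")
        assert len(out) == 1   # rescued: significant once, |log2FC|>=1 twice


class TestImprinting:
    def test_rules(self):
        fr = pd.DataFrame({
            "feature_id": ["a"] * 3 + ["b"] + ["c"],
            "tissue": ["liver"] * 3 + ["liver"] + ["liver"],
            "stage": ["F40", "F70", "D1", "F40", "F40"],
            "paternal_fraction": [0.96, 0.97, 0.95, 0.80, 0.50]})
        out = asetest.call_imprinted(fr).set_index("feature_id")
        assert out.loc["a", "imprint_flag"]
        assert out.loc["a", "silenced_allele"] == "maternal"
        assert not out.loc["b", "imprint_flag"]
        assert out.loc["b", "strong_poe_flag"]
        assert not out.loc["c", "imprint_flag"]
        assert not out.loc["c", "strong_poe_flag"]


class TestDirectionSwitch:
    def _res(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "tissue", "stage",
                                           "log2fc", "fdr"])

    def test_opposite_signs_flagged(self):
        res = self._res([("g", "liver", "F40", -2.0, 0.01),
                         ("g", "liver", "D168", 2.0, 0.01)])
        assert asetest.detect_direction_switch(res).iloc[0]["direction_switch_flag"]

    def test_same_direction_not_flagged(self):
        res = self._res([("g", "liver", "F40", 2.0, 0.01),
                         ("g", "liver", "D168", 1.5, 0.01)])
        assert not asetest.detect_direction_switch(res).iloc[0]["direction_switch_flag"]

    def test_single_context_not_flagged(self):
        res = self._res([("g", "liver", "F40", 2.0, 0.01),
                         ("g", "liver", "D168", -1.5, 0.50)])
        assert not asetest.detect_direction_switch(res).iloc[0]["direction_switch_flag"]


class TestBiasCorrelation:
    def test_identical_vectors(self):
        x = pd.Series([0.1, 0.5, 0.9, 0.3], index=list("abcd"))
        assert asetest.bias_correlation(x, x) == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = pd.Series([0.1, 0.5, 0.9], index=list("abc"))
        assert asetest.bias_correlation(x, 1 - x) == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(6)
        x = pd.Series(rng.random(500))
        y = pd.Series(rng.random(500))
        assert abs(asetest.bias_correlation(x, y)) < 3 / np.sqrt(500)

    def test_too_few_missing(self):
        x = pd.Series([0.1, 0.2], index=list("ab"))
        assert np.isnan(asetest.bias_correlation(x, x))
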