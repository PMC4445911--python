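import numpy as np
import pandas as pd
import pytest

from tradepgls.model_inference import (
    ModelSpec, bonferroni, build_design, candidate_set, enumerate_submodels,
    fit_submodels, importance_table, model_average, rank_models,
    variable_importance,
)
from tradepgls.pgls import PGLSFit


def _dummy_fit(terms, betas, ll, n=100):
    k = len(terms)
    from tradepgls.pgls import aicc as _aicc
    return PGLSFit(
        terms=list(terms), beta=np.asarray(betas, float),
        se=np.ones(k), t=np.ones(k), p=np.full(k, 0.5),
        lambda_hat=0.5, sigma2_hat=1.0, loglik=ll, r2=0.5, adj_r2=0.4,
        F=1.0, F_df=(k - 1, n - k), F_p=0.5, aicc=_aicc(ll, k, n),
        n=n, k=k, K=k + 2, rss=1.0)


def _fits_with_aicc(values):
    """Models named m0, m1... whose AICc differences equal the given deltas."""
    fits = {}
    for i, a in enumerate(values):
        spec = ModelSpec((f"m{i}",))
        fit = _dummy_fit(["(Intercept)", f"m{i}"], [0.0, 1.0], -50.0)
        fit.aicc = a
        fits[spec] = fit
    return fits


class TestEnumerate:
    def test_three_predictors_give_eight_models(self):
        specs = enumerate_submodels(["a", "b", "c"])
        assert len(specs) == 8
        assert ModelSpec(()) in specs

    def test_zero_predictors_intercept_only(self):
        assert enumerate_submodels([]) == [ModelSpec(())]

    def test_nine_blocks_give_512(self):
        blocks = ["cites", "grey", "ln_range", "ln_numbers", "ln_mass",
                  "iucn_threatened", "song", "status", "yellow"]
        assert len(enumerate_submodels(blocks)) == 2 ** 9

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError, match="submodels"):
            enumerate_submodels([f"x{i}" for i in range(21)])


class TestRanking:
    def test_delta_two_weights(self):
        mset = rank_models(_fits_with_aicc([100.0, 102.0]))
        w = mset.table["weight"].to_numpy()
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)
        assert mset.table["delta_aicc"].min() == 0.0

    def test_equal_aicc_uniform_weights(self):
        mset = rank_models(_fits_with_aicc([100.0] * 5))
        assert np.allclose(mset.table["weight"], 0.2)

    def test_weights_sum_to_one_large_set(self, small_study):
        table = small_study["table"]
        from tradepgls.ensemble import vcv_for_table
        V, df = vcv_for_table(table, small_study["large"][0])
        from tradepgls.data_ingest import TraitTable
        design = build_design(TraitTable(df), "ln_price",
                              ["ln_numbers", "ln_mass", "status_alien"])
        if design.n < V.n:
            V = V.submatrix(design.species)
        mset = fit_submodels(design, V)
        assert len(mset) == 8
        assert mset.table["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_weights_invariant_to_constant_aicc_shift(self):
        w0 = rank_models(_fits_with_aicc([10.0, 12.0, 15.0]))
        w1 = rank_models(_fits_with_aicc([110.0, 112.0, 115.0]))
        assert np.allclose(w0.table["weight"], w1.table["weight"], atol=1e-12)


class TestImportance:
    def test_predictor_in_every_model_has_importance_one(self):
        fits = {
            ModelSpec(("a",)): _dummy_fit(["(Intercept)", "a"], [0, 1], -50),
            ModelSpec(("a", "b")): _dummy_fit(["(Intercept)", "a", "b"],
                                              [0, 1, 2], -49),
        }
        mset = rank_models(fits)
        assert variable_importance(mset, "a") == pytest.approx(1.0)

    def test_hand_weighted_sum(self):
        # weights (0.5, 0.2, 0.3); predictor "a" in the first two models
        fits = _fits_with_aicc([0.0, 0.0, 0.0])
        mset = rank_models(fits)
        mset.table["weight"] = [0.5, 0.2, 0.3]
        mask_terms = {("m0",), ("m1",)}
        imp = sum(w for w, spec in zip(mset.table["weight"],
                                       mset.table["model"])
                  if tuple(spec.terms) in mask_terms)
        assert imp == pytest.approx(0.7)

    def test_unknown_predictor_raises(self):
        mset = rank_models(_fits_with_aicc([1.0, 2.0]))
        with pytest.raises(KeyError):
            variable_importance(mset, "nope")

    def test_complementarity(self, small_study):
        from tradepgls.data_ingest import TraitTable
        from tradepgls.ensemble import vcv_for_table

        V, df = vcv_for_table(small_study["table"], small_study["large"][0])
        design = build_design(TraitTable(df), "ln_price",
                              ["ln_numbers", "ln_mass", "song_attractiveness"])
        if design.n < V.n:
            V = V.submatrix(design.species)
        mset = fit_submodels(design, V)
        for term in ("ln_numbers", "ln_mass", "song_attractiveness"):
            inc = variable_importance(mset, term)
            exc = sum(w for w, s in zip(mset.table["weight"],
                                        mset.table["model"])
                      if not s.includes(term))
            assert inc == pytest.approx(1.0 - exc, abs=1e-9)


class TestModelAverage:
    def test_single_model_is_identity(self):
        fit = _dummy_fit(["(Intercept)", "a"], [0.3, 1.7], -50)
        mset = rank_models({ModelSpec(("a",)): fit})
        avg = model_average(mset)
        assert avg.loc["a", "conditional"] == pytest.approx(1.7)
        assert avg.loc["a", "full"] == pytest.approx(1.7)

    def test_two_equal_weight_models_average(self):
        fits = {
            ModelSpec(("a",)): _dummy_fit(["(Intercept)", "a"], [0, 1.0], -50),
            ModelSpec(("a", "b")): _dummy_fit(["(Intercept)", "a", "b"],
                                              [0, 3.0, 2.0], -50),
        }
        # same loglik but different k -> different AICc; force equal weights
        mset = rank_models(fits)
        mset.table["weight"] = 0.5
        avg = model_average(mset)
        assert avg.loc["a", "conditional"] == pytest.approx(2.0)
        # "b" appears in only one model: conditional ignores absence,
        # full shrinks toward zero
        assert avg.loc["b", "conditional"] == pytest.approx(2.0)
        assert avg.loc["b", "full"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, small_study):
        from tradepgls.data_ingest import TraitTable
        from tradepgls.ensemble import vcv_for_table

        V, df = vcv_for_table(small_study["table"], small_study["large"][0])
        design = build_design(TraitTable(df), "ln_price",
                              ["ln_numbers", "ln_mass", "status_alien"])
        if design.n < V.n:
            V = V.submatrix(design.species)
        mset = fit_submodels(design, V)
        avg = model_average(mset)
        # brute-force weighted sums over the enumerated model list
        for term in ("ln_numbers", "ln_mass", "status_alien"):
            num = den = 0.0
            for w, spec in zip(mset.table["weight"], mset.table["model"]):
                if spec.includes(term):
                    num += w * mset.fits[spec].coef(term)
                    den += w
            assert avg.loc[term, "conditional"] == pytest.approx(
                num / den, abs=1e-10)
            assert avg.loc[term, "full"] == pytest.approx(num, abs=1e-10)


class TestCandidateSet:
    def test_strict_threshold_boundary(self):
        mset = rank_models(_fits_with_aicc([100.0, 103.9, 104.1]))
        sub = candidate_set(mset, threshold=4.0)
        assert len(sub) == 2

    def test_infinite_threshold_keeps_all(self):
        mset = rank_models(_fits_with_aicc([1.0, 9.0, 40.0]))
        assert len(candidate_set(mset, np.inf)) == 3

    def test_nonpositive_threshold_rejected(self):
        mset = rank_models(_fits_with_aicc([1.0, 2.0]))
        with pytest.raises(ValueError):
            candidate_set(mset, 0.0)


class TestBonferroni:
    def test_eleven_colour_family(self):
        out = bonferroni([0.004, 0.01], m=11)
        assert out["threshold"] == pytest.approx(0.05 / 11)
        assert out["significant"] == [True, False]

    def test_single_test_threshold(self):
        out = bonferroni([0.049], m=1)
        assert out["threshold"] == pytest.approx(0.05)
        assert out["significant"] == [True]

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni([0.01], m=0)
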