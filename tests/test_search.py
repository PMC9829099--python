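"""OLS fitting, BIC scoring, and the greedy best-first search."""

import math

import numpy as np
import pytest

import poipcm as pp
from poipcm.search import CollinearityError, SearchError


def _mixture(library, weights, intercept):
    out = np.full(21, float(intercept))
    for name, w in weights.items():
        out = out + w * library[name].vector
    return out


class TestFitModel:
    def test_intercept_only_baseline(self, library, two_poi_dataset):
        fit = pp.fit_model(two_poi_dataset.similarity, library, ())
        assert fit.intercept == pytest.approx(two_poi_dataset.similarity.mean())
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.k_params == 1

    def test_exact_interpolation(self, library):
        y = _mixture(library, {"nST": 0.13}, 0.1)
        data = np.tile(y, (4, 1))
        fit = pp.fit_model(data, library, ("nST",))
        assert fit.coef_map["nST"] == pytest.approx(0.13, abs=1e-12)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.r2 == pytest.approx(1.0)

    def test_normal_equations_oracle(self, library):
        """Betas and RSS match the closed-form (X'X)^-1 X'y solution."""
        rng = np.random.default_rng(5)
        data = rng.normal(0.05, 0.05, size=(5, 21))
        names = ("nST", "ET", "AP")
        fit = pp.fit_model(data, library, names)
        X_cell = np.column_stack([np.ones(21)] + [library[n].vector for n in names])
        X = np.tile(X_cell, (5, 1))
        y = data.ravel()
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(coef[0], abs=1e-10)
        assert np.allclose(fit.betas, coef[1:], atol=1e-10)
        resid = y - X @ coef
        assert fit.rss == pytest.approx(float(resid @ resid), abs=1e-10)

    def test_statsmodels_cross_check(self, library, two_poi_dataset):
        """Independent OLS implementation agrees on coefficients and R^2."""
        sm = pytest.importorskip("statsmodels.api")
        data = two_poi_dataset.similarity
        names = ("nST", "ET")
        fit = pp.fit_model(data, library, names)
        X_cell = np.column_stack([library[n].vector for n in names])
        X = sm.add_constant(np.tile(X_cell, (data.shape[0], 1)))
        res = sm.OLS(data.ravel(), X).fit()
        assert fit.intercept == pytest.approx(res.params[0], abs=1e-10)
        assert np.allclose(fit.betas, res.params[1:], atol=1e-10)
        assert fit.r2 == pytest.approx(res.rsquared, abs=1e-10)

    def test_collinear_set_rejected(self, library, two_poi_dataset):
        """AV = 2*PE + 2*NE - 1 makes {PE, NE, AV} rank deficient with an
        intercept."""
        with pytest.raises(CollinearityError):
            pp.fit_model(two_poi_dataset.similarity, library, ("PE", "NE", "AV"))


class TestBIC:
    def test_hand_evaluation(self):
        expected = 10 * math.log(2.5 / 10) + (2 + 1) * math.log(10)
        assert pp.bic(2.5, 10, 2) == pytest.approx(expected, abs=1e-12)

    def test_penalty_monotonicity(self):
        assert pp.bic(2.5, 100, 3) > pp.bic(2.5, 100, 2)

    def test_likelihood_monotonicity(self):
        assert pp.bic(3.0, 100, 2) > pp.bic(2.5, 100, 2)

    def test_invalid_dof(self):
        with pytest.raises(SearchError):
            pp.bic(1.0, 3, 5)


class TestGBFS:
    def test_zero_noise_single_poi(self, library):
        """A unique perfect predictor is recovered alone on one path."""
        data = np.tile(_mixture(library, {"ET": 0.5}, 0.2), (10, 1))
        res = pp.gbfs_search(data, library)
        assert res.final_set == ("ET",)
        assert res.n_path == 1
        assert len(res.paths[0].levels) == 2  # level-2 additions all rejected

    def test_two_poi_simulation_order_and_bruteforce(self, library, two_poi_dataset):
        res = pp.gbfs_search(two_poi_dataset.similarity, library)
        assert res.final_set == ("nST", "ET")  # acceptance order
        best = pp.best_subset_search(two_poi_dataset.similarity, library)
        assert set(best.poi_set) == set(res.final_set)
        assert res.final_fit.bic == pytest.approx(best.bic)

    def test_tied_candidates_branch(self, library):
        """Symmetric AP/AB data force two equivalent level-1 candidates."""
        sub = library.subset(["AP", "AB", "ET"])
        data = np.tile(_mixture(library, {"AP": 0.3, "AB": 0.3}, 0.05), (8, 1))
        res = pp.gbfs_search(data, sub, pp.SearchConfig(dedupe=False))
        assert res.n_path >= 2
        terminal = {frozenset(p.accepted) for p in res.paths
                    if {"AP", "AB"} <= set(p.accepted)}
        assert frozenset({"AP", "AB"}) in terminal
        bics = [p.terminal_fit.bic for p in res.paths
                if frozenset(p.accepted) == frozenset({"AP", "AB"})]
        assert max(bics) - min(bics) < 1e-9
        deduped = pp.gbfs_search(data, sub, pp.SearchConfig(dedupe=True))
        assert deduped.n_path < res.n_path

    def test_null_data_selects_nothing(self, library):
        rng = np.random.default_rng(9)
        data = np.full((20, 21), 0.1) + rng.normal(0, 1e-6, size=(20, 21))
        res = pp.gbfs_search(data, library)
        assert res.final_set == ()

    def test_accepted_steps_drop_bic(self, library, two_poi_dataset):
        """Every accepted step lowers path BIC by more than delta_accept."""
        res = pp.gbfs_search(two_poi_dataset.similarity, library)
        for path in res.paths:
            prev = res.baseline_none.bic
            for k in range(1, len(path.accepted) + 1):
                fit = pp.fit_model(two_poi_dataset.similarity, library,
                                   path.accepted[:k])
                assert prev - fit.bic > 2.0
                prev = fit.bic
        if res.final_set:
            assert res.final_fit.bic < res.baseline_none.bic - 2.0

    def test_greedy_vs_bruteforce_small_library(self, library, two_poi_dataset):
        """On <= 8 POIs, greedy terminal BIC >= exhaustive best subset."""
        sub = library.subset(["ET", "nST", "ST", "AP", "AB", "TV", "FS", "VE"])
        res = pp.gbfs_search(two_poi_dataset.similarity, sub)
        best = pp.best_subset_search(two_poi_dataset.similarity, sub)
        assert res.final_fit.bic >= best.bic - 1e-9

    def test_library_order_invariance(self, two_poi_dataset, library):
        rev = library.subset(list(reversed(library.names)))
        a = pp.gbfs_search(two_poi_dataset.similarity, library)
        b = pp.gbfs_search(two_poi_dataset.similarity, rev)
        assert set(a.final_set) == set(b.final_set)
        assert a.final_fit.bic == pytest.approx(b.final_fit.bic)

    def test_empty_library_rejected(self, two_poi_dataset):
        with pytest.raises(SearchError):
            pp.gbfs_search(two_poi_dataset.similarity,
                           pp.POILibrary(pois=()))


class TestSearchTrace:
    def test_reference_columns_and_levels(self, library, two_poi_dataset):
        res = pp.gbfs_search(two_poi_dataset.similarity, library)
        trace = pp.search_trace(res, library)
        assert np.allclose(trace["None"], res.baseline_none.bic)
        level1 = trace[trace["level"] == 1].iloc[0]
        cand = {n: level1[n] for n in library.names}
        assert min(cand, key=cand.get) == "nST"
        level2 = trace[(trace["level"] == 2) & (trace["path"] == 0)].iloc[0]
        others = {n: level2[n] for n in library.names if n != "nST"}
        assert min(others, key=others.get) == "ET"

    def test_zero_noise_trace_minimum(self, library):
        data = np.tile(_mixture(library, {"Sa": 0.4}, 0.0), (6, 1))
        res = pp.gbfs_search(data, library)
        trace = pp.search_trace(res, library)
        level1 = trace[trace["level"] == 1].iloc[0]
        cand = {n: level1[n] for n in library.names}
        assert min(cand, key=cand.get) == "Sa"


class TestEstimator:
    def test_fit_predict_score(self, library, two_poi_dataset):
        model = pp.PatternComponentModel(library=library)
        model.fit(two_poi_dataset.similarity)
        assert model.selected_ == ("nST", "ET")
        assert model.betas_[0] == pytest.approx(0.12, abs=0.02)
        pred = model.predict(two_poi_dataset.similarity)
        assert pred.shape == two_poi_dataset.similarity.shape
        assert 0.5 < model.score(two_poi_dataset.similarity) <= 1.0

    def test_score_consistency_with_fit_r2(self, library, two_poi_dataset):
        """Reconstruction applied back to the training data reproduces the
        ModelFit R^2."""
        model = pp.PatternComponentModel(library=library).fit(two_poi_dataset.similarity)
        assert model.score(two_poi_dataset.similarity) == pytest.approx(model.r2_,
                                                                        abs=1e-10)

    def test_get_set_params_clone(self, library):
        from sklearn.base import clone

        model = pp.PatternComponentModel(library=library, delta_accept=3.0)
        params = model.get_params()
        assert params["delta_accept"] == 3.0
        cloned = clone(model)
        assert cloned.get_params()["delta_accept"] == 3.0
        with pytest.raises(ValueError):
            model.set_params(bogus=1)

    def test_unfitted_predict_raises(self, library):
        with pytest.raises(SearchError):
            pp.PatternComponentModel(library=library).predict()
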