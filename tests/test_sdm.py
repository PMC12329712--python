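"""SDM pipeline: statistics vs brute-force oracles, coefficient recovery,
cross-validation behaviour, projection and richness invariants."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from lusa.grids import GridGeometry
from lusa.sdm import (
    auc,
    balanced_weights,
    build_species_dataset,
    clean_occurrences,
    cross_validate,
    fit_species_model,
    fit_weighted_logistic,
    mean_range_change,
    optimize_threshold,
    project_range,
    prune_correlated,
    sample_pseudo_absences,
    select_by_aic,
    stack_richness,
    suitability_map,
    tss,
    weighted_log_likelihood,
    SDModel,
)
from lusa.synthetic import generate_species, labeled_survey

GEOM = GridGeometry(shape=(10, 10), cell_area=10_000.0)


class TestCleanOccurrences:
    def test_one_record_per_cell(self):
        x, y = GEOM.cell_center(np.array([2, 2]), np.array([3, 3]))
        rec = pd.DataFrame({"species_id": "a", "x": x + [0.0, 10.0], "y": y})
        out = clean_occurrences(rec, GEOM)
        assert len(out) == 1

    def test_out_of_bounds_dropped(self):
        rec = pd.DataFrame({"species_id": "a", "x": [-5.0, 5000.0], "y": [5000.0, 5000.0]})
        out = clean_occurrences(rec, GEOM)
        assert len(out) == 1

    def test_nan_coordinates_dropped(self):
        rec = pd.DataFrame({"species_id": "a", "x": [np.nan, 5000.0], "y": [1.0, 5000.0]})
        assert len(clean_occurrences(rec, GEOM)) == 1

    def test_distinct_occupied_cells_all_kept(self, cfg, base_env):
        species, records = generate_species(base_env, 1, cfg)
        rec = records[records["species_id"] == species[0].species_id]
        row, col = base_env.geometry.cell_of(rec["x"].to_numpy(), rec["y"].to_numpy())
        k = len(set(zip(row.tolist(), col.tolist())))
        assert len(clean_occurrences(rec, base_env.geometry)) == k


class TestPseudoAbsences:
    def test_default_count_is_1000(self):
        mask = np.zeros(GEOM.shape, dtype=bool)
        mask[:2] = True
        pts = sample_pseudo_absences(mask, GEOM, seed=1)
        assert len(pts) == 1000

    def test_all_points_outside_range_mask(self):
        mask = np.zeros(GEOM.shape, dtype=bool)
        mask[:5] = True
        pts = sample_pseudo_absences(mask, GEOM, n=500, seed=2)
        row, col = GEOM.cell_of(pts["x"].to_numpy(), pts["y"].to_numpy())
        for r, c in zip(row, col):  # point-in-mask loop oracle
            assert not mask[r, c]

    def test_reproducible_by_seed(self):
        mask = np.zeros(GEOM.shape, dtype=bool)
        mask[0, 0] = True
        a = sample_pseudo_absences(mask, GEOM, n=50, seed=7)
        b = sample_pseudo_absences(mask, GEOM, n=50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_unsuitable_area_raises(self):
        with pytest.raises(ValueError, match="unsuitable"):
            sample_pseudo_absences(np.ones(GEOM.shape, dtype=bool), GEOM, seed=0)


class TestPruneCorrelated:
    def test_duplicate_predictor_dropped(self, rng):
        x = rng.normal(size=500)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=500)})
        kept = prune_correlated(X, threshold=0.7)
        assert "c" in kept
        assert len(set(kept) & {"a", "b"}) == 1

    def test_independent_noise_all_retained(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(10_000, 6)), columns=list("abcdef"))
        assert prune_correlated(X, threshold=0.7) == list("abcdef")

    def test_constant_predictor_dropped_with_warning(self, rng):
        X = pd.DataFrame({"a": np.ones(100), "b": rng.normal(size=100),
                          "c": rng.normal(size=100)})
        with pytest.warns(UserWarning, match="constant"):
            kept = prune_correlated(X)
        assert kept == ["b", "c"]

    def test_retained_set_passes_full_matrix_check(self, rng):
        base = rng.normal(size=(2000, 4))
        X = pd.DataFrame({
            "a": base[:, 0],
            "b": base[:, 0] * 0.95 + 0.05 * base[:, 1],
            "c": base[:, 1],
            "d": base[:, 2],
            "e": base[:, 2] * 0.9 + 0.1 * base[:, 3],
        })
        kept = prune_correlated(X, threshold=0.7)
        corr = X[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.7


class TestFitWeightedLogistic:
    def test_symmetric_data_zero_intercept(self, rng):
        x = rng.normal(size=2000)
        X = pd.DataFrame({"x": np.concatenate([x, -x])})
        y = np.concatenate([np.ones(2000, int), np.zeros(2000, int)])
        fit = fit_weighted_logistic(X, y)
        assert abs(fit.params["const"]) < 0.1

    def test_recovers_true_coefficients_within_3se(self, rng):
        n = 5000
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        truth = {"const": -0.5, "a": 1.2, "b": -0.8, "c": 0.0}
        eta = truth["const"] + X @ np.array([truth["a"], truth["b"], truth["c"]])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_weighted_logistic(X, y)
        for name in ("const", "a", "b", "c"):
            assert abs(fit.params[name] - truth[name]) < 3 * fit.bse[name]

    def test_fitted_likelihood_beats_truth(self, rng):
        n = 2000
        X = pd.DataFrame({"a": rng.normal(size=n)})
        eta = 0.3 + 1.0 * X["a"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_weighted_logistic(X, y)
        ll_truth = weighted_log_likelihood({"const": 0.3, "a": 1.0}, X, y)
        assert fit.llf >= ll_truth - 1e-9

    def test_equal_total_class_weights(self, rng):
        y = np.concatenate([np.ones(30, int), np.zeros(970, int)])
        w = balanced_weights(y)
        assert w[y == 1].sum() == pytest.approx(w[y == 0].sum())
        assert w.sum() == pytest.approx(len(y))

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_weighted_logistic(X, np.array([1, 1]))

    def test_perfect_separation_flagged(self):
        X = pd.DataFrame({"a": np.concatenate([np.arange(50) + 10.0, -np.arange(50) - 10.0])})
        y = np.concatenate([np.ones(50, int), np.zeros(50, int)])
        with pytest.warns(Warning):
            fit = fit_weighted_logistic(X, y)
        assert fit.separation


class TestSelectByAIC:
    def test_single_candidate(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=200)})
        y = (rng.random(200) < 1 / (1 + np.exp(-X["a"]))).astype(int)
        preds, fit = select_by_aic(X, y, None, ["a"])
        assert preds == ["a"]

    def test_aic_formula_oracle(self, rng):
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 + X["a"])))).astype(int)
        preds, fit = select_by_aic(X, y, None, ["a", "b"])
        k = len(preds) + 1
        ll = weighted_log_likelihood(dict(fit.params), X, y)
        assert fit.aic == pytest.approx(2 * k - 2 * ll, rel=1e-6)

    def test_true_subset_recovered_in_most_replicates(self):
        """Generating model uses predictors {1, 3} of 5; exhaustive AIC
        selection should include both in at least 90% of replicates."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            n = 5000
            X = pd.DataFrame(rng.normal(size=(n, 5)),
                             columns=[f"x{i}" for i in range(5)])
            eta = -0.2 + 0.8 * X["x1"] - 0.6 * X["x3"]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            preds, _ = select_by_aic(X, y, None, list(X.columns))
            hits += {"x1", "x3"} <= set(preds)
        assert hits / n_rep >= 0.9


class TestSkillStatistics:
    def test_tss_perfect_classification(self):
        assert tss(10, 0, 20, 0) == 1.0

    def test_tss_forced_arithmetic(self):
        assert tss(8, 2, 90, 10) == pytest.approx(0.7)

    def test_tss_empty_class_rejected(self):
        with pytest.raises(ValueError):
            tss(0, 0, 5, 5)

    def test_tss_random_scores_mean_zero(self, rng):
        vals = []
        labels = np.concatenate([np.ones(20, int), np.zeros(30, int)])
        for _ in range(1000):
            scores = rng.random(50)
            thr = 0.5
            pred = scores >= thr
            tp = int((pred & (labels == 1)).sum())
            fp = int((pred & (labels == 0)).sum())
            vals.append(tss(tp, 20 - tp, 30 - fp, fp))
        assert abs(np.mean(vals)) < 0.02

    def test_auc_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auc(scores, labels) == 1.0

    def test_auc_forced_pairs(self):
        scores = np.array([0.9, 0.4, 0.6, 0.2])
        labels = np.array([1, 1, 0, 0])
        assert auc(scores, labels) == pytest.approx(0.75)

    def test_auc_all_ties_half(self):
        assert auc(np.full(10, 0.3), np.array([1] * 5 + [0] * 5)) == 0.5

    def test_auc_brute_force_and_sklearn(self, rng):
        """Pair-counting oracle and the library AUC on random instances."""
        for _ in range(100):
            n1, n0 = rng.integers(2, 15, size=2)
            scores = np.round(rng.random(n1 + n0), 2)  # force ties
            labels = np.array([1] * n1 + [0] * n0)
            pos, neg = scores[:n1], scores[n1:]
            wins = sum((p > a) + 0.5 * (p == a) for p in pos for a in neg)
            oracle = wins / (n1 * n0)
            assert auc(scores, labels) == pytest.approx(oracle)
            assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


class TestOptimizeThreshold:
    def test_separated_scores_attain_tss_one(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        labels = np.array([1, 1, 0, 0])
        thr, best = optimize_threshold(scores, labels)
        assert best == 1.0
        assert 0.3 < thr <= 0.8

    def test_matches_fine_grid_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 40))
            scores = rng.random(n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            thr, best = optimize_threshold(scores, labels)
            grid = np.arange(0, 1.001, 0.001)
            n1, n0 = labels.sum(), (1 - labels).sum()
            oracle = max(
                (scores[labels == 1] >= t).sum() / n1
                + (scores[labels == 0] < t).sum() / n0
                - 1.0
                for t in grid
            )
            assert best >= oracle - 1e-12

    def test_tie_break_smallest_threshold(self):
        scores = np.array([0.9, 0.9, 0.1, 0.1])
        labels = np.array([1, 1, 0, 0])
        thr, _ = optimize_threshold(scores, labels)
        # all thresholds in (0.1, 0.9] attain TSS = 1; smallest candidate wins
        assert thr == pytest.approx(0.9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestCrossValidate:
    def test_strong_species_retained(self, rng):
        n = 600
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        eta = 2.0 * X["a"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        cv = cross_validate(X, y, ["a"], k=5, seed=0)
        assert cv.retained
        assert cv.auc_mean > 0.8

    def test_shuffled_labels_auc_near_half(self):
        aucs = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            n = 150
            X = pd.DataFrame({"a": rng.normal(size=n)})
            y = np.array([1] * 50 + [0] * 100)
            rng.shuffle(y)
            cv = cross_validate(X, y, ["a"], k=5, seed=rep)
            aucs.append(cv.auc_mean)
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_too_few_records_rejected(self):
        X = pd.DataFrame({"a": np.arange(6.0)})
        y = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError):
            cross_validate(X, y, ["a"], k=5, seed=0)


class TestEndToEndRecovery:
    def test_pipeline_recovers_true_slopes_within_3se(self, cfg, base_env):
        """Full prune -> AIC -> fit -> threshold -> CV chain on a labelled
        survey of one synthetic species: true predictors selected, slope
        coefficients within 3 SE, model retained."""
        from lusa.sdm import SpeciesDataset

        species, _ = generate_species(base_env, 1, cfg)
        sp = species[0]
        rng = np.random.default_rng(123)
        X, y = labeled_survey(sp, base_env, n=5000, rng=rng)
        dataset = SpeciesDataset(sp.species_id, X, y, balanced_weights(y))
        model = fit_species_model(dataset, seed=1)
        true_active = {k for k, v in sp.true_coefficients.items()
                       if k != "intercept" and abs(v) > 0}
        assert model.retained
        assert true_active <= set(model.selected_predictors)
        fit = model.fit
        for name in true_active:
            if name in fit.params.index:
                err = abs(fit.params[name] - sp.true_coefficients[name])
                assert err < 3 * fit.bse[name]


class TestProjectionAndRichness:
    def _model(self, threshold, coeffs=None):
        coeffs = coeffs or {"intercept": 0.0, "forest": 4.0}
        return SDModel(
            species_id="m", selected_predictors=[k for k in coeffs if k != "intercept"],
            coefficients=coeffs, threshold=threshold,
            cv_auc_mean=0.9, cv_tss_mean=0.5, retained=True,
        )

    def test_empty_mask_empty_distribution(self, base_env):
        dist = project_range(self._model(0.5), base_env,
                             np.zeros(base_env.geometry.shape, bool))
        assert not dist.any()

    def test_zero_threshold_full_mask_all_present(self, base_env):
        dist = project_range(self._model(0.0), base_env,
                             np.ones(base_env.geometry.shape, bool))
        assert dist.all()

    def test_matches_cell_loop_oracle(self, base_env):
        model = self._model(0.6)
        mask = np.zeros(base_env.geometry.shape, bool)
        mask[::2] = True
        dist = project_range(model, base_env, mask)
        p = suitability_map(model, base_env)
        for r in range(mask.shape[0]):
            for c in range(mask.shape[1]):
                assert dist[r, c] == (p[r, c] >= 0.6 and mask[r, c])

    def test_monotone_in_threshold(self, base_env):
        mask = np.ones(base_env.geometry.shape, bool)
        lo = project_range(self._model(0.3), base_env, mask)
        hi = project_range(self._model(0.7), base_env, mask)
        assert not (hi & ~lo).any()  # raising threshold never adds cells

    def test_richness_stack_and_order_invariance(self, base_env):
        geom = base_env.geometry
        d1 = np.zeros(geom.shape, bool)
        d1[:3] = True
        d2 = np.ones(geom.shape, bool)
        r12 = stack_richness({"a": d1, "b": d2}, geom, 2015)
        r21 = stack_richness({"b": d2, "a": d1}, geom, 2015)
        np.testing.assert_array_equal(r12.counts, r21.counts)
        assert r12.counts.max() == 2
        loop = d1.astype(int) + d2.astype(int)
        np.testing.assert_array_equal(r12.counts, loop)

    def test_no_species_zero_richness(self, base_env):
        r = stack_richness({}, base_env.geometry, 2015)
        assert r.counts.sum() == 0


class TestMeanRangeChange:
    def test_unchanged_distributions_zero(self):
        d = {"a": np.ones((3, 3), bool)}
        assert mean_range_change(d, d) == 0.0

    def test_double_and_half_average(self):
        base = {"a": np.array([[True, False]]), "b": np.array([[True, True]])}
        now = {"a": np.array([[True, True]]), "b": np.array([[True, False]])}
        assert mean_range_change(now, base) == pytest.approx((100.0 - 50.0) / 2)

    def test_zero_baseline_excluded_with_warning(self):
        base = {"a": np.zeros((2, 2), bool), "b": np.ones((2, 2), bool)}
        now = {"a": np.ones((2, 2), bool), "b": np.ones((2, 2), bool)}
        with pytest.warns(UserWarning, match="zero baseline"):
            assert mean_range_change(now, base) == 0.0
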