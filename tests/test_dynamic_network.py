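import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emadyn as ed
from emadyn.dynamic_network import LaggedEdge, ContemporaneousEdge, NetworkModel

from conftest import toy_adjusted


def adjusted_for(dataset, var, window_days=3.0):
    series = ed.to_equidistant_grid(dataset, var)
    trend = ed.lowpass_trend(series, window_days=window_days)
    return ed.covariate_adjust(series, trend)


class TestCovariateAdjust:
    def test_slot_effect_removed(self, design):
        dgp = ed.make_dgp(
            ("fatigue", "worry"),
            np.zeros((2, 2)),
            circadian_amplitude=10.0,
            circadian_peak="20:00",
            scale=5.0,
        )
        ds = ed.simulate_subject(design, dgp, seed=44)
        adj = adjusted_for(ds, "fatigue")
        resid = adj.residual
        slots = adj.slot_of_day
        for s in range(5):
            vals = resid[slots == s]
            vals = vals[~np.isnan(vals)]
            assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(len(vals))

    def test_residual_mean_zero(self, dataset_default):
        adj = adjusted_for(dataset_default, "fatigue")
        assert abs(np.nanmean(adj.residual)) < 1e-8 * 100

    def test_additive_constant_invariance(self, dataset_full):
        adj0 = adjusted_for(dataset_full, "fatigue")
        shifted = dataset_full.records.copy()
        is_f = shifted["item_id"] == "fatigue"
        shifted.loc[is_f, "value"] += 11.5
        ds = ed.EmaDataset(
            subject_id="s",
            design=dataset_full.design,
            schedule=dataset_full.schedule,
            records=shifted,
            answered_mask=dataset_full.answered_mask,
        )
        adj1 = adjusted_for(ds, "fatigue")
        np.testing.assert_allclose(adj1.residual, adj0.residual, atol=1e-9)

    def test_reconstruction_identity(self, dataset_default):
        g = ed.to_equidistant_grid(dataset_default, "fatigue")
        trend = ed.lowpass_trend(g)
        adj = ed.covariate_adjust(g, trend)
        obs = g.observed
        rebuilt = (
            adj.residual + adj.removed_trend + adj.removed_slot + adj.removed_weekend
        )
        np.testing.assert_allclose(rebuilt[obs], g.values[obs], atol=1e-10)

    def test_white_noise_variance_nearly_preserved(self):
        rng = np.random.default_rng(3)
        reps = []
        for r in range(20):
            n = 250
            vals = rng.standard_normal(n)
            from test_basic_report import series_from

            s = series_from(vals, per_day=5)
            adj = ed.covariate_adjust(s, ed.lowpass_trend(s))
            reps.append(np.nanvar(adj.residual) / np.var(vals))
        assert abs(np.mean(reps) - 1.0) < 0.10

    def test_wrong_grid_rejected(self, dataset_full, dataset_default):
        g_full = ed.to_equidistant_grid(dataset_full, "fatigue")
        d_small = ed.StudyDesign(subject_id="s", n_days=20)
        ds_small = ed.simulate_subject(d_small, ed.null_dgp(("fatigue", "worry")), seed=2)
        g_small = ed.to_equidistant_grid(ds_small, "fatigue")
        trend_small = ed.lowpass_trend(g_small)
        with pytest.raises(ed.ParameterError):
            ed.covariate_adjust(g_full, trend_small)


class TestLagPairs:
    def test_fully_observed_combinatorics(self):
        adj = toy_adjusted({"a": np.arange(50.0), "b": np.arange(50.0) ** 2}, per_day=5)
        pairs = ed.build_lag_pairs(adj)
        assert len(pairs) == 4 * 10  # 4 transitions/day x 10 days

    def test_overnight_never_paired(self):
        adj = toy_adjusted({"a": np.arange(20.0)}, per_day=5)
        pairs = ed.build_lag_pairs(adj)
        days = adj[0].day_index
        assert all(days[p.prev] == days[p.curr] for p in pairs)
        boundary = {(4, 5), (9, 10), (14, 15)}
        assert not boundary & {(p.prev, p.curr) for p in pairs}

    def test_missing_value_drops_pair(self):
        a = np.arange(20.0)
        b = np.arange(20.0)
        b[7] = np.nan
        adj = toy_adjusted({"a": a, "b": b}, per_day=5)
        pairs = {(p.prev, p.curr) for p in ed.build_lag_pairs(adj)}
        assert (6, 7) not in pairs and (7, 8) not in pairs
        assert len(pairs) == 16 - 2


class TestLaggedModel:
    def test_matches_normal_equations_oracle(self):
        """2 variables, 12 fully observed occasions: coefficients equal the
        closed-form least-squares solution to 1e-8."""
        rng = np.random.default_rng(8)
        x_vals = rng.normal(size=12)
        y_vals = 0.5 * np.roll(x_vals, 1) + rng.normal(size=12) * 0.5
        adj = toy_adjusted({"y": y_vals, "x": x_vals}, per_day=4)
        pairs = ed.build_lag_pairs(adj)
        model = ed.fit_lagged_model(adj, pairs, min_pairs_per_predictor=4)

        sy, sx = np.std(y_vals, ddof=1), np.std(x_vals, ddof=1)
        prev = np.array([p.prev for p in pairs])
        curr = np.array([p.curr for p in pairs])
        xmat = np.column_stack([np.ones(len(prev)), y_vals[prev] / sy, x_vals[prev] / sx])
        for target, vals, sd in (("y", y_vals, sy), ("x", x_vals, sx)):
            beta = np.linalg.solve(xmat.T @ xmat, xmat.T @ (vals[curr] / sd))
            got = {e.source: e.beta for e in model.lagged_edges if e.target == target}
            assert got["y"] == pytest.approx(beta[1], abs=1e-8)
            assert got["x"] == pytest.approx(beta[2], abs=1e-8)

    def test_insufficient_pairs_error_names_threshold(self):
        adj = toy_adjusted({"a": np.arange(8.0), "b": np.arange(8.0)[::-1]}, per_day=4)
        with pytest.raises(ed.InsufficientDataError, match="20"):
            ed.fit_lagged_model(adj, ed.build_lag_pairs(adj))

    def test_collinear_predictors_rejected(self):
        base = np.arange(40.0)
        adj = toy_adjusted({"a": base, "b": 2 * base}, per_day=5)
        with pytest.raises(ed.CollinearityError):
            ed.fit_lagged_model(adj, ed.build_lag_pairs(adj), min_pairs_per_predictor=4)

    def test_more_than_three_variables_rejected(self):
        data = {f"v{i}": np.random.default_rng(i).normal(size=40) for i in range(4)}
        adj = toy_adjusted(data, per_day=5)
        with pytest.raises(ed.ParameterError, match="3"):
            ed.fit_lagged_model(adj, ed.build_lag_pairs(adj))

    def test_affine_invariance(self, dataset_default):
        """Scaling a variable by 10 and shifting by 7 leaves standardized
        estimates and p-values unchanged to 1e-10."""
        model0 = ed.estimate_network(dataset_default, ("fatigue", "worry"))
        rec = dataset_default.records.copy()
        is_w = rec["item_id"] == "worry"
        rec.loc[is_w, "value"] = rec.loc[is_w, "value"] * 10 + 7
        ds = ed.EmaDataset(
            subject_id="s",
            design=dataset_default.design,
            schedule=dataset_default.schedule,
            records=rec,
            answered_mask=dataset_default.answered_mask,
        )
        model1 = ed.estimate_network(ds, ("fatigue", "worry"))
        for e0, e1 in zip(model0.lagged_edges, model1.lagged_edges):
            assert e1.beta == pytest.approx(e0.beta, abs=1e-10)
            assert e1.p == pytest.approx(e0.p, abs=1e-10)
        for c0, c1 in zip(model0.contemporaneous_edges, model1.contemporaneous_edges):
            assert c1.r == pytest.approx(c0.r, abs=1e-10)
            assert c1.p == pytest.approx(c0.p, abs=1e-10)


class TestContemporaneous:
    def _model_with_innovations(self, innov, variables):
        return NetworkModel(
            variables=tuple(variables),
            lagged_edges=(),
            contemporaneous_edges=(),
            n_lag_pairs=len(innov),
            n_occasions_used=len(innov),
            innovations=innov,
        )

    def test_two_variable_case_is_plain_correlation(self):
        rng = np.random.default_rng(0)
        innov = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=1000)
        model = ed.fit_contemporaneous(self._model_with_innovations(innov, ["a", "b"]))
        (edge,) = model.contemporaneous_edges
        assert edge.r == pytest.approx(np.corrcoef(innov.T)[0, 1], abs=1e-12)
        assert edge.r == pytest.approx(0.5, abs=0.06)

    def test_three_variable_partial_matches_residualization_oracle(self):
        rng = np.random.default_rng(1)
        cov = np.array([[1, 0.5, 0.3], [0.5, 1, 0.4], [0.3, 0.4, 1]])
        innov = rng.multivariate_normal(np.zeros(3), cov, size=400)
        model = ed.fit_contemporaneous(self._model_with_innovations(innov, ["a", "b", "c"]))
        # oracle: correlate OLS residuals after removing the third variable
        def partial(i, j, k):
            def resid(v, on):
                x = np.column_stack([np.ones(len(on)), on])
                return v - x @ np.linalg.lstsq(x, v, rcond=None)[0]

            return np.corrcoef(
                resid(innov[:, i], innov[:, k]), resid(innov[:, j], innov[:, k])
            )[0, 1]

        got = {e.key(): e.r for e in model.contemporaneous_edges}
        assert got["a~b"] == pytest.approx(partial(0, 1, 2), abs=1e-10)
        assert got["a~c"] == pytest.approx(partial(0, 2, 1), abs=1e-10)
        assert got["b~c"] == pytest.approx(partial(1, 2, 0), abs=1e-10)

    def test_null_innovations_calibrated(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 400
        for _ in range(reps):
            innov = rng.standard_normal((80, 2))
            model = ed.fit_contemporaneous(self._model_with_innovations(innov, ["a", "b"]))
            hits += model.contemporaneous_edges[0].p < 0.05
        assert 0.02 < hits / reps < 0.08

    def test_insufficient_occasions_rejected(self):
        innov = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ed.InsufficientDataError, match="30"):
            ed.fit_contemporaneous(self._model_with_innovations(innov, ["a", "b"]))


class TestRelevanceFilter:
    CANONICAL = [
        (0.25, 0.01, True),  # significant and sizeable -> kept
        (0.50, 0.20, False),  # sizeable but not significant -> dropped
        (0.15, 0.001, False),  # significant but small -> dropped
    ]

    def _model(self, edges):
        lagged = tuple(
            LaggedEdge("worry", "fatigue", beta, 0.1, p) for beta, p, _ in edges
        )
        return NetworkModel(
            variables=("fatigue", "worry"),
            lagged_edges=lagged,
            contemporaneous_edges=(),
            n_lag_pairs=100,
            n_occasions_used=120,
        )

    def test_canonical_truth_table(self):
        model = self._model(self.CANONICAL)
        kept = ed.relevance_filter(model)
        assert [e.beta for e in kept.lagged_edges] == [0.25]

    def test_strict_inequalities_at_thresholds(self):
        model = self._model([(0.2, 0.01, False), (0.25, 0.05, False)])
        assert ed.relevance_filter(model).lagged_edges == ()

    def test_manual_drop_applies_last(self):
        model = self._model(self.CANONICAL)
        kept = ed.relevance_filter(model, manual_drop={"worry->fatigue"})
        assert kept.lagged_edges == ()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-1, 1, allow_nan=False),
                st.floats(0, 1, allow_nan=False),
            ),
            max_size=8,
        )
    )
    def test_subset_and_idempotent(self, raw):
        model = self._model([(b, p, None) for b, p in raw])
        once = ed.relevance_filter(model)
        assert set(once.lagged_edges) <= set(model.lagged_edges)
        twice = ed.relevance_filter(once)
        assert twice.lagged_edges == once.lagged_edges


class TestEnumerateModels:
    def test_four_variables_six_subsets(self):
        subsets = ed.enumerate_models(["fatigue", "a", "b", "c"], focal="fatigue")
        assert len(subsets) == 6  # C(3,1) pairs + C(3,2) triples
        assert all("fatigue" in s for s in subsets)
        sizes = [len(s) for s in subsets]
        assert sizes == [2, 2, 2, 3, 3, 3]

    def test_single_variable_empty(self):
        assert ed.enumerate_models(["fatigue"], focal="fatigue") == []

    def test_missing_focal_rejected(self):
        with pytest.raises(ed.UnknownVariableError):
            ed.enumerate_models(["a", "b"], focal="fatigue")

    def test_deterministic_order(self):
        a = ed.enumerate_models(["f", "x", "y", "z"], focal="f")
        b = ed.enumerate_models(["f", "x", "y", "z"], focal="f")
        assert a == b
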