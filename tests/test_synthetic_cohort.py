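import numpy as np
import pandas as pd
import pytest

import emadyn as ed
from emadyn.synthetic_cohort import make_dgp


def grid_values(ds, var):
    return ed.to_equidistant_grid(ds, var).values


def same_day_lag1_corr(values, day_index):
    prev = [values[t - 1] for t in range(1, len(values)) if day_index[t] == day_index[t - 1]]
    curr = [values[t] for t in range(1, len(values)) if day_index[t] == day_index[t - 1]]
    return np.corrcoef(prev, curr)[0, 1]


class TestSimulateSubject:
    def test_white_noise_mean_and_autocorr(self, design, null_dgp_2var, dataset_full):
        vals = grid_values(dataset_full, "fatigue")
        t = len(vals)
        # baseline 50, scale 10 -> sample mean near 50
        assert abs(vals.mean() - 50.0) < 3 * 10 / np.sqrt(t)
        r = same_day_lag1_corr(vals, dataset_full.schedule.day_index)
        assert abs(r) < 3 / np.sqrt(t)

    def test_ar_diagonal_04_autocorr_recovered(self, design):
        phi = 0.4 * np.eye(2)
        dgp = make_dgp(("fatigue", "worry"), phi)
        ds = ed.simulate_subject(design, dgp, seed=7)
        r = same_day_lag1_corr(grid_values(ds, "fatigue"), ds.schedule.day_index)
        assert abs(r - 0.4) < 0.1

    def test_exact_stream_matches_recursion_oracle(self, design):
        """Independent re-implementation of the documented draw order
        (stationary draw each morning, then Phi z + chol(Sigma) eps)
        reproduces the simulated values exactly."""
        phi = np.array([[0.4]])
        dgp = make_dgp(("fatigue",), phi, baseline=60.0, scale=8.0)
        ds = ed.simulate_subject(design, dgp, seed=99)
        sched = ds.schedule
        rng = np.random.default_rng(99)
        chol_innov = np.linalg.cholesky(dgp.innovation_cov)
        chol_stat = np.linalg.cholesky(dgp.stationary_cov())
        z = np.empty(len(sched))
        state = np.zeros(1)
        for t in range(len(sched)):
            if sched.first_of_day[t]:
                state = chol_stat @ rng.standard_normal(1)
            else:
                state = phi @ state + chol_innov @ rng.standard_normal(1)
            z[t] = state[0]
        expected = np.clip(60.0 + 8.0 * z, 0, 100)
        np.testing.assert_allclose(grid_values(ds, "fatigue"), expected, atol=1e-12)

    def test_same_seed_identical(self, design, null_dgp_2var):
        a = ed.simulate_subject(design, null_dgp_2var, seed=5)
        b = ed.simulate_subject(design, null_dgp_2var, seed=5)
        assert a.records.equals(b.records)

    def test_nonstationary_phi_rejected(self, design):
        with pytest.raises(ed.ParameterError, match="spectral radius"):
            make_dgp(("a", "b"), 1.01 * np.eye(2), np.eye(2)).validate()

    def test_non_pd_sigma_rejected(self):
        with pytest.raises(ed.ParameterError, match="positive definite"):
            make_dgp(("a", "b"), np.zeros((2, 2)), np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_unknown_variable_rejected(self, design):
        dgp = ed.null_dgp(("not_an_item", "worry"))
        with pytest.raises(ed.InvalidDesignError, match="not_an_item"):
            ed.simulate_subject(design, dgp, seed=0)

    def test_default_dgp_clipping_below_1pct(self, design):
        ds = ed.simulate_subject(design, ed.default_dgp(), seed=3)
        assert ds.clipped_fraction < 0.01

    def test_context_offsets_shift_level_means(self, design):
        dgp = ed.default_dgp()
        long = ed.StudyDesign(subject_id="s", n_days=120)
        ds = ed.simulate_subject(long, dgp, seed=21)
        fatigue = ed.to_equidistant_grid(ds, "fatigue")
        location = ed.to_equidistant_grid(ds, "location")
        dep = ed.categorical_dependency(fatigue, location)
        means = dep.table.set_index("level")["mean"]
        # school (level 1) carries a +8 fatigue offset relative to home
        assert means[1] - means[0] == pytest.approx(8.0, abs=2.5)


class TestMissingness:
    def test_no_missingness_identity(self, dataset_full):
        dgp = ed.null_dgp(("fatigue", "worry"), compliance=ed.CompliancePlan(p0=1.0, daily_decay=1.0))
        out = ed.apply_missingness(dataset_full, dgp, seed=1)
        assert out.records.equals(dataset_full.records)
        assert out.answered_mask.all()

    def test_invalid_p0_rejected(self, dataset_full):
        with pytest.raises(ed.ParameterError, match="p0"):
            ed.CompliancePlan(p0=0.0).validate()

    def test_answer_fraction_matches_closed_form(self, design, null_dgp_2var):
        p0, decay = 0.6, 0.99
        dgp = ed.null_dgp(("fatigue", "worry"), compliance=ed.CompliancePlan(p0=p0, daily_decay=decay))
        full = ed.simulate_subject(design, dgp, seed=1)
        expected = dgp.compliance.expected_answer_fraction(design.n_days)
        d = np.arange(design.n_days)
        closed_form = p0 * np.mean(decay ** d)
        assert expected == pytest.approx(closed_form, abs=1e-12)
        fracs = [
            ed.apply_missingness(full, dgp, seed=s).answered_mask.mean()
            for s in range(500)
        ]
        mc_se = np.sqrt(expected * (1 - expected) / len(full.schedule) / 500)
        assert np.mean(fracs) == pytest.approx(expected, abs=4 * mc_se)

    def test_default_preset_near_observed_regime(self):
        # p0=0.52, decay=0.993 over a 49-day period: low-forties answer share
        plan = ed.CompliancePlan()
        assert plan.expected_answer_fraction(49) == pytest.approx(0.44, abs=0.01)

    def test_conservation_answered_plus_unanswered(self, design, null_dgp_2var, dataset_full):
        out = ed.apply_missingness(dataset_full, null_dgp_2var, seed=9)
        n_answered = out.answered_mask.sum()
        assert n_answered + (~out.answered_mask).sum() == len(out.schedule)
        # records only at answered prompts
        occ = out.records[["day_index", "clock_time"]].drop_duplicates()
        assert len(occ) == n_answered

    def test_requires_fully_answered(self, design, null_dgp_2var, dataset_full):
        thinned = ed.apply_missingness(dataset_full, null_dgp_2var, seed=2)
        with pytest.raises(ed.EmadynError, match="fully answered"):
            ed.apply_missingness(thinned, null_dgp_2var, seed=3)

    def test_state_dependent_mode_reduces_high_fatigue_answers(self, design):
        dgp = ed.null_dgp(
            ("fatigue", "worry"),
            compliance=ed.CompliancePlan(p0=0.7, daily_decay=1.0, state_slope=1.5),
        )
        full = ed.simulate_subject(design, dgp, seed=31)
        out = ed.apply_missingness(full, dgp, seed=32)
        z = full.latent[:, 0]
        assert z[out.answered_mask].mean() < z[~out.answered_mask].mean()


class TestCohort:
    def test_single_subject_equals_derived_seed(self, design, null_dgp_2var):
        cohort = ed.simulate_cohort(1, design, null_dgp_2var, master_seed=17, with_missingness=False)
        ss = np.random.SeedSequence(17).spawn(1)[0]
        sim_seed, _, _ = ss.spawn(3)
        direct = ed.simulate_subject(
            ed.StudyDesign(subject_id="t001-001"), null_dgp_2var, sim_seed
        )
        assert cohort[0].records.equals(direct.records)

    def test_cohort_reruns_identical(self, design, null_dgp_2var):
        a = ed.simulate_cohort(5, design, null_dgp_2var, master_seed=3)
        b = ed.simulate_cohort(5, design, null_dgp_2var, master_seed=3)
        for x, y in zip(a, b):
            assert x.records.equals(y.records)
            assert (x.answered_mask == y.answered_mask).all()

    def test_jitter_varies_phi_but_stays_stationary(self, design):
        dgp = ed.default_dgp()
        # jittered lag matrices differ across subjects and remain stationary
        from emadyn.synthetic_cohort import _jitter_phi

        rngs = [np.random.default_rng(s) for s in range(8)]
        mats = [_jitter_phi(np.asarray(dgp.lag_matrix), 0.08, r) for r in rngs]
        assert all(np.max(np.abs(np.linalg.eigvals(m))) < 1.0 for m in mats)
        assert any(not np.allclose(mats[0], m) for m in mats[1:])
        cohort = ed.simulate_cohort(3, design, dgp, master_seed=5, phi_jitter_sd=0.08)
        assert len(cohort) == 3

    def test_invalid_cohort_size(self, design, null_dgp_2var):
        with pytest.raises(ed.ParameterError):
            ed.simulate_cohort(0, design, null_dgp_2var, master_seed=0)


class TestSerialization:
    def test_dgp_yaml_round_trip(self, tmp_path):
        dgp = ed.default_dgp()
        path = tmp_path / "dgp.yaml"
        ed.save_dgp(dgp, path)
        loaded = ed.load_dgp(path)
        np.testing.assert_allclose(loaded.lag_matrix, dgp.lag_matrix)
        np.testing.assert_allclose(loaded.innovation_cov, dgp.innovation_cov)
        assert loaded.variables == dgp.variables
        assert loaded.context.level_probs == dgp.context.level_probs
        assert loaded.compliance == dgp.compliance

    def test_dataset_csv_round_trip(self, tmp_path, design, dataset_default):
        rec_path = tmp_path / "rec.csv"
        sched_path = tmp_path / "sched.csv"
        ed.write_dataset_csv(dataset_default, rec_path, sched_path)
        loaded = ed.read_dataset_csv(rec_path, sched_path, design)
        assert (loaded.answered_mask == dataset_default.answered_mask).all()
        pd.testing.assert_frame_equal(
            loaded.records.reset_index(drop=True),
            dataset_default.records[["day_index", "clock_time", "item_id", "value"]],
        )

    def test_unit_variance_innovations(self):
        phi = np.array([[0.3, 0.3], [0.0, 0.2]])
        sigma = ed.innovations_for_unit_variance(phi)
        from scipy.linalg import solve_discrete_lyapunov

        v = solve_discrete_lyapunov(phi, sigma)
        np.testing.assert_allclose(v, np.eye(2), atol=1e-10)
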