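"""EM estimation of the VAR mixture: likelihood, steps, starts, resets, IC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lcvar.data import CovariateSpec, Schedule, build_design, standardize
from lcvar.model import (
    FitConfig,
    VarClusterModel,
    conditional_loglik,
    count_parameters,
    e_step,
    fit_grid,
    information_criteria,
    m_step,
    pseudo_random_start,
    rational_start,
    reset_degenerate,
    run_em,
)
from lcvar.synthetic import (
    SimulationSpec, flat_profiles, make_var_params, simulate_panel,
)
from conftest import make_panel


def _univariate_design(series, lag=1):
    vals = np.asarray(series, dtype=float)[:, None] * 10 + 50  # park on 0-100
    panel = make_panel({"p": vals}, schedule=Schedule(max(1, len(vals) // 6 + 1), 6))
    panel.data.loc[:, "item_1"] = np.asarray(series, dtype=float)
    from lcvar.data import EmaPanel

    # bypass slider-range validation: likelihood tests work on model scale
    return build_design(panel, lag, CovariateSpec(beep_indicators=False))


def _model(lag, A, B, Sigma, pi=1.0):
    A = [np.atleast_2d(np.asarray(a, dtype=float)) for a in A]
    return VarClusterModel(lag=lag, A=A, B=np.atleast_2d(B), Sigma=np.atleast_2d(Sigma), pi=pi)


class TestConditionalLoglik:
    def test_univariate_hand_computed(self):
        design = _univariate_design([0.0, 1.0, 0.5])
        model = _model(1, [[0.5]], [[0.0]], [[1.0]])
        # residuals 1 - 0.5*0 = 1 and 0.5 - 0.5*1 = 0 under N(0, 1)
        expected = -0.5 * np.log(2 * np.pi) * 2 - 0.5 * (1.0 + 0.0)
        assert conditional_loglik(design, model) == pytest.approx(expected)
        assert conditional_loglik(design, model) == pytest.approx(-2.337877, abs=1e-6)

    def test_zero_residual_closed_form(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, (13, 2))
        panel = make_panel({"p": vals}, schedule=Schedule(3, 6))
        design = build_design(panel, 1, CovariateSpec(beep_indicators=False))
        # model that interpolates exactly: A=0, intercept = outcome? impossible;
        # instead set Sigma=I and compute via residuals directly
        model = _model(1, [np.zeros((2, 2))], np.zeros((2, 1)), np.eye(2))
        resid = design.outcomes
        expected = -0.5 * (2 * np.log(2 * np.pi) * len(resid) + (resid**2).sum())
        assert conditional_loglik(design, model) == pytest.approx(expected)

    def test_inflating_sigma_decreases_loglik_at_zero_residual(self):
        vals = np.full((12, 2), 50.0)
        panel = make_panel({"p": vals}, schedule=Schedule(2, 6))
        design = build_design(panel, 1, CovariateSpec(beep_indicators=False))
        A = [np.zeros((2, 2))]
        B = np.full((2, 1), 50.0)          # exact mean: residuals all zero
        ll1 = conditional_loglik(design, _model(1, A, B, np.eye(2)))
        ll2 = conditional_loglik(design, _model(1, A, B, 2 * np.eye(2)))
        assert ll2 < ll1


class TestESte:
    def _design(self, seed=0, n=6):
        m = make_var_params(2, 1, seed=seed)
        spec = SimulationSpec(
            n_participants=n, cluster_models=[m],
            cluster_proportions=np.array([1.0]),
            diurnal_profiles=flat_profiles(1, 6, 2),
            n_days=4, seed=seed, min_cluster_members=1,
        )
        panel, _ = simulate_panel(spec)
        return build_design(panel, 1)

    def test_identical_models_split_evenly(self):
        design = self._design()
        m = _model(1, [np.zeros((2, 2))], np.zeros((2, 5 + 1)), np.eye(2), pi=0.5)
        resp, _ = e_step(design, [m, m])
        np.testing.assert_allclose(resp, 0.5)

    def test_single_cluster_all_ones(self):
        design = self._design()
        m = _model(1, [np.zeros((2, 2))], np.zeros((2, 6)), np.eye(2), pi=1.0)
        resp, _ = e_step(design, [m])
        np.testing.assert_allclose(resp, 1.0)

    def test_well_separated_brute_force_oracle(self):
        # univariate participants around +5 and -5; two intercept-only models
        vals_hi = np.full((20, 1), 5.0)
        vals_lo = np.full((20, 1), -5.0)
        panel = make_panel({"hi": vals_hi + 50, "lo": vals_lo + 50},
                           schedule=Schedule(4, 6))
        design = build_design(panel, 1, CovariateSpec(beep_indicators=False))
        m_hi = _model(1, [[0.0]], [[55.0]], [[1.0]], pi=0.5)
        m_lo = _model(1, [[0.0]], [[45.0]], [[1.0]], pi=0.5)
        resp, _ = e_step(design, [m_hi, m_lo])

        # brute-force normalized likelihoods per participant
        def loglik(y, mean):
            r = y - mean
            return float(-0.5 * (np.log(2 * np.pi) * len(r) + (r**2).sum()))

        for i, pid in enumerate(design.participant_ids):
            rows = design.row_participant == pid
            y = design.outcomes[rows, 0]
            l1, l2 = loglik(y, 55.0), loglik(y, 45.0)
            w = np.exp(l1 - np.logaddexp(l1, l2))
            assert resp[i, 0] == pytest.approx(w, abs=1e-6)
            assert min(resp[i, 0], 1.0 - resp[i, 0]) < 1e-6

    def test_extreme_loglik_differences_no_overflow(self):
        design = self._design()
        m1 = _model(1, [np.zeros((2, 2))], np.zeros((2, 6)), np.eye(2), pi=0.5)
        m2 = _model(1, [np.zeros((2, 2))], np.full((2, 6), 500.0), np.eye(2), pi=0.5)
        resp, ll = e_step(design, [m1, m2])
        assert np.isfinite(ll)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-10)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_rows_always_normalized(self, seed):
        design = self._design(seed=seed % 7, n=4)
        rng = np.random.default_rng(seed)
        models = [
            _model(1, [rng.normal(0, 0.2, (2, 2))], rng.normal(0, 1, (2, 6)),
                   np.eye(2), pi=p)
            for p in (0.3, 0.7)
        ]
        resp, _ = e_step(design, models)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_uniform_weights_match_ols_normal_equations(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        design = build_design(panel, 1, CovariateSpec(beep_indicators=False))
        resp = np.ones((len(design.participant_ids), 1))
        (model,), props = m_step(design, resp, [1])
        X, Y = design.predictors, design.outcomes
        C = np.linalg.solve(X.T @ X, X.T @ Y)          # direct normal equations
        np.testing.assert_allclose(model.coefficient_matrix(), C, atol=1e-8)
        assert props[0] == pytest.approx(1.0)

    def test_zero_noise_exact_recovery(self):
        A = np.array([[0.5, 0.2], [-0.1, 0.4]])
        c = np.array([30.0, 20.0])
        x = np.zeros((30, 2))
        x[0] = [50.0, 40.0]
        for t in range(1, 30):
            x[t] = c + A @ x[t - 1]
        panel = make_panel({"p": x}, schedule=Schedule(5, 6))
        design = build_design(panel, 1, CovariateSpec(beep_indicators=False))
        resp = np.ones((1, 1))
        (model,), _ = m_step(design, resp, [1])
        np.testing.assert_allclose(model.A[0], A, atol=1e-8)
        np.testing.assert_allclose(model.B[:, 0], c, atol=1e-6)

    def test_duplicating_every_participant_leaves_estimates_unchanged(
        self, two_cluster_panel
    ):
        panel, _, _ = two_cluster_panel
        doubled = panel.data.copy()
        doubled["participant_id"] = doubled["participant_id"] + "_copy"
        import pandas as pd
        from lcvar.data import EmaPanel

        big = EmaPanel(
            pd.concat([panel.data, doubled], ignore_index=True),
            panel.schedule, panel.variable_names,
        )
        d1 = build_design(panel, 1)
        d2 = build_design(big, 1)
        r1 = np.ones((len(d1.participant_ids), 1))
        r2 = np.ones((len(d2.participant_ids), 1))
        (m1,), _ = m_step(d1, r1, [1])
        (m2,), _ = m_step(d2, r2, [1])
        np.testing.assert_allclose(m1.A[0], m2.A[0], atol=1e-10)
        np.testing.assert_allclose(m1.Sigma, m2.Sigma, atol=1e-10)


class TestStarts:
    def test_pseudo_random_k1_assigns_everyone(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        design = build_design(panel, 1)
        resp = pseudo_random_start(design, 1, np.random.default_rng(0))
        np.testing.assert_allclose(resp, 1.0)

    def test_pseudo_random_deterministic_under_seed(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        design = build_design(panel, 1)
        a = pseudo_random_start(design, 2, np.random.default_rng(7))
        b = pseudo_random_start(design, 2, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_pseudo_random_k_exceeding_n_fails(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        design = build_design(panel, 1)
        with pytest.raises(ValueError, match="exceeds"):
            pseudo_random_start(design, 99, np.random.default_rng(0))

    def test_pseudo_random_separates_opposite_dynamics(self, two_cluster_panel):
        panel, truth, _ = two_cluster_panel
        z, _ = standardize(panel)
        design = build_design(z, 1)
        best = 0.0
        for seed in range(10):
            resp = pseudo_random_start(design, 2, np.random.default_rng(seed))
            assign = np.argmax(resp, axis=1)
            tru = np.array([truth.labels[p] for p in design.participant_ids])
            acc = max(np.mean(assign == tru), np.mean(assign != tru))
            best = max(best, acc)
        assert best >= 0.9

    def test_rational_start_separable_blobs(self):
        # long series + strong opposite cross-effects: the per-participant
        # coefficient vectors form two blobs many SEs apart
        m1 = make_var_params(2, 1, cross_effect=0.6, seed=1, noise_scale=0.0,
                             cross_pairs=[(0, 1, 1.0), (1, 0, 1.0)])
        m2 = make_var_params(2, 1, cross_effect=0.6, seed=2, noise_scale=0.0,
                             cross_pairs=[(0, 1, -1.0), (1, 0, -1.0)])
        spec = SimulationSpec(
            n_participants=16, cluster_models=[m1, m2],
            cluster_proportions=np.array([0.5, 0.5]),
            diurnal_profiles=flat_profiles(2, 6, 2), n_days=40, seed=6,
        )
        panel, truth = simulate_panel(spec)
        z, _ = standardize(panel)
        design = build_design(z, 1)
        resp = rational_start(design, 2, np.random.default_rng(1))
        assign = np.argmax(resp, axis=1)
        tru = np.array([truth.labels[p] for p in design.participant_ids])
        acc = max(np.mean(assign == tru), np.mean(assign != tru))
        assert acc >= 0.9

    def test_rational_start_degenerate_falls_back(self):
        vals = np.tile(np.linspace(10, 90, 12)[:, None], (1, 2))
        panel = make_panel({f"p{i}": vals for i in range(4)},
                           schedule=Schedule(2, 6))
        design = build_design(panel, 1, CovariateSpec(beep_indicators=False))
        with pytest.warns(UserWarning, match="pseudo-random"):
            resp = rational_start(design, 2, np.random.default_rng(0))
        assert resp.shape == (4, 2)


class TestResetDegenerate:
    def test_zero_sigma_becomes_all_tens_pd_projected(self):
        m = _model(1, [np.zeros((2, 2))], np.zeros((2, 1)), np.zeros((2, 2)))
        out = reset_degenerate(m, 10.0)
        # literal rule: 0 + 10 everywhere, then nearest-PD projection
        target = np.full((2, 2), 10.0)
        assert np.linalg.norm(out.Sigma - target) < 1e-3
        assert np.linalg.eigvalsh(out.Sigma).min() > 0

    def test_identity_plus_ten_ones_eigenvalues(self):
        m = _model(1, [np.zeros((2, 2))], np.zeros((2, 1)), np.eye(2))
        out = reset_degenerate(m, 10.0)
        evals = np.sort(np.linalg.eigvalsh(out.Sigma))
        np.testing.assert_allclose(evals, [1.0, 21.0], atol=1e-9)

    def test_zero_increment_keeps_sigma(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        m = _model(1, [np.zeros((2, 2))], np.zeros((2, 1)), S)
        out = reset_degenerate(m, 0.0)
        np.testing.assert_allclose(out.Sigma, S, atol=1e-12)


class TestRunEm:
    def test_single_cluster_monotone_trace(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        design = build_design(panel, 1)
        cfg = FitConfig(k_min=1, k_max=1, lag_min=1, lag_max=1, min_members=1)
        resp0 = np.ones((len(design.participant_ids), 1))
        fit = run_em(design, 1, [1], resp0, cfg)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert fit.converged

    def test_two_separated_clusters_recovered_exactly(self, two_cluster_panel):
        from sklearn.metrics import adjusted_rand_score

        panel, truth, _ = two_cluster_panel
        z, _ = standardize(panel)
        design = build_design(z, 1)
        cfg = FitConfig(k_min=2, k_max=2, lag_min=1, lag_max=1, seed=3)
        resp0 = pseudo_random_start(design, 2, np.random.default_rng(3))
        fit = run_em(design, 2, [1, 1], resp0, cfg)
        labs = [fit.hard_labels[p] for p in design.participant_ids]
        tru = [truth.labels[p] for p in design.participant_ids]
        assert adjusted_rand_score(tru, labs) == 1.0

    def test_loglik_invariant_under_label_permutation(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        z, _ = standardize(panel)
        design = build_design(z, 1)
        cfg = FitConfig(k_min=2, k_max=2, lag_min=1, lag_max=1, seed=3)
        resp0 = pseudo_random_start(design, 2, np.random.default_rng(3))
        fit = run_em(design, 2, [1, 1], resp0, cfg)
        swapped = [fit.clusters[1], fit.clusters[0]]
        _, ll = e_step(design, swapped)
        assert ll == pytest.approx(fit.loglik, abs=1e-8)
        q = count_parameters(swapped)
        hqc, aic = information_criteria(ll, q, fit.n_modeled_rows)
        assert hqc == pytest.approx(fit.hqc, abs=1e-10)
        assert aic == pytest.approx(fit.aic, abs=1e-10)

    def test_responsibilities_rows_sum_to_one(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        z, _ = standardize(panel)
        design = build_design(z, 1)
        cfg = FitConfig(seed=5)
        resp0 = pseudo_random_start(design, 2, np.random.default_rng(5))
        fit = run_em(design, 2, [1, 1], resp0, cfg)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-10)


class TestCountParameters:
    def test_minimal_univariate(self):
        m = _model(1, [[0.5]], [[0.0]], [[1.0]])
        assert count_parameters([m]) == 3          # 1 AR + 1 intercept + 1 var

    def test_two_cluster_formula(self):
        ms = [_model(1, [np.zeros((2, 2))], np.zeros((2, 1)), np.eye(2))] * 2
        assert count_parameters(ms) == 2 * (4 + 2 + 3) + 1

    def test_large_mixture_hand_count(self):
        # K=3, d=14, p=3, intercept + 5 covariates
        ms = [
            _model(3, [np.zeros((14, 14))] * 3, np.zeros((14, 6)), np.eye(14))
        ] * 3
        per_cluster = 14 * 14 * 3 + 14 * 6 + 14 * 15 // 2
        assert count_parameters(ms) == 3 * per_cluster + 2


class TestInformationCriteria:
    def test_zero_params_reduces_to_scaled_deviance(self):
        hqc, aic = information_criteria(-100.0, 0, 50)
        assert hqc == pytest.approx(200.0 / 50)
        assert aic == pytest.approx(200.0 / 50)

    def test_penalty_strictly_increases_with_q(self):
        h1, a1 = information_criteria(-100.0, 5, 50)
        h2, a2 = information_criteria(-100.0, 6, 50)
        assert h2 > h1 and a2 > a1

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError, match="ln"):
            information_criteria(-1.0, 1, 2)


class TestFitGrid:
    def test_single_cell_equals_plain_var(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        cfg = FitConfig(k_min=1, k_max=1, lag_min=1, lag_max=1,
                        min_members=1, n_pseudo_random_starts=2, seed=0)
        grid = fit_grid(panel, cfg)
        design = build_design(panel, 1)
        resp = np.ones((len(design.participant_ids), 1))
        (direct,), _ = m_step(design, resp, [1])
        np.testing.assert_allclose(
            grid.selected.clusters[0].A[0], direct.A[0], atol=1e-6
        )

    def test_selected_is_hqc_argmin(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        z, _ = standardize(panel)
        cfg = FitConfig(k_min=2, k_max=2, lag_min=1, lag_max=2,
                        n_pseudo_random_starts=3, seed=1)
        grid = fit_grid(z, cfg)
        hqcs = [c.fit.hqc for c in grid.cells if c.fit is not None]
        assert grid.selected.hqc == pytest.approx(min(hqcs))

    def test_heterogeneous_lag_vectors_canonical(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        z, _ = standardize(panel)
        cfg = FitConfig(k_min=2, k_max=2, lag_min=1, lag_max=2,
                        n_pseudo_random_starts=2, seed=2,
                        heterogeneous_lags=True)
        grid = fit_grid(z, cfg)
        seen = [c.lags for c in grid.cells]
        assert seen == [(1, 1), (1, 2), (2, 2)]
        for lags in seen:
            assert list(lags) == sorted(lags)
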