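"""Weighted NMF solver, Qexp, factor scan, diagnostics, matching."""

import numpy as np
import pandas as pd
import pytest

from sourcerisk.receptor_model import (FactorScan, best_fit, fit,
                                       match_factors, model_fit_stats,
                                       q_expected, scan_factors)


def _random_instance(rng, n=30, m=6, K=2, noise=0.0):
    G0 = rng.uniform(0.5, 2.0, size=(n, K))
    F0 = rng.uniform(0.1, 1.0, size=(K, m))
    X = G0 @ F0
    if noise:
        X = np.clip(X + rng.normal(0, noise, X.shape), 0, None)
    U = np.full_like(X, 0.1)
    return X, U, G0, F0


class TestQExpected:
    def test_paper_scale_dimensions_by_hand_arithmetic(self):
        assert q_expected(2622, 26, 7) == 68172 - 18536 == 49636

    def test_no_parameters_gives_nm(self):
        assert q_expected(10, 5, 0) == 50

    def test_strictly_decreasing_in_k(self):
        vals = [q_expected(100, 10, k) for k in range(5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_overparameterized_rejected(self):
        with pytest.raises(ValueError, match="over-parameterized"):
            q_expected(10, 4, 3)


class TestFit:
    def test_noiseless_data_recovered_to_near_zero_q(self, rng):
        X, U, _, _ = _random_instance(rng, n=20, m=5, K=2)
        model = fit(X, U, K=2, seed=0, max_iter=20000, tol=1e-12)
        assert model.Q < 1e-6 * model.Qexp
        assert np.all(model.G >= 0) and np.all(model.F >= 0)

    def test_rank_one_matrix_reconstructed_exactly(self, rng):
        a, b = rng.uniform(1, 2, 15), rng.uniform(1, 2, 6)
        X = np.outer(a, b)
        model = fit(X, np.full_like(X, 0.1), K=1, seed=0, max_iter=20000, tol=1e-13)
        rel = np.abs(model.reconstruct() - X) / X
        assert rel.max() < 1e-6

    def test_deterministic_given_seed(self, rng):
        X, U, _, _ = _random_instance(rng, noise=0.1)
        m1 = fit(X, U, K=2, seed=7, max_iter=500)
        m2 = fit(X, U, K=2, seed=7, max_iter=500)
        assert np.array_equal(m1.G, m2.G) and np.array_equal(m1.F, m2.F)

    def test_objective_never_increases(self, rng):
        X, U, _, _ = _random_instance(rng, noise=0.2)
        model = fit(X, U, K=3, seed=1, max_iter=800, check_monotone=True,
                    track_history=True)
        diffs = np.diff(model.q_history)
        assert np.all(diffs <= 1e-9 * model.q_history[:-1] + 1e-12)

    def test_profile_rows_normalized_over_mass_species(self, rng):
        X, U, _, _ = _random_instance(rng, noise=0.1)
        model = fit(X, U, K=2, seed=0, max_iter=500)
        np.testing.assert_allclose(model.F.sum(axis=1), 1.0, atol=1e-9)

    def test_column_scaling_invariance_of_q(self, rng):
        # scaling one species' data and uncertainty leaves the scaled
        # residuals, and hence Q, unchanged
        X, U, _, _ = _random_instance(rng, noise=0.1)
        m1 = fit(X, U, K=2, seed=3, max_iter=1000)
        Xs, Us = X.copy(), U.copy()
        Xs[:, 0] *= 37.0
        Us[:, 0] *= 37.0
        m2 = fit(Xs, Us, K=2, seed=3, max_iter=1000)
        assert m2.Q == pytest.approx(m1.Q, rel=1e-8)

    def test_invalid_inputs_rejected(self, rng):
        X, U, _, _ = _random_instance(rng)
        with pytest.raises(ValueError, match="positive"):
            fit(X, np.zeros_like(U), K=2)
        with pytest.raises(ValueError, match="finite"):
            fit(X * np.nan, U, K=2)
        with pytest.raises(ValueError, match="K"):
            fit(X, U, K=7)

    def test_nonconvergence_warns_and_flags(self, rng):
        X, U, _, _ = _random_instance(rng, noise=0.2)
        with pytest.warns(RuntimeWarning, match="converge"):
            model = fit(X, U, K=2, seed=0, max_iter=3)
        assert not model.converged


class TestScan:
    def test_best_q_nonincreasing_in_k(self, rng):
        X, U, _, _ = _random_instance(rng, n=40, m=8, K=3, noise=0.3)
        scan = scan_factors(X, U, k_min=1, k_max=4, n_starts=10, seed=0,
                            max_iter=2000)
        qs = scan.table.sort_values("K")["Q"].to_numpy()
        assert np.all(np.diff(qs) <= 1e-6 * qs[:-1])

    def test_elbow_rule_selects_before_flattening(self):
        # trajectory that flattens between 7 and 8 factors
        ratios = [12.9, 9.0, 6.0, 4.0, 3.0, 2.4, 1.95, 1.93, 1.92, 1.91]
        table = pd.DataFrame({"K": range(1, 11), "Q": ratios,
                              "Qexp": 1.0, "q_ratio": ratios,
                              "n_converged": 10})
        assert FactorScan(table).select_k(threshold=0.10) == 7

    def test_elbow_falls_back_to_largest_k(self):
        ratios = [10.0, 5.0, 2.0]
        table = pd.DataFrame({"K": [1, 2, 3], "Q": ratios, "Qexp": 1.0,
                              "q_ratio": ratios, "n_converged": 10})
        assert FactorScan(table).select_k(threshold=0.10) == 3


class TestDiagnostics:
    def test_perfect_reconstruction_has_unit_slope_and_r2(self, rng):
        X, U, G0, F0 = _random_instance(rng)
        model = fit(X, U, K=2, seed=0, max_iter=20000, tol=1e-12)
        slope, r2 = model_fit_stats(X, model)
        assert slope == pytest.approx(1.0, abs=1e-5)
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_half_scale_reconstruction_detected(self, rng):
        X, U, G0, F0 = _random_instance(rng)
        model = fit(X, U, K=2, seed=0, max_iter=5000)
        model.G = model.G * 0.5
        slope, r2 = model_fit_stats(X, model)
        assert slope == pytest.approx(0.5, abs=0.01)
        assert r2 > 0.999

    def test_degenerate_input_rejected(self, rng):
        X = np.ones((5, 3))
        model = fit(X, np.full_like(X, 0.1), K=1, seed=0, max_iter=200)
        with pytest.raises(ValueError, match="degenerate"):
            model_fit_stats(X * 0 + 1, model)


class TestMatching:
    def test_identity_match(self, rng):
        F = rng.uniform(0, 1, size=(4, 6))
        perm, sims = match_factors(F, F)
        assert np.array_equal(perm, np.arange(4))
        np.testing.assert_allclose(sims, 1.0, atol=1e-12)

    def test_row_permutation_recovered(self, rng):
        F = rng.uniform(0, 1, size=(5, 7))
        p = rng.permutation(5)
        perm, sims = match_factors(F[p], F)
        assert np.array_equal(perm, p)
        np.testing.assert_allclose(sims, 1.0, atol=1e-12)

    def test_unrelated_profiles_report_without_error(self, rng):
        A = rng.uniform(0, 1, size=(3, 8))
        B = rng.uniform(0, 1, size=(3, 8))
        perm, sims = match_factors(A, B)
        assert sorted(perm) == [0, 1, 2]
        assert np.all((0 <= sims) & (sims <= 1 + 1e-12))


class TestBestFit:
    def test_best_of_starts_takes_lowest_q(self, rng):
        X, U, _, _ = _random_instance(rng, noise=0.2)
        model = best_fit(X, U, K=2, n_starts=5, seed=0, max_iter=1500)
        assert model.Q == pytest.approx(model.all_q.min())
        assert model.n_converged >= 1
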