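import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from nestscape.mlpe import (
    MODEL_SET,
    aicc,
    effect_signs,
    enumerate_pairs,
    fit_mlpe,
    rank_model_set,
)


def incidence_matrix(pairs: pd.DataFrame, n_individuals: int) -> np.ndarray:
    Z = np.zeros((len(pairs), n_individuals))
    Z[np.arange(len(pairs)), pairs["i_index"]] = 1.0
    Z[np.arange(len(pairs)), pairs["j_index"]] = 1.0
    return Z


def dense_loglik(y, X_design, pairs, n_ind, beta, sigma_u2, sigma_e2):
    """Independent oracle: direct multivariate-normal density with
    V = sigma_u^2 Z Z' + sigma_e^2 I."""
    Z = incidence_matrix(pairs, n_ind)
    V = sigma_u2 * Z @ Z.T + sigma_e2 * np.eye(len(y))
    return multivariate_normal.logpdf(y, mean=X_design @ beta, cov=V)


def dense_profile_loglik(y, X_design, pairs, n_ind, theta):
    """Profiled ML at fixed theta via dense GLS (the grid-search oracle)."""
    Z = incidence_matrix(pairs, n_ind)
    W = np.eye(len(y)) + theta * Z @ Z.T
    Wi = np.linalg.inv(W)
    beta = np.linalg.solve(X_design.T @ Wi @ X_design, X_design.T @ Wi @ y)
    r = y - X_design @ beta
    sigma_e2 = r @ Wi @ r / len(y)
    _, logdet = np.linalg.slogdet(W)
    return -0.5 * (len(y) * np.log(2 * np.pi * sigma_e2) + logdet + len(y)), beta, sigma_e2


def simulate_mlpe(pairs, x, beta0, beta, sigma_u, sigma_e, n_ind, seed):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sigma_u, n_ind)
    eps = rng.normal(0, sigma_e, len(pairs))
    return beta0 + beta * x + u[pairs["i_index"]] + u[pairs["j_index"]] + eps


class TestEnumeratePairs:
    @pytest.mark.parametrize("n,expected", [(103, 5253), (89, 3916)])
    def test_pair_count_arithmetic(self, n, expected):
        ind = pd.DataFrame(
            {"id": [f"i{k}" for k in range(n)],
             "location_id": [f"L{k}" for k in range(n)],
             "x": np.arange(n, dtype=float), "y": np.zeros(n)}
        )
        assert len(enumerate_pairs(ind)) == expected

    def test_within_location_exclusion_closed_form(self):
        m = 6
        ind = pd.DataFrame(
            {"id": [f"i{k}" for k in range(m + 3)],
             "location_id": ["same"] * m + ["a", "b", "c"],
             "x": np.arange(m + 3, dtype=float), "y": np.zeros(m + 3)}
        )
        pairs = enumerate_pairs(ind)
        assert (~pairs["included"]).sum() == m * (m - 1) // 2

    def test_single_individual_rejected(self):
        ind = pd.DataFrame({"id": ["a"], "location_id": ["L"], "x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError, match="two individuals"):
            enumerate_pairs(ind)


class TestAICc:
    def test_hand_arithmetic(self):
        assert aicc(-10.0, 3, 10) == pytest.approx(30.0)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 3, 10**9) == pytest.approx(20 + 6, abs=1e-6)

    def test_penalty_monotone_in_k(self):
        assert aicc(-10.0, 4, 20) > aicc(-10.0, 3, 20)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n=4"):
            aicc(-10.0, 3, 4)


@pytest.fixture
def toy_problem():
    """4 individuals, 6 pairs — small enough for dense oracles."""
    ind = pd.DataFrame(
        {"id": list("abcd"), "location_id": list("ABCD"),
         "x": [0.0, 1.0, 2.0, 3.0], "y": [0.0, 0.0, 0.0, 0.0]}
    )
    pairs = enumerate_pairs(ind)
    rng = np.random.default_rng(3)
    x = rng.normal(size=6)
    y = simulate_mlpe(pairs, x, 1.0, 2.0, sigma_u=0.7, sigma_e=0.5, n_ind=4, seed=10)
    return pairs, x, y


class TestFitMLPE:
    def test_zero_theta_limit_matches_ols(self, scattered_pairs):
        rng = np.random.default_rng(0)
        x = rng.normal(size=len(scattered_pairs))
        y = 3.0 + 1.2 * x + rng.normal(0, 0.4, len(scattered_pairs))
        fit = fit_mlpe(y, pd.DataFrame({"x": x}), scattered_pairs, standardize=False)
        A = np.column_stack([np.ones_like(x), x])
        beta_ols = np.linalg.lstsq(A, y, rcond=None)[0]
        assert fit.coefficients["(Intercept)"] == pytest.approx(beta_ols[0], abs=1e-4)
        assert fit.coefficients["x"] == pytest.approx(beta_ols[1], abs=1e-4)
        assert fit.theta < 0.05

    def test_loglik_matches_dense_mvn_oracle(self, toy_problem):
        pairs, x, y = toy_problem
        fit = fit_mlpe(y, pd.DataFrame({"x": x}), pairs, standardize=False)
        Xd = np.column_stack([np.ones(6), x])
        beta = np.array([fit.coefficients["(Intercept)"], fit.coefficients["x"]])
        ll = dense_loglik(y, Xd, pairs, 4, beta, fit.sigma_u2, fit.sigma_e2)
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-6)

    def test_profile_optimum_matches_grid_search_oracle(self, toy_problem):
        pairs, x, y = toy_problem
        fit = fit_mlpe(y, pd.DataFrame({"x": x}), pairs, standardize=False)
        Xd = np.column_stack([np.ones(6), x])
        # two-stage grid over the full profile domain, final step 1e-3
        coarse = np.arange(0.0, 50.0, 0.05)
        t0 = coarse[int(np.argmax([dense_profile_loglik(y, Xd, pairs, 4, t)[0] for t in coarse]))]
        fine = np.arange(max(0.0, t0 - 0.1), t0 + 0.1, 1e-3)
        lls = [dense_profile_loglik(y, Xd, pairs, 4, t)[0] for t in fine]
        theta_grid = fine[int(np.argmax(lls))]
        assert fit.log_likelihood >= max(lls) - 1e-9
        assert fit.theta == pytest.approx(theta_grid, abs=1e-3)

    def test_parameter_recovery_simulation(self, scattered_pairs):
        # truth: beta = 1, rho = 0.3 -> theta = sigma_u^2/sigma_e^2 with
        # sigma_u^2 = 0.3, sigma_e^2 = 0.4 (so 2*0.3+0.4 normalizes to 1)
        rng = np.random.default_rng(42)
        su, se = np.sqrt(0.3), np.sqrt(0.4)
        betas, rhos = [], []
        for rep in range(60):
            x = rng.normal(size=len(scattered_pairs))
            y = simulate_mlpe(scattered_pairs, x, 0.0, 1.0, su, se, 30, seed=rep)
            fit = fit_mlpe(y, pd.DataFrame({"x": x}), scattered_pairs, standardize=False)
            betas.append(fit.coefficients["x"])
            rhos.append(fit.rho)
        assert np.mean(betas) == pytest.approx(1.0, abs=0.05)
        assert np.mean(rhos) == pytest.approx(0.3, abs=0.05)

    def test_row_permutation_invariance(self, toy_problem):
        pairs, x, y = toy_problem
        fit = fit_mlpe(y, pd.DataFrame({"x": x}), pairs, standardize=False)
        perm = np.random.default_rng(0).permutation(len(y))
        fit_p = fit_mlpe(
            y[perm], pd.DataFrame({"x": x[perm]}), pairs.iloc[perm].reset_index(drop=True),
            standardize=False,
        )
        assert fit_p.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-8)
        assert fit_p.coefficients["x"] == pytest.approx(fit.coefficients["x"], abs=1e-8)

    def test_aicc_differences_invariant_to_response_shift(self, scattered_pairs):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=len(scattered_pairs))
        x2 = rng.normal(size=len(scattered_pairs))
        y = simulate_mlpe(scattered_pairs, x1, 0.0, 1.0, 0.5, 0.5, 30, seed=5)
        d0 = (fit_mlpe(y, pd.DataFrame({"a": x1}), scattered_pairs).aicc
              - fit_mlpe(y, pd.DataFrame({"b": x2}), scattered_pairs).aicc)
        d1 = (fit_mlpe(y + 100.0, pd.DataFrame({"a": x1}), scattered_pairs).aicc
              - fit_mlpe(y + 100.0, pd.DataFrame({"b": x2}), scattered_pairs).aicc)
        assert d0 == pytest.approx(d1, abs=1e-6)

    def test_rank_deficient_design_rejected(self, scattered_pairs):
        x = np.random.default_rng(0).normal(size=len(scattered_pairs))
        with pytest.raises(ValueError, match="rank|constant"):
            fit_mlpe(np.ones(len(scattered_pairs)), pd.DataFrame({"a": x, "b": x}), scattered_pairs)

    def test_rho_within_theoretical_bound(self, toy_problem):
        pairs, x, y = toy_problem
        fit = fit_mlpe(y, pd.DataFrame({"x": x}), pairs, standardize=False)
        assert 0.0 <= fit.rho <= 0.5


class TestRankModelSet:
    def _predictors(self, pairs, seed=0):
        rng = np.random.default_rng(seed)
        return {k: rng.normal(size=len(pairs)) for k in "AHPMW"}

    def test_leaderboard_has_ten_sorted_rows(self, scattered_pairs):
        preds = self._predictors(scattered_pairs)
        gd = np.random.default_rng(9).normal(size=len(scattered_pairs))
        y = np.random.default_rng(10).normal(size=len(scattered_pairs))
        board, fits = rank_model_set(y, preds, gd, scattered_pairs)
        assert len(board) == len(fits) == 10
        assert board["aicc"].is_monotonic_increasing
        assert set(board["model"]) == set(MODEL_SET)
        assert all(v.startswith("GD") for v in board["variables"])

    def test_noise_predictor_raises_k_but_not_fit(self, scattered_pairs):
        rng = np.random.default_rng(3)
        gd = rng.normal(size=len(scattered_pairs))
        y = 2.0 * gd + rng.normal(0, 1.0, len(scattered_pairs))
        preds = self._predictors(scattered_pairs, seed=4)
        board, fits = rank_model_set(y, preds, gd, scattered_pairs)
        ibd = fits["Isolation by distance"]
        agri = fits["Agriculture only"]
        assert agri.log_likelihood >= ibd.log_likelihood - 1e-8
        assert agri.k == ibd.k + 1

    def test_missing_predictor_rejected(self, scattered_pairs):
        with pytest.raises(KeyError, match="missing"):
            rank_model_set(
                np.zeros(len(scattered_pairs)), {"A": np.zeros(len(scattered_pairs))},
                np.zeros(len(scattered_pairs)), scattered_pairs,
            )


class TestEffectSigns:
    def _fit_with(self, coefs):
        from nestscape.mlpe import MLPEFit

        all_coefs = {"(Intercept)": 0.0, "GD": 0.5, **coefs}
        return MLPEFit(
            coefficients=all_coefs, sigma_u2=0.1, sigma_e2=0.1, log_likelihood=0.0,
            k=len(all_coefs) + 2, n=100, aicc=0.0, theta=1.0,
            predictor_names=tuple(c for c in all_coefs if c != "(Intercept)"),
            standardized=True,
        )

    def test_published_sparse_large_ordering(self):
        # standardized coefficients of a published best-fit model
        fit = self._fit_with({"W": 0.91, "A": 0.69, "H": 0.65, "M": -0.43, "P": -0.25})
        df = effect_signs(fit)
        assert df["class"].tolist() == ["W", "A", "H", "M", "P"]
        assert df.set_index("class")["label"].to_dict() == {
            "W": "restriction", "A": "restriction", "H": "restriction",
            "M": "facilitation", "P": "facilitation",
        }

    def test_all_positive_means_no_facilitation(self):
        fit = self._fit_with({"A": 0.2, "B": 0.9})
        assert (effect_signs(fit)["label"] == "restriction").all()

    def test_tie_breaks_by_class_name_and_flags(self):
        fit = self._fit_with({"B": 0.5, "A": -0.5})
        df = effect_signs(fit)
        assert df["class"].tolist() == ["A", "B"]
        assert df["tied"].all()

    def test_zero_coefficient_ranks_last(self):
        fit = self._fit_with({"A": 0.0, "B": 0.1})
        df = effect_signs(fit)
        assert df.iloc[-1]["class"] == "A" and df.iloc[-1]["sign"] == "0"
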