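"""Design assembly and the Bernoulli log-link point-process fit."""
import numpy as np
import pytest
from scipy.optimize import minimize

import naaglm as na
from conftest import all_light_hypnogram
from naaglm.glm import STAGE_COLUMNS


@pytest.fixture(scope="module")
def basis():
    return na.build_history_basis(None)


def small_design(basis, seed=0, n_bins=2000, rate=0.02):
    # rate 0.02/bin -> mean gap 50 s, so lags populate the full 120-s
    # history window and every spline coefficient is identified
    """A compact design with plenty of events for optimisation checks."""
    rng = np.random.default_rng(seed)
    hyp = all_light_hypnogram(n_bins / 3600.0)
    # wide covariate windows so both indicators cover several events
    # (narrow windows risk quasi-separation and a divergent coefficient)
    events = [na.EventInterval(200.0, 900.0, na.EventKind.OSA),
              na.EventInterval(1000.0, 1700.0, na.EventKind.AROUSAL)]
    onsets = []
    t = 130.5
    while t < n_bins:
        gap = rng.exponential(1.0 / rate)
        t += max(np.round(gap), 1.0)
        if t < n_bins:
            onsets.append(t)
    train = na.NAAEventTrain(np.array(onsets))
    return na.build_design(train, hyp, events, basis,
                           window=(0.0, float(n_bins)))


class TestBuildDesign:
    def test_all_light_no_events_covariate_block(self, basis):
        hyp = all_light_hypnogram(2.0)
        train = na.NAAEventTrain(np.array([500.5, 900.5]))
        D = na.build_design(train, hyp, [], basis, window=(0.0, 7200.0))
        block = D.X[:, :6]
        # LIGHT indicator on, all other stage + SDB/arousal columns off
        assert np.allclose(block[:, 1], 1.0)
        assert np.allclose(np.delete(block, 1, axis=1), 0.0)

    def test_history_columns_follow_lag_and_window(self, basis):
        hyp = all_light_hypnogram(2.0)
        train = na.NAAEventTrain(np.array([200.0]))
        D = na.build_design(train, hyp, [], basis, window=(0.0, 7200.0))
        i230 = np.flatnonzero(D.bin_start == 230.0)[0]
        expected = basis.evaluate(230.5 - 200.0)
        assert np.allclose(D.X[i230, 6:], expected)
        i330 = np.flatnonzero(D.bin_start == 330.0)[0]
        assert np.allclose(D.X[i330, 6:], 0.0)  # lag 130.5 s > window

    def test_row_count_and_burn_in(self, basis):
        hyp = all_light_hypnogram(2.0)
        train = na.NAAEventTrain(np.array([500.5]))
        D = na.build_design(train, hyp, [], basis, window=(0.0, 7200.0))
        assert D.n_bins == 7200
        assert int(D.include.sum()) == 7200 - 120

    def test_two_onsets_in_one_bin_rejected(self, basis):
        hyp = all_light_hypnogram(1.0)
        train = na.NAAEventTrain(np.array([500.2, 500.7]))
        with pytest.raises(ValueError, match="one bin"):
            na.build_design(train, hyp, [], basis, window=(0.0, 3600.0))

    def test_onset_on_bin_edge_belongs_to_right_bin(self, basis):
        hyp = all_light_hypnogram(1.0)
        train = na.NAAEventTrain(np.array([500.0]))
        D = na.build_design(train, hyp, [], basis, window=(0.0, 3600.0))
        assert D.y[500] == 1.0 and D.y[499] == 0.0

    def test_sdb_indicator_marks_overlapping_bins(self, basis):
        hyp = all_light_hypnogram(1.0)
        events = [na.EventInterval(100.25, 102.5, na.EventKind.HYPOPNEA)]
        D = na.build_design(na.NAAEventTrain(np.array([500.5])), hyp, events,
                            basis, window=(0.0, 3600.0))
        sdb = D.X[:, 4]
        assert sdb[100] == 1.0 and sdb[102] == 1.0
        assert sdb[99] == 0.0 and sdb[103] == 0.0

    def test_full_column_rank_on_generic_data(self, night, basis):
        D = na.build_design(night.train, night.hypnogram, night.events, basis)
        X = D.X[D.include]
        keep = ~np.all(X == 0.0, axis=0)
        assert np.linalg.matrix_rank(X[:, keep]) == keep.sum()


class TestFit:
    def test_constant_rate_closed_form(self):
        # single retained column: MLE log-rate = log(events / bins)
        rng = np.random.default_rng(0)
        n = 5000
        y = (rng.random(n) < 0.03).astype(float)
        X = np.ones((n, 1))
        m = na.PointProcessGLM().fit(X, y)
        assert abs(m.coef_[0] - np.log(y.mean())) < 1e-6

    def test_row_permutation_leaves_estimates_unchanged(self, basis):
        D = small_design(basis, seed=1)
        mask = D.include
        X, y = D.X[mask], D.y[mask]
        m1 = na.PointProcessGLM().fit(X, y, D.column_names)
        perm = np.random.default_rng(2).permutation(y.size)
        m2 = na.PointProcessGLM().fit(X[perm], y[perm], D.column_names)
        assert np.max(np.abs(m1.coef_ - m2.coef_)) < 1e-10

    def test_matches_generic_likelihood_optimizer(self, basis):
        D = small_design(basis, seed=3)
        mask = D.include
        m = na.PointProcessGLM().fit(D.X[mask], D.y[mask], D.column_names)
        keep = [i for i, c in enumerate(D.column_names) if c in m.column_names_]
        X, y = D.X[mask][:, keep], D.y[mask]

        def nll(theta):
            eta = X @ theta
            if np.any(eta[y == 0.0] >= 0.0):
                return 1e12
            return -(eta[y == 1.0].sum() + np.log1p(-np.exp(eta[y == 0.0])).sum())

        def grad(theta):
            eta = X @ theta
            p = np.exp(np.minimum(eta, -1e-12))
            g = np.where(y == 1.0, 1.0, -p / (1.0 - p))
            return -(X.T @ g)

        res = minimize(nll, m.coef_ + 0.05, jac=grad, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        assert np.max(np.abs(res.x - m.coef_)) < 1e-6

    def test_loglik_not_below_null_model(self, basis):
        D = small_design(basis, seed=4)
        mask = D.include
        m = na.PointProcessGLM().fit(D.X[mask], D.y[mask], D.column_names)
        rate = D.y[mask].mean()
        null_ll = (D.y[mask].sum() * np.log(rate)
                   + (mask.sum() - D.y[mask].sum()) * np.log1p(-rate))
        assert m.log_likelihood_ >= null_ll - 1e-9

    def test_all_zero_columns_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        y = (rng.random(3000) < 0.02).astype(float)
        X = np.column_stack([np.ones(3000), np.zeros(3000)])
        with pytest.warns(UserWarning, match="all-zero"):
            m = na.PointProcessGLM().fit(X, y, ("c", "z"))
        assert m.column_names_ == ("c",)

    def test_few_events_flagged_unreliable(self):
        y = np.zeros(2000)
        y[[100, 500]] = 1.0
        with pytest.warns(UserWarning, match="unreliable"):
            m = na.PointProcessGLM().fit(np.ones((2000, 1)), y)
        assert not m.reliable_

    def test_covariance_symmetric_psd(self, fitted_night):
        _, m = fitted_night
        C = m.covariance_
        assert np.allclose(C, C.T)
        assert np.min(np.linalg.eigvalsh(C)) > -1e-10

    def test_coefficients_match_statsmodels_glm(self, basis):
        # independent route: statsmodels Binomial GLM with log link
        import statsmodels.api as sm

        D = small_design(basis, seed=6)
        mask = D.include
        m = na.PointProcessGLM().fit(D.X[mask], D.y[mask], D.column_names)
        keep = [i for i, c in enumerate(D.column_names) if c in m.column_names_]
        glm = sm.GLM(
            D.y[mask], D.X[mask][:, keep],
            family=sm.families.Binomial(link=sm.families.links.Log()),
        )
        res = glm.fit(start_params=m.coef_, maxiter=200, tol=1e-10)
        assert np.max(np.abs(res.params - m.coef_)) < 1e-4

    def test_covariance_is_inverse_observed_information(self, basis):
        # oracle: numerical Hessian of the analytic gradient at the optimum
        D = small_design(basis, seed=6)
        mask = D.include
        m = na.PointProcessGLM().fit(D.X[mask], D.y[mask], D.column_names)
        keep = [i for i, c in enumerate(D.column_names) if c in m.column_names_]
        X, y = D.X[mask][:, keep], D.y[mask]

        def grad(theta):
            eta = X @ theta
            p = np.exp(eta)
            g = np.where(y == 1.0, 1.0, -p / (1.0 - p))
            return X.T @ g

        k = m.coef_.size
        H = np.zeros((k, k))
        h = 1e-6
        for j in range(k):
            e = np.zeros(k)
            e[j] = h
            H[:, j] = (grad(m.coef_ + e) - grad(m.coef_ - e)) / (2 * h)
        cov_oracle = np.linalg.inv(-(H + H.T) / 2.0)
        se_oracle = np.sqrt(np.diag(cov_oracle))
        se = np.sqrt(np.diag(m.covariance_))
        assert np.max(np.abs(se - se_oracle) / se_oracle) < 1e-4


class TestPredict:
    def test_constant_model_constant_intensity(self, basis):
        hyp = all_light_hypnogram(1.0)
        train = na.NAAEventTrain(np.array([], dtype=float))
        D = na.build_design(train, hyp, [], basis, window=(0.0, 3600.0))
        m = na.PointProcessGLM()
        m.column_names_ = ("I_LIGHT",)
        m.coef_ = np.array([-3.0])
        m.covariance_ = np.eye(1)
        lam = m.predict_intensity(D).lam
        assert np.allclose(lam, np.exp(-3.0))

    def test_cumulative_intensity_is_running_sum(self, fitted_night):
        night, m = fitted_night
        inten = m.predict_intensity(m.design_)
        edges, cum = inten.cumulative()
        assert np.isclose(cum[-1], inten.lam.sum())
        mid_t = edges[len(edges) // 2]
        assert np.isclose(
            inten.cumulative_at(mid_t), inten.lam[: len(edges) // 2].sum()
        )

    def test_column_mismatch_rejected(self, fitted_night, basis):
        _, m = fitted_night
        with pytest.raises(ValueError, match="columns"):
            m.predict_intensity(np.ones((10, 3)))


def test_stage_columns_partition_every_bin(night, basis):
    D = na.build_design(night.train, night.hypnogram, night.events, basis)
    assert np.allclose(D.X[:, : len(STAGE_COLUMNS)].sum(axis=1), 1.0)
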