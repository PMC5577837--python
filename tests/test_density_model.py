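"""Count-model ladder: fitting, dispersion, selection and Vuong comparison."""

import numpy as np
import pandas as pd
import pytest

from divebottom3d import density_model as dm


def _poisson_table(n, beta, rng, offset_scale=(2e3, 2e4)):
    k = len(beta) - 1
    x = rng.standard_normal((n, max(k, 1)))
    offset = np.log(rng.uniform(*offset_scale, n))
    mu = np.exp(beta[0] + x[:, :k] @ beta[1:] + offset)
    out = {"pee_count": rng.poisson(mu), "volume": np.exp(offset)}
    for j in range(x.shape[1]):
        out[f"x{j + 1}"] = x[:, j]
    return pd.DataFrame(out)


class TestFitCountModel:
    def test_poisson_slope_ci_coverage(self):
        """95% CIs cover the generating slopes at the nominal rate."""
        rng = np.random.default_rng(10)
        beta = np.array([-7.0, 0.4, -0.3])
        hits = []
        for _ in range(60):
            tab = _poisson_table(400, beta, rng)
            spec = dm.ModelSpec(
                family="poisson", count_covariates=("x1", "x2"), zero_covariates=()
            )
            fit = dm.fit_count_model(tab, spec)
            for name, b in [("x1", beta[1]), ("x2", beta[2])]:
                target = b * tab[name].std()
                lo, hi = fit.conf_int.loc[name]
                hits.append(lo <= target <= hi)
        assert 0.88 <= np.mean(hits) <= 0.99

    def test_zinb_without_inflation_reduces_to_nb(self):
        rng = np.random.default_rng(11)
        tab = dm.simulate_zinb(
            800, np.array([-7.0, -0.4]), np.array([-8.0]), theta=3.0, rng=rng
        )
        nb = dm.fit_count_model(
            tab, dm.ModelSpec(family="negbin", count_covariates=("x1",), zero_covariates=())
        )
        zinb = dm.fit_count_model(
            tab, dm.ModelSpec(family="zinb", count_covariates=("x1",), zero_covariates=())
        )
        for name in ("const", "x1"):
            assert abs(zinb.params[name] - nb.params[name]) < 2 * nb.bse[name]

    def test_zinb_generative_recovery(self):
        rng = np.random.default_rng(12)
        beta = np.array([-7.0, -0.4, 0.3])
        gamma = np.array([-1.0, 0.8])
        tab = dm.simulate_zinb(1000, beta, gamma, theta=3.0, rng=rng)
        fit = dm.fit_count_model(
            tab,
            dm.ModelSpec(
                family="zinb", count_covariates=("x1", "x2"), zero_covariates=("x1",)
            ),
        )
        assert fit.converged
        targets = {
            "x1": beta[1] * tab.x1.std(),
            "x2": beta[2] * tab.x2.std(),
            "zero_x1": gamma[1] * tab.x1.std(),
        }
        for name, value in targets.items():
            assert abs(fit.params[name] - value) < 3 * fit.bse[name]
        assert fit.theta == pytest.approx(3.0, rel=0.25)

    def test_offset_always_present(self):
        """Doubling every volume shifts the intercept by -log 2 exactly and
        leaves the slopes untouched (offset reparametrization)."""
        rng = np.random.default_rng(13)
        tab = _poisson_table(500, np.array([-7.0, 0.5]), rng)
        spec = dm.ModelSpec(family="poisson", count_covariates=("x1",), zero_covariates=())
        f1 = dm.fit_count_model(tab, spec)
        tab2 = tab.assign(volume=2 * tab.volume)
        f2 = dm.fit_count_model(tab2, spec)
        assert f2.params["const"] - f1.params["const"] == pytest.approx(-np.log(2), abs=1e-5)
        assert f2.params["x1"] == pytest.approx(f1.params["x1"], abs=1e-6)

    def test_standardization_makes_fit_affine_invariant(self):
        rng = np.random.default_rng(14)
        tab = _poisson_table(400, np.array([-7.0, 0.5]), rng)
        spec = dm.ModelSpec(family="poisson", count_covariates=("x1",), zero_covariates=())
        f1 = dm.fit_count_model(tab, spec)
        f2 = dm.fit_count_model(tab.assign(x1=1000.0 * tab.x1 + 5.0), spec)
        assert f2.params["x1"] == pytest.approx(f1.params["x1"], abs=1e-6)

    def test_collinear_covariates_screened(self):
        rng = np.random.default_rng(15)
        tab = _poisson_table(300, np.array([-7.0, 0.5]), rng)
        tab["x2"] = tab.x1 * 1.001 + rng.normal(0, 1e-4, len(tab))
        with pytest.raises(ValueError, match="collinear"):
            dm.fit_count_model(
                tab,
                dm.ModelSpec(
                    family="poisson", count_covariates=("x1", "x2"), zero_covariates=()
                ),
            )

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(16)
        tab = _poisson_table(10, np.array([-7.0]), rng)
        with pytest.raises(ValueError, match="rows"):
            dm.fit_count_model(
                tab, dm.ModelSpec(family="poisson", count_covariates=(), zero_covariates=())
            )


class TestOverdispersion:
    def test_equidispersed_poisson_near_one(self):
        rng = np.random.default_rng(17)
        tab = _poisson_table(1000, np.array([-7.0]), rng)
        fit = dm.fit_count_model(
            tab, dm.ModelSpec(family="poisson", count_covariates=(), zero_covariates=())
        )
        assert dm.overdispersion(fit) == pytest.approx(1.0, abs=0.1)

    def test_nb_with_triple_variance(self):
        # NB2 with mu = 6, theta = 3 has variance/mean = 1 + mu/theta = 3
        rng = np.random.default_rng(18)
        n = 1000
        mu = 6.0
        y = rng.poisson(rng.gamma(shape=3.0, scale=mu / 3.0, size=n))
        tab = pd.DataFrame({"pee_count": y, "volume": np.full(n, 1e4)})
        fit = dm.fit_count_model(
            tab, dm.ModelSpec(family="poisson", count_covariates=(), zero_covariates=())
        )
        assert dm.overdispersion(fit) == pytest.approx(3.0, abs=0.3)

    def test_all_zero_response_flagged(self):
        tab = pd.DataFrame({"pee_count": np.zeros(50, int), "volume": np.full(50, 1e4)})
        with pytest.warns(UserWarning, match="all-zero"):
            fit = dm.fit_count_model(
                tab,
                dm.ModelSpec(family="poisson", count_covariates=(), zero_covariates=()),
            )
        assert fit.flagged is not None and not fit.converged
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(dm.overdispersion(fit))


class TestSelectModel:
    def test_true_covariates_selected_consistently(self):
        """With 2 real effects among 5 candidates, both are selected."""
        rng = np.random.default_rng(19)
        beta = np.array([-7.0, 0.5, -0.5, 0.0, 0.0, 0.0])
        hits = 0
        reps = 20
        for _ in range(reps):
            tab = _poisson_table(300, beta, rng)
            fit, _ = dm.select_model(
                tab, family="poisson",
                count_menu=("x1", "x2", "x3", "x4", "x5"), zero_menu=(),
            )
            chosen = set(fit.spec.count_covariates)
            hits += {"x1", "x2"} <= chosen
        assert hits >= 0.85 * reps

    def test_single_candidate_returned_trivially(self):
        rng = np.random.default_rng(20)
        tab = _poisson_table(300, np.array([-7.0, 0.6]), rng)
        fit, ledger = dm.select_model(
            tab, family="poisson", count_menu=("x1",), zero_menu=()
        )
        assert fit.spec.count_covariates in [(), ("x1",)]
        assert len(ledger) == 2  # {} and {x1}

    def test_pure_noise_covariates_mostly_unselected(self):
        rng = np.random.default_rng(21)
        beta = np.array([-7.0, 0.0, 0.0, 0.0])
        empty = 0
        reps = 10
        for _ in range(reps):
            tab = _poisson_table(300, beta, rng)
            fit, _ = dm.select_model(
                tab, family="poisson", count_menu=("x1", "x2", "x3"), zero_menu=()
            )
            empty += len(fit.spec.count_covariates) == 0
        assert empty >= 7


class TestVuong:
    def _pair(self, rng, zinb=True):
        if zinb:
            tab = dm.simulate_zinb(
                1000, np.array([-7.0, -0.4]), np.array([-0.8, 0.6]), theta=3.0, rng=rng
            )
        else:
            tab = _poisson_table(1000, np.array([-7.0, -0.4]), rng)
        f_zinb = dm.fit_count_model(
            tab, dm.ModelSpec(family="zinb", count_covariates=("x1",), zero_covariates=("x1",))
        )
        f_pois = dm.fit_count_model(
            tab, dm.ModelSpec(family="poisson", count_covariates=("x1",), zero_covariates=())
        )
        return f_zinb, f_pois

    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(22)
        f_zinb, _ = self._pair(rng)
        z, p = dm.vuong_compare(f_zinb, f_zinb)
        assert z == 0.0 and p == 1.0

    def test_favours_zinb_on_zinb_data(self):
        rng = np.random.default_rng(23)
        wins = 0
        for _ in range(8):
            f_zinb, f_pois = self._pair(rng, zinb=True)
            z, p = dm.vuong_compare(f_zinb, f_pois)
            wins += (z > 0) and (p < 0.01)
        assert wins >= 7

    def test_null_rate_on_poisson_data(self):
        rng = np.random.default_rng(24)
        significant = 0
        for _ in range(8):
            f_zinb, f_pois = self._pair(rng, zinb=False)
            _, p = dm.vuong_compare(f_zinb, f_pois)
            significant += p < 0.01
        assert significant <= 2

    def test_aic_prefers_zinb_on_zinb_data(self):
        rng = np.random.default_rng(25)
        better = converged = 0
        for _ in range(8):
            f_zinb, f_pois = self._pair(rng, zinb=True)
            if not f_zinb.converged:  # flagged fits are excluded from selection
                continue
            converged += 1
            better += f_zinb.aic < f_pois.aic
        assert converged >= 6
        assert better == converged
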