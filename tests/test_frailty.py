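"""Shared gamma-frailty Cox model against independent oracles.

The plain-Cox limit (theta = 0) is checked against a 1-D golden-section
maximizer of the Breslow partial likelihood and against lifelines'
left-truncated CoxPHFitter; fixed-theta and profiled fits are checked
against values frozen from R ``survival::coxph`` with ``frailty.gamma``
on the identical dataset.
"""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from lrc_healthspan.inference import cox_frailty_fit, martingale_residuals, scaled_hr

from conftest import make_records


def breslow_partial_loglik(beta, entry, exit_, event, x):
    """Brute-force partial likelihood: explicit loop over risk sets."""
    ll = 0.0
    for t in np.unique(exit_[event == 1]):
        risk = (entry < t) & (exit_ >= t)
        d = (exit_ == t) & (event == 1)
        ll += beta * x[d].sum() - d.sum() * np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def random_dataset(rng, n):
    entry = rng.uniform(0, 2, n) * (rng.random(n) < 0.5)
    x = rng.normal(size=n)
    t = entry + rng.exponential(np.exp(-0.5 * x), n)
    c = entry + rng.exponential(2.0, n)
    exit_ = np.minimum(t, c)
    event = (t <= c).astype(int)
    if event.sum() == 0:
        event[np.argmin(exit_)] = 1
    return entry, exit_, event, x


class TestPlainCoxLimit:
    def test_symmetric_toy_gives_zero(self):
        # z=1 deaths at {1,3}; z=0 deaths at {1,3}: exchangeable
        recs = make_records([0] * 4, [1, 3, 1, 3], [1] * 4, z=[1, 1, 0, 0])
        fit = cox_frailty_fit(recs, ["z"], theta=0)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_six_subject_toy_vs_golden_section(self):
        entry = np.zeros(6)
        exit_ = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0, 1, 0, 1, 0])
        recs = make_records(entry, exit_, event, z=x)
        fit = cox_frailty_fit(recs, ["z"], theta=0)
        res = minimize_scalar(
            lambda b: -breslow_partial_loglik(b, entry, exit_, event, x),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10},
        )
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-4)

    def test_random_datasets_vs_grid_oracle(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 15:
            n = int(rng.integers(8, 31))
            entry, exit_, event, x = random_dataset(rng, n)
            res = minimize_scalar(
                lambda b: -breslow_partial_loglik(b, entry, exit_, event, x),
                bounds=(-8, 8), method="bounded", options={"xatol": 1e-9},
            )
            if abs(res.x) > 7.5:
                continue  # monotone likelihood on this draw
            recs = make_records(entry, exit_, event, z=x)
            fit = cox_frailty_fit(recs, ["z"], theta=0)
            assert fit.beta[0] == pytest.approx(res.x, abs=1e-3)
            checked += 1

    def test_matches_lifelines_left_truncated(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(1)
        n = 200
        entry, exit_, event, x = random_dataset(rng, n)
        sex = rng.integers(0, 2, n).astype(float)
        recs = make_records(entry, exit_, event, z=x, sex=sex)
        fit = cox_frailty_fit(recs, ["z", "sex"], theta=0)
        df = pd.DataFrame(dict(entry=entry, T=exit_, E=event, z=x, sex=sex))
        cph = lifelines.CoxPHFitter().fit(df, "T", "E", entry_col="entry")
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-4)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-4)

    def test_no_events_rejected(self):
        recs = make_records([0, 0], [1, 2], [0, 0], z=[0, 1])
        with pytest.raises(ValueError):
            cox_frailty_fit(recs, ["z"])


def r_reference_dataset():
    """The dataset whose coxph(frailty.gamma) results are frozen below."""
    rng = np.random.default_rng(11)
    F, m = 80, 4
    theta, b = 0.6, -0.5
    fam = np.repeat(np.arange(F), m)
    u = rng.gamma(1 / theta, theta, F)[fam]
    x = rng.normal(size=F * m)
    entry = rng.uniform(0, 5, F * m)
    t = entry + rng.exponential(1 / (0.08 * u * np.exp(b * x)))
    c = entry + rng.exponential(15, F * m)
    exit_ = np.minimum(t, c)
    event = (t <= c).astype(int)
    return make_records(entry, exit_, event, fam=[f"f{f:03d}" for f in fam], x=x)


class TestGammaFrailty:
    # frozen from R survival::coxph(Surv(entry, stop, event) ~ x +
    # frailty.gamma(fam), ties="breslow") on r_reference_dataset()
    R_FIXED = {0.3: (-0.55643, 0.09145), 0.6: (-0.60781, 0.09704)}
    R_EM = (-0.63089, 0.09985, 0.7929)

    @pytest.mark.parametrize("theta", [0.3, 0.6])
    def test_fixed_theta_matches_coxph(self, theta):
        recs = r_reference_dataset()
        fit = cox_frailty_fit(recs, ["x"], theta=theta)
        beta_r, se_r = self.R_FIXED[theta]
        assert fit.beta[0] == pytest.approx(beta_r, abs=1e-3)
        assert fit.se[0] == pytest.approx(se_r, abs=2e-3)

    def test_profiled_theta_matches_coxph_em(self):
        recs = r_reference_dataset()
        fit = cox_frailty_fit(recs, ["x"])
        beta_r, se_r, theta_r = self.R_EM
        assert fit.beta[0] == pytest.approx(beta_r, abs=2e-3)
        assert fit.se[0] == pytest.approx(se_r, abs=3e-3)
        assert fit.theta == pytest.approx(theta_r, abs=0.02)
        assert fit.converged

    def test_parameter_recovery_beta_grid(self):
        """Unbiased recovery across log-HR values at 400 families."""
        for seed, b in ((3, np.log(0.5)), (4, np.log(0.8)), (5, 0.0)):
            rng = np.random.default_rng(seed)
            F, m = 400, 3
            theta = 0.3
            fam = np.repeat(np.arange(F), m)
            u = rng.gamma(1 / theta, theta, F)[fam]
            x = rng.normal(size=F * m)
            t = rng.exponential(1 / (0.05 * u * np.exp(b * x)))
            c = rng.exponential(30, F * m)
            exit_ = np.minimum(t, c) + 1e-9
            event = (t <= c).astype(int)
            recs = make_records(np.zeros(F * m), exit_, event,
                                fam=[f"f{f}" for f in fam], x=x)
            fit = cox_frailty_fit(recs, ["x"])
            assert abs(fit.beta[0] - b) < 2 * fit.se[0]

    def test_frailty_posterior_means_average_one(self):
        recs = r_reference_dataset()
        fit = cox_frailty_fit(recs, ["x"], theta=0.5)
        u = np.array(list(fit.frailty.values()))
        assert np.all(u > 0)
        assert np.mean(u) == pytest.approx(1.0, abs=0.1)

    def test_monotone_likelihood_flagged(self):
        # all events in one level of a binary covariate: beta diverges
        recs = make_records(
            np.zeros(20),
            np.arange(1, 21),
            [1] * 10 + [0] * 10,
            z=[1.0] * 10 + [0.0] * 10,
        )
        fit = cox_frailty_fit(recs, ["z"], theta=0)
        assert not fit.converged
        assert "monotone_likelihood" in fit.flags


class TestScaledHR:
    def _fit(self):
        rng = np.random.default_rng(9)
        n = 120
        x = rng.uniform(0, 1, n)
        t = rng.exponential(np.exp(0.5 * x), n) + 1e-9
        recs = make_records(np.zeros(n), t, np.ones(n, int), lrc=x)
        return cox_frailty_fit(recs, ["lrc"], theta=0)

    def test_inverse_construction(self):
        fit = self._fit()
        fit.beta[0] = np.log(0.95) / 0.1
        hr, _ = scaled_hr(fit, "lrc", 0.1)
        assert hr == pytest.approx(0.95)

    def test_exponent_law(self):
        fit = self._fit()
        hr1, _ = scaled_hr(fit, "lrc", 1.0)
        hr01, _ = scaled_hr(fit, "lrc", 0.1)
        assert hr1 == pytest.approx(hr01**10)

    def test_ci_width_grows_with_scale(self):
        fit = self._fit()
        widths = []
        for s in (0.1, 0.5, 1.0, 2.0):
            _, (lo, hi) = scaled_hr(fit, "lrc", s)
            widths.append(np.log(hi) - np.log(lo))
        assert np.all(np.diff(widths) > 0)

    def test_binary_covariate_rejected(self):
        recs = make_records(np.zeros(4), [1, 2, 3, 4], [1, 1, 1, 1], z=[0, 1, 0, 1])
        fit = cox_frailty_fit(recs, ["z"], theta=0)
        with pytest.raises(ValueError):
            scaled_hr(fit, "z")


class TestMartingaleResiduals:
    def test_sum_to_zero(self):
        recs = r_reference_dataset()
        fit = cox_frailty_fit(recs, ["x"], theta=0.5)
        r = martingale_residuals(fit)
        assert abs(r.sum()) < 1e-6

    def test_zero_exposure_limit(self):
        # a censored subject whose (entry, exit] window contains no event
        # time accumulates no hazard: residual exactly 0
        recs = make_records([0, 0, 0, 0, 5.0], [1, 2, 3, 4, 5.001],
                            [1, 1, 1, 1, 0], z=[0, 1, 1, 0, 1])
        fit = cox_frailty_fit(recs, ["z"], theta=0)
        r = martingale_residuals(fit)
        assert r[4] == pytest.approx(0.0, abs=1e-12)

    def test_flat_vs_covariate_under_linear_effect(self):
        rng = np.random.default_rng(21)
        n = 400
        x = rng.uniform(-1, 1, n)
        t = rng.exponential(np.exp(-0.8 * x), n) + 1e-9
        recs = make_records(np.zeros(n), t, np.ones(n, int), x=x)
        fit = cox_frailty_fit(recs, ["x"], theta=0)
        r = martingale_residuals(fit)
        # under a correctly specified linear effect the residual trend is flat:
        # binned means stay within a noise band around zero
        bins = np.digitize(x, np.linspace(-1, 1, 5)[1:-1])
        for k in range(3):
            assert abs(r[bins == k].mean()) < 3 / np.sqrt(max((bins == k).sum(), 1))
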