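"""Shared gamma-frailty Cox regression with left truncation.

Model: the hazard of person ``j`` in family ``i`` is

    lambda(t_ij) = u_i * lambda_0(t_ij) * exp(beta' z_ij)

with an unspecified baseline ``lambda_0``, fixed effects ``beta`` and a
family-shared frailty ``u_i ~ Gamma(mean 1, variance theta)``.  Delayed
entry (left truncation) is handled through age-scale risk sets
``R(t) = {j : entry_j < t <= exit_j}``; ties use the Breslow approximation.

Estimation is EM: the E-step replaces each frailty by its posterior mean
``(1/theta + D_i) / (1/theta + Lambda_i)`` given the family's event count
``D_i`` and accumulated cumulative hazard ``Lambda_i``; the M-step runs
Newton–Raphson on the partial likelihood with ``log u_i`` as an offset and
updates the Breslow baseline.  The frailty variance is found by maximising
the gamma-integrated marginal likelihood profile over ``log theta``.

Standard errors for ``beta`` come from the penalized observed information
of the joint (beta, log-frailty) problem — the frailty block is profiled
out via a Schur complement, so the uncertainty in the estimated family
frailties propagates into the reported SEs (the approach used by penalized
partial-likelihood frailty software).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm

__all__ = [
    "FrailtyCoxFit",
    "cox_frailty_fit",
    "scaled_hr",
    "martingale_residuals",
    "ConvergenceError",
]

_LOG_THETA_MIN = np.log(1e-8)
_LOG_THETA_MAX = np.log(8.0)
_BETA_TOL = 1e-6
_LOGLIK_RTOL = 1e-8
_MAX_EM_ITER = 200
# |log HR| beyond this is treated as a diverging (monotone) likelihood
_BETA_DIVERGED = 15.0


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FrailtyCoxFit:
    """Result of a gamma-frailty Cox fit."""

    covariate_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    theta: float
    loglik: float
    frailty: dict[str, float]
    n: int
    n_events: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    # internals carried for residuals / baseline reconstruction
    _entry: np.ndarray | None = None
    _exit: np.ndarray | None = None
    _event: np.ndarray | None = None
    _X: np.ndarray | None = None
    _fam_codes: np.ndarray | None = None
    _event_times: np.ndarray | None = None
    _baseline_jumps: np.ndarray | None = None

    @property
    def hazard_ratios(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.beta)

    def confint(self, alpha: float = 0.05) -> np.ndarray:
        """(k, 2) Wald CI bounds on the hazard-ratio scale."""
        zq = norm.ppf(1 - alpha / 2)
        lo = np.exp(self.beta - zq * self.se)
        hi = np.exp(self.beta + zq * self.se)
        return np.column_stack([lo, hi])

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2 * norm.sf(np.abs(self.wald_z))

    def summary(self) -> pd.DataFrame:
        ci = self.confint()
        return pd.DataFrame(
            {
                "term": self.covariate_names,
                "coef": self.beta,
                "se": self.se,
                "hr": self.hazard_ratios,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "z": self.wald_z,
                "p": self.p_values,
            }
        )

    def as_dict(self) -> dict:
        """JSON-serializable summary (estimates, SEs, CIs, p, convergence)."""
        ci = self.confint()
        return {
            "model": "cox_gamma_frailty",
            "terms": self.covariate_names,
            "coef": self.beta.tolist(),
            "se": self.se.tolist(),
            "hr": self.hazard_ratios.tolist(),
            "ci_low": ci[:, 0].tolist(),
            "ci_high": ci[:, 1].tolist(),
            "p": self.p_values.tolist(),
            "theta": self.theta,
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
            "flags": list(self.flags),
        }

    def cumulative_baseline(self, ages: np.ndarray) -> np.ndarray:
        """Breslow cumulative baseline hazard evaluated at ``ages``."""
        cum = np.concatenate(([0.0], np.cumsum(self._baseline_jumps)))
        idx = np.searchsorted(self._event_times, ages, side="right")
        return cum[idx]


def _design_from_records(records, covariates):
    from ..events import SurvivalRecord  # noqa: F401  (documented input type)

    entry = np.array([r.entry_age for r in records], dtype=float)
    exit_ = np.array([r.exit_age for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=int)
    fams = np.array([r.family_id for r in records])
    X = np.column_stack(
        [np.array([float(r.covariates[c]) for r in records]) for c in covariates]
    )
    return entry, exit_, event, X, fams


class _PartialLikelihood:
    """Breslow partial likelihood with delayed entry, O(n log n) per eval."""

    def __init__(self, entry, exit_, event, X):
        self.entry = entry
        self.exit = exit_
        self.event = event.astype(bool)
        self.X = X
        self.n, self.p = X.shape
        ts, counts = np.unique(exit_[self.event], return_counts=True)
        self.ts = ts  # distinct event times, ascending
        self.d = counts.astype(float)  # Breslow multiplicities
        # subject j is at risk for event-time indices [a_j, b_j)
        self.a = np.searchsorted(ts, entry, side="right")
        self.b = np.searchsorted(ts, exit_, side="right")
        # index of own event time for event subjects
        self.ev_idx = np.searchsorted(ts, exit_[self.event])

    def risk_sums(self, w, V=None):
        """Sums over risk sets at each event time via difference arrays.

        Returns S0 (T,) for weights ``w`` and, if ``V`` (n, q) given, the
        matching (T, q) sums of ``w * V``.
        """
        T = self.ts.size
        diff = np.zeros(T + 1)
        np.add.at(diff, self.a, w)
        np.add.at(diff, self.b, -w)
        S0 = np.cumsum(diff)[:T]
        if V is None:
            return S0
        q = V.shape[1]
        diffV = np.zeros((T + 1, q))
        np.add.at(diffV, self.a, w[:, None] * V)
        np.add.at(diffV, self.b, -(w[:, None] * V))
        SV = np.cumsum(diffV, axis=0)[:T]
        return S0, SV

    def loglik_grad_hess(self, beta, offset):
        eta = self.X @ beta + offset
        # the partial likelihood is invariant to a constant shift in eta
        # (sum of event multiplicities equals the number of events), so
        # centre at the max to keep exp() finite for diverging coefficients
        eta = eta - eta.max()
        w = np.exp(eta)
        # pairwise products for the S2 sums, q = p*(p+1)/2 flattened
        iu = np.triu_indices(self.p)
        XX = self.X[:, iu[0]] * self.X[:, iu[1]]
        S0, S1 = self.risk_sums(w, self.X)
        _, S2f = self.risk_sums(w, XX)
        ll = float(eta[self.event].sum() - (self.d * np.log(S0)).sum())
        mean = S1 / S0[:, None]
        grad = self.X[self.event].sum(axis=0) - (self.d[:, None] * mean).sum(axis=0)
        S2 = np.zeros((self.ts.size, self.p, self.p))
        S2[:, iu[0], iu[1]] = S2f
        S2[:, iu[1], iu[0]] = S2f
        cov = S2 / S0[:, None, None] - mean[:, :, None] * mean[:, None, :]
        hess = -(self.d[:, None, None] * cov).sum(axis=0)
        return ll, grad, hess, w, S0, S1

    def newton(self, beta0, offset, max_iter=50):
        beta = beta0.copy()
        ll, grad, hess, *_ = self.loglik_grad_hess(beta, offset)
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                # near-flat direction (e.g. diverging coefficient); a small
                # ridge keeps the step defined so divergence can be flagged
                ridge = -hess + 1e-6 * np.eye(self.p)
                try:
                    step = np.linalg.solve(ridge, grad)
                except np.linalg.LinAlgError as err:
                    raise ConvergenceError(f"singular information matrix: {err}") from err
            # step halving
            for _ in range(30):
                cand = beta + step
                ll_new = self.loglik_only(cand, offset)
                if ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            beta_new = beta + step
            done = np.max(np.abs(beta_new - beta)) < _BETA_TOL
            beta = beta_new
            if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > _BETA_DIVERGED:
                break  # monotone likelihood; the caller flags it
            ll, grad, hess, *_ = self.loglik_grad_hess(beta, offset)
            if done:
                break
        return beta, ll, hess

    def loglik_only(self, beta, offset):
        eta = self.X @ beta + offset
        eta = eta - eta.max()
        w = np.exp(eta)
        S0 = self.risk_sums(w)
        return float(eta[self.event].sum() - (self.d * np.log(S0)).sum())

    def breslow(self, w):
        """Baseline jumps d_t / S0(t) and per-subject cumulative baseline
        increments Lambda0(exit) - Lambda0(entry)."""
        S0 = self.risk_sums(w)
        jumps = self.d / S0
        cum = np.concatenate(([0.0], np.cumsum(jumps)))
        inc = cum[self.b] - cum[self.a]
        return jumps, inc


def _marginal_loglik(pl, jumps, lam_fam, D_fam, eta_fixed, theta):
    """Gamma-integrated marginal log-likelihood with Breslow baseline."""
    ev_terms = eta_fixed[pl.event].sum() + np.log(jumps[pl.ev_idx]).sum()
    if theta < 1e-10:
        return float(ev_terms - lam_fam.sum())
    nu = 1.0 / theta
    fam_terms = (
        nu * np.log(nu)
        - gammaln(nu)
        + gammaln(nu + D_fam)
        - (nu + D_fam) * np.log(nu + lam_fam)
    )
    return float(ev_terms + fam_terms.sum())


def cox_frailty_fit(
    records,
    covariates: list[str],
    *,
    theta: float | None = None,
    max_iter: int = _MAX_EM_ITER,
) -> FrailtyCoxFit:
    """Fit the shared gamma-frailty Cox model.

    Parameters
    ----------
    records
        Sequence of :class:`~lrc_healthspan.events.SurvivalRecord`; family
        membership comes from ``family_id`` and covariate values from the
        record's ``covariates`` mapping.
    covariates
        Names of the (numeric) covariates to include.
    theta
        Fixed frailty variance; ``0`` gives a plain left-truncated Cox
        model, ``None`` (default) estimates theta by profile likelihood.
    """
    records = list(records)
    if not records:
        raise ValueError("no survival records")
    entry, exit_, event, X, fams = _design_from_records(records, covariates)
    if event.sum() == 0:
        raise ValueError("no events in the data; the partial likelihood is undefined")
    fam_labels, fam_codes = np.unique(fams, return_inverse=True)
    F = fam_labels.size
    pl = _PartialLikelihood(entry, exit_, event, X)
    D_fam = np.bincount(fam_codes, weights=event.astype(float), minlength=F)

    state = {"beta": np.zeros(X.shape[1]), "u": np.ones(F)}
    flags: list[str] = []

    def em(theta_val, record_state=True):
        beta = state["beta"].copy()
        u = state["u"].copy()
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            offset = np.log(u)[fam_codes]
            beta_new, _, hess = pl.newton(beta, offset)
            if np.max(np.abs(beta_new)) > _BETA_DIVERGED:
                flags.append("monotone_likelihood")
                beta = beta_new
                break
            w = np.exp(X @ beta_new + offset)
            jumps, inc = pl.breslow(w)
            # family cumulative hazards: frailty-free linear predictor times
            # the shared Breslow baseline (frailty enters via the posterior)
            lam_subj = np.exp(X @ beta_new) * inc
            lam_fam = np.bincount(fam_codes, weights=lam_subj, minlength=F)
            if theta_val > 0:
                nu = 1.0 / theta_val
                u_new = (nu + D_fam) / (nu + lam_fam)
            else:
                u_new = np.ones(F)
            ll = _marginal_loglik(pl, jumps, lam_fam, D_fam, X @ beta_new, theta_val)
            db = np.max(np.abs(beta_new - beta))
            beta, u = beta_new, u_new
            if db < _BETA_TOL and abs(ll - ll_prev) <= _LOGLIK_RTOL * (abs(ll_prev) + 1):
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        if record_state:
            state["beta"], state["u"] = beta, u
        return beta, u, ll_prev, converged

    if theta is not None and theta <= 1e-10:
        theta_hat = 0.0
        beta_hat, u_hat, ll_hat, converged = em(0.0)
    elif theta is not None:
        theta_hat = float(theta)
        beta_hat, u_hat, ll_hat, converged = em(theta_hat)
    else:
        def neg_profile(log_theta):
            _, _, ll, _ = em(float(np.exp(log_theta)))
            return -ll

        res = minimize_scalar(
            neg_profile,
            bounds=(_LOG_THETA_MIN, _LOG_THETA_MAX),
            method="bounded",
            options={"xatol": 1e-3},
        )
        theta_hat = float(np.exp(res.x))
        if theta_hat < 2e-8:
            theta_hat = 0.0
        beta_hat, u_hat, ll_hat, converged = em(theta_hat)

    if "monotone_likelihood" in flags:
        converged = False

    if "monotone_likelihood" in flags:
        se = np.full_like(beta_hat, np.nan)
    else:
        try:
            se = _beta_se(pl, X, beta_hat, u_hat, fam_codes, theta_hat, F)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            converged = False
            se = np.full_like(beta_hat, np.nan)

    offset = np.log(u_hat)[fam_codes]
    with np.errstate(over="ignore", invalid="ignore"):
        w = np.exp(X @ beta_hat + offset)
        jumps, _ = pl.breslow(w)
    return FrailtyCoxFit(
        covariate_names=list(covariates),
        beta=beta_hat,
        se=se,
        theta=theta_hat,
        loglik=ll_hat,
        frailty={str(lbl): float(v) for lbl, v in zip(fam_labels, u_hat)},
        n=len(records),
        n_events=int(event.sum()),
        converged=converged,
        flags=flags,
        _entry=entry,
        _exit=exit_,
        _event=event,
        _X=X,
        _fam_codes=fam_codes,
        _event_times=pl.ts,
        _baseline_jumps=jumps,
    )


def _beta_se(pl, X, beta, u, fam_codes, theta, F):
    """SE(beta) from the penalized joint information in (beta, log u).

    The log-frailty block carries the gamma penalty curvature
    ``u_i / theta``; profiling it out by a Schur complement yields the
    variance of beta accounting for frailty estimation.  With theta = 0 the
    penalty is infinite and this reduces to the plain Cox information.
    """
    offset = np.log(u)[fam_codes]
    _, _, hess, w, S0, S1 = pl.loglik_grad_hess(beta, offset)
    I_bb = -hess
    if theta <= 0:
        return np.sqrt(np.diag(np.linalg.inv(I_bb)))

    T = pl.ts.size
    # per-family risk sums R (T, F) and per-covariate family sums
    diff = np.zeros((T + 1, F))
    np.add.at(diff, (pl.a, fam_codes), w)
    np.add.at(diff, (pl.b, fam_codes), -w)
    R = np.cumsum(diff, axis=0)[:T]

    c = pl.d / S0  # (T,)
    mean = S1 / S0[:, None]  # (T, p)

    # I_ww = sum_t d_t [diag(r/S0) - (r/S0)(r/S0)'] + diag(u/theta)
    M = R * (np.sqrt(pl.d) / S0)[:, None]
    I_ww = np.diag((c[:, None] * R).sum(axis=0) + u / theta) - M.T @ M

    # I_bw[l, f] = sum_t d_t [Sxg_lf/S0 - mean_l * r_f/S0]
    p = X.shape[1]
    I_bw = np.zeros((p, F))
    for l in range(p):
        diffx = np.zeros((T + 1, F))
        wx = w * X[:, l]
        np.add.at(diffx, (pl.a, fam_codes), wx)
        np.add.at(diffx, (pl.b, fam_codes), -wx)
        Sxg = np.cumsum(diffx, axis=0)[:T]
        I_bw[l] = (c[:, None] * Sxg).sum(axis=0) - (
            (pl.d * mean[:, l] / S0)[:, None] * R
        ).sum(axis=0)

    Y = np.linalg.solve(I_ww, I_bw.T)  # (F, p)
    schur = I_bb - I_bw @ Y
    return np.sqrt(np.diag(np.linalg.inv(schur)))


def scaled_hr(fit: FrailtyCoxFit, covariate: str, scale: float = 0.1, alpha: float = 0.05):
    """Hazard ratio per ``scale`` units of a continuous covariate.

    Returns (hr, (ci_low, ci_high)); the CI follows from the exact
    rescaling of the Wald interval on the log-hazard scale (delta method on
    ``scale * beta``).
    """
    if covariate not in fit.covariate_names:
        raise ValueError(f"covariate {covariate!r} not in fit")
    k = fit.covariate_names.index(covariate)
    vals = fit._X[:, k]
    if np.unique(vals).size <= 2:
        raise ValueError(f"covariate {covariate!r} is not continuous; scaling undefined")
    zq = norm.ppf(1 - alpha / 2)
    b, s = scale * fit.beta[k], abs(scale) * fit.se[k]
    return float(np.exp(b)), (float(np.exp(b - zq * s)), float(np.exp(b + zq * s)))


def martingale_residuals(fit: FrailtyCoxFit) -> np.ndarray:
    """Per-subject martingale residuals of a converged fit.

    ``r_j = delta_j - u_i exp(x_j beta) (Lambda0(exit_j) - Lambda0(entry_j))``
    with the truncation-adjusted Breslow baseline.  They sum to zero by the
    baseline estimating equation.
    """
    if not fit.converged:
        raise ConvergenceError("residuals requested from a non-converged fit")
    u = np.array([fit.frailty[k] for k in sorted(fit.frailty)])
    # frailty dict keys sorted == np.unique order used at fit time
    offset = np.log(u)[fit._fam_codes]
    w = np.exp(fit._X @ fit.beta + offset)
    lam = fit.cumulative_baseline(fit._exit) - fit.cumulative_baseline(fit._entry)
    return fit._event - w * lam
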