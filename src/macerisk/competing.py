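"""Competing-risks estimation: Aalen–Johansen CIF and Fine–Gray regression.

The cumulative incidence function (CIF) of cause k,
``F_k(t) = P(T <= t, cause = k)``, is estimated nonparametrically by the
Aalen–Johansen estimator

    F_k(t) = sum_{t_j <= t} S(t_j-) d_kj / n_j ,

with ``S`` the all-cause Kaplan–Meier left limit, ``d_kj`` the cause-k
events at ``t_j`` and ``n_j`` the at-risk count.

The Fine–Gray model regresses the subdistribution hazard of cause 1 on
covariates. Subjects with a competing event remain in the cause-1 risk
set after their event, down-weighted by the inverse probability of
censoring weight ``G(t)/G(T_i)`` where ``G`` is the Kaplan–Meier
estimator of the censoring distribution. Estimation maximizes the
weighted partial likelihood by Newton–Raphson; the variance is a robust
(sandwich) estimator built from per-subject score residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CifEstimate",
    "FineGrayFit",
    "cif_aalen_johansen",
    "fit_fine_gray",
    "fine_gray_pseudo_loglik",
    "censoring_km",
    "single_factor_screen",
    "ConvergenceError",
    "SeparationError",
]

_WEIGHT_FLOOR = 1e-10


class ConvergenceError(RuntimeError):
    """Newton–Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(f"{message}; trace (iter, loglik, max|grad|): {trace}")
        self.trace = trace


class SeparationError(RuntimeError):
    """Monotone likelihood (complete separation) in a covariate."""


# ---------------------------------------------------------------------------
# Aalen–Johansen
# ---------------------------------------------------------------------------


@dataclass
class CifEstimate:
    cause: int
    times: np.ndarray  # all-cause event-time grid, ascending
    cif: np.ndarray  # CIF at each grid point (right-continuous step)
    variance: np.ndarray  # Aalen-type pointwise variance
    n: int
    horizon: Optional[float] = None
    cif_at_horizon: Optional[float] = None

    def at(self, t: float) -> float:
        """CIF value at time ``t`` (step-function lookup)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cif[idx])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.variance[idx])


def _validate_time_event(time: np.ndarray, event: np.ndarray) -> None:
    if time.size == 0:
        raise ValueError("empty input: at least one record required")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be strictly positive and finite")
    if not np.isin(event, (0, 1, 2)).all():
        raise ValueError("event codes must be 0 (censored), 1 or 2")


def cif_aalen_johansen(
    time: Sequence[float],
    event: Sequence[int],
    cause: int = 1,
    horizon: Optional[float] = None,
) -> CifEstimate:
    """Aalen–Johansen cumulative incidence of ``cause``.

    Parameters
    ----------
    time, event : arrays
        Follow-up times (days) and event codes 0/1/2.
    cause : int
        Cause of interest (1 or 2).
    horizon : float, optional
        If given, ``cif_at_horizon`` holds the CIF at
        ``min(horizon, last event time)``.

    Notes
    -----
    With no events of the requested cause the CIF is identically zero.
    The pointwise variance is the Aalen-type (delta-method) estimator.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _validate_time_event(time, event)
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")

    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    n = t_s.size

    # unique all-cause event times with counts
    is_event = e_s > 0
    if not is_event.any():
        grid = np.array([])
        return CifEstimate(
            cause=cause,
            times=grid,
            cif=np.array([]),
            variance=np.array([]),
            n=n,
            horizon=horizon,
            cif_at_horizon=0.0 if horizon is not None else None,
        )
    uniq = np.unique(t_s[is_event])
    # counts at each unique event time
    d_all = np.zeros(uniq.size)
    d_k = np.zeros(uniq.size)
    idx = np.searchsorted(uniq, t_s[is_event])
    np.add.at(d_all, idx, 1.0)
    idx_k = np.searchsorted(uniq, t_s[e_s == cause])
    np.add.at(d_k, idx_k, 1.0)
    # at-risk just before each unique event time
    n_at = n - np.searchsorted(t_s, uniq, side="left")

    # all-cause KM left limits S(t_j-)
    surv_factors = 1.0 - d_all / n_at
    S_left = np.concatenate([[1.0], np.cumprod(surv_factors)[:-1]])
    jump = S_left * d_k / n_at
    cif = np.cumsum(jump)

    # Aalen-type variance (Marubini–Valsecchi form), guarded at n_j == d_j
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(n_at > d_all, d_all / (n_at * (n_at - d_all)), 0.0)
    b = S_left**2 * ((n_at - d_k) / n_at) * d_k / n_at**2
    c = S_left * d_k / n_at**2
    ca, cb, cc = np.cumsum(a), np.cumsum(b), np.cumsum(c)
    # var(t) = sum_l (F(t)-F(l))^2 a_l + sum_l b_l - 2 sum_l (F(t)-F(l)) c_l
    # expand so each prefix is a cumulative sum
    caF = np.cumsum(a * cif)
    caF2 = np.cumsum(a * cif**2)
    ccF = np.cumsum(c * cif)
    variance = (
        cif**2 * ca - 2 * cif * caF + caF2 + cb - 2 * (cif * cc - ccF)
    )
    variance = np.maximum(variance, 0.0)

    est = CifEstimate(
        cause=cause, times=uniq, cif=cif, variance=variance, n=n, horizon=horizon
    )
    if horizon is not None:
        est.cif_at_horizon = est.at(min(horizon, uniq[-1]))
    return est


# ---------------------------------------------------------------------------
# Censoring Kaplan–Meier (for IPCW weights)
# ---------------------------------------------------------------------------


def censoring_km(time: np.ndarray, event: np.ndarray):
    """Kaplan–Meier of the censoring distribution G(t).

    Both event types (1 and 2) censor the censoring process; at tied
    times events stay in the censoring risk set (the convention of the
    reference Fine–Gray implementations). Returns a function evaluating
    the left-continuous limit ``G(t-)`` on arrays.
    """
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    n = t_s.size
    cens_mask = e_s == 0
    if not cens_mask.any():
        return lambda t: np.ones_like(np.asarray(t, dtype=float))
    uniq = np.unique(t_s[cens_mask])
    d_c = np.zeros(uniq.size)
    np.add.at(d_c, np.searchsorted(uniq, t_s[cens_mask]), 1.0)
    n_at = n - np.searchsorted(t_s, uniq, side="left")
    n_at = np.maximum(n_at, d_c)
    G = np.cumprod(1.0 - d_c / n_at)

    def g_left(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(uniq, t, side="left") - 1  # strictly before t
        out = np.where(idx < 0, 1.0, G[np.clip(idx, 0, G.size - 1)])
        return np.maximum(out, _WEIGHT_FLOOR)

    return g_left


# ---------------------------------------------------------------------------
# Fine–Gray
# ---------------------------------------------------------------------------


@dataclass
class FineGrayFit:
    covariate_names: list
    coefficients: np.ndarray  # log subdistribution hazard ratios
    robust_se: np.ndarray
    vcov: np.ndarray
    shr: np.ndarray
    ci95: np.ndarray  # (k, 2)
    pvalues: np.ndarray
    pseudo_loglik: float
    n: int
    n_events_cause1: int
    aic: float
    bic: float
    n_iter: int
    ties: str = "breslow"
    trace: list = field(default_factory=list)

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "robust_se": self.robust_se,
                "shr": self.shr,
                "ci95_low": self.ci95[:, 0],
                "ci95_high": self.ci95[:, 1],
                "p": self.pvalues,
            },
            index=self.covariate_names,
        )


class _FGData:
    """Precomputed sufficient structures for the weighted partial likelihood.

    Subjects are sorted by time. For each unique cause-1 event time s_j the
    weighted risk-set sums decompose as
        S0(s_j) = A(s_j) + G(s_j-) * B(s_j)
    where A sums exp(x'b) over subjects with T >= s_j and B sums
    exp(x'b)/G(T_i-) over competing-event subjects with T_i < s_j; both
    are prefix/suffix sums, making each Newton iteration O(n log n).
    """

    def __init__(self, time, event, X):
        order = np.argsort(time, kind="stable")
        self.order = order
        self.t = time[order]
        self.e = event[order]
        self.X = X[order]
        self.n, self.k = X.shape
        g_left = censoring_km(time, event)
        self.G_own = g_left(self.t)  # G(T_i-)
        self.d1_mask = self.e == 1
        self.d2_mask = self.e == 2
        self.s, inv = np.unique(self.t[self.d1_mask], return_inverse=True)
        self.m = self.s.size
        self.d = np.zeros(self.m)
        np.add.at(self.d, inv, 1.0)
        self.G_s = g_left(self.s)  # G(s_j-)
        # index boundaries
        self.first_ge = np.searchsorted(self.t, self.s, side="left")  # T_i >= s_j
        self.n_lt = self.first_ge  # count of T_i < s_j
        # map each subject to number of event times s_j <= T_i
        self.n_le_T = np.searchsorted(self.s, self.t, side="right")
        # tied groups (for Efron): indices of cause-1 subjects per event time
        self.event_time_index = np.full(self.n, -1)
        self.event_time_index[self.d1_mask] = inv


def _risk_sums(data: _FGData, eta):
    """S0, S1, S2 at each cause-1 event time; also per-subject pieces."""
    w = np.exp(eta)
    X = data.X
    XX = X[:, :, None] * X[:, None, :]
    # suffix sums over subjects sorted by time (A terms: T_i >= s_j)
    sufw = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    sufwX = np.concatenate(
        [np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1], np.zeros((1, data.k))]
    )
    sufwXX = np.concatenate(
        [np.cumsum((w[:, None, None] * XX)[::-1], axis=0)[::-1],
         np.zeros((1, data.k, data.k))]
    )
    A0 = sufw[data.first_ge]
    A1 = sufwX[data.first_ge]
    A2 = sufwXX[data.first_ge]
    # prefix sums over competing-event subjects (B terms: eps=2, T_i < s_j)
    w2 = np.where(data.d2_mask, w / data.G_own, 0.0)
    prew = np.concatenate([[0.0], np.cumsum(w2)])
    prewX = np.concatenate([np.zeros((1, data.k)), np.cumsum(w2[:, None] * X, axis=0)])
    prewXX = np.concatenate(
        [np.zeros((1, data.k, data.k)), np.cumsum(w2[:, None, None] * XX, axis=0)]
    )
    B0 = prew[data.n_lt]
    B1 = prewX[data.n_lt]
    B2 = prewXX[data.n_lt]
    S0 = A0 + data.G_s * B0
    S1 = A1 + data.G_s[:, None] * B1
    S2 = A2 + data.G_s[:, None, None] * B2
    return w, S0, S1, S2


def _loglik_grad_hess(data: _FGData, beta, ties="breslow"):
    eta = data.X @ beta
    w, S0, S1, S2 = _risk_sums(data, eta)
    d1 = data.d1_mask
    if ties == "breslow" or np.all(data.d <= 1):
        ll = float(eta[d1].sum() - np.sum(data.d * np.log(S0)))
        mean = S1 / S0[:, None]
        grad = data.X[d1].sum(axis=0) - (data.d[:, None] * mean).sum(axis=0)
        hess = -(
            np.einsum("j,jab->ab", data.d / S0, S2)
            - np.einsum("j,ja,jb->ab", data.d, mean, mean)
        )
        return ll, grad, hess, (S0, S1, mean, w)
    # Efron within tied cause-1 groups
    ll = float(eta[d1].sum())
    grad = data.X[d1].sum(axis=0).astype(float)
    hess = np.zeros((data.k, data.k))
    wX = w[:, None] * data.X
    for j in range(data.m):
        dj = int(data.d[j])
        tied = np.where((data.event_time_index == j))[0]
        eD0 = w[tied].sum()
        eD1 = wX[tied].sum(axis=0)
        eD2 = (wX[tied][:, :, None] * data.X[tied][:, None, :]).sum(axis=0)
        for ell in range(dj):
            f = ell / dj
            s0 = S0[j] - f * eD0
            s1 = S1[j] - f * eD1
            s2 = S2[j] - f * eD2
            ll -= np.log(s0)
            mean = s1 / s0
            grad -= mean
            hess -= s2 / s0 - np.outer(mean, mean)
    mean_b = S1 / S0[:, None]
    return ll, grad, hess, (S0, S1, mean_b, w)


def fine_gray_pseudo_loglik(time, event, X, beta, ties="breslow") -> float:
    """Weighted partial log-likelihood at ``beta`` (for oracle checks)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != time.size:
        X = X.T
    data = _FGData(time, event, X)
    beta = np.atleast_1d(np.asarray(beta, float))
    ll, _, _, _ = _loglik_grad_hess(data, beta, ties)
    return ll


def _score_residuals(data: _FGData, beta, S0, mean, w):
    """Per-subject score residuals (Breslow form) for the sandwich."""
    d_over_S0 = data.d / S0
    P0 = np.concatenate([[0.0], np.cumsum(d_over_S0)])
    P1 = np.concatenate([np.zeros((1, data.k)), np.cumsum(d_over_S0[:, None] * mean, axis=0)])
    q = data.d * data.G_s / S0
    Q0_suf = np.concatenate([np.cumsum(q[::-1])[::-1], [0.0]])
    Q1_suf = np.concatenate([np.cumsum((q[:, None] * mean)[::-1], axis=0)[::-1], np.zeros((1, data.k))])

    n_le = data.n_le_T  # events with s_j <= T_i
    U = np.zeros((data.n, data.k))
    # event term
    ev = data.d1_mask
    U[ev] += data.X[ev] - mean[data.event_time_index[ev]]
    # natural risk-set term
    U -= w[:, None] * (data.X * P0[n_le][:, None] - P1[n_le])
    # competing-event extended risk-set term (s_j > T_i)
    c2 = data.d2_mask
    n_gt = n_le  # suffix starting at index n_le gives s_j > T_i
    U[c2] -= (w[c2] / data.G_own[c2])[:, None] * (
        data.X[c2] * Q0_suf[n_gt[c2]][:, None] - Q1_suf[n_gt[c2]]
    )
    return U


def fit_fine_gray(
    time,
    event,
    X,
    covariate_names: Optional[list] = None,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-8,
    bic_n: str = "events",
) -> FineGrayFit:
    """Fit a Fine–Gray subdistribution-hazard regression for cause 1.

    Parameters
    ----------
    time, event : arrays (n,)
        Follow-up days and event codes 0/1/2.
    X : array (n, k)
        Numeric covariates.
    ties : {"breslow", "efron"}
        Tie handling for tied cause-1 event times.
    bic_n : {"events", "total"}
        Sample size in the BIC penalty: number of cause-1 events
        (default, standard for partial likelihoods) or total n.

    Returns
    -------
    FineGrayFit
        Coefficients (log sHR), robust sandwich SEs, exp-scale sHRs with
        normal-theory 95% CIs, Wald p-values, pseudo-log-likelihood and
        AIC/BIC (``-2 ll + 2 k`` and ``-2 ll + k log n_events``).

    Raises
    ------
    ConvergenceError
        If Newton–Raphson does not reach ``max|grad| < tol``.
    SeparationError
        If the likelihood is monotone in some covariate.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    _validate_time_event(time, event)
    n, k = X.shape
    if covariate_names is None:
        covariate_names = [f"x{i}" for i in range(k)]
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    d1 = int(np.sum(event == 1))
    if d1 < 1:
        raise ValueError("at least one cause-1 event is required")
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("at least two distinct covariate patterns are required")

    data = _FGData(time, event, X)
    beta = np.zeros(k)
    trace = []
    ll, grad, hess, aux = _loglik_grad_hess(data, beta, ties)
    for it in range(1, max_iter + 1):
        gmax = float(np.max(np.abs(grad)))
        trace.append((it - 1, ll, gmax))
        if gmax < tol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {it}", trace) from exc
        # Newton decrement at the float noise floor: large-n gradient
        # components carry O(n eps) summation noise, so the absolute
        # gradient criterion may be unreachable; the decrement g'H^{-1}g
        # is scale-invariant and ~1e-10 means the coefficients are within
        # ~1e-5 curvature-norm of the optimum (SEs are >= 1e-2 here).
        if float(-(grad @ step)) < 1e-10:
            break
        new_beta = beta - step
        new_ll, new_grad, new_hess, new_aux = _loglik_grad_hess(data, new_beta, ties)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-11 * max(1.0, abs(ll)):
            step *= 0.5
            halvings += 1
            if halvings > 30:
                raise ConvergenceError("step-halving failed to improve loglik", trace)
            new_beta = beta - step
            new_ll, new_grad, new_hess, new_aux = _loglik_grad_hess(data, new_beta, ties)
        beta, ll, grad, hess, aux = new_beta, new_ll, new_grad, new_hess, new_aux
        if np.max(np.abs(beta)) > 15:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"monotone likelihood: covariate {covariate_names[j]!r} diverges "
                f"(|coef| > 15); check for complete separation"
            )
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", trace)

    S0, S1, mean, w = aux[0], aux[1], aux[2], aux[3]
    U = _score_residuals(data, beta, S0, mean, w)
    info = -hess
    info_inv = np.linalg.inv(info)
    meat = U.T @ U
    vcov = info_inv @ meat @ info_inv
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    ci = np.column_stack([np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)])
    bic_size = d1 if bic_n == "events" else n
    return FineGrayFit(
        covariate_names=list(covariate_names),
        coefficients=beta,
        robust_se=se,
        vcov=vcov,
        shr=np.exp(beta),
        ci95=ci,
        pvalues=pvals,
        pseudo_loglik=ll,
        n=n,
        n_events_cause1=d1,
        aic=-2 * ll + 2 * k,
        bic=-2 * ll + k * np.log(bic_size),
        n_iter=it,
        ties=ties,
        trace=trace,
    )


def single_factor_screen(time, event, profiles, factors: Optional[list] = None):
    """Univariable Fine–Gray fit per binary risk factor.

    One fit per factor, Wald p-values, no multiplicity adjustment.
    Factors with zero positives (or zero negatives) are flagged
    inestimable rather than raising.
    """
    import pandas as pd

    from .profiles import BOOLEAN_FIELDS

    if factors is None:
        factors = list(BOOLEAN_FIELDS)
    rows = []
    for f in factors:
        x = np.array([float(getattr(p, f)) for p in profiles])
        if x.sum() == 0 or x.sum() == x.size:
            rows.append(
                {"factor": f, "shr": np.nan, "ci95_low": np.nan, "ci95_high": np.nan,
                 "p": np.nan, "n_positive": int(x.sum()), "estimable": False}
            )
            continue
        try:
            fit = fit_fine_gray(time, event, x[:, None], covariate_names=[f])
            rows.append(
                {"factor": f, "shr": float(fit.shr[0]), "ci95_low": float(fit.ci95[0, 0]),
                 "ci95_high": float(fit.ci95[0, 1]), "p": float(fit.pvalues[0]),
                 "n_positive": int(x.sum()), "estimable": True}
            )
        except (SeparationError, ConvergenceError) as exc:
            warnings.warn(f"factor {f!r} inestimable: {exc}")
            rows.append(
                {"factor": f, "shr": np.nan, "ci95_low": np.nan, "ci95_high": np.nan,
                 "p": np.nan, "n_positive": int(x.sum()), "estimable": False}
            )
    return pd.DataFrame(rows)
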