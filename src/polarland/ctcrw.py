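"""Continuous-time correlated random walk (CTCRW) fitting and prediction.

The movement model: per axis, velocity follows an Ornstein-Uhlenbeck process
dv = -beta v dt + sigma dW and position is its integral.  The two axes share
(beta, sigma).  Observations are positions plus independent isotropic
Gaussian error whose SD is fixed by the fix's quality class.  Because the
transition density between irregular fix times is available in closed form,
the exact likelihood is a Kalman-filter product of Gaussian innovations, and
daily positions are obtained from the Rauch-Tung-Striebel smoother
(conditioning on all data, the standard use of the model for track
regularisation).

Parameters are estimated by maximum likelihood on (log beta, log sigma) with
multiple starts; per-class measurement SDs are fixed constants, not
estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .timeutil import doy_of

_DIFFUSE_POS_VAR = 1e6  # km^2
_DIFFUSE_VEL_VAR = 1e4  # (km/day)^2


def _phi_q(beta: float, sigma2: float, dt: float):
    """Exact discrete transition and noise covariance of the integrated OU
    state (position, velocity) over a step of dt days."""
    if dt == 0.0:
        return (1.0, 0.0, 1.0), (0.0, 0.0, 0.0)
    e = math.exp(-beta * dt)
    phi01 = (1.0 - e) / beta
    qvv = sigma2 * (1.0 - e * e) / (2.0 * beta)
    qxv = sigma2 * (1.0 - e) ** 2 / (2.0 * beta * beta)
    qxx = (sigma2 / (beta * beta)) * (
        dt - 2.0 * (1.0 - e) / beta + (1.0 - e * e) / (2.0 * beta)
    )
    return (1.0, phi01, e), (qxx, qxv, qvv)


def kalman_loglik(
    times: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    obs_var: np.ndarray,
    beta: float,
    sigma: float,
    diffuse_pos_var: float = _DIFFUSE_POS_VAR,
    diffuse_vel_var: float = _DIFFUSE_VEL_VAR,
) -> float:
    """Exact log-likelihood of both axes via one shared-covariance filter.

    Initial state: first fix position, zero velocity, large diffuse
    covariance.  Both axes share the covariance recursion because dynamics
    and per-fix error variances are identical across axes.
    """
    sigma2 = sigma * sigma
    n = len(times)
    ax, bx = float(xs[0]), 0.0
    ay, by = float(ys[0]), 0.0
    p00, p01, p11 = diffuse_pos_var, 0.0, diffuse_vel_var
    t_prev = float(times[0])
    ll = 0.0
    log2pi = math.log(2.0 * math.pi)
    for i in range(n):
        dt = float(times[i]) - t_prev
        if dt > 0.0:
            (f0, f1, e), (qxx, qxv, qvv) = _phi_q(beta, sigma2, dt)
            ax, bx = ax + f1 * bx, e * bx
            ay, by = ay + f1 * by, e * by
            np00 = p00 + 2.0 * f1 * p01 + f1 * f1 * p11 + qxx
            np01 = e * (p01 + f1 * p11) + qxv
            np11 = e * e * p11 + qvv
            p00, p01, p11 = np00, np01, np11
        t_prev = float(times[i])
        if p00 < 0.0:  # guard against cancellation at extreme trial params
            p00 = 0.0
        if p11 < 0.0:
            p11 = 0.0
        s = p00 + float(obs_var[i])
        if s <= 0.0:
            raise FloatingPointError("non-positive innovation variance")
        ex = float(xs[i]) - ax
        ey = float(ys[i]) - ay
        ll += -0.5 * (2.0 * (log2pi + math.log(s)) + (ex * ex + ey * ey) / s)
        kx = p00 / s
        kv = p01 / s
        ax += kx * ex
        bx += kv * ex
        ay += kx * ey
        by += kv * ey
        p00, p01, p11 = p00 - kx * p00, p01 - kx * p01, p11 - kv * p01
    return ll


@dataclass
class CtcrwFit:
    """Fitted CTCRW parameters for one track."""

    beta_hat: float
    sigma_hat: float
    beta_se: float
    sigma_se: float
    loglik: float
    converged: bool
    n_fixes: int
    message: str = ""

    @property
    def aic(self) -> float:
        return 2 * 2 - 2 * self.loglik


def _track_arrays(track):
    f = track.fixes
    return (
        f["t"].to_numpy(float),
        f["x_km"].to_numpy(float),
        f["y_km"].to_numpy(float),
        (f["error_sd_m"].to_numpy(float) / 1000.0) ** 2,
    )


_STARTS = [(0.5, 2.0), (0.05, 0.5), (2.0, 8.0)]


def fit_ctcrw(track, starts=_STARTS) -> CtcrwFit:
    """Maximum-likelihood (beta, sigma) by Nelder-Mead on the log scale.

    Requires at least 10 fixes spanning at least 20 days.  Standard errors
    come from the numerical Hessian of the negative log-likelihood in log
    parameters, delta-method transformed to the natural scale.
    """
    times, xs, ys, obs_var = _track_arrays(track)
    if len(times) < 10:
        raise ValueError("need at least 10 fixes to fit the movement model")
    if times[-1] - times[0] < 20:
        raise ValueError("need fixes spanning at least 20 days")
    if np.all(times == times[0]):
        raise ValueError("degenerate track: all fixes at one time")

    def nll(theta):
        b, s = math.exp(theta[0]), math.exp(theta[1])
        try:
            out = -kalman_loglik(times, xs, ys, obs_var, b, s)
        except (OverflowError, FloatingPointError, ValueError, ZeroDivisionError):
            return 1e12
        return out if math.isfinite(out) else 1e12

    best = None
    for b0, s0 in starts:
        res = minimize(
            nll,
            x0=[math.log(b0), math.log(s0)],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    beta_hat, sigma_hat = math.exp(theta[0]), math.exp(theta[1])

    # numerical Hessian of nll in log-params
    h = 1e-4
    H = np.zeros((2, 2))
    f0 = nll(theta)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            fpp = nll(theta + ei + ej)
            fpm = nll(theta + ei - ej)
            fmp = nll(theta - ei + ej)
            fmm = nll(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_log = np.array([np.nan, np.nan])

    return CtcrwFit(
        beta_hat=beta_hat,
        sigma_hat=sigma_hat,
        beta_se=beta_hat * float(se_log[0]),
        sigma_se=sigma_hat * float(se_log[1]),
        loglik=-best.fun,
        converged=bool(best.success and np.isfinite(f0)),
        n_fixes=len(times),
        message=best.message,
    )


def _filter_smooth(times, xs, ys, obs_var, has_obs, beta, sigma):
    """Kalman filter + RTS smoother over a merged epoch grid.

    `has_obs` marks epochs carrying an observation.  Returns smoothed means
    per axis and smoothed covariances (shared across axes).
    """
    sigma2 = sigma * sigma
    n = len(times)
    m_f = np.zeros((n, 2, 2))  # epoch, axis, (pos, vel)
    P_f = np.zeros((n, 2, 2))
    m_p = np.zeros((n, 2, 2))
    P_p = np.zeros((n, 2, 2))
    Phi = np.zeros((n, 2, 2))  # transition INTO epoch i from i-1

    first = int(np.argmax(has_obs))
    m = np.array([[xs[first], 0.0], [ys[first], 0.0]])
    P = np.diag([_DIFFUSE_POS_VAR, _DIFFUSE_VEL_VAR])
    t_prev = times[0]
    for i in range(n):
        dt = times[i] - t_prev
        (f0, f1, e), (qxx, qxv, qvv) = _phi_q(beta, sigma2, dt)
        F = np.array([[1.0, f1], [0.0, e]])
        Q = np.array([[qxx, qxv], [qxv, qvv]])
        m = m @ F.T
        P = F @ P @ F.T + Q
        t_prev = times[i]
        Phi[i] = F
        m_p[i], P_p[i] = m, P
        if has_obs[i]:
            s = P[0, 0] + obs_var[i]
            K = P[:, 0] / s
            innov = np.array([xs[i], ys[i]]) - m[:, 0]
            m = m + np.outer(innov, K)
            P = P - np.outer(K, P[0, :])  # (I - K H) P with K = P[:,0]/s
            P = 0.5 * (P + P.T)
        m_f[i], P_f[i] = m, P

    m_s = np.copy(m_f)
    P_s = np.copy(P_f)
    for i in range(n - 2, -1, -1):
        Pp = P_p[i + 1]
        C = P_f[i] @ Phi[i + 1].T @ np.linalg.inv(Pp)
        m_s[i] = m_f[i] + (m_s[i + 1] - m_p[i + 1]) @ C.T
        P_s[i] = P_f[i] + C @ (P_s[i + 1] - Pp) @ C.T
    return m_s, P_s


@dataclass
class PredictedPath:
    """Regularised daily positions with uncertainty and gap flags."""

    days: np.ndarray  # integer day index (days since 1 Jan of start year)
    x: np.ndarray
    y: np.ndarray
    sd_km: np.ndarray
    gap_excluded: np.ndarray
    observed_support: np.ndarray  # days to nearest observation

    def __len__(self) -> int:
        return len(self.days)


def smooth_at(track, fit: CtcrwFit, pred_times: np.ndarray):
    """Smoothed state mean/SD at arbitrary epochs, merged with the fixes."""
    times, xs, ys, obs_var = _track_arrays(track)
    pred_times = np.asarray(pred_times, float)
    all_t = np.concatenate([times, pred_times])
    all_x = np.concatenate([xs, np.zeros(len(pred_times))])
    all_y = np.concatenate([ys, np.zeros(len(pred_times))])
    all_v = np.concatenate([obs_var, np.zeros(len(pred_times))])
    has_obs = np.concatenate(
        [np.ones(len(times), bool), np.zeros(len(pred_times), bool)]
    )
    order = np.argsort(all_t, kind="stable")
    m_s, P_s = _filter_smooth(
        all_t[order], all_x[order], all_y[order], all_v[order], has_obs[order],
        fit.beta_hat, fit.sigma_hat,
    )
    pos = np.empty(len(order), dtype=int)
    pos[order] = np.arange(len(order))
    idx = pos[len(times):]
    px = m_s[idx, 0, 0]
    py = m_s[idx, 1, 0]
    sd = np.sqrt(np.clip(P_s[idx, 0, 0], 0, None))
    return px, py, sd


def predict_daily(
    fit: CtcrwFit, track, start_day: int, end_day: int, max_gap_days: float = 14.0
) -> PredictedPath:
    """Smoothed daily (00:00) positions from start_day to end_day inclusive.

    Days whose bracketing observations are more than `max_gap_days` apart
    are flagged gap_excluded (days outside the observation span have no
    bracket and are likewise flagged); they remain listed so coverage can be
    reported, but downstream land-day counts omit them.
    """
    if not fit.converged and not np.isfinite(fit.loglik):
        raise ValueError("cannot predict from a non-converged fit")
    times = track.fixes["t"].to_numpy(float)
    days = np.arange(int(start_day), int(end_day) + 1)
    epochs = days.astype(float)
    px, py, sd = smooth_at(track, fit, epochs)

    gap = np.zeros(len(days), bool)
    support = np.empty(len(days))
    for k, t in enumerate(epochs):
        i = np.searchsorted(times, t, side="right")
        before = times[i - 1] if i > 0 else None
        after = times[i] if i < len(times) else None
        support[k] = min(
            abs(t - before) if before is not None else np.inf,
            abs(after - t) if after is not None else np.inf,
        )
        if before is None or after is None:
            gap[k] = True
        elif after - before > max_gap_days:
            gap[k] = True
    return PredictedPath(days, px, py, sd, gap, support)


@dataclass
class GapValidationResult:
    proportion_on_land: float
    se: float
    n_midpoints: int


def crossvalidate_withheld(track, coast, fit=None, n_withheld: int = 5, seed: int = 0):
    """Withheld-location cross-validation of land/ice classification.

    Withholds `n_withheld` observed fixes at random, refits, predicts at the
    withheld times and compares the predicted on-land status against the
    status of the observed positions.  Returns the misclassification rate.
    """
    n = track.n_fixes
    if n <= n_withheld:
        raise ValueError("track too short for withheld-location validation")
    rng = np.random.default_rng(seed)
    withheld = np.sort(rng.choice(n, size=n_withheld, replace=False))
    mask = np.ones(n, bool)
    mask[withheld] = False
    sub = track.subset(mask)
    subfit = fit_ctcrw(sub)
    f = track.fixes
    t_w = f["t"].to_numpy(float)[withheld]
    px, py, _ = smooth_at(sub, subfit, t_w)
    obs_status = [
        coast.on_land(f["x_km"].iloc[i], f["y_km"].iloc[i]) for i in withheld
    ]
    pred_status = [coast.on_land(x, y) for x, y in zip(px, py)]
    return float(np.mean([o != p for o, p in zip(obs_status, pred_status)]))


def validate_gap_midpoints(tracks, coast, fits=None, half_window: float = 7.0):
    """Fourteen-day-gap validation against observed on-land midpoints.

    For every observed on-land fix with another observation at least
    `half_window` days before and after, all observations strictly inside
    the 14-day window are removed, the midpoint is re-predicted with the
    track's fitted parameters, and the on-land indicator of the prediction
    is recorded.  Returns the mean indicator with its binomial SE.
    """
    indicators: list[bool] = []
    for k, track in enumerate(tracks):
        fit = fits[k] if fits is not None else fit_ctcrw(track)
        f = track.fixes
        times = f["t"].to_numpy(float)
        xs = f["x_km"].to_numpy(float)
        ys = f["y_km"].to_numpy(float)
        for i in range(len(times)):
            if not coast.on_land(xs[i], ys[i]):
                continue
            t_m = times[i]
            if not (
                np.any(times <= t_m - half_window)
                and np.any(times >= t_m + half_window)
            ):
                continue
            keep = np.abs(times - t_m) >= half_window
            sub = track.subset(keep)
            px, py, _ = smooth_at(sub, fit, np.array([t_m]))
            indicators.append(coast.on_land(float(px[0]), float(py[0])))
    n = len(indicators)
    if n == 0:
        return GapValidationResult(float("nan"), float("nan"), 0)
    p = float(np.mean(indicators))
    se = math.sqrt(p * (1 - p) / n) if n > 1 else float("nan")
    return GapValidationResult(p, se, n)


def data_gap_fraction(track, threshold_days: float = 4.0) -> float:
    """Fraction of between-fix intervals exceeding `threshold_days`."""
    t = track.fixes["t"].to_numpy(float)
    if len(t) < 2:
        return float("nan")
    return float(np.mean(np.diff(t) > threshold_days))
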