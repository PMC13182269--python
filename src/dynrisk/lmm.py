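"""Random-intercept / random-slope linear mixed model, fitted by ML.

The model for subject i at time t is

    y_i(t) = beta0 + beta1 * t + b0_i + b1_i * t + eps,
    (b0_i, b1_i) ~ N(0, D),  eps ~ N(0, sigma2),

i.e. the ``value ~ time + (time | subject)`` formula. Estimation is plain
maximum likelihood (not REML) so the log-likelihood composes exactly with
the survival part of the joint model when the association is zero. The
2x2 covariance D is parameterized by its log-Cholesky factor and the
fixed effects are profiled out by GLS, leaving a 4-parameter quasi-Newton
problem.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .datasets import LongitudinalDataset

__all__ = ["LMMFit", "fit_lmm", "lmm_loglik", "predict_blup", "subject_arrays"]

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_CHOL_LOG_LB, _CHOL_LOG_UB = np.log(1e-6), np.log(1e3)
_SIGMA_LOG_LB = np.log(1e-8)


class NonIdentifiableError(ValueError):
    """Raised when the slope (or another parameter) cannot be identified."""


@dataclass
class LMMFit:
    beta: np.ndarray            # (2,) fixed intercept and slope
    D: np.ndarray               # (2, 2) random-effect covariance
    sigma2: float               # residual variance
    loglik: float
    converged: bool
    blups: dict = field(default_factory=dict)   # subject_id -> (b0, b1)
    boundary: bool = False

    @property
    def params(self) -> dict:
        return {"beta": self.beta, "D": self.D, "sigma2": self.sigma2}


def subject_arrays(data: LongitudinalDataset) -> list[tuple[object, np.ndarray, np.ndarray]]:
    """Per-subject (id, times, values) arrays from a single-feature dataset."""
    if data.n_features != 1:
        raise ValueError(f"expected a single-feature dataset, got {data.n_features} features")
    meas = data.measurements
    out = []
    grouped = meas.groupby("subject_id", sort=False)
    order = {sid: k for k, sid in enumerate(data.subjects["subject_id"])}
    items = sorted(grouped, key=lambda kv: order.get(kv[0], len(order)))
    for sid, df in items:
        out.append((sid, df["time"].to_numpy(float), df["value"].to_numpy(float)))
    return out


def _chol_from_packed(u: np.ndarray) -> np.ndarray:
    L = np.zeros((2, 2))
    L[0, 0] = np.exp(u[0])
    L[1, 1] = np.exp(u[1])
    L[1, 0] = u[2]
    return L


def _pack_chol(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, float)
    jitter = 0.0
    for _ in range(6):
        try:
            L = np.linalg.cholesky(D + jitter * np.eye(2))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10)
    else:  # pragma: no cover
        L = np.diag(np.sqrt(np.maximum(np.diag(D), 1e-12)))
    return np.array(
        [np.log(max(L[0, 0], 1e-6)), np.log(max(L[1, 1], 1e-6)), L[1, 0]]
    )


def _marginal_loglik_subject(t, y, beta, D, sigma2) -> float:
    Z = np.column_stack([np.ones_like(t), t])
    V = Z @ D @ Z.T + sigma2 * np.eye(len(t))
    resid = y - Z @ beta
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    return -0.5 * (len(t) * _LOG2PI + logdet + resid @ np.linalg.solve(V, resid))


def lmm_loglik(params: dict, data: LongitudinalDataset) -> float:
    """Marginal Gaussian log-likelihood at explicit parameters.

    ``params`` carries ``beta`` (length 2), ``D`` (2x2 PSD) and
    ``sigma2`` (> 0).
    """
    beta = np.asarray(params["beta"], float)
    D = np.asarray(params["D"], float)
    sigma2 = float(params["sigma2"])
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    eigs = np.linalg.eigvalsh((D + D.T) / 2)
    if eigs.min() < -1e-10:
        raise ValueError("D must be positive semidefinite")
    total = 0.0
    for _, t, y in subject_arrays(data):
        total += _marginal_loglik_subject(t, y, beta, D, sigma2)
    return float(total)


def _profiled_negloglik(u: np.ndarray, subjects) -> tuple[float, np.ndarray]:
    """Negative loglik with beta profiled out by GLS, plus the GLS beta."""
    L = _chol_from_packed(u[:3])
    D = L @ L.T
    sigma2 = np.exp(u[3])
    XtVX = np.zeros((2, 2))
    XtVy = np.zeros(2)
    pieces = []
    for _, t, y in subjects:
        Z = np.column_stack([np.ones_like(t), t])
        V = Z @ D @ Z.T + sigma2 * np.eye(len(t))
        try:
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(2)  # finite penalty keeps line searches alive
        XtVX += Z.T @ Vinv @ Z
        XtVy += Z.T @ Vinv @ y
        sign, logdet = np.linalg.slogdet(V)
        pieces.append((Z, y, Vinv, logdet))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros(2)
    nll = 0.0
    for Z, y, Vinv, logdet in pieces:
        r = y - Z @ beta
        nll += 0.5 * (len(y) * _LOG2PI + logdet + r @ Vinv @ r)
    return nll, beta


def fit_lmm(
    data: LongitudinalDataset,
    tol: float = 1e-8,
    n_restarts: int = 3,
    seed: int = 0,
) -> LMMFit:
    """ML fit of the random-intercept/random-slope model for one feature."""
    subjects = subject_arrays(data)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    all_times = np.concatenate([t for _, t, _ in subjects])
    all_y = np.concatenate([y for _, _, y in subjects])
    if len(np.unique(all_times)) < 2:
        raise NonIdentifiableError("all measurement times identical; slope not identifiable")

    # moment-based start: pooled OLS for beta, residual variance split
    X = np.column_stack([np.ones_like(all_times), all_times])
    beta_ols, *_ = np.linalg.lstsq(X, all_y, rcond=None)
    resid_var = max(np.var(all_y - X @ beta_ols), 1e-6)
    u0 = np.concatenate(
        [_pack_chol(np.diag([resid_var / 4, resid_var / 100])), [np.log(resid_var / 2)]]
    )

    rng = np.random.default_rng(seed)
    best = None
    starts = [u0]
    for attempt, start in enumerate(starts):
        res = optimize.minimize(
            lambda u: _profiled_negloglik(u, subjects)[0],
            start,
            method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-7, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if best.success:
            break
        if len(starts) < n_restarts:  # jittered restart on non-convergence
            starts.append(u0 + rng.normal(0, 0.3, size=4))

    u = best.x
    L = _chol_from_packed(u[:3])
    D = L @ L.T
    sigma2 = float(np.exp(u[3]))
    _, beta = _profiled_negloglik(u, subjects)
    loglik = -float(best.fun)
    boundary = bool(u[0] < _CHOL_LOG_LB + 1e-6 or u[1] < _CHOL_LOG_LB + 1e-6)
    if boundary:
        warnings.warn("random-effect covariance at boundary (near-singular D)", RuntimeWarning)
    fit = LMMFit(
        beta=beta,
        D=D,
        sigma2=sigma2,
        loglik=loglik,
        converged=bool(best.success),
        boundary=boundary,
    )
    fit.blups = {
        sid: predict_blup(fit, t, y) for sid, t, y in subjects
    }
    return fit


def predict_blup(fit: LMMFit, times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Empirical-Bayes (posterior mean) random effects for one subject.

    Closed-form Gaussian posterior given the fitted population
    parameters. With no observations the prior mean (0, 0) is returned.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if t.size == 0:
        return (0.0, 0.0)
    D = fit.D
    if np.linalg.det(D) < 1e-14 and np.abs(D).max() < 1e-7:
        return (0.0, 0.0)
    Z = np.column_stack([np.ones_like(t), t])
    r = y - Z @ fit.beta
    # posterior precision = Z'Z/sigma2 + D^-1 ; use the V-form to tolerate singular D
    V = Z @ D @ Z.T + fit.sigma2 * np.eye(len(t))
    b = D @ Z.T @ np.linalg.solve(V, r)
    return (float(b[0]), float(b[1]))
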