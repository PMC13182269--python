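"""Joint latent-class mixed model.

Latent subgroups share the random-effect covariance and residual
variance but have class-specific fixed trajectories (intercept + slope)
and class-specific Weibull hazards under a proportional-hazards
constraint (shared shape, class-specific rate). Class membership is an
intercept-only multinomial. Conditional on class, the longitudinal and
survival parts are independent, so the subject likelihood is

    L_i = sum_g pi_g * N(y_i; Z beta_g, Z D Z' + sigma2 I)
                   * h_g(T_i)^delta_i * exp(-Lambda_g(T_i)).

Estimation is a generalized EM: posterior class weights in the E-step;
closed-form pi and class-rate updates, a profiled 1-D search for the
shared Weibull shape, and a short quasi-Newton pass over the variance
parameters (with class fixed effects profiled by weighted GLS) in the
M-step. The observed log-likelihood is non-decreasing across iterations.
Model size is chosen by BIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .datasets import LongitudinalDataset
from .joint import _Prepared, _lmm_loglik_vec, fit_null_weibull
from .lmm import _chol_from_packed, _pack_chol, fit_lmm

__all__ = ["JLCMFit", "fit_jlcm", "grid_search_fit", "select_ng", "class_risk_score"]

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class JLCMFit:
    ng: int
    pi: np.ndarray                  # (G,) class probabilities
    class_beta: np.ndarray          # (G, 2) per-class intercept and slope
    D: np.ndarray                   # shared 2x2 random-effect covariance
    sigma2: float
    log_kappa: float                # shared Weibull shape (log)
    log_lambda: np.ndarray          # (G,) class-specific log rates
    posteriors: np.ndarray          # (n, G) subject class probabilities
    loglik: float
    bic: float
    converged: bool
    class_sizes: np.ndarray = field(default_factory=lambda: np.array([]))
    n_iter: int = 0
    loglik_history: list = field(default_factory=list)
    subject_ids: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        g = self.ng
        return (g - 1) + 2 * g + 3 + 1 + 1 + g

    def min_class_size_ok(self, min_size: int = 5) -> bool:
        """Class-size constraint on modal assignments (> min_size per class)."""
        return bool(np.all(self.class_sizes > min_size))


def _component_logliks(prep: _Prepared, pi, class_beta, D, sigma2, log_kappa, log_lambda):
    """(n, G) array of log[pi_g * f_long * f_surv] per subject and class."""
    G = len(pi)
    kappa = np.exp(log_kappa)
    out = np.empty((len(prep), G))
    logT = np.log(prep.T)
    for g in range(G):
        ll_long = _lmm_loglik_vec(prep, class_beta[g], D, sigma2)
        ll_surv = prep.delta * (log_kappa + log_lambda[g] + (kappa - 1) * logT) \
            - np.exp(log_lambda[g]) * prep.T ** kappa
        out[:, g] = np.log(max(pi[g], 1e-300)) + ll_long + ll_surv
    return out


def _mixture_loglik(comp: np.ndarray) -> float:
    mx = comp.max(axis=1, keepdims=True)
    return float(np.sum(mx[:, 0] + np.log(np.exp(comp - mx).sum(axis=1))))


def _suffstats(prep: _Prepared) -> dict:
    """Per-subject sufficient statistics for GLS (independent of parameters)."""
    m = prep.mask
    t = np.where(m, prep.t, 0.0)
    y = np.where(m, prep.y, 0.0)
    return {
        "n": prep.n_obs.astype(float),
        "st": t.sum(1),
        "stt": (t * t).sum(1),
        "sy": y.sum(1),
        "sty": (t * y).sum(1),
    }


def _weighted_gls_beta(stats: dict, w_g, D, sigma2) -> np.ndarray:
    """Weighted GLS fixed effects for one class, via the Woodbury identity.

    Z'V^-1 Z = M/s2 - M Sigma M / s2^2 and Z'V^-1 y likewise, with
    M = Z'Z and Sigma = (M/s2 + D^-1)^-1, all 2x2 and vectorized.
    """
    n, st, stt = stats["n"], stats["st"], stats["stt"]
    sy, sty = stats["sy"], stats["sty"]
    Dinv = np.linalg.inv(D + 1e-12 * np.eye(2))
    a11 = n / sigma2 + Dinv[0, 0]
    a12 = st / sigma2 + Dinv[0, 1]
    a22 = stt / sigma2 + Dinv[1, 1]
    det = a11 * a22 - a12 * a12
    s11, s12, s22 = a22 / det, -a12 / det, a11 / det
    # u = Sigma @ (Z'Z columns), v = Sigma @ Z'y
    v0 = s11 * sy + s12 * sty
    v1 = s12 * sy + s22 * sty
    # M Sigma M entries (M symmetric with entries [[n, st], [st, stt]])
    m00, m01, m11 = n, st, stt
    q00 = m00 * (s11 * m00 + s12 * m01) + m01 * (s12 * m00 + s22 * m01)
    q01 = m00 * (s11 * m01 + s12 * m11) + m01 * (s12 * m01 + s22 * m11)
    q11 = m01 * (s11 * m01 + s12 * m11) + m11 * (s12 * m01 + s22 * m11)
    g00 = m00 / sigma2 - q00 / sigma2**2
    g01 = m01 / sigma2 - q01 / sigma2**2
    g11 = m11 / sigma2 - q11 / sigma2**2
    h0 = sy / sigma2 - (m00 * v0 + m01 * v1) / sigma2**2
    h1 = sty / sigma2 - (m01 * v0 + m11 * v1) / sigma2**2
    XtVX = np.array([[w_g @ g00, w_g @ g01], [w_g @ g01, w_g @ g11]])
    XtVy = np.array([w_g @ h0, w_g @ h1])
    # tiny ridge keeps near-empty classes numerically solvable
    return np.linalg.solve(XtVX + 1e-10 * np.eye(2), XtVy)


def fit_jlcm(
    data: LongitudinalDataset,
    ng: int = 2,
    start: dict | None = None,
    max_iter: int = 200,
    tol: float = 1e-7,
    min_class_weight: float = 1e-3,
) -> JLCMFit:
    """Generalized-EM fit with ``ng`` latent classes.

    ``ng = 1`` reduces exactly to the separable LMM + censored-Weibull
    fit. An empty-class collapse triggers one perturbed restart before
    the fit is flagged non-converged.
    """
    if ng < 1:
        raise ValueError("ng must be >= 1")
    prep = _Prepared(data)
    n = len(prep)

    if ng == 1:
        lfit = fit_lmm(data)
        lk, ll = fit_null_weibull(prep.T, prep.delta)
        from .joint import weibull_surv_loglik

        loglik = lfit.loglik + weibull_surv_loglik(lk, ll, prep.T, prep.delta)
        fit = JLCMFit(
            ng=1,
            pi=np.array([1.0]),
            class_beta=lfit.beta[None, :].copy(),
            D=lfit.D,
            sigma2=lfit.sigma2,
            log_kappa=lk,
            log_lambda=np.array([ll]),
            posteriors=np.ones((n, 1)),
            loglik=loglik,
            bic=-2 * loglik + 8 * np.log(n),
            converged=lfit.converged,
            class_sizes=np.array([n]),
            subject_ids=list(prep.ids),
        )
        return fit

    params = start if start is not None else _canonical_start(data, prep, ng)
    attempt = 0
    while True:
        fit = _em_loop(prep, ng, params, max_iter, tol, min_class_weight)
        if fit is not None:
            break
        attempt += 1
        if attempt > 1:
            # collapsed twice: return a flagged non-converged degenerate fit
            fit = _em_loop(prep, ng, params, max_iter, tol, min_class_weight=0.0)
            fit.converged = False
            break
        rng = np.random.default_rng(12345)
        params = _perturb(params, rng, scale=0.5)
        logger.warning("empty class collapse; restarting EM from perturbed start")
    fit.subject_ids = list(prep.ids)
    return fit


def _canonical_start(data, prep: _Prepared, ng: int) -> dict:
    """Start from the one-class fit, splitting classes along the slope axis."""
    lfit = fit_lmm(data)
    lk, ll = fit_null_weibull(prep.T, prep.delta)
    slope_sd = max(np.sqrt(max(lfit.D[1, 1], 0.0)), 0.05)
    offsets = np.linspace(-1, 1, ng)
    return {
        "pi": np.full(ng, 1.0 / ng),
        "class_beta": np.stack(
            [lfit.beta + np.array([0.0, o * slope_sd]) for o in offsets]
        ),
        "D": lfit.D,
        "sigma2": lfit.sigma2,
        "log_kappa": lk,
        "log_lambda": np.full(ng, ll) + np.linspace(-0.2, 0.2, ng),
    }


def _perturb(params: dict, rng: np.random.Generator, scale: float = 0.3) -> dict:
    out = {k: np.copy(v) if isinstance(v, np.ndarray) else v for k, v in params.items()}
    out["class_beta"] = out["class_beta"] + rng.normal(
        0, scale * (0.1 + np.abs(out["class_beta"]).mean()), out["class_beta"].shape
    )
    out["log_lambda"] = out["log_lambda"] + rng.normal(0, scale, out["log_lambda"].shape)
    p = np.abs(out["pi"] + rng.normal(0, 0.1, len(out["pi"])))
    out["pi"] = p / p.sum()
    return out


def _em_loop(prep, ng, params, max_iter, tol, min_class_weight):
    pi = np.array(params["pi"], float)
    class_beta = np.array(params["class_beta"], float)
    D = np.array(params["D"], float)
    sigma2 = float(params["sigma2"])
    log_kappa = float(params["log_kappa"])
    log_lambda = np.array(params["log_lambda"], float)
    n = len(prep)

    history = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        comp = _component_logliks(prep, pi, class_beta, D, sigma2, log_kappa, log_lambda)
        loglik = _mixture_loglik(comp)
        history.append(loglik)
        # E-step
        mx = comp.max(axis=1, keepdims=True)
        w = np.exp(comp - mx)
        w /= w.sum(axis=1, keepdims=True)
        if min_class_weight > 0 and np.any(w.sum(axis=0) < min_class_weight * n):
            return None  # class collapse -> caller restarts
        # M-step: membership
        pi = w.mean(axis=0)
        # M-step: survival (profile shared shape, closed-form rates)
        d_g = w.T @ prep.delta

        def neg_surv(lk):
            kap = np.exp(lk)
            Tk = prep.T ** kap
            val = 0.0
            for g in range(ng):
                denom = w[:, g] @ Tk
                lam_g = max(d_g[g], 1e-12) / max(denom, 1e-300)
                val += d_g[g] * (lk + np.log(lam_g)) \
                    + (kap - 1) * (w[:, g] @ (prep.delta * np.log(prep.T))) \
                    - lam_g * denom
            return -val

        res = optimize.minimize_scalar(neg_surv, bounds=(-4, 5), method="bounded")
        log_kappa = float(res.x)
        kap = np.exp(log_kappa)
        Tk = prep.T ** kap
        for g in range(ng):
            log_lambda[g] = np.log(max(d_g[g], 1e-12) / max(w[:, g] @ Tk, 1e-300))
        # M-step: longitudinal (short quasi-Newton on variance params,
        # class fixed effects profiled by weighted GLS)
        u0 = np.concatenate([_pack_chol(D), [np.log(sigma2)]])
        stats = _suffstats(prep)

        def neg_q(u):
            L = _chol_from_packed(u[:3])
            D_ = L @ L.T
            s2_ = np.exp(u[3])
            total = 0.0
            betas = []
            for g in range(ng):
                try:
                    bg = _weighted_gls_beta(stats, w[:, g], D_, s2_)
                except np.linalg.LinAlgError:
                    bg = class_beta[g]
                betas.append(bg)
                total += w[:, g] @ _lmm_loglik_vec(prep, bg, D_, s2_)
            if not np.isfinite(total):
                return np.inf, np.array(class_beta)
            return -total, np.stack(betas)

        res = optimize.minimize(
            lambda u: neg_q(u)[0], u0, method="L-BFGS-B",
            bounds=[(np.log(1e-6), np.log(1e3))] * 2 + [(-50, 50), (np.log(1e-8), 20)],
            options={"maxiter": 25, "ftol": 1e-10},
        )
        u = res.x if res.fun <= neg_q(u0)[0] else u0  # GEM: never decrease Q
        L = _chol_from_packed(u[:3])
        D = L @ L.T
        sigma2 = float(np.exp(u[3]))
        _, class_beta = neg_q(u)

        if loglik - prev < tol * (1 + abs(loglik)) and it > 1:
            converged = True
            break
        prev = loglik

    comp = _component_logliks(prep, pi, class_beta, D, sigma2, log_kappa, log_lambda)
    loglik = _mixture_loglik(comp)
    history.append(loglik)
    mx = comp.max(axis=1, keepdims=True)
    post = np.exp(comp - mx)
    post /= post.sum(axis=1, keepdims=True)
    modal = post.argmax(axis=1)
    class_sizes = np.bincount(modal, minlength=ng)
    n_params = (ng - 1) + 2 * ng + 3 + 1 + 1 + ng
    return JLCMFit(
        ng=ng, pi=pi, class_beta=class_beta, D=D, sigma2=sigma2,
        log_kappa=log_kappa, log_lambda=log_lambda, posteriors=post,
        loglik=loglik, bic=-2 * loglik + n_params * np.log(n),
        converged=converged, class_sizes=class_sizes, n_iter=it,
        loglik_history=history,
    )


def grid_search_fit(
    data: LongitudinalDataset,
    ng: int = 2,
    n_starts: int = 10,
    seed: int = 0,
    **kwargs,
) -> JLCMFit:
    """Best-of-``n_starts`` EM fits from jittered canonical starts."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if ng == 1:
        return fit_jlcm(data, ng=1, **kwargs)
    prep = _Prepared(data)
    base = _canonical_start(data, prep, ng)
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        start = base if k == 0 else _perturb(base, rng)
        fit = fit_jlcm(data, ng=ng, start=start, **kwargs)
        if best is None:
            best = fit
        elif fit.converged and (not best.converged or fit.loglik > best.loglik):
            best = fit
    return best


def select_ng(
    data: LongitudinalDataset,
    candidates=(1, 2),
    n_starts: int = 10,
    seed: int = 0,
    **kwargs,
) -> JLCMFit:
    """Fit each candidate class count and return the minimum-BIC fit.

    Ties break toward the smaller class count (candidates are scanned in
    ascending order with a strict improvement requirement).
    """
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("candidates must be non-empty")
    best = None
    for ng in candidates:
        fit = grid_search_fit(data, ng=ng, n_starts=n_starts, seed=seed, **kwargs)
        if best is None or fit.bic < best.bic - 1e-9:
            best = fit
    return best


def class_risk_score(
    fit: JLCMFit, times: np.ndarray, values: np.ndarray, s: float, t: float
) -> float:
    """Posterior-weighted class-specific conditional event probability.

    ``times``/``values`` are the subject's measurements up to ``s``;
    survival to ``s`` enters the class posterior. Returns
    sum_g P(g | history, T > s) * (1 - S_g(t) / S_g(s)).
    """
    if t < s:
        raise ValueError("t must be >= s")
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    kappa = np.exp(fit.log_kappa)
    lam = np.exp(fit.log_lambda)
    logw = np.log(np.maximum(fit.pi, 1e-300)).copy()
    for g in range(fit.ng):
        if times.size:
            Z = np.column_stack([np.ones_like(times), times])
            V = Z @ fit.D @ Z.T + fit.sigma2 * np.eye(len(times))
            r = values - Z @ fit.class_beta[g]
            sign, logdet = np.linalg.slogdet(V)
            logw[g] += -0.5 * (len(times) * _LOG2PI + logdet + r @ np.linalg.solve(V, r))
        logw[g] += -lam[g] * s ** kappa  # survival to s
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    cond_risk = 1.0 - np.exp(-lam * (t ** kappa - s ** kappa))
    return float(np.clip(w @ cond_risk, 0.0, 1.0))
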