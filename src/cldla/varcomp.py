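"""REML estimation of the two-random-effect mixed model, and the LRT.

The model is y = Xβ + Σ_c u_c + e with u_c ~ N(0, σ²_c K_c) for each
relationship matrix K_c (polygenic always, QTL per window) and
e ~ N(0, σ²_e I).  The restricted log-likelihood is

    ℓ_R = -(1/2) [ (n-p) log 2π + log|V| + log|X'V⁻¹X| + y'Py ]

with V = Σ_c σ²_c K_c + σ²_e I and P the REML projection.  The 2π
constant is included so closed-form oracles match absolutely, not only
in differences.

The residual variance is profiled out analytically: with variance
ratios γ_c = σ²_c/σ²_e and H = I + Σ γ_c K_c, the profiled optimum is
σ̂²_e = y'P̃y/(n-p).  One-kernel models are accelerated by an
eigen-decomposition of K (every evaluation is then O(n)); with two or
more kernels each evaluation is a Cholesky factorisation.  The
contract is the maximised ℓ_R, not the algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .kinship import RelationshipMatrix

__all__ = ["MixedModelSpec", "REMLFit", "reml_fit", "lrt"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixedModelSpec:
    """Response, fixed-effect design and random-effect structures."""

    y: np.ndarray
    random: list[tuple[RelationshipMatrix, str]]
    X: np.ndarray | None = None   # default: intercept only

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = len(self.y)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response contains non-finite values")
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.shape[0] != n:
            raise ValueError("fixed design rows do not match response length")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("singular fixed-effect design")
        labels = [lab for _, lab in self.random]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate random-effect labels")
        for K, lab in self.random:
            if K.values.shape != (n, n):
                raise ValueError(f"random effect {lab!r} dimension mismatch")
        if n <= self.X.shape[1]:
            raise ValueError("need more observations than fixed effects")


@dataclass
class REMLFit:
    """One converged (or honestly non-converged) REML fit."""

    varcomp: dict[str, float]     # per-label σ², plus "residual"
    beta: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    labels: tuple[str, ...]
    n_obs: int
    y_checksum: float
    x_checksum: float


def _profiled_loglik_dense(gammas: np.ndarray, y: np.ndarray, X: np.ndarray,
                           Ks: list[np.ndarray], want_grad: bool = False):
    """ℓ_R profiled over σ²_e for H = I + Σ γ_c K_c (generic path).

    Returns (ℓ, σ̂²_e, β̂) and, when ``want_grad``, the exact gradient
    ∂ℓ/∂γ_c = -(1/2)[tr(P̃ K_c) - (r' K_c r)/σ̂²_e] with r = P̃ y
    (envelope theorem at the profiled residual variance).
    """
    n, p = X.shape
    bad = (-np.inf, np.nan, np.full(p, np.nan)) + ((np.zeros(len(Ks)),) if want_grad else ())
    H = np.eye(n)
    for g, K in zip(gammas, Ks):
        if g > 0:
            H = H + g * K
    try:
        c, low = linalg.cho_factor(H, lower=True)
    except np.linalg.LinAlgError:
        return bad
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(c))))
    Hi_y = linalg.cho_solve((c, low), y)
    Hi_X = linalg.cho_solve((c, low), X)
    XtHiX = X.T @ Hi_X
    sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    if sign <= 0:
        return bad
    A = np.linalg.inv(XtHiX)
    beta = A @ (X.T @ Hi_y)
    r = Hi_y - Hi_X @ beta          # P̃ y
    quad = float(y @ r)
    if quad <= 0:
        return bad
    sigma2_e = quad / (n - p)
    ll = -0.5 * ((n - p) * (_LOG2PI + np.log(sigma2_e) + 1.0)
                 + logdet_H + logdet_XtHiX)
    if not want_grad:
        return float(ll), float(sigma2_e), beta
    Hi = linalg.cho_solve((c, low), np.eye(n))
    grad = np.empty(len(Ks))
    for i, K in enumerate(Ks):
        KHiX = K @ Hi_X
        tr_PK = float(np.sum(Hi * K)) - float(np.sum((Hi_X @ A) * KHiX))
        grad[i] = -0.5 * (tr_PK - float(r @ K @ r) / sigma2_e)
    return float(ll), float(sigma2_e), beta, grad


def _profiled_loglik_eigen(gamma: float, lam: np.ndarray, yt: np.ndarray,
                           Xt: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Eigen-accelerated one-kernel path: H diagonal in the K basis."""
    n, p = Xt.shape
    w = 1.0 + gamma * lam
    logdet_H = float(np.sum(np.log(w)))
    wy = yt / w
    XtHiX = Xt.T @ (Xt / w[:, None])
    sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    if sign <= 0:
        return -np.inf, np.nan, np.full(p, np.nan)
    beta = np.linalg.solve(XtHiX, Xt.T @ wy)
    resid = yt - Xt @ beta
    quad = float(resid @ (resid / w))
    if quad <= 0:
        return -np.inf, np.nan, beta
    sigma2_e = quad / (n - p)
    ll = -0.5 * ((n - p) * (_LOG2PI + np.log(sigma2_e) + 1.0)
                 + logdet_H + logdet_XtHiX)
    return float(ll), float(sigma2_e), beta


def reml_fit(spec: MixedModelSpec, init: dict[str, float] | None = None,
             tol: float = 1e-6, max_iter: int = 200) -> REMLFit:
    """Maximise the restricted log-likelihood over variance components.

    ``init`` optionally provides starting σ² values keyed by label
    (used to warm-start the window scans from the null solution).
    """
    y_raw, X = spec.y, spec.X
    n, p = X.shape
    Ks = [K.values for K, _ in spec.random]
    labels = [lab for _, lab in spec.random]
    vary = float(np.var(y_raw)) if np.var(y_raw) > 0 else 1.0
    floor = 1e-8 * vary
    # optimise on a standardised response so the variance-ratio search is
    # exactly scale-equivariant; undo the scaling in the reported fit
    y_scale = float(np.sqrt(vary))
    y = y_raw / y_scale

    def finish(gammas, ll, s2e, beta, n_iter, converged):
        # undo the internal standardisation of y
        ll = ll - (n - p) * np.log(y_scale)
        s2e = s2e * y_scale**2
        beta = np.asarray(beta, float) * y_scale
        comps = {}
        for lab, g in zip(labels, gammas):
            val = g * s2e
            comps[lab] = 0.0 if val < floor else float(val)
        comps["residual"] = float(s2e)
        return REMLFit(comps, beta, float(ll), int(n_iter),
                       bool(converged), tuple(labels), n,
                       float(np.sum(y_raw)), float(np.sum(X)))

    if len(Ks) == 0:
        ll, s2e, beta = _profiled_loglik_dense(np.empty(0), y, X, Ks)
        return finish([], ll, s2e, beta, 0, True)

    if len(Ks) == 1:
        lam, U = np.linalg.eigh(Ks[0])
        yt, Xt = U.T @ y, U.T @ X

        def neg(log_gamma: float) -> float:
            return -_profiled_loglik_eigen(np.exp(log_gamma), lam, yt, Xt)[0]

        # coarse grid then local refinement: the profile is smooth in log γ
        grid = np.linspace(-25.0, 15.0, 81)
        vals = np.array([neg(g) for g in grid])
        k = int(np.argmin(vals))
        lo = grid[max(0, k - 1)]
        hi = grid[min(len(grid) - 1, k + 1)]
        res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        # compare against the γ=0 boundary explicitly
        candidates = [(0.0, *_profiled_loglik_eigen(0.0, lam, yt, Xt))]
        g_hat = float(np.exp(res.x))
        candidates.append((g_hat, *_profiled_loglik_eigen(g_hat, lam, yt, Xt)))
        g_best, ll, s2e, beta = max(candidates, key=lambda c: c[1])
        return finish([g_best], ll, s2e, beta, len(grid) + res.nfev, True)

    # two or more kernels: bounded quasi-Newton on the ratios
    if init is not None:
        start = []
        s2e0 = max(init.get("residual", vary / 2.0), floor)
        for lab in labels:
            start.append(max(init.get(lab, 0.0), 0.0) / s2e0)
        x0 = np.array(start)
    else:
        x0 = np.full(len(Ks), 0.5)

    gamma_hi = 1e6
    best = {"ll": -np.inf, "x": x0, "s2e": np.nan, "beta": None}

    def neg_with_grad(gammas: np.ndarray):
        gammas = np.clip(gammas, 0.0, gamma_hi)
        ll, s2e, beta, grad = _profiled_loglik_dense(gammas, y, X, Ks,
                                                     want_grad=True)
        if ll > best["ll"]:
            best.update(ll=ll, x=gammas.copy(), s2e=s2e, beta=beta)
        if not np.isfinite(ll):
            return 1e12, np.zeros(len(Ks))
        return -ll, -grad

    def neg_plain(gammas: np.ndarray) -> float:
        if np.any(gammas < 0) or np.any(gammas > gamma_hi):
            return 1e12
        ll, s2e, beta = _profiled_loglik_dense(gammas, y, X, Ks)
        if ll > best["ll"]:
            best.update(ll=ll, x=gammas.copy(), s2e=s2e, beta=beta)
        return -ll if np.isfinite(ll) else 1e12

    bounds = [(0.0, gamma_hi)] * len(Ks)
    res = optimize.minimize(neg_with_grad, x0, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": max_iter, "ftol": 1e-12,
                                     "gtol": 1e-9})
    nfev = res.nfev
    converged = bool(res.success)
    if not converged:
        # quasi-Newton can stall on a flat boundary profile; polish with a
        # bound-respecting simplex restart from the best point seen
        ll_before = best["ll"]
        res2 = optimize.minimize(neg_plain, np.clip(best["x"], 0.0, gamma_hi),
                                 method="Nelder-Mead",
                                 options={"maxiter": 400, "fatol": 1e-10,
                                          "xatol": 1e-10})
        nfev += res2.nfev
        converged = bool(res2.success) or (best["ll"] - ll_before) < tol
    # the reported optimum is the best point ever evaluated, which also
    # guarantees ℓ1 >= ℓ0 under a warm start at the null solution
    gammas = np.clip(best["x"], 0.0, None)
    ll, s2e, beta = best["ll"], best["s2e"], best["beta"]
    converged = converged and np.isfinite(ll)
    return finish(gammas, ll, s2e, beta, nfev, converged)


def lrt(fit_null: REMLFit, fit_alt: REMLFit) -> float:
    """Likelihood-ratio statistic −2(ℓ0 − ℓ1) for nested REML fits.

    Values in (−1e-6, 0) are clamped to 0; anything more negative is an
    optimiser failure and raises.
    """
    if not (fit_null.converged and fit_alt.converged):
        raise ValueError("both fits must have converged")
    if fit_null.n_obs != fit_alt.n_obs or fit_null.y_checksum != fit_alt.y_checksum \
            or fit_null.x_checksum != fit_alt.x_checksum:
        raise ValueError("fits are not on the same response/fixed design")
    if not set(fit_null.labels) <= set(fit_alt.labels):
        raise ValueError("null model is not nested in the alternative")
    value = -2.0 * (fit_null.loglik - fit_alt.loglik)
    if value < -1e-6:
        raise ValueError(f"negative LRT {value:.3g}: alternative optimiser failed")
    return max(0.0, value)
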