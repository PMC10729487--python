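"""Internal penalized least-squares engine with REML selection.

Fits Gaussian models of the form

    y = X_dense @ beta_d + u[fam_idx] + eps,
    penalty: sum_j lambda_j * beta_j' S_j beta_j  +  lambda_f * ||u||^2

i.e. penalized regression splines (quadratic penalties on dense coefficient
blocks) plus an optional random intercept expressed as a ridge-penalized
indicator block. Smoothing parameters and the variance ratio are selected
by restricted maximum likelihood; sigma^2 is profiled out.

The indicator block's cross-product matrix is diagonal, so everything is
solved through the Schur complement on the (small) dense part: per-fit
cost is O(n * p_dense^2) regardless of the number of families, which keeps
bootstrap refits cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = ["DenseBlock", "PLSFit", "fit_pls"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class DenseBlock:
    """A penalized block of dense design columns.

    ``S`` is the within-block penalty (PSD); its null space stays
    unpenalized and counts toward the model's fixed dimension.
    """
    name: str
    start: int
    stop: int
    S: np.ndarray
    rank: int = field(init=False)
    logdet_plus: float = field(init=False)

    def __post_init__(self):
        w = np.linalg.eigvalsh(self.S)
        tol = max(w.max(), 0.0) * 1e-10 if w.size else 0.0
        pos = w[w > tol]
        self.rank = int(len(pos))
        self.logdet_plus = float(np.sum(np.log(pos))) if self.rank else 0.0


@dataclass
class PLSFit:
    beta: np.ndarray              # dense coefficients
    u: np.ndarray                 # indicator (random-intercept) coefficients
    Vdd: np.ndarray               # unscaled covariance of dense coefficients
    sigma2: float
    lambdas: dict                 # block name -> lambda (includes "family")
    edf: dict                     # block name -> effective df
    edf_total: float
    reml: float                   # -2 * restricted log-likelihood
    n: int
    n_unpenalized: int
    fitted: np.ndarray
    resid: np.ndarray
    var_family: float             # sigma_f^2 = sigma2 / lambda_family (0 if none)

    def cov_dense(self) -> np.ndarray:
        """Posterior/Henderson covariance of the dense coefficients."""
        return self.sigma2 * self.Vdd


def _assemble_S(p_d: int, blocks, lam: dict) -> np.ndarray:
    S = np.zeros((p_d, p_d))
    for b in blocks:
        S[b.start:b.stop, b.start:b.stop] += lam[b.name] * b.S
    return S


def _solve_sym(A: np.ndarray, B):
    """Solve A X = B for symmetric PD A with a jittered Cholesky fallback."""
    jitter = 0.0
    base = np.mean(np.diag(A)) if A.size else 1.0
    for _ in range(6):
        try:
            c, low = linalg.cho_factor(A + jitter * np.eye(A.shape[0]),
                                       lower=True)
            return linalg.cho_solve((c, low), B), 2.0 * np.sum(np.log(np.diag(c)))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * max(base, 1.0))
    raise np.linalg.LinAlgError("penalized normal equations not positive definite")


class _Workspace:
    """Sufficient statistics reused across REML evaluations."""

    def __init__(self, Xd, y, fam_idx, n_fam):
        self.n, self.p_d = Xd.shape
        self.Xd = Xd
        self.y = y
        self.XtX = Xd.T @ Xd
        self.Xty = Xd.T @ y
        self.yty = float(y @ y)
        self.fam_idx = fam_idx
        self.n_fam = n_fam
        if fam_idx is not None:
            self.counts = np.bincount(fam_idx, minlength=n_fam).astype(float)
            self.Zty = np.bincount(fam_idx, weights=y, minlength=n_fam)
            # Xd' Z : per-family column sums of Xd
            A_du = np.zeros((self.p_d, n_fam))
            for j in range(self.p_d):
                A_du[j] = np.bincount(fam_idx, weights=Xd[:, j],
                                      minlength=n_fam)
            self.A_du = A_du
        else:
            self.counts = None

    def solve(self, S_d: np.ndarray, lam_f: float | None):
        """Return (beta_d, u, Vdd, rss, pen, logdetA, tr_Ainv_uu, G)."""
        A_dd = self.XtX + S_d
        if self.counts is None:
            Vdd, logdetA = _solve_sym(A_dd, np.eye(self.p_d))
            beta = Vdd @ self.Xty
            u = np.zeros(0)
            fitted = self.Xd @ beta
            resid = self.y - fitted
            rss = float(resid @ resid)
            pen = float(beta @ S_d @ beta)
            return beta, u, Vdd, rss, pen, logdetA, 0.0, None, fitted, resid
        a_uu = self.counts + lam_f
        W = self.A_du / a_uu                      # p_d x F
        S_schur = A_dd - W @ self.A_du.T
        Vdd, logdet_schur = _solve_sym(S_schur, np.eye(self.p_d))
        rhs = self.Xty - W @ self.Zty
        beta = Vdd @ rhs
        u = (self.Zty - self.A_du.T @ beta) / a_uu
        fitted = self.Xd @ beta + u[self.fam_idx]
        resid = self.y - fitted
        rss = float(resid @ resid)
        pen = float(beta @ S_d @ beta) + lam_f * float(u @ u)
        logdetA = float(np.sum(np.log(a_uu))) + logdet_schur
        # trace of the indicator block of A^{-1}
        G = Vdd @ self.A_du                        # p_d x F
        tr_uu = float(np.sum(1.0 / a_uu)
                      + np.sum(self.A_du * G, axis=0) @ (1.0 / a_uu**2))
        return beta, u, Vdd, rss, pen, logdetA, tr_uu, G, fitted, resid


def _reml_value(ws: _Workspace, blocks, lam, lam_f, n_unpen):
    S_d = _assemble_S(ws.p_d, blocks, lam)
    out = ws.solve(S_d, lam_f)
    rss_pen = max(out[3] + out[4], 1e-300)
    nm = ws.n - n_unpen
    sigma2 = rss_pen / nm
    logdetA = out[5]
    logdet_S = sum(b.rank * np.log(lam[b.name]) + b.logdet_plus
                   for b in blocks if b.rank > 0 and lam[b.name] > 0)
    if ws.counts is not None:
        logdet_S += ws.n_fam * np.log(lam_f)
    reml = nm * (_LOG2PI + np.log(sigma2) + 1.0) + logdetA - logdet_S
    return reml, sigma2, out


def fit_pls(Xd: np.ndarray, y: np.ndarray, blocks: list[DenseBlock],
            fam_idx: np.ndarray | None = None, n_fam: int = 0,
            lambdas: dict | None = None,
            log_bounds: tuple[float, float] = (-10.0, 16.0),
            maxiter: int = 400) -> PLSFit:
    """Fit the penalized model; REML-select any lambda not supplied.

    ``lambdas`` may fix a subset (keys: block names and "family"); the rest
    are optimized on the log scale within ``log_bounds``.
    """
    Xd = np.asarray(Xd, dtype=float)
    y = np.asarray(y, dtype=float)
    ws = _Workspace(Xd, y, fam_idx, n_fam)
    lambdas = dict(lambdas or {})

    names = [b.name for b in blocks if b.rank > 0]
    if fam_idx is not None:
        names.append("family")
    free = [nm for nm in names if nm not in lambdas]
    rank_total = sum(b.rank for b in blocks) + (n_fam if fam_idx is not None else 0)
    n_unpen = ws.p_d + (n_fam if fam_idx is not None else 0) - rank_total
    if ws.n <= n_unpen:
        raise ValueError("more unpenalized coefficients than observations")

    def lam_of(rho):
        lam = {b.name: lambdas.get(b.name, 1.0) for b in blocks}
        lam_f = lambdas.get("family", 1.0)
        for nm, r in zip(free, rho):
            r = float(np.clip(r, *log_bounds))
            if nm == "family":
                lam_f = np.exp(r)
            else:
                lam[nm] = np.exp(r)
        return lam, lam_f

    def objective(rho):
        lam, lam_f = lam_of(np.atleast_1d(rho))
        try:
            return _reml_value(ws, blocks, lam, lam_f, n_unpen)[0]
        except np.linalg.LinAlgError:
            return 1e12

    if free:
        if len(free) == 1:
            res = optimize.minimize_scalar(
                lambda r: objective([r]), bounds=log_bounds, method="bounded",
                options={"xatol": 1e-6})
            rho_opt = [res.x]
        else:
            res = optimize.minimize(
                objective, np.zeros(len(free)), method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-7})
            rho_opt = res.x
    else:
        rho_opt = []
    lam, lam_f = lam_of(np.atleast_1d(rho_opt) if len(free) else [])

    reml, sigma2, out = _reml_value(ws, blocks, lam, lam_f, n_unpen)
    beta, u, Vdd, rss, pen, logdetA, tr_uu, G, fitted, resid = out

    # effective degrees of freedom: edf = p - tr(A^{-1} S), blockwise
    edf = {}
    for b in blocks:
        m = b.stop - b.start
        Vb = Vdd[b.start:b.stop, b.start:b.stop]
        edf[b.name] = float(m - lam[b.name] * np.trace(Vb @ b.S))
    edf_total = ws.p_d - sum(
        lam[b.name] * np.trace(Vdd[b.start:b.stop, b.start:b.stop] @ b.S)
        for b in blocks)
    var_family = 0.0
    if fam_idx is not None:
        edf["family"] = float(n_fam - lam_f * tr_uu)
        edf_total += edf["family"]
        var_family = sigma2 / lam_f
        lam["family"] = lam_f
    return PLSFit(beta=beta, u=u, Vdd=Vdd, sigma2=sigma2, lambdas=lam,
                  edf=edf, edf_total=float(edf_total), reml=float(reml),
                  n=ws.n, n_unpenalized=n_unpen, fitted=fitted, resid=resid,
                  var_family=float(var_family))
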