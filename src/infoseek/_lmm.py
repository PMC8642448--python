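"""Profiled maximum-likelihood solver for the crossed mixed model used throughout.

The model is fixed in form: a numeric response regressed on a small set of
fixed covariates, with by-participant random intercept and slopes (one slope
per fixed covariate that is a utility term) and a by-item random intercept.
Participants and items are fully crossed, so the random-effects design does
not decompose into independent groups; the likelihood is evaluated with the
usual profiled representation

    y = X b + Z u + e,   u ~ N(0, s2 * Lam Lam'),   e ~ N(0, s2 I)

where ``Lam`` holds the relative (to the residual) random-effect scales.
Both b and s2 are profiled out analytically, leaving a low-dimensional
optimisation over the log relative scales.  All heavy quantities
(Z'Z, Z'X, Z'y, ...) are computed once; each likelihood evaluation costs one
dense Cholesky of a q x q matrix, q = n_subjects*(1+p) + n_items.

Satterthwaite denominator degrees of freedom for the fixed-effect t tests
are computed numerically from the observed information of the deviance in
the variance parameters, in the manner popularised by lmerTest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.optimize
import scipy.sparse as sp
from scipy import stats

__all__ = ["CrossedLMM", "LMMResult"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LMMResult:
    """Container for one fitted crossed mixed model."""

    fe_params: np.ndarray          # fixed-effect estimates, order of exog columns
    fe_se: np.ndarray              # standard errors
    fe_names: list
    df: np.ndarray                 # Satterthwaite df (inf when not computed)
    sigma2: float                  # residual variance
    vc: dict                       # variance components on the data scale
    loglike: float
    n_obs: int
    k_params: int                  # fixed + variance components incl. residual
    converged: bool
    reml: bool
    cov_structure: str
    theta: np.ndarray = field(repr=False, default=None)
    cov_fe: np.ndarray = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglike

    @property
    def bic(self) -> float:
        return self.k_params * np.log(self.n_obs) - 2.0 * self.loglike

    @property
    def tvalues(self) -> np.ndarray:
        return self.fe_params / self.fe_se

    @property
    def pvalues(self) -> np.ndarray:
        df = np.where(np.isfinite(self.df), self.df, 1e9)
        return 2.0 * stats.t.sf(np.abs(self.tvalues), df)


class CrossedLMM:
    """ML/REML estimation of a crossed random-effects linear model.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p_fe) fixed-effects design (first column typically the intercept).
    subject : (n,) integer codes 0..nS-1.
    item : (n,) integer codes 0..nI-1.
    slope_cols : indices into X's columns that get a by-subject random slope.
    cov_structure : 'diagonal' (independent subject effects, default) or
        'unstructured' (full covariance among subject intercept+slopes).
    """

    def __init__(self, y, X, subject, item, slope_cols=(), *,
                 cov_structure="diagonal", fe_names=None):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.n = self.y.shape[0]
        self.p_fe = self.X.shape[1]
        self.subject = np.asarray(subject)
        self.item = np.asarray(item)
        self.slope_cols = list(slope_cols)
        if cov_structure not in ("diagonal", "unstructured"):
            raise ValueError(f"unknown covariance structure {cov_structure!r}")
        self.cov_structure = cov_structure
        self.fe_names = list(fe_names) if fe_names is not None else [
            f"x{j}" for j in range(self.p_fe)]

        self.nS = int(self.subject.max()) + 1
        self.nI = int(self.item.max()) + 1
        if self.nI < 2:
            raise ValueError("item random intercept requires at least 2 items")
        # subject block: intercept + slopes, contiguous per subject
        self.p_sub = 1 + len(self.slope_cols)
        self.q = self.nS * self.p_sub + self.nI

        self._build_designs()
        self._precompute()

    # ------------------------------------------------------------------ setup
    def _build_designs(self):
        n, p_sub = self.n, self.p_sub
        rows = np.repeat(np.arange(n), p_sub)
        cols = (self.subject[:, None] * p_sub
                + np.arange(p_sub)[None, :]).ravel()
        vals = np.hstack([np.ones((n, 1)),
                          self.X[:, self.slope_cols]]).ravel()
        item_rows = np.arange(n)
        item_cols = self.nS * p_sub + self.item
        rows = np.concatenate([rows, item_rows])
        cols = np.concatenate([cols, item_cols])
        vals = np.concatenate([vals, np.ones(n)])
        self.Z = sp.csr_matrix((vals, (rows, cols)), shape=(n, self.q))

        # map each Z column to its variance-component index:
        # 0..p_sub-1 for subject intercept/slopes, p_sub for item
        self.col_comp = np.empty(self.q, dtype=int)
        for j in range(p_sub):
            self.col_comp[np.arange(self.nS) * p_sub + j] = j
        self.col_comp[self.nS * p_sub:] = p_sub
        self.n_comp = p_sub + 1

    def _precompute(self):
        Z, X, y = self.Z, self.X, self.y
        self.ZtZ = np.asarray((Z.T @ Z).todense())
        self.ZtX = np.asarray(Z.T @ X)
        self.Zty = np.asarray(Z.T @ y).ravel()
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    # --------------------------------------------------------------- likelihood
    def _lambda_scales(self, theta):
        """Per-column scaling for the diagonal structure."""
        return np.exp(0.5 * theta)[self.col_comp]

    def _theta_to_T(self, theta):
        """Unstructured: lower-triangular relative Cholesky for subject block.

        theta layout: p_sub log-diagonal entries, then off-diagonal entries
        row-wise, then log item scale (last).
        """
        p = self.p_sub
        T = np.zeros((p, p))
        T[np.diag_indices(p)] = np.exp(0.5 * theta[:p])
        off = theta[p:p + p * (p - 1) // 2]
        T[np.tril_indices(p, -1)] = off
        return T

    def _profiled_quantities(self, theta):
        """Return (logdet V*, XtViX, XtViy, ytViy) for V* = I + Z Lam^2 Z'."""
        if self.cov_structure == "diagonal":
            s = self._lambda_scales(theta)
            M = self.ZtZ * s[:, None] * s[None, :]
            A = self.ZtX * s[:, None]
            a = self.Zty * s
        else:
            T = self._theta_to_T(theta)
            item_s = np.exp(0.5 * theta[-1])
            # Lam = blockdiag(kron(I_nS, T), item_s * I_nI); apply by blocks
            p, nS = self.p_sub, self.nS
            nsub = nS * p
            ZtZ = self.ZtZ
            # right-multiply by Lam, left by Lam'
            def right_apply(Mx):
                out = np.empty_like(Mx)
                sub = Mx[:, :nsub].reshape(Mx.shape[0], nS, p)
                out[:, :nsub] = (sub @ T).reshape(Mx.shape[0], nsub)
                out[:, nsub:] = Mx[:, nsub:] * item_s
                return out
            M = right_apply(right_apply(ZtZ).T)
            LamT = np.empty((self.q, self.ZtX.shape[1]))
            sub = self.ZtX[:nsub].reshape(nS, p, -1)
            LamT[:nsub] = np.einsum("ij,sjk->sik", T.T, sub).reshape(nsub, -1)
            LamT[nsub:] = self.ZtX[nsub:] * item_s
            A = LamT
            a = np.empty(self.q)
            a[:nsub] = (T.T @ self.Zty[:nsub].reshape(nS, p).T).T.ravel()
            a[nsub:] = self.Zty[nsub:] * item_s

        M[np.diag_indices_from(M)] += 1.0
        try:
            L = sla.cholesky(M, lower=True, check_finite=False)
        except sla.LinAlgError:
            return None
        logdet = 2.0 * np.log(np.diag(L)).sum()
        RA = sla.solve_triangular(L, A, lower=True, check_finite=False)
        ra = sla.solve_triangular(L, a, lower=True, check_finite=False)
        XtViX = self.XtX - RA.T @ RA
        XtViy = self.Xty - RA.T @ ra
        ytViy = self.yty - ra @ ra
        return logdet, XtViX, XtViy, ytViy

    def _neg2ll_profiled(self, theta, reml):
        q = self._profiled_quantities(theta)
        if q is None:
            return 1e12
        logdet, XtViX, XtViy, ytViy = q
        try:
            c = sla.cho_factor(XtViX, check_finite=False)
        except sla.LinAlgError:
            return 1e12
        beta = sla.cho_solve(c, XtViy, check_finite=False)
        rss = ytViy - beta @ XtViy
        if rss <= 0:
            return 1e12
        if reml:
            nf = self.n - self.p_fe
            s2 = rss / nf
            logdet_xvx = 2.0 * np.log(np.diag(c[0])).sum()
            return (nf * (_LOG2PI + np.log(s2)) + logdet + logdet_xvx + nf)
        n = self.n
        s2 = rss / n
        return n * (_LOG2PI + np.log(s2)) + logdet + n

    # -------------------------------------------------------------------- fit
    def _n_theta(self):
        if self.cov_structure == "diagonal":
            return self.n_comp
        return self.p_sub + self.p_sub * (self.p_sub - 1) // 2 + 1

    def _start_theta(self):
        t = np.full(self._n_theta(), np.log(0.3))
        if self.cov_structure == "unstructured":
            t[self.p_sub:-1] = 0.0  # off-diagonals start at zero
        return t

    def fit(self, *, reml=False, compute_df=False, start=None,
            maxiter=400) -> LMMResult:
        theta0 = self._start_theta() if start is None else np.asarray(start, float)
        obj = lambda t: self._neg2ll_profiled(t, reml)
        res = scipy.optimize.minimize(
            obj, theta0, method="L-BFGS-B",
            bounds=[(-14.0, 8.0) if i < self._n_theta() else None
                    for i in range(self._n_theta())]
            if self.cov_structure == "diagonal" else None,
            options={"maxiter": maxiter, "maxfun": 4 * maxiter})
        # polish with Nelder-Mead if L-BFGS-B stopped abnormally
        converged = bool(res.success)
        if not converged:
            res2 = scipy.optimize.minimize(
                obj, res.x, method="Nelder-Mead",
                options={"maxiter": 200 * self._n_theta(), "xatol": 1e-6,
                         "fatol": 1e-8})
            if res2.fun <= res.fun:
                res = res2
            converged = bool(res2.success)
        theta = res.x

        quant = self._profiled_quantities(theta)
        if quant is None:
            raise RuntimeError("variance profile singular at the optimum")
        logdet, XtViX, XtViy, ytViy = quant
        c = sla.cho_factor(XtViX, check_finite=False)
        beta = sla.cho_solve(c, XtViy, check_finite=False)
        rss = ytViy - beta @ XtViy
        denom = (self.n - self.p_fe) if reml else self.n
        s2 = rss / denom
        cov_fe = s2 * sla.cho_solve(c, np.eye(self.p_fe), check_finite=False)
        se = np.sqrt(np.diag(cov_fe))
        loglike = -0.5 * self._neg2ll_profiled(theta, reml)

        vc = self._variance_components(theta, s2)
        k = self.p_fe + self._n_theta() + 1  # + residual variance
        dfs = np.full(self.p_fe, np.inf)
        if compute_df:
            dfs = self._satterthwaite_df(theta, s2, reml)

        return LMMResult(
            fe_params=beta, fe_se=se, fe_names=self.fe_names, df=dfs,
            sigma2=s2, vc=vc, loglike=loglike, n_obs=self.n, k_params=k,
            converged=converged, reml=reml, cov_structure=self.cov_structure,
            theta=theta, cov_fe=cov_fe)

    def _variance_components(self, theta, s2):
        names = ["subject_intercept"] + [
            f"subject_slope_{self.fe_names[j]}" for j in self.slope_cols]
        if self.cov_structure == "diagonal":
            lam2 = np.exp(theta)
            vc = {nm: s2 * lam2[i] for i, nm in enumerate(names)}
            vc["item_intercept"] = s2 * lam2[self.p_sub]
        else:
            T = self._theta_to_T(theta)
            G = s2 * (T @ T.T)
            vc = {nm: G[i, i] for i, nm in enumerate(names)}
            vc["subject_cov"] = G
            vc["item_intercept"] = s2 * np.exp(theta[-1])
        vc["residual"] = s2
        return vc

    # --------------------------------------------------- Satterthwaite df
    def _deviance_phi(self, logphi, reml):
        """Deviance as a function of log variance components (residual first),
        with the fixed effects profiled out (lmerTest parameterisation)."""
        s2 = np.exp(logphi[0])
        theta = logphi[1:] - logphi[0]
        if self.cov_structure == "unstructured":
            # off-diagonal entries are not variances; passed through untransformed
            p = self.p_sub
            theta = np.array(logphi[1:], float)
            theta[:p] -= logphi[0]
            theta[-1] -= logphi[0]
        quant = self._profiled_quantities(theta)
        if quant is None:
            return 1e12
        logdet, XtViX, XtViy, ytViy = quant
        try:
            c = sla.cho_factor(XtViX, check_finite=False)
        except sla.LinAlgError:
            return 1e12
        beta = sla.cho_solve(c, XtViy, check_finite=False)
        rss = ytViy - beta @ XtViy
        dev = self.n * (_LOG2PI + np.log(s2)) + logdet + rss / s2
        if reml:
            dev += 2.0 * np.log(np.diag(c[0])).sum() - self.p_fe * (
                _LOG2PI + np.log(s2))
        return dev

    def _cov_beta_jj(self, logphi, reml):
        s2 = np.exp(logphi[0])
        if self.cov_structure == "unstructured":
            p = self.p_sub
            theta = np.array(logphi[1:], float)
            theta[:p] -= logphi[0]
            theta[-1] -= logphi[0]
        else:
            theta = logphi[1:] - logphi[0]
        quant = self._profiled_quantities(theta)
        if quant is None:
            return np.full(self.p_fe, np.nan)
        _, XtViX, _, _ = quant
        try:
            cov = s2 * sla.cho_solve(
                sla.cho_factor(XtViX, check_finite=False),
                np.eye(self.p_fe), check_finite=False)
        except sla.LinAlgError:
            return np.full(self.p_fe, np.nan)
        return np.diag(cov)

    def _satterthwaite_df(self, theta, s2, reml):
        nphi = self._n_theta() + 1
        logphi = np.empty(nphi)
        logphi[0] = np.log(s2)
        if self.cov_structure == "unstructured":
            p = self.p_sub
            logphi[1:] = theta
            logphi[1:1 + p] += logphi[0]
            logphi[-1] += logphi[0]
        else:
            logphi[1:] = theta + logphi[0]
        h = 1e-4
        # observed information of the deviance (Hessian, central differences)
        H = np.zeros((nphi, nphi))
        f0 = self._deviance_phi(logphi, reml)
        for i in range(nphi):
            for j in range(i, nphi):
                ei = np.zeros(nphi); ei[i] = h
                ej = np.zeros(nphi); ej[j] = h
                fpp = self._deviance_phi(logphi + ei + ej, reml)
                fpm = self._deviance_phi(logphi + ei - ej, reml)
                fmp = self._deviance_phi(logphi - ei + ej, reml)
                fmm = self._deviance_phi(logphi - ei - ej, reml)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        try:
            cov_phi = 2.0 * np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            return np.full(self.p_fe, np.inf)
        # gradient of each Var(beta_j) w.r.t. log phi
        V0 = self._cov_beta_jj(logphi, reml)
        G = np.zeros((nphi, self.p_fe))
        for i in range(nphi):
            ei = np.zeros(nphi); ei[i] = h
            G[i] = (self._cov_beta_jj(logphi + ei, reml)
                    - self._cov_beta_jj(logphi - ei, reml)) / (2 * h)
        dfs = np.empty(self.p_fe)
        for j in range(self.p_fe):
            g = G[:, j]
            var_of_var = float(g @ cov_phi @ g)
            if var_of_var <= 0 or not np.isfinite(var_of_var):
                dfs[j] = np.inf
            else:
                dfs[j] = 2.0 * V0[j] ** 2 / var_of_var
        with np.errstate(invalid="ignore"):
            dfs = np.clip(dfs, 1.0, float(self.n - self.p_fe))
        return dfs
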