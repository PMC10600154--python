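"""Profiled (RE)ML engine for the two model structures used here:

* cohort random intercept + individual random intercept
* cohort random intercept + correlated individual (intercept, slope)

The implementation follows the penalized-least-squares formulation: with
``u = Lambda(theta) v``, ``v ~ N(0, sigma^2 I)``, the deviance profiles out
both ``beta`` and ``sigma^2``, leaving a 2- or 4-dimensional bounded
optimisation over the relative covariance factor ``theta``.  All
cross-products are precomputed once per design, so refits with a new
response (parametric bootstrap) cost only the small-matrix path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

__all__ = ["REMLProblem", "REMLResult", "ConvergenceError"]

_LOG2PI = math.log(2.0 * math.pi)


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries scipy diagnostics in ``result``."""

    def __init__(self, message: str, result) -> None:
        super().__init__(message)
        self.result = result


@dataclass
class REMLResult:
    theta: np.ndarray           # relative covariance parameters at optimum
    sigma2: float               # residual variance estimate
    beta: np.ndarray
    cov_beta: np.ndarray
    ranef: np.ndarray           # random effects u = Lambda v, length q
    loglik: float
    converged: bool
    n_obs: int
    n_fixed: int
    n_evals: int

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


class REMLProblem:
    """One design (X, Z-structure, grouping) with a swappable response.

    Parameters
    ----------
    X : (n, p) fixed-effects design, full column rank.
    cohort_codes : (n,) int codes in ``0..K-1``.
    calf_codes : (n,) int codes in ``0..J-1``.
    housing : (n,) float random-slope covariate, or None for the
        intercept-only structure.
    reml : use the REML criterion (default) rather than ML.
    """

    def __init__(
        self,
        X: np.ndarray,
        cohort_codes: np.ndarray,
        calf_codes: np.ndarray,
        housing: np.ndarray | None = None,
        reml: bool = True,
    ) -> None:
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        self.n, self.p = n, p
        self.reml = reml
        self.K = int(cohort_codes.max()) + 1
        self.J = int(calf_codes.max()) + 1
        self.slope = housing is not None
        # int64 upcast matters: pandas Categorical codes arrive as int8 and
        # would overflow in the 2*code column arithmetic below
        self.cohort_codes = np.asarray(cohort_codes, dtype=np.int64)
        self.calf_codes = np.asarray(calf_codes, dtype=np.int64)
        self.housing = None if housing is None else np.asarray(housing, dtype=float)

        q = self.K + self.J * (2 if self.slope else 1)
        Z = np.zeros((n, q))
        rows = np.arange(n)
        Z[rows, self.cohort_codes] = 1.0
        if self.slope:
            Z[rows, self.K + 2 * self.calf_codes] = 1.0
            Z[rows, self.K + 2 * self.calf_codes + 1] = self.housing
        else:
            Z[rows, self.K + self.calf_codes] = 1.0
        self.q = q
        self._Z = Z
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.XtX = X.T @ X
        self.X = X
        self.y: np.ndarray | None = None

    # -- response ---------------------------------------------------------
    def set_y(self, y: np.ndarray) -> None:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError("response length mismatch")
        self.y = y
        self.Zty = self._Z.T @ y
        self.Xty = self.X.T @ y
        self.yty = float(y @ y)

    # -- Lambda(theta) application ---------------------------------------
    def _lam_right(self, M: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Return ``M @ Lambda(theta)`` using the block structure."""
        out = np.empty_like(M)
        if self.slope:
            tc, l11, l21, l22 = theta
            out[:, : self.K] = M[:, : self.K] * tc
            Mi = M[:, self.K:].reshape(M.shape[0], self.J, 2)
            out[:, self.K::2] = Mi[:, :, 0] * l11 + Mi[:, :, 1] * l21
            out[:, self.K + 1::2] = Mi[:, :, 1] * l22
        else:
            tc, ti = theta
            out[:, : self.K] = M[:, : self.K] * tc
            out[:, self.K:] = M[:, self.K:] * ti
        return out

    def _lam_both(self, M: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Return ``Lambda' @ M @ Lambda``."""
        return self._lam_right(self._lam_right(M, theta).T, theta).T

    def _lam_vec(self, v: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Return ``Lambda' @ v`` (equals ``v @ Lambda``)."""
        return self._lam_right(v[None, :], theta)[0]

    def _lam_apply(self, v: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Return ``Lambda @ v``."""
        out = np.empty_like(v)
        if self.slope:
            tc, l11, l21, l22 = theta
            out[: self.K] = v[: self.K] * tc
            vi = v[self.K:].reshape(self.J, 2)
            out[self.K::2] = vi[:, 0] * l11
            out[self.K + 1::2] = vi[:, 0] * l21 + vi[:, 1] * l22
        else:
            tc, ti = theta
            out[: self.K] = v[: self.K] * tc
            out[self.K:] = v[self.K:] * ti
        return out

    # -- profiled deviance ------------------------------------------------
    def _solve_core(self, theta: np.ndarray):
        A = self._lam_both(self.ZtZ, theta)
        A[np.diag_indices_from(A)] += 1.0
        L = linalg.cholesky(A, lower=True, check_finite=False)
        CtZX = self._lam_right(self.ZtX.T, theta).T
        CtZy = self._lam_vec(self.Zty, theta)
        RZX = linalg.solve_triangular(L, CtZX, lower=True, check_finite=False)
        RZy = linalg.solve_triangular(L, CtZy, lower=True, check_finite=False)
        S = self.XtX - RZX.T @ RZX
        cX = self.Xty - RZX.T @ RZy
        R = linalg.cholesky(S, lower=True, check_finite=False)
        beta = linalg.cho_solve((R, True), cX, check_finite=False)
        r2 = self.yty - RZy @ RZy - cX @ beta
        r2 = max(float(r2), 1e-300)
        logdet_A = 2.0 * float(np.log(np.diag(L)).sum())
        logdet_S = 2.0 * float(np.log(np.diag(R)).sum())
        return L, RZy, CtZy, CtZX, S, R, beta, r2, logdet_A, logdet_S

    def deviance(self, theta: np.ndarray) -> float:
        try:
            *_, r2, logdet_A, logdet_S = self._solve_core(theta)
        except linalg.LinAlgError:
            return np.inf
        n, p = self.n, self.p
        if self.reml:
            nu = n - p
            return logdet_A + logdet_S + nu * (1.0 + _LOG2PI + math.log(r2 / nu))
        return logdet_A + n * (1.0 + _LOG2PI + math.log(r2 / n))

    # -- fit --------------------------------------------------------------
    def fit(
        self,
        y: np.ndarray | None = None,
        theta0: np.ndarray | None = None,
        xatol: float = 1e-5,
        fatol: float = 1e-7,
        maxiter: int = 2000,
    ) -> REMLResult:
        if y is not None:
            self.set_y(y)
        if self.y is None:
            raise ValueError("no response set")
        if theta0 is None:
            theta0 = (
                np.array([0.5, 0.5, 0.0, 0.5])
                if self.slope
                else np.array([0.5, 0.5])
            )
        bounds = (
            [(0.0, None), (0.0, None), (None, None), (0.0, None)]
            if self.slope
            else [(0.0, None), (0.0, None)]
        )
        res = optimize.minimize(
            self.deviance,
            np.asarray(theta0, dtype=float),
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
        )
        if not res.success and not np.isfinite(res.fun):
            raise ConvergenceError(
                f"REML optimisation failed: {res.message}", res
            )
        theta = np.asarray(res.x, dtype=float)
        (L, RZy, CtZy, CtZX, S, R, beta, r2, _, _) = self._solve_core(theta)
        nu = self.n - self.p if self.reml else self.n
        sigma2 = r2 / nu
        cov_beta = sigma2 * linalg.cho_solve((R, True), np.eye(self.p),
                                             check_finite=False)
        # BLUPs: v = A^{-1} (Lambda'Z'y - Lambda'Z'X beta); u = Lambda v
        rhs = CtZy - CtZX @ beta
        v = linalg.cho_solve((L, True), rhs, check_finite=False)
        ranef = self._lam_apply(v, theta)
        return REMLResult(
            theta=theta,
            sigma2=float(sigma2),
            beta=beta,
            cov_beta=cov_beta,
            ranef=ranef,
            loglik=-0.5 * float(res.fun),
            converged=bool(res.success),
            n_obs=self.n,
            n_fixed=self.p,
            n_evals=int(res.nfev),
        )

    # -- interpretation ---------------------------------------------------
    def variance_components(self, result: REMLResult) -> dict[str, float]:
        s2 = result.sigma2
        if self.slope:
            tc, l11, l21, l22 = result.theta
            return {
                "V_coh": s2 * tc * tc,
                "V_ind0": s2 * l11 * l11,
                "cov_ind01": s2 * l11 * l21,
                "V_ind1": s2 * (l21 * l21 + l22 * l22),
                "V_e0": s2,
            }
        tc, ti = result.theta
        return {
            "V_coh": s2 * tc * tc,
            "V_ind0": s2 * ti * ti,
            "V_e0": s2,
        }

    def split_ranef(self, result: REMLResult):
        """Split the stacked random-effect vector into cohort and calf parts."""
        u = result.ranef
        coh = u[: self.K]
        if self.slope:
            calf = u[self.K:].reshape(self.J, 2)
            return coh, calf[:, 0], calf[:, 1]
        return coh, u[self.K:], None

    def simulate_response(
        self,
        beta: np.ndarray,
        var_coh: float,
        var_ind0: float,
        var_e: float,
        rng: np.random.Generator,
        var_ind1: float = 0.0,
        cov_ind01: float = 0.0,
    ) -> np.ndarray:
        """Draw a response from the model at the given parameters (for
        parametric bootstrap)."""
        mean = self.X @ beta
        coh = rng.normal(0.0, math.sqrt(max(var_coh, 0.0)), self.K)
        if self.slope:
            cov = np.array([[var_ind0, cov_ind01], [cov_ind01, var_ind1]])
            evals, evecs = np.linalg.eigh(cov)
            root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
            b = rng.standard_normal((self.J, 2)) @ root.T
            contrib = (
                b[self.calf_codes, 0] + b[self.calf_codes, 1] * self.housing
            )
        else:
            b0 = rng.normal(0.0, math.sqrt(max(var_ind0, 0.0)), self.J)
            contrib = b0[self.calf_codes]
        e = rng.normal(0.0, math.sqrt(max(var_e, 0.0)), self.n)
        return mean + coh[self.cohort_codes] + contrib + e
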