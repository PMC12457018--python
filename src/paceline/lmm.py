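"""Linear mixed models with crossed random intercepts, fitted by REML.

The model is

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2 * tau_k I),   e ~ N(0, s2 I)

with one or two crossed random-intercept factors (the analyses here use
individual identity and prior-test count).  The restricted likelihood is
profiled analytically over the fixed effects and the residual variance,
leaving a direct numerical optimisation over the variance ratios ``tau``
only — one- or two-dimensional, so the thousands of refits in permutation
and bootstrap loops stay cheap.  All linear algebra runs through the
random-effect cross-products: for a single factor the core matrix is
diagonal, and for two crossed factors where one is small (prior-test count
has at most four levels) it reduces to a diagonal block plus a small Schur
complement, so one likelihood evaluation costs microseconds.

The surface follows statsmodels conventions: a model object built from data
whose :meth:`LinearMixedModel.fit` returns a results object with estimates,
standard errors, variance components and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = ["LinearMixedModel", "LMMResults", "SingularDesignError", "ConvergenceError"]

_LOG2PI = np.log(2.0 * np.pi)
_SMALL_FACTOR_MAX = 32


class SingularDesignError(ValueError):
    """Fixed-effect design is rank deficient."""


class ConvergenceError(RuntimeError):
    """Variance-ratio optimisation failed to converge."""


def _encode_groups(values) -> tuple[np.ndarray, np.ndarray]:
    codes, uniques = pd.factorize(np.asarray(values))
    return codes.astype(np.intp), uniques


class LinearMixedModel:
    """Gaussian linear mixed model with up to two crossed random intercepts.

    Parameters
    ----------
    endog : array
        Response vector.
    exog : array (n, p)
        Fixed-effect design including the intercept column.
    groups : dict[str, array]
        Mapping from random-factor name to per-row labels; each factor
        contributes an independent random intercept per level.
    exog_names : sequence of str, optional
    """

    def __init__(self, endog, exog, groups: dict, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        n, p = self.exog.shape
        if n != len(self.endog):
            raise ValueError("endog and exog lengths differ")
        self.exog_names = list(exog_names) if exog_names is not None else [f"x{j}" for j in range(p)]
        rank = np.linalg.matrix_rank(self.exog)
        if rank < p:
            _, r = np.linalg.qr(self.exog)
            bad = [self.exog_names[j] for j in range(p) if abs(r[min(j, rank - 1), j]) < 1e-8]
            raise SingularDesignError(f"collinear fixed-effect columns: {bad or self.exog_names}")
        if len(groups) not in (1, 2):
            raise ValueError("supports one or two crossed random intercepts")
        names = list(groups)
        encoded = {nm: _encode_groups(groups[nm]) for nm in names}
        for nm in names:
            if len(encoded[nm][1]) < 2:
                raise ValueError(f"random factor {nm!r} needs >= 2 levels")
        names.sort(key=lambda nm: -len(encoded[nm][1]))  # large factor first
        self.group_names = names
        self._codes = [encoded[nm][0] for nm in names]
        self._levels = [encoded[nm][1] for nm in names]
        self._sizes = [len(u) for u in self._levels]
        self._build_crossproducts()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        fixed: list[str],
        groups: list[str],
        categorical: tuple[str, ...] = (),
    ) -> "LinearMixedModel":
        """Build from a tidy session table.

        ``fixed`` columns named in ``categorical`` are dummy-coded (first
        level dropped); an intercept is always prepended.  Rows with
        missing values in any used column are rejected.
        """
        used = [response, *fixed, *groups]
        if data[used].isna().any().any():
            raise ValueError("missing values in model columns; filter first")
        cols = [np.ones(len(data))]
        names = ["Intercept"]
        for term in fixed:
            if term in categorical:
                dummies = pd.get_dummies(data[term], prefix=term, drop_first=True, dtype=float)
                cols.extend(dummies[c].to_numpy() for c in dummies)
                names.extend(dummies.columns)
            else:
                cols.append(data[term].to_numpy(dtype=float))
                names.append(term)
        X = np.column_stack(cols)
        return cls(
            data[response].to_numpy(dtype=float),
            X,
            {g: data[g].to_numpy() for g in groups},
            exog_names=names,
        )

    # -- internals ---------------------------------------------------------

    def _build_crossproducts(self) -> None:
        X, y = self.exog, self.endog
        c1 = self._codes[0]
        q1 = self._sizes[0]
        self._n1 = np.bincount(c1, minlength=q1).astype(float)
        self._Z1tX = np.zeros((q1, X.shape[1]))
        np.add.at(self._Z1tX, c1, X)
        self._Z1ty = np.bincount(c1, y, minlength=q1)
        if len(self.group_names) == 2:
            c2, q2 = self._codes[1], self._sizes[1]
            if q2 > _SMALL_FACTOR_MAX:
                raise ValueError(
                    f"second crossed factor must have <= {_SMALL_FACTOR_MAX} levels, "
                    f"got {q2}"
                )
            self._n2 = np.bincount(c2, minlength=q2).astype(float)
            self._N12 = np.bincount(c1 * q2 + c2, minlength=q1 * q2).reshape(q1, q2).astype(float)
            self._Z2tX = np.zeros((q2, X.shape[1]))
            np.add.at(self._Z2tX, c2, X)
            self._Z2ty = np.bincount(c2, y, minlength=q2)
        self._XtX = X.T @ X
        self._Xty = X.T @ y
        self._yty = float(y @ y)

    def _quad(self, tau: np.ndarray):
        """Quadratic forms a'V0^-1 b and log|V0| through the Woodbury core.

        Returns (XtViX, XtViy, ytViy, logdet_v, solver) where ``solver``
        maps stacked right-hand sides through M^-1 for BLUP computation.
        """
        U1x, u1y = np.sqrt(tau[0]) * self._Z1tX, np.sqrt(tau[0]) * self._Z1ty
        d1 = 1.0 + tau[0] * self._n1
        if len(self.group_names) == 1:
            XtViX = self._XtX - U1x.T @ (U1x / d1[:, None])
            XtViy = self._Xty - U1x.T @ (u1y / d1)
            ytViy = self._yty - u1y @ (u1y / d1)
            logdet = float(np.sum(np.log(d1)))

            def solver(a1, a2):
                return a1 / (d1[:, None] if a1.ndim == 2 else d1), None

            return XtViX, XtViy, ytViy, logdet, solver
        s1, s2 = np.sqrt(tau[0]), np.sqrt(tau[1])
        U2x, u2y = s2 * self._Z2tX, s2 * self._Z2ty
        M12 = (s1 * s2) * self._N12
        C = np.diag(1.0 + tau[1] * self._n2) - M12.T @ (M12 / d1[:, None])
        cf = linalg.cho_factor(C, lower=True)

        def solver(a1, a2):
            t2 = linalg.cho_solve(cf, a2 - M12.T @ (a1 / (d1[:, None] if a1.ndim == 2 else d1)))
            t1 = (a1 - M12 @ t2) / (d1[:, None] if a1.ndim == 2 else d1)
            return t1, t2

        t1x, t2x = solver(U1x, U2x)
        t1y, t2y = solver(u1y, u2y)
        XtViX = self._XtX - U1x.T @ t1x - U2x.T @ t2x
        XtViy = self._Xty - U1x.T @ t1y - U2x.T @ t2y
        ytViy = self._yty - u1y @ t1y - u2y @ t2y
        logdet = float(np.sum(np.log(d1)) + 2.0 * np.sum(np.log(np.diag(cf[0]))))
        return XtViX, XtViy, ytViy, logdet, solver

    def _profile(self, tau: np.ndarray):
        """Profiled REML criterion and GLS estimates at variance ratios tau."""
        n, p = self.exog.shape
        XtViX, XtViy, ytViy, logdet_v, _ = self._quad(tau)
        cf = linalg.cho_factor(XtViX)
        beta = linalg.cho_solve(cf, XtViy)
        rss = max(ytViy - XtViy @ beta, 1e-12)
        sigma2 = rss / (n - p)
        logdet_x = 2.0 * np.log(np.diag(cf[0])).sum()
        crit = (n - p) * np.log(sigma2) + logdet_v + logdet_x
        return crit, beta, sigma2, XtViX

    def _crit(self, log_tau: np.ndarray) -> float:
        try:
            return self._profile(np.exp(np.clip(log_tau, -30.0, 30.0)))[0]
        except linalg.LinAlgError:
            return np.inf

    def fit(self, start_log_tau=None) -> "LMMResults":
        k = len(self.group_names)
        if k == 1:
            res = optimize.minimize_scalar(
                lambda z: self._crit(np.array([z])), bounds=(-16.0, 16.0), method="bounded",
                options={"xatol": 1e-6},
            )
            log_tau = np.array([res.x])
            converged = res.success
        else:
            x0 = np.zeros(k) if start_log_tau is None else np.asarray(start_log_tau, dtype=float)
            best = optimize.minimize(
                self._crit, x0, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
            )
            # retry from a near-zero-variance start if the surface looks flat
            if not np.isfinite(best.fun):
                best = optimize.minimize(
                    self._crit, np.full(k, -6.0), method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
                )
            log_tau = best.x
            converged = np.isfinite(best.fun)
        if not np.isfinite(self._crit(log_tau)):
            raise ConvergenceError(f"REML optimisation failed at log tau {log_tau}")
        tau = np.exp(np.clip(log_tau, -30.0, 30.0))
        tau[tau < 1e-10] = 0.0
        crit, beta, sigma2, XtViX = self._profile(tau)
        n, p = self.exog.shape
        cov = sigma2 * linalg.inv(XtViX)
        loglik = -0.5 * (crit + (n - p) * (1.0 + _LOG2PI))
        vc = {name: float(sigma2 * tau[j]) for j, name in enumerate(self.group_names)}
        return LMMResults(
            model=self,
            params=beta,
            cov_params=cov,
            sigma2_resid=float(sigma2),
            vc=vc,
            tau=tau,
            loglik=float(loglik),
            converged=bool(converged),
        )


@dataclass
class LMMResults:
    """REML estimates, uncertainties and variance components."""

    model: LinearMixedModel
    params: np.ndarray
    cov_params: np.ndarray
    sigma2_resid: float
    vc: dict
    tau: np.ndarray
    loglik: float
    converged: bool

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values (normal reference)."""
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fixed-effect fitted values X @ beta."""
        return self.model.exog @ self.params

    def random_effects(self) -> list[np.ndarray]:
        """BLUPs of the random intercepts, one array per factor."""
        m = self.model
        r = m.endog - self.fittedvalues
        tau = self.tau
        z1tr = np.bincount(m._codes[0], r, minlength=m._sizes[0])
        a1 = np.sqrt(tau[0]) * z1tr
        if len(m.group_names) == 1:
            _, _, _, _, solver = m._quad(tau)
            t1, _ = solver(a1, None)
            return [tau[0] * (z1tr - self._v0inv_z1(t1, None))]
        z2tr = np.bincount(m._codes[1], r, minlength=m._sizes[1])
        a2 = np.sqrt(tau[1]) * z2tr
        _, _, _, _, solver = m._quad(tau)
        t1, t2 = solver(a1, a2)
        u1 = tau[0] * (z1tr - self._v0inv_z1(t1, t2))
        u2 = tau[1] * (z2tr - self._v0inv_z2(t1, t2))
        return [u1, u2]

    def _v0inv_z1(self, t1, t2):
        """Z1' Z S [t1; t2] — the correction term of the Woodbury identity."""
        m = self.model
        tau = self.tau
        out = np.sqrt(tau[0]) * m._n1 * t1
        if t2 is not None:
            out = out + np.sqrt(tau[1]) * (m._N12 @ t2)
        return out

    def _v0inv_z2(self, t1, t2):
        m = self.model
        tau = self.tau
        return np.sqrt(tau[0]) * (m._N12.T @ t1) + np.sqrt(tau[1]) * m._n2 * t2

    def conditional_residuals(self) -> np.ndarray:
        """Residuals after removing fixed effects and BLUP random effects."""
        m = self.model
        u = self.random_effects()
        r = m.endog - self.fittedvalues - u[0][m._codes[0]]
        if len(u) > 1:
            r = r - u[1][m._codes[1]]
        return r

    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted model (parametric bootstrap)."""
        m = self.model
        y = self.fittedvalues + rng.normal(0.0, np.sqrt(self.sigma2_resid), len(m.endog))
        for k, name in enumerate(m.group_names):
            u = rng.normal(0.0, np.sqrt(self.vc[name]), m._sizes[k])
            y += u[m._codes[k]]
        return y

    def summary(self) -> str:
        lines = ["Linear mixed model (REML)", "=" * 60]
        lines.append(f"{'term':<24}{'coef':>10}{'se':>10}{'z':>8}{'p':>8}")
        for name, b, se, z, p in zip(self.exog_names, self.params, self.bse,
                                     self.zvalues, self.pvalues):
            lines.append(f"{name:<24}{b:>10.4f}{se:>10.4f}{z:>8.2f}{p:>8.4f}")
        lines.append("-" * 60)
        for name, v in self.vc.items():
            lines.append(f"var({name:<18}) {v:>10.4f}")
        lines.append(f"var(residual         ) {self.sigma2_resid:>10.4f}")
        lines.append(f"REML log-likelihood    {self.loglik:>10.3f}")
        return "\n".join(lines)
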