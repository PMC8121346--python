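"""Mixed-effects logistic regression with diagonal random-effects covariance.

Maximum-likelihood estimation under the Laplace approximation, in the style
of lme4's default GLMM scheme: for candidate random-effect scale parameters
the fixed effects and the per-group random-effect modes are found jointly by
penalized iteratively reweighted least squares (PIRLS), and the resulting
Laplace deviance is minimised over the scales with a derivative-free
(Nelder-Mead) search.  Random slopes are mutually uncorrelated by
construction (one scale parameter per random term), matching the
double-bar ``(1 + x1 + x2 || group)`` specification.

The model is parameterised with spherical random effects: for group i with
random design ``M_i`` (columns a subset of the fixed design),

    logit P(y = 1) = X beta + M_i diag(sigma) u_i,   u_i ~ N(0, I_q),

so ``sigma`` >= 0 are the random-effect standard deviations and sigma = 0 is
an interior-boundary point handled without special-casing.

Confidence intervals: Wald (from the Schur-complement curvature of the
penalized system) or likelihood-profile (bisection on the profiled deviance
at the chi-square(1) cutoff, holding ``sigma`` at its MLE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

logger = logging.getLogger("stepdyn")

_CHI2_95 = float(stats.chi2.ppf(0.95, df=1))
#: random-effect scales below this (on the standardized predictor scale) are
#: treated as singular
SINGULAR_SD = 1e-4


@dataclass
class MixedLogitFit:
    """Result of a Laplace-ML mixed logistic fit."""

    fe_names: list[str]
    beta: np.ndarray
    se: np.ndarray  # Wald standard errors (sigma held fixed)
    re_names: list[str]
    re_sd: np.ndarray  # random-effect standard deviations
    deviance: float
    n_obs: int
    n_groups: int
    converged: bool
    n_outer_evals: int
    dropped_re: list[str] = field(default_factory=list)
    _model: "MixedLogitModel | None" = None

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.beta - z * self.se, self.beta + z * self.se])

    def profile_ci(self, level: float = 0.95) -> tuple[np.ndarray, list[str]]:
        """Likelihood-profile CIs per fixed effect.

        Returns (bounds array, per-coefficient method used); any side that
        cannot be bracketed falls back to the Wald bound for that
        coefficient and is flagged ``"wald"``.
        """
        if self._model is None:
            raise RuntimeError("fit is detached from its model; profile unavailable")
        cutoff = float(stats.chi2.ppf(level, df=1))
        wald = self.wald_ci(level)
        out = np.empty((len(self.beta), 2))
        methods = []
        for j in range(len(self.beta)):
            lo, hi, ok = self._model._profile_bounds(self, j, cutoff, wald[j])
            out[j] = (lo, hi)
            methods.append("profile" if ok else "wald")
        return out, methods


class MixedLogitModel:
    """Bernoulli GLMM with logit link and diagonal random-effects covariance.

    Parameters
    ----------
    X : (n, p) array
        Fixed-effects design (include the intercept column explicitly).
    y : (n,) array of {0, 1}
    groups : (n,) array
        Group labels (any hashable); rows need not be sorted.
    re_cols : sequence of int, optional
        Columns of ``X`` that also get a random effect (default: all).
    fe_names : sequence of str, optional
    """

    def __init__(self, X, y, groups, re_cols=None, fe_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n, p) aligned with y")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("outcome contains a single class; model not identifiable")
        codes, uniques = _factorize(np.asarray(groups))
        order = np.argsort(codes, kind="stable")
        self.X = X[order]
        self.y = y[order]
        self.g = codes[order]
        self.group_labels = uniques
        self.n_groups = len(uniques)
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups for a mixed model")
        # reduceat boundaries of the sorted groups
        self.starts = np.searchsorted(self.g, np.arange(self.n_groups))
        self.re_cols = list(range(X.shape[1])) if re_cols is None else list(re_cols)
        self.M = self.X[:, self.re_cols]
        p = X.shape[1]
        self.fe_names = list(fe_names) if fe_names is not None else [f"x{j}" for j in range(p)]

    # -- inner loop ---------------------------------------------------------

    def _pirls(self, sigma, beta, u, offset=None, free=None, max_iter=80, tol=1e-10):
        """Jointly maximize the penalized log-likelihood over (beta, u).

        ``free`` selects which fixed-effect columns are optimised (profile
        fits freeze one); ``offset`` is added to the linear predictor.
        Returns (beta, u, penalized loglik, Schur complement S of the free
        block, per-group A matrices).
        """
        X, y, g, M = self.X, self.y, self.g, self.M
        q = len(self.re_cols)
        if free is None:
            free = np.arange(X.shape[1])
        Xf = X[:, free]
        if offset is None:
            offset = 0.0
        Zs = M * sigma  # row-wise scaled random design

        def pll(beta, u):
            eta = Xf @ beta + np.einsum("nq,nq->n", Zs, u[g]) + offset
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            return ll - 0.5 * float(np.sum(u * u)), eta

        cur, eta = pll(beta, u)
        S = None
        A = None
        for _ in range(max_iter):
            mu = special.expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            r = y - mu
            # per-group blocks via reduceat on row-wise outer products
            A = np.add.reduceat(w[:, None, None] * Zs[:, :, None] * Zs[:, None, :],
                                self.starts, axis=0)
            A[:, np.arange(q), np.arange(q)] += 1.0
            XWZ = np.add.reduceat(w[:, None, None] * Xf[:, :, None] * Zs[:, None, :],
                                  self.starts, axis=0)  # (G, pf, q)
            XWX = (Xf * w[:, None]).T @ Xf
            gb = Xf.T @ r
            gu = np.add.reduceat(Zs * r[:, None], self.starts, axis=0) - u

            B = np.linalg.solve(A, np.transpose(XWZ, (0, 2, 1)))  # (G, q, pf)
            S = XWX - np.einsum("gpq,gqr->pr", XWZ, B)
            rhs = gb - np.einsum("gpq,gq->p", XWZ, np.linalg.solve(A, gu[..., None])[..., 0])
            dbeta = np.linalg.solve(S, rhs)
            du = np.linalg.solve(A, gu[..., None])[..., 0] - np.einsum("gqp,p->gq", B, dbeta)

            step = 1.0
            for _ in range(30):  # halve until improvement
                nb, nu = beta + step * dbeta, u + step * du
                new, neta = pll(nb, nu)
                if new >= cur - 1e-13:
                    break
                step *= 0.5
            beta, u, eta = nb, nu, neta
            if abs(new - cur) < tol * (1.0 + abs(cur)):
                cur = new
                break
            cur = new
        return beta, u, cur, S, A

    def _deviance(self, sigma, state):
        beta, u, pll_val, S, A = self._pirls(sigma, state["beta"], state["u"])
        state["beta"], state["u"], state["S"] = beta, u, S
        _, logdet = np.linalg.slogdet(A)
        return -2.0 * pll_val + float(logdet.sum())

    # -- outer loop ---------------------------------------------------------

    def fit(self, start_sd: float = 0.3, maxfev: int = 400) -> MixedLogitFit:
        p = self.X.shape[1]
        q = len(self.re_cols)
        state = {"beta": np.zeros(p), "u": np.zeros((self.n_groups, q)), "S": None}
        # warm up the fixed effects at sigma = start
        x0 = np.full(q, start_sd)

        res = optimize.minimize(
            lambda s, st=state: self._deviance(np.abs(s), st),
            x0,
            method="Nelder-Mead",
            options={"fatol": 1e-4, "xatol": 1e-4, "maxfev": maxfev},
        )
        sigma = np.abs(res.x)

        dropped: list[str] = []
        singular = sigma < SINGULAR_SD
        if singular.any():
            names = [self.fe_names[self.re_cols[k]] for k in np.flatnonzero(singular)]
            logger.info("singular random-effect scale(s) for %s; pinned to zero", names)
            dropped = names
            sigma = np.where(singular, 0.0, sigma)
            if (~singular).any():
                idx = np.flatnonzero(~singular)

                def dev_sub(s_sub, st=state):
                    s = np.zeros(q)
                    s[idx] = np.abs(s_sub)
                    return self._deviance(s, st)

                res2 = optimize.minimize(
                    dev_sub, sigma[idx], method="Nelder-Mead",
                    options={"fatol": 1e-4, "xatol": 1e-4, "maxfev": maxfev},
                )
                sigma[idx] = np.abs(res2.x)

        dev = self._deviance(sigma, state)
        cov = np.linalg.inv(state["S"])
        fit = MixedLogitFit(
            fe_names=list(self.fe_names),
            beta=state["beta"].copy(),
            se=np.sqrt(np.diag(cov)),
            re_names=[self.fe_names[c] for c in self.re_cols],
            re_sd=sigma,
            deviance=float(dev),
            n_obs=int(self.y.size),
            n_groups=self.n_groups,
            converged=bool(res.success),
            n_outer_evals=int(res.nfev),
            dropped_re=dropped,
            _model=self,
        )
        self._fit_state = {"sigma": sigma, "beta": state["beta"].copy(),
                           "u": state["u"].copy(), "deviance": float(dev)}
        return fit

    # -- profile likelihood -------------------------------------------------

    def _profile_deviance(self, j: int, value: float, state) -> float:
        """Deviance with beta_j fixed, other betas and u re-optimised."""
        sigma = self._fit_state["sigma"]
        free = np.array([k for k in range(self.X.shape[1]) if k != j])
        offset = self.X[:, j] * value
        beta, u, pll_val, _, A = self._pirls(
            sigma, state["beta"], state["u"], offset=offset, free=free
        )
        state["beta"], state["u"] = beta, u
        _, logdet = np.linalg.slogdet(A)
        return -2.0 * pll_val + float(logdet.sum())

    def _profile_bounds(self, fit: MixedLogitFit, j: int, cutoff: float,
                        wald_bounds) -> tuple[float, float, bool]:
        dev0 = self._fit_state["deviance"]
        bhat = fit.beta[j]
        se = max(fit.se[j], 1e-8)
        free = np.array([k for k in range(self.X.shape[1]) if k != j])
        base_state = {
            "beta": self._fit_state["beta"][free].copy(),
            "u": self._fit_state["u"].copy(),
        }

        def g(v, st):
            return self._profile_deviance(j, v, st) - dev0 - cutoff

        bounds = []
        ok = True
        for side, wald_b in zip((-1.0, 1.0), wald_bounds):
            st = {"beta": base_state["beta"].copy(), "u": base_state["u"].copy()}
            inner = bhat  # g(inner) < 0 by construction (deviance minimum)
            outer = None
            for k in (1.0, 2.0, 4.0, 8.0, 16.0, 32.0):
                v = bhat + side * k * se
                if g(v, st) > 0:
                    outer = v
                    break
                inner = v
            if outer is None:
                logger.warning("could not bracket profile bound for %s; Wald fallback",
                               fit.fe_names[j])
                bounds.append(float(wald_b))
                ok = False
                continue
            a, b = (inner, outer) if side > 0 else (outer, inner)
            try:
                root = optimize.brentq(
                    lambda v: g(v, st), a, b, xtol=max(1e-4 * se, 1e-10), maxiter=60
                )
                bounds.append(float(root))
            except ValueError:
                bounds.append(float(wald_b))
                ok = False
        return bounds[0], bounds[1], ok


def _factorize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniques, codes = np.unique(values, return_inverse=True)
    return codes.astype(np.int64), uniques
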