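"""Maximum-likelihood beta regression with a covariate-driven precision
submodel, optional family random intercept, AIC model selection, diagnostics
and bootstrap confidence intervals.

The model for a proportion response :math:`y_i \\in (0,1)` is

.. math::

    y_i \\sim \\mathrm{Beta}(\\mu_i \\phi_i, (1-\\mu_i)\\phi_i), \\qquad
    \\mathrm{logit}(\\mu_i) = x_i^\\top \\beta, \\qquad
    \\log(\\phi_i) = z_i^\\top \\gamma .

The precision submodel lets the dispersion of the response depend on
covariates — here, the number of sequences behind each species' diversity
estimate, so that species measured from more sequences are treated as more
precisely observed.  The mixed variant adds a Gaussian random intercept per
taxonomic family to the mean submodel, integrated out by a Laplace
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .predictors import DesignMatrix

__all__ = [
    "BetaRegression",
    "BetaRegressionResults",
    "MixedBetaRegression",
    "MixedBetaRegressionResults",
    "BootstrapResult",
    "model_selection",
    "vif",
    "beta_loglik",
]

_ETA_CLIP = 30.0  # |linear predictor| beyond this is numerically saturated
_ZETA_CLIP = 30.0


def _mu_phi(X, Z, beta, gamma):
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    zeta = np.clip(Z @ gamma, -_ZETA_CLIP, _ZETA_CLIP)
    return special.expit(eta), np.exp(zeta)


def beta_loglik(y, X, Z, beta, gamma) -> float:
    """Log-likelihood (nats) of the variable-precision beta model."""
    y = np.asarray(y, float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError(
            "response must be strictly inside (0,1); run adjust_zeros on boundary values"
        )
    mu, phi = _mu_phi(X, Z, np.asarray(beta, float), np.asarray(gamma, float))
    a, b = mu * phi, (1 - mu) * phi
    return float(
        np.sum(
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1) * np.log(y)
            + (b - 1) * np.log1p(-y)
        )
    )


class BetaRegression:
    """Beta regression model with logit mean link and log precision link.

    Parameters
    ----------
    y : array
        Response, strictly inside (0, 1).
    X : array
        Mean-submodel design (n, p); include the intercept column.
    Z : array, optional
        Precision-submodel design (n, q); defaults to intercept only.
    """

    def __init__(self, y, X, Z=None, x_names=None, z_names=None):
        self.y = np.asarray(y, float)
        self.X = np.atleast_2d(np.asarray(X, float))
        if Z is None:
            Z = np.ones((len(self.y), 1))
        self.Z = np.atleast_2d(np.asarray(Z, float))
        if np.any((self.y <= 0) | (self.y >= 1)):
            raise ValueError(
                "response must be strictly inside (0,1); run adjust_zeros first"
            )
        if len(self.y) != self.X.shape[0] or len(self.y) != self.Z.shape[0]:
            raise ValueError("y, X, Z must have the same number of rows")
        self.x_names = list(x_names) if x_names is not None else [
            f"x{j}" for j in range(self.X.shape[1])
        ]
        self.z_names = list(z_names) if z_names is not None else [
            f"z{j}" for j in range(self.Z.shape[1])
        ]
        self._check_rank()
        # precomputed response transforms
        self._ystar = np.log(self.y) - np.log1p(-self.y)
        self._logy = np.log(self.y)
        self._log1my = np.log1p(-self.y)

    @classmethod
    def from_design(cls, design: DesignMatrix) -> "BetaRegression":
        return cls(design.y, design.X, design.Z, design.x_names, design.z_names)

    # ---------------------------------------------------------------- rank
    def _check_rank(self):
        for M, names, label in ((self.X, self.x_names, "X"), (self.Z, self.z_names, "Z")):
            r = np.linalg.matrix_rank(M)
            if r < M.shape[1]:
                # identify a minimal offending column by incremental rank
                bad = []
                for j in range(M.shape[1]):
                    if np.linalg.matrix_rank(M[:, : j + 1]) <= np.linalg.matrix_rank(M[:, :j]):
                        bad.append(names[j])
                raise ValueError(f"rank-deficient {label}; collinear columns: {bad}")

    # ---------------------------------------------------------- likelihood
    @property
    def p(self):
        return self.X.shape[1]

    @property
    def q(self):
        return self.Z.shape[1]

    @property
    def k_params(self):
        return self.p + self.q

    def _split(self, params):
        return params[: self.p], params[self.p :]

    def loglike(self, params) -> float:
        beta, gamma = self._split(np.asarray(params, float))
        mu, phi = _mu_phi(self.X, self.Z, beta, gamma)
        a, b = mu * phi, (1 - mu) * phi
        return float(
            np.sum(
                special.gammaln(phi)
                - special.gammaln(a)
                - special.gammaln(b)
                + (a - 1) * self._logy
                + (b - 1) * self._log1my
            )
        )

    def score(self, params) -> np.ndarray:
        """Analytic gradient of the log-likelihood."""
        beta, gamma = self._split(np.asarray(params, float))
        mu, phi = _mu_phi(self.X, self.Z, beta, gamma)
        a, b = mu * phi, (1 - mu) * phi
        mustar = special.digamma(a) - special.digamma(b)
        d_eta = phi * (self._ystar - mustar) * mu * (1 - mu)
        d_zeta = phi * (
            special.digamma(phi)
            - mu * special.digamma(a)
            - (1 - mu) * special.digamma(b)
            + mu * self._logy
            + (1 - mu) * self._log1my
        )
        return np.concatenate([self.X.T @ d_eta, self.Z.T @ d_zeta])

    def _negll_grad(self, params):
        return -self.loglike(params), -self.score(params)

    def hessian(self, params) -> np.ndarray:
        """Analytic Hessian of the log-likelihood."""
        beta, gamma = self._split(np.asarray(params, float))
        mu, phi = _mu_phi(self.X, self.Z, beta, gamma)
        a, b = mu * phi, (1 - mu) * phi
        psi1a, psi1b = special.polygamma(1, a), special.polygamma(1, b)
        mustar = special.digamma(a) - special.digamma(b)
        m = mu * (1 - mu)
        ystar = self._ystar
        # d2/deta2
        w = phi * (-phi * m**2 * (psi1a + psi1b) + (ystar - mustar) * (1 - 2 * mu) * m)
        # d2/dzeta2
        r = (
            special.digamma(phi)
            - mu * special.digamma(a)
            - (1 - mu) * special.digamma(b)
            + mu * self._logy
            + (1 - mu) * self._log1my
        )
        d = phi * r + phi**2 * (
            special.polygamma(1, phi) - mu**2 * psi1a - (1 - mu) ** 2 * psi1b
        )
        # cross term d2/deta dzeta
        c = phi * m * ((ystar - mustar) - phi * (mu * psi1a - (1 - mu) * psi1b))
        Hbb = self.X.T @ (w[:, None] * self.X)
        Hgg = self.Z.T @ (d[:, None] * self.Z)
        Hbg = self.X.T @ (c[:, None] * self.Z)
        return np.block([[Hbb, Hbg], [Hbg.T, Hgg]])

    def _fit_newton(self, x0, gtol, maxiter=100):
        """Damped Newton ascent with Levenberg-style regularization when the
        observed information is not positive definite away from the optimum;
        returns (params, llf, grad_norm) or None on failure."""
        x = np.asarray(x0, float)
        ll = self.loglike(x)
        if not np.isfinite(ll):
            return None
        k = x.size
        for it in range(maxiter):
            g = self.score(x)
            gnorm = float(np.max(np.abs(g)))
            if gnorm <= gtol * 1e-2 or (gnorm <= gtol and it > 2):
                return x, ll, gnorm
            H = self.hessian(x)
            ev_max = float(np.linalg.eigvalsh(H).max())
            if ev_max > -1e-10:
                # shift spectrum so -H is positive definite (damped ascent)
                H = H - (ev_max + 1e-2 * max(1.0, abs(ev_max))) * np.eye(k)
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError:
                return None
            if not np.all(np.isfinite(step)):
                return None
            lam = 1.0
            for _ls in range(40):
                x_new = x + lam * step
                ll_new = self.loglike(x_new)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                lam *= 0.5
            else:
                return None
            improved = ll_new - ll
            x, ll = x_new, ll_new
            if improved < 1e-13 and np.max(np.abs(self.score(x))) <= gtol:
                return x, ll, float(np.max(np.abs(self.score(x))))
        g = float(np.max(np.abs(self.score(x))))
        return (x, ll, g) if g <= gtol else None

    def start_params(self) -> np.ndarray:
        """Deterministic start: logit-scale least squares for beta,
        method-of-moments precision intercept, remaining gamma at zero."""
        beta0, *_ = np.linalg.lstsq(self.X, self._ystar, rcond=None)
        mu0 = special.expit(np.clip(self.X @ beta0, -_ETA_CLIP, _ETA_CLIP))
        resid = self.y - mu0
        s2 = float(np.mean(resid**2 / np.maximum(mu0 * (1 - mu0), 1e-8)))
        phi0 = max(1.0 / max(s2, 1e-8) - 1.0, 1.5)
        gamma0 = np.zeros(self.q)
        gamma0[0] = np.log(phi0)
        return np.concatenate([beta0, gamma0])

    def fit(
        self,
        start_params=None,
        maxiter: int = 500,
        gtol: float = 1e-6,
        n_restarts: int = 3,
        compute_cov: bool = True,
    ) -> "BetaRegressionResults":
        """Maximize the likelihood by quasi-Newton with analytic gradient.

        Up to ``n_restarts`` deterministic jittered restarts are attempted if
        the gradient sup-norm at the optimum exceeds ``gtol``; a fit that
        still fails is returned with ``converged=False`` rather than raised.
        """
        x0 = np.asarray(start_params, float) if start_params is not None else self.start_params()
        newton = self._fit_newton(x0, gtol)
        if newton is not None:
            params, llf, gnorm = newton
            cov = self._cov_params(params) if compute_cov else None
            return BetaRegressionResults(self, params, llf, cov, True, gnorm)
        best = None
        rng = np.random.default_rng(0)  # restart jitter only; fit is deterministic
        for attempt in range(n_restarts + 1):
            trial = x0 if attempt == 0 else x0 + rng.normal(0, 0.1 * (attempt), size=x0.size)
            res = optimize.minimize(
                self._negll_grad,
                trial,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
            )
            gnorm = float(np.max(np.abs(self.score(res.x))))
            if gnorm > gtol:
                polish = self._fit_newton(res.x, gtol, maxiter=50)
                if polish is not None and polish[1] >= -res.fun - 1e-9:
                    x_p, ll_p, gnorm = polish
                    cov = self._cov_params(x_p) if compute_cov else None
                    return BetaRegressionResults(self, x_p, ll_p, cov, True, gnorm)
            if best is None or -res.fun > best[0]:
                best = (-res.fun, res.x, gnorm)
            if gnorm <= gtol:
                break
        llf, params, gnorm = best
        converged = gnorm <= gtol
        cov = self._cov_params(params) if compute_cov else None
        return BetaRegressionResults(self, params, llf, cov, converged, gnorm)

    def _cov_params(self, params) -> np.ndarray:
        """Inverse observed information from the analytic Hessian."""
        H = self.hessian(np.asarray(params, float))
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-H)
        return cov


@dataclass
class BootstrapResult:
    """Case-bootstrap replicate coefficients and percentile intervals."""

    params: np.ndarray  # (B_ok, k) converged replicate estimates
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    names: list[str]
    B: int
    n_failed: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.names, "ci_2.5": self.ci_lower, "ci_97.5": self.ci_upper}
        )


class BetaRegressionResults:
    """Fitted beta regression: estimates, uncertainty, diagnostics."""

    def __init__(self, model, params, llf, cov_params, converged, grad_norm):
        self.model = model
        self.params = np.asarray(params, float)
        self.llf = float(llf)
        self._cov = cov_params
        self.converged = bool(converged)
        self.grad_norm = float(grad_norm)
        self.bootstrap_result: BootstrapResult | None = None

    # ------------------------------------------------------------ pieces
    @property
    def beta(self):
        return self.params[: self.model.p]

    @property
    def gamma(self):
        return self.params[self.model.p :]

    @property
    def k_params(self):
        return self.model.k_params

    @property
    def aic(self):
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def cov_params(self):
        return self._cov

    @property
    def bse(self):
        d = np.diag(self._cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)

    @property
    def zvalues(self):
        return self.params / self.bse

    @property
    def pvalues(self):
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def names(self):
        return [f"mean:{n}" for n in self.model.x_names] + [
            f"precision:{n}" for n in self.model.z_names
        ]

    @property
    def linpred(self):
        return self.model.X @ self.beta

    @property
    def fitted_mu(self):
        return special.expit(np.clip(self.linpred, -_ETA_CLIP, _ETA_CLIP))

    @property
    def fitted_phi(self):
        return np.exp(np.clip(self.model.Z @ self.gamma, -_ZETA_CLIP, _ZETA_CLIP))

    @property
    def resid_response(self):
        return self.model.y - self.fitted_mu

    @property
    def resid(self):
        """Standardized weighted residual on the link scale (default
        residual for spatial/phylogenetic diagnostics)."""
        mu, phi = self.fitted_mu, self.fitted_phi
        a, b = mu * phi, (1 - mu) * phi
        mustar = special.digamma(a) - special.digamma(b)
        v = special.polygamma(1, a) + special.polygamma(1, b)
        return (self.model._ystar - mustar) / np.sqrt(v)

    @property
    def pseudo_r2(self):
        """Squared Pearson correlation between logit(y) and the fitted mean
        linear predictor."""
        ystar, eta = self.model._ystar, self.linpred
        if np.std(ystar) == 0 or np.std(eta) == 0:
            raise ValueError("zero variance in response or linear predictor")
        r = np.corrcoef(ystar, eta)[0, 1]
        return float(r**2)

    # --------------------------------------------------------- bootstrap
    def bootstrap(self, B: int = 1000, seed: int = 0, warm_start: bool = True) -> BootstrapResult:
        """Case (row) bootstrap with percentile 95% intervals.

        Species rows are resampled with replacement and the fixed+precision
        model refitted; spatial eigenvector columns, if present in X, travel
        with their rows (treated as fixed covariates).
        """
        if B < 100:
            raise ValueError("B must be >= 100")
        m = self.model
        rng = np.random.default_rng(seed)
        n = len(m.y)
        start = self.params if warm_start else None
        reps, failed = [], 0
        for _ in range(B):
            idx = rng.integers(0, n, n)
            try:
                sub = BetaRegression(m.y[idx], m.X[idx], m.Z[idx], m.x_names, m.z_names)
                r = sub.fit(start_params=start, n_restarts=1, compute_cov=False)
            except (ValueError, np.linalg.LinAlgError):
                failed += 1
                continue
            if r.converged:
                reps.append(r.params)
            else:
                failed += 1
        if failed > 0.1 * B:
            warnings.warn(f"{failed}/{B} bootstrap replicates failed to converge")
        reps = np.asarray(reps)
        lo = np.percentile(reps, 2.5, axis=0)
        hi = np.percentile(reps, 97.5, axis=0)
        out = BootstrapResult(reps, lo, hi, self.names, B, failed, seed)
        self.bootstrap_result = out
        return out

    # ------------------------------------------------------ effect curves
    def predict_effect(
        self,
        design: DesignMatrix,
        target_column: str,
        grid=None,
        n_grid: int = 50,
        method: str = "delta",
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Response-scale effect of one predictor with the others at their
        sample means (binary covariates at their sample proportion).

        ``grid`` is on the raw covariate scale; defaults to the observed
        range.  The confidence band is delta-method on the link scale by
        default, or percentile over stored bootstrap replicates
        (``method='bootstrap'`` after calling :meth:`bootstrap`).
        """
        if target_column not in design.x_names:
            raise ValueError(f"{target_column!r} not in design columns {design.x_names}")
        j = design.x_names.index(target_column)
        raw = design.raw
        if grid is None:
            if raw is not None and target_column in raw.columns:
                lo_r, hi_r = raw[target_column].min(), raw[target_column].max()
            else:
                col = design.X[:, j]
                lo_r, hi_r = col.min(), col.max()
                if target_column in design.center:
                    lo_r = lo_r * design.scale[target_column] + design.center[target_column]
                    hi_r = hi_r * design.scale[target_column] + design.center[target_column]
            grid = np.linspace(lo_r, hi_r, n_grid)
        grid = np.asarray(grid, float)
        if raw is not None and target_column in raw.columns:
            obs_lo, obs_hi = raw[target_column].min(), raw[target_column].max()
            if grid.min() < obs_lo or grid.max() > obs_hi:
                warnings.warn("effect grid extends outside the observed covariate range")
        base = design.X.mean(axis=0)  # standardized continuous -> ~0; dummies -> proportion
        Xg = np.tile(base, (len(grid), 1))
        Xg[:, j] = design.standardize_value(target_column, grid)
        eta = Xg @ self.beta
        mu = special.expit(eta)
        zc = stats.norm.ppf(1 - alpha / 2)
        if method == "delta":
            covb = self._cov[: self.model.p, : self.model.p]
            se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, covb, Xg))
            lo, hi = special.expit(eta - zc * se), special.expit(eta + zc * se)
        elif method == "bootstrap":
            if self.bootstrap_result is None:
                raise ValueError("call bootstrap() before method='bootstrap'")
            betas = self.bootstrap_result.params[:, : self.model.p]
            curves = special.expit(betas @ Xg.T)
            lo = np.percentile(curves, 100 * alpha / 2, axis=0)
            hi = np.percentile(curves, 100 * (1 - alpha / 2), axis=0)
        else:
            raise ValueError("method must be 'delta' or 'bootstrap'")
        return pd.DataFrame(
            {target_column: grid, "mu": mu, "ci_lower": lo, "ci_upper": hi, "method": method}
        )

    # ------------------------------------------------------------ summary
    def summary(self) -> str:
        boot = self.bootstrap_result
        lines = [
            "Beta regression (logit mean link, log precision link)",
            f"  N = {len(self.model.y)}   log-likelihood = {self.llf:.4f}   "
            f"AIC = {self.aic:.4f}",
            f"  pseudo R-squared = {self.pseudo_r2:.4f}   converged = {self.converged}",
            "",
        ]
        header = f"{'':28s}{'estimate':>10s}{'SE':>9s}{'z':>9s}{'p':>9s}"
        if boot is not None:
            header += f"{'boot 2.5%':>11s}{'boot 97.5%':>11s}"
        se, z, p = self.bse, self.zvalues, self.pvalues
        lines.append("Mean submodel")
        lines.append(header)
        for i, name in enumerate(self.names):
            if i == self.model.p:
                lines.append("Precision submodel")
                lines.append(header)
            row = (
                f"  {name:26s}{self.params[i]:10.4f}{se[i]:9.4f}{z[i]:9.3f}{p[i]:9.4f}"
            )
            if boot is not None:
                row += f"{boot.ci_lower[i]:11.4f}{boot.ci_upper[i]:11.4f}"
            lines.append(row)
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "coef": self.names,
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )
        if self.bootstrap_result is not None:
            df["ci_2.5"] = self.bootstrap_result.ci_lower
            df["ci_97.5"] = self.bootstrap_result.ci_upper
        return df


# ===================================================================== mixed


class MixedBetaRegression(BetaRegression):
    """Beta regression with a Gaussian random intercept per group (taxonomic
    family) in the mean submodel, integrated out by a Laplace approximation.
    """

    def __init__(self, y, X, Z=None, groups=None, x_names=None, z_names=None):
        super().__init__(y, X, Z, x_names, z_names)
        if groups is None:
            raise ValueError("groups required for the mixed model")
        codes, uniques = pd.factorize(np.asarray(groups))
        if len(uniques) < 2:
            raise ValueError("mixed model needs at least 2 groups (families)")
        self.group_idx = codes
        self.group_labels = list(map(str, uniques))
        self.n_groups = len(uniques)

    @classmethod
    def from_design(cls, design: DesignMatrix) -> "MixedBetaRegression":
        return cls(
            design.y, design.X, design.Z, design.family, design.x_names, design.z_names
        )

    @property
    def k_params(self):
        return self.p + self.q + 1  # + random-intercept variance

    # per-observation derivatives of the beta log-density wrt eta
    def _eta_derivs(self, eta, phi):
        mu = special.expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        a, b = mu * phi, (1 - mu) * phi
        ll = (
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1) * self._logy
            + (b - 1) * self._log1my
        )
        mustar = special.digamma(a) - special.digamma(b)
        m = mu * (1 - mu)
        u = phi * (self._ystar - mustar) * m
        w = phi * (
            -phi * m**2 * (special.polygamma(1, a) + special.polygamma(1, b))
            + (self._ystar - mustar) * (1 - 2 * mu) * m
        )
        return ll, u, w

    def _laplace(self, params, return_modes=False):
        """Laplace-approximate marginal log-likelihood at (beta, gamma, log sigma).

        The per-group conditional modes are independent 1-D concave problems
        solved by damped Newton, warm-started from the previous call (the
        outer optimizer moves in small steps, so 2-3 iterations suffice).
        """
        beta, gamma, lsig = params[: self.p], params[self.p : self.p + self.q], params[-1]
        sig2 = np.exp(2 * lsig)
        eta0 = self.X @ beta
        phi = np.exp(np.clip(self.Z @ gamma, -_ZETA_CLIP, _ZETA_CLIP))
        g = self.group_idx
        b = getattr(self, "_mode_cache", np.zeros(self.n_groups)).copy()

        def h_parts(bvec):
            ll, u, w = self._eta_derivs(eta0 + bvec[g], phi)
            h = np.bincount(g, ll, minlength=self.n_groups) - bvec**2 / (2 * sig2)
            grad = np.bincount(g, u, minlength=self.n_groups) - bvec / sig2
            hess = np.bincount(g, w, minlength=self.n_groups) - 1 / sig2
            return h, grad, hess

        h, grad, hess = h_parts(b)
        for _ in range(50):
            if np.max(np.abs(grad)) < 1e-9:
                break
            step = np.clip(-grad / np.minimum(hess, -1e-10), -3.0, 3.0)
            lam = np.ones(self.n_groups)
            for _ls in range(20):
                b_new = b + lam * step
                h_new, grad_new, hess_new = h_parts(b_new)
                worse = h_new < h - 1e-12
                if not worse.any():
                    break
                lam = np.where(worse, lam * 0.5, lam)
            b, h, grad, hess = b_new, h_new, grad_new, hess_new
        self._mode_cache = b.copy()
        marg = float(np.sum(h - 0.5 * np.log(sig2) - 0.5 * np.log(np.maximum(-hess, 1e-300))))
        if return_modes:
            return marg, b
        return marg

    def fit(self, start_params=None, maxiter: int = 300, **_) -> "MixedBetaRegressionResults":
        self._mode_cache = np.zeros(self.n_groups)  # idempotent refits
        if start_params is None:
            base = BetaRegression(self.y, self.X, self.Z, self.x_names, self.z_names).fit(
                compute_cov=False
            )
            start_params = np.concatenate([base.params, [np.log(0.3)]])
        x0 = np.asarray(start_params, float)
        bounds = [(None, None)] * (self.p + self.q) + [(np.log(1e-6), np.log(10.0))]
        res = optimize.minimize(
            lambda th: -self._laplace(th),
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11},
        )
        llf = -res.fun
        params = res.x
        sigma = float(np.exp(params[-1]))
        boundary = sigma < 1e-3
        _, modes = self._laplace(params, return_modes=True)
        # covariance of (beta, gamma) from numerical Hessian of the marginal ll
        k = params.size
        H = np.zeros((k, k))
        hstep = 1e-4 * np.maximum(np.abs(params), 1.0)
        f0 = llf
        fs = {}

        def feval(delta):
            key = tuple(np.round(delta / hstep, 6))
            if key not in fs:
                fs[key] = self._laplace(params + delta)
            return fs[key]

        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = hstep[i]
                ej = np.zeros(k); ej[j] = hstep[j]
                if i == j:
                    H[i, i] = (feval(ei) - 2 * f0 + feval(-ei)) / hstep[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        feval(ei + ej) - feval(ei - ej) - feval(-ei + ej) + feval(-ei - ej)
                    ) / (4 * hstep[i] * hstep[j])
        try:
            cov_full = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov_full = np.linalg.pinv(-H)
        return MixedBetaRegressionResults(
            self, params[:-1], llf, cov_full[:-1, :-1], res.success, 0.0,
            sigma=sigma, boundary=boundary, random_effects=modes,
        )


class MixedBetaRegressionResults(BetaRegressionResults):
    """Laplace-approximated mixed beta regression fit."""

    approximation = "laplace"

    def __init__(self, model, params, llf, cov_params, converged, grad_norm,
                 sigma, boundary, random_effects):
        super().__init__(model, params, llf, cov_params, converged, grad_norm)
        self.sigma = float(sigma)
        self.group_var = float(sigma**2)
        self.boundary = bool(boundary)
        self.random_effects = dict(zip(model.group_labels, random_effects))

    @property
    def k_params(self):
        return self.model.k_params  # includes the variance parameter

    def summary(self) -> str:
        base = super().summary()
        return base + (
            f"\nRandom intercept (family): sd = {self.sigma:.4f}"
            f"{'  [boundary]' if self.boundary else ''}   approximation = laplace"
        )


# ============================================================== diagnostics


def vif(X: np.ndarray, names=None, intercept_col: int | None = 0) -> pd.DataFrame:
    """Variance inflation factor of each predictor: 1/(1-R^2) from OLS of the
    column on all other columns (intercept included).

    Perfect collinearity is reported as ``inf``.
    """
    X = np.asarray(X, float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    cols = [j for j in range(X.shape[1]) if j != intercept_col]
    if len(cols) < 3:
        raise ValueError("VIF needs at least 3 predictors beyond the intercept")
    out = []
    for j in cols:
        others = [c for c in range(X.shape[1]) if c != j]
        M = X[:, others]
        if intercept_col is None:
            M = np.column_stack([np.ones(X.shape[0]), M])
        coef, *_ = np.linalg.lstsq(M, X[:, j], rcond=None)
        resid = X[:, j] - M @ coef
        tss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        rss = np.sum(resid**2)
        r2 = 1 - rss / tss if tss > 0 else 1.0
        out.append({"predictor": names[j], "vif": np.inf if r2 >= 1 - 1e-12 else 1 / (1 - r2)})
    return pd.DataFrame(out)


# =========================================================== model selection

#: candidate name -> (uses precision submodel, uses family random intercept)
CANDIDATE_MODELS = {
    "fixed": (False, False),
    "fixed+precision": (True, False),
    "fixed+re": (False, True),
    "fixed+precision+re": (True, True),
}


def model_selection(y, X, Z, family_labels, x_names=None, z_names=None):
    """Fit the four candidate structures and rank them by AIC.

    Candidates: fixed effects only; + precision submodel; + family random
    intercept; + both.  Returns ``(table, winner_name, fits)`` with the table
    sorted by ascending AIC over converged fits.
    """
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    Z0 = np.ones((len(y), 1))
    z0_names = ["intercept"]
    fits = {}
    rows = []
    for name, (use_precision, use_re) in CANDIDATE_MODELS.items():
        Zc = Z if use_precision else Z0
        zc_names = z_names if use_precision else z0_names
        try:
            if use_re:
                model = MixedBetaRegression(y, X, Zc, family_labels, x_names, zc_names)
            else:
                model = BetaRegression(y, X, Zc, x_names, zc_names)
            fit = model.fit()
            fits[name] = fit
            rows.append(
                {
                    "model": name,
                    "k": fit.k_params,
                    "loglik": fit.llf,
                    "aic": fit.aic,
                    "converged": fit.converged,
                }
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"candidate {name} failed: {exc}")
            rows.append(
                {"model": name, "k": np.nan, "loglik": np.nan, "aic": np.nan, "converged": False}
            )
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no candidate model converged")
    winner = ok.iloc[0]["model"]
    return table, winner, fits
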