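"""Per-harvest mixed models: NB2 GLMMs, Gaussian LMMs, marginal means, contrasts.

The abundance analyses fit, separately for each harvest,

    response ~ elevation * season * treatment + (1 | site)

with a negative-binomial (NB2, log link) family for counts and a Gaussian
family for diversity point estimates.  The NB mixed model is fitted by
maximum likelihood with a Laplace approximation over the site random
intercepts (adequate for the study's four sites); no installed Python
package fits NB GLMMs, so the estimator lives here.  Heat-vs-control
contrasts are reported as percent change, 100*(exp(delta)-1), with
delta-method standard errors — the standard back-transform for log-link
marginal-mean contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm

from .design import ModelMatrix

__all__ = [
    "NegativeBinomialMixedModel",
    "GaussianMixedModel",
    "MixedFitResults",
    "PercentChange",
    "fit_nb_glmm",
    "fit_gaussian_lmm",
    "estimate_marginal_means",
    "percent_change_contrast",
]

_ETA_CLIP = 30.0


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PercentChange:
    """A heat-vs-control contrast on the link scale and (for log links) in percent."""

    delta: float
    se_delta: float
    percent: float | None
    se_percent: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float
    cell: dict
    harvest: str | None
    link: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.percent is None:
            return f"difference {self.delta:+.3f} ± {self.se_delta:.3f} (identity link)"
        return f"{self.percent:+.1f}% ± {self.se_percent:.1f}%"


def _nb_loglik(y: np.ndarray, eta: np.ndarray, k: float) -> np.ndarray:
    """Pointwise NB2 log-likelihood with log link (variance mu + mu^2/k)."""
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    return (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1)
        + k * (np.log(k) - np.log(k + mu))
        + y * (eta - np.log(k + mu))
    )


def _nb_eta_derivs(y, eta, k):
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    grad = y - (y + k) * mu / (k + mu)
    hess = -(y + k) * k * mu / (k + mu) ** 2
    return grad, hess


def _laplace_loglik(y, X, offset, group_idx, n_groups, beta, log_k, log_s2):
    """Marginal log-likelihood, Laplace-approximated over group intercepts."""
    k = np.exp(log_k)
    s2 = np.exp(log_s2)
    eta0 = X @ beta + offset
    u = np.zeros(n_groups)
    for _ in range(100):
        g, h = _nb_eta_derivs(y, eta0 + u[group_idx], k)
        grad = np.bincount(group_idx, weights=g, minlength=n_groups) - u / s2
        hess = np.bincount(group_idx, weights=h, minlength=n_groups) - 1.0 / s2
        step = grad / hess
        # damped Newton for stability far from the mode
        step = np.clip(step, -4.0, 4.0)
        u = u - step
        if np.max(np.abs(grad)) < 1e-10:
            break
    g, h = _nb_eta_derivs(y, eta0 + u[group_idx], k)
    hess = np.bincount(group_idx, weights=h, minlength=n_groups) - 1.0 / s2
    ll_data = _nb_loglik(y, eta0 + u[group_idx], k).sum()
    ll = ll_data - 0.5 * np.sum(u**2) / s2 - 0.5 * n_groups * np.log(s2) - 0.5 * np.sum(np.log(-hess))
    return ll


def _numeric_hessian(fun, x, eps=1e-4):
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            f = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * eps * eps)
            H[i, j] = H[j, i] = f
    return H


class MixedFitResults:
    """Estimates, uncertainties and diagnostics of a fitted mixed model.

    Provides Wald-z inference on the fixed effects, estimated marginal
    means over requested factors (equal weights over the remaining ones),
    and percent-change contrasts for log-link fits.
    """

    def __init__(
        self,
        params: pd.Series,
        cov_params: pd.DataFrame,
        *,
        link: str,
        k: float | None,
        scale: float | None,
        sigma_u: float,
        llf: float,
        converged: bool,
        grad_norm: float,
        boundary: bool,
        design: ModelMatrix | None,
        harvest: str | None = None,
        n_obs: int = 0,
        model: object | None = None,
    ):
        self.params = params
        self.cov_params = cov_params
        self.link = link
        self.k = k
        self.scale = scale
        self.sigma_u = sigma_u
        self.llf = llf
        self.converged = converged
        self.grad_norm = grad_norm
        self.boundary = boundary
        self.design = design
        self.harvest = harvest
        self.n_obs = n_obs
        self.model = model

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        # Wald z reference distribution; the small number of sites makes any
        # df-based refinement poorly identified, so none is attempted.
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    # -- marginal means -----------------------------------------------------

    def _require_design(self) -> ModelMatrix:
        if self.design is None:
            raise ValueError("fit was built without a ModelMatrix; marginal means unavailable")
        return self.design

    def _linear_combo(self, L: np.ndarray) -> tuple[float, float]:
        b = self.params.to_numpy()
        V = self.cov_params.to_numpy()
        return float(L @ b), float(np.sqrt(max(L @ V @ L, 0.0)))

    def marginal_means(self, factors: Sequence[str], alpha: float = 0.05) -> pd.DataFrame:
        """Estimated marginal means on the link scale for cells of ``factors``.

        Each cell's estimate is L beta with SE sqrt(L Sigma L'); L averages the
        coded rows over the levels of every fixed factor not requested.
        """
        design = self._require_design()
        unknown = [f for f in factors if f not in design.factors]
        if unknown:
            raise KeyError(f"factors not in design: {unknown}")
        import itertools as it

        rows = []
        z = stats.norm.ppf(1 - alpha / 2)
        for combo in it.product(*(design.levels[f] for f in factors)):
            fix = dict(zip(factors, combo))
            L = design.emm_row(fix)
            est, se = self._linear_combo(L)
            rows.append({**fix, "estimate": est, "se": se, "ci_lo": est - z * se, "ci_hi": est + z * se})
        return pd.DataFrame(rows)

    def contrast(
        self,
        cell: Mapping[str, str],
        between: str = "treatment",
        levels: tuple[str, str] | None = None,
    ) -> tuple[float, float]:
        """Link-scale difference between two levels of ``between`` at ``cell``."""
        design = self._require_design()
        if levels is None:
            lv = design.levels[between]
            levels = (lv[-1], lv[0])  # non-reference (heat) minus reference (control)
        L1 = design.emm_row({**cell, between: levels[0]})
        L0 = design.emm_row({**cell, between: levels[1]})
        return self._linear_combo(L1 - L0)

    def percent_change(
        self,
        cell: Mapping[str, str],
        between: str = "treatment",
        levels: tuple[str, str] | None = None,
        alpha: float = 0.05,
    ) -> PercentChange:
        """Heat-vs-control contrast as percent change (log link only).

        percent = 100*(exp(delta)-1); SE(percent) = 100*exp(delta)*SE(delta)
        by the delta method; the CI is the back-transformed link-scale CI.
        Identity-link fits return the raw difference with percent fields None.
        """
        delta, se = self.contrast(cell, between, levels)
        p = 2 * stats.norm.sf(abs(delta) / se) if se > 0 else (0.0 if delta != 0 else 1.0)
        if self.link != "log":
            return PercentChange(
                delta=delta, se_delta=se, percent=None, se_percent=None,
                ci_low=None, ci_high=None, p_value=p, cell=dict(cell),
                harvest=self.harvest, link=self.link,
            )
        z = stats.norm.ppf(1 - alpha / 2)
        return PercentChange(
            delta=delta,
            se_delta=se,
            percent=100.0 * np.expm1(delta),
            se_percent=100.0 * np.exp(delta) * se,
            ci_low=100.0 * np.expm1(delta - z * se),
            ci_high=100.0 * np.expm1(delta + z * se),
            p_value=p,
            cell=dict(cell),
            harvest=self.harvest,
            link=self.link,
        )

    def summary(self) -> str:
        head = (
            f"{'NB2 GLMM (log link)' if self.link == 'log' else 'Gaussian LMM'}"
            f"  n={self.n_obs}  llf={self.llf:.2f}  converged={self.converged}"
        )
        disp = (
            f"k={self.k:.3f}" if self.k is not None else f"residual var={self.scale:.4f}"
        )
        tab = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "z": self.zvalues, "p": self.pvalues}
        )
        lines = [head, f"dispersion: {disp}  random-intercept SD: {self.sigma_u:.4f}"
                 + ("  [boundary]" if self.boundary else ""), tab.to_string(float_format="%.4f")]
        return "\n".join(lines)


class NegativeBinomialMixedModel:
    """NB2 GLMM with a single random-intercept grouping factor (log link).

    Fitted by maximum likelihood with a Laplace approximation of the
    random-intercept integral; Wald covariance comes from the observed
    information of the approximated marginal likelihood.  ``groups=None``
    fits a plain NB2 GLM.
    """

    def __init__(
        self,
        endog,
        design: ModelMatrix | np.ndarray,
        groups: Sequence | None = None,
        offset: Sequence | None = None,
        exog_names: Sequence[str] | None = None,
        harvest: str | None = None,
    ):
        self.endog = np.asarray(endog, float)
        if np.any(self.endog < 0) or np.any(self.endog != np.rint(self.endog)):
            raise ValueError("counts must be non-negative integers")
        if isinstance(design, ModelMatrix):
            self.design = design
            self.exog = design.matrix
            self.exog_names = list(design.columns)
            if groups is None and design.group_ids is not None:
                groups = design.group_ids
        else:
            self.design = None
            self.exog = np.asarray(design, float)
            self.exog_names = list(exog_names) if exog_names else [f"x{i}" for i in range(self.exog.shape[1])]
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and design have different numbers of rows")
        self.offset = np.zeros_like(self.endog) if offset is None else np.asarray(offset, float)
        if self.offset.shape[0] != self.endog.shape[0]:
            raise ValueError("offset length mismatch")
        self.harvest = harvest
        if groups is not None:
            codes, uniques = pd.factorize(np.asarray(groups))
            if len(codes) != len(self.endog):
                raise ValueError("groups length mismatch")
            self.group_idx, self.group_levels = codes, list(uniques)
        else:
            self.group_idx, self.group_levels = None, []

    @classmethod
    def from_design(cls, endog, design: ModelMatrix, **kw) -> "NegativeBinomialMixedModel":
        return cls(endog, design, **kw)

    def _loglike(self, theta: np.ndarray) -> float:
        p = self.exog.shape[1]
        beta, log_k = theta[:p], theta[p]
        if self.group_idx is None:
            eta = self.exog @ beta + self.offset
            return float(_nb_loglik(self.endog, eta, np.exp(log_k)).sum())
        return float(
            _laplace_loglik(
                self.endog, self.exog, self.offset, self.group_idx,
                len(self.group_levels), beta, log_k, theta[p + 1],
            )
        )

    def fit(self, start_params: np.ndarray | None = None, maxiter: int = 500) -> MixedFitResults:
        p = self.exog.shape[1]
        if start_params is None:
            # log-linear least squares start
            z = np.log(self.endog + 0.5) - self.offset
            beta0, *_ = np.linalg.lstsq(self.exog, z, rcond=None)
            start = np.concatenate([beta0, [0.0]])
            if self.group_idx is not None:
                start = np.concatenate([start, [np.log(0.1)]])
        else:
            start = np.asarray(start_params, float)
        neg = lambda th: -self._loglike(th)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(neg, start, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-7})
            if not res.success:  # polish with Nelder-Mead from the BFGS point
                res2 = optimize.minimize(neg, res.x, method="Nelder-Mead",
                                         options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
                if res2.fun <= res.fun:
                    res2.jac = optimize.approx_fprime(res2.x, neg, 1e-6)
                    res = res2
        theta = res.x
        grad = res.jac if getattr(res, "jac", None) is not None else optimize.approx_fprime(theta, neg, 1e-6)
        grad_norm = float(np.max(np.abs(grad)))
        converged = bool(res.success or grad_norm < 1e-3)
        sigma_u = float(np.exp(theta[p + 1] / 2)) if self.group_idx is not None else 0.0
        boundary = False
        if self.group_idx is not None and sigma_u < 1e-3:
            # variance component at the boundary: reduce to the fixed-effect model
            reduced = NegativeBinomialMixedModel(
                self.endog, self.exog, groups=None, offset=self.offset,
                exog_names=self.exog_names, harvest=self.harvest,
            )
            out = reduced.fit(start_params=theta[: p + 1], maxiter=maxiter)
            out.design = self.design
            out.boundary = True
            return out
        H = _numeric_hessian(neg, theta)
        try:
            cov_all = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_all = np.linalg.pinv(H)
            converged = False
        cov_all = 0.5 * (cov_all + cov_all.T)
        # guard against a non-PSD numeric Hessian far from a clean optimum
        eig = np.linalg.eigvalsh(cov_all[:p, :p])
        if eig.min() < 0:
            cov_all[:p, :p] += (-eig.min() + 1e-12) * np.eye(p)
        return MixedFitResults(
            params=pd.Series(theta[:p], index=self.exog_names),
            cov_params=pd.DataFrame(cov_all[:p, :p], index=self.exog_names, columns=self.exog_names),
            link="log",
            k=float(np.exp(theta[p])),
            scale=None,
            sigma_u=sigma_u,
            llf=float(-res.fun),
            converged=converged,
            grad_norm=grad_norm,
            boundary=boundary,
            design=self.design,
            harvest=self.harvest,
            n_obs=len(self.endog),
            model=self,
        )


class GaussianMixedModel:
    """Gaussian LMM with one random-intercept factor (identity link).

    A front-end over statsmodels MixedLM (ML by default; REML available).
    ``groups=None`` or degenerate data fall back to OLS.
    """

    def __init__(
        self,
        endog,
        design: ModelMatrix | np.ndarray,
        groups: Sequence | None = None,
        exog_names: Sequence[str] | None = None,
        harvest: str | None = None,
    ):
        self.endog = np.asarray(endog, float)
        if isinstance(design, ModelMatrix):
            self.design = design
            self.exog = design.matrix
            self.exog_names = list(design.columns)
            if groups is None and design.group_ids is not None:
                groups = design.group_ids
        else:
            self.design = None
            self.exog = np.asarray(design, float)
            self.exog_names = list(exog_names) if exog_names else [f"x{i}" for i in range(self.exog.shape[1])]
        self.groups = None if groups is None else np.asarray(groups)
        self.harvest = harvest

    def fit(self, reml: bool = False) -> MixedFitResults:
        names = self.exog_names
        if self.groups is None or np.var(self.endog) == 0:
            ols = sm.OLS(self.endog, self.exog).fit()
            scale = float(ols.scale) if np.var(self.endog) > 0 else 0.0
            cov = ols.cov_params() if scale > 0 else np.zeros((len(names), len(names)))
            return MixedFitResults(
                params=pd.Series(ols.params, index=names),
                cov_params=pd.DataFrame(np.asarray(cov), index=names, columns=names),
                link="identity", k=None, scale=scale, sigma_u=0.0,
                llf=float(ols.llf) if scale > 0 else np.inf,
                converged=True, grad_norm=0.0, boundary=self.groups is not None,
                design=self.design, harvest=self.harvest, n_obs=len(self.endog), model=self,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM(self.endog, self.exog, groups=self.groups)
            # lbfgs occasionally reports success at a spurious point; fit with
            # two optimisers and keep the better likelihood
            res = None
            for method in ("bfgs", "powell"):
                try:
                    cand = mod.fit(reml=reml, method=method)
                except Exception:
                    continue
                if np.isfinite(cand.llf) and (res is None or cand.llf > res.llf + 1e-8):
                    res = cand
            if res is None:
                raise ConvergenceError("MixedLM failed with all optimisers")
        sigma_u = float(np.sqrt(np.asarray(res.cov_re)[0, 0]))
        cov = np.asarray(res.cov_params())[: len(names), : len(names)]
        return MixedFitResults(
            params=pd.Series(np.asarray(res.fe_params), index=names),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            link="identity", k=None, scale=float(res.scale), sigma_u=sigma_u,
            llf=float(res.llf), converged=bool(res.converged), grad_norm=0.0,
            boundary=sigma_u < 1e-6, design=self.design, harvest=self.harvest,
            n_obs=len(self.endog), model=self,
        )


# --- functional front-ends ---------------------------------------------------

def fit_nb_glmm(y, X, group_ids=None, offset=None, exog_names=None, harvest=None) -> MixedFitResults:
    """Fit the NB2 GLMM (Laplace ML).  ``X`` may be a ModelMatrix or array."""
    return NegativeBinomialMixedModel(y, X, groups=group_ids, offset=offset,
                                      exog_names=exog_names, harvest=harvest).fit()


def fit_gaussian_lmm(y, X, group_ids=None, exog_names=None, harvest=None, reml=False) -> MixedFitResults:
    """Fit the Gaussian LMM (ML by default)."""
    return GaussianMixedModel(y, X, groups=group_ids, exog_names=exog_names, harvest=harvest).fit(reml=reml)


def estimate_marginal_means(fit: MixedFitResults, factors: Sequence[str]) -> pd.DataFrame:
    return fit.marginal_means(factors)


def percent_change_contrast(fit: MixedFitResults, cell: Mapping[str, str], harvest: str | None = None) -> PercentChange:
    out = fit.percent_change(cell)
    if harvest is not None:
        out.harvest = harvest
    return out
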