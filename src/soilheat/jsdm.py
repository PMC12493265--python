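"""Hierarchical Bayesian joint species distribution models (jSDMs).

Three families cover the study's model sets: a lognormal-Poisson for
Collembola counts (Poisson observation with a per-observation latent normal
on the log mean), and a two-part hurdle for fungal reads — probit
presence/absence on all samples and a Gaussian model of log-transformed,
per-species scaled counts on the present samples.  Species-level
coefficients are drawn around trait-predicted expectations (beta_jk ~
N((T gamma)_jk, tau_k^2)), and a block random intercept absorbs large-scale
geographic structure.  Inference is Gibbs sampling with conjugate normal /
inverse-gamma updates; the lognormal-Poisson latent layer uses adaptive
Metropolis-within-Gibbs.  Priors are weakly informative (normal on
gamma, inverse-gamma on variances); no numerical equivalence with any
particular jSDM package is claimed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelMatrix

__all__ = [
    "JSDMSpec",
    "PosteriorDraws",
    "JointSpeciesModel",
    "JSDMResults",
    "prevalence_filter",
    "fit_jsdm",
    "psrf",
    "classify_support",
    "variance_partition",
    "default_term_groups",
]

FAMILIES = ("lognormal_poisson", "hurdle_probit", "hurdle_lognormal")


@dataclass
class JSDMSpec:
    """MCMC plan and support level for a jSDM fit (defaults: 4 x 250 draws)."""

    family: str = "lognormal_poisson"
    chains: int = 4
    samples: int = 250
    transient: int = 250
    thin: int = 1
    support_level: float = 0.95
    psrf_threshold: float = 1.2

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.chains < 1 or self.samples < 1 or self.thin < 1 or self.transient < 0:
            raise ValueError("invalid MCMC plan")


class PosteriorDraws:
    """chains x iterations x parameters array with parameter names."""

    def __init__(self, array: np.ndarray, names: Sequence[str]):
        array = np.asarray(array, float)
        if array.ndim != 3 or array.shape[2] != len(names):
            raise ValueError("draws must be (chains, iterations, parameters)")
        if not np.all(np.isfinite(array)):
            raise ValueError("posterior draws contain non-finite values")
        self.array = array
        self.names = list(names)
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_samples(self) -> int:
        return self.array.shape[1]

    @property
    def n_total(self) -> int:
        return self.n_chains * self.n_samples

    def __getitem__(self, name: str) -> np.ndarray:
        return self.array[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        return self[name].reshape(-1)


def prevalence_filter(Y: pd.DataFrame, threshold: float = 0.25) -> tuple[pd.DataFrame, int]:
    """Drop rare taxa occurring in fewer than ceil(threshold * n_units) samples.

    Returns the reduced matrix and the occurrence cutoff (e.g. 30 of 120
    units at the 25% threshold).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    n_units = Y.shape[0]
    cutoff = int(np.ceil(threshold * n_units))
    occ = (Y > 0).sum(axis=0)
    keep = occ[occ >= cutoff].index
    return Y[keep], cutoff


def _sample_truncnorm(rng, mean, positive):
    """Truncated standard-deviation-1 normals, sign constrained by presence."""
    lo = np.where(positive, 0.0, -np.inf)
    hi = np.where(positive, np.inf, 0.0)
    a = stats.norm.cdf(lo - mean)
    b = stats.norm.cdf(hi - mean)
    u = a + (b - a) * rng.random(mean.shape)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return mean + stats.norm.ppf(u)


class JointSpeciesModel:
    """A jSDM over a filtered community matrix.

    Parameters
    ----------
    Y
        Samples x species matrix: counts (lognormal_poisson), presence or
        counts (hurdle_probit), or raw reads (hurdle_lognormal, which
        internally log-transforms and z-scores the present counts per
        species).
    X
        Fixed-effect design (ModelMatrix or array).  Covariates such as log
        sequencing depth enter as extra columns.
    traits
        Species x trait-level matrix T (an intercept column is prepended if
        absent); expected coefficients are T gamma.
    random_ids
        Block labels per sample for the random intercept, or None.
    """

    def __init__(
        self,
        Y: pd.DataFrame,
        X: ModelMatrix | np.ndarray,
        traits: pd.DataFrame | None = None,
        random_ids: Sequence | None = None,
        family: str = "lognormal_poisson",
        extra_covariates: pd.DataFrame | None = None,
    ):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        self.family = family
        self.Y = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y))
        self.species = list(self.Y.columns)
        if isinstance(X, ModelMatrix):
            self.design: ModelMatrix | None = X
            Xm = X.matrix
            self.term_names = list(X.columns)
            if random_ids is None and X.group_ids is not None:
                random_ids = X.group_ids
        else:
            self.design = None
            Xm = np.asarray(X, float)
            self.term_names = [f"x{i}" for i in range(Xm.shape[1])]
        if extra_covariates is not None:
            extra = extra_covariates.loc[self.Y.index] if isinstance(extra_covariates, pd.DataFrame) else pd.DataFrame(np.asarray(extra_covariates))
            Xm = np.column_stack([Xm, extra.to_numpy(float)])
            self.term_names += list(extra.columns)
        self.X = Xm
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("Y and X have different numbers of samples")
        if traits is not None:
            T = traits.loc[self.species]
            if "Intercept" not in T.columns:
                T = pd.concat([pd.Series(1.0, index=T.index, name="Intercept"), T], axis=1)
            self.traits = T
        else:
            self.traits = pd.DataFrame({"Intercept": np.ones(len(self.species))}, index=self.species)
        if random_ids is not None:
            codes, uniques = pd.factorize(np.asarray(random_ids))
            self.block_idx, self.blocks = codes, list(uniques)
        else:
            self.block_idx, self.blocks = None, []

    # ------------------------------------------------------------------

    def fit(
        self,
        chains: int = 4,
        samples: int = 250,
        transient: int = 250,
        thin: int = 1,
        seed: int = 0,
        spec: JSDMSpec | None = None,
    ) -> "JSDMResults":
        if spec is not None:
            chains, samples = spec.chains, spec.samples
            transient, thin = spec.transient, spec.thin
        n, S = self.Y.shape
        p = self.X.shape[1]
        t = self.traits.shape[1]
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(chains)]
        chain_draws = [
            self._run_chain(samples, transient, thin, s) for s in seeds
        ]
        beta = np.stack([c["beta"] for c in chain_draws])       # C x D x p x S
        gamma = np.stack([c["gamma"] for c in chain_draws])     # C x D x t x p
        sig2 = np.stack([c["sig2"] for c in chain_draws]) if chain_draws[0]["sig2"] is not None else None
        sigB2 = np.stack([c["sigB2"] for c in chain_draws]) if chain_draws[0]["sigB2"] is not None else None
        names: list[str] = []
        flat = []
        for k, term in enumerate(self.term_names):
            for j, sp in enumerate(self.species):
                names.append(f"beta[{sp},{term}]")
                flat.append(beta[:, :, k, j])
        for a, tr in enumerate(self.traits.columns):
            for k, term in enumerate(self.term_names):
                names.append(f"gamma[{tr},{term}]")
                flat.append(gamma[:, :, a, k])
        if sig2 is not None:
            for j, sp in enumerate(self.species):
                names.append(f"sigma2[{sp}]")
                flat.append(sig2[:, :, j])
        if sigB2 is not None:
            names.append(f"sigmaB2")
            flat.append(sigB2)
        draws = PosteriorDraws(np.stack(flat, axis=2), names)
        return JSDMResults(self, draws, beta=beta, gamma=gamma, seed=seed)

    # ------------------------------------------------------------------

    def _prepare_response(self):
        """Family-specific observed structures for the sampler."""
        Yv = self.Y.to_numpy(float)
        if self.family == "lognormal_poisson":
            return {"counts": Yv}
        if self.family == "hurdle_probit":
            return {"present": Yv > 0}
        # hurdle_lognormal: z-scored log counts on present cells
        present = Yv > 0
        with np.errstate(divide="ignore"):
            logged = np.where(present, np.log(Yv, where=present, out=np.zeros_like(Yv)), np.nan)
        mean = np.nanmean(np.where(present, logged, np.nan), axis=0)
        sd = np.nanstd(np.where(present, logged, np.nan), axis=0)
        sd = np.where((sd == 0) | ~np.isfinite(sd), 1.0, sd)
        zed = (logged - mean) / sd
        return {"present": present, "z": np.where(present, zed, 0.0)}

    def _run_chain(self, samples: int, transient: int, thin: int, seed: int) -> dict:
        rng = np.random.default_rng(seed)
        n, S = self.Y.shape
        p = self.X.shape[1]
        Tm = self.traits.to_numpy(float)
        t = Tm.shape[1]
        X = self.X
        data = self._prepare_response()
        family = self.family
        has_blocks = self.block_idx is not None
        B = len(self.blocks) if has_blocks else 0

        # hyperpriors (weakly informative)
        g_prior_var = 100.0
        a_tau, b_tau = 2.0, 1.0
        a_sig, b_sig = 2.0, 1.0
        a_B, b_B = 2.0, 0.25

        # initial values (chain-specific jitter for dispersion diagnostics)
        if family == "lognormal_poisson":
            resp = np.log(data["counts"] + 0.5)
        elif family == "hurdle_probit":
            resp = np.where(data["present"], 1.0, -1.0)
        else:
            resp = data["z"]
        beta = np.linalg.lstsq(X, resp, rcond=None)[0] + rng.normal(0, 0.25, size=(p, S))
        gamma = np.zeros((t, p))
        tau2 = np.ones(p)
        sig2 = np.ones(S)
        a_blk = np.zeros((B, S)) if has_blocks else None
        sigB2 = 0.1
        if family == "lognormal_poisson":
            eta = resp.copy()
            step = np.full(S, 0.5)
            acc = np.zeros(S)
            counts = data["counts"]
        if family.startswith("hurdle"):
            present = data["present"]
        if family == "hurdle_lognormal":
            rows = [np.flatnonzero(present[:, j]) for j in range(S)]
            Xj = [X[r] for r in rows]
            XtXj = [x.T @ x for x in Xj]
            yj = [data["z"][rows[j], j] for j in range(S)]
            blkj = [self.block_idx[rows[j]] if has_blocks else None for j in range(S)]

        total = transient + samples * thin
        keep_beta = np.empty((samples, p, S))
        keep_gamma = np.empty((samples, t, p))
        keep_sig2 = np.empty((samples, S)) if family != "hurdle_probit" else None
        keep_sigB2 = np.empty(samples) if has_blocks else None
        kept = 0

        XtX = X.T @ X

        for it in range(total):
            mu_lin = X @ beta  # n x S
            if has_blocks and family != "hurdle_lognormal":
                ablock = a_blk[self.block_idx]
                mu_full = mu_lin + ablock
            else:
                mu_full = mu_lin

            if family == "lognormal_poisson":
                # adaptive MH on the latent log-means
                prop = eta + rng.normal(0, 1, size=eta.shape) * step[None, :]
                ll_new = counts * prop - np.exp(np.clip(prop, -30, 30))
                ll_old = counts * eta - np.exp(np.clip(eta, -30, 30))
                pr_new = -0.5 * (prop - mu_full) ** 2 / sig2[None, :]
                pr_old = -0.5 * (eta - mu_full) ** 2 / sig2[None, :]
                accept = np.log(rng.random(eta.shape)) < (ll_new + pr_new - ll_old - pr_old)
                eta = np.where(accept, prop, eta)
                acc += accept.mean(axis=0)
                if it < transient and (it + 1) % 50 == 0:
                    rate = acc / 50.0
                    step *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
                    step = np.clip(step, 0.02, 5.0)
                    acc[:] = 0.0
                work = eta
                res_var = sig2
            elif family == "hurdle_probit":
                work = _sample_truncnorm(rng, mu_full, present)
                res_var = np.ones(S)
            else:
                work = None  # per-species responses
                res_var = sig2

            # beta | rest (conjugate normal), species by species
            mu_beta = Tm @ gamma  # S x p expected coefficients
            for j in range(S):
                if family == "hurdle_lognormal":
                    r = rows[j]
                    if r.size == 0:
                        beta[:, j] = mu_beta[j] + rng.normal(0, np.sqrt(tau2))
                        continue
                    Xl, XtXl = Xj[j], XtXj[j]
                    y_res = yj[j] - (a_blk[blkj[j], j] if has_blocks else 0.0)
                    prec = XtXl / sig2[j] + np.diag(1.0 / tau2)
                    rhs = Xl.T @ y_res / sig2[j] + mu_beta[j] / tau2
                else:
                    y_res = work[:, j] - (a_blk[self.block_idx, j] if has_blocks else 0.0)
                    prec = XtX / res_var[j] + np.diag(1.0 / tau2)
                    rhs = X.T @ y_res / res_var[j] + mu_beta[j] / tau2
                L = np.linalg.cholesky(prec)
                m = np.linalg.solve(prec, rhs)
                beta[:, j] = m + np.linalg.solve(L.T, rng.normal(size=p))

            # block random intercepts and their variance
            if has_blocks:
                for j in range(S):
                    if family == "hurdle_lognormal":
                        r, Xl = rows[j], Xj[j]
                        if r.size == 0:
                            a_blk[:, j] = rng.normal(0, np.sqrt(sigB2), size=B)
                            continue
                        resid = yj[j] - Xl @ beta[:, j]
                        bidx = blkj[j]
                    else:
                        resid = work[:, j] - X @ beta[:, j]
                        bidx = self.block_idx
                    ssum = np.bincount(bidx, weights=resid, minlength=B)
                    cnt = np.bincount(bidx, minlength=B)
                    v = 1.0 / (cnt / res_var[j] + 1.0 / sigB2)
                    m = v * ssum / res_var[j]
                    a_blk[:, j] = m + np.sqrt(v) * rng.normal(size=B)
                sigB2 = 1.0 / rng.gamma(a_B + 0.5 * B * S, 1.0 / (b_B + 0.5 * np.sum(a_blk**2)))

            # residual variances
            if family == "lognormal_poisson":
                resid = eta - X @ beta - (a_blk[self.block_idx] if has_blocks else 0.0)
                sig2 = 1.0 / rng.gamma(a_sig + 0.5 * n, 1.0 / (b_sig + 0.5 * np.sum(resid**2, axis=0)))
            elif family == "hurdle_lognormal":
                for j in range(S):
                    r = rows[j]
                    if r.size == 0:
                        sig2[j] = 1.0 / rng.gamma(a_sig, 1.0 / b_sig)
                        continue
                    resid = yj[j] - Xj[j] @ beta[:, j] - (a_blk[blkj[j], j] if has_blocks else 0.0)
                    sig2[j] = 1.0 / rng.gamma(a_sig + 0.5 * r.size, 1.0 / (b_sig + 0.5 * np.sum(resid**2)))

            # trait projection gamma and term-level shrinkage tau2
            TtT = Tm.T @ Tm
            for k in range(p):
                prec = TtT / tau2[k] + np.eye(t) / g_prior_var
                rhs = Tm.T @ beta[k, :] / tau2[k]
                L = np.linalg.cholesky(prec)
                m = np.linalg.solve(prec, rhs)
                gamma[:, k] = m + np.linalg.solve(L.T, rng.normal(size=t))
                dev = beta[k, :] - Tm @ gamma[:, k]
                tau2[k] = 1.0 / rng.gamma(a_tau + 0.5 * S, 1.0 / (b_tau + 0.5 * np.sum(dev**2)))

            if it >= transient and (it - transient) % thin == 0:
                keep_beta[kept] = beta
                keep_gamma[kept] = gamma
                if keep_sig2 is not None:
                    keep_sig2[kept] = sig2
                if keep_sigB2 is not None:
                    keep_sigB2[kept] = sigB2
                kept += 1

        return {
            "beta": keep_beta,
            "gamma": keep_gamma,
            "sig2": keep_sig2,
            "sigB2": keep_sigB2,
        }


class JSDMResults:
    """Posterior draws plus support classification, PSRF and variance partitioning."""

    def __init__(self, model: JointSpeciesModel, draws: PosteriorDraws, beta: np.ndarray, gamma: np.ndarray, seed: int):
        self.model = model
        self.draws = draws
        self._beta = beta    # chains x draws x p x S
        self._gamma = gamma  # chains x draws x t x p
        self.seed = seed

    @property
    def beta_mean(self) -> pd.DataFrame:
        m = self._beta.mean(axis=(0, 1))  # p x S
        return pd.DataFrame(m.T, index=self.model.species, columns=self.model.term_names)

    @property
    def gamma_mean(self) -> pd.DataFrame:
        m = self._gamma.mean(axis=(0, 1))
        return pd.DataFrame(m, index=self.model.traits.columns, columns=self.model.term_names)

    def psrf(self) -> pd.Series:
        return psrf(self.draws)

    def check_convergence(self, threshold: float = 1.2) -> None:
        """Refuse downstream use when any parameter's R-hat exceeds the threshold."""
        r = self.psrf()
        worst = r.max()
        if worst > threshold:
            bad = r.idxmax()
            raise RuntimeError(
                f"MCMC not converged: max R-hat {worst:.3f} ({bad}) > {threshold}"
            )

    def support(self, level: float = 0.95) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Sign-probability classification of every species x term coefficient.

        Returns (classification, P(beta > 0)); classification is 'positive'
        when P(beta > 0) >= level, 'negative' when P(beta < 0) >= level and
        'neutral' otherwise.
        """
        flat = self._beta.reshape(-1, *self._beta.shape[2:])  # (C*D) x p x S
        p_pos = (flat > 0).mean(axis=0).T   # S x p
        prob = pd.DataFrame(p_pos, index=self.model.species, columns=self.model.term_names)
        cls = pd.DataFrame("neutral", index=prob.index, columns=prob.columns)
        cls = cls.mask(prob >= level, "positive").mask(1.0 - prob >= level, "negative")
        return cls, prob

    def variance_partition(self, term_groups: Mapping[str, Sequence[str]] | None = None) -> pd.DataFrame:
        return variance_partition(self, self.model.X, term_groups)

    def summary(self) -> str:
        r = self.psrf()
        cls, _ = self.support()
        n_pos = int((cls == "positive").to_numpy().sum())
        n_neg = int((cls == "negative").to_numpy().sum())
        return (
            f"jSDM ({self.model.family}): {len(self.model.species)} species, "
            f"{self.draws.n_chains} chains x {self.draws.n_samples} = {self.draws.n_total} draws\n"
            f"max R-hat {r.max():.3f}; supported responses: {n_pos} positive, {n_neg} negative"
        )


def fit_jsdm(Y, X, T=None, random_ids=None, spec: JSDMSpec | None = None, seed: int = 0) -> JSDMResults:
    """Build and fit a jSDM in one call (see :class:`JointSpeciesModel`)."""
    spec = spec or JSDMSpec()
    model = JointSpeciesModel(Y, X, traits=T, random_ids=random_ids, family=spec.family)
    return model.fit(spec=spec, seed=seed)


def psrf(draws: PosteriorDraws | np.ndarray) -> pd.Series:
    """Gelman–Rubin potential scale reduction factor per parameter.

    R-hat = sqrt((W + var(chain means)) / W) with W the mean within-chain
    variance; identical chains give exactly 1 and well-separated chains give
    values far above 1.2.  Requires at least two chains.
    """
    if isinstance(draws, PosteriorDraws):
        arr, names = draws.array, draws.names
    else:
        arr = np.asarray(draws, float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        names = [f"p{i}" for i in range(arr.shape[2])]
    if arr.shape[0] < 2:
        raise ValueError("PSRF requires at least two chains")
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    Bn = arr.mean(axis=1).var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt((W + Bn) / W)
    r = np.where(W == 0, np.where(Bn == 0, 1.0, np.inf), r)
    return pd.Series(r, index=names)


def classify_support(draws: PosteriorDraws, level: float = 0.95, prefix: str = "beta[") -> pd.Series:
    """Classify each named coefficient by posterior sign probability."""
    out = {}
    for name in draws.names:
        if not name.startswith(prefix):
            continue
        flat = draws.flat(name)
        p_pos = float((flat > 0).mean())
        if p_pos >= level:
            out[name] = "positive"
        elif 1 - p_pos >= level:
            out[name] = "negative"
        else:
            out[name] = "neutral"
    return pd.Series(out)


def default_term_groups(term_names: Sequence[str]) -> dict[str, list[str]]:
    """Treatment vs natural grouping of fixed-effect columns (intercept excluded)."""
    treatment = [c for c in term_names if "treatment[" in c]
    natural = [c for c in term_names if c != "Intercept" and c not in treatment]
    return {"treatment": treatment, "natural": natural}


def variance_partition(
    results: JSDMResults,
    X: np.ndarray | None = None,
    term_groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Share of explained variance per species attributed to term groups.

    Uses the posterior-mean coefficients: each group's contribution is the
    variance over the design of its partial linear predictor (within-group
    covariance only), plus the random-intercept variance as its own group;
    shares are normalised to sum to one per species.
    """
    model = results.model
    X = model.X if X is None else np.asarray(X, float)
    term_names = model.term_names
    groups = dict(term_groups) if term_groups is not None else default_term_groups(term_names)
    seen: set[str] = set()
    for g, cols in groups.items():
        overlap = seen.intersection(cols)
        if overlap:
            raise ValueError(f"term groups overlap on {sorted(overlap)}")
        unknown = [c for c in cols if c not in term_names]
        if unknown:
            raise ValueError(f"unknown terms in group {g!r}: {unknown}")
        seen.update(cols)
    beta = results.beta_mean  # species x terms
    parts = {}
    for g, cols in groups.items():
        idx = [term_names.index(c) for c in cols]
        if not idx:
            parts[g] = np.zeros(len(model.species))
            continue
        eta = X[:, idx] @ beta.iloc[:, idx].to_numpy().T  # n x S
        parts[g] = eta.var(axis=0)
    if model.block_idx is not None:
        sigB2 = float(results.draws["sigmaB2"].mean())
        parts["random"] = np.full(len(model.species), sigB2)
    out = pd.DataFrame(parts, index=model.species)
    total = out.sum(axis=1)
    total = total.replace(0.0, np.nan)
    out = out.div(total, axis=0).fillna(0.0)
    return out
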