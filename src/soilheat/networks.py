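"""Collembola–fungi association networks and connectance null-model tests.

For each elevation x season subset of the recovery harvest (20 samples: 2
sites x 5 plots x 2 treatments), fungal conditional log-abundances are
regressed on standardised Collembola abundances and their interactions with
the heat treatment using a conjugate Bayesian ridge (normal-inverse-gamma)
linear model.  Pairs whose 95% equal-tailed credible interval excludes zero
form signed bipartite networks per treatment; connectance (edges / (nC*nF))
is computed separately for positive and negative associations, and
treatment differences in connectance are tested against a null distribution
obtained by permuting treatment labels across the subset's samples — a
label-exchangeability null that preserves every species' marginal
distribution exactly.  Edges are statistical associations, not demonstrated
trophic links.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationSubset",
    "AssociationModel",
    "AssociationResults",
    "SignedBipartiteNetwork",
    "NullModelResult",
    "make_subsets",
    "fit_association_model",
    "extract_network",
    "connectance",
    "connectance_difference_test",
]


@dataclass
class AssociationSubset:
    """One elevation x season slice of a harvest, ready for association fitting.

    ``response`` holds per-fungus log-transformed, z-scored abundances with
    NaN where the fungus is absent (the models are conditional on presence);
    ``predictors`` holds log(x+1) z-scored Collembola abundances
    (standardised within the subset); ``heat`` is the treatment indicator.
    """

    elevation: str
    season: str
    harvest: str
    response: pd.DataFrame      # samples x fungi, NaN where absent
    predictors: pd.DataFrame    # samples x collembola, standardised
    heat: np.ndarray            # 0/1 per sample
    meta: pd.DataFrame
    covariates: pd.DataFrame | None = None  # block indicators, log depth, ...

    @property
    def collembola(self) -> list[str]:
        return list(self.predictors.columns)

    @property
    def fungi(self) -> list[str]:
        return list(self.response.columns)

    @property
    def n_samples(self) -> int:
        return len(self.meta)


@dataclass
class SignedBipartiteNetwork:
    """Signed weighted bipartite network between Collembola and fungi."""

    collembola: list[str]
    fungi: list[str]
    edges: pd.DataFrame  # columns: collembola, fungus, sign, weight
    treatment: str

    def n_edges(self, sign: str | None = None) -> int:
        if sign is None:
            return len(self.edges)
        return int((self.edges["sign"] == sign).sum())

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.collembola, bipartite="collembola")
        g.add_nodes_from(self.fungi, bipartite="fungi")
        for _, e in self.edges.iterrows():
            g.add_edge(e["collembola"], e["fungus"], sign=e["sign"], weight=float(e["weight"]))
        return g


@dataclass
class NullModelResult:
    """Observed connectance difference with its permutation null distribution."""

    observed: float
    null: np.ndarray
    z: float
    p_value: float
    n_null: int
    seed: int
    sign: str
    degenerate: bool = False


def make_subsets(
    study,
    harvest: str = "H3",
    min_fungal_presence: float = 0.25,
    min_collembola_occupancy: int = 3,
    min_predictors: int = 1,
) -> list[AssociationSubset]:
    """Split a study into elevation x season association subsets at one harvest.

    Collembola species must occur in at least ``min_collembola_occupancy``
    samples of a subset to act as predictors; a subset with fewer than
    ``min_predictors`` usable predictors is skipped with a logged reason
    (very low Collembola prevalence makes associations undeterminable).
    Fungi must be present in at least ``min_fungal_presence`` of the
    subset's samples.
    """
    units = study.units
    mask_h = units["harvest"] == harvest
    subsets: list[AssociationSubset] = []
    for elevation in dict.fromkeys(units["elevation"]):
        for season in dict.fromkeys(units["season"]):
            rows = units.index[mask_h & (units["elevation"] == elevation) & (units["season"] == season)]
            if len(rows) == 0:
                continue
            meta = units.loc[rows]
            counts = study.collembola.loc[rows]
            occupancy = (counts > 0).sum(axis=0)
            usable = [c for c in counts.columns if occupancy[c] >= min_collembola_occupancy]
            if len(usable) < min_predictors:
                logger.warning(
                    "skipping subset %s/%s at %s: only %d Collembola species with occupancy >= %d",
                    elevation, season, harvest, len(usable), min_collembola_occupancy,
                )
                continue
            logged = np.log1p(counts[usable])
            sd = logged.std(ddof=0)
            keep = sd[sd > 0].index
            if len(keep) < len(usable):
                logger.warning("dropping zero-variance predictors in %s/%s: %s",
                               elevation, season, sorted(set(usable) - set(keep)))
            if len(keep) < min_predictors:
                logger.warning("skipping subset %s/%s: no non-degenerate predictors", elevation, season)
                continue
            Z = (logged[keep] - logged[keep].mean()) / logged[keep].std(ddof=0)
            reads = study.fungal_reads.loc[rows]
            present = reads > 0
            min_n = int(np.ceil(min_fungal_presence * len(rows)))
            fungi = [f for f in reads.columns if present[f].sum() >= min_n]
            with np.errstate(divide="ignore"):
                logreads = np.log(reads[fungi].where(present[fungi]))
            mean, sd_f = logreads.mean(), logreads.std(ddof=0)
            sd_f = sd_f.replace(0.0, 1.0)
            response = (logreads - mean) / sd_f
            # code heat from the design's treatment ordering: non-first level = heat
            levels = list(dict.fromkeys(units["treatment"]))
            heat = (meta["treatment"] == levels[-1]).to_numpy(float)
            # block indicators and scaled log depth absorb shared-environment
            # and sequencing-depth structure that would otherwise masquerade
            # as cross-trophic association
            cov = pd.get_dummies(meta["block"], drop_first=True).astype(float)
            cov.columns = [f"block[{c}]" for c in cov.columns]
            depths = getattr(study, "depths", None)
            if depths is not None:
                ld = np.log(depths.loc[rows].to_numpy(float))
                sd_d = ld.std()
                cov["log_depth"] = (ld - ld.mean()) / (sd_d if sd_d > 0 else 1.0)
            subsets.append(
                AssociationSubset(
                    elevation=elevation, season=season, harvest=harvest,
                    response=response, predictors=Z, heat=heat, meta=meta,
                    covariates=cov if cov.shape[1] else None,
                )
            )
    return subsets


class AssociationModel:
    """Conjugate Bayesian linear association model for one subset.

    Per fungus f (on its present samples):

        y_f = a + b_heat * heat + sum_c beta_cf z_c + sum_c delta_cf (z_c * heat) + eps

    with conjugate ridge prior beta | sigma^2 ~ N(0, sigma^2 g I) and
    sigma^2 ~ InvGamma(a0, b0).  The control association of pair (c, f) is
    beta_cf and the heat association beta_cf + delta_cf; their posterior
    marginals are Student-t and evaluated analytically, which keeps the
    permutation null model cheap.
    """

    def __init__(self, subset: AssociationSubset, prior_scale: float = 1.0, a0: float = 2.0, b0: float = 1.0):
        self.subset = subset
        self.g = float(prior_scale) ** 2
        self.a0, self.b0 = float(a0), float(b0)
        self._Z = subset.predictors.to_numpy(float)
        self._Y = subset.response.to_numpy(float)  # NaN where absent
        self._ok = np.isfinite(self._Y)

    def fit(self, heat: np.ndarray | None = None) -> "AssociationResults":
        sub = self.subset
        heat = sub.heat if heat is None else np.asarray(heat, float)
        Z = self._Z
        n, nC = Z.shape
        nF = self._Y.shape[1]
        cov = (
            sub.covariates.to_numpy(float)
            if sub.covariates is not None
            else np.empty((n, 0))
        )
        X = np.column_stack([np.ones(n), heat, cov, Z, Z * heat[:, None]])
        p = X.shape[1]
        base = 2 + cov.shape[1]
        prior_prec = np.eye(p) / self.g
        means = np.empty((p, nF))
        ctrl_var = np.empty((nC, nF))
        heat_var = np.empty((nC, nF))
        heat_mean = np.empty((nC, nF))
        dfs = np.empty(nF)
        scale2 = np.empty(nF)  # posterior b_n / a_n
        sl = slice(base, base + nC)
        il = slice(base + nC, base + 2 * nC)
        for f in range(nF):
            ok = self._ok[:, f]
            Xf = X[ok]
            yf = self._Y[ok, f]
            P = Xf.T @ Xf + prior_prec
            V = np.linalg.inv(P)
            m = V @ (Xf.T @ yf)
            a_n = self.a0 + 0.5 * ok.sum()
            b_n = max(self.b0 + 0.5 * float(yf @ yf - m @ P @ m), 1e-12)
            means[:, f] = m
            ctrl_var[:, f] = np.diag(V)[sl]
            heat_var[:, f] = np.diag(V)[sl] + np.diag(V)[il] + 2 * np.diag(V[sl, il])
            heat_mean[:, f] = m[sl] + m[il]
            dfs[f] = 2 * a_n
            scale2[f] = b_n / a_n
        return AssociationResults(
            self,
            ctrl_mean=means[sl],
            ctrl_scale=np.sqrt(np.maximum(ctrl_var, 0.0) * scale2),
            heat_mean=heat_mean,
            heat_scale=np.sqrt(np.maximum(heat_var, 0.0) * scale2),
            dfs=dfs,
        )


class AssociationResults:
    """Posterior association coefficients per (collembolan, fungus, treatment).

    Marginal posteriors are Student-t; means, scales and degrees of freedom
    are stored as (collembola x fungi) arrays so credible-interval filtering
    stays cheap inside the permutation null model.
    """

    def __init__(self, model, ctrl_mean, ctrl_scale, heat_mean, heat_scale, dfs):
        self.model = model
        self.subset = model.subset
        self._mean = {"control": ctrl_mean, "extreme_heat": heat_mean}
        self._scale = {"control": ctrl_scale, "extreme_heat": heat_scale}
        self._df = dfs  # per fungus

    def _bounds(self, treatment: str, level: float):
        tq = stats.t.ppf(0.5 + level / 2, self._df)[None, :]
        m, s = self._mean[treatment], self._scale[treatment]
        return m - tq * s, m + tq * s

    def edge_signs(self, treatment: str, level: float = 0.95) -> np.ndarray:
        """+1 / -1 / 0 matrix (collembola x fungi) from CI-excludes-zero filtering."""
        lo, hi = self._bounds(treatment, level)
        return np.where(lo > 0, 1, np.where(hi < 0, -1, 0))

    def coefficient_table(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean and equal-tailed CI for every pair and treatment."""
        sub = self.subset
        rows = []
        for treatment in ("control", "extreme_heat"):
            lo, hi = self._bounds(treatment, level)
            m = self._mean[treatment]
            for ci, c in enumerate(sub.collembola):
                for fi, f in enumerate(sub.fungi):
                    rows.append(
                        {
                            "collembola": c, "fungus": f, "treatment": treatment,
                            "mean": m[ci, fi], "ci_lo": lo[ci, fi], "ci_hi": hi[ci, fi],
                        }
                    )
        return pd.DataFrame(rows)

    def network(self, treatment: str, level: float = 0.95) -> SignedBipartiteNetwork:
        """Edges whose equal-tailed CI at ``level`` excludes zero."""
        sub = self.subset
        signs = self.edge_signs(treatment, level)
        m = self._mean[treatment]
        idx = np.argwhere(signs != 0)
        edges = pd.DataFrame(
            {
                "collembola": [sub.collembola[i] for i, _ in idx],
                "fungus": [sub.fungi[j] for _, j in idx],
                "sign": ["positive" if signs[i, j] > 0 else "negative" for i, j in idx],
                "weight": [m[i, j] for i, j in idx],
            }
        )
        return SignedBipartiteNetwork(
            collembola=sub.collembola, fungi=sub.fungi, edges=edges, treatment=treatment
        )


def fit_association_model(subset: AssociationSubset, prior_scale: float = 1.0) -> AssociationResults:
    """Fit the subset's Bayesian association model (conjugate ridge)."""
    return AssociationModel(subset, prior_scale=prior_scale).fit()


def extract_network(results: AssociationResults, level: float = 0.95) -> dict[str, SignedBipartiteNetwork]:
    """Signed bipartite network per treatment at the given credible level."""
    return {t: results.network(t, level) for t in ("control", "extreme_heat")}


def connectance(network: SignedBipartiteNetwork, sign: str) -> float:
    """Edges of the given sign divided by all possible links nC * nF."""
    nC, nF = len(network.collembola), len(network.fungi)
    if nC == 0 or nF == 0:
        raise ValueError("connectance undefined for an empty node set")
    return network.n_edges(sign) / (nC * nF)


def _connectance_difference(results: AssociationResults, sign: str, level: float) -> float:
    s = 1 if sign == "positive" else -1
    heat = results.edge_signs("extreme_heat", level)
    ctrl = results.edge_signs("control", level)
    n_pairs = heat.size
    return (float(np.sum(heat == s)) - float(np.sum(ctrl == s))) / n_pairs


def connectance_difference_test(
    subset: AssociationSubset,
    sign: str = "negative",
    n_null: int = 999,
    seed: int = 0,
    level: float = 0.95,
    prior_scale: float = 1.0,
    alternative: str = "greater",
) -> NullModelResult:
    """Permutation test of the heat-minus-control connectance difference.

    The null replicates permute the treatment labels across the subset's
    samples and re-run the full fit -> CI-filter -> connectance pipeline.
    p uses the add-one convention, one-sided toward a connectance increase
    by default ('two-sided' uses |d|).
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    model = AssociationModel(subset, prior_scale=prior_scale)
    observed = _connectance_difference(model.fit(), sign, level)
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for b in range(n_null):
        perm = rng.permutation(subset.heat)
        null[b] = _connectance_difference(model.fit(heat=perm), sign, level)
    sd = float(null.std(ddof=1))
    degenerate = sd == 0.0
    z = float("nan") if degenerate else (observed - float(null.mean())) / sd
    if alternative == "greater":
        exceed = int(np.sum(null >= observed))
    elif alternative == "two-sided":
        exceed = int(np.sum(np.abs(null - null.mean()) >= abs(observed - null.mean())))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    p = (1 + exceed) / (1 + n_null)
    if degenerate:
        warnings.warn("null distribution has zero spread; z undefined, p from exceedance count")
    return NullModelResult(
        observed=float(observed), null=null, z=z, p_value=float(p),
        n_null=n_null, seed=seed, sign=sign, degenerate=degenerate,
    )
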