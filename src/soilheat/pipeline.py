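"""Per-harvest analysis pipeline: abundance models, diversity, jSDMs, networks.

Each enabled stage runs separately for every harvest (baseline H1,
resistance H2, recovery H3, following the study's convention of fitting all
models per harvest); failures in one stage are collected and reported
without suppressing the others, and every result records the harvest and
seed that produced it.
"""

from __future__ import annotations

import dataclasses
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import diversity as dv
from .design import build_model_matrix
from .io import StudyBundle, config_hash
from .jsdm import JSDMSpec, JointSpeciesModel, prevalence_filter
from .mixed import GaussianMixedModel, NegativeBinomialMixedModel
from .networks import connectance_difference_test, extract_network, fit_association_model, make_subsets

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

FACTORS = ("elevation", "season", "treatment")


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run; defaults mirror the study's choices."""

    seed: int = 0
    stages: tuple[str, ...] = ("abundance", "diversity", "jsdm", "networks")
    harvests: tuple[str, ...] | None = None          # None = all in the data
    jsdm_harvests: tuple[str, ...] = ("H2", "H3")    # resistance and recovery
    network_harvest: str = "H3"
    prevalence_threshold: float = 0.25
    support_level: float = 0.95
    q_orders: tuple[float, ...] = (0.0, 1.0, 2.0)
    chains: int = 4
    samples: int = 250
    transient: int = 250
    thin: int = 1
    n_null: int = 999
    psrf_threshold: float = 1.2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    """All pipeline outputs plus provenance and collected stage errors."""

    contrasts: pd.DataFrame | None = None
    diversity: pd.DataFrame | None = None
    diversity_contrasts: pd.DataFrame | None = None
    jsdm_support: dict = field(default_factory=dict)
    jsdm_variance: dict = field(default_factory=dict)
    jsdm_psrf: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    null_tests: pd.DataFrame | None = None
    errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> Path:
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("contrasts", "diversity", "diversity_contrasts", "null_tests"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(directory / f"{name}.csv", index=False)
        for key, df in self.jsdm_support.items():
            df.to_csv(directory / f"jsdm_support_{key}.csv")
        for key, df in self.jsdm_variance.items():
            df.to_csv(directory / f"jsdm_variance_{key}.csv")
        for key, nets in self.networks.items():
            for treatment, net in nets.items():
                net.edges.to_csv(directory / f"network_{key}_{treatment}.csv", index=False)
        meta = {
            "provenance": self.provenance,
            "jsdm_max_psrf": {k: float(v.max()) for k, v in self.jsdm_psrf.items()},
            "errors": self.errors,
        }
        (directory / "run.json").write_text(json.dumps(meta, indent=2, default=str))
        return directory


def _harvest_frames(bundle: StudyBundle, harvests):
    units = bundle.units
    order = harvests or tuple(dict.fromkeys(units["harvest"]))
    for h in order:
        rows = units.index[units["harvest"] == h]
        if len(rows):
            yield h, units.loc[rows]


def _abundance_stage(bundle: StudyBundle, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for harvest, meta in _harvest_frames(bundle, config.harvests):
        mm = build_model_matrix(meta, factors=FACTORS, groups="site")
        responses: dict[str, tuple[np.ndarray, np.ndarray | None]] = {
            "collembola_total": (bundle.collembola.loc[meta.index].sum(axis=1).to_numpy(), None)
        }
        depths = bundle.depths.loc[meta.index].to_numpy(float)
        log_depth = np.log(depths)
        guilds = bundle.fungal_guilds
        for guild in dict.fromkeys(guilds):
            taxa = guilds.index[guilds == guild]
            responses[f"guild:{guild}"] = (
                bundle.fungal_reads.loc[meta.index, taxa].sum(axis=1).to_numpy(),
                log_depth - log_depth.mean(),
            )
        for name, (y, covariate) in responses.items():
            design = mm
            if covariate is not None:
                # sequencing depth enters as an estimated covariate column
                design = dataclasses.replace(
                    mm,
                    matrix=np.column_stack([mm.matrix, covariate]),
                    columns=mm.columns + ["log_depth"],
                )
            try:
                fit_obj = NegativeBinomialMixedModel(y, design.matrix, groups=mm.group_ids,
                                                     exog_names=design.columns, harvest=harvest).fit()
                fit_obj.design = mm  # cell contrasts use the factorial part only
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("abundance fit failed for %s at %s: %s", name, harvest, exc)
                continue
            for elevation in mm.levels["elevation"]:
                for season in mm.levels["season"]:
                    cell = {"elevation": elevation, "season": season}
                    pc = _percent_change_padded(fit_obj, cell, design, covariate is not None)
                    rows.append(
                        {
                            "harvest": harvest, "response": name,
                            "elevation": elevation, "season": season,
                            "pct_change": pc.percent, "se": pc.se_percent,
                            "delta": pc.delta, "se_delta": pc.se_delta,
                            "ci_lo": pc.ci_low, "ci_hi": pc.ci_high, "p": pc.p_value,
                            "converged": fit_obj.converged,
                        }
                    )
    return pd.DataFrame(rows)


def _percent_change_padded(fit, cell, design, has_covariate):
    """Percent change for a cell; a centred covariate contributes 0 to the contrast."""
    if not has_covariate:
        return fit.percent_change(cell)
    # contrast rows need a trailing zero for the covariate column
    base = fit.design
    L1 = np.append(base.emm_row({**cell, "treatment": base.levels["treatment"][-1]}), 0.0)
    L0 = np.append(base.emm_row({**cell, "treatment": base.levels["treatment"][0]}), 0.0)
    import scipy.stats as st

    b = fit.params.to_numpy()
    V = fit.cov_params.to_numpy()
    L = L1 - L0
    delta = float(L @ b)
    se = float(np.sqrt(max(L @ V @ L, 0.0)))
    z = st.norm.ppf(0.975)
    from .mixed import PercentChange

    return PercentChange(
        delta=delta, se_delta=se,
        percent=100 * np.expm1(delta), se_percent=100 * np.exp(delta) * se,
        ci_low=100 * np.expm1(delta - z * se), ci_high=100 * np.expm1(delta + z * se),
        p_value=float(2 * st.norm.sf(abs(delta) / se)) if se > 0 else 1.0,
        cell=dict(cell), harvest=fit.harvest, link="log",
    )


def _diversity_stage(bundle: StudyBundle, config: PipelineConfig):
    records = []
    for community, matrix in (("collembola", bundle.collembola), ("fungi", bundle.fungal_reads)):
        for harvest, meta in _harvest_frames(bundle, config.harvests):
            sub = matrix.loc[meta.index]
            nonempty = sub.index[sub.sum(axis=1) > 0]
            if len(nonempty) < len(sub):
                logger.warning("%s/%s: dropping %d empty samples from diversity",
                               community, harvest, len(sub) - len(nonempty))
            samples = [sub.loc[u].to_numpy() for u in nonempty]
            if not samples:
                continue
            base = dv.equalise_samples(samples)
            for u, s in zip(nonempty, samples):
                for q in config.q_orders:
                    est = dv.estimate_at_coverage(s, q, base)
                    records.append(
                        {
                            "unit_id": u, "community": community, "harvest": harvest,
                            "q": q, "estimate": est.estimate, "coverage": est.coverage,
                            "mode": est.mode,
                        }
                    )
    table = pd.DataFrame(records)
    # Gaussian LMMs on the point estimates, per community / harvest / q
    rows = []
    for (community, harvest, q), grp in table.groupby(["community", "harvest", "q"]):
        meta = bundle.units.loc[grp["unit_id"]]
        mm = build_model_matrix(meta, factors=FACTORS, groups="site")
        try:
            fit = GaussianMixedModel(grp["estimate"].to_numpy(), mm, harvest=harvest).fit()
        except Exception as exc:  # pragma: no cover
            logger.warning("diversity LMM failed (%s %s q=%s): %s", community, harvest, q, exc)
            continue
        for elevation in mm.levels["elevation"]:
            for season in mm.levels["season"]:
                pc = fit.percent_change({"elevation": elevation, "season": season})
                rows.append(
                    {
                        "community": community, "harvest": harvest, "q": q,
                        "elevation": elevation, "season": season,
                        "difference": pc.delta, "se": pc.se_delta, "p": pc.p_value,
                    }
                )
    return table, pd.DataFrame(rows)


def _jsdm_stage(bundle: StudyBundle, config: PipelineConfig, report: ReportBundle, seed: int) -> None:
    for harvest, meta in _harvest_frames(bundle, config.jsdm_harvests):
        mm = build_model_matrix(meta, factors=FACTORS, groups="block")
        spec_kw = dict(chains=config.chains, samples=config.samples,
                       transient=config.transient, thin=config.thin)
        # Collembola: lognormal-Poisson with vertical-stratification traits
        Yc, cutoff = prevalence_filter(bundle.collembola.loc[meta.index], config.prevalence_threshold)
        if Yc.shape[1]:
            traits = pd.get_dummies(bundle.collembola_traits.loc[Yc.columns]).astype(float)
            res = JointSpeciesModel(Yc, mm, traits=traits, family="lognormal_poisson").fit(
                seed=seed, **spec_kw
            )
            key = f"collembola_{harvest}"
            cls, _ = res.support(config.support_level)
            report.jsdm_support[key] = cls
            report.jsdm_variance[key] = res.variance_partition()
            report.jsdm_psrf[key] = res.psrf()
        # Fungi: hurdle (probit presence + Gaussian conditional abundance)
        Yf, _ = prevalence_filter(bundle.fungal_reads.loc[meta.index], config.prevalence_threshold)
        if Yf.shape[1]:
            traits = pd.get_dummies(bundle.fungal_guilds.loc[Yf.columns]).astype(float)
            log_depth = np.log(bundle.depths.loc[meta.index].to_numpy(float))
            cov = pd.DataFrame({"log_depth": log_depth - log_depth.mean()}, index=meta.index)
            for family, tag in (("hurdle_probit", "occurrence"), ("hurdle_lognormal", "abundance")):
                res = JointSpeciesModel(
                    Yf, mm, traits=traits, family=family, extra_covariates=cov
                ).fit(seed=seed + 1, **spec_kw)
                key = f"fungi_{tag}_{harvest}"
                cls, _ = res.support(config.support_level)
                report.jsdm_support[key] = cls
                report.jsdm_variance[key] = res.variance_partition()
                report.jsdm_psrf[key] = res.psrf()
    for key, r in report.jsdm_psrf.items():
        if float(r.max()) > config.psrf_threshold:
            logger.warning("jSDM %s: max R-hat %.3f exceeds %.2f; interpret with caution",
                           key, float(r.max()), config.psrf_threshold)


def _network_stage(bundle: StudyBundle, config: PipelineConfig, report: ReportBundle, seed: int) -> None:
    subsets = make_subsets(bundle, harvest=config.network_harvest)
    rows = []
    for i, sub in enumerate(subsets):
        key = f"{sub.elevation}_{sub.season}_{sub.harvest}"
        results = fit_association_model(sub)
        report.networks[key] = extract_network(results, config.support_level)
        for sign in ("negative", "positive"):
            nt = connectance_difference_test(
                sub, sign=sign, n_null=config.n_null, seed=seed + i, level=config.support_level
            )
            rows.append(
                {
                    "elevation": sub.elevation, "season": sub.season, "harvest": sub.harvest,
                    "sign": sign, "connectance_diff": nt.observed, "z": nt.z,
                    "p": nt.p_value, "n_null": nt.n_null, "seed": nt.seed,
                }
            )
    report.null_tests = pd.DataFrame(rows)


def run_pipeline(bundle: StudyBundle, config: PipelineConfig | None = None) -> ReportBundle:
    """Run all enabled stages; deterministic given config.seed."""
    config = config or PipelineConfig()
    report = ReportBundle()
    report.provenance = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config_hash(config.to_dict()),
    }
    stage_fns = {
        "abundance": lambda: setattr(report, "contrasts", _abundance_stage(bundle, config)),
        "diversity": lambda: _set_diversity(report, bundle, config),
        "jsdm": lambda: _jsdm_stage(bundle, config, report, config.seed + 100),
        "networks": lambda: _network_stage(bundle, config, report, config.seed + 200),
    }
    for stage in config.stages:
        if stage not in stage_fns:
            report.errors[stage] = "unknown stage"
            continue
        try:
            stage_fns[stage]()
        except Exception:
            report.errors[stage] = traceback.format_exc()
            logger.exception("stage %s failed", stage)
    return report


def _set_diversity(report, bundle, config):
    table, contrasts = _diversity_stage(bundle, config)
    report.diversity = table
    report.diversity_contrasts = contrasts
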