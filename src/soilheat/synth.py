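"""Synthetic study generator mirroring the split-plot heat-event experiment.

The generator draws Collembola counts from a negative-binomial mixed model
with site random intercepts and elevation x season x treatment effects on
the log scale, fungal metabarcoding reads from a probit/lognormal hurdle
with a sequencing-depth effect and block random intercepts, and optionally
plants Collembola -> fungus association structure (a linear shift of fungal
conditional log-abundance by standardised Collembola abundances, with a
treatment interaction).  Every parameter used in generation is retained in
the returned :class:`SyntheticStudy`, so estimators can be tested for
parameter recovery without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignSpec, STUDY_DESIGN, build_model_matrix, enumerate_units, units_to_frame

__all__ = [
    "CollembolaParams",
    "FungalParams",
    "AssociationParams",
    "SyntheticStudy",
    "simulate_collembola",
    "simulate_fungi",
    "simulate_study",
    "default_collembola_params",
    "default_fungal_params",
    "default_association_params",
    "treatment_cell_betas",
    "standardise_collembola",
]

FACTORS = ("elevation", "season", "treatment")


def treatment_cell_betas(
    cell_effects: Mapping[tuple[str, str], float],
    elevations: Sequence[str] = ("high", "low"),
    seasons: Sequence[str] = ("spring", "summer", "autumn"),
    treatment_level: str = "extreme_heat",
) -> dict[str, float]:
    """Convert per-cell heat/control log-ratios into dummy-coded coefficients.

    ``cell_effects[(elevation, season)]`` is the log of the heat:control mean
    ratio in that cell; missing cells default to 0.  The returned mapping
    assigns the treatment main effect and all treatment interactions so the
    coded model reproduces those cell-wise ratios exactly (reference cell =
    first elevation x first season).
    """
    e0, s0 = elevations[0], seasons[0]
    d = {(e, s): float(cell_effects.get((e, s), 0.0)) for e in elevations for s in seasons}
    beta: dict[str, float] = {f"treatment[{treatment_level}]": d[(e0, s0)]}
    for e in elevations[1:]:
        beta[f"elevation[{e}]:treatment[{treatment_level}]"] = d[(e, s0)] - d[(e0, s0)]
    for s in seasons[1:]:
        beta[f"season[{s}]:treatment[{treatment_level}]"] = d[(e0, s)] - d[(e0, s0)]
    for e in elevations[1:]:
        for s in seasons[1:]:
            beta[f"elevation[{e}]:season[{s}]:treatment[{treatment_level}]"] = (
                d[(e, s)] - d[(e0, s)] - d[(e, s0)] + d[(e0, s0)]
            )
    return beta


def _beta_frame(
    species: Sequence[str],
    columns: Sequence[str],
    coeffs: Mapping[str, Mapping[str, float]],
    strict: bool = True,
) -> pd.DataFrame:
    """Species x column coefficient table; unspecified entries are zero.

    ``strict=False`` silently drops coefficients for design columns that do
    not exist (used by the default factories so they degrade gracefully on
    reduced designs).
    """
    beta = pd.DataFrame(0.0, index=list(species), columns=list(columns))
    for sp, colmap in coeffs.items():
        for col, value in colmap.items():
            if col not in beta.columns:
                if strict:
                    raise KeyError(f"unknown design column {col!r}")
                continue
            beta.loc[sp, col] = float(value)
    return beta


@dataclass
class CollembolaParams:
    """Generator parameters for Collembola counts.

    ``beta`` maps each harvest to a species x design-column table of
    log-scale fixed effects (dummy coding, reference cell = spring / high
    elevation / control).  ``k`` is the NB2 size parameter
    (variance = mu + mu^2/k); ``site_sd`` the SD of per-(site, species)
    random intercepts.
    """

    species: list[str]
    trait: dict[str, str]  # epedaphic | hemiedaphic | euedaphic
    beta: dict[str, pd.DataFrame]
    site_sd: float = 0.4
    k: float = 1.5

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError("NB size parameter k must be > 0")
        if self.site_sd < 0:
            raise ValueError("site_sd must be >= 0")


@dataclass
class FungalParams:
    """Generator parameters for fungal reads (hurdle model).

    ``gamma``: probit-scale occurrence coefficients per harvest;
    ``delta``: conditional log-abundance coefficients per harvest.  Reads for
    present taxa are exp(X delta + depth_coef * log depth + block effect +
    noise), rounded; depths are log-normal.
    """

    taxa: list[str]
    guild: dict[str, str]  # saprotroph | pathogen | symbiont | unassigned
    gamma: dict[str, pd.DataFrame]
    delta: dict[str, pd.DataFrame]
    sigma: float = 0.6
    depth_coef: float = 1.0
    depth_log_mean: float = 10.0
    depth_log_sd: float = 0.4
    block_sd_occurrence: float = 0.3
    block_sd_abundance: float = 0.25

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("residual sigma must be > 0")
        if not (self.depth_log_sd >= 0):
            raise ValueError("depth_log_sd must be >= 0")


@dataclass
class AssociationParams:
    """Planted Collembola -> fungus association slopes.

    ``control``: slopes of fungal conditional log-abundance on standardised
    Collembola abundance common to both treatments; ``heat_interaction``:
    additional slopes active only under extreme heat.  Zero matrices give a
    null world with no cross-trophic structure.
    """

    control: pd.DataFrame  # collembola x fungi
    heat_interaction: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.control.index.equals(self.heat_interaction.index) or not self.control.columns.equals(
            self.heat_interaction.columns
        ):
            raise ValueError("control and heat_interaction must share index/columns")
        if not (np.isfinite(self.control.to_numpy()).all() and np.isfinite(self.heat_interaction.to_numpy()).all()):
            raise ValueError("association slopes must be finite")

    @classmethod
    def zeros(cls, collembola: Sequence[str], fungi: Sequence[str]) -> "AssociationParams":
        z = pd.DataFrame(0.0, index=list(collembola), columns=list(fungi))
        return cls(control=z, heat_interaction=z.copy())


@dataclass
class SyntheticStudy:
    """A complete simulated study plus the ground truth that generated it."""

    spec: DesignSpec
    units: pd.DataFrame
    collembola: pd.DataFrame
    collembola_traits: pd.Series
    fungal_reads: pd.DataFrame
    depths: pd.Series
    fungal_guilds: pd.Series
    cparams: CollembolaParams
    fparams: FungalParams
    aparams: AssociationParams
    seed: int

    def __post_init__(self) -> None:
        for mat in (self.collembola, self.fungal_reads):
            if not mat.index.equals(self.units.index):
                raise ValueError("count matrices must be row-aligned with units")


def _harvest_design(units: pd.DataFrame):
    return build_model_matrix(units, factors=FACTORS, groups=None)


def simulate_collembola(
    params: CollembolaParams, units: pd.DataFrame | Sequence, seed: int
) -> pd.DataFrame:
    """Draw the Collembola species x sample count matrix.

    Counts are NB2 with mean exp(X beta + site effect) and size ``k``;
    ``k = inf`` gives the Poisson limit.  Reproducible given ``seed``.
    """
    frame = units if isinstance(units, pd.DataFrame) else units_to_frame(units)
    rng = np.random.default_rng(seed)
    mm = _harvest_design(frame)
    missing = [h for h in frame["harvest"].unique() if h not in params.beta]
    if missing:
        raise KeyError(f"no coefficients for harvests {missing}")
    sites = list(dict.fromkeys(frame["site"]))
    u_site = pd.DataFrame(
        rng.normal(0.0, params.site_sd, size=(len(sites), len(params.species))),
        index=sites,
        columns=params.species,
    )
    eta = np.zeros((len(frame), len(params.species)))
    for harvest, beta in params.beta.items():
        rows = (frame["harvest"] == harvest).to_numpy()
        if not rows.any():
            continue
        b = beta.reindex(index=params.species, columns=mm.columns).fillna(0.0).to_numpy()
        eta[rows] = mm.matrix[rows] @ b.T
    eta += u_site.loc[frame["site"]].to_numpy()
    mu = np.exp(eta)
    if math.isinf(params.k):
        counts = rng.poisson(mu)
    else:
        counts = rng.negative_binomial(params.k, params.k / (params.k + mu))
    return pd.DataFrame(counts, index=frame.index, columns=params.species)


def simulate_fungi(
    params: FungalParams,
    units: pd.DataFrame | Sequence,
    seed: int,
    shift: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw fungal reads (hurdle: probit occurrence, lognormal abundance) and depths.

    ``shift`` (units x taxa) is added to the conditional log-abundance linear
    predictor; :func:`simulate_study` uses it to plant associations.
    """
    frame = units if isinstance(units, pd.DataFrame) else units_to_frame(units)
    rng = np.random.default_rng(seed)
    mm = _harvest_design(frame)
    n, nf = len(frame), len(params.taxa)
    depths = pd.Series(
        np.exp(rng.normal(params.depth_log_mean, params.depth_log_sd, size=n)),
        index=frame.index,
        name="depth",
    )
    blocks = list(dict.fromkeys(frame["block"]))
    b_occ = pd.DataFrame(
        rng.normal(0.0, params.block_sd_occurrence, size=(len(blocks), nf)), index=blocks, columns=params.taxa
    )
    b_ab = pd.DataFrame(
        rng.normal(0.0, params.block_sd_abundance, size=(len(blocks), nf)), index=blocks, columns=params.taxa
    )
    eta_occ = np.zeros((n, nf))
    eta_ab = np.zeros((n, nf))
    for harvest in frame["harvest"].unique():
        rows = (frame["harvest"] == harvest).to_numpy()
        for store, table in ((eta_occ, params.gamma), (eta_ab, params.delta)):
            if harvest not in table:
                raise KeyError(f"no coefficients for harvest {harvest!r}")
            b = table[harvest].reindex(index=params.taxa, columns=mm.columns).fillna(0.0).to_numpy()
            store[rows] = mm.matrix[rows] @ b.T
    eta_occ += b_occ.loc[frame["block"]].to_numpy()
    eta_ab += b_ab.loc[frame["block"]].to_numpy()
    eta_ab += params.depth_coef * np.log(depths.to_numpy())[:, None]
    if shift is not None:
        eta_ab = eta_ab + np.asarray(shift, float)
    present = rng.random((n, nf)) < stats.norm.cdf(eta_occ)
    log_reads = eta_ab + rng.normal(0.0, params.sigma, size=(n, nf))
    reads = np.where(present, np.maximum(np.rint(np.exp(log_reads)), 1).astype(int), 0)
    return pd.DataFrame(reads, index=frame.index, columns=params.taxa), depths


def standardise_collembola(
    counts: pd.DataFrame, units: pd.DataFrame, within: Sequence[str] = ("harvest", "elevation", "season")
) -> pd.DataFrame:
    """log(x+1)-transform then z-score Collembola abundances within design cells.

    This is the predictor transform of the association models; the generator
    applies the same transform so planted slopes are on the estimator's
    scale.  Zero-variance cells map to 0.
    """
    logged = np.log1p(counts)
    keys = units.loc[counts.index, list(within)]
    def _z(g: pd.DataFrame) -> pd.DataFrame:
        sd = g.std(ddof=0)
        return (g - g.mean()) / sd.replace(0.0, np.nan)
    out = logged.groupby([keys[c] for c in within], group_keys=False).apply(_z)
    return out.fillna(0.0).loc[counts.index]


def simulate_study(
    cparams: CollembolaParams,
    fparams: FungalParams,
    aparams: AssociationParams,
    spec: DesignSpec = STUDY_DESIGN,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate a full synthetic study with recoverable cross-trophic structure."""
    if list(aparams.control.index) != list(cparams.species):
        raise ValueError("association rows must match Collembola species")
    if list(aparams.control.columns) != list(fparams.taxa):
        raise ValueError("association columns must match fungal taxa")
    ss = np.random.SeedSequence(seed)
    seed_c, seed_f = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    units = units_to_frame(enumerate_units(spec))
    collembola = simulate_collembola(cparams, units, seed_c)
    z = standardise_collembola(collembola, units)
    heat = (units["treatment"] == spec.treatments[-1]).to_numpy(float)[:, None]
    shift = z.to_numpy() @ aparams.control.to_numpy() + heat * (
        z.to_numpy() @ aparams.heat_interaction.to_numpy()
    )
    reads, depths = simulate_fungi(fparams, units, seed_f, shift=shift)
    return SyntheticStudy(
        spec=spec,
        units=units,
        collembola=collembola,
        collembola_traits=pd.Series(cparams.trait, name="trait"),
        fungal_reads=reads,
        depths=depths,
        fungal_guilds=pd.Series(fparams.guild, name="guild"),
        cparams=cparams,
        fparams=fparams,
        aparams=aparams,
        seed=seed,
    )


# --- default (study-scale) parameter sets -----------------------------------

_COLLEMBOLA = [
    ("Entomobrya nivalis", "epedaphic"),
    ("Lepidocyrtus cyaneus", "epedaphic"),
    ("Sminthurinus aureus", "epedaphic"),
    ("Parisotoma notabilis", "hemiedaphic"),
    ("Folsomia quadrioculata", "hemiedaphic"),
    ("Isotoma viridis", "hemiedaphic"),
    ("Isotomiella minor", "euedaphic"),
    ("Protaphorura pseudovanderdrifti", "euedaphic"),
    ("Mesaphorura macrochaeta", "euedaphic"),
]

# community-wide heat:control log-ratios per harvest and (elevation, season):
# strong spring/summer declines at low elevation immediately after the event,
# with recovery in spring but not in summer.
_HEAT_CELLS = {
    "H1": {},
    "H2": {("low", "spring"): math.log(0.31), ("low", "summer"): math.log(0.23)},
    "H3": {("low", "summer"): math.log(0.24)},
}


def default_collembola_params(spec: DesignSpec = STUDY_DESIGN) -> CollembolaParams:
    """Nine-species community with heat responses concentrated at low elevation.

    Species' heat responses are heterogeneous — rarer species decline more
    steeply than dominants (log-scale multipliers 0.4..1.6) — so extreme heat
    reduces evenness and hence coverage-standardised diversity, not just
    total abundance.  The per-cell multiplier-weighted effects are calibrated
    so the community-total heat:control ratio in each planted cell equals the
    nominal cell value.
    """
    species = [s for s, _ in _COLLEMBOLA]
    trait = dict(_COLLEMBOLA)
    columns = _harvest_design(units_to_frame(enumerate_units(spec))).columns
    intercepts = np.linspace(3.0, 1.0, len(species))
    multipliers = np.linspace(0.4, 1.6, len(species))  # dominants spared, rare species hit
    weights = np.exp(intercepts)

    def _cell_scale(delta: float) -> float:
        """Scalar s with sum_i w_i exp(s * m_i * delta) = exp(delta) * sum_i w_i."""
        if delta == 0.0:
            return 1.0
        from scipy.optimize import brentq

        f = lambda s: np.log(np.sum(weights * np.exp(s * multipliers * delta))) - np.log(
            weights.sum()
        ) - delta
        return float(brentq(f, 1e-6, 10.0))

    beta = {}
    for harvest in spec.harvests:
        cells = _HEAT_CELLS.get(harvest, {})
        scaled = {cell: _cell_scale(d) * d for cell, d in cells.items()}
        coeffs = {}
        for i, sp in enumerate(species):
            shared = treatment_cell_betas(
                {cell: multipliers[i] * d for cell, d in scaled.items()},
                spec.elevations, spec.seasons, spec.treatments[-1],
            )
            coeffs[sp] = {
                "Intercept": intercepts[i],
                "elevation[low]": -0.5,
                "season[summer]": -0.3,
                "season[autumn]": -0.2,
                **shared,
            }
        beta[harvest] = _beta_frame(species, columns, coeffs, strict=False)
    return CollembolaParams(species=species, trait=trait, beta=beta, site_sd=0.4, k=1.5)


_GUILD_PLAN = [("saprotroph", 18), ("pathogen", 8), ("symbiont", 8), ("unassigned", 6)]

# guild-level heat:control log-ratios of conditional relative abundance:
# pathogens rise after summer heat at both elevations during recovery;
# symbionts dip in spring at high elevation right after the event.
_GUILD_HEAT_CELLS = {
    "H2": {"symbiont": {("high", "spring"): math.log(0.35)}},
    "H3": {
        "pathogen": {("low", "summer"): math.log(2.59), ("high", "summer"): math.log(2.14)},
        "symbiont": {("high", "summer"): math.log(2.44)},
        "unassigned": {("low", "spring"): math.log(1.43)},
    },
}


def default_fungal_params(spec: DesignSpec = STUDY_DESIGN, n_taxa: int | None = None) -> FungalParams:
    """~40-taxon fungal community, stable except for guild-level heat shifts."""
    taxa, guild = [], {}
    for g, count in _GUILD_PLAN:
        for i in range(count):
            name = f"{g.capitalize()}_{i + 1:02d}"
            taxa.append(name)
            guild[name] = g
    if n_taxa is not None:
        taxa = taxa[:n_taxa]
        guild = {t: guild[t] for t in taxa}
    columns = _harvest_design(units_to_frame(enumerate_units(spec))).columns
    # occurrence intercepts: prevalence from ~0.35 to ~0.95
    occ0 = np.linspace(-0.4, 1.7, len(taxa))
    # conditional relative abundance intercepts (log scale, relative to depth)
    ab0 = np.linspace(-6.5, -4.0, len(taxa))
    gamma, delta = {}, {}
    for harvest in spec.harvests:
        gcoef, dcoef = {}, {}
        guild_cells = _GUILD_HEAT_CELLS.get(harvest, {})
        for i, t in enumerate(taxa):
            shared = treatment_cell_betas(
                guild_cells.get(guild[t], {}), spec.elevations, spec.seasons, spec.treatments[-1]
            )
            gcoef[t] = {"Intercept": occ0[i], "elevation[low]": 0.2}
            dcoef[t] = {"Intercept": ab0[i], "season[summer]": 0.15, **shared}
        gamma[harvest] = _beta_frame(taxa, columns, gcoef, strict=False)
        delta[harvest] = _beta_frame(taxa, columns, dcoef, strict=False)
    return FungalParams(taxa=taxa, guild=guild, gamma=gamma, delta=delta)


def default_association_params(
    cparams: CollembolaParams | None = None, fparams: FungalParams | None = None
) -> AssociationParams:
    """Negative heat-only Collembola-saprotroph associations, none in control.

    Mirrors the study's finding that extreme heat increased the connectance
    of negative associations, driven by saprotrophic fungi: each saprotroph
    acquires a strong negative association (slope -2 on the standardised
    log-abundance scale) with one of four collembolan species, active only
    under heat.  One consumer per fungus keeps the planted
    slopes identifiable: stacking several strong consumers on one fungus
    would inflate that fungus's response variance and dilute every slope
    after the per-taxon scaling.
    """
    cparams = cparams or default_collembola_params()
    fparams = fparams or default_fungal_params()
    ap = AssociationParams.zeros(cparams.species, fparams.taxa)
    saprotrophs = [t for t in fparams.taxa if fparams.guild[t] == "saprotroph"]
    consumers = [cparams.species[i] for i in (0, 1, 3, 6)]
    for j, f in enumerate(saprotrophs):
        ap.heat_interaction.loc[consumers[j % len(consumers)], f] = -2.0
    return ap
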