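"""Split-plot experimental design: unit enumeration, factorial coding, temperature regimes.

The study layout is a split-plot design with regional blocks, one site per
elevation nested in each block, seasons applied at the plot level, and the
temperature treatment and harvest randomised at the soil-core (sample) level.
The default :class:`DesignSpec` reproduces the field campaign's layout:
2 elevations x 2 sites x 3 seasons x 5 plots x 2 treatments x 3 harvests
= 360 experimental units, 120 per harvest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "SampleUnit",
    "ModelMatrix",
    "TemperatureRegime",
    "enumerate_units",
    "units_to_frame",
    "build_model_matrix",
    "derive_temperature_regimes",
    "STUDY_DESIGN",
]


class InvalidDesignError(ValueError):
    """Raised when a design specification is internally inconsistent."""


@dataclass(frozen=True)
class DesignSpec:
    """Factor levels and nesting counts of the split-plot design.

    Each block contains ``sites_per_block`` sites at every elevation (one in
    the field study).  Plots are nested in site x season; treatment and
    harvest vary at the sample level within a plot.
    """

    n_blocks: int = 2
    sites_per_block: int = 1  # sites per elevation within each block
    elevations: tuple[str, ...] = ("high", "low")
    seasons: tuple[str, ...] = ("spring", "summer", "autumn")
    plots_per_site_season: int = 5
    treatments: tuple[str, ...] = ("control", "extreme_heat")
    harvests: tuple[str, ...] = ("H1", "H2", "H3")

    def __post_init__(self) -> None:
        for name in ("n_blocks", "sites_per_block", "plots_per_site_season"):
            if getattr(self, name) < 1:
                raise InvalidDesignError(f"{name} must be >= 1")
        for name in ("elevations", "seasons", "treatments", "harvests"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise InvalidDesignError(f"{name} must have at least one level")
            if len(set(levels)) != len(levels):
                raise InvalidDesignError(f"duplicate levels in {name}: {levels}")

    @property
    def n_sites(self) -> int:
        """Total number of sites (nested within elevation)."""
        return self.n_blocks * self.sites_per_block * len(self.elevations)

    @property
    def n_units(self) -> int:
        return (
            len(self.elevations)
            * self.n_blocks
            * self.sites_per_block
            * len(self.seasons)
            * self.plots_per_site_season
            * len(self.treatments)
            * len(self.harvests)
        )


STUDY_DESIGN = DesignSpec()


@dataclass(frozen=True)
class SampleUnit:
    """One experimental soil core with its full factor coding."""

    unit_id: str
    block: str
    site: str
    elevation: str
    season: str
    plot: str
    treatment: str
    harvest: str


def enumerate_units(spec: DesignSpec) -> list[SampleUnit]:
    """Enumerate every factor combination of the design exactly once.

    Sites are labelled ``<block>-<elevation>`` (with a numeric suffix when a
    block holds more than one site per elevation) and plots
    ``<site>-<season>-P<k>``, making the nesting explicit in the labels while
    the fields keep it explicit in the data.
    """
    units: list[SampleUnit] = []
    uid = 0
    blocks = [f"B{b + 1}" for b in range(spec.n_blocks)]
    for block, elevation in itertools.product(blocks, spec.elevations):
        for s in range(spec.sites_per_block):
            site = f"{block}-{elevation}" if spec.sites_per_block == 1 else f"{block}-{elevation}-S{s + 1}"
            for season in spec.seasons:
                for p in range(spec.plots_per_site_season):
                    plot = f"{site}-{season}-P{p + 1}"
                    for treatment, harvest in itertools.product(spec.treatments, spec.harvests):
                        uid += 1
                        units.append(
                            SampleUnit(
                                unit_id=f"U{uid:04d}",
                                block=block,
                                site=site,
                                elevation=elevation,
                                season=season,
                                plot=plot,
                                treatment=treatment,
                                harvest=harvest,
                            )
                        )
    return units


def units_to_frame(units: Sequence[SampleUnit]) -> pd.DataFrame:
    """Tabulate units as a metadata frame (one row per experimental unit)."""
    return pd.DataFrame([vars(u) for u in units]).set_index("unit_id", drop=False)


def _dummy_columns(
    frame: pd.DataFrame, factor: str, levels: Sequence[str], reference: str
) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for level in levels:
        if level == reference:
            continue
        cols[f"{factor}[{level}]"] = (frame[factor] == level).to_numpy(float)
    return cols


@dataclass
class ModelMatrix:
    """Fixed-effect design matrix with treatment (dummy) coding.

    ``matrix`` holds one row per unit; the intercept corresponds to the
    reference cell (by default spring, high elevation, control).  ``levels``
    records the ordered levels of every coded factor so that rows for
    arbitrary cells — e.g. for marginal means — can be produced later with
    :meth:`row_for_cell`.
    """

    matrix: np.ndarray
    columns: list[str]
    factors: list[str]
    levels: dict[str, tuple[str, ...]]
    reference: dict[str, str]
    interactions: bool
    group_ids: np.ndarray | None = None
    frame: pd.DataFrame | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row_for_cell(self, cell: Mapping[str, str]) -> np.ndarray:
        """Coded row for a single fully specified factor combination."""
        for f in self.factors:
            if f not in cell:
                raise KeyError(f"cell is missing factor {f!r}")
            if cell[f] not in self.levels[f]:
                raise KeyError(f"unknown level {cell[f]!r} for factor {f!r}")
        frame = pd.DataFrame([{f: cell[f] for f in self.factors}])
        coded = _code_frame(frame, self.factors, self.levels, self.reference, self.interactions)
        return coded[self.columns].to_numpy(float)[0]

    def cell_grid(self, fix: Mapping[str, str] | None = None) -> list[dict[str, str]]:
        """All factor-level combinations, optionally fixing some factors."""
        fix = dict(fix or {})
        free = [f for f in self.factors if f not in fix]
        cells = []
        for combo in itertools.product(*(self.levels[f] for f in free)):
            cell = dict(fix)
            cell.update(dict(zip(free, combo)))
            cells.append(cell)
        return cells

    def emm_row(self, fix: Mapping[str, str]) -> np.ndarray:
        """Row for a marginal-mean cell: averages over factors not in ``fix``."""
        rows = np.stack([self.row_for_cell(c) for c in self.cell_grid(fix)])
        return rows.mean(axis=0)


def _code_frame(
    frame: pd.DataFrame,
    factors: Sequence[str],
    levels: Mapping[str, Sequence[str]],
    reference: Mapping[str, str],
    interactions: bool,
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(frame))}
    per_factor: list[dict[str, np.ndarray]] = []
    for f in factors:
        d = _dummy_columns(frame, f, levels[f], reference[f])
        per_factor.append(d)
        cols.update(d)
    if interactions:
        for order in range(2, len(factors) + 1):
            for combo in itertools.combinations(range(len(factors)), order):
                for named in itertools.product(*(per_factor[i].items() for i in combo)):
                    name = ":".join(n for n, _ in named)
                    value = np.prod(np.stack([v for _, v in named]), axis=0)
                    cols[name] = value
    return pd.DataFrame(cols, index=frame.index)


def build_model_matrix(
    units: Sequence[SampleUnit] | pd.DataFrame,
    factors: Sequence[str] = ("elevation", "season", "treatment"),
    reference: Mapping[str, str] | None = None,
    interactions: bool = True,
    groups: str | None = "site",
) -> ModelMatrix:
    """Dummy-coded fixed-effect matrix for the (by default three-way) factorial.

    Parameters
    ----------
    units
        Sample units or an equivalent metadata frame.
    factors
        Fixed factors to code, in order.  The full-interaction coding of
        E x S x T levels yields E*S*T columns including the intercept.
    reference
        Reference level per factor.  Defaults to the first level encountered
        in the design-spec ordering, which for the default factors is the
        (spring, high elevation, control) cell.
    groups
        Metadata column used as the random-effect grouping vector
        (``site`` or ``block``), or None.
    """
    frame = units if isinstance(units, pd.DataFrame) else units_to_frame(units)
    for f in factors:
        if f not in frame.columns:
            raise KeyError(f"unknown factor {f!r}; available: {list(frame.columns)}")
    # preserve first-appearance order, which follows the DesignSpec tuples
    levels = {f: tuple(dict.fromkeys(frame[f])) for f in factors}
    reference = dict(reference or {})
    for f in factors:
        reference.setdefault(f, levels[f][0])
        if reference[f] not in levels[f]:
            raise KeyError(f"reference level {reference[f]!r} absent from factor {f!r}")
        # reorder levels so the reference comes first
        levels[f] = (reference[f],) + tuple(l for l in levels[f] if l != reference[f])
    coded = _code_frame(frame, factors, levels, reference, interactions)
    group_ids = None
    if groups is not None:
        if groups not in frame.columns:
            raise KeyError(f"unknown grouping column {groups!r}")
        group_ids = frame[groups].to_numpy()
    return ModelMatrix(
        matrix=coded.to_numpy(float),
        columns=list(coded.columns),
        factors=list(factors),
        levels=levels,
        reference=reference,
        interactions=interactions,
        group_ids=group_ids,
        frame=frame,
    )


@dataclass(frozen=True)
class TemperatureRegime:
    """Incubation temperature protocol for one elevation x season context.

    ``ambient_mean`` is the control set-point (mean daily temperature of the
    incubation window); ``extreme_value`` is the heat-event set-point (the
    99th percentile of daily means over the reference climate period),
    applied for ``heat_duration`` consecutive days.  Both regimes run a
    16 h light / 8 h dark diel cycle with a 6 degC day-night amplitude.
    """

    ambient_mean: float
    extreme_value: float
    heat_duration: int = 7
    diel_amplitude: float = 6.0
    photoperiod: tuple[int, int] = (16, 8)

    def __post_init__(self) -> None:
        if self.extreme_value < self.ambient_mean:
            raise InvalidDesignError("extreme_value must be >= ambient_mean")

    def diel_cycle(self, base: float | None = None) -> tuple[float, float]:
        """(day, night) temperatures around ``base`` preserving its 24-h mean.

        With an L-h day and D-h night, day = base + A*D/24*? — concretely the
        split keeps the time-weighted mean equal to ``base`` while the
        day-night difference equals the diel amplitude.
        """
        if base is None:
            base = self.ambient_mean
        light, dark = self.photoperiod
        total = light + dark
        day = base + self.diel_amplitude * dark / total
        night = day - self.diel_amplitude
        return day, night


def derive_temperature_regimes(
    daily_means: pd.Series,
    window_months: Iterable[int],
    percentile: float = 99.0,
    quantile_method: str = "linear",
    heat_duration: int = 7,
    diel_amplitude: float = 6.0,
) -> TemperatureRegime:
    """Derive a temperature regime from a reference-period daily mean series.

    The ambient (control) level is the mean of daily means falling in the
    incubation window's calendar months; the heat-event level is the
    ``percentile`` (default 99th) of daily means over the whole reference
    period.  The percentile interpolation rule is configurable; the default
    interpolates linearly between order statistics.
    """
    values = np.asarray(daily_means, float)
    if values.size == 0:
        raise ValueError("daily_means is empty")
    if not np.all(np.isfinite(values)):
        raise ValueError("daily_means contains non-finite temperatures")
    months = set(int(m) for m in window_months)
    if not months:
        raise ValueError("window_months is empty")
    index = pd.DatetimeIndex(daily_means.index)
    in_window = index.month.isin(sorted(months))
    if not in_window.any():
        raise ValueError(f"no observations in window months {sorted(months)}")
    ambient = float(values[np.asarray(in_window)].mean())
    extreme = float(np.percentile(values, percentile, method=quantile_method))
    extreme = max(extreme, ambient)
    return TemperatureRegime(
        ambient_mean=ambient,
        extreme_value=extreme,
        heat_duration=heat_duration,
        diel_amplitude=diel_amplitude,
    )
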