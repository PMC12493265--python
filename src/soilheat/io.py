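"""CSV round-tripping of study bundles (metadata, counts, traits, depths)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["StudyBundle", "load_study", "write_study", "META_COLUMNS"]

META_COLUMNS = ["unit_id", "block", "site", "elevation", "season", "plot", "treatment", "harvest"]


@dataclass
class StudyBundle:
    """Aligned study tables plus provenance; the pipeline's input container."""

    units: pd.DataFrame
    collembola: pd.DataFrame
    collembola_traits: pd.Series
    fungal_reads: pd.DataFrame
    depths: pd.Series
    fungal_guilds: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.units["unit_id"].duplicated().any():
            dupes = self.units["unit_id"][self.units["unit_id"].duplicated()].tolist()
            raise ValueError(f"duplicate unit_id values: {dupes[:5]}")
        for name, mat in (("collembola", self.collembola), ("fungal_reads", self.fungal_reads)):
            if not mat.index.equals(self.units.index):
                raise ValueError(f"{name} matrix is not row-aligned with metadata")
            arr = mat.to_numpy()
            if (arr < 0).any():
                raise ValueError(f"{name} matrix contains negative counts")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _align(matrix: pd.DataFrame, units: pd.DataFrame, label: str, path) -> pd.DataFrame:
    missing = units.index.difference(matrix.index)
    if len(missing):
        raise ValueError(f"{path}: no {label} row for unit(s) {list(missing[:5])}")
    extra = matrix.index.difference(units.index)
    if len(extra):
        raise ValueError(f"{path}: {label} rows for unknown unit(s) {list(extra[:5])}")
    return matrix.loc[units.index]


def load_study(directory: str | Path) -> StudyBundle:
    """Load and validate a study bundle from its CSV directory.

    Expects metadata.csv, collembola_counts.csv, collembola_traits.csv,
    fungal_reads.csv, fungal_depths.csv and fungal_traits.csv.  Rows are
    re-aligned to metadata order, so shuffled inputs load identically.
    """
    directory = Path(directory)
    meta_path = directory / "metadata.csv"
    units = pd.read_csv(meta_path)
    _require_columns(units, META_COLUMNS, meta_path)
    units = units.set_index("unit_id", drop=False)

    def _matrix(name: str) -> pd.DataFrame:
        path = directory / name
        df = pd.read_csv(path)
        _require_columns(df, ["unit_id"], path)
        return _align(df.set_index("unit_id"), units, name.split(".")[0], path)

    collembola = _matrix("collembola_counts.csv")
    reads = _matrix("fungal_reads.csv")
    depths_df = _matrix("fungal_depths.csv")
    _require_columns(depths_df.reset_index(), ["depth"], directory / "fungal_depths.csv")
    ct = pd.read_csv(directory / "collembola_traits.csv")
    _require_columns(ct, ["species", "trait"], directory / "collembola_traits.csv")
    ft = pd.read_csv(directory / "fungal_traits.csv")
    _require_columns(ft, ["taxon", "guild"], directory / "fungal_traits.csv")
    bundle = StudyBundle(
        units=units,
        collembola=collembola,
        collembola_traits=ct.set_index("species")["trait"],
        fungal_reads=reads,
        depths=depths_df["depth"],
        fungal_guilds=ft.set_index("taxon")["guild"],
        provenance={"source": str(directory)},
    )
    return bundle


def write_study(study, directory: str | Path) -> Path:
    """Write a study (SyntheticStudy or StudyBundle) to CSVs readable by load_study."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study.units[META_COLUMNS].to_csv(directory / "metadata.csv", index=False)
    study.collembola.rename_axis("unit_id").to_csv(directory / "collembola_counts.csv")
    study.fungal_reads.rename_axis("unit_id").to_csv(directory / "fungal_reads.csv")
    study.depths.rename("depth").rename_axis("unit_id").to_csv(directory / "fungal_depths.csv")
    study.collembola_traits.rename("trait").rename_axis("species").to_csv(directory / "collembola_traits.csv")
    study.fungal_guilds.rename("guild").rename_axis("taxon").to_csv(directory / "fungal_traits.csv")
    return directory


def as_bundle(study, seed: int | None = None) -> StudyBundle:
    """View a SyntheticStudy as a StudyBundle without touching disk."""
    return StudyBundle(
        units=study.units,
        collembola=study.collembola,
        collembola_traits=study.collembola_traits,
        fungal_reads=study.fungal_reads,
        depths=study.depths,
        fungal_guilds=study.fungal_guilds,
        provenance={"synthetic_seed": study.seed if seed is None else seed},
    )


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(json.dumps(config_dict, sort_keys=True, default=str).encode()).hexdigest()[:12]
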