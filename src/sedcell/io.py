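"""File I/O, schema validation, run configuration and pipeline orchestration.

All tables are UTF-8 comma-separated CSV with a decimal point; units are
fixed in the column names (``_um``, ``_um3``, ``_fg``, ``_fmol``) and are not
configurable — this eliminates silent unit bugs. The measurement schema is

    cell_id,sample_id,depth_mbsf,modality,length_um,width_um,height_um

with ``height_um`` empty except for AFM rows. Rows with width > length are
canonicalized (larger axis as length) with a logged warning count; schema
violations (missing column, non-numeric cell, non-positive dimension,
missing AFM height) raise :class:`~sedcell.errors.SchemaError` naming the
offending row and column. Values are persisted unrounded; rounding is a
display concern only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import carbon as carbon_mod
from .corrections import CorrectionTable, apply_correction_table, default_correction_table
from .datasets import load_composition_landsort, load_thaa_landsort
from .errors import (
    ConfigurationError,
    DegenerateSampleError,
    SchemaError,
)
from .morphometry import (
    DEFAULT_COCCOID_MAX_AR,
    DEFAULT_FILAMENT_MIN_AR,
    CellMeasurement,
    Modality,
    Morphotype,
    compute_volume_table,
)
from .profile_stats import (
    SampleSummary,
    bootstrap_ci,
    depth_trend_anova,
    summaries_to_frame,
    summarize_sample,
)

__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "write_summary",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("sedcell")

MEASUREMENT_COLUMNS = [
    "cell_id",
    "sample_id",
    "depth_mbsf",
    "modality",
    "length_um",
    "width_um",
    "height_um",
]

_NUMERIC_COLUMNS = ["depth_mbsf", "length_um", "width_um", "height_um"]


def _coerce_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r}, row {row + 2}"
        )
    return out


def read_measurements(path, canonicalize: bool = True, as_objects: bool = False):
    """Read and validate a per-cell measurement CSV.

    Returns a validated DataFrame (unknown columns preserved), or a list of
    :class:`~sedcell.morphometry.CellMeasurement` when ``as_objects``. An
    empty table raises :class:`~sedcell.errors.DegenerateSampleError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DegenerateSampleError(f"{path}: measurement file is empty") from None
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise DegenerateSampleError(f"{path}: measurement file contains no rows")

    for col in _NUMERIC_COLUMNS:
        df[col] = _coerce_numeric(df, col, path)

    modality = df["modality"].astype(str)
    valid = {m.value for m in Modality}
    bad_mod = ~modality.isin(valid)
    if bad_mod.any():
        row = int(np.flatnonzero(bad_mod.to_numpy())[0])
        raise SchemaError(
            f"{path}: unknown modality {modality.iloc[row]!r} in row {row + 2}; "
            f"expected one of {sorted(valid)}"
        )

    for col in ("length_um", "width_um"):
        vals = df[col].to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: column {col!r} must be positive, got {df[col].iloc[row]!r} "
                f"in row {row + 2}"
            )
    depth = df["depth_mbsf"].to_numpy(dtype=float)
    if np.any(~np.isfinite(depth) | (depth < 0)):
        row = int(np.flatnonzero(~np.isfinite(depth) | (depth < 0))[0])
        raise SchemaError(f"{path}: depth_mbsf must be >= 0 in row {row + 2}")

    is_afm = modality.to_numpy() == Modality.AFM.value
    height = df["height_um"].to_numpy(dtype=float)
    missing_h = is_afm & ~np.isfinite(height)
    if missing_h.any():
        row = int(np.flatnonzero(missing_h)[0])
        raise SchemaError(f"{path}: AFM row {row + 2} is missing height_um")
    stray_h = ~is_afm & np.isfinite(height)
    if stray_h.any():
        row = int(np.flatnonzero(stray_h)[0])
        raise SchemaError(
            f"{path}: height_um is only valid for AFM rows, found value in row {row + 2}"
        )
    bad_h = is_afm & (height <= 0)
    if bad_h.any():
        row = int(np.flatnonzero(bad_h)[0])
        raise SchemaError(f"{path}: height_um must be positive in row {row + 2}")

    swapped = df["width_um"].to_numpy() > df["length_um"].to_numpy()
    if swapped.any():
        if not canonicalize:
            row = int(np.flatnonzero(swapped)[0])
            raise SchemaError(f"{path}: width > length in row {row + 2}")
        logger.warning(
            "%s: canonicalized %d row(s) with width > length", path, int(swapped.sum())
        )
        L = df["length_um"].to_numpy(dtype=float)
        W = df["width_um"].to_numpy(dtype=float)
        df["length_um"], df["width_um"] = np.maximum(L, W), np.minimum(L, W)

    if as_objects:
        return [
            CellMeasurement(
                cell_id=str(r.cell_id),
                sample_id=str(r.sample_id),
                depth=float(r.depth_mbsf),
                modality=Modality(r.modality),
                length=float(r.length_um),
                width=float(r.width_um),
                height=float(r.height_um) if np.isfinite(r.height_um) else None,
            )
            for r in df.itertuples()
        ]
    return df


def write_measurements(path, df: pd.DataFrame) -> Path:
    """Write a measurement (or derived) table; lossless at full float precision."""
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_summary(path, summaries: Sequence[SampleSummary]) -> Path:
    """Write per-sample summaries as a long-format CSV."""
    path = Path(path)
    summaries_to_frame(summaries).to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (TOML-serializable)."""

    cells: List[str] = field(default_factory=list)
    thaa: Optional[str] = None
    composition: Optional[str] = None
    abundance: Optional[str] = None
    correction_factors: Optional[str] = None
    coccoid_max_ar: float = DEFAULT_COCCOID_MAX_AR
    filament_min_ar: float = DEFAULT_FILAMENT_MIN_AR
    aa_c_fraction: float = 0.55
    thaa_c_source: str = "composition"
    bootstrap_reps: int = 1000
    seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.aa_c_fraction <= 1.0):
            raise ConfigurationError("aa_c_fraction must be in (0, 1]")
        if self.bootstrap_reps < 100:
            raise ConfigurationError("bootstrap_reps must be >= 100")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for section in ("inputs", "params", "output"):
            flat.update(raw.get(section, {}))
        flat.update({k: v for k, v in raw.items() if not isinstance(v, dict)})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        cfg = cls(**flat)
        # resolve paths relative to the config file
        base = path.parent
        cfg.cells = [str((base / p)) for p in cfg.cells]
        for attr in ("thaa", "composition", "abundance", "correction_factors"):
            val = getattr(cfg, attr)
            if val:
                setattr(cfg, attr, str(base / val))
        cfg.outdir = str(base / cfg.outdir)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _resolve_table(config: RunConfig) -> CorrectionTable:
    if config.correction_factors:
        return CorrectionTable.from_toml(config.correction_factors)
    return default_correction_table()


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Run the full analysis: measure → volume → correct → summarize →
    carbon → density, writing per-stage outputs plus a manifest.

    Deterministic for fixed inputs and seed. On failure, files already
    written by this run are removed before the error propagates. Returns the
    output paths keyed by stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    written: List[Path] = []
    outputs: Dict[str, Path] = {}

    def _emit(name: str, filename: str, writer) -> None:
        path = outdir / filename
        writer(path)
        written.append(path)
        outputs[name] = path

    try:
        if not config.cells:
            raise ConfigurationError("no measurement files configured")
        frames = [read_measurements(p) for p in config.cells]
        cells = pd.concat(frames, ignore_index=True)
        table = _resolve_table(config)

        volumes = compute_volume_table(
            cells, config.coccoid_max_ar, config.filament_min_ar
        )
        corrected = apply_correction_table(volumes, table)
        _emit("volumes", "volumes.csv", lambda p: corrected.to_csv(p, index=False))

        # FM-based summaries feed the carbon density, mirroring the use of
        # corrected FM volumes for the depth profiles.
        fm = corrected[corrected["modality"] == Modality.FM.value]
        summary_source = fm if len(fm) else corrected
        summaries = [
            summarize_sample(g)
            for _, g in summary_source.groupby("sample_id", sort=True)
        ]
        _emit("summary", "summary.csv", lambda p: write_summary(p, summaries))

        profile: dict = {"samples": [], "trends": {}}
        for s in sorted(summaries, key=lambda s: s.depth):
            vols = summary_source.loc[
                summary_source["sample_id"] == s.sample_id, "volume_corrected_um3"
            ].to_numpy()
            lo, hi = bootstrap_ci(
                vols, "mean", n_reps=config.bootstrap_reps, seed=config.seed
            )
            profile["samples"].append(
                {
                    "sample_id": s.sample_id,
                    "depth_mbsf": s.depth,
                    "n_cells": s.n_cells,
                    "fractions": s.fractions,
                    "weighted_mean_volume_um3": s.weighted_mean_volume,
                    "mean_volume_ci95_um3": [lo, hi],
                }
            )
        for morph in Morphotype:
            groups = [
                np.log10(g["volume_corrected_um3"].to_numpy())
                for _, g in summary_source[
                    summary_source["morphotype"] == morph.value
                ].groupby("sample_id", sort=True)
            ]
            groups = [g for g in groups if len(g) >= 2]
            if len(groups) >= 2:
                t = depth_trend_anova(groups)
                profile["trends"][morph.value] = {
                    "F": t.statistic,
                    "df_between": t.df_between,
                    "df_within": t.df_within,
                    "p_value": t.p_value,
                    "transform": "log10",
                }
        _emit(
            "profile",
            "profile.json",
            lambda p: p.write_text(json.dumps(profile, indent=2) + "\n"),
        )

        if config.thaa:
            thaa_df = pd.read_csv(config.thaa)
            comp_df = pd.read_csv(config.composition) if config.composition else None
            result = carbon_mod.carbon_table(
                thaa_df,
                comp_df,
                aa_c_fraction=config.aa_c_fraction,
                thaa_c_source=config.thaa_c_source,
            )
            summary_df = summaries_to_frame(summaries)
            weights = summary_df.drop_duplicates("sample_id")[
                ["depth_mbsf", "weighted_mean_volume_um3"]
            ]
            result = pd.merge_asof(
                result.sort_values("depth_mbsf"),
                weights.sort_values("depth_mbsf"),
                on="depth_mbsf",
                direction="nearest",
                tolerance=1e-6,
            )
            result["carbon_density_fg_um3"] = (
                result["total_c_fg"] / result["weighted_mean_volume_um3"]
            )
            if config.abundance:
                ab = pd.read_csv(config.abundance)[["depth_mbsf", "cells_per_cm3"]]
                result = pd.merge_asof(
                    result.sort_values("depth_mbsf"),
                    ab.sort_values("depth_mbsf"),
                    on="depth_mbsf",
                    direction="nearest",
                    tolerance=1e-6,
                )
                result["sediment_c_ug_cm3"] = carbon_mod.total_sediment_carbon(
                    result["total_c_fg"].to_numpy(), result["cells_per_cm3"].to_numpy()
                )
            _emit("carbon", "carbon.csv", lambda p: result.to_csv(p, index=False))

        manifest = {
            "config": config.to_dict(),
            "correction_factors": table.to_dict(),
            "outputs": {k: p.name for k, p in outputs.items()},
        }
        _emit(
            "manifest",
            "manifest.json",
            lambda p: p.write_text(json.dumps(manifest, indent=2) + "\n"),
        )
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return outputs
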