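"""Synthetic sub-seafloor morphometry studies.

The raw per-cell microscopy tables behind the depth profiles have no public
accession, so this module generates studies with the statistical structure
the analysis assumes, letting every pipeline stage be exercised end to end:

* Cell volumes are lognormal within each sample, with the median declining
  log-linearly in depth between a surface anchor (0.05 µm³ at the shallowest
  sample) and a deep anchor (0.005 µm³ at 60 mbsf) for coccoid/elongated
  cells — an order-of-magnitude decline, with a geometric standard deviation
  of 2 giving roughly an order of magnitude of within-sample spread.
  Filaments follow their own anchors (0.3 → 0.08 µm³) with a narrower spread.
* The morphotype mix defaults to 45% coccoid, 50% elongated, 5% filamentous
  at every depth.
* Dimensions are back-solved from (volume, aspect ratio) under the
  morphotype's shape model (sphere for coccoid, capsule otherwise) so the
  analysis-side volume computation is exactly consistent; aspect ratios are
  drawn uniformly per morphotype (coccoid 1–1.3, elongated 1.3–3,
  filamentous 10–20) independent of volume.
* Observation bias per imaging modality is the exact inverse of the
  correction cascade: observed volume = true volume ÷ composite correction
  factor, dimensions rescaled by its cube root (FM volumes end up inflated —
  the halo dominates; SEM volumes shrunk). Optional lognormal measurement
  noise can be layered on top (off by default, so the correction round-trip
  is exact).
* Per-sample THAA values are anchored to the packaged measured table
  (log-interpolated over depth) with lognormal noise; compositions perturb
  the packaged mole-% rows and renormalize. Cell abundance declines
  log-linearly from 10¹⁰ cells cm⁻³ at the surface to 10⁸ at 60 mbsf.

All randomness flows from a single root seed through per-table derived
streams, so a fixed config and seed reproduce every table bit for bit and
regenerating one table never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .corrections import CorrectionTable, composite_factor, default_correction_table
from .datasets import load_composition_landsort, load_thaa_landsort
from .errors import ConfigurationError
from .morphometry import Modality, Morphotype

__all__ = [
    "GeneratorConfig",
    "generate_true_cells",
    "observe_cells",
    "generate_thaa_profile",
    "generate_abundance_profile",
    "write_study",
]

_DEFAULT_DEPTHS = (0.4, 2.75, 4.32, 9.57, 14.55, 20.53, 38.95, 60.0)

# stream ids for per-table derived rngs
_STREAM_CELLS = 1
_STREAM_THAA = 2
_STREAM_COMPOSITION = 3
_STREAM_ABUNDANCE = 4
_STREAM_NOISE = {Modality.FM: 5, Modality.SEM: 6, Modality.AFM: 7}


@dataclass
class GeneratorConfig:
    """All parameters of a synthetic study; defaults are the study conditions
    the depth profiles describe (see module docstring)."""

    depths: Tuple[float, ...] = _DEFAULT_DEPTHS
    n_cells_per_depth: int = 300
    surface_median_volume: float = 0.05
    deep_median_volume: float = 0.005
    volume_gsd: float = 2.0
    fractions: Mapping[str, float] = field(
        default_factory=lambda: {"coccoid": 0.45, "elongated": 0.50, "filamentous": 0.05}
    )
    filament_surface_median: float = 0.3
    filament_deep_median: float = 0.08
    filament_gsd: float = 1.5
    coccoid_ar_range: Tuple[float, float] = (1.0, 1.3)
    elongated_ar_range: Tuple[float, float] = (1.3, 3.0)
    filament_ar_range: Tuple[float, float] = (10.0, 20.0)
    measurement_noise_gsd: float = 1.0
    thaa_noise_gsd: float = 1.1
    composition_noise: float = 0.10
    abundance_surface: float = 1e10
    abundance_deep: float = 1e8
    abundance_depth_range: Tuple[float, float] = (0.0, 60.0)
    abundance_noise_gsd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.depths) < 1 or any(d < 0 for d in self.depths):
            raise ConfigurationError("depths must be non-negative")
        if list(self.depths) != sorted(self.depths):
            raise ConfigurationError("depths must be increasing")
        if self.n_cells_per_depth < 1:
            raise ConfigurationError("n_cells_per_depth must be >= 1")
        for name in ("surface_median_volume", "deep_median_volume",
                     "filament_surface_median", "filament_deep_median"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.deep_median_volume > self.surface_median_volume:
            raise ConfigurationError("deep volume anchor must not exceed the surface anchor")
        if self.filament_deep_median > self.filament_surface_median:
            raise ConfigurationError("deep filament anchor must not exceed the surface anchor")
        for name in ("volume_gsd", "filament_gsd", "measurement_noise_gsd",
                     "thaa_noise_gsd", "abundance_noise_gsd"):
            if getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} is a geometric sd and must be >= 1")
        fr = {Morphotype(k).value: float(v) for k, v in self.fractions.items()}
        if any(v < 0 for v in fr.values()) or abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ConfigurationError("morphotype fractions must be >= 0 and sum to 1")
        self.fractions = fr
        for name in ("coccoid_ar_range", "elongated_ar_range", "filament_ar_range"):
            lo, hi = getattr(self, name)
            if not (1.0 <= lo <= hi):
                raise ConfigurationError(f"{name} must satisfy 1 <= low <= high")
        if self.composition_noise < 0:
            raise ConfigurationError("composition_noise must be >= 0")

    def _log_interp(self, depth, surface_value: float, deep_value: float,
                    depth_range: Optional[Tuple[float, float]] = None):
        lo, hi = depth_range if depth_range is not None else (self.depths[0], self.depths[-1])
        if hi == lo:
            return np.full_like(np.asarray(depth, dtype=float), surface_value)
        t = np.clip((np.asarray(depth, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
        return 10 ** (np.log10(surface_value) + t * (np.log10(deep_value) - np.log10(surface_value)))

    def median_volume_at(self, depth):
        """Depth-interpolated median volume (µm³) of coccoid/elongated cells."""
        return self._log_interp(depth, self.surface_median_volume, self.deep_median_volume)

    def filament_median_at(self, depth):
        """Depth-interpolated median volume (µm³) of filamentous cells."""
        return self._log_interp(depth, self.filament_surface_median, self.filament_deep_median)

    def sample_ids(self) -> list[str]:
        return [f"S{i:02d}" for i in range(len(self.depths))]


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), int(stream)])


def _backsolve_dimensions(
    volume: np.ndarray, aspect_ratio: np.ndarray, is_coccoid: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Width and length consistent with the analysis shape models.

    Coccoid volumes are spheres on the width: W = (6V/π)^{1/3}, L = AR·W.
    Elongated/filamentous volumes are capsules with L = AR·W:
    V = (π/4)·W³·(AR − 1/3) → W = (4V / (π(AR − 1/3)))^{1/3}.
    """
    W = np.where(
        is_coccoid,
        (6.0 * volume / math.pi) ** (1.0 / 3.0),
        (4.0 * volume / (math.pi * (aspect_ratio - 1.0 / 3.0))) ** (1.0 / 3.0),
    )
    return W, aspect_ratio * W


def generate_true_cells(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw the true (bias-free) cell population of a synthetic study.

    Returns one row per cell: ``sample_id``, ``depth_mbsf``, ``cell_id``,
    ``morphotype``, ``volume_true_um3`` and the true ``length_um``/
    ``width_um`` consistent with the morphotype's shape model. With
    ``volume_gsd = 1`` every volume equals the depth's median (degenerate,
    useful for exactness tests).
    """
    rng = _rng(cfg, _STREAM_CELLS)
    morph_names = [m.value for m in Morphotype]
    probs = np.array([cfg.fractions.get(m, 0.0) for m in morph_names])
    frames = []
    for i, (sid, depth) in enumerate(zip(cfg.sample_ids(), cfg.depths)):
        n = cfg.n_cells_per_depth
        morph_idx = rng.choice(len(morph_names), size=n, p=probs)
        morph = np.array(morph_names, dtype=object)[morph_idx]
        is_fil = morph == Morphotype.FILAMENTOUS.value
        is_cocc = morph == Morphotype.COCCOID.value

        median = np.where(
            is_fil, cfg.filament_median_at(depth), cfg.median_volume_at(depth)
        )
        sigma = np.where(is_fil, math.log(cfg.filament_gsd), math.log(cfg.volume_gsd))
        volume = np.exp(rng.normal(np.log(median), sigma))

        ar = np.empty(n)
        for mask, (lo, hi) in (
            (is_cocc, cfg.coccoid_ar_range),
            (morph == Morphotype.ELONGATED.value, cfg.elongated_ar_range),
            (is_fil, cfg.filament_ar_range),
        ):
            ar[mask] = rng.uniform(lo, hi, size=int(mask.sum()))

        W, L = _backsolve_dimensions(volume, ar, is_cocc)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "depth_mbsf": depth,
                    "cell_id": [f"{sid}C{j:04d}" for j in range(n)],
                    "morphotype": morph,
                    "volume_true_um3": volume,
                    "length_um": L,
                    "width_um": W,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def observe_cells(
    true_cells: pd.DataFrame,
    modality: Modality,
    table: Optional[CorrectionTable] = None,
    cfg: Optional[GeneratorConfig] = None,
) -> pd.DataFrame:
    """Simulate how a modality observes the true cells.

    Observed volume = true volume ÷ composite correction factor for the
    cell's morphotype and the modality; dimensions are rescaled by the cube
    root, so aspect ratios (and hence classification) are preserved. Emits
    the measurement CSV schema consumed by the analysis pipeline (height is
    left empty — FM/SEM measure length and width only). AFM observation is
    not modeled: the generator's shape models carry no independent height.

    If ``cfg.measurement_noise_gsd > 1``, an additional lognormal volume
    error is applied per cell (seeded from the config's root seed).
    """
    modality = Modality(modality)
    if modality is Modality.AFM:
        raise ConfigurationError("observe_cells models FM and SEM observation only")
    if table is None:
        table = default_correction_table()
    comp = {m.value: composite_factor(m, modality, table) for m in Morphotype}
    factors = true_cells["morphotype"].map(comp).to_numpy(dtype=float)
    scale = (1.0 / factors) ** (1.0 / 3.0)
    if cfg is not None and cfg.measurement_noise_gsd > 1.0:
        rng = _rng(cfg, _STREAM_NOISE[modality])
        noise = np.exp(
            rng.normal(0.0, math.log(cfg.measurement_noise_gsd), size=len(true_cells))
        )
        scale = scale * noise ** (1.0 / 3.0)
    return pd.DataFrame(
        {
            "cell_id": true_cells["cell_id"],
            "sample_id": true_cells["sample_id"],
            "depth_mbsf": true_cells["depth_mbsf"],
            "modality": modality.value,
            "length_um": true_cells["length_um"].to_numpy() * scale,
            "width_um": true_cells["width_um"].to_numpy() * scale,
            "height_um": np.nan,
        }
    )


def generate_thaa_profile(cfg: GeneratorConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample THAA table and amino-acid compositions for the study grid.

    THAA anchors come from the packaged measured table, log-interpolated over
    depth (clamped beyond its range), with multiplicative lognormal noise of
    geometric sd ``thaa_noise_gsd``. Compositions take the nearest measured
    row in depth; with ``composition_noise > 0`` each detected analyte's
    mole-% is perturbed lognormally and the row renormalized to sum to
    exactly 100; with zero noise the measured rows are reproduced verbatim.
    """
    anchor = load_thaa_landsort().sort_values("depth_mbsf")
    comp_ref = load_composition_landsort().sort_values("depth_mbsf").reset_index(drop=True)
    analytes = [c for c in comp_ref.columns if c not in ("sample_id", "depth_mbsf")]

    depths = np.asarray(cfg.depths, dtype=float)
    log_thaa = np.interp(
        depths,
        anchor["depth_mbsf"].to_numpy(dtype=float),
        np.log10(anchor["thaa_fmol_per_cell"].to_numpy(dtype=float)),
    )
    thaa = 10**log_thaa
    if cfg.thaa_noise_gsd > 1.0:
        rng = _rng(cfg, _STREAM_THAA)
        thaa = thaa * np.exp(rng.normal(0.0, math.log(cfg.thaa_noise_gsd), size=len(depths)))
    thaa_df = pd.DataFrame(
        {
            "sample_id": cfg.sample_ids(),
            "depth_mbsf": depths,
            "thaa_fmol_per_cell": thaa,
        }
    )

    rng_comp = _rng(cfg, _STREAM_COMPOSITION)
    ref_depths = comp_ref["depth_mbsf"].to_numpy(dtype=float)
    rows = []
    for sid, depth in zip(cfg.sample_ids(), depths):
        nearest = int(np.argmin(np.abs(ref_depths - depth)))
        values = comp_ref.loc[nearest, analytes].to_numpy(dtype=float)
        if cfg.composition_noise > 0:
            detected = values > 0
            perturbed = values.copy()
            perturbed[detected] = values[detected] * np.exp(
                rng_comp.normal(0.0, cfg.composition_noise, size=int(detected.sum()))
            )
            values = 100.0 * perturbed / perturbed.sum()
        rows.append({"sample_id": sid, "depth_mbsf": depth, **dict(zip(analytes, values))})
    return thaa_df, pd.DataFrame(rows)


def generate_abundance_profile(cfg: GeneratorConfig) -> pd.DataFrame:
    """Cell abundance (cells cm⁻³) per sample: deterministic log-linear
    decline between the surface and deep anchors, optional lognormal noise."""
    depths = np.asarray(cfg.depths, dtype=float)
    abundance = cfg._log_interp(
        depths, cfg.abundance_surface, cfg.abundance_deep, cfg.abundance_depth_range
    )
    if cfg.abundance_noise_gsd > 1.0:
        rng = _rng(cfg, _STREAM_ABUNDANCE)
        abundance = abundance * np.exp(
            rng.normal(0.0, math.log(cfg.abundance_noise_gsd), size=len(depths))
        )
    return pd.DataFrame(
        {
            "sample_id": cfg.sample_ids(),
            "depth_mbsf": depths,
            "cells_per_cm3": abundance,
        }
    )


def write_study(
    cfg: GeneratorConfig,
    outdir,
    table: Optional[CorrectionTable] = None,
) -> Dict[str, Path]:
    """Generate a full study and write its tables to ``outdir``.

    Writes ``cells_fm.csv``, ``cells_sem.csv``, ``thaa.csv``,
    ``composition.csv``, ``abundance.csv`` and a ``manifest.json`` recording
    the full config (including the seed). Returns the paths keyed by table
    name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    true_cells = generate_true_cells(cfg)
    paths: Dict[str, Path] = {}

    fm = observe_cells(true_cells, Modality.FM, table, cfg)
    sem = observe_cells(true_cells, Modality.SEM, table, cfg)
    thaa_df, comp_df = generate_thaa_profile(cfg)
    abundance_df = generate_abundance_profile(cfg)
    for name, df in (
        ("cells_fm", fm),
        ("cells_sem", sem),
        ("thaa", thaa_df),
        ("composition", comp_df),
        ("abundance", abundance_df),
    ):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path

    manifest = {
        "generator": "sedcell.synthetic",
        "config": dataclasses.asdict(cfg),
        "tables": {k: p.name for k, p in paths.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=list) + "\n")
    paths["manifest"] = manifest_path
    return paths
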