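"""Per-sample summaries and depth-profile statistics.

Aggregates corrected per-cell volumes into morphotype fractions, mean/median
volumes, percentile boxes (5/10/25/50/75/90/95) and the morphotype-weighted
mean volume that forms the denominator of the carbon density. Depth trends
are tested with a one-way fixed-effects ANOVA (by default on log10 volumes,
since within-sample volumes spread over roughly an order of magnitude and are
lognormal-like); uncertainty comes from a seeded percentile bootstrap.
Paired-modality concordance (e.g. corrected FM vs SEM volumes of the same
cells) is summarized by the mean log10 ratio and the least-squares slope
through the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateSampleError,
    InvalidDesignError,
    InvalidMeasurementError,
)
from .morphometry import Morphotype

__all__ = [
    "PERCENTILE_RANKS",
    "SampleSummary",
    "TrendResult",
    "ConcordanceSummary",
    "summarize_sample",
    "summaries_to_frame",
    "depth_trend_anova",
    "bootstrap_ci",
    "modality_concordance",
]

PERCENTILE_RANKS = (5, 10, 25, 50, 75, 90, 95)


@dataclass
class SampleSummary:
    """Morphotype mix and volume statistics of one sample."""

    sample_id: str
    depth: float
    n_cells: int
    fractions: Dict[str, float]
    mean_volume: Dict[str, float]
    median_volume: Dict[str, float]
    percentiles: Dict[str, Dict[int, float]]
    weighted_mean_volume: float


@dataclass
class TrendResult:
    """One-way ANOVA result; both degrees of freedom are reported explicitly."""

    statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class ConcordanceSummary:
    """Agreement between paired volume estimates from two modalities."""

    mean_log10_ratio: float
    slope_through_origin: float
    concordant: bool


def summarize_sample(
    cells: pd.DataFrame,
    volume_col: str = "volume_corrected_um3",
    sample_id: str | None = None,
    depth: float | None = None,
) -> SampleSummary:
    """Summarize one sample's classified, corrected cells.

    ``cells`` needs ``morphotype`` and ``volume_col`` columns (and
    ``sample_id``/``depth_mbsf`` unless passed explicitly). Percentiles use
    linear interpolation between order statistics. The weighted mean volume
    is Σᵢ fᵢ·V̄ᵢ over morphotypes, which equals the grand mean volume.
    """
    if len(cells) == 0:
        raise DegenerateSampleError("cannot summarize an empty sample")
    if sample_id is None:
        ids = cells["sample_id"].unique()
        if len(ids) != 1:
            raise ConfigurationError(f"expected a single sample, got {list(ids)}")
        sample_id = str(ids[0])
    if depth is None:
        depth = float(cells["depth_mbsf"].iloc[0])
    vols = cells[volume_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(vols)) or np.any(vols <= 0):
        raise InvalidMeasurementError("volumes must be positive and finite")
    morphs = cells["morphotype"].astype(str).to_numpy()

    n = len(cells)
    fractions: Dict[str, float] = {}
    mean_volume: Dict[str, float] = {}
    median_volume: Dict[str, float] = {}
    percentiles: Dict[str, Dict[int, float]] = {}
    for morph in Morphotype:
        mask = morphs == morph.value
        fractions[morph.value] = float(mask.sum()) / n
        if mask.any():
            v = vols[mask]
            mean_volume[morph.value] = float(v.mean())
            median_volume[morph.value] = float(np.median(v))
            percentiles[morph.value] = {
                q: float(np.percentile(v, q)) for q in PERCENTILE_RANKS
            }
    weighted = sum(
        fractions[m] * mean_volume[m] for m in mean_volume if fractions[m] > 0
    )
    return SampleSummary(
        sample_id=sample_id,
        depth=depth,
        n_cells=n,
        fractions=fractions,
        mean_volume=mean_volume,
        median_volume=median_volume,
        percentiles=percentiles,
        weighted_mean_volume=float(weighted),
    )


def summaries_to_frame(summaries: Iterable[SampleSummary]) -> pd.DataFrame:
    """Long-format table: one row per (sample, morphotype) plus sample-level
    columns (n_cells, weighted mean volume) repeated on each row."""
    rows: List[dict] = []
    for s in summaries:
        for morph, frac in s.fractions.items():
            if morph not in s.mean_volume:
                continue
            row = {
                "sample_id": s.sample_id,
                "depth_mbsf": s.depth,
                "n_cells": s.n_cells,
                "weighted_mean_volume_um3": s.weighted_mean_volume,
                "morphotype": morph,
                "fraction": frac,
                "mean_volume_um3": s.mean_volume[morph],
                "median_volume_um3": s.median_volume[morph],
            }
            row.update({f"p{q}_um3": s.percentiles[morph][q] for q in PERCENTILE_RANKS})
            rows.append(row)
    return pd.DataFrame(rows)


def depth_trend_anova(groups: Sequence[Sequence[float]]) -> TrendResult:
    """One-way fixed-effects ANOVA across depth groups.

    The caller chooses raw or log-transformed volumes; the statistic is
    computed on the supplied values. Requires at least two groups with at
    least two observations each.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise InvalidDesignError("ANOVA requires >= 2 groups with >= 2 observations each")
    f, p = stats.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    return TrendResult(
        statistic=float(f),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        p_value=float(p),
    )


def bootstrap_ci(
    values: Sequence[float],
    statistic: str = "mean",
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> Tuple[float, float]:
    """Seeded percentile-bootstrap interval for the mean or median."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateSampleError("cannot bootstrap an empty sample")
    if n_reps < 100:
        raise ConfigurationError("n_reps must be >= 100")
    if not (0.0 < level < 1.0):
        raise ConfigurationError("level must be in (0, 1)")
    stat_fn = {"mean": np.mean, "median": np.median}.get(statistic)
    if stat_fn is None:
        raise ConfigurationError(f"unknown statistic {statistic!r}; use 'mean' or 'median'")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_reps, v.size))
    reps = stat_fn(v[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(reps, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def modality_concordance(
    pairs: Sequence[Tuple[float, float]] | np.ndarray,
    band: float = 0.05,
) -> ConcordanceSummary:
    """Agreement of paired volumes (A, B) from two modalities.

    Reports the mean log10(B/A) ratio and the least-squares slope of B on A
    through the origin; the pair set is declared concordant when the mean
    log-ratio lies within ±``band`` (identity = 0, i.e. a 1:1 line).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InvalidDesignError("need >= 2 (volume_A, volume_B) pairs")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise InvalidMeasurementError("paired volumes must be positive and finite")
    a, b = arr[:, 0], arr[:, 1]
    mean_log_ratio = float(np.mean(np.log10(b) - np.log10(a)))
    slope = float(np.sum(a * b) / np.sum(a * a))
    return ConcordanceSummary(
        mean_log10_ratio=mean_log_ratio,
        slope_through_origin=slope,
        concordant=abs(mean_log_ratio) <= band,
    )
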