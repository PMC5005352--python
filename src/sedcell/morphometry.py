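"""Morphotype classification and biovolume computation.

Cells measured under epifluorescence (FM), scanning electron (SEM) or atomic
force (AFM) microscopy arrive as tabulated length/width(/height) dimensions in
micrometers. This module classifies each cell into one of three morphotypes by
its aspect ratio — coccoid (AR ≈ 1), elongated (rods and prolate spheroids),
filamentous (AR ≥ 10) — and computes a geometric biovolume under a shape model:

* sphere            V = (π/6)·d³                     (coccoid; d = width)
* capsule           V = (π/4)·W²·(L − W/3)           (rod/filament: cylinder
                                                      with hemispherical caps)
* prolate spheroid  V = (π/6)·L·W²                   (SEM alternative for rods)
* ellipsoid         V = (π/6)·L·W·H                  (AFM, measured height)

For FM and SEM the cell height is assumed equal to the width, so volumes depend
on (L, W) only; AFM supplies an independent height and uses the general
ellipsoid. All volumes here are *raw observed* biovolumes; treatment
corrections are applied downstream (see :mod:`sedcell.corrections`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidMeasurementError

__all__ = [
    "Modality",
    "Morphotype",
    "ShapeModel",
    "CellMeasurement",
    "DEFAULT_COCCOID_MAX_AR",
    "DEFAULT_FILAMENT_MIN_AR",
    "classify_morphotype",
    "volume_sphere",
    "volume_capsule",
    "volume_prolate_spheroid",
    "volume_ellipsoid",
    "cell_volume",
    "compute_volume_table",
]


class Modality(str, Enum):
    """Imaging modality the dimensions were measured with."""

    FM = "FM"
    SEM = "SEM"
    AFM = "AFM"


class Morphotype(str, Enum):
    """Shape class of a cell. "elongated" subsumes rods and prolate spheroids."""

    COCCOID = "coccoid"
    ELONGATED = "elongated"
    FILAMENTOUS = "filamentous"


class ShapeModel(str, Enum):
    """Geometric model used to convert dimensions into a biovolume."""

    SPHERE = "sphere"
    CAPSULE = "capsule"
    PROLATE_SPHEROID = "prolate_spheroid"
    ELLIPSOID = "ellipsoid"


#: Aspect-ratio boundary between coccoid and elongated cells. Cocci have
#: AR ≈ 1; the exact cut is a convention and is exposed everywhere it is used.
DEFAULT_COCCOID_MAX_AR = 1.3

#: Aspect ratio at and above which a cell counts as filamentous.
DEFAULT_FILAMENT_MIN_AR = 10.0


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise InvalidMeasurementError(f"{name} must be positive and finite, got {value!r}")
    return value


@dataclass
class CellMeasurement:
    """One measured cell.

    Dimensions are micrometers; ``depth`` is meters below seafloor (mbsf).
    Length/width are canonicalized so the larger measured axis is stored as
    the length (manual measurement order is arbitrary). ``height`` is present
    if and only if the modality is AFM. ``morphotype`` is assigned by the
    pipeline, never supplied as input.
    """

    cell_id: str
    sample_id: str
    depth: float
    modality: Modality
    length: float
    width: float
    height: Optional[float] = None
    morphotype: Optional[Morphotype] = field(default=None)

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if self.depth < 0:
            raise InvalidMeasurementError(f"depth must be >= 0 mbsf, got {self.depth}")
        self.length = _check_positive("length", self.length)
        self.width = _check_positive("width", self.width)
        if self.length < self.width:  # orientation-agnostic canonicalization
            self.length, self.width = self.width, self.length
        if self.modality is Modality.AFM:
            if self.height is None:
                raise InvalidMeasurementError(
                    f"cell {self.cell_id!r}: AFM measurement requires a height"
                )
            self.height = _check_positive("height", self.height)
        elif self.height is not None:
            raise InvalidMeasurementError(
                f"cell {self.cell_id!r}: height is only valid for AFM measurements"
            )
        if self.morphotype is not None:
            self.morphotype = Morphotype(self.morphotype)

    @property
    def aspect_ratio(self) -> float:
        return self.length / self.width


def classify_morphotype(
    length: float,
    width: float,
    coccoid_max_ar: float = DEFAULT_COCCOID_MAX_AR,
    filament_min_ar: float = DEFAULT_FILAMENT_MIN_AR,
) -> Morphotype:
    """Classify a cell by its length-to-width aspect ratio.

    AR = max(L, W) / min(L, W) — invariant to swapping the two axes.
    Filamentous when AR ≥ ``filament_min_ar``, coccoid when
    AR ≤ ``coccoid_max_ar``, elongated in between.
    """
    length = _check_positive("length", length)
    width = _check_positive("width", width)
    if coccoid_max_ar < 1.0:
        raise ConfigurationError(f"coccoid_max_ar must be >= 1, got {coccoid_max_ar}")
    if filament_min_ar <= coccoid_max_ar:
        raise ConfigurationError(
            f"filament_min_ar ({filament_min_ar}) must exceed coccoid_max_ar ({coccoid_max_ar})"
        )
    ar = max(length, width) / min(length, width)
    if ar >= filament_min_ar:
        return Morphotype.FILAMENTOUS
    if ar <= coccoid_max_ar:
        return Morphotype.COCCOID
    return Morphotype.ELONGATED


def volume_sphere(diameter):
    """Sphere volume (π/6)·d³ in µm³ for a diameter in µm."""
    d = np.asarray(diameter, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise InvalidMeasurementError("sphere diameter must be positive and finite")
    out = (math.pi / 6.0) * d**3
    return float(out) if np.isscalar(diameter) or out.ndim == 0 else out


def volume_capsule(length, width, *, canonicalize: bool = True):
    """Capsule (spherocylinder) volume (π/4)·W²·(L − W/3).

    A cylinder of total length L and diameter W with hemispherical caps;
    reduces exactly to the sphere when L = W. If ``canonicalize`` the larger
    axis is used as L, otherwise L < W raises.
    """
    L = np.asarray(length, dtype=float)
    W = np.asarray(width, dtype=float)
    if np.any(~np.isfinite(L)) or np.any(~np.isfinite(W)) or np.any(L <= 0) or np.any(W <= 0):
        raise InvalidMeasurementError("capsule dimensions must be positive and finite")
    if canonicalize:
        L, W = np.maximum(L, W), np.minimum(L, W)
    elif np.any(L < W):
        raise InvalidMeasurementError("capsule requires length >= width")
    out = (math.pi / 4.0) * W**2 * (L - W / 3.0)
    return float(out) if out.ndim == 0 else out


def volume_prolate_spheroid(length, width, *, canonicalize: bool = True):
    """Prolate-spheroid volume (π/6)·L·W²; equals the sphere when L = W."""
    L = np.asarray(length, dtype=float)
    W = np.asarray(width, dtype=float)
    if np.any(~np.isfinite(L)) or np.any(~np.isfinite(W)) or np.any(L <= 0) or np.any(W <= 0):
        raise InvalidMeasurementError("spheroid dimensions must be positive and finite")
    if canonicalize:
        L, W = np.maximum(L, W), np.minimum(L, W)
    elif np.any(L < W):
        raise InvalidMeasurementError("prolate spheroid requires length >= width")
    out = (math.pi / 6.0) * L * W**2
    return float(out) if out.ndim == 0 else out


def volume_ellipsoid(length, width, height):
    """General ellipsoid volume (π/6)·L·W·H (AFM: measured height)."""
    L = np.asarray(length, dtype=float)
    W = np.asarray(width, dtype=float)
    H = np.asarray(height, dtype=float)
    for name, a in (("length", L), ("width", W), ("height", H)):
        if np.any(~np.isfinite(a)) or np.any(a <= 0):
            raise InvalidMeasurementError(f"ellipsoid {name} must be positive and finite")
    out = (math.pi / 6.0) * L * W * H
    return float(out) if out.ndim == 0 else out


def _default_shape(m: CellMeasurement) -> ShapeModel:
    if m.modality is Modality.AFM and m.height is not None:
        return ShapeModel.ELLIPSOID
    if m.morphotype is Morphotype.COCCOID:
        return ShapeModel.SPHERE
    return ShapeModel.CAPSULE


def cell_volume(m: CellMeasurement, shape: Optional[ShapeModel] = None) -> float:
    """Raw observed biovolume of a classified cell, in µm³.

    If ``shape`` is omitted the shape model is dispatched from the morphotype
    and modality: coccoid → sphere on the width, elongated/filamentous →
    capsule, AFM with a measured height → ellipsoid.
    """
    if shape is None:
        if m.morphotype is None:
            raise InvalidMeasurementError(
                f"cell {m.cell_id!r} has no morphotype; classify before computing volume"
            )
        shape = _default_shape(m)
    shape = ShapeModel(shape)
    if shape is ShapeModel.SPHERE:
        return volume_sphere(m.width)
    if shape is ShapeModel.CAPSULE:
        return volume_capsule(m.length, m.width)
    if shape is ShapeModel.PROLATE_SPHEROID:
        return volume_prolate_spheroid(m.length, m.width)
    if shape is ShapeModel.ELLIPSOID:
        if m.height is None:
            raise InvalidMeasurementError(
                f"cell {m.cell_id!r}: ellipsoid model requires a measured height"
            )
        return volume_ellipsoid(m.length, m.width, m.height)
    raise ConfigurationError(f"unknown shape model {shape!r}")


def compute_volume_table(
    df: pd.DataFrame,
    coccoid_max_ar: float = DEFAULT_COCCOID_MAX_AR,
    filament_min_ar: float = DEFAULT_FILAMENT_MIN_AR,
) -> pd.DataFrame:
    """Vectorized classification + volume computation on a measurement table.

    Expects the measurement CSV schema (``length_um``, ``width_um``, optional
    ``height_um``, ``modality``); returns a copy with ``morphotype``,
    ``shape_model`` and ``volume_raw_um3`` columns appended. Length and width
    are canonicalized in place (larger axis as length).
    """
    if coccoid_max_ar < 1.0 or filament_min_ar <= coccoid_max_ar:
        raise ConfigurationError("require 1 <= coccoid_max_ar < filament_min_ar")
    out = df.copy()
    L = out["length_um"].to_numpy(dtype=float)
    W = out["width_um"].to_numpy(dtype=float)
    if np.any(~np.isfinite(L)) or np.any(~np.isfinite(W)) or np.any(L <= 0) or np.any(W <= 0):
        raise InvalidMeasurementError("all lengths and widths must be positive and finite")
    L, W = np.maximum(L, W), np.minimum(L, W)
    out["length_um"] = L
    out["width_um"] = W
    ar = L / W
    morph = np.where(
        ar >= filament_min_ar,
        Morphotype.FILAMENTOUS.value,
        np.where(ar <= coccoid_max_ar, Morphotype.COCCOID.value, Morphotype.ELONGATED.value),
    )

    H = (
        out["height_um"].to_numpy(dtype=float)
        if "height_um" in out.columns
        else np.full(len(out), np.nan)
    )
    is_afm = out["modality"].astype(str).to_numpy() == Modality.AFM.value
    if np.any(is_afm & ~np.isfinite(H)):
        raise InvalidMeasurementError("AFM rows require a height_um value")

    shape = np.where(
        is_afm,
        ShapeModel.ELLIPSOID.value,
        np.where(
            morph == Morphotype.COCCOID.value,
            ShapeModel.SPHERE.value,
            ShapeModel.CAPSULE.value,
        ),
    )
    vol = np.empty(len(out), dtype=float)
    sph = shape == ShapeModel.SPHERE.value
    cap = shape == ShapeModel.CAPSULE.value
    ell = shape == ShapeModel.ELLIPSOID.value
    if sph.any():
        vol[sph] = volume_sphere(W[sph])
    if cap.any():
        vol[cap] = volume_capsule(L[cap], W[cap], canonicalize=False)
    if ell.any():
        vol[ell] = volume_ellipsoid(L[ell], W[ell], H[ell])

    out["morphotype"] = morph
    out["shape_model"] = shape
    out["volume_raw_um3"] = vol
    return out
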