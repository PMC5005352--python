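"""Amino-acid carbon stoichiometry: THAA → cell carbon → carbon density.

Total hydrolyzable amino acids (THAA, fmol per cell) are converted to carbon
in three steps:

1. **THAA → THAA-C** (fmol C per cell): multiply by the composition-weighted
   mean number of carbon atoms per amino-acid residue. The weights are the
   mole fractions of the 18 analytes of the HPLC panel; carbon counts are the
   free-amino-acid stoichiometry (hydrolysis restores the water lost in the
   peptide bond), e.g. Gly 2, Ala 3, Leu 6, Phe/Tyr 9.
2. **THAA-C → total cell carbon** (fg C per cell): multiply by the carbon
   molar mass (12.011 g mol⁻¹ — fmol × g mol⁻¹ = fg) and divide by the
   assumed fraction of total cell carbon residing in amino acids
   (default 0.55, with 0.40 and 0.75 as sensitivity presets).
3. **Cell carbon → carbon density** (fg C µm⁻³): divide by the
   morphotype-weighted mean cell volume of the sample,
   C_d = C_cell / (V̄_coccoid·f_coccoid + V̄_elongated·f_elongated +
   V̄_filamentous·f_filamentous).

Sediment-integrated biomass (µg C per cm³ sediment) is cell carbon times
cell abundance; the extraction efficiency of the cell-separation step is the
percentage of total sediment cells recovered in the extract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateSampleError,
    InvalidCompositionError,
    InvalidFractionsError,
    InvalidMeasurementError,
)
from .morphometry import Morphotype

__all__ = [
    "CARBON_MOLAR_MASS",
    "AA_C_FRACTION_PRESETS",
    "AminoAcidCarbonRegistry",
    "DEFAULT_REGISTRY",
    "AminoAcidComposition",
    "CarbonEstimate",
    "normalize_composition",
    "mean_carbon_atoms_per_residue",
    "thaa_to_thaa_c",
    "total_cell_carbon",
    "carbon_density",
    "total_sediment_carbon",
    "extraction_efficiency",
    "carbon_table",
]

#: Molar mass of carbon, g mol^-1. fmol C x g mol^-1 = fg C.
CARBON_MOLAR_MASS = 12.011

#: Named presets for the amino-acid-carbon / total-carbon fraction: the 0.55
#: default (E. coli macromolecular composition) and the low/high sensitivity
#: cases discussed for environmental cells.
AA_C_FRACTION_PRESETS = {"low": 0.40, "default": 0.55, "high": 0.75}

#: Carbon atoms per free amino-acid residue for the 18 HPLC analytes.
_CARBON_ATOMS = {
    "Asp": 4,
    "Glu": 5,
    "Ser": 3,
    "His": 6,
    "Gly": 2,
    "Thr": 4,
    "Arg": 6,
    "beta-Ala": 3,
    "Tau": 2,
    "Ala": 3,
    "gamma-Aba": 4,
    "Tyr": 9,
    "Val": 5,
    "Phe": 9,
    "Ile": 6,
    "Leu": 6,
    "Orn": 5,
    "Lys": 6,
}


@dataclass(frozen=True)
class AminoAcidCarbonRegistry:
    """Carbon atoms per free residue for each analyte of the HPLC panel."""

    carbon_atoms: Mapping[str, int] = field(default_factory=lambda: dict(_CARBON_ATOMS))

    def __post_init__(self) -> None:
        for name, n in self.carbon_atoms.items():
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ConfigurationError(f"carbon count for {name!r} must be a positive integer")

    def __getitem__(self, name: str) -> int:
        try:
            return self.carbon_atoms[name]
        except KeyError:
            raise ConfigurationError(f"analyte {name!r} missing from carbon registry") from None


DEFAULT_REGISTRY = AminoAcidCarbonRegistry()


@dataclass
class AminoAcidComposition:
    """Mole-percent composition of one sample over the 18 analytes.

    Analytes below detection are stored as 0. The raw percentages are
    accepted when they sum to 100 within a ±5 tolerance (printed rows sum to
    99.8–100.2 after rounding) and are renormalized downstream.
    """

    sample_id: str
    mole_percent: Mapping[str, float]

    def __post_init__(self) -> None:
        total = float(sum(self.mole_percent.values()))
        if any(v < 0 for v in self.mole_percent.values()):
            raise InvalidCompositionError(f"sample {self.sample_id!r}: negative mole percent")
        if not (95.0 <= total <= 105.0):
            raise InvalidCompositionError(
                f"sample {self.sample_id!r}: mole percentages sum to {total:.2f}, "
                "expected ~100 (within [95, 105])"
            )


def normalize_composition(c) -> dict[str, float]:
    """Renormalize mole percentages to exact mole fractions summing to 1.

    Accepts an :class:`AminoAcidComposition` or a plain name → percent
    mapping; relative proportions are preserved.
    """
    mapping = c.mole_percent if isinstance(c, AminoAcidComposition) else c
    total = float(sum(mapping.values()))
    if total <= 0:
        raise InvalidCompositionError("composition sums to zero; cannot normalize")
    return {name: float(v) / total for name, v in mapping.items()}


def mean_carbon_atoms_per_residue(
    c, registry: AminoAcidCarbonRegistry = DEFAULT_REGISTRY
) -> float:
    """Composition-weighted mean carbon atoms per residue, Σᵢ fᵢ·Cᵢ.

    Bounded by [2, 9] (glycine to tyrosine/phenylalanine) for any valid
    composition.
    """
    fractions = normalize_composition(c)
    return float(sum(f * registry[name] for name, f in fractions.items()))


def thaa_to_thaa_c(thaa, mean_c: float):
    """THAA (fmol cell⁻¹) → THAA-C (fmol C cell⁻¹): thaa × mean carbon atoms."""
    t = np.asarray(thaa, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise InvalidMeasurementError("THAA must be finite and >= 0")
    if not (math.isfinite(mean_c) and mean_c > 0):
        raise ConfigurationError(f"mean carbon atoms per residue must be > 0, got {mean_c!r}")
    out = t * mean_c
    return float(out) if out.ndim == 0 else out


def total_cell_carbon(thaa_c, aa_c_fraction: float = 0.55):
    """Total cell carbon (fg C cell⁻¹) from THAA-C (fmol C cell⁻¹).

    total_c = thaa_c × 12.011 / aa_c_fraction. Inversely proportional to the
    assumed amino-acid-carbon fraction: halving the fraction doubles the
    estimate.
    """
    if not (0.0 < aa_c_fraction <= 1.0):
        raise ConfigurationError(f"aa_c_fraction must be in (0, 1], got {aa_c_fraction!r}")
    t = np.asarray(thaa_c, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise InvalidMeasurementError("THAA-C must be finite and >= 0")
    out = t * CARBON_MOLAR_MASS / aa_c_fraction
    return float(out) if out.ndim == 0 else out


def carbon_density(
    total_c: float,
    fractions: Mapping[Morphotype, float],
    mean_volumes: Mapping[Morphotype, float],
) -> float:
    """Cell-specific carbon density C_d (fg C µm⁻³).

    ``total_c`` divided by the morphotype-weighted mean cell volume
    Σᵢ fᵢ·V̄ᵢ; satisfies C_d × weighted mean volume = total_c exactly.
    """
    fsum = float(sum(fractions.values()))
    if abs(fsum - 1.0) > 1e-6:
        raise InvalidFractionsError(f"morphotype fractions sum to {fsum!r}, expected 1")
    denom = 0.0
    for morph, f in fractions.items():
        if f == 0:
            continue
        v = mean_volumes.get(Morphotype(morph), mean_volumes.get(morph))
        if v is None or not (math.isfinite(v) and v > 0):
            raise DegenerateSampleError(
                f"mean volume for {morph} must be positive when its fraction is nonzero"
            )
        denom += f * v
    if denom <= 0:
        raise DegenerateSampleError("weighted mean volume is zero")
    return float(total_c) / denom


def total_sediment_carbon(total_c, abundance):
    """Sediment-integrated microbial carbon (µg C cm⁻³ sediment).

    fg C cell⁻¹ × cells cm⁻³ × 10⁻⁹ (fg → µg).
    """
    a = np.asarray(abundance, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a < 0):
        raise InvalidMeasurementError("cell abundance must be finite and >= 0")
    out = np.asarray(total_c, dtype=float) * a * 1e-9
    return float(out) if out.ndim == 0 else out


def extraction_efficiency(extracted: float, total: float) -> float:
    """Cell recovery of the density-gradient extraction, in percent.

    100 × extracted / total. Values above 100% are physically suspect
    (counting error) and are flagged with a warning rather than rejected.
    """
    if not (math.isfinite(total) and total > 0):
        raise DegenerateSampleError(f"total cell count must be > 0, got {total!r}")
    if not (math.isfinite(extracted) and extracted >= 0):
        raise InvalidMeasurementError(f"extracted cell count must be >= 0, got {extracted!r}")
    eff = 100.0 * extracted / total
    if eff > 100.0:
        warnings.warn(
            f"extraction efficiency {eff:.1f}% exceeds 100%; check counts", stacklevel=2
        )
    return eff


@dataclass
class CarbonEstimate:
    """Per-sample carbon bookkeeping along the THAA → biomass chain."""

    sample_id: str
    depth: float
    thaa: float
    thaa_c: float
    aa_c_fraction: float
    total_c: float
    carbon_density: Optional[float] = None
    sediment_carbon: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.aa_c_fraction <= 1.0):
            raise ConfigurationError("aa_c_fraction must be in (0, 1]")
        expected = self.thaa_c * CARBON_MOLAR_MASS / self.aa_c_fraction
        if not math.isclose(self.total_c, expected, rel_tol=1e-9, abs_tol=1e-12):
            raise ConfigurationError(
                f"total_c {self.total_c!r} inconsistent with thaa_c x 12.011 / aa_c_fraction"
            )


def carbon_table(
    thaa_df: pd.DataFrame,
    composition_df: Optional[pd.DataFrame] = None,
    aa_c_fraction: float = 0.55,
    registry: AminoAcidCarbonRegistry = DEFAULT_REGISTRY,
    thaa_c_source: str = "table",
) -> pd.DataFrame:
    """Vectorized carbon pipeline over a per-sample THAA table.

    ``thaa_df`` needs ``sample_id``, ``depth_mbsf``, ``thaa_fmol_per_cell``
    and (for ``thaa_c_source="table"``) ``thaa_c_fmol_per_cell``. With
    ``thaa_c_source="composition"`` THAA-C is recomputed from the mole-%
    composition table instead of taken from the measured column.

    Returns a frame with ``thaa_fmol``, ``thaa_c_fmol``, ``total_c_fg`` and
    the ``aa_c_fraction`` used.
    """
    out = thaa_df.copy()
    out = out.rename(columns={"thaa_fmol_per_cell": "thaa_fmol"})
    if thaa_c_source == "table":
        if "thaa_c_fmol_per_cell" not in thaa_df.columns:
            raise ConfigurationError(
                "thaa_c_source='table' requires a thaa_c_fmol_per_cell column"
            )
        out["thaa_c_fmol"] = thaa_df["thaa_c_fmol_per_cell"].to_numpy(dtype=float)
    elif thaa_c_source == "composition":
        if composition_df is None:
            raise ConfigurationError("thaa_c_source='composition' requires a composition table")
        comp = composition_df.set_index("sample_id")
        analyte_cols = [c for c in comp.columns if c in registry.carbon_atoms]
        mean_c = {}
        for sid, row in comp[analyte_cols].iterrows():
            mean_c[sid] = mean_carbon_atoms_per_residue(row.to_dict(), registry)
        missing = set(out["sample_id"]) - set(mean_c)
        if missing:
            raise ConfigurationError(f"no composition for samples {sorted(missing)}")
        out["thaa_c_fmol"] = [
            thaa_to_thaa_c(t, mean_c[s])
            for s, t in zip(out["sample_id"], out["thaa_fmol"])
        ]
    else:
        raise ConfigurationError(f"unknown thaa_c_source {thaa_c_source!r}")
    out["aa_c_fraction"] = aa_c_fraction
    out["total_c_fg"] = total_cell_carbon(out["thaa_c_fmol"].to_numpy(), aa_c_fraction)
    keep = ["sample_id", "depth_mbsf", "thaa_fmol", "thaa_c_fmol", "aa_c_fraction", "total_c_fg"]
    return out[keep]
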