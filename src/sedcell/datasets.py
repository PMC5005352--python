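"""Loaders for the packaged reference tables.

The package ships transcriptions of the published per-sample THAA
measurements (fmol per cell, with their THAA-C values) and the amino-acid
mole-percent compositions for the seven Landsort Deep samples (0.4–38.95
mbsf), plus the default correction-factor set. These are the measured inputs
of the carbon pipeline; the raw per-cell microscopy tables have no public
accession and are emulated by :mod:`sedcell.synthetic`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .corrections import CorrectionTable, default_correction_table

__all__ = [
    "load_thaa_landsort",
    "load_composition_landsort",
    "default_correction_table",
]


def _read_csv(name: str) -> pd.DataFrame:
    ref = resources.files("sedcell.data") / name
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_thaa_landsort() -> pd.DataFrame:
    """Per-sample THAA and THAA-C (fmol cell⁻¹) for the seven samples."""
    return _read_csv("landsort_thaa.csv")


def load_composition_landsort() -> pd.DataFrame:
    """Amino-acid mole-% composition (18 analytes) per sample.

    Analytes not detected (beta-Ala, Tau, gamma-Aba, Orn) are stored as 0.
    """
    return _read_csv("landsort_aa_molepct.csv")
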