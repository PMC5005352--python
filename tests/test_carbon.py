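import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sedcell as sc
from sedcell.carbon import DEFAULT_REGISTRY
from sedcell.errors import (
    ConfigurationError,
    DegenerateSampleError,
    InvalidCompositionError,
    InvalidFractionsError,
)

#: Printed per-sample totals (fg C cell^-1) for the seven measured samples.
PRINTED_TOTAL_C = {0.4: 19, 2.75: 26, 4.32: 29, 9.57: 31, 14.55: 21, 20.53: 14, 38.95: 17}


class TestRegistry:
    def test_covers_the_18_analytes(self):
        assert len(DEFAULT_REGISTRY.carbon_atoms) == 18
        assert DEFAULT_REGISTRY["Gly"] == 2
        assert DEFAULT_REGISTRY["Tyr"] == 9
        assert DEFAULT_REGISTRY["Tau"] == 2

    def test_registry_matches_composition_columns(self, composition_table):
        analytes = [c for c in composition_table.columns if c not in ("sample_id", "depth_mbsf")]
        assert set(analytes) == set(DEFAULT_REGISTRY.carbon_atoms)

    def test_unknown_analyte_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            DEFAULT_REGISTRY["Pyroglutamate"]


class TestComposition:
    def test_normalize_trivial(self):
        assert sc.normalize_composition({"Gly": 100.0}) == {"Gly": 1.0}
        assert sc.normalize_composition({"Gly": 50.0, "Ala": 50.0}) == {
            "Gly": 0.5,
            "Ala": 0.5,
        }

    def test_normalize_measured_row(self, composition_table):
        row = composition_table.iloc[0].drop(["sample_id", "depth_mbsf"]).to_dict()
        # independent tally of the printed surface row
        assert sum(row.values()) == pytest.approx(99.8, abs=1e-9)
        fractions = sc.normalize_composition(row)
        assert sum(fractions.values()) == pytest.approx(1.0, rel=1e-12)
        assert fractions["Gly"] / fractions["Ala"] == pytest.approx(11.7 / 14.2, rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidCompositionError):
            sc.normalize_composition({"Gly": 0.0, "Ala": 0.0})

    def test_far_from_100_rejected(self):
        with pytest.raises(InvalidCompositionError):
            sc.AminoAcidComposition("bad", {"Gly": 50.0})


class TestMeanCarbonAtoms:
    def test_pure_and_mixed(self):
        assert sc.mean_carbon_atoms_per_residue({"Gly": 100.0}) == pytest.approx(2.0)
        assert sc.mean_carbon_atoms_per_residue({"Gly": 50.0, "Ala": 50.0}) == pytest.approx(2.5)

    def test_surface_sample_value(self, composition_table):
        # frozen from an independent tally of the printed mole-% row:
        # sum(pct * C atoms) / sum(pct) = 462.7 / 99.8
        row = composition_table.iloc[0].drop(["sample_id", "depth_mbsf"]).to_dict()
        assert sc.mean_carbon_atoms_per_residue(row) == pytest.approx(462.7 / 99.8, rel=1e-9)

    @given(
        pcts=st.lists(
            st.floats(min_value=0.0, max_value=100.0), min_size=18, max_size=18
        ).filter(lambda v: sum(v) > 1.0)
    )
    def test_bounded_by_glycine_and_aromatics(self, pcts):
        comp = dict(zip(DEFAULT_REGISTRY.carbon_atoms, pcts))
        mean_c = sc.mean_carbon_atoms_per_residue(comp)
        assert 2.0 <= mean_c <= 9.0


class TestThaaToCarbon:
    def test_linearity(self):
        assert sc.thaa_to_thaa_c(0.0, 4.5) == 0.0
        assert sc.thaa_to_thaa_c(1.0, 2.0) == pytest.approx(2.0)
        assert sc.thaa_to_thaa_c(0.3, 4.5) == pytest.approx(3 * sc.thaa_to_thaa_c(0.1, 4.5))

    def test_surface_sample_against_printed_thaa_c(self, composition_table):
        row = composition_table.iloc[0].drop(["sample_id", "depth_mbsf"]).to_dict()
        thaa_c = sc.thaa_to_thaa_c(0.18, sc.mean_carbon_atoms_per_residue(row))
        assert thaa_c == pytest.approx(0.8345, abs=1e-3)
        # 2-significant-figure input rounding dominates the gap to the printed 0.88
        assert thaa_c == pytest.approx(0.88, rel=0.10)

    @pytest.mark.parametrize(
        "thaa_c,fraction,expected",
        [
            (0.88, 0.55, 19.2176),
            (1.4, 0.55, 30.5735),
            (0.78, 0.40, 23.4214),
            (0.78, 0.55, 17.0338),
        ],
    )
    def test_total_cell_carbon(self, thaa_c, fraction, expected):
        assert sc.total_cell_carbon(thaa_c, fraction) == pytest.approx(expected, abs=1e-3)

    def test_all_measured_rows_round_to_printed_totals(self, thaa_table):
        for _, row in thaa_table.iterrows():
            total = sc.total_cell_carbon(row["thaa_c_fmol_per_cell"], 0.55)
            assert abs(total - PRINTED_TOTAL_C[row["depth_mbsf"]]) <= 1.0

    @given(
        thaa_c=st.floats(min_value=0.0, max_value=10.0),
        frac=st.floats(min_value=0.1, max_value=0.9),
    )
    def test_inverse_proportionality_in_aa_c_fraction(self, thaa_c, frac):
        """Halving the assumed amino-acid-carbon fraction doubles the estimate."""
        assert sc.total_cell_carbon(thaa_c, frac / 2) == pytest.approx(
            2 * sc.total_cell_carbon(thaa_c, frac), rel=1e-9
        )

    def test_fraction_domain(self):
        with pytest.raises(ConfigurationError):
            sc.total_cell_carbon(1.0, 0.0)
        with pytest.raises(ConfigurationError):
            sc.total_cell_carbon(1.0, 1.5)


class TestCarbonDensity:
    def test_single_morphotype(self):
        cd = sc.carbon_density(20.0, {sc.Morphotype.COCCOID: 1.0}, {sc.Morphotype.COCCOID: 0.02})
        assert cd == pytest.approx(1000.0)

    def test_weighted_mean_denominator(self):
        fractions = {
            sc.Morphotype.COCCOID: 0.6,
            sc.Morphotype.ELONGATED: 0.35,
            sc.Morphotype.FILAMENTOUS: 0.05,
        }
        volumes = {
            sc.Morphotype.COCCOID: 0.05,
            sc.Morphotype.ELONGATED: 0.1,
            sc.Morphotype.FILAMENTOUS: 0.3,
        }
        cd = sc.carbon_density(19.0, fractions, volumes)
        weighted = 0.6 * 0.05 + 0.35 * 0.1 + 0.05 * 0.3
        assert cd == pytest.approx(19.0 / weighted, rel=1e-12)

    @given(
        total_c=st.floats(min_value=1.0, max_value=100.0),
        f=st.floats(min_value=0.01, max_value=0.99),
        v1=st.floats(min_value=1e-3, max_value=1.0),
        v2=st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_inverse_identity(self, total_c, f, v1, v2):
        """carbon density x weighted mean volume = total carbon, exactly."""
        fractions = {sc.Morphotype.COCCOID: f, sc.Morphotype.ELONGATED: 1.0 - f}
        volumes = {sc.Morphotype.COCCOID: v1, sc.Morphotype.ELONGATED: v2}
        cd = sc.carbon_density(total_c, fractions, volumes)
        weighted = f * v1 + (1 - f) * v2
        assert cd * weighted == pytest.approx(total_c, rel=1e-12)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidFractionsError):
            sc.carbon_density(10.0, {sc.Morphotype.COCCOID: 0.5}, {sc.Morphotype.COCCOID: 0.1})

    def test_zero_volume_rejected_when_fraction_nonzero(self):
        with pytest.raises(DegenerateSampleError):
            sc.carbon_density(10.0, {sc.Morphotype.COCCOID: 1.0}, {sc.Morphotype.COCCOID: 0.0})


class TestSedimentCarbonAndEfficiency:
    @pytest.mark.parametrize(
        "total_c,abundance,expected",
        [(23.0, 1e10, 230.0), (10.0, 1e9, 10.0), (10.0, 0.0, 0.0)],
    )
    def test_sediment_carbon_units(self, total_c, abundance, expected):
        assert sc.total_sediment_carbon(total_c, abundance) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "extracted,total,expected", [(5e8, 1e9, 50.0), (0.0, 1e9, 0.0), (7.0, 7.0, 100.0)]
    )
    def test_extraction_efficiency(self, extracted, total, expected):
        assert sc.extraction_efficiency(extracted, total) == pytest.approx(expected)

    def test_over_100_percent_flagged(self):
        with pytest.warns(UserWarning, match="exceeds 100%"):
            assert sc.extraction_efficiency(2.0, 1.0) == pytest.approx(200.0)

    def test_zero_total_rejected(self):
        with pytest.raises(DegenerateSampleError):
            sc.extraction_efficiency(1.0, 0.0)


class TestCarbonTable:
    def test_table_source_uses_measured_thaa_c(self, thaa_table):
        out = sc.carbon_table(thaa_table, aa_c_fraction=0.55, thaa_c_source="table")
        assert np.allclose(
            out["thaa_c_fmol"], thaa_table["thaa_c_fmol_per_cell"], rtol=1e-12
        )

    def test_composition_source_recomputes_thaa_c(self, thaa_table, composition_table):
        out = sc.carbon_table(
            thaa_table, composition_table, aa_c_fraction=0.55, thaa_c_source="composition"
        )
        # every recomputed THAA-C within 10% of the measured column
        ratio = out["thaa_c_fmol"] / thaa_table["thaa_c_fmol_per_cell"]
        assert np.all(np.abs(np.log(ratio)) < np.log(1.10))

    def test_missing_composition_rejected(self, thaa_table):
        with pytest.raises(ConfigurationError):
            sc.carbon_table(thaa_table, thaa_c_source="composition")
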