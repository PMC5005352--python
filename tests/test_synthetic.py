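import numpy as np
import pandas as pd
import pytest

import sedcell as sc
from conftest import geometric_mean, run_full_pipeline
from sedcell.errors import ConfigurationError


class TestGeneratorConfig:
    def test_defaults_describe_the_study_conditions(self):
        cfg = sc.GeneratorConfig()
        assert cfg.surface_median_volume == 0.05
        assert cfg.deep_median_volume == 0.005
        assert cfg.depths[0] == 0.4 and cfg.depths[-1] == 60.0
        assert sum(cfg.fractions.values()) == pytest.approx(1.0)
        assert cfg.fractions["filamentous"] == pytest.approx(0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"deep_median_volume": 0.1},           # deeper anchor above surface
            {"fractions": {"coccoid": 0.7, "elongated": 0.7, "filamentous": -0.4}},
            {"volume_gsd": 0.5},
            {"n_cells_per_depth": 0},
            {"depths": (10.0, 1.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            sc.GeneratorConfig(**kwargs)

    def test_median_volume_interpolation_is_log_linear(self):
        cfg = sc.GeneratorConfig(depths=(0.0, 60.0))
        mid = cfg.median_volume_at(30.0)
        assert mid == pytest.approx(np.sqrt(0.05 * 0.005), rel=1e-9)


class TestGenerateTrueCells:
    def test_seed_determinism_bit_identical(self, tmp_path):
        cfg = sc.GeneratorConfig(seed=9, n_cells_per_depth=60)
        a = sc.write_study(cfg, tmp_path / "a")
        b = sc.write_study(cfg, tmp_path / "b")
        for name in ("cells_fm", "cells_sem", "thaa", "composition", "abundance"):
            assert a[name].read_bytes() == b[name].read_bytes()

    def test_different_seed_different_cells(self):
        a = sc.generate_true_cells(sc.GeneratorConfig(seed=1, n_cells_per_depth=50))
        b = sc.generate_true_cells(sc.GeneratorConfig(seed=2, n_cells_per_depth=50))
        assert not np.allclose(a["volume_true_um3"], b["volume_true_um3"])

    def test_degenerate_gsd_collapses_to_median(self):
        cfg = sc.GeneratorConfig(seed=0, n_cells_per_depth=50, volume_gsd=1.0, filament_gsd=1.0)
        cells = sc.generate_true_cells(cfg)
        surface = cells[(cells.depth_mbsf == 0.4) & (cells.morphotype != "filamentous")]
        assert np.allclose(surface["volume_true_um3"], 0.05, rtol=1e-12)
        fil = cells[(cells.depth_mbsf == 0.4) & (cells.morphotype == "filamentous")]
        assert np.allclose(fil["volume_true_um3"], 0.3, rtol=1e-12)

    def test_filament_fraction_near_configured(self):
        cfg = sc.GeneratorConfig(seed=5, n_cells_per_depth=300)
        cells = sc.generate_true_cells(cfg)
        frac = (cells["morphotype"] == "filamentous").mean()
        n = len(cells)
        # within 4 binomial standard errors of the configured 5%
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 4 * se

    def test_dimensions_consistent_with_shape_models(self):
        cells = sc.generate_true_cells(sc.GeneratorConfig(seed=3, n_cells_per_depth=100))
        cocc = cells[cells.morphotype == "coccoid"]
        np.testing.assert_allclose(
            sc.volume_sphere(cocc["width_um"].to_numpy()),
            cocc["volume_true_um3"],
            rtol=1e-10,
        )
        rods = cells[cells.morphotype != "coccoid"]
        np.testing.assert_allclose(
            sc.volume_capsule(rods["length_um"].to_numpy(), rods["width_um"].to_numpy()),
            rods["volume_true_um3"],
            rtol=1e-10,
        )

    def test_aspect_ratios_respect_morphotype_bands(self):
        cells = sc.generate_true_cells(sc.GeneratorConfig(seed=3, n_cells_per_depth=200))
        ar = cells["length_um"] / cells["width_um"]
        assert (ar[cells.morphotype == "coccoid"] <= 1.3 + 1e-12).all()
        assert (ar[cells.morphotype == "filamentous"] >= 10.0 - 1e-12).all()


class TestObserveCells:
    def test_identity_table_preserves_volumes(self, small_study):
        _, true_cells, _, _ = small_study
        from sedcell.corrections import Treatment

        identity = sc.CorrectionTable(
            factors={(m, t): 1.0 for m in sc.Morphotype for t in Treatment},
            applicability={mod: () for mod in sc.Modality},
        )
        obs = sc.observe_cells(true_cells, sc.Modality.FM, identity)
        np.testing.assert_allclose(obs["length_um"], true_cells["length_um"], rtol=1e-12)

    def test_fm_bias_is_inverse_composite(self, small_study, correction_table):
        _, true_cells, fm, _ = small_study
        cocc = true_cells.morphotype == "coccoid"
        observed_vol = sc.volume_sphere(fm.loc[cocc, "width_um"].to_numpy())
        np.testing.assert_allclose(
            observed_vol, true_cells.loc[cocc, "volume_true_um3"] / 0.61275, rtol=1e-10
        )

    def test_afm_not_modeled(self, small_study):
        _, true_cells, _, _ = small_study
        with pytest.raises(ConfigurationError):
            sc.observe_cells(true_cells, sc.Modality.AFM)

    def test_pipeline_round_trip_recovers_true_volumes(self, small_study):
        """observe -> classify -> volume -> correct returns the true volumes."""
        _, true_cells, fm, sem = small_study
        for observed in (fm, sem):
            corrected = run_full_pipeline(observed)
            rel = np.abs(
                corrected["volume_corrected_um3"].to_numpy()
                - true_cells["volume_true_um3"].to_numpy()
            ) / true_cells["volume_true_um3"].to_numpy()
            assert rel.max() < 1e-6

    def test_measurement_noise_breaks_exactness_but_not_centering(self):
        cfg = sc.GeneratorConfig(seed=4, n_cells_per_depth=200, measurement_noise_gsd=1.2)
        true_cells = sc.generate_true_cells(cfg)
        fm = sc.observe_cells(true_cells, sc.Modality.FM, cfg=cfg)
        corrected = run_full_pipeline(fm)
        log_ratio = np.log(
            corrected["volume_corrected_um3"].to_numpy()
            / true_cells["volume_true_um3"].to_numpy()
        )
        assert np.abs(log_ratio).max() > 1e-3      # noise present
        assert abs(log_ratio.mean()) < 0.05        # unbiased on average


class TestProfiles:
    def test_zero_noise_reproduces_measured_tables(self, thaa_table, composition_table):
        cfg = sc.GeneratorConfig(
            depths=tuple(thaa_table["depth_mbsf"]), thaa_noise_gsd=1.0, composition_noise=0.0
        )
        thaa, comp = sc.generate_thaa_profile(cfg)
        np.testing.assert_allclose(
            thaa["thaa_fmol_per_cell"], thaa_table["thaa_fmol_per_cell"], rtol=1e-12
        )
        analytes = [c for c in comp.columns if c not in ("sample_id", "depth_mbsf")]
        np.testing.assert_allclose(
            comp[analytes].to_numpy(), composition_table[analytes].to_numpy(), rtol=1e-12
        )

    def test_zero_noise_carbon_matches_measured_totals(self, thaa_table):
        printed = {0.4: 19, 2.75: 26, 4.32: 29, 9.57: 31, 14.55: 21, 20.53: 14, 38.95: 17}
        cfg = sc.GeneratorConfig(
            depths=tuple(thaa_table["depth_mbsf"]), thaa_noise_gsd=1.0, composition_noise=0.0
        )
        thaa, comp = sc.generate_thaa_profile(cfg)
        out = sc.carbon_table(thaa, comp, aa_c_fraction=0.55, thaa_c_source="composition")
        for _, row in out.iterrows():
            assert abs(row["total_c_fg"] - printed[row["depth_mbsf"]]) <= 1.0

    def test_noisy_compositions_sum_to_100(self):
        cfg = sc.GeneratorConfig(seed=8, composition_noise=0.2)
        _, comp = sc.generate_thaa_profile(cfg)
        analytes = [c for c in comp.columns if c not in ("sample_id", "depth_mbsf")]
        np.testing.assert_allclose(comp[analytes].sum(axis=1), 100.0, rtol=1e-9)

    def test_abundance_log_linear_midpoint(self):
        cfg = sc.GeneratorConfig(depths=(0.0, 30.0, 60.0))
        ab = sc.generate_abundance_profile(cfg)
        np.testing.assert_allclose(
            ab["cells_per_cm3"], [1e10, 1e9, 1e8], rtol=1e-9
        )

    def test_surface_sediment_carbon_scale(self):
        # 23 fg per cell at 1e10 cells/cm3 -> 230 ug C/cm3
        assert sc.total_sediment_carbon(23.0, 1e10) == pytest.approx(230.0)


class TestParameterRecovery:
    def test_anchor_recovery_over_seeds(self):
        """Surface and deep geometric-mean corrected volumes bracket the
        configured anchors (0.05, 0.005 um^3) for most seeds."""
        hits_surface = hits_deep = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = sc.GeneratorConfig(seed=seed, n_cells_per_depth=150)
            true_cells = sc.generate_true_cells(cfg)
            fm = sc.observe_cells(true_cells, sc.Modality.FM, cfg=cfg)
            corrected = run_full_pipeline(fm)
            main = corrected[corrected.morphotype != "filamentous"]
            for anchor, depth, bump in (
                (0.05, 0.4, "surface"),
                (0.005, 60.0, "deep"),
            ):
                vols = main.loc[main.depth_mbsf == depth, "volume_corrected_um3"]
                lo, hi = sc.bootstrap_ci(np.log(vols), "mean", n_reps=400, seed=seed)
                ok = lo <= np.log(anchor) <= hi
                if bump == "surface":
                    hits_surface += ok
                else:
                    hits_deep += ok
        assert hits_surface >= 0.8 * n_seeds
        assert hits_deep >= 0.8 * n_seeds
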