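import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sedcell as sc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def correction_table():
    return sc.default_correction_table()


@pytest.fixture(scope="session")
def thaa_table():
    return sc.load_thaa_landsort()


@pytest.fixture(scope="session")
def composition_table():
    return sc.load_composition_landsort()


@pytest.fixture(scope="session")
def small_study():
    """A small deterministic synthetic study shared across tests."""
    cfg = sc.GeneratorConfig(seed=11, n_cells_per_depth=120)
    true_cells = sc.generate_true_cells(cfg)
    fm = sc.observe_cells(true_cells, sc.Modality.FM, cfg=cfg)
    sem = sc.observe_cells(true_cells, sc.Modality.SEM, cfg=cfg)
    return cfg, true_cells, fm, sem


def run_full_pipeline(measurements: pd.DataFrame, table=None) -> pd.DataFrame:
    """Classification -> raw volume -> corrected volume on a measurement table."""
    vols = sc.compute_volume_table(measurements)
    return sc.apply_correction_table(vols, table)


def geometric_mean(values) -> float:
    return float(np.exp(np.mean(np.log(np.asarray(values, dtype=float)))))
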