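"""Shared fixtures: small simulated studies and a pipeline run.

Everything is generated programmatically at test time; session scope
keeps the pipeline run shared across the tests that inspect it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sexconflict.config import SimulationConfig
from sexconflict.io import write_dataset
from sexconflict.pipeline import PipelineConfig, run_pipeline
from sexconflict.simulate import simulate_dataset


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_species=3,
        n_genes=80,
        sites_per_gene=25,
        seed=42,
        coupling=2.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def pipeline_run(small_dataset, tmp_path_factory):
    """One full pipeline run on the small fixture, shared session-wide."""
    root = tmp_path_factory.mktemp("pipeline")
    data_dir = root / "data"
    out_dir = root / "out"
    write_dataset(small_dataset, data_dir)
    config = PipelineConfig(
        dataset_dir=str(data_dir),
        outdir=str(out_dir),
        seed=42,
        n_perm=200,
        n_subsample=200,
    )
    run_pipeline(config)
    return {"config": config, "data_dir": data_dir, "out_dir": out_dir}


@pytest.fixture
def toy_sample_sheet() -> pd.DataFrame:
    rows = []
    for sex, tag in (("male", "m"), ("female", "f")):
        for i in range(1, 6):
            ind = f"{tag}{i}"
            for tissue in ("gonad", "spleen"):
                rows.append(
                    {
                        "sample": f"{ind}_{tissue}",
                        "species": "sp1",
                        "individual": ind,
                        "sex": sex,
                        "tissue": tissue,
                    }
                )
    return pd.DataFrame(rows)
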