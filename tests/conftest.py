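import numpy as np
import pandas as pd
import pytest

from hepe.grid import GridSpec
from hepe.pipeline import RunConfig, run_pipeline
from hepe.synthetic import ScenarioConfig, gen_scenario


@pytest.fixture
def small_grid() -> GridSpec:
    """10x10 grid of 100 m cells, NW corner at (0, 1000)."""
    return GridSpec(origin_x=0.0, origin_y=1000.0, cell_size=100.0, n_rows=10, n_cols=10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scenario() -> ScenarioConfig:
    return ScenarioConfig()


@pytest.fixture(scope="session")
def default_bundle(default_scenario, tmp_path_factory):
    """The default synthetic study day written to disk once per session."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = gen_scenario(default_scenario, out)
    return manifest


@pytest.fixture(scope="session")
def pipeline_run(default_scenario, default_bundle, tmp_path_factory):
    """Full pipeline executed once on the default scenario; shared downstream."""
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = RunConfig(
        stations_csv=str(default_bundle["stations"]),
        sm_dir=str(default_bundle["stations"].parent),
        psd_raster=str(default_bundle["psd_raster"]),
        out_dir=str(out),
        log_level="WARNING",
    )
    report = run_pipeline(cfg)
    return {"scenario": default_scenario, "config": cfg, "report": report, "out": out}


@pytest.fixture(scope="session")
def sde_table(pipeline_run) -> pd.DataFrame:
    return pd.read_csv(pipeline_run["out"] / "sde.csv")
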