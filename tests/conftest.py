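import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chdamp.pipeline import (
    RunConfig,
    cmd_calibrate,
    cmd_carve,
    cmd_collate,
    cmd_engine,
    cmd_prepare,
    cmd_synth,
)
from chdamp.synthetic import SurrogateParams, generate_snapshot_set

settings.register_profile(
    "chdamp",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("chdamp")


@pytest.fixture(scope="session")
def neutral_benchmark():
    """Default surrogate benchmark: neutral kernel, 5 R + 5 TS snapshots,
    40 residues each."""
    return generate_snapshot_set(params=SurrogateParams(seed=1))


@pytest.fixture(scope="session")
def charged_benchmark():
    """Same benchmark shape with a strongly charged kernel (Q_RK = -2)."""
    return generate_snapshot_set(
        kernel_spec={"q_rk": -2, "n_atoms": 10}, params=SurrogateParams(seed=1)
    )


@pytest.fixture(scope="session")
def pipeline_workdir(tmp_path_factory):
    """One full synth -> carve -> prepare -> engine -> collate -> calibrate
    run over files, shared across tests."""
    workdir = tmp_path_factory.mktemp("chd_pipeline")
    cfg = RunConfig(workdir=str(workdir), seed=1)
    cmd_synth(cfg)
    cmd_carve(cfg)
    cmd_prepare(cfg)
    cmd_engine(cfg)
    cmd_collate(cfg)
    results = cmd_calibrate(cfg)
    return {"config": cfg, "workdir": workdir, "results": results}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
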