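from pathlib import Path

import numpy as np
import pytest

REPO_ROOT = Path(__file__).resolve().parent.parent
MINI_CONFIG = REPO_ROOT / "configs" / "mini.yaml"

from ecgitank.camera import CameraModel
from ecgitank.electro import ScenarioConfig, simulate_activation, synthesize_vm
from ecgitank.geometry import make_heart_mesh, make_torso_tank, place_electrodes


@pytest.fixture(scope="session")
def heart4():
    """30 mm sphere at the study's 4 mm edge target (642 vertices)."""
    return make_heart_mesh((30.0, 30.0, 30.0), target_edge_mm=4.0)


@pytest.fixture(scope="session")
def heart7():
    """Coarser 30 mm sphere for cheaper end-to-end tests (162 vertices)."""
    return make_heart_mesh((30.0, 30.0, 30.0), target_edge_mm=7.0)


@pytest.fixture(scope="session")
def tank13(heart7):
    return make_torso_tank(heart7, (1.3, 1.3, 1.3), target_edge_mm=9.0)


@pytest.fixture(scope="session")
def sock108(heart4):
    return place_electrodes(heart4, 108, seed=1)


@pytest.fixture(scope="session")
def camera_truth():
    return CameraModel(x_cop=np.array([0.0, -220.0, 0.0]), x_foc=np.zeros(3))


@pytest.fixture(scope="session")
def scenario7(heart7):
    return ScenarioConfig(pacing_site=0, seed=11)


@pytest.fixture(scope="session")
def at7(heart7, scenario7):
    return simulate_activation(heart7, scenario7)


@pytest.fixture(scope="session")
def vm7(heart7, scenario7, at7):
    return synthesize_vm(at7, scenario7.apd_field(heart7.n_vertices), rate=1000.0)


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """One shared end-to-end run of the packaged 2-sequence mini config."""
    from ecgitank.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("mini") / "run"
    return run_pipeline(MINI_CONFIG, out)
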