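import numpy as np
import pandas as pd
import pytest

from touchersp.config import PipelineConfig, StudyConfig
from touchersp.preprocess import EegEpochs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_study_cfg():
    """Smallest config that still exercises every stage."""
    return StudyConfig(
        n_subjects=3,
        trials_per_cell=4,
        fs_sensor=200.0,
        fs_eeg=256.0,
        n_channels=16,
        seed=99,
    )


@pytest.fixture
def tiny_pipeline_cfg(tiny_study_cfg):
    return PipelineConfig(
        study=tiny_study_cfg, bands={"alpha": (8.0, 12.0)}, time_decim=8
    )


def make_epochs(data: np.ndarray, fs: float = 256.0, t0_ms: float = -5500.0) -> EegEpochs:
    """Wrap a (trials, channels, samples) array as onset-locked epochs."""
    n_tr, n_ch, n_s = data.shape
    t_ms = t0_ms + np.arange(n_s) * (1000.0 / fs)
    trials = pd.DataFrame(
        {
            "trial": np.arange(n_tr),
            "texture": ["hessian", "silk"] * (n_tr // 2) + ["hessian"] * (n_tr % 2),
            "condition": ["sensory"] * n_tr,
        }
    )
    return EegEpochs(data, t_ms, fs, trials, [f"E{i:03d}" for i in range(n_ch)])
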