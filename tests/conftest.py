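import numpy as np
import pytest

from flowcol.config import ExperimentConfig, default_config
from flowcol.glif import GLIFParams
from flowcol.network import ConnectivityRules, Geometry, NeuronTypeSpec


def tiny_config(seed: int = 3) -> ExperimentConfig:
    """A few-hundred-neuron column that runs an onset experiment in seconds."""
    cfg = default_config(seed=seed)
    scale = {
        "L1_Htr3a": 8, "L23_Exc": 80, "L23_Pvalb": 14, "L23_Sst": 8, "L23_Htr3a": 8,
        "L4_Exc": 90, "L4_Pvalb": 16, "L4_Sst": 8, "L4_Htr3a": 6,
        "L5_Exc": 50, "L5_Pvalb": 10, "L5_Sst": 6, "L5_Htr3a": 4,
        "L6_Exc": 50, "L6_Pvalb": 10, "L6_Sst": 6, "L6_Htr3a": 4,
    }
    import dataclasses

    for name, count in scale.items():
        cfg.types[name] = dataclasses.replace(cfg.types[name], count=count)
    cfg.n_lgn_units = 40
    cfg.n_trials = 2
    return cfg


@pytest.fixture(scope="session")
def tiny_cfg() -> ExperimentConfig:
    return tiny_config()


@pytest.fixture
def lif_params() -> GLIFParams:
    """An ASC-free membrane with round numbers (tau = 10 ms, rheobase 100 pA)."""
    return GLIFParams(C=100.0, g=10.0, E_L=-70.0, v_th=-60.0, v_reset=-70.0, t_ref=2.0)


@pytest.fixture
def glif3_params() -> GLIFParams:
    return GLIFParams(
        C=120.0, g=5.0, E_L=-70.0, v_th=-50.0, v_reset=-70.0, t_ref=4.0,
        asc_k=(0.03, 0.3), asc_amp=(-12.0, -35.0),
    )
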