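import numpy as np
import pytest

from bpval.model import SessionSeries, StudyDataset, Variable
from bpval.simulate import SimulationConfig, VariableModel


def build_dataset(series_values):
    """Build a StudyDataset from {(pid, session, variable): [7 values]}."""
    ds = StudyDataset()
    for (pid, sess, var), values in series_values.items():
        ds.add_series(SessionSeries(pid, sess, Variable(var), list(values)))
    return ds


@pytest.fixture
def tiny_dataset():
    """Two participants x two sessions x one variable, integer readings."""
    return build_dataset(
        {
            ("P1", 1, "SBP"): [120, 121, 122, 119, 118, 121, 120],
            ("P1", 2, "SBP"): [118, 119, 120, 118, 117, 119, 118],
            ("P2", 1, "SBP"): [130, 132, 129, 131, 130, 133, 131],
            ("P2", 2, "SBP"): [128, 129, 127, 130, 129, 131, 130],
        }
    )


@pytest.fixture
def small_sim_config():
    """Low-noise 40-subject config used where speed matters."""
    return SimulationConfig(
        n_subjects=40,
        seed=7,
        dropout=0.0,
        session_effect_sd=1.0,
        criterion_noise_sd=1.0,
        test_noise_sd=1.0,
        variables={
            "SBP": VariableModel(127.0, 16.0, 90.0, 180.0, 2.0),
            "DBP": VariableModel(74.0, 10.0, 40.0, 130.0, 2.0),
            "HR": VariableModel(71.0, 10.0, 40.0, 180.0, 1.5),
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
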