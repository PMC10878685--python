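from pathlib import Path

import numpy as np
import pytest

from agreekit import (BootstrapConfig, ColumnSpec, MeasurementSet,
                      load_measurements)

DATA_DIR = Path(__file__).parent / "data"


def make_set(x, y, **kwargs) -> MeasurementSet:
    """Single-replicate MeasurementSet from two 1-D sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return MeasurementSet(x_reps=x[:, None], y_reps=y[:, None], **kwargs)


@pytest.fixture(scope="session")
def pefr():
    """Classic peak expiratory flow dataset: 17 subjects, two meters, two
    replicate readings each (the standard public method-comparison table)."""
    spec = ColumnSpec(reference_cols=("wright1", "wright2"),
                      candidate_cols=("mini1", "mini2"),
                      subject_id_col="subject")
    ms, _ = load_measurements(DATA_DIR / "pefr_peakflow.csv", spec)
    return ms


@pytest.fixture
def small_boot():
    """Cheap bootstrap settings for unit tests."""
    return BootstrapConfig(n_boot=300, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
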