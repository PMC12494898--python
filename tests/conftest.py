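import numpy as np
import pandas as pd
import pytest

from paleodispersal.calibration import make_test_curve


@pytest.fixture(scope="session")
def identity_curve():
    return make_test_curve("identity", (7000, 12000))


@pytest.fixture(scope="session")
def wiggle_curve():
    return make_test_curve("wiggle", (6000, 13000))


@pytest.fixture()
def tiny_database(tmp_path):
    """Well-formed 3-row date database CSV on disk."""
    df = pd.DataFrame({
        "lab_id": ["L1", "L2", "L3"],
        "site_id": ["A", "A", "B"],
        "lon": [10.0, 10.0, 20.0],
        "lat": [20.0, 20.0, 25.0],
        "c14_age": [9000.0, 9050.0, 8000.0],
        "c14_error": [80.0, 60.0, 100.0],
        "ceramic": [1, 0, 1],
    })
    path = tmp_path / "dates.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
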