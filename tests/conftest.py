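import numpy as np
import pandas as pd
import pytest

from qsmlm import LocalizationTable


@pytest.fixture
def simple_table():
    """Three localizations over two frames, 60 ms/frame."""
    return LocalizationTable(
        pd.DataFrame({"x": [0.0, 100.0, 0.0], "y": [0.0, 0.0, 100.0],
                      "frame": [1, 1, 2]}),
        frame_time=0.06,
    )


@pytest.fixture
def rich_table():
    """Table with uncertainty and intensity columns, values at native
    write precision (1e-4 nm)."""
    rng = np.random.default_rng(7)
    n = 40
    return LocalizationTable(
        pd.DataFrame({
            "x": np.round(rng.uniform(0, 2000, n), 4),
            "y": np.round(rng.uniform(0, 2000, n), 4),
            "frame": rng.integers(1, 500, n),
            "sigma": np.round(rng.uniform(10, 60, n), 4),
            "intensity": np.round(rng.uniform(100, 900, n), 4),
        }),
        frame_time=0.06,
    )


def make_table(xy, frames=None, frame_time=0.06):
    xy = np.asarray(xy, float)
    if frames is None:
        frames = np.ones(len(xy), dtype=int)
    return LocalizationTable(
        pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "frame": frames}),
        frame_time=frame_time,
    )
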