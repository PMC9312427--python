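import numpy as np
import pytest
from hypothesis import settings

from skylinecheck.skyline_log import SkylineTrace

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def three_tip_newick():
    return "((A:1.0,B:1.0):1.0,C:2.0);"


@pytest.fixture
def toy_trace():
    """Two-row trace: current CI [500, 900], ancestral CI [5000, 9000]."""
    return SkylineTrace(
        time=np.array([0.0, 1e4]),
        mean=np.array([700.0, 7000.0]),
        median=np.array([700.0, 7000.0]),
        lower=np.array([500.0, 5000.0]),
        upper=np.array([900.0, 9000.0]),
    )


@pytest.fixture
def degenerate_trace():
    """Zero-width intervals: current 700, ancestral 7000 (ratio 10 forced)."""
    return SkylineTrace(
        time=np.array([0.0, 1e4]),
        mean=np.array([700.0, 7000.0]),
        median=np.array([700.0, 7000.0]),
        lower=np.array([700.0, 7000.0]),
        upper=np.array([700.0, 7000.0]),
    )


def make_trace_file(tmp_path, text, name="skyline.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path
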