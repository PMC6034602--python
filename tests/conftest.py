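import numpy as np
import pytest

from cytospat.geometry import MarkedPointPattern, PlotWindow


@pytest.fixture
def unit_window() -> PlotWindow:
    return PlotWindow("unit", ((0, 0), (1, 0), (1, 1), (0, 1)))


@pytest.fixture
def square100() -> PlotWindow:
    return PlotWindow("sq100", ((0, 0), (100, 0), (100, 100), (0, 100)))


def make_pattern(window, coords, mark="2x"):
    coords = np.asarray(coords, dtype=float)
    return MarkedPointPattern(
        window, coords[:, 0], coords[:, 1], np.full(len(coords), mark, dtype=object)
    )


def merge_patterns(*patterns):
    """Concatenate same-window patterns, keeping their marks."""
    w = patterns[0].window
    x = np.concatenate([p.x for p in patterns])
    y = np.concatenate([p.y for p in patterns])
    m = np.concatenate([p.marks for p in patterns])
    return MarkedPointPattern(w, x, y, m, patterns[0].labels)
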