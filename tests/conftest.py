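import numpy as np
import pandas as pd
import pytest

from immunodyn._solver import warmup
from immunodyn.feature_extraction import EventTable, PanelConfig


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    """Pay the numba JIT cost once per session."""
    warmup()


@pytest.fixture
def small_panel():
    return PanelConfig(
        cell_types=("A", "B", "C", "D"),
        functional_markers=("m1", "m2", "m3"),
        conditions=("unstim", "stim"),
    )


def make_events(patient="P1", timepoint="T1", condition="unstim",
                cell_types=("A", "B"), counts=(50, 150),
                marker_values=None, markers=("m1", "m2", "m3"),
                transformed=False):
    """Build a toy EventTable with constant marker values per subset."""
    rows = []
    for ct, n in zip(cell_types, counts):
        for _ in range(n):
            row = {"cell_type": ct}
            for m in markers:
                row[m] = (marker_values or {}).get((ct, m), 1.0)
            rows.append(row)
    return EventTable(patient, timepoint, condition, pd.DataFrame(rows),
                      transformed=transformed)


@pytest.fixture
def events_factory():
    return make_events


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
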