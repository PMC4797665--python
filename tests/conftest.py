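import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
import pytest

from usagevis.dataio import CodingMap, ColorMap, PageFlowRecord, assemble_dataset
from usagevis.synth import SimConfig, generate


def make_flow(rows):
    """rows: (user_id, page_id, iso start, duration_s)."""
    return [
        PageFlowRecord(u, p, pd.Timestamp(t, tz="UTC"), d) for u, p, t, d in rows
    ]


def make_dataset(rows, coding_entries, colors=None, user_ids=None, user_cols=None):
    flow = make_flow(rows)
    coding = CodingMap(coding_entries)
    if colors is None:
        colors = ColorMap({c: f"#{c:02X}{c:02X}{c:02X}" for c in coding.codes})
    if user_ids is None:
        user_ids = sorted({r.user_id for r in flow})
    users = pd.DataFrame(user_cols or {}, index=pd.Index(user_ids, name="user_id"))
    return assemble_dataset(flow, coding, colors, users)


@pytest.fixture
def small_coding():
    return {
        "pageA": (1, "eating plan"),
        "pageB": (1, "eating plan"),
        "pageC": (2, "tools"),
        "pageD": (3, "review"),
    }


@pytest.fixture
def tiny_dataset(small_coding):
    """Two users; u1's views exercise binning + merging, u2 has one view."""
    rows = [
        ("u1", "pageA", "2011-06-01 18:00:00", 40),
        ("u1", "pageB", "2011-06-01 18:01:00", 10),
        ("u1", "pageC", "2011-06-01 18:02:00", 61),
        ("u2", "pageA", "2011-06-02 10:00:00", 5),
    ]
    return make_dataset(rows, small_coding)


@pytest.fixture(scope="session")
def synth_dataset():
    """One moderately sized simulated cohort shared across tests."""
    return generate(SimConfig(n_users=40, seed=11))


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    plt.close("all")
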