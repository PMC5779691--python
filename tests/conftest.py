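import numpy as np
import pytest

from scbc import AnalytePanel, ChamberRecord, ChipDataset, CohortCondition
from scbc.calling import SecretionCallTable


@pytest.fixture
def panel():
    return AnalytePanel.default()


@pytest.fixture
def small_panel():
    return AnalytePanel(("IL2", "CCL3", "IFNg"))


@pytest.fixture
def condition():
    return CohortCondition("test", T1_hours=4.0, T2_hours=20.0, stimulation="tetramer")


def build_chip(values_by_count, panel, condition, chip_id="chip", n_cols=25):
    """ChipDataset from {cell_count: (n, panel.size) intensity array}."""
    chambers = []
    cid = 0
    for count, vals in values_by_count.items():
        for rowvals in np.atleast_2d(vals):
            chambers.append(
                ChamberRecord(
                    chamber_id=cid,
                    row=cid // n_cols,
                    col=cid % n_cols,
                    cell_count=count,
                    raw_intensity=np.asarray(rowvals, dtype=float),
                    saturated=np.zeros(len(rowvals), dtype=bool),
                )
            )
            cid += 1
    return ChipDataset(chip_id, panel, condition, chambers)


@pytest.fixture
def make_chip(condition):
    def _make(values_by_count, panel, **kw):
        return build_chip(values_by_count, panel, condition, **kw)

    return _make


def make_call_table(calls, rates, panel, T2_hours=1.0, label="cond"):
    """SecretionCallTable straight from boolean/rate arrays (net = rate * T2)."""
    calls = np.asarray(calls, dtype=bool)
    rates = np.asarray(rates, dtype=float)
    cond = CohortCondition(label, T1_hours=0.0, T2_hours=T2_hours)
    return SecretionCallTable(
        condition=cond,
        panel=panel,
        chamber_ids=np.arange(calls.shape[0]),
        calls=calls,
        net=rates * T2_hours,
        rates=rates,
        saturated=np.zeros_like(calls, dtype=bool),
    )


@pytest.fixture
def call_table_factory():
    return make_call_table
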