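"""Shared fixtures: tiny hand-built records and seeded synthetic sets."""

import numpy as np
import pytest

from pmkinetics import KineticCurve, RecordSet, WellRecord


def make_record(
    strain="S1",
    phenotype="P1",
    plate="PM01",
    well="A01",
    replicate=1,
    times=None,
    values=None,
    project="PROJ",
    temperature=37.0,
):
    """A WellRecord with sensible defaults for unit tests."""
    if times is None:
        times = np.arange(0, 100, 10.0)
    if values is None:
        values = np.linspace(0, 90, len(times))
    return WellRecord(
        project=project,
        species="Bacillus sp.",
        strain=strain,
        phenotype=phenotype,
        plate=plate,
        well=well,
        replicate=replicate,
        temperature=temperature,
        curve=KineticCurve(times, values),
    )


def logistic_curve(times, baseline=20.0, amplitude=200.0, rate=0.01, midpoint=1000.0):
    return baseline + amplitude / (1.0 + np.exp(-rate * (times - midpoint)))


@pytest.fixture
def times_72h():
    """72 h at 15-min cycles: 289 points."""
    return np.arange(289) * 15.0


@pytest.fixture
def mixed_catalog():
    """10 records: 6 of strain S1, 4 of S2, across 2 plates."""
    records = []
    wells = ["A01", "A02", "A03", "B01", "B02", "B03"]
    for i, well in enumerate(wells):
        records.append(make_record(strain="S1", phenotype=f"P{i}", well=well))
    for i, well in enumerate(wells[:4]):
        records.append(
            make_record(strain="S2", phenotype=f"P{i}", plate="PM02", well=well)
        )
    return RecordSet(records)
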