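"""Shared fixtures: tiny hand-made datasets and the session-wide benchmark sweep."""

from __future__ import annotations

import pytest

from anchormotif.alphabet import CHARGED, HYDROPHOBIC
from anchormotif.benchmark import (
    BenchmarkCondition,
    ImplantSpec,
    run_benchmark,
)
from anchormotif.io import Dataset, SequenceRecord, TerminalSegment

HC = HYDROPHOBIC + CHARGED


def make_segment(residues: str, parent_id: str = "s1", end: str = "N") -> TerminalSegment:
    return TerminalSegment(parent_id, end, len(residues), residues)


@pytest.fixture
def toy_dataset() -> Dataset:
    return Dataset(
        [
            SequenceRecord("p1", "MKRAAVILWC", "positive"),
            SequenceRecord("p2", "MKRAAVILWD", "positive"),
            SequenceRecord("n1", "GGGGGGGGGG", "negative"),
        ]
    )


@pytest.fixture(scope="session")
def benchmark_sweep():
    """One 3-replicate sweep over the six benchmark conditions.

    Shared across the acceptance tests; replicate seeds derive from the
    fixed session seed 1 the same way the acceptance script derives them.
    """
    conditions = [
        BenchmarkCondition(
            "hydrophobic_100",
            ImplantSpec(flank_alphabet=HYDROPHOBIC, true_ratio=1.0),
            removal=False,
        ),
        BenchmarkCondition(
            "hc_100", ImplantSpec(flank_alphabet=HC, true_ratio=1.0), removal=False
        ),
        BenchmarkCondition(
            "hc_40_removal", ImplantSpec(flank_alphabet=HC, true_ratio=0.4), removal=True
        ),
        BenchmarkCondition(
            "hc_100_removal", ImplantSpec(flank_alphabet=HC, true_ratio=1.0), removal=True
        ),
        BenchmarkCondition(
            "hc_10", ImplantSpec(flank_alphabet=HC, true_ratio=0.1), removal=False
        ),
        BenchmarkCondition(
            "hc_40", ImplantSpec(flank_alphabet=HC, true_ratio=0.4), removal=False
        ),
    ]
    return run_benchmark(conditions, replicates=3, seed=1)


def condition_records(sweep, name):
    recs = sweep.records
    return recs[recs["condition"] == name]
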