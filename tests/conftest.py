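import pytest

from pvsignal.ingest import Quarter, Report, ReportStore
from pvsignal.meddra import MedDRAHierarchy
from pvsignal.synthetic import SignalSpec, SimConfig, generate_reports


def make_report(case_id, drugs, reactions, version=0, quarter=Quarter(2020, 1), **kw):
    """Compact report constructor for hand-written fixtures."""
    return Report(case_id=case_id, version=version, quarter=quarter,
                  drugs=tuple(drugs), reactions=frozenset(reactions), **kw)


@pytest.fixture
def toy_hierarchy():
    """5-PT vocabulary: pt1/pt2 in socA, pt3/pt4 in socB, pt5 in socC;
    one SMQ covering pt1+pt3, one covering pt3 only."""
    return MedDRAHierarchy(
        pt_to_soc={"pt1": "socA", "pt2": "socA", "pt3": "socB",
                   "pt4": "socB", "pt5": "socC"},
        smq_members={"smqX": frozenset({"pt1", "pt3"}),
                     "smqY": frozenset({"pt3"})},
    )


@pytest.fixture
def six_report_store(toy_hierarchy):
    """The hand-enumerable store: 2 PS reports with pt1, 1 PS without,
    1 background with pt1, 2 background without -> (a,b,c,d) = (2,1,1,2)."""
    return ReportStore([
        make_report("R1", [("drugx", "PS")], {"pt1"}),
        make_report("R2", [("drugx", "PS")], {"pt1", "pt2"}),
        make_report("R3", [("drugx", "PS")], {"pt3"}),
        make_report("R4", [("other", "PS"), ("drugx", "C")], {"pt1"}),
        make_report("R5", [("other", "PS")], {"pt4"}),
        make_report("R6", [("other", "PS")], {"pt5"}),
    ])


@pytest.fixture(scope="session")
def signal_config():
    """Standard study conditions with one strong embedded signal
    (rr=20 on drug000 x pt007)."""
    return SimConfig(seed=42, signals=(SignalSpec(0, 7, 20.0),))


@pytest.fixture(scope="session")
def signal_store(signal_config):
    return generate_reports(signal_config)


@pytest.fixture(scope="session")
def small_null_store():
    """1,000-report null extract for brute-force oracle comparisons."""
    return generate_reports(SimConfig(seed=9, n_reports=1_000))
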