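"""2x2 contingency tables of drug-event co-reporting against the full background.

For a target drug and an event label, the table cells are

========  ==============================  ==========================
cell      target drug (primary suspect)   all other reports
========  ==============================  ==========================
event     a                               c
no event  b                               d
========  ==============================  ==========================

The counting unit defaults to the distinct deduplicated report: a report
contributes at most once to each label's table, and exactly one cell of it.
Reports where the target drug appears only as secondary suspect or
concomitant count as background, matching a primary-suspect-only inclusion
rule.  An alternative ``event`` counting unit treats each (report, reaction
PT) occurrence as the unit, for the aggregation ambiguity at SOC level.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .ingest import ReportStore
from .meddra import MedDRAHierarchy, SMQ_NA_LABEL, event_labels


class LabelError(KeyError):
    """Raised for an event label unknown at the requested level."""


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # target drug & label
    b: int  # target drug, no label
    c: int  # background, label
    d: int  # background, no label

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected a under independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _label_units(store: ReportStore, drug: str, level: str,
                 h: MedDRAHierarchy, count_unit: str):
    """Yield (is_ps, Counter of label -> unit multiplicity) per report."""
    if count_unit not in ("report", "event"):
        raise ValueError(f"unknown count unit {count_unit!r}")
    for r in store:
        labels = event_labels(r, h, level)
        if level == "SMQ" and not labels:
            labels = {SMQ_NA_LABEL}
        if count_unit == "report":
            counts = Counter({lab: 1 for lab in labels})
        else:
            counts = Counter()
            if level == "PT":
                counts.update(r.reactions)
            elif level == "SOC":
                from .meddra import SOC_UNMAPPED_LABEL
                counts.update(h.pt_to_soc.get(pt, SOC_UNMAPPED_LABEL)
                              for pt in r.reactions)
            else:  # SMQ: one unit per (PT, SMQ) membership
                hit = False
                for pt in r.reactions:
                    for smq, pts in h.smq_members.items():
                        if pt in pts:
                            counts[smq] += 1
                            hit = True
                if not hit:
                    counts[SMQ_NA_LABEL] = len(r.reactions)
        yield r.is_primary_suspect(drug), counts


def build_table(all_reports: ReportStore, drug: str, label: str, level: str,
                h: MedDRAHierarchy, count_unit: str = "report") -> ContingencyTable:
    """Build the 2x2 table for one (drug, label) pair.

    ``all_reports`` must be deduplicated and period-filtered but NOT
    restricted to the target drug — the background columns need every
    report in the window.
    """
    if label not in h.labels_at(level):
        raise LabelError(f"label {label!r} unknown at level {level}")
    a = b = c = d = 0
    for is_ps, counts in _label_units(all_reports, drug, level, h, count_unit):
        total = sum(counts.values()) if count_unit == "event" else 1
        with_label = counts.get(label, 0)
        if count_unit == "report":
            with_label = 1 if with_label else 0
        if is_ps:
            a += with_label
            b += total - with_label
        else:
            c += with_label
            d += total - with_label
    return ContingencyTable(a, b, c, d)


def build_all_tables(all_reports: ReportStore, drug: str, level: str,
                     h: MedDRAHierarchy, min_count: int = 0,
                     count_unit: str = "report") -> list[tuple[str, ContingencyTable]]:
    """Tables for every label observed at the level with ``a >= min_count``.

    Single pass over the store; ordering follows first observation (ranking
    is downstream).  At SMQ level, reports whose reactions match no SMQ are
    pooled under the reserved not-applicable label.
    """
    ps_units: Counter[str] = Counter()
    bg_units: Counter[str] = Counter()
    n_ps = n_bg = 0
    order: dict[str, None] = {}
    for is_ps, counts in _label_units(all_reports, drug, level, h, count_unit):
        total = sum(counts.values()) if count_unit == "event" else 1
        tgt = ps_units if is_ps else bg_units
        for lab, m in counts.items():
            order.setdefault(lab, None)
            tgt[lab] += m if count_unit == "event" else 1
        if is_ps:
            n_ps += total
        else:
            n_bg += total
    out = []
    for lab in order:
        a = ps_units.get(lab, 0)
        if a < min_count:
            continue
        c = bg_units.get(lab, 0)
        out.append((lab, ContingencyTable(a, n_ps - a, c, n_bg - c)))
    return out
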