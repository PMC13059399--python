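"""MedDRA-style event hierarchy: PT -> SOC mapping and SMQ membership.

The hierarchy used here is the two relations the screening pipeline needs:
a total map from preferred terms (PTs) to system organ classes (SOCs), and
named Standardised MedDRA Query (SMQ) subsets of the PT vocabulary.  SMQ
membership is a single flat set — narrow and broad scope are not
distinguished.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .ingest import Report

#: SMQ-level label for reports whose reactions belong to no SMQ.
SMQ_NA_LABEL = "NA"
#: SOC-level label for PTs absent from the PT->SOC map.
SOC_UNMAPPED_LABEL = "unmapped"

LEVELS = ("PT", "SOC", "SMQ")


class HierarchyError(Exception):
    """Raised when hierarchy files violate the PT->SOC / SMQ invariants."""


@dataclass(frozen=True)
class MedDRAHierarchy:
    pt_to_soc: dict[str, str]
    smq_members: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for smq, pts in self.smq_members.items():
            if not pts:
                raise HierarchyError(f"SMQ {smq!r} has no member PTs")
            missing = pts - self.pt_to_soc.keys()
            if missing:
                raise HierarchyError(
                    f"SMQ {smq!r} members missing from PT vocabulary: {sorted(missing)}")

    @property
    def pts(self) -> set[str]:
        return set(self.pt_to_soc)

    @property
    def socs(self) -> set[str]:
        return set(self.pt_to_soc.values())

    def pts_in_smq(self, smq: str) -> frozenset[str]:
        return self.smq_members[smq]

    def labels_at(self, level: str) -> set[str]:
        """All labels that can occur at a level (including reserved buckets)."""
        if level == "PT":
            return self.pts
        if level == "SOC":
            return self.socs | {SOC_UNMAPPED_LABEL}
        if level == "SMQ":
            return set(self.smq_members) | {SMQ_NA_LABEL}
        raise ValueError(f"unknown level {level!r}")


def load_hierarchy(pt_soc_path: str | Path,
                   smq_path: str | Path | None = None) -> MedDRAHierarchy:
    """Load the hierarchy from TSV files of (pt, soc) and (smq, pt) pairs.

    Duplicate (pt, soc) rows are deduplicated silently; a PT mapped to two
    different SOCs is an error, as is an SMQ member PT absent from the PT
    file.
    """
    pt_to_soc: dict[str, str] = {}
    with open(pt_soc_path, newline="") as f:
        for row in csv.reader(f, delimiter="\t"):
            if not row or not row[0].strip():
                continue
            pt, soc = row[0].strip(), row[1].strip()
            if pt in pt_to_soc and pt_to_soc[pt] != soc:
                raise HierarchyError(
                    f"PT {pt!r} mapped to both {pt_to_soc[pt]!r} and {soc!r}")
            pt_to_soc[pt] = soc

    smq_members: dict[str, set[str]] = {}
    if smq_path is not None:
        with open(smq_path, newline="") as f:
            for row in csv.reader(f, delimiter="\t"):
                if not row or not row[0].strip():
                    continue
                smq_members.setdefault(row[0].strip(), set()).add(row[1].strip())
    return MedDRAHierarchy(pt_to_soc,
                           {k: frozenset(v) for k, v in smq_members.items()})


def write_hierarchy(h: MedDRAHierarchy, pt_soc_path: str | Path,
                    smq_path: str | Path) -> None:
    with open(pt_soc_path, "w", newline="") as f:
        w = csv.writer(f, delimiter="\t")
        for pt in sorted(h.pt_to_soc):
            w.writerow([pt, h.pt_to_soc[pt]])
    with open(smq_path, "w", newline="") as f:
        w = csv.writer(f, delimiter="\t")
        for smq in sorted(h.smq_members):
            for pt in sorted(h.smq_members[smq]):
                w.writerow([smq, pt])


def event_labels(report: Report, h: MedDRAHierarchy, level: str) -> set[str]:
    """Labels a report contributes to at the given aggregation level.

    PT level returns the reaction set itself.  SOC level returns the image
    of the reactions under the PT->SOC map (PTs absent from the map fall in
    the reserved ``unmapped`` bucket).  SMQ level returns every SMQ whose
    member set intersects the reactions — possibly empty; such reports are
    pooled under the not-applicable row downstream.  A report contributes
    each label at most once regardless of how many reactions map to it.
    """
    if level == "PT":
        return set(report.reactions)
    if level == "SOC":
        return {h.pt_to_soc.get(pt, SOC_UNMAPPED_LABEL) for pt in report.reactions}
    if level == "SMQ":
        return {smq for smq, pts in h.smq_members.items() if pts & report.reactions}
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
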