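"""Report ingestion: parsing, drug-name normalization, deduplication, inclusion filters.

Two input dialects are supported:

* ``faers`` — a minimal FAERS-style set of dollar-delimited ASCII tables
  (DEMO / DRUG / REAC / OUTC / INDI) joined on ``primaryid``, mirroring the
  layout of the quarterly FAERS extracts.
* ``csv`` — one row per report with ``;``-joined multi-valued cells, which
  keeps hand-written fixtures readable.

Both dialects round-trip exactly through the paired writers, so synthetic
collections can stand in for a curated FAERS download in every test.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for demographic values the reporter did not supply.  FAERS-style
#: data tabulates "Unknown" as a category of its own, so this is an explicit
#: value rather than None.
UNKNOWN = "unknown"

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "OT": "other",
}
OUTCOME_NAMES = {v: k for k, v in OUTCOME_CODES.items()}
SEX_VALUES = ("female", "male", UNKNOWN)
AGE_GROUPS = ("under18", "18plus", UNKNOWN)


class IngestError(Exception):
    """Raised for unreadable or structurally invalid input tables."""


@dataclass(frozen=True, order=True)
class Quarter:
    """A calendar year-quarter, ordered chronologically."""

    year: int
    q: int

    def __post_init__(self) -> None:
        if not 1 <= self.q <= 4:
            raise ValueError(f"quarter must be 1-4, got {self.q}")

    def __str__(self) -> str:
        return f"{self.year}Q{self.q}"

    @classmethod
    def parse(cls, text: str) -> "Quarter":
        year, _, q = text.upper().partition("Q")
        return cls(int(year), int(q))

    @classmethod
    def from_fda_dt(cls, fda_dt: str) -> "Quarter":
        """Derive the calendar quarter from a YYYYMMDD receipt date."""
        year, month = int(fda_dt[:4]), int(fda_dt[4:6])
        return cls(year, (month - 1) // 3 + 1)

    def to_fda_dt(self) -> str:
        # mid-quarter date; from_fda_dt inverts it
        return f"{self.year}{self.q * 3 - 1:02d}15"

    def index(self) -> int:
        return self.year * 4 + (self.q - 1)

    @classmethod
    def range(cls, start: "Quarter", end: "Quarter") -> list["Quarter"]:
        if start > end:
            raise ValueError(f"start quarter {start} after end {end}")
        out = []
        y, q = start.year, start.q
        while (y, q) <= (end.year, end.q):
            out.append(cls(y, q))
            y, q = (y + 1, 1) if q == 4 else (y, q + 1)
        return out


@dataclass(slots=True)
class Report:
    """One spontaneous safety report (a single version of a case).

    Treated as immutable by every operation in the package; stores and
    filters share Report instances rather than copying them.
    """

    case_id: str
    version: int
    quarter: Quarter
    drugs: tuple[tuple[str, str], ...]  # (canonical name, role code)
    reactions: frozenset[str]  # MedDRA preferred terms
    sex: str = UNKNOWN
    age_group: str = UNKNOWN
    country: str = UNKNOWN
    outcomes: frozenset[str] = frozenset()
    indication: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.version < 0:
            raise ValueError("version must be >= 0")

    def is_primary_suspect(self, drug: str) -> bool:
        return any(name == drug and role == "PS" for name, role in self.drugs)

    def has_drug(self, drug: str) -> bool:
        return any(name == drug for name, _ in self.drugs)


@dataclass
class ReportStore:
    """An ordered collection of reports with source provenance."""

    reports: list[Report] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.reports:
            key = (r.case_id, r.version)
            if key in seen:
                raise IngestError(f"duplicate case_id+version {key}")
            seen.add(key)


def normalize_drug_name(raw: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Case-fold, trim, and map through the synonym table.

    Unmapped names are returned case-folded, so downstream matching is
    always on canonical lowercase names.
    """
    name = raw.strip().casefold()
    if synonyms:
        return synonyms.get(name, name)
    return name


def _normalize_report_drugs(drugs: Iterable[tuple[str, str]],
                            synonyms: Mapping[str, str] | None) -> tuple[tuple[str, str], ...]:
    out = []
    for name, role in drugs:
        role = role.strip().upper()
        if role not in ROLE_CODES:
            logger.warning("unknown drug role %r treated as concomitant", role)
            role = "C"
        out.append((normalize_drug_name(name, synonyms), role))
    return tuple(out)


# ---------------------------------------------------------------------------
# FAERS-style dollar-delimited dialect
# ---------------------------------------------------------------------------

FAERS_TABLES = ("demo", "drug", "reac", "outc", "indi")
_MANDATORY = ("demo", "drug", "reac")


def _read_dollar_table(path: str | Path, name: str) -> pd.DataFrame:
    bad = 0

    def on_bad(line):  # pragma: no cover - exercised only on malformed input
        nonlocal bad
        bad += 1
        logger.warning("skipping malformed %s row: %s", name, line)
        return None

    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False,
                     engine="python", on_bad_lines=on_bad)
    total = len(df) + bad
    if total and bad / total > 0.10:
        raise IngestError(f"{name} table: {bad}/{total} rows malformed")
    return df


def read_faers_tables(paths: Mapping[str, str | Path],
                      synonyms: Mapping[str, str] | None = None) -> ReportStore:
    """Read a FAERS-style table set into a :class:`ReportStore`.

    ``paths`` maps lowercase table names (``demo``, ``drug``, ``reac``,
    optionally ``outc``, ``indi``) to file paths.  Tables are joined on the
    ``primaryid`` column; reports with no reaction rows are dropped with a
    warning, since a report without an adverse event carries no signal
    information.
    """
    paths = {k.lower(): v for k, v in paths.items()}
    for name in _MANDATORY:
        if name not in paths:
            raise IngestError(f"mandatory table {name!r} missing")

    demo = _read_dollar_table(paths["demo"], "demo")
    drug = _read_dollar_table(paths["drug"], "drug")
    reac = _read_dollar_table(paths["reac"], "reac")
    outc = _read_dollar_table(paths["outc"], "outc") if "outc" in paths else None
    indi = _read_dollar_table(paths["indi"], "indi") if "indi" in paths else None

    drugs_by_id: dict[str, list[tuple[str, str]]] = {}
    for row in drug.itertuples(index=False):
        drugs_by_id.setdefault(row.primaryid, []).append((row.drugname, row.role_cod))
    reac_by_id: dict[str, set[str]] = {}
    for row in reac.itertuples(index=False):
        reac_by_id.setdefault(row.primaryid, set()).add(row.pt)
    outc_by_id: dict[str, set[str]] = {}
    if outc is not None:
        for row in outc.itertuples(index=False):
            outc_by_id.setdefault(row.primaryid, set()).add(
                OUTCOME_CODES.get(row.outc_cod, "other"))
    indi_by_id: dict[str, str] = {}
    if indi is not None:
        for row in indi.itertuples(index=False):
            indi_by_id.setdefault(row.primaryid, row.indi_pt)

    reports: list[Report] = []
    dropped = 0
    for row in demo.itertuples(index=False):
        pid = row.primaryid
        pts = reac_by_id.get(pid)
        if not pts:
            dropped += 1
            continue
        reports.append(Report(
            case_id=row.caseid,
            version=int(row.caseversion),
            quarter=Quarter.from_fda_dt(row.fda_dt),
            drugs=_normalize_report_drugs(drugs_by_id.get(pid, []), synonyms),
            reactions=frozenset(pts),
            sex=getattr(row, "sex", UNKNOWN) or UNKNOWN,
            age_group=getattr(row, "age_grp", UNKNOWN) or UNKNOWN,
            country=getattr(row, "occr_country", UNKNOWN) or UNKNOWN,
            outcomes=frozenset(outc_by_id.get(pid, ())),
            indication=indi_by_id.get(pid, UNKNOWN),
        ))
    if dropped:
        logger.warning("dropped %d reports with no reaction rows", dropped)
    return ReportStore(reports, provenance=f"faers-tables:{paths['demo']}")


def write_faers_tables(store: ReportStore, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a store into the dollar-delimited table set (inverse of
    :func:`read_faers_tables` up to drug-name normalization)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / f"{name.upper()}.txt" for name in FAERS_TABLES}
    files = {name: open(p, "w", newline="") for name, p in paths.items()}
    try:
        w = {name: csv.writer(f, delimiter="$") for name, f in files.items()}
        w["demo"].writerow(["primaryid", "caseid", "caseversion", "fda_dt",
                            "sex", "age_grp", "occr_country"])
        w["drug"].writerow(["primaryid", "drugname", "role_cod"])
        w["reac"].writerow(["primaryid", "pt"])
        w["outc"].writerow(["primaryid", "outc_cod"])
        w["indi"].writerow(["primaryid", "indi_pt"])
        for r in store:
            pid = f"{r.case_id}.{r.version}"
            w["demo"].writerow([pid, r.case_id, r.version, r.quarter.to_fda_dt(),
                                r.sex, r.age_group, r.country])
            for name, role in r.drugs:
                w["drug"].writerow([pid, name, role])
            for pt in sorted(r.reactions):
                w["reac"].writerow([pid, pt])
            for oc in sorted(r.outcomes):
                w["outc"].writerow([pid, OUTCOME_NAMES[oc]])
            if r.indication != UNKNOWN:
                w["indi"].writerow([pid, r.indication])
    finally:
        for f in files.values():
            f.close()
    return paths


# ---------------------------------------------------------------------------
# Simple one-row-per-report CSV dialect
# ---------------------------------------------------------------------------

_CSV_HEADER = ["case_id", "version", "quarter", "drugs", "reactions",
               "sex", "age_group", "country", "outcomes", "indication"]


def read_simple_csv(path: str | Path,
                    synonyms: Mapping[str, str] | None = None) -> ReportStore:
    """Read the one-row-per-report CSV dialect.

    Multi-valued cells are ``;``-joined; drug entries are ``name:role`` pairs.
    """
    reports: list[Report] = []
    with open(path, newline="") as f:
        reader = csv.DictReader(f)
        for row in reader:
            if not row["reactions"]:
                logger.warning("dropping report %s with no reactions", row["case_id"])
                continue
            drugs = [tuple(entry.rsplit(":", 1)) for entry in row["drugs"].split(";") if entry]
            reports.append(Report(
                case_id=row["case_id"],
                version=int(row["version"]),
                quarter=Quarter.parse(row["quarter"]),
                drugs=_normalize_report_drugs(drugs, synonyms),
                reactions=frozenset(row["reactions"].split(";")),
                sex=row["sex"] or UNKNOWN,
                age_group=row["age_group"] or UNKNOWN,
                country=row["country"] or UNKNOWN,
                outcomes=frozenset(x for x in row["outcomes"].split(";") if x),
                indication=row["indication"] or UNKNOWN,
            ))
    return ReportStore(reports, provenance=f"csv:{path}")


def write_simple_csv(store: ReportStore, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(_CSV_HEADER)
        for r in store:
            writer.writerow([
                r.case_id, r.version, str(r.quarter),
                ";".join(f"{n}:{ro}" for n, ro in r.drugs),
                ";".join(sorted(r.reactions)),
                r.sex, r.age_group, r.country,
                ";".join(sorted(r.outcomes)),
                r.indication,
            ])
    return path


def read_synonyms(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV of (raw name, canonical name); keys case-folded."""
    out: dict[str, str] = {}
    with open(path, newline="") as f:
        for row in csv.reader(f, delimiter="\t"):
            if len(row) >= 2:
                out[row[0].strip().casefold()] = row[1].strip().casefold()
    return out


# ---------------------------------------------------------------------------
# Cleaning and inclusion filters
# ---------------------------------------------------------------------------

def deduplicate(store: ReportStore) -> ReportStore:
    """Keep exactly one report per case: the highest version.

    Version ties are broken by the latest receipt quarter, then by input
    order (last occurrence wins) — the FAERS convention that later
    transmissions supersede earlier ones.
    """
    best: dict[str, tuple[tuple[int, int, int], Report]] = {}
    for i, r in enumerate(store):
        key = (r.version, r.quarter.index(), i)
        if r.case_id not in best or key >= best[r.case_id][0]:
            best[r.case_id] = (key, r)
    kept = [r for _, r in sorted(best.values(), key=lambda kr: kr[0][2])]
    return ReportStore(kept, provenance=store.provenance + "|dedup")


def filter_primary_suspect(store: ReportStore, drug: str) -> ReportStore:
    """Retain only reports where ``drug`` (canonical name) has role PS."""
    kept = [r for r in store if r.is_primary_suspect(drug)]
    return ReportStore(kept, provenance=store.provenance + f"|ps:{drug}")


def filter_period(store: ReportStore, start: Quarter, end: Quarter) -> ReportStore:
    """Retain reports received in [start, end] inclusive on both ends."""
    if start > end:
        raise ValueError(f"start quarter {start} after end {end}")
    kept = [r for r in store if start <= r.quarter <= end]
    return ReportStore(kept, provenance=store.provenance + f"|window:{start}-{end}")
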