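"""Frequency summaries of report characteristics (year, sex, age, country,
outcomes, indications) with round-half-up percentages."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .ingest import ReportStore, UNKNOWN

#: Fields summarize() accepts.  ``outcome`` is multi-valued: a report may
#: carry several outcome codes and counts toward each; every other field is
#: single-valued per report.
FIELDS = ("year", "sex", "age_group", "country", "outcome", "indication")

_OUTCOME_ORDER = ("death", "life_threatening", "hospitalization",
                  "disability", "other", UNKNOWN)
#: Fields whose long category tails are pooled into "Other".
_POOLED = ("country", "indication")


@dataclass(frozen=True)
class FrequencyTable:
    field: str
    rows: tuple[tuple[str, int, str], ...]  # (category, count, percent)
    total: int


def percent(n: int, total: int) -> str:
    """100*n/total as a 2-decimal round-half-up string; caller guards total=0."""
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Decimal(100) * Decimal(n) / Decimal(total)
    return str(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize(store: ReportStore, field: str,
              top_n: int | None = None) -> FrequencyTable:
    """Tabulate one characteristic over a deduplicated, drug-filtered store.

    Categories are sorted by count descending (years ascending); the unknown
    sentinel is always tabulated when present.  For country and indication,
    categories beyond ``top_n`` are pooled into ``"Other"`` (the unknown
    sentinel is never pooled).  Outcomes are counted per report per outcome
    code; a report with no outcome codes counts as unknown.
    """
    if field not in FIELDS:
        raise ValueError(f"unknown field {field!r}; expected one of {FIELDS}")
    total = len(store)
    counts: Counter[str] = Counter()
    for r in store:
        if field == "year":
            counts[str(r.quarter.year)] += 1
        elif field == "outcome":
            if r.outcomes:
                counts.update(r.outcomes)
            else:
                counts[UNKNOWN] += 1
        else:
            counts[getattr(r, field)] += 1

    if field == "year":
        cats = sorted(counts)
    elif field == "outcome":
        cats = [c for c in _OUTCOME_ORDER if c in counts]
        cats += sorted(set(counts) - set(cats))
    else:
        cats = sorted(counts, key=lambda c: (-counts[c], c))

    if top_n is not None and field in _POOLED:
        keep = [c for c in cats if c != UNKNOWN][:top_n]
        pooled = sum(counts[c] for c in cats if c not in keep and c != UNKNOWN)
        cats = keep + ([UNKNOWN] if UNKNOWN in counts else [])
        if pooled:
            counts["Other"] = pooled
            cats.append("Other")

    rows = tuple((c, counts[c], percent(counts[c], total)) for c in cats)
    return FrequencyTable(field=field, rows=rows, total=total)


def render(table: FrequencyTable) -> str:
    """TSV rendering: category, count, percent."""
    lines = [f"# {table.field}\tn={table.total}", "category\tcount\tpercent"]
    lines += [f"{c}\t{n}\t{p}" for c, n, p in table.rows]
    return "\n".join(lines) + "\n"
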