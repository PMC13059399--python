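#!/usr/bin/env python
"""Descriptive summary of the primary-suspect reports in the simulated extract.

Mirrors the report-characteristics table of a pharmacovigilance study:
deduplicate case versions, restrict to the quarter window and the analysis
drug as primary suspect, then tabulate year, sex, age group, country,
serious outcomes and indications with round-half-up percentages.
Writes one TSV per field under results/analysis/.
"""

import argparse
from pathlib import Path

from pvsignal.descriptives import FIELDS, render, summarize
from pvsignal.ingest import (Quarter, deduplicate, filter_period,
                             filter_primary_suspect, read_simple_csv)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path, default=Path("scratch/sim/reports.csv"))
    ap.add_argument("--drug", default="drug000")
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    raw = read_simple_csv(args.input)
    deduped = deduplicate(raw)
    windowed = filter_period(deduped, Quarter(2018, 1), Quarter(2024, 3))
    ps = filter_primary_suspect(windowed, args.drug)
    print(f"funnel: {len(raw)} rows -> {len(deduped)} cases -> "
          f"{len(windowed)} in window -> {len(ps)} PS for {args.drug} "
          f"({100 * len(ps) / len(windowed):.4f}%)")

    args.out.mkdir(parents=True, exist_ok=True)
    for field in FIELDS:
        tab = summarize(ps, field, top_n=7 if field == "indication" else
                        5 if field == "country" else None)
        (args.out / f"descriptives_{field}.tsv").write_text(render(tab))
    print(f"wrote descriptive tables for {', '.join(FIELDS)} to {args.out}")
    print(render(summarize(ps, "sex")))


if __name__ == "__main__":
    main()
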