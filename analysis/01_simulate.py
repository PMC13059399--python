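#!/usr/bin/env python
"""Generate the synthetic FAERS-like extract used by the downstream analyses.

Draws the standard study conditions (50,000 reports, 25 drugs, 100 PTs,
analysis drug primary-suspect on ~2% of reports, >99% sex/age missingness,
5% duplicated cases) with three embedded rr=20 signals on the analysis drug,
and writes the extract in both supported dialects plus the synthetic MedDRA
hierarchy under scratch/sim/.
"""

import argparse
from pathlib import Path

from pvsignal.ingest import write_faers_tables, write_simple_csv
from pvsignal.meddra import write_hierarchy
from pvsignal.synthetic import (SignalSpec, SimConfig, drug_name,
                                generate_reports, make_meddra, pt_name)

SIGNALS = (SignalSpec(0, 7, 20.0), SignalSpec(0, 11, 20.0),
           SignalSpec(0, 23, 20.0))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("scratch/sim"))
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed, signals=SIGNALS)
    store = generate_reports(cfg)
    h = make_meddra(cfg, n_socs=10,
                    smq_specs=[("smq_renal", {pt_name(j) for j in range(0, 30)}),
                               ("smq_msk", {pt_name(j) for j in range(25, 60)})])
    args.out.mkdir(parents=True, exist_ok=True)
    write_simple_csv(store, args.out / "reports.csv")
    write_faers_tables(store, args.out / "faers")
    write_hierarchy(h, args.out / "pt_soc.tsv", args.out / "smq.tsv")
    with open(args.out / "ground_truth.tsv", "w") as f:
        f.write("drug\tevent\trr\n")
        for s in SIGNALS:
            f.write(f"{drug_name(s.drug_id)}\t{pt_name(s.event_id)}\t{s.rr}\n")

    n_cases = len({r.case_id for r in store})
    print(f"wrote {len(store)} report rows ({n_cases} distinct cases) to {args.out}")
    print(f"embedded signals: " + ", ".join(
        f"{drug_name(s.drug_id)} x {pt_name(s.event_id)} (rr={s.rr})" for s in SIGNALS))


if __name__ == "__main__":
    main()
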