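"""End-to-end orchestration: ingest -> deduplicate -> window -> descriptives
and per-level disproportionality screens with ranked outputs.

One ingest pass feeds two result streams: descriptive frequency tables run
on the primary-suspect-filtered store, while the contingency tables run on
the full deduplicated background store (every report in the window), which
the 2x2 background columns require.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dastats import DAResult, Thresholds, compute_all, round2
from .descriptives import FIELDS, render, summarize
from .ingest import (Quarter, ReportStore, deduplicate, filter_period,
                     filter_primary_suspect, read_faers_tables,
                     read_simple_csv, read_synonyms)
from .meddra import LEVELS, SMQ_NA_LABEL, SOC_UNMAPPED_LABEL, load_hierarchy

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("label", "case_reports", "ROR", "ROR_lo95", "ROR_hi95",
                  "PRR", "chi2", "EBGM", "EBGM05", "IC", "IC025", "signal")

#: Reserved labels excluded from ranked signal tables (kept in full dumps).
_EXCLUDED_FROM_RANKING = {SMQ_NA_LABEL, SOC_UNMAPPED_LABEL}


@dataclass(frozen=True)
class PipelineConfig:
    input: str
    format: str  # "faers" (directory of $-tables) or "csv"
    drug: str
    pt_soc_path: str
    smq_path: str | None = None
    synonyms_path: str | None = None
    quarter_start: Quarter = Quarter(2018, 1)
    quarter_end: Quarter = Quarter(2024, 3)
    thresholds: Thresholds = field(default_factory=Thresholds)
    levels: tuple[str, ...] = ("PT", "SOC", "SMQ")
    top_n: int = 30
    out_dir: str = "results"
    count_unit: str = "report"
    ic_method: str = "closed"
    yates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("level set must be nonempty")
        for lv in self.levels:
            if lv not in LEVELS:
                raise ValueError(f"unknown level {lv!r}")
        if self.quarter_start > self.quarter_end:
            raise ValueError("invalid quarter window")


def rank_results(results: list[DAResult], key: str = "ic025",
                 descending: bool = True) -> list[DAResult]:
    """Order results by a statistic; ties broken by case count descending,
    then label lexicographic."""
    if key not in ("ic025", "a", "ebgm05"):
        raise ValueError(f"unsupported ranking key {key!r}")
    sign = -1.0 if descending else 1.0
    return sorted(results, key=lambda r: (sign * getattr(r, key), -r.a, r.label))


def top_n(ordered: list[DAResult], n: int) -> list[DAResult]:
    if n < 1:
        raise ValueError("n must be >= 1")
    return ordered[:n]


def results_tsv(results: list[DAResult]) -> str:
    lines = ["\t".join(RESULT_COLUMNS)]
    for r in results:
        lines.append("\t".join([
            r.label, str(r.a), round2(r.ror), round2(r.ror_lo95),
            round2(r.ror_hi95), round2(r.prr), round2(r.chi2),
            round2(r.ebgm), round2(r.ebgm05), round2(r.ic), round2(r.ic025),
            str(int(r.signal)),
        ]))
    return "\n".join(lines) + "\n"


def load_store(cfg: PipelineConfig) -> ReportStore:
    synonyms = read_synonyms(cfg.synonyms_path) if cfg.synonyms_path else None
    if cfg.format == "faers":
        d = Path(cfg.input)
        paths = {name: d / f"{name.upper()}.txt"
                 for name in ("demo", "drug", "reac", "outc", "indi")
                 if (d / f"{name.upper()}.txt").exists()}
        return read_faers_tables(paths, synonyms)
    if cfg.format == "csv":
        return read_simple_csv(cfg.input, synonyms)
    raise ValueError(f"unknown input format {cfg.format!r}")


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the whole screen and write all outputs under ``cfg.out_dir``.

    Outputs: one TSV per descriptive field, a full result TSV and a top-N
    TSV (ranked by IC025 descending) per aggregation level, and a
    provenance YAML recording the report funnel and config hash.  Outputs
    are byte-deterministic for fixed inputs and config.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = load_hierarchy(cfg.pt_soc_path, cfg.smq_path)

    raw = load_store(cfg)
    deduped = deduplicate(raw)
    background = filter_period(deduped, cfg.quarter_start, cfg.quarter_end)
    ps_store = filter_primary_suspect(background, cfg.drug)
    logger.info("funnel: %d raw -> %d deduplicated -> %d in window -> %d PS for %s",
                len(raw), len(deduped), len(background), len(ps_store), cfg.drug)

    for fld in FIELDS:
        tab = summarize(ps_store, fld, top_n=7 if fld == "indication" else
                        5 if fld == "country" else None)
        (out / f"descriptives_{fld}.tsv").write_text(render(tab))

    level_summaries = {}
    for level in cfg.levels:
        results = compute_all(background, cfg.drug, level, h,
                              th=cfg.thresholds, count_unit=cfg.count_unit,
                              ic_method=cfg.ic_method, yates=cfg.yates)
        rankable = [r for r in results if r.label not in _EXCLUDED_FROM_RANKING]
        ranked = rank_results(rankable, key="ic025", descending=True)
        (out / f"signals_{level}_full.tsv").write_text(results_tsv(results))
        (out / f"signals_{level}_top{cfg.top_n}.tsv").write_text(
            results_tsv(top_n(ranked, cfg.top_n)))
        level_summaries[level] = {
            "labels": len(results),
            "signals": sum(r.signal for r in results),
        }

    from importlib.metadata import version as _dist_version
    try:
        pkg_version = _dist_version("pvsignal")
    except Exception:
        pkg_version = "unknown"
    provenance = {
        "version": pkg_version,
        "config_hash": _config_hash(cfg),
        "drug": cfg.drug,
        "window": [str(cfg.quarter_start), str(cfg.quarter_end)],
        "n_raw": len(raw),
        "n_deduplicated": len(deduped),
        "N": len(background),
        "drug_total": len(ps_store),
        "levels": level_summaries,
    }
    (out / "provenance.yaml").write_text(
        yaml.safe_dump(provenance, sort_keys=True))
    return provenance
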