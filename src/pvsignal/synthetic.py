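"""Synthetic spontaneous-reporting-system generator with known ground truth.

Emulates a curated FAERS quarterly extract at desk scale: multi-drug,
multi-event reports with role codes, near-total demographic missingness,
duplicate case versions, country / outcome / indication fields, and embedded
drug-event signals of configurable strength.  The sampling scheme is simple
enough that the expected 2x2 table of any (drug, event) pair has a closed
form (:func:`expected_counts`), which serves as the oracle for recovery
tests of the whole downstream pipeline.

Sampling scheme per report:

1. a primary-suspect (PS) drug is drawn from ``background_drug_rates``;
2. the number of event draws ``k`` is geometric on {1, 2, ...} with mean
   ``mean_events_per_report``;
3. ``k`` preferred terms are drawn i.i.d. from the event distribution
   conditional on the PS drug — the background ``background_event_rates``
   with every signalled event's probability multiplied by its ``rr`` and the
   vector renormalized — and the report's reaction set is the distinct set;
4. secondary-suspect / concomitant drugs, demographics (with configured
   unknown-probabilities), country, outcomes, indication and receipt quarter
   are filled in independently of the signal structure;
5. a configurable fraction of cases is emitted twice, as version 0 plus a
   version-1 update with resampled demographics, to exercise deduplication.

Under this scheme, P(event e appears on a report | PS drug d) is exactly
``1 - G(1 - q_e(d))`` where ``G`` is the probability generating function of
the geometric event count and ``q_e(d)`` the renormalized conditional event
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ingest import Quarter, Report, ReportStore, UNKNOWN
from .meddra import MedDRAHierarchy


class SimConfigError(ValueError):
    """Invalid generator configuration."""


def drug_name(i: int) -> str:
    return f"drug{i:03d}"


def pt_name(j: int) -> str:
    return f"pt{j:03d}"


def soc_name(s: int) -> str:
    return f"soc{s:02d}"


# Realistic desk-scale defaults for the ancillary fields, shaped like the
# demographic profile of a rare-disease biologic extract: reporting heavily
# concentrated in one country, sex/age almost always unreported, outcomes
# mostly absent, one dominant indication.
COUNTRY_DIST = (("us", 0.935), ("gb", 0.022), ("de", 0.010), ("fr", 0.008),
                ("jp", 0.005), ("other", 0.020))
INDICATION_DIST = (("hereditary hypophosphataemic rickets", 0.780),
                   (UNKNOWN, 0.147),
                   ("hypophosphataemic osteomalacia", 0.019),
                   ("hypophosphataemia", 0.018),
                   ("phosphorus metabolism disorder", 0.017),
                   ("osteomalacia", 0.008),
                   ("rickets", 0.002),
                   ("other", 0.009))
OUTCOME_RATES = (("death", 0.006), ("life_threatening", 0.0014),
                 ("hospitalization", 0.063), ("disability", 0.002),
                 ("other", 0.120))
P_FEMALE_GIVEN_KNOWN = 0.6
P_UNDER18_GIVEN_KNOWN = 0.53


@dataclass(frozen=True)
class SignalSpec:
    """An embedded drug-event signal: multiplier ``rr`` on the event's
    conditional reporting probability given the PS drug."""

    drug_id: int
    event_id: int
    rr: float

    def __post_init__(self) -> None:
        if self.rr < 0:
            raise SimConfigError("rr must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the standard study conditions.

    The default extract has 50,000 reports over 25 drugs and a 100-PT
    vocabulary, with the analysis drug (``drug000``) primary suspect on 2%
    of reports, two event draws per report on average, sex/age unknown on
    >99% of reports, and 5% of cases duplicated as a second version.
    """

    seed: int
    n_reports: int = 50_000
    n_drugs: int = 25
    n_events: int = 100
    background_drug_rates: tuple[float, ...] | None = None
    background_event_rates: tuple[float, ...] | None = None
    mean_events_per_report: float = 2.0
    signals: tuple[SignalSpec, ...] = ()
    miss_sex: float = 0.995
    miss_age: float = 0.997
    miss_country: float = 0.0
    duplicate_rate: float = 0.05
    quarter_start: Quarter = Quarter(2018, 1)
    quarter_end: Quarter = Quarter(2024, 3)
    mean_extra_drugs: float = 0.7

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise SimConfigError("n_reports must be >= 1")
        if self.n_drugs < 1 or self.n_events < 1:
            raise SimConfigError("vocabulary sizes must be >= 1")
        if self.mean_events_per_report < 1:
            raise SimConfigError("mean_events_per_report must be >= 1")
        if self.background_drug_rates is None:
            object.__setattr__(self, "background_drug_rates",
                               _default_drug_rates(self.n_drugs))
        if self.background_event_rates is None:
            object.__setattr__(self, "background_event_rates",
                               tuple([1.0 / self.n_events] * self.n_events))
        for name, vec, size in (("background_drug_rates", self.background_drug_rates, self.n_drugs),
                                ("background_event_rates", self.background_event_rates, self.n_events)):
            if len(vec) != size:
                raise SimConfigError(f"{name} length {len(vec)} != {size}")
            if any(p < 0 or p > 1 for p in vec):
                raise SimConfigError(f"{name} entries must lie in [0, 1]")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise SimConfigError(f"{name} must sum to 1 (got {sum(vec)!r})")
        for name, p in (("miss_sex", self.miss_sex), ("miss_age", self.miss_age),
                        ("miss_country", self.miss_country),
                        ("duplicate_rate", self.duplicate_rate)):
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        for s in self.signals:
            if not (0 <= s.drug_id < self.n_drugs and 0 <= s.event_id < self.n_events):
                raise SimConfigError(f"signal {s} references unknown drug/event id")
        if self.quarter_start > self.quarter_end:
            raise SimConfigError("quarter_start after quarter_end")


def _default_drug_rates(n_drugs: int) -> tuple[float, ...]:
    # analysis drug (index 0) primary-suspect on 2% of reports
    if n_drugs == 1:
        return (1.0,)
    rest = 0.98 / (n_drugs - 1)
    return (0.02,) + tuple([rest] * (n_drugs - 1))


def conditional_event_dist(config: SimConfig, drug_id: int) -> np.ndarray:
    """Event distribution given PS drug: background with signalled events'
    probabilities multiplied by rr, renormalized."""
    q = np.array(config.background_event_rates, dtype=float)
    for s in config.signals:
        if s.drug_id == drug_id:
            q[s.event_id] *= s.rr
    total = q.sum()
    if total <= 0:
        raise SimConfigError("conditional event distribution degenerate")
    return q / total


def event_given_drug_prob(config: SimConfig, drug_id: int, event_id: int) -> float:
    """Closed-form P(event appears on a report | PS drug).

    With geometric event count K on {1,2,...} at success probability
    p = 1/mean, the PGF is G(s) = ps / (1 - (1-p)s), so the probability the
    event is missed in all K draws is G(1 - q) and
    P(present) = 1 - G(1 - q).
    """
    q = float(conditional_event_dist(config, drug_id)[event_id])
    p = 1.0 / config.mean_events_per_report
    s = 1.0 - q
    return 1.0 - p * s / (1.0 - (1.0 - p) * s)


def expected_counts(config: SimConfig,
                    pair: tuple[int, int]) -> tuple[float, float, float, float]:
    """Expected (a, b, c, d) of the pair's 2x2 table under the sampling
    scheme, counting distinct deduplicated reports; sums to ``n_reports``."""
    d_id, e_id = pair
    if not (0 <= d_id < config.n_drugs and 0 <= e_id < config.n_events):
        raise KeyError(f"unknown (drug, event) pair {pair}")
    n = config.n_reports
    p_drug = config.background_drug_rates[d_id]
    ea = n * p_drug * event_given_drug_prob(config, d_id, e_id)
    eb = n * p_drug - ea
    ec = n * sum(config.background_drug_rates[dd]
                 * event_given_drug_prob(config, dd, e_id)
                 for dd in range(config.n_drugs) if dd != d_id)
    return ea, eb, ec, n - ea - eb - ec


def make_meddra(config: SimConfig, n_socs: int,
                smq_specs: list[tuple[str, set[str]]] | None = None) -> MedDRAHierarchy:
    """Synthetic event hierarchy: PT j belongs to SOC (j mod n_socs)."""
    if not 1 <= n_socs <= config.n_events:
        raise SimConfigError("need 1 <= n_socs <= n_events")
    pt_to_soc = {pt_name(j): soc_name(j % n_socs) for j in range(config.n_events)}
    members: dict[str, frozenset[str]] = {}
    for name, pts in (smq_specs or []):
        pts = frozenset(pts)
        if not pts:
            raise SimConfigError(f"SMQ {name!r} is empty")
        unknown = pts - pt_to_soc.keys()
        if unknown:
            raise SimConfigError(f"SMQ {name!r} references unknown PTs {sorted(unknown)}")
        members[name] = pts
    return MedDRAHierarchy(pt_to_soc, members)


def generate_reports(config: SimConfig) -> ReportStore:
    """Draw a report collection under the configured scheme.

    Exactly ``n_reports`` distinct case ids are produced; duplicated cases
    append a version-1 update after all originals.  Bit-identical output
    for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    ps_drug = rng.choice(config.n_drugs, size=n, p=np.array(config.background_drug_rates))
    k = rng.geometric(1.0 / config.mean_events_per_report, size=n)

    # event draws, grouped by conditional distribution to vectorize rng.choice
    signal_drugs = sorted({s.drug_id for s in config.signals})
    events = np.empty(int(k.sum()), dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(k)])
    flat_report = np.repeat(np.arange(n), k)
    bg_mask = ~np.isin(ps_drug, signal_drugs)
    for group_drug in [None] + signal_drugs:
        mask = bg_mask if group_drug is None else (ps_drug == group_drug)
        flat_sel = mask[flat_report]
        total = int(flat_sel.sum())
        if total == 0:
            continue
        dist = (np.array(config.background_event_rates) if group_drug is None
                else conditional_event_dist(config, group_drug))
        events[flat_sel] = rng.choice(config.n_events, size=total, p=dist)

    n_extra = rng.poisson(config.mean_extra_drugs, size=n)
    extra_names = rng.choice(config.n_drugs, size=int(n_extra.sum()),
                             p=np.array(config.background_drug_rates))
    extra_roles = rng.choice(np.array(["SS", "C"]), size=int(n_extra.sum()))
    extra_off = np.concatenate([[0], np.cumsum(n_extra)])

    sex_known = rng.random(n) >= config.miss_sex
    sex_female = rng.random(n) < P_FEMALE_GIVEN_KNOWN
    age_known = rng.random(n) >= config.miss_age
    age_under = rng.random(n) < P_UNDER18_GIVEN_KNOWN
    country_known = rng.random(n) >= config.miss_country
    countries = rng.choice([c for c, _ in COUNTRY_DIST], size=n,
                           p=[p for _, p in COUNTRY_DIST])
    outc_draws = rng.random((n, len(OUTCOME_RATES)))
    indications = rng.choice([c for c, _ in INDICATION_DIST], size=n,
                             p=[p for _, p in INDICATION_DIST])
    quarters = Quarter.range(config.quarter_start, config.quarter_end)
    q_idx = rng.integers(0, len(quarters), size=n)
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_sex_female = rng.random(n) < P_FEMALE_GIVEN_KNOWN

    width = len(str(max(n - 1, 1)))
    drug_names = [drug_name(i) for i in range(config.n_drugs)]
    pt_names = [pt_name(j) for j in range(config.n_events)]
    outcome_names = [name for name, _ in OUTCOME_RATES]
    outc_mask = (outc_draws < np.array([r for _, r in OUTCOME_RATES])).tolist()

    # pull everything out of numpy once; the per-report loop is pure python
    ps_l, ev_l, off_l = ps_drug.tolist(), events.tolist(), offsets.tolist()
    extra_names_l, extra_roles_l = extra_names.tolist(), extra_roles.tolist()
    extra_off_l = extra_off.tolist()
    sexes = [("female" if f else "male") if kn else UNKNOWN
             for kn, f in zip(sex_known.tolist(), sex_female.tolist())]
    ages = [("under18" if u else "18plus") if kn else UNKNOWN
            for kn, u in zip(age_known.tolist(), age_under.tolist())]
    countries_l = [c if kn else UNKNOWN
                   for kn, c in zip(country_known.tolist(), countries.tolist())]
    indications_l = indications.tolist()
    q_l = [quarters[i] for i in q_idx.tolist()]
    dup_l, dup_sex_l = dup_mask.tolist(), dup_sex_female.tolist()

    reports: list[Report] = []
    dups: list[Report] = []
    for i in range(n):
        drugs = [(drug_names[ps_l[i]], "PS")]
        drugs += [(drug_names[extra_names_l[j]], extra_roles_l[j])
                  for j in range(extra_off_l[i], extra_off_l[i + 1])]
        rep = Report(
            case_id=f"C{i:0{width}d}",
            version=0,
            quarter=q_l[i],
            drugs=tuple(drugs),
            reactions=frozenset(pt_names[e] for e in ev_l[off_l[i]:off_l[i + 1]]),
            sex=sexes[i],
            age_group=ages[i],
            country=countries_l[i],
            outcomes=frozenset(name for name, hit in zip(outcome_names, outc_mask[i]) if hit),
            indication=indications_l[i],
        )
        reports.append(rep)
        if dup_l[i]:
            # version-1 update: same clinical content, demographics may change
            dups.append(Report(
                case_id=rep.case_id, version=1, quarter=rep.quarter,
                drugs=rep.drugs, reactions=rep.reactions,
                sex=("female" if dup_sex_l[i] else "male") if sexes[i] != UNKNOWN else UNKNOWN,
                age_group=rep.age_group, country=rep.country,
                outcomes=rep.outcomes, indication=rep.indication,
            ))
    return ReportStore(reports + dups, provenance=f"synthetic:seed={config.seed}")
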