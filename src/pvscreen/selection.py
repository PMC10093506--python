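"""Inclusion/exclusion criteria and deduplication for the renal case set.

Rules are applied in a fixed order (window, reporter, drug, event, age, sex)
and every rejected report is attributed to the FIRST failing rule, so the
audit trail is reproducible. Deduplication uses a deterministic field key —
the probabilistic record-linkage used on the real database is out of scope
and replaced by this declared stand-in.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .icsr import HP_REPORTERS, ICSR, IcsrStore
from .meddra import TermDictionary

__all__ = [
    "RULE_ORDER",
    "SelectionConfig",
    "SelectionAudit",
    "deduplicate",
    "is_case",
    "select_cases",
]

RULE_ORDER = ("window", "reporter", "drug", "event", "age", "sex")


@dataclass(frozen=True)
class SelectionConfig:
    date_window: tuple[date, date]
    index_drugs: frozenset[str]
    event_hlts: frozenset[str]
    allowed_roles: frozenset[str] = frozenset({"suspected", "interacting"})
    hp_reporters: frozenset[str] = HP_REPORTERS
    require_age: bool = True
    require_sex: bool = True

    def __post_init__(self) -> None:
        if self.date_window[0] > self.date_window[1]:
            raise ValueError("date_window start must not exceed end")
        if not self.allowed_roles:
            raise ValueError("allowed_roles must be nonempty")


@dataclass
class SelectionAudit:
    """Per-rule rejection counts; n_in − n_out == sum of rejections."""

    n_in: int = 0
    n_out: int = 0
    n_duplicates_removed: int = 0
    rejected: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})

    def check(self) -> None:
        if self.n_in - self.n_out != sum(self.rejected.values()):
            raise AssertionError("audit counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_in), ("duplicates_removed", self.n_duplicates_removed)]
        rows += [(f"rejected_{r}", self.rejected[r]) for r in RULE_ORDER]
        rows.append(("cases", self.n_out))
        return pd.DataFrame(rows, columns=["step", "count"])


def _dedup_key(report: ICSR):
    age = None if report.age_years is None else round(report.age_years)
    return (
        report.country,
        report.sex,
        age,
        tuple(sorted(report.drug_codes(roles={"suspected"}))),
        tuple(sorted(report.pt_codes())),
        report.report_date,
    )


def deduplicate(store: IcsrStore) -> tuple[IcsrStore, list[str]]:
    """Collapse reports sharing the duplicate key to the lowest report_id.

    Key: (country, sex, rounded age, sorted suspected-drug codes, sorted PT
    codes, report date). Returns the deduplicated store and the removed ids.
    Idempotent.
    """
    survivors: dict[tuple, ICSR] = {}
    removed: list[str] = []
    for report in store:
        key = _dedup_key(report)
        kept = survivors.get(key)
        if kept is None:
            survivors[key] = report
        elif report.report_id < kept.report_id:
            removed.append(kept.report_id)
            survivors[key] = report
        else:
            removed.append(report.report_id)
    kept_ids = {r.report_id for r in survivors.values()}
    return (
        IcsrStore(r for r in store if r.report_id in kept_ids),
        sorted(removed),
    )


def is_case(
    report: ICSR,
    config: SelectionConfig,
    dictionary: TermDictionary,
    event_pts: frozenset[str] | None = None,
) -> tuple[bool, list[str]]:
    """Evaluate every selection rule; returns (flag, failed-rule names).

    ``event_pts`` may be passed to reuse a precomputed HLT expansion. Raises
    if a reaction PT is absent from the dictionary.
    """
    for r in report.reactions:
        dictionary.term(r.pt_code)  # raises DictionaryError if unknown
    if event_pts is None:
        event_pts = dictionary.pts_under(config.event_hlts)

    reasons = []
    lo, hi = config.date_window
    if not lo <= report.report_date <= hi:
        reasons.append("window")
    if report.reporter not in config.hp_reporters:
        reasons.append("reporter")
    if not _single_index_drug(report, config):
        reasons.append("drug")
    if not any(r.pt_code in event_pts for r in report.reactions):
        reasons.append("event")
    if config.require_age and report.age_years is None:
        reasons.append("age")
    if config.require_sex and report.sex == "unknown":
        reasons.append("sex")
    return (not reasons, reasons)


def _single_index_drug(report: ICSR, config: SelectionConfig) -> bool:
    # an index drug with an allowed role, and no OTHER drug named as suspected
    suspected = {d.drug_code for d in report.drugs if d.role == "suspected"}
    for d in report.drugs:
        if d.drug_code in config.index_drugs and d.role in config.allowed_roles:
            if suspected <= {d.drug_code}:
                return True
    return False


def select_cases(
    store: IcsrStore, config: SelectionConfig, dictionary: TermDictionary
) -> tuple[IcsrStore, SelectionAudit]:
    """Deduplicate, then filter; audit counts attributed in rule order."""
    deduped, removed = deduplicate(store)
    audit = SelectionAudit(n_in=len(deduped), n_duplicates_removed=len(removed))
    event_pts = dictionary.pts_under(config.event_hlts)
    cases = []
    for report in deduped:
        ok, reasons = is_case(report, config, dictionary, event_pts=event_pts)
        if ok:
            cases.append(report)
        else:
            audit.rejected[reasons[0]] += 1
    audit.n_out = len(cases)
    audit.check()
    return IcsrStore(cases), audit
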