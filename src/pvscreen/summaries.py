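"""Cohort characteristics and time-to-onset summaries for the selected cases.

Conventions (documented because the outputs are meant to be reproducible
bit-for-bit): percentages are rounded half-up to integers; the standard
deviation is the sample SD (n−1); quantiles use linear interpolation between
order statistics. A case carries one aggregated outcome, derived from its
reaction outcomes by a fixed severity priority (fatal > not recovered >
recovered with sequelae > recovering > recovered > unknown).
"""
from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .icsr import ICSR, IcsrStore, time_to_onset
from .meddra import TermDictionary

__all__ = [
    "percent",
    "CharacteristicsBlock",
    "CharacteristicsTable",
    "TtoSummary",
    "characteristics",
    "tto_summary",
    "tto_to_frame",
]

_OUTCOME_PRIORITY = (
    "fatal",
    "not_recovered",
    "recovered_with_sequelae",
    "recovering",
    "recovered",
    "unknown",
)


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-up (banker's rounding deliberately avoided)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(math.floor(100 * numerator / denominator + 0.5))


def report_outcome(report: ICSR) -> str:
    """Aggregate reaction outcomes to one case-level outcome by severity."""
    outcomes = {r.outcome for r in report.reactions}
    for level in _OUTCOME_PRIORITY:
        if level in outcomes:
            return level
    return "unknown"


def report_seriousness(report: ICSR) -> str:
    """'serious' | 'not_serious' | 'unknown' at report level."""
    flags = report.serious_flags_union()
    if flags:
        return "serious"
    reported = [r.serious_flags for r in report.reactions]
    if all(f is not None for f in reported):
        return "not_serious"
    return "unknown"


@dataclass
class CharacteristicsBlock:
    n: int
    age_mean: Optional[float]
    age_sd: Optional[float]
    sex_counts: dict[str, int]
    hlt_counts: dict[str, int]
    seriousness_counts: dict[str, int]
    outcome_counts: dict[str, int]
    discontinued: int
    top_countries: list[tuple[str, int]]
    top_indications: list[tuple[str, int]]


@dataclass
class CharacteristicsTable:
    """One block per index drug plus an 'all' block (cohort overall)."""

    per_drug: dict[str, CharacteristicsBlock]
    overall: CharacteristicsBlock

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for drug, block in {**self.per_drug, "all": self.overall}.items():
            n = block.n
            rows.append((drug, "cohort", "n", block.n, None))
            rows.append((drug, "age", "mean", block.age_mean, None))
            rows.append((drug, "age", "sd", block.age_sd, None))
            for section, counts in (
                ("sex", block.sex_counts),
                ("hlt", block.hlt_counts),
                ("seriousness", block.seriousness_counts),
                ("outcome", block.outcome_counts),
            ):
                for cat, cnt in sorted(counts.items()):
                    rows.append((drug, section, cat, cnt, percent(cnt, n) if n else None))
            rows.append(
                (drug, "action", "discontinued", block.discontinued,
                 percent(block.discontinued, n) if n else None)
            )
            for country, cnt in block.top_countries:
                rows.append((drug, "country", country, cnt, percent(cnt, n) if n else None))
            for ind, cnt in block.top_indications:
                rows.append((drug, "indication", ind, cnt, percent(cnt, n) if n else None))
        return pd.DataFrame(rows, columns=["drug", "section", "category", "count", "pct"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            self.to_frame().to_json(orient="records", indent=2)
        )


@dataclass(frozen=True)
class TtoSummary:
    drug_code: str
    hlt_code: str
    n_with_tto: int
    n_total: int
    median: Optional[float]
    q25: Optional[float]
    q75: Optional[float]
    mean: Optional[float]
    sd: Optional[float]
    display: bool

    def __post_init__(self) -> None:
        if self.n_with_tto > self.n_total:
            raise ValueError("n_with_tto cannot exceed n_total")
        if self.median is not None:
            assert self.q25 <= self.median <= self.q75


def _index_entry(report: ICSR, index_drugs: frozenset[str]):
    for d in report.drugs:
        if d.drug_code in index_drugs and d.role in {"suspected", "interacting"}:
            return d
    raise ValueError(
        f"{report.report_id}: no index drug entry — not a selected case"
    )


def _case_hlts(
    report: ICSR, dictionary: TermDictionary, event_hlts: Optional[frozenset[str]]
) -> frozenset[str]:
    out: set[str] = set()
    for r in report.reactions:
        hlts = dictionary.hlts_of_pt(r.pt_code)
        if event_hlts is not None:
            hlts &= event_hlts
        out |= hlts
    return frozenset(out)


def characteristics(
    cases: IcsrStore,
    index_drugs: Iterable[str],
    dictionary: TermDictionary,
    event_hlts: Optional[Iterable[str]] = None,
    top_k_countries: int = 5,
    top_k_indications: int = 3,
) -> CharacteristicsTable:
    """Per-drug and overall cohort characteristics.

    A case is attributed to its index drug entry; HLT counts are distinct
    (case, HLT) pairs over the reaction PTs (one case may hit several HLTs),
    with the case count as denominator. ``event_hlts`` restricts HLT
    attribution to the event scope when given.
    """
    index_drugs = frozenset(index_drugs)
    scope = frozenset(event_hlts) if event_hlts is not None else None
    groups: dict[str, list[ICSR]] = {d: [] for d in sorted(index_drugs)}
    for report in cases:
        entry = _index_entry(report, index_drugs)
        groups[entry.drug_code].append(report)

    def block(reports: list[ICSR]) -> CharacteristicsBlock:
        n = len(reports)
        ages = [r.age_years for r in reports if r.age_years is not None]
        age_mean = float(np.mean(ages)) if ages else None
        age_sd = float(np.std(ages, ddof=1)) if len(ages) > 1 else None
        sex_counts = Counter(r.sex for r in reports)
        hlt_counts: Counter = Counter()
        for r in reports:
            hlt_counts.update(_case_hlts(r, dictionary, scope))
        seriousness = Counter(report_seriousness(r) for r in reports)
        outcomes = Counter(report_outcome(r) for r in reports)
        discontinued = sum(
            1
            for r in reports
            if _index_entry(r, index_drugs).action_taken == "withdrawn"
        )
        countries = Counter(r.country for r in reports)
        indications = Counter(
            _index_entry(r, index_drugs).indication
            for r in reports
            if _index_entry(r, index_drugs).indication
        )
        return CharacteristicsBlock(
            n=n,
            age_mean=age_mean,
            age_sd=age_sd,
            sex_counts=dict(sex_counts),
            hlt_counts=dict(hlt_counts),
            seriousness_counts=dict(seriousness),
            outcome_counts=dict(outcomes),
            discontinued=discontinued,
            top_countries=countries.most_common(top_k_countries),
            top_indications=indications.most_common(top_k_indications),
        )

    return CharacteristicsTable(
        per_drug={d: block(reports) for d, reports in groups.items()},
        overall=block([r for reports in groups.values() for r in reports]),
    )


def tto_summary(
    cases: IcsrStore,
    index_drugs: Iterable[str],
    dictionary: TermDictionary,
    min_display: int = 3,
    event_hlts: Optional[Iterable[str]] = None,
) -> list[TtoSummary]:
    """Per (drug, HLT) time-to-onset summaries, pooled over reactions.

    ``display`` is true only for cells with n_total strictly above
    ``min_display``; quantiles are suppressed (None) when fewer than two cases
    carry a defined TTO, mirroring an 'unknown' rendering.
    """
    index_drugs = frozenset(index_drugs)
    scope = frozenset(event_hlts) if event_hlts is not None else None
    ttos: dict[tuple[str, str], list[int]] = {}
    cases_in: dict[tuple[str, str], set[str]] = {}
    cases_tto: dict[tuple[str, str], set[str]] = {}
    for report in cases:
        entry = _index_entry(report, index_drugs)
        for rxn in report.reactions:
            hlts = dictionary.hlts_of_pt(rxn.pt_code)
            if scope is not None:
                hlts &= scope
            tto = time_to_onset(entry, rxn)
            for h in hlts:
                key = (entry.drug_code, h)
                cases_in.setdefault(key, set()).add(report.report_id)
                if tto is not None:
                    ttos.setdefault(key, []).append(tto)
                    cases_tto.setdefault(key, set()).add(report.report_id)

    out = []
    for key in sorted(cases_in):
        drug, hlt = key
        values = ttos.get(key, [])
        n_with = len(cases_tto.get(key, ()))
        n_total = len(cases_in[key])
        if n_with >= 2:
            q25, med, q75 = (float(x) for x in np.percentile(values, [25, 50, 75]))
        else:
            q25 = med = q75 = None
        mean = float(np.mean(values)) if values else None
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
        out.append(
            TtoSummary(
                drug_code=drug,
                hlt_code=hlt,
                n_with_tto=n_with,
                n_total=n_total,
                median=med,
                q25=q25,
                q75=q75,
                mean=mean,
                sd=sd,
                display=n_total > min_display,
            )
        )
    return out


def tto_to_frame(summaries: list[TtoSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": s.drug_code,
                "hlt": s.hlt_code,
                "n_with_tto": s.n_with_tto,
                "n_total": s.n_total,
                "median": s.median,
                "q25": s.q25,
                "q75": s.q75,
                "mean": s.mean,
                "sd": s.sd,
                "display": s.display,
            }
            for s in summaries
        ],
        columns=["drug", "hlt", "n_with_tto", "n_total", "median", "q25", "q75",
                 "mean", "sd", "display"],
    )
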