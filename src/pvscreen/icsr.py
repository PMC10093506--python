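"""Data model and delimited-table I/O for individual case safety reports.

Storage is three-table normal form (reports / drugs / reactions joined on
``report_id``), mirroring the one-to-many structure of a spontaneous report
without implementing any regulatory XML. The on-disk dialect is documented in
DIALECT.md at the repository root.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "ROLES",
    "ACTIONS",
    "OUTCOMES",
    "REPORTERS",
    "SEXES",
    "SERIOUS_FLAGS",
    "HP_REPORTERS",
    "DialectError",
    "LinkageError",
    "DrugEntry",
    "ReactionEntry",
    "ICSR",
    "IcsrStore",
    "read_store",
    "write_store",
    "time_to_onset",
]

logger = logging.getLogger(__name__)

ROLES = frozenset({"suspected", "interacting", "concomitant"})
ACTIONS = frozenset({"withdrawn", "dose_reduced", "continued", "unknown"})
OUTCOMES = frozenset(
    {
        "recovered",
        "recovering",
        "not_recovered",
        "recovered_with_sequelae",
        "fatal",
        "unknown",
    }
)
REPORTERS = frozenset(
    {"physician", "pharmacist", "other_health_professional", "consumer", "unknown"}
)
HP_REPORTERS = frozenset({"physician", "pharmacist", "other_health_professional"})
SEXES = frozenset({"male", "female", "unknown"})
SERIOUS_FLAGS = frozenset(
    {
        "hospitalization",
        "life_threatening",
        "death",
        "disability",
        "congenital_anomaly",
        "other_medically_significant",
    }
)


class DialectError(ValueError):
    """A file value falls outside the documented dialect."""


class LinkageError(ValueError):
    """A child-table row references a report that does not exist."""


@dataclass(frozen=True, slots=True)
class DrugEntry:
    drug_code: str
    role: str
    start_date: Optional[date] = None
    action_taken: str = "unknown"
    indication: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"invalid drug role {self.role!r}")
        if self.action_taken not in ACTIONS:
            raise ValueError(f"invalid action_taken {self.action_taken!r}")


@dataclass(frozen=True, slots=True)
class ReactionEntry:
    """One reported reaction.

    ``serious_flags`` is ``None`` when seriousness was not reported, an empty
    frozenset when explicitly non-serious, and a nonempty frozenset of
    criteria otherwise.
    """

    pt_code: str
    onset_date: Optional[date] = None
    outcome: str = "unknown"
    serious_flags: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"invalid outcome {self.outcome!r}")
        if self.serious_flags is not None and not self.serious_flags <= SERIOUS_FLAGS:
            bad = set(self.serious_flags) - SERIOUS_FLAGS
            raise ValueError(f"invalid serious flag(s) {sorted(bad)}")


@dataclass(frozen=True, slots=True)
class ICSR:
    report_id: str
    report_date: date
    country: str
    reporter: str
    age_years: Optional[float]
    sex: str
    drugs: tuple[DrugEntry, ...]
    reactions: tuple[ReactionEntry, ...]

    def __post_init__(self) -> None:
        if self.reporter not in REPORTERS:
            raise ValueError(f"{self.report_id}: invalid reporter {self.reporter!r}")
        if self.sex not in SEXES:
            raise ValueError(f"{self.report_id}: invalid sex {self.sex!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"{self.report_id}: negative age")
        if not self.drugs:
            raise ValueError(f"{self.report_id}: report has no drug entry")
        if not self.reactions:
            raise ValueError(f"{self.report_id}: report has no reaction entry")
        # fatal outcome implies the death criterion at report level
        if any(r.outcome == "fatal" for r in self.reactions):
            flags = self.serious_flags_union()
            if flags is None or "death" not in flags:
                raise ValueError(
                    f"{self.report_id}: fatal outcome without death seriousness flag"
                )

    def serious_flags_union(self) -> Optional[frozenset[str]]:
        """Union of reported seriousness criteria; None if none were reported."""
        reported = [r.serious_flags for r in self.reactions if r.serious_flags is not None]
        if not reported:
            return None
        return frozenset().union(*reported)

    def pt_codes(self) -> frozenset[str]:
        return frozenset(r.pt_code for r in self.reactions)

    def drug_codes(self, roles: Iterable[str] = ROLES) -> frozenset[str]:
        roleset = frozenset(roles)
        return frozenset(d.drug_code for d in self.drugs if d.role in roleset)


class IcsrStore:
    """An ordered collection of reports with unique ``report_id``."""

    def __init__(self, reports: Iterable[ICSR]):
        self._by_id: dict[str, ICSR] = {}
        for r in reports:
            if r.report_id in self._by_id:
                raise ValueError(f"duplicate report_id {r.report_id!r}")
            self._by_id[r.report_id] = r

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[ICSR]:
        return iter(self._by_id.values())

    def __contains__(self, report_id: str) -> bool:
        return report_id in self._by_id

    def get(self, report_id: str) -> ICSR:
        return self._by_id[report_id]

    @property
    def report_ids(self) -> list[str]:
        return list(self._by_id)

    def sorted(self) -> "IcsrStore":
        return IcsrStore(sorted(self, key=lambda r: r.report_id))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IcsrStore):
            return NotImplemented
        return sorted(self._by_id) == sorted(other._by_id) and all(
            self._by_id[k] == other._by_id[k] for k in self._by_id
        )


# ---------------------------------------------------------------------------
# dialect helpers

def _fmt_date(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


def _parse_date(s: str, where: str) -> Optional[date]:
    s = s.strip()
    if not s:
        return None
    if len(s) < 10:  # partial date (year or year-month): treated as missing
        return None
    try:
        return date.fromisoformat(s)
    except ValueError as e:
        raise DialectError(f"{where}: bad date {s!r}") from e


def _parse_enum(s: str, allowed: frozenset[str], default: str, where: str) -> str:
    s = s.strip()
    if not s:
        if not default:
            raise DialectError(f"{where}: mandatory enum value missing")
        return default
    if s not in allowed:
        raise DialectError(f"{where}: value {s!r} not in dialect {sorted(allowed)}")
    return s


def _fmt_flags(flags: Optional[frozenset[str]]) -> str:
    if flags is None:
        return ""
    if not flags:
        return "none"
    return "|".join(sorted(flags))


def _parse_flags(s: str, where: str) -> Optional[frozenset[str]]:
    s = s.strip()
    if not s:
        return None
    if s == "none":
        return frozenset()
    flags = frozenset(s.split("|"))
    bad = flags - SERIOUS_FLAGS
    if bad:
        raise DialectError(f"{where}: unknown serious flag(s) {sorted(bad)}")
    return flags


_REPORT_COLS = ["report_id", "report_date", "country", "reporter", "age_years", "sex"]
_DRUG_COLS = ["report_id", "drug_code", "role", "start_date", "action_taken", "indication"]
_REACTION_COLS = ["report_id", "pt_code", "onset_date", "outcome", "serious_flags"]


def read_store(
    reports_path: str | Path,
    drugs_path: str | Path,
    reactions_path: str | Path,
) -> IcsrStore:
    """Read and fully link three delimited tables into a validated store."""
    rep_df = _read(reports_path, _REPORT_COLS)
    drug_df = _read(drugs_path, _DRUG_COLS)
    rxn_df = _read(reactions_path, _REACTION_COLS)

    known = set(rep_df["report_id"])
    drugs: dict[str, list[DrugEntry]] = {rid: [] for rid in known}
    for i, row in enumerate(drug_df.itertuples(index=False), start=2):
        where = f"{drugs_path} row {i}"
        if row.report_id not in known:
            raise LinkageError(f"{where}: unknown report_id {row.report_id!r}")
        drugs[row.report_id].append(
            DrugEntry(
                drug_code=row.drug_code,
                role=_parse_enum(row.role, ROLES, "", where),
                start_date=_parse_date(row.start_date, where),
                action_taken=_parse_enum(row.action_taken, ACTIONS, "unknown", where),
                indication=row.indication.strip() or None,
            )
        )
    reactions: dict[str, list[ReactionEntry]] = {rid: [] for rid in known}
    for i, row in enumerate(rxn_df.itertuples(index=False), start=2):
        where = f"{reactions_path} row {i}"
        if row.report_id not in known:
            raise LinkageError(f"{where}: unknown report_id {row.report_id!r}")
        reactions[row.report_id].append(
            ReactionEntry(
                pt_code=row.pt_code,
                onset_date=_parse_date(row.onset_date, where),
                outcome=_parse_enum(row.outcome, OUTCOMES, "unknown", where),
                serious_flags=_parse_flags(row.serious_flags, where),
            )
        )

    out = []
    for i, row in enumerate(rep_df.itertuples(index=False), start=2):
        where = f"{reports_path} row {i}"
        rd = _parse_date(row.report_date, where)
        if rd is None:
            raise DialectError(f"{where}: report_date is mandatory")
        age = float(row.age_years) if row.age_years.strip() else None
        out.append(
            ICSR(
                report_id=row.report_id,
                report_date=rd,
                country=row.country,
                reporter=_parse_enum(row.reporter, REPORTERS, "unknown", where),
                age_years=age,
                sex=_parse_enum(row.sex, SEXES, "unknown", where),
                drugs=tuple(drugs[row.report_id]),
                reactions=tuple(reactions[row.report_id]),
            )
        )
    return IcsrStore(out)


def _read(path: str | Path, expected: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DialectError(f"{path}: missing column(s) {missing}")
    return df


def write_store(
    store: IcsrStore,
    reports_path: str | Path,
    drugs_path: str | Path,
    reactions_path: str | Path,
) -> None:
    """Write a store as three CSV tables, sorted by report_id (bit-stable)."""
    rep_rows, drug_rows, rxn_rows = [], [], []
    for r in sorted(store, key=lambda x: x.report_id):
        rep_rows.append(
            (
                r.report_id,
                r.report_date.isoformat(),
                r.country,
                r.reporter,
                "" if r.age_years is None else _fmt_num(r.age_years),
                r.sex,
            )
        )
        for d in r.drugs:
            drug_rows.append(
                (
                    r.report_id,
                    d.drug_code,
                    d.role,
                    _fmt_date(d.start_date),
                    d.action_taken,
                    d.indication or "",
                )
            )
        for x in r.reactions:
            rxn_rows.append(
                (
                    r.report_id,
                    x.pt_code,
                    _fmt_date(x.onset_date),
                    x.outcome,
                    _fmt_flags(x.serious_flags),
                )
            )
    pd.DataFrame(rep_rows, columns=_REPORT_COLS).to_csv(reports_path, index=False)
    pd.DataFrame(drug_rows, columns=_DRUG_COLS).to_csv(drugs_path, index=False)
    pd.DataFrame(rxn_rows, columns=_REACTION_COLS).to_csv(reactions_path, index=False)


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def time_to_onset(drug: DrugEntry, reaction: ReactionEntry) -> Optional[int]:
    """Days from drug start to reaction onset; None if undefined.

    Undefined when either date is missing or onset precedes start (the latter
    is logged as a warning, never raised).
    """
    if drug.start_date is None or reaction.onset_date is None:
        return None
    delta = (reaction.onset_date - drug.start_date).days
    if delta < 0:
        logger.warning(
            "onset %s precedes start %s for drug %s; time-to-onset undefined",
            reaction.onset_date,
            drug.start_date,
            drug.drug_code,
        )
        return None
    return delta
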