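"""Case/non-case 2×2 tables, reporting odds ratio, and signal flagging.

All four cells are counted at report level over the full deduplicated store,
so (a, b, c, d) is a true partition of the eligible reports:

    a  — reports naming the index drug (allowed role) with ≥1 event reaction
    b  — reports without the index drug but with the event
    c  — reports with the index drug, without the event
    d  — reports with neither

ROR = (a/c)/(b/d) = ad/bc with a log-scale Wald 95% interval
exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d)).  A signal of disproportionate
reporting (SDR) requires a strictly greater than ``min_cases`` (default 5),
ROR strictly above 1, and a CI lower bound strictly above 1.  No multiplicity
adjustment is applied: this is screening, not confirmatory testing.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .icsr import IcsrStore

__all__ = [
    "ContingencyTable",
    "ScreenConfig",
    "DisproportionalityResult",
    "build_table",
    "ror_ci",
    "flag_sdr",
    "screen",
    "results_to_frame",
    "write_results",
]

_DEFAULT_ROLES = frozenset({"suspected", "interacting"})


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ScreenConfig:
    """``min_cases`` is exclusive: a pair needs a > min_cases to be estimated."""

    min_cases: int = 5
    z_multiplier: float = 1.96
    correction: bool = False  # opt-in Haldane–Anscombe 0.5 on zero cells

    def __post_init__(self) -> None:
        if self.min_cases < 0:
            raise ValueError("min_cases must be >= 0")
        if not self.z_multiplier > 0:
            raise ValueError("z_multiplier must be > 0")


@dataclass(frozen=True)
class DisproportionalityResult:
    drug_code: str
    event: str
    table: ContingencyTable
    ror: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    computable: bool
    sdr: bool

    def __post_init__(self) -> None:
        if self.computable:
            assert self.ror is not None and self.ci_low is not None
            assert self.ci_low <= self.ror <= self.ci_high
        if self.sdr and not self.computable:
            raise ValueError("sdr implies computable")


def build_table(
    store: IcsrStore,
    drug_code: str,
    event_pts: Iterable[str],
    roles: frozenset[str] = _DEFAULT_ROLES,
) -> ContingencyTable:
    """Cross-classify every report exactly once (report-level counting)."""
    event_pts = frozenset(event_pts)
    if not event_pts:
        raise ValueError("event PT set must be nonempty")
    a = b = c = d = 0
    for report in store:
        has_drug = any(
            e.drug_code == drug_code and e.role in roles for e in report.drugs
        )
        has_event = any(r.pt_code in event_pts for r in report.reactions)
        if has_drug:
            if has_event:
                a += 1
            else:
                c += 1
        elif has_event:
            b += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def ror_ci(
    table: ContingencyTable, z: float = 1.96, correction: bool = False
) -> Optional[tuple[float, float, float]]:
    """(ROR, CI low, CI high), or None when any cell is below 1.

    With ``correction`` a 0.5 is added to every cell whenever any cell is
    zero (comparability option; off by default).
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if correction and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) < 0.5:  # a zero cell without correction
        return None
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return (
        ror,
        math.exp(log_ror - z * se),
        math.exp(log_ror + z * se),
    )


def flag_sdr(
    ror: Optional[float],
    ci_low: Optional[float],
    a: int,
    config: ScreenConfig = ScreenConfig(),
) -> bool:
    """Strict SDR rule: a > min_cases AND ROR > 1 AND CI lower bound > 1."""
    if ror is None or ci_low is None:
        return False
    return a > config.min_cases and ror > 1.0 and ci_low > 1.0


def screen(
    store: IcsrStore,
    drugs: Iterable[str],
    events: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
    config: ScreenConfig = ScreenConfig(),
    roles: frozenset[str] = _DEFAULT_ROLES,
) -> list[DisproportionalityResult]:
    """One result per (drug, event) pair, sorted by drug then event name.

    ``events`` maps an event label to its PT set. Pairs with a ≤ min_cases,
    or with a zero cell (absent correction), carry no estimate
    (computable=False). Every table partitions the whole store.
    """
    if isinstance(events, Mapping):
        event_items = list(events.items())
    else:
        event_items = list(events)
    event_items = [(name, frozenset(pts)) for name, pts in event_items]
    for name, pts in event_items:
        if not pts:
            raise ValueError(f"event {name!r} has an empty PT set")

    # precompute per-report membership once
    memberships = [
        (report.drug_codes(roles), report.pt_codes()) for report in store
    ]
    results = []
    for drug in sorted(set(drugs)):
        for name, pts in sorted(event_items):
            a = b = c = d = 0
            for drugset, ptset in memberships:
                has_drug = drug in drugset
                has_event = not ptset.isdisjoint(pts)
                if has_drug:
                    if has_event:
                        a += 1
                    else:
                        c += 1
                elif has_event:
                    b += 1
                else:
                    d += 1
            table = ContingencyTable(a, b, c, d)
            est = None
            if table.a > config.min_cases:
                est = ror_ci(table, z=config.z_multiplier, correction=config.correction)
            if est is None:
                results.append(
                    DisproportionalityResult(
                        drug_code=drug, event=name, table=table,
                        ror=None, ci_low=None, ci_high=None,
                        computable=False, sdr=False,
                    )
                )
            else:
                ror, lo, hi = est
                results.append(
                    DisproportionalityResult(
                        drug_code=drug, event=name, table=table,
                        ror=ror, ci_low=lo, ci_high=hi, computable=True,
                        sdr=flag_sdr(ror, lo, table.a, config),
                    )
                )
    return results


def prr(table: ContingencyTable):
    """Proportional reporting ratio — deliberately not implemented.

    Only the reporting odds ratio is supported; this stub marks the boundary.
    """
    raise NotImplementedError("PRR is out of scope; use ror_ci")


def bayesian_shrinkage(table: ContingencyTable, method: str = "IC"):
    """BCPNN/IC and EBGM/MGPS estimators — deliberately not implemented."""
    raise NotImplementedError(f"{method} shrinkage is out of scope; use ror_ci")


def results_to_frame(results: Sequence[DisproportionalityResult]) -> pd.DataFrame:
    rows = [
        {
            "drug": r.drug_code,
            "event": r.event,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "ror": r.ror,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "computable": r.computable,
            "sdr": r.sdr,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["drug", "event", "a", "b", "c", "d", "ror", "ci_low", "ci_high",
                 "computable", "sdr"],
    )


def write_results(
    results: Sequence[DisproportionalityResult],
    csv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Full-precision export; display rounding belongs to report rendering.

    The JSON twin carries a metadata note that no multiplicity adjustment is
    applied.
    """
    df = results_to_frame(results)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        records = [
            {
                "drug": r.drug_code, "event": r.event,
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "ror": r.ror, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "computable": r.computable, "sdr": r.sdr,
            }
            for r in results
        ]
        payload = {
            "metadata": {
                "method": "reporting odds ratio, log-scale Wald CI",
                "multiplicity_adjustment": "none (screening, not confirmatory)",
            },
            "results": records,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
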