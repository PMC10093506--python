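"""Medical-terminology hierarchy (SOC > HLGT > HLT > PT) used for event definition.

Terms are matched by opaque code; names are metadata. The HLGT level is
represented but optional: an HLT may link directly to a SOC or go through an
HLGT. Lowest-level terms (LLTs) are out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "LEVELS",
    "DictionaryError",
    "Term",
    "TermDictionary",
    "load_dictionary",
    "save_dictionary",
    "renal_selection",
    "RENAL_SOC_NAME",
    "RENAL_HLT_NAMES",
]

LEVELS = ("SOC", "HLGT", "HLT", "PT")

# child level -> admissible parent levels (HLGT is optional, hence HLT->SOC)
_ALLOWED_LINKS = {
    "PT": {"HLT"},
    "HLT": {"HLGT", "SOC"},
    "HLGT": {"SOC"},
    "SOC": set(),
}

#: Name of the system organ class grouping renal/urinary events.
RENAL_SOC_NAME = "Renal and urinary disorders"

#: The seven high-level terms defining the renal event scope. Other HLTs under
#: the same SOC (urological, infectious) are deliberately excluded.
RENAL_HLT_NAMES = (
    "Glomerulonephritis and nephrotic syndrome",
    "Nephritis NEC",
    "Nephropathies and tubular disorders NEC",
    "Renal disorders NEC",
    "Renal failure and impairment",
    "Renal hypertension and related conditions",
    "Renal vascular and ischemic conditions",
)


class DictionaryError(ValueError):
    """Raised when a term dictionary violates its structural invariants."""


@dataclass(frozen=True, slots=True)
class Term:
    """A single dictionary term. ``level`` is fixed at construction."""

    code: str
    name: str
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise DictionaryError(
                f"unknown level {self.level!r} for term {self.code!r}; "
                f"expected one of {LEVELS}"
            )
        if not self.code:
            raise DictionaryError("term code must be non-empty")


class TermDictionary:
    """Validated PT→HLT(→HLGT)→SOC hierarchy with expansion queries.

    Invariants enforced at construction: codes unique; links connect adjacent
    declared levels only; every PT has ≥1 HLT parent; every HLT reaches ≥1 SOC
    (directly or through an HLGT); every HLGT has ≥1 SOC parent.
    """

    def __init__(self, terms: Iterable[Term], links: Iterable[tuple[str, str]]):
        self._terms: dict[str, Term] = {}
        for t in terms:
            if t.code in self._terms:
                raise DictionaryError(f"duplicate term code {t.code!r}")
            self._terms[t.code] = t

        self._parents: dict[str, set[str]] = {c: set() for c in self._terms}
        self._children: dict[str, set[str]] = {c: set() for c in self._terms}
        for child, parent in links:
            if child not in self._terms:
                raise DictionaryError(f"link references unknown child code {child!r}")
            if parent not in self._terms:
                raise DictionaryError(f"link references unknown parent code {parent!r}")
            clevel = self._terms[child].level
            plevel = self._terms[parent].level
            if plevel not in _ALLOWED_LINKS[clevel]:
                raise DictionaryError(
                    f"illegal link {child!r} ({clevel}) -> {parent!r} ({plevel})"
                )
            self._parents[child].add(parent)
            self._children[parent].add(child)

        for code, term in self._terms.items():
            if term.level == "PT" and not self._parents[code]:
                raise DictionaryError(f"PT {code!r} has no HLT parent")
            if term.level == "HLGT" and not self._parents[code]:
                raise DictionaryError(f"HLGT {code!r} has no SOC parent")
            if term.level == "HLT" and not self.socs_of_hlt(code):
                raise DictionaryError(f"HLT {code!r} reaches no SOC")

    # -- lookups ---------------------------------------------------------

    def __contains__(self, code: str) -> bool:
        return code in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    @property
    def terms(self) -> Mapping[str, Term]:
        return dict(self._terms)

    def term(self, code: str) -> Term:
        try:
            return self._terms[code]
        except KeyError:
            raise DictionaryError(f"unknown term code {code!r}") from None

    def level(self, code: str) -> str:
        return self.term(code).level

    def name(self, code: str) -> str:
        return self.term(code).name

    def codes_at(self, level: str) -> frozenset[str]:
        return frozenset(c for c, t in self._terms.items() if t.level == level)

    # -- traversal -------------------------------------------------------

    def hlts_of_pt(self, pt_code: str) -> frozenset[str]:
        t = self.term(pt_code)
        if t.level != "PT":
            raise DictionaryError(f"{pt_code!r} is {t.level}, not PT")
        return frozenset(self._parents[pt_code])

    def socs_of_hlt(self, hlt_code: str) -> frozenset[str]:
        """SOC codes reachable from an HLT, directly or through an HLGT."""
        out: set[str] = set()
        for p in self._parents.get(hlt_code, ()):
            if self._terms[p].level == "SOC":
                out.add(p)
            else:  # HLGT
                out.update(self._parents[p])
        return frozenset(out)

    def hlts_under_soc(self, soc_code: str) -> frozenset[str]:
        t = self.term(soc_code)
        if t.level != "SOC":
            raise DictionaryError(f"{soc_code!r} is {t.level}, not SOC")
        out: set[str] = set()
        for c in self._children[soc_code]:
            if self._terms[c].level == "HLT":
                out.add(c)
            elif self._terms[c].level == "HLGT":
                out.update(
                    g for g in self._children[c] if self._terms[g].level == "HLT"
                )
        return frozenset(out)

    def pts_under(self, hlt_codes: Iterable[str]) -> frozenset[str]:
        """Union of PT codes linked to any of the given HLTs (deduplicated)."""
        out: set[str] = set()
        for h in hlt_codes:
            t = self.term(h)
            if t.level != "HLT":
                raise DictionaryError(f"{h!r} is {t.level}, not HLT")
            out.update(self._children[h])
        return frozenset(out)

    def links(self) -> list[tuple[str, str]]:
        return sorted(
            (child, parent)
            for child, parents in self._parents.items()
            for parent in parents
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermDictionary):
            return NotImplemented
        return self._terms == other._terms and self._parents == other._parents


def load_dictionary(terms_path: str | Path, links_path: str | Path) -> TermDictionary:
    """Read a dictionary from two delimited tables and validate it.

    ``terms_path``: columns ``code,name,level``; ``links_path``: columns
    ``child_code,parent_code``. Comma or tab delimited, UTF-8, header row
    required.
    """
    terms_df = _read_table(terms_path, ["code", "name", "level"])
    links_df = _read_table(links_path, ["child_code", "parent_code"])
    terms = [
        Term(code=r.code, name=r.name, level=r.level)
        for r in terms_df.itertuples(index=False)
    ]
    links = list(zip(links_df["child_code"], links_df["parent_code"]))
    return TermDictionary(terms, links)


def save_dictionary(
    d: TermDictionary, terms_path: str | Path, links_path: str | Path
) -> None:
    """Write a dictionary as the two-table format read by :func:`load_dictionary`."""
    terms_df = pd.DataFrame(
        [(t.code, t.name, t.level) for t in d.terms.values()],
        columns=["code", "name", "level"],
    ).sort_values(["level", "code"], kind="stable")
    links_df = pd.DataFrame(d.links(), columns=["child_code", "parent_code"])
    terms_df.to_csv(terms_path, index=False)
    links_df.to_csv(links_path, index=False)


def _read_table(path: str | Path, expected: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DictionaryError(f"{path}: missing column(s) {missing}")
    return df


def renal_selection(d: TermDictionary) -> frozenset[str]:
    """The seven HLT codes defining the renal event scope.

    Locates the renal SOC by name, then matches the seven HLT names beneath it
    (case-insensitive). Any other HLT under that SOC — urological or infectious
    groupings — is excluded. Raises :class:`DictionaryError` naming every
    missing HLT.
    """
    soc_codes = [
        c
        for c in d.codes_at("SOC")
        if d.name(c).casefold() == RENAL_SOC_NAME.casefold()
    ]
    if not soc_codes:
        raise DictionaryError(f"dictionary has no SOC named {RENAL_SOC_NAME!r}")
    by_name: dict[str, str] = {}
    for soc in soc_codes:
        for h in d.hlts_under_soc(soc):
            by_name.setdefault(d.name(h).casefold(), h)
    wanted = {n.casefold(): n for n in RENAL_HLT_NAMES}
    missing = [orig for key, orig in wanted.items() if key not in by_name]
    if missing:
        raise DictionaryError(f"renal HLT name(s) missing from dictionary: {sorted(missing)}")
    return frozenset(by_name[key] for key in wanted)
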