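"""Synthetic spontaneous-report database with known statistical structure.

The generative model is deliberately simple so that ground truth is analytic:

* each report carries exactly one *suspected* drug, drawn from ``drug_marginals``;
* each event PT is included independently with probability ``q_P``, except for
  injected (drug, PT) signals where the inclusion *odds* are multiplied by λ;
* reports whose PT vector comes up empty are redrawn (every report has ≥1
  reaction).

With that structure the population reporting odds ratio of an injected pair is
exactly λ — the ≥1-reaction conditioning cancels out of the odds ratio — and
:func:`expected_ror` returns the exact closed form for every pair, including
the mildly contaminated comparator that arises when other drugs carry signals
on the same PT. Missingness, out-of-window dates, consumer reporters and
near-duplicate reports are injected at configurable rates so every downstream
exclusion rule has records to reject; demographics are cosmetic only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Iterator, Optional

import numpy as np

from .icsr import ICSR, DrugEntry, IcsrStore, ReactionEntry

__all__ = [
    "SignalSpec",
    "SyntheticConfig",
    "generate",
    "expected_ror",
    "replicate_tables",
    "inject_duplicates",
]

_COUNTRIES = ("US", "JP", "DE", "GB", "CA", "FR", "IT", "BR")
_COUNTRY_W = (0.39, 0.15, 0.08, 0.05, 0.04, 0.12, 0.09, 0.08)
_HP = ("physician", "pharmacist", "other_health_professional")
_HP_W = (0.6, 0.2, 0.2)
_OUTCOMES = ("recovered", "recovering", "not_recovered", "recovered_with_sequelae", "fatal", "unknown")
_OUTCOME_W = (0.16, 0.10, 0.10, 0.01, 0.14, 0.49)
_ACTIONS = ("withdrawn", "dose_reduced", "continued", "unknown")
_ACTION_W = (0.39, 0.10, 0.21, 0.30)
_INDICATIONS = ("chronic myeloid leukemia", "gastrointestinal tumor", "acute lymphoid leukemia", "")
_INDICATION_W = (0.54, 0.10, 0.04, 0.32)
_CONCOMITANTS = ("allopurinol", "omeprazole", "paracetamol")
_FLAGS = ("hospitalization", "life_threatening", "death", "disability", "congenital_anomaly", "other_medically_significant")


@dataclass(frozen=True, slots=True)
class SignalSpec:
    """An injected association: the reporting odds of ``pt_code`` given
    ``drug_code`` are multiplied by ``odds_multiplier`` (λ=1 ⇒ no association)."""

    drug_code: str
    pt_code: str
    odds_multiplier: float

    def __post_init__(self) -> None:
        if not self.odds_multiplier > 0:
            raise ValueError("odds_multiplier must be > 0")


@dataclass
class SyntheticConfig:
    n_reports: int
    drug_marginals: dict[str, float]
    pt_marginals: dict[str, float]
    signals: list[SignalSpec] = field(default_factory=list)
    duplicate_rate: float = 0.0
    missing_age_rate: float = 0.0
    missing_sex_rate: float = 0.0
    consumer_reporter_rate: float = 0.0
    out_of_window_rate: float = 0.0
    date_window: tuple[date, date] = (date(2001, 11, 7), date(2021, 6, 2))
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        total = sum(self.drug_marginals.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"drug_marginals must sum to 1 (got {total})")
        if any(p < 0 for p in self.drug_marginals.values()):
            raise ValueError("drug_marginals must be nonnegative")
        for pt, q in self.pt_marginals.items():
            if not 0 < q < 1:
                raise ValueError(f"pt_marginals[{pt!r}] must lie in (0,1)")
        for s in self.signals:
            if s.drug_code not in self.drug_marginals:
                raise ValueError(f"signal references undeclared drug {s.drug_code!r}")
            if s.pt_code not in self.pt_marginals:
                raise ValueError(f"signal references undeclared PT {s.pt_code!r}")
        for name in ("duplicate_rate", "missing_age_rate", "missing_sex_rate",
                     "consumer_reporter_rate", "out_of_window_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0,1)")
        if self.date_window[0] > self.date_window[1]:
            raise ValueError("date_window start must not exceed end")

    # -- serialization (for the CLI config file) -------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["date_window"] = [self.date_window[0].isoformat(), self.date_window[1].isoformat()]
        d["signals"] = [asdict(s) for s in self.signals]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "date_window" in d:
            lo, hi = d["date_window"]
            d["date_window"] = (date.fromisoformat(lo), date.fromisoformat(hi))
        d["signals"] = [SignalSpec(**s) for s in d.get("signals", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# core draws

def _inclusion_probs(config: SyntheticConfig) -> tuple[list[str], list[str], np.ndarray]:
    """Per-(drug, PT) inclusion probability matrix after odds multiplication."""
    drugs = list(config.drug_marginals)
    pts = list(config.pt_marginals)
    q = np.array([config.pt_marginals[p] for p in pts])
    probs = np.tile(q, (len(drugs), 1))
    for s in config.signals:
        i, j = drugs.index(s.drug_code), pts.index(s.pt_code)
        odds = s.odds_multiplier * q[j] / (1 - q[j])
        probs[i, j] = odds / (1 + odds)
    return drugs, pts, probs


def _draw_exposure_events(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (drug index per report, boolean PT inclusion matrix).

    Zero-PT rows are redrawn (with their drug kept fixed) until nonempty.
    """
    drugs, pts, probs = _inclusion_probs(config)
    p = np.array([config.drug_marginals[d] for d in drugs])
    n = config.n_reports
    k = len(pts)
    drug_idx = rng.choice(len(drugs), size=n, p=p)
    mat = np.zeros((n, k), dtype=bool)
    # sample each drug group from the ≥1-PT conditional by batched rejection
    for di in range(len(drugs)):
        where = np.flatnonzero(drug_idx == di)
        need = len(where)
        if need == 0:
            continue
        p_nonempty = 1.0 - float(np.prod(1.0 - probs[di]))
        got: list[np.ndarray] = []
        have = 0
        while have < need:
            batch = int((need - have) / max(p_nonempty, 1e-12) * 1.1) + 16
            draw = rng.random((batch, k)) < probs[di]
            keep = draw[draw.any(axis=1)]
            got.append(keep)
            have += len(keep)
        mat[where] = np.concatenate(got)[:need]
    return drug_idx, mat


def generate(config: SyntheticConfig) -> IcsrStore:
    """Generate a fully populated store; pure function of the config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    drugs = list(config.drug_marginals)
    pts = list(config.pt_marginals)
    drug_idx, mat = _draw_exposure_events(config, rng)
    n = config.n_reports
    lo, hi = config.date_window
    span = (hi - lo).days

    # demographics / report-level attributes, vectorized
    ages = rng.normal(64.0, 14.0, size=n)
    while True:  # truncate to [18, 100] by resampling
        bad = (ages < 18) | (ages > 100)
        if not bad.any():
            break
        ages[bad] = rng.normal(64.0, 14.0, size=int(bad.sum()))
    ages = np.round(ages)
    age_missing = rng.random(n) < config.missing_age_rate
    male = rng.random(n) < 0.54
    sex_missing = rng.random(n) < config.missing_sex_rate
    consumer = rng.random(n) < config.consumer_reporter_rate
    hp = rng.choice(len(_HP), size=n, p=_HP_W)
    countries = rng.choice(len(_COUNTRIES), size=n, p=_COUNTRY_W)
    offsets = rng.integers(0, span + 1, size=n)
    out_of_window = rng.random(n) < config.out_of_window_rate
    early = rng.integers(1, 1500, size=n)  # days before window start
    start_lag = rng.integers(5, 400, size=n)   # drug start before report date
    onset_lag = rng.integers(0, 5, size=n)     # onset shortly before report
    tto_known = rng.random(n) < 0.5
    actions = rng.choice(len(_ACTIONS), size=n, p=_ACTION_W)
    indications = rng.choice(len(_INDICATIONS), size=n, p=_INDICATION_W)
    with_conco = rng.random(n) < 0.2
    conco = rng.choice(len(_CONCOMITANTS), size=n)

    # reaction-level attributes, flattened over all (report, PT) inclusions
    counts = mat.sum(axis=1)
    total = int(counts.sum())
    outcomes_flat = rng.choice(len(_OUTCOMES), size=total, p=_OUTCOME_W).tolist()
    flags_unreported = (rng.random(total) < 0.15).tolist()
    n_flags = rng.integers(0, 3, size=total).tolist()
    flag_order = np.argsort(rng.random((total, len(_FLAGS))), axis=1)[:, :2].tolist()
    starts = np.concatenate(([0], np.cumsum(counts))).tolist()
    rxn_cols = mat.nonzero()[1].tolist()  # row-major: report i owns
    #   rxn_cols[starts[i] : starts[i+1]]

    # cheap python-scalar views for the construction loop
    drug_idx = drug_idx.tolist()
    ages = ages.tolist()
    age_missing = age_missing.tolist()
    male = male.tolist()
    sex_missing = sex_missing.tolist()
    consumer = consumer.tolist()
    hp = hp.tolist()
    countries = countries.tolist()
    offsets = offsets.tolist()
    out_of_window = out_of_window.tolist()
    early = early.tolist()
    start_lag = start_lag.tolist()
    onset_lag = onset_lag.tolist()
    tto_known = tto_known.tolist()
    actions = actions.tolist()
    indications = indications.tolist()
    with_conco = with_conco.tolist()
    conco = conco.tolist()

    reports = []
    for i in range(n):
        report_date = (
            lo - timedelta(days=early[i])
            if out_of_window[i]
            else lo + timedelta(days=offsets[i])
        )
        start = report_date - timedelta(days=start_lag[i])
        onset = report_date - timedelta(days=onset_lag[i])
        drug_entries = [
            DrugEntry(
                drug_code=drugs[drug_idx[i]],
                role="suspected",
                start_date=start if tto_known[i] else None,
                action_taken=_ACTIONS[actions[i]],
                indication=_INDICATIONS[indications[i]] or None,
            )
        ]
        if with_conco[i]:
            drug_entries.append(
                DrugEntry(drug_code=_CONCOMITANTS[conco[i]], role="concomitant")
            )
        reactions = []
        for t in range(starts[i], starts[i + 1]):
            oc = _OUTCOMES[outcomes_flat[t]]
            if flags_unreported[t]:
                flags: Optional[frozenset[str]] = None
            else:
                flags = frozenset(_FLAGS[f] for f in flag_order[t][: n_flags[t]])
            if oc == "fatal":
                flags = (flags or frozenset()) | {"death"}
            reactions.append(
                ReactionEntry(
                    pt_code=pts[rxn_cols[t]],
                    onset_date=onset if tto_known[i] else None,
                    outcome=oc,
                    serious_flags=flags,
                )
            )
        reports.append(
            ICSR(
                report_id=f"R{i:07d}",
                report_date=report_date,
                country=_COUNTRIES[countries[i]],
                reporter="consumer" if consumer[i] else _HP[hp[i]],
                age_years=None if age_missing[i] else ages[i],
                sex="unknown" if sex_missing[i] else ("male" if male[i] else "female"),
                drugs=tuple(drug_entries),
                reactions=tuple(reactions),
            )
        )
    store = IcsrStore(reports)
    if config.duplicate_rate > 0:
        store, _ = inject_duplicates(store, config.duplicate_rate, config.seed + 1)
    return store


# ---------------------------------------------------------------------------
# analytic ground truth

def expected_ror(config: SyntheticConfig, drug_code: str, pt_code: str) -> float:
    """Exact population reporting odds ratio of the generative model.

    Conditions on the ≥1-reaction redraw; the conditioning cancels so the
    value equals the injected λ for a pair whose PT carries no other drug's
    signal, and 1.0 for non-injected pairs in that situation.
    """
    if drug_code not in config.drug_marginals:
        raise ValueError(f"unknown drug {drug_code!r}")
    if pt_code not in config.pt_marginals:
        raise ValueError(f"unknown PT {pt_code!r}")
    drugs, pts, probs = _inclusion_probs(config)
    j = pts.index(pt_code)
    z = 1.0 - np.prod(1.0 - probs, axis=1)  # P(≥1 PT | drug)
    e = probs[:, j] / z                     # P(event | drug, ≥1 PT)
    p = np.array([config.drug_marginals[d] for d in drugs])
    i = drugs.index(drug_code)
    others = np.arange(len(drugs)) != i
    w = p[others] / p[others].sum()
    e_other = float(w @ e[others])
    odds_drug = e[i] / (1 - e[i])
    odds_other = e_other / (1 - e_other)
    return float(odds_drug / odds_other)


def replicate_tables(
    config: SyntheticConfig,
    drug_code: str,
    pt_code: str,
    n_replicates: int,
    seed: Optional[int] = None,
) -> Iterator[tuple[int, int, int, int]]:
    """Yield (a, b, c, d) for independent replicate databases.

    Draws only the exposure/event layer of the generative model (identical
    distribution to :func:`generate`, demographics skipped), which keeps large
    replication studies fast. ``seed`` defaults to ``config.seed``.
    """
    drugs = list(config.drug_marginals)
    pts = list(config.pt_marginals)
    i, j = drugs.index(drug_code), pts.index(pt_code)
    root = np.random.default_rng(config.seed if seed is None else seed)
    for child in root.spawn(n_replicates):
        drug_idx, mat = _draw_exposure_events(config, child)
        exposed = drug_idx == i
        event = mat[:, j]
        a = int((exposed & event).sum())
        b = int((~exposed & event).sum())
        c = int((exposed & ~event).sum())
        d = int((~exposed & ~event).sum())
        yield a, b, c, d


# ---------------------------------------------------------------------------
# duplicates

def inject_duplicates(
    store: IcsrStore, rate: float, seed: int
) -> tuple[IcsrStore, dict[str, str]]:
    """Append ⌊rate·n⌋ near-copies of randomly chosen reports.

    A planted duplicate shares every matching field (country, age, sex, drugs,
    reactions, dates) and differs only in ``report_id`` (original id plus a
    ``-dup<k>`` suffix, lexicographically after the original). Returns the new
    store and the mapping original_id → duplicate_id.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0,1)")
    n_dup = int(rate * len(store))
    if n_dup == 0:
        return store, {}
    rng = np.random.default_rng(seed)
    ids = store.report_ids
    chosen = rng.choice(len(ids), size=n_dup, replace=False)
    mapping: dict[str, str] = {}
    extra = []
    for k, idx in enumerate(sorted(int(x) for x in chosen)):
        orig = store.get(ids[idx])
        dup_id = f"{orig.report_id}-dup{k}"
        extra.append(
            ICSR(
                report_id=dup_id,
                report_date=orig.report_date,
                country=orig.country,
                reporter=orig.reporter,
                age_years=orig.age_years,
                sex=orig.sex,
                drugs=orig.drugs,
                reactions=orig.reactions,
            )
        )
        mapping[orig.report_id] = dup_id
    return IcsrStore(list(store) + extra), mapping
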