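from __future__ import annotations

from datetime import date

import pytest

from pvscreen import (
    ICSR,
    DrugEntry,
    IcsrStore,
    ReactionEntry,
    SelectionConfig,
    example_dictionary,
    renal_selection,
)
from pvscreen.fixtures import SCREEN_PTS, TKI_DRUGS

WINDOW = (date(2001, 11, 7), date(2021, 6, 2))


def mk_report(
    report_id,
    *,
    report_date=date(2015, 6, 1),
    country="FR",
    reporter="physician",
    age=60.0,
    sex="male",
    drugs=None,
    reactions=None,
):
    """Compliant-by-default report builder for hand fixtures."""
    if drugs is None:
        drugs = [DrugEntry("imatinib", "suspected", start_date=date(2015, 1, 1))]
    if reactions is None:
        reactions = [ReactionEntry("PT_RF", onset_date=date(2015, 5, 1))]
    return ICSR(
        report_id=report_id,
        report_date=report_date,
        country=country,
        reporter=reporter,
        age_years=age,
        sex=sex,
        drugs=tuple(drugs),
        reactions=tuple(reactions),
    )


@pytest.fixture(scope="session")
def dictionary():
    return example_dictionary()


@pytest.fixture(scope="session")
def renal_hlts(dictionary):
    return renal_selection(dictionary)


@pytest.fixture
def selection_config(renal_hlts):
    return SelectionConfig(
        date_window=WINDOW,
        index_drugs=frozenset(TKI_DRUGS),
        event_hlts=renal_hlts,
    )


@pytest.fixture
def eight_report_store():
    """Two compliant reports plus one violation of each selection rule."""
    return IcsrStore(
        [
            mk_report("R01", country="US", age=60.0),
            mk_report("R02", country="JP", age=64.0),
            mk_report("R03", report_date=date(2021, 7, 1)),          # window
            mk_report("R04", reporter="consumer"),                    # reporter
            mk_report(                                                # drug
                "R05", drugs=[DrugEntry("aspirin", "suspected")]
            ),
            mk_report("R06", reactions=[ReactionEntry("PT_NAUS")]),   # event
            mk_report("R07", age=None),                               # age
            mk_report("R08", sex="unknown"),                          # sex
        ]
    )


@pytest.fixture
def crossclass_store():
    """Hand fixture for build_table: a=2, b=1, c=3, d=2 for imatinib/PT_RF."""
    drug = [DrugEntry("imatinib", "suspected")]
    other = [DrugEntry("aspirin", "suspected")]
    event = [ReactionEntry("PT_RF")]
    none_ = [ReactionEntry("PT_NAUS")]
    return IcsrStore(
        [
            mk_report("T1", drugs=drug, reactions=event),
            mk_report("T2", drugs=drug, reactions=event),
            mk_report("T3", drugs=other, reactions=event),
            mk_report("T4", drugs=drug, reactions=none_),
            mk_report("T5", drugs=drug, reactions=none_),
            mk_report("T6", drugs=drug, reactions=none_),
            mk_report("T7", drugs=other, reactions=none_),
            mk_report("T8", drugs=other, reactions=none_),
        ]
    )


@pytest.fixture(scope="session")
def small_synth_config():
    from pvscreen import SignalSpec, SyntheticConfig

    return SyntheticConfig(
        n_reports=2_000,
        drug_marginals={d: 0.2 for d in TKI_DRUGS},
        pt_marginals={p: 0.02 for p in SCREEN_PTS},
        signals=[SignalSpec("imatinib", "PT_NS", 5.0)],
        missing_age_rate=0.1,
        missing_sex_rate=0.1,
        consumer_reporter_rate=0.1,
        out_of_window_rate=0.05,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_synth_store(small_synth_config):
    from pvscreen import generate

    return generate(small_synth_config)
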