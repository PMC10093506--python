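from __future__ import annotations

from datetime import date

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvscreen import DrugEntry, IcsrStore, ReactionEntry, characteristics, percent, tto_summary
from pvscreen.fixtures import TKI_DRUGS
from pvscreen.summaries import report_outcome, report_seriousness, tto_to_frame
from conftest import mk_report


class TestPercent:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (287, 1409, 20),
            (726, 1409, 52),
            (0, 100, 0),
            (1, 200, 1),     # 0.5 rounds up (half-up, not banker's)
            (3, 200, 2),     # 1.5 rounds up
            (100, 100, 100),
        ],
    )
    def test_values(self, num, den, expected):
        assert percent(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent(1, 0)

    @given(st.integers(0, 10_000), st.integers(1, 10_000))
    def test_bounded(self, num, den):
        p = percent(num, den)
        assert 0 <= p <= 100 * max(1, num // den + 1)
        assert abs(p - 100 * num / den) <= 0.5


class TestOutcomeAggregation:
    def test_priority(self):
        r = mk_report(
            "X",
            reactions=[
                ReactionEntry("PT_RF", outcome="recovered"),
                ReactionEntry(
                    "PT_AKI", outcome="fatal", serious_flags=frozenset({"death"})
                ),
            ],
        )
        assert report_outcome(r) == "fatal"

    def test_unknown_only(self):
        assert report_outcome(mk_report("X")) == "unknown"

    def test_seriousness_three_way(self):
        serious = mk_report(
            "A",
            reactions=[ReactionEntry("PT_RF", serious_flags=frozenset({"hospitalization"}))],
        )
        not_serious = mk_report(
            "B", reactions=[ReactionEntry("PT_RF", serious_flags=frozenset())]
        )
        unknown = mk_report("C", reactions=[ReactionEntry("PT_RF")])
        assert report_seriousness(serious) == "serious"
        assert report_seriousness(not_serious) == "not_serious"
        assert report_seriousness(unknown) == "unknown"


class TestCharacteristics:
    def test_single_case(self, dictionary, renal_hlts):
        case = mk_report(
            "C1",
            reactions=[
                ReactionEntry("PT_RF", serious_flags=frozenset({"hospitalization"}))
            ],
        )
        table = characteristics(
            IcsrStore([case]), TKI_DRUGS, dictionary, event_hlts=renal_hlts
        )
        block = table.per_drug["imatinib"]
        assert block.n == 1
        assert block.sex_counts == {"male": 1}
        assert percent(block.sex_counts["male"], block.n) == 100
        assert block.seriousness_counts == {"serious": 1}
        assert block.hlt_counts == {"HLT_RFI": 1}

    def test_mean_and_sample_sd(self, dictionary):
        cases = IcsrStore(
            [mk_report("C1", age=60.0, country="US"), mk_report("C2", age=64.0)]
        )
        table = characteristics(cases, TKI_DRUGS, dictionary)
        assert table.overall.age_mean == pytest.approx(62.0)
        assert table.overall.age_sd == pytest.approx(2.8284271247, rel=1e-9)

    def test_case_counted_once_per_hlt(self, dictionary, renal_hlts):
        # two reactions in the same HLT count the case once for that HLT;
        # reactions in different HLTs count it in each
        case = mk_report(
            "C1",
            reactions=[
                ReactionEntry("PT_RF"),
                ReactionEntry("PT_AKI"),   # same HLT as PT_RF
                ReactionEntry("PT_NS"),    # different HLT
            ],
        )
        table = characteristics(
            IcsrStore([case]), TKI_DRUGS, dictionary, event_hlts=renal_hlts
        )
        assert table.per_drug["imatinib"].hlt_counts == {"HLT_RFI": 1, "HLT_GNS": 1}

    def test_counts_sum_to_n(self, dictionary, renal_hlts, small_synth_store, selection_config):
        from pvscreen import select_cases

        cases, _ = select_cases(small_synth_store, selection_config, dictionary)
        table = characteristics(cases, TKI_DRUGS, dictionary, event_hlts=renal_hlts)
        for block in list(table.per_drug.values()) + [table.overall]:
            assert sum(block.sex_counts.values()) == block.n
            assert sum(block.outcome_counts.values()) == block.n
            assert sum(block.seriousness_counts.values()) == block.n

    def test_reorder_invariance(self, dictionary, renal_hlts, small_synth_store, selection_config):
        from pvscreen import select_cases

        cases, _ = select_cases(small_synth_store, selection_config, dictionary)
        shuffled = IcsrStore(list(cases)[::-1])
        t1 = characteristics(cases, TKI_DRUGS, dictionary, event_hlts=renal_hlts)
        t2 = characteristics(shuffled, TKI_DRUGS, dictionary, event_hlts=renal_hlts)
        assert t1.overall.hlt_counts == t2.overall.hlt_counts
        assert t1.per_drug["imatinib"].outcome_counts == t2.per_drug["imatinib"].outcome_counts

    def test_non_case_rejected(self, dictionary):
        stray = mk_report("C1", drugs=[DrugEntry("aspirin", "suspected")])
        with pytest.raises(ValueError, match="no index drug"):
            characteristics(IcsrStore([stray]), TKI_DRUGS, dictionary)


def _case_with_ttos(report_id, ttos, drug="imatinib", pt="PT_RF"):
    start = date(2015, 1, 1)
    return mk_report(
        report_id,
        drugs=[DrugEntry(drug, "suspected", start_date=start)],
        reactions=[
            ReactionEntry(pt, onset_date=date(2015, 1, 1) + __import__("datetime").timedelta(days=t))
            for t in ttos
        ],
    )


class TestTtoSummary:
    def test_quartiles_linear_interpolation(self, dictionary, renal_hlts):
        cases = IcsrStore(
            [
                _case_with_ttos("C1", [10]),
                _case_with_ttos("C2", [20]),
                _case_with_ttos("C3", [30]),
                _case_with_ttos("C4", [40]),
            ]
        )
        rows = tto_summary(cases, TKI_DRUGS, dictionary, event_hlts=renal_hlts)
        (row,) = [r for r in rows if r.hlt_code == "HLT_RFI"]
        assert (row.q25, row.median, row.q75) == (17.5, 25.0, 32.5)
        assert row.n_with_tto == 4 and row.n_total == 4
        assert row.display  # 4 > 3

    def test_single_tto_reported_unknown(self, dictionary, renal_hlts):
        cases = IcsrStore([_case_with_ttos("C1", [60])])
        (row,) = tto_summary(cases, TKI_DRUGS, dictionary, event_hlts=renal_hlts)
        assert row.n_with_tto == 1
        assert row.median is None and row.q25 is None and row.q75 is None
        assert row.mean == 60.0  # statistic still computed for export

    def test_display_threshold_strict(self, dictionary, renal_hlts):
        cases = IcsrStore([_case_with_ttos(f"C{i}", [10 * i]) for i in range(1, 4)])
        (row,) = tto_summary(cases, TKI_DRUGS, dictionary, event_hlts=renal_hlts)
        assert row.n_total == 3 and not row.display

    def test_missing_dates_counted_in_total_only(self, dictionary, renal_hlts):
        cases = IcsrStore(
            [
                _case_with_ttos("C1", [10]),
                _case_with_ttos("C2", [20]),
                mk_report("C3"),  # start date present, onset in fixture default
                mk_report(
                    "C4",
                    drugs=[DrugEntry("imatinib", "suspected")],  # no start date
                ),
            ]
        )
        (row,) = tto_summary(cases, TKI_DRUGS, dictionary, event_hlts=renal_hlts)
        assert row.n_total == 4
        assert row.n_with_tto == 3

    def test_permutation_invariance(self, dictionary, renal_hlts):
        values = [5, 80, 33, 12, 47]
        for order in (values, values[::-1], sorted(values)):
            cases = IcsrStore(
                [_case_with_ttos(f"C{i}", [v]) for i, v in enumerate(order)]
            )
            rows = tto_summary(cases, TKI_DRUGS, dictionary, event_hlts=renal_hlts)
            assert rows[0].median == float(np.median(values))

    def test_frame_columns(self, dictionary, renal_hlts):
        cases = IcsrStore([_case_with_ttos("C1", [10]), _case_with_ttos("C2", [30])])
        df = tto_to_frame(tto_summary(cases, TKI_DRUGS, dictionary, event_hlts=renal_hlts))
        assert list(df.columns)[:4] == ["drug", "hlt", "n_with_tto", "n_total"]
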