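from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvscreen import (
    ContingencyTable,
    IcsrStore,
    ScreenConfig,
    build_table,
    flag_sdr,
    ror_ci,
    screen,
)
from pvscreen.disprop import results_to_frame, write_results
from pvscreen.fixtures import SCREEN_PTS, TKI_DRUGS

# frozen once from statsmodels Table2x2 (z = Phi^-1(0.975) = 1.959964...):
#   Table2x2([[20, 100], [980, 99900]]).oddsratio_confint()
_ORACLE_TABLE = (20, 100, 980, 99900)
_ORACLE_OR = 20.387755102040817
_ORACLE_CI = (12.562779148993457, 33.086672397173665)
_Z_EXACT = 1.959963984540054


class TestBuildTable:
    def test_empty_store(self):
        t = build_table(IcsrStore([]), "imatinib", {"PT_RF"})
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)

    def test_degenerate_all_drug_and_event(self, crossclass_store):
        only = IcsrStore([r for r in crossclass_store if r.report_id in ("T1", "T2")])
        t = build_table(only, "imatinib", {"PT_RF"})
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 0)

    def test_hand_cross_classification(self, crossclass_store):
        t = build_table(crossclass_store, "imatinib", {"PT_RF"})
        assert (t.a, t.b, t.c, t.d) == (2, 1, 3, 2)

    def test_empty_event_set_rejected(self, crossclass_store):
        with pytest.raises(ValueError, match="nonempty"):
            build_table(crossclass_store, "imatinib", set())

    def test_conservation(self, crossclass_store):
        t = build_table(crossclass_store, "imatinib", {"PT_RF"})
        assert t.total == len(crossclass_store)

    def test_concomitant_role_not_drug_positive(self, crossclass_store):
        t = build_table(
            crossclass_store, "imatinib", {"PT_RF"}, roles=frozenset({"concomitant"})
        )
        assert t.a == 0


class TestRorCi:
    def test_symmetric_table(self):
        ror, lo, hi = ror_ci(ContingencyTable(10, 10, 10, 10))
        assert ror == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)  # reciprocal bounds

    def test_against_frozen_reference(self):
        ror, lo, hi = ror_ci(ContingencyTable(*_ORACLE_TABLE), z=_Z_EXACT)
        assert ror == pytest.approx(_ORACLE_OR, rel=1e-12)
        assert lo == pytest.approx(_ORACLE_CI[0], rel=1e-9)
        assert hi == pytest.approx(_ORACLE_CI[1], rel=1e-9)

    def test_zero_cell_undefined(self):
        assert ror_ci(ContingencyTable(6, 0, 994, 99000)) is None

    def test_zero_cell_with_correction(self):
        ror, lo, hi = ror_ci(ContingencyTable(6, 0, 994, 99000), correction=True)
        assert math.isfinite(ror) and lo < ror < hi

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    @given(
        st.tuples(*(st.integers(1, 50),) * 4),
        st.floats(0.5, 3.0),
    )
    def test_swap_symmetry(self, cells, z):
        a, b, c, d = cells
        r1 = ror_ci(ContingencyTable(a, b, c, d), z=z)
        r2 = ror_ci(ContingencyTable(b, a, d, c), z=z)
        assert r1[0] == pytest.approx(1 / r2[0], rel=1e-12)
        w1 = math.log(r1[2]) - math.log(r1[1])
        w2 = math.log(r2[2]) - math.log(r2[1])
        assert w1 == pytest.approx(w2, rel=1e-9)

    @given(st.integers(1, 200), st.integers(1, 200), st.integers(2, 100))
    def test_monotone_in_a(self, b, d, margin):
        # b, d fixed; a + c fixed: larger a gives strictly larger ROR
        rors = []
        for a in range(1, margin):
            c = margin - a
            rors.append(ror_ci(ContingencyTable(a, b, c, d))[0])
        assert all(x < y for x, y in zip(rors, rors[1:]))

    @settings(max_examples=200)
    @given(st.tuples(*(st.integers(1, 30),) * 4))
    def test_exact_cross_product_ratio(self, cells):
        a, b, c, d = cells
        ror = ror_ci(ContingencyTable(a, b, c, d))[0]
        assert ror == pytest.approx(float(Fraction(a * d, b * c)), rel=1e-14)

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*(st.integers(1, 30),) * 4))
    def test_sampled_oracle_equivalence(self, cells):
        sm = pytest.importorskip("statsmodels.api")
        a, b, c, d = cells
        ref = sm.stats.Table2x2(np.array([[a, b], [c, d]]), shift_zeros=False)
        ror, lo, hi = ror_ci(ContingencyTable(a, b, c, d), z=_Z_EXACT)
        assert ror == pytest.approx(ref.oddsratio, rel=1e-12)
        lo_ref, hi_ref = ref.oddsratio_confint()
        assert lo == pytest.approx(lo_ref, rel=1e-9)
        assert hi == pytest.approx(hi_ref, rel=1e-9)


class TestOutOfScopeStubs:
    def test_prr_and_shrinkage_unimplemented(self):
        from pvscreen.disprop import bayesian_shrinkage, prr

        t = ContingencyTable(1, 1, 1, 1)
        with pytest.raises(NotImplementedError):
            prr(t)
        with pytest.raises(NotImplementedError):
            bayesian_shrinkage(t)


class TestFlagSdr:
    @pytest.mark.parametrize(
        "ror, ci_low, a, expected",
        [
            (2.52, 1.16, 20, True),   # published nephrotic-syndrome signal
            (3.95, 1.77, 10, True),   # published thrombotic-microangiopathy signal
            (2.0, 1.0, 10, False),    # boundary: lower bound must be strictly > 1
            (1.0, 0.5, 10, False),
            (2.0, 1.2, 5, False),     # a must exceed min_cases strictly
            (2.0, 1.2, 6, True),
        ],
    )
    def test_rule(self, ror, ci_low, a, expected):
        assert flag_sdr(ror, ci_low, a) is expected

    def test_undefined_never_flags(self):
        assert flag_sdr(None, None, 100) is False

    def test_threshold_configurable(self):
        assert flag_sdr(2.0, 1.2, 4, ScreenConfig(min_cases=3)) is True


class TestScreen:
    def test_grid_cardinality(self, small_synth_store):
        events = {p: {p} for p in SCREEN_PTS}
        results = screen(small_synth_store, TKI_DRUGS, events)
        assert len(results) == 65  # 5 drugs x 13 events

    def test_sorted_by_drug_then_event(self, small_synth_store):
        events = {p: {p} for p in SCREEN_PTS}
        results = screen(small_synth_store, TKI_DRUGS, events)
        keys = [(r.drug_code, r.event) for r in results]
        assert keys == sorted(keys)

    def test_a_at_threshold_not_computable(self, crossclass_store):
        results = screen(
            crossclass_store, ["imatinib"], {"renal": {"PT_RF"}},
            ScreenConfig(min_cases=2),
        )
        assert results[0].table.a == 2
        assert not results[0].computable and results[0].ror is None

    def test_conservation_every_pair(self, small_synth_store):
        events = {p: {p} for p in SCREEN_PTS}
        for r in screen(small_synth_store, TKI_DRUGS, events):
            assert r.table.total == len(small_synth_store)

    def test_sdr_implies_computable(self, small_synth_store):
        events = {p: {p} for p in SCREEN_PTS}
        for r in screen(small_synth_store, TKI_DRUGS, events):
            if r.sdr:
                assert r.computable and r.ci_low > 1.0
            if r.computable:
                assert r.ci_low <= r.ror <= r.ci_high

    def test_injected_signal_flagged(self, small_synth_store):
        # small_synth_store carries imatinib/PT_NS at lambda=5
        events = {p: {p} for p in SCREEN_PTS}
        results = screen(small_synth_store, TKI_DRUGS, events)
        hit = next(
            r for r in results if (r.drug_code, r.event) == ("imatinib", "PT_NS")
        )
        assert hit.sdr

    def test_export_round_trip(self, small_synth_store, tmp_path):
        events = {p: {p} for p in SCREEN_PTS}
        results = screen(small_synth_store, TKI_DRUGS, events)
        write_results(results, tmp_path / "r.csv", tmp_path / "r.json")
        df = results_to_frame(results)
        assert len(df) == 65
        import json

        payload = json.loads((tmp_path / "r.json").read_text())
        assert "multiplicity_adjustment" in payload["metadata"]
        assert len(payload["results"]) == 65
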