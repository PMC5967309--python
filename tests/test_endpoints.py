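"""Tests for CID component flagging, first/sustained timing and censoring."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cidkit.endpoints import (
    CidThresholds,
    _sustained_flag_week,
    censor_day,
    derive_all,
    first_cid,
    flag_components,
    sustained_cid,
)

from conftest import brute_force_sustained, single_patient_tables


def flags_for(weeks, fev1, sgrq, **kwargs):
    b, v, e, f = single_patient_tables(weeks, fev1, sgrq, **kwargs)
    return flag_components(b, v), e, f.iloc[0]


class TestThresholdValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(fev1_drop=0.0),
            dict(sgrq_rise=-1.0),
            dict(sustained_min_consecutive=1),
            dict(sustained_fraction=0.0),
            dict(sustained_fraction=1.2),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            CidThresholds(**kwargs)


class TestComponentFlags:
    @pytest.mark.parametrize(
        "baseline,visit,expected",
        [
            (1.47, 1.29, True),  # 180 mL drop (the published group-mean pair)
            (1.50, 1.40, True),  # exactly 100 mL: inclusive boundary
            (1.50, 1.401, False),  # 1 mL above the boundary unflags
            (1.50, 1.55, False),
        ],
    )
    def test_fev1_boundary_inclusive(self, baseline, visit, expected):
        flags, _, _ = flags_for([4], [visit], [50.0], fev1_baseline=baseline)
        assert bool(flags["fev1_flag"].iloc[0]) is expected

    @pytest.mark.parametrize(
        "baseline,visit,expected",
        [
            (43.42, 47.42, True),  # rise of exactly 4 points flags
            (43.42, 47.41, False),
            (50.0, 40.0, False),
        ],
    )
    def test_sgrq_boundary_inclusive(self, baseline, visit, expected):
        flags, _, _ = flags_for([4], [1.5], [visit], sgrq_baseline=baseline)
        assert bool(flags["sgrq_flag"].iloc[0]) is expected

    def test_missing_visit_value_gives_missing_flag(self):
        flags, _, _ = flags_for([4, 8], [np.nan, 1.2], [np.nan, 50.0])
        assert flags["fev1_flag"].isna().iloc[0] and not flags["fev1_flag"].isna().iloc[1]
        assert flags["sgrq_flag"].isna().iloc[0]

    def test_missing_baseline_excludes_component_with_warning(self, caplog):
        b, v, e, f = single_patient_tables([4], [1.2], [60.0])
        b.loc[0, "fev1_baseline"] = np.nan
        with caplog.at_level(logging.WARNING, logger="cidkit.endpoints"):
            flags = flag_components(b, v)
        assert flags["fev1_flag"].isna().all()
        assert not flags["sgrq_flag"].isna().any()
        assert any("FEV1" in r.message and "P1" in r.message for r in caplog.records)


class TestCensorDay:
    def test_completed_study_censors_at_end(self):
        fu = {"patient_id": "P", "last_contact_day": 364, "discontinued_early": False, "study_end_day": 364}
        assert censor_day(fu) == 364

    def test_early_discontinuation_censors_at_last_contact(self):
        fu = {"patient_id": "P", "last_contact_day": 100, "discontinued_early": True, "study_end_day": 182}
        assert censor_day(fu) == 100

    def test_contact_after_study_end_rejected(self):
        fu = {"patient_id": "P", "last_contact_day": 400, "discontinued_early": False, "study_end_day": 364}
        with pytest.raises(ValueError):
            censor_day(fu)


class TestFirstCid:
    def test_earliest_component_wins(self):
        # FEV1 first flags at week 12 (day 84); exacerbation at day 30
        flags, _, fu = flags_for(
            [4, 8, 12], [1.5, 1.45, 1.35], [50.0, 50.0, 50.0], exac_days=[30]
        )
        _, _, e, _ = single_patient_tables([4], [1.5], [50.0], exac_days=[30])
        res = first_cid(flags, e, fu)
        assert res["first_cid_event"] and res["first_cid_day"] == 30
        assert res["first_cid_components"] == ("EXACERBATION",)

    def test_component_ties_are_all_recorded(self):
        flags, e, fu = flags_for([4, 8], [1.5, 1.39], [50.0, 55.0])
        res = first_cid(flags, e, fu)
        assert res["first_cid_day"] == 56
        assert res["first_cid_components"] == ("FEV1", "SGRQ")

    def test_no_event_censored_at_study_end(self):
        flags, e, fu = flags_for(
            [4, 8, 12, 16, 20, 24], [1.5] * 6, [50.0] * 6, duration_weeks=26
        )
        res = first_cid(flags, e, fu)
        assert not res["first_cid_event"]
        assert res["first_cid_day"] == 182
        assert res["first_cid_components"] == ()


class TestSustainedCid:
    def test_consecutive_pair_rule(self):
        # flags at weeks 8 and 12 -> sustained at week 8 (day 56)
        flags, e, fu = flags_for([4, 8, 12], [1.5, 1.35, 1.35], [50.0] * 3)
        res = sustained_cid(flags, e, fu)
        assert res["sustained_cid_event"] and res["sustained_cid_day"] == 56

    def test_fraction_rule_over_alternating_pattern(self):
        # 24-week grid; FEV1 flags at weeks 8, 16, 24 and not at 12, 20:
        # from week 8 the available visits are {8,12,16,20,24}, 3/5 flagged.
        weeks = [4, 8, 12, 16, 20, 24]
        fev1 = [1.5, 1.35, 1.5, 1.35, 1.5, 1.35]
        flags, e, fu = flags_for(weeks, fev1, [50.0] * 6, duration_weeks=24)
        res = sustained_cid(flags, e, fu)
        assert res["sustained_cid_event"] and res["sustained_cid_day"] == 56
        assert res["sustained_cid_components"] == ("FEV1",)

    def test_single_exacerbation_is_sustained_by_definition(self):
        flags, _, fu = flags_for([4, 8], [1.5, 1.5], [50.0, 50.0], exac_days=[30])
        _, _, e, _ = single_patient_tables([4], [1.5], [50.0], exac_days=[30])
        res = sustained_cid(flags, e, fu)
        assert res["sustained_cid_event"] and res["sustained_cid_day"] == 30
        assert res["exac_sustained_event"]

    def test_isolated_mid_record_flag_is_not_sustained(self):
        flags, e, fu = flags_for(
            [4, 8, 12, 16, 20, 24], [1.5, 1.35, 1.5, 1.5, 1.5, 1.5], [50.0] * 6
        )
        res = sustained_cid(flags, e, fu)
        assert not res["sustained_cid_event"]

    def test_missing_intervening_visit_breaks_consecutive_rule(self):
        # flagged at 8, missing at 12, flagged at 16: rule (a) fails, and
        # 2/3 available visits from week 8 still satisfies rule (b)
        weeks = np.array([4, 8, 12, 16])
        flags = np.array([0.0, 1.0, np.nan, 1.0])
        assert _sustained_flag_week(weeks, flags, 4, 2, 0.5) == 8
        # ... but a sparser tail does not
        weeks = np.array([4, 8, 12, 16, 20, 24])
        flags = np.array([0.0, 1.0, np.nan, 0.0, 0.0, 0.0])
        assert _sustained_flag_week(weeks, flags, 4, 2, 0.5) is None


@settings(max_examples=300, deadline=None)
@given(
    st.lists(
        st.sampled_from([True, False, None]), min_size=1, max_size=10
    )
)
def test_rule_engine_matches_bruteforce_on_random_patterns(pattern):
    """The vectorized sustained-rule engine agrees with an independent
    plain-Python reading of the rule on arbitrary flag/missing patterns."""
    weeks = np.arange(4, 4 * len(pattern) + 1, 4)
    flags = np.array(
        [np.nan if p is None else float(p) for p in pattern], dtype=float
    )
    got = _sustained_flag_week(weeks, flags, 4, 2, 0.5)
    want = brute_force_sustained(weeks, pattern)
    assert got == want


class TestDeriveAll:
    def test_matches_per_patient_application(self, small_cohort):
        b, v, e, f = small_cohort
        table = derive_all(b, v, e, f)
        flags = flag_components(b, v)
        fu = f.set_index("patient_id", drop=False)
        rng = np.random.default_rng(1)
        for pid in rng.choice(b["patient_id"], size=25, replace=False):
            pf = flags[flags["patient_id"] == pid]
            pe = e[e["patient_id"] == pid]
            expect = {}
            expect.update(first_cid(pf, pe, fu.loc[pid]))
            expect.update(sustained_cid(pf, pe, fu.loc[pid]))
            row = table.set_index("patient_id").loc[pid]
            for key in ("first_cid_day", "first_cid_event", "sustained_cid_day",
                        "sustained_cid_event", "fev1_first_day", "sgrq_sustained_day",
                        "exac_first_event", "censor_day"):
                assert row[key] == expect[key], (pid, key)

    def test_orphan_rows_rejected_with_ids(self, small_cohort):
        b, v, e, f = small_cohort
        bad = pd.concat(
            [v, pd.DataFrame([{"patient_id": "GHOST", "visit_week": 4,
                               "visit_day": 28, "fev1": 1.0, "sgrq": 50.0}])]
        )
        with pytest.raises(ValueError, match="GHOST"):
            derive_all(b, bad, e, f)

    def test_sustained_implies_first_in_order(self, cid_small):
        sus = cid_small["sustained_cid_event"]
        assert (cid_small.loc[sus, "first_cid_event"]).all()
        assert (
            cid_small.loc[sus, "first_cid_day"] <= cid_small.loc[sus, "sustained_cid_day"]
        ).all()
        # component-level event implies overall event
        for key in ("fev1", "sgrq", "exac"):
            assert (
                ~cid_small[f"{key}_first_event"] | cid_small["first_cid_event"]
            ).all()

    def test_exacerbation_sustained_equals_first(self, cid_small):
        assert cid_small["exac_sustained_event"].equals(cid_small["exac_first_event"])
        assert cid_small["exac_sustained_day"].equals(cid_small["exac_first_day"])

    def test_component_counts_never_below_overall(self, cid_small):
        comp_any = (
            cid_small["fev1_first_event"]
            | cid_small["sgrq_first_event"]
            | cid_small["exac_first_event"]
        )
        assert comp_any.equals(cid_small["first_cid_event"])
        n_components = (
            cid_small["fev1_first_event"].sum()
            + cid_small["sgrq_first_event"].sum()
            + cid_small["exac_first_event"].sum()
        )
        assert n_components >= cid_small["first_cid_event"].sum()

    def test_raising_threshold_never_adds_events(self, small_cohort):
        b, v, e, f = small_cohort
        default = derive_all(b, v, e, f)
        strict = derive_all(b, v, e, f, CidThresholds(fev1_drop=0.2))
        assert strict["fev1_first_event"].sum() <= default["fev1_first_event"].sum()
        assert strict["first_cid_event"].sum() <= default["first_cid_event"].sum()
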