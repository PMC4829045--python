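import datetime as dt

import pytest
from hypothesis import given, strategies as st

from skeletochron.errors import (
    DataAvailabilityError,
    DegenerateSampleError,
    ParameterError,
)
from skeletochron.otc import (
    Relation,
    TimingClassification,
    classify_deposition,
    infer_deposition_window,
    otc_fallback_length,
)
from skeletochron.simulate import SimConfig, simulate_population


class TestClassifyDeposition:
    @pytest.mark.parametrize(
        "otc, lag, expected",
        [
            (57.7, 57.7, Relation.COINCIDENT),  # CM-12: both marks at 57.7 cm
            (55.9, 55.1, Relation.LAG_BEFORE_INJECTION),  # CM-1
            (69.4, 69.6, Relation.LAG_AFTER_INJECTION),  # CM-4
        ],
    )
    def test_printed_examples(self, otc, lag, expected):
        assert classify_deposition(otc, lag, tolerance=0.1) is expected

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ParameterError):
            classify_deposition(50.0, 50.0, tolerance=-0.1)

    @given(
        a=st.floats(10, 100), b=st.floats(10, 100), tol=st.floats(0, 1)
    )
    def test_antisymmetry(self, a, b, tol):
        fwd = classify_deposition(a, b, tol)
        rev = classify_deposition(b, a, tol)
        swap = {
            Relation.LAG_BEFORE_INJECTION: Relation.LAG_AFTER_INJECTION,
            Relation.LAG_AFTER_INJECTION: Relation.LAG_BEFORE_INJECTION,
            Relation.COINCIDENT: Relation.COINCIDENT,
        }
        assert rev is swap[fwd]


def _cls(tid, date, relation, otc=50.0, lag=50.0):
    return TimingClassification(
        turtle_id=tid, injection_date=date, scl_from_otc=otc, scl_from_lag=lag,
        relation=relation,
    )


class TestInferDepositionWindow:
    def test_study_window_is_late_december_to_mid_may(self, study_result):
        w = study_result.window
        assert w.lower_bound == (12, 21)
        assert w.upper_bound == (5, 16)
        assert w.contains_doy(91)  # spring deposition

    def test_single_coincident_observation_is_one_sided(self):
        w = infer_deposition_window(
            [_cls("a", dt.date(1998, 5, 12), Relation.COINCIDENT)]
        )
        assert w.lower_bound is None
        assert w.upper_bound == (5, 12)

    def test_lag_before_turtles_do_not_move_the_window(self):
        # an April injection postdating its LAG is individual variability,
        # reported per-turtle, not folded into the population bracket
        w = infer_deposition_window([
            _cls("a", dt.date(1998, 12, 21), Relation.LAG_AFTER_INJECTION),
            _cls("b", dt.date(1997, 4, 23), Relation.LAG_BEFORE_INJECTION),
            _cls("c", dt.date(1998, 5, 12), Relation.COINCIDENT),
        ])
        assert w.lower_bound == (12, 21)
        assert w.upper_bound == (5, 12)
        assert len(w.per_turtle) == 3

    def test_empty_input_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            infer_deposition_window([])


class TestOtcFallback:
    def test_mark_at_section_edge_returns_recovery_length(self, study_fixture):
        records, profiles = study_fixture
        rec = records[0]
        prof = profiles[0]
        assert otc_fallback_length(
            prof.section_diameter, prof, rec
        ) == pytest.approx(rec.scl_at_recovery)

    def test_fallback_used_for_resorbed_tagging_lag(self, study_result):
        # CM-13's 1994 LAG sits in the resorption core; its printed estimate
        # comes from the OTC mark
        assert study_result.fallback_ids == ["CM-13"]
        row = study_result.table1[study_result.table1["id"] == "CM-13"].iloc[0]
        assert row["estimated_scl"] == 47.0
        assert row["difference"] == -1.5

    def test_missing_mark_is_data_availability_error(self, study_fixture):
        records, profiles = study_fixture
        rec = next(r for r in records if r.id == "CM-6")  # no OTC mark
        prof = next(b for b in profiles if b.turtle_id == "CM-6")
        with pytest.raises(DataAvailabilityError):
            otc_fallback_length(None, prof, rec)

    def test_noise_free_simulated_injection_recovers_true_scl(self):
        cfg = SimConfig(n_turtles=20, seed=9, scl_error_sd=0.0, diameter_error_sd=0.0,
                        otc_fraction=1.0)
        records, profiles, truth = simulate_population(cfg)
        for rec, prof in zip(records, profiles):
            t = truth.by_id(rec.id)
            got = otc_fallback_length(prof.otc_diameter, prof, rec)
            assert got == pytest.approx(t.scl_at(t.date_otc), abs=1e-6)


def test_relations_agree_with_true_event_order():
    """Noise-free, injections spread over the year: every non-coincident
    classification matches the true order of injection vs matched-LAG
    deposition taken from simulator ground truth."""
    from skeletochron.pipeline import run_pipeline

    cfg = SimConfig(n_turtles=100, seed=17, scl_error_sd=0.0, diameter_error_sd=0.0,
                    deposition_doy_sd=0.0, otc_fraction=1.0, otc_at_tagging=False,
                    p_double_lag=0.0, stranding_doy_range=(150, 365))
    records, profiles, truth = simulate_population(cfg)
    result = run_pipeline(records, profiles)
    for c in result.window.per_turtle:
        t = truth.by_id(c.turtle_id)
        lag_date = next(
            e.date for e in t.lag_events if e.calendar_year == c.lag_year
        )
        if c.relation is Relation.LAG_BEFORE_INJECTION:
            assert lag_date < c.injection_date
        elif c.relation is Relation.LAG_AFTER_INJECTION:
            assert lag_date > c.injection_date
        else:
            # coincident at the 0.1 cm reporting resolution: the raw gap
            # between the marks is below two rounding steps
            assert abs(c.scl_from_lag - c.scl_from_otc) < 0.2
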