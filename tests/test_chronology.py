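import datetime as dt

import pytest
from hypothesis import given, strategies as st

from skeletochron.backcalc import back_calculate_length
from skeletochron.chronology import (
    AssignmentBasis,
    DepositionSeason,
    YearAssignment,
    assign_lag_years,
    collapse_double_lags,
    select_lag_nearest_date,
)
from skeletochron.errors import EmptyProfileError, LagResorbedError, StructuralError
from skeletochron.simulate import SimConfig, simulate_population


class TestCollapseDoubleLags:
    def test_no_flags_is_identity(self):
        d = [18.0, 20.0, 22.0]
        assert collapse_double_lags(d, [False] * 3) == d

    def test_flagged_pair_keeps_outer_line(self):
        out = collapse_double_lags([18.0, 19.9, 20.0, 22.0], [False, True, True, False])
        assert out == [18.0, 20.0, 22.0]

    def test_collapsed_double_back_calculates_like_its_outer_line(self, study_fixture):
        # the 1998 double of CM-12 reads as one annual mark at 57.7 cm
        records, profiles = study_fixture
        rec = next(r for r in records if r.id == "CM-12")
        prof = next(b for b in profiles if b.turtle_id == "CM-12")
        collapsed = collapse_double_lags(prof.lag_diameters, prof.double_flags)
        assert len(collapsed) == len(prof.lag_diameters) - 1
        scl = back_calculate_length(
            collapsed[0], prof.section_diameter, rec.scl_at_recovery
        )
        assert round(scl, 1) == 57.7

    def test_odd_run_of_flags_is_structural_error(self):
        with pytest.raises(StructuralError, match="pairs"):
            collapse_double_lags([18.0, 18.1, 18.2], [True, True, True])

    def test_flag_length_mismatch_is_structural_error(self):
        with pytest.raises(StructuralError):
            collapse_double_lags([18.0, 19.0], [True])

    @given(
        diams=st.lists(
            st.floats(3.0, 30.0), min_size=1, max_size=12, unique=True
        ).map(sorted),
        pair_at=st.integers(0, 10),
    )
    def test_never_longer_and_strictly_increasing(self, diams, pair_at):
        flags = [False] * len(diams)
        if pair_at + 1 < len(diams):
            flags[pair_at] = flags[pair_at + 1] = True
        out = collapse_double_lags(diams, flags)
        assert len(out) <= len(diams)
        assert all(a < b for a, b in zip(out, out[1:]))


class TestAssignLagYears:
    def test_spring_stranding_no_edge_growth_is_same_year(self):
        # CM-6: stranded 9 May 2000, final LAG at the bone edge
        out = assign_lag_years(2, dt.date(2000, 5, 9), edge_growth_present=False)
        assert [a.calendar_year for a in out] == [1999, 2000]
        assert out[-1].basis is AssignmentBasis.EDGE_SAME_YEAR

    def test_spring_stranding_with_edge_growth_is_previous_year(self):
        out = assign_lag_years(1, dt.date(2001, 4, 23), edge_growth_present=True)
        assert out[0].calendar_year == 2000
        assert out[0].basis is AssignmentBasis.EDGE_PREVIOUS_YEAR

    def test_post_season_stranding_with_edge_growth_is_stranding_year(self):
        # by December that year's spring LAG has long been deposited
        out = assign_lag_years(3, dt.date(2001, 12, 11), edge_growth_present=True)
        assert [a.calendar_year for a in out] == [1999, 2000, 2001]

    def test_stranding_before_deposition_forces_previous_year(self):
        out = assign_lag_years(1, dt.date(2001, 2, 1), edge_growth_present=False)
        assert out[0].calendar_year == 2000

    def test_empty_profile_is_an_error(self):
        with pytest.raises(EmptyProfileError):
            assign_lag_years(0, dt.date(2000, 5, 9), False)

    @given(
        n=st.integers(1, 15),
        doy=st.integers(1, 365),
        year=st.integers(1990, 2010),
        edge=st.booleans(),
    )
    def test_years_are_consecutive_ending_at_outermost(self, n, doy, year, edge):
        stranded = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
        out = assign_lag_years(n, stranded, edge)
        years = [a.calendar_year for a in out]
        assert years == list(range(years[-1] - n + 1, years[-1] + 1))
        assert years[-1] in (year, year - 1)

    def test_noise_free_simulation_recovers_true_deposition_years(self):
        """Post-season strandings make the edge rule unambiguous: every
        assigned year equals the simulator's true deposition year."""
        cfg = SimConfig(n_turtles=40, seed=5, scl_error_sd=0.0, diameter_error_sd=0.0,
                        p_double_lag=0.0, stranding_doy_range=(150, 365))
        records, profiles, truth = simulate_population(cfg)
        threshold = 0.05
        for rec, prof in zip(records, profiles):
            t = truth.by_id(rec.id)
            true_years = [e.calendar_year for e in t.lag_events if not e.resorbed]
            edge = (prof.section_diameter - prof.lag_diameters[-1]) > threshold
            out = assign_lag_years(len(prof.lag_diameters), rec.date_stranded, edge)
            assert [a.calendar_year for a in out] == true_years


def _assignments(years):
    return [
        YearAssignment(lag_index=i, calendar_year=y, basis=AssignmentBasis.COUNTED_BACK)
        for i, y in enumerate(years)
    ]


class TestSelectLagNearestDate:
    def test_tagging_shortly_after_deposition_selects_that_year(self):
        # CM-1 tagged 23 April 1997 -> the 1997 LAG
        idx = select_lag_nearest_date(_assignments([1997, 1998]), dt.date(1997, 4, 23))
        assert idx == 0

    def test_december_tagging_selects_the_coming_spring(self):
        # CM-4 tagged 21 December 1998: spring 1999 is nearer than spring 1998
        idx = select_lag_nearest_date(_assignments([1998, 1999]), dt.date(1998, 12, 21))
        assert idx == 1

    def test_exact_midpoint_breaks_toward_the_later_lag(self):
        season = DepositionSeason()
        mid_days = (season.nominal_date(2001) - season.nominal_date(2000)).days / 2
        target = season.nominal_date(2000) + dt.timedelta(days=int(mid_days))
        assert (season.nominal_date(2001) - target).days == (
            target - season.nominal_date(2000)
        ).days
        assert select_lag_nearest_date(_assignments([2000, 2001]), target, season) == 1

    def test_resorbed_target_year_signals_otc_fallback(self):
        # CM-13: tagged June 1994, earliest surviving LAG is 1995
        with pytest.raises(LagResorbedError, match="resorption"):
            select_lag_nearest_date(
                _assignments(list(range(1995, 2004))), dt.date(1994, 6, 17)
            )

    def test_no_lags_is_an_error(self):
        with pytest.raises(EmptyProfileError):
            select_lag_nearest_date([], dt.date(2000, 1, 1))
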