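"""Exposure-estimation primitives: travel time, area scaling, load propagation,
flow-weighted antecedent means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deicer_biofilm.config import TravelTimeLaw
from deicer_biofilm.hydro import (
    CompositeEvent,
    align_event_to_site,
    antecedent_features,
    event_volume_from_flow,
    flow_weighted_mean,
    propagate_concentration,
    scale_by_drainage_area,
    travel_time,
)


def make_event(start="2010-01-01", hours=168.0, site="DS1", volume=100.0,
               conc=50.0, **kw) -> CompositeEvent:
    s = pd.Timestamp(start)
    return CompositeEvent(
        start=s, end=s + pd.Timedelta(hours=hours), site=site,
        volume=volume, concentration=conc, **kw,
    )


class TestTravelTime:
    def test_unit_flow_returns_coefficient(self):
        assert travel_time(1.0) == pytest.approx(29.35, abs=1e-12)

    def test_power_law_evaluation(self):
        # independent evaluation of the power law at Q=2
        expected = 29.35 * 2.0 ** (-0.62)
        assert travel_time(2.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("q", [0.0, -1.0])
    def test_nonpositive_flow_rejected(self, q):
        with pytest.raises(ValueError):
            travel_time(q)

    def test_monotone_decreasing_on_grid(self):
        # brute-force numeric oracle: strictly decreasing over a flow grid
        grid = np.logspace(-2, 3, 200)
        t = travel_time(grid)
        assert np.all(np.diff(t) < 0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_covariance(self, q):
        # doubling the flow multiplies the travel time by 2**-0.62
        assert travel_time(2 * q) == pytest.approx(
            travel_time(q) * 2.0 ** (-0.62), rel=1e-9
        )

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError, match="calibrated"):
            travel_time(1.0, TravelTimeLaw(), flow_unit="m3/s")


class TestDrainageAreaScaling:
    def test_equal_per_area_yields(self):
        assert scale_by_drainage_area(10, 30, 10, 30, 20) == pytest.approx(20.0)

    def test_zero_inputs(self):
        assert scale_by_drainage_area(0, 0, 10, 30, 20) == 0.0

    def test_hand_computed_mixed_yields(self):
        # ((5/25 + 12/30) / 2) * 20 = 6
        assert scale_by_drainage_area(5, 12, 25, 30, 20) == pytest.approx(6.0)

    def test_linear_in_each_gage_quantity(self):
        base = scale_by_drainage_area(5, 12, 25, 30, 20)
        up_only = scale_by_drainage_area(10, 12, 25, 30, 20)
        assert up_only - base == pytest.approx(
            scale_by_drainage_area(5, 12, 25, 30, 20) - scale_by_drainage_area(0, 12, 25, 30, 20)
        )

    @pytest.mark.parametrize("areas", [(0, 30, 20), (25, -1, 20), (25, 30, 0)])
    def test_nonpositive_area_rejected(self, areas):
        with pytest.raises(ValueError):
            scale_by_drainage_area(5, 12, *areas)


class TestLoadPropagation:
    def test_mass_balance_arithmetic(self):
        ev = make_event(volume=100, conc=50)
        assert propagate_concentration(ev, 200.0) == pytest.approx(25.0)

    def test_identity_at_equal_volume(self):
        ev = make_event(volume=100, conc=50)
        assert propagate_concentration(ev, 100.0) == pytest.approx(50.0)

    def test_zero_target_volume_rejected(self):
        with pytest.raises(ValueError):
            propagate_concentration(make_event(), 0.0)

    @given(
        st.floats(min_value=0.1, max_value=1e4),
        st.floats(min_value=0.1, max_value=1e4),
        st.floats(min_value=0.1, max_value=1e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_conserved_exactly(self, volume, conc, target):
        ev = make_event(volume=volume, conc=conc)
        out = propagate_concentration(ev, target)
        assert out * target == pytest.approx(ev.load, rel=1e-12)

    def test_censored_source_uses_reporting_level(self):
        ev = make_event(volume=100, conc=3.0, censored=True, reporting_level=8.0)
        assert ev.working_concentration == 8.0
        assert propagate_concentration(ev, 100.0) == pytest.approx(8.0)


class TestEventAlignment:
    @staticmethod
    def flow_frame(q=1.0):
        t = pd.date_range("2010-01-01", "2010-01-20", freq="1h")
        return pd.DataFrame({"timestamp": t, "flow": np.full(len(t), q)})

    def test_zero_coefficient_leaves_event_unshifted(self):
        ev = make_event("2010-01-05")
        out = align_event_to_site(
            ev, self.flow_frame(), TravelTimeLaw(coefficient=0.0)
        )
        assert out.start == ev.start and out.end == ev.end

    def test_unit_flow_shifts_by_coefficient_hours(self):
        ev = make_event("2010-01-05", hours=48)
        out = align_event_to_site(ev, self.flow_frame(1.0))
        assert out.start - ev.start == pd.Timedelta(hours=29.35)
        assert out.end - out.start == ev.end - ev.start

    def test_equidistant_tie_uses_earlier_observation(self):
        # two observations straddle the midpoint symmetrically with
        # different flows; the earlier (larger-shift-free) one must win
        mid = pd.Timestamp("2010-01-05 12:00")
        flow = pd.DataFrame(
            {
                "timestamp": [mid - pd.Timedelta("30min"), mid + pd.Timedelta("30min")],
                "flow": [1.0, 100.0],
            }
        )
        ev = make_event("2010-01-05", hours=24)
        assert ev.midpoint == mid
        out = align_event_to_site(ev, flow)
        assert out.start - ev.start == pd.Timedelta(hours=29.35)

    def test_no_observation_near_midpoint_rejected(self):
        ev = make_event("2011-06-01")
        with pytest.raises(ValueError, match="no flow observation"):
            align_event_to_site(ev, self.flow_frame())


class TestFlowWeightedMean:
    def test_weighted_mean_arithmetic(self):
        evs = [
            make_event("2010-01-01", hours=24, volume=1, conc=10),
            make_event("2010-01-03", hours=24, volume=3, conc=20),
        ]
        s = flow_weighted_mean(evs, pd.Timestamp("2010-01-10"), 2)
        assert s.flow_weighted_mean == pytest.approx(17.5)
        assert s.total_load == pytest.approx(1 * 10 + 3 * 20)

    def test_single_event_returns_own_concentration(self):
        evs = [make_event("2010-01-01", volume=7, conc=42)]
        s = flow_weighted_mean(evs, pd.Timestamp("2010-01-10"), 2)
        assert s.flow_weighted_mean == pytest.approx(42.0)

    def test_empty_window_flagged_missing(self):
        s = flow_weighted_mean([], pd.Timestamp("2010-01-10"), 2)
        assert s.flow_weighted_mean is None and s.total_load is None

    def test_event_selection_keyed_to_midpoint(self):
        # midpoint outside the window excludes the event even if the
        # interval overlaps it
        ev = make_event("2010-01-01", hours=96, volume=1, conc=10)
        end = ev.midpoint + pd.Timedelta(weeks=2, hours=-1)
        inside = flow_weighted_mean([ev], end, 2)
        assert inside.flow_weighted_mean == pytest.approx(10.0)
        outside = flow_weighted_mean([ev], ev.midpoint + pd.Timedelta(weeks=2, hours=1), 2)
        assert outside.flow_weighted_mean is None

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.1, max_value=100),
                st.floats(min_value=1.0, max_value=500),
                st.integers(min_value=0, max_value=12),
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_mean_bounded_by_contributing_concentrations(self, triples):
        evs = [
            make_event(pd.Timestamp("2010-01-01") + pd.Timedelta(days=d),
                       hours=24, volume=v, conc=c)
            for v, c, d in triples
        ]
        s = flow_weighted_mean(evs, pd.Timestamp("2010-01-20"), 3)
        if s.flow_weighted_mean is not None:
            concs = [e.working_concentration for e in evs
                     if pd.Timestamp("2009-12-30") < e.midpoint <= pd.Timestamp("2010-01-20")]
            assert min(concs) - 1e-9 <= s.flow_weighted_mean <= max(concs) + 1e-9

    def test_split_invariance(self):
        # splitting one event into two with the same total volume and the
        # same concentration leaves the mean unchanged
        whole = [make_event("2010-01-02", hours=48, volume=10, conc=30),
                 make_event("2010-01-05", hours=24, volume=4, conc=12)]
        split = [
            make_event("2010-01-02", hours=24, volume=6, conc=30),
            make_event("2010-01-03", hours=24, volume=4, conc=30),
            make_event("2010-01-05", hours=24, volume=4, conc=12),
        ]
        end = pd.Timestamp("2010-01-10")
        a = flow_weighted_mean(whole, end, 2)
        b = flow_weighted_mean(split, end, 2)
        assert a.flow_weighted_mean == pytest.approx(b.flow_weighted_mean)
        assert a.total_load == pytest.approx(b.total_load)

    def test_low_completeness_flagged_missing(self):
        evs = [make_event("2010-01-09", hours=24, volume=1, conc=10)]
        s = flow_weighted_mean(evs, pd.Timestamp("2010-01-10"), 2, min_completeness=0.5)
        assert s.flow_weighted_mean is None
        assert 0 < s.completeness < 0.5


class TestEventVolume:
    def test_constant_flow_integrates_to_rate_times_duration(self):
        t = pd.date_range("2010-01-01", periods=100, freq="1h")
        flow = pd.DataFrame({"timestamp": t, "flow": np.full(100, 5.0)})
        v = event_volume_from_flow(flow, t[0], t[0] + pd.Timedelta(hours=48))
        assert v == pytest.approx(5.0 * 48)

    def test_uncovered_interval_rejected(self):
        t = pd.date_range("2010-01-01", periods=10, freq="1h")
        flow = pd.DataFrame({"timestamp": t, "flow": np.ones(10)})
        with pytest.raises(ValueError, match="cover"):
            event_volume_from_flow(flow, t[0], t[-1] + pd.Timedelta(hours=5))


def test_antecedent_features_table_layout():
    evs = {
        "DS1": [make_event("2010-01-01", hours=24, volume=2, conc=10),
                make_event("2010-01-05", hours=24, volume=2, conc=30)],
    }
    visits = pd.DataFrame(
        {"site": ["DS1"], "timestamp": [pd.Timestamp("2010-01-10")]}
    )
    out = antecedent_features(evs, visits, windows_weeks=(2,), min_completeness=0.0)
    assert len(out) == 1
    assert out.loc[0, "flow_weighted_mean_cod"] == pytest.approx(20.0)
    assert out.loc[0, "n_events"] == 2
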