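"""Four-quadrant concordance and half-circle polar trending statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemotrend import (
    DeltaPair,
    InvalidInputError,
    PairedCO,
    PolarTrending,
    UndefinedResultError,
    compute_deltas,
    four_quadrant,
    polar_stats,
    polar_transform,
)


def dp(d_ref, d_test, baseline=5.0):
    """DeltaPair with percentage changes computed against a common baseline."""
    return DeltaPair(
        "p", d_ref, d_test, 100.0 * d_ref / baseline, 100.0 * d_test / baseline
    )


def dp_pct(pct_ref, pct_test):
    return DeltaPair("p", pct_ref / 20.0, pct_test / 20.0, pct_ref, pct_test)


class TestComputeDeltas:
    def test_hand_values(self):
        t1 = [PairedCO("a", 1, 5.0, 6.0), PairedCO("b", 1, 6.0, 4.0)]
        t2 = [PairedCO("a", 2, 6.0, 6.0), PairedCO("b", 2, 6.0, 3.0)]
        deltas = {d.patient_id: d for d in compute_deltas(t1, t2)}
        assert deltas["a"].d_ref == pytest.approx(1.0)
        assert deltas["a"].pct_ref == pytest.approx(20.0)
        assert deltas["a"].d_test == pytest.approx(0.0)
        assert deltas["a"].pct_test == pytest.approx(0.0)
        assert deltas["b"].d_test == pytest.approx(-1.0)
        assert deltas["b"].pct_test == pytest.approx(-25.0)

    def test_unmatched_patient_skipped_with_warning(self, caplog):
        t1 = [PairedCO("a", 1, 5.0, 5.0), PairedCO("only_t1", 1, 5.0, 5.0)]
        t2 = [PairedCO("a", 2, 6.0, 6.0)]
        with caplog.at_level("WARNING", logger="hemotrend.trending"):
            deltas = compute_deltas(t1, t2)
        assert [d.patient_id for d in deltas] == ["a"]
        assert any("only_t1" in r.message for r in caplog.records)


class TestFourQuadrant:
    def test_all_concordant(self):
        assert four_quadrant([dp_pct(20, 20), dp_pct(-20, -20)])["concordance_pct"] == 100.0

    def test_single_discordant(self):
        assert four_quadrant([dp_pct(20, -20)])["concordance_pct"] == 0.0

    def test_exclusion_zone_drops_small_changes(self):
        out = four_quadrant([dp_pct(10, 10), dp_pct(20, 20), dp_pct(20, -20)], zone_pct=15)
        assert out["n_excluded"] == 1
        assert out["n_included"] == 2
        assert out["concordance_pct"] == 50.0
        assert out["good_trending"] is False

    def test_zone_requires_both_axes_small(self):
        # large reference change, tiny test change: kept (and discordant-ish)
        out = four_quadrant([dp_pct(30, 5), dp_pct(25, 25)], zone_pct=15)
        assert out["n_excluded"] == 0

    def test_all_excluded_is_an_explicit_undefined_result(self):
        with pytest.raises(UndefinedResultError):
            four_quadrant([dp_pct(5, 5), dp_pct(-3, 2)], zone_pct=15)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            four_quadrant([])

    @given(
        pcts=st.lists(
            st.tuples(st.floats(-60, 60), st.floats(-60, 60)), min_size=1, max_size=40
        ),
        zone=st.floats(1, 30),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_brute_force_sign_counting(self, pcts, zone):
        deltas = [dp_pct(a, b) for a, b in pcts]
        kept = [(a, b) for a, b in pcts if not (abs(a) < zone and abs(b) < zone)]
        if not kept:
            with pytest.raises(UndefinedResultError):
                four_quadrant(deltas, zone_pct=zone)
            return
        conc = sum(1 for a, b in kept if np.sign(a) == np.sign(b) and a != 0 and b != 0)
        expected = 100.0 * conc / len(kept)
        assert four_quadrant(deltas, zone_pct=zone)["concordance_pct"] == pytest.approx(expected)


class TestPolarTransform:
    def test_identity_line_point(self):
        p = polar_transform(dp(1.0, 1.0))
        assert p.angle_deg == pytest.approx(0.0, abs=1e-12)
        assert p.radius == pytest.approx(1.0)
        assert p.included

    def test_concordant_negative_change_folds_onto_axis(self):
        p = polar_transform(dp(-1.0, -1.0))
        assert p.angle_deg == pytest.approx(0.0, abs=1e-12)
        assert p.radius == pytest.approx(1.0)

    def test_reference_only_change(self):
        p = polar_transform(dp(1.0, 0.0))
        assert p.angle_deg == pytest.approx(-45.0)
        assert p.radius == pytest.approx(0.5)

    def test_small_mean_change_excluded_by_zone(self):
        p = polar_transform(dp(0.4, 0.4), zone_lmin=0.5)
        assert not p.included
        boundary = polar_transform(dp(0.5, 0.5), zone_lmin=0.5)
        assert boundary.included  # boundary points kept

    @given(
        d=st.tuples(st.floats(-3, 3), st.floats(-3, 3)),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_positive_scaling_preserves_angle(self, d, scale):
        p1 = polar_transform(dp(*d))
        p2 = polar_transform(dp(scale * d[0], scale * d[1]))
        assert p2.angle_deg == pytest.approx(p1.angle_deg, abs=1e-9)
        assert p2.radius == pytest.approx(scale * p1.radius, rel=1e-9)


class TestPolarStats:
    def test_identity_line_points(self):
        out = polar_stats([dp(1.0, 1.0), dp(2.0, 2.0), dp(-1.5, -1.5)])
        assert out["mean_polar_angle_deg"] == pytest.approx(0.0, abs=1e-12)
        assert out["radial_loa_low_deg"] == pytest.approx(0.0, abs=1e-12)
        assert out["concordance_pct"] == 100.0
        assert out["good_trending"] is True

    def test_symmetric_angles_hand_value(self):
        # angles {+10, -10}: mean 0, sd 10*sqrt(2) = 14.14, LOA +/- 27.72
        a = math.radians(10.0 + 45.0)
        pts = [dp(2.0 * math.cos(a), 2.0 * math.sin(a)),
               dp(2.0 * math.sin(a), 2.0 * math.cos(a))]
        out = polar_stats(pts)
        assert out["mean_polar_angle_deg"] == pytest.approx(0.0, abs=1e-9)
        assert out["radial_loa_high_deg"] == pytest.approx(1.96 * 10 * math.sqrt(2), abs=1e-6)

    def test_zone_excludes_small_radius_points_from_all_statistics(self):
        pts = [dp(1.0, 1.0), dp(2.0, 2.0), dp(0.3, 0.5)]  # last: radius 0.4
        out = polar_stats(pts, zone_lmin=0.5)
        assert out["n_included"] == 2
        assert out["mean_polar_angle_deg"] == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_included_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            polar_stats([dp(0.1, 0.1), dp(0.2, 0.1)], zone_lmin=0.5)

    def test_percentile_loa_option(self):
        rng = np.random.default_rng(3)
        pts = [dp(r, t) for r, t in 1.0 + 0.3 * rng.standard_normal((50, 2))]
        est = PolarTrending(radial_loa_method="percentile").fit(pts)
        angles = np.array([p.angle_deg for p in est.points_ if p.included])
        lo, hi = np.percentile(angles, [2.5, 97.5])
        assert est.radial_loa_low_deg_ == pytest.approx(lo)
        assert est.radial_loa_high_deg_ == pytest.approx(hi)


@given(
    ds=st.lists(st.tuples(st.floats(-3, 3), st.floats(-3, 3)), min_size=4, max_size=30)
)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_method_swap_negates_angles_and_preserves_concordance(ds):
    fwd = [polar_transform(dp(a, b)) for a, b in ds]
    rev = [polar_transform(dp(b, a)) for a, b in ds]
    for (a, b), f, r in zip(ds, fwd, rev):
        if a == 0 and b == 0:
            continue  # zero change vector: angle is a convention, not a datum
        # angles on the fold boundary (+/-180) are their own negation mod 360
        diff = (f.angle_deg + r.angle_deg) % 360.0
        assert min(diff, 360.0 - diff) == pytest.approx(0.0, abs=1e-9)
        assert f.radius == pytest.approx(r.radius)
    deltas_fwd = [dp(a, b) for a, b in ds]
    deltas_rev = [dp(b, a) for a, b in ds]
    try:
        c1 = four_quadrant(deltas_fwd, zone_pct=15)["concordance_pct"]
    except UndefinedResultError:
        with pytest.raises(UndefinedResultError):
            four_quadrant(deltas_rev, zone_pct=15)
        return
    assert four_quadrant(deltas_rev, zone_pct=15)["concordance_pct"] == pytest.approx(c1)
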