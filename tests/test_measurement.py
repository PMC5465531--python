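"""Cardiac output computation from raw quantities and replicate precision."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemotrend import (
    EchoMeasurement,
    InvalidInputError,
    ReplicatePrecision,
    ThermodilutionSeries,
    echo_cardiac_output,
    lvot_area,
    pac_cardiac_output,
    precision_stats,
)


class TestLvotArea:
    @pytest.mark.parametrize(
        "diameters, expected",
        [
            ([2.0, 2.0, 2.0], math.pi),                # unit radius
            ([1.8, 2.0, 2.2], math.pi),                # symmetric about 2.0
            ([1.6], math.pi * 0.64),                   # single measurement, r=0.8
        ],
    )
    def test_circular_area_from_mean_diameter(self, diameters, expected):
        assert lvot_area(diameters) == pytest.approx(expected, rel=1e-12)

    def test_rounded_pi_literal_reproduces_printed_formula(self):
        assert lvot_area([2.0, 2.0, 2.0], pi_literal=3.14) == pytest.approx(3.14, abs=1e-15)

    @pytest.mark.parametrize("bad", [[], [0.0], [-1.5, 2.0], [float("nan")]])
    def test_rejects_empty_or_nonpositive(self, bad):
        with pytest.raises(InvalidInputError):
            lvot_area(bad)

    @given(
        d=st.lists(st.floats(0.5, 4.0), min_size=1, max_size=6),
        factor=st.floats(1.01, 3.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_scale_law_doubling_diameters_quadruples_area(self, d, factor):
        base = lvot_area(d)
        scaled = lvot_area([factor * x for x in d])
        assert scaled == pytest.approx(factor**2 * base, rel=1e-9)
        assert scaled > base  # strictly increasing in scale


class TestEchoCardiacOutput:
    def test_hand_computed_stroke_volume_and_co(self):
        m = EchoMeasurement("p1", 1, (2.0, 2.0, 2.0), (20.0,) * 5, 100.0)
        out = echo_cardiac_output(m)
        assert out["sv_ml"] == pytest.approx(math.pi * 20.0, rel=1e-12)   # 62.83 ml
        assert out["co_lmin"] == pytest.approx(math.pi * 2.0, rel=1e-12)  # 6.28 L/min

    def test_low_heart_rate_example(self):
        m = EchoMeasurement("p1", 1, (2.0,) * 3, (10.0,) * 5, 50.0)
        out = echo_cardiac_output(m)
        assert out["sv_ml"] == pytest.approx(31.4159, abs=1e-3)
        assert out["co_lmin"] == pytest.approx(1.5708, abs=1e-3)

    def test_near_degenerate_vti_yields_near_zero_co_without_error(self):
        m = EchoMeasurement("p1", 1, (2.0,) * 3, (0.001,) * 5, 100.0)
        out = echo_cardiac_output(m)
        assert 0 < out["co_lmin"] < 1e-3

    def test_replicate_order_is_irrelevant(self):
        a = EchoMeasurement("p", 1, (1.8, 2.0, 2.2), (18, 20, 22, 19, 21), 90.0)
        b = EchoMeasurement("p", 1, (2.2, 1.8, 2.0), (21, 19, 22, 20, 18), 90.0)
        assert echo_cardiac_output(a) == echo_cardiac_output(b)

    def test_nonpositive_heart_rate_rejected(self):
        with pytest.raises(InvalidInputError):
            EchoMeasurement("p", 1, (2.0,) * 3, (20.0,) * 5, 0.0)

    def test_off_nominal_replicate_counts_warn_but_compute(self, caplog):
        with caplog.at_level("WARNING", logger="hemotrend.measurement"):
            m = EchoMeasurement("p", 1, (2.0, 2.0), (20.0,) * 4, 80.0)
        assert echo_cardiac_output(m)["co_lmin"] > 0
        assert sum("nominal" in r.message for r in caplog.records) == 2


class TestPacCardiacOutput:
    @pytest.mark.parametrize(
        "boluses, expected",
        [
            ((5, 6, 7, 6, 6), 6.0),
            ((4, 4, 4, 4, 4), 4.0),
            ((5.2, 5.8, 6.1, 5.9, 6.0), 5.8),
        ],
    )
    def test_mean_of_bolus_series(self, boluses, expected):
        s = ThermodilutionSeries("p", 1, boluses)
        assert pac_cardiac_output(s) == pytest.approx(expected, rel=1e-12)

    def test_fewer_than_two_boluses_rejected(self):
        with pytest.raises(InvalidInputError):
            ThermodilutionSeries("p", 1, (5.0,))


class TestReplicatePrecision:
    def test_constant_replicates_give_zero_precision(self):
        res = precision_stats([[6.0] * 5, [4.2] * 5], "ref")
        assert res.pooled_cv == 0.0
        assert res.precision_pct == 0.0
        assert res.lsc_pct == 0.0

    def test_single_subject_hand_value(self):
        # CV = 1/10, n = 3: precision = 100*2*0.1/sqrt(3), LSC = precision*sqrt(2)
        res = precision_stats([[9.0, 10.0, 11.0]], "ref")
        assert res.pooled_cv == pytest.approx(0.1, rel=1e-12)
        assert res.precision_pct == pytest.approx(11.5470, abs=1e-4)
        assert res.lsc_pct == pytest.approx(16.3299, abs=1e-4)

    def test_rms_pooling_of_two_subjects(self):
        s = math.sqrt(2.0)
        a = [10 - 0.6 * s, 10, 10, 10, 10 + 0.6 * s]  # CV 0.06
        b = [10 - 1.0 * s, 10, 10, 10, 10 + 1.0 * s]  # CV 0.10
        res = precision_stats([a, b], "ref")
        assert res.pooled_cv == pytest.approx(math.sqrt((0.0036 + 0.01) / 2), rel=1e-9)
        assert res.precision_pct == pytest.approx(7.3756, abs=1e-3)

    def test_pooling_is_idempotent_over_subject_copies(self):
        one = precision_stats([[9.0, 10.0, 11.0]], "x")
        many = precision_stats([[9.0, 10.0, 11.0]] * 7, "x")
        assert many.pooled_cv == pytest.approx(one.pooled_cv, rel=1e-12)
        assert many.precision_pct == pytest.approx(one.precision_pct, rel=1e-12)

    def test_alternative_k_and_mean_pooling(self):
        est = ReplicatePrecision(k=1.96, pooling="mean").fit([[9.0, 10.0, 11.0]])
        assert est.precision_pct_ == pytest.approx(100 * 1.96 * 0.1 / math.sqrt(3), rel=1e-12)

    def test_subject_with_single_replicate_named_in_error(self):
        with pytest.raises(InvalidInputError, match="subject 1"):
            precision_stats([[5.0, 6.0], [5.0]], "ref")

    def test_recovers_generating_cv_at_large_n(self):
        rng = np.random.default_rng(42)
        cv = 0.09
        sets = 6.0 * (1.0 + rng.normal(0.0, cv, size=(1000, 5)))
        res = precision_stats(list(sets), "ref")
        assert res.pooled_cv == pytest.approx(cv, abs=0.005)
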