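"""Binomial occupancy model: examples frozen against independent oracles.

Tail probabilities are cross-checked against brute-force summation of the
binomial pmf written out with ``math.comb`` (no scipy), and the joint
reversal probability against full enumeration over occupancy pairs.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tugtrap.occupancy import (
    CargoGeometry,
    MotorPopulation,
    OccupancyModel,
    contact_fraction,
    default_dynein,
    default_kinesin,
    expected_in_contact,
    joint_reversal_probability,
    kinesin_team_probabilities,
    lipid_residence_time,
    occupancy_pmf,
    occupancy_tail,
    rotational_rms_angle,
    scale_motor_count,
)


def _pmf(n, p, k):
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def _tail(n, p, m):
    return sum(_pmf(n, p, k) for k in range(m, n + 1))


class TestGeometry:
    def test_contact_fraction_750nm_cargo(self):
        # 0.08 um^2 on a 750-nm sphere is ~4.5% of 4*pi*R^2
        geom = CargoGeometry(diameter=750.0, contact_area=0.08)
        assert contact_fraction(geom) == pytest.approx(0.0453, abs=1e-4)

    def test_zero_area(self):
        assert contact_fraction(CargoGeometry(contact_area=0.0)) == 0.0

    def test_area_exceeding_sphere_rejected(self):
        with pytest.raises(ValueError):
            CargoGeometry(diameter=750.0, contact_area=10.0)

    @pytest.mark.parametrize(
        "count, d_ref, d_tgt, raw, two_sf",
        [
            (3.5, 90.0, 750.0, 243.0556, 240.0),
            (30.0, 250.0, 750.0, 270.0, 270.0),
            (17.0, 400.0, 400.0, 17.0, 17.0),
        ],
    )
    def test_surface_area_scaling(self, count, d_ref, d_tgt, raw, two_sf):
        out = scale_motor_count(count, d_ref, d_tgt)
        assert out["raw"] == pytest.approx(raw, rel=1e-6)
        assert out["rounded_2sf"] == two_sf

    def test_scaling_rejects_bad_diameter(self):
        with pytest.raises(ValueError):
            scale_motor_count(3.5, 0.0, 750.0)

    @pytest.mark.parametrize(
        "total, p, raw, nearest",
        [(240, 0.04, 9.6, 10), (40, 0.04, 1.6, 2), (0, 0.5, 0.0, 0)],
    )
    def test_expected_in_contact(self, total, p, raw, nearest):
        out = expected_in_contact(total, p)
        assert out["raw"] == pytest.approx(raw)
        assert out["nearest_int"] == nearest


class TestBinomials:
    def test_pmf_single_kinesin(self):
        assert occupancy_pmf(40, 0.04, 1) == pytest.approx(
            40 * 0.04 * 0.96**39, rel=1e-12
        )

    def test_pmf_rejects_k_beyond_n(self):
        with pytest.raises(ValueError):
            occupancy_pmf(10, 0.5, 11)

    def test_tail_at_zero_threshold_is_one(self):
        assert occupancy_tail(40, 0.04, 0) == 1.0

    @pytest.mark.parametrize("n, p, m", [(40, 0.04, 1), (240, 0.04, 6), (10, 0.3, 4)])
    def test_tail_matches_brute_force_sum(self, n, p, m):
        assert occupancy_tail(n, p, m) == pytest.approx(_tail(n, p, m), rel=1e-10)

    def test_tail_reference_values(self):
        assert occupancy_tail(40, 0.04, 1) == pytest.approx(0.80463, abs=1e-5)
        assert occupancy_tail(240, 0.04, 6) == pytest.approx(0.92044, abs=1e-5)

    # p stays clear of subnormal floats, where scipy's beta-function
    # backend overflows
    _probs = st.one_of(st.just(0.0), st.just(1.0), st.floats(1e-9, 1.0 - 1e-9))

    @given(n=st.integers(1, 300), p=_probs)
    def test_pmf_normalizes(self, n, p):
        total = sum(occupancy_pmf(n, p, k) for k in range(n + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(n=st.integers(1, 100), p=st.floats(0.01, 0.99))
    def test_tail_monotone_in_threshold(self, n, p):
        tails = [occupancy_tail(n, p, m) for m in range(n + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    @given(n=st.integers(2, 100), m=st.integers(1, 5))
    def test_tail_monotone_in_p_and_n(self, n, m):
        m = min(m, n)
        assert occupancy_tail(n, 0.3, m) <= occupancy_tail(n, 0.6, m) + 1e-15
        assert occupancy_tail(n, 0.3, m) <= occupancy_tail(n + 5, 0.3, m) + 1e-15


class TestJointReversal:
    def test_default_model_gives_74_percent(self):
        assert joint_reversal_probability(OccupancyModel()) == pytest.approx(
            0.7406, abs=5e-4
        )

    def test_zero_contact_probability(self):
        model = OccupancyModel(contact_fraction_p=0.0)
        assert joint_reversal_probability(model) == 0.0

    def test_certain_occupancy(self):
        model = OccupancyModel(
            dynein=default_dynein(6),
            kinesin=default_kinesin(1),
            contact_fraction_p=1.0,
        )
        assert joint_reversal_probability(model) == pytest.approx(1.0)

    @pytest.mark.parametrize("nd, nk, p", [(8, 3, 0.3), (12, 5, 0.1), (6, 2, 0.7)])
    def test_matches_enumeration_over_occupancy_pairs(self, nd, nk, p):
        model = OccupancyModel(
            dynein=default_dynein(nd),
            kinesin=default_kinesin(nk),
            contact_fraction_p=p,
            team_threshold_dynein=min(6, nd),
            team_threshold_kinesin=1,
        )
        brute = sum(
            _pmf(nd, p, i) * _pmf(nk, p, j)
            for i in range(nd + 1)
            for j in range(nk + 1)
            if i >= model.team_threshold_dynein and j >= model.team_threshold_kinesin
        )
        assert joint_reversal_probability(model) == pytest.approx(brute, rel=1e-10)

    def test_threshold_above_count_rejected(self):
        with pytest.raises(ValueError):
            OccupancyModel(dynein=default_dynein(4), team_threshold_dynein=6)


class TestKinesinTeams:
    def test_reference_split(self):
        out = kinesin_team_probabilities(40, 0.04)
        assert out["P_0K"] == pytest.approx(0.1954, abs=1e-4)
        assert out["P_1K"] == pytest.approx(0.3256, abs=1e-4)
        assert out["P_gt1K"] == pytest.approx(0.4790, abs=1e-4)

    def test_zero_success_probability(self):
        assert kinesin_team_probabilities(25, 0.0) == {
            "P_0K": 1.0,
            "P_1K": 0.0,
            "P_gt1K": 0.0,
        }

    _probs = st.one_of(st.just(0.0), st.just(1.0), st.floats(1e-9, 1.0 - 1e-9))

    @given(n=st.integers(1, 200), p=_probs)
    def test_components_sum_to_one(self, n, p):
        out = kinesin_team_probabilities(n, p)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)


class TestTimescales:
    @pytest.mark.parametrize(
        "area, d, ms", [(0.08, 10.0, 2.0), (0.08, 1.4, 14.2857), (0.0, 5.0, 0.0)]
    )
    def test_lipid_residence_time(self, area, d, ms):
        assert lipid_residence_time(area, d)["ms"] == pytest.approx(ms, rel=1e-4)

    def test_residence_rejects_nonpositive_diffusion(self):
        with pytest.raises(ValueError):
            lipid_residence_time(0.08, 0.0)

    def test_rotation_during_flyback_is_about_one_degree(self):
        # 750-nm sphere, water viscosity, 0.05 ms
        angle = rotational_rms_angle(750.0, 1e-3, 295.0, 5e-5)
        assert angle == pytest.approx(1.0, abs=0.05)

    def test_rotation_zero_duration(self):
        assert rotational_rms_angle(750.0, 1e-3, 295.0, 0.0) == 0.0

    def test_rotation_sqrt_time_scaling(self):
        a1 = rotational_rms_angle(750.0, 1e-3, 295.0, 1e-4)
        a4 = rotational_rms_angle(750.0, 1e-3, 295.0, 4e-4)
        assert a4 == pytest.approx(2.0 * a1, rel=1e-9)

    def test_rotation_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            rotational_rms_angle(-1.0, 1e-3, 295.0, 1e-4)


class TestMotorPopulation:
    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            MotorPopulation("x", "sideways", 1.0, 1.0, 1.0, 10)

    def test_negative_rate(self):
        with pytest.raises(ValueError):
            MotorPopulation("x", "plus", 1.0, -1.0, 1.0, 10)
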