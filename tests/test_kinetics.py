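"""Binding-kinetics closed forms, Gillespie trajectories and first passage.

The analytic first-passage recursion is itself validated against a linear
solve of the birth-death hitting-time equations, so the Monte Carlo layer is
checked against an independently verified oracle.
"""

import numpy as np
import pytest

from tugtrap.io import derive_rng
from tugtrap.kinetics import (
    characteristic_time,
    equilibrium_occupancy,
    expected_bound,
    first_passage_analytic,
    first_passage_mc,
    mean_occupancy,
    simulate_binding,
)


def _hitting_time_linear_solve(n, k_on, k_off, m):
    """Mean time from state 0 to state m via the full linear system.

    For transient states k < m: (lam_k + mu_k) h_k = 1 + lam_k h_{k+1} +
    mu_k h_{k-1}, with h_m = 0; solve A h = b with numpy.
    """
    size = m
    a = np.zeros((size, size))
    b = np.ones(size)
    for k in range(size):
        lam = (n - k) * k_on
        mu = k * k_off
        a[k, k] = lam + mu
        if k + 1 < size:
            a[k, k + 1] = -lam
        if k - 1 >= 0:
            a[k, k - 1] = -mu
    return float(np.linalg.solve(a, b)[0])


class TestClosedForms:
    @pytest.mark.parametrize(
        "k_on, k_off, c_eq",
        [(1.6, 0.27, 0.8556), (5.0, 1.0, 0.8333), (2.0, 0.0, 1.0)],
    )
    def test_equilibrium_occupancy(self, k_on, k_off, c_eq):
        assert equilibrium_occupancy(k_on, k_off) == pytest.approx(c_eq, abs=1e-4)

    def test_both_rates_zero_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_occupancy(0.0, 0.0)

    @pytest.mark.parametrize(
        "k_on, k_off, tau",
        [(1.6, 0.27, 0.5348), (5.0, 1.0, 0.16667), (0.5, 0.5, 1.0)],
    )
    def test_characteristic_time(self, k_on, k_off, tau):
        assert characteristic_time(k_on, k_off) == pytest.approx(tau, abs=1e-4)

    def test_occupancy_starts_at_zero(self):
        assert mean_occupancy(0.0, 1.6, 0.27) == 0.0

    def test_occupancy_at_characteristic_time_is_63_percent(self):
        for k_on, k_off in [(1.6, 0.27), (5.0, 1.0)]:
            tau = characteristic_time(k_on, k_off)
            c = mean_occupancy(tau, k_on, k_off)
            assert c == pytest.approx(
                equilibrium_occupancy(k_on, k_off) * (1 - 1 / np.e), rel=1e-12
            )

    def test_occupancy_limit(self):
        tau = characteristic_time(1.6, 0.27)
        assert mean_occupancy(50 * tau, 1.6, 0.27) == pytest.approx(
            equilibrium_occupancy(1.6, 0.27), abs=1e-9
        )

    def test_occupancy_rejects_negative_time(self):
        with pytest.raises(ValueError):
            mean_occupancy(-0.1, 1.6, 0.27)

    def test_occupancy_satisfies_rate_equation(self):
        # finite-difference check of dC/dt = k_on (1 - C) - k_off C
        k_on, k_off, h = 1.6, 0.27, 1e-6
        for t in (0.05, 0.3, 1.0, 3.0):
            lhs = (mean_occupancy(t + h, k_on, k_off)
                   - mean_occupancy(t - h, k_on, k_off)) / (2 * h)
            c = mean_occupancy(t, k_on, k_off)
            assert lhs == pytest.approx(k_on * (1 - c) - k_off * c, rel=1e-5)

    @pytest.mark.parametrize(
        "n, k_on, k_off, t, value",
        [(10, 1.6, 0.27, 0.5348, 5.41), (2, 5.0, 1.0, 0.16667, 1.05), (0, 5, 1, 1, 0.0)],
    )
    def test_expected_bound(self, n, k_on, k_off, t, value):
        assert expected_bound(n, k_on, k_off, t) == pytest.approx(value, abs=0.01)


class TestTrajectories:
    def test_no_attachment_without_on_rate(self):
        _, states = simulate_binding(5, 0.0, 1.0, 10.0, derive_rng(0, 1))
        assert np.all(states == 0)

    def test_absorbs_at_full_occupancy_without_off_rate(self):
        times, states = simulate_binding(5, 2.0, 0.0, 100.0, derive_rng(0, 2))
        assert states[-1] == 5
        assert np.all(np.diff(states) == 1)

    def test_event_times_strictly_increase(self):
        times, _ = simulate_binding(10, 1.6, 0.27, 50.0, derive_rng(0, 3))
        assert np.all(np.diff(times) > 0)

    def test_deterministic_given_seed(self):
        t1, s1 = simulate_binding(10, 1.6, 0.27, 20.0, derive_rng(9, 0))
        t2, s2 = simulate_binding(10, 1.6, 0.27, 20.0, derive_rng(9, 0))
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(s1, s2)

    def test_long_run_average_matches_equilibrium(self):
        n, k_on, k_off, t_max = 10, 1.6, 0.27, 1e4
        times, states = simulate_binding(n, k_on, k_off, t_max, derive_rng(0, 4))
        edges = np.append(times, t_max)
        dwell = np.diff(edges)
        mean_frac = float(np.sum(states * dwell) / t_max / n)
        # SE from batch means over 100 macro-batches
        batches = np.array_split(np.arange(times.size), 100)
        bm = [np.sum(states[b] * dwell[b]) / np.sum(dwell[b]) / n for b in batches]
        se = np.std(bm, ddof=1) / np.sqrt(len(bm))
        assert abs(mean_frac - equilibrium_occupancy(k_on, k_off)) < 3 * max(se, 1e-3)

    def test_ensemble_mean_matches_rate_equation(self):
        # mean-field correspondence is exact for independent motors
        n, k_on, k_off = 10, 1.6, 0.27
        t_probe = characteristic_time(k_on, k_off)
        rng = derive_rng(0, 5)
        vals = []
        for _ in range(2000):
            times, states = simulate_binding(n, k_on, k_off, t_probe, rng)
            vals.append(states[np.searchsorted(times, t_probe, "right") - 1])
        vals = np.asarray(vals, dtype=float)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - expected_bound(n, k_on, k_off, t_probe)) < 3 * se


class TestFirstPassage:
    def test_recursion_matches_linear_solve(self):
        for n, k_on, k_off, m in [(10, 1.6, 0.27, 6), (10, 1.6, 0.27, 3),
                                  (5, 2.0, 3.0, 5), (2, 5.0, 1.0, 1)]:
            assert first_passage_analytic(n, k_on, k_off, m) == pytest.approx(
                _hitting_time_linear_solve(n, k_on, k_off, m), rel=1e-10
            )

    def test_six_of_ten_dyneins(self):
        assert first_passage_analytic(10, 1.6, 0.27, 6) == pytest.approx(
            0.5686, abs=2e-4
        )

    def test_first_of_two_kinesins_is_single_exponential(self):
        assert first_passage_analytic(2, 5.0, 1.0, 1) == pytest.approx(0.1, rel=1e-12)

    def test_pure_birth_limit(self):
        n, k_on, m = 7, 1.3, 5
        expected = sum(1.0 / ((n - k) * k_on) for k in range(m))
        assert first_passage_analytic(n, k_on, 0.0, m) == pytest.approx(expected)

    def test_zero_threshold_by_convention(self):
        assert first_passage_analytic(10, 1.6, 0.27, 0) == 0.0
        assert first_passage_mc(10, 1.6, 0.27, 0, 10, derive_rng(0, 6)).mean == 0.0

    def test_threshold_beyond_n_rejected(self):
        with pytest.raises(ValueError):
            first_passage_analytic(5, 1.0, 1.0, 6)

    def test_unreachable_state(self):
        with pytest.raises(ValueError):
            first_passage_mc(5, 0.0, 1.0, 2, 10, derive_rng(0, 7))

    @pytest.mark.parametrize("n, m", [(10, 6), (10, 3), (2, 1), (5, 5)])
    def test_mc_agrees_with_analytic_oracle(self, n, m):
        k_on, k_off = (1.6, 0.27) if n != 2 else (5.0, 1.0)
        res = first_passage_mc(n, k_on, k_off, m, 3000, derive_rng(0, 8, n, m))
        exact = first_passage_analytic(n, k_on, k_off, m)
        assert abs(res.mean - exact) < 3 * res.sem
        assert res.sem > 0 and res.replicates == 3000
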