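"""Synthetic trace generator: OU statistics, programmed events, ground truth."""

import math

import numpy as np
import pytest

from tugtrap.io import derive_rng
from tugtrap.occupancy import BOLTZMANN_PN_NM
from tugtrap.synth import (
    TraceGenConfig,
    TrapConfig,
    flyback_segment,
    generate_dataset,
    generate_trace,
    stall_segment,
    thermal_segment,
    truth_pairs,
)

TRAP = TrapConfig()
NOISELESS = TrapConfig(detector_noise_sd=0.0)


class TestThermalBath:
    def test_stationary_sd_matches_equipartition(self):
        x = thermal_segment(NOISELESS, 50.0, derive_rng(0, 0))
        expected = math.sqrt(BOLTZMANN_PN_NM * NOISELESS.temperature / NOISELESS.stiffness)
        assert np.std(x) == pytest.approx(expected, rel=0.05)

    def test_detector_noise_adds_in_quadrature(self):
        trap = TrapConfig(detector_noise_sd=10.0)
        x = thermal_segment(trap, 50.0, derive_rng(0, 1))
        expected = math.hypot(trap.thermal_sd, 10.0)
        assert np.std(x) == pytest.approx(expected, rel=0.05)

    def test_stiff_trap_limit(self):
        trap = TrapConfig(stiffness=20.0, detector_noise_sd=0.0)
        x = thermal_segment(trap, 5.0, derive_rng(0, 2))
        assert np.std(x) < 0.5  # nm

    def test_lag1_autocorrelation_matches_ou(self):
        x = thermal_segment(NOISELESS, 50.0, derive_rng(0, 3))
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        expected = math.exp(-NOISELESS.dt / NOISELESS.relaxation_time)
        assert r1 == pytest.approx(expected, abs=0.02)

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            thermal_segment(TRAP, 0.0, derive_rng(0, 4))


class TestStallSegment:
    def test_noise_free_plateau_equals_force_over_stiffness(self):
        seg = stall_segment(TRAP, "plus", 6.0, 2000.0, 1.0, derive_rng(0, 0),
                            noise_scale=0.0)
        assert seg["positions"].max() == pytest.approx(300.0, rel=1e-6)

    def test_minus_direction_sign(self):
        seg = stall_segment(TRAP, "minus", 6.0, 2000.0, 1.0, derive_rng(0, 0),
                            noise_scale=0.0)
        assert seg["positions"].min() == pytest.approx(-300.0, rel=1e-6)

    def test_initial_slope_is_unloaded_velocity(self):
        seg = stall_segment(TRAP, "plus", 6.0, 2000.0, 1.0, derive_rng(0, 0),
                            noise_scale=0.0)
        slope = seg["positions"][0] / TRAP.dt
        assert slope == pytest.approx(2000.0, rel=0.01)

    def test_half_max_width_equals_programmed_duration(self):
        for force, duration in [(6.0, 1.0), (4.4, 0.8), (12.0, 1.3)]:
            seg = stall_segment(TRAP, "plus", force, 2000.0, duration,
                                derive_rng(0, 0), noise_scale=0.0)
            x = seg["positions"]
            above = np.flatnonzero(x >= 0.5 * x.max())
            width = (above[-1] - above[0] + 1) * TRAP.dt
            assert abs(width - duration) <= 2 * TRAP.dt

    def test_duration_shorter_than_rise_rejected(self):
        with pytest.raises(ValueError, match="shorter than the rise"):
            stall_segment(TRAP, "plus", 12.0, 2000.0, 0.3, derive_rng(0, 0))


class TestFlyback:
    def test_free_flyback_reenters_band_within_5_ms(self):
        seg = flyback_segment(TRAP, 300.0, "free", derive_rng(0, 0))
        assert 0 < seg["band_entry_time"] < 0.005

    def test_tug_of_war_band_entry_at_programmed_resist_time(self):
        seg = flyback_segment(TRAP, 300.0, "tug_of_war", derive_rng(0, 0),
                              resist_time=0.05)
        assert seg["band_entry_time"] == pytest.approx(0.05, rel=1e-9)
        assert seg["duration"] > 0.05

    def test_start_inside_band_is_zero_length(self):
        seg = flyback_segment(TRAP, 5.0, "free", derive_rng(0, 0))
        assert seg["positions"].size == 0 and seg["band_entry_time"] == 0.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            flyback_segment(TRAP, 300.0, "sideways", derive_rng(0, 0))


class TestGenerateTrace:
    def test_deterministic_given_seed(self):
        t1, g1 = generate_trace(TraceGenConfig(n_events=10), seed=3, trace_index=2)
        t2, g2 = generate_trace(TraceGenConfig(n_events=10), seed=3, trace_index=2)
        np.testing.assert_array_equal(t1.position_parallel, t2.position_parallel)
        assert g1.equals(g2)

    def test_truth_counts_events(self):
        _, truth = generate_trace(TraceGenConfig(n_events=15), seed=3)
        assert (~truth["premature"]).sum() == 15

    def test_certain_rapid_reversal(self):
        cfg = TraceGenConfig(n_events=30, p_rr=1.0)
        _, truth = generate_trace(cfg, seed=5)
        pairs = truth_pairs(truth)
        assert (pairs["inactive_duration"] < 0.5).all()
        assert pairs["is_rr"].all()

    def test_truth_pair_fractions_follow_coin(self):
        q = 0.5
        frames = [generate_trace(TraceGenConfig(n_events=40, p_kinesin=q),
                                 seed=11, trace_index=i)[1] for i in range(30)]
        import pandas as pd

        pairs = truth_pairs(pd.concat(frames, ignore_index=True))
        n = len(pairs)
        assert n == 30 * 39
        for ptype, p_exp in {"KK": q * q, "KD": q * (1 - q),
                             "DK": (1 - q) * q, "DD": (1 - q) ** 2}.items():
            frac = (pairs["pair_type"] == ptype).mean()
            se = math.sqrt(p_exp * (1 - p_exp) / n)
            assert abs(frac - p_exp) < 3.5 * se

    def test_dynein_pairs_give_2pN_periodicity(self):
        _, truth = generate_trace(
            TraceGenConfig(n_events=40, p_kinesin=0.0, force_jitter_sd=0.0), seed=7
        )
        forces = truth["stall_force"].to_numpy()
        steps = forces / 2.2
        assert np.allclose(steps, np.round(steps))

    def test_kinesin_forces_are_multiples_of_6pN(self):
        _, truth = generate_trace(
            TraceGenConfig(n_events=40, p_kinesin=1.0, force_jitter_sd=0.0), seed=7
        )
        assert set(np.round(truth["stall_force"], 6)) <= {6.0, 12.0}

    def test_perpendicular_channel_is_thermal(self):
        trace, _ = generate_trace(TraceGenConfig(n_events=10), seed=9)
        expected = math.hypot(TRAP.thermal_sd, TRAP.detector_noise_sd)
        assert np.std(trace.position_perpendicular) == pytest.approx(expected, rel=0.1)


class TestGenerateDataset:
    def test_empty_dataset(self, tmp_path):
        out = generate_dataset(0, TraceGenConfig(n_events=5), seed=1,
                               out_dir=tmp_path)
        assert out["manifest"]["traces"] == []
        assert (tmp_path / "manifest.json").exists()

    def test_files_round_trip_and_truth_rows(self, tmp_path):
        from tugtrap.io import read_trace

        out = generate_dataset(2, TraceGenConfig(n_events=6), seed=1,
                               out_dir=tmp_path)
        csvs = sorted(tmp_path.glob("synth-*.csv"))
        assert len(csvs) == 2
        back = read_trace(csvs[0])
        np.testing.assert_array_equal(
            back.position_parallel, out["traces"][0].position_parallel
        )
        assert len(out["truth"]) == sum(e["n_events"] for e in
                                        out["manifest"]["traces"])

    def test_same_seed_same_dataset(self):
        a = generate_dataset(3, TraceGenConfig(n_events=5), seed=2)
        b = generate_dataset(3, TraceGenConfig(n_events=5), seed=2)
        for ta, tb in zip(a["traces"], b["traces"]):
            np.testing.assert_array_equal(ta.position_parallel, tb.position_parallel)
        assert a["truth"].equals(b["truth"])
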