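"""Synthetic optical-trap trace generator with full ground truth.

A trapped 750-nm cargo with no motors engaged is an overdamped bead in a
harmonic well: an Ornstein-Uhlenbeck (OU) process with relaxation time
``tau = gamma / K_T`` and stationary SD ``sqrt(k_B T / K_T)``.  Motor events
are layered on top of this bath:

* a **stall** is a deterministic excursion following the linear
  force-velocity relation ``v(F) = v0 (1 - F / F_stall)`` (exponential
  approach to the plateau ``F_stall / K_T``), held so that the width of the
  event at half-maximal force equals the programmed stall duration;
* a **fly-back** returns the cargo to the trap center after detachment —
  either a free OU relaxation (complete within a few ms) or a
  phenomenological tug-of-war return whose time constant is set so the 2-SD
  band is first re-entered at the programmed resist time;
* **inactive periods** between events are pure OU segments at the center.

Event identities (K vs D) come from the coin-toss model; inactive gaps are
drawn short (< 0.5 s, a rapid reversal) with probability ``p_rr``, which
defaults to the binomial occupancy model's joint reversal probability.
Every event is recorded in a ground-truth table so detection can be scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .cointoss import simulate_sequence
from .io import TraceFile, derive_rng, write_trace
from .occupancy import (
    BOLTZMANN_PN_NM,
    OccupancyModel,
    joint_reversal_probability,
    kinesin_team_probabilities,
)

__all__ = [
    "TrapConfig",
    "TraceGenConfig",
    "thermal_segment",
    "stall_segment",
    "flyback_segment",
    "generate_trace",
    "generate_dataset",
    "truth_pairs",
]


@dataclass(frozen=True)
class TrapConfig:
    """Optical trap and detection parameters.

    stiffness pN/nm; sampling_rate Hz; temperature K; cargo_diameter nm;
    viscosity Pa s (default 3x water, a crude bulk value for assay buffer
    near a coverslip); detector_noise_sd nm of white read-out noise.
    ``drag_coefficient`` (pN s/nm) overrides Stokes' law when given.
    """

    stiffness: float = 0.02
    sampling_rate: float = 2000.0
    temperature: float = 295.0
    cargo_diameter: float = 750.0
    viscosity: float = 3.0e-3
    drag_coefficient: float | None = None
    detector_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.stiffness <= 0 or self.sampling_rate <= 0:
            raise ValueError("stiffness and sampling_rate must be positive")
        if self.temperature <= 0 or self.cargo_diameter <= 0:
            raise ValueError("temperature and cargo_diameter must be positive")
        if self.drag < 0 or self.detector_noise_sd < 0:
            raise ValueError("drag and detector noise must be non-negative")

    @property
    def drag(self) -> float:
        """Drag coefficient gamma in pN s/nm (Stokes: 6 pi eta R)."""
        if self.drag_coefficient is not None:
            return self.drag_coefficient
        radius_m = self.cargo_diameter * 1e-9 / 2.0
        gamma_si = 6.0 * math.pi * self.viscosity * radius_m  # N s/m
        return gamma_si * 1e3  # 1 N s/m = 1e3 pN s/nm

    @property
    def relaxation_time(self) -> float:
        """Trap relaxation time tau = gamma / K_T in seconds."""
        return self.drag / self.stiffness

    @property
    def thermal_sd(self) -> float:
        """Stationary thermal position SD sqrt(k_B T / K_T) in nm."""
        return math.sqrt(BOLTZMANN_PN_NM * self.temperature / self.stiffness)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def metadata(self, trace_id: str) -> dict:
        return {
            "trap_stiffness": self.stiffness,
            "sampling_rate": self.sampling_rate,
            "temperature": self.temperature,
            "cargo_diameter": self.cargo_diameter,
            "trace_id": trace_id,
        }


def _ou_noise(n: int, dt: float, tau: float, rng: np.random.Generator,
              z0: float = 0.0) -> tuple[np.ndarray, float]:
    """Unit-variance stationary OU samples via the exact discrete update.

    z[i] = a z[i-1] + sqrt(1-a^2) xi,  a = exp(-dt/tau).  Returns the path
    and its final value so noise stays continuous across segments.
    """
    if n <= 0:
        return np.empty(0), z0
    a = math.exp(-dt / tau)
    innov = rng.normal(0.0, math.sqrt(1.0 - a * a), n)
    z, _ = lfilter([1.0], [1.0, -a], innov, zi=[a * z0])
    return z, float(z[-1])


def thermal_segment(trap: TrapConfig, duration: float,
                    rng: np.random.Generator | int,
                    z0: float | None = None) -> np.ndarray:
    """Motor-free positions in the trap: exact OU plus detector noise.

    ``z0`` sets the initial normalized OU state (default: a stationary
    draw).  The sample SD converges to ``sqrt(thermal_sd^2 +
    detector_noise_sd^2)``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n = int(round(duration * trap.sampling_rate))
    if z0 is None:
        z0 = rng.normal()
    z, _ = _ou_noise(n, trap.dt, trap.relaxation_time, rng, z0)
    x = z * trap.thermal_sd
    if trap.detector_noise_sd > 0:
        x = x + rng.normal(0.0, trap.detector_noise_sd, n)
    return x


# factor by which motor engagement stiffens the cargo-trap linkage; thermal
# fluctuations during stalls and tug-of-war fly-backs shrink accordingly
MOTOR_NOISE_SCALE = 0.5

#: deterministic rise is truncated at this many force-velocity time constants
_RISE_SPAN = 3.5
# fraction of the plateau reached at truncation, and the half-max lead time
_RISE_LEVEL = 1.0 - math.exp(-_RISE_SPAN)
_HALF_RISE = math.log(2.0)


def stall_segment(
    trap: TrapConfig,
    direction: str,
    stall_force: float,
    unloaded_velocity: float,
    stall_duration: float,
    rng: np.random.Generator | int,
    noise_scale: float = 1.0,
) -> dict:
    """Deterministic stall excursion plus thermal noise.

    The cargo leaves the center following ``x(t) = X (1 - exp(-t/tau_r))``
    with plateau ``X = stall_force / K_T`` and ``tau_r = X / v0`` (the linear
    force-velocity relation), then holds the plateau so that the width of
    the event at half-maximal force equals ``stall_duration``.  Returns the
    positions, the time of first reaching the plateau and the detach time
    (segment end).
    """
    if stall_force <= 0 or unloaded_velocity <= 0:
        raise ValueError("stall_force and unloaded_velocity must be positive")
    sgn = {"plus": 1.0, "minus": -1.0}[direction]
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    plateau = stall_force / trap.stiffness
    tau_r = plateau / unloaded_velocity
    rise_time = _RISE_SPAN * tau_r
    # time above half-max contributed by the rise
    above_half_rise = rise_time - _HALF_RISE * tau_r
    hold = stall_duration - above_half_rise
    if hold <= 0:
        raise ValueError(
            f"stall_duration {stall_duration:.3f}s shorter than the rise of a "
            f"{stall_force:.2f} pN event ({above_half_rise:.3f}s above half-max)"
        )
    dt = trap.dt
    n_rise = max(int(round(rise_time / dt)), 1)
    n_hold = max(int(round(hold / dt)), 1)
    t_rise = np.arange(1, n_rise + 1) * dt
    path = np.concatenate(
        [plateau * (1.0 - np.exp(-t_rise / tau_r)), np.full(n_hold, plateau)]
    )
    n = path.size
    sd = trap.thermal_sd * MOTOR_NOISE_SCALE * noise_scale
    tau_n = trap.relaxation_time * MOTOR_NOISE_SCALE**2
    z, _ = _ou_noise(n, dt, tau_n, rng, 0.0)
    x = sgn * path + z * sd
    if trap.detector_noise_sd > 0 and noise_scale > 0:
        x = x + rng.normal(0.0, trap.detector_noise_sd, n)
    return {
        "positions": x,
        "peak_time": n_rise * dt,
        "detach_time": n * dt,
        "plateau": sgn * plateau,
    }


def flyback_segment(
    trap: TrapConfig,
    start_position: float,
    kind: str,
    rng: np.random.Generator | int,
    resist_time: float = 0.05,
    noise_scale: float = 1.0,
) -> dict:
    """Return of the cargo to the trap center after motor detachment.

    ``kind="free"``: OU relaxation with the trap time constant, complete
    within a few ms.  ``kind="tug_of_war"``: exponential return slowed by a
    transient opposing-motor force; its time constant is chosen so the 2-SD
    fluctuation band is first entered at ``resist_time`` (10-100 ms scale).
    Returns positions and the band-entry time.
    """
    if kind not in ("free", "tug_of_war"):
        raise ValueError(f"unknown fly-back kind {kind!r}")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    band = 2.0 * math.hypot(trap.thermal_sd, trap.detector_noise_sd)
    x0 = float(start_position)
    if abs(x0) <= band:
        return {"positions": np.empty(0), "band_entry_time": 0.0, "duration": 0.0}
    dt = trap.dt
    if kind == "free":
        tau = trap.relaxation_time
        sd = trap.thermal_sd * noise_scale
    else:
        tau = resist_time / math.log(abs(x0) / band)
        sd = trap.thermal_sd * MOTOR_NOISE_SCALE * noise_scale
    # run until the mean path is deep inside the band (~0.25 SD)
    floor = max(0.25 * trap.thermal_sd, 1.0)
    duration = tau * math.log(abs(x0) / floor)
    n = max(int(round(duration / dt)), 1)
    t = np.arange(1, n + 1) * dt
    path = x0 * np.exp(-t / tau)
    tau_n = trap.relaxation_time * (MOTOR_NOISE_SCALE**2 if kind == "tug_of_war" else 1.0)
    z, _ = _ou_noise(n, dt, tau_n, rng, 0.0)
    x = path + z * sd
    if trap.detector_noise_sd > 0 and noise_scale > 0:
        x = x + rng.normal(0.0, trap.detector_noise_sd, n)
    return {
        "positions": x,
        "band_entry_time": tau * math.log(abs(x0) / band),
        "duration": n * dt,
    }


@dataclass(frozen=True)
class TraceGenConfig:
    """Study conditions for a synthetic trace.

    Defaults emulate an untreated early phagosome: fair coin between motor
    classes, dynein recruited in pairs (force steps ~2.2 pN), 1-2 kinesins
    at 6 pN each, and rapid-reversal probability taken from the occupancy
    model (0.74 for Nd=240, Nk=40, p=0.04).
    """

    trap: TrapConfig = TrapConfig()
    occupancy: OccupancyModel = OccupancyModel()
    n_events: int = 40
    p_kinesin: float = 0.5
    p_rr: float | None = None  # None -> joint_reversal_probability(occupancy)
    p_tow_given_rr: float = 0.5
    tow_resist_range: tuple[float, float] = (0.02, 0.08)  # s
    rr_gap_mean: float = 0.15  # s, exponential, capped below rr_gap_cap
    rr_gap_cap: float = 0.4
    slow_gap_offset: float = 0.7  # s; non-RR gaps are offset + Exp(slow_gap_mean)
    slow_gap_mean: float = 1.0
    unloaded_velocity: float = 2000.0  # nm/s
    stall_duration_range: tuple[float, float] = (0.7, 1.4)  # s at half-max
    min_plateau_hold: float = 0.2  # s
    dynein_pair_recruitment: bool = True
    dynein_team_pairs: tuple[int, int] = (2, 5)  # engaged pairs (x 2.2 pN)
    dynein_single_range: tuple[int, int] = (1, 2)  # engaged singles (x 1.1 pN)
    force_jitter_sd: float = 0.25  # pN, realized force scatter around nominal
    premature_rate: float = 0.0
    initial_inactive: float = 1.2  # s of motor-free signal for calibration
    thermal_noise_scale: float = 1.0  # 0 -> noise-free pipeline checks


def _draw_event(cfg: TraceGenConfig, label: str, rng: np.random.Generator) -> dict:
    """Team size and realized stall force for one event."""
    occ = cfg.occupancy
    if label == "K":
        kt = kinesin_team_probabilities(occ.kinesin.total_count, occ.contact_fraction_p)
        p_single = kt["P_1K"] / (kt["P_1K"] + kt["P_gt1K"])
        n_motors = 1 if rng.random() < p_single else 2
        nominal = n_motors * occ.kinesin.single_motor_force
    else:
        single = occ.dynein.single_motor_force
        if cfg.dynein_pair_recruitment:
            pairs = rng.integers(cfg.dynein_team_pairs[0], cfg.dynein_team_pairs[1] + 1)
            n_motors = 2 * int(pairs)
        else:
            n_motors = int(
                rng.integers(cfg.dynein_single_range[0], cfg.dynein_single_range[1] + 1)
            )
        nominal = n_motors * single
    force = nominal
    if cfg.force_jitter_sd > 0:
        force = max(nominal + rng.normal(0.0, cfg.force_jitter_sd), 0.3 * nominal)
    return {"n_motors": n_motors, "force": float(force)}


def _stall_duration(cfg: TraceGenConfig, force: float, rng: np.random.Generator) -> float:
    """Half-max width draw, long enough to hold a clean plateau."""
    tau_r = force / cfg.trap.stiffness / cfg.unloaded_velocity
    floor = (_RISE_SPAN - _HALF_RISE) * tau_r + cfg.min_plateau_hold
    lo, hi = cfg.stall_duration_range
    return max(rng.uniform(lo, hi), floor)


def generate_trace(
    config: TraceGenConfig, seed: int, trace_index: int = 0
) -> tuple[TraceFile, pd.DataFrame]:
    """Synthesize one trace and its ground-truth event table.

    The event schedule is: initial inactive segment (for center
    calibration), then per event stall -> fly-back -> inactive gap.  Gaps
    are short (< 0.5 s) with probability ``p_rr``; reversal gaps drawn short
    may additionally be tug-of-war fly-backs with zero inactive time.
    Deterministic given ``(seed, trace_index)``.
    """
    trap = config.trap
    p_rr = config.p_rr
    if p_rr is None:
        p_rr = joint_reversal_probability(config.occupancy)
    rng = derive_rng(seed, trace_index)
    labels = simulate_sequence(config.n_events, config.p_kinesin, rng).labels

    ns = config.thermal_noise_scale
    segments: list[np.ndarray] = []
    records: list[dict] = []
    t_cursor = 0.0

    def _push(x: np.ndarray) -> None:
        nonlocal t_cursor
        segments.append(x)
        t_cursor += x.size * trap.dt

    def _inactive(duration: float) -> None:
        if duration <= trap.dt:
            return
        n = int(round(duration / trap.sampling_rate**-1))
        if n < 1:
            return
        if ns > 0:
            # start at the center so segment joins stay continuous
            _push(thermal_segment(trap, duration, rng, z0=0.0))
        else:
            _push(np.zeros(n))

    _inactive(config.initial_inactive)

    for i, label in enumerate(labels):
        # decide the gap *after* this event now, because a tug-of-war
        # fly-back is a property of the (event, next-event) reversal pair
        next_label = labels[i + 1] if i + 1 < config.n_events else None
        is_rr = rng.random() < p_rr
        is_reversal = next_label is not None and next_label != label
        tow = bool(is_reversal and is_rr and rng.random() < config.p_tow_given_rr)
        if next_label is None:
            gap = config.initial_inactive / 2.0
            is_rr = False
        elif tow:
            gap = 0.0
        elif is_rr:
            gap = min(rng.exponential(config.rr_gap_mean), config.rr_gap_cap)
        else:
            gap = config.slow_gap_offset + rng.exponential(config.slow_gap_mean)

        premature = (
            config.premature_rate > 0
            and next_label == label
            and rng.random() < config.premature_rate
        )
        if premature:
            # a low-force event detaching mid-rise: fails both stall criteria
            # and shows high velocity just prior to detachment
            pre = _premature_segment(config, label, rng)
            t0 = t_cursor
            _push(pre["positions"])
            fb = flyback_segment(trap, pre["positions_end"], "free", rng, noise_scale=ns)
            records.append(
                {
                    "event_index": -1,
                    "label": label,
                    "n_motors": 1,
                    "stall_force": pre["peak_force"],
                    "t_start": t0,
                    "t_detach": t_cursor,
                    "t_end": t_cursor + fb["band_entry_time"],
                    "t_stall": pre["t_stall"],
                    "flyback_kind": "free",
                    "flyback_time": fb["band_entry_time"],
                    "inactive_after": 0.05,
                    "is_rr_after": True,
                    "premature": True,
                }
            )
            _push(fb["positions"])
            _inactive(0.05)

        event = _draw_event(config, label, rng)
        duration = _stall_duration(config, event["force"], rng)
        t0 = t_cursor
        seg = stall_segment(
            trap,
            "plus" if label == "K" else "minus",
            event["force"],
            config.unloaded_velocity,
            duration,
            rng,
            noise_scale=ns,
        )
        _push(seg["positions"])
        t_detach = t_cursor
        kind = "tug_of_war" if tow else "free"
        resist = rng.uniform(*config.tow_resist_range)
        fb = flyback_segment(
            trap, seg["plateau"], kind, rng, resist_time=resist, noise_scale=ns
        )
        records.append(
            {
                "event_index": i,
                "label": label,
                "n_motors": event["n_motors"],
                "stall_force": event["force"],
                "t_start": t0,
                "t_detach": t_detach,
                "t_end": t_detach + fb["band_entry_time"],
                "t_stall": duration,
                "flyback_kind": kind,
                "flyback_time": fb["band_entry_time"],
                "inactive_after": gap if next_label is not None else np.nan,
                "is_rr_after": bool(is_rr) if next_label is not None else False,
                "premature": False,
            }
        )
        _push(fb["positions"])
        _inactive(gap)

    x = np.concatenate(segments)
    if ns > 0:
        y = thermal_segment(trap, x.size * trap.dt, rng)[: x.size]
    else:
        y = np.zeros(x.size)
    trace_id = f"synth-{seed}-{trace_index:04d}"
    trace = TraceFile(
        time=np.arange(x.size) * trap.dt,
        position_parallel=x,
        position_perpendicular=y,
        metadata=trap.metadata(trace_id),
    )
    truth = pd.DataFrame.from_records(records)
    truth.insert(0, "trace_id", trace_id)
    return trace, truth


def _premature_segment(cfg: TraceGenConfig, label: str, rng: np.random.Generator) -> dict:
    """Partial excursion that detaches mid-rise (premature motor detachment)."""
    trap = cfg.trap
    sgn = 1.0 if label == "K" else -1.0
    target = 5.0  # pN the motor was headed for
    plateau = target / trap.stiffness
    tau_r = plateau / cfg.unloaded_velocity
    # detach at ~half the target force, where velocity is still ~v0/2
    t_det = _HALF_RISE * tau_r
    n = max(int(round(t_det / trap.dt)), 2)
    t = np.arange(1, n + 1) * trap.dt
    path = sgn * plateau * (1.0 - np.exp(-t / tau_r))
    sd = trap.thermal_sd * MOTOR_NOISE_SCALE * cfg.thermal_noise_scale
    z, _ = _ou_noise(n, trap.dt, trap.relaxation_time * MOTOR_NOISE_SCALE**2, rng)
    x = path + z * sd
    if trap.detector_noise_sd > 0 and cfg.thermal_noise_scale > 0:
        x = x + rng.normal(0.0, trap.detector_noise_sd, n)
    peak = abs(path[-1]) * trap.stiffness
    return {
        "positions": x,
        "positions_end": path[-1],
        "peak_force": peak,
        "t_stall": t_det / 2.0,
    }


def truth_pairs(truth: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth consecutive event pairs (premature events merged away).

    Pair type is ``first.label + second.label``; the intervening inactive
    time is the first event's programmed gap, and ``is_rr`` marks gaps below
    0.5 s.  Pairs never span trace boundaries.
    """
    rows = []
    for trace_id, group in truth[~truth["premature"]].groupby("trace_id", sort=False):
        g = group.sort_values("t_start").reset_index(drop=True)
        for i in range(len(g) - 1):
            first, second = g.loc[i], g.loc[i + 1]
            rows.append(
                {
                    "trace_id": trace_id,
                    "pair_type": first["label"] + second["label"],
                    "inactive_duration": first["inactive_after"],
                    "is_rr": bool(first["is_rr_after"]),
                    "flyback_kind": first["flyback_kind"],
                    "flyback_time": first["flyback_time"],
                }
            )
    return pd.DataFrame.from_records(
        rows,
        columns=[
            "trace_id",
            "pair_type",
            "inactive_duration",
            "is_rr",
            "flyback_kind",
            "flyback_time",
        ],
    )


def generate_dataset(
    n_traces: int,
    config: TraceGenConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> dict:
    """Generate ``n_traces`` traces with per-trace seeds derived from *seed*.

    Returns ``{"traces": [...], "truth": DataFrame, "manifest": {...}}``;
    when ``out_dir`` is given, also writes one CSV per trace, the truth
    table and a JSON manifest.
    """
    if n_traces < 0:
        raise ValueError("n_traces must be non-negative")
    traces, truths, entries = [], [], []
    for i in range(n_traces):
        trace, truth = generate_trace(config, seed, trace_index=i)
        traces.append(trace)
        truths.append(truth)
        entries.append(
            {
                "trace_id": trace.metadata["trace_id"],
                "n_samples": int(trace.time.size),
                "n_events": int((~truth["premature"]).sum()),
            }
        )
    truth_all = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=["trace_id"])
    )
    manifest = {"seed": int(seed), "n_traces": n_traces, "traces": entries}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for trace in traces:
            write_trace(trace, out_dir / f"{trace.metadata['trace_id']}.csv")
        truth_all.to_csv(out_dir / "ground_truth.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"traces": traces, "truth": truth_all, "manifest": manifest}
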