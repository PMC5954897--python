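"""Stall detection and event-pair analysis of optical-trap traces.

The analysis mirrors how trap records of bidirectional cargo are scored by
hand: calibrate the thermal fluctuation band at the trap center, segment
excursions beyond 2 center-SDs (with hysteresis down to 1 SD to avoid
chatter), convert displacement to force via ``F = K_T x``, keep events whose
peak force and half-max width pass per-direction thresholds, merge premature
detachments into the stall they interrupt, then type consecutive stalls as
DD/DK/KD/KK pairs.  Reversal pairs (DK/KD) get an intervening inactive time
(rapid reversal if < 0.5 s) and a fly-back time, whose slow population marks
tug-of-war between the opposing teams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import median_filter

from .io import TraceFile

__all__ = [
    "CenterCalibration",
    "StallEvent",
    "EventPair",
    "StallThresholds",
    "CalibrationError",
    "calibrate_center",
    "segment_candidates",
    "detect_stalls",
    "flag_premature",
    "detect_inactive",
    "pair_events",
    "measure_flyback",
    "classify_tow",
    "inactive_histogram",
    "force_histogram",
    "fit_two_gaussians",
    "compare_groups",
    "recovery_report",
    "analyze_trace",
]

#: median-filter width (s) applied to the force trace before thresholding
SMOOTH_WINDOW = 0.005
#: rapid-reversal threshold on the intervening inactive time (s)
RR_THRESHOLD = 0.5


class CalibrationError(RuntimeError):
    """No qualifying motor-free segment found for center calibration."""


@dataclass
class CenterCalibration:
    """Trap-center statistics from a motor-free segment."""

    center_position: float  # nm
    center_sd: float  # nm, along the MT axis
    perpendicular_sd: float | None = None
    segment: tuple[float, float] | None = None  # (t0, t1) used

    @property
    def band(self) -> float:
        """Excursion threshold: 2 SD from the center fluctuations."""
        return 2.0 * self.center_sd


@dataclass
class StallEvent:
    """A detected force-generation episode."""

    trace_id: str
    direction: str  # "plus" (K) or "minus" (D)
    t_start: float
    t_end: float
    peak_force: float  # pN
    t_stall: float  # s, width at half-maximal force
    peak_time: float
    release_time: float  # last time within 90% of peak, ~motor detachment
    pre_detachment_velocity: float = float("nan")  # nm/s
    premature_flag: bool = False

    @property
    def label(self) -> str:
        return "K" if self.direction == "plus" else "D"


@dataclass
class EventPair:
    """Two consecutive stalls on one cargo."""

    first: StallEvent
    second: StallEvent
    pair_type: str  # DD / DK / KD / KK
    inactive_duration: float
    is_rr: bool
    flyback_time: float = float("nan")
    tow_class: str = "n/a"  # with_tow / no_tow / n/a

    @property
    def is_reversal(self) -> bool:
        return self.pair_type in ("DK", "KD")


@dataclass(frozen=True)
class StallThresholds:
    """Per-direction stall acceptance rules.

    Defaults follow the kinesin criterion (max force > 3 pN and half-max
    width > 0.5 s) in both directions; ``low_force()`` gives the relaxed
    minus-direction rule (0.7 pN / 0.3 s) used for dynein-depleted,
    CC1-treated-like data where single-dynein stalls of ~1.1 pN must count.
    """

    min_force_plus: float = 3.0
    min_duration_plus: float = 0.5
    min_force_minus: float = 3.0
    min_duration_minus: float = 0.5

    @classmethod
    def low_force(cls) -> "StallThresholds":
        return cls(min_force_minus=0.7, min_duration_minus=0.3)

    def passes(self, direction: str, peak_force: float, t_stall: float) -> bool:
        if direction == "plus":
            return peak_force > self.min_force_plus and t_stall > self.min_duration_plus
        return peak_force > self.min_force_minus and t_stall > self.min_duration_minus


def _smooth(x: np.ndarray, fs: float, window: float = SMOOTH_WINDOW) -> np.ndarray:
    k = max(int(round(window * fs)) | 1, 3)  # odd kernel
    return median_filter(x, size=k, mode="nearest")


def calibrate_center(
    trace: TraceFile,
    quiet_segment: tuple[float, float] | None = None,
    min_quiet: float = 0.5,
) -> CenterCalibration:
    """Center position and fluctuation SD from a motor-free stretch.

    If ``quiet_segment`` (t0, t1) is not supplied, the quiet stretch is
    located automatically.  Dwell levels (histogram modes of the smoothed
    position) are candidate baselines; because the detector is zeroed at
    the trap center, candidates are tried nearest-zero first — this keeps a
    long stall plateau from masquerading as the center when stalls dominate
    the record.  For each candidate the noise scale is bootstrapped from
    the lowest decile of distances and refined once, quiet samples are
    those within 5 scale units (gaps up to 10 ms bridged), and the first
    candidate with a run of at least ``min_quiet`` seconds wins.  Raises
    :class:`CalibrationError` when none qualifies.
    """
    fs = trace.sampling_rate
    x = trace.position_parallel
    if quiet_segment is not None:
        i0, i1 = (max(int(round(t * fs)), 0) for t in quiet_segment)
        if i1 - i0 < 2:
            raise CalibrationError("explicit quiet segment too short")
        sel = slice(i0, i1)
    else:
        f = _smooth(x, fs)
        sel = None
        for center_guess in _dwell_candidates(f):
            dev = np.abs(f - center_guess)
            # q10(|z|) = 0.1257 sigma for a Gaussian; assumes the cargo
            # spends >= 10% of the record at this level.  The initial guess
            # is inflated by excursion samples, so contract it by repeated
            # median refinement on the provisional quiet set — this peels
            # off stall levels lying only a few noise widths from center
            scale = float(np.quantile(dev, 0.10)) / 0.1257
            # cap by the sample-to-sample noise, which stalls and rises
            # barely perturb — keeps the refinement from diverging when
            # quiet time is scarce
            s_hf = float(np.std(np.diff(x))) / math.sqrt(2.0)
            if s_hf > 0:
                scale = min(scale, 2.0 * s_hf)
            if scale == 0:
                scale = max(float(np.std(x)), 1e-9)
            for _ in range(3):
                provisional = dev < 3.0 * scale
                if not provisional.any():
                    break
                scale = float(np.median(dev[provisional])) / 0.6745
            quiet = dev < 5.0 * scale
            # bridge isolated excursion samples up to 10 ms
            quiet = median_filter(quiet, size=max(int(round(0.01 * fs)) | 1, 3))
            run = _longest_run(quiet)
            if run is None:
                continue
            # guard against fly-back/rise tails leaking past the run edges
            guard = int(round(0.02 * fs))
            if run.stop - run.start > min_quiet * fs + 2 * guard:
                run = slice(run.start + guard, run.stop - guard)
            if run.stop - run.start >= min_quiet * fs:
                sel = run
                break
        if sel is None:
            raise CalibrationError(
                f"no motor-free segment of >= {min_quiet} s found"
            )
    y = trace.position_perpendicular
    seg = x[sel]
    center = float(np.median(seg))
    robust_sd = 1.4826 * float(np.median(np.abs(seg - center)))
    return CenterCalibration(
        center_position=center,
        center_sd=robust_sd if robust_sd > 0 else float(np.std(seg)),
        perpendicular_sd=float(np.std(y[sel])) if y is not None else None,
        segment=(sel.start / fs, sel.stop / fs),
    )


def _dwell_candidates(f: np.ndarray, max_candidates: int = 5) -> list[float]:
    """Histogram dwell levels, ordered by distance from the detector zero."""
    counts, edges = np.histogram(f, bins=200)
    width = edges[1] - edges[0]
    order = np.argsort(counts)[::-1]
    centers: list[float] = []
    for i in order:
        if counts[i] < 0.2 * counts[order[0]]:
            break
        c = 0.5 * (edges[i] + edges[i + 1])
        if all(abs(c - c2) > 10 * width for c2 in centers):
            centers.append(float(c))
        if len(centers) >= max_candidates:
            break
    return sorted(centers, key=abs)


def _longest_run(mask: np.ndarray) -> slice | None:
    if not mask.any():
        return None
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    best = np.argmax(stops - starts)
    return slice(int(starts[best]), int(stops[best]))


def segment_candidates(
    trace: TraceFile, calibration: CenterCalibration
) -> list[StallEvent]:
    """All excursions beyond the 2-SD band, measured but unfiltered.

    Hysteresis segmentation: an event is a contiguous run where the smoothed
    distance from center exceeds 1 SD, provided the run somewhere exceeds
    2 SD.  Peak force is the trap stiffness times the mean position over
    the 100 ms ending at motor release (the last sample within 90% of the
    smoothed extremum) — averaging the held plateau is unbiased where a raw
    maximum over many noisy samples is not; ``t_stall`` is the width at
    half-maximal smoothed force.
    """
    fs = trace.sampling_rate
    k_t = trace.trap_stiffness
    x = trace.position_parallel - calibration.center_position
    f = _smooth(x, fs)
    sd = calibration.center_sd
    mask1 = np.abs(f) >= sd
    events: list[StallEvent] = []
    run_start = None
    padded = np.concatenate(([False], mask1, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    trace_id = str(trace.metadata.get("trace_id", ""))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        seg = f[i0:i1]
        peak_idx = int(np.argmax(np.abs(seg)))
        if abs(seg[peak_idx]) < 2.0 * sd:
            continue
        sgn = math.copysign(1.0, seg[peak_idx])
        rel = sgn * seg  # positive toward the excursion
        peak_val = rel[peak_idx]
        half = np.flatnonzero(rel >= 0.5 * peak_val)
        t_stall = (half[-1] - half[0] + 1) / fs if half.size else 0.0
        above90 = np.flatnonzero(rel >= 0.9 * peak_val)
        rel_release = int(above90[-1]) if above90.size else peak_idx
        release = (i0 + rel_release) / fs
        # plateau level: mean raw position over the 100 ms before release
        w0 = max(rel_release - int(round(0.1 * fs)), 0)
        plateau_pos = float(np.mean(sgn * x[i0 + w0 : i0 + rel_release + 1]))
        peak_force = k_t * plateau_pos
        events.append(
            StallEvent(
                trace_id=trace_id,
                direction="plus" if sgn > 0 else "minus",
                t_start=i0 / fs,
                t_end=i1 / fs,
                peak_force=float(peak_force),
                t_stall=float(t_stall),
                peak_time=(i0 + peak_idx) / fs,
                release_time=float(release),
            )
        )
    return events


def detect_stalls(
    trace: TraceFile,
    calibration: CenterCalibration,
    thresholds: StallThresholds = StallThresholds(),
    merge_premature: bool = True,
) -> list[StallEvent]:
    """Detected stalls: candidates passing the per-direction criteria.

    With ``merge_premature`` (default), sub-threshold candidates that look
    like premature detachments are first merged into the following stall of
    the same direction (see :func:`flag_premature`).
    """
    candidates = segment_candidates(trace, calibration)
    if merge_premature:
        candidates = flag_premature(candidates, trace)
    return [
        ev
        for ev in candidates
        if not ev.premature_flag
        and thresholds.passes(ev.direction, ev.peak_force, ev.t_stall)
    ]


def flag_premature(
    candidates: list[StallEvent],
    trace: TraceFile,
    window: float = 0.2,
    speed_factor: float = 5.0,
    speed_floor: float = 150.0,
    merge_window: float = 2.0,
    thresholds: StallThresholds = StallThresholds(),
) -> list[StallEvent]:
    """Flag premature detachments among sub-threshold candidates.

    The cargo's velocity in the ``window`` seconds before detachment
    distinguishes a motor that let go mid-rise (still moving fast) from a
    genuine stall (parked at its plateau).  A sub-threshold candidate is
    flagged when its pre-detachment speed exceeds ``speed_factor`` times the
    median speed of the full stalls (or ``speed_floor`` nm/s if that median
    is noise-limited).  Flagged events merge into the next same-direction
    stall within ``merge_window`` s — the merged record keeps the stall's
    force but starts at the premature event, so the pair count treats them
    as one event.
    """
    fs = trace.sampling_rate
    x = trace.position_parallel
    n_win = max(int(round(window * fs)), 4)

    def _speed(ev: StallEvent) -> float:
        i1 = int(round(ev.release_time * fs))
        i0 = max(i1 - n_win, 0)
        if i1 - i0 < 4:
            return float("nan")
        t = np.arange(i0, i1) / fs
        slope = np.polyfit(t, x[i0:i1], 1)[0]
        return abs(float(slope))

    out = [replace(ev) for ev in candidates]
    for ev in out:
        ev.pre_detachment_velocity = _speed(ev)
    full = [
        ev for ev in out if thresholds.passes(ev.direction, ev.peak_force, ev.t_stall)
    ]
    sub = [ev for ev in out if ev not in full]
    med_speed = (
        float(np.nanmedian([ev.pre_detachment_velocity for ev in full]))
        if full
        else 0.0
    )
    cutoff = max(speed_factor * med_speed, speed_floor)
    for ev in sub:
        # a real premature detachment is a genuine excursion, not a noise
        # blip grazing the band
        if (
            ev.pre_detachment_velocity > cutoff
            and ev.peak_force >= 1.0
            and ev.t_stall >= 0.02
        ):
            ev.premature_flag = True
    # merge each premature event into the next same-direction full stall
    out_sorted = sorted(out, key=lambda e: e.t_start)
    for i, ev in enumerate(out_sorted):
        if not ev.premature_flag:
            continue
        for nxt in out_sorted[i + 1 :]:
            if nxt.premature_flag:
                continue
            if (
                nxt.direction == ev.direction
                and nxt.t_start - ev.t_end <= merge_window
                and thresholds.passes(nxt.direction, nxt.peak_force, nxt.t_stall)
            ):
                nxt.t_start = ev.t_start
                break
            break  # an intervening event of any kind stops the merge
    return out_sorted


def detect_inactive(
    trace: TraceFile,
    calibration: CenterCalibration,
    stalls: list[StallEvent],
    min_band_fraction: float = 0.9,
) -> list[dict]:
    """Inter-stall intervals where the cargo sits at the trap center.

    Each interval between consecutive stalls qualifies when the smoothed
    position stays within the 2-SD band for at least ``min_band_fraction``
    of its samples (tolerating isolated excursions).  The interval carries
    its own raw SD for the fluctuation comparison against the free trap.
    """
    fs = trace.sampling_rate
    x = trace.position_parallel - calibration.center_position
    f = _smooth(x, fs)
    out = []
    ordered = sorted(stalls, key=lambda e: e.t_start)
    for first, second in zip(ordered, ordered[1:]):
        i0 = int(round(first.t_end * fs))
        i1 = int(round(second.t_start * fs))
        if i1 <= i0:
            continue
        inside = np.abs(f[i0:i1]) < calibration.band
        if inside.mean() < min_band_fraction:
            continue
        out.append(
            {
                "t_start": i0 / fs,
                "t_end": i1 / fs,
                "duration": (i1 - i0) / fs,
                "position_sd": float(np.std(x[i0:i1])),
                "after_event": first,
                "before_event": second,
            }
        )
    return out


def pair_events(
    stalls: list[StallEvent],
    inactive_intervals: list[dict] | None = None,
    rr_threshold: float = RR_THRESHOLD,
) -> list[EventPair]:
    """Type consecutive stalls as DD/DK/KD/KK pairs.

    The intervening inactive time is the detected center-dwell between the
    two stalls, or the raw gap between the events when no qualifying
    interval exists (0 when the stalls abut — such pairs are rapid
    reversals by definition).
    """
    ordered = sorted(stalls, key=lambda e: e.t_start)
    gap_of = {}
    for iv in inactive_intervals or []:
        gap_of[id(iv["after_event"])] = iv["duration"]
    pairs = []
    for first, second in zip(ordered, ordered[1:]):
        gap = gap_of.get(id(first), max(second.t_start - first.t_end, 0.0))
        pairs.append(
            EventPair(
                first=first,
                second=second,
                pair_type=first.label + second.label,
                inactive_duration=float(gap),
                is_rr=gap < rr_threshold,
            )
        )
    return pairs


def measure_flyback(
    trace: TraceFile, calibration: CenterCalibration, pair: EventPair
) -> float:
    """Fly-back time of a reversal pair, in seconds.

    Measured from the first event's motor release (last sample within 90%
    of peak) to the first re-entry of the smoothed position into the 2-SD
    center band.  Returns NaN when the trace ends before re-entry.
    """
    if not pair.is_reversal:
        raise ValueError("fly-back is defined for reversal (DK/KD) pairs")
    fs = trace.sampling_rate
    x = trace.position_parallel - calibration.center_position
    f = _smooth(x, fs)
    i0 = int(round(pair.first.release_time * fs))
    i_stop = int(round(pair.second.t_start * fs))
    if i0 >= f.size:
        return float("nan")
    inside = np.flatnonzero(np.abs(f[i0:i_stop]) < calibration.band)
    if inside.size == 0:
        return float("nan")
    return float(inside[0] / fs)


def classify_tow(
    flyback_times: np.ndarray | list[float],
    method: str = "threshold",
    cutoff: float = 0.005,
) -> dict:
    """Split reversal fly-backs into fast (no tug-of-war) and slow (tug-of-war).

    ``threshold``: slower than ``cutoff`` (default 5 ms, the upper bound of
    free fly-backs) means opposing motors resisted the return.  ``cluster``:
    1-D two-class split of log-times maximizing between-class variance
    (Otsu), for when no threshold is assumed; falls back to the threshold
    rule below 4 values.
    """
    times = np.asarray(flyback_times, dtype=float)
    times = times[np.isfinite(times)]
    if times.size == 0:
        return {"classes": [], "with_tow_fraction": float("nan"), "cutoff": cutoff,
                "method": method}
    used = method
    if method == "cluster":
        if times.size < 4:
            used = "threshold"
        else:
            cutoff = _otsu_split(np.log(np.maximum(times, 1e-6)))
            cutoff = float(np.exp(cutoff))
    elif method != "threshold":
        raise ValueError(f"unknown method {method!r}")
    classes = ["with_tow" if t > cutoff else "no_tow" for t in times]
    frac = sum(c == "with_tow" for c in classes) / len(classes)
    return {
        "classes": classes,
        "with_tow_fraction": float(frac),
        "cutoff": float(cutoff),
        "method": used,
    }


def _otsu_split(values: np.ndarray) -> float:
    order = np.sort(values)
    best_t, best_score = order[0], -np.inf
    for i in range(1, order.size):
        lo, hi = order[:i], order[i:]
        score = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if score > best_score:
            best_score, best_t = score, (order[i - 1] + order[i]) / 2.0
    return float(best_t)


def inactive_histogram(
    pairs: list[EventPair], bin_width: float = 0.5
) -> dict[str, dict]:
    """Inactive-time histogram per reversal type (DK and KD separately).

    The first bin (< 0.5 s by default) collects the rapid reversals; its
    fraction is the empirical analogue of the occupancy model's joint
    probability.
    """
    out: dict[str, dict] = {}
    for ptype in ("DK", "KD"):
        gaps = np.array(
            [p.inactive_duration for p in pairs if p.pair_type == ptype], dtype=float
        )
        if gaps.size == 0:
            out[ptype] = {"edges": np.array([]), "counts": np.array([]),
                          "first_bin_fraction": float("nan"), "n": 0}
            continue
        top = max(bin_width, float(gaps.max()))
        edges = np.arange(0.0, top + bin_width, bin_width)
        counts, edges = np.histogram(gaps, bins=edges)
        out[ptype] = {
            "edges": edges,
            "counts": counts,
            "first_bin_fraction": float((gaps < bin_width).mean()),
            "n": int(gaps.size),
        }
    return out


def force_histogram(
    forces: np.ndarray | list[float],
    bin_width: float = 0.5,
    normalize: bool = False,
) -> dict:
    """Stall-force histogram with fixed-width bins (default 0.5 pN).

    ``normalize`` scales counts to the maximum bin (the display convention
    for comparing categories of different size).  Also reports histogram
    modes by simple peak-picking for unitary-force periodicity checks.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0:
        return {"edges": np.array([]), "counts": np.array([]), "modes": []}
    if np.any(forces <= 0):
        raise ValueError("stall forces must be positive")
    top = math.ceil(forces.max() / bin_width) * bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(forces, bins=edges)
    values = counts / counts.max() if normalize else counts.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    modes = [
        float(centers[i])
        for i in range(len(counts))
        if counts[i] > 0
        and (i == 0 or counts[i] >= counts[i - 1])
        and (i == len(counts) - 1 or counts[i] > counts[i + 1])
    ]
    return {"edges": edges, "counts": values, "modes": modes}


def fit_two_gaussians(
    forces: np.ndarray | list[float],
    method: str = "mixture",
    rng_seed: int = 0,
) -> dict:
    """Two-component Gaussian fit of a stall-force sample.

    ``mixture`` fits a 2-component Gaussian mixture by maximum likelihood
    (EM); ``histogram`` least-squares fits a sum of two Gaussians to the
    0.5-pN binned histogram.  The weight of the low-mean component is the
    single-motor fraction (e.g. single- vs multi-kinesin events).  A
    degenerate fit (components collapsed onto each other) is flagged.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size < 20:
        raise ValueError("need at least 20 values for a two-component fit")
    if method == "mixture":
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(
            n_components=2, n_init=5, random_state=rng_seed, reg_covar=1e-4
        ).fit(forces.reshape(-1, 1))
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_.ravel()
    elif method == "histogram":
        hist = force_histogram(forces)
        centers = (hist["edges"][:-1] + hist["edges"][1:]) / 2.0
        counts = np.asarray(hist["counts"], dtype=float)

        def model(c, w1, m1, s1, w2, m2, s2):
            return w1 * np.exp(-0.5 * ((c - m1) / s1) ** 2) + w2 * np.exp(
                -0.5 * ((c - m2) / s2) ** 2
            )

        q1, q3 = np.quantile(forces, [0.25, 0.75])
        p0 = [counts.max(), q1, 1.0, counts.max(), q3, 1.0]
        try:
            popt, _ = optimize.curve_fit(model, centers, counts, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise RuntimeError(
                f"two-Gaussian histogram fit did not converge: {exc}"
            ) from exc
        amp = np.array([popt[0] * abs(popt[2]), popt[3] * abs(popt[5])])
        means = np.array([popt[1], popt[4]])
        sds = np.abs(np.array([popt[2], popt[5]]))
        weights = amp / amp.sum()
    else:
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    # components overlapping heavily (or one vanishing) mean the sample does
    # not support two populations
    sep = abs(means[1] - means[0])
    degenerate = sep < 1.5 * (sds[0] + sds[1]) or weights.min() < 0.02
    return {
        "means": means,
        "sds": sds,
        "weights": weights,
        "low_force_weight": float(weights[0]),
        "degenerate": bool(degenerate),
        "method": method,
    }


def compare_groups(values_a, values_b) -> dict:
    """Unpaired two-tailed Student's t test between two samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate and np.isclose(a.mean(), b.mean()):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_ind(a, b)
    return {
        "t_statistic": float(stat),
        "p_value": float(p),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sem_a": float(a.std(ddof=1) / math.sqrt(a.size)),
        "sem_b": float(b.std(ddof=1) / math.sqrt(b.size)),
        "degenerate_variance": bool(degenerate),
    }


# ---------------------------------------------------------------------------
# end-to-end helpers


def analyze_trace(
    trace: TraceFile,
    thresholds: StallThresholds = StallThresholds(),
    calibration: CenterCalibration | None = None,
) -> dict:
    """Full single-trace pipeline: calibrate, detect, pair, measure fly-backs."""
    cal = calibration or calibrate_center(trace)
    stalls = detect_stalls(trace, cal, thresholds)
    inactive = detect_inactive(trace, cal, stalls)
    pairs = pair_events(stalls, inactive)
    for pair in pairs:
        if pair.is_reversal:
            pair.flyback_time = measure_flyback(trace, cal, pair)
    return {"calibration": cal, "stalls": stalls, "inactive": inactive, "pairs": pairs}


def recovery_report(
    detected_stalls: list[StallEvent],
    detected_pairs: list[EventPair],
    truth_events: pd.DataFrame,
    truth_pair_table: pd.DataFrame | None = None,
) -> dict:
    """Score detection against the generator's ground truth.

    Events match when a detected stall overlaps a truth event (same trace)
    for more than 50% of the truth interval.  Reports event precision and
    recall, per-event force errors, the 4x4 pair-type confusion table and
    rapid-reversal agreement.
    """
    truth = truth_events[~truth_events["premature"]].reset_index(drop=True)
    matches: dict[int, StallEvent] = {}
    used = set()
    by_trace: dict[str, list[StallEvent]] = {}
    for ev in detected_stalls:
        by_trace.setdefault(ev.trace_id, []).append(ev)
    for idx, row in truth.iterrows():
        best, best_ov = None, 0.0
        for ev in by_trace.get(row["trace_id"], []):
            if id(ev) in used:
                continue
            ov = min(ev.t_end, row["t_end"]) - max(ev.t_start, row["t_start"])
            if ov > best_ov:
                best, best_ov = ev, ov
        span = row["t_end"] - row["t_start"]
        if best is not None and best_ov > 0.5 * span:
            matches[idx] = best
            used.add(id(best))
    n_truth, n_det = len(truth), len(detected_stalls)
    recall = len(matches) / n_truth if n_truth else float("nan")
    precision = len(matches) / n_det if n_det else float("nan")
    force_err = np.array(
        [
            abs(matches[i].peak_force - truth.loc[i, "stall_force"])
            / truth.loc[i, "stall_force"]
            for i in matches
        ]
    )
    # pair-type confusion via matched events
    labels = ("DD", "DK", "KD", "KK")
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    rr_agree = 0
    rr_total = 0
    det_pair_by_first = {id(p.first): p for p in detected_pairs}
    for trace_id, group in truth.groupby("trace_id", sort=False):
        g = group.sort_values("t_start")
        idxs = list(g.index)
        for a, b in zip(idxs, idxs[1:]):
            true_type = truth.loc[a, "label"] + truth.loc[b, "label"]
            ev_a, ev_b = matches.get(a), matches.get(b)
            if ev_a is None or ev_b is None:
                continue
            pair = det_pair_by_first.get(id(ev_a))
            if pair is None or pair.second is not ev_b:
                continue
            confusion.loc[true_type, pair.pair_type] += 1
            rr_total += 1
            if pair.is_rr == bool(truth.loc[a, "is_rr_after"]):
                rr_agree += 1
    total_pairs = int(confusion.values.sum())
    diag = float(np.trace(confusion.values) / total_pairs) if total_pairs else float("nan")
    return {
        "event_recall": float(recall),
        "event_precision": float(precision),
        "n_truth_events": int(n_truth),
        "n_detected_events": int(n_det),
        "force_relative_error_median": float(np.median(force_err)) if force_err.size else float("nan"),
        "force_relative_error_p95": float(np.quantile(force_err, 0.95)) if force_err.size else float("nan"),
        "pair_confusion": confusion,
        "pair_diagonal_fraction": diag,
        "rr_agreement": float(rr_agree / rr_total) if rr_total else float("nan"),
    }
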