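"""Motor-microtubule binding kinetics.

Each motor in the contact zone attaches to the microtubule at rate ``k_on``
and detaches at ``k_off``, independently of the others.  The mean bound
fraction C(t), starting from none bound, obeys

    dC/dt = k_on (1 - C) - k_off C
    C(t)  = C_eq (1 - exp(-(k_on + k_off) t)),   C_eq = k_on / (k_on + k_off)

with characteristic time 1/(k_on + k_off).  The number bound is a
birth-death chain on {0..n} with birth rate (n-k) k_on and death rate
k k_off; the time for a team of m motors to first assemble is the hitting
time of state m from 0, computed here both by exact recursion and by
event-driven (Gillespie) Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticsResult",
    "FirstPassageResult",
    "equilibrium_occupancy",
    "mean_occupancy",
    "characteristic_time",
    "expected_bound",
    "simulate_binding",
    "first_passage_mc",
    "first_passage_analytic",
]


@dataclass
class KineticsResult:
    """Mean-field occupancy summary for one motor species."""

    c_eq: float
    characteristic_time: float
    occupancy_times: np.ndarray
    occupancy_curve: np.ndarray
    mean_bound_at: float  # n_contact * C(t_query)


@dataclass
class FirstPassageResult:
    """Monte-Carlo first-passage summary (time for m of n motors to bind)."""

    mean: float
    sem: float
    replicates: int
    threshold: int
    quantiles: dict[str, float]


def equilibrium_occupancy(k_on: float, k_off: float) -> float:
    """Equilibrium bound fraction C_eq = k_on / (k_on + k_off)."""
    _check_rates(k_on, k_off)
    return k_on / (k_on + k_off)


def characteristic_time(k_on: float, k_off: float) -> float:
    """Relaxation time 1/(k_on + k_off): C reaches 63% of C_eq here."""
    _check_rates(k_on, k_off)
    return 1.0 / (k_on + k_off)


def mean_occupancy(t, k_on: float, k_off: float):
    """Mean bound fraction C(t) from the zero-bound initial condition."""
    _check_rates(k_on, k_off)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    c = equilibrium_occupancy(k_on, k_off) * (1.0 - np.exp(-(k_on + k_off) * t))
    return float(c) if c.ndim == 0 else c


def expected_bound(n_contact: float, k_on: float, k_off: float, t: float) -> float:
    """Mean number of bound motors at time t out of n_contact in the zone."""
    if n_contact < 0:
        raise ValueError("n_contact must be non-negative")
    return n_contact * mean_occupancy(t, k_on, k_off)


def summarize(n_contact: float, k_on: float, k_off: float,
              t_query: float | None = None, n_points: int = 200) -> KineticsResult:
    """Occupancy curve and headline numbers for one species.

    ``t_query`` defaults to the characteristic time, where C = 0.63 C_eq.
    """
    tau = characteristic_time(k_on, k_off)
    t_query = tau if t_query is None else t_query
    times = np.linspace(0.0, 6.0 * tau, n_points)
    return KineticsResult(
        c_eq=equilibrium_occupancy(k_on, k_off),
        characteristic_time=tau,
        occupancy_times=times,
        occupancy_curve=mean_occupancy(times, k_on, k_off),
        mean_bound_at=expected_bound(n_contact, k_on, k_off, t_query),
    )


# ---------------------------------------------------------------------------
# stochastic layer


def simulate_binding(
    n: int,
    k_on: float,
    k_off: float,
    t_max: float,
    rng: np.random.Generator | int,
    start_bound: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact event-driven trajectory of the number of bound motors.

    Returns ``(times, states)`` where ``times[0] = 0`` with ``states[0] =
    start_bound`` and subsequent entries record every attachment/detachment
    up to ``t_max``.  Gillespie sampling: in state k the total rate is
    ``(n-k) k_on + k k_off`` and the next event is a birth with probability
    proportional to its rate.
    """
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not 0 <= start_bound <= n:
        raise ValueError("start_bound outside [0, n]")
    _check_rates(k_on, k_off, allow_both_zero=True)
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng

    times = [0.0]
    states = [int(start_bound)]
    t, k = 0.0, int(start_bound)
    while True:
        birth = (n - k) * k_on
        death = k * k_off
        total = birth + death
        if total == 0.0:  # absorbing (k_on=0 at k=0, or k_off=0 at k=n)
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        k += 1 if rng.random() < birth / total else -1
        times.append(t)
        states.append(k)
    return np.asarray(times), np.asarray(states)


def first_passage_mc(
    n: int,
    k_on: float,
    k_off: float,
    m: int,
    replicates: int,
    rng: np.random.Generator | int,
) -> FirstPassageResult:
    """Monte-Carlo mean first-passage time from 0 bound to m bound.

    Each replicate runs the birth-death chain from the empty state until it
    first reaches ``m`` (e.g. the assembly of a 6-dynein team out of the ~10
    dyneins in the contact zone).
    """
    _check_passage_args(n, m)
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if m == 0:
        return FirstPassageResult(0.0, 0.0, replicates, 0, {})
    if k_on <= 0:
        raise ValueError("k_on must be positive to ever reach m >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng

    samples = np.empty(replicates)
    for i in range(replicates):
        t, k = 0.0, 0
        while k < m:
            birth = (n - k) * k_on
            death = k * k_off
            total = birth + death
            t += rng.exponential(1.0 / total)
            k += 1 if rng.random() < birth / total else -1
        samples[i] = t
    q = np.quantile(samples, [0.25, 0.5, 0.75])
    return FirstPassageResult(
        mean=float(samples.mean()),
        sem=float(samples.std(ddof=1) / math.sqrt(replicates)),
        replicates=replicates,
        threshold=m,
        quantiles={"q25": float(q[0]), "median": float(q[1]), "q75": float(q[2])},
    )


def first_passage_analytic(n: int, k_on: float, k_off: float, m: int) -> float:
    """Exact mean hitting time of state m from 0 for the birth-death chain.

    Standard recursion over the expected step-up times t_k (state k -> k+1):

        t_0 = 1/lambda_0,   t_k = 1/lambda_k + (mu_k / lambda_k) t_{k-1}

    with lambda_k = (n-k) k_on and mu_k = k k_off; the answer is the sum of
    t_0..t_{m-1}.  Serves as the exact oracle for :func:`first_passage_mc`.
    """
    _check_passage_args(n, m)
    if m == 0:
        return 0.0
    total = 0.0
    t_k = 0.0
    for k in range(m):
        lam = (n - k) * k_on
        mu = k * k_off
        if lam <= 0:
            raise ValueError(f"state {m} unreachable: zero birth rate at k={k}")
        t_k = 1.0 / lam + (mu / lam) * t_k if k else 1.0 / lam
        total += t_k
    return total


def _check_rates(k_on: float, k_off: float, allow_both_zero: bool = False) -> None:
    if k_on < 0 or k_off < 0:
        raise ValueError("rates must be non-negative")
    if not allow_both_zero and k_on + k_off == 0:
        raise ValueError("k_on and k_off cannot both be zero")


def _check_passage_args(n: int, m: int) -> None:
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    if m < 0 or m > n:
        raise ValueError(f"threshold m={m} outside [0, n={n}]")
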