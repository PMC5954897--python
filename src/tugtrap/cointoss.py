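"""Coin-toss model of motor-class activation and event-pair statistics.

Successive force-generation events on one cargo are labeled by the motor
class that drove them: K (kinesin, plus-end) or D (dynein, minus-end).  If
classes are activated independently with P(K) = q, consecutive overlapping
pairs occur with frequencies {KK: q^2, KD: q(1-q), DK: (1-q)q, DD: (1-q)^2};
a fair coin (q = 0.5) puts every pair type at 25%.  This module simulates
such sequences, tabulates observed pair fractions, and tests uniformity and
lag-1 independence (the "no memory" Markov property).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency, chisquare

__all__ = [
    "EventSequence",
    "PairStats",
    "PAIR_TYPES",
    "simulate_sequence",
    "pair_fractions",
    "direction_fraction",
    "uniformity_test",
    "lag1_independence",
]

PAIR_TYPES = ("DD", "DK", "KD", "KK")
_ALPHABET = frozenset("KD")


@dataclass
class EventSequence:
    """Ordered stall labels, optionally grouped by source trace."""

    labels: list[str]
    trace_ids: list | None = None  # parallel to labels; None = single trace

    def __post_init__(self) -> None:
        bad = set(self.labels) - _ALPHABET
        if bad:
            raise ValueError(f"labels outside alphabet {{K, D}}: {sorted(bad)}")
        if self.trace_ids is not None and len(self.trace_ids) != len(self.labels):
            raise ValueError("trace_ids must parallel labels")

    def __len__(self) -> int:
        return len(self.labels)

    def per_trace(self) -> list[list[str]]:
        """Labels split by trace; pairs never span a trace boundary."""
        if self.trace_ids is None:
            return [self.labels] if self.labels else []
        groups: dict = {}
        for lab, tid in zip(self.labels, self.trace_ids):
            groups.setdefault(tid, []).append(lab)
        return list(groups.values())


@dataclass
class PairStats:
    """Counts and fractions of the four consecutive-pair types."""

    counts: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in PAIR_TYPES}
    )

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        n = self.total_pairs
        return {t: (c / n if n else 0.0) for t, c in self.counts.items()}


def simulate_sequence(
    n: int, p_kinesin: float, rng: np.random.Generator | int
) -> EventSequence:
    """Draw n i.i.d. stall labels with P(K) = p_kinesin.

    ``p_kinesin = 0.5`` is the fair coin; unequal values model regulatory
    bias toward one motor class.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= p_kinesin <= 1.0:
        raise ValueError("p_kinesin must lie in [0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    draws = rng.random(n) < p_kinesin
    return EventSequence(labels=["K" if d else "D" for d in draws])


def pair_fractions(sequence: EventSequence) -> PairStats:
    """Count all consecutive overlapping pairs within each trace.

    A trace of s stalls contributes s - 1 pairs (reversal chains like
    KD -> DK -> KD share events between pairs); traces shorter than 2 stalls
    contribute none, and pairs never straddle trace boundaries.  An empty
    sequence yields zero pairs, not an error.
    """
    stats = PairStats()
    for labels in sequence.per_trace():
        for first, second in zip(labels, labels[1:]):
            stats.counts[first + second] += 1
    return stats


def direction_fraction(sequence: EventSequence) -> dict[str, float]:
    """Fraction of K- vs D-driven stalls over the whole sequence."""
    if len(sequence) == 0:
        raise ValueError("need at least one label")
    n_k = sum(1 for lab in sequence.labels if lab == "K")
    frac_k = n_k / len(sequence)
    return {"fraction_K": frac_k, "fraction_D": 1.0 - frac_k}


def uniformity_test(pair_counts: dict[str, int]) -> dict[str, float]:
    """Chi-square goodness of fit of pair counts against uniform 25% (df=3)."""
    observed = np.array([pair_counts.get(t, 0) for t in PAIR_TYPES], dtype=float)
    if np.any(observed < 0):
        raise ValueError("counts must be non-negative")
    total = observed.sum()
    if total == 0:
        raise ValueError("cannot test an empty pair table")
    stat, p = chisquare(observed, f_exp=np.full(4, total / 4.0))
    return {"statistic": float(stat), "p_value": float(p)}


def lag1_independence(sequence: EventSequence) -> dict[str, float | None]:
    """2x2 contingency test of each label against its predecessor.

    Under the coin-toss (memoryless) model the current motor class is
    independent of the previous one.  Returns ``{"statistic": None,
    "p_value": None, "reason": ...}`` when the table is degenerate (fewer
    than 2 pairs, or a label never occurs), since the test is undefined
    there.
    """
    table = np.zeros((2, 2))
    idx = {"K": 0, "D": 1}
    n_pairs = 0
    for labels in sequence.per_trace():
        for first, second in zip(labels, labels[1:]):
            table[idx[first], idx[second]] += 1
            n_pairs += 1
    if n_pairs < 2:
        return {"statistic": None, "p_value": None, "reason": "insufficient data"}
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return {"statistic": None, "p_value": None, "reason": "degenerate margins"}
    stat, p, _, _ = chi2_contingency(table, correction=True)
    return {"statistic": float(stat), "p_value": float(p), "reason": None}
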