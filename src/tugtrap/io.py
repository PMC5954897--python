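"""Trace file I/O, run configuration and seed management.

Traces are stored as plain CSV (columns ``time_s,x_nm,y_nm``) with a commented
header block carrying the trap metadata, so fixtures stay inspectable and
diff-able.  Units are fixed package-wide: nm, pN, s, K; displacement toward the
microtubule plus end is positive, so force bookkeeping is simply
``F = trap_stiffness * x``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "TraceFile",
    "RunConfig",
    "TraceFormatError",
    "TraceValidationError",
    "read_trace",
    "write_trace",
    "derive_rng",
    "derive_seed",
]

#: metadata keys every trace must declare
REQUIRED_METADATA = (
    "trap_stiffness",
    "sampling_rate",
    "temperature",
    "cargo_diameter",
    "trace_id",
)

_NUMERIC_METADATA = ("trap_stiffness", "sampling_rate", "temperature", "cargo_diameter")


class TraceFormatError(ValueError):
    """Malformed trace file (missing metadata key, bad columns, ...)."""


class TraceValidationError(ValueError):
    """Structurally valid file whose contents violate a trace invariant."""


@dataclass
class TraceFile:
    """A position-time record of a trapped cargo.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, on a uniform grid of step
        ``1 / metadata['sampling_rate']``.
    position_parallel : array of float
        Bead position along the microtubule axis in nm (plus-end positive).
    position_perpendicular : array of float or None
        Optional perpendicular channel in nm; ``None`` marks an absent channel
        (never substituted with zeros).
    metadata : dict
        Must contain ``trap_stiffness`` (pN/nm), ``sampling_rate`` (Hz),
        ``temperature`` (K), ``cargo_diameter`` (nm) and ``trace_id``.
    """

    time: np.ndarray
    position_parallel: np.ndarray
    position_perpendicular: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position_parallel = np.asarray(self.position_parallel, dtype=float)
        if self.position_perpendicular is not None:
            self.position_perpendicular = np.asarray(
                self.position_perpendicular, dtype=float
            )
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def sampling_rate(self) -> float:
        return float(self.metadata["sampling_rate"])

    @property
    def trap_stiffness(self) -> float:
        return float(self.metadata["trap_stiffness"])

    @property
    def duration(self) -> float:
        """Trace span in seconds, counting one full sample period per sample."""
        return self.time.size / self.sampling_rate

    def force(self) -> np.ndarray:
        """Instantaneous trap force in pN: ``trap_stiffness * x``."""
        return self.trap_stiffness * self.position_parallel

    def validate(self) -> None:
        missing = [k for k in REQUIRED_METADATA if k not in self.metadata]
        if missing:
            raise TraceFormatError(f"trace metadata missing required key(s): {missing}")
        if self.sampling_rate <= 0:
            raise TraceValidationError("sampling_rate must be > 0")
        if self.trap_stiffness <= 0:
            raise TraceValidationError("trap_stiffness must be > 0")
        n = self.time.size
        if n < 2:
            raise TraceValidationError(
                "a trace needs at least 2 samples to establish a time grid"
            )
        if self.position_parallel.size != n:
            raise TraceValidationError("time and position arrays differ in length")
        if self.position_perpendicular is not None and (
            self.position_perpendicular.size != n
        ):
            raise TraceValidationError("perpendicular channel length mismatch")
        dt = np.diff(self.time)
        step = 1.0 / self.sampling_rate
        if np.any(dt <= 0):
            raise TraceValidationError("time must be strictly increasing")
        if not np.allclose(dt, step, rtol=1e-6, atol=1e-9 * step):
            raise TraceValidationError(
                "time grid is not uniform at 1/sampling_rate spacing"
            )


def write_trace(trace: TraceFile, path: str | Path) -> Path:
    """Write *trace* as commented-header CSV; returns the path written.

    Values are written with 17 significant digits so a read-back reproduces
    the stored doubles exactly.
    """
    trace.validate()
    path = Path(path)
    buf = _io.StringIO()
    for key, value in sorted(trace.metadata.items()):
        buf.write(f"# {key}: {value}\n")
    has_y = trace.position_perpendicular is not None
    buf.write("time_s,x_nm,y_nm\n" if has_y else "time_s,x_nm\n")
    cols = [trace.time, trace.position_parallel]
    if has_y:
        cols.append(trace.position_perpendicular)
    for row in zip(*cols):
        buf.write(",".join(format(v, ".17g") for v in row) + "\n")
    path.write_text(buf.getvalue())
    return path


def read_trace(path: str | Path) -> TraceFile:
    """Read a trace CSV written by :func:`write_trace`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    metadata: dict[str, Any] = {}
    header: list[str] = []
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" not in line:
                    raise TraceFormatError(f"malformed metadata line: {line!r}")
                key, _, value = line.lstrip("# ").partition(":")
                metadata[key.strip()] = value.strip()
            elif not header:
                header = [c.strip() for c in line.split(",")]
            else:
                data_lines.append(line)
    missing = [k for k in REQUIRED_METADATA if k not in metadata]
    if missing:
        raise TraceFormatError(f"trace header missing required key(s): {missing}")
    for key in _NUMERIC_METADATA:
        try:
            metadata[key] = float(metadata[key])
        except ValueError as exc:
            raise TraceFormatError(f"metadata key {key!r} is not numeric") from exc
    if not data_lines:
        raise TraceFormatError("trace file contains no samples")
    arr = np.loadtxt(_io.StringIO("\n".join(data_lines)), delimiter=",", ndmin=2)
    if arr.shape[1] != len(header) or header[:2] != ["time_s", "x_nm"]:
        raise TraceFormatError(f"unexpected column layout: {header}")
    y = arr[:, header.index("y_nm")] if "y_nm" in header else None
    return TraceFile(
        time=arr[:, 0],
        position_parallel=arr[:, 1],
        position_perpendicular=y,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Top-level seed plus a nested parameter document.

    Every stochastic operation in the package receives a generator derived
    from ``seed`` through :func:`derive_rng`, so a config fully determines a
    run.  Configs round-trip through YAML unchanged.
    """

    seed: int
    params: dict[str, Any] = field(default_factory=dict)

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = yaml.safe_dump(
            {"seed": int(self.seed), "params": self.params}, sort_keys=True
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict) or "seed" not in doc:
            raise TraceFormatError("config document must contain a 'seed' key")
        return cls(seed=int(doc["seed"]), params=doc.get("params", {}) or {})


# ---------------------------------------------------------------------------
# seed plumbing

def derive_seed(seed: int, *key: int) -> np.random.SeedSequence:
    """Child seed-sequence for stream *key* under the top-level *seed*.

    The counter scheme is ``SeedSequence(seed, spawn_key=key)``: stream
    ``(i,)`` is the i-th trace, ``(i, j)`` the j-th sub-stream of that trace.
    Distinct keys give statistically independent streams; the same
    ``(seed, key)`` always reproduces the same stream.
    """
    return np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))


def derive_rng(seed: int, *key: int) -> np.random.Generator:
    """`numpy` Generator for stream *key* under the top-level *seed*."""
    return np.random.default_rng(derive_seed(seed, *key))
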