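"""Containers and plain-text I/O for voltage-clamp traces, event lists and metrics.

Conventions (fixed throughout the package): times are seconds, currents pA,
potentials mV; inward current is negative.  The native on-disk trace format is
a two-column delimited text file (``time_s``, ``current_pA``) with a JSON
metadata sidecar, chosen so files are portable and diff-able.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trace",
    "EventTrain",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "metric_table",
    "read_metrics",
    "write_metrics",
    "read_config",
    "write_config",
]

#: relative tolerance for checking the time column against the declared rate
_TIME_RTOL = 1e-6

METRIC_COLUMNS = ["neuron_id", "nucleus", "condition", "metric", "value", "units"]
NUCLEI = ("PHN", "INC")


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled whole-cell current recording.

    Parameters
    ----------
    samples
        Current in pA (inward negative).
    sampling_rate
        Hz, > 0.
    t0
        Time of the first sample, s.
    holding_potential
        Command potential in mV (junction-potential corrected upstream).
    burst_window
        ``(start_s, end_s)`` of the stimulus burst, or ``None``.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    holding_potential: float = -75.0
    burst_window: tuple[float, float] | None = None
    condition: str = ""
    neuron_id: str = ""
    trace_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if self.burst_window is not None:
            b0, b1 = self.burst_window
            if not (b0 < b1):
                raise ValueError("burst_window must satisfy start < end")
            if b0 < self.t0 - _TIME_RTOL or b1 > self.t_end + _TIME_RTOL:
                raise ValueError("burst_window lies outside the trace extent")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def with_offset(self, offset_pa: float) -> "Trace":
        """Return a copy with a constant current offset added (for testing
        baseline-invariance of downstream operations)."""
        return replace(self, samples=self.samples + offset_pa)


@dataclass(frozen=True)
class EventTrain:
    """Sorted EPSC peak times with peak amplitudes relative to local baseline."""

    times: np.ndarray
    amplitudes: np.ndarray
    source: str = "detected"  # "detected" | "truth"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and amplitudes must be equal-length 1-D arrays")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("event times must be sorted")
        if np.any(a >= 0):
            raise ValueError("EPSC amplitudes must be negative (inward)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# trace files


def write_trace(trace: Trace, path, metadata_path=None) -> None:
    """Write a trace as two-column text plus a JSON metadata sidecar.

    Values are printed with ``%.17g`` so a read round-trips bit-identically.
    """
    path = Path(path)
    metadata_path = Path(metadata_path) if metadata_path else path.with_suffix(".json")
    t = trace.times
    with open(path, "w") as fh:
        fh.write("time_s\tcurrent_pA\n")
        for ti, xi in zip(t, trace.samples):
            fh.write(f"{ti:.17g}\t{xi:.17g}\n")
    meta = {
        "sampling_rate": trace.sampling_rate,
        "t0": trace.t0,
        "holding_potential": trace.holding_potential,
        "burst_window": list(trace.burst_window) if trace.burst_window else None,
        "condition": trace.condition,
        "neuron_id": trace.neuron_id,
        "trace_index": trace.trace_index,
    }
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_trace(path, metadata_path=None) -> Trace:
    """Read a two-column trace file and its metadata sidecar.

    The time column, when present, must be uniform and consistent with the
    declared sampling rate to one part in 10^6; otherwise a ``ValueError``
    names the offending line.
    """
    path = Path(path)
    metadata_path = Path(metadata_path) if metadata_path else path.with_suffix(".json")
    with open(metadata_path) as fh:
        meta = json.load(fh)
    try:
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed trace file {path}: {exc}") from exc
    if "current_pA" not in frame.columns:
        raise ValueError(f"malformed trace file {path}: missing current_pA column")
    samples = frame["current_pA"].to_numpy(dtype=float)
    fs = float(meta["sampling_rate"])
    t0 = float(meta.get("t0", 0.0))
    if "time_s" in frame.columns and len(frame) > 1:
        t = frame["time_s"].to_numpy(dtype=float)
        dt = 1.0 / fs
        expected = t0 + np.arange(t.size) * dt
        bad = np.nonzero(np.abs(t - expected) > _TIME_RTOL * max(abs(expected[-1]), dt))[0]
        if bad.size:
            raise ValueError(
                f"time column inconsistent with sampling_rate={fs} Hz "
                f"at line {bad[0] + 2} of {path}"
            )
    bw = meta.get("burst_window")
    return Trace(
        samples=samples,
        sampling_rate=fs,
        t0=t0,
        holding_potential=float(meta.get("holding_potential", -75.0)),
        burst_window=tuple(bw) if bw else None,
        condition=meta.get("condition", ""),
        neuron_id=meta.get("neuron_id", ""),
        trace_index=int(meta.get("trace_index", 0)),
    )


# ---------------------------------------------------------------------------
# event lists


def write_events(train: EventTrain, path) -> None:
    with open(path, "w") as fh:
        fh.write("event_time_s,amplitude_pA\n")
        for ti, ai in zip(train.times, train.amplitudes):
            fh.write(f"{ti:.17g},{ai:.17g}\n")


def read_events(path, source: str = "detected") -> EventTrain:
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.empty:
        return EventTrain(np.array([]), np.array([]), source=source)
    t = frame["event_time_s"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError(f"event times in {path} are not sorted")
    return EventTrain(t, frame["amplitude_pA"].to_numpy(dtype=float), source=source)


# ---------------------------------------------------------------------------
# metric tables


def metric_table(rows) -> pd.DataFrame:
    """Build and validate a long-format metric table.

    One value per (neuron_id, condition, metric); nucleus must be PHN or INC.
    """
    frame = pd.DataFrame(list(rows), columns=METRIC_COLUMNS)
    bad = set(frame["nucleus"]) - set(NUCLEI)
    if bad:
        raise ValueError(f"unknown nucleus labels: {sorted(bad)}")
    dup = frame.duplicated(subset=["neuron_id", "condition", "metric"])
    if dup.any():
        raise ValueError("duplicate (neuron_id, condition, metric) rows")
    return frame


def write_metrics(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.17g")


def read_metrics(path) -> pd.DataFrame:
    return metric_table(
        pd.read_csv(path, float_precision="round_trip").to_dict("records")
    )


# ---------------------------------------------------------------------------
# pipeline configuration


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}
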