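"""Sustained-response statistics from EPSC event trains.

Implements the burst-response quantification: 100-ms peristimulus frequency
histograms averaged over the (three) sweeps of a neuron, the duration of the
increased EPSC frequency (time from burst termination until the mean of three
adjacent bins falls to or below the pre-burst baseline frequency), the EPSC
frequency over the first second after the burst, and per-neuron percent
reductions under a drug.

Conventions documented here because the source procedure leaves them open:
the three-bin rule is evaluated as a *sliding* window stepping one bin at a
time, and the reported duration is the time from burst end to the *start* of
the first qualifying triplet (0.1 s resolution; a disjoint-triplet variant is
available).  The comparison at the boundary is inclusive ("equal to or
smaller").  Bins are anchored at burst termination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_io import EventTrain

__all__ = [
    "FrequencyHistogram",
    "SustainedResponse",
    "bin_events",
    "baseline_rate",
    "duration_of_increase",
    "post_burst_rate",
    "percent_reduction",
    "mean_percent_reduction",
    "sustained_response",
]

BIN_WIDTH_S = 0.1
TRIPLET = 3  # number of adjacent bins averaged by the duration rule


@dataclass(frozen=True)
class FrequencyHistogram:
    """Event rates per bin (events/s), averaged across sweeps.

    The bin grid is anchored at ``origin`` (burst termination): the first
    post-burst bin starts exactly there.
    """

    bin_edges: np.ndarray  # s, len = n_bins + 1
    rates: np.ndarray  # events/s
    bin_width: float
    n_traces: int
    origin: float  # burst_end

    def __post_init__(self) -> None:
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, self.bin_width, rtol=1e-9, atol=1e-12):
            raise ValueError("bins must be uniform")

    @property
    def post_burst_rates(self) -> np.ndarray:
        first = int(np.searchsorted(self.bin_edges, self.origin - 1e-12))
        return self.rates[first:]


@dataclass(frozen=True)
class SustainedResponse:
    baseline_rate: float  # events/s
    duration: float  # s
    post_burst_rate_1s: float  # events/s
    capped: bool  # rate never returned to baseline within the trace

    def __post_init__(self) -> None:
        if self.duration < 0 or self.post_burst_rate_1s < 0:
            raise ValueError("duration and rates must be >= 0")


def bin_events(
    trains: list[EventTrain],
    burst_end: float,
    bin_width: float = BIN_WIDTH_S,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> FrequencyHistogram:
    """Average peristimulus frequency histogram over sweeps.

    Counts per bin are averaged across ``trains`` and divided by the bin
    width.  The grid is anchored at ``burst_end``; ``t_stop`` defaults to the
    last bin edge covering the latest event.
    """
    if not trains:
        raise ValueError("need at least one event train")
    if t_stop is None:
        latest = max((t.times[-1] for t in trains if len(t)), default=burst_end)
        t_stop = max(latest, burst_end) + bin_width
    k_lo = int(np.floor((t_start - burst_end) / bin_width + 1e-9))
    k_hi = int(np.ceil((t_stop - burst_end) / bin_width - 1e-9))
    edges = burst_end + bin_width * np.arange(k_lo, k_hi + 1)
    counts = np.zeros(edges.size - 1)
    for train in trains:
        counts += np.histogram(train.times, bins=edges)[0]
    rates = counts / len(trains) / bin_width
    return FrequencyHistogram(
        bin_edges=edges,
        rates=rates,
        bin_width=bin_width,
        n_traces=len(trains),
        origin=burst_end,
    )


def baseline_rate(trains: list[EventTrain], pre_window: tuple[float, float]) -> float:
    """Average pre-burst EPSC frequency: events in the window / (length * sweeps)."""
    a, b = pre_window
    if not b > a:
        raise ValueError("pre-burst window must have positive length")
    if not trains:
        raise ValueError("need at least one event train")
    n = sum(int(np.sum((t.times >= a) & (t.times < b))) for t in trains)
    return n / ((b - a) * len(trains))


def duration_of_increase(
    hist: FrequencyHistogram,
    baseline: float,
    mode: str = "sliding",
) -> tuple[float, bool]:
    """Duration of the increased EPSC frequency after the burst.

    Scans windows of three adjacent post-burst bins; the duration runs from
    burst termination to the start of the first window whose mean rate is
    less than or equal to ``baseline``.  Returns ``(duration, capped)`` where
    ``capped`` is True when no window qualifies within the histogram, in which
    case the full post-burst extent is reported.

    ``mode='sliding'`` steps one bin at a time (default); ``'disjoint'``
    steps three.
    """
    if mode not in ("sliding", "disjoint"):
        raise ValueError("mode must be 'sliding' or 'disjoint'")
    post = hist.post_burst_rates
    if post.size < TRIPLET:
        raise ValueError("need at least three post-burst bins")
    step = 1 if mode == "sliding" else TRIPLET
    for i in range(0, post.size - TRIPLET + 1, step):
        if post[i : i + TRIPLET].mean() <= baseline + 1e-12:
            return i * hist.bin_width, False
    return post.size * hist.bin_width, True


def post_burst_rate(
    trains: list[EventTrain],
    burst_end: float,
    window: float = 1.0,
    t_stop: float | None = None,
) -> float:
    """EPSC frequency over ``window`` seconds after burst termination."""
    if not trains:
        raise ValueError("need at least one event train")
    if t_stop is not None and t_stop < burst_end + window - 1e-9:
        raise ValueError(f"trace ends before {window} s after the burst")
    n = sum(
        int(np.sum((t.times >= burst_end) & (t.times < burst_end + window)))
        for t in trains
    )
    return n / (window * len(trains))


def percent_reduction(control: float, drug: float) -> float:
    """100 * (control - drug) / control for one neuron; control must be > 0."""
    if control <= 0:
        raise ValueError("control value must be > 0")
    return 100.0 * (control - drug) / control


def mean_percent_reduction(controls, drugs) -> tuple[float, np.ndarray, int]:
    """Per-neuron percent reductions, averaged across neurons.

    Computed per neuron *then* averaged (the mean of ratios, not the ratio of
    means).  Neurons with a non-positive control value are excluded; their
    count is returned alongside the mean and the per-neuron values.
    """
    c = np.asarray(controls, dtype=float)
    d = np.asarray(drugs, dtype=float)
    if c.shape != d.shape:
        raise ValueError("control and drug arrays must align")
    ok = c > 0
    per_neuron = 100.0 * (c[ok] - d[ok]) / c[ok]
    n_excluded = int((~ok).sum())
    mean = float(per_neuron.mean()) if per_neuron.size else float("nan")
    return mean, per_neuron, n_excluded


def sustained_response(
    trains: list[EventTrain],
    burst_window: tuple[float, float],
    t_stop: float,
    pre_window: tuple[float, float] | None = None,
    bin_width: float = BIN_WIDTH_S,
    mode: str = "sliding",
) -> SustainedResponse:
    """Full sustained-response summary for one neuron/condition.

    Builds the averaged histogram anchored at burst termination, estimates the
    pre-burst baseline frequency, and applies the duration and 1-s frequency
    rules.
    """
    b0, b1 = burst_window
    if pre_window is None:
        pre_window = (0.0, b0)
    base = baseline_rate(trains, pre_window)
    hist = bin_events(trains, burst_end=b1, bin_width=bin_width, t_start=b1, t_stop=t_stop)
    duration, capped = duration_of_increase(hist, base, mode=mode)
    rate1 = post_burst_rate(trains, burst_end=b1, t_stop=t_stop)
    return SustainedResponse(
        baseline_rate=base,
        duration=duration,
        post_burst_rate_1s=rate1,
        capped=capped,
    )
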