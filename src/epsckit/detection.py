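"""Threshold detection of spontaneous EPSCs in voltage-clamp traces.

An EPSC is accepted when the peak of the inward current, measured relative to
a local baseline, is strictly larger than ``threshold_factor`` (default 3)
times the SD of the baseline noise estimated before burst stimulation.  The
trace is zero-phase low-pass filtered at 1 kHz before peak finding, mirroring
the acquisition filter; stimulus-artifact intervals are blanked.

The peak amplitude is measured from a local baseline (median of a 10 ms
window just before the peak) rather than from absolute zero, which makes
detection invariant to holding-current offsets and slow drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .trace_io import EventTrain, Trace

__all__ = [
    "NoiseEstimate",
    "MatchResult",
    "estimate_baseline_sd",
    "detect_epscs",
    "stimulus_blank_windows",
    "match_to_truth",
]

#: default detection threshold multiple of the baseline-noise SD
THRESHOLD_FACTOR = 3.0
#: default merge distance between event peaks (s)
MIN_SEPARATION_S = 0.003
#: acquisition-mirroring low-pass corner (Hz)
LOWPASS_HZ = 1000.0
#: local-baseline window and guard before the peak (s)
BASELINE_WINDOW_S = 0.010
BASELINE_GAP_S = 0.002
#: rise window for the re-arm criterion (s): a peak must be preceded within
#: this window by a sample at least threshold above it, so secondary noise
#: minima riding on an event's decay tail are not counted as new events
RISE_WINDOW_S = 0.003


@dataclass(frozen=True)
class NoiseEstimate:
    sd: float  # pA
    window: tuple[float, float]
    method: str  # "raw" | "robust"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class MatchResult:
    recall: float
    precision: float
    time_errors: np.ndarray  # s, detected - truth for matched pairs
    n_matched: int
    degenerate: bool  # true when precision/recall fell back to the convention


def estimate_baseline_sd(
    trace: Trace,
    window: tuple[float, float] | None = None,
    method: str = "robust",
) -> NoiseEstimate:
    """SD of the pre-burst baseline noise.

    ``window`` defaults to everything before the burst.  The robust method
    uses 1.4826 * MAD, which resists contamination by spontaneous EPSCs in
    the baseline; ``raw`` is the plain sample SD.
    """
    if window is None:
        if trace.burst_window is None:
            raise ValueError("no burst window; pass an explicit baseline window")
        window = (trace.t0, trace.burst_window[0])
    a, b = window
    if trace.burst_window is not None and b > trace.burst_window[0] + 1e-9:
        raise ValueError("baseline window must precede the burst")
    if a < trace.t0 - 1e-9 or b > trace.t_end + 1e-9:
        raise ValueError("baseline window lies outside the trace")
    if b - a < 0.5:
        raise ValueError("baseline window must be at least 0.5 s")
    t = trace.times
    x = trace.samples[(t >= a) & (t < b)]
    if method == "raw":
        sd = float(np.std(x))
    elif method == "robust":
        sd = float(1.4826 * np.median(np.abs(x - np.median(x))))
    else:
        raise ValueError(f"unknown method {method!r}")
    return NoiseEstimate(sd=sd, window=(a, b), method=method)


def stimulus_blank_windows(
    burst_start: float,
    pulse_count: int = 20,
    pulse_rate_hz: float = 100.0,
    pre_s: float = 0.0005,
    post_s: float = 0.002,
) -> list[tuple[float, float]]:
    """Blanking intervals around each stimulus pulse of the burst."""
    period = 1.0 / pulse_rate_hz
    return [
        (burst_start + k * period - pre_s, burst_start + k * period + post_s)
        for k in range(pulse_count)
    ]


def _normalize_windows(windows) -> list[tuple[float, float]]:
    if not windows:
        return []
    ws = sorted((float(a), float(b)) for a, b in windows)
    merged = [ws[0]]
    for a, b in ws[1:]:
        if a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def detect_epscs(
    trace: Trace,
    noise: NoiseEstimate,
    min_separation: float = MIN_SEPARATION_S,
    blank_windows=None,
    threshold_factor: float = THRESHOLD_FACTOR,
    lowpass_hz: float | None = LOWPASS_HZ,
) -> EventTrain:
    """Detect EPSC peaks by the 3x-baseline-SD criterion.

    Local minima of the (low-pass filtered) current are accepted when their
    depth below the local baseline strictly exceeds
    ``threshold_factor * noise.sd``; minima closer than ``min_separation``
    merge to the deeper one; peaks inside ``blank_windows`` are discarded.
    """
    x = np.asarray(trace.samples, dtype=float).copy()
    fs = trace.sampling_rate
    if noise.sd == 0 and np.std(x) > 0:
        warnings.warn("noise SD is zero for a non-flat trace; threshold degenerates")
    blanks = _normalize_windows(blank_windows)
    # interpolate across the blank windows *before* filtering so the stimulus
    # artifact cannot ring past its blank under the zero-phase filter
    t_all = trace.times
    for a, b in blanks:
        sel = (t_all >= a) & (t_all <= b)
        if sel.any():
            i0, i1 = np.nonzero(sel)[0][[0, -1]]
            left = x[i0 - 1] if i0 > 0 else x[i1 + 1] if i1 + 1 < x.size else 0.0
            right = x[i1 + 1] if i1 + 1 < x.size else left
            x[i0 : i1 + 1] = np.linspace(left, right, i1 - i0 + 1)
    if lowpass_hz and lowpass_hz < fs / 2:
        sos = butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
        x = sosfiltfilt(sos, x)

    distance = max(1, int(round(min_separation * fs)))
    idx, _ = find_peaks(-x, distance=distance)

    gap = int(round(BASELINE_GAP_S * fs))
    win = max(1, int(round(BASELINE_WINDOW_S * fs)))
    thr = threshold_factor * noise.sd

    # local baseline: median of the `win` samples ending `gap` before the peak
    idx = idx[idx - gap - win >= 0]
    if idx.size:
        sw = np.lib.stride_tricks.sliding_window_view(x, win)
        local_base = np.median(sw[idx - gap - win], axis=1)
        amp = x[idx] - local_base
        keep = -amp > thr  # strict inequality at the 3*SD boundary
        # re-arm: require a genuine downward deflection just before the peak
        rise = max(1, int(round(RISE_WINDOW_S * fs)))
        ok = idx - rise >= 0
        keep &= ok
        if rise > 1:
            swr = np.lib.stride_tricks.sliding_window_view(x, rise)
            pre_max = np.max(swr[np.clip(idx - rise, 0, None)], axis=1)
            keep &= pre_max - x[idx] > thr
        idx, amp = idx[keep], amp[keep]
    else:
        amp = np.asarray([])

    times = trace.t0 + idx / fs
    if blanks and times.size:
        edges = np.asarray(blanks).ravel()
        outside = np.searchsorted(edges, times, side="right") % 2 == 0
        times, amp = times[outside], amp[outside]
    return EventTrain(times, amp, source="detected")


def match_to_truth(detected, truth, tolerance: float = 0.002) -> MatchResult:
    """One-to-one greedy matching of detected to true event times.

    Candidate pairs within ``tolerance`` are taken in order of |time error|;
    recall = matched / n_truth, precision = matched / n_detected.  When a
    denominator is zero the corresponding score is reported as 1.0 with the
    ``degenerate`` flag set.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    td = np.asarray(getattr(detected, "times", detected), dtype=float)
    tt = np.asarray(getattr(truth, "event_times", getattr(truth, "times", truth)), dtype=float)

    pairs = []
    lo = np.searchsorted(tt, td - tolerance)
    hi = np.searchsorted(tt, td + tolerance)
    for di, (a, b) in enumerate(zip(lo, hi)):
        for ti in range(a, b):
            pairs.append((abs(td[di] - tt[ti]), di, ti))
    pairs.sort()
    used_d, used_t = set(), set()
    errors = []
    for err, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        errors.append(td[di] - tt[ti])
    n = len(errors)
    degenerate = td.size == 0 or tt.size == 0
    recall = n / tt.size if tt.size else 1.0
    precision = n / td.size if td.size else 1.0
    return MatchResult(
        recall=float(recall),
        precision=float(precision),
        time_errors=np.asarray(errors),
        n_matched=n,
        degenerate=degenerate,
    )
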