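"""Quantification of agonist puff responses.

Covers the whole receptor-pharmacology block of the pipeline: reversal
potential from an I-V scan, rectification index (RI) with the RI < 1
classification of Ca2+-permeable-AMPA-receptor-like (inwardly rectifying)
responses, the NMDA/AMPA peak ratio, 10-s charge transfer normalised by input
capacitance, the voltage-step capacitance estimator, and the series-resistance
quality-control rule.

Sign conventions: RI is computed from response magnitudes normalised by the
magnitude of the driving force, so a purely ohmic conductance gives exactly
RI = 1 regardless of the sign bookkeeping of the raw currents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid

from .trace_io import Trace

__all__ = [
    "PuffResponse",
    "RectificationResult",
    "NMDAResult",
    "SeriesResistanceQC",
    "CapacitanceEstimate",
    "peak_response",
    "rectification_index",
    "find_reversal",
    "nmda_ampa_ratio",
    "charge_transfer",
    "input_capacitance",
    "series_resistance_qc",
]

#: window after puff onset searched for the response extremum (s)
PEAK_WINDOW_S = 2.0
#: Rs drift fraction above which a recording is discarded (inclusive pass at 0.20)
RS_MAX_CHANGE = 0.20


@dataclass(frozen=True)
class PuffResponse:
    """Agonist-evoked current at a stated holding potential."""

    trace: Trace
    agonist: str  # "KA" | "NMDA"
    holding_potential: float  # mV
    puff_time: float  # s

    def __post_init__(self) -> None:
        if not (self.trace.t0 <= self.puff_time <= self.trace.t_end):
            raise ValueError("puff_time lies outside the trace")
        if not self.agonist:
            raise ValueError("agonist must be labeled")


@dataclass(frozen=True)
class RectificationResult:
    reversal: float  # mV
    i_plus40: float  # pA at reversal + 40 mV
    i_minus60: float  # pA at reversal - 60 mV
    ri: float
    classification: str  # "inward" (RI<1) | "outward" (RI>=1)


@dataclass(frozen=True)
class NMDAResult:
    nmda_peak_at_plus40: float
    ampa_peak_at_minus70: float
    ratio: float
    charge_10s: float  # pC
    input_capacitance: float  # pF
    charge_per_pf: float  # pC/pF


@dataclass(frozen=True)
class SeriesResistanceQC:
    rs_values: np.ndarray  # MOhm per sweep
    max_change_fraction: float
    passed: bool


@dataclass(frozen=True)
class CapacitanceEstimate:
    capacitance_pf: float
    rs_mohm: float
    rin_mohm: float
    valid: bool


def peak_response(
    resp: PuffResponse,
    baseline_window: float = 0.2,
    peak_window: float = PEAK_WINDOW_S,
) -> float:
    """Signed extremum of the baseline-subtracted current after puff onset.

    Baseline is the mean current over ``baseline_window`` seconds immediately
    before the puff; the extremum is searched within ``peak_window`` seconds
    after it.
    """
    tr = resp.trace
    t = tr.times
    pre = (t >= resp.puff_time - baseline_window) & (t < resp.puff_time)
    post = (t >= resp.puff_time) & (t <= resp.puff_time + peak_window)
    if not post.any():
        raise ValueError("no samples after puff onset")
    base = tr.samples[pre].mean() if pre.any() else 0.0
    seg = tr.samples[post] - base
    return float(seg[np.argmax(np.abs(seg))])


def rectification_index(i_plus40: float, i_minus60: float) -> RectificationResult:
    """RI = (|I_+40|/40) / (|I_-60|/60), with RI < 1 classified inward.

    ``i_plus40`` and ``i_minus60`` are response amplitudes at +40 and -60 mV
    relative to the reversal potential.  Magnitudes are used so an ohmic
    conductance yields exactly 1.
    """
    if i_minus60 == 0:
        raise ValueError("I_-60 is zero; RI undefined")
    ri = (abs(i_plus40) / 40.0) / (abs(i_minus60) / 60.0)
    cls = "inward" if ri < 1.0 else "outward"
    return RectificationResult(
        reversal=float("nan"),
        i_plus40=float(i_plus40),
        i_minus60=float(i_minus60),
        ri=float(ri),
        classification=cls,
    )


def find_reversal(holdings, peaks) -> float:
    """Reversal potential by linear interpolation of peak response vs holding.

    Requires responses that bracket zero (a sign change, or an exact zero).
    """
    v = np.asarray(holdings, dtype=float)
    i = np.asarray(peaks, dtype=float)
    if v.size != i.size or v.size < 2:
        raise ValueError("need peak responses at >= 2 holding potentials")
    order = np.argsort(v)
    v, i = v[order], i[order]
    zero = np.nonzero(i == 0)[0]
    if zero.size:
        return float(v[zero[0]])
    sign_change = np.nonzero(np.diff(np.sign(i)) != 0)[0]
    if not sign_change.size:
        raise ValueError("responses do not bracket zero; cannot interpolate reversal")
    k = sign_change[0]
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))


def nmda_ampa_ratio(
    nmda: PuffResponse, ampa: PuffResponse, holding_tol: float = 1.0
) -> float:
    """|peak NMDA at +40 mV| / |peak AMPA at -70 mV|, peaks from pre-puff baseline."""
    if abs(nmda.holding_potential - 40.0) > holding_tol:
        raise ValueError("NMDA response must be recorded at +40 mV")
    if abs(ampa.holding_potential - (-70.0)) > holding_tol:
        raise ValueError("AMPA response must be recorded at -70 mV")
    a = peak_response(ampa)
    if a == 0:
        raise ValueError("AMPA peak is zero; ratio undefined")
    return abs(peak_response(nmda)) / abs(a)


def charge_transfer(
    resp: PuffResponse,
    capacitance_pf: float,
    window: float = 10.0,
    baseline_window: float = 0.2,
) -> tuple[float, float]:
    """Charge transfer over ``window`` s after the puff, and per pF.

    Trapezoidal integral of the baseline-subtracted signed current over
    [puff, puff + window]; the magnitude is reported in pC (pA.s) and divided
    by the input capacitance.
    """
    if capacitance_pf <= 0:
        raise ValueError("capacitance must be > 0")
    tr = resp.trace
    if tr.t_end < resp.puff_time + window - 0.5 / tr.sampling_rate:
        raise ValueError(f"trace shorter than {window} s after the puff")
    t = tr.times
    pre = (t >= resp.puff_time - baseline_window) & (t < resp.puff_time)
    base = tr.samples[pre].mean() if pre.any() else 0.0
    sel = (t >= resp.puff_time) & (t <= resp.puff_time + window)
    q = trapezoid(tr.samples[sel] - base, t[sel])  # pA*s == pC
    q = abs(float(q))
    return q, q / capacitance_pf


def _transient_charge(trace: Trace, step_time: float, step_end: float):
    """Baseline current, steady-state current and transient charge of a step."""
    t = trace.times
    pre = t < step_time
    if not pre.any():
        raise ValueError("no pre-step baseline samples")
    base = trace.samples[pre].mean()
    during = (t >= step_time) & (t < step_end)
    n_dur = int(during.sum())
    if n_dur < 8:
        raise ValueError("step window too short to reach steady state")
    x = trace.samples[during] - base
    tail = x[-max(2, n_dur // 4):]
    i_ss = tail.mean()
    # steady state check: the tail must be flat relative to the transient
    transient_span = np.max(np.abs(x - i_ss))
    if transient_span > 0 and np.abs(tail[0] - tail[-1]) > 0.05 * transient_span:
        raise ValueError("step response did not reach steady state")
    q = trapezoid(x - i_ss, t[during])  # pA*s
    return base, float(i_ss), float(q), t[during], x


def input_capacitance(
    step_response: Trace,
    dv_mv: float = 10.0,
    step_time: float = 0.05,
    step_end: float | None = None,
    correct_rs: bool = True,
) -> CapacitanceEstimate:
    """Input capacitance from the charge of the capacitive step transient.

    C = Q / dV where Q is the integral of the transient current above the
    steady-state level.  With a series resistance Rs the raw charge
    underestimates C by (Rm/(Rs+Rm))^2; when ``correct_rs`` the factor is
    undone using Rs from the extrapolated transient onset and Rin = dV/I_ss.
    Charge integration (rather than a single-exponential fit) is used because
    it is robust to multi-exponential transients.
    """
    if dv_mv == 0:
        raise ValueError("dv must be nonzero")
    if step_end is None:
        step_end = step_response.t_end
    _, i_ss, q, t_dur, x = _transient_charge(step_response, step_time, step_end)
    q = abs(q)
    peak = np.max(np.abs(x - i_ss))
    if peak < 1e-12:
        return CapacitanceEstimate(0.0, float("nan"), float("nan"), valid=False)
    # pC / mV = nF -> pF
    c_raw = 1000.0 * q / abs(dv_mv)
    rs = rin = float("nan")
    if abs(i_ss) > 1e-12:
        rin = 1000.0 * abs(dv_mv) / abs(i_ss)  # MOhm
        # extrapolate the transient to the step onset for I0 = dV/Rs
        y = np.abs(x - i_ss)
        sel = y > 0.05 * peak
        if sel.sum() >= 3:
            coef = np.polyfit(t_dur[sel] - step_time, np.log(y[sel]), 1)
            i0 = float(np.exp(coef[1]))
        else:
            i0 = float(peak)
        rs = 1000.0 * abs(dv_mv) / i0
        rm = rin - rs
        if correct_rs and rm > 0:
            c_raw *= (rin / rm) ** 2
    return CapacitanceEstimate(float(c_raw), rs, rin, valid=True)


def series_resistance_qc(
    test_pulses: list[Trace],
    dv_mv: float = -10.0,
    step_time: float = 0.05,
    peak_window: float = 0.02,
) -> SeriesResistanceQC:
    """Series resistance per sweep from the peak of the -10 mV test-pulse
    transient; fail when Rs drifts by more than 20% from the first sweep."""
    if len(test_pulses) < 2:
        raise ValueError("need at least two test-pulse sweeps")
    rs = []
    for tr in test_pulses:
        t = tr.times
        pre = t < step_time
        base = tr.samples[pre].mean() if pre.any() else 0.0
        sel = (t >= step_time) & (t <= step_time + peak_window)
        seg = tr.samples[sel] - base
        if seg.size == 0 or np.max(np.abs(seg)) < 1e-9:
            raise ValueError("no capacitive transient in test pulse")
        i_peak = seg[np.argmax(np.abs(seg))]
        rs.append(1000.0 * abs(dv_mv) / abs(i_peak))  # MOhm
    rs = np.asarray(rs)
    change = float(np.max(np.abs(rs - rs[0]) / rs[0]))
    return SeriesResistanceQC(rs_values=rs, max_change_fraction=change,
                              passed=change <= RS_MAX_CHANGE + 1e-12)
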