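"""Glue: run detection + sustained-response metrics over simulated cohorts."""

from __future__ import annotations

import pandas as pd

from . import detection, response_metrics
from .synthgen import NeuronRecord
from .trace_io import metric_table

__all__ = ["neuron_condition_metrics", "cohort_metrics"]


def _trains_for(record: NeuronRecord, condition: str, from_truth: bool,
                detector_kwargs: dict):
    from .trace_io import EventTrain

    trains = []
    for trace, truth in record.conditions[condition]:
        if from_truth or trace is None:
            trains.append(EventTrain(truth.event_times, truth.event_amplitudes,
                                     source="truth"))
            continue
        noise = detection.estimate_baseline_sd(trace)
        blanks = detection.stimulus_blank_windows(record.burst_window[0])
        trains.append(detection.detect_epscs(trace, noise, blank_windows=blanks,
                                             **detector_kwargs))
    return trains


def neuron_condition_metrics(
    record: NeuronRecord,
    condition: str,
    from_truth: bool = False,
    **detector_kwargs,
) -> dict:
    """Sustained-response metrics for one neuron in one condition."""
    trains = _trains_for(record, condition, from_truth, detector_kwargs)
    resp = response_metrics.sustained_response(
        trains,
        burst_window=record.burst_window,
        t_stop=record.trace_duration,
    )
    return {
        "duration_s": resp.duration,
        "post_rate_1s": resp.post_burst_rate_1s,
        "baseline_rate": resp.baseline_rate,
        "duration_capped": float(resp.capped),
    }


_UNITS = {
    "duration_s": "s",
    "post_rate_1s": "events/s",
    "baseline_rate": "events/s",
    "duration_capped": "bool",
}


def cohort_metrics(records: list[NeuronRecord], from_truth: bool = False,
                   **detector_kwargs) -> pd.DataFrame:
    """Long-format metric table for a cohort (all neurons, all conditions)."""
    rows = []
    for rec in records:
        for condition in rec.conditions:
            vals = neuron_condition_metrics(rec, condition, from_truth,
                                            **detector_kwargs)
            for metric, value in vals.items():
                rows.append({
                    "neuron_id": rec.neuron_id,
                    "nucleus": rec.nucleus,
                    "condition": condition,
                    "metric": metric,
                    "value": value,
                    "units": _UNITS[metric],
                })
    return metric_table(rows)
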