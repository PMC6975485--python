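"""Normality-gated statistical battery and publication-style group report.

Test selection mirrors the analysis protocol of the study being reproduced:
Shapiro-Wilk decides normality (alpha = 0.05; for paired comparisons the gate
is applied to the paired differences); normal data get Student's t tests
(paired or pooled-variance unpaired), non-normal data get the Wilcoxon
signed-rank or Mann-Whitney test; distribution comparisons use the two-sample
Kolmogorov-Smirnov test.  Post hoc power is computed from the noncentral t
distribution at alpha = 0.05.  No multiple-testing correction is applied,
matching the original battery -- interpret the report accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .response_metrics import mean_percent_reduction

__all__ = [
    "StatsRow",
    "Comparison",
    "choose_test",
    "run_test",
    "posthoc_power",
    "build_report",
    "drug_plan",
    "rows_to_frame",
]

NORMALITY_ALPHA = 0.05
#: sample size up to which rank tests use the exact null distribution
EXACT_RANK_N = 12
#: asymptotic relative efficiency of rank vs t tests under a normal parent,
#: used to deflate n for rank-test power (the ARE convention of standard power calculators)
RANK_ARE = 3.0 / math.pi

PAIRED_TESTS = ("paired t", "wilcoxon")
UNPAIRED_TESTS = ("unpaired t", "mann-whitney")


@dataclass(frozen=True)
class StatsRow:
    """One comparison of the group report (publication-style row)."""

    label: str
    parameter: str
    group_names: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    sd: tuple[float, float]
    normality: str  # "normal" | "non-normal"
    test: str
    p: float
    power: float
    incomplete: bool = False


@dataclass(frozen=True)
class Comparison:
    """A requested comparison for :func:`build_report`.

    kind:
      - "paired_condition": control vs drug within one nucleus (paired)
      - "nucleus_reduction": per-neuron percent reduction, PHN vs INC (unpaired)
      - "nucleus_metric": a metric compared PHN vs INC (unpaired)
      - "nucleus_distribution": distribution of a metric PHN vs INC (KS)
    """

    label: str
    parameter: str
    metric: str
    kind: str
    nucleus: str | None = None
    conditions: tuple[str, str] = ("control", "drug")


def _shapiro_normal(x, alpha: float = NORMALITY_ALPHA) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        return False  # degenerate; treat as non-normal
    return stats.shapiro(x).pvalue >= alpha


def choose_test(paired: bool, x, y, alpha: float = NORMALITY_ALPHA,
                gate: str = "differences") -> str:
    """Select the location test by the Shapiro-Wilk normality gate.

    Paired data are gated on the paired differences by default
    (``gate='per-group'`` gates each sample instead); unpaired data require
    every group to pass.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 3:
        raise ValueError("need n >= 3 per group")
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must align")
        if gate == "differences":
            normal = _shapiro_normal(x - y, alpha)
        else:
            normal = _shapiro_normal(x, alpha) and _shapiro_normal(y, alpha)
        return "paired t" if normal else "wilcoxon"
    normal = _shapiro_normal(x, alpha) and _shapiro_normal(y, alpha)
    return "unpaired t" if normal else "mann-whitney"


def run_test(test: str, x, y) -> tuple[float, float]:
    """Run a named test; return (statistic, two-tailed p).

    Rank tests use the exact null distribution for n <= 12 (no ties) and the
    continuity-corrected normal approximation otherwise.  The unpaired t is
    Student's pooled-variance test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if test == "paired t":
        d = x - y
        if np.std(d, ddof=1) == 0:
            raise ValueError("zero variance of paired differences")
        res = stats.ttest_rel(x, y)
    elif test == "unpaired t":
        if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
            raise ValueError("zero variance in both groups")
        res = stats.ttest_ind(x, y, equal_var=True)
    elif test == "wilcoxon":
        d = x - y
        d = d[d != 0]
        exact = d.size <= EXACT_RANK_N and np.unique(np.abs(d)).size == d.size
        res = stats.wilcoxon(d, method="exact" if exact else "approx",
                             correction=True)
    elif test == "mann-whitney":
        pooled = np.concatenate([x, y])
        exact = (
            max(x.size, y.size) <= EXACT_RANK_N
            and np.unique(pooled).size == pooled.size
        )
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided",
            method="exact" if exact else "asymptotic",
        )
    elif test == "ks":
        res = stats.ks_2samp(x, y)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def posthoc_power(test: str, x, y, alpha: float = 0.05) -> float:
    """Post hoc power at the observed effect size, two-tailed.

    Two-sample tests use Cohen's d with the pooled SD and the noncentral t;
    paired tests use d_z = mean(diff)/sd(diff).  For the rank tests the
    noncentral-t power is evaluated at an ARE-deflated sample size
    (n * 3/pi), the conventional normal-parent approximation.  The KS test
    has no standard power model; NaN is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if test == "ks":
        return float("nan")
    if test in PAIRED_TESTS:
        d = x - y
        sd = np.std(d, ddof=1)
        if sd == 0:
            raise ValueError("zero effect-size denominator")
        dz = abs(d.mean()) / sd
        n = d.size * (RANK_ARE if test == "wilcoxon" else 1.0)
        return _nct_power(ncp=dz * math.sqrt(n), df=n - 1, alpha=alpha)
    n1, n2 = x.size, y.size
    pooled = math.sqrt(
        ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        raise ValueError("zero effect-size denominator")
    d_eff = abs(x.mean() - y.mean()) / pooled
    are = RANK_ARE if test == "mann-whitney" else 1.0
    m1, m2 = n1 * are, n2 * are
    ncp = d_eff * math.sqrt(m1 * m2 / (m1 + m2))
    return _nct_power(ncp=ncp, df=m1 + m2 - 2, alpha=alpha)


def _nct_power(ncp: float, df: float, alpha: float) -> float:
    """Two-tailed rejection probability of a t test under noncentrality ncp."""
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


# ---------------------------------------------------------------------------
# report assembly


def _metric_values(metrics: pd.DataFrame, metric: str, nucleus: str, condition: str):
    sel = metrics[
        (metrics["metric"] == metric)
        & (metrics["nucleus"] == nucleus)
        & (metrics["condition"] == condition)
    ].sort_values("neuron_id")
    return sel["neuron_id"].to_numpy(), sel["value"].to_numpy(dtype=float)


def _row(label, parameter, names, x, y, paired: bool, force_test: str | None = None):
    incomplete = min(len(x), len(y)) < 3 or (paired and len(x) != len(y))
    if incomplete:
        return StatsRow(label, parameter, names, (len(x), len(y)),
                        (float("nan"),) * 2, (float("nan"),) * 2,
                        "n/a", "n/a", float("nan"), float("nan"), incomplete=True)
    if force_test:
        test = force_test
        normality = "n/a"
    else:
        test = choose_test(paired, x, y)
        normality = "normal" if test in ("paired t", "unpaired t") else "non-normal"
    _, p = run_test(test, x, y)
    try:
        power = posthoc_power(test, x, y)
    except ValueError:
        power = float("nan")
    return StatsRow(
        label=label, parameter=parameter, group_names=names,
        n=(len(x), len(y)),
        mean=(float(np.mean(x)), float(np.mean(y))),
        sd=(float(np.std(x, ddof=1)), float(np.std(y, ddof=1))),
        normality=normality, test=test, p=p, power=power,
    )


def build_report(metrics: pd.DataFrame, plan: list[Comparison]) -> list[StatsRow]:
    """Assemble a publication-style report: one :class:`StatsRow` per comparison.

    ``metrics`` is a long-format metric table (see ``trace_io.metric_table``).
    Comparisons with missing cells are flagged incomplete rather than raised.
    """
    rows = []
    for comp in plan:
        if comp.kind == "paired_condition":
            c0, c1 = comp.conditions
            ids0, x = _metric_values(metrics, comp.metric, comp.nucleus, c0)
            ids1, y = _metric_values(metrics, comp.metric, comp.nucleus, c1)
            common = np.intersect1d(ids0, ids1)
            x = x[np.isin(ids0, common)]
            y = y[np.isin(ids1, common)]
            rows.append(_row(comp.label, comp.parameter, (c0, c1), x, y, paired=True))
        elif comp.kind == "nucleus_reduction":
            c0, c1 = comp.conditions
            groups = []
            for nucleus in ("PHN", "INC"):
                ids0, ctrl = _metric_values(metrics, comp.metric, nucleus, c0)
                ids1, drug = _metric_values(metrics, comp.metric, nucleus, c1)
                common = np.intersect1d(ids0, ids1)
                ctrl = ctrl[np.isin(ids0, common)]
                drug = drug[np.isin(ids1, common)]
                _, per_neuron, _ = mean_percent_reduction(ctrl, drug)
                groups.append(per_neuron)
            rows.append(_row(comp.label, comp.parameter, ("PHN", "INC"),
                             groups[0], groups[1], paired=False))
        elif comp.kind in ("nucleus_metric", "nucleus_distribution"):
            cond = comp.conditions[0]
            _, x = _metric_values(metrics, comp.metric, "PHN", cond)
            _, y = _metric_values(metrics, comp.metric, "INC", cond)
            force = "ks" if comp.kind == "nucleus_distribution" else None
            rows.append(_row(comp.label, comp.parameter, ("PHN", "INC"),
                             x, y, paired=False, force_test=force))
        else:
            raise ValueError(f"unknown comparison kind {comp.kind!r}")
    return rows


def drug_plan(drug: str) -> list[Comparison]:
    """The six-comparison plan of one drug experiment (duration and 1-s rate,
    each nucleus paired control-vs-drug, plus PHN-vs-INC percent reductions)."""
    c = ("control", drug)
    return [
        Comparison("A", "Duration of PHN neurons (s)", "duration_s",
                   "paired_condition", nucleus="PHN", conditions=c),
        Comparison("B", "Duration of INC neurons (s)", "duration_s",
                   "paired_condition", nucleus="INC", conditions=c),
        Comparison("C", "EPSC rate of PHN neurons (events/s)", "post_rate_1s",
                   "paired_condition", nucleus="PHN", conditions=c),
        Comparison("D", "EPSC rate of INC neurons (events/s)", "post_rate_1s",
                   "paired_condition", nucleus="INC", conditions=c),
        Comparison("E", f"Reduction in duration by {drug} (%)", "duration_s",
                   "nucleus_reduction", conditions=c),
        Comparison("F", f"Reduction in EPSC rate by {drug} (%)", "post_rate_1s",
                   "nucleus_reduction", conditions=c),
    ]


def rows_to_frame(rows: list[StatsRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        recs.append({
            "label": r.label,
            "parameter": r.parameter,
            "group1": r.group_names[0], "group2": r.group_names[1],
            "n1": r.n[0], "n2": r.n[1],
            "mean1": r.mean[0], "mean2": r.mean[1],
            "sd1": r.sd[0], "sd2": r.sd[1],
            "normality": r.normality, "test": r.test,
            "p": r.p, "power": r.power, "incomplete": r.incomplete,
        })
    return pd.DataFrame.from_records(recs)
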