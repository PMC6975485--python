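# Methods

`epsckit` quantifies burst-evoked sustained EPSC responses and agonist puff
responses in whole-cell voltage-clamp recordings, and ships a synthetic-data
generator with known ground truth so every stage of the pipeline can be
validated without raw recordings.  Conventions throughout: time in seconds,
current in pA (inward negative), potential in mV.

## Sustained-response quantification

**Event detection.**  An EPSC is accepted where the peak of the inward
current, measured against a local baseline, strictly exceeds `k` times the SD
of the baseline noise estimated in a pre-burst window (`k = 3` by default).
Details that the threshold criterion alone leaves open, and how we resolved
them:

- The trace is zero-phase low-pass filtered at 1 kHz (4th-order Butterworth,
  forward-backward) before peak finding, mirroring the acquisition filter.
- Baseline-noise SD defaults to the robust estimator `1.4826 * MAD` over the
  pre-burst window (>= 0.5 s), which resists contamination by spontaneous
  EPSCs; the raw sample SD is available as `method="raw"`.
- The peak amplitude is measured from a *local* baseline — the median of a
  10 ms window ending 2 ms before the peak — not from absolute zero.  This
  makes detection invariant to holding-current offsets and slow drift (a
  tested property).
- Candidate minima closer than `min_separation = 3 ms` merge to the deeper
  one.
- A re-arm criterion requires a sample at least one threshold *above* the
  peak within the preceding 3 ms.  Without it, secondary noise minima riding
  on an event's ~5 ms decay tail are counted as events and precision drops by
  tens of points.
- Stimulus artifacts (20 pulses at 100 Hz) are blanked over
  [pulse - 0.5 ms, pulse + 2 ms].  Blanked segments are linearly interpolated
  *before* filtering — otherwise the ~200 pA artifact rings past its blank
  under the zero-phase filter — and no detected peak may lie inside a blank.

Detector validation matches detected peak times to ground-truth onset times
shifted by the kernel's deterministic onset-to-peak latency (1.28 ms at the
default 0.5/5 ms kinetics), one-to-one greedy by time error, tolerance 2 ms.

**Frequency histograms and duration.**  Event counts are binned at 100 ms,
averaged over the (three) sweeps of a neuron, and divided by the bin width.
The bin grid is anchored at burst termination.  The duration of the increased
EPSC frequency runs from burst termination to the start of the first window
of three adjacent bins whose mean rate is *less than or equal to* the
pre-burst baseline frequency.  Two readings of "three adjacent bins" are
possible; we evaluate a **sliding** window stepping one bin at a time
(0.1 s resolution) and report the start of the first qualifying triplet.  The
disjoint-triplet variant (0.3 s quantisation) is available via
`mode="disjoint"`.  If no triplet qualifies, the full post-burst extent is
reported with `capped=True`.  The post-burst EPSC frequency is counted over
exactly 1 s after burst termination.  Percent reductions are computed per
neuron and then averaged (mean of ratios, not ratio of means); neurons with a
non-positive control value are excluded and counted.

Events during the 0.2 s burst itself contribute to no metric: the baseline
window ends at burst onset and the histogram/1-s windows start at burst end.

## Puff-response quantification

Peaks are extrema of the baseline-subtracted current within 2 s of puff
onset (baseline: mean over 0.2 s before the puff).  The reversal potential
interpolates peak response vs holding potential linearly to the zero
crossing.  The rectification index is

    RI = (|I_+40| / 40) / (|I_-60| / 60)

with amplitudes taken at +40 / -60 mV relative to the reversal potential;
magnitudes normalised by driving force make an ohmic conductance exactly 1.
RI < 1 classifies a response as inwardly rectifying (Ca2+-permeable-AMPAR
phenotype), RI >= 1 as outwardly rectifying.  The NMDA/AMPA ratio is
|peak at +40 mV (NMDA)| / |peak at -70 mV (KA)|; holding potentials are
validated from metadata.  Charge transfer integrates the baseline-subtracted
signed current (trapezoid) over 10 s after the puff and reports the magnitude
in pC, normalised by input capacitance (pC/pF).

**Input capacitance** comes from the charge of the capacitive transient of a
10 mV step: C = Q/dV with Q the integral of current above the steady-state
level.  Series resistance makes the raw charge underestimate C by
(Rm/(Rs+Rm))^2; the estimator undoes that factor using Rs extrapolated from
the transient onset (log-linear fit) and Rin = dV/I_ss.  Charge integration
was chosen over a single-exponential fit because it is robust to
multi-exponential transients.  Recovery error is < 2% for C in 20-200 pF and
Rs in 5-20 MOhm in the RC model (tested).  **Series-resistance QC** computes
Rs = dV / peak transient per -10 mV/100 ms test pulse and fails a recording
when Rs drifts more than 20% from the first sweep (inclusive pass at exactly
20%).

## Statistical battery

Normality is gated by Shapiro-Wilk at alpha = 0.05; for paired comparisons
the gate is applied to the paired differences (per-group gating available via
a flag).  Normal data: Student's t tests (paired, or pooled-variance
unpaired; Welch is deliberately not the default).  Non-normal: Wilcoxon
signed-rank (paired) or Mann-Whitney (unpaired).  Distribution comparisons:
two-sample Kolmogorov-Smirnov.  Rank tests use the exact null distribution
for n <= 12 without ties and the continuity-corrected normal approximation
otherwise.  Post hoc power is the two-tailed rejection probability of the
noncentral t distribution at the observed effect size (Cohen's d with pooled
SD, or d_z for paired data) at alpha = 0.05; for rank tests the sample size
is deflated by the normal-parent asymptotic relative efficiency 3/pi.  The KS
test gets no power value.  **No multiple-testing correction is applied** —
the report mirrors a fixed battery of planned comparisons; interpret
accordingly.

## Synthetic data generator

The generator emulates the statistical structure of burst recordings:

- EPSC times are an inhomogeneous Poisson process:
  `lambda(t) = b` before burst end and `b + A*exp(-(t-t_end)/tau)` after.
  The exponential-decay elevation is the simplest two-parameter model that
  produces a seconds-long sustained response; elevation events are drawn by
  inverting the cumulative rate.
- EPSC shape is a biexponential kernel normalised so its peak equals the
  event amplitude; defaults tau_rise = 0.5 ms, tau_decay = 5 ms (typical
  AMPA-receptor EPSC kinetics).
- Amplitudes are log-normal (mean 20 pA, SD 8 pA, inward) truncated below at
  half the detection threshold (1.5 x noise SD) so that some events are
  genuinely sub-threshold and detector misses are exercised.
- Gaussian baseline noise, default SD 2 pA; sampling 5 kHz (upper end of the
  2-5 kHz digitisation range, chosen for peak fidelity); 10 s traces with the
  burst at 2.0-2.2 s.
- The stimulus artifact is 20 biphasic 0.1 ms, ±200 pA rectangles at 100 Hz.
- The spontaneous baseline rate defaults to 10 events/s — a mid-range value
  for spontaneous EPSCs in brainstem slice recordings; it is config-exposed
  because no published value constrains it.
- Cohorts pair control and drug conditions within neurons: each neuron gets a
  multiplicative log-normal random effect (CV 0.25, chosen to match the
  published between-neuron coefficients of variation) on both elevation
  amplitude and decay, shared across conditions; a drug multiplies the
  elevation amplitude and decay by scales in [0, 1].  Three sweeps per neuron
  per condition.
- Puff responses follow a driving-force model I = g*(V - V_rev), scaled by a
  rectification factor above reversal, with instant rise and monoexponential
  decay.  RC step responses implement the exact single-compartment
  Rs-(Rm||C) solution.

**Calibration to the published group means.**  For each drug x nucleus group
the elevation parameters are chosen so that the *measured* pipeline outputs
(duration and 1-s rate, with detection in the loop) reproduce the published
group means.  Because the elevated rate only asymptotes to baseline, the
3-bin crossing is noise-driven and the measured duration exceeds the naive
crossing time; we therefore fitted a response surface by simulation
(duration ~= 0.40 + 0.51 tau + 1.08 tau ln(A/b) - 0.027 ln(A/b); detected
rate ~= 0.945 b + (0.8675 - 0.0031 e) e with e the true extra-event count)
and invert it on a bounded grid.  Coefficients are frozen in `synthgen`.
Where the [0, 1] drug-scale box binds (near-null drug effects), the drug
condition can undershoot its target slightly (worst case ~0.2 s of
duration).

## What passing tests do and do not show

The generator reproduces Poisson counting statistics, detector-limited
observation, and the published per-group means, so it validates the
*procedures* — detection, binning, the duration rule, RI/charge arithmetic,
test selection, power.  It does not reproduce several features of real data:
correlated event amplitudes and kinetics, bursty (non-Poisson) release,
electrode drift, or the real pairing reliability of repeated measurements.
One consequence is quantified honestly by the end-to-end checks: with
Poisson counting noise the per-neuron measured duration has SD ~0.6 s, so
small paired duration effects (~0.3 s at n = 8) reach significance in only a
minority of replicates, whereas the published data report p ~ 0.001 for such
effects — the real per-neuron duration measurements must be less variable
than a Poisson-count model permits.  The pipeline's significance checks
therefore target the 1-s rate metric (high power at the published effect
sizes) plus the percent-reduction orderings; the duration battery is still
computed and reported.  Similarly, peak-extremum noise bias shifts simulated
RI values upward by ~2%, moving the RI < 1 proportions a few points below
the population values (still within cohort sampling error).

## Problem sizes

Default validation sizes, chosen as the package's own reproducibility
settings: 50 traces for the detector operating point; 100 random histograms
for the duration oracle; 100 cohorts of the published sizes (48/45) for RI
proportions; 2000 null replicates for test calibration; 100k replicates for
the power oracle; 100 full pipeline replicates (3 drugs x 2 nuclei x 8
neurons x 2 conditions x 3 sweeps) for the drug-effect direction check.
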