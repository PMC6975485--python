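"""Generator: Poisson event statistics, trace rendering, puff/RC models, cohorts."""

import numpy as np
import pytest
from dataclasses import replace

from epsckit import synthgen as sg
from epsckit.receptor_pharm import peak_response, rectification_index
from epsckit.trace_io import EventTrain
from epsckit import response_metrics as rm
from epsckit.group_stats import run_test


class TestSampleEventTimes:
    def test_constant_rate_mean_count(self):
        """Constant lambda=10/s over 10 s: replicate mean within 3 SE of 100."""
        cfg = sg.SimulationConfig(baseline_rate=10.0, elevation_amplitude=0.0,
                                  elevation_tau=1.0, seed=0)
        rng = np.random.default_rng(1)
        counts = [len(sg.sample_event_times(cfg, rng=rng)) for _ in range(1000)]
        se = np.sqrt(100.0 / 1000)
        assert abs(np.mean(counts) - 100.0) < 3 * se

    def test_zero_rates_empty_train(self):
        cfg = sg.SimulationConfig(baseline_rate=0.0, elevation_amplitude=0.0)
        assert len(sg.sample_event_times(cfg)) == 0

    def test_elevation_extra_count_matches_integral(self):
        """Extra events above baseline match A*tau*(1-exp(-(T-t0)/tau))."""
        cfg = sg.SimulationConfig(baseline_rate=0.0, elevation_amplitude=20.0,
                                  elevation_tau=1.0, trace_duration=10.0)
        expected = 20.0 * 1.0 * (1 - np.exp(-(10.0 - cfg.burst_end) / 1.0))
        rng = np.random.default_rng(2)
        counts = [len(sg.sample_event_times(cfg, rng=rng)) for _ in range(500)]
        se = np.sqrt(expected / 500)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_drug_effect_scales_elevation_mass(self):
        cfg = sg.SimulationConfig(baseline_rate=0.0, elevation_amplitude=30.0,
                                  elevation_tau=1.0)
        eff = sg.DrugEffect(rate_scale=0.5, tau_scale=0.5, label="x")
        rng = np.random.default_rng(3)
        counts = [len(sg.sample_event_times(cfg, eff, rng=rng)) for _ in range(500)]
        expected = 15.0 * 0.5 * (1 - np.exp(-(10.0 - cfg.burst_end) / 0.5))
        assert abs(np.mean(counts) - expected) < 3 * np.sqrt(expected / 500)

    def test_times_sorted_in_bounds_amplitudes_negative(self, default_config):
        truth = sg.sample_event_times(default_config)
        assert np.all(np.diff(truth.event_times) > 0)
        assert truth.event_times[0] >= 0
        assert truth.event_times[-1] <= default_config.trace_duration
        assert np.all(truth.event_amplitudes < 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sg.SimulationConfig(baseline_rate=-1.0)
        with pytest.raises(ValueError):
            sg.SimulationConfig(elevation_tau=0.0)
        with pytest.raises(ValueError):
            sg.SimulationConfig(tau_rise=0.01, tau_decay=0.005)


class TestRenderTrace:
    def test_single_event_peak_amplitude(self, clean_config):
        """A lone -20 pA event renders with minimum -20 pA within 1%."""
        truth = sg.GroundTruth(np.array([1.0]), np.array([-20.0]))
        cfg = replace(clean_config, baseline_rate=0.0)
        tr = sg.render_trace(truth, cfg)
        assert tr.samples.min() == pytest.approx(-20.0, rel=0.01)

    def test_empty_truth_noiseless_is_zero_outside_artifacts(self, clean_config):
        truth = sg.GroundTruth(np.array([]), np.array([]))
        tr = sg.render_trace(truth, replace(clean_config, artifact_amplitude=200.0))
        t = tr.times
        in_burst = (t >= clean_config.burst_start) & (t <= clean_config.burst_end)
        assert np.all(tr.samples[~in_burst] == 0.0)
        assert np.any(tr.samples[in_burst] != 0.0)  # artifacts present

    def test_noise_sd_recovered(self):
        cfg = sg.SimulationConfig(noise_sd=2.0, baseline_rate=0.0,
                                  elevation_amplitude=0.0, artifact_amplitude=0.0,
                                  seed=5)
        truth = sg.GroundTruth(np.array([]), np.array([]))
        tr = sg.render_trace(truth, cfg)
        assert np.std(tr.samples) == pytest.approx(2.0, rel=0.05)

    def test_kernel_superposition_reconstructs_trace(self, clean_config):
        """Subtracting independently computed kernels leaves < 1e-9 pA residual."""
        cfg = replace(clean_config, baseline_rate=5.0)
        truth = sg.sample_event_times(cfg)
        tr = sg.render_trace(truth, cfg)
        t = tr.times
        model = np.zeros_like(t)
        t_pk, norm = sg.biexp_kernel_peak_norm(cfg.tau_rise, cfg.tau_decay)
        for te, a in zip(truth.event_times, truth.event_amplitudes):
            dt = t - te
            m = dt >= 0
            model[m] += (
                a * (np.exp(-dt[m] / cfg.tau_decay) - np.exp(-dt[m] / cfg.tau_rise)) / norm
            )
        assert np.max(np.abs(tr.samples - model)) < 1e-9

    def test_seed_determinism_and_divergence(self, default_config):
        t1 = sg.sample_event_times(default_config)
        t2 = sg.sample_event_times(default_config)
        assert np.array_equal(t1.event_times, t2.event_times)
        tr1 = sg.render_trace(t1, default_config)
        tr2 = sg.render_trace(t2, default_config)
        assert np.array_equal(tr1.samples, tr2.samples)
        other = sg.sample_event_times(replace(default_config, seed=43))
        assert not np.array_equal(t1.event_times, other.event_times)


class TestPuffAndRC:
    def test_zero_response_at_reversal(self):
        resp = sg.generate_puff_response(peak=-300.0, decay_tau=1.0, holding=0.0,
                                         reversal=0.0)
        assert np.all(resp.trace.samples == 0.0)

    def test_linear_iv_driving_force_ratio(self):
        """Ohmic conductance: peaks at rev+40 and rev-60 have ratio -2/3."""
        up = sg.generate_puff_response(-300.0, 1.0, holding=40.0, reversal=0.0)
        dn = sg.generate_puff_response(-300.0, 1.0, holding=-60.0, reversal=0.0)
        assert peak_response(up) / peak_response(dn) == pytest.approx(-2.0 / 3.0)
        assert peak_response(dn) == pytest.approx(-300.0, rel=1e-6)

    def test_rectification_feeds_ri(self):
        """rectification=0.5 at +40 mV yields downstream RI = 0.5."""
        up = sg.generate_puff_response(-300.0, 1.0, 40.0, 0.0, rectification=0.5)
        dn = sg.generate_puff_response(-300.0, 1.0, -60.0, 0.0, rectification=0.5)
        res = rectification_index(peak_response(up), peak_response(dn))
        assert res.ri == pytest.approx(0.5, rel=1e-6)
        assert res.classification == "inward"

    def test_rc_step_peak_and_steady_state(self):
        tr = sg.generate_rc_step(capacitance_pf=100.0, rs_mohm=10.0, rm_mohm=1000.0,
                                 dv_mv=10.0)
        # peak ~ dV/Rs = 1000 pA; steady state ~ dV/(Rs+Rm) = 9.9 pA
        assert tr.samples.max() == pytest.approx(1000.0, rel=0.05)
        t = tr.times
        ss = tr.samples[(t > 0.13) & (t < 0.15)].mean()
        assert ss == pytest.approx(10000.0 / 1010.0, rel=0.01)


class TestCohort:
    def test_cohort_shape(self, default_config):
        recs = sg.generate_cohort(8, default_config, sg.DrugEffect(0.5, 0.5, "NAS"),
                                  seed=1, render=False)
        assert len(recs) == 8
        for rec in recs:
            assert set(rec.conditions) == {"control", "NAS"}
            assert all(len(v) == 3 for v in rec.conditions.values())

    def test_cohort_determinism(self, default_config):
        a = sg.generate_cohort(3, default_config, seed=9, render=False)
        b = sg.generate_cohort(3, default_config, seed=9, render=False)
        for ra, rb in zip(a, b):
            for cond in ra.conditions:
                for (_, ta), (_, tb) in zip(ra.conditions[cond], rb.conditions[cond]):
                    assert np.array_equal(ta.event_times, tb.event_times)

    def test_null_effect_cohorts_exchangeable(self, default_config):
        """With unit effect scales the paired duration test is non-significant
        in >= 90% of replicates (type-I error control of the whole pipeline)."""
        eff = sg.DrugEffect(1.0, 1.0, label="sham")
        nonsig = 0
        R = 100
        for rep in range(R):
            recs = sg.generate_cohort(8, default_config, eff, seed=5000 + rep,
                                      render=False)
            ctrl, drug = [], []
            for rec in recs:
                vals = {}
                for cond, sweeps in rec.conditions.items():
                    trains = [EventTrain(t.event_times, t.event_amplitudes, "truth")
                              for _, t in sweeps]
                    resp = rm.sustained_response(trains, rec.burst_window,
                                                 rec.trace_duration)
                    vals[cond] = resp.duration
                ctrl.append(vals["control"])
                drug.append(vals["sham"])
            _, p = run_test("paired t", np.array(ctrl), np.array(drug))
            nonsig += p >= 0.05
        assert nonsig >= 0.9 * R


class TestCalibration:
    def test_preset_scales_within_unit_box(self):
        for drug, nucleus in sg.PUBLISHED_GROUP_MEANS:
            cfg, eff = sg.published_preset(drug, nucleus)
            assert 0 <= eff.rate_scale <= 1 and 0 <= eff.tau_scale <= 1
            assert cfg.elevation_amplitude > cfg.baseline_rate

    def test_stronger_published_effect_gives_smaller_elevation_mass(self):
        """The NAS effect is larger in PHN than INC: the drug-scaled elevation
        mass (relative to control) must be smaller for PHN."""
        def residual_mass(drug, nucleus):
            cfg, eff = sg.published_preset(drug, nucleus)
            tau_d = cfg.elevation_tau * eff.tau_scale
            mass_d = cfg.elevation_amplitude * eff.rate_scale * tau_d
            return mass_d / (cfg.elevation_amplitude * cfg.elevation_tau)

        assert residual_mass("NAS", "PHN") < residual_mass("NAS", "INC")
        assert residual_mass("APV", "INC") < residual_mass("APV", "PHN")
        assert residual_mass("FFA", "PHN") < residual_mass("FFA", "INC")
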