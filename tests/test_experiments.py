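import numpy as np
import pytest

from oxysim import (CCKExperiment, CalibrationError, PopulationSpec,
                    PulseTrainProtocol, calibrate_basal_rate,
                    load_population_table, run_pulse_protocol,
                    sample_population, simulate_cck_experiment,
                    simulate_population)
from oxysim.experiments import _lognormal, detection_error_pct


class TestCalibration:
    def test_zero_target_gives_zero_rate(self):
        res = calibrate_basal_rate(0.0)
        assert res.rate_hz == 0.0

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_basal_rate(-1.0)

    def test_unreachable_target_reports_bracket(self, spiking_params):
        with pytest.raises(CalibrationError, match="unreachable"):
            calibrate_basal_rate(500.0, spiking_params, bracket=(0.0, 50.0),
                                 run_duration=50.0, n_seeds=2)

    def test_spontaneous_rate_needs_published_input_rate(self,
                                                         spiking_params):
        """Calibrating to the 2.5 spikes/s spontaneous rate recovers a
        balanced PSP rate near the published 292 Hz."""
        res = calibrate_basal_rate(2.5, spiking_params, run_duration=400.0,
                                   n_seeds=4, master_seed=1)
        assert res.rate_hz == pytest.approx(292.0, rel=0.08)
        assert res.achieved_rate == pytest.approx(2.5, abs=0.08)


class TestPulseProtocol:
    def test_zero_pulses_release_nothing(self, secretion_params):
        proto = PulseTrainProtocol(frequency=13.0, n_pulses=0)
        assert run_pulse_protocol(proto, secretion_params).total_pg == 0.0

    def test_self_normalisation_near_unity(self, secretion_params):
        """S2/S1 at the reference frequency itself is ~1 after the rest
        interval lets the terminal recover."""
        proto = PulseTrainProtocol(frequency=12.0, n_pulses=600,
                                   normalize=True)
        res = run_pulse_protocol(proto, secretion_params)
        assert res.s2_over_s1 == pytest.approx(1.0, abs=0.03)

    def test_normalised_ratio_increases_with_frequency(self,
                                                       secretion_params):
        ratios = []
        for f in (4.0, 12.0, 30.0):
            proto = PulseTrainProtocol(frequency=f, n_pulses=600,
                                       normalize=True)
            ratios.append(run_pulse_protocol(proto,
                                             secretion_params).s2_over_s1)
        assert ratios[0] < ratios[1] < ratios[2]


class TestDetectionErrorCounting:
    def test_always_larger_challenge_is_error_free(self):
        basal = np.array([1.0, 2.0, 3.0])
        assert detection_error_pct(basal, basal + 0.1) == 0.0

    def test_ties_count_as_errors(self):
        basal = np.array([1.0, 2.0])
        assert detection_error_pct(basal, basal.copy()) == 100.0

    def test_mixed_outcomes(self):
        basal = np.array([1.0, 1.0, 1.0, 1.0])
        chall = np.array([2.0, 0.5, 2.0, 0.5])
        assert detection_error_pct(basal, chall) == 50.0


class TestCCKExperiment:
    def test_zero_dose_response_within_noise(self, spiking_params):
        exp = CCKExperiment(dose=0.0, n_runs=6, master_seed=3,
                            cck_start=120.0, duration=240.0,
                            basal_window=100.0, post_window=120.0,
                            cv_pre=20.0, cv_post=100.0)
        res = simulate_cck_experiment(exp, spiking_params)
        assert abs(res.summary["increment_5min"]) < 0.15

    def test_both_response_conventions_reported(self, spiking_params):
        exp = CCKExperiment(dose=20.0, n_runs=4, master_seed=1,
                            cck_start=120.0, duration=300.0,
                            basal_window=100.0, post_window=180.0,
                            cv_pre=20.0, cv_post=150.0)
        res = simulate_cck_experiment(exp, spiking_params)
        assert res.summary["increment_post_peak"] > \
            res.summary["increment_5min"] > 0.0


class TestPopulationSampling:
    def test_zero_sd_yields_identical_neurons(self):
        spec = PopulationSpec(rate_sd=0.0, cck_sd=0.0)
        pop = sample_population(spec, master_seed=9)
        assert np.allclose(pop["I_re_Hz"], 292.0)
        assert np.allclose(pop["k_CCK"], 20.0)

    def test_lognormal_matches_arithmetic_moments(self, rng):
        draws = _lognormal(292.0, 292.0, 100_000, rng)
        assert draws.mean() == pytest.approx(292.0, rel=0.02)
        assert draws.std() == pytest.approx(292.0, rel=0.05)

    def test_fixture_average_input_rate(self):
        table = load_population_table("ahp_random_rate")
        assert table["I_re_Hz"].mean() == pytest.approx(291.7, abs=0.05)
        assert len(table) == 23

    def test_fixture_scenarios_disjoint(self):
        with_ahp = load_population_table("ahp_random_rate_cck")
        without = load_population_table("noahp_random_rate_cck")
        assert with_ahp["ahp"].all()
        assert not without["ahp"].any()

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            load_population_table("nope")


class TestPopulationSimulation:
    def test_single_neuron_has_no_population_spread(self, spiking_params):
        pop = sample_population(PopulationSpec(n_neurons=1, rate_sd=0.0,
                                               cck_sd=0.0))
        res = simulate_population(pop, duration=60.0, master_seed=4)
        assert np.allclose(res.rate_sd, 0.0)

    def test_heterogeneity_raises_population_sd(self, spiking_params):
        """Log-normal input-rate spread raises the across-neuron SD of
        the firing rate well above the homogeneous value."""
        homog = load_population_table("ahp_fixed").iloc[:12]
        heterog = load_population_table("ahp_random_rate").iloc[:12]
        res_h = simulate_population(homog, duration=120.0, master_seed=5)
        res_x = simulate_population(heterog, duration=120.0, master_seed=5)
        assert res_x.summary["basal_rate_sd"] > \
            1.3 * res_h.summary["basal_rate_sd"]


class TestResponseDependencies:
    def test_rate_increment_stable_but_secretion_increment_grows(
            self, spiking_params, secretion_params):
        """The firing-rate response to a fixed CCK dose varies <35%
        between 1 and 7 spikes/s basal rates, while the secretion
        response grows with the basal rate."""
        out = {}
        for rate in (165.0, 895.0):  # ~1 and ~7 spikes/s
            exp = CCKExperiment(dose=20.0, basal_rate_hz=rate, n_runs=10,
                                master_seed=21, cck_start=350.0,
                                duration=650.0, basal_window=300.0)
            res = simulate_cck_experiment(exp, spiking_params,
                                          secretion_params=secretion_params)
            pk = int(res.summary["peak_time_s"])
            sec_inc = (res.secretion_bins[:, pk:pk + 25].mean()
                       - res.secretion_bins[:, 50:350].mean())
            out[rate] = (res.summary["increment_post_peak"], sec_inc)
        r_low, r_high = out[165.0][0], out[895.0][0]
        assert abs(r_low - r_high) / max(r_low, r_high) < 0.35
        assert out[895.0][1] > 2.0 * out[165.0][1]

    def test_error_rate_decreases_with_episode_duration(
            self, spiking_params, secretion_params):
        """Longer challenge episodes are easier to detect, with and
        without an AHP."""
        from oxysim import DetectionAssay, run_detection_assay

        for ahp in (True, False):
            assay = DetectionAssay(basal_rate_sps=3.0, increment_sps=1.0,
                                   episode_durations=(1.0, 10.0),
                                   total_duration=3000.0, n_runs=2,
                                   master_seed=17, with_ahp=ahp)
            res = run_detection_assay(assay, spiking_params,
                                      secretion_params)
            means = res.groupby("episode_duration_s")["error_pct"].mean()
            assert means[10.0] < means[1.0]


class TestSecretionSeparability:
    def test_6s_secretion_levels_separate_only_with_ahp(
            self, spiking_params, secretion_params):
        """With an AHP, 6-s-bin secretion at mean rates 1/4/7 spikes/s
        forms non-overlapping clouds (1st vs 99th percentiles of
        adjacent levels); without an AHP adjacent levels overlap."""
        from oxysim import calibrate_basal_rate, run_spiking
        from oxysim.secretion import run_secretion_flags

        def percentiles(with_ahp):
            sp = spiking_params if with_ahp else \
                spiking_params.replace(k_ahp=0.0)
            out = []
            for target in (1.0, 4.0, 7.0):
                cal = calibrate_basal_rate(target, sp, tolerance=0.1,
                                           run_duration=300.0, n_seeds=3,
                                           master_seed=31)
                p = sp.replace(i_re=cal.rate_hz, i_ri=cal.rate_hz)
                res = run_spiking(p, duration=2600.0, seed=[31, int(target)])
                s = run_secretion_flags(res.spike_flags, secretion_params).s
                per_bin = s[200_000:].reshape(-1, 6000).mean(axis=1)
                out.append(np.percentile(per_bin, [1, 99]))
            return out

        with_ahp = percentiles(True)
        assert with_ahp[0][1] < with_ahp[1][0]  # 1 vs 4 spikes/s
        assert with_ahp[1][1] < with_ahp[2][0]  # 4 vs 7 spikes/s
        without = percentiles(False)
        overlaps = [without[0][1] >= without[1][0],
                    without[1][1] >= without[2][0]]
        assert any(overlaps)
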