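import numpy as np
import pytest

from erfp.exceptions import DesignError, LayoutError, ParameterError
from erfp.synth import (
    BehaviorParams,
    SwayParams,
    TrialEventsSpec,
    make_study,
    ou_noise,
    simulate_behavior,
    simulate_sway,
)
from erfp.variability import sliding_sd


def make_trial_specs(n_trials=3, soa=100.0, rt=700.0, spacing=4500.0, load="n.a."):
    return [
        TrialEventsSpec(
            trial=i + 1, t0_ms=1000.0 + i * spacing, soa_ms=soa, rt_ms=rt, task_load=load
        )
        for i in range(n_trials)
    ]


class TestBehaviorParams:
    def test_invalid_values_rejected(self):
        with pytest.raises(ParameterError):
            BehaviorParams.experiment1(p_manual_error=1.5)
        with pytest.raises(ParameterError):
            BehaviorParams.experiment1(rt_noise_sigma_ms=-1)
        with pytest.raises(ParameterError):
            BehaviorParams.experiment1(soa_levels=(0, 1000))
        with pytest.raises(ParameterError):
            BehaviorParams(base_rt_ms={"n.a.": -5.0}, consolidation_ms={"n.a.": 0.0})

    def test_expected_rt_closed_form(self):
        p = BehaviorParams.experiment1()
        assert p.expected_rt(100) == 613 + 238
        assert p.expected_rt(1000) == 613


class TestSimulateBehavior:
    def test_deterministic_given_seed(self, tiny_behavior_params):
        a = simulate_behavior(tiny_behavior_params, seed=3)
        b = simulate_behavior(tiny_behavior_params, seed=3)
        assert a.equals(b)

    def test_no_bottleneck_no_soa_effect(self):
        p = BehaviorParams.experiment1(
            consolidation_ms={"n.a.": 0.0}, n_participants=8, n_blocks=2, trials_per_cell=10
        )
        t = simulate_behavior(p, seed=5)
        cell = t.groupby(["participant", "soa"])["rt_ms"].mean().unstack()
        effect = (cell[100] - cell[1000]).mean()
        se = (cell[100] - cell[1000]).sem()
        assert abs(effect) < 3 * se + 1.0

    def test_analytic_means_converge(self):
        # base 500, C 250 -> expected means 650 (SOA 100) and 500 (SOA 1000)
        p = BehaviorParams(
            base_rt_ms={"n.a.": 500.0},
            consolidation_ms={"n.a.": 250.0},
            n_participants=2,
            n_blocks=25,
            trials_per_cell=5,
        )
        t = simulate_behavior(p, seed=9)
        means = t.groupby("soa")["rt_ms"].mean()
        n_per = len(t) / 2
        se = np.sqrt(60**2 + 80**2) / np.sqrt(n_per)
        assert means[100] == pytest.approx(650.0, abs=3 * se)
        assert means[1000] == pytest.approx(500.0, abs=3 * se)

    def test_object_never_repeats(self, tiny_behavior_params):
        t = simulate_behavior(tiny_behavior_params, seed=1)
        for (_, _), sub in t.groupby(["participant", "block"]):
            assert (sub["object"].to_numpy()[1:] != sub["object"].to_numpy()[:-1]).all()

    def test_no_vocal_errors_in_ignore_trials(self):
        p = BehaviorParams.experiment2(
            n_participants=2, n_blocks=1, trials_per_cell=5, p_vocal_error=0.5
        )
        t = simulate_behavior(p, seed=2)
        assert not t.loc[t["task_load"] == "ignore", "vocal_error"].any()
        assert t.loc[t["task_load"] == "report", "vocal_error"].any()


class TestSimulateSway:
    def test_bit_identical_given_seed(self, sway_params):
        specs = make_trial_specs(2)
        a = simulate_sway(specs, sway_params, seed=4)
        b = simulate_sway(specs, sway_params, seed=4)
        assert a.samples.equals(b.samples)
        assert a.events == b.events

    def test_zero_rate_equals_pure_baseline_noise(self):
        params = SwayParams(impulse_rate_hz=0.0)
        rec = simulate_sway(make_trial_specs(2), params, seed=17)
        rng = np.random.default_rng(17)
        expected_mx = ou_noise(
            rec.n_samples, params.baseline_sigma, params.baseline_tau_ms, 1000.0, rng
        )
        expected_my = ou_noise(
            rec.n_samples, params.baseline_sigma, params.baseline_tau_ms, 1000.0, rng
        )
        np.testing.assert_array_equal(rec.channel("Mx"), expected_mx)
        np.testing.assert_array_equal(rec.channel("My"), expected_my)

    def test_suppression_vs_rebound_ordering(self):
        # rate 0 during suppression, doubled after the response: sliding SD
        # must be lower in the suppression window for every simulated run
        params = SwayParams(
            impulse_rate_hz=3.0,
            phase_multipliers={
                "pre_fixation": 1.0,
                "fixation_to_target": 1.0,
                "suppression": 0.0,
                "rebound": 2.0,
            },
        )
        for seed in range(5):
            specs = make_trial_specs(6, soa=100.0, rt=500.0)
            rec = simulate_sway(specs, params, seed=seed)
            sd = sliding_sd(rec.channel("Mx"), 1000.0)
            t = sd.times_ms
            supp = rebound = 0.0
            for spec in specs:
                m_supp = (t >= spec.visual_ms + 100) & (t <= spec.response_ms - 100)
                m_reb = (t >= spec.response_ms + 100) & (t <= spec.t0_ms + 2900)
                supp += sd.values[m_supp].mean()
                rebound += sd.values[m_reb].mean()
            assert supp < rebound

    def test_mean_variability_increases_with_rate(self):
        # Monte-Carlo over 20 seeds: average sliding SD strictly increasing in λ0
        means = []
        for lam in (0.0, 2.0, 6.0):
            acc = 0.0
            for seed in range(20):
                rec = simulate_sway(
                    make_trial_specs(1), SwayParams(impulse_rate_hz=lam), seed=seed
                )
                acc += sliding_sd(rec.channel("My"), 1000.0).values.mean()
            means.append(acc / 20)
        assert means[0] < means[1] < means[2]

    def test_overlapping_trials_rejected(self, sway_params):
        specs = make_trial_specs(2, spacing=2000.0)
        with pytest.raises(LayoutError, match="overlap"):
            simulate_sway(specs, sway_params, seed=0)

    def test_event_markers_embedded(self, sway_params):
        specs = make_trial_specs(2, soa=1000.0, rt=650.0)
        rec = simulate_sway(specs, sway_params, seed=0)
        codes = [(e.trial, e.code) for e in rec.events]
        assert ((1, "CUE_ONSET") in codes) and ((2, "MANUAL_RESPONSE") in codes)
        cue = next(e for e in rec.events if e.trial == 1 and e.code == "CUE_ONSET")
        aud = next(e for e in rec.events if e.trial == 1 and e.code == "AUDITORY_TARGET")
        assert aud.sample_index - cue.sample_index == 2000  # 1,000 + SOA ms at 1 kHz

    def test_too_short_soa_rejected(self):
        with pytest.raises(ParameterError, match="SOA"):
            TrialEventsSpec(trial=1, t0_ms=1000, soa_ms=40.0, rt_ms=500)


class TestMakeStudy:
    def test_cell_counts_per_block(self):
        p = BehaviorParams.experiment1(n_participants=1)
        _, trials = make_study(1, behavior=p, sway=SwayParams(), seed=0)
        per_block = trials.groupby(["block", "soa", "tone", "orientation"]).size()
        assert (per_block == 10).all()  # each cell 10x per block

    def test_experiment2_has_task_load_factor(self):
        p = BehaviorParams.experiment2(n_participants=1, n_blocks=1)
        _, trials = make_study(2, behavior=p, sway=SwayParams(), seed=0)
        assert set(trials["task_load"]) == {"report", "ignore"}

    def test_single_participant_single_block_row_count(self):
        p = BehaviorParams.experiment1(n_participants=1, n_blocks=1, trials_per_cell=5)
        recs, trials = make_study(1, behavior=p, sway=SwayParams(), seed=0)
        assert len(trials) == 40  # 8 cells x 5
        assert list(recs) == [1]
        assert len(recs[1].events) == 4 * 40

    def test_indivisible_counterbalancing_rejected(self):
        p = BehaviorParams.experiment1(n_participants=1, n_blocks=1, trials_per_cell=2)
        with pytest.raises(DesignError, match="divisible"):
            make_study(1, behavior=p, sway=SwayParams(), seed=0)
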