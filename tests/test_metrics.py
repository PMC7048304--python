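import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluttersim import (InsufficientSpikesError, ParameterError, RateResponse,
                        adaptation_strength, classify_neuron,
                        make_pulse_train, median_spike_time, per_event_counts,
                        psth, rate_response_significant, rayleigh_statistic,
                        vector_strength)

WINDOW = (0.0, 10_000.0)


class TestVectorStrength:
    def test_perfect_locking(self):
        spikes = np.arange(10) * 25.0
        vs, n = vector_strength(spikes, 25.0, WINDOW)
        assert vs == pytest.approx(1.0) and n == 10

    def test_antiphase_cancellation(self):
        spikes = np.sort(np.concatenate([np.arange(10) * 25.0,
                                         np.arange(10) * 25.0 + 12.5]))
        vs, _ = vector_strength(spikes, 25.0, WINDOW)
        assert vs == pytest.approx(0.0, abs=1e-12)

    def test_uniform_spikes_give_small_vs(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0.0, 10_000.0, 10_000))
        vs, _ = vector_strength(spikes, 25.0, WINDOW)
        assert vs < 0.05  # E[VS] ~ sqrt(pi/4N) ~ 0.009

    def test_no_spikes_is_an_error_not_zero(self):
        with pytest.raises(InsufficientSpikesError):
            vector_strength(np.array([]), 25.0, WINDOW)

    @given(shift=st.floats(-1000.0, 1000.0))
    @settings(derandomize=True, max_examples=30)
    def test_translation_invariance(self, shift):
        """VS is a resultant length: uniform time shifts only rotate phases."""
        rng = np.random.default_rng(7)
        spikes = np.sort(rng.uniform(1000.0, 9000.0, 200))
        vs0, _ = vector_strength(spikes, 25.0, WINDOW)
        vs1, _ = vector_strength(spikes + shift, 25.0,
                                 (WINDOW[0] + shift, WINDOW[1] + shift))
        assert vs1 == pytest.approx(vs0, rel=1e-9)

    def test_matches_circular_statistics_oracle(self):
        """VS equals |mean resultant| of the phase distribution."""
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.exponential(40.0, 500).cumsum())
        spikes = spikes[spikes < WINDOW[1]]
        vs, _ = vector_strength(spikes, 25.0, WINDOW)
        oracle = np.abs(np.mean(np.exp(2j * np.pi * spikes / 25.0)))
        assert vs == pytest.approx(oracle, abs=1e-12)


class TestRayleigh:
    @pytest.mark.parametrize("vs, n, expected", [
        (1.0, 10, 20.0),
        (0.0, 1000, 0.0),
        (0.1, 690, 13.8),
    ])
    def test_formula(self, vs, n, expected):
        assert rayleigh_statistic(vs, n) == pytest.approx(expected)


class TestRateResponseSignificance:
    @pytest.mark.parametrize("driven, sm, sd, sps, expected", [
        (40.0, 4.0, 1.0, 20.0, True),
        (5.0, 4.0, 1.0, 3.0, False),     # below mean + 2 sd
        (50.0, 4.0, 1.0, 0.8, False),    # too few spikes per stimulus
        (5.0, 4.0, 0.0, 3.0, True),      # zero-variance spont: threshold=mean
    ])
    def test_decision_rule(self, driven, sm, sd, sps, expected):
        assert rate_response_significant(driven, sm, sd, sps) is expected


def _responses(mean_rates, vs=0.9, rs=100.0, significant=True):
    return [RateResponse(rate_hz=r, mean_rate=m, sem_rate=0.0,
                         spikes_per_stim=m / 2.0, vs=vs, rs=rs,
                         significant=significant)
            for r, m in zip(range(8, 49, 4), mean_rates)]


class TestClassification:
    def test_increasing_rates_with_synchrony_is_sync_plus(self):
        cls = classify_neuron(_responses(np.linspace(10, 60, 11)), 4.0, 1.0)
        assert cls.label == "Sync+"
        assert cls.spearman_rho == pytest.approx(1.0)

    def test_decreasing_rates_with_synchrony_is_sync_minus(self):
        cls = classify_neuron(_responses(np.linspace(60, 10, 11)), 4.0, 1.0)
        assert cls.label == "Sync-"
        assert cls.spearman_rho == pytest.approx(-1.0)

    def test_weak_correlation_is_nonmonotonic(self):
        rates = np.array([20, 25, 22, 28, 24, 30, 26, 23, 27, 21, 29.0])
        cls = classify_neuron(_responses(rates), 4.0, 1.0)
        assert cls.label == "SyncNM"
        assert abs(cls.spearman_rho) < 0.8

    def test_no_synchrony_is_nsync(self):
        cls = classify_neuron(
            _responses(np.linspace(10, 60, 11), vs=0.05, rs=5.0), 4.0, 1.0)
        assert cls.label == "nSync+"

    def test_synchrony_needs_three_consecutive_rates(self):
        responses = _responses(np.linspace(10, 60, 11), vs=0.05, rs=5.0)
        # two isolated pairs of synchronised rates do not qualify
        for i in (0, 1, 5, 6):
            r = responses[i]
            responses[i] = RateResponse(r.rate_hz, r.mean_rate, 0.0,
                                        r.spikes_per_stim, 0.9, 100.0, True)
        assert classify_neuron(responses, 4.0, 1.0).label == "nSync+"

    def test_insignificant_rate_response_is_nonresponsive(self):
        cls = classify_neuron(
            _responses(np.linspace(4, 5, 11), significant=False), 4.0, 1.0)
        assert cls.label == "non-responsive"

    def test_missing_rates_rejected(self):
        with pytest.raises(ParameterError, match="48"):
            classify_neuron(_responses(np.linspace(10, 60, 11))[:-1], 4.0,
                            1.0)

    def test_rank_invariance_of_monotone_profiles(self):
        """Any strictly increasing profile has rho = 1 regardless of spacing."""
        warped = 10 + np.cumsum([1, 9, 1, 14, 2, 1, 30, 2, 1, 1, 5.0])
        cls = classify_neuron(_responses(warped), 4.0, 1.0)
        assert cls.spearman_rho == pytest.approx(1.0)

    def test_trial_order_does_not_matter(self):
        """Classification depends on summary stats only, not response order."""
        resp = _responses(np.linspace(10, 60, 11))
        shuffled = [resp[i] for i in [5, 0, 10, 2, 8, 1, 9, 3, 7, 4, 6]]
        assert classify_neuron(shuffled, 4.0, 1.0).label == \
            classify_neuron(resp, 4.0, 1.0).label


class TestPerEventCounts:
    def test_one_spike_per_event(self):
        train = make_pulse_train(8.0, 500.0)
        spikes = train.events_trial_ms() + 12.0
        np.testing.assert_array_equal(
            per_event_counts(spikes, train, latency_ms=10.0), np.ones(4))

    def test_empty_train_gives_zeros(self):
        train = make_pulse_train(8.0, 500.0)
        np.testing.assert_array_equal(
            per_event_counts(np.array([]), train), np.zeros(4))


class TestAdaptationStrength:
    def test_equal_rates_no_adaptation(self):
        assert adaptation_strength(np.array([2.0, 2.0])) == 0.0

    def test_halved_rate_is_half(self):
        assert adaptation_strength(np.array([2.0, 1.0])) == pytest.approx(0.5)

    def test_facilitation_is_negative(self):
        assert adaptation_strength(np.array([1.0, 1.5])) == pytest.approx(-0.5)

    def test_zero_reference_signalled(self):
        with pytest.raises(InsufficientSpikesError):
            adaptation_strength(np.array([0.0, 1.0]))


class TestPSTH:
    def test_single_spike_unit_mass(self):
        out = psth([np.array([100.0])], sigma_ms=10.0, t_max_ms=200.0,
                   dt_ms=0.5)
        mass = np.trapezoid(out.rate, out.time_ms) / 1000.0
        assert mass == pytest.approx(1.0, rel=1e-3)
        assert out.time_ms[np.argmax(out.rate)] == pytest.approx(100.0,
                                                                 abs=0.5)

    def test_empty_trains_zero(self):
        out = psth([np.array([]), np.array([])], t_max_ms=100.0)
        assert np.all(out.rate == 0.0)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        lam = 20.0  # spk/s
        trains = [np.sort(rng.uniform(0, 5000.0, rng.poisson(lam * 5.0)))
                  for _ in range(50)]
        out = psth(trains, sigma_ms=10.0, t_max_ms=5000.0, dt_ms=1.0)
        interior = (out.time_ms > 100) & (out.time_ms < 4900)
        assert np.mean(out.rate[interior]) == pytest.approx(lam, rel=0.05)

    def test_mass_conservation_interior_spikes(self):
        rng = np.random.default_rng(1)
        trains = [np.sort(rng.uniform(100.0, 900.0, 30)) for _ in range(5)]
        out = psth(trains, sigma_ms=10.0, t_max_ms=1000.0, dt_ms=0.5)
        mass = np.trapezoid(out.rate, out.time_ms) / 1000.0
        assert mass == pytest.approx(30.0, rel=0.01)


class TestMedianSpikeTime:
    def test_simple_median(self):
        assert median_spike_time(np.array([10.0, 20.0, 30.0]),
                                 (0.0, 200.0)) == 20.0

    def test_relative_to_onset_and_windowed(self):
        spikes = np.array([400.0, 510.0, 520.0, 530.0, 900.0])
        assert median_spike_time(spikes, (500.0, 700.0)) == 20.0

    def test_onset_burst_median_is_early(self):
        spikes = 500.0 + np.array([5.0, 10.0, 15.0, 20.0, 40.0])
        assert median_spike_time(spikes, (500.0, 700.0)) < 50.0

    def test_no_spikes_signalled(self):
        with pytest.raises(InsufficientSpikesError):
            median_spike_time(np.array([100.0]), (500.0, 700.0))
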