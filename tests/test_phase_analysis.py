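"""Beta-band phase extraction, return maps, region partition, transition rates."""

import itertools

import numpy as np
import pytest

from stngpe.phase_analysis import (
    MatchCriterion,
    PhaseSeries,
    bandpass_beta,
    build_return_map,
    instantaneous_phase,
    locked_state_center,
    matches_experiment,
    min_signal_length,
    partition_regions,
    transition_rates,
    wrap_phase,
)

FS = 1000.0  # Hz


def tone(freq, dur_s=10.0, fs=FS, phase=0.0):
    t = np.arange(int(dur_s * fs)) / fs
    return t, np.sin(2 * np.pi * freq * t + phase)


class TestBandpass:
    def test_passband_tone_preserved_without_phase_lag(self):
        t, x = tone(20.0)
        y = bandpass_beta(x, FS)
        core = slice(2000, -2000)
        amp = np.max(np.abs(y[core]))
        assert 0.9 <= amp <= 1.1
        # zero-phase filtering: peak correlation at zero lag
        xc = np.correlate(y[core], x[core], "full")
        lag = np.argmax(xc) - (len(y[core]) - 1)
        assert abs(lag) <= 1

    def test_stopband_tone_suppressed(self):
        t, x = tone(2.0)
        y = bandpass_beta(x, FS)
        assert np.max(np.abs(y[2000:-2000])) < 0.1

    def test_constant_signal_maps_to_zero(self):
        y = bandpass_beta(np.full(5000, 3.7), FS)
        assert np.max(np.abs(y)) < 1e-9

    def test_short_signal_rejected_with_minimum(self):
        n = min_signal_length(FS) - 1
        with pytest.raises(ValueError, match="need >= "):
            bandpass_beta(np.zeros(n), FS)


class TestInstantaneousPhase:
    def test_pure_tone_phase_slope(self):
        t, x = tone(20.0)
        ps = instantaneous_phase(bandpass_beta(x, FS), time=t * 1000.0)
        u = ps.unwrapped()[2000:-2000]
        slope = np.polyfit(t[2000:-2000], u, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 20.0, rel=0.01)

    def test_amplitude_invariance(self):
        _, x = tone(15.0)
        a = instantaneous_phase(x).phase
        b = instantaneous_phase(4.2 * x).phase
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_negation_shifts_phase_by_pi(self):
        _, x = tone(15.0)
        a = instantaneous_phase(x).phase[1000:-1000]
        b = instantaneous_phase(-x).phase[1000:-1000]
        d = np.abs(wrap_phase(a - b))
        np.testing.assert_allclose(d, np.pi, atol=1e-6)

    def test_phases_wrapped_to_half_open_interval(self):
        _, x = tone(23.0)
        p = instantaneous_phase(x).phase
        assert np.all(p > -np.pi) and np.all(p <= np.pi)


def phase_series(freq, dur_s=10.0, offset=0.0, label=""):
    t = np.arange(int(dur_s * FS)) / FS
    phi = wrap_phase(2 * np.pi * freq * t + offset)
    return PhaseSeries(time=t * 1000.0, phase=phi, label=label)


class TestReturnMap:
    def test_identical_phases_record_checkpoint_value(self):
        lfp = phase_series(20.0)
        rm = build_return_map(lfp, lfp, checkpoint=0.0)
        np.testing.assert_allclose(rm.values, 0.0, atol=1e-9)

    def test_constant_lag_recorded_exactly(self):
        delta = 0.8
        lfp = phase_series(20.0)
        spk = phase_series(20.0, offset=delta)
        rm = build_return_map(lfp, spk)
        np.testing.assert_allclose(rm.values, delta, atol=1e-6)

    def test_crossing_count_matches_cycle_count(self):
        rm = build_return_map(phase_series(20.0), phase_series(20.0, offset=0.3))
        assert abs(rm.n - 200) <= 1

    def test_mismatched_grids_rejected(self):
        a = phase_series(20.0, dur_s=1.0)
        b = phase_series(20.0, dur_s=2.0)
        with pytest.raises(ValueError, match="time grid"):
            build_return_map(a, b)

    def test_window_too_short_rejected(self):
        a = phase_series(20.0, dur_s=0.04)
        with pytest.raises(ValueError, match="crossings"):
            build_return_map(a, a)

    def test_checkpoint_invariance_for_locked_signals(self):
        """For strongly locked signals the rates barely move under
        checkpoint shifts of +-pi/4."""
        rng = np.random.default_rng(0)
        t = np.arange(int(30.0 * FS)) / FS
        common = 2 * np.pi * 20.0 * t + 0.3 * np.cumsum(rng.standard_normal(t.size)) / np.sqrt(FS)
        lfp = PhaseSeries(time=t * 1000.0, phase=wrap_phase(common))
        spk = PhaseSeries(time=t * 1000.0,
                          phase=wrap_phase(common + 0.5 +
                                           0.05 * rng.standard_normal(t.size)))
        base = transition_rates(partition_regions(build_return_map(lfp, spk, 0.0))[0])
        for cp in (-np.pi / 4, np.pi / 4):
            rm = build_return_map(lfp, spk, cp)
            rates = transition_rates(partition_regions(rm)[0])
            diff = np.abs(rates.rates - base.rates)
            assert np.nanmax(diff) < 0.02


class TestPartitionRegions:
    def _map(self, values):
        from stngpe.phase_analysis import ReturnMapSeries
        values = np.asarray(values, dtype=float)
        return ReturnMapSeries(checkpoint=0.0, values=values,
                               crossing_times=50.0 * np.arange(values.size))

    def test_tight_cluster_fills_synchronization_region(self, rng):
        vals = 1.1 + 0.1 * (rng.uniform(-1, 1, 400))
        labels, center = partition_regions(self._map(vals))
        assert np.all(labels == 1)
        assert abs(center - 1.1) < 0.05

    def test_uniform_phases_occupy_each_region_quarterly(self):
        rng = np.random.default_rng(99)
        vals = rng.uniform(-np.pi, np.pi, 10_000)
        labels, _ = partition_regions(self._map(vals))
        for k in (1, 2, 3, 4):
            assert np.mean(labels == k) == pytest.approx(0.25, abs=0.02)

    def test_antiphase_points_fall_in_region_three(self, rng):
        center_vals = 0.4 + 0.05 * rng.standard_normal(50)
        anti = wrap_phase(center_vals + np.pi)
        labels, center = partition_regions(self._map(np.concatenate([center_vals,
                                                                     anti])))
        # cluster splits evenly; the antiphase half sits in region 3
        anti_labels = labels[50:]
        assert np.all(anti_labels == 3) or np.all(labels[:50] == 3)

    def test_uniform_fallback_center_is_finite(self):
        # perfectly balanced four-point configuration: resultant ~ 0
        vals = np.array([0.0, np.pi / 2, np.pi, -np.pi / 2] * 25)
        c = locked_state_center(vals)
        assert -np.pi < c <= np.pi


class TestTransitionRates:
    def test_single_region_never_leaves(self):
        r = transition_rates(np.ones(10, dtype=int))
        assert r.rates[0] == 0.0
        assert np.all(np.isnan(r.rates[1:]))

    def test_alternating_labels_always_leave(self):
        r = transition_rates(np.array([1, 2] * 5))
        assert r.rates[0] == 1.0
        # the final point (region 2) cannot leave but still counts
        assert r.rates[1] == pytest.approx(4 / 5)

    def test_hand_counted_example(self):
        r = transition_rates(np.array([1, 1, 2, 3, 1, 1, 1, 2]))
        assert r.rates[0] == pytest.approx(2 / 5)
        assert r.rates[1] == pytest.approx(1 / 2)
        assert r.rates[2] == pytest.approx(1.0)
        assert np.isnan(r.rates[3])

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            transition_rates(np.array([2]))

    def test_exhaustive_agreement_with_brute_force_oracle(self):
        """Equivalence with a direct per-point count on all label sequences
        of length <= 8 over the four symbols (downsampled above length 6)."""
        def oracle(seq):
            occ = {k: 0 for k in (1, 2, 3, 4)}
            lea = {k: 0 for k in (1, 2, 3, 4)}
            for i, lab in enumerate(seq):
                occ[lab] += 1
                if i + 1 < len(seq) and seq[i + 1] != lab:
                    lea[lab] += 1
            return [lea[k] / occ[k] if occ[k] else np.nan for k in (1, 2, 3, 4)]

        rng = np.random.default_rng(0)
        seqs = []
        for n in (2, 3, 4, 5, 6):
            seqs.extend(itertools.product((1, 2, 3, 4), repeat=n))
        for n in (7, 8):
            seqs.extend(tuple(rng.integers(1, 5, n)) for _ in range(2000))
        for seq in seqs:
            got = transition_rates(np.array(seq)).rates
            np.testing.assert_allclose(got, oracle(seq), equal_nan=True)


class TestMatchCriterion:
    def _rates(self, values):
        from stngpe.phase_analysis import TransitionRates
        values = np.asarray(values, dtype=float)
        return TransitionRates(occupancy=np.full(4, 10), leaves=np.zeros(4),
                               rates=values)

    def test_exact_reference_matches(self):
        crit = MatchCriterion()
        assert matches_experiment(self._rates(crit.reference_rates), crit)

    def test_boundary_at_k_sd_is_inclusive(self):
        crit = MatchCriterion()
        vals = crit.reference_rates.copy()
        vals[2] += 0.7 * crit.reference_sds[2]
        assert matches_experiment(self._rates(vals), crit)

    def test_beyond_k_sd_fails(self):
        crit = MatchCriterion()
        vals = crit.reference_rates.copy()
        vals[2] += 0.8 * crit.reference_sds[2]
        assert not matches_experiment(self._rates(vals), crit)

    def test_missing_rate_fails(self):
        crit = MatchCriterion()
        vals = crit.reference_rates.copy()
        vals[3] = np.nan
        assert not matches_experiment(self._rates(vals), crit)

    def test_invalid_criterion_rejected(self):
        with pytest.raises(ValueError):
            MatchCriterion(reference_sds=np.array([0.1, 0.1, 0.0, 0.1]))


class TestDesynchronizedNull:
    def test_independent_signals_spread_over_regions_with_high_rates(self):
        """Two independent filtered-noise phases: ~25% occupancy in the
        synchronization region and high transition rates."""
        rng = np.random.default_rng(42)
        t = np.arange(int(60.0 * FS)) / FS
        a = bandpass_beta(rng.standard_normal(t.size), FS)
        b = bandpass_beta(rng.standard_normal(t.size), FS)
        pa = instantaneous_phase(a, time=t * 1000.0)
        pb = instantaneous_phase(b, time=t * 1000.0)
        rm = build_return_map(pa, pb)
        labels, _ = partition_regions(rm)
        rates = transition_rates(labels)
        assert np.mean(labels == 1) == pytest.approx(0.25, abs=0.10)
        assert np.nanmin(rates.rates) > 0.5
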