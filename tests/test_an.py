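import numpy as np
import pytest
from hypothesis import given, strategies as st

from bushylso.an import (ANParams, MissingPeripheryError, RateLevel,
                         an_intensity, kappa_from_vs, periphery_adapter,
                         sample_an_train, silence, vs_from_kappa)
from bushylso.bushy import run_gbc
from bushylso.metrics import vector_strength
from bushylso.spikes import SpikeTrain
from bushylso.stimuli import make_stimulus


class TestVonMisesSynchrony:
    def test_zero_kappa_is_uniform(self):
        assert vs_from_kappa(0.0) == 0.0

    def test_large_kappa_approaches_point_mass(self):
        assert vs_from_kappa(1e4) > 0.9999

    def test_kappa_two_matches_quadrature(self):
        # independent oracle: trapezoid integration of the cos-weighted
        # von Mises density over one cycle
        kappa = 2.0
        phi = np.linspace(-np.pi, np.pi, 20001)
        dens = np.exp(kappa * np.cos(phi))
        expected = np.trapezoid(np.cos(phi) * dens, phi) / np.trapezoid(dens, phi)
        assert vs_from_kappa(kappa) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("bad", [-1.0, np.inf, np.nan])
    def test_invalid_kappa_rejected(self, bad):
        with pytest.raises(ValueError):
            vs_from_kappa(bad)

    @given(st.floats(min_value=0.0, max_value=0.99))
    def test_inversion_round_trip(self, vs):
        assert vs_from_kappa(kappa_from_vs(vs)) == pytest.approx(vs, abs=1e-9)

    def test_near_degenerate_target_is_large_but_finite(self):
        kappa = kappa_from_vs(0.999999)
        assert np.isfinite(kappa) and kappa > 1e3

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            kappa_from_vs(1.0)

    def test_monotone_in_kappa(self):
        ks = np.linspace(0, 20, 50)
        vals = [vs_from_kappa(k) for k in ks]
        assert np.all(np.diff(vals) > 0)


class TestIntensity:
    def test_onset_ramp_starts_at_spont(self, an_params):
        spec = make_stimulus("pure", freq=7000)
        assert an_intensity(spec, an_params, 0.0) == an_params.spont_rate

    def test_plateau_flat_without_synchrony(self, an_params):
        # 7 kHz is above the fine-structure cutoff: kappa = 0
        spec = make_stimulus("pure", freq=7000, duration=100.0,
                             analysis_window=(10.0, 100.0))
        t = np.linspace(40.0, 60.0, 50)
        lam = an_intensity(spec, an_params, t)
        flat = lam / an_params.onset_adapt.factor(t)  # remove onset decay
        assert np.ptp(flat) / flat.mean() < 1e-6

    def test_cycle_mean_equals_rate_level_function(self, an_params):
        # numeric integration oracle over one envelope cycle, late in the
        # stimulus (onset adaptation decayed, no spontaneous-floor clipping)
        spec = make_stimulus("am", mod_freq=200, level=55.0)
        period = 1000.0 / spec.mod_freq
        t0 = 400.0 - period
        t = np.linspace(t0, 400.0, 4001)
        lam = an_intensity(spec, an_params, t)
        onset = an_params.onset_adapt.factor(t).mean()
        driven = an_params.rate_level("am").driven(55.0)
        cycle_mean = np.trapezoid(lam, t) / period
        assert cycle_mean == pytest.approx(driven * onset, rel=1e-3)

    def test_out_of_range_time_rejected(self, an_params):
        spec = make_stimulus("pure")
        with pytest.raises(ValueError):
            an_intensity(spec, an_params, 26.0)
        with pytest.raises(ValueError):
            an_intensity(spec, an_params, -1.0)

    def test_kappa_zero_above_cutoff(self, an_params):
        prof = an_params.sync_profile
        assert prof.vector_strength("pure", 6000.0, 70.0) == 0.0
        assert prof.vector_strength("am", 2000.0, 35.0) == 0.0


class TestSampling:
    def test_equal_seeds_identical(self, an_params):
        spec = make_stimulus("am", mod_freq=300)
        a = sample_an_train(spec, an_params, 7)
        b = sample_an_train(spec, an_params, 7)
        assert np.array_equal(a.times, b.times)
        c = sample_an_train(spec, an_params, 8)
        assert not np.array_equal(a.times, c.times)

    def test_spontaneous_rate_and_dead_time(self, spont_trains_20):
        pooled_n = sum(len(tr) for tr in spont_trains_20)
        total_s = 20.0 * len(spont_trains_20)
        rate = pooled_n / total_s
        sem = np.sqrt(pooled_n) / total_s
        assert rate == pytest.approx(70.0, abs=max(3 * sem, 1.0))
        assert min(tr.min_isi() for tr in spont_trains_20) >= 0.45

    def test_zero_intensity_gives_empty_train(self):
        params = ANParams(spont_rate=0.0)
        spec = silence(1000.0)
        assert len(sample_an_train(spec, params, 3)) == 0

    @pytest.mark.parametrize("level,kind,freq", [
        (70.0, "pure", 7000.0),   # saturated driven rate, no synchrony
        (20.0, "pure", 7000.0),   # mid-slope of the rate-level function
    ])
    def test_sustained_rate_tracks_rate_level(self, an_params, level, kind,
                                              freq):
        spec = make_stimulus(kind, freq=freq, level=level, duration=2000.0)
        lo, hi = spec.analysis_window
        n = 0
        trials = 8
        for k in range(trials):
            tr = sample_an_train(spec, an_params, (11, k))
            t = tr.times
            n += int(((t >= lo) & (t <= hi)).sum())
        rate = 1000.0 * n / ((hi - lo) * trials)
        # compare against the nominal sustained mean (includes the slow
        # onset-adaptation tail inside the window)
        grid = np.linspace(lo, hi, 4001)
        nominal = an_intensity(spec, an_params, grid).mean()
        sem = np.sqrt(max(n, 1)) / ((hi - lo) * trials) * 1000.0
        assert rate == pytest.approx(nominal, rel=0.02 + 3 * sem / nominal)

    def test_realized_vs_matches_kappa_at_low_rate(self):
        # at low rates the refractory interaction is negligible, so the
        # realized VS of the thinned process should match the von Mises
        # target; use a floor-free parameter set so the spontaneous floor
        # does not clip the envelope trough
        params = ANParams(spont_rate=0.0, rate_level_am=RateLevel(sat_rate=80.0))
        spec = make_stimulus("am", mod_freq=100, level=35.0)
        lo, hi = spec.analysis_window
        pooled = []
        for k in range(40):
            t = sample_an_train(spec, params, (12, k)).times
            pooled.append(t[(t >= lo) & (t <= hi)])
        pooled = np.concatenate(pooled)
        target = params.sync_profile.vector_strength("am", 100.0, 35.0)
        measured = vector_strength(pooled, 100.0)
        se = 1.0 / np.sqrt(pooled.size)
        assert measured == pytest.approx(target, abs=0.03 + 3 * se)


class TestPeripheryAdapter:
    def test_missing_adapter_is_informative(self):
        spec = make_stimulus("pure")
        with pytest.raises(MissingPeripheryError, match="optional"):
            periphery_adapter("nonexistent-model", spec)

    def test_unsorted_times_normalized(self):
        spec = make_stimulus("pure")
        train = periphery_adapter(lambda s: [5.0, 1.0, 3.0], spec)
        assert np.array_equal(train.times, [1.0, 3.0, 5.0])

    def test_adapter_train_feeds_bushy_stage(self, an_params):
        # type-level substitution: adapter output is a SpikeTrain usable
        # exactly like surrogate trains downstream
        spec = make_stimulus("pure", duration=50.0,
                             analysis_window=(10.0, 50.0))
        rng = np.random.default_rng(0)
        trains = [periphery_adapter(
            lambda s: np.sort(rng.uniform(0, s.duration, 40)), spec)
            for _ in range(20)]
        out = run_gbc(trains)
        assert isinstance(out, SpikeTrain)
        assert out.duration == spec.duration
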