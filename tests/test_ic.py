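"""Multi-unit spike detection, neurometrics, tonotopy and phase locking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0, i1
from scipy.stats import norm

from chrophys import ic, synth
from chrophys.datatypes import MEARecording
from chrophys.synth.mea import RateLevelSigmoid

from conftest import match_fraction


def noise_recording(seed=0, n_channels=4, dur_ms=1200.0, noise_sd=5.0):
    rng = np.random.default_rng(seed)
    fs = 32.0
    data = rng.normal(0, noise_sd, size=(n_channels, int(dur_ms * fs)))
    events = pd.DataFrame(
        [
            dict(
                time_ms=t,
                kind="blank",
                intensity=np.nan,
                rep=k,
                train_dur_ms=np.nan,
                pulse_rate_hz=np.nan,
                pulse_width_ms=1.0,
            )
            for k, t in enumerate(np.arange(150.0, dur_ms - 50.0, 200.0))
        ]
    )
    return MEARecording(
        data=data, fs=fs, electrode_depths=50.0 * np.arange(n_channels), events=events
    )


class TestDetectSpikes:
    def test_false_positive_rate_on_pure_noise(self):
        """Monte-Carlo bound: the effective ~3.5-sigma threshold plus dead
        time keeps noise crossings below ~10/s per channel."""
        rec = noise_recording(seed=0, dur_ms=2000.0)
        sp = ic.detect_spikes(rec)
        for st_ in sp.spike_times:
            assert st_.size / 2.0 < 10.0

    def test_planted_spikes_recovered(self, pulse_mea_recording):
        _, rec = pulse_mea_recording
        sp = ic.detect_spikes(rec)
        tol = 2.0 / rec.fs
        for ch in range(rec.n_channels):
            truth = rec.truth["spike_times"][ch]
            if truth.size < 20:
                continue
            assert match_fraction(truth, sp.spike_times[ch], tol) >= 0.95

    def test_common_mode_artefact_cancelled_by_global_mean(self):
        """Channel-identical transients vanish under global-mean subtraction
        (algebraic identity) but trigger detections without it."""
        rec = noise_recording(seed=3, n_channels=4, dur_ms=1200.0, noise_sd=0.0)
        rec.data[:] = 0.0
        fs = rec.fs
        art_t = np.arange(0.0, 4.0, 1.0 / fs)
        art = -40.0 * np.exp(-art_t / 0.5)  # large negative-going transient
        stim = rec.events.time_ms.to_numpy()
        for t0 in stim:
            j = int(round((t0 + 60.0) * fs))
            rec.data[:, j : j + art.size] += art
        with_car = ic.detect_spikes(rec, subtract_global_mean=True)
        without = ic.detect_spikes(rec, subtract_global_mean=False)
        assert all(s.size == 0 for s in with_car.spike_times)
        assert all(s.size > 0 for s in without.spike_times)

    def test_single_channel_warns_and_skips_global_mean(self):
        rec = noise_recording(n_channels=1)
        with pytest.warns(UserWarning):
            ic.detect_spikes(rec)

    def test_missing_pre_stimulus_window_rejected(self):
        rec = noise_recording()
        rec.events = rec.events.assign(time_ms=5.0)  # window would start < 0
        with pytest.raises(ValueError):
            ic.detect_spikes(rec)


class TestWindowedRate:
    def test_rate_arithmetic(self):
        rates = ic.windowed_rate(
            np.array([5.0, 10.0, 20.0]), np.array([0.0]), (2.0, 25.0)
        )
        assert rates[0] == pytest.approx(3 / 0.023)

    def test_empty_train_gives_zero(self):
        assert ic.windowed_rate(np.array([]), np.array([0.0]), (0.0, 110.0))[0] == 0.0

    def test_poisson_mean_recovered(self):
        rng = np.random.default_rng(5)
        lam = 12.0  # mean count per 100 ms window
        events = 1000.0 * np.arange(100.0)
        spikes = np.sort(
            np.concatenate(
                [t + rng.uniform(0, 100.0, rng.poisson(lam)) for t in events]
            )
        )
        rates = ic.windowed_rate(spikes, events, (0.0, 100.0))
        sem = np.std(rates) / 10.0
        assert abs(rates.mean() - lam / 0.1) <= 3 * sem


class TestAUCDprime:
    def test_identical_distributions(self):
        a = np.full(30, 7.0)
        auc, dp = ic.auc_dprime(a, a)
        assert auc == 0.5
        assert dp == 0.0

    def test_closed_form_gaussian_gap(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.0, 1.0, 10_000)
        b = rng.normal(1.0, 1.0, 10_000)
        auc, dp = ic.auc_dprime(a, b)
        assert auc == pytest.approx(norm.cdf(1 / np.sqrt(2)), abs=0.01)
        assert dp == pytest.approx(1.0, abs=0.05)

    def test_complete_separation_is_clipped(self):
        a = np.arange(30.0)
        b = a + 100.0
        auc, dp = ic.auc_dprime(a, b)
        assert auc == pytest.approx(59.0 / 60.0)
        assert np.isfinite(dp)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            ic.auc_dprime([1.0], [2.0, 3.0])

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 20)
        _, d1 = ic.auc_dprime(a, b)
        _, d2 = ic.auc_dprime(b, a)
        assert d1 == pytest.approx(-d2, abs=1e-12)


class TestCumulativeDprime:
    def test_known_step_sequence(self):
        """Steps of ~0.4 accumulate to cross 1 at the third intensity."""
        rng = np.random.default_rng(0)
        base = rng.normal(10.0, 1.0, 100_000)
        rates = [base + k * 0.4 for k in (1, 2, 3)]  # unit-variance: d' = shift
        res = ic.cumulative_dprime_threshold(
            rates, np.array([1.0, 2.0, 3.0]), base, scheme="successive"
        )
        assert np.allclose(res.dprime, 0.4, atol=0.02)
        assert np.allclose(res.cumulative_dprime, [0.4, 0.8, 1.2], atol=0.05)
        assert res.threshold_intensity == 3.0

    def test_no_response_gives_nan_threshold(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10.0, 1.0, 30)
        rates = [rng.normal(10.0, 1.0, 30) for _ in range(4)]
        res = ic.cumulative_dprime_threshold(
            rates, np.arange(1.0, 5.0), base
        )
        assert abs(res.cumulative_dprime[-1]) < 1.0
        assert np.isnan(res.threshold_intensity)
        assert not res.responsive

    def test_rescaling_invariance_of_rank_auc(self):
        rng = np.random.default_rng(2)
        base = rng.normal(10.0, 2.0, 30)
        rates = [rng.normal(10.0 + k, 2.0, 30) for k in range(1, 5)]
        r1 = ic.cumulative_dprime_threshold(rates, np.arange(1.0, 5.0), base)
        r2 = ic.cumulative_dprime_threshold(
            [r * 3.7 for r in rates], np.arange(1.0, 5.0), base * 3.7
        )
        assert np.allclose(r1.cumulative_dprime, r2.cumulative_dprime)

    def test_baseline_scheme_supported(self):
        rng = np.random.default_rng(3)
        base = rng.normal(5.0, 1.0, 30)
        rates = [rng.normal(5.0 + 2 * k, 1.0, 30) for k in range(1, 4)]
        res = ic.cumulative_dprime_threshold(
            rates, np.arange(1.0, 4.0), base, scheme="baseline"
        )
        assert res.scheme == "baseline"
        assert np.all(np.diff(res.dprime) >= -0.5)  # steps grow against baseline


class TestResponsiveAndBestElectrode:
    def test_responsive_flags(self):
        rng = np.random.default_rng(4)
        blank = [rng.normal(5.0, 1.0, 30) for _ in range(2)]
        strong = rng.normal(50.0, 5.0, 30)
        weak = rng.normal(5.0, 1.0, 30)
        flags = ic.responsive_units([strong, weak], blank)
        assert flags.tolist() == [True, False]

    @pytest.mark.parametrize(
        "thresholds,expected",
        [
            ([5.0, 3.0, 4.0], 1.0),
            ([5.0, 3.0, 3.0, 4.0], 1.5),
            ([np.nan, 2.0, np.nan], 1.0),
            ([7.0], 0.0),
        ],
    )
    def test_best_electrode_with_ties(self, thresholds, expected):
        assert ic.best_electrode(np.array(thresholds)) == expected


class TestTonotopicFit:
    def test_collinear_points_exact(self):
        freqs = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        depths = 200.0 + 350.0 * np.log2(freqs)
        fit = ic.tonotopic_fit(depths, freqs)
        assert fit.slope == pytest.approx(350.0, abs=1e-9)
        assert fit.removed_outliers.size == 0

    def test_outliers_removed_in_two_rounds(self):
        freqs = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 3.0, 12.0])
        depths = 200.0 + 350.0 * np.log2(freqs)
        depths[6] += 900.0  # gross outliers
        depths[7] -= 900.0
        fit = ic.tonotopic_fit(depths, freqs)
        assert set(fit.removed_outliers) == {6, 7}
        assert fit.slope == pytest.approx(350.0, abs=1e-9)
        assert fit.intercept == pytest.approx(200.0, abs=1e-6)

    def test_point_on_line_never_removed(self):
        freqs = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        depths = 200.0 + 350.0 * np.log2(freqs)
        rng = np.random.default_rng(0)
        depths_noisy = depths + rng.normal(0, 20.0, depths.size)
        fit0 = ic.tonotopic_fit(depths_noisy, freqs)
        new_f = 6.0
        new_d = fit0.slope * np.log2(new_f) + fit0.intercept
        fit1 = ic.tonotopic_fit(
            np.append(depths_noisy, new_d), np.append(freqs, new_f)
        )
        assert depths_noisy.size not in fit1.removed_outliers
        assert fit1.slope == pytest.approx(fit0.slope, rel=0.05)

    def test_deterministic_rerun(self):
        freqs = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        depths = 100.0 + 300.0 * np.log2(freqs)
        depths[0] -= 700.0
        a = ic.tonotopic_fit(depths, freqs)
        b = ic.tonotopic_fit(depths, freqs)
        assert a.slope == b.slope and np.array_equal(a.removed_outliers, b.removed_outliers)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ic.tonotopic_fit(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))


class TestVectorStrength:
    def test_aligned_spikes_give_unity(self):
        times = 60.0 + 10.0 * np.arange(5)  # identical phase every cycle
        res = ic.vector_strength(times, 10.0)
        assert res.raw_vs == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_spikes_cancel(self):
        times = np.concatenate([60.0 + 10.0 * np.arange(3), 65.0 + 10.0 * np.arange(3)])
        res = ic.vector_strength(times, 10.0)
        assert res.raw_vs == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_matches_bessel_ratio(self):
        rng = np.random.default_rng(6)
        n = 10_000
        phases = rng.vonmises(np.pi, 2.0, n)
        times = 50.0 + rng.integers(0, 6, n) * 10.0 + np.mod(phases, 2 * np.pi) / (
            2 * np.pi
        ) * 10.0
        res = ic.vector_strength(times, 10.0)
        assert res.vs == pytest.approx(i1(2.0) / i0(2.0), abs=0.01)
        assert res.significant

    def test_rayleigh_gate_zeroes_weak_locking(self):
        # construct n=100 spikes with raw VS ~ 0.25 -> L = 12.5 < 13.8
        rng = np.random.default_rng(11)
        for _ in range(50):
            phases = rng.vonmises(0.0, 0.515, 100)
            times = 50.0 + rng.integers(0, 6, 100) * 10.0 + np.mod(
                phases, 2 * np.pi
            ) / (2 * np.pi) * 10.0
            res = ic.vector_strength(times, 10.0)
            if 0.2 < res.raw_vs < 0.26:
                assert res.rayleigh_l == pytest.approx(
                    2 * 100 * res.raw_vs**2, rel=1e-12
                )
                if res.rayleigh_l < 13.8:
                    assert res.vs == 0.0
                    assert not res.significant
                break
        else:
            pytest.fail("no realization with raw VS near 0.25")

    def test_no_spikes_handled(self):
        res = ic.vector_strength(np.array([]), 10.0)
        assert res.vs == 0.0 and res.n == 0 and not res.significant

    @settings(deadline=None, max_examples=20)
    @given(shift=st.integers(min_value=-5, max_value=5))
    def test_invariant_to_integer_period_time_shifts(self, shift):
        rng = np.random.default_rng(12)
        times = 50.0 + rng.uniform(0, 60.0, 200)
        r0 = ic.vector_strength(times, 10.0, window_ms=(0.0, 1e9))
        r1 = ic.vector_strength(times + 10.0 * shift, 10.0, window_ms=(0.0, 1e9))
        assert r1.raw_vs == pytest.approx(r0.raw_vs, abs=1e-9)
        assert 0.0 <= r1.raw_vs <= 1.0


class TestEndToEndRecovery:
    def test_planted_vs_recovered_through_full_pipeline(self):
        """Detection + pooled, background-corrected VS lands within 0.05 of
        the planted Bessel-ratio vector strength."""
        errs = []
        for seed in range(6):
            params = synth.MEAParams(
                n_electrodes=16,
                intensities=(5.0,),
                n_reps=30,
                train=(100.0, 100.0, 1.0),
                phase_kappa=2.0,
                best_depth_um=400.0,
                spatial_sigma_um=800.0,
                noise_sd_uv=5.0,
                post_ms=60.0,
                rate_level=RateLevelSigmoid(
                    floor=0.5, ceiling=60.0, midpoint=2.0, slope=2.0
                ),
            )
            rec = synth.gen_mea_recording(params, seed)
            sp = ic.detect_spikes(rec)
            ev = rec.events
            res = ic.pooled_vector_strength(
                sp,
                ev[ev.kind == "train"].time_ms.to_numpy(),
                10.0,
                blank_times_ms=ev[ev.kind == "blank"].time_ms.to_numpy(),
            )
            errs.append(res.vs - rec.truth["planted_vs"])
        assert np.median(np.abs(errs)) <= 0.05
        assert np.max(np.abs(errs)) <= 0.08
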