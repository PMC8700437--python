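"""Surrogate sEMG generator and fatigue-cohort simulation."""

import numpy as np
import pytest

from rcdpe import (
    CohortSpec,
    PESettings,
    band_power_ratio_db,
    gen_fatigue_cohort,
    gen_semg_surrogate,
    gen_white_noise,
    normalized_psd,
    permutation_entropy,
    rcdpe,
)


class TestWhiteNoise:
    def test_reproducible_under_seed(self):
        a = gen_white_noise(1000, 10_000.0, seed=9)
        b = gen_white_noise(1000, 10_000.0, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_moments(self):
        sig = gen_white_noise(100_000, 10_000.0, seed=2)
        assert abs(sig.samples.mean()) < 4 / np.sqrt(100_000)
        assert sig.samples.std() == pytest.approx(1.0, rel=0.02)

    def test_normalized_pe_near_one(self):
        sig = gen_white_noise(100_000, 10_000.0, seed=4)
        assert permutation_entropy(sig, PESettings(d=3, tau=1)).value > 0.99


class TestSurrogate:
    def test_noise_floor_calibration(self):
        sig = gen_semg_surrogate(10_000.0, 10.0, (20, 500), -30.0, seed=1)
        psd = normalized_psd(sig)
        ratio = band_power_ratio_db(psd, (0, 500), (500, 5000))
        assert ratio == pytest.approx(30.0, abs=1.0)

    def test_disabled_floor_leaves_band_clean(self):
        sig = gen_semg_surrogate(10_000.0, 10.0, (20, 500), None, seed=1)
        psd = normalized_psd(sig)
        ratio = band_power_ratio_db(psd, (0, 500), (500, 5000))
        assert ratio > 60.0  # only spectral-mask leakage remains

    def test_unit_variance_and_seed_determinism(self):
        a = gen_semg_surrogate(10_000.0, 2.0, (20, 400), -30.0, seed=7)
        b = gen_semg_surrogate(10_000.0, 2.0, (20, 400), -30.0, seed=7)
        assert np.array_equal(a.samples, b.samples)
        assert a.samples.std() == pytest.approx(1.0, abs=1e-9)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            gen_semg_surrogate(1000.0, 1.0, (20, 600), -30.0, seed=0)


class TestCohortSpec:
    def test_mismatched_edges_rejected(self):
        with pytest.raises(ValueError, match="band_end_by_window"):
            CohortSpec(n_windows=3, band_end_by_window=(500.0, 400.0))

    def test_increasing_edges_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            CohortSpec(band_end_by_window=(400.0, 500.0, 320.0, 250.0))


class TestFatigueCohort:
    def test_windows_cover_signal_equally(self, small_cohort):
        _, cohort = small_cohort
        for subj in cohort:
            lengths = {b - a for a, b in subj.window_bounds}
            assert len(lengths) == 1
            assert subj.window_bounds[-1][1] == len(subj.signal)

    def test_entropy_decreases_across_windows(self, small_cohort):
        # spectral compression lowers ordinal complexity at the matched scale
        _, cohort = small_cohort
        for subj in cohort:
            vals = [rcdpe(w, 10, 4).value for w in subj.windows]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_null_cohort_has_no_effect(self):
        spec = CohortSpec(
            n_subjects=4,
            duration_s=4.0,
            n_windows=2,
            band_end_by_window=(500.0, 500.0),
            seed=3,
        )
        cohort = gen_fatigue_cohort(spec)
        deltas = [
            rcdpe(s.windows[0], 10, 3).value - rcdpe(s.windows[1], 10, 3).value for s in cohort
        ]
        assert abs(np.mean(deltas)) < 0.005  # estimator noise only

    def test_cohort_determinism(self):
        spec = CohortSpec(n_subjects=2, duration_s=2.0, seed=21)
        a, b = gen_fatigue_cohort(spec), gen_fatigue_cohort(spec)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.signal.samples, sb.signal.samples)

    def test_wider_band_gap_gives_larger_delta(self):
        # parameter recovery: the injected effect grows with the band gap
        base = dict(n_subjects=3, duration_s=4.0, seed=13)
        narrow = CohortSpec(band_end_by_window=(500.0, 460.0, 430.0, 400.0), **base)
        wide = CohortSpec(band_end_by_window=(500.0, 400.0, 320.0, 250.0), **base)

        def mean_w1_w4_delta(spec):
            cohort = gen_fatigue_cohort(spec)
            return np.mean(
                [rcdpe(s.windows[0], 10, 4).value - rcdpe(s.windows[3], 10, 4).value for s in cohort]
            )

        assert mean_w1_w4_delta(wide) > mean_w1_w4_delta(narrow)
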