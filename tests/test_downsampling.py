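"""Composite downsampling and the DPE / cDPE / rcDPE estimators."""

import numpy as np
import pytest

from rcdpe import (
    PESettings,
    cdpe,
    composite_downsample,
    count_patterns,
    dpe,
    mpe,
    permutation_entropy,
    rcdpe,
    shannon_entropy,
)


class TestCompositeDownsample:
    def test_three_phase_example(self):
        ds = composite_downsample(np.arange(1.0, 8), 3)
        assert np.array_equal(ds.phases[0], [1, 4, 7])
        assert np.array_equal(ds.phases[1], [2, 5])
        assert np.array_equal(ds.phases[2], [3, 6])

    def test_identity_factor(self):
        x = np.arange(10.0)
        ds = composite_downsample(x, 1)
        assert len(ds.phases) == 1 and np.array_equal(ds.phases[0], x)

    def test_factor_exceeding_length(self):
        with pytest.raises(ValueError, match="exceeds"):
            composite_downsample(np.arange(5.0), 6)

    @pytest.mark.parametrize("tau", [2, 3, 10])
    def test_phases_partition_the_signal(self, tau, rng):
        x = rng.standard_normal(101)
        ds = composite_downsample(x, tau)
        assert max(ds.phase_lengths) - min(ds.phase_lengths) <= 1
        pooled = np.sort(np.concatenate(ds.phases))
        assert np.array_equal(pooled, np.sort(x))  # no sample lost or duplicated


class TestDownsamplingEstimators:
    def test_factor_one_collapse(self, signal_battery):
        s = PESettings(d=3, tau=1)
        for x in signal_battery:
            base = permutation_entropy(x, s).value
            assert dpe(x, 1, 3).value == base
            assert cdpe(x, 1, 3).value == base
            assert rcdpe(x, 1, 3).value == base

    def test_ramp_is_zero_at_any_factor(self):
        ramp = np.arange(300.0)
        for tau in (1, 3, 7):
            assert dpe(ramp, tau, 3).value == 0.0

    def test_dpe_is_phase_one_pe(self, rng):
        x = rng.standard_normal(2000)
        phase1 = composite_downsample(x, 4).phases[0]
        assert dpe(x, 4, 3).value == permutation_entropy(phase1, PESettings(d=3, tau=1)).value

    def test_cdpe_equals_per_phase_average(self, rng):
        x = rng.standard_normal(2000)
        s = PESettings(d=3, tau=1)
        hs = [
            shannon_entropy(count_patterns(p, s)).value
            for p in composite_downsample(x, 5).phases
        ]
        assert cdpe(x, 5, 3).value == pytest.approx(np.mean(hs), abs=1e-14)

    def test_rcdpe_equals_pooled_pmf_oracle(self, rng):
        x = rng.standard_normal(3000)
        tau, d = 6, 4
        s = PESettings(d=d, tau=1)
        pmfs = [count_patterns(p, s).pmf for p in composite_downsample(x, tau).phases]
        expected = shannon_entropy(np.mean(pmfs, axis=0), d=d).value
        assert rcdpe(x, tau, d).value == pytest.approx(expected, abs=1e-14)

    def test_jensen_rcdpe_dominates_cdpe(self, signal_battery):
        for x in signal_battery:
            for tau in (2, 3, 5, 10):
                assert rcdpe(x, tau, 3).value >= cdpe(x, tau, 3).value - 1e-12

    def test_white_noise_asymptote_at_all_factors(self, white_signal):
        for tau in (2, 5, 10):
            assert abs(rcdpe(white_signal, tau, 4).value - 1.0) < 0.02

    def test_sinusoid_deterministic_recomputation(self):
        # period (41 samples) not a multiple of tau: phases sample distinct
        # cycle positions, yet the estimate is exactly reproducible
        x = np.sin(2 * np.pi * np.arange(5000) / 41.0)
        a = rcdpe(x, 3, 3).value
        b = rcdpe(x, 3, 3).value
        assert a == b and 0.0 < a < 1.0

    def test_variance_reduction_on_iid_noise_smoke(self):
        # scaled-down version of the estimator-variance ordering claim
        rng = np.random.default_rng(42)
        r_vals, m_vals, d_vals = [], [], []
        for _ in range(30):
            x = rng.standard_normal(5000)
            r_vals.append(rcdpe(x, 10, 3).value)
            m_vals.append(mpe(x, 10, 3).value)
            d_vals.append(dpe(x, 10, 3).value)
        assert np.std(r_vals) < np.std(m_vals)
        assert np.std(r_vals) < np.std(d_vals)

    def test_prefilter_near_noop_below_post_decimation_nyquist(self):
        # a signal whose band sits below fs/(2 tau) is barely touched by the
        # optional anti-aliasing prefilter, while broadband noise is not
        from rcdpe import gen_semg_surrogate, gen_white_noise

        band_limited = gen_semg_surrogate(10_000.0, 4.0, (20, 500), None, seed=9)
        plain = rcdpe(band_limited, 4, 3).value
        filtered = rcdpe(band_limited, 4, 3, prefilter=True).value
        assert abs(plain - filtered) < 0.02

        broadband = gen_white_noise(40_000, 10_000.0, seed=9)
        assert rcdpe(broadband, 4, 3, prefilter=True).value < rcdpe(broadband, 4, 3).value - 0.005
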