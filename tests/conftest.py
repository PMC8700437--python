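import numpy as np
import pytest

from rcdpe import CohortSpec, Signal, gen_fatigue_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211209)


@pytest.fixture(scope="session")
def white_signal():
    """Long i.i.d. uniform-noise signal at 10 kHz."""
    rng = np.random.default_rng(1)
    return Signal(rng.random(100_000), fs=10_000.0, label="white")


@pytest.fixture(scope="session")
def signal_battery():
    """Small, varied seeded signals: noise, AR(1), sinusoid, ramp+jitter."""
    rng = np.random.default_rng(7)
    sigs = []
    for i in range(5):
        sigs.append(rng.standard_normal(600))
    for phi in (0.5, 0.9, 0.99):
        e = rng.standard_normal(600)
        x = np.zeros(600)
        for t in range(1, 600):
            x[t] = phi * x[t - 1] + e[t]
        sigs.append(x)
    t = np.arange(600)
    sigs.append(np.sin(2 * np.pi * t / 37.0))
    sigs.append(t + 0.1 * rng.standard_normal(600))
    sigs.append(np.round(rng.standard_normal(600), 1))  # heavy ties (quantized)
    return sigs


@pytest.fixture(scope="session")
def small_cohort():
    """3-subject, shortened default-bands cohort for pipeline tests."""
    spec = CohortSpec(n_subjects=3, duration_s=6.0, seed=11)
    return spec, gen_fatigue_cohort(spec)
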