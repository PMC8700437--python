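"""Surrogate sEMG signals and multi-subject fatigue cohorts.

Real sEMG is, to second order, band-limited stochastic activity: the
physiological content of a biceps recording lies roughly in 20-500 Hz,
far below the 10 kHz acquisition rate, with an instrumentation noise
floor some 30 dB down.  The surrogate is zero-phase band-pass-filtered
Gaussian noise plus a white noise floor, normalized to unit variance.

Fatigue is emulated as progressive spectral compression: motor-unit
action potentials lengthen as a muscle tires, which concentrates power at
lower frequencies and biases the ordinal-pattern distribution toward
monotone patterns — hence lower permutation entropy.  A cohort subject is
four consecutive surrogate segments whose upper band edge shrinks window
by window (default 500 -> 400 -> 320 -> 250 Hz); the 500 Hz fresh-window
edge equals the effective Nyquist at scale 10, so the scale matched to
the signal band is 10 by construction.

Every level (cohort -> subject -> window) derives its RNG stream
deterministically from the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .types import Signal

__all__ = ["CohortSpec", "FatigueSubject", "gen_white_noise", "gen_semg_surrogate", "gen_fatigue_cohort"]


@dataclass
class CohortSpec:
    """Parameters of the synthetic multi-subject fatigue simulation.

    Defaults mirror the acquisition geometry of a biceps fatigue protocol:
    10 subjects, 10 kHz sampling, 27.4 s records (274,000 samples) split
    into 4 equal windows, activity band starting at 20 Hz with a
    non-increasing upper edge per window, and a -30 dB white noise floor.
    """

    n_subjects: int = 10
    fs: float = 10_000.0
    duration_s: float = 27.4
    n_windows: int = 4
    band_start: float = 20.0
    band_end_by_window: tuple[float, ...] = (500.0, 400.0, 320.0, 250.0)
    noise_floor_db: float = -30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.n_windows < 2:
            raise ValueError("need at least two windows for a fatigue contrast")
        if len(self.band_end_by_window) != self.n_windows:
            raise ValueError(
                f"band_end_by_window has {len(self.band_end_by_window)} entries "
                f"for {self.n_windows} windows"
            )
        edges = self.band_end_by_window
        if any(e2 > e1 for e1, e2 in zip(edges, edges[1:])):
            raise ValueError("band_end_by_window must be non-increasing (fatigue compresses the band)")
        for e in edges:
            if not self.band_start <= e <= self.fs / 2:
                raise ValueError(f"band edge {e} Hz outside [{self.band_start}, fs/2]")
        if self.duration_s * self.fs / self.n_windows < 2:
            raise ValueError("windows too short")


@dataclass
class FatigueSubject:
    """One simulated subject: the concatenated signal plus window boundaries."""

    subject_id: str
    signal: Signal
    window_bounds: list[tuple[int, int]]
    seed_entropy: int

    @property
    def windows(self) -> list[Signal]:
        return [
            Signal(self.signal.samples[a:b], self.signal.fs, label=f"{self.subject_id}/W{i + 1}")
            for i, (a, b) in enumerate(self.window_bounds)
        ]


def gen_white_noise(n: int, fs: float, seed: int | np.random.Generator = 0) -> Signal:
    """i.i.d. standard Gaussian samples; the reference uncorrelated signal."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Signal(rng.standard_normal(int(n)), fs, label="white-noise")


def gen_semg_surrogate(
    fs: float,
    duration_s: float,
    band: tuple[float, float] = (20.0, 500.0),
    noise_floor_db: float | None = -30.0,
    seed: int | np.random.Generator = 0,
) -> Signal:
    """Band-limited Gaussian surrogate of an sEMG record, unit variance.

    Gaussian noise is band-limited to ``band`` by a zero-phase spectral
    mask: unity inside the band with half-cosine tapers just inside each
    edge, zero outside.  Zero phase means the filter itself injects no
    asymmetric ordinal patterns, and the sharp edge keeps essentially all
    core power inside the band, so the in-band/out-of-band power ratio is
    set by ``noise_floor_db`` alone.  A white floor at ``noise_floor_db``
    relative to the in-band power is added (``None`` or ``-inf`` disables
    it); the sum is rescaled to unit variance.
    """
    f1, f2 = band
    if not 0 < f1 < f2 < fs / 2:
        raise ValueError(f"band {band} must satisfy 0 < f1 < f2 < fs/2 = {fs / 2}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # half-cosine tapers occupy the outer 5% (capped at 10 Hz) of the band
    w = min(10.0, 0.05 * (f2 - f1))
    mask = np.zeros_like(freqs)
    flat = (freqs >= f1 + w) & (freqs <= f2 - w)
    mask[flat] = 1.0
    lo = (freqs >= f1) & (freqs < f1 + w)
    mask[lo] = 0.5 * (1 - np.cos(np.pi * (freqs[lo] - f1) / w))
    hi = (freqs > f2 - w) & (freqs <= f2)
    mask[hi] = 0.5 * (1 + np.cos(np.pi * (freqs[hi] - (f2 - w)) / w))
    core = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * mask, n)
    core /= core.std()
    x = core
    if noise_floor_db is not None and np.isfinite(noise_floor_db):
        floor_amp = 10.0 ** (noise_floor_db / 20.0)
        x = core + floor_amp * rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    return Signal(x, fs, label=f"semg-surrogate[{f1:g}-{f2:g}Hz]")


def gen_fatigue_cohort(spec: CohortSpec) -> list[FatigueSubject]:
    """Simulate a fatigue cohort: one multi-window surrogate per subject.

    Subject RNG streams are spawned from ``SeedSequence(spec.seed)`` so the
    cohort is fully reproducible and subjects are mutually independent.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    n_win = int(round(spec.duration_s * spec.fs / spec.n_windows))
    cohort: list[FatigueSubject] = []
    for s, sseq in enumerate(subject_seeds):
        window_seqs = sseq.spawn(spec.n_windows)
        segments = []
        bounds = []
        pos = 0
        for w, wseq in enumerate(window_seqs):
            seg = gen_semg_surrogate(
                fs=spec.fs,
                duration_s=n_win / spec.fs,
                band=(spec.band_start, spec.band_end_by_window[w]),
                noise_floor_db=spec.noise_floor_db,
                seed=np.random.default_rng(wseq),
            )
            segments.append(seg.samples)
            bounds.append((pos, pos + seg.samples.size))
            pos += seg.samples.size
        sid = f"S{s + 1:02d}"
        sig = Signal(np.concatenate(segments), spec.fs, label=sid)
        cohort.append(
            FatigueSubject(
                subject_id=sid,
                signal=sig,
                window_bounds=bounds,
                seed_entropy=int(sseq.entropy) if sseq.entropy is not None else 0,
            )
        )
    return cohort
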