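"""Frequency-domain utilities linking scale choice to bandwidth.

Coarse-graining or downsampling by a factor ``m`` lowers the effective
sampling rate to ``fs/m`` and hence the observable band to ``fs/(2m)``.
For sEMG sampled at 10 kHz, scale 10 brings the analysis exactly onto the
0-500 Hz band where the physiological activity lives.  Coarse-graining
additionally low-pass filters: the block mean is an ``m``-tap
constant-coefficient FIR whose -3 dB cutoff this module computes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import signal as sps

from .types import Signal

__all__ = [
    "PSDEstimate",
    "normalized_psd",
    "band_power",
    "band_power_ratio_db",
    "ma_filter_cutoff",
    "effective_rate",
    "nyquist_after",
]


@dataclass
class PSDEstimate:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    density: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.freqs.shape != self.density.shape:
            raise ValueError("frequency grid and density must have the same shape")

    def to_text(self, path) -> None:
        """Two-column delimited export (freq_hz, density)."""
        np.savetxt(
            path,
            np.column_stack([self.freqs, self.density]),
            delimiter=",",
            header="freq_hz,density",
            comments="",
        )


def normalized_psd(
    signal: Signal,
    segment_s: float = 1.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> PSDEstimate:
    """Welch PSD rescaled so its trapezoidal integral over the band is 1.

    Defaults: 1-second Hann segments with 50% overlap.  The unit-integral
    normalization makes records of different power directly comparable.
    """
    nperseg = int(round(segment_s * signal.fs))
    if nperseg > len(signal):
        raise ValueError(
            f"segment of {nperseg} samples longer than signal ({len(signal)} samples)"
        )
    freqs, density = sps.welch(
        signal.samples,
        fs=signal.fs,
        window=window,
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
    )
    total = np.trapezoid(density, freqs)
    if total <= 0:
        raise ValueError("signal has zero power; cannot normalize PSD")
    return PSDEstimate(freqs=freqs, density=density / total, normalized=True)


def band_power(psd: PSDEstimate, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the density over ``band`` (Hz).

    Band edges falling between grid points are handled by linear
    interpolation of the density at the exact edge.
    """
    f1, f2 = band
    if f1 < 0 or f2 < f1:
        raise ValueError(f"invalid band {band}")
    fmax = psd.freqs[-1]
    if f2 > fmax + 1e-9:
        raise ValueError(f"band {band} extends beyond the Nyquist grid ({fmax} Hz)")
    f2 = min(f2, fmax)
    inner = (psd.freqs > f1) & (psd.freqs < f2)
    fgrid = np.concatenate([[f1], psd.freqs[inner], [f2]])
    dgrid = np.interp(fgrid, psd.freqs, psd.density)
    return float(np.trapezoid(dgrid, fgrid))


def band_power_ratio_db(
    psd: PSDEstimate, band_a: tuple[float, float], band_b: tuple[float, float]
) -> float:
    """``10 log10`` of the integrated-power ratio between two bands.

    With the physiological band as ``band_a`` and the noise band as
    ``band_b`` this is the in-band signal-to-noise figure in dB; returns
    +inf when ``band_b`` carries no power.
    """
    pa = band_power(psd, band_a)
    pb = band_power(psd, band_b)
    if pb == 0:
        return float("inf") if pa > 0 else float("nan")
    if pa == 0:
        return float("-inf")
    return float(10.0 * np.log10(pa / pb))


def ma_filter_cutoff(m: int, fs: float) -> float:
    """-3 dB cutoff of the ``m``-tap moving-average FIR at rate ``fs``.

    Solves ``|sin(pi m f / fs) / (m sin(pi f / fs))| = 1/sqrt(2)``
    numerically on (0, fs/m), which is exact for all ``m`` (the common
    0.443*fs/m approximation is not).  ``m=1`` is the identity filter:
    the cutoff is the Nyquist frequency fs/2.
    """
    if int(m) != m or m < 1:
        raise ValueError("tap count m must be an integer >= 1")
    m = int(m)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if m == 1:
        return fs / 2.0

    target = 1.0 / np.sqrt(2.0)

    def gain_excess(f: float) -> float:
        h = np.sin(np.pi * m * f / fs) / (m * np.sin(np.pi * f / fs))
        return abs(h) - target

    # magnitude falls monotonically from 1 at DC to 0 at the first null fs/m
    lo, hi = fs * 1e-9, fs / m * (1 - 1e-9)
    return float(optimize.brentq(gain_excess, lo, hi, xtol=1e-13 * fs))


def effective_rate(fs: float, scale: int) -> float:
    """Sampling rate after coarse-graining/downsampling by ``scale``."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    return fs / scale


def nyquist_after(fs: float, scale: int) -> float:
    """Highest observable frequency after reduction by ``scale``."""
    return effective_rate(fs, scale) / 2.0
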