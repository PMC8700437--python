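"""Core containers shared by all estimators.

A :class:`Signal` is the universal input: a finite real-valued sample
vector with a known sampling frequency.  Ordinal analysis turns windows of
a signal into a :class:`PatternDistribution` (an empirical pmf over the
``d!`` ordinal patterns), and every entropy estimator reduces one or more
of those distributions to an :class:`EntropyValue`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Signal",
    "PESettings",
    "PatternDistribution",
    "EntropyValue",
    "SignalLengthWarning",
    "METHODS",
]

#: Recognised estimator names, in the order they appear in profiles.
METHODS = ("PE", "MPE", "cMPE", "rcMPE", "DPE", "cDPE", "rcDPE")


class SignalLengthWarning(UserWarning):
    """Signal shorter than the recommended minimum for reliable pattern counts."""


@dataclass
class Signal:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    samples : array-like of float
        Sample values, arbitrary units.  Must be finite and of length >= 2.
    fs : float
        Sampling frequency in Hz, > 0.
    label : str
        Free-text identifier (subject id, channel name, ...).
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size < 2:
            raise ValueError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        if not (self.fs > 0):
            raise ValueError("sampling frequency must be positive")
        self.fs = float(self.fs)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.samples.size / self.fs


@dataclass
class PESettings:
    """Parameters of a permutation-entropy computation.

    ``d`` is the embedding dimension (window length of the ordinal
    comparison), ``tau`` the time delay between compared samples, which
    doubles as the downsampling factor of the DPE family.  ``normalized``
    selects division by ``ln(d!)`` so values land in [0, 1].

    ``tie_policy`` controls ranking of equal sample values: ``"earlier"``
    (the stable convention — the earlier temporal index receives the lower
    rank) or ``"random"`` (ties broken by a seeded random order, mostly
    useful for sensitivity checks on quantized data).
    """

    d: int = 3
    tau: int = 1
    normalized: bool = True
    tie_policy: str = "earlier"
    tie_seed: int = 0

    def __post_init__(self) -> None:
        if int(self.d) != self.d or self.d < 2:
            raise ValueError("embedding dimension d must be an integer >= 2")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError("time delay tau must be an integer >= 1")
        if self.tie_policy not in ("earlier", "random"):
            raise ValueError("tie_policy must be 'earlier' or 'random'")
        self.d = int(self.d)
        self.tau = int(self.tau)

    def check_length(self, n: int) -> None:
        """Warn when fewer usable windows than the 5*d! recommendation."""
        usable = n - (self.d - 1) * self.tau
        if usable < 5 * math.factorial(self.d):
            warnings.warn(
                f"only {usable} ordinal windows available for d={self.d}, "
                f"tau={self.tau}; at least {5 * math.factorial(self.d)} are "
                "recommended for a reliable pattern distribution",
                SignalLengthWarning,
                stacklevel=3,
            )


@dataclass
class PatternDistribution:
    """Empirical distribution over the ``d!`` ordinal patterns."""

    counts: np.ndarray
    d: int
    n_windows: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64).ravel()
        if self.counts.size != math.factorial(self.d):
            raise ValueError(
                f"expected {math.factorial(self.d)} pattern counts for d={self.d}, "
                f"got {self.counts.size}"
            )
        if np.any(self.counts < 0):
            raise ValueError("pattern counts must be nonnegative")
        self.n_windows = int(self.counts.sum())

    @property
    def pmf(self) -> np.ndarray:
        """Pattern probabilities; uniform-0 convention when nothing counted."""
        if self.n_windows == 0:
            raise ValueError("no windows counted; pmf undefined")
        return self.counts / self.n_windows


@dataclass(frozen=True)
class EntropyValue:
    """One entropy measurement: value plus the settings that produced it."""

    value: float
    method: str
    scale: int
    d: int
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        hi = 1.0 if self.normalized else math.log(math.factorial(self.d))
        if not (-1e-12 <= self.value <= hi + 1e-12):
            raise ValueError(f"entropy {self.value} outside [0, {hi}]")

    def __float__(self) -> float:
        return float(self.value)
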