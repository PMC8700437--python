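"""Coarse-graining and the MPE / cMPE / rcMPE estimators.

Coarse-graining at scale ``m`` replaces non-overlapping blocks of ``m``
consecutive samples by their mean — equivalently an ``m``-tap
constant-coefficient FIR filter followed by decimation by ``m``.  The
composite procedure shifts the block start through all ``m`` offsets,
producing ``m`` coarse-grained phases:

* MPE   — PE of the first phase only;
* cMPE  — mean of the per-phase PEs;
* rcMPE — entropy of the mean of the per-phase pattern pmfs (refined
  composite: pool the distributions first, take one entropy).

By Jensen's inequality on the concave Shannon entropy, rcMPE >= cMPE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ordinal import count_patterns, shannon_entropy
from .types import EntropyValue, PESettings, Signal

__all__ = ["CoarseGrainSet", "coarse_grain", "composite_coarse_grain", "mpe", "cmpe", "rcmpe"]


def _raw(signal: Signal | np.ndarray) -> np.ndarray:
    return signal.samples if isinstance(signal, Signal) else np.asarray(signal, dtype=np.float64).ravel()


@dataclass
class CoarseGrainSet:
    """The ``m`` phase-shifted coarse-grained versions of one signal."""

    scale: int
    phases: list[np.ndarray]

    @property
    def phase_lengths(self) -> list[int]:
        return [p.size for p in self.phases]


def coarse_grain(signal: Signal | np.ndarray, m: int, k: int = 1) -> np.ndarray:
    """Phase-``k`` coarse-grained sequence at scale ``m``.

    Element ``j`` (1-based) is the mean of raw samples ``m(j-1)+k`` ..
    ``mj+k-1`` (1-based), i.e. consecutive non-overlapping ``m``-blocks
    starting at offset ``k``.  Trailing samples that do not fill a block
    are discarded.
    """
    x = _raw(signal)
    if int(m) != m or m < 1:
        raise ValueError("scale m must be an integer >= 1")
    m = int(m)
    if not 1 <= k <= m:
        raise ValueError(f"phase k={k} outside [1, m={m}]")
    n_blocks = (x.size - k + 1) // m
    if n_blocks < 1:
        raise ValueError(f"signal too short for scale m={m}, phase k={k}")
    start = k - 1
    return x[start : start + n_blocks * m].reshape(n_blocks, m).mean(axis=1)


def composite_coarse_grain(signal: Signal | np.ndarray, m: int) -> CoarseGrainSet:
    """All ``m`` coarse-grained phases at scale ``m``."""
    return CoarseGrainSet(scale=int(m), phases=[coarse_grain(signal, m, k) for k in range(1, int(m) + 1)])


def _settings(d: int, normalized: bool, tie_policy: str, tie_seed: int) -> PESettings:
    return PESettings(d=d, tau=1, normalized=normalized, tie_policy=tie_policy, tie_seed=tie_seed)


def mpe(
    signal: Signal | np.ndarray,
    m: int,
    d: int = 3,
    normalized: bool = True,
    tie_policy: str = "earlier",
    tie_seed: int = 0,
) -> EntropyValue:
    """Multiscale PE: the PE (delay 1) of the scale-``m`` coarse-grained signal."""
    s = _settings(d, normalized, tie_policy, tie_seed)
    dist = count_patterns(coarse_grain(signal, m, 1), s)
    return shannon_entropy(dist, normalized=normalized, method="MPE", scale=int(m))


def cmpe(
    signal: Signal | np.ndarray,
    m: int,
    d: int = 3,
    normalized: bool = True,
    tie_policy: str = "earlier",
    tie_seed: int = 0,
) -> EntropyValue:
    """Composite MPE: mean of the per-phase PEs over the ``m`` coarse phases."""
    s = _settings(d, normalized, tie_policy, tie_seed)
    grains = composite_coarse_grain(signal, m)
    values = [
        shannon_entropy(count_patterns(p, s), normalized=normalized).value for p in grains.phases
    ]
    return EntropyValue(
        value=float(np.mean(values)), method="cMPE", scale=int(m), d=d, normalized=normalized
    )


def rcmpe(
    signal: Signal | np.ndarray,
    m: int,
    d: int = 3,
    normalized: bool = True,
    tie_policy: str = "earlier",
    tie_seed: int = 0,
    length_weighted: bool = False,
) -> EntropyValue:
    """Refined composite MPE: entropy of the phase-averaged pattern pmf.

    Per-phase pmfs enter with equal weight by default even when phase
    lengths differ by one sample; ``length_weighted`` pools raw counts
    instead (weighting each phase by its window count).
    """
    s = _settings(d, normalized, tie_policy, tie_seed)
    grains = composite_coarse_grain(signal, m)
    dists = [count_patterns(p, s) for p in grains.phases]
    if length_weighted:
        pooled = np.sum([dd.counts for dd in dists], axis=0)
        pmf = pooled / pooled.sum()
    else:
        pmf = np.mean([dd.pmf for dd in dists], axis=0)
    ev = shannon_entropy(pmf, d=d, normalized=normalized)
    return EntropyValue(value=ev.value, method="rcMPE", scale=int(m), d=d, normalized=normalized)
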