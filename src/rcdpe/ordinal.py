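"""Ordinal pattern extraction and permutation entropy.

Each length-``d`` window of a signal is mapped to the permutation that
sorts it ascending; the Shannon entropy of the empirical distribution of
those permutations is the permutation entropy (PE).  Patterns are indexed
by the lexicographic Lehmer code of the sorting permutation, so pattern 0
is the fully ascending window and pattern ``d!-1`` the fully descending
one.  Equal values are ranked by temporal order by default (stable
Bandt-Pompe convention); a seeded random tie-break is available for
sensitivity studies on quantized data.
"""

from __future__ import annotations

import math

import numpy as np

from .types import EntropyValue, PatternDistribution, PESettings, Signal

__all__ = [
    "encode_pattern",
    "encode_windows",
    "count_patterns",
    "shannon_entropy",
    "permutation_entropy",
    "pattern_to_permutation",
    "permutation_to_pattern",
]


def _sorting_permutations(
    windows: np.ndarray, tie_policy: str = "earlier", tie_seed: int = 0
) -> np.ndarray:
    """Row-wise permutation that sorts each window ascending.

    Ties: 'earlier' keeps temporal order among equal values (stable sort);
    'random' permutes equal values with a seeded RNG.
    """
    if tie_policy == "earlier":
        return np.argsort(windows, axis=1, kind="stable")
    if tie_policy == "random":
        rng = np.random.default_rng(tie_seed)
        jitter = rng.random(windows.shape)
        # lexsort: last key is primary, so sample value dominates the jitter
        return np.lexsort((jitter, windows), axis=1)
    raise ValueError(f"unknown tie policy {tie_policy!r}")


def _lehmer_index(perms: np.ndarray) -> np.ndarray:
    """Lexicographic rank in [0, d!) of each permutation row."""
    n, d = perms.shape
    codes = np.zeros(n, dtype=np.int64)
    for i in range(d - 1):
        smaller_after = (perms[:, i + 1 :] < perms[:, i : i + 1]).sum(axis=1)
        codes += smaller_after * math.factorial(d - 1 - i)
    return codes


def permutation_to_pattern(perm: np.ndarray) -> str:
    """Render a sorting permutation as the field's 1-based digit string.

    The ascending 2-window is "12", the descending one "21".
    """
    return "".join(str(p + 1) for p in np.asarray(perm).ravel())


def pattern_to_permutation(index: int, d: int) -> np.ndarray:
    """Invert the Lehmer index back to the sorting permutation."""
    if not 0 <= index < math.factorial(d):
        raise ValueError(f"pattern index {index} outside [0, {math.factorial(d)})")
    remaining = list(range(d))
    perm = np.empty(d, dtype=np.int64)
    for i in range(d):
        f = math.factorial(d - 1 - i)
        q, index = divmod(index, f)
        perm[i] = remaining.pop(q)
    return perm


def encode_pattern(
    window: np.ndarray, tie_policy: str = "earlier", tie_seed: int = 0
) -> int:
    """Ordinal pattern index of a single length-``d`` window.

    Returns the Lehmer index of the permutation sorting ``window``
    ascending; 0 for a strictly increasing window.
    """
    window = np.asarray(window, dtype=np.float64).ravel()
    if window.size < 2:
        raise ValueError("window must contain at least 2 values")
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    perms = _sorting_permutations(window[None, :], tie_policy, tie_seed)
    return int(_lehmer_index(perms)[0])


def encode_windows(
    x: np.ndarray, d: int, tau: int, tie_policy: str = "earlier", tie_seed: int = 0
) -> np.ndarray:
    """Pattern index of every delay-``tau`` window of ``x`` (vectorized)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    n_windows = x.size - (d - 1) * tau
    if n_windows < 1:
        raise ValueError(
            f"signal of length {x.size} too short for d={d}, tau={tau} "
            f"(needs at least {(d - 1) * tau + 1} samples)"
        )
    idx = np.arange(n_windows)[:, None] + tau * np.arange(d)[None, :]
    perms = _sorting_permutations(x[idx], tie_policy, tie_seed)
    return _lehmer_index(perms)


def count_patterns(signal: Signal | np.ndarray, settings: PESettings) -> PatternDistribution:
    """Empirical ordinal-pattern distribution of a signal.

    Every one of the ``N - (d-1)*tau`` delay-``tau`` windows contributes one
    count, exactly the Bandt-Pompe estimate of the pattern pmf.
    """
    x = signal.samples if isinstance(signal, Signal) else np.asarray(signal, dtype=np.float64)
    settings.check_length(x.size)
    codes = encode_windows(x, settings.d, settings.tau, settings.tie_policy, settings.tie_seed)
    counts = np.bincount(codes, minlength=math.factorial(settings.d))
    return PatternDistribution(counts=counts, d=settings.d)


def shannon_entropy(
    dist: PatternDistribution | np.ndarray,
    d: int | None = None,
    normalized: bool = True,
    method: str = "PE",
    scale: int = 1,
) -> EntropyValue:
    """Shannon entropy of a pattern distribution, in nats.

    Zero-probability patterns contribute nothing (0*ln 0 := 0).  With
    ``normalized`` the value is divided by ``ln(d!)`` so the uniform
    distribution maps to 1.
    """
    if isinstance(dist, PatternDistribution):
        pmf = dist.pmf
        d = dist.d
    else:
        pmf = np.asarray(dist, dtype=np.float64).ravel()
        if d is None:
            raise ValueError("d is required when passing a bare pmf")
        if pmf.size != math.factorial(d):
            raise ValueError(f"pmf length {pmf.size} != {d}! = {math.factorial(d)}")
        if np.any(pmf < -1e-12) or abs(pmf.sum() - 1.0) > 1e-9:
            raise ValueError("invalid pmf: entries must be >= 0 and sum to 1")
    pos = pmf[pmf > 0]
    h = float(-(pos * np.log(pos)).sum())
    if normalized:
        h /= math.log(math.factorial(d))
    # clip the tiny negative/overshoot round-off at the exact bounds
    hi = 1.0 if normalized else math.log(math.factorial(d))
    h = min(max(h, 0.0), hi) + 0.0  # +0.0 turns -0.0 into 0.0
    return EntropyValue(value=h, method=method, scale=scale, d=d, normalized=normalized)


def permutation_entropy(signal: Signal | np.ndarray, settings: PESettings) -> EntropyValue:
    """Permutation entropy of a signal: count patterns, then Shannon entropy."""
    dist = count_patterns(signal, settings)
    return shannon_entropy(dist, normalized=settings.normalized, method="PE", scale=settings.tau)
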