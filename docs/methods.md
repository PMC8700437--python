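# Methods

## Ordinal patterns and permutation entropy

A window of `d` samples taken `τ` apart is reduced to the permutation that
sorts it ascending; the signal's ordinal content is the empirical
distribution `p̂` of those `d!` patterns over all `N − (d−1)τ` window
starts. Permutation entropy is the Shannon entropy of `p̂` in nats, with
`0·ln 0 := 0` for unobserved patterns, optionally normalized by `ln(d!)`.
The measure assumes a weakly stationary, uniformly sampled signal; it is
exactly invariant to strictly increasing amplitude transforms, which makes
it robust to sensor gain and monotone distortion.

**Pattern indexing.** Patterns are indexed by the lexicographic Lehmer code
of the sorting permutation (0 = ascending, `d!−1` = descending). Any
bijection would do; this one is documented and easy to check against a
brute-force sort oracle, which the test suite does.

**Ties.** Equal sample values are ranked by temporal order (earlier index →
lower rank), the stable convention; a seeded random tie-break is available
as `tie_policy="random"` for probing sensitivity on coarsely quantized
data. On real quantized recordings results can depend on tie handling at
high scales, where block averaging reduces the dynamic range; the policy is
therefore an explicit parameter rather than a hidden choice.

**Length guard.** Several minimum-length recommendations exist
(`N ≫ d!`, `N ≥ 5d!`, `N > (d+1)!`). None is enforced hard: the package
warns (`SignalLengthWarning`) when fewer than `5·d!` windows are usable and
leaves the decision to the analyst, since profile scans deliberately visit
scales where the guard trips.

## Scaling families

**Coarse-graining (MPE/cMPE/rcMPE).** Scale `m` replaces non-overlapping
blocks of `m` consecutive samples by their mean; phase `k ∈ 1..m` starts
the blocks at offset `k`. Trailing samples that do not fill a block are
discarded (real `N` is rarely divisible). The block mean is an `m`-tap
constant-coefficient FIR filter followed by decimation — verified in-suite
against a convolution oracle — so coarse-graining both narrows the band and
low-pass filters within it.

**Downsampling (DPE/cDPE/rcDPE).** Factor `τ` keeps every `τ`-th sample;
the `τ` phases are disjoint and their union is the raw signal. No
anti-aliasing prefilter is applied by default — deliberately, because the
filter would itself reshape the ordinal statistics; an optional
`prefilter=True` (zero-phase Butterworth at 0.8× the post-decimation
Nyquist) exists for studying the aliasing regime. DPE is the PE of the
first phase; the library's plain `permutation_entropy` with delay `τ`
instead pools windows from *all* phases (the classical delay-embedding
count) — the two coincide at `τ = 1` and differ only by phase pooling
otherwise.

**Composite and refined composite.** Composite estimators average the
per-phase entropies; refined composite estimators average the per-phase
pattern pmfs first and evaluate a single entropy. Since Shannon entropy is
concave, the refined value always dominates the composite one (Jensen).
Per-phase pmfs enter the refined average with equal weights even though
phase lengths may differ by one window; `length_weighted=True` pools raw
counts instead (the two are indistinguishable at realistic lengths, and
the equal-weight mean matches the estimator's published definition).

**Numerical conventions.** Entropies are clipped to their exact bounds
(`[0, 1]` normalized) to absorb round-off; at-scale-1 all six estimators
collapse bit-for-bit to plain PE, which the suite asserts exactly.

## Scale ↔ bandwidth

Scaling by `m` lowers the effective sampling rate to `fs/m` and the
observable band to `fs/(2m)`. For 10 kHz sEMG, scale 10 → 1 kHz → 0–500 Hz,
the band that carries the physiological content; beyond the matched scale,
decimation aliases and all estimators drift toward the white-noise value.
The −3 dB cutoff of the `m`-tap averaging filter is found by root-finding
on `|sin(πmf/fs)/(m sin(πf/fs))| = 1/√2` over `(0, fs/m)` rather than the
`0.443·fs/m` approximation, so small-`m` cases are exact (`m=2` gives
`fs/4` analytically; `m=10` at 10 kHz gives 444.87 Hz). PSDs use Welch's
method (1 s Hann segments, 50 % overlap — configurable; the defaults are a
conventional choice, not a fitted one) rescaled to unit trapezoidal
integral so band-power ratios are scale-free.

## Synthetic cohort

The generator emulates a sustained-contraction sEMG study to second-order
statistics: per subject, four consecutive windows of band-limited Gaussian
noise at `fs = 10 kHz`, 27.4 s total (274,000 samples, the length of a
typical record in such protocols), band 20 Hz up to a per-window upper
edge of 500 → 400 → 320 → 250 Hz, plus a white instrumentation floor at
−30 dB relative to in-band power — chosen so the [0–500]/[500–5000] Hz
band-power ratio lands near 30 dB, the order observed in careful laboratory
acquisitions. Fatigue is modeled as this progressive spectral compression,
the spectral signature of action-potential lengthening; narrower bands
produce longer monotone ordinal runs and hence lower entropy at the
matched scale. The fresh window's 500 Hz edge equals the post-decimation
Nyquist at scale 10, so the discriminative scale is ~10 by construction.

Band-limiting uses a zero-phase spectral mask (unity in-band, half-cosine
tapers occupying the outer 5 % of the band, capped at 10 Hz, zero outside).
Zero phase avoids injecting asymmetric ordinal patterns, and the sharp edge
keeps out-of-band leakage below the noise floor, so the floor parameter
alone sets the band-power ratio; an IIR band-pass with its −3 dB point at
the band edge would leak several percent of the signal power into the
adjacent band and spoil that calibration. Seeding is hierarchical
(`SeedSequence` spawn: cohort → subject → window), making cohorts exactly
reproducible and subjects independent.

What the surrogate does **not** model: motor-unit action-potential trains
and recruitment, amplitude non-stationarity within a window, force-signal
coupling, electrode artifacts, or any non-Gaussian structure. Passing tests
therefore show that the estimators and pipeline behave correctly on signals
with the study's spectral geometry — not that real recordings will produce
these exact entropy values.

## Pipeline and statistics

Records are split into four equal consecutive windows (remainder dropped
from the end). Entropy-vs-scale profiles run over scales 1..100 by default,
with the downsampling factor tied to the scale (`τ = m`) so all methods
see the same effective rate. Window deltas use the five pairs
W1−W2, W1−W3, W1−W4, W2−W3, W3−W4 (earlier minus later, so fatigue gives
positive deltas). The discriminative scale maximizes the mean absolute
delta over subjects and pairs, ties broken toward the smaller scale — an
explicit operationalization of what is usually done by inspecting the
delta curves.

Statistics: repeated-measures ANOVA (statsmodels `AnovaRM`) on the balanced
within-subject design — fatigue step (or delta pair) × method × dimension
as within factors — with Bonferroni-corrected paired t-tests as post-hocs,
α = 0.05. Normality (Lilliefors on per-cell residuals) and variance
homogeneity (Levene) are *reported* alongside but never gate the analysis.
Both entry points — raw window entropies and pairwise deltas — are exposed,
since either can serve as the repeated measure.

Deliberately small problem sizes in the test suite (shortened cohorts,
restricted method/dimension grids) keep the default run quick; the
full-length default cohort with the complete scale grid is exercised once,
in the end-to-end acceptance test.

## Known limitations

- Estimator bias at high scales (few windows) is not corrected, only
  flagged by the length guard; closed-form bias/variance expressions are
  out of scope and covered empirically instead.
- `AnovaRM` requires a fully balanced design; unbalanced cohorts raise
  rather than silently dropping subjects.
- The generator's stationary-within-window assumption makes window
  boundaries artificially sharp compared with real fatigue progressions.
- Weighted/amplitude-aware PE variants and other entropy families (sample,
  Rényi) are intentionally absent.
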