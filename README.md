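# rcdpe — multiscale & downsampling permutation entropy for sEMG fatigue analysis

Surface electromyography (sEMG) records the summed electrical activity of a
muscle's motor units. As a muscle fatigues during a sustained contraction,
motor-unit action potentials lengthen and firing synchronizes, which biases
the signal toward long monotone stretches and *lowers its ordinal
complexity*. This package implements the permutation-entropy (PE) estimator
family used to track that complexity loss, for researchers analysing
electrophysiological time series and anyone who needs careful multiscale PE
estimators.

## The estimators

For a signal `x` of length `N`, embedding dimension `d` and delay `τ`, each
window `(x_n, x_{n+τ}, …, x_{n+(d−1)τ})` is coded by the permutation sorting
it ascending. With `p̂_i` the empirical frequency of pattern `i`,

    Ĥ = −Σ_{i=1}^{d!} p̂_i ln p̂_i,     normalized:  Ĥ / ln(d!)  ∈ [0, 1].

Scaling variants reduce the signal before the PE step:

| estimator | scaling | combination |
|---|---|---|
| MPE | mean of non-overlapping `m`-blocks (coarse-graining) | PE of the first phase |
| cMPE | all `m` block-offset phases | mean of per-phase PEs |
| rcMPE | all `m` phases | entropy of the mean per-phase pmf |
| DPE | keep every `τ`-th sample (decimation) | PE of the first phase |
| cDPE | all `τ` decimation phases | mean of per-phase PEs |
| rcDPE | all `τ` phases | entropy of the mean per-phase pmf |

Decimated phases partition the raw samples (no sample shared), so — unlike
coarse-grained phases, which overlap in block content — their pattern
distributions are free of artifact cross-correlation. That makes **rcDPE**
the lowest-variance member of the family on uncorrelated noise, which the
test suite verifies empirically.

Scaling by `m` divides the sampling rate: the observable band shrinks to
`fs/(2m)`. For sEMG sampled at 10 kHz, scale 10 maps the analysis onto the
physiological 0–500 Hz band — the spectral reasoning behind choosing the
analysis scale is in `rcdpe.spectral`.

## Worked example

```python
from rcdpe import gen_semg_surrogate, mpe, rcdpe, ma_filter_cutoff, effective_rate

sig = gen_semg_surrogate(fs=10_000.0, duration_s=10.0, band=(20, 500),
                         noise_floor_db=-30.0, seed=42)
print(rcdpe(sig, 1, 4).value, rcdpe(sig, 10, 4).value)   # 0.5555  0.9999
print(effective_rate(10_000.0, 10), ma_filter_cutoff(10, 10_000.0))  # 1000.0  444.87
```

The surrogate is band-limited noise mimicking sEMG: heavily oversampled at
10 kHz, its scale-1 entropy is low (0.5555 — adjacent samples are strongly
correlated); at scale 10 the effective rate is 1 kHz, the decimated signal
fills its whole band and the normalized rcDPE reaches 0.9999. The 10-tap
moving-average filter implicit in scale-10 coarse-graining cuts off at
444.9 Hz — right at the band edge.

`examples/` holds one narrative script per capability (ordinal basics,
multiscale profiles, scale↔bandwidth reasoning, the fatigue study). Running
`python examples/04_fatigue_study.py` simulates a 5-subject fatigue cohort
whose band compresses 500→400→320→250 Hz over the four windows W1..W4 and
prints the pipeline result: mean rcDPE at the selected scale falling
0.9669 → 0.8925 → 0.8157 → 0.7484 with the fatigue factor significant at
`F(3,12) ≈ 2961, p < 0.001` — the synthetic analogue of the entropy decline
seen in real fatigue recordings.

A thin CLI mirrors the stages: `rcdpe simulate`, `rcdpe pe`,
`rcdpe profile`, `rcdpe fatigue-study` (see `--help`).

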