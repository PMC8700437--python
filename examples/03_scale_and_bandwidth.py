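"""The scale <-> bandwidth link: why scale 10 suits 10 kHz sEMG.

Coarse-graining or downsampling by m divides the sampling rate by m, so
the observable band shrinks to fs/(2m).  For sEMG acquired at 10 kHz,
scale 10 yields a 1 kHz effective rate — exactly the 0-500 Hz band where
the physiological activity lives.  Coarse-graining additionally low-pass
filters with an m-tap moving average; its -3 dB cutoff for m=10 is about
445 Hz, right at that band edge.  The band-power ratio printed last shows
the surrogate's in-band dominance over the instrumentation noise floor.
"""

from rcdpe import (
    band_power_ratio_db,
    effective_rate,
    gen_semg_surrogate,
    ma_filter_cutoff,
    normalized_psd,
    nyquist_after,
)

fs = 10_000.0
print("scale  effective rate [Hz]  observable band [Hz]  MA cutoff [Hz]")
for m in (1, 2, 5, 10, 20):
    print(
        f"{m:5d}  {effective_rate(fs, m):19.0f}  0-{nyquist_after(fs, m):<18.0f}"
        f"  {ma_filter_cutoff(m, fs):8.1f}"
    )

sig = gen_semg_surrogate(fs=fs, duration_s=10.0, band=(20, 500), noise_floor_db=-30.0, seed=7)
psd = normalized_psd(sig)
ratio = band_power_ratio_db(psd, (0, 500), (500, 5000))
print(f"\nsurrogate band power ratio [0-500 Hz] / [500-5000 Hz]: {ratio:.1f} dB")
print(
    "~30 dB means the noise band carries a thousandth of the signal power,"
    "\nso decimation up to scale 10 folds back only negligible aliased noise."
)
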