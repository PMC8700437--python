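"""Entropy-vs-scale profiles: coarse-graining vs downsampling estimators.

A 10 kHz surrogate sEMG record (band-limited noise, 20-500 Hz) is heavily
oversampled, so adjacent samples are strongly correlated and scale-1 PE is
low.  Increasing the scale moves the analysis toward the signal's own
band: entropy rises and then flattens once the effective Nyquist falls
inside the band.  The refined composite estimators (rcMPE, rcDPE) average
the pattern distributions of all phase-shifted scaled signals before the
single entropy evaluation, which is why rcMPE >= cMPE and rcDPE >= cDPE
at every scale (Jensen's inequality).
"""

from rcdpe import cdpe, cmpe, gen_semg_surrogate, mpe, permutation_entropy, rcdpe, rcmpe, PESettings

sig = gen_semg_surrogate(fs=10_000.0, duration_s=10.0, band=(20, 500), noise_floor_db=-30.0, seed=42)

print("scale   MPE    cMPE   rcMPE   cDPE   rcDPE")
for m in (1, 2, 5, 10, 20, 40):
    row = [f(sig, m, 4).value for f in (mpe, cmpe, rcmpe, cdpe, rcdpe)]
    print(f"{m:5d}  " + "  ".join(f"{v:.4f}" for v in row))

pe1 = permutation_entropy(sig, PESettings(d=4)).value
print(f"\nplain PE at d=4: {pe1:.4f} (all estimators collapse to this at scale 1)")
print(
    "Values rise with scale as decimation/averaging whitens the oversampled"
    "\nband-limited signal, and the refined columns dominate their composite"
    "\ncounterparts at every scale."
)
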