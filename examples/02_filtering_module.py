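"""The temporal FIR filtering module as a standalone signal filter.

Builds a 4-tap moving-average bank, applies it causally to a noisy pulse
waveform, and reads its frequency response: the printed gains explain the
attenuation measured on the signal.
"""

import numpy as np

import videopulse as vp
from videopulse.fm_filter import FIRFilterBank, apply_fir, frequency_response

cfg = vp.SyntheticConfig(duration_s=20.0, hr_bpm=66.0, seed=1)
clean = vp.make_pulse_waveform(cfg)
rng = np.random.default_rng(0)
noisy = clean.samples + rng.normal(scale=1.0, size=clean.n_samples)

bank = FIRFilterBank(np.full((1, 4), 0.25))  # 4-tap boxcar, order K=3
smoothed = apply_fir(noisy, bank)

def snr(x):
    return 10 * np.log10(np.sum(clean.samples**2) / np.sum((clean.samples - x) ** 2))

print(f"SNR before filtering: {snr(noisy):6.2f} dB")
print(f"SNR after filtering:  {snr(smoothed):6.2f} dB")

freqs, gains = frequency_response(bank, fps=cfg.fps, n_freq=512)
for f in (1.1, 5.0, 10.0):
    g = np.abs(gains[0, np.argmin(np.abs(freqs - f))])
    print(f"|H({f:4.1f} Hz)| = {g:.3f}  ({20 * np.log10(g):6.1f} dB)")
# the pulse fundamental (~1.1 Hz) passes nearly unattenuated while
# high-frequency noise is suppressed, which is where the SNR gain comes from
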