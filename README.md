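# videopulse

Remote photoplethysmography (rPPG): recovering the blood volume pulse (BVP)
waveform — and from it the heart rate — from the minute skin-color
fluctuations in ordinary video. The package implements a two-branch
fully convolutional network whose distinguishing ingredient is the
**filtering module (FM)**: a learnable causal finite-impulse-response
operator applied along the time axis,

```
y(t) = Σ_{k=0..K} h(k) · x(t − k),
```

embedded at several points of the motion path so the network learns
band-selective temporal filters jointly with its spatial feature
extractors. Around the network it provides everything an rPPG study needs:

* **Preprocessing** — appearance input `A(t) = std((C(t)+C(t−1))/2)` and
  motion input `M(t) = std(C(t)−C(t−1))` (per-frame, per-channel standard
  scores), cut into 256-frame windows.
* **Network variants** — `fm-fcn` (FMs + fully convolutional temporal head),
  `fcn-can` (no FMs), `fm-can` (FMs + dense head), `can` (plain
  convolutional attention network), for ablation studies; training loop,
  checkpoints, windowed video inference. The backend is a compact
  tape-based autodiff engine on numpy (gradients are finite-difference
  checked in the test suite).
* **Classical baselines** — GREEN, CHROM, POS, PBV, LGI and FastICA-based
  blind source separation, all sharing one band-pass/standardization tail.
* **Heart rate** — zero-phase Butterworth band-pass (0.66–3.0 Hz) and
  FFT-peak estimation with zero padding; `bpm = 60·argmax|FFT|` in band.
* **Metrics** — waveform MAE / Pearson R / time-domain
  `SNR = 10·log10(Σy² / Σ(y−ŷ)²)`; heart-rate MAE, MRE, error SD, R and
  the clinical accuracy rate ACC (error within ±10% of reference or
  ±5 bpm, whichever is greater); Bland–Altman limits of agreement
  `mean ± 1.96·SD`; pairwise t-tests for model comparison.
* **Synthetic data** — a seeded generator rendering pulse-modulated skin
  patches (green-dominant gains, dicrotic secondary wave, illumination
  drift, motion jitter, sensor noise) with exact ground-truth waveforms,
  so the entire pipeline is testable without any dataset download.

## Worked example

```python
import videopulse as vp

cfg = vp.SyntheticConfig(duration_s=10.0, hr_bpm=72.0, seed=7)
frames, reference = vp.render_video(cfg)
waveform = vp.run_baseline("pos", frames, crop_fraction=1.0)
print(vp.estimate_hr(waveform).bpm)   # 72.0
```

Running `python examples/03_train_network.py` (16 synthetic training clips,
15 epochs, one CPU core, ~20 s) prints:

```
held-out windows: 4
heart-rate MAE:   0.44 bpm
clinical ACC:     100.0 %  (|err| <= max(5, 10%) bpm)
waveform r:       0.966
waveform SNR:     12.34 dB
```

i.e. the trained network rates every held-out window within clinical
tolerance and reconstructs the waveform at r ≈ 0.97. The other scripts in
`examples/` demonstrate the classical extractors, the standalone filtering
module, and Bland–Altman agreement analysis; `videopulse --help` lists the
equivalent command-line workflows (`synth`, `baseline`, `train`, `infer`,
`hr`, `evaluate`, `compare`).

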