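# Methods

## Signal model

A camera observing skin records, per color channel, an intensity matrix
C(t) whose pixels decompose as I_ij(t) = s_ij(t) + n_ij(t): a weak
quasi-periodic pulse component s (cardiac blood-volume changes modulating
light absorption, strongest in green) plus interference n (illumination
drift, motion, sensor noise). All ingestion scales integer pixel types by
their type maximum, so every downstream computation operates on [0,1]
floats.

## Preprocessing

Two network inputs are derived per frame pair, both standardized per frame
and per channel with the population standard deviation ("average value of
a frame" / "standard deviation of a frame" convention):

* appearance `A(t) = (Ave(t) − μ)/σ`, `Ave(t) = (C(t)+C(t−1))/2` — a
  denoised view of *where* skin is;
* motion `M(t) = (D(t) − μ)/σ`, `D(t) = C(t) − C(t−1)` — frame differencing
  removes common-mode intensity (ambient light, global gain) before
  standardization removes the remaining scale.

Conventions: `A(0)` copies `A(1)` and `M(0)` is zero so windows keep their
length; frames with spatial σ < 1e−6 emit zeros ("no variation means no
signal") rather than ε-regularized divisions, making static inputs exactly
neutral. Standardization is per frame; a per-clip alternative exists
behind the same helper but is not the default, since the per-frame reading
matches the stated per-frame μ/σ. Sequences are cut into non-overlapping
256-frame windows (~8.5 s at 30 fps — at least two pulse periods at the
lowest supported rate), each preprocessed independently; trailing
remainders are dropped.

Spatial resizing is exact area (box) averaging via interval-overlap
matrices, so constant frames stay constant and power-of-two cascades equal
direct downsampling.

## Filtering modules

The FM is a causal FIR filter along time, y[t] = Σ_{k=0..K} h(k)·x[t−k],
with one learnable tap vector per feature channel (shared over space, like
any convolution kernel). "Order 3" means K = 3 past taps, four
coefficients. Samples before t = 0 are supplied by replicating x[0]
(default) — avoiding the startup transient zero padding would inject into
the first K frames — or by zeros, by configuration. A pixelwise mode (one
response per pixel) is kept for standalone filtering. Taps initialize to
the identity response plus uniform noise of scale 0.01, so an untrained FM
is a near-pass-through and training shapes the frequency response
H(f) = Σ h(k)·exp(−i2πfk/fps), which `frequency_response` evaluates on
[0, fps/2]. No constraint (e.g. unit DC gain) is imposed on trained taps.

## Network

Two branches over a window of frames. The motion branch extracts the
pulse; the appearance branch computes per-frame spatial attention that
gates the motion features at each block junction. Blocks (each branch has
its own weights):

* **PCC** — two 3×3 convolutions (tanh), default 32 channels (8 at desk
  scale), clustering the principal image components;
* attention mask 1: 1×1 convolution on appearance features → sigmoid →
  per-frame L1 normalization scaled by H·W (mean gate of one, so the mask
  scale is immaterial), multiplied into motion features; then 2×2 average
  pooling and dropout;
* **SE** — two more 3×3 convolutions (tanh, default 64 channels), mask 2,
  pooling, dropout;
* **SR** — global (adaptive) spatial average pooling to one feature vector
  per frame, plus dropout;
* **filter block** — a pointwise channel-mixing map (tanh) on the per-frame
  vector, preceded in FM variants by an order-3 FM;
* **head** — fully convolutional: a temporal 1-D convolution (kernel 9,
  ≈0.3 s at 30 fps, below the shortest pulse period) and a pointwise
  convolution emitting one amplitude per frame. The dense alternative
  (CAN variants) flattens the per-frame spatial map into two fully
  connected layers, which is exactly what makes it the larger model.

FM placement in the motion path: after PCC (per channel over the feature
map), after SR (on the per-frame vector), inside the filter block, and a
terminal FM on the output waveform. The four variants — `fm-fcn`,
`fcn-can`, `fm-can`, `can` — share every non-FM parameter name, so a
variant with all FMs frozen to the identity response reproduces its
FM-free counterpart to float precision; the tests rely on this to isolate
the filtering as the only architectural delta.

Exact tensor sizes, dropout placement and mask arithmetic are this
package's reconstruction; they are recorded in `ModelConfig` (channel
widths, dropout rates, kernel sizes, seed) so any choice can be overridden.

## Training

Targets are the reference waveforms standardized per window (the estimated
amplitude is arbitrary); the loss is mean squared error; the optimizer is
Adam at 1e−3 (3e−3 at desk scale), batches of 2–4 windows, ≤30 epochs.
Training, dropout and shuffling derive from one integer seed, making loss
histories bit-reproducible. Divergence (non-finite loss) aborts with a
diagnostic rather than continuing. The numerical backend is a tape-based
reverse-mode autodiff engine over numpy arrays (im2col convolutions,
einsum FIR taps); parameters train in float32 for speed, and every layer's
analytic gradient is validated against central finite differences in
float64 in the test suite.

Inference on longer videos runs per window, standardizes each window's
output, and concatenates.

## Heart rate

Waveforms are band-passed with a zero-phase (forward–backward) order-3
Butterworth filter over 0.66–3.0 Hz (40–180 bpm, covering resting through
exercise rates). The rate is the maximal in-band bin of the magnitude
spectrum after mean removal and 4× zero padding (sub-bin resolution:
1.76 bpm for a 256-sample window at 30 fps), ties broken toward the lower
frequency; an all-zero waveform raises an explicit undefined-rate error
instead of returning NaN. Reference and estimated rates are computed with
identical machinery, per window.

## Metrics

Waveform quality on per-window standardized pairs: MAE, the
product-moment correlation R (clamped to [−1,1] against rounding), and
time-domain SNR = 10·log10(Σy²/Σ(y−ŷ)²) dB — the time-domain form is used
because a frequency-domain SNR can credit harmonic noise energy as signal.
A zero-residual pair reports the 80 dB cap rather than infinity.

Heart-rate accuracy per window series: MAE; MRE = mean(|e−r|/r)·100%; the
population standard deviation of the absolute errors; R; and
ACC = ATE/(ATE+UTE), the fraction of windows whose error is within
max(5 bpm, 10% of reference), boundary inclusive — the clinical
heart-rate tolerance. Agreement is summarized by Bland–Altman limits
mean(d) ± 1.96·SD(d) on signed differences, with the population SD for
consistency (a sample-SD flag is available for the conventional variant).
Models are compared by two-sided paired t-tests on aligned per-window
error series (α = 0.05), reporting the significance flag h, p, and the
confidence interval of the mean difference; an identically-zero difference
series yields p = 1, h = 0 by convention. Whether waveform metrics should
be pooled over all samples instead of averaged per window is not uniquely
determined; per-window-then-average is implemented.

## Classical baselines

All operate on the spatial-mean RGB trace of a centered crop (default
fraction 0.6 of each dimension; no skin detector) and share the band-pass
and standardization tail so comparisons are like-for-like. GREEN is the
band-passed green channel. CHROM normalizes channels by their windowed
temporal means, projects onto X = 3R−2G and Y = 1.5R+G−1.5B and combines
S = X − (σX/σY)·Y with Hann-weighted 50%-overlap-add (1.6 s windows).
POS uses sliding 1.6 s windows with S1 = G−B, S2 = G+B−2R,
h = S1 + (σS1/σS2)·S2 and per-sample overlap-add. PBV solves
(C_n C_nᵀ)w = p for the blood-volume signature p = (0.33, 0.77, 0.53)
(ridge-guarded) and outputs wᵀC_n. LGI removes the leading singular
direction of the mean-centered trace — the dominant common-mode variation —
and keeps the most pulse-energetic residual component; it therefore
*requires* some common-mode interference to anchor that direction, and on
a trace whose only variation is the pulse it would remove the pulse
itself. ICA detrends and standardizes the channels, unmixes three
components by seeded FastICA, and keeps the component with the strongest
in-band spectral peak, falling back to GREEN on non-convergence.

## Synthetic data

Each clip is a centered ellipse (half the frame area, 0.8 aspect) of skin
color (0.72, 0.55, 0.45) on a gray background. The pulse template is two
Gaussian bumps per cycle — systolic at phase 0.15 (width 0.08) and a
dicrotic secondary wave at 0.45 (width 0.12, relative height 0.3) — driven
through the configured heart-rate trajectory by phase integration, so
variable rates and morphology checks are both possible in closed form.
Skin pixels are modulated by `pulse_amplitude` (default 0.01, a realistic
~1% fractional intensity change) times green-dominant channel gains
(0.4, 1.0, 0.6), reflecting hemoglobin's absorption ordering. Interference
terms: a global sinusoidal illumination drift (amplitude 0.02 at 0.15 Hz,
below the pulse band), rigid per-frame translation jitter (SD 0.3 px), and
i.i.d. Gaussian sensor noise (SD 0.01, about 2.5 gray levels of 8-bit).
All randomness derives from one seed; datasets derive per-clip seeds
deterministically from a master seed.

What the generator does **not** emulate: articulated facial motion,
specular reflections, codec compression, skin-tone diversity,
ballistocardiographic waveform variability. Passing tests therefore
demonstrate correct mechanics and the expected ordering of methods under
controlled interference — not performance on real video.

## The desk-scale benchmark

The reference self-validation experiment (`videopulse.benchmark`) trains
each variant on 24 synthetic clips (heart rates uniform in 50–110 bpm,
default interference), evaluates on 12 held-out clips, with 8×8 inputs,
8/12 feature channels, 256-frame windows, 20 epochs at learning rate 3e−3
— sized so one training takes ~30 s on a single CPU core and the entire
train-all-variants experiment stays within a routine test run. At this
scale the trained network rates held-out windows with sub-bpm MAE and 100%
clinical ACC, and mean waveform SNR orders the variants
fm-fcn > fcn-can > fm-can > can, the filtering modules and the
convolutional head each contributing several dB.

## Numerical conventions and edge cases

* Population (÷N) standard deviations throughout the metrics.
* Zero-variance guards: static frames → zero outputs (preprocessing);
  constant traces → zero waveforms (baselines); constant series → explicit
  errors (correlation, spectral rate).
* SNR capped at 80 dB; masks normalized to mean gate 1; FFT peak ties go
  to the lower frequency.
* Waveform resampling is linear interpolation on [0, (N−1)/fps] with
  clamped endpoints; reference traces are resampled to the video rate
  before comparison, since metrics pair samples on a common grid.
* Timestamps in label files are seconds; irregular spacing is interpolated
  to a uniform grid.

## Limitations

Inputs are assumed to be face-centered skin crops; no face detection,
tracking or skin segmentation is provided. The network backend favors
clarity and testability over throughput — full-scale (36×36, hundreds of
clips) training is possible but slow on one core. Interbeat-interval and
heart-rate-variability analysis are out of scope.
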