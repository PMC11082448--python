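"""Two-branch pulse-extraction networks with learnable filtering modules.

The motion branch extracts the pulse from standardized frame differences;
the appearance branch, fed with averaged frames, produces per-frame spatial
attention masks that gate the motion features at each block junction.  Four
variants share the convolutional trunk:

* ``fm-fcn``  — filtering modules (FMs) in the motion path plus a fully
  convolutional temporal head emitting one waveform sample per frame.
* ``fcn-can`` — the same network without FMs.
* ``fm-can``  — FMs plus a dense (fully connected) per-frame head.
* ``can``     — convolutional attention network: no FMs, dense head.

Blocks: PCC (2 conv layers clustering principal image components), SE
(pool + dropout + 2 conv layers), SR (global spatial pooling + dropout
producing the per-frame signal vector), and a filter block (channel-mixing
map, preceded by an FM in the FM variants) before the head.  All FMs are
order-``fm_order`` causal FIR taps per feature channel, initialized near
identity; a variant with FMs frozen to the identity response reproduces its
FM-free counterpart exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from ._nn import Adam, Tensor, ops
from .fm_filter import FMLayer
from .io_media import BVPWaveform, FrameSequence
from .preprocess import ClipPair, spatial_downsample, window_clips

__all__ = ["ModelConfig", "PulseNet", "build_model", "train_model", "infer_video",
           "save_checkpoint", "load_checkpoint", "VARIANTS"]

VARIANTS = ("fm-fcn", "fm-can", "fcn-can", "can")


@dataclass
class ModelConfig:
    variant: str = "fm-fcn"
    input_size: int = 36
    window: int = 256
    conv_channels: tuple[int, int] = (32, 64)
    fm_order: int = 3
    dropout_rates: tuple[float, float, float] = (0.25, 0.25, 0.5)
    head_hidden: int = 128  # dense-head width (CAN variants)
    fcn_kernel: int = 9  # temporal kernel of the FCN head
    dtype: str = "float32"  # training precision; float64 for gradient audits
    seed: int = 0

    def __post_init__(self):
        self.variant = self.variant.lower().replace("_", "-")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.window < 2 * self.fm_order:
            raise ValueError("window must be at least twice the FM order")
        if any(not 0 <= r < 1 for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.input_size % 4:
            raise ValueError("input_size must be divisible by 4 (two 2x2 pools)")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")

    @property
    def has_fm(self) -> bool:
        return self.variant in ("fm-fcn", "fm-can")

    @property
    def fcn_head(self) -> bool:
        return self.variant in ("fm-fcn", "fcn-can")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class PulseNet:
    """A built network instance; parameters live in a flat named dict."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c1, c2 = cfg.conv_channels
        self.params: dict[str, Tensor] = {}
        self.fms: dict[str, FMLayer] = {}
        p = self.params

        def conv(name: str, cin: int, cout: int, k: int = 3):
            p[f"{name}.w"] = Tensor(
                _glorot(rng, (k, k, cin, cout), k * k * cin, k * k * cout),
                requires_grad=True,
            )
            p[f"{name}.b"] = Tensor(np.zeros(cout), requires_grad=True)

        # shared trunk (both branches have their own weights)
        for branch in ("app", "mot"):
            conv(f"{branch}.pcc1", 3, c1)
            conv(f"{branch}.pcc2", c1, c1)
            conv(f"{branch}.se1", c1, c2)
            conv(f"{branch}.se2", c2, c2)
        conv("mask1", c1, 1, k=1)
        conv("mask2", c2, 1, k=1)

        # filter block: channel mixing on the per-frame signal vector
        p["mix.w"] = Tensor(_glorot(rng, (c2, c2), c2, c2), requires_grad=True)
        p["mix.b"] = Tensor(np.zeros(c2), requires_grad=True)

        s2 = cfg.input_size // 4  # spatial size after two 2x2 pools
        if cfg.fcn_head:
            k = cfg.fcn_kernel
            p["head1.w"] = Tensor(
                _glorot(rng, (k, c2, c2), k * c2, k * c2), requires_grad=True
            )
            p["head1.b"] = Tensor(np.zeros(c2), requires_grad=True)
            p["head2.w"] = Tensor(_glorot(rng, (1, c2, 1), c2, 1), requires_grad=True)
            p["head2.b"] = Tensor(np.zeros(1), requires_grad=True)
        else:
            flat = s2 * s2 * c2
            p["fc1.w"] = Tensor(
                _glorot(rng, (flat, cfg.head_hidden), flat, cfg.head_hidden),
                requires_grad=True,
            )
            p["fc1.b"] = Tensor(np.zeros(cfg.head_hidden), requires_grad=True)
            p["fc2.w"] = Tensor(
                _glorot(rng, (cfg.head_hidden, 1), cfg.head_hidden, 1),
                requires_grad=True,
            )
            p["fc2.b"] = Tensor(np.zeros(1), requires_grad=True)

        if cfg.has_fm:
            fm_rng = np.random.default_rng(rng.integers(2**31 - 1))
            self.fms["fm_pcc"] = FMLayer(c1, cfg.fm_order, rng=fm_rng)
            if cfg.fcn_head:
                self.fms["fm_sr"] = FMLayer(c2, cfg.fm_order, rng=fm_rng)
            else:
                self.fms["fm_sr"] = FMLayer(s2 * s2 * c2, cfg.fm_order, rng=fm_rng)
            self.fms["fm_filter"] = FMLayer(c2, cfg.fm_order, rng=fm_rng)
            self.fms["fm_out"] = FMLayer(1, cfg.fm_order, rng=fm_rng)
            for name, fm in self.fms.items():
                p[f"{name}.h"] = fm.taps

        self._dt = np.dtype(cfg.dtype)
        for tensor in p.values():
            tensor.data = tensor.data.astype(self._dt)
        self._drop_rng = np.random.default_rng(cfg.seed + 1)

    # -- parameter plumbing -----------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> None:
        for k, v in state.items():
            if k not in self.params:
                if strict:
                    raise KeyError(f"unexpected parameter {k!r}")
                continue
            if self.params[k].data.shape != np.asarray(v).shape:
                raise ValueError(f"shape mismatch for {k!r}")
            self.params[k].data[:] = v

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def freeze_fms_to_identity(self) -> None:
        """Set every filtering module to the exact pass-through response."""
        for fm in self.fms.values():
            fm.set_identity()

    # -- forward -----------------------------------------------------------

    def _fm_map(self, x: Tensor, fm: FMLayer, b: int, t: int) -> Tensor:
        """Apply an FM over time to a (B*T,H,W,C) feature map."""
        _, h, w, c = x.shape
        xt = x.reshape(b, t, h, w, c).transpose(0, 2, 3, 1, 4).reshape(b * h * w, t, c)
        yt = fm(xt)
        return yt.reshape(b, h, w, t, c).transpose(0, 3, 1, 2, 4).reshape(b * t, h, w, c)

    def _mask(self, feats: Tensor, name: str) -> Tensor:
        """Sigmoid 1x1-conv attention, L1-normalized to a mean gate of one."""
        m = ops.conv2d(feats, self.params[f"{name}.w"], self.params[f"{name}.b"]).sigmoid()
        _, h, w, _ = m.shape
        total = m.sum(axis=(1, 2), keepdims=True)
        return m * float(h * w) / total

    def forward_batch(self, appearance: np.ndarray, motion: np.ndarray,
                      training: bool = False) -> Tensor:
        """(B,T,H,W,3) appearance and motion -> (B,T) waveform tensor."""
        cfg = self.cfg
        b, t = appearance.shape[:2]
        d1, d2, d3 = cfg.dropout_rates
        rng = self._drop_rng
        p = self.params
        sz = appearance.shape[2]
        flat_shape = (b * t, sz, sz, 3)
        a = Tensor(np.ascontiguousarray(appearance.reshape(flat_shape), dtype=self._dt))
        m = Tensor(np.ascontiguousarray(motion.reshape(flat_shape), dtype=self._dt))

        # PCC block
        a = ops.conv2d(a, p["app.pcc1.w"], p["app.pcc1.b"]).tanh()
        a = ops.conv2d(a, p["app.pcc2.w"], p["app.pcc2.b"]).tanh()
        m = ops.conv2d(m, p["mot.pcc1.w"], p["mot.pcc1.b"]).tanh()
        m = ops.conv2d(m, p["mot.pcc2.w"], p["mot.pcc2.b"]).tanh()
        if cfg.has_fm:
            m = self._fm_map(m, self.fms["fm_pcc"], b, t)
        m = m * self._mask(a, "mask1")
        a = ops.dropout(ops.avg_pool2d(a), d1, rng, training)
        m = ops.dropout(ops.avg_pool2d(m), d1, rng, training)

        # SE block
        a = ops.conv2d(a, p["app.se1.w"], p["app.se1.b"]).tanh()
        a = ops.conv2d(a, p["app.se2.w"], p["app.se2.b"]).tanh()
        m = ops.conv2d(m, p["mot.se1.w"], p["mot.se1.b"]).tanh()
        m = ops.conv2d(m, p["mot.se2.w"], p["mot.se2.b"]).tanh()
        m = m * self._mask(a, "mask2")
        m = ops.dropout(ops.avg_pool2d(m), d2, rng, training)

        if cfg.fcn_head:
            # SR block: adaptive (global) spatial pooling to one vector per frame
            v = ops.spatial_mean(m).reshape(b, t, -1)
            v = ops.dropout(v, d3, rng, training)
            if cfg.has_fm:
                v = self.fms["fm_sr"](v)
                v = self.fms["fm_filter"](v)
            v = ops.dense(v, p["mix.w"], p["mix.b"]).tanh()  # filter-block mixing
            v = ops.conv1d(v, p["head1.w"], p["head1.b"]).tanh()
            out = ops.conv1d(v, p["head2.w"], p["head2.b"])  # (B,T,1)
        else:
            _, h2, w2, c2 = m.shape
            v = m.reshape(b, t, h2 * w2 * c2)
            v = ops.dropout(v, d3, rng, training)
            if cfg.has_fm:
                v = self.fms["fm_sr"](v)
            v = ops.dense(v, p["fc1.w"], p["fc1.b"]).tanh()
            out = ops.dense(v, p["fc2.w"], p["fc2.b"])  # (B,T,1)
        if cfg.has_fm:
            out = self.fms["fm_out"](out)
        return out.reshape(b, t)

    def forward(self, clip: ClipPair) -> BVPWaveform:
        """Evaluation-mode forward pass on one window."""
        if clip.appearance.shape[1] != self.cfg.input_size:
            raise ValueError(
                f"clip size {clip.appearance.shape[1]} does not match model "
                f"input_size {self.cfg.input_size}"
            )
        out = self.forward_batch(clip.appearance[None], clip.motion[None],
                                 training=False)
        return BVPWaveform(out.data[0], fps=clip.fps, role="estimated")

    __call__ = forward


def build_model(cfg: ModelConfig) -> PulseNet:
    """Construct a seeded network instance for the configured variant."""
    return PulseNet(cfg)


def _standardize_target(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    sd = y.std()
    return (y - y.mean()) / (sd if sd > 0 else 1.0)


def train_model(
    model: PulseNet,
    train: list[tuple[ClipPair, BVPWaveform]],
    val: list[tuple[ClipPair, BVPWaveform]] | None = None,
    lr: float = 1e-3,
    epochs: int = 30,
    batch_size: int = 2,
    seed: int | None = None,
) -> list[dict]:
    """Minimize MSE between predicted and standardized reference waveforms.

    Returns the per-epoch history [{'epoch', 'train_loss', 'val_loss'}, ...].
    A fixed seed makes the shuffling, dropout and therefore the whole loss
    history reproducible.
    """
    if not train:
        raise ValueError("training set is empty")
    seed = model.cfg.seed if seed is None else seed
    shuffle_rng = np.random.default_rng(seed + 10_000)
    model._drop_rng = np.random.default_rng(seed + 20_000)
    opt = Adam(model.params, lr=lr)

    def stack(batch):
        app = np.stack([c.appearance for c, _ in batch])
        mot = np.stack([c.motion for c, _ in batch])
        tgt = np.stack([_standardize_target(w.samples[: c.n_frames]) for c, w in batch])
        return app, mot, tgt

    history: list[dict] = []
    idx = np.arange(len(train))
    for epoch in range(epochs):
        shuffle_rng.shuffle(idx)
        losses = []
        for start in range(0, len(idx), batch_size):
            batch = [train[i] for i in idx[start : start + batch_size]]
            app, mot, tgt = stack(batch)
            pred = model.forward_batch(app, mot, training=True)
            loss = ops.mse(pred, tgt)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val:
            vlosses = []
            for vstart in range(0, len(val), batch_size):
                app, mot, tgt = stack(val[vstart : vstart + batch_size])
                pred = model.forward_batch(app, mot, training=False)
                vlosses.append(float(ops.mse(pred, tgt).data))
            rec["val_loss"] = float(np.mean(vlosses))
        history.append(rec)
    return history


def infer_video(model: PulseNet, fs: FrameSequence) -> BVPWaveform:
    """Window a sequence, run per-window forward passes, stitch the outputs.

    Each window's output is standardized before concatenation (the network
    amplitude is arbitrary); the result is sampled at the video fps.
    """
    cfg = model.cfg
    if fs.n_frames < cfg.window:
        raise ValueError(
            f"need at least {cfg.window} frames ({cfg.window / fs.fps:.1f} s at "
            f"{fs.fps} fps), got {fs.n_frames}"
        )
    if fs.frames.shape[1] != cfg.input_size or fs.frames.shape[2] != cfg.input_size:
        fs = spatial_downsample(fs, cfg.input_size)
    clips = window_clips(fs, window=cfg.window)
    pieces = [_standardize_target(model.forward(c).samples) for c in clips]
    return BVPWaveform(np.concatenate(pieces), fps=fs.fps, role="estimated")


def save_checkpoint(model: PulseNet, path: str | Path) -> Path:
    """Single-file .npz archive holding parameters plus the full config."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {f"param::{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(asdict(model.cfg)))
    np.savez(path, **payload)
    return path


def load_checkpoint(path: str | Path) -> PulseNet:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg_raw = json.loads(str(data["config_json"]))
        for key in ("conv_channels", "dropout_rates"):
            cfg_raw[key] = tuple(cfg_raw[key])
        cfg = ModelConfig(**cfg_raw)
        model = PulseNet(cfg)
        model.load_state_dict(
            {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
        )
    return model
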