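"""Multi-task nuclei segmentation network.

The architecture follows the HoVer-Net family contract: a shared
convolutional encoder and three task-specific decoders that emit

* ``foreground`` — per-pixel nucleus probability,
* ``class_probs`` — per-pixel distribution over background + 5 cell types,
* ``dist``/``flow`` — the scalar distance field and its unit-gradient flow
  used by the flow-tracking post-processing.

The network itself is a deliberately small residual-free fully
convolutional net (two encoder stages with a single 2x downsampling, skip
connections into each decoder) implemented directly on numpy arrays with
hand-written backpropagation (im2col convolutions, Adam).  It is sized for
CPU training on synthetic patches: the segmentation *procedure* —
multi-task heads, flow post-processing, panoptic scoring — is the point,
not ImageNet-scale capacity.  Width, learning rate and epochs are all
config-driven.

Losses: cross-entropy for the foreground and class heads; mean-squared
error for the distance and flow regressions, the flow loss masked to
foreground pixels.  All stochasticity (weight init) is seeded through
``ModelConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ModelConfig",
    "NetworkOutput",
    "SegModel",
    "build_model",
    "train",
    "predict",
    "predict_image",
    "save_checkpoint",
    "load_checkpoint",
]

#: the distance head regresses dist / DIST_SCALE to keep head magnitudes comparable
DIST_SCALE = 5.0
N_CLASSES = 5  # cell types; class head emits N_CLASSES + 1 channels (background first)
DOWNSAMPLE = 2  # encoder downsampling factor


@dataclass
class ModelConfig:
    channels: int = 16  # encoder base width; deep stage uses 2x
    patch_size: int = 64
    learning_rate: float = 5e-3
    epochs: int = 300
    batch_size: int = 4
    seed: int = 0
    dtype: str = "float32"  # float64 only for gradient checking

    def validate(self) -> None:
        for name in ("channels", "patch_size", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0 (0 freezes the parameters)")
        if self.patch_size % DOWNSAMPLE != 0:
            raise ValueError(
                f"patch_size must be divisible by the encoder downsampling factor "
                f"({DOWNSAMPLE}); got {self.patch_size}"
            )


@dataclass
class NetworkOutput:
    """Per-pixel network outputs for one image."""

    foreground: np.ndarray  # (H, W) in [0, 1]
    class_probs: np.ndarray  # (6, H, W), sums to 1 per pixel
    dist: np.ndarray  # (H, W) >= 0
    flow: np.ndarray  # (2, H, W)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    v = sliding_window_view(xp, (k, k), axis=(2, 3))  # n,c,h,w,k,k
    return np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    n, c, h, w = x_shape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    return dxp[:, :, p : p + h, p : p + w]


class _Conv:
    """k x k same-padding convolution, stride 1."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = cin * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k = k
        self.cin = cin
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        self._cols, self._xshape = cols, x.shape
        out = np.matmul(self.w[None], cols)  # (n, cout, h*w)
        out += self.b[None, :, None]
        return out.reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, co, h, w = dout.shape
        dflat = dout.reshape(n, co, h * w)
        self.dw += np.matmul(dflat, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.db += dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T[None], dflat)
        return _col2im(dcols, self._xshape, self.k)

    def params(self):
        yield self.w, self.dw
        yield self.b, self.db


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


def _avgpool2(x):
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_back(dout):
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) * 0.25


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample2_back(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


_HEADS = {"fg": 1, "type": N_CLASSES + 1, "geom": 3}


class SegModel:
    """Shared encoder + three decoders, trained with Adam."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        c = config.channels
        dt = np.dtype(config.dtype).type
        self.dtype = dt
        rng = np.random.default_rng(config.seed)
        self.layers: dict[str, _Conv] = {
            "e1": _Conv(3, c, 3, rng, dt),
            "e2": _Conv(c, c, 3, rng, dt),
            "e3": _Conv(c, 2 * c, 3, rng, dt),
            "e4": _Conv(2 * c, 2 * c, 3, rng, dt),
        }
        for head, nout in _HEADS.items():
            self.layers[f"{head}_up"] = _Conv(2 * c, c, 3, rng, dt)
            self.layers[f"{head}_skip"] = _Conv(c, c, 1, rng, dt)
            self.layers[f"{head}_mid"] = _Conv(c, c, 3, rng, dt)
            self.layers[f"{head}_out"] = _Conv(c, nout, 1, rng, dt)
        self._relus: dict[str, _ReLU] = {}
        self._adam_t = 0
        self._adam_m = {k: [np.zeros_like(p) for p, _ in ly.params()] for k, ly in self.layers.items()}
        self._adam_v = {k: [np.zeros_like(p) for p, _ in ly.params()] for k, ly in self.layers.items()}

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """x: (N, 3, H, W) float in [0, 1]; H, W divisible by DOWNSAMPLE."""
        r = self._relus = {k: _ReLU() for k in
                           ["e1", "e2", "e3", "e4"] +
                           [f"{h}_{s}" for h in _HEADS for s in ("a", "m")]}
        L = self.layers
        e1 = r["e1"].forward(L["e1"].forward(x))
        e2 = r["e2"].forward(L["e2"].forward(e1))
        p = _avgpool2(e2)
        e3 = r["e3"].forward(L["e3"].forward(p))
        e4 = r["e4"].forward(L["e4"].forward(e3))
        self._e2 = e2
        out = {}
        for h in _HEADS:
            u = _upsample2(e4)
            a = L[f"{h}_up"].forward(u)
            s = L[f"{h}_skip"].forward(e2)
            x1 = r[f"{h}_a"].forward(a + s)
            x2 = r[f"{h}_m"].forward(L[f"{h}_mid"].forward(x1))
            out[h] = L[f"{h}_out"].forward(x2)
        return out

    def backward(self, grads: dict[str, np.ndarray]) -> None:
        L, r = self.layers, self._relus
        d_e4 = None
        d_e2_skip = None
        for h in _HEADS:
            d = L[f"{h}_out"].backward(grads[h])
            d = r[f"{h}_m"].backward(d)
            d = L[f"{h}_mid"].backward(d)
            d = r[f"{h}_a"].backward(d)
            da = L[f"{h}_up"].backward(d)
            ds = L[f"{h}_skip"].backward(d)
            du = _upsample2_back(da)
            d_e4 = du if d_e4 is None else d_e4 + du
            d_e2_skip = ds if d_e2_skip is None else d_e2_skip + ds
        d = r["e4"].backward(d_e4)
        d = L["e4"].backward(d)
        d = r["e3"].backward(d)
        d = L["e3"].backward(d)
        d = _avgpool2_back(d)
        d = d + d_e2_skip
        d = r["e2"].backward(d)
        d = L["e2"].backward(d)
        d = r["e1"].backward(d)
        L["e1"].backward(d)

    def zero_grad(self) -> None:
        for ly in self.layers.values():
            ly.dw[:] = 0.0
            ly.db[:] = 0.0

    def adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, ly in self.layers.items():
            for i, (p, g) in enumerate(ly.params()):
                m = self._adam_m[k][i]
                v = self._adam_v[k][i]
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                mh = m / (1 - beta1**t)
                vh = v / (1 - beta2**t)
                p -= lr * mh / (np.sqrt(vh) + eps)

    # -- parameter access for checkpoints ---------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {}
        for k, ly in self.layers.items():
            d[f"{k}.w"] = ly.w
            d[f"{k}.b"] = ly.b
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for k, ly in self.layers.items():
            ly.w = np.array(d[f"{k}.w"], dtype=self.dtype)
            ly.b = np.array(d[f"{k}.b"], dtype=self.dtype)


def build_model(config: ModelConfig) -> SegModel:
    """Construct the network; parameter initialisation is seeded."""
    return SegModel(config)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _sigmoid(z):
    return 0.5 * (np.tanh(0.5 * z) + 1.0)


def _softmax(z, axis=1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _losses_and_grads(out: dict[str, np.ndarray], targets: dict[str, np.ndarray]):
    """Combined multi-task loss and per-head gradients.

    targets: fg (N,H,W) {0,1}; cls (N,H,W) int 0..5; dist (N,H,W) already
    divided by DIST_SCALE; flow (N,2,H,W) unit vectors.
    """
    n, _, h, w = out["fg"].shape
    npix = n * h * w

    z = out["fg"][:, 0]
    t = targets["fg"]
    p = _sigmoid(z)
    bce = -(t * np.log(p + 1e-12) + (1 - t) * np.log(1 - p + 1e-12)).sum() / npix
    g_fg = ((p - t) / npix)[:, None]

    zc = out["type"]
    probs = _softmax(zc, axis=1)
    cls = targets["cls"]
    onehot = np.eye(probs.shape[1], dtype=probs.dtype)[cls].transpose(0, 3, 1, 2)
    ce = -(onehot * np.log(probs + 1e-12)).sum() / npix
    g_type = (probs - onehot) / npix

    geom = out["geom"]
    dist_t = targets["dist"]
    flow_t = targets["flow"]
    fgm = targets["fg"][:, None]
    d_err = geom[:, 0] - dist_t
    mse_d = (d_err**2).sum() / npix
    nfg = max(float(fgm.sum()), 1.0)
    f_err = (geom[:, 1:] - flow_t) * fgm
    mse_f = (f_err**2).sum() / nfg
    g_geom = np.empty_like(geom)
    g_geom[:, 0] = 2.0 * d_err / npix
    g_geom[:, 1:] = 2.0 * f_err / nfg

    total = bce + ce + mse_d + mse_f
    parts = {"bce": bce, "ce": ce, "mse_dist": mse_d, "mse_flow": mse_f}
    return total, parts, {"fg": g_fg, "type": g_type, "geom": g_geom}


def _stack_targets(targets_list, dtype=np.float32) -> dict[str, np.ndarray]:
    return {
        "fg": np.stack([t.foreground.astype(dtype) for t in targets_list]),
        "cls": np.stack([t.class_map.astype(np.int64) for t in targets_list]),
        "dist": np.stack([(t.dist / DIST_SCALE).astype(dtype) for t in targets_list]),
        "flow": np.stack([t.flow.astype(dtype) for t in targets_list]),
    }


def _prep_images(images, dtype=np.float32) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=dtype) / dtype(255.0) for im in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def train(model: SegModel, scenes, config: ModelConfig | None = None):
    """Full-batch training on a list of synthetic scenes.

    Targets are derived with :func:`henuclei.synthetic.scene_to_training_targets`.
    Returns (model, loss_history).  Raises on an empty dataset.
    """
    from .synthetic import scene_to_training_targets

    if config is None:
        config = model.config
    scenes = list(scenes)
    if not scenes:
        raise ValueError("training requires at least one scene")
    x = _prep_images([s.image for s in scenes], dtype=model.dtype)
    tgt = _stack_targets([scene_to_training_targets(s) for s in scenes], dtype=model.dtype)
    history: list[float] = []
    bs = min(config.batch_size, len(scenes))
    for _epoch in range(config.epochs):
        epoch_loss = 0.0
        for start in range(0, len(scenes), bs):
            sl = slice(start, min(start + bs, len(scenes)))
            out = model.forward(x[sl])
            loss, _parts, grads = _losses_and_grads(
                out, {k: v[sl] for k, v in tgt.items()}
            )
            if config.learning_rate > 0:
                model.zero_grad()
                model.backward(grads)
                model.adam_step(config.learning_rate)
            epoch_loss += loss * (sl.stop - start)
        history.append(epoch_loss / len(scenes))
    return model, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _output_from_raw(raw: dict[str, np.ndarray]) -> NetworkOutput:
    fg = _sigmoid(raw["fg"][0, 0])
    probs = _softmax(raw["type"], axis=1)[0]
    dist = np.maximum(raw["geom"][0, 0], 0.0) * DIST_SCALE
    flow = raw["geom"][0, 1:]
    return NetworkOutput(foreground=fg, class_probs=probs, dist=dist, flow=flow)


def predict(model: SegModel, image: np.ndarray) -> NetworkOutput:
    """Single-tile inference on an RGB uint8 image (H, W divisible by 2)."""
    x = _prep_images([image], dtype=model.dtype)
    return _output_from_raw(model.forward(x))


def predict_image(
    model: SegModel,
    image: np.ndarray,
    patch_size: int | None = None,
    margin: int = 8,
) -> NetworkOutput:
    """Tiled whole-image inference with overlap stitching.

    Tiles of ``patch_size`` overlap by ``2*margin``; only each tile's
    central region is kept, so a fully convolutional model produces a
    seamless field.  The image is reflect-padded to cover the borders and
    any size mismatch.  Deterministic.
    """
    if patch_size is None:
        patch_size = model.config.patch_size
    if margin >= patch_size / 2:
        raise ValueError("margin must be smaller than patch_size / 2")
    if margin % DOWNSAMPLE or patch_size % DOWNSAMPLE:
        raise ValueError("patch_size and margin must be divisible by the downsampling factor")
    h, w = image.shape[:2]
    if h <= patch_size and w <= patch_size and h == patch_size and w == patch_size:
        return predict(model, image)

    core = patch_size - 2 * margin
    ph = int(np.ceil(h / core)) * core
    pw = int(np.ceil(w / core)) * core
    padded = np.pad(
        image,
        ((margin, ph - h + margin), (margin, pw - w + margin), (0, 0)),
        mode="reflect",
    )
    fg = np.zeros((ph, pw))
    probs = np.zeros((N_CLASSES + 1, ph, pw))
    dist = np.zeros((ph, pw))
    flow = np.zeros((2, ph, pw))
    for top in range(0, ph, core):
        for left in range(0, pw, core):
            tile = padded[top : top + patch_size, left : left + patch_size]
            o = predict(model, tile)
            sl = (slice(top, top + core), slice(left, left + core))
            c = (slice(margin, margin + core),) * 2
            fg[sl] = o.foreground[c]
            probs[(slice(None),) + sl] = o.class_probs[(slice(None),) + c]
            dist[sl] = o.dist[c]
            flow[(slice(None),) + sl] = o.flow[(slice(None),) + c]
    return NetworkOutput(
        foreground=fg[:h, :w],
        class_probs=probs[:, :h, :w],
        dist=dist[:h, :w],
        flow=flow[:, :h, :w],
    )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: SegModel, path) -> None:
    """Single-file checkpoint with the config embedded."""
    np.savez(path, __config__=json.dumps(asdict(model.config)), **model.state_dict())


def load_checkpoint(path) -> SegModel:
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig(**json.loads(str(data["__config__"])))
        model = SegModel(config)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
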