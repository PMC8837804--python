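"""Projection-domain U-Net mapping polyenergetic to virtual monoenergetic
line-integral images, implemented in NumPy with manual backpropagation.

Architecture: a symmetric encoder/decoder.  Each level applies two 3x3
convolutions (zero-padded, stride 1) each followed by a ReLU; levels are
connected by 2x2 max pooling on the way down and bilinear x2 upsampling plus
channel-wise concatenation of the matching encoder output on the way up.
Feature maps double per level from ``base_features`` to
``base_features * 2**(depth-1)``.  No batch normalization or other input
scaling is applied, so the network operates directly on the physical
-ln(I/I0) scale.  A final 1x1 convolution (zero-initialized by default, so
an untrained network predicts zero) maps back to a single channel.

Training minimizes the mean absolute error with Adam.  The full-scale
configuration matches the reference protocol (depth 7, 16..1024 features,
Adam 1e-5, beta1 0.900, beta2 0.999, batch 18, 300 epochs); the desk-scale
configuration (depth 4, base 8, 100 epochs) compensates its ~30x smaller
update budget with a larger, cosine-annealed learning rate (see
docs/methods.md for the rationale).

Everything is float32 and fully seeded; inference is a pure function.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetConfig",
    "TrainedModel",
    "UNet",
    "build_network",
    "split_dataset",
    "split_indices",
    "train",
    "predict",
    "predict_images",
    "desk_config",
]


@dataclass(frozen=True)
class NetConfig:
    """Hyperparameters of the network and its training run."""

    depth: int = 7
    base_features: int = 16
    kernel: int = 3
    learning_rate: float = 1e-5
    beta1: float = 0.900
    beta2: float = 0.999
    batch_size: int = 18
    epochs: int = 300
    lr_schedule: str = "constant"      # 'constant' | 'cosine' | 'warmup-cosine'
    seed: int = 0
    final_zero_init: bool = True

    def __post_init__(self):
        if self.depth < 1 or self.base_features < 1:
            raise ValueError("depth and base_features must be >= 1")
        if self.lr_schedule not in ("constant", "cosine", "warmup-cosine"):
            raise ValueError(
                "lr_schedule must be 'constant', 'cosine' or 'warmup-cosine'")

    @property
    def bottleneck_features(self) -> int:
        return self.base_features * 2 ** (self.depth - 1)

    @property
    def divisor(self) -> int:
        """Required divisor of the input spatial dimensions."""
        return 2 ** (self.depth - 1)


def desk_config(seed: int = 0, epochs: int = 100,
                learning_rate: float = 6e-3) -> NetConfig:
    """The reduced configuration used for desk-scale end-to-end runs."""
    return NetConfig(depth=4, base_features=8, epochs=epochs,
                     learning_rate=learning_rate, lr_schedule="cosine",
                     seed=seed)


# ---------------------------------------------------------------------------
# Layers (forward caches what backward needs; grads accumulate in .dW/.db)
# ---------------------------------------------------------------------------

class _Conv:
    """Same-padded convolution as k*k shifted batched GEMMs over cached
    contiguous input slices (fastest variant at these layer sizes)."""

    def __init__(self, cin, cout, k, rng, zero_init=False):
        self.k = k
        fan_in = cin * k * k
        if zero_init:
            self.W = np.zeros((cout, cin, k, k), np.float32)
        else:
            self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                (cout, cin, k, k)).astype(np.float32)
        self.b = np.zeros(cout, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        k, pad = self.k, self.k // 2
        b_sz, cin, h, w = x.shape
        cout = self.W.shape[0]
        if k == 1:
            self._cols = [np.ascontiguousarray(x).reshape(b_sz, cin, h * w)]
        else:
            xpad = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            self._cols = [
                np.ascontiguousarray(xpad[:, :, di:di + h, dj:dj + w])
                .reshape(b_sz, cin, h * w)
                for di in range(k) for dj in range(k)
            ]
        y = np.zeros((b_sz, cout, h, w), np.float32)
        yf = y.reshape(b_sz, cout, h * w)
        for (di, dj), xs in zip(np.ndindex(k, k), self._cols):
            yf += self.W[None, :, :, di, dj] @ xs
        y += self.b[None, :, None, None]
        self._hw = (h, w)
        return y

    def backward(self, dy):
        k, pad = self.k, self.k // 2
        h, w = self._hw
        b_sz, cout = dy.shape[:2]
        cin = self.W.shape[1]
        dyf = np.ascontiguousarray(dy).reshape(b_sz, cout, h * w)
        self.db += dy.sum(axis=(0, 2, 3))
        dxpad = np.zeros((b_sz, cin, h + 2 * pad, w + 2 * pad), np.float32)
        for (di, dj), xs in zip(np.ndindex(k, k), self._cols):
            self.dW[:, :, di, dj] += (dyf @ xs.transpose(0, 2, 1)).sum(axis=0)
            dxpad[:, :, di:di + h, dj:dj + w] += (
                self.W[None, :, :, di, dj].transpose(0, 2, 1) @ dyf
            ).reshape(b_sz, cin, h, w)
        self._cols = None
        if pad:
            return dxpad[:, :, pad:-pad, pad:-pad]
        return dxpad

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x):
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling requires even spatial dimensions")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(b, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, c, h, w = self._shape
        dxr = np.zeros((b, c, h // 2, w // 2, 4), np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(b, c, h, w)

    def params(self):
        return []


class _BilinearUp2:
    """x2 bilinear upsampling (half-pixel-center convention) as dense
    interpolation matrices, so forward and backward are plain GEMMs."""

    _cache: dict = {}

    @classmethod
    def _matrix(cls, n_in):
        m = cls._cache.get(n_in)
        if m is None:
            src = (np.arange(2 * n_in) + 0.5) / 2.0 - 0.5
            i0 = np.clip(np.floor(src).astype(np.int64), 0, n_in - 1)
            i1 = np.minimum(i0 + 1, n_in - 1)
            w = np.clip(src - i0, 0.0, 1.0).astype(np.float32)
            m = np.zeros((2 * n_in, n_in), np.float32)
            m[np.arange(2 * n_in), i0] += 1 - w
            m[np.arange(2 * n_in), i1] += w
            cls._cache[n_in] = m
        return m

    def forward(self, x):
        b, c, h, w = x.shape
        self._my = self._matrix(h)
        self._mx = self._matrix(w)
        return self._my[None, None] @ x @ self._mx.T[None, None]

    def backward(self, dy):
        return self._my.T[None, None] @ dy @ self._mx[None, None]

    def params(self):
        return []


class _Block:
    """Two (conv 3x3 + ReLU) stages."""

    def __init__(self, cin, cout, k, rng):
        self.layers = [_Conv(cin, cout, k, rng), _ReLU(),
                       _Conv(cout, cout, k, rng), _ReLU()]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def params(self):
        return [p for lay in self.layers for p in lay.params()]


class UNet:
    """The encoder/decoder network; see the module docstring."""

    def __init__(self, config: NetConfig, in_channels: int = 1,
                 out_channels: int = 1):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = [config.base_features * 2 ** i for i in range(config.depth)]
        k = config.kernel
        self.enc = [_Block(in_channels if i == 0 else f[i - 1], f[i], k, rng)
                    for i in range(config.depth)]
        self.pools = [_MaxPool2() for _ in range(config.depth - 1)]
        self.ups = [_BilinearUp2() for _ in range(config.depth - 1)]
        self.dec = [_Block(f[i + 1] + f[i], f[i], k, rng)
                    for i in reversed(range(config.depth - 1))]
        self.head = _Conv(f[0], out_channels, 1, rng,
                          zero_init=config.final_zero_init)

    # -- plumbing ----------------------------------------------------------
    def _layers(self):
        return [*self.enc, *self.dec, self.head]

    def params(self):
        return [p for lay in self._layers() for p in lay.params()]

    @property
    def num_params(self) -> int:
        return int(sum(w.size for w, _ in self.params()))

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def get_weights(self):
        return [w.copy() for w, _ in self.params()]

    def set_weights(self, weights):
        own = self.params()
        if len(weights) != len(own):
            raise ValueError("weight list does not match the architecture")
        for (w, _), new in zip(own, weights):
            w[...] = new

    # -- compute -----------------------------------------------------------
    def check_input(self, x):
        d = self.config.divisor
        if x.ndim != 4:
            raise ValueError("input must be (batch, channel, H, W)")
        h, w = x.shape[2:]
        if h % d or w % d:
            raise ValueError(
                f"input spatial size {(h, w)} not divisible by {d}; "
                f"pad to ({-(-h // d) * d}, {-(-w // d) * d})")

    def forward(self, x):
        self.check_input(x)
        x = np.ascontiguousarray(x, np.float32)
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([x, skip], axis=1)
            x = dec.forward(x)
        return self.head.forward(x)

    def backward(self, dy):
        dy = self.head.backward(dy)
        # reversed(dec) pairs with skips[0], skips[1], ... in that order
        d_skips = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            dy = dec.backward(dy)
            n_up = dy.shape[1] - self._skip_channels[len(d_skips)]
            d_skip = dy[:, n_up:]
            dy = up.backward(np.ascontiguousarray(dy[:, :n_up]))
            d_skips.append(d_skip)
        for i in reversed(range(len(self.enc))):
            if i < len(self.pools):
                dy = self.pools[i].backward(dy)
                dy = dy + d_skips[i]
            dy = self.enc[i].backward(dy)
        return dy

    def predict(self, x, batch_size: int = 32):
        """Inference without caching side effects on the result."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[i:i + batch_size]).copy())
        return np.concatenate(out, axis=0)


def build_network(config: NetConfig, in_channels: int = 1,
                  out_channels: int = 1) -> UNet:
    """Construct the network for a configuration."""
    return UNet(config, in_channels, out_channels)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            w -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedModel:
    """A trained network with its configuration, history and provenance."""

    model: UNet
    config: NetConfig
    history: dict                      # {'train_mae': [...], 'val_mae': [...]}
    provenance: dict = field(default_factory=dict)

    @property
    def epochs_run(self) -> int:
        return len(self.history["train_mae"])


def split_indices(n: int, train_fraction: float = 0.8, seed: int = 0):
    """Disjoint shuffled train/test index arrays of sizes round(n*f), n-round(n*f)."""
    if n <= 0:
        raise ValueError("cannot split an empty dataset")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(n * train_fraction))
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train:]


def split_dataset(pairs, train_fraction: float = 0.8, seed: int = 0):
    """Split a sequence of pairs into shuffled, disjoint train/test subsets."""
    tr, te = split_indices(len(pairs), train_fraction, seed)
    return [pairs[i] for i in tr], [pairs[i] for i in te]


def dataset_hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def _mae(model: UNet, x, y, batch_size):
    total = 0.0
    for i in range(0, x.shape[0], batch_size):
        pred = model.forward(x[i:i + batch_size])
        total += float(np.abs(pred - y[i:i + batch_size]).sum())
    return total / y.size


def train(model: UNet, train_x, train_y, config: NetConfig | None = None,
          val_x=None, val_y=None, verbose: bool = False) -> TrainedModel:
    """Optimize MAE with Adam; records per-epoch losses, keeps best-val weights.

    ``train_x``/``train_y`` are aligned (N, 1, H, W) stacks of poly and mono
    line-integral images.  Fully deterministic given ``config.seed``.
    """
    config = config or model.config
    train_x = np.asarray(train_x, np.float32)
    train_y = np.asarray(train_y, np.float32)
    if train_x.shape != train_y.shape:
        raise ValueError("input/target stacks must have identical shapes")
    has_val = val_x is not None and val_y is not None
    if has_val:
        val_x = np.asarray(val_x, np.float32)
        val_y = np.asarray(val_y, np.float32)
        if val_x.shape != val_y.shape:
            raise ValueError("validation stacks must have identical shapes")
    model.check_input(train_x)

    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model.params(), config.learning_rate, config.beta1, config.beta2)
    n = train_x.shape[0]
    bs = min(config.batch_size, n)
    history = {"train_mae": [], "val_mae": []}
    best = (np.inf, model.get_weights())

    warmup = max(1, config.epochs // 10)
    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / max(1, config.epochs - 1)))
        elif config.lr_schedule == "warmup-cosine" and epoch < warmup:
            lr = config.learning_rate * (epoch + 1) / warmup
        elif config.lr_schedule == "warmup-cosine":
            t = (epoch - warmup) / max(1, config.epochs - 1 - warmup)
            lr = config.learning_rate * 0.5 * (1.0 + np.cos(np.pi * t))
        else:
            lr = config.learning_rate
        perm = rng.permutation(n)
        epoch_abs = 0.0
        for i in range(0, n, bs):
            idx = perm[i:i + bs]
            xb, yb = train_x[idx], train_y[idx]
            pred = model.forward(xb)
            resid = pred - yb
            loss = float(np.abs(resid).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {i // bs}")
            model.zero_grad()
            model.backward(np.sign(resid).astype(np.float32) / resid.size)
            opt.step(lr)
            epoch_abs += float(np.abs(resid).sum())
        history["train_mae"].append(epoch_abs / train_y.size)
        if has_val:
            vmae = _mae(model, val_x, val_y, max(bs, 8))
            history["val_mae"].append(vmae)
            if vmae < best[0]:
                best = (vmae, model.get_weights())
        if verbose:
            msg = f"epoch {epoch + 1:4d}  train MAE {history['train_mae'][-1]:.5g}"
            if has_val:
                msg += f"  val MAE {history['val_mae'][-1]:.5g}"
            print(msg)

    if has_val and np.isfinite(best[0]):
        model.set_weights(best[1])
    provenance = {"dataset_hash": dataset_hash(train_x, train_y),
                  "seed": config.seed, "n_train": int(n),
                  "n_val": int(val_x.shape[0]) if has_val else 0}
    return TrainedModel(model, config, history, provenance)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_images(trained: TrainedModel | UNet, images: np.ndarray) -> np.ndarray:
    """Run inference on an (N, H, W) stack, reflect-padding to a valid size."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    images = np.asarray(images, np.float32)
    squeeze = images.ndim == 2
    if squeeze:
        images = images[None]
    n, h, w = images.shape
    d = model.config.divisor
    ph = (-h) % d
    pw = (-w) % d
    x = images[:, None]
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    out = model.predict(x)[:, 0, :h, :w]
    return out[0] if squeeze else out


def predict(trained: TrainedModel, projections) -> "ProjectionSet":
    """Predict virtual monoenergetic projections for a polyenergetic set."""
    from .projector import ProjectionSet

    if not isinstance(projections, ProjectionSet):
        raise TypeError("predict expects a ProjectionSet; "
                        "use predict_images for raw arrays")
    if projections.kind != "poly":
        warnings.warn(f"predicting from a {projections.kind!r} projection set; "
                      "expected 'poly'", stacklevel=2)
    images = predict_images(trained, projections.images)
    meta = dict(projections.meta)
    meta["model"] = {"seed": trained.config.seed,
                     "depth": trained.config.depth,
                     "epochs_run": trained.epochs_run,
                     **trained.provenance}
    return ProjectionSet(images, projections.angles.copy(),
                         projections.geometry, "predicted-mono", meta)
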