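"""Image classification of RGB scalograms, one binary model per contrast.

The backend is pluggable; the bundled reference backend is a compact
convolutional network — conv(3x3, 16) + ReLU + maxpool(2) followed by
conv(3x3, 32) + ReLU + maxpool(2), global average pooling and a softmax
dense layer — implemented directly on NumPy so it trains on a single CPU in
minutes.  A parameter-free 4x4 average-pooling stem reduces the 224x224
input to 56x56 before the first convolution; scalograms are smooth at that
scale, so this trades no useful structure for a ~16x drop in compute.
Training is plain SGD with momentum on cross-entropy, mini-batches of 10,
at most 30 epochs with per-epoch validation; the parameters achieving the
best validation accuracy are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image


class StratificationError(ValueError):
    """A class is too small to populate every split."""


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: 0.8/0.1/0.1 split, ≤30 epochs, batches of 10."""

    max_epochs: int = 30
    batch_size: int = 10
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    backend: str = "reference_cnn"
    learning_rate: float = 1e-2
    momentum: float = 0.9
    patience: int = 6  # epochs without val-accuracy improvement before stopping

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9 or min(self.split) <= 0:
            raise ValueError("split fractions must be positive and sum to 1")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")


def split_dataset(
    manifest: pd.DataFrame, config: TrainConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stratified, seeded train/val/test partition of an image manifest.

    Proportions per class match ``config.split`` within one image; the three
    parts are disjoint and their union is the input.  Row indices are
    preserved so images can be addressed positionally.
    """
    rng = np.random.default_rng(config.seed)
    parts: list[list[int]] = [[], [], []]
    for label in sorted(manifest["label"].unique()):
        idx = manifest.index[manifest["label"] == label].to_numpy()
        if len(idx) < 10:
            raise StratificationError(
                f"class {label!r} has only {len(idx)} images; need >= 10"
            )
        idx = rng.permutation(idx)
        n = len(idx)
        n_train = int(round(config.split[0] * n))
        n_val = int(round(config.split[1] * n))
        n_val = max(1, min(n_val, n - n_train - 1))
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train : n_train + n_val])
        parts[2].extend(idx[n_train + n_val :])
    return tuple(manifest.loc[sorted(p)] for p in parts)  # type: ignore[return-value]


def load_images(manifest: pd.DataFrame, images: np.ndarray | None = None) -> np.ndarray:
    """Resolve manifest rows to an (n, H, W, 3) uint8 array.

    ``images`` is the in-memory array aligned with the manifest's positional
    index; when absent, PNGs are loaded from the ``path`` column.
    """
    if images is not None:
        return images[manifest.index.to_numpy()]
    out = []
    for path in manifest["path"]:
        try:
            out.append(np.asarray(Image.open(path).convert("RGB")))
        except OSError as exc:
            raise OSError(f"cannot read image {path!r}") from exc
    return np.stack(out)


# ---------------------------------------------------------------------------
# Reference CNN backend (NumPy)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    # x: (B, H, W, C) -> (B, (H-2)*(W-2), C*9) for a 3x3 valid convolution
    win = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(1, 2))
    b, h, w, c = win.shape[:4]
    return np.ascontiguousarray(win).reshape(b, h * w, c * 9), (h, w, c)


def _col2im(dcols: np.ndarray, h: int, w: int, c: int, full_shape) -> np.ndarray:
    b = dcols.shape[0]
    d = dcols.reshape(b, h, w, c, 3, 3)
    dx = np.zeros(full_shape, dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            dx[:, i : i + h, j : j + w, :] += d[:, :, :, :, i, j]
    return dx


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    v = x[:, : 2 * h2, : 2 * w2, :].reshape(b, h2, 2, w2, 2, c)
    out = v.max(axis=(2, 4))
    mask = v == out[:, :, None, :, None, :]
    return out, mask


def _maxpool2_back(dout: np.ndarray, mask: np.ndarray, shape) -> np.ndarray:
    b, h, w, c = shape
    dx = np.zeros(shape, dtype=dout.dtype)
    d = mask * dout[:, :, None, :, None, :]
    dx[:, : mask.shape[1] * 2, : mask.shape[3] * 2, :] = d.reshape(
        b, mask.shape[1] * 2, mask.shape[3] * 2, c
    )
    return dx


@dataclass
class ReferenceCNN:
    """Two-conv-layer softmax CNN on NumPy arrays.

    Parameters are stored as a dict of arrays; `forward` returns class
    probabilities, and `train_batch` performs one SGD-with-momentum step.
    """

    n_classes: int = 2
    stem_pool: int = 4
    params: dict = field(default_factory=dict)
    _vel: dict = field(default_factory=dict)

    def init_params(self, rng: np.random.Generator) -> None:
        # He-normal initialization; float32 keeps CPU matmuls fast
        self.params = {
            "W1": rng.normal(0, np.sqrt(2 / 27), (27, 16)).astype(np.float32),
            "b1": np.zeros(16, dtype=np.float32),
            "W2": rng.normal(0, np.sqrt(2 / 144), (144, 32)).astype(np.float32),
            "b2": np.zeros(32, dtype=np.float32),
            "W3": rng.normal(0, np.sqrt(2 / 32), (32, self.n_classes)).astype(np.float32),
            "b3": np.zeros(self.n_classes, dtype=np.float32),
        }
        self._vel = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _stem(self, images: np.ndarray) -> np.ndarray:
        x = images.astype(np.float32) / np.float32(255.0) - np.float32(0.5)
        b, h, w, c = x.shape
        p = self.stem_pool
        return x[:, : h // p * p, : w // p * p, :].reshape(
            b, h // p, p, w // p, p, c
        ).mean(axis=(2, 4))

    def _forward(self, x: np.ndarray, keep: bool = False):
        cache = {}
        cols1, (h1, w1, _) = _im2col(x)
        a1 = cols1 @ self.params["W1"] + self.params["b1"]
        r1 = np.maximum(a1, 0).reshape(x.shape[0], h1, w1, 16)
        p1, m1 = _maxpool2(r1)
        cols2, (h2, w2, _) = _im2col(p1)
        a2 = cols2 @ self.params["W2"] + self.params["b2"]
        r2 = np.maximum(a2, 0).reshape(x.shape[0], h2, w2, 32)
        p2, m2 = _maxpool2(r2)
        g = p2.mean(axis=(1, 2))
        logits = g @ self.params["W3"] + self.params["b3"]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        if keep:
            cache.update(
                x=x, cols1=cols1, r1=r1, m1=m1, p1=p1,
                cols2=cols2, r2=r2, m2=m2, p2=p2, g=g, dims=(h1, w1, h2, w2),
            )
        return probs, cache

    def predict_proba(self, images: np.ndarray, batch: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch):
            probs, _ = self._forward(self._stem(images[i : i + batch]))
            out.append(probs)
        return np.concatenate(out) if out else np.empty((0, self.n_classes))

    def train_batch(self, images: np.ndarray, y: np.ndarray,
                    lr: float, momentum: float) -> tuple[float, int]:
        """One SGD step; returns (batch loss, correct predictions in batch)."""
        x = self._stem(images)
        probs, c = self._forward(x, keep=True)
        b = len(y)
        hits = int((probs.argmax(axis=1) == y).sum())
        loss = -np.log(np.maximum(probs[np.arange(b), y], 1e-300)).mean()
        if not np.isfinite(loss):
            raise TrainingError("non-finite loss")
        h1, w1, h2, w2 = c["dims"]
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b
        grads = {
            "W3": c["g"].T @ dlogits,
            "b3": dlogits.sum(axis=0),
        }
        dg = dlogits @ self.params["W3"].T
        dp2 = np.broadcast_to(
            dg[:, None, None, :] / (c["p2"].shape[1] * c["p2"].shape[2]),
            c["p2"].shape,
        )
        dr2 = _maxpool2_back(dp2, c["m2"], c["r2"].shape)
        da2 = (dr2 * (c["r2"] > 0)).reshape(b, h2 * w2, 32)
        grads["W2"] = np.einsum("bpc,bpf->cf", c["cols2"], da2)
        grads["b2"] = da2.sum(axis=(0, 1))
        dcols2 = da2 @ self.params["W2"].T
        dp1 = _col2im(dcols2, h2, w2, 16, c["p1"].shape)
        dr1 = _maxpool2_back(dp1, c["m1"], c["r1"].shape)
        da1 = (dr1 * (c["r1"] > 0)).reshape(b, h1 * w1, 16)
        grads["W1"] = np.einsum("bpc,bpf->cf", c["cols1"], da1)
        grads["b1"] = da1.sum(axis=(0, 1))
        for k, g in grads.items():
            self._vel[k] = np.float32(momentum) * self._vel[k] - np.float32(lr) * g
            self.params[k] = self.params[k] + self._vel[k]
        return float(loss), hits


@dataclass
class TrainedModel:
    """A trained backend plus its class list and per-epoch history."""

    backend: str
    model: ReferenceCNN
    classes: list
    history: list[dict] = field(default_factory=list)


def train(
    train_manifest: pd.DataFrame,
    val_manifest: pd.DataFrame,
    config: TrainConfig = TrainConfig(),
    images: np.ndarray | None = None,
) -> TrainedModel:
    """Train the reference CNN on a manifest split.

    Runs at most ``config.max_epochs`` epochs with per-epoch validation and
    returns the parameters achieving the best validation accuracy.  Training
    stops early when validation accuracy has not improved for
    ``config.patience`` epochs.  All randomness (initialization, batch order)
    flows from ``config.seed``.
    """
    if config.backend != "reference_cnn":
        raise ValueError(f"unknown backend {config.backend!r}")
    if len(train_manifest) == 0 or len(val_manifest) == 0:
        raise ValueError("train and validation sets must be nonempty")
    classes = sorted(pd.concat([train_manifest, val_manifest])["label"].unique())
    lut = {c: i for i, c in enumerate(classes)}
    x_train = load_images(train_manifest, images)
    y_train = train_manifest["label"].map(lut).to_numpy()
    x_val = load_images(val_manifest, images)
    y_val = val_manifest["label"].map(lut).to_numpy()

    rng = np.random.default_rng(config.seed)
    net = ReferenceCNN(n_classes=len(classes))
    net.init_params(rng)
    best = {k: v.copy() for k, v in net.params.items()}
    best_acc, best_epoch, history = -1.0, 0, []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(y_train))
        losses, hits = [], 0
        for i in range(0, len(order), config.batch_size):
            sel = order[i : i + config.batch_size]
            try:
                loss, h = net.train_batch(x_train[sel], y_train[sel],
                                          config.learning_rate, config.momentum)
            except TrainingError as exc:
                raise TrainingError(f"diverged at epoch {epoch}: {exc}") from exc
            losses.append(loss)
            hits += h
        val_pred = net.predict_proba(x_val).argmax(axis=1)
        hist = dict(
            epoch=epoch,
            train_loss=float(np.mean(losses)),
            train_acc=hits / len(y_train),
            val_acc=float((val_pred == y_val).mean()),
        )
        history.append(hist)
        if hist["val_acc"] > best_acc:
            best_acc, best_epoch = hist["val_acc"], epoch
            best = {k: v.copy() for k, v in net.params.items()}
        if epoch - best_epoch >= config.patience:
            break
    net.params = best
    return TrainedModel(backend=config.backend, model=net, classes=list(classes),
                        history=history)


def predict_scores(
    model: TrainedModel,
    manifest: pd.DataFrame,
    images: np.ndarray | None = None,
) -> pd.DataFrame:
    """Class-probability scores for every manifest row.

    Returns the manifest with one ``score_<class>`` column per class; scores
    sum to 1 per image, and the argmax column is the predicted label.
    """
    x = load_images(manifest, images)
    probs = model.model.predict_proba(x)
    out = manifest.copy()
    for i, c in enumerate(model.classes):
        out[f"score_{c}"] = probs[:, i]
    out["predicted"] = [model.classes[i] for i in probs.argmax(axis=1)]
    return out
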