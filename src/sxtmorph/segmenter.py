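"""3D encoder–decoder semantic segmentation of organelles in LAC volumes.

The network is a symmetric 3D U-Net: each encoder level applies two
(3×3×3 convolution → instance normalization → ReLU) blocks and halves the
resolution; the decoder mirrors it with nearest-neighbor upsampling and
skip concatenation, and a 1×1×1 head produces per-voxel class logits.
Training minimizes the sum of multilabel cross-entropy and soft Dice loss,
with random intensity scaling and elastic deformation as augmentation,
k-fold cross-validation with early stopping on the held-out fold, and
ensembling by voxel-wise averaging of the folds' softmax outputs.
Inference is block-wise on an overlapping grid with linear (triangular)
blending weights, after binning the input by a configurable factor.

The full-scale configuration (depth 5, 96 initial filters, 96³ blocks) is
expressible but desk-scale configurations (depth 3, 8 filters, 32³ blocks)
are the supported regime: forward and backward passes are implemented in
numpy, so throughput is CPU-bound.  All randomness (fold split, weight
init, block sampling, augmentation) derives from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .volume_io import LACVolume, LabeledVolume, SEMANTIC_LABELS


@dataclass
class SegConfig:
    """Architecture and training configuration.

    ``block_shape`` must be divisible by ``2**(depth-1)``.  ``n_folds=1``
    is the degenerate overfitting mode (validation = training), used for
    sanity checks; real training uses ≥ 2 folds.
    """

    depth: int = 5
    init_filters: int = 96
    block_shape: tuple[int, int, int] = (96, 96, 96)
    bin_factor: int = 2
    n_folds: int = 3
    early_stop_patience_epochs: int = 50
    seed: int = 0
    labels: tuple[int, ...] = tuple(SEMANTIC_LABELS)
    learning_rate: float = 1e-3
    batch_size: int = 2
    max_epochs: int = 1000
    blocks_per_cell: int = 2

    def __post_init__(self) -> None:
        down = 2 ** (self.depth - 1)
        if any(s % down for s in self.block_shape):
            raise ValueError(
                f"block_shape {self.block_shape} must be divisible by "
                f"2^(depth-1) = {down}")
        if self.n_folds < 1:
            raise ValueError("n_folds must be at least 1")

    @property
    def n_labels(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# layers (forward + manual backward, float32)

class _Conv3d:
    def __init__(self, c_in, c_out, kernel, rng):
        fan_in = c_in * kernel ** 3
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.normal(0, scale, (c_out, c_in * kernel ** 3))
                  .astype(np.float32))
        self.b = np.zeros(c_out, np.float32)
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.grads = {}

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x):
        k = self.kernel
        c, d, h, w = x.shape
        if k == 1:
            self._cols = x.reshape(c, -1).T
        else:
            pad = k // 2
            xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
            win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
            # (c, d, h, w, k, k, k) -> (d*h*w, c*k^3)
            self._cols = np.ascontiguousarray(
                win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(d * h * w, -1)
        self._shape = (d, h, w)
        y = self._cols @ self.W.T + self.b
        return np.ascontiguousarray(y.T.reshape(self.c_out, d, h, w))

    def backward(self, dy):
        d, h, w = self._shape
        k = self.kernel
        dyf = dy.reshape(self.c_out, -1).T
        self.grads["W"] = (dyf.T @ self._cols).astype(np.float32)
        self.grads["b"] = dyf.sum(axis=0).astype(np.float32)
        dcols = dyf @ self.W
        if k == 1:
            return np.ascontiguousarray(dcols.T.reshape(self.c_in, d, h, w))
        pad = k // 2
        dxp = np.zeros((self.c_in, d + 2 * pad, h + 2 * pad, w + 2 * pad),
                       np.float32)
        dcols = dcols.reshape(d, h, w, self.c_in, k, k, k)
        for kz in range(k):
            for ky in range(k):
                for kx in range(k):
                    dxp[:, kz:kz + d, ky:ky + h, kx:kx + w] += \
                        dcols[:, :, :, :, kz, ky, kx].transpose(3, 0, 1, 2)
        return dxp[:, pad:pad + d, pad:pad + h, pad:pad + w]


class _InstanceNorm:
    eps = 1e-5

    def __init__(self, c):
        self.gamma = np.ones(c, np.float32)
        self.beta = np.zeros(c, np.float32)
        self.grads = {}

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x):
        c = x.shape[0]
        flat = x.reshape(c, -1)
        self._mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (flat - self._mu) * self._inv
        y = self.gamma[:, None] * self._xhat + self.beta[:, None]
        return y.reshape(x.shape).astype(np.float32)

    def backward(self, dy):
        c = dy.shape[0]
        dyf = dy.reshape(c, -1)
        n = dyf.shape[1]
        self.grads["gamma"] = (dyf * self._xhat).sum(axis=1).astype(np.float32)
        self.grads["beta"] = dyf.sum(axis=1).astype(np.float32)
        dxhat = dyf * self.gamma[:, None]
        dx = (dxhat - dxhat.mean(axis=1, keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=1, keepdims=True)
              ) * self._inv
        return dx.reshape(dy.shape).astype(np.float32)


class _ReLU:
    def params(self):
        return {}

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


def _avgpool2(x):
    c, d, h, w = x.shape
    return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))


def _avgpool2_backward(dy):
    return np.repeat(np.repeat(np.repeat(dy, 2, 1), 2, 2), 2, 3) / 8.0


def _upsample2(x):
    return np.repeat(np.repeat(np.repeat(x, 2, 1), 2, 2), 2, 3)


def _upsample2_backward(dy):
    c, d, h, w = dy.shape
    return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


def _conv_block(c_in, c_out, rng):
    return [_Conv3d(c_in, c_out, 3, rng), _InstanceNorm(c_out), _ReLU(),
            _Conv3d(c_out, c_out, 3, rng), _InstanceNorm(c_out), _ReLU()]


def _run_forward(layers, x):
    for layer in layers:
        x = layer.forward(x)
    return x


def _run_backward(layers, dy):
    for layer in reversed(layers):
        dy = layer.backward(dy)
    return dy


class UNet3D:
    """Symmetric 3D U-Net over single-channel blocks (numpy implementation)."""

    def __init__(self, config: SegConfig, rng: np.random.Generator):
        self.config = config
        ch = [config.init_filters * 2 ** l for l in range(config.depth)]
        self.enc = [_conv_block(1 if l == 0 else ch[l - 1], ch[l], rng)
                    for l in range(config.depth)]
        self.dec = [_conv_block(ch[l] + ch[l + 1], ch[l], rng)
                    for l in range(config.depth - 1)]
        self.head = _Conv3d(ch[0], config.n_labels, 1, rng)

    def _all_layers(self):
        for block in self.enc + self.dec:
            yield from block
        yield self.head

    def parameters(self):
        out = []
        for i, layer in enumerate(self._all_layers()):
            for name, arr in layer.params().items():
                out.append((f"{i}.{name}", layer, name, arr))
        return out

    def forward(self, x):
        """x: (D, H, W) float block -> logits (L, D, H, W)."""
        x = x[None].astype(np.float32)
        skips = []
        depth = self.config.depth
        for l in range(depth):
            x = _run_forward(self.enc[l], x)
            if l < depth - 1:
                skips.append(x)
                x = _avgpool2(x)
        self._skip_channels = []
        for l in range(depth - 2, -1, -1):
            x = _upsample2(x)
            skip = skips[l]
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            x = _run_forward(self.dec[l], x)
        return self.head.forward(x)

    def backward(self, dlogits):
        depth = self.config.depth
        dy = self.head.backward(dlogits)
        dskips = {}
        levels = list(range(depth - 2, -1, -1))
        # walk the decoder in reverse order of forward execution
        for pos in range(len(levels) - 1, -1, -1):
            l = levels[pos]
            dy = _run_backward(self.dec[l], dy)
            c_skip = self._skip_channels[pos]
            dskips[l] = dy[:c_skip]
            dy = _upsample2_backward(dy[c_skip:])
        for l in range(depth - 1, -1, -1):
            if l < depth - 1:
                dy = _avgpool2_backward(dy)
                dy = dy + dskips[l]
            dy = _run_backward(self.enc[l], dy)
        return dy

    def predict_block(self, block):
        """Softmax probabilities (L, D, H, W) for one block."""
        logits = self.forward(block)
        return softmax_probs(logits)

    def state_arrays(self):
        return {key: arr for key, _l, _n, arr in self.parameters()}

    def load_state(self, arrays):
        for key, _layer, _name, arr in self.parameters():
            arr[...] = arrays[key]


# ---------------------------------------------------------------------------
# loss

def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def combined_loss(probs: np.ndarray, target: np.ndarray,
                  eps: float = 1e-7) -> float:
    """Cross-entropy plus (1 − mean soft Dice over foreground labels).

    ``probs``: (L, D, H, W) per-voxel probabilities (must sum to 1);
    ``target``: (D, H, W) integer labels indexing the L classes.  Dice is
    averaged over foreground (non-zero) labels present in the target.
    """
    if probs.shape[1:] != target.shape:
        raise ValueError("probability and target shapes differ")
    n_labels = probs.shape[0]
    flat_p = probs.reshape(n_labels, -1).astype(np.float64)
    flat_t = target.ravel()
    n = flat_t.size
    ce = -np.log(np.maximum(flat_p[flat_t, np.arange(n)], eps)).mean()
    dice_terms = []
    for c in range(1, n_labels):
        t_c = (flat_t == c)
        if not t_c.any():
            continue
        p_c = flat_p[c]
        dice = 2 * p_c[t_c].sum() / (p_c.sum() + t_c.sum())
        dice_terms.append(dice)
    dice_loss = 1.0 - float(np.mean(dice_terms)) if dice_terms else 0.0
    return float(ce + dice_loss)


def _loss_and_grad_logits(logits: np.ndarray, target: np.ndarray):
    """Combined loss and its gradient with respect to the logits."""
    n_labels = logits.shape[0]
    p = softmax_probs(logits).astype(np.float64)
    flat_p = p.reshape(n_labels, -1)
    flat_t = target.ravel()
    n = flat_t.size
    onehot = np.zeros_like(flat_p)
    onehot[flat_t, np.arange(n)] = 1.0
    ce = -np.log(np.maximum(flat_p[flat_t, np.arange(n)], 1e-12)).mean()
    dce_dz = (flat_p - onehot) / n

    g_p = np.zeros_like(flat_p)          # d(dice_loss)/d p
    dice_terms = []
    fg = [c for c in range(1, n_labels) if (flat_t == c).any()]
    for c in fg:
        t_c = onehot[c]
        p_c = flat_p[c]
        inter = (p_c * t_c).sum()
        denom = p_c.sum() + t_c.sum()
        dice_terms.append(2 * inter / denom)
        # d dice_c / d p_c = 2 (t denom − inter) / denom²; loss -= dice/|fg|
        g_p[c] -= (2 * (t_c * denom - inter) / denom ** 2) / len(fg)
    # chain through softmax: dz = p ⊙ (g − Σ_c g_c p_c)
    ddice_dz = flat_p * (g_p - (g_p * flat_p).sum(axis=0, keepdims=True))
    dice_loss = 1.0 - float(np.mean(dice_terms)) if dice_terms else 0.0
    grad = (dce_dz + ddice_dz).reshape(logits.shape).astype(np.float32)
    return float(ce + dice_loss), grad


# ---------------------------------------------------------------------------
# augmentation

def augment_sample(lac_block: np.ndarray, label_block: np.ndarray,
                   seed: int | np.random.Generator = 0,
                   intensity_range: tuple[float, float] = (0.9, 1.1),
                   elastic_alpha_vox: float = 0.5,
                   elastic_sigma_vox: float = 12.0,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Random intensity scaling plus a shared elastic warp.

    The same smooth displacement field warps image (trilinear) and labels
    (nearest-neighbor); the intensity scale applies to the image only.
    ``intensity_range=(1, 1)`` with ``elastic_alpha_vox=0`` is the
    identity.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    scale = rng.uniform(*intensity_range)
    out_img = lac_block * scale
    out_lab = label_block
    if elastic_alpha_vox > 0:
        shape = lac_block.shape
        disp = []
        for _ in range(3):
            field = ndimage.gaussian_filter(rng.normal(size=shape),
                                            elastic_sigma_vox)
            # normalize so the displacement magnitude is alpha voxels RMS
            field *= elastic_alpha_vox / max(field.std(), 1e-12)
            disp.append(field)
        grid = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                           indexing="ij")
        coords = [g + d for g, d in zip(grid, disp)]
        out_img = ndimage.map_coordinates(out_img, coords, order=1,
                                          mode="nearest")
        out_lab = ndimage.map_coordinates(label_block, coords, order=0,
                                          mode="nearest")
    return out_img.astype(np.float32), out_lab.astype(label_block.dtype)


# ---------------------------------------------------------------------------
# binning

def bin_volume(data: np.ndarray, factor: int, labels: bool = False
               ) -> np.ndarray:
    """Downsample by ``factor``: mean-pooling for images, striding for labels."""
    if factor == 1:
        return data
    trimmed = data[tuple(slice(0, (s // factor) * factor)
                         for s in data.shape)]
    if labels:
        return trimmed[::factor, ::factor, ::factor]
    shape = []
    for s in trimmed.shape:
        shape.extend([s // factor, factor])
    return trimmed.reshape(shape).mean(axis=(1, 3, 5))


def unbin_labels(data: np.ndarray, factor: int,
                 out_shape: tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbor upsample back to the original grid shape."""
    if factor > 1:
        data = np.repeat(np.repeat(np.repeat(data, factor, 0), factor, 1),
                         factor, 2)
    pad = [(0, max(0, t - s)) for s, t in zip(data.shape, out_shape)]
    data = np.pad(data, pad, mode="edge")
    return data[tuple(slice(0, t) for t in out_shape)]


# ---------------------------------------------------------------------------
# block fusion

def _block_starts(size: int, block: int, stride: int) -> list[int]:
    if size <= block:
        return [0]
    starts = list(range(0, size - block + 1, stride))
    if starts[-1] != size - block:
        starts.append(size - block)
    return starts


def _ramp(n: int) -> np.ndarray:
    # triangular ramp, strictly positive so weight sums never vanish
    x = np.arange(n, dtype=np.float64)
    return np.minimum(x + 1, n - x) / n


def fuse_blocks(predict_fns, volume: np.ndarray,
                block_shape: tuple[int, int, int], n_labels: int,
                overlap: float = 0.5) -> np.ndarray:
    """Blend block-wise probabilities over an oversampled grid.

    ``predict_fns`` are callables block -> (L, *block_shape) probabilities
    (one per ensemble member); members are averaged voxel-wise.  Linear
    (triangular) ramp weights make the per-voxel weights a partition of
    unity after normalization, so constant predictions fuse exactly.
    Volumes smaller than one block are padded and cropped back.
    """
    orig_shape = volume.shape
    pad = [(0, max(0, b - s)) for s, b in zip(volume.shape, block_shape)]
    if any(p[1] for p in pad):
        volume = np.pad(volume, pad, mode="edge")
    shape = volume.shape
    stride = tuple(max(1, int(round(b * (1 - overlap))))
                   for b in block_shape)
    weight_block = (_ramp(block_shape[0])[:, None, None]
                    * _ramp(block_shape[1])[None, :, None]
                    * _ramp(block_shape[2])[None, None, :])
    acc = np.zeros((n_labels,) + shape, np.float64)
    wsum = np.zeros(shape, np.float64)
    for z0 in _block_starts(shape[0], block_shape[0], stride[0]):
        for y0 in _block_starts(shape[1], block_shape[1], stride[1]):
            for x0 in _block_starts(shape[2], block_shape[2], stride[2]):
                sl = (slice(z0, z0 + block_shape[0]),
                      slice(y0, y0 + block_shape[1]),
                      slice(x0, x0 + block_shape[2]))
                block = volume[sl]
                prob = np.mean([fn(block) for fn in predict_fns], axis=0)
                acc[(slice(None),) + sl] += prob * weight_block
                wsum[sl] += weight_block
    probs = acc / wsum
    crop = (slice(None),) + tuple(slice(0, s) for s in orig_shape)
    return probs[crop]


# ---------------------------------------------------------------------------
# training

class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {key: np.zeros_like(arr) for key, _l, _n, arr in params}
        self.v = {key: np.zeros_like(arr) for key, _l, _n, arr in params}

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, name, arr in params:
            g = grads[key]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            arr -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)
                    ).astype(arr.dtype)


@dataclass
class TrainedEnsemble:
    """k independently trained fold models plus their validation histories."""

    models: list
    histories: list[dict] = field(default_factory=list)
    config: SegConfig | None = None
    normalization: tuple[float, float] = (0.0, 1.0)


def _prepare_cell(lac, labels, config):
    img = lac.data if isinstance(lac, LACVolume) else np.asarray(lac)
    lab = labels.data if isinstance(labels, LabeledVolume) \
        else np.asarray(labels)
    img = bin_volume(img.astype(np.float32), config.bin_factor)
    lab = bin_volume(lab, config.bin_factor, labels=True)
    return img, lab


def _sample_block(img, lab, block_shape, rng):
    pads = [(0, max(0, b - s)) for s, b in zip(img.shape, block_shape)]
    if any(p[1] for p in pads):
        img = np.pad(img, pads, mode="edge")
        lab = np.pad(lab, pads, mode="edge")
    starts = [int(rng.integers(0, s - b + 1)) if s > b else 0
              for s, b in zip(img.shape, block_shape)]
    sl = tuple(slice(s, s + b) for s, b in zip(starts, block_shape))
    return img[sl], lab[sl]


def _train_one_model(train_cells, val_cells, config, rng,
                     norm, augment=True):
    model = UNet3D(config, rng)
    optimizer = _Adam(model.parameters(), config.learning_rate)
    mean, sd = norm
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, patience = np.inf, None, 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_cells))
        epoch_losses = []
        for ci in order:
            img, lab = train_cells[ci]
            for _ in range(config.blocks_per_cell):
                grads_acc = None
                batch_loss = 0.0
                for _b in range(config.batch_size):
                    bi, bl = _sample_block(img, lab, config.block_shape, rng)
                    if augment:
                        bi, bl = augment_sample(bi, bl, rng)
                    logits = model.forward((bi - mean) / sd)
                    loss, dlogits = _loss_and_grad_logits(logits, bl)
                    model.backward(dlogits / config.batch_size)
                    step_grads = {key: layer.grads[name].copy()
                                  for key, layer, name, _arr
                                  in model.parameters()}
                    if grads_acc is None:
                        grads_acc = step_grads
                    else:
                        for key in grads_acc:
                            grads_acc[key] += step_grads[key]
                    batch_loss += loss / config.batch_size
                optimizer.step(model.parameters(), grads_acc)
                epoch_losses.append(batch_loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        val_loss = _validation_loss(model, val_cells, config, norm)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val, patience = val_loss, 0
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        else:
            patience += 1
            if patience >= config.early_stop_patience_epochs:
                break
    if best_state is not None:
        model.load_state(best_state)
    return model, history


def _validation_loss(model, val_cells, config, norm):
    mean, sd = norm
    losses = []
    for img, lab in val_cells:
        # deterministic center block per validation cell
        starts = [max(0, (s - b) // 2)
                  for s, b in zip(img.shape, config.block_shape)]
        pads = [(0, max(0, b - s))
                for s, b in zip(img.shape, config.block_shape)]
        vi, vl = img, lab
        if any(p[1] for p in pads):
            vi = np.pad(vi, pads, mode="edge")
            vl = np.pad(vl, pads, mode="edge")
        sl = tuple(slice(s, s + b)
                   for s, b in zip(starts, config.block_shape))
        logits = model.forward((vi[sl] - mean) / sd)
        losses.append(combined_loss(softmax_probs(logits), vl[sl]))
    return float(np.mean(losses))


def train_ensemble(dataset, config: SegConfig,
                   augment: bool = True) -> TrainedEnsemble:
    """Train one model per cross-validation fold and return the ensemble.

    ``dataset`` is a list of ``(lac, labels)`` single-cell pairs (volumes
    or bare arrays on the unbinned grid).  Validation cells of each fold
    are disjoint from its training cells; early stopping monitors the
    combined loss on the held-out fold.
    """
    if len(dataset) < config.n_folds:
        raise ValueError(
            f"dataset has {len(dataset)} cells for {config.n_folds} folds")
    rng = np.random.default_rng(config.seed)
    cells = [_prepare_cell(lac, lab, config) for lac, lab in dataset]
    all_img = np.concatenate([c[0].ravel() for c in cells])
    norm = (float(all_img.mean()), float(all_img.std()) or 1.0)
    order = rng.permutation(len(cells))
    folds = [list(order[f::config.n_folds]) for f in range(config.n_folds)]
    models, histories = [], []
    for f, val_idx in enumerate(folds):
        if config.n_folds == 1:
            train_idx = val_idx
        else:
            train_idx = [i for i in order if i not in val_idx]
        fold_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, f]))
        model, history = _train_one_model(
            [cells[i] for i in train_idx], [cells[i] for i in val_idx],
            config, fold_rng, norm, augment=augment)
        models.append(model)
        histories.append(history)
    return TrainedEnsemble(models=models, histories=histories,
                           config=config, normalization=norm)


def predict(ensemble: TrainedEnsemble, lac: LACVolume
            ) -> tuple[np.ndarray, LabeledVolume]:
    """Ensemble prediction on a full LAC volume.

    Returns ``(probabilities, LabeledVolume)`` on the original (unbinned)
    grid: per-voxel probabilities are the fold-averaged, linearly blended
    block outputs; labels are the argmax, upsampled by nearest neighbor.
    """
    config = ensemble.config
    data = lac.data if isinstance(lac, LACVolume) else np.asarray(lac)
    voxel_um = lac.voxel_um if isinstance(lac, LACVolume) else 1.0
    binned = bin_volume(data.astype(np.float32), config.bin_factor)
    mean, sd = ensemble.normalization
    fns = [(lambda block, m=m: m.predict_block((block - mean) / sd))
           for m in ensemble.models]
    probs = fuse_blocks(fns, binned, config.block_shape, config.n_labels)
    labels_binned = np.argmax(probs, axis=0).astype(np.int32)
    labels_full = unbin_labels(labels_binned, config.bin_factor, data.shape)
    labeled = LabeledVolume(labels_full, voxel_um)
    return probs, labeled


# ---------------------------------------------------------------------------
# checkpoints

def save_ensemble(ensemble: TrainedEnsemble, directory: str | Path) -> Path:
    """Save fold weights (npz) plus the SegConfig as JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = asdict(ensemble.config)
    cfg["normalization"] = list(ensemble.normalization)
    (directory / "config.json").write_text(json.dumps(cfg, sort_keys=True))
    for f, model in enumerate(ensemble.models):
        np.savez(directory / f"fold_{f}.npz", **model.state_arrays())
    return directory


def load_ensemble(directory: str | Path) -> TrainedEnsemble:
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    norm = tuple(cfg.pop("normalization"))
    cfg["block_shape"] = tuple(cfg["block_shape"])
    cfg["labels"] = tuple(cfg["labels"])
    config = SegConfig(**cfg)
    models = []
    rng = np.random.default_rng(0)
    for path in sorted(directory.glob("fold_*.npz")):
        model = UNet3D(config, rng)
        with np.load(path) as arrays:
            model.load_state(dict(arrays))
        models.append(model)
    return TrainedEnsemble(models=models, config=config, normalization=norm)
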