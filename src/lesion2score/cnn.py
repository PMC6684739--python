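"""Compact 3D convolutional network regressing a score from a lesion mask.

Architecture (fixed): 61x73x61 binary input -> 3D convolution with four 3x3x3
kernels, zero ("same") padding -> ReLU -> 3D max pooling with 8x8x8 windows,
stride 8, partial edge windows included (ceil mode), giving 8x10x8 maps per
kernel -> fully connected layer of 500 ReLU units -> single sigmoid output.
Training minimizes mean squared error against scores affinely rescaled into
[0.1, 0.9] (the sigmoid cannot represent raw negative scores), with Adam.

The network is small (112 convolutional parameters plus the dense layers) and
is implemented directly in numpy.  Because lesion masks are sparse binary
blobs, the convolution is evaluated only on the dilated bounding box of the
lesion; everywhere else the pre-activation equals the kernel bias, which is
folded into pooling analytically.  A dense scipy.ndimage reference
implementation of the same forward pass is kept alongside and the two are
held equal in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, GridError, StateError, ValidationError
from .imaging import GRID_SHAPE, LesionImage

_KSIZE = 3
_POOL = 8
#: Pooled spatial shape per kernel: ceil(61/8), ceil(73/8), ceil(61/8).
POOLED_SHAPE = tuple(-(-s // _POOL) for s in GRID_SHAPE)
_N_CELLS = int(np.prod(POOLED_SHAPE))


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters of the 3D CNN.

    The architecture fields mirror the fixed design (four 3^3 kernels, 8^3
    max pooling, 500 hidden units); the optimization fields are free.
    """

    n_kernels: int = 4
    fc_units: int = 500
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_kernels < 1 or self.fc_units < 1:
            raise ConfigurationError("n_kernels and fc_units must be positive")
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigurationError("invalid optimization settings")

    @property
    def n_conv_params(self) -> int:
        """Trainable convolution parameters: kernels * 27 weights + biases."""
        return self.n_kernels * _KSIZE**3 + self.n_kernels

    @property
    def n_flat_features(self) -> int:
        return _N_CELLS * self.n_kernels


@dataclass
class ScoreScaler:
    """Invertible affine map from the training score range onto [0.1, 0.9].

    Keeps sigmoid targets away from saturation.  Degenerate training scores
    (all equal) map to 0.5 and invert to the constant.
    """

    lo: float = 0.1
    hi: float = 0.9
    score_min: float = 0.0
    score_max: float = 1.0
    degenerate: bool = False

    @classmethod
    def fit(cls, scores, lo: float = 0.1, hi: float = 0.9) -> "ScoreScaler":
        scores = np.asarray(scores, dtype=np.float64)
        smin, smax = float(scores.min()), float(scores.max())
        return cls(lo=lo, hi=hi, score_min=smin, score_max=smax, degenerate=smin == smax)

    def forward(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=np.float64)
        if self.degenerate:
            return np.full_like(s, 0.5 * (self.lo + self.hi))
        return self.lo + (s - self.score_min) * (self.hi - self.lo) / (
            self.score_max - self.score_min
        )

    def inverse(self, raw) -> np.ndarray:
        """Descale network outputs; raw values are clipped to [lo, hi]."""
        r = np.clip(np.asarray(raw, dtype=np.float64), self.lo, self.hi)
        if self.degenerate:
            return np.full_like(r, self.score_min)
        return self.score_min + (r - self.lo) * (self.score_max - self.score_min) / (
            self.hi - self.lo
        )


def _cell_window_size(cell_xyz: tuple[int, int, int]) -> int:
    return int(
        np.prod([min(_POOL, dim - _POOL * c) for c, dim in zip(cell_xyz, GRID_SHAPE)])
    )


class SparseLesionPatch:
    """Precomputed sparse representation of one mask for fast conv+pool.

    Stores the 27-voxel windows of every voxel in the lesion's bounding box
    dilated by one (everywhere else the convolution pre-activation equals the
    kernel bias), the pooling cell of each such voxel, and per-cell bookkeeping
    for the ceil-mode max pool.
    """

    __slots__ = (
        "windows",
        "order",
        "starts",
        "cells",
        "full_inside",
        "n_patch",
    )

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask)
        if mask.shape != GRID_SHAPE:
            raise GridError(f"mask shape {mask.shape} != {GRID_SHAPE}")
        pos = np.argwhere(mask)
        if pos.size == 0:
            # Empty mask: conv output is bias everywhere; no patch voxels.
            self.windows = np.zeros((0, _KSIZE**3), dtype=np.uint8)
            self.order = np.zeros(0, dtype=np.intp)
            self.starts = np.zeros(0, dtype=np.intp)
            self.cells = np.zeros(0, dtype=np.intp)
            self.full_inside = np.zeros(0, dtype=bool)
            self.n_patch = 0
            return
        lo = np.maximum(pos.min(axis=0) - 1, 0)
        hi = np.minimum(pos.max(axis=0) + 1, np.array(GRID_SHAPE) - 1)
        # Sub-volume padded by one more voxel (zeros) so every window is local.
        sub = np.zeros(tuple(hi - lo + 3), dtype=np.uint8)
        src = mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        sub[1:-1, 1:-1, 1:-1] = src
        win = np.lib.stride_tricks.sliding_window_view(sub, (_KSIZE, _KSIZE, _KSIZE))
        self.windows = win.reshape(-1, _KSIZE**3).copy()
        dims = hi - lo + 1
        gx, gy, gz = np.meshgrid(
            np.arange(lo[0], hi[0] + 1),
            np.arange(lo[1], hi[1] + 1),
            np.arange(lo[2], hi[2] + 1),
            indexing="ij",
        )
        cell_id = (
            (gx // _POOL) * (POOLED_SHAPE[1] * POOLED_SHAPE[2])
            + (gy // _POOL) * POOLED_SHAPE[2]
            + (gz // _POOL)
        ).reshape(-1)
        self.n_patch = cell_id.size
        self.order = np.argsort(cell_id, kind="stable")
        sorted_cells = cell_id[self.order]
        self.cells, self.starts, counts = np.unique(
            sorted_cells, return_index=True, return_counts=True
        )
        sizes = np.array(
            [
                _cell_window_size(np.unravel_index(c, POOLED_SHAPE))
                for c in self.cells
            ]
        )
        self.full_inside = counts == sizes

    @classmethod
    def from_image(cls, image: LesionImage | np.ndarray) -> "SparseLesionPatch":
        mask = image.voxels if isinstance(image, LesionImage) else image
        return cls(mask)


@dataclass
class _Weights:
    Wc: np.ndarray  # (n_kernels, 27)
    bc: np.ndarray  # (n_kernels,)
    W1: np.ndarray  # (n_flat, fc_units)
    b1: np.ndarray  # (fc_units,)
    w2: np.ndarray  # (fc_units,)
    b2: float

    def copy(self) -> "_Weights":
        return _Weights(
            self.Wc.copy(), self.bc.copy(), self.W1.copy(), self.b1.copy(),
            self.w2.copy(), float(self.b2),
        )


def _init_weights(config: CNNConfig, rng: np.random.Generator) -> _Weights:
    nk, nf, nh = config.n_kernels, config.n_flat_features, config.fc_units
    return _Weights(
        Wc=rng.normal(0, np.sqrt(2.0 / 27), (nk, _KSIZE**3)).astype(np.float32),
        bc=np.zeros(nk, dtype=np.float32),
        W1=rng.normal(0, np.sqrt(2.0 / nf), (nf, nh)).astype(np.float32),
        b1=np.zeros(nh, dtype=np.float32),
        w2=rng.normal(0, np.sqrt(1.0 / nh), nh).astype(np.float32),
        b2=0.0,
    )


def _pooled_maps(patch: SparseLesionPatch, W: _Weights):
    """Pooled ReLU-conv feature maps (n_cells, n_kernels) plus intermediates."""
    default = np.maximum(W.bc, 0.0)  # pooled value of any all-background window
    nk = W.bc.shape[0]
    pooled = np.tile(default, (_N_CELLS, 1)).astype(np.float32)
    if patch.n_patch == 0:
        return pooled, None, None
    conv = patch.windows.astype(np.float32) @ W.Wc.T + W.bc
    act = np.maximum(conv, 0.0)
    act_sorted = act[patch.order]
    segmax = np.maximum.reduceat(act_sorted, patch.starts, axis=0)
    eff = np.where(
        patch.full_inside[:, None], segmax, np.maximum(segmax, default[None, :])
    )
    pooled[patch.cells] = eff
    return pooled, act_sorted, segmax


def _forward(patch: SparseLesionPatch, W: _Weights):
    pooled, act_sorted, segmax = _pooled_maps(patch, W)
    z = pooled.reshape(-1)
    h_pre = z @ W.W1 + W.b1
    h = np.maximum(h_pre, 0.0)
    o = float(h @ W.w2 + W.b2)
    out = 1.0 / (1.0 + np.exp(-o))
    return out, {
        "pooled": pooled,
        "act_sorted": act_sorted,
        "segmax": segmax,
        "z": z,
        "h_pre": h_pre,
        "h": h,
    }


def _backward(patch: SparseLesionPatch, W: _Weights, cache: dict, out: float, dout: float, grads: _Weights):
    """Accumulate parameter gradients for one image into ``grads``."""
    do = np.float32(dout * out * (1.0 - out))
    h, z = cache["h"], cache["z"]
    grads.w2 += do * h
    grads.b2 += float(do)
    dh = do * W.w2
    dh_pre = dh * (cache["h_pre"] > 0)
    grads.W1 += np.outer(z, dh_pre)
    grads.b1 += dh_pre
    dz = (W.W1 @ dh_pre).astype(np.float32)
    _backward_conv(patch, W, cache, dz, grads)


def _backward_conv(patch: SparseLesionPatch, W: _Weights, cache: dict, dz: np.ndarray, grads: _Weights):
    """Route pooled-map gradients dz (flat, n_cells*n_kernels) to conv params."""
    dpooled = dz.reshape(_N_CELLS, -1)

    default = np.maximum(W.bc, 0.0)
    relu_bias_open = (W.bc > 0).astype(np.float32)
    if patch.n_patch == 0:
        grads.bc += dpooled.sum(axis=0) * relu_bias_open
        return
    segmax = cache["segmax"]
    act_sorted = cache["act_sorted"]
    dp_t = dpooled[patch.cells]
    # Cells whose max came from outside the patch (pure-bias windows).
    from_outside = (~patch.full_inside[:, None]) & (default[None, :] > segmax)
    outside_grad = dpooled.sum(axis=0) - dp_t.sum(axis=0)  # untouched cells
    outside_grad += (dp_t * from_outside).sum(axis=0)
    grads.bc += outside_grad * relu_bias_open

    from_patch = (~from_outside) & (segmax > 0)
    if not from_patch.any():
        return
    seg_sizes = np.diff(np.append(patch.starts, patch.n_patch))
    seg_id = np.repeat(np.arange(patch.cells.size), seg_sizes)
    ismax = act_sorted == segmax[seg_id]
    tie_cnt = np.add.reduceat(ismax.astype(np.float32), patch.starts, axis=0)
    route = (dp_t * from_patch).astype(np.float32)
    dconv_sorted = ismax * (route / np.maximum(tie_cnt, 1.0))[seg_id]
    dconv = np.empty_like(dconv_sorted)
    dconv[patch.order] = dconv_sorted
    grads.Wc += dconv.T @ patch.windows.astype(np.float32)
    grads.bc += dconv.sum(axis=0)


def forward_dense(W: _Weights, mask: np.ndarray):
    """Dense reference forward pass (scipy correlate + explicit ceil pooling).

    Returns (sigmoid output, pooled maps of shape POOLED_SHAPE + (n_kernels,),
    hidden activations).  Used as the oracle for the sparse path.
    """
    mask = np.asarray(mask, dtype=np.float32)
    if mask.shape != GRID_SHAPE:
        raise GridError(f"input shape {mask.shape} != {GRID_SHAPE}")
    nk = W.bc.shape[0]
    pooled = np.empty(POOLED_SHAPE + (nk,), dtype=np.float32)
    for k in range(nk):
        kernel = W.Wc[k].reshape(_KSIZE, _KSIZE, _KSIZE)
        conv = ndimage.correlate(mask, kernel, mode="constant", cval=0.0) + W.bc[k]
        act = np.maximum(conv, 0.0)
        padded = np.full(
            tuple(c * _POOL for c in POOLED_SHAPE), -np.inf, dtype=np.float32
        )
        padded[: GRID_SHAPE[0], : GRID_SHAPE[1], : GRID_SHAPE[2]] = act
        pooled[..., k] = (
            padded.reshape(
                POOLED_SHAPE[0], _POOL, POOLED_SHAPE[1], _POOL, POOLED_SHAPE[2], _POOL
            )
            .max(axis=(1, 3, 5))
        )
    z = pooled.reshape(-1)
    h = np.maximum(z @ W.W1 + W.b1, 0.0)
    o = float(h @ W.w2 + W.b2)
    return 1.0 / (1.0 + np.exp(-o)), pooled, h


@dataclass
class CNNResults:
    """Trained CNN: weights, score scaler, and training diagnostics."""

    config: CNNConfig
    weights: _Weights
    scaler: ScoreScaler
    loss_history: list = field(default_factory=list)
    initial_loss: float | None = None
    final_loss: float | None = None

    def _patch(self, image) -> SparseLesionPatch:
        if isinstance(image, SparseLesionPatch):
            return image
        return SparseLesionPatch.from_image(image)

    def predict_raw(self, image) -> float:
        """Sigmoid output in (0,1) for one image."""
        out, _ = _forward(self._patch(image), self.weights)
        return out

    def _hidden(self, images) -> tuple[np.ndarray, np.ndarray]:
        if not isinstance(images, (list, tuple)):
            images = [images]
        W = self.weights
        Z = np.stack(
            [_pooled_maps(self._patch(im), W)[0].reshape(-1) for im in images]
        )
        H = np.maximum(Z @ W.W1 + W.b1, 0.0)
        raw = 1.0 / (1.0 + np.exp(-(H @ W.w2 + W.b2)))
        return H, raw

    def predict(self, images) -> np.ndarray:
        """Descaled score predictions for one image or a list."""
        _, raw = self._hidden(images)
        return self.scaler.inverse(raw)

    def features(self, images) -> np.ndarray:
        """Post-ReLU activations of the 500-unit fully connected layer."""
        H, _ = self._hidden(images)
        return H.astype(np.float64)

    def summary(self) -> str:
        W = self.weights
        n_params = (
            W.Wc.size + W.bc.size + W.W1.size + W.b1.size + W.w2.size + 1
        )
        lines = [
            "3D CNN results",
            "--------------",
            f"kernels:            {self.config.n_kernels} x 3x3x3 "
            f"({self.config.n_conv_params} conv params)",
            f"pooled maps:        {POOLED_SHAPE} x {self.config.n_kernels}",
            f"fc units:           {self.config.fc_units}",
            f"total params:       {n_params}",
            f"epochs trained:     {len(self.loss_history)}",
        ]
        if self.initial_loss is not None and self.final_loss is not None:
            lines.append(
                f"train MSE (scaled): {self.initial_loss:.6g} -> {self.final_loss:.6g}"
            )
        return "\n".join(lines)

    def save(self, path) -> None:
        """Archive config + weights + scaler into a single .npz file."""
        W = self.weights
        np.savez_compressed(
            path,
            Wc=W.Wc, bc=W.bc, W1=W.W1, b1=W.b1, w2=W.w2, b2=W.b2,
            scaler=np.array(
                [self.scaler.lo, self.scaler.hi, self.scaler.score_min,
                 self.scaler.score_max, float(self.scaler.degenerate)]
            ),
            config=np.array(
                [self.config.n_kernels, self.config.fc_units, self.config.epochs,
                 self.config.batch_size, self.config.learning_rate, self.config.seed]
            ),
            loss_history=np.array(self.loss_history),
        )

    @classmethod
    def load(cls, path) -> "CNNResults":
        with np.load(path) as z:
            cfg_arr = z["config"]
            config = CNNConfig(
                n_kernels=int(cfg_arr[0]), fc_units=int(cfg_arr[1]),
                epochs=int(cfg_arr[2]), batch_size=int(cfg_arr[3]),
                learning_rate=float(cfg_arr[4]), seed=int(cfg_arr[5]),
            )
            s = z["scaler"]
            scaler = ScoreScaler(
                lo=float(s[0]), hi=float(s[1]), score_min=float(s[2]),
                score_max=float(s[3]), degenerate=bool(s[4]),
            )
            weights = _Weights(
                Wc=z["Wc"], bc=z["bc"], W1=z["W1"], b1=z["b1"],
                w2=z["w2"], b2=float(z["b2"]),
            )
            return cls(
                config=config, weights=weights, scaler=scaler,
                loss_history=list(z["loss_history"]),
            )


class LesionCNN:
    """Model builder for the 3D CNN; ``fit`` returns :class:`CNNResults`.

    ``patches`` may carry precomputed :class:`SparseLesionPatch` objects (the
    LOOCV harness reuses them across folds); otherwise they are built here.
    """

    def __init__(self, images, scores, config: CNNConfig | None = None, patches=None):
        if len(images) != len(scores):
            raise ValidationError("images and scores lengths differ")
        if len(images) < 2:
            raise ValidationError("CNN training needs at least two pairs")
        self.images = list(images)
        self.scores = np.asarray(scores, dtype=np.float64)
        self.config = config or CNNConfig()
        self.patches = (
            list(patches)
            if patches is not None
            else [SparseLesionPatch.from_image(im) for im in self.images]
        )

    def fit(self) -> CNNResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        W = _init_weights(cfg, rng)
        scaler = ScoreScaler.fit(self.scores)
        results = CNNResults(config=cfg, weights=W, scaler=scaler)
        if scaler.degenerate:
            # Constant predictor; nothing to learn.
            return results
        targets = scaler.forward(self.scores)
        n = len(self.patches)

        def full_mse(weights: _Weights) -> float:
            Z = np.stack([_pooled_maps(p, weights)[0].reshape(-1) for p in self.patches])
            H = np.maximum(Z @ weights.W1 + weights.b1, 0.0)
            preds = 1.0 / (1.0 + np.exp(-(H @ weights.w2 + weights.b2)))
            return float(np.mean((preds - targets) ** 2))

        results.initial_loss = full_mse(W)

        # Adam state
        m = _Weights(*(np.zeros_like(getattr(W, f)) for f in ("Wc", "bc", "W1", "b1", "w2")), 0.0)
        v = _Weights(*(np.zeros_like(getattr(W, f)) for f in ("Wc", "bc", "W1", "b1", "w2")), 0.0)
        step = 0
        fields = ("Wc", "bc", "W1", "b1", "w2", "b2")

        for _ in range(cfg.epochs):
            perm = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                batch = perm[start : start + cfg.batch_size]
                grads = _Weights(
                    *(np.zeros_like(getattr(W, f)) for f in ("Wc", "bc", "W1", "b1", "w2")),
                    0.0,
                )
                # Sparse conv + pooling per image; fully connected part batched.
                caches = [_pooled_maps(self.patches[i], W) for i in batch]
                Z = np.stack([c[0].reshape(-1) for c in caches])
                Hpre = Z @ W.W1 + W.b1
                H = np.maximum(Hpre, 0.0)
                out = 1.0 / (1.0 + np.exp(-(H @ W.w2 + W.b2)))
                err = out - targets[batch]
                losses = err**2
                dO = ((2.0 / batch.size) * err * out * (1.0 - out)).astype(np.float32)
                grads.w2 += H.T @ dO
                grads.b2 += float(dO.sum())
                dHpre = np.outer(dO, W.w2) * (Hpre > 0)
                grads.W1 += Z.T @ dHpre
                grads.b1 += dHpre.sum(axis=0)
                dZ = (dHpre @ W.W1.T).astype(np.float32)
                for bpos, i in enumerate(batch):
                    pooled, act_sorted, segmax = caches[bpos]
                    _backward_conv(
                        self.patches[i],
                        W,
                        {"act_sorted": act_sorted, "segmax": segmax},
                        dZ[bpos],
                        grads,
                    )
                step += 1
                b1c = 1.0 - cfg.adam_beta1**step
                b2c = 1.0 - cfg.adam_beta2**step
                for f in fields:
                    g = getattr(grads, f)
                    mf = cfg.adam_beta1 * getattr(m, f) + (1 - cfg.adam_beta1) * g
                    vf = cfg.adam_beta2 * getattr(v, f) + (1 - cfg.adam_beta2) * (
                        g * g if isinstance(g, np.ndarray) else g**2
                    )
                    setattr(m, f, mf)
                    setattr(v, f, vf)
                    upd = cfg.learning_rate * (mf / b1c) / (np.sqrt(vf / b2c) + cfg.adam_eps)
                    if isinstance(g, np.ndarray):
                        setattr(W, f, (getattr(W, f) - upd).astype(np.float32))
                    else:
                        setattr(W, f, float(getattr(W, f) - upd))
                epoch_losses.append(float(np.mean(losses)))
            results.loss_history.append(float(np.mean(epoch_losses)))
        results.final_loss = full_mse(W)
        return results


def fit_cnn(images, scores, config: CNNConfig | None = None, patches=None) -> CNNResults:
    """Train the 3D CNN on (images, scores); deterministic given config.seed."""
    return LesionCNN(images, scores, config, patches).fit()


def cnn_forward(model: CNNResults, image) -> float:
    """Raw forward pass of a trained model on one image; output in (0,1)."""
    if not isinstance(model, CNNResults):
        raise StateError("cnn_forward requires a trained CNNResults")
    mask = image.voxels if isinstance(image, LesionImage) else np.asarray(image)
    if mask.shape != GRID_SHAPE:
        raise GridError(f"input shape {mask.shape} != {GRID_SHAPE}")
    return model.predict_raw(LesionImage((mask > 0).astype(np.uint8)))


def extract_cnn_features(model: CNNResults, images) -> np.ndarray:
    """Fully-connected-layer activations (n, 500), all entries >= 0."""
    if not isinstance(model, CNNResults):
        raise StateError("extract_cnn_features requires a trained CNNResults")
    return model.features(images)
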