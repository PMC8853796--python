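"""Encoder-decoder (U-net) segmentation model for 3-class skin scenes.

The architecture is the classical contraction/expansion design: per level
two 3x3 convolutions (each followed by batch normalisation and ReLU), 2x2
max pooling between encoder levels, a double-convolution bottleneck at
2x the deepest encoder width, and a decoder that at each level applies
parameter-free 2x nearest-neighbour upsampling, a 3x3 convolution halving
the channels, concatenation with the matching encoder feature map
(decoder first, encoder second), and two further 3x3 convolutions.  The
head is a 3x3 convolution to ``final_reduce_filters`` channels followed by
a 1x1 convolution to the class logits with per-pixel softmax.

At full scale (``base_filters=64``, ``depth=4``, ``final_reduce_filters=32``)
this realises the published 24-convolution layout; scaled-down widths are
used for desk-scale training and tests.  Because every operation is
translation-equivariant and the only spatial constraint is divisibility by
2**depth (handled by reflect padding), a model trained on fixed 512x512
patches predicts images of arbitrary size in a single forward pass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .synthdata import LabeledImage
from .tiling import _reflect_indices, extract_patches, stitch

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegNetConfig:
    """Architecture hyperparameters.

    ``base_filters=64`` instantiates the full-scale published layout;
    small widths (8 or 16) give desk-scale models with the identical
    topology.
    """

    in_channels: int = 3
    n_classes: int = 3
    base_filters: int = 64
    depth: int = 4
    use_batch_norm: bool = True
    final_reduce_filters: int = 32
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.base_filters < 1 or self.depth < 1 or self.n_classes < 2:
            raise ValueError("invalid SegNetConfig")


def table1_config(seed: int = 0) -> SegNetConfig:
    """The full-scale configuration (64 base filters, depth 4)."""
    return SegNetConfig(base_filters=64, depth=4, final_reduce_filters=32,
                        seed=seed)


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 4
    learning_rate: float = 1e-4
    augment_flips: bool = True
    normalize: bool = True
    loss: str = "cross_entropy"
    class_weighting: str = "none"  # or "inverse_frequency"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is supported")


@dataclass
class TrainHistory:
    """Per-epoch training curves; the fit() results object."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss if self.val_loss else np.nan,
            "train_acc": self.train_acc,
            "val_acc": self.val_acc if self.val_acc else np.nan,
        })

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["Training history", "================",
                 df.to_string(index=False, float_format=lambda v: f"{v:.4f}")]
        if self.best_epoch >= 0:
            lines.append(f"best epoch (val loss): {self.best_epoch + 1}")
        return "\n".join(lines)


def _conv_bn_relu(cin, cout, ksize, rng, dtype, use_bn, tag):
    layers: list[nn.Layer] = [nn.Conv2D(cin, cout, ksize, rng, dtype,
                                        name=f"{tag}.conv")]
    if use_bn:
        layers.append(nn.BatchNorm(cout, dtype, name=f"{tag}.bn"))
    layers.append(nn.ReLU())
    return nn.Sequential(layers)


class UNet:
    """The segmentation model object.

    Construct from a :class:`SegNetConfig` (weights are seeded and
    deterministic), then ``fit`` on patch arrays and ``predict_image`` on
    rasters of arbitrary size.
    """

    def __init__(self, config: SegNetConfig):
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)
        b, d = config.base_filters, config.depth
        bn = config.use_batch_norm
        enc_ch = [b * 2 ** l for l in range(d)]
        bott_ch = b * 2 ** d

        self.enc_blocks: list[nn.Sequential] = []
        cin = config.in_channels
        for l, ch in enumerate(enc_ch):
            self.enc_blocks.append(nn.Sequential([
                _conv_bn_relu(cin, ch, 3, rng, dtype, bn, f"enc{l}a"),
                _conv_bn_relu(ch, ch, 3, rng, dtype, bn, f"enc{l}b"),
            ]))
            cin = ch
        self.pools = [nn.MaxPool2() for _ in range(d)]
        self.bottleneck = nn.Sequential([
            _conv_bn_relu(enc_ch[-1], bott_ch, 3, rng, dtype, bn, "bot_a"),
            _conv_bn_relu(bott_ch, bott_ch, 3, rng, dtype, bn, "bot_b"),
        ])
        self.ups: list[nn.Upsample2] = []
        self.upconvs: list[nn.Sequential] = []
        self.dec_blocks: list[nn.Sequential] = []
        cin = bott_ch
        for l in reversed(range(d)):
            ch = enc_ch[l]
            self.ups.append(nn.Upsample2())
            self.upconvs.append(_conv_bn_relu(cin, ch, 3, rng, dtype, bn,
                                              f"up{l}"))
            self.dec_blocks.append(nn.Sequential([
                _conv_bn_relu(2 * ch, ch, 3, rng, dtype, bn, f"dec{l}a"),
                _conv_bn_relu(ch, ch, 3, rng, dtype, bn, f"dec{l}b"),
            ]))
            cin = ch
        self.final_reduce = _conv_bn_relu(b, config.final_reduce_filters, 3,
                                          rng, dtype, bn, "reduce")
        self.head = nn.Conv2D(config.final_reduce_filters, config.n_classes,
                              1, rng, dtype, name="head")
        self._all = nn.Sequential(
            self.enc_blocks + [self.bottleneck] + self.upconvs
            + self.dec_blocks + [self.final_reduce, self.head]
        )
        self.norm_mean: np.ndarray | None = None
        self.norm_std: np.ndarray | None = None

    # ---- parameter bookkeeping -------------------------------------------

    def params(self):
        return self._all.params()

    def parameter_count(self) -> int:
        """Trainable parameters: kernels, biases, batch-norm affine terms."""
        return int(sum(v.size for _, v, _ in self.params()))

    # ---- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a NHWC batch whose sides divide 2**depth."""
        d = self.config.depth
        skips = []
        h = x
        for l in range(d):
            h = self.enc_blocks[l].forward(h, train)
            skips.append(h)
            h = self.pools[l].forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._cat_sizes = []
        for i, l in enumerate(reversed(range(d))):
            h = self.ups[i].forward(h, train)
            h = self.upconvs[i].forward(h, train)
            self._cat_sizes.append(h.shape[-1])
            h = np.concatenate([h, skips[l]], axis=-1)
            h = self.dec_blocks[i].forward(h, train)
        h = self.final_reduce.forward(h, train)
        return self.head.forward(h, train)

    # ---- training --------------------------------------------------------

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        if self.norm_mean is None:
            return x
        return (x - self.norm_mean) / self.norm_std

    def fit(self, train_images: np.ndarray, train_masks: np.ndarray,
            val_images: np.ndarray | None = None,
            val_masks: np.ndarray | None = None,
            train_config: TrainConfig | None = None,
            early_stop_val_acc: float | None = None) -> TrainHistory:
        """Train with per-pixel cross-entropy and Adam; returns the history.

        Augmentation applies, per sample and per step, independent random
        horizontal and vertical flips jointly to image and mask.
        ``early_stop_val_acc`` stops once validation pixel accuracy reaches
        the given level (checked at epoch end).
        """
        tc = train_config or TrainConfig()
        dtype = np.dtype(self.config.dtype).type
        if train_images.ndim != 4 or len(train_images) == 0:
            raise ValueError("train_images must be a nonempty NHWC array")
        if train_images.shape[:3] != train_masks.shape:
            raise ValueError("patch/mask shape mismatch")
        x = np.ascontiguousarray(train_images, dtype=dtype)
        y = np.ascontiguousarray(train_masks, dtype=np.int64)
        if tc.normalize:
            self.norm_mean = x.mean(axis=(0, 1, 2)).astype(dtype)
            self.norm_std = np.maximum(x.std(axis=(0, 1, 2)),
                                       1e-6).astype(dtype)
        weights = None
        if tc.class_weighting == "inverse_frequency":
            freq = np.bincount(y.reshape(-1),
                               minlength=self.config.n_classes).astype(float)
            freq = np.maximum(freq, 1.0)
            weights = (freq.sum() / (len(freq) * freq)).astype(dtype)

        rng = np.random.default_rng(tc.seed)
        opt = nn.Adam(self._all, lr=tc.learning_rate)
        history = TrainHistory()
        n = len(x)
        best_val = np.inf
        best_state = None
        for epoch in range(tc.epochs):
            order = rng.permutation(n)
            ep_loss, ep_correct, ep_px = 0.0, 0, 0
            for start in range(0, n, tc.batch_size):
                idx = order[start:start + tc.batch_size]
                xb = x[idx]
                yb = y[idx]
                if tc.augment_flips:
                    xb, yb = xb.copy(), yb.copy()
                    for j in range(len(idx)):
                        if rng.random() < 0.5:
                            xb[j] = xb[j, ::-1]
                            yb[j] = yb[j, ::-1]
                        if rng.random() < 0.5:
                            xb[j] = xb[j, :, ::-1]
                            yb[j] = yb[j, :, ::-1]
                xb = self._normalize(xb)
                self._all.zero_grad()
                logits = self.forward(xb, train=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, yb, weights)
                self._backprop(dlogits)
                opt.step()
                ep_loss += loss * yb.size
                ep_correct += int((logits.argmax(-1) == yb).sum())
                ep_px += yb.size
            history.train_loss.append(ep_loss / ep_px)
            history.train_acc.append(ep_correct / ep_px)
            if val_images is not None and len(val_images):
                vl, va = self.evaluate_loss(val_images, val_masks,
                                            batch_size=tc.batch_size,
                                            class_weights=weights)
                history.val_loss.append(vl)
                history.val_acc.append(va)
                if vl < best_val:
                    best_val = vl
                    history.best_epoch = epoch
                    best_state = self._state_arrays()
                logger.info("epoch %d: loss %.4f acc %.4f | val %.4f/%.4f",
                            epoch + 1, history.train_loss[-1],
                            history.train_acc[-1], vl, va)
                if early_stop_val_acc is not None and va >= early_stop_val_acc:
                    break
            else:
                logger.info("epoch %d: loss %.4f acc %.4f", epoch + 1,
                            history.train_loss[-1], history.train_acc[-1])
        if best_state is not None:
            self._load_state_arrays(best_state)
        return history

    def _backprop(self, dlogits: np.ndarray) -> None:
        d = self.config.depth
        dy = self.head.backward(dlogits)
        dy = self.final_reduce.backward(dy)
        dskips: dict[int, np.ndarray] = {}
        # decoder stages ran i = 0..d-1 matching encoder level l = d-1-i;
        # unwind them in reverse order
        for i in reversed(range(d)):
            l = d - 1 - i
            dy = self.dec_blocks[i].backward(dy)
            nch = self._cat_sizes[i]
            dy, dskip = dy[..., :nch].copy(), dy[..., nch:].copy()
            dskips[l] = dskip
            dy = self.upconvs[i].backward(dy)
            dy = self.ups[i].backward(dy)
        dy = self.bottleneck.backward(dy)
        for l in reversed(range(d)):
            dy = self.pools[l].backward(dy)
            dy = dy + dskips[l]
            dy = self.enc_blocks[l].backward(dy)

    def evaluate_loss(self, images: np.ndarray, masks: np.ndarray,
                      batch_size: int = 4,
                      class_weights: np.ndarray | None = None,
                      ) -> tuple[float, float]:
        """Mean loss and pixel accuracy in eval mode (no augmentation)."""
        dtype = np.dtype(self.config.dtype).type
        x = np.asarray(images, dtype=dtype)
        y = np.asarray(masks, dtype=np.int64)
        tot_loss, correct, px = 0.0, 0, 0
        for start in range(0, len(x), batch_size):
            xb = self._normalize(x[start:start + batch_size])
            yb = y[start:start + batch_size]
            logits = self.forward(xb, train=False)
            loss, _ = nn.softmax_cross_entropy(logits, yb, class_weights)
            tot_loss += loss * yb.size
            correct += int((logits.argmax(-1) == yb).sum())
            px += yb.size
        return tot_loss / px, correct / px

    # ---- inference -------------------------------------------------------

    def predict_image(self, pixels: np.ndarray, max_pixels: int | None = None,
                      tile_size: int = 512,
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Segment an arbitrary-size RGB raster.

        The raster is reflect-padded so both sides divide 2**depth, a
        single eval-mode forward pass is run, padding is cropped, and the
        per-pixel softmax probabilities plus the argmax labels (ties to
        the lower class index) are returned.  If the padded image exceeds
        ``max_pixels`` the image is processed in tiles via the tiling
        module and stitched — a memory fallback, flagged in the log.
        """
        pixels = np.asarray(pixels)
        if pixels.ndim != 3 or pixels.shape[2] != self.config.in_channels:
            raise ValueError("expected an HxWx3 raster")
        if pixels.size == 0:
            raise ValueError("empty image")
        h, w = pixels.shape[:2]
        mult = 2 ** self.config.depth
        ph, pw = -h % mult + h, -w % mult + w
        if max_pixels is not None and ph * pw > max_pixels:
            logger.warning("image %dx%d exceeds %d px; tiled inference",
                           h, w, max_pixels)
            return self._predict_tiled(pixels, tile_size)
        ridx = _reflect_indices(h, ph)
        cidx = _reflect_indices(w, pw)
        padded = pixels[ridx][:, cidx]
        dtype = np.dtype(self.config.dtype).type
        xb = self._normalize(padded[None].astype(dtype))
        logits = self.forward(xb, train=False)[0]
        probs = nn.softmax(logits)[:h, :w]
        labels = probs.argmax(axis=-1).astype(np.uint8)
        return labels, probs

    def _predict_tiled(self, pixels, tile_size):
        img = LabeledImage(pixels=pixels,
                           mask=np.zeros(pixels.shape[:2], dtype=np.uint8))
        grid, patches = extract_patches(img, patch_size=tile_size)
        prob_tiles = []
        for p in patches:
            _, probs = self.predict_image(p.pixels)
            prob_tiles.append(probs)
        probs = stitch(grid, prob_tiles)
        labels = probs.argmax(axis=-1).astype(np.uint8)
        return labels, probs

    # ---- persistence -----------------------------------------------------

    def _state_arrays(self) -> dict[str, np.ndarray]:
        state = {name: v.copy() for name, v, _ in self.params()}
        for layer in self._iter_layers():
            if isinstance(layer, nn.BatchNorm):
                state[f"{layer.name}.running_mean"] = layer.running_mean.copy()
                state[f"{layer.name}.running_var"] = layer.running_var.copy()
        return state

    def _load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for name, v, _ in self.params():
            v[...] = state[name]
        for layer in self._iter_layers():
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = state[f"{layer.name}.running_mean"]
                layer.running_var[...] = state[f"{layer.name}.running_var"]

    def _iter_layers(self):
        stack = list(self._all.layers)
        while stack:
            layer = stack.pop()
            if isinstance(layer, nn.Sequential):
                stack.extend(layer.layers)
            else:
                yield layer

    def save(self, path: Path | str, extra: dict | None = None) -> None:
        """Write weights (.npz) plus a JSON sidecar with the config."""
        path = Path(path)
        state = self._state_arrays()
        if self.norm_mean is not None:
            state["__norm_mean"] = self.norm_mean
            state["__norm_std"] = self.norm_std
        np.savez_compressed(path, **state)
        sidecar = {
            "config": asdict(self.config),
            "parameter_count": self.parameter_count(),
        }
        if extra:
            sidecar.update(extra)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: Path | str) -> "UNet":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        model = cls(SegNetConfig(**sidecar["config"]))
        with np.load(path if path.suffix == ".npz"
                     else path.with_suffix(".npz")) as data:
            state = {k: data[k] for k in data.files}
        if "__norm_mean" in state:
            model.norm_mean = state.pop("__norm_mean")
            model.norm_std = state.pop("__norm_std")
        model._load_state_arrays(state)
        return model


def expected_parameter_count(config: SegNetConfig) -> int:
    """Closed-form trainable-parameter count of a configuration.

    Sums, layer by layer, kernel weights + biases for each convolution and
    the two affine terms per channel for each batch norm.  Kept separate
    from the network so the built model can be audited against it.
    """
    def conv(cin, cout, k):
        return k * k * cin * cout + cout

    def bn(c):
        return 2 * c if config.use_batch_norm else 0

    b, d = config.base_filters, config.depth
    total = 0
    cin = config.in_channels
    for l in range(d):
        ch = b * 2 ** l
        total += conv(cin, ch, 3) + bn(ch) + conv(ch, ch, 3) + bn(ch)
        cin = ch
    bott = b * 2 ** d
    total += conv(cin, bott, 3) + bn(bott) + conv(bott, bott, 3) + bn(bott)
    cin = bott
    for l in reversed(range(d)):
        ch = b * 2 ** l
        total += conv(cin, ch, 3) + bn(ch)          # post-upsample conv
        total += conv(2 * ch, ch, 3) + bn(ch)       # after concatenation
        total += conv(ch, ch, 3) + bn(ch)
        cin = ch
    total += conv(b, config.final_reduce_filters, 3)
    total += bn(config.final_reduce_filters)
    total += conv(config.final_reduce_filters, config.n_classes, 1)
    return total
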