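"""Deterministic patch extraction from large images and lossless reassembly.

Whole-body photographs are far larger than what a segmentation network can
hold in memory during training, so training and validation data are cut
into nonoverlapping fixed-size tiles (default 512x512, stride equal to the
tile size).  Images whose sides are not multiples of the tile size are
reflect-padded on the bottom and right edges; `stitch` inverts the whole
operation exactly, so stitch(extract_patches(x)) == x pixelwise for images
and masks alike.  Pure-background tiles carry no skin/lesion signal and are
dropped by a deterministic foreground-fraction rule before training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import LabeledImage


@dataclass(frozen=True)
class PatchGrid:
    """Geometry of one tiling: enough to reassemble the original image."""

    patch_size: int
    stride: int
    pad_top: int
    pad_left: int
    pad_bottom: int
    pad_right: int
    original_height: int
    original_width: int
    n_rows: int
    n_cols: int


@dataclass
class Patch:
    pixels: np.ndarray  # (p, p, 3)
    mask: np.ndarray | None  # (p, p) or None
    row: int
    col: int
    source_id: str = ""


def _reflect_indices(n: int, total: int) -> np.ndarray:
    """Indices implementing reflect padding of arbitrary width.

    Maps 0..total-1 onto 0..n-1 by mirroring without repeating the edge
    sample (numpy's 'reflect' mode), but valid for any padding width —
    np.pad rejects reflect pads wider than the axis.
    """
    idx = np.arange(total)
    if n == 1:
        return np.zeros(total, dtype=int)
    period = 2 * (n - 1)
    idx = idx % period
    return np.where(idx < n, idx, period - idx)


def _pad_reflect(arr: np.ndarray, pad_bottom: int, pad_right: int) -> np.ndarray:
    h, w = arr.shape[:2]
    ridx = _reflect_indices(h, h + pad_bottom)
    cidx = _reflect_indices(w, w + pad_right)
    return arr[ridx][:, cidx]


def _pad_zero(arr: np.ndarray, pad_bottom: int, pad_right: int) -> np.ndarray:
    pads = [(0, pad_bottom), (0, pad_right)] + [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, pads, mode="constant")


def extract_patches(image: LabeledImage, patch_size: int = 512,
                    stride: int | None = None, pad_mode: str = "reflect",
                    ) -> tuple[PatchGrid, list[Patch]]:
    """Tile an image (and its mask) into nonoverlapping fixed-size patches.

    The image is padded on the bottom/right to the next multiple of
    ``patch_size`` (reflect by default, zeros behind ``pad_mode="zero"``)
    and cut row-major.  Only ``stride == patch_size`` is supported: the
    overlapping case is rejected rather than half-implemented.
    """
    if patch_size < 16:
        raise ValueError("patch_size must be >= 16")
    stride = patch_size if stride is None else stride
    if stride != patch_size:
        raise ValueError("only nonoverlapping tiling (stride == patch_size) "
                         "is supported")
    h, w = image.mask.shape
    if h < 1 or w < 1:
        raise ValueError("image must be at least 1x1")
    pad_b = (-h) % patch_size
    pad_r = (-w) % patch_size
    pad = {"reflect": _pad_reflect, "zero": _pad_zero}[pad_mode]
    pixels = pad(np.asarray(image.pixels), pad_b, pad_r)
    mask = pad(np.asarray(image.mask), pad_b, pad_r)
    n_rows = (h + pad_b) // patch_size
    n_cols = (w + pad_r) // patch_size
    grid = PatchGrid(
        patch_size=patch_size, stride=stride,
        pad_top=0, pad_left=0, pad_bottom=pad_b, pad_right=pad_r,
        original_height=h, original_width=w, n_rows=n_rows, n_cols=n_cols,
    )
    patches = []
    for r in range(n_rows):
        for c in range(n_cols):
            sl = np.s_[r * patch_size:(r + 1) * patch_size,
                       c * patch_size:(c + 1) * patch_size]
            patches.append(Patch(pixels=pixels[sl], mask=mask[sl],
                                 row=r, col=c, source_id=image.id))
    return grid, patches


def foreground_fraction(mask: np.ndarray) -> float:
    """Fraction of pixels labelled skin or psoriasis."""
    return float((mask > 0).mean())


def filter_background_patches(patches: list[Patch],
                              min_foreground_fraction: float = 0.0,
                              ) -> list[Patch]:
    """Drop tiles whose skin+psoriasis fraction is <= the threshold.

    The default threshold 0 removes exactly the pure-background tiles
    (those containing no skin and no psoriasis pixels); a single foreground
    pixel retains the tile.
    """
    for p in patches:
        if p.mask is None:
            raise ValueError(f"patch ({p.row},{p.col}) carries no mask")
    return [p for p in patches
            if foreground_fraction(p.mask) > min_foreground_fraction]


def stitch(grid: PatchGrid, patches: list[Patch] | list[np.ndarray],
           attr: str = "pixels") -> np.ndarray:
    """Reassemble a full-size raster from a complete set of tiles.

    ``patches`` may be :class:`Patch` objects (``attr`` selects pixels or
    mask) or bare arrays paired implicitly in row-major order only when
    every Patch position is present exactly once.
    """
    p = grid.patch_size
    ph, pw = grid.n_rows * p, grid.n_cols * p
    seen: dict[tuple[int, int], np.ndarray] = {}
    if patches and isinstance(patches[0], Patch):
        for patch in patches:  # type: ignore[assignment]
            key = (patch.row, patch.col)
            if key in seen:
                raise ValueError(f"duplicate patch at {key}")
            data = getattr(patch, attr)
            if data is None:
                raise ValueError(f"patch {key} has no '{attr}'")
            seen[key] = np.asarray(data)
    else:
        if len(patches) != grid.n_rows * grid.n_cols:
            raise ValueError("bare-array stitching needs exactly one array "
                             "per grid cell in row-major order")
        for i, arr in enumerate(patches):
            seen[(i // grid.n_cols, i % grid.n_cols)] = np.asarray(arr)
    missing = [(r, c) for r in range(grid.n_rows) for c in range(grid.n_cols)
               if (r, c) not in seen]
    if missing:
        raise ValueError(f"missing patches at {missing[:4]}...")
    sample = next(iter(seen.values()))
    out = np.empty((ph, pw) + sample.shape[2:], dtype=sample.dtype)
    for (r, c), data in seen.items():
        out[r * p:(r + 1) * p, c * p:(c + 1) * p] = data
    return out[:grid.original_height, :grid.original_width]
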