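"""Seeded synthetic body photographs with pixel-perfect 3-class ground truth.

Real clinical photographs of psoriasis patients are not publicly
distributable, so every downstream stage of this package (tiling, network
training, evaluation, agreement analysis) is exercised on synthetic scenes:
a connected "body" silhouette of smoothly shaded skin on a studio-backdrop
background, with psoriasis lesions rendered as irregular reddened blobs
strictly inside the silhouette.  The generator is deterministic given a
:class:`SceneSpec` (which embeds a seed), and the realised psoriasis area
fraction — psoriasis pixels over body (skin + psoriasis) pixels, the same
definition the evaluation module uses — is driven to the requested target
by a monotone search over a global lesion-radius multiplier.

Labels: 0 = background, 1 = healthy skin, 2 = psoriasis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

BACKGROUND, SKIN, PSORIASIS = 0, 1, 2

#: indexed-PNG palette for label masks (background slate, skin tan, lesion red)
MASK_PALETTE = [40, 40, 48, 224, 172, 138, 200, 48, 48]

# Maximum factor by which the achievement loop may blow up lesion_scale
# before the target fraction is declared geometrically infeasible.
_MAX_RADIUS_MULTIPLIER = 8.0


class InfeasibleSpecError(ValueError):
    """Raised when a scene's target psoriasis fraction cannot be realised."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic body scene.

    Parameters
    ----------
    height, width
        Output raster size in pixels (each >= 64).
    target_psoriasis_fraction
        Desired psoriasis / (skin + psoriasis) pixel fraction in [0, 1].
    n_lesions
        Number of lesion blobs seeded inside the silhouette.
    lesion_scale
        Mean lesion radius in pixels before the achievement loop rescales.
    body_fraction
        Approximate fraction of the image covered by the body silhouette.
    texture_noise
        Standard deviation of per-pixel colour jitter in [0, 1] units.
    seed
        Seed for the scene's private random generator.
    """

    height: int
    width: int
    target_psoriasis_fraction: float = 0.2
    n_lesions: int = 5
    lesion_scale: float = 40.0
    body_fraction: float = 0.5
    texture_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("height and width must be >= 64")
        if not 0.0 <= self.target_psoriasis_fraction <= 1.0:
            raise ValueError("target_psoriasis_fraction must be in [0, 1]")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if not 0.0 < self.body_fraction <= 1.0:
            raise ValueError("body_fraction must be in (0, 1]")
        if self.n_lesions == 0 and self.target_psoriasis_fraction > 0:
            raise InfeasibleSpecError(
                "target_psoriasis_fraction > 0 requires n_lesions >= 1"
            )


@dataclass
class LabeledImage:
    """An RGB raster in [0, 1] with an aligned {0, 1, 2} label mask."""

    pixels: np.ndarray  # (H, W, 3) float
    mask: np.ndarray  # (H, W) uint8
    id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != self.mask.shape:
            raise ValueError("pixels and mask must share spatial dimensions")
        labels = np.unique(self.mask)
        if labels.size and (labels.min() < 0 or labels.max() > 2):
            raise ValueError("mask labels must be in {0, 1, 2}")


@dataclass
class ManifestEntry:
    id: str
    image_path: str
    mask_path: str
    split: str
    true_ratio: float


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry] = field(default_factory=list)
    seed: int = 0

    def split_ids(self, split: str) -> list[str]:
        return [e.id for e in self.entries if e.split == split]

    def save(self, path: Path | str) -> None:
        # paths are written relative to the manifest so identical seeds
        # yield byte-identical manifests regardless of the output directory
        path = Path(path)
        base = path.parent.resolve()

        def rel(p: str) -> str:
            rp = Path(p).resolve()
            try:
                return rp.relative_to(base).as_posix()
            except ValueError:
                return str(rp)

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "image_path", "mask_path", "split", "true_ratio"])
            for e in self.entries:
                writer.writerow(
                    [e.id, rel(e.image_path), rel(e.mask_path), e.split,
                     f"{e.true_ratio:.8f}"]
                )

    @classmethod
    def load(cls, path: Path | str, seed: int = 0) -> "DatasetManifest":
        path = Path(path)
        base = path.parent
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    ManifestEntry(
                        id=row["id"],
                        image_path=str(base / row["image_path"]),
                        mask_path=str(base / row["mask_path"]),
                        split=row["split"],
                        true_ratio=float(row["true_ratio"]),
                    )
                )
        return cls(entries=entries, seed=seed)


def _blob_mask(center: tuple[float, float], radius: float,
               profile_fn, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a star-shaped blob; only its bounding box is evaluated."""
    h, w = shape
    cy, cx = center
    rmax = radius * 2.2
    y0, y1 = max(0, int(cy - rmax)), min(h, int(cy + rmax) + 1)
    x0, x1 = max(0, int(cx - rmax)), min(w, int(cx + rmax) + 1)
    out = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    out[y0:y1, x0:x1] = rr <= radius * profile_fn(theta)
    return out


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Low-frequency random field in roughly [-1, 1], for shading."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    scale = np.abs(smooth).max()
    return smooth / scale if scale > 0 else smooth


def _body_silhouette(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    # ellipse sized so its area is ~ body_fraction of the frame, capped to fit
    s = min(np.sqrt(spec.body_fraction * 4.0 / np.pi), 0.96)
    ry, rx = s * h / 2.0, s * w / 2.0
    cy = h / 2.0 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2.0 + rng.uniform(-0.02, 0.02) * w
    harmonics = [
        (0.10 * rng.uniform(0.3, 1.0) / k, rng.uniform(0, 2 * np.pi))
        for k in range(1, 5)
    ]
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - cy) / ry, (xx - cx) / rx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    profile = np.ones_like(rr)
    for k, (amp, phase) in enumerate(harmonics, start=1):
        profile += amp * np.cos(k * theta + phase)
    return rr <= np.clip(profile, 0.5, None)


def _lesion_fraction(body: np.ndarray, lesions: np.ndarray) -> float:
    body_px = int(body.sum())
    return float((lesions & body).sum() / body_px) if body_px else 0.0


def generate_body_image(spec: SceneSpec) -> LabeledImage:
    """Render one synthetic scene with its ground-truth mask.

    The realised psoriasis fraction of body pixels lands within +/-0.05 of
    ``spec.target_psoriasis_fraction`` whenever that is geometrically
    feasible; otherwise :class:`InfeasibleSpecError` is raised rather than
    silently falling short.  Identical spec (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    body = _body_silhouette(spec, rng)

    # --- lesion geometry: star blobs, global radius multiplier bisected to
    # hit the target fraction (monotone until lesions saturate the body)
    lesion_mask = np.zeros((h, w), dtype=bool)
    target = spec.target_psoriasis_fraction
    if spec.n_lesions > 0 and target > 0:
        interior = ndimage.binary_erosion(
            body, iterations=max(2, int(min(h, w) * 0.02))
        )
        iy, ix = np.nonzero(interior)
        if iy.size == 0:
            iy, ix = np.nonzero(body)
        picks = rng.integers(0, iy.size, size=spec.n_lesions)
        centers = [(float(iy[p]), float(ix[p])) for p in picks]
        base_radii = spec.lesion_scale * rng.uniform(0.5, 1.5, size=spec.n_lesions)
        # freeze one angular profile per lesion so the bisection re-rasterises
        # identical shapes at different scales
        lesion_params = []
        for i in range(spec.n_lesions):
            n_h = 4
            amps = [0.35 * rng.uniform(0.3, 1.0) / k for k in range(1, n_h + 1)]
            phases = [rng.uniform(0, 2 * np.pi) for _ in range(n_h)]
            lesion_params.append((centers[i], base_radii[i], amps, phases))

        def rasterise(mult: float) -> np.ndarray:
            acc = np.zeros((h, w), dtype=bool)
            for (c, r, amps, phases) in lesion_params:
                def prof(th, amps=amps, phases=phases):
                    p = np.ones_like(th)
                    for k, (a, ph) in enumerate(zip(amps, phases), start=1):
                        p += a * np.cos(k * th + ph)
                    return np.clip(p, 0.35, None)
                acc |= _blob_mask(c, r * mult, prof, (h, w))
            return acc & body

        lo, hi = 0.0, _MAX_RADIUS_MULTIPLIER
        best = rasterise(1.0)
        if abs(_lesion_fraction(body, best) - target) > 0.02:
            hi_mask = rasterise(hi)
            if _lesion_fraction(body, hi_mask) < target - 0.05:
                raise InfeasibleSpecError(
                    f"target fraction {target} unreachable with n_lesions="
                    f"{spec.n_lesions}, lesion_scale={spec.lesion_scale}"
                )
            for _ in range(24):
                mid = 0.5 * (lo + hi)
                best = rasterise(mid)
                f = _lesion_fraction(body, best)
                if abs(f - target) <= 0.01:
                    break
                if f < target:
                    lo = mid
                else:
                    hi = mid
        lesion_mask = best
        realised = _lesion_fraction(body, lesion_mask)
        if abs(realised - target) > 0.05:
            raise InfeasibleSpecError(
                f"achievement loop stalled at fraction {realised:.3f} "
                f"for target {target:.3f}"
            )

    mask = np.zeros((h, w), dtype=np.uint8)
    mask[body] = SKIN
    mask[lesion_mask] = PSORIASIS

    # --- colour model: shaded backdrop, shaded tan skin, reddened lesions
    shade_sigma = max(8.0, min(h, w) / 12.0)
    skin_shade = 1.0 + 0.15 * _smooth_field(rng, (h, w), shade_sigma)
    bg_shade = 1.0 + 0.20 * _smooth_field(rng, (h, w), shade_sigma)
    speckle = _smooth_field(rng, (h, w), 2.0)

    img = np.empty((h, w, 3), dtype=np.float64)
    bg_color = np.array([0.32, 0.36, 0.42])
    skin_color = np.array([0.80, 0.62, 0.50])
    lesion_color = np.array([0.72, 0.26, 0.24])
    img[:] = bg_color * bg_shade[..., None]
    img[body] = skin_color * skin_shade[body, None]
    lesion_px = skin_color * 0.25 + lesion_color * 0.75
    img[lesion_mask] = lesion_px * skin_shade[lesion_mask, None]
    # silvery scale speckle on lesions only (mimics desquamation highlights)
    img[lesion_mask] += 0.10 * speckle[lesion_mask, None]

    if spec.texture_noise > 0:
        img += rng.normal(0.0, spec.texture_noise, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    # quantise to 8 bits so in-memory scenes match their PNG round trip
    img = np.round(img * 255.0) / 255.0
    return LabeledImage(pixels=img, mask=mask, id=f"scene-{spec.seed}")


def realized_psoriasis_fraction(mask: np.ndarray) -> float:
    """Psoriasis over body (skin + psoriasis) pixel fraction of a mask."""
    body = int(((mask == SKIN) | (mask == PSORIASIS)).sum())
    return float((mask == PSORIASIS).sum() / body) if body else 0.0


def save_labeled_image(img: LabeledImage, image_path: Path | str,
                       mask_path: Path | str) -> None:
    """Write the raster as 8-bit RGB PNG and the mask as indexed PNG."""
    arr = np.round(np.asarray(img.pixels) * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(image_path, format="PNG")
    pal = Image.fromarray(img.mask.astype(np.uint8), mode="P")
    pal.putpalette(MASK_PALETTE + [0] * (768 - len(MASK_PALETTE)))
    pal.save(mask_path, format="PNG")


def load_labeled_image(image_path: Path | str, mask_path: Path | str,
                       id: str = "") -> LabeledImage:
    pixels = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.float64)
    mask = np.asarray(Image.open(mask_path), dtype=np.uint8)
    return LabeledImage(pixels=pixels / 255.0, mask=mask,
                        id=id or Path(image_path).stem)


DEFAULT_SPEC_RANGES: dict = {
    "height": (192, 320),
    "width": (192, 320),
    "target_psoriasis_fraction": (0.02, 0.45),
    "n_lesions": (2, 8),
    "lesion_scale_rel": (0.06, 0.16),  # relative to min(height, width)
    "body_fraction": (0.35, 0.6),
    "texture_noise": (0.01, 0.03),
}


def sample_scene_spec(rng: np.random.Generator, spec_ranges: dict | None = None,
                      seed: int | None = None) -> SceneSpec:
    """Draw one SceneSpec from (uniform) parameter ranges."""
    r = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        r.update(spec_ranges)
    h = int(rng.integers(r["height"][0], r["height"][1] + 1))
    w = int(rng.integers(r["width"][0], r["width"][1] + 1))
    return SceneSpec(
        height=h,
        width=w,
        target_psoriasis_fraction=float(rng.uniform(*r["target_psoriasis_fraction"])),
        n_lesions=int(rng.integers(r["n_lesions"][0], r["n_lesions"][1] + 1)),
        lesion_scale=float(rng.uniform(*r["lesion_scale_rel"]) * min(h, w)),
        body_fraction=float(rng.uniform(*r["body_fraction"])),
        texture_noise=float(rng.uniform(*r["texture_noise"])),
        seed=int(seed if seed is not None else rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(out_dir: Path | str, n_train: int, n_val: int, n_test: int,
                     spec_ranges: dict | None = None, seed: int = 0,
                     ) -> DatasetManifest:
    """Write a train/val/test image+mask dataset and its manifest to disk.

    Per-image specs are sampled reproducibly from ``spec_ranges``; the same
    seed yields byte-identical files and manifest.  A sidecar YAML records
    the seed and ranges.
    """
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split counts must be >= 0")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = DatasetManifest(seed=seed)
    counter = 0
    for split, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        for _ in range(n):
            # a sampled spec can be geometrically infeasible (large target
            # fraction, few small lesions); resample deterministically
            img = None
            for _attempt in range(8):
                scene_seed = int(rng.integers(0, 2**31 - 1))
                spec = sample_scene_spec(rng, spec_ranges, seed=scene_seed)
                try:
                    img = generate_body_image(spec)
                    break
                except InfeasibleSpecError:
                    continue
            if img is None:
                raise InfeasibleSpecError(
                    "spec_ranges produce infeasible scenes repeatedly")
            img_id = f"{split}-{counter:04d}"
            counter += 1
            image_path = out_dir / "images" / f"{img_id}.png"
            mask_path = out_dir / "masks" / f"{img_id}.png"
            save_labeled_image(img, image_path, mask_path)
            manifest.entries.append(
                ManifestEntry(
                    id=img_id,
                    image_path=str(image_path),
                    mask_path=str(mask_path),
                    split=split,
                    true_ratio=realized_psoriasis_fraction(img.mask),
                )
            )
    manifest.save(out_dir / "manifest.csv")
    with open(out_dir / "dataset.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "seed": seed,
                "spec_ranges": {
                    k: list(v) if isinstance(v, tuple) else v
                    for k, v in {**DEFAULT_SPEC_RANGES, **(spec_ranges or {})}.items()
                },
                "counts": {"train": n_train, "val": n_val, "test": n_test},
            },
            fh,
        )
    return manifest
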