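"""Synthetic CT-like lung nodule phantoms with paired ground-truth masks.

Each phantom emulates a cropped axial chest-CT slice at the level of the
lung fields: a mid-grey soft-tissue background, two dark elliptical lung
fields, bright curvilinear vessel distractors, and one or more bright
circular nodules. The nodule disks are the foreground class; the binary
mask is the exact union of the rendered disks, so ground truth is perfect
by construction.

The module also provides the augmentation set used to expand a small
dataset sixfold (original, horizontal and vertical flips, 90° and 180°
rotations, and a central crop resized back), an 80/20 train/validation
splitter, and PNG + CSV persistence so datasets round-trip through disk.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["PhantomSpec", "ImageSample", "NodulePlacement", "disk_mask",
           "sample_placements", "render_phantom", "generate_phantom",
           "generate_dataset", "augment_dataset", "split_dataset",
           "persist_dataset", "load_dataset", "AUGMENT_NAMES"]

#: intensity of the soft-tissue background surrounding the lung fields
BODY_INTENSITY = 0.55
#: additive intensity of vessel distractors inside the lungs
VESSEL_CONTRAST = 0.22

AUGMENT_NAMES = ("orig", "hflip", "vflip", "rot90", "rot180", "crop")


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one family of phantoms.

    ``lung_field`` is ``(row_axis_frac, col_axis_frac, base_intensity)``:
    the semi-axes of each elliptical lung field as fractions of
    ``image_size`` and the interior (air) intensity.
    """

    image_size: int = 256
    nodule_count_range: tuple[int, int] = (1, 3)
    nodule_radius_range: tuple[float, float] = (3.0, 12.0)
    nodule_contrast_range: tuple[float, float] = (0.25, 0.5)
    lung_field: tuple[float, float, float] = (0.32, 0.20, 0.18)
    vessel_count_range: tuple[int, int] = (2, 6)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        for name in ("nodule_count_range", "nodule_radius_range",
                     "nodule_contrast_range", "vessel_count_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
        if self.nodule_radius_range[0] < 1:
            raise ValueError("nodule radius lower bound must be >= 1 pixel")
        if self.nodule_count_range[0] < 0:
            raise ValueError("nodule count cannot be negative")
        if not 0.0 <= self.lung_field[2] <= 1.0:
            raise ValueError("lung base intensity must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @classmethod
    def roi(cls, image_size: int = 64) -> "PhantomSpec":
        """Nodule-centred ROI-crop regime: small images, resolvable nodules.

        Emulates the common protocol of cropping a small patch around each
        nodule centroid, where the nodule occupies a larger fraction of the
        field than in a full axial slice.
        """
        return cls(image_size=image_size, nodule_count_range=(1, 2),
                   nodule_radius_range=(3.0 * image_size / 64,
                                        8.0 * image_size / 64),
                   vessel_count_range=(1, 4))

    def scaled(self, image_size: int) -> "PhantomSpec":
        """The same anatomy at another resolution (radii scale linearly)."""
        f = image_size / self.image_size
        return replace(self, image_size=image_size,
                       nodule_radius_range=(max(1.0, self.nodule_radius_range[0] * f),
                                            max(1.0, self.nodule_radius_range[1] * f)))


@dataclass
class ImageSample:
    """One image/mask pair; ``source_id`` tracks the pre-augmentation original."""

    id: str
    image: np.ndarray  # (H, W, 3) float in [0, 1], three identical channels
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.source_id:
            self.source_id = self.id
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(f"image/mask spatial dims differ: "
                             f"{self.image.shape[:2]} vs {self.mask.shape}")


@dataclass(frozen=True)
class NodulePlacement:
    center: tuple[float, float]  # (row, col) in pixels
    radius: float
    contrast: float


def disk_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    """Binary disk: pixels whose center lies within Euclidean ``radius``."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (d2 <= radius ** 2).astype(np.uint8)


def _lung_centers(size: int) -> list[tuple[float, float]]:
    return [(0.5 * size, 0.30 * size), (0.5 * size, 0.70 * size)]


def _lung_interior(size: int, lung_field: tuple[float, float, float]) -> np.ndarray:
    ar, ac = lung_field[0] * size, lung_field[1] * size
    rr, cc = np.mgrid[0:size, 0:size]
    interior = np.zeros((size, size), dtype=bool)
    for cr, ccenter in _lung_centers(size):
        interior |= ((rr - cr) / ar) ** 2 + ((cc - ccenter) / ac) ** 2 <= 1.0
    return interior


def sample_placements(spec: PhantomSpec, rng: np.random.Generator) -> list[NodulePlacement]:
    """Draw nodule centers (inside a lung field), radii and contrasts."""
    n = int(rng.integers(spec.nodule_count_range[0], spec.nodule_count_range[1] + 1))
    size = spec.image_size
    ar, ac = spec.lung_field[0] * size, spec.lung_field[1] * size
    placements = []
    for _ in range(n):
        cr, cc = _lung_centers(size)[int(rng.integers(0, 2))]
        # polar sampling keeps the center well inside the ellipse
        theta = rng.uniform(0, 2 * math.pi)
        rho = math.sqrt(rng.uniform(0, 1)) * 0.75
        center = (cr + rho * ar * math.sin(theta), cc + rho * ac * math.cos(theta))
        center = (float(np.clip(center[0], 1, size - 2)),
                  float(np.clip(center[1], 1, size - 2)))
        radius = float(rng.uniform(*spec.nodule_radius_range))
        contrast = float(rng.uniform(*spec.nodule_contrast_range))
        placements.append(NodulePlacement(center, radius, contrast))
    return placements


def _draw_vessels(canvas: np.ndarray, interior: np.ndarray,
                  spec: PhantomSpec, rng: np.random.Generator) -> None:
    """Paint bright curvilinear distractors (vessel cross-sections)."""
    size = spec.image_size
    n = int(rng.integers(spec.vessel_count_range[0], spec.vessel_count_range[1] + 1))
    rows, cols = np.nonzero(interior)
    if rows.size == 0 or n == 0:
        return
    for _ in range(n):
        k = int(rng.integers(0, rows.size))
        r, c = float(rows[k]), float(cols[k])
        angle = rng.uniform(0, 2 * math.pi)
        curvature = rng.uniform(-0.08, 0.08)
        length = rng.uniform(0.1, 0.35) * size
        width = rng.uniform(0.8, 1.6)
        steps = max(int(length), 4)
        for s in range(steps):
            angle += curvature * rng.uniform(0.5, 1.5) / 4
            r += math.sin(angle)
            c += math.cos(angle)
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < size and 0 <= ci < size) or not interior[ri, ci]:
                break
            w = int(math.ceil(width))
            rlo, rhi = max(ri - w, 0), min(ri + w + 1, size)
            clo, chi = max(ci - w, 0), min(ci + w + 1, size)
            sub = canvas[rlo:rhi, clo:chi]
            rr, cc = np.mgrid[rlo:rhi, clo:chi]
            hit = (rr - r) ** 2 + (cc - c) ** 2 <= width ** 2
            sub[hit] = np.maximum(sub[hit], spec.lung_field[2] + VESSEL_CONTRAST)


def render_phantom(spec: PhantomSpec, placements: Sequence[NodulePlacement],
                   rng: np.random.Generator, sample_id: str = "phantom") -> ImageSample:
    """Render background, vessels and the given nodules; build the mask.

    The mask is exactly the union of the nodule disks; vessels and noise
    perturb only the image.
    """
    size = spec.image_size
    canvas = np.full((size, size), BODY_INTENSITY)
    interior = _lung_interior(size, spec.lung_field)
    canvas[interior] = spec.lung_field[2]
    _draw_vessels(canvas, interior, spec, rng)
    mask = np.zeros((size, size), dtype=np.uint8)
    for p in placements:
        disk = disk_mask((size, size), p.center, p.radius)
        mask |= disk
        canvas = np.where(disk, canvas + p.contrast, canvas)
    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    image = np.repeat(canvas[:, :, None], 3, axis=2)
    return ImageSample(id=sample_id, image=image, mask=mask)


def generate_phantom(spec: PhantomSpec, seed: int, sample_id: str = "phantom") -> ImageSample:
    """Deterministically generate one phantom from ``(spec, seed)``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), spec.seed]))
    placements = sample_placements(spec, rng)
    return render_phantom(spec, placements, rng, sample_id=sample_id)


def generate_dataset(n: int, spec: PhantomSpec, seed: int | None = None) -> list[ImageSample]:
    """Generate ``n`` phantoms with per-sample seeds derived from ``seed``."""
    if n < 0:
        raise ValueError(f"dataset size must be non-negative, got {n}")
    master = spec.seed if seed is None else int(seed)
    children = np.random.SeedSequence(master).spawn(n)
    samples = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        placements = sample_placements(spec, rng)
        samples.append(render_phantom(spec, placements, rng, sample_id=f"ph{i:04d}"))
    return samples


# -- augmentation -------------------------------------------------------

def _resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an (H, W, 3) float image."""
    chans = [np.asarray(Image.fromarray(image[:, :, c].astype(np.float32), mode="F")
                        .resize((size, size), Image.BILINEAR))
             for c in range(image.shape[2])]
    return np.clip(np.stack(chans, axis=2).astype(np.float64), 0.0, 1.0)


def _resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resize of a binary (H, W) mask."""
    out = Image.fromarray((mask * 255).astype(np.uint8), mode="L").resize(
        (size, size), Image.NEAREST)
    return (np.asarray(out) > 127).astype(np.uint8)


def _center_crop(sample: ImageSample, frac: float = 0.75) -> tuple[np.ndarray, np.ndarray]:
    h, w = sample.mask.shape
    ch, cw = int(round(h * frac)), int(round(w * frac))
    r0, c0 = (h - ch) // 2, (w - cw) // 2
    return (sample.image[r0:r0 + ch, c0:c0 + cw],
            sample.mask[r0:r0 + ch, c0:c0 + cw])


def augment_dataset(samples: Sequence[ImageSample]) -> list[ImageSample]:
    """Expand each sample sixfold with paired image/mask transforms.

    Variants: original, horizontal flip, vertical flip, 90° and 180°
    rotations, and a central 75% crop resized back to the original size
    (bilinear for the image, nearest-neighbour for the mask).
    """
    if len(samples) == 0:
        raise ValueError("augment_dataset requires a non-empty input")
    out: list[ImageSample] = []
    for s in samples:
        h = s.mask.shape[0]
        geo = {
            "orig": (s.image, s.mask),
            "hflip": (s.image[:, ::-1], s.mask[:, ::-1]),
            "vflip": (s.image[::-1, :], s.mask[::-1, :]),
            "rot90": (np.rot90(s.image, 1, axes=(0, 1)), np.rot90(s.mask, 1)),
            "rot180": (np.rot90(s.image, 2, axes=(0, 1)), np.rot90(s.mask, 2)),
        }
        crop_img, crop_mask = _center_crop(s)
        geo["crop"] = (_resize_image(crop_img, h), _resize_mask(crop_mask, h))
        for name in AUGMENT_NAMES:
            img, msk = geo[name]
            out.append(ImageSample(id=f"{s.id}-{name}",
                                   image=np.ascontiguousarray(img),
                                   mask=np.ascontiguousarray(msk),
                                   source_id=s.source_id))
    return out


# -- splitting ----------------------------------------------------------

def split_dataset(samples: Sequence[ImageSample], train_fraction: float,
                  seed: int, leak_free: bool = True
                  ) -> tuple[list[ImageSample], list[ImageSample]]:
    """Random disjoint train/validation partition.

    With ``leak_free`` (default) the partition is drawn over distinct
    ``source_id`` groups so augmented copies of one original can never
    straddle the split; the 80/20 floor is then applied to the group
    count. Without it the samples themselves are partitioned and
    ``len(train) == floor(train_fraction * n)`` exactly.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    samples = list(samples)
    if leak_free:
        sources = sorted({s.source_id for s in samples})
        order = rng.permutation(len(sources))
        n_train = int(math.floor(train_fraction * len(sources)))
        train_sources = {sources[i] for i in order[:n_train]}
        train = [s for s in samples if s.source_id in train_sources]
        val = [s for s in samples if s.source_id not in train_sources]
    else:
        order = rng.permutation(len(samples))
        n_train = int(math.floor(train_fraction * len(samples)))
        chosen = set(order[:n_train].tolist())
        train = [s for i, s in enumerate(samples) if i in chosen]
        val = [s for i, s in enumerate(samples) if i not in chosen]
    return train, val


# -- persistence --------------------------------------------------------

def persist_dataset(samples: Sequence[ImageSample], directory: str | Path) -> Path:
    """Write images/masks as 8-bit PNG plus a CSV manifest; return its path."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        img_rel = os.path.join("images", f"{s.id}.png")
        mask_rel = os.path.join("masks", f"{s.id}.png")
        img8 = np.clip(np.rint(s.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(img8, mode="RGB").save(directory / img_rel)
        Image.fromarray((s.mask * 255).astype(np.uint8), mode="L").save(
            directory / mask_rel)
        rows.append({"id": s.id, "source_id": s.source_id,
                     "image": img_rel, "mask": mask_rel})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=["id", "source_id", "image", "mask"]).to_csv(
        manifest, index=False)
    return manifest


def load_dataset(directory: str | Path) -> list[ImageSample]:
    """Load a persisted dataset; raises ``FileNotFoundError`` naming any missing file."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest found at {manifest}")
    frame = pd.read_csv(manifest)
    samples = []
    for row in frame.itertuples(index=False):
        img_path = directory / row.image
        mask_path = directory / row.mask
        for p in (img_path, mask_path):
            if not p.exists():
                raise FileNotFoundError(f"dataset file missing: {p}")
        image = np.asarray(Image.open(img_path).convert("RGB")).astype(np.float64) / 255.0
        mask = (np.asarray(Image.open(mask_path).convert("L")) > 127).astype(np.uint8)
        samples.append(ImageSample(id=str(row.id), image=image, mask=mask,
                                   source_id=str(row.source_id)))
    return samples
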