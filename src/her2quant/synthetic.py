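"""Synthetic IHC-like tiles and composite slides.

The generator emulates the visual semantics of HER2 immunohistochemistry at
the level a tile classifier needs: an eosin-pink background, cells with
hematoxylin-stained nuclei, and DAB-brown membrane rings whose intensity and
completeness increase with the HER2 score. The four scored classes use
disjoint intensity ranges, so the learning task is well posed; a plain
mean-brown-intensity threshold already separates them. ``normal`` renders
sparse small cells with no membrane staining and ``noise`` renders scan
artifacts (blank fields, blur, fold streaks).

Slide-level ground truth follows the clinical >10 % rule transposed from
cells to tiles: the score is the highest class among {1+, 2+, 3+} whose
proportion among tumor tiles exceeds 0.10, otherwise 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import TILE_CLASSES, TUMOR_CLASSES
from .errors import ConfigurationError
from .tlcn import TileDataset

TILE_SIZE = 256

#: Class-conditioned DAB membrane intensity ranges (fraction of full brown).
MEMBRANE_INTENSITY: dict[str, tuple[float, float]] = {
    "0": (0.0, 0.03),
    "1+": (0.10, 0.25),
    "2+": (0.35, 0.55),
    "3+": (0.70, 0.95),
}
#: Fraction of each cell boundary that is stained.
MEMBRANE_COMPLETENESS: dict[str, tuple[float, float]] = {
    "0": (0.0, 0.0),
    "1+": (0.25, 0.45),
    "2+": (0.60, 0.80),
    "3+": (0.90, 1.00),
}

_BACKGROUND = np.array([231.0, 204.0, 231.0])  # eosin-like pink (R==B: stain-neutral)
_NUCLEUS_TUMOR = np.array([96.0, 74.0, 152.0])  # hematoxylin purple
_NUCLEUS_NORMAL = np.array([70.0, 78.0, 150.0])
_DAB_BROWN = np.array([125.0, 74.0, 28.0])


@dataclass
class SynthTileSpec:
    """Fully resolved recipe for one tile; identical spec -> identical image."""

    class_label: str
    seed: int = 0
    n_cells: int | None = None
    membrane_intensity: float | None = None
    membrane_completeness: float | None = None

    def __post_init__(self):
        if self.class_label not in TILE_CLASSES:
            raise ConfigurationError(f"unknown tile class {self.class_label!r}")


@dataclass
class SynthSlideSpec:
    """Recipe for a composite slide built from a class mixture over tiles."""

    grid_rows: int
    grid_cols: int
    mixture: dict[str, float] = field(default_factory=lambda: {"3+": 0.5, "normal": 0.5})
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("slide grid dims must be >= 1")
        for cls in self.mixture:
            if cls not in TILE_CLASSES:
                raise ConfigurationError(f"unknown class in mixture: {cls!r}")
        total = float(sum(self.mixture.values()))
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(f"mixture must sum to 1, got {total}")
        if not any(c in TUMOR_CLASSES and v > 0 for c, v in self.mixture.items()):
            raise ConfigurationError("mixture must contain at least one scored (tumor) class")


def _draw_cells(img: np.ndarray, rng: np.random.Generator, n_cells: int,
                radius_range: tuple[float, float], nucleus_color: np.ndarray,
                intensity: float, completeness: float) -> None:
    size = img.shape[0]
    for _ in range(n_cells):
        r = rng.uniform(*radius_range)
        cy = rng.uniform(r, size - r)
        cx = rng.uniform(r, size - r)
        lo_y, hi_y = max(0, int(cy - r - 3)), min(size, int(cy + r + 4))
        lo_x, hi_x = max(0, int(cx - r - 3)), min(size, int(cx + r + 4))
        yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
        dy, dx = yy - cy, xx - cx
        dist = np.hypot(dy, dx)
        patch = img[lo_y:hi_y, lo_x:hi_x]
        # faint cytoplasm then nucleus
        cyto = dist <= r
        patch[cyto] = 0.85 * patch[cyto] + 0.15 * nucleus_color
        nucleus = dist <= 0.45 * r
        patch[nucleus] = 0.25 * patch[nucleus] + 0.75 * nucleus_color
        if intensity > 0 and completeness > 0:
            ring = np.abs(dist - r) <= 3.0
            if completeness < 1.0:
                phi0 = rng.uniform(0, 2 * np.pi)
                ang = np.mod(np.arctan2(dy, dx) - phi0, 2 * np.pi)
                ring &= ang <= 2 * np.pi * completeness
            alpha = min(intensity, 1.0)
            patch[ring] = (1 - alpha) * patch[ring] + alpha * _DAB_BROWN


def _noise_tile(rng: np.random.Generator) -> np.ndarray:
    kind = int(rng.integers(3))
    if kind == 0:  # blank glass
        img = np.full((TILE_SIZE, TILE_SIZE, 3), 246.0)
        img += rng.normal(0, 3, img.shape)
    elif kind == 1:  # out-of-focus tissue
        img = np.broadcast_to(_BACKGROUND, (TILE_SIZE, TILE_SIZE, 3)).copy()
        img += rng.normal(0, 25, img.shape)
        img = gaussian_filter(img, sigma=(7, 7, 0))
    else:  # tissue fold: dark overlapping streaks
        img = np.broadcast_to(_BACKGROUND, (TILE_SIZE, TILE_SIZE, 3)).copy()
        yy, xx = np.mgrid[0:TILE_SIZE, 0:TILE_SIZE]
        for _ in range(int(rng.integers(2, 5))):
            theta = rng.uniform(0, np.pi)
            offset = rng.uniform(-0.5 * TILE_SIZE, 1.5 * TILE_SIZE)
            width = rng.uniform(6, 18)
            d = np.abs(np.cos(theta) * xx + np.sin(theta) * yy - offset)
            mask = d < width
            img[mask] *= 0.35
        img += rng.normal(0, 4, img.shape)
    return img


def generate_tile(spec: SynthTileSpec | str, seed: int | None = None) -> np.ndarray:
    """Render one 256x256x3 uint8 tile; deterministic under the spec seed."""
    if isinstance(spec, str):
        spec = SynthTileSpec(class_label=spec, seed=0 if seed is None else seed)
    rng = np.random.default_rng(spec.seed)
    cls = spec.class_label
    if cls == "noise":
        img = _noise_tile(rng)
    else:
        img = np.broadcast_to(_BACKGROUND, (TILE_SIZE, TILE_SIZE, 3)).copy()
        img += rng.normal(0, 3, img.shape)
        if cls == "normal":
            n_cells = spec.n_cells if spec.n_cells is not None else int(rng.integers(8, 15))
            _draw_cells(img, rng, n_cells, (6.0, 9.0), _NUCLEUS_NORMAL, 0.0, 0.0)
        else:
            n_cells = spec.n_cells if spec.n_cells is not None else int(rng.integers(28, 37))
            lo, hi = MEMBRANE_INTENSITY[cls]
            intensity = (
                spec.membrane_intensity
                if spec.membrane_intensity is not None
                else float(rng.uniform(lo, hi))
            )
            lo, hi = MEMBRANE_COMPLETENESS[cls]
            completeness = (
                spec.membrane_completeness
                if spec.membrane_completeness is not None
                else float(rng.uniform(lo, hi))
            )
            _draw_cells(img, rng, n_cells, (12.0, 18.0), _NUCLEUS_TUMOR, intensity, completeness)
    return np.clip(img, 0, 255).astype(np.uint8)


def dab_proxy(image: np.ndarray) -> float:
    """Mean brown-stain proxy: positive part of (R - B), scaled to [0, 1]."""
    img = image.astype(np.float32)
    return float(np.maximum(img[..., 0] - img[..., 2], 0.0).mean() / 255.0)


def generate_dataset(n_per_class: int, seed: int = 0) -> TileDataset:
    """Balanced six-class tile dataset with a per-class 8:1:1 split."""
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels, slide_ids, splits = [], [], [], []
    n_train = int(0.8 * n_per_class)
    n_val = int(0.1 * n_per_class)
    for cls in TILE_CLASSES:
        tile_seeds = rng.integers(0, 2**31, size=n_per_class)
        for i, ts in enumerate(tile_seeds):
            images.append(generate_tile(SynthTileSpec(class_label=cls, seed=int(ts))))
            labels.append(cls)
            slide_ids.append(f"synth-{cls}-{i // 20}")
            if i < n_train:
                splits.append("train")
            elif i < n_train + n_val:
                splits.append("val")
            else:
                splits.append("test")
    return TileDataset(
        images=np.stack(images),
        labels=np.array(labels, dtype=object),
        slide_ids=np.array(slide_ids, dtype=object),
        splits=np.array(splits, dtype=object),
    )


def label_by_rule(proportions: np.ndarray | dict[str, float]) -> str:
    """Slide score from tumor-tile proportions via the >10 % rule."""
    if isinstance(proportions, dict):
        p = np.array([proportions.get(c, 0.0) for c in TUMOR_CLASSES], dtype=float)
    else:
        p = np.asarray(proportions, dtype=float)
    for k in (3, 2, 1):
        if p[k] > 0.10:
            return TUMOR_CLASSES[k]
    return "0"


def _sample_vector(cls: str, rng: np.random.Generator) -> np.ndarray:
    """One tumor-proportion vector whose rule label is ``cls``."""
    while True:
        p = np.zeros(4)
        if cls == "3+":
            p[3] = rng.uniform(0.10, 1.0)
            rest = rng.dirichlet(np.ones(3)) * (1.0 - p[3])
            p[:3] = rest
        elif cls == "2+":
            p[3] = rng.uniform(0.0, 0.10)
            p[2] = rng.uniform(0.10, 1.0 - p[3])
            rest = rng.dirichlet(np.ones(2)) * (1.0 - p[2] - p[3])
            p[:2] = rest
        elif cls == "1+":
            hi = rng.uniform(0.0, 0.10, size=2)
            p[2], p[3] = hi
            p[1] = rng.uniform(0.10, 1.0 - hi.sum())
            p[0] = 1.0 - p[1:].sum()
        else:
            p[1:] = rng.uniform(0.0, 0.10, size=3)
            p[0] = 1.0 - p[1:].sum()
        if p.min() >= 0 and label_by_rule(p) == cls:
            return p


def generate_category_vectors(
    n: int, seed: int = 0
) -> tuple[np.ndarray, list[str]]:
    """``n`` tumor-proportion vectors, class-balanced, labeled by the rule."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    vectors, labels = [], []
    for i in range(n):
        cls = TUMOR_CLASSES[i % 4]
        vectors.append(_sample_vector(cls, rng))
        labels.append(cls)
    return np.array(vectors), labels


def generate_slide(
    spec: SynthSlideSpec,
) -> tuple[np.ndarray, str, list[list[str]]]:
    """Composite slide image, its rule-derived ground truth, and tile truth.

    Tiling the returned image with a 256-px non-overlapping window recovers
    the constituent tiles pixel for pixel.
    """
    rng = np.random.default_rng(spec.seed)
    n_tiles = spec.grid_rows * spec.grid_cols
    classes = [c for c in TILE_CLASSES if spec.mixture.get(c, 0) > 0]
    quotas = np.array([spec.mixture[c] * n_tiles for c in classes])
    counts = np.floor(quotas).astype(int)
    remainder = n_tiles - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for j in order[:remainder]:
        counts[j] += 1
    assignment = [c for c, k in zip(classes, counts) for _ in range(k)]
    rng.shuffle(assignment)

    image = np.empty((spec.grid_rows * TILE_SIZE, spec.grid_cols * TILE_SIZE, 3), dtype=np.uint8)
    tile_truth: list[list[str]] = []
    idx = 0
    for r in range(spec.grid_rows):
        row_truth = []
        for c in range(spec.grid_cols):
            cls = assignment[idx]
            idx += 1
            tile = generate_tile(SynthTileSpec(class_label=cls, seed=int(rng.integers(0, 2**31))))
            image[r * TILE_SIZE : (r + 1) * TILE_SIZE, c * TILE_SIZE : (c + 1) * TILE_SIZE] = tile
            row_truth.append(cls)
        tile_truth.append(row_truth)

    tumor_counts = {c: assignment.count(c) for c in TUMOR_CLASSES}
    n_tumor = sum(tumor_counts.values())
    proportions = {c: tumor_counts[c] / n_tumor for c in TUMOR_CLASSES}
    truth = label_by_rule(proportions)
    return image, truth, tile_truth
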