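"""Whole-slide pipeline: sliding-window tiling, tile-class aggregation into
the four-class proportion vector, and end-to-end slide scoring.

Tiling is non-overlapping (stride == tile size) with partial edge windows
dropped; windows are half-open ``[x0, x0+256) x [y0, y0+256)`` with a
top-left origin. No tissue mask is applied: blank or artifact regions are
expected to land in the classifier's ``noise``/``normal`` classes, which are
excluded from the proportion vector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .backbone import TileClassifier
from .config import TILE_CLASSES, TUMOR_CLASSES, SCORE_TO_CLINICAL
from .errors import DataError, NoTumorTilesError
from .tlcn import predict_tiles
from .whspn import SlideScorer


@dataclass
class Tile:
    row: int
    col: int
    x0: int  # column offset, px
    y0: int  # row offset, px
    image: np.ndarray  # [256, 256, 3] view into the slide


@dataclass
class TileGrid:
    slide_id: str
    tiles: list[Tile]
    tile_size: int = 256
    stride: int = 256
    n_rows: int = 0
    n_cols: int = 0


@dataclass
class CategoryVector:
    """Proportions of (0, 1+, 2+, 3+) among tiles predicted as those classes."""

    p: np.ndarray
    n_tumor_tiles: int
    n_total_tiles: int

    def to_dict(self) -> dict:
        return {
            "p": [float(v) for v in self.p],
            "n_tumor_tiles": self.n_tumor_tiles,
            "n_total_tiles": self.n_total_tiles,
        }


@dataclass
class SlideRecord:
    slide_id: str
    tile_classes: list[tuple[int, int, str]]  # (row, col, class)
    category_vector: CategoryVector | None
    pred_score: str | None
    pred_clinical: str | None
    true_score: str | None = None
    unscorable: bool = False
    tile_probs: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "tile_classes": [[r, c, k] for r, c, k in self.tile_classes],
            "category_vector": None if self.category_vector is None else self.category_vector.to_dict(),
            "pred_score": self.pred_score,
            "pred_clinical": self.pred_clinical,
            "true_score": self.true_score,
            "unscorable": self.unscorable,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def tile_slide(
    image: np.ndarray, tile_size: int = 256, stride: int = 256, slide_id: str = "slide"
) -> TileGrid:
    """Crop a slide into the grid of full non-overlapping windows."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DataError(f"slide must be an RGB H x W x 3 array, got {image.shape}")
    h, w = image.shape[:2]
    n_rows = max(0, (h - tile_size) // stride + 1)
    n_cols = max(0, (w - tile_size) // stride + 1)
    if n_rows == 0 or n_cols == 0:
        warnings.warn(
            f"slide {slide_id!r} ({h}x{w}) smaller than tile size {tile_size}; empty grid"
        )
        return TileGrid(slide_id=slide_id, tiles=[], tile_size=tile_size, stride=stride)
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * stride, c * stride
            tiles.append(
                Tile(row=r, col=c, x0=x0, y0=y0, image=image[y0 : y0 + tile_size, x0 : x0 + tile_size])
            )
    return TileGrid(
        slide_id=slide_id, tiles=tiles, tile_size=tile_size, stride=stride,
        n_rows=n_rows, n_cols=n_cols,
    )


def aggregate(predictions: Sequence[str]) -> CategoryVector:
    """Tumor-class proportion vector; normal/noise excluded from both sides."""
    bad = set(predictions) - set(TILE_CLASSES)
    if bad:
        raise DataError(f"unknown classes in predictions: {sorted(map(str, bad))}")
    counts = np.array([sum(1 for p in predictions if p == c) for c in TUMOR_CLASSES], dtype=float)
    n_tumor = int(counts.sum())
    if n_tumor == 0:
        raise NoTumorTilesError("no tiles predicted as a scored (0/1+/2+/3+) class")
    return CategoryVector(p=counts / n_tumor, n_tumor_tiles=n_tumor, n_total_tiles=len(predictions))


def _load_slide_image(slide: str | Path | np.ndarray) -> tuple[np.ndarray | None, TileGrid | None, str]:
    """Accept an array, an image file, or a pre-tiled directory with manifest."""
    if isinstance(slide, np.ndarray):
        return slide, None, "slide"
    path = Path(slide)
    if path.is_dir():
        import imageio.v3 as iio

        manifest = path / "tiles.csv"
        if not manifest.exists():
            raise DataError(f"pre-tiled slide directory {path} lacks tiles.csv")
        df = pd.read_csv(manifest)
        required = {"path", "row", "col", "x0", "y0"}
        if not required.issubset(df.columns):
            raise DataError(f"tiles.csv must have columns {sorted(required)}")
        tiles = [
            Tile(
                row=int(rec.row), col=int(rec.col), x0=int(rec.x0), y0=int(rec.y0),
                image=np.asarray(iio.imread(path / rec.path)),
            )
            for rec in df.itertuples()
        ]
        grid = TileGrid(slide_id=path.name, tiles=tiles)
        return None, grid, path.name
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path), None, path.stem
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)), None, path.stem


def score_slide(
    slide: str | Path | np.ndarray,
    tile_model: TileClassifier,
    wsi_scorer: SlideScorer,
    slide_id: str | None = None,
    true_score: str | None = None,
) -> SlideRecord:
    """Full pipeline: tile -> classify -> aggregate -> predict HER2 score.

    A slide whose tiles are all predicted normal/noise is returned as an
    unscorable record rather than raising.
    """
    image, grid, inferred_id = _load_slide_image(slide)
    slide_id = slide_id or inferred_id
    if grid is None:
        grid = tile_slide(image, slide_id=slide_id)
    if not grid.tiles:
        return SlideRecord(
            slide_id=slide_id, tile_classes=[], category_vector=None,
            pred_score=None, pred_clinical=None, true_score=true_score, unscorable=True,
        )
    batch = np.stack([t.image for t in grid.tiles])
    classes, probs = predict_tiles(tile_model, batch)
    tile_classes = [(t.row, t.col, k) for t, k in zip(grid.tiles, classes)]
    try:
        vector = aggregate(classes)
    except NoTumorTilesError:
        return SlideRecord(
            slide_id=slide_id, tile_classes=tile_classes, category_vector=None,
            pred_score=None, pred_clinical=None, true_score=true_score,
            unscorable=True, tile_probs=probs,
        )
    score = wsi_scorer.predict(vector.p[None, :])[0]
    return SlideRecord(
        slide_id=slide_id,
        tile_classes=tile_classes,
        category_vector=vector,
        pred_score=score,
        pred_clinical=SCORE_TO_CLINICAL[score],
        true_score=true_score,
        tile_probs=probs,
    )


def predictions_to_frame(record: SlideRecord) -> pd.DataFrame:
    """Per-tile prediction table (row, col, class, six probabilities)."""
    rows = []
    for i, (r, c, k) in enumerate(record.tile_classes):
        row = {"row": r, "col": c, "class": k}
        if record.tile_probs is not None:
            for j, name in enumerate(("p0", "p1", "p2", "p3", "pnormal", "pnoise")):
                row[name] = float(record.tile_probs[i, j])
        rows.append(row)
    return pd.DataFrame(rows)
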