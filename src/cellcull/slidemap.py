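"""Slide-map assembly, flat-field illumination correction and file I/O.

A slide-map is the full image of a smear slide assembled from raster-scanned
tiles. Shading is modelled as multiplicative (transmission imaging), so
uneven illumination is corrected by dividing by a blank background image and
rescaling to a constant reference level.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: relative clamp applied to background pixels before division
EPSILON_FRACTION = 1.0 / 65535.0
#: default background gray level of a corrected map
DEFAULT_TARGET_LEVEL = 220.0

VALID_LABELS = ("suitable", "unsuitable", "unlabeled")


@dataclass
class SlideMap:
    """Assembled RGB slide image with its tile-grid geometry.

    Coordinates are 0-based (row, col) with the origin at the top-left.
    """

    pixels: np.ndarray  # (H, W, 3)
    tile_grid: tuple[int, int]
    tile_shape: tuple[int, int]

    def __post_init__(self):
        h, w = self.pixels.shape[:2]
        gr, gc = self.tile_grid
        th, tw = self.tile_shape
        if (h, w) != (gr * th, gc * tw):
            raise ValueError(
                f"raster {h}x{w} does not equal tile_grid {gr}x{gc} "
                f"times tile_shape {th}x{tw}")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class SelectionRecord:
    """Boundary polygon and suitability label of one selected object."""

    object_id: int
    boundary: np.ndarray  # (k, 2) of (row, col); closed polygon, k >= 3
    label: str = "unlabeled"

    def __post_init__(self):
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise ValueError("boundary must be an (k, 2) array of (row, col)")
        if len(self.boundary) < 3:
            raise ValueError("boundary needs at least 3 vertices")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}")


def stitch_tiles(tiles, grid: tuple[int, int]) -> SlideMap:
    """Assemble row-major tiles into a slide-map without blending."""
    rows, cols = grid
    tiles = [np.asarray(t) for t in tiles]
    if len(tiles) != rows * cols:
        raise ValueError(f"expected {rows * cols} tiles, got {len(tiles)}")
    shape0 = tiles[0].shape
    if any(t.shape != shape0 for t in tiles):
        raise ValueError("all tiles must have the same shape")
    th, tw = shape0[:2]
    blocks = [[tiles[i * cols + j] for j in range(cols)] for i in range(rows)]
    pixels = np.block(blocks) if tiles[0].ndim == 2 else np.concatenate(
        [np.concatenate(row, axis=1) for row in blocks], axis=0)
    return SlideMap(pixels=pixels, tile_grid=(rows, cols), tile_shape=(th, tw))


def split_tiles(slide: SlideMap) -> list[np.ndarray]:
    """Inverse of :func:`stitch_tiles`: recover the row-major tile list."""
    th, tw = slide.tile_shape
    rows, cols = slide.tile_grid
    return [slide.pixels[i * th:(i + 1) * th, j * tw:(j + 1) * tw].copy()
            for i in range(rows) for j in range(cols)]


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, SlideMap) else np.asarray(image)


def correct_illumination(slide, background,
                         target_level: float = DEFAULT_TARGET_LEVEL):
    """Flat-field correction: divide by the blank background image.

    The output is rescaled so clear-background regions sit at
    ``target_level``. ``background`` may equal the map's shape or be a single
    tile, in which case it is tiled across the map. Returns the same type as
    the input (``SlideMap`` in, ``SlideMap`` out).
    """
    raw = _pixels(slide).astype(np.float64)
    bg = _pixels(background).astype(np.float64)
    if bg.ndim == 2:
        bg = bg[:, :, None]
    if raw.ndim == 2:
        raw = raw[:, :, None]
    if bg.shape[:2] != raw.shape[:2]:
        reps_r, rem_r = divmod(raw.shape[0], bg.shape[0])
        reps_c, rem_c = divmod(raw.shape[1], bg.shape[1])
        if rem_r or rem_c:
            raise ValueError("background shape matches neither the map nor a tile")
        bg = np.tile(bg, (reps_r, reps_c, 1))
    if bg.shape[2] == 1 and raw.shape[2] == 3:
        bg = np.repeat(bg, 3, axis=2)

    eps = EPSILON_FRACTION * max(bg.max(), 1.0)
    n_clamped = int((bg <= eps).sum())
    if n_clamped:
        warnings.warn(f"{n_clamped} background pixels <= epsilon were clamped",
                      stacklevel=2)
        bg = np.maximum(bg, eps)
    corrected = raw / bg * target_level
    corrected = np.squeeze(corrected)
    if isinstance(slide, SlideMap):
        return SlideMap(pixels=corrected, tile_grid=slide.tile_grid,
                        tile_shape=slide.tile_shape)
    return corrected


def to_grayscale(image) -> np.ndarray:
    """Unweighted mean of the three channels (the convention used throughout)."""
    px = _pixels(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return px.astype(np.float64).mean(axis=2)


# ---------------------------------------------------------------------------
# image and record I/O
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return tifffile.imread(path)
    import imageio.v3 as iio
    return iio.imread(path)


def write_image(path, image) -> None:
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        photometric = "rgb" if image.ndim == 3 and image.shape[2] in (3, 4) \
            else "minisblack"
        tifffile.imwrite(path, image, photometric=photometric)
        return
    import imageio.v3 as iio
    iio.imwrite(path, image)


def write_selection_records(records, path) -> None:
    payload = {"objects": [
        {"object_id": int(r.object_id),
         "label": r.label,
         "boundary": np.asarray(r.boundary).tolist()}
        for r in records
    ]}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_selection_records(path) -> list[SelectionRecord]:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed selection file {path}: {exc}") from exc
    if "objects" not in payload:
        raise ValueError("malformed selection file: missing 'objects' field")
    records = []
    for i, obj in enumerate(payload["objects"]):
        for field_name in ("object_id", "boundary"):
            if field_name not in obj:
                raise ValueError(
                    f"malformed selection record {i}: missing '{field_name}'")
        records.append(SelectionRecord(
            object_id=obj["object_id"],
            boundary=np.asarray(obj["boundary"], dtype=float),
            label=obj.get("label", "unlabeled"),
        ))
    return records
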