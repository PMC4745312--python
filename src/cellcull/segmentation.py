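"""Object detection on corrected slide-maps.

The cascade: grayscale conversion, bicubic half-resolution downsampling,
contrast flattening with H-minima/H-maxima morphological reconstruction,
edge detection (Sobel + Laplacian-of-Gaussian zero crossings), morphological
cleanup (closing, hole filling, small-object removal), and connected-component
extraction back at full resolution. There is no randomness anywhere in this
module; the whole pipeline is deterministic.

Touching cells are deliberately *not* split: clumps must be rejected as
unsuitable downstream, so a clump is a single object here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, transform
from skimage.filters import sobel, threshold_otsu

from . import slidemap as sm

#: assumed dynamic range of corrected gray images
DYNAMIC_RANGE = 255.0


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the detection cascade.

    ``h_minima_depth``/``h_maxima_depth`` are fractions of the dynamic range;
    they flatten regional extrema shallower than that depth, suppressing
    texture before edge detection. ``min_object_area`` is in full-resolution
    pixels^2 and is rescaled internally for the half-resolution stage.
    """

    downsample_factor: int = 2
    h_minima_depth: float = 0.05
    h_maxima_depth: float = 0.05
    log_sigma: float = 2.0
    min_object_area: int = 400
    closing_radius: int = 2
    border_policy: str = "drop"  # "keep" | "drop"
    edge_combine: str = "or"  # "or" | "and"
    target_level: float = sm.DEFAULT_TARGET_LEVEL

    def __post_init__(self):
        if not (0 <= self.h_minima_depth < 1 and 0 <= self.h_maxima_depth < 1):
            raise ValueError("h depths must lie in [0, 1) of dynamic range")
        if self.min_object_area <= 0:
            raise ValueError("min_object_area must be positive")
        if self.border_policy not in ("keep", "drop"):
            raise ValueError("border_policy must be 'keep' or 'drop'")
        if self.edge_combine not in ("or", "and"):
            raise ValueError("edge_combine must be 'or' or 'and'")


@dataclass
class ObjectRecord:
    """One segmented object, aligned with the full-resolution slide-map."""

    object_id: int
    mask: np.ndarray  # boolean, local (bbox) frame
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) excl.
    boundary: np.ndarray  # (k, 2) full-frame pixel coordinates, clockwise
    crop: np.ndarray | None = None  # RGB bbox cutout
    gray_crop: np.ndarray | None = None
    label: str | None = None

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def full_mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def downsample_half(image: np.ndarray) -> np.ndarray:
    """Bicubic reduction to half resolution (ceil of each dimension)."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image too small to downsample")
    out_shape = (int(np.ceil(image.shape[0] / 2)),
                 int(np.ceil(image.shape[1] / 2)))
    if image.ndim == 3:
        out_shape = out_shape + (image.shape[2],)
    return transform.resize(image, out_shape, order=3, mode="reflect",
                            anti_aliasing=True, preserve_range=True)


def flatten_contrast(gray: np.ndarray, h_min: float, h_max: float) -> np.ndarray:
    """Suppress shallow regional extrema via morphological reconstruction.

    ``h_min``/``h_max`` are fractions of :data:`DYNAMIC_RANGE`. Minima
    shallower than ``h_min`` and maxima shallower than ``h_max`` are
    flattened; deeper extrema lose exactly that depth (H-transform property).
    """
    gray = np.asarray(gray, dtype=np.float64)
    footprint = np.ones((3, 3))
    out = gray
    hmax = h_max * DYNAMIC_RANGE
    if hmax > 0:
        out = morphology.reconstruction(out - hmax, out, method="dilation",
                                        footprint=footprint)
    hmin = h_min * DYNAMIC_RANGE
    if hmin > 0:
        out = morphology.reconstruction(out + hmin, out, method="erosion",
                                        footprint=footprint)
    return out


def _log_zero_crossings(gray: np.ndarray, sigma: float) -> np.ndarray:
    """Zero crossings of the Laplacian-of-Gaussian, magnitude-thresholded."""
    log = ndi.gaussian_laplace(gray, sigma=sigma)
    thresh = 0.75 * np.mean(np.abs(log))
    if thresh <= 0:
        return np.zeros(gray.shape, dtype=bool)
    edges = np.zeros(gray.shape, dtype=bool)
    for axis in (0, 1):
        a = np.take(log, range(log.shape[axis] - 1), axis=axis)
        b = np.take(log, range(1, log.shape[axis]), axis=axis)
        crossing = (np.sign(a) * np.sign(b) < 0) & (np.abs(a - b) > thresh)
        near_zero_a = np.abs(a) <= np.abs(b)
        mark_a = crossing & near_zero_a
        mark_b = crossing & ~near_zero_a
        if axis == 0:
            edges[:-1, :] |= mark_a
            edges[1:, :] |= mark_b
        else:
            edges[:, :-1] |= mark_a
            edges[:, 1:] |= mark_b
    return edges


def edge_image(gray: np.ndarray, log_sigma: float = 2.0,
               combine: str = "or") -> np.ndarray:
    """Binary edge map: Sobel (Otsu-thresholded) combined with LoG crossings."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("edge_image expects a 2-D gray image")
    grad = sobel(gray)
    if grad.max() - grad.min() < 1e-12:
        sobel_edges = np.zeros(gray.shape, dtype=bool)
    else:
        sobel_edges = grad > threshold_otsu(grad)
    log_edges = _log_zero_crossings(gray, log_sigma)
    if combine == "and":
        return sobel_edges & log_edges
    return sobel_edges | log_edges


def morphological_cleanup(binary: np.ndarray, closing_radius: int = 2,
                          min_area: int = 100) -> np.ndarray:
    """Close edge contours, fill holes and drop sub-threshold components."""
    binary = np.asarray(binary, dtype=bool)
    if closing_radius > 0:
        binary = morphology.closing(binary, morphology.disk(closing_radius))
    binary = ndi.binary_fill_holes(binary)
    return morphology.remove_small_objects(binary, max_size=min_area - 1,
                                           connectivity=2)


# ---------------------------------------------------------------------------
# boundary tracing and object extraction
# ---------------------------------------------------------------------------

# Moore neighborhood in clockwise order starting west
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbor boundary trace, clockwise from the topmost-leftmost
    boundary pixel. Returns (k, 2) integer (row, col) coordinates; the polygon
    is closed implicitly (last vertex connects back to the first)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (rows[0], cols[np.argmin(cols[rows == rows[0]])])
    if mask.sum() == 1:
        return np.array([[start[0] - 1, start[1] - 1]])

    boundary = [start]
    # backtrack starts west of the start pixel (guaranteed background)
    backtrack_dir = 0  # index into _MOORE pointing at the backtrack cell
    current = start
    limit = 4 * (padded.shape[0] * padded.shape[1])
    for _ in range(limit):
        found = False
        for step in range(8):
            k = (backtrack_dir + step) % 8
            nb = (current[0] + _MOORE[k][0], current[1] + _MOORE[k][1])
            if padded[nb]:
                # next backtrack: the cell examined just before this neighbor
                prev = (backtrack_dir + step - 1) % 8
                prev_cell = (current[0] + _MOORE[prev][0],
                             current[1] + _MOORE[prev][1])
                # direction index from nb towards prev_cell
                d = (prev_cell[0] - nb[0], prev_cell[1] - nb[1])
                backtrack_dir = _MOORE.index(d)
                current = nb
                found = True
                break
        if not found:  # isolated pixel reached via pathological input
            break
        if current == start and boundary[0] == start and len(boundary) > 1:
            break
        boundary.append(current)
    return np.asarray(boundary) - 1  # undo padding offset


def upsample_mask(mask: np.ndarray, full_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor 2x upsampling of a half-resolution mask/label image."""
    up = np.repeat(np.repeat(mask, 2, axis=0), 2, axis=1)
    return up[: full_shape[0], : full_shape[1]]


def extract_objects(mask: np.ndarray, slide, min_area: int = 0,
                    gray: np.ndarray | None = None) -> list[ObjectRecord]:
    """One :class:`ObjectRecord` per 8-connected component of ``mask``.

    Records are ordered deterministically by the top-left corner of their
    bounding box. ``slide`` supplies the RGB crops (``SlideMap`` or array or
    None); ``gray`` optionally supplies precomputed gray values.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    pixels = None if slide is None else sm._pixels(slide)
    if gray is None and pixels is not None and pixels.ndim == 3:
        gray = sm.to_grayscale(pixels)
    labels = measure.label(mask, connectivity=2)
    regions = sorted(measure.regionprops(labels),
                     key=lambda r: (r.bbox[0], r.bbox[1]))
    records = []
    oid = 0
    for region in regions:
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        local = labels[r0:r1, c0:c1] == region.label
        boundary = trace_boundary(local) + np.array([r0, c0])
        rec = ObjectRecord(
            object_id=oid,
            mask=local,
            bbox=(r0, c0, r1, c1),
            boundary=boundary,
            crop=None if pixels is None else pixels[r0:r1, c0:c1].copy(),
            gray_crop=None if gray is None else gray[r0:r1, c0:c1].copy(),
        )
        records.append(rec)
        oid += 1
    return records


def records_to_objects(records, slide) -> list[ObjectRecord]:
    """Rebuild :class:`ObjectRecord` crops/masks from boundary polygons."""
    from skimage.draw import polygon

    pixels = sm._pixels(slide)
    gray = sm.to_grayscale(pixels) if pixels.ndim == 3 else pixels
    out = []
    for rec in records:
        b = np.asarray(rec.boundary)
        rr, cc = polygon(b[:, 0], b[:, 1], shape=pixels.shape[:2])
        full = np.zeros(pixels.shape[:2], dtype=bool)
        full[rr, cc] = True
        full[b[:, 0].astype(int), b[:, 1].astype(int)] = True
        r0, r1 = int(b[:, 0].min()), int(b[:, 0].max()) + 1
        c0, c1 = int(b[:, 1].min()), int(b[:, 1].max()) + 1
        out.append(ObjectRecord(
            object_id=rec.object_id,
            mask=full[r0:r1, c0:c1],
            bbox=(r0, c0, r1, c1),
            boundary=b.astype(int),
            crop=pixels[r0:r1, c0:c1].copy() if pixels.ndim == 3 else None,
            gray_crop=gray[r0:r1, c0:c1].copy(),
            label=getattr(rec, "label", None),
        ))
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def segment_slidemap(slide, background=None,
                     config: SegmentationConfig = SegmentationConfig()
                     ) -> list[ObjectRecord]:
    """Run the full detection cascade on a slide-map.

    Stages, in order: illumination correction (if a background is given),
    grayscale conversion, bicubic half-resolution downsampling, H-minima /
    H-maxima contrast flattening, Sobel+LoG edge detection, morphological
    cleanup, and full-resolution object extraction.
    """
    corrected = slide if background is None else sm.correct_illumination(
        slide, background, target_level=config.target_level)
    pixels = sm._pixels(corrected)
    gray_full = sm.to_grayscale(pixels) if pixels.ndim == 3 else np.asarray(
        pixels, dtype=np.float64)
    gray_half = downsample_half(gray_full)
    flat = flatten_contrast(gray_half, config.h_minima_depth,
                            config.h_maxima_depth)
    edges = edge_image(flat, log_sigma=config.log_sigma,
                       combine=config.edge_combine)
    factor2 = config.downsample_factor ** 2
    clean = morphological_cleanup(edges, closing_radius=config.closing_radius,
                                  min_area=max(config.min_object_area // factor2, 1))
    if config.border_policy == "drop":
        clean = _drop_border_components(clean)
    full_mask = upsample_mask(clean, gray_full.shape)
    return extract_objects(full_mask, corrected,
                           min_area=config.min_object_area, gray=gray_full)


def _drop_border_components(binary: np.ndarray) -> np.ndarray:
    labels = measure.label(binary, connectivity=2)
    border_labels = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
    border_labels = border_labels[border_labels != 0]
    if border_labels.size:
        binary = binary & ~np.isin(labels, border_labels)
    return binary


def match_to_ground_truth(records, truth, iou_threshold: float = 0.7):
    """Greedy IoU matching of segmented objects against planted truth.

    Returns ``(matches, recall)`` where matches is a list of
    ``(record_index, truth_index, iou)`` and recall the fraction of truth
    objects matched at or above the threshold.
    """
    matches = []
    used = set()
    for ti, tobj in enumerate(truth.objects):
        best = (None, 0.0)
        tr0, tc0, tr1, tc1 = tobj.bbox
        for ri, rec in enumerate(records):
            if ri in used:
                continue
            r0, c0, r1, c1 = rec.bbox
            if r1 <= tr0 or tr1 <= r0 or c1 <= tc0 or tc1 <= c0:
                continue
            # intersect over the union of the two bboxes only
            ur0, uc0 = min(r0, tr0), min(c0, tc0)
            ur1, uc1 = max(r1, tr1), max(c1, tc1)
            a = np.zeros((ur1 - ur0, uc1 - uc0), dtype=bool)
            b = np.zeros_like(a)
            a[r0 - ur0:r1 - ur0, c0 - uc0:c1 - uc0] = rec.mask
            b[tr0 - ur0:tr1 - ur0, tc0 - uc0:tc1 - uc0] = tobj.mask
            inter = np.logical_and(a, b).sum()
            if inter == 0:
                continue
            iou = inter / np.logical_or(a, b).sum()
            if iou > best[1]:
                best = (ri, iou)
        if best[0] is not None and best[1] >= iou_threshold:
            matches.append((best[0], ti, best[1]))
            used.add(best[0])
    recall = len(matches) / max(len(truth.objects), 1)
    return matches, recall
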