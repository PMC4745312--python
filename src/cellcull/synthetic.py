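"""Seeded generators of synthetic smear scenes and planted-signal feature tables.

The generator emulates the imaging situation the rest of the package is built
for: Papanicolaou-stained buccal cells photographed in transmission at low
magnification, so cells absorb light and appear darker than a bright, smoothly
shaded background.  Four object phenotypes are rendered:

* ``suitable``   -- an isolated, near-elliptical, convex cell with a smooth
  interior (gentle nuclear shading plus low-amplitude noise);
* ``folded``     -- an elongated cell carrying a darker ridge band across its
  body and a notched, less convex outline;
* ``debris``     -- a cell covered with high-contrast dark speckle;
* ``overlapping``-- two intersecting ellipses forming one connected object,
  darker where they overlap.

Every randomised quantity is drawn from :class:`numpy.random.Generator`
streams spawned deterministically from a single scene seed, so equal seeds
produce byte-identical images and tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

PHENOTYPES = ("suitable", "debris", "folded", "overlapping")
UNSUITABLE_PHENOTYPES = ("debris", "folded", "overlapping")

#: default 8-bit background gray level of the blank slide
DEFAULT_BACKGROUND_LEVEL = 230.0
#: default stain color (transmission RGB of fully stained material);
#: a hematoxylin-like blue-purple
DEFAULT_STAIN_COLOR = (110, 70, 150)

_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic slide scene.

    Defaults follow the imaging scale of the target instrument: tiles of
    1024 x 1280 pixels, assembled into a 2 x 2 slide-map holding 10 suitable
    and 10 unsuitable objects.
    """

    image_height: int = 2048
    image_width: int = 2560
    tile_rows: int = 2
    tile_cols: int = 2
    n_suitable: int = 10
    n_unsuitable: int = 10
    unsuitable_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    cell_radius_range: tuple[float, float] = (18.0, 36.0)
    illumination_gradient_amplitude: float = 0.2
    texture_noise_sd_suitable: float = 2.0
    texture_noise_sd_unsuitable: float = 8.0
    sensor_noise_sd: float = 1.0
    background_level: float = DEFAULT_BACKGROUND_LEVEL
    stain_color: tuple[int, int, int] = DEFAULT_STAIN_COLOR
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.unsuitable_mix) - 1.0) > 1e-9:
            raise ValueError("unsuitable_mix proportions must sum to 1")
        if self.n_suitable < 0 or self.n_unsuitable < 0:
            raise ValueError("object counts must be non-negative")
        lo, hi = self.cell_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("cell_radius_range must be positive and ordered")
        if self.image_height % self.tile_rows or self.image_width % self.tile_cols:
            raise ValueError("image dimensions must be divisible by the tile grid")

    @property
    def tile_shape(self) -> tuple[int, int]:
        return (self.image_height // self.tile_rows,
                self.image_width // self.tile_cols)


@dataclass
class TruthObject:
    """One planted object: phenotype, suitability label and its mask."""

    object_id: int
    phenotype: str
    label: str  # "suitable" | "unsuitable"
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), exclusive
    mask: np.ndarray  # boolean, local (bbox) frame

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass
class GroundTruth:
    image_shape: tuple[int, int]
    objects: list[TruthObject] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.objects)

    @property
    def labels(self) -> list[str]:
        return [o.label for o in self.objects]


# ---------------------------------------------------------------------------
# single-cell rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, center, a, b, phi):
    """Boolean mask of a rotated ellipse with semi-axes a >= b."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    # rotate into the ellipse frame; phi measured from the column axis
    x = dx * np.cos(phi) + dy * np.sin(phi)
    y = -dx * np.sin(phi) + dy * np.cos(phi)
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def _render_absorbance(phenotype: str, radius: float, texture_sd: float,
                       rng: np.random.Generator):
    """Render one object as (absorbance field, mask) in a padded local frame.

    Absorbance is in [0, 1]: 0 = clear glass, 1 = opaque stain.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if radius < 5:
        raise ValueError("radius must be >= 5 px to render texture")

    pad = 14
    size = int(np.ceil(2 * radius * 2.6)) + 2 * pad
    shape = (size, size)
    center = (size / 2.0, size / 2.0)
    phi = rng.uniform(0, np.pi)
    A = np.zeros(shape, dtype=np.float64)

    if phenotype == "suitable":
        ratio = rng.uniform(1.0, 1.25)
        a, b = radius * ratio, radius
        mask = _ellipse_mask(shape, center, a, b, phi)
        A[mask] = 0.38
        # smooth nuclear shading: darker gaussian blob near the center
        rr, cc = np.mgrid[:size, :size]
        nuc = 0.18 * np.exp(-(((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                              / (2 * (0.45 * radius) ** 2)))
        A += nuc * mask

    elif phenotype == "folded":
        ratio = rng.uniform(1.7, 2.3)
        a, b = radius * ratio, radius * 0.85
        mask = _ellipse_mask(shape, center, a, b, phi)
        # ridge band across the cell (the fold), in the ellipse frame
        rr, cc = np.mgrid[:size, :size]
        x = (cc - center[1]) * np.cos(phi) + (rr - center[0]) * np.sin(phi)
        ridge = np.abs(x - rng.uniform(-0.3, 0.3) * a) < 0.18 * a
        A[mask] = 0.38
        A[mask & ridge] += 0.30
        # notch: bite a disk out of the outline (concavity)
        ny = center[0] - b * np.cos(phi)
        nx = center[1] + b * np.sin(phi)
        bite = _ellipse_mask(shape, (ny, nx), 0.45 * b, 0.45 * b, 0.0)
        mask = mask & ~bite
        A[~mask] = 0.0

    elif phenotype == "debris":
        ratio = rng.uniform(1.0, 1.4)
        a, b = radius * ratio, radius
        mask = _ellipse_mask(shape, center, a, b, phi)
        A[mask] = 0.38
        n_speck = max(6, int(mask.sum() / 120))
        rows, cols = np.nonzero(mask)
        idx = rng.integers(0, rows.size, size=n_speck)
        for r0, c0 in zip(rows[idx], cols[idx]):
            sr = rng.uniform(1.0, 3.0)
            speck = _ellipse_mask(shape, (r0, c0), sr, sr, 0.0)
            A[speck & mask] += 0.42
    else:  # overlapping
        ratio = rng.uniform(1.0, 1.3)
        a1, b1 = radius * ratio, radius
        m1 = _ellipse_mask(shape, center, a1, b1, phi)
        theta = rng.uniform(0, 2 * np.pi)
        dist = radius * rng.uniform(1.1, 1.4)
        c2 = (center[0] + dist * np.sin(theta), center[1] + dist * np.cos(theta))
        r2 = radius * rng.uniform(0.8, 1.1)
        m2 = _ellipse_mask(shape, c2, r2 * rng.uniform(1.0, 1.3), r2,
                           rng.uniform(0, np.pi))
        mask = m1 | m2
        A[m1] += 0.38
        A[m2] += 0.38

    # soften hard edges, then add interior texture noise
    A = ndi.gaussian_filter(A, sigma=1.0)
    noise = rng.normal(0.0, texture_sd / 255.0, size=shape)
    A += noise * mask
    np.clip(A, 0.0, 1.0, out=A)

    # crop to the mask bounding box plus padding
    rows, cols = np.nonzero(mask)
    r0 = max(rows.min() - pad, 0)
    r1 = min(rows.max() + 1 + pad, size)
    c0 = max(cols.min() - pad, 0)
    c1 = min(cols.max() + 1 + pad, size)
    return A[r0:r1, c0:c1], mask[r0:r1, c0:c1]


def colorize(absorbance: np.ndarray,
             stain_color=DEFAULT_STAIN_COLOR,
             background_level: float = DEFAULT_BACKGROUND_LEVEL) -> np.ndarray:
    """Turn an absorbance field into an 8-bit RGB transmission image."""
    s = np.asarray(stain_color, dtype=np.float64) / 255.0
    trans = 1.0 - absorbance[..., None] * (1.0 - s[None, None, :])
    img = background_level * trans
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_cell(phenotype: str, radius: float, texture_sd: float,
                rng: np.random.Generator,
                stain_color=DEFAULT_STAIN_COLOR,
                background_level: float = DEFAULT_BACKGROUND_LEVEL):
    """Render one object; returns ``(crop, mask)``.

    ``crop`` is an 8-bit RGB image of the object on a clean background patch,
    ``mask`` the boolean object mask in the same frame.
    """
    A, mask = _render_absorbance(phenotype, radius, texture_sd, rng)
    return colorize(A, stain_color, background_level), mask


# ---------------------------------------------------------------------------
# whole-scene generation
# ---------------------------------------------------------------------------

def illumination_field(shape: tuple[int, int], amplitude: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative shading field in [1 - amplitude, 1].

    A low-order 2-D polynomial in normalized coordinates with seeded
    coefficients, rescaled so its range spans exactly ``amplitude`` of the
    dynamic range (constant field when amplitude == 0).
    """
    h, w = shape
    v, u = np.mgrid[0:h, 0:w]
    u = u / max(w - 1, 1)
    v = v / max(h - 1, 1)
    c = rng.uniform(-1.0, 1.0, size=5)
    g = c[0] * u + c[1] * v + c[2] * u * v + c[3] * u ** 2 + c[4] * v ** 2
    if amplitude == 0:
        return np.ones(shape)
    lo, hi = g.min(), g.max()
    if hi - lo < 1e-12:
        return np.ones(shape)
    g = (g - lo) / (hi - lo)
    return 1.0 - amplitude * g


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all objects."""


def _phenotype_sequence(spec: SceneSpec, rng: np.random.Generator) -> list[str]:
    phenos = ["suitable"] * spec.n_suitable
    if spec.n_unsuitable:
        phenos += [str(p) for p in rng.choice(
            UNSUITABLE_PHENOTYPES, size=spec.n_unsuitable,
            p=np.asarray(spec.unsuitable_mix))]
    return phenos


def compose_scene(spec: SceneSpec):
    """Render the full scene raster.

    Returns ``(scene_rgb, background_rgb, truth)`` where the background image
    carries only the illumination gradient (no objects, no noise).
    """
    shape = (spec.image_height, spec.image_width)
    ss = np.random.SeedSequence(spec.seed)
    place_ss, illum_ss, noise_ss, pheno_ss, obj_root = ss.spawn(5)
    place_rng = np.random.default_rng(place_ss)
    pheno_rng = np.random.default_rng(pheno_ss)

    field = illumination_field(shape, spec.illumination_gradient_amplitude,
                               np.random.default_rng(illum_ss))
    background = np.clip(
        np.round(spec.background_level * field), 0, 255
    ).astype(np.uint8)
    background = np.repeat(background[:, :, None], 3, axis=2)

    phenos = _phenotype_sequence(spec, pheno_rng)
    obj_streams = obj_root.spawn(len(phenos))

    A_total = np.zeros(shape, dtype=np.float64)
    occupied = np.zeros(shape, dtype=bool)
    truth = GroundTruth(image_shape=shape)
    margin = 12  # pixels kept clear between objects and around borders

    for oid, (pheno, oss) in enumerate(zip(phenos, obj_streams)):
        orng = np.random.default_rng(oss)
        sd = (spec.texture_noise_sd_suitable if pheno == "suitable"
              else spec.texture_noise_sd_unsuitable)
        radius = orng.uniform(*spec.cell_radius_range)
        A, mask = _render_absorbance(pheno, radius, sd, orng)
        mh, mw = mask.shape
        placed = False
        for _ in range(_PLACEMENT_ATTEMPTS):
            r0 = int(place_rng.integers(margin, shape[0] - mh - margin))
            c0 = int(place_rng.integers(margin, shape[1] - mw - margin))
            grown = ndi.binary_dilation(mask, iterations=margin // 2)
            if not (occupied[r0:r0 + mh, c0:c0 + mw] & grown).any():
                occupied[r0:r0 + mh, c0:c0 + mw] |= grown
                A_total[r0:r0 + mh, c0:c0 + mw] += A
                rows, cols = np.nonzero(mask)
                rb0, rb1 = rows.min(), rows.max() + 1
                cb0, cb1 = cols.min(), cols.max() + 1
                truth.objects.append(TruthObject(
                    object_id=oid,
                    phenotype=pheno,
                    label="suitable" if pheno == "suitable" else "unsuitable",
                    bbox=(r0 + rb0, c0 + cb0, r0 + rb1, c0 + cb1),
                    mask=mask[rb0:rb1, cb0:cb1].copy(),
                ))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place object {oid} ({pheno}) after "
                f"{_PLACEMENT_ATTEMPTS} attempts; scene density too high for "
                f"{len(phenos)} objects of radius up to {spec.cell_radius_range[1]}"
            )

    np.clip(A_total, 0.0, 1.0, out=A_total)
    s = np.asarray(spec.stain_color, dtype=np.float64) / 255.0
    trans = 1.0 - A_total[..., None] * (1.0 - s[None, None, :])
    scene = spec.background_level * field[..., None] * trans
    if spec.sensor_noise_sd > 0:
        noise_rng = np.random.default_rng(noise_ss)
        scene = scene + noise_rng.normal(0.0, spec.sensor_noise_sd,
                                         size=scene.shape)
    scene = np.clip(np.round(scene), 0, 255).astype(np.uint8)
    return scene, background, truth


def generate_slide_scene(spec: SceneSpec):
    """Generate ``(tiles, background, truth)`` for a synthetic slide.

    Tiles partition the scene in row-major order without gaps or overlaps;
    the background image carries only the illumination gradient.
    """
    scene, background, truth = compose_scene(spec)
    th, tw = spec.tile_shape
    tiles = [
        scene[i * th:(i + 1) * th, j * tw:(j + 1) * tw].copy()
        for i in range(spec.tile_rows)
        for j in range(spec.tile_cols)
    ]
    return tiles, background, truth


# ---------------------------------------------------------------------------
# planted-signal feature tables
# ---------------------------------------------------------------------------

def generate_feature_dataset(n_per_class: int, n_informative: int,
                             n_noise: int, separation: float,
                             seed: int = 0):
    """Two-class Gaussian feature table with planted informative columns.

    Informative columns differ between classes by ``separation`` standard
    deviations; noise columns are identically distributed in both classes.
    Column names flag the planted features (``informative_*`` / ``noise_*``).
    Returns a :class:`pandas.DataFrame` with a trailing ``label`` column.
    """
    import pandas as pd

    if n_per_class <= 0 or n_informative < 0 or n_noise < 0:
        raise ValueError("counts must be positive")
    if n_informative + n_noise == 0:
        raise ValueError("at least one feature required")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    d = n_informative + n_noise
    X = rng.normal(size=(2 * n_per_class, d))
    X[n_per_class:, :n_informative] += separation
    names = [f"informative_{i:02d}" for i in range(n_informative)]
    names += [f"noise_{i:02d}" for i in range(n_noise)]
    df = pd.DataFrame(X, columns=names)
    df["label"] = ["unsuitable"] * n_per_class + ["suitable"] * n_per_class
    return df


# ---------------------------------------------------------------------------
# ground-truth serialization
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write ground truth as JSON (id, phenotype, label, bbox, boundary)."""
    from .segmentation import trace_boundary

    objs = []
    for o in truth.objects:
        boundary = trace_boundary(o.mask) + np.array([o.bbox[0], o.bbox[1]])
        objs.append({
            "object_id": int(o.object_id),
            "phenotype": o.phenotype,
            "label": o.label,
            "bbox": [int(v) for v in o.bbox],
            "boundary": np.asarray(boundary, dtype=int).tolist(),
        })
    payload = {"image_shape": list(truth.image_shape), "objects": objs}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def scene_spec_from_dict(cfg: dict) -> SceneSpec:
    """Build a :class:`SceneSpec` from a plain dict (e.g. parsed YAML)."""
    fields = {f.name for f in dataclasses.fields(SceneSpec)}
    unknown = set(cfg) - fields
    if unknown:
        raise ValueError(f"unknown SceneSpec fields: {sorted(unknown)}")
    cfg = dict(cfg)
    for key in ("unsuitable_mix", "cell_radius_range", "stain_color"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return SceneSpec(**cfg)
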