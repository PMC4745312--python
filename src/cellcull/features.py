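"""Morphology and texture features of segmented objects.

The seven core features driving suitability classification are:

========================  =====================================================
eccentricity              sqrt(1 - b^2/a^2) of the moment-equivalent ellipse
solidity                  area / convex-hull area
normalized_variance       sigma^2 / mu^2 of masked gray values
normalized_kurtosis       E[(x - mu)^4] / sigma^4 (non-excess; Gaussian -> 3)
entropy                   -sum p log2 p over the 256-bin masked histogram
glcm_energy               sum M_ij^2 of the summed co-occurrence matrix at
                          offset 5 in the eight compass directions, restricted
                          to pixel pairs inside the mask
gabor_variance            variance of the masked Gabor response, averaged over
                          orientations 0/45/90/135 degrees
========================  =====================================================

A wider registry of standard features fills out the usual categories (size
and shape, histogram, color, co-occurrence and Fourier/Gabor texture,
topology). All intensity features are computed over masked pixels only, so
pixels outside the object never influence a value.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage import measure, morphology

#: names of the seven core features
CORE_FEATURES = (
    "eccentricity", "solidity", "normalized_variance", "normalized_kurtosis",
    "entropy", "glcm_energy", "gabor_variance",
)

GLCM_LEVELS = 64
GLCM_OFFSET = 5
GABOR_SIGMA = 4.0
GABOR_FREQUENCY = 0.1


def _masked(gray, mask):
    gray = np.asarray(gray, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    return gray[mask]


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def eccentricity(mask) -> float:
    """Eccentricity of the ellipse with the same second central moments."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 5:
        raise ValueError("mask too small for moment estimation")
    region = measure.regionprops(mask.astype(np.uint8))[0]
    if region.axis_minor_length < 1e-12:
        warnings.warn("degenerate (collinear) mask", stacklevel=2)
        return 1.0 - 1e-9
    return float(region.eccentricity)


def solidity(mask) -> float:
    """Area over convex-hull area, in (0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("mask too small for a convex hull")
    region = measure.regionprops(mask.astype(np.uint8))[0]
    return float(region.solidity)


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def normalized_variance(gray_crop, mask) -> float:
    """sigma^2 / mu^2 over masked pixels (population moments)."""
    x = _masked(gray_crop, mask)
    if x.size < 2:
        raise ValueError("need at least 2 masked pixels")
    mu = x.mean()
    if abs(mu) < 1e-12:
        raise ValueError("normalized variance undefined for zero mean")
    return float(x.var() / mu ** 2)


def normalized_kurtosis(gray_crop, mask) -> float:
    """E[(x - mu)^4] / sigma^4 over masked pixels; Gaussian gives 3."""
    x = _masked(gray_crop, mask)
    if x.size < 2:
        raise ValueError("need at least 2 masked pixels")
    mu = x.mean()
    var = x.var()
    if var < 1e-24:
        raise ValueError("kurtosis undefined for zero variance")
    return float(np.mean((x - mu) ** 4) / var ** 2)


def entropy(gray_crop, mask) -> float:
    """Shannon entropy (bits) of the 256-bin masked intensity histogram."""
    x = _masked(gray_crop, mask)
    if x.size < 1:
        raise ValueError("need at least 1 masked pixel")
    counts, _ = np.histogram(np.clip(x, 0, 255), bins=256, range=(0, 256))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# co-occurrence texture
# ---------------------------------------------------------------------------

def masked_glcm(gray_crop, mask, levels: int = GLCM_LEVELS,
                offset: int = GLCM_OFFSET) -> np.ndarray:
    """Summed, normalized co-occurrence matrix at the given offset in the
    eight compass directions, using only pixel pairs both inside the mask."""
    gray = np.clip(np.asarray(gray_crop, dtype=np.float64), 0, 255)
    mask = np.asarray(mask, dtype=bool)
    q = np.minimum((gray / 256.0 * levels).astype(np.intp), levels - 1)
    M = np.zeros((levels, levels), dtype=np.float64)
    h, w = q.shape
    total = 0
    directions = [(0, 1), (1, 1), (1, 0), (1, -1),
                  (0, -1), (-1, -1), (-1, 0), (-1, 1)]
    for dr, dc in [(u * offset, v * offset) for u, v in directions]:
        r0s, r0e = max(0, -dr), min(h, h - dr)
        c0s, c0e = max(0, -dc), min(w, w - dc)
        if r0s >= r0e or c0s >= c0e:
            continue
        src = np.s_[r0s:r0e, c0s:c0e]
        dst = np.s_[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        valid = mask[src] & mask[dst]
        a = q[src][valid]
        b = q[dst][valid]
        np.add.at(M, (a, b), 1.0)
        total += a.size
    if total == 0:
        raise ValueError("no valid in-mask pixel pairs at the GLCM offset")
    return M / total


def glcm_energy(gray_crop, mask) -> float:
    """Angular second moment of the masked co-occurrence matrix, in (0, 1]."""
    M = masked_glcm(gray_crop, mask)
    return float((M ** 2).sum())


def _glcm_stats(gray_crop, mask):
    M = masked_glcm(gray_crop, mask)
    i = np.arange(M.shape[0])
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(((ii - jj) ** 2 * M).sum())
    homogeneity = float((M / (1.0 + np.abs(ii - jj))).sum())
    pi = M.sum(axis=1)
    pj = M.sum(axis=0)
    mu_i = (i * pi).sum()
    mu_j = (i * pj).sum()
    sd_i = math.sqrt(max(((i - mu_i) ** 2 * pi).sum(), 0.0))
    sd_j = math.sqrt(max(((i - mu_j) ** 2 * pj).sum(), 0.0))
    if sd_i * sd_j < 1e-12:
        correlation = 0.0
    else:
        correlation = float(((ii - mu_i) * (jj - mu_j) * M).sum() / (sd_i * sd_j))
    nz = M[M > 0]
    glcm_ent = float(-(nz * np.log2(nz)).sum())
    return contrast, correlation, homogeneity, glcm_ent


# ---------------------------------------------------------------------------
# Gabor texture
# ---------------------------------------------------------------------------

def gabor_kernel(theta: float, sigma_x: float = GABOR_SIGMA,
                 sigma_y: float = GABOR_SIGMA,
                 frequency: float = GABOR_FREQUENCY) -> np.ndarray:
    """Even (cosine) Gabor kernel
    exp(-(x^2/sx^2 + y^2/sy^2)/2) * cos(2 pi u (x cos t + y sin t))."""
    r = int(np.ceil(3.0 * max(sigma_x, sigma_y)))
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(np.float64)
    envelope = np.exp(-0.5 * (x ** 2 / sigma_x ** 2 + y ** 2 / sigma_y ** 2))
    carrier = np.cos(2 * np.pi * frequency * (x * np.cos(theta)
                                              + y * np.sin(theta)))
    return envelope * carrier


def gabor_variance(gray_crop, mask, frequency: float = GABOR_FREQUENCY,
                   sigma: float = GABOR_SIGMA) -> float:
    """Variance of the masked Gabor response, averaged over orientations
    0, 45, 90 and 135 degrees."""
    gray = np.asarray(gray_crop, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    r = int(np.ceil(3.0 * sigma))
    padded = np.pad(gray, r, mode="reflect")
    variances = []
    for theta in (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4):
        k = gabor_kernel(theta, sigma, sigma, frequency)
        resp = fftconvolve(padded, k, mode="same")[r:-r, r:-r]
        variances.append(resp[mask].var())
    return float(np.mean(variances))


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _region(obj):
    return measure.regionprops(np.asarray(obj.mask, dtype=np.uint8))[0]


def _boundary_irregularity(obj):
    """Perimeter^2 / (4 pi area): 1 for a disk, larger for rough outlines."""
    region = _region(obj)
    p = region.perimeter
    return float(p ** 2 / (4 * np.pi * region.area))


def _channel(obj, idx):
    if obj.crop is None:
        raise ValueError("object has no RGB crop")
    return np.asarray(obj.crop, dtype=np.float64)[..., idx][np.asarray(obj.mask, bool)]


def _fft_band_power(obj, band):
    """Fraction of non-DC spectral power in a radial frequency band."""
    gray = np.asarray(obj.gray_crop, dtype=np.float64) * np.asarray(obj.mask, bool)
    F = np.abs(np.fft.fftshift(np.fft.fft2(gray - gray.mean()))) ** 2
    h, w = F.shape
    yy, xx = np.mgrid[:h, :w]
    r = np.hypot(yy - h / 2, xx - w / 2) / (max(h, w) / 2)
    total = F.sum()
    if total < 1e-24:
        return 0.0
    lo, hi = band
    return float(F[(r >= lo) & (r < hi)].sum() / total)


def _extrema_density(obj, mode):
    """Regional extrema per masked pixel of the lightly smoothed crop."""
    gray = ndi.gaussian_filter(np.asarray(obj.gray_crop, dtype=np.float64), 1.0)
    mask = ndi.binary_erosion(np.asarray(obj.mask, bool), iterations=2)
    if not mask.any():
        return 0.0
    fn = morphology.local_maxima if mode == "max" else morphology.local_minima
    ext = fn(gray, connectivity=2) & mask
    n_comp = measure.label(ext, connectivity=2).max()
    return float(n_comp / mask.sum())


def _safe_skew(x):
    sd = x.std()
    if sd < 1e-12:
        return 0.0
    return float(np.mean(((x - x.mean()) / sd) ** 3))


def _build_registry():
    g = lambda obj: (obj.gray_crop, obj.mask)  # noqa: E731
    reg = {
        # --- size and shape ---
        "area": lambda o: float(_region(o).area),
        "perimeter": lambda o: float(_region(o).perimeter),
        "circularity": lambda o: float(4 * np.pi * _region(o).area
                                       / max(_region(o).perimeter ** 2, 1e-12)),
        "boundary_irregularity": _boundary_irregularity,
        "major_axis_length": lambda o: float(_region(o).axis_major_length),
        "minor_axis_length": lambda o: float(_region(o).axis_minor_length),
        "extent": lambda o: float(_region(o).extent),
        "eccentricity": lambda o: eccentricity(o.mask),
        "solidity": lambda o: solidity(o.mask),
        # --- histogram ---
        "gray_mean": lambda o: float(_masked(*g(o)).mean()),
        "gray_sd": lambda o: float(_masked(*g(o)).std()),
        "gray_skewness": lambda o: _safe_skew(_masked(*g(o))),
        "normalized_variance": lambda o: normalized_variance(*g(o)),
        "normalized_kurtosis": lambda o: normalized_kurtosis(*g(o)),
        "entropy": lambda o: entropy(*g(o)),
        "gray_p10": lambda o: float(np.percentile(_masked(*g(o)), 10)),
        "gray_p25": lambda o: float(np.percentile(_masked(*g(o)), 25)),
        "gray_median": lambda o: float(np.percentile(_masked(*g(o)), 50)),
        "gray_p75": lambda o: float(np.percentile(_masked(*g(o)), 75)),
        "gray_p90": lambda o: float(np.percentile(_masked(*g(o)), 90)),
        # --- color ---
        "mean_red": lambda o: float(_channel(o, 0).mean()),
        "mean_green": lambda o: float(_channel(o, 1).mean()),
        "mean_blue": lambda o: float(_channel(o, 2).mean()),
        "sd_red": lambda o: float(_channel(o, 0).std()),
        "sd_green": lambda o: float(_channel(o, 1).std()),
        "sd_blue": lambda o: float(_channel(o, 2).std()),
        "ratio_red_green": lambda o: float(_channel(o, 0).mean()
                                           / max(_channel(o, 1).mean(), 1e-12)),
        "ratio_green_blue": lambda o: float(_channel(o, 1).mean()
                                            / max(_channel(o, 2).mean(), 1e-12)),
        "ratio_red_blue": lambda o: float(_channel(o, 0).mean()
                                          / max(_channel(o, 2).mean(), 1e-12)),
        # --- co-occurrence texture ---
        "glcm_energy": lambda o: glcm_energy(*g(o)),
        "glcm_contrast": lambda o: _glcm_stats(*g(o))[0],
        "glcm_correlation": lambda o: _glcm_stats(*g(o))[1],
        "glcm_homogeneity": lambda o: _glcm_stats(*g(o))[2],
        "glcm_entropy": lambda o: _glcm_stats(*g(o))[3],
        "gradient_mean": lambda o: float(np.hypot(
            *np.gradient(np.asarray(o.gray_crop, float)))[np.asarray(o.mask, bool)].mean()),
        "gradient_sd": lambda o: float(np.hypot(
            *np.gradient(np.asarray(o.gray_crop, float)))[np.asarray(o.mask, bool)].std()),
        # --- Fourier / Gabor texture ---
        "gabor_variance": lambda o: gabor_variance(*g(o)),
        "gabor_variance_lowfreq": lambda o: gabor_variance(*g(o), frequency=0.05),
        "gabor_variance_highfreq": lambda o: gabor_variance(*g(o), frequency=0.2),
        "fft_power_low": lambda o: _fft_band_power(o, (0.0, 0.15)),
        "fft_power_mid": lambda o: _fft_band_power(o, (0.15, 0.4)),
        "fft_power_high": lambda o: _fft_band_power(o, (0.4, 1.01)),
        # --- topology (surface-morphology proxies, non-canonical) ---
        "euler_number": lambda o: float(_region(o).euler_number),
        "local_maxima_density": lambda o: _extrema_density(o, "max"),
        "local_minima_density": lambda o: _extrema_density(o, "min"),
    }
    return reg


_REGISTRY = _build_registry()

#: registry name lists
FULL_REGISTRY = tuple(_REGISTRY)
CORE_REGISTRY = CORE_FEATURES


def registry_names(registry: str = "full") -> tuple[str, ...]:
    if registry == "full":
        return FULL_REGISTRY
    if registry == "core":
        return CORE_REGISTRY
    raise ValueError("registry must be 'full' or 'core'")


def compute_features(obj, names=CORE_FEATURES) -> dict[str, float]:
    """Compute the named features for one object.

    Per-feature failures are recorded as NaN unless the failing feature is
    one of the seven core features, in which case the error propagates (the
    object cannot be scored without them).
    """
    out = {}
    for name in names:
        try:
            out[name] = _REGISTRY[name](obj)
        except KeyError:
            raise ValueError(f"unknown feature {name!r}") from None
        except Exception:
            if name in CORE_FEATURES:
                raise
            out[name] = float("nan")
    return out


def compute_feature_table(objects, registry="full") -> pd.DataFrame:
    """Feature table: one row per object, one column per registered feature,
    plus a ``label`` column when objects carry labels."""
    names = registry_names(registry) if isinstance(registry, str) else tuple(registry)
    rows, ids, labels = [], [], []
    for obj in objects:
        rows.append(compute_features(obj, names))
        ids.append(obj.object_id)
        labels.append(getattr(obj, "label", None))
    df = pd.DataFrame(rows, index=pd.Index(ids, name="object_id"))
    df = df.fillna(df.median(numeric_only=True))
    if any(lab is not None for lab in labels):
        df["label"] = labels
    return df


def feature_matrix(table: pd.DataFrame):
    """Split a feature table into (X, feature_names, labels-or-None)."""
    cols = [c for c in table.columns if c != "label"]
    X = table[cols].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy() if "label" in table.columns else None
    return X, cols, y
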