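"""Independent brute-force oracles used to check the implementation.

Everything here is a literal, loop-based transcription of the defining
formulas, written without reference to the package internals.
"""

from __future__ import annotations

import numpy as np


def eccentricity_from_moments(mask: np.ndarray) -> float:
    """Eccentricity via explicit central moments and eigenvalues."""
    rows, cols = np.nonzero(mask)
    r0, c0 = rows.mean(), cols.mean()
    mu20 = np.mean((cols - c0) ** 2)
    mu02 = np.mean((rows - r0) ** 2)
    mu11 = np.mean((cols - c0) * (rows - r0))
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    l1, l2 = sorted(np.linalg.eigvalsh(cov), reverse=True)
    return float(np.sqrt(1.0 - l2 / l1))


def solidity_from_hull(mask: np.ndarray) -> float:
    """Area over convex-hull area computed on the pixel raster."""
    from skimage.morphology import convex_hull_image

    hull = convex_hull_image(mask)
    return float(mask.sum() / hull.sum())


def entropy_bruteforce(gray: np.ndarray, mask: np.ndarray) -> float:
    x = np.clip(np.asarray(gray, float)[np.asarray(mask, bool)], 0, 255)
    total = 0.0
    n = x.size
    for level in range(256):
        c = np.sum((x >= level) & (x < level + 1))
        if c:
            p = c / n
            total -= p * np.log2(p)
    return float(total)


def glcm_energy_bruteforce(gray: np.ndarray, mask: np.ndarray,
                           levels: int = 64, offset: int = 5) -> float:
    """O(n^2)-style pairwise enumeration of the co-occurrence matrix."""
    gray = np.clip(np.asarray(gray, float), 0, 255)
    mask = np.asarray(mask, bool)
    q = np.minimum((gray / 256.0 * levels).astype(int), levels - 1)
    h, w = q.shape
    M = np.zeros((levels, levels))
    directions = [(0, 1), (1, 1), (1, 0), (1, -1),
                  (0, -1), (-1, -1), (-1, 0), (-1, 1)]
    total = 0
    for dr, dc in [(u * offset, v * offset) for u, v in directions]:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    M[q[r, c], q[r2, c2]] += 1
                    total += 1
    if total == 0:
        raise ValueError("no pairs")
    M /= total
    return float((M ** 2).sum())


def auc_concordance(scores, truth) -> float:
    """AUC as exhaustive pairwise concordance, ties counted 1/2."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def scatter_matrices_literal(X0, X1):
    """Literal loop transcription of the weighted scatter matrices.

    Conventions match the documented ones: a sample is excluded from its own
    within-class weighted mean; coincident points share mass equally; zero
    distance to the weighted mean gives that sample the class's full lambda
    mass (tie-shared).
    """
    classes = [np.atleast_2d(np.asarray(X, float)) for X in (X0, X1)]
    n = [len(c) for c in classes]
    P = [ni / sum(n) for ni in n]
    d = classes[0].shape[1]

    def dist(a, b):
        return float(np.linalg.norm(a - b))

    def wmean(x, Xj, exclude=None):
        ds = [None if l == exclude else dist(x, Xj[l]) for l in range(len(Xj))]
        valid = [l for l, v in enumerate(ds) if v is not None]
        zeros = [l for l in valid if ds[l] == 0]
        w = np.zeros(len(Xj))
        if zeros:
            for l in zeros:
                w[l] = 1.0 / len(zeros)
        else:
            s = sum(1.0 / ds[l] for l in valid)
            for l in valid:
                w[l] = (1.0 / ds[l]) / s
        return w @ Xj

    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    for i in (0, 1):
        Xi = classes[i]
        for j in (0, 1):
            Xj = classes[j]
            M = np.array([wmean(Xi[k], Xj, exclude=(k if i == j else None))
                          for k in range(n[i])])
            dists = np.array([dist(Xi[k], M[k]) for k in range(n[i])])
            if (dists == 0).any():
                lam = (dists == 0).astype(float)
                lam /= lam.sum()
            else:
                lam = 1.0 / dists
                lam /= lam.sum()
            S = sum(lam[k] / n[i] * np.outer(Xi[k] - M[k], Xi[k] - M[k])
                    for k in range(n[i]))
            if i == j:
                Sw += P[i] * S
            else:
                Sb += P[i] * S
    return Sb, Sw


def cleanup_naive(binary: np.ndarray, closing_radius: int,
                  min_area: int) -> np.ndarray:
    """Naive re-implementation of the binary cleanup sequence."""
    from scipy import ndimage as ndi

    binary = np.asarray(binary, bool)
    if closing_radius > 0:
        yy, xx = np.mgrid[-closing_radius:closing_radius + 1,
                          -closing_radius:closing_radius + 1]
        disk = (yy ** 2 + xx ** 2) <= closing_radius ** 2
        # outside-image counts as foreground during the erosion half of the
        # closing, so objects touching the border are not eaten away
        binary = ndi.binary_erosion(ndi.binary_dilation(binary, disk), disk,
                                    border_value=1)
    binary = ndi.binary_fill_holes(binary)
    lab, nlab = ndi.label(binary, structure=np.ones((3, 3)))
    out = np.zeros_like(binary)
    for k in range(1, nlab + 1):
        comp = lab == k
        if comp.sum() >= min_area:
            out |= comp
    return out
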