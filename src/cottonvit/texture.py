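"""Gray-level co-occurrence texture features per seed per band.

The GLCM tallies how often a pixel of gray level i co-occurs with a
pixel of gray level j at a fixed spatial offset, normalized to a joint
probability table p(i, j).  Four scalar features summarize it:

    contrast    = sum (i - j)^2 p(i, j)
    correlation = sum (i - mu_i)(j - mu_j) p(i, j) / (sigma_i sigma_j)
    energy      = sum p(i, j)^2
    entropy     = -sum p(i, j) log2 p(i, j)        (0 log 0 = 0)

Patches are quantized to a fixed number of gray levels with level edges
spanning the (masked) patch range, which makes the features invariant
to constant gray offsets.  Pairs with either pixel outside the seed
mask are dropped, so the background never leaks into the statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCMFeatures:
    contrast: float
    correlation: float
    energy: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.contrast, self.correlation, self.energy, self.entropy])


FEATURE_NAMES = ("contrast", "correlation", "energy", "entropy")


def quantize(patch: np.ndarray, levels: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Quantize a gray patch to ``levels`` bins spanning its (masked) range."""
    patch = np.asarray(patch, dtype=float)
    vals = patch[mask] if mask is not None else patch
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return np.zeros(patch.shape, dtype=np.intp)
    q = np.floor((patch - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm(image_patch: np.ndarray, levels: int = 16, distance: int = 1,
         angle: int = 0, symmetric: bool = True,
         mask: np.ndarray | None = None) -> np.ndarray:
    """Normalized gray-level co-occurrence matrix of one patch.

    ``image_patch`` may be a float image (quantized here) or an integer
    image already holding gray levels in [0, levels).  ``angle`` is one
    of 0, 45, 90, 135 degrees; ``distance`` scales the offset.  With
    ``mask`` given, only pixel pairs fully inside the mask are counted.
    """
    patch = np.asarray(image_patch)
    if patch.ndim != 2:
        raise ValueError("patch must be 2-D")
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")
    if np.issubdtype(patch.dtype, np.integer):
        q = patch.astype(np.intp)
        if q.min() < 0 or q.max() >= levels:
            raise ValueError("integer patch values must lie in [0, levels)")
    else:
        q = quantize(patch, levels, mask)
    valid = np.ones(patch.shape, bool) if mask is None else np.asarray(mask, bool)

    dr, dc = (d * distance for d in _ANGLE_OFFSETS[angle])
    H, W = q.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("patch too small for the requested offset")
    src = q[r0:r1, c0:c1]
    dst = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ok = valid[r0:r1, c0:c1] & valid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    if not ok.any():
        raise ValueError("no valid pixel pairs in patch")
    counts = np.bincount(src[ok] * levels + dst[ok],
                         minlength=levels * levels).reshape(levels, levels).astype(float)
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def texture_features(p: np.ndarray) -> GLCMFeatures:
    """Contrast, correlation, energy and entropy of a normalized GLCM."""
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized")
    L = p.shape[0]
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    contrast = float(np.sum((i - j) ** 2 * p))
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    mu_i, mu_j = pi @ np.arange(L), pj @ np.arange(L)
    var_i = pi @ (np.arange(L) - mu_i) ** 2
    var_j = pj @ (np.arange(L) - mu_j) ** 2
    if var_i == 0 or var_j == 0:
        warnings.warn("degenerate gray-level marginal; correlation set to 0",
                      RuntimeWarning, stacklevel=2)
        correlation = 0.0
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * p)
                            / np.sqrt(var_i * var_j))
    energy = float(np.sum(p * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return GLCMFeatures(contrast=contrast, correlation=correlation,
                        energy=energy, entropy=entropy)


def seed_texture_matrix(cube, mask: np.ndarray, band_indices,
                        levels: int = 16, distance: int = 1, angle: int = 0,
                        symmetric: bool = True) -> np.ndarray:
    """Per-seed texture features over selected bands.

    Returns a (seeds x 4*len(band_indices)) matrix, rows ordered by seed
    label, columns band-major in the order contrast, correlation,
    energy, entropy — 4 features per band, e.g. 2080 columns for a full
    520-band cube.
    """
    band_indices = np.asarray(band_indices, dtype=int)
    if band_indices.size == 0:
        raise ValueError("band_indices is empty")
    if band_indices.min() < 0 or band_indices.max() >= cube.n_bands:
        raise IndexError("band index out of range")
    mask = np.asarray(mask)
    K = int(mask.max())
    slices = ndimage.find_objects(mask.astype(np.intp))
    out = np.empty((K, 4 * band_indices.size))
    for k in range(1, K + 1):
        sl = slices[k - 1]
        if sl is None:
            raise ValueError(f"seed label {k} missing from mask")
        if (sl[0].stop - sl[0].start) < 2 or (sl[1].stop - sl[1].start) < 2:
            raise ValueError(f"seed {k}: bounding box smaller than 2x2")
        seed_mask = mask[sl] == k
        for b, band in enumerate(band_indices):
            patch = cube.S[sl[0], sl[1], band]
            p = glcm(patch, levels=levels, distance=distance, angle=angle,
                     symmetric=symmetric, mask=seed_mask)
            out[k - 1, 4 * b:4 * b + 4] = texture_features(p).as_array()
    return out


def texture_column_names(wavelengths: np.ndarray, band_indices) -> list[str]:
    """CSV column labels, ``<band_nm>_<feature>`` in matrix order."""
    return [f"{wavelengths[b]:.0f}nm_{f}"
            for b in np.asarray(band_indices, int) for f in FEATURE_NAMES]
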