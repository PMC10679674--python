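"""Reflectance calibration and per-seed extraction.

Raw hyperspectral captures come with a white-reference frame (empty
plate, lamps on) and a dark-current frame (shutter closed).  Raw digital
numbers O are converted to reflectance with the standard two-point
correction

    S = (O - Y) / (X - Y)

where X is the white frame and Y the dark frame.  From the calibrated
cube the pipeline takes two views: one mean spectrum per seed region of
interest, and one grayscale image per wavelength band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class RawCapture:
    """Raw digital-number cube plus its white/dark reference frames."""

    O: np.ndarray  # (lines, samples, bands)
    X: np.ndarray  # white reference, same shape
    Y: np.ndarray  # dark current, same shape
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.O.shape == self.X.shape == self.Y.shape):
            raise ValueError(
                f"shape mismatch: O{self.O.shape} X{self.X.shape} Y{self.Y.shape}")


@dataclass
class PlateCube:
    """Calibrated reflectance cube with its wavelength axis (nm)."""

    S: np.ndarray  # (lines, samples, bands)
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.S.ndim != 3:
            raise ValueError("S must be (lines, samples, bands)")
        if self.wavelengths.size != self.S.shape[2]:
            raise ValueError("wavelength axis length != band count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.S.shape[2]


@dataclass
class SeedRecord:
    """One seed: its mean spectrum, provenance, and (optional) vitality."""

    seed_id: int
    plate: int
    spectrum: np.ndarray
    n_pixels: int
    vitality_cm: float | None = None
    row: int = -1
    col: int = -1
    extra: dict = field(default_factory=dict)


def correct_reflectance(raw: RawCapture, average_references: bool = True) -> PlateCube:
    """Apply the black/white two-point correction S = (O - Y)/(X - Y).

    Parameters
    ----------
    raw : RawCapture
    average_references : average X and Y over the line (scan) axis before
        correcting.  Reference frames are captured once per session and
        carry their own shot noise; averaging along the push-broom axis
        suppresses it without touching the spectral or sample axes.

    Degenerate pixels where X == Y are set to 0 and reported once via a
    warning rather than propagating NaN into downstream statistics.
    """
    O = np.asarray(raw.O, dtype=np.float64)
    X = np.asarray(raw.X, dtype=np.float64)
    Y = np.asarray(raw.Y, dtype=np.float64)
    if average_references:
        X = np.broadcast_to(X.mean(axis=0, keepdims=True), O.shape)
        Y = np.broadcast_to(Y.mean(axis=0, keepdims=True), O.shape)
    denom = X - Y
    degenerate = denom == 0
    if degenerate.all():
        raise ValueError("white and dark references are identical everywhere")
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(degenerate, 0.0, (O - Y) / np.where(degenerate, 1.0, denom))
    n_bad = int(degenerate.sum())
    if n_bad:
        warnings.warn(f"{n_bad} pixels with X == Y set to reflectance 0",
                      RuntimeWarning, stacklevel=2)
    wl = raw.wavelengths
    if wl is None:
        wl = np.arange(O.shape[2], dtype=float)
    return PlateCube(S=S, wavelengths=np.asarray(wl, dtype=float))


def extract_seed_spectra(cube: PlateCube, mask: np.ndarray,
                         summary: str = "mean") -> np.ndarray:
    """Per-seed summary spectra from a label mask.

    ``mask`` holds 0 for background and 1..K for seed regions; the result
    row k-1 is the per-band mean (or median) over the pixels of label k,
    rows ordered by ascending label.
    """
    mask = np.asarray(mask)
    if mask.shape != cube.S.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} != cube spatial {cube.S.shape[:2]}")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("mask contains no seed labels")
    K = int(labels.max())
    reducer = {"mean": np.mean, "median": np.median}[summary]
    out = np.empty((K, cube.n_bands), dtype=np.float64)
    for k in range(1, K + 1):
        sel = mask == k
        if not sel.any():
            raise ValueError(f"label {k} has no pixels")
        out[k - 1] = reducer(cube.S[sel], axis=0)
    return out


def extract_band_image(cube: PlateCube, band_index: int) -> np.ndarray:
    """The untransformed spatial slice at one band index."""
    if not 0 <= band_index < cube.n_bands:
        raise IndexError(f"band index {band_index} out of range [0, {cube.n_bands})")
    return cube.S[:, :, band_index]
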