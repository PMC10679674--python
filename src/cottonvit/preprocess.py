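"""Spectral pretreatments: SNV, MSC and Savitzky-Golay smoothing.

All three operate row-wise on a (samples x bands) matrix.  SNV and SG
are row-local; MSC needs a reference spectrum, which by default is the
mean spectrum of the training partition, frozen at fit time and reused
for test rows.  The repo-wide spread convention is the sample standard
deviation (ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: center and scale each row to mean 0, sd 1."""
    X = np.asarray(spectra, dtype=float)
    X = np.atleast_2d(X)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"constant spectrum in rows {bad.tolist()}: SNV undefined")
    return (X - mu) / sd


def msc(spectra: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative Scatter Correction against a reference spectrum.

    Each row x is regressed on the reference, x ~ a*ref + b, and the
    correction inverts the fitted affine map: (x - b) / a.  With no
    explicit reference the mean of the input rows is used.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.size != X.shape[1]:
        raise ValueError("reference length != band count")
    if ref.std(ddof=1) == 0:
        raise ValueError("reference spectrum has zero spread")
    rc = ref - ref.mean()
    denom = rc @ rc
    a = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(a == 0):
        raise ValueError("zero fitted slope; MSC correction undefined")
    b = X.mean(axis=1) - a * ref.mean()
    return (X - b[:, None]) / a[:, None]


def sg_smooth(spectra: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing (no derivative) along the band axis.

    Terminal windows are handled by evaluating the edge polynomial fits
    (scipy's ``interp`` mode), so a polynomial row of degree <= polyorder
    is reproduced exactly everywhere.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if window > X.shape[1]:
        raise ValueError("window larger than band count")
    return savgol_filter(X, window_length=window, polyorder=polyorder,
                         axis=1, mode="interp")


@dataclass
class PreprocessSpec:
    method: str = "SG"          # one of SG, SNV, MSC
    sg_window: int = 11
    sg_polyorder: int = 2
    msc_reference: np.ndarray | str = "train-mean"

    def validate(self) -> None:
        if self.method not in {"SG", "SNV", "MSC"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")


class Preprocessor:
    """fit-on-train / apply-to-test wrapper around the three pretreatments.

    SNV and SG are row-local so fitting is a no-op for them; MSC freezes
    the training-mean reference so test rows never inform the model.
    """

    def __init__(self, spec: PreprocessSpec | str = "SG", **kwargs):
        if isinstance(spec, str):
            spec = PreprocessSpec(method=spec, **kwargs)
        spec.validate()
        self.spec = spec
        self.reference_: np.ndarray | None = None

    def fit(self, X_train: np.ndarray) -> "Preprocessor":
        if self.spec.method == "MSC":
            ref = self.spec.msc_reference
            if isinstance(ref, str):  # "train-mean"
                self.reference_ = np.asarray(X_train, dtype=float).mean(axis=0)
            else:
                self.reference_ = np.asarray(ref, dtype=float)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        m = self.spec.method
        if m == "SNV":
            return snv(X)
        if m == "SG":
            return sg_smooth(X, self.spec.sg_window, self.spec.sg_polyorder)
        if self.reference_ is None:
            raise RuntimeError("MSC preprocessor not fitted")
        return msc(X, self.reference_)

    def fit_transform(self, X_train: np.ndarray) -> np.ndarray:
        return self.fit(X_train).transform(X_train)
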