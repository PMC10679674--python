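"""Plate segmentation and semantic-segmentation metrics.

Seeds sit bright on a dark plate background, so a deterministic
Otsu-threshold + connected-components stage separates them; components
below an area floor are discarded and labels are renumbered row-major
by centroid so that label k is the k-th seed in reading order.
Segmentation quality against a ground-truth mask is scored with the two
standard semantic-segmentation metrics, pixel accuracy (PA) and mean
intersection-over-union (MIoU), both on the 2-class background/seed
problem and reported in percent.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

logger = logging.getLogger(__name__)


def segment_plate(band_image: np.ndarray, min_area: int = 20) -> np.ndarray:
    """Segment seeds in a single-band image into a row-major label mask."""
    img = np.asarray(band_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("band image must be single-channel")
    if img.max() == img.min():
        raise ValueError("blank image: nothing to segment")
    thresh = threshold_otsu(img)
    binary = img > thresh
    labels = cc_label(binary, connectivity=2)  # 8-connectivity
    props = [r for r in regionprops(labels) if r.area >= min_area]
    if not props:
        raise ValueError("no components left after area filtering")

    # order row-major: group centroids into rows, then sort by column
    cents = np.array([r.centroid for r in props])  # (K, 2) = (cy, cx)
    heights = [r.bbox[2] - r.bbox[0] for r in props]
    row_gap = 0.6 * float(np.median(heights))
    order_y = np.argsort(cents[:, 0], kind="stable")
    rows: list[list[int]] = []
    for idx in order_y:
        if rows and cents[idx, 0] - cents[rows[-1][0], 0] <= row_gap:
            rows[-1].append(idx)
        else:
            rows.append([idx])
    out = np.zeros_like(labels, dtype=np.uint8)
    new_label = 0
    for row in rows:
        for idx in sorted(row, key=lambda i: cents[i, 1]):
            new_label += 1
            out[labels == props[idx].label] = new_label
    return out


def _binary_confusion(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    p = (np.asarray(pred) > 0).ravel()
    t = (np.asarray(truth) > 0).ravel()
    n = np.empty((2, 2), dtype=np.int64)
    for i in (0, 1):
        for j in (0, 1):
            n[i, j] = int(np.sum((t == bool(i)) & (p == bool(j))))
    return n  # n[i, j]: truth class i predicted as class j


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of correctly classified pixels (2-class), in percent."""
    n = _binary_confusion(pred, truth)
    return float(np.trace(n) / n.sum() * 100.0)


def mean_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean intersection-over-union over the observed classes, in percent.

    A class absent from both prediction and truth is excluded from the
    mean (and logged) rather than contributing an undefined 0/0 term.
    """
    n = _binary_confusion(pred, truth)
    ious = []
    for c in (0, 1):
        union = n[c, :].sum() + n[:, c].sum() - n[c, c]
        if union == 0:
            logger.info("class %d absent from both masks; excluded from MIoU", c)
            continue
        ious.append(n[c, c] / union)
    return float(np.mean(ious) * 100.0)
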