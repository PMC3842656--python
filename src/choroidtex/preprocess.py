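"""Pre-processing of OCT B-scans: denoising, RPE detection, sub-RPE flattening.

The retinal pigment epithelium (RPE) is the brightest band in most columns of
a fundus OCT B-scan.  Everything in this package analyses the choroid, the
vascular layer *beneath* the RPE, so pre-processing has three jobs:

1. remove salt-and-pepper acquisition noise with a small median filter,
2. locate the RPE row in every column, robustly against residual impulses,
3. cut away the retina above the RPE and shift every column up so the RPE
   sits at row 0 ("flattening"), leaving a rectangular image of the choroid
   padded with a ``-1`` sentinel.

Coordinates are 0-based ``(row, col)`` with row 0 the shallowest tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RPEContour",
    "FlattenedChoroid",
    "median_filter",
    "detect_rpe_simple",
    "detect_rpe",
    "build_rpe_image",
    "flatten",
    "preprocess_bscan",
]

SENTINEL = -1


@dataclass
class RPEContour:
    """Per-column RPE row index.

    ``rows[n]`` is the detected RPE row for column ``n``.  Columns where no
    candidate cluster exists (all-zero columns) carry the sentinel value
    ``M - 1`` (the last row) and are marked in ``flagged``; flagged columns
    are excluded from the downstream validity mask.
    """

    rows: np.ndarray
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        if self.flagged is None:
            self.flagged = np.zeros(self.rows.shape, dtype=bool)
        else:
            self.flagged = np.asarray(self.flagged, dtype=bool)
        if self.flagged.shape != self.rows.shape:
            raise ValueError("flagged and rows must have the same length")

    def __len__(self) -> int:
        return int(self.rows.size)


@dataclass
class FlattenedChoroid:
    """Sub-RPE image with the RPE shifted to row 0.

    ``pixels`` holds grey levels in [0, 255] where ``valid_mask`` is True and
    the sentinel ``-1`` elsewhere.  Every column's valid run starts at row 0.
    """

    pixels: np.ndarray
    valid_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {image.shape}")
    return image


def median_filter(image: np.ndarray, mask_rows: int = 3, mask_cols: int = 3) -> np.ndarray:
    """Median-filter a B-scan with an odd rectangular mask (default 3x3).

    Borders are handled by edge replication so no artificial dark frame is
    introduced that could perturb the column-maximum RPE search.
    """
    image = _check_image(image)
    if mask_rows % 2 == 0 or mask_cols % 2 == 0:
        raise ValueError("median mask dimensions must be odd")
    if mask_rows > image.shape[0] or mask_cols > image.shape[1]:
        raise ValueError("median mask larger than image")
    return ndimage.median_filter(image, size=(mask_rows, mask_cols), mode="nearest")


def detect_rpe_simple(image: np.ndarray) -> RPEContour:
    """Per-column argmax RPE detector.

    Returns, for each column, the row of maximum brightness; ties are broken
    towards the smallest row index (shallowest tissue).  Sensitive to
    residual impulse noise — prefer :func:`detect_rpe`.
    """
    image = _check_image(image)
    if image.size == 0:
        raise ValueError("empty image")
    return RPEContour(rows=np.argmax(image, axis=0))


def detect_rpe(image: np.ndarray, p_r: float = 0.9) -> RPEContour:
    """Cluster-median RPE detector.

    For each column, the candidate set is every row whose grey level is at
    least ``p_r`` times the column maximum; the detected row is the (lower)
    median of the candidate rows.  Taking the median of the bright cluster
    rather than the bare argmax makes the detector robust to single bright
    outliers and to flat-topped (saturated) RPE bands.

    All-zero columns have no meaningful cluster; they return the last row
    ``M - 1`` and are flagged.
    """
    image = _check_image(image).astype(np.float64)
    if not 0.0 < p_r <= 1.0:
        raise ValueError(f"p_r must be in (0, 1], got {p_r}")
    m_rows, n_cols = image.shape
    col_max = image.max(axis=0)
    rows = np.empty(n_cols, dtype=np.intp)
    flagged = np.zeros(n_cols, dtype=bool)
    candidate = image >= (col_max * p_r)[None, :]
    for n in range(n_cols):
        if col_max[n] <= 0:
            rows[n] = m_rows - 1
            flagged[n] = True
            continue
        cand = np.flatnonzero(candidate[:, n])
        # lower median keeps the result an existing row index
        rows[n] = cand[(cand.size - 1) // 2]
    return RPEContour(rows=rows, flagged=flagged)


def build_rpe_image(image: np.ndarray, contour: RPEContour) -> np.ndarray:
    """Blank out everything above the RPE with the ``-1`` sentinel.

    Pixels at rows >= the contour are copied from the (median-filtered)
    input; rows above are set to −1 so genuine zero-valued choroid pixels
    stay distinguishable from out-of-region ones.
    """
    image = _check_image(image)
    m_rows, n_cols = image.shape
    if len(contour) != n_cols:
        raise ValueError(f"contour length {len(contour)} != image columns {n_cols}")
    if np.any(contour.rows < 0) or np.any(contour.rows >= m_rows):
        raise ValueError("contour row index out of image range")
    out = image.astype(np.int16, copy=True)
    row_idx = np.arange(m_rows)[:, None]
    out[row_idx < contour.rows[None, :]] = SENTINEL
    return out


def flatten(rpe_image: np.ndarray, contour: RPEContour) -> FlattenedChoroid:
    """Shift each column up by its RPE row so the RPE sits at row 0.

    The trailing space below each shifted column is filled with the −1
    sentinel.  Output dimensions equal the input's (maximum possible choroid
    depth), so ``out[m, n] == in[m + contour[n], n]`` for valid ``m``.
    Columns flagged by the detector are wholly invalid.
    """
    rpe_image = _check_image(rpe_image)
    m_rows, n_cols = rpe_image.shape
    if len(contour) != n_cols:
        raise ValueError(f"contour length {len(contour)} != image columns {n_cols}")
    out = np.full((m_rows, n_cols), SENTINEL, dtype=np.int16)
    for n in range(n_cols):
        top = int(contour.rows[n])
        depth = m_rows - top
        out[:depth, n] = rpe_image[top:, n]
    valid = out != SENTINEL
    valid[:, contour.flagged] = False
    out[:, contour.flagged] = SENTINEL
    return FlattenedChoroid(pixels=out, valid_mask=valid)


def preprocess_bscan(
    image: np.ndarray,
    median_size: int = 3,
    p_r: float = 0.9,
) -> tuple[FlattenedChoroid, RPEContour]:
    """Full pre-processing chain: median filter → RPE detect → flatten."""
    filtered = median_filter(image, median_size, median_size)
    contour = detect_rpe(filtered, p_r=p_r)
    rpe_image = build_rpe_image(filtered, contour)
    return flatten(rpe_image, contour), contour
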