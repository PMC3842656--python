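"""Brightness correction and the multiscale conditional-morphology filter bank.

The flattened choroid image is first made brightness-uniform by subtracting a
30x30 local mean (vessels are at most ~20x20 px, so the mean window is more
than twice the largest object and tracks only the illumination field).  The
residual image is then opened/closed with disc structuring elements of
diameter 3, 5, 7, 9 and 11 px, binarized at half the normalized range (dark
pixels → vessel candidates), and each binary map is refined by *conditional*
erosion and dilation: the plain neighborhood min/max is applied at a pixel
only where a local-mean condition governed by the effectiveness constants
``p_we`` / ``p_wd`` and the threshold map ``p_mn`` permits it.  The condition
makes the operators adaptive — they clean artefacts in flat regions while
leaving textured regions untouched.

Conditional erosion keeps the input pixel where ``(1 - p_we) * p_mn <= s_re``
and takes the neighborhood minimum otherwise; conditional dilation keeps the
pixel where ``(p_wd + 1) * p_mn >= s_rd`` and takes the neighborhood maximum
otherwise.  ``s_re`` / ``s_rd`` are means of the (normalized) grey opened
image over the forward / backward shifted square windows of the structuring
element's bounding box.  At ``p_we = p_wd = 0`` the operators run at full
intensity; at ``p_we = 1`` erosion is the identity, and at ``p_wd = 1`` with
``p_mn ≡ 1`` dilation is the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import FlattenedChoroid

__all__ = [
    "CorrectedChoroid",
    "ConditionalParams",
    "ScaleStack",
    "DEFAULT_SCALES",
    "EFFECTIVENESS_GRID",
    "disc_footprint",
    "brightness_correction",
    "build_mask",
    "filter_bank",
    "binarize",
    "conditional_erosion",
    "conditional_dilation",
    "refine",
    "build_scale_stack",
]

DEFAULT_SCALES: tuple[int, ...] = (3, 5, 7, 9, 11)
DEFAULT_MEAN_MASK = 30

#: effectiveness-constant sweep grid, -1.0 .. 1.0 in steps of 0.1
EFFECTIVENESS_GRID: np.ndarray = np.round(np.arange(-10, 11) / 10.0, 1)


@dataclass
class CorrectedChoroid:
    """Signed brightness residuals of the flattened choroid.

    ``pixels`` is the input minus its 30x30 masked local mean, defined on the
    interior band where the mean window has full support; everything outside
    the band or the valid choroid is 0 and masked out.
    """

    pixels: np.ndarray
    valid_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ConditionalParams:
    """Parameters of the conditional erosion/dilation operators.

    p_we, p_wd : float in [-1, 1]
        Erosion / dilation effectiveness.  0 = maximum intensity of the
        conditional operation; 1 disables erosion entirely.
    p_mn : float or array in [0, 1]
        Threshold map; constant by default (0.5).
    n_rounds : int
        Number of sequential dilation-then-erosion rounds (default 3).
    """

    p_we: float = 0.0
    p_wd: float = 0.0
    p_mn: float | np.ndarray = 0.5
    n_rounds: int = 3

    def __post_init__(self) -> None:
        if not -1.0 <= self.p_we <= 1.0:
            raise ValueError(f"p_we must be in [-1, 1], got {self.p_we}")
        if not -1.0 <= self.p_wd <= 1.0:
            raise ValueError(f"p_wd must be in [-1, 1], got {self.p_wd}")
        p_mn = np.asarray(self.p_mn, dtype=float)
        if np.any(p_mn < 0) or np.any(p_mn > 1):
            raise ValueError("p_mn must lie in [0, 1]")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


@dataclass
class ScaleStack:
    """Per-scale opened (L_Oi), binary (L_Bi) and refined (L_Ki) images."""

    scales: tuple[int, ...]
    opened: dict[int, np.ndarray] = field(default_factory=dict)
    binary: dict[int, np.ndarray] = field(default_factory=dict)
    refined: dict[int, np.ndarray] = field(default_factory=dict)


def disc_footprint(size: int) -> np.ndarray:
    """Boolean disc footprint of diameter ``size`` (odd), L2 ball in a size x size box."""
    if size < 1 or size % 2 == 0:
        raise ValueError(f"structuring-element size must be odd and >= 1, got {size}")
    r = (size - 1) // 2
    dm, dn = np.mgrid[-r : r + 1, -r : r + 1]
    return (dm * dm + dn * dn) <= r * r


def _integral(img: np.ndarray) -> np.ndarray:
    """Summed-area table with a leading zero row/column."""
    s = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=s[1:, 1:])
    return s


def _window_sum(sat: np.ndarray, shape: tuple[int, int],
                row_off: tuple[int, int], col_off: tuple[int, int]) -> np.ndarray:
    """Per-pixel sum over the shifted window [m+row_off[0], m+row_off[1]] x cols.

    Offsets are inclusive; out-of-image parts of the window are ignored
    (shrinking window).
    """
    m_rows, n_cols = shape
    r0 = np.clip(np.arange(m_rows) + row_off[0], 0, m_rows)
    r1 = np.clip(np.arange(m_rows) + row_off[1] + 1, 0, m_rows)
    c0 = np.clip(np.arange(n_cols) + col_off[0], 0, n_cols)
    c1 = np.clip(np.arange(n_cols) + col_off[1] + 1, 0, n_cols)
    return (sat[np.ix_(r1, c1)] - sat[np.ix_(r0, c1)]
            - sat[np.ix_(r1, c0)] + sat[np.ix_(r0, c0)])


def _shifted_window_mean(img: np.ndarray, row_off: tuple[int, int],
                         col_off: tuple[int, int]) -> np.ndarray:
    """Mean of ``img`` over a shifted rectangular window, shrinking at borders."""
    sat = _integral(img)
    total = _window_sum(sat, img.shape, row_off, col_off)
    count = _window_sum(_integral(np.ones_like(img, dtype=np.float64)),
                        img.shape, row_off, col_off)
    out = np.zeros_like(total)
    np.divide(total, count, out=out, where=count > 0)
    return out


def minmax01(img: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Min-max normalize to [0, 1] over the masked region (whole image if no mask).

    Degenerate input (max == min) maps to all zeros.
    """
    img = np.asarray(img, dtype=np.float64)
    region = img[mask] if mask is not None else img
    if region.size == 0:
        return np.zeros_like(img)
    lo, hi = float(region.min()), float(region.max())
    if hi == lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def brightness_correction(choroid: FlattenedChoroid,
                          mask_size: int = DEFAULT_MEAN_MASK) -> CorrectedChoroid:
    """Subtract the ``mask_size`` x ``mask_size`` local mean from the choroid.

    The local mean is computed over valid (non-sentinel) pixels only, with
    window offsets −(mask_size/2 − 1) .. +mask_size/2 around each pixel.  The
    residual is defined only on the interior band where the window has full
    support; the exterior band is zeroed and masked out.
    """
    m_rows, n_cols = choroid.shape
    if m_rows < mask_size or n_cols < mask_size:
        raise ValueError(
            f"image {m_rows}x{n_cols} smaller than the {mask_size}x{mask_size} mean mask")
    half = mask_size // 2
    off = (-(half - 1), half)  # 30 -> offsets -14 .. +15
    valid = choroid.valid_mask.astype(np.float64)
    pix = np.where(choroid.valid_mask, choroid.pixels, 0).astype(np.float64)
    win_sum = _window_sum(_integral(pix), choroid.shape, off, off)
    win_cnt = _window_sum(_integral(valid), choroid.shape, off, off)
    local_mean = np.zeros_like(win_sum)
    np.divide(win_sum, win_cnt, out=local_mean, where=win_cnt > 0)
    residual = pix - local_mean
    band = build_mask(choroid, mask_size=mask_size)
    residual[~band] = 0.0
    return CorrectedChoroid(pixels=residual, valid_mask=band)


def build_mask(choroid: FlattenedChoroid, mask_size: int = DEFAULT_MEAN_MASK) -> np.ndarray:
    """Validity mask: non-sentinel choroid pixels within the interior band."""
    m_rows, n_cols = choroid.shape
    half = mask_size // 2
    band = np.zeros((m_rows, n_cols), dtype=bool)
    lo = half - 1
    band[lo : m_rows - half, lo : n_cols - half] = True
    return choroid.valid_mask & band


def _grey_max(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return ndimage.maximum_filter(img, footprint=footprint, mode="constant", cval=-np.inf)


def _grey_min(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return ndimage.minimum_filter(img, footprint=footprint, mode="constant", cval=np.inf)


def filter_bank(corrected: CorrectedChoroid | np.ndarray,
                mask: np.ndarray | None = None,
                scales: tuple[int, ...] = DEFAULT_SCALES,
                order: str = "as-printed") -> dict[int, np.ndarray]:
    """Multiscale disc-SE morphological filtering of the masked residual image.

    For each scale ``i`` the masked residual is passed through the grey-scale
    max-then-min composite over the disc SE_i (``order="as-printed"``; this is
    a morphological closing, which removes dark structures smaller than the
    SE).  ``order="opening"`` applies min-then-max instead.  Out-of-image
    neighborhood members are ignored (shrinking window).
    """
    if isinstance(corrected, CorrectedChoroid):
        if mask is None:
            mask = corrected.valid_mask
        corrected = corrected.pixels
    if len(scales) == 0:
        raise ValueError("empty scale set")
    if order not in ("as-printed", "opening"):
        raise ValueError(f"unknown order {order!r}")
    img = np.asarray(corrected, dtype=np.float64)
    if mask is not None:
        img = img * mask
    out: dict[int, np.ndarray] = {}
    for size in scales:
        fp = disc_footprint(size)
        if order == "as-printed":
            out[size] = _grey_min(_grey_max(img, fp), fp)
        else:
            out[size] = _grey_max(_grey_min(img, fp), fp)
    return out


def binarize(opened: np.ndarray, mask: np.ndarray | None = None,
             p_r: float = 0.5) -> np.ndarray:
    """Threshold the normalized opened image, selecting DARK pixels.

    The image is min-max normalized over the masked region; output is 1 where
    the normalized value is < ``p_r`` (choroidal vessels are dark), masked
    pixels are 0.  A constant image is degenerate and maps to all zeros.
    """
    if not 0.0 < p_r < 1.0:
        raise ValueError(f"binarization threshold must be in (0, 1), got {p_r}")
    opened = np.asarray(opened, dtype=np.float64)
    region = opened[mask] if mask is not None else opened
    if region.size == 0 or region.max() == region.min():
        warnings.warn("degenerate (constant) image in binarize: all-zero output",
                      stacklevel=2)
        return np.zeros(opened.shape, dtype=np.uint8)
    norm = (opened - region.min()) / (region.max() - region.min())
    out = (norm < p_r).astype(np.uint8)
    if mask is not None:
        out &= mask.astype(np.uint8)
    return out


def _check_binary(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if not np.isin(img, (0, 1)).all():
        raise ValueError("input image must be binary")
    return img.astype(np.uint8)


def _neighborhood_means(grey_norm: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward (s_re) and backward (s_rd) shifted square-window means."""
    s_re = _shifted_window_mean(grey_norm, (1, size), (1, size))
    s_rd = _shifted_window_mean(grey_norm, (-size, -1), (-size, -1))
    return s_re, s_rd


def conditional_erosion(binary: np.ndarray, grey: np.ndarray,
                        params: ConditionalParams, size: int,
                        mask: np.ndarray | None = None) -> np.ndarray:
    """Conditional erosion of ``binary`` guided by the grey image ``grey``.

    Keeps the input pixel where ``(1 - p_we) * p_mn <= s_re``; otherwise
    outputs the minimum of the binary image over the disc SE neighborhood.
    ``s_re`` is the mean of the min-max-normalized grey image over the square
    window shifted forward by +1..+size in both axes.
    """
    binary = _check_binary(binary)
    grey = np.asarray(grey, dtype=np.float64)
    if binary.shape != grey.shape:
        raise ValueError("binary and grey images must share a shape")
    s_re, _ = _neighborhood_means(minmax01(grey, mask), size)
    keep = (1.0 - params.p_we) * np.asarray(params.p_mn, dtype=float) <= s_re
    eroded = ndimage.minimum_filter(binary, footprint=disc_footprint(size),
                                    mode="constant", cval=1)
    return np.where(keep, binary, eroded).astype(np.uint8)


def conditional_dilation(binary: np.ndarray, grey: np.ndarray,
                         params: ConditionalParams, size: int,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """Conditional dilation of ``binary`` guided by the grey image ``grey``.

    Keeps the input pixel where ``(p_wd + 1) * p_mn >= s_rd``; otherwise
    outputs the maximum of the binary image over the disc SE neighborhood.
    ``s_rd`` is the mean of the normalized grey image over the square window
    shifted backward by −size..−1 in both axes.
    """
    binary = _check_binary(binary)
    grey = np.asarray(grey, dtype=np.float64)
    if binary.shape != grey.shape:
        raise ValueError("binary and grey images must share a shape")
    _, s_rd = _neighborhood_means(minmax01(grey, mask), size)
    keep = (params.p_wd + 1.0) * np.asarray(params.p_mn, dtype=float) >= s_rd
    dilated = ndimage.maximum_filter(binary, footprint=disc_footprint(size),
                                     mode="constant", cval=0)
    return np.where(keep, binary, dilated).astype(np.uint8)


def refine(binary: np.ndarray, grey: np.ndarray, params: ConditionalParams,
           size: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Sequential conditional dilation then erosion, ``params.n_rounds`` times.

    Removes small artefacts and fills holes in the binary vessel maps.  When
    a validity mask is given, masked-out pixels are forced back to 0 after
    every operation so dilation can never grow outside the choroid.
    """
    out = _check_binary(binary)
    # the grey guide image is constant across rounds, so the condition maps
    # are precomputed once (equivalent to chaining the public operators)
    norm = minmax01(np.asarray(grey, dtype=np.float64), mask)
    s_re, s_rd = _neighborhood_means(norm, size)
    p_mn = np.asarray(params.p_mn, dtype=float)
    keep_e = (1.0 - params.p_we) * p_mn <= s_re
    keep_d = (params.p_wd + 1.0) * p_mn >= s_rd
    fp = disc_footprint(size)
    m8 = mask.astype(np.uint8) if mask is not None else None
    for _ in range(params.n_rounds):
        dil = ndimage.maximum_filter(out, footprint=fp, mode="constant", cval=0)
        out = np.where(keep_d, out, dil).astype(np.uint8)
        if m8 is not None:
            out &= m8
        ero = ndimage.minimum_filter(out, footprint=fp, mode="constant", cval=1)
        out = np.where(keep_e, out, ero).astype(np.uint8)
        if m8 is not None:
            out &= m8
    return out


def build_scale_stack(corrected: CorrectedChoroid,
                      scales: tuple[int, ...] = DEFAULT_SCALES,
                      params: ConditionalParams | None = None,
                      p_r_bin: float = 0.5,
                      order: str = "as-printed") -> ScaleStack:
    """Run the full filter bank: opening, binarization and refinement per scale."""
    if params is None:
        params = ConditionalParams()
    mask = corrected.valid_mask
    stack = ScaleStack(scales=tuple(scales))
    stack.opened = filter_bank(corrected, mask, scales, order=order)
    for size in scales:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = binarize(stack.opened[size], mask, p_r=p_r_bin)
        stack.binary[size] = b
        stack.refined[size] = refine(b, stack.opened[size], params, size, mask)
    return stack
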