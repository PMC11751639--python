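"""B-scan boundary segmentation and thickness-map assembly.

Each B-scan is cropped to a square, its inner (upper) and outer (lower)
retinal boundaries are segmented — either by the deterministic gradient
oracle in this module or by the trainable U-Net in :mod:`octphen.unet` —
per-column thickness is the inclusive count of mask rows, and the profiles of
all slices are stacked into one thickness map per eye.  Map orientation: row
index = B-scan (slice) index, column = A-scan position; row 0 of each B-scan
is superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage

__all__ = [
    "SegmentationMask",
    "ThicknessProfile",
    "ThicknessMap",
    "MapQCError",
    "crop_bscan",
    "oracle_segment",
    "mask_from_edges",
    "postprocess_mask",
    "thickness_profile",
    "assemble_map",
]


class MapQCError(ValueError):
    """Raised when a thickness map fails quality control."""


@dataclass
class SegmentationMask:
    """Binary retina mask with per-column boundary rows.

    Per column the 1-pixels form a single contiguous vertical run (enforced by
    :func:`postprocess_mask`); flagged columns have no usable boundary and
    carry ``upper_edge = lower_edge = -1``.
    """

    mask: np.ndarray  # (n_rows, n_cols) bool
    upper_edge: np.ndarray  # (n_cols,) int, -1 where flagged
    lower_edge: np.ndarray
    flags: np.ndarray  # (n_cols,) bool, True = column unusable

    def __post_init__(self) -> None:
        ok = ~self.flags
        if np.any(self.upper_edge[ok] > self.lower_edge[ok]):
            raise ValueError("upper_edge must not exceed lower_edge on unflagged columns")


@dataclass
class ThicknessProfile:
    """Per-column retinal thickness of one B-scan, px; NaN where flagged."""

    thickness: np.ndarray  # (n_cols,) float
    quality_flags: np.ndarray  # (n_cols,) bool


@dataclass
class ThicknessMap:
    """Per-eye thickness image: rows = B-scan index, cols = A-scan position."""

    map: np.ndarray  # (n_slices, n_cols) float, finite and >= 0
    subject_id: str = ""
    eye: str = "left"
    qc_metrics: dict = field(default_factory=dict)


def crop_bscan(image: np.ndarray, out_rows: int | None = None) -> np.ndarray:
    """Crop equal numbers of rows from the superior (top) and inferior
    (bottom) edges to obtain a square image (default target = width).

    An odd remainder removes the extra row from the bottom.  E.g. 650x512 ->
    512x512 with 69 rows dropped from each edge.  Row 0 stays superior.
    """
    n_rows, n_cols = image.shape[-2], image.shape[-1]
    target = n_cols if out_rows is None else out_rows
    if n_rows < target:
        raise ValueError(f"input has {n_rows} rows, fewer than the {target} required")
    drop = n_rows - target
    top = drop // 2
    bottom = drop - top
    return image[..., top : n_rows - bottom, :]


def crop_offset(n_rows: int, out_rows: int) -> int:
    """Rows removed from the top by :func:`crop_bscan` (surface-shift amount)."""
    return (n_rows - out_rows) // 2


def mask_from_edges(
    upper: np.ndarray, lower: np.ndarray, n_rows: int, flags: np.ndarray | None = None
) -> SegmentationMask:
    """Build a contiguous-run mask from integer boundary rows."""
    upper = np.asarray(upper, int)
    lower = np.asarray(lower, int)
    n_cols = upper.size
    if flags is None:
        flags = np.zeros(n_cols, bool)
    flags = flags | (upper < 0) | (lower >= n_rows) | (upper > lower)
    r = np.arange(n_rows)[:, None]
    mask = (r >= upper[None, :]) & (r <= lower[None, :]) & ~flags[None, :]
    u = np.where(flags, -1, upper)
    lo = np.where(flags, -1, lower)
    return SegmentationMask(mask, u, lo, flags)


def postprocess_mask(raw: np.ndarray) -> SegmentationMask:
    """Reduce an arbitrary binary mask to one contiguous vertical run per
    column (the longest), flagging empty columns.  Robust to speckle islands."""
    raw = np.asarray(raw) > 0.5
    n_rows, n_cols = raw.shape
    upper = np.full(n_cols, -1)
    lower = np.full(n_cols, -1)
    flags = np.zeros(n_cols, bool)
    padded = np.zeros((n_rows + 2, n_cols), bool)
    padded[1:-1] = raw
    starts = ~padded[:-1] & padded[1:]  # run starts at row index of this True
    ends = padded[:-1] & ~padded[1:]
    for c in range(n_cols):
        s = np.flatnonzero(starts[:, c])
        e = np.flatnonzero(ends[:, c]) - 1
        if s.size == 0:
            flags[c] = True
            continue
        lengths = e - s + 1
        k = int(np.argmax(lengths))
        upper[c], lower[c] = s[k], e[k]
    return mask_from_edges(upper, lower, n_rows, flags)


def oracle_segment(
    image: np.ndarray,
    smooth_sigma: float = 1.5,
    min_contrast: float = 0.05,
) -> SegmentationMask:
    """Deterministic boundary oracle based on the vertical intensity gradient.

    Per column the image is smoothed along rows; the upper boundary is the
    sub-pixel location of the strongest positive (dark-to-bright) gradient
    peak and the lower boundary that of the strongest negative peak below it.
    Sub-pixel peak positions are converted to mask rows so that the mask-row
    count is an unbiased estimate of the continuous thickness.  Columns whose
    gradient extremes fall below ``min_contrast`` are flagged, not failed.
    """
    img = np.asarray(image, float)
    n_rows, n_cols = img.shape
    sm = ndimage.gaussian_filter1d(img, smooth_sigma, axis=0)
    g = np.gradient(sm, axis=0)

    flags = (g.max(axis=0) < min_contrast) | (g.min(axis=0) > -min_contrast)
    upper = np.full(n_cols, -1)
    lower = np.full(n_cols, -1)
    rows = np.arange(n_rows)
    for c in np.flatnonzero(~flags):
        gc = g[:, c]
        iu = int(np.argmax(gc))
        # negative peak searched strictly below the upper peak
        below = gc[iu + 1 :]
        if below.size == 0:
            flags[c] = True
            continue
        il = iu + 1 + int(np.argmin(below))
        eu = _peak_centroid(rows, np.clip(gc, 0.0, None), iu)
        el = _peak_centroid(rows, np.clip(-gc, 0.0, None), il)
        u = int(np.ceil(eu))
        lo = int(np.ceil(el)) - 1  # last retina row (band is [upper, lower))
        if u > lo or u < 0 or lo >= n_rows:
            flags[c] = True
        else:
            upper[c], lower[c] = u, lo
    return mask_from_edges(upper, lower, n_rows, flags)


def _peak_centroid(rows: np.ndarray, w: np.ndarray, i: int, half: int = 2) -> float:
    lo, hi = max(i - half, 0), min(i + half + 1, rows.size)
    ww = w[lo:hi]
    tot = ww.sum()
    return float(rows[lo:hi] @ ww / tot) if tot > 0 else float(i)


def thickness_profile(mask: SegmentationMask) -> ThicknessProfile:
    """Thickness = inclusive mask-row count per column; flagged -> NaN."""
    t = (mask.lower_edge - mask.upper_edge + 1).astype(float)
    t[mask.flags] = np.nan
    return ThicknessProfile(t, mask.flags.copy())


def assemble_map(
    profiles: list[ThicknessProfile],
    subject_id: str = "",
    eye: str = "left",
    max_missing_fraction: float = 0.2,
) -> ThicknessMap:
    """Stack per-slice profiles into a thickness map, interpolating flagged
    cells bilinearly (nearest-neighbour fallback at edges).

    Raises :class:`MapQCError` when more than ``max_missing_fraction`` of
    cells are flagged, emulating image-quality exclusions.
    """
    widths = {p.thickness.size for p in profiles}
    if len(widths) != 1:
        raise ValueError("all profiles must have the same width")
    m = np.stack([p.thickness for p in profiles])
    missing = ~np.isfinite(m)
    frac = float(missing.mean())
    if frac > max_missing_fraction:
        raise MapQCError(
            f"{frac:.1%} of cells missing exceeds the {max_missing_fraction:.0%} limit"
        )
    if missing.any():
        rr, cc = np.nonzero(~missing)
        pts = np.column_stack([rr, cc])
        vals = m[~missing]
        mr, mc = np.nonzero(missing)
        filled = interpolate.griddata(pts, vals, np.column_stack([mr, mc]), method="linear")
        bad = ~np.isfinite(filled)
        if bad.any():
            filled[bad] = interpolate.griddata(
                pts, vals, np.column_stack([mr[bad], mc[bad]]), method="nearest"
            )
        m = m.copy()
        m[missing] = filled
    med = np.median(m)
    mad = np.median(np.abs(m - med)) + 1e-12
    qc = {
        "missing_fraction": frac,
        "outlier_score": float(np.mean(np.abs(m - med) > 6.0 * mad)),
    }
    return ThicknessMap(np.maximum(m, 0.0), subject_id, eye, qc)
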