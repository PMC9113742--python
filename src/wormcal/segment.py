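"""Worm segmentation, perimeter extraction and cross-frame registration.

The edge-detection stage of the calcium-imaging pipeline: each frame is
smoothed and thresholded (Otsu), the largest connected component is kept and
hole-filled, its sub-pixel boundary is traced by marching squares, resampled
to a fixed number of equal-arc-length points, and perimeters are registered
across frames by a cyclic-shift search so that a given kymograph row means
the same body position throughout the recording.

Conventions: coordinates are (row, col), 0-based, pixel centres at integers.
Contours are traversed "counter-clockwise", defined as positive signed area
in the (x=col, y=row) plane.  Head and tail are not identified; registration
is purely shift-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

__all__ = [
    "SegmentConfig",
    "WormContour",
    "ContourSequence",
    "WormNotFoundError",
    "segment_frame",
    "extract_contour",
    "register_contours",
    "match_cyclic",
    "align_to_reference",
    "contours_to_csv",
]


class WormNotFoundError(ValueError):
    """No worm-sized foreground component in the frame."""


@dataclass
class SegmentConfig:
    """Settings of the edge-detection operator.

    The contract is fixed (frame -> mask -> ordered perimeter); the operator
    itself is configurable.  ``background_subtract`` removes a per-frame
    median before thresholding (off by default).
    """

    smooth_sigma: float = 1.0
    closing_radius: int = 2
    min_area: int = 100
    background_subtract: bool = False
    n_points: int = 200        # P, perimeter samples after resampling
    contour_smooth: float = 2.0  # periodic Gaussian smoothing (samples)


@dataclass
class WormContour:
    """Ordered closed sub-pixel boundary of the worm in one frame."""

    frame_index: int
    points: np.ndarray          # (P, 2) of (row, col); closed, not repeated
    arc_length: float
    anchor_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (P, 2)")
        if len(self.points) < 20:
            raise ValueError("contour needs at least 20 points")

    def signed_area(self) -> float:
        x, y = self.points[:, 1], self.points[:, 0]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def is_simple(self) -> bool:
        """True if the closed polyline has no self-intersection."""
        try:
            from shapely.geometry import Polygon

            return Polygon(self.points[:, ::-1]).is_valid
        except Exception:  # pragma: no cover - shapely always present in practice
            return True


@dataclass
class ContourSequence:
    """Per-frame contours, same point count, consistent traversal direction."""

    contours: list[WormContour]
    orientation_flag: int = 1

    def __post_init__(self) -> None:
        counts = {len(c.points) for c in self.contours}
        if len(counts) > 1:
            raise ValueError(f"contour point counts differ: {sorted(counts)}")

    @property
    def n_points(self) -> int:
        return len(self.contours[0].points)

    def __len__(self) -> int:
        return len(self.contours)


def segment_frame(frame: np.ndarray, cfg: SegmentConfig | None = None) -> np.ndarray:
    """Binary worm mask of a single frame.

    Gaussian smoothing + Otsu threshold; the worm is taken to be the
    *minority* intensity class, which makes the operator symmetric under
    contrast inversion.  The largest connected component is kept, closed and
    hole-filled.
    """
    cfg = cfg or SegmentConfig()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("frame must be a non-empty 2-D array")
    if cfg.background_subtract:
        img = img - np.median(img)
    if cfg.smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.smooth_sigma)
    if np.ptp(img) < 1e-9:
        raise WormNotFoundError("frame is constant; no worm found")
    # canonicalise polarity (reflect if the majority class is bright) so the
    # operator is exactly symmetric under contrast inversion
    lo, hi = img.min(), img.max()
    if np.median(img) > (lo + hi) / 2:
        img = (lo + hi) - img
    thr = filters.threshold_otsu(img)
    bright = img > thr
    mask = bright if bright.mean() <= 0.5 else ~bright
    if cfg.closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(cfg.closing_radius))
    labels = measure.label(mask)
    if labels.max() == 0:
        raise WormNotFoundError("no foreground component found")
    sizes = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < cfg.min_area:
        raise WormNotFoundError(
            f"largest component ({sizes[biggest - 1]} px) below min_area {cfg.min_area}"
        )
    mask = labels == biggest
    return ndimage.binary_fill_holes(mask)


def _resample_closed(points: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    """Resample a closed polyline to n equal-arc-length points."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    keep = seg > 1e-12
    closed = np.vstack([closed[:-1][keep], closed[-1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s_new = np.linspace(0, total, n, endpoint=False)
    rows = np.interp(s_new, cum, closed[:, 0])
    cols = np.interp(s_new, cum, closed[:, 1])
    return np.column_stack([rows, cols]), float(total)


def _smooth_periodic(points: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return points
    return np.column_stack([
        ndimage.gaussian_filter1d(points[:, 0], sigma, mode="wrap"),
        ndimage.gaussian_filter1d(points[:, 1], sigma, mode="wrap"),
    ])


def extract_contour(mask: np.ndarray, frame_index: int = 0,
                    cfg: SegmentConfig | None = None) -> WormContour:
    """Sub-pixel outer boundary of the mask, CCW, P equal-arc-length points.

    Marching squares at the 0.5 level; the staircase is lightly smoothed
    (periodic Gaussian over contour samples) so arc length approximates the
    true smooth boundary rather than the rasterised one.
    """
    cfg = cfg or SegmentConfig()
    mask = np.asarray(mask).astype(bool)
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("worm touches the image border (clipped); cannot extract contour")
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise WormNotFoundError("mask has no boundary")
    boundary = max(contours, key=len)
    if np.linalg.norm(boundary[0] - boundary[-1]) < 1e-9:
        boundary = boundary[:-1]
    # resample densely, smooth the rasterisation staircase, then resample to P
    dense, _ = _resample_closed(boundary, max(4 * cfg.n_points, len(boundary)))
    dense = _smooth_periodic(dense, cfg.contour_smooth * len(dense) / cfg.n_points / 4)
    pts, arc = _resample_closed(dense, cfg.n_points)
    contour = WormContour(frame_index=frame_index, points=pts, arc_length=arc)
    if contour.signed_area() < 0:
        contour.points = contour.points[::-1].copy()
    return contour


def match_cyclic(a: np.ndarray, b: np.ndarray) -> tuple[int, float]:
    """Cyclic shift k minimising sum |a_j - b_{(j+k) mod P}|^2.

    Returns (k, rms distance at the optimum).  Both inputs are (P, 2) with
    equal P.  FFT cross-correlation makes the search O(P log P).
    """
    if a.shape != b.shape:
        raise ValueError("contour point counts differ")
    za = a[:, 1] + 1j * a[:, 0]
    zb = b[:, 1] + 1j * b[:, 0]
    # cross[k] = Re sum_j a_j conj(b_{j+k}); roll(b, -k) then matches a
    cross = np.real(np.fft.ifft(np.conj(np.fft.fft(za)) * np.fft.fft(zb)))
    k = int(np.argmax(cross))
    ssd = np.sum(np.abs(za) ** 2) + np.sum(np.abs(zb) ** 2) - 2 * cross[k]
    return k, float(np.sqrt(max(ssd, 0.0) / len(a)))


def register_contours(contours: list[WormContour]) -> ContourSequence:
    """Make traversal direction consistent and remove cyclic-shift jitter.

    Each frame's contour is rolled so its points correspond (by index) to
    the previous frame's; the applied shift is recorded as ``anchor_index``.
    Frames whose traversal direction disagrees with the first frame are
    flipped first.
    """
    if len(contours) < 2:
        raise ValueError("need at least 2 contours to register")
    p = len(contours[0].points)
    for c in contours:
        if len(c.points) != p:
            raise ValueError("contour point counts differ")
    out: list[WormContour] = []
    ref_sign = np.sign(contours[0].signed_area()) or 1.0
    prev = None
    for c in contours:
        pts = c.points
        if np.sign(0.5 * np.sum(pts[:, 1] * np.roll(pts[:, 0], -1)
                                - np.roll(pts[:, 1], -1) * pts[:, 0])) != ref_sign:
            pts = pts[::-1].copy()
        if prev is None:
            shift = 0
        else:
            shift, _ = match_cyclic(prev, pts)
        aligned = np.roll(pts, -shift, axis=0)
        out.append(WormContour(frame_index=c.frame_index, points=aligned,
                               arc_length=c.arc_length, anchor_index=shift))
        prev = aligned
    return ContourSequence(contours=out, orientation_flag=int(ref_sign))


def align_to_reference(points: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, int, bool]:
    """Align a contour to a reference by orientation flip + cyclic shift.

    ``reference`` may have a different point count; it is resampled to match.
    Returns (aligned points, shift, flipped).  Used to map registered
    kymograph rows onto ground-truth perimeter fractions.
    """
    ref, _ = _resample_closed(reference, len(points))
    best = None
    for flipped, pts in ((False, points), (True, points[::-1].copy())):
        k, rms = match_cyclic(ref, pts)
        if best is None or rms < best[3]:
            best = (np.roll(pts, -k, axis=0), k, flipped, rms)
    return best[0], best[1], best[2]


def contours_to_csv(seq: ContourSequence, path: str | Path) -> None:
    """Export as tidy CSV (frame, point_index, row, col)."""
    rows = []
    for c in seq.contours:
        for i, (r, col) in enumerate(c.points):
            rows.append((c.frame_index, i, r, col))
    pd.DataFrame(rows, columns=["frame", "point_index", "row", "col"]).to_csv(
        path, index=False
    )
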