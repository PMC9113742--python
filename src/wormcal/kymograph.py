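"""Perimeter "line-scan" kymographs and Ca2+ transient quantification.

The body-wall muscle lies just under the cuticle, so the fluorescence signal
is sampled along a thin band on the inward normal of the registered worm
perimeter: the kymograph has perimeter position on one axis and time on the
other.  Rows are normalised to ΔF/F0 with a per-row percentile baseline,
contraction-associated transients are detected as spatiotemporally connected
supra-threshold regions, and the recording is summarised by the mean of the
event peaks.  A caffeine (SR store release) readout watches the whole-worm
trace for a global response within a fixed window after drug addition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import measure

from .segment import ContourSequence
from .synth import VideoStack

__all__ = [
    "Kymograph",
    "Transient",
    "TransientSet",
    "PeakSummary",
    "CaffeineResponse",
    "build_kymograph",
    "compute_dff",
    "detect_transients",
    "average_peak",
    "caffeine_response",
]


@dataclass
class Kymograph:
    """P x T intensity grid: perimeter position (rows) against frame (cols)."""

    values: np.ndarray
    frame_interval: float
    band_width: float = 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("kymograph must be 2-D with P, T >= 2")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("kymograph values must be finite and >= 0")

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.values.astype(np.float32))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values).to_csv(path, index_label="perimeter_index")


@dataclass
class Transient:
    """One detected Ca2+ event."""

    time: float                # s, at the event peak
    position: float            # perimeter fraction in [0, 1)
    peak_dff: float            # peak ΔF/F0
    duration: float            # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class TransientSet:
    """Detected events plus the per-row baseline map used to normalise."""

    events: list[Transient]
    f0_map: np.ndarray

    def __post_init__(self) -> None:
        self.f0_map = np.asarray(self.f0_map, dtype=float)
        if np.any(self.f0_map <= 0):
            raise ValueError("F0 must be > 0 everywhere")

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.time, e.position, e.peak_dff, e.duration) for e in self.events],
            columns=["time_s", "perimeter_fraction", "peak_dff", "duration_s"],
        )


@dataclass
class PeakSummary:
    """Mean of event peaks — the per-recording summary statistic."""

    mean_peak: float
    n_events: int
    no_events: bool

    @property
    def value(self) -> float:
        return self.mean_peak


@dataclass
class CaffeineResponse:
    """Whole-worm response to caffeine-evoked SR Ca2+ store release."""

    baseline: float        # mean whole-worm ΔF/F0 before addition
    peak_post: float       # max whole-worm ΔF/F0 in the response window
    latency: float         # s from addition to threshold crossing (nan if none)
    responder: bool

    def __post_init__(self) -> None:
        if np.isfinite(self.latency) and self.latency < 0:
            raise ValueError("latency must be >= 0")


def build_kymograph(video: VideoStack, contours: ContourSequence,
                    band_width: float = 3.0, inset: float = 1.0) -> Kymograph:
    """Sample the muscle band along the inward normal of each perimeter point.

    Entry (p, t) is the mean of ``band_width`` samples taken at 1 px spacing
    along the inward normal at registered perimeter point p of frame t
    (bilinear interpolation).  Sampling starts ``inset`` px inside the
    contour so that sub-pixel contour error does not blend in background.
    Raises if any sample leaves the image.
    """
    if band_width < 1:
        raise ValueError("band_width must be >= 1")
    if len(contours) != video.n_frames:
        raise ValueError("one registered contour per frame is required")
    n_p = contours.n_points
    n_t = video.n_frames
    h, w = video.frames.shape[1:]
    offsets = inset + np.arange(int(round(band_width))) + 0.5
    values = np.empty((n_p, n_t))
    for t, contour in enumerate(contours.contours):
        pts = contour.points
        d = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
        tang = d / np.linalg.norm(d, axis=1, keepdims=True)
        # positive-area traversal in (x=col, y=row): inward normal is the
        # tangent rotated by +90 deg -> (row, col) = (t_col, -t_row)
        inward = np.column_stack([tang[:, 1], -tang[:, 0]])
        coords = pts[:, None, :] + offsets[None, :, None] * inward[:, None, :]
        if (coords[..., 0].min() < 0 or coords[..., 0].max() > h - 1
                or coords[..., 1].min() < 0 or coords[..., 1].max() > w - 1):
            raise ValueError(f"band sampling leaves the image in frame {t}")
        samples = ndimage.map_coordinates(
            video.frames[t],
            [coords[..., 0].ravel(), coords[..., 1].ravel()],
            order=1,
        ).reshape(n_p, len(offsets))
        values[:, t] = samples.mean(axis=1)
    return Kymograph(np.clip(values, 0, None), video.frame_interval, band_width)


def _detrend_rows(values: np.ndarray, frame_interval: float) -> np.ndarray:
    """Divide out a per-row exponential bleach fit, preserving the row mean level."""
    t = np.arange(values.shape[1]) * frame_interval
    out = np.empty_like(values)
    for i, row in enumerate(values):
        pos = np.clip(row, 1e-9, None)
        b, a = np.polyfit(t, np.log(pos), 1)
        trend = np.exp(a + b * t)
        out[i] = row / trend * trend[0]
    return out


def compute_dff(kymo: Kymograph, f0_method: str = "percentile",
                percentile: float = 10.0, detrend: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
    """Normalise to ΔF/F0 with a per-row baseline.

    ``f0_method='percentile'`` (default) uses the row's ``percentile``-th
    intensity over time, robust as long as events occupy less than
    (100 - percentile)% of frames.  ``'median'`` and ``'mean'`` are
    alternatives.  With ``detrend=True`` an exponential bleach trend is
    divided out per row first.  Returns (dff grid, f0 map).
    """
    values = kymo.values
    if detrend:
        values = _detrend_rows(values, kymo.frame_interval)
    if f0_method == "percentile":
        f0 = np.percentile(values, percentile, axis=1)
    elif f0_method == "median":
        f0 = np.median(values, axis=1)
    elif f0_method == "mean":
        f0 = values.mean(axis=1)
    else:
        raise ValueError(f"unknown f0_method {f0_method!r}")
    if np.any(f0 <= 0):
        raise ValueError("F0 <= 0 in at least one row; cannot normalise")
    dff = (values - f0[:, None]) / f0[:, None]
    return dff, f0


def detect_transients(dff: np.ndarray, f0_map: np.ndarray, frame_interval: float,
                      k_thresh: float = 4.0, min_duration: float = 0.3,
                      merge_radius: float = 0.05, merge_gap: float = 0.2,
                      min_amplitude: float = 0.05) -> TransientSet:
    """Detect Ca2+ events as connected supra-threshold regions.

    A sample is a candidate when its ΔF/F0 exceeds the row median by
    ``k_thresh`` robust standard deviations (1.4826 * MAD), with an absolute
    floor of ``min_amplitude`` ΔF/F0 (events below ~5% are not scorable
    with this indicator, and on near-noiseless data the MAD alone would
    chase sampling ripple).  Candidates are closed along time (gaps of one
    sample are bridged) and merged by 8-connectivity on the perimeter x time
    grid.  Fragments that residual registration jitter split across nearby
    rows are re-merged when they are within ``merge_radius`` of the
    perimeter and ``merge_gap`` seconds of one another.  Events shorter than
    ``min_duration`` are then discarded.  An empty result is valid.
    """
    dff = np.asarray(dff, dtype=float)
    if not np.all(np.isfinite(dff)):
        raise ValueError("dff must be finite")
    med = np.median(dff, axis=1, keepdims=True)
    mad = np.median(np.abs(dff - med), axis=1, keepdims=True)
    sigma = 1.4826 * mad
    thresh = med + np.maximum(k_thresh * sigma, min_amplitude)
    cand = dff > thresh
    # bridge single-sample dropouts along time
    cand = ndimage.binary_closing(cand, structure=np.ones((1, 3), bool))
    labels = measure.label(cand, connectivity=2)
    n_p = dff.shape[0]
    # raw fragments: (t0, t1, pos, t_peak, peak)
    frags = []
    for region in measure.regionprops(labels, intensity_image=dff):
        t0, t1 = region.bbox[1], region.bbox[3]
        p_peak, t_peak = region.coords[
            np.argmax(dff[region.coords[:, 0], region.coords[:, 1]])
        ]
        frags.append([t0, t1, p_peak / n_p, int(t_peak), float(dff[p_peak, t_peak])])
    frags.sort(key=lambda f: f[0])

    def circ_dist(a: float, b: float) -> float:
        d = abs(a - b)
        return min(d, 1.0 - d)

    gap_frames = merge_gap / frame_interval
    merged: list[list] = []
    for f in frags:
        target = None
        for m in merged:
            if f[0] - m[1] <= gap_frames and circ_dist(f[2], m[2]) <= merge_radius:
                target = m
                break
        if target is None:
            merged.append(list(f))
        else:
            target[1] = max(target[1], f[1])
            if f[4] > target[4]:
                target[2], target[3], target[4] = f[2], f[3], f[4]

    events: list[Transient] = []
    for t0, t1, pos, t_peak, peak in merged:
        duration = (t1 - t0) * frame_interval
        if duration < min_duration:
            continue
        events.append(Transient(
            time=float(t_peak * frame_interval),
            position=float(pos),
            peak_dff=peak,
            duration=float(duration),
        ))
    events.sort(key=lambda e: e.time)
    return TransientSet(events=events, f0_map=f0_map)


def average_peak(ts: TransientSet) -> PeakSummary:
    """Arithmetic mean of event peak ΔF/F0 (0 with a flag when no events)."""
    if len(ts) == 0:
        return PeakSummary(mean_peak=0.0, n_events=0, no_events=True)
    peaks = [e.peak_dff for e in ts.events]
    return PeakSummary(mean_peak=float(np.mean(peaks)), n_events=len(peaks),
                       no_events=False)


def recording_max(dff: np.ndarray) -> float:
    """Secondary summary: the single maximum ΔF/F0 of the whole recording."""
    return float(np.max(dff))


def caffeine_response(dff: np.ndarray, frame_interval: float, t_caffeine: float,
                      window: float = 10.0, k_thresh: float = 3.0
                      ) -> CaffeineResponse:
    """Whole-worm SR store-release readout after caffeine addition.

    The whole-worm trace is the spatial mean of ΔF/F0 per frame.  The worm
    is a responder when the post-addition peak exceeds the pre-addition
    baseline by ``k_thresh`` robust SD of the baseline (floored at a small
    absolute ΔF/F0 so a perfectly noiseless baseline is not trivially
    exceeded).  Latency is the first threshold crossing after addition.
    """
    trace = np.asarray(dff).mean(axis=0)
    n_t = trace.size
    times = np.arange(n_t) * frame_interval
    if not (0 < t_caffeine < times[-1]):
        raise ValueError("t_caffeine must lie inside the recording")
    pre = trace[times < t_caffeine]
    if pre.size < 2:
        raise ValueError("no pre-addition baseline frames")
    baseline = float(pre.mean())
    mad = float(np.median(np.abs(pre - np.median(pre))))
    delta = max(k_thresh * 1.4826 * mad, 0.05)
    t_end = t_caffeine + window
    if t_end > times[-1]:
        warnings.warn("response window extends past the recording; truncated")
        t_end = times[-1]
    in_win = (times >= t_caffeine) & (times <= t_end)
    post = trace[in_win]
    peak_post = float(post.max())
    crossing = np.flatnonzero(post - baseline >= delta)
    latency = float(times[in_win][crossing[0]] - t_caffeine) if crossing.size else float("nan")
    responder = peak_post - baseline >= delta
    return CaffeineResponse(baseline=baseline, peak_post=peak_post,
                            latency=latency, responder=bool(responder))
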