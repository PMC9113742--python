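"""Synthetic data generators with machine-checkable ground truth.

Every input modality of the pipeline — single-worm GCaMP fluorescence video,
Fluo-4 plate-reader leak traces, swimming bend/curl tables, survival cohorts
and immunoblot densitometry tables — can be generated here with configurable
effect sizes and noise, together with a :class:`GroundTruth` manifest that
downstream stages are tested against by parameter recovery.

The worm is rendered as a non-self-intersecting open tube around a slowly
undulating midline (a partially immobilised animal in a droplet, not a
free-swimming coiled one).  Muscle fluorescence lives in an annular band just
inside the cuticle; Ca2+ transients are localised bumps on that band, Gaussian
in perimeter position with exponential temporal decay.  Noise is additive
Gaussian by default (camera/plate-reader read noise proxy); Poisson shot noise
is available as an option but off by default so fixed seeds give bit-identical
output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import cKDTree

from .leak import LeakTrace

__all__ = [
    "WormVideoParams",
    "GroundTruth",
    "VideoStack",
    "GeometryError",
    "gen_worm_video",
    "gen_leak_trace",
    "gen_behavior_events",
    "gen_survival_cohort",
    "gen_densitometry",
    "write_video_dataset",
    "read_video_dataset",
]


class GeometryError(ValueError):
    """Raised when the requested worm geometry does not fit the image."""


@dataclass
class WormVideoParams:
    """Rendering and acquisition parameters for a synthetic worm video.

    Units: times in seconds, lengths in pixels, intensities in arbitrary
    units (AU).  ``transient_amplitude`` is the dimensionless peak ΔF/F0 of a
    Ca2+ event; ``transient_spatial_sigma`` is the Gaussian width of an event
    as a fraction of the worm perimeter.
    """

    frame_rate: float = 10.0          # frames / s
    duration: float = 20.0            # s; the assay records 20-s videos
    image_size: tuple[int, int] = (128, 400)  # (H, W) pixels
    worm_length: float = 300.0        # px
    worm_halfwidth: float = 12.0      # px
    midline_wave_amplitude: float = 15.0  # px
    midline_wave_period: float = 8.0  # s, temporal period of the undulation
    muscle_band_width: float = 5.0    # px, annulus just inside the contour
    baseline_intensity: float = 100.0  # AU, background (F_bg)
    baseline_muscle: float = 400.0    # AU, muscle band baseline (F0)
    transient_amplitude: float = 0.8  # peak ΔF/F0 of each event (A)
    transient_rate: float = 0.25      # events / s (Poisson)
    transient_decay: float = 1.0      # s, exponential decay of each event
    transient_spatial_sigma: float = 0.03  # fraction of perimeter
    noise_sd: float = 20.0            # AU, additive Gaussian
    bleach_rate: float = 0.0          # fraction / s, multiplicative on worm
    caffeine_time: float | None = None  # s, global SR-release event
    caffeine_decay: float = 3.0       # s, decay of the caffeine response
    interior_fraction: float = 0.45   # interior intensity as fraction of F0
    poisson_noise: bool = False       # shot noise option, off by default
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.transient_amplitude < 0:
            raise ValueError("transient_amplitude must be >= 0")
        if self.transient_rate < 0:
            raise ValueError("transient_rate must be >= 0")
        if self.transient_decay <= 0:
            raise ValueError("transient_decay must be > 0")
        if not (0 < self.transient_spatial_sigma < 0.5):
            raise ValueError("transient_spatial_sigma must be in (0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.worm_halfwidth <= 0 or self.worm_length <= 0:
            raise ValueError("worm dimensions must be > 0")
        if self.muscle_band_width <= 0 or self.muscle_band_width > self.worm_halfwidth:
            raise ValueError("muscle_band_width must be in (0, worm_halfwidth]")
        h, w = self.image_size
        margin = 2.0
        x_extent = self.worm_length / 2 + self.worm_halfwidth + margin
        y_extent = self.midline_wave_amplitude + self.worm_halfwidth + margin
        if 2 * x_extent >= w or 2 * y_extent >= h:
            raise GeometryError(
                f"worm (length {self.worm_length}, halfwidth {self.worm_halfwidth}, "
                f"wave amplitude {self.midline_wave_amplitude}) does not fit inside "
                f"a {h}x{w} image"
            )


@dataclass
class GroundTruth:
    """Scripted truth for one synthetic dataset.

    ``event_times`` / ``event_positions`` / ``event_amplitudes`` describe the
    scripted Ca2+ transients (positions are perimeter fractions in [0, 1) on
    the stored true contours).  ``true_contours`` holds one (K, 2) array of
    (row, col) points per frame.  Scalar truths of the non-video modalities
    live in ``scalars``.
    """

    event_times: list[float] = field(default_factory=list)
    event_positions: list[float] = field(default_factory=list)
    event_amplitudes: list[float] = field(default_factory=list)
    true_contours: list[np.ndarray] = field(default_factory=list)
    perimeters: list[float] = field(default_factory=list)
    scalars: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.event_times)
        if not (len(self.event_positions) == len(self.event_amplitudes) == n):
            raise ValueError("event list lengths must agree")

    def to_json(self, path: str | Path, include_contours: bool = True) -> None:
        payload = {
            "event_times": list(map(float, self.event_times)),
            "event_positions": list(map(float, self.event_positions)),
            "event_amplitudes": list(map(float, self.event_amplitudes)),
            "perimeters": list(map(float, self.perimeters)),
            "scalars": self.scalars,
        }
        if include_contours:
            payload["true_contours"] = [c.tolist() for c in self.true_contours]
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            event_times=payload.get("event_times", []),
            event_positions=payload.get("event_positions", []),
            event_amplitudes=payload.get("event_amplitudes", []),
            true_contours=[np.asarray(c, float) for c in payload.get("true_contours", [])],
            perimeters=payload.get("perimeters", []),
            scalars=payload.get("scalars", {}),
        )


@dataclass
class VideoStack:
    """A frames x H x W intensity grid with its frame interval (s)."""

    frames: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (T, H, W) array")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def to_tiff(self, path: str | Path) -> None:
        """Write as multi-page 16-bit grayscale TIFF (values clipped/rounded)."""
        data = np.clip(np.round(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(str(path), data, metadata={"frame_interval_s": self.frame_interval})

    @classmethod
    def from_tiff(cls, path: str | Path, frame_interval: float) -> "VideoStack":
        return cls(tifffile.imread(str(path)).astype(float), frame_interval)


# ---------------------------------------------------------------------------
# worm geometry


def _midline(params: WormVideoParams, t: float) -> np.ndarray:
    """Midline points (row, col) at ~1 px spacing for frame time t."""
    h, w = params.image_size
    cy, cx = h / 2.0, w / 2.0
    n = int(np.ceil(params.worm_length)) + 1
    xs = cx - params.worm_length / 2 + np.linspace(0, params.worm_length, n)
    phase = 2 * np.pi * ((xs - xs[0]) / params.worm_length - t / params.midline_wave_period)
    ys = cy + params.midline_wave_amplitude * np.sin(phase)
    return np.column_stack([ys, xs])


def true_contour(params: WormVideoParams, t: float) -> np.ndarray:
    """Analytic outline of the worm tube at frame time t.

    Returns an ordered, closed (first point not repeated) list of (row, col)
    points with positive signed area in (x=col, y=row) convention, i.e. the
    same traversal direction the segmentation stage produces.
    """
    mid = _midline(params, t)
    d = np.gradient(mid, axis=0)
    tang = d / np.linalg.norm(d, axis=1, keepdims=True)
    # normal to tangent (rotate +90 deg in (x=col, y=row) plane)
    normal = np.column_stack([tang[:, 1], -tang[:, 0]])
    hw = params.worm_halfwidth
    top = mid + hw * normal
    bottom = mid - hw * normal

    def cap(center: np.ndarray, n_from: np.ndarray, outward: np.ndarray) -> np.ndarray:
        """Semicircle of radius hw from n_from to -n_from bulging along `outward`."""
        a0 = np.arctan2(n_from[0], n_from[1])
        k = max(8, int(np.pi * hw))
        for sign in (1.0, -1.0):
            angles = np.linspace(a0, a0 + sign * np.pi, k + 2)[1:-1]
            mid_dir = np.array([np.sin(angles[k // 2]), np.cos(angles[k // 2])])
            if np.dot(mid_dir, outward) > 0:
                return center + hw * np.column_stack([np.sin(angles), np.cos(angles)])
        raise AssertionError("unreachable")

    tail_arc = cap(mid[-1], normal[-1], tang[-1])
    head_arc = cap(mid[0], -normal[0], -tang[0])
    pts = np.vstack([top, tail_arc, bottom[::-1], head_arc])
    # enforce positive signed area in (x=col, y=row)
    x, y = pts[:, 1], pts[:, 0]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area < 0:
        pts = pts[::-1]
    return pts


def _arc_lengths(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Cumulative arc length at each point of a closed polyline, and total."""
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    return cum, float(seg.sum())


# ---------------------------------------------------------------------------
# video generator


def gen_worm_video(params: WormVideoParams) -> tuple[VideoStack, GroundTruth]:
    """Render a synthetic single-worm GCaMP video with scripted transients.

    Deterministic for a fixed seed.  The muscle band (annulus of
    ``muscle_band_width`` just inside the contour) sits at ``baseline_muscle``
    (F0); transients occur at Poisson times with rate ``transient_rate``, each
    a perimeter-Gaussian bump of amplitude ``transient_amplitude * F0`` with
    exponential decay.  If ``caffeine_time`` is set, a band-wide step-and-decay
    event is added at that time.  Worm fluorescence bleaches as
    ``exp(-bleach_rate * t)``; background does not.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    n_frames = int(round(params.duration * params.frame_rate))
    dt = 1.0 / params.frame_rate

    n_events = rng.poisson(params.transient_rate * params.duration)
    ev_times = np.sort(rng.uniform(0, params.duration, n_events))
    ev_pos = rng.uniform(0, 1, n_events)
    ev_amp = np.full(n_events, params.transient_amplitude)

    f_bg = params.baseline_intensity
    f0 = params.baseline_muscle
    interior = params.interior_fraction * f0
    hw_ = params.worm_halfwidth
    band_w = params.muscle_band_width

    frames = np.empty((n_frames, h, w))
    contours: list[np.ndarray] = []
    perimeters: list[float] = []

    # candidate pixel window around the worm (worm geometry is translation
    # invariant in time apart from the vertical wave, so one box serves all
    # frames)
    cy, cx = h / 2.0, w / 2.0
    pad = 3.0
    r0 = max(0, int(np.floor(cy - params.midline_wave_amplitude - hw_ - pad)))
    r1 = min(h, int(np.ceil(cy + params.midline_wave_amplitude + hw_ + pad)))
    c0 = max(0, int(np.floor(cx - params.worm_length / 2 - hw_ - pad)))
    c1 = min(w, int(np.ceil(cx + params.worm_length / 2 + hw_ + pad)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    grid_pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    for k in range(n_frames):
        t = k * dt
        mid = _midline(params, t)
        contour = true_contour(params, t)
        contours.append(contour)
        arcs, perim = _arc_lengths(contour)
        perimeters.append(perim)

        dist = cKDTree(mid).query(grid_pts, workers=-1)[0]
        frame = np.full((h, w), f_bg)
        sub = np.full(grid_pts.shape[0], f_bg)
        body = dist <= hw_
        band = body & (dist > hw_ - band_w)
        inner = body & ~band
        sub[inner] = interior
        band_vals = np.full(band.sum(), f0)

        if n_events or params.caffeine_time is not None:
            # perimeter coordinate of each band pixel via nearest contour point
            idx = cKDTree(contour).query(grid_pts[band], workers=-1)[1]
            s_pix = arcs[idx]
            sigma_s = params.transient_spatial_sigma * perim
            for te, ue, ae in zip(ev_times, ev_pos, ev_amp):
                if te <= t:
                    ds = np.abs(s_pix - ue * perim)
                    ds = np.minimum(ds, perim - ds)
                    band_vals += (
                        ae * f0 * np.exp(-((ds / sigma_s) ** 2) / 2)
                        * np.exp(-(t - te) / params.transient_decay)
                    )
            if params.caffeine_time is not None and t >= params.caffeine_time:
                band_vals += (
                    params.transient_amplitude * f0
                    * np.exp(-(t - params.caffeine_time) / params.caffeine_decay)
                )
        sub[band] = band_vals

        if params.bleach_rate:
            bleach = np.exp(-params.bleach_rate * t)
            sub[body] *= bleach
        frame[r0:r1, c0:c1] = sub.reshape(rr.shape)
        frames[k] = frame

    if params.poisson_noise:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    if params.noise_sd > 0:
        frames += rng.normal(0.0, params.noise_sd, frames.shape)
        np.clip(frames, 0, None, out=frames)

    video = VideoStack(frames, dt)
    gt = GroundTruth(
        event_times=list(map(float, ev_times)),
        event_positions=list(map(float, ev_pos)),
        event_amplitudes=list(map(float, ev_amp)),
        true_contours=contours,
        perimeters=perimeters,
        scalars={
            "transient_amplitude": params.transient_amplitude,
            "caffeine_time": params.caffeine_time,
            "f0": f0,
            "f_bg": f_bg,
            "bleach_rate": params.bleach_rate,
        },
    )
    return video, gt


def write_video_dataset(video: VideoStack, gt: GroundTruth, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tif`` and its ground-truth manifest ``<prefix>.json``."""
    prefix = Path(prefix)
    tif = prefix.with_suffix(".tif")
    manifest = prefix.with_suffix(".json")
    video.to_tiff(tif)
    gt.to_json(manifest)
    return tif, manifest


def read_video_dataset(prefix: str | Path, frame_interval: float) -> tuple[VideoStack, GroundTruth]:
    prefix = Path(prefix)
    return (
        VideoStack.from_tiff(prefix.with_suffix(".tif"), frame_interval),
        GroundTruth.from_json(prefix.with_suffix(".json")),
    )


# ---------------------------------------------------------------------------
# plate-reader leak traces


def gen_leak_trace(
    baseline: float = 1000.0,
    k_up: float = 0.05,
    plateau: float = 400.0,
    s_leak: float = 2.0,
    t_atp: float = 60.0,
    t_tg: float = 240.0,
    duration: float = 420.0,
    noise_sd: float = 0.0,
    sample_rate: float = 1.0,
    seed: int = 0,
) -> tuple[LeakTrace, GroundTruth]:
    """Piecewise Fluo-4 trace of a microsome uptake/leak experiment.

    Flat ``baseline`` before ATP addition at ``t_atp``; exponential approach
    to ``plateau`` with rate ``k_up`` while SERCA pumps Ca2+ into the
    microsomes; linear rise of slope ``s_leak`` after thapsigargin blocks
    re-uptake at ``t_tg``, exposing the passive channel leak.
    """
    if not (0 < t_atp < t_tg < duration):
        raise ValueError("phase times must satisfy 0 < t_atp < t_tg < duration")
    if plateau >= baseline:
        raise ValueError("plateau must be below baseline (uptake lowers the signal)")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration, 1.0 / sample_rate)
    f = np.full_like(times, baseline)
    up = (times >= t_atp) & (times < t_tg)
    f[up] = plateau + (baseline - plateau) * np.exp(-k_up * (times[up] - t_atp))
    post = times >= t_tg
    f_at_tg = plateau + (baseline - plateau) * np.exp(-k_up * (t_tg - t_atp))
    f[post] = f_at_tg + s_leak * (times[post] - t_tg)
    if noise_sd > 0:
        f = f + rng.normal(0, noise_sd, f.shape)
    trace = LeakTrace(times=times, fluorescence=f, t_atp=t_atp, t_tg=t_tg)
    gt = GroundTruth(scalars={
        "baseline": baseline,
        "k_up": k_up,
        "plateau": plateau,
        "s_leak": s_leak,
        "t_plateau": min(t_atp + np.log(100.0) / k_up, t_tg) if k_up > 0 else t_tg,
        "normalized_leak": s_leak / (baseline - plateau),
    })
    return trace, gt


# ---------------------------------------------------------------------------
# behaviour, survival, densitometry tables


def gen_behavior_events(
    bend_rate: float = 60.0,
    curl_prob: float = 0.1,
    minutes: float = 1.0,
    n_worms: int = 60,
    group: str = "WT",
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-worm swimming bend/curl counts over a scoring window.

    Bends are Poisson(bend_rate * minutes); each bend independently curls
    with probability ``curl_prob`` (curls ~ Binomial(bends, curl_prob)).
    Defaults follow the assay: 1-min scoring windows, ~60 worms per group.
    """
    if bend_rate < 0:
        raise ValueError("bend_rate must be >= 0")
    if not (0 <= curl_prob <= 1):
        raise ValueError("curl_prob must be in [0, 1]")
    if minutes <= 0:
        raise ValueError("minutes must be > 0")
    rng = np.random.default_rng(seed)
    bends = rng.poisson(bend_rate * minutes, n_worms)
    curls = rng.binomial(bends, curl_prob)
    df = pd.DataFrame({
        "worm_id": [f"{group}_{i:03d}" for i in range(n_worms)],
        "group": group,
        "bends": bends,
        "curls": curls,
        "minutes": minutes,
    })
    gt = GroundTruth(scalars={"bend_rate": bend_rate, "curl_prob": curl_prob})
    return df, gt


def gen_survival_cohort(
    shape: float = 4.0,
    scale: float = 20.0,
    n: int = 60,
    censor_day: int | None = None,
    group: str = "WT",
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Weibull lifespans rounded up to whole days (>= 1), with censoring.

    Defaults (shape 4, scale 20 d) give a mean lifespan of ~18 days, the
    wild-type value of the lifespan assay.  Records alive past
    ``censor_day`` are recorded at that day and flagged censored.
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("Weibull shape and scale must be > 0")
    if n < 2:
        raise ValueError("need n >= 2 records to form a survival curve")
    rng = np.random.default_rng(seed)
    life = scale * rng.weibull(shape, n)
    days = np.maximum(np.ceil(life), 1).astype(int)
    censored = np.zeros(n, dtype=bool)
    if censor_day is not None:
        late = days > censor_day
        days = np.where(late, censor_day, days)
        censored = late
    df = pd.DataFrame({
        "worm_id": [f"{group}_{i:03d}" for i in range(n)],
        "group": group,
        "day": days,
        "censored": censored,
    })
    gt = GroundTruth(scalars={
        "shape": shape,
        "scale": scale,
        "mean_lifespan": scale * math.gamma(1 + 1 / shape),
    })
    return df, gt


def gen_densitometry(
    group_means: dict[str, float] | None = None,
    cv: float = 0.15,
    reps: int = 3,
    target: str = "FKB-2",
    unc68_intensity: float = 100.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Immunoblot band tables: lognormal replicate ratios around group means.

    Each replicate's complex-member band is expressed relative to its
    corresponding UNC-68 band; replicates are lognormal with coefficient of
    variation ``cv`` around the group mean ratio.  ``reps=3`` mirrors
    triplicate blots.
    """
    if group_means is None:
        group_means = {"WT": 1.0, "KO": 0.3}
    if any(m <= 0 for m in group_means.values()):
        raise ValueError("group means must be > 0")
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for grp, mean in group_means.items():
        if cv > 0:
            sigma2 = np.log1p(cv**2)
            mu = np.log(mean) - sigma2 / 2
            ratios = rng.lognormal(mu, np.sqrt(sigma2), reps)
        else:
            ratios = np.full(reps, mean)
        for i, r in enumerate(ratios):
            rows.append({
                "sample_id": f"{grp}_{target}_{i}",
                "group": grp,
                "target": target,
                "intensity": r * unc68_intensity,
                "unc68_intensity": unc68_intensity,
            })
    df = pd.DataFrame(rows)
    gt = GroundTruth(scalars={"group_means": group_means, "cv": cv})
    return df, gt
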