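"""Microsome Ca2+ uptake/leak kinetics from Fluo-4 plate-reader traces.

A leak-assay trace has four phases: a flat dye baseline, ATP-initiated SERCA
uptake (exponential decay of the cytosolic-side signal towards a loaded
plateau), the plateau itself, and — after thapsigargin blocks re-uptake — a
rise whose slope is proportional to the passive Ca2+ leak through the release
channel.  This module segments those phases, fits the uptake rate ``k_up``
and the leak slope ``s_leak``, and normalises the slope by the uptake depth
``(F_b - plateau)`` so traces from different microsome loads are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LeakTrace",
    "PhaseBoundaries",
    "LeakFit",
    "segment_phases",
    "fit_leak",
    "compare_leak",
    "read_leak_csv",
]


@dataclass
class LeakTrace:
    """Annotated fluorescence time series of one well.

    ``t_atp`` and ``t_tg`` are the experimenter-recorded addition times of
    ATP (starts uptake) and thapsigargin (blocks SERCA, exposes leak).
    """

    times: np.ndarray
    fluorescence: np.ndarray
    t_atp: float
    t_tg: float
    phase_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.t_atp is None or self.t_tg is None:
            raise ValueError("trace must be annotated with t_atp and t_tg")
        if not (self.times[0] <= self.t_atp < self.t_tg <= self.times[-1]):
            raise ValueError("phase times must satisfy t0 <= t_atp < t_tg <= t_end")


@dataclass
class PhaseBoundaries:
    """Sample-index boundaries of the four phases of a leak trace."""

    i_atp: int       # first sample of the uptake phase
    i_plateau: int   # first sample of the plateau phase
    i_tg: int        # first sample of the leak phase
    plateau_reached: bool = True


@dataclass
class LeakFit:
    """Fitted kinetic parameters of one leak trace."""

    baseline: float          # F_b, AU
    k_up: float              # 1/s
    plateau: float           # AU
    s_leak: float            # AU/s
    normalized_leak: float   # 1/s, s_leak / (F_b - plateau)
    residual_rms: float
    endpoint_delta: float    # F(end) - F(t_tg), a model-free leak readout

    def __post_init__(self) -> None:
        if self.baseline <= self.plateau:
            raise ValueError("fit violates F_b > plateau")
        if self.k_up < 0:
            raise ValueError("k_up must be >= 0")
        if not np.isfinite(self.normalized_leak):
            raise ValueError("normalized_leak must be finite")


def segment_phases(trace: LeakTrace, settle: float = 10.0,
                   tol_frac: float = 0.01) -> PhaseBoundaries:
    """Locate the phase boundaries of an annotated leak trace.

    The plateau onset is the first time after ATP addition where the
    magnitude of the windowed slope stays below ``tol_frac`` times the peak
    uptake slope for at least ``settle`` seconds.  If the signal never
    settles before thapsigargin, a warning is issued and the last pre-Tg
    window is used as the plateau.
    """
    t, f = trace.times, trace.fluorescence
    i_atp = int(np.searchsorted(t, trace.t_atp))
    i_tg = int(np.searchsorted(t, trace.t_tg))
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(settle / dt)))

    seg = slice(i_atp, i_tg)
    fs = f[seg]
    if fs.size < w + 2:
        warnings.warn("uptake phase too short to detect a plateau; using last window")
        return PhaseBoundaries(i_atp, max(i_atp, i_tg - max(2, w)), i_tg, False)
    # slope over a settle-long window: robust to noise, scale cancels in the
    # relative threshold
    slopes = (fs[w:] - fs[:-w]) / (t[seg][w:] - t[seg][:-w])
    thresh = tol_frac * np.max(np.abs(slopes))
    settled = np.abs(slopes) < thresh
    idx = np.flatnonzero(settled)
    if idx.size == 0:
        warnings.warn("plateau never reached before thapsigargin; using last pre-Tg window")
        return PhaseBoundaries(i_atp, max(i_atp, i_tg - w), i_tg, False)
    i_plateau = i_atp + int(idx[0])
    return PhaseBoundaries(i_atp, i_plateau, i_tg, True)


def _uptake_model(t: np.ndarray, plateau: float, depth: float, k: float) -> np.ndarray:
    return plateau + depth * np.exp(-k * t)


def fit_leak(trace: LeakTrace, phases: PhaseBoundaries | None = None) -> LeakFit:
    """Fit baseline, uptake kinetics and post-thapsigargin leak slope.

    ``F_b`` is the pre-ATP mean; ``(k_up, plateau)`` come from a
    least-squares exponential fit of the uptake phase; ``s_leak`` is the
    least-squares line slope of the leak phase.
    """
    if phases is None:
        phases = segment_phases(trace)
    t, f = trace.times, trace.fluorescence
    base = f[: phases.i_atp]
    up_t = t[phases.i_atp: phases.i_tg] - t[phases.i_atp]
    up_f = f[phases.i_atp: phases.i_tg]
    leak_t = t[phases.i_tg:]
    leak_f = f[phases.i_tg:]
    if base.size < 3 or up_t.size < 3 or leak_t.size < 3:
        raise ValueError("each phase needs at least 3 samples to fit")

    f_b = float(base.mean())
    p0 = (float(up_f[-1]), float(up_f[0] - up_f[-1]), max(1.0 / max(up_t[-1], 1e-9), 1e-4))
    popt, _ = curve_fit(_uptake_model, up_t, up_f, p0=p0, maxfev=10000)
    plateau, depth, k_up = (float(v) for v in popt)
    k_up = abs(k_up)

    s_leak, intercept = np.polyfit(leak_t - leak_t[0], leak_f, 1)
    s_leak = float(s_leak)

    pred_up = _uptake_model(up_t, plateau, depth, k_up)
    pred_leak = intercept + s_leak * (leak_t - leak_t[0])
    resid = np.concatenate([base - f_b, up_f - pred_up, leak_f - pred_leak])
    depth_bp = f_b - plateau
    if depth_bp <= 0:
        raise ValueError("fitted plateau is not below baseline; not an uptake trace")
    return LeakFit(
        baseline=f_b,
        k_up=k_up,
        plateau=plateau,
        s_leak=s_leak,
        normalized_leak=s_leak / depth_bp,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        endpoint_delta=float(leak_f[-1] - leak_f[0]),
    )


def compare_leak(fits_a: list[LeakFit], fits_b: list[LeakFit]) -> dict:
    """Difference in mean normalised leak between two groups, with a t test."""
    from .stats import t_test

    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("need at least 2 fits per group")
    a = np.array([f.normalized_leak for f in fits_a])
    b = np.array([f.normalized_leak for f in fits_b])
    tstat, p = t_test(a, b)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "difference": float(a.mean() - b.mean()),
        "t": tstat,
        "p_value": p,
    }


def read_leak_csv(csv_path: str | Path, additions: dict | str | Path) -> list[tuple[str, str, LeakTrace]]:
    """Read (time, fluorescence, well, group) CSV plus addition-time sidecar.

    ``additions`` is a mapping (or JSON file) with keys ``t_atp`` and
    ``t_tg``, optionally per-well.  Returns (well, group, trace) triples.
    """
    import json

    df = pd.read_csv(csv_path)
    required = {"time", "fluorescence", "well"}
    if not required.issubset(df.columns):
        raise ValueError(f"leak CSV needs columns {sorted(required)}")
    if not isinstance(additions, dict):
        additions = json.loads(Path(additions).read_text())
    out = []
    for well, sub in df.groupby("well", sort=True):
        times = additions.get(str(well), additions)
        group = str(sub["group"].iloc[0]) if "group" in sub else ""
        out.append((
            str(well),
            group,
            LeakTrace(
                times=sub["time"].to_numpy(),
                fluorescence=sub["fluorescence"].to_numpy(),
                t_atp=float(times["t_atp"]),
                t_tg=float(times["t_tg"]),
            ),
        ))
    return out
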