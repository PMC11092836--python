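"""Functional clearance metrics from particle tracks and intensity movies.

Implements the output side of the structure-function analysis:

* a temporally averaged Eulerian flow field from particle trajectories;
* clearance directionality ``D(R) = |<v>| / <|v|>`` over square windows of
  side R, its exponential correlation length R0 and the multi-cell summary
  DR80 = D(R = 80 um);
* clearance speed and clearance per beat (CPB = speed / CBF);
* ciliary beat frequency from pixel-wise Fourier analysis of high-speed
  intensity movies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "EulerianFlow",
    "DirectionalityCurve",
    "ClearanceSummary",
    "read_tracks",
    "track_velocities",
    "eulerian_average",
    "directionality_curve",
    "fit_correlation_length",
    "bootstrap_r0",
    "directionality_at",
    "clearance_speed",
    "compute_cpb",
    "estimate_cbf",
]

TRACK_COLUMNS = ("TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y")


@dataclass
class EulerianFlow:
    """Per-bin mean velocity estimated from all trajectories passing through."""

    u: np.ndarray         # (ny, nx) mean x-velocity; NaN where no data
    v: np.ndarray
    counts: np.ndarray    # (ny, nx) number of velocity samples per bin
    bin_size: float       # um
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


@dataclass
class DirectionalityCurve:
    """D(R) with the per-window samples needed for bootstrap statistics."""

    R_um: np.ndarray
    D: np.ndarray
    window_values: list = field(default_factory=list)  # per R: array of window D
    r0_um: float | None = None
    fit_r2: float | None = None
    fit_accepted: bool | None = None
    dr80: float | None = None
    r0_bootstrap: np.ndarray | None = None


@dataclass
class ClearanceSummary:
    """Per-condition functional summary."""

    clearance_speed_um_s: float | None
    cbf_hz: float | None
    cpb_um_beat: float | None
    dr80: float | None = None
    r0_um: float | None = None
    provenance: dict = field(default_factory=dict)


def read_tracks(path) -> pd.DataFrame:
    """Read a TrackMate-style track table (CSV with TRACK_ID/FRAME/POSITION_*).

    Non-numeric header repetition rows (as exported by TrackMate 7) are
    dropped; positions are returned as floats in the units of the file.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table lacks columns: {missing}")
    df = df[list(TRACK_COLUMNS)].apply(pd.to_numeric, errors="coerce").dropna()
    df = df.astype({"TRACK_ID": int, "FRAME": int})
    return df.sort_values(["TRACK_ID", "FRAME"], ignore_index=True)


def track_velocities(tracks: pd.DataFrame, frame_interval: float = 1.0) -> pd.DataFrame:
    """Forward-difference velocities per track step.

    Returns a frame with columns x, y (segment start position) and u, v in
    um per ``frame_interval`` time unit.  Steps across frame gaps use the
    actual frame difference.
    """
    rows = []
    for _, g in tracks.groupby("TRACK_ID", sort=False):
        if len(g) < 2:
            continue
        x = g["POSITION_X"].to_numpy()
        y = g["POSITION_Y"].to_numpy()
        f = g["FRAME"].to_numpy()
        df = np.diff(f) * frame_interval
        ok = df > 0
        rows.append(
            pd.DataFrame(
                {
                    "x": x[:-1][ok],
                    "y": y[:-1][ok],
                    "u": np.diff(x)[ok] / df[ok],
                    "v": np.diff(y)[ok] / df[ok],
                }
            )
        )
    if not rows:
        raise ValueError("no track has two or more frames; cannot form velocities")
    return pd.concat(rows, ignore_index=True)


def eulerian_average(
    tracks: pd.DataFrame,
    bin_size: float = 2.0,
    frame_interval: float = 1.0,
    extent: tuple[float, float] | None = None,
) -> EulerianFlow:
    """Temporally averaged Eulerian flow field from trajectories.

    Each finite-difference velocity is assigned to the spatial bin of its
    segment start; the per-bin mean over all passages through that bin is
    the field estimate.  Bins never visited are NaN and flagged by counts=0.
    """
    vel = track_velocities(tracks, frame_interval=frame_interval)
    x0 = 0.0 if extent is not None else float(vel["x"].min())
    y0 = 0.0 if extent is not None else float(vel["y"].min())
    if extent is not None:
        Lx, Ly = extent
    else:
        Lx = float(vel["x"].max()) - x0 + 1e-9
        Ly = float(vel["y"].max()) - y0 + 1e-9
    nx = max(1, int(np.ceil(Lx / bin_size)))
    ny = max(1, int(np.ceil(Ly / bin_size)))
    ix = np.clip(((vel["x"] - x0) / bin_size).astype(int), 0, nx - 1)
    iy = np.clip(((vel["y"] - y0) / bin_size).astype(int), 0, ny - 1)
    flat = iy * nx + ix
    counts = np.bincount(flat, minlength=nx * ny).astype(float)
    su = np.bincount(flat, weights=vel["u"], minlength=nx * ny)
    sv = np.bincount(flat, weights=vel["v"], minlength=nx * ny)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (su / counts).reshape(ny, nx)
        v = (sv / counts).reshape(ny, nx)
    return EulerianFlow(
        u=u, v=v, counts=counts.reshape(ny, nx), bin_size=bin_size, origin=(x0, y0)
    )


def _window_directionality(u, v, occ, min_occupancy=0.5):
    """D of one window: |mean v| / mean |v| over occupied bins."""
    if occ.mean() < min_occupancy:
        return np.nan
    uu = u[occ]
    vv = v[occ]
    mag = np.hypot(uu, vv)
    denom = mag.mean()
    if denom == 0:
        return np.nan
    return float(np.hypot(uu.mean(), vv.mean()) / denom)


def directionality_curve(
    flow: EulerianFlow,
    R_um: np.ndarray | None = None,
    min_occupancy: float = 0.5,
) -> DirectionalityCurve:
    """Clearance directionality D(R) over square windows tiled across the field.

    For each window side R the field is tiled with non-overlapping windows
    (plus one centred window); windows with less than ``min_occupancy``
    occupied bins are skipped and D(R) is the mean over the rest.
    """
    ny, nx = flow.u.shape
    if not flow.occupied.any():
        raise ValueError("flow field has no occupied bins")
    if R_um is None:
        rmax = min(nx, ny) * flow.bin_size
        R_um = np.arange(2 * flow.bin_size, rmax + 1e-9, 2 * flow.bin_size)
    R_um = np.asarray(R_um, dtype=float)
    if np.any(R_um < flow.bin_size):
        raise ValueError("window side must be at least one bin")
    occ = flow.occupied
    D = np.full(R_um.size, np.nan)
    window_values = []
    for k, R in enumerate(R_um):
        w = max(1, int(round(R / flow.bin_size)))
        vals = []
        for j0 in range(0, ny - w + 1, w):
            for i0 in range(0, nx - w + 1, w):
                vals.append(
                    _window_directionality(
                        flow.u[j0:j0 + w, i0:i0 + w],
                        flow.v[j0:j0 + w, i0:i0 + w],
                        occ[j0:j0 + w, i0:i0 + w],
                        min_occupancy,
                    )
                )
        # centred window, useful when w does not tile the field evenly
        jc, ic = (ny - w) // 2, (nx - w) // 2
        if jc >= 0 and ic >= 0:
            vals.append(
                _window_directionality(
                    flow.u[jc:jc + w, ic:ic + w],
                    flow.v[jc:jc + w, ic:ic + w],
                    occ[jc:jc + w, ic:ic + w],
                    min_occupancy,
                )
            )
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        window_values.append(vals)
        if vals.size:
            D[k] = vals.mean()
    keep = np.isfinite(D)
    curve = DirectionalityCurve(
        R_um=R_um[keep],
        D=D[keep],
        window_values=[wv for wv, k in zip(window_values, keep) if k],
    )
    if curve.R_um.size >= 4:
        fit_correlation_length(curve)
    if curve.R_um.size:
        curve.dr80 = directionality_at(curve, 80.0)
    return curve


def fit_correlation_length(
    curve: DirectionalityCurve,
    r2_threshold: float = 0.8,
) -> tuple[float | None, float, bool]:
    """Exponential fit of the D(R) trace with offset normalization.

    The trace is fitted with ``a exp(-R/R0) + c`` by least squares; the
    plateau offset ``c`` absorbs the long-range directionality floor so the
    decay length is not biased by it.  Fits with coefficient of
    determination at or below ``r2_threshold`` are rejected (accepted=False);
    a non-decaying trace is likewise rejected rather than raising.
    """
    if curve.R_um.size < 4:
        raise ValueError("need at least 4 points to fit D(R)")
    R = curve.R_um
    y = curve.D

    def model(r, r0, a, c):
        return a * np.exp(-r / r0) + c

    span = float(np.max(y) - np.min(y))
    try:
        if span <= 1e-12:
            raise RuntimeError("flat trace")
        popt, _ = curve_fit(
            model,
            R,
            y,
            p0=[max(R.mean() / 2, 1.0), span, float(np.min(y))],
            bounds=([1e-6, 0.0, -1.0], [np.inf, 2.0, 1.0]),
            maxfev=5000,
        )
        r0 = float(popt[0])
        pred = model(R, *popt)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        accepted = bool(r2 > r2_threshold and r0 > 0)
    except RuntimeError:
        r0, r2, accepted = None, 0.0, False
    curve.r0_um = r0 if accepted else None
    curve.fit_r2 = r2
    curve.fit_accepted = accepted
    return curve.r0_um, r2, accepted


def bootstrap_r0(
    curve: DirectionalityCurve,
    n_boot: int = 1000,
    seed: int = 0,
    r2_threshold: float = 0.8,
) -> np.ndarray:
    """Bootstrap R0 by resampling the windows behind each D(R) point."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_boot):
        D = np.array(
            [
                wv[rng.integers(0, wv.size, wv.size)].mean() if wv.size else np.nan
                for wv in curve.window_values
            ]
        )
        ok = np.isfinite(D)
        if ok.sum() < 4:
            continue
        boot = DirectionalityCurve(R_um=curve.R_um[ok], D=D[ok])
        r0, _, accepted = fit_correlation_length(boot, r2_threshold)
        if accepted and r0 is not None:
            out.append(r0)
    curve.r0_bootstrap = np.asarray(out)
    return curve.r0_bootstrap


def directionality_at(curve: DirectionalityCurve, R: float = 80.0) -> float:
    """D(R) at the requested window size, interpolating between samples.

    Outside the sampled support the nearest available window size is used.
    """
    if curve.R_um.size == 0:
        raise ValueError("empty directionality curve")
    return float(np.interp(R, curve.R_um, curve.D))


def clearance_speed(tracks: pd.DataFrame, frame_interval: float) -> float:
    """Mean frame-to-frame particle speed in um per second."""
    if frame_interval is None or frame_interval <= 0:
        raise ValueError("frame_interval (seconds per frame) is required")
    vel = track_velocities(tracks, frame_interval=frame_interval)
    return float(np.hypot(vel["u"], vel["v"]).mean())


def compute_cpb(speed, cbf) -> float:
    """Clearance per beat: clearance speed divided by beat frequency.

    Accepts paired per-FOV arrays (ratio computed per FOV, then averaged) or
    scalar means recorded separately (single ratio of means).
    """
    speed = np.asarray(speed, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    if np.any(cbf <= 0):
        raise ValueError("beat frequency must be positive")
    if speed.shape != cbf.shape:
        raise ValueError("speed and cbf must have matching shapes")
    return float(np.mean(speed / cbf))


def estimate_cbf(
    movie: np.ndarray,
    fps: float,
    band: tuple[float, float] | None = None,
    variance_factor: float = 2.0,
) -> tuple[np.ndarray, float]:
    """Ciliary beat frequency by pixel-wise Fourier spectral analysis.

    Every cilia-associated pixel (temporal standard deviation above
    ``variance_factor`` times the median pixel std) contributes the dominant
    frequency of its intensity spectrum within ``band`` (default 0.5 Hz to
    Nyquist).  Returns the per-pixel CBF map (NaN off-cilia) and the mean
    over selected pixels.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, height, width)")
    n_frames = movie.shape[0]
    if n_frames < 64:
        raise ValueError("need at least 64 frames for spectral CBF")
    if band is None:
        band = (0.5, fps / 2)
    if band[1] > fps / 2 + 1e-9:
        raise ValueError("band exceeds the Nyquist frequency")

    std = movie.std(axis=0)
    # absolute floor guards against an entirely static movie, where the
    # median std is numerical noise and a relative rule would select pixels
    floor = 1e-9 * (np.ptp(movie) + 1e-30)
    thresh = max(variance_factor * np.median(std), floor)
    sel = std > thresh
    if not sel.any():
        raise ValueError("no pixel passes the temporal-variance threshold (no ciliary signal)")

    sig = movie[:, sel] - movie[:, sel].mean(axis=0)
    freqs = np.fft.rfftfreq(n_frames, d=1.0 / fps)
    spec = np.abs(np.fft.rfft(sig, axis=0))
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError("frequency band contains no spectral bins")
    peak = np.argmax(spec[in_band], axis=0)
    cbf_vals = freqs[in_band][peak]
    cbf_map = np.full(movie.shape[1:], np.nan)
    cbf_map[sel] = cbf_vals
    return cbf_map, float(cbf_vals.mean())
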