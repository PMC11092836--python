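"""Synthetic fixtures with known ground truth for every pipeline input.

Each generator returns the fixture plus a ``GroundTruth`` record of the
generating parameters, so parameter-recovery tests can close the loop:
masks with known gap wavelength and coverage, track tables from known flow
fields and diffusivities, intensity movies with known beat frequencies, and
cell-composition tables with a known linear relation to directionality.

Parameter defaults sit in the operating regime of airway epithelia:
gap wavelengths 13-28 um, cilia lengths 5-8 um, beat amplitudes 7-13 um,
coverages 20-95%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epithelium import EpitheliumSpec, generate_epithelium, rasterize_mask
from .pattern_metrics import CiliationMask

__all__ = [
    "GroundTruth",
    "synth_ciliation_mask",
    "synth_tracks",
    "synth_cbf_movie",
    "synth_composition_dataset",
]


@dataclass
class GroundTruth:
    """Generating parameters attached to a synthetic fixture."""

    kind: str
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"kind": self.kind, **self.params}


def synth_ciliation_mask(
    gap_wavelength: float = 25.0,
    coverage: float = 0.5,
    jitter: float = 1.0,
    pixel_size: float = 1.0,
    seed: int = 0,
    n_rows: int = 51,
    n_cols: int = 51,
) -> tuple[CiliationMask, GroundTruth]:
    """Binary ciliation mask from the epithelium generator, truth attached."""
    spec = EpitheliumSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        coverage=coverage,
        gap_wavelength_mean=gap_wavelength,
        gap_wavelength_std=0.0,
        center_jitter_std=jitter,
        beat_order_target=0.9,
        seed=seed,
    )
    cells = generate_epithelium(spec)
    mask = rasterize_mask(cells, pixel_size=pixel_size)
    truth = GroundTruth(
        "ciliation_mask",
        {
            "gap_wavelength_um": gap_wavelength,
            "coverage": coverage,
            "jitter_um": jitter,
            "pixel_size_um": pixel_size,
            "seed": seed,
        },
    )
    return mask, truth


def _analytic_field(model: str, speed: float, extent: float):
    if model == "uniform":
        return lambda p: np.column_stack([np.full(p.shape[0], speed), np.zeros(p.shape[0])])
    if model == "vortex":
        c = extent / 2.0

        def vortex(p):
            dx = p[:, 0] - c
            dy = p[:, 1] - c
            r = np.hypot(dx, dy)
            scale = speed * np.exp(0.5) * (r / (extent / 4)) * np.exp(-0.5 * (r / (extent / 4)) ** 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                ux = np.where(r > 0, -dy / r * scale, 0.0)
                uy = np.where(r > 0, dx / r * scale, 0.0)
            return np.column_stack([ux, uy])

        return vortex
    raise ValueError(f"unknown flow model '{model}'")


def synth_tracks(
    flow_model: str = "uniform",
    speed: float = 3.0,
    diffusivity: float = 0.0,
    n_tracks: int = 100,
    n_frames: int = 50,
    fps: float = 1.0,
    extent: float = 200.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Track table integrated from an analytic flow field plus Brownian noise.

    ``speed`` is in um/s, ``diffusivity`` in um^2/s, frames at ``fps``; the
    table follows the TrackMate dialect (TRACK_ID, FRAME, POSITION_X/Y).
    Positions are not wrapped, emulating particles crossing a field of view.
    """
    rng = np.random.default_rng(seed)
    vfun = _analytic_field(flow_model, speed, extent)
    dt = 1.0 / fps
    pos = rng.uniform(0, extent, size=(n_tracks, 2))
    rows = []
    for frame in range(n_frames):
        rows.append(
            pd.DataFrame(
                {
                    "TRACK_ID": np.arange(n_tracks),
                    "FRAME": frame,
                    "POSITION_X": pos[:, 0],
                    "POSITION_Y": pos[:, 1],
                }
            )
        )
        step = vfun(pos) * dt
        if diffusivity > 0:
            step = step + np.sqrt(2 * diffusivity * dt) * rng.standard_normal((n_tracks, 2))
        pos = pos + step
    table = pd.concat(rows, ignore_index=True).sort_values(
        ["TRACK_ID", "FRAME"], ignore_index=True
    )
    truth = GroundTruth(
        "tracks",
        {
            "flow_model": flow_model,
            "speed_um_s": speed,
            "diffusivity_um2_s": diffusivity,
            "fps": fps,
            "n_tracks": n_tracks,
            "n_frames": n_frames,
            "seed": seed,
        },
    )
    return table, truth


def synth_cbf_movie(
    frequency_map: np.ndarray,
    fps: float = 140.0,
    n_frames: int = 280,
    noise_sd: float = 0.05,
    amplitude: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Per-pixel sinusoidal intensity movie with known beat frequencies.

    ``frequency_map`` gives each pixel's oscillation frequency in Hz; zero
    (or NaN) pixels stay static apart from the additive Gaussian noise.
    Frequencies at or above Nyquist raise.
    """
    fmap = np.nan_to_num(np.asarray(frequency_map, dtype=float))
    if np.any(fmap >= fps / 2):
        raise ValueError("frequency map contains components at or above Nyquist")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / fps
    phase = rng.uniform(0, 2 * np.pi, fmap.shape)
    movie = amplitude * np.sin(
        2 * np.pi * fmap[None, :, :] * t[:, None, None] + phase[None, :, :]
    )
    movie[:, fmap == 0] = 0.0
    if noise_sd > 0:
        movie = movie + rng.normal(0, noise_sd, movie.shape)
    truth = GroundTruth(
        "cbf_movie",
        {"fps": fps, "n_frames": n_frames, "noise_sd": noise_sd, "seed": seed},
    )
    return movie, truth


def synth_composition_dataset(
    true_coefficients=(0.1, 0.008, -0.01, 0.05),
    noise_sd: float = 0.03,
    n_conditions: int = 12,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Cell-type composition table with a known linear link to directionality.

    Predictors are drawn over realistic ranges (ciliated 20-95%, MUC5AC+
    0-40%, SCGB1A1+/MUC5AC+ ratio 0-5); the response is
    ``intercept + b1*ciliated + b2*muc5ac + b3*ratio + noise`` clipped to
    [0, 1], mimicking how directionality relates to composition.
    """
    if n_conditions < len(true_coefficients) + 2:
        raise ValueError("need at least p + 2 conditions")
    rng = np.random.default_rng(seed)
    ciliated = rng.uniform(20, 95, n_conditions)
    muc5ac = rng.uniform(0, 40, n_conditions)
    ratio = rng.uniform(0, 5, n_conditions)
    b0, b1, b2, b3 = true_coefficients
    y = b0 + b1 * ciliated + b2 * muc5ac + b3 * ratio
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, n_conditions)
    clipped = np.clip(y, 0.0, 1.0)
    clip_rate = float(np.mean(clipped != y))
    table = pd.DataFrame(
        {
            "condition": [f"cond{i:02d}" for i in range(n_conditions)],
            "pct_ciliated": ciliated,
            "pct_muc5ac": muc5ac,
            "scgb_muc_ratio": ratio,
        }
    )
    truth = GroundTruth(
        "composition",
        {
            "coefficients": tuple(true_coefficients),
            "noise_sd": noise_sd,
            "clip_rate": clip_rate,
            "seed": seed,
        },
    )
    return table, clipped, truth
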