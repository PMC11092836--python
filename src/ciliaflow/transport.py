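"""Langevin tracer transport through the cilia-driven flow.

Tracer particles seeded near the cilia tips follow

    dr/dt = v(r) + sqrt(2 D) eta(t)

with v the precomputed in-plane flow (um per beat period) and eta a standard
white noise.  The equation is integrated with the Euler-Maruyama scheme on
the doubly periodic domain; time is measured in beat periods and the thermal
noise amplitude is converted with the ciliary beat frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hydrodynamics import VelocityField

__all__ = [
    "TracerEnsemble",
    "advect_tracers",
    "tracks_to_table",
    "ensemble_cpb",
    "estimate_effective_diffusivity",
]

#: thermal diffusivity of 1 um beads in water at room temperature, um^2/s
THERMAL_DIFFUSIVITY = 0.4


@dataclass
class TracerEnsemble:
    """Trajectories of passive tracers on the periodic domain.

    ``positions`` holds the unwrapped trajectory (n_steps+1, n_particles, 2)
    in micrometres, sampled every integration step of ``dt`` beat periods;
    wrap into the domain with ``wrapped()`` when comparing against the field.
    """

    positions: np.ndarray
    dt_beats: float
    diffusivity: float
    cbf: float
    extent: tuple[float, float]
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0] - 1

    @property
    def times_beats(self) -> np.ndarray:
        return np.arange(self.positions.shape[0]) * self.dt_beats

    def wrapped(self) -> np.ndarray:
        return np.mod(self.positions, np.asarray(self.extent))

    def displacements(self) -> np.ndarray:
        """Net unwrapped displacement of each particle, (n_particles, 2)."""
        return self.positions[-1] - self.positions[0]


def advect_tracers(
    field: VelocityField,
    n_particles: int = 500,
    n_beats: float = 500,
    steps_per_beat: int = 20,
    diffusivity: float = THERMAL_DIFFUSIVITY,
    cbf: float = 2.9,
    seed: int = 0,
    initial_positions: np.ndarray | None = None,
) -> TracerEnsemble:
    """Integrate tracers through the flow with the Euler-Maruyama scheme.

    Particles start uniformly distributed over the domain (unless explicit
    positions are given) and evolve for ``n_beats`` beat periods with
    ``steps_per_beat`` steps each.  ``diffusivity`` is in um^2/s and is
    converted to per-beat units with the beat frequency ``cbf`` (Hz).
    """
    if diffusivity < 0:
        raise ValueError("diffusivity must be non-negative")
    if cbf <= 0:
        raise ValueError("beat frequency must be positive")
    rng = np.random.default_rng(seed)
    Lx, Ly = field.extent
    if initial_positions is None:
        pos = rng.uniform(0, [Lx, Ly], size=(n_particles, 2))
    else:
        pos = np.array(initial_positions, dtype=float)
        n_particles = pos.shape[0]
    dt = 1.0 / steps_per_beat
    n_steps = int(round(n_beats * steps_per_beat))

    vmax = float(np.max(np.hypot(field.u, field.v))) if field.u.size else 0.0
    if vmax * dt > field.grid_spacing:
        warnings.warn(
            "tracer step exceeds one field grid cell at peak speed; "
            "increase steps_per_beat for accuracy",
            stacklevel=2,
        )

    noise_scale = np.sqrt(2.0 * diffusivity * dt / cbf)  # um per step
    out = np.empty((n_steps + 1, n_particles, 2))
    out[0] = pos
    unwrapped = pos.copy()
    wrapped = np.mod(pos, (Lx, Ly))
    for k in range(1, n_steps + 1):
        vel = field.interpolate(wrapped)
        step = vel * dt
        if noise_scale > 0:
            step = step + noise_scale * rng.standard_normal((n_particles, 2))
        unwrapped = unwrapped + step
        wrapped = np.mod(wrapped + step, (Lx, Ly))
        out[k] = unwrapped
    return TracerEnsemble(
        positions=out,
        dt_beats=dt,
        diffusivity=diffusivity,
        cbf=cbf,
        extent=field.extent,
        seed=seed,
        meta={"steps_per_beat": steps_per_beat, "n_beats": n_beats},
    )


def ensemble_cpb(ensemble: TracerEnsemble) -> float:
    """Clearance per beat of the ensemble: mean per-beat travel distance.

    Trajectories are resampled at one frame per beat and CPB is the mean
    frame-to-frame speed in um/beat, matching how clearance speed is read
    off particle tracks before normalizing by beat frequency.
    """
    stride = max(1, int(round(1.0 / ensemble.dt_beats)))
    beats = ensemble.positions[::stride]
    steps = np.diff(beats, axis=0)
    return float(np.mean(np.hypot(steps[..., 0], steps[..., 1])))


def estimate_effective_diffusivity(tracks: pd.DataFrame, frame_interval: float) -> float:
    """Effective diffusivity from the drift-corrected mean squared displacement.

    For each track the ensemble-mean velocity is removed (so advection does
    not masquerade as diffusion), and the residual per-step displacement
    variance gives ``D_eff = var / (4 dt)`` -- the slope of the 2-D MSD at
    lag one frame.  This is how an effective noise scale is read off
    experimental particle tracks when tracers see more agitation than
    thermal motion alone.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive (seconds per frame)")
    steps = []
    for _, g in tracks.groupby("TRACK_ID", sort=False):
        if len(g) < 2:
            continue
        dx = np.diff(g["POSITION_X"].to_numpy())
        dy = np.diff(g["POSITION_Y"].to_numpy())
        steps.append(np.column_stack([dx, dy]))
    if not steps:
        raise ValueError("no track has two or more frames")
    disp = np.concatenate(steps)
    resid = disp - disp.mean(axis=0)
    return float(np.sum(resid.var(axis=0)) / (4.0 * frame_interval))


def tracks_to_table(
    ensemble: TracerEnsemble,
    frames_per_beat: float = 1.0,
    wrap: bool = False,
) -> pd.DataFrame:
    """Convert the ensemble to a long-format track table.

    Output columns follow the TrackMate export dialect consumed by the flow
    metrics reader: TRACK_ID, FRAME, POSITION_X, POSITION_Y (um).  Frames
    are sampled at ``frames_per_beat`` per beat period, starting at frame 0.
    """
    stride = max(1, int(round(1.0 / (ensemble.dt_beats * frames_per_beat))))
    traj = ensemble.wrapped() if wrap else ensemble.positions
    traj = traj[::stride]
    n_frames, n_particles, _ = traj.shape
    track_id = np.repeat(np.arange(n_particles), n_frames)
    frame = np.tile(np.arange(n_frames), n_particles)
    xy = traj.transpose(1, 0, 2).reshape(-1, 2)
    return pd.DataFrame(
        {
            "TRACK_ID": track_id,
            "FRAME": frame,
            "POSITION_X": xy[:, 0],
            "POSITION_Y": xy[:, 1],
        }
    )
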