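"""Cilia-driven Stokes flow from regularized Stokeslets above a no-slip wall.

Each ciliated cell is represented by a single horizontal regularized
Stokeslet (Cortez blob ``phi_eps(r) = 15 eps^4 / (8 pi (r^2+eps^2)^{7/2})``)
at one cilia length above the wall at z = 0.  The wall is honoured exactly by
an image system derived for this blob: for a horizontal force F at height h,

    8 pi mu u(x) = S(b0) F - S(b) F - 2 h^2 PD(b) F - 2 h DZ(b) F
                   - 4 h ROT(b) F - 6 h^2 eps^2 F / R^5

with b0 = x - X (source), b = x - X* (image point), R^2 = |b|^2 + eps^2,
PD the potential (source) doublet grad(F.grad)(1/R), DZ the z-derivative of
the regularized Stokeslet, and ROT a rotlet of strength z_hat x F.  The
combination is exactly divergence-free and cancels the wall velocity to
machine precision (verified in the test suite).

Periodic boundary conditions are applied by truncation: interactions further
than one periodic image away (> 250 um by default) are dropped, which is
accurate because the wall causes a quadratic far-field decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epithelium import CellMap, EpitheliumSpec

__all__ = [
    "StokesletSystem",
    "VelocityField",
    "stokeslet_velocity_halfspace",
    "free_space_stokeslet",
    "assemble_stokeslets",
    "compute_velocity_field",
    "calibrate_force_constant",
]

DEFAULT_EPSILON = 2.5       # um; regularization length ~ quarter cell diameter
DEFAULT_TRUNCATION = 250.0  # um; drop interactions beyond one periodic image


def free_space_stokeslet(eval_points, position, force, epsilon: float) -> np.ndarray:
    """Velocity of a free-space regularized Stokeslet (mu = 1).

    ``8 pi u_i = f_i (r^2 + 2 eps^2)/R^3 + (f . b) b_i / R^3`` with
    ``b = x - X`` and ``R = sqrt(r^2 + eps^2)``.
    """
    x = np.atleast_2d(np.asarray(eval_points, dtype=float))
    b = x - np.asarray(position, dtype=float)
    f = np.asarray(force, dtype=float)
    r2 = np.einsum("ij,ij->i", b, b)
    R3 = (r2 + epsilon**2) ** 1.5
    fb = b @ f
    u = (f[None, :] * (r2 + 2 * epsilon**2)[:, None] + b * fb[:, None]) / R3[:, None]
    return u / (8 * np.pi)


def stokeslet_velocity_halfspace(eval_points, position, force, epsilon: float) -> np.ndarray:
    """Velocity of a horizontal regularized Stokeslet above the no-slip wall z=0.

    Parameters
    ----------
    eval_points : (n, 3) array
        Evaluation points with z >= 0.
    position : (3,) array
        Stokeslet location; z must be positive.
    force : (3,) array
        Force vector; must be horizontal (z component zero).
    epsilon : float
        Regularization (blob) length in micrometres.
    """
    x = np.atleast_2d(np.asarray(eval_points, dtype=float))
    X = np.asarray(position, dtype=float)
    f = np.asarray(force, dtype=float)
    h = X[2]
    if h <= 0:
        raise ValueError("stokeslet must sit above the wall (z > 0)")
    if abs(f[2]) > 1e-12 * max(1.0, np.linalg.norm(f)):
        raise ValueError("only horizontal forces are supported")
    if np.any(x[:, 2] < -1e-12):
        raise ValueError("evaluation points must satisfy z >= 0")

    u = free_space_stokeslet(x, X, f, epsilon)

    Xim = np.array([X[0], X[1], -h])
    b = x - Xim
    r2 = np.einsum("ij,ij->i", b, b)
    R2 = r2 + epsilon**2
    R3 = R2**1.5
    R5 = R2**2.5
    fb = b @ f

    # image regularized Stokeslet, opposite sign
    u_img = (f[None, :] * (r2 + 2 * epsilon**2)[:, None] + b * fb[:, None]) / R3[:, None]

    # potential doublet grad (f . grad) (1/R):  -f/R^3 + 3 (f.b) b / R^5
    pd = -f[None, :] / R3[:, None] + 3 * fb[:, None] * b / R5[:, None]

    # z-derivative of the image Stokeslet applied to f
    bz = b[:, 2]
    dz = (
        f[None, :] * (2 * bz / R3 - 3 * bz * (r2 + 2 * epsilon**2) / R5)[:, None]
        - 3 * (bz * fb / R5)[:, None] * b
    )
    dz[:, 2] += fb / R3

    # rotlet of strength g = z_hat x f:  (g x b) / R^3
    g = np.array([-f[1], f[0], 0.0])
    rot = np.cross(np.broadcast_to(g, b.shape), b) / R3[:, None]

    blob = 6 * h**2 * epsilon**2 * f[None, :] / R5[:, None]

    u -= (u_img + 2 * h**2 * pd + 2 * h * dz + 4 * h * rot + blob) / (8 * np.pi)
    return u


@dataclass
class StokesletSystem:
    """Force singularities for one epithelium realization."""

    positions: np.ndarray          # (n, 3) um; z = cilia length
    forces: np.ndarray             # (n, 3); horizontal
    epsilon: float
    extent: tuple[float, float]
    truncation_radius: float = DEFAULT_TRUNCATION
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float)).reshape(-1, 3)
        self.forces = np.atleast_2d(np.asarray(self.forces, dtype=float)).reshape(-1, 3)
        if self.positions.shape != self.forces.shape:
            raise ValueError("positions and forces must have matching shapes")
        if self.positions.size and np.any(self.positions[:, 2] <= 0):
            raise ValueError("all stokeslets must sit above the wall")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class VelocityField:
    """In-plane flow sampled on a regular grid at cilia-tip height.

    ``u`` and ``v`` are (ny, nx) arrays in micrometres per beat period;
    the grid is doubly periodic with ``u[j, i]`` at
    ``((i + 1/2) dx, (j + 1/2) dy)``.
    """

    u: np.ndarray
    v: np.ndarray
    grid_spacing: float
    extent: tuple[float, float]
    height: float
    meta: dict = field(default_factory=dict)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Bilinear periodic interpolation of (u, v) at (n, 2) points."""
        Lx, Ly = self.extent
        ny, nx = self.u.shape
        dx, dy = Lx / nx, Ly / ny
        gx = (points[:, 0] / dx) - 0.5
        gy = (points[:, 1] / dy) - 0.5
        i0 = np.floor(gx).astype(int)
        j0 = np.floor(gy).astype(int)
        tx = gx - i0
        ty = gy - j0
        i0m, i1m = i0 % nx, (i0 + 1) % nx
        j0m, j1m = j0 % ny, (j0 + 1) % ny
        out = np.empty((points.shape[0], 2))
        for k, comp in enumerate((self.u, self.v)):
            c00 = comp[j0m, i0m]
            c10 = comp[j0m, i1m]
            c01 = comp[j1m, i0m]
            c11 = comp[j1m, i1m]
            out[:, k] = (
                c00 * (1 - tx) * (1 - ty)
                + c10 * tx * (1 - ty)
                + c01 * (1 - tx) * ty
                + c11 * tx * ty
            )
        return out


def assemble_stokeslets(
    cells: CellMap,
    force_constant: float = 1.0,
    epsilon: float = DEFAULT_EPSILON,
    truncation_radius: float = DEFAULT_TRUNCATION,
) -> StokesletSystem:
    """One horizontal Stokeslet per ciliated cell.

    Force magnitude is ``force_constant * amplitude`` (strength proportional
    to beat amplitude), direction ``(cos theta, sin theta, 0)`` along the
    power-stroke direction, applied at one cilia length above the wall.
    """
    spec = cells.spec
    if cells.ciliated is None or cells.beat_angle is None or cells.amplitude is None:
        if cells.ciliated is not None and cells.n_ciliated == 0:
            return StokesletSystem(
                positions=np.empty((0, 3)),
                forces=np.empty((0, 3)),
                epsilon=epsilon,
                extent=spec.extent,
                truncation_radius=truncation_radius,
                meta={"force_constant": force_constant, "cilia_length": spec.cilia_length},
            )
        raise ValueError("cell map must carry ciliated flags, angles and amplitudes")
    sel = cells.ciliated
    xy = cells.centers[sel]
    theta = cells.beat_angle[sel]
    amp = cells.amplitude[sel]
    pos = np.column_stack([xy, np.full(sel.sum(), spec.cilia_length)])
    mag = force_constant * amp
    forces = np.column_stack([mag * np.cos(theta), mag * np.sin(theta), np.zeros_like(mag)])
    return StokesletSystem(
        positions=pos,
        forces=forces,
        epsilon=epsilon,
        extent=spec.extent,
        truncation_radius=truncation_radius,
        meta={"force_constant": force_constant, "cilia_length": spec.cilia_length},
    )


def _pair_kernel_sum(pts, P, F, eps2, trunc2, shifts, out):
    """Accumulate the wall Green's function over all source-target pairs.

    ``shifts`` are the periodic lattice offsets (applied after reduction to
    the minimal image) whose copies can possibly lie within the truncation
    radius.  Plain nested loops: compiled with numba when available.
    """
    n_pts = pts.shape[0]
    n_src = P.shape[0]
    n_sh = shifts.shape[0]
    for i in range(n_pts):
        px = pts[i, 0]
        py = pts[i, 1]
        pz = pts[i, 2]
        ax = 0.0
        ay = 0.0
        az = 0.0
        for j in range(n_src):
            h = P[j, 2]
            fx = F[j, 0]
            fy = F[j, 1]
            for k in range(n_sh):
                bx = px - P[j, 0] + shifts[k, 0]
                by = py - P[j, 1] + shifts[k, 1]
                rho2 = bx * bx + by * by
                if rho2 > trunc2:
                    continue
                fb = bx * fx + by * fy
                bz0 = pz - h
                r2 = rho2 + bz0 * bz0
                R2 = r2 + eps2
                R3 = R2 * np.sqrt(R2)
                # primary stokeslet
                c0 = (r2 + 2.0 * eps2) / R3
                ax += fx * c0 + bx * fb / R3
                ay += fy * c0 + by * fb / R3
                az += bz0 * fb / R3
                # image system
                bz1 = pz + h
                r2 = rho2 + bz1 * bz1
                R2 = r2 + eps2
                R3 = R2 * np.sqrt(R2)
                R5 = R3 * R2
                c1 = (r2 + 2.0 * eps2) / R3
                h2 = h * h
                # image stokeslet
                ax -= fx * c1 + bx * fb / R3
                ay -= fy * c1 + by * fb / R3
                az -= bz1 * fb / R3
                # potential doublet, coefficient -2 h^2
                ax -= 2.0 * h2 * (-fx / R3 + 3.0 * fb * bx / R5)
                ay -= 2.0 * h2 * (-fy / R3 + 3.0 * fb * by / R5)
                az -= 2.0 * h2 * (3.0 * fb * bz1 / R5)
                # z-doublet, coefficient -2 h
                base = 2.0 * bz1 / R3 - 3.0 * bz1 * (r2 + 2.0 * eps2) / R5
                ax -= 2.0 * h * (fx * base - 3.0 * bz1 * fb * bx / R5)
                ay -= 2.0 * h * (fy * base - 3.0 * bz1 * fb * by / R5)
                az -= 2.0 * h * (fb / R3 - 3.0 * bz1 * bz1 * fb / R5)
                # rotlet (strength z_hat x F), coefficient -4 h
                ax -= 4.0 * h * fx * bz1 / R3
                ay -= 4.0 * h * fy * bz1 / R3
                az += 4.0 * h * fb / R3
                # blob correction, coefficient -6 h^2 eps^2
                ax -= 6.0 * h2 * eps2 * fx / R5
                ay -= 6.0 * h2 * eps2 * fy / R5
        out[i, 0] = ax
        out[i, 1] = ay
        out[i, 2] = az
    return out


try:  # compiled path; the pure-Python loop is the fallback
    from numba import njit

    _pair_kernel_sum_jit = njit(cache=True, fastmath=True)(_pair_kernel_sum)
except ImportError:  # pragma: no cover
    _pair_kernel_sum_jit = None


def evaluate_velocity(system: StokesletSystem, eval_points: np.ndarray) -> np.ndarray:
    """Superpose all Stokeslets and their periodic images at arbitrary points.

    For every source, periodic copies whose horizontal distance to the
    evaluation point is within the truncation radius are included; copies
    further than that are dropped (wall screening makes the far field decay
    cubically at cilia height, so the truncation error is small).
    """
    pts = np.atleast_2d(np.asarray(eval_points, dtype=float))
    out = np.zeros((pts.shape[0], 3))
    if system.n == 0:
        return out
    Lx, Ly = system.extent
    # wrap horizontal coordinates into [0, L); copies within the truncation
    # radius then come from lattice shifts k with |k|*L <= L + truncation
    P = system.positions.copy()
    P[:, 0] %= Lx
    P[:, 1] %= Ly
    pts_wrapped = pts.copy()
    pts_wrapped[:, 0] %= Lx
    pts_wrapped[:, 1] %= Ly
    kx = int(np.floor((system.truncation_radius + Lx) / Lx))
    ky = int(np.floor((system.truncation_radius + Ly) / Ly))
    shifts = np.array(
        [(i * Lx, j * Ly) for i in range(-kx, kx + 1) for j in range(-ky, ky + 1)],
        dtype=float,
    )
    fun = _pair_kernel_sum_jit if _pair_kernel_sum_jit is not None else _pair_kernel_sum
    fun(
        pts_wrapped,
        P,
        system.forces,
        float(system.epsilon**2),
        float(system.truncation_radius**2),
        shifts,
        out,
    )
    return out / (8 * np.pi)


def compute_velocity_field(
    system: StokesletSystem,
    grid_spacing: float = 2.5,
    height: float | None = None,
) -> VelocityField:
    """Sample the in-plane flow on a regular grid at cilia-tip height.

    Velocities are in micrometres per beat period (the force constant folds
    viscosity and beat period into a single calibrated scale).
    """
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    Lx, Ly = system.extent
    if height is None:
        height = float(system.positions[:, 2].mean()) if system.n else 1.0
    nx = max(1, int(round(Lx / grid_spacing)))
    ny = max(1, int(round(Ly / grid_spacing)))
    gx = (np.arange(nx) + 0.5) * (Lx / nx)
    gy = (np.arange(ny) + 0.5) * (Ly / ny)
    GX, GY = np.meshgrid(gx, gy, indexing="xy")
    pts = np.column_stack([GX.ravel(), GY.ravel(), np.full(GX.size, height)])
    vel = evaluate_velocity(system, pts)
    u = vel[:, 0].reshape(ny, nx)
    v = vel[:, 1].reshape(ny, nx)
    return VelocityField(
        u=u, v=v, grid_spacing=Lx / nx, extent=system.extent, height=height,
        meta=dict(system.meta),
    )


def calibrate_force_constant(
    human_spec: EpitheliumSpec,
    benchmark_cpb: float = 7.75,
    diffusivity: float = 0.4,
    cbf: float = 2.9,
    seed: int = 0,
    rtol: float = 0.02,
    grid_spacing: float = 2.5,
    n_particles: int = 500,
    n_beats: int = 500,
) -> float:
    """Fix the single free scale of the model against the measured benchmark.

    The Stokeslet strength per unit beat amplitude is the one parameter the
    flow model does not set; it is chosen so that the full pipeline (flow +
    Brownian tracers at the given diffusivity) reproduces the benchmark
    clearance per beat.  CPB is monotone increasing in the force constant, so
    the root is found by bisection on a bracketing interval obtained from the
    (nearly linear) unit-force response.
    """
    from .transport import advect_tracers, ensemble_cpb

    cells = __import__("ciliaflow.epithelium", fromlist=["generate_epithelium"]).generate_epithelium(
        EpitheliumSpec(**{**human_spec.to_dict(), "seed": seed})
    )
    system = assemble_stokeslets(cells, force_constant=1.0)
    base = compute_velocity_field(system, grid_spacing=grid_spacing)

    def cpb_of(c: float) -> float:
        scaled = VelocityField(
            u=c * base.u, v=c * base.v, grid_spacing=base.grid_spacing,
            extent=base.extent, height=base.height,
        )
        ens = advect_tracers(
            scaled, n_particles=n_particles, n_beats=n_beats,
            diffusivity=diffusivity, cbf=cbf, seed=seed,
        )
        return ensemble_cpb(ens)

    # linear estimate from the unit response brackets the root
    unit = cpb_of(1.0)
    if unit <= 0:
        raise RuntimeError("unit-force field produced no transport; cannot calibrate")
    lo = 0.2 * benchmark_cpb / unit
    hi = 5.0 * benchmark_cpb / unit
    if not (cpb_of(lo) < benchmark_cpb < cpb_of(hi)):
        raise RuntimeError("calibration interval does not bracket the benchmark CPB")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = cpb_of(mid)
        if abs(val - benchmark_cpb) <= rtol * benchmark_cpb:
            return float(mid)
        if val < benchmark_cpb:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))
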