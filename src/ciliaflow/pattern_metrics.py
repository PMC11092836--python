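"""Structural metrics of ciliation patterns.

A ciliated epithelium, viewed from above after thresholding a cilia marker,
is a binary image: patches of multiciliated cells separated by gaps of
secretory/other cells.  This module quantifies that pattern with the metrics
used throughout the package:

* ``coverage`` — fraction (or %) of the tissue that is ciliated;
* ``C(R)`` — radial two-point correlation of the binary image, whose first
  local maximum is the ciliation gap wavelength ``lambda`` (mean spacing of
  ciliated patches);
* ``COP`` — crystalline order parameter, ``1 - 2*std(lambda)/mean(lambda)``
  across fields of view, measuring how regular the patch lattice is;
* ``OP`` — director-free orientational order parameter of ciliary beat
  angles, ``sqrt(<sin 2t>^2 + <cos 2t>^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "CiliationMask",
    "CorrelationCurve",
    "PatternSummary",
    "two_point_correlation",
    "extract_gap_wavelength",
    "crystalline_order",
    "beat_order_parameter",
    "coverage_fraction",
    "circle_perimeter_offsets",
]


@dataclass
class CiliationMask:
    """Binary ciliation image with physical pixel size.

    Parameters
    ----------
    image : ndarray of shape (m, n)
        Values in {0, 1}; 1 marks ciliated pixels.
    pixel_size : float
        Edge length of one pixel in micrometres.
    fov_id : str, optional
        Identifier of the field of view the mask came from.
    """

    image: np.ndarray
    pixel_size: float
    fov_id: str = ""

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 2 or img.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        vals = np.unique(img)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.image = img.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass
class CorrelationCurve:
    """Radial two-point correlation C(R) of a ciliation mask."""

    radii_px: np.ndarray
    values: np.ndarray
    pixel_size: float
    gap_wavelength_um: float | None = None

    @property
    def radii_um(self) -> np.ndarray:
        return self.radii_px * self.pixel_size


@dataclass
class PatternSummary:
    """Structural metrics of one condition (possibly several FOVs)."""

    coverage_pct: float
    gap_wavelength_mean_um: float | None
    gap_wavelength_std_um: float | None
    cop: float | None
    beat_op: float | None
    provenance: dict = field(default_factory=dict)


def circle_perimeter_offsets(radius: int) -> np.ndarray:
    """Integer (dx, dy) offsets on the perimeter of a circle of given radius.

    Midpoint-circle rasterization: all integer points whose rounded distance
    to the origin equals ``radius``, restricted to the annulus
    ``radius - 0.5 <= r < radius + 0.5``.
    """
    if radius == 0:
        return np.array([[0, 0]])
    r = int(radius)
    span = np.arange(-r - 1, r + 2)
    dx, dy = np.meshgrid(span, span, indexing="ij")
    dist = np.hypot(dx, dy)
    sel = np.round(dist).astype(int) == r
    return np.stack([dx[sel], dy[sel]], axis=1)


def _autocorr_counts(img: np.ndarray, periodic: bool) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized autocorrelation sum(I(i,j) I(i+x, j+y)) and pair counts.

    Returns arrays indexed by offsets x in [-(m-1), m-1], y in [-(n-1), n-1]
    (non-periodic) or x in [0, m), y in [0, n) (periodic), along with the
    number of valid pixel pairs N at each offset.
    """
    I = img.astype(np.float64)
    m, n = I.shape
    if periodic:
        F = np.fft.rfft2(I)
        corr = np.fft.irfft2(F * np.conj(F), s=(m, n))
        counts = np.full((m, n), float(m * n))
        return corr, counts
    corr = fftconvolve(I, I[::-1, ::-1], mode="full")  # offset (x,y) at index (m-1+x, n-1+y)
    xs = np.arange(-(m - 1), m)
    ys = np.arange(-(n - 1), n)
    counts = np.outer(m - np.abs(xs), n - np.abs(ys)).astype(float)
    return corr, counts


def two_point_correlation(
    mask: CiliationMask,
    max_radius_px: int | None = None,
    periodic: bool = False,
) -> CorrelationCurve:
    """Radial two-point correlation C(R) of a binary mask.

    The planar correlation ``C_hat(x, y) = (1/N) * sum_ij I(i,j) I(i+x,j+y)``
    (with N the number of in-bounds pixel pairs at that offset) is averaged
    over the integer-rounded perimeter of a circle of radius R.  With
    ``periodic=True`` offsets wrap around the image, which matches rasters of
    the doubly periodic simulated epithelium; the default divides by
    ``(m-x)(n-y)`` overlap counts as appropriate for experimental images.
    """
    img = mask.image
    m, n = img.shape
    if max_radius_px is None:
        max_radius_px = min(m, n) // 2
    corr, counts = _autocorr_counts(img, periodic)
    radii = np.arange(0, max_radius_px + 1)
    values = np.empty(radii.size)
    for k, R in enumerate(radii):
        offs = circle_perimeter_offsets(R)
        if periodic:
            c = corr[offs[:, 0] % m, offs[:, 1] % n]
            N = counts[offs[:, 0] % m, offs[:, 1] % n]
        else:
            sel = (np.abs(offs[:, 0]) < m) & (np.abs(offs[:, 1]) < n)
            offs = offs[sel]
            c = corr[offs[:, 0] + m - 1, offs[:, 1] + n - 1]
            N = counts[offs[:, 0] + m - 1, offs[:, 1] + n - 1]
        values[k] = np.mean(c / N)
    curve = CorrelationCurve(radii_px=radii, values=values, pixel_size=mask.pixel_size)
    curve.gap_wavelength_um = extract_gap_wavelength(curve)
    return curve


def two_point_correlation_direct(mask: CiliationMask, max_radius_px: int | None = None) -> CorrelationCurve:
    """Literal double-sum evaluation of C(R); reference path for small images."""
    img = mask.image.astype(np.float64)
    m, n = img.shape
    if max_radius_px is None:
        max_radius_px = min(m, n) // 2
    radii = np.arange(0, max_radius_px + 1)
    values = np.empty(radii.size)
    for k, R in enumerate(radii):
        offs = circle_perimeter_offsets(R)
        terms = []
        for dx, dy in offs:
            if abs(dx) >= m or abs(dy) >= n:
                continue
            # slide so the shift (dx, dy) stays in bounds for either sign
            i0, i1 = max(0, -dx), min(m, m - dx)
            j0, j1 = max(0, -dy), min(n, n - dy)
            prod = img[i0:i1, j0:j1] * img[i0 + dx:i1 + dx, j0 + dy:j1 + dy]
            N = (m - abs(dx)) * (n - abs(dy))
            terms.append(prod.sum() / N)
        values[k] = np.mean(terms)
    return CorrelationCurve(radii_px=radii, values=values, pixel_size=mask.pixel_size)


def extract_gap_wavelength(
    curve: CorrelationCurve,
    min_radius_px: int = 2,
    smooth_window: int = 3,
) -> float | None:
    """Gap wavelength: location (um) of the first local maximum of C(R).

    C(R) is lightly smoothed (moving average over ``smooth_window`` samples)
    and scanned outward from ``min_radius_px``; the first sample strictly
    greater than both neighbours wins.  Returns None when C(R) has no
    interior maximum (e.g. a featureless mask).
    """
    v = curve.values
    if v.size < min_radius_px + 2:
        return None
    span = float(np.max(v) - np.min(v))
    if span < 1e-9:  # featureless mask (all ones / all zeros)
        return None
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        v = np.convolve(np.pad(v, pad, mode="edge"), kernel, mode="valid")
    rise = 1e-6 * span  # ignore floating-point ripple
    for i in range(max(min_radius_px, 1), v.size - 1):
        # a genuine rise followed by a non-rise; >= tolerates flat tops
        if v[i] > v[i - 1] + rise and v[i] >= v[i + 1]:
            # parabolic sub-pixel refinement of the integer-radius peak
            denom = v[i - 1] - 2 * v[i] + v[i + 1]
            shift = 0.5 * (v[i - 1] - v[i + 1]) / denom if denom != 0 else 0.0
            return float((curve.radii_px[i] + shift) * curve.pixel_size)
    return None


def crystalline_order(gap_wavelengths_um) -> float:
    """Crystalline order parameter across FOVs: 1 - 2*std(lambda)/mean(lambda).

    Sample (n-1) standard deviation.  Perfectly regular patterns give 1;
    values can be negative for very heterogeneous patchiness.
    """
    lam = np.asarray(gap_wavelengths_um, dtype=float)
    lam = lam[np.isfinite(lam)]
    if lam.size < 2:
        raise ValueError("need at least two FOV wavelengths")
    mean = lam.mean()
    if mean == 0:
        raise ValueError("mean wavelength is zero")
    return float(1.0 - 2.0 * lam.std(ddof=1) / mean)


def beat_order_parameter(angles_rad) -> float:
    """Director-free orientational order parameter of beat angles.

    ``OP = sqrt(<sin 2t>^2 + <cos 2t>^2)``; invariant under t -> t + pi,
    1 for perfect alignment, 0 for an isotropic director field.
    """
    t = np.asarray(angles_rad, dtype=float)
    if t.size == 0:
        raise ValueError("empty angle set")
    s = np.sin(2 * t).mean()
    c = np.cos(2 * t).mean()
    return float(np.hypot(s, c))


def coverage_fraction(mask_or_flags, as_percent: bool = True) -> float:
    """Cilia coverage from a mask (area mode) or per-cell flags (cell mode).

    A 2-D binary array is treated as a pixel mask (area-weighted coverage);
    a 1-D boolean array as per-cell ciliated flags (cell-count coverage, the
    definition used for 'percentage of luminal cells that are ciliated').
    """
    if isinstance(mask_or_flags, CiliationMask):
        arr = mask_or_flags.image
    else:
        arr = np.asarray(mask_or_flags)
    if arr.size == 0:
        raise ValueError("empty input")
    frac = float(np.mean(arr != 0))
    return 100.0 * frac if as_percent else frac
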