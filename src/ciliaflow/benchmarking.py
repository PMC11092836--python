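"""Headline structure-function analyses.

Assembles the top-level results from the lower-level modules: predicted
CPB and clearance-directionality curves as a function of cilia coverage
(with uncertainty bands from re-seeding and input-metric spread), the
composition-to-directionality linear regression with predictor ablations,
and tidy benchmark-map tables comparing measured conditions against the
model curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .epithelium import EpitheliumSpec, generate_epithelium
from .flow_metrics import directionality_curve, eulerian_average
from .hydrodynamics import VelocityField, assemble_stokeslets, compute_velocity_field
from .transport import THERMAL_DIFFUSIVITY, advect_tracers, ensemble_cpb, tracks_to_table

__all__ = [
    "CompositionProfile",
    "BenchmarkRecord",
    "RegressionModel",
    "simulate_condition",
    "prediction_curves",
    "fit_directionality_regression",
    "benchmark_map",
    "HUMAN_AIRWAY",
    "RAT_AIRWAY",
    "PC_MEDIUM",
]

# Measured tissue-level input metrics (means) used as standard conditions:
# human airways BG0-6, rat airways BG0-1, and PneumaCult-cultured epithelium.
HUMAN_AIRWAY = dict(
    gap_wavelength_mean=24.5, gap_wavelength_std=2.9,
    cilia_length=7.1, amplitude_mean=12.9, amplitude_std=0.9,
    beat_order_target=0.85,
)
RAT_AIRWAY = dict(
    gap_wavelength_mean=26.8, gap_wavelength_std=2.2,
    cilia_length=5.1, amplitude_mean=8.1, amplitude_std=1.0,
    beat_order_target=0.6,
)
PC_MEDIUM = dict(
    gap_wavelength_mean=13.6, gap_wavelength_std=0.5,
    cilia_length=7.0, amplitude_mean=12.8, amplitude_std=0.8,
    beat_order_target=0.85,
)


@dataclass
class CompositionProfile:
    """Luminal cell-type composition of one condition (percentages)."""

    condition: str
    pct_ciliated: float
    pct_muc5ac: float
    pct_scgb1a1: float
    pct_double_positive: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pct_ciliated", "pct_muc5ac", "pct_scgb1a1", "pct_double_positive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100]")
        if self.pct_double_positive > min(self.pct_muc5ac, self.pct_scgb1a1) + 1e-9:
            raise ValueError("double positives cannot exceed either single-marker percentage")

    @property
    def scgb_muc_ratio(self) -> float | None:
        """SCGB1A1+/MUC5AC+ ratio; None when MUC5AC+ is zero (undefined)."""
        if self.pct_muc5ac == 0:
            return None
        return self.pct_scgb1a1 / self.pct_muc5ac


@dataclass
class BenchmarkRecord:
    """One measured or simulated condition for the benchmark maps."""

    condition: str
    coverage_pct: float
    cpb_um_beat: float
    directionality: float | None = None
    composition: CompositionProfile | None = None
    source: str = "measured"

    def __post_init__(self) -> None:
        if self.source not in ("measured", "simulated", "literature"):
            raise ValueError("source must be measured | simulated | literature")


@dataclass
class RegressionModel:
    """OLS fit of directionality on composition predictors."""

    params: pd.Series
    r_squared: float
    n: int
    predictors: tuple

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(table[list(self.predictors)], has_constant="add")
        return np.asarray(X @ self.params)


def simulate_condition(
    spec: EpitheliumSpec,
    force_constant: float,
    diffusivity: float = THERMAL_DIFFUSIVITY,
    cbf: float = 2.9,
    grid_spacing: float = 2.5,
    n_particles: int = 500,
    n_beats: float = 500,
    bin_size: float = 5.0,
    seed: int | None = None,
) -> dict:
    """Run the full pipeline for one epithelium spec and summarize outputs.

    Generates the tissue, computes the Stokeslet flow, advects Brownian
    tracers, and measures CPB plus the directionality curve (DR80, R0) from
    the Eulerian average of the simulated tracks.
    """
    if seed is not None:
        spec = EpitheliumSpec(**{**spec.to_dict(), "seed": seed})
    cells = generate_epithelium(spec)
    out = {
        "coverage_pct": 100 * (cells.realized_coverage() if cells.ciliated is not None else 0.0),
        "seed": spec.seed,
    }
    if cells.n_ciliated == 0:
        # no ciliated cells: zero flow, pure diffusion
        nx = max(1, int(round(spec.extent[0] / grid_spacing)))
        ny = max(1, int(round(spec.extent[1] / grid_spacing)))
        fld = VelocityField(
            u=np.zeros((ny, nx)), v=np.zeros((ny, nx)),
            grid_spacing=spec.extent[0] / nx, extent=spec.extent,
            height=spec.cilia_length,
        )
    else:
        system = assemble_stokeslets(cells, force_constant=force_constant)
        fld = compute_velocity_field(system, grid_spacing=grid_spacing)
    ens = advect_tracers(
        fld, n_particles=n_particles, n_beats=n_beats,
        diffusivity=diffusivity, cbf=cbf, seed=spec.seed,
    )
    out["cpb_um_beat"] = ensemble_cpb(ens)
    tracks = tracks_to_table(ens)
    flow = eulerian_average(tracks, bin_size=bin_size, extent=None)
    curve = directionality_curve(flow)
    out["dr80"] = curve.dr80
    out["r0_um"] = curve.r0_um
    out["fit_r2"] = curve.fit_r2
    out["curve"] = curve
    return out


def prediction_curves(
    base_spec: EpitheliumSpec,
    coverage_grid=np.linspace(0.1, 1.0, 7),
    n_seeds: int = 5,
    force_constant: float | None = None,
    diffusivity: float = THERMAL_DIFFUSIVITY,
    cbf: float = 2.9,
    **sim_kwargs,
) -> pd.DataFrame:
    """CPB and directionality vs cilia coverage, mean and spread over seeds.

    Returns one row per coverage point with mean/std of CPB and DR80 over
    ``n_seeds`` independent tissue realizations.
    """
    if force_constant is None:
        raise ValueError("a calibrated force constant is required")
    rows = []
    for cov in np.asarray(coverage_grid, dtype=float):
        cpbs, dirs = [], []
        for s in range(n_seeds):
            spec = EpitheliumSpec(
                **{**base_spec.to_dict(), "coverage": float(cov), "seed": base_spec.seed + 1000 * s}
            )
            res = simulate_condition(
                spec, force_constant, diffusivity=diffusivity, cbf=cbf, **sim_kwargs
            )
            cpbs.append(res["cpb_um_beat"])
            dirs.append(res["dr80"])
        rows.append(
            {
                "coverage": cov,
                "cpb_mean": float(np.mean(cpbs)),
                "cpb_std": float(np.std(cpbs)),
                "dir_mean": float(np.mean(dirs)),
                "dir_std": float(np.std(dirs)),
                "n_seeds": n_seeds,
            }
        )
    return pd.DataFrame(rows)


def fit_directionality_regression(
    table: pd.DataFrame,
    response,
    predictors=("pct_ciliated", "pct_muc5ac", "scgb_muc_ratio"),
) -> RegressionModel:
    """OLS regression of clearance directionality on composition predictors.

    The full model uses percentage of ciliated cells, percentage of MUC5AC+
    cells and the SCGB1A1+/MUC5AC+ ratio; passing a predictor subset
    reproduces the ablations.
    """
    predictors = tuple(predictors)
    y = np.asarray(response, dtype=float)
    if len(y) < len(predictors) + 2:
        raise ValueError("need at least p + 2 observations")
    X = sm.add_constant(table[list(predictors)].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    return RegressionModel(
        params=fit.params, r_squared=float(fit.rsquared), n=int(len(y)), predictors=predictors
    )


def benchmark_map(
    records: list[BenchmarkRecord],
    curves: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Tidy tables for the clearance-per-beat and cellular-composition maps.

    Returns ``{"cpb_map": ..., "composition_map": ..., "curves": ...}``;
    records missing a composition profile are simply absent from the
    composition map.  MUC5AC+ = 0 gives an undefined (NaN) ratio marker.
    """
    for rec in records:
        if not isinstance(rec, BenchmarkRecord):
            raise ValueError(f"not a BenchmarkRecord: {rec!r}")
    cpb_rows = [
        {
            "condition": r.condition,
            "coverage_pct": r.coverage_pct,
            "cpb_um_beat": r.cpb_um_beat,
            "directionality": r.directionality,
            "source": r.source,
        }
        for r in records
    ]
    comp_rows = []
    for r in records:
        if r.composition is None:
            continue
        ratio = r.composition.scgb_muc_ratio
        comp_rows.append(
            {
                "condition": r.condition,
                "pct_ciliated": r.composition.pct_ciliated,
                "pct_muc5ac": r.composition.pct_muc5ac,
                "scgb_muc_ratio": np.nan if ratio is None else ratio,
                "ratio_undefined": ratio is None,
                "source": r.source,
            }
        )
    return {
        "cpb_map": pd.DataFrame(cpb_rows),
        "composition_map": pd.DataFrame(comp_rows),
        "curves": curves if curves is not None else pd.DataFrame(),
    }
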