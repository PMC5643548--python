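"""Cell survival from heterogeneous nuclear dose: the predictive core.

Survival follows a local-effect formulation: a lethal-event density
``v(D_local)`` is integrated over the nucleus volume,

    S = exp( - integral v(D_local) dV )

with a two-branch density based on the linear-quadratic (LQ) model below a
threshold dose ``D_t`` and a purely exponential response above it,

    v(d) = (alpha d + beta d^2) / V_nucleus                      d <= D_t
    v(d) = v(D_t) + S_max (d - D_t) / V_nucleus                  d >  D_t

where ``S_max = alpha + 2 beta D_t`` makes the density continuously
differentiable at the threshold.  ``D_local`` in a voxel is the sparse
GNP-track dose plus the homogeneous photon background dose.

Survival curves average ``S`` over independent Monte Carlo cell
realizations per dose point.  The mean inactivation dose (MID) is the area
under the survival curve; the sensitizer enhancement ratio (SER) is the
MID without gold divided by the MID with gold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .cell_model import (
    VOXEL_VOLUME_UM3,
    CellGeometry,
    CompartmentLoading,
    CompartmentSource,
    NucleusDoseGrid,
    score_dose,
)
from .gnp_source import GnpSpec, TrackLibrary, build_library
from .spectrum import preset_spectrum

__all__ = [
    "RadiosensitivityParams",
    "SurvivalResult",
    "Scenario",
    "lethal_event_density",
    "survival_from_grid",
    "survival_curve",
    "lq_survival",
    "fit_lq",
    "mid",
    "mid_lq",
    "ser",
]

DEFAULT_DOSES_GY = tuple(float(d) for d in np.arange(0.0, 8.5, 1.0))


@dataclass(frozen=True)
class RadiosensitivityParams:
    """LQ radiosensitivity with the high-dose threshold (PC-3 defaults)."""

    alpha: float = 0.217  # 1/Gy
    beta: float = 0.044  # 1/Gy^2
    d_threshold_gy: float = 23.9

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.d_threshold_gy <= 0:
            raise ValueError("threshold dose must be positive")

    @property
    def s_max(self) -> float:
        """Log-survival slope above the threshold, 1/Gy."""
        return self.alpha + 2.0 * self.beta * self.d_threshold_gy


def lethal_event_density(d_local_gy, params: RadiosensitivityParams,
                         nucleus_volume_um3: float):
    """Lethal events per um^3 at local dose ``d_local_gy`` (vectorised)."""
    d = np.asarray(d_local_gy, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative local dose")
    a, b, dt = params.alpha, params.beta, params.d_threshold_gy
    below = a * d + b * d * d
    v_dt = a * dt + b * dt * dt
    above = v_dt + params.s_max * (d - dt)
    out = np.where(d <= dt, below, above) / nucleus_volume_um3
    return out if out.ndim else float(out)


def survival_from_grid(grid: NucleusDoseGrid,
                       params: RadiosensitivityParams) -> float:
    """Integrate the lethal-event density over the nucleus for one cell.

    Sparse voxels see GNP dose plus background; the remaining nucleus
    volume sees background only.
    """
    v_nuc = grid.nucleus_volume_um3
    bg = grid.background_dose_gy
    integral = lethal_event_density(bg, params, v_nuc) \
        * (v_nuc - grid.n_voxels * VOXEL_VOLUME_UM3)
    if grid.n_voxels:
        v = lethal_event_density(grid.voxel_doses + bg, params, v_nuc)
        integral += float(np.sum(v)) * VOXEL_VOLUME_UM3
    return float(np.exp(-integral))


def lq_survival(dose_gy, alpha: float, beta: float):
    """Plain LQ survival ``exp(-alpha D - beta D^2)``."""
    d = np.asarray(dose_gy, dtype=float)
    out = np.exp(-(alpha * d + beta * d * d))
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Scenario -> survival curve
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """One predictive configuration: beam, GNP size, localization, cell."""

    source: str = "gulmay_100kvp"
    gnp_diameter_nm: float = 1.9
    loading: CompartmentLoading = field(default_factory=CompartmentLoading)
    geometry: CellGeometry = field(default_factory=CellGeometry)
    params: RadiosensitivityParams = field(default_factory=RadiosensitivityParams)
    doses_gy: tuple = DEFAULT_DOSES_GY
    n_tracks: int = 10_000
    n_repeats: int = 30
    seed: int = 0
    label: str = ""

    def build_library(self, seed=None) -> TrackLibrary:
        spectrum = preset_spectrum(self.source)
        return build_library(GnpSpec(self.gnp_diameter_nm), spectrum,
                             self.n_tracks, seed=seed)


@dataclass
class SurvivalResult:
    """Survival curve with per-realization detail and MID."""

    doses_gy: np.ndarray
    surviving_fraction: np.ndarray  # mean over repeats
    per_repeat: np.ndarray  # (n_repeats, n_doses)
    label: str = ""

    @property
    def sem(self) -> np.ndarray:
        n = self.per_repeat.shape[0]
        if n < 2:
            return np.zeros_like(self.surviving_fraction)
        return self.per_repeat.std(axis=0, ddof=1) / np.sqrt(n)

    @property
    def mid_gy(self) -> float:
        return mid(self)

    def mid_jackknife(self) -> tuple[float, float]:
        """(MID, jackknife standard error) over cell realizations."""
        n = self.per_repeat.shape[0]
        if n < 2:
            return self.mid_gy, 0.0
        total = self.per_repeat.sum(axis=0)
        mids = np.array([
            _mid_from_points(self.doses_gy, (total - self.per_repeat[i]) / (n - 1))
            for i in range(n)
        ])
        se = np.sqrt((n - 1) / n * np.sum((mids - mids.mean()) ** 2))
        return self.mid_gy, float(se)


def _mid_from_points(doses, sf) -> float:
    """Trapezoidal area under the curve plus exponential tail."""
    doses = np.asarray(doses, dtype=float)
    sf = np.asarray(sf, dtype=float)
    area = float(np.trapezoid(sf, doses))
    # analytic exponential extrapolation from the last two points
    if len(doses) >= 2 and sf[-1] > 0 and sf[-2] > sf[-1]:
        lam = np.log(sf[-2] / sf[-1]) / (doses[-1] - doses[-2])
        area += float(sf[-1] / lam)
    return area


def mid(result) -> float:
    """Mean inactivation dose: area under the survival curve, Gy."""
    return _mid_from_points(result.doses_gy, result.surviving_fraction)


def mid_lq(params: RadiosensitivityParams, d_max_gy: float = 20.0,
           step_gy: float = 0.1) -> float:
    """MID of the plain LQ curve, evaluated on a dense dose grid."""
    d = np.arange(0.0, d_max_gy + step_gy / 2, step_gy)
    s = lq_survival(d, params.alpha, params.beta)
    return _mid_from_points(d, s)


def ser(mid_without_gnp: float, mid_with_gnp: float) -> float:
    """Sensitizer enhancement ratio: MID(no gold) / MID(gold)."""
    if mid_with_gnp <= 0:
        raise ZeroDivisionError("MID with GNPs must be positive")
    if mid_without_gnp <= 0:
        raise ValueError("MID without GNPs must be positive")
    return mid_without_gnp / mid_with_gnp


def survival_curve(scenario: Scenario, library: TrackLibrary | None = None,
                   doses_gy=None, n_repeats=None, seed=None) -> SurvivalResult:
    """Mean survival over independent Monte Carlo cell realizations.

    The master seed spawns one child stream for the track library and one
    per (dose, repeat) realization, so results are reproducible and the
    library does not depend on the number of repeats.
    """
    doses = np.asarray(scenario.doses_gy if doses_gy is None else doses_gy,
                       dtype=float)
    n_rep = scenario.n_repeats if n_repeats is None else n_repeats
    seed = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    lib_ss, sim_ss = ss.spawn(2)
    loading = scenario.loading
    has_gold = (loading.media_mg_ml > 0 or loading.cytoplasm_mg_ml > 0
                or loading.nucleus_mg_ml > 0)
    if has_gold and library is None:
        library = scenario.build_library(seed=lib_ss)
    per_repeat = np.ones((n_rep, len(doses)))
    if has_gold:
        sources = [
            CompartmentSource(library, comp, loading.concentration(comp))
            for comp in ("nucleus", "cytoplasm", "media")
            if loading.concentration(comp) > 0
        ]
        child = iter(sim_ss.spawn(len(doses) * n_rep))
        for j, d in enumerate(doses):
            for i in range(n_rep):
                rng = np.random.default_rng(next(child))
                if d == 0:
                    continue  # no absorptions, survival 1
                grid = score_dose(sources, scenario.geometry, float(d), rng)
                per_repeat[i, j] = survival_from_grid(grid, scenario.params)
    else:
        per_repeat *= lq_survival(doses, scenario.params.alpha,
                                  scenario.params.beta)[None, :]
    return SurvivalResult(
        doses_gy=doses,
        surviving_fraction=per_repeat.mean(axis=0),
        per_repeat=per_repeat,
        label=scenario.label or f"{scenario.source}/{scenario.gnp_diameter_nm}nm",
    )


def fit_lq(doses_gy, survival_values) -> tuple[float, float]:
    """Fit ``S = exp(-alpha D - beta D^2)`` by nonlinear least squares.

    The fit runs on the linear survival scale with nonnegativity bounds on
    both parameters.  Requires at least three dose points.
    """
    d = np.asarray(doses_gy, dtype=float)
    s = np.asarray(survival_values, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 dose points")
    if np.any((s <= 0) | (s > 1.0 + 1e-12)):
        raise ValueError("survival values must lie in (0, 1]")
    # seed from a log-scale quadratic fit
    with np.errstate(divide="ignore"):
        coef = np.polyfit(d, -np.log(s), 2)
    p0 = (max(coef[1], 0.0), max(coef[0], 0.0))
    try:
        popt, _ = curve_fit(lambda dd, a, b: lq_survival(dd, a, b), d, s,
                            p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
                            maxfev=10_000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"LQ fit did not converge (doses={d.tolist()}, p0={p0}): {exc}"
        ) from exc
    return float(popt[0]), float(popt[1])
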