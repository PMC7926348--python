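"""Estimation of site excess chemical potentials from occupancy and current data.

The observables are (a) equilibrium mean occupancies of the four sites,
typically from block-averaged molecular-dynamics runs at 0.5 M, and (b) one
or more single-channel currents in the Ohmic regime, typically at 0.14 M.
Both are smooth functions of the site excess potentials dmu through the
exact ensemble, so the fit is a bounded nonlinear least-squares problem:

    minimise  sum_occ (model - obs)^2  +  sum_iv ((I_model - I_obs)/w)^2

with the current block rescaled by w (default max |I_obs|) so both blocks
are O(1).  Each observation carries its own bath composition, so occupancy
data at one concentration and current data at another are handled
consistently.  The pore diffusivity is fixed at a tenth of the bulk value by
default (a single shared D is optionally fitted); the fixed charge nf is a
reference, not a fitted parameter.  A deterministic multistart (fixed seed,
uniform draws in the box) guards against local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import DEFAULT_SOLVENT_MOLARITY, DEFAULT_TEMPERATURE
from .ensemble import BathState, EnergyParams, SiteParams, solve_ensemble
from .transport import (
    DrivingForces,
    PoreGeometry,
    compute_transport,
    entry_barriers,
)

__all__ = [
    "OccupancyObservation",
    "CurrentObservation",
    "FitResult",
    "fit_site_potentials",
    "fit_diagnostics",
]

DEFAULT_PORE_DIFFUSIVITY = 1.33e-10  # m^2/s, a tenth of the bulk value


@dataclass(frozen=True)
class OccupancyObservation:
    """Mean occupancy of one site at one bath concentration."""

    site: int  # 1-based, S1..S4
    mean_occupancy: float
    bath_c: float  # mol/L
    se: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.site <= 4:
            raise ValueError(f"site must be 1..4, got {self.site}")
        if not 0.0 <= self.mean_occupancy <= 1.0:
            raise ValueError(
                f"mean occupancy must lie in [0,1], got {self.mean_occupancy}"
            )
        if self.bath_c <= 0:
            raise ValueError(f"bath concentration must be positive, got {self.bath_c}")


@dataclass(frozen=True)
class CurrentObservation:
    """Single-channel current at one voltage and bath pair."""

    voltage: float  # V
    current: float  # A
    bath_c_L: float  # mol/L, intracellular side
    bath_c_R: float  # mol/L

    def __post_init__(self) -> None:
        if not (math.isfinite(self.voltage) and math.isfinite(self.current)):
            raise ValueError("voltage and current must be finite")
        if self.bath_c_L <= 0 or self.bath_c_R <= 0:
            raise ValueError("bath concentrations must be positive")


@dataclass
class FitResult:
    dmu_hat: np.ndarray
    D_hat: float
    ssr: float
    residuals: np.ndarray
    n_starts: int
    converged: bool
    seed: int = 0
    start_ssr: list[float] = field(default_factory=list)


class UnderdeterminedFitError(ValueError):
    """Raised when the observation set cannot pin down the parameters."""


def _model_residuals(
    dmu: np.ndarray,
    D: float,
    occ: list[OccupancyObservation],
    iv: list[CurrentObservation],
    ep: EnergyParams,
    geom: PoreGeometry,
    cw: float,
    T: float,
    weight: float,
) -> np.ndarray:
    sp = SiteParams(dmu=tuple(dmu), D=(D,) * 4)
    res = []
    # one ensemble solve per distinct occupancy bath
    ens_cache: dict[float, np.ndarray] = {}
    for ob in occ:
        if ob.bath_c not in ens_cache:
            ens = solve_ensemble(ep, sp, BathState(ob.bath_c, cw=cw, T=T))
            ens_cache[ob.bath_c] = ens.occupancy
        res.append(ens_cache[ob.bath_c][ob.site - 1] - ob.mean_occupancy)
    for cb in iv:
        c_mean = 0.5 * (cb.bath_c_L + cb.bath_c_R)
        bath = BathState(c_mean, cw=cw, T=T)
        forces = DrivingForces.from_baths(cb.bath_c_L, cb.bath_c_R, dphi=cb.voltage)
        tr = compute_transport(ep, sp, bath, geom, forces)
        res.append((tr.current - cb.current) / weight)
    return np.asarray(res)


def fit_site_potentials(
    occ: list[OccupancyObservation],
    iv: list[CurrentObservation],
    ep: EnergyParams | None = None,
    geom: PoreGeometry | None = None,
    *,
    bounds: tuple[float, float] = (0.0, 8.0),
    n_starts: int = 8,
    seed: int = 0,
    fit_D: bool = False,
    D: float = DEFAULT_PORE_DIFFUSIVITY,
    current_weight: float | None = None,
    cw: float = DEFAULT_SOLVENT_MOLARITY,
    T: float = DEFAULT_TEMPERATURE,
) -> FitResult:
    """Joint least-squares fit of the four site excess potentials.

    Requires occupancy observations covering all four sites and at least one
    current observation (the current fixes the overall magnitude scale).
    Returns the best of ``n_starts`` bounded least-squares runs started from
    a seeded uniform draw in the box; the objective is deterministic, so the
    result is reproducible and independent of observation order.
    """
    ep = ep or EnergyParams()
    geom = geom or PoreGeometry()
    if not occ:
        raise UnderdeterminedFitError("no occupancy observations: fit is under-determined")
    if len({ob.site for ob in occ}) < 4:
        raise UnderdeterminedFitError(
            "occupancy observations must cover all four sites"
        )
    if fit_D and not iv:
        raise UnderdeterminedFitError(
            "diffusivity is only identifiable from current data"
        )
    occ = sorted(occ, key=lambda o: (o.bath_c, o.site))
    iv = sorted(iv, key=lambda o: (o.voltage, o.bath_c_L, o.bath_c_R))
    if current_weight is None:
        current_weight = max((abs(cb.current) for cb in iv), default=1.0) or 1.0

    lo, hi = bounds
    rng = np.random.default_rng(seed)
    starts = rng.uniform(lo, hi, size=(max(1, n_starts), 4))
    # log10(D) is the natural scale when D is free
    if fit_D:
        logD_bounds = (math.log10(D) - 2.0, math.log10(D) + 2.0)
        starts = np.column_stack([starts, np.full(len(starts), math.log10(D))])

    def objective(theta: np.ndarray) -> np.ndarray:
        dmu = theta[:4]
        d_val = 10.0 ** theta[4] if fit_D else D
        return _model_residuals(dmu, d_val, occ, iv, ep, geom, cw, T, current_weight)

    lower = [lo] * 4 + ([logD_bounds[0]] if fit_D else [])
    upper = [hi] * 4 + ([logD_bounds[1]] if fit_D else [])

    best = None
    start_ssr: list[float] = []
    any_converged = False
    for x0 in starts:
        sol = least_squares(objective, x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12)
        ssr = float(2.0 * sol.cost)
        start_ssr.append(ssr)
        any_converged = any_converged or sol.success
        if best is None or ssr < best[0]:
            best = (ssr, sol)
    assert best is not None
    ssr, sol = best
    dmu_hat = sol.x[:4].copy()
    D_hat = 10.0 ** sol.x[4] if fit_D else D
    return FitResult(
        dmu_hat=dmu_hat,
        D_hat=float(D_hat),
        ssr=ssr,
        residuals=sol.fun.copy(),
        n_starts=len(starts),
        converged=any_converged,
        seed=seed,
        start_ssr=start_ssr,
    )


def fit_diagnostics(
    fit: FitResult,
    occ: list[OccupancyObservation],
    iv: list[CurrentObservation],
    ep: EnergyParams | None = None,
    geom: PoreGeometry | None = None,
    *,
    barrier_c: float = 0.14,
    cw: float = DEFAULT_SOLVENT_MOLARITY,
    T: float = DEFAULT_TEMPERATURE,
) -> dict:
    """Post-fit report: per-observation residuals, implied entry barriers at
    ``barrier_c`` mol/L and implied occupancies at every observed bath."""
    ep = ep or EnergyParams()
    geom = geom or PoreGeometry()
    occ = sorted(occ, key=lambda o: (o.bath_c, o.site))
    iv = sorted(iv, key=lambda o: (o.voltage, o.bath_c_L, o.bath_c_R))
    weight = max((abs(cb.current) for cb in iv), default=1.0) or 1.0
    res = _model_residuals(
        fit.dmu_hat, fit.D_hat, occ, iv, ep, geom, cw, T, weight
    )
    if len(res) != len(occ) + len(iv):
        raise ValueError("observation sets do not match the fitted residual vector")
    sp = SiteParams(dmu=tuple(fit.dmu_hat), D=(fit.D_hat,) * 4)
    barriers = entry_barriers(ep, sp, BathState(barrier_c, cw=cw, T=T), from_n=2)
    implied_occ = {
        c: solve_ensemble(ep, sp, BathState(c, cw=cw, T=T)).occupancy.tolist()
        for c in sorted({ob.bath_c for ob in occ})
    }
    return {
        "dmu_hat": fit.dmu_hat.tolist(),
        "D_hat": fit.D_hat,
        "ssr": float(res @ res),
        "occupancy_residuals": res[: len(occ)].tolist(),
        "current_residuals": res[len(occ):].tolist(),
        "entry_barriers_kT": barriers.tolist(),
        "barrier_concentration_M": barrier_c,
        "implied_occupancy": implied_occ,
    }
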