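"""Whole-cell comparison pipeline.

Whole-cell recordings sum the current through every channel in a cell.
Under the assumption that the number of channels and their open probability
are constant within a recording, the series can be normalised by the peak
current — here the current at -10 mV with 140 mM bath Na — and treated as a
single effective channel.  This module produces the theoretical counterpart
of such a series: for each bath composition the equilibrium ensemble is
built at the mean of the two bulk concentrations, the linear-response
current is evaluated on the voltage grid, and everything is normalised by
the reference-point magnitude.  The ratio of experimental to theoretical
current then estimates the effective open probability P_eff, defined up to
the (unknown) open probability at peak current P_max:
P_open(V) = P_eff(V) * P_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    CONCENTRATION_CLAMP,
    DEFAULT_SOLVENT_MOLARITY,
    DEFAULT_TEMPERATURE,
)
from .ensemble import BathState, EnergyParams, SiteParams
from .transport import (
    DrivingForces,
    PoreGeometry,
    compute_transport,
    reversal_potential,
)

__all__ = [
    "BathSeriesPoint",
    "GatingEstimate",
    "wholecell_iv_series",
    "effective_open_probability",
    "current_concentration_curve",
    "DEFAULT_VOLTAGE_GRID",
    "REFERENCE_BATH",
    "REFERENCE_VOLTAGE",
]

DEFAULT_VOLTAGE_GRID = np.arange(-100e-3, 60e-3 + 1e-9, 10e-3)  # V
REFERENCE_BATH = 0.14  # mol/L Na in the bath at the normalisation point
REFERENCE_VOLTAGE = -10e-3  # V, the peak-current voltage
VOLTAGE_MATCH_TOL = 0.5e-3  # V, nearest-voltage alignment tolerance


@dataclass
class BathSeriesPoint:
    """One bath composition of a whole-cell series: raw and normalised
    theoretical currents on the voltage grid, plus the Nernst reversal
    potential (bath minus pipette convention)."""

    bath_Na: float  # mol/L (nominal; 0 allowed, clamped downstream)
    pipette_Na: float  # mol/L
    voltages: np.ndarray  # V
    raw_current: np.ndarray  # A
    normalized_current: np.ndarray
    phi_rev: float  # V


@dataclass
class GatingEstimate:
    """Effective open probability per grid point.  Entries where the
    theoretical current is below the masking floor are NaN.  Values outside
    [0,1] (including negative ones, where theory and data disagree in sign)
    are reported as-is."""

    p_eff: np.ndarray
    p_max: float | None = None

    @property
    def p_open(self) -> np.ndarray | None:
        if self.p_max is None:
            return None
        return self.p_eff * self.p_max


def _series_current(
    bath_Na: float,
    pipette_Na: float,
    voltages: np.ndarray,
    ep: EnergyParams,
    sp: SiteParams,
    geom: PoreGeometry,
    cw: float,
    T: float,
    clamp: float,
) -> np.ndarray:
    """Linear-response current (A) on a voltage grid for one bath pair.

    The equilibrium reference is the arithmetic mean of the two (clamped)
    bulk concentrations; the chemical gradient drives from pipette (side L,
    intracellular) to bath.
    """
    c_bath = max(bath_Na, clamp)
    c_pip = max(pipette_Na, clamp)
    bath = BathState(0.5 * (c_bath + c_pip), cw=cw, T=T)
    out = np.empty_like(voltages, dtype=float)
    for i, v in enumerate(voltages):
        forces = DrivingForces.from_baths(c_pip, c_bath, dphi=float(v), clamp=clamp)
        out[i] = compute_transport(ep, sp, bath, geom, forces).current
    return out


def wholecell_iv_series(
    baths: list[float],
    pipette: float = 0.020,
    ep: EnergyParams | None = None,
    sp: SiteParams | None = None,
    geom: PoreGeometry | None = None,
    voltages: np.ndarray | None = None,
    *,
    cw: float = DEFAULT_SOLVENT_MOLARITY,
    T: float = DEFAULT_TEMPERATURE,
    clamp: float = CONCENTRATION_CLAMP,
    signed_reference: bool = False,
) -> list[BathSeriesPoint]:
    """Theoretical normalised IV curves for a series of bath Na levels.

    All currents are divided by the current at -10 mV with the 0.14 M
    reference bath — its absolute value by default, its signed value with
    ``signed_reference=True``.  The series must contain the reference bath.
    """
    ep = ep or EnergyParams()
    sp = sp or SiteParams()
    geom = geom or PoreGeometry()
    voltages = DEFAULT_VOLTAGE_GRID if voltages is None else np.asarray(voltages, float)
    if not any(abs(b - REFERENCE_BATH) < 1e-9 for b in baths):
        raise ValueError(
            f"bath series must include the {REFERENCE_BATH} M reference bath"
        )
    ref_current = _series_current(
        REFERENCE_BATH, pipette, np.array([REFERENCE_VOLTAGE]), ep, sp, geom, cw, T, clamp
    )[0]
    denom = ref_current if signed_reference else abs(ref_current)
    if denom == 0:
        raise ValueError("reference current is zero; cannot normalise")
    points = []
    for b in baths:
        raw = _series_current(b, pipette, voltages, ep, sp, geom, cw, T, clamp)
        points.append(
            BathSeriesPoint(
                bath_Na=b,
                pipette_Na=pipette,
                voltages=voltages.copy(),
                raw_current=raw,
                normalized_current=raw / denom,
                phi_rev=reversal_potential(max(b, clamp), pipette, clamp=clamp, T=T),
            )
        )
    return points


def effective_open_probability(
    I_exp: np.ndarray,
    I_theory: np.ndarray,
    floor: float = 1e-15,
) -> GatingEstimate:
    """Elementwise ratio I_exp/I_theory on matched (voltage, bath) grids.

    ``floor`` (A; default 1e-3 pA) masks points where the theoretical
    current is too small to divide by.  Ratios are not clipped: values
    above 1 or below 0 are genuine disagreements and are reported.
    """
    I_exp = np.asarray(I_exp, dtype=float)
    I_theory = np.asarray(I_theory, dtype=float)
    if I_exp.shape != I_theory.shape:
        raise ValueError(
            f"grid mismatch: experimental {I_exp.shape} vs theoretical {I_theory.shape}"
        )
    p_eff = np.full(I_exp.shape, np.nan)
    ok = np.abs(I_theory) >= floor
    p_eff[ok] = I_exp[ok] / I_theory[ok]
    return GatingEstimate(p_eff=p_eff)


def current_concentration_curve(
    ep: EnergyParams | None = None,
    sp: SiteParams | None = None,
    geom: PoreGeometry | None = None,
    voltage: float = 0.050,
    concentrations: list[float] | None = None,
    mode: str = "symmetric",
    *,
    pipette: float = 0.020,
    cw: float = DEFAULT_SOLVENT_MOLARITY,
    T: float = DEFAULT_TEMPERATURE,
    clamp: float = CONCENTRATION_CLAMP,
) -> pd.DataFrame:
    """Current versus bulk concentration at a fixed voltage.

    ``symmetric``: both baths at c, purely electrical driving.
    ``bath_series``: pipette fixed, bath swept; the electrochemical driving
    includes the chemical gradient and the equilibrium ensemble sits at the
    mean concentration.
    """
    if concentrations is None or len(concentrations) == 0:
        raise ValueError("concentrations must be a non-empty list")
    if mode not in ("symmetric", "bath_series"):
        raise ValueError(f"mode must be 'symmetric' or 'bath_series', got {mode!r}")
    ep = ep or EnergyParams()
    sp = sp or SiteParams()
    geom = geom or PoreGeometry()
    rows = []
    for c in concentrations:
        if c <= 0 and mode == "symmetric":
            raise ValueError(f"symmetric-mode concentration must be positive, got {c}")
        if mode == "symmetric":
            bath = BathState(c, cw=cw, T=T)
            forces = DrivingForces(dphi=voltage)
            I = compute_transport(ep, sp, bath, geom, forces).current
            phi_rev = 0.0
        else:
            I = _series_current(
                c, pipette, np.array([voltage]), ep, sp, geom, cw, T, clamp
            )[0]
            phi_rev = reversal_potential(max(c, clamp), pipette, clamp=clamp, T=T)
        rows.append(
            {
                "concentration_M": c,
                "voltage_V": voltage,
                "current_A": I,
                "current_pA": I * 1e12,
                "phi_rev_V": phi_rev,
            }
        )
    return pd.DataFrame(rows)
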