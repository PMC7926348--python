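"""Linear-response transport through the four-site pore.

Near equilibrium the response of each site's mean occupancy to a small
electrochemical gradient is a fluctuation (Kubo) formula: the susceptibility
of site m to a chemical gradient is

    chi_m = Cov(n_m, N) / (2 kT V_m),      N = sum_m n_m,

i.e. the variance of the site's occupancy plus its covariances with every
other site, per site volume.  The electrical susceptibility is the same
object scaled by the mean voltage-drop fraction (2*nu_bar, equal to 1 at
nu_bar = 1/2).  A generalised Einstein relation converts susceptibility to a
per-site conductivity sigma_m = (z e)^2 D_m chi_m, and the sites compose in
series:

    I = (dphi + deta*kT/e) / R_total,   R_total = sum_m L_m / (A_m sigma_m).

One non-conducting site therefore blocks the whole pore.  Also here: entry
barriers, the fixed-charge value at which n- and (n+1)-ion ground states are
degenerate (resonant, barrier-less conduction), and the diffusion-limited
transit rate D/Lc^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np

from .constants import (
    ANGSTROM,
    CONCENTRATION_CLAMP,
    DEFAULT_TEMPERATURE,
    E_CHARGE,
    kT_joules,
    kT_over_e_volts,
)
from .ensemble import (
    BathState,
    EnergyParams,
    EnsembleResult,
    PoreConfiguration,
    SiteParams,
    electrostatic_energy,
    enumerate_configurations,
    perturbed_occupancies,
    solve_ensemble,
)

__all__ = [
    "PoreGeometry",
    "DrivingForces",
    "TransportResult",
    "mole_fraction",
    "chemical_gradient",
    "susceptibilities",
    "finite_difference_susceptibility",
    "site_conductivity",
    "total_resistance",
    "pore_current",
    "reversal_potential",
    "entry_barriers",
    "resonance_charge",
    "diffusion_limited_rate",
    "compute_transport",
]

# Site geometry of the NaChBac selectivity filter (homology model, PMF-based
# estimates): per-site radius/length/area/volume, S1..S4 intra->extracellular.
_DEFAULT_RADIUS = (3.06, 2.77, 2.75, 2.77)  # Å
_DEFAULT_LENGTH = (3.0, 4.0, 3.0, 2.0)  # Å
_DEFAULT_AREA = (116.0, 126.0, 90.0, 78.0)  # Å^2
_DEFAULT_VOLUME = (117.0, 129.0, 80.0, 63.0)  # Å^3


@dataclass(frozen=True)
class PoreGeometry:
    """Per-site pore geometry in Å units, with SI accessors."""

    radius: tuple[float, ...] = _DEFAULT_RADIUS
    length: tuple[float, ...] = _DEFAULT_LENGTH
    area: tuple[float, ...] = _DEFAULT_AREA
    volume: tuple[float, ...] = _DEFAULT_VOLUME
    Lc: float = 12.0

    def __post_init__(self) -> None:
        for name in ("radius", "length", "area", "volume"):
            vals = getattr(self, name)
            object.__setattr__(self, name, tuple(float(v) for v in vals))
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"geometry field {name} must be positive")
        if self.Lc <= 0:
            raise ValueError("total filter length Lc must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.volume)

    @property
    def volume_m3(self) -> np.ndarray:
        return np.asarray(self.volume) * ANGSTROM**3

    @property
    def area_m2(self) -> np.ndarray:
        return np.asarray(self.area) * ANGSTROM**2

    @property
    def length_m(self) -> np.ndarray:
        return np.asarray(self.length) * ANGSTROM


@dataclass(frozen=True)
class DrivingForces:
    """Electrochemical driving: applied potential dphi (V, side L minus R),
    chemical gradient deta (kT), optional concentration difference dc (mol/L)
    and mean voltage-drop fraction nu_bar."""

    dphi: float = 0.0
    deta: float = 0.0
    dc: float = 0.0
    nu_bar: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.nu_bar < 1.0:
            raise ValueError(f"nu_bar must lie in (0,1), got {self.nu_bar}")

    @classmethod
    def from_baths(
        cls,
        c_left: float,
        c_right: float,
        dphi: float = 0.0,
        clamp: float = CONCENTRATION_CLAMP,
        nu_bar: float = 0.5,
    ) -> "DrivingForces":
        """Build driving forces from two bath concentrations (mol/L).

        Side L is the intracellular/pipette side.
        """
        deta = chemical_gradient(c_left, c_right, clamp=clamp)
        return cls(dphi=dphi, deta=deta, dc=c_left - c_right, nu_bar=nu_bar)


@dataclass
class TransportResult:
    """Per-site susceptibilities (SI, 1/(J m^3)), conductivities (S/m),
    resistances (Ohm), and total series current (A)."""

    chi_eta: np.ndarray
    chi_phi: np.ndarray
    sigma: np.ndarray
    resistance: np.ndarray
    current: float
    blocked: bool = False
    negative_chi: bool = False

    @property
    def current_pA(self) -> float:
        return self.current * 1e12

    @property
    def total_resistance(self) -> float:
        return float(self.resistance.sum())


def mole_fraction(c: float, cw: float) -> float:
    """Solute mole fraction x = c/cw."""
    if c <= 0 or cw <= 0:
        raise ValueError(f"concentrations must be positive, got c={c}, cw={cw}")
    return c / cw


def chemical_gradient(
    cL: float, cR: float, clamp: float = CONCENTRATION_CLAMP
) -> float:
    """Chemical driving deta = ln(xL/xR) in kT.

    Both concentrations are floored at ``clamp`` (default 0.1 mM) before the
    log so a nominally Na-free bath yields a finite gradient.
    """
    if cL <= 0 and clamp <= 0:
        raise ValueError("cL is non-positive and clamp does not rescue it")
    if cR <= 0 and clamp <= 0:
        raise ValueError("cR is non-positive and clamp does not rescue it")
    if cL < 0 or cR < 0:
        raise ValueError(f"concentrations must be non-negative, got {cL}, {cR}")
    return math.log(max(cL, clamp) / max(cR, clamp))


def susceptibilities(
    ens: EnsembleResult,
    geom: PoreGeometry,
    forces: DrivingForces,
    bath: BathState,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-site susceptibilities (chi_eta, chi_phi) in 1/(J m^3).

    chi_eta_m = Cov(n_m, N)/(2 kT V_m); chi_phi_m = 2*nu_bar*chi_eta_m.
    """
    V = geom.volume_m3
    if np.any(V <= 0):
        raise ValueError("site volumes must be positive")
    kT = kT_joules(bath.T)
    cov_with_total = ens.covariance.sum(axis=1)  # Cov(n_m, N)
    chi_eta = cov_with_total / (2.0 * kT * V)
    chi_phi = 2.0 * forces.nu_bar * chi_eta
    return chi_eta, chi_phi


def finite_difference_susceptibility(
    ep: EnergyParams,
    sp: SiteParams,
    bath: BathState,
    geom: PoreGeometry,
    which: Literal["eta", "phi"] = "eta",
    step: float = 1e-4,
    nu_bar: float = 0.5,
) -> np.ndarray:
    """Susceptibility by central finite difference of the perturbed ensemble.

    Independent oracle for :func:`susceptibilities`: the gradient enters the
    configuration free energy as -N*delta/2 (chemical, delta in kT) or
    -N*z*nu_bar*u (electrical, u = e*dphi/kT), the mean occupancies of the
    perturbed distribution are differentiated symmetrically, and the result
    is converted to SI per-volume units.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    configs = enumerate_configurations(sp.n_sites)
    N = np.array([c.n for c in configs], dtype=float)
    if which == "eta":
        shift = -N / 2.0
    elif which == "phi":
        shift = -N * ep.z * nu_bar
    else:
        raise ValueError(f"which must be 'eta' or 'phi', got {which!r}")
    occ_plus = perturbed_occupancies(ep, sp, bath, shift * step)
    occ_minus = perturbed_occupancies(ep, sp, bath, -shift * step)
    deriv = (occ_plus - occ_minus) / (2.0 * step)
    return deriv / (kT_joules(bath.T) * geom.volume_m3)


def site_conductivity(
    chi_eta: np.ndarray,
    chi_phi: np.ndarray,
    sp: SiteParams,
    z: int = 1,
) -> np.ndarray:
    """Per-site conductivity via the Einstein relation, S/m.

    sigma_m = (z e)^2 D_m (chi_phi_m + chi_eta_m)/2 — the mean of the two
    susceptibilities, which coincide at nu_bar = 1/2 so this reduces to
    (z e)^2 D_m chi_m.  (The alternative reading, summing the two without
    the half, would double every conductivity; it is not used.)  Negative
    susceptibilities propagate to negative sigma rather than being clipped.
    """
    chi = (np.asarray(chi_eta) + np.asarray(chi_phi)) / 2.0
    return (z * E_CHARGE) ** 2 * np.asarray(sp.D) * chi


def total_resistance(sigma: np.ndarray, geom: PoreGeometry) -> np.ndarray:
    """Per-site series resistances R_m = L_m/(A_m sigma_m), Ohm.

    Sites with non-positive conductivity get infinite resistance.
    """
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore"):
        R = np.where(sigma > 0, geom.length_m / (geom.area_m2 * sigma), np.inf)
    return R


def pore_current(
    sigma: np.ndarray,
    geom: PoreGeometry,
    forces: DrivingForces,
    T: float = DEFAULT_TEMPERATURE,
) -> float:
    """Series current I = (dphi + deta*kT/e)/R_total in amperes.

    Positive current flows from side L (intracellular) to side R.  If any
    site is non-conducting the series path is blocked and the current is 0.
    """
    R = total_resistance(sigma, geom)
    if not np.all(np.isfinite(R)):
        return 0.0
    driving = forces.dphi + forces.deta * kT_over_e_volts(T)
    return driving / float(R.sum())


def compute_transport(
    ep: EnergyParams,
    sp: SiteParams,
    bath: BathState,
    geom: PoreGeometry,
    forces: DrivingForces,
) -> TransportResult:
    """Full linear-response pipeline: ensemble -> susceptibilities ->
    conductivities -> series current."""
    ens = solve_ensemble(ep, sp, bath)
    chi_eta, chi_phi = susceptibilities(ens, geom, forces, bath)
    sigma = site_conductivity(chi_eta, chi_phi, sp, z=ep.z)
    R = total_resistance(sigma, geom)
    blocked = bool(np.any(~np.isfinite(R)))
    current = pore_current(sigma, geom, forces, T=bath.T)
    return TransportResult(
        chi_eta=chi_eta,
        chi_phi=chi_phi,
        sigma=sigma,
        resistance=R,
        current=current,
        blocked=blocked,
        negative_chi=bool(np.any(chi_eta < 0)),
    )


def reversal_potential(
    cL: float,
    cR: float,
    clamp: float = CONCENTRATION_CLAMP,
    T: float = DEFAULT_TEMPERATURE,
) -> float:
    """Nernst reversal potential phi_rev = (kT/e) ln(xL/xR) in volts, with
    the same concentration clamp as :func:`chemical_gradient`."""
    return kT_over_e_volts(T) * chemical_gradient(cL, cR, clamp=clamp)


def _best_dmu_sum(dmu: tuple[float, ...], n: int) -> float:
    """Largest sum of excess potentials over any n-site subset (the
    minimum-free-energy n-ion configuration at fixed n)."""
    if n == 0:
        return 0.0
    return max(sum(combo) for combo in combinations(dmu, n))


def entry_barriers(
    ep: EnergyParams,
    sp: SiteParams,
    bath: BathState,
    from_n: int = 2,
) -> np.ndarray:
    """Free-energy barrier (kT) to add the (from_n+1)-th ion to each site.

    Barrier_m = [E(from_n+1)-E(from_n)] - ln x - dmu_m
                + ln((from_n+1)!*(S-1-from_n)!) - ln(from_n!*(S-from_n)!)

    Electrostatic and combinatorial terms depend only on the ion count, so
    the barrier is independent of which sites hold the reference ions.
    Raising the bulk concentration lowers every barrier by the same amount.
    """
    S = sp.n_sites
    if not 0 <= from_n <= S - 1:
        raise ValueError(f"from_n must be in [0, {S - 1}], got {from_n}")
    cfg_lo = PoreConfiguration((1,) * from_n + (0,) * (S - from_n))
    cfg_hi = PoreConfiguration((1,) * (from_n + 1) + (0,) * (S - from_n - 1))
    dE = electrostatic_energy(cfg_hi, ep) - electrostatic_energy(cfg_lo, ep)
    comb = (
        math.lgamma(from_n + 2)
        + math.lgamma(S - from_n)
        - math.lgamma(from_n + 1)
        - math.lgamma(S - from_n + 1)
    )
    return dE - bath.log_x - np.asarray(sp.dmu) + comb


def resonance_charge(
    ep: EnergyParams,
    sp: SiteParams,
    bath: BathState,
    n_lo: int = 2,
    combinatorial: bool = True,
) -> float:
    """Fixed charge nf* at which the minimum-free-energy n_lo- and
    (n_lo+1)-ion configurations are degenerate (resonant conduction).

    Since E = Uc (nf + z n)^2 has equal curvature for every n, the crossing
    is linear in nf:

        Uc*z*(2 nf + z(2 n_lo + 1)) + d_rest = 0

    with d_rest collecting the -ln x, best-subset dmu, and (optionally)
    combinatorial differences between the two ground states.  With dmu = 0,
    x = 1 and no combinatorial terms this reduces to nf* = -z(n_lo + 1/2).
    """
    S = sp.n_sites
    if not 0 <= n_lo <= S - 1:
        raise ValueError(f"n_lo must be in [0, {S - 1}], got {n_lo}")
    if ep.Uc <= 0:
        raise ValueError("resonance requires Uc > 0")
    d_rest = -bath.log_x - (
        _best_dmu_sum(sp.dmu, n_lo + 1) - _best_dmu_sum(sp.dmu, n_lo)
    )
    if combinatorial:
        d_rest += (
            math.lgamma(n_lo + 2)
            + math.lgamma(S - n_lo)
            - math.lgamma(n_lo + 1)
            - math.lgamma(S - n_lo + 1)
        )
    return -(ep.z * (2 * n_lo + 1)) / 2.0 - d_rest / (2.0 * ep.Uc * ep.z)


def diffusion_limited_rate(D: float, Lc: float) -> float:
    """Barrier-free transit rate D/Lc^2 in ions/s (D in m^2/s, Lc in Å)."""
    if D <= 0 or Lc <= 0:
        raise ValueError(f"D and Lc must be positive, got D={D}, Lc={Lc}")
    return D / (Lc * ANGSTROM) ** 2
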