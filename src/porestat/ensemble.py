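"""Exact grand-canonical ensemble of the discrete-site pore.

The selectivity filter is a lattice of ``n_sites`` binding sites (default 4,
labelled S1..S4 from the intracellular to the extracellular side), each
occupied by at most one ion of a single permeant species.  A configuration
is a tuple of site indicators; with 4 sites there are 16 configurations and
every thermodynamic quantity is an exact sum over them.

The free energy of a configuration, in kT, is

    G({n}) = Uc*(nf + z*n)^2  -  sum_m n_m*(ln x + dmu_m)
             + ln(n0!) + ln(n!)

where ``x = c/cw`` is the bulk mole fraction, ``dmu_m`` the excess chemical
potential of site m relative to bulk, ``n`` the ion count, ``n0`` the number
of empty sites, and the quadratic term is the capacitor estimate of the
electrostatic energy of a pore of effective fixed charge ``nf``.  The
factorial terms account for indistinguishability of ions and vacancies.
Configuration probabilities are Boltzmann weights exp(-G) normalised over
the full state space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_SOLVENT_MOLARITY, DEFAULT_TEMPERATURE

__all__ = [
    "PoreConfiguration",
    "EnergyParams",
    "SiteParams",
    "BathState",
    "EnsembleResult",
    "enumerate_configurations",
    "electrostatic_energy",
    "configuration_free_energy",
    "solve_ensemble",
]


@dataclass(frozen=True)
class PoreConfiguration:
    """One occupancy pattern of the filter sites.

    ``occupancy[m] == 1`` means site m holds an ion; index 0 is S1
    (intracellular end).
    """

    occupancy: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.occupancy:
            raise ValueError("occupancy must have at least one site")
        if any(o not in (0, 1) for o in self.occupancy):
            raise ValueError(f"site indicators must be 0 or 1, got {self.occupancy}")

    @property
    def n(self) -> int:
        """Total number of ions in the pore."""
        return sum(self.occupancy)

    @property
    def n0(self) -> int:
        """Number of empty sites."""
        return len(self.occupancy) - self.n


@dataclass(frozen=True)
class EnergyParams:
    """Capacitor electrostatics: E(n) = Uc*(nf + z*n)^2.

    Uc is the self-energy e^2/2C in kT; nf the effective fixed pore charge
    in units of e (non-integer values encode partial charges/protonation);
    z the ionic valence.
    """

    Uc: float = 10.0
    nf: float = -2.5
    z: int = 1

    def __post_init__(self) -> None:
        if self.Uc < 0:
            raise ValueError(f"Uc must be non-negative, got {self.Uc}")
        if self.z == 0:
            raise ValueError("ionic valence z must be non-zero")


@dataclass(frozen=True)
class SiteParams:
    """Per-site excess chemical potentials (kT, bulk minus site) and
    diffusivities (m^2/s)."""

    dmu: tuple[float, ...] = (2.3, 3.4, 2.8, 2.4)
    D: tuple[float, ...] = (1.33e-10,) * 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "dmu", tuple(float(v) for v in self.dmu))
        object.__setattr__(self, "D", tuple(float(v) for v in self.D))
        if len(self.dmu) != len(self.D):
            raise ValueError("dmu and D must have the same length")
        if not all(math.isfinite(v) for v in self.dmu):
            raise ValueError("dmu must be finite")
        if any(d <= 0 for d in self.D):
            raise ValueError("diffusivities must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.dmu)


@dataclass(frozen=True)
class BathState:
    """Bulk reservoir: solute concentration c (mol/L), solvent concentration
    cw (mol/L), temperature (K), reference potential (V) and excess chemical
    potential reference (kT)."""

    c: float
    cw: float = DEFAULT_SOLVENT_MOLARITY
    T: float = DEFAULT_TEMPERATURE
    phi: float = 0.0
    mu0_excess: float = 0.0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"solute concentration must be positive, got {self.c}")
        if self.cw <= 0:
            raise ValueError(f"solvent concentration must be positive, got {self.cw}")
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.c >= self.cw:
            raise ValueError(
                f"solute concentration {self.c} M must be below solvent {self.cw} M"
            )

    @property
    def x(self) -> float:
        """Bulk mole fraction c/cw."""
        return self.c / self.cw

    @property
    def log_x(self) -> float:
        return math.log(self.x)


@dataclass
class EnsembleResult:
    """Exact ensemble summary: partition function, per-configuration
    probabilities (in enumeration order), per-site mean occupancies,
    occupancy covariance matrix and the grand potential Omega = -ln Z (kT)."""

    Z: float
    probabilities: np.ndarray
    occupancy: np.ndarray
    covariance: np.ndarray
    grand_potential: float
    configurations: list[PoreConfiguration] = field(default_factory=list)

    @property
    def total_occupancy(self) -> float:
        """Mean total ion count <N>."""
        return float(self.occupancy.sum())


def enumerate_configurations(n_sites: int = 4) -> list[PoreConfiguration]:
    """All 2^n_sites occupancy patterns in binary order, S1 least significant.

    The order is the canonical indexing used by every array-valued output of
    this module.
    """
    if not isinstance(n_sites, (int, np.integer)) or n_sites < 1:
        raise ValueError(f"n_sites must be a positive integer, got {n_sites!r}")
    return [
        PoreConfiguration(tuple((k >> m) & 1 for m in range(n_sites)))
        for k in range(2**n_sites)
    ]


def electrostatic_energy(config: PoreConfiguration, ep: EnergyParams) -> float:
    """Capacitor energy Uc*(nf + z*n)^2 in kT; depends only on the ion count."""
    return ep.Uc * (ep.nf + ep.z * config.n) ** 2


def configuration_free_energy(
    config: PoreConfiguration,
    ep: EnergyParams,
    sp: SiteParams,
    bath: BathState,
) -> float:
    """Free energy G of one configuration in kT (see module docstring).

    Configurations with the same ion count differ only through the
    sum of site excess potentials over the occupied sites.
    """
    if len(config.occupancy) != sp.n_sites:
        raise ValueError(
            f"configuration has {len(config.occupancy)} sites, "
            f"SiteParams has {sp.n_sites}"
        )
    g = electrostatic_energy(config, ep)
    for occ, dmu in zip(config.occupancy, sp.dmu):
        if occ:
            g -= bath.log_x + dmu
    g += math.lgamma(config.n0 + 1) + math.lgamma(config.n + 1)
    return g


def _free_energy_table(
    ep: EnergyParams, sp: SiteParams, bath: BathState
) -> tuple[list[PoreConfiguration], np.ndarray, np.ndarray]:
    """Configurations, occupancy matrix (n_config x n_sites) and G vector."""
    configs = enumerate_configurations(sp.n_sites)
    occ = np.array([c.occupancy for c in configs], dtype=float)
    G = np.array([configuration_free_energy(c, ep, sp, bath) for c in configs])
    return configs, occ, G


def solve_ensemble(ep: EnergyParams, sp: SiteParams, bath: BathState) -> EnsembleResult:
    """Exact ensemble over all configurations.

    Probabilities are exp(-G) normalised with the minimum G subtracted
    before exponentiation, so the result is invariant to a uniform shift of
    the free energies and safe against overflow.
    """
    configs, occ, G = _free_energy_table(ep, sp, bath)
    g_shift = G - G.min()
    w = np.exp(-g_shift)
    p = w / w.sum()
    mean_occ = p @ occ
    second = (occ * p[:, None]).T @ occ  # <n_m n_m'>
    cov = second - np.outer(mean_occ, mean_occ)
    log_Z = float(logsumexp(-G))
    return EnsembleResult(
        Z=math.exp(log_Z),
        probabilities=p,
        occupancy=mean_occ,
        covariance=cov,
        grand_potential=-log_Z,
        configurations=configs,
    )


def perturbed_occupancies(
    ep: EnergyParams,
    sp: SiteParams,
    bath: BathState,
    energy_shift: Sequence[float],
) -> np.ndarray:
    """Mean site occupancies under per-configuration energy shifts (kT).

    Used by the finite-difference susceptibility oracle: the shift vector is
    added to G configuration-by-configuration before re-normalising.
    """
    _, occ, G = _free_energy_table(ep, sp, bath)
    shift = np.asarray(energy_shift, dtype=float)
    if shift.shape != G.shape:
        raise ValueError(f"energy_shift must have shape {G.shape}, got {shift.shape}")
    Gp = G + shift
    w = np.exp(-(Gp - Gp.min()))
    p = w / w.sum()
    return p @ occ
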