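"""Synthetic data with the statistical structure the analysis assumes.

Three generators emulate the three kinds of input the pipeline consumes:

* block-averaged equilibrium site occupancies at 0.5 M (the molecular-
  dynamics condition) with Gaussian block noise;
* Ohmic single-channel IV records in symmetric 0.14 M baths with
  multiplicative amplitude noise;
* whole-cell normalised IV series over a bath-dilution ladder, distorted by
  a Boltzmann gating sigmoid so the current collapses at hyperpolarised
  voltages, plus additive SEM-scale noise.

Every generator is driven by a ``TruthRecord`` carrying the ground-truth
parameters and a seed; regeneration from the same record is bit-identical,
and different seeds share the identical noiseless core.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .constants import CONCENTRATION_CLAMP, DEFAULT_SOLVENT_MOLARITY, DEFAULT_TEMPERATURE
from .ensemble import BathState, EnergyParams, SiteParams, solve_ensemble
from .fitting import CurrentObservation, OccupancyObservation, DEFAULT_PORE_DIFFUSIVITY
from .transport import DrivingForces, PoreGeometry, compute_transport
from .wholecell import (
    DEFAULT_VOLTAGE_GRID,
    REFERENCE_BATH,
    REFERENCE_VOLTAGE,
    _series_current,
)

__all__ = [
    "TruthRecord",
    "generate_occupancy_observations",
    "generate_singlechannel_iv",
    "generate_wholecell_dataset",
    "DEFAULT_BATH_SERIES",
]

# Bath Na dilution ladder (mol/L): 140 mM full strength down to nominally
# Na-free, NaCl replaced by equimolar KCl in the emulated protocol.
DEFAULT_BATH_SERIES = [0.140, 0.126, 0.100, 0.070, 0.035, 0.014, 0.0]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for a synthetic dataset.

    ``gating`` is (v_half, slope) in volts for the Boltzmann open-probability
    sigmoid P(V) = 1/(1+exp(-(V-v_half)/slope)); the defaults place the peak
    of the gated whole-cell current at -10 mV on the standard grid.
    """

    dmu_true: tuple[float, ...] = (2.3, 3.4, 2.8, 2.4)
    D_true: float = DEFAULT_PORE_DIFFUSIVITY
    nf: float = -2.5
    Uc: float = 10.0
    gating: tuple[float, float] = (-0.020, 0.007)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gating[1] <= 0:
            raise ValueError("gating slope must be positive")

    @property
    def energy_params(self) -> EnergyParams:
        return EnergyParams(Uc=self.Uc, nf=self.nf)

    @property
    def site_params(self) -> SiteParams:
        return SiteParams(dmu=self.dmu_true, D=(self.D_true,) * 4)

    def open_probability(self, voltage: np.ndarray | float) -> np.ndarray | float:
        from scipy.special import expit

        v_half, slope = self.gating
        return expit((np.asarray(voltage, float) - v_half) / slope)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        d["dmu_true"] = tuple(d["dmu_true"])
        d["gating"] = tuple(d["gating"])
        return cls(**d)


def generate_occupancy_observations(
    truth: TruthRecord,
    bath_c: float = 0.5,
    n_blocks: int = 50,
    noise_sd: float = 0.02,
    *,
    cw: float = DEFAULT_SOLVENT_MOLARITY,
    T: float = DEFAULT_TEMPERATURE,
    seed: int | None = None,
) -> list[OccupancyObservation]:
    """Block-averaged site occupancies around the exact ensemble means.

    Each of ``n_blocks`` block means is drawn Gaussian around the exact
    occupancy with sd ``noise_sd`` and truncated to [0,1]; the observation
    is the mean of blocks with its standard error.  ``noise_sd=0`` returns
    the exact model occupancies.
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ens = solve_ensemble(truth.energy_params, truth.site_params, BathState(bath_c, cw=cw, T=T))
    out = []
    for m, exact in enumerate(ens.occupancy, start=1):
        blocks = np.clip(
            exact + noise_sd * rng.standard_normal(n_blocks), 0.0, 1.0
        )
        mean = float(np.clip(blocks.mean(), 0.0, 1.0))
        se = float(blocks.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else noise_sd
        out.append(OccupancyObservation(site=m, mean_occupancy=mean, bath_c=bath_c, se=se))
    return out


def generate_singlechannel_iv(
    truth: TruthRecord,
    voltages: np.ndarray | None = None,
    bath_c: float = 0.14,
    rel_noise: float = 0.05,
    *,
    geom: PoreGeometry | None = None,
    cw: float = DEFAULT_SOLVENT_MOLARITY,
    T: float = DEFAULT_TEMPERATURE,
    seed: int | None = None,
) -> list[CurrentObservation]:
    """Ohmic single-channel IV records in symmetric baths.

    Multiplicative Gaussian amplitude noise (default 5%) preserves the zero
    crossing at 0 mV exactly.  Voltages outside the +/-100 mV Ohmic window
    are rejected — the linear-response theory does not extend there.
    """
    if voltages is None:
        voltages = np.arange(-100e-3, 100e-3 + 1e-9, 20e-3)
    voltages = np.asarray(voltages, dtype=float)
    if voltages.size == 0:
        raise ValueError("voltage list must be non-empty")
    if np.any(np.abs(voltages) > 0.100 + 1e-12):
        raise ValueError("voltages beyond +/-100 mV are outside the Ohmic regime")
    if rel_noise < 0:
        raise ValueError(f"rel_noise must be non-negative, got {rel_noise}")
    geom = geom or PoreGeometry()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    bath = BathState(bath_c, cw=cw, T=T)
    out = []
    for v in voltages:
        I = compute_transport(
            truth.energy_params, truth.site_params, bath, geom, DrivingForces(dphi=float(v))
        ).current
        I_obs = I * (1.0 + rel_noise * rng.standard_normal())
        out.append(
            CurrentObservation(voltage=float(v), current=float(I_obs), bath_c_L=bath_c, bath_c_R=bath_c)
        )
    return out


def generate_wholecell_dataset(
    truth: TruthRecord,
    bath_series: list[float] | None = None,
    pipette: float = 0.020,
    voltages: np.ndarray | None = None,
    sem: float = 0.05,
    *,
    geom: PoreGeometry | None = None,
    cw: float = DEFAULT_SOLVENT_MOLARITY,
    T: float = DEFAULT_TEMPERATURE,
    clamp: float = CONCENTRATION_CLAMP,
    seed: int | None = None,
) -> pd.DataFrame:
    """Whole-cell normalised IV series distorted by voltage gating.

    Theoretical currents are multiplied by the gating sigmoid, normalised by
    the absolute gated current at the (-10 mV, 0.14 M) reference point, and
    perturbed by additive Gaussian noise of scale ``sem``.  A nominally
    Na-free bath member is generated at the 0.1 mM clamp.
    """
    bath_series = DEFAULT_BATH_SERIES if bath_series is None else list(bath_series)
    if not any(abs(b - REFERENCE_BATH) < 1e-9 for b in bath_series):
        raise ValueError(f"bath series must include the {REFERENCE_BATH} M reference")
    voltages = DEFAULT_VOLTAGE_GRID if voltages is None else np.asarray(voltages, float)
    if sem < 0:
        raise ValueError(f"sem must be non-negative, got {sem}")
    geom = geom or PoreGeometry()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ep, sp = truth.energy_params, truth.site_params

    ref_raw = _series_current(
        REFERENCE_BATH, pipette, np.array([REFERENCE_VOLTAGE]), ep, sp, geom, cw, T, clamp
    )[0]
    ref = abs(ref_raw * truth.open_probability(REFERENCE_VOLTAGE))
    rows = []
    for b in bath_series:
        raw = _series_current(b, pipette, voltages, ep, sp, geom, cw, T, clamp)
        gated = raw * truth.open_probability(voltages)
        noisy = gated / ref + sem * rng.standard_normal(voltages.size)
        for v, nc in zip(voltages, noisy):
            rows.append(
                {
                    "bath_Na": b,
                    "pipette_Na": pipette,
                    "voltage": float(v),
                    "normalized_current": float(nc),
                    "sem": sem,
                }
            )
    return pd.DataFrame(rows)
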