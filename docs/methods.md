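# Methods

## Model

The selectivity filter is treated as a grand-canonical lattice gas: four
binding sites S1–S4 (intracellular → extracellular), single occupancy,
one permeant species (Na⁺; K⁺ and Cl⁻ are taken as non-permeant and
ignored). The 2⁴ = 16 configurations are enumerated exactly in binary
order with S1 as the least-significant site; every ensemble quantity is an
exact finite sum, so there is no sampling error anywhere in the
equilibrium layer.

The configuration free energy combines four terms (all in kT):

* **Electrostatics** — the pore is approximated as a capacitor,
  `E(n) = U_c (n_f + z n)²` with `U_c = e²/2C`. E depends only on the ion
  count, not on which sites are occupied. The effective fixed charge `n_f`
  absorbs the glutamate ring, partial charges and possible protonation,
  and is deliberately allowed to be non-integer.
* **Ideal insertion** — `−n ln x` with mole fraction `x = c/c_w`;
  the solvent concentration defaults to 55.5 M (water).
* **Site affinity** — `−Σ n_m Δμ̄_m`, the excess chemical potential of each
  site relative to bulk. This is the only term that splits equal-n
  configurations.
* **Mixing entropy** — `ln n₀! + ln n!` for indistinguishable ions and
  vacancies. Including these terms is what places the 2→3 resonance at
  n_f ≈ −2.70 rather than −2.68; the resonance check pins this reading of
  the distribution's prefactor.

Probabilities are computed as `exp(−(G − G_min))` normalised, making the
result invariant to any uniform shift of G and immune to overflow; the
partition function itself is evaluated with `logsumexp`.

## Transport

Linear response around equilibrium. The susceptibility of site m to a
chemical gradient is the fluctuation formula
`χ_m = Cov(n_m, N)/(2 kT V_m)`; the electrical susceptibility is the same
kernel scaled by `2ν̄`, where ν̄ is the mean fraction of the voltage drop
felt at a site. We collapse ν̄ to 1/2 for every site (symmetric pore); no
per-site voltage-drop profile is modelled, so the two susceptibilities
coincide and the Einstein relation `σ_m = (ze)² D_m (χ^δφ + χ^δη)/2`
reduces to `σ_m = (ze)² D_m χ_m`. Site conductivities compose in series,
`R_total = Σ L_m/(A_m σ_m)`, which encodes the physical statement that one
non-conducting site blocks the pore; a blocked path reports zero current
with a flag rather than an exception. Driving is
`δφ + δη·kT/e` with `δη = ln(x_L/x_R)` and side L the
intracellular/pipette side; current is positive from L to R.

The independent oracle for the susceptibilities is a central finite
difference of the perturbed ensemble (the gradient enters each
configuration's energy as `−N δη/2`). The randomized cross-check uses step
1e-2 kT: truncation there is ~1e-5 relative, while much smaller steps run
into the roundoff floor in near-frozen regimes (large U_c pins N, all
covariances with N cancel to ~1e-16 of the occupancy scale). At the
canonical parameter set the two routes agree to better than 1e-9 relative.

Asymmetric baths are handled by building the equilibrium reference
ensemble at the arithmetic mean of the two bulk concentrations; the
chemical gradient uses the actual pair. Concentrations are floored at
0.1 mM before any logarithm, so a nominally Na-free bath yields a finite
(~5 kT) gradient — that magnitude is at the edge of linear response, and
the Na-free member of a whole-cell series should be read with that caveat.

Derived diagnostics: the entry barrier for the (n+1)-th ion into site m,
`ΔG_m = [E(n+1)−E(n)] − ln x − Δμ̄_m + Δ(entropy terms)`, independent of
where the n resident ions sit; the resonant fixed charge `n_f*` solved in
closed form (E is quadratic with equal curvature in n_f, so the level
crossing is linear); and the diffusion-limited transit scale `D/L_c²`,
the natural upper bound on conduction (~9×10⁷ ions/s for
D = 1.33×10⁻¹⁰ m²/s and L_c = 12 Å, i.e. tens of pA).

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| Δμ̄₁..₄ | kT | 2.3, 3.4, 2.8, 2.4 | fitted set reproducing occupancies and current scale |
| U_c | kT | 10 | pore self-energy; water permittivity in the pore unknown but < 80 |
| n_f | e | −2.5 | reference where E(3) − E(2) = 0 (third-ion electrostatic cost vanishes) |
| D_m | m²/s | 1.33×10⁻¹⁰ | one tenth of bulk Na⁺ diffusivity, uniform across sites |
| c_w | mol/L | 55.5 | water |
| T | K | 298.15 | room temperature; kT/e = 25.693 mV |
| clamp | mol/L | 1e-4 | floor preventing divergent gradients at zero bath Na |
| geometry | Å | per-site table | PMF-derived site radii/lengths; spheroidal area/volume estimates |

Geometry (radius, length, area, volume per site): S1 3.06/3/116/117,
S2 2.77/4/126/129, S3 2.75/3/90/80, S4 2.77/2/78/63; total length 12 Å.

## Fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`) over
Δμ̄ ∈ [0, 8]⁴, jointly on occupancy residuals and current residuals
rescaled by `w = max|I_obs|` so both blocks are O(1); each observation
carries its own bath composition. Eight multistarts drawn uniformly in the
box from a fixed seed guard against local minima; the objective is
deterministic, so results are reproducible and independent of observation
order. D is fixed at a tenth of bulk by default — with occupancy data at a
single concentration and no current point, D is not identifiable (the
ensemble does not contain it), which is why the under-determined
configurations raise rather than fit. An optional flag fits a single
shared D on a log₁₀ scale.

## Whole-cell pipeline

Whole-cell series are normalised by the current at −10 mV with the 0.14 M
reference bath (absolute value by default; signed-value mode provided for
current–concentration plots). The effective open probability is the
elementwise ratio of experimental to theoretical current, masked (NaN)
where the theoretical current is below 1e-3 pA; ratios outside [0, 1] are
reported untouched — they are the interesting disagreements, not outliers
to clip. The reversal potential is Nernstian, `(kT/e) ln(x_L/x_R)`,
reported bath-minus-pipette so a 20 mM pipette against a clamped 0.1 mM
bath gives −136 mV.

## Synthetic data

The generators emulate the statistical structure of the three input kinds,
not their microscopic origin:

* occupancies: Gaussian block noise (sd 0.02, truncated to [0, 1]) around
  the exact ensemble means at 0.5 M — mean ± SE over 50 blocks, the shape
  in which MD block averages are reported. No autocorrelation between
  blocks is modelled.
* single-channel IV: exact linear-response currents in symmetric 0.14 M
  baths with 5% multiplicative amplitude noise, restricted to the
  ±100 mV Ohmic window. No gating noise, dwell times or capacitive
  transients.
* whole-cell series: theoretical currents over a bath ladder
  140 → 0 mM (0 clamped to 0.1 mM), multiplied by a Boltzmann gating
  sigmoid `P(V) = 1/(1+exp(−(V−v_half)/s))` with v_half = −20 mV,
  s = 7 mV — a phenomenological stand-in for voltage gating chosen so the
  gated peak lands at −10 mV on the standard −100…+60 mV grid — plus
  additive noise of SEM scale 0.05.

Every generator is driven by a `TruthRecord` (parameters + seed):
regeneration is bit-identical, and different seeds share the same
noiseless core. Because the generators draw from the same model family the
fitter assumes, parameter-recovery results demonstrate the estimator's
correctness and precision under the stated noise, not robustness to model
misspecification (real pores have voltage-dependent gating, non-Ohmic
tails, and correlated MD noise).

## Numerical choices and limitations

* All checks run on the exact 16-state ensemble; the recovery study uses
  50 replicates with 4 multistarts each (the objective is smooth and
  low-dimensional; more starts change nothing but runtime).
* Units: SI everywhere internally, energies in kT, geometry in Å with SI
  accessors; display units (mV, pA, mM) exist only at the I/O boundary.
* Linear response only: the theory is trusted for |V| ≲ 100 mV and
  gradients ≲ 5 kT; far-from-equilibrium kinetics, K⁺ block and
  mixed-species selectivity are out of scope.
* The 3.6 mM NaOH adjustment to the nominal 140 mM NaCl solutions is
  ignored (nominal concentrations used throughout); the config accepts
  arbitrary concentrations if a corrected value is preferred.
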