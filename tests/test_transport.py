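"""Transport-layer tests: susceptibilities against the finite-difference
oracle, series current composition, barriers, resonance and rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from porestat import (
    BathState,
    DrivingForces,
    EnergyParams,
    PoreGeometry,
    SiteParams,
    chemical_gradient,
    diffusion_limited_rate,
    entry_barriers,
    finite_difference_susceptibility,
    mole_fraction,
    pore_current,
    resonance_charge,
    reversal_potential,
    site_conductivity,
    solve_ensemble,
    susceptibilities,
)
from porestat.constants import kT_joules, kT_over_e_volts
from porestat.transport import compute_transport, total_resistance
from conftest import random_parameter_draw


class TestScalars:
    def test_mole_fraction(self):
        assert mole_fraction(0.14, 55.5) == pytest.approx(2.5225e-3, rel=1e-4)
        assert mole_fraction(0.5, 55.5) == pytest.approx(9.009e-3, rel=1e-4)
        assert mole_fraction(55.5, 55.5) == 1.0
        with pytest.raises(ValueError):
            mole_fraction(-1.0, 55.5)

    def test_chemical_gradient(self):
        assert chemical_gradient(0.020, 0.0001) == pytest.approx(5.30, abs=0.01)
        assert chemical_gradient(0.14, 0.14) == 0.0
        assert chemical_gradient(0.14, 0.02) == pytest.approx(math.log(7), rel=1e-12)
        # the clamp floors a zero concentration at 0.1 mM
        assert chemical_gradient(0.020, 0.0) == pytest.approx(5.2983, abs=1e-3)
        with pytest.raises(ValueError):
            chemical_gradient(0.0, 0.1, clamp=0.0)

    def test_reversal_potential(self):
        assert reversal_potential(0.14, 0.14) == 0.0
        # Na-free bath (clamped) against a 20 mM pipette, bath-minus-pipette
        phi = reversal_potential(0.0001, 0.020)
        assert phi * 1e3 == pytest.approx(25.693 * math.log(0.0001 / 0.020), abs=0.01)
        assert phi <= -35e-3
        # Nernst slope: a decade of concentration is ~59.2 mV
        assert reversal_potential(0.1, 0.01) * 1e3 == pytest.approx(59.2, abs=0.1)

    def test_diffusion_limited_rate(self):
        rate = diffusion_limited_rate(1.33e-10, 12.0)
        assert rate == pytest.approx(9.24e7, rel=0.01)
        # charge flux scale of the barrier-less pore is tens of pA
        assert rate * 1.602e-19 == pytest.approx(1.5e-11, rel=0.05)
        assert diffusion_limited_rate(1.33e-10, 24.0) == pytest.approx(rate / 4)


class TestSusceptibilities:
    def test_single_site_bernoulli(self):
        """For a one-site pore chi = p(1-p)/(2 kT V): the variance of a
        Bernoulli occupancy."""
        ep = EnergyParams(Uc=1.0, nf=-0.5)
        sp = SiteParams(dmu=(2.0,), D=(1e-10,))
        bath = BathState(0.14)
        geom = PoreGeometry(radius=(3.0,), length=(3.0,), area=(100.0,), volume=(100.0,), Lc=3.0)
        ens = solve_ensemble(ep, sp, bath)
        chi_eta, chi_phi = susceptibilities(ens, geom, DrivingForces(), bath)
        p = ens.occupancy[0]
        expected = p * (1 - p) / (2 * kT_joules(bath.T) * 100e-30)
        assert chi_eta[0] == pytest.approx(expected, rel=1e-12)
        assert chi_phi[0] == pytest.approx(chi_eta[0], rel=1e-12)  # nu_bar = 1/2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_closed_form_matches_finite_difference(self, seed):
        """Kubo fluctuation formula vs numerical derivative of the
        perturbed ensemble, for random parameter draws."""
        ep, sp, bath = random_parameter_draw(np.random.default_rng(seed))
        geom = PoreGeometry()
        ens = solve_ensemble(ep, sp, bath)
        chi_eta, chi_phi = susceptibilities(ens, geom, DrivingForces(), bath)
        # step 1e-2: truncation ~1e-5 while staying clear of the roundoff
        # floor that tiny covariances (near-frozen ion count) hit at 1e-4
        fd = finite_difference_susceptibility(ep, sp, bath, geom, "eta", step=1e-2)
        assert np.all(np.abs(fd - chi_eta) <= 1e-3 * np.abs(chi_eta))
        fd_phi = finite_difference_susceptibility(ep, sp, bath, geom, "phi", step=1e-2)
        assert np.allclose(fd_phi, chi_phi, rtol=1e-3)

    def test_fitted_parameters_tight_agreement(self, fitted_params, bath_014, geometry):
        """At the fitted parameter set the oracle agrees to better than
        relative 1e-4 even at step 1e-4."""
        ep, sp = fitted_params
        ens = solve_ensemble(ep, sp, bath_014)
        chi, _ = susceptibilities(ens, geometry, DrivingForces(), bath_014)
        fd = finite_difference_susceptibility(ep, sp, bath_014, geometry, "eta", step=1e-4)
        assert np.all(np.abs(fd - chi) <= 1e-4 * np.abs(chi))

    def test_second_order_convergence(self, fitted_params, bath_014, geometry):
        ep, sp = fitted_params
        ens = solve_ensemble(ep, sp, bath_014)
        chi, _ = susceptibilities(ens, geometry, DrivingForces(), bath_014)
        err = lambda h: np.abs(
            finite_difference_susceptibility(ep, sp, bath_014, geometry, "eta", step=h) - chi
        ).max()
        e1, e2 = err(2e-2), err(1e-2)
        assert e1 / e2 == pytest.approx(4.0, rel=0.15)

    def test_strong_coupling_pins_total_count(self, geometry):
        """Large Uc with nf = -2 freezes N = 2; the oracle must still agree
        with the closed form driven only by within-shell covariances."""
        ep = EnergyParams(Uc=200.0, nf=-2.0)
        sp = SiteParams(dmu=(2.3, 3.4, 2.8, 2.4))
        bath = BathState(0.14)
        ens = solve_ensemble(ep, sp, bath)
        assert ens.total_occupancy == pytest.approx(2.0, abs=1e-6)
        chi, _ = susceptibilities(ens, geometry, DrivingForces(), bath)
        fd = finite_difference_susceptibility(ep, sp, bath, geometry, "eta")
        # with N frozen Cov(n_m, N) vanishes identically: both routes must
        # agree on zero at the scale of the unpinned (Uc=10) susceptibility
        ens_ref = solve_ensemble(EnergyParams(Uc=10.0, nf=-2.0), sp, bath)
        chi_ref, _ = susceptibilities(ens_ref, geometry, DrivingForces(), bath)
        scale = np.abs(chi_ref).max()
        assert np.all(np.abs(chi) < 1e-9 * scale)
        assert np.all(np.abs(fd - chi) < 1e-9 * scale)

    def test_step_must_be_positive(self, fitted_params, bath_014, geometry):
        ep, sp = fitted_params
        with pytest.raises(ValueError):
            finite_difference_susceptibility(ep, sp, bath_014, geometry, "eta", step=0.0)


class TestConductivityAndCurrent:
    def test_einstein_relation_linearity(self, fitted_params, bath_014, geometry):
        ep, sp = fitted_params
        ens = solve_ensemble(ep, sp, bath_014)
        chi_eta, chi_phi = susceptibilities(ens, geometry, DrivingForces(), bath_014)
        sigma = site_conductivity(chi_eta, chi_phi, sp)
        sp2 = SiteParams(dmu=sp.dmu, D=tuple(2 * d for d in sp.D))
        assert np.allclose(site_conductivity(chi_eta, chi_phi, sp2), 2 * sigma)
        assert np.allclose(site_conductivity(np.zeros(4), np.zeros(4), sp), 0.0)

    def test_reversal_condition_zero_current(self, fitted_params, bath_014, geometry):
        ep, sp = fitted_params
        deta = 1.7
        forces = DrivingForces(dphi=-deta * kT_over_e_volts(), deta=deta)
        ens = solve_ensemble(ep, sp, bath_014)
        chi_eta, chi_phi = susceptibilities(ens, geometry, forces, bath_014)
        sigma = site_conductivity(chi_eta, chi_phi, sp)
        assert pore_current(sigma, geometry, forces) == pytest.approx(0.0, abs=1e-25)

    def test_ohms_law_composition(self):
        """Equal conductivities and no chemical gradient reduce to Ohm's
        law with the geometric series resistance."""
        geom = PoreGeometry()
        sigma = np.full(4, 0.05)
        forces = DrivingForces(dphi=0.010)
        expected = 0.010 * 0.05 / (geom.length_m / geom.area_m2).sum()
        assert pore_current(sigma, geom, forces) == pytest.approx(expected, rel=1e-12)

    def test_blocked_site_zeroes_current(self, geometry):
        sigma = np.array([0.05, 0.0, 0.05, 0.05])
        forces = DrivingForces(dphi=0.050)
        assert pore_current(sigma, geometry, forces) == 0.0
        assert np.isinf(total_resistance(sigma, geometry)[1])

    def test_series_order_invariance(self, geometry):
        sigma = np.array([0.01, 0.02, 0.04, 0.08])
        R = total_resistance(sigma, geometry).sum()
        perm = [2, 0, 3, 1]
        geom_p = PoreGeometry(
            radius=tuple(geometry.radius[i] for i in perm),
            length=tuple(geometry.length[i] for i in perm),
            area=tuple(geometry.area[i] for i in perm),
            volume=tuple(geometry.volume[i] for i in perm),
        )
        R_p = total_resistance(sigma[perm], geom_p).sum()
        assert R_p == pytest.approx(R, rel=1e-12)

    def test_current_sign_follows_driving(self, fitted_params, bath_014, geometry):
        ep, sp = fitted_params
        for dphi, deta in [(0.05, 0.0), (-0.05, 0.0), (0.0, 2.0), (0.0, -2.0), (0.02, -3.0)]:
            forces = DrivingForces(dphi=dphi, deta=deta)
            tr = compute_transport(ep, sp, bath_014, geometry, forces)
            driving = dphi + deta * kT_over_e_volts()
            assert math.copysign(1, tr.current) == math.copysign(1, driving) or driving == 0

    def test_small_current_at_two_molar(self, fitted_params, geometry):
        """Even at 2 M the predicted current stays below 10 pA: the overall
        entry barrier keeps the pore far from its diffusion limit."""
        ep, sp = fitted_params
        tr = compute_transport(ep, sp, BathState(2.0), geometry, DrivingForces(dphi=0.050))
        assert 0 < abs(tr.current_pA) < 10.0


class TestBarriers:
    def test_fitted_barriers_match_printed_values(self, fitted_params, bath_014):
        """Third-ion entry barriers ~ (4.0, 2.9, 3.6, 4.0) kT at 0.14 M."""
        ep, sp = fitted_params
        dg = entry_barriers(ep, sp, bath_014, from_n=2)
        assert np.allclose(dg, [4.088, 2.988, 3.588, 3.988], atol=2e-3)
        assert np.allclose(dg, [4.0, 2.9, 3.6, 4.0], atol=0.15)

    def test_concentration_shift_is_uniform(self, fitted_params):
        ep, sp = fitted_params
        d1 = entry_barriers(ep, sp, BathState(0.14), from_n=2)
        d2 = entry_barriers(ep, sp, BathState(0.5), from_n=2)
        shift = d1 - d2
        assert np.allclose(shift, math.log(0.5 / 0.14), atol=1e-12)
        assert np.all(d2 < d1)  # higher concentration lowers every barrier

    def test_pure_combinatorial_limit(self):
        """Uc=0, dmu=0, x=1: only the entropy term survives, -ln 4 for the
        first ion."""
        ep = EnergyParams(Uc=0.0, nf=0.0)
        sp = SiteParams(dmu=(0.0,) * 4)
        bath = BathState(55.49999, cw=55.5)  # x ~ 1
        dg = entry_barriers(ep, sp, bath, from_n=0)
        assert np.allclose(dg, -math.log(4), atol=1e-5)

    def test_most_favoured_site_smallest_barrier(self, fitted_params, bath_014, bath_05):
        ep, sp = fitted_params
        dg = entry_barriers(ep, sp, bath_014, from_n=2)
        assert np.argmin(dg) == np.argmax(sp.dmu) == 1
        ens = solve_ensemble(ep, sp, bath_05)
        assert np.argmax(ens.occupancy) == 1

    def test_full_pore_rejected(self, fitted_params, bath_014):
        ep, sp = fitted_params
        with pytest.raises(ValueError):
            entry_barriers(ep, sp, bath_014, from_n=4)


class TestResonance:
    def test_two_three_transition_near_minus_2p7(self, fitted_params, bath_014):
        ep, sp = fitted_params
        nf_star = resonance_charge(ep, sp, bath_014, n_lo=2)
        assert nf_star == pytest.approx(-2.70, abs=0.05)

    def test_pure_electrostatic_degeneracy(self):
        ep = EnergyParams(Uc=10.0, nf=-1.0)
        sp = SiteParams(dmu=(0.0,) * 4)
        bath = BathState(55.49999, cw=55.5)  # x ~ 1
        nf_star = resonance_charge(ep, sp, bath, n_lo=2, combinatorial=False)
        assert nf_star == pytest.approx(-2.5, abs=1e-4)

    def test_concentration_pulls_resonance_toward_reference(self, fitted_params):
        """Raising the bath concentration moves nf* toward -2.5."""
        ep, sp = fitted_params
        nf_low = resonance_charge(ep, sp, BathState(0.14), n_lo=2)
        nf_high = resonance_charge(ep, sp, BathState(1.0), n_lo=2)
        assert abs(nf_high + 2.5) < abs(nf_low + 2.5)

    def test_degenerate_ground_states_equiprobable(self, fitted_params, bath_014):
        """At nf = nf* the minimal 2-ion and 3-ion configurations carry
        equal probability in the exact ensemble."""
        ep, sp = fitted_params
        nf_star = resonance_charge(ep, sp, bath_014, n_lo=2)
        ens = solve_ensemble(EnergyParams(Uc=ep.Uc, nf=nf_star), sp, bath_014)
        best = {}
        for p, c in zip(ens.probabilities, ens.configurations):
            if c.n in (2, 3):
                best[c.n] = max(best.get(c.n, 0.0), p)
        assert best[2] == pytest.approx(best[3], rel=1e-9)
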