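import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_suspension
from spionlab.constants import CONSTANTS
from spionlab.magnetodynamics import (
    FieldExcitation,
    MediumSpec,
    ModelDomainError,
    ParticleSpec,
    SuspensionSpec,
    brown_time,
    debye_chi,
    effective_time,
    equilibrium_susceptibility,
    heating_power,
    hysteresis_energy_numeric,
    langevin,
    langevin_argument,
    langevin_magnetization,
    neel_time,
    power_vs_diameter,
    susceptibility_spectrum,
    warn_if_nonlinear,
)


def make_particle(dm=16e-9, ratio=1.5, K=21e3, msp=300e3, tau0=1e-9):
    return ParticleSpec(
        core_diameter=dm,
        hydrodynamic_ratio=ratio,
        anisotropy_constant=K,
        core_saturation_magnetization=msp,
        attempt_time=tau0,
    )


class TestNeelTime:
    def test_zero_anisotropy_limit_returns_attempt_time(self, medium_310k):
        # exponent -> 0 as K -> 0: tauN -> tau0
        p = make_particle(K=1e-12)
        assert neel_time(p, medium_310k) == pytest.approx(1e-9, rel=1e-9)

    def test_reference_value_16nm(self, medium_310k):
        # frozen from a direct high-precision evaluation of
        # tau0*exp(K*pi*dm^3/6 / (kB*T)) at K=21 kJ/m^3, T=310 K, dm=16 nm
        p = make_particle()
        assert neel_time(p, medium_310k) == pytest.approx(3.733874782634622e-05, rel=1e-12)

    def test_strictly_increasing_in_diameter(self, medium_310k):
        taus = [neel_time(make_particle(dm=d), medium_310k) for d in (10e-9, 14e-9, 18e-9)]
        assert taus[0] < taus[1] < taus[2]

    def test_overflow_cap_raises(self, medium_310k):
        with pytest.raises(ModelDomainError, match="superparamagnetic"):
            neel_time(make_particle(dm=70e-9), medium_310k)


class TestBrownTime:
    def test_linear_in_viscosity(self, particle_16nm):
        t1 = brown_time(particle_16nm, MediumSpec(viscosity=1e-3, temperature=310))
        t2 = brown_time(particle_16nm, MediumSpec(viscosity=2e-3, temperature=310))
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_reference_value_24nm_hydro(self, medium_310k):
        # frozen from direct evaluation: 3*Vh*eta/(kB*T) at dh=24 nm
        p = make_particle(dm=16e-9, ratio=1.5)
        assert p.hydrodynamic_diameter == pytest.approx(24e-9)
        assert brown_time(p, medium_310k) == pytest.approx(4.517548549610859e-06, rel=1e-12)

    def test_cubic_scaling_in_hydrodynamic_diameter(self, medium_310k):
        p1 = make_particle(dm=10e-9, ratio=1.5)
        p2 = make_particle(dm=20e-9, ratio=1.5)
        assert brown_time(p2, medium_310k) == pytest.approx(
            8 * brown_time(p1, medium_310k), rel=1e-12
        )


class TestEffectiveTime:
    def test_equal_times_halve(self):
        assert effective_time(2e-6, 2e-6) == pytest.approx(1e-6, rel=1e-12)

    def test_infinite_neel_reduces_to_brown(self):
        assert effective_time(math.inf, 3.3e-6) == 3.3e-6
        assert effective_time(3.3e-6, math.inf) == 3.3e-6

    def test_harmonic_reference(self):
        # exact rational: 1e-5*1e-6/1.1e-5 = 10/11 us
        assert effective_time(1e-5, 1e-6) == pytest.approx(9.090909090909091e-07, rel=1e-12)

    def test_commutative_and_below_min(self):
        a, b = 3.7e-5, 4.5e-6
        assert effective_time(a, b) == effective_time(b, a)
        assert effective_time(a, b) <= min(a, b)

    def test_both_infinite_rejected(self):
        with pytest.raises(ValueError):
            effective_time(math.inf, math.inf)


class TestLangevin:
    def test_odd_and_zero_at_zero(self, suspension):
        assert langevin_magnetization(0.0, suspension) == 0.0
        m = langevin_magnetization(1e3, suspension)
        assert langevin_magnetization(-1e3, suspension) == pytest.approx(-m, rel=1e-12)

    def test_xi_one_reference(self):
        # coth(1) - 1 from a high-precision series evaluation
        assert langevin(1.0) == pytest.approx(0.31303528549933146, rel=1e-12)

    def test_saturation_limit(self, suspension):
        ms = suspension.saturation_magnetization
        m = langevin_magnetization(1e9, suspension)
        assert m < ms
        assert m == pytest.approx(ms, rel=1e-3)

    def test_series_matches_direct_at_switch_point(self):
        # continuity across the series/direct switch at |xi| = 1e-4
        lo, hi = langevin(0.99999e-4), langevin(1.00001e-4)
        assert abs(hi - lo) < 1e-8
        for xi in (1e-6, 1e-5, 1e-4, 1e-3):
            assert langevin(xi) == pytest.approx(xi / 3 - xi**3 / 45, rel=1e-6)

    def test_vectorized(self):
        out = langevin(np.array([0.0, 1.0, -1.0]))
        assert out.shape == (3,)
        assert out[1] == -out[2]


class TestEquilibriumSusceptibility:
    def test_empty_suspension(self, particle_16nm, medium_310k):
        susp = SuspensionSpec(
            particle=particle_16nm, medium=medium_310k, number_density=0.0
        )
        assert equilibrium_susceptibility(susp) == 0.0

    def test_curie_scaling(self, particle_16nm):
        s1 = SuspensionSpec(
            particle=particle_16nm,
            medium=MediumSpec(viscosity=8.9e-4, temperature=300.0),
            number_density=1e20,
        )
        s2 = SuspensionSpec(
            particle=particle_16nm,
            medium=MediumSpec(viscosity=8.9e-4, temperature=600.0),
            number_density=1e20,
        )
        assert equilibrium_susceptibility(s2) == pytest.approx(
            equilibrium_susceptibility(s1) / 2, rel=1e-12
        )

    def test_matches_finite_difference_slope(self, rng):
        # chi0 must equal the numerical dM/dH at H -> 0 within 0.1 %
        for _ in range(10):
            susp = random_suspension(rng)
            chi0 = equilibrium_susceptibility(susp)
            # pick h so that xi(h) ~ 1e-2 (well inside the linear regime)
            h = 1e-2 / float(langevin_argument(1.0, susp))
            slope = (
                langevin_magnetization(h, susp) - langevin_magnetization(-h, susp)
            ) / (2 * h)
            assert slope == pytest.approx(chi0, rel=1e-3)


class TestSusceptibilitySpectrum:
    def test_static_limit(self, suspension):
        spec = susceptibility_spectrum(suspension, [0.0])
        assert spec.chi_real[0] == pytest.approx(spec.equilibrium_chi, rel=1e-12)
        assert spec.chi_imag[0] == 0.0

    def test_debye_peak_identity(self, suspension):
        spec0 = susceptibility_spectrum(suspension, [1.0])
        f_peak = 1.0 / (2 * math.pi * spec0.effective_tau)
        spec = susceptibility_spectrum(suspension, [f_peak])
        assert spec.chi_real[0] == pytest.approx(spec.equilibrium_chi / 2, rel=1e-12)
        assert spec.chi_imag[0] == pytest.approx(spec.equilibrium_chi / 2, rel=1e-12)

    def test_omega_tau_three(self, suspension):
        # exact rationals 3/10 and 1/10
        tau = susceptibility_spectrum(suspension, [1.0]).effective_tau
        f = 3.0 / (2 * math.pi * tau)
        spec = susceptibility_spectrum(suspension, [f])
        assert spec.chi_imag[0] == pytest.approx(0.3 * spec.equilibrium_chi, rel=1e-12)
        assert spec.chi_real[0] == pytest.approx(0.1 * spec.equilibrium_chi, rel=1e-12)

    def test_algebraic_identities_on_grid(self, suspension):
        freqs = np.geomspace(1e0, 1e8, 50)
        spec = susceptibility_spectrum(suspension, freqs)
        wt = 2 * np.pi * freqs * spec.effective_tau
        np.testing.assert_allclose(
            spec.chi_real * (1 + wt**2), spec.equilibrium_chi, rtol=1e-13
        )
        np.testing.assert_allclose(
            spec.chi_imag * (1 + wt**2), wt * spec.equilibrium_chi, rtol=1e-13
        )

    def test_invariants(self, suspension):
        spec = susceptibility_spectrum(suspension, np.geomspace(1e0, 1e9, 200))
        assert np.all(spec.chi_imag >= 0)
        assert np.all(spec.chi_real <= spec.equilibrium_chi + 1e-15)
        assert np.all(np.diff(spec.chi_real) <= 1e-15)


class TestHeatingPower:
    def test_zero_chi_zero_power(self, excitation_58khz):
        assert heating_power(excitation_58khz, 0.0) == 0.0

    def test_reference_58khz_20mt(self, excitation_58khz):
        # frozen: f*pi*mu0*(B0/mu0)^2*0.1 at 58.3 kHz, 20 mT
        assert heating_power(excitation_58khz, 0.1) == pytest.approx(
            5828316.68112283, rel=1e-12
        )

    def test_quadratic_in_amplitude(self):
        e1 = FieldExcitation(frequency=1e5, amplitude=1e3)
        e2 = FieldExcitation(frequency=1e5, amplitude=2e3)
        assert heating_power(e2, 0.05) == pytest.approx(4 * heating_power(e1, 0.05))

    def test_induction_amplitude_equivalence(self):
        e_b = FieldExcitation(frequency=1e5, induction=20e-3)
        e_h = FieldExcitation(frequency=1e5, amplitude=20e-3 / CONSTANTS.vacuum_permeability)
        assert heating_power(e_b, 0.1) == pytest.approx(heating_power(e_h, 0.1), rel=1e-14)


def _linear_response_series(chi_real, chi_imag, h0, n):
    t = np.arange(n) / n  # one period, endpoint excluded
    phase = 2 * np.pi * t
    h = h0 * np.cos(phase)
    m = h0 * (chi_real * np.cos(phase) + chi_imag * np.sin(phase))
    return m, h


class TestHysteresisEnergy:
    def test_in_phase_loop_has_zero_area(self):
        m, h = _linear_response_series(0.3, 0.0, 1e4, 10_000)
        du = hysteresis_energy_numeric(m, h)
        scale = CONSTANTS.vacuum_permeability * (1e4) ** 2
        assert abs(du) < 1e-6 * scale

    def test_matches_closed_form_ellipse_area(self):
        h0, chi_i = 1.5e4, 0.07
        m, h = _linear_response_series(0.2, chi_i, h0, 10_000)
        du = hysteresis_energy_numeric(m, h)
        expected = math.pi * CONSTANTS.vacuum_permeability * h0**2 * chi_i
        assert du == pytest.approx(expected, rel=1e-3)

    def test_quadratic_in_amplitude(self):
        m1, h1 = _linear_response_series(0.2, 0.07, 1e4, 10_000)
        m2, h2 = _linear_response_series(0.2, 0.07, 2e4, 10_000)
        assert hysteresis_energy_numeric(m2, h2) == pytest.approx(
            4 * hysteresis_energy_numeric(m1, h1), rel=1e-9
        )

    def test_energy_equals_power_over_frequency(self, suspension, excitation_58khz):
        # Delta U = P/f in the linear regime (conservation consistency)
        spec = susceptibility_spectrum(suspension, [excitation_58khz.frequency])
        h0 = excitation_58khz.amplitude
        m, h = _linear_response_series(spec.chi_real[0], spec.chi_imag[0], h0, 10_000)
        du = hysteresis_energy_numeric(m, h)
        p = heating_power(excitation_58khz, spec.chi_imag[0])
        assert du == pytest.approx(p / excitation_58khz.frequency, rel=1e-3)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            hysteresis_energy_numeric(np.zeros(100), np.zeros(99))

    def test_non_cyclic_series_rejected(self):
        t = np.linspace(0, 0.25, 100)  # quarter period only
        h = 1e4 * np.cos(2 * np.pi * t)
        with pytest.raises(ValueError, match="cycle"):
            hysteresis_energy_numeric(h * 0.1, h)


class TestPowerVsDiameter:
    def test_single_diameter_is_argmax(self, medium_310k, excitation_58khz):
        res = power_vs_diameter(
            make_particle(), medium_310k, excitation_58khz, [16e-9]
        )
        assert res.argmax_diameter == 16e-9
        assert not res.interior_maximum

    def test_reference_parameters_unimodal(self, medium_310k, excitation_58khz):
        d = np.linspace(5e-9, 40e-9, 351)
        res = power_vs_diameter(make_particle(), medium_310k, excitation_58khz, d)
        assert res.unimodal
        assert res.interior_maximum
        # dense-grid oracle: peak sits where omega*tau crosses 1
        wt = excitation_58khz.angular_frequency * res.effective_tau
        assert wt[res.argmax_index - 1] < 1 < wt[res.argmax_index + 1]

    def test_debye_regime_monotone(self, medium_310k):
        # low frequency keeps omega*tau << 1 over small diameters: P increasing
        exc = FieldExcitation(frequency=1e2, induction=20e-3)
        d = np.linspace(5e-9, 12e-9, 50)
        res = power_vs_diameter(make_particle(), medium_310k, exc, d)
        assert np.all(np.diff(res.power) > 0)

    def test_empty_diameters_rejected(self, medium_310k, excitation_58khz):
        with pytest.raises(ValueError):
            power_vs_diameter(make_particle(), medium_310k, excitation_58khz, [])

    def test_physical_normalizations_run(self, medium_310k, excitation_58khz):
        d = np.linspace(10e-9, 30e-9, 5)
        res = power_vs_diameter(
            make_particle(),
            medium_310k,
            excitation_58khz,
            d,
            normalization="mass_concentration",
            mass_concentration=25.0,
            core_density=5000.0,
        )
        assert np.all(res.power > 0)


class TestLinearResponseWarning:
    def test_warns_above_threshold(self, medium_310k):
        big = ParticleSpec(
            core_diameter=25e-9,
            hydrodynamic_ratio=1.5,
            anisotropy_constant=21e3,
            core_saturation_magnetization=480e3,
        )
        susp = SuspensionSpec(particle=big, medium=medium_310k, number_density=1e20)
        exc = FieldExcitation(frequency=58.3e3, induction=50e-3)
        with pytest.warns(UserWarning, match="linear-response"):
            warn_if_nonlinear(exc, susp)

    def test_silent_below_threshold(self, suspension):
        import warnings

        exc = FieldExcitation(frequency=58.3e3, induction=1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            warn_if_nonlinear(exc, suspension)


class TestSpecValidation:
    def test_invalid_particle(self):
        with pytest.raises(ValueError):
            make_particle(dm=-1e-9)
        with pytest.raises(ValueError):
            ParticleSpec(
                core_diameter=10e-9,
                hydrodynamic_diameter=5e-9,
                anisotropy_constant=1e4,
                core_saturation_magnetization=3e5,
            )

    def test_excitation_needs_exactly_one_amplitude(self):
        with pytest.raises(ValueError):
            FieldExcitation(frequency=1e5)
        with pytest.raises(ValueError):
            FieldExcitation(frequency=1e5, amplitude=1.0, induction=1.0)

    def test_angular_frequency(self):
        exc = FieldExcitation(frequency=100.0, amplitude=1.0)
        assert exc.angular_frequency == pytest.approx(200 * math.pi)

    def test_suspension_mass_number_roundtrip(self, particle_16nm, medium_310k):
        s = SuspensionSpec(
            particle=particle_16nm,
            medium=medium_310k,
            mass_concentration=5.0,
            core_density=5170.0,
        )
        s2 = SuspensionSpec(
            particle=particle_16nm,
            medium=medium_310k,
            number_density=s.number_density,
            core_density=5170.0,
        )
        assert s2.mass_concentration == pytest.approx(5.0, rel=1e-12)


@settings(max_examples=30, deadline=None)
@given(
    dm=st.floats(6e-9, 20e-9),
    ratio=st.floats(1.0, 2.0),
    eta=st.floats(3e-4, 5e-3),
    temp=st.floats(280.0, 330.0),
)
def test_effective_time_below_both_mechanisms(dm, ratio, eta, temp):
    p = make_particle(dm=dm, ratio=ratio)
    m = MediumSpec(viscosity=eta, temperature=temp)
    tn, tb = neel_time(p, m), brown_time(p, m)
    te = effective_time(tn, tb)
    assert te <= min(tn, tb) * (1 + 1e-12)


@settings(max_examples=30, deadline=None)
@given(chi0=st.floats(1e-4, 10.0), tau=st.floats(1e-8, 1e-3), wt=st.floats(1e-3, 1e3))
def test_debye_pair_identities(chi0, tau, wt):
    omega = wt / tau
    cr, ci = debye_chi(chi0, tau, omega)
    assert ci >= 0
    assert cr <= chi0
    assert cr * (1 + wt**2) == pytest.approx(chi0, rel=1e-9)
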