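"""Forward-model unit and property tests.

Closed-form predictions (wavelength mixing, power laws, delay factors,
degeneracy ratios) are checked against independent numeric oracles:
brute-force Gaussian pulse-overlap integrals and direct evaluation of the
susceptibility denominators.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colortsfg import physics
from colortsfg.physics import (BeamConfig, ResonanceModel, chi3_resonant,
                               chi3_total, chi3_lorentzian_intensity,
                               delay_factor, fit_power_exponents,
                               fwhm_to_sigma, mix_wavelengths,
                               signal_intensity, sigma_to_fwhm)


def make_beam(tau=60.0, power=30.0, wavelength=1300.0, delay=0.0):
    return BeamConfig(wavelength, power, tau, 12.5, delay)


# ---------------------------------------------------------------------------
# wavelength mixing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("lam1, lam2, expected_nm", [
    (1045.0, 1300.0, (348, 373, 401, 433)),
    (1030.0, 1320.0, (343, 370, 402, 440)),
])
def test_mixing_reproduces_observed_emission_lines(lam1, lam2, expected_nm):
    cs = mix_wavelengths(lam1, lam2)
    assert tuple(round(w) for w in cs.emission_wavelengths) == expected_nm


def test_mixing_exact_values_for_opo_pair():
    cs = mix_wavelengths(1045.0, 1300.0)
    np.testing.assert_allclose(cs.emission_wavelengths,
                               (348.333, 372.702, 400.737, 433.333),
                               atol=5e-3)
    assert cs.labels == ("THG1", "TSFG1", "TSFG2", "THG2")
    assert cs.get("TSFG1").process_orders == (2, 1)


def test_mixing_degenerate_single_beam():
    cs = mix_wavelengths(1200.0, 1200.0)
    assert np.allclose(cs.emission_wavelengths, 400.0)


@given(lam1=st.floats(800, 1400), lam2=st.floats(800, 1400))
@settings(max_examples=50, deadline=None)
def test_mixing_energy_conservation(lam1, lam2):
    """1/lambda_em = n1/lambda1 + n2/lambda2 for every channel."""
    for ch in mix_wavelengths(lam1, lam2):
        n1, n2 = ch.process_orders
        assert ch.emission_wavelength == pytest.approx(
            1.0 / (n1 / lam1 + n2 / lam2), abs=0.01)


def test_mixing_rejects_nonpositive_wavelength():
    with pytest.raises(ValueError):
        mix_wavelengths(-1.0, 1300.0)


# ---------------------------------------------------------------------------
# resonant susceptibility
# ---------------------------------------------------------------------------


def test_zero_amplitude_reduces_to_nonresonant_background():
    model = ResonanceModel(4.5, 4.6, 4.55, 0.3, 0.3, 0.12,
                           resonant_amplitude=0.0, nonresonant_chi3=0.07)
    assert chi3_total(1.5, model) == pytest.approx(0.07)


def _far_detuned(three_photon=4.5, gamma_da=0.12):
    """Single three-photon resonance; 1P/2P factors pushed far away so the
    triple product is effectively one Lorentzian."""
    return ResonanceModel(one_photon_energy=400.0, two_photon_energy=400.0,
                          three_photon_energy=three_photon, gamma_ba=0.1,
                          gamma_ca=0.1, gamma_da=gamma_da,
                          resonant_amplitude=1.0)


def test_susceptibility_peaks_at_three_photon_resonance():
    model = _far_detuned()
    omegas = np.linspace(1.3, 1.7, 4001)
    mag = np.abs(chi3_resonant(omegas, model)) ** 2
    peak = omegas[np.argmax(mag)]
    assert peak == pytest.approx(model.three_photon_energy / 3.0, abs=2e-4)


def test_half_width_of_three_photon_lorentzian():
    """|chi_res|^2 drops to half its peak at omega_da/3 +- gamma_da/3 when
    the 1P/2P factors are effectively constant (far detuned oracle)."""
    model = _far_detuned()
    peak = np.abs(chi3_resonant(model.three_photon_energy / 3.0, model)) ** 2
    for sign in (-1, 1):
        w = (model.three_photon_energy + sign * model.gamma_da) / 3.0
        assert np.abs(chi3_resonant(w, model)) ** 2 == pytest.approx(
            peak / 2.0, rel=2e-3)


@given(omega=st.floats(1.2, 1.8))
@settings(max_examples=50, deadline=None)
def test_product_form_matches_lorentzian_form(omega):
    """|chi_res(omega)|^2 from the complex product equals the explicit
    triple-Lorentzian expression to 1e-12 relative."""
    model = ResonanceModel.oxyhemoglobin()
    a = abs(chi3_resonant(omega, model)) ** 2
    b = chi3_lorentzian_intensity(omega, model)
    assert a == pytest.approx(b, rel=1e-12)


def test_predicted_thg_spectrum_peaks_at_soret_triple():
    """With a single three-photon resonance and large detuning elsewhere,
    the excitation-wavelength peak of the predicted THG spectrum sits at
    3x the transition wavelength (within one grid step)."""
    model = _far_detuned(
        three_photon=physics.wavelength_to_angular_frequency(415.0))
    lams = np.arange(1100.0, 1400.0, 2.0)
    omegas = physics.wavelength_to_angular_frequency(1.0) / lams  # 2 pi c / lam
    mag = np.abs(chi3_resonant(omegas, model)) ** 2
    peak_lam = lams[np.argmax(mag)]
    assert abs(peak_lam - 3 * 415.0) <= 2.0


def test_mixture_endpoints_and_bounds():
    oxy, deoxy = ResonanceModel.oxyhemoglobin(), ResonanceModel.deoxyhemoglobin()
    omega = 1.5
    assert physics.chi3_mixture(omega, 1.0, oxy, deoxy) == pytest.approx(
        chi3_total(omega, oxy))
    assert physics.chi3_mixture(omega, 0.0, oxy, deoxy) == pytest.approx(
        oxy.nonresonant_chi3 + chi3_resonant(omega, deoxy))
    with pytest.raises(ValueError):
        physics.chi3_mixture(omega, 1.5, oxy, deoxy)


# ---------------------------------------------------------------------------
# delay dependence: closed forms vs numeric overlap integrals
# ---------------------------------------------------------------------------


def overlap_integral(tau1, tau2, delta, orders):
    """Brute-force \\int I1^n1(t) I2^n2(t - delta) dt for Gaussian pulses,
    normalized to its zero-delay value."""
    t = np.linspace(-3000, 3000, 60001)
    i1 = np.exp(-t ** 2 / (2 * tau1 ** 2))
    n1, n2 = orders

    def integral(d):
        i2 = np.exp(-(t - d) ** 2 / (2 * tau2 ** 2))
        return np.trapezoid(i1 ** n1 * i2 ** n2, t)

    return integral(delta) / integral(0.0)


@pytest.mark.parametrize("channel, orders", [("TSFG1", (2, 1)),
                                             ("TSFG2", (1, 2))])
def test_delay_factor_matches_numeric_overlap(channel, orders):
    tau1, tau2 = fwhm_to_sigma(240.0), fwhm_to_sigma(140.0)
    for delta in np.linspace(-500.0, 500.0, 21):
        b1 = make_beam(tau=tau1, wavelength=1045.0)
        b2 = make_beam(tau=tau2, wavelength=1300.0, delay=delta)
        closed = delay_factor(b1, b2, channel)
        numeric = overlap_integral(tau1, tau2, delta, orders)
        assert closed == pytest.approx(numeric, rel=1e-6, abs=1e-12)


def test_thg_channels_are_delay_flat():
    b1 = make_beam(wavelength=1045.0)
    for delta in (-400.0, 0.0, 250.0):
        b2 = make_beam(wavelength=1300.0, delay=delta)
        assert delay_factor(b1, b2, "THG1") == 1.0
        assert delay_factor(b1, b2, "THG2") == 1.0


def test_delay_factor_e_fold_point():
    tau1, tau2 = 80.0, 50.0
    delta = math.sqrt(tau1 ** 2 + 2 * tau2 ** 2)
    b1 = make_beam(tau=tau1)
    b2 = make_beam(tau=tau2, delay=delta)
    assert delay_factor(b1, b2, "TSFG1") == pytest.approx(math.exp(-1.0))


# ---------------------------------------------------------------------------
# power / duration dependence
# ---------------------------------------------------------------------------


def test_thg2_cubic_in_second_beam_power():
    b1, b2 = make_beam(wavelength=1045.0), make_beam(wavelength=1300.0)
    r1 = signal_intensity(b1, b2, "THG2", 1.0)
    r2 = signal_intensity(b1, b2.with_power(2 * b2.average_power), "THG2", 1.0)
    assert r2 / r1 == pytest.approx(8.0)


def test_tsfg1_quadratic_linear_power_scaling():
    b1, b2 = make_beam(wavelength=1045.0), make_beam(wavelength=1300.0)
    base = signal_intensity(b1, b2, "TSFG1", 1.0)
    assert signal_intensity(b1.with_power(2 * b1.average_power), b2,
                            "TSFG1", 1.0) / base == pytest.approx(4.0)
    assert signal_intensity(b1, b2.with_power(2 * b2.average_power),
                            "TSFG1", 1.0) / base == pytest.approx(2.0)


def test_degeneracy_ratio_against_numeric_integrals():
    """For identical beams, rate(TSFG1)/rate(THG1) = 9, and the same value
    follows from the brute-force 9*int(I1^2 I2)/int(I1^3) oracle."""
    tau = 70.0
    b1 = make_beam(tau=tau, wavelength=1200.0)
    b2 = make_beam(tau=tau, wavelength=1200.0)
    closed = signal_intensity(b1, b2, "TSFG1", 1.0) / \
        signal_intensity(b1, b2, "THG1", 1.0)
    t = np.linspace(-1500, 1500, 40001)
    g = np.exp(-t ** 2 / (2 * tau ** 2))
    numeric = 9.0 * np.trapezoid(g ** 2 * g, t) / np.trapezoid(g ** 3, t)
    assert closed == pytest.approx(9.0, rel=1e-12)
    assert closed == pytest.approx(numeric, rel=1e-9)


def test_tsfg_tau_mixing_matches_numeric_integrals():
    """The Eq-2 tau-mixing denominator reproduces brute-force pulse-overlap
    integrals for unequal pulse durations."""
    tau1, tau2 = 101.9, 59.4
    b1 = make_beam(tau=tau1, wavelength=1045.0)
    b2 = make_beam(tau=tau2, wavelength=1300.0)
    closed = signal_intensity(b1, b2, "TSFG1", 1.0) / \
        signal_intensity(b1, b2, "THG1", 1.0)
    t = np.linspace(-2000, 2000, 80001)
    g1 = np.exp(-t ** 2 / (2 * tau1 ** 2)) / tau1
    g2 = np.exp(-t ** 2 / (2 * tau2 ** 2)) / tau2
    numeric = 9.0 * np.trapezoid(g1 ** 2 * g2, t) / np.trapezoid(g1 ** 3, t)
    assert closed == pytest.approx(numeric, rel=1e-9)


@given(t1=st.floats(40, 300), t2=st.floats(40, 300),
       p1=st.floats(1, 100), p2=st.floats(1, 100))
@settings(max_examples=50, deadline=None)
def test_beam_swap_symmetry(t1, t2, p1, p2):
    """Swapping the beams maps TSFG1 onto TSFG2."""
    b1 = BeamConfig(1045.0, p1, t1, 12.5)
    b2 = BeamConfig(1300.0, p2, t2, 12.5)
    assert signal_intensity(b2, b1, "TSFG1", 1.0) == pytest.approx(
        signal_intensity(b1, b2, "TSFG2", 1.0), rel=1e-12)


@pytest.mark.parametrize("channel", ["THG1", "THG2", "TSFG1", "TSFG2"])
def test_signal_decreasing_in_pulse_durations(channel):
    """Signals fall monotonically with every pulse duration that enters
    the channel (strictly for its own beam(s); a single-beam THG channel
    is flat in the other beam's duration)."""
    taus = np.linspace(50.0, 250.0, 9)
    for fixed in (60.0, 150.0):
        rates1 = np.array([
            signal_intensity(make_beam(tau=t, wavelength=1045.0),
                             make_beam(tau=fixed, wavelength=1300.0),
                             channel, 1.0) for t in taus])
        rates2 = np.array([
            signal_intensity(make_beam(tau=fixed, wavelength=1045.0),
                             make_beam(tau=t, wavelength=1300.0),
                             channel, 1.0) for t in taus])
        for rates, own in ((rates1, channel != "THG2"),
                           (rates2, channel != "THG1")):
            if own:
                assert all(np.diff(rates) < 0)
            else:
                assert np.allclose(np.diff(rates), 0.0)


def test_unknown_channel_rejected():
    b = make_beam()
    with pytest.raises(ValueError):
        signal_intensity(b, b, "SHG", 1.0)
    with pytest.raises(ValueError):
        delay_factor(b, b, "SHG")


# ---------------------------------------------------------------------------
# power-exponent recovery
# ---------------------------------------------------------------------------


def _power_design():
    p1 = np.array([5, 5, 10, 10, 20, 20, 40, 40, 80, 80], dtype=float)
    p2 = np.array([5, 10, 5, 20, 10, 40, 20, 80, 40, 80], dtype=float)
    return list(zip(p1, p2))


@pytest.mark.parametrize("channel, expected", [
    ("THG2", (0.0, 3.0)), ("TSFG1", (2.0, 1.0)), ("TSFG2", (1.0, 2.0)),
])
def test_exponents_recovered_from_noise_free_signals(channel, expected):
    powers = _power_design()
    rates = [signal_intensity(make_beam(power=pp1, wavelength=1045.0),
                              make_beam(power=pp2, wavelength=1300.0),
                              channel, 1.0) for pp1, pp2 in powers]
    n1, n2 = fit_power_exponents(powers, rates)
    assert n1 == pytest.approx(expected[0], abs=1e-10)
    assert n2 == pytest.approx(expected[1], abs=1e-10)


def test_constant_rates_give_zero_exponents():
    n1, n2 = fit_power_exponents(_power_design(), [7.0] * 10)
    assert n1 == pytest.approx(0.0, abs=1e-12)
    assert n2 == pytest.approx(0.0, abs=1e-12)


def test_degenerate_power_design_is_an_error():
    with pytest.raises(ValueError):
        fit_power_exponents([(10.0, 20.0)] * 5, [1.0] * 5)


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------


def test_fwhm_sigma_round_trip():
    assert sigma_to_fwhm(fwhm_to_sigma(240.0)) == pytest.approx(240.0)
    assert fwhm_to_sigma(240.0) == pytest.approx(
        240.0 / (2 * math.sqrt(2 * math.log(2))))


def test_beam_validation():
    with pytest.raises(ValueError):
        BeamConfig(1045.0, -1.0, 100.0, 12.5)
    with pytest.raises(ValueError):
        BeamConfig(1045.0, 30.0, 100.0, 12.5 / 1e7)  # tau ~ period
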