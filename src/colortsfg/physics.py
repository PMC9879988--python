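"""Closed-form forward model of THG and TSFG signal generation.

Two femtosecond pulse trains at near-infrared wavelengths lambda1 (pump) and
lambda2 (OPO/OPA) overlapped in a chi(3) medium produce four third-order
signals: two third harmonics at lambda1/3 and lambda2/3 and two sum-frequency
signals at 1/(2/lambda1 + 1/lambda2) and 1/(1/lambda1 + 2/lambda2).  This
module provides

* the wavelength-mixing arithmetic (:func:`mix_wavelengths`),
* the dependence of each signal on average powers, pulse durations and
  inter-pulse delay for Gaussian pulses (:func:`signal_intensity`,
  :func:`delay_factor`),
* the resonant third-order susceptibility of an absorber such as hemoglobin
  near its Soret band (:class:`ResonanceModel`, :func:`chi3_resonant`), and
* a log-log regression utility recovering the power-law exponents from
  measured signal/power series (:func:`fit_power_exponents`).

Units: lengths in nm, times in fs (repetition period in ns), average powers
in mW, angular frequencies in rad/fs.  Pulse durations are the Gaussian
sigma parameter of the temporal intensity profile
``I(t) = (I0/sqrt(2 pi)) (T/tau) exp(-t^2 / 2 tau^2)``; helpers convert
to and from the intensity FWHM (factor 2 sqrt(2 ln 2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT_NM_PER_FS",
    "CHANNEL_ORDERS",
    "BeamConfig",
    "Channel",
    "ChannelSet",
    "ResonanceModel",
    "SignalPrediction",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "wavelength_to_angular_frequency",
    "angular_frequency_to_wavelength",
    "mix_wavelengths",
    "chi3_resonant",
    "chi3_total",
    "chi3_lorentzian_intensity",
    "chi3_mixture",
    "chi3_at_emission",
    "delay_factor",
    "signal_intensity",
    "fit_power_exponents",
]

#: speed of light, nm per fs
SPEED_OF_LIGHT_NM_PER_FS = 299.792458

#: photons drawn from (beam1, beam2) for each detection channel
CHANNEL_ORDERS = {
    "THG1": (3, 0),
    "TSFG1": (2, 1),
    "TSFG2": (1, 2),
    "THG2": (0, 3),
}

_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert an intensity FWHM pulse duration to the Gaussian sigma."""
    return fwhm / _FWHM_FACTOR


def sigma_to_fwhm(sigma: float) -> float:
    """Convert a Gaussian sigma pulse duration to the intensity FWHM."""
    return sigma * _FWHM_FACTOR


def wavelength_to_angular_frequency(wavelength_nm: float) -> float:
    """Angular frequency (rad/fs) of light at ``wavelength_nm``."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 2.0 * math.pi * SPEED_OF_LIGHT_NM_PER_FS / wavelength_nm


def angular_frequency_to_wavelength(omega: float) -> float:
    """Vacuum wavelength (nm) for an angular frequency in rad/fs."""
    if omega <= 0:
        raise ValueError("angular frequency must be positive")
    return 2.0 * math.pi * SPEED_OF_LIGHT_NM_PER_FS / omega


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeamConfig:
    """One excitation pulse train.

    Parameters
    ----------
    center_wavelength : float
        Center wavelength in nm.
    average_power : float
        Average power at the sample in mW.
    pulse_duration : float
        Gaussian sigma-equivalent duration in fs (see module docstring).
    repetition_period : float
        Pulse-to-pulse period T in ns (12.5 ns for an 80 MHz oscillator,
        1000 ns for a 1 MHz amplifier).
    delay : float
        Arrival-time offset of this train relative to a shared clock, fs.
    """

    center_wavelength: float
    average_power: float
    pulse_duration: float
    repetition_period: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        for name in ("center_wavelength", "average_power", "pulse_duration",
                     "repetition_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.pulse_duration >= 0.1 * self.repetition_period * 1e6:
            raise ValueError("pulse_duration must be much shorter than the "
                             "repetition period")

    @property
    def repetition_period_fs(self) -> float:
        return self.repetition_period * 1e6

    def with_power(self, power_mw: float) -> "BeamConfig":
        return replace(self, average_power=power_mw)


@dataclass(frozen=True)
class Channel:
    label: str
    emission_wavelength: float
    process_orders: tuple[int, int]


@dataclass(frozen=True)
class ChannelSet:
    """Ordered set of detection channels produced by a beam pair."""

    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        for ch in self.channels:
            if ch.label not in CHANNEL_ORDERS:
                raise ValueError(f"unknown channel label {ch.label!r}")
            if CHANNEL_ORDERS[ch.label] != ch.process_orders:
                raise ValueError(
                    f"channel {ch.label} must have process orders "
                    f"{CHANNEL_ORDERS[ch.label]}, got {ch.process_orders}")

    def __iter__(self):
        return iter(self.channels)

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(ch.label for ch in self.channels)

    @property
    def emission_wavelengths(self) -> tuple[float, ...]:
        return tuple(ch.emission_wavelength for ch in self.channels)

    def get(self, label: str) -> Channel:
        for ch in self.channels:
            if ch.label == label:
                return ch
        raise KeyError(f"channel {label!r} not in set {self.labels}")

    def subset(self, labels: Sequence[str]) -> "ChannelSet":
        return ChannelSet(tuple(self.get(lb) for lb in labels))


@dataclass(frozen=True)
class ResonanceModel:
    """Resonant + non-resonant third-order susceptibility of a material.

    The resonant part is a product of three detuning factors with one-,
    two- and three-photon transition frequencies ``omega_ba``, ``omega_ca``,
    ``omega_da`` and dephasing rates ``gamma_*`` (all rad/fs).  The
    microscopic numerator (number density times the four transition dipole
    moments over hbar cubed) is collapsed into the single non-negative
    amplitude ``resonant_amplitude``; only the magnitude of chi(3) enters
    measurable signals.
    """

    one_photon_energy: float
    two_photon_energy: float
    three_photon_energy: float
    gamma_ba: float
    gamma_ca: float
    gamma_da: float
    resonant_amplitude: float
    nonresonant_chi3: float = 0.0

    def __post_init__(self) -> None:
        if min(self.gamma_ba, self.gamma_ca, self.gamma_da) <= 0:
            raise ValueError("dephasing rates must be strictly positive")
        if self.resonant_amplitude < 0:
            raise ValueError("resonant_amplitude must be non-negative")
        if self.nonresonant_chi3 < 0:
            raise ValueError("nonresonant_chi3 must be non-negative")

    # -- default hemoglobin parameterizations --------------------------------
    #
    # The three-photon resonance sits at the Soret absorption band: emission
    # 415 nm for oxyhemoglobin, 430 nm for deoxyhemoglobin.  One- and
    # two-photon transitions are placed far from the excitation band
    # (1030-1320 nm fundamental) so the three-photon factor dominates, and
    # gamma_da = 0.12 rad/fs makes the on/off-resonance signal ratio of the
    # default scene generator land mid-range of the observed 10-20x.
    # Amplitudes are normalized so |chi_res| = 1 at exact peak.

    @classmethod
    def from_soret_peak(cls, emission_peak_nm: float,
                        gamma_da: float = 0.12,
                        nonresonant_chi3: float = 0.05,
                        peak_magnitude: float = 1.0) -> "ResonanceModel":
        """Build a three-photon-dominant model peaking at ``emission_peak_nm``."""
        omega_da = wavelength_to_angular_frequency(emission_peak_nm)
        model = cls(
            one_photon_energy=4.54,
            two_photon_energy=4.60,
            gamma_ba=0.4,
            gamma_ca=0.4,
            three_photon_energy=omega_da,
            gamma_da=gamma_da,
            resonant_amplitude=1.0,
            nonresonant_chi3=nonresonant_chi3,
        )
        peak = abs(chi3_resonant(omega_da / 3.0, model))
        return replace(model, resonant_amplitude=peak_magnitude / peak)

    @classmethod
    def oxyhemoglobin(cls) -> "ResonanceModel":
        return cls.from_soret_peak(415.0)

    @classmethod
    def deoxyhemoglobin(cls) -> "ResonanceModel":
        return cls.from_soret_peak(430.0)


@dataclass(frozen=True)
class SignalPrediction:
    """Per-channel expected photon rates (photons/s) for a beam pair."""

    rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, rate in self.rates.items():
            if rate < 0:
                raise ValueError(f"rate for {label} must be non-negative")

    def __getitem__(self, label: str) -> float:
        return self.rates[label]


# ---------------------------------------------------------------------------
# wavelength mixing
# ---------------------------------------------------------------------------


def mix_wavelengths(lambda1: float, lambda2: float) -> ChannelSet:
    """Emission wavelengths of the four third-order signals of a beam pair.

    Returns the channel set sorted by increasing emission wavelength, each
    channel tagged with its process orders (n1, n2) = photons drawn from
    beam 1 and beam 2.  The emission wavelength of a channel satisfies
    ``1/lambda_em = n1/lambda1 + n2/lambda2``.
    """
    if lambda1 <= 0 or lambda2 <= 0:
        raise ValueError("excitation wavelengths must be positive")
    channels = []
    for label, (n1, n2) in CHANNEL_ORDERS.items():
        lam = 1.0 / (n1 / lambda1 + n2 / lambda2)
        channels.append(Channel(label, lam, (n1, n2)))
    channels.sort(key=lambda ch: ch.emission_wavelength)
    return ChannelSet(tuple(channels))


# ---------------------------------------------------------------------------
# resonant susceptibility
# ---------------------------------------------------------------------------


def chi3_resonant(omega: float | np.ndarray, model: ResonanceModel) -> complex | np.ndarray:
    """Resonant chi(3) at excitation angular frequency ``omega`` (rad/fs).

    ``A / {[(w_da - 3w) - i g_da] [(w_ca - 2w) - i g_ca] [(w_ba - w) - i g_ba]}``
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    den = (((model.three_photon_energy - 3.0 * omega) - 1j * model.gamma_da)
           * ((model.two_photon_energy - 2.0 * omega) - 1j * model.gamma_ca)
           * ((model.one_photon_energy - omega) - 1j * model.gamma_ba))
    out = model.resonant_amplitude / den
    return out if out.shape else complex(out)


def chi3_total(omega: float | np.ndarray, model: ResonanceModel) -> complex | np.ndarray:
    """Total chi(3) = nonresonant background + resonant term."""
    return model.nonresonant_chi3 + chi3_resonant(omega, model)


def chi3_lorentzian_intensity(omega: float | np.ndarray, model: ResonanceModel) -> float | np.ndarray:
    """|chi_res|^2 written as the product of three Lorentzian factors.

    Algebraically identical to ``abs(chi3_resonant(...))**2``; kept as a
    separate code path so the two forms can be cross-checked.
    """
    omega = np.asarray(omega, dtype=float)
    num = model.resonant_amplitude ** 2
    den = (((model.three_photon_energy - 3.0 * omega) ** 2 + model.gamma_da ** 2)
           * ((model.two_photon_energy - 2.0 * omega) ** 2 + model.gamma_ca ** 2)
           * ((model.one_photon_energy - omega) ** 2 + model.gamma_ba ** 2))
    out = num / den
    return out if out.shape else float(out)


def chi3_mixture(omega: float | np.ndarray, saturation: float,
                 oxy: ResonanceModel, deoxy: ResonanceModel,
                 nonresonant_chi3: float | None = None) -> complex | np.ndarray:
    """chi(3) of hemoglobin at oxygen saturation ``saturation`` in [0, 1].

    Susceptibilities are additive in number density, so a partially
    oxygenated cell mixes the two resonant terms linearly:
    ``chi_nr + s * chi_res_oxy + (1 - s) * chi_res_deoxy``.
    """
    if not 0.0 <= saturation <= 1.0:
        raise ValueError("saturation must lie in [0, 1]")
    chinr = oxy.nonresonant_chi3 if nonresonant_chi3 is None else nonresonant_chi3
    return (chinr
            + saturation * chi3_resonant(omega, oxy)
            + (1.0 - saturation) * chi3_resonant(omega, deoxy))


def chi3_at_emission(emission_wavelength_nm: float, model: ResonanceModel) -> complex:
    """Total chi(3) evaluated at the excitation frequency whose third
    harmonic is ``emission_wavelength_nm`` (the three-photon pathway)."""
    omega = wavelength_to_angular_frequency(emission_wavelength_nm) / 3.0
    return chi3_total(omega, model)


# ---------------------------------------------------------------------------
# power / duration / delay dependence
# ---------------------------------------------------------------------------


def delay_factor(beam1: BeamConfig, beam2: BeamConfig, channel: str) -> float:
    """Signal attenuation caused by the inter-pulse delay, in [0, 1].

    For Gaussian pulses the temporal overlap integrals give
    ``exp(-D^2 / (tau1^2 + 2 tau2^2))`` for the (2, 1) channel and
    ``exp(-D^2 / (tau2^2 + 2 tau1^2))`` for (1, 2), with
    ``D = beam2.delay - beam1.delay``.  Single-beam THG channels are
    delay-independent and return exactly 1.
    """
    if channel not in CHANNEL_ORDERS:
        raise ValueError(f"unknown channel label {channel!r}")
    if channel in ("THG1", "THG2"):
        return 1.0
    delta = beam2.delay - beam1.delay
    t1, t2 = beam1.pulse_duration, beam2.pulse_duration
    if channel == "TSFG1":
        return math.exp(-delta ** 2 / (t1 ** 2 + 2.0 * t2 ** 2))
    return math.exp(-delta ** 2 / (t2 ** 2 + 2.0 * t1 ** 2))


def signal_intensity(beam1: BeamConfig, beam2: BeamConfig, channel: str,
                     chi3_magnitude: float, calibration: float = 1.0) -> float:
    """Expected photon rate of one detection channel.

    Single-beam channels scale as ``(T/tau)^2 P^3`` and dual-beam channels
    as ``9 sqrt(3) T^2 / (tau_i tau_j sqrt((tau_i/tau_j)^2 + 2)) P_i^2 P_j``,
    multiplied by ``|chi(3)|^2``, by the delay factor, and by a single
    calibration scalar converting the arbitrary units to photons/s.
    """
    if channel not in CHANNEL_ORDERS:
        raise ValueError(f"unknown channel label {channel!r}")
    if chi3_magnitude < 0:
        raise ValueError("chi3_magnitude must be non-negative")
    if not math.isclose(beam1.repetition_period, beam2.repetition_period,
                        rel_tol=1e-9):
        raise ValueError("beams must share a repetition period")
    T = beam1.repetition_period_fs
    p1, p2 = beam1.average_power, beam2.average_power
    t1, t2 = beam1.pulse_duration, beam2.pulse_duration
    if channel == "THG1":
        shape = (T / t1) ** 2 * p1 ** 3
    elif channel == "THG2":
        shape = (T / t2) ** 2 * p2 ** 3
    elif channel == "TSFG1":
        shape = (9.0 * math.sqrt(3.0) * T ** 2
                 / (t1 * t2 * math.sqrt((t1 / t2) ** 2 + 2.0))) * p1 ** 2 * p2
    else:  # TSFG2
        shape = (9.0 * math.sqrt(3.0) * T ** 2
                 / (t1 * t2 * math.sqrt((t2 / t1) ** 2 + 2.0))) * p1 * p2 ** 2
    return calibration * chi3_magnitude ** 2 * shape * delay_factor(beam1, beam2, channel)


def predict_signals(beam1: BeamConfig, beam2: BeamConfig,
                    channels: ChannelSet, chi3_magnitude: float,
                    calibration: float = 1.0) -> SignalPrediction:
    """Evaluate :func:`signal_intensity` for every channel in a set."""
    return SignalPrediction({
        ch.label: signal_intensity(beam1, beam2, ch.label, chi3_magnitude,
                                   calibration)
        for ch in channels
    })


# ---------------------------------------------------------------------------
# power-law exponent recovery
# ---------------------------------------------------------------------------


def fit_power_exponents(powers: Sequence[tuple[float, float]],
                        rates: Sequence[float]) -> tuple[float, float]:
    """Log-log least-squares exponents of a signal versus the two powers.

    Fits ``log rate = c + n1 log P1 + n2 log P2``.  A power that is held
    constant across the design contributes no information and its exponent
    is reported as 0.  Raises ``ValueError`` for a fully degenerate design
    (both powers constant) or non-positive inputs.
    """
    powers = np.asarray(powers, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if powers.ndim != 2 or powers.shape[1] != 2:
        raise ValueError("powers must be a sequence of (P1, P2) pairs")
    if len(powers) != len(rates):
        raise ValueError("powers and rates must have equal length")
    if np.any(powers <= 0) or np.any(rates <= 0):
        raise ValueError("powers and rates must be strictly positive")
    logp = np.log(powers)
    logr = np.log(rates)
    varying = [j for j in range(2) if np.ptp(logp[:, j]) > 1e-12]
    if not varying:
        raise ValueError("degenerate design: all power settings are equal")
    design = np.column_stack([np.ones(len(logr))] + [logp[:, j] for j in varying])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("degenerate design: powers are collinear in log space")
    coef, *_ = np.linalg.lstsq(design, logr, rcond=None)
    exponents = [0.0, 0.0]
    for k, j in enumerate(varying):
        exponents[j] = float(coef[1 + k])
    return exponents[0], exponents[1]
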