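"""Excitation-spectrum extraction from wavelength-scanned image series.

Raw photon counts depend on excitation power and pulse duration; before
spectra can be compared across a wavelength scan each acquisition is
normalized by its power/duration factor so that normalized values are
proportional to |chi(3)|^2.  Single-beam (third-harmonic) images are
divided by the cube of the power and multiplied by the square of the pulse
duration; dual-beam images are divided by the full channel-specific
mixing factor including the 9*sqrt(3) prefactor and the tau-mixing
denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack import ImageStack

__all__ = [
    "SpectralRecord", "SpectralSeries", "normalize_single_beam",
    "denormalize_single_beam", "normalize_dual_beam",
    "denormalize_dual_beam", "single_beam_factor", "dual_beam_factor",
    "extract_spectrum", "enhancement_factor", "spectrum_to_csv",
]


def single_beam_factor(power_mw: float, tau_fs: float,
                       repetition_period_ns: float = 1.0) -> float:
    """Power/duration factor of a single-beam THG signal: (T/tau)^2 P^3."""
    if power_mw <= 0 or tau_fs <= 0:
        raise ValueError("power and pulse duration must be positive")
    T = repetition_period_ns * 1e6
    return (T / tau_fs) ** 2 * power_mw ** 3


def dual_beam_factor(channel: str, p1: float, p2: float, tau1: float,
                     tau2: float, repetition_period_ns: float = 1.0) -> float:
    """Power/duration factor of a channel of the dual-beam scheme.

    TSFG channels use ``9 sqrt(3) T^2 / (tau_i tau_j sqrt((tau_i/tau_j)^2 + 2))
    P_i^2 P_j``; THG channels reduce to the single-beam factor of their beam.
    """
    if min(p1, p2, tau1, tau2) <= 0:
        raise ValueError("powers and pulse durations must be positive")
    T = repetition_period_ns * 1e6
    if channel == "THG1":
        return single_beam_factor(p1, tau1, repetition_period_ns)
    if channel == "THG2":
        return single_beam_factor(p2, tau2, repetition_period_ns)
    if channel == "TSFG1":
        return (9.0 * math.sqrt(3.0) * T ** 2
                / (tau1 * tau2 * math.sqrt((tau1 / tau2) ** 2 + 2.0))) \
            * p1 ** 2 * p2
    if channel == "TSFG2":
        return (9.0 * math.sqrt(3.0) * T ** 2
                / (tau1 * tau2 * math.sqrt((tau2 / tau1) ** 2 + 2.0))) \
            * p1 * p2 ** 2
    raise ValueError(f"unknown channel label {channel!r}")


def normalize_single_beam(stack: ImageStack, power_mw: float,
                          tau_fs: float) -> ImageStack:
    """Divide by P^3 and multiply by tau^2 (single-beam normalization)."""
    if power_mw <= 0:
        raise ValueError("power must be positive")
    if tau_fs <= 0:
        raise ValueError("pulse duration must be positive")
    data = stack.data.astype(float) * tau_fs ** 2 / power_mw ** 3
    return stack.with_data(data, normalized="single_beam")


def denormalize_single_beam(stack: ImageStack, power_mw: float,
                            tau_fs: float) -> ImageStack:
    """Inverse of :func:`normalize_single_beam` (exact round trip)."""
    if power_mw <= 0 or tau_fs <= 0:
        raise ValueError("power and pulse duration must be positive")
    data = stack.data.astype(float) * power_mw ** 3 / tau_fs ** 2
    return stack.with_data(data, normalized=False)


def normalize_dual_beam(stack: ImageStack, p1: float, p2: float,
                        tau1: float, tau2: float,
                        repetition_period_ns: float = 1.0) -> ImageStack:
    """Divide each channel by its full dual-beam power/duration factor, so
    normalized values are proportional to |chi(3)|^2."""
    data = stack.data.astype(float).copy()
    for k, label in enumerate(stack.channel_labels):
        data[:, k] /= dual_beam_factor(label, p1, p2, tau1, tau2,
                                       repetition_period_ns)
    return stack.with_data(data, normalized="dual_beam")


def denormalize_dual_beam(stack: ImageStack, p1: float, p2: float,
                          tau1: float, tau2: float,
                          repetition_period_ns: float = 1.0) -> ImageStack:
    """Inverse of :func:`normalize_dual_beam` (exact round trip)."""
    data = stack.data.astype(float).copy()
    for k, label in enumerate(stack.channel_labels):
        data[:, k] *= dual_beam_factor(label, p1, p2, tau1, tau2,
                                       repetition_period_ns)
    return stack.with_data(data, normalized=False)


@dataclass(frozen=True)
class SpectralRecord:
    """One acquisition of a wavelength scan."""

    excitation_wavelength: float
    stack: ImageStack
    power_mw: float
    tau_fs: float


@dataclass
class SpectralSeries:
    """Wavelength scan: records must be strictly monotone in wavelength."""

    records: list[SpectralRecord]

    def __post_init__(self) -> None:
        w = [r.excitation_wavelength for r in self.records]
        d = np.diff(w)
        if len(w) > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("scan wavelengths must be strictly monotone")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.asarray([r.excitation_wavelength for r in self.records])


def extract_spectrum(series: SpectralSeries, mask: np.ndarray,
                     channel: str | float = "THG2",
                     background_mask: np.ndarray | None = None,
                     normalize: str = "single") -> pd.DataFrame:
    """Mean normalized signal inside ``mask`` per scan wavelength.

    Each record is normalized by its own power and pulse duration
    ("single" uses the single-beam factor of the selected channel's beam;
    "dual" uses the full dual-beam factor; "none" skips normalization).
    When ``background_mask`` is given, the median normalized value of that
    region is subtracted before averaging.  Dispersion is the standard
    deviation across mask pixels.
    """
    if normalize not in ("single", "dual", "none"):
        raise ValueError("normalize must be 'single', 'dual' or 'none'")
    mask = np.asarray(mask, dtype=bool)
    rows = []
    for rec in series.records:
        if normalize == "single":
            norm = normalize_single_beam(rec.stack, rec.power_mw, rec.tau_fs)
        elif normalize == "dual":
            p1, p2 = (rec.stack.plane_powers[0]
                      if rec.stack.plane_powers is not None
                      else (rec.power_mw, rec.power_mw))
            t1, t2 = (rec.stack.plane_durations[0]
                      if rec.stack.plane_durations is not None
                      else (rec.tau_fs, rec.tau_fs))
            norm = normalize_dual_beam(rec.stack, p1, p2, t1, t2)
        else:
            norm = rec.stack
        img = norm.channel(channel)[0]
        if not mask.any():
            raise ValueError(f"empty region mask at excitation wavelength "
                             f"{rec.excitation_wavelength:.0f} nm")
        values = img[mask].astype(float)
        if background_mask is not None and background_mask.any():
            values = values - np.median(img[np.asarray(background_mask, bool)])
        rows.append(dict(
            wavelength_nm=rec.excitation_wavelength,
            channel=str(channel),
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
            n_pixels=int(values.size),
        ))
    return pd.DataFrame(rows)


def enhancement_factor(spectrum: pd.DataFrame, on_wavelength: float,
                       off_wavelength: float) -> float:
    """Ratio of the mean signal at two scan wavelengths, on/off resonance."""
    w = spectrum["wavelength_nm"].to_numpy()
    for target in (on_wavelength, off_wavelength):
        if not np.isclose(w, target).any():
            raise ValueError(f"wavelength {target} nm is not in the scan")
    on = float(spectrum.loc[np.isclose(w, on_wavelength), "mean"].iloc[0])
    off = float(spectrum.loc[np.isclose(w, off_wavelength), "mean"].iloc[0])
    if off <= 0:
        raise ValueError("off-resonance signal must be positive")
    return on / off


def spectrum_to_csv(spectrum: pd.DataFrame, path) -> None:
    """Write a spectrum table (wavelength_nm, channel, mean, sd, n_pixels)."""
    spectrum.to_csv(path, index=False)
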