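"""Multi-channel image stack container.

An :class:`ImageStack` holds a pixel grid indexed ``(plane, channel, y, x)``
— planes are time points, z positions, or a single frame — together with
the physical acquisition metadata the analysis needs: channel emission
wavelengths and labels, pixel size, per-plane beam powers and pulse
durations, and the random seed that produced simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """Pixel grid plus acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (n_planes, n_channels, ny, nx)
        Photon counts (non-negative integers for raw data; floats after
        normalization).
    channel_wavelengths : tuple of float
        Emission wavelength per channel, nm.
    channel_labels : tuple of str
        Process labels (THG1/TSFG1/TSFG2/THG2) per channel.
    axis : str
        Meaning of the leading axis: "t", "z" or "single".
    pixel_size_um : float
        Lateral pixel size, micrometers.
    dwell_time_us : float
        Pixel dwell time, microseconds.
    plane_positions : ndarray or None
        Time of each plane (seconds) for axis "t", depth (micrometers)
        for axis "z".
    plane_powers : ndarray or None, shape (n_planes, 2)
        Average powers (P1, P2) in mW used for each plane.
    plane_durations : ndarray or None, shape (n_planes, 2)
        Pulse durations (tau1, tau2) in fs (Gaussian sigma) per plane.
    z_step_um : float or None
        z increment for axis "z".
    seed : int or None
        Seed that generated the data, if simulated.
    extras : dict
        Free-form flags (e.g. ``normalized``, ``pileup_warning``).
    """

    data: np.ndarray
    channel_wavelengths: tuple[float, ...]
    channel_labels: tuple[str, ...]
    axis: str = "single"
    pixel_size_um: float = 0.5
    dwell_time_us: float = 5.0
    plane_positions: np.ndarray | None = None
    plane_powers: np.ndarray | None = None
    plane_durations: np.ndarray | None = None
    z_step_um: float | None = None
    seed: int | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # (channel, y, x) -> add plane axis
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("data must have shape (plane, channel, y, x)")
        if self.data.shape[1] != len(self.channel_wavelengths):
            raise ValueError("channel_wavelengths must match data channels")
        if len(self.channel_labels) != len(self.channel_wavelengths):
            raise ValueError("channel_labels must match channel_wavelengths")
        if self.axis not in ("t", "z", "single"):
            raise ValueError("axis must be 't', 'z' or 'single'")
        for name in ("plane_positions", "plane_powers", "plane_durations"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape[0] != self.n_planes:
                    raise ValueError(f"{name} must have one entry per plane")
                setattr(self, name, val)

    # -- shape helpers -------------------------------------------------------

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    # -- channel access ------------------------------------------------------

    def channel_index(self, key: str | float) -> int:
        """Locate a channel by label ("THG2") or by emission wavelength
        rounded to the nearest nm (433 or "S433")."""
        if isinstance(key, str) and key in self.channel_labels:
            return self.channel_labels.index(key)
        if isinstance(key, str) and key.startswith("S"):
            key = float(key[1:])
        try:
            target = float(key)
        except (TypeError, ValueError):
            raise KeyError(f"channel {key!r} not found; have labels "
                           f"{self.channel_labels} at "
                           f"{self.channel_wavelengths} nm") from None
        for i, lam in enumerate(self.channel_wavelengths):
            if round(lam) == round(target):
                return i
        raise KeyError(f"no channel at {target:.0f} nm; have "
                       f"{tuple(round(w) for w in self.channel_wavelengths)}")

    def channel(self, key: str | float) -> np.ndarray:
        """Pixel data of one channel, shape (n_planes, ny, nx)."""
        return self.data[:, self.channel_index(key)]

    def plane(self, i: int) -> "ImageStack":
        """Single-plane view as a new stack."""
        return replace(
            self,
            data=self.data[i:i + 1].copy(),
            axis="single",
            plane_positions=None if self.plane_positions is None
            else self.plane_positions[i:i + 1].copy(),
            plane_powers=None if self.plane_powers is None
            else self.plane_powers[i:i + 1].copy(),
            plane_durations=None if self.plane_durations is None
            else self.plane_durations[i:i + 1].copy(),
            extras=dict(self.extras),
        )

    def with_data(self, data: np.ndarray, **extra_flags: Any) -> "ImageStack":
        """Copy of this stack with new pixel data and updated flags."""
        extras = dict(self.extras)
        extras.update(extra_flags)
        return replace(self, data=np.asarray(data), extras=extras)
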