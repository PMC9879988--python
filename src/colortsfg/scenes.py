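"""Seeded generator of synthetic color TSFG image data.

Produces three-channel frames, time series and z-stacks with the
statistical structure the downstream analysis assumes: red blood cells
whose third-order susceptibility carries an oxygenation-dependent Soret
resonance, vessel walls, non-resonant distractor structures (myelin,
pigment cells, lipid bodies, interfaces), row-by-row scan timing that
elongates fast-moving arterial cells, depth attenuation, and Poisson
counting noise.

Contrast model
--------------
THG/TSFG emission is interface-localized: a homogeneous medium produces no
signal.  The generator therefore assigns to every object a one-pixel
boundary shell with weight ``|chi_object - chi_surround|**2``, plus a
resonance-weighted interior term for hemoglobin-filled cytoplasm (the
enhancement is present throughout hemoglobin-rich areas, not only at the
membrane).  Zebrafish cell nuclei carry only non-resonant susceptibility
and hence a wavelength-flat signal.

Expected photon counts per pixel are ``dwell x detection efficiency x
signal_intensity`` evaluated with the local ``|chi(3)|**2``; observed
counts are Poisson draws from a seeded generator with per-(frame, channel)
stream splitting keyed on the canonical channel order, so reordering
channels does not change the draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from . import physics
from .physics import (BeamConfig, ChannelSet, ResonanceModel, CHANNEL_ORDERS,
                      fwhm_to_sigma)
from .stack import ImageStack
from .segmentation import SegmentationResult

__all__ = [
    "Cell", "Vessel", "Distractor", "SceneSpec",
    "reference_beams", "deep_beams", "default_calibration",
    "expected_frame", "render_frame", "render_timeseries", "render_zstack",
    "ground_truth_masks", "embryo_scene", "static_cell_scene",
    "hypoxia_schedule",
]

_CANONICAL = {label: i for i, label in enumerate(CHANNEL_ORDERS)}


# ---------------------------------------------------------------------------
# scene description
# ---------------------------------------------------------------------------


@dataclass
class Cell:
    """One red blood cell.

    ``center`` is (y, x) in micrometers at t = 0; ``velocity`` is (vy, vx)
    in micrometers per second.  ``pulse_amplitude``/``pulse_period`` modulate
    the speed sinusoidally for cells carried by pulsatile arterial flow.
    """

    center: tuple[float, float]
    orientation: float = 0.0
    oxygen_saturation: float = 1.0
    velocity: tuple[float, float] = (0.0, 0.0)
    pulse_amplitude: float = 0.0
    pulse_period: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.oxygen_saturation <= 1.0:
            raise ValueError("oxygen_saturation must lie in [0, 1]")

    def displacement(self, t: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Integrated displacement (dy, dx) after time t seconds."""
        t = np.asarray(t, dtype=float)
        if self.pulse_amplitude:
            phase = 2.0 * math.pi * t / self.pulse_period
            eff = t + self.pulse_amplitude * self.pulse_period / (2.0 * math.pi) \
                * (1.0 - np.cos(phase))
        else:
            eff = t
        return self.velocity[0] * eff, self.velocity[1] * eff


@dataclass
class Vessel:
    """Straight tube segment; ``start``/``end`` are (y, x) in micrometers."""

    start: tuple[float, float]
    end: tuple[float, float]
    radius: float
    kind: str = "vein"  # "artery" (pulsatile) or "vein" (constant flow)
    wall_chi3: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in ("artery", "vein"):
            raise ValueError("vessel kind must be 'artery' or 'vein'")
        if self.radius <= 0:
            raise ValueError("vessel radius must be positive")


@dataclass
class Distractor:
    """Non-resonant structure producing THG/TSFG signal in all channels."""

    kind: str  # myelin_fiber | pigment_cell | lipid_body | interface
    center: tuple[float, float]
    size: tuple[float, float] = (5.0, 5.0)  # semi-axes, micrometers
    orientation: float = 0.0
    chi3: float = 0.3

    _KINDS = ("myelin_fiber", "pigment_cell", "lipid_body", "interface")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"distractor kind must be one of {self._KINDS}")


# geometry defaults: conventional morphology, micrometers
_HUMAN_RADIUS = 3.75              # biconcave disc, 7.5 um diameter
_FISH_SEMI = (5.5, 3.5)           # 11 x 7 um ellipsoid
_FISH_NUCLEUS_SEMI = (2.5, 1.5)   # 5 x 3 um central nucleus


@dataclass
class SceneSpec:
    """Full description of a synthetic field of view."""

    shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.5
    species: str = "zebrafish"  # or "human"
    cells: list[Cell] = field(default_factory=list)
    vessels: list[Vessel] = field(default_factory=list)
    distractors: list[Distractor] = field(default_factory=list)
    medium_chi3: float = 0.0
    cell_nonresonant_chi3: float = 0.05
    nucleus_chi3: float = 0.12
    plasma_chi3: float = 0.0
    interior_weight: float = 0.5
    oxy_model: ResonanceModel = field(default_factory=ResonanceModel.oxyhemoglobin)
    deoxy_model: ResonanceModel = field(default_factory=ResonanceModel.deoxyhemoglobin)
    detection_efficiency: dict[str, float] = field(
        default_factory=lambda: {"THG1": 0.3, "TSFG1": 0.5, "TSFG2": 1.0,
                                 "THG2": 1.0})
    dwell_time_us: float = 5.0
    calibration: float | None = None
    wrap_margin_um: float = 6.0
    vignette_radius_um: float | None = None  # radial TSFG falloff; off by default

    def __post_init__(self) -> None:
        if self.species not in ("human", "zebrafish"):
            raise ValueError("species must be 'human' or 'zebrafish'")
        if self.dwell_time_us <= 0:
            raise ValueError("dwell time must be positive")

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size_um,
                self.shape[1] * self.pixel_size_um)

    def efficiency(self, label: str) -> float:
        return self.detection_efficiency.get(label, 1.0)


# ---------------------------------------------------------------------------
# reference excitation configurations and calibration
# ---------------------------------------------------------------------------


def reference_beams(power1: float = 15.0, power2: float = 30.0,
                    delay: float = 0.0) -> tuple[BeamConfig, BeamConfig]:
    """OPO-system configuration: 1045/1300 nm, 80 MHz, 240/140 fs FWHM.

    The pump power defaults to half the OPO power: the dual-beam channels
    grow faster with power than the single-beam ones, and attenuating the
    pump balances the simultaneous channel levels while keeping the
    brightest pixels below the photon pile-up regime.
    """
    return (BeamConfig(1045.0, power1, fwhm_to_sigma(240.0), 12.5, 0.0),
            BeamConfig(1300.0, power2, fwhm_to_sigma(140.0), 12.5, delay))


def deep_beams(power1: float = 30.0, power2: float = 30.0,
               delay: float = 0.0) -> tuple[BeamConfig, BeamConfig]:
    """OPA-system configuration: 1030/1320 nm, 1 MHz, 250/180 fs FWHM."""
    return (BeamConfig(1030.0, power1, fwhm_to_sigma(250.0), 1000.0, 0.0),
            BeamConfig(1320.0, power2, fwhm_to_sigma(180.0), 1000.0, delay))


def default_calibration() -> float:
    """Photons/s per unit |chi(3)|^2, anchored so that an oxygenated RBC
    boundary pixel in the 433 nm channel of the reference OPO configuration
    emits about 2e6 photons/s (the observed per-cell signal scale)."""
    b1, b2 = reference_beams()
    oxy = ResonanceModel.oxyhemoglobin()
    chi2 = abs(physics.chi3_at_emission(b2.center_wavelength / 3.0, oxy)) ** 2
    unit = physics.signal_intensity(b1, b2, "THG2", 1.0)
    return 2.0e6 / (unit * chi2)


_DEFAULT_CALIBRATION = default_calibration()


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _grid(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = spec.shape
    y = (np.arange(ny) + 0.5) * spec.pixel_size_um
    x = (np.arange(nx) + 0.5) * spec.pixel_size_um
    return y[:, None], x[None, :]


def _ellipse(yy, xx, cy, cx, a_long, a_short, theta) -> np.ndarray:
    dy, dx = yy - cy, xx - cx
    c, s = math.cos(theta), math.sin(theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / a_long) ** 2 + (v / a_short) ** 2 <= 1.0


def _shell(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def _cell_position(spec: SceneSpec, cell: Cell, teff: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cell center (cy, cx) at per-row effective times, wrapped along x.

    Positions wrap with period (field width + 2 * margin) so that cells
    re-enter the field and the per-frame census stays roughly constant;
    a cell near the wrap seam is simply clipped at the field edge.
    """
    dy, dx = cell.displacement(teff)
    _, width = spec.field_um
    m = spec.wrap_margin_um
    period = width + 2.0 * m
    cx = np.mod(cell.center[1] + dx + m, period) - m
    cy = cell.center[0] + dy
    return cy, cx


def _cell_footprints(spec: SceneSpec, cell: Cell, t: float,
                     row_time_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Rasterized (footprint, nucleus) masks at frame time ``t``.

    The scan acquires rows sequentially, so row ``r`` sees the cell at
    ``t + r * row_time_s``; fast cells therefore appear sheared/elongated.
    """
    yy, xx = _grid(spec)
    ny = spec.shape[0]
    teff = t + np.arange(ny)[:, None] * row_time_s
    cy, cx = _cell_position(spec, cell, teff)
    if spec.species == "human":
        foot = _ellipse(yy, xx, cy, cx, _HUMAN_RADIUS, _HUMAN_RADIUS,
                        cell.orientation)
        nucleus = np.zeros_like(foot)
    else:
        foot = _ellipse(yy, xx, cy, cx, *_FISH_SEMI, cell.orientation)
        nucleus = _ellipse(yy, xx, cy, cx, *_FISH_NUCLEUS_SEMI,
                           cell.orientation)
    return foot, nucleus


def _vessel_footprint(spec: SceneSpec, vessel: Vessel) -> np.ndarray:
    yy, xx = _grid(spec)
    (y0, x0), (y1, x1) = vessel.start, vessel.end
    vy, vx = y1 - y0, x1 - x0
    norm2 = vy * vy + vx * vx
    if norm2 == 0:
        dist2 = (yy - y0) ** 2 + (xx - x0) ** 2
    else:
        s = np.clip(((yy - y0) * vy + (xx - x0) * vx) / norm2, 0.0, 1.0)
        dist2 = (yy - (y0 + s * vy)) ** 2 + (xx - (x0 + s * vx)) ** 2
    return dist2 <= vessel.radius ** 2


def _distractor_footprint(spec: SceneSpec, d: Distractor) -> np.ndarray:
    yy, xx = _grid(spec)
    if d.kind == "interface":
        half = max(d.size[1], spec.pixel_size_um)
        return np.abs(yy - d.center[0]) <= half
    return _ellipse(yy, xx, d.center[0], d.center[1], d.size[0], d.size[1],
                    d.orientation)


# ---------------------------------------------------------------------------
# expected images
# ---------------------------------------------------------------------------


def _chi2_map(spec: SceneSpec, emission_nm: float, t: float,
              row_time_s: float,
              saturations: Sequence[float] | None = None) -> np.ndarray:
    """Effective |chi(3)|^2 contrast map for one emission wavelength."""
    out = np.zeros(spec.shape, dtype=float)
    med = spec.medium_chi3

    for vessel in spec.vessels:
        foot = _vessel_footprint(spec, vessel)
        out[_shell(foot)] += abs(vessel.wall_chi3 - med) ** 2

    for d in spec.distractors:
        foot = _distractor_footprint(spec, d)
        out[_shell(foot)] += abs(d.chi3 - med) ** 2
        if d.kind == "myelin_fiber":
            # multilamellar interior also radiates
            out[foot] += 0.3 * abs(d.chi3 - med) ** 2

    for i, cell in enumerate(spec.cells):
        s = cell.oxygen_saturation if saturations is None else saturations[i]
        foot, nucleus = _cell_footprints(spec, cell, t, row_time_s)
        chi_cell = physics.chi3_mixture(
            physics.wavelength_to_angular_frequency(emission_nm) / 3.0,
            s, spec.oxy_model, spec.deoxy_model,
            nonresonant_chi3=spec.cell_nonresonant_chi3)
        out[_shell(foot)] += abs(chi_cell - spec.plasma_chi3) ** 2
        cytoplasm = foot & ~nucleus
        # hemoglobin fills the cytoplasm: resonance-weighted interior term
        out[cytoplasm] += spec.interior_weight * \
            abs(chi_cell - spec.cell_nonresonant_chi3) ** 2
        if nucleus.any():
            # nucleus carries only non-resonant chi(3): wavelength-flat
            flat = abs(spec.nucleus_chi3 - spec.cell_nonresonant_chi3) ** 2
            out[_shell(nucleus)] += flat
            out[nucleus] += spec.interior_weight * flat
    return out


def _vignette(spec: SceneSpec, label: str) -> np.ndarray | float:
    if spec.vignette_radius_um is None or label in ("THG1", "THG2"):
        return 1.0
    yy, xx = _grid(spec)
    hy, hx = spec.field_um[0] / 2.0, spec.field_um[1] / 2.0
    r = np.hypot(yy - hy, xx - hx)
    # TSFG efficiency falls off radially (chromatic foci mismatch):
    # ~30% reduction at vignette_radius_um off-center
    return np.clip(1.0 - 0.3 * (r / spec.vignette_radius_um) ** 2, 0.2, 1.0)


def expected_frame(spec: SceneSpec, beams: tuple[BeamConfig, BeamConfig],
                   channels: ChannelSet, t: float = 0.0,
                   saturations: Sequence[float] | None = None) -> np.ndarray:
    """Noise-free expected photon counts, shape (n_channels, ny, nx)."""
    if len(channels) < 1:
        raise ValueError("need at least one detection channel")
    beam1, beam2 = beams
    calib = spec.calibration if spec.calibration is not None \
        else _DEFAULT_CALIBRATION
    row_time_s = spec.shape[1] * spec.dwell_time_us * 1e-6
    dwell_s = spec.dwell_time_us * 1e-6
    out = np.empty((len(channels),) + spec.shape, dtype=float)
    for k, ch in enumerate(channels):
        chi2 = _chi2_map(spec, ch.emission_wavelength, t, row_time_s,
                         saturations)
        rate = physics.signal_intensity(beam1, beam2, ch.label, 1.0,
                                        calibration=calib)
        out[k] = dwell_s * spec.efficiency(ch.label) * rate * chi2 \
            * _vignette(spec, ch.label)
    return out


def _pileup_limit(spec: SceneSpec, beams) -> float:
    # photon counting saturates above ~1 detected photon per 4 laser pulses
    pulses_per_pixel = spec.dwell_time_us * 1e-6 / (beams[0].repetition_period * 1e-9)
    return pulses_per_pixel / 4.0


def _rng(seed: int, frame: int, label: str) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(frame, _CANONICAL[label]))
    return np.random.default_rng(ss)


def _metadata(spec, beams, channels, n_planes):
    b1, b2 = beams
    return dict(
        channel_wavelengths=tuple(ch.emission_wavelength for ch in channels),
        channel_labels=tuple(ch.label for ch in channels),
        pixel_size_um=spec.pixel_size_um,
        dwell_time_us=spec.dwell_time_us,
        plane_powers=np.tile([b1.average_power, b2.average_power],
                             (n_planes, 1)),
        plane_durations=np.tile([b1.pulse_duration, b2.pulse_duration],
                                (n_planes, 1)),
    )


def render_frame(spec: SceneSpec, beams: tuple[BeamConfig, BeamConfig],
                 channels: ChannelSet, t: float = 0.0, seed: int = 0,
                 _frame_index: int = 0,
                 saturations: Sequence[float] | None = None) -> ImageStack:
    """Render one time point with Poisson counting noise."""
    expected = expected_frame(spec, beams, channels, t, saturations)
    pileup = bool(expected.max() > _pileup_limit(spec, beams))
    if pileup:
        warnings.warn("expected counts exceed 1 photon per 4 laser pulses: "
                      "photon pile-up regime", stacklevel=2)
    counts = np.empty_like(expected)
    for k, ch in enumerate(channels):
        counts[k] = _rng(seed, _frame_index, ch.label).poisson(expected[k])
    return ImageStack(
        data=counts[None].astype(np.int64),
        axis="single",
        plane_positions=np.array([t]),
        seed=seed,
        extras={"pileup_warning": pileup, "t_index": _frame_index},
        **_metadata(spec, beams, channels, 1),
    )


def render_timeseries(spec: SceneSpec, beams: tuple[BeamConfig, BeamConfig],
                      channels: ChannelSet, n_frames: int,
                      frame_interval: float, seed: int = 0,
                      saturation_schedule: Callable[[float], float | Sequence[float]] | None = None
                      ) -> ImageStack:
    """Render ``n_frames`` frames ``frame_interval`` seconds apart.

    ``saturation_schedule(t_seconds)`` may return a scalar (applied to all
    cells) or one value per cell; when omitted, each cell keeps its own
    ``oxygen_saturation``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    frames, times, pileup = [], [], False
    for i in range(n_frames):
        t = i * frame_interval
        sats = None
        if saturation_schedule is not None:
            s = saturation_schedule(t)
            sats = [float(s)] * len(spec.cells) if np.isscalar(s) \
                else list(np.asarray(s, dtype=float))
        fr = render_frame(spec, beams, channels, t=t, seed=seed,
                          _frame_index=i, saturations=sats)
        pileup |= fr.extras["pileup_warning"]
        frames.append(fr.data[0])
        times.append(t)
    return ImageStack(
        data=np.stack(frames),
        axis="t",
        plane_positions=np.asarray(times),
        seed=seed,
        extras={"pileup_warning": pileup, "frame_interval_s": frame_interval},
        **_metadata(spec, beams, channels, n_frames),
    )


def render_zstack(spec: SceneSpec, beams: tuple[BeamConfig, BeamConfig],
                  channels: ChannelSet, z_positions: Sequence[float],
                  per_plane_powers: Sequence[float] | np.ndarray,
                  eal_true: float, seed: int = 0) -> ImageStack:
    """Render a z-series with depth attenuation and power stepping.

    The expected signal of a channel with process orders (n1, n2) at depth
    z is the surface frame scaled by ``(P1(z)/P1)^n1 (P2(z)/P2)^n2 *
    exp(-3 z / eal_true)``; Poisson noise is applied after scaling.
    ``per_plane_powers`` is either one scalar per plane (both beams scaled
    together) or one (P1, P2) pair per plane.
    """
    z = np.asarray(z_positions, dtype=float)
    if np.any(np.diff(z) <= 0):
        raise ValueError("z_positions must be strictly increasing")
    if not eal_true > 0:
        raise ValueError("eal_true must be positive (may be inf)")
    powers = np.asarray(per_plane_powers, dtype=float)
    if powers.ndim == 1:
        powers = np.column_stack([powers, powers])
    if powers.shape != (len(z), 2):
        raise ValueError("per_plane_powers must match z_positions")
    beam1, beam2 = beams
    base = expected_frame(spec, beams, channels, t=0.0)
    planes = []
    for i, zi in enumerate(z):
        att = math.exp(-3.0 * zi / eal_true) if np.isfinite(eal_true) else 1.0
        plane = np.empty_like(base)
        for k, ch in enumerate(channels):
            n1, n2 = ch.process_orders
            scale = ((powers[i, 0] / beam1.average_power) ** n1
                     * (powers[i, 1] / beam2.average_power) ** n2 * att)
            plane[k] = _rng(seed, i, ch.label).poisson(base[k] * scale)
        planes.append(plane)
    meta = _metadata(spec, beams, channels, len(z))
    meta["plane_powers"] = powers
    return ImageStack(
        data=np.stack(planes).astype(np.int64),
        axis="z",
        plane_positions=z,
        z_step_um=float(z[1] - z[0]) if len(z) > 1 else None,
        seed=seed,
        extras={"eal_true_um": float(eal_true)},
        **meta,
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def ground_truth_masks(spec: SceneSpec,
                       times: Sequence[float] = (0.0,)) -> SegmentationResult:
    """Exact vessel-lumen and per-frame RBC masks, consistent with the
    rendered (row-sheared, wrapped) cell displacements."""
    vessel = np.zeros(spec.shape, dtype=bool)
    for v in spec.vessels:
        vessel |= _vessel_footprint(spec, v)
    row_time_s = spec.shape[1] * spec.dwell_time_us * 1e-6
    rbc, labels = [], []
    for t in times:
        mask = np.zeros(spec.shape, dtype=bool)
        lab = np.zeros(spec.shape, dtype=np.int32)
        for i, cell in enumerate(spec.cells):
            foot, _ = _cell_footprints(spec, cell, t, row_time_s)
            mask |= foot
            lab[foot] = i + 1
        rbc.append(mask)
        labels.append(lab)
    return SegmentationResult(vessel_mask=vessel,
                              rbc_masks=np.stack(rbc),
                              labels=np.stack(labels))


# ---------------------------------------------------------------------------
# scene factories
# ---------------------------------------------------------------------------


def embryo_scene(seed: int = 0, shape: tuple[int, int] = (128, 256),
                 pixel_size_um: float = 0.5,
                 cells_per_vessel: int | None = None,
                 saturation: float = 1.0, species: str = "zebrafish",
                 with_distractors: bool = True) -> SceneSpec:
    """Trunk-vasculature scene: a pulsatile artery and a constant-flow vein
    running along x, each carrying a train of flowing RBCs, plus
    non-resonant distractor structures outside the vessels."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(901,)))
    height, width = shape[0] * pixel_size_um, shape[1] * pixel_size_um
    artery_y, vein_y = 0.28 * height, 0.62 * height
    # embryonic trunk vessels are barely wider than the cells they carry
    radius = 4.0
    spec = SceneSpec(shape=shape, pixel_size_um=pixel_size_um, species=species)
    spec.vessels = [
        Vessel((artery_y, -10.0), (artery_y, width + 10.0), radius, "artery"),
        Vessel((vein_y, -10.0), (vein_y, width + 10.0), radius, "vein"),
    ]
    margin = spec.wrap_margin_um
    period = width + 2.0 * margin
    if cells_per_vessel is None:
        # keep neighbouring cells resolvable: ~15.5 um center spacing
        cells_per_vessel = max(3, int(period / 15.5))
    spacing = period / cells_per_vessel
    # train speeds: fast enough for visible intra-frame shear of arterial
    # cells, slow enough that neighbours stay resolvable, and chosen
    # non-commensurate with typical frame intervals so the wrapped train
    # samples many positions along the lumen
    for y0, speed, kind in ((artery_y, 213.7, "artery"),
                            (vein_y, 107.3, "vein")):
        for i in range(cells_per_vessel):
            x0 = i * spacing + rng.uniform(-0.08, 0.08) * spacing
            yj = y0 + rng.uniform(-1.0, 1.0)
            spec.cells.append(Cell(
                center=(yj, x0),
                orientation=rng.uniform(-0.15, 0.15),
                oxygen_saturation=saturation,
                velocity=(0.0, speed),
                pulse_amplitude=0.5 if kind == "artery" else 0.0,
                pulse_period=0.5,
            ))
    if with_distractors:
        spec.distractors = [
            Distractor("myelin_fiber", (0.08 * height, width / 2.0),
                       (0.45 * width, 0.8), orientation=0.0, chi3=0.35),
            Distractor("pigment_cell", (0.85 * height, 0.25 * width),
                       (6.0, 4.0), orientation=0.6, chi3=0.3),
            Distractor("lipid_body", (0.85 * height, 0.7 * width),
                       (2.0, 2.0), chi3=0.4),
        ]
    return spec


def static_cell_scene(saturations: Sequence[float],
                      shape: tuple[int, int] = (64, 64),
                      pixel_size_um: float = 0.5,
                      species: str = "zebrafish",
                      seed: int = 0) -> SceneSpec:
    """Immobilized RBCs on a grid (sealed-chamber preparations)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(902,)))
    height, width = shape[0] * pixel_size_um, shape[1] * pixel_size_um
    n = len(saturations)
    ncol = max(1, int(math.floor(width / 16.0)))
    nrow = int(math.ceil(n / ncol))
    if nrow * 16.0 > height:
        raise ValueError("field too small for the requested cell count")
    spec = SceneSpec(shape=shape, pixel_size_um=pixel_size_um, species=species)
    for i, s in enumerate(saturations):
        r, c = divmod(i, ncol)
        spec.cells.append(Cell(
            center=(8.0 + r * 16.0 + rng.uniform(-1, 1),
                    8.0 + c * 16.0 + rng.uniform(-1, 1)),
            orientation=rng.uniform(0, math.pi),
            oxygen_saturation=float(s),
        ))
    return spec


def hypoxia_schedule(control_end_min: float = 30.0,
                     hypoxia_end_min: float = 180.0,
                     s_min: float = 0.72,
                     decline_tau_min: float | None = None
                     ) -> Callable[[float], float]:
    """Oxygen-saturation time course of the sealed-chamber hypoxia assay.

    Saturation holds at 1 during the control window, declines exponentially
    towards ``s_min`` while the chamber is sealed, and steps back to 1 when
    the chamber is opened.  The default floor s_min = 0.72 makes the
    oxygenation index R drop by ~40% at full hypoxia, the typical drop
    after 3 h in a sealed chamber.  Argument of the returned callable is
    time in seconds.
    """
    if decline_tau_min is None:
        decline_tau_min = (hypoxia_end_min - control_end_min) / 3.0

    def schedule(t_seconds: float) -> float:
        t_min = t_seconds / 60.0
        if t_min < control_end_min:
            return 1.0
        if t_min < hypoxia_end_min:
            return s_min + (1.0 - s_min) * math.exp(
                -(t_min - control_end_min) / decline_tau_min)
        return 1.0

    return schedule
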