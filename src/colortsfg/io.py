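"""Readers/writers, run configuration and the end-to-end workflows.

Image stacks travel as multi-page TIFF (one page per channel per plane)
with a plain-text YAML sidecar carrying the acquisition metadata the
analysis needs — channel emission wavelengths and labels, pixel size,
per-plane powers and durations, z/t positions, and the generating seed.
The ratiometric analysis is undefined without channel wavelengths, so a
missing sidecar key is a hard error.

Two workflows tie the stages together: the embryo time-series workflow
(simulate -> segment -> oximetry) and the deep z-series workflow
(simulate -> EAL fit -> renormalize -> segment).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from . import attenuation, oximetry, physics, scenes, segmentation
from .stack import ImageStack

__all__ = ["write_stack", "read_stack", "write_mask", "RunConfig",
           "load_config", "run_pipeline"]

_REQUIRED_KEYS = ("channel_wavelengths", "channel_labels", "axis",
                  "pixel_size_um", "dwell_time_us")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    n_p, n_c, ny, nx = stack.data.shape
    pages = stack.data.reshape(n_p * n_c, ny, nx)
    if np.issubdtype(pages.dtype, np.integer):
        pages = pages.astype(np.int32)
    else:
        pages = pages.astype(np.float32)
    tifffile.imwrite(path, pages)
    meta: dict[str, Any] = dict(
        channel_wavelengths=[float(w) for w in stack.channel_wavelengths],
        channel_labels=list(stack.channel_labels),
        axis=stack.axis,
        pixel_size_um=float(stack.pixel_size_um),
        dwell_time_us=float(stack.dwell_time_us),
        n_planes=n_p,
        n_channels=n_c,
        seed=stack.seed,
        z_step_um=stack.z_step_um,
        extras={k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in stack.extras.items()},
    )
    for name in ("plane_positions", "plane_powers", "plane_durations"):
        arr = getattr(stack, name)
        meta[name] = None if arr is None else np.asarray(arr).tolist()
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF + sidecar pair back into an :class:`ImageStack`.

    Channel order is taken from the sidecar metadata, never assumed from
    page order conventions; missing channel-wavelength metadata is a hard
    error because the ratiometric analysis is undefined without it.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} is missing")
    meta = yaml.safe_load(sidecar.read_text())
    for key in _REQUIRED_KEYS:
        if key not in meta or meta[key] is None:
            raise KeyError(f"sidecar {sidecar.name} is missing required "
                           f"metadata key {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_p, n_c = int(meta["n_planes"]), int(meta["n_channels"])
    data = pages.reshape(n_p, n_c, *pages.shape[-2:])
    return ImageStack(
        data=data,
        channel_wavelengths=tuple(meta["channel_wavelengths"]),
        channel_labels=tuple(meta["channel_labels"]),
        axis=meta["axis"],
        pixel_size_um=meta["pixel_size_um"],
        dwell_time_us=meta["dwell_time_us"],
        plane_positions=None if meta.get("plane_positions") is None
        else np.asarray(meta["plane_positions"], dtype=float),
        plane_powers=None if meta.get("plane_powers") is None
        else np.asarray(meta["plane_powers"], dtype=float),
        plane_durations=None if meta.get("plane_durations") is None
        else np.asarray(meta["plane_durations"], dtype=float),
        z_step_um=meta.get("z_step_um"),
        seed=meta.get("seed"),
        extras=meta.get("extras") or {},
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary (or label) mask as 8-bit TIFF."""
    path = Path(path)
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    else:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    tifffile.imwrite(path, arr)
    return path


# ---------------------------------------------------------------------------
# run configuration and pipelines
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    workflow: str = "embryo"            # "embryo" or "deep"
    out_dir: str = "results"
    seed: int = 0
    input_stack: str | None = None      # skip simulation when given
    # simulation
    n_frames: int = 30
    frame_interval_s: float = 300.0     # 5 min
    shape: tuple[int, int] = (128, 256)
    saturation: float = 1.0
    hypoxia: bool = False
    # beams (pump attenuated to balance the simultaneous channels)
    system: str = "opo"                 # "opo" (1045/1300) or "opa" (1030/1320)
    power1_mw: float = 15.0
    power2_mw: float = 30.0
    # segmentation
    recipe: str = "ratio_sum"
    sigma: float = 1.0
    min_size: int = 9
    threshold: str | float = "otsu"
    # oximetry windows, minutes
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    control_window: tuple[float, float] = (0.0, 30.0)
    # deep workflow
    n_planes: int = 14
    z_step_um: float = 4.0
    eal_true_um: float = 150.0
    power_step: float = 1.12            # power multiplier per plane

    def beams(self):
        if self.system == "opo":
            return scenes.reference_beams(self.power1_mw, self.power2_mw)
        if self.system == "opa":
            return scenes.deep_beams(self.power1_mw, self.power2_mw)
        raise ValueError("system must be 'opo' or 'opa'")

    def channels(self):
        b1, b2 = self.beams()
        full = physics.mix_wavelengths(b1.center_wavelength,
                                       b2.center_wavelength)
        # the shortest-wavelength THG1 signal is poorly transmitted and
        # not detected; keep the three detected channels
        return full.subset(["TSFG1", "TSFG2", "THG2"])


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration (keys as in :class:`RunConfig`)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    for key, val in raw.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, tuple) and isinstance(val, (list, tuple)):
            val = tuple(val)
        if key == "windows" and isinstance(val, dict):
            val = {k: tuple(v) for k, v in val.items()}
        setattr(cfg, key, val)
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps({k: str(v) for k, v in vars(cfg).items()},
                      sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _run_log(cfg: RunConfig, out: Path, stages: list[str]) -> None:
    from . import __version__
    log = dict(version=__version__, seed=cfg.seed,
               config_hash=_config_hash(cfg), workflow=cfg.workflow,
               stages=stages,
               params={k: str(v) for k, v in vars(cfg).items()})
    (out / "run_log.json").write_text(json.dumps(log, indent=2))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured workflow and write all outputs.

    Embryo workflow: simulate (or load) a time series, compute the vessel
    and RBC masks, the per-frame R series, and window summaries.  Deep
    workflow: simulate (or load) a power-stepped z-stack, fit the EAL per
    channel, renormalize, and segment the renormalized stack.  Stage
    failures are re-raised with the stage name attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        beams = cfg.beams()
        channels = cfg.channels()
        results: dict[str, Any] = {}
        stages = []

        if cfg.workflow == "embryo":
            stage = "simulate"
            if cfg.input_stack:
                stack = read_stack(cfg.input_stack)
            else:
                spec = scenes.embryo_scene(seed=cfg.seed, shape=cfg.shape,
                                           saturation=cfg.saturation)
                schedule = scenes.hypoxia_schedule() if cfg.hypoxia else None
                stack = scenes.render_timeseries(
                    spec, beams, channels, cfg.n_frames, cfg.frame_interval_s,
                    seed=cfg.seed, saturation_schedule=schedule)
                write_stack(stack, out / "timeseries.tif")
            stages.append("simulate")

            stage = "segment"
            seg = segmentation.segment_timeseries(
                stack, segmentation.EnhancementRecipe(cfg.recipe),
                sigma=cfg.sigma, threshold=cfg.threshold,
                min_size=cfg.min_size)
            write_mask(seg.vessel_mask, out / "vessel_mask.tif")
            write_mask(seg.rbc_masks.any(axis=0), out / "rbc_mask_any.tif")
            stages.append("segment")

            stage = "oximetry"
            oxi = oximetry.timeseries_R(stack, seg)
            oxi.table.to_csv(out / "oximetry_frames.csv", index=False)
            oxi.cells.to_csv(out / "oximetry_cells.csv", index=False)
            if cfg.windows:
                summaries = oximetry.normalize_to_control(
                    oxi, cfg.control_window, cfg.windows)
                pd_path = out / "oximetry_windows.csv"
                with open(pd_path, "w") as fh:
                    fh.write("window,normalized_R\n")
                    for name, val in summaries.items():
                        fh.write(f"{name},{val:.6f}\n")
                results["windows"] = summaries
            stages.append("oximetry")
            results.update(segmentation=seg, oximetry=oxi, stack=stack)

        elif cfg.workflow == "deep":
            stage = "simulate"
            if cfg.input_stack:
                stack = read_stack(cfg.input_stack)
            else:
                spec = scenes.embryo_scene(seed=cfg.seed, shape=cfg.shape,
                                           saturation=cfg.saturation,
                                           with_distractors=True)
                for cell in spec.cells:   # deep stacks image static planes
                    cell.velocity = (0.0, 0.0)
                z = np.arange(cfg.n_planes) * cfg.z_step_um
                ramp = cfg.power_step ** np.arange(cfg.n_planes)
                powers = np.column_stack([cfg.power1_mw * ramp,
                                          cfg.power2_mw * ramp])
                stack = scenes.render_zstack(spec, beams, channels, z,
                                             powers, cfg.eal_true_um,
                                             seed=cfg.seed)
                write_stack(stack, out / "zstack.tif")
            stages.append("simulate")

            stage = "depthfit"
            fits = [attenuation.fit_eal(stack, channel=lb)
                    for lb in stack.channel_labels]
            attenuation.fit_report(fits).to_csv(out / "eal_fits.csv",
                                                index=False)
            renorm = attenuation.renormalize_zstack(stack, fits)
            write_stack(renorm, out / "zstack_renormalized.tif")
            stages.append("depthfit")

            stage = "segment"
            seg = segmentation.segment_timeseries(
                renorm, segmentation.EnhancementRecipe(cfg.recipe),
                sigma=cfg.sigma, threshold=cfg.threshold,
                min_size=cfg.min_size)
            write_mask(seg.vessel_mask, out / "vessel_mask.tif")
            stages.append("segment")
            results.update(fits=fits, segmentation=seg, stack=stack,
                           renormalized=renorm)
        else:
            raise ValueError(f"unknown workflow {cfg.workflow!r}")

        _run_log(cfg, out, stages)
        return results
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
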