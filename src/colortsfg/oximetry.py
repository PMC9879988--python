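"""Label-free red blood cell oximetry from ratiometric TSFG signals.

With 1045/1300 nm excitation the 401 nm and 433 nm signals straddle the
oxy/deoxy Soret peaks, so the per-cell ratio R = S401/S433 reports the
oxygenation state: oxygenated cells show a higher R.  R is estimated per
segmented cell as the slope of a least-squares regression of the 401 nm
pixel signals on the 433 nm pixel signals, through the origin by default
(with background removed, zero signal at 433 implies zero at 401).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import SegmentationResult
from .stack import ImageStack

__all__ = [
    "CellR", "OximetryResult", "cell_R", "frame_R", "timeseries_R",
    "normalize_to_control", "welch_test",
]


@dataclass(frozen=True)
class CellR:
    """Oxygenation parameter of one cell: regression slope with its
    standard error and the number of pixels used."""

    R: float
    se: float
    n_pixels: int


def cell_R(frame: ImageStack, cell_pixels: np.ndarray,
           numerator: str | float = 401, denominator: str | float = 433,
           intercept: bool = False, min_pixels: int = 5) -> CellR:
    """Slope of S401 vs S433 over one cell's pixels.

    ``cell_pixels`` is a boolean mask (or label image == label) selecting
    the segmented cell.  ``intercept=True`` adds a free intercept; the
    default regresses through the origin.
    """
    mask = np.asarray(cell_pixels, dtype=bool)
    if mask.sum() < min_pixels:
        raise ValueError(f"cell has {int(mask.sum())} pixels; "
                         f"need at least {min_pixels}")
    y = frame.channel(numerator)[0][mask].astype(float)
    x = frame.channel(denominator)[0][mask].astype(float)
    if not np.any(x != 0):
        raise ValueError("all-zero denominator channel: R undefined")
    if intercept:
        design = np.column_stack([x, np.ones_like(x)])
    else:
        design = x[:, None]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = max(len(x) - design.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    return CellR(R=float(coef[0]), se=float(np.sqrt(cov[0, 0])),
                 n_pixels=int(mask.sum()))


def frame_R(frame: ImageStack, labels: np.ndarray,
            min_pixels: int = 5, **kwargs) -> pd.DataFrame:
    """Per-cell R for every labeled component in one frame.

    Cells with too few pixels or an undefined ratio are skipped.
    """
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        try:
            est = cell_R(frame, labels == lab, min_pixels=min_pixels, **kwargs)
        except ValueError:
            continue
        rows.append(dict(label=int(lab), R=est.R, se_R=est.se,
                         n_pixels=est.n_pixels))
    return pd.DataFrame(rows, columns=["label", "R", "se_R", "n_pixels"])


@dataclass
class OximetryResult:
    """Per-frame oxygenation summary of a time series."""

    table: pd.DataFrame          # frame, time_s, n_cells, mean_R, sd_R
    cells: pd.DataFrame          # frame, label, R, se_R, n_pixels
    excluded_frames: list[int] = field(default_factory=list)

    @property
    def series(self) -> pd.Series:
        return self.table.set_index("frame")["mean_R"]


def timeseries_R(stack: ImageStack, segmentation: SegmentationResult,
                 min_pixels: int = 5, **kwargs) -> OximetryResult:
    """Frame-wise average of per-cell R over a segmented time series.

    Frames where no cell passes the pixel-count filter are flagged in
    ``excluded_frames`` and omitted from the summary table.
    """
    if segmentation.labels.shape[0] != stack.n_planes:
        raise ValueError("segmentation frames do not match the stack")
    times = (stack.plane_positions if stack.plane_positions is not None
             else np.arange(stack.n_planes, dtype=float))
    frames, cell_rows, excluded = [], [], []
    for f in range(stack.n_planes):
        per_cell = frame_R(stack.plane(f), segmentation.labels[f],
                           min_pixels=min_pixels, **kwargs)
        if per_cell.empty:
            excluded.append(f)
            continue
        per_cell.insert(0, "frame", f)
        cell_rows.append(per_cell)
        frames.append(dict(frame=f, time_s=float(times[f]),
                           n_cells=len(per_cell),
                           mean_R=float(per_cell["R"].mean()),
                           sd_R=float(per_cell["R"].std(ddof=1))
                           if len(per_cell) > 1 else 0.0))
    table = pd.DataFrame(frames,
                         columns=["frame", "time_s", "n_cells", "mean_R",
                                  "sd_R"])
    cells = (pd.concat(cell_rows, ignore_index=True) if cell_rows
             else pd.DataFrame(columns=["frame", "label", "R", "se_R",
                                        "n_pixels"]))
    return OximetryResult(table=table, cells=cells, excluded_frames=excluded)


def normalize_to_control(result: OximetryResult,
                         control_window: tuple[float, float],
                         summary_windows: dict[str, tuple[float, float]]
                         ) -> dict[str, float]:
    """Window summaries normalized to the control period.

    Windows are (start, end) in minutes.  Each window's mean R is divided
    by the median R of the control window, so the control value is 1 by
    construction when the control window is its own summary.
    """
    t_min = result.table["time_s"].to_numpy() / 60.0
    r = result.table["mean_R"].to_numpy()

    def window_values(lo, hi):
        sel = (t_min >= lo) & (t_min < hi)
        if not sel.any():
            raise ValueError(f"window [{lo}, {hi}) min contains no frames")
        return r[sel]

    control_median = float(np.median(window_values(*control_window)))
    if control_median == 0:
        raise ValueError("control-window median R is zero")
    return {name: float(np.mean(window_values(*win))) / control_median
            for name, win in summary_windows.items()}


def welch_test(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance two-tailed t test.

    Returns (statistic, p).  Two groups with zero variance and equal means
    are reported as indistinguishable (statistic 0, p = 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)
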