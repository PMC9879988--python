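"""Shared fixtures: beam configurations, channel sets and rendered scenes.

Expensive renders are session-scoped so the unit suites and the end-to-end
checks reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from colortsfg import mix_wavelengths, physics, scenes
from colortsfg.scenes import reference_beams
from colortsfg import segmentation


@pytest.fixture(scope="session")
def beams():
    return reference_beams()


@pytest.fixture(scope="session")
def channels3(beams):
    b1, b2 = beams
    return mix_wavelengths(b1.center_wavelength,
                           b2.center_wavelength).subset(
        ["TSFG1", "TSFG2", "THG2"])


@pytest.fixture(scope="session")
def embryo_fixture(beams, channels3):
    """Default seeded embryo time series: 30 frames every 5 min, ~18
    flowing cells per frame, with ground truth and the default
    segmentation."""
    spec = scenes.embryo_scene(seed=1)
    stack = scenes.render_timeseries(spec, beams, channels3, 30, 300.0,
                                     seed=1)
    truth = scenes.ground_truth_masks(spec, times=stack.plane_positions)
    seg = segmentation.segment_timeseries(stack)
    return dict(spec=spec, stack=stack, truth=truth, seg=seg)


@pytest.fixture(scope="session")
def oxy_deoxy_cells(beams, channels3):
    """Rendered immobilized cells: oxygenated (N=6) and deoxygenated (N=8),
    with ground-truth labels."""
    out = {}
    for name, sats, seed in (("oxy", [1.0] * 6, 11), ("deoxy", [0.0] * 8, 12)):
        spec = scenes.static_cell_scene(sats, shape=(96, 96), seed=seed)
        stack = scenes.render_frame(spec, beams, channels3, seed=seed + 10)
        labels = scenes.ground_truth_masks(spec).labels[0]
        out[name] = dict(spec=spec, stack=stack, labels=labels)
    return out


@pytest.fixture(scope="session")
def saturation_sweep(beams, channels3):
    """Mean estimated R per generator saturation level, >=100 cells per
    level (7 fields of 16 immobilized cells each)."""
    from colortsfg import oximetry

    levels = [0.0, 0.25, 0.5, 0.75, 1.0]
    means = []
    for s in levels:
        values = []
        for rep in range(7):
            spec = scenes.static_cell_scene([s] * 16, shape=(128, 128),
                                            seed=rep)
            stack = scenes.render_frame(spec, beams, channels3,
                                        seed=100 + rep)
            labels = scenes.ground_truth_masks(spec).labels[0]
            values.extend(oximetry.frame_R(stack, labels)["R"])
        means.append(float(np.mean(values)))
    return levels, means


@pytest.fixture(scope="session")
def oxy_scan(beams):
    """Single-beam THG excitation scan (1120-1300 nm, 10 nm steps) of
    immobilized oxygenated cells, with power and pulse duration drifting
    across the scan as they do on a real OPO, plus the noise-free truth."""
    from colortsfg import spectroscopy

    spec = scenes.static_cell_scene([1.0] * 4, shape=(64, 64), seed=0)
    mask = scenes.ground_truth_masks(spec).rbc_masks[0]
    records, truth = [], {}
    for i, lam in enumerate(np.arange(1120.0, 1301.0, 10.0)):
        power = 30.0 + 0.05 * (lam - 1120.0)
        tau = physics.fwhm_to_sigma(140.0 + 0.1 * (lam - 1120.0))
        pair = (physics.BeamConfig(1045.0, 1e-9, physics.fwhm_to_sigma(240.0),
                                   12.5),
                physics.BeamConfig(lam, power, tau, 12.5))
        chans = physics.mix_wavelengths(1045.0, lam).subset(["THG2"])
        stack = scenes.render_frame(spec, pair, chans, seed=5,
                                    _frame_index=i)
        records.append(spectroscopy.SpectralRecord(lam, stack, power, tau))
        expected = scenes.expected_frame(spec, pair, chans)[0]
        truth[lam] = float(expected[mask].mean()) * tau ** 2 / power ** 3
    return dict(series=spectroscopy.SpectralSeries(records), mask=mask,
                truth=truth, spec=spec)
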