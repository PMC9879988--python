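"""Synthetic-scene generator tests: determinism, Poisson statistics,
oxygenation-dependent contrast, scan-shear motion, depth scaling, and
ground-truth consistency."""

import numpy as np
import pytest

from colortsfg import mix_wavelengths, physics, scenes
from colortsfg.scenes import (Cell, SceneSpec, Vessel, embryo_scene,
                              expected_frame, ground_truth_masks,
                              hypoxia_schedule, render_frame,
                              render_timeseries, render_zstack,
                              static_cell_scene)


def single_beam(lam=1240.0, power=30.0):
    """OPO-only excitation (pump effectively off) for single-beam THG."""
    return (physics.BeamConfig(1045.0, 1e-9, physics.fwhm_to_sigma(240.0),
                               12.5),
            physics.BeamConfig(lam, power, physics.fwhm_to_sigma(140.0),
                               12.5))


def thg2_channel(lam):
    return mix_wavelengths(1045.0, lam).subset(["THG2"])


def test_uniform_medium_produces_no_signal(beams, channels3):
    spec = SceneSpec(shape=(32, 32))
    assert expected_frame(spec, beams, channels3).max() == 0.0


def test_same_seed_reproduces_identical_counts(beams, channels3):
    spec = static_cell_scene([1.0], shape=(32, 32))
    a = render_frame(spec, beams, channels3, seed=7)
    b = render_frame(spec, beams, channels3, seed=7)
    assert np.array_equal(a.data, b.data)
    c = render_frame(spec, beams, channels3, seed=8)
    assert not np.array_equal(a.data, c.data)


def test_channel_order_does_not_change_draws(beams):
    """Poisson streams are keyed on the canonical channel identity, so a
    reordered channel set yields the same counts per channel."""
    spec = static_cell_scene([1.0], shape=(32, 32))
    full = mix_wavelengths(1045.0, 1300.0)
    fwd = full.subset(["TSFG1", "TSFG2", "THG2"])
    rev = full.subset(["THG2", "TSFG1", "TSFG2"])
    a = render_frame(spec, beams, fwd, seed=3)
    b = render_frame(spec, beams, rev, seed=3)
    assert np.array_equal(a.channel("THG2"), b.channel("THG2"))
    assert np.array_equal(a.channel("TSFG1"), b.channel("TSFG1"))


def test_poisson_mean_converges_to_expected_image(beams, channels3):
    spec = static_cell_scene([1.0], shape=(32, 32))
    expected = expected_frame(spec, beams, channels3)
    acc = np.zeros_like(expected)
    n = 400
    for k in range(n):
        acc += render_frame(spec, beams, channels3, seed=k).data[0]
    acc /= n
    sel = expected > 1.0
    rel = np.abs(acc[sel] - expected[sel]).sum() / expected[sel].sum()
    assert rel < 0.02


def test_oxygenation_raises_the_401_to_433_ratio(beams, channels3):
    """The mean S401/S433 of an oxygenated cell exceeds the deoxygenated
    one (expected images; Soret resonance sits closer to 415 nm)."""
    ratios = {}
    for s in (0.0, 1.0):
        spec = static_cell_scene([s], shape=(48, 48))
        exp = expected_frame(spec, beams, channels3)
        mask = ground_truth_masks(spec).rbc_masks[0]
        stack_ratio = exp[channels3.labels.index("TSFG2")][mask].mean() / \
            exp[channels3.labels.index("THG2")][mask].mean()
        ratios[s] = stack_ratio
    assert ratios[1.0] > ratios[0.0]


def test_on_off_resonance_enhancement_in_expected_range():
    """Single-beam THG from the default oxygenated cell is 10-20x stronger
    at 1240 nm than at 1120 nm excitation, matching the observed
    enhancement window."""
    spec = static_cell_scene([1.0], shape=(48, 48))
    mask = ground_truth_masks(spec).rbc_masks[0]
    means = {}
    for lam in (1120.0, 1240.0):
        exp = expected_frame(spec, single_beam(lam), thg2_channel(lam))[0]
        means[lam] = exp[mask].mean()
    ratio = means[1240.0] / means[1120.0]
    assert 10.0 <= ratio <= 20.0


def test_nucleus_signal_is_wavelength_flat():
    """Zebrafish nuclei carry only non-resonant susceptibility: their
    normalized expected signal is identical across excitation wavelengths,
    while cytoplasm signal is strongly enhanced on resonance."""
    spec = static_cell_scene([1.0], shape=(48, 48), species="zebrafish")
    yy, xx = np.mgrid[0:48, 0:48] * 0.5 + 0.25
    cell = spec.cells[0]
    nucleus = ((xx - cell.center[1]) ** 2 / 1.0 ** 2
               + (yy - cell.center[0]) ** 2 / 1.0 ** 2) <= 1.0  # deep interior
    vals = {}
    for lam in (1120.0, 1240.0):
        exp = expected_frame(spec, single_beam(lam), thg2_channel(lam))[0]
        prefactor = physics.signal_intensity(*single_beam(lam), "THG2", 1.0)
        vals[lam] = exp[nucleus].mean() / prefactor
    assert vals[1240.0] == pytest.approx(vals[1120.0], rel=1e-9)


def test_render_rejects_too_few_channels(beams):
    spec = static_cell_scene([1.0], shape=(32, 32))
    with pytest.raises(ValueError):
        expected_frame(spec, beams, physics.ChannelSet(()))


def test_pileup_regime_is_flagged(channels3):
    spec = static_cell_scene([1.0], shape=(32, 32))
    hot = (physics.BeamConfig(1045.0, 300.0, physics.fwhm_to_sigma(240.0),
                              12.5),
           physics.BeamConfig(1300.0, 300.0, physics.fwhm_to_sigma(140.0),
                              12.5))
    with pytest.warns(UserWarning, match="pile-up"):
        frame = render_frame(spec, hot, channels3, seed=0)
    assert frame.extras["pileup_warning"]


# ---------------------------------------------------------------------------
# time series and motion
# ---------------------------------------------------------------------------


def test_static_cells_render_identical_expected_images(beams, channels3):
    spec = static_cell_scene([0.8, 0.3], shape=(64, 64))
    a = expected_frame(spec, beams, channels3, t=0.0)
    b = expected_frame(spec, beams, channels3, t=2.0)
    np.testing.assert_array_equal(a, b)


def test_timeseries_length_and_times(beams, channels3):
    spec = static_cell_scene([1.0], shape=(32, 32))
    ts = render_timeseries(spec, beams, channels3, 3, 5.0, seed=0)
    assert ts.n_planes == 3
    np.testing.assert_allclose(ts.plane_positions, [0.0, 5.0, 10.0])
    with pytest.raises(ValueError):
        render_timeseries(spec, beams, channels3, 0, 5.0)


def test_saturation_schedule_drives_channel_ratio_down(beams, channels3):
    spec = static_cell_scene([1.0], shape=(48, 48))
    mask = ground_truth_masks(spec).rbc_masks[0]
    sched = lambda t: 1.0 if t < 1.0 else 0.2
    ratios = []
    for t, sats in ((0.0, [1.0]), (2.0, [0.2])):
        exp = expected_frame(spec, beams, channels3, t=t, saturations=sats)
        ratios.append(exp[channels3.labels.index("TSFG2")][mask].mean()
                      / exp[channels3.labels.index("THG2")][mask].mean())
    assert ratios[1] < ratios[0]


def test_fast_arterial_cells_appear_elongated(beams):
    """Row-sequential scanning shears fast cells along the scan direction:
    the rendered footprint's x extent exceeds the static one."""
    def spec_with_speed(v):
        s = SceneSpec(shape=(64, 128), species="zebrafish")
        s.cells = [Cell(center=(16.0, 32.0), velocity=(0.0, v))]
        return s

    static = ground_truth_masks(spec_with_speed(0.0)).rbc_masks[0]
    moving = ground_truth_masks(spec_with_speed(400.0)).rbc_masks[0]
    def width(mask):
        cols = np.where(mask.any(axis=0))[0]
        return cols.max() - cols.min()
    assert width(moving) > width(static)


def test_hypoxia_schedule_shape():
    sched = hypoxia_schedule(control_end_min=30, hypoxia_end_min=180)
    assert sched(10 * 60) == 1.0
    mid = [sched(t * 60) for t in (40, 90, 170)]
    assert all(np.diff(mid) < 0) and all(0.7 < v < 1.0 for v in mid)
    assert sched(200 * 60) == 1.0


# ---------------------------------------------------------------------------
# z-stacks
# ---------------------------------------------------------------------------


def test_zstack_depth_and_power_scaling(beams, channels3):
    """Expected signal scales as P^3 exp(-3z/EAL): at z = EAL with constant
    power the mean drops to e^-3; doubling power multiplies it by 8."""
    spec = static_cell_scene([1.0] * 4, shape=(64, 64))
    base = expected_frame(spec, beams, channels3)
    eal = 100.0
    z = np.array([0.0, eal])
    st = render_zstack(spec, beams, channels3, z, [30.0, 30.0], eal,
                       seed=0)
    k = channels3.labels.index("THG2")
    bright = base[k] > 1.0
    ratio = st.data[1, k][bright].sum() / st.data[0, k][bright].sum()
    assert ratio == pytest.approx(np.exp(-3.0), rel=0.1)

    st2 = render_zstack(spec, beams, channels3, np.array([0.0, 1e-9]),
                        [30.0, 60.0], np.inf, seed=0)
    ratio2 = st2.data[1, k][bright].sum() / st2.data[0, k][bright].sum()
    assert ratio2 == pytest.approx(8.0, rel=0.1)


def test_zstack_validation(beams, channels3):
    spec = static_cell_scene([1.0], shape=(32, 32))
    with pytest.raises(ValueError):
        render_zstack(spec, beams, channels3, [0.0, 0.0], [30, 30], 100.0)
    with pytest.raises(ValueError):
        render_zstack(spec, beams, channels3, [0.0, 4.0], [30, 30], -50.0)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def test_ground_truth_empty_scene():
    spec = SceneSpec(shape=(32, 32))
    truth = ground_truth_masks(spec)
    assert not truth.rbc_masks.any()
    assert not truth.vessel_mask.any()


def test_ground_truth_static_cell_footprint():
    spec = static_cell_scene([1.0], shape=(48, 48), species="zebrafish")
    truth = ground_truth_masks(spec)
    mask = truth.rbc_masks[0]
    # area close to the 11 x 7 um ellipse, centroid at the commanded center
    area_um2 = mask.sum() * spec.pixel_size_um ** 2
    assert area_um2 == pytest.approx(np.pi * 5.5 * 3.5, rel=0.1)
    cy, cx = np.argwhere(mask).mean(axis=0) * spec.pixel_size_um
    assert cy == pytest.approx(spec.cells[0].center[0], abs=0.5)
    assert cx == pytest.approx(spec.cells[0].center[1], abs=0.5)


def test_ground_truth_tracks_commanded_displacement():
    spec = SceneSpec(shape=(64, 128), species="human")
    spec.cells = [Cell(center=(16.0, 20.0), velocity=(0.0, 10.0))]
    spec.dwell_time_us = 1e-6  # negligible intra-frame shear
    truth = ground_truth_masks(spec, times=[0.0, 1.0])
    c0 = np.argwhere(truth.rbc_masks[0]).mean(axis=0)
    c1 = np.argwhere(truth.rbc_masks[1]).mean(axis=0)
    dx_um = (c1[1] - c0[1]) * spec.pixel_size_um
    assert dx_um == pytest.approx(10.0, abs=0.5)
    assert c1[0] == pytest.approx(c0[0], abs=1.0)


def test_embryo_scene_census(embryo_fixture):
    """The default embryo fixture keeps a roughly constant population of
    detectable cells in every frame."""
    truth = embryo_fixture["truth"]
    for f in range(truth.rbc_masks.shape[0]):
        n = len(np.unique(truth.labels[f])) - 1
        assert n >= 14


def test_vessel_and_cell_invariants():
    with pytest.raises(ValueError):
        Vessel((0, 0), (0, 10), radius=-1.0)
    with pytest.raises(ValueError):
        Cell(center=(0, 0), oxygen_saturation=1.5)
    with pytest.raises(ValueError):
        embryo_scene(species="frog")
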