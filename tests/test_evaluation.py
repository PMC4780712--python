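import numpy as np
import pytest

from cbctscatter import (CNRReport, ProjectionStack, ROISpec, build_phantom,
                         compute_cnr, compute_spr, cupping_index,
                         fit_diagnostics, line_profile, roi_stats)
from cbctscatter.phantoms import Insert, PhantomSpec
from cbctscatter.recon import ReconVolume


def test_constant_image_roi_stats():
    img = np.full((30, 30), 4.2)
    mean, sd, n = roi_stats(img, ROISpec(side_px=11))
    assert mean == pytest.approx(4.2)
    assert sd == pytest.approx(0.0, abs=1e-12)
    assert n == 121


def test_checkerboard_roi_stats_match_direct_formula():
    img = np.indices((31, 31)).sum(axis=0) % 2 * 2.0  # checkerboard {0, 2}
    mean, sd, n = roi_stats(img, ROISpec(side_px=11))
    # independent direct evaluation over the same 11x11 patch
    patch = img[10:21, 10:21].ravel()
    mu = patch.sum() / patch.size
    var = ((patch - mu) ** 2).sum() / (patch.size - 1)
    assert n == 121
    assert mean == pytest.approx(mu)
    assert sd == pytest.approx(np.sqrt(var))
    assert sd == pytest.approx(1.004, abs=1e-2)


def test_out_of_bounds_roi_raises():
    with pytest.raises(ValueError, match="outside"):
        roi_stats(np.ones((8, 8)), ROISpec(side_px=11))
    with pytest.raises(ValueError, match="outside"):
        roi_stats(np.ones((20, 20)),
                  ROISpec(domain="image", shape="circle", diameter_cm=0.9,
                          center=(2.0, 0.0)), pixel_size_cm=0.1)


def _spr_stack(primary, scatter):
    primary = np.asarray(primary, float)[None]
    scatter = np.asarray(scatter, float)[None]
    return ProjectionStack(channels={"total": primary + scatter,
                                     "primary": primary, "scatter": scatter},
                           angles=np.zeros(1))


def test_spr_closed_cases():
    ones = np.ones((15, 15))
    roi = ROISpec(side_px=11)
    assert compute_spr(_spr_stack(ones, 0 * ones), roi).spr == 0.0
    assert compute_spr(_spr_stack(ones, ones), roi).spr == 1.0
    with pytest.raises(ValueError, match="primary"):
        compute_spr(_spr_stack(0 * ones, ones), roi)


def test_fit_diagnostics_exact_and_degenerate():
    x = np.array([0.5, 1, 2, 5, 10, 20, 46.6])
    a, b, r2 = fit_diagnostics(x, 3.0 * np.log(x) + 7.0)
    assert (a, b, r2) == (pytest.approx(3.0), pytest.approx(7.0),
                          pytest.approx(1.0))
    a, b, r2 = fit_diagnostics(x, np.full(x.size, 5.0))
    assert a == pytest.approx(0.0, abs=1e-12)
    assert r2 == 0.0
    with pytest.raises(ValueError):
        fit_diagnostics([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        fit_diagnostics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_fit_diagnostics_matches_grid_search_on_noisy_data():
    rng = np.random.default_rng(7)
    x = np.array([0.5, 1, 2, 5, 10, 20])
    y = 2.0 * np.log(x) + 10.0 + rng.normal(0, 0.5, x.size)
    a, b, r2 = fit_diagnostics(x, y)
    best = (None, None, np.inf)
    for aa in np.linspace(1, 3, 301):
        for bb in np.linspace(9, 11, 301):
            ss = np.sum((y - aa * np.log(x) - bb) ** 2)
            if ss < best[2]:
                best = (aa, bb, ss)
    assert a == pytest.approx(best[0], abs=0.01)
    assert b == pytest.approx(best[1], abs=0.01)
    lx = np.log(x)
    ss_res = np.sum((y - a * lx - b) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    assert r2 == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)


def _cnr_volume(phantom, insert_values, water_value=0.0, noise_sd=20.0,
                n=160, vox_mm=1.0, seed=0):
    rng = np.random.default_rng(seed)
    img = rng.normal(water_value, noise_sd, (1, n, n))
    pix = vox_mm / 10.0
    x = (np.arange(n) - (n - 1) / 2.0) * pix
    xx, yy = np.meshgrid(x, x)
    for ins, val in zip(phantom.inserts, insert_values):
        mask = np.hypot(xx - ins.center_xy[0], yy - ins.center_xy[1]) <= 0.45
        img[0, mask] = val
    return ReconVolume(voxels=img, voxel_size_mm=vox_mm)


def test_cnr_closed_cases():
    ph = PhantomSpec(body_diameter=10.0, inserts=[
        Insert(center_xy=(2.5, 0.0), diameter=3.0, height=10.0,
               material="muscle")])
    vol = _cnr_volume(ph, [10.0], water_value=10.0, noise_sd=20.0)
    rep = compute_cnr(vol, ph)
    # insert mean = measured water mean gives CNR ~ 0 up to sampling noise
    assert rep.per_insert["cnr"][0] == pytest.approx(
        abs(10.0 - rep.ct_water_mean) / rep.ct_water_sd)
    vol = _cnr_volume(ph, [150.0], water_value=10.0, noise_sd=20.0)
    rep = compute_cnr(vol, ph)
    expected = abs(150.0 - rep.ct_water_mean) / rep.ct_water_sd
    assert rep.per_insert["cnr"][0] == pytest.approx(expected)
    assert rep.per_insert["cnr"][0] == pytest.approx(7.0, rel=0.25)


def test_cnr_equals_one_when_contrast_equals_background_noise():
    ph = PhantomSpec(body_diameter=10.0, inserts=[
        Insert(center_xy=(2.5, 0.0), diameter=3.0, height=10.0,
               material="muscle")])
    vol = _cnr_volume(ph, [0.0])
    bg = (-2.5, 0.0)
    from cbctscatter.evaluation import _roi_mask

    rep0 = compute_cnr(vol, ph, background_center=bg)
    vol.voxels[0][_roi_mask(vol.voxels[0],
                            ROISpec(domain="image", shape="circle",
                                    diameter_cm=0.9, center=(2.5, 0.0)),
                            0.1)] = rep0.ct_water_mean + rep0.ct_water_sd
    rep = compute_cnr(vol, ph, background_center=bg)
    assert rep.per_insert["cnr"][0] == pytest.approx(1.0, abs=1e-12)


def test_cnr_report_is_internally_consistent():
    ph = build_phantom("mc_10cm_five_tissue")
    vol = _cnr_volume(ph, [40.0, 800.0, -80.0, 200.0, -700.0])
    rep = compute_cnr(vol, ph)
    recomputed = (rep.per_insert["ct_mean"] - rep.ct_water_mean).abs() \
        / rep.ct_water_sd
    assert np.array_equal(rep.per_insert["cnr"].values, recomputed.values)
    assert rep.mean_cnr == pytest.approx(rep.per_insert["cnr"].mean())
    with pytest.raises(ValueError, match="SD"):
        flat = ReconVolume(voxels=np.zeros((1, 160, 160)), voxel_size_mm=1.0)
        compute_cnr(flat, ph)


def test_cupping_index_zero_for_uniform_and_positive_for_dip(water10):
    uniform = ReconVolume(voxels=np.zeros((1, 128, 128)), voxel_size_mm=1.0)
    assert cupping_index(uniform, water10) == 0.0

    # synthetic parabolic dip of depth d at the center of the body
    n, vox = 128, 1.0
    x = (np.arange(n) - (n - 1) / 2.0) * vox / 10.0
    xx, yy = np.meshgrid(x, x)
    r2 = xx**2 + yy**2
    d = 50.0
    img = (d * r2 / water10.body_radius**2)[None]
    vol = ReconVolume(voxels=img, voxel_size_mm=vox)
    got = cupping_index(vol, water10)
    # direct evaluation of the band means on the same parabola
    rb = water10.body_radius
    r = np.sqrt(r2)
    center = r <= 0.15 * rb
    edge = (r >= 0.65 * rb) & (r <= 0.80 * rb)
    expected = img[0][edge].mean() - img[0][center].mean()
    assert got == pytest.approx(expected, rel=1e-12)
    assert got > 0.4 * d


def test_line_profile_basics():
    img = np.full((20, 20), 3.0)
    prof = line_profile(img, (2, 2), (17, 17), n_samples=50)
    assert np.allclose(prof, 3.0)
    ramp = np.tile(np.arange(20.0), (20, 1))
    fwd = line_profile(ramp, (10, 2), (10, 17), n_samples=31)
    rev = line_profile(ramp, (10, 17), (10, 2), n_samples=31)
    assert np.allclose(fwd, rev[::-1])
    with pytest.raises(ValueError, match="outside"):
        line_profile(img, (0, 0), (25, 25))


def test_profile_crosses_insert_plateau():
    ph = PhantomSpec(body_diameter=10.0, inserts=[
        Insert(center_xy=(0.0, 0.0), diameter=3.0, height=10.0,
               material="dense_bone_800")])
    vol = _cnr_volume(ph, [500.0], noise_sd=1.0)
    prof = line_profile(vol.voxels[0], (80, 20), (80, 140), n_samples=121)
    assert prof.max() == pytest.approx(500.0, abs=5.0)
    assert (prof > 450).sum() >= 5  # a plateau, not a spike
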