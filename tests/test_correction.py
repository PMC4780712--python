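import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbctscatter import (CollimatorSetting, ProjectionStack, SmoothingConfig,
                         correct_projection, correct_two_fov,
                         estimate_scatter, extrapolate_projection,
                         fit_log_model, fit_log_model_sweep, project_primary)
from cbctscatter.correction import ScatterEstimate

from conftest import make_two_fov_fixtures


def _stack(values, rows=(0, None)):
    arr = np.asarray(values, float)
    if arr.ndim == 2:
        arr = arr[None]
    meta = {"illuminated_rows": [rows[0], rows[1] if rows[1] is not None
                                 else arr.shape[1]]}
    return ProjectionStack(channels={"total": arr},
                           angles=np.zeros(arr.shape[0]), meta=meta)


def test_equal_observations_give_a_flat_model():
    c = 7.5
    s = _stack(np.full((4, 6), c))
    model = fit_log_model(14.0, s, 42.0, _stack(np.full((4, 6), c)))
    assert np.allclose(model.a, 0.0)
    assert np.allclose(model.b[model.valid_mask], c)


def test_two_point_fit_reproduces_published_roi_means():
    """Closed-form two-point solution for ROI means 7095 @14mm, 8167 @42mm."""
    s14 = _stack(np.full((2, 2), 7095.0))
    s42 = _stack(np.full((2, 2), 8167.0))
    model = fit_log_model(14.0, s14, 42.0, s42)
    a = 1072.0 / np.log(3.0)
    assert np.allclose(model.a[model.valid_mask], a)
    assert np.allclose(model.b[model.valid_mask],
                       7095.0 - a * np.log(14.0))
    assert model.b[0, 0, 0] == pytest.approx(4519.6, abs=0.5)
    est = extrapolate_projection(model, 0.5)
    assert est[0, 0, 0] == pytest.approx(3843.0, abs=1.0)
    # the model interpolates both knots exactly
    assert np.allclose(extrapolate_projection(model, 14.0), 7095.0)
    assert np.allclose(extrapolate_projection(model, 42.0), 8167.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(y1=st.floats(1.0, 1e5), ratio=st.floats(1.001, 10.0),
       x1=st.floats(0.5, 20.0), xr=st.floats(1.1, 10.0))
def test_two_point_exactness_property(y1, ratio, x1, xr):
    x2 = x1 * xr
    y2 = y1 * ratio
    model = fit_log_model(x1, _stack([[y1]]), x2, _stack([[y2]]))
    assert extrapolate_projection(model, x1)[0, 0, 0] == pytest.approx(y1, rel=1e-9)
    assert extrapolate_projection(model, x2)[0, 0, 0] == pytest.approx(y2, rel=1e-9)


def test_non_positive_slope_pixels_fall_back_to_flat():
    s14 = _stack([[100.0, 100.0]])
    s42 = _stack([[90.0, 120.0]])
    model = fit_log_model(14.0, s14, 42.0, s42)
    assert model.a[0, 0, 0] == 0.0
    assert model.a[0, 0, 1] > 0.0
    assert extrapolate_projection(model, 0.5)[0, 0, 0] == pytest.approx(100.0)


def test_sweep_fit_matches_grid_search_oracle():
    rng = np.random.default_rng(3)
    slits = np.array([0.5, 1.0, 2.0, 5.0, 10.0, 20.0])
    y = 40.0 * np.log(slits) + 300.0 + rng.normal(0, 5.0, slits.size)
    stacks = [_stack([[v]]) for v in y]
    model = fit_log_model_sweep(slits, stacks)
    # brute-force grid search over (a, b)
    best = (None, None, np.inf)
    for a in np.linspace(20, 60, 401):
        for b in np.linspace(250, 350, 401):
            ss = np.sum((y - a * np.log(slits) - b) ** 2)
            if ss < best[2]:
                best = (a, b, ss)
    assert model.a[0, 0, 0] == pytest.approx(best[0], abs=0.2)
    assert model.b[0, 0, 0] == pytest.approx(best[1], abs=0.5)
    assert model.r2 is not None and 0 < model.r2[0, 0, 0] <= 1


def test_extrapolation_rejects_non_positive_target():
    model = fit_log_model(14.0, _stack([[10.0]]), 42.0, _stack([[20.0]]))
    with pytest.raises(ValueError, match="target slit must be > 0"):
        extrapolate_projection(model, 0.0)
    with pytest.raises(ValueError, match="target slit must be > 0"):
        extrapolate_projection(model, -1.0)


def test_extrapolation_monotone_in_target_where_slope_positive():
    model = fit_log_model(14.0, _stack([[10.0]]), 42.0, _stack([[20.0]]))
    vals = [extrapolate_projection(model, t)[0, 0, 0]
            for t in (1.0, 5.0, 14.0, 42.0, 60.0)]
    assert np.all(np.diff(vals) > 0)


def test_mismatched_stacks_raise():
    with pytest.raises(ValueError, match="slit sizes"):
        fit_log_model(14.0, _stack([[1.0]]), 14.0, _stack([[2.0]]))
    a = _stack(np.ones((3, 4)))
    b = ProjectionStack(channels={"total": np.ones((1, 3, 4))},
                        angles=np.array([90.0]))
    with pytest.raises(ValueError, match="angles"):
        fit_log_model(14.0, a, 42.0, b)
    with pytest.raises(ValueError, match="shapes"):
        fit_log_model(14.0, a, 42.0, _stack(np.ones((5, 4))))


# ---------------------------------------------------------- smoothing kernel

def test_kernel_is_normalized_and_matches_explicit_gaussian():
    cfg = SmoothingConfig(window=11, sigma=5.0)
    k = cfg.kernel()
    assert k.shape == (11, 11)
    assert k.sum() == pytest.approx(1.0, abs=1e-12)
    # independent evaluation of the truncated normalized Gaussian
    ref = np.empty((11, 11))
    for i in range(11):
        for j in range(11):
            ref[i, j] = np.exp(-((i - 5) ** 2 + (j - 5) ** 2) / (2 * 25.0))
    ref /= ref.sum()
    assert np.allclose(k, ref, atol=1e-15)


def test_smoothing_preserves_dc_and_reproduces_kernel_on_impulse():
    raw = _stack(np.full((30, 40), 12.0))
    est = estimate_scatter(raw, np.full((1, 30, 40), 4.0))
    assert np.allclose(est.scatter, 8.0, atol=1e-12)  # constant residual

    impulse = np.zeros((1, 30, 40))
    impulse[0, 15, 20] = 1.0
    zero = _stack(np.zeros((30, 40)))
    est = estimate_scatter(zero, -impulse)  # residual = impulse
    k = SmoothingConfig().kernel()
    assert np.allclose(est.scatter[0, 10:21, 15:26], k, atol=1e-15)


def test_zero_residual_gives_zero_scatter():
    raw = _stack(np.random.default_rng(0).uniform(1, 10, (2, 20, 20)))
    est = estimate_scatter(raw, raw["total"].copy())
    assert np.all(est.scatter == 0)


def test_correct_projection_identity_and_floor():
    raw = _stack(np.full((10, 10), 50.0))
    zero_est = ScatterEstimate(scatter=np.zeros((1, 10, 10)), raw_source="x",
                               extrapolation_slit=2.7,
                               smoothing=SmoothingConfig())
    assert np.array_equal(correct_projection(raw, zero_est)["total"],
                          raw["total"])
    big = ScatterEstimate(scatter=np.full((1, 10, 10), 100.0), raw_source="x",
                          extrapolation_slit=2.7, smoothing=SmoothingConfig())
    corrected = correct_projection(raw, big, floor=1.0)
    assert np.all(corrected["total"] == 1.0)


# ------------------------------------------------------- end-to-end analytic

def test_correction_reduces_rmse_to_true_primary(geom_small, mono60, water10):
    """On Poisson fixtures with known scatter, correction beats the raw data."""
    s14, s42, _ = make_two_fov_fixtures(geom_small, mono60, water10,
                                        amplitude=0.4, s0=0.5, poisson=True,
                                        seed=1, i0=2e4, n_views=4)
    corrected, model, est = correct_two_fov(s14, 14.0, s42, 42.0,
                                            target_slit_mm=2.7, floor=1.0)
    mask = model.valid_mask
    true_primary = s14["primary"]
    for v in range(s14.n_views):
        m = mask[v]
        rmse_raw = np.sqrt(np.mean((s14["total"][v][m] - true_primary[v][m]) ** 2))
        rmse_cor = np.sqrt(np.mean((corrected["total"][v][m] - true_primary[v][m]) ** 2))
        assert rmse_cor < rmse_raw


def test_extrapolation_recovers_primary_in_log_regime(geom_small, mono60, water10):
    """Weak, strongly saturating scatter: the log model extrapolates to the
    primary within 2% per pixel in the overlap band."""
    s14, s42, field = make_two_fov_fixtures(geom_small, mono60, water10,
                                            amplitude=5e-4, s0=0.05,
                                            i0=1e4, n_views=2)
    model = fit_log_model(14.0, s14, 42.0, s42)
    est = extrapolate_projection(model, 0.5)
    mask = model.valid_mask & (s14["primary"] > 1e3)
    # at the 0.5 mm target the synthetic scatter is <= 1% of the primary
    scatter_at_target = s14["scatter"] * (field.slit_response(0.5)
                                          / field.slit_response(14.0))
    assert np.all(scatter_at_target[mask] <= 0.011 * s14["primary"][mask])
    rel = np.abs(est[mask] - s14["primary"][mask]) / s14["primary"][mask]
    assert rel.max() < 0.02


def test_noise_ordering_estimated_corrected_raw(geom_small, mono60, water10):
    """Extrapolated projections are noisiest; corrected slightly noisier than
    raw -- the projection-domain SD pattern of the two-FOV workflow."""
    s14, s42, _ = make_two_fov_fixtures(geom_small, mono60, water10,
                                        amplitude=0.3, s0=5.0, poisson=True,
                                        seed=2, i0=7000.0, n_views=2)
    corrected, model, est = correct_two_fov(s14, 14.0, s42, 42.0,
                                            target_slit_mm=2.7, floor=1.0)
    extrapolated = extrapolate_projection(model, 2.7)
    # noise SD measured against the noiseless expectation, inside the band
    s14_clean, s42_clean, _ = make_two_fov_fixtures(
        geom_small, mono60, water10, amplitude=0.3, s0=5.0, i0=7000.0,
        n_views=2)
    mask = model.valid_mask & (s14_clean["primary"] > 100.0)
    clean_model = fit_log_model(14.0, s14_clean, 42.0, s42_clean)

    def noise_sd(img, ref):
        return np.std(img[mask] - ref[mask])

    sd_raw = noise_sd(s14["total"], s14_clean["total"])
    sd_est = noise_sd(extrapolated, extrapolate_projection(clean_model, 2.7))
    corrected_clean, *_ = correct_two_fov(s14_clean, 14.0, s42_clean, 42.0,
                                          target_slit_mm=2.7, floor=1.0)
    sd_cor = noise_sd(corrected["total"], corrected_clean["total"])
    assert sd_est > sd_cor > sd_raw


def test_correcting_the_large_fov_flags_rows_outside_overlap(
        geom_small, mono60, water10):
    s14, s42, _ = make_two_fov_fixtures(geom_small, mono60, water10,
                                        n_views=2)
    corrected, model, _ = correct_two_fov(s14, 14.0, s42, 42.0,
                                          correct="large", floor=1e-6)
    assert corrected.meta["uncorrected_rows_flagged"]
    outside = ~model.valid_mask
    assert np.array_equal(corrected["total"][outside], s42["total"][outside])
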