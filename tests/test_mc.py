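import numpy as np
import pytest
from scipy.integrate import quad

from cbctscatter import (CollimatorSetting, build_phantom, build_spectrum,
                         simulate_scan, simulate_view, view_seed)
from cbctscatter.materials import ELECTRON_REST_KEV, material_mu
from cbctscatter.mc.engine import run_slit_sweep
from cbctscatter.mc.kernels import sample_compton_batch


@pytest.fixture(scope="module")
def geom(geom_small):
    return geom_small


@pytest.fixture(scope="module")
def coll14(geom):
    return CollimatorSetting(slit_mm=14.0, geometry=geom)


def test_air_phantom_has_almost_no_scatter(geom, coll14, mono60):
    ph = build_phantom("air_10cm")
    stack, _ = simulate_view(ph, geom, coll14, mono60, 100_000, seed=4,
                             detector_model="ideal")
    assert stack["scatter"].sum() < 0.005 * stack["total"].sum()


def test_beer_lambert_primary_transmission(geom, mono60, water10):
    """Pencil beam through 10 cm of water: closed-form transmission oracle."""
    n = 300_000
    coll = CollimatorSetting(slit_mm=1.0, geometry=geom)
    stack, _ = simulate_view(water10, geom, coll, mono60, n, seed=11,
                             detector_model="ideal", emit_y_half_cm=0.02)
    p_hat = stack["primary"].sum() / n
    mu = material_mu("water", 60.0)[3]
    p = np.exp(-mu * 10.0)
    assert abs(p_hat - p) < 3.0 * np.sqrt(p * (1 - p) / n) + 2e-4


def test_klein_nishina_mean_scattered_energy():
    """Sampled mean energy after one Compton event vs numerical KN integral."""
    e0 = 60.0
    k = e0 / ELECTRON_REST_KEV

    def dsigma(cos_t):  # Klein-Nishina differential cross-section (unnormalized)
        r = 1.0 / (1.0 + k * (1.0 - cos_t))  # E'/E
        return r**2 * (r + 1.0 / r - (1.0 - cos_t**2))

    norm = quad(dsigma, -1, 1)[0]
    mean_expected = e0 * quad(lambda c: dsigma(c) / (1 + k * (1 - c)), -1, 1)[0] / norm
    n = 200_000
    energies, cosines = sample_compton_batch(123, e0, n)
    se = energies.std() / np.sqrt(n)
    assert abs(energies.mean() - mean_expected) < 3 * se
    assert np.all(energies <= e0 + 1e-12)
    assert np.all(energies >= e0 / (1 + 2 * k) - 1e-12)
    assert np.all(np.abs(cosines) <= 1.0)


def test_channel_conservation_is_exact(geom, coll14, poly120):
    ph = build_phantom("mc_10cm_five_tissue")
    stack, _ = simulate_view(ph, geom, coll14, poly120, 100_000, seed=2)
    assert np.array_equal(stack["total"],
                          stack["primary"] + stack["scatter"])


def test_unweighted_total_counts_detected_photons(geom, coll14, mono60, water10):
    stack, records = simulate_view(water10, geom, coll14, mono60, 50_000,
                                   seed=9, return_photons=True)
    assert stack["total"].sum() == pytest.approx(stack.meta["n_detected"])
    assert len(records) == stack.meta["n_detected"]


def test_photon_records_define_the_channels(geom, coll14, poly120):
    ph = build_phantom("mc_10cm_five_tissue")
    stack, rec = simulate_view(ph, geom, coll14, poly120, 50_000, seed=3,
                               return_photons=True)
    scattered = (rec["n_compton_phantom"] + rec["n_rayleigh_phantom"]) > 0
    assert scattered.sum() == pytest.approx(stack["scatter"].sum())
    assert (~scattered).sum() == pytest.approx(stack["primary"].sum())
    assert np.all(rec["energy"] <= poly120.energies.max() + 1e-6)


def test_identical_seed_gives_bit_identical_stacks(geom, coll14, poly120, water10):
    a, _ = simulate_view(water10, geom, coll14, poly120, 30_000, seed=7)
    b, _ = simulate_view(water10, geom, coll14, poly120, 30_000, seed=7)
    assert np.array_equal(a["total"], b["total"])
    assert np.array_equal(a["scatter"], b["scatter"])
    c, _ = simulate_view(water10, geom, coll14, poly120, 30_000, seed=8)
    assert not np.array_equal(a["total"], c["total"])


def test_doubling_photons_doubles_counts_within_poisson(geom, coll14, mono60, water10):
    n = 80_000
    a, _ = simulate_view(water10, geom, coll14, mono60, n, seed=21)
    b, _ = simulate_view(water10, geom, coll14, mono60, 2 * n, seed=22)
    ca, cb = a["total"].sum(), b["total"].sum()
    sigma = np.sqrt(ca + cb / 4)
    assert abs(cb / 2 - ca) < 3 * sigma


def test_single_view_scan_equals_simulate_view(mono60, water10):
    from cbctscatter.geometry import ScannerGeometry

    geom1 = ScannerGeometry(det_rows=96, det_cols=120, det_pitch_mm=2.0,
                            n_views=1)
    coll = CollimatorSetting(slit_mm=14.0, geometry=geom1)
    scan = simulate_scan(water10, geom1, coll, mono60, 40_000, master_seed=5)
    view, _ = simulate_view(water10, geom1, coll, mono60, 40_000,
                            seed=view_seed(5, 0))
    assert np.array_equal(scan["total"], view["total"])


def test_rotational_symmetry_of_a_plain_cylinder(mono60, water10):
    """View-to-view total intensity varies only at the Poisson level."""
    from cbctscatter.geometry import ScannerGeometry

    geom = ScannerGeometry(det_rows=96, det_cols=120, det_pitch_mm=2.0,
                           n_views=6)
    coll = CollimatorSetting(slit_mm=14.0, geometry=geom)
    scan = simulate_scan(water10, geom, coll, mono60, 150_000, master_seed=6)
    counts = scan["total"].sum(axis=(1, 2))
    expected = counts.mean()
    assert np.all(np.abs(counts - expected) < 4 * np.sqrt(expected))


def test_sweep_enumerates_the_full_factorial():
    df = run_slit_sweep(enumerate_only=True)
    assert len(df) == 84
    assert df.groupby(["diameter_cm", "layout"]).size().eq(7).all()


def test_sweep_degenerate_single_factor():
    df = run_slit_sweep(diameters=[10.0], layouts=["muscle"], slits_mm=[5.0],
                        enumerate_only=True)
    assert len(df) == 1


def test_sweep_record_count_is_product_of_factors():
    df = run_slit_sweep(diameters=[10.0, 20.0], layouts=["muscle", "adipose"],
                        slits_mm=[1.0, 5.0, None], enumerate_only=True)
    assert len(df) == 2 * 2 * 3


def test_sweep_rejects_empty_factors():
    with pytest.raises(ValueError, match="non-empty"):
        run_slit_sweep(diameters=[], enumerate_only=True)


def test_primary_is_invariant_to_collimation_in_the_band(geom, mono60, water10):
    """Only scatter changes with the slit; primary fluence does not."""
    roi = (slice(46, 50), slice(56, 64))
    means = {}
    for slit, n in ((5.0, 400_000), (42.0, 400_000)):
        coll = CollimatorSetting(slit_mm=slit, geometry=geom)
        st, _ = simulate_view(water10, geom, coll, mono60, n, seed=31,
                              fluence_normalized=True, detector_model="ideal")
        w = st.meta["weight"]
        counts = st["primary"][0][roi].sum() / w
        means[slit] = (st["primary"][0][roi].sum(), counts)
    a, ca = means[5.0]
    b, cb = means[42.0]
    sigma = np.sqrt(a**2 / ca + b**2 / cb)  # weighted-count Poisson error
    assert abs(a - b) < 3.5 * sigma


def test_spr_monotone_nonincreasing_as_slit_shrinks(geom, poly120):
    """Central SPR decreases when the collimator closes (within 2x MC error)."""
    ph = build_phantom("mc_10cm_five_tissue")
    sprs, errs = [], []
    for slit in (2.0, 10.0, None):
        coll = (CollimatorSetting(slit_mm=slit, geometry=geom) if slit
                else CollimatorSetting(slit_mm=None, geometry=geom))
        st, _ = simulate_view(ph, geom, coll, poly120, 600_000, seed=41,
                              fluence_normalized=True)
        w = st.meta["weight"]
        roi = (slice(44, 52), slice(52, 68))
        s = st["scatter"][0][roi].sum()
        p = st["primary"][0][roi].sum()
        spr = s / p
        # relative MC error from unweighted counts
        rel = np.sqrt(w / s + w / p)
        sprs.append(spr)
        errs.append(spr * rel)
    for i in range(len(sprs) - 1):
        assert sprs[i] <= sprs[i + 1] + 2 * (errs[i] + errs[i + 1])


def test_uncollimated_20cm_spr_in_literature_band(geom, poly120):
    """Head-size water cylinder, open beam: SPR within the CBCT range."""
    ph = build_phantom("water_20cm")
    coll = CollimatorSetting(slit_mm=None, geometry=geom)
    st, _ = simulate_view(ph, geom, coll, poly120, 3_000_000, seed=51,
                          fluence_normalized=True)
    roi = (slice(44, 52), slice(52, 68))
    spr = st["scatter"][0][roi].sum() / st["primary"][0][roi].sum()
    assert 0.4 <= spr <= 2.0
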