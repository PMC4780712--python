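"""Monte Carlo simulation of CBCT acquisitions.

Each detected photon carries the per-history interaction labels (number of
Compton/Rayleigh events in phantom and detector), so projections separate
exactly into primary and scatter channels: ``total = primary + scatter``
per pixel by construction.

Exposure convention: histories are always emitted into the collimated beam
(no photon is wasted outside the slit).  With ``fluence_normalized=True``
each history carries the statistical weight ``band_area / open_area`` so
that intensities are directly comparable across collimator settings at a
fixed tube output -- the convention used for slit sweeps and for two-FOV
acquisitions.  With ``fluence_normalized=False`` (the default) weights are
1 and pixel values are raw detected photon counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..geometry import CollimatorSetting, ScannerGeometry, open_collimation
from ..materials import mu_table_fine
from ..phantoms import MC_DIAMETERS, MC_LAYOUTS, PhantomSpec, build_phantom
from ..projections import ProjectionStack
from ..spectrum import EnergySpectrum
from .kernels import transport_view as _transport_view

# fine energy grid used by the transport kernel [keV]
_E_MIN, _E_MAX, _E_STEP = 10.0, 150.0, 0.5
_E_GRID = np.arange(_E_MIN, _E_MAX + _E_STEP / 2, _E_STEP)

DEFAULT_SCINTILLATOR_THICKNESS_CM = 0.06  # 0.6 mm CsI

PHOTON_RECORD_DTYPE = np.dtype([
    ("row", np.int32), ("col", np.int32), ("energy", np.float32),
    ("n_compton_phantom", np.int16), ("n_rayleigh_phantom", np.int16),
    ("n_compton_detector", np.int16), ("n_rayleigh_detector", np.int16),
    ("view_index", np.int32),
])


def view_seed(master_seed: int, view_index: int) -> int:
    """Deterministic per-view stream seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(view_index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _kernel_inputs(phantom: PhantomSpec, angle_deg: float):
    """Flatten the phantom into priority-ordered region arrays (cores first),
    with insert centers rotated opposite to the gantry angle."""
    mats = phantom.material_names()
    mat_index = {m: i for i, m in enumerate(mats)}
    cx, cy, r2, hz, mid = [], [], [], [], []
    c = np.cos(np.deg2rad(-angle_deg))
    s = np.sin(np.deg2rad(-angle_deg))

    def rotated(x, y):
        return c * x - s * y, s * x + c * y

    for ins in phantom.inserts:  # cores first: innermost wins
        if ins.core_diameter is not None:
            x, y = rotated(*ins.center_xy)
            cx.append(x); cy.append(y)
            r2.append((ins.core_diameter / 2.0) ** 2)
            hz.append(ins.height / 2.0)
            mid.append(mat_index[ins.core_material])
    for ins in phantom.inserts:
        x, y = rotated(*ins.center_xy)
        cx.append(x); cy.append(y)
        r2.append(ins.radius**2)
        hz.append(ins.height / 2.0)
        mid.append(mat_index[ins.material])
    return (mats, mat_index,
            np.asarray(cx, float), np.asarray(cy, float),
            np.asarray(r2, float), np.asarray(hz, float),
            np.asarray(mid, np.int64))


def simulate_view(phantom: PhantomSpec, geometry: ScannerGeometry,
                  collimation: CollimatorSetting, spectrum: EnergySpectrum,
                  n_photons: int, seed: int, *,
                  view_index: int = 0,
                  fluence_normalized: bool = False,
                  detector_model: str = "scintillator",
                  scintillator_thickness_cm: float = DEFAULT_SCINTILLATOR_THICKNESS_CM,
                  classify_with_detector: bool = False,
                  emit_y_half_cm: float | None = None,
                  return_photons: bool = False):
    """Transport ``n_photons`` histories through one view.

    Returns ``(ProjectionStack with one view, photon records or None)``.
    ``emit_y_half_cm`` optionally narrows the transverse emission aperture
    (e.g. for pencil-beam validation).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    angle = float(geometry.angles[view_index])
    mats, _, reg_cx, reg_cy, reg_r2, reg_hz, reg_mat = _kernel_inputs(phantom, angle)
    all_mats = mats + ["detector_scintillator"]
    table = mu_table_fine(all_mats, _E_GRID)  # (n_mat, n_e, 3)
    mu_pe = np.ascontiguousarray(table[:, :, 0])
    mu_co = np.ascontiguousarray(table[:, :, 1])
    mu_ra = np.ascontiguousarray(table[:, :, 2])
    mu_tot = np.ascontiguousarray(table.sum(axis=2))
    mu_maj = np.ascontiguousarray(mu_tot[:-1].max(axis=0))  # phantom materials only
    det_mat = len(all_mats) - 1

    w = np.cumsum(spectrum.weights)
    spec_cdf = w / w[-1]
    spec_energies = np.asarray(spectrum.energies, float)

    pitch_cm = geometry.det_pitch_mm / 10.0
    det_x = geometry.sdd - geometry.sad
    band = collimation.beam_height_at_detector / 2.0
    z_half = min(band, geometry.det_height_cm / 2.0)
    emit_y = geometry.det_width_cm / 2.0 if emit_y_half_cm is None else emit_y_half_cm
    weight = 1.0
    if fluence_normalized:
        weight = (2.0 * z_half * 2.0 * emit_y) / (geometry.det_height_cm
                                                  * geometry.det_width_cm)

    total = np.zeros((geometry.det_rows, geometry.det_cols))
    primary = np.zeros_like(total)
    scatter = np.zeros_like(total)
    rec_n = n_photons if return_photons else 1
    rec_row = np.empty(rec_n, np.int32)
    rec_col = np.empty(rec_n, np.int32)
    rec_energy = np.empty(rec_n, np.float32)
    rec_co_ph = np.empty(rec_n, np.int16)
    rec_ra_ph = np.empty(rec_n, np.int16)
    rec_co_det = np.empty(rec_n, np.int16)
    rec_ra_det = np.empty(rec_n, np.int16)

    n_detected, n_runaway = _transport_view(
        int(seed) & 0xFFFFFFFF, int(n_photons), float(weight),
        geometry.sad, det_x, pitch_cm, geometry.det_rows, geometry.det_cols,
        float(emit_y), -z_half, z_half,
        phantom.body_radius**2, phantom.body_height / 2.0, 0,
        reg_cx, reg_cy, reg_r2, reg_hz, reg_mat,
        _E_MIN, _E_STEP, mu_pe, mu_co, mu_ra, mu_tot, mu_maj,
        spec_cdf, spec_energies,
        det_mat, float(scintillator_thickness_cm),
        detector_model == "ideal", bool(classify_with_detector),
        total, primary, scatter,
        bool(return_photons), rec_row, rec_col, rec_energy,
        rec_co_ph, rec_ra_ph, rec_co_det, rec_ra_det)
    if n_runaway:
        import warnings

        warnings.warn(f"{n_runaway} histories exceeded the interaction cap")

    meta = {"phantom": phantom.name, "n_photons": int(n_photons),
            "seed": int(seed), "weight": weight,
            "slit_mm": collimation.slit_mm,
            "effective_slit_mm": collimation.effective_slit_mm,
            "det_pitch_mm": geometry.det_pitch_mm,
            "sad": geometry.sad, "sdd": geometry.sdd,
            "detector_model": detector_model,
            "fluence_normalized": fluence_normalized,
            "n_detected": int(n_detected), "n_runaway": int(n_runaway),
            "illuminated_rows": list(collimation.illuminated_rows)}
    stack = ProjectionStack(
        channels={"total": total[None], "primary": primary[None],
                  "scatter": scatter[None]},
        angles=np.array([angle]), meta=meta)
    records = None
    if return_photons:
        records = np.empty(n_detected, PHOTON_RECORD_DTYPE)
        records["row"] = rec_row[:n_detected]
        records["col"] = rec_col[:n_detected]
        records["energy"] = rec_energy[:n_detected]
        records["n_compton_phantom"] = rec_co_ph[:n_detected]
        records["n_rayleigh_phantom"] = rec_ra_ph[:n_detected]
        records["n_compton_detector"] = rec_co_det[:n_detected]
        records["n_rayleigh_detector"] = rec_ra_det[:n_detected]
        records["view_index"] = view_index
    return stack, records


def simulate_scan(phantom: PhantomSpec, geometry: ScannerGeometry,
                  collimation: CollimatorSetting, spectrum: EnergySpectrum,
                  n_photons_per_view: int, master_seed: int,
                  **view_kwargs) -> ProjectionStack:
    """Simulate every view of a scan; per-view seeds derive from the master."""
    views = {c: [] for c in ("total", "primary", "scatter")}
    meta = None
    for v in range(geometry.n_views):
        stack, _ = simulate_view(phantom, geometry, collimation, spectrum,
                                 n_photons_per_view, view_seed(master_seed, v),
                                 view_index=v, **view_kwargs)
        for c in views:
            views[c].append(stack[c][0])
        if meta is None:
            meta = dict(stack.meta)
    meta["seed"] = int(master_seed)
    meta["n_photons_per_view"] = int(n_photons_per_view)
    return ProjectionStack(
        channels={c: np.stack(a) for c, a in views.items()},
        angles=geometry.angles.copy(), meta=meta)


def air_flat_field(geometry: ScannerGeometry, collimation: CollimatorSetting,
                   spectrum: EnergySpectrum, n_photons: int, seed: int, *,
                   smooth_sigma_px: float = 3.0, **view_kwargs) -> np.ndarray:
    """Open-field (no phantom) detector image for flat-field normalization.

    The air image is smooth by construction, so mild Gaussian smoothing
    suppresses Monte Carlo noise without biasing the flat field.
    """
    from scipy.ndimage import gaussian_filter

    vacuum = PhantomSpec(body_diameter=1e-3, body_height=1e-3,
                         body_material="air", name="air_flat")
    stack, _ = simulate_view(vacuum, geometry, collimation, spectrum,
                             n_photons, seed, **view_kwargs)
    flat = stack["total"][0]
    if smooth_sigma_px > 0:
        r0, r1 = collimation.illuminated_rows
        band = flat[r0:r1]
        if band.size:
            flat[r0:r1] = gaussian_filter(band, smooth_sigma_px, mode="nearest")
    return flat


DEFAULT_SLITS_MM: tuple[float | None, ...] = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, None)


def run_slit_sweep(diameters=MC_DIAMETERS, layouts=MC_LAYOUTS,
                   slits_mm=DEFAULT_SLITS_MM, n_photons: int = 200_000,
                   master_seed: int = 0, *,
                   geometry: ScannerGeometry | None = None,
                   spectrum: EnergySpectrum | None = None,
                   downsample: int = 4, roi_side_cm: float = 0.55,
                   enumerate_only: bool = False,
                   **view_kwargs) -> pd.DataFrame:
    """Factorial collimation sweep over phantom diameter x layout x slit.

    The default factors (3 diameters x 4 insert layouts x 7 collimation
    settings) enumerate 84 scan configurations.  For each configuration the
    first view is simulated fluence-normalized and the central-ROI mean of
    each channel plus the SPR is tallied.  ``roi_side_cm`` is the physical
    ROI footprint (default 5.5 mm, the 11x11-pixel ROI at native 0.5 mm
    pitch).  ``enumerate_only=True`` lists configurations without running.
    """
    from ..evaluation import ROISpec, compute_spr
    from ..spectrum import build_spectrum

    if not (len(tuple(diameters)) and len(tuple(layouts)) and len(tuple(slits_mm))):
        raise ValueError("factor lists must be non-empty")
    if geometry is None:
        geometry = ScannerGeometry().downsampled(downsample)
    if spectrum is None and not enumerate_only:
        spectrum = build_spectrum()
    rows = []
    run = 0
    for d in diameters:
        for layout in layouts:
            preset = f"mc_{int(d)}cm_{layout}"
            for slit in slits_mm:
                coll = (open_collimation(geometry) if slit is None
                        else CollimatorSetting(slit_mm=float(slit),
                                               geometry=geometry))
                rec = {"diameter_cm": float(d), "layout": layout,
                       "phantom": preset,
                       "slit_mm": None if slit is None else float(slit),
                       "slit_x_mm": coll.effective_slit_mm}
                if not enumerate_only:
                    phantom = build_phantom(preset)
                    stack, _ = simulate_view(
                        phantom, geometry, coll, spectrum, n_photons,
                        view_seed(master_seed, run),
                        fluence_normalized=True, **view_kwargs)
                    side_px = max(1, int(round(roi_side_cm * 10
                                               / geometry.det_pitch_mm)))
                    roi = ROISpec(domain="projection", shape="square",
                                  side_px=side_px)
                    spr = compute_spr(stack, roi)
                    rec.update({"mean_total": spr.mean_total,
                                "mean_primary": spr.mean_primary,
                                "mean_scatter": spr.mean_scatter,
                                "sd_total": spr.sd_total,
                                "spr": spr.spr,
                                "n_detected": stack.meta["n_detected"]})
                rows.append(rec)
                run += 1
    return pd.DataFrame(rows)
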