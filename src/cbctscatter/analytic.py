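"""Analytic forward model: Beer-Lambert primaries plus a parametric scatter field.

This module is the fast, noiseless (or Poisson) counterpart of the Monte
Carlo engine.  It computes exact line integrals through the cylindrical
phantom (spectral summation over the beam, so polyenergetic projections
carry realistic beam hardening) and can add a low-frequency synthetic
scatter field whose slit response ``g(s)`` is configurable.  It serves as
fixture generator and as the primary-channel oracle for Monte Carlo tests;
it makes no claim of physical scatter accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geometry import CollimatorSetting, ScannerGeometry
from .materials import get_material, material_mu
from .phantoms import PhantomSpec
from .projections import ProjectionStack
from .spectrum import EnergySpectrum


def _segment_interval(p0, d, cx, cy, r, hz):
    """Intersection of rays with a finite cylinder, vectorized over rays.

    ``p0``: (3,) start point; ``d``: (n, 3) unit directions.  Returns
    ``(t0, t1)`` arrays with ``t0 >= 0``; misses have ``t0 >= t1``.
    """
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    px, py, pz = p0[0] - cx, p0[1] - cy, p0[2]
    a = dx * dx + dy * dy
    b = px * dx + py * dy
    c = px * px + py * py - r * r
    disc = b * b - a * c
    t0 = np.full(d.shape[0], 1.0)
    t1 = np.zeros(d.shape[0])
    hit = (disc > 0) & (a > 1e-16)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tc0 = np.where(hit, (-b - sq) / a, 1.0)
        tc1 = np.where(hit, (-b + sq) / a, 0.0)
    axial = (a <= 1e-16) & (c < 0)
    tc0 = np.where(axial, -1e30, tc0)
    tc1 = np.where(axial, 1e30, tc1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (-hz - pz) / np.where(np.abs(dz) > 1e-16, dz, np.inf)
        tb = (hz - pz) / np.where(np.abs(dz) > 1e-16, dz, np.inf)
    tz0 = np.minimum(ta, tb)
    tz1 = np.maximum(ta, tb)
    flat = np.abs(dz) <= 1e-16
    tz0 = np.where(flat, np.where(abs(p0[2]) < hz, -1e30, 1.0), tz0)
    tz1 = np.where(flat, np.where(abs(p0[2]) < hz, 1e30, 0.0), tz1)
    lo = np.maximum(np.maximum(tc0, tz0), 0.0)
    hi = np.minimum(tc1, tz1)
    return lo, hi


def ray_path_lengths(source, targets, phantom: PhantomSpec,
                     angle_deg: float = 0.0) -> dict[str, np.ndarray]:
    """Per-material intersection lengths [cm] for source->target segments.

    ``targets`` is (n, 3); the phantom is rotated by the gantry angle.
    Nested structures resolve innermost-wins (core length is subtracted from
    its sheath, insert lengths from the body).  Rays that miss return zeros.
    """
    source = np.asarray(source, float)
    targets = np.atleast_2d(np.asarray(targets, float))
    d = targets - source
    seg_len = np.linalg.norm(d, axis=1)
    d = d / seg_len[:, None]
    c = np.cos(np.deg2rad(-angle_deg))
    s = np.sin(np.deg2rad(-angle_deg))

    lengths: dict[str, np.ndarray] = {m: np.zeros(d.shape[0])
                                      for m in phantom.material_names()}
    b0, b1 = _segment_interval(source, d, 0.0, 0.0, phantom.body_radius,
                               phantom.body_height / 2.0)
    b1 = np.minimum(b1, seg_len)
    body_len = np.clip(b1 - b0, 0.0, None)
    for ins in phantom.inserts:
        x = c * ins.center_xy[0] - s * ins.center_xy[1]
        y = s * ins.center_xy[0] + c * ins.center_xy[1]
        i0, i1 = _segment_interval(source, d, x, y, ins.radius, ins.height / 2.0)
        i1 = np.minimum(i1, seg_len)
        ins_len = np.clip(i1 - i0, 0.0, None)
        if ins.core_diameter is not None:
            c0, c1 = _segment_interval(source, d, x, y, ins.core_diameter / 2.0,
                                       ins.height / 2.0)
            c1 = np.minimum(c1, seg_len)
            core_len = np.clip(c1 - c0, 0.0, None)
            lengths[ins.core_material] += core_len
            ins_len = ins_len - core_len
        lengths[ins.material] += ins_len
        body_len = body_len - ins_len
        if ins.core_diameter is not None:
            body_len = body_len - core_len
    lengths[phantom.body_material] += np.clip(body_len, 0.0, None)
    return lengths


def _detector_grid(geometry: ScannerGeometry) -> tuple[np.ndarray, np.ndarray]:
    pitch = geometry.det_pitch_mm / 10.0
    y = (np.arange(geometry.det_cols) - (geometry.det_cols - 1) / 2.0) * pitch
    z = (np.arange(geometry.det_rows) - (geometry.det_rows - 1) / 2.0) * pitch
    return y, z


def project_primary(phantom: PhantomSpec, geometry: ScannerGeometry,
                    collimation: CollimatorSetting, spectrum: EnergySpectrum,
                    i0: float = 1.0e4) -> ProjectionStack:
    """Noiseless Beer-Lambert primary projections for every view.

    Pixel value: ``i0 * sum_E w(E) exp(-sum_m mu_m(E) L_m)``; zero outside
    the illuminated rows.
    """
    if i0 <= 0:
        raise ValueError("open-field intensity must be positive")
    y, z = _detector_grid(geometry)
    det_x = geometry.sdd - geometry.sad
    yy, zz = np.meshgrid(y, z)
    targets = np.column_stack([np.full(yy.size, det_x), yy.ravel(), zz.ravel()])
    source = np.array([-geometry.sad, 0.0, 0.0])
    r0, r1 = collimation.illuminated_rows
    mats = phantom.material_names()
    mus = {m: material_mu(m, spectrum.energies)[3] for m in mats}

    views = np.zeros((geometry.n_views, geometry.det_rows, geometry.det_cols))
    for v, ang in enumerate(geometry.angles):
        lens = ray_path_lengths(source, targets, phantom, angle_deg=ang)
        optical = np.zeros((spectrum.energies.size, yy.size))
        for m in mats:
            optical += np.outer(mus[m], lens[m])
        img = (i0 * spectrum.weights @ np.exp(-optical)).reshape(yy.shape)
        img[:r0] = 0.0
        img[r1:] = 0.0
        views[v] = img
    meta = {"phantom": phantom.name, "i0": i0,
            "slit_mm": collimation.slit_mm,
            "effective_slit_mm": collimation.effective_slit_mm,
            "det_pitch_mm": geometry.det_pitch_mm,
            "sad": geometry.sad, "sdd": geometry.sdd,
            "analytic": True, "illuminated_rows": [r0, r1]}
    return ProjectionStack(channels={"total": views.copy(), "primary": views,
                                     "scatter": np.zeros_like(views)},
                           angles=geometry.angles.copy(), meta=meta)


def log_slit_response(s0_mm: float = 5.0) -> Callable[[float], float]:
    """Saturating slit response ``g(s) = ln(1 + s/s0)``; ``g(0) = 0``."""
    def g(slit_mm: float) -> float:
        return float(np.log1p(slit_mm / s0_mm))
    return g


def satexp_slit_response(s0_mm: float = 10.0) -> Callable[[float], float]:
    """Alternative saturating-exponential response ``g(s) = 1 - exp(-s/s0)``."""
    def g(slit_mm: float) -> float:
        return float(1.0 - np.exp(-slit_mm / s0_mm))
    return g


@dataclass(frozen=True)
class AnalyticScatterField:
    """Smooth low-frequency scatter: ``amplitude * i0 * profile * g(slit)``.

    ``profile`` maps normalized detector coordinates (u, v in [-1, 1]) to a
    non-negative smooth shape (default: broad Gaussian bump, the dominant
    low-frequency character of physical scatter).
    """

    amplitude: float = 0.3
    slit_response: Callable[[float], float] = field(default_factory=log_slit_response)
    profile: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def evaluate(self, geometry: ScannerGeometry, slit_mm: float,
                 i0: float) -> np.ndarray:
        y, z = _detector_grid(geometry)
        u = y / (geometry.det_width_cm / 2.0)
        v = z / (geometry.det_height_cm / 2.0)
        uu, vv = np.meshgrid(u, v)
        if self.profile is None:
            shape = np.exp(-(uu**2 + vv**2) / 0.8)
        else:
            shape = np.asarray(self.profile(uu, vv), float)
        if np.any(shape < 0):
            raise ValueError("scatter profile must be non-negative")
        g = self.slit_response(float(slit_mm))
        if g < 0:
            raise ValueError("slit response must be non-negative")
        return self.amplitude * i0 * g * shape


def add_scatter_and_noise(primary: ProjectionStack, field_: AnalyticScatterField,
                          collimation: CollimatorSetting, poisson: bool = False,
                          seed: int = 0) -> ProjectionStack:
    """Add the parametric scatter field (and optional Poisson noise).

    Scatter is confined to the illuminated band; ``total = primary + scatter``
    holds exactly pre-noise and in expectation with noise.
    """
    geometry_pitch = primary.meta.get("det_pitch_mm", 1.0)
    i0 = float(primary.meta.get("i0", primary["primary"].max() or 1.0))
    n_views, n_rows, n_cols = primary.shape
    r0, r1 = primary.meta.get("illuminated_rows", (0, n_rows))
    # rebuild minimal geometry facts for the field's normalized coordinates
    from .geometry import ScannerGeometry as _G

    geom = _G(sad=primary.meta.get("sad", 49.54),
              sdd=primary.meta.get("sdd", 71.4),
              det_rows=n_rows, det_cols=n_cols, det_pitch_mm=geometry_pitch,
              n_views=n_views, angles=primary.angles)
    scatter_img = field_.evaluate(geom, collimation.effective_slit_mm, i0)
    scatter_img = np.broadcast_to(scatter_img, primary.shape).copy()
    scatter_img[:, :r0] = 0.0
    scatter_img[:, r1:] = 0.0
    prim = primary["primary"].copy()
    if poisson:
        rng = np.random.default_rng(seed)
        prim = rng.poisson(prim).astype(float)
        scatter_img = rng.poisson(scatter_img).astype(float)
    meta = dict(primary.meta)
    meta.update({"scatter_amplitude": field_.amplitude, "poisson": poisson,
                 "noise_seed": seed})
    return ProjectionStack(
        channels={"total": prim + scatter_img, "primary": prim,
                  "scatter": scatter_img},
        angles=primary.angles.copy(), meta=meta)
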