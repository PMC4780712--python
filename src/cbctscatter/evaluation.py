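"""ROI statistics, SPR, log-fit diagnostics, CNR, cupping index, profiles.

Conventions: sample (n-1) standard deviations throughout; projection-domain
ROI tallies default to the first view; CNR follows
``|CT# - CT#_water| / SD_water`` with the water background ROI placed
automatically at the most insert-free spot of the body.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantoms import PhantomSpec
from .projections import ProjectionStack


@dataclass(frozen=True)
class ROISpec:
    """Square (pixels) or circular (cm) region of interest.

    ``center`` is ``(row, col)`` in pixels for projection-domain ROIs and
    ``(x, y)`` in cm for image-domain ROIs; ``None`` means image center.
    """

    domain: str = "projection"            # "projection" | "image"
    shape: str = "square"                 # "square" | "circle"
    side_px: int = 11
    diameter_cm: float = 0.9
    center: tuple[float, float] | None = None

    def __post_init__(self):
        if self.domain not in ("projection", "image"):
            raise ValueError("domain must be 'projection' or 'image'")
        if self.shape not in ("square", "circle"):
            raise ValueError("shape must be 'square' or 'circle'")
        if self.shape == "square" and self.side_px < 1:
            raise ValueError("square ROI side must be >= 1 pixel")
        if self.shape == "circle" and self.diameter_cm <= 0:
            raise ValueError("circular ROI diameter must be positive")


def _roi_mask(image: np.ndarray, roi: ROISpec,
              pixel_size_cm: float = 1.0) -> np.ndarray:
    nr, nc = image.shape
    if roi.center is None:
        cr, cc = (nr - 1) / 2.0, (nc - 1) / 2.0
    elif roi.domain == "image":
        cr = (nr - 1) / 2.0 + roi.center[1] / pixel_size_cm
        cc = (nc - 1) / 2.0 + roi.center[0] / pixel_size_cm
    else:
        cr, cc = roi.center
    mask = np.zeros(image.shape, dtype=bool)
    if roi.shape == "square":
        half = roi.side_px // 2
        r0 = int(round(cr)) - half
        c0 = int(round(cc)) - half
        r1, c1 = r0 + roi.side_px, c0 + roi.side_px
        if r0 < 0 or c0 < 0 or r1 > nr or c1 > nc:
            raise ValueError("ROI extends outside the image")
        mask[r0:r1, c0:c1] = True
    else:
        radius_px = roi.diameter_cm / 2.0 / pixel_size_cm
        if (cr - radius_px < -0.5 or cc - radius_px < -0.5
                or cr + radius_px > nr - 0.5 or cc + radius_px > nc - 0.5):
            raise ValueError("ROI extends outside the image")
        rr, cc_ = np.mgrid[0:nr, 0:nc]
        mask = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius_px**2
    if not mask.any():
        raise ValueError("empty ROI")
    return mask


def roi_stats(image: np.ndarray, roi: ROISpec,
              pixel_size_cm: float = 1.0) -> tuple[float, float, int]:
    """(mean, sample SD, pixel count) over the ROI."""
    vals = np.asarray(image, float)[_roi_mask(np.asarray(image), roi,
                                              pixel_size_cm)]
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, int(vals.size)


@dataclass(frozen=True)
class SPRResult:
    mean_total: float
    mean_primary: float
    mean_scatter: float
    sd_total: float
    sd_primary: float
    sd_scatter: float
    spr: float


def compute_spr(stack: ProjectionStack, roi: ROISpec,
                view: int = 0) -> SPRResult:
    """Scatter-to-primary ratio from ROI means of the channel images."""
    for c in ("primary", "scatter"):
        if not stack.has_channel(c):
            raise ValueError(f"stack lacks the {c!r} channel")
    mt, st, _ = roi_stats(stack["total"][view], roi)
    mp, sp, _ = roi_stats(stack["primary"][view], roi)
    ms, ss, _ = roi_stats(stack["scatter"][view], roi)
    if mp <= 0:
        raise ValueError("zero primary intensity in ROI: SPR undefined")
    return SPRResult(mean_total=mt, mean_primary=mp, mean_scatter=ms,
                     sd_total=st, sd_primary=sp, sd_scatter=ss, spr=ms / mp)


def fit_diagnostics(x, y) -> tuple[float, float, float]:
    """Least-squares fit of ``y = a*ln(x) + b``; returns ``(a, b, r2)``.

    Constant ``y`` (zero total variance) returns ``r2 = 0`` by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired observations")
    if np.any(x <= 0) or np.unique(x).size < 2:
        raise ValueError("slit sizes must be positive and not all equal")
    lx = np.log(x)
    coef, *_ = np.linalg.lstsq(np.column_stack([lx, np.ones_like(lx)]), y,
                               rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid = y - (a * lx + b)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return a, b, 0.0
    return a, b, 1.0 - float(np.sum(resid**2)) / ss_tot


@dataclass(frozen=True)
class CNRReport:
    per_insert: pd.DataFrame       # material, ct_mean, cnr
    ct_water_mean: float
    ct_water_sd: float
    mean_cnr: float


def _background_center(phantom: PhantomSpec) -> tuple[float, float]:
    """Pick the body location farthest from every insert (and the rim)."""
    r_max = phantom.body_radius - 0.6
    best, best_d = (0.0, 0.0), -1.0
    for rad in np.linspace(0.0, max(r_max, 0.0), 12):
        for ang in np.linspace(0.0, 2 * np.pi, 36, endpoint=False):
            x, y = rad * np.cos(ang), rad * np.sin(ang)
            d = phantom.body_radius - np.hypot(x, y)
            for ins in phantom.inserts:
                d = min(d, np.hypot(x - ins.center_xy[0],
                                    y - ins.center_xy[1]) - ins.radius)
            if d > best_d:
                best_d, best = d, (x, y)
    return best


def compute_cnr(volume, phantom: PhantomSpec,
                insert_roi_cm: float = 0.9, slice_index: int | None = None,
                background_center: tuple[float, float] | None = None) -> CNRReport:
    """Per-insert contrast-to-noise ratio on the central slice.

    ``CNR = |CT# - CT#_water| / SD_water`` with ROIs of ``insert_roi_cm``
    diameter at the insert centers (bone cores use the core) and in an
    insert-free background region.
    """
    img, pixel_cm = _central_slice(volume, slice_index)
    if background_center is None:
        background_center = _background_center(phantom)
    bg_roi = ROISpec(domain="image", shape="circle", diameter_cm=insert_roi_cm,
                     center=background_center)
    water_mean, water_sd, _ = roi_stats(img, bg_roi, pixel_cm)
    if water_sd == 0:
        raise ValueError("zero background SD: CNR undefined")
    rows = []
    for ins in phantom.inserts:
        mat = ins.core_material or ins.material
        roi = ROISpec(domain="image", shape="circle", diameter_cm=insert_roi_cm,
                      center=ins.center_xy)
        m, _, _ = roi_stats(img, roi, pixel_cm)
        rows.append({"material": mat, "ct_mean": m,
                     "cnr": abs(m - water_mean) / water_sd})
    df = pd.DataFrame(rows)
    return CNRReport(per_insert=df, ct_water_mean=water_mean,
                     ct_water_sd=water_sd,
                     mean_cnr=float(df["cnr"].mean()) if len(df) else 0.0)


def _central_slice(volume, slice_index=None) -> tuple[np.ndarray, float]:
    """Accept a ReconVolume or a bare 2D/3D array (+1 cm pixels)."""
    voxels = getattr(volume, "voxels", volume)
    pixel_cm = getattr(volume, "voxel_size_mm", 10.0) / 10.0
    voxels = np.asarray(voxels, float)
    if voxels.ndim == 3:
        k = voxels.shape[0] // 2 if slice_index is None else slice_index
        return voxels[k], pixel_cm
    return voxels, pixel_cm


def cupping_index(volume, phantom: PhantomSpec,
                  slice_index: int | None = None,
                  center_frac: float = 0.15,
                  edge_fracs: tuple[float, float] = (0.65, 0.80)) -> float:
    """Edge-band mean minus central mean over the water body (central slice).

    Positive under cupping (center depressed), ~0 for an artifact-free
    uniform body.  Insert regions are excluded from both bands.
    """
    img, pixel_cm = _central_slice(volume, slice_index)
    nr, nc = img.shape
    x = (np.arange(nc) - (nc - 1) / 2.0) * pixel_cm
    y = (np.arange(nr) - (nr - 1) / 2.0) * pixel_cm
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx, yy)
    rb = phantom.body_radius
    free = np.ones_like(img, dtype=bool)
    for ins in phantom.inserts:
        free &= np.hypot(xx - ins.center_xy[0],
                         yy - ins.center_xy[1]) > ins.radius + 2 * pixel_cm
    center = free & (r <= center_frac * rb)
    edge = free & (r >= edge_fracs[0] * rb) & (r <= edge_fracs[1] * rb)
    if not center.any() or not edge.any():
        raise ValueError("cupping bands empty; volume too coarse for phantom")
    return float(img[edge].mean() - img[center].mean())


def line_profile(image: np.ndarray, start, end, n_samples: int = 200) -> np.ndarray:
    """Bilinearly interpolated profile between two (row, col) endpoints."""
    from scipy.ndimage import map_coordinates

    image = np.asarray(image, float)
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    for p in (start, end):
        if (p < -0.5).any() or p[0] > image.shape[0] - 0.5 or p[1] > image.shape[1] - 0.5:
            raise ValueError("profile endpoints outside the image")
    t = np.linspace(0.0, 1.0, n_samples)
    coords = np.outer(1 - t, start) + np.outer(t, end)
    return map_coordinates(image, coords.T, order=1, mode="nearest")
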