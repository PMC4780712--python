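"""Two-FOV projection-domain scatter correction.

The method: acquire the same scan with two axial collimations (small and
large FOV), fit ``y = a ln(x) + b`` per pixel to the two total intensities
``y`` versus slit size ``x``, extrapolate the model to a small slit where
scatter is negligible, take the low-frequency component (2D Gaussian,
11x11 window, sigma 5 px) of the difference between the raw projection and
the extrapolated one as the scatter estimate, and subtract it from the raw
projection before reconstruction.

With exactly two observations the per-pixel model interpolates both inputs
exactly:

    a = (y2 - y1) / ln(x2/x1),   b = y1 - a ln(x1).

Pixels whose large-FOV intensity does not exceed the small-FOV one (pure
noise implies a non-positive slope) fall back to ``a = 0`` so that
extrapolation to small slits cannot diverge; their scatter estimate is then
driven by their neighbors through the low-pass filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

from .projections import ProjectionStack


@dataclass(frozen=True)
class SmoothingConfig:
    """Truncated, renormalized 2D Gaussian kernel parameters."""

    window: int = 11     # odd pixel count
    sigma: float = 5.0   # pixels

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def kernel(self) -> np.ndarray:
        """Explicit window x window Gaussian, normalized to sum 1."""
        half = self.window // 2
        ax = np.arange(-half, half + 1, dtype=float)
        g1 = np.exp(-(ax**2) / (2.0 * self.sigma**2))
        k = np.outer(g1, g1)
        return k / k.sum()


@dataclass
class ScatterFitModel:
    """Per-pixel natural-log regression ``y = a ln(x) + b``."""

    a: np.ndarray                 # (n_views, rows, cols)
    b: np.ndarray
    valid_mask: np.ndarray        # pixels inside the two-FOV overlap band
    fit_domain: tuple[float, ...]  # slit sizes used [mm]
    r2: np.ndarray | None = None  # defined only for > 2 observations
    meta: dict = field(default_factory=dict)


def _check_compatible(stacks: list[ProjectionStack]):
    shapes = {s.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError("projection stacks have mismatched shapes")
    ref = stacks[0].angles
    for s in stacks[1:]:
        if not np.allclose(s.angles, ref):
            raise ValueError("projection stacks have mismatched view angles")


def _overlap_mask(stacks: list[ProjectionStack]) -> np.ndarray:
    """Rows illuminated by every acquisition (the smallest FOV's band)."""
    shape = stacks[0].shape
    r0, r1 = 0, shape[1]
    for s in stacks:
        rows = s.meta.get("illuminated_rows")
        if rows is not None:
            r0, r1 = max(r0, rows[0]), min(r1, rows[1])
    mask = np.zeros(shape, dtype=bool)
    mask[:, r0:r1, :] = True
    return mask


def fit_log_model(x1: float, stack1: ProjectionStack,
                  x2: float, stack2: ProjectionStack) -> ScatterFitModel:
    """Exact two-point per-pixel log fit to total intensity.

    ``x1``/``x2`` are the collimating slit sizes [mm] of the two scans.
    Requires matching geometry and view angles; the model is valid on the
    overlap band of the two FOVs where both intensities are positive.
    """
    if x1 <= 0 or x2 <= 0 or x1 == x2:
        raise ValueError("slit sizes must be positive and distinct")
    _check_compatible([stack1, stack2])
    y1 = stack1["total"].astype(float)
    y2 = stack2["total"].astype(float)
    if x1 > x2:  # orient so x1 is the smaller FOV
        x1, x2, y1, y2 = x2, x1, y2, y1
    mask = _overlap_mask([stack1, stack2]) & (y1 > 0) & (y2 > 0)
    a = (y2 - y1) / np.log(x2 / x1)
    a = np.where(mask & (y2 > y1), a, 0.0)  # non-positive slope fallback
    b = np.where(mask, y1 - a * np.log(x1), 0.0)
    return ScatterFitModel(a=a, b=b, valid_mask=mask, fit_domain=(x1, x2),
                           meta={"mode": "two-point"})


def fit_log_model_sweep(slits_mm, stacks: list[ProjectionStack]) -> ScatterFitModel:
    """Per-pixel least-squares log fit to >= 3 collimation settings."""
    slits = np.asarray(slits_mm, float)
    if slits.size < 3 or np.any(slits <= 0) or np.unique(slits).size < 2:
        raise ValueError("need >= 3 positive, non-degenerate slit sizes")
    if len(stacks) != slits.size:
        raise ValueError("one stack per slit size required")
    _check_compatible(list(stacks))
    y = np.stack([s["total"].astype(float) for s in stacks])  # (k, v, r, c)
    lx = np.log(slits)
    lxc = lx - lx.mean()
    denom = float(np.sum(lxc**2))
    a = np.tensordot(lxc, y, axes=(0, 0)) / denom
    b = y.mean(axis=0) - a * lx.mean()
    fitted = a[None] * lx[:, None, None, None] + b[None]
    ss_res = np.sum((y - fitted) ** 2, axis=0)
    ss_tot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    mask = _overlap_mask(list(stacks)) & np.all(y > 0, axis=0)
    a = np.where(mask, a, 0.0)
    b = np.where(mask, b, 0.0)
    return ScatterFitModel(a=a, b=b, valid_mask=mask,
                           fit_domain=tuple(float(s) for s in slits),
                           r2=np.where(mask, r2, 0.0),
                           meta={"mode": "least-squares"})


def extrapolate_projection(model: ScatterFitModel,
                           target_slit: float) -> np.ndarray:
    """Evaluate the per-pixel model at ``target_slit`` mm (clamped at 0).

    The natural-log model diverges as the slit approaches zero, so the
    target must be a positive slit size.  The workflow default (2.7 mm)
    balances residual scatter against the noise amplification of the
    extrapolation, which grows as ln(x1/target)/ln(x2/x1).
    """
    if target_slit <= 0:
        raise ValueError(
            "target slit must be > 0: the model y = a ln(x) + b is "
            "undefined at x = 0; extrapolate to a small positive slit")
    est = model.a * np.log(target_slit) + model.b
    return np.clip(est, 0.0, None) * model.valid_mask


@dataclass
class ScatterEstimate:
    """Low-frequency scatter image per view, on the fit's valid mask."""

    scatter: np.ndarray
    raw_source: str               # which acquisition will be corrected
    extrapolation_slit: float     # mm
    smoothing: SmoothingConfig
    valid_mask: np.ndarray | None = None


def estimate_scatter(raw: ProjectionStack, extrapolated: np.ndarray,
                     smoothing: SmoothingConfig | None = None,
                     extrapolation_slit: float = 0.5,
                     raw_source: str = "small-fov") -> ScatterEstimate:
    """Gaussian low-pass of (raw - extrapolated), clamped at zero.

    The extrapolated projection is nearly scatter-free but noisy; the
    residual's low-frequency component is the scatter estimate.  Border
    handling is by reflection; the kernel is the explicit truncated
    normalized Gaussian.
    """
    smoothing = smoothing or SmoothingConfig()
    total = raw["total"].astype(float)
    if total.shape != extrapolated.shape:
        raise ValueError("raw stack and extrapolated projection shapes differ")
    k = smoothing.kernel()
    resid = total - extrapolated
    smoothed = np.empty_like(resid)
    for v in range(resid.shape[0]):
        smoothed[v] = correlate(resid[v], k, mode="reflect")
    return ScatterEstimate(scatter=np.clip(smoothed, 0.0, None),
                           raw_source=raw_source,
                           extrapolation_slit=extrapolation_slit,
                           smoothing=smoothing)


def correct_projection(raw: ProjectionStack, scatter: ScatterEstimate,
                       floor: float = 1.0) -> ProjectionStack:
    """Subtract the scatter estimate; floor keeps the log transform valid."""
    total = raw["total"].astype(float)
    if total.shape != scatter.scatter.shape:
        raise ValueError("raw stack and scatter estimate shapes differ")
    corrected = np.maximum(total - scatter.scatter, floor)
    meta = dict(raw.meta)
    meta.update({"scatter_corrected": True,
                 "extrapolation_slit_mm": scatter.extrapolation_slit,
                 "smoothing_window": scatter.smoothing.window,
                 "smoothing_sigma": scatter.smoothing.sigma,
                 "floor": floor, "raw_source": scatter.raw_source})
    return ProjectionStack(channels={"total": corrected},
                           angles=raw.angles.copy(), meta=meta)


def correct_two_fov(small_fov: ProjectionStack, slit_small_mm: float,
                    large_fov: ProjectionStack, slit_large_mm: float, *,
                    target_slit_mm: float = 2.7,
                    smoothing: SmoothingConfig | None = None,
                    correct: str = "small", floor: float = 1.0,
                    ) -> tuple[ProjectionStack, ScatterFitModel, ScatterEstimate]:
    """End-to-end correction of one of the two acquisitions (default: small FOV)."""
    model = fit_log_model(slit_small_mm, small_fov, slit_large_mm, large_fov)
    extrap = extrapolate_projection(model, target_slit_mm)
    raw = small_fov if correct == "small" else large_fov
    est = estimate_scatter(raw, extrap, smoothing,
                           extrapolation_slit=target_slit_mm,
                           raw_source=f"{correct}-fov")
    est.valid_mask = model.valid_mask
    corrected = correct_projection(raw, est, floor=floor)
    if correct == "large":
        # rows outside the overlap band stay uncorrected; flag them
        outside = ~model.valid_mask
        corrected.channels["total"][outside] = raw["total"][outside]
        corrected.meta["uncorrected_rows_flagged"] = True
    return corrected, model, est
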