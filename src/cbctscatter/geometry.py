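"""Scanner geometry and axial collimation.

Coordinates are right-handed with the origin at the isocenter and z along
the rotation axis.  At gantry angle 0 the source sits at ``(-sad, 0, 0)``
and the flat-panel detector is centered on ``(+sdd - sad, 0, 0)`` with
pixel columns along +y and rows along +z (row 0 at the -z edge).  Pixel
indices are 0-based and index intervals are half-open.

The axial collimator is a thin slit at ``collimator_distance`` from the
source.  Its default position is calibrated once so that a 4 cm axial
field of view at the isocenter corresponds to a 14 mm slit, the anchor
measured on the modeled scanner; the 13 cm FOV then maps to ~45 mm, only
approximately the 42 mm reported for that scanner (the two published film
measurements are not mutually consistent with a single thin-slit geometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

# nominal dental CBCT values: SAD 49.54 cm, SDD 71.4 cm, 384x480 detector at
# 0.5 mm pitch, 301 views over 360 degrees, 120 kVp.
DEFAULT_SAD_CM = 49.54
DEFAULT_SDD_CM = 71.4
DEFAULT_DET_ROWS = 384
DEFAULT_DET_COLS = 480
DEFAULT_DET_PITCH_MM = 0.5
DEFAULT_N_VIEWS = 301

# collimator anchored so slit_for_fov(4 cm) -> 14 mm
DEFAULT_COLLIMATOR_DISTANCE_CM = 1.4 * DEFAULT_SAD_CM / 4.0


def _default_angles(n_views: int) -> np.ndarray:
    return np.arange(n_views) * (360.0 / n_views)


@dataclass(frozen=True)
class ScannerGeometry:
    """Circular cone-beam geometry with a flat-panel detector."""

    sad: float = DEFAULT_SAD_CM          # source-axis distance [cm]
    sdd: float = DEFAULT_SDD_CM          # source-detector distance [cm]
    det_rows: int = DEFAULT_DET_ROWS     # axial pixel count
    det_cols: int = DEFAULT_DET_COLS     # transverse pixel count
    det_pitch_mm: float = DEFAULT_DET_PITCH_MM
    n_views: int = DEFAULT_N_VIEWS
    angles: np.ndarray = None            # degrees, strictly increasing
    collimator_distance: float = DEFAULT_COLLIMATOR_DISTANCE_CM  # cm from source

    def __post_init__(self):
        if self.angles is None:
            object.__setattr__(self, "angles", _default_angles(self.n_views))
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        if not (self.sad > 0 and self.sdd > 0 and self.sad < self.sdd):
            raise ValueError("require 0 < sad < sdd")
        if min(self.det_rows, self.det_cols, self.n_views) < 1:
            raise ValueError("detector grid and view count must be >= 1")
        if self.det_pitch_mm <= 0:
            raise ValueError("detector pitch must be positive")
        if not (0 < self.collimator_distance < self.sdd):
            raise ValueError("collimator must lie between source and detector")
        if angles.size != self.n_views:
            raise ValueError("angles length must equal n_views")
        if angles.size > 1 and not np.all(np.diff(angles) > 0):
            raise ValueError("angles must be strictly increasing")
        if angles.size and (angles[-1] - angles[0]) >= 360.0 + 1e-9:
            raise ValueError("angles must span less than 360 degrees")

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    @property
    def det_width_cm(self) -> float:
        return self.det_cols * self.det_pitch_mm / 10.0

    @property
    def det_height_cm(self) -> float:
        return self.det_rows * self.det_pitch_mm / 10.0

    @property
    def max_fov_cm(self) -> float:
        """Largest axial FOV the detector can cover at the isocenter."""
        return self.det_height_cm / self.magnification

    @property
    def open_slit_mm(self) -> float:
        """Slit opening whose beam exactly covers the detector height."""
        return 10.0 * self.det_height_cm * self.collimator_distance / self.sdd

    def downsampled(self, factor: int) -> "ScannerGeometry":
        """Same physical detector on a coarser pixel grid."""
        if factor < 1 or self.det_rows % factor or self.det_cols % factor:
            raise ValueError("factor must divide the detector grid")
        return replace(self, det_rows=self.det_rows // factor,
                       det_cols=self.det_cols // factor,
                       det_pitch_mm=self.det_pitch_mm * factor)

    def with_views(self, n_views: int) -> "ScannerGeometry":
        return replace(self, n_views=n_views, angles=_default_angles(n_views))


@dataclass(frozen=True)
class CollimatorSetting:
    """Axial slit opening; ``slit_mm=None`` means fully open."""

    slit_mm: float | None
    geometry: ScannerGeometry = field(default_factory=ScannerGeometry, repr=False)

    def __post_init__(self):
        if self.slit_mm is not None and self.slit_mm <= 0:
            raise ValueError("slit opening must be positive (or None for open)")

    @property
    def is_open(self) -> bool:
        return self.slit_mm is None

    @property
    def effective_slit_mm(self) -> float:
        """Open collimation mapped to the slit that just covers the detector."""
        g = self.geometry
        return g.open_slit_mm if self.is_open else min(self.slit_mm, g.open_slit_mm)

    @property
    def beam_height_at_iso(self) -> float:
        """Illuminated axial extent at the isocenter [cm]."""
        g = self.geometry
        return self.effective_slit_mm / 10.0 * g.sad / g.collimator_distance

    @property
    def beam_height_at_detector(self) -> float:
        g = self.geometry
        return self.effective_slit_mm / 10.0 * g.sdd / g.collimator_distance

    @property
    def illuminated_rows(self) -> tuple[int, int]:
        """Half-open [row0, row1) interval of detector rows in the beam."""
        g = self.geometry
        half = self.beam_height_at_detector / 2.0
        pitch_cm = g.det_pitch_mm / 10.0
        center = g.det_rows / 2.0
        r0 = int(math.floor(center - half / pitch_cm))
        r1 = int(math.ceil(center + half / pitch_cm))
        return max(r0, 0), min(r1, g.det_rows)


def build_default_geometry() -> ScannerGeometry:
    """The modeled dental scanner's nominal geometry."""
    return ScannerGeometry()


def slit_for_fov(axial_fov_at_iso: float, geometry: ScannerGeometry) -> CollimatorSetting:
    """Slit whose beam covers ``axial_fov_at_iso`` cm at the isocenter.

    Uses similar triangles through the point source; errors if the requested
    FOV exceeds what the detector can image.
    """
    if geometry.collimator_distance <= 0:
        raise ValueError("degenerate collimator at the source position")
    if axial_fov_at_iso <= 0:
        raise ValueError("FOV must be positive")
    if axial_fov_at_iso > geometry.max_fov_cm + 1e-9:
        raise ValueError(
            f"FOV {axial_fov_at_iso} cm exceeds detector axial coverage "
            f"({geometry.max_fov_cm:.2f} cm at isocenter)"
        )
    slit_mm = 10.0 * axial_fov_at_iso * geometry.collimator_distance / geometry.sad
    return CollimatorSetting(slit_mm=slit_mm, geometry=geometry)


def open_collimation(geometry: ScannerGeometry) -> CollimatorSetting:
    return CollimatorSetting(slit_mm=None, geometry=geometry)
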