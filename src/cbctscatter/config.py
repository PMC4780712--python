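"""Run configuration: a fully serializable description of a pipeline run.

A :class:`RunConfig` validates every parameter against the module
preconditions before any computation starts; an identical config (same
seed) re-runs to bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .correction import SmoothingConfig
from .geometry import ScannerGeometry
from .phantoms import PHANTOM_PRESETS, build_phantom
from .spectrum import build_spectrum


@dataclass
class RunConfig:
    # geometry
    sad: float = 49.54
    sdd: float = 71.4
    det_rows: int = 96
    det_cols: int = 120
    det_pitch_mm: float = 2.0
    n_views: int = 48
    collimator_distance: float | None = None
    # spectrum
    kvp: float = 120.0
    filtration_al_mm: float = 10.0
    spectrum_mode: str = "polychromatic"
    energy_kev: float = 60.0
    # phantom & acquisition
    phantom: str = "mc_10cm_five_tissue"
    fov_small_cm: float = 4.0
    slit_small_mm: float | None = 14.0   # explicit slit wins over FOV
    slit_large_mm: float | None = 42.0
    n_photons_per_view: int = 500_000
    n_photons_flat: int = 4_000_000
    seed: int = 0
    detector_model: str = "scintillator"
    # correction
    target_slit_mm: float = 2.7
    smoothing_window: int = 11
    smoothing_sigma: float = 5.0
    floor: float = 1e-3
    # reconstruction
    recon_nx: int = 128
    recon_nz: int = 1
    voxel_size_mm: float = 0.9
    filter_window: str = "ramlak"
    insert_roi_cm: float = 0.9
    # output
    out_dir: str = "cbct_run"
    save_format: str = "mha"

    def __post_init__(self):
        self.geometry()          # raises on invalid geometry
        self.spectrum()
        if self.phantom not in PHANTOM_PRESETS:
            raise ValueError(f"unknown phantom preset {self.phantom!r}")
        build_phantom(self.phantom)
        self.smoothing()
        if self.n_photons_per_view < 1 or self.n_photons_flat < 1:
            raise ValueError("photon budgets must be >= 1")
        if self.target_slit_mm <= 0:
            raise ValueError("extrapolation target slit must be positive")
        if min(self.recon_nx, self.recon_nz) < 1 or self.voxel_size_mm <= 0:
            raise ValueError("invalid reconstruction grid")
        if self.detector_model not in ("scintillator", "ideal"):
            raise ValueError("detector_model must be 'scintillator' or 'ideal'")
        if self.phantom not in PHANTOM_PRESETS:
            raise ValueError(f"unknown phantom preset {self.phantom!r}")

    def geometry(self) -> ScannerGeometry:
        kwargs = dict(sad=self.sad, sdd=self.sdd, det_rows=self.det_rows,
                      det_cols=self.det_cols, det_pitch_mm=self.det_pitch_mm,
                      n_views=self.n_views)
        if self.collimator_distance is not None:
            kwargs["collimator_distance"] = self.collimator_distance
        return ScannerGeometry(**kwargs)

    def spectrum(self):
        return build_spectrum(self.kvp, self.filtration_al_mm,
                              mode=self.spectrum_mode,
                              energy_kev=self.energy_kev)

    def smoothing(self) -> SmoothingConfig:
        return SmoothingConfig(window=self.smoothing_window,
                               sigma=self.smoothing_sigma)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
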