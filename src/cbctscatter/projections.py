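"""Projection stacks: per-view detector images with separable channels.

A :class:`ProjectionStack` carries up to three channels -- ``total``,
``primary`` and ``scatter`` -- as ``(n_views, det_rows, det_cols)`` arrays,
the gantry angles, and a metadata dictionary describing how the stack was
produced (geometry, collimation, phantom, photon budget, seed, per-photon
statistical weight).  Channel conservation ``total == primary + scatter``
holds exactly for simulated stacks.

Stacks round-trip to disk as one MetaImage (.mha) file per channel plus a
JSON sidecar, or as multi-page TIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CHANNELS = ("total", "primary", "scatter")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class ProjectionStack:
    channels: dict[str, np.ndarray]
    angles: np.ndarray                      # degrees, one per view
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        shape = next(iter(shapes.values()))
        if len(shape) != 3:
            raise ValueError("channels must be (n_views, rows, cols)")
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size != shape[0]:
            raise ValueError("one gantry angle per view required")
        for name, arr in self.channels.items():
            if np.any(arr < 0):
                raise ValueError(f"negative intensities in channel {name!r}")

    @property
    def n_views(self) -> int:
        return self.angles.size

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]

    @property
    def total(self) -> np.ndarray:
        return self.channels["total"]

    def has_channel(self, channel: str) -> bool:
        return channel in self.channels

    def check_conservation(self, rtol: float = 0.0, atol: float = 1e-9) -> bool:
        if not all(c in self.channels for c in CHANNELS):
            return True
        return np.allclose(self.channels["total"],
                           self.channels["primary"] + self.channels["scatter"],
                           rtol=rtol, atol=atol)

    def view(self, index: int, channel: str = "total") -> np.ndarray:
        return self.channels[channel][index]

    def copy_with(self, **new_channels: np.ndarray) -> "ProjectionStack":
        ch = dict(self.channels)
        ch.update(new_channels)
        return ProjectionStack(channels=ch, angles=self.angles.copy(),
                               meta=dict(self.meta))

    # ---------------------------------------------------------------- I/O
    def save(self, path_prefix: str | Path, fmt: str = "mha") -> list[Path]:
        """Write one volume file per channel plus a ``.json`` sidecar."""
        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for name, arr in self.channels.items():
            if fmt == "mha":
                import SimpleITK as sitk

                img = sitk.GetImageFromArray(np.ascontiguousarray(arr, np.float32))
                pitch = float(self.meta.get("det_pitch_mm", 1.0))
                img.SetSpacing((pitch, pitch, 1.0))
                out = prefix.with_name(f"{prefix.name}_{name}.mha")
                sitk.WriteImage(img, str(out))
            elif fmt == "tiff":
                import tifffile

                out = prefix.with_name(f"{prefix.name}_{name}.tiff")
                tifffile.imwrite(out, arr.astype(np.float32))
            else:
                raise ValueError("fmt must be 'mha' or 'tiff'")
            written.append(out)
        sidecar = prefix.with_name(f"{prefix.name}.json")
        sidecar.write_text(json.dumps(
            {"angles": self.angles.tolist(), "channels": list(self.channels),
             "format": fmt, "meta": _jsonable(self.meta)}, indent=2))
        written.append(sidecar)
        return written

    @classmethod
    def load(cls, path_prefix: str | Path) -> "ProjectionStack":
        prefix = Path(path_prefix)
        sidecar = json.loads(prefix.with_name(f"{prefix.name}.json").read_text())
        fmt = sidecar["format"]
        channels = {}
        for name in sidecar["channels"]:
            if fmt == "mha":
                import SimpleITK as sitk

                img = sitk.ReadImage(str(prefix.with_name(f"{prefix.name}_{name}.mha")))
                channels[name] = sitk.GetArrayFromImage(img).astype(np.float64)
            else:
                import tifffile

                channels[name] = tifffile.imread(
                    prefix.with_name(f"{prefix.name}_{name}.tiff")).astype(np.float64)
        return cls(channels=channels, angles=np.asarray(sidecar["angles"]),
                   meta=sidecar.get("meta", {}))


def photon_records_to_csv(records: np.ndarray, path: str | Path) -> Path:
    """Dump list-mode photon records (structured array) as CSV."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(records).to_csv(path, index=False)
    return path
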