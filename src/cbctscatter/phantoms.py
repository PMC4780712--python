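"""Digital cylindrical phantoms with tissue-equivalent rod inserts.

All phantoms are a water-filled cylinder (axis along z, centered on the
isocenter) holding 3-cm-diameter rod inserts.  Two preset families are
provided:

* ``mc_{10,15,20}cm_{muscle,bone,adipose,five_tissue}`` -- the twelve
  characterization layouts: water bodies of 10/15/20 cm diameter and 10 cm
  height with a single central rod (muscle, dense bone at 800 mg/cc, or
  adipose) or five rods (muscle, dense bone 800, adipose, trabecular bone,
  lung inhale).
* ``exp_10cm_setting1`` / ``exp_10cm_setting2`` -- the evaluation layouts:
  a 10 cm body with five of the ten tissue-equivalent plugs each; the bone
  plugs carry a 1-cm dense-bone core inside a soft-tissue-equivalent sheath.

Insert positions are not prescribed by the layouts' source; five-rod
presets place one rod at the center and four on a ring at 60% of the body
radius, single-rod presets use the center.  Positions are configurable via
an explicit :class:`PhantomSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import get_material

FIVE_TISSUE_MATERIALS = ("muscle", "dense_bone_800", "adipose",
                         "trabecular_bone", "lung_inhale")
EXP_SETTING1_MATERIALS = ("lung_inhale", "adipose", "breast", "muscle", "liver")
EXP_SETTING2_MATERIALS = ("lung_exhale", "trabecular_bone", "dense_bone_800",
                          "dense_bone_1250", "dense_bone_1750")
_BONE_CORE_MATERIALS = {"dense_bone_800", "dense_bone_1250", "dense_bone_1750"}


@dataclass(frozen=True)
class Insert:
    """A rod insert; ``core_*`` model a dense core inside a sheath."""

    center_xy: tuple[float, float]       # cm, axial plane
    diameter: float                      # cm
    height: float                        # cm
    material: str
    core_diameter: float | None = None   # cm
    core_material: str | None = None

    def __post_init__(self):
        if self.diameter <= 0 or self.height <= 0:
            raise ValueError("insert dimensions must be positive")
        get_material(self.material)
        if (self.core_diameter is None) != (self.core_material is None):
            raise ValueError("core diameter and material go together")
        if self.core_diameter is not None:
            if not 0 < self.core_diameter < self.diameter:
                raise ValueError("core must be smaller than its sheath")
            get_material(self.core_material)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical water body plus rod inserts."""

    body_diameter: float                 # cm
    body_height: float = 10.0            # cm
    body_material: str = "water"
    inserts: tuple[Insert, ...] = field(default_factory=tuple)
    name: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "inserts", tuple(self.inserts))
        if self.body_diameter <= 0 or self.body_height <= 0:
            raise ValueError("body dimensions must be positive")
        get_material(self.body_material)
        r_body = self.body_diameter / 2.0
        tol = 1e-9
        for i, ins in enumerate(self.inserts):
            d = float(np.hypot(*ins.center_xy))
            if d + ins.radius > r_body + tol:
                raise ValueError(f"insert {i} ({ins.material}) extends outside the body")
            if ins.height > self.body_height + tol:
                raise ValueError(f"insert {i} ({ins.material}) taller than the body")
        for i in range(len(self.inserts)):
            for j in range(i + 1, len(self.inserts)):
                a, b = self.inserts[i], self.inserts[j]
                gap = float(np.hypot(a.center_xy[0] - b.center_xy[0],
                                     a.center_xy[1] - b.center_xy[1]))
                if gap < a.radius + b.radius - tol:
                    raise ValueError(
                        f"inserts {i} ({a.material}) and {j} ({b.material}) overlap")

    @property
    def body_radius(self) -> float:
        return self.body_diameter / 2.0

    def material_names(self) -> list[str]:
        names = [self.body_material]
        for ins in self.inserts:
            for m in (ins.material, ins.core_material):
                if m and m not in names:
                    names.append(m)
        return names

    def material_at(self, x: float, y: float, z: float) -> str | None:
        """Material name at a point, or None outside the body (innermost wins)."""
        if abs(z) > self.body_height / 2.0:
            return None
        if x * x + y * y > self.body_radius**2:
            return None
        for ins in self.inserts:
            if abs(z) > ins.height / 2.0:
                continue
            dx, dy = x - ins.center_xy[0], y - ins.center_xy[1]
            rr = dx * dx + dy * dy
            if rr <= ins.radius**2:
                if ins.core_diameter is not None and rr <= (ins.core_diameter / 2) ** 2:
                    return ins.core_material
                return ins.material
        return self.body_material


def _ring_positions(n_ring: int, ring_radius: float,
                    central: bool) -> list[tuple[float, float]]:
    pos: list[tuple[float, float]] = [(0.0, 0.0)] if central else []
    for k in range(n_ring):
        ang = 2.0 * np.pi * k / n_ring
        pos.append((ring_radius * np.cos(ang), ring_radius * np.sin(ang)))
    return pos


def _rod_layout(body_diameter: float, materials: tuple[str, ...],
                height: float, with_cores: bool) -> tuple[Insert, ...]:
    n = len(materials)
    if n == 1:
        positions = [(0.0, 0.0)]
    else:
        positions = _ring_positions(n - 1, 0.6 * body_diameter / 2.0, central=True)
    inserts = []
    for (x, y), mat in zip(positions, materials):
        core_d = core_m = None
        if with_cores and mat in _BONE_CORE_MATERIALS:
            # bone plug: 1 cm dense-bone core in a soft-tissue-equivalent sheath
            core_d, core_m = 1.0, mat
            mat = "muscle"
        inserts.append(Insert(center_xy=(x, y), diameter=3.0, height=height,
                              material=mat, core_diameter=core_d,
                              core_material=core_m))
    return tuple(inserts)


def _build_presets() -> dict[str, PhantomSpec]:
    presets: dict[str, PhantomSpec] = {}
    single = {"muscle": ("muscle",), "bone": ("dense_bone_800",),
              "adipose": ("adipose",)}
    for d in (10, 15, 20):
        for key, mats in single.items():
            name = f"mc_{d}cm_{key}"
            presets[name] = PhantomSpec(
                body_diameter=float(d), body_height=10.0, name=name,
                inserts=_rod_layout(float(d), mats, height=10.0, with_cores=False))
        name = f"mc_{d}cm_five_tissue"
        presets[name] = PhantomSpec(
            body_diameter=float(d), body_height=10.0, name=name,
            inserts=_rod_layout(float(d), FIVE_TISSUE_MATERIALS,
                                height=10.0, with_cores=False))
    for idx, mats in ((1, EXP_SETTING1_MATERIALS), (2, EXP_SETTING2_MATERIALS)):
        name = f"exp_10cm_setting{idx}"
        presets[name] = PhantomSpec(
            body_diameter=10.0, body_height=10.0, name=name,
            inserts=_rod_layout(10.0, mats, height=5.0, with_cores=True))
    presets["water_10cm"] = PhantomSpec(body_diameter=10.0, name="water_10cm")
    presets["water_15cm"] = PhantomSpec(body_diameter=15.0, name="water_15cm")
    presets["water_20cm"] = PhantomSpec(body_diameter=20.0, name="water_20cm")
    presets["air_10cm"] = PhantomSpec(body_diameter=10.0, body_material="air",
                                      name="air_10cm")
    return presets


PHANTOM_PRESETS: dict[str, PhantomSpec] = _build_presets()

MC_LAYOUTS = ("muscle", "bone", "adipose", "five_tissue")
MC_DIAMETERS = (10.0, 15.0, 20.0)


def build_phantom(preset: str | PhantomSpec) -> PhantomSpec:
    """Return a preset phantom by name, or validate an explicit spec."""
    if isinstance(preset, PhantomSpec):
        return preset
    try:
        return PHANTOM_PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown phantom preset {preset!r}; known: "
            f"{', '.join(sorted(PHANTOM_PRESETS))}") from None
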