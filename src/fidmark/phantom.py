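"""Declarative phantom geometry and voxelization.

The study phantom is a 30 x 31 x 15 cm block of near-tissue-equivalent
bolus built from 2 cm layers, with three cylindrical fiducial markers of
each material (gold 0.9 x 3 mm, carbon 1 x 3 mm, polymer 1 x 5 mm)
embedded in the central layer about 5 cm apart.

Coordinates are right-handed, in mm, with the origin at the phantom corner;
a voxel's position is its center; voxel indices are 0-based.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import DomainError, GeometryError
from .materials import MaterialTable, default_materials

__all__ = ["MarkerSpec", "PhantomSpec", "MaterialVolume", "default_study_phantom", "voxelize"]


@dataclass(frozen=True)
class MarkerSpec:
    """A cylindrical fiducial marker.

    ``center`` is in mm (phantom frame), ``axis`` is a unit vector along the
    cylinder axis, ``diameter`` and ``length`` are in mm.
    """

    material: str
    diameter: float
    length: float
    center: tuple[float, float, float]
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise DomainError("marker diameter and length must be positive")
        a = np.asarray(self.axis, dtype=float)
        n = float(np.linalg.norm(a))
        if n == 0:
            raise DomainError("marker axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(a / n))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (N, 3) [mm] inside the finite cylinder."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center)
        axis = np.asarray(self.axis)
        t = p @ axis
        radial2 = np.einsum("ij,ij->i", p, p) - t**2
        return (np.abs(t) <= self.length / 2.0) & (radial2 <= (self.diameter / 2.0) ** 2)


@dataclass(frozen=True)
class PhantomSpec:
    """Rectangular uniform phantom with embedded markers.

    ``extent_cm`` is (x, y, z) in cm; ``layer_thickness_cm`` records the
    bolus layer structure (geometric bookkeeping only -- the material is
    uniform); ``markers`` are :class:`MarkerSpec` in mm coordinates.
    """

    extent_cm: tuple[float, float, float]
    layer_thickness_cm: float = 2.0
    background_material: str = "soft_tissue"
    markers: tuple[MarkerSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent_cm) or self.layer_thickness_cm <= 0:
            raise DomainError("phantom extents and layer thickness must be positive")
        object.__setattr__(self, "markers", tuple(self.markers))
        ext = self.extent_mm
        for m in self.markers:
            if not all(0 <= c <= e for c, e in zip(m.center, ext)):
                raise GeometryError(f"marker center {m.center} outside phantom extent {ext} mm")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(10.0 * e for e in self.extent_cm)

    def markers_of(self, material: str) -> tuple[MarkerSpec, ...]:
        return tuple(m for m in self.markers if m.material == material)

    def to_toml(self, path: str | Path) -> None:
        lines = [
            f"extent_cm = [{', '.join(repr(float(e)) for e in self.extent_cm)}]",
            f"layer_thickness_cm = {float(self.layer_thickness_cm)!r}",
            f'background_material = "{self.background_material}"',
            "",
        ]
        for m in self.markers:
            lines += [
                "[[markers]]",
                f'material = "{m.material}"',
                f"diameter = {float(m.diameter)!r}",
                f"length = {float(m.length)!r}",
                f"center = [{', '.join(repr(float(c)) for c in m.center)}]",
                f"axis = [{', '.join(repr(float(a)) for a in m.axis)}]",
                "",
            ]
        Path(path).write_text("\n".join(lines))

    @classmethod
    def from_toml(cls, path: str | Path) -> "PhantomSpec":
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        markers = tuple(
            MarkerSpec(
                material=m["material"],
                diameter=m["diameter"],
                length=m["length"],
                center=tuple(m["center"]),
                axis=tuple(m.get("axis", (1.0, 0.0, 0.0))),
            )
            for m in cfg.get("markers", [])
        )
        return cls(
            extent_cm=tuple(cfg["extent_cm"]),
            layer_thickness_cm=cfg.get("layer_thickness_cm", 2.0),
            background_material=cfg.get("background_material", "soft_tissue"),
            markers=markers,
        )


# Marker dimensions (diameter, length) in mm per material.
MARKER_DIMENSIONS_MM: dict[str, tuple[float, float]] = {
    "gold": (0.9, 3.0),
    "carbon": (1.0, 3.0),
    "polymer": (1.0, 5.0),
}


def default_study_phantom() -> PhantomSpec:
    """The study phantom: 30 x 31 x 15 cm bolus block, nine markers on a
    3 x 3 grid (one row per material) spaced 5 cm apart in the central layer,
    marker axes in the slice plane (along +x)."""
    extent = (30.0, 31.0, 15.0)
    cx, cy, cz = 150.0, 155.0, 75.0
    rows = ("gold", "carbon", "polymer")
    markers = []
    for iy, material in enumerate(rows):
        d, length = MARKER_DIMENSIONS_MM[material]
        y = cy + (iy - 1) * 50.0
        for ix in range(3):
            x = cx + (ix - 1) * 50.0
            markers.append(MarkerSpec(material, d, length, (x, y, cz), (1.0, 0.0, 0.0)))
    return PhantomSpec(extent_cm=extent, layer_thickness_cm=2.0, markers=tuple(markers))


@dataclass(frozen=True)
class MaterialVolume:
    """Voxelized material-label grid.

    ``labels`` is an int array indexed [ix, iy, iz]; ``names`` maps label
    values to material names; ``voxel_size`` is (dx, dy, dz) mm; ``origin``
    is the phantom-frame position [mm] of the corner of voxel (0, 0, 0)
    (so the center of voxel i is ``origin + (i + 0.5) * voxel_size``).
    """

    labels: np.ndarray
    names: tuple[str, ...]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise DomainError("voxel sizes must be positive")

    def material_mask(self, name: str) -> np.ndarray:
        if name not in self.names:
            raise GeometryError(f"material {name!r} not present in volume")
        return self.labels == self.names.index(name)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = []
        for n, dv, o in zip(self.labels.shape, self.voxel_size, self.origin):
            axes.append(o + (np.arange(n) + 0.5) * dv)
        return tuple(axes)

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.voxel_size) + [1.0])
        affine[:3, 3] = np.asarray(self.origin) + 0.5 * np.asarray(self.voxel_size)
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))


def voxelize(
    spec: PhantomSpec,
    voxel_size: float | tuple[float, float, float],
    materials: MaterialTable | None = None,
) -> MaterialVolume:
    """Voxelize a phantom: a voxel gets a marker's material iff its center
    lies inside that marker's cylinder, else the background material.

    Requires the in-plane voxel size to resolve the smallest marker
    (voxel_size <= diameter / 2).
    """
    if np.isscalar(voxel_size):
        vs = (float(voxel_size),) * 3
    else:
        vs = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in vs):
        raise DomainError("voxel size must be positive")
    if spec.markers:
        dmin = min(m.diameter for m in spec.markers)
        if max(vs) > dmin / 2.0 + 1e-12:
            worst = min(spec.markers, key=lambda m: m.diameter)
            raise DomainError(
                f"voxel size {max(vs)} mm too coarse to resolve the {worst.material} "
                f"marker (diameter {worst.diameter} mm); need <= {dmin / 2.0} mm"
            )
    table = materials or default_materials()
    for m in spec.markers:
        table[m.material]  # raises MaterialLookupError if unknown
    table[spec.background_material]

    ext = spec.extent_mm
    shape = tuple(int(np.ceil(e / v)) for e, v in zip(ext, vs))
    names = [spec.background_material] + sorted({m.material for m in spec.markers})
    labels = np.zeros(shape, dtype=np.int16)
    xs = (np.arange(shape[0]) + 0.5) * vs[0]
    ys = (np.arange(shape[1]) + 0.5) * vs[1]
    zs = (np.arange(shape[2]) + 0.5) * vs[2]
    for m in spec.markers:
        # restrict the membership test to the marker's bounding box
        half = m.length / 2.0 + m.diameter / 2.0
        sel = []
        for axis_vals, c in zip((xs, ys, zs), m.center):
            idx = np.nonzero(np.abs(axis_vals - c) <= half + max(vs))[0]
            sel.append(idx)
        if any(idx.size == 0 for idx in sel):
            continue
        gx, gy, gz = np.meshgrid(xs[sel[0]], ys[sel[1]], zs[sel[2]], indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        inside = m.contains(pts).reshape(gx.shape)
        lab = names.index(m.material)
        sub = labels[np.ix_(sel[0], sel[1], sel[2])]
        sub[inside] = lab
        labels[np.ix_(sel[0], sel[1], sel[2])] = sub
    return MaterialVolume(labels=labels, names=tuple(names), voxel_size=vs)
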