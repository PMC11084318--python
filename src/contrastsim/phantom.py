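"""Geometric phantoms: slabs and disk (finite-cylinder) inserts.

Two phantoms are modelled.  The simulation phantom is a 45 mm Plexiglas slab
holding 14 contrast-filled disks of radius 10 mm whose thicknesses are
linearly spaced from 0.2 to 2.6 mm (breast-equivalent block with iodinated
inserts).  The well-plate phantom is a thin polystyrene base carrying two rows
of liquid columns, one row per contrast agent, with column heights set by the
filled volume.

Coordinate convention: the beam axis is +z with the point source at the
origin; the phantom entrance face sits at ``z = z0`` (the source-to-object
distance).  All lengths are millimetres.  Disk axes are parallel to the beam
axis, so ray/primitive intersections have closed forms: a slab is an
axis-aligned box and a disk a z-aligned finite cylinder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .materials import (
    Solution,
    naditmb,
    iohexol,
    pmma_solid,
    polystyrene_solid,
    solution_for_iodine_concentration,
)

__all__ = [
    "SlabPrimitive",
    "DiskPrimitive",
    "PhantomSpec",
    "LayoutError",
    "build_simulation_phantom",
    "build_wellplate_phantom",
    "path_length",
    "contrast_solutions",
]


class LayoutError(ValueError):
    """Raised when primitives cannot be placed without overlap."""


@dataclass(frozen=True)
class SlabPrimitive:
    """Axis-aligned box: lateral extent (x, y) centered on ``center_xy``."""

    thickness: float  # mm, along z
    lateral_extent: Tuple[float, float]  # mm (x width, y height)
    z0: float  # entrance face, mm from source
    material: Solution
    center_xy: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("slab thickness must be positive")

    @property
    def z1(self) -> float:
        return self.z0 + self.thickness


@dataclass(frozen=True)
class DiskPrimitive:
    """Finite cylinder with axis parallel to z."""

    center: Tuple[float, float, float]  # mm; z is the cylinder mid-plane
    radius: float  # mm
    thickness: float  # mm along z
    material: Solution
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.thickness <= 0:
            raise ValueError("disk radius and thickness must be positive")

    @property
    def z0(self) -> float:
        return self.center[2] - self.thickness / 2.0

    @property
    def z1(self) -> float:
        return self.center[2] + self.thickness / 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Ordered primitives: slabs first, then disks.

    A disk whose volume lies inside a slab *replaces* the slab material there
    (attenuation bookkeeping subtracts the disk chord from the slab chord);
    free-standing disks (well-plate liquid columns) simply add material.
    """

    slabs: Tuple[SlabPrimitive, ...]
    disks: Tuple[DiskPrimitive, ...]
    name: str = ""

    def __post_init__(self) -> None:
        for i, a in enumerate(self.disks):
            for b in self.disks[i + 1:]:
                z_overlap = min(a.z1, b.z1) - max(a.z0, b.z0)
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if z_overlap > 0 and d < a.radius + b.radius:
                    raise LayoutError(f"disks {a.label!r} and {b.label!r} overlap")
        for d in self.disks:
            slab = self.embedding_slab(d)
            if slab is not None:
                ex, ey = slab.lateral_extent
                cx, cy = slab.center_xy
                if (abs(d.center[0] - cx) + d.radius > ex / 2
                        or abs(d.center[1] - cy) + d.radius > ey / 2):
                    raise LayoutError(f"disk {d.label!r} extends outside its slab")

    def embedding_slab(self, disk: DiskPrimitive) -> Optional[SlabPrimitive]:
        """The slab whose z-range contains the disk, if any."""
        for s in self.slabs:
            if s.z0 - 1e-9 <= disk.z0 and disk.z1 <= s.z1 + 1e-9:
                return s
        return None

    @property
    def primitives(self):
        return list(self.slabs) + list(self.disks)


def _normalize(direction: np.ndarray) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d, axis=-1, keepdims=True)
    return d / n


def _box_chords(origins, directions, slab: SlabPrimitive) -> np.ndarray:
    """Vectorized ray/box intersection lengths (mm)."""
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(_normalize(directions))
    ex, ey = slab.lateral_extent
    cx, cy = slab.center_xy
    lo = np.array([cx - ex / 2, cy - ey / 2, slab.z0])
    hi = np.array([cx + ex / 2, cy + ey / 2, slab.z1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - o) / d
        t2 = (hi - o) / d
    # rays parallel to a face: inside -> (-inf, inf), outside -> empty
    inside = (o >= lo) & (o <= hi)
    parallel = d == 0
    t1 = np.where(parallel, np.where(inside, -np.inf, np.inf), t1)
    t2 = np.where(parallel, np.where(inside, np.inf, -np.inf), t2)
    t_near = np.minimum(t1, t2).max(axis=-1)
    t_far = np.maximum(t1, t2).min(axis=-1)
    return np.maximum(t_far - np.maximum(t_near, 0.0), 0.0)


def _cylinder_chords(origins, directions, disk: DiskPrimitive) -> np.ndarray:
    """Vectorized ray/finite-cylinder (z-axis) intersection lengths (mm)."""
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(_normalize(directions))
    cx, cy, _ = disk.center
    ox, oy, oz = o[..., 0] - cx, o[..., 1] - cy, o[..., 2]
    dx, dy, dz = d[..., 0], d[..., 1], d[..., 2]
    a = dx * dx + dy * dy
    b = 2.0 * (ox * dx + oy * dy)
    c = ox * ox + oy * oy - disk.radius**2
    t_lo = np.full(ox.shape, -np.inf)
    t_hi = np.full(ox.shape, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = b * b - 4 * a * c
        sq = np.sqrt(np.maximum(disc, 0.0))
        q1 = (-b - sq) / (2 * a)
        q2 = (-b + sq) / (2 * a)
    quad = a > 1e-30
    miss = quad & (disc < 0)
    t_lo = np.where(quad, q1, t_lo)
    t_hi = np.where(quad, q2, t_hi)
    # a == 0: ray parallel to axis; inside radius iff c <= 0
    axis_out = ~quad & (c > 0)
    # z caps
    with np.errstate(divide="ignore", invalid="ignore"):
        tz1 = (disk.z0 - oz) / dz
        tz2 = (disk.z1 - oz) / dz
    z_par = dz == 0
    z_in = (oz >= disk.z0) & (oz <= disk.z1)
    tz_lo = np.where(z_par, np.where(z_in, -np.inf, np.inf), np.minimum(tz1, tz2))
    tz_hi = np.where(z_par, np.where(z_in, np.inf, -np.inf), np.maximum(tz1, tz2))
    t_near = np.maximum(t_lo, tz_lo)
    t_far = np.minimum(t_hi, tz_hi)
    length = np.maximum(t_far - np.maximum(t_near, 0.0), 0.0)
    return np.where(miss | axis_out, 0.0, length)


def path_length(origin, direction, primitive) -> float:
    """Exact intersection length (mm) of one ray with one primitive.

    ``direction`` need not be normalized (it is normalized internally); a ray
    that misses returns 0.
    """
    if isinstance(primitive, SlabPrimitive):
        out = _box_chords(origin, direction, primitive)
    elif isinstance(primitive, DiskPrimitive):
        out = _cylinder_chords(origin, direction, primitive)
    else:
        raise TypeError(f"unsupported primitive {type(primitive).__name__}")
    return float(np.asarray(out).reshape(-1)[0])


def primitive_chords(origins, directions, primitive) -> np.ndarray:
    """Vectorized :func:`path_length` over arrays of rays."""
    if isinstance(primitive, SlabPrimitive):
        return _box_chords(origins, directions, primitive)
    if isinstance(primitive, DiskPrimitive):
        return _cylinder_chords(origins, directions, primitive)
    raise TypeError(f"unsupported primitive {type(primitive).__name__}")


def contrast_solutions(iodine_mg_per_ml: float = 23.35,
                       density: float = 1.0) -> Tuple[Solution, Solution]:
    """(NaDITMB solution, iohexol solution) at matched iodine concentration."""
    a = solution_for_iodine_concentration(naditmb(), iodine_mg_per_ml, density,
                                          label="NaDITMB")
    b = solution_for_iodine_concentration(iohexol(), iodine_mg_per_ml, density,
                                          label="Omnipaque")
    return a, b


def build_simulation_phantom(
    contrast: Solution,
    slab_thickness: float = 45.0,
    slab_extent: Tuple[float, float] = (200.0, 200.0),
    slab_material: Optional[Solution] = None,
    disk_radius: float = 10.0,
    disk_count: int = 14,
    thickness_range: Tuple[float, float] = (0.2, 2.6),
    z0: float = 1000.0,
    columns: int = 2,
    gap: float = 5.0,
    name: str = "",
) -> PhantomSpec:
    """Plexiglas slab with contrast disks on a grid, thicknesses linearly spaced.

    Disks are laid out column-major on a ``columns x ceil(count/columns)`` grid
    with ``gap`` mm between footprints and are centered in slab depth.
    """
    slab = SlabPrimitive(slab_thickness, slab_extent, z0,
                         slab_material or pmma_solid())
    rows = -(-disk_count // columns)
    pitch = 2 * disk_radius + gap
    thicknesses = np.linspace(thickness_range[0], thickness_range[1], disk_count)
    z_mid = z0 + slab_thickness / 2.0
    disks: List[DiskPrimitive] = []
    for i, t in enumerate(thicknesses):
        col, row = divmod(i, rows)
        x = (col - (columns - 1) / 2.0) * pitch
        y = (row - (rows - 1) / 2.0) * pitch
        if max(abs(x), abs(y)) + disk_radius > max(slab_extent) / 2:
            raise LayoutError("disk grid does not fit inside the slab")
        if t > slab_thickness:
            raise LayoutError("disk thicker than the slab")
        disks.append(DiskPrimitive((x, y, z_mid), disk_radius, float(t),
                                   contrast, label=f"disk{i + 1:02d}_t{t:.2f}mm"))
    return PhantomSpec((slab,), tuple(disks), name=name or "simulation-phantom")


def build_wellplate_phantom(
    row_a_material: Optional[Solution] = None,
    row_b_material: Optional[Solution] = None,
    volumes_ml: Sequence[float] = (0.2, 0.2, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1),
    well_diameter: float = 6.4,
    well_depth: float = 10.9,
    well_pitch: float = 9.0,
    base_thickness: float = 1.0,
    base_extent: Tuple[float, float] = (130.0, 40.0),
    base_material: Optional[Solution] = None,
    z0: float = 1000.0,
    iodine_mg_per_ml: float = 23.35,
    density: float = 1.04,
    name: str = "",
) -> PhantomSpec:
    """Two rows of contrast-filled wells on a thin plastic base.

    Row A holds the candidate agent (NaDITMB), row B the reference agent
    (Omnipaque/iohexol); both at the same per-cavity iodine concentration.
    Cavity volumes follow the study layout: cavities 1-3 hold 0.2 mL, 4-8 hold
    0.1 mL.  Liquid column height is ``V / (pi r^2)``.
    """
    if row_a_material is None or row_b_material is None:
        sol_a, sol_b = contrast_solutions(iodine_mg_per_ml, density)
        row_a_material = row_a_material or sol_a
        row_b_material = row_b_material or sol_b
    base = SlabPrimitive(base_thickness, base_extent, z0,
                         base_material or polystyrene_solid())
    r = well_diameter / 2.0
    n = len(volumes_ml)
    disks: List[DiskPrimitive] = []
    for row_idx, (material, row_name) in enumerate(
            [(row_a_material, "A"), (row_b_material, "B")]):
        y = (0.5 - row_idx) * well_pitch
        for i, v_ml in enumerate(volumes_ml):
            height = (v_ml * 1000.0) / (np.pi * r * r)  # mm
            if height > well_depth:
                raise LayoutError(
                    f"volume {v_ml} mL implies column height {height:.2f} mm "
                    f"exceeding well depth {well_depth} mm")
            x = (i - (n - 1) / 2.0) * well_pitch
            disks.append(DiskPrimitive(
                (x, y, z0 + base_thickness + height / 2.0), r, float(height),
                material, label=f"{row_name}{i + 1}"))
    return PhantomSpec((base,), tuple(disks), name=name or "well-plate")
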