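"""Slice-wise segmentation contours and contour stacks.

A muscle segmented in transverse MR images is represented as a
:class:`ContourStack`: for each imaging slice (axial position ``z`` in
millimetres along the shank axis, increasing distal to proximal) one or
more boundary polygons in the slice plane.  Outer polygons enclose muscle
tissue; ``hole`` polygons mark excluded interior regions (vessels,
aponeuroses) and are subtracted when cross-sectional areas are computed.

All coordinates are physical millimetres.  The shank reference frame runs
from the calcaneal tuberosity (``z_distal``, 0 % shank length) to the
tibial plateau (``z_proximal``, 100 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely.geometry as sgeom

from .errors import DegenerateGeometryError, ValidationError

__all__ = ["Contour", "ContourStack", "signed_polygon_area"]

#: slices may extend this far beyond the shank landmarks (mm); the
#: gastrocnemii originate on the femoral condyles above the tibial plateau.
DEFAULT_LANDMARK_TOLERANCE_MM = 80.0

_AREA_EPS_MM2 = 1e-9


def signed_polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (positive = counter-clockwise)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise DegenerateGeometryError(
            f"polygon needs >=3 planar vertices, got shape {v.shape}"
        )
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Contour:
    """One boundary polygon in a transverse slice.

    Parameters
    ----------
    z : float
        Axial position of the slice, mm.
    vertices : (n, 2) array
        Ordered planar vertex coordinates, mm.  Stored counter-clockwise
        after :meth:`normalized`.
    role : {"outer", "hole"}
        Whether the polygon bounds muscle tissue or an excluded interior
        region.
    """

    z: float
    vertices: np.ndarray
    role: str = "outer"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.role not in ("outer", "hole"):
            raise ValidationError(f"contour role must be 'outer' or 'hole', got {self.role!r}")

    @property
    def area(self) -> float:
        """Absolute enclosed area, mm^2."""
        return abs(signed_polygon_area(self.vertices))

    def is_ccw(self) -> bool:
        return signed_polygon_area(self.vertices) > 0

    def normalized(self) -> "Contour":
        """Return a copy with counter-clockwise vertex winding."""
        if self.is_ccw():
            return replace(self)
        return replace(self, vertices=self.vertices[::-1].copy())

    def validate(self, check_simple: bool = True) -> None:
        """Raise :class:`ValidationError` on degenerate or self-intersecting polygons."""
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError(f"contour at z={self.z}: vertices must be (n, 2)")
        if len(self.vertices) < 3:
            raise ValidationError(
                f"contour at z={self.z}: polygon has {len(self.vertices)} vertices (<3)"
            )
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError(f"contour at z={self.z}: non-finite vertex coordinates")
        if abs(signed_polygon_area(self.vertices)) <= _AREA_EPS_MM2:
            raise DegenerateGeometryError(
                f"contour at z={self.z}: degenerate polygon with (near-)zero area"
            )
        if check_simple:
            # self-intersection is rejected, not repaired: silent repair could
            # corrupt areas
            ring = sgeom.LinearRing(self.vertices)
            if not ring.is_simple:
                raise ValidationError(
                    f"contour at z={self.z}: self-intersecting polygon"
                )


@dataclass
class ContourStack:
    """All segmentation contours of one muscle of one subject.

    ``slice_positions`` is the strictly increasing grid of segmented slice
    positions; every contour's ``z`` must equal one of them.
    ``shank_landmarks`` is ``(z_distal, z_proximal)``: calcaneal tuberosity
    and tibial plateau, mm.
    """

    muscle_label: str
    contours: list[Contour]
    slice_positions: np.ndarray
    shank_landmarks: tuple[float, float] | None = None
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)

    def contours_at(self, z: float) -> list[Contour]:
        return [c for c in self.contours if c.z == z]

    def normalized(self) -> "ContourStack":
        """Copy with all contours wound counter-clockwise and slices sorted."""
        order = np.argsort(self.slice_positions)
        return replace(
            self,
            contours=sorted((c.normalized() for c in self.contours), key=lambda c: c.z),
            slice_positions=self.slice_positions[order],
        )

    def validate(
        self,
        check_simple: bool = True,
        landmark_tolerance_mm: float = DEFAULT_LANDMARK_TOLERANCE_MM,
    ) -> None:
        z = self.slice_positions
        if z.size < 1:
            raise ValidationError("stack has no slices")
        if not np.all(np.diff(z) > 0):
            raise ValidationError("slice positions must be strictly increasing")
        zset = set(z.tolist())
        by_slice: dict[float, list[Contour]] = {}
        for c in self.contours:
            c.validate(check_simple=check_simple)
            if c.z not in zset:
                raise ValidationError(
                    f"contour at z={c.z} does not match any slice position"
                )
            by_slice.setdefault(c.z, []).append(c)
        for zi, group in by_slice.items():
            if not any(c.role == "outer" for c in group):
                raise ValidationError(f"slice z={zi}: hole contour without outer contour")
        if check_simple:
            self._validate_hole_containment(by_slice)
        if self.shank_landmarks is not None:
            zd, zp = self.shank_landmarks
            if not zp > zd:
                raise ValidationError(
                    f"shank landmarks must satisfy z_proximal > z_distal, got {zd}, {zp}"
                )
            if z[0] < zd - landmark_tolerance_mm or z[-1] > zp + landmark_tolerance_mm:
                raise ValidationError(
                    "muscle slices extend beyond the shank landmarks by more than "
                    f"{landmark_tolerance_mm} mm"
                )

    def _validate_hole_containment(self, by_slice: dict[float, list["Contour"]]) -> None:
        for zi, group in by_slice.items():
            holes = [c for c in group if c.role == "hole"]
            if not holes:
                continue
            outers = [sgeom.Polygon(c.vertices) for c in group if c.role == "outer"]
            for c in holes:
                poly = sgeom.Polygon(c.vertices)
                if not any(o.contains(poly.representative_point()) for o in outers):
                    raise ValidationError(
                        f"slice z={zi}: hole contour lies outside every outer contour"
                    )
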