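"""From contour stacks to measured muscle morphology.

The measured quantities mirror a slice-wise MRI volumetry workflow:

* the anatomical cross-sectional area (ACSA) of every segmented slice is the
  summed area of its outer contours minus any hole areas;
* muscle length ``L`` is the axial distance between the two marginal slices;
* measured volume ``V`` is the trapezoidal integral of the ACSA profile
  along the muscle;
* the shape factor ``p = V / (ACSA_max * L)`` is the mean-to-max ratio of
  the ACSA profile and is dimensionless (1 for a cylinder, 1/3 for a cone,
  2/3 for a spheroid);
* the location of ACSA_max is reported in percent of shank length measured
  from the calcaneal tuberosity (0 %) to the tibial plateau (100 %).

Internal unit is millimetres; morphology scalars are reported in
cm / cm^2 / cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import ContourStack, signed_polygon_area
from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "ACSAProfile",
    "MuscleMorphology",
    "polygon_area",
    "acsa_profile",
    "muscle_length",
    "integrate_volume",
    "find_acsa_max",
    "measure_morphology",
]

MM2_PER_CM2 = 100.0
MM3_PER_CM3 = 1000.0
MM_PER_CM = 10.0


@dataclass
class ACSAProfile:
    """Sampled cross-sectional area profile of one muscle.

    ``z`` (mm, strictly increasing) and ``acsa`` (mm^2, >= 0) have equal
    length; ``shank_landmarks`` is carried through from the stack.
    """

    z: np.ndarray
    acsa: np.ndarray
    shank_landmarks: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.acsa = np.asarray(self.acsa, dtype=float)
        if self.z.shape != self.acsa.shape or self.z.ndim != 1:
            raise ValidationError("z and acsa must be 1-D arrays of equal length")
        if self.z.size and not np.all(np.diff(self.z) > 0):
            raise ValidationError("profile z must be strictly increasing")
        if np.any(self.acsa < 0):
            raise ValidationError("ACSA must be non-negative everywhere")


@dataclass
class MuscleMorphology:
    """Measured per-muscle morphology scalars (cm-based units)."""

    subject_id: str
    muscle_label: str
    l_muscle_cm: float
    acsa_max_cm2: float
    acsa_max_position_pct_shank: float
    v_measured_cm3: float
    shape_factor: float

    def validate(self) -> None:
        for name in ("l_muscle_cm", "acsa_max_cm2", "v_measured_cm3", "shape_factor"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.acsa_max_position_pct_shank <= 100.0:
            raise ValidationError("acsa_max_position_pct_shank must lie in [0, 100]")
        if self.shape_factor > 1.0 + 1e-9:
            raise ValidationError("shape_factor cannot exceed 1 (mean ACSA <= max ACSA)")


def polygon_area(vertices) -> float:
    """Absolute area of a simple polygon by the shoelace formula, mm^2.

    Orientation-independent.  Raises :class:`DegenerateGeometryError` for
    fewer than 3 vertices or a numerically zero area.
    """
    a = abs(signed_polygon_area(np.asarray(vertices, dtype=float)))
    if a <= 1e-12:
        raise DegenerateGeometryError("degenerate polygon: zero area")
    return a


def acsa_profile(stack: ContourStack) -> ACSAProfile:
    """Per-slice ACSA: sum of outer contour areas minus hole areas."""
    z = np.asarray(stack.slice_positions, dtype=float)
    outer = dict.fromkeys(z.tolist(), 0.0)
    hole = dict.fromkeys(z.tolist(), 0.0)
    for c in stack.contours:
        (outer if c.role == "outer" else hole)[c.z] += c.area
    acsa = np.empty_like(z)
    for i, zi in enumerate(z.tolist()):
        if hole[zi] > outer[zi]:
            raise ValidationError(
                f"slice z={zi}: hole area {hole[zi]:.3f} exceeds outer area {outer[zi]:.3f}"
            )
        acsa[i] = outer[zi] - hole[zi]
    return ACSAProfile(z=z, acsa=acsa, shank_landmarks=stack.shank_landmarks)


def muscle_length(profile: ACSAProfile) -> float:
    """Axial distance between the two marginal slices, cm."""
    if profile.z.size < 2:
        raise ValidationError("muscle length needs at least 2 slices")
    return float(profile.z[-1] - profile.z[0]) / MM_PER_CM


def integrate_volume(profile: ACSAProfile) -> float:
    """Composite trapezoidal integral of ACSA over z, cm^3."""
    if profile.z.size < 2:
        raise ValidationError("volume integration needs at least 2 slices")
    return float(np.trapezoid(profile.acsa, profile.z)) / MM3_PER_CM3


def find_acsa_max(profile: ACSAProfile) -> tuple[float, float]:
    """Maximum sampled ACSA (cm^2) and its shank-relative position (%).

    Position is ``100 * (z_peak - z_distal) / (z_proximal - z_distal)``;
    ties resolve to the most distal tied slice.
    """
    if profile.shank_landmarks is None:
        raise ValidationError("shank landmarks required to locate ACSA_max")
    if profile.z.size == 0:
        raise ValidationError("empty profile")
    i = int(np.argmax(profile.acsa))  # argmax -> first (most distal) tied slice
    zd, zp = profile.shank_landmarks
    pos = 100.0 * (profile.z[i] - zd) / (zp - zd)
    return float(profile.acsa[i]) / MM2_PER_CM2, float(pos)


def measure_morphology(stack: ContourStack, validate: bool = True) -> MuscleMorphology:
    """Full per-muscle measurement: L, ACSA_max and location, V, shape factor."""
    if validate:
        stack.validate()
    prof = acsa_profile(stack)
    length = muscle_length(prof)
    volume = integrate_volume(prof)
    acsa_max, pos = find_acsa_max(prof)
    p = volume / (acsa_max * length)
    morph = MuscleMorphology(
        subject_id=stack.subject_id,
        muscle_label=stack.muscle_label,
        l_muscle_cm=length,
        acsa_max_cm2=acsa_max,
        acsa_max_position_pct_shank=pos,
        v_measured_cm3=volume,
        shape_factor=p,
    )
    morph.validate()
    return morph
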