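"""Synthetic muscles with known ground truth.

Real triceps-surae ACSA profiles are smooth and unimodal, with a
muscle-specific peak location along the shank.  Two kinds of synthetic
geometry reproduce that structure with analytically known morphology:

* **analytic solids** (cylinder, cone, spheroid) whose shape factors are
  exact limits (1, 1/3, 2/3) — oracles for the measurement pipeline;
* **parametric muscles** whose ACSA profile follows a scaled beta kernel
  ``ACSA(t) ∝ t^(α-1) (1-t)^(β-1)`` on the muscle extent ``t ∈ [0, 1]``.
  The kernel's mode (peak location within the muscle) and mean-to-max ratio
  (the shape factor) are independently controllable, so a target
  ``(p, peak)`` pair is inverted to ``(α, β)`` by 1-D root finding.

Cross-sections are circles of prescribed area: only areas enter any measured
quantity, so in-plane realism is not attempted.  Slice sections that are
analytically zero (cone apex, spheroid poles, kernel endpoints) are floored
to a tiny positive area so every slice carries a valid simple polygon; the
floor is small enough (≤ 1e-5 of the peak area) to leave measured shape
factors unchanged at the 1e-4 level.

``make_cohort`` draws per-subject morphology (length, ACSA_max, shape
factor, peak position in % shank) from independent truncated normal
distributions; the built-in ``OLDER_FEMALE_TS`` preset carries the
distributions of a cohort of 21 healthy older women (soleus and the two
gastrocnemii).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .contours import Contour, ContourStack
from .errors import InfeasibleSpecError, ValidationError

__all__ = [
    "AnalyticSolidSpec",
    "ParametricMuscleSpec",
    "MuscleDistributions",
    "CohortSpec",
    "make_analytic_solid",
    "solve_profile_parameters",
    "make_parametric_muscle",
    "make_cohort",
    "older_female_ts",
    "OLDER_FEMALE_TS",
]


# ---------------------------------------------------------------------------
# circle polygons and slice grids

@lru_cache(maxsize=32)
def _unit_ngon(n: int) -> np.ndarray:
    """Regular n-gon on the unit circle, counter-clockwise."""
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([np.cos(theta), np.sin(theta)])


def circle_polygon(area_mm2: float, n_vertices: int = 64) -> np.ndarray:
    """Regular n-gon whose shoelace area equals ``area_mm2`` exactly.

    The circumradius is inflated relative to the target circle so the
    inscribed polygon area matches the requested area, removing the
    discretization bias of plain inscribed polygons.
    """
    if n_vertices < 8:
        raise ValidationError("need at least 8 vertices per contour")
    if not area_mm2 > 0:
        raise ValidationError("contour area must be positive")
    radius = np.sqrt(2.0 * area_mm2 / (n_vertices * np.sin(2.0 * np.pi / n_vertices)))
    return radius * _unit_ngon(n_vertices)


def _slice_grid(length_mm: float, spacing_mm: float) -> np.ndarray:
    """0 .. length grid at the given spacing; both marginal slices included."""
    k = int(np.floor(length_mm / spacing_mm + 1e-9))
    z = spacing_mm * np.arange(k + 1, dtype=float)
    if z[-1] < length_mm - 1e-9:
        z = np.append(z, length_mm)
    else:
        z[-1] = length_mm
    return z


def _stack_from_areas(
    z: np.ndarray,
    areas: np.ndarray,
    n_vertices: int,
    muscle_label: str,
    subject_id: str,
    shank_landmarks: tuple[float, float] | None,
) -> ContourStack:
    contours = [
        Contour(z=float(zi), vertices=circle_polygon(float(ai), n_vertices))
        for zi, ai in zip(z, areas)
    ]
    return ContourStack(
        muscle_label=muscle_label,
        contours=contours,
        slice_positions=z,
        shank_landmarks=shank_landmarks,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# analytic solids

@dataclass
class AnalyticSolidSpec:
    """A cylinder, cone or prolate spheroid sampled in transverse slices.

    ``radius_mm`` is the in-plane radius (cone: base radius; spheroid:
    equatorial radius); ``length_mm`` the axial extent.
    """

    kind: str  # {"cylinder", "cone", "spheroid"}
    radius_mm: float
    length_mm: float
    slice_spacing_mm: float = 2.0
    vertices_per_contour: int = 64

    def validate(self) -> None:
        if self.kind not in ("cylinder", "cone", "spheroid"):
            raise InfeasibleSpecError(f"unknown solid kind {self.kind!r}")
        if not (self.radius_mm > 0 and self.length_mm > 0 and self.slice_spacing_mm > 0):
            raise InfeasibleSpecError("solid dimensions must be positive")
        if not self.slice_spacing_mm < self.length_mm / 2:
            raise InfeasibleSpecError("slice spacing must be < length / 2")
        if self.vertices_per_contour < 8:
            raise InfeasibleSpecError("need >= 8 vertices per contour")


def make_analytic_solid(spec: AnalyticSolidSpec) -> ContourStack:
    """Contour stack of an analytic solid (shape-factor oracle geometry)."""
    spec.validate()
    z = _slice_grid(spec.length_mm, spec.slice_spacing_mm)
    a_max = np.pi * spec.radius_mm**2
    if spec.kind == "cylinder":
        areas = np.full_like(z, a_max)
    elif spec.kind == "cone":
        # apex at the proximal end; A(z) is quadratic in the distance from it
        areas = a_max * (1.0 - z / spec.length_mm) ** 2
    else:  # spheroid
        c = spec.length_mm / 2.0
        areas = a_max * (1.0 - ((z - c) / c) ** 2)
    areas = np.maximum(areas, a_max * 1e-6)  # poles/apex: tiny valid polygon
    return _stack_from_areas(
        z, areas, spec.vertices_per_contour,
        muscle_label=spec.kind, subject_id="analytic",
        shank_landmarks=(0.0, spec.length_mm),
    )


# ---------------------------------------------------------------------------
# beta-kernel profile family

def _log_mean_to_max(s: float, mode: float) -> float:
    """log(mean/max) of the beta kernel with alpha-1 = s*mode, beta-1 = s*(1-mode)."""
    alpha = 1.0 + s * mode
    beta = 1.0 + s * (1.0 - mode)
    log_max = s * (mode * np.log(mode) + (1.0 - mode) * np.log(1.0 - mode))
    return float(special.betaln(alpha, beta)) - log_max


def solve_profile_parameters(p_target: float, peak_relative: float) -> tuple[float, float]:
    """Invert (shape factor, peak location) to beta-kernel exponents (α, β).

    The kernel's mode equals ``peak_relative`` exactly for every point of the
    line ``α = 1 + s·m, β = 1 + s·(1-m)``; along that line the mean-to-max
    ratio falls monotonically from 1 (s → 0, flat profile) towards 0, so the
    target is bracketed and solved by Brent's method.
    """
    if not 0.0 < peak_relative < 1.0:
        raise InfeasibleSpecError(
            f"peak_relative must lie in (0, 1), got {peak_relative}"
        )
    if not 0.0 < p_target < 1.0:
        raise InfeasibleSpecError(
            f"shape-factor target must lie in (0, 1) for a unimodal profile, "
            f"got {p_target}; p -> 1 is the flat-cylinder limit"
        )
    target = np.log(p_target)
    lo, hi = 1e-12, 4.0
    while _log_mean_to_max(hi, peak_relative) > target:
        hi *= 2.0
        if hi > 1e9:
            raise InfeasibleSpecError(
                f"no beta kernel with mode {peak_relative} reaches mean/max "
                f"= {p_target}; attainable range at this mode is (0, 1)"
            )
    s = optimize.brentq(
        lambda v: _log_mean_to_max(v, peak_relative) - target, lo, hi,
        xtol=1e-13, rtol=8.9e-16,
    )
    return 1.0 + s * peak_relative, 1.0 + s * (1.0 - peak_relative)


def _beta_kernel(t: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """t^(α-1) (1-t)^(β-1), with the zero endpoints handled exactly."""
    out = np.zeros_like(t)
    inner = (t > 0) & (t < 1)
    ti = t[inner]
    out[inner] = np.exp((alpha - 1.0) * np.log(ti) + (beta - 1.0) * np.log(1.0 - ti))
    return out


# ---------------------------------------------------------------------------
# parametric muscles

@dataclass
class ParametricMuscleSpec:
    """A single synthetic muscle with prescribed measured morphology.

    The sampled maximum ACSA equals ``acsa_max_cm2`` exactly and the extent
    equals ``l_muscle_cm``; the beta-kernel exponents are solved so the
    continuous profile has mean/max = ``shape_factor_target`` and mode at
    ``peak_relative`` of the muscle extent.  ``muscle_offset_mm`` places the
    distal muscle end in the shank frame ``(z_distal_mm, z_proximal_mm)``.
    """

    l_muscle_cm: float
    acsa_max_cm2: float
    shape_factor_target: float
    peak_relative: float
    z_distal_mm: float = 0.0
    z_proximal_mm: float = 360.0
    muscle_offset_mm: float = 0.0
    slice_spacing_mm: float = 2.0
    vertices_per_contour: int = 64

    def validate(self) -> None:
        if not (self.l_muscle_cm > 0 and self.acsa_max_cm2 > 0):
            raise InfeasibleSpecError("muscle dimensions must be positive")
        if not self.z_proximal_mm > self.z_distal_mm:
            raise InfeasibleSpecError("z_proximal must exceed z_distal")
        if not self.slice_spacing_mm < 10.0 * self.l_muscle_cm / 2:
            raise InfeasibleSpecError("slice spacing must be < muscle length / 2")
        if self.muscle_offset_mm < self.z_distal_mm:
            raise InfeasibleSpecError("muscle extends distal of the calcaneal landmark")


def make_parametric_muscle(
    spec: ParametricMuscleSpec, subject_id: str = "", muscle_label: str = "muscle"
) -> ContourStack:
    """Contour stack whose measured morphology recovers the given parameters.

    Closure tolerances: measured shape factor within 0.01 of
    ``shape_factor_target`` (typically ~1e-4 at 2 mm spacing) and peak
    position within one slice spacing.
    """
    spec.validate()
    alpha, beta = solve_profile_parameters(spec.shape_factor_target, spec.peak_relative)
    length_mm = spec.l_muscle_cm * 10.0
    a_max_mm2 = spec.acsa_max_cm2 * 100.0
    z_local = _slice_grid(length_mm, spec.slice_spacing_mm)
    kernel = _beta_kernel(z_local / length_mm, alpha, beta)
    areas = a_max_mm2 * kernel / kernel.max()  # sampled maximum == ACSA_max
    areas = np.maximum(areas, a_max_mm2 * 1e-5)
    return _stack_from_areas(
        spec.muscle_offset_mm + z_local, areas, spec.vertices_per_contour,
        muscle_label=muscle_label, subject_id=subject_id,
        shank_landmarks=(spec.z_distal_mm, spec.z_proximal_mm),
    )


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class MuscleDistributions:
    """(mean, SD) of the per-subject morphology parameters for one muscle.

    ``profile_mode`` is the peak location within the muscle extent (fixed
    per muscle); the drawn shank-relative peak position then determines the
    muscle's placement along the shank.
    """

    l_muscle_cm: tuple[float, float]
    acsa_max_cm2: tuple[float, float]
    shape_factor: tuple[float, float]
    peak_pct_shank: tuple[float, float]
    profile_mode: float = 0.6


@dataclass
class CohortSpec:
    """Monte-Carlo cohort: n subjects, per-muscle parameter distributions."""

    n: int
    muscles: dict[str, MuscleDistributions]
    seed: int = 0
    shank_length_mm: float = 360.0
    slice_spacing_mm: float = 2.0
    vertices_per_contour: int = 64
    truncation_sd: float = 3.0
    overhang_mm: float = 80.0  # gastrocnemii may cross the tibial plateau
    preset_name: str = ""

    def validate(self) -> None:
        if self.n < 1:
            raise InfeasibleSpecError("cohort size must be >= 1")
        if not self.muscles:
            raise InfeasibleSpecError("cohort needs at least one muscle")
        for name, d in self.muscles.items():
            for attr in ("l_muscle_cm", "acsa_max_cm2", "shape_factor", "peak_pct_shank"):
                mean, sd = getattr(d, attr)
                if sd < 0:
                    raise InfeasibleSpecError(f"{name}.{attr}: SD must be >= 0")
            if not 0.0 < d.profile_mode < 1.0:
                raise InfeasibleSpecError(f"{name}: profile_mode must lie in (0, 1)")


#: older-female triceps-surae preset: per-muscle means ± SDs of length (cm),
#: ACSA_max (cm^2), shape factor, and ACSA_max position (% shank).
OLDER_FEMALE_TS: dict[str, MuscleDistributions] = {
    "SOL": MuscleDistributions(
        l_muscle_cm=(30.8, 0.7), acsa_max_cm2=(24.0, 4.4),
        shape_factor=(0.484, 0.027), peak_pct_shank=(59.3, 3.5),
        profile_mode=0.50,
    ),
    "GM": MuscleDistributions(
        l_muscle_cm=(24.7, 1.4), acsa_max_cm2=(13.1, 2.3),
        shape_factor=(0.556, 0.028), peak_pct_shank=(75.0, 4.3),
        profile_mode=0.65,
    ),
    "GL": MuscleDistributions(
        l_muscle_cm=(21.2, 2.1), acsa_max_cm2=(7.6, 1.2),
        shape_factor=(0.568, 0.049), peak_pct_shank=(80.6, 5.1),
        profile_mode=0.70,
    ),
}


def older_female_ts(
    n: int = 21, seed: int = 0, muscles: tuple[str, ...] = ("SOL", "GM", "GL")
) -> CohortSpec:
    """CohortSpec for the older-female triceps-surae study conditions (n = 21)."""
    unknown = set(muscles) - set(OLDER_FEMALE_TS)
    if unknown:
        raise InfeasibleSpecError(f"unknown muscles {sorted(unknown)}")
    return CohortSpec(
        n=n,
        muscles={m: replace(OLDER_FEMALE_TS[m]) for m in muscles},
        seed=seed,
        preset_name="older-female-ts",
    )


def _draw_truncnorm(rng: np.random.Generator, mean: float, sd: float, k: float) -> float:
    if sd == 0.0:
        return mean
    return float(stats.truncnorm.rvs(-k, k, loc=mean, scale=sd, random_state=rng))


_MAX_RETRIES = 200


def make_cohort(spec: CohortSpec) -> tuple[list[ContourStack], pd.DataFrame]:
    """Generate n subjects × muscles plus the ground-truth parameter table.

    Per-subject parameters are independent truncated-normal draws (±3 SD by
    default); draws whose implied shank placement is infeasible — peak
    outside the shank, muscle below the calcaneal tuberosity or more than
    ``overhang_mm`` proximal of the tibial plateau — are redrawn, with a
    bounded retry count.  All randomness flows from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k = spec.truncation_sd
    shank = spec.shank_length_mm
    stacks: list[ContourStack] = []
    rows = []
    for i in range(spec.n):
        subject = f"S{i + 1:04d}"
        for muscle, dist in spec.muscles.items():
            for attempt in range(_MAX_RETRIES):
                length_cm = _draw_truncnorm(rng, *dist.l_muscle_cm, k)
                acsa_cm2 = _draw_truncnorm(rng, *dist.acsa_max_cm2, k)
                p = _draw_truncnorm(rng, *dist.shape_factor, k)
                peak_pct = _draw_truncnorm(rng, *dist.peak_pct_shank, k)
                offset = peak_pct / 100.0 * shank - dist.profile_mode * length_cm * 10.0
                feasible = (
                    length_cm > 0 and acsa_cm2 > 0 and 0.0 < p < 1.0
                    and 0.0 < peak_pct < 100.0
                    and offset >= 0.0
                    and offset + length_cm * 10.0 <= shank + spec.overhang_mm
                )
                if feasible:
                    break
            else:
                raise InfeasibleSpecError(
                    f"{subject}/{muscle}: no feasible draw in {_MAX_RETRIES} tries; "
                    "check the distribution/placement parameters"
                )
            mspec = ParametricMuscleSpec(
                l_muscle_cm=length_cm,
                acsa_max_cm2=acsa_cm2,
                shape_factor_target=p,
                peak_relative=dist.profile_mode,
                z_distal_mm=0.0,
                z_proximal_mm=shank,
                muscle_offset_mm=offset,
                slice_spacing_mm=spec.slice_spacing_mm,
                vertices_per_contour=spec.vertices_per_contour,
            )
            stacks.append(make_parametric_muscle(mspec, subject_id=subject, muscle_label=muscle))
            rows.append(
                {
                    "subject_id": subject,
                    "muscle_label": muscle,
                    "l_muscle_cm": length_cm,
                    "acsa_max_cm2": acsa_cm2,
                    "shape_factor": p,
                    "peak_pct_shank": peak_pct,
                    "v_implied_cm3": p * acsa_cm2 * length_cm,
                }
            )
    return stacks, pd.DataFrame(rows)
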