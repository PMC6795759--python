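"""Muscle shape factors and simplified volume estimation.

The measured volume of a muscle equals its mean ACSA times its length.
Writing the mean ACSA as a fraction ``p`` (the shape factor) of the maximal
ACSA gives the two working equations of the simplified assessment:

    p           = V_measured / (ACSA_max * L_muscle)
    V_estimated = p * ACSA_max * L_muscle

``p`` is muscle-specific and varies little between subjects of the same
population, so a cohort-average ``p`` plus a single ACSA measurement and the
muscle length suffice to estimate volume without whole-muscle segmentation.

Two built-in factor tables are provided for the triceps surae (soleus SOL,
gastrocnemius medialis GM, gastrocnemius lateralis GL): ``OLDER_ADULT_FACTORS``
(healthy older women) and ``YOUNG_ADULT_FACTORS`` (healthy young adults).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .geometry import MuscleMorphology

__all__ = [
    "ShapeFactorTable",
    "VolumeEstimate",
    "shape_factor",
    "estimate_volume",
    "build_factor_table",
    "cross_estimate",
    "OLDER_ADULT_FACTORS",
    "YOUNG_ADULT_FACTORS",
]


@dataclass
class ShapeFactorTable:
    """Per-muscle mean shape factors for one cohort (optionally with SDs)."""

    cohort_label: str
    factors: dict[str, float]
    dispersion: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for muscle, p in self.factors.items():
            if not 0.0 < p <= 1.0:
                raise ValidationError(
                    f"shape factor for {muscle} must lie in (0, 1], got {p}"
                )

    def __getitem__(self, muscle_label: str) -> float:
        try:
            return self.factors[muscle_label]
        except KeyError:
            raise ValidationError(
                f"no shape factor for muscle {muscle_label!r} in table "
                f"{self.cohort_label!r} (has {sorted(self.factors)})"
            ) from None

    def to_json(self, path) -> None:
        payload = {"cohort_label": self.cohort_label, "factors": self.factors}
        if self.dispersion is not None:
            payload["dispersion"] = self.dispersion
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ShapeFactorTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            cohort_label=payload["cohort_label"],
            factors={str(k): float(v) for k, v in payload["factors"].items()},
            dispersion=payload.get("dispersion"),
        )


#: factors measured in healthy older female adults (n = 21)
OLDER_ADULT_FACTORS = ShapeFactorTable(
    "older",
    factors={"SOL": 0.484, "GM": 0.556, "GL": 0.568},
    dispersion={"SOL": 0.027, "GM": 0.028, "GL": 0.049},
)

#: factors previously reported for healthy young adults (n = 13)
YOUNG_ADULT_FACTORS = ShapeFactorTable(
    "young",
    factors={"SOL": 0.496, "GM": 0.592, "GL": 0.569},
)


@dataclass
class VolumeEstimate:
    """A shape-factor based volume estimate for one (subject, muscle)."""

    subject_id: str
    muscle_label: str
    v_estimated_cm3: float
    factor_source: str

    def __post_init__(self) -> None:
        if not self.v_estimated_cm3 > 0:
            raise ValidationError("estimated volume must be positive")


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValidationError(f"{name} must be positive, got {value}")


def shape_factor(v_measured_cm3: float, acsa_max_cm2: float, l_muscle_cm: float) -> float:
    """Dimensionless shape factor p = V / (ACSA_max * L)."""
    _require_positive(
        v_measured_cm3=v_measured_cm3, acsa_max_cm2=acsa_max_cm2, l_muscle_cm=l_muscle_cm
    )
    return v_measured_cm3 / (acsa_max_cm2 * l_muscle_cm)


def estimate_volume(
    p: float,
    acsa_max_cm2: float,
    l_muscle_cm: float,
    subject_id: str = "",
    muscle_label: str = "",
    factor_source: str = "",
) -> VolumeEstimate:
    """Simplified volume estimate V = p * ACSA_max * L (cm^3)."""
    _require_positive(p=p, acsa_max_cm2=acsa_max_cm2, l_muscle_cm=l_muscle_cm)
    return VolumeEstimate(
        subject_id=subject_id,
        muscle_label=muscle_label,
        v_estimated_cm3=p * acsa_max_cm2 * l_muscle_cm,
        factor_source=factor_source,
    )


def build_factor_table(
    morphologies: list[MuscleMorphology], cohort_label: str
) -> ShapeFactorTable:
    """Unweighted per-muscle mean (and sample SD) of individual shape factors."""
    groups: dict[str, list[float]] = {}
    for m in morphologies:
        groups.setdefault(m.muscle_label, []).append(m.shape_factor)
    factors, dispersion = {}, {}
    for muscle, ps in groups.items():
        if len(ps) < 2:
            raise ValidationError(
                f"muscle {muscle!r} has {len(ps)} subject(s); need >=2 to average"
            )
        factors[muscle] = float(np.mean(ps))
        dispersion[muscle] = float(np.std(ps, ddof=1))
    return ShapeFactorTable(cohort_label, factors=factors, dispersion=dispersion)


def cross_estimate(
    cohort: list[MuscleMorphology], table: ShapeFactorTable
) -> list[VolumeEstimate]:
    """Estimate every cohort muscle's volume with the table's mean factors.

    Uses each subject's own measured ACSA_max and L with the cohort-mean
    factor of the table — the cross-validation setting in which factor
    mismatch between cohorts shows up as systematic over/underestimation.
    """
    return [
        estimate_volume(
            table[m.muscle_label],
            m.acsa_max_cm2,
            m.l_muscle_cm,
            subject_id=m.subject_id,
            muscle_label=m.muscle_label,
            factor_source=table.cohort_label,
        )
        for m in cohort
    ]
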