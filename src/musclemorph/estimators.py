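"""scikit-learn compatible wrappers around the morphometry pipeline.

``ContourMorphometry`` is a stateless transformer turning contour stacks
into a morphology DataFrame; ``ShapeFactorVolumeEstimator`` is a regressor
that learns per-muscle mean shape factors from measured volumes (fit) and
predicts volumes as p * ACSA_max * L (predict).  Both follow the estimator
API (get_params/set_params, fitted attributes with trailing underscores) and
compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError
from .geometry import measure_morphology
from .shape import (
    OLDER_ADULT_FACTORS,
    YOUNG_ADULT_FACTORS,
    ShapeFactorTable,
    build_factor_table,
)

__all__ = ["ContourMorphometry", "ShapeFactorVolumeEstimator"]

_PRESETS = {"older": OLDER_ADULT_FACTORS, "young": YOUNG_ADULT_FACTORS}

#: column names expected by ShapeFactorVolumeEstimator
FEATURE_COLUMNS = ["muscle_label", "ACSA_max_cm2", "L_muscle_cm"]


class ContourMorphometry(TransformerMixin, BaseEstimator):
    """Transform contour stacks into measured morphology rows.

    Parameters
    ----------
    validate : bool, default True
        Run full stack validation (polygon simplicity, hole containment)
        before measuring.
    """

    def __init__(self, validate: bool = True):
        self.validate = validate

    def fit(self, X, y=None):
        self.n_features_in_ = 1  # sequence of ContourStack
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of ContourStack -> morphology DataFrame (cm units)."""
        rows = []
        for stack in X:
            m = measure_morphology(stack, validate=self.validate)
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "muscle_label": m.muscle_label,
                    "L_muscle_cm": m.l_muscle_cm,
                    "ACSA_max_cm2": m.acsa_max_cm2,
                    "acsa_max_position_pct_shank": m.acsa_max_position_pct_shank,
                    "V_measured_cm3": m.v_measured_cm3,
                    "shape_factor": m.shape_factor,
                }
            )
        return pd.DataFrame(rows)


class ShapeFactorVolumeEstimator(RegressorMixin, BaseEstimator):
    """Muscle-volume regressor based on per-muscle mean shape factors.

    ``fit(X, y)`` learns one mean shape factor per muscle from measured
    volumes ``y`` (cm^3), where ``X`` is a DataFrame with columns
    ``muscle_label``, ``ACSA_max_cm2``, ``L_muscle_cm``.  ``predict``
    returns ``p[muscle] * ACSA_max * L``.

    Parameters
    ----------
    factors : None, "older", "young", dict or ShapeFactorTable
        If given, fit skips learning and uses these factors instead —
        the cross-cohort validation setting.
    """

    def __init__(self, factors=None):
        self.factors = factors

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise ValidationError(
                f"X must be a DataFrame with columns {FEATURE_COLUMNS}"
            )
        missing = set(FEATURE_COLUMNS) - set(X.columns)
        if missing:
            raise ValidationError(f"X missing columns {sorted(missing)}")
        return X

    def _resolve_table(self) -> ShapeFactorTable | None:
        if self.factors is None:
            return None
        if isinstance(self.factors, ShapeFactorTable):
            return self.factors
        if isinstance(self.factors, str):
            try:
                return _PRESETS[self.factors]
            except KeyError:
                raise ValidationError(
                    f"unknown factor preset {self.factors!r}; use {sorted(_PRESETS)}"
                ) from None
        if isinstance(self.factors, dict):
            return ShapeFactorTable("custom", factors=dict(self.factors))
        raise ValidationError(f"cannot interpret factors={self.factors!r}")

    def fit(self, X, y=None):
        X = self._as_frame(X)
        table = self._resolve_table()
        if table is None:
            if y is None:
                raise ValidationError("y (measured volumes, cm^3) required to learn factors")
            y = np.asarray(y, dtype=float)
            from .geometry import MuscleMorphology

            morphs = [
                MuscleMorphology(
                    subject_id=str(i),
                    muscle_label=str(row.muscle_label),
                    l_muscle_cm=float(row.L_muscle_cm),
                    acsa_max_cm2=float(row.ACSA_max_cm2),
                    acsa_max_position_pct_shank=50.0,  # not used for factors
                    v_measured_cm3=float(v),
                    shape_factor=float(v)
                    / (float(row.ACSA_max_cm2) * float(row.L_muscle_cm)),
                )
                for i, (row, v) in enumerate(zip(X.itertuples(index=False), y))
            ]
            table = build_factor_table(morphs, cohort_label="fitted")
        self.table_ = table
        self.factors_ = dict(table.factors)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "table_")
        X = self._as_frame(X)
        return np.array(
            [
                self.table_[str(row.muscle_label)]
                * float(row.ACSA_max_cm2)
                * float(row.L_muscle_cm)
                for row in X.itertuples(index=False)
            ]
        )
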