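"""Agreement and group-comparison statistics for volume validation.

Mirrors a standard method-agreement workflow: relative RMS difference and
R² between estimated and measured volumes, paired t-test (after a
Kolmogorov–Smirnov normality check of the differences), coefficient of
variation of shape factors, and a one-way ANOVA with Bonferroni post-hoc
comparisons across muscles.

Notes on definitions (the field's papers rarely print formulas):

* ``relative_rms`` defaults to the RMS of per-subject relative differences,
  ``100·sqrt(mean(((est-meas)/meas)^2))``; a pooled alternative
  (RMS of absolute differences divided by the mean measured volume) is
  available via ``definition="pooled"``.
* ``r_squared`` is the squared Pearson correlation — invariant under
  positive rescaling of either vector, which is why switching factor tables
  (a per-muscle rescaling of the estimates) cannot change it.
* The normality check is the KS test against a normal with estimated
  parameters, i.e. the Lilliefors variant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .errors import ValidationError
from .geometry import MuscleMorphology
from .shape import ShapeFactorTable, cross_estimate

__all__ = [
    "AgreementStats",
    "AnovaResult",
    "CohortValidationReport",
    "relative_rms",
    "r_squared",
    "coefficient_of_variation",
    "paired_comparison",
    "muscle_anova",
    "validate_cohort",
]


def _paired_arrays(v_estimated, v_measured) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(v_estimated, dtype=float)
    meas = np.asarray(v_measured, dtype=float)
    if est.shape != meas.shape or est.ndim != 1:
        raise ValidationError("estimated and measured must be 1-D arrays of equal length")
    return est, meas


def relative_rms(v_estimated, v_measured, definition: str = "per_subject") -> float:
    """Relative RMS difference between estimated and measured volumes, %."""
    est, meas = _paired_arrays(v_estimated, v_measured)
    if est.size < 1:
        raise ValidationError("need at least one pair")
    if definition == "per_subject":
        if np.any(meas <= 0):
            raise ValidationError("measured volumes must be positive")
        return 100.0 * float(np.sqrt(np.mean(((est - meas) / meas) ** 2)))
    if definition == "pooled":
        denom = float(np.mean(meas))
        if denom <= 0:
            raise ValidationError("mean measured volume must be positive")
        return 100.0 * float(np.sqrt(np.mean((est - meas) ** 2))) / denom
    raise ValidationError(f"unknown RMS definition {definition!r}")


def r_squared(v_estimated, v_measured) -> float:
    """Coefficient of determination as squared Pearson correlation."""
    est, meas = _paired_arrays(v_estimated, v_measured)
    if est.size < 3:
        raise ValidationError("need at least 3 pairs for R^2")
    if np.ptp(est) == 0 or np.ptp(meas) == 0:
        raise ValidationError("R^2 undefined for zero-variance input")
    r = sps.pearsonr(est, meas).statistic
    if not np.isfinite(r):
        raise ValidationError("R^2 undefined: correlation is not finite")
    return float(r * r)


def coefficient_of_variation(values) -> float:
    """100 × sample SD / mean, %."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("CV needs at least 2 values")
    mean = float(np.mean(v))
    if mean == 0:
        raise ValidationError("CV undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / mean


@dataclass
class PairedComparison:
    normality_p: float | None
    t_statistic: float | None
    p_value: float | None
    significant: bool
    mean_difference: float
    degenerate: bool = False


def paired_comparison(v_estimated, v_measured, alpha: float = 0.05) -> PairedComparison:
    """Two-sided paired t-test of estimated vs measured, with normality check.

    Normality of the paired differences is assessed first (Lilliefors /
    KS-with-estimated-parameters).  Constant differences (zero variance) are
    reported as degenerate: no test statistic is computed.
    """
    est, meas = _paired_arrays(v_estimated, v_measured)
    if est.size < 3:
        raise ValidationError("paired comparison needs at least 3 pairs")
    diff = est - meas
    mean_diff = float(np.mean(diff))
    if np.allclose(diff, diff[0]):
        return PairedComparison(
            normality_p=None, t_statistic=None, p_value=None,
            significant=False, mean_difference=mean_diff, degenerate=True,
        )
    _, norm_p = lilliefors(diff, dist="norm")
    res = sps.ttest_rel(est, meas)
    return PairedComparison(
        normality_p=float(norm_p),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        mean_difference=mean_diff,
    )


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    t_statistic: float
    p_adjusted: float
    significant: bool


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise: list[PairwiseComparison]
    note: str = ""


def muscle_anova(values_by_muscle: dict, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA across muscles with Bonferroni-adjusted pairwise t-tests.

    Pairwise comparisons use pooled-variance two-sample t-tests; with two
    groups the ANOVA F equals the squared pairwise t.  Muscles measured in
    the same subjects are, strictly, repeated measures; the between-subjects
    ANOVA is used deliberately and flagged in the result note.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_muscle.items()}
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    for name, g in groups.items():
        if g.size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")
    f, p = sps.f_oneway(*groups.values())
    names = list(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        res = sps.ttest_ind(groups[a], groups[b], equal_var=True)
        p_adj = min(1.0, float(res.pvalue) * m)
        pairwise.append(
            PairwiseComparison(
                group_a=a, group_b=b, t_statistic=float(res.statistic),
                p_adjusted=p_adj, significant=bool(p_adj < alpha),
            )
        )
    return AnovaResult(
        f_statistic=float(f), p_value=float(p), pairwise=pairwise,
        note="one-way between-groups ANOVA; muscles are repeated measures "
             "within subject, which this analysis ignores by design",
    )


@dataclass
class AgreementStats:
    """Agreement of estimated vs measured volume for one (muscle, factor table)."""

    muscle_label: str
    factor_source: str
    n: int
    rms_relative_pct: float
    r_squared: float
    mean_difference_cm3: float
    normality_p: float | None
    t_statistic: float | None
    p_value: float | None
    significant: bool
    mean_v_measured_cm3: float
    mean_v_estimated_cm3: float


@dataclass
class CohortValidationReport:
    """Machine-readable summary of a cohort cross-validation run."""

    agreement: list[AgreementStats]
    shape_factor_cv_pct: dict[str, float]
    shape_factor_anova: AnovaResult | None
    alpha: float
    n_subjects: int
    factor_tables: list[str]
    rms_definition: str
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        lines = [
            f"Cohort validation (n={self.n_subjects}, alpha={self.alpha}, "
            f"RMS definition: {self.rms_definition})",
            "",
            f"{'muscle':<8}{'factors':<10}{'relRMS %':>10}{'R^2':>8}"
            f"{'meanDiff cm3':>14}{'p':>10}{'sig':>5}",
        ]
        for a in self.agreement:
            pv = "n/a" if a.p_value is None else f"{a.p_value:.4f}"
            lines.append(
                f"{a.muscle_label:<8}{a.factor_source:<10}{a.rms_relative_pct:>10.2f}"
                f"{a.r_squared:>8.3f}{a.mean_difference_cm3:>14.2f}{pv:>10}"
                f"{'*' if a.significant else '':>5}"
            )
        lines.append("")
        cv = ", ".join(f"{m}: {v:.1f}%" for m, v in self.shape_factor_cv_pct.items())
        lines.append(f"Shape-factor CV: {cv}")
        an = self.shape_factor_anova
        if an is not None:
            lines.append(
                f"Shape-factor ANOVA: F={an.f_statistic:.2f}, p={an.p_value:.2e}"
            )
            for pw in an.pairwise:
                lines.append(
                    f"  {pw.group_a} vs {pw.group_b}: t={pw.t_statistic:.2f}, "
                    f"p_adj={pw.p_adjusted:.4f}{' *' if pw.significant else ''}"
                )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def validate_cohort(
    cohort: list[MuscleMorphology],
    tables: list[ShapeFactorTable],
    alpha: float = 0.05,
    rms_definition: str = "per_subject",
) -> CohortValidationReport:
    """Full agreement analysis of a measured cohort against factor tables.

    For every (muscle, table) pair: estimate volumes with the table's mean
    factor and each subject's own ACSA_max and length, then compute relative
    RMS, R², mean difference and the paired test.  Adds per-muscle shape
    factor CVs and the across-muscle ANOVA.
    """
    muscles = sorted({m.muscle_label for m in cohort})
    by_muscle = {
        mus: [m for m in cohort if m.muscle_label == mus] for mus in muscles
    }
    agreement = []
    for table in tables:
        estimates = cross_estimate(cohort, table)
        est_by_key = {(e.subject_id, e.muscle_label): e.v_estimated_cm3 for e in estimates}
        for mus in muscles:
            group = by_muscle[mus]
            meas = np.array([m.v_measured_cm3 for m in group])
            est = np.array([est_by_key[(m.subject_id, m.muscle_label)] for m in group])
            pc = paired_comparison(est, meas, alpha=alpha)
            agreement.append(
                AgreementStats(
                    muscle_label=mus,
                    factor_source=table.cohort_label,
                    n=len(group),
                    rms_relative_pct=relative_rms(est, meas, definition=rms_definition),
                    r_squared=r_squared(est, meas),
                    mean_difference_cm3=pc.mean_difference,
                    normality_p=pc.normality_p,
                    t_statistic=pc.t_statistic,
                    p_value=pc.p_value,
                    significant=pc.significant,
                    mean_v_measured_cm3=float(np.mean(meas)),
                    mean_v_estimated_cm3=float(np.mean(est)),
                )
            )
    cv = {
        mus: coefficient_of_variation([m.shape_factor for m in by_muscle[mus]])
        for mus in muscles
    }
    if len(muscles) >= 2:
        anova = muscle_anova(
            {mus: [m.shape_factor for m in by_muscle[mus]] for mus in muscles},
            alpha=alpha,
        )
        notes = [anova.note]
    else:
        anova = None
        notes = ["single-muscle cohort: across-muscle ANOVA skipped"]
    return CohortValidationReport(
        agreement=agreement,
        shape_factor_cv_pct=cv,
        shape_factor_anova=anova,
        alpha=alpha,
        n_subjects=len({m.subject_id for m in cohort}),
        factor_tables=[t.cohort_label for t in tables],
        rms_definition=rms_definition,
        notes=notes,
    )
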