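"""Core domain types for digital cytometry.

All expression values are in linear (non-log) space. The deconvolution model
is ``A x = b``: ``A`` a signature matrix of reference expression profiles
(genes x cell types), ``b`` a bulk mixture profile (genes x samples) and
``x`` the unknown cell-type proportions per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignatureMatrix",
    "MixtureProfile",
    "ClinicalTable",
    "ProportionEstimate",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


def _check_finite_nonneg(values: np.ndarray, what: str) -> None:
    if not np.isfinite(values).all():
        raise ValidationError(f"{what} contains non-finite values")
    if (values < 0).any():
        raise ValidationError(f"{what} contains negative values")


@dataclass
class SignatureMatrix:
    """Reference expression of marker genes per cell type (genes x cell types)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "gene_ids")
        _check_unique(self.data.columns, "cell_types")
        if self.data.shape[1] < 2:
            raise ValidationError("signature matrix needs at least 2 cell types")
        if self.data.shape[0] < 1:
            raise ValidationError("signature matrix needs at least 1 gene")
        _check_finite_nonneg(self.data.to_numpy(), "signature matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_types(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class MixtureProfile:
    """Bulk expression per sample (genes x samples), linear space."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "gene_ids")
        _check_unique(self.data.columns, "sample_ids")
        if self.data.size == 0:
            raise ValidationError("mixture profile is empty")
        _check_finite_nonneg(self.data.to_numpy(), "mixture profile")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


GRADE_LEVELS = ["G1", "G2", "G3", "G4"]
STAGE_LEVELS = ["T1", "T2", "T3", "T4"]
TUMOR_STATUS_LEVELS = ["tumor-free", "with-tumor"]
SURVIVAL_STATUS_LEVELS = ["alive", "deceased"]
GENDER_LEVELS = ["female", "male"]
LATERALITY_LEVELS = ["left", "right"]

_CATEGORICAL_LEVELS = {
    "grade": GRADE_LEVELS,
    "stage": STAGE_LEVELS,
    "tumor_status": TUMOR_STATUS_LEVELS,
    "survival_status": SURVIVAL_STATUS_LEVELS,
    "gender": GENDER_LEVELS,
    "laterality": LATERALITY_LEVELS,
}

CLINICAL_COLUMNS = list(_CATEGORICAL_LEVELS) + ["age_at_diagnosis", "overall_survival"]


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates.

    Missing values are carried explicitly as NA; operations that exclude
    missing rows must report the excluded count rather than dropping
    silently.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample_ids")
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise ValidationError(f"clinical table missing columns: {missing_cols}")
        for col, levels in _CATEGORICAL_LEVELS.items():
            vals = self.data[col].dropna()
            bad = set(vals) - set(levels)
            if bad:
                raise ValidationError(f"invalid {col} values: {sorted(bad)}")
        surv = pd.to_numeric(self.data["overall_survival"], errors="raise")
        if (surv.dropna() < 0).any():
            raise ValidationError("overall_survival must be >= 0")
        age = pd.to_numeric(self.data["age_at_diagnosis"], errors="raise")
        if (age.dropna() <= 0).any():
            raise ValidationError("age_at_diagnosis must be > 0")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index


@dataclass
class ProportionEstimate:
    """Estimated cell-type fractions per sample plus per-sample fit diagnostics.

    ``fractions`` is samples x cell types, every row summing to 1 (or all
    zero for a flagged degenerate sample). ``diagnostics`` carries columns
    ``rmse``, ``pearson_r``, ``p_value``, ``nu_selected`` and the boolean
    ``degenerate`` flag, indexed like ``fractions``.
    """

    fractions: pd.DataFrame
    diagnostics: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        _check_unique(self.fractions.index, "sample_ids")
        _check_unique(self.fractions.columns, "cell_types")
        if self.diagnostics is None:
            self.diagnostics = pd.DataFrame(
                {
                    "rmse": np.nan,
                    "pearson_r": np.nan,
                    "p_value": np.nan,
                    "nu_selected": np.nan,
                    "degenerate": False,
                },
                index=self.fractions.index,
            )
        vals = self.fractions.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("fractions contain non-finite values")
        if (vals < -self.SUM_TOL).any() or (vals > 1 + self.SUM_TOL).any():
            raise ValidationError("fractions must lie in [0, 1]")
        sums = vals.sum(axis=1)
        degenerate = self.diagnostics["degenerate"].to_numpy(dtype=bool)
        ok = np.isclose(sums, 1.0, atol=self.SUM_TOL) | (degenerate & (sums == 0.0))
        if not ok.all():
            bad = self.fractions.index[~ok].tolist()
            raise ValidationError(f"per-sample fractions must sum to 1: {bad[:5]}")
        pv = self.diagnostics["p_value"].dropna()
        if ((pv < 0) | (pv > 1)).any():
            raise ValidationError("p_value must lie in [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.fractions.index

    @property
    def cell_types(self) -> pd.Index:
        return self.fractions.columns
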