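"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the study design end to end: a marker-block
signature matrix over the 22-type leukocyte taxonomy, per-sample true
proportions drawn from four immune-pattern archetypes, bulk mixtures
``b = A x`` with multiplicative log-normal noise, marker-gene tracks built
to hit target correlations with family fractions (PDCD1- and INFG-like
tracks against CD8 T-cells, an RGS5-like track against mast cells), and
clinical covariates whose links to the fractions have the directions seen
in clear cell renal cell carcinoma cohorts: higher CD8 fraction at higher
grade/stage, higher mast-cell (and monocyte) fractions in lower-grade and
tumor-free patients. All effect sizes are configuration, and all of them
can be zeroed for null calibration.

Archetype family means encode the four published immune patterns

    1  CD4 < CD8 ≈ MΦ      2  CD8 < CD4 < MΦ
    3  CD4 < MΦ < CD8      4  CD8 < CD4 ≈ MΦ

and were calibrated once so that the cohort-level Pearson correlation
between the CD8 T-cell and macrophage fractions is ≈ −0.46 at the default
Dirichlet concentration. Each archetype also has a distinctive minor-
family profile (NK; monocytes/DC; plasma/γδ; mast/B) which is what makes
the four patterns separable without exaggerating the CD8–MΦ contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .aggregation import (
    LM22_CELL_TYPES,
    LM22_FAMILIES,
    LM22_FAMILY_OF,
    default_lm22_map,
)
from .datatypes import (
    ClinicalTable,
    MixtureProfile,
    SignatureMatrix,
    ValidationError,
)

__all__ = [
    "ClinicalEffects",
    "GeneratorConfig",
    "ARCHETYPE_NAMES",
    "ARCHETYPE_FAMILY_MEANS",
    "make_signature",
    "make_proportions",
    "make_mixtures",
    "make_marker_tracks",
    "make_clinical",
    "generate_cohort",
    "Cohort",
    "aggregate_to_families",
]

ARCHETYPE_NAMES = ["CD4<CD8≈MΦ", "CD8<CD4<MΦ", "CD4<MΦ<CD8", "CD8<CD4≈MΦ"]


def _archetype(spec: Mapping[str, float]) -> dict[str, float]:
    rest = 1.0 - sum(spec.values())
    flat = [f for f in LM22_FAMILIES if f not in spec]
    if rest <= 0:
        raise ValidationError("archetype fractions exceed 1")
    means = {f: rest / len(flat) for f in flat}
    means.update(spec)
    return {f: means[f] for f in LM22_FAMILIES}


# family-level mean fractions per archetype (calibrated: see module docstring)
ARCHETYPE_FAMILY_MEANS = {
    "CD4<CD8≈MΦ": _archetype(
        {"CD4 T cells": 0.20, "CD8 T cells": 0.28, "Macrophages": 0.28,
         "Neutrophils": 0.05, "Eosinophils": 0.04}
    ),
    "CD8<CD4<MΦ": _archetype(
        {"CD4 T cells": 0.22, "CD8 T cells": 0.14, "Macrophages": 0.36,
         "Monocytes": 0.07, "Dendritic cells": 0.06}
    ),
    "CD4<MΦ<CD8": _archetype(
        {"CD4 T cells": 0.12, "CD8 T cells": 0.38, "Macrophages": 0.24,
         "Plasma cells": 0.06, "Gamma delta T cells": 0.05}
    ),
    "CD8<CD4≈MΦ": _archetype(
        {"CD4 T cells": 0.25, "CD8 T cells": 0.12, "Macrophages": 0.25,
         "Mast cells": 0.10, "B cells": 0.09, "Monocytes": 0.09,
         "NK cells": 0.07}
    ),
}


@dataclass(frozen=True)
class ClinicalEffects:
    """Log-odds effect sizes (per SD of the fraction) linking fractions to clinic.

    Directions follow the cohort findings the generator emulates; zero all
    of them (``ClinicalEffects.null()``) for calibration runs.
    """

    cd8_grade: float = 1.2        # higher CD8 -> higher grade
    mast_grade: float = -0.6      # higher mast -> lower grade
    monocyte_grade: float = -0.6  # higher monocytes -> lower grade
    cd8_stage: float = 1.2
    mast_stage: float = -0.6
    monocyte_stage: float = -0.6
    mast_tumor_free: float = 0.8  # higher mast -> more likely tumor-free
    nk_tumor_free: float = 0.5    # higher NK -> more likely tumor-free

    @classmethod
    def null(cls) -> "ClinicalEffects":
        return cls(**{f: 0.0 for f in cls.__dataclass_fields__})


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``n_genes`` defaults to 200 for speed; ``lm22_scale()`` gives the
    547-gene configuration matching the published signature size.
    ``noise_sigma`` is the SD of the gene-wise multiplicative log-normal
    noise on the mixtures. ``target_correlations`` maps marker gene name ->
    (family, target Pearson r).
    """

    n_genes: int = 200
    n_samples: int = 500
    archetype_weights: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    dirichlet_concentration: float = 400.0
    within_family_concentration: float = 5.0
    noise_sigma: float = 0.1
    target_correlations: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {
            "PDCD1": ("CD8 T cells", 0.85),
            "INFG": ("CD8 T cells", 0.79),
            "RGS5": ("Mast cells", 0.60),
        }
    )
    clinical_effects: ClinicalEffects = field(default_factory=ClinicalEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.archetype_weights) != 4:
            raise ValidationError("need exactly 4 archetype weights")
        if abs(sum(self.archetype_weights) - 1.0) > 1e-9:
            raise ValidationError("archetype_weights must sum to 1")
        if any(w < 0 for w in self.archetype_weights):
            raise ValidationError("archetype_weights must be non-negative")
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValidationError("counts must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.dirichlet_concentration <= 0:
            raise ValidationError("dirichlet_concentration must be positive")
        for gene, (family, r) in self.target_correlations.items():
            if not abs(r) < 1.0:
                raise ValidationError(
                    f"target |r| must be < 1 for {gene} (got {r})"
                )
            if family not in LM22_FAMILIES:
                raise ValidationError(f"unknown family {family!r} for {gene}")

    def lm22_scale(self) -> "GeneratorConfig":
        """The 547-gene configuration mirroring the published signature size."""
        return replace(self, n_genes=547)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def make_signature(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> SignatureMatrix:
    """Marker-block signature: each cell type gets a disjoint block of
    dedicated marker genes with high expression in its own column and a low
    shared baseline elsewhere; leftover genes are baseline-only."""
    n_types = len(LM22_CELL_TYPES)
    if config.n_genes < n_types:
        raise ValidationError(
            f"n_genes must be >= {n_types} (one marker per cell type)"
        )
    rng = rng if rng is not None else _rng(config, 0)
    per_type = config.n_genes // n_types
    values = rng.lognormal(mean=0.0, sigma=0.25, size=(config.n_genes, n_types))
    for j in range(n_types):
        rows = slice(j * per_type, (j + 1) * per_type)
        values[rows, j] = rng.lognormal(mean=np.log(50.0), sigma=0.25, size=per_type)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    df = pd.DataFrame(values, index=genes, columns=LM22_CELL_TYPES)
    df.index.name = "gene"
    return SignatureMatrix(df)


def make_proportions(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Ground-truth fine-type fractions and archetype labels.

    Family fractions per sample are Dirichlet draws around the sample's
    archetype means (concentration ``dirichlet_concentration``); each
    family fraction is then split across its member fine types by a flat
    Dirichlet (``within_family_concentration``). Rows sum to 1 exactly.
    """
    rng = rng if rng is not None else _rng(config, 1)
    n = config.n_samples
    labels_idx = rng.choice(4, size=n, p=np.asarray(config.archetype_weights))
    members = {
        fam: [t for t in LM22_CELL_TYPES if LM22_FAMILY_OF[t] == fam]
        for fam in LM22_FAMILIES
    }
    fine = np.zeros((n, len(LM22_CELL_TYPES)))
    col_of = {t: i for i, t in enumerate(LM22_CELL_TYPES)}
    for i in range(n):
        means = ARCHETYPE_FAMILY_MEANS[ARCHETYPE_NAMES[labels_idx[i]]]
        alpha = config.dirichlet_concentration * np.array(
            [means[f] for f in LM22_FAMILIES]
        )
        fam_frac = rng.dirichlet(alpha)
        for fam, frac in zip(LM22_FAMILIES, fam_frac):
            kids = members[fam]
            if len(kids) == 1:
                fine[i, col_of[kids[0]]] = frac
            else:
                split = rng.dirichlet(
                    np.full(len(kids), config.within_family_concentration)
                )
                for t, s in zip(kids, split):
                    fine[i, col_of[t]] = frac * s
    samples = [f"S{i + 1:04d}" for i in range(n)]
    fractions = pd.DataFrame(fine, index=samples, columns=LM22_CELL_TYPES)
    fractions.index.name = "sample_id"
    labels = pd.Series(
        [ARCHETYPE_NAMES[k] for k in labels_idx], index=samples, name="archetype"
    )
    labels.index.name = "sample_id"
    return fractions, labels


def make_mixtures(
    sig: SignatureMatrix,
    true_fractions: pd.DataFrame,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> MixtureProfile:
    """Bulk mixtures ``b = A x`` with gene-wise log-normal noise.

    ``noise_sigma = 0`` gives exact linear mixtures.
    """
    rng = rng if rng is not None else _rng(config, 2)
    if (true_fractions.to_numpy() < 0).any():
        raise ValidationError("fractions must be non-negative")
    x = true_fractions[list(sig.cell_types)].to_numpy()
    b = sig.values @ x.T
    if config.noise_sigma > 0:
        b = b * np.exp(rng.normal(0.0, config.noise_sigma, size=b.shape))
    df = pd.DataFrame(b, index=sig.gene_ids, columns=true_fractions.index)
    df.index.name = "gene"
    return MixtureProfile(df)


def make_marker_tracks(
    true_fractions: pd.DataFrame,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Marker-gene expression rows with target correlations to families.

    Each track is the standardized family fraction scaled by r plus an
    independent Gaussian residual of variance 1 - r^2, then shifted onto a
    positive expression scale (the Pearson correlation is affine-
    invariant). Input may be fine-type or already family-aggregated
    fractions. Returns a genes x samples frame appendable to a mixture.
    """
    rng = rng if rng is not None else _rng(config, 3)
    fam = aggregate_to_families(true_fractions)
    rows = {}
    for gene, (family, r) in config.target_correlations.items():
        if not abs(r) < 1.0:
            raise ValidationError(f"target |r| must be < 1, got {r}")
        if family not in fam.columns:
            raise ValidationError(f"family {family!r} absent from fractions")
        z = fam[family].to_numpy()
        sd = z.std()
        if sd == 0:
            raise ValidationError(f"family {family!r} has zero variance")
        z = (z - z.mean()) / sd
        track = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(z.shape)
        rows[gene] = np.clip(10.0 + 1.5 * track, 0.01, None)
    out = pd.DataFrame(rows, index=true_fractions.index).T
    out.index.name = "gene"
    out.columns.name = None
    return out


def aggregate_to_families(fractions: pd.DataFrame) -> pd.DataFrame:
    """Group fine-type fraction columns into family columns (pass-through
    if the columns already are families)."""
    if all(c in LM22_FAMILIES for c in fractions.columns):
        return fractions
    mapping = default_lm22_map().family_of
    unmapped = [c for c in fractions.columns if c not in mapping]
    if unmapped:
        raise ValidationError(f"unmapped cell types: {unmapped}")
    out = fractions.T.groupby(
        [mapping[c] for c in fractions.columns], sort=False
    ).sum().T
    return out[[f for f in LM22_FAMILIES if f in out.columns]]


def _ordinal_from_latent(
    eta: np.ndarray, cutpoints: Sequence[float], levels: Sequence[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """Ordinal draw from a proportional-odds model: P(Y <= j) = sigmoid(c_j - eta)."""
    u = rng.uniform(size=eta.shape)
    cum = np.array([1.0 / (1.0 + np.exp(-(c - eta))) for c in cutpoints]).T
    idx = (u[:, None] > cum).sum(axis=1)
    return np.asarray(levels)[idx]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# cutpoints reproduce the marginal category frequencies of the emulated
# cohort's patient table (519 graded: 14/226/204/75; 526 staged:
# 268/69/178/11; 493 with tumor status: 356 tumor-free)
_GRADE_CUTS = [_logit(14 / 519), _logit(240 / 519), _logit(444 / 519)]
_STAGE_CUTS = [_logit(268 / 526), _logit(337 / 526), _logit(515 / 526)]
_TUMOR_FREE_BASE = _logit(356 / 493)
_ALIVE_P = {"tumor-free": 0.85, "with-tumor": 0.40}
_MALE_P = 342 / 526
_LEFT_P = 247 / 534
_MISSING_RATES = {"grade": 7 / 526, "tumor_status": 33 / 526}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def make_clinical(
    true_fractions: pd.DataFrame,
    archetypes: pd.Series,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> ClinicalTable:
    """Clinical covariates linked to the true fractions.

    Grade and stage follow proportional-odds models whose latent rises
    with the CD8 fraction and falls with mast/monocyte fractions; tumor
    status is Bernoulli with log-odds of being tumor-free increasing in
    the mast (and NK) fractions; gender and laterality are independent
    coin flips at the emulated cohort's observed rates; age and overall
    survival come from fixed distributions. All links honour
    ``config.clinical_effects`` and vanish under ``ClinicalEffects.null()``.
    """
    rng = rng if rng is not None else _rng(config, 4)
    fam = aggregate_to_families(true_fractions)
    eff = config.clinical_effects
    z8 = _zscore(fam["CD8 T cells"].to_numpy())
    zmast = _zscore(fam["Mast cells"].to_numpy())
    zmono = _zscore(fam["Monocytes"].to_numpy())
    znk = _zscore(fam["NK cells"].to_numpy())
    n = fam.shape[0]

    eta_grade = eff.cd8_grade * z8 + eff.mast_grade * zmast + eff.monocyte_grade * zmono
    grade = _ordinal_from_latent(eta_grade, _GRADE_CUTS,
                                 ["G1", "G2", "G3", "G4"], rng)
    eta_stage = eff.cd8_stage * z8 + eff.mast_stage * zmast + eff.monocyte_stage * zmono
    stage = _ordinal_from_latent(eta_stage, _STAGE_CUTS,
                                 ["T1", "T2", "T3", "T4"], rng)
    logit_free = _TUMOR_FREE_BASE + eff.mast_tumor_free * zmast + eff.nk_tumor_free * znk
    p_free = 1.0 / (1.0 + np.exp(-logit_free))
    tumor_status = np.where(
        rng.uniform(size=n) < p_free, "tumor-free", "with-tumor"
    )
    alive_p = np.where(tumor_status == "tumor-free",
                       _ALIVE_P["tumor-free"], _ALIVE_P["with-tumor"])
    survival_status = np.where(rng.uniform(size=n) < alive_p, "alive", "deceased")
    gender = np.where(rng.uniform(size=n) < _MALE_P, "male", "female")
    laterality = np.where(rng.uniform(size=n) < _LEFT_P, "left", "right")
    age = np.clip(rng.normal(61.0, 12.0, size=n), 26.0, 90.0)
    overall_survival = rng.gamma(
        shape=1.5, scale=np.where(survival_status == "alive", 35.0, 18.0)
    )

    df = pd.DataFrame(
        {
            "grade": grade,
            "stage": stage,
            "tumor_status": tumor_status,
            "survival_status": survival_status,
            "gender": gender,
            "laterality": laterality,
            "age_at_diagnosis": np.round(age, 1),
            "overall_survival": np.round(overall_survival, 2),
        },
        index=fam.index,
    )
    df.index.name = "sample_id"
    # mirror the emulated cohort's missingness: a few grades and tumor
    # statuses unknown (downstream operations must report exclusions)
    for col, rate in _MISSING_RATES.items():
        mask = rng.uniform(size=n) < rate
        df.loc[mask, col] = pd.NA
    return ClinicalTable(df)


@dataclass
class Cohort:
    """One fully simulated study: inputs plus ground truth."""

    signature: SignatureMatrix
    mixture: MixtureProfile           # includes appended marker-gene tracks
    true_fractions: pd.DataFrame      # fine types
    true_family_fractions: pd.DataFrame
    archetypes: pd.Series
    clinical: ClinicalTable
    marker_tracks: pd.DataFrame


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate every input the pipeline consumes, deterministically from
    (config, seed)."""
    sig = make_signature(config)
    fractions, archetypes = make_proportions(config)
    mixture = make_mixtures(sig, fractions, config)
    tracks = make_marker_tracks(fractions, config)
    full = pd.concat([mixture.data, tracks])
    full.index.name = "gene"
    clinical = make_clinical(fractions, archetypes, config)
    return Cohort(
        signature=sig,
        mixture=MixtureProfile(full),
        true_fractions=fractions,
        true_family_fractions=aggregate_to_families(fractions),
        archetypes=archetypes,
        clinical=clinical,
        marker_tracks=tracks,
    )
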