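"""Estimate immune-cell fractions from bulk expression by nu-SVR.

The model is ``A x = b``: the bulk profile ``b`` of each sample is
regressed on the columns of the signature matrix ``A`` with a
linear-kernel nu-support-vector regression. The regression coefficients
are the raw cell-type weights; negative weights are clamped to zero and
the remainder renormalized to sum to one. nu is selected per sample from a
small grid by lowest reconstruction RMSE.

Standardization: each sample is centered and scaled over the shared genes,
and the signature matrix is standardized by its *global* mean and standard
deviation. Global (rather than per-column) standardization preserves the
relative scale of the columns, so on a noiseless mixture the exact
proportions remain a feasible regression solution; per-sample scaling
makes the estimated fractions invariant to any positive rescaling of the
sample.

Fit significance is an empirical p-value: the sample's gene labels are
permuted (breaking the gene <-> signature correspondence), the regression
is refit at the selected nu, and the p-value is the add-one-smoothed
fraction of null reconstruction correlations at least as large as the
observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .datatypes import (
    MixtureProfile,
    ProportionEstimate,
    SignatureMatrix,
    ValidationError,
)
from .io import align_genes

logger = logging.getLogger(__name__)

__all__ = [
    "DeconvolutionConfig",
    "SampleFit",
    "harmonize_mixture",
    "fit_sample",
    "empirical_pvalue",
    "deconvolve",
    "filter_by_pvalue",
]


@dataclass(frozen=True)
class DeconvolutionConfig:
    """Settings for the deconvolution stage.

    The epsilon-tube of the SVR is controlled implicitly by nu (nu lower-
    bounds the support-vector fraction and upper-bounds the training-error
    fraction), so no epsilon parameter is exposed.
    """

    nu_grid: Sequence[float] = (0.25, 0.5, 0.75)
    n_permutations: int = 100
    seed: int = 0
    # cross-platform quantile harmonization; off by default because it
    # replaces each sample's value distribution wholesale and is only
    # appropriate when signature and mixture come from different platforms
    harmonize: bool = False
    delog: bool = False  # apply 2**x - 1 to undo log2(x+1) storage before fitting
    compute_pvalues: bool = True

    def __post_init__(self) -> None:
        if len(self.nu_grid) == 0:
            raise ValidationError("nu_grid must be non-empty")
        if any(not (0.0 < nu < 1.0) for nu in self.nu_grid):
            raise ValidationError("every nu must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")


@dataclass
class SampleFit:
    """Result of fitting one sample."""

    fractions: np.ndarray
    rmse: float
    pearson_r: float
    nu_selected: float
    degenerate: bool = False
    raw_weights: Optional[np.ndarray] = field(default=None, repr=False)


def harmonize_mixture(sig: SignatureMatrix, mix: MixtureProfile) -> MixtureProfile:
    """Quantile-map each sample onto the signature's pooled distribution.

    Removes gross platform/scale differences between the mixture and the
    signature matrix while preserving within-sample gene ranks: gene ranked
    i-th in a sample is assigned the ((i + 0.5) / G)-quantile of the pooled
    signature values. A cross-platform harmonization stage in the spirit of
    batch-correcting deconvolution front ends; a rank-preserving quantile
    map, not a reimplementation of any proprietary procedure.
    """
    n_genes = mix.data.shape[0]
    if n_genes < 2:
        raise ValidationError("harmonization needs at least 2 genes")
    pool = np.sort(sig.values.ravel())
    ref = np.quantile(pool, (np.arange(n_genes) + 0.5) / n_genes)
    out = np.empty_like(mix.values)
    for j in range(out.shape[1]):
        order = np.argsort(mix.values[:, j], kind="stable")
        out[order, j] = ref
    return MixtureProfile(
        pd.DataFrame(out, index=mix.gene_ids, columns=mix.sample_ids)
    )


def _standardize(sig_values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a_std = sig_values.std()
    if a_std == 0:
        raise ValidationError("signature matrix has zero variance")
    y_std = y.std()
    if y_std == 0:
        raise ValidationError("sample has zero variance across genes")
    return (sig_values - sig_values.mean()) / a_std, (y - y.mean()) / y_std


def _svr_fit(x_std: np.ndarray, y_std: np.ndarray, nu: float):
    """One nu-SVR fit; returns (raw weights, rmse, pearson r) of A.w vs y."""
    model = NuSVR(kernel="linear", nu=nu, C=1.0)
    model.fit(x_std, y_std)
    w = model.coef_.ravel().copy()
    recon = x_std @ w + model.intercept_[0]
    rmse = float(np.sqrt(np.mean((recon - y_std) ** 2)))
    if recon.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(recon, y_std)[0, 1])
    return w, rmse, r


def fit_sample(
    sig: SignatureMatrix,
    sample_expression: np.ndarray,
    config: DeconvolutionConfig = DeconvolutionConfig(),
) -> SampleFit:
    """Deconvolve one sample: grid over nu, keep the lowest-RMSE fit.

    Negative coefficients are clamped to zero and the remainder
    renormalized to sum to one. If every coefficient is <= 0 the sample is
    flagged degenerate and gets all-zero fractions.
    """
    y = np.asarray(sample_expression, dtype=float)
    if y.shape[0] != sig.values.shape[0]:
        raise ValidationError(
            f"sample has {y.shape[0]} genes, signature has {sig.values.shape[0]}"
        )
    x_std, y_std = _standardize(sig.values, y)
    best = None
    for nu in config.nu_grid:
        w, rmse, r = _svr_fit(x_std, y_std, nu)
        if best is None or rmse < best[1]:
            best = (w, rmse, r, nu)
    w, rmse, r, nu = best
    clamped = np.clip(w, 0.0, None)
    total = clamped.sum()
    if total <= 0:
        logger.warning("degenerate sample: all SVR coefficients <= 0")
        return SampleFit(
            fractions=np.zeros_like(clamped), rmse=rmse, pearson_r=r,
            nu_selected=nu, degenerate=True, raw_weights=w,
        )
    return SampleFit(
        fractions=clamped / total, rmse=rmse, pearson_r=r,
        nu_selected=nu, degenerate=False, raw_weights=w,
    )


def empirical_pvalue(
    sig: SignatureMatrix,
    sample_expression: np.ndarray,
    fitted_r: float,
    config: DeconvolutionConfig,
    rng: Optional[np.random.Generator] = None,
    nu: Optional[float] = None,
) -> float:
    """Permutation p-value for a fitted sample.

    Builds the null by permuting the sample's gene labels and refitting at
    the selected nu; p = (1 + #{null r >= fitted r}) / (n_permutations + 1),
    so p is never exactly zero.
    """
    if config.n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if nu is None:
        nu = config.nu_grid[0]
    y = np.asarray(sample_expression, dtype=float)
    x_std, y_std = _standardize(sig.values, y)
    n_ge = 0
    for _ in range(config.n_permutations):
        perm = rng.permutation(y_std.shape[0])
        _, _, r_null = _svr_fit(x_std, y_std[perm], nu)
        if r_null >= fitted_r:
            n_ge += 1
    return (1 + n_ge) / (config.n_permutations + 1)


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    # per-sample stream derived from (seed, index): reproducible regardless
    # of evaluation order
    return np.random.default_rng(np.random.SeedSequence([seed, sample_index]))


def deconvolve(
    sig: SignatureMatrix,
    mix: MixtureProfile,
    config: DeconvolutionConfig = DeconvolutionConfig(),
) -> ProportionEstimate:
    """Full deconvolution of a mixture batch.

    Aligns genes, optionally harmonizes, then fits each sample and (if
    configured) attaches an empirical p-value. Per-sample failures
    (zero variance, degenerate coefficients) are flagged, never abort the
    batch.
    """
    sig_a, mix_a = align_genes(sig, mix)
    if config.delog:
        mix_a = MixtureProfile(np.exp2(mix_a.data) - 1.0)
    if config.harmonize:
        mix_a = harmonize_mixture(sig_a, mix_a)
    n_types = len(sig_a.cell_types)
    n_samples = len(mix_a.sample_ids)
    fractions = np.zeros((n_samples, n_types))
    diag = pd.DataFrame(
        {
            "rmse": np.nan,
            "pearson_r": np.nan,
            "p_value": np.nan,
            "nu_selected": np.nan,
            "degenerate": False,
        },
        index=mix_a.sample_ids,
    )
    for i, sample_id in enumerate(mix_a.sample_ids):
        y = mix_a.values[:, i]
        try:
            fit = fit_sample(sig_a, y, config)
        except ValidationError as exc:
            logger.warning("sample %s flagged: %s", sample_id, exc)
            diag.iloc[i, diag.columns.get_loc("degenerate")] = True
            continue
        fractions[i] = fit.fractions
        diag.iloc[i, diag.columns.get_loc("rmse")] = fit.rmse
        diag.iloc[i, diag.columns.get_loc("pearson_r")] = fit.pearson_r
        diag.iloc[i, diag.columns.get_loc("nu_selected")] = fit.nu_selected
        diag.iloc[i, diag.columns.get_loc("degenerate")] = fit.degenerate
        if config.compute_pvalues and not fit.degenerate:
            p = empirical_pvalue(
                sig_a, y, fit.pearson_r, config,
                rng=_sample_rng(config.seed, i), nu=fit.nu_selected,
            )
            diag.iloc[i, diag.columns.get_loc("p_value")] = p
        if (i + 1) % 50 == 0 or i + 1 == n_samples:
            logger.info("deconvolved %d/%d samples", i + 1, n_samples)
    return ProportionEstimate(
        fractions=pd.DataFrame(
            fractions, index=mix_a.sample_ids, columns=sig_a.cell_types
        ),
        diagnostics=diag,
    )


def filter_by_pvalue(est: ProportionEstimate, alpha: float = 0.05) -> ProportionEstimate:
    """Keep samples whose deconvolution p-value is below ``alpha``."""
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must lie in (0, 1], got {alpha}")
    if alpha == 1.0:  # vacuous filter: p is always <= 1
        keep = pd.Series(True, index=est.sample_ids)
    else:
        keep = est.diagnostics["p_value"] < alpha
    n_keep, n_total = int(keep.sum()), len(keep)
    logger.info(
        "p-value filter at alpha=%g: retained %d/%d samples",
        alpha, n_keep, n_total,
    )
    if n_keep == 0:
        logger.warning("p-value filter removed every sample")
    return ProportionEstimate(
        fractions=est.fractions.loc[keep],
        diagnostics=est.diagnostics.loc[keep],
    )
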