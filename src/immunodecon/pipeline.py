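"""End-to-end orchestration: simulate -> deconvolve -> aggregate -> cluster -> associate.

Each stage reads its predecessors' files from the run directory and writes
its own outputs there, so any prefix of the pipeline can be rerun or
inspected. A ``manifest.json`` records package/library versions, the seed,
input file hashes and sample counts before/after the deconvolution
p-value filter. Stage outputs are pure functions of (inputs, config,
seed): a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import __version__
from .aggregation import aggregate, default_lm22_map
from .clustering import (
    ImmuneClassModel,
    kmeans_fit,
    name_clusters,
    select_k_elbow,
)
from .datatypes import ValidationError
from .deconvolution import DeconvolutionConfig, deconvolve, filter_by_pvalue
from .io import (
    read_clinical,
    read_expression_matrix,
    read_proportions,
    write_clinical,
    write_json,
    write_proportions,
)
from .stats import (
    compare_fraction_by_clinical,
    crosstab_cluster_vs_clinical,
    gene_fraction_correlation,
)
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

STAGES = ("simulate", "deconvolve", "aggregate", "cluster", "associate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full run. Every field has a workable default, so
    ``PipelineConfig(out_dir=...)`` reproduces the synthetic study."""

    out_dir: Union[str, Path] = "run"
    stages: Sequence[str] = STAGES
    seed: int = 0
    # simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # deconvolve (n_permutations kept modest for batch runs)
    nu_grid: Sequence[float] = (0.25, 0.5, 0.75)
    n_permutations: int = 50
    harmonize: bool = False
    delog: bool = False
    alpha: float = 0.05
    # external inputs (used when the simulate stage is disabled)
    signature_path: Optional[str] = None
    mixture_path: Optional[str] = None
    clinical_path: Optional[str] = None
    # cluster
    k: Optional[int] = None          # None -> elbow selection over k_range
    k_range: Sequence[int] = tuple(range(1, 11))
    n_restarts: int = 10
    tau: float = 0.02
    # associate
    association_tests: Sequence[str] = ("grade", "stage", "tumor_status")
    focal_family: str = "CD8 T cells"
    marker_genes: Sequence[str] = ("PDCD1", "INFG", "RGS5")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen:
            eff = gen.pop("clinical_effects", None)
            gcfg = GeneratorConfig(**gen) if eff is None else GeneratorConfig(
                **gen, clinical_effects=type(GeneratorConfig().clinical_effects)(**eff)
            )
            cfg.generator = gcfg
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: missing input file {path}")
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    A stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are retained.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    manifest: dict = {
        "immunodecon_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "inputs": {},
        "counts": {},
    }
    try:
        enabled = [s for s in STAGES if s in config.stages]
        unknown = set(config.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stage(s): {sorted(unknown)}")

        sig_path = Path(config.signature_path) if config.signature_path else out / "signature.tsv"
        mix_path = Path(config.mixture_path) if config.mixture_path else out / "mixture.tsv"
        clin_path = Path(config.clinical_path) if config.clinical_path else out / "clinical.csv"

        if "simulate" in enabled:
            _run_stage("simulate", _simulate, config, out, manifest)
        if "deconvolve" in enabled:
            for p in (sig_path, mix_path):
                _require(p, "deconvolve")
            manifest["inputs"]["signature"] = _sha256(sig_path)
            manifest["inputs"]["mixture"] = _sha256(mix_path)
            _run_stage("deconvolve", _deconvolve, config, out, manifest,
                       sig_path, mix_path)
        if "aggregate" in enabled:
            _require(out / "fractions_filtered.tsv", "aggregate")
            _run_stage("aggregate", _aggregate, config, out, manifest)
        if "cluster" in enabled:
            _require(out / "family_fractions.tsv", "cluster")
            _run_stage("cluster", _cluster, config, out, manifest)
        if "associate" in enabled:
            for p in (out / "family_fractions.tsv", clin_path):
                _require(p, "associate")
            _run_stage("associate", _associate, config, out, manifest,
                       clin_path, mix_path)
    finally:
        write_json(manifest, out / "manifest.json")
        logging.getLogger().removeHandler(fh)
        fh.close()
    return out


def _run_stage(name, fn, config, out, manifest, *args) -> None:
    logger.info("=== stage %s ===", name)
    try:
        fn(config, out, manifest, *args)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def _simulate(config: PipelineConfig, out: Path, manifest: dict) -> None:
    gen = config.generator
    if gen.seed != config.seed:
        gen = type(gen)(**{**asdict(gen), "seed": config.seed,
                           "clinical_effects": gen.clinical_effects,
                           "target_correlations": gen.target_correlations})
    cohort = generate_cohort(gen)
    cohort.signature.data.to_csv(out / "signature.tsv", sep="\t",
                                 index_label="gene", float_format="%.17g")
    cohort.mixture.data.to_csv(out / "mixture.tsv", sep="\t",
                               index_label="gene", float_format="%.17g")
    cohort.true_fractions.to_csv(out / "true_fractions.tsv", sep="\t",
                                 index_label="sample_id", float_format="%.17g")
    cohort.archetypes.to_frame().to_csv(out / "archetypes.csv",
                                        index_label="sample_id")
    write_clinical(cohort.clinical, out / "clinical.csv")
    manifest["counts"]["simulated_samples"] = int(gen.n_samples)


def _deconvolve(config: PipelineConfig, out: Path, manifest: dict,
                sig_path: Path, mix_path: Path) -> None:
    sig = read_expression_matrix(sig_path, "signature")
    mix = read_expression_matrix(mix_path, "mixture")
    dcfg = DeconvolutionConfig(
        nu_grid=tuple(config.nu_grid), n_permutations=config.n_permutations,
        seed=config.seed, harmonize=config.harmonize, delog=config.delog,
    )
    if config.alpha < 1.0 / (config.n_permutations + 1):
        logger.warning(
            "alpha=%g is below the attainable p-value floor 1/(n_permutations+1)"
            "=%g; every sample would be filtered out",
            config.alpha, 1.0 / (config.n_permutations + 1),
        )
    est = deconvolve(sig, mix, dcfg)
    write_proportions(est, out / "fractions.tsv")
    kept = filter_by_pvalue(est, config.alpha)
    write_proportions(kept, out / "fractions_filtered.tsv")
    manifest["counts"]["deconvolved_samples"] = int(len(est.sample_ids))
    manifest["counts"]["samples_after_pvalue_filter"] = int(len(kept.sample_ids))


def _aggregate(config: PipelineConfig, out: Path, manifest: dict) -> None:
    est = read_proportions(out / "fractions_filtered.tsv")
    fam = aggregate(est, default_lm22_map())
    write_proportions(fam, out / "family_fractions.tsv")
    manifest["counts"]["families"] = int(len(fam.cell_types))


def _cluster(config: PipelineConfig, out: Path, manifest: dict) -> None:
    fam = read_proportions(out / "family_fractions.tsv")
    profile: dict[int, float] = {}
    if config.k is None:
        k, profile = select_k_elbow(fam.fractions, config.k_range,
                                    seed=config.seed,
                                    n_restarts=config.n_restarts)
    else:
        k = config.k
    model = kmeans_fit(fam.fractions, k, seed=config.seed,
                       n_restarts=config.n_restarts, inertia_profile=profile)
    model.archetype_names = name_clusters(model, tau=config.tau)
    write_json(model, out / "immune_classes.json")
    manifest["counts"]["k_selected"] = int(k)


def _associate(config: PipelineConfig, out: Path, manifest: dict,
               clin_path: Path, mix_path: Path) -> None:
    fam = read_proportions(out / "family_fractions.tsv")
    clinical = read_clinical(clin_path)
    results: dict = {"fraction_comparisons": {}, "crosstabs": {},
                     "gene_correlations": {}}
    model = None
    model_path = out / "immune_classes.json"
    if model_path.exists():
        with open(model_path, encoding="utf-8") as fhm:
            model = ImmuneClassModel.from_dict(json.load(fhm))
    for grouping in config.association_tests:
        res = compare_fraction_by_clinical(fam, clinical, config.focal_family,
                                           grouping)
        results["fraction_comparisons"][grouping] = {
            stratum: r.to_dict() for stratum, r in res.items()
        }
        if model is not None:
            col = {"grade": "grade", "stage": "stage",
                   "tumor_status": "tumor_status"}.get(grouping, grouping)
            tr, table = crosstab_cluster_vs_clinical(model, clinical, col)
            results["crosstabs"][grouping] = {
                "test": tr.to_dict(),
                "table": {r: {c: int(table.loc[r, c]) for c in table.columns}
                          for r in table.index},
            }
    if mix_path.exists():
        mix = read_expression_matrix(mix_path, "mixture")
        for gene in config.marker_genes:
            if gene not in mix.gene_ids:
                continue
            fam_target = config.generator.target_correlations.get(
                gene, (config.focal_family, None)
            )[0]
            try:
                tr = gene_fraction_correlation(mix, fam, gene, fam_target)
            except ValidationError as exc:
                logger.warning("gene correlation %s skipped: %s", gene, exc)
                continue
            results["gene_correlations"][gene] = tr.to_dict()
    write_json(results, out / "associations.json")
    manifest["counts"]["association_tests"] = sum(
        len(v) for v in results.values()
    )
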