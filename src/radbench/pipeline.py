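"""End-to-end orchestration: simulate -> dose-response -> GSEA -> benchmark.

A :class:`RunConfig` (loadable from YAML) carries every stage's parameters
and seeds; :func:`run_all` executes the stages in order, writing plain-text
artifacts plus a machine-readable manifest with input hashes, seeds and
the package version.  Reruns with an identical config produce
byte-identical numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .dose_response import compute_profiles
from .enrichment import gsea, rank_genes, results_to_frame
from .evaluation import benchmark, reports_to_json
from .io import (
    file_sha256,
    load_gmt,
    write_curves,
    write_expression,
    write_gmt,
    write_manifest,
)
from .predictors import ModelSpec, MODEL_NAMES
from .synthetic_data import CohortConfig, generate_gene_sets, generate_paired_cohorts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    discovery: CohortConfig = field(default_factory=CohortConfig)
    validation: CohortConfig = field(
        default_factory=lambda: CohortConfig(
            n_samples=60, n_tissues=9, dose_grid=(2.0, 4.0, 6.0), seed=1
        )
    )
    shared_gene_fraction: float = 1.0
    dose_range: tuple[float, float] = (0.0, 8.0)
    seed: int = 0
    # gene sets: either a GMT path or generation parameters
    gmt_path: str | None = None
    n_sets: int = 200
    n_planted: int = 10
    set_size_range: tuple[int, int] = (15, 100)
    # gsea
    n_perm: int = 1000
    fdr_threshold: float = 0.05
    min_set_size: int = 15
    max_set_size: int = 500
    # predictors / evaluation
    models: tuple[str, ...] = MODEL_NAMES
    signature_size: int = 30
    n_keep: int = 1000
    mrmr_K: int = 10
    alpha_mix: float = 0.5
    n_lambda: int = 100
    inner_folds: int = 10
    n_folds: int = 10
    n_iterations: int = 10
    n_repeats: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.shared_gene_fraction <= 1:
            raise ValueError("shared_gene_fraction must lie in (0, 1]")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.gmt_path is not None and not Path(self.gmt_path).is_file():
            raise FileNotFoundError(f"gene-set file not found: {self.gmt_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("discovery", "validation"):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                if "dose_grid" in sub:
                    sub["dose_grid"] = tuple(float(d) for d in sub["dose_grid"])
                kwargs[key] = CohortConfig(**sub)
        for key in ("dose_range", "set_size_range", "models"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def model_specs(self) -> list[ModelSpec]:
        return [
            ModelSpec(
                name=name,
                signature_size=self.signature_size,
                n_keep=self.n_keep,
                K=self.mrmr_K,
                alpha_mix=self.alpha_mix,
                n_lambda=self.n_lambda,
                inner_folds=self.inner_folds,
            )
            for name in self.models
        ]


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the manifest dict.

    Stage failures raise after the already-produced artifacts are flushed,
    with the failing stage named in the log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }
    t0 = time.time()

    stage = "simulate"
    logger.info("stage %s", stage)
    disc, valid = generate_paired_cohorts(
        config.discovery, config.validation, config.shared_gene_fraction
    )
    cohorts = {"discovery": disc, "validation": valid}
    for name, cohort in cohorts.items():
        write_expression(cohort.expression, out / f"{name}_expression.tsv")
        write_curves(cohort.curves, out / f"{name}_curves.csv")
        (out / f"{name}_truth.json").write_text(cohort.truth.to_json())
    manifest["stages"][stage] = {
        "n_common_genes": len(
            set(disc.gene_ids) & set(valid.gene_ids)
        ),
        "discovery_seed": config.discovery.seed,
        "validation_seed": config.validation.seed,
    }

    stage = "dose_response"
    logger.info("stage %s", stage)
    profiles = {}
    for name, cohort in cohorts.items():
        profile = compute_profiles(cohort.curves, config.dose_range)
        profile.to_frame().to_csv(
            out / f"{name}_profile.csv", index=False, float_format="%.10g"
        )
        profiles[name] = profile
        manifest["stages"].setdefault(stage, {})[name] = {
            "n_fitted": len(profile.sample_ids),
            "n_excluded": len(profile.excluded),
        }

    stage = "gene_sets"
    logger.info("stage %s", stage)
    if config.gmt_path is not None:
        collection = load_gmt(config.gmt_path)
    else:
        collection = generate_gene_sets(
            universe=disc.gene_ids,
            signal_genes=disc.truth.signal_gene_ids,
            n_sets=config.n_sets,
            n_planted=config.n_planted,
            size_range=config.set_size_range,
            seed=config.seed,
            signal_signs=disc.truth.signal_signs,
        )
        write_gmt(collection, out / "gene_sets.gmt")
    manifest["stages"][stage] = {"n_sets": len(collection)}

    stage = "gsea"
    logger.info("stage %s", stage)
    y_d = profiles["discovery"].y("sf2")
    ranking = rank_genes(disc.expression[y_d.index], y_d)
    results = gsea(
        ranking,
        collection,
        n_perm=config.n_perm,
        min_size=config.min_set_size,
        max_size=config.max_set_size,
        seed=config.seed,
    )
    frame = results_to_frame(results)
    frame.to_csv(out / "enrichment.csv", index=False, float_format="%.10g")
    n_sig = int((frame["fdr_q"] < config.fdr_threshold).sum()) if len(frame) else 0
    manifest["stages"][stage] = {
        "n_tested": len(frame),
        "n_significant": n_sig,
        "n_perm": config.n_perm,
        "seed": config.seed,
    }

    stage = "benchmark"
    logger.info("stage %s", stage)
    discovery_xy = (
        disc.expression[y_d.index],
        y_d.to_numpy(float),
    )
    y_v = profiles["validation"].y("sf2")
    validation_xy = (valid.expression[y_v.index], y_v.to_numpy(float))
    reports, table = benchmark(
        config.model_specs(),
        discovery_xy,
        validation_xy,
        n_folds=config.n_folds,
        n_iterations=config.n_iterations,
        n_repeats=config.n_repeats,
        seed=config.seed,
    )
    table.to_csv(out / "benchmark.csv", index=False, float_format="%.10g")
    (out / "benchmark.json").write_text(reports_to_json(reports))
    manifest["stages"][stage] = {"n_models": len(config.models), "seed": config.seed}

    for artifact in sorted(out.iterdir()):
        if artifact.name != "manifest.json" and artifact.is_file():
            manifest["artifacts"][artifact.name] = file_sha256(artifact)
    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    write_manifest(manifest, out / "manifest.json")
    return manifest
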