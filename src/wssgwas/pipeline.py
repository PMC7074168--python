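"""Configuration, file round-tripping, and the end-to-end pipeline driver.

All derived artifacts are plain-text TSV (matrices as i/j/value triplets) so
every intermediate is inspectable; a JSON manifest records input checksums and
per-stage dimensions for every run.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import __version__
from .annotation import annotate_windows, read_bed_genes, read_gff3_genes
from .association import WeightedSingleStepGWAS, windows_to_frame
from .exceptions import ConfigurationError
from .mixed_model import ModelSpec, summarize_trait
from .pedigree import Pedigree
from .plink import read_plink
from .qc import apply_genotype_qc


@dataclass
class TraitModelConfig:
    """Per-trait model settings."""

    trait: str
    factors: tuple = ("sex", "year", "use_type", "farm")
    covariates: tuple = ("age_days",)

    def to_spec(self) -> ModelSpec:
        return ModelSpec(self.trait, tuple(self.factors), tuple(self.covariates))


@dataclass
class AnalysisConfig:
    """Whole-run configuration (paths, thresholds, wssGWAS settings)."""

    pedigree_path: str
    genotype_prefix: str
    phenotype_path: str
    traits: list = field(default_factory=list)
    genes_path: str | None = None
    qc: dict = field(default_factory=dict)
    iterations: int = 3
    window_size: int = 20
    threshold_percent: float = 1.0
    beta: float = 0.95
    reml_method: str = "em"
    seed: int = 0
    out_dir: str = "wssgwas_out"

    def __post_init__(self) -> None:
        if not self.traits:
            raise ConfigurationError("config lists no traits to analyse")
        self.traits = [
            t if isinstance(t, TraitModelConfig) else TraitModelConfig(**t)
            for t in self.traits
        ]
        for name, lo in (("iterations", 1), ("window_size", 2)):
            if getattr(self, name) < lo:
                raise ConfigurationError(f"{name} must be >= {lo}")
        if not (0.0 < self.beta <= 1.0):
            raise ConfigurationError("beta must be in (0, 1]")

    def validate_paths(self) -> None:
        missing = [
            p
            for p in (self.pedigree_path, self.phenotype_path)
            if not Path(p).exists()
        ]
        if self.genes_path and not Path(self.genes_path).exists():
            missing.append(self.genes_path)
        gp = Path(str(self.genotype_prefix) + ".bed")
        gp2 = Path(str(self.genotype_prefix) + ".ped")
        if not gp.exists() and not gp2.exists():
            missing.append(str(self.genotype_prefix) + ".{bed,ped}")
        if missing:
            raise ConfigurationError(f"input files not found: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad config file {path}: {exc}") from None


@dataclass
class RunManifest:
    """Provenance record emitted by every pipeline run."""

    version: str
    config_hash: str
    input_checksums: dict
    stages: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_triplets(matrix, ids, path) -> None:
    """Write a (sparse or dense) matrix as an indexed i/j/value TSV."""
    M = sp.coo_matrix(matrix)
    pd.DataFrame(
        {"i": np.asarray(ids, dtype=object)[M.row],
         "j": np.asarray(ids, dtype=object)[M.col],
         "value": M.data}
    ).to_csv(path, sep="\t", index=False)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    return Pedigree.from_frame(df)


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    pedigree.to_frame().to_csv(path, index=False)


def run_pipeline(config: AnalysisConfig) -> RunManifest:
    """QC -> relationships -> REML -> wssGWAS -> selection -> annotation.

    Writes per-trait window tables, GEBV tables, variance components and a
    manifest under ``config.out_dir``; aborts with the stage name on error.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        "pedigree": _sha256(config.pedigree_path),
        "phenotypes": _sha256(config.phenotype_path),
    }
    for ext in (".bed", ".bim", ".fam", ".ped", ".map"):
        p = Path(str(config.genotype_prefix) + ext)
        if p.exists():
            inputs[f"genotypes{ext}"] = _sha256(p)
    if config.genes_path:
        inputs["genes"] = _sha256(config.genes_path)
    cfg_hash = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in sorted(config.__dict__.items())}, sort_keys=True
        ).encode()
    ).hexdigest()
    manifest = RunManifest(__version__, cfg_hash, inputs, started=time.time())

    stage = "load"
    try:
        pedigree = read_pedigree_csv(config.pedigree_path)
        genotypes = read_plink(config.genotype_prefix)
        phenotypes = pd.read_csv(config.phenotype_path)
        phenotypes["id"] = phenotypes["id"].astype(str)
        manifest.stages["load"] = {
            "pedigree_animals": len(pedigree),
            "genotyped_animals": genotypes.n_animals,
            "snps": genotypes.n_snps,
            "phenotype_records": len(phenotypes),
        }

        stage = "qc"
        genotypes, report = apply_genotype_qc(genotypes, **config.qc)
        manifest.stages["qc"] = {
            "animals_removed": report.n_individuals_removed_call_rate,
            "snps_removed_call_rate": report.n_snps_removed_call_rate,
            "snps_removed_maf": report.n_snps_removed_maf,
            "snps_removed_hwe": report.n_snps_removed_hwe,
            "snps_removed_position": report.n_snps_removed_position,
            "snps_retained": report.n_snps_out,
            "thresholds": report.thresholds,
        }
        pd.DataFrame([manifest.stages["qc"]]).to_csv(
            out / "qc_report.tsv", sep="\t", index=False
        )

        per_trait_selected = []
        for tcfg in config.traits:
            stage = f"trait:{tcfg.trait}"
            spec = tcfg.to_spec()
            phen = phenotypes.dropna(subset=[tcfg.trait]).copy()
            model = WeightedSingleStepGWAS(phen, pedigree, genotypes, spec=spec)
            res = model.fit(
                iterations=config.iterations,
                window_size=config.window_size,
                threshold_percent=config.threshold_percent,
                beta=config.beta,
                reml_method=config.reml_method,
            )
            s = summarize_trait(phen[tcfg.trait])
            pd.DataFrame(
                [
                    {
                        "trait": tcfg.trait,
                        "N": s.n,
                        "mean": s.mean,
                        "SD": s.sd,
                        "min": s.min,
                        "max": s.max,
                        "CV_percent": s.cv_percent,
                        "sigma_a2": res.vc.sigma_a2,
                        "sigma_e2": res.vc.sigma_e2,
                        "sigma_p2": res.vc.sigma_p2,
                        "h2": res.vc.h2,
                        "se_h2": res.vc.se_h2,
                    }
                ]
            ).to_csv(out / f"{tcfg.trait}_variance_components.tsv", sep="\t", index=False)
            windows_to_frame(res.run.window_profiles[-1]).to_csv(
                out / f"{tcfg.trait}_window_profile.tsv", sep="\t", index=False
            )
            sel_frame = res.selected_frame()
            sel_frame.to_csv(out / f"{tcfg.trait}_selected_windows.tsv", sep="\t", index=False)
            per_trait_selected.append(res.selected)
            for it, (w, u) in enumerate(zip(res.run.weights, res.run.effects), 1):
                pd.DataFrame(
                    {"snp": genotypes.snp_map["snp"], "weight": w.d, "effect": u.u}
                ).to_csv(out / f"{tcfg.trait}_iter{it}_snp.tsv", sep="\t", index=False)
            manifest.stages[f"wssgwas:{tcfg.trait}"] = {
                "records": len(phen),
                "h2": res.vc.h2,
                "selected_windows": len(res.selected),
                "backsolve_relative_deviation": res.run.backsolve_relative_deviation,
            }

        stage = "annotation"
        if config.genes_path:
            gp = str(config.genes_path)
            genes = (
                read_gff3_genes(gp)
                if gp.endswith((".gff", ".gff3"))
                else read_bed_genes(gp)
            )
            for tcfg, selected in zip(config.traits, per_trait_selected):
                annotate_windows(selected, genes, genotypes.snp_map).to_csv(
                    out / f"{tcfg.trait}_candidate_genes.tsv", sep="\t", index=False
                )

        stage = "union"
        from .association import nonredundant_union

        union = nonredundant_union(per_trait_selected)
        windows_to_frame(union).to_csv(
            out / "nonredundant_windows.tsv", sep="\t", index=False
        )
        manifest.stages["union"] = {"nonredundant_windows": len(union)}
    except Exception:
        manifest.finished = time.time()
        manifest.stages["failed_stage"] = stage
        manifest.write(out / "manifest.json")
        raise
    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest
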