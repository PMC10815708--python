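"""End-to-end pipeline: load configured inputs, run the prioritization
cascade, annotate the survivors, and write the result tables.

The config (YAML or dict) names the per-sample per-caller VCF manifest, the
phenotype table, the gene model, the blacklists and the annotation tables,
plus the cascade thresholds.  Outputs: candidate TSV, population-database
match TSV, merged expression matrix TSV, a JSON stage report with survivor
counts per filter, and optionally a heatmap image.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import io as svio
from .cohort import partition_by_thi
from .expression import ExpressionDataset, expression_summary, read_ortholog_map
from .model import ACMGClass, CandidateRegion, Subgroup
from .popdb import annotate_popdb, join_constraints
from .prioritize import (
    DEFAULT_KEEP_ACMG,
    GeneIndex,
    PrioritizationParams,
    run_prioritization,
)

logger = logging.getLogger("svprior")


@dataclass
class PipelineConfig:
    vcf_manifest: str
    phenotype: str
    gene_bed: str
    flags_list: str
    olfactory_list: str
    population_db: Optional[str] = None
    constraints: Optional[str] = None
    expression: List[dict] = field(default_factory=list)  # [{name, path}, ...]
    ortholog_map: Optional[str] = None
    out_dir: str = "svprior_results"
    thi_threshold: Optional[float] = None
    acmg_key: str = "ACMG"
    min_ro: float = 0.60
    min_samples: int = 2
    min_callers: int = 2
    max_sv_length: int = 100_000
    keep_acmg: Tuple[str, ...] = tuple(sorted(c.value for c in DEFAULT_KEEP_ACMG))
    breakpoint_tol: int = 200
    overlap_mode: str = "reciprocal"
    uniqueness_against: str = "clusters"
    heatmap: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def params(self) -> PrioritizationParams:
        return PrioritizationParams(
            max_sv_length=self.max_sv_length,
            keep_acmg=frozenset(ACMGClass(v) for v in self.keep_acmg),
            min_ro=self.min_ro,
            min_samples=self.min_samples,
            min_callers=self.min_callers,
            breakpoint_tol=self.breakpoint_tol,
            overlap_mode=self.overlap_mode,
            uniqueness_against=self.uniqueness_against,
        )


def load_manifest_calls(manifest_path, acmg_key: str = "ACMG"):
    """Read every VCF listed in the manifest (columns: sample, caller, path)
    into per-caller call lists."""
    manifest = pd.read_csv(manifest_path, sep="\t")
    for col in ("sample", "caller", "path"):
        if col not in manifest.columns:
            raise svio.FormatError(f"{manifest_path}: missing column {col!r}")
    calls_by_caller: Dict[str, list] = {}
    for row in manifest.itertuples(index=False):
        calls = svio.read_caller_vcf(
            row.path, caller_id=str(row.caller), sample_id=str(row.sample),
            acmg_key=acmg_key,
        )
        calls_by_caller.setdefault(str(row.caller), []).extend(calls)
    return calls_by_caller


def run_pipeline(config: PipelineConfig) -> Tuple[List[CandidateRegion], dict]:
    """Execute the whole cascade from files; returns (candidates, report)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load inputs"
    try:
        cohort = svio.read_phenotype(config.phenotype)
        cohort = partition_by_thi(cohort, threshold_override=config.thi_threshold)
        genes = svio.read_gene_bed(config.gene_bed)
        gene_index = GeneIndex(genes)
        flags = svio.read_gene_list(config.flags_list)
        olfactory = svio.read_gene_list(config.olfactory_list)
        calls_by_caller = load_manifest_calls(config.vcf_manifest, config.acmg_key)

        stage = "prioritization cascade"
        candidates, report = run_prioritization(
            calls_by_caller,
            severe_samples=cohort.samples_in(Subgroup.SEVERE),
            nonsevere_samples=cohort.samples_in(Subgroup.NON_SEVERE),
            gene_index=gene_index,
            flags_list=flags,
            olfactory_list=olfactory,
            params=config.params(),
        )

        stage = "population-database annotation"
        if config.population_db:
            db = svio.read_population_db(config.population_db)
            annotate_popdb(candidates, db)
            svio.write_popdb_match_table(candidates, out_dir / "popdb_matches.tsv")
            report["popdb"] = {
                "candidates_with_match": sum(1 for c in candidates if c.popdb_matches),
                "candidates_absent": sum(1 for c in candidates if not c.popdb_matches),
            }

        stage = "constraint annotation"
        if config.constraints:
            constraints = svio.read_constraints(config.constraints)
            join_constraints(candidates, constraints)

        stage = "expression summarization"
        if config.expression:
            datasets = [
                ExpressionDataset.from_tsv(e["path"], name=e["name"], unit=e.get("unit", ""))
                for e in config.expression
            ]
            ortho = read_ortholog_map(config.ortholog_map) if config.ortholog_map else None
            candidate_genes = set().union(
                *(c.gene_symbols for c in candidates)
            ) if candidates else set()
            display = expression_summary(datasets, ortho, genes=candidate_genes or None)
            display.to_csv(out_dir / "expression_matrix.tsv", sep="\t", index_label="gene")
            if config.heatmap and not display.empty:
                from .expression import plot_heatmap

                plot_heatmap(display, out_dir / "expression_heatmap.png")

        stage = "write outputs"
        svio.write_candidate_table(candidates, out_dir / "candidates.tsv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc

    return candidates, report
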