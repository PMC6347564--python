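"""End-to-end orchestration from a single YAML config.

Stages: (simulate | read inputs) -> callable filtering -> per-gene and
per-set diversity with bootstrap CIs -> diversity-tail GO enrichment ->
report.  One global seed deterministically derives per-stage seeds
(keyed by stage name and individual), so reruns with the same config
are byte-identical and adding a stage never shifts another stage's
random stream.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from ._utils import derive_seed
from .diversity import age_diversity_correlation
from .enrichment import enrichment_table, hypergeom_enrich, mean_gene_ratios, tail_genes
from .filters import FilterConfig, gc_track_from_fasta
from .model import GeneDiversityModel, GeneDiversityResults
from .simulate import presets, simulate_genome, write_dataset

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration schema (unknown keys rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IndividualConfig(_Strict):
    id: str
    age: Optional[float] = None          # specimen age in years
    vcf: Optional[str] = None            # files mode only
    roh_bed: Optional[str] = None        # optional ROH tracts to exclude


class FiltersConfig(_Strict):
    mq_min: float = 25.0
    min_depth: int = 10
    coverage_quantiles: Tuple[float, float] = (0.025, 0.975)
    gc_window: int = 201
    gc_bin_width: float = 0.05
    min_bin_sites: int = 100

    def to_filter_config(self) -> FilterConfig:
        return FilterConfig(
            mq_min=self.mq_min,
            min_depth=self.min_depth,
            coverage_quantiles=tuple(self.coverage_quantiles),
            gc_window=self.gc_window,
            gc_bin_width=self.gc_bin_width,
            min_bin_sites=self.min_bin_sites,
        )


class DiversityConfig(_Strict):
    min_callable: int = 2000
    require_outgroup: bool = True
    background_min_length: int = 500
    flank_bp: int = 1000


class BootstrapConfig(_Strict):
    B: int = 5000
    quantiles: Tuple[float, float] = (0.025, 0.975)

    @field_validator("B")
    @classmethod
    def _b_positive(cls, v):
        if v < 1:
            raise ValueError("bootstrap B must be >= 1")
        return v


class EnrichmentConfig(_Strict):
    tail_fraction: float = 0.05
    min_category_size: int = 2
    k_override: Optional[int] = None


class InputsConfig(_Strict):
    genes: Optional[str] = None
    uniqueness_bed: Optional[str] = None
    repeats_bed: Optional[str] = None
    outgroup: Optional[str] = None
    gene_sets: Optional[str] = None
    go_genes: Optional[str] = None
    go_names: Optional[str] = None
    reference_fasta: Optional[str] = None
    chrom_lengths: Optional[Dict[str, int]] = None


class RunConfig(_Strict):
    seed: int = 1
    output_dir: str = "genediv_out"
    preset: Optional[str] = None         # synthetic mode
    preset_overrides: Dict[str, float] = Field(default_factory=dict)
    write_synthetic: bool = False
    individuals: List[IndividualConfig] = Field(default_factory=list)
    test_sets: List[str] = Field(default_factory=list)  # default: all non-background
    background_set: str = "background"
    age_correlation_set: Optional[str] = None
    filters: FiltersConfig = Field(default_factory=FiltersConfig)
    diversity: DiversityConfig = Field(default_factory=DiversityConfig)
    bootstrap: BootstrapConfig = Field(default_factory=BootstrapConfig)
    enrichment: EnrichmentConfig = Field(default_factory=EnrichmentConfig)
    inputs: InputsConfig = Field(default_factory=InputsConfig)

    @field_validator("individuals")
    @classmethod
    def _unique_ids(cls, v):
        ids = [i.id for i in v]
        if len(ids) != len(set(ids)):
            raise ValueError("individual ids must be unique")
        return v


def validate_config(config_path: str) -> RunConfig:
    """Parse and validate the YAML run config; fills all defaults and
    rejects unknown keys (typo safety)."""
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    if cfg.preset is None:
        missing = [i.id for i in cfg.individuals if i.vcf is None]
        if missing or not cfg.individuals:
            raise ValueError(
                "files mode requires a vcf per individual "
                f"(missing for: {missing or 'all'})"
            )
        for name in ("genes", "outgroup", "gene_sets"):
            if getattr(cfg.inputs, name) is None:
                raise ValueError(f"files mode requires inputs.{name}")
        for ind in cfg.individuals:
            for p in (ind.vcf, ind.roh_bed):
                if p is not None and not os.path.exists(p):
                    raise ValueError(f"missing input file: {p}")
        for name in vars(cfg.inputs):
            p = getattr(cfg.inputs, name)
            if isinstance(p, str) and not os.path.exists(p):
                raise ValueError(f"missing input file: {p}")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    canon = yaml.safe_dump(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    config: RunConfig
    config_hash: str
    seed: int
    results: Dict[str, GeneDiversityResults]
    set_summary: pd.DataFrame
    enrichment_top: Optional[pd.DataFrame]
    enrichment_bottom: Optional[pd.DataFrame]
    age_correlation: Optional[float]
    output_paths: Dict[str, str] = field(default_factory=dict)

    def table_hash(self) -> str:
        """Hash of all emitted tables — the reproducibility fingerprint."""
        h = hashlib.sha256()
        for ind in sorted(self.results):
            h.update(self.results[ind].gene_table.to_csv().encode())
        h.update(self.set_summary.to_csv().encode())
        for df in (self.enrichment_top, self.enrichment_bottom):
            if df is not None:
                h.update(df.to_csv().encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage assembly
# ---------------------------------------------------------------------------

def _build_models(cfg: RunConfig):
    """Assemble per-individual GeneDiversityModels from preset or files."""
    fc = cfg.filters.to_filter_config()
    div = cfg.diversity

    if cfg.preset is not None:
        table = presets(seed=cfg.seed)
        if cfg.preset not in table:
            raise ValueError(f"unknown preset {cfg.preset!r}; "
                             f"choose from {sorted(table)}")
        from .simulate import apply_overrides

        spec = table[cfg.preset]
        if cfg.preset_overrides:
            spec = apply_overrides(spec, cfg.preset_overrides)
        ids = [i.id for i in cfg.individuals] or ["ind1"]
        ds = simulate_genome(spec, individual_ids=ids)
        if cfg.write_synthetic:
            write_dataset(ds, os.path.join(cfg.output_dir, "synthetic"))
        models = {}
        for ind in ids:
            exclude = ds.shared.roh if not ds.shared.roh.is_empty() else None
            models[ind] = GeneDiversityModel(
                ds.callsets[ind], ds.genes, ds.shared.outgroup,
                gene_sets=ds.gene_sets,
                reference_gc={spec.chrom: ds.shared.gc},
                keep_masks=[ds.shared.uniqueness_mask],
                remove_masks=[ds.shared.repeat_mask],
                exclude=exclude,
                filter_config=fc,
                min_callable=div.min_callable,
                require_outgroup=div.require_outgroup,
                premask=ds.shared.site_premask(),
                site_gc=ds.shared.site_gc(),
            )
        go = ds.go
        return models, go

    # files mode
    from . import io as gio

    genes = gio.read_genes(cfg.inputs.genes, flank_bp=div.flank_bp,
                           chrom_lengths=cfg.inputs.chrom_lengths)
    outgroup = gio.read_outgroup(cfg.inputs.outgroup)
    gene_sets = gio.read_gene_sets(cfg.inputs.gene_sets, cfg.background_set)
    keep = [gio.read_mask(cfg.inputs.uniqueness_bed)] if cfg.inputs.uniqueness_bed else []
    remove = [gio.read_mask(cfg.inputs.repeats_bed)] if cfg.inputs.repeats_bed else []
    reference_gc = (
        gc_track_from_fasta(cfg.inputs.reference_fasta, fc.gc_window)
        if cfg.inputs.reference_fasta else None
    )
    go = None
    if cfg.inputs.go_genes:
        go = gio.read_go_annotation(cfg.inputs.go_genes, cfg.inputs.go_names)

    models = {}
    for ind in cfg.individuals:
        callset = gio.read_genotype_calls(ind.vcf)
        exclude = gio.read_mask(ind.roh_bed) if ind.roh_bed else None
        models[ind.id] = GeneDiversityModel(
            callset, genes, outgroup, gene_sets=gene_sets,
            reference_gc=reference_gc, keep_masks=keep, remove_masks=remove,
            exclude=exclude, filter_config=fc,
            min_callable=div.min_callable,
            require_outgroup=div.require_outgroup,
        )
    return models, go


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run every stage and write the report tables under output_dir."""
    os.makedirs(cfg.output_dir, exist_ok=True)
    chash = config_hash(cfg)
    models, go = _build_models(cfg)

    results: Dict[str, GeneDiversityResults] = {}
    for ind, model in models.items():
        results[ind] = model.fit(
            B=cfg.bootstrap.B,
            seed=derive_seed(cfg.seed, "bootstrap", ind),
            quantiles=tuple(cfg.bootstrap.quantiles),
        )

    # set summary across individuals
    rows = []
    for ind, res in results.items():
        tab = res.set_table().reset_index()
        tab.insert(0, "individual", ind)
        rows.append(tab)
    set_summary = pd.concat(rows, ignore_index=True)

    # diversity-tail enrichment on the first (up to) three individuals
    enr_top = enr_bottom = None
    if go is not None and len(results) >= 1:
        trio = dict(list(results.items())[:3])
        means = mean_gene_ratios({k: v.gene_table for k, v in trio.items()})
        if len(means) >= 20:
            top = tail_genes(means, "top", cfg.enrichment.tail_fraction)
            bottom = tail_genes(means, "bottom", cfg.enrichment.tail_fraction)
            enr_top = enrichment_table(hypergeom_enrich(
                top, bottom, go, cfg.enrichment.min_category_size,
                cfg.enrichment.k_override))
            enr_bottom = enrichment_table(hypergeom_enrich(
                bottom, top, go, cfg.enrichment.min_category_size,
                cfg.enrichment.k_override))
        else:
            log.warning("only %d eligible genes; skipping tail enrichment", len(means))

    # age correlation (needs >= 3 aged individuals and a chosen set)
    age_corr = None
    ages = {i.id: i.age for i in cfg.individuals if i.age is not None}
    set_name = cfg.age_correlation_set
    if set_name and len(ages) >= 3:
        pairs = [
            (ages[ind], results[ind].normalized(set_name))
            for ind in ages if ind in results
        ]
        if len(pairs) >= 3:
            age_corr = age_diversity_correlation(
                [p[0] for p in pairs], [p[1] for p in pairs]
            )

    report = RunReport(
        config=cfg, config_hash=chash, seed=cfg.seed,
        results=results, set_summary=set_summary,
        enrichment_top=enr_top, enrichment_bottom=enr_bottom,
        age_correlation=age_corr,
    )
    _write_report(report)
    return report


def _write_report(report: RunReport) -> None:
    out = report.config.output_dir
    paths = report.output_paths
    header = f"# config_hash={report.config_hash} seed={report.seed}\n"

    def write_df(df: pd.DataFrame, name: str, index: bool):
        path = os.path.join(out, name)
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index)
        paths[name] = path

    for ind, res in report.results.items():
        write_df(res.gene_table, f"per_gene.{ind}.tsv", index=True)
    write_df(report.set_summary, "set_summary.tsv", index=False)
    if report.enrichment_top is not None:
        write_df(report.enrichment_top, "enrichment_top.tsv", index=False)
        write_df(report.enrichment_bottom, "enrichment_bottom.tsv", index=False)

    meta = {
        "config_hash": report.config_hash,
        "seed": report.seed,
        "table_hash": report.table_hash(),
        "age_correlation": (
            None if report.age_correlation is None else float(report.age_correlation)
        ),
        "individuals": sorted(report.results),
        "skipped_records": {
            ind: res.model.callset.skipped_records
            for ind, res in report.results.items()
        },
        "degenerate_replicates": {
            ind: {
                f"{name}.{ci_name}": ci.n_degenerate
                for name, cis in res.bootstrap_cis.items()
                for ci_name, ci in cis.items()
            }
            for ind, res in report.results.items()
        },
        "enrichment_method": "hypergeometric + Bonferroni",
    }
    path = os.path.join(out, "report.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    paths["report.yaml"] = path
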