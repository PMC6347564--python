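"""Model/Results front end for single-genome gene-diversity analysis.

`GeneDiversityModel` bundles one individual's evidence (callset, gene
models, outgroup track, masks) with the filtering scheme;
:meth:`GeneDiversityModel.fit` derives the callable mask, counts SNPs
and fixed differences per gene, pools them per gene set, normalizes
test sets against the background set, and attaches bootstrap CIs.  The
returned :class:`GeneDiversityResults` carries the per-gene table, the
set summaries and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import GeneModel, GeneSetTable, GenomeCallset, OutgroupTrack
from .diversity import (
    MIN_CALLABLE_DEFAULT,
    SetDiversitySummary,
    count_genes,
    normalized_diversity,
    per_site_heterozygosity,
    set_ratio,
)
from .filters import (
    CoverageBand,
    FilterConfig,
    callable_flags,
    exclude_intervals,
    flags_to_mask,
    gc_coverage_band,
    mask_membership,
)
from .intervals import MaskTrack
from .resampling import (
    B_DEFAULT,
    QUANTILES_DEFAULT,
    BootstrapCI,
    bootstrap_normalized_ci,
    bootstrap_set_ci,
)


class GeneDiversityModel:
    """SNP/FD gene-diversity model for one diploid individual.

    Parameters
    ----------
    callset
        Per-site genotype calls with depth and mapping quality.
    genes
        Gene models (flanked bodies are the counting units).
    outgroup
        Outgroup (chimpanzee) allele track for polarizing homozygous sites.
    gene_sets
        Named sets to summarise, including the designated background set.
    reference_gc
        chrom -> per-base GC fraction, for the GC-corrected coverage band.
    keep_masks, remove_masks
        Uniqueness-style masks to intersect and repeat-style masks to drop.
    exclude
        Optional extra exclusion track (e.g. runs of homozygosity -> "Altai*").
    callable_track
        Precomputed callable mask; skips band estimation when given.
    """

    def __init__(
        self,
        callset: GenomeCallset,
        genes: Mapping[str, GeneModel],
        outgroup: OutgroupTrack,
        gene_sets: Optional[GeneSetTable] = None,
        reference_gc: Optional[Mapping[str, np.ndarray]] = None,
        keep_masks: Sequence[MaskTrack] = (),
        remove_masks: Sequence[MaskTrack] = (),
        exclude: Optional[MaskTrack] = None,
        filter_config: Optional[FilterConfig] = None,
        callable_track: Optional[MaskTrack] = None,
        min_callable: int = MIN_CALLABLE_DEFAULT,
        require_outgroup: bool = True,
        premask: Optional[Dict[str, np.ndarray]] = None,
        site_gc: Optional[Dict[str, np.ndarray]] = None,
    ):
        if callable_track is None and reference_gc is None:
            raise ValueError("need reference_gc to derive the callable mask "
                             "(or pass callable_track directly)")
        self.callset = callset
        self.genes = dict(genes)
        self.outgroup = outgroup
        self.gene_sets = gene_sets
        self.reference_gc = reference_gc
        self.keep_masks = tuple(keep_masks)
        self.remove_masks = tuple(remove_masks)
        self.exclude = exclude
        self.filter_config = filter_config or FilterConfig()
        self._callable_track = callable_track
        self.min_callable = min_callable
        self.require_outgroup = require_outgroup
        # optional precomputed caches, reusable across individuals whose
        # callsets share the same site positions (simulation studies)
        self._premask = premask
        self._site_gc = site_gc

    # -- mask derivation ---------------------------------------------------
    def derive_callable(self):
        """(site flags, coverage band): the per-site callable rule.

        ROH/extra exclusions from ``exclude`` are applied to the flags.
        """
        if self._callable_track is not None:
            track = self._callable_track
            if self.exclude is not None and not self.exclude.is_empty():
                track = exclude_intervals(track, self.exclude)
            flags = {
                chrom: track.contains(chrom, block.pos)
                for chrom, block in self.callset.chroms.items()
            }
            return flags, None
        premask = self._premask
        if premask is None:
            premask = mask_membership(self.callset, self.keep_masks, self.remove_masks)
        band = gc_coverage_band(
            self.callset, self.reference_gc, self.filter_config,
            premask=premask, site_gc=self._site_gc,
        )
        flags = callable_flags(
            self.callset, band, self.reference_gc, self.filter_config,
            premask=premask, site_gc=self._site_gc,
        )
        if self.exclude is not None and not self.exclude.is_empty():
            for chrom, block in self.callset.chroms.items():
                flags[chrom] &= ~self.exclude.contains(chrom, block.pos)
        return flags, band

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        B: int = B_DEFAULT,
        seed: int = 0,
        quantiles: Tuple[float, float] = QUANTILES_DEFAULT,
        build_track: bool = True,
    ) -> "GeneDiversityResults":
        """Count, pool, normalize, and bootstrap.

        ``B=0`` skips bootstrapping (point estimates only).
        ``build_track=False`` skips materialising the callable interval
        track (counts are identical for all-sites callsets; saves time
        in large replicated simulations).
        """
        flags, band = self.derive_callable()
        track = flags_to_mask(self.callset, flags) if build_track else None
        gene_table = count_genes(
            self.callset, self.genes, track, self.outgroup,
            min_callable=self.min_callable, require_outgroup=self.require_outgroup,
            site_callable=flags,
        )

        summaries: Dict[str, SetDiversitySummary] = {}
        cis: Dict[str, Dict[str, BootstrapCI]] = {}
        if self.gene_sets is not None:
            bg_name = self.gene_sets.background_name
            bg_members = self.gene_sets.background
            bg = set_ratio(gene_table, bg_members, set_name=bg_name)
            summaries[bg_name] = bg
            bg_table = gene_table.loc[sorted(set(bg_members) & set(gene_table.index))]
            for name in sorted(self.gene_sets.sets):
                if name == bg_name:
                    continue
                members = self.gene_sets.members(name)
                test = set_ratio(gene_table, members, set_name=name)
                summaries[name] = normalized_diversity(test, bg)
                if B > 0:
                    sub = gene_table.loc[sorted(set(members) & set(gene_table.index))]
                    cis[name] = {
                        "mean_ratio": bootstrap_set_ci(
                            sub, B=B, seed=seed, quantiles=quantiles,
                            statistic_name=f"{name}.mean_ratio",
                        ),
                        "normalized": bootstrap_normalized_ci(
                            sub, bg_table, B=B, seed=seed, quantiles=quantiles,
                            statistic_name=f"{name}.normalized",
                        ),
                    }
            if B > 0:
                cis[bg_name] = {
                    "mean_ratio": bootstrap_set_ci(
                        bg_table, B=B, seed=seed, quantiles=quantiles,
                        statistic_name=f"{bg_name}.mean_ratio",
                    )
                }

        return GeneDiversityResults(
            model=self,
            callable_track=track,
            site_flags=flags,
            coverage_band=band,
            gene_table=gene_table,
            set_summaries=summaries,
            bootstrap_cis=cis,
            B=B,
            seed=seed,
        )


@dataclass
class GeneDiversityResults:
    """Fitted per-individual diversity estimates."""

    model: GeneDiversityModel
    callable_track: Optional[MaskTrack]
    site_flags: Dict[str, np.ndarray]
    coverage_band: Optional[CoverageBand]
    gene_table: pd.DataFrame
    set_summaries: Dict[str, SetDiversitySummary]
    bootstrap_cis: Dict[str, Dict[str, BootstrapCI]]
    B: int
    seed: int

    @property
    def individual_id(self) -> str:
        return self.model.callset.individual_id

    # -- headline quantities -------------------------------------------
    @property
    def n_callable_sites(self) -> int:
        if self.callable_track is not None:
            return self.callable_track.total_length()
        return int(sum(f.sum() for f in self.site_flags.values()))

    def heterozygosity(self) -> float:
        """Genome-wide heterozygous sites per callable site."""
        return per_site_heterozygosity(
            self.model.callset, self.callable_track, site_callable=self.site_flags
        )[2]

    def normalized(self, set_name: str) -> float:
        s = self.set_summaries[set_name]
        if s.normalized is None:
            raise ValueError(f"{set_name!r} has no normalized value (background set?)")
        return s.normalized

    def normalized_ci(self, set_name: str) -> BootstrapCI:
        return self.bootstrap_cis[set_name]["normalized"]

    def set_table(self) -> pd.DataFrame:
        rows = []
        for name, s in self.set_summaries.items():
            ci = self.bootstrap_cis.get(name, {}).get("normalized")
            rows.append(
                {
                    "set": name,
                    "n_genes": s.n_genes_used,
                    "sum_snp": s.sum_snp,
                    "sum_fd": s.sum_fd,
                    "mean_ratio": s.mean_ratio,
                    "normalized": s.normalized,
                    "log2_normalized": s.log2_normalized,
                    "ci_lower": ci.lower if ci else np.nan,
                    "ci_upper": ci.upper if ci else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("set").sort_index()

    def summary(self) -> str:
        lines = []
        lines.append("Gene diversity (SNP/FD) results")
        lines.append("=" * 46)
        lines.append(f"individual:        {self.individual_id}")
        lines.append(f"callable sites:    {self.n_callable_sites:,}")
        n_pass = int(self.gene_table["passes_min_callable"].sum())
        lines.append(f"genes passing:     {n_pass} / {len(self.gene_table)}")
        lines.append(f"heterozygosity:    {self.heterozygosity():.3e} per callable site")
        lines.append(f"bootstrap:         B={self.B}, seed={self.seed}")
        if self.set_summaries:
            lines.append("")
            df = self.set_table()
            with pd.option_context("display.float_format", "{:.4g}".format):
                lines.append(df.to_string())
        return "\n".join(lines)

    def plot_normalized(self, ax=None):
        """log2 normalized diversity per set with bootstrap CI error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.set_table().dropna(subset=["normalized"])
        y = np.log2(df["normalized"])
        lo = y - np.log2(df["ci_lower"])
        hi = np.log2(df["ci_upper"]) - y
        ax.errorbar(range(len(df)), y, yerr=[lo, hi], fmt="o", capsize=4)
        ax.axhline(0.0, ls="--", color="grey")
        ax.set_xticks(range(len(df)), df.index, rotation=45, ha="right")
        ax.set_ylabel("log2 normalized SNP/FD")
        ax.set_title(self.individual_id)
        return ax
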