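"""The SNP/FD gene-diversity statistic.

Within a single diploid genome, a *SNP* is a biallelic heterozygous
site and a *fixed difference* (FD) is a site homozygous for an allele
that differs from the outgroup (chimpanzee) allele.  The per-gene ratio
SNP/FD normalizes heterozygosity by local divergence, cancelling
mutation-rate heterogeneity along the genome.  Gene sets are summarised
by the pooled ratio Σsnp/Σfd, and a test set is *normalized* by dividing
its pooled ratio by that of a non-immune background set.

Both SNP and FD counting are restricted by default to callable sites
with a defined outgroup allele, so numerator and denominator share one
opportunity set (``require_outgroup=False`` relaxes this for SNPs).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import encode_allele
from .containers import GeneModel, GenomeCallset, OutgroupTrack, SiteBlock
from .intervals import MaskTrack

MIN_CALLABLE_DEFAULT = 2000  # genes with fewer callable sites are excluded


class SiteClass(enum.IntEnum):
    MATCH = 0        # homozygous, equal to the outgroup allele
    SNP = 1          # biallelic heterozygous site
    FD = 2           # homozygous, different from the outgroup allele
    NO_OUTGROUP = 3  # outgroup allele undefined at the site
    EXCLUDED = 4     # non-SNV or more than two observed alleles


class UndefinedRatioError(ValueError):
    """Raised when a requested SNP/FD ratio has a zero FD denominator."""


# ---------------------------------------------------------------------------
# site classification
# ---------------------------------------------------------------------------

def classify_codes(
    a1: np.ndarray,
    a2: np.ndarray,
    n_alleles: np.ndarray,
    is_snv: np.ndarray,
    outgroup: np.ndarray,
    require_outgroup: bool = True,
) -> np.ndarray:
    """Vectorized site classification over allele-code arrays.

    ``outgroup`` uses code -1 for "absent".  Precedence: EXCLUDED
    (non-SNV / >2 alleles) first, then NO_OUTGROUP, then heterozygous ->
    SNP, then homozygous against the outgroup.
    """
    out = np.full(np.shape(a1), SiteClass.MATCH, dtype=np.int8)
    het = a1 != a2
    hom = ~het
    no_og = outgroup < 0
    out[het] = SiteClass.SNP
    out[hom & ~no_og & (a1 != outgroup)] = SiteClass.FD
    if require_outgroup:
        out[no_og] = SiteClass.NO_OUTGROUP
    else:
        out[no_og & hom] = SiteClass.NO_OUTGROUP
    out[(~np.asarray(is_snv, bool)) | (np.asarray(n_alleles) > 2)] = SiteClass.EXCLUDED
    return out


def classify_site(
    genotype: Tuple[str, str],
    alleles_observed: int,
    outgroup_allele: Optional[str],
    is_snv: bool = True,
    require_outgroup: bool = True,
) -> SiteClass:
    """Classify one site; scalar convenience wrapper over classify_codes."""
    a = sorted(encode_allele(g) for g in genotype)
    og = -1 if outgroup_allele is None else encode_allele(outgroup_allele)
    cls = classify_codes(
        np.array([a[0]]), np.array([a[1]]),
        np.array([alleles_observed]), np.array([is_snv]),
        np.array([og]), require_outgroup=require_outgroup,
    )
    return SiteClass(int(cls[0]))


# ---------------------------------------------------------------------------
# per-gene counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneDiversity:
    """Per-gene callable-site, SNP and FD counts with the derived ratio."""

    gene_id: str
    callable_sites: int
    snp: int
    fd: int
    min_callable: int = MIN_CALLABLE_DEFAULT

    @property
    def ratio(self) -> float:
        return self.snp / self.fd if self.fd > 0 else math.nan

    @property
    def passes_min_callable(self) -> bool:
        return self.callable_sites >= self.min_callable


def _classified(block: SiteBlock, chrom: str, outgroup: OutgroupTrack,
                require_outgroup: bool) -> np.ndarray:
    og = outgroup.alleles_at(chrom, block.pos)
    return classify_codes(block.a1, block.a2, block.n_alleles, block.is_snv, og,
                          require_outgroup=require_outgroup)


def _interval_counts(block, cls, in_mask, chrom, mask, intervals):
    """(callable_length, snp, fd) totals over a list of half-open intervals."""
    starts = np.array([s for s, _ in intervals], dtype=np.int64)
    ends = np.array([e for _, e in intervals], dtype=np.int64)
    callable_len = int(mask.overlap_lengths(chrom, starts, ends).sum())
    snp_ind = np.cumsum(((cls == SiteClass.SNP) & in_mask).astype(np.int64))
    fd_ind = np.cumsum(((cls == SiteClass.FD) & in_mask).astype(np.int64))
    snp_ind = np.concatenate([[0], snp_ind])
    fd_ind = np.concatenate([[0], fd_ind])
    i0 = np.searchsorted(block.pos, starts)
    i1 = np.searchsorted(block.pos, ends)
    return callable_len, int((snp_ind[i1] - snp_ind[i0]).sum()), int((fd_ind[i1] - fd_ind[i0]).sum())


def gene_counts(
    callset: GenomeCallset,
    gene: GeneModel,
    callable_track: MaskTrack,
    outgroup: OutgroupTrack,
    min_callable: int = MIN_CALLABLE_DEFAULT,
    require_outgroup: bool = True,
) -> GeneDiversity:
    """Count callable sites, SNPs and FDs over a gene's flanked body.

    ``callable_sites`` is the callable-mask overlap with the body (before
    the outgroup requirement); SNP/FD counts additionally require a
    defined outgroup allele under the default shared-universe rule.
    """
    block = callset.chroms.get(gene.chrom)
    if block is None:
        return GeneDiversity(gene.gene_id, 0, 0, 0, min_callable)
    cls = _classified(block, gene.chrom, outgroup, require_outgroup)
    in_mask = callable_track.contains(gene.chrom, block.pos)
    c, s, f = _interval_counts(block, cls, in_mask, gene.chrom, callable_track, [gene.body])
    return GeneDiversity(gene.gene_id, c, s, f, min_callable)


def count_genes(
    callset: GenomeCallset,
    genes: Mapping[str, GeneModel],
    callable_track: Optional[MaskTrack],
    outgroup: OutgroupTrack,
    min_callable: int = MIN_CALLABLE_DEFAULT,
    require_outgroup: bool = True,
    site_callable: Optional[Mapping[str, np.ndarray]] = None,
) -> pd.DataFrame:
    """Vectorized per-gene counting for a whole gene collection.

    Returns a DataFrame indexed by gene_id with columns
    (callable_sites, snp, fd, ratio, passes_min_callable); equivalent to
    calling :func:`gene_counts` per gene but classifying each
    chromosome once.

    ``site_callable`` may supply precomputed per-site callable flags
    (chrom -> bool array aligned to the callset) in place of interval
    lookups; callable_sites is then the flagged-site count per body,
    identical to the mask overlap for all-sites callsets.
    """
    if callable_track is None and site_callable is None:
        raise ValueError("need callable_track or site_callable")
    by_chrom: Dict[str, list] = {}
    for g in genes.values():
        by_chrom.setdefault(g.chrom, []).append(g)

    records = []
    for chrom, chrom_genes in by_chrom.items():
        block = callset.chroms.get(chrom)
        starts = np.array([g.body[0] for g in chrom_genes], dtype=np.int64)
        ends = np.array([g.body[1] for g in chrom_genes], dtype=np.int64)
        if block is None:
            zero = np.zeros(len(chrom_genes), dtype=np.int64)
            if callable_track is not None:
                callable_len = callable_track.overlap_lengths(chrom, starts, ends)
            else:
                callable_len = zero
            snp = fd = zero
        else:
            if site_callable is not None:
                in_mask = site_callable[chrom]
            else:
                in_mask = callable_track.contains(chrom, block.pos)
            cls = _classified(block, chrom, outgroup, require_outgroup)
            i0 = np.searchsorted(block.pos, starts)
            i1 = np.searchsorted(block.pos, ends)
            snp_cum = np.concatenate([[0], np.cumsum((cls == SiteClass.SNP) & in_mask, dtype=np.int32)])
            fd_cum = np.concatenate([[0], np.cumsum((cls == SiteClass.FD) & in_mask, dtype=np.int32)])
            snp = snp_cum[i1] - snp_cum[i0]
            fd = fd_cum[i1] - fd_cum[i0]
            if callable_track is not None:
                callable_len = callable_track.overlap_lengths(chrom, starts, ends)
            else:
                ok_cum = np.concatenate([[0], np.cumsum(in_mask, dtype=np.int32)])
                callable_len = ok_cum[i1] - ok_cum[i0]
        for g, c, s, f in zip(chrom_genes, callable_len, snp, fd):
            records.append((g.gene_id, int(c), int(s), int(f)))

    df = pd.DataFrame(records, columns=["gene_id", "callable_sites", "snp", "fd"])
    df = df.set_index("gene_id").sort_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio"] = np.where(df["fd"] > 0, df["snp"] / df["fd"], np.nan)
    df["passes_min_callable"] = df["callable_sites"] >= min_callable
    return df


def partition_features(
    callset: GenomeCallset,
    gene: GeneModel,
    callable_track: MaskTrack,
    outgroup: OutgroupTrack,
    min_callable: int = MIN_CALLABLE_DEFAULT,
    require_outgroup: bool = True,
) -> Dict[str, GeneDiversity]:
    """Split a gene's counts into exon / intron / flank partitions.

    The three partitions tile the gene body, so their counts sum to
    :func:`gene_counts` on the same gene.  Requires exon annotation.
    """
    if not gene.exons:
        raise ValueError(f"{gene.gene_id}: no exon annotation; cannot partition")
    block = callset.chroms.get(gene.chrom)
    exons = list(gene.exons)
    introns = []
    cur = gene.core[0]
    for s, e in exons:
        if s > cur:
            introns.append((cur, s))
        cur = e
    if cur < gene.core[1]:
        introns.append((cur, gene.core[1]))
    flanks = []
    if gene.body[0] < gene.core[0]:
        flanks.append((gene.body[0], gene.core[0]))
    if gene.core[1] < gene.body[1]:
        flanks.append((gene.core[1], gene.body[1]))

    out = {}
    for name, intervals in (("exon", exons), ("intron", introns), ("flank", flanks)):
        if block is None or not intervals:
            out[name] = GeneDiversity(gene.gene_id, 0, 0, 0, min_callable)
            continue
        cls = _classified(block, gene.chrom, outgroup, require_outgroup)
        in_mask = callable_track.contains(gene.chrom, block.pos)
        c, s, f = _interval_counts(block, cls, in_mask, gene.chrom, callable_track, intervals)
        out[name] = GeneDiversity(gene.gene_id, c, s, f, min_callable)
    return out


# ---------------------------------------------------------------------------
# set-level summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SetDiversitySummary:
    """Pooled SNP/FD over a gene set, optionally normalized to background."""

    set_name: str
    n_genes_used: int
    sum_snp: int
    sum_fd: int
    normalized: Optional[float] = None

    @property
    def mean_ratio(self) -> float:
        if self.sum_fd <= 0:
            raise UndefinedRatioError(f"set {self.set_name!r} has zero FD sum")
        return self.sum_snp / self.sum_fd

    @property
    def log2_normalized(self) -> Optional[float]:
        if self.normalized is None:
            return None
        return math.log2(self.normalized)


GeneTable = Union[pd.DataFrame, Iterable[GeneDiversity]]


def _as_frame(genes: GeneTable) -> pd.DataFrame:
    if isinstance(genes, pd.DataFrame):
        return genes
    rows = [
        (g.gene_id, g.callable_sites, g.snp, g.fd, g.passes_min_callable)
        for g in genes
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "callable_sites", "snp", "fd", "passes_min_callable"])
    return df.set_index("gene_id")


def set_ratio(genes: GeneTable, members: Iterable[str], set_name: str = "set") -> SetDiversitySummary:
    """Pooled Σsnp/Σfd over the member genes that pass the callable filter.

    Genes with fd = 0 still contribute their snp and fd(=0) to the sums;
    pooling (not averaging per-gene ratios) weights genes by divergence
    opportunity.
    """
    df = _as_frame(genes)
    member_ids = sorted(set(members) & set(df.index))
    sub = df.loc[member_ids]
    sub = sub[sub["passes_min_callable"]]
    if len(sub) == 0:
        raise ValueError(f"set {set_name!r}: no member genes pass the callable filter")
    summary = SetDiversitySummary(
        set_name=set_name,
        n_genes_used=int(len(sub)),
        sum_snp=int(sub["snp"].sum()),
        sum_fd=int(sub["fd"].sum()),
    )
    if summary.sum_fd == 0:
        raise UndefinedRatioError(f"set {set_name!r} has zero FD sum")
    return summary


def normalized_diversity(
    test: SetDiversitySummary, background: SetDiversitySummary
) -> SetDiversitySummary:
    """Divide the test set's pooled ratio by the background's."""
    bg = background.mean_ratio
    if bg <= 0:
        raise UndefinedRatioError(
            f"background set {background.set_name!r} has non-positive mean ratio"
        )
    return replace(test, normalized=test.mean_ratio / bg)


def background_set(
    genes: Mapping[str, GeneModel],
    immune_exclusion_ids: Iterable[str],
    min_length_bp: int = 500,
) -> frozenset:
    """All genes minus any with reported immune function minus genes whose
    annotated core is shorter than ``min_length_bp`` (strict <)."""
    excl = set(immune_exclusion_ids)
    out = frozenset(
        gid for gid, g in genes.items()
        if gid not in excl and g.core_length >= min_length_bp
    )
    if not out:
        raise ValueError("background gene set is empty after exclusions")
    return out


# ---------------------------------------------------------------------------
# auxiliary statistics
# ---------------------------------------------------------------------------

def age_diversity_correlation(ages: Sequence[float], values: Sequence[float]) -> float:
    """Pearson correlation between specimen ages and normalized diversity."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.size < 3:
        raise ValueError("need at least three individuals")
    if not (np.isfinite(ages).all() and np.isfinite(values).all()):
        raise ValueError("ages and values must be finite")
    if np.ptp(ages) == 0 or np.ptp(values) == 0:
        raise ValueError("zero variance in ages or values")
    return float(stats.pearsonr(ages, values).statistic)


def per_site_heterozygosity(
    callset: GenomeCallset,
    callable_track: Optional[MaskTrack] = None,
    site_callable: Optional[Mapping[str, np.ndarray]] = None,
) -> Tuple[int, int, float]:
    """(het sites, callable sites, rate): biallelic heterozygous SNVs per
    callable site — the genome-wide heterozygosity estimate."""
    if callable_track is None and site_callable is None:
        raise ValueError("need callable_track or site_callable")
    het = 0
    n = 0
    for chrom, block in callset.chroms.items():
        if site_callable is not None:
            sel = site_callable[chrom]
            n += int(sel.sum())
        else:
            sel = callable_track.contains(chrom, block.pos)
        het += int((block.is_het() & block.is_snv & (block.n_alleles <= 2) & sel).sum())
    if site_callable is None:
        n = callable_track.total_length()
    return het, n, het / n if n else math.nan
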