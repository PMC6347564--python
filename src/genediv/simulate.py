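"""Synthetic diploid genomes with the statistical structure the
SNP/FD analysis assumes.

The generator emulates what the real inputs look like to the pipeline:
per-site genotype calls with depth and mapping quality over annotated
gene bodies, an outgroup allele track with blocky alignment gaps,
uniqueness/repeat masks, optional runs of homozygosity, and gene sets
with set-specific diversity multipliers (an MHC-like set with strongly
elevated heterozygosity, an innate-immune-like set at background level).

The generative model per territory site: with probability m*mu (m = the
covering gene's diversity multiplier) the site is a biallelic
heterozygous SNV; otherwise with probability d it is homozygous derived
(differing from the outgroup allele); otherwise it matches the
outgroup.  Sites are independent — counts and ratios, the statistics
measured downstream, are insensitive to linkage at the scales tested.

Everything is driven by a single spec seed through keyed sub-streams,
so the same spec reproduces byte-identical data, and adding an
individual never shifts another individual's stream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from ._utils import rng_for
from .containers import (
    GeneModel,
    GeneSetTable,
    GenomeCallset,
    GoAnnotation,
    OutgroupTrack,
    SiteBlock,
)
from .intervals import MaskTrack

MEAN_FDS_PER_GENE_TARGET = 272  # calibration anchor for the divergence default


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SetDefinition:
    """A named gene set with a diversity multiplier.

    ``dispersion`` is the lognormal sigma of per-gene multipliers around
    the set multiplier (mean-centred, so E[per-gene m] = multiplier);
    it is only applied when multiplier != 1, keeping null sets exactly
    null.
    """

    name: str
    n_genes: int
    multiplier: float = 1.0
    dispersion: float = 0.3
    go_marker: Optional[str] = None


@dataclass(frozen=True)
class GeneLengthModel:
    mean_core: int = 20_000      # lognormal mean core length; ~22 kb body
    sigma_log: float = 0.4
    min_core: int = 1_000


@dataclass(frozen=True)
class CoverageModel:
    """Rounded-Gaussian depth: mean depends linearly on local GC."""

    mean_depth: float = 30.0
    gc_slope: float = -0.5       # relative mean change per unit GC deviation
    overdispersion: float = 1.3  # variance = overdispersion * mean


@dataclass(frozen=True)
class MQModel:
    mean: float = 37.0
    sd: float = 5.0


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    chrom: str = "chr1"
    chrom_length: int = 20_000_000
    n_background_genes: int = 500
    gene_length: GeneLengthModel = GeneLengthModel()
    flank_bp: int = 1000
    heterozygosity: float = 1.6e-5   # per-site het probability mu
    divergence: float = 1.2e-2       # per-site FD probability d
    set_definitions: Tuple[SetDefinition, ...] = ()
    roh_fraction: float = 0.0        # genome fraction in ROH tracts
    n_roh_tracts: int = 10
    coverage: CoverageModel = CoverageModel()
    mq: MQModel = MQModel()
    gc_block_bp: int = 10_000        # GC composition varies at this scale
    gc_mean: float = 0.41
    gc_sd: float = 0.07
    outgroup_missing_fraction: float = 0.02
    outgroup_missing_block_bp: int = 500
    uniqueness_gap_fraction: float = 0.03
    uniqueness_gap_block_bp: int = 800
    repeat_fraction: float = 0.03
    repeat_block_bp: int = 300
    multiallelic_rate: float = 1e-6
    indel_rate: float = 2e-5

    def __post_init__(self):
        if not (0 < self.heterozygosity < self.divergence < 1):
            raise ValueError("expect 0 < heterozygosity < divergence < 1")
        for s in self.set_definitions:
            if s.multiplier <= 0:
                raise ValueError(f"set {s.name!r}: multiplier must be positive")

    @property
    def n_genes(self) -> int:
        return self.n_background_genes + sum(s.n_genes for s in self.set_definitions)

    def roh_tracts(self) -> Tuple[Tuple[int, int], ...]:
        """Evenly spaced homozygosity tracts covering ``roh_fraction``."""
        if self.roh_fraction <= 0:
            return ()
        tract_len = int(self.chrom_length * self.roh_fraction / self.n_roh_tracts)
        spacing = self.chrom_length // self.n_roh_tracts
        return tuple(
            (i * spacing, min(i * spacing + tract_len, self.chrom_length))
            for i in range(self.n_roh_tracts)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def apply_overrides(spec: SyntheticSpec, overrides: Mapping[str, float]) -> SyntheticSpec:
    """Replace scalar spec fields by name; ``mean_core`` reaches into the
    gene-length model.  Integer-valued fields are coerced from floats."""
    int_fields = {"chrom_length", "n_background_genes", "flank_bp", "n_roh_tracts", "seed"}
    kwargs = {}
    for key, value in overrides.items():
        if key == "mean_core":
            kwargs["gene_length"] = dataclasses.replace(
                spec.gene_length, mean_core=int(value)
            )
        elif key in int_fields:
            kwargs[key] = int(value)
        else:
            kwargs[key] = value
    return dataclasses.replace(spec, **kwargs)


def _immune_sets(mhc_multiplier: float, innate_multiplier: float = 1.0):
    return (
        SetDefinition("mhc_like", 14, multiplier=mhc_multiplier, go_marker="GO:MHC0001"),
        SetDefinition("innate_like", 100, multiplier=innate_multiplier, go_marker="GO:INN0001"),
    )


def presets(seed: int = 0) -> Dict[str, SyntheticSpec]:
    """The documented preset table.

    Heterozygosity anchors: Vindija Neandertal 1.6e-5, Denisovan 1.8e-5;
    set-multiplier anchors: archaic MHC-like x47, present-day x7; the
    African/non-African baselines put pooled SNP/FD at 0.158 and 0.080.
    The vindija/denisovan/altai_roh presets keep all set multipliers at
    1 because they model genome-wide heterozygosity, which an inflated
    MHC-like set would distort at toy-genome scale; null_immune sets
    every immune multiplier to exactly 1.
    """
    neutral_sets = _immune_sets(1.0, 1.0)
    return {
        "archaic": SyntheticSpec(
            seed=seed, heterozygosity=1.6e-5, set_definitions=_immune_sets(47.0)
        ),
        "vindija": SyntheticSpec(
            seed=seed, heterozygosity=1.6e-5, set_definitions=neutral_sets
        ),
        "denisovan": SyntheticSpec(
            seed=seed, heterozygosity=1.8e-5, set_definitions=neutral_sets
        ),
        "altai_roh": SyntheticSpec(
            seed=seed, heterozygosity=1.6e-5, set_definitions=neutral_sets,
            roh_fraction=0.15,
        ),
        "african": SyntheticSpec(
            seed=seed, heterozygosity=1.9e-3, set_definitions=_immune_sets(7.0)
        ),
        "non_african": SyntheticSpec(
            seed=seed, heterozygosity=9.6e-4, set_definitions=_immune_sets(7.0)
        ),
        "null_immune": SyntheticSpec(
            seed=seed, heterozygosity=1.9e-3, set_definitions=neutral_sets
        ),
    }


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    spec: SyntheticSpec,
) -> Tuple[Dict[str, GeneModel], GeneSetTable, GoAnnotation]:
    """Place non-overlapping genes with exons, assign set membership and
    GO annotation.

    Genes are laid out left to right with inter-gene gaps of at least
    2 x flank, so flanked bodies never overlap and per-gene counts are
    independent.  Set membership is a seeded random partition.
    """
    rng = rng_for(spec.seed, "annotation")
    n = spec.n_genes
    glm = spec.gene_length

    mu_log = np.log(glm.mean_core) - glm.sigma_log**2 / 2
    cores = np.maximum(
        glm.min_core, rng.lognormal(mu_log, glm.sigma_log, n).astype(np.int64)
    )
    gaps = 2 * spec.flank_bp + rng.integers(0, 2_000, n)

    genes: Dict[str, GeneModel] = {}
    pos = int(gaps[0])
    order: List[str] = []
    for i in range(n):
        start = pos
        end = start + int(cores[i])
        if end + spec.flank_bp > spec.chrom_length:
            raise ValueError(
                f"genome of {spec.chrom_length} bp too short for {n} genes"
            )
        gid = f"G{i:05d}"
        exons = _simulate_exons(rng, start, end)
        genes[gid] = GeneModel(
            gene_id=gid,
            symbol=f"SYM{i:05d}",
            chrom=spec.chrom,
            core=(start, end),
            body=(start - spec.flank_bp, end + spec.flank_bp),
            exons=exons,
            strand="+" if rng.random() < 0.5 else "-",
        )
        order.append(gid)
        pos = end + int(gaps[i]) if i + 1 < n else end

    # seeded random partition into sets; the remainder is background
    shuffled = list(order)
    rng.shuffle(shuffled)
    sets: Dict[str, frozenset] = {}
    cursor = 0
    for sd in spec.set_definitions:
        sets[sd.name] = frozenset(shuffled[cursor : cursor + sd.n_genes])
        cursor += sd.n_genes
    sets["background"] = frozenset(shuffled[cursor:])
    gene_sets = GeneSetTable(sets=sets, background_name="background")

    # GO annotation: one marker term per set plus random background terms
    gene_to_terms: Dict[str, set] = {g: set() for g in order}
    term_names: Dict[str, str] = {}
    for sd in spec.set_definitions:
        if sd.go_marker:
            term_names[sd.go_marker] = f"{sd.name} marker"
            for g in sets[sd.name]:
                gene_to_terms[g].add(sd.go_marker)
    for t in range(30):
        term = f"GO:R{t:04d}"
        term_names[term] = f"random category {t}"
        size = int(min(rng.integers(5, 51), len(order)))
        for g in rng.choice(order, size=size, replace=False):
            gene_to_terms[str(g)].add(term)
    go = GoAnnotation(
        gene_to_terms={g: frozenset(ts) for g, ts in gene_to_terms.items()},
        term_names=term_names,
    )
    return genes, gene_sets, go


def _simulate_exons(rng, start: int, end: int) -> Tuple[Tuple[int, int], ...]:
    """A few exons of 100-400 bp spread evenly through the core."""
    core_len = end - start
    n_ex = max(1, core_len // 4000)
    bounds = np.linspace(start, end, n_ex + 1).astype(np.int64)
    exons = []
    for i in range(n_ex):
        seg_s, seg_e = int(bounds[i]), int(bounds[i + 1])
        length = int(min(rng.integers(100, 401), seg_e - seg_s))
        offset = int(rng.integers(0, max(1, seg_e - seg_s - length + 1)))
        exons.append((seg_s + offset, seg_s + offset + length))
    return tuple(exons)


# ---------------------------------------------------------------------------
# genome-level shared context
# ---------------------------------------------------------------------------

# MaskTrack helper for single-chromosome construction
def _single_chrom_track(chrom: str, starts, ends) -> MaskTrack:
    return MaskTrack({chrom: (np.asarray(starts, np.int64), np.asarray(ends, np.int64))})


@dataclass
class SharedGenome:
    """Individual-independent context: reference, GC track, masks,
    outgroup track, and the flattened site positions of gene territory."""

    spec: SyntheticSpec
    genes: Dict[str, GeneModel]
    ref_codes: np.ndarray
    gc: np.ndarray
    uniqueness_mask: MaskTrack
    repeat_mask: MaskTrack
    territory: MaskTrack
    site_pos: np.ndarray
    outgroup: OutgroupTrack
    roh: MaskTrack

    @property
    def chrom(self) -> str:
        return self.spec.chrom

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {self.spec.chrom: self.spec.chrom_length}

    # cached per-site lookups, valid for every individual of this world
    def site_gc(self) -> Dict[str, np.ndarray]:
        if not hasattr(self, "_site_gc"):
            self._site_gc = {self.chrom: self.gc[self.site_pos]}
        return self._site_gc

    def site_premask(self) -> Dict[str, np.ndarray]:
        if not hasattr(self, "_premask"):
            ok = self.uniqueness_mask.contains(self.chrom, self.site_pos)
            ok &= ~self.repeat_mask.contains(self.chrom, self.site_pos)
            self._premask = {self.chrom: ok}
        return self._premask


def simulate_reference(spec: SyntheticSpec, genes: Mapping[str, GeneModel]) -> SharedGenome:
    """Generate the shared (cross-individual) genome context."""
    rng = rng_for(spec.seed, "reference")
    L = spec.chrom_length
    chrom = spec.chrom

    # blockwise GC composition, then per-base sequence; the generative GC
    # field itself serves as the per-site GC fraction source (a 201-bp
    # window over the realized sequence estimates the same quantity)
    n_blocks = L // spec.gc_block_bp + 1
    p_gc = np.clip(rng.normal(spec.gc_mean, spec.gc_sd, n_blocks), 0.2, 0.7).astype(np.float32)
    gc = np.repeat(p_gc, spec.gc_block_bp)[:L]
    strong = rng.random(L, dtype=np.float32) < gc  # G or C
    pick = rng.random(L, dtype=np.float32) < np.float32(0.5)
    ref = np.where(strong, np.where(pick, np.int8(1), np.int8(2)),
                   np.where(pick, np.int8(0), np.int8(3)))
    del strong, pick

    gaps = _blocks(rng, L, spec.uniqueness_gap_fraction, spec.uniqueness_gap_block_bp, chrom)
    uniqueness = gaps.complement({chrom: L})
    repeats = _blocks(rng, L, spec.repeat_fraction, spec.repeat_block_bp, chrom)

    bodies = sorted(g.body for g in genes.values())
    territory = _single_chrom_track(
        chrom, [b[0] for b in bodies], [b[1] for b in bodies]
    )
    ts, te = territory.intervals(chrom)
    site_pos = np.concatenate([np.arange(s, e) for s, e in zip(ts, te)])

    og_missing = _blocks(rng, L, spec.outgroup_missing_fraction, spec.outgroup_missing_block_bp, chrom)
    og_defined = ~og_missing.contains(chrom, site_pos)
    og_pos = site_pos[og_defined]
    outgroup = OutgroupTrack(chroms={chrom: (og_pos, ref[og_pos].astype(np.int8))})
    outgroup.build_dense({chrom: L})

    roh = _single_chrom_track(
        chrom,
        [t[0] for t in spec.roh_tracts()],
        [t[1] for t in spec.roh_tracts()],
    ) if spec.roh_fraction > 0 else MaskTrack.empty()

    return SharedGenome(
        spec=spec,
        genes=dict(genes),
        ref_codes=ref,
        gc=gc,
        uniqueness_mask=uniqueness,
        repeat_mask=repeats,
        territory=territory,
        site_pos=site_pos,
        outgroup=outgroup,
        roh=roh,
    )


def _blocks(rng, length, fraction, mean_block, chrom) -> MaskTrack:
    if fraction <= 0:
        return MaskTrack.empty()
    n = max(1, int(length * fraction / mean_block))
    starts = np.sort(rng.integers(0, length, n))
    lens = np.maximum(1, rng.exponential(mean_block, n).astype(np.int64))
    ends = np.minimum(starts + lens, length)
    return _single_chrom_track(chrom, starts, ends)


# ---------------------------------------------------------------------------
# per-individual callset
# ---------------------------------------------------------------------------

def simulate_individual(
    shared: SharedGenome,
    gene_sets: GeneSetTable,
    individual_id: str,
) -> GenomeCallset:
    """Draw one individual's per-site genotype calls over gene territory."""
    spec = shared.spec
    rng = rng_for(spec.seed, "individual", individual_id)
    chrom = spec.chrom
    pos = shared.site_pos
    n = pos.size
    ref = shared.ref_codes[pos]

    # per-site het multiplier from the covering gene's set membership
    mult = np.ones(n, dtype=np.float32)
    gene_mult = _per_gene_multipliers(rng, shared.genes, spec, gene_sets)
    gene_list = sorted(shared.genes.values(), key=lambda g: g.body[0])
    starts = np.array([g.body[0] for g in gene_list], dtype=np.int64)
    ends = np.array([g.body[1] for g in gene_list], dtype=np.int64)
    i0 = np.searchsorted(pos, starts)
    i1 = np.searchsorted(pos, ends)
    for g, a, b in zip(gene_list, i0, i1):
        m = gene_mult[g.gene_id]
        if m != 1.0:
            mult[a:b] = m
    if not shared.roh.is_empty():
        mult[shared.roh.contains(chrom, pos)] = 0.0

    # site states
    u = rng.random(n, dtype=np.float32)
    p_het = np.float32(spec.heterozygosity) * mult
    het = u < p_het
    fd = (~het) & (u < p_het + np.float32(spec.divergence))
    variant = het | fd

    # alleles: derived allele differs from the reference/outgroup base
    a1 = ref.copy()
    a2 = ref.copy()
    v_idx = np.flatnonzero(variant)
    shift = rng.integers(1, 4, v_idx.size, dtype=np.int8)
    alt = ((ref[v_idx] + shift) % 4).astype(np.int8)
    h = het[v_idx]
    a1[v_idx] = np.where(h, np.minimum(ref[v_idx], alt), alt)
    a2[v_idx] = np.where(h, np.maximum(ref[v_idx], alt), alt)

    n_alleles = np.ones(n, dtype=np.int8)
    n_alleles[v_idx] = 2
    is_snv = np.ones(n, dtype=bool)

    # rare multiallelic records (excluded downstream: "biallelic" is strict)
    n_ma = rng.poisson(spec.multiallelic_rate * n)
    if n_ma:
        ma = np.unique(rng.integers(0, n, n_ma))
        s1 = (ref[ma] + 1) % 4
        s2 = (ref[ma] + 2) % 4
        a1[ma], a2[ma] = np.minimum(s1, s2), np.maximum(s1, s2)
        n_alleles[ma] = 3

    # rare non-SNV (indel) records
    n_ind = rng.poisson(spec.indel_rate * n)
    if n_ind:
        ind = np.unique(rng.integers(0, n, n_ind))
        is_snv[ind] = False
        a1[ind] = a2[ind] = -1
        n_alleles[ind] = 2

    # depth: rounded Gaussian, GC-dependent mean, overdispersed
    cov = spec.coverage
    gc_site = shared.gc[pos]
    mean_d = cov.mean_depth * (1.0 + cov.gc_slope * (gc_site - spec.gc_mean))
    depth = np.rint(
        mean_d + np.sqrt(cov.overdispersion * np.maximum(mean_d, 1e-6))
        * rng.standard_normal(n, dtype=np.float32)
    )
    depth = np.maximum(depth, 0).astype(np.int32)

    mq = np.asarray(
        np.round(spec.mq.mean + spec.mq.sd * rng.standard_normal(n, dtype=np.float32), 2),
        dtype=np.float32,
    )
    np.maximum(mq, 0, out=mq)

    block = SiteBlock(
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=np.int8),
        a1=a1,
        a2=a2,
        depth=depth,
        mq=mq,
        is_snv=is_snv,
        n_alleles=n_alleles,
    )
    return GenomeCallset(individual_id=individual_id, chroms={chrom: block})


def _per_gene_multipliers(rng, genes, spec, gene_sets) -> Dict[str, float]:
    """Mean-centred lognormal per-gene multipliers; exactly 1 for
    multiplier-1 sets and the background."""
    mult = {gid: 1.0 for gid in genes}
    for sd in spec.set_definitions:
        members = sorted(gene_sets.members(sd.name))
        if sd.multiplier == 1.0 or sd.dispersion <= 0:
            draws = np.full(len(members), sd.multiplier)
        else:
            draws = sd.multiplier * rng.lognormal(
                -sd.dispersion**2 / 2, sd.dispersion, len(members)
            )
        for gid, m in zip(members, draws):
            mult[gid] = float(m)
    return mult


# ---------------------------------------------------------------------------
# full dataset convenience + writing
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    genes: Dict[str, GeneModel]
    gene_sets: GeneSetTable
    go: GoAnnotation
    shared: SharedGenome
    callsets: Dict[str, GenomeCallset]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return self.shared.chrom_lengths

    def model(self, individual_id: str, exclude_roh: bool = False, **kwargs):
        """A ready-to-fit :class:`~genediv.model.GeneDiversityModel` for one
        simulated individual, with shared per-site caches attached."""
        from .model import GeneDiversityModel

        return GeneDiversityModel(
            self.callsets[individual_id],
            self.genes,
            self.shared.outgroup,
            gene_sets=self.gene_sets,
            reference_gc={self.spec.chrom: self.shared.gc},
            keep_masks=[self.shared.uniqueness_mask],
            remove_masks=[self.shared.repeat_mask],
            exclude=self.shared.roh if exclude_roh else None,
            premask=self.shared.site_premask(),
            site_gc=self.shared.site_gc(),
            **kwargs,
        )


def simulate_genome(
    spec: SyntheticSpec,
    individual_ids: Sequence[str] = ("ind1",),
    annotation=None,
) -> SyntheticDataset:
    """Generate annotation, shared genome and per-individual callsets."""
    if annotation is None:
        annotation = simulate_annotation(spec)
    genes, gene_sets, go = annotation
    shared = simulate_reference(spec, genes)
    callsets = {
        ind: simulate_individual(shared, gene_sets, ind) for ind in individual_ids
    }
    return SyntheticDataset(
        spec=spec, genes=genes, gene_sets=gene_sets, go=go,
        shared=shared, callsets=callsets,
    )


def write_dataset(ds: SyntheticDataset, outdir: str) -> Dict[str, str]:
    """Write the dataset in standard formats; returns the path manifest."""
    import os

    from . import io as gio

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    gio.write_fasta({ds.spec.chrom: ds.shared.ref_codes}, p("reference.fa"))
    gio.write_mask(ds.shared.uniqueness_mask, p("uniqueness.bed"))
    gio.write_mask(ds.shared.repeat_mask, p("repeats.bed"))
    if not ds.shared.roh.is_empty():
        gio.write_mask(ds.shared.roh, p("roh.bed"))
    gio.write_outgroup(ds.shared.outgroup, p("outgroup.tsv"))
    gio.write_genes(ds.genes, p("genes.tsv"))
    gio.write_gene_sets(ds.gene_sets, p("gene_sets.tsv"))
    gio.write_go_annotation(ds.go, p("go_genes.tsv"), p("go_names.tsv"))
    for ind, callset in ds.callsets.items():
        gio.write_callset_vcf(callset, p(f"{ind}.vcf"), ds.chrom_lengths)
    with open(p("manifest.yaml"), "w") as fh:
        yaml.safe_dump(
            {"spec": ds.spec.to_dict(), "individuals": sorted(ds.callsets)},
            fh, sort_keys=True,
        )
    return paths
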