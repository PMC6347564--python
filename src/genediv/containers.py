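"""In-memory data model for single-genome diversity analysis.

The pipeline measures within-individual diversity (heterozygous sites)
normalized by divergence to an outgroup (fixed differences), per gene.
These containers hold the evidence: per-site genotype calls with their
quality annotations, the outgroup allele track, gene models with flanks,
gene-set membership, and flattened GO annotation.

All coordinates are 0-based half-open.  Alleles are stored as int8 codes
(0..3 = A,C,G,T; -1 = absent/unknown), which keeps 10^7-site callsets
cheap and makes site classification a handful of vectorized comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np

from ._utils import decode_allele


# ---------------------------------------------------------------------------
# genotype calls
# ---------------------------------------------------------------------------

@dataclass
class SiteBlock:
    """Columnar per-chromosome site calls (positions sorted, unique)."""

    pos: np.ndarray        # int64
    ref: np.ndarray        # int8 allele code
    a1: np.ndarray         # int8 genotype allele (a1 <= a2)
    a2: np.ndarray         # int8
    depth: np.ndarray      # int32
    mq: np.ndarray         # float32
    is_snv: np.ndarray     # bool
    n_alleles: np.ndarray  # int8, distinct alleles observed at the record

    def __post_init__(self):
        n = self.pos.size
        for name in ("ref", "a1", "a2", "depth", "mq", "is_snv", "n_alleles"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name!r} length mismatch")
        if n > 1 and bool(np.any(self.pos[1:] <= self.pos[:-1])):
            raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def is_het(self) -> np.ndarray:
        return self.a1 != self.a2


@dataclass
class GenomeCallset:
    """One individual's per-site genotype calls with depth and mapping quality."""

    individual_id: str
    chroms: Dict[str, SiteBlock] = field(default_factory=dict)
    skipped_records: int = 0  # malformed records dropped at read time

    @property
    def n_sites(self) -> int:
        return sum(b.n_sites for b in self.chroms.values())

    def chrom_names(self) -> List[str]:
        return sorted(self.chroms)


# ---------------------------------------------------------------------------
# outgroup track
# ---------------------------------------------------------------------------

@dataclass
class OutgroupTrack:
    """Sparse per-position outgroup (chimpanzee) allele map.

    Positions without alignment data are simply absent, not stored as N:
    absence means the site cannot be polarized and is excluded from both
    SNP and FD counting under the shared-universe rule.
    """

    chroms: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    dropped_rows: int = 0  # rows with non-ACGT alleles dropped at read time
    _dense: Dict[str, np.ndarray] = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_positions(self) -> int:
        return sum(p.size for p, _ in self.chroms.values())

    def build_dense(self, chrom_lengths: Mapping[str, int]) -> None:
        """Cache genome-length int8 lookup arrays (1 byte/bp) so repeated
        bulk queries become fancy indexing instead of binary search."""
        for chrom, length in chrom_lengths.items():
            if chrom in self.chroms and chrom not in self._dense:
                arr = np.full(int(length), -1, dtype=np.int8)
                p, a = self.chroms[chrom]
                arr[p] = a
                self._dense[chrom] = arr

    def alleles_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Outgroup allele code for each query position; -1 where absent."""
        if chrom in self._dense:
            return self._dense[chrom][pos]
        out = np.full(np.asarray(pos).shape, -1, dtype=np.int8)
        if chrom not in self.chroms:
            return out
        tpos, tallele = self.chroms[chrom]
        idx = np.searchsorted(tpos, pos)
        ok = (idx < tpos.size) & (tpos[np.minimum(idx, tpos.size - 1)] == pos)
        out[ok] = tallele[idx[ok]]
        return out


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene's counting unit: annotated core, exons, and flanked body.

    ``body`` is the core extended by ``flank_bp`` on each side (clamped to
    the chromosome), so counts include introns, exons and 1 kb of
    flanking sequence capturing adjacent regulatory elements.
    """

    gene_id: str
    symbol: str
    chrom: str
    core: Tuple[int, int]
    body: Tuple[int, int]
    exons: Tuple[Tuple[int, int], ...]
    strand: str = "?"

    def __post_init__(self):
        cs, ce = self.core
        bs, be = self.body
        if not (bs <= cs <= ce <= be):
            raise ValueError(f"{self.gene_id}: core must lie within body")
        for es, ee in self.exons:
            if not (cs <= es < ee <= ce):
                raise ValueError(f"{self.gene_id}: exon [{es},{ee}) outside core")

    @property
    def core_length(self) -> int:
        return self.core[1] - self.core[0]

    @property
    def body_length(self) -> int:
        return self.body[1] - self.body[0]


def merge_exons(exons) -> Tuple[Tuple[int, int], ...]:
    """Sort and merge possibly-overlapping exon intervals."""
    ex = sorted((int(s), int(e)) for s, e in exons)
    out: List[List[int]] = []
    for s, e in ex:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


# ---------------------------------------------------------------------------
# gene sets and GO annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneSetTable:
    """Named gene sets plus the designated background set name."""

    sets: Dict[str, frozenset]
    background_name: str = "background"

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def members(self, name: str) -> frozenset:
        return self.sets[name]

    @property
    def background(self) -> frozenset:
        return self.sets[self.background_name]

    def missing_from(self, known_gene_ids) -> Dict[str, frozenset]:
        known = frozenset(known_gene_ids)
        out = {}
        for name, members in self.sets.items():
            miss = members - known
            if miss:
                out[name] = miss
        return out


@dataclass
class GoAnnotation:
    """Flattened gene -> GO mapping and GO id -> name table (no graph)."""

    gene_to_terms: Dict[str, frozenset]
    term_names: Dict[str, str] = field(default_factory=dict)

    def genes_for(self, term: str) -> frozenset:
        return frozenset(g for g, ts in self.gene_to_terms.items() if term in ts)

    def terms(self) -> List[str]:
        out = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return sorted(out)

    def name(self, term: str) -> str:
        return self.term_names.get(term, term)


def genotype_string(a1: int, a2: int) -> str:
    """Human-readable genotype like 'A/G' from allele codes."""
    return f"{decode_allele(int(a1))}/{decode_allele(int(a2))}"
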