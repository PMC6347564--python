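"""Readers and writers for the standard-format inputs.

Everything on disk follows the field's conventions — VCF 4.x (1-based)
for genotype calls, BED3 (0-based half-open) for masks and ROH tracts, a
1-based TSV for the outgroup allele track, and plain TSVs for gene
models, gene sets and GO annotation.  All 1-based formats are converted
to the internal 0-based half-open convention at this boundary and
nowhere else.
"""

from __future__ import annotations

import logging
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._utils import decode_allele, encode_allele
from .containers import (
    GeneModel,
    GeneSetTable,
    GenomeCallset,
    GoAnnotation,
    OutgroupTrack,
    SiteBlock,
    merge_exons,
)
from .intervals import MaskTrack

log = logging.getLogger(__name__)


class InputError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# genotype VCF
# ---------------------------------------------------------------------------

def read_genotype_calls(
    vcf_path: str,
    region: Optional[Tuple[str, int, int]] = None,
    depth_field: str = "DP",
    mq_field: str = "MQ",
) -> GenomeCallset:
    """Read a single-sample VCF into a :class:`GenomeCallset`.

    Depth is looked up first in FORMAT, then in INFO, under
    ``depth_field``; mapping quality likewise under ``mq_field`` (the
    original whole-genome VCFs carry these as site-level annotations, so
    both layouts are accepted).  Non-SNV records are retained with
    ``is_snv=False``; multiallelic records are retained with the full
    observed allele count so downstream classification can exclude them.
    Records with malformed or missing genotypes are skipped and counted.
    """
    vcf = VCF(str(vcf_path), gts012=False)
    if len(vcf.samples) != 1:
        raise InputError(
            f"{vcf_path}: expected exactly one sample, found {len(vcf.samples)}"
        )
    individual = vcf.samples[0]

    acc: Dict[str, Dict[str, list]] = {}
    skipped = 0
    for v in vcf:
        chrom = v.CHROM
        pos0 = v.POS - 1
        if region is not None:
            rc, rs, re_ = region
            if chrom != rc or not (rs <= pos0 < re_):
                continue
        ref = v.REF.upper()
        alts = [a.upper() for a in v.ALT]
        alleles = [ref] + [a for a in alts if a != "."]
        snv = all(len(a) == 1 and a in "ACGT" for a in alleles)

        gt = v.genotypes[0] if v.genotypes else None
        if gt is None or len(gt) < 2 or gt[0] < 0 or gt[1] < 0:
            skipped += 1
            continue
        try:
            g1, g2 = alleles[gt[0]], alleles[gt[1]]
        except IndexError:
            skipped += 1
            continue

        depth = _site_number(v, depth_field)
        mq = _site_number(v, mq_field)

        c1, c2 = encode_allele(g1) if len(g1) == 1 else -1, (
            encode_allele(g2) if len(g2) == 1 else -1
        )
        if c2 < c1:
            c1, c2 = c2, c1

        cols = acc.setdefault(
            chrom,
            {k: [] for k in ("pos", "ref", "a1", "a2", "depth", "mq", "is_snv", "n_alleles")},
        )
        cols["pos"].append(pos0)
        cols["ref"].append(encode_allele(ref) if len(ref) == 1 else -1)
        cols["a1"].append(c1)
        cols["a2"].append(c2)
        cols["depth"].append(int(depth) if depth is not None else 0)
        cols["mq"].append(float(mq) if mq is not None else 0.0)
        cols["is_snv"].append(snv)
        cols["n_alleles"].append(len(set(alleles)))

    chroms = {}
    for chrom, cols in acc.items():
        pos = np.asarray(cols["pos"], dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        dup = np.zeros(pos.size, dtype=bool)
        dup[1:] = np.diff(pos) == 0
        if dup.any():
            skipped += int(dup.sum())
            keep = ~dup
        else:
            keep = slice(None)
        chroms[chrom] = SiteBlock(
            pos=pos[keep],
            ref=np.asarray(cols["ref"], dtype=np.int8)[order][keep],
            a1=np.asarray(cols["a1"], dtype=np.int8)[order][keep],
            a2=np.asarray(cols["a2"], dtype=np.int8)[order][keep],
            depth=np.asarray(cols["depth"], dtype=np.int32)[order][keep],
            mq=np.asarray(cols["mq"], dtype=np.float32)[order][keep],
            is_snv=np.asarray(cols["is_snv"], dtype=bool)[order][keep],
            n_alleles=np.asarray(cols["n_alleles"], dtype=np.int8)[order][keep],
        )
    if skipped:
        log.warning("%s: skipped %d malformed/duplicate records", vcf_path, skipped)
    return GenomeCallset(individual_id=individual, chroms=chroms, skipped_records=skipped)


def _site_number(v, field):
    try:
        arr = v.format(field)
    except KeyError:
        arr = None
    if arr is not None:
        val = np.asarray(arr).ravel()[0]
        if np.isfinite(val):
            return float(val)
    val = v.INFO.get(field)
    return float(val) if val is not None else None


def write_callset_vcf(
    callset: GenomeCallset,
    path: str,
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write a callset as an uncompressed single-sample VCF 4.2.

    Reference-matching homozygous sites are emitted with ``ALT=.`` and
    ``GT=0/0`` (an all-sites VCF, as used for callable-site masking).
    Non-SNV sites are written as a 2-bp deletion record.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genediv-simulate\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{callset.individual_id}\n"
        )
        for chrom in callset.chrom_names():
            b = callset.chroms[chrom]
            lines = _vcf_lines(chrom, b)
            fh.write("\n".join(lines))
            if lines:
                fh.write("\n")


def _vcf_lines(chrom: str, b: SiteBlock) -> list:
    lines = []
    for i in range(b.n_sites):
        pos1 = int(b.pos[i]) + 1
        dp = int(b.depth[i])
        mq = float(b.mq[i])
        if not b.is_snv[i]:
            base = decode_allele(int(b.ref[i])) if b.ref[i] >= 0 else "A"
            ref, alt, gt = base, base + "T", "1/1"  # insertion, genotype non-SNV
        else:
            ref = decode_allele(int(b.ref[i]))
            g1, g2 = int(b.a1[i]), int(b.a2[i])
            alt_codes = []
            for g in (g1, g2):
                if g != b.ref[i] and g not in alt_codes:
                    alt_codes.append(g)
            # pad the ALT list so the observed allele count round-trips
            extra = int(b.n_alleles[i]) - 1 - len(alt_codes)
            for c in range(4):
                if extra <= 0:
                    break
                if c != b.ref[i] and c not in alt_codes:
                    alt_codes.append(c)
                    extra -= 1
            alleles = [int(b.ref[i])] + alt_codes
            alt = ",".join(decode_allele(c) for c in alt_codes) if alt_codes else "."
            gt = f"{alleles.index(g1)}/{alleles.index(g2)}"
        lines.append(
            f"{chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\t.\tMQ={mq:.2f}\tGT:DP\t{gt}:{dp}"
        )
    return lines


# ---------------------------------------------------------------------------
# BED masks
# ---------------------------------------------------------------------------

def read_mask(bed_path: str) -> MaskTrack:
    """Read a BED3 file into a merged :class:`MaskTrack`."""
    try:
        df = pd.read_csv(
            bed_path,
            sep=r"\s+",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return MaskTrack.empty()
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise InputError(f"{bed_path}: start > end at line {bad[0] + 1}")
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        out[str(chrom)] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
        )
    return MaskTrack(out)


def write_mask(track: MaskTrack, bed_path: str) -> None:
    track.to_dataframe().to_csv(bed_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene annotation table
# ---------------------------------------------------------------------------

def read_genes(
    table_path: str,
    flank_bp: int = 1000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> Dict[str, GeneModel]:
    """Read the gene table (TSV) into GeneModels keyed by gene_id.

    Exons are encoded ``start-end;start-end`` in absolute coordinates.
    Rows duplicated by (symbol, chrom, start, end) collapse to one model,
    mirroring uniqueness filtering by HGNC symbol and coordinates.
    The body is the core extended by ``flank_bp``, clamped to
    [0, chromosome length].
    """
    df = pd.read_csv(table_path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "symbol", "chrom", "start", "end", "strand", "exons"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{table_path}: missing columns {sorted(missing)}")
    df = df.drop_duplicates(subset=["symbol", "chrom", "start", "end"], keep="first")
    df = df.sort_values(["chrom", "start", "gene_id"], kind="stable")

    genes: Dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom_lengths is not None and chrom not in chrom_lengths:
            raise InputError(f"{table_path}: unknown chromosome {chrom!r}")
        core = (int(row.start), int(row.end))
        hi = chrom_lengths[chrom] if chrom_lengths is not None else None
        body_start = max(0, core[0] - flank_bp)
        body_end = core[1] + flank_bp if hi is None else min(hi, core[1] + flank_bp)
        exons = []
        if isinstance(row.exons, str) and row.exons.strip():
            for part in row.exons.split(";"):
                s, e = part.split("-")
                s, e = int(s), int(e)
                if not (core[0] <= s < e <= core[1]):
                    raise InputError(
                        f"{table_path}: exon [{s},{e}) outside gene {row.gene_id} core {core}"
                    )
                exons.append((s, e))
        genes[str(row.gene_id)] = GeneModel(
            gene_id=str(row.gene_id),
            symbol=str(row.symbol),
            chrom=chrom,
            core=core,
            body=(body_start, body_end),
            exons=merge_exons(exons),
            strand=str(row.strand),
        )
    return genes


def write_genes(genes: Mapping[str, GeneModel], table_path: str) -> None:
    rows = []
    for g in genes.values():
        rows.append(
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.chrom,
                "start": g.core[0],
                "end": g.core[1],
                "strand": g.strand,
                "exons": ";".join(f"{s}-{e}" for s, e in g.exons),
            }
        )
    pd.DataFrame(rows).sort_values(["chrom", "start", "gene_id"]).to_csv(
        table_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# outgroup allele track
# ---------------------------------------------------------------------------

def read_outgroup(track_path: str) -> OutgroupTrack:
    """Read the TSV outgroup track (chrom, 1-based pos, allele).

    Rows whose allele is not an unambiguous ACGT base are dropped (and
    counted): an undefined outgroup state is represented by absence.
    Duplicate rows are collapsed; conflicting duplicates are an error.
    """
    df = pd.read_csv(
        track_path, sep="\t", header=None, names=["chrom", "pos", "allele"],
        dtype={"chrom": str, "allele": str}, comment="#",
    )
    df["allele"] = df["allele"].str.upper()
    valid = df["allele"].isin(list("ACGT"))
    dropped = int((~valid).sum())
    df = df[valid]
    df = df.drop_duplicates()
    conflict = df.duplicated(subset=["chrom", "pos"], keep=False)
    if conflict.any():
        row = df[conflict].iloc[0]
        raise InputError(
            f"{track_path}: conflicting outgroup alleles at {row['chrom']}:{row['pos']}"
        )
    chroms = {}
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64) - 1  # to 0-based
        allele = grp["allele"].map(code).to_numpy(np.int8)
        order = np.argsort(pos)
        chroms[str(chrom)] = (pos[order], allele[order])
    return OutgroupTrack(chroms=chroms, dropped_rows=dropped)


def write_outgroup(track: OutgroupTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            pos, allele = track.chroms[chrom]
            bases = np.array(list("ACGT"))[allele]
            block = pd.DataFrame({"chrom": chrom, "pos": pos + 1, "allele": bases})
            block.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene sets and GO tables
# ---------------------------------------------------------------------------

def read_gene_sets(path: str, background_name: str = "background") -> GeneSetTable:
    """Read the two-column (set_name, gene_id) membership TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"set_name", "gene_id"} <= set(df.columns):
        raise InputError(f"{path}: expected columns set_name, gene_id")
    sets = {
        str(name): frozenset(grp["gene_id"])
        for name, grp in df.groupby("set_name", sort=False)
    }
    return GeneSetTable(sets=sets, background_name=background_name)


def write_gene_sets(table: GeneSetTable, path: str) -> None:
    rows = [
        {"set_name": name, "gene_id": gid}
        for name in sorted(table.sets)
        for gid in sorted(table.sets[name])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_go_annotation(genes_path: str, names_path: Optional[str] = None) -> GoAnnotation:
    """Read flattened (gene_id, go_id) pairs and optional GO-name table."""
    df = pd.read_csv(genes_path, sep="\t", dtype=str)
    if not {"gene_id", "go_id"} <= set(df.columns):
        raise InputError(f"{genes_path}: expected columns gene_id, go_id")
    df = df.drop_duplicates(subset=["gene_id", "go_id"])
    gene_to_terms = {
        str(gid): frozenset(grp["go_id"]) for gid, grp in df.groupby("gene_id", sort=False)
    }
    names = {}
    if names_path is not None:
        nd = pd.read_csv(names_path, sep="\t", dtype=str)
        if not {"go_id", "name"} <= set(nd.columns):
            raise InputError(f"{names_path}: expected columns go_id, name")
        names = dict(zip(nd["go_id"], nd["name"]))
    return GoAnnotation(gene_to_terms=gene_to_terms, term_names=names)


def write_go_annotation(annotation: GoAnnotation, genes_path: str, names_path: str) -> None:
    rows = [
        {"gene_id": g, "go_id": t}
        for g in sorted(annotation.gene_to_terms)
        for t in sorted(annotation.gene_to_terms[g])
    ]
    pd.DataFrame(rows).to_csv(genes_path, sep="\t", index=False)
    pd.DataFrame(
        [{"go_id": t, "name": n} for t, n in sorted(annotation.term_names.items())]
    ).to_csv(names_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, np.ndarray], path: str, width: int = 80) -> None:
    """Write int8-coded sequences as FASTA."""
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    with open(path, "w") as fh:
        for name, codes in seqs.items():
            fh.write(f">{name}\n")
            arr = lut[np.where((codes >= 0) & (codes < 4), codes, 4)]
            raw = arr.tobytes().decode("ascii")
            for i in range(0, len(raw), width):
                fh.write(raw[i : i + width])
                fh.write("\n")


def read_fasta_codes(path: str) -> Dict[str, np.ndarray]:
    """Read a FASTA into int8 allele-code arrays (N and others -> -1)."""
    from pyfaidx import Fasta

    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    out = {}
    with Fasta(str(path), build_index=True, rebuild=True) as fa:
        for name in fa.keys():
            seq = str(fa[name][:])
            out[name] = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return out
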