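"""Callable-site filtering.

A site is *callable* when it passes mapping quality (> 25, strict),
minimum depth (> 10, strict), a GC-corrected coverage band (its depth
lies within the empirical 2.5%/97.5% depth quantiles of sites of similar
GC content — guarding against collapsed repeats and mapping dropouts),
sits inside every keep-mask (e.g. 35-mer uniqueness) and outside every
remove-mask (e.g. tandem repeats).  Diversity is only ever counted over
callable sites, so these filters define the opportunity set for both
SNPs and fixed differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .containers import GenomeCallset
from .intervals import MaskTrack

GcSource = Mapping[str, np.ndarray]  # chrom -> per-base GC fraction


@dataclass
class FilterConfig:
    """Thresholds of the callable-site scheme; defaults follow the
    high-coverage archaic genome processing they mirror."""

    mq_min: float = 25.0          # strict: mq must exceed this
    min_depth: int = 10           # strict: depth must exceed this
    coverage_quantiles: Tuple[float, float] = (0.025, 0.975)
    gc_window: int = 201          # centred window for per-site GC fraction
    gc_bin_width: float = 0.05
    min_bin_sites: int = 100      # sparser GC bins inherit the global band

    def __post_init__(self):
        lo, hi = self.coverage_quantiles
        if not (0 < lo < hi < 1):
            raise ValueError("coverage quantiles must satisfy 0 < lower < upper < 1")
        if self.gc_window < 1 or self.gc_window % 2 == 0:
            raise ValueError("gc_window must be an odd positive integer")


@dataclass
class CoverageBand:
    """Per-GC-bin inclusive depth bounds from empirical quantiles."""

    lower: np.ndarray             # per-bin lower depth bound
    upper: np.ndarray             # per-bin upper depth bound
    gc_bin_width: float = 0.05
    quantile_levels: Tuple[float, float] = (0.025, 0.975)
    min_depth: int = 10
    genome_wide: Tuple[float, float] = (0.0, np.inf)

    def __post_init__(self):
        if np.any(self.lower > self.upper):
            raise ValueError("coverage band has lower > upper in some GC bin")

    @property
    def n_bins(self) -> int:
        return int(self.lower.size)

    def bin_of(self, gc: np.ndarray) -> np.ndarray:
        b = (np.asarray(gc) * np.float32(1.0 / self.gc_bin_width)).astype(np.int32)
        return np.minimum(b, self.n_bins - 1)

    def depth_in_band(self, depth: np.ndarray, gc: np.ndarray) -> np.ndarray:
        """Inclusive band test (the strict >min_depth cut is separate)."""
        b = self.bin_of(gc)
        return (depth >= self.lower[b]) & (depth <= self.upper[b])


# ---------------------------------------------------------------------------
# GC tracks
# ---------------------------------------------------------------------------

def gc_track_from_codes(ref_codes: np.ndarray, window: int = 201) -> np.ndarray:
    """Per-base GC fraction of a centred window over int8 base codes.

    Ambiguous bases (code -1) are excluded from both numerator and
    denominator; windows are truncated at chromosome ends.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    half = window // 2
    n = ref_codes.size

    def windowed_sum(x):
        # cumsum-based sliding window, truncated at the ends; sliced rather
        # than fancy-indexed so 10^8-base tracks stay cheap
        cum = np.concatenate([[0], np.cumsum(x, dtype=np.int64)])
        out = np.empty(n, dtype=np.int64)
        if n <= 2 * half:
            for i in range(n):
                out[i] = cum[min(i + half + 1, n)] - cum[max(i - half, 0)]
            return out
        out[half : n - half] = cum[2 * half + 1 :] - cum[: n - 2 * half]
        out[:half] = cum[half + 1 : 2 * half + 1] - cum[0]
        out[n - half :] = cum[n] - cum[n - 2 * half : n - half]
        return out

    gc_count = windowed_sum((ref_codes == 1) | (ref_codes == 2))
    n_valid = windowed_sum(ref_codes >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, gc_count / n_valid, 0.5)
    return frac.astype(np.float32)


def gc_track_from_fasta(fasta_path: str, window: int = 201) -> Dict[str, np.ndarray]:
    from .io import read_fasta_codes

    return {c: gc_track_from_codes(codes, window) for c, codes in read_fasta_codes(fasta_path).items()}


def _gc_at(reference_gc: GcSource, chrom: str, pos: np.ndarray) -> np.ndarray:
    track = reference_gc[chrom]
    return track[pos]


# ---------------------------------------------------------------------------
# coverage band estimation
# ---------------------------------------------------------------------------

def _hist_quantiles(values: np.ndarray, counts: np.ndarray, qs) -> np.ndarray:
    """Type-7 (linear interpolation) quantiles of a multiset given as a
    value/count histogram — exact, without materialising the multiset."""
    n = int(counts.sum())
    if n == 0:
        raise ValueError("empty multiset")
    cum = np.cumsum(counts)
    out = []
    for q in qs:
        h = (n - 1) * q
        lo_rank, frac = int(np.floor(h)), h - np.floor(h)
        v_lo = values[np.searchsorted(cum, lo_rank + 1)]
        v_hi = values[np.searchsorted(cum, min(lo_rank + 2, n))]
        out.append(v_lo + frac * (v_hi - v_lo))
    return np.asarray(out, dtype=float)


def mask_membership(
    callset: GenomeCallset,
    keep_masks: Sequence[MaskTrack] = (),
    remove_masks: Sequence[MaskTrack] = (),
) -> Dict[str, np.ndarray]:
    """Per-site flags: inside every keep-mask and outside every remove-mask."""
    out = {}
    for chrom, block in callset.chroms.items():
        ok = np.ones(block.n_sites, dtype=bool)
        for m in keep_masks:
            ok &= m.contains(chrom, block.pos)
        for m in remove_masks:
            ok &= ~m.contains(chrom, block.pos)
        out[chrom] = ok
    return out


def gc_coverage_band(
    callset: GenomeCallset,
    reference_gc: GcSource,
    config: FilterConfig | None = None,
    keep_masks: Sequence[MaskTrack] = (),
    remove_masks: Sequence[MaskTrack] = (),
    premask: Optional[Dict[str, np.ndarray]] = None,
    site_gc: Optional[Dict[str, np.ndarray]] = None,
) -> CoverageBand:
    """Estimate per-GC-bin 2.5%/97.5% empirical depth quantiles.

    The band is estimated on sites that already pass the mapping-quality
    cut and the uniqueness/repeat masks, so repeat-driven pileups do not
    distort the quantiles.  Bins with fewer than ``min_bin_sites`` sites
    inherit the genome-wide band.  ``premask`` can supply precomputed
    :func:`mask_membership` flags to avoid repeated interval lookups.
    """
    config = config or FilterConfig()
    if callset.n_sites == 0:
        raise ValueError("cannot estimate a coverage band from an empty callset")
    if premask is None:
        premask = mask_membership(callset, keep_masks, remove_masks)

    n_bins = int(np.ceil(1.0 / config.gc_bin_width))
    max_d = 0
    per_chrom = []
    for chrom, block in callset.chroms.items():
        sel = (block.mq > config.mq_min) & premask[chrom]
        if not sel.any():
            continue
        depth = block.depth[sel]
        if site_gc is not None:
            gc = site_gc[chrom][sel]
        else:
            gc = _gc_at(reference_gc, chrom, block.pos[sel])
        per_chrom.append((depth, gc))
        max_d = max(max_d, int(depth.max()))
    if not per_chrom:
        raise ValueError("no sites pass the pre-band filters")

    # 2-D histogram (gc bin x depth) -> exact per-bin quantiles
    hist = np.zeros((n_bins, max_d + 1), dtype=np.int64)
    for depth, gc in per_chrom:
        b = np.clip((gc / config.gc_bin_width).astype(np.int64), 0, n_bins - 1)
        flat = b * (max_d + 1) + np.clip(depth, 0, max_d)
        hist += np.bincount(flat, minlength=n_bins * (max_d + 1)).reshape(hist.shape)
    depth_values = np.arange(max_d + 1, dtype=np.int64)

    global_counts = hist.sum(axis=0)
    gw = _hist_quantiles(depth_values, global_counts, config.coverage_quantiles)

    lower = np.full(n_bins, gw[0])
    upper = np.full(n_bins, gw[1])
    for b in range(n_bins):
        if hist[b].sum() >= config.min_bin_sites:
            lo, hi = _hist_quantiles(depth_values, hist[b], config.coverage_quantiles)
            lower[b], upper[b] = lo, hi

    return CoverageBand(
        lower=lower,
        upper=upper,
        gc_bin_width=config.gc_bin_width,
        quantile_levels=config.coverage_quantiles,
        min_depth=config.min_depth,
        genome_wide=(float(gw[0]), float(gw[1])),
    )


# ---------------------------------------------------------------------------
# callable mask
# ---------------------------------------------------------------------------

def callable_flags(
    callset: GenomeCallset,
    band: CoverageBand,
    reference_gc: GcSource,
    config: FilterConfig | None = None,
    keep_masks: Sequence[MaskTrack] = (),
    remove_masks: Sequence[MaskTrack] = (),
    premask: Optional[Dict[str, np.ndarray]] = None,
    site_gc: Optional[Dict[str, np.ndarray]] = None,
) -> Dict[str, np.ndarray]:
    """Per-site callable flags: mq > mq_min, depth > min_depth, depth
    within the GC bin's coverage band, inside keep-masks, outside
    remove-masks."""
    config = config or FilterConfig()
    if premask is None:
        premask = mask_membership(callset, keep_masks, remove_masks)
    out = {}
    for chrom, block in callset.chroms.items():
        ok = (block.mq > config.mq_min) & (block.depth > config.min_depth)
        ok &= premask[chrom]
        if site_gc is not None:
            gc = site_gc[chrom]
        else:
            gc = _gc_at(reference_gc, chrom, block.pos)
        ok &= band.depth_in_band(block.depth, gc)
        out[chrom] = ok
    return out


def flags_to_mask(callset: GenomeCallset, flags: Dict[str, np.ndarray]) -> MaskTrack:
    """Turn per-site flags into a merged interval track (runs of adjacent
    flagged sites become intervals)."""
    out = {}
    for chrom, block in callset.chroms.items():
        ok = flags.get(chrom)
        if ok is None or not ok.any():
            continue
        p = block.pos[ok]
        breaks = np.flatnonzero(np.diff(p) > 1)
        starts = p[np.concatenate([[0], breaks + 1])]
        ends = p[np.concatenate([breaks, [p.size - 1]])] + 1
        out[chrom] = (starts, ends)
    return MaskTrack(out)


def callable_mask(
    callset: GenomeCallset,
    band: CoverageBand,
    reference_gc: GcSource,
    config: FilterConfig | None = None,
    keep_masks: Sequence[MaskTrack] = (),
    remove_masks: Sequence[MaskTrack] = (),
    premask: Optional[Dict[str, np.ndarray]] = None,
) -> MaskTrack:
    """Derive the per-individual callable-site mask.

    A site is callable iff mq > mq_min, depth > min_depth, depth within
    its GC bin's coverage band, inside every keep-mask and outside every
    remove-mask.  Runs of adjacent callable sites become intervals.
    """
    flags = callable_flags(
        callset, band, reference_gc, config, keep_masks, remove_masks, premask
    )
    return flags_to_mask(callset, flags)


def exclude_intervals(mask: MaskTrack, remove: MaskTrack) -> MaskTrack:
    """Set difference mask \\ remove (e.g. drop ROH tracts: Altai*)."""
    return mask.subtract(remove)
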