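"""Gene-resampling bootstrap for pooled SNP/FD ratios.

Uncertainty in set-level diversity comes from which genes the set
happens to contain, so the resampling unit is the gene: each replicate
draws N genes with replacement (N = set size), re-pools Σsnp/Σfd, and
the CI is the percentile interval of the replicate statistics at the
2.5%/97.5% quantiles (plain percentile bootstrap, B = 5000 by default).
Replicates whose FD sum is zero are dropped and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .diversity import GeneTable, _as_frame

B_DEFAULT = 5000
QUANTILES_DEFAULT = (0.025, 0.975)
_CHUNK = 500  # replicates per vectorized block (bounds peak memory)


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap confidence interval."""

    statistic_name: str
    point_estimate: float
    lower: float
    upper: float
    B: int = B_DEFAULT
    quantile_levels: Tuple[float, float] = QUANTILES_DEFAULT
    seed: Optional[int] = None
    n_degenerate: int = 0  # replicates dropped for a zero FD sum

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def log2(self) -> "BootstrapCI":
        """The log2-scale CI: log2 of the ratio CI endpoints."""
        return replace(
            self,
            statistic_name=f"log2_{self.statistic_name}",
            point_estimate=math.log2(self.point_estimate),
            lower=math.log2(self.lower),
            upper=math.log2(self.upper),
        )


def _set_arrays(genes: GeneTable):
    df = _as_frame(genes)
    df = df[df["passes_min_callable"]]
    if len(df) == 0:
        raise ValueError("no genes pass the callable filter")
    return df["snp"].to_numpy(np.int64), df["fd"].to_numpy(np.int64)


def _resampled_sums(rng, snp, fd, n_rep):
    """Sum snp and fd over n_rep with-replacement resamples of the set."""
    n = snp.size
    idx = rng.integers(0, n, size=(n_rep, n))
    return snp[idx].sum(axis=1), fd[idx].sum(axis=1)


def _percentile_ci(reps: np.ndarray, quantiles) -> Tuple[float, float]:
    lo, hi = np.quantile(reps, quantiles)  # type-7 linear interpolation
    return float(lo), float(hi)


def bootstrap_set_ci(
    genes: GeneTable,
    B: int = B_DEFAULT,
    seed: int = 0,
    quantiles: Tuple[float, float] = QUANTILES_DEFAULT,
    statistic_name: str = "mean_ratio",
) -> BootstrapCI:
    """Bootstrap CI for a gene set's pooled SNP/FD ratio."""
    snp, fd = _set_arrays(genes)
    total_fd = int(fd.sum())
    if total_fd == 0:
        raise ValueError("set has zero FD sum; ratio undefined")
    rng = np.random.default_rng(seed)

    reps = np.empty(B)
    degenerate = 0
    filled = 0
    for start in range(0, B, _CHUNK):
        n_rep = min(_CHUNK, B - start)
        s, f = _resampled_sums(rng, snp, fd, n_rep)
        ok = f > 0
        degenerate += int((~ok).sum())
        k = int(ok.sum())
        reps[filled : filled + k] = s[ok] / f[ok]
        filled += k
    if filled == 0:
        raise ValueError("all bootstrap replicates had zero FD sums")
    lo, hi = _percentile_ci(reps[:filled], quantiles)
    return BootstrapCI(
        statistic_name=statistic_name,
        point_estimate=float(snp.sum() / total_fd),
        lower=lo,
        upper=hi,
        B=B,
        quantile_levels=tuple(quantiles),
        seed=seed,
        n_degenerate=degenerate,
    )


def bootstrap_normalized_ci(
    test_genes: GeneTable,
    background_genes: GeneTable,
    B: int = B_DEFAULT,
    seed: int = 0,
    quantiles: Tuple[float, float] = QUANTILES_DEFAULT,
    statistic_name: str = "normalized_diversity",
) -> BootstrapCI:
    """Bootstrap CI for normalized diversity (test ratio / background ratio).

    Test and background sets are resampled independently within each
    replicate, each with its own set size.  Use ``.log2()`` on the result
    for the log2-scale interval.
    """
    t_snp, t_fd = _set_arrays(test_genes)
    b_snp, b_fd = _set_arrays(background_genes)
    if t_fd.sum() == 0 or b_fd.sum() == 0:
        raise ValueError("test or background set has zero FD sum")
    rng = np.random.default_rng(seed)

    reps = np.empty(B)
    degenerate = 0
    filled = 0
    for start in range(0, B, _CHUNK):
        n_rep = min(_CHUNK, B - start)
        ts, tf = _resampled_sums(rng, t_snp, t_fd, n_rep)
        bs, bf = _resampled_sums(rng, b_snp, b_fd, n_rep)
        ok = (tf > 0) & (bf > 0) & (bs > 0)
        degenerate += int((~ok).sum())
        k = int(ok.sum())
        reps[filled : filled + k] = (ts[ok] / tf[ok]) / (bs[ok] / bf[ok])
        filled += k
    if filled == 0:
        raise ValueError("all bootstrap replicates degenerate")
    lo, hi = _percentile_ci(reps[:filled], quantiles)
    point = float((t_snp.sum() / t_fd.sum()) / (b_snp.sum() / b_fd.sum()))
    return BootstrapCI(
        statistic_name=statistic_name,
        point_estimate=point,
        lower=lo,
        upper=hi,
        B=B,
        quantile_levels=tuple(quantiles),
        seed=seed,
        n_degenerate=degenerate,
    )


def bootstrap_mean_normalized_ci(
    per_individual: Sequence[Tuple[GeneTable, GeneTable]],
    B: int = B_DEFAULT,
    seed: int = 0,
    quantiles: Tuple[float, float] = QUANTILES_DEFAULT,
    statistic_name: str = "mean_normalized_diversity",
) -> BootstrapCI:
    """Bootstrap CI for the across-individual mean normalized diversity.

    Each replicate resamples the test and background sets within every
    individual and averages the resulting normalized ratios — the CI
    behind "average values for AH/PDH" style comparisons.
    """
    arrays = []
    for test_genes, background_genes in per_individual:
        t = _set_arrays(test_genes)
        b = _set_arrays(background_genes)
        if t[1].sum() == 0 or b[1].sum() == 0:
            raise ValueError("an individual's set has zero FD sum")
        arrays.append((t, b))
    rng = np.random.default_rng(seed)

    reps = np.empty(B)
    degenerate = 0
    filled = 0
    for start in range(0, B, _CHUNK):
        n_rep = min(_CHUNK, B - start)
        acc = np.zeros(n_rep)
        ok = np.ones(n_rep, dtype=bool)
        for (t_snp, t_fd), (b_snp, b_fd) in arrays:
            ts, tf = _resampled_sums(rng, t_snp, t_fd, n_rep)
            bs, bf = _resampled_sums(rng, b_snp, b_fd, n_rep)
            good = (tf > 0) & (bf > 0) & (bs > 0)
            ok &= good
            with np.errstate(divide="ignore", invalid="ignore"):
                acc += np.where(good, (ts / np.maximum(tf, 1)) / np.maximum(bs / np.maximum(bf, 1), 1e-300), 0.0)
        degenerate += int((~ok).sum())
        k = int(ok.sum())
        reps[filled : filled + k] = acc[ok] / len(arrays)
        filled += k
    if filled == 0:
        raise ValueError("all bootstrap replicates degenerate")
    lo, hi = _percentile_ci(reps[:filled], quantiles)
    point = float(
        np.mean([
            (t_snp.sum() / t_fd.sum()) / (b_snp.sum() / b_fd.sum())
            for (t_snp, t_fd), (b_snp, b_fd) in arrays
        ])
    )
    return BootstrapCI(
        statistic_name=statistic_name,
        point_estimate=point,
        lower=lo,
        upper=hi,
        B=B,
        quantile_levels=tuple(quantiles),
        seed=seed,
        n_degenerate=degenerate,
    )
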