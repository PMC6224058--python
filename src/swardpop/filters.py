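"""SNP/locus filter cascade and read-depth saturation curves.

The cascade applies, in a fixed auditable order:

1. per-cell minimum depth (cells below become missing),
2. per-locus excessive total depth (repeat-region guard),
3. per-locus missing-data ceiling,
4. multi-allelic removal (a third allele observed in any sample),
5. mean-AAF band across samples (inclusive retention at the bounds).

Presets carry the thresholds used for the three dataset kinds: individual
plants, the three validation pools, and the 56 merged field pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AAFMatrix, AlleleCountMatrix, ValidationError


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 30
    max_total_depth: int = 150_000
    max_missing: int = 0
    mean_aaf_band: tuple[float, float] = (0.10, 0.90)
    remove_multiallelic: bool = True
    #: band applies to the mean across samples ("mean") or is satisfied when
    #: at least one sample falls inside it ("any-sample")
    band_scope: str = "mean"
    band_inclusive: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.mean_aaf_band
        if not (0 <= lo < hi <= 1):
            raise ValidationError("mean_aaf_band must satisfy 0 <= lo < hi <= 1")
        if self.min_depth < 1 or self.max_total_depth < 1:
            raise ValidationError("depth thresholds must be positive")
        if self.band_scope not in ("mean", "any-sample"):
            raise ValidationError("band_scope must be 'mean' or 'any-sample'")

    @classmethod
    def pool_preset(cls) -> "FilterConfig":
        """Thresholds for the 56 merged field pools (no missing data allowed)."""
        return cls(min_depth=30, max_total_depth=150_000, max_missing=0)

    @classmethod
    def validation_pool_preset(cls) -> "FilterConfig":
        """Thresholds for the three replicate validation pools."""
        return cls(min_depth=30, max_total_depth=3_500, max_missing=0)

    @classmethod
    def merged_pool_preset(cls) -> "FilterConfig":
        """Thresholds for pairwise-merged validation pools."""
        return cls(min_depth=30, max_total_depth=7_000, max_missing=0)

    @classmethod
    def individual_preset(cls, max_missing: int = 5) -> "FilterConfig":
        """Thresholds for individual-plant data (missing ceiling 1, 5 or 10)."""
        return cls(min_depth=30, max_total_depth=6_000, max_missing=max_missing)


@dataclass
class FilterReport:
    """Per-step surviving-locus counts plus the retained locus indices."""

    steps: list[tuple[str, int]] = field(default_factory=list)
    kept_indices: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_loci"])


def filter_cascade(
    counts: AlleleCountMatrix,
    aaf: AAFMatrix,
    cfg: FilterConfig,
) -> tuple[AAFMatrix, FilterReport]:
    """Apply the locus filter cascade; returns the filtered AAF matrix.

    ``counts`` and ``aaf`` must share loci and samples.  The report lists the
    number of surviving loci after each step; ``kept_indices`` indexes into
    the input loci so callers can subset the count matrix in parallel.
    """
    if counts.loci != aaf.loci or counts.samples != aaf.samples:
        raise ValidationError("counts and aaf must share loci and samples")

    report = FilterReport()
    report.steps.append(("input", counts.n_loci))

    # 1. per-cell depth -> missing
    depth = counts.depth
    missing = aaf.missing | (depth < cfg.min_depth)
    vals = np.where(missing, np.nan, aaf.aaf)
    report.steps.append(("min_depth_cells", counts.n_loci))

    keep = np.ones(counts.n_loci, dtype=bool)

    # 2. excessive total depth across samples
    total = depth.sum(axis=1) + counts.extra_allele_count.sum(axis=1)
    keep &= total <= cfg.max_total_depth
    report.steps.append(("max_total_depth", int(keep.sum())))

    # 3. missing-data ceiling
    keep &= missing.sum(axis=1) <= cfg.max_missing
    report.steps.append(("max_missing", int(keep.sum())))

    # 4. multi-allelic removal
    if cfg.remove_multiallelic:
        keep &= (counts.extra_allele_count == 0).all(axis=1)
    report.steps.append(("multiallelic", int(keep.sum())))

    # 5. mean-AAF band
    lo, hi = cfg.mean_aaf_band
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        if cfg.band_scope == "mean":
            stat = np.nanmean(vals, axis=1)
            in_band = _in_band(stat, lo, hi, cfg.band_inclusive)
        else:
            in_band = np.any(
                _in_band(vals, lo, hi, cfg.band_inclusive) & ~np.isnan(vals),
                axis=1,
            )
    keep &= np.where(np.isnan(vals).all(axis=1), False, in_band)
    report.steps.append(("mean_aaf_band", int(keep.sum())))

    idx = np.flatnonzero(keep)
    report.kept_indices = idx
    out = AAFMatrix(
        loci=[aaf.loci[i] for i in idx],
        samples=list(aaf.samples),
        aaf=vals[idx],
    )
    if out.n_loci == 0:
        warnings.warn("filter cascade removed every locus", stacklevel=2)
    return out, report


def _in_band(x: np.ndarray, lo: float, hi: float, inclusive: bool) -> np.ndarray:
    if inclusive:
        return (x >= lo) & (x <= hi)
    return (x > lo) & (x < hi)


def saturation_curve(
    read_positions: np.ndarray,
    thresholds: tuple[int, ...] = (10, 30, 100, 300),
    grid: tuple[int, ...] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Positions covered at each minimum depth as reads are subsampled.

    ``read_positions`` is the multiset of mapped positions, one entry per
    read.  For each grid value, that many reads are drawn without replacement
    (seeded) and the number of distinct positions with depth at or above each
    threshold is counted.  The curve is non-decreasing in reads for a fixed
    threshold and non-increasing in threshold for fixed reads.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    read_positions = np.asarray(read_positions)
    n_reads = read_positions.size
    if grid is None:
        grid = tuple(
            int(x) for x in np.linspace(0, n_reads, 6, dtype=int)
        )
    if max(grid) > n_reads:
        raise ValidationError("grid values must not exceed the read count")
    perm = rng.permutation(n_reads)  # one shuffle => nested subsamples
    rows = []
    for g in sorted(grid):
        sub = read_positions[perm[:g]]
        if sub.size:
            _, depth = np.unique(sub, return_counts=True)
        else:
            depth = np.array([], dtype=int)
        for t in thresholds:
            rows.append(
                {"reads": g, "threshold": t,
                 "positions": int((depth >= t).sum())}
            )
    return pd.DataFrame(rows)
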