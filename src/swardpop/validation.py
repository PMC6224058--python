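"""Pool-vs-individual validation metrics.

Agreement between pooled and individually-derived allele frequencies
(Pearson r and median absolute deviation), genotype-call concordance across
technical replicates, SNP-set intersections (Venn cells), and the AAF
spectrum of reproducible vs non-reproducible SNP calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .containers import AAFMatrix, GenotypeMatrix, MISSING_CALL, ValidationError


@dataclass(frozen=True)
class AgreementSummary:
    n_snps: int
    pearson_r: float
    median_deviation: float          # median |x - y|
    signed_median_deviation: float   # median (x - y), for bias inspection


def compare_aaf(x: np.ndarray, y: np.ndarray) -> AgreementSummary:
    """Pearson r and median absolute deviation over shared non-missing loci."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError("AAF vectors must have equal length")
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValidationError(
            f"need >= 3 paired non-missing values, got {int(ok.sum())}"
        )
    xs, ys = x[ok], y[ok]
    r = float(stats.pearsonr(xs, ys).statistic)
    return AgreementSummary(
        n_snps=int(ok.sum()),
        pearson_r=r,
        median_deviation=float(np.median(np.abs(xs - ys))),
        signed_median_deviation=float(np.median(xs - ys)),
    )


def genotype_concordance(
    replicates: list[GenotypeMatrix],
    denominator: str = "all-called",
) -> dict[str, float]:
    """Identical-call fractions across technical replicates of one individual.

    Loci are intersected by (chrom, pos); fractions are computed over loci
    called (non-missing) in every replicate compared (``all-called``) or in at
    least one (``union``, missing counted as discordant).
    """
    if len(replicates) < 2:
        raise ValidationError("need at least 2 replicates")
    keysets = [dict((l.key, i) for i, l in enumerate(g.loci))
               for g in replicates]
    shared = set(keysets[0])
    for ks in keysets[1:]:
        shared &= set(ks)
    if not shared:
        raise ValidationError("replicates share no loci")
    shared = sorted(shared)
    calls = np.stack(
        [
            g.calls[[ks[k] for k in shared], 0]
            for g, ks in zip(replicates, keysets)
        ]
    )  # replicates x loci

    def pair_frac(a: np.ndarray, b: np.ndarray) -> float:
        if denominator == "all-called":
            ok = (a != MISSING_CALL) & (b != MISSING_CALL)
            if ok.sum() == 0:
                return float("nan")
            return float((a[ok] == b[ok]).mean())
        ok = (a != MISSING_CALL) | (b != MISSING_CALL)
        return float(((a == b) & (a != MISSING_CALL))[ok].mean())

    pairwise = [
        pair_frac(calls[i], calls[j])
        for i, j in combinations(range(len(replicates)), 2)
    ]
    if denominator == "all-called":
        ok = (calls != MISSING_CALL).all(axis=0)
    else:
        ok = (calls != MISSING_CALL).any(axis=0)
    allway = float(
        ((calls[:, ok] == calls[0, ok]).all(axis=0)).mean()
    ) if ok.sum() else float("nan")
    return {
        "pairwise_identical_fraction": float(np.mean(pairwise)),
        "allway_identical_fraction": allway,
        "n_shared_loci": len(shared),
    }


def snp_set_intersections(sets: dict[str, set]) -> dict:
    """Exact Venn-cell counts for 2 or 3 named SNP sets.

    Cell keys are frozensets of the set names whose members (and only whose
    members) contain the SNP; percentages are relative to the union.
    """
    if len(sets) < 2:
        raise ValidationError("need at least 2 sets")
    names = list(sets)
    union = set().union(*sets.values())
    cells: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(
                *(sets[n] for n in names if n not in combo), set()
            )
            cells[frozenset(combo)] = len(inside - outside)
    pct = {
        cell: (100.0 * n / len(union) if union else 0.0)
        for cell, n in cells.items()
    }
    return {"cells": cells, "percent_of_union": pct, "union_size": len(union)}


def spectrum_by_reproducibility(
    aaf: AAFMatrix,
    reproducible: set,
    nonreproducible: set,
    sample: str,
    cutoff: float = 0.03,
) -> dict[str, float]:
    """Fraction of SNPs below an AAF cutoff, per reproducibility class.

    ``reproducible``/``nonreproducible`` are disjoint sets of (chrom, pos)
    keys; fractions are computed in the focal ``sample``.
    """
    if reproducible & nonreproducible:
        raise ValidationError("reproducible and non-reproducible sets overlap")
    j = aaf.sample_index(sample)
    by_key = {l.key: i for i, l in enumerate(aaf.loci)}

    def frac(snps: set) -> float:
        idx = [by_key[k] for k in snps if k in by_key]
        vals = aaf.aaf[idx, j]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            warnings.warn("empty reproducibility class", stacklevel=3)
            return float("nan")
        return float((vals < cutoff).mean())

    return {
        "reproducible_below_cutoff": frac(reproducible),
        "nonreproducible_below_cutoff": frac(nonreproducible),
        "cutoff": cutoff,
    }
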