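"""Pooled allele-frequency estimation from allelic read counts.

For a pool of ``n_plants`` diploids the latent alternative-allele frequency
lives (to sampling resolution) on the grid ``f_k = k / n`` with
``n = 2 * n_plants`` chromosomes.  We place a discrete posterior on that grid:

* likelihood: ``alt ~ Binomial(ref + alt, f (1 - eps) + (1 - f) eps)`` with
  a symmetric per-read error rate ``eps``;
* prior: a folded, informative neutral-diversity prior.  Interior grid points
  receive mass proportional to ``1/f + 1/(1 - f)`` (the folded Watterson
  shape), normalised so the total interior mass equals ``min(1, theta * a_n)``
  with ``a_n`` the harmonic number ``sum_{i<n} 1/i``; the remaining mass is
  split equally between the fixed-reference (f = 0) and fixed-alternative
  (f = 1) boundary points.

The summary carries the posterior mean (the AAF estimate) and the boundary
masses ``p0``/``p1``, to which the fixation rules are applied: the frequency
is snapped to 0 whenever ``1 - p0 < 0.9`` and to 1 whenever ``p1 > 0.9``
(zero rule evaluated first).  Note the zero rule is deliberately asymmetric —
it zeroes a site whenever the posterior leaves more than 10% mass on the
fixed-reference boundary, which is a conservative guard against error-driven
low-frequency calls.

``theta`` itself is estimated per pooled sample with a simplified Watterson
estimator: the fraction of assessable sites (depth >= ``min_depth``) that
segregate (minor-allele read count >= ``mac``), divided by ``a_n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    AAFMatrix,
    AlleleCountMatrix,
    ConfigError,
    GenotypeMatrix,
    MISSING_CALL,
    ValidationError,
)

DEFAULT_ERROR_RATE = 1e-3
DEFAULT_POOL_SIZE = 40


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (Watterson's denominator for n chromosomes)."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass(frozen=True)
class ThetaEstimate:
    """Per-sample Watterson-style diversity estimate used as a prior scale."""

    theta: float
    n_segregating: int
    n_sites: int
    mac_threshold: int
    pool_chromosomes: int

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValidationError("theta must be >= 0")


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summary for one locus x sample cell."""

    aaf_estimate: float
    p0: float
    p1: float
    depth: int

    def __post_init__(self) -> None:
        if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1):
            raise ValidationError("boundary masses must lie in [0, 1]")
        if self.p0 + self.p1 > 1 + 1e-9:
            raise ValidationError("p0 + p1 must not exceed 1")


def estimate_theta(
    counts: AlleleCountMatrix,
    sample: str,
    mac: int = 3,
    min_depth: int = 30,
    pool_size: int = DEFAULT_POOL_SIZE,
) -> ThetaEstimate:
    """Watterson-style theta for one pooled sample.

    theta = S / (L * a_n) with S the number of segregating sites (minor-allele
    read count >= ``mac``) among the L sites with depth >= ``min_depth``, and
    n = 2 * pool_size chromosomes.
    """
    if mac < 1:
        raise ConfigError("mac must be >= 1")
    j = counts.sample_index(sample)
    ref = counts.ref_count[:, j]
    alt = counts.alt_count[:, j]
    depth = ref + alt
    assessable = depth >= min_depth
    n_sites = int(assessable.sum())
    if n_sites == 0:
        raise ValidationError(
            f"no assessable sites for sample {sample!r} at min_depth={min_depth}"
        )
    minor = np.minimum(ref, alt)
    n_seg = int((assessable & (minor >= mac)).sum())
    n_chrom = 2 * pool_size
    theta = n_seg / (n_sites * harmonic_number(n_chrom))
    return ThetaEstimate(
        theta=theta,
        n_segregating=n_seg,
        n_sites=n_sites,
        mac_threshold=mac,
        pool_chromosomes=n_chrom,
    )


def _prior_log(theta: float, pool_chromosomes: int) -> np.ndarray:
    """Log prior over the (n+1)-point frequency grid."""
    n = pool_chromosomes
    f = np.arange(1, n) / n
    raw = 1.0 / f + 1.0 / (1.0 - f)
    interior_mass = min(1.0, theta * harmonic_number(n))
    # theta == 0 collapses the prior onto the boundaries; keep a tiny interior
    # floor so the posterior remains proper for genuinely polymorphic data.
    interior_mass = max(interior_mass, 1e-12)
    prior = np.empty(n + 1)
    prior[1:n] = raw / raw.sum() * interior_mass
    prior[0] = prior[n] = (1.0 - interior_mass) / 2.0
    return np.log(np.maximum(prior, 1e-300))


def posterior_af(
    ref: int,
    alt: int,
    theta: ThetaEstimate | float,
    error_rate: float = DEFAULT_ERROR_RATE,
    pool_chromosomes: int = 2 * DEFAULT_POOL_SIZE,
) -> PosteriorSummary:
    """Grid posterior for a single (ref, alt) read-count pair."""
    if not 0 <= error_rate < 0.5:
        raise ConfigError("error_rate must be in [0, 0.5)")
    if pool_chromosomes < 2:
        raise ConfigError("pool_chromosomes must be >= 2")
    if ref < 0 or alt < 0 or ref + alt < 1:
        raise ValidationError("need ref, alt >= 0 with ref + alt >= 1")
    th = theta.theta if isinstance(theta, ThetaEstimate) else float(theta)
    n = pool_chromosomes
    f = np.arange(n + 1) / n
    q = f * (1 - error_rate) + (1 - f) * error_rate
    q = np.clip(q, 1e-300, 1 - 1e-16)
    log_post = (
        _prior_log(th, n) + alt * np.log(q) + ref * np.log1p(-q)
    )
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    return PosteriorSummary(
        aaf_estimate=float(np.dot(f, post)),
        p0=float(post[0]),
        p1=float(post[n]),
        depth=ref + alt,
    )


def apply_fixation_rules(post: PosteriorSummary) -> float:
    """Snap an estimate to a boundary per the posterior fixation rules.

    Zero rule first: return 0 when 1 - p0 < 0.9; then return 1 when p1 > 0.9;
    otherwise return the posterior mean.
    """
    if 1.0 - post.p0 < 0.9:
        return 0.0
    if post.p1 > 0.9:
        return 1.0
    return post.aaf_estimate


def posterior_af_matrix(
    counts: AlleleCountMatrix,
    theta: dict[str, ThetaEstimate] | float,
    error_rate: float = DEFAULT_ERROR_RATE,
    pool_chromosomes: int = 2 * DEFAULT_POOL_SIZE,
    chunk: int = 200_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised grid posterior over a whole count matrix.

    Returns (aaf_mean, p0, p1) arrays of shape (n_loci, n_samples); cells with
    zero depth are NaN.  ``theta`` may be a mapping sample -> ThetaEstimate
    (per-sample priors, as estimated from the data) or a single scalar.
    """
    if not 0 <= error_rate < 0.5:
        raise ConfigError("error_rate must be in [0, 0.5)")
    n = pool_chromosomes
    f = np.arange(n + 1) / n
    q = np.clip(f * (1 - error_rate) + (1 - f) * error_rate, 1e-300, 1 - 1e-16)
    log_q = np.log(q)
    log_1mq = np.log1p(-q)

    shape = (counts.n_loci, counts.n_samples)
    aaf = np.full(shape, np.nan)
    p0 = np.full(shape, np.nan)
    p1 = np.full(shape, np.nan)

    for j, s in enumerate(counts.samples):
        th = theta[s].theta if isinstance(theta, dict) else float(theta)
        log_prior = _prior_log(th, n)
        ref = counts.ref_count[:, j].astype(float)
        alt = counts.alt_count[:, j].astype(float)
        ok = ref + alt >= 1
        idx = np.flatnonzero(ok)
        for start in range(0, idx.size, chunk):
            block = idx[start : start + chunk]
            lp = (
                log_prior[None, :]
                + alt[block, None] * log_q[None, :]
                + ref[block, None] * log_1mq[None, :]
            )
            lp -= lp.max(axis=1, keepdims=True)
            post = np.exp(lp)
            post /= post.sum(axis=1, keepdims=True)
            aaf[block, j] = post @ f
            p0[block, j] = post[:, 0]
            p1[block, j] = post[:, n]
    return aaf, p0, p1


def estimate_aaf_matrix(
    counts: AlleleCountMatrix,
    error_rate: float = DEFAULT_ERROR_RATE,
    mac: int = 3,
    min_depth: int = 30,
    pool_size: int = DEFAULT_POOL_SIZE,
    apply_fixation: bool = True,
) -> tuple[AAFMatrix, dict[str, ThetaEstimate]]:
    """Full stage-one estimation: per-sample theta, grid posterior, fixation.

    Cells with zero depth are missing in the returned matrix.
    """
    thetas = {
        s: estimate_theta(counts, s, mac=mac, min_depth=min_depth,
                          pool_size=pool_size)
        for s in counts.samples
    }
    aaf, p0, p1 = posterior_af_matrix(
        counts, thetas, error_rate=error_rate, pool_chromosomes=2 * pool_size
    )
    if apply_fixation:
        with np.errstate(invalid="ignore"):
            aaf = np.where(1.0 - p0 < 0.9, 0.0, aaf)
            aaf = np.where((p1 > 0.9) & ~(1.0 - p0 < 0.9), 1.0, aaf)
        aaf[np.isnan(p0)] = np.nan
    return (
        AAFMatrix(loci=list(counts.loci), samples=list(counts.samples),
                  aaf=aaf),
        thetas,
    )


def aaf_from_genotypes(gt: GenotypeMatrix, locus_index: int) -> float:
    """Alternative-allele frequency from individual calls at one locus.

    Sum of alternative-allele doses over the called individuals divided by the
    number of called chromosomes (2 per individual); missing calls drop out of
    numerator and denominator.  NaN when every call is missing.
    """
    row = gt.calls[locus_index]
    called = row != MISSING_CALL
    n = int(called.sum())
    if n == 0:
        return float("nan")
    return float(row[called].sum() / (2 * n))


def aaf_matrix_from_genotypes(gt: GenotypeMatrix) -> np.ndarray:
    """Per-locus AAF_ind over all individuals (NaN where all calls missing)."""
    called = gt.calls != MISSING_CALL
    n = called.sum(axis=1)
    dose = np.where(called, gt.calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, dose / (2.0 * n), np.nan)
    return out
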