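"""Core in-memory containers for the pooled-GBS sward pipeline.

The pipeline operates on three aligned matrix containers — raw allelic read
counts, alternative-allele frequencies (AAF) and individual genotype calls —
all indexed by an ordered list of biallelic loci and an ordered list of sample
(or individual) identifiers.  Loci are kept in a deterministic order (chrom
lexicographic, then position ascending) so that matrices from different
pipeline stages can be joined positionally.

Missing AAF values are carried as an explicit boolean mask; the ``aaf`` array
holds NaN under the mask purely so that accidental unmasked arithmetic is
loud rather than silently wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING_CALL = -1  # sentinel in GenotypeMatrix.calls (dose otherwise 0/1/2)


class FormatError(ValueError):
    """A file does not conform to the expected layout (header, fields)."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant (range, uniqueness)."""


class ConfigError(ValueError):
    """A configuration value is outside its allowed domain."""


@dataclass(frozen=True, order=True)
class Locus:
    """A biallelic SNP locus (1-based position, VCF convention)."""

    chrom: str
    pos: int
    ref_allele: str = "N"
    alt_allele: str = "N"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"locus position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"ref and alt allele identical ({self.ref_allele}) at "
                f"{self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _check_unique_sorted(loci: list[Locus]) -> None:
    keys = [l.key for l in loci]
    if len(set(keys)) != len(keys):
        seen, dup = set(), None
        for k in keys:
            if k in seen:
                dup = k
                break
            seen.add(k)
        raise ValidationError(f"duplicate locus {dup[0]}:{dup[1]}")


def locus_order(loci: list[Locus]) -> np.ndarray:
    """Indices that sort loci by (chrom, pos)."""
    return np.array(
        sorted(range(len(loci)), key=lambda i: loci[i].key), dtype=np.intp
    )


@dataclass
class AlleleCountMatrix:
    """Per-locus x per-sample reference / alternative read counts.

    ``extra_allele_count`` holds reads supporting neither the reference nor
    the recorded alternative allele; any non-zero entry marks the locus as
    multi-allelic for filtering purposes.
    """

    loci: list[Locus]
    samples: list[str]
    ref_count: np.ndarray
    alt_count: np.ndarray
    extra_allele_count: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = (len(self.loci), len(self.samples))
        if self.extra_allele_count is None:
            self.extra_allele_count = np.zeros(shape, dtype=np.int64)
        for name in ("ref_count", "alt_count", "extra_allele_count"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != shape:
                raise ValidationError(
                    f"{name} shape {arr.shape} inconsistent with "
                    f"{len(self.loci)} loci x {len(self.samples)} samples"
                )
            if (arr < 0).any():
                raise ValidationError(f"negative value in {name}")
            setattr(self, name, arr)
        _check_unique_sorted(self.loci)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def depth(self) -> np.ndarray:
        """ref + alt read depth (extra-allele reads excluded)."""
        return self.ref_count + self.alt_count

    def sorted_by_locus(self) -> "AlleleCountMatrix":
        order = locus_order(self.loci)
        return AlleleCountMatrix(
            loci=[self.loci[i] for i in order],
            samples=list(self.samples),
            ref_count=self.ref_count[order],
            alt_count=self.alt_count[order],
            extra_allele_count=self.extra_allele_count[order],
        )

    def select_loci(self, index: np.ndarray) -> "AlleleCountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return AlleleCountMatrix(
            loci=[self.loci[i] for i in index],
            samples=list(self.samples),
            ref_count=self.ref_count[index],
            alt_count=self.alt_count[index],
            extra_allele_count=self.extra_allele_count[index],
        )

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCountMatrix):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.samples == other.samples
            and np.array_equal(self.ref_count, other.ref_count)
            and np.array_equal(self.alt_count, other.alt_count)
            and np.array_equal(self.extra_allele_count, other.extra_allele_count)
        )


@dataclass
class AAFMatrix:
    """Alternative-allele frequencies with an explicit missing mask."""

    loci: list[Locus]
    samples: list[str]
    aaf: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = (len(self.loci), len(self.samples))
        self.aaf = np.asarray(self.aaf, dtype=float).copy()
        if self.aaf.shape != shape:
            raise ValidationError(
                f"aaf shape {self.aaf.shape} inconsistent with loci/samples"
            )
        if self.missing is None:
            self.missing = np.isnan(self.aaf)
        self.missing = np.asarray(self.missing, dtype=bool).copy()
        if self.missing.shape != shape:
            raise ValidationError("missing mask shape mismatch")
        self.missing |= np.isnan(self.aaf)
        self.aaf[self.missing] = np.nan
        valid = self.aaf[~self.missing]
        if valid.size and ((valid < 0) | (valid > 1)).any():
            raise ValidationError("AAF value outside [0, 1]")
        _check_unique_sorted(self.loci)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_complete(self) -> bool:
        return not self.missing.any()

    def select_loci(self, index: np.ndarray) -> "AAFMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return AAFMatrix(
            loci=[self.loci[i] for i in index],
            samples=list(self.samples),
            aaf=self.aaf[index],
            missing=self.missing[index],
        )

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AAFMatrix):
            return NotImplemented
        same_vals = np.array_equal(
            np.where(self.missing, -9.0, self.aaf),
            np.where(other.missing, -9.0, other.aaf),
        )
        return (
            self.loci == other.loci
            and self.samples == other.samples
            and np.array_equal(self.missing, other.missing)
            and same_vals
        )


@dataclass
class GenotypeMatrix:
    """Per-locus x per-individual genotype calls.

    ``calls`` holds the alternative-allele dose (0 = hom ref, 1 = het,
    2 = hom alt) or :data:`MISSING_CALL`.
    """

    loci: list[Locus]
    individuals: list[str]
    calls: np.ndarray
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (len(self.loci), len(self.individuals))
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != shape:
            raise ValidationError("calls shape inconsistent with loci/individuals")
        allowed = {MISSING_CALL, 0, 1, 2}
        observed = set(np.unique(self.calls).tolist())
        if not observed <= allowed:
            raise ValidationError(f"invalid genotype codes {observed - allowed}")
        _check_unique_sorted(self.loci)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def select_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            loci=[self.loci[i] for i in index],
            individuals=list(self.individuals),
            calls=self.calls[index],
            depth=None if self.depth is None else self.depth[index],
            gq=None if self.gq is None else self.gq[index],
        )
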