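"""Genetic diversity and cultivar-composition dynamics.

Expected heterozygosity per locus and sample (He = 2 p (1 - p) on the pooled
alternative-allele frequency), its per-sample mean as a diversity index, the
composition/replicate/year sequential ANOVA of mean He, PCA of the AAF matrix
(centered, not scaled; samples as rows), cultivar-private SNP detection, and
the private-SNP-based cultivar-abundance estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import design_blocks, sequential_decomposition
from .containers import AAFMatrix, ValidationError
from .design import SampleDesign

_OTHER = {"Merks": "Meloni", "Meloni": "Merks"}


@dataclass
class DiversityTable:
    samples: list[str]
    he: np.ndarray          # loci x samples
    mean_he: pd.Series      # per sample, over non-missing loci


def heterozygosity(aaf: AAFMatrix) -> DiversityTable:
    """He = 2 p (1 - p) per locus and sample; mean He per sample."""
    with np.errstate(invalid="ignore"):
        he = 2.0 * aaf.aaf * (1.0 - aaf.aaf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(he, axis=0)
    return DiversityTable(
        samples=list(aaf.samples),
        he=he,
        mean_he=pd.Series(mean, index=aaf.samples, name="mean_he"),
    )


def _align(design: list[SampleDesign], samples: list[str]
           ) -> list[SampleDesign]:
    by_id = {s.sample_id: s for s in design}
    missing = [x for x in samples if x not in by_id]
    if missing:
        raise ValidationError(f"samples not in design: {missing[:5]}")
    return [by_id[x] for x in samples]


def anova_mean_he(
    div: DiversityTable, design: list[SampleDesign]
) -> pd.DataFrame:
    """Sequential ANOVA of mean He: composition, comp x replicate, comp x year.

    On the full 7 x 2 x 4 design the df column is (6, 7, 21) with 21 residual
    df.  Returns a frame with term, df, sum_sq, mean_sq, F, p rows (residual
    last).
    """
    aligned = _align(design, div.samples)
    y = div.mean_he.to_numpy()
    blocks = design_blocks(aligned)
    dec = sequential_decomposition(y, blocks)
    df_map = dec.attrs["df"]
    for term, d in df_map.items():
        if term != "residual" and d == 0:
            raise ValidationError(
                f"term {term} confounded with earlier terms (0 df)"
            )
    if df_map["residual"] < 1:
        raise ValidationError("no residual degrees of freedom")
    rows = []
    ms_res = float(dec["rss"][0]) / df_map["residual"]
    for term in ("comp", "comp_rep", "comp_year"):
        ss = float(dec[f"ss_{term}"][0])
        d = df_map[term]
        ms = ss / d
        F = ms / ms_res if ms_res > 0 else np.inf if ms > 0 else np.nan
        p = float(stats.f.sf(F, d, df_map["residual"])) if np.isfinite(F) else np.nan
        rows.append({"term": term, "df": d, "sum_sq": ss, "mean_sq": ms,
                     "F": F, "p": p})
    rows.append({"term": "residual", "df": df_map["residual"],
                 "sum_sq": float(dec["rss"][0]), "mean_sq": ms_res,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


@dataclass
class PcaResult:
    scores: np.ndarray              # samples x components
    variance_explained: np.ndarray  # fractions, non-increasing
    loadings: np.ndarray            # loci x components
    samples: list[str]

    def pc1(self) -> pd.Series:
        return pd.Series(self.scores[:, 0], index=self.samples, name="pc1")


def pca_aaf(
    aaf: AAFMatrix, design: list[SampleDesign] | None = None
) -> PcaResult:
    """PCA of the centered, non-scaled AAF matrix (samples as rows).

    The PC1 sign is fixed so that pure-Merks samples (ryegrass content Merks
    only) score negative on average; without such samples (or a design) the
    largest-magnitude loading of each component is made positive.
    """
    if not aaf.is_complete():
        raise ValidationError("AAF matrix has missing values; filter first")
    if aaf.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if aaf.n_loci < 1:
        raise ValidationError("PCA needs at least 1 locus")
    X = aaf.aaf.T.copy()                      # samples x loci
    X -= X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(aaf.n_samples - 1, aaf.n_loci)
    scores = (U * s)[:, :k]
    loadings = Vt.T[:, :k]
    var = s[:k] ** 2
    var_frac = var / max((X**2).sum(), np.finfo(float).tiny)

    signs = np.ones(k)
    for c in range(k):
        signs[c] = 1.0 if loadings[np.argmax(np.abs(loadings[:, c])), c] >= 0 else -1.0
    if design is not None:
        aligned = _align(design, list(aaf.samples))
        pure_merks = [i for i, s_ in enumerate(aligned)
                      if s_.ryegrass_content == "Merks"]
        if pure_merks and scores[pure_merks, 0].mean() * signs[0] > 0:
            signs[0] *= -1.0
    return PcaResult(
        scores=scores * signs,
        variance_explained=var_frac,
        loadings=loadings * signs,
        samples=list(aaf.samples),
    )


def private_snps(
    aaf: AAFMatrix,
    design: list[SampleDesign],
    focal: str,
    min_aaf: float = 0.0,
    include_mixtures: bool = True,
) -> np.ndarray:
    """Indices of loci private to the focal ryegrass cultivar.

    A locus is focal-private when its AAF is exactly 0 (post fixation rules)
    in every sample of plots containing only the other cultivar, and exceeds
    ``min_aaf`` in at least one sample of a plot containing the focal cultivar
    (pure or, by default, mixed).
    """
    if focal not in _OTHER:
        raise ValidationError(f"focal cultivar must be Merks or Meloni, got {focal!r}")
    aligned = _align(design, list(aaf.samples))
    other = _OTHER[focal]
    pure_other = [i for i, s in enumerate(aligned)
                  if s.ryegrass_content == other]
    if not pure_other:
        raise ValidationError(f"design has no pure {other} plots")
    focal_contents = {focal, "both"} if include_mixtures else {focal}
    with_focal = [i for i, s in enumerate(aligned)
                  if s.ryegrass_content in focal_contents]
    vals = aaf.aaf
    zero_in_other = (vals[:, pure_other] == 0.0).all(axis=1)
    poly_in_focal = np.nan_to_num(vals[:, with_focal], nan=0.0).max(axis=1) > min_aaf
    return np.flatnonzero(zero_in_other & poly_in_focal)


def cultivar_abundance(
    aaf: AAFMatrix,
    private_merks: np.ndarray,
    private_meloni: np.ndarray,
    design: list[SampleDesign],
) -> pd.DataFrame:
    """Per-sample mean private-SNP AAF and cultivar-proportion estimates.

    The proportion estimate normalises each sample's mean private AAF by the
    average over pure plots of the focal cultivar, where the proportion is 1
    by construction.
    """
    if len(private_merks) == 0 or len(private_meloni) == 0:
        raise ValidationError("both private SNP sets must be non-empty")
    aligned = _align(design, list(aaf.samples))
    out = pd.DataFrame(index=pd.Index(aaf.samples, name="sample_id"))
    out["seed_composition"] = [s.seed_composition for s in aligned]
    out["replicate"] = [s.replicate for s in aligned]
    out["year"] = [s.year for s in aligned]
    for focal, idx in (("merks", private_merks), ("meloni", private_meloni)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_priv = np.nanmean(aaf.aaf[np.asarray(idx)], axis=0)
        out[f"mean_private_aaf_{focal}"] = mean_priv
        pure = [i for i, s in enumerate(aligned)
                if s.ryegrass_content == focal.capitalize()]
        ref = float(np.nanmean(mean_priv[pure])) if pure else np.nan
        if not np.isfinite(ref) or ref == 0:
            warnings.warn(
                f"pure-plot mean private AAF for {focal} is zero or missing; "
                "proportion estimate unavailable",
                stacklevel=2,
            )
            out[f"w_{focal}"] = np.nan
        else:
            out[f"w_{focal}"] = mean_priv / ref
    return out
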