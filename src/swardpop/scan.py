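"""Per-SNP selection scan on pooled allele-frequency time series.

Each SNP's AAF vector over the 56 samples is decomposed sequentially into a
PC1 covariate (cultivar differentiation and mixture dynamics), seed
composition, composition-by-replicate, composition-by-year and residual
components.  The scan statistic is the ratio of the composition-by-year mean
square to the residual mean square: temporal change consistent across
replicate plots of a composition, relative to plot-specific change.  The null
distribution of the statistic is fitted empirically by maximum likelihood
(log-normal, chi-square, F and gamma candidates; AIC selection), upper-tail
p-values are drawn from the selected fit, and outliers are called by
Benjamini-Hochberg FDR.

The statistic ``stat_mss_over_rss`` (mean square over the residual *sum* of
squares) is emitted alongside; it differs from the default only by the
constant residual df, so the empirically fitted p-values are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._linalg import design_blocks, sequential_decomposition
from .containers import AAFMatrix, ValidationError
from .design import SampleDesign

TERMS = ("pc1", "comp", "comp_rep", "comp_year")


@dataclass(frozen=True)
class NullFit:
    family: str
    params: tuple[float, ...]
    log_likelihood: float
    aic: float
    selected: bool = False

    def frozen(self):
        return _FAMILIES[self.family](self.params)


def _lognorm(params):
    mu, sigma = params
    return stats.lognorm(s=sigma, scale=np.exp(mu))


def _chi2(params):
    df, scale = params
    return stats.chi2(df, loc=0, scale=scale)


def _fdist(params):
    dfn, dfd = params
    return stats.f(dfn, dfd, loc=0, scale=1)


def _gamma(params):
    shape, scale = params
    return stats.gamma(shape, loc=0, scale=scale)


_FAMILIES = {
    "lognormal": _lognorm,
    "chisquare": _chi2,
    "F": _fdist,
    "gamma": _gamma,
}


def decompose_variance_matrix(
    aaf: AAFMatrix,
    design: list[SampleDesign],
    pc1: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Sequential variance decomposition of every SNP row.

    Requires a complete AAF matrix whose sample order matches ``design``.
    Returns one row per SNP with per-term SS, RSS, TSS, the scan statistic
    and its literal MSS/RSS variant; df per term are in ``attrs['df']``.
    SNPs with zero total or residual variance get NaN statistics and are
    flagged in the ``degenerate`` column.
    """
    if not aaf.is_complete():
        raise ValidationError("AAF matrix has missing values; filter first")
    by_id = {s.sample_id: s for s in design}
    try:
        aligned = [by_id[x] for x in aaf.samples]
    except KeyError as exc:
        raise ValidationError(f"sample {exc} not in design") from exc
    pc1 = np.asarray(
        pc1.reindex(aaf.samples) if isinstance(pc1, pd.Series) else pc1, float
    )
    if pc1.shape != (aaf.n_samples,):
        raise ValidationError("pc1 scores must be one value per sample")
    blocks = design_blocks(aligned, pc1=pc1)
    dec = sequential_decomposition(aaf.aaf.T, blocks)
    df_map = dec.attrs["df"]
    ms_sy = dec["ss_comp_year"] / df_map["comp_year"]
    ms_res = dec["rss"] / df_map["residual"]
    degenerate = (dec["tss"] <= 0) | (dec["rss"] <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dec["stat"] = np.where(degenerate, np.nan, ms_sy / ms_res)
        dec["stat_mss_over_rss"] = np.where(degenerate, np.nan,
                                            ms_sy / dec["rss"])
    dec["degenerate"] = degenerate
    dec.attrs["df"] = df_map
    return dec


def decompose_variance(
    aaf_row: np.ndarray,
    design: list[SampleDesign],
    pc1: np.ndarray,
) -> pd.Series:
    """Decomposition of a single SNP's AAF vector (see matrix variant)."""
    aaf_row = np.asarray(aaf_row, float)
    if np.isnan(aaf_row).any():
        raise ValidationError("AAF row has missing values")
    blocks = design_blocks(design, pc1=np.asarray(pc1, float))
    dec = sequential_decomposition(aaf_row, blocks)
    row = dec.iloc[0].copy()
    df_map = dec.attrs["df"]
    if row["tss"] <= 0 or row["rss"] <= 0:
        row["stat"] = np.nan
        row["degenerate"] = True
    else:
        row["stat"] = (
            (row["ss_comp_year"] / df_map["comp_year"])
            / (row["rss"] / df_map["residual"])
        )
        row["degenerate"] = False
    return row


def scan_statistic(decomposition: pd.DataFrame) -> np.ndarray:
    """The scan statistic column (NaN for degenerate SNPs)."""
    return decomposition["stat"].to_numpy()


def fit_null(
    statistics: np.ndarray,
    families: tuple[str, ...] = ("lognormal", "chisquare", "F", "gamma"),
) -> list[NullFit]:
    """MLE fit of candidate null families; lowest AIC is marked selected.

    Non-finite and non-positive statistics are excluded (their count is
    available from the caller's data); at least 100 usable values are
    required.  The log-normal is parameterised by the mean and standard
    deviation of the log statistics, which is its exact MLE.
    """
    x = np.asarray(statistics, float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 100:
        raise ValidationError(
            f"need >= 100 finite positive statistics, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise ValidationError("statistics are constant; cannot fit a null")
    fits = []
    for fam in families:
        if fam == "lognormal":
            lx = np.log(x)
            params = (float(lx.mean()), float(lx.std(ddof=0)))
        elif fam == "chisquare":
            df, _, scale = stats.chi2.fit(x, floc=0)
            params = (float(df), float(scale))
        elif fam == "F":
            dfn, dfd, _, _ = stats.f.fit(x, floc=0, fscale=1)
            params = (float(dfn), float(dfd))
        elif fam == "gamma":
            shape, _, scale = stats.gamma.fit(x, floc=0)
            params = (float(shape), float(scale))
        else:
            raise ValueError(f"unknown family {fam!r}")
        ll = float(_FAMILIES[fam](params).logpdf(x).sum())
        fits.append(
            NullFit(family=fam, params=params, log_likelihood=ll,
                    aic=2 * len(params) - 2 * ll)
        )
    best = int(np.argmin([f.aic for f in fits]))
    fits[best] = NullFit(**{**vars(fits[best]), "selected": True})
    return fits


def selected_fit(fits: list[NullFit]) -> NullFit:
    return next(f for f in fits if f.selected)


def pvalues_and_calls(
    statistics: np.ndarray,
    fit: NullFit,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail p-values, BH q-values, outlier flags, KS diagnostic.

    The KS statistic and p-value of the p-values against Uniform(0, 1) are in
    ``attrs['ks']``; they diagnose how well the fitted null describes the
    observed statistic distribution.
    """
    x = np.asarray(statistics, float)
    dist = fit.frozen()
    p = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    p[ok] = dist.sf(x[ok])
    q = np.full(x.shape, np.nan)
    outlier = np.zeros(x.shape, dtype=bool)
    if ok.any():
        rej, qvals, _, _ = multipletests(p[ok], alpha=fdr, method="fdr_bh")
        q[ok] = qvals
        outlier[ok] = rej
    ks = stats.kstest(p[ok], "uniform")
    out = pd.DataFrame({"stat": x, "p": p, "q": q, "outlier": outlier})
    out.attrs["ks"] = {"statistic": float(ks.statistic),
                       "pvalue": float(ks.pvalue)}
    out.attrs["fdr"] = fdr
    return out


def run_scan(
    aaf: AAFMatrix,
    design: list[SampleDesign],
    pc1: np.ndarray | pd.Series,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, list[NullFit]]:
    """Decompose, fit the null, and call outliers in one step."""
    dec = decompose_variance_matrix(aaf, design, pc1)
    fits = fit_null(dec["stat"].to_numpy())
    calls = pvalues_and_calls(dec["stat"].to_numpy(), selected_fit(fits),
                              fdr=fdr)
    result = pd.concat([dec.reset_index(drop=True),
                        calls[["p", "q", "outlier"]]], axis=1)
    result.attrs.update(dec.attrs)
    result.attrs["ks"] = calls.attrs["ks"]
    return result, fits
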