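"""Herbage yield arithmetic and the mixed-model hypothesis tests.

Dry-matter weight (DMW, t/ha) is the plot fresh weight scaled by the dried
subsample's dry-matter fraction; botanical fractions are the per-subsample
dry-weight shares averaged over subsamples.  Annual DMW is analysed with
linear mixed models (maximum likelihood, so likelihood-ratio tests on fixed
effects are valid) with random intercepts for replicate and year:

* H1 (compositions 1-4): total DMW ~ ryegrass cultivar x clover presence;
* H2 (compositions 3-5): DMW ~ ryegrass component (Merks / Meloni / mixture);
* H3 (compositions 5-7): DMW ~ clover component (Lemmon / Crossway / mixture);

H2 and H3 are additionally run on the grass and clover DMW separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .containers import ValidationError
from .design import COMPOSITION_CONTENT


def dry_matter_weight(
    fresh_total_kg: float,
    sub_fresh: float,
    sub_dry: float,
    area_ha: float,
) -> float:
    """DMW in t/ha from a plot fresh weight and a dried subsample.

    The subsample weights may be in any common unit; only their ratio (the
    dry-matter fraction) is used.
    """
    if sub_fresh <= 0:
        raise ValidationError("subsample fresh weight must be positive")
    if sub_dry > sub_fresh:
        raise ValidationError("subsample dry weight exceeds its fresh weight")
    if fresh_total_kg < 0 or sub_dry < 0:
        raise ValidationError("weights must be non-negative")
    dry_fraction = sub_dry / sub_fresh
    return (fresh_total_kg / 1000.0) * dry_fraction / area_ha


def botanical_fractions(subsamples: np.ndarray) -> np.ndarray:
    """Plot-level (grass, clover, weed) fractions from dried subsamples.

    ``subsamples`` is n x 3 per-fraction dry weights; each subsample is
    normalised to fractions and the plot value is their unweighted mean.
    Zero-total subsamples are excluded with a warning.
    """
    sub = np.atleast_2d(np.asarray(subsamples, float))
    if sub.shape[1] != 3:
        raise ValidationError("expected 3 fraction columns (grass/clover/weed)")
    totals = sub.sum(axis=1)
    ok = totals > 0
    if not ok.any():
        raise ValidationError("all subsamples have zero total dry weight")
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} zero-total subsample(s)",
            stacklevel=2,
        )
    fracs = sub[ok] / totals[ok, None]
    return fracs.mean(axis=0)


# ---------------------------------------------------------------------------
# mixed models

_HYPOTHESES = {
    # id: (compositions, response, full fixed formula, reduced fixed formula,
    #      tested term)
    "H1a": ((1, 2, 3, 4), "dmw_total",
            "C(rye) + C(clover_presence) + C(rye):C(clover_presence)",
            "C(rye) + C(clover_presence)", "rye x clover interaction"),
    "H1b": ((1, 2, 3, 4), "dmw_total",
            "C(rye) + C(clover_presence)", "C(clover_presence)",
            "ryegrass cultivar"),
    "H1c": ((1, 2, 3, 4), "dmw_total",
            "C(rye) + C(clover_presence)", "C(rye)", "clover presence"),
    "H2a": ((3, 4, 5), "dmw_total", "C(rye)", "1", "ryegrass component"),
    "H2b": ((3, 4, 5), "dmw_grass", "C(rye)", "1", "ryegrass component"),
    "H2c": ((3, 4, 5), "dmw_clover", "C(rye)", "1", "ryegrass component"),
    "H3a": ((5, 6, 7), "dmw_total", "C(clover)", "1", "clover component"),
    "H3b": ((5, 6, 7), "dmw_grass", "C(clover)", "1", "clover component"),
    "H3c": ((5, 6, 7), "dmw_clover", "C(clover)", "1", "clover component"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One yield hypothesis test: model, response and tested component."""

    hypothesis: str

    def __post_init__(self) -> None:
        if self.hypothesis not in _HYPOTHESES:
            raise ValidationError(
                f"unknown hypothesis {self.hypothesis!r}; "
                f"expected one of {sorted(_HYPOTHESES)}"
            )

    @property
    def compositions(self) -> tuple[int, ...]:
        return _HYPOTHESES[self.hypothesis][0]

    @property
    def response(self) -> str:
        return _HYPOTHESES[self.hypothesis][1]

    @property
    def full_formula(self) -> str:
        return _HYPOTHESES[self.hypothesis][2]

    @property
    def reduced_formula(self) -> str:
        return _HYPOTHESES[self.hypothesis][3]

    @property
    def tested_term(self) -> str:
        return _HYPOTHESES[self.hypothesis][4]


def prepare_yield_table(yields: pd.DataFrame) -> pd.DataFrame:
    """Attach cultivar-content factor columns to an annual yield table.

    Expects columns seed_composition, replicate, year and one or more of
    dmw_total / dmw_grass / dmw_clover.
    """
    required = {"seed_composition", "replicate", "year"}
    missing = required - set(yields.columns)
    if missing:
        raise ValidationError(f"yield table missing columns {sorted(missing)}")
    out = yields.copy()
    content = out["seed_composition"].map(
        lambda c: COMPOSITION_CONTENT[int(c)]
    )
    out["rye"] = content.map(lambda t: t[0])
    out["clover"] = content.map(lambda t: t[1])
    out["clover_presence"] = np.where(out["clover"] == "none", "no", "yes")
    return out


@dataclass
class FittedYieldModel:
    formula: str
    log_likelihood: float
    n_fixed_params: int
    n_obs: int
    params: pd.Series
    converged: bool


def fit_yield_model(
    yields: pd.DataFrame,
    fixed_formula: str,
    response: str,
    compositions: tuple[int, ...] | None = None,
) -> FittedYieldModel:
    """ML mixed-model fit with crossed random intercepts for replicate and year.

    A singular random-effect fit (variance component at the boundary) is
    accepted with a warning; the likelihood is still valid for LRTs.
    """
    data = prepare_yield_table(yields)
    if compositions is not None:
        data = data[data["seed_composition"].isin(compositions)]
    if data.empty:
        raise ValidationError("no yield rows in the requested compositions")
    data = data.reset_index(drop=True)
    formula = f"{response} ~ {fixed_formula}"
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula,
            data,
            groups=np.ones(len(data)),
            re_formula="0",
            vc_formula={"rep": "0 + C(replicate)", "yr": "0 + C(year)"},
        )
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                fit = model.fit(reml=False, method=method, maxiter=500)
            except Exception:
                continue
            if best is None or fit.llf > best.llf + 1e-9:
                best = fit
            if best is not None and getattr(best, "converged", False):
                break
    if best is None:
        raise ValidationError(f"mixed model failed to fit: {formula}")
    return FittedYieldModel(
        formula=formula,
        log_likelihood=float(best.llf),
        n_fixed_params=int(best.model.exog.shape[1]),
        n_obs=len(data),
        params=best.params,
        converged=bool(getattr(best, "converged", True)),
    )


def likelihood_ratio_test(
    full: FittedYieldModel, reduced: FittedYieldModel
) -> tuple[float, int, float]:
    """(chi-square, df, p) comparing nested ML fits on identical rows."""
    if reduced.n_obs != full.n_obs:
        raise ValidationError("models fit on different numbers of rows")
    df = full.n_fixed_params - reduced.n_fixed_params
    if df < 1:
        raise ValidationError("reduced model is not nested in the full model")
    chi2 = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    chi2 = max(chi2, 0.0)  # guard optimizer noise at the boundary
    return chi2, df, float(stats.chi2.sf(chi2, df))


def test_hypothesis(
    yields: pd.DataFrame, hypothesis: str
) -> dict[str, float | int | str]:
    """Run one Table-style hypothesis test; returns chi2, df, p and metadata."""
    spec = ModelSpec(hypothesis)
    full = fit_yield_model(
        yields, spec.full_formula, spec.response, spec.compositions
    )
    reduced = fit_yield_model(
        yields, spec.reduced_formula, spec.response, spec.compositions
    )
    chi2, df, p = likelihood_ratio_test(full, reduced)
    return {
        "hypothesis": hypothesis,
        "tested_term": spec.tested_term,
        "response": spec.response,
        "chi2": chi2,
        "df": df,
        "p": p,
    }


def read_yield_table(path) -> pd.DataFrame:
    """Read an annual yield TSV, auto-detecting plausible column names.

    Accepts the package's own layout directly; common alternatives
    (composition / comp / year / rep / total etc.) are renamed.  Fails loudly
    when the required columns cannot be identified.
    """
    df = pd.read_csv(path, sep="\t")
    aliases = {
        "composition": "seed_composition",
        "comp": "seed_composition",
        "seed_comp": "seed_composition",
        "rep": "replicate",
        "block": "replicate",
        "total": "dmw_total",
        "dmw": "dmw_total",
        "grass": "dmw_grass",
        "clover": "dmw_clover",
    }
    df = df.rename(
        columns={c: aliases.get(c.strip().lower(), c.strip().lower())
                 for c in df.columns}
    )
    required = {"seed_composition", "replicate", "year", "dmw_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"could not identify yield columns {sorted(missing)} in {path}; "
            f"found {sorted(df.columns)}"
        )
    return df
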