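"""Synthetic trial generator with ground truth.

The generator emulates the statistical structure the analysis assumes:

* two founder cultivars drawn from a small number of founder individuals
  (Merks-like: 3 parental components; Meloni-like: 2), so per-cultivar allele
  frequencies sit on the grid k / (2 * founders), with designated
  cultivar-private loci (frequency exactly 0 in the other cultivar);
* per-plot cultivar-proportion trajectories w(plot, year): monoculture
  compositions are constant at 0 or 1; mixed compositions follow a logistic
  trajectory with a composition-level trend, shared per-year offsets, and
  independent plot-level noise;
* optional selected loci: a deterministic per-year additive allele-frequency
  shift shared by replicate plots of the same composition — exactly the
  alternative the scan's composition-by-year term is built to detect;
* plant sampling: 40 diploid genotypes per plot-year drawn under
  Hardy-Weinberg at the plot's population allele frequency, pooled with equal
  tissue weight so the pool frequency is the mean genotype dose / 2;
* read sampling: per-cell depth ~ negative binomial, alternative reads ~
  Binomial(depth, f (1 - eps) + (1 - f) eps).

All randomness flows from a single seed through spawned substreams
(0: cultivar construction, 1: trajectories, 2: plant/read sampling), so a
config is reproducible bit-for-bit and cultivar profiles are stable across
calls that do or do not simulate reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    AlleleCountMatrix,
    ConfigError,
    GenotypeMatrix,
    Locus,
)
from .design import (
    COMPOSITION_CONTENT,
    MERKS_SEED_FRACTION,
    SampleDesign,
    full_design,
)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CultivarProfile:
    """Per-locus allele frequencies of one founder cultivar."""

    name: str
    af: np.ndarray
    private_loci: np.ndarray  # indices where the OTHER cultivar has af == 0

    def __post_init__(self) -> None:
        af = np.asarray(self.af, float)
        if ((af < 0) | (af > 1)).any():
            raise ConfigError("cultivar allele frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class SelectedLocus:
    """A locus under selection: additive AF shift per year of cultivation.

    The shift is shared by replicate plots; ``compositions`` restricts it to a
    subset of seed compositions (None = all).
    """

    locus: int
    shift_per_year: float
    compositions: tuple[int, ...] | None = None


@dataclass(frozen=True)
class TrajectoryModel:
    """Logistic model for the Merks proportion w in mixed-cultivar plots.

    logit w(plot, year) = logit_base + logit_trend * (year - 1)
                          + year_logit_offsets[year - 1] + plot noise,
    with independent plot-year noise of sd ``plot_noise_sd``.  Non-monotone
    shared dynamics (e.g. Merks prominent in years 1 and 4 only) are expressed
    through the per-year offsets.
    """

    logit_base: float = 0.0
    logit_trend: float = 0.0
    year_logit_offsets: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    plot_noise_sd: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    n_loci: int = 5_000
    founders_merks: int = 3
    founders_meloni: int = 2
    #: fraction of loci private to (Merks, Meloni); defaults chosen to match
    #: the 1.1% / 2.8% private shares observed in the field SNP panel
    private_locus_fraction: tuple[float, float] = (0.011, 0.028)
    trajectory: TrajectoryModel = field(default_factory=TrajectoryModel)
    selected_loci: tuple[SelectedLocus, ...] = ()
    n_plants_sampled: int = 40
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0
    error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if self.founders_merks < 2 or self.founders_meloni < 2:
            raise ConfigError("founder counts must be >= 2")
        if sum(self.private_locus_fraction) > 1:
            raise ConfigError("private locus fractions must sum to <= 1")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigError("error_rate must be in [0, 0.5)")
        if self.n_plants_sampled < 1:
            raise ConfigError("n_plants_sampled must be >= 1")


@dataclass
class TruthRecord:
    """Latent quantities of one simulated trial, for recovery tests."""

    merks: CultivarProfile
    meloni: CultivarProfile
    w: pd.Series                 # Merks proportion per sample_id
    population_af: np.ndarray    # loci x samples, post-selection, clipped
    sample_aaf: np.ndarray       # realized 40-plant pool AAF, loci x samples
    selected_loci: tuple[SelectedLocus, ...]


@dataclass
class SimulatedTrial:
    counts: AlleleCountMatrix
    truth: TruthRecord
    genotypes: dict[str, GenotypeMatrix] | None = None


def _substreams(seed: int, n: int = 3) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_founder_af(
    rng: np.random.Generator, base: np.ndarray, founders: int
) -> np.ndarray:
    """Cultivar AF = allele count among 2*founders haplotypes / (2*founders)."""
    n_hap = 2 * founders
    return rng.binomial(n_hap, base) / n_hap


def simulate_cultivars(
    config: SimulationConfig,
) -> tuple[CultivarProfile, CultivarProfile]:
    """Construct the Merks-like / Meloni-like allele-frequency profiles."""
    rng = _substreams(config.seed)[0]
    L = config.n_loci
    n_hap_m = 2 * config.founders_merks
    n_hap_o = 2 * config.founders_meloni
    # symmetric unimodal base spectrum with mass away from the extremes,
    # emulating a SNP panel ascertained at intermediate frequencies; also
    # keeps expected He ordered by founder count under the >=1-allele clamp
    base = rng.beta(3.0, 3.0, size=L)
    # shared loci carry at least one alternative allele in BOTH cultivars, so
    # the designated private sets are exactly the loci with af == 0 in the
    # other cultivar (the ground truth the recovery tests compare against)
    af_merks = np.maximum(1, rng.binomial(n_hap_m, base)) / n_hap_m
    af_meloni = np.maximum(1, rng.binomial(n_hap_o, base)) / n_hap_o

    f_m, f_o = config.private_locus_fraction
    assignment = rng.choice(3, size=L, p=[f_m, f_o, 1 - f_m - f_o])
    merks_private = np.flatnonzero(assignment == 0)
    meloni_private = np.flatnonzero(assignment == 1)
    af_meloni[merks_private] = 0.0
    af_merks[meloni_private] = 0.0
    return (
        CultivarProfile("Merks", af_merks, merks_private),
        CultivarProfile("Meloni", af_meloni, meloni_private),
    )


def _merks_proportion(
    config: SimulationConfig,
    design: list[SampleDesign],
    rng: np.random.Generator,
) -> pd.Series:
    """Latent Merks proportion w for every design sample."""
    traj = config.trajectory
    w = {}
    for s in design:
        seed_frac = MERKS_SEED_FRACTION[s.seed_composition]
        if seed_frac in (0.0, 1.0):
            w[s.sample_id] = seed_frac
            continue
        t = s.year - 1
        logit = (
            traj.logit_base
            + traj.logit_trend * t
            + traj.year_logit_offsets[t]
            + rng.normal(0.0, traj.plot_noise_sd)
        )
        w[s.sample_id] = float(_logistic(np.array(logit)))
    return pd.Series(w, name="w_merks")


def population_af(
    config: SimulationConfig,
    merks: CultivarProfile,
    meloni: CultivarProfile,
    w: float,
    composition: int,
    year: int,
) -> np.ndarray:
    """Population AF of one plot-year: mixture of cultivars plus selection."""
    p = w * merks.af + (1.0 - w) * meloni.af
    for sel in config.selected_loci:
        if sel.compositions is None or composition in sel.compositions:
            p[sel.locus] += sel.shift_per_year * (year - 1)
    return np.clip(p, 0.0, 1.0)


def default_loci(n: int) -> list[Locus]:
    width = len(str(n))
    return [Locus("chr1", 10 * i + 1, "A", "C") for i in range(n)]


def simulate_trial(
    config: SimulationConfig,
    design: list[SampleDesign] | None = None,
    return_genotypes: bool = False,
) -> SimulatedTrial:
    """Simulate pooled read counts (one column per design sample) plus truth."""
    if design is None:
        design = full_design()
    if not design:
        raise ConfigError("design must contain at least one sample")
    _, traj_rng, read_rng = _substreams(config.seed)
    merks, meloni = simulate_cultivars(config)
    w = _merks_proportion(config, design, traj_rng)

    L, n_plants = config.n_loci, config.n_plants_sampled
    n_chrom = 2 * n_plants
    pop_af = np.empty((L, len(design)))
    samp_aaf = np.empty((L, len(design)))
    ref = np.empty((L, len(design)), dtype=np.int64)
    alt = np.empty((L, len(design)), dtype=np.int64)
    genotypes: dict[str, GenotypeMatrix] | None = {} if return_genotypes else None
    loci = default_loci(L)

    disp = config.depth_dispersion
    nb_p = disp / (disp + config.depth_mean)
    eps = config.error_rate

    for j, s in enumerate(design):
        p = population_af(
            config, merks, meloni, w[s.sample_id], s.seed_composition, s.year
        )
        pop_af[:, j] = p
        dose = read_rng.binomial(2, p[:, None], size=(L, n_plants))
        f = dose.sum(axis=1) / n_chrom
        samp_aaf[:, j] = f
        depth = read_rng.negative_binomial(disp, nb_p, size=L)
        q = f * (1 - eps) + (1 - f) * eps
        a = read_rng.binomial(depth, q)
        alt[:, j] = a
        ref[:, j] = depth - a
        if genotypes is not None:
            genotypes[s.sample_id] = GenotypeMatrix(
                loci=loci,
                individuals=[f"{s.sample_id}_pl{k}" for k in range(n_plants)],
                calls=dose.astype(np.int8),
            )

    counts = AlleleCountMatrix(
        loci=loci,
        samples=[s.sample_id for s in design],
        ref_count=ref,
        alt_count=alt,
    )
    truth = TruthRecord(
        merks=merks,
        meloni=meloni,
        w=w,
        population_af=pop_af,
        sample_aaf=samp_aaf,
        selected_loci=config.selected_loci,
    )
    return SimulatedTrial(counts=counts, truth=truth, genotypes=genotypes)


# ---------------------------------------------------------------------------
# yield simulation


@dataclass(frozen=True)
class YieldEffects:
    """Additive effects (t/ha) and variance components for simulated yields.

    Defaults emulate the trial's qualitative pattern: clover presence raises
    total yield by about 2 t/ha, Meloni outyields Merks, the erect clover
    cultivar gives a higher clover share than the creeping one.
    """

    mu: float = 12.0
    meloni: float = 1.0               # Meloni vs Merks ryegrass component
    mixture_rye: float = 0.5          # both-cultivar rye vs Merks
    clover_presence: float = 2.0
    rye_clover_interaction: float = 0.0
    lemmon: float = 1.0               # Lemmon-only vs mixed clover component
    crossway: float = -1.0            # Crossway-only vs mixed clover component
    sd_replicate: float = 0.3
    sd_year: float = 1.0
    sd_residual: float = 0.5
    grass_fraction_logit: float = 0.7
    grass_fraction_lemmon: float = -0.4   # Lemmon pushes clover share up
    grass_fraction_crossway: float = 0.4
    grass_fraction_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in ("sd_replicate", "sd_year", "sd_residual",
                     "grass_fraction_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


def _rye_effect(effects: YieldEffects, content: str) -> float:
    return {"Merks": 0.0, "Meloni": effects.meloni,
            "both": effects.mixture_rye}[content]


def _clover_effect(effects: YieldEffects, content: str) -> float:
    if content == "none":
        return 0.0
    extra = {"both": 0.0, "Lemmon": effects.lemmon,
             "Crossway": effects.crossway}[content]
    return effects.clover_presence + extra


def simulate_yield(
    design: list[SampleDesign] | None = None,
    effects: YieldEffects = YieldEffects(),
    seed: int = 0,
) -> pd.DataFrame:
    """Annual yield table: total/grass/clover DMW per plot-year (t/ha).

    Total DMW is additive in the cultivar-content effects with random
    replicate and year intercepts; the grass/clover split follows a logistic
    fraction model in mixed plots (grass fraction 1 in ryegrass monocultures;
    weed fraction 0 throughout).
    """
    if design is None:
        design = full_design()
    rng = np.random.default_rng(seed)
    reps = sorted({s.replicate for s in design})
    years = sorted({s.year for s in design})
    rep_eff = dict(zip(reps, rng.normal(0, effects.sd_replicate, len(reps))))
    year_eff = dict(zip(years, rng.normal(0, effects.sd_year, len(years))))

    rows = []
    for s in design:
        rye, clover = COMPOSITION_CONTENT[s.seed_composition]
        total = (
            effects.mu
            + _rye_effect(effects, rye)
            + _clover_effect(effects, clover)
            + (effects.rye_clover_interaction
               if (rye == "Meloni" and clover != "none") else 0.0)
            + rep_eff[s.replicate]
            + year_eff[s.year]
            + rng.normal(0, effects.sd_residual)
        )
        if clover == "none":
            frac_grass = 1.0
        else:
            logit = (
                effects.grass_fraction_logit
                + {"both": 0.0,
                   "Lemmon": effects.grass_fraction_lemmon,
                   "Crossway": effects.grass_fraction_crossway}[clover]
                + rng.normal(0, effects.grass_fraction_sd)
            )
            frac_grass = float(_logistic(np.array(logit)))
        rows.append(
            {
                "plot": s.plot_id,
                "seed_composition": s.seed_composition,
                "replicate": s.replicate,
                "year": s.year,
                "ryegrass_content": rye,
                "clover_content": clover,
                "dmw_total": total,
                "dmw_grass": total * frac_grass,
                "dmw_clover": total * (1.0 - frac_grass),
                "frac_grass": frac_grass,
                "frac_clover": 1.0 - frac_grass,
                "frac_weed": 0.0,
            }
        )
    return pd.DataFrame(rows)


def with_selection(
    config: SimulationConfig,
    n_selected: int,
    shift_per_year: float,
    rng_seed: int | None = None,
) -> SimulationConfig:
    """Config copy with ``n_selected`` randomly placed selected loci."""
    rng = np.random.default_rng(
        config.seed + 7_919 if rng_seed is None else rng_seed
    )
    loci = rng.choice(config.n_loci, size=n_selected, replace=False)
    sel = tuple(SelectedLocus(int(l), shift_per_year) for l in sorted(loci))
    return replace(config, selected_loci=sel)
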