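"""Trial design: seed compositions, plots, replicates, years.

The field trial sows seven seed compositions in two replicate plots (A/B,
14 plots), and samples the ryegrass component of every plot once per year for
four years: 56 population samples of 40 leaves each.  Each population sample
is pooled into two replicate tissue pools (112 pools) whose read data are
merged before allele-frequency estimation, so the count matrix carries one
column per population sample.

Composition -> cultivar-content mapping (percentages of sown seed):

====  =====  ======  ======  ========
comp  Merks  Meloni  Lemmon  Crossway
====  =====  ======  ======  ========
1     100    -       -       -
2     -      100     -       -
3     70     -       15      15
4     -      70      15      15
5     35     35      15      15
6     35     35      30      -
7     35     35      -       30
====  =====  ======  ======  ========
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .containers import FormatError, ValidationError

COMPOSITIONS = range(1, 8)
REPLICATES = ("A", "B")
YEARS = range(1, 5)

N_PLANTS_PER_SAMPLE = 40
N_TISSUE_POOLS_PER_SAMPLE = 2

#: composition -> (ryegrass content, clover content)
COMPOSITION_CONTENT: dict[int, tuple[str, str]] = {
    1: ("Merks", "none"),
    2: ("Meloni", "none"),
    3: ("Merks", "both"),
    4: ("Meloni", "both"),
    5: ("both", "both"),
    6: ("both", "Lemmon"),
    7: ("both", "Crossway"),
}

#: composition -> seed mass fraction of Merks within the ryegrass component
MERKS_SEED_FRACTION: dict[int, float] = {
    1: 1.0, 2: 0.0, 3: 1.0, 4: 0.0, 5: 0.5, 6: 0.5, 7: 0.5,
}


@dataclass(frozen=True)
class SampleDesign:
    """One population sample: a plot in a given year."""

    sample_id: str
    plot_id: int
    seed_composition: int
    replicate: str
    year: int
    ryegrass_content: str
    clover_content: str


def plot_id(composition: int, replicate: str) -> int:
    """Plot numbering 1-14: compositions in order, replicate A before B."""
    return 2 * (composition - 1) + (1 if replicate == "A" else 2)


def make_sample(composition: int, replicate: str, year: int) -> SampleDesign:
    if composition not in COMPOSITIONS:
        raise ValidationError(
            f"seed composition must be in 1-7, got {composition}"
        )
    if replicate not in REPLICATES:
        raise ValidationError(f"replicate must be A or B, got {replicate!r}")
    if year not in YEARS:
        raise ValidationError(f"year must be in 1-4, got {year}")
    rye, clover = COMPOSITION_CONTENT[composition]
    return SampleDesign(
        sample_id=f"c{composition}{replicate}_y{year}",
        plot_id=plot_id(composition, replicate),
        seed_composition=composition,
        replicate=replicate,
        year=year,
        ryegrass_content=rye,
        clover_content=clover,
    )


def full_design() -> list[SampleDesign]:
    """The complete 7 x 2 x 4 trial design: 56 population samples."""
    return [
        make_sample(c, r, y)
        for c in COMPOSITIONS
        for r in REPLICATES
        for y in YEARS
    ]


def tissue_pool_ids(design: list[SampleDesign]) -> list[str]:
    """Identifiers of the replicate tissue pools (two per population sample)."""
    return [
        f"{s.sample_id}_p{k}"
        for s in design
        for k in range(1, N_TISSUE_POOLS_PER_SAMPLE + 1)
    ]


def design_frame(design: list[SampleDesign]) -> pd.DataFrame:
    """Design as a DataFrame indexed by sample_id (for model fitting)."""
    df = pd.DataFrame([vars(s) for s in design])
    return df.set_index("sample_id", drop=False)


def read_design_table(path) -> list[SampleDesign]:
    """Read a sample design TSV (sample_id, seed_composition, replicate, year).

    Cultivar contents are derived from the composition; a sample_id column is
    optional (a canonical id is generated when absent).  Partial designs are
    accepted with a warning; duplicate (composition, replicate, year) triples
    are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"seed_composition", "replicate", "year"}
    if not required <= set(df.columns):
        raise FormatError(
            f"design table {path} missing columns "
            f"{sorted(required - set(df.columns))}"
        )
    records = []
    seen: set[tuple[int, str, int]] = set()
    for i, row in df.iterrows():
        comp = int(row["seed_composition"])
        rep = str(row["replicate"])
        year = int(row["year"])
        triple = (comp, rep, year)
        if triple in seen:
            raise ValidationError(
                f"duplicate (composition, replicate, year) triple {triple} "
                f"at row {i + 2}"
            )
        seen.add(triple)
        s = make_sample(comp, rep, year)
        if "sample_id" in df.columns and isinstance(row["sample_id"], str):
            s = SampleDesign(**{**vars(s), "sample_id": row["sample_id"]})
        records.append(s)
    if len(records) < len(COMPOSITIONS) * len(REPLICATES) * len(YEARS):
        warnings.warn(
            f"partial design: {len(records)} of 56 samples present",
            stacklevel=2,
        )
    return records


def write_design_table(design: list[SampleDesign], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "seed_composition": [s.seed_composition for s in design],
            "replicate": [s.replicate for s in design],
            "year": [s.year for s in design],
        }
    )
    df.to_csv(path, sep="\t", index=False)
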