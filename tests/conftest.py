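import numpy as np
import pytest

import swardpop as sp


@pytest.fixture(scope="session")
def design():
    return sp.full_design()


@pytest.fixture(scope="session")
def small_trial():
    """A modest null trial shared by fast tests (2000 loci, depth 100)."""
    cfg = sp.SimulationConfig(n_loci=2000, seed=42)
    return cfg, sp.simulate_trial(cfg)


@pytest.fixture(scope="session")
def small_pipeline(design, small_trial):
    """Estimated + filtered AAF matrix for the small trial."""
    _, trial = small_trial
    aaf, thetas = sp.estimate_aaf_matrix(trial.counts)
    filt, report = sp.filter_cascade(
        trial.counts, aaf, sp.FilterConfig.pool_preset()
    )
    return {"trial": trial, "aaf": filt, "report": report, "thetas": thetas}


@pytest.fixture
def toy_counts():
    """3 loci x 2 samples with hand-set counts."""
    loci = [
        sp.Locus("chr1", 100, "A", "G"),
        sp.Locus("chr1", 200, "C", "T"),
        sp.Locus("chr2", 50, "G", "A"),
    ]
    return sp.AlleleCountMatrix(
        loci=loci,
        samples=["s1", "s2"],
        ref_count=np.array([[30, 40], [50, 10], [0, 25]]),
        alt_count=np.array([[30, 0], [10, 35], [60, 25]]),
    )


def write_minimal_vcf(path, records, samples=("ind1",), fmt="GT:DP:GQ:AD"):
    """Write a small VCF: records are (chrom, pos, ref, alt, [per-sample str])."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "##contig=<ID=chr1>",
        "##contig=<ID=chr2>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for chrom, pos, ref, alt, cells in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t"
            + "\t".join(cells)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
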