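"""Readers and writers for count, AAF and genotype artifacts.

Tabular artifacts are tab-separated UTF-8 with one header line and ``.`` for
missing values.  Count tables carry three columns per sample
(``<sample>.ref``, ``<sample>.alt``, ``<sample>.other``); AAF tables carry one
column per sample.  VCF input goes through cyvcf2 (allelic depths from the
``AD`` format field; genotype calls from ``GT``/``DP``/``GQ``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    MISSING_CALL,
    AAFMatrix,
    AlleleCountMatrix,
    FormatError,
    GenotypeMatrix,
    Locus,
    ValidationError,
)

_LOCUS_COLS = ["chrom", "pos", "ref", "alt"]


def _loci_from_frame(df: pd.DataFrame, path) -> list[Locus]:
    try:
        return [
            Locus(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in df.itertuples()
        ]
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed locus row ({exc})") from exc


def read_count_table(path, dialect: str = "tsv") -> AlleleCountMatrix:
    """Read an allele-count matrix from TSV or from a VCF with AD fields.

    Loci are returned sorted by (chrom, pos) regardless of input order.
    """
    if dialect == "tsv":
        return _read_count_tsv(path)
    if dialect == "vcf-ad":
        return _read_count_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_count_tsv(path) -> AlleleCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:4]) != _LOCUS_COLS:
        raise FormatError(
            f"{path}: header must start with {_LOCUS_COLS}, "
            f"got {list(df.columns[:4])}"
        )
    count_cols = list(df.columns[4:])
    samples: list[str] = []
    for col in count_cols:
        if col.endswith(".ref"):
            samples.append(col[:-4])
    for s in samples:
        for suffix in (".ref", ".alt"):
            if f"{s}{suffix}" not in count_cols:
                raise FormatError(f"{path}: sample {s} missing column {s}{suffix}")
    if not samples:
        raise FormatError(f"{path}: no per-sample count columns found")

    loci = _loci_from_frame(df[_LOCUS_COLS].astype({"pos": int}), path)

    def counts(suffix: str, required: bool) -> np.ndarray:
        cols = []
        for s in samples:
            name = f"{s}{suffix}"
            if name not in df.columns:
                if required:
                    raise FormatError(f"{path}: missing column {name}")
                cols.append(np.zeros(len(df), dtype=np.int64))
                continue
            raw = pd.to_numeric(df[name], errors="coerce")
            if raw.isna().any():
                row = int(raw.index[raw.isna()][0]) + 2  # header is line 1
                raise ValidationError(
                    f"{path}: non-numeric count in column {name}, line {row}"
                )
            if (raw < 0).any():
                row = int(raw.index[raw < 0][0]) + 2
                raise ValidationError(
                    f"{path}: negative count in column {name}, line {row}"
                )
            cols.append(raw.to_numpy(dtype=np.int64))
        return np.column_stack(cols)

    mat = AlleleCountMatrix(
        loci=loci,
        samples=samples,
        ref_count=counts(".ref", required=True),
        alt_count=counts(".alt", required=True),
        extra_allele_count=counts(".other", required=False),
    )
    return mat.sorted_by_locus()


def _read_count_vcf(path) -> AlleleCountMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci, refs, alts, extras = [], [], [], []
    for variant in vcf:
        if len(variant.ALT) < 1:
            continue
        ad = variant.format("AD")
        if ad is None:
            raise FormatError(f"{path}: record without AD field at "
                              f"{variant.CHROM}:{variant.POS}")
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # cyvcf2 encodes missing AD as negative fill
        loci.append(
            Locus(variant.CHROM, variant.POS, variant.REF, variant.ALT[0])
        )
        refs.append(ad[:, 0])
        alts.append(ad[:, 1] if ad.shape[1] > 1 else np.zeros(len(samples), int))
        extras.append(
            ad[:, 2:].sum(axis=1) if ad.shape[1] > 2
            else np.zeros(len(samples), int)
        )
    mat = AlleleCountMatrix(
        loci=loci,
        samples=samples,
        ref_count=np.array(refs, dtype=np.int64),
        alt_count=np.array(alts, dtype=np.int64),
        extra_allele_count=np.array(extras, dtype=np.int64),
    )
    return mat.sorted_by_locus()


def write_count_table(mat: AlleleCountMatrix, path) -> None:
    data = {
        "chrom": [l.chrom for l in mat.loci],
        "pos": [l.pos for l in mat.loci],
        "ref": [l.ref_allele for l in mat.loci],
        "alt": [l.alt_allele for l in mat.loci],
    }
    for j, s in enumerate(mat.samples):
        data[f"{s}.ref"] = mat.ref_count[:, j]
        data[f"{s}.alt"] = mat.alt_count[:, j]
        data[f"{s}.other"] = mat.extra_allele_count[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_aaf_table(path) -> AAFMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:4]) != _LOCUS_COLS:
        raise FormatError(f"{path}: header must start with {_LOCUS_COLS}")
    samples = list(df.columns[4:])
    loci = _loci_from_frame(df[_LOCUS_COLS].astype({"pos": int}), path)
    vals = (
        df[samples].replace(".", np.nan).apply(pd.to_numeric).to_numpy(float)
    )
    mat = AAFMatrix(loci=loci, samples=samples, aaf=vals)
    order = np.array(
        sorted(range(len(loci)), key=lambda i: loci[i].key), dtype=np.intp
    )
    return mat.select_loci(order)


def write_aaf_table(mat: AAFMatrix, path) -> None:
    data = {
        "chrom": [l.chrom for l in mat.loci],
        "pos": [l.pos for l in mat.loci],
        "ref": [l.ref_allele for l in mat.loci],
        "alt": [l.alt_allele for l in mat.loci],
    }
    for j, s in enumerate(mat.samples):
        col = np.where(
            mat.missing[:, j],
            ".",
            np.char.mod("%.10g", np.nan_to_num(mat.aaf[:, j])),
        )
        data[s] = col
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_genotype_vcf(path, min_depth: int = 10, min_gq: int = 30
                      ) -> tuple[GenotypeMatrix, dict]:
    """Read individual genotype calls from a VCF.

    Only biallelic SNP records are kept; indels and multi-allelic records are
    dropped and counted in the returned report.  Calls with read depth below
    ``min_depth`` or genotype quality below ``min_gq`` are set to missing.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    loci, rows, depths, gqs = [], [], [], []
    n_dropped_indel = n_dropped_multi = 0
    saw_gt = False
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_dropped_multi += 1
            continue
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_dropped_indel += 1
            continue
        gt_types = variant.gt_types  # 0 homref, 1 het, 2 unknown, 3 homalt
        saw_gt = True
        dose = np.select(
            [gt_types == 0, gt_types == 1, gt_types == 3],
            [0, 1, 2],
            default=MISSING_CALL,
        ).astype(np.int8)
        dp = variant.gt_depths.astype(np.int64)
        gq = variant.gt_quals
        gq = np.where(np.isnan(gq), -1, gq).astype(np.int64)
        dose = np.where((dp < min_depth) | (gq < min_gq), MISSING_CALL, dose)
        loci.append(Locus(variant.CHROM, variant.POS, variant.REF,
                          variant.ALT[0]))
        rows.append(dose.astype(np.int8))
        depths.append(dp)
        gqs.append(gq)
    if loci and not saw_gt:
        raise FormatError(f"{path}: VCF has no GT field")
    gm = GenotypeMatrix(
        loci=loci,
        individuals=individuals,
        calls=np.array(rows, dtype=np.int8).reshape(len(loci),
                                                    len(individuals)),
        depth=np.array(depths, dtype=np.int64).reshape(len(loci),
                                                       len(individuals)),
        gq=np.array(gqs, dtype=np.int64).reshape(len(loci), len(individuals)),
    )
    report = {
        "n_dropped_multiallelic": n_dropped_multi,
        "n_dropped_indel": n_dropped_indel,
        "n_kept": len(loci),
    }
    return gm, report
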