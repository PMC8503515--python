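"""Readers and writers: VCF genotypes, panel/assignment/results tables.

All tabular formats are tab-separated text with a header.  VCF reading is
single-pass and allele-aware: a panel SNP is matched by CHROM+POS and its
unordered allele pair; when the panel's minor allele is the VCF REF, the
count is 2 - ALT dosage.  Strand flips are never guessed — palindromic
(A/T, C/G) sites are matched literally and listed in a warning.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import PANEL_COLUMNS, GenotypeMatrix, PopulationAssignment, SnpPanel
from .spectrum import SpectrumResult

logger = logging.getLogger("ancspec")

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
# cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_ALT_DOSAGE = np.array([0.0, 1.0, np.nan, 2.0])


class FormatError(ValueError):
    """A malformed panel/assignment/results file."""


@dataclass
class VcfReadReport:
    """Bookkeeping from one VCF pass."""

    n_records: int = 0
    n_skipped_not_biallelic_snp: int = 0
    n_allele_mismatch: int = 0
    missing_panel_snps: list[str] = dataclass_field(default_factory=list)
    palindromic_snps: list[str] = dataclass_field(default_factory=list)


def read_vcf(
    path: str | Path,
    panel: SnpPanel | None = None,
    samples: list[str] | None = None,
) -> GenotypeMatrix:
    """Read hard-call genotypes from a VCF.

    With a panel, columns follow the panel's SNP order and hold counts of
    the panel's minor allele; panel SNPs absent from the VCF become
    all-missing columns; matched positions with a different allele pair are
    skipped and counted.  Without a panel, every biallelic SNP record is
    kept with the ALT allele counted.  Non-SNP and multi-allelic records
    are skipped with a counted warning either way.  The returned matrix
    carries a ``report`` attribute (:class:`VcfReadReport`).
    """
    vcf = VCF(str(path), samples=samples, gts012=False)
    sample_ids = list(vcf.samples)
    report = VcfReadReport()

    if panel is not None:
        lookup: dict[tuple[str, int], list[int]] = {}
        for col, rec in enumerate(panel.df.itertuples(index=False)):
            lookup.setdefault((str(rec.CHROM), int(rec.POS)), []).append(col)
        values = np.full((len(sample_ids), panel.M), np.nan)
        seen = np.zeros(panel.M, dtype=bool)
    else:
        columns: list[np.ndarray] = []
        variants_rows: list[tuple] = []

    for variant in vcf:
        report.n_records += 1
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            report.n_skipped_not_biallelic_snp += 1
            continue
        ref, alt = variant.REF.upper(), variant.ALT[0].upper()
        dosage = _ALT_DOSAGE[np.asarray(variant.gt_types)]
        if panel is None:
            columns.append(dosage)
            variants_rows.append(
                (str(variant.CHROM), int(variant.POS), variant.ID or
                 f"{variant.CHROM}:{variant.POS}", alt, ref)
            )
            continue
        cols = lookup.get((str(variant.CHROM), int(variant.POS)))
        if not cols:
            continue
        for col in cols:
            minor = panel.df["MINOR"].iat[col]
            other = panel.df["OTHER"].iat[col]
            if {ref, alt} != {minor, other}:
                report.n_allele_mismatch += 1
                continue
            if frozenset((minor, other)) in _PALINDROMIC:
                report.palindromic_snps.append(panel.df["ID"].iat[col])
            values[:, col] = dosage if minor == alt else 2.0 - dosage
            seen[col] = True

    if panel is not None:
        report.missing_panel_snps = [
            panel.df["ID"].iat[i] for i in np.flatnonzero(~seen)
        ]
        if not seen.any():
            raise ValueError(f"no panel SNPs found in {path}")
        geno = GenotypeMatrix(
            values=values, sample_ids=sample_ids, snp_ids=panel.snp_ids, validate=False
        )
    else:
        if not columns:
            raise ValueError(f"no biallelic SNP records in {path}")
        variants = pd.DataFrame(
            variants_rows, columns=["CHROM", "POS", "ID", "A1", "A2"]
        )
        geno = GenotypeMatrix(
            values=np.column_stack(columns),
            sample_ids=sample_ids,
            snp_ids=list(variants["ID"]),
            variants=variants,
        )
    if report.n_skipped_not_biallelic_snp:
        logger.warning(
            "%d non-biallelic/non-SNP records skipped", report.n_skipped_not_biallelic_snp
        )
    if report.n_allele_mismatch:
        logger.warning("%d records skipped for allele mismatch", report.n_allele_mismatch)
    if report.missing_panel_snps:
        logger.warning(
            "%d panel SNPs absent from VCF", len(report.missing_panel_snps)
        )
    if report.palindromic_snps:
        warnings.warn(
            f"{len(report.palindromic_snps)} palindromic (A/T or C/G) panel sites "
            "matched literally; strand flips are not auto-corrected",
            stacklevel=2,
        )
    geno.report = report  # type: ignore[attr-defined]
    return geno


def write_panel(panel: SnpPanel, path: str | Path) -> None:
    """Write a panel as TSV with columns CHROM POS ID MINOR OTHER POP MAF."""
    df = panel.df[PANEL_COLUMNS].copy()
    df["MAF"] = [repr(float(v)) for v in df["MAF"]]  # full precision round-trip
    df.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> SnpPanel:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header != PANEL_COLUMNS:
        raise FormatError(
            f"{path}: line 1: expected header {PANEL_COLUMNS}, got {header}"
        )
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"CHROM": str, "ID": str, "MINOR": str, "OTHER": str, "POP": str},
    )
    try:
        df["POS"] = df["POS"].astype(int)
        df["MAF"] = df["MAF"].astype(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: malformed POS/MAF column: {exc}") from None
    return SnpPanel(df)


def read_assignment(path: str | Path) -> PopulationAssignment:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header != ["SAMPLE", "POP"]:
        raise FormatError(
            f"{path}: line 1: expected header ['SAMPLE', 'POP'], got {header}"
        )
    df = pd.read_csv(path, sep="\t", dtype=str)
    return PopulationAssignment.from_frame(df)


def write_assignment(assignment: PopulationAssignment, path: str | Path) -> None:
    assignment.to_frame().to_csv(path, sep="\t", index=False)


def write_results(result: SpectrumResult, path: str | Path) -> None:
    """One row per input sample, in input order."""
    frame = result.to_frame()
    for c in frame.columns:
        if frame[c].dtype == float:
            frame[c] = [repr(float(v)) for v in frame[c]]
    frame.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "SAMPLE" not in df.columns:
        raise FormatError(f"{path}: line 1: missing SAMPLE column")
    return df


def write_grm(grm_matrix: np.ndarray, sample_ids: list[str], path: str | Path) -> None:
    """Square GRM as TSV with sample IDs as header row and first column."""
    pd.DataFrame(grm_matrix, index=sample_ids, columns=sample_ids).to_csv(
        path, sep="\t", index_label="SAMPLE"
    )


def write_genotype_table(geno: GenotypeMatrix, path: str | Path) -> None:
    """Plain genotype matrix: samples as rows, SNP IDs as columns, NA missing."""
    pd.DataFrame(geno.values, index=geno.sample_ids, columns=geno.snp_ids).to_csv(
        path, sep="\t", index_label="SAMPLE", na_rep="NA"
    )


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="SAMPLE")
    return GenotypeMatrix(
        values=df.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        snp_ids=[str(c) for c in df.columns],
    )


_VCF_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeMatrix, panel: SnpPanel, path: str | Path) -> None:
    """Minimal VCF 4.2 export of hard-call genotypes aligned to a panel.

    The panel's OTHER allele is written as REF and the MINOR allele as ALT,
    so the stored count is the ALT dosage.  Rows are emitted in coordinate
    order per chromosome as required by the format.
    """
    geno.check_aligned(panel)
    df = panel.df.assign(COLIDX=np.arange(panel.M)).sort_values(
        ["CHROM", "POS"], kind="mergesort"
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ancspec\n")
        for chrom in dict.fromkeys(df["CHROM"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        for rec in df.itertuples(index=False):
            calls = [
                _VCF_GT.get(v, "./.") for v in geno.values[:, rec.COLIDX]
            ]
            fh.write(
                f"{rec.CHROM}\t{rec.POS}\t{rec.ID}\t{rec.OTHER}\t{rec.MINOR}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def file_checksum(path: str | Path) -> str:
    """MD5 of a file, for run-provenance log lines."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
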