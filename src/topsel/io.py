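"""Reading and writing the delimited / VCF formats the toolkit touches.

Genotypes arrive either as VCF (biallelic SNPs; dosage = count of the ALT
allele) or as a delimited individuals x markers dosage table taken at face
value.  GBLUP is invariant to allele-label flips after centering, so the
dosage convention only needs to be consistent within a file.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PhenotypeTable, SelectionResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotype_matrix",
    "read_phenotype_table",
    "write_rankings",
    "read_rankings",
]


def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_vcf_dosages(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        # with gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(rec.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        columns.append(gt)
        marker_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP VCF records", n_skipped)
    if not columns:
        raise ValueError("no biallelic SNP records in VCF")
    return samples, marker_ids, np.column_stack(columns)


def minor_allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Per-marker MAF from (possibly NaN-containing) dosage columns."""
    p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def read_genotype_matrix(path, format: str | None = None, maf_min: float = 0.0) -> GenotypeMatrix:
    """Read a genotype dosage matrix from VCF or a delimited table.

    Markers with minor allele frequency strictly below ``maf_min`` are
    removed; missing entries are imputed to the marker mean dosage and
    flagged in the returned missing mask.

    Parameters
    ----------
    path : file path
    format : "vcf", "delimited", or None to guess from the extension
    maf_min : MAF threshold in [0, 0.5]
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "delimited"
    if format == "vcf":
        ids, markers, dosages = _read_vcf_dosages(path)
    elif format == "delimited":
        try:
            df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ValueError(f"could not parse genotype table {path}: {exc}") from exc
        ids = [str(i) for i in df.index]
        markers = [str(c) for c in df.columns]
        dosages = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    keep = minor_allele_frequencies(dosages) >= maf_min if maf_min > 0 else np.ones(
        dosages.shape[1], dtype=bool
    )
    if not keep.any():
        raise ValueError(f"no markers survive MAF filter at {maf_min}")
    dosages = dosages[:, keep]
    markers = [m for m, k in zip(markers, keep) if k]

    missing = ~np.isfinite(dosages)
    if missing.any():
        logger.info("mean-imputing %d missing dosages", int(missing.sum()))
        col_means = np.nanmean(dosages, axis=0)
        dosages = np.where(missing, col_means[np.newaxis, :], dosages)

    # imputed entries are flagged missing, so the 0/1/2 invariant is only
    # enforced on originally-observed dosages
    return GenotypeMatrix(ids, markers, dosages, missing)


def read_phenotype_table(path) -> PhenotypeTable:
    """Read a delimited phenotype table (first column = individual id,
    header = trait names); blank/NA cells become missing."""
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate individual ids in phenotype table: {dupes}")
    values = df.to_numpy(dtype=float)
    return PhenotypeTable(
        [str(i) for i in df.index], [str(c) for c in df.columns], values
    )


def write_rankings(result: SelectionResult, path) -> None:
    """Write a selection result as a delimited ranking table.

    Values round-trip losslessly at 12 significant digits.
    """
    if len(result) == 0:
        raise ValueError("refusing to write an empty selection result")
    df = result.to_frame()
    df["score"] = [f"{s:.12g}" for s in df["score"]]
    df.to_csv(path, sep="\t", index=False)


def read_rankings(path) -> SelectionResult:
    df = pd.read_csv(path, sep="\t")
    return SelectionResult(
        target_label="",
        candidate_ids=[str(c) for c in df["candidate_id"]],
        scores=df["score"].to_numpy(dtype=float),
    )
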