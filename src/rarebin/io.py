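"""Reading and writing the pipeline's file formats.

Genotypes travel as VCF v4.2 (GT field, 1-based positions); sample sheets,
variant annotation sheets, assay measurements and all reports are
tab-separated text. VCF parsing uses cyvcf2; output VCFs carry only the GT
FORMAT field and are written as plain text.
"""

from __future__ import annotations

import os
from typing import Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from rarebin.containers import GenotypeMatrix

SAMPLE_COLUMNS = ["sample_id", "cohort", "status"]
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "annotation"]
ASSAY_COLUMNS = ["allele_id", "condition", "area", "batch"]


def read_vcf(path: str) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Load a VCF into a dosage matrix plus a per-variant site table."""
    vcf = VCF(path, gts012=True)  # gt_types: 0/1/2 dosage, 3 = missing
    samples = list(vcf.samples)
    dosage_rows = []
    records = []
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        dosage_rows.append(gt)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        records.append(
            {
                "variant_id": vid,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
    vcf.close()
    if not records:
        raise ValueError(f"no variant records in {path}")
    dosages = np.vstack(dosage_rows).T  # samples x variants
    variants = pd.DataFrame(records)
    gm = GenotypeMatrix(dosages, samples, variants["variant_id"].tolist())
    return gm, variants


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, variants: pd.DataFrame, path: str) -> None:
    """Write a GT-only VCF v4.2; ``variants`` supplies site columns."""
    variants = variants.set_index("variant_id", drop=False)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = pd.unique(variants["chrom"].astype(str))
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, vid in enumerate(gm.variant_ids):
            row = variants.loc[vid]
            gts = [
                "./." if np.isnan(d) else _GT_CODE[d] for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_sample_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(df["status"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown status labels: {sorted(bad)}")
    return df


def read_variant_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    if "variant_id" not in df.columns:
        raise ValueError("variant sheet must contain a variant_id column")
    return df


def read_assay_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"allele_id": str, "batch": str})
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str) -> None:
    """Bit-stable TSV output: fixed column order, 6 significant digits."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
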