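"""Readers and writers for the pipeline's file formats.

Tabular data (expression, gene models, classifications, effects) travels
as TSV; peaks as BED (0-based half-open, name in column 4 and replicate
support in column 5); variants as minimal single-sample VCF 4.2 (1-based
positions). Coordinate-convention conversion is centralized here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ["gene_id", "group", "replicate", "log_mean", "log_sd",
                      "polymorphic"]
GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss"]

VALID_GROUPS = {"F0_B6", "F0_CAST", "F1i_B", "F1i_C", "F1r_B", "F1r_C"}


def to_zero_based(pos_1based: int) -> int:
    """VCF-style 1-based position -> 0-based coordinate."""
    return pos_1based - 1


def to_one_based(pos_0based: int) -> int:
    """0-based coordinate -> VCF-style 1-based position."""
    return pos_0based + 1


# -- expression ------------------------------------------------------------

def write_expression_table(measurements: pd.DataFrame, path) -> None:
    measurements.to_csv(path, sep="\t", index=False,
                        columns=EXPRESSION_COLUMNS)


def read_expression_table(path) -> pd.DataFrame:
    """Read and validate a replicate-level expression table.

    Raises ValueError naming offending line numbers for non-positive or
    non-finite log_sd, unknown groups, or duplicate
    (gene, group, replicate) records.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    # +2: header line plus 1-based numbering.
    lines = df.index.to_numpy() + 2
    bad_sd = ~(np.isfinite(df["log_sd"]) & (df["log_sd"] > 0))
    if bad_sd.any():
        raise ValueError(
            f"{path}: non-positive log_sd at lines "
            f"{lines[bad_sd.to_numpy()].tolist()}")
    bad_group = ~df["group"].isin(VALID_GROUPS)
    if bad_group.any():
        raise ValueError(
            f"{path}: unknown group at lines "
            f"{lines[bad_group.to_numpy()].tolist()}")
    dup = df.duplicated(subset=["gene_id", "group", "replicate"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (gene, group, replicate) at lines "
            f"{lines[dup.to_numpy()].tolist()}")
    df["polymorphic"] = df["polymorphic"].astype(bool)
    return df[EXPRESSION_COLUMNS + [c for c in df.columns
                                    if c not in EXPRESSION_COLUMNS]]


# -- peaks (BED) -----------------------------------------------------------

def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """BED5-style: chrom, start, end, name, support (doublehit/singlehit)."""
    peaks.to_csv(path, sep="\t", index=False, header=False,
                 columns=["chrom", "start", "end", "name", "support"])


def read_peaks_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "support"])
    if df["name"].isna().all():
        df["name"] = [f"peak_{i}" for i in range(len(df))]
    df["support"] = df["support"].fillna("doublehit")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]].tolist()
        raise ValueError(f"{path}: start >= end at records {bad}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


# -- variants (VCF) --------------------------------------------------------

def write_variants_vcf(variants: pd.DataFrame, path,
                       sample: str = "CAST") -> None:
    """Minimal single-sample VCF 4.2 with a GT field."""
    chroms = variants["chrom"].unique() if len(variants) else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for rec in variants.itertuples():
            gt = getattr(rec, "genotype", "1/1")
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t"
                     f"PASS\t.\tGT\t{gt}\n")


def read_variants_vcf(path, homozygous_only: bool = True) -> pd.DataFrame:
    """Read variants; heterozygous or missing-genotype records are dropped
    (with a counted log line) when ``homozygous_only``. SNP/indel kind is
    inferred from REF/ALT lengths; indels anchor at their VCF POS."""
    rows, n_dropped = [], 0
    vcf = VCF(str(path), gts012=True)
    for rec in vcf:
        gt = rec.gt_types[0] if len(rec.gt_types) else 3
        homozygous_alt = gt == 2
        if homozygous_only and not homozygous_alt:
            n_dropped += 1
            continue
        alt = rec.ALT[0] if rec.ALT else rec.REF
        rows.append({
            "chrom": rec.CHROM,
            "pos": rec.POS,
            "ref": rec.REF,
            "alt": alt,
            "kind": "snp" if len(rec.REF) == 1 and len(alt) == 1 else "indel",
            "genotype_homozygous": homozygous_alt,
        })
    vcf.close()
    if n_dropped:
        logger.info("dropped %d non-homozygous variant records", n_dropped)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "kind",
                                       "genotype_homozygous"])


# -- gene models -----------------------------------------------------------

def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False, columns=GENE_COLUMNS)


def read_genes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: gene with start >= end")
    inside = (df["tss"] >= df["start"]) & (df["tss"] < df["end"])
    if not inside.all():
        raise ValueError(f"{path}: TSS outside gene span")
    return df


# -- gene lists ------------------------------------------------------------

def read_known_imprinted(path) -> dict[str, int]:
    """Two-column TSV (gene_id, database_score 0-4) -> mapping."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "database_score"} <= set(df.columns):
        raise ValueError(f"{path}: need gene_id and database_score columns")
    return dict(zip(df["gene_id"], df["database_score"].astype(int)))


def read_gene_list(path) -> list[str]:
    """One gene symbol per line (e.g. a disease-gene list)."""
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
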