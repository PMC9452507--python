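"""Readers and writers for the plain-text interchange formats.

Genotypes travel either as a variants x samples TSV with a metadata
prefix (chrom, pos, ref, alt) or as a minimal VCF with a DS FORMAT field;
expression, annotation, z panels and posterior matrices are TSV; gene
sets are GMT.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from liverqtl.datatypes import ExpressionMatrix, GenotypeMatrix

GENO_META = ["chrom", "pos", "ref", "alt"]


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = genotypes.variants[GENO_META].join(genotypes.dosages.T)
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    variants = df[GENO_META].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    dosages = df.drop(columns=GENO_META).T.astype(float)
    dosages.index.name = "sample_id"
    return GenotypeMatrix(dosages, variants)


def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with dosages in a DS FORMAT field."""
    samples = list(genotypes.sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Minor allele dosage">\n')
        for chrom in pd.unique(genotypes.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = genotypes.variants.sort_values(["chrom", "pos"]).index
        for vid in order:
            meta = genotypes.variants.loc[vid]
            vals = genotypes.dosages[vid]
            cells = ["." if not np.isfinite(v) else f"{v:g}" for v in vals]
            fh.write(
                f"{meta['chrom']}\t{int(meta['pos'])}\t{vid}\t{meta['ref']}\t"
                f"{meta['alt']}\t.\t.\t.\tDS\t" + "\t".join(cells) + "\n"
            )


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Parse the minimal dosage VCF written by :func:`write_genotypes_vcf`."""
    meta_rows, data_rows, vids, samples = [], [], [], None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], \
                parts[3], parts[4]
            fmt = parts[8].split(":")
            ds_i = fmt.index("DS")
            row = []
            for cell in parts[9:]:
                field = cell.split(":")[ds_i]
                row.append(np.nan if field == "." else float(field))
            meta_rows.append({"variant_id": vid, "chrom": str(chrom), "pos": pos,
                              "ref": ref, "alt": alt})
            vids.append(vid)
            data_rows.append(row)
    if samples is None:
        raise ValueError(f"no #CHROM header line in {path}")
    variants = pd.DataFrame(meta_rows).set_index("variant_id")
    dosages = pd.DataFrame(
        np.asarray(data_rows, dtype=float).T,
        index=pd.Index(samples, name="sample_id"), columns=variants.index,
    )
    return GenotypeMatrix(dosages, variants)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    if path.suffix == ".vcf":
        return read_genotypes_vcf(path)
    return read_genotypes_tsv(path)


def write_expression(expr: ExpressionMatrix, tpm_path, counts_path) -> None:
    expr.tpm.rename_axis("gene_id").to_csv(tpm_path, sep="\t")
    expr.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_expression(tpm_path, counts_path, annotation: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(
        read_matrix_tsv(tpm_path), read_matrix_tsv(counts_path), annotation
    )


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.rename_axis("gene_id").to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0,
                      dtype={"chrom": str, "symbol": str})
    ann["chrom"] = ann["chrom"].astype(str)
    return ann


def write_gmt(catalog: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, members in catalog.items():
            fh.write("\t".join([set_id, "na", *members]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    catalog: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                catalog[parts[0]] = [g for g in parts[2:] if g]
    return catalog


def write_zpanel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.rename_axis("gene_id").to_csv(path, sep="\t", na_rep="")


def read_zpanel(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(float)
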