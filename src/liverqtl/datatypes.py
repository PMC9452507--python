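"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_META_COLUMNS = ["chrom", "pos", "ref", "alt"]
GENE_META_COLUMNS = ["symbol", "chrom", "tss", "strand", "biotype"]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    ``dosages`` is a DataFrame indexed by sample id with one column per
    variant id; entries are minor-allele dosages in [0, 2], NaN = missing.
    ``variants`` is indexed by variant id with columns chrom, pos, ref, alt.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.variants.index):
            self.variants = self.variants.loc[self.dosages.columns]
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self, axis: str = "sample") -> pd.Series:
        """Fraction of non-missing calls per sample or per variant."""
        notna = self.dosages.notna()
        if axis == "sample":
            return notna.mean(axis=1)
        if axis == "variant":
            return notna.mean(axis=0)
        raise ValueError("axis must be 'sample' or 'variant'")

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[list(sample_ids)], self.variants)

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        ids = list(variant_ids)
        return GenotypeMatrix(self.dosages[ids], self.variants.loc[ids])

    def restrict_chrom(self, chrom: str) -> "GenotypeMatrix":
        ids = self.variants.index[self.variants["chrom"].astype(str) == str(chrom)]
        return self.subset_variants(ids)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression on TPM and read-count scales.

    Both frames are indexed by gene id with one column per sample id and
    must share indices.  ``genes`` carries symbol, chrom, tss, strand,
    biotype per gene.
    """

    tpm: pd.DataFrame
    counts: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.tpm.index.equals(self.counts.index):
            raise ValueError("tpm and counts must share the gene index")
        if not self.tpm.columns.equals(self.counts.columns):
            raise ValueError("tpm and counts must share the sample columns")
        missing = self.tpm.index.difference(self.genes.index)
        if len(missing):
            raise ValueError(f"genes table lacks metadata for {list(missing)[:5]}")
        self.genes = self.genes.loc[self.tpm.index]

    @property
    def sample_ids(self) -> pd.Index:
        return self.tpm.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def n_samples(self) -> int:
        return self.tpm.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.tpm[ids], self.counts[ids], self.genes)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        ids = list(gene_ids)
        return ExpressionMatrix(
            self.tpm.loc[ids], self.counts.loc[ids], self.genes.loc[ids]
        )


@dataclass
class TruthTable:
    """Ground truth recorded by the synthetic generators."""

    cis_effects: list = field(default_factory=list)  # (gene, variant, beta_latent, afc)
    swap_pairs: list = field(default_factory=list)
    sex: dict = field(default_factory=dict)  # sample id -> 'male' | 'female'
    causal_twas_genes: list = field(default_factory=list)
    liver_specific_genes: list = field(default_factory=list)
    tissue_shared_genes: list = field(default_factory=list)
    sqtl_genes: list = field(default_factory=list)  # (gene, variant, shift)
    enriched_set: str | None = None
    enriched_set_lnor: float | None = None
    eqtl_genes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cis_effects": [list(t) for t in self.cis_effects],
            "swap_pairs": [list(t) for t in self.swap_pairs],
            "sex": dict(self.sex),
            "causal_twas_genes": list(self.causal_twas_genes),
            "liver_specific_genes": list(self.liver_specific_genes),
            "tissue_shared_genes": list(self.tissue_shared_genes),
            "sqtl_genes": [list(t) for t in self.sqtl_genes],
            "enriched_set": self.enriched_set,
            "enriched_set_lnor": self.enriched_set_lnor,
            "eqtl_genes": list(self.eqtl_genes),
        }
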