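"""Synthetic cohort generators with known ground truth.

Every generator is a pure function of its config and seed: identical
inputs give identical outputs.  The generators cover genotypes in
Hardy-Weinberg proportions (with a hemizygous-male X block), expression
with cis effects planted both additively on a latent normal scale and
multiplicatively on the TPM scale, sample swaps, exon-usage counts with
planted splicing QTLs, correlated multi-dataset TWAS z panels, tissue
posterior-probability matrices with planted liver-specific genes, and
gene-set catalogs with a configurable planted enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from liverqtl.datatypes import ExpressionMatrix, GenotypeMatrix, TruthTable

#: chromosome names used for autosomal genes/variants, cycled in order
AUTOSOMES = ("1", "2")


@dataclass
class SimConfig:
    """Parameters for the synthetic cohort generators."""

    n_samples: int = 192
    n_variants: int = 200
    n_genes: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    cis_window: int = 1_000_000
    effect_table: list = field(default_factory=list)  # (gene, variant, beta_latent, afc)
    noise_sd: float = 1.0
    sex_fraction_female: float = 0.5
    n_datasets: int = 6
    panel_rho: float = 0.5
    causal_genes: list = field(default_factory=list)
    causal_shift: float = 4.0
    missing_rate: float = 0.0
    seed: int = 0
    # layout / nuisance knobs
    n_chromosomes: int = 2
    n_x_variants: int = 0
    gene_spacing: int = 2_500_000
    n_exons: int = 4
    exon_reads: int = 1000
    sqtl_table: list = field(default_factory=list)  # (gene, variant, shift)
    include_sex_markers: bool = False

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_variants", "n_genes", "n_datasets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be contained in (0, 0.5]")
        if not abs(self.panel_rho) < 1:
            raise ValueError("|panel_rho| must be < 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def gen_annotation(config: SimConfig) -> pd.DataFrame:
    """Gene annotation laid out deterministically on the autosomes.

    Genes are placed round-robin across ``n_chromosomes`` autosomes at
    TSS = 1e6 + k * gene_spacing so that 1-Mb cis windows of neighbouring
    genes barely overlap.  When ``include_sex_markers`` is set, an
    XIST-like (chrX) and an RPS4Y1-like (chrY) marker gene are appended.
    """
    chroms = [AUTOSOMES[i % config.n_chromosomes] for i in range(config.n_genes)]
    per_chrom: dict[str, int] = {}
    rows = []
    for i, chrom in enumerate(chroms):
        k = per_chrom.get(chrom, 0)
        per_chrom[chrom] = k + 1
        rows.append(
            {
                "gene_id": f"G{i + 1:04d}",
                "symbol": f"SYM{i + 1:04d}",
                "chrom": chrom,
                "tss": 1_000_000 + k * config.gene_spacing,
                "strand": "+",
                "biotype": "protein_coding",
            }
        )
    if config.include_sex_markers:
        rows.append(
            {"gene_id": "G_XIST", "symbol": "XIST", "chrom": "X",
             "tss": 1_000_000, "strand": "+", "biotype": "lincRNA"}
        )
        rows.append(
            {"gene_id": "G_RPS4Y1", "symbol": "RPS4Y1", "chrom": "Y",
             "tss": 1_000_000, "strand": "+", "biotype": "protein_coding"}
        )
    return pd.DataFrame(rows).set_index("gene_id")


def gen_genotypes(
    config: SimConfig, annotation: pd.DataFrame | None = None
) -> tuple[GenotypeMatrix, TruthTable]:
    """Hard-call dosages in {0,1,2} drawn per variant from HWE proportions.

    Autosomal variants are assigned cyclically to annotated genes and
    positioned uniformly within half the cis window of the gene's TSS, so
    every gene has cis variants by construction.  If ``n_x_variants`` > 0
    an X block is appended on which males are hemizygous (dosage 0 or 2,
    never 1).  True sexes are recorded in the returned TruthTable.
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if annotation is None:
        annotation = gen_annotation(config)
    rng = config.rng(salt=1)
    samples = _sample_ids(config.n_samples)

    n_female = int(round(config.sex_fraction_female * config.n_samples))
    sex = np.array(["female"] * n_female + ["male"] * (config.n_samples - n_female))
    rng.shuffle(sex)

    auto_genes = annotation.index[~annotation["chrom"].isin(["X", "Y"])]
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_variants)
    half = config.cis_window // 2

    meta_rows = []
    cols = np.empty((config.n_samples, config.n_variants), dtype=float)
    for j in range(config.n_variants):
        gene = auto_genes[j % len(auto_genes)]
        chrom = annotation.at[gene, "chrom"]
        tss = int(annotation.at[gene, "tss"])
        pos = int(max(1, tss + rng.integers(-half, half + 1)))
        q = mafs[j]
        cols[:, j] = rng.choice(
            [0.0, 1.0, 2.0],
            size=config.n_samples,
            p=[(1 - q) ** 2, 2 * q * (1 - q), q**2],
        )
        meta_rows.append(
            {"variant_id": f"v{j + 1:05d}", "chrom": chrom, "pos": pos,
             "ref": "A", "alt": "G"}
        )

    if config.n_x_variants:
        x_mafs = rng.uniform(lo, hi, size=config.n_x_variants)
        male = sex == "male"
        xcols = np.empty((config.n_samples, config.n_x_variants), dtype=float)
        for j in range(config.n_x_variants):
            q = x_mafs[j]
            female_calls = rng.choice(
                [0.0, 1.0, 2.0],
                size=config.n_samples,
                p=[(1 - q) ** 2, 2 * q * (1 - q), q**2],
            )
            # hemizygous males: one allele, coded 0/2
            male_calls = 2.0 * rng.binomial(1, q, size=config.n_samples)
            xcols[:, j] = np.where(male, male_calls, female_calls)
            meta_rows.append(
                {"variant_id": f"x{j + 1:05d}", "chrom": "X",
                 "pos": 1_000_000 + j * 1000, "ref": "A", "alt": "G"}
            )
        cols = np.hstack([cols, xcols])

    variants = pd.DataFrame(meta_rows).set_index("variant_id")
    dosages = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"),
                           columns=variants.index)
    truth = TruthTable(sex={s: str(x) for s, x in zip(samples, sex)})
    return GenotypeMatrix(dosages, variants), truth


def _check_effects_cis(
    effect_table, annotation: pd.DataFrame, variants: pd.DataFrame, window: int
) -> None:
    for gene, variant, _beta, _afc in effect_table:
        if gene not in annotation.index:
            raise KeyError(f"unknown gene {gene!r} in effect table")
        if variant not in variants.index:
            raise KeyError(f"unknown variant {variant!r} in effect table")
        tss = int(annotation.at[gene, "tss"])
        pos = int(variants.at[variant, "pos"])
        same_chrom = str(annotation.at[gene, "chrom"]) == str(variants.at[variant, "chrom"])
        if not same_chrom or abs(pos - tss) > window:
            raise ValueError(
                f"planted effect {gene}~{variant} lies outside the cis window"
            )


def gen_expression(
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    config: SimConfig,
    truth: TruthTable | None = None,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Expression with planted cis effects on both modelling scales.

    For genes without a planted aFC the TPM is ``baseline * exp(latent)``
    with latent = sum(beta_latent * dosage) + N(0, noise_sd^2), i.e. the
    effect is additive on the latent normal scale.  For genes with a
    planted aFC the TPM follows the multiplicative dosage model
    ``baseline * (1 + (afc-1)/2 * dosage) * exp(noise)`` so that the mean
    TPM in the dosage-2 group is exactly ``afc`` times the dosage-0 group.
    Counts are TPM scaled by a per-sample library factor and rounded.
    Sex-marker genes (XIST-like high in females, RPS4Y1-like high in
    males) are populated when present in the annotation.
    """
    _check_effects_cis(config.effect_table, annotation, genotypes.variants,
                       config.cis_window)
    truth = truth or TruthTable()
    rng = config.rng(salt=2)
    samples = list(genotypes.sample_ids)
    n = len(samples)
    genes = annotation.index

    afc_by_gene: dict[str, tuple[str, float]] = {}
    beta_by_gene: dict[str, list[tuple[str, float]]] = {}
    for gene, variant, beta, afc in config.effect_table:
        if afc is not None and afc != 1.0:
            afc_by_gene[gene] = (variant, float(afc))
        if beta:
            beta_by_gene.setdefault(gene, []).append((variant, float(beta)))
        truth.cis_effects.append((gene, variant, beta, afc))

    baselines = rng.lognormal(mean=2.0, sigma=0.5, size=len(genes))
    tpm = np.zeros((len(genes), n))
    sexes = np.array([truth.sex.get(s, "female") for s in samples])
    female = sexes == "female"

    for gi, gene in enumerate(genes):
        symbol = annotation.at[gene, "symbol"]
        noise = rng.normal(0.0, config.noise_sd, size=n)
        if symbol == "XIST":
            base = np.where(female, 50.0, 0.5)
            tpm[gi] = base * np.exp(0.2 * noise)
            continue
        if symbol == "RPS4Y1":
            base = np.where(female, 0.5, 50.0)
            tpm[gi] = base * np.exp(0.2 * noise)
            continue
        if gene in afc_by_gene:
            variant, afc = afc_by_gene[gene]
            d = genotypes.dosages[variant].to_numpy(dtype=float)
            slope = (afc - 1.0) / 2.0
            tpm[gi] = baselines[gi] * (1.0 + slope * d) * np.exp(noise)
        else:
            latent = noise.copy()
            for variant, beta in beta_by_gene.get(gene, []):
                latent += beta * genotypes.dosages[variant].to_numpy(dtype=float)
            tpm[gi] = baselines[gi] * np.exp(0.5 * latent)

    lib = rng.uniform(20.0, 40.0, size=n)
    counts = np.rint(tpm * lib)

    tpm_df = pd.DataFrame(tpm, index=genes, columns=samples)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    return ExpressionMatrix(tpm_df, counts_df, annotation), truth


def inject_swaps(
    expr: ExpressionMatrix, pairs: list[tuple[str, str]],
    truth: TruthTable | None = None,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Exchange expression columns for each sample pair; genotypes untouched."""
    truth = truth or TruthTable()
    seen: set[str] = set()
    for a, b in pairs:
        if a == b:
            raise ValueError(f"degenerate swap pair ({a}, {b})")
        for s in (a, b):
            if s not in expr.sample_ids:
                raise KeyError(f"unknown sample id {s!r}")
            if s in seen:
                raise ValueError(f"sample {s!r} appears in more than one swap pair")
            seen.add(s)
    tpm = expr.tpm.copy()
    counts = expr.counts.copy()
    for a, b in pairs:
        tpm[[a, b]] = tpm[[b, a]].to_numpy()
        counts[[a, b]] = counts[[b, a]].to_numpy()
        truth.swap_pairs.append((a, b))
    return ExpressionMatrix(tpm, counts, expr.genes), truth


def gen_exon_usage(
    annotation: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: SimConfig,
    truth: TruthTable | None = None,
) -> tuple[dict[str, pd.DataFrame], TruthTable]:
    """Multinomial exon counts per gene, with optional genotype-shifted usage.

    Returns a mapping gene id -> samples x exons count DataFrame.  For a
    planted entry ``(gene, variant, shift)`` the expected usage of exon 0
    increases by ``shift * dosage / 2`` at the expense of exon 1, so the
    dosage-2 and dosage-0 group means differ by ``shift`` on exon 0.
    """
    truth = truth or TruthTable()
    rng = config.rng(salt=3)
    samples = list(genotypes.sample_ids)
    planted = {g: (v, float(s)) for g, v, s in config.sqtl_table}
    out: dict[str, pd.DataFrame] = {}
    for gene in annotation.index:
        if str(annotation.at[gene, "chrom"]) in ("X", "Y"):
            continue
        k = config.n_exons
        if gene in planted and k < 2:
            raise ValueError(f"sQTL gene {gene} needs >= 2 exons")
        if gene in planted:
            # deterministic base leaving room to move `shift` mass e1 -> e0
            shift = planted[gene][1]
            buffer = (1.0 - abs(shift)) / k
            base = np.full(k, np.nan)
            base[0] = buffer
            base[1] = abs(shift) + buffer
            if k > 2:
                base[2:] = (1.0 - base[0] - base[1]) / (k - 2)
            if buffer <= 0 or (base < 0).any():
                raise ValueError(
                    f"planted shift {shift} on {gene} produces negative proportions"
                )
        else:
            base = rng.dirichlet(np.full(k, 5.0))
        probs = np.tile(base, (len(samples), 1))
        if gene in planted:
            variant, shift = planted[gene]
            d = genotypes.dosages[variant].to_numpy(dtype=float)
            delta = shift * d / 2.0
            probs[:, 0] = base[0] + delta
            probs[:, 1] = base[1] - delta
            if (probs < 0).any():
                raise ValueError(
                    f"planted shift {shift} on {gene} produces negative proportions"
                )
            truth.sqtl_genes.append((gene, variant, shift))
        counts = np.vstack(
            [rng.multinomial(config.exon_reads, p) for p in probs]
        )
        out[gene] = pd.DataFrame(
            counts, index=samples,
            columns=[f"{gene}:e{e + 1}" for e in range(k)],
        )
    return out, truth


def gen_reference_panels(
    config: SimConfig, truth: TruthTable | None = None
) -> tuple[pd.DataFrame, TruthTable]:
    """Genes x datasets TWAS z panel with equicorrelated null rows.

    Null genes are multivariate normal with unit variances and pairwise
    correlation ``panel_rho``; causal genes get ``causal_shift`` added in
    every dataset.  Entries are masked missing (NaN) at ``missing_rate``.
    """
    if config.n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    k = config.n_datasets
    rho = config.panel_rho
    if rho <= -1.0 / (k - 1):
        raise ValueError(
            f"panel_rho={rho} gives a non-positive-definite equicorrelation "
            f"matrix for K={k}"
        )
    truth = truth or TruthTable()
    rng = config.rng(salt=4)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, size=config.n_genes,
                                method="cholesky")
    causal = [g for g in config.causal_genes if g in genes]
    idx = {g: i for i, g in enumerate(genes)}
    for g in causal:
        z[idx[g]] += config.causal_shift
    if config.missing_rate > 0:
        mask = rng.random(z.shape) < config.missing_rate
        z[mask] = np.nan
    truth.causal_twas_genes.extend(causal)
    panel = pd.DataFrame(z, index=pd.Index(genes, name="gene_id"),
                         columns=[f"dataset{i + 1}" for i in range(k)])
    return panel, truth


def gen_posterior_matrix(
    config: SimConfig,
    tissues: list[str],
    liver_tissues: list[str],
    n_specific: int = 10,
    n_shared: int = 10,
    truth: TruthTable | None = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """Genes x tissues eQTL posterior-probability matrix in [0, 1].

    The first ``n_specific`` genes are liver-specific (posterior near 1 in
    liver tissues, near 0 elsewhere), the next ``n_shared`` genes are high
    everywhere, and the remainder carry a latent factor shared by the
    liver columns so they correlate more with each other than with
    non-liver columns.
    """
    if not liver_tissues:
        raise ValueError("liver_tissues must be non-empty")
    if not set(liver_tissues) <= set(tissues):
        raise ValueError("liver_tissues must be a subset of tissues")
    if len(tissues) < 3:
        raise ValueError("need at least 3 tissues")
    truth = truth or TruthTable()
    rng = config.rng(salt=5)
    n = config.n_genes
    genes = [f"G{i + 1:05d}" for i in range(n)]
    is_liver = np.array([t in liver_tissues for t in tissues])

    shared = rng.normal(0.0, 1.5, size=n)            # tissue-shared propensity
    liver_factor = rng.normal(0.0, 1.5, size=n)      # liver-only structure
    logits = (
        shared[:, None]
        + np.where(is_liver[None, :], liver_factor[:, None], 0.0)
        + rng.normal(0.0, 0.8, size=(n, len(tissues)))
    )
    spec = slice(0, min(n_specific, n))
    shared_block = slice(spec.stop, min(spec.stop + n_shared, n))
    logits[spec, :] = np.where(is_liver[None, :], 6.0, -6.0)
    logits[spec, :] += rng.normal(0.0, 0.3, size=logits[spec, :].shape)
    logits[shared_block, :] = 6.0 + rng.normal(
        0.0, 0.3, size=logits[shared_block, :].shape
    )
    post = 1.0 / (1.0 + np.exp(-logits))
    truth.liver_specific_genes.extend(genes[spec])
    truth.tissue_shared_genes.extend(genes[shared_block])
    return (
        pd.DataFrame(post, index=pd.Index(genes, name="gene_id"), columns=tissues),
        truth,
    )


def gen_gene_sets(
    annotation: pd.DataFrame,
    config: SimConfig,
    eqtl_genes: list[str] | None = None,
    target_lnor: float = 1.5,
    base_rate: float = 0.3,
    n_control_sets: int = 3,
    truth: TruthTable | None = None,
) -> tuple[dict[str, list[str]], TruthTable]:
    """GMT-style catalog with one planted-enrichment set plus controls.

    Genes carrying a planted eQTL (``eqtl_genes``, default taken from the
    effect table) enter the enriched set with membership odds elevated by
    ``target_lnor`` over the ``base_rate`` baseline; control sets are
    uniform draws at the base rate.
    """
    truth = truth or TruthTable()
    rng = config.rng(salt=6)
    genes = [g for g in annotation.index
             if str(annotation.at[g, "chrom"]) not in ("X", "Y")]
    if eqtl_genes is None:
        eqtl_genes = sorted({g for g, *_ in config.effect_table})
    eqtl = np.array([g in set(eqtl_genes) for g in genes])
    logit0 = np.log(base_rate / (1 - base_rate))
    p1 = 1.0 / (1.0 + np.exp(-(logit0 + target_lnor)))
    if not 0 < p1 < 1:
        raise ValueError(f"target lnOR {target_lnor} unreachable at base rate "
                         f"{base_rate}")
    probs = np.where(eqtl, p1, base_rate)
    member = rng.random(len(genes)) < probs
    catalog = {"enriched_set": [g for g, m in zip(genes, member) if m]}
    for c in range(n_control_sets):
        keep = rng.random(len(genes)) < base_rate
        catalog[f"control_set_{c + 1}"] = [g for g, m in zip(genes, keep) if m]
    truth.enriched_set = "enriched_set"
    truth.enriched_set_lnor = target_lnor
    truth.eqtl_genes = list(eqtl_genes)
    return catalog, truth
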