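"""Variant/gene filtering, normalization transforms, and covariate assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtri
from scipy.stats import rankdata

from liverqtl.datatypes import GenotypeMatrix


def maf(dosages: np.ndarray | pd.Series) -> float:
    """Minor allele frequency from a dosage vector in [0, 2].

    Allele frequency f = mean(dosage)/2 over non-missing entries;
    MAF = min(f, 1 - f).
    """
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("all entries missing")
    f = d.mean() / 2.0
    return float(min(f, 1.0 - f))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Enumerates every heterozygote count consistent with the observed
    allele counts and sums the probabilities of configurations no more
    likely than the observed one (Wigginton-style exact test).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype call required")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # possible heterozygote counts share the parity of the rare allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_rr = (n_rare - hets) // 2
    n_cc = n - hets - n_rr
    logp = (
        gammaln(n + 1)
        - gammaln(n_rr + 1)
        - gammaln(hets + 1)
        - gammaln(n_cc + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def filter_variants(
    genotypes: GenotypeMatrix,
    callrate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants by call rate, MAF and HWE; record all reasons.

    A variant is dropped iff call rate < callrate_min OR MAF < maf_min OR
    HWE exact p < hwe_alpha (all strict inequalities).  Returns the
    filtered matrix and a per-variant table with boolean reason columns.
    """
    d = genotypes.dosages
    call_rate = d.notna().mean(axis=0)
    rows = []
    for vid in d.columns:
        col = d[vid].to_numpy(dtype=float)
        col = col[np.isfinite(col)]
        if col.size == 0:
            rows.append((vid, 0.0, np.nan, np.nan, True, True, False))
            continue
        v_maf = maf(col)
        hard = np.rint(col).astype(int)
        hwe_p = hwe_exact_test(
            int((hard == 0).sum()), int((hard == 1).sum()), int((hard == 2).sum())
        )
        rows.append(
            (
                vid,
                float(call_rate[vid]),
                v_maf,
                hwe_p,
                call_rate[vid] < callrate_min,
                v_maf < maf_min,
                hwe_p < hwe_alpha,
            )
        )
    report = pd.DataFrame(
        rows,
        columns=["variant_id", "call_rate", "maf", "hwe_p",
                 "low_call_rate", "low_maf", "hwe_fail"],
    ).set_index("variant_id")
    report["dropped"] = report[["low_call_rate", "low_maf", "hwe_fail"]].any(axis=1)
    kept = report.index[~report["dropped"]]
    return genotypes.subset_variants(kept), report


def filter_genes(
    tpm: pd.DataFrame,
    counts: pd.DataFrame,
    tpm_thr: float = 0.1,
    read_thr: float = 6,
    n_thr: int = 10,
) -> pd.Index:
    """Genes expressed above threshold in enough individuals.

    A gene is kept iff the number of samples with TPM strictly greater
    than ``tpm_thr`` AND reads >= ``read_thr`` is at least ``n_thr``.
    """
    if not tpm.index.equals(counts.index) or not tpm.columns.equals(counts.columns):
        raise ValueError("tpm and counts must share gene and sample indices")
    ok = (tpm > tpm_thr) & (counts >= read_thr)
    return tpm.index[ok.sum(axis=1) >= n_thr]


def quantile_normalize_to_average(tpm: pd.DataFrame) -> pd.DataFrame:
    """Map each sample's values onto the average empirical distribution.

    The value at rank r in a sample is replaced by the mean across
    samples of the r-th order statistic; ties within a sample receive
    the mean of their target values.  Within-sample ranks are preserved.
    """
    if tpm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    vals = tpm.to_numpy(dtype=float)
    order_means = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = rankdata(vals[:, j], method="average")
        # average rank -> interpolate between adjacent order-statistic means
        out[:, j] = np.interp(ranks, np.arange(1, len(order_means) + 1), order_means)
    return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)


def inverse_normal_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse normal transform, offset (r - 0.5)/n, average ties."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.allclose(v, v[0]):
        raise ValueError("constant vector cannot be transformed")
    ranks = rankdata(v, method="average")
    return ndtri((ranks - 0.5) / v.size)


def _sign_fixed_pcs(matrix: np.ndarray, k: int) -> np.ndarray:
    """Top-k left singular vectors of a column-standardized matrix.

    Sign fixed by making each component's largest-|loading| sample entry
    positive so results are deterministic.
    """
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (matrix - mu) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    for j in range(pcs.shape[1]):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def genotype_pcs(genotypes: GenotypeMatrix, k: int = 3) -> pd.DataFrame:
    """Principal components of the standardized dosage matrix (ancestry PCs)."""
    n, m = genotypes.dosages.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n_samples, n_variants)={min(n, m)}")
    if k == 0:
        return pd.DataFrame(index=genotypes.sample_ids)
    d = genotypes.dosages.to_numpy(dtype=float)
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), col_mean, d)
    pcs = _sign_fixed_pcs(d, k)
    return pd.DataFrame(
        pcs, index=genotypes.sample_ids, columns=[f"geno_PC{i + 1}" for i in range(k)]
    )


def expression_factors(expr_normalized: pd.DataFrame, n_factors: int) -> pd.DataFrame:
    """Top PCs of normalized expression, used as hidden-confounder covariates.

    ``expr_normalized`` is genes x samples; returns samples x factors.
    """
    n = expr_normalized.shape[1]
    if n_factors >= n:
        raise ValueError(f"n_factors={n_factors} must be < n_samples={n}")
    if n_factors == 0:
        return pd.DataFrame(index=expr_normalized.columns)
    pcs = _sign_fixed_pcs(expr_normalized.to_numpy(dtype=float).T, n_factors)
    return pd.DataFrame(
        pcs,
        index=expr_normalized.columns,
        columns=[f"expr_factor{i + 1}" for i in range(n_factors)],
    )


def assemble_covariates(
    *blocks: pd.DataFrame, standardize: bool = True
) -> pd.DataFrame:
    """Join covariate blocks on sample id, standardize, check full rank."""
    blocks = tuple(b for b in blocks if b is not None and b.shape[1] > 0)
    if not blocks:
        raise ValueError("no covariate blocks provided")
    cov = pd.concat(blocks, axis=1, join="inner")
    if cov.isna().any().any():
        raise ValueError("covariates contain missing entries after alignment")
    if standardize:
        vals = cov.to_numpy(dtype=float)
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        cov = pd.DataFrame((vals - mu) / sd, index=cov.index, columns=cov.columns)
    if np.linalg.matrix_rank(cov.to_numpy(dtype=float)) < cov.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return cov
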