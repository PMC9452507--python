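"""Splicing-QTL testing on exon-usage proportions.

A distance-based pseudo-F statistic compares exon-usage composition
vectors between genotype groups, with permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from liverqtl.association import bh_fdr, cis_pairs


@dataclass
class ExonUsage:
    """Exon-usage proportions for one gene: samples x exons, rows sum to 1."""

    gene_id: str
    proportions: pd.DataFrame
    total_reads: pd.Series
    missing: pd.Index  # samples with zero total reads


def exon_usage(exon_counts: pd.DataFrame, gene_id: str = "") -> ExonUsage:
    """Proportions = counts / per-sample total; zero-total rows marked missing."""
    if exon_counts.shape[1] < 2:
        raise ValueError(f"gene {gene_id or '?'} has a single exon")
    counts = exon_counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = counts / totals[:, None]
    props_df = pd.DataFrame(props, index=exon_counts.index,
                            columns=exon_counts.columns)
    missing = exon_counts.index[totals == 0]
    return ExonUsage(gene_id, props_df, pd.Series(totals, index=exon_counts.index),
                     missing)


def _pseudo_f(usage: np.ndarray, groups: np.ndarray) -> float:
    """Anderson-style pseudo-F on Euclidean distances between usage vectors."""
    grand = usage.mean(axis=0)
    labels = np.unique(groups)
    ssb = 0.0
    ssw = 0.0
    for g in labels:
        sub = usage[groups == g]
        mu = sub.mean(axis=0)
        ssb += len(sub) * float(((mu - grand) ** 2).sum())
        ssw += float(((sub - mu) ** 2).sum())
    df_b = len(labels) - 1
    df_w = len(usage) - len(labels)
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / df_b) / (ssw / df_w)


def _genotype_groups(dosage: np.ndarray, min_group: int = 5) -> np.ndarray | None:
    """Round dosages to {0,1,2}; merge undersized groups toward the nearest."""
    groups = np.rint(np.clip(dosage, 0, 2)).astype(int)
    for _ in range(3):
        labels, counts = np.unique(groups, return_counts=True)
        small = labels[counts < min_group]
        if small.size == 0:
            break
        g = small[0]
        others = labels[labels != g]
        if others.size == 0:
            return None
        nearest = others[np.argmin(np.abs(others - g))]
        groups[groups == g] = nearest
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or counts.min() < min_group:
        return None
    return groups


def sqtl_test(
    usage: ExonUsage,
    dosage: pd.Series | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    min_group: int = 5,
) -> tuple[float, float]:
    """Permutation p-value for genotype effect on exon usage.

    Statistic: pseudo-F between rounded-dosage groups on Euclidean
    distances; p = (1 + #{perm stat >= observed}) / (1 + n_perm).
    Raises if no valid grouping (>= 2 groups of >= ``min_group``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(dosage, pd.Series):
        dosage = dosage.loc[usage.proportions.index].to_numpy(dtype=float)
    keep = ~usage.proportions.index.isin(usage.missing)
    props = usage.proportions.to_numpy(dtype=float)[keep]
    d = np.asarray(dosage, dtype=float)[keep]
    groups = _genotype_groups(d, min_group)
    if groups is None:
        raise ValueError(
            f"gene {usage.gene_id or '?'}: no genotype grouping with >= 2 groups "
            f"of >= {min_group} samples"
        )
    observed = _pseudo_f(props, groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += _pseudo_f(props, rng.permutation(groups)) >= observed
    p = (1 + exceed) / (1 + n_perm)
    return float(observed), float(p)


def sqtl_scan(
    usages: dict[str, ExonUsage],
    genotypes,
    annotation: pd.DataFrame,
    window_bp: int = 1_000_000,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Best cis variant per gene by pseudo-F, permutation p, BH q across genes."""
    rows = []
    genes = [g for g in sorted(usages) if g in annotation.index]
    pairs = cis_pairs(annotation.loc[genes], genotypes.variants, window_bp)
    for i, gene in enumerate(genes):
        vids = pairs.loc[pairs["gene_id"] == gene, "variant_id"]
        best = None
        for j, vid in enumerate(vids):
            dosage = genotypes.dosages[vid]
            try:
                stat, p = sqtl_test(
                    usages[gene], dosage, n_perm=n_perm,
                    seed=(seed, i, j).__hash__() & 0x7FFFFFFF,
                )
            except ValueError:
                continue
            if best is None or p < best[2] or (p == best[2] and stat > best[1]):
                best = (vid, stat, p)
        if best is not None:
            rows.append((gene, *best))
    out = pd.DataFrame(rows, columns=["gene_id", "variant_id", "stat", "p"])
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out
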