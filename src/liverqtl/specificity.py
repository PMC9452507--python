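"""Tissue clustering and rank-based liver-specificity scoring.

Tissues are clustered on 1 - Spearman correlation of their per-gene eQTL
posterior profiles with average linkage.  Per-gene specificity contrasts
the gene's posterior rank in two liver datasets (score1 = sum of the two
liver ranks) against its mean rank in the non-liver tissues (score2);
specificity = score1/score2, so rank-homogeneous genes sit at exactly 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, rankdata, spearmanr


def tissue_clustering(posteriors: pd.DataFrame) -> np.ndarray:
    """Average-linkage tree over tissues at distance 1 - Spearman rho.

    Returns a scipy linkage matrix; leaf order follows the input columns.
    """
    if posteriors.shape[1] < 3:
        raise ValueError("need >= 3 tissues")
    for col in posteriors.columns:
        if posteriors[col].nunique() <= 1:
            raise ValueError(f"tissue column {col!r} is constant; rho undefined")
    rho = spearmanr(posteriors.to_numpy(dtype=float)).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return linkage(squareform(dist, checks=False), method="average")


def siblings_in_tree(link: np.ndarray, i: int, j: int) -> bool:
    """True if leaves i and j are merged directly with each other."""
    return any((int(a) == i and int(b) == j) or (int(a) == j and int(b) == i)
               for a, b, _, _ in link)


def specificity_score(
    posteriors: pd.DataFrame,
    liver_columns: list[str],
    nonliver_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene liver-specificity ratio from within-tissue posterior ranks.

    Ranks are computed within each tissue column across genes, ascending
    (larger posterior -> larger rank), ties averaged.  score1 = sum of the
    two liver ranks, score2 = mean non-liver rank, specificity =
    score1/score2.  Table returned sorted by specificity descending.
    """
    if len(liver_columns) != 2:
        raise ValueError("exactly 2 liver columns required")
    if nonliver_columns is None:
        nonliver_columns = [c for c in posteriors.columns if c not in liver_columns]
    if not nonliver_columns:
        raise ValueError("no non-liver columns")
    ranks = posteriors.apply(lambda col: rankdata(col, method="average"), axis=0)
    score1 = ranks[liver_columns].sum(axis=1)
    score2 = ranks[nonliver_columns].mean(axis=1)
    out = pd.DataFrame(
        {"score1": score1, "score2": score2, "specificity": score1 / score2},
        index=posteriors.index,
    )
    return out.sort_values("specificity", ascending=False, kind="mergesort")


def rank_set_enrichment(
    specificity_table: pd.DataFrame, gene_set: list[str]
) -> tuple[float, float, str]:
    """Two-sided rank-sum test of a gene set on the specificity ranking.

    Wilcoxon rank-sum (normal approximation with continuity correction)
    of set members vs. the complement on the specificity values.  Returns
    (statistic, p, direction) with direction 'higher' when set members
    rank higher in specificity.
    """
    universe = set(specificity_table.index)
    members = sorted(universe & set(gene_set))
    if not members:
        raise ValueError("gene set does not intersect the universe")
    if len(members) >= len(universe):
        raise ValueError("gene set covers the whole universe")
    rest = sorted(universe - set(members))
    if len(rest) < 2 or len(members) < 1 or len(universe) - len(members) < 2:
        raise ValueError("degenerate split for the rank-sum test")
    x = specificity_table.loc[members, "specificity"].to_numpy()
    y = specificity_table.loc[rest, "specificity"].to_numpy()
    stat, p = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    direction = "higher" if stat > len(x) * len(y) / 2 else "lower"
    return float(stat), float(p), direction
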