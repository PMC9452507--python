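"""Gene-set enrichment of eQTL evidence.

Log odds ratios (optionally adjusted for average expression) from
logistic regression, with Wald confidence intervals and Cochran's Q
heterogeneity tests across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class EnrichmentResult:
    dataset_id: str
    set_id: str
    lnor: float
    se: float
    ci_low: float
    ci_high: float
    adjusted: bool
    zero_cell_corrected: bool
    n_in_sig: int
    n_in_nonsig: int
    n_out_sig: int
    n_out_nonsig: int


def eqtl_indicator(gene_results: pd.DataFrame, p_thr: float = 1e-5,
                   p_col: str = "p") -> pd.Series:
    """Per-gene boolean: best cis p strictly below threshold."""
    if gene_results.index.has_duplicates:
        raise ValueError("gene_results must carry one best p per gene")
    return gene_results[p_col] < p_thr


def set_log_or(
    indicator: pd.Series,
    membership: pd.Series,
    adjust_expression: pd.Series | None = None,
    dataset_id: str = "",
    set_id: str = "",
) -> EnrichmentResult:
    """Natural-log odds ratio that set members carry a significant eQTL.

    Logistic regression of the eQTL indicator on set membership; without
    the expression covariate the coefficient equals the closed-form 2x2
    log odds ratio.  With ``adjust_expression`` (per-gene mean TPM) a
    log10(TPM + 1) covariate is added.  Zero 2x2 cells fall back to the
    Haldane-Anscombe 0.5-corrected closed form and are flagged.
    """
    genes = indicator.index.intersection(membership.index)
    y = indicator.loc[genes].astype(int).to_numpy()
    m = membership.loc[genes].astype(int).to_numpy()
    if m.sum() == 0 or m.sum() == len(m):
        raise ValueError("gene set must leave genes both inside and outside")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both indicator levels must be present")

    a = int(((m == 1) & (y == 1)).sum())  # in set, significant
    b = int(((m == 1) & (y == 0)).sum())
    c = int(((m == 0) & (y == 1)).sum())
    d = int(((m == 0) & (y == 0)).sum())
    zero_cell = min(a, b, c, d) == 0

    adjusted = adjust_expression is not None
    if zero_cell and not adjusted:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        lnor = float(np.log(aa * dd / (bb * cc)))
        se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
    else:
        cols = [np.ones(len(y)), m]
        if adjusted:
            tpm = adjust_expression.loc[genes].to_numpy(dtype=float)
            cols.append(np.log10(tpm + 1.0))
        x = np.column_stack(cols)
        fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        lnor = float(fit.params[1])
        se = float(fit.bse[1])
    return EnrichmentResult(
        dataset_id, set_id, lnor, se,
        lnor - 1.96 * se, lnor + 1.96 * se,
        adjusted, zero_cell, a, b, c, d,
    )


def cochran_q(
    results: list[EnrichmentResult], n_sets_tested: int = 1
) -> tuple[float, int, float, float]:
    """Cochran's Q heterogeneity test across datasets for one gene set.

    Q = sum w_i (lnOR_i - weighted mean)^2 with w_i = 1/se_i^2, p from
    chi-square with k-1 df; the Bonferroni p multiplies by the number of
    sets tested, capped at 1.
    """
    finite = [r for r in results if np.isfinite(r.lnor) and np.isfinite(r.se)
              and r.se > 0]
    if len(finite) < 2:
        raise ValueError("Cochran's Q needs >= 2 datasets with finite estimates")
    lnors = np.array([r.lnor for r in finite])
    w = np.array([1.0 / r.se**2 for r in finite])
    mean_w = float((w * lnors).sum() / w.sum())
    q = float((w * (lnors - mean_w) ** 2).sum())
    df = len(finite) - 1
    p = float(stats.chi2.sf(q, df))
    p_bonf = float(min(1.0, p * n_sets_tested))
    return q, df, p, p_bonf


def enrich_catalog(
    indicators: dict[str, pd.Series],
    catalog: dict[str, list[str]],
    adjust_expression: dict[str, pd.Series] | None = None,
    absent_as_null: bool = False,
) -> pd.DataFrame:
    """Enrichment of every (dataset, set) combination plus heterogeneity.

    ``indicators`` maps dataset id -> per-gene eQTL indicator.  When
    ``absent_as_null`` is set, genes in the union universe missing from a
    dataset are treated as not significant (the microarray-style
    assumption); otherwise each dataset uses its own gene universe.
    """
    universe = None
    if absent_as_null:
        universe = pd.Index(sorted(set().union(*[set(v.index)
                                                 for v in indicators.values()])))
    rows = []
    per_set: dict[str, list[EnrichmentResult]] = {}
    for ds, ind in indicators.items():
        if absent_as_null:
            ind = ind.reindex(universe, fill_value=False)
        for set_id, members in catalog.items():
            membership = pd.Series(ind.index.isin(members), index=ind.index)
            tpm = None
            if adjust_expression and ds in adjust_expression:
                tpm = adjust_expression[ds].reindex(ind.index).fillna(0.0)
            res = set_log_or(ind, membership, tpm, dataset_id=ds, set_id=set_id)
            per_set.setdefault(set_id, []).append(res)
            rows.append(vars(res))
    out = pd.DataFrame(rows)
    n_sets = len(catalog)
    het = {}
    for set_id, results in per_set.items():
        if len(results) >= 2:
            q, df, p, p_bonf = cochran_q(results, n_sets_tested=n_sets)
            het[set_id] = (q, df, p, p_bonf)
    if het:
        out["het_q"] = out["set_id"].map(lambda s: het.get(s, (np.nan,) * 4)[0])
        out["het_p"] = out["set_id"].map(lambda s: het.get(s, (np.nan,) * 4)[2])
        out["het_p_bonf"] = out["set_id"].map(lambda s: het.get(s, (np.nan,) * 4)[3])
    return out
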