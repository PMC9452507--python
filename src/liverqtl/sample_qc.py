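"""Sample-level quality control.

Call-rate exclusion, sex concordance from genotypes and expression,
duplicate screening via genotype concordance, and genotype/expression
swap detection by predicting expression of strongly cis-regulated genes
from genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from liverqtl.association import cis_pairs, residualize
from liverqtl.datatypes import ExpressionMatrix, GenotypeMatrix

UNKNOWN = "unknown"


@dataclass
class SampleQcReport:
    """Accumulates per-sample QC calls and exclusion flags."""

    call_rate: dict = field(default_factory=dict)
    genotype_sex: dict = field(default_factory=dict)
    expression_sex: dict = field(default_factory=dict)
    reported_sex: dict = field(default_factory=dict)
    swap_match: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)  # sample -> set of flag strings

    def flag(self, sample: str, reason: str) -> None:
        self.flags.setdefault(sample, set()).add(reason)

    @property
    def excluded(self) -> set:
        return {s for s, f in self.flags.items() if f}

    def to_frame(self) -> pd.DataFrame:
        samples = sorted(
            set(self.call_rate) | set(self.genotype_sex) | set(self.expression_sex)
            | set(self.flags) | set(self.reported_sex)
        )
        return pd.DataFrame(
            {
                "call_rate": [self.call_rate.get(s, np.nan) for s in samples],
                "genotype_sex": [self.genotype_sex.get(s, UNKNOWN) for s in samples],
                "expression_sex": [self.expression_sex.get(s, UNKNOWN) for s in samples],
                "reported_sex": [self.reported_sex.get(s, UNKNOWN) for s in samples],
                "swap_match": [self.swap_match.get(s, "") for s in samples],
                "flags": [",".join(sorted(self.flags.get(s, set()))) for s in samples],
            },
            index=pd.Index(samples, name="sample_id"),
        )


def sample_call_rate_filter(
    genotypes: GenotypeMatrix,
    threshold: float = 0.98,
    report: SampleQcReport | None = None,
) -> tuple[GenotypeMatrix, SampleQcReport]:
    """Remove samples whose genotype call rate is strictly below threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    report = report or SampleQcReport()
    rates = genotypes.call_rate("sample")
    for s, rate in rates.items():
        report.call_rate[s] = float(rate)
        if rate < threshold:
            report.flag(s, "low_call_rate")
    kept = [s for s in genotypes.sample_ids if rates[s] >= threshold]
    return genotypes.subset_samples(kept), report


def genotype_sex(
    x_genotypes: GenotypeMatrix,
    het_threshold: float = 0.1,
    min_variants: int = 50,
) -> pd.Series:
    """Sex call from X-chromosome heterozygosity.

    Heterozygosity = fraction of dosage-1 calls among non-missing X calls;
    below ``het_threshold`` -> male, else female.  Fewer than
    ``min_variants`` X variants -> every call is 'unknown'.
    """
    d = x_genotypes.dosages
    if d.shape[1] == 0:
        warnings.warn("no X variants present; all sex calls unknown")
        return pd.Series(UNKNOWN, index=d.index)
    if d.shape[1] < min_variants:
        return pd.Series(UNKNOWN, index=d.index)
    hard = np.rint(d.to_numpy(dtype=float))
    het = np.nansum(hard == 1, axis=1) / np.maximum(
        np.isfinite(hard).sum(axis=1), 1
    )
    return pd.Series(
        np.where(het < het_threshold, "male", "female"), index=d.index
    )


def expression_sex(
    expr: ExpressionMatrix, xist_id: str, rps4y1_id: str
) -> pd.Series:
    """Sex call by 2-means clustering on the two sex-marker genes.

    The cluster with the higher XIST-like centroid is labelled female.
    Degenerate configurations (single sample, no separation) yield
    'unknown' for every sample.
    """
    for gid in (xist_id, rps4y1_id):
        if gid not in expr.gene_ids:
            raise KeyError(f"marker gene {gid!r} absent from expression matrix")
    feats = np.log1p(
        expr.tpm.loc[[xist_id, rps4y1_id]].to_numpy(dtype=float)
    ).T
    samples = expr.sample_ids
    if feats.shape[0] < 2 or np.allclose(feats, feats[0]):
        return pd.Series(UNKNOWN, index=samples)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(feats)
    labels = km.labels_
    if len(set(labels)) < 2:
        return pd.Series(UNKNOWN, index=samples)
    female_cluster = int(np.argmax(km.cluster_centers_[:, 0]))
    return pd.Series(
        np.where(labels == female_cluster, "female", "male"), index=samples
    )


def sex_concordance(
    reported: pd.Series, genotype_call: pd.Series, expression_call: pd.Series
) -> set:
    """Samples whose reported sex disagrees with BOTH data-derived calls.

    'unknown' in any call never triggers exclusion.
    """
    excluded = set()
    for s in reported.index:
        rep = reported.get(s, UNKNOWN)
        geno = genotype_call.get(s, UNKNOWN)
        expr = expression_call.get(s, UNKNOWN)
        if UNKNOWN in (rep, geno, expr):
            continue
        if rep != geno and rep != expr:
            excluded.add(s)
    return excluded


def relatedness_screen(
    genotypes: GenotypeMatrix,
    duplicate_threshold: float = 0.95,
    min_shared: int = 100,
) -> tuple[pd.DataFrame, list]:
    """Pairwise hard-call concordance; pairs above threshold are duplicates.

    Returns a long-format table (sample_a, sample_b, concordance,
    n_shared, assessable, duplicate) over unordered pairs (self-pairs
    excluded) and the list of duplicate pairs.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need >= 2 samples")
    if genotypes.n_variants < min_shared:
        raise ValueError(f"need >= {min_shared} variants")
    hard = np.rint(genotypes.dosages.to_numpy(dtype=float))
    samples = list(genotypes.sample_ids)
    rows = []
    duplicates = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            both = np.isfinite(hard[i]) & np.isfinite(hard[j])
            n_shared = int(both.sum())
            if n_shared < min_shared:
                rows.append((samples[i], samples[j], np.nan, n_shared, False, False))
                continue
            conc = float((hard[i][both] == hard[j][both]).mean())
            dup = conc >= duplicate_threshold
            if dup:
                duplicates.append((samples[i], samples[j]))
            rows.append((samples[i], samples[j], conc, n_shared, True, dup))
    table = pd.DataFrame(
        rows,
        columns=["sample_a", "sample_b", "concordance", "n_shared",
                 "assessable", "duplicate"],
    )
    return table, duplicates


def swap_scan(
    genotypes: GenotypeMatrix,
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    k: int = 100,
    window_bp: int = 1_000_000,
    r_floor: float = 0.3,
    leave_one_out: bool = False,
) -> tuple[pd.DataFrame, set]:
    """Detect genotype/expression swaps via expression prediction.

    Selects the ``k`` genes whose best cis variant is most strongly
    correlated with expression (|Pearson r|, after optional covariate
    residualization, subject to an |r| >= ``r_floor`` eligibility floor),
    fits one simple linear model expression ~ dosage per gene, predicts a
    k-vector of expression per sample from its genotypes, and correlates
    predictions against every sample's observed expression.  A sample
    whose best match (argmax correlation) is not itself is flagged along
    with the matched sample.

    Returns the samples x samples match-correlation matrix and the
    flagged sample set.
    """
    samples = list(expr.columns)
    geno = genotypes.subset_samples(samples)
    cov = None if covariates is None else covariates.loc[samples].to_numpy(float)

    pairs = cis_pairs(annotation.loc[annotation.index.intersection(expr.index)],
                      geno.variants, window_bp)
    if pairs.empty:
        raise ValueError("no predictive genes: no cis pairs available")

    e_res = residualize(expr.to_numpy(float), cov)
    g_res = residualize(geno.dosages.to_numpy(float).T, cov)
    e_idx = {g: i for i, g in enumerate(expr.index)}
    g_idx = {v: i for i, v in enumerate(geno.variant_ids)}
    e_norm = np.sqrt((e_res**2).sum(axis=1))
    g_norm = np.sqrt((g_res**2).sum(axis=1))

    best: dict[str, tuple[float, str]] = {}
    for gene, sub in pairs.groupby("gene_id", sort=True):
        gi = e_idx[gene]
        if e_norm[gi] == 0:
            continue
        for vid in sub["variant_id"]:
            vi = g_idx[vid]
            if g_norm[vi] == 0:
                continue
            r = float(e_res[gi] @ g_res[vi] / (e_norm[gi] * g_norm[vi]))
            if gene not in best or abs(r) > abs(best[gene][0]):
                best[gene] = (r, vid)

    eligible = [(abs(r), gene, vid) for gene, (r, vid) in best.items()
                if abs(r) >= r_floor]
    if not eligible:
        raise ValueError("no predictive genes")
    eligible.sort(reverse=True)
    if len(eligible) < k:
        warnings.warn(
            f"only {len(eligible)} eligible genes (requested {k}); using all"
        )
    chosen = eligible[:k]

    n = len(samples)
    obs = np.empty((len(chosen), n))
    pred = np.empty((len(chosen), n))
    for row, (_, gene, vid) in enumerate(chosen):
        y = expr.loc[gene].to_numpy(float)
        d = geno.dosages[vid].to_numpy(float)
        obs[row] = y
        if leave_one_out:
            for s in range(n):
                mask = np.arange(n) != s
                slope, intercept = np.polyfit(d[mask], y[mask], 1)
                pred[row, s] = intercept + slope * d[s]
        else:
            slope, intercept = np.polyfit(d, y, 1)
            pred[row] = intercept + slope * d

    pc = pred - pred.mean(axis=0)
    oc = obs - obs.mean(axis=0)
    pn = np.sqrt((pc**2).sum(axis=0))
    on = np.sqrt((oc**2).sum(axis=0))
    pn[pn == 0] = np.inf
    on[on == 0] = np.inf
    match = (pc / pn).T @ (oc / on)  # [predicted sample, observed sample]
    match_df = pd.DataFrame(match, index=samples, columns=samples)

    flagged: set = set()
    for i, s in enumerate(samples):
        j = int(np.argmax(match[i]))
        if j != i:
            flagged.add(s)
            flagged.add(samples[j])
    return match_df, flagged


def run_sample_qc(
    genotypes: GenotypeMatrix,
    expr: ExpressionMatrix,
    expr_int: pd.DataFrame,
    annotation: pd.DataFrame,
    reported_sex: pd.Series,
    xist_id: str | None = None,
    rps4y1_id: str | None = None,
    call_rate_threshold: float = 0.98,
    het_threshold: float = 0.1,
    k: int = 100,
) -> SampleQcReport:
    """Full QC pass combining all screens into one report."""
    report = SampleQcReport()
    report.reported_sex = {s: reported_sex.get(s, UNKNOWN) for s in genotypes.sample_ids}
    filtered, report = sample_call_rate_filter(genotypes, call_rate_threshold, report)

    geno_sex = genotype_sex(filtered.restrict_chrom("X"), het_threshold)
    report.genotype_sex = dict(geno_sex)
    if xist_id and rps4y1_id:
        expr_sex = expression_sex(expr, xist_id, rps4y1_id)
    else:
        expr_sex = pd.Series(UNKNOWN, index=expr.sample_ids)
    report.expression_sex = dict(expr_sex)
    for s in sex_concordance(reported_sex, geno_sex, expr_sex):
        report.flag(s, "sex_mismatch")

    if filtered.n_variants >= 100 and filtered.n_samples >= 2:
        _, duplicates = relatedness_screen(filtered)
        for a, b in duplicates:
            report.flag(a, "duplicate")
            report.flag(b, "duplicate")

    match, flagged = swap_scan(filtered, expr_int, annotation, k=k)
    for s in match.index:
        report.swap_match[s] = match.columns[int(np.argmax(match.loc[s].to_numpy()))]
    for s in flagged:
        report.flag(s, "swap")
    return report
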