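"""cis/trans eQTL mapping.

Covariate-adjusted linear scans computed by residualizing expression and
dosage on the covariates and using the correlation-to-t identity, adaptive
permutation gene-level (eGene) p-values with beta extrapolation, allelic
fold-change fits under a log-of-linear model, BH FDR, and trans quality
flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

P_FLOOR = 5e-324  # smallest positive subnormal double; underflow marker


@dataclass
class EGeneResult:
    gene_id: str
    best_variant: str
    p_nominal_min: float
    p_beta: float
    p_empirical: float
    n_perm: int
    beta_a: float
    beta_b: float


@dataclass
class AfcFit:
    gene_id: str
    variant_id: str
    c0: float
    c1: float
    log2_afc: float
    p: float
    converged: bool


def residualize(matrix: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of each row of ``matrix`` (k x n) on covariates + intercept."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = matrix.shape[1]
    if covariates is None or covariates.size == 0:
        x = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        x = np.column_stack([np.ones(n), covariates])
    q, r = np.linalg.qr(x)
    if np.abs(np.diag(r)).min() < 1e-10 * np.abs(np.diag(r)).max():
        raise ValueError("covariates are collinear")
    return matrix - (matrix @ q) @ q.T


def _corr_to_pt(r: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 0.0))
    t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(p <= 0, P_FLOOR, p)
    return t, p


def cis_pairs(
    annotation: pd.DataFrame,
    variants: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """All (gene, variant) pairs with the variant inside the cis window.

    The window is the closed interval [TSS - window_bp, TSS + window_bp]
    on the gene's chromosome.
    """
    if annotation["tss"].isna().any():
        missing = annotation.index[annotation["tss"].isna()]
        raise ValueError(f"genes missing TSS: {list(missing)[:5]}")
    rows = []
    vpos = variants["pos"].astype(int)
    vchrom = variants["chrom"].astype(str)
    for gene in annotation.index:
        tss = int(annotation.at[gene, "tss"])
        chrom = str(annotation.at[gene, "chrom"])
        hit = (vchrom == chrom) & (vpos >= tss - window_bp) & (vpos <= tss + window_bp)
        for vid in variants.index[hit]:
            rows.append((gene, vid))
    return pd.DataFrame(rows, columns=["gene_id", "variant_id"])


def cis_scan(
    expr_int: pd.DataFrame,
    genotypes,
    covariates: pd.DataFrame | None,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Linear association for each cis pair after covariate adjustment.

    Equivalent to OLS of expression on dosage + covariates: both sides are
    residualized on the covariates (with intercept) and the t statistic on
    the dosage coefficient recovered via the correlation identity with
    df = n - #covariates - 2.  Returns a table with beta, t, p and BH q
    within the cis family.
    """
    samples = list(expr_int.columns)
    n = len(samples)
    cov = None if covariates is None else covariates.loc[samples].to_numpy(float)
    k_cov = 0 if cov is None else cov.shape[1]
    df = n - k_cov - 2
    if df < 1:
        raise ValueError("not enough samples for the covariate count")

    e_res = residualize(expr_int.to_numpy(float), cov)
    g_res = residualize(genotypes.dosages.loc[samples].to_numpy(float).T, cov)
    e_idx = {g: i for i, g in enumerate(expr_int.index)}
    g_idx = {v: i for i, v in enumerate(genotypes.variant_ids)}

    e_norm = np.sqrt((e_res**2).sum(axis=1))
    g_norm = np.sqrt((g_res**2).sum(axis=1))

    gi = pairs["gene_id"].map(e_idx).to_numpy()
    vi = pairs["variant_id"].map(g_idx).to_numpy()
    if np.isnan(gi.astype(float)).any() or np.isnan(vi.astype(float)).any():
        raise KeyError("pair references a gene or variant absent from the matrices")

    dots = np.einsum("ij,ij->i", e_res[gi], g_res[vi])
    denom = e_norm[gi] * g_norm[vi]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, dots / denom, 0.0)
        beta = np.where(g_norm[vi] > 0, dots / g_norm[vi] ** 2, 0.0)
    t, p = _corr_to_pt(r, df)
    out = pairs.copy()
    out["beta"] = beta
    out["t"] = t
    out["p"] = p
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def egene_pvalue(
    gene: str,
    genotypes_cis,
    expr_int: pd.DataFrame | pd.Series,
    covariates: pd.DataFrame | None,
    max_perm: int = 1000,
    adaptive_stop: int = 100,
    seed: int = 0,
) -> EGeneResult:
    """Gene-level p-value from adaptive permutations with beta extrapolation.

    The expression vector is residualized once and its residuals permuted
    (genotypes and covariates fixed); per permutation the minimum nominal
    p over the gene's cis variants is recorded.  Permutation stops early
    once ``adaptive_stop`` minima beat the observed minimum.  A Beta(a, b)
    is fitted to the permutation minima by maximum likelihood (moments
    start) and the gene-level p is its CDF at the observed minimum; the
    empirical permutation p is reported alongside.
    """
    if max_perm < 10:
        raise ValueError("max_perm must be >= 10")
    if isinstance(expr_int, pd.DataFrame):
        expr_vec = expr_int.loc[gene]
    else:
        expr_vec = expr_int
    samples = list(expr_vec.index)
    n = len(samples)
    cov = None if covariates is None else covariates.loc[samples].to_numpy(float)
    k_cov = 0 if cov is None else cov.shape[1]
    df = n - k_cov - 2

    e = residualize(expr_vec.to_numpy(float), cov)[0]
    g = residualize(genotypes_cis.dosages.loc[samples].to_numpy(float).T, cov)
    g_norm = np.sqrt((g**2).sum(axis=1))
    keep = g_norm > 0
    if not keep.any():
        raise ValueError("no polymorphic cis variants")
    g, g_norm = g[keep], g_norm[keep]
    variant_ids = np.asarray(genotypes_cis.variant_ids)[keep]
    e_norm = np.sqrt((e**2).sum())

    r_obs = g @ e / (g_norm * e_norm)
    _, p_all = _corr_to_pt(r_obs, df)
    best = int(np.argmin(p_all))
    p_obs = float(p_all[best])

    rng = np.random.default_rng(seed)
    minima: list[float] = []
    hits = 0
    chunk = 100
    while len(minima) < max_perm and hits < adaptive_stop:
        b = min(chunk, max_perm - len(minima))
        perms = np.vstack([rng.permutation(e) for _ in range(b)])
        r = (g @ perms.T) / (g_norm[:, None] * e_norm)
        _, p = _corr_to_pt(r, df)
        pmin = p.min(axis=0)
        minima.extend(pmin.tolist())
        hits += int((pmin <= p_obs).sum())
    minima_arr = np.clip(np.asarray(minima), 1e-300, 1.0 - 1e-12)

    a, b_par = _fit_beta(minima_arr)
    p_beta = float(stats.beta.cdf(p_obs, a, b_par))
    p_emp = (1 + int((minima_arr <= p_obs).sum())) / (1 + len(minima_arr))
    return EGeneResult(
        gene_id=gene,
        best_variant=str(variant_ids[best]),
        p_nominal_min=p_obs,
        p_beta=p_beta,
        p_empirical=float(p_emp),
        n_perm=len(minima_arr),
        beta_a=float(a),
        beta_b=float(b_par),
    )


def _fit_beta(x: np.ndarray) -> tuple[float, float]:
    """Beta(a, b) fit: MLE with method-of-moments start, moments fallback."""
    m, v = x.mean(), x.var(ddof=1)
    v = max(v, 1e-12)
    common = m * (1 - m) / v - 1.0
    a0, b0 = max(m * common, 1e-3), max((1 - m) * common, 1e-3)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b, _, _ = stats.beta.fit(x, a0, b0, floc=0, fscale=1)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            raise ValueError
        return float(a), float(b)
    except Exception:
        return float(a0), float(b0)


def egene_scan(
    expr_int: pd.DataFrame,
    genotypes,
    covariates: pd.DataFrame | None,
    annotation: pd.DataFrame,
    window_bp: int = 1_000_000,
    max_perm: int = 1000,
    adaptive_stop: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """eGene analysis across all genes with >= 1 cis variant; BH q added."""
    pairs = cis_pairs(annotation.loc[annotation.index.intersection(expr_int.index)],
                      genotypes.variants, window_bp)
    results = []
    for i, (gene, sub) in enumerate(pairs.groupby("gene_id", sort=True)):
        cis_geno = genotypes.subset_variants(sub["variant_id"])
        res = egene_pvalue(
            gene, cis_geno, expr_int.loc[gene], covariates,
            max_perm=max_perm, adaptive_stop=adaptive_stop,
            seed=(seed, i).__hash__() & 0x7FFFFFFF,
        )
        results.append(res)
    out = pd.DataFrame([vars(r) for r in results])
    if len(out):
        out["q"] = bh_fdr(out["p_beta"].to_numpy())
    return out


def afc_fit(
    tpm: np.ndarray | pd.Series,
    dosage: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
    gene_id: str = "",
    variant_id: str = "",
    max_iter: int = 100,
) -> AfcFit:
    """Allelic fold change under a log-of-linear model.

    Fits log(TPM + 1) = log((c0 + 1) + c1 * d) + gamma' covariates + eps
    by Gauss-Newton with backtracking, profiling out the linear
    covariates (which carry no intercept: the log baseline IS the
    intercept, keeping c0 identifiable); start c1 = 0,
    c0 + 1 = exp(mean log(TPM + 1)).  The positivity constraint on the
    fitted mean is enforced over the observed dosage range.  p-value from
    the likelihood-ratio test against c1 = 0; log2 aFC =
    log2((c0 + 2 c1)/c0) clipped to +/- log2(100).
    """
    y = np.log1p(np.asarray(tpm, dtype=float))
    d = np.asarray(dosage, dtype=float)
    if (np.asarray(tpm, dtype=float) < 0).any():
        raise ValueError("TPM must be non-negative")
    if len(np.unique(np.rint(d))) < 2:
        raise ValueError("need >= 2 dosage groups")
    n = y.size
    if covariates is None:
        q = np.zeros((n, 0))
        q0, _ = np.linalg.qr(np.ones((n, 1)))
    else:
        cv = np.asarray(covariates, dtype=float)
        if cv.ndim == 1:
            cv = cv[:, None]
        q, _ = np.linalg.qr(cv - cv.mean(axis=0))
        q0, _ = np.linalg.qr(np.column_stack([np.ones(n), cv]))

    def project_out(v: np.ndarray) -> np.ndarray:
        if q.shape[1] == 0:
            return v
        return v - q @ (q.T @ v)

    y_res0 = y - q0 @ (q0.T @ y)
    sse0 = float(y_res0 @ y_res0)  # null: c1 = 0, baseline absorbed

    a = float(np.exp(y.mean()))  # a = c0 + 1, baseline on the +1 scale
    c1 = 0.0
    d_lo, d_hi = d.min(), d.max()

    def feasible(a_, c1_):
        return a_ + c1_ * d_lo > 1e-12 and a_ + c1_ * d_hi > 1e-12 and a_ > 1e-12

    def sse(a_, c1_):
        f = np.log(a_ + c1_ * d)
        r = project_out(y - f)
        return float(r @ r), r

    cur_sse, _ = sse(a, c1)
    converged = False
    for _ in range(max_iter):
        mu = a + c1 * d
        jac = np.column_stack([1.0 / mu, d / mu])
        jac = project_out(jac)
        f = np.log(mu)
        r = project_out(y - f)
        jtj = jac.T @ jac
        jtr = jac.T @ r
        try:
            step = np.linalg.solve(jtj + 1e-10 * np.eye(2), jtr)
        except np.linalg.LinAlgError:
            break
        if np.abs(step).max() < 1e-12 * (1 + abs(a)):
            converged = True
            break
        alpha = 1.0
        improved = False
        for _ in range(40):
            a_new, c1_new = a + alpha * step[0], c1 + alpha * step[1]
            if feasible(a_new, c1_new):
                new_sse, _ = sse(a_new, c1_new)
                if new_sse < cur_sse - 1e-16:
                    a, c1, cur_sse = a_new, c1_new, new_sse
                    improved = True
                    break
            alpha *= 0.5
        if not improved:
            converged = True
            break

    lrt = n * np.log(max(sse0, 1e-300) / max(cur_sse, 1e-300))
    p = float(stats.chi2.sf(max(lrt, 0.0), 1))
    c0 = max(a - 1.0, 1e-12)  # back to the TPM scale
    ratio = (c0 + 2.0 * c1) / c0
    cap = np.log2(100.0)
    log2_afc = float(np.clip(np.log2(max(ratio, 1e-12)), -cap, cap))
    return AfcFit(gene_id, variant_id, float(c0), float(c1), log2_afc, p, converged)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (one correction family)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def trans_scan(
    expr_int: pd.DataFrame,
    genotypes,
    covariates: pd.DataFrame | None,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Same linear model as cis_scan restricted to cross-chromosome pairs.

    BH correction is applied within the trans family only.
    """
    samples = list(expr_int.columns)
    n = len(samples)
    cov = None if covariates is None else covariates.loc[samples].to_numpy(float)
    k_cov = 0 if cov is None else cov.shape[1]
    df = n - k_cov - 2
    if df < 1:
        raise ValueError("not enough samples for the covariate count")

    e_res = residualize(expr_int.to_numpy(float), cov)
    g_res = residualize(genotypes.dosages.loc[samples].to_numpy(float).T, cov)
    e_norm = np.sqrt((e_res**2).sum(axis=1))
    g_norm = np.sqrt((g_res**2).sum(axis=1))
    e_norm[e_norm == 0] = np.inf
    g_norm[g_norm == 0] = np.inf

    r = (e_res / e_norm[:, None]) @ (g_res / g_norm[:, None]).T
    gene_chrom = annotation.loc[expr_int.index, "chrom"].astype(str).to_numpy()
    var_chrom = genotypes.variants["chrom"].astype(str).to_numpy()
    cross = gene_chrom[:, None] != var_chrom[None, :]

    gi, vi = np.nonzero(cross)
    t, p = _corr_to_pt(r[gi, vi], df)
    out = pd.DataFrame(
        {
            "gene_id": np.asarray(expr_int.index)[gi],
            "variant_id": np.asarray(genotypes.variant_ids)[vi],
            "t": t,
            "p": p,
        }
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["pos"] = out["variant_id"].map(genotypes.variants["pos"]).astype(int)
    out["variant_chrom"] = out["variant_id"].map(
        genotypes.variants["chrom"].astype(str)
    )
    return out


def trans_clump(
    assocs: pd.DataFrame, q_max: float = 0.1, region_bp: int = 1_000_000
) -> pd.DataFrame:
    """One representative variant per (gene, region) among significant hits.

    For each gene, significant variants are visited in ascending p; a
    variant joins an existing region if on the same chromosome and within
    ``region_bp`` of that region's representative, otherwise it seeds a
    new region.  Representatives (the first, lowest-p member) are returned
    with a ``region_id`` and the gene's region count.
    """
    sig = assocs[assocs["q"] < q_max]
    reps = []
    for gene, sub in sig.groupby("gene_id", sort=True):
        sub = sub.sort_values("p", kind="mergesort")
        regions: list[dict] = []
        for _, row in sub.iterrows():
            placed = False
            for reg in regions:
                if (
                    row["variant_chrom"] == reg["chrom"]
                    and abs(int(row["pos"]) - reg["pos"]) <= region_bp
                ):
                    placed = True
                    break
            if not placed:
                regions.append(
                    {"chrom": row["variant_chrom"], "pos": int(row["pos"]),
                     "row": row}
                )
        for i, reg in enumerate(regions):
            rep = reg["row"].copy()
            rep["region_id"] = f"{gene}:r{i + 1}"
            rep["n_regions"] = len(regions)
            reps.append(rep)
    return pd.DataFrame(reps).reset_index(drop=True) if reps else pd.DataFrame(
        columns=list(assocs.columns) + ["region_id", "n_regions"]
    )


def trans_flags(
    clumped: pd.DataFrame,
    crossmap_pairs: pd.DataFrame | None,
    annotation: pd.DataFrame,
    max_regions: int = 2,
) -> pd.DataFrame:
    """Quality flags for clumped trans associations.

    Flags: ``crossmap`` (target gene in a cross-mappability pair),
    ``multi_region`` (gene with more than ``max_regions`` significant
    regions), ``no_symbol`` (missing gene symbol), ``pseudogene`` (biotype
    contains 'pseudogene').  ``high_quality`` iff no flags.
    """
    risky: set[str] = set()
    if crossmap_pairs is not None and len(crossmap_pairs):
        risky = set(crossmap_pairs.iloc[:, 0]) | set(crossmap_pairs.iloc[:, 1])
    out = clumped.copy()
    flags_col = []
    for _, row in out.iterrows():
        gene = row["gene_id"]
        flags = []
        if gene in risky:
            flags.append("crossmap")
        if int(row.get("n_regions", 1)) > max_regions:
            flags.append("multi_region")
        symbol = annotation.at[gene, "symbol"] if gene in annotation.index else ""
        if symbol is None or (isinstance(symbol, float) and np.isnan(symbol)) or \
                str(symbol).strip() == "":
            flags.append("no_symbol")
        biotype = str(annotation.at[gene, "biotype"]) if gene in annotation.index else ""
        if "pseudogene" in biotype:
            flags.append("pseudogene")
        flags_col.append(",".join(flags))
    out["flags"] = flags_col
    out["high_quality"] = [f == "" for f in flags_col]
    return out
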