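"""Bulk RNA-seq count-matrix analysis for the LPS vs IL-4 contrast.

The workflow starts from a genes x samples integer count matrix with
group labels (PBS / LPS / IL4) and covers:

* CPM / log2CPM with a library-size-adjusted prior count, and FPKM;
* the two expression filters (CPM > 0.1 in >= 3 samples; group-mean
  log2CPM > 0 in LPS or IL-4);
* TMM (trimmed mean of M-values) between-sample normalization factors;
* a precision-weighted moderated differential-expression test: per-gene
  linear models on log2CPM with observation weights from a fitted
  mean-variance trend and empirical-Bayes shrinkage of residual
  variances toward an abundance-dependent prior;
* Benjamini-Hochberg FDR and the FDR < 0.05 / |log2FC| > 1 thresholds;
* IL-4-referenced z-scores, leading-log-fold-change MDS, average-linkage
  hierarchical clustering, cell-type signature overlap ratios, and
  hypergeometric gene-set enrichment against a user-supplied background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import linkage
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "cpm",
    "log2cpm",
    "filter_min_cpm",
    "tmm_norm_factors",
    "filter_group_mean",
    "de_test",
    "bh_adjust",
    "apply_de_thresholds",
    "zscore_vs_reference",
    "fpkm",
    "mds_coordinates",
    "signature_overlap_ratio",
    "hcluster",
    "enrich_hypergeometric",
    "read_gmt",
]


@dataclass
class CountMatrix:
    """Genes x samples integer counts with group labels and TMM factors."""

    counts: pd.DataFrame
    groups: pd.Series
    norm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integers")
        if list(self.groups.index) != list(self.counts.columns):
            self.groups = self.groups.reindex(self.counts.columns)
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.groups.copy(),
                           self.norm_factors.copy())

    def subset_groups(self, keep: tuple[str, ...]) -> "CountMatrix":
        cols = self.groups[self.groups.isin(keep)].index
        return CountMatrix(self.counts[cols], self.groups[cols],
                           self.norm_factors[cols])


# ---------------------------------------------------------------------------
# CPM / FPKM
# ---------------------------------------------------------------------------


def cpm(cm: CountMatrix, log: bool = False, prior: float = 2.0,
        normalized: bool = True) -> pd.DataFrame:
    """Counts per million: counts / (library size x TMM factor) x 1e6.

    With ``log=True`` returns log2CPM with a library-size-adjusted prior
    count: for sample j with effective library N_j, the prior added to
    counts is p_j = prior * N_j / mean(N), and
    log2CPM = log2((count + p_j) / (N_j + 2 p_j) * 1e6).
    """
    lib = cm.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    eff = lib * (cm.norm_factors.to_numpy(dtype=float) if normalized
                 else np.ones_like(lib))
    c = cm.counts.to_numpy(dtype=float)
    if not log:
        out = c / eff[None, :] * 1e6
    else:
        pj = prior * eff / eff.mean()
        out = np.log2((c + pj[None, :]) / (eff + 2 * pj)[None, :] * 1e6)
    return pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns)


def log2cpm(cm: CountMatrix, prior: float = 2.0,
            normalized: bool = True) -> pd.DataFrame:
    return cpm(cm, log=True, prior=prior, normalized=normalized)


def fpkm(cm: CountMatrix, lengths_kb: pd.Series,
         normalized: bool = True) -> pd.DataFrame:
    """Fragments per kilobase per million: CPM / gene length (kb)."""
    missing = cm.counts.index.difference(lengths_kb.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for {len(missing)} genes "
                         f"(e.g. {missing[0]!r})")
    lk = lengths_kb.reindex(cm.counts.index).to_numpy(dtype=float)
    if (lk <= 0).any():
        raise ValueError("gene lengths must be positive")
    return cpm(cm, normalized=normalized).div(lk, axis=0)


# ---------------------------------------------------------------------------
# expression filters
# ---------------------------------------------------------------------------


def filter_min_cpm(cm: CountMatrix, threshold: float = 0.1,
                   min_samples: int = 3) -> CountMatrix:
    """Keep genes with CPM > threshold in at least ``min_samples`` samples."""
    c = cpm(cm, normalized=False)
    keep = (c > threshold).sum(axis=1) >= min_samples
    return cm.subset_genes(cm.counts.index[keep])


def filter_group_mean(log2cpm_df: pd.DataFrame, groups: pd.Series,
                      which: tuple[str, ...] = ("LPS", "IL4"),
                      min_log2cpm: float = 0.0) -> pd.Index:
    """Genes whose group-mean log2CPM exceeds the minimum in any named group."""
    unknown = set(which) - set(groups.unique())
    if unknown:
        raise ValueError(f"unknown group(s): {sorted(unknown)}")
    keep = np.zeros(len(log2cpm_df), dtype=bool)
    for g in which:
        cols = groups[groups == g].index
        keep |= (log2cpm_df[cols].mean(axis=1) > min_log2cpm).to_numpy()
    return log2cpm_df.index[keep]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Single TMM factor (log2) between one sample and the reference column."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 0.0
    o, r = obs[pos], ref[pos]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic binomial variance of M as precision weight
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:  # identical relative profiles
        return 0.0
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_norm_factors(cm: CountMatrix, trim_m: float = 0.3,
                     trim_a: float = 0.05,
                     ref_column: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the one whose upper quartile of scaled counts
    is closest to the mean upper quartile.  For each sample, M-values
    (log ratios to the reference) and A-values (log abundances) are
    doubly trimmed (30% on M, 5% on A by default) and the factor is the
    precision-weighted mean of the surviving M-values.
    """
    c = cm.counts.to_numpy(dtype=float)
    if c.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = c.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("all-zero sample column")
    if ref_column is None:
        uq = np.array([np.quantile(col[col > 0] / n, 0.75) if (col > 0).any() else 0.0
                       for col, n in zip(c.T, lib)])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(cm.counts.columns).index(ref_column)
    log_f = np.array([
        _tmm_pair(c[:, j], c[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(c.shape[1])])
    factors = 2.0 ** log_f
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=cm.counts.columns, name="norm_factor")


# ---------------------------------------------------------------------------
# moderated differential expression (precision-weighted, voom-style)
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorized)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-8:
            break
    return y


def _fit_fdist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match s2 ~ s0^2 * F(df, d0); returns (d0, s0^2 scale ratio).

    Works on z = log(s2): E z and Var z have closed forms through digamma
    / trigamma; d0 solves trigamma(d0/2) = Var z - trigamma(df/2).
    Returns (inf, exp(mean adjustment)) when residual variability vanishes.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e_z = z.mean()
    v_z = z.var(ddof=1) if len(z) > 1 else 0.0
    resid_var = v_z - special.polygamma(1, df / 2.0)
    if resid_var <= 0:
        d0 = np.inf
        log_s02 = e_z - (special.polygamma(0, df / 2.0) - np.log(df / 2.0))
    else:
        d0 = 2.0 * float(_trigamma_inverse(np.array([resid_var]))[0])
        log_s02 = (e_z - (special.polygamma(0, df / 2.0) - np.log(df / 2.0))
                   + (special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, float(np.exp(log_s02))


def _wls_per_gene(y: np.ndarray, x: np.ndarray, w: np.ndarray):
    """Weighted LS of y_g ~ [1, x] per gene (vectorized over genes).

    Returns (beta1, se1_unscaled, sigma2, df_resid) where the standard
    error of the contrast coefficient is se1_unscaled * sigma.
    """
    n = y.shape[1]
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    swy = (w * y).sum(axis=1)
    swxy = (w * x * y).sum(axis=1)
    det = sw * swxx - swx ** 2
    b1 = (sw * swxy - swx * swy) / det
    b0 = (swy - b1 * swx) / sw
    resid = y - b0[:, None] - b1[:, None] * x[None, :]
    df = n - 2
    sigma2 = (w * resid ** 2).sum(axis=1) / df
    se1_unscaled = np.sqrt(sw / det)
    return b1, se1_unscaled, sigma2, df


def de_test(cm: CountMatrix, group_a: str = "LPS", group_b: str = "IL4",
            prior: float = 0.5, span: float = 0.5,
            recompute_norm: bool = True) -> pd.DataFrame:
    """Moderated differential expression, ``group_a`` vs ``group_b``.

    Positive log2FC means higher in ``group_a`` (default: up in LPS
    relative to IL-4).  The test is a precision-weighted per-gene linear
    model on log2CPM: a lowess mean-variance trend of sqrt residual
    standard deviation against average log2 count assigns each
    observation a weight 1/trend^4; weighted least squares gives the
    coefficient, and residual variances are shrunk by empirical Bayes
    toward an abundance-dependent (lowess) prior before forming
    moderated t statistics.  Returns a DETable DataFrame with columns
    (gene_id, log2fc, ave_log2cpm, t, p, fdr, passes_fc_filter).
    """
    sub = cm.subset_groups((group_a, group_b))
    na = int((sub.groups == group_a).sum())
    nb = int((sub.groups == group_b).sum())
    if na < 2 or nb < 2:
        raise ValueError("need at least two samples per group")
    if recompute_norm:
        sub.norm_factors = tmm_norm_factors(sub)
    x = (sub.groups == group_a).to_numpy(dtype=float)

    lib = (sub.library_sizes.to_numpy(dtype=float)
           * sub.norm_factors.to_numpy(dtype=float))
    counts = sub.counts.to_numpy(dtype=float)
    y = np.log2((counts + prior) / (lib + 1.0)[None, :] * 1e6)

    # first pass: unweighted fit for the mean-variance trend
    w0 = np.ones_like(y)
    b1, se_u, sigma2, df = _wls_per_gene(y, x, w0)
    b0 = (y - b1[:, None] * x[None, :]).mean(axis=1)
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(np.sqrt(sigma2))
    order = np.argsort(sx)
    trend = lowess(sy[order], sx[order], frac=span, return_sorted=False)
    lo_x, lo_y = sx[order], trend
    # piecewise-linear interpolation of the trend at fitted log-counts
    fitted = b0[:, None] + b1[:, None] * x[None, :]
    fitted_counts = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    sqrt_sd = np.interp(fitted_counts, lo_x, lo_y)
    w = 1.0 / np.clip(sqrt_sd, 1e-6, None) ** 4

    b1, se_u, sigma2, df = _wls_per_gene(y, x, w)

    # empirical-Bayes shrinkage toward an abundance-dependent prior
    ave = y.mean(axis=1)
    log_s2 = np.log(np.clip(sigma2, 1e-12, None))
    s2_trend = np.exp(lowess(log_s2[np.argsort(ave)], ave[np.argsort(ave)],
                             frac=span, return_sorted=False))
    s2_trend = s2_trend[np.argsort(np.argsort(ave))]
    d0, scale = _fit_fdist(sigma2 / s2_trend, df)
    s02 = scale * s2_trend
    if np.isinf(d0):
        s2_post = s02
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * sigma2) / (d0 + df)
        df_total = d0 + df
    t = b1 / (se_u * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    det = pd.DataFrame({
        "gene_id": sub.counts.index,
        "log2fc": b1,
        "ave_log2cpm": ave,
        "t": t,
        "p": p,
    }).set_index("gene_id", drop=False)
    det["fdr"] = bh_adjust(det["p"].to_numpy())
    det["passes_fc_filter"] = np.abs(det["log2fc"]) > 1.0
    return det


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def apply_de_thresholds(det: pd.DataFrame, fdr: float = 0.05,
                        abs_log2fc: float = 1.0) -> tuple[pd.Index, pd.Index]:
    """(significant, high-magnitude) gene sets: FDR < cut, plus |log2FC| > cut."""
    sig = det.index[det["fdr"] < fdr]
    high = det.index[(det["fdr"] < fdr) & (det["log2fc"].abs() > abs_log2fc)]
    return sig, high


# ---------------------------------------------------------------------------
# derived views
# ---------------------------------------------------------------------------


def zscore_vs_reference(expr: pd.DataFrame, groups: pd.Series,
                        reference_group: str = "IL4") -> pd.DataFrame:
    """Per-gene z-scores using the reference group's mean and sd only.

    Genes with zero reference standard deviation come back as NaN rows
    (flagged missing), not infinities.
    """
    ref_cols = groups[groups == reference_group].index
    if len(ref_cols) < 2:
        raise ValueError("reference group needs at least two samples")
    mu = expr[ref_cols].mean(axis=1)
    sd = expr[ref_cols].std(axis=1, ddof=1)
    z = expr.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z


def mds_coordinates(log2cpm_df: pd.DataFrame, top_n: int = 500,
                    n_dim: int = 2) -> pd.DataFrame:
    """Classical MDS of samples on leading-log-fold-change distances.

    The distance between two samples is the root-mean-square of the
    ``top_n`` largest absolute log2 expression differences between them;
    the distance matrix is embedded by classical (Torgerson) scaling.
    """
    x = log2cpm_df.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 3:
        raise ValueError("MDS needs at least three samples")
    k = min(top_n, x.shape[0])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (x[:, i] - x[:, j]) ** 2
            top = np.partition(diff2, len(diff2) - k)[-k:]
            d[i, j] = d[j, i] = np.sqrt(top.mean())
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ (d ** 2) @ j_mat
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:n_dim]
    coords = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))
    return pd.DataFrame(coords, index=log2cpm_df.columns,
                        columns=[f"dim{i + 1}" for i in range(n_dim)])


def signature_overlap_ratio(de_set, signatures: dict[str, set],
                            universe) -> pd.Series:
    """Per-signature fraction of (in-universe) signature genes that are DE.

    ratio = |signature ∩ de_set| / |signature ∩ universe|; a signature
    with no genes in the universe reports NaN (missing).
    """
    de = set(de_set)
    uni = set(universe)
    out = {}
    for name, genes in signatures.items():
        in_uni = set(genes) & uni
        out[name] = (len(in_uni & de) / len(in_uni)) if in_uni else np.nan
    return pd.Series(out, name="overlap_ratio")


def hcluster(matrix: pd.DataFrame, metric: str = "euclidean",
             method: str = "average") -> np.ndarray:
    """Agglomerative (UPGMA by default) linkage of the matrix rows."""
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("clustering needs at least two rows")
    if np.isnan(x).any():
        raise ValueError("matrix contains NaN rows")
    return linkage(x, method=method, metric=metric)


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    category_id: str
    overlap: int
    category_size: int
    query_size: int
    background_size: int
    p: float
    fdr: float = np.nan


def enrich_hypergeometric(query, categories: dict[str, set],
                          background) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query set per category.

    Categories are intersected with the background universe first; the
    p-value is P(overlap >= observed) under sampling |query| genes from
    the background without replacement.  BH adjustment across categories.
    Raises when the query is not a subset of the background.
    """
    bg = set(background)
    q = set(query)
    if not q <= bg:
        raise ValueError("query set must be a subset of the background")
    rows = []
    for name, genes in categories.items():
        cat = set(genes) & bg
        k = len(cat & q)
        # P(X >= k), X ~ Hypergeom(M=|bg|, K=|cat|, n=|q|)
        p = float(stats.hypergeom.sf(k - 1, len(bg), len(cat), len(q))) if cat else np.nan
        rows.append(dict(category_id=name, overlap=k, category_size=len(cat),
                         query_size=len(q), background_size=len(bg), p=p))
    df = pd.DataFrame(rows, columns=["category_id", "overlap", "category_size",
                                     "query_size", "background_size", "p"])
    ok = df["p"].notna()
    df["fdr"] = np.nan
    if ok.any():
        df.loc[ok, "fdr"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    return df


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
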