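"""Normalization, QC and stage-wise differential expression for count matrices.

Library-size normalization is trimmed-mean-of-M-values (TMM): per-gene
log-ratios against a reference sample are doubly trimmed (30% on M, 5% on
A) and combined by a precision-weighted mean; factors are rescaled to
multiply to 1.  A DESeq-style median-of-ratios alternative is provided
behind the same interface.

The differential test is a negative-binomial Wald test: per-gene
method-of-moments dispersions are shrunk 50/50 toward a mean-dispersion
trend fitted across all genes, the log2 fold change of factor-normalized
group means (pseudo-count 0.5 per group) is divided by its asymptotic
standard error, and p-values come from the normal tail with
Benjamini-Hochberg adjustment per comparison.  A gene is flagged DE when
|log2FC| > 1 and padj < 0.05.

Genes with fewer than 5 raw counts summed over the two compared groups are
not tested (method-of-moments dispersion is unstable there); they are
returned flagged with NaN p-values.  All-zero genes get p = 1, log2FC = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

DE_LFC_THRESHOLD = 1.0
DE_PADJ_THRESHOLD = 0.05
LOW_COUNT_MIN_TOTAL = 5


@dataclass(frozen=True)
class DegResult:
    gene_id: str
    stage_numerator: str
    stage_denominator: str
    log2fc: float
    pvalue: float
    padj: float
    is_de: bool
    direction: str  # up | down | none


def apply_de_rule(log2fc: float, padj: float) -> tuple[bool, str]:
    """The published DE decision rule: |log2FC| > 1 and padj < 0.05."""
    de = bool(abs(log2fc) > DE_LFC_THRESHOLD and not np.isnan(padj) and padj < DE_PADJ_THRESHOLD)
    direction = "none" if not de else ("up" if log2fc > 0 else "down")
    return de, direction


def tmm_factors(matrix: CountMatrix, ref_sample: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """TMM scaling factor per sample, rescaled so the factors multiply to 1."""
    counts = matrix.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with all-zero counts")
    samples = matrix.sample_ids
    if ref_sample is None:
        # reference: sample whose upper-quartile (of scaled counts) is closest to the mean
        with np.errstate(divide="ignore"):
            f75 = np.array([np.quantile(counts[:, i] / lib[i], 0.75) for i in range(len(samples))])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = samples.index(ref_sample)
    ref = counts[:, ref_idx]
    factors = np.ones(len(samples))
    for i in range(len(samples)):
        if i == ref_idx:
            continue
        obs = counts[:, i]
        keep = (obs > 0) & (ref > 0)
        if keep.sum() == 0:
            continue
        y, r = obs[keep], ref[keep]
        m = np.log2((y / lib[i]) / (r / lib[ref_idx]))
        a = 0.5 * np.log2((y / lib[i]) * (r / lib[ref_idx]))
        # asymptotic variance of M (delta method) -> inverse-variance weights
        v = (lib[i] - y) / (lib[i] * y) + (lib[ref_idx] - r) / (lib[ref_idx] * r)
        n = len(m)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rank_m = stats.rankdata(m, method="average")
        rank_a = stats.rankdata(a, method="average")
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep2.sum() == 0 or not np.isfinite(v[keep2]).all():
            continue
        w = 1.0 / v[keep2]
        factors[i] = 2.0 ** (np.sum(w * m[keep2]) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def median_of_ratios_factors(matrix: CountMatrix) -> pd.Series:
    """DESeq-style size factors rescaled to the TMM convention.

    Returned on the same scale as :func:`tmm_factors` (a multiplier of the
    library size, product 1), so the two are interchangeable downstream.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    logs = np.log(counts, where=counts > 0, out=np.full_like(counts, np.nan))
    ref = np.nanmean(np.where(counts > 0, logs, np.nan), axis=1)
    usable = np.isfinite(ref) & (counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene expressed in every sample")
    size = np.exp(np.median(logs[usable] - ref[usable, None], axis=0))
    factors = size / lib
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.sample_ids, name="mor_factor")


def effective_library_sizes(matrix: CountMatrix, factors: pd.Series) -> pd.Series:
    return matrix.library_sizes * factors


def cpm(matrix: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million of the effective (factor-scaled) library size."""
    if factors is None:
        factors = pd.Series(1.0, index=matrix.sample_ids)
    eff = matrix.library_sizes.to_numpy(dtype=float) * factors.reindex(matrix.sample_ids).to_numpy()
    return matrix.counts / eff * 1e6


def fpkm(matrix: CountMatrix, factors: pd.Series | None = None,
         gene_lengths: pd.Series | None = None) -> pd.DataFrame:
    """FPKM = CPM / (gene length in kb)."""
    lengths = gene_lengths if gene_lengths is not None else matrix.gene_lengths
    if lengths is None:
        raise ValueError("gene lengths required for FPKM")
    lengths = lengths.reindex(matrix.counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("zero or missing gene length")
    return cpm(matrix, factors).div(lengths / 1e3, axis=0)


def _log_expr(matrix: CountMatrix, factors: pd.Series | None) -> pd.DataFrame:
    """log2(FPKM + 1) when lengths are available, else log2(CPM + 1)."""
    if matrix.gene_lengths is not None and not matrix.gene_lengths.isna().any():
        values = fpkm(matrix, factors)
    else:
        values = cpm(matrix, factors)
    return np.log2(values + 1.0)


def replicate_correlation(matrix: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Sample x sample Pearson correlation of log2 expression.

    Zero-variance samples yield NaN for their pairs (reported as missing).
    """
    expr = _log_expr(matrix, factors)
    return expr.corr(method="pearson")


def pca_samples(matrix: CountMatrix, n_components: int = 2,
                factors: pd.Series | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on centered log2 expression (genes as features)."""
    n_samples = len(matrix.sample_ids)
    if n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    if n_components > n_samples - 1:
        raise ValueError("n_components exceeds samples - 1")
    x = _log_expr(matrix, factors).to_numpy().T
    x = x - x.mean(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    df = pd.DataFrame(coords, index=matrix.sample_ids,
                      columns=[f"PC{i + 1}" for i in range(n_components)])
    return df, pca.explained_variance_ratio_


def _fit_dispersion_trend(mu: np.ndarray, pooled_var: np.ndarray, inv_c: float,
                          mean_var_factor: float = 0.0, n_bins: int = 20) -> tuple[float, float]:
    """Mean-dispersion trend alpha(mu) = a0 + a1/mu from binned moments.

    Genes are binned by mean; per bin, alpha is recovered from the *bin
    averages* of the variance and mean (ratios of averages are far less
    noisy and less attenuated than averaging per-gene MoM ratios, whose
    mu^2 denominator is inflated at small replicate numbers).
    ``mean_var_factor`` is var(mu-hat)/var(count) of the pooled gene mean
    and corrects the residual E[mu-hat^2] > mu^2 inflation in the bins.
    """
    ok = (mu > 0) & np.isfinite(pooled_var)
    mu, pooled_var = mu[ok], pooled_var[ok]
    if mu.size < 10:
        return 0.01, 0.0
    order = np.argsort(mu)
    bins = np.array_split(order, min(n_bins, max(2, mu.size // 10)))
    bx, by = [], []
    for idx in bins:
        m_bar = mu[idx].mean()
        v_bar = pooled_var[idx].mean()
        m2_bar = (mu[idx] ** 2).mean() - mean_var_factor * v_bar
        alpha_bin = (v_bar - m_bar * inv_c) / max(m2_bar, 1e-12)
        bx.append(m_bar)
        by.append(max(alpha_bin, 0.0))
    x = 1.0 / np.asarray(bx)
    y = np.asarray(by)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0, a1 = float(coef[0]), float(coef[1])
    return max(a0, 1e-6), max(a1, 0.0)


def nb_deg_test(matrix: CountMatrix, stage_num: str, stage_den: str,
                factors: pd.Series | None = None) -> list[DegResult]:
    """NB Wald test of stage_num vs stage_den (one result per gene)."""
    for stage in (stage_num, stage_den):
        if stage not in matrix.design.stages:
            raise ValueError(f"stage {stage!r} absent from design")
    if factors is None:
        factors = tmm_factors(matrix)
    cols1 = matrix.design.samples_for_stage(stage_num)
    cols2 = matrix.design.samples_for_stage(stage_den)
    raw1 = matrix.counts[cols1].to_numpy(dtype=float)
    raw2 = matrix.counts[cols2].to_numpy(dtype=float)
    eff = effective_library_sizes(matrix, factors)
    c1 = eff[cols1].to_numpy() / 1e6  # per-million effective size factors
    c2 = eff[cols2].to_numpy() / 1e6
    q1 = raw1 / c1
    q2 = raw2 / c2
    m1 = q1.mean(axis=1)
    m2 = q2.mean(axis=1)
    n1, n2 = len(cols1), len(cols2)

    total_raw = raw1.sum(axis=1) + raw2.sum(axis=1)
    all_zero = total_raw == 0
    low_count = (total_raw < LOW_COUNT_MIN_TOTAL) & ~all_zero

    # method-of-moments dispersion on normalized counts, pooled within groups
    var1 = q1.var(axis=1, ddof=1)
    var2 = q2.var(axis=1, ddof=1)
    pooled_var = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
    mu_bar = 0.5 * (m1 + m2)
    inv_c = 0.5 * (np.mean(1.0 / c1) + np.mean(1.0 / c2))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (pooled_var - mu_bar * inv_c) / mu_bar**2
    alpha_raw = np.where(np.isfinite(alpha_raw), np.clip(alpha_raw, 0.0, 10.0), 0.0)
    tested = ~(all_zero | low_count)
    a0, a1 = _fit_dispersion_trend(mu_bar[tested], pooled_var[tested], inv_c,
                                   mean_var_factor=(1.0 / n1 + 1.0 / n2) / 4.0)
    alpha_trend = a0 + a1 / np.maximum(mu_bar, 1e-8)
    alpha = np.clip(0.5 * alpha_raw + 0.5 * alpha_trend, 1e-8, 10.0)

    p1, p2 = m1 + 0.5, m2 + 0.5
    log2fc = np.log2(p1 / p2)
    # var(log mean-hat) by the delta method on NB group means
    v1 = (p1 * np.mean(1.0 / c1) + alpha * p1**2) / n1 / p1**2
    v2 = (p2 * np.mean(1.0 / c2) + alpha * p2**2) / n2 / p2**2
    se_log2 = np.sqrt(v1 + v2) / np.log(2)
    z = log2fc / se_log2
    pvalues = 2.0 * stats.norm.sf(np.abs(z))
    pvalues = np.where(all_zero, 1.0, pvalues)
    log2fc = np.where(all_zero, 0.0, log2fc)
    pvalues = np.where(low_count, np.nan, pvalues)

    padj = np.full_like(pvalues, np.nan)
    mask = ~np.isnan(pvalues)
    if mask.any():
        padj[mask] = multipletests(pvalues[mask], method="fdr_bh")[1]

    results = []
    for i, gid in enumerate(matrix.gene_ids):
        de, direction = apply_de_rule(log2fc[i], padj[i])
        results.append(DegResult(gid, stage_num, stage_den, float(log2fc[i]),
                                 float(pvalues[i]), float(padj[i]), de, direction))
    return results


def stagewise_deg(matrix: CountMatrix,
                  factors: pd.Series | None = None) -> dict[tuple[str, str], list[DegResult]]:
    """NB Wald test for every consecutive stage comparison of the design."""
    if factors is None:
        factors = tmm_factors(matrix)
    return {
        (num, den): nb_deg_test(matrix, num, den, factors)
        for num, den in matrix.design.consecutive_comparisons
    }


def de_gene_sets(stagewise: dict[tuple[str, str], list[DegResult]]) -> dict[tuple[str, str], set[str]]:
    return {comp: {r.gene_id for r in results if r.is_de} for comp, results in stagewise.items()}


def updown_counts(stagewise: dict[tuple[str, str], list[DegResult]]) -> pd.DataFrame:
    rows = []
    for (num, den), results in stagewise.items():
        rows.append({
            "comparison": f"{num}_vs_{den}",
            "up": sum(r.direction == "up" for r in results),
            "down": sum(r.direction == "down" for r in results),
        })
    return pd.DataFrame(rows)


def venn_specific_degs(
    stagewise: dict[tuple[str, str], list[DegResult]],
) -> tuple[dict[tuple[str, str], int], dict[frozenset, int]]:
    """Exact set algebra over per-comparison DE gene sets.

    Returns (per-comparison unique counts, all 2^k - 1 region counts keyed
    by the frozenset of comparisons a region belongs to).
    """
    sets = de_gene_sets(stagewise)
    if len(sets) < 2:
        raise ValueError("Venn needs at least 2 comparisons")
    comps = list(sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(comps) + 1):
        for members in itertools.combinations(comps, r):
            inside = set.intersection(*(sets[c] for c in members))
            outside = set.union(set(), *(sets[c] for c in comps if c not in members))
            regions[frozenset(members)] = len(inside - outside)
    unique = {c: regions[frozenset([c])] for c in comps}
    return unique, regions
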