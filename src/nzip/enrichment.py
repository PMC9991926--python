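"""Neurite/soma enrichment statistics for tiled reporter libraries.

Counting noise in amplicon libraries is overdispersed relative to Poisson, so
per-tile enrichment is tested under a negative-binomial GLM with a log link
(variance mu + alpha*mu^2), in the style of the standard RNA-seq
differential-expression framework: median-of-ratios size factors enter as
offsets, per-tile method-of-moments dispersions are moderated toward a fitted
mean-dispersion trend (alpha(mu) = a0 + a1/mu), and the compartment
coefficient is tested with a Wald z statistic, BH-corrected across tiles.
Exact replication of any particular differential-expression tool is not
attempted; descriptive per-replicate log2 ratios with a 0.5 pseudocount are
reported alongside the model-based estimates.

Condition shifts (depolarization, knockdown) are tested on the
compartment x condition interaction coefficient of the same model; positive
values mean more neurite-enriched in the treatment condition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .read_processing import CountTable

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# normalization

def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no tile has positive counts in all samples")
    log_ratios = log_counts.loc[usable].sub(log_geomean[usable], axis=0)
    sf = np.exp(log_ratios.median(axis=0))
    if not np.isfinite(sf).all() or (sf <= 0).any():
        raise ValueError("degenerate size factors (all-zero sample?)")
    return sf


def normalize_counts(
    table: CountTable, per_million: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample by its total assigned reads (per-million by default);
    also returns median-of-ratios size factors used by the NB model."""
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    scale = 1e6 if per_million else totals.mean()
    normalized = table.counts.div(totals, axis=1) * scale
    return normalized, size_factors_median_of_ratios(table.counts)


# ---------------------------------------------------------------------------
# descriptive per-replicate ratios

def replicate_ratios(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 0.5,
    condition: str | None = None,
) -> pd.DataFrame:
    """Per-tile, per-replicate log2((neurite + pc) / (soma + pc)) on
    normalized counts.  Every replicate must contribute exactly one neurite
    and one soma sample."""
    meta = samples
    if condition is not None:
        meta = meta[meta["condition"] == condition]
    out = {}
    for (cond, rep), grp in meta.groupby(["condition", "replicate"], sort=True):
        neu = grp.index[grp["compartment"] == "neurite"]
        som = grp.index[grp["compartment"] == "soma"]
        if len(neu) != 1 or len(som) != 1:
            raise ValueError(
                f"replicate {rep!r} (condition {cond!r}) is not a neurite/soma pair"
            )
        label = f"{cond}:{rep}" if condition is None else str(rep)
        out[label] = np.log2(
            (normalized[neu[0]] + pseudocount) / (normalized[som[0]] + pseudocount)
        )
    return pd.DataFrame(out, index=normalized.index)


# ---------------------------------------------------------------------------
# dispersion estimation

def _mom_dispersions(
    counts: np.ndarray, sf: np.ndarray, groups: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tile method-of-moments dispersion pooled over design cells,
    computed on size-factor-normalized counts."""
    norm = counts / sf
    alphas = np.zeros(counts.shape[0])
    weights = np.zeros(counts.shape[0])
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        # E[var of normalized counts] ~ mu * mean(1/sf) + alpha * mu^2
        xi = np.mean(1.0 / sf[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - xi * m) / m**2
        ok = m > 0
        df = len(idx) - 1
        alphas[ok] += df * np.clip(a[ok], 0.0, None)
        weights[ok] += df
    with np.errstate(invalid="ignore"):
        alpha = np.where(weights > 0, alphas / np.maximum(weights, 1), 0.0)
    base_mean = norm.mean(axis=1)
    return alpha, base_mean


def _fit_dispersion_trend(alpha: np.ndarray, mean: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by iteratively reweighted least squares
    (gamma-type weights).  Falls back to a flat median trend."""
    use = (alpha > 1e-8) & (mean > 0)
    fallback = (float(np.median(alpha[alpha > 0])) if (alpha > 0).any() else 1e-8, 0.0)
    if use.sum() < 10:
        return fallback
    y = alpha[use]
    X = np.column_stack([np.ones(use.sum()), 1.0 / mean[use]])
    coef = np.array([np.median(y), 0.0])
    for _ in range(5):
        pred = np.clip(X @ coef, 1e-10, None)
        w = 1.0 / pred**2
        WX = X * w[:, None]
        try:
            coef_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        except np.linalg.LinAlgError:
            return fallback
        coef_new = np.clip(coef_new, 0.0, None)
        if np.allclose(coef_new, coef, rtol=1e-4):
            coef = coef_new
            break
        coef = coef_new
    if coef[0] <= 0 and coef[1] <= 0:
        return fallback
    return float(coef[0]), float(coef[1])


def estimate_dispersions(
    counts: np.ndarray,
    sf: np.ndarray,
    groups: list[np.ndarray],
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Moderated per-tile dispersions: method-of-moments estimates shrunk
    toward the fitted mean-dispersion trend, with weight
    prior_df / (prior_df + residual df).  With triplicate compartments the
    residual degrees of freedom are small, so moderation is strong."""
    alpha_mom, base_mean = _mom_dispersions(counts, sf, groups)
    a0, a1 = _fit_dispersion_trend(alpha_mom, base_mean)
    with np.errstate(divide="ignore"):
        trend = np.where(base_mean > 0, a0 + a1 / np.clip(base_mean, 1e-12, None), a0)
    resid_df = sum(max(len(g) - 1, 0) for g in groups)
    w = prior_df / (prior_df + max(resid_df, 1))
    alpha = (1 - w) * alpha_mom + w * trend
    alpha = np.clip(alpha, 1e-8, 10.0)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "alpha_mom": alpha_mom,
            "alpha_trend": trend,
            "alpha": alpha,
        }
    )


# ---------------------------------------------------------------------------
# NB Wald tests

def _wald_fit(y, X, alpha, offset, test_coef):
    """Fit one NB GLM and return (coefs, se, z, p, converged) for the tested
    coefficient (natural-log scale)."""
    fam = sm.families.NegativeBinomial(alpha=max(float(alpha), 1e-8))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
        coef = res.params[test_coef]
        se = res.bse[test_coef]
        if not (np.isfinite(coef) and np.isfinite(se) and se > 0):
            return np.nan, np.nan, np.nan, np.nan, False
        z = coef / se
        p = 2.0 * stats.norm.sf(abs(z))
        return coef, se, z, p, True
    except Exception:
        return np.nan, np.nan, np.nan, np.nan, False


def nb_wald_localization(
    table: CountTable,
    condition: str | None = None,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-tile neurite/soma enrichment: NB Wald test on the compartment
    coefficient, BH-adjusted across tiles.

    Returns a frame indexed by tile with log2fc, se (log2 scale), stat, p,
    padj, base_mean, per-tile dispersion, and convergence flag.  Requires at
    least two replicates per compartment.
    """
    meta = table.samples
    if condition is not None:
        meta = meta[meta["condition"] == condition]
    neurite = meta["compartment"] == "neurite"
    soma = meta["compartment"] == "soma"
    if neurite.sum() < 2 or soma.sum() < 2:
        raise ValueError("need >= 2 replicates per compartment")
    cols = list(meta.index)
    counts = table.counts[cols].to_numpy(dtype=float)
    sf = size_factors_median_of_ratios(table.counts[cols]).to_numpy()
    comp = neurite.loc[cols].to_numpy(dtype=float)
    groups = [np.where(comp == 0)[0], np.where(comp == 1)[0]]
    disp = estimate_dispersions(counts, sf, groups, prior_df=prior_df)
    X = np.column_stack([np.ones(len(cols)), comp])
    offset = np.log(sf)
    rows = []
    for i, tile in enumerate(table.counts.index):
        coef, se, z, p, ok = _wald_fit(counts[i], X, disp["alpha"].iat[i], offset, 1)
        rows.append((coef / LN2, se / LN2, z, p, ok))
    out = pd.DataFrame(
        rows, index=table.counts.index,
        columns=["log2fc", "se", "stat", "p", "converged"],
    )
    out["base_mean"] = disp["base_mean"].to_numpy()
    out["dispersion"] = disp["alpha"].to_numpy()
    out["padj"] = bh_adjust(out["p"])
    return out


def condition_shift_test(
    table: CountTable,
    condition_pair: tuple[str, str],
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Test whether the neurite/soma ratio of each tile differs between two
    conditions (compartment x condition interaction Wald test).

    ``condition_pair = (reference, treatment)``; positive delta_log2fc means
    the tile is more neurite-enriched under the treatment.
    """
    ref, treat = condition_pair
    meta = table.samples[table.samples["condition"].isin(condition_pair)]
    cols = list(meta.index)
    comp = (meta["compartment"] == "neurite").to_numpy(dtype=float)
    cond = (meta["condition"] == treat).to_numpy(dtype=float)
    for c, label in [(comp, "compartment"), (cond, "condition")]:
        if len(set(c)) != 2:
            raise ValueError(f"both levels of {label} required")
    for cv in (0.0, 1.0):
        for mv in (0.0, 1.0):
            if ((cond == cv) & (comp == mv)).sum() < 2:
                raise ValueError("need >= 2 replicates per compartment and condition")
    counts = table.counts[cols].to_numpy(dtype=float)
    sf = size_factors_median_of_ratios(table.counts[cols]).to_numpy()
    cells = [
        np.where((comp == mv) & (cond == cv))[0]
        for mv in (0.0, 1.0) for cv in (0.0, 1.0)
    ]
    disp = estimate_dispersions(counts, sf, cells, prior_df=prior_df)
    X = np.column_stack([np.ones(len(cols)), comp, cond, comp * cond])
    offset = np.log(sf)
    rows = []
    for i, tile in enumerate(table.counts.index):
        coef, se, z, p, ok = _wald_fit(counts[i], X, disp["alpha"].iat[i], offset, 3)
        rows.append((coef / LN2, se / LN2, z, p, ok))
    out = pd.DataFrame(
        rows, index=table.counts.index,
        columns=["delta_log2fc", "se", "stat", "p", "converged"],
    )
    out["base_mean"] = disp["base_mean"].to_numpy()
    out["padj"] = bh_adjust(out["p"])
    return out


# ---------------------------------------------------------------------------
# multiple testing, calling, group tests, QC

def bh_adjust(p_values) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.  NaN entries are
    excluded from the number of tests and returned as NaN."""
    p = np.asarray(p_values, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(adj, index=p_values.index)
    return adj


def call_localized_tiles(
    results: pd.DataFrame, lfc_min: float = 1.0, padj_max: float = 0.1
) -> pd.DataFrame:
    """Flag neurite-localized tiles: log2FC >= lfc_min and padj < padj_max."""
    out = results.copy()
    out["localized"] = (out["log2fc"] >= lfc_min) & (out["padj"] < padj_max)
    return out


def per_gene_summary(
    called: pd.DataFrame, gene_ids: pd.Series
) -> pd.DataFrame:
    """Per-gene count of localized tiles; ``gene_ids`` maps tile -> gene."""
    df = called.join(gene_ids.rename("gene_id"))
    grp = df.groupby("gene_id")["localized"]
    return pd.DataFrame(
        {"n_tiles": grp.size(), "n_localized": grp.sum().astype(int)}
    )


def group_shift_test(group_a, group_b) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum p comparing two groups of values.

    Exact enumeration when both groups have <= 25 observations and no ties;
    tie-corrected normal approximation otherwise.  Returns (p, method).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    if no_ties and a.size <= 25 and b.size <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue), method


def replicate_qc(
    table: CountTable, min_spearman: float = 0.85
) -> dict[str, pd.DataFrame]:
    """Pairwise Spearman correlation of raw counts between replicates within
    each compartment; warns when any pair falls below ``min_spearman``."""
    out = {}
    for comp, grp in table.samples.groupby("compartment"):
        cols = list(grp.index)
        mat = table.counts[cols].corr(method="spearman")
        out[comp] = mat
        if len(cols) >= 2:
            tri = mat.values[np.triu_indices(len(cols), k=1)]
            if (tri < min_spearman).any():
                warnings.warn(
                    f"{comp}: replicate Spearman correlation below "
                    f"{min_spearman} (min {tri.min():.3f})",
                    stacklevel=2,
                )
    return out


def gene_expression_qc(
    exon_counts: pd.Series,
    intron_counts: pd.Series,
    sense_counts: pd.Series,
    antisense_counts: pd.Series,
    min_exon_intron: float = 2.5,
    min_sense_antisense: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.Index:
    """Retain genes with clean exonic, sense-strand signal:
    log2(exon/intron) > 2.5 and log2(sense/antisense) > 2 (pseudocounted)."""
    ei = np.log2((exon_counts + pseudocount) / (intron_counts + pseudocount))
    sa = np.log2((sense_counts + pseudocount) / (antisense_counts + pseudocount))
    keep = (ei > min_exon_intron) & (sa > min_sense_antisense)
    return exon_counts.index[keep]
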