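"""Normalization, NB Wald enrichment, BH, Wilcoxon, QC filters."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from nzip.enrichment import (
    bh_adjust,
    call_localized_tiles,
    condition_shift_test,
    gene_expression_qc,
    group_shift_test,
    nb_wald_localization,
    normalize_counts,
    per_gene_summary,
    replicate_qc,
    replicate_ratios,
    size_factors_median_of_ratios,
)
from nzip.read_processing import CountTable
from nzip.simulate import SimConfig, simulate_counts, simulate_perturbation
from tests.conftest import make_truth


# --- normalization --------------------------------------------------------

def test_per_million_scaling(tiny_table):
    counts = tiny_table.counts.copy()
    counts["s_soma_1"] = [200, 1_999_700, 100]
    table = CountTable(counts, tiny_table.samples)
    norm, _ = normalize_counts(table)
    assert norm.loc["a", "s_soma_1"] == pytest.approx(100.0)


def test_identical_samples_equal_size_factors(tiny_table):
    counts = tiny_table.counts.copy()
    counts["s_soma_2"] = counts["s_soma_1"]
    sf = size_factors_median_of_ratios(counts)
    assert sf["s_soma_1"] == pytest.approx(sf["s_soma_2"])
    norm, _ = normalize_counts(CountTable(counts, tiny_table.samples))
    assert (norm["s_soma_1"] == norm["s_soma_2"]).all()


def test_size_factors_match_oracle(rng):
    counts = pd.DataFrame(rng.integers(1, 500, size=(40, 5)))
    # brute-force median-of-ratios
    logg = np.log(counts).mean(axis=1)
    expected = [
        float(np.exp(np.median(np.log(counts[j]) - logg))) for j in counts.columns
    ]
    sf = size_factors_median_of_ratios(counts)
    assert np.allclose(sf.to_numpy(), expected)


def test_all_zero_sample_rejected(tiny_table):
    counts = tiny_table.counts.copy()
    counts["s_soma_1"] = 0
    with pytest.raises(ValueError):
        normalize_counts(CountTable(counts, tiny_table.samples))


# --- replicate ratios -----------------------------------------------------

def test_replicate_ratio_pseudocount_arithmetic(tiny_table):
    norm = pd.DataFrame(
        {"s_soma_1": [49.5, 0.0], "n_neu_1": [99.5, 0.0]},
        index=["x", "y"],
    )
    samples = tiny_table.samples.loc[["s_soma_1", "n_neu_1"]]
    ratios = replicate_ratios(norm, samples)
    assert ratios.loc["x"].iloc[0] == pytest.approx(1.0)
    assert ratios.loc["y"].iloc[0] == pytest.approx(0.0)


def test_replicate_ratios_match_formula(rng, tiny_table):
    norm = pd.DataFrame(
        rng.uniform(0, 200, size=(20, 4)),
        columns=tiny_table.counts.columns,
    )
    ratios = replicate_ratios(norm, tiny_table.samples)
    for rep in ("1", "2"):
        neu = f"n_neu_{rep}"
        som = f"s_soma_{rep}"
        expected = np.log2((norm[neu] + 0.5) / (norm[som] + 0.5))
        assert np.allclose(ratios[f"control:{rep}"], expected)


def test_unpaired_replicate_rejected(tiny_table):
    samples = tiny_table.samples.drop("n_neu_2")
    norm = tiny_table.counts.drop(columns="n_neu_2").astype(float)
    with pytest.raises(ValueError):
        replicate_ratios(norm, samples)


# --- BH -------------------------------------------------------------------

def bh_oracle(p):
    """Literal step-up construction."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_worked_examples():
    assert np.allclose(bh_adjust([0.05, 0.05, 0.05]), [0.05] * 3)
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_matches_oracle_and_is_permutation_invariant(rng):
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        adj = bh_adjust(p)
        assert np.allclose(adj, bh_oracle(p))
        perm = rng.permutation(len(p))
        assert np.allclose(bh_adjust(p[perm]), np.asarray(adj)[perm])
        # monotone in p
        order = np.argsort(p)
        assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


def test_bh_excludes_nan_from_m():
    adj = bh_adjust(pd.Series([0.01, np.nan, 0.04]))
    assert np.isnan(adj.iloc[1])
    assert np.allclose(adj.dropna(), bh_oracle([0.01, 0.04]))


# --- Wilcoxon rank-sum ----------------------------------------------------

def rank_sum_exact_oracle(a, b):
    """Exhaustive enumeration of group assignments (no ties)."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n = len(a)
    mu = n * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(pooled, n):
        w = sum(ranks[v] for v in combo)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


def test_wilcoxon_extreme_groups_exact():
    p, method = group_shift_test([1, 2, 3], [4, 5, 6])
    assert method == "exact"
    assert p == pytest.approx(0.1)


def test_wilcoxon_identical_groups():
    p, _ = group_shift_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert p > 0.65


def test_wilcoxon_matches_permutation_oracle(rng):
    for _ in range(15):
        na, nb = int(rng.integers(3, 8)), int(rng.integers(3, 8))
        vals = rng.permutation(100)[: na + nb].astype(float)
        a, b = list(vals[:na]), list(vals[na:])
        p, method = group_shift_test(a, b)
        assert method == "exact"
        assert p == pytest.approx(rank_sum_exact_oracle(a, b))
    with pytest.raises(ValueError):
        group_shift_test([], [1.0])


# --- NB Wald localization -------------------------------------------------

def test_identical_columns_give_zero_lfc(small_count_table):
    """Tiles with identical counts in every sample: log2FC = 0, p ~ 1."""
    table, _ = small_count_table
    col = table.counts.iloc[:, 0]
    counts = pd.concat([col] * 6, axis=1)
    counts.columns = table.counts.columns[: 6]
    res = nb_wald_localization(CountTable(counts, table.samples))
    assert res["log2fc"].abs().max() < 1e-6
    assert (res["p"].dropna() > 0.99).all()


def test_model_lfc_agrees_with_pseudocount_ratios(small_count_table):
    """NB model log2FC and the mean per-replicate pseudocount ratio agree
    within 0.25 for well-covered tiles."""
    table, _ = small_count_table
    res = nb_wald_localization(table)
    norm, _ = normalize_counts(table, per_million=False)
    ratios = replicate_ratios(norm, table.samples).mean(axis=1)
    well = res["base_mean"] >= 100
    assert well.sum() > 100
    assert (res.loc[well, "log2fc"] - ratios[well]).abs().max() < 0.25


def test_effect_tiles_detected(small_count_table):
    table, truth = small_count_table
    res = call_localized_tiles(nb_wald_localization(table))
    eff = truth["effect"].to_numpy()
    assert res["localized"][eff == 2.0].mean() > 0.8
    assert res["localized"][eff == 0.0].mean() < 0.05


def test_per_gene_summary(small_count_table):
    table, truth = small_count_table
    res = call_localized_tiles(nb_wald_localization(table))
    genes = pd.Series(
        ["geneA"] * 150 + ["geneB"] * 150, index=table.counts.index
    )
    summary = per_gene_summary(res, genes)
    assert summary.loc["geneA", "n_localized"] > 0
    assert summary["n_tiles"].sum() == 300


def test_requires_two_replicates_per_compartment(tiny_table):
    samples = tiny_table.samples.copy()
    samples.loc["n_neu_2", "compartment"] = "soma"
    with pytest.raises(ValueError):
        nb_wald_localization(CountTable(tiny_table.counts, samples))


def test_matches_pydeseq2_reference(small_count_table):
    """Independent cross-check against the DESeq2 reimplementation: the
    group-mean log2FC is estimator-identical and calls agree."""
    import logging

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    table, _ = small_count_table
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logging.disable(logging.WARNING)
        dds = DeseqDataSet(
            counts=table.counts.T,
            metadata=table.samples[["compartment"]],
            design="~compartment",
            quiet=True,
        )
        dds.deseq2()
        ds = DeseqStats(
            dds, contrast=["compartment", "neurite", "soma"], quiet=True
        )
        ds.summary()
        logging.disable(logging.NOTSET)
    ref = ds.results_df
    mine = nb_wald_localization(table)
    assert (ref["log2FoldChange"] - mine["log2fc"]).abs().median() < 0.01
    agree = ((ref["padj"] < 0.1) == (mine["padj"] < 0.1)).mean()
    assert agree > 0.9


# --- condition shift ------------------------------------------------------

def make_two_condition_table(attenuation, seed=3, n=200):
    effects = np.zeros(n)
    effects[:30] = 2.0
    truth = make_truth(n, effects=effects, seed=seed)
    cfg = SimConfig(depth=2e5, dispersion=0.05, replicates=3, seed=seed)
    rng = np.random.default_rng(seed)
    t1 = simulate_counts(truth, cfg, rng, condition="control")
    t2 = simulate_counts(
        simulate_perturbation(truth, attenuation), cfg, rng, condition="kd"
    )
    counts = pd.concat([t1.counts, t2.counts], axis=1)
    samples = pd.concat([t1.samples, t2.samples])
    return CountTable(counts, samples), effects


def test_identical_conditions_give_null_shift():
    table, _ = make_two_condition_table(attenuation=1.0)
    res = condition_shift_test(table, ("control", "kd"))
    assert abs(res["delta_log2fc"].median()) < 0.1
    assert (res["padj"] < 0.05).mean() < 0.05


def test_knockdown_shift_detected():
    table, effects = make_two_condition_table(attenuation=0.25)
    res = condition_shift_test(table, ("control", "kd"))
    hit = res["padj"] < 0.05
    assert hit[effects == 2.0].mean() > 0.7
    assert (res["delta_log2fc"][effects == 2.0] < 0).all()
    assert hit[effects == 0.0].mean() < 0.05


# --- QC -------------------------------------------------------------------

def test_replicate_qc_extremes(tiny_table):
    counts = tiny_table.counts.copy()
    counts["s_soma_2"] = counts["s_soma_1"]
    mats = replicate_qc(CountTable(counts, tiny_table.samples))
    assert mats["soma"].loc["s_soma_1", "s_soma_2"] == pytest.approx(1.0)
    counts = pd.DataFrame(
        {"s_soma_1": [1, 2, 3, 4], "s_soma_2": [4, 3, 2, 1],
         "n_neu_1": [1, 2, 3, 4], "n_neu_2": [1, 2, 3, 4]},
    )
    samples = tiny_table.samples.set_axis(counts.columns, axis=0)
    with pytest.warns(UserWarning):
        mats = replicate_qc(CountTable(counts, samples))
    assert mats["soma"].iloc[0, 1] == pytest.approx(-1.0)


def test_replicate_qc_matches_spearman(rng):
    counts = pd.DataFrame(
        rng.integers(0, 1000, size=(60, 4)),
        columns=["a", "b", "c", "d"],
    )
    samples = pd.DataFrame(
        {"compartment": ["soma"] * 4, "replicate": list("1234"),
         "condition": ["control"] * 4},
        index=counts.columns,
    )
    from scipy.stats import spearmanr

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mats = replicate_qc(CountTable(counts, samples))
    expected = spearmanr(counts["a"], counts["b"]).statistic
    assert mats["soma"].loc["a", "b"] == pytest.approx(expected)


def test_gene_expression_qc():
    exon = pd.Series({"clean": 1000, "intronic": 500, "antisense": 800})
    intron = pd.Series({"clean": 10, "intronic": 500, "antisense": 8})
    sense = pd.Series({"clean": 1000, "intronic": 500, "antisense": 100})
    anti = pd.Series({"clean": 10, "intronic": 5, "antisense": 90})
    kept = gene_expression_qc(exon, intron, sense, anti)
    assert list(kept) == ["clean"]


def test_gene_expression_qc_matches_oracle(rng):
    n = 80
    idx = [f"g{i}" for i in range(n)]
    cols = [pd.Series(rng.integers(0, 2000, size=n), index=idx) for _ in range(4)]
    kept = set(gene_expression_qc(*cols))
    expected = {
        g for g in idx
        if np.log2((cols[0][g] + 0.5) / (cols[1][g] + 0.5)) > 2.5
        and np.log2((cols[2][g] + 0.5) / (cols[3][g] + 0.5)) > 2.0
    }
    assert kept == expected
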