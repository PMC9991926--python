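"""Motif scanners and motif-localization association analyses.

Scanned features:

* miRNA seed sites — a 7mer site is the reverse complement (DNA) of miRNA
  positions 2-8; the 8mer appends an A opposite position 1.  For the let-7
  family the 7mer is CTACCTC and the 8mer CTACCTCA.  Occurrences are counted
  allowing overlap.
* (AU)n — the largest n such that ("AT")^n occurs as an exact substring;
  any interruption resets the run.
* CPE — a configurable U-rich consensus (default TTTTAT), flagged anywhere
  in the sequence and within its last 30 nt, where it is most active.

Association analyses group tiles or transcripts by motif content and compare
their neurite/soma enrichment distributions (rank-sum for groups, t-test per
miRNA family).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import group_shift_test

LET7_SITE7 = "CTACCTC"
CPE_DEFAULT = ("TTTTAT",)

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def revcomp_dna(seq: str) -> str:
    """Reverse complement, RNA accepted (U treated as T), DNA returned."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedEntry:
    family: str
    seed: str   # RNA, miRNA positions 2-8
    site7: str  # DNA, reverse complement of the seed
    site8: str  # site7 + "A"


def build_seed_sites(mirna_table: pd.DataFrame) -> list[SeedEntry]:
    """Seed-site entries from a table of mature miRNA sequences
    (columns ``family`` and ``sequence``, RNA or DNA).

    Family members with identical positions 2-8 collapse into a single
    entry; the collapsed family name joins the member names with '/'.
    """
    by_site: dict[str, dict] = {}
    for family, seq in zip(mirna_table["family"], mirna_table["sequence"]):
        seq = str(seq).strip().upper()
        if len(seq) < 8:
            raise ValueError(f"{family}: mature sequence shorter than 8 nt")
        seed = seq[1:8].replace("T", "U")
        site7 = revcomp_dna(seed)
        entry = by_site.setdefault(site7, {"families": [], "seed": seed})
        if family not in entry["families"]:
            entry["families"].append(family)
    return [
        SeedEntry(
            family="/".join(v["families"]),
            seed=v["seed"],
            site7=site7,
            site8=site7 + "A",
        )
        for site7, v in by_site.items()
    ]


def count_sites(sequence: str, site: str) -> int:
    """Number of (possibly overlapping) occurrences of ``site``."""
    if not site:
        raise ValueError("empty site")
    sequence = sequence.upper()
    n = 0
    pos = sequence.find(site)
    while pos >= 0:
        n += 1
        pos = sequence.find(site, pos + 1)
    return n


def max_au_repeat(sequence: str) -> int:
    """Largest n with ("AT")^n as an exact substring of the sequence."""
    sequence = sequence.upper()
    n = 0
    while "AT" * (n + 1) in sequence:
        n += 1
    return n


def scan_cpe(
    sequence: str, last_n: int = 30, motifs: tuple[str, ...] = CPE_DEFAULT
) -> tuple[bool, bool]:
    """(CPE anywhere, CPE within the last ``last_n`` bases)."""
    sequence = sequence.upper()
    anywhere = any(m in sequence for m in motifs)
    tail = sequence[-last_n:]
    return anywhere, any(m in tail for m in motifs)


def annotate_sequences(
    sequences: pd.Series | dict,
    seed_entries: list[SeedEntry] | None = None,
    cpe_motifs: tuple[str, ...] = CPE_DEFAULT,
    cpe_last_n: int = 30,
) -> pd.DataFrame:
    """Motif annotation table: per-family 7mer counts, let-7 7mer/8mer
    counts, maximal (AU)n and CPE flags, one row per sequence."""
    if isinstance(sequences, dict):
        sequences = pd.Series(sequences)
    seed_entries = seed_entries or []
    rows = []
    for sid, seq in sequences.items():
        seq = str(seq).upper().replace("U", "T")
        row: dict = {"sequence_id": sid}
        for entry in seed_entries:
            row[f"sites7_{entry.family}"] = count_sites(seq, entry.site7)
        row["let7_sites7"] = count_sites(seq, LET7_SITE7)
        row["let7_sites8"] = count_sites(seq, LET7_SITE7 + "A")
        row["max_au"] = max_au_repeat(seq)
        anywhere, last = scan_cpe(seq, last_n=cpe_last_n, motifs=cpe_motifs)
        row["cpe_anywhere"] = anywhere
        row[f"cpe_last{cpe_last_n}"] = last
        rows.append(row)
    return pd.DataFrame(rows).set_index("sequence_id")


# ---------------------------------------------------------------------------
# association analyses

def _let7_grouping(annotations: pd.DataFrame) -> pd.Series:
    g = pd.Series("no site", index=annotations.index)
    g[annotations["let7_sites7"] >= 1] = ">=1 7mer"
    g[annotations["let7_sites8"] >= 1] = ">=1 8mer"
    return g


def _let7_count_grouping(annotations: pd.DataFrame) -> pd.Series:
    n = annotations["let7_sites7"]
    return pd.Series(
        np.select([n == 0, n == 1], ["0 sites", "1 site"], ">1 site"),
        index=annotations.index,
    )


def _au_grouping(annotations: pd.DataFrame, threshold: int = 6) -> pd.Series:
    au = annotations["max_au"]
    return pd.Series(
        np.where(au >= threshold, f"(AU){threshold}+", f"(AU)0-{threshold - 1}"),
        index=annotations.index,
    )


GROUPINGS = {
    "let7": _let7_grouping,
    "let7_count": _let7_count_grouping,
    "au": _au_grouping,
}


def group_localization_cdf(
    annotations: pd.DataFrame,
    enrichment_values: pd.Series,
    grouping: str = "let7",
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Group enrichment values by motif content and compare groups pairwise.

    ``grouping`` is one of 'let7' (no site / >=1 7mer / >=1 8mer),
    'let7_count' (0 / 1 / >1 sites) or 'au' ((AU)0-5 vs (AU)6+).  Returns
    CDF-ready value vectors per non-empty group and a frame of pairwise
    two-sided rank-sum p-values.
    """
    if grouping not in GROUPINGS:
        raise KeyError(f"unknown grouping {grouping!r}; one of {sorted(GROUPINGS)}")
    labels = GROUPINGS[grouping](annotations)
    shared = annotations.index.intersection(enrichment_values.dropna().index)
    labels = labels.loc[shared]
    values = enrichment_values.loc[shared]
    groups: dict[str, np.ndarray] = {}
    for name in labels.unique():
        vals = values[labels == name].to_numpy()
        if vals.size == 0:
            warnings.warn(f"group {name!r} empty; dropped", stacklevel=2)
            continue
        groups[name] = np.sort(vals)
    comparisons = []
    for a, b in itertools.combinations(sorted(groups), 2):
        p, method = group_shift_test(groups[a], groups[b])
        comparisons.append(
            {
                "group_a": a, "group_b": b,
                "n_a": groups[a].size, "n_b": groups[b].size,
                "median_a": float(np.median(groups[a])),
                "median_b": float(np.median(groups[b])),
                "p": p, "method": method,
            }
        )
    return groups, pd.DataFrame(comparisons)


def family_enrichment_volcano(
    annotations: pd.DataFrame,
    enrichment_values: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-miRNA-family mean enrichment of site-bearing tiles and a
    two-sided t-test against site-free tiles.

    Families with fewer than two tiles on either side of the contrast are
    skipped with a warning.  ``significant`` marks p < alpha, with the
    direction (neurite/soma) given by the sign of the mean difference.
    """
    site_cols = [c for c in annotations.columns if c.startswith("sites7_")]
    shared = annotations.index.intersection(enrichment_values.dropna().index)
    ann = annotations.loc[shared]
    vals = enrichment_values.loc[shared]
    rows = []
    for col in site_cols:
        family = col[len("sites7_"):]
        has = ann[col] >= 1
        a = vals[has].to_numpy()
        b = vals[~has].to_numpy()
        if a.size < 2 or b.size < 2:
            warnings.warn(f"family {family!r}: insufficient contrast; skipped",
                          stacklevel=2)
            continue
        t, p = stats.ttest_ind(a, b)
        diff = float(a.mean() - b.mean())
        rows.append(
            {
                "family": family,
                "n_sites": int(has.sum()),
                "mean_log2fc_sites": float(a.mean()),
                "mean_log2fc_no_sites": float(b.mean()),
                "mean_diff": diff,
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
                "direction": "neurite" if diff > 0 else "soma",
            }
        )
    return pd.DataFrame(rows)


def endogenous_localization(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    transcript_to_gene: pd.Series,
    annotations: pd.DataFrame | None = None,
    min_total_tpm: float = 10.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Transcript-level neurite/soma localization from TPM tables.

    Keeps the most abundant isoform per gene (highest summed average TPM
    across compartments, ties broken by transcript id), requires a summed
    average TPM of at least ``min_total_tpm``, and computes
    log2((mean neurite + 1) / (mean soma + 1)).  Motif annotations (indexed
    by transcript) are joined when provided.
    """
    for comp in ("neurite", "soma"):
        if (samples["compartment"] == comp).sum() == 0:
            raise ValueError(f"no {comp} samples in metadata")
    neu_cols = samples.index[samples["compartment"] == "neurite"]
    som_cols = samples.index[samples["compartment"] == "soma"]
    mean_neu = tpm[list(neu_cols)].mean(axis=1)
    mean_som = tpm[list(som_cols)].mean(axis=1)
    total = mean_neu + mean_som
    df = pd.DataFrame(
        {
            "gene_id": transcript_to_gene.reindex(tpm.index),
            "mean_tpm_neurite": mean_neu,
            "mean_tpm_soma": mean_som,
            "total_tpm": total,
        }
    )
    df = df.dropna(subset=["gene_id"])
    df = df.sort_values(["gene_id", "total_tpm"], ascending=[True, False])
    df = (
        df.reset_index()
        .rename(columns={"index": "transcript_id"})
        .sort_values(["gene_id", "total_tpm", "transcript_id"],
                     ascending=[True, False, True])
        .drop_duplicates("gene_id", keep="first")
        .set_index("transcript_id")
    )
    df = df[df["total_tpm"] >= min_total_tpm]
    df["log2_ratio"] = np.log2(
        (df["mean_tpm_neurite"] + pseudocount) / (df["mean_tpm_soma"] + pseudocount)
    )
    if annotations is not None:
        df = df.join(annotations, how="left")
    return df


def localization_shift(
    reference: pd.DataFrame, perturbed: pd.DataFrame
) -> pd.Series:
    """Per-transcript change in log2 ratio between two endogenous
    localization tables (perturbed minus reference)."""
    shared = reference.index.intersection(perturbed.index)
    return perturbed.loc[shared, "log2_ratio"] - reference.loc[shared, "log2_ratio"]


def mirna_family_abundance(
    mirna_counts: pd.DataFrame, family_map: pd.Series
) -> pd.DataFrame:
    """Fraction of total miRNA reads per family and compartment (columns are
    compartments or samples; fractions sum to 1 per column)."""
    if (mirna_counts.values < 0).any():
        raise ValueError("negative counts")
    fam = family_map.reindex(mirna_counts.index)
    grouped = mirna_counts.groupby(fam).sum()
    totals = grouped.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero total miRNA counts in a column")
    return grouped.div(totals, axis=1)
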