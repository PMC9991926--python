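"""Amplicon read counting: adapter location, UMI extraction, indel-free
matching of inserts to the designed library.

Reads follow the layout ``UMI - ADAPTER5 - tile - ADAPTER3``.  A read is used
only if it contains the upstream adapter exactly; the UMI is the fixed-length
stretch immediately preceding it, and the insert is everything after it,
truncated at the downstream adapter when present.  Inserts are matched to
library sequences exactly (no indels, no mismatches by default):

* insert == tile sequence, or
* tile sequence is a prefix of the insert (read runs into the partially
  sequenced downstream adapter), or
* the insert is a prefix of the tile and at least ``min_match`` nt long
  (truncated read).

Reads matching more than one tile are rejected as ambiguous rather than
assigned arbitrarily, which matters for mutagenized libraries where variants
differ by a single base.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .adapters import ADAPTER3, ADAPTER5

NO_ADAPTER = "no_adapter"
NO_MATCH = "no_match"
AMBIGUOUS = "ambiguous"
ASSIGNED = "assigned"

SAMPLE_SHEET_COLUMNS = ["file", "sample", "compartment", "replicate", "condition"]


@dataclass
class CountTable:
    """Tiles x samples integer counts plus per-sample metadata."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # index: sample; columns: compartment, replicate, condition

    def __post_init__(self):
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def tile_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class LibraryIndex:
    """Exact-match index over library sequences.

    ``by_seq`` resolves full-sequence identity; the sorted sequence list
    supports prefix range queries for truncated reads.
    """

    by_seq: dict[str, list[str]]
    sorted_seqs: list[str]
    lengths: list[int]
    min_match: int = 40

    @classmethod
    def from_frame(
        cls, library: pd.DataFrame, seq_col: str = "sequence",
        id_col: str | None = None, min_match: int = 40,
    ) -> "LibraryIndex":
        if id_col is None:
            id_col = "variant_id" if "variant_id" in library.columns else "tile_id"
        by_seq: dict[str, list[str]] = {}
        for tid, seq in zip(library[id_col], library[seq_col]):
            by_seq.setdefault(seq, []).append(str(tid))
        return cls(
            by_seq=by_seq,
            sorted_seqs=sorted(by_seq),
            lengths=sorted({len(s) for s in by_seq}),
            min_match=min_match,
        )


def extract_insert(
    read_sequence: str, umi_length: int = 10, allow_n_in_umi: bool = True
) -> tuple[str, str] | str:
    """Locate the upstream adapter, return ``(umi, insert)`` or a rejection
    reason.  The insert is truncated at the downstream adapter if present."""
    pos = read_sequence.find(ADAPTER5)
    if pos < 0:
        return NO_ADAPTER
    if pos < umi_length:
        return NO_ADAPTER
    umi = read_sequence[pos - umi_length : pos]
    if not allow_n_in_umi and "N" in umi:
        return NO_ADAPTER
    insert = read_sequence[pos + len(ADAPTER5) :]
    cut = insert.find(ADAPTER3)
    if cut >= 0:
        insert = insert[:cut]
    return umi, insert


def match_to_library(insert: str, index: LibraryIndex) -> str:
    """Match an insert to the library without indels; returns a tile id or a
    rejection reason.  Any N in the insert fails exact matching."""
    if not insert or "N" in insert:
        return NO_MATCH
    hits: set[str] = set()
    # tile == insert, or tile is a prefix of the insert
    for L in index.lengths:
        if L > len(insert):
            break
        hits.update(index.by_seq.get(insert[:L], ()))
    if len(insert) >= index.min_match:
        # truncated read: insert is a (possibly improper) prefix of a tile

        lo = bisect.bisect_left(index.sorted_seqs, insert)
        while lo < len(index.sorted_seqs) and index.sorted_seqs[lo].startswith(insert):
            hits.update(index.by_seq[index.sorted_seqs[lo]])
            lo += 1
    if not hits:
        return NO_MATCH
    if len(hits) > 1:
        return AMBIGUOUS
    return hits.pop()


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    return sheet


def count_reads(
    sample_sheet: pd.DataFrame,
    library: pd.DataFrame,
    umi_length: int = 10,
    dedup: bool = True,
    min_match: int = 40,
) -> tuple[CountTable, pd.DataFrame]:
    """Process per-sample FASTQ files into a tiles x samples count table.

    With ``dedup`` (the default) reads sharing (tile, UMI) within a sample are
    counted once.  Returns the count table and per-sample processing stats
    (total / assigned / no_adapter / no_match / ambiguous, and the policy
    used, so the matching rules stay auditable).
    """
    index = LibraryIndex.from_frame(library, min_match=min_match)
    id_col = "variant_id" if "variant_id" in library.columns else "tile_id"
    tile_ids = [str(t) for t in library[id_col]]
    counts: dict[str, dict[str, int]] = {}
    stats_rows = []
    for _, row in sample_sheet.iterrows():
        sample = row["sample"]
        per_tile: dict[str, int] = dict.fromkeys(tile_ids, 0)
        seen: set[tuple[str, str]] = set()
        n_total = n_no_adapter = n_no_match = n_ambiguous = n_assigned = 0
        with pysam.FastxFile(str(row["file"])) as fq:
            for entry in fq:
                n_total += 1
                parsed = extract_insert(entry.sequence.upper(), umi_length)
                if parsed == NO_ADAPTER:
                    n_no_adapter += 1
                    continue
                umi, insert = parsed
                hit = match_to_library(insert, index)
                if hit == NO_MATCH:
                    n_no_match += 1
                    continue
                if hit == AMBIGUOUS:
                    n_ambiguous += 1
                    continue
                if dedup:
                    key = (hit, umi)
                    if key in seen:
                        continue
                    seen.add(key)
                per_tile[hit] += 1
                n_assigned += 1
        counts[sample] = per_tile
        stats_rows.append(
            {
                "sample": sample,
                "total": n_total,
                "assigned": n_assigned,
                "no_adapter": n_no_adapter,
                "no_match": n_no_match,
                "ambiguous": n_ambiguous,
                "umi_dedup": dedup,
                "umi_length": umi_length,
                "min_match": min_match,
            }
        )
    counts_df = pd.DataFrame(counts, index=tile_ids, columns=list(sample_sheet["sample"]))
    samples = sample_sheet.set_index("sample")[["compartment", "replicate", "condition"]]
    return CountTable(counts_df, samples), pd.DataFrame(stats_rows)


def filter_detected_tiles(
    table: CountTable, min_mean_reads: float = 20.0,
    min_reads: float = 20.0, min_samples: int = 3,
) -> tuple[CountTable, dict]:
    """Keep tiles with a mean raw count across all samples of at least
    ``min_mean_reads`` (inclusive).  Also reports the number of tiles with at
    least ``min_reads`` reads in at least ``min_samples`` samples, the
    detection summary used to describe library coverage."""
    means = table.counts.mean(axis=1)
    keep = means >= min_mean_reads
    detected = int(((table.counts >= min_reads).sum(axis=1) >= min_samples).sum())
    summary = {
        "n_tiles_total": int(len(table.counts)),
        "n_tiles_retained": int(keep.sum()),
        "n_tiles_detected": detected,
        "min_mean_reads": min_mean_reads,
    }
    return CountTable(table.counts.loc[keep].copy(), table.samples.copy()), summary
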