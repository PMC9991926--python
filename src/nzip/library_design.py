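"""Tiled oligo library design for 3' UTR zipcode mapping.

Candidate 3' UTRs are cut into overlapping fixed-size tiles (75 nt / 15-nt
offset for short UTRs, 100 nt / 25-nt offset for long ones); the final tile
absorbs any remainder up to a per-regime maximum.  Scrambled versions of
selected first tiles serve as negative controls, and every library member is
flanked by constant adapters for amplicon sequencing.

Coordinates are 0-based half-open internally; exported TSVs additionally
carry 1-based inclusive columns.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .adapters import ADAPTER3, ADAPTER5

_VALID_DNA = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class UtrRecord:
    """One 3' UTR sequence; the unit being tiled.

    ``isoform_tag`` distinguishes alternative UTRs of the same gene
    (e.g. ``"Cflar_1"``); it defaults to the gene id.
    """

    gene_id: str
    sequence: str
    isoform_tag: str = ""

    def __post_init__(self):
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{self.gene_id}: empty UTR sequence")
        if not _VALID_DNA.match(seq):
            bad = sorted(set(seq) - set("ACGT"))
            raise ValueError(f"{self.gene_id}: non-ACGT characters {bad}")
        object.__setattr__(self, "sequence", seq)
        if not self.isoform_tag:
            object.__setattr__(self, "isoform_tag", self.gene_id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TileSpec:
    """Tiling regime: step size, offset between starts, and the largest
    length the final (remainder-absorbing) tile may take."""

    tile_size: int
    offset: int
    max_last_size: int

    def __post_init__(self):
        if self.offset > self.tile_size:
            raise ValueError("offset must not exceed tile_size")
        if self.max_last_size < self.tile_size:
            raise ValueError("max_last_size must be >= tile_size")


@dataclass(frozen=True)
class Tile:
    gene_id: str
    tile_number: int
    start: int
    end: int
    sequence: str
    is_control: bool = False

    def __post_init__(self):
        if not self.is_control and self.end - self.start != len(self.sequence):
            raise ValueError("tile coordinates inconsistent with sequence length")

    @property
    def tile_id(self) -> str:
        if self.is_control:
            return f"{self.gene_id}-scr{self.tile_number}"
        return f"{self.gene_id}-{self.tile_number}"


@dataclass(frozen=True)
class OligoRecord:
    tile_id: str
    full_sequence: str


# Short UTRs (< 500 nt) get 75-nt tiles every 15 nt (last tile <= 80 nt);
# UTRs of >= 500 nt get 100-nt tiles every 25 nt (last tile <= 110 nt).
SMALL_SPEC = TileSpec(75, 15, 80)
LARGE_SPEC = TileSpec(100, 25, 110)


def tile_parameters(utr_length: int) -> TileSpec:
    """Tiling regime for a UTR of the given length."""
    if utr_length < 1:
        raise ValueError("utr_length must be >= 1")
    return SMALL_SPEC if utr_length < 500 else LARGE_SPEC


def tile_utr(utr: UtrRecord, spec: TileSpec | None = None) -> list[Tile]:
    """Cut a UTR into tiles covering [0, L) exactly.

    Tiles start at 0, offset, 2*offset, ...; the last regular tile absorbs the
    remainder when the result stays within ``max_last_size``, otherwise an
    extra right-anchored tile of ``tile_size`` ending at L is added so that
    coverage of the UTR is still complete.
    """
    if spec is None:
        spec = tile_parameters(len(utr))
    L = len(utr)
    size, off, max_last = spec.tile_size, spec.offset, spec.max_last_size
    if L < size:
        raise ValueError(
            f"{utr.gene_id}: UTR length {L} shorter than tile size {size}"
        )
    starts = list(range(0, L - size + 1, off))
    intervals = [(s, s + size) for s in starts]
    last_start, last_end = intervals[-1]
    remainder = L - last_end
    if remainder > 0:
        if (L - last_start) <= max_last:
            intervals[-1] = (last_start, L)
        else:
            intervals.append((L - size, L))
    return [
        Tile(utr.gene_id, i + 1, s, e, utr.sequence[s:e])
        for i, (s, e) in enumerate(intervals)
    ]


def make_scrambled_controls(
    tile: Tile, n_controls: int, rng_seed: int
) -> list[Tile]:
    """Scrambled (base-composition-preserving) controls of a source tile.

    Fisher-Yates shuffles with a recorded seed; a permutation identical to the
    source sequence is resampled (impossible to avoid for homopolymers, which
    are returned as-is).
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    if not tile.sequence:
        raise ValueError("source tile has empty sequence")
    rng = np.random.default_rng(rng_seed)
    bases = np.frombuffer(tile.sequence.encode(), dtype="S1")
    homopolymer = len(set(tile.sequence)) == 1
    out = []
    for k in range(n_controls):
        scr = rng.permutation(bases)
        while not homopolymer and scr.tobytes().decode() == tile.sequence:
            scr = rng.permutation(bases)
        out.append(
            Tile(
                gene_id=tile.gene_id,
                tile_number=k + 1,
                start=0,
                end=len(tile.sequence),
                sequence=scr.tobytes().decode(),
                is_control=True,
            )
        )
    return out


def assemble_oligo(tile: Tile) -> OligoRecord:
    """Flank a tile with the constant adapters, in synthesis orientation."""
    return OligoRecord(tile.tile_id, ADAPTER5 + tile.sequence + ADAPTER3)


def design_library(
    utrs: list[UtrRecord],
    control_genes: list[str] | None = None,
    n_controls: int = 5,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Design the full tiled library: tiles per UTR plus scrambled controls
    generated from the first tile of each gene in ``control_genes``.

    Returns a table with one row per library member including the full oligo
    (adapter5 + tile + adapter3) and both 0-based half-open and 1-based
    inclusive coordinates.
    """
    control_genes = control_genes or []
    rows: list[dict] = []
    tiles_by_gene: dict[str, list[Tile]] = {}
    for utr in utrs:
        tiles = tile_utr(utr)
        tiles_by_gene[utr.gene_id] = tiles
        rows.extend(_tile_row(t) for t in tiles)
    for j, gene in enumerate(control_genes):
        if gene not in tiles_by_gene:
            raise KeyError(f"control source gene {gene!r} not among the UTRs")
        first = tiles_by_gene[gene][0]
        for ctrl in make_scrambled_controls(first, n_controls, rng_seed + j):
            rows.append(_tile_row(ctrl))
    return pd.DataFrame(rows)


def _tile_row(t: Tile) -> dict:
    return {
        "tile_id": t.tile_id,
        "gene_id": t.gene_id,
        "tile_number": t.tile_number,
        "start": t.start,
        "end": t.end,
        "start_1based": t.start + 1,
        "end_1based": t.end,
        "sequence": t.sequence,
        "is_control": t.is_control,
        "oligo": assemble_oligo(t).full_sequence,
    }


def read_utrs_fasta(path) -> list[UtrRecord]:
    """Read UTR sequences from FASTA; record id becomes the gene id."""
    return [
        UtrRecord(gene_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_library(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_library(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tile_id": str, "gene_id": str})


def select_candidate_genes(
    log2fc: pd.DataFrame,
    padj: pd.DataFrame,
    reference_log2fc: pd.Series | None = None,
    sig_level: float = 0.05,
) -> list[str]:
    """Voting rules choosing candidate neurite-localized genes from several
    published enrichment datasets.

    A gene is selected when it is significant (adjusted p < ``sig_level``) in
    at least four datasets with median log2FC > 1 and (mean log2FC > 1 or a
    positive log2FC in every dataset where it was measured), or when it is
    significant in at least five datasets and any one of the three log2FC
    conditions holds.  Genes without an enrichment value in the reference
    system (``reference_log2fc`` NA) are excluded.
    """
    if log2fc.empty:
        return []
    if not log2fc.columns.equals(padj.columns) or not log2fc.index.equals(padj.index):
        raise ValueError("log2fc and padj must share index and columns")
    selected = []
    for gene in log2fc.index:
        lfc = log2fc.loc[gene]
        if reference_log2fc is not None and pd.isna(reference_log2fc.get(gene, np.nan)):
            continue
        sig = ((padj.loc[gene] < sig_level) & lfc.notna()).sum()
        vals = lfc.dropna()
        if vals.empty:
            continue
        median_gt1 = vals.median() > 1
        mean_gt1 = vals.mean() > 1
        all_pos = (vals > 0).all()
        rule_a = sig >= 4 and median_gt1 and (mean_gt1 or all_pos)
        rule_b = sig >= 5 and (median_gt1 or mean_gt1 or all_pos)
        if rule_a or rule_b:
            selected.append(gene)
    return selected


def library_to_fasta(df: pd.DataFrame, path) -> None:
    """Write full oligo sequences (adapters included) as FASTA."""
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write(f">{row['tile_id']}\n{row['oligo']}\n")
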