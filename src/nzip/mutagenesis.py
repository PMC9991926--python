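"""Saturation-mutagenesis library design for fine-mapping zipcodes.

Each selected parent tile is expanded into every possible single-base
substitution plus complement-swap windows (A<->T, C<->G applied within
consecutive non-overlapping 2-, 5- and 10-nt windows that partition the
tile), with the wild-type sequence and three scrambled versions as controls.
For a parent of length L this gives

    3L + ceil(L/2) + ceil(L/5) + ceil(L/10) + 4

library members.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .library_design import Tile, make_scrambled_controls

_VALID_DNA = re.compile(r"^[ACGT]+$")

BASES = "ACGT"
_SWAP = str.maketrans("ATCG", "TAGC")  # A<->T, C<->G (complement without reversal)


class VariantClass(str, Enum):
    wildtype = "wildtype"
    single_sub = "single_sub"
    window2 = "window2"
    window5 = "window5"
    window10 = "window10"
    scrambled = "scrambled"


@dataclass(frozen=True)
class VariantTile:
    parent_tile_id: str
    variant_class: VariantClass
    alt_sequence: str
    position: int | None = None  # 0-based start of the mutated span
    span: int | None = None


def _check_seq(sequence: str) -> str:
    sequence = sequence.upper()
    if not _VALID_DNA.match(sequence):
        raise ValueError("sequence must contain only A/C/G/T")
    return sequence


def single_substitutions(parent_sequence: str, parent_id: str = "") -> list[VariantTile]:
    """All 3L single-base substitutions, position-major, alternatives in
    A < C < G < T order."""
    seq = _check_seq(parent_sequence)
    out = []
    for pos, ref in enumerate(seq):
        for alt in BASES:
            if alt == ref:
                continue
            out.append(
                VariantTile(
                    parent_tile_id=parent_id,
                    variant_class=VariantClass.single_sub,
                    alt_sequence=seq[:pos] + alt + seq[pos + 1 :],
                    position=pos,
                    span=1,
                )
            )
    return out


def swap_bases(sequence: str) -> str:
    """The A<->T / C<->G involution applied to every base."""
    return sequence.translate(_SWAP)


def window_transitions(
    parent_sequence: str, w: int, parent_id: str = "", allow_any_width: bool = False
) -> list[VariantTile]:
    """Complement-swap every base within consecutive non-overlapping windows
    of width ``w`` (last window truncated), one variant per window."""
    if w not in (2, 5, 10) and not allow_any_width:
        raise ValueError("window width must be 2, 5 or 10 (or pass allow_any_width)")
    if w < 1:
        raise ValueError("window width must be >= 1")
    seq = _check_seq(parent_sequence)
    cls = {2: VariantClass.window2, 5: VariantClass.window5, 10: VariantClass.window10}.get(
        w, VariantClass.window2
    )
    out = []
    for start in range(0, len(seq), w):
        end = min(start + w, len(seq))
        alt = seq[:start] + swap_bases(seq[start:end]) + seq[end:]
        out.append(
            VariantTile(
                parent_tile_id=parent_id,
                variant_class=cls,
                alt_sequence=alt,
                position=start,
                span=end - start,
            )
        )
    return out


def expected_variant_count(L: int) -> int:
    """Closed-form library size per parent of length L (controls included)."""
    return 3 * L + math.ceil(L / 2) + math.ceil(L / 5) + math.ceil(L / 10) + 4


def design_mutagenesis_library(
    parents: list[Tile], rng_seed: int = 0, n_scrambled: int = 3
) -> pd.DataFrame:
    """Full mutagenesis library for a set of parent tiles.

    Per parent: wild-type, all single substitutions, 2/5/10-nt swap windows,
    and ``n_scrambled`` scrambled controls.  Sequences generated by more than
    one design rule are kept as distinct records and flagged in the
    ``duplicate_sequence`` column so that library totals stay auditable.
    """
    if not parents:
        raise ValueError("no parent tiles supplied")
    rows: list[dict] = []
    for j, parent in enumerate(parents):
        seq = _check_seq(parent.sequence)
        pid = parent.tile_id
        variants: list[VariantTile] = [
            VariantTile(pid, VariantClass.wildtype, seq)
        ]
        variants += single_substitutions(seq, pid)
        for w in (2, 5, 10):
            variants += window_transitions(seq, w, pid)
        for scr in make_scrambled_controls(parent, n_scrambled, rng_seed + j):
            variants.append(VariantTile(pid, VariantClass.scrambled, scr.sequence))
        counter: dict[str, int] = {}
        for v in variants:
            counter[v.alt_sequence] = counter.get(v.alt_sequence, 0) + 1
        for i, v in enumerate(variants):
            rows.append(
                {
                    "variant_id": f"{pid}|{v.variant_class.value}|{i}",
                    "parent_tile_id": pid,
                    "variant_class": v.variant_class.value,
                    "position": v.position,
                    "span": v.span,
                    "sequence": v.alt_sequence,
                    "duplicate_sequence": counter[v.alt_sequence] > 1,
                }
            )
    return pd.DataFrame(rows)


def select_tiles_for_mutagenesis(
    enrichment: pd.DataFrame, padj_max: float = 0.1, lfc_min: float = 1.0
) -> list[str]:
    """Tiles eligible for mutagenesis: significantly (adjusted p < 0.1) and
    highly (mean log2FC > 1) neurite-enriched."""
    ok = (enrichment["padj"] < padj_max) & (enrichment["log2fc"] > lfc_min)
    return enrichment.loc[ok, "tile_id"].tolist()
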