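"""Ground-truth-bearing synthetic data for the whole pipeline.

The generator emulates a tiled 3' UTR reporter experiment: random UTRs with
implanted zipcode motifs (let-7 seed sites, (AT)n repeats, CPE), the designed
tile library, two-compartment negative-binomial counts in which motif-bearing
tiles are relatively depleted in soma (the destabilization model, expressed
directly as a log2 neurite/soma effect split symmetrically across
compartments), and single-end amplicon FASTQ reads with UMIs, sequencing
errors and PCR duplicates.

Every output is reproducible bit-for-bit from (config, seed).  UMIs are drawn
distinct within each (sample, tile), so molecule identity is unambiguous in
the simulated truth; real UMI-space collisions are not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .adapters import ADAPTER3, ADAPTER5
from .library_design import UtrRecord, design_library
from .motifs import LET7_SITE7, max_au_repeat, count_sites
from .read_processing import CountTable

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-scale defaults: a ~100-UTR library measured in neurite/soma
    triplicates, NB-dispersed counts, 10-nt UMIs.

    Effects are Delta-log2FC(neurite/soma): per let-7 site and per (AT)6+
    tile; positive values mean neurite enrichment via soma depletion.
    """

    n_genes: int = 99
    utr_len_min: int = 200
    utr_len_max: int = 2000
    p_let7: float = 0.2          # per-gene implant probability, 1-3 sites
    p_au: float = 0.2            # per-gene (AT)n implant probability, n in 6-8
    p_cpe: float = 0.2
    effect_let7_per_site: float = 1.0
    effect_au: float = 1.5
    au_min_repeats: int = 6
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    replicates: int = 3
    depth: float = 1_000_000.0   # expected reads per sample
    umi_length: int = 10
    read_length: int = 150
    error_rate: float = 0.001    # per-base substitution rate
    pcr_duplication_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("p_let7", "p_au", "p_cpe", "error_rate", "pcr_duplication_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.utr_len_min < 75:
            raise ValueError("utr_len_min must allow at least one tile (>= 75)")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _implant(seq: list[str], motif: str, occupied: list[tuple[int, int]],
             rng: np.random.Generator) -> int | None:
    """Place a motif at a random position not overlapping prior implants."""
    L = len(seq)
    if L < len(motif):
        return None
    for _ in range(200):
        pos = int(rng.integers(0, L - len(motif) + 1))
        if all(pos + len(motif) <= s or pos >= e for s, e in occupied):
            seq[pos : pos + len(motif)] = list(motif)
            occupied.append((pos, pos + len(motif)))
            return pos
    return None


def simulate_utrs(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[UtrRecord], pd.DataFrame]:
    """Random UTRs with motifs implanted at non-overlapping positions.

    Returns the UTR records and an implant map (gene, motif, position).
    """
    rng = rng or np.random.default_rng(config.seed)
    utrs, implants = [], []
    for g in range(config.n_genes):
        gene = f"gene{g:03d}"
        L = int(rng.integers(config.utr_len_min, config.utr_len_max + 1))
        seq = list(_random_seq(rng, L))
        occupied: list[tuple[int, int]] = []
        if rng.random() < config.p_let7:
            for _ in range(int(rng.integers(1, 4))):
                pos = _implant(seq, LET7_SITE7, occupied, rng)
                if pos is not None:
                    implants.append((gene, "let7", pos, LET7_SITE7))
        if rng.random() < config.p_au:
            n = int(rng.integers(config.au_min_repeats, 9))
            motif = "AT" * n
            pos = _implant(seq, motif, occupied, rng)
            if pos is not None:
                implants.append((gene, f"au{n}", pos, motif))
        if rng.random() < config.p_cpe:
            pos = _implant(seq, "TTTTAT", occupied, rng)
            if pos is not None:
                implants.append((gene, "cpe", pos, "TTTTAT"))
        utrs.append(UtrRecord(gene_id=gene, sequence="".join(seq)))
    implant_map = pd.DataFrame(
        implants, columns=["gene_id", "motif", "position", "sequence"]
    )
    return utrs, implant_map


def tile_truth(
    library: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-tile ground truth: motif content of the tile sequence, the implied
    true log2FC(neurite/soma), and a log-normal baseline abundance.

    Motif-free tiles have effect 0 (pure null).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    id_col = "tile_id" if "tile_id" in library.columns else "variant_id"
    rows = []
    for tid, seq in zip(library[id_col], library["sequence"]):
        n_let7 = count_sites(seq, LET7_SITE7)
        au = max_au_repeat(seq)
        effect = config.effect_let7_per_site * n_let7
        if au >= config.au_min_repeats:
            effect += config.effect_au
        rows.append((tid, seq, n_let7, au, effect))
    truth = pd.DataFrame(
        rows, columns=["tile_id", "sequence", "n_let7", "max_au", "effect"]
    ).set_index("tile_id")
    truth["baseline"] = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, size=len(truth)
    )
    return truth


def simulate_counts(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    condition: str = "control",
) -> CountTable:
    """Two-compartment NB counts for one condition.

    Expected soma counts are baseline * 2^(-effect/2) and neurite counts
    baseline * 2^(+effect/2) (log2 ratio = effect), scaled so that the mean
    expected sample total equals ``depth``; counts are independent NB draws
    with the configured dispersion per replicate.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    baseline = truth["baseline"].to_numpy()
    effect = truth["effect"].to_numpy()
    depth_scale = config.depth / baseline.sum()
    counts = {}
    meta = []
    for comp, sign in (("soma", -1.0), ("neurite", +1.0)):
        mu = baseline * np.power(2.0, sign * effect / 2.0) * depth_scale
        for rep in range(1, config.replicates + 1):
            name = f"{condition}_{comp}_{rep}"
            counts[name] = _nb_draw(rng, mu, config.dispersion)
            meta.append((name, comp, str(rep), condition))
    samples = pd.DataFrame(
        meta, columns=["sample", "compartment", "replicate", "condition"]
    ).set_index("sample")
    return CountTable(pd.DataFrame(counts, index=truth.index), samples)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha < 1e-12:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_perturbation(truth: pd.DataFrame, attenuation: float) -> pd.DataFrame:
    """Second-condition truth: motif effects scaled by ``attenuation``
    (1 = unchanged, 0 = motif effects abolished)."""
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError("attenuation must be in [0, 1]")
    out = truth.copy()
    out["effect"] = out["effect"] * attenuation
    return out


def combine_count_tables(tables: list[CountTable]) -> CountTable:
    counts = pd.concat([t.counts for t in tables], axis=1)
    samples = pd.concat([t.samples for t in tables], axis=0)
    return CountTable(counts, samples)


def _mutate_read(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[int(rng.integers(0, 3))].encode()
    return arr.tobytes().decode()


def simulate_fastq(
    table: CountTable,
    library: pd.DataFrame,
    config: SimConfig,
    outdir,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Write one FASTQ per sample from a molecule-count table.

    Each counted molecule becomes one read ``UMI + adapter + tile + adapter``
    truncated to the read length, with per-base substitution errors; PCR
    duplicates re-emit a molecule with the same UMI (and fresh errors) with
    the configured probability.  Returns the sample sheet.
    """
    min_read = config.umi_length + len(ADAPTER5) + 40
    if config.read_length < min_read:
        raise ValueError(f"read_length must be >= {min_read}")
    rng = rng or np.random.default_rng(config.seed + 3)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    id_col = "tile_id" if "tile_id" in library.columns else "variant_id"
    seq_of = dict(zip(library[id_col].astype(str), library["sequence"]))
    rows = []
    for sample in table.counts.columns:
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            r = 0
            for tile_id, n_mol in table.counts[sample].items():
                if n_mol == 0:
                    continue
                template = ADAPTER5 + seq_of[str(tile_id)] + ADAPTER3
                umis: set[str] = set()
                while len(umis) < n_mol:
                    umis.add(_random_seq(rng, config.umi_length))
                for umi in sorted(umis):
                    full = (umi + template)[: config.read_length]
                    n_copies = 1
                    while rng.random() < config.pcr_duplication_rate:
                        n_copies += 1
                    for _ in range(n_copies):
                        read = _mutate_read(full, config.error_rate, rng)
                        r += 1
                        fh.write(
                            f"@{sample}:{tile_id}:{r}\n{read}\n+\n{'I' * len(read)}\n"
                        )
        meta = table.samples.loc[sample]
        rows.append(
            {
                "file": str(path),
                "sample": sample,
                "compartment": meta["compartment"],
                "replicate": meta["replicate"],
                "condition": meta["condition"],
            }
        )
    return pd.DataFrame(rows)


def simulate_experiment(
    config: SimConfig,
    outdir=None,
    conditions: dict[str, float] | None = None,
    write_fastq: bool = False,
):
    """End-to-end simulation: UTRs -> library -> truth -> counts
    (-> FASTQ when requested).

    ``conditions`` maps condition name to attenuation of motif effects
    (default a single 'control' condition at attenuation 1).  Returns a dict
    with utrs, implant map, library, per-condition truth, the combined count
    table and, when written, the sample sheet.
    """
    conditions = conditions or {"control": 1.0}
    rng = np.random.default_rng(config.seed)
    utrs, implant_map = simulate_utrs(config, rng)
    library = design_library(utrs, rng_seed=config.seed)
    noncontrol = library[~library["is_control"]].reset_index(drop=True)
    truth = tile_truth(noncontrol, config, rng)
    tables = []
    truths = {}
    for name, attenuation in conditions.items():
        t = simulate_perturbation(truth, attenuation)
        truths[name] = t
        tables.append(simulate_counts(t, config, rng, condition=name))
    table = combine_count_tables(tables)
    result = {
        "utrs": utrs,
        "implant_map": implant_map,
        "library": noncontrol,
        "truth": truths,
        "counts": table,
    }
    if write_fastq:
        if outdir is None:
            raise ValueError("outdir required when writing FASTQ")
        result["sample_sheet"] = simulate_fastq(table, noncontrol, config, outdir, rng)
    return result
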