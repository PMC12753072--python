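"""Synthetic regulatory landscapes with planted ground truth.

The generator emulates the inputs of a single-cell chromatin / GWAS
integration study: a small multi-chromosome genome; cell-type-specific open
chromatin peaks, each private peak carrying an exact copy of its type's
transcription-factor motif written into the genome; a noisy binary
cell x peak matrix over a differentiation lineage; and GWAS variants whose
risk signal is concentrated at motif bases inside the vulnerable (terminal)
cell type's peaks.

Lineage gradient
----------------
Cell types along the lineage progressively activate the terminal type's
regulatory elements: a type at lineage rank ``r`` (of ``R`` ranks) owns,
inside its fixed peak budget, a fraction ``lineage_gradient * r / (R - 1)``
of the vulnerable type's motif-bearing peaks (nested along the lineage).
This mirrors how germline regulatory risk can rise progressively along a
differentiation trajectory while remaining maximal in the terminal state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

from .data_io import (
    BASES,
    AccessibilityMatrix,
    GenomeSequences,
    IntervalSet,
    write_bedgraph,
    write_cell_matrix,
    write_gene_annotation,
    write_intervals,
    write_sequences,
    write_variant_table,
    SignalTrack,
)

DEFAULT_MOTIFS = {
    "BE": "TGACTCAT",     # AP-1-like
    "club": "CACGTGAC",   # E-box-like
    "LE1": "GATAAGGA",    # GATA-like
    "LE2": "TGTTTACA",    # forkhead (FOXA1)-like
}


@dataclass
class SimulationSpec:
    """All knobs of the synthetic landscape; the defaults are the study
    conditions every planted-signal test runs under."""

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrA": 4_000_000, "chrB": 4_000_000})
    gc_fraction: float = 0.41
    motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    peaks_per_type: int = 400
    peak_length: int = 200
    shared_fraction: float = 0.10
    cells_per_type: int = 150
    capture_rate: float = 0.9
    noise_rate: float = 0.02
    lineage: tuple[str, ...] = ("BE", "club", "LE1", "LE2")
    lineage_gradient: float = 0.6
    vulnerable_type: str = "LE2"
    n_variants: int = 2000
    fraction_functional: float = 0.05
    functional_z_mean: float = 4.0
    closing_fraction: float = 0.8
    n_ld_blocks: int = 100

    def __post_init__(self) -> None:
        for name, rate in [
            ("gc_fraction", self.gc_fraction),
            ("shared_fraction", self.shared_fraction),
            ("capture_rate", self.capture_rate),
            ("noise_rate", self.noise_rate),
            ("fraction_functional", self.fraction_functional),
            ("closing_fraction", self.closing_fraction),
            ("lineage_gradient", self.lineage_gradient),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if min(self.chrom_lengths.values()) < 10 * self.peak_length:
            raise ValueError("chromosomes must be >= 10x peak length")
        motifs = list(self.motifs.values())
        if len(set(motifs)) != len(motifs):
            raise ValueError("cell-type motifs must be distinct")
        for m in motifs:
            if len(m) < 6 or set(m) - set(BASES):
                raise ValueError(f"motif {m!r} must be length >= 6 over A/C/G/T")
        if set(self.lineage) != set(self.motifs):
            raise ValueError("lineage must order exactly the cell types")
        if self.vulnerable_type not in self.motifs:
            raise ValueError(f"unknown vulnerable type {self.vulnerable_type!r}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.lineage)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per operation so each stage is re-runnable."""
        return np.random.default_rng([self.seed, stream])


def generate_genome(spec: SimulationSpec) -> GenomeSequences:
    """I.i.d. bases at the requested GC fraction."""
    rng = spec.rng(0)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for name, length in spec.chrom_lengths.items():
        draws = rng.choice(4, size=length, p=probs)
        seqs[name] = codes[draws].tobytes().decode("ascii")
    return GenomeSequences(seqs)


def _place_disjoint_peaks(spec: SimulationSpec, n_total: int,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Place n_total peaks disjointly, >= 1 peak-length apart, across chroms."""
    plen = spec.peak_length
    slot = 2 * plen  # peak plus the mandatory gap
    names = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in names], dtype=float)
    capacity = np.floor((lengths - plen) / slot).astype(int)
    if capacity.sum() < n_total:
        raise ValueError(
            f"genome too small: capacity for {capacity.sum()} disjoint peaks, "
            f"{n_total} requested"
        )
    # proportional allocation, remainder to the largest chromosomes
    alloc = np.floor(n_total * lengths / lengths.sum()).astype(int)
    alloc = np.minimum(alloc, capacity)
    i = 0
    while alloc.sum() < n_total:
        order = np.argsort(capacity - alloc)[::-1]
        alloc[order[i % len(order)]] += 1
        i += 1
    rows = []
    for chrom, k, L in zip(names, alloc, spec.chrom_lengths.values()):
        if k == 0:
            continue
        free = L - k * slot
        offsets = np.sort(rng.integers(0, free + 1, size=k))
        starts = offsets + np.arange(k) * slot + plen // 2
        for s in starts:
            rows.append((chrom, int(s), int(s) + plen))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def plant_peaks_and_motifs(
    genome: GenomeSequences, spec: SimulationSpec
) -> tuple[GenomeSequences, dict[str, IntervalSet], pd.DataFrame]:
    """Plant peaks and motifs; returns (mutated genome, per-type peak sets,
    ground-truth peak table).

    Every type's peak set has exactly ``peaks_per_type`` intervals: shared
    housekeeping peaks (motif-free), the type's private motif peaks, and --
    for non-vulnerable lineage ranks -- a nested slice of the vulnerable
    type's motif peaks per the lineage gradient.
    """
    rng = spec.rng(1)
    types = spec.cell_types
    n_shared = int(round(spec.shared_fraction * spec.peaks_per_type))
    ranks = {t: i for i, t in enumerate(types)}
    denom = max(len(types) - 1, 1)
    n_borrow = {
        t: 0 if t == spec.vulnerable_type
        else int(round(spec.lineage_gradient * ranks[t] / denom
                       * (spec.peaks_per_type - n_shared)))
        for t in types
    }
    n_private = {t: spec.peaks_per_type - n_shared - n_borrow[t] for t in types}
    if min(n_private.values()) < 1:
        raise ValueError("peaks_per_type too small for shared/gradient budget")

    n_total = n_shared + sum(n_private.values())
    placed = _place_disjoint_peaks(spec, n_total, rng)
    order = rng.permutation(n_total)

    owners = np.empty(n_total, dtype=object)
    owners[order[:n_shared]] = "shared"
    cursor = n_shared
    for t in types:
        owners[order[cursor:cursor + n_private[t]]] = t
        cursor += n_private[t]
    placed["owner"] = owners

    # write motifs into the genome at a uniform offset inside each private peak
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    motif_start = np.full(n_total, -1, dtype=np.int64)
    for i, row in placed.iterrows():
        if row["owner"] == "shared":
            continue
        motif = spec.motifs[row["owner"]]
        lo, hi = row["start"] + 10, row["end"] - 10 - len(motif)
        pos = int(rng.integers(lo, hi + 1))
        seqs[row["chrom"]][pos:pos + len(motif)] = motif.encode("ascii")
        motif_start[i] = pos
    placed["motif_start"] = motif_start
    placed["strand"] = "+"

    mutated = GenomeSequences({c: s.decode("ascii") for c, s in seqs.items()})

    vuln_idx = placed.index[placed["owner"] == spec.vulnerable_type].to_numpy()
    borrow_order = rng.permutation(vuln_idx)  # nested along the lineage
    shared_idx = placed.index[placed["owner"] == "shared"].to_numpy()

    peaksets = {}
    for t in types:
        own = placed.index[placed["owner"] == t].to_numpy()
        idx = np.concatenate([shared_idx, own, borrow_order[:n_borrow[t]]])
        sub = placed.loc[np.sort(idx), ["chrom", "start", "end"]]
        peaksets[t] = IntervalSet(sub).sort()
    return mutated, peaksets, placed


def union_peaks(truth: pd.DataFrame) -> IntervalSet:
    """All planted peaks as one sorted IntervalSet (the matrix column space)."""
    return IntervalSet(truth[["chrom", "start", "end"]]).sort()


def simulate_cell_matrix(
    peaksets: dict[str, IntervalSet], spec: SimulationSpec
) -> tuple[AccessibilityMatrix, pd.DataFrame]:
    """Bernoulli capture of own peaks, background noise on the rest, and
    pseudotime uniform within each lineage rank."""
    if len(peaksets) < 2:
        raise ValueError("need >= 2 cell types")
    if spec.cells_per_type < 1:
        raise ValueError("zero cells requested")
    rng = spec.rng(2)

    union = IntervalSet(
        pd.concat([ps.df for ps in peaksets.values()]).drop_duplicates()
    ).sort()
    key = union.df["chrom"].astype(str) + ":" + union.df["start"].astype(str)
    col_of = {k: i for i, k in enumerate(key)}
    own_cols = {
        t: np.array([
            col_of[f"{c}:{s}"]
            for c, s in zip(ps.df["chrom"], ps.df["start"])
        ])
        for t, ps in peaksets.items()
    }

    n_peaks = len(union)
    blocks, meta_rows = [], []
    for rank, t in enumerate(spec.cell_types):
        block = (rng.random((spec.cells_per_type, n_peaks))
                 < spec.noise_rate).astype(np.int8)
        own = (rng.random((spec.cells_per_type, len(own_cols[t])))
               < spec.capture_rate).astype(np.int8)
        block[:, own_cols[t]] = own
        blocks.append(block)
        pt = rank + rng.random(spec.cells_per_type)
        for j in range(spec.cells_per_type):
            meta_rows.append((f"{t}_{j:04d}", t, pt[j]))

    counts = scipy.sparse.csr_matrix(np.vstack(blocks))
    cells = pd.DataFrame(meta_rows, columns=["cell_id", "cell_type", "pseudotime"])
    return AccessibilityMatrix(counts, union), cells


def simulate_gwas(
    genome: GenomeSequences, truth: pd.DataFrame, spec: SimulationSpec
) -> pd.DataFrame:
    """GWAS variants with planted functional signal.

    Functional variants sit at motif bases inside the vulnerable type's
    peaks, alt allele differing from the motif consensus; the risk allele is
    the motif-breaking (alt) allele with probability ``closing_fraction``
    (planted direction -1), otherwise the motif-preserving ref allele
    (direction +1).  Neutral variants are uniform outside motif footprints
    with z ~ N(0,1) and small fine-mapping posterior.
    """
    rng = spec.rng(3)
    n_func = int(round(spec.n_variants * spec.fraction_functional))
    n_neutral = spec.n_variants - n_func

    vuln = truth[truth["owner"] == spec.vulnerable_type]
    motif_len = len(spec.motifs[spec.vulnerable_type])
    slots = [
        (row["chrom"], int(row["motif_start"]) + k)
        for _, row in vuln.iterrows() for k in range(motif_len)
    ]
    if n_func > len(slots):
        raise ValueError(
            f"{n_func} functional variants requested but only {len(slots)} "
            "motif positions available"
        )
    pick = rng.choice(len(slots), size=n_func, replace=False)

    # motif footprints to exclude for neutral placement
    footprints: dict[str, set[int]] = {c: set() for c in genome.chrom_names}
    for _, row in truth.iterrows():
        if row["motif_start"] >= 0:
            m = spec.motifs[row["owner"]]
            footprints[row["chrom"]].update(
                range(int(row["motif_start"]), int(row["motif_start"]) + len(m)))

    rows = []
    for i in pick:
        chrom, pos0 = slots[i]
        ref = genome.base_at(chrom, pos0 + 1)
        alt = rng.choice([b for b in BASES if b != ref])
        magnitude = abs(rng.normal(spec.functional_z_mean, 1.0))
        closing = rng.random() < spec.closing_fraction
        z = magnitude if closing else -magnitude  # z>0: risk allele is alt
        direction = -1 if closing else 1
        pp = rng.uniform(0.5, 1.0)
        rows.append((chrom, pos0 + 1, ref, alt, z, pp, 1, direction))

    used = {(c, p) for c, p, *_ in rows}
    names = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in names], dtype=float)
    cum = lengths.cumsum()
    while len(rows) < n_func + n_neutral:
        g = rng.uniform(0, cum[-1])
        ci = int(np.searchsorted(cum, g, side="right"))
        chrom = names[ci]
        pos0 = int(g - (cum[ci] - lengths[ci]))
        if pos0 >= spec.chrom_lengths[chrom] or pos0 in footprints[chrom]:
            continue
        if (chrom, pos0 + 1) in used:
            continue
        used.add((chrom, pos0 + 1))
        ref = genome.base_at(chrom, pos0 + 1)
        alt = rng.choice([b for b in BASES if b != ref])
        rows.append((chrom, pos0 + 1, ref, alt, rng.normal(), rng.uniform(0, 0.1),
                     0, 0))

    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "z", "pp",
                       "is_functional", "planted_direction"],
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)

    # LD blocks: equal-width positional bins over the concatenated genome
    offsets = dict(zip(names, np.concatenate([[0.0], cum[:-1]])))
    gpos = df["pos"].to_numpy() - 1 + np.array([offsets[c] for c in df["chrom"]])
    width = cum[-1] / spec.n_ld_blocks
    df["ld_block"] = np.minimum((gpos // width).astype(np.int64),
                                spec.n_ld_blocks - 1)
    df["maf"] = rng.uniform(0.05, 0.5, size=len(df)).round(4)
    df.insert(0, "id", [f"v{i:05d}" for i in range(len(df))])
    return df[["id", "chrom", "pos", "ref", "alt", "z", "pp", "ld_block", "maf",
               "is_functional", "planted_direction"]]


def make_gene_annotation(truth: pd.DataFrame) -> pd.DataFrame:
    """One synthetic gene per planted peak, TSS at the peak midpoint,
    alternating strand."""
    mid = ((truth["start"] + truth["end"]) // 2 + 1).to_numpy()  # 1-based
    return pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(len(truth))],
        "chrom": truth["chrom"].to_numpy(),
        "tss": mid,
        "strand": np.where(np.arange(len(truth)) % 2 == 0, "+", "-"),
    })


def promoter_intervals(genes: pd.DataFrame, upstream: int = 1000,
                       downstream: int = 100) -> IntervalSet:
    """Strand-aware promoter windows [TSS-upstream, TSS+downstream]."""
    tss0 = genes["tss"].to_numpy() - 1
    plus = genes["strand"].to_numpy() == "+"
    start = np.where(plus, tss0 - upstream, tss0 - downstream)
    end = np.where(plus, tss0 + downstream + 1, tss0 + upstream + 1)
    df = pd.DataFrame({
        "chrom": genes["chrom"].to_numpy(),
        "start": np.maximum(start, 0),
        "end": end,
    })
    return IntervalSet(df).normalize()


def make_haplo_scores(genes: pd.DataFrame, truth: pd.DataFrame,
                      variants: pd.DataFrame, spec: SimulationSpec) -> pd.DataFrame:
    """Synthetic haploinsufficiency table: genes whose peak hosts a planted
    functional variant draw from a higher-scoring distribution."""
    rng = spec.rng(4)
    func = variants[variants["is_functional"] == 1]
    starts = truth["start"].to_numpy()
    ends = truth["end"].to_numpy()
    chroms = truth["chrom"].to_numpy()
    perturbed = np.zeros(len(truth), dtype=bool)
    for _, v in func.iterrows():
        hit = (chroms == v["chrom"]) & (starts <= v["pos"] - 1) & (v["pos"] - 1 < ends)
        perturbed |= hit
    score = np.where(perturbed, rng.beta(4, 2, size=len(truth)),
                     rng.beta(2, 4, size=len(truth)))
    return pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(),
                         "score": score.round(4)})


def make_target_geneset(genes: pd.DataFrame, truth: pd.DataFrame,
                        spec: SimulationSpec) -> list[str]:
    """TF-target emulation: the genes of the vulnerable type's motif peaks."""
    mask = (truth["owner"] == spec.vulnerable_type).to_numpy()
    return list(genes.loc[mask, "gene_id"])


def make_signal_track(truth: pd.DataFrame, spec: SimulationSpec,
                      peak_value: float = 6.0,
                      baseline: float = 1.0) -> SignalTrack:
    """ChIP-like coverage: elevated over the vulnerable type's peaks,
    baseline elsewhere."""
    rows = []
    vuln = truth[truth["owner"] == spec.vulnerable_type]
    for chrom, length in spec.chrom_lengths.items():
        sub = vuln[vuln["chrom"] == chrom].sort_values("start")
        cursor = 0
        for _, pk in sub.iterrows():
            if pk["start"] > cursor:
                rows.append((chrom, cursor, int(pk["start"]), baseline))
            rows.append((chrom, int(pk["start"]), int(pk["end"]), peak_value))
            cursor = int(pk["end"])
        if cursor < length:
            rows.append((chrom, cursor, length, baseline))
    return SignalTrack(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                   "value"]))


def simulate_bundle(spec: SimulationSpec):
    """Run all generators; returns a dict of every simulated object."""
    genome = generate_genome(spec)
    genome, peaksets, truth = plant_peaks_and_motifs(genome, spec)
    matrix, cells = simulate_cell_matrix(peaksets, spec)
    variants = simulate_gwas(genome, truth, spec)
    genes = make_gene_annotation(truth)
    haplo = make_haplo_scores(genes, truth, variants, spec)
    return {
        "haplo": haplo,
        "targets": make_target_geneset(genes, truth, spec),
        "track": make_signal_track(truth, spec),
        "spec": spec,
        "genome": genome,
        "peaksets": peaksets,
        "truth": truth,
        "matrix": matrix,
        "cells": cells,
        "variants": variants,
        "genes": genes,
        "promoters": promoter_intervals(genes),
    }


def write_bundle(bundle: dict, outdir) -> dict:
    """Write the full input bundle; returns {name: path}."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "matrix": outdir / "matrix.mtx",
        "cells": outdir / "cells.tsv",
        "peaks": outdir / "peaks.bed",
        "variants": outdir / "variants.tsv",
        "genes": outdir / "genes.tsv",
        "promoters": outdir / "promoters.bed",
        "truth": outdir / "peak_truth.tsv",
        "haplo": outdir / "haplo_scores.tsv",
        "targets": outdir / "target_genes.txt",
        "track": outdir / "signal.bedgraph",
    }
    write_sequences(bundle["genome"], paths["genome"])
    write_cell_matrix(bundle["matrix"], bundle["cells"],
                      paths["matrix"], paths["cells"], paths["peaks"])
    write_variant_table(bundle["variants"], paths["variants"])
    write_gene_annotation(bundle["genes"], paths["genes"])
    write_intervals(bundle["promoters"], paths["promoters"])
    bundle["truth"].to_csv(paths["truth"], sep="\t", index=False)
    bundle["haplo"].to_csv(paths["haplo"], sep="\t", index=False)
    paths["targets"].write_text("\n".join(bundle["targets"]) + "\n")
    write_bedgraph(bundle["track"], paths["track"])
    for t, ps in bundle["peaksets"].items():
        p = outdir / f"peaks_{t}.bed"
        write_intervals(ps, p)
        paths[f"peaks_{t}"] = p
    return paths
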