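"""Domain containers and readers/writers for the standard genomic formats.

Coordinate conventions
----------------------
Interval types (peaks, promoters, signal tracks) are BED-style: 0-based,
half-open ``[start, end)``.  Variants are VCF-style 1-based positions.  The
single conversion rule lives in :func:`variant_overlaps_interval`: a variant
at 1-based position ``p`` overlaps ``[s, e)`` iff ``s <= p - 1 < e``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
BASES = ("A", "C", "G", "T")

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "z", "pp", "ld_block", "maf"]
TRUTH_COLUMNS = ["is_functional", "planted_direction"]


class DataFormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# Genome sequences
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequences:
    """Named chromosomes of DNA text over the alphabet {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - DNA_ALPHABET
            if bad:
                offset = next(i for i, c in enumerate(seq) if c in bad)
                raise DataFormatError(
                    f"illegal character {seq[offset]!r} in {name} at offset {offset}"
                )

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice, N-padded where it overhangs the ends."""
        seq = self.sequences[chrom]
        left_pad = max(0, -start)
        right_pad = max(0, end - len(seq))
        core = seq[max(0, start):min(len(seq), end)]
        return "N" * left_pad + core + "N" * right_pad

    def base_at(self, chrom: str, pos_1based: int) -> str:
        """Single base at a 1-based position."""
        if not 1 <= pos_1based <= len(self.sequences[chrom]):
            raise DataFormatError(
                f"position {pos_1based} outside {chrom} (length {len(self.sequences[chrom])})"
            )
        return self.sequences[chrom][pos_1based - 1]


def read_sequences(path: str | Path) -> GenomeSequences:
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise DataFormatError(f"duplicate FASTA header {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    return GenomeSequences(seqs)


def write_sequences(genome: GenomeSequences, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Interval sets (BED semantics)
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Genomic intervals, 0-based half-open, as a DataFrame with columns
    chrom/start/end and optional name/value."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end"]))

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if len(df):
            if (df["start"] < 0).any():
                raise DataFormatError("negative interval start")
            bad = df["start"] >= df["end"]
            if bad.any():
                row = df[bad].iloc[0]
                raise DataFormatError(
                    f"empty or inverted interval {row['chrom']}:{row['start']}-{row['end']}"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def normalize(self) -> "IntervalSet":
        """Sort by (chrom, start) and merge overlapping or touching intervals."""
        if not len(self.df):
            return IntervalSet(self.df.copy())
        rows = []
        for chrom, sub in self.df.sort_values(["chrom", "start", "end"]).groupby(
                "chrom", sort=True):
            cur_s, cur_e = None, None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:  # overlap or touch
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def sort(self) -> "IntervalSet":
        return IntervalSet(
            self.df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        )


def variant_overlaps_interval(pos_1based: int, start: int, end: int) -> bool:
    """The one 1-based <-> 0-based conversion used everywhere."""
    return start <= pos_1based - 1 < end


def map_variants_to_intervals(
    chroms: pd.Series, positions: pd.Series, intervals: IntervalSet
) -> np.ndarray:
    """Index of the interval containing each variant, -1 when none.

    Interval set must be sorted and non-overlapping per chromosome.
    """
    result = np.full(len(chroms), -1, dtype=np.int64)
    df = intervals.df
    for chrom, sub in df.groupby("chrom", sort=False):
        mask = (chroms == chrom).to_numpy()
        if not mask.any():
            continue
        pos0 = positions.to_numpy()[mask] - 1
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        out = np.where(ok, sub.index.to_numpy()[np.clip(idx, 0, None)], -1)
        result[mask] = out
    return result


def read_intervals(path: str | Path) -> IntervalSet:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
    except pd.errors.EmptyDataError:
        return IntervalSet()
    except ValueError as exc:
        raise DataFormatError(f"malformed BED file {path}: {exc}") from exc
    return IntervalSet(df)


def write_intervals(ivs: IntervalSet, path: str | Path,
                    names: list[str] | None = None) -> None:
    df = ivs.df[["chrom", "start", "end"]].copy()
    if names is not None:
        df["name"] = names
    df.to_csv(path, sep="\t", header=False, index=False)


normalize_intervals = IntervalSet.normalize


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def _validate_variant_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"variant table missing column(s): {', '.join(missing)}")
    for col in ("ref", "alt"):
        bad = ~df[col].isin(BASES)
        if bad.any():
            raise DataFormatError(
                f"non-SNV allele {df.loc[bad, col].iloc[0]!r} in variant "
                f"{df.loc[bad, 'id'].iloc[0]!r}"
            )
    same = df["ref"] == df["alt"]
    if same.any():
        raise DataFormatError(f"ref == alt for variant {df.loc[same, 'id'].iloc[0]!r}")
    if ((df["pp"] < 0) | (df["pp"] > 1)).any():
        raise DataFormatError("pp outside [0, 1]")
    return df


def read_variant_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    except ValueError as exc:
        raise DataFormatError(f"unparseable variant table {path}: {exc}") from exc
    df = _validate_variant_frame(df)
    for col in ("pos", "ld_block"):
        if not np.issubdtype(df[col].dtype, np.integer):
            try:
                df[col] = df[col].astype(np.int64)
            except ValueError as exc:
                raise DataFormatError(f"unparseable numeric column {col!r}") from exc
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    _validate_variant_frame(df).to_csv(path, sep="\t", index=False)


def validate_against_genome(variants: pd.DataFrame,
                            genome: GenomeSequences) -> pd.DataFrame:
    """Check genome base at each variant position equals the ref allele.

    Returns a report frame (id, chrom, pos, expected ref, found base, ok);
    never mutates the input.
    """
    found = [
        genome.base_at(chrom, pos)
        for chrom, pos in zip(variants["chrom"], variants["pos"])
    ]
    return pd.DataFrame({
        "id": variants["id"].to_numpy(),
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "ref": variants["ref"].to_numpy(),
        "found": found,
        "ok": variants["ref"].to_numpy() == np.array(found),
    })


# ---------------------------------------------------------------------------
# Cell x peak accessibility matrix
# ---------------------------------------------------------------------------

@dataclass
class AccessibilityMatrix:
    """Cells x peaks counts (CSR) aligned to a peak IntervalSet."""

    counts: scipy.sparse.csr_matrix
    peaks: IntervalSet

    def __post_init__(self) -> None:
        self.counts = scipy.sparse.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DataFormatError("negative count in accessibility matrix")
        if self.counts.shape[1] != len(self.peaks):
            raise DataFormatError(
                f"matrix has {self.counts.shape[1]} peak columns but peak set has "
                f"{len(self.peaks)} intervals"
            )

    @property
    def binary(self) -> scipy.sparse.csr_matrix:
        """Accessibility as count >= 1."""
        out = self.counts.copy()
        out.data = (out.data >= 1).astype(np.int8)
        out.eliminate_zeros()
        return out


def _validate_cell_meta(cells: pd.DataFrame) -> pd.DataFrame:
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise DataFormatError(f"duplicate cell id {dup!r}")
    if "pseudotime" in cells.columns:
        pt = cells["pseudotime"].dropna()
        if len(pt) and ((~np.isfinite(pt)) | (pt < 0)).any():
            raise DataFormatError("pseudotime must be finite and >= 0")
    return cells


def read_cell_matrix(
    matrix_path: str | Path, cells_path: str | Path, peaks_path: str | Path
) -> tuple[AccessibilityMatrix, pd.DataFrame, IntervalSet]:
    """Load the (matrix, cell metadata, peak BED) triple.

    The matrix may be MatrixMarket (cells x peaks) or dense TSV without header.
    """
    peaks = read_intervals(peaks_path)
    cells = _validate_cell_meta(pd.read_csv(cells_path, sep="\t"))
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        counts = scipy.sparse.csr_matrix(scipy.io.mmread(str(matrix_path)))
    else:
        dense = pd.read_csv(matrix_path, sep="\t", header=None).to_numpy()
        counts = scipy.sparse.csr_matrix(dense)
    if counts.shape != (len(cells), len(peaks)):
        raise DataFormatError(
            f"dimension mismatch: matrix {counts.shape}, {len(cells)} cells, "
            f"{len(peaks)} peaks"
        )
    return AccessibilityMatrix(counts, peaks), cells, peaks


def write_cell_matrix(
    matrix: AccessibilityMatrix, cells: pd.DataFrame,
    matrix_path: str | Path, cells_path: str | Path, peaks_path: str | Path,
) -> None:
    # mmwrite writes floats by default; field="integer" keeps the round trip exact
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, matrix.counts.astype(np.int64), field="integer")
    Path(matrix_path).write_bytes(buf.getvalue())
    cells.to_csv(cells_path, sep="\t", index=False)
    write_intervals(matrix.peaks, peaks_path)


# ---------------------------------------------------------------------------
# Gene annotation and signal tracks
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = ["gene_id", "chrom", "tss", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"gene annotation missing column(s): {', '.join(missing)}")
    if not df["strand"].isin(["+", "-"]).all():
        raise DataFormatError("strand must be '+' or '-'")
    return df


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


@dataclass
class SignalTrack:
    """bedGraph-semantics coverage: sorted, non-overlapping per chromosome."""

    df: pd.DataFrame  # chrom, start, end, value

    def __post_init__(self) -> None:
        df = self.df.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise DataFormatError(f"overlapping signal intervals on {chrom}")
        self.df = df


def read_bedgraph(path: str | Path) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return SignalTrack(df)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    track.df.to_csv(path, sep="\t", header=False, index=False)
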