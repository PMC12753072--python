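"""Sequence -> chromatin accessibility classifier.

A residual convolutional network maps fixed-length one-hot DNA windows to an
accessibility probability.  Training windows are peak-centered positives and
GC-matched, peak-excluded genomic negatives; evaluation is k-fold
cross-validation plus an entirely held-out chromosome.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import ResidualNet
from .data_io import GenomeSequences, IntervalSet

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The topology (residual conv blocks with batch norm and ReLU, identity
    skips, global max pooling, sigmoid head) is fixed; every size is
    configurable.
    """

    window_length: int = 1000
    n_blocks: int = 3
    n_filters: int = 64
    kernel_size: int = 11
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    cv_folds: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length % 2 != 0:
            raise ValueError("window_length must be even")
        if self.window_length < 2 * self.kernel_size:
            raise ValueError("window_length must be >= 2x kernel size")
        if self.n_blocks < 1:
            raise ValueError("need >= 1 residual block")

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Desk-scale preset used by the demo pipeline and tests."""
        defaults = dict(window_length=200, n_blocks=1, n_filters=32,
                        kernel_size=11, epochs=12, batch_size=32,
                        learning_rate=5e-3, cv_folds=20, seed=0)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TrainingSet:
    sequences: list[str]
    labels: np.ndarray
    groups: np.ndarray           # peak id of each window (negatives share
                                 # the id of their GC-paired positive)
    window_length: int
    coords: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class EvalReport:
    fold_aurocs: list[float]
    n_pos: int
    n_neg: int
    heldout_auroc: float | None = None

    @property
    def cv_auroc_mean(self) -> float | None:
        return float(np.mean(self.fold_aurocs)) if self.fold_aurocs else None


@dataclass
class TrainedAccessibilityModel:
    config: ModelConfig
    net: ResidualNet
    fingerprint: str


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def one_hot_encode(seq: str) -> np.ndarray:
    """L x 4 one-hot matrix, columns A/C/G/T; N rows all-zero."""
    out = np.zeros((len(seq), 4))
    for i, base in enumerate(seq.upper()):
        if base == "N":
            continue
        try:
            out[i, _BASE_INDEX[base]] = 1.0
        except KeyError:
            raise ValueError(f"illegal character {base!r} at position {i}") from None
    return out


def encode_batch(seqs: list[str], L: int | None = None) -> np.ndarray:
    if L is not None:
        for i, s in enumerate(seqs):
            if len(s) != L:
                raise ValueError(
                    f"window {i} has length {len(s)}, expected {L}")
    if not seqs:
        return np.zeros((0, L or 0, 4))
    return np.stack([one_hot_encode(s) for s in seqs])


def gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    return (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0


# ---------------------------------------------------------------------------
# Training set construction
# ---------------------------------------------------------------------------

def _window_overlaps_peaks(chrom: str, start: int, end: int,
                           peaks_by_chrom: dict) -> bool:
    entry = peaks_by_chrom.get(chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = np.searchsorted(ends, start, side="right")
    return i < len(starts) and starts[i] < end


def build_training_set(
    genome: GenomeSequences,
    peaks: IntervalSet,
    L: int,
    neg_ratio: float = 1.0,
    excluded_chrom: str | None = None,
    gc_tolerance: float = 0.05,
    seed: int = 0,
    max_tries: int = 500,
) -> TrainingSet:
    """Peak-centered positives and GC-matched peak-free negatives.

    Negatives are sampled genome-wide (outside every peak and off the
    excluded chromosome), each required to match the GC content of a
    randomly paired positive within ``gc_tolerance``.
    """
    if excluded_chrom is not None and excluded_chrom not in genome.sequences:
        raise ValueError(f"excluded_chrom {excluded_chrom!r} not in genome")
    rng = np.random.default_rng(seed)
    norm = peaks.normalize()
    peaks_by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in norm.df.groupby("chrom")
    }

    seqs, labels, groups, coords = [], [], [], []
    pos_gc = []
    usable = norm.df[norm.df["chrom"] != excluded_chrom]
    for peak_id, row in usable.iterrows():
        mid = (row["start"] + row["end"]) // 2
        start = mid - L // 2
        seq = genome.fetch(row["chrom"], start, start + L)
        seqs.append(seq)
        labels.append(1)
        groups.append(peak_id)
        coords.append((row["chrom"], start, start + L))
        pos_gc.append(gc_fraction(seq))
    n_pos = len(seqs)
    if n_pos == 0:
        raise ValueError("no usable peaks for training")

    chroms = [c for c in genome.chrom_names if c != excluded_chrom]
    weights = np.array([len(genome.sequences[c]) - L for c in chroms], dtype=float)
    if (weights <= 0).any():
        raise ValueError("chromosome shorter than window length")
    weights /= weights.sum()

    n_neg = int(round(neg_ratio * n_pos))
    worst_gap = 0.0
    for _ in range(n_neg):
        target = pos_gc[rng.integers(n_pos)]
        best_gap = np.inf
        placed = False
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            start = int(rng.integers(0, len(genome.sequences[chrom]) - L + 1))
            if _window_overlaps_peaks(chrom, start, start + L, peaks_by_chrom):
                continue
            seq = genome.fetch(chrom, start, start + L)
            gap = abs(gc_fraction(seq) - target)
            best_gap = min(best_gap, gap)
            if gap <= gc_tolerance:
                seqs.append(seq)
                labels.append(0)
                groups.append(int(rng.integers(n_pos)))  # fold with a random peak
                coords.append((chrom, start, start + L))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot satisfy GC matching within {gc_tolerance:.3f} after "
                f"{max_tries} tries (best achieved {best_gap:.3f})")
        worst_gap = max(worst_gap, best_gap)

    coords_df = pd.DataFrame(coords, columns=["chrom", "start", "end"])
    return TrainingSet(seqs, np.array(labels, dtype=float),
                       np.array(groups), L, coords_df)


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------

def _fingerprint(training: TrainingSet) -> str:
    h = hashlib.sha256()
    for s, y in zip(training.sequences, training.labels):
        h.update(s.encode())
        h.update(b"1" if y else b"0")
    return h.hexdigest()


def _fit_net(config: ModelConfig, x: np.ndarray, y: np.ndarray,
             seed: int) -> ResidualNet:
    net = ResidualNet(config.n_blocks, config.n_filters, config.kernel_size,
                      seed=seed)
    net.fit(x, y, epochs=config.epochs, batch_size=config.batch_size,
            lr=config.learning_rate, seed=seed + 1)
    return net


def _group_folds(groups: np.ndarray, n_folds: int,
                 seed: int) -> list[np.ndarray]:
    """Peak-level folds: all windows sharing a group id land in one fold."""
    rng = np.random.default_rng(seed)
    unique = rng.permutation(np.unique(groups))
    chunks = np.array_split(unique, n_folds)
    return [np.flatnonzero(np.isin(groups, chunk)) for chunk in chunks]


def train_model(config: ModelConfig,
                training: TrainingSet) -> tuple[TrainedAccessibilityModel, EvalReport]:
    """K-fold cross-validated training plus a final refit on all windows."""
    if training.window_length != config.window_length:
        raise ValueError(
            f"window length mismatch: config {config.window_length}, "
            f"data {training.window_length}")
    y = training.labels
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if min(n_pos, n_neg) < 50:
        raise ValueError("need >= 50 examples per class")
    if config.cv_folds > 1 and config.cv_folds > len(y) // 2:
        raise ValueError(
            f"{config.cv_folds} folds infeasible with {len(y)} examples")

    x = encode_batch(training.sequences, training.window_length)
    fold_aurocs = []
    if config.cv_folds > 1:
        folds = _group_folds(training.groups, config.cv_folds, config.seed)
        for k, val_idx in enumerate(folds):
            if len(np.unique(y[val_idx])) < 2:
                continue  # degenerate fold: AUROC undefined
            train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
            net = _fit_net(config, x[train_idx], y[train_idx],
                           seed=config.seed + 1000 + k)
            scores = net.predict_proba(x[val_idx])
            fold_aurocs.append(auroc(scores, y[val_idx]))

    final = _fit_net(config, x, y, seed=config.seed)
    model = TrainedAccessibilityModel(config, final, _fingerprint(training))
    report = EvalReport(fold_aurocs, n_pos, n_neg)
    return model, report


def predict_accessibility(model: TrainedAccessibilityModel,
                          windows: list[str] | np.ndarray) -> np.ndarray:
    """Accessibility scores in [0, 1], order-preserving, batch-invisible."""
    if isinstance(windows, np.ndarray) and windows.ndim == 3:
        x = windows
    else:
        x = encode_batch(list(windows), model.config.window_length)
    if x.shape[0] == 0:
        return np.zeros(0)
    return model.net.predict_proba(x)


def evaluate_heldout(
    model: TrainedAccessibilityModel,
    genome: GenomeSequences,
    peaks: IntervalSet,
    heldout_chrom: str,
    gc_tolerance: float = 0.05,
    seed: int = 0,
) -> tuple[float, int, int]:
    """AUROC on the held-out chromosome: its peak windows vs GC-matched
    peak-free windows from the same chromosome."""
    sub_genome = GenomeSequences(
        {heldout_chrom: genome.sequences[heldout_chrom]})
    sub_peaks = IntervalSet(
        peaks.df[peaks.df["chrom"] == heldout_chrom]).normalize()
    if not len(sub_peaks):
        raise ValueError(f"no peaks on held-out chromosome {heldout_chrom}")
    testset = build_training_set(
        sub_genome, sub_peaks, model.config.window_length,
        gc_tolerance=gc_tolerance, seed=seed)
    scores = predict_accessibility(model, testset.sequences)
    return (auroc(scores, testset.labels),
            int(testset.labels.sum()), int((1 - testset.labels).sum()))


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(random positive outranks random negative),
    ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    import scipy.stats
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Persistence (directory: config JSON + weights NPZ + fingerprint)
# ---------------------------------------------------------------------------

def save_model(model: TrainedAccessibilityModel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(asdict(model.config),
                                                   indent=2))
    np.savez(outdir / "weights.npz", **model.net.state_dict())
    (outdir / "fingerprint.txt").write_text(model.fingerprint + "\n")


def load_model(indir: str | Path) -> TrainedAccessibilityModel:
    indir = Path(indir)
    config = ModelConfig(**json.loads((indir / "config.json").read_text()))
    net = ResidualNet(config.n_blocks, config.n_filters, config.kernel_size,
                      seed=config.seed)
    with np.load(indir / "weights.npz") as npz:
        net.load_state_dict(dict(npz))
    fingerprint = (indir / "fingerprint.txt").read_text().strip()
    return TrainedAccessibilityModel(config, net, fingerprint)
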