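"""Per-cell germline trait-relevance scores (TRS) with permutation nulls.

A cell's TRS aggregates the fine-mapping posterior probabilities (PP) of
sentinel variants falling in that cell's accessible peaks, normalized by the
cell's accessible-peak count so that TRS does not track per-cell depth.
Empirical p-values always use the (1 + k) / (1 + n) estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.stats

from .data_io import AccessibilityMatrix, IntervalSet, map_variants_to_intervals


def select_sentinels(variants: pd.DataFrame) -> pd.DataFrame:
    """One sentinel per LD block: the max-PP variant, ties to smallest
    (chrom, pos)."""
    if not len(variants):
        return variants.copy()
    ordered = variants.sort_values(
        ["ld_block", "pp", "chrom", "pos"],
        ascending=[True, False, True, True],
    )
    return ordered.groupby("ld_block", sort=True).head(1).reset_index(drop=True)


def _peak_weights(sentinels: pd.DataFrame, peaks: IntervalSet) -> np.ndarray:
    """Per-peak summed sentinel PP; sentinels outside all peaks contribute
    nowhere."""
    w = np.zeros(len(peaks))
    if not len(sentinels):
        return w
    idx = map_variants_to_intervals(sentinels["chrom"], sentinels["pos"], peaks)
    inside = idx >= 0
    np.add.at(w, idx[inside], sentinels["pp"].to_numpy()[inside])
    return w


def _trs_from_weights(binary: scipy.sparse.csr_matrix,
                      weights: np.ndarray) -> np.ndarray:
    peak_counts = np.asarray(binary.sum(axis=1)).ravel()
    sums = binary @ weights
    with np.errstate(invalid="ignore", divide="ignore"):
        trs = np.where(peak_counts > 0, sums / np.maximum(peak_counts, 1), 0.0)
    return trs


def compute_trs(matrix: AccessibilityMatrix, sentinels: pd.DataFrame,
                normalize: bool = True) -> pd.DataFrame:
    """TRS per cell.

    With ``normalize`` (default) the sentinel-PP sum is divided by the
    cell's accessible-peak count; raw-sum mode is kept behind the flag.
    Cells with no accessible peaks get TRS 0 and are flagged degenerate.
    """
    binary = matrix.binary
    weights = _peak_weights(sentinels, matrix.peaks)
    peak_counts = np.asarray(binary.sum(axis=1)).ravel()
    sums = binary @ weights
    if normalize:
        trs = np.where(peak_counts > 0, sums / np.maximum(peak_counts, 1), 0.0)
    else:
        trs = sums
    return pd.DataFrame({
        "trs": trs,
        "accessible_peak_count": peak_counts.astype(int),
        "degenerate": peak_counts == 0,
    })


def percell_null(matrix: AccessibilityMatrix, sentinels: pd.DataFrame,
                 n_perm: int, seed: int, normalize: bool = True) -> pd.DataFrame:
    """Empirical per-cell p-values under a uniform sentinel-placement null.

    Each permutation drops the peak-overlapping sentinel PP weights onto
    peaks drawn uniformly without replacement from all peaks; p =
    (1 + #{perm >= obs}) / (n_perm + 1).  Only the weights that contribute
    to the observed TRS (sentinels inside peaks) are reassigned, so the null
    is exchangeable with the observed placement when sentinels are uniform.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    binary = matrix.binary
    n_peaks = len(matrix.peaks)
    idx = map_variants_to_intervals(sentinels["chrom"], sentinels["pos"],
                                    matrix.peaks)
    pp = sentinels["pp"].to_numpy()[idx >= 0]
    m = len(pp)
    obs = compute_trs(matrix, sentinels, normalize=normalize)

    W = np.zeros((n_peaks, n_perm))
    for j in range(n_perm):
        W[rng.choice(n_peaks, size=m, replace=False), j] = rng.permutation(pp)
    peak_counts = obs["accessible_peak_count"].to_numpy()
    perm_sums = binary @ W  # cells x n_perm
    if normalize:
        perm = perm_sums / np.maximum(peak_counts, 1)[:, None]
        perm[peak_counts == 0] = 0.0
    else:
        perm = perm_sums
    k = (perm >= obs["trs"].to_numpy()[:, None]).sum(axis=1)
    out = obs.copy()
    out["p"] = (1 + k) / (n_perm + 1)
    return out


def flag_risk_cells(trs: np.ndarray, q: float = 0.95) -> np.ndarray:
    """Flag cells at or above the empirical q-quantile of TRS (tie-inclusive:
    all-equal input flags every cell)."""
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    trs = np.asarray(trs, dtype=float)
    if trs.size == 0:
        raise ValueError("no cells")
    cutoff = np.quantile(trs, q)
    return trs >= cutoff


def celltype_enrichment(flags: np.ndarray, labels: pd.Series | np.ndarray,
                        n_perm: int, seed: int) -> pd.DataFrame:
    """Per-type enrichment of flagged (risk) cells against a label-shuffle
    null: observed flagged fraction, null mean/SD, Z, empirical p, BH q."""
    flags = np.asarray(flags, dtype=bool)
    labels = np.asarray(labels)
    types, inverse = np.unique(labels, return_inverse=True)
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    if flags.sum() < 1:
        raise ValueError("no flagged cells")
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)

    counts = np.bincount(inverse, minlength=len(types)).astype(float)
    obs = np.bincount(inverse, weights=flags, minlength=len(types)) / counts

    perm_frac = np.empty((n_perm, len(types)))
    for j in range(n_perm):
        shuffled = rng.permutation(flags)
        perm_frac[j] = np.bincount(inverse, weights=shuffled,
                                   minlength=len(types)) / counts
    mean = perm_frac.mean(axis=0)
    sd = perm_frac.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        zs = np.where(sd > 0, (obs - mean) / sd, 0.0)
    p = (1 + (perm_frac >= obs[None, :]).sum(axis=0)) / (n_perm + 1)
    qvals = scipy.stats.false_discovery_control(p, method="bh")
    return pd.DataFrame({
        "cell_type": types,
        "n_cells": counts.astype(int),
        "observed_fraction": obs,
        "null_mean": mean,
        "null_sd": sd,
        "z": zs,
        "p": p,
        "q": qvals,
    })


def pseudotime_trend(trs: np.ndarray, pseudotime: np.ndarray,
                     n_bins: int = 10, n_perm: int = 999,
                     seed: int = 0) -> tuple[pd.DataFrame, float, float]:
    """Monotone trend of TRS along pseudotime.

    Cells are split into equal-count pseudotime bins; the statistic is the
    Spearman rho between bin rank and bin-mean TRS, with an empirical p from
    permuting the cell-to-pseudotime assignment.
    """
    trs = np.asarray(trs, dtype=float)
    pt = np.asarray(pseudotime, dtype=float)
    keep = np.isfinite(pt)
    if not keep.any():
        raise ValueError("all pseudotime values missing")
    trs, pt = trs[keep], pt[keep]
    if not 2 <= n_bins <= len(trs):
        raise ValueError(f"n_bins must be in [2, {len(trs)}], got {n_bins}")
    rng = np.random.default_rng(seed)

    order = np.argsort(pt, kind="stable")
    bin_members = np.array_split(order, n_bins)
    # bin-assignment matrix for vectorized permutation means
    M = np.zeros((n_bins, len(trs)))
    for b, members in enumerate(bin_members):
        M[b, members] = 1.0 / len(members)

    def rho_of(values: np.ndarray) -> float:
        means = M @ values
        return scipy.stats.spearmanr(np.arange(n_bins), means).statistic

    rho = rho_of(trs)
    perm_rhos = np.empty(n_perm)
    for j in range(n_perm):
        perm_rhos[j] = rho_of(rng.permutation(trs))
    p = (1 + (perm_rhos >= rho).sum()) / (n_perm + 1)

    summary = pd.DataFrame({
        "bin": np.arange(n_bins),
        "n_cells": [len(m) for m in bin_members],
        "pseudotime_mid": [pt[m].mean() for m in bin_members],
        "mean_trs": M @ trs,
    })
    return summary, float(rho), float(p)
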