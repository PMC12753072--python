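"""Joint prioritization of regulatory and GWAS scores.

Both scores are log10-|value| transformed with a positive floor.  The joint
model fits marginal Gaussians to the two transformed scores (their observed
correlation R is reported and should be near 0); the joint probability of a
variant is the product of the two marginal CDFs, large only when both scores
are extreme.  Candidates are the variants with joint probability above a
threshold (default 0.90), with no LD pruning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .data_io import IntervalSet, map_variants_to_intervals


def log_abs_transform(values: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """log10(max(|v|, floor)); symmetric in the sign of v."""
    if floor <= 0:
        raise ValueError(f"floor must be > 0, got {floor}")
    return np.log10(np.maximum(np.abs(np.asarray(values, dtype=float)), floor))


@dataclass
class JointModel:
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    r: float
    floor: float


def fit_joint_model(x: np.ndarray, y: np.ndarray,
                    floor: float = 1e-4) -> JointModel:
    """Marginal Gaussian fit to the transformed scores; warns if |R| > 0.1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 100:
        raise ValueError(f"need >= 100 variants to fit, got {len(x)}")
    sd_x, sd_y = x.std(ddof=1), y.std(ddof=1)
    if sd_x == 0 or sd_y == 0:
        raise ValueError("degenerate (constant) score axis")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) > 0.1:
        warnings.warn(f"scores are correlated (R = {r:.3f}); the "
                      "product-of-marginals joint probability assumes "
                      "independence", stacklevel=2)
    return JointModel(float(x.mean()), float(sd_x), float(y.mean()),
                      float(sd_y), r, floor)


def joint_probability(jm: JointModel, x: np.ndarray,
                      y: np.ndarray) -> np.ndarray:
    """Product of marginal Gaussian CDFs, strictly increasing in each score."""
    fx = scipy.stats.norm.cdf((np.asarray(x, dtype=float) - jm.mean_x) / jm.sd_x)
    fy = scipy.stats.norm.cdf((np.asarray(y, dtype=float) - jm.mean_y) / jm.sd_y)
    return fx * fy


def prioritize_variants(scores: pd.DataFrame, floor: float = 1e-4
                        ) -> tuple[pd.DataFrame, JointModel]:
    """Fit the joint model on a scored variant table (deep_score, z) and
    attach x/y transforms and the joint probability."""
    x = log_abs_transform(scores["deep_score"].to_numpy(), floor)
    y = log_abs_transform(scores["z"].to_numpy(), floor)
    jm = fit_joint_model(x, y, floor)
    out = scores.copy().reset_index(drop=True)
    out["log_abs_deep"] = x
    out["log_abs_z"] = y
    out["joint_probability"] = joint_probability(jm, x, y)
    return out, jm


def select_candidates(scored: pd.DataFrame,
                      threshold: float = 0.90) -> pd.DataFrame:
    """Exactly the variants with joint probability > threshold; no LD
    pruning."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return scored[scored["joint_probability"] > threshold].reset_index(drop=True)


def direction_test(candidate_scores: np.ndarray,
                   background_scores: np.ndarray) -> dict:
    """Do candidate risk alleles lean toward chromatin closing?

    One-sided Wilcoxon rank-sum (candidates smaller than background) on the
    risk-oriented scores, plus the fraction of candidates below zero.
    """
    cand = np.asarray(candidate_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    cand = cand[np.isfinite(cand)]
    bg = bg[np.isfinite(bg)]
    if len(cand) == 0 or len(bg) == 0:
        raise ValueError("both groups must be non-empty")
    res = scipy.stats.mannwhitneyu(cand, bg, alternative="less")
    return {
        "median": float(np.median(cand)),
        "p": float(res.pvalue),
        "frac_negative": float((cand < 0).mean()),
        "n_candidates": len(cand),
        "n_background": len(bg),
    }


def annotate_candidates(candidates: pd.DataFrame, genes: pd.DataFrame,
                        upstream: int = 1000,
                        downstream: int = 100) -> pd.DataFrame:
    """Promoter/distal classification against strand-aware TSS windows.

    A variant is 'promoter of G' when it lies within [TSS - upstream,
    TSS + downstream] oriented by G's strand; otherwise 'distal' with the
    nearest gene and signed (TSS-relative, strand-oriented) distance.
    """
    if not len(genes):
        raise ValueError("empty gene annotation")
    out = candidates.copy().reset_index(drop=True)
    feature, nearest, distance = [], [], []
    by_chrom = {c: sub.reset_index(drop=True) for c, sub in genes.groupby("chrom")}
    for _, v in out.iterrows():
        sub = by_chrom.get(v["chrom"])
        if sub is None:
            feature.append("distal")
            nearest.append(None)
            distance.append(np.nan)
            continue
        # signed distance oriented by strand: positive = downstream of TSS
        delta = int(v["pos"]) - sub["tss"].to_numpy()
        oriented = np.where(sub["strand"].to_numpy() == "+", delta, -delta)
        in_window = (oriented >= -upstream) & (oriented <= downstream)
        j = int(np.argmin(np.abs(oriented)))
        if in_window.any():
            k = int(np.flatnonzero(in_window)[
                np.argmin(np.abs(oriented[in_window]))])
            feature.append("promoter")
            nearest.append(sub["gene_id"].iloc[k])
            distance.append(int(oriented[k]))
        else:
            feature.append("distal")
            nearest.append(sub["gene_id"].iloc[j])
            distance.append(int(oriented[j]))
    out["feature_class"] = feature
    out["nearest_gene"] = nearest
    out["tss_distance"] = distance
    return out


def promoter_flags(variants: pd.DataFrame,
                   promoters: IntervalSet) -> np.ndarray:
    """Boolean promoter membership for each variant."""
    idx = map_variants_to_intervals(variants["chrom"], variants["pos"],
                                    promoters)
    return idx >= 0


def promoter_enrichment(candidate_in_promoter: np.ndarray,
                        all_in_promoter: np.ndarray,
                        is_candidate: np.ndarray) -> dict:
    """Fold and Pearson chi-square (no continuity correction) for promoter
    convergence of the candidate set.

    ``all_in_promoter``/``is_candidate`` cover every scanned variant;
    ``candidate_in_promoter`` is the candidate subset's promoter mask.
    fold = promoter fraction among candidates / promoter fraction overall.
    """
    cand = np.asarray(candidate_in_promoter, dtype=bool)
    allp = np.asarray(all_in_promoter, dtype=bool)
    isc = np.asarray(is_candidate, dtype=bool)
    if cand.sum() + (~cand).sum() == 0:
        raise ValueError("empty candidate set")
    noncand_prom = int(allp[~isc].sum())
    noncand_non = int((~allp[~isc]).sum())
    table = np.array([
        [int(cand.sum()), int((~cand).sum())],
        [noncand_prom, noncand_non],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 margin in {table.tolist()}")
    chi2, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    overall_frac = allp.mean()
    cand_frac = cand.mean()
    return {
        "fold": float(cand_frac / overall_frac) if overall_frac > 0 else np.inf,
        "chi2": float(chi2),
        "p": float(p),
        "candidate_promoter_fraction": float(cand_frac),
        "overall_promoter_fraction": float(overall_frac),
        "table": table,
    }


def threshold_sweep(scored: pd.DataFrame, promoters: IntervalSet,
                    thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Candidate count and promoter fraction across joint-probability
    thresholds (default grid 0.05 ... 0.95 step 0.05)."""
    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 0.951, 0.05), 2)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold list")
    if ((thresholds < 0) | (thresholds > 1)).any():
        raise ValueError("thresholds must be in [0, 1]")
    in_prom = promoter_flags(scored, promoters)
    rows = []
    jp = scored["joint_probability"].to_numpy()
    for t in thresholds:
        sel = jp > t
        n = int(sel.sum())
        frac = float(in_prom[sel].mean()) if n else np.nan
        rows.append((t, n, frac))
    return pd.DataFrame(rows,
                        columns=["threshold", "n_selected", "promoter_fraction"])
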