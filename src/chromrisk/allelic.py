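"""In-silico allelic effect scores on predicted chromatin accessibility.

For each SNV the trained model scores a ref-allele and an alt-allele window;
``deep_score = p_alt - p_ref`` (alt-oriented, negative = chromatin closing).
The risk-oriented score flips the sign so it describes the risk allele: for
z > 0 the risk allele is alt and the score is unchanged, for z < 0 the risk
allele is ref and the score is negated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .chromatin_model import TrainedAccessibilityModel, predict_accessibility
from .data_io import GenomeSequences


class ReferenceMismatchError(ValueError):
    pass


def make_allele_windows(genome: GenomeSequences, chrom: str, pos: int,
                        ref: str, alt: str, L: int) -> tuple[str, str]:
    """Ref/alt windows of length L with the variant at 0-based offset L/2;
    chromosome-end overhangs are N-padded."""
    if not 1 <= pos <= len(genome.sequences[chrom]):
        raise ValueError(f"position {pos} outside {chrom}")
    found = genome.base_at(chrom, pos)
    if found != ref:
        raise ReferenceMismatchError(
            f"reference mismatch at {chrom}:{pos}: found {found}, expected {ref}")
    offset = L // 2
    start = (pos - 1) - offset
    window = genome.fetch(chrom, start, start + L)
    ref_window = window
    alt_window = window[:offset] + alt + window[offset + 1:]
    return ref_window, alt_window


def scan_variants(model: TrainedAccessibilityModel, genome: GenomeSequences,
                  variants: pd.DataFrame, L: int | None = None) -> pd.DataFrame:
    """AllelicScore table for every variant, input order preserved.

    Scores are identical whether variants are scored singly or in batch:
    prediction is per-window deterministic.
    """
    L = L if L is not None else model.config.window_length
    if L != model.config.window_length:
        raise ValueError(
            f"model window length {model.config.window_length} != requested {L}")
    ref_windows, alt_windows = [], []
    for _, v in variants.iterrows():
        rw, aw = make_allele_windows(genome, v["chrom"], int(v["pos"]),
                                     v["ref"], v["alt"], L)
        ref_windows.append(rw)
        alt_windows.append(aw)
    p_ref = predict_accessibility(model, ref_windows)
    p_alt = predict_accessibility(model, alt_windows)
    out = variants.copy().reset_index(drop=True)
    out["p_ref"] = p_ref
    out["p_alt"] = p_alt
    out["deep_score"] = p_alt - p_ref
    out["abs_score"] = np.abs(out["deep_score"])
    oriented, risk_allele = orient_to_risk(out["deep_score"].to_numpy(),
                                           out["z"].to_numpy())
    out["risk_oriented_score"] = oriented
    out["risk_allele"] = risk_allele
    return out


def score_variant(model: TrainedAccessibilityModel, genome: GenomeSequences,
                  variant: pd.Series, L: int | None = None) -> pd.Series:
    return scan_variants(model, genome, variant.to_frame().T, L).iloc[0]


def orient_to_risk(deep_score: np.ndarray,
                   z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Risk-oriented score and risk-allele identity from the signed GWAS Z.

    z > 0: risk allele is alt, score unchanged; z < 0: risk allele is ref,
    score negated; z == 0: orientation undefined, score NaN with a warning.
    """
    deep_score = np.asarray(deep_score, dtype=float)
    z = np.asarray(z, dtype=float)
    if (z == 0).any():
        warnings.warn(f"{int((z == 0).sum())} variant(s) with z == 0 excluded "
                      "from risk orientation", stacklevel=2)
    oriented = np.where(z > 0, deep_score,
                        np.where(z < 0, -deep_score, np.nan))
    risk_allele = np.where(z > 0, "alt", np.where(z < 0, "ref", "none"))
    return oriented, risk_allele


def stratify_scores_by_class(
    abs_scores: np.ndarray, classes: np.ndarray
) -> tuple[dict[str, float], float, bool]:
    """eQTL-style stratification of |score| by confidence class.

    Classes are 'HC', 'LC', 'non'; returns per-class medians, the one-sided
    Wilcoxon rank-sum p for HC > non, and whether the medians are monotone
    HC >= LC >= non.
    """
    abs_scores = np.asarray(abs_scores, dtype=float)
    classes = np.asarray(classes)
    groups = {}
    for name in ("HC", "LC", "non"):
        vals = abs_scores[classes == name]
        if len(vals) == 0:
            raise ValueError(f"class {name!r} is empty")
        groups[name] = vals
    medians = {name: float(np.median(v)) for name, v in groups.items()}
    monotone = medians["HC"] >= medians["LC"] >= medians["non"]
    p = scipy.stats.mannwhitneyu(groups["HC"], groups["non"],
                                 alternative="greater").pvalue
    return medians, float(p), monotone
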