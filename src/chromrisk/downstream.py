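"""Category-based heritability enrichment and downstream gene-level tests.

The heritability estimator is the unit-LD-score limit of stratified LD score
regression, appropriate for unlinked variants: the per-SNP association
signal is z^2 - 1 (expectation 0 under the null, N*h2/M under polygenicity),
a category's heritability share is its share of the total signal, and
enrichment is that share divided by the category's SNP share.  Uncertainty
comes from a leave-one-block-out jackknife over contiguous position blocks,
mirroring the block-jackknife convention of LD score regression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .data_io import SignalTrack


def build_heritability_categories(variants: pd.DataFrame,
                                  candidate_ids: set | np.ndarray) -> pd.Series:
    """Three-way partition: A = candidates, B = non-candidates with |z| at or
    above the candidates' minimum |z|, C = the rest."""
    candidate_ids = set(candidate_ids)
    if not candidate_ids:
        raise ValueError("empty candidate set")
    is_a = variants["id"].isin(candidate_ids).to_numpy()
    zmin = np.abs(variants.loc[is_a, "z"]).min()
    absz = np.abs(variants["z"].to_numpy())
    cats = np.where(is_a, "A", np.where(absz >= zmin, "B", "C"))
    return pd.Series(cats, index=variants.index, name="category")


def heritability_enrichment(z: np.ndarray, categories: np.ndarray,
                            n_jackknife_blocks: int = 100) -> pd.DataFrame:
    """Per-category heritability share, SNP share, enrichment, jackknife SE.

    Variants are assumed position-ordered; jackknife blocks are contiguous
    slices in that order.
    """
    z = np.asarray(z, dtype=float)
    categories = np.asarray(categories)
    signal = z ** 2 - 1
    total = signal.sum()
    if total <= 0:
        raise ValueError(
            f"non-positive total heritability signal ({total:.2f}); "
            "enrichment undefined")
    names = [c for c in pd.unique(categories)]
    n = len(z)
    onehot = {c: (categories == c).astype(float) for c in names}

    def estimates(mask: np.ndarray) -> dict[str, float]:
        tot = signal[mask].sum()
        out = {}
        for c in names:
            sel = onehot[c][mask].astype(bool)
            snp_share = sel.mean()
            h2_share = signal[mask][sel].sum() / tot
            out[c] = h2_share / snp_share if snp_share > 0 else np.nan
        return out

    full = estimates(np.ones(n, dtype=bool))

    blocks = np.array_split(np.arange(n), n_jackknife_blocks)
    jack = {c: [] for c in names}
    for block in blocks:
        mask = np.ones(n, dtype=bool)
        mask[block] = False
        est = estimates(mask)
        for c in names:
            jack[c].append(est[c])
    rows = []
    for c in names:
        vals = np.array(jack[c], dtype=float)
        ok = np.isfinite(vals)
        nb = ok.sum()
        se = (np.sqrt((nb - 1) / nb * ((vals[ok] - vals[ok].mean()) ** 2).sum())
              if nb > 1 else np.nan)
        sel = onehot[c].astype(bool)
        rows.append({
            "category": c,
            "n_snps": int(sel.sum()),
            "snp_share": float(sel.mean()),
            "h2_share": float(signal[sel].sum() / total),
            "enrichment": float(full[c]),
            "jackknife_se": float(se),
        })
    return pd.DataFrame(rows)


def dosage_sensitivity_test(candidate_genes: list[str],
                            background_genes: list[str],
                            scores: pd.DataFrame) -> dict:
    """One-sided Wilcoxon rank-sum (candidates greater) on haploinsufficiency
    scores; unscored genes are dropped with a warning."""
    table = dict(zip(scores["gene_id"], scores["score"]))
    cand = [table[g] for g in candidate_genes if g in table]
    bg = [table[g] for g in background_genes if g in table]
    dropped = (len(candidate_genes) - len(cand)) + (len(background_genes) - len(bg))
    if dropped:
        warnings.warn(f"{dropped} gene(s) unscored and dropped", stacklevel=2)
    if not cand or not bg:
        raise ValueError("no scored genes in one of the groups")
    res = scipy.stats.mannwhitneyu(cand, bg, alternative="greater")
    return {
        "median_candidates": float(np.median(cand)),
        "median_background": float(np.median(bg)),
        "p": float(res.pvalue),
        "n_candidates": len(cand),
        "n_background": len(bg),
        "n_dropped": dropped,
    }


def gene_set_overlap_test(candidate_genes: set | list,
                          target_set: set | list,
                          universe: set | list) -> dict:
    """Hypergeometric upper-tail p for overlap of the candidate genes with a
    target gene set within a stated universe."""
    universe = set(universe)
    candidate_genes = set(candidate_genes)
    target_set = set(target_set)
    for name, group in [("candidate", candidate_genes), ("target", target_set)]:
        outside = group - universe
        if outside:
            raise ValueError(
                f"{name} gene(s) outside universe: {sorted(outside)[:5]}")
    overlap = len(candidate_genes & target_set)
    n_univ, n_targ, n_cand = len(universe), len(target_set), len(candidate_genes)
    p = float(scipy.stats.hypergeom.sf(overlap - 1, n_univ, n_targ, n_cand))
    return {"overlap": overlap, "p": p, "n_candidates": n_cand,
            "n_targets": n_targ, "n_universe": n_univ}


def tss_metaprofile(track: SignalTrack, genes: pd.DataFrame,
                    chrom_lengths: dict[str, int], flank: int = 3000,
                    bin_size: int = 50, background_draws: int = 100,
                    seed: int = 0) -> dict:
    """Length-weighted mean signal in fixed bins across TSS-centered windows.

    Minus-strand genes are reversed so bin 0 is always 5'-most; the
    background profile repeats the procedure at random positions.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin size")
    n_bins = 2 * flank // bin_size
    rng = np.random.default_rng(seed)

    # dense per-chromosome coverage arrays (synthetic genomes are small)
    coverage = {c: np.zeros(l) for c, l in chrom_lengths.items()}
    for _, row in track.df.iterrows():
        arr = coverage.get(row["chrom"])
        if arr is not None:
            arr[int(row["start"]):min(int(row["end"]), len(arr))] = row["value"]

    def window_profile(chrom: str, center0: int, minus: bool) -> np.ndarray | None:
        start, end = center0 - flank, center0 + flank
        arr = coverage.get(chrom)
        if arr is None or start < 0 or end > len(arr):
            return None
        prof = arr[start:end].reshape(n_bins, bin_size).mean(axis=1)
        return prof[::-1] if minus else prof

    profiles, kept = [], []
    for _, g in genes.iterrows():
        prof = window_profile(g["chrom"], int(g["tss"]) - 1,
                              g["strand"] == "-")
        if prof is None:
            warnings.warn(f"gene {g['gene_id']} window off-chromosome; dropped",
                          stacklevel=2)
            continue
        profiles.append(prof)
        kept.append(g["gene_id"])
    if not profiles:
        raise ValueError("no gene window fits any chromosome")
    matrix = np.vstack(profiles)

    names = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in names], dtype=float)
    weights = lens / lens.sum()
    bg = []
    while len(bg) < background_draws:
        chrom = names[rng.choice(len(names), p=weights)]
        center = int(rng.integers(flank, chrom_lengths[chrom] - flank))
        prof = window_profile(chrom, center, False)
        if prof is not None:
            bg.append(prof)
    return {
        "gene_ids": kept,
        "matrix": matrix,
        "mean_profile": matrix.mean(axis=0),
        "background_profile": np.vstack(bg).mean(axis=0),
        "bin_size": bin_size,
        "flank": flank,
    }


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return scipy.stats.false_discovery_control(p, method="bh")
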