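# chromrisk

Chromatin-informed mapping of germline cancer risk onto single cells, and
fine-mapping of the regulatory alleles that carry it.

Most germline risk variants for common cancers are noncoding, so their
effects are mediated by the regulatory landscape of particular cell types.
`chromrisk` implements, as a tested end-to-end pipeline, the two halves of
that mapping problem for single-cell ATAC-seq + GWAS integration:

1. **Which cells carry the risk?** Per-cell trait-relevance scores (TRS)
   aggregate GWAS fine-mapping posteriors over each cell's open chromatin,
   with permutation nulls at the cell and cell-type level and a pseudotime
   trend test along a differentiation lineage.
2. **Which alleles do the damage?** A residual convolutional network learns
   to recognize the sequence determinants of open chromatin; each SNV is
   scored by the predicted accessibility difference between its two alleles,
   and variants are prioritized by the joint distribution of regulatory and
   GWAS evidence, followed by direction, promoter-convergence, heritability
   and gene-level statistics.

The package is aimed at statistical/regulatory genomicists who want the
method components individually (each is a plain function over standard
containers) or the whole pipeline with planted-truth validation. Every
stage runs on synthetic data with known ground truth — no downloads — so
all statistical claims the pipeline makes are checked by recovery tests.

## The statistics at the core

**Trait-relevance score.** With binary accessibility $b_{cp} \in \{0,1\}$
for cell $c$ and peak $p$, and one sentinel variant per LD block (the
max-posterior variant, posterior $\pi_s$, in peak $p(s)$),

$$\mathrm{TRS}_c \;=\; \frac{\sum_{s\,:\,b_{c,p(s)}=1} \pi_s}{\sum_p b_{cp}}.$$

Cells in the top 5% of TRS are risk-flagged; each cell type's flagged
fraction is compared with a label-shuffle null (Z, empirical p, BH q). The
per-cell null reassigns the in-peak sentinel weights to uniformly drawn
peaks; empirical p-values are always $(1+k)/(1+n)$.

**Allelic effect score.** A trained network $f$ maps a one-hot $L\times4$
window to an accessibility probability. For a SNV with ref/alt windows
$w_\mathrm{ref}, w_\mathrm{alt}$ centered on the variant,

$$\Delta = f(w_\mathrm{alt}) - f(w_\mathrm{ref}) \in [-1, 1],$$

negative $\Delta$ meaning the alt allele closes chromatin. The
risk-oriented score flips the sign when the GWAS Z is negative (risk allele
= ref).

**Joint prioritization.** With $x = \log_{10}\max(|\Delta|, \epsilon)$ and
$y = \log_{10}\max(|Z|, \epsilon)$, marginal Gaussians are fitted and the
joint probability is the product of marginal CDFs
$\Phi\!\left(\frac{x-\mu_x}{\sigma_x}\right)\Phi\!\left(\frac{y-\mu_y}{\sigma_y}\right)$
(the two scores are checked to be near-independent). Variants above 0.90
are candidates; downstream statistics include a Wilcoxon direction test, a
chi-square promoter enrichment, a three-category heritability enrichment in
the no-LD limit (per-SNP signal $z^2-1$, block-jackknife SEs), dosage
sensitivity and gene-set overlap tests, and TSS meta-profiles.

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
default synthetic landscape (seed 1) and write their tables to `results/`:

```bash
python analysis/01_simulate_landscape.py
python analysis/02_cell_risk_map.py
python analysis/03_train_accessibility_model.py
python analysis/04_score_allelic_effects.py
python analysis/05_prioritize_candidates.py
python analysis/06_downstream_statistics.py
```

which prints, stage by stage:

```
simulated landscape: 1264 peaks, 600 cells, 2000 variants
risk concentrates in LE2 (Z = 9.88); 1 significant type(s); pseudotime trend rho = 0.952 (p = 0.001)
CV AUROC = 0.953 over 5 folds; held-out chrB AUROC = 0.940 (197 pos / 197 neg)
median |effect|: functional 0.359 vs neutral 0.0044; 100% of motif-breaking alt alleles close chromatin
77 candidate loci (joint probability > 0.90); R = 0.167; risk alleles negative in 78% (rank-sum p = 1.3e-16); promoter fold = 4.81 (chi-square p = 2.8e-68)
category A: 21.0-fold heritability enrichment (SE 2.5); dosage-sensitivity p = 3.9e-27; target-set overlap p = 1.4e-40; TSS signal ratio = 5.66
```

Reading this: the terminal luminal type (LE2), the only type whose peaks
carry planted risk variants, is the unique significantly enriched type and
risk rises monotonically along the lineage; the network recognizes the
planted motif on a never-seen chromosome; motif-breaking alleles score
negative; and the 77 selected candidates (all truly functional here, 78%
with chromatin-closing risk alleles — the planted closing fraction is 0.8)
concentrate in promoters and carry the heritability excess.

The same pipeline is exposed as a CLI
(`chromrisk run-all --seed 1 --outdir runs/demo`, with per-stage
subcommands `simulate`, `cellrisk`, `train`, `score`, `prioritize`,
`downstream`, `report`), driven by a YAML config
(`chromrisk init-config --out config.yaml`). Real inputs (FASTA, BED,
MTX/TSV, GWAS TSV, bedGraph) can replace the simulated bundle by dropping
them into the run's `inputs/` directory in the same formats.

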