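# Methods

This note documents the models and procedures `chromrisk` implements, the
synthetic study conditions every test runs under, and the numerical choices
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

Intervals (peaks, promoters, signal tracks) are BED-style 0-based
half-open; variants are VCF-style 1-based. The single conversion rule — a
variant at 1-based position `p` overlaps `[s, e)` iff `s <= p-1 < e` —
lives in `data_io.variant_overlaps_interval` and is used everywhere.
Soft-masked (lowercase) FASTA input is uppercased, not excluded.

## Trait-relevance scoring

A sentinel variant per LD block is the block's maximum-posterior variant,
ties broken by smallest (chrom, pos). A cell's TRS is the sum of sentinel
posteriors over the cell's accessible peaks divided by its accessible-peak
count. The normalization is deliberate: the raw sum grows with per-cell
peak count, i.e. with sequencing depth, and the quantity of interest is
risk concentration, not coverage. The unnormalized sum remains available
(`normalize=False`).

Three permutation nulls, all using the $(1+k)/(1+n)$ estimator so p-values
never reach 0:

- **Per-cell**: each permutation reassigns the *in-peak* sentinel weights
  to peaks drawn uniformly without replacement. Only the weights that
  contribute to the observed score are reassigned; reassigning every
  sentinel's weight (including those outside any peak) would put strictly
  more mass on peaks under the null than in the observed configuration and
  bias the p-values upward. With all peaks of equal length and sentinel
  positions uniform, this null is exchangeable with the observed placement,
  and the p-values calibrate (the acceptance suite checks the 5% rejection
  rate). The statistic is effectively continuous only when several
  sentinels fall in peaks; with very sparse weights the test is
  conservative (ties at TRS = 0), never anticonservative.
- **Cell-type**: cells with TRS at or above the empirical 0.95 quantile are
  risk-flagged (tie-inclusive, so a degenerate all-equal input flags every
  cell); each type's flagged fraction is compared against label shuffles
  (Z from the null mean/SD, empirical p, BH q across types).
- **Pseudotime trend**: cells are split into equal-count pseudotime bins
  (quantile bins are robust to pseudotime density; the bin count defaults
  to 10); the statistic is Spearman's rho between bin rank and bin-mean
  TRS, with p from permuting the cell-to-pseudotime assignment. Pseudotime
  is taken as input, never inferred.

Network propagation over a cell-cell kNN graph (as some published
trait-relevance methods add) is intentionally not implemented; aggregation
plus permutation is the tested procedure.

## Sequence -> accessibility model

Architecture: one-hot $L \times 4$ input (A/C/G/T columns, N rows all-zero)
-> stem convolution + batch norm + ReLU -> residual blocks
(conv-BN-ReLU-conv-BN plus identity skip, ReLU) -> global max pooling over
positions -> dense sigmoid logit. Implemented directly in NumPy with
explicit backprop; convolutions are im2col matmuls so the arithmetic runs
in BLAS. Training is Adam on binary cross-entropy, bit-reproducible for a
fixed (seed, config, data) triple. Prediction uses batch-norm running
statistics, so results are independent of batch slicing (up to the last
float bit of BLAS summation order).

Defaults: the library default is 3 blocks x 64 filters on 1000 bp windows
(typical for accessibility models); the `small` preset used by the demo
pipeline and the tests is 1 block x 32 filters, kernel 11, 200 bp windows,
12 epochs, lr 5e-3, batch 32. The filter count matters: with a global max
pool the gradient reaching a convolution filter is sparse, and 16-filter
nets occasionally fail to discover the planted motif from an unlucky
initialization; 32 filters trains reliably across seeds.

Training windows: positives centered on peak midpoints; negatives
genome-wide windows with zero peak overlap, each GC-matched within 0.05 to
a randomly drawn positive (the standard guard against the model learning
GC content), at 1:1 by default. Cross-validation partitions windows at the
peak level (a peak's window appears in exactly one fold; each negative
follows a randomly assigned peak), preventing leakage; one whole chromosome
is excluded from training and used for final evaluation. No
reverse-complement augmentation by default, keeping evaluation
deterministic; the synthetic motifs are planted on the forward strand.
AUROC uses the Mann-Whitney identity with ties counted 1/2, verified
exactly against an all-pairs oracle.

## Allelic scoring

Ref and alt windows of length $L$ place the variant at 0-based offset
$L/2$ (centering maximizes receptive-field symmetry); windows overhanging a
chromosome end are N-padded. The allelic score is
$f(\mathrm{alt}) - f(\mathrm{ref})$, so it is exactly antisymmetric under
swapping the alleles (and re-validating against a genome carrying the other
base). Risk orientation follows the sign of the effect-allele Z: $z > 0$
means the alt allele is the risk allele and the score is kept; $z < 0$
flips it; $z = 0$ is excluded with a warning. eQTL-style validation
stratifies $|\Delta|$ by confidence class and tests high-confidence vs
non-eQTLs with a one-sided rank-sum; the low-confidence class is reported
descriptively.

## Joint prioritization

Both scores are $\log_{10}\max(|v|, \epsilon)$ transformed. The floor
$\epsilon$ defaults to `1e-4`: the allelic score is a difference of two
bounded probabilities, and differences below ~1e-4 are numerical noise
(ties at exactly 0 occur); a much smaller floor lets that noise stretch the
lower tail of $\log|\Delta|$ and inflate its fitted SD until no variant can
exceed the selection threshold. The floor is per-call configurable.

The joint model fits marginal Gaussian means/SDs and reports the Pearson
correlation R between the two transformed scores, warning when |R| > 0.1;
the joint probability is the product of marginal CDFs, which is exact under
independence and is strictly increasing in each score. A bivariate form is
deliberately not fitted: on planted data the functional minority induces
a mild positive R, and the product rule keeps selection interpretable as
"extreme in both margins". Candidates are variants with joint probability
above 0.90, with no LD pruning. Under the global null the selected
fraction at threshold $t$ is $1 - t + t\ln t$ (the tail mass of a product
of independent uniforms), which the acceptance suite verifies by Monte
Carlo at $n = 10^6$.

Promoter annotation is strand-aware: a variant is in the promoter of a
gene when it lies within [TSS-1000, TSS+100] oriented by the gene's
strand (the convention of the usual promoter annotators); otherwise it is
distal, with nearest gene and signed TSS-relative distance. Promoter
enrichment is a Pearson chi-square without continuity correction on the
candidate x promoter 2x2 table, with fold = candidate promoter fraction
over the overall promoter fraction.

## Heritability enrichment

Implemented in the unit-LD-score limit, which is exact for the unlinked
synthetic variants: the per-SNP association signal is $z^2 - 1$
(expectation 0 for a null SNP), a category's heritability share is its
share of the total signal, and enrichment is heritability share divided by
SNP share. Categories follow the three-way design: A = candidates, B =
non-candidates with $|z|$ at or above the minimum candidate $|z|$, C = the
rest. SEs come from a leave-one-block-out jackknife over 100 contiguous
position-ordered blocks, mirroring the block-jackknife convention of LD
score regression. The estimator requires positive total signal
$\sum(z^2-1)$ and raises otherwise — which is why the calibration null is
a *uniform polygenic background* ($z \sim N(0, \sqrt{1.1})$ for every SNP):
every category then shares the same per-SNP heritability, the expected
enrichment is 1 for each, and the precondition holds almost surely. A
fully signal-free null ($z \sim N(0,1)$ everywhere) has non-positive total
signal with probability 1/2 and no defined enrichment.

Gene-level tests: dosage sensitivity is a one-sided rank-sum (candidates
greater) on haploinsufficiency scores, dropping unscored genes with a
warning; gene-set overlap is the hypergeometric upper tail within an
explicit universe. TSS meta-profiles average bedGraph coverage in 50 bp
bins across TSS +/- 3 kb windows (length-weighted within bins), reversing
minus-strand genes so bin 0 is always 5'-most, with a background profile
from random matched positions.

## Synthetic study conditions

The generator produces every input the pipeline consumes, with planted
ground truth. Defaults (the conditions all recovery tests run under):

- Genome: two chromosomes of 4 Mb, i.i.d. bases at GC 0.41. The size is
  chosen so that promoter windows (one synthetic gene per peak, TSS at the
  peak midpoint, alternating strand) cover a minority of the genome —
  on a much smaller genome promoter annotation saturates and promoter
  enrichment is undefined in practice.
- Four cell types (BE, club, LE1, LE2) along a differentiation lineage,
  each with 400 peaks of 200 bp: 10% shared housekeeping peaks (no motif),
  the rest private peaks each carrying one exact copy of that type's 8 bp
  consensus motif written into the genome (AP-1-, E-box-, GATA- and
  forkhead-like). Motifs are exact strings, not PWMs, so planted-signal
  recovery is unambiguous. Peaks are disjoint and at least one peak length
  apart.
- **Lineage gradient**: a type at lineage rank $r$ of $R$ owns, inside its
  fixed 400-peak budget, a nested fraction $0.6\,r/(R-1)$ of the terminal
  (vulnerable) type's motif peaks (0 / 0.2 / 0.4 for BE / club / LE1).
  This emulates progressive activation of terminal-type regulatory
  elements along differentiation and is what makes germline risk rise
  *monotonically* along pseudotime rather than jumping at the terminal
  state; with a flat-flat-flat-high profile the expected 10-bin Spearman
  rho is only ~0.64 by the rank-expectation formula, which would
  misrepresent a genuinely monotone trend. The gradient is small enough
  that the terminal type remains the unique significantly enriched type
  (verified by the recovery tests).
- Cells: 150 per type; a cell captures each of its own peaks with
  probability 0.9 and any other peak with probability 0.02, independently;
  pseudotime is uniform within a type, offset by lineage rank.
- GWAS: 2,000 variants, 5% functional. Functional variants sit at distinct
  motif bases inside the vulnerable type's peaks with ref = the planted
  consensus base and alt != consensus (so alt always breaks the motif);
  $|z| \sim |N(4,1)|$, sign positive (risk allele = the motif-breaking
  alt, planted direction -1) with probability 0.8, posterior
  $\sim U(0.5, 1)$. Neutral variants are uniform outside motif footprints
  with $z \sim N(0,1)$ and posterior $\sim U(0, 0.1)$. LD blocks are 100
  equal-width positional bins — block ids are only consumed by sentinel
  selection, so realistic LD structure is out of scope.
- Downstream inputs: a haploinsufficiency table in which genes whose peak
  hosts a functional variant draw from Beta(4,2) and others from Beta(2,4);
  a target gene set = the vulnerable type's peak genes; and a ChIP-like
  bedGraph with value 6 over vulnerable peaks on a baseline of 1.

Everything is byte-deterministic under the spec's seed; each generator
draws from its own seeded stream so stages can be re-run independently.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: LD between variants, PWM-like motif degeneracy
and strandedness, read-level counts (the matrix is binary), doublets,
batch effects, chromatin co-accessibility structure beyond the planted
type/lineage design, and realistic genome composition (repeats, CpG
islands). Recovery results on this landscape demonstrate correctness of
the estimators, not expected effect sizes on real tissue.

## Pipeline and problem sizes

Stages communicate through files in a run directory; a manifest records
parameters and SHA-256 hashes of all inputs and outputs, so re-running a
completed stage with identical parameters is a no-op and deleting an
output rebuilds it bit-identically. Per-stage seeds derive from
SHA-256(global seed, stage name), so adding a stage never perturbs another
stage's randomness. End-to-end reruns under a fixed seed are
byte-identical.

The demo configuration uses the default landscape with the small model
preset and 5 CV folds; the library default of 20 folds is available via
config. The acceptance script runs the full pipeline plus two standalone
estimator checks (joint-selection null at $n = 10^6$, planted heritability
recovery at $n = 10^5$) in a few minutes on one CPU. Calibration tests in
the suite pool 500-2,500 simulated replicates per null.

## Known limitations

- The joint-probability functional form (product of marginal Gaussian
  CDFs) is one defensible reading of a "2D Gaussian" selection rule;
  empirical-tail alternatives would select fewer variants at the same
  threshold. The transform floor interacts with the classifier's score
  resolution, as discussed above.
- The heritability estimator is the no-LD special case; with linked
  variants it would require LD scores and a regression, not a share ratio.
- The NumPy network is deliberately small; it is adequate for exact
  planted motifs but is not a drop-in for genome-scale accessibility
  models (no GPU path, no multi-task heads, no quantitative regression).
- The per-cell TRS null is conservative for cells whose accessible peaks
  carry no sentinel weight (ties at zero); interpretation of per-cell p
  near 1 should account for this.
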