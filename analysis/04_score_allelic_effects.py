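"""Score every variant's allelic effect on predicted accessibility.

For each SNV the model scores a ref- and an alt-allele window; the signed
difference (alt - ref) is the allelic effect, negative meaning the alt
allele closes chromatin. Scores are then oriented to the risk allele using
the sign of the GWAS Z.
"""

import importlib

import pandas as pd

common = importlib.import_module("00_common")

run = common.get_run(__doc__)
run.simulate()
run.train()
run.score()
scored = pd.read_csv(run.path("allelic_scores.tsv"), sep="\t")
func = scored[scored.is_functional == 1]
neut = scored[scored.is_functional == 0]
print(f"median |effect|: functional {func.abs_score.median():.3f} vs "
      f"neutral {neut.abs_score.median():.4f}; "
      f"{(func.deep_score < 0).mean():.0%} of motif-breaking alt alleles "
      "close chromatin")
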