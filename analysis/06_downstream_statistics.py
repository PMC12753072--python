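"""Downstream statistics for the candidate loci.

Partitions heritability across candidates (A), high-|Z| non-candidates (B)
and the rest (C) in the no-LD limit with block-jackknife errors; tests
candidate genes for dosage sensitivity and target-set overlap; and builds
the TSS meta-profile of the ChIP-like signal track.
"""

import importlib
import json

import pandas as pd

common = importlib.import_module("00_common")

run = common.get_run(__doc__)
for stage in ("simulate", "train", "score", "prioritize", "downstream"):
    getattr(run, stage)()
herit = pd.read_csv(run.path("heritability.tsv"), sep="\t")
s = json.loads(run.path("downstream_summary.json").read_text())
a = herit.set_index("category").loc["A"]
print(f"category A: {a['enrichment']:.1f}-fold heritability enrichment "
      f"(SE {a['jackknife_se']:.1f}); dosage-sensitivity p = "
      f"{s['dosage_sensitivity']['p']:.2g}; target-set overlap p = "
      f"{s['gene_set_overlap']['p']:.2g}; TSS signal ratio = "
      f"{s['tss_signal_ratio']:.2f}")
common.publish(run, "heritability.tsv", "downstream_summary.json",
               "tss_profile.tsv")
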