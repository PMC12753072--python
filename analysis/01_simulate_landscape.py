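"""Generate the synthetic study landscape.

Builds the full input bundle: an 8 Mb two-chromosome genome; four epithelial
cell types along a differentiation lineage, each with 400 open-chromatin
peaks carrying that type's planted motif; a noisy binary cell x peak matrix
(600 cells, capture 0.9 / noise 0.02); and 2,000 GWAS variants of which 5%
are functional -- placed on motif bases inside the terminal (vulnerable)
type's peaks with |Z| ~ N(4,1) and high fine-mapping posteriors.
"""

import importlib
import json

common = importlib.import_module("00_common")

run = common.get_run(__doc__)
run.simulate()
inputs = run.path("inputs")
n_peaks = sum(1 for _ in open(inputs / "peaks.bed"))
n_variants = sum(1 for _ in open(inputs / "variants.tsv")) - 1
n_cells = sum(1 for _ in open(inputs / "cells.tsv")) - 1
print(f"simulated landscape: {n_peaks} peaks, {n_cells} cells, "
      f"{n_variants} variants ({inputs})")
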