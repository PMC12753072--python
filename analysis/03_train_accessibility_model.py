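"""Train the sequence -> accessibility classifier for the vulnerable type.

Fits the residual conv net on 200 bp windows centered on the vulnerable
type's peaks against GC-matched background windows, holding out one whole
chromosome; reports cross-validated and held-out-chromosome AUROC.
"""

import importlib
import json

common = importlib.import_module("00_common")

run = common.get_run(__doc__)
run.simulate()
run.train()
ev = json.loads(run.path("model_eval.json").read_text())
print(f"CV AUROC = {ev['cv_auroc_mean']:.3f} over {len(ev['fold_aurocs'])} "
      f"folds; held-out {ev['heldout_chrom']} AUROC = "
      f"{ev['heldout_auroc']:.3f} ({ev['n_pos']} pos / {ev['n_neg']} neg)")
common.publish(run, "model_eval.json")
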