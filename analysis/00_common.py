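"""Shared plumbing for the numbered analysis drivers.

All drivers operate on one pipeline run directory (``scratch/analysis`` by
default, override with --outdir) and copy their small result tables into
``results/``.  Stages already up to date (hash match in the manifest) are
not recomputed, so the drivers can be run in order or individually.
"""

import argparse
import shutil
from pathlib import Path

from chromrisk import pipeline

REPO = Path(__file__).resolve().parents[1]
RESULTS = REPO / "results"


def get_run(description: str) -> pipeline.PipelineRun:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path,
                        default=REPO / "scratch" / "analysis")
    args = parser.parse_args()
    config = pipeline.default_config()
    config["seed"] = args.seed
    return pipeline.PipelineRun(config, args.outdir)


def publish(run: pipeline.PipelineRun, *names: str) -> None:
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        shutil.copy(run.path(name), RESULTS / name)
        print(f"  -> results/{name}")
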