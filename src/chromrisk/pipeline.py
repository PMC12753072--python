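"""Configuration-driven orchestration: simulate -> cell risk -> train ->
score -> prioritize -> downstream -> report.

Stages communicate through files in the run directory, so each stage can be
re-run in isolation; a manifest records parameters and content hashes of
every input and output.  Each stage derives its own seed from the global
seed and the stage name, so adding a stage never perturbs another stage's
randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic, cell_risk, chromatin_model, downstream, prioritize
from . import synthetic
from .data_io import (
    read_bedgraph,
    read_cell_matrix,
    read_gene_annotation,
    read_intervals,
    read_sequences,
    read_variant_table,
)

STAGES = ("simulate", "cellrisk", "train", "score", "prioritize",
          "downstream", "report")

REQUIRED_KEYS = (
    "seed",
    "simulation.peaks_per_type",
    "model.window_length",
    "cellrisk.top_quantile",
    "prioritize.threshold",
)


def default_config() -> dict:
    """The demo configuration: synthetic mode at the default study
    conditions, small model architecture."""
    return {
        "seed": 0,
        "simulation": {k: v for k, v in
                       dataclasses.asdict(synthetic.SimulationSpec(seed=0)).items()
                       if k != "seed"},
        "model": {
            "window_length": 200,
            "n_blocks": 1,
            "n_filters": 32,
            "kernel_size": 11,
            "epochs": 12,
            "batch_size": 32,
            "learning_rate": 5e-3,
            "cv_folds": 5,
            "heldout_chrom": "chrB",
        },
        "cellrisk": {
            "n_perm_cell": 100,
            "n_perm_type": 1000,
            "n_perm_trend": 999,
            "top_quantile": 0.95,
            "n_bins": 10,
        },
        "prioritize": {
            "threshold": 0.90,
            "floor": 1e-4,
            "promoter_upstream": 1000,
            "promoter_downstream": 100,
        },
        "downstream": {
            "n_jackknife_blocks": 100,
            "flank": 3000,
            "bin_size": 50,
            "background_draws": 100,
        },
    }


def validate_config(config: dict) -> dict:
    for dotted in REQUIRED_KEYS:
        node = config
        for part in dotted.split("."):
            if not isinstance(node, dict) or part not in node:
                raise KeyError(f"config missing required key {dotted!r}")
            node = node[part]
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _center_mean(profile: np.ndarray, k: int = 4) -> float:
    mid = len(profile) // 2
    return float(profile[mid - k // 2: mid + k // 2].mean())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """A pipeline run rooted at a directory, with a manifest."""

    def __init__(self, config: dict, outdir: str | Path):
        self.config = validate_config(config)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"stages": {}}

    # -- manifest helpers ---------------------------------------------------
    def _record(self, stage: str, params: dict, inputs: list[Path],
                outputs: list[Path], status: str, elapsed: float) -> None:
        self.manifest["stages"][stage] = {
            "params": params,
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "status": status,
            "elapsed_s": round(elapsed, 3),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2,
                                                 default=str))

    def _up_to_date(self, stage: str, params: dict,
                    outputs: list[Path]) -> bool:
        entry = self.manifest["stages"].get(stage)
        if entry is None or entry.get("status") != "ok":
            return False
        if json.dumps(entry["params"], sort_keys=True, default=str) != \
                json.dumps(params, sort_keys=True, default=str):
            return False
        for p in outputs:
            rec = entry["outputs"].get(str(p))
            if rec is None or not Path(p).exists() or _sha256(Path(p)) != rec:
                return False
        return True

    def path(self, name: str) -> Path:
        return self.outdir / name

    # -- stages -------------------------------------------------------------
    def simulate(self) -> None:
        params = dict(self.config["simulation"])
        spec = synthetic.SimulationSpec(
            seed=stage_seed(self.config["seed"], "simulate"), **{
                k: (tuple(v) if k == "lineage" else v)
                for k, v in params.items()
            })
        indir = self.path("inputs")
        outputs = [indir / n for n in (
            "genome.fa", "matrix.mtx", "cells.tsv", "peaks.bed",
            "variants.tsv", "genes.tsv", "promoters.bed", "peak_truth.tsv",
            "haplo_scores.tsv", "target_genes.txt", "signal.bedgraph")]
        if self._up_to_date("simulate", params, outputs):
            return
        t0 = time.time()
        bundle = synthetic.simulate_bundle(spec)
        synthetic.write_bundle(bundle, indir)
        self._record("simulate", params, [], sorted(indir.glob("*")), "ok",
                     time.time() - t0)

    def cellrisk(self) -> None:
        params = dict(self.config["cellrisk"])
        indir = self.path("inputs")
        inputs = [indir / "matrix.mtx", indir / "cells.tsv",
                  indir / "peaks.bed", indir / "variants.tsv"]
        outputs = [self.path("trs_cells.tsv"), self.path("trs_celltypes.tsv"),
                   self.path("trs_trend.tsv"), self.path("trs_summary.json")]
        if self._up_to_date("cellrisk", params, outputs):
            return
        t0 = time.time()
        seed = stage_seed(self.config["seed"], "cellrisk")
        matrix, cells, _ = read_cell_matrix(*inputs[:3])
        variants = read_variant_table(inputs[3])
        sentinels = cell_risk.select_sentinels(variants)
        percell = cell_risk.percell_null(matrix, sentinels,
                                         n_perm=params["n_perm_cell"],
                                         seed=seed)
        flags = cell_risk.flag_risk_cells(percell["trs"].to_numpy(),
                                          q=params["top_quantile"])
        percell.insert(0, "cell_id", cells["cell_id"])
        percell["risk_flag"] = flags
        enrich = cell_risk.celltype_enrichment(
            flags, cells["cell_type"], n_perm=params["n_perm_type"],
            seed=seed + 1)
        bins, rho, trend_p = cell_risk.pseudotime_trend(
            percell["trs"].to_numpy(), cells["pseudotime"].to_numpy(),
            n_bins=params["n_bins"], n_perm=params["n_perm_trend"],
            seed=seed + 2)
        percell.to_csv(outputs[0], sep="\t", index=False)
        enrich.to_csv(outputs[1], sep="\t", index=False)
        bins.to_csv(outputs[2], sep="\t", index=False)
        top = enrich.sort_values("z", ascending=False).iloc[0]
        outputs[3].write_text(json.dumps({
            "n_sentinels": len(sentinels),
            "top_type": top["cell_type"],
            "top_type_z": top["z"],
            "n_significant_types": int((enrich["q"] < 0.05).sum()),
            "pseudotime_rho": rho,
            "pseudotime_p": trend_p,
        }, indent=2, default=str))
        self._record("cellrisk", params, inputs, outputs, "ok",
                     time.time() - t0)

    def train(self) -> None:
        params = dict(self.config["model"])
        indir = self.path("inputs")
        vuln = self.config["simulation"].get("vulnerable_type", "LE2")
        inputs = [indir / "genome.fa", indir / f"peaks_{vuln}.bed"]
        model_dir = self.path("model")
        outputs = [model_dir / "config.json", model_dir / "weights.npz",
                   model_dir / "fingerprint.txt", self.path("model_eval.json")]
        if self._up_to_date("train", params, outputs):
            return
        t0 = time.time()
        seed = stage_seed(self.config["seed"], "train")
        heldout = params.pop("heldout_chrom") if "heldout_chrom" in params \
            else None
        config = chromatin_model.ModelConfig(seed=seed, **{
            k: v for k, v in params.items() if k != "heldout_chrom"})
        genome = read_sequences(inputs[0])
        peaks = read_intervals(inputs[1])
        training = chromatin_model.build_training_set(
            genome, peaks, config.window_length, excluded_chrom=heldout,
            seed=seed + 1)
        model, report = chromatin_model.train_model(config, training)
        if heldout is not None:
            heldout_auroc, n_pos, n_neg = chromatin_model.evaluate_heldout(
                model, genome, peaks, heldout, seed=seed + 2)
            report.heldout_auroc = heldout_auroc
        chromatin_model.save_model(model, model_dir)
        outputs[3].write_text(json.dumps({
            "cv_auroc_mean": report.cv_auroc_mean,
            "fold_aurocs": report.fold_aurocs,
            "heldout_auroc": report.heldout_auroc,
            "heldout_chrom": heldout,
            "n_pos": report.n_pos,
            "n_neg": report.n_neg,
        }, indent=2))
        params["heldout_chrom"] = heldout
        self._record("train", params, inputs, outputs, "ok", time.time() - t0)

    def score(self) -> None:
        params = {}
        indir = self.path("inputs")
        inputs = [indir / "genome.fa", indir / "variants.tsv",
                  self.path("model") / "weights.npz"]
        outputs = [self.path("allelic_scores.tsv")]
        if self._up_to_date("score", params, outputs):
            return
        t0 = time.time()
        genome = read_sequences(inputs[0])
        variants = read_variant_table(inputs[1])
        model = chromatin_model.load_model(self.path("model"))
        scored = allelic.scan_variants(model, genome, variants)
        scored.to_csv(outputs[0], sep="\t", index=False)
        self._record("score", params, inputs, outputs, "ok", time.time() - t0)

    def prioritize(self) -> None:
        params = dict(self.config["prioritize"])
        indir = self.path("inputs")
        inputs = [self.path("allelic_scores.tsv"), indir / "genes.tsv",
                  indir / "promoters.bed"]
        outputs = [self.path("joint_scores.tsv"), self.path("candidates.tsv"),
                   self.path("candidates.bed"),
                   self.path("threshold_sweep.tsv"),
                   self.path("prioritize_summary.json")]
        if self._up_to_date("prioritize", params, outputs):
            return
        t0 = time.time()
        scored = pd.read_csv(inputs[0], sep="\t",
                             dtype={"chrom": str, "ref": str, "alt": str})
        genes = read_gene_annotation(inputs[1])
        promoters = read_intervals(inputs[2])
        joint, jm = prioritize.prioritize_variants(scored,
                                                   floor=params["floor"])
        candidates = prioritize.select_candidates(joint,
                                                  params["threshold"])
        candidates = prioritize.annotate_candidates(
            candidates, genes, upstream=params["promoter_upstream"],
            downstream=params["promoter_downstream"])
        is_cand = joint["joint_probability"].to_numpy() > params["threshold"]
        all_prom = prioritize.promoter_flags(joint, promoters)
        enrich = prioritize.promoter_enrichment(
            all_prom[is_cand], all_prom, is_cand)
        direction = prioritize.direction_test(
            candidates["risk_oriented_score"].to_numpy(),
            joint.loc[~is_cand, "risk_oriented_score"].to_numpy())
        sweep = prioritize.threshold_sweep(joint, promoters)
        joint.to_csv(outputs[0], sep="\t", index=False)
        candidates.to_csv(outputs[1], sep="\t", index=False)
        with open(outputs[2], "w") as fh:
            for _, v in candidates.iterrows():
                fh.write(f"{v['chrom']}\t{v['pos'] - 1}\t{v['pos']}\t{v['id']}\n")
        sweep.to_csv(outputs[3], sep="\t", index=False)
        outputs[4].write_text(json.dumps({
            "n_candidates": len(candidates),
            "joint_model": dataclasses.asdict(jm),
            "direction_test": direction,
            "promoter_enrichment": {k: (v.tolist() if isinstance(v, np.ndarray)
                                        else v)
                                    for k, v in enrich.items()},
        }, indent=2))
        self._record("prioritize", params, inputs, outputs, "ok",
                     time.time() - t0)

    def downstream(self) -> None:
        params = dict(self.config["downstream"])
        indir = self.path("inputs")
        inputs = [self.path("candidates.tsv"), self.path("joint_scores.tsv"),
                  indir / "haplo_scores.tsv", indir / "target_genes.txt",
                  indir / "genes.tsv", indir / "signal.bedgraph"]
        outputs = [self.path("heritability.tsv"),
                   self.path("downstream_summary.json"),
                   self.path("tss_profile.tsv")]
        if self._up_to_date("downstream", params, outputs):
            return
        t0 = time.time()
        seed = stage_seed(self.config["seed"], "downstream")
        candidates = pd.read_csv(inputs[0], sep="\t", dtype={"chrom": str})
        joint = pd.read_csv(inputs[1], sep="\t", dtype={"chrom": str})
        haplo = pd.read_csv(inputs[2], sep="\t")
        targets = [l for l in inputs[3].read_text().splitlines() if l]
        genes = read_gene_annotation(inputs[4])
        track = read_bedgraph(inputs[5])

        cats = downstream.build_heritability_categories(
            joint, set(candidates["id"]))
        herit = downstream.heritability_enrichment(
            joint["z"].to_numpy(), cats.to_numpy(),
            n_jackknife_blocks=params["n_jackknife_blocks"])
        cand_genes = sorted(set(candidates["nearest_gene"].dropna()))
        bg_genes = sorted(set(haplo["gene_id"]) - set(cand_genes))
        dosage = downstream.dosage_sensitivity_test(cand_genes, bg_genes,
                                                    haplo)
        overlap = downstream.gene_set_overlap_test(
            cand_genes, targets, list(haplo["gene_id"]))
        genome = read_sequences(indir / "genome.fa")
        cand_gene_rows = genes[genes["gene_id"].isin(cand_genes)]
        profile = downstream.tss_metaprofile(
            track, cand_gene_rows, genome.lengths, flank=params["flank"],
            bin_size=params["bin_size"],
            background_draws=params["background_draws"], seed=seed)
        herit.to_csv(outputs[0], sep="\t", index=False)
        outputs[1].write_text(json.dumps({
            "dosage_sensitivity": dosage,
            "gene_set_overlap": overlap,
            # signal at the TSS itself (central 4 bins) over the genome background
            "tss_signal_ratio": float(
                _center_mean(profile["mean_profile"])
                / profile["background_profile"].mean()),
        }, indent=2))
        pd.DataFrame({
            "bin": np.arange(len(profile["mean_profile"])),
            "mean_signal": profile["mean_profile"],
            "background_signal": profile["background_profile"],
        }).to_csv(outputs[2], sep="\t", index=False)
        self._record("downstream", params, inputs, outputs, "ok",
                     time.time() - t0)

    def report(self) -> None:
        outputs = [self.path("report.txt")]
        t0 = time.time()
        lines = ["chromrisk pipeline report", "=" * 25, ""]
        for name in ("trs_summary", "model_eval", "prioritize_summary",
                     "downstream_summary"):
            p = self.path(f"{name}.json")
            if p.exists():
                lines.append(f"[{name}]")
                lines.append(json.dumps(json.loads(p.read_text()), indent=2))
                lines.append("")
        outputs[0].write_text("\n".join(lines))
        self._record("report", {}, [], outputs, "ok", time.time() - t0)

    def run_all(self, stages: tuple[str, ...] = STAGES) -> dict:
        for stage in stages:
            getattr(self, stage)()
        return self.manifest


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    return PipelineRun(config, outdir).run_all()
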