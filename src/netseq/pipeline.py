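"""End-to-end orchestration on synthetic data.

``run_demo`` exercises every stage on a toy genome — simulate,
occupancy with mispriming removal, per-replicate pause calling, IDR,
pause metrics, region indices, antisense quantification, feature
assembly, and classification — and writes a markdown report plus a
machine-readable JSON manifest.  All thresholds default to the
analysis constants: expression filter > 2 reads/bp, 3 sd over a 200-nt
background window, >= 2 reads per pause, IDR < 1%.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (annotation, antisense, classifier, features, idr, occupancy,
               pause_calling, pause_metrics, region_indices, simulate)


@dataclass
class PipelineConfig:
    """Thresholds and windows used across the pipeline."""

    expression_threshold: float = 2.0
    pause_z: float = 3.0
    pause_min_reads: int = 2
    background_window: int = 200
    idr_threshold: float = 0.01
    region_windows: dict = field(
        default_factory=lambda: dict(region_indices.DEFAULT_WINDOWS))
    seed: int = 0
    n_genes: int = 60
    classifier_trees: int = 200
    classifier_mtry: int = 20

    def __post_init__(self) -> None:
        for name in ("expression_threshold", "pause_z", "pause_min_reads",
                     "background_window", "idr_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # lists, not tuples, so the config round-trips through JSON
        self.region_windows = {k: list(v)
                               for k, v in self.region_windows.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def run_demo(seed: int = 0, outdir="demo_out", skip: tuple[str, ...] = (),
             config: PipelineConfig | None = None) -> dict:
    """Run every stage on a toy genome; returns the manifest dict.

    ``skip`` names stages to omit (e.g. ``("classify",)``).  Writes
    ``report.md`` and ``manifest.json`` under ``outdir``.
    """
    cfg = config or PipelineConfig(seed=seed)
    cfg.seed = seed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"seed": seed, "stages": {}}
    lines = ["# NET-seq synthetic demonstration", ""]

    sim_cfg = simulate.SimulationConfig(n_genes=cfg.n_genes, seed=seed)
    genome, ann = simulate.generate_toy_genome(sim_cfg)
    rep1, rep2, truth = simulate.simulate_occupancy(ann, sim_cfg)
    manifest["stages"]["simulate"] = {
        "n_genes": len(ann), "n_planted": int(len(truth)),
        "n_reproducible": int(truth["reproducible"].sum())}
    lines += [f"- simulated {len(ann)} genes, {len(truth)} planted pauses "
              f"({int(truth['reproducible'].sum())} reproducible)"]

    reads = simulate.simulate_misprimed_reads(genome, ann, 0.2, seed,
                                              n_reads=5000)
    retained, removed = occupancy.filter_mispriming(reads, genome)
    manifest["stages"]["occupancy"] = {
        "reads": len(reads), "misprimed_removed": removed}
    lines += [f"- mispriming filter removed {removed} of {len(reads)} reads"]

    filt = pause_calling.select_well_expressed(
        rep1, rep2, ann, min_coverage=cfg.expression_threshold)
    calls1 = pause_calling.call_pauses(
        rep1, ann, filt, window=cfg.background_window, z=cfg.pause_z,
        min_reads=cfg.pause_min_reads)
    calls2 = pause_calling.call_pauses(
        rep2, ann, filt, window=cfg.background_window, z=cfg.pause_z,
        min_reads=cfg.pause_min_reads)
    manifest["stages"]["call_pauses"] = {
        "passing_genes": int(filt["passes"].sum()),
        "calls_rep1": len(calls1), "calls_rep2": len(calls2)}
    lines += [f"- called {len(calls1)}/{len(calls2)} pauses in replicates "
              f"over {int(filt['passes'].sum())} well-expressed genes"]

    pairs = idr.match_pauses(calls1, calls2)
    pairs, params = idr.assign_idr(pairs)
    reproducible = idr.reproducible_pauses(pairs, cfg.idr_threshold)
    manifest["stages"]["idr"] = {
        "pairs": len(pairs), "reproducible": len(reproducible),
        "fraction_of_initial": len(reproducible)
        / (0.5 * (len(calls1) + len(calls2)))}
    lines += [f"- IDR kept {len(reproducible)} of {len(pairs)} matched "
              f"pauses at {cfg.idr_threshold:.0%}"]

    length = pause_metrics.considered_length(filt, ann)
    density = pause_metrics.pause_density(reproducible, length)
    pos = pause_metrics.positional_distribution(reproducible, ann)
    manifest["stages"]["pause_metrics"] = {
        "density_per_kb": density,
        "positional": pos.set_index("bin")["fraction"].to_dict()}
    lines += [f"- reproducible pause density {density:.2f}/kb"]

    merged = occupancy.merge_replicates(rep1, rep2)
    pi = region_indices.region_index_table(merged, ann)
    med = pi.groupby("region")["PI"].median().to_dict()
    manifest["stages"]["region_indices"] = {
        "median_PI": {k: float(v) for k, v in med.items()}}
    lines += ["- median pausing indices: "
              + ", ".join(f"{k}={v:.2f}" for k, v in sorted(med.items()))]

    anti_ann, removed_units = antisense.build_antisense_annotation(ann)
    anti_pi = antisense.antisense_position_matrix(merged, ann)
    manifest["stages"]["antisense"] = {
        "units": len(anti_ann), "removed_overlapping": len(removed_units)}
    lines += [f"- built {len(anti_ann)} antisense units "
              f"({len(removed_units)} removed for overlap)"]

    if "classify" not in skip:
        loci = features.labeled_loci(reproducible, ann, seed)
        table = features.assemble_features(loci, genome, ann)
        tests = features.feature_distribution_tests(table)
        clf_cfg = classifier.ClassifierConfig(
            n_trees=cfg.classifier_trees, mtry=cfg.classifier_mtry,
            seed=seed)
        result = classifier.train_and_evaluate(table, clf_cfg)
        manifest["stages"]["classifier"] = {
            "auc": result.auc, "n_features_tested":
                int((tests["status"] == "tested").sum())}
        lines += [f"- random-forest AUC {result.auc:.3f} on held-out loci"]

    manifest["runtime_s"] = time.time() - t0
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "report.md", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return manifest
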