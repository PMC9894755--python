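"""Configuration-driven orchestration of the full analysis.

A JSON run config lists stages (in the fixed topological order
simulate -> preprocess -> structure/associations -> enrichment/network ->
prediction) with per-stage parameters. Every output directory gets a
manifest stamped with the config hash, the master seed and the package
version; unchanged stages are skipped on rerun. Per-stage seeds are
derived from the master seed by stage name, so adding a stage never
perturbs another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cohort_io, preprocess, structure, associations, set_enrichment, network
from .simulate import SimulationConfig, generate_cohort

__all__ = ["run_pipeline", "stage_seed", "STAGE_ORDER"]

STAGE_ORDER = ["simulate", "preprocess", "cluster", "associate", "enrich", "network"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed by stage name."""
    h = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1)[0] % (2**31 - 1))


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    stages = config.get("stages", STAGE_ORDER)
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in STAGE_ORDER if s in stages]

    manifest_path = outdir / "manifest.json"
    previous = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest = {
        "config_hash": _config_hash(config),
        "seed": master_seed,
        "version": __version__,
        "stages": {},
    }

    def outputs_exist(names: list[str]) -> bool:
        return all((outdir / n).exists() for n in names)

    def stage_done(stage: str, names: list[str]) -> bool:
        prev = previous.get("stages", {}).get(stage)
        return (
            previous.get("config_hash") == manifest["config_hash"]
            and prev is not None
            and prev.get("status") == "ok"
            and outputs_exist(names)
        )

    state: dict = {}

    def load_inputs(stage: str):
        """Upstream artifacts for a stage, from memory or prior files."""
        if "matrix" not in state:
            p = outdir / "raw_metabolites.tsv"
            if not p.exists():
                raise FileNotFoundError(f"stage {stage!r}: missing upstream output {p}")
            state["matrix"], _ = cohort_io.read_metabolite_matrix(p)
            state["annotations"] = cohort_io.read_annotations(outdir / "annotations.tsv")
            state["taxa"] = cohort_io.read_taxa_table(outdir / "taxa.tsv", outdir / "loads.tsv")
            state["metadata"] = cohort_io.read_metadata(outdir / "metadata.tsv")

    for stage in stages:
        params = config.get(stage, {})
        try:
            if stage == "simulate":
                names = ["raw_metabolites.tsv", "taxa.tsv", "loads.tsv", "metadata.tsv", "annotations.tsv", "truth.json"]
                if stage_done(stage, names):
                    manifest["stages"][stage] = {"status": "cached", "outputs": names}
                    continue
                cfg = SimulationConfig(**{**params, "seed": stage_seed(master_seed, stage)})
                matrix, taxa, metadata, annotations, truth = generate_cohort(cfg)
                state.update(matrix=matrix, taxa=taxa, metadata=metadata, annotations=annotations)
                cohort_io.write_metabolite_matrix(matrix, outdir / "raw_metabolites.tsv")
                cohort_io.write_taxa_table(taxa, outdir / "taxa.tsv", outdir / "loads.tsv")
                cohort_io.write_metadata(metadata, outdir / "metadata.tsv")
                cohort_io.write_annotations(annotations, outdir / "annotations.tsv")
                cohort_io.write_report(dataclasses.asdict(truth), outdir / "truth.json", "json")
            elif stage == "preprocess":
                names = ["standardized.tsv", "detection.json"]
                if stage_done(stage, names):
                    manifest["stages"][stage] = {"status": "cached", "outputs": names}
                    continue
                load_inputs(stage)
                logged = preprocess.log10_transform(state["matrix"])
                std, _ = preprocess.robust_standardize(logged)
                state["standardized"] = std
                cohort_io.write_metabolite_matrix(std, outdir / "standardized.tsv")
                summary = preprocess.detection_summary(state["matrix"], state["annotations"])
                cohort_io.write_report(dataclasses.asdict(summary), outdir / "detection.json", "json")
            elif stage == "cluster":
                names = ["clusters.json"]
                if stage_done(stage, names):
                    manifest["stages"][stage] = {"status": "cached", "outputs": names}
                    continue
                load_inputs(stage)
                std = state.get("standardized")
                if std is None:
                    std, _ = cohort_io.read_metabolite_matrix(outdir / "standardized.tsv")
                    std.scale_tag = "standardized"
                complete, _ = preprocess.min_impute(std)
                D = structure.compute_distance(complete, "canberra")
                seed = stage_seed(master_seed, stage)
                gap = structure.select_k_gap(
                    complete, D,
                    k_range=range(1, params.get("kmax", 15) + 1),
                    B=params.get("B", 50), seed=seed,
                )
                fit = structure.kmedoids_fit(D, gap.chosen_k, seed=seed)
                robust = structure.cluster_robustness(
                    complete, D, fit,
                    n_subsamples=params.get("robustness", 100),
                    fraction=params.get("frac", 0.9), seed=seed,
                )
                cohort_io.write_report(
                    {
                        "gap": dataclasses.asdict(gap),
                        "clustering": dataclasses.asdict(fit),
                        "robustness": dataclasses.asdict(robust),
                    },
                    outdir / "clusters.json", "json",
                )
            elif stage == "associate":
                names = ["associations.tsv"]
                if stage_done(stage, names):
                    manifest["stages"][stage] = {"status": "cached", "outputs": names}
                    continue
                load_inputs(stage)
                records = []
                for scan in params.get("strata", [{"stratum": "all"}]):
                    recs, _ = associations.association_scan(
                        state["matrix"], state["metadata"], **scan
                    )
                    records.extend(recs)
                cohort_io.write_report(
                    records, outdir / "associations.tsv", "tsv",
                    columns=["feature_id", "stratum", "U", "p", "q", "direction",
                             "n_case", "n_ctrl", "prevalence"],
                )
                state["associations"] = records
            elif stage == "enrich":
                names = ["enrichment.tsv"]
                if stage_done(stage, names):
                    manifest["stages"][stage] = {"status": "cached", "outputs": names}
                    continue
                load_inputs(stage)
                sets = set_enrichment.build_metabolite_sets(state["annotations"])
                recs = set_enrichment.set_enrichment_scan(
                    state["matrix"], state["metadata"], sets,
                    n_permutations=params.get("n_permutations", 10000),
                    seed=stage_seed(master_seed, stage),
                )
                cohort_io.write_report(
                    recs, outdir / "enrichment.tsv", "tsv",
                    columns=["set_id", "set_type", "stratum", "observed_second_level_p",
                             "perm_p", "q", "n_in", "n_out", "n_permutations", "seed"],
                )
            elif stage == "network":
                names = ["edges.tsv"]
                if stage_done(stage, names):
                    manifest["stages"][stage] = {"status": "cached", "outputs": names}
                    continue
                load_inputs(stage)
                absolute, _ = network.estimate_absolute_abundance(state["taxa"])
                feats = params.get("features")
                matrix = state["matrix"].subset_features(feats) if feats else state["matrix"]
                edges, _ = network.correlation_network(
                    absolute, matrix, min_pairs=params.get("min_pairs"),
                )
                cohort_io.write_report(
                    edges, outdir / "edges.tsv", "tsv",
                    columns=["taxon_id", "feature_id", "rho", "n_pairs", "p", "q", "kept"],
                )
            manifest["stages"][stage] = {"status": "ok", "outputs": names}
        except Exception as exc:  # halt with a structured error report
            manifest["stages"][stage] = {"status": "error", "error": f"{type(exc).__name__}: {exc}"}
            manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
            raise
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
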