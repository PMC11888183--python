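"""End-to-end orchestration: simulate -> flow scoring -> Perturb-seq
preprocessing -> pseudotime -> phenotyping -> integration.

A single YAML config drives the run; every stochastic stage receives a
sub-seed derived from the global seed by hashing the stage name, so
toggling one stage never perturbs another's random stream.  Every output
file is checksummed into a manifest for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import cellprep, flowscreen, perturbstats, simdata, trajectory
from .integrate import integrate_screens

log = logging.getLogger("dualscreen")


@dataclass
class RunConfig:
    outdir: str = "dualscreen_run"
    seed: int = 0
    run_flow: bool = True
    run_perturb: bool = True
    run_integrate: bool = True
    sim: dict = field(default_factory=dict)
    flow: dict = field(default_factory=dict)  # ScreenDesign fields
    prep: dict = field(default_factory=lambda: {"min_umis": 3, "max_mito": 0.05, "min_rnas": 200})
    trajectory: dict = field(default_factory=lambda: {"k": 10, "n_variable": 2000})
    phenotype: dict = field(default_factory=lambda: {"alpha": 0.05})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2^31."""
    return (global_seed * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the artifact manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(path: Path) -> None:
        artifacts.append(path)

    sim_kwargs = dict(config.sim)
    sim_kwargs["seed"] = stage_seed(config.seed, "simulate")
    sim_config = simdata.SimConfig(**sim_kwargs)
    sim_config.to_yaml(outdir / "sim_config.yaml")
    emit(outdir / "sim_config.yaml")
    config.to_yaml(outdir / "run_config.yaml")
    emit(outdir / "run_config.yaml")

    log.info("stage simulate: library of %d target genes", sim_config.n_target_genes)
    library = simdata.simulate_library(sim_config)
    library.to_tsv(outdir / "library.tsv")
    emit(outdir / "library.tsv")

    flow_results = None
    if config.run_flow:
        log.info("stage flow: simulating sorted-bin screen and scoring")
        try:
            counts, flow_truth = simdata.simulate_flow_screen(sim_config, library)
            counts.to_tsv(outdir / "flow_counts.tsv")
            emit(outdir / "flow_counts.tsv")
            flow_truth.to_tsv(outdir / "flow_truth_cells.tsv", outdir / "flow_truth_effects.tsv")
            emit(outdir / "flow_truth_cells.tsv")
            emit(outdir / "flow_truth_effects.tsv")
            design = flowscreen.ScreenDesign(**config.flow)
            flow_results = flowscreen.score_screen(
                counts, library, design, seed=stage_seed(config.seed, "flow_scoring")
            )
            flow_results.to_csv(outdir / "flow_genes.tsv", sep="\t")
            emit(outdir / "flow_genes.tsv")
        except Exception as exc:
            raise RuntimeError(f"[flow] stage failed: {exc}") from exc

    perturb_results = None
    if config.run_perturb:
        log.info("stage perturb: simulating single-cell screen")
        try:
            adata, truth = simdata.simulate_perturb_seq(sim_config, library)
            for p in cellprep.write_cell_dataset(adata, outdir / "perturb_raw").values():
                emit(Path(p))
            truth.to_tsv(outdir / "perturb_truth_cells.tsv", outdir / "perturb_truth_effects.tsv")
            emit(outdir / "perturb_truth_cells.tsv")
            emit(outdir / "perturb_truth_effects.tsv")

            assignments = cellprep.assign_guides(
                adata, min_umis=config.prep.get("min_umis", 3),
                guide_to_gene=library.guide_to_gene,
            )
            assignments.to_csv(outdir / "assignments.tsv", sep="\t")
            emit(outdir / "assignments.tsv")
            filtered, report = cellprep.qc_filter(
                adata, assignments,
                max_mito=config.prep.get("max_mito", 0.05),
                min_rnas=config.prep.get("min_rnas", 200),
            )
            cellprep.write_qc_report(report, outdir / "qc_report.json")
            emit(outdir / "qc_report.json")
            log.info("qc kept %d / %d cells", report["n_kept"], report["n_input"])

            cellprep.normalize_expression(filtered)
            features = cellprep.select_variable_features(
                filtered, n=config.trajectory.get("n_variable", 2000)
            )
            x = filtered[:, features].layers["lognorm"]
            result = trajectory.infer_pseudotime(
                np.asarray(x), k=config.trajectory.get("k", 10),
                cell_ids=filtered.obs_names,
                seed=stage_seed(config.seed, "trajectory"),
            )
            panel = simdata.gene_panel(sim_config)
            prog = panel.loc[panel["gene_class"] == "progenitor_marker", "gene_id"].tolist()[:3]
            diff = panel.loc[panel["gene_class"] == "differentiation_marker", "gene_id"].tolist()[:3]
            result = trajectory.orient_pseudotime(result, filtered, prog, diff)
            trajectory.write_pseudotime(result, outdir / "pseudotime.tsv")
            emit(outdir / "pseudotime.tsv")

            perturb_results, _ = perturbstats.phenotype_targets(
                result.pseudotime,
                filtered.obs["target_gene"].fillna(""),
                alpha=config.phenotype.get("alpha", 0.05),
            )
            perturb_results.to_csv(outdir / "phenotypes.tsv", sep="\t")
            emit(outdir / "phenotypes.tsv")
        except Exception as exc:
            raise RuntimeError(f"[perturb] stage failed: {exc}") from exc

    if config.run_integrate:
        if flow_results is None or perturb_results is None:
            log.info("stage integrate skipped: both screen arms are required")
        else:
            try:
                table, rho = integrate_screens(flow_results, perturb_results)
                table.to_csv(outdir / "integrated.tsv", sep="\t")
                emit(outdir / "integrated.tsv")
                from . import __version__

                (outdir / "integration_summary.json").write_text(
                    json.dumps(
                        {
                            "spearman_rho": rho,
                            "n_genes": len(table),
                            "version": __version__,
                            "seed": config.seed,
                        },
                        indent=2,
                    )
                    + "\n"
                )
                emit(outdir / "integration_summary.json")
            except Exception as exc:
                raise RuntimeError(f"[integrate] stage failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "files": {
            str(p.relative_to(outdir)): _checksum(p) for p in sorted(set(artifacts))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
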