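"""Configuration-driven end-to-end orchestration on synthetic data.

Stages run in dependency order (synth -> matrix -> clustering; synth ->
layers/barseq/single_cell), each writing its outputs under a per-stage
subdirectory. Re-running with the same config and seed reproduces identical
numeric summaries; disabled stages are served from cached outputs when
present, otherwise a dependency error names the missing stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from . import barseq as bq
from . import clustering as cl
from . import laminar as lam
from . import single_cell as sc
from . import synth
from . import tracer as tr

STAGE_ORDER = ["synth", "matrix", "clustering", "layers", "barseq", "single_cell"]
DEPENDENCIES = {
    "matrix": ["synth"],
    "clustering": ["matrix"],
    "layers": ["synth"],
    "barseq": ["synth"],
    "single_cell": ["synth"],
}


class PipelineError(RuntimeError):
    pass


class DependencyError(PipelineError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "pipeline_out"
    stages: dict = field(
        default_factory=lambda: {name: True for name in STAGE_ORDER}
    )
    n_clusters: int = 3
    layers_k: int = 2
    alpha: float = 0.05
    n_perm: int = 199
    max_areas: int = 3
    n_shuffles: int = 50
    mixture: dict = field(default_factory=lambda: {"C1": 0.6, "C2": 0.4})
    composition_method: str = "nnls"
    bvls_bounds: tuple = (0.01, 1.0)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        for stage in config.stages:
            if stage not in STAGE_ORDER:
                raise PipelineError(f"unknown stage: {stage!r}")
        return config

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bvls_bounds"] = list(d["bvls_bounds"])
        return d


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages and return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = synth.SyntheticConfig(seed=config.seed)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "files": {},
    }
    enabled = {s: config.stages.get(s, True) for s in STAGE_ORDER}
    failed: set[str] = set()
    context: dict = {}

    def artifact(stage: str, name: str) -> Path:
        d = outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d / name

    def check_deps(stage: str) -> None:
        for dep in DEPENDENCIES.get(stage, []):
            if dep in failed:
                raise DependencyError(f"stage {dep!r} failed")
            if not enabled[dep] and dep not in context.get("cached", set()):
                raise DependencyError(
                    f"stage {stage!r} requires outputs of disabled stage {dep!r} "
                    "and no cached outputs were found"
                )

    # -- stage implementations -------------------------------------------

    def run_synth() -> dict:
        experiments, truth = synth.generate_tracer_experiments(scfg)
        blanks = synth.generate_blank_brains(scfg)
        dataset, barcode_truth = synth.generate_barcoded_neurons(scfg)
        cells, _, _, cell_truth = synth.generate_single_cells(scfg)
        context.update(
            experiments=experiments,
            tracer_truth=truth,
            blanks=blanks,
            barcode=dataset,
            barcode_truth=barcode_truth,
            cells=cells,
            cell_truth=cell_truth,
        )
        blanks.to_csv(artifact("synth", "blanks.csv"))
        dataset.counts.to_csv(artifact("synth", "barcode_counts.csv"))
        meta = pd.DataFrame(
            {
                "spikein": dataset.spikein,
                "soma_depth": dataset.soma_depth,
                "brain_id": dataset.brain_id,
                "subgroup_truth": barcode_truth.neuron_subgroups,
            }
        )
        meta.to_csv(artifact("synth", "barcode_meta.csv"))
        cells.fractions.to_csv(artifact("synth", "single_cell_fractions.csv"))
        return {
            "n_experiments": len(experiments),
            "n_blank_brains": len(blanks),
            "n_neurons": dataset.n_neurons,
            "n_cells": len(cells.fractions),
        }

    def run_matrix() -> dict:
        ontology = synth.make_synthetic_ontology()
        matrix = tr.output_fraction_matrix(context["experiments"], ontology)
        calibration = tr.blank_calibration(context["blanks"], k=6.0)
        retro = [
            tr.TracerExperiment(
                id=f"retro-{e.id}",
                modality="retrograde",
                label_source=e.label_source,
                injection_region=e.injection_region,
                injection_xyz=e.injection_xyz,
                signal=e.signal,
            )
            for e in context["experiments"]
        ]
        input_matrix = tr.input_fraction_matrix(retro, calibration, ontology)
        mean_dist, sd_dist, _ = tr.injection_distances(context["experiments"])
        summary = tr.division_summary(matrix, ontology)
        matrix.to_csv(artifact("matrix", "output_matrix.csv"))
        input_matrix.to_csv(artifact("matrix", "input_matrix.csv"))
        summary.to_csv(artifact("matrix", "division_summary.csv"))
        context["matrix"] = matrix
        return {
            "shape": list(matrix.data.shape),
            "division_shares_avg": summary.loc["average"].round(6).to_dict(),
            "injection_distance_mean_um": round(mean_dist, 3),
            "injection_distance_sd_um": round(sd_dist, 3),
            "mean_in_degree": float(tr.in_degree(matrix).mean()),
        }

    def run_clustering() -> dict:
        if "matrix" not in context:
            context["matrix"] = tr.ConnectivityMatrix.from_csv(
                outdir / "matrix" / "output_matrix.csv", kind="output"
            )
        dendrogram, assignment = cl.spearman_complete_cluster(
            context["matrix"], k=config.n_clusters
        )
        (outdir / "clustering").mkdir(exist_ok=True)
        (outdir / "clustering" / "dendrogram.nwk").write_text(
            dendrogram.to_newick()
        )
        assignment.labels.to_csv(artifact("clustering", "assignment.csv"))
        result = {"k": assignment.k}
        truth = context.get("tracer_truth")
        if truth is not None:
            planted = [
                truth.experiment_classes[r] for r in assignment.labels.index
            ]
            result["ari_vs_planted"] = float(
                adjusted_rand_score(planted, assignment.labels)
            )
        sims = cl.within_cluster_similarity(context["matrix"], assignment)
        result["within_cluster_spearman"] = {
            int(k): (None if pd.isna(v) else round(float(v), 6))
            for k, v in sims.items()
        }
        return result

    def run_layers() -> dict:
        dataset = context["barcode"]
        truth = context["barcode_truth"]
        somas = list(
            zip(dataset.soma_depth, (f"sg{g}" for g in truth.neuron_subgroups))
        )
        profile = lam.depth_histogram(somas)
        delineation = lam.delineate_layers(profile, k=config.layers_k)
        (artifact("layers", "delineation.json")).write_text(
            json.dumps(delineation.to_dict(), indent=2)
        )
        context["delineation"] = delineation
        return {
            "n_layers": len(delineation.layers),
            "boundaries_um": [l.depth_max for l in delineation.layers[:-1]],
        }

    def run_barseq() -> dict:
        dataset = context["barcode"]
        truth = context["barcode_truth"]
        norm = bq.normalize_barcodes(dataset)
        binary = bq.binarize(norm)
        tree = bq.entropy_split(
            binary,
            norm.soma_depth,
            max_areas=config.max_areas,
            alpha=config.alpha,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        classes = bq.major_class_clustering(norm, n_classes=2, seed=config.seed)
        merged = bq.merge_by_laminae(tree, norm, classes, alpha=config.alpha)
        merged.to_csv(artifact("barseq", "subgroups.csv"))
        planted = pd.Series(
            truth.neuron_subgroups, index=dataset.counts.index
        ).loc[merged.index]
        areas = dataset.areas
        cond = bq.conditional_projection_prob(binary, areas[0], areas[1])
        return {
            "n_leaves": len(tree.leaves()),
            "n_subgroups_after_merge": int(merged.nunique()),
            "ari_vs_planted": float(adjusted_rand_score(planted, merged)),
            "conditional_prob_example": cond,
        }

    def run_single_cell() -> dict:
        cells = context["cells"]
        bulk, mix_truth = synth.synthesize_bulk(cells, config.mixture)
        estimate = sc.estimate_composition(
            cells,
            bulk,
            min_cluster_size=min(15, cells.cluster_sizes().min()),
            method=config.composition_method,
            bounds=tuple(config.bvls_bounds),
        )
        binary = (cells.fractions > 1e-3).astype(int)
        xor = sc.xor_discreteness_test(
            binary, n_shuffles=config.n_shuffles, seed=config.seed
        )
        estimate.proportions.to_csv(artifact("single_cell", "composition.csv"))
        recovery = {
            c: abs(estimate.proportions.get(c, 0.0) - p)
            for c, p in mix_truth.mixture_proportions.items()
        }
        return {
            "composition_rss": estimate.rss,
            "composition_max_abs_error": float(max(recovery.values())),
            "xor_p_value": xor.p_value,
            "xor_var_ratio": (
                xor.var_actual / xor.var_shuffled if xor.var_shuffled else None
            ),
        }

    runners = {
        "synth": run_synth,
        "matrix": run_matrix,
        "clustering": run_clustering,
        "layers": run_layers,
        "barseq": run_barseq,
        "single_cell": run_single_cell,
    }

    for stage in STAGE_ORDER:
        if not enabled[stage]:
            report["stages"][stage] = {"status": "disabled"}
            continue
        try:
            check_deps(stage)
            summary = runners[stage]()
            report["stages"][stage] = {"status": "ok", "summary": summary}
        except DependencyError as exc:
            failed.add(stage)
            report["stages"][stage] = {"status": "dependency-error", "error": str(exc)}
        except Exception as exc:  # stage failure: record and skip downstream
            failed.add(stage)
            report["stages"][stage] = {"status": "failed", "error": str(exc)}

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "report.json":
            report["files"][str(path.relative_to(outdir))] = _hash_file(path)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
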