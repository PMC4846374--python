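"""End-to-end orchestration: QC -> markers -> structure -> overlap -> modules.

A :class:`RunConfig` (YAML/JSON-loadable) names either input files (FPKM
matrix + metadata) or a synthetic-data configuration, the stage toggles and
thresholds, the seed and the output directory.  Every stage writes delimited
tables (plus Newick/JSON where appropriate) into a per-stage subdirectory, and
the run closes with a manifest recording parameters, seed and SHA-256
checksums of every artifact — identical config and seed give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .datamodel import ExpressionMatrix, SampleMetadata, aggregate_replicates, population_label
from .markers import (
    calls_to_frame,
    mean_fold_markers,
    per_replicate_markers,
    pole_enriched_genes,
)
from .modules import correlation_dissimilarity, cut_modules, diana_cluster, variable_genes
from .overlap import OverlapScenario, monte_carlo_null, overlap_counts
from .qc import qc_report
from .simulate import SimConfig, generate_dataset
from .structure import (
    agglomerative_dendrogram,
    classical_mds,
    js_distance_matrix,
    transform_profiles,
)

logger = logging.getLogger("hippoaxis")

STAGES = ("qc", "markers", "cluster", "overlap", "modules")


@dataclass
class RunConfig:
    """Parameters of a pipeline run (all numeric defaults follow the study)."""

    matrix_path: str | None = None
    metadata_path: str | None = None
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    stages: tuple[str, ...] = STAGES
    expressed_fpkm: float = 10.0
    mean_fold: float = 3.0
    replicate_fold: float = 2.0
    pole_fold: float = 2.0
    qc_r_threshold: float = 0.90
    contamination_fpkm: float = 10.0
    n_variable: int = 1000
    variable_fpkm_min: float = 5.0
    n_modules: int = 8
    module_cut_height: float | None = None
    n_reps: int = 1000
    seed: int = 0
    out_dir: str = "hippoaxis_run"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate:
        sim = SimConfig(seed=config.seed, **config.sim_overrides)
        matrix, meta, manifest = generate_dataset(sim)
        sim_dir = out / "simulated"
        sim_dir.mkdir(parents=True, exist_ok=True)
        io.write_matrix(matrix, sim_dir / "matrix.tsv")
        io.write_metadata(meta, sim_dir / "metadata.tsv")
        io.write_json(manifest.to_jsonable(), sim_dir / "ground_truth.json")
        return matrix, meta, manifest
    if not config.matrix_path or not config.metadata_path:
        raise ValueError("matrix_path and metadata_path required when simulate=False")
    matrix = io.load_matrix(config.matrix_path)
    meta = io.load_metadata(config.metadata_path)
    meta.validate_against(matrix)
    return matrix, meta, None


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    On stage failure a ``FAILED`` marker naming the stage is written, partial
    outputs are retained, and the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    def save_table(df: pd.DataFrame, rel: str, **kwargs) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", float_format=io.FLOAT_FORMAT, **kwargs)
        checksums[rel] = _sha256(path)

    def save_text(text: str, rel: str) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text)
        checksums[rel] = _sha256(path)

    def save_json(obj, rel: str) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        io.write_json(obj, path)
        checksums[rel] = _sha256(path)

    stage = "load"
    try:
        matrix, meta, truth = _load_inputs(config, out)
        spike_genes = [g for g in matrix.gene_ids if g.startswith("ERCC-")]
        panel = list(truth.config.contamination_panel) if truth is not None else None

        if "qc" in config.stages:
            stage = "qc"
            report = qc_report(
                matrix,
                meta,
                contamination_panel=panel,
                spike_genes=spike_genes or None,
                r_threshold=config.qc_r_threshold,
                contamination_threshold=config.contamination_fpkm,
            )
            save_table(report.replicates.pairs, "qc/replicate_correlations.tsv", index=False)
            if report.contamination is not None:
                save_table(report.contamination.samples, "qc/contamination.tsv")
            save_json(report.to_jsonable(), "qc/summary.json")
            logger.info("QC: mean replicate r = %.3f, passed = %s",
                        report.replicates.mean_r, report.passed)

        # spike-ins are excluded from all downstream analyses
        analysis = matrix.drop_genes(spike_genes)
        pm = aggregate_replicates(analysis, meta)

        if "markers" in config.stages:
            stage = "markers"
            by_class: dict[str, list[str]] = {}
            for cls, region in meta.populations:
                by_class.setdefault(cls, []).append(population_label(cls, region))
            for cls, pops in by_class.items():
                if len(pops) >= len(pm.population_labels):
                    continue
                calls = mean_fold_markers(
                    pm, pops, fold=config.mean_fold, threshold=config.expressed_fpkm
                )
                logger.info("markers: %d genes >%g-fold enriched in %s",
                            len(calls), config.mean_fold, cls)
                save_table(calls_to_frame(calls), f"markers/mean_fold_{cls}.tsv", index=False)
                rep_calls = per_replicate_markers(
                    analysis, meta, pops,
                    fold=config.replicate_fold, threshold=config.expressed_fpkm,
                )
                save_table(
                    calls_to_frame(rep_calls), f"markers/per_replicate_{cls}.tsv", index=False
                )

        if "cluster" in config.stages:
            stage = "cluster"
            profiles = transform_profiles(pm)
            dmat = js_distance_matrix(profiles)
            save_table(dmat, "structure/population_jsd.tsv")
            dendro = agglomerative_dendrogram(dmat)
            save_text(dendro.to_newick() + "\n", "structure/population_dendrogram.newick")
            rep_profiles = transform_profiles(analysis)
            rep_dmat = js_distance_matrix(rep_profiles)
            save_table(rep_dmat, "structure/replicate_jsd.tsv")
            coords = classical_mds(rep_dmat, k=2)
            save_table(coords, "structure/replicate_mds.tsv")

        if "overlap" in config.stages:
            stage = "overlap"
            classes = pm.classes_with_both_poles()
            if len(classes) >= 2:
                universes, enriched = {}, {}
                for cls in classes:
                    d_label = population_label(cls, "dorsal")
                    v_label = population_label(cls, "ventral")
                    sub = pm.data[[d_label, v_label]]
                    universes[cls] = list(sub.index[sub.max(axis=1) > config.expressed_fpkm])
                    pe = pole_enriched_genes(
                        pm, cls, fold=config.pole_fold, threshold=config.expressed_fpkm
                    )
                    enriched[cls] = {"dorsal": pe.dorsal_genes, "ventral": pe.ventral_genes}
                    logger.info(
                        "overlap: class %s expressed=%d dorsal=%d ventral=%d",
                        cls, len(universes[cls]), len(pe.dorsal_genes), len(pe.ventral_genes),
                    )
                scenario = OverlapScenario(universes=universes, enriched=enriched)
                observed = overlap_counts(scenario)
                results = {"observed": observed, "poles": {}}
                for pole in ("dorsal", "ventral", "both"):
                    res = monte_carlo_null(
                        scenario, pole=pole, n_reps=config.n_reps, seed=config.seed
                    )
                    results["poles"][pole] = res.to_jsonable()
                    save_table(
                        pd.DataFrame({"null_overlap": res.null_draws}),
                        f"overlap/null_draws_{pole}.tsv",
                        index=False,
                    )
                save_json(results, "overlap/results.json")
            else:
                logger.info("overlap: fewer than 2 classes with both poles; skipped")

        if "modules" in config.stages:
            stage = "modules"
            selected = variable_genes(
                pm, n=config.n_variable, fpkm_min=config.variable_fpkm_min
            )
            cd = correlation_dissimilarity(pm, genes=selected)
            tree = diana_cluster(cd.D)
            if config.module_cut_height is not None:
                assignment = cut_modules(
                    tree, list(cd.D.index), height=config.module_cut_height, pm=pm
                )
            else:
                assignment = cut_modules(
                    tree, list(cd.D.index), n_modules=config.n_modules, pm=pm
                )
            logger.info("modules: %d modules over %d genes",
                        assignment.n_modules, len(assignment.labels))
            save_table(assignment.labels.to_frame("module"), "modules/assignments.tsv")
            if assignment.profiles is not None:
                save_table(assignment.profiles, "modules/profiles.tsv")

        stage = "manifest"
        config_echo = config.to_jsonable()
        config_echo.pop("out_dir")  # not a scientific parameter; keeps runs comparable
        manifest = {
            "config": config_echo,
            "seed": config.seed,
            "checksums": checksums,
            "package": "hippoaxis 0.1.0",
        }
        io.write_json(manifest, out / "manifest.json")
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        raise
    return out
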