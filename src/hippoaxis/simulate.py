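"""Synthetic FPKM generator with planted, manifest-recorded structure.

The generator emulates the sorted-population hippocampal design: eight
(cell class, region) populations x three biological replicates, lognormal
background expression, multiplicative lognormal replicate noise calibrated so
that within-population replicate correlation sits near the reported regime of
r ~ 0.98, planted class-marker and dorsal/ventral gradient genes at stated
fold changes, planted co-expression modules, an ERCC-like spike-in ladder and
an interneuron/glial contamination panel (silent unless leakage > 0).

Fold planting acts on population means *before* noise, so recovery tests have
exact expected folds; the noiseless limit (``replicate_cv=0``) reproduces the
planted folds exactly.  One integer seed drives all random streams through a
counter-split scheme (``SeedSequence(seed, spawn_key=...)``), so adding a
planted feature does not perturb background values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_POPULATIONS,
    ExpressionMatrix,
    PopulationMatrix,
    SampleMetadata,
    population_label,
)
from .overlap import OverlapScenario

# stream ids for the counter-split RNG scheme
_STREAM_BASELINE = 0
_STREAM_NOISE = 1
_STREAM_CONTAMINATION = 2

#: Interneuron / non-neuronal marker panel used as the default contamination
#: readout (GABAergic, astrocyte, oligodendrocyte, microglia, endothelial).
DEFAULT_CONTAMINATION_PANEL = (
    "Gad1",
    "Gad2",
    "Sst",
    "Pvalb",
    "Vip",
    "Npy",
    "Gfap",
    "Aqp4",
    "Mbp",
    "Plp1",
    "Cx3cr1",
    "C1qa",
    "Cldn5",
    "Pdgfra",
)


@dataclass(frozen=True)
class PlantedClassMarkers:
    """``count`` genes enriched ``fold``-times in every population of ``populations``."""

    populations: tuple[str, ...]  # population labels, e.g. ("GC-dorsal", "GC-ventral")
    fold: float
    count: int


@dataclass(frozen=True)
class PlantedRegionGenes:
    """Genes enriched ``fold``-times at one pole in the affected cell classes."""

    pole: str  # "dorsal" | "ventral"
    fold: float
    count: int
    classes: tuple[str, ...] = ("GC", "CA3", "CA1")


@dataclass(frozen=True)
class PlantedModule:
    """Co-expressed gene block sharing a population-weight profile."""

    weights: tuple[float, ...]  # one multiplicative weight per population
    count: int


def _default_class_markers() -> tuple[PlantedClassMarkers, ...]:
    # Strength ordering plants the observed hierarchy: granule cells split
    # first, then mossy vs pyramidal, class distinctions, and finally the
    # (smaller) dorsal-ventral differences.
    return (
        PlantedClassMarkers(("GC-dorsal", "GC-ventral"), 8.0, 150),
        PlantedClassMarkers(("MC",), 6.0, 100),
        PlantedClassMarkers(("CA3-dorsal", "CA3-ventral"), 4.0, 60),
        PlantedClassMarkers(("CA2",), 4.0, 60),
        PlantedClassMarkers(("CA1-dorsal", "CA1-ventral"), 4.0, 60),
    )


def _default_region_genes() -> tuple[PlantedRegionGenes, ...]:
    return (
        PlantedRegionGenes("dorsal", 3.0, 40),
        PlantedRegionGenes("ventral", 3.0, 40),
    )


def _default_modules(n_populations: int = 8) -> tuple[PlantedModule, ...]:
    # One-hot boosts, one module per population.  The boost (1.8x) keeps the
    # max/min weight ratio below every fold-rule threshold (2x), so module
    # membership never masquerades as a planted marker or gradient gene.
    mods = []
    for p in range(n_populations):
        w = [1.0] * n_populations
        w[p] = 1.8
        mods.append(PlantedModule(tuple(w), 40))
    return tuple(mods)


@dataclass(frozen=True)
class SimConfig:
    """Stated-world parameters of the synthetic experiment.

    ``replicate_cv`` is the coefficient of variation of the multiplicative
    lognormal replicate noise; the default (0.17) was calibrated once by
    simulation so the mean within-population replicate Pearson r on raw FPKM
    is ~0.98, the reported regime.
    """

    n_genes: int = 5000
    populations: tuple[tuple[str, str], ...] = DEFAULT_POPULATIONS
    n_replicates: int = 3
    baseline_log10_mean: float = 1.0
    baseline_log10_sd: float = 0.8
    replicate_cv: float = 0.17
    planted_class_markers: tuple[PlantedClassMarkers, ...] = field(
        default_factory=_default_class_markers
    )
    planted_region_genes: tuple[PlantedRegionGenes, ...] = field(
        default_factory=_default_region_genes
    )
    planted_modules: tuple[PlantedModule, ...] = field(default_factory=_default_modules)
    contamination_panel: tuple[str, ...] = DEFAULT_CONTAMINATION_PANEL
    contamination_leakage: float = 0.0  # per-sample contamination probability
    contamination_fpkm: float = 50.0  # panel FPKM in a contaminated sample
    n_spike_ins: int = 92
    spike_in_range_log10: tuple[float, float] = (-1.0, 3.0)
    planted_floor_fpkm: float = 20.0  # baseline floor for planted-feature genes
    seed: int = 0

    def population_labels(self) -> list[str]:
        return [population_label(c, r) for c, r in self.populations]

    def planted_gene_total(self) -> int:
        total = sum(m.count for m in self.planted_class_markers)
        total += sum(r.count for r in self.planted_region_genes)
        total += sum(m.count for m in self.planted_modules)
        total += len(self.contamination_panel)
        total += self.n_spike_ins
        return total

    def validate(self) -> None:
        if self.planted_gene_total() > self.n_genes:
            raise ValueError(
                f"planted gene counts ({self.planted_gene_total()}) exceed n_genes ({self.n_genes})"
            )
        labels = set(self.population_labels())
        for m in self.planted_class_markers:
            if m.fold <= 1:
                raise ValueError("planted marker folds must exceed 1")
            unknown = set(m.populations) - labels
            if unknown:
                raise ValueError(f"unknown marker populations {sorted(unknown)}")
        for r in self.planted_region_genes:
            if r.fold <= 1:
                raise ValueError("planted region folds must exceed 1")
            if r.pole not in ("dorsal", "ventral"):
                raise ValueError(f"unknown pole {r.pole!r}")
        for mod in self.planted_modules:
            if len(mod.weights) != len(self.populations):
                raise ValueError("module weight profile must have one weight per population")
        if not 0 <= self.contamination_leakage < 1:
            raise ValueError("contamination leakage must be in [0, 1)")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be non-negative")


@dataclass(frozen=True)
class GroundTruthManifest:
    """Per-gene planted roles plus sample-level ground truth.

    ``genes`` columns: ``role`` (background | class_marker | region_gene |
    module_member | contamination | spike_in), ``fold``, ``populations``,
    ``pole``, ``classes``, ``module``.
    """

    genes: pd.DataFrame
    contaminated_samples: tuple[str, ...]
    spike_in_fpkm: pd.Series
    config: SimConfig

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.genes.index[self.genes["role"] == role])

    def class_marker_set(self, populations: Sequence[str]) -> list[str]:
        key = ",".join(sorted(populations))
        mask = (self.genes["role"] == "class_marker") & (
            self.genes["populations"].fillna("").map(
                lambda s: ",".join(sorted(s.split("|"))) if s else ""
            )
            == key
        )
        return list(self.genes.index[mask])

    def region_gene_set(self, pole: str, cell_class: str | None = None) -> list[str]:
        mask = (self.genes["role"] == "region_gene") & (self.genes["pole"] == pole)
        if cell_class is not None:
            mask &= self.genes["classes"].fillna("").map(
                lambda s: cell_class in s.split("|") if s else False
            )
        return list(self.genes.index[mask])

    def module_members(self) -> dict[int, list[str]]:
        sub = self.genes[self.genes["role"] == "module_member"]
        out: dict[int, list[str]] = {}
        for gene, mod in sub["module"].items():
            out.setdefault(int(mod), []).append(gene)
        return out

    @property
    def spike_in_genes(self) -> list[str]:
        return self.genes_with_role("spike_in")

    @property
    def contamination_genes(self) -> list[str]:
        return self.genes_with_role("contamination")

    def to_jsonable(self) -> dict:
        cfg = asdict(self.config)
        return {
            "config": cfg,
            "contaminated_samples": list(self.contaminated_samples),
            "spike_in_fpkm": self.spike_in_fpkm.to_dict(),
            "genes": {
                gene: {k: (None if pd.isna(v) else v) for k, v in row.items()}
                for gene, row in self.genes.to_dict("index").items()
            },
        }


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=sigma, size=shape)


def generate_dataset(
    config: SimConfig | None = None,
) -> tuple[ExpressionMatrix, SampleMetadata, GroundTruthManifest]:
    """Generate a replicate-level FPKM matrix with planted structure.

    Deterministic given ``config.seed``; population mean FPKM of a planted
    marker is exactly ``fold`` x every off-target population mean before
    replicate noise.
    """
    config = config or SimConfig()
    config.validate()

    pops = config.population_labels()
    n_pops = len(pops)
    n_genes = config.n_genes
    seed = config.seed

    # --- gene roles ------------------------------------------------------
    roles = pd.DataFrame(
        {
            "role": "background",
            "fold": np.nan,
            "populations": pd.Series([None] * n_genes, dtype=object),
            "pole": pd.Series([None] * n_genes, dtype=object),
            "classes": pd.Series([None] * n_genes, dtype=object),
            "module": np.nan,
        },
        index=[f"G{i:05d}" for i in range(n_genes)],
    )
    gene_ids = list(roles.index)
    cursor = 0

    def take(count: int) -> list[int]:
        nonlocal cursor
        idx = list(range(cursor, cursor + count))
        cursor += count
        return idx

    marker_rows: list[tuple[list[int], PlantedClassMarkers]] = []
    for m in config.planted_class_markers:
        idx = take(m.count)
        marker_rows.append((idx, m))
        roles.iloc[idx, roles.columns.get_loc("role")] = "class_marker"
        roles.iloc[idx, roles.columns.get_loc("fold")] = m.fold
        roles.iloc[idx, roles.columns.get_loc("populations")] = "|".join(m.populations)

    region_rows: list[tuple[list[int], PlantedRegionGenes]] = []
    for r in config.planted_region_genes:
        idx = take(r.count)
        region_rows.append((idx, r))
        roles.iloc[idx, roles.columns.get_loc("role")] = "region_gene"
        roles.iloc[idx, roles.columns.get_loc("fold")] = r.fold
        roles.iloc[idx, roles.columns.get_loc("pole")] = r.pole
        roles.iloc[idx, roles.columns.get_loc("classes")] = "|".join(r.classes)

    module_rows: list[tuple[list[int], PlantedModule]] = []
    for mi, mod in enumerate(config.planted_modules):
        idx = take(mod.count)
        module_rows.append((idx, mod))
        roles.iloc[idx, roles.columns.get_loc("role")] = "module_member"
        roles.iloc[idx, roles.columns.get_loc("module")] = mi

    contam_idx = take(len(config.contamination_panel))
    for j, gi in enumerate(contam_idx):
        gene_ids[gi] = config.contamination_panel[j]
        roles.iloc[gi, roles.columns.get_loc("role")] = "contamination"

    spike_idx = take(config.n_spike_ins)
    for j, gi in enumerate(spike_idx):
        gene_ids[gi] = f"ERCC-{j + 1:05d}"
        roles.iloc[gi, roles.columns.get_loc("role")] = "spike_in"

    roles.index = pd.Index(gene_ids, name="gene_id")

    # --- population means ------------------------------------------------
    rng_base = _rng(seed, _STREAM_BASELINE)
    baseline = 10.0 ** rng_base.normal(
        config.baseline_log10_mean, config.baseline_log10_sd, size=n_genes
    )
    planted = roles["role"].isin(["class_marker", "region_gene", "module_member"]).to_numpy()
    baseline = np.where(
        planted, np.maximum(baseline, config.planted_floor_fpkm), baseline
    )

    means = np.tile(baseline[:, None], (1, n_pops))
    pop_index = {p: j for j, p in enumerate(pops)}
    pop_class = {p: c for (c, r), p in zip(config.populations, pops)}
    pop_region = {p: r for (c, r), p in zip(config.populations, pops)}

    for idx, m in marker_rows:
        for p in m.populations:
            means[np.ix_(idx, [pop_index[p]])] *= m.fold
    for idx, r in region_rows:
        for p in pops:
            if pop_region[p] == r.pole and pop_class[p] in r.classes:
                means[np.ix_(idx, [pop_index[p]])] *= r.fold
    for idx, mod in module_rows:
        means[idx, :] *= np.asarray(mod.weights)[None, :]

    means[contam_idx, :] = 0.0
    if config.n_spike_ins:
        ladder = np.logspace(
            config.spike_in_range_log10[0],
            config.spike_in_range_log10[1],
            config.n_spike_ins,
        )
        means[spike_idx, :] = ladder[:, None]

    # --- replicates ------------------------------------------------------
    sample_ids, cls_col, region_col, rep_col = [], [], [], []
    for (cls, region), p in zip(config.populations, pops):
        for rep in range(1, config.n_replicates + 1):
            sample_ids.append(f"{p}_r{rep}")
            cls_col.append(cls)
            region_col.append(region)
            rep_col.append(rep)

    rng_noise = _rng(seed, _STREAM_NOISE)
    n_samples = len(sample_ids)
    noise = _lognormal_noise(rng_noise, config.replicate_cv, (n_genes, n_samples))
    sample_pop_idx = np.repeat(np.arange(n_pops), config.n_replicates)
    values = means[:, sample_pop_idx] * noise

    # --- contamination ---------------------------------------------------
    rng_contam = _rng(seed, _STREAM_CONTAMINATION)
    contaminated = []
    if config.contamination_leakage > 0 and contam_idx:
        hit = rng_contam.random(n_samples) < config.contamination_leakage
        level_noise = _lognormal_noise(
            rng_contam, config.replicate_cv, (len(contam_idx), n_samples)
        )
        for s in np.flatnonzero(hit):
            values[contam_idx, s] = config.contamination_fpkm * level_noise[:, s]
            contaminated.append(sample_ids[s])

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=roles.index, columns=sample_ids)
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {"cell_class": cls_col, "region": region_col, "replicate": rep_col},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    spike_fpkm = pd.Series(
        means[spike_idx, 0], index=roles.index[spike_idx], name="fpkm"
    )
    manifest = GroundTruthManifest(
        genes=roles,
        contaminated_samples=tuple(contaminated),
        spike_in_fpkm=spike_fpkm,
        config=config,
    )
    return matrix, meta, manifest


def plant_overlap_scenario(
    n_expressed: Mapping[str, int],
    n_enriched: Mapping[str, int],
    n_shared: int,
    seed: int = 0,
    pole: str = "dorsal",
) -> tuple[OverlapScenario, dict]:
    """Construct per-class enriched gene lists with a known shared core.

    Each class receives an expressed-gene universe of the stated size and an
    enriched list containing exactly ``n_shared`` genes common to *all*
    classes; the remaining enriched genes are private to their class, so every
    pairwise and higher-order intersection equals the shared core.
    """
    classes = list(n_expressed)
    if set(n_enriched) != set(classes):
        raise ValueError("n_expressed and n_enriched must cover the same classes")
    if n_shared < 0:
        raise ValueError("n_shared must be non-negative")
    for cls in classes:
        if n_enriched[cls] < n_shared:
            raise ValueError(
                f"n_shared ({n_shared}) exceeds n_enriched for class {cls!r}"
            )
        if n_expressed[cls] < n_enriched[cls]:
            raise ValueError(f"class {cls!r}: enriched count exceeds universe size")

    shared = [f"SHARED{i:04d}" for i in range(n_shared)]
    universes: dict[str, list[str]] = {}
    enriched: dict[str, dict[str, list[str]]] = {}
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(9,)))
    for cls in classes:
        private = [f"{cls}_ENR{i:04d}" for i in range(n_enriched[cls] - n_shared)]
        background = [
            f"{cls}_BG{i:04d}"
            for i in range(n_expressed[cls] - n_enriched[cls])
        ]
        universe = shared + private + background
        order = rng.permutation(len(universe))
        universes[cls] = [universe[i] for i in order]
        enr = {"dorsal": [], "ventral": []}
        enr[pole] = shared + private
        enriched[cls] = enr

    scenario = OverlapScenario(universes=universes, enriched=enriched)
    truth = {"shared_genes": shared, "n_shared": n_shared, "pole": pole}
    return scenario, truth
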