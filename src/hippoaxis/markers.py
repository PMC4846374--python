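"""Expressed-gene filter and the three fold-enrichment marker rules.

All rules operate on FPKM and are scale-free (multiplying the whole matrix by
a positive constant changes no call):

* ``expressed_filter`` — a gene is analyzable if its maximum population-mean
  FPKM strictly exceeds a threshold (default 10).
* ``mean_fold_markers`` — a gene is an X-fold marker of a target population
  set if every target population's mean FPKM is at least X times every
  off-target population's mean (default X = 3, the class-marker rule).
* ``per_replicate_markers`` — the stricter dendrogram-marker rule: every
  target *replicate* must be at least 2-fold above every non-target replicate.
* ``pole_enriched_genes`` — within one cell class, genes at least 2-fold
  enriched at the dorsal or ventral pole relative to the opposite pole.

The written sources mix "more than X-fold" and "at least X-fold" for the same
rule; the threshold comparison defaults to closed (>=) with ``closed=False``
selecting the strict reading.  A positive target over a zero off-target mean
yields fold = +inf and sorts first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    PopulationMatrix,
    SampleMetadata,
    aggregate_replicates,
    population_label,
)

EXPRESSED_FPKM = 10.0


@dataclass(frozen=True)
class MarkerCall:
    """A gene passing a fold-enrichment rule for a target population set."""

    gene_id: str
    target: tuple[str, ...]
    rule: str  # per_replicate_2fold | mean_Xfold | pole_2fold
    fold: float  # minimum achieved fold (may be +inf)
    target_mean_fpkm: float


def _calls_frame(calls: Sequence[MarkerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "rule": c.rule,
                "target": "|".join(c.target),
                "fold": c.fold,
                "target_mean_fpkm": c.target_mean_fpkm,
            }
            for c in calls
        ]
    )


def expressed_filter(
    pm: PopulationMatrix, threshold: float = EXPRESSED_FPKM
) -> list[str]:
    """Genes whose maximum population-mean FPKM strictly exceeds ``threshold``."""
    mask = pm.data.max(axis=1) > threshold
    return list(pm.data.index[mask])


def _resolve_targets(pm: PopulationMatrix, target: Sequence[str]) -> list[str]:
    target = list(target)
    if not target:
        raise ValueError("target population set is empty")
    labels = pm.population_labels
    missing = [t for t in target if t not in labels]
    if missing:
        raise KeyError(f"target population(s) not in matrix: {missing}")
    if len(target) >= len(labels):
        raise ValueError("target must be a proper subset of populations")
    return target


def _fold_calls(
    tmin: pd.Series,
    omax: pd.Series,
    tmean: pd.Series,
    genes: Sequence[str],
    fold: float,
    closed: bool,
    rule: str,
    target: tuple[str, ...],
) -> list[MarkerCall]:
    calls = []
    for g in genes:
        t, o = tmin[g], omax[g]
        if t <= 0:
            continue
        ok = (t >= fold * o) if closed else (t > fold * o)
        if not ok:
            continue
        achieved = float("inf") if o == 0 else float(t / o)
        calls.append(MarkerCall(g, target, rule, achieved, float(tmean[g])))
    calls.sort(key=lambda c: (-c.fold, c.gene_id))
    return calls


def mean_fold_markers(
    pm: PopulationMatrix,
    target: Sequence[str],
    fold: float = 3.0,
    threshold: float = EXPRESSED_FPKM,
    closed: bool = True,
) -> list[MarkerCall]:
    """X-fold enrichment of population-mean FPKM against all off-target populations.

    A gene is called iff it passes the expressed filter and
    min(target means) >= fold * max(off-target means) (strict > with
    ``closed=False``).
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    target = _resolve_targets(pm, target)
    others = [p for p in pm.population_labels if p not in target]
    expressed = expressed_filter(pm, threshold)
    tmin = pm.data[target].min(axis=1)
    tmean = pm.data[target].mean(axis=1)
    omax = pm.data[others].max(axis=1)
    return _fold_calls(
        tmin, omax, tmean, expressed, fold, closed, "mean_Xfold", tuple(target)
    )


def per_replicate_markers(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    target: Sequence[str],
    fold: float = 2.0,
    threshold: float = EXPRESSED_FPKM,
    closed: bool = True,
    against: str = "each",
) -> list[MarkerCall]:
    """Replicate-level rule: every target replicate beats every non-target replicate.

    ``target`` is a set of population labels.  With ``against="each"`` (the
    strictest reading, default) the comparison is against every individual
    non-target replicate; ``against="mean"`` compares against the mean of the
    remaining replicates.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    pm = aggregate_replicates(matrix, meta)
    target = _resolve_targets(pm, target)
    target_samples: list[str] = []
    for cls, region in meta.populations:
        if population_label(cls, region) in target:
            target_samples.extend(meta.samples_in(cls, region))
    other_samples = [s for s in matrix.sample_ids if s not in target_samples]
    expressed = expressed_filter(pm, threshold)
    tmin = matrix.data[target_samples].min(axis=1)
    tmean = matrix.data[target_samples].mean(axis=1)
    if against == "each":
        oref = matrix.data[other_samples].max(axis=1)
    elif against == "mean":
        oref = matrix.data[other_samples].mean(axis=1)
    else:
        raise ValueError(f"unknown comparison mode {against!r}")
    return _fold_calls(
        tmin, oref, tmean, expressed, fold, closed, "per_replicate_2fold", tuple(target)
    )


@dataclass(frozen=True)
class PoleEnrichment:
    """Dorsal- and ventral-enriched marker calls for one cell class."""

    cell_class: str
    dorsal: list[MarkerCall]
    ventral: list[MarkerCall]

    @property
    def dorsal_genes(self) -> list[str]:
        return [c.gene_id for c in self.dorsal]

    @property
    def ventral_genes(self) -> list[str]:
        return [c.gene_id for c in self.ventral]


def pole_enriched_genes(
    pm: PopulationMatrix,
    cell_class: str,
    fold: float = 2.0,
    threshold: float = EXPRESSED_FPKM,
    closed: bool = True,
) -> PoleEnrichment:
    """Genes enriched at either pole of one cell class (>= 2-fold by default).

    The expressed filter is applied within the two pole populations (FPKM >
    threshold in at least one of them).  The dorsal and ventral lists are
    disjoint by construction for fold > 1.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    d_label = population_label(cell_class, "dorsal")
    v_label = population_label(cell_class, "ventral")
    for label in (d_label, v_label):
        if label not in pm.population_labels:
            raise ValueError(f"population {label} missing for class {cell_class}")
    sub = pm.data[[d_label, v_label]]
    expressed = list(sub.index[sub.max(axis=1) > threshold])
    d, v = sub[d_label], sub[v_label]
    dorsal = _fold_calls(d, v, d, expressed, fold, closed, "pole_2fold", (d_label,))
    ventral = _fold_calls(v, d, v, expressed, fold, closed, "pole_2fold", (v_label,))
    return PoleEnrichment(cell_class=cell_class, dorsal=dorsal, ventral=ventral)


def calls_to_frame(calls: Sequence[MarkerCall]) -> pd.DataFrame:
    """Marker calls as a flat table (gene, rule, target, fold, target mean)."""
    if not calls:
        return pd.DataFrame(
            columns=["gene_id", "rule", "target", "fold", "target_mean_fpkm"]
        )
    return _calls_frame(calls)
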