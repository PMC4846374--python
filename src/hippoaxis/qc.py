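"""Replicate-quality and purity gates on the expression matrix.

Three checks mirror the study design's quality criteria:

* within-population replicate correlation — whole-transcriptome Pearson r
  between every pair of replicates of the same population must exceed 0.90
  (the gate is applied to *all* pairs, the strictest reading);
* spike-in reproducibility — the same correlation machinery restricted to the
  ERCC-like spike-in block;
* contamination — FPKM of an interneuron/non-neuronal marker panel must stay
  below a threshold in every sample (default FPKM 10, the expression cutoff,
  since no separate purity threshold is stated).

Correlations default to raw FPKM (replicate scatter is assessed on raw
values); a log10(x+1) option exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, SampleMetadata, population_label

REPLICATE_R_THRESHOLD = 0.90


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either vector has zero variance."""
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class ReplicateCorrelationReport:
    """Pairwise within-population replicate correlations and pass flags."""

    pairs: pd.DataFrame  # population, sample_a, sample_b, r, passed
    threshold: float

    @property
    def min_r_per_population(self) -> pd.Series:
        return self.pairs.groupby("population", sort=False)["r"].min()

    @property
    def failed_populations(self) -> list[str]:
        bad = self.pairs.loc[~self.pairs["passed"], "population"]
        return list(dict.fromkeys(bad))

    @property
    def passed(self) -> bool:
        return not self.pairs["passed"].eq(False).any()

    @property
    def mean_r(self) -> float:
        return float(self.pairs["r"].mean())


def replicate_correlation(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    threshold: float = REPLICATE_R_THRESHOLD,
    log_scale: bool = False,
) -> ReplicateCorrelationReport:
    """Pairwise Pearson r between replicates of the same population.

    A pair fails if r <= threshold or r is undefined (zero-variance replicate,
    reported as NaN).
    """
    meta.validate_against(matrix)
    values = matrix.data
    if log_scale:
        values = np.log10(values + 1)
    rows = []
    for cls, region in meta.populations:
        samples = meta.samples_in(cls, region)
        if len(samples) < 2:
            raise ValueError(
                f"population {population_label(cls, region)} has fewer than 2 replicates"
            )
        label = population_label(cls, region)
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                r = _pearson(
                    values[samples[i]].to_numpy(), values[samples[j]].to_numpy()
                )
                passed = bool(np.isfinite(r) and r > threshold)
                rows.append((label, samples[i], samples[j], r, passed))
    pairs = pd.DataFrame(
        rows, columns=["population", "sample_a", "sample_b", "r", "passed"]
    )
    return ReplicateCorrelationReport(pairs=pairs, threshold=threshold)


def spikein_correlation(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    spike_genes: Sequence[str],
    threshold: float = REPLICATE_R_THRESHOLD,
) -> ReplicateCorrelationReport:
    """Replicate correlation restricted to the spike-in gene block."""
    present = [g for g in spike_genes if g in matrix.data.index]
    if not present:
        raise ValueError("no spike-in genes present in matrix")
    return replicate_correlation(matrix.subset(genes=present), meta, threshold)


@dataclass(frozen=True)
class ContaminationReport:
    """Per-sample contamination flags from a marker-gene panel."""

    samples: pd.DataFrame  # index sample, columns flagged, max_fpkm, offending_genes
    missing_genes: tuple[str, ...]
    threshold: float

    @property
    def flagged_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["flagged"]])


def contamination_check(
    matrix: ExpressionMatrix,
    panel: Iterable[str],
    threshold: float = 10.0,
) -> ContaminationReport:
    """Flag samples where any panel gene exceeds the FPKM threshold.

    Panel genes absent from the matrix are reported, not fatal; an empty panel
    is an error.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("contamination panel is empty")
    present = [g for g in panel if g in matrix.data.index]
    missing = tuple(g for g in panel if g not in matrix.data.index)
    rows = []
    sub = matrix.data.loc[present] if present else pd.DataFrame(columns=matrix.sample_ids)
    for sample in matrix.sample_ids:
        if present:
            col = sub[sample]
            over = col[col > threshold]
            rows.append(
                (bool(len(over)), float(col.max()), "|".join(over.index))
            )
        else:
            rows.append((False, float("nan"), ""))
    samples = pd.DataFrame(
        rows,
        index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=["flagged", "max_fpkm", "offending_genes"],
    )
    return ContaminationReport(samples=samples, missing_genes=missing, threshold=threshold)


@dataclass(frozen=True)
class QCReport:
    """Combined QC outcome; ``passed`` is True iff no stated gate is violated."""

    replicates: ReplicateCorrelationReport
    spike_ins: ReplicateCorrelationReport | None
    contamination: ContaminationReport | None

    @property
    def passed(self) -> bool:
        ok = self.replicates.passed
        if self.contamination is not None:
            ok = ok and not self.contamination.flagged_samples
        return ok

    def to_jsonable(self) -> dict:
        out = {
            "passed": self.passed,
            "replicate_threshold": self.replicates.threshold,
            "replicate_mean_r": self.replicates.mean_r,
            "replicate_min_r": self.replicates.min_r_per_population.to_dict(),
            "failed_populations": self.replicates.failed_populations,
        }
        if self.spike_ins is not None:
            out["spikein_mean_r"] = self.spike_ins.mean_r
        if self.contamination is not None:
            out["contamination_threshold"] = self.contamination.threshold
            out["contaminated_samples"] = self.contamination.flagged_samples
            out["missing_panel_genes"] = list(self.contamination.missing_genes)
        return out


def qc_report(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    contamination_panel: Iterable[str] | None = None,
    spike_genes: Sequence[str] | None = None,
    r_threshold: float = REPLICATE_R_THRESHOLD,
    contamination_threshold: float = 10.0,
) -> QCReport:
    """Run all QC gates and assemble a report."""
    reps = replicate_correlation(matrix, meta, r_threshold)
    spikes = None
    if spike_genes:
        spikes = spikein_correlation(matrix, meta, spike_genes, r_threshold)
    contam = None
    if contamination_panel is not None:
        contam = contamination_check(matrix, contamination_panel, contamination_threshold)
    return QCReport(replicates=reps, spike_ins=spikes, contamination=contam)
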