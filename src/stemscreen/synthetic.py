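"""Synthetic multi-study expression data with planted pluripotency markers.

The generator emulates the statistical structure the screen assumes: several
independent studies on a shared probeset universe, each contrasting a small
pluripotent group against a small differentiated group on the log2 scale.
Genes are interrogated by 1-3 probesets. Each gene draws an independent
per-study baseline (study-specific normalization offsets and biology), shared
by its probesets; samples add i.i.d. Gaussian noise. Planted marker genes get
a fixed log2 effect added to their pluripotent samples in their active
studies, so ground truth for screen recovery is known exactly.

Defaults model the screen's study conditions: 7 studies, ~2000 genes, 3
biological replicates per group, a 3.0 log2 (8-fold) marker effect over
0.25 log2 within-group noise — strong markers on a quiet array, the regime a
rank-based fold-change screen is designed for.

A single NumPy generator seeded once drives everything; draws are ordered by
(gene, probeset, study, sample-block) so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .io_model import (
    AnnotationRecord,
    AnnotationTable,
    ExpressionStudy,
    ScreenReport,
    StemscreenError,
    write_annotation,
    write_expression_study,
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated multi-study dataset.

    All intensity-scale parameters are in log2 units. ``probesets_per_gene``
    is an inclusive (low, high) range sampled uniformly per gene.
    ``planted_study_fraction`` is the per-(marker, study) probability that the
    study carries the marker's effect; 1.0 plants every marker in every study.
    """

    n_studies: int = 7
    n_genes: int = 2000
    probesets_per_gene: tuple[int, int] = (1, 3)
    samples_per_group: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.25
    n_planted: int = 20
    effect_size: float = 3.0
    planted_study_fraction: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.probesets_per_gene
        if self.n_studies < 1 or self.n_genes < 1 or self.samples_per_group < 1:
            raise StemscreenError("n_studies, n_genes, samples_per_group must be >= 1")
        if not (1 <= lo <= hi):
            raise StemscreenError(
                f"probesets_per_gene range {self.probesets_per_gene} must satisfy "
                "1 <= low <= high"
            )
        if self.baseline_sd <= 0 or self.noise_sd <= 0:
            raise StemscreenError("baseline_sd and noise_sd must be > 0")
        if not (0 < self.planted_study_fraction <= 1):
            raise StemscreenError("planted_study_fraction must be in (0, 1]")
        if not (0 <= self.n_planted < self.n_genes):
            raise StemscreenError("n_planted must satisfy 0 <= n_planted < n_genes")


@dataclass(frozen=True)
class GroundTruth:
    """Which genes carry the planted effect, and in which studies."""

    planted_genes: frozenset[str]
    active_studies: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_genes", frozenset(self.planted_genes))
        object.__setattr__(
            self,
            "active_studies",
            {g: frozenset(s) for g, s in dict(self.active_studies).items()},
        )
        if not set(self.active_studies) <= self.planted_genes:
            raise StemscreenError("active_studies keys must be planted genes")


def _gene_label(index: int) -> str:
    return f"GENE{index + 1:04d}"


def _probeset_id(gene_index: int, probeset_index: int) -> str:
    # Affymetrix-flavoured, unique, lexicographically stable ids
    return f"{100000 + gene_index * 10 + probeset_index}_at"


def simulate_studies(
    config: SimConfig,
) -> tuple[list[ExpressionStudy], AnnotationTable, GroundTruth]:
    """Draw one multi-study dataset; fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.probesets_per_gene

    n_probesets_of = rng.integers(lo, hi + 1, size=config.n_genes)
    planted_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_planted, replace=False)
    )
    planted_set = set(int(i) for i in planted_idx)

    study_ids = [f"study{i + 1}" for i in range(config.n_studies)]
    # active-study mask per planted gene, in gene-index order
    active: dict[str, frozenset[str]] = {}
    active_mask: dict[int, np.ndarray] = {}
    for g in planted_idx:
        mask = rng.random(config.n_studies) < config.planted_study_fraction
        active_mask[int(g)] = mask
        active[_gene_label(int(g))] = frozenset(
            s for s, on in zip(study_ids, mask) if on
        )

    n_per_study = 2 * config.samples_per_group
    total_probesets = int(n_probesets_of.sum())
    values = np.empty((config.n_studies, total_probesets, n_per_study))
    probeset_ids: list[str] = []
    annotation_records: list[AnnotationRecord] = []

    row = 0
    for g in range(config.n_genes):
        baselines = rng.normal(
            config.baseline_mean, config.baseline_sd, size=config.n_studies
        )
        effect = np.zeros(config.n_studies)
        if g in planted_set:
            effect[active_mask[g]] = config.effect_size
        for j in range(int(n_probesets_of[g])):
            noise = rng.normal(0.0, config.noise_sd, size=(config.n_studies, n_per_study))
            block = baselines[:, None] + noise
            # pluripotent samples occupy the first samples_per_group columns
            block[:, : config.samples_per_group] += effect[:, None]
            values[:, row, :] = block
            probeset_ids.append(_probeset_id(g, j))
            annotation_records.append(
                AnnotationRecord(
                    probeset_id=_probeset_id(g, j),
                    gene_id=str(10000 + g),
                    gene_symbol=_gene_label(g),
                    gene_name=f"simulated gene {_gene_label(g)}"
                    + (" (planted marker)" if g in planted_set else ""),
                )
            )
            row += 1

    studies = []
    for s, study_id in enumerate(study_ids):
        sample_ids = [
            f"{study_id}_plu{i + 1}" for i in range(config.samples_per_group)
        ] + [f"{study_id}_dif{i + 1}" for i in range(config.samples_per_group)]
        group_of = {
            sid: ("pluripotent" if i < config.samples_per_group else "differentiated")
            for i, sid in enumerate(sample_ids)
        }
        studies.append(
            ExpressionStudy(
                study_id=study_id,
                probeset_ids=tuple(probeset_ids),
                sample_ids=tuple(sample_ids),
                values=values[s],
                group_of=group_of,
            )
        )
    truth = GroundTruth(
        planted_genes=frozenset(_gene_label(g) for g in planted_set),
        active_studies=active,
    )
    return studies, AnnotationTable(tuple(annotation_records)), truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoverySummary:
    """How well the screen recovered the planted markers.

    ``sensitivity`` — fraction of planted genes retained by the screen.
    ``precision`` — fraction of retained genes that are planted; when nothing
    is retained, precision is vacuously reported as 1.0 with
    ``precision_defined=False``.
    ``gene_overlap_of`` — per planted gene, its gene_overlap in the report
    (0 when absent).
    """

    sensitivity: float
    precision: float
    precision_defined: bool
    gene_overlap_of: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_overlap_of", dict(self.gene_overlap_of))


def evaluate_recovery(report: ScreenReport, truth: GroundTruth) -> RecoverySummary:
    """Score a screen report against simulation ground truth (deterministic)."""
    retained_overlap: dict[str, int] = {}
    for record in report.records:
        retained_overlap[record.gene_label] = record.gene_overlap
    retained = set(retained_overlap)
    planted = set(truth.planted_genes)
    hits = retained & planted
    sensitivity = len(hits) / len(planted) if planted else 1.0
    if retained:
        precision, precision_defined = len(hits) / len(retained), True
    else:
        precision, precision_defined = 1.0, False
    return RecoverySummary(
        sensitivity=sensitivity,
        precision=precision,
        precision_defined=precision_defined,
        gene_overlap_of={g: retained_overlap.get(g, 0) for g in sorted(planted)},
    )


# ---------------------------------------------------------------------------
# On-disk round trip of a simulated dataset
# ---------------------------------------------------------------------------


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene_label\tactive_studies\n")
        for gene in sorted(truth.planted_genes):
            studies = ",".join(sorted(truth.active_studies.get(gene, frozenset())))
            handle.write(f"{gene}\t{studies}\n")


def read_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    planted: list[str] = []
    active: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
        if header.split("\t") != ["gene_label", "active_studies"]:
            raise StemscreenError(
                f"{path}: line 1: expected header 'gene_label<TAB>active_studies'"
            )
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise StemscreenError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(parts)}"
                )
            gene, studies = parts
            planted.append(gene)
            active[gene] = frozenset(s for s in studies.split(",") if s)
    return GroundTruth(planted_genes=frozenset(planted), active_studies=active)


def write_dataset(
    studies: Iterable[ExpressionStudy],
    annotation: AnnotationTable,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, list[Path]]:
    """Write matrix/design TSVs per study plus annotation.tsv and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices: list[Path] = []
    designs: list[Path] = []
    for study in studies:
        matrix_path = outdir / f"matrix_{study.study_id}.tsv"
        design_path = outdir / f"design_{study.study_id}.tsv"
        write_expression_study(study, matrix_path, design_path)
        matrices.append(matrix_path)
        designs.append(design_path)
    write_annotation(annotation, outdir / "annotation.tsv")
    write_truth(truth, outdir / "truth.tsv")
    return {"matrices": matrices, "designs": designs}
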