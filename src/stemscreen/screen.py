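"""Cross-study rank-overlap screen.

The screen mirrors a meta-analysis strategy for finding pluripotency
markers across independent microarray studies that share a platform:

1. per study, score every probeset by log2 fold change — the mean log2
   intensity over pluripotent samples minus the mean over differentiated
   samples (no variance moderation; the screen is rank-based);
2. keep each study's top-k probesets (k = 100 by default);
3. count, for every probeset, how many studies top-listed it, and for every
   gene the number of studies in which *any* of its probesets is top-listed
   (union over probesets, so the gene count can exceed each probeset's);
4. retain genes whose study count reaches ``min_studies`` (4 by default)
   and report one row per top-listed probeset of each retained gene.

Ranking direction defaults to ``esc_high`` (signed fold change descending,
pluripotent-enriched first); ``absolute`` ranks by |fold change| and picks up
markers of differentiation as well. Ties are broken lexicographically on
probeset id, which makes every ranking total and the whole screen
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_model import (
    AnnotationTable,
    ExpressionStudy,
    ScreenRecord,
    ScreenReport,
    StemscreenError,
)

DIRECTIONS = ("esc_high", "absolute")


@dataclass(frozen=True)
class FoldChangeTable:
    """Per-probeset signed log2 fold change (pluripotent minus differentiated)."""

    study_id: str
    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))


@dataclass(frozen=True)
class StudyTopList:
    """One study's ordered top-k probesets, best first."""

    study_id: str
    k: int
    direction: str
    probesets: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probesets", tuple(self.probesets))
        if len(set(self.probesets)) != len(self.probesets):
            raise StemscreenError(
                f"top list for study {self.study_id!r} contains duplicates"
            )


def fold_changes(study: ExpressionStudy) -> FoldChangeTable:
    """Signed log2 fold change per probeset: mean(pluripotent) - mean(differentiated)."""
    plu = [study.sample_ids.index(s) for s in study.samples_in("pluripotent")]
    dif = [study.sample_ids.index(s) for s in study.samples_in("differentiated")]
    if not plu or not dif:
        raise StemscreenError(f"study {study.study_id!r}: a group has zero samples")
    diff = study.values[:, plu].mean(axis=1) - study.values[:, dif].mean(axis=1)
    return FoldChangeTable(
        study_id=study.study_id,
        entries={p: float(d) for p, d in zip(study.probeset_ids, diff)},
    )


def top_k(fc: FoldChangeTable, k: int, direction: str = "esc_high") -> StudyTopList:
    """The k best probesets under the chosen ranking, ties broken by id.

    ``esc_high`` ranks by signed fold change descending (pluripotent-enriched
    first); ``absolute`` by |fold change| descending. The list never expands
    past k on ties; its length is min(k, number of probesets).
    """
    if k < 1:
        raise StemscreenError(f"k must be >= 1, got {k}")
    if direction not in DIRECTIONS:
        raise StemscreenError(
            f"unknown ranking direction {direction!r}; expected one of {DIRECTIONS}"
        )
    if direction == "esc_high":
        key = lambda item: (-item[1], item[0])
    else:
        key = lambda item: (-abs(item[1]), item[0])
    ranked = sorted(fc.entries.items(), key=key)
    return StudyTopList(
        study_id=fc.study_id,
        k=k,
        direction=direction,
        probesets=tuple(p for p, _ in ranked[:k]),
    )


def _study_sets(toplists: Sequence[StudyTopList]) -> dict[str, set[str]]:
    """Map probeset -> set of study_ids whose top list contains it."""
    seen_studies: set[str] = set()
    for tl in toplists:
        if tl.study_id in seen_studies:
            raise StemscreenError(f"duplicate study_id {tl.study_id!r} in top lists")
        seen_studies.add(tl.study_id)
    sets: dict[str, set[str]] = {}
    for tl in toplists:
        for probeset in tl.probesets:
            sets.setdefault(probeset, set()).add(tl.study_id)
    return sets


def probeset_overlap(toplists: Sequence[StudyTopList]) -> dict[str, int]:
    """Per probeset, the number of studies whose top list contains it."""
    return {p: len(studies) for p, studies in _study_sets(toplists).items()}


def gene_overlap(
    toplists: Sequence[StudyTopList], annotation: AnnotationTable
) -> dict[str, int]:
    """Per gene, the size of the union of its probesets' study sets.

    A gene counts in a study as soon as any one of its probesets is
    top-listed there, hence gene_overlap >= max probeset_overlap over the
    gene's probesets. Unannotated probesets are an error (self-annotated
    transcribed loci are legitimate singleton genes, absent ones are not).
    """
    gene_studies: dict[str, set[str]] = {}
    for probeset, studies in _study_sets(toplists).items():
        label = annotation.gene_label(probeset)
        gene_studies.setdefault(label, set()).update(studies)
    return {gene: len(studies) for gene, studies in gene_studies.items()}


def run_screen(
    studies: Iterable[ExpressionStudy],
    annotation: AnnotationTable,
    k: int = 100,
    min_studies: int = 4,
    direction: str = "esc_high",
) -> ScreenReport:
    """Full screen: fold changes -> per-study top-k -> overlaps -> retention.

    Genes whose gene_overlap reaches ``min_studies`` are retained; the report
    carries one record per top-listed probeset of each retained gene, sorted
    canonically (gene overlap desc, probeset overlap desc, probeset id asc).
    """
    studies = list(studies)
    if not studies:
        raise StemscreenError("run_screen needs at least one study")
    toplists = [top_k(fold_changes(study), k, direction) for study in studies]
    p_overlap = probeset_overlap(toplists)
    g_overlap = gene_overlap(toplists, annotation)
    retained = {gene for gene, count in g_overlap.items() if count >= min_studies}
    records = []
    for probeset, count in p_overlap.items():
        rec = annotation.record_for(probeset)
        if rec.gene_label in retained:
            records.append(
                ScreenRecord(
                    probeset_id=probeset,
                    gene_id=rec.gene_id,
                    probeset_overlap=count,
                    gene_overlap=g_overlap[rec.gene_label],
                    gene_symbol=rec.gene_symbol,
                    gene_name=rec.gene_name,
                )
            )
    return ScreenReport.from_records(
        n_studies=len(studies),
        k=k,
        min_studies=min_studies,
        records=records,
        direction=direction,
    )
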