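"""Domain types and tabular I/O for the cross-study expression screen.

All artifacts are UTF-8 tab-separated text with '.' decimal separators:

* expression matrix — header ``probeset_id<TAB>sample1<TAB>...``, one row per
  probeset of log2 intensities;
* design — header ``sample_id<TAB>group`` with group in
  {``pluripotent``, ``differentiated``};
* annotation — header ``probeset_id<TAB>gene_id<TAB>gene_symbol<TAB>gene_name``
  (gene fields may be empty; a symbol-less probeset self-annotates, i.e. its
  gene label is its own accession, so transcribed-locus probesets survive
  gene-level aggregation as singleton genes);
* screen report — ``#``-prefixed metadata lines followed by a header that
  mirrors the published marker table (Probesets, Gene ID, overlap counts,
  Gene symbol, Gene names).

Probeset order in matrix files is preserved on read; screen reports are kept
in a canonical order (gene overlap desc, probeset overlap desc, probeset id
asc) regardless of the order found on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("pluripotent", "differentiated")

REPORT_COLUMNS = (
    "Probesets",
    "Gene ID",
    "Overlapping number of probesets",
    "Overlapping number of genes",
    "Gene symbol",
    "Gene names",
)


class StemscreenError(ValueError):
    """Base class for validation and I/O failures raised by this package."""


# ---------------------------------------------------------------------------
# Expression studies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionStudy:
    """One study's normalized log2 intensity matrix plus its group design.

    ``values`` has one row per probeset and one column per sample, in the
    order of ``probeset_ids`` / ``sample_ids``. ``group_of`` assigns every
    sample to ``pluripotent`` or ``differentiated``; both groups must be
    non-empty for a fold change to exist.
    """

    study_id: str
    probeset_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probeset_ids", tuple(self.probeset_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "group_of", dict(self.group_of))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            raise StemscreenError(
                f"study {self.study_id!r}: duplicate probeset IDs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise StemscreenError(f"study {self.study_id!r}: duplicate sample IDs")
        if values.shape != (len(self.probeset_ids), len(self.sample_ids)):
            raise StemscreenError(
                f"study {self.study_id!r}: matrix shape {values.shape} does not "
                f"match {len(self.probeset_ids)} probesets x "
                f"{len(self.sample_ids)} samples"
            )
        if np.isnan(values).any():
            raise StemscreenError(
                f"study {self.study_id!r}: matrix contains missing values"
            )
        for sample in self.sample_ids:
            group = self.group_of.get(sample)
            if group is None:
                raise StemscreenError(
                    f"study {self.study_id!r}: sample {sample!r} has no group "
                    "assignment in the design"
                )
            if group not in GROUPS:
                raise StemscreenError(
                    f"study {self.study_id!r}: sample {sample!r} has unknown "
                    f"group {group!r}; expected one of {GROUPS}"
                )
        for group in GROUPS:
            if not self.samples_in(group):
                raise StemscreenError(
                    f"study {self.study_id!r}: group {group!r} is empty"
                )

    def samples_in(self, group: str) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.group_of[s] == group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.probeset_ids), columns=list(self.sample_ids)
        )

    def with_swapped_groups(self) -> "ExpressionStudy":
        """Return the same study with pluripotent/differentiated labels swapped."""
        flipped = {
            s: GROUPS[1] if g == GROUPS[0] else GROUPS[0]
            for s, g in self.group_of.items()
        }
        return replace(self, group_of=flipped)


def read_expression_study(
    matrix_path: str | Path,
    design_path: str | Path,
    study_id: str | None = None,
) -> ExpressionStudy:
    """Load one study from a matrix TSV and a two-column design TSV.

    Rows containing any missing value are dropped with a logged warning
    (silent imputation would change fold-change ranks). Samples present in
    the matrix but absent from the design are rejected.
    """
    matrix_path = Path(matrix_path)
    design_path = Path(design_path)
    try:
        frame = pd.read_csv(
            matrix_path,
            sep="\t",
            index_col=0,
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise StemscreenError(f"{matrix_path}: malformed matrix TSV: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise StemscreenError(f"{matrix_path}: duplicate probeset IDs {dupes}")
    for column in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[column]):
            bad = frame[pd.to_numeric(frame[column], errors="coerce").isna()]
            line = int(bad.reset_index().index[0]) + 2 if len(bad) else "?"
            raise StemscreenError(
                f"{matrix_path}: non-numeric expression value in column "
                f"{column!r} near line {line}"
            )
    incomplete = frame.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "%s: dropping %d probeset rows with missing values",
            matrix_path,
            int(incomplete.sum()),
        )
        frame = frame.loc[~incomplete]

    design = _read_design(design_path)
    missing = [s for s in frame.columns if s not in design]
    if missing:
        raise StemscreenError(
            f"{design_path}: samples {missing} from {matrix_path.name} are "
            "missing from the design"
        )
    return ExpressionStudy(
        study_id=study_id if study_id is not None else matrix_path.stem,
        probeset_ids=tuple(str(p) for p in frame.index),
        sample_ids=tuple(str(s) for s in frame.columns),
        values=frame.to_numpy(dtype=float),
        group_of={s: design[s] for s in frame.columns},
    )


def _read_design(design_path: Path) -> dict[str, str]:
    design: dict[str, str] = {}
    with open(design_path, encoding="utf-8") as handle:
        header = handle.readline()
        if header.rstrip("\n").split("\t") != ["sample_id", "group"]:
            raise StemscreenError(
                f"{design_path}: line 1: expected header 'sample_id<TAB>group'"
            )
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise StemscreenError(
                    f"{design_path}: line {lineno}: expected 2 tab-separated "
                    f"fields, got {len(parts)}"
                )
            sample, group = parts
            if sample in design:
                raise StemscreenError(
                    f"{design_path}: line {lineno}: duplicate sample {sample!r}"
                )
            if group not in GROUPS:
                raise StemscreenError(
                    f"{design_path}: line {lineno}: unknown group {group!r}; "
                    f"expected one of {GROUPS}"
                )
            design[sample] = group
    return design


def write_expression_study(
    study: ExpressionStudy, matrix_path: str | Path, design_path: str | Path
) -> None:
    """Write a study back to matrix/design TSVs (full float precision)."""
    frame = study.to_frame()
    frame.index.name = "probeset_id"
    frame.to_csv(matrix_path, sep="\t", float_format=None)
    with open(design_path, "w", encoding="utf-8") as handle:
        handle.write("sample_id\tgroup\n")
        for sample in study.sample_ids:
            handle.write(f"{sample}\t{study.group_of[sample]}\n")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationRecord:
    probeset_id: str
    gene_id: str = ""
    gene_symbol: str = ""
    gene_name: str = ""

    @property
    def gene_label(self) -> str:
        """Gene symbol, or the probeset's own accession when symbol-less."""
        return self.gene_symbol if self.gene_symbol else self.probeset_id


@dataclass(frozen=True)
class AnnotationTable:
    """Probeset → gene identity map with self-annotation for symbol-less rows."""

    records: tuple[AnnotationRecord, ...]
    _by_probeset: dict[str, AnnotationRecord] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        index: dict[str, AnnotationRecord] = {}
        for record in self.records:
            if record.probeset_id in index:
                raise StemscreenError(
                    f"annotation: duplicate probeset_id {record.probeset_id!r}"
                )
            index[record.probeset_id] = record
        object.__setattr__(self, "_by_probeset", index)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, probeset_id: str) -> bool:
        return probeset_id in self._by_probeset

    def record_for(self, probeset_id: str) -> AnnotationRecord:
        try:
            return self._by_probeset[probeset_id]
        except KeyError:
            raise StemscreenError(
                f"annotation: probeset {probeset_id!r} is not annotated"
            ) from None

    def gene_label(self, probeset_id: str) -> str:
        return self.record_for(probeset_id).gene_label


ANNOTATION_COLUMNS = ("probeset_id", "gene_id", "gene_symbol", "gene_name")


def read_annotation(path: str | Path) -> AnnotationTable:
    path = Path(path)
    records: list[AnnotationRecord] = []
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != ANNOTATION_COLUMNS:
            raise StemscreenError(
                f"{path}: line 1: expected header "
                f"{'<TAB>'.join(ANNOTATION_COLUMNS)}"
            )
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise StemscreenError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields, "
                    f"got {len(parts)}"
                )
            records.append(AnnotationRecord(*parts))
    try:
        return AnnotationTable(tuple(records))
    except StemscreenError as exc:
        raise StemscreenError(f"{path}: {exc}") from None


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for rec in table.records:
            handle.write(
                f"{rec.probeset_id}\t{rec.gene_id}\t{rec.gene_symbol}\t"
                f"{rec.gene_name}\n"
            )


# ---------------------------------------------------------------------------
# Screen report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenRecord:
    """One report row: a probeset, its gene, and the two overlap counts.

    ``probeset_overlap`` counts the studies whose top-k list contains this
    probeset; ``gene_overlap`` counts the studies in which *any* probeset of
    the same gene is top-listed, so gene_overlap >= probeset_overlap always.
    """

    probeset_id: str
    gene_id: str
    probeset_overlap: int
    gene_overlap: int
    gene_symbol: str = ""
    gene_name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.probeset_overlap <= self.gene_overlap):
            raise StemscreenError(
                f"record {self.probeset_id!r}: overlap counts "
                f"({self.probeset_overlap}, {self.gene_overlap}) violate "
                "0 <= probeset_overlap <= gene_overlap"
            )

    @property
    def gene_label(self) -> str:
        return self.gene_symbol if self.gene_symbol else self.probeset_id


def _record_sort_key(record: ScreenRecord) -> tuple[int, int, str]:
    return (-record.gene_overlap, -record.probeset_overlap, record.probeset_id)


@dataclass(frozen=True)
class ScreenReport:
    """Result of the cross-study screen, in canonical row order."""

    n_studies: int
    k: int
    min_studies: int
    records: tuple[ScreenRecord, ...]
    direction: str = "esc_high"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    @classmethod
    def from_records(
        cls,
        n_studies: int,
        k: int,
        min_studies: int,
        records: Iterable[ScreenRecord],
        direction: str = "esc_high",
    ) -> "ScreenReport":
        """Build a report, sorting records into canonical order and validating."""
        ordered = tuple(sorted(records, key=_record_sort_key))
        report = cls(n_studies, k, min_studies, ordered, direction)
        report.validate()
        return report

    def validate(self) -> None:
        for record in self.records:
            if record.gene_overlap > self.n_studies:
                raise StemscreenError(
                    f"record {record.probeset_id!r}: gene_overlap "
                    f"{record.gene_overlap} exceeds n_studies {self.n_studies}"
                )
            if record.gene_overlap < self.min_studies:
                raise StemscreenError(
                    f"record {record.probeset_id!r}: gene_overlap "
                    f"{record.gene_overlap} is below the retention threshold "
                    f"{self.min_studies}"
                )
        keys = [_record_sort_key(r) for r in self.records]
        if keys != sorted(keys):
            raise StemscreenError("report records are not in canonical order")

    def record_for(self, probeset_id: str) -> ScreenRecord:
        for record in self.records:
            if record.probeset_id == probeset_id:
                return record
        raise StemscreenError(f"report has no record for probeset {probeset_id!r}")

    def records_for_gene(self, gene_label: str) -> tuple[ScreenRecord, ...]:
        return tuple(r for r in self.records if r.gene_label == gene_label)

    @property
    def gene_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for record in self.records:
            seen.setdefault(record.gene_label, None)
        return tuple(seen)


def write_screen_report(report: ScreenReport, path: str | Path) -> None:
    """Serialize a report; fails if ordering/threshold invariants are broken."""
    report.validate()
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"# n_studies={report.n_studies}\n")
        handle.write(f"# k={report.k}\n")
        handle.write(f"# min_studies={report.min_studies}\n")
        handle.write(f"# direction={report.direction}\n")
        handle.write("\t".join(REPORT_COLUMNS) + "\n")
        for rec in report.records:
            handle.write(
                f"{rec.probeset_id}\t{rec.gene_id}\t{rec.probeset_overlap}\t"
                f"{rec.gene_overlap}\t{rec.gene_symbol}\t{rec.gene_name}\n"
            )


def read_screen_report(path: str | Path) -> ScreenReport:
    """Parse a report TSV, canonicalizing row order; inverse of write."""
    path = Path(path)
    meta: dict[str, str] = {}
    records: list[ScreenRecord] = []
    with open(path, encoding="utf-8") as handle:
        lineno = 0
        header_seen = False
        for raw in handle:
            lineno += 1
            line = raw.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not line:
                continue
            parts = line.split("\t")
            if not header_seen:
                if tuple(parts) != REPORT_COLUMNS:
                    raise StemscreenError(
                        f"{path}: line {lineno}: expected report header "
                        f"{list(REPORT_COLUMNS)}"
                    )
                header_seen = True
                continue
            if len(parts) != len(REPORT_COLUMNS):
                raise StemscreenError(
                    f"{path}: line {lineno}: expected {len(REPORT_COLUMNS)} "
                    f"fields, got {len(parts)}"
                )
            probeset_id, gene_id, p_ov, g_ov, symbol, name = parts
            try:
                record = ScreenRecord(
                    probeset_id=probeset_id,
                    gene_id=gene_id,
                    probeset_overlap=int(p_ov),
                    gene_overlap=int(g_ov),
                    gene_symbol=symbol,
                    gene_name=name,
                )
            except StemscreenError as exc:
                raise StemscreenError(f"{path}: line {lineno}: {exc}") from None
            records.append(record)
    for key in ("n_studies", "k", "min_studies"):
        if key not in meta:
            raise StemscreenError(f"{path}: missing '# {key}=' metadata line")
    try:
        return ScreenReport.from_records(
            n_studies=int(meta["n_studies"]),
            k=int(meta["k"]),
            min_studies=int(meta["min_studies"]),
            records=records,
            direction=meta.get("direction", "esc_high"),
        )
    except StemscreenError as exc:
        raise StemscreenError(f"{path}: {exc}") from None


def packaged_marker_table_path() -> Path:
    """Path of the packaged published marker-table fixture (33 records)."""
    return Path(__file__).parent / "data" / "table1_screen_report.tsv"


def read_packaged_marker_table() -> ScreenReport:
    return read_screen_report(packaged_marker_table_path())
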