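"""Spliced-transcript assembly and exon-junction-aware ORF scanning.

Alternative exon inclusion can create a premature stop codon whose three
nucleotides are contributed by two adjacent exons: skipping an internal exon
joins sequence that, read in frame, happens to spell TAA/TAG/TGA at the new
junction. This module assembles a transcript isoform from an ordered exon
selection, records where each exon junction falls in the spliced sequence,
scans the forward strand for the first open reading frame, and flags stop
codons that straddle a junction.

Result coordinates are 1-based inclusive nucleotide positions (the
convention of transcript annotation); junctions are 0-based internally and
converted in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .io_model import StemscreenError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Exon:
    """A named exon sequence over {A, C, G, T}, uppercase-normalized.

    Ambiguity codes are rejected outright: the point of the scan is exact
    stop-codon accounting, which an N would silently corrupt.
    """

    exon_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise StemscreenError(f"exon {self.exon_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise StemscreenError(
                f"exon {self.exon_id!r}: invalid bases {sorted(bad)} "
                "(only A/C/G/T are accepted)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptIsoform:
    """A spliced mRNA: ordered exons, their concatenation, and junction map.

    ``junctions`` holds the 0-based positions in ``spliced_sequence`` where a
    new exon begins; the first junction equals the length of the first exon,
    and a single-exon transcript has none.
    """

    isoform_id: str
    exon_order: tuple[str, ...]
    spliced_sequence: str
    junctions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_order", tuple(self.exon_order))
        object.__setattr__(self, "junctions", tuple(self.junctions))
        if list(self.junctions) != sorted(set(self.junctions)):
            raise StemscreenError(
                f"isoform {self.isoform_id!r}: junctions must be strictly increasing"
            )
        if any(j <= 0 or j >= len(self.spliced_sequence) for j in self.junctions):
            raise StemscreenError(
                f"isoform {self.isoform_id!r}: junctions must fall strictly "
                "inside the spliced sequence"
            )


def splice(
    exons: Mapping[str, Exon] | Iterable[Exon],
    order: Sequence[str],
    isoform_id: str | None = None,
) -> TranscriptIsoform:
    """Concatenate exons in the given order and record junction positions."""
    if not isinstance(exons, Mapping):
        exons = {exon.exon_id: exon for exon in exons}
    if not order:
        raise StemscreenError("splice: exon order is empty")
    pieces = []
    for exon_id in order:
        if exon_id not in exons:
            raise StemscreenError(f"splice: unknown exon id {exon_id!r}")
        pieces.append(exons[exon_id].sequence)
    junctions = []
    pos = 0
    for piece in pieces[:-1]:
        pos += len(piece)
        junctions.append(pos)
    return TranscriptIsoform(
        isoform_id=isoform_id if isoform_id is not None else "+".join(order),
        exon_order=tuple(order),
        spliced_sequence="".join(pieces),
        junctions=tuple(junctions),
    )


@dataclass(frozen=True)
class OrfResult:
    """Outcome of a forward-strand ORF scan, in 1-based coordinates.

    ``start_pos`` is the first nucleotide of the initiator codon (None when
    no start exists under the policy). ``stop_interval`` is the inclusive
    nucleotide span of the terminating stop codon, or None when translation
    runs off the end. ``peptide_length`` counts residues including the
    initiator and excluding the stop. ``junction_spanning_stop`` is True when
    the stop codon's nucleotides are contributed by two exons, i.e. an exon
    boundary falls strictly inside the codon's interval.
    """

    start_pos: int | None
    stop_interval: tuple[int, int] | None
    peptide_length: int | None
    junction_spanning_stop: bool = False

    @property
    def has_orf(self) -> bool:
        return self.start_pos is not None


START_POLICIES = ("first_atg", "position_1")


def scan_orf(isoform: TranscriptIsoform, start_policy: str = "first_atg") -> OrfResult:
    """Translate from the start codon to the first in-frame stop.

    ``first_atg`` starts at the first ATG anywhere in the spliced sequence;
    ``position_1`` forces the reading frame to open at nucleotide 1 (used
    when the transcript is already CDS-trimmed). Codons are read
    consecutively; the scan halts at the first of TAA/TAG/TGA. Without a
    stop, the peptide length counts all complete codons read.
    """
    seq = isoform.spliced_sequence
    if len(seq) < 3:
        raise StemscreenError(
            f"isoform {isoform.isoform_id!r}: spliced sequence shorter than one codon"
        )
    if start_policy not in START_POLICIES:
        raise StemscreenError(
            f"unknown start policy {start_policy!r}; expected one of {START_POLICIES}"
        )
    if start_policy == "first_atg":
        start0 = seq.find(START_CODON)
        if start0 == -1:
            return OrfResult(start_pos=None, stop_interval=None, peptide_length=None)
    else:
        start0 = 0

    n_codons = 0
    for codon_start in range(start0, len(seq) - 2, 3):
        codon = seq[codon_start : codon_start + 3]
        if codon in STOP_CODONS:
            # a junction at 0-based position j splits the codon iff the new
            # exon begins at its 2nd or 3rd nucleotide
            spanning = any(
                codon_start < j < codon_start + 3 for j in isoform.junctions
            )
            return OrfResult(
                start_pos=start0 + 1,
                stop_interval=(codon_start + 1, codon_start + 3),
                peptide_length=n_codons,
                junction_spanning_stop=spanning,
            )
        n_codons += 1
    return OrfResult(start_pos=start0 + 1, stop_interval=None, peptide_length=n_codons)


_SAFE_CODONS = ("GCT", "GAA", "CTG", "AAA", "TTC", "GGC", "CCT", "GAT")


def synthetic_junction_stop_exons() -> dict[str, Exon]:
    """A synthetic three-exon gene whose exon-2-skipping isoform is truncated.

    The exon sequences are constructed, not taken from any real transcript.
    Exon 1 opens with ATG and carries 50 complete non-stop codons plus one
    dangling T (151 nt). Including exon 2 continues the frame (the junction
    codon reads TCT) into a longer ORF; skipping to exon 3, which begins GA,
    assembles TGA across the junction, so the short isoform terminates at
    nt 151-153 after a 50-residue peptide.
    """
    body = "".join(_SAFE_CODONS[i % len(_SAFE_CODONS)] for i in range(49))
    exon1 = "ATG" + body + "T"
    assert len(exon1) == 151
    exon2_body = "".join(_SAFE_CODONS[(i + 3) % len(_SAFE_CODONS)] for i in range(29))
    exon2 = "CT" + exon2_body + "TGA"
    exon3 = "GACCCGGGTTTACGT"
    return {
        "exon1": Exon("exon1", exon1),
        "exon2": Exon("exon2", exon2),
        "exon3": Exon("exon3", exon3),
    }


def read_exons_fasta(path: str | Path) -> dict[str, Exon]:
    """Load exons from FASTA; the record id is the exon id."""
    exons: dict[str, Exon] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in exons:
            raise StemscreenError(f"{path}: duplicate exon id {record.id!r}")
        exons[record.id] = Exon(exon_id=record.id, sequence=str(record.seq))
    if not exons:
        raise StemscreenError(f"{path}: no FASTA records found")
    return exons


def write_exons_fasta(exons: Mapping[str, Exon], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for exon in exons.values():
            handle.write(f">{exon.exon_id}\n{exon.sequence}\n")
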