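# Methods

## The screen

Each study *s* contributes a normalized log2 expression matrix (probesets ×
samples) and a design assigning every sample to the pluripotent or the
differentiated group. The per-probeset score is the unmoderated log2 fold
change

    FC_{s,p} = mean_{i in pluripotent} x_{s,p,i} − mean_{j in differentiated} x_{s,p,j}

equivalently the log2 ratio of within-group geometric means on the raw
scale. No t-statistic, shrinkage or p-value is computed: the screen relies
on between-study consistency, not within-study inference, so the only
per-study output that matters is a ranking.

Ranking direction `esc_high` sorts by signed FC descending, putting
pluripotent-enriched probesets first; this is the default because the screen
targets genes that fall on differentiation. An `absolute` mode (|FC|
descending) is provided for screens that should also surface
differentiation-induced genes — the published table contains entries such
as COL1A1 that plausibly entered that way, and the chosen mode is recorded
in the report header. Ties are broken lexicographically on probeset id and
the list is never expanded past *k*: every ranking is total, so the whole
pipeline is deterministic and byte-reproducible.

Overlap counting: a probeset's overlap is the number of studies whose top-*k*
list contains it. A gene's study set is the union over its probesets of the
studies listing that probeset, and its overlap is the size of that union —
hence gene overlap ≥ the max of its probesets' overlaps, and ≤ their sum.
Selection happens at probeset level and aggregation afterward, matching a
report that carries both counts per row. The retention filter applies to the
*gene*-level count (a table that keeps rows with probeset overlap 2–3 but
gene overlap 4 forces this reading). Studies need not share an identical
probeset universe: a probeset absent from a study simply cannot be
top-listed there.

Probesets without a gene symbol self-annotate — their gene label is their
own accession — so "transcribed locus" probesets survive aggregation as
singleton genes instead of being silently merged or dropped.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 100 | per-study top-list size (probesets) |
| `min_studies` | 4 | gene-level overlap needed for retention |
| `direction` | `esc_high` | ranking key (signed vs absolute FC) |

## The simulator

`SimConfig` defaults describe the study conditions the screen assumes:
7 independent studies, 2000 genes interrogated by 1–3 probesets (drawn
uniformly per gene), 3 samples per group. Per gene and study a baseline is
drawn once from Normal(8.0, 2.0²) log2 units — capturing both biological
level and study-specific offsets — and shared by the gene's probesets, which
matters: shared baseline with independent per-probeset noise
(Normal(0, 0.25²) per sample) is what makes the gene-level union count
informative beyond any single probeset. The 20 planted markers add +3.0
log2 (8-fold) to the pluripotent group in their active studies;
`planted_study_fraction` thins the active set per (marker, study) to model
markers that not every study can see. A 3.0 effect over 0.25 noise is the
strong-marker regime a fold-change-only screen presumes; recovery
degradation can be explored by shrinking the ratio or the fraction.

One `numpy` generator seeded once drives all draws, ordered by gene → (its
baselines) → probeset → (its noise block); the planted-gene indices and
per-marker active-study masks are drawn before the value loop. Identical
configs therefore reproduce matrices bit-for-bit on any platform.

What the simulator does *not* model: platform probe effects, batch or lab
structure beyond the per-study baseline, raw-intensity (pre-log)
distributions, correlated genes, or missingness. Passing recovery tests
show the screen's logic is correct under its own assumptions; they do not
show that real array studies satisfy those assumptions.

Recovery scoring: sensitivity = retained∩planted / planted; precision =
retained∩planted / retained. An empty report leaves precision undefined; it
is reported as 1.0 with `precision_defined=False` so downstream tables stay
numeric while the edge is visible.

## The ORF scanner

A transcript isoform is an ordered exon concatenation plus the 0-based
positions where each new exon begins. The scan reads consecutive codons
from the start codon — the first ATG anywhere (`first_atg`), or nucleotide 1
(`position_1`) for CDS-trimmed input — and halts at the first TAA/TAG/TGA.
Results use 1-based inclusive nucleotide coordinates, the convention of
transcript annotation; the stop codon is "junction-spanning" when an exon
boundary falls strictly inside its 3-nt interval, i.e. the triplet is
assembled from two exons. Only the forward strand is scanned (the input is
mRNA sense sequence), and ambiguity codes are rejected at exon construction
rather than guessed at, since the module's purpose is exact stop
accounting. Without any stop, the peptide length counts all complete codons
read; without any ATG under `first_atg`, the result is an explicit
absent-ORF value, not an error.

The packaged demo gene is synthetic: exon 1 carries ATG plus 49 non-stop
codons and a dangling T (151 nt), exon 3 begins GA, so the exon-2-skipping
isoform assembles TGA at nt 151–153 and encodes 50 residues, while the
exon-1+2 isoform reads through the junction (codon TCT) into a longer ORF.
It reproduces the junction-stop geometry exactly without shipping any
third-party sequence.

## Numerical and format choices

- All tabular I/O is UTF-8 TSV, '.' decimals, no thousands separators;
  expression values are written at full float precision and re-read with
  round-trip parsing, so write→read is exact.
- Matrix rows containing missing values are dropped at load with a warning;
  imputation would silently change ranks.
- Screen reports are kept in a canonical order (gene overlap desc, probeset
  overlap desc, probeset id asc). Reading canonicalizes; writing validates
  and refuses records violating ordering or the retention threshold.
- Fold changes are plain float64 mean differences; antisymmetry under group
  swap is exact in IEEE arithmetic and asserted as such.

## Problem sizes used in tests

Unit tests run on studies of tens of probesets; the recovery and null
suites run the full default configuration (7 studies × ~4000 probesets × 6
samples) across ten seeds each, a few seconds in total. The brute-force
overlap oracle covers 200 random instances of up to 6 studies and 100
probesets. These sizes exercise every code path at the defaults the screen
documents while keeping the suite fast.

## Known limitations

- The screen consumes already-normalized log2 matrices; CEL-level
  normalization and probe summarization are out of scope.
- Whether the original top-100 selection ranked by signed or absolute fold
  change, and whether it was made at probeset or gene level before
  combining, is not recoverable from the published description; this design
  fixes signed ranking at probeset level with post-hoc gene aggregation,
  and exposes `absolute` as an option.
- Gene-level aggregation trusts the annotation table; mis-mapped probesets
  propagate into gene counts.
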