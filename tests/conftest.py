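import numpy as np
import pytest

from stemscreen import AnnotationRecord, AnnotationTable, ExpressionStudy
from stemscreen.orf import synthetic_junction_stop_exons


def build_study(study_id, per_probeset, n_plu=None, n_dif=None):
    """Build an ExpressionStudy from {probeset: (pluripotent vals, differentiated vals)}."""
    probesets = list(per_probeset)
    first_plu, first_dif = per_probeset[probesets[0]]
    n_plu = len(first_plu) if n_plu is None else n_plu
    n_dif = len(first_dif) if n_dif is None else n_dif
    samples = [f"{study_id}_p{i}" for i in range(n_plu)] + [
        f"{study_id}_d{i}" for i in range(n_dif)
    ]
    groups = {s: ("pluripotent" if i < n_plu else "differentiated") for i, s in enumerate(samples)}
    values = np.array([list(plu) + list(dif) for plu, dif in per_probeset.values()], dtype=float)
    return ExpressionStudy(
        study_id=study_id,
        probeset_ids=tuple(probesets),
        sample_ids=tuple(samples),
        values=values,
        group_of=groups,
    )


def annotation_for(gene_of):
    """AnnotationTable from {probeset: gene_symbol} ('' means self-annotated)."""
    return AnnotationTable(
        tuple(
            AnnotationRecord(probeset_id=p, gene_id="", gene_symbol=g, gene_name="")
            for p, g in gene_of.items()
        )
    )


@pytest.fixture
def demo_exons():
    return synthetic_junction_stop_exons()
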