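"""The cross-study screen: fold changes, top-k ranking, overlap counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemscreen import (
    FoldChangeTable,
    StemscreenError,
    StudyTopList,
    fold_changes,
    gene_overlap,
    probeset_overlap,
    run_screen,
    top_k,
)
from stemscreen.io_model import write_screen_report
from stemscreen.synthetic import SimConfig, simulate_studies

from conftest import annotation_for, build_study


class TestFoldChanges:
    def test_mean_difference_is_exact(self):
        study = build_study("s", {"p1": ([8, 8, 8], [5, 5, 5])})
        assert fold_changes(study).entries["p1"] == 3.0

    def test_swapping_groups_negates(self):
        study = build_study("s", {"p1": ([8, 8, 8], [5, 5, 5])})
        assert fold_changes(study.with_swapped_groups()).entries["p1"] == -3.0

    def test_matches_bruteforce_two_loop_means(self):
        rng = np.random.default_rng(0)
        values = rng.normal(8, 2, size=(20, 6))
        study = build_study(
            "s", {f"p{i:02d}": (values[i, :3], values[i, 3:]) for i in range(20)}
        )
        fc = fold_changes(study).entries
        for i, probeset in enumerate(study.probeset_ids):
            plu = sum(values[i, j] for j in range(3)) / 3
            dif = sum(values[i, j] for j in range(3, 6)) / 3
            assert fc[probeset] == pytest.approx(plu - dif, abs=1e-12)

    @given(
        plu=st.lists(st.floats(-16, 16, allow_nan=False), min_size=1, max_size=5),
        dif=st.lists(st.floats(-16, 16, allow_nan=False), min_size=1, max_size=5),
    )
    @settings(deadline=None, derandomize=True)
    def test_antisymmetry_under_group_swap(self, plu, dif):
        study = build_study("s", {"p1": (plu, dif)})
        forward = fold_changes(study).entries["p1"]
        backward = fold_changes(study.with_swapped_groups()).entries["p1"]
        assert forward == -backward


class TestTopK:
    def test_signed_ranking(self):
        fc = FoldChangeTable("s", {"a": 3.0, "b": 2.0, "c": 1.0})
        assert top_k(fc, 2).probesets == ("a", "b")

    def test_tie_broken_lexicographically_without_expansion(self):
        fc = FoldChangeTable("s", {"b": 2.0, "a": 2.0})
        assert top_k(fc, 1).probesets == ("a",)

    def test_absolute_vs_esc_high_direction(self):
        fc = FoldChangeTable("s", {"a": -3.0, "b": 2.0})
        assert top_k(fc, 1, "absolute").probesets == ("a",)
        assert top_k(fc, 1, "esc_high").probesets == ("b",)

    @given(
        entries=st.dictionaries(
            st.text("abcdefgh", min_size=1, max_size=3),
            st.floats(-8, 8, allow_nan=False),
            min_size=1,
            max_size=20,
        ),
        k=st.integers(1, 25),
        direction=st.sampled_from(["esc_high", "absolute"]),
    )
    @settings(deadline=None, derandomize=True)
    def test_size_and_input_order_invariance(self, entries, k, direction):
        fc = FoldChangeTable("s", entries)
        result = top_k(fc, k, direction)
        assert len(result.probesets) == min(k, len(entries))
        reversed_fc = FoldChangeTable("s", dict(reversed(list(entries.items()))))
        assert top_k(reversed_fc, k, direction).probesets == result.probesets

    def test_k_below_one_rejected(self):
        with pytest.raises(StemscreenError, match="k"):
            top_k(FoldChangeTable("s", {"a": 1.0}), 0)


def toy_lists(memberships):
    """StudyTopLists from {study_id: [probesets]}."""
    return [
        StudyTopList(study_id=sid, k=len(ps), direction="esc_high", probesets=tuple(ps))
        for sid, ps in memberships.items()
    ]


class TestOverlapCounting:
    def test_single_study_counts_one_each(self):
        counts = probeset_overlap(toy_lists({"s1": ["a", "b"]}))
        assert counts == {"a": 1, "b": 1}

    def test_probeset_in_all_seven_studies_counts_seven(self):
        lists = toy_lists({f"s{i}": ["marker", f"filler{i}"] for i in range(7)})
        assert probeset_overlap(lists)["marker"] == 7

    def test_duplicate_study_id_rejected(self):
        lists = toy_lists({"s1": ["a"]}) + toy_lists({"s1": ["b"]})
        with pytest.raises(StemscreenError, match="duplicate study_id"):
            probeset_overlap(lists)

    def test_gene_union_semantics(self):
        # p1 listed in studies 1-3, p2 in 3-4 -> the gene spans 4 studies
        lists = toy_lists({"s1": ["p1"], "s2": ["p1"], "s3": ["p1", "p2"], "s4": ["p2"]})
        annotation = annotation_for({"p1": "G", "p2": "G"})
        assert gene_overlap(lists, annotation) == {"G": 4}

    def test_single_probeset_gene_equals_probeset_overlap(self):
        lists = toy_lists({"s1": ["p1"], "s2": ["p1"], "s3": []})
        annotation = annotation_for({"p1": "G"})
        assert gene_overlap(lists, annotation)["G"] == probeset_overlap(lists)["p1"]

    def test_unannotated_probeset_failure_names_it(self):
        lists = toy_lists({"s1": ["mystery_at"]})
        with pytest.raises(StemscreenError, match="mystery_at"):
            gene_overlap(lists, annotation_for({}))

    def test_counts_match_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_studies = int(rng.integers(1, 7))
            probesets = [f"p{i:03d}" for i in range(int(rng.integers(4, 101)))]
            gene_of = {p: f"G{i // int(rng.integers(1, 4))}" for i, p in enumerate(probesets)}
            k = int(rng.integers(1, len(probesets) + 1))
            lists = [
                StudyTopList(
                    f"s{s}", k, "esc_high",
                    tuple(rng.choice(probesets, size=k, replace=False)),
                )
                for s in range(n_studies)
            ]
            p_counts = probeset_overlap(lists)
            g_counts = gene_overlap(lists, annotation_for(gene_of))
            for p in set().union(*(tl.probesets for tl in lists)):
                assert p_counts[p] == sum(1 for tl in lists if p in tl.probesets)
            for gene in set(gene_of.values()):
                members = [p for p in probesets if gene_of[p] == gene]
                union = {tl.study_id for tl in lists for p in members if p in tl.probesets}
                if union:
                    assert g_counts[gene] == len(union)
                else:
                    assert gene not in g_counts

    def test_gene_overlap_bounded_by_probeset_overlaps(self):
        rng = np.random.default_rng(5)
        probesets = [f"p{i}" for i in range(30)]
        gene_of = {p: f"G{i // 3}" for i, p in enumerate(probesets)}
        lists = [
            StudyTopList(f"s{s}", 8, "esc_high",
                         tuple(rng.choice(probesets, size=8, replace=False)))
            for s in range(5)
        ]
        p_counts = probeset_overlap(lists)
        g_counts = gene_overlap(lists, annotation_for(gene_of))
        for gene, count in g_counts.items():
            members = [p for p in p_counts if gene_of[p] == gene]
            assert max(p_counts[p] for p in members) <= count
            assert count <= sum(p_counts[p] for p in members)
            assert count <= len(lists)


@pytest.fixture(scope="module")
def small_sim():
    config = SimConfig(n_studies=7, n_genes=150, n_planted=5, seed=3)
    return simulate_studies(config)


class TestRunScreen:
    def test_unreachable_threshold_empties_report(self, small_sim):
        studies, annotation, _ = small_sim
        report = run_screen(studies, annotation, k=10, min_studies=8)
        assert report.records == ()

    def test_planted_marker_leads_report_with_full_overlap(self, small_sim):
        studies, annotation, truth = small_sim
        report = run_screen(studies, annotation, k=10, min_studies=4)
        first = report.records[0]
        assert first.gene_label in truth.planted_genes
        assert first.probeset_overlap == first.gene_overlap == 7

    def test_raising_min_studies_shrinks_record_set(self, small_sim):
        studies, annotation, _ = small_sim
        loose = run_screen(studies, annotation, k=20, min_studies=4)
        strict = run_screen(studies, annotation, k=20, min_studies=5)
        assert set(strict.records) <= set(loose.records)
        smaller_k = run_screen(studies, annotation, k=10, min_studies=4)
        assert {r.probeset_id for r in smaller_k.records} <= {
            r.probeset_id for r in loose.records
        }

    def test_identical_inputs_give_byte_identical_reports(self, small_sim, tmp_path):
        studies, annotation, _ = small_sim
        for name in ("r1.tsv", "r2.tsv"):
            write_screen_report(run_screen(studies, annotation, k=10), tmp_path / name)
        assert (tmp_path / "r1.tsv").read_bytes() == (tmp_path / "r2.tsv").read_bytes()

    def test_no_studies_rejected(self, small_sim):
        _, annotation, _ = small_sim
        with pytest.raises(StemscreenError, match="at least one"):
            run_screen([], annotation)
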