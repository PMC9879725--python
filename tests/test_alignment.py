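"""Wave-based distance computation and LCS-graph construction."""

import random

import pytest

from varrel.alignment import (
    build_lcs_graph,
    edit_distance,
    element_set,
    enumerate_minimal,
    lcs_length,
    node_level,
    to_dot,
)
from varrel.errors import EnumerationCapError
from varrel.oracle_fixtures import dp_full_matrix, enumerate_paths
from varrel.variant_model import Deletion, Insertion, patch

from conftest import all_strings, canonical


class TestEditDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("CATATATCG", "CTTATAGCAT", 7),
        ("CT", "TG", 2),
        ("CT", "GC", 2),
        ("TG", "GC", 2),
        ("ATTTA", "ATTA", 1),
        ("ACGT", "ACGT", 0),
        ("", "ACGT", 4),
        ("ACGT", "", 4),
        ("", "", 0),
    ])
    def test_examples(self, a, b, expected):
        assert edit_distance(a, b) == expected
        assert edit_distance(b, a) == expected

    @pytest.mark.parametrize("a,b,expected", [
        ("CATATATCG", "CTTATAGCAT", 6),
        ("ACGT", "ACGT", 4),
        ("AAA", "TTT", 0),
    ])
    def test_lcs_length(self, a, b, expected):
        assert lcs_length(a, b) == expected


class TestWaves:
    def test_first_wave_runs_at_initial_heuristic(self):
        graph = build_lcs_graph("CATATATCG", "CTTATAGCAT")
        assert graph.waves[0].f == 1  # h(R, O, 0, 0) = ||R| - |O||
        assert graph.waves[0].rows == [1, 2]
        assert graph.waves[0].cols == [0, 1, 1]

    def test_printed_frontier_progression(self):
        graph = build_lcs_graph("CATATATCG", "CTTATAGCAT")
        snapshots = {w.f: (w.rows, w.cols) for w in graph.waves}
        assert snapshots[3] == ([2, 3, 4, 5, 6, 6, 7],
                                [1, 2, 3, 3, 4, 5, 6, 6])
        assert snapshots[5] == ([3, 4, 5, 6, 7, 7, 8, 8, 9],
                                [2, 3, 4, 5, 6, 7, 7, 7, 8, 8])
        assert snapshots[7] == ([4, 5, 6, 7, 8, 8, 9, 10, 10, 10],
                                [3, 4, 5, 6, 7, 8, 8, 9, 9, 9, 9])

    def test_constant_parity_and_final_wave_equals_distance(self):
        rng = random.Random(11)
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 15)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 15)))
            graph = build_lcs_graph(a, b)
            fs = [w.f for w in graph.waves]
            assert fs[0] == abs(len(a) - len(b))
            assert all(nxt - cur == 2 for cur, nxt in zip(fs, fs[1:]))
            assert fs[-1] == graph.distance == edit_distance(a, b)

    def test_frontier_arrays_stay_linear(self):
        graph = build_lcs_graph("CATATATCG" * 3, "CTTATAGCAT" * 3)
        for wave in graph.waves:
            assert len(wave.rows) <= len(graph.reference) + 1
            assert len(wave.cols) <= len(graph.observed) + 1


class TestNodeLevel:
    def test_first_match(self):
        assert node_level(1, 1, 0) == 1

    def test_virtual_source(self):
        assert node_level(0, 0, 0) == 0

    def test_final_match_of_worked_example(self):
        matrix = dp_full_matrix("CATATATCG", "CTTATAGCAT")
        assert matrix[7, 10] == 5
        assert node_level(7, 10, int(matrix[7, 10])) == 6


class TestGraph:
    def test_single_interior_match(self):
        graph = build_lcs_graph("CT", "TG")
        interior = [n for n in graph.nodes
                    if n not in (graph.source, graph.sink)]
        assert interior == [(2, 1)]  # the shared T
        reps = enumerate_minimal(graph)
        assert [canonical(r) for r in reps] \
            == [(Deletion(1), Insertion(2, "G"))]

    def test_identity_chain(self):
        graph = build_lcs_graph("ACGT", "ACGT")
        assert graph.nodes == {(0, 0): 0, (1, 1): 1, (2, 2): 2,
                               (3, 3): 3, (4, 4): 4, (5, 5): 5}
        reps = enumerate_minimal(graph)
        assert len(reps) == 1 and not reps[0].operations

    @pytest.mark.parametrize("a,b,count", [
        ("ATTTA", "ATTA", 3),
        ("TTTTTT", "TTTTT", 6),
        ("GCTTT", "AGCTT", 3),
    ])
    def test_minimal_representation_counts(self, a, b, count):
        assert len(enumerate_minimal(build_lcs_graph(a, b))) == count

    def test_known_representation_set(self):
        reps = enumerate_minimal(build_lcs_graph("GCTTT", "AGCTT"))
        assert {canonical(r) for r in reps} == {
            (Insertion(0, "A"), Deletion(3)),
            (Insertion(0, "A"), Deletion(4)),
            (Insertion(0, "A"), Deletion(5)),
        }

    def test_cap_aborts_enumeration(self):
        with pytest.raises(EnumerationCapError):
            enumerate_minimal(build_lcs_graph("ATTTA", "ATTA"), cap=2)

    @pytest.mark.parametrize("a,b,expected", [
        ("CT", "TG", {Deletion(1), Insertion(2, "G")}),
        ("CT", "GC", {Insertion(0, "G"), Deletion(2)}),
        ("ACGT", "ACGT", set()),
        ("GCTTT", "AGCTT",
         {Insertion(0, "A"), Deletion(3), Deletion(4), Deletion(5)}),
    ])
    def test_element_sets(self, a, b, expected):
        assert element_set(build_lcs_graph(a, b)) == frozenset(expected)

    def test_gap_labels_reconstruct_observed(self):
        rng = random.Random(23)
        for _ in range(30):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 10)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 10)))
            graph = build_lcs_graph(a, b)
            for rep in enumerate_minimal(graph, cap=50000):
                assert patch(a, rep) == b
                assert len(rep) == graph.distance

    def test_scales_to_long_similar_sequences(self):
        # a quadratic |R|x|O| table would hold 4e8 cells here; the wave
        # frontier keeps construction effectively linear for similar strings
        rng = random.Random(5)
        reference = "".join(rng.choice("ACGT") for _ in range(20000))
        observed = reference[:9999] + "T" + reference[10000:]
        if observed == reference:
            observed = reference[:9999] + "A" + reference[10000:]
        graph = build_lcs_graph(reference, observed)
        assert graph.distance == 2
        psi = element_set(graph)
        assert any(isinstance(e, Deletion) for e in psi)

    def test_dot_export_mentions_every_node(self):
        graph = build_lcs_graph("ATTTA", "ATTA")
        dot = to_dot(graph)
        assert dot.startswith("digraph")
        assert "source" in dot and "sink" in dot
        assert dot.count("->") >= len(graph.nodes) - 1


class TestOracleEquivalence:
    def test_exhaustive_small_strings(self):
        strings = all_strings("ACT", 4)
        for a in strings:
            for b in strings:
                matrix = dp_full_matrix(a, b)
                assert edit_distance(a, b) == int(matrix[-1, -1]), (a, b)
                graph = build_lcs_graph(a, b, record_waves=False)
                fast = {canonical(r)
                        for r in enumerate_minimal(graph, cap=100000)}
                slow = enumerate_paths(matrix, a, b)
                assert fast == {canonical(r) for r in slow}, (a, b)
                assert element_set(graph) == frozenset(
                    op for r in slow for op in r.operations), (a, b)

    def test_random_pairs(self):
        rng = random.Random(7)
        for _ in range(500):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 12)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 12)))
            matrix = dp_full_matrix(a, b)
            assert edit_distance(a, b) == int(matrix[-1, -1]), (a, b)
            graph = build_lcs_graph(a, b, record_waves=False)
            fast = {canonical(r)
                    for r in enumerate_minimal(graph, cap=200000)}
            slow = enumerate_paths(matrix, a, b, cap=200000)
            assert fast == {canonical(r) for r in slow}, (a, b)
            assert element_set(graph) == frozenset(
                op for r in slow for op in r.operations), (a, b)
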