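import itertools
import math

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigmap.annotation import Reference, ReferenceKind
from sigmap.model import (
    EntityClass,
    MapEntity,
    Reaction,
    RegulationClass,
    SignallingMap,
)
from sigmap.scoring import (
    ABSENT,
    DISCONNECTED,
    PPINetwork,
    ConfidenceResult,
    func_score,
    func_score_from_symbols,
    ppi_distance,
    ref_score,
    score_map,
    write_score_report,
)

from .conftest import protein


def path_ppi(*nodes):
    return PPINetwork.from_edges(zip(nodes, nodes[1:]))


def two_protein_map(ppi_distance_nodes):
    """Map with one reaction A -> B; proteins named by first/last node."""
    a, b = ppi_distance_nodes[0], ppi_distance_nodes[-1]
    smap = SignallingMap(width=400, height=200)
    smap.add_entity(protein("ea", hugo=a, x=10))
    smap.add_entity(protein("eb", hugo=b, x=200))
    smap.add_reaction(Reaction(id="r", reactants=["ea"], products=["eb"]))
    return smap


class TestRefScore:
    def test_two_reviews_is_five(self, two_reviews):
        assert ref_score(two_reviews) == 5

    def test_no_references_is_zero(self):
        assert ref_score([]) == 0

    def test_one_original_one_review_is_four(self):
        refs = [Reference("1"), Reference("2", ReferenceKind.REVIEW)]
        assert ref_score(refs) == 1 + 3

    def test_single_original_is_one_single_review_is_three(self):
        assert ref_score([Reference("1")]) == 1
        assert ref_score([Reference("1", ReferenceKind.REVIEW)]) == 3

    @given(st.integers(0, 10), st.integers(0, 10))
    def test_capped_weighted_sum(self, n_orig, n_rev):
        refs = [Reference(str(i)) for i in range(n_orig)]
        refs += [Reference(str(100 + i), ReferenceKind.REVIEW) for i in range(n_rev)]
        expected = min(5, n_orig + 3 * n_rev) if refs else 0
        assert ref_score(refs) == expected

    @given(st.integers(0, 5), st.integers(0, 5))
    def test_monotone_in_reference_counts(self, n_orig, n_rev):
        refs = [Reference(str(i)) for i in range(n_orig)]
        refs += [Reference(str(100 + i), ReferenceKind.REVIEW) for i in range(n_rev)]
        assert ref_score(refs + [Reference("x")]) >= ref_score(refs)
        assert ref_score(refs + [Reference("y", ReferenceKind.REVIEW)]) >= ref_score(refs)


class TestPpiDistance:
    def test_direct_edge_is_one(self):
        assert ppi_distance("A", "B", path_ppi("A", "B")) == 1

    def test_two_step_path(self):
        assert ppi_distance("A", "B", path_ppi("A", "X", "B")) == 2

    def test_disconnected_components(self):
        ppi = PPINetwork.from_edges([("A", "X"), ("B", "Y")])
        assert ppi_distance("A", "B", ppi) == DISCONNECTED

    def test_absent_symbol(self):
        assert ppi_distance("A", "ZZZ", path_ppi("A", "B")) == ABSENT

    def test_self_distance_zero(self):
        assert ppi_distance("A", "A", path_ppi("A", "B")) == 0

    def test_case_insensitive_nodes(self):
        assert ppi_distance("a", "b", path_ppi("A", "B")) == 1


class TestFuncScore:
    def test_all_pairs_direct_gives_five(self):
        smap = SignallingMap(width=500, height=300)
        smap.add_entity(protein("ea", hugo="A", x=10))
        smap.add_entity(protein("eb", hugo="B", x=200))
        smap.add_entity(protein("ec", hugo="C", x=400))
        smap.add_reaction(
            Reaction(id="r", reactants=["ea"], products=["eb"],
                     regulators=[("ec", RegulationClass.CATALYSIS)])
        )
        ppi = PPINetwork.from_edges([("A", "B"), ("A", "C"), ("B", "C")])
        assert func_score(smap.reactions["r"], smap, ppi) == 5

    @pytest.mark.parametrize(
        "nodes,expected",
        [
            (["A", "B"], 5),
            (["A", "X", "B"], 4),
            (["A", "X", "Y", "B"], 3),
            (["A", "X", "Y", "Z", "B"], 2),
        ],
    )
    def test_planted_path_distances(self, nodes, expected):
        smap = two_protein_map(nodes)
        assert func_score(smap.reactions["r"], smap, path_ppi(*nodes)) == expected

    def test_disconnected_pair_gives_zero(self):
        smap = two_protein_map(["A", "B"])
        ppi = PPINetwork.from_edges([("A", "X"), ("B", "Y")])
        assert func_score(smap.reactions["r"], smap, ppi) == 0

    def test_absent_symbol_gives_zero(self):
        smap = two_protein_map(["A", "B"])
        ppi = path_ppi("A", "Q")
        assert func_score(smap.reactions["r"], smap, ppi) == 0

    def test_fewer_than_two_proteins_gives_zero(self):
        smap = SignallingMap(width=300, height=200)
        smap.add_entity(protein("ea", hugo="A"))
        smap.add_entity(
            MapEntity(id="ph", name="growth", entity_class=EntityClass.PHENOTYPE,
                      position=(150, 0), size=(80, 40))
        )
        smap.add_reaction(Reaction(id="r", reactants=["ea"], products=["ph"]))
        assert func_score(smap.reactions["r"], smap, path_ppi("A", "B")) == 0

    def test_remote_but_connected_floors_at_one(self):
        nodes = [f"N{i}" for i in range(9)]  # distance 8 -> 6-8 clamps to 1
        smap = two_protein_map(nodes)
        assert func_score(smap.reactions["r"], smap, path_ppi(*nodes)) == 1


def brute_force_func(symbols, graph: nx.Graph) -> int:
    """Independent oracle: Floyd–Warshall all-pairs + the score formula."""
    symbols = sorted(symbols)
    if len(symbols) < 2:
        return 0
    if any(s not in graph for s in symbols):
        return 0
    dist = dict(nx.floyd_warshall(graph))
    pair_dists = []
    for a, b in itertools.combinations(symbols, 2):
        d = dist[a][b]
        if math.isinf(d):
            return 0
        pair_dists.append(d)
    mean = sum(pair_dists) / len(pair_dists)
    return max(1, min(5, 6 - math.floor(mean + 0.5)))


class TestFuncAgainstOracle:
    @pytest.mark.parametrize("trial", range(50))
    def test_random_graphs_small(self, trial):
        import random

        rng = random.Random(trial)
        n = rng.randint(2, 15)
        p = rng.uniform(0.05, 0.5)
        g = nx.gnp_random_graph(n, p, seed=trial)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        ppi = PPINetwork(graph=g)
        k = rng.randint(2, min(5, n))
        symbols = set(rng.sample([f"G{i}" for i in range(n)], k))
        assert func_score_from_symbols(symbols, ppi).func_score == brute_force_func(symbols, g)

    def test_adding_edge_never_decreases_score(self):
        import random

        rng = random.Random(42)
        for trial in range(30):
            n = rng.randint(3, 12)
            g = nx.gnp_random_graph(n, 0.3, seed=trial)
            g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
            symbols = set(rng.sample([f"G{i}" for i in range(n)], 3))
            before = func_score_from_symbols(symbols, PPINetwork(graph=g)).func_score
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            g2 = g.copy()
            g2.add_edge(*rng.choice(non_edges))
            after = func_score_from_symbols(symbols, PPINetwork(graph=g2)).func_score
            assert after >= before


class TestScoreMap:
    def test_all_reactions_scored_idempotent(self, tmp_path):
        from sigmap.fixtures import build_map, dna_repair_spec

        smap, truth = build_map(dna_repair_spec(seed=2))
        ppi = PPINetwork.from_edges(
            zip(sorted(truth["hugo_symbols"]), sorted(truth["hugo_symbols"])[1:])
        )
        results = score_map(smap, ppi)
        rxn_results = {k for k in results if k in smap.reactions}
        assert rxn_results == set(smap.reactions)
        for rxn in smap.reactions.values():
            assert rxn.annotation.confidence is not None
        again = score_map(smap, ppi)
        assert {k: (v.ref_score, v.func_score) for k, v in results.items()} == {
            k: (v.ref_score, v.func_score) for k, v in again.items()
        }
        n = write_score_report(results, tmp_path / "scores.tsv")
        assert n == len(results)

    def test_complex_with_direct_edge_scores_five(self, complex_map):
        ppi = PPINetwork.from_edges([("P1", "P2")])
        results = score_map(complex_map, ppi)
        assert results["c"].func_score == 5
        assert complex_map.entities["c"].annotation.confidence.func_score == 5

    def test_absent_protein_zeroes_func_keeps_ref(self, phospho_map, two_reviews):
        phospho_map.reactions["r1"].annotation.references = list(two_reviews)
        ppi = PPINetwork.from_edges([("A", "Q")])  # B absent
        results = score_map(phospho_map, ppi)
        assert results["r1"].func_score == 0
        assert results["r1"].ref_score == 5
        assert results["r1"].func_mean == "undefined"


@settings(max_examples=150, deadline=None)
@given(
    st.lists(st.sampled_from(["A", "B", "C", "D", "E"]), min_size=0, max_size=5),
    st.lists(
        st.tuples(
            st.sampled_from(["A", "B", "C", "D", "E", "F"]),
            st.sampled_from(["A", "B", "C", "D", "E", "F"]),
        ),
        max_size=10,
    ),
)
def test_scores_always_in_range(symbols, edges):
    ppi = PPINetwork.from_edges([e for e in edges if e[0] != e[1]])
    res = func_score_from_symbols(set(symbols), ppi)
    assert res.func_score in {0, 1, 2, 3, 4, 5}
    assert isinstance(res, ConfidenceResult)
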