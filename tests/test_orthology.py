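"""BDBH, Markov clustering and threshold semantics of the family calls."""

import itertools

import networkx as nx
import numpy as np
import pytest

from flavoscan.align import align_local
from flavoscan.orthology import (FamilyPrototype, bdbh, best_hits, call_orthologs,
                                 cluster_similarity_graph, count_tryptophans,
                                 make_prototypes)
from flavoscan.riboswitch import RiboswitchHit
from flavoscan.synthetic import mutate_to_identity, synthetic_prototypes
from flavoscan.tu import TranscriptionalUnit

from .conftest import random_protein


def _toy_proteomes(rng, n=5, length=25):
    a = {f"a{i}": random_protein(rng, length) for i in range(n)}
    b = {f"b{i}": mutate_to_identity(a[f"a{i}"], 0.7, rng) for i in range(n)}
    return a, b


def test_best_hit_of_identical_proteomes_is_self(rng):
    a, _ = _toy_proteomes(rng)
    assert best_hits(a, a) == {k: k for k in a}


def test_hitless_query_maps_to_none(rng):
    a = {"q": "WWWWWWWW"}
    b = {"s": "PPPPPPPP"}  # W/P scores negative in BLOSUM62
    assert best_hits(a, b) == {"q": None}


def test_best_hits_match_exhaustive_maximisation(rng):
    a, b = _toy_proteomes(rng)
    got = best_hits(a, b)
    for q in a:
        scored = [(align_local(a[q], b[s]).score, s) for s in sorted(b)]
        best_score = max(s for s, _ in scored)
        want = None if best_score <= 0 else min(s for sc, s in scored if sc == best_score)
        assert got[q] == want


def test_bdbh_identity_pairing_and_symmetry(rng):
    a, b = _toy_proteomes(rng, n=4)
    pairs = bdbh(a, b)
    assert pairs == {(f"a{i}", f"b{i}") for i in range(4)}
    assert {(y, x) for x, y in pairs} == bdbh(b, a)


def test_bdbh_excludes_non_reciprocal_pairs(rng):
    root = random_protein(rng, 30)
    # a0 and a1 are both closest to b0; only one direction can be reciprocal
    a = {"a0": root, "a1": mutate_to_identity(root, 0.9, rng)}
    b = {"b0": root}
    pairs = bdbh(a, b)
    assert pairs == {("a0", "b0")}


def test_two_triangles_cluster_separately():
    edges = [(f"x{i}", f"x{j}", 1.0) for i, j in itertools.combinations(range(3), 2)]
    edges += [(f"y{i}", f"y{j}", 1.0) for i, j in itertools.combinations(range(3), 2)]
    clusters = cluster_similarity_graph(edges, inflation=2.0)
    assert sorted(sorted(c) for c in clusters) == [["x0", "x1", "x2"], ["y0", "y1", "y2"]]


def test_singleton_node_preserved():
    assert cluster_similarity_graph([], nodes=["lonely"]) == [frozenset({"lonely"})]


def test_weakly_joined_cliques_split_and_clusters_partition_nodes():
    edges = [(f"u{i}", f"u{j}", 1.0) for i, j in itertools.combinations(range(4), 2)]
    edges += [(f"v{i}", f"v{j}", 1.0) for i, j in itertools.combinations(range(4), 2)]
    edges.append(("u0", "v0", 0.01))
    for inflation in (1.5, 2.0, 3.0, 4.0):
        clusters = cluster_similarity_graph(edges, inflation=inflation)
        assert sorted(sorted(c) for c in clusters) == \
            [[f"u{i}" for i in range(4)], [f"v{i}" for i in range(4)]]
    # clusters never cross connected components (checked via an external graph lib)
    g = nx.Graph((u, v) for u, v, _ in edges)
    comps = list(nx.connected_components(g))
    for c in cluster_similarity_graph(edges, inflation=2.0):
        assert any(c <= comp for comp in comps)


def test_nonpositive_weight_rejected():
    with pytest.raises(ValueError):
        cluster_similarity_graph([("a", "b", 0.0)])


def _candidate(prototype, identity, coverage, rng):
    """A protein aligning to ``prototype`` at roughly the given local identity/coverage."""
    L = len(prototype)
    kept = prototype[: int(round(coverage * L))]
    return mutate_to_identity(kept, identity, rng)


def test_threshold_semantics_default_family(rng):
    proto = FamilyPrototype("RibZ", random_protein(rng, 200))
    good = _candidate(proto.sequence, 0.55, 0.95, rng)
    low_identity = _candidate(proto.sequence, 0.20, 0.95, rng)
    calls = call_orthologs({"g": {"good": good, "low": low_identity}}, [proto])
    assert [(c.gene_id, c.family) for c in calls] == [("good", "RibZ")]
    assert calls[0].identity > 0.38 and calls[0].coverage >= 0.80


def test_low_coverage_rejected_despite_high_identity(rng):
    proto = FamilyPrototype("RibM", random_protein(rng, 200))
    fragment = proto.sequence[:100]  # identity 1.0 but coverage 0.5
    assert call_orthologs({"g": {"frag": fragment}}, [proto]) == []


def test_rfnt_override_is_stricter(rng):
    protos = make_prototypes(synthetic_prototypes())
    rfnt = next(p for p in protos if p.family == "RfnT")
    assert (rfnt.identity_min, rfnt.coverage_min) == (0.42, 0.90)
    candidate = _candidate(rfnt.sequence, 0.40, 0.95, rng)
    assert call_orthologs({"g": {"c": candidate}}, [rfnt]) == []
    # the same identity/coverage passes a default-threshold family
    other = FamilyPrototype("RibN", rfnt.sequence)
    calls = call_orthologs({"g": {"c": candidate}}, [other])
    assert [c.family for c in calls] == ["RibN"]


def test_gene_matching_two_families_keeps_higher_identity(rng):
    seq = random_protein(rng, 180)
    p_hi = FamilyPrototype("ImpX", mutate_to_identity(seq, 0.9, rng))
    p_lo = FamilyPrototype("RibU", mutate_to_identity(seq, 0.6, rng))
    calls = call_orthologs({"g": {"c": seq}}, [p_hi, p_lo])
    assert [c.family for c in calls] == ["ImpX"]


def test_riboswitch_evidence_rescues_borderline_candidate(rng):
    proto = FamilyPrototype("RibV", random_protein(rng, 200), identity_min=0.38)
    borderline = _candidate(proto.sequence, 0.36, 1.0, rng)
    tus = {"g": [TranscriptionalUnit("chr.TU0", ["c"], "chr", "+", (0, 600))]}
    hit = RiboswitchHit("chr.TU0", "g", "chr", 10, 150, "+", 60.0)
    without = call_orthologs({"g": {"c": borderline}}, [proto], tus=tus)
    with_ribo = call_orthologs({"g": {"c": borderline}}, [proto],
                               riboswitch_hits=[hit], tus=tus, margin=0.05)
    assert without == []
    assert len(with_ribo) == 1
    assert with_ribo[0].threshold_override and with_ribo[0].riboswitch_linked


def test_raising_identity_floor_never_adds_calls(rng):
    proto_seq = random_protein(rng, 150)
    proteome = {f"c{i}": _candidate(proto_seq, t, 1.0, rng)
                for i, t in enumerate([0.3, 0.45, 0.6, 0.9])}
    previous = None
    for floor in (0.3, 0.38, 0.5, 0.7, 0.95):
        calls = call_orthologs({"g": proteome},
                               [FamilyPrototype("RibZ", proto_seq, identity_min=floor)])
        if previous is not None:
            assert len(calls) <= previous
        previous = len(calls)


def test_empty_prototype_list_rejected(rng):
    with pytest.raises(ValueError):
        call_orthologs({"g": {"c": "MKL"}}, [])


def test_count_tryptophans():
    assert count_tryptophans("WWAWW") == 4
    assert count_tryptophans("") == 0
    rng = np.random.default_rng(5)
    seq = random_protein(rng, 100)
    assert count_tryptophans(seq) == sum(1 for c in seq if c == "W")
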