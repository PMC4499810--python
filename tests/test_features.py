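"""Similarity features: normalization, sequence scores, topology, assembly."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iinalign import (
    IIN,
    IINError,
    Interface,
    Kind,
    WeightVector,
    assemble_stack,
    lift_protein_feature,
    normalize_feature,
    pairwise_scores_to_feature,
    smith_waterman,
    topo_vertex_scores,
)
from iinalign.features import (
    EAW_KEY,
    FeatureMatrix,
    read_feature_matrix,
    read_weights,
    write_feature_matrix,
    write_weights,
)

from conftest import make_random_iin


def path_graph():
    """a - b - c with a,c domains and b a ligand."""
    a = Interface("a", 1, 30, Kind.DOMAIN)
    c = Interface("c", 1, 30, Kind.DOMAIN)
    b = Interface("b", 1, 15, Kind.LIGAND)
    return IIN([a, b, c], [(a.id, b.id), (c.id, b.id)])


def cycle4():
    doms = [Interface(f"d{i}", 1, 30, Kind.DOMAIN) for i in range(2)]
    ligs = [Interface(f"l{i}", 1, 15, Kind.LIGAND) for i in range(2)]
    edges = [
        (doms[0].id, ligs[0].id),
        (ligs[0].id, doms[1].id),
        (doms[1].id, ligs[1].id),
        (ligs[1].id, doms[0].id),
    ]
    return IIN(doms + ligs, edges)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------


def bfs_dist(adj, src):
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def all_shortest_paths(adj, s, t):
    """Enumerate every shortest s->t path by recursive descent."""
    dist = bfs_dist(adj, s)
    if t not in dist:
        return []
    out = []

    def walk(u, path):
        if u == t:
            out.append(path)
            return
        for w in adj[u]:
            if dist.get(w) == dist[u] + 1 and dist.get(w, math.inf) <= dist[t]:
                walk(w, path + [w])

    walk(s, [s])
    return [p for p in out if len(p) - 1 == dist[t]]


def brute_topo(net, feature):
    adj = {v: sorted(net.neighbors(v)) for v in net.vertex_ids}
    nodes = net.vertex_ids
    out = {}
    dists = {v: bfs_dist(adj, v) for v in nodes}
    for v in nodes:
        reach = {u: d for u, d in dists[v].items() if u != v}
        if feature == "degree":
            out[v] = len(adj[v])
        elif feature == "avg_shortest_path":
            out[v] = sum(reach.values()) / len(reach) if reach else 0.0
        elif feature == "closeness":
            m = sum(reach.values()) / len(reach) if reach else 0.0
            out[v] = 1.0 / m if m else 0.0
        elif feature == "eccentricity":
            out[v] = max(reach.values()) if reach else 0.0
        elif feature == "radiality":
            comp = set(dists[v])
            diam = max(
                max((d for u, d in dists[w].items() if u != w), default=0) for w in comp
            )
            aspl = sum(reach.values()) / len(reach) if reach else 0.0
            out[v] = (diam + 1 - aspl) / diam if diam else 0.0
        elif feature == "neighbourhood_connectivity":
            out[v] = (
                sum(len(adj[w]) for w in adj[v]) / len(adj[v]) if adj[v] else 0.0
            )
        elif feature == "topological_coefficient":
            nv = set(adj[v])
            shares = [
                len(nv & set(adj[w])) / len(nv)
                for w in nodes
                if w != v and nv and len(nv & set(adj[w]))
            ]
            out[v] = sum(shares) / len(shares) if shares else 0.0
        elif feature in ("betweenness", "stress"):
            total = 0.0
            for s, t in combinations(nodes, 2):
                if s == v or t == v:
                    continue
                paths = all_shortest_paths(adj, s, t)
                if not paths:
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                if feature == "stress":
                    total += through
                else:
                    total += through / len(paths)
            out[v] = total
    return out


def brute_smith_waterman(a, b, sub, gap_open=10.0, gap_extend=0.5):
    """Exhaustive enumeration of gapped local alignments (affine costs)."""
    best = 0.0

    def ext(i, j, score, last):
        nonlocal best
        best = max(best, score)
        if i < len(a) and j < len(b):
            ext(i + 1, j + 1, score + sub[a[i]][b[j]], "m")
        if i < len(a):
            ext(i + 1, j, score - (gap_extend if last == "g1" else gap_open), "g1")
        if j < len(b):
            ext(i, j + 1, score - (gap_extend if last == "g2" else gap_open), "g2")

    for i in range(len(a)):
        for j in range(len(b)):
            ext(i + 1, j + 1, sub[a[i]][b[j]], "m")
    return best


# ---------------------------------------------------------------------------
# Topological features
# ---------------------------------------------------------------------------


class TestTopoScores:
    def test_path_hand_values(self):
        net = path_graph()
        b = "b,1,15"
        assert topo_vertex_scores(net, "degree")[b] == 2
        assert topo_vertex_scores(net, "betweenness")[b] == 1.0
        assert topo_vertex_scores(net, "closeness")[b] == 1.0
        assert topo_vertex_scores(net, "stress")[b] == 1.0

    def test_cycle4_symmetry(self):
        net = cycle4()
        ecc = topo_vertex_scores(net, "eccentricity")
        nc = topo_vertex_scores(net, "neighbourhood_connectivity")
        assert set(ecc.values()) == {2.0}
        assert set(nc.values()) == {2.0}

    def test_isolated_vertex_distance_features_zero(self):
        net = IIN([Interface("x", 1, 30, Kind.DOMAIN)])
        for f in ("closeness", "eccentricity", "avg_shortest_path", "radiality"):
            assert topo_vertex_scores(net, f)["x,1,30"] == 0.0

    @pytest.mark.parametrize(
        "feature",
        [
            "degree",
            "avg_shortest_path",
            "betweenness",
            "closeness",
            "eccentricity",
            "neighbourhood_connectivity",
            "radiality",
            "stress",
            "topological_coefficient",
        ],
    )
    def test_matches_brute_force_on_random_graphs(self, feature, rng):
        for _ in range(6):
            net = make_random_iin(rng, 4, 6, 0.35)
            got = topo_vertex_scores(net, feature)
            want = brute_topo(net, feature)
            for v in net.vertex_ids:
                assert got[v] == pytest.approx(want[v], abs=1e-9), (feature, v)


class TestNormalizeFeature:
    def test_equal_scores_map_to_one(self):
        fm = normalize_feature("f", Kind.DOMAIN, {"a": 3.0}, {"b": 3.0})
        assert fm.score("a", "b") == 1.0

    def test_extreme_pair_maps_to_zero(self):
        fm = normalize_feature("f", Kind.DOMAIN, {"a": 0.0, "b": 10.0}, {"c": 0.0, "d": 10.0})
        assert fm.score("a", "d") == 0.0
        assert fm.score("b", "c") == 0.0
        assert fm.score("a", "c") == 1.0
        assert fm.score("b", "d") == 1.0

    def test_flat_scores_give_all_ones(self):
        fm = normalize_feature("f", Kind.LIGAND, {"a": 5, "b": 5}, {"c": 5})
        assert np.all(fm.values == 1.0)

    @given(
        shift=st.floats(-50, 50),
        negate=st.booleans(),
        scores=st.lists(st.floats(0, 100), min_size=2, max_size=6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariance_under_shift_and_negation(self, shift, negate, scores):
        s1 = {f"a{i}": v for i, v in enumerate(scores)}
        s2 = {f"b{i}": v * 0.7 for i, v in enumerate(scores)}
        sign = -1.0 if negate else 1.0
        t1 = {k: sign * (v + shift) for k, v in s1.items()}
        t2 = {k: sign * (v + shift) for k, v in s2.items()}
        ref = normalize_feature("f", Kind.DOMAIN, s1, s2).values
        alt = normalize_feature("f", Kind.DOMAIN, t1, t2).values
        assert np.allclose(ref, alt, atol=1e-9)


class TestSmithWaterman:
    def test_exact_match_of_prolines(self):
        # three P-P matches at BLOSUM62 value 7 each
        assert smith_waterman("PPP", "PPP") == 21.0

    def test_empty_sequence_scores_zero(self):
        assert smith_waterman("PPWK", "") == 0.0
        assert smith_waterman("", "") == 0.0

    def test_symmetry(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(aas, size=int(rng.integers(1, 8))))
            b = "".join(rng.choice(aas, size=int(rng.integers(1, 8))))
            assert smith_waterman(a, b) == smith_waterman(b, a)

    def test_matches_exhaustive_enumeration(self, rng):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        alphabet = list("PKWG")
        sub = {
            x: {y: float(blosum[x, y]) for y in alphabet} for x in alphabet
        }
        for _ in range(25):
            a = "".join(rng.choice(alphabet, size=int(rng.integers(1, 7))))
            b = "".join(rng.choice(alphabet, size=int(rng.integers(1, 7))))
            assert smith_waterman(a, b) == pytest.approx(
                brute_smith_waterman(a, b, sub)
            ), (a, b)


class TestScaling:
    def test_constant_scores_map_to_one(self):
        fm = pairwise_scores_to_feature(
            "f", Kind.DOMAIN, {("a", "b"): 4.0, ("a", "c"): 4.0}, ["a"], ["b", "c"]
        )
        assert np.all(fm.values == 1.0)

    def test_log_endpoints(self):
        fm = pairwise_scores_to_feature(
            "f", Kind.DOMAIN, {("a", "b"): 0.0, ("a", "c"): 9.0}, ["a"], ["b", "c"],
            mode="log",
        )
        assert fm.score("a", "b") == 0.0
        assert fm.score("a", "c") == 1.0

    def test_linear_max_direct_arithmetic(self):
        fm = pairwise_scores_to_feature(
            "f", Kind.DOMAIN,
            {("a", "x"): 0.0, ("a", "y"): 3.0, ("a", "z"): 9.0},
            ["a"], ["x", "y", "z"],
        )
        assert fm.score("a", "x") == 0.0
        assert fm.score("a", "y") == pytest.approx(1 / 3)
        assert fm.score("a", "z") == 1.0

    def test_negative_scores_rejected(self):
        with pytest.raises(IINError):
            pairwise_scores_to_feature("f", Kind.DOMAIN, {("a", "b"): -1.0}, ["a"], ["b"])


class TestLiftProteinFeature:
    def nets(self):
        n1 = IIN(
            [
                Interface("P", 1, 30, Kind.DOMAIN),
                Interface("P", 40, 69, Kind.DOMAIN),
                Interface("R", 1, 30, Kind.DOMAIN),
            ]
        )
        n2 = IIN([Interface("Q", 1, 30, Kind.DOMAIN)])
        return n1, n2

    def test_broadcast_to_all_vertex_pairs(self):
        n1, n2 = self.nets()
        fm = lift_protein_feature("blast", {("P", "Q"): 0.8}, n1, n2, Kind.DOMAIN)
        assert fm.score("P,1,30", "Q,1,30") == 0.8
        assert fm.score("P,40,69", "Q,1,30") == 0.8

    def test_missing_protein_pair_scores_zero(self):
        n1, n2 = self.nets()
        fm = lift_protein_feature("blast", {("P", "Q"): 0.8}, n1, n2, Kind.DOMAIN)
        assert fm.score("R,1,30", "Q,1,30") == 0.0

    def test_constant_within_protein_blocks(self, rng):
        n1 = IIN(
            [Interface(f"P{i}", 1 + 40 * j, 30 + 40 * j, Kind.LIGAND)
             for i in range(3) for j in range(2)]
        )
        n2 = IIN(
            [Interface(f"Q{i}", 1 + 40 * j, 15 + 40 * j, Kind.LIGAND)
             for i in range(2) for j in range(2)]
        )
        table = {(f"P{i}", f"Q{k}"): float(rng.uniform()) for i in range(3) for k in range(2)}
        fm = lift_protein_feature("func", table, n1, n2, Kind.LIGAND)
        for a in n1.ligand_ids:
            for b in n2.ligand_ids:
                assert fm.score(a, b) == table[(n1.protein(a), n2.protein(b))]


class TestAssembleStack:
    def fm(self, name, vals):
        return FeatureMatrix(("a",), ("x", "y"), np.array([vals]), name=name, side=Kind.DOMAIN)

    def test_single_feature_identity(self):
        fm = self.fm("f", [0.2, 0.9])
        base = assemble_stack([fm], WeightVector({"f": 1.0}))
        assert np.allclose(base.domain.values, fm.values)

    def test_convex_combination(self):
        base = assemble_stack(
            [self.fm("f", [1.0, 0.0]), self.fm("g", [0.0, 0.0])],
            WeightVector({"f": 0.4, "g": 0.6}),
        )
        assert base.domain.score("a", "x") == pytest.approx(0.4)

    def test_many_equal_weights_give_mean(self, rng):
        mats = [self.fm(f"f{i}", list(rng.uniform(size=2))) for i in range(29)]
        base = assemble_stack(
            mats, WeightVector({m.name: 1.0 / 29 for m in mats})
        )
        mean = np.mean([m.values for m in mats], axis=0)
        assert np.allclose(base.domain.values, mean)

    def test_unknown_feature_in_weights_rejected(self):
        with pytest.raises(IINError):
            assemble_stack([self.fm("f", [1, 0])], WeightVector({"f": 0.5, "ghost": 0.5}))


class TestFeatureIO:
    def test_score_table_reader(self, tmp_path):
        from iinalign.features import read_score_table

        p = tmp_path / "blast.tsv"
        p.write_text("id1\tid2\tscore\nP\tQ\t123.5\nR\tQ\t7\n")
        table = read_score_table(p)
        assert table == {("P", "Q"): 123.5, ("R", "Q"): 7.0}

    def test_matrix_round_trip(self, tmp_path, rng):
        fm = FeatureMatrix(
            ("a", "b"), ("x", "y"), rng.uniform(size=(2, 2)),
            name="demo", side=Kind.LIGAND, provenance="imported",
        )
        p = tmp_path / "demo.tsv"
        write_feature_matrix(fm, p)
        back = read_feature_matrix(p)
        assert back.name == "demo" and back.side is Kind.LIGAND
        assert np.allclose(back.values, fm.values)

    def test_weights_round_trip(self, tmp_path):
        wv = WeightVector({"f": 0.25, "g": 1.0}, eaw=0.5)
        p = tmp_path / "w.cfg"
        write_weights(wv, p)
        back = read_weights(p)
        assert back.weights == wv.weights and back.eaw == wv.eaw

    def test_eaw_reserved_key(self):
        with pytest.raises(IINError):
            WeightVector({EAW_KEY: 0.5})
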