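"""Aligner behaviour: greedy baseline, seed-and-extend, and the edge bonus."""

import math

import numpy as np

from iinalign import (
    IIN,
    Interface,
    Kind,
    eaw_demo_fixture,
    greedy_align,
    greedyplus_align,
    seed_extend_align,
)
from iinalign.features import BaseScores, PairScores

from conftest import make_random_iin, make_random_instance


# ---------------------------------------------------------------------------
# Independent step-by-step simulator: full dictionary rescan at every step
# ---------------------------------------------------------------------------


def naive_greedyplus(net1, net2, base, eaw):
    """Replay the algorithm with plain dictionaries and a full rescan of all
    candidate pairs at every step (no arrays, no incremental bookkeeping)."""
    pairs = {}
    counts = {}
    for kind in (Kind.DOMAIN, Kind.LIGAND):
        side = base.side(kind)
        for a in net1.side_ids(kind):
            for b in net2.side_ids(kind):
                pairs[(a, b)] = side.score(a, b)
                counts[(a, b)] = 0
    used1, used2 = set(), set()
    out = []
    while True:
        best_key, best_pair = None, None
        for (a, b), s in pairs.items():
            if a in used1 or b in used2:
                continue
            if math.isinf(eaw):
                prio = (counts[(a, b)], s)
            else:
                prio = (s + eaw * counts[(a, b)],)
            key = (*[-p for p in prio], net1.kind(a) is not Kind.DOMAIN, a, b)
            if best_key is None or key < best_key:
                best_key, best_pair = key, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        out.append((a, b))
        used1.add(a)
        used2.add(b)
        for n1 in net1.neighbors(a):
            if n1 in used1:
                continue
            for n2 in net2.neighbors(b):
                if n2 in used2 or net1.kind(n1) != net2.kind(n2):
                    continue
                counts[(n1, n2)] += 1
    return out


def isomorphic_cycles():
    """Two isomorphic 4-cycles with indicator base scores."""
    def net(prefix):
        doms = [Interface(f"{prefix}d{i}", 1, 30, Kind.DOMAIN) for i in range(2)]
        ligs = [Interface(f"{prefix}l{i}", 1, 15, Kind.LIGAND) for i in range(2)]
        return IIN(
            doms + ligs,
            [
                (doms[0].id, ligs[0].id),
                (ligs[0].id, doms[1].id),
                (doms[1].id, ligs[1].id),
                (ligs[1].id, doms[0].id),
            ],
        )

    n1, n2 = net("a"), net("b")
    dom = {}
    lig = {}
    for i in range(2):
        dom[(f"ad{i},1,30", f"bd{i},1,30")] = 1.0
        lig[(f"al{i},1,15", f"bl{i},1,15")] = 1.0
    base = BaseScores(
        domain=PairScores.from_mapping(dom, n1.domain_ids, n2.domain_ids),
        ligand=PairScores.from_mapping(lig, n1.ligand_ids, n2.ligand_ids),
    )
    return n1, n2, base


class TestGreedy:
    def test_identity_indicator_gives_identity_mapping(self):
        n1, n2, base = isomorphic_cycles()
        trace = greedy_align(n1, n2, base)
        assert all(a[1:] == b[1:] for a, b in trace.pair_ids())

    def test_two_by_two_selection_order(self):
        n1 = IIN([Interface("a1", 1, 30, Kind.DOMAIN), Interface("a2", 1, 30, Kind.DOMAIN)])
        n2 = IIN([Interface("b1", 1, 30, Kind.DOMAIN), Interface("b2", 1, 30, Kind.DOMAIN)])
        base = BaseScores(
            domain=PairScores(n1.domain_ids, n2.domain_ids, np.array([[0.9, 0.8], [0.8, 0.1]])),
            ligand=PairScores((), (), np.zeros((0, 0))),
        )
        trace = greedy_align(n1, n2, base)
        assert trace.pair_ids() == [("a1,1,30", "b1,1,30"), ("a2,1,30", "b2,1,30")]

    def test_alignment_size_is_smaller_side_sum(self, rng):
        for _ in range(10):
            n1 = make_random_iin(rng, int(rng.integers(1, 5)), int(rng.integers(1, 7)), 0.3, "A")
            n2 = make_random_iin(rng, int(rng.integers(1, 5)), int(rng.integers(1, 7)), 0.3, "B")
            base = BaseScores(
                domain=PairScores(
                    n1.domain_ids, n2.domain_ids,
                    rng.uniform(size=(len(n1.domain_ids), len(n2.domain_ids))),
                ),
                ligand=PairScores(
                    n1.ligand_ids, n2.ligand_ids,
                    rng.uniform(size=(len(n1.ligand_ids), len(n2.ligand_ids))),
                ),
            )
            expect = min(len(n1.domain_ids), len(n2.domain_ids)) + min(
                len(n1.ligand_ids), len(n2.ligand_ids)
            )
            assert len(greedy_align(n1, n2, base)) == expect
            assert len(greedyplus_align(n1, n2, base, eaw=0.3)) == expect


class TestGreedyPlus:
    def test_eaw_zero_equals_greedy(self, rng):
        for _ in range(50):
            n1, n2, base = make_random_instance(rng)
            assert greedyplus_align(n1, n2, base, eaw=0.0) == greedy_align(n1, n2, base)

    def test_demo_fixture_third_pair_flips_with_bonus(self):
        net1, net2, base = eaw_demo_fixture()
        with_bonus = greedyplus_align(net1, net2, base, eaw=1.0)
        without = greedyplus_align(net1, net2, base, eaw=0.0)
        assert with_bonus.pair_ids()[2] == ("C,1,30", "3,1,30")
        assert without.pair_ids()[2] == ("E,1,30", "3,1,30")
        # the flip is driven by two accumulated bonus increments
        assert with_bonus.pairs[2].bonus_count == 2

    def test_isomorphic_cycles_align_all_edges(self):
        n1, n2, base = isomorphic_cycles()
        for eaw in (0.0, 0.5, 5.0):
            trace = greedyplus_align(n1, n2, base, eaw=eaw)
            mapping = trace.mapping
            aligned_edges = sum(
                1 for d, l in n1.edges if (mapping[d], mapping[l]) in n2.edges
            )
            assert aligned_edges == 4

    def test_trace_matches_naive_simulator(self, rng):
        for _ in range(25):
            n1, n2, base = make_random_instance(
                rng, n_dom=int(rng.integers(1, 5)), n_lig=int(rng.integers(1, 9))
            )
            eaw = float(rng.choice([0.0, 0.1, 0.5, 2.0]))
            got = greedyplus_align(n1, n2, base, eaw=eaw).pair_ids()
            assert got == naive_greedyplus(n1, n2, base, eaw)

    def test_infinite_eaw_matches_naive_simulator(self, rng):
        for _ in range(15):
            n1, n2, base = make_random_instance(rng, n_dom=3, n_lig=6, edge_prob=0.35)
            got = greedyplus_align(n1, n2, base, eaw=math.inf).pair_ids()
            assert got == naive_greedyplus(n1, n2, base, math.inf)

    def test_monotone_bonus_priority(self):
        """On the demo fixture, raising the EAW never demotes the pair whose
        selection depends on the bonus."""
        net1, net2, base = eaw_demo_fixture()
        target = ("C,1,30", "3,1,30")
        position = []
        for eaw in (0.0, 0.5, 0.76, 1.0, 2.0):
            order = greedyplus_align(net1, net2, base, eaw=eaw).pair_ids()
            position.append(order.index(target) if target in order else len(order))
        assert position == sorted(position, reverse=True)

    def test_infinite_eaw_always_extends_an_edge_when_possible(self, rng):
        """Replay: at every step, if some free candidate pair had received a
        bonus, the selected pair must have received one too."""
        for _ in range(20):
            n1, n2, base = make_random_instance(rng, n_dom=3, n_lig=7, edge_prob=0.3)
            trace = greedyplus_align(n1, n2, base, eaw=math.inf)
            used1, used2 = set(), set()
            counts = {}
            for kind in (Kind.DOMAIN, Kind.LIGAND):
                for a in n1.side_ids(kind):
                    for b in n2.side_ids(kind):
                        counts[(a, b)] = 0
            for step in trace:
                free_bonused = any(
                    c > 0 for (a, b), c in counts.items() if a not in used1 and b not in used2
                )
                if free_bonused:
                    assert counts[(step.id1, step.id2)] > 0
                used1.add(step.id1)
                used2.add(step.id2)
                for x in n1.neighbors(step.id1):
                    for y in n2.neighbors(step.id2):
                        if x not in used1 and y not in used2 and n1.kind(x) == n2.kind(y):
                            counts[(x, y)] += 1

    def test_min_score_floor_stops_early(self):
        net1, net2, base = eaw_demo_fixture()
        trace = greedyplus_align(net1, net2, base, eaw=0.0, min_score=2.0)
        assert len(trace) == 3  # 10, 9, 5 pass; 1 and 0.5 do not

    def test_runtime_on_large_sparse_networks(self, rng):
        """Soft sanity check: |L| = 500, |E| ~ 600 aligns in seconds."""
        import time

        def big(prefix):
            doms = [Interface(f"{prefix}d{i}", 1, 30, Kind.DOMAIN) for i in range(25)]
            ligs = [Interface(f"{prefix}l{j}", 1, 15, Kind.LIGAND) for j in range(500)]
            edges = []
            for j, l in enumerate(ligs):
                edges.append((doms[int(rng.integers(0, 25))].id, l.id))
                if rng.uniform() < 0.2:
                    edges.append((doms[int(rng.integers(0, 25))].id, l.id))
            return IIN(doms + ligs, set(edges))

        n1, n2 = big("A"), big("B")
        base = BaseScores(
            domain=PairScores(n1.domain_ids, n2.domain_ids, rng.uniform(size=(25, 25))),
            ligand=PairScores(n1.ligand_ids, n2.ligand_ids, rng.uniform(size=(500, 500))),
        )
        t0 = time.time()
        trace = greedyplus_align(n1, n2, base, eaw=0.5)
        assert len(trace) == 525
        assert time.time() - t0 < 30.0


class TestSeedExtend:
    def star(self, prefix, n=3):
        d = Interface(f"{prefix}hub", 1, 30, Kind.DOMAIN)
        ls = [Interface(f"{prefix}l{i}", 1, 15, Kind.LIGAND) for i in range(n)]
        return IIN([d] + ls, [(d.id, l.id) for l in ls])

    def test_star_alignment_covers_all_leaves(self):
        n1, n2 = self.star("a"), self.star("b")
        dom = {(f"ahub,1,30", f"bhub,1,30"): 1.0}
        lig = {(f"al{i},1,15", f"bl{i},1,15"): 0.5 for i in range(3)}
        base = BaseScores(
            domain=PairScores.from_mapping(dom, n1.domain_ids, n2.domain_ids),
            ligand=PairScores.from_mapping(lig, n1.ligand_ids, n2.ligand_ids),
        )
        trace = seed_extend_align(n1, n2, base)
        assert len(trace) == 4
        mapping = trace.mapping
        aligned_edges = sum(1 for d, l in n1.edges if (mapping[d], mapping[l]) in n2.edges)
        assert aligned_edges == 3

    def test_isolated_seed_dead_ends_immediately(self):
        n1 = IIN([Interface("a", 1, 30, Kind.DOMAIN), Interface("al", 1, 15, Kind.LIGAND)])
        n2 = IIN([Interface("b", 1, 30, Kind.DOMAIN), Interface("bl", 1, 15, Kind.LIGAND)])
        base = BaseScores(
            domain=PairScores(n1.domain_ids, n2.domain_ids, np.array([[1.0]])),
            ligand=PairScores(n1.ligand_ids, n2.ligand_ids, np.array([[0.9]])),
        )
        trace = seed_extend_align(n1, n2, base)
        assert len(trace) == 1

    def test_every_non_seed_step_aligns_an_edge(self, rng):
        for _ in range(15):
            n1, n2, base = make_random_instance(rng, n_dom=3, n_lig=6, edge_prob=0.4)
            trace = seed_extend_align(n1, n2, base)
            mapping = {}
            for idx, step in enumerate(trace):
                if idx > 0:
                    extends = any(
                        (x, step.id1) in n1.edges or (step.id1, x) in n1.edges
                        for x in mapping
                    )
                    new_edges = sum(
                        1
                        for d, l in n1.edges
                        if d in {**mapping, step.id1: step.id2}
                        and l in {**mapping, step.id1: step.id2}
                        and ({**mapping, step.id1: step.id2}[d], {**mapping, step.id1: step.id2}[l]) in n2.edges
                    )
                    prev_edges = sum(
                        1
                        for d, l in n1.edges
                        if d in mapping and l in mapping and (mapping[d], mapping[l]) in n2.edges
                    )
                    assert new_edges >= prev_edges + 1
                mapping[step.id1] = step.id2
            assert len(trace) <= min(len(n1.domain_ids), len(n2.domain_ids)) + min(
                len(n1.ligand_ids), len(n2.ligand_ids)
            )
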