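"""Greedy alignment of bipartite interface-interaction networks.

Three one-to-one, partition-respecting aligners are provided:

* :func:`greedyplus_align` -- the main algorithm.  It repeatedly aligns the
  unaligned same-side vertex pair with the highest *working* score, which is
  the assembled base similarity plus an accumulated edge-alignment bonus:
  whenever a pair (u, v) is aligned, every pair (n1, n2) of still-unaligned
  same-side neighbours (n1 of u, n2 of v) has its working score raised by the
  edge alignment weight (EAW).  Bonuses accumulate across steps and are never
  removed, so a candidate pair supported by several aligned edges is boosted
  several times.  With EAW = 0 the edge term vanishes and the algorithm
  reduces to the plain greedy aligner; as EAW grows without bound it behaves
  like a seed-and-extend strategy -- an edge-extending candidate always beats
  a non-extending one -- but, unlike seed-and-extend, it continues past dead
  frontiers.  ``eaw=math.inf`` is honoured exactly via a two-key
  (bonus count, base score) selection rather than arithmetic infinity.

* :func:`greedy_align` -- baseline: vertices aligned purely in descending
  order of base similarity, edges never considered.

* :func:`seed_extend_align` -- baseline: seeds at the highest-scoring pair
  overall, then only aligns frontier pairs adjacent (on both sides) to an
  already-aligned pair, so every non-seed step aligns at least one edge pair;
  stops at the first empty frontier.

All three iterate until the smaller side of each partition is exhausted
(except seed-and-extend, which may dead-end early) and break score ties
deterministically: domain side before ligand side, then lexicographically by
(id in network 1, id in network 2).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .core import IIN, AlignmentTrace, IINError, Kind, TraceStep
from .features import BaseScores, PairScores


class _Side:
    """Mutable per-side working state for the iterative aligners."""

    __slots__ = (
        "kind", "ids1", "ids2", "base", "work", "count",
        "free1", "free2", "nbr1", "nbr2",
    )

    def __init__(self, kind: Kind, net1: IIN, net2: IIN, scores: PairScores):
        self.kind = kind
        self.ids1 = net1.side_ids(kind)
        self.ids2 = net2.side_ids(kind)
        restricted = scores.restrict(self.ids1, self.ids2)
        self.base = restricted.values.copy()
        self.work = restricted.values.copy()
        self.count = np.zeros_like(self.base, dtype=np.int64)
        self.free1 = np.ones(len(self.ids1), dtype=bool)
        self.free2 = np.ones(len(self.ids2), dtype=bool)
        self.nbr1: list[np.ndarray] = []
        self.nbr2: list[np.ndarray] = []

    @property
    def active(self) -> bool:
        return bool(self.free1.any() and self.free2.any())


def _build_sides(net1: IIN, net2: IIN, base: BaseScores) -> dict[Kind, _Side]:
    sides = {
        Kind.DOMAIN: _Side(Kind.DOMAIN, net1, net2, base.domain),
        Kind.LIGAND: _Side(Kind.LIGAND, net1, net2, base.ligand),
    }
    # neighbour index lists point into the opposite side's matrices
    for kind, side in sides.items():
        other = sides[Kind.LIGAND if kind is Kind.DOMAIN else Kind.DOMAIN]
        oidx1 = {v: i for i, v in enumerate(other.ids1)}
        oidx2 = {v: j for j, v in enumerate(other.ids2)}
        side.nbr1 = [
            np.array(sorted(oidx1[u] for u in net1.neighbors(v)), dtype=np.intp)
            for v in side.ids1
        ]
        side.nbr2 = [
            np.array(sorted(oidx2[u] for u in net2.neighbors(v)), dtype=np.intp)
            for v in side.ids2
        ]
    return sides


_NEG_INF = -np.inf


def _best_finite(side: _Side) -> Optional[tuple[float, int, int]]:
    if not side.active:
        return None
    flat = int(np.argmax(side.work))
    i, j = divmod(flat, side.work.shape[1])
    val = side.work[i, j]
    if val == _NEG_INF:
        return None
    return float(val), i, j


def _best_infinite(side: _Side) -> Optional[tuple[int, float, int, int]]:
    if not side.active:
        return None
    mask = side.free1[:, None] & side.free2[None, :]
    if not mask.any():
        return None
    counts = np.where(mask, side.count, -1)
    cmax = int(counts.max())
    vals = np.where(counts == cmax, side.work, _NEG_INF)
    flat = int(np.argmax(vals))
    i, j = divmod(flat, vals.shape[1])
    return cmax, float(side.base[i, j]), i, j


def _retire(side: _Side, i: int, j: int) -> None:
    side.free1[i] = False
    side.free2[j] = False
    side.work[i, :] = _NEG_INF
    side.work[:, j] = _NEG_INF


def _bonus(sides: dict[Kind, _Side], side: _Side, i: int, j: int, eaw: float) -> None:
    """Add the EAW to every pair of still-unaligned neighbours of (i, j)."""
    other = sides[Kind.LIGAND if side.kind is Kind.DOMAIN else Kind.DOMAIN]
    n1 = side.nbr1[i]
    n2 = side.nbr2[j]
    if n1.size == 0 or n2.size == 0:
        return
    n1 = n1[other.free1[n1]]
    n2 = n2[other.free2[n2]]
    if n1.size == 0 or n2.size == 0:
        return
    ix = np.ix_(n1, n2)
    other.count[ix] += 1
    if math.isfinite(eaw):
        other.work[ix] += eaw


def greedyplus_align(
    net1: IIN,
    net2: IIN,
    base: BaseScores,
    eaw: float,
    min_score: Optional[float] = None,
) -> AlignmentTrace:
    """Greedy alignment with an additive edge-alignment bonus.

    ``base`` must cover every same-side cross pair of the two networks.
    ``eaw`` is the non-negative edge alignment weight; ``math.inf`` selects
    pairs by (bonus count, base score) so an edge-extending candidate always
    wins while overflow is avoided.  ``min_score``, if given, stops the
    alignment once the best available working score falls below it.
    """
    if not (eaw >= 0.0):
        raise IINError(f"EAW must be >= 0, got {eaw}")
    sides = _build_sides(net1, net2, base)
    infinite = math.isinf(eaw)
    steps: list[TraceStep] = []
    step = 0
    while True:
        if infinite:
            picks = [
                (cand, side)
                for side in (sides[Kind.DOMAIN], sides[Kind.LIGAND])
                if (cand := _best_infinite(side)) is not None
            ]
            if not picks:
                break
            # higher bonus count, then higher base; domain side wins ties by order
            (cnt, val, i, j), side = max(
                picks, key=lambda p: (p[0][0], p[0][1], p[1].kind is Kind.DOMAIN)
            )
            bonus = math.inf if cnt > 0 else 0.0
        else:
            picks = [
                (cand, side)
                for side in (sides[Kind.DOMAIN], sides[Kind.LIGAND])
                if (cand := _best_finite(side)) is not None
            ]
            if not picks:
                break
            (val, i, j), side = max(
                picks, key=lambda p: (p[0][0], p[1].kind is Kind.DOMAIN)
            )
            if min_score is not None and val < min_score:
                break
            cnt = int(side.count[i, j])
            bonus = eaw * cnt
        steps.append(
            TraceStep(
                step=step,
                id1=side.ids1[i],
                id2=side.ids2[j],
                base_score=float(side.base[i, j]),
                eaw_bonus=bonus,
                bonus_count=cnt,
            )
        )
        _retire(side, i, j)
        _bonus(sides, side, i, j, eaw)
        step += 1
    return AlignmentTrace(steps)


def greedy_align(net1: IIN, net2: IIN, base: BaseScores) -> AlignmentTrace:
    """Baseline: align pairs purely in descending order of base similarity.

    Implemented by a single global sort (score descending, then domain side
    first, then lexicographic ids) and a one-pass greedy sweep -- an
    intentionally different mechanism from the iterative rescan of
    :func:`greedyplus_align`, to which it must be equivalent at EAW = 0.
    """
    entries: list[tuple[float, int, int, int, Kind, tuple, tuple]] = []
    for rank, kind in enumerate((Kind.DOMAIN, Kind.LIGAND)):
        scores = base.side(kind).restrict(net1.side_ids(kind), net2.side_ids(kind))
        for i, a in enumerate(scores.ids1):
            for j in range(len(scores.ids2)):
                entries.append((-scores.values[i, j], rank, i, j, kind, scores.ids1, scores.ids2))
    entries.sort(key=lambda e: e[:4])
    used1: set[str] = set()
    used2: set[str] = set()
    steps: list[TraceStep] = []
    for neg, _, i, j, kind, ids1, ids2 in entries:
        a, b = ids1[i], ids2[j]
        if a in used1 or b in used2:
            continue
        used1.add(a)
        used2.add(b)
        steps.append(TraceStep(len(steps), a, b, -neg, 0.0, 0))
    return AlignmentTrace(steps)


def seed_extend_align(net1: IIN, net2: IIN, base: BaseScores) -> AlignmentTrace:
    """Baseline: seed at the top-scoring pair, then extend along edges only.

    After the seed, a pair (u, v) is eligible only if u is adjacent to an
    already-aligned network-1 vertex whose partner is adjacent to v, so every
    non-seed step aligns at least one edge pair.  Terminates as soon as the
    frontier is empty (dead end; no restart).
    """
    scores = {
        kind: base.side(kind).restrict(net1.side_ids(kind), net2.side_ids(kind))
        for kind in (Kind.DOMAIN, Kind.LIGAND)
    }

    def best_of(cands: set[tuple[str, str]]) -> Optional[tuple[str, str, float]]:
        best = None
        for a, b in cands:
            kind = net1.kind(a)
            s = scores[kind].score(a, b)
            key = (-s, kind is not Kind.DOMAIN, a, b)
            if best is None or key < best[0]:
                best = (key, a, b, s)
        if best is None:
            return None
        return best[1], best[2], best[3]

    all_pairs = {
        (a, b)
        for kind in (Kind.DOMAIN, Kind.LIGAND)
        for a in net1.side_ids(kind)
        for b in net2.side_ids(kind)
    }
    if not all_pairs:
        return AlignmentTrace([])
    seed = best_of(all_pairs)
    steps = [TraceStep(0, seed[0], seed[1], seed[2], 0.0, 0)]
    used1, used2 = {seed[0]}, {seed[1]}
    aligned = [(seed[0], seed[1])]
    while True:
        frontier: set[tuple[str, str]] = set()
        for u, v in aligned:
            for n1 in net1.neighbors(u):
                if n1 in used1:
                    continue
                for n2 in net2.neighbors(v):
                    if n2 in used2 or net1.kind(n1) != net2.kind(n2):
                        continue
                    frontier.add((n1, n2))
        pick = best_of(frontier)
        if pick is None:
            break
        a, b, s = pick
        steps.append(TraceStep(len(steps), a, b, s, 0.0, 0))
        used1.add(a)
        used2.add(b)
        aligned.append((a, b))
    return AlignmentTrace(steps)


ALGORITHMS = {
    "greedyplus": greedyplus_align,
    "greedy": lambda net1, net2, base, eaw=None, **kw: greedy_align(net1, net2, base),
    "seedextend": lambda net1, net2, base, eaw=None, **kw: seed_extend_align(net1, net2, base),
}
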