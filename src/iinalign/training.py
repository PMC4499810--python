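"""Weight training by random-restart hill climbing, and feature reduction.

The objective is orthology recovery: a candidate weight vector (one weight in
[0, 1] per similarity feature, plus the edge alignment weight trained on the
same interval) is scored by assembling the weighted base similarity, running
the greedy-with-edge-bonus aligner, and counting represented protein
orthologies (RPO); edges aligned (EA) breaks ties between runs.

Each restart draws independent uniform weights and hill-climbs through a
fixed schedule of shrinking step sizes -- 0.01**0.25 (~0.32), 0.1, 0.03,
0.01.  At each step size, single-parameter +/-step moves are proposed in
random order; a move is kept unless the previous alignment had strictly more
RPOs (ties keep the new value, allowing plateau drift), and moves leaving
[0, 1] are rejected.  The next step size starts only when no single-parameter
move strictly improves RPO.

Two reduction procedures shrink the feature set: a redundancy filter that
removes one member of any feature pair closer than a Euclidean-distance
threshold, and an iterative loop that retrains, averages weights over the
top-k parameter sets, drops the lowest-weighted feature, and stops before any
removal that would reduce the best achievable RPO.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .align import greedyplus_align
from .core import IIN, IINError, OrthologyMap
from .evaluation import evaluate
from .features import (
    EAW_KEY,
    BaseScores,
    FeatureMatrix,
    Kind,
    PairScores,
    WeightVector,
)

#: Step-size schedule: the fourth root of the finest step, then 0.1, 0.03, 0.01.
DEFAULT_SCHEDULE: tuple[float, ...] = (0.01 ** 0.25, 0.1, 0.03, 0.01)

Objective = Callable[[dict[str, float]], tuple[int, int]]


@dataclass
class TrainingRun:
    """Everything needed to reproduce and inspect one training run."""

    seed: int
    restarts: int
    schedule: tuple[float, ...]
    best_weights: WeightVector
    best_rpo: int
    best_ea: int
    history: list[tuple[int, int, int, dict[str, float]]] = field(default_factory=list)
    # history rows: (restart index, rpo, ea, converged weights incl. EAW)


def _propose(value: float, step: float, sign: int) -> Optional[float]:
    new = value + sign * step
    if 0.0 <= new <= 1.0:
        return new
    return None


def hill_climb(
    initial: dict[str, float],
    objective: Objective,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, float], tuple[int, int]]:
    """Coordinate-wise stochastic hill climbing over weights in [0, 1].

    Moves are reverted only on a strict RPO decrease; a move that ties is
    kept (plateau drift) but does not count as an improvement.  For each step
    size the climb passes over the parameters (random order, random first
    sign, both signs tried) until a full pass brings no strict improvement.
    Returns the final weights and their (rpo, ea).
    """
    if list(schedule) != sorted(schedule, reverse=True):
        raise IINError("step schedule must be strictly decreasing")
    rng = rng or np.random.default_rng()
    names = sorted(initial)
    current = dict(initial)
    for name, w in current.items():
        if not (0.0 <= w <= 1.0):
            raise IINError(f"initial weight {name}={w} outside [0, 1]")
    cur_rpo, cur_ea = objective(current)

    for step in schedule:
        while True:
            improved = False
            order = [names[i] for i in rng.permutation(len(names))]
            for name in order:
                first_sign = 1 if rng.integers(0, 2) else -1
                for sign in (first_sign, -first_sign):
                    moved = False
                    while True:
                        new = _propose(current[name], step, sign)
                        if new is None:
                            break
                        trial = dict(current)
                        trial[name] = new
                        rpo, ea = objective(trial)
                        if rpo < cur_rpo:
                            break  # revert: previous alignment had more RPOs
                        current, cur_ea = trial, ea
                        moved = True
                        if rpo > cur_rpo:
                            cur_rpo = rpo
                            improved = True
                            continue  # keep stepping the same parameter
                        break  # tie kept; stop stepping this parameter
                    if moved:
                        break  # do not also try the opposite sign
            if not improved:
                break
    return current, (cur_rpo, cur_ea)


def make_objective(
    matrices: Sequence[FeatureMatrix],
    net1: IIN,
    net2: IIN,
    orth: OrthologyMap,
) -> Objective:
    """Weights -> (rpo, ea) via assemble -> align -> evaluate.

    The per-side feature tensors are stacked once so each evaluation is a
    single weighted contraction plus one alignment.
    """
    sides: dict[Kind, tuple[tuple[str, ...], tuple[str, ...], list[str], np.ndarray]] = {}
    for kind in (Kind.DOMAIN, Kind.LIGAND):
        mats = [m for m in matrices if m.side is kind]
        if not mats:
            sides[kind] = ((), (), [], np.zeros((0, 0, 0)))
            continue
        ids1, ids2 = mats[0].ids1, mats[0].ids2
        for m in mats:
            if m.ids1 != ids1 or m.ids2 != ids2:
                raise IINError(f"feature {m.name!r} does not share the pair universe")
        tensor = np.stack([m.values for m in mats])
        sides[kind] = (ids1, ids2, [m.name for m in mats], tensor)
    feature_names = sorted({m.name for m in matrices})

    def objective(weights: dict[str, float]) -> tuple[int, int]:
        missing = set(feature_names) - set(weights)
        if missing:
            raise IINError(f"objective weights missing features: {sorted(missing)}")
        eaw = weights.get(EAW_KEY, 0.0)
        assembled = {}
        for kind, (ids1, ids2, names, tensor) in sides.items():
            if tensor.size == 0:
                assembled[kind] = PairScores((), (), np.zeros((0, 0)))
                continue
            w = np.array([weights[n] for n in names])
            assembled[kind] = PairScores(ids1, ids2, np.tensordot(w, tensor, axes=1))
        base = BaseScores(domain=assembled[Kind.DOMAIN], ligand=assembled[Kind.LIGAND])
        trace = greedyplus_align(net1, net2, base, eaw=eaw)
        report = evaluate(trace, net1, net2, orth)
        return report.rpo, report.ea

    return objective


def train(
    matrices: Sequence[FeatureMatrix],
    net1: IIN,
    net2: IIN,
    orth: OrthologyMap,
    restarts: int = 50,
    seed: int = 0,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
) -> TrainingRun:
    """Random-restart hill climbing over feature weights and the EAW.

    Each restart draws independent uniform [0, 1] starting weights.  The best
    restart maximises RPO, with ties broken by EA and then by the lowest
    restart index.  Fully reproducible from ``seed``.
    """
    if restarts < 1:
        raise IINError("restarts must be >= 1")
    objective = make_objective(matrices, net1, net2, orth)
    param_names = sorted({m.name for m in matrices}) + [EAW_KEY]
    run = TrainingRun(
        seed=seed,
        restarts=restarts,
        schedule=tuple(schedule),
        best_weights=WeightVector({}, 0.0),
        best_rpo=-1,
        best_ea=-1,
    )
    root = np.random.SeedSequence(seed)
    for restart, child in enumerate(root.spawn(restarts)):
        rng = np.random.default_rng(child)
        initial = {name: float(rng.uniform()) for name in param_names}
        final, (rpo, ea) = hill_climb(initial, objective, schedule, rng)
        run.history.append((restart, rpo, ea, dict(final)))
        if (rpo, ea) > (run.best_rpo, run.best_ea):
            run.best_rpo, run.best_ea = rpo, ea
            run.best_weights = WeightVector.from_dict(final)
    return run


def write_training_log(run: TrainingRun, path) -> None:
    names = sorted(run.history[0][3]) if run.history else []
    with open(path, "w") as fh:
        fh.write(f"# seed={run.seed}\trestarts={run.restarts}\n")
        fh.write("restart\trpo\tea\t" + "\t".join(names) + "\n")
        for restart, rpo, ea, weights in run.history:
            fh.write(
                f"{restart}\t{rpo}\t{ea}\t"
                + "\t".join(f"{weights[n]:.6g}" for n in names)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Feature reduction
# ---------------------------------------------------------------------------


def feature_distance(a: FeatureMatrix, b: FeatureMatrix) -> float:
    """Euclidean distance between two same-side vectorized matrices."""
    if a.side is not b.side or a.ids1 != b.ids1 or a.ids2 != b.ids2:
        raise IINError(
            f"features {a.name!r} and {b.name!r} do not share a pair universe"
        )
    return float(np.linalg.norm(a.values - b.values))


def reduce_redundant(
    features: Sequence[FeatureMatrix], threshold: float = 0.10
) -> list[FeatureMatrix]:
    """Drop near-duplicate features (pairwise Euclidean distance <= threshold).

    While any same-side pair lies within the threshold, the member of the
    closest pair with the smallest summed distance to all remaining features
    -- the one most similar to everything else -- is removed.  Ties fall back
    to name order.  Fewer than two features pass through unchanged.
    """
    current = list(features)
    while len(current) >= 2:
        comparable = [
            (a, b)
            for a, b in itertools.combinations(range(len(current)), 2)
            if current[a].side is current[b].side
            and current[a].ids1 == current[b].ids1
            and current[a].ids2 == current[b].ids2
        ]
        close = [
            (feature_distance(current[a], current[b]), a, b)
            for a, b in comparable
            if feature_distance(current[a], current[b]) <= threshold
        ]
        if not close:
            break
        _, a, b = min(close, key=lambda t: (t[0], current[t[1]].name, current[t[2]].name))

        def summed(idx: int) -> float:
            return sum(
                feature_distance(current[idx], current[k])
                for k in range(len(current))
                if k != idx
                and current[k].side is current[idx].side
                and current[k].ids1 == current[idx].ids1
                and current[k].ids2 == current[idx].ids2
            )

        drop = min((a, b), key=lambda idx: (summed(idx), current[idx].name))
        del current[drop]
    return current


def reduce_iterative(
    features: Sequence[FeatureMatrix],
    net1: IIN,
    net2: IIN,
    orth: OrthologyMap,
    top_k: int = 50,
    restarts: int = 50,
    seed: int = 0,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
) -> list[FeatureMatrix]:
    """Iteratively drop the least load-bearing feature without losing RPO.

    Train on the current set; among the ``top_k`` best parameter sets compute
    each feature's mean weight; remove the feature with the lowest mean and
    retrain.  Stops (without removing) as soon as a removal would reduce the
    best achievable RPO.  Returns the surviving features.
    """
    if not features:
        raise IINError("reduce_iterative requires at least one feature")
    current = list(features)
    run = train(current, net1, net2, orth, restarts=restarts, seed=seed, schedule=schedule)
    best_rpo = run.best_rpo
    while len({m.name for m in current}) > 1:
        top = sorted(run.history, key=lambda h: (-h[1], -h[2], h[0]))[:top_k]
        names = sorted({m.name for m in current})
        means = {
            name: float(np.mean([h[3][name] for h in top])) for name in names
        }
        drop_name = min(names, key=lambda n: (means[n], n))
        trial = [m for m in current if m.name != drop_name]
        trial_run = train(trial, net1, net2, orth, restarts=restarts, seed=seed, schedule=schedule)
        if trial_run.best_rpo < best_rpo:
            break
        current, run = trial, trial_run
        best_rpo = max(best_rpo, trial_run.best_rpo)
    return current
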