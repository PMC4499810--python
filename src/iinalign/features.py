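"""Vertex-pair similarity features and their normalization.

The aligner scores candidate vertex pairs with a weighted sum of per-feature
similarity matrices, one matrix per (feature, network side).  Three feature
families are supported:

* sequence similarity -- Smith-Waterman with BLOSUM62 for the short ligand
  peptides (computed here); BLAST scores for proteins and domains are long
  enough for external scoring and are consumed as imported score tables;
* functional similarity -- imported score tables (e.g. GO semantic
  similarity);
* topological similarity -- nine per-vertex graph measures (degree, average
  shortest path length, betweenness, closeness, eccentricity, neighbourhood
  connectivity, radiality, stress, topological coefficient), turned into
  pairwise similarities by the difference-based normalization below.

Per-vertex topological scores are turned into a similarity for a cross pair
(i, j) as ``raw_ij = M - |score_i - score_j|`` with ``M`` the largest
absolute cross-network difference, then log-normalized to [0, 1] via
``adj_ij = log(raw_ij + 1) / log(M + 1)`` (all ones when ``M = 0``).  The +1
shift makes the map well defined at ``raw = 0`` and pins the endpoints:
identical scores give 1, the most dissimilar pair gives 0.

Clustering coefficient is deliberately absent: every vertex of a bipartite
graph has clustering coefficient zero, so it carries no signal here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .core import IIN, IINError, Kind

EAW_KEY = "EAW"

TOPO_FEATURES = (
    "degree",
    "avg_shortest_path",
    "betweenness",
    "closeness",
    "eccentricity",
    "neighbourhood_connectivity",
    "radiality",
    "stress",
    "topological_coefficient",
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class PairScores:
    """A dense score matrix over sorted cross-network vertex id lists."""

    ids1: tuple[str, ...]
    ids2: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.ids1 = tuple(self.ids1)
        self.ids2 = tuple(self.ids2)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids1), len(self.ids2)):
            raise IINError(
                f"score matrix shape {self.values.shape} does not match id lists "
                f"({len(self.ids1)}, {len(self.ids2)})"
            )
        if sorted(self.ids1) != list(self.ids1) or sorted(self.ids2) != list(self.ids2):
            order1 = np.argsort(np.array(self.ids1, dtype=object))
            order2 = np.argsort(np.array(self.ids2, dtype=object))
            self.values = self.values[np.ix_(order1, order2)]
            self.ids1 = tuple(self.ids1[i] for i in order1)
            self.ids2 = tuple(self.ids2[j] for j in order2)
        self._idx1 = {v: i for i, v in enumerate(self.ids1)}
        self._idx2 = {v: j for j, v in enumerate(self.ids2)}

    @classmethod
    def from_mapping(
        cls,
        scores: Mapping[tuple[str, str], float],
        ids1: Sequence[str],
        ids2: Sequence[str],
        default: float = 0.0,
    ) -> "PairScores":
        ids1, ids2 = tuple(sorted(ids1)), tuple(sorted(ids2))
        values = np.full((len(ids1), len(ids2)), default, dtype=float)
        i1 = {v: i for i, v in enumerate(ids1)}
        i2 = {v: j for j, v in enumerate(ids2)}
        for (a, b), s in scores.items():
            if a in i1 and b in i2:
                values[i1[a], i2[b]] = s
        return cls(ids1, ids2, values)

    def score(self, id1: str, id2: str) -> float:
        return float(self.values[self._idx1[id1], self._idx2[id2]])

    def restrict(self, ids1: Sequence[str], ids2: Sequence[str]) -> "PairScores":
        try:
            rows = [self._idx1[v] for v in sorted(ids1)]
            cols = [self._idx2[v] for v in sorted(ids2)]
        except KeyError as exc:
            raise IINError(f"score matrix does not cover vertex {exc.args[0]!r}") from exc
        return PairScores(tuple(sorted(ids1)), tuple(sorted(ids2)), self.values[np.ix_(rows, cols)])


@dataclass
class FeatureMatrix(PairScores):
    """A named, side-specific similarity matrix with all values in [0, 1]."""

    name: str = ""
    side: Kind = Kind.DOMAIN
    provenance: str = "computed"

    def __post_init__(self):
        super().__post_init__()
        self.side = Kind(self.side)
        if self.provenance not in ("computed", "imported"):
            raise IINError(f"provenance must be computed|imported, got {self.provenance!r}")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise IINError(f"feature {self.name!r} has values outside [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)


@dataclass
class WeightVector:
    """Per-feature weights plus the edge alignment weight (EAW).

    Feature weights live in [0, 1] (the training interval); the EAW is any
    non-negative real, with ``math.inf`` meaning "always prefer aligning an
    edge" (the seed-and-extend limit).
    """

    weights: dict[str, float]
    eaw: float = 0.0

    def __post_init__(self):
        if EAW_KEY in self.weights:
            raise IINError(f"{EAW_KEY} is a reserved key; pass it as the eaw field")
        for name, w in self.weights.items():
            if not (0.0 <= w <= 1.0):
                raise IINError(f"weight {name}={w} outside [0, 1]")
        if not (self.eaw >= 0.0):
            raise IINError(f"EAW must be >= 0, got {self.eaw}")

    def as_dict(self) -> dict[str, float]:
        d = dict(self.weights)
        d[EAW_KEY] = self.eaw
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "WeightVector":
        d = dict(d)
        eaw = d.pop(EAW_KEY, 0.0)
        return cls(d, eaw)


@dataclass
class BaseScores:
    """Assembled base similarity, one matrix per network side."""

    domain: PairScores
    ligand: PairScores

    def side(self, kind: Kind) -> PairScores:
        return self.domain if Kind(kind) is Kind.DOMAIN else self.ligand


@dataclass
class FeatureStack:
    """Named collection of feature matrices plus a weight vector."""

    matrices: list[FeatureMatrix]
    weights: WeightVector

    def names(self) -> tuple[str, ...]:
        return tuple(sorted({m.name for m in self.matrices}))

    def assemble(self, weights: Optional[WeightVector] = None) -> BaseScores:
        return assemble_stack(self.matrices, weights or self.weights)


# ---------------------------------------------------------------------------
# Topological vertex scores
# ---------------------------------------------------------------------------


def _distance_stats(g: nx.Graph) -> dict[str, tuple[float, float]]:
    """Per vertex: (mean distance to reachable vertices, max distance)."""
    out = {}
    for v, dists in nx.all_pairs_shortest_path_length(g):
        other = [d for u, d in dists.items() if u != v]
        if other:
            out[v] = (sum(other) / len(other), float(max(other)))
        else:
            out[v] = (0.0, 0.0)
    return out


def _stress_centrality(g: nx.Graph) -> dict[str, float]:
    """Number of shortest paths passing through each vertex.

    Counted over unordered source-target pairs within each connected
    component, endpoints excluded, no normalization.
    """
    stress = {v: 0.0 for v in g}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        n = len(nodes)
        if n < 3:
            continue
        idx = {v: i for i, v in enumerate(nodes)}
        dist = np.full((n, n), np.inf)
        sigma = np.zeros((n, n))
        for s in nodes:
            si = idx[s]
            dist[si, si] = 0
            sigma[si, si] = 1
            queue = [s]
            while queue:
                nxt = []
                for u in queue:
                    ui = idx[u]
                    for w in g[u]:
                        wi = idx[w]
                        if not np.isfinite(dist[si, wi]):
                            dist[si, wi] = dist[si, ui] + 1
                            nxt.append(w)
                        if dist[si, wi] == dist[si, ui] + 1:
                            sigma[si, wi] += sigma[si, ui]
                queue = nxt
        iu, ju = np.triu_indices(n, k=1)
        for v in nodes:
            vi = idx[v]
            on_path = dist[iu, vi] + dist[vi, ju] == dist[iu, ju]
            not_endpoint = (iu != vi) & (ju != vi)
            stress[v] = float(np.sum(sigma[iu, vi] * sigma[vi, ju] * (on_path & not_endpoint)))
    return stress


def _topological_coefficient(g: nx.Graph) -> dict[str, float]:
    out = {}
    for v in g:
        nv = set(g[v])
        if not nv:
            out[v] = 0.0
            continue
        shared = []
        for w in g:
            if w == v:
                continue
            common = nv & set(g[w])
            if common:
                shared.append(len(common) / len(nv))
        out[v] = sum(shared) / len(shared) if shared else 0.0
    return out


def topo_vertex_scores(net: IIN, feature: str) -> dict[str, float]:
    """One finite raw score per vertex for the named topological feature.

    Distance-based measures are computed within connected components; for an
    isolated vertex every distance-based feature is defined as 0.
    """
    if len(net) == 0:
        raise IINError("topo_vertex_scores requires a nonempty network")
    if feature not in TOPO_FEATURES:
        raise IINError(f"unknown topological feature {feature!r}")
    g = net.to_networkx()

    if feature == "degree":
        return {v: float(d) for v, d in g.degree()}
    if feature == "betweenness":
        return {v: float(b) for v, b in nx.betweenness_centrality(g, normalized=False).items()}
    if feature == "stress":
        return _stress_centrality(g)
    if feature == "neighbourhood_connectivity":
        return {
            v: (sum(g.degree(w) for w in g[v]) / g.degree(v)) if g.degree(v) else 0.0
            for v in g
        }
    if feature == "topological_coefficient":
        return _topological_coefficient(g)

    stats = _distance_stats(g)
    if feature == "avg_shortest_path":
        return {v: stats[v][0] for v in g}
    if feature == "closeness":
        return {v: (1.0 / stats[v][0] if stats[v][0] > 0 else 0.0) for v in g}
    if feature == "eccentricity":
        return {v: stats[v][1] for v in g}
    # radiality: (component diameter + 1 - mean distance) / diameter
    out = {}
    for comp in nx.connected_components(g):
        diam = max(stats[v][1] for v in comp)
        for v in comp:
            out[v] = (diam + 1.0 - stats[v][0]) / diam if diam > 0 else 0.0
    return out


def normalize_feature(
    name: str,
    side: Kind,
    scores1: Mapping[str, float],
    scores2: Mapping[str, float],
    provenance: str = "computed",
) -> FeatureMatrix:
    """Difference-based similarity between two per-vertex score sets.

    ``raw_ij = M - |s1_i - s2_j|`` with ``M = max |s1_x - s2_y|`` over all
    cross pairs, then ``adj_ij = log(raw_ij + 1)/log(M + 1)``; if the score
    sets are flat (``M = 0``) every pair is maximally similar (all ones).
    The result is invariant to adding a constant to, or negating, all scores.
    """
    if not scores1 or not scores2:
        raise IINError("normalize_feature requires nonempty score sets")
    ids1 = tuple(sorted(scores1))
    ids2 = tuple(sorted(scores2))
    v1 = np.array([float(scores1[v]) for v in ids1])
    v2 = np.array([float(scores2[v]) for v in ids2])
    if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
        raise IINError(f"non-finite vertex score in feature {name!r}")
    diff = np.abs(v1[:, None] - v2[None, :])
    m = float(diff.max())
    if m == 0.0:
        adj = np.ones_like(diff)
    else:
        adj = np.log1p(m - diff) / math.log1p(m)
    return FeatureMatrix(ids1, ids2, adj, name=name, side=Kind(side), provenance=provenance)


def topo_feature_matrix(net1: IIN, net2: IIN, side: Kind, feature: str) -> FeatureMatrix:
    """Convenience: raw topological scores on both nets -> normalized matrix."""
    side = Kind(side)
    s1 = topo_vertex_scores(net1, feature)
    s2 = topo_vertex_scores(net2, feature)
    keep1 = {v: s1[v] for v in net1.side_ids(side)}
    keep2 = {v: s2[v] for v in net2.side_ids(side)}
    return normalize_feature(f"{feature}_{side.value}", side, keep1, keep2)


# ---------------------------------------------------------------------------
# Sequence similarity
# ---------------------------------------------------------------------------

_aligner_cache: dict[tuple[str, float, float], "object"] = {}


def _get_aligner(matrix: str, gap_open: float, gap_extend: float):
    key = (matrix, gap_open, gap_extend)
    if key not in _aligner_cache:
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(matrix)
        aligner.open_gap_score = -abs(gap_open)
        aligner.extend_gap_score = -abs(gap_extend)
        _aligner_cache[key] = aligner
    return _aligner_cache[key]


def smith_waterman(
    seq1: str,
    seq2: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Optimal local-alignment score with affine gaps.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  The empty
    local alignment scores 0, so the result is never negative, and the score
    is symmetric in its arguments.
    """
    if not seq1 or not seq2:
        return 0.0
    aligner = _get_aligner(matrix, gap_open, gap_extend)
    return max(0.0, float(aligner.score(seq1, seq2)))


def sequence_feature_matrix(
    net1: IIN,
    net2: IIN,
    side: Kind = Kind.LIGAND,
    mode: str = "linear_max",
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    name: Optional[str] = None,
) -> FeatureMatrix:
    """Smith-Waterman similarity between all same-side cross pairs.

    Vertices without an attached sequence score 0 against everything.
    """
    side = Kind(side)
    ids1, ids2 = net1.side_ids(side), net2.side_ids(side)
    raw: dict[tuple[str, str], float] = {}
    for a in ids1:
        sa = net1.interface(a).sequence
        for b in ids2:
            sb = net2.interface(b).sequence
            raw[(a, b)] = smith_waterman(sa or "", sb or "", matrix, gap_open, gap_extend)
    return pairwise_scores_to_feature(
        name or f"smith_waterman_{side.value}", side, raw, ids1, ids2, mode=mode
    )


# ---------------------------------------------------------------------------
# Imported pairwise scores
# ---------------------------------------------------------------------------


def pairwise_scores_to_feature(
    name: str,
    side: Kind,
    raw_pair_scores: Mapping[tuple[str, str], float],
    ids1: Sequence[str],
    ids2: Sequence[str],
    mode: str = "linear_max",
    provenance: str = "computed",
) -> FeatureMatrix:
    """Scale non-negative raw pair scores into [0, 1].

    ``linear_max`` divides by the global maximum (all-zero input stays zero);
    ``log`` applies ``log(s + 1)/log(max + 1)``.  Pairs absent from the input
    default to 0.
    """
    if mode not in ("linear_max", "log"):
        raise IINError(f"unknown scaling mode {mode!r}")
    ps = PairScores.from_mapping(raw_pair_scores, ids1, ids2, default=0.0)
    vals = ps.values
    if vals.size and vals.min() < 0:
        raise IINError(f"negative raw score in feature {name!r}")
    top = float(vals.max()) if vals.size else 0.0
    if top == 0.0:
        scaled = np.zeros_like(vals)
    elif mode == "linear_max":
        scaled = vals / top
    else:
        scaled = np.log1p(vals) / math.log1p(top)
    return FeatureMatrix(ps.ids1, ps.ids2, scaled, name=name, side=Kind(side), provenance=provenance)


def lift_protein_feature(
    name: str,
    protein_pairs: Mapping[tuple[str, str], float],
    net1: IIN,
    net2: IIN,
    side: Kind,
    provenance: str = "imported",
) -> FeatureMatrix:
    """Broadcast protein-level scores in [0, 1] onto same-side vertex pairs.

    Every vertex pair inherits the score of its protein pair; missing protein
    pairs contribute 0.  The result is constant within protein blocks.
    """
    side = Kind(side)
    ids1, ids2 = net1.side_ids(side), net2.side_ids(side)
    values = np.zeros((len(ids1), len(ids2)))
    for i, a in enumerate(ids1):
        pa = net1.protein(a)
        for j, b in enumerate(ids2):
            s = protein_pairs.get((pa, net2.protein(b)), protein_pairs.get((net2.protein(b), pa), 0.0))
            values[i, j] = s
    return FeatureMatrix(ids1, ids2, values, name=name, side=side, provenance=provenance)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_stack(
    matrices: Sequence[FeatureMatrix], weights: WeightVector
) -> BaseScores:
    """Weighted sum of feature matrices per side: ``base = sum_f w_f adj_f``.

    Every feature named in the weight vector must exist on at least one side;
    weighting an unknown feature is an error.  Features present on only one
    side simply contribute nothing to the other side.
    """
    known = {m.name for m in matrices}
    unknown = set(weights.weights) - known
    if unknown:
        raise IINError(f"weights refer to unknown features: {sorted(unknown)}")
    missing = known - set(weights.weights)
    if missing:
        raise IINError(f"features lack weights: {sorted(missing)}")

    sides: dict[Kind, PairScores] = {}
    for kind in (Kind.DOMAIN, Kind.LIGAND):
        side_mats = [m for m in matrices if m.side is kind]
        if not side_mats:
            sides[kind] = PairScores((), (), np.zeros((0, 0)))
            continue
        ids1, ids2 = side_mats[0].ids1, side_mats[0].ids2
        total = np.zeros((len(ids1), len(ids2)))
        for m in side_mats:
            if m.ids1 != ids1 or m.ids2 != ids2:
                raise IINError(
                    f"feature {m.name!r} does not share the {kind.value}-side pair universe"
                )
            total += weights.weights[m.name] * m.values
        sides[kind] = PairScores(ids1, ids2, total)
    return BaseScores(domain=sides[Kind.DOMAIN], ligand=sides[Kind.LIGAND])


# ---------------------------------------------------------------------------
# Feature / weight / score-table I/O
# ---------------------------------------------------------------------------


def read_score_table(path) -> dict[tuple[str, str], float]:
    """Read an imported pairwise score table (TSV: id1, id2, score)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["id1", "id2", "score"])
    if len(df) and str(df.iloc[0]["id1"]).lower() == "id1":
        df = df.iloc[1:]
    return {
        (str(r.id1), str(r.id2)): float(r.score) for r in df.itertuples(index=False)
    }


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# feature={fm.name}\tside={fm.side.value}\tprovenance={fm.provenance}\n")
        fh.write("id1\tid2\tscore\n")
        for i, a in enumerate(fm.ids1):
            for j, b in enumerate(fm.ids2):
                fh.write(f"{a}\t{b}\t{fm.values[i, j]:.10g}\n")


def read_feature_matrix(path) -> FeatureMatrix:
    name, side, provenance = "", Kind.DOMAIN, "imported"
    scores: dict[tuple[str, str], float] = {}
    ids1: set[str] = set()
    ids2: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tok in line[1:].split("\t"):
                    key, _, val = tok.strip().partition("=")
                    if key == "feature":
                        name = val
                    elif key == "side":
                        side = Kind(val)
                    elif key == "provenance":
                        provenance = val
                continue
            if not line or line.startswith("id1\t"):
                continue
            a, b, s = line.split("\t")
            scores[(a, b)] = float(s)
            ids1.add(a)
            ids2.add(b)
    ps = PairScores.from_mapping(scores, sorted(ids1), sorted(ids2))
    return FeatureMatrix(ps.ids1, ps.ids2, ps.values, name=name, side=side, provenance=provenance)


def write_weights(weights: WeightVector, path) -> None:
    """Write a key=value config; ``EAW`` is the reserved edge-weight key."""
    with open(path, "w") as fh:
        for name in sorted(weights.weights):
            fh.write(f"{name}={weights.weights[name]:.10g}\n")
        fh.write(f"{EAW_KEY}={weights.eaw:.10g}\n")


def read_weights(path) -> WeightVector:
    d: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, val = line.partition("=")
            if not sep:
                raise IINError(f"{path}:{lineno}: expected key=value")
            d[key.strip()] = math.inf if val.strip() in ("inf", "Infinity") else float(val)
    return WeightVector.from_dict(d)
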