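"""Synthetic paired interface-interaction networks with planted orthology.

The generator emulates the qualitative shape of experimentally mapped
peptide-recognition (e.g. SH3) interaction data -- a sparse bipartite graph
with relatively few high-degree domain vertices fanning out to many
low-degree ligand sites -- and the divergence of two related species from a
common ancestor:

1. An ancestor network is drawn by preferential attachment: each ligand site
   attaches to one domain chosen proportionally to (current degree + 1), and
   to a second domain with probability (mean ligand degree - 1), producing
   the hub-and-spoke, multi-fan topology of real interface networks.
2. Two descendant networks are derived independently: every vertex is
   deleted with probability ``vertex_loss_prob``, and every surviving edge
   has its ligand endpoint rewired to a random surviving ligand with
   probability ``rewire_prob`` (resampling only the ligand endpoint keeps the
   networks bipartite).
3. Vertices surviving in both descendants form the planted vertex map.
   Domains carry one vertex per protein; ligand sites are grouped
   ``ligands_per_protein`` per protein.  Co-copied proteins with surviving
   vertices on both sides of the species split are the planted protein
   orthology.
4. Similarity features: the "informative" feature scores planted pairs from
   a normal distribution centred at ``feature_informativeness`` (mu) and all
   other pairs at 1 - mu, both with standard deviation ``feature_noise`` and
   clamped to [0, 1]; ``n_noise_features`` additional features are pure
   uniform noise.  All matrices come with an equal-weight vector.

Everything is reproducible from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import IIN, IINError, Interface, Kind, OrthologyMap
from .features import (
    BaseScores,
    FeatureMatrix,
    FeatureStack,
    PairScores,
    WeightVector,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study condition."""

    n_domains: int = 20
    n_ligands: int = 150
    mean_ligand_degree: float = 1.3
    rewire_prob: float = 0.1
    vertex_loss_prob: float = 0.05
    feature_informativeness: float = 0.9
    feature_noise: float = 0.05
    n_noise_features: int = 3
    ligands_per_protein: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_domains < 1 or self.n_ligands < 1 or self.ligands_per_protein < 1:
            raise IINError("vertex counts must be >= 1")
        if not (1.0 <= self.mean_ligand_degree <= 2.0):
            raise IINError("mean ligand degree must lie in [1, 2]")
        for name in ("rewire_prob", "vertex_loss_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise IINError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.feature_informativeness <= 1.0):
            raise IINError("feature informativeness must lie in (0, 1]")
        if self.feature_noise < 0 or self.n_noise_features < 0:
            raise IINError("noise parameters must be non-negative")


@dataclass
class SyntheticInstance:
    """One generated study instance."""

    scenario: SyntheticScenario
    net1: IIN
    net2: IIN
    orthology: OrthologyMap
    planted: dict[str, str]  # vertex id in net1 -> vertex id in net2
    stack: FeatureStack

    def base_scores(self, weights: Optional[WeightVector] = None) -> BaseScores:
        return self.stack.assemble(weights)

    def planted_recovery(self, trace) -> float:
        """Fraction of planted vertex pairs present in an alignment trace."""
        if not self.planted:
            return 0.0
        pairs = trace.pair_set
        hit = sum(1 for a, b in self.planted.items() if (a, b) in pairs)
        return hit / len(self.planted)


def _ancestor_edges(scn: SyntheticScenario, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Preferential attachment of ligand indices to domain indices."""
    degree = np.zeros(scn.n_domains)
    p_second = scn.mean_ligand_degree - 1.0
    edges: list[tuple[int, int]] = []
    for lig in range(scn.n_ligands):
        probs = (degree + 1.0) / (degree + 1.0).sum()
        first = int(rng.choice(scn.n_domains, p=probs))
        edges.append((first, lig))
        degree[first] += 1
        if scn.n_domains > 1 and rng.uniform() < p_second:
            probs = (degree + 1.0).copy()
            probs[first] = 0.0
            probs /= probs.sum()
            second = int(rng.choice(scn.n_domains, p=probs))
            edges.append((second, lig))
            degree[second] += 1
    return edges


def _descend(
    scn: SyntheticScenario,
    ancestor_edges: list[tuple[int, int]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, set[tuple[int, int]]]:
    """One descendant: vertex survival masks and (domain, ligand) index edges."""
    dom_alive = rng.uniform(size=scn.n_domains) >= scn.vertex_loss_prob
    lig_alive = rng.uniform(size=scn.n_ligands) >= scn.vertex_loss_prob
    alive_ligs = np.flatnonzero(lig_alive)
    edges: set[tuple[int, int]] = set()
    for d, l in ancestor_edges:
        if not dom_alive[d] or not lig_alive[l]:
            continue
        target = l
        if alive_ligs.size and rng.uniform() < scn.rewire_prob:
            for _ in range(10):  # avoid creating a duplicate edge
                cand = int(rng.choice(alive_ligs))
                if (d, cand) not in edges:
                    target = cand
                    break
            else:
                continue
        if (d, target) not in edges:
            edges.add((d, target))
    return dom_alive, lig_alive, edges


def _interfaces(
    scn: SyntheticScenario, species: int, dom_alive: np.ndarray, lig_alive: np.ndarray,
    rng: np.random.Generator,
) -> tuple[dict[int, Interface], dict[int, Interface]]:
    doms: dict[int, Interface] = {}
    for d in np.flatnonzero(dom_alive):
        doms[int(d)] = Interface(f"S{species}D{d:03d}", 1, 60, Kind.DOMAIN)
    ligs: dict[int, Interface] = {}
    for l in np.flatnonzero(lig_alive):
        l = int(l)
        protein = f"S{species}P{l // scn.ligands_per_protein:03d}"
        start = 1 + 40 * (l % scn.ligands_per_protein)
        seq = "".join(rng.choice(list(_AA), size=15))
        ligs[l] = Interface(protein, start, start + 14, Kind.LIGAND, seq)
    return doms, ligs


def _clamped_normal(rng: np.random.Generator, mean: float, sd: float, shape) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=shape), 0.0, 1.0)


def _feature_pair(
    name: str,
    side: Kind,
    ids1: tuple[str, ...],
    ids2: tuple[str, ...],
    planted_pairs: set[tuple[str, str]],
    mu: float,
    sigma: float,
    rng: np.random.Generator,
) -> FeatureMatrix:
    values = _clamped_normal(rng, 1.0 - mu, sigma, (len(ids1), len(ids2)))
    i1 = {v: i for i, v in enumerate(ids1)}
    i2 = {v: j for j, v in enumerate(ids2)}
    for a, b in sorted(planted_pairs):
        if a in i1 and b in i2:
            values[i1[a], i2[b]] = _clamped_normal(rng, mu, sigma, ())
    return FeatureMatrix(ids1, ids2, values, name=name, side=side, provenance="computed")


def generate_pair(scn: SyntheticScenario) -> SyntheticInstance:
    """Generate two diverged networks, the planted truth, and a feature stack.

    Raises on degenerate scenarios where a descendant loses an entire side.
    """
    rng = np.random.default_rng(scn.seed)
    ancestor = _ancestor_edges(scn, rng)

    nets: list[IIN] = []
    doms_by_species: list[dict[int, Interface]] = []
    ligs_by_species: list[dict[int, Interface]] = []
    for species in (1, 2):
        dom_alive, lig_alive, edges = _descend(scn, ancestor, rng)
        if not dom_alive.any() or not lig_alive.any():
            raise IINError(
                f"degenerate scenario: species {species} lost an entire vertex side"
            )
        doms, ligs = _interfaces(scn, species, dom_alive, lig_alive, rng)
        net = IIN(
            list(doms.values()) + list(ligs.values()),
            [(doms[d].id, ligs[l].id) for d, l in sorted(edges)],
        )
        nets.append(net)
        doms_by_species.append(doms)
        ligs_by_species.append(ligs)

    planted: dict[str, str] = {}
    for d in sorted(set(doms_by_species[0]) & set(doms_by_species[1])):
        planted[doms_by_species[0][d].id] = doms_by_species[1][d].id
    for l in sorted(set(ligs_by_species[0]) & set(ligs_by_species[1])):
        planted[ligs_by_species[0][l].id] = ligs_by_species[1][l].id

    orthology = OrthologyMap()
    shared_proteins = {
        (nets[0].protein(a), nets[1].protein(b)) for a, b in planted.items()
    }
    for p, q in sorted(shared_proteins):
        orthology.add(p, q)

    planted_pairs = set(planted.items())
    matrices: list[FeatureMatrix] = []
    mu, sigma = scn.feature_informativeness, scn.feature_noise
    for kind in (Kind.DOMAIN, Kind.LIGAND):
        matrices.append(
            _feature_pair(
                "informative", kind,
                nets[0].side_ids(kind), nets[1].side_ids(kind),
                planted_pairs, mu, sigma, rng,
            )
        )
    for k in range(scn.n_noise_features):
        for kind in (Kind.DOMAIN, Kind.LIGAND):
            ids1, ids2 = nets[0].side_ids(kind), nets[1].side_ids(kind)
            matrices.append(
                FeatureMatrix(
                    ids1, ids2,
                    rng.uniform(size=(len(ids1), len(ids2))),
                    name=f"noise{k}", side=kind, provenance="computed",
                )
            )

    n_features = 1 + scn.n_noise_features
    equal = 1.0 / (n_features + 1)
    weights = WeightVector(
        {name: equal for name in {m.name for m in matrices}}, eaw=equal
    )
    return SyntheticInstance(
        scenario=scn,
        net1=nets[0],
        net2=nets[1],
        orthology=orthology,
        planted=planted,
        stack=FeatureStack(matrices, weights),
    )


def eaw_demo_fixture() -> tuple[IIN, IIN, BaseScores]:
    """Hand-built 5+5-vertex pair where the edge bonus changes step three.

    With EAW = 1 the third aligned pair is (C..., 3...): the pair's working
    score is raised twice by the bonus, once for each of the first two
    ligand alignments adjacent to it, overtaking the base-preferred (E..., 3...).
    With EAW = 0 the third pair is (E..., 3...) instead.  Both networks are
    bipartite and single-component.
    """
    lig = Kind.LIGAND
    dom = Kind.DOMAIN
    net1 = IIN(
        [
            Interface("A", 1, 15, lig),
            Interface("B", 1, 15, lig),
            Interface("D", 1, 15, lig),
            Interface("C", 1, 30, dom),
            Interface("E", 1, 30, dom),
        ],
        [("C,1,30", "A,1,15"), ("C,1,30", "B,1,15"), ("C,1,30", "D,1,15"), ("E,1,30", "D,1,15")],
    )
    net2 = IIN(
        [
            Interface("1", 1, 15, lig),
            Interface("2", 1, 15, lig),
            Interface("4", 1, 15, lig),
            Interface("3", 1, 30, dom),
            Interface("5", 1, 30, dom),
        ],
        [("3,1,30", "1,1,15"), ("3,1,30", "2,1,15"), ("3,1,30", "4,1,15"), ("5,1,30", "4,1,15")],
    )
    lig_scores = {
        ("A,1,15", "1,1,15"): 10.0,
        ("B,1,15", "2,1,15"): 9.0,
        ("D,1,15", "4,1,15"): 1.0,
    }
    dom_scores = {
        ("C,1,30", "3,1,30"): 3.5,
        ("E,1,30", "3,1,30"): 5.0,
        ("C,1,30", "5,1,30"): 0.5,
        ("E,1,30", "5,1,30"): 0.5,
    }
    base = BaseScores(
        domain=PairScores.from_mapping(dom_scores, net1.domain_ids, net2.domain_ids, default=0.2),
        ligand=PairScores.from_mapping(lig_scores, net1.ligand_ids, net2.ligand_ids, default=0.2),
    )
    return net1, net2, base
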