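"""Orthology-recovery metrics for network alignments.

Given an alignment and a known protein orthology map, three counts are
reported together with their data-dependent maxima:

* **OVP** (orthologous vertex pairs): aligned interface pairs whose parent
  proteins are orthologous.
* **RPO** (represented protein orthologies): distinct orthologous protein
  pairs with at least one such aligned interface pair; a protein pair can be
  represented at most once, so RPO <= OVP always.
* **EA** (edges aligned): edge pairs, one edge per network, whose both
  endpoint pairs appear in the alignment.  Because alignments respect the
  domain/ligand partition and every edge joins a domain to a ligand, each
  aligned edge pair decomposes uniquely into a (domain pair, ligand pair)
  and is counted exactly once.

The maxima are what a perfect alignment of the given data could reach:
``max_ea = min(|E1|, |E2|)``; ``max_rpo`` counts orthologous protein pairs
with at least one same-side vertex pair available; ``max_ovp`` is the size of
a maximum one-to-one matching on the same-side vertex-pair graph restricted
to orthologous proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .core import IIN, AlignmentTrace, IINError, Kind, OrthologyMap


@dataclass(frozen=True)
class MetricsReport:
    rpo: int
    ovp: int
    ea: int
    max_rpo: int
    max_ovp: int
    max_ea: int

    def __post_init__(self):
        if not (0 <= self.rpo <= self.ovp):
            raise IINError(f"invariant violated: rpo={self.rpo} > ovp={self.ovp}")
        if self.ea > self.max_ea or self.rpo > self.max_rpo or self.ovp > self.max_ovp:
            raise IINError("metric exceeds its data-dependent maximum")

    def fractions(self) -> dict[str, float]:
        return {
            "rpo": self.rpo / self.max_rpo if self.max_rpo else 0.0,
            "ovp": self.ovp / self.max_ovp if self.max_ovp else 0.0,
            "ea": self.ea / self.max_ea if self.max_ea else 0.0,
        }


def _orthologous(orth: OrthologyMap, p: str, q: str) -> bool:
    return orth.contains(p, q)


def metric_maxima(net1: IIN, net2: IIN, orth: OrthologyMap) -> tuple[int, int, int]:
    """(max_rpo, max_ovp, max_ea) reachable on this data."""
    max_ea = min(net1.n_edges, net2.n_edges)

    max_rpo = 0
    match_graph = nx.Graph()
    left: set[str] = set()
    for p, q in orth.pairs:
        pair_found = False
        for a, b in ((p, q), (q, p)):
            for kind in (Kind.DOMAIN, Kind.LIGAND):
                v1 = net1.vertices_of_protein(a, kind)
                v2 = net2.vertices_of_protein(b, kind)
                if v1 and v2:
                    pair_found = True
                    for u in v1:
                        left.add(("1", u))
                        for v in v2:
                            match_graph.add_edge(("1", u), ("2", v))
        if pair_found:
            max_rpo += 1

    if match_graph.number_of_edges():
        matching = nx.bipartite.hopcroft_karp_matching(match_graph, top_nodes=left)
        max_ovp = len(matching) // 2
    else:
        max_ovp = 0
    return max_rpo, max_ovp, max_ea


def evaluate(trace: AlignmentTrace, net1: IIN, net2: IIN, orth: OrthologyMap) -> MetricsReport:
    """Score an alignment: RPO / OVP / EA plus their maxima.

    The result depends only on the set of aligned pairs, not on trace order.
    Raises on vertices unknown to either network or on partition-violating
    pairs.
    """
    for p in trace:
        if p.id1 not in net1:
            raise IINError(f"trace vertex {p.id1} not in network 1")
        if p.id2 not in net2:
            raise IINError(f"trace vertex {p.id2} not in network 2")
    trace.check_partition(net1, net2)

    ovp = 0
    rpo_pairs: set[tuple[str, str]] = set()
    for p in trace:
        prot1, prot2 = net1.protein(p.id1), net2.protein(p.id2)
        if _orthologous(orth, prot1, prot2):
            ovp += 1
            rpo_pairs.add((prot1, prot2) if prot1 <= prot2 else (prot2, prot1))

    mapping = trace.mapping
    ea = 0
    for d, l in net1.edges:
        md, ml = mapping.get(d), mapping.get(l)
        if md is not None and ml is not None and (md, ml) in net2.edges:
            ea += 1

    max_rpo, max_ovp, max_ea = metric_maxima(net1, net2, orth)
    return MetricsReport(len(rpo_pairs), ovp, ea, max_rpo, max_ovp, max_ea)


def write_report(report: MetricsReport, path) -> None:
    """Counts and percentages of maxima as a two-column TSV."""
    frac = report.fractions()
    with open(path, "w") as fh:
        fh.write("metric\tvalue\tmax\tpercent\n")
        for name, value, mx in (
            ("rpo", report.rpo, report.max_rpo),
            ("ovp", report.ovp, report.max_ovp),
            ("ea", report.ea, report.max_ea),
        ):
            fh.write(f"{name}\t{value}\t{mx}\t{100.0 * frac[name]:.1f}\n")
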