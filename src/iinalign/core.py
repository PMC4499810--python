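"""Bipartite interface-interaction network (IIN) data model and file I/O.

An IIN is an undirected bipartite graph whose vertices are individual binding
sites ("interfaces") on proteins -- peptide-recognition domains on one side,
short peptide ligand sites on the other -- and whose edges are physical
interactions between a domain and a ligand site.  Vertices are identified by
the canonical string ``PROTEIN,start,end`` with 1-based inclusive amino-acid
coordinates; the protein name therefore must not itself contain a comma.

This module owns the vertex/network/alignment/orthology containers and the
plain-text formats used throughout the package:

* network edge list: TSV with columns ``domain_id`` and ``ligand_id``;
* vertex metadata: TSV with columns ``id``, ``kind``, ``protein``, ``start``,
  ``end``, ``sequence`` (sequence optional, needed only for isolated vertices,
  kinds and sequences);
* orthology map: two-column TSV of protein pairs;
* alignment trace: TSV with columns ``step``, ``u``, ``v``, ``base_score``,
  ``eaw_bonus``, ``total``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional

import networkx as nx


class IINError(ValueError):
    """Base class for data-model violations."""


class ParseError(IINError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


class BipartitenessError(IINError):
    """An edge or declaration violates the domain/ligand bipartition."""


class Kind(str, Enum):
    DOMAIN = "domain"
    LIGAND = "ligand"


def parse_interface_id(vid: str) -> tuple[str, int, int]:
    """Split ``PROTEIN,start,end`` into its components.

    Raises :class:`IINError` if the id does not have exactly three
    comma-separated fields with integer coordinates.
    """
    parts = vid.split(",")
    if len(parts) != 3:
        raise IINError(
            f"interface id {vid!r} is not of the form PROTEIN,start,end "
            "(protein names must not contain commas)"
        )
    protein, start_s, end_s = parts
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise IINError(f"non-integer coordinates in interface id {vid!r}") from exc
    return protein, start, end


@dataclass(frozen=True, order=True)
class Interface:
    """One binding site (domain or ligand) on a protein.

    Coordinates are 1-based and inclusive, following the amino-acid-position
    convention of the source data.  If a sequence is attached its length must
    equal the span ``end - start + 1``.
    """

    protein_id: str
    start: int
    end: int
    kind: Kind
    sequence: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if "," in self.protein_id:
            raise IINError(f"protein id {self.protein_id!r} contains a comma")
        if not self.protein_id:
            raise IINError("empty protein id")
        if self.start < 1:
            raise IINError(f"{self.id}: start must be >= 1")
        if self.end < self.start:
            raise IINError(f"{self.id}: end must be >= start")
        if self.sequence is not None and len(self.sequence) != self.span:
            raise IINError(
                f"{self.id}: sequence length {len(self.sequence)} != span {self.span}"
            )

    @property
    def id(self) -> str:
        return f"{self.protein_id},{self.start},{self.end}"

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_id(cls, vid: str, kind: Kind, sequence: Optional[str] = None) -> "Interface":
        protein, start, end = parse_interface_id(vid)
        return cls(protein, start, end, Kind(kind), sequence)


class IIN:
    """Validated bipartite interface-interaction network.

    Edges always join a domain vertex to a ligand vertex and are stored as
    ``(domain_id, ligand_id)`` pairs.  Construction rejects duplicate vertex
    ids, edges with unknown endpoints, self-loops and within-side edges.
    """

    def __init__(self, interfaces: Iterable[Interface], edges: Iterable[tuple[str, str]] = ()):
        self._interfaces: dict[str, Interface] = {}
        for itf in interfaces:
            if itf.id in self._interfaces:
                raise IINError(f"duplicate vertex id {itf.id}")
            self._interfaces[itf.id] = itf
        self._adj: dict[str, set[str]] = {vid: set() for vid in self._interfaces}
        self._edges: set[tuple[str, str]] = set()
        for a, b in edges:
            self.add_edge_validated(a, b)

    def add_edge_validated(self, a: str, b: str) -> None:
        for vid in (a, b):
            if vid not in self._interfaces:
                raise IINError(f"edge ({a}, {b}) references unknown vertex {vid}")
        if a == b:
            raise IINError(f"self-loop on {a}")
        ka, kb = self._interfaces[a].kind, self._interfaces[b].kind
        if ka == kb:
            raise BipartitenessError(
                f"edge ({a}, {b}) joins two {ka.value} vertices"
            )
        dom, lig = (a, b) if ka is Kind.DOMAIN else (b, a)
        self._edges.add((dom, lig))
        self._adj[dom].add(lig)
        self._adj[lig].add(dom)

    # -- accessors ---------------------------------------------------------
    @property
    def domain_ids(self) -> tuple[str, ...]:
        return tuple(sorted(v for v, i in self._interfaces.items() if i.kind is Kind.DOMAIN))

    @property
    def ligand_ids(self) -> tuple[str, ...]:
        return tuple(sorted(v for v, i in self._interfaces.items() if i.kind is Kind.LIGAND))

    @property
    def vertex_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._interfaces))

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._edges)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __len__(self) -> int:
        return len(self._interfaces)

    def __contains__(self, vid: str) -> bool:
        return vid in self._interfaces

    def interface(self, vid: str) -> Interface:
        return self._interfaces[vid]

    def kind(self, vid: str) -> Kind:
        return self._interfaces[vid].kind

    def protein(self, vid: str) -> str:
        return self._interfaces[vid].protein_id

    def neighbors(self, vid: str) -> frozenset[str]:
        return frozenset(self._adj[vid])

    def side_ids(self, kind: Kind) -> tuple[str, ...]:
        return self.domain_ids if Kind(kind) is Kind.DOMAIN else self.ligand_ids

    def proteins(self, kind: Optional[Kind] = None) -> frozenset[str]:
        return frozenset(
            i.protein_id
            for i in self._interfaces.values()
            if kind is None or i.kind is Kind(kind)
        )

    def vertices_of_protein(self, protein: str, kind: Optional[Kind] = None) -> tuple[str, ...]:
        return tuple(
            sorted(
                vid
                for vid, i in self._interfaces.items()
                if i.protein_id == protein and (kind is None or i.kind is Kind(kind))
            )
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, IIN):
            return NotImplemented
        return self._interfaces == other._interfaces and self._edges == other._edges

    def __repr__(self) -> str:
        return (
            f"IIN(|D|={len(self.domain_ids)}, |L|={len(self.ligand_ids)}, "
            f"|E|={self.n_edges})"
        )

    def to_networkx(self) -> nx.Graph:
        """Export as a networkx graph with ``kind`` node attributes."""
        g = nx.Graph()
        for vid, itf in sorted(self._interfaces.items()):
            g.add_node(
                vid,
                kind=itf.kind.value,
                protein=itf.protein_id,
                start=itf.start,
                end=itf.end,
                bipartite=0 if itf.kind is Kind.DOMAIN else 1,
            )
        g.add_edges_from(sorted(self._edges))
        return g


@dataclass(frozen=True)
class TraceStep:
    """One aligned pair with the scores that selected it."""

    step: int
    id1: str
    id2: str
    base_score: float
    eaw_bonus: float
    bonus_count: int = 0

    @property
    def total(self) -> float:
        return self.base_score + self.eaw_bonus


class AlignmentTrace:
    """Ordered one-to-one list of aligned interface pairs.

    Invariants enforced at construction: no interface id is used twice on
    either side.  Partition-respecting pairing (domain-domain / ligand-ligand)
    is the aligner's responsibility and can be re-checked against a pair of
    networks with :meth:`check_partition`.
    """

    def __init__(self, pairs: Iterable[TraceStep]):
        self.pairs: tuple[TraceStep, ...] = tuple(pairs)
        seen1: set[str] = set()
        seen2: set[str] = set()
        for p in self.pairs:
            if p.id1 in seen1 or p.id2 in seen2:
                raise IINError(f"vertex reused in alignment at step {p.step}: {p.id1}/{p.id2}")
            seen1.add(p.id1)
            seen2.add(p.id2)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[TraceStep]:
        return iter(self.pairs)

    @property
    def mapping(self) -> dict[str, str]:
        return {p.id1: p.id2 for p in self.pairs}

    @property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset((p.id1, p.id2) for p in self.pairs)

    def pair_ids(self) -> list[tuple[str, str]]:
        return [(p.id1, p.id2) for p in self.pairs]

    def check_partition(self, net1: IIN, net2: IIN) -> None:
        for p in self.pairs:
            if net1.kind(p.id1) != net2.kind(p.id2):
                raise BipartitenessError(
                    f"step {p.step} aligns {p.id1} ({net1.kind(p.id1).value}) to "
                    f"{p.id2} ({net2.kind(p.id2).value})"
                )

    def __eq__(self, other) -> bool:
        if not isinstance(other, AlignmentTrace):
            return NotImplemented
        return self.pair_ids() == other.pair_ids()


class OrthologyMap:
    """Set of unordered protein-id pairs, one protein per species.

    Protein ids are bare names without coordinates.  Membership tests accept
    either argument order.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs: set[tuple[str, str]] = set()
        for p, q in pairs:
            self.add(p, q)

    @staticmethod
    def _norm(p: str, q: str) -> tuple[str, str]:
        return (p, q) if p <= q else (q, p)

    def add(self, p: str, q: str) -> None:
        for name in (p, q):
            if "," in name:
                raise IINError(f"orthology entry {name!r} looks like a vertex id, not a protein")
        self._pairs.add(self._norm(p, q))

    def contains(self, p: str, q: str) -> bool:
        return self._norm(p, q) in self._pairs

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._pairs))

    def __eq__(self, other) -> bool:
        if not isinstance(other, OrthologyMap):
            return NotImplemented
        return self._pairs == other._pairs


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_EDGE_HEADER = "domain_id\tligand_id"
_VERTEX_HEADER = "id\tkind\tprotein\tstart\tend\tsequence"


def read_vertex_metadata(path) -> dict[str, Interface]:
    """Read the vertex-metadata TSV into ``{id: Interface}``."""
    out: dict[str, Interface] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("id\t"):
                continue
            fields = line.split("\t")
            if len(fields) not in (5, 6):
                raise ParseError(path, lineno, f"expected 5-6 columns, got {len(fields)}")
            vid, kind, protein, start, end = fields[:5]
            seq = fields[5] if len(fields) == 6 and fields[5] else None
            try:
                itf = Interface(protein, int(start), int(end), Kind(kind), seq)
            except (ValueError, IINError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            if itf.id != vid:
                raise ParseError(path, lineno, f"id column {vid!r} disagrees with {itf.id!r}")
            out[vid] = itf
    return out


def write_vertex_metadata(net: IIN, path) -> None:
    with open(path, "w") as fh:
        fh.write(_VERTEX_HEADER + "\n")
        for vid in net.vertex_ids:
            i = net.interface(vid)
            fh.write(
                "\t".join(
                    [vid, i.kind.value, i.protein_id, str(i.start), str(i.end), i.sequence or ""]
                )
                + "\n"
            )


def read_iin(path, format: str = "edge_tsv", vertices=None) -> IIN:
    """Read an IIN from a tab-separated edge list.

    The canonical layout puts domain ids in the first column and ligand ids in
    the second (a ``domain_id<TAB>ligand_id`` header is recognised and
    skipped).  If a vertex-metadata file is given, vertex kinds (and
    sequences, isolated vertices) are taken from it and cross-checked: a
    vertex declared on one side but used on the other raises
    :class:`BipartitenessError` naming the offending edge.
    """
    if format != "edge_tsv":
        raise ValueError(f"unknown format {format!r}")
    meta = read_vertex_metadata(vertices) if vertices is not None else None

    edge_rows: list[tuple[int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line == _EDGE_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
            edge_rows.append((lineno, fields[0], fields[1]))

    kinds: dict[str, Kind] = {}
    if meta is not None:
        kinds = {vid: itf.kind for vid, itf in meta.items()}
    for lineno, a, b in edge_rows:
        for vid, kind in ((a, Kind.DOMAIN), (b, Kind.LIGAND)):
            prev = kinds.get(vid)
            if prev is None:
                kinds[vid] = kind
            elif prev is not kind:
                raise BipartitenessError(
                    f"{path}:{lineno}: edge ({a}, {b}) uses {vid} as a "
                    f"{kind.value} but it is declared/used as a {prev.value}"
                )

    interfaces: dict[str, Interface] = {}
    if meta is not None:
        interfaces.update(meta)
    for lineno, a, b in edge_rows:
        for vid in (a, b):
            if vid not in interfaces:
                try:
                    interfaces[vid] = Interface.from_id(vid, kinds[vid])
                except IINError as exc:
                    raise ParseError(path, lineno, str(exc)) from exc
    return IIN(interfaces.values(), [(a, b) for _, a, b in edge_rows])


def write_iin(net: IIN, path, vertices=None) -> None:
    """Write the edge list (sorted, deterministic); optionally the metadata."""
    with open(path, "w") as fh:
        fh.write(_EDGE_HEADER + "\n")
        for dom, lig in sorted(net.edges):
            fh.write(f"{dom}\t{lig}\n")
    if vertices is not None:
        write_vertex_metadata(net, vertices)


def write_graphml(net: IIN, path) -> None:
    """GraphML export for interoperability (not the canonical format)."""
    nx.write_graphml(net.to_networkx(), path)


def read_orthology(path) -> OrthologyMap:
    out = OrthologyMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein1\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError(path, lineno, "expected two non-empty protein ids")
            try:
                out.add(fields[0], fields[1])
            except IINError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return out


def write_orthology(orth: OrthologyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\n")
        for p, q in orth:
            fh.write(f"{p}\t{q}\n")


_TRACE_HEADER = "step\tu\tv\tbase_score\teaw_bonus\ttotal"


def write_trace(trace: AlignmentTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(_TRACE_HEADER + "\n")
        for p in trace:
            fh.write(
                f"{p.step}\t{p.id1}\t{p.id2}\t{p.base_score:.10g}"
                f"\t{p.eaw_bonus:.10g}\t{p.total:.10g}\n"
            )


def read_trace(path) -> AlignmentTrace:
    steps: list[TraceStep] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line == _TRACE_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(path, lineno, f"expected 6 columns, got {len(fields)}")
            try:
                steps.append(
                    TraceStep(
                        step=int(fields[0]),
                        id1=fields[1],
                        id2=fields[2],
                        base_score=float(fields[3]),
                        eaw_bonus=float(fields[4]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return AlignmentTrace(steps)


def read_fasta_sequences(path) -> dict[str, str]:
    """Read interface sequences keyed by vertex id from a FASTA file."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq)
    return out


def attach_sequences(net: IIN, sequences: Mapping[str, str]) -> IIN:
    """Return a copy of ``net`` with sequences attached where provided."""
    interfaces = []
    for vid in net.vertex_ids:
        i = net.interface(vid)
        seq = sequences.get(vid, i.sequence)
        interfaces.append(Interface(i.protein_id, i.start, i.end, i.kind, seq))
    return IIN(interfaces, net.edges)
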