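"""Build ligand-side vertices from predicted binding peptides.

Peptide-recognition screens report fixed-length target peptides (15-mers for
the SH3 data this package is modelled on).  Sites that do not overlap each
become their own network vertex; runs of overlapping sites are merged into a
single vertex as long as the merged span stays within ``max_len`` (30 amino
acids by default).  Oversized runs are split into several vertices: every
split into contiguous groups of whole sites with each group spanning at most
``max_len`` is considered, and the split minimising the summed pairwise
residue overlap between the resulting vertices is chosen (ties broken by
fewest vertices, then leftmost cut positions).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .core import IIN, IINError, Interface, Kind

DEFAULT_WINDOW = 15
DEFAULT_MAX_LEN = 30


@dataclass(frozen=True, order=True)
class PredictedSite:
    """A predicted binding peptide on a ligand protein (1-based inclusive)."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise IINError(f"bad site coordinates {self.protein_id},{self.start},{self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "PredictedSite") -> bool:
        return self.start <= other.end and other.start <= self.end


def _span_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _group_span(sites: Sequence[PredictedSite]) -> tuple[int, int]:
    return (min(s.start for s in sites), max(s.end for s in sites))


def _best_partition(run: Sequence[PredictedSite], max_len: int) -> list[list[PredictedSite]]:
    """Exhaustively choose the contiguous partition of an overlap run.

    Objective (lexicographic): minimum summed pairwise residue overlap between
    the resulting vertex spans, then fewest vertices, then lexicographically
    smallest cut-position tuple (leftmost cuts).
    """
    k = len(run)
    if k == 1 or _group_span(run)[1] - _group_span(run)[0] + 1 <= max_len:
        return [list(run)]
    best_key = None
    best_groups: Optional[list[list[PredictedSite]]] = None
    # cut pattern: bit i set => cut between site i and i+1
    for mask in range(1 << (k - 1)):
        groups: list[list[PredictedSite]] = [[]]
        for i, site in enumerate(run):
            groups[-1].append(site)
            if i < k - 1 and (mask >> i) & 1:
                groups.append([])
        spans = [_group_span(g) for g in groups]
        if any(hi - lo + 1 > max_len for lo, hi in spans):
            continue
        total_overlap = sum(_span_overlap(a, b) for a, b in combinations(spans, 2))
        cuts = tuple(i for i in range(k - 1) if (mask >> i) & 1)
        key = (total_overlap, len(groups), cuts)
        if best_key is None or key < best_key:
            best_key, best_groups = key, groups
    if best_groups is None:
        raise IINError(
            f"no split of {k} overlapping sites on {run[0].protein_id} fits max_len={max_len}"
        )
    return best_groups


def _merge_groups(sites: Sequence[PredictedSite], max_len: int) -> list[list[PredictedSite]]:
    """Partition one protein's sites into vertex groups (sorted by position)."""
    if not sites:
        return []
    proteins = {s.protein_id for s in sites}
    if len(proteins) > 1:
        raise IINError(f"merge_sites called with multiple proteins: {sorted(proteins)}")
    if max_len < max(s.span for s in sites):
        raise IINError(f"max_len={max_len} is smaller than a site span")
    ordered = sorted(sites, key=lambda s: (s.start, s.end))
    groups: list[list[PredictedSite]] = []
    # split into transitively-overlapping runs
    run: list[PredictedSite] = [ordered[0]]
    run_end = ordered[0].end
    for site in ordered[1:]:
        if site.start <= run_end:  # overlaps the run so far
            run.append(site)
            run_end = max(run_end, site.end)
        else:
            groups.extend(_best_partition(run, max_len))
            run, run_end = [site], site.end
    groups.extend(_best_partition(run, max_len))
    return groups


def merge_sites(
    sites: Iterable[PredictedSite],
    max_len: int = DEFAULT_MAX_LEN,
    sequence: Optional[str] = None,
) -> list[Interface]:
    """Merge one protein's predicted sites into ligand vertices.

    ``sequence``, if given, is the full protein sequence from which vertex
    sequences are sliced.  Duplicate sites collapse into one vertex.  Returns
    vertices sorted by position; every input site is wholly contained in
    exactly one returned vertex and every vertex spans at most ``max_len``.
    """
    site_list = sorted(set(sites))
    out: list[Interface] = []
    for group in _merge_groups(site_list, max_len):
        lo, hi = _group_span(group)
        seq = sequence[lo - 1 : hi] if sequence is not None else None
        out.append(Interface(group[0].protein_id, lo, hi, Kind.LIGAND, seq))
    return out


def site_vertex_assignment(
    sites: Iterable[PredictedSite], max_len: int = DEFAULT_MAX_LEN
) -> dict[PredictedSite, str]:
    """Map each input site to the id of the vertex that contains it."""
    site_list = sorted(set(sites))
    assignment: dict[PredictedSite, str] = {}
    for group in _merge_groups(site_list, max_len):
        lo, hi = _group_span(group)
        vid = f"{group[0].protein_id},{lo},{hi}"
        for s in group:
            assignment[s] = vid
    return assignment


def build_iin(
    interactions: Iterable[tuple[Interface, PredictedSite]],
    max_len: int = DEFAULT_MAX_LEN,
    extra_domains: Iterable[Interface] = (),
    ligand_sequences: Optional[dict[str, str]] = None,
) -> IIN:
    """Assemble an IIN from (domain, predicted site) interaction records.

    Ligand vertices are produced by :func:`merge_sites` per ligand protein;
    each interaction becomes an edge from its domain to the vertex containing
    its site, with duplicate edges collapsed.  ``extra_domains`` adds isolated
    (predeclared but unconnected) domain vertices.
    """
    interactions = list(interactions)
    domains: dict[str, Interface] = {}
    for d in list(extra_domains) + [d for d, _ in interactions]:
        if d.kind is not Kind.DOMAIN:
            raise IINError(f"{d.id} used as a domain but has kind {d.kind.value}")
        prev = domains.setdefault(d.id, d)
        if prev != d:
            raise IINError(f"conflicting declarations for domain {d.id}")

    by_protein: dict[str, set[PredictedSite]] = {}
    for _, site in interactions:
        by_protein.setdefault(site.protein_id, set()).add(site)

    ligands: dict[str, Interface] = {}
    assignment: dict[PredictedSite, str] = {}
    for protein in sorted(by_protein):
        sites = by_protein[protein]
        seq = (ligand_sequences or {}).get(protein)
        for itf in merge_sites(sites, max_len, sequence=seq):
            ligands[itf.id] = itf
        assignment.update(site_vertex_assignment(sites, max_len))

    edges: set[tuple[str, str]] = set()
    for dom, site in interactions:
        vid = assignment.get(site)
        if vid is None or vid not in ligands:  # pragma: no cover - internal consistency
            raise IINError(f"site {site} not covered by any ligand vertex")
        edges.add((dom.id, vid))
    return IIN(list(domains.values()) + list(ligands.values()), sorted(edges))
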