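"""Consensus pan-genome assembly: circular core order plus linear fGIs.

Per-strain gene orders are first reduced to cluster adjacency counts
(within contigs only — a contig break never contributes an adjacency).
The consensus *core* order follows majority core-to-core transitions,
treating intervening flexible clusters as transparent so clade-specific
islands do not fragment the core path; the walk is seeded and oriented by
a designated reference strain and reports whether the ends close into a
circle.  Flexible clusters are chained by majority adjacency into maximal
*linear* paths (cycles are broken at the weakest link with a warning),
anchored to the core clusters that flank them in carrier strains; chains
of fewer than three clusters are discarded to a log rather than reported
as islands.  A strain x position percent-of-longest matrix ("heatmap")
over the assembled layout flags truncated members and contig-edge ORFs.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import GenomeLayout, OrthologClusterSet

__all__ = [
    "AdjacencyTable", "CoreAssembly", "FgiAssembly", "PanAssembly",
    "adjacency_vectors", "assemble_core", "assemble_fgis",
    "build_pan_assembly", "layout_heatmap", "canonical_circular",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- adjacency

@dataclass
class AdjacencyTable:
    """Cluster adjacency counts plus the underlying per-contig sequences."""

    sequences: dict[str, list[list[str]]]     # strain -> per-contig clusters
    pair_counts: Counter                      # ordered (u, v) immediate pairs

    def undirected(self, u: str, v: str) -> int:
        return self.pair_counts.get((u, v), 0) + self.pair_counts.get((v, u), 0)

    def per_strain_totals(self) -> dict[str, int]:
        return {strain: sum(max(len(c) - 1, 0) for c in contigs)
                for strain, contigs in self.sequences.items()}


def adjacency_vectors(cs: OrthologClusterSet,
                      layouts: dict[str, GenomeLayout]) -> AdjacencyTable:
    """Count immediate cluster adjacencies within contigs."""
    assign = cs.assignment()
    sequences: dict[str, list[list[str]]] = {}
    counts: Counter = Counter()
    for strain in sorted(layouts):
        lay = layouts[strain]
        contig_seqs = []
        for contig, orfs in lay.contigs.items():
            seq = []
            for orf in orfs:
                if orf not in assign:
                    raise ValueError(f"input-mismatch: ORF {orf} in layout "
                                     f"{strain} is absent from the clusters")
                seq.append(assign[orf])
            contig_seqs.append(seq)
            for u, v in zip(seq, seq[1:]):
                counts[(u, v)] += 1
        sequences[strain] = contig_seqs
    return AdjacencyTable(sequences=sequences, pair_counts=counts)


# ---------------------------------------------------------------- core

@dataclass
class CoreAssembly:
    core_order: list[str]
    is_circular: bool
    segment_starts: list[int]      # indices into core_order; >1 => fragmented
    reference_strain: str

    @property
    def fragmented(self) -> bool:
        return len(self.segment_starts) > 1


def _core_projected_counts(adj: AdjacencyTable, core_ids: set[str]
                           ) -> dict[str, Counter]:
    """Undirected core-to-core transition counts, skipping flexible
    clusters (they are transparent for the core walk)."""
    neighbors: dict[str, Counter] = defaultdict(Counter)
    for contigs in adj.sequences.values():
        for seq in contigs:
            cores = [c for c in seq if c in core_ids]
            for u, v in zip(cores, cores[1:]):
                if u == v:
                    continue
                neighbors[u][v] += 1
                neighbors[v][u] += 1
    return neighbors


def assemble_core(adj: AdjacencyTable, core_ids,
                  reference_strain: str | None = None) -> CoreAssembly:
    """Greedy majority walk over core-to-core transitions.

    The start cluster and initial direction come from the reference
    strain's first contig (the reference influences only rotation and
    direction, never adjacency weights).  Ties between equally supported
    successors break to the lexicographically smaller cluster id.  If the
    walk exhausts its neighbors before covering all core clusters, the
    remaining clusters open new (flagged) segments rather than raising.
    """
    core_ids = set(core_ids)
    if not core_ids:
        raise ValueError("core_ids must be nonempty")
    neighbors = _core_projected_counts(adj, core_ids)
    if reference_strain is None:
        reference_strain = sorted(adj.sequences)[0]
    ref_cores = [c for seq in adj.sequences[reference_strain]
                 for c in seq if c in core_ids]
    start = ref_cores[0] if ref_cores else sorted(core_ids)[0]
    preferred_second = ref_cores[1] if len(ref_cores) > 1 else None

    order: list[str] = []
    segment_starts: list[int] = []
    visited: set[str] = set()
    current: str | None = None
    while len(visited) < len(core_ids):
        if current is None:
            nxt = (start if start not in visited
                   else min(core_ids - visited))
            segment_starts.append(len(order))
        else:
            candidates = [(c, n) for c, n in neighbors[current].items()
                          if c not in visited]
            if current == start and preferred_second is not None \
                    and preferred_second in dict(candidates):
                # orient the walk the way the reference strain reads
                nxt = preferred_second
            elif candidates:
                nxt = min(candidates, key=lambda cn: (-cn[1], cn[0]))[0]
            else:
                current = None
                continue
        order.append(nxt)
        visited.add(nxt)
        current = nxt
    is_circular = (len(segment_starts) == 1 and len(order) > 2
                   and neighbors[order[-1]].get(order[0], 0) > 0)
    if len(segment_starts) > 1:
        logger.warning("core assembly fragmented into %d segments",
                       len(segment_starts))
    return CoreAssembly(core_order=order, is_circular=is_circular,
                        segment_starts=segment_starts,
                        reference_strain=reference_strain)


def canonical_circular(order: list[str]) -> tuple[str, ...]:
    """Canonical form of a circular order up to rotation and reflection."""
    if not order:
        return ()
    best = None
    for seq in (list(order), list(reversed(order))):
        pivot = seq.index(min(seq))
        rot = tuple(seq[pivot:] + seq[:pivot])
        if best is None or rot < best:
            best = rot
    return best


# ---------------------------------------------------------------- fGIs

@dataclass
class FgiAssembly:
    fgi_id: str
    left_anchor: str | None
    right_anchor: str | None
    members: list[str]
    carriers: frozenset


@dataclass
class DiscardedFgi:
    members: list[str]
    carriers: frozenset
    reason: str


def _flexible_runs(adj: AdjacencyTable, flexible_ids: set[str]):
    """Maximal runs of flexible clusters with their flanking core clusters."""
    runs = []
    for strain, contigs in adj.sequences.items():
        for seq in contigs:
            i = 0
            while i < len(seq):
                if seq[i] in flexible_ids:
                    j = i
                    while j < len(seq) and seq[j] in flexible_ids:
                        j += 1
                    left = seq[i - 1] if i > 0 else None
                    right = seq[j] if j < len(seq) else None
                    runs.append((strain, left, seq[i:j], right))
                    i = j
                else:
                    i += 1
    return runs


def _majority(counter: Counter) -> str | None:
    if not counter:
        return None
    return min(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def assemble_fgis(adj: AdjacencyTable, flexible_ids, core_order: list[str],
                  min_fgi_size: int = 3
                  ) -> tuple[list[FgiAssembly], list[DiscardedFgi]]:
    """Chain flexible clusters into anchored linear fGIs.

    Returns (retained fGIs, discard log).  Chains shorter than
    ``min_fgi_size`` go to the log; a cycle among flexible clusters is
    broken at its weakest adjacency with a warning (islands are expected
    to be linear).
    """
    flexible_ids = set(flexible_ids)
    runs = _flexible_runs(adj, flexible_ids)
    edge_counts: Counter = Counter()
    graph: dict[str, Counter] = defaultdict(Counter)
    member_strains: dict[str, set[str]] = defaultdict(set)
    left_flank: dict[str, Counter] = defaultdict(Counter)
    right_flank: dict[str, Counter] = defaultdict(Counter)
    for strain, left, members, right in runs:
        for m in members:
            member_strains[m].add(strain)
        for u, v in zip(members, members[1:]):
            if u != v:
                key = tuple(sorted((u, v)))
                edge_counts[key] += 1
                graph[u][v] += 1
                graph[v][u] += 1
        if left is not None:
            left_flank[members[0]][left] += 1
        if right is not None:
            right_flank[members[-1]][right] += 1

    # connected components over flexible clusters
    unassigned = set(flexible_ids) & set(member_strains)
    paths: list[list[str]] = []
    for start in sorted(unassigned):
        if start not in unassigned:
            continue
        comp = {start}
        queue = [start]
        while queue:
            node = queue.pop()
            for nb in graph[node]:
                if nb in unassigned and nb not in comp:
                    comp.add(nb)
                    queue.append(nb)
        unassigned -= comp
        paths.extend(_paths_from_component(comp, graph, edge_counts))

    core_pos = {c: i for i, c in enumerate(core_order)}
    records = []
    for path in paths:
        la = _majority(left_flank[path[0]])
        ra = _majority(right_flank[path[-1]])
        la_rev = _majority(left_flank[path[-1]])
        ra_rev = _majority(right_flank[path[0]])
        # orient by anchor positions on the core; fall back to lexicographic
        fwd_key = (core_pos.get(la, len(core_pos)) if la else len(core_pos))
        rev_key = (core_pos.get(la_rev, len(core_pos)) if la_rev
                   else len(core_pos))
        flip = False
        if rev_key < fwd_key:
            flip = True
        elif rev_key == fwd_key and tuple(reversed(path)) < tuple(path):
            flip = True
        if flip:
            path = list(reversed(path))
            la, ra = la_rev, ra_rev
        carriers = frozenset(s for m in path for s in member_strains[m])
        records.append((path, la, ra, carriers))

    retained, discarded = [], []
    for path, la, ra, carriers in records:
        if len(path) < min_fgi_size:
            discarded.append(DiscardedFgi(
                members=path, carriers=carriers,
                reason=f"fewer than {min_fgi_size} ORF clusters"))
        else:
            retained.append((path, la, ra, carriers))
    retained.sort(key=lambda r: (
        core_pos.get(r[1], len(core_pos)) if r[1] else len(core_pos),
        -len(r[0]), r[0][0]))
    fgis = [FgiAssembly(fgi_id=f"fGI_{i:03d}", left_anchor=la,
                        right_anchor=ra, members=path, carriers=carriers)
            for i, (path, la, ra, carriers) in enumerate(retained, start=1)]
    return fgis, discarded


def _paths_from_component(comp: set[str], graph: dict[str, Counter],
                          edge_counts: Counter) -> list[list[str]]:
    """Decompose one connected component into linear paths."""
    sub: dict[str, Counter] = {
        n: Counter({m: c for m, c in graph[n].items() if m in comp})
        for n in comp}
    paths = []
    remaining = set(comp)
    while remaining:
        live = {n: Counter({m: c for m, c in sub[n].items()
                            if m in remaining})
                for n in remaining}
        endpoints = sorted(n for n in remaining if len(live[n]) <= 1)
        if endpoints:
            start = endpoints[0]
        else:
            # cycle: drop the weakest edge, then retry
            weakest = min(
                (tuple(sorted((u, v)))
                 for u in remaining for v in live[u]),
                key=lambda e: (edge_counts[e], e))
            logger.warning("cyclic fGI path broken at weakest adjacency "
                           "%s-%s", *weakest)
            u, v = weakest
            del sub[u][v]
            del sub[v][u]
            continue
        path = [start]
        remaining.discard(start)
        current = start
        while True:
            nxt_candidates = [(m, c) for m, c in sub[current].items()
                              if m in remaining]
            if not nxt_candidates:
                break
            nxt = min(nxt_candidates, key=lambda mc: (-mc[1], mc[0]))[0]
            path.append(nxt)
            remaining.discard(nxt)
            current = nxt
        paths.append(path)
    return paths


# ---------------------------------------------------------------- assembly

@dataclass
class PanAssembly:
    core: CoreAssembly
    fgis: list[FgiAssembly]
    discarded_fgis: list[DiscardedFgi]

    @property
    def core_order(self) -> list[str]:
        return self.core.core_order

    @property
    def is_circular(self) -> bool:
        return self.core.is_circular


def build_pan_assembly(cs: OrthologClusterSet,
                       layouts: dict[str, GenomeLayout],
                       core_ids, reference_strain: str | None = None,
                       min_fgi_size: int = 3) -> PanAssembly:
    adj = adjacency_vectors(cs, layouts)
    core_ids = set(core_ids)
    core = assemble_core(adj, core_ids, reference_strain)
    flexible = {cl.cluster_id for cl in cs.clusters} - core_ids
    fgis, discarded = assemble_fgis(adj, flexible, core.core_order,
                                    min_fgi_size)
    return PanAssembly(core=core, fgis=fgis, discarded_fgis=discarded)


# ---------------------------------------------------------------- heatmap

@dataclass
class HeatmapResult:
    values: pd.DataFrame          # strain x position, percent or NaN
    contig_break: pd.DataFrame    # strain x position, bool
    positions: list[tuple[str, str]]   # (segment id, cluster id)


def layout_heatmap(assembly: PanAssembly, cs: OrthologClusterSet,
                   layouts: dict[str, GenomeLayout],
                   strain_order: list[str] | None = None) -> HeatmapResult:
    """Percent-of-longest per strain over the assembled layout.

    Cells are ``100 * len(member) / len(longest member)`` or NaN for
    absence; contig-edge members carry an additional flag (their length,
    hence shade, is unreliable).  Row order follows ``strain_order``
    (e.g. tree leaf order) when supplied.
    """
    strains = strain_order or sorted(layouts)
    positions = [("core", c) for c in assembly.core_order]
    for fgi in assembly.fgis:
        positions.extend((fgi.fgi_id, c) for c in fgi.members)
    columns = [c for _, c in positions]
    values = pd.DataFrame(np.nan, index=strains, columns=columns)
    breaks = pd.DataFrame(False, index=strains, columns=columns)
    by_id = cs.by_id()
    edge = {orf: lay.orf_meta[orf].at_contig_edge
            for lay in layouts.values() for orf in lay.orf_ids()}
    wanted = set(columns)
    for cl_id in wanted:
        cl = by_id.get(cl_id)
        if cl is None:
            continue
        for m in cl.members:
            if m.strain in values.index:
                values.at[m.strain, cl_id] = m.percent_of_longest
                breaks.at[m.strain, cl_id] = edge.get(m.orf_id, False)
    return HeatmapResult(values=values, contig_break=breaks,
                         positions=positions)
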