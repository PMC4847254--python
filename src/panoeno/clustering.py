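"""Neighborhood-aware ortholog clustering.

ORFs from many strains are grouped into ortholog clusters using two signals:

* a normalized protein similarity (a BLAST-score-ratio: local alignment
  score divided by the smaller self-score, so identical sequences and exact
  prefix truncations both score 1.0), and
* a conserved-gene-neighborhood (CGN) score: the fraction of the up-to
  ``2*window`` flanking positions of one ORF whose best match in the other
  strain sits at the corresponding flanking position of the other ORF.

The combined score ``C = norm + lambda * neigh`` drives a greedy
agglomeration over cross-strain ORF pairs, constrained to at most one
member per strain per cluster.  The neighborhood term is what separates
byte-identical paralogs (e.g. IS elements) that sit in different genomic
contexts: their similarity is 1.0 but their flanks share nothing, so the
combined score falls below the merge threshold and each context keeps its
own cluster.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import read_blast_table

__all__ = [
    "OrfMeta", "GenomeLayout", "MatchTable", "ClusteringParams",
    "ClusterMember", "Cluster", "OrthologClusterSet",
    "score_protein_pairs", "neighborhood_score", "build_clusters",
    "classify_clusters", "exhaustive_best_partition", "layout_from_att",
]


# ------------------------------------------------------------------ layouts

@dataclass(frozen=True)
class OrfMeta:
    contig: str
    index: int            # 0-based position on its contig
    start: int            # 1-based inclusive, nucleotide
    end: int
    strand: str           # recorded but unused for neighborhood correspondence
    length_aa: int
    at_contig_edge: bool


@dataclass
class GenomeLayout:
    """Ordered ORFs of one strain, split over contigs."""

    strain_tag: str
    contigs: dict[str, list[str]]          # contig id -> ordered ORF ids
    orf_meta: dict[str, OrfMeta]

    def orf_ids(self) -> list[str]:
        return [o for orfs in self.contigs.values() for o in orfs]

    def validate(self) -> None:
        for contig, orfs in self.contigs.items():
            for i, orf in enumerate(orfs):
                m = self.orf_meta[orf]
                if m.contig != contig or m.index != i:
                    raise ValueError(f"layout {self.strain_tag}: inconsistent "
                                     f"index for {orf}")
                if m.length_aa <= 0:
                    raise ValueError(f"layout {self.strain_tag}: non-positive "
                                     f"length for {orf}")


def layout_from_att(att: pd.DataFrame, strain: str) -> GenomeLayout:
    """Rebuild a strain layout from att-table rows.

    Row order within a contig is the gene order; minus-strand ORFs are
    recognised by start > end (the att-file convention).
    """
    sub = att[att["strain_tag"] == strain]
    contigs: dict[str, list[str]] = {}
    meta: dict[str, OrfMeta] = {}
    for contig_id, grp in sub.groupby("contig_id", sort=True):
        orfs = []
        for _, row in grp.iterrows():
            start, end = int(row["start"]), int(row["end"])
            strand = "+" if start <= end else "-"
            lo, hi = min(start, end), max(start, end)
            length_aa = (hi - lo + 1) // 3 - 1
            orfs.append((row["orf_id"], lo, hi, strand, length_aa))
        orfs.sort(key=lambda r: r[1])
        contigs[contig_id] = [o[0] for o in orfs]
        for i, (orf_id, lo, hi, strand, length_aa) in enumerate(orfs):
            meta[orf_id] = OrfMeta(
                contig=contig_id, index=i, start=lo, end=hi, strand=strand,
                length_aa=length_aa,
                at_contig_edge=(i == 0 or i == len(orfs) - 1))
    return GenomeLayout(strain_tag=strain, contigs=contigs, orf_meta=meta)


# ------------------------------------------------------------------ matches

@dataclass
class MatchTable:
    """Pairwise protein matches with score-ratio normalization.

    ``entries`` holds both orders of every retained pair, mapping
    ``(orf_a, orf_b) -> (raw_score, normalized_score)``; ``best_match``
    maps ``(orf, other_strain) -> best-matching orf`` in that strain.
    """

    entries: dict[tuple[str, str], tuple[float, float]]
    strain_of: dict[str, str]
    best_match: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.best_match:
            best: dict[tuple[str, str], tuple[float, str]] = {}
            for (a, b), (_, norm) in self.entries.items():
                if a == b:
                    continue
                key = (a, self.strain_of[b])
                cur = best.get(key)
                # highest norm wins; ties -> lexicographically smallest id
                if cur is None or (-norm, b) < (-cur[0], cur[1]):
                    best[key] = (norm, b)
            self.best_match = {k: v[1] for k, v in best.items()}

    def normalized(self, a: str, b: str) -> float:
        entry = self.entries.get((a, b))
        return entry[1] if entry else 0.0


def _blast_like_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST-style affine gaps: a gap of length L costs 11 + L
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def _self_scores(seqs: list[str]) -> np.ndarray:
    """Local self-alignment scores: the sum of BLOSUM62 diagonal entries
    (all positive), so the optimal self alignment is the full diagonal."""
    mat = substitution_matrices.load("BLOSUM62")
    diag = np.zeros(128)
    for aa in mat.alphabet:
        diag[ord(aa)] = mat[aa, aa]
    return np.array([diag[np.frombuffer(s.encode(), dtype=np.uint8)].sum()
                     for s in seqs])


def _candidate_pairs(orf_ids: list[str], seqs: list[str], strains: list[str],
                     k: int = 4, min_shared: int = 4,
                     max_bucket: int = 500) -> list[tuple[int, int]]:
    """Cross-strain index pairs sharing >= min_shared k-mers."""
    n = len(orf_ids)
    index: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        for kmer in {s[j:j + k] for j in range(len(s) - k + 1)}:
            index[kmer].append(i)
    chunks = []
    for bucket in index.values():
        b = len(bucket)
        if b < 2 or b > max_bucket:
            continue
        arr = np.asarray(bucket, dtype=np.int64)
        ii, jj = np.triu_indices(b, 1)
        chunks.append(arr[ii] * n + arr[jj])
    if not chunks:
        return []
    keys, counts = np.unique(np.concatenate(chunks), return_counts=True)
    keep = keys[counts >= min_shared]
    out = []
    for key in keep:
        i, j = int(key // n), int(key % n)
        if strains[i] != strains[j]:
            out.append((i, j))
    return out


def score_protein_pairs(gset, mode: str = "internal",
                        external_table=None,
                        min_normalized_score: float = 0.35,
                        k: int = 4, min_shared_kmers: int = 4) -> MatchTable:
    """All-vs-all protein similarity as a normalized match table.

    ``internal`` mode computes local-alignment scores (BLOSUM62, BLAST-like
    gap costs) over k-mer-prefiltered candidate pairs and normalizes each
    raw score by the smaller of the two self-scores.  ``external-table``
    mode ingests a 12-column BLAST tabular file (path or DataFrame) and
    normalizes bitscores the same way using the self-hit rows.

    Pairs below ``min_normalized_score`` are omitted.  Self-pairs are
    stored with normalized score 1.0.
    """
    layouts = gset.layouts
    if len(layouts) < 2:
        raise ValueError("need at least 2 strains to score protein pairs")
    strain_of = {orf: strain for strain, lay in layouts.items()
                 for orf in lay.orf_ids()}
    entries: dict[tuple[str, str], tuple[float, float]] = {}

    if mode == "internal":
        orf_ids = sorted(strain_of)
        seqs = [gset.proteins[o] for o in orf_ids]
        strains = [strain_of[o] for o in orf_ids]
        selfs = _self_scores(seqs)
        for i, orf in enumerate(orf_ids):
            entries[(orf, orf)] = (float(selfs[i]), 1.0)
        aligner = _blast_like_aligner()
        for i, j in _candidate_pairs(orf_ids, seqs, strains,
                                     k=k, min_shared=min_shared_kmers):
            raw = float(aligner.score(seqs[i], seqs[j]))
            norm = min(1.0, raw / min(selfs[i], selfs[j]))
            if norm < min_normalized_score:
                continue
            a, b = orf_ids[i], orf_ids[j]
            entries[(a, b)] = (raw, norm)
            entries[(b, a)] = (raw, norm)
    elif mode in ("external-table", "external"):
        if external_table is None:
            raise ValueError("external-table mode requires external_table")
        df = (external_table if isinstance(external_table, pd.DataFrame)
              else read_blast_table(external_table))
        selfbits: dict[str, float] = {}
        for _, row in df.iterrows():
            if row["query"] == row["subject"]:
                selfbits[row["query"]] = max(selfbits.get(row["query"], 0.0),
                                             float(row["bitscore"]))
        for _, row in df.iterrows():
            a, b = row["query"], row["subject"]
            if a == b:
                entries[(a, a)] = (float(row["bitscore"]), 1.0)
                continue
            if a not in strain_of or b not in strain_of:
                raise ValueError(f"match table references unknown ORF "
                                 f"{a if a not in strain_of else b}")
            if strain_of[a] == strain_of[b]:
                continue
            if a not in selfbits or b not in selfbits:
                raise ValueError(
                    f"external table lacks self-hit for "
                    f"{a if a not in selfbits else b}; self rows are "
                    f"required for score-ratio normalization")
            raw = float(row["bitscore"])
            norm = min(1.0, raw / min(selfbits[a], selfbits[b]))
            if norm < min_normalized_score:
                continue
            prev = entries.get((a, b))
            if prev is None or norm > prev[1]:
                entries[(a, b)] = (raw, norm)
                entries[(b, a)] = (raw, norm)
        for orf in strain_of:
            entries.setdefault((orf, orf), (selfbits.get(orf, 0.0), 1.0))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MatchTable(entries=entries, strain_of=strain_of)


# ------------------------------------------------------------- neighborhood

def _flank(layout: GenomeLayout, meta: OrfMeta, offset: int) -> str | None:
    orfs = layout.contigs[meta.contig]
    idx = meta.index + offset
    if 0 <= idx < len(orfs):
        return orfs[idx]
    return None


def neighborhood_score(a: str, b: str, layouts: dict[str, GenomeLayout],
                       matches: MatchTable, window: int = 5) -> float:
    """Conserved-gene-neighborhood agreement of two ORFs, in [0, 1].

    For each of the up-to ``2*window`` flanking positions of ``a`` the
    corresponding (same-offset) position of ``b`` is checked for holding
    the best match of the flank.  Positions truncated by contig ends
    reduce the denominator and never count as mismatches; if no positions
    are comparable the score is 0.
    """
    sa, sb = matches.strain_of[a], matches.strain_of[b]
    if sa == sb:
        raise ValueError("neighborhood_score requires ORFs from different "
                         "strains")
    la, lb = layouts[sa], layouts[sb]
    ma, mb = la.orf_meta[a], lb.orf_meta[b]
    best = matches.best_match
    num = den = 0
    for off in range(-window, window + 1):
        if off == 0:
            continue
        fa = _flank(la, ma, off)
        fb = _flank(lb, mb, off)
        if fa is None or fb is None:
            continue
        den += 1
        if best.get((fa, sb)) == fb:
            num += 1
    return num / den if den else 0.0


# ---------------------------------------------------------------- clusters

@dataclass
class ClusteringParams:
    neighborhood_window: int = 5
    neighborhood_weight: float = 1.0        # lambda
    min_normalized_score: float = 0.35
    min_neighborhood_score: float = 0.7
    core_fraction: float = 0.75

    def __post_init__(self):
        if self.neighborhood_window < 1:
            raise ValueError("neighborhood_window must be >= 1")

    @property
    def merge_threshold(self) -> float:
        """Minimum combined score for a merge: with lambda > 0 a pair must
        make up in neighborhood agreement what pure similarity cannot
        prove, which is what keeps identical IS elements in novel contexts
        apart."""
        return (self.min_normalized_score
                + self.neighborhood_weight * self.min_neighborhood_score)


@dataclass(frozen=True)
class ClusterMember:
    orf_id: str
    strain: str
    length_aa: int
    percent_of_longest: float


@dataclass
class Cluster:
    cluster_id: str
    members: list[ClusterMember]
    centroid: str                 # longest member; ties -> smallest ORF id

    @property
    def strains(self) -> set[str]:
        return {m.strain for m in self.members}

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class OrthologClusterSet:
    clusters: list[Cluster]
    params: ClusteringParams
    strains: list[str]

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def assignment(self) -> dict[str, str]:
        return {m.orf_id: cl.cluster_id
                for cl in self.clusters for m in cl.members}

    def by_id(self) -> dict[str, Cluster]:
        return {cl.cluster_id: cl for cl in self.clusters}

    def presence_matrix(self) -> pd.DataFrame:
        """strains x clusters boolean presence."""
        cols = [cl.cluster_id for cl in self.clusters]
        mat = pd.DataFrame(False, index=list(self.strains), columns=cols)
        for cl in self.clusters:
            for m in cl.members:
                mat.loc[m.strain, cl.cluster_id] = True
        return mat

    def partition(self) -> set[frozenset]:
        return {frozenset(m.orf_id for m in cl.members)
                for cl in self.clusters}


def _flank_agreement(a: str, b: str, layouts, matches,
                     window: int) -> tuple[int, int]:
    """(matching, comparable) flank positions of ``a`` against ``b``."""
    sa, sb = matches.strain_of[a], matches.strain_of[b]
    la, lb = layouts[sa], layouts[sb]
    ma, mb = la.orf_meta[a], lb.orf_meta[b]
    best = matches.best_match
    num = den = 0
    for off in range(-window, window + 1):
        if off == 0:
            continue
        fa = _flank(la, ma, off)
        fb = _flank(lb, mb, off)
        if fa is None or fb is None:
            continue
        den += 1
        if best.get((fa, sb)) == fb:
            num += 1
    return num, den


def _scored_pairs(matches: MatchTable, layouts: dict[str, GenomeLayout],
                  params: ClusteringParams
                  ) -> list[tuple[float, float, str, str]]:
    """Unordered cross-strain pairs as ``(C, pair threshold, a, b)``,
    descending by combined score.

    The neighborhood term pools the comparable flank positions of both
    directions.  A pair with *no* comparable positions at all (each ORF
    hard against the opposite contig end) carries no neighborhood
    evidence either way: for such pairs the lambda term is waived from
    both the score and the threshold, and similarity alone decides.
    """
    lam = params.neighborhood_weight
    tau_full = params.merge_threshold
    tau_bare = params.min_normalized_score
    window = params.neighborhood_window
    pairs = []
    for (a, b), (_, norm) in matches.entries.items():
        if a >= b or matches.strain_of[a] == matches.strain_of[b]:
            continue
        if lam > 0:
            na, da = _flank_agreement(a, b, layouts, matches, window)
            nb, db = _flank_agreement(b, a, layouts, matches, window)
            if da + db == 0:
                pairs.append((norm, tau_bare, a, b))
                continue
            neigh = (na + nb) / (da + db)
        else:
            neigh = 0.0
        pairs.append((norm + lam * neigh, tau_full, a, b))
    pairs.sort(key=lambda p: (-p[0], p[2], p[3]))
    return pairs


def _finalize_clusters(groups: list[list[str]], matches: MatchTable,
                       layouts: dict[str, GenomeLayout],
                       params: ClusteringParams) -> OrthologClusterSet:
    lengths = {orf: lay.orf_meta[orf].length_aa
               for lay in layouts.values() for orf in lay.orf_ids()}
    records = []
    for group in groups:
        members = sorted(group)
        centroid = min(members, key=lambda o: (-lengths[o], o))
        longest = lengths[centroid]
        records.append((members, centroid, longest))
    records.sort(key=lambda r: r[0][0])
    clusters = []
    for idx, (members, centroid, longest) in enumerate(records, start=1):
        cl = Cluster(
            cluster_id=f"CL_{idx:05d}",
            members=[ClusterMember(
                orf_id=o, strain=matches.strain_of[o],
                length_aa=lengths[o],
                percent_of_longest=100.0 * lengths[o] / longest)
                for o in members],
            centroid=centroid)
        clusters.append(cl)
    return OrthologClusterSet(clusters=clusters, params=params,
                              strains=sorted(layouts))


def _check_universe(matches: MatchTable, layouts) -> None:
    layout_orfs = {o for lay in layouts.values() for o in lay.orf_ids()}
    if set(matches.strain_of) != layout_orfs:
        raise ValueError("input-mismatch: match table and layouts cover "
                         "different ORF universes")


def build_clusters(matches: MatchTable, layouts: dict[str, GenomeLayout],
                   params: ClusteringParams | None = None) -> OrthologClusterSet:
    """Greedy agglomeration of cross-strain pairs by combined score.

    Pairs are processed in descending ``C = norm + lambda*neigh`` order
    (ties by lexicographic ORF-id pair); a pair merges its clusters only if
    ``C`` clears the merge threshold and the union keeps at most one member
    per strain.  Unmerged ORFs become singletons.
    """
    params = params or ClusteringParams()
    _check_universe(matches, layouts)
    parent: dict[str, str] = {o: o for o in matches.strain_of}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    strains_in: dict[str, set[str]] = {o: {matches.strain_of[o]}
                                       for o in parent}
    for combined, tau, a, b in _scored_pairs(matches, layouts, params):
        if combined < tau:
            continue
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        if strains_in[ra] & strains_in[rb]:
            continue
        # deterministic union: smaller id becomes the root
        ra, rb = sorted((ra, rb))
        parent[rb] = ra
        strains_in[ra] |= strains_in.pop(rb)
    groups: dict[str, list[str]] = defaultdict(list)
    for orf in parent:
        groups[find(orf)].append(orf)
    return _finalize_clusters(list(groups.values()), matches, layouts, params)


def classify_clusters(cs: OrthologClusterSet, n_strains: int | None = None,
                      core_fraction: float | None = None) -> dict[str, str]:
    """Label each cluster ``core`` or ``flexible``.

    A cluster is core iff it has members (partial or complete) in at least
    ``ceil(core_fraction * n_strains)`` distinct strains.
    """
    n = n_strains if n_strains is not None else cs.n_strains
    frac = core_fraction if core_fraction is not None else cs.params.core_fraction
    if not (0 < frac <= 1):
        raise ValueError("core_fraction must be in (0, 1]")
    need = math.ceil(frac * n - 1e-9)
    return {cl.cluster_id: ("core" if len(cl.strains) >= need else "flexible")
            for cl in cs.clusters}


# ------------------------------------------------------- exhaustive oracle

def exhaustive_best_partition(matches: MatchTable,
                              layouts: dict[str, GenomeLayout],
                              params: ClusteringParams | None = None,
                              max_component: int = 12) -> set[frozenset]:
    """Optimal constrained partition by exhaustive search (small inputs).

    Every cross-strain pair whose combined score clears the merge
    threshold carries ortholog evidence of weight ``C - threshold``;
    pairs below the threshold carry none.  The search maximises the total
    evidence realised inside clusters, subject to at most one member per
    strain per cluster; ties prefer more clusters (so unsupported merges
    never happen), then the lexicographically smallest partition.
    Partitions factorise over connected components of the supported-pair
    graph, so only components (bounded by ``max_component``) are
    enumerated.
    """
    params = params or ClusteringParams()
    _check_universe(matches, layouts)
    pair_score: dict[frozenset, float] = {}
    adj: dict[str, set[str]] = defaultdict(set)
    for score, tau, a, b in _scored_pairs(matches, layouts, params):
        if score < tau:
            continue
        pair_score[frozenset((a, b))] = score - tau
        adj[a].add(b)
        adj[b].add(a)
    all_orfs = sorted(matches.strain_of)
    seen: set[str] = set()
    result: set[frozenset] = set()
    for start in all_orfs:
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        queue = [start]
        while queue:
            node = queue.pop()
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    comp.append(nb)
                    queue.append(nb)
        comp.sort()
        if len(comp) == 1:
            result.add(frozenset(comp))
            continue
        if len(comp) > max_component:
            raise ValueError(
                f"component of {len(comp)} ORFs exceeds enumeration guard "
                f"({max_component}); use build_clusters for large inputs")
        best = None   # (score, n_clusters, canonical, clusters)
        strain_of = matches.strain_of

        def recurse(i: int, clusters: list[list[str]], score: float):
            nonlocal best
            if i == len(comp):
                canonical = tuple(sorted(tuple(sorted(c)) for c in clusters))
                if best is None:
                    better = True
                else:
                    bscore, bn, bcanon = best[0]
                    if score > bscore + 1e-12:
                        better = True
                    elif score < bscore - 1e-12:
                        better = False
                    elif len(clusters) != bn:
                        better = len(clusters) > bn
                    else:
                        better = canonical < bcanon
                if better:
                    best = ((score, len(clusters), canonical),
                            [list(c) for c in clusters])
                return
            orf = comp[i]
            for cl in clusters:
                if any(strain_of[o] == strain_of[orf] for o in cl):
                    continue
                gain = sum(pair_score.get(frozenset((orf, o)), 0.0)
                           for o in cl)
                cl.append(orf)
                recurse(i + 1, clusters, score + gain)
                cl.pop()
            clusters.append([orf])
            recurse(i + 1, clusters, score)
            clusters.pop()

        recurse(0, [], 0.0)
        for cl in best[1]:
            result.add(frozenset(cl))
    return result
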