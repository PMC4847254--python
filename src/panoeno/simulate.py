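"""Synthetic bacterial pan-genome generator with complete ground truth.

The generator emulates the structures a pan-genome analysis must recover
from real strain collections:

* a clonal frame of core genes in a conserved *circular* order, present in
  every strain;
* flexible genomic islands (fGIs): blocks of extra genes inserted at a
  single intergenic slot of the core frame and confined to one clade of
  the strain tree;
* byte-identical IS-element proteins placed at several distinct
  neighborhood positions (each position is its own true cluster);
* frameshift-style truncations: a per-strain prefix of the full protein,
  optionally followed by a second short ORF for the downstream fragment;
* contig fragmentation: each strain is linearised at a random origin and
  split by breaks placed between genes, never inside one;
* SNPs accumulated along the known tree on a separate nucleotide
  reference, emitted as per-strain VCFs against a designated reference
  strain.

Protein sequences are drawn from a uniform 20-letter alphabet per
ancestral gene and mutated per branch at ``snp_rate`` substitutions per
site per unit branch length, so sequence similarity mirrors the tree and
the same simulation exercises clustering and phylogeny reconstruction.
Fixing the seed fixes every emitted byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pio
from .clustering import (Cluster, ClusterMember, ClusteringParams,
                         GenomeLayout, OrfMeta, OrthologClusterSet,
                         layout_from_att)
from .profiles import HYPOTHETICAL, load_pathway_config
from .trees import StrainTree, simulate_tree

__all__ = [
    "SimConfig", "GroundTruth", "GenomeSet", "TrueFgi", "simulate_tree",
    "simulate_pangenome", "write_genome_set", "read_genome_set",
    "read_ground_truth", "cluster_set_from_truth",
]

AA_BYTES = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
NT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA_INDEX = np.zeros(128, dtype=np.int64)
for _i, _b in enumerate(AA_BYTES):
    _AA_INDEX[_b] = _i


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated strain collection.

    Defaults describe the demonstration-scale collection used throughout
    the examples (12 strains, 120 core genes, 4 islands); rates follow
    what a streamlined lactic-acid-bacterium genome would show at the
    scale of a single analysis run.
    """

    n_strains: int = 12
    n_core_genes: int = 120
    n_fgis: int = 4
    fgi_size_range: tuple[int, int] = (3, 10)
    truncation_rate: float = 0.02       # per gene per strain
    is_element_copies: int = 3
    snp_rate: float = 0.02              # substitutions / site / unit branch
    contig_break_rate: float = 2.0      # expected breaks per genome (Poisson)
    seed: int = 0
    genome_bp: int = 100_000            # nucleotide reference length
    protein_length_range: tuple[int, int] = (80, 260)
    intergenic_gap: int = 100
    emit_downstream_orf: bool = False
    annotate_functions: bool = True

    def __post_init__(self):
        if self.n_core_genes < 10:
            raise SimConfigError("n_core_genes must be >= 10")
        if self.fgi_size_range[0] < 1:
            raise SimConfigError("fgi_size_range min must be >= 1")
        for name in ("truncation_rate", "snp_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name} must be in [0, 1]")
        if self.contig_break_rate < 0:
            raise SimConfigError("contig_break_rate must be >= 0")


@dataclass(frozen=True)
class TrueFgi:
    fgi_id: str
    left_anchor: str            # core cluster immediately left of the island
    right_anchor: str
    members: tuple[str, ...]    # ordered member cluster ids
    carriers: frozenset         # strain tags; always a clade of the tree


@dataclass
class GroundTruth:
    true_clusters: dict[str, str]               # ORF id -> cluster id
    true_core_ids: set[str]
    true_core_order: list[str]                  # circular ancestral order
    true_fgis: list[TrueFgi]
    true_is_ids: list[str]
    true_tree: StrainTree
    true_truncations: dict[tuple[str, str], float]   # (strain, cluster) -> frac
    true_snps: dict[str, list[tuple[int, str, str]]]
    snps_per_branch: dict[int, int]             # preorder child node -> count
    reference_strain: str
    cluster_annotations: dict[str, str]

    @property
    def min_branch_snps(self) -> int:
        return min(self.snps_per_branch.values()) if self.snps_per_branch else 0


@dataclass
class GenomeSet:
    strains: list[str]
    layouts: dict[str, GenomeLayout]
    proteins: dict[str, str]                    # ORF id -> aa sequence
    annotations: dict[str, str]                 # ORF id -> annotation string
    reference_strain: str = ""
    reference_genome: str = ""
    variants: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)

    def orf_count(self, strain: str) -> int:
        return len(self.layouts[strain].orf_ids())


# ------------------------------------------------------------------ helpers

def _evolve_family(ancestral: np.ndarray, branches, n_nodes: int,
                   rate: float, rng) -> dict[str, np.ndarray]:
    """Mutate an ancestral protein along the tree; returns leaf arrays."""
    seqs: list[np.ndarray | None] = [None] * n_nodes
    seqs[0] = ancestral
    leaves: dict[str, np.ndarray] = {}
    for parent, child, bl, label in branches:
        s = seqs[parent]
        p = min(1.0, rate * bl)
        m = int(rng.binomial(len(s), p))
        if m:
            s = s.copy()
            pos = rng.choice(len(s), size=m, replace=False)
            cur_idx = _AA_INDEX[s[pos]]
            new_idx = (cur_idx + 1 + rng.integers(0, 19, size=m)) % 20
            s[pos] = AA_BYTES[new_idx]
        seqs[child] = s
        if label is not None:
            leaves[label] = s
    return leaves


def _pick_insertion_slots(n_core: int, needed: int, rng) -> list[int]:
    """Distinct intergenic slots on the circular core, pairwise non-adjacent.

    Isolated insertions keep each planted island a self-contained
    adjacency chain (two adjacent islands would be indistinguishable from
    one larger island).
    """
    if needed == 0:
        return []
    if 2 * needed > n_core:
        raise SimConfigError(
            f"{needed} insertions do not fit {n_core} intergenic anchor "
            f"slots with isolation; increase n_core_genes")
    for _ in range(1000):
        slots = sorted(int(s) for s in
                       rng.choice(n_core, size=needed, replace=False))
        gaps_ok = all(slots[i + 1] - slots[i] >= 2
                      for i in range(len(slots) - 1))
        if gaps_ok and (needed < 2 or (slots[0] + n_core - slots[-1]) >= 2):
            return slots
    # deterministic fallback: evenly spaced
    return [int(i * n_core / needed) for i in range(needed)]


# ---------------------------------------------------------------- simulate

def simulate_pangenome(cfg: SimConfig, tree: StrainTree
                       ) -> tuple[GenomeSet, GroundTruth]:
    leaves = tree.leaf_labels
    if len(leaves) != cfg.n_strains:
        raise ValueError(f"tree has {len(leaves)} leaves, config expects "
                         f"{cfg.n_strains} strains")
    (rng_fam, rng_place, rng_evo, rng_trunc, rng_layout,
     rng_snp) = [np.random.default_rng(s)
                 for s in np.random.SeedSequence(cfg.seed).spawn(6)]
    branches = list(tree.branch_iter())
    n_nodes = max(max(p, c) for p, c, _, _ in branches) + 1

    lo, hi = cfg.protein_length_range
    core_ids = [f"fam_core_{i:04d}" for i in range(1, cfg.n_core_genes + 1)]
    ancestral: dict[str, np.ndarray] = {}
    for fam in core_ids:
        L = int(rng_fam.integers(lo, hi + 1))
        ancestral[fam] = AA_BYTES[rng_fam.integers(0, 20, L)]

    # fGIs: sizes, member families, clade assignment
    fgi_sizes = [int(rng_place.integers(cfg.fgi_size_range[0],
                                        cfg.fgi_size_range[1] + 1))
                 for _ in range(cfg.n_fgis)]
    fgi_members: list[list[str]] = []
    for j, size in enumerate(fgi_sizes, start=1):
        members = [f"fam_fgi_{j:02d}_{k:02d}" for k in range(1, size + 1)]
        fgi_members.append(members)
        for fam in members:
            L = int(rng_fam.integers(lo, hi + 1))
            ancestral[fam] = AA_BYTES[rng_fam.integers(0, 20, L)]
    edges = tree.edges()
    internal = [cl for cl, _ in edges if 2 <= len(cl) < len(leaves)]
    terminal = [cl for cl, _ in edges if len(cl) == 1]
    if cfg.n_fgis > len(internal) + len(terminal):
        raise SimConfigError("more fGIs than tree edges to confine them to")
    # prefer multi-strain clades: islands seen by >=2 carriers survive a
    # contig break or linearisation origin falling inside one carrier's copy
    if cfg.n_fgis <= len(internal):
        chosen = rng_place.choice(len(internal), size=cfg.n_fgis,
                                  replace=False)
        fgi_carriers = [frozenset(internal[int(c)]) for c in chosen]
    else:
        extra = cfg.n_fgis - len(internal)
        chosen = rng_place.choice(len(terminal), size=extra, replace=False)
        fgi_carriers = ([frozenset(cl) for cl in internal]
                        + [frozenset(terminal[int(c)]) for c in chosen])

    # IS element: one protein, identical in every copy and strain
    is_ids = [f"fam_is_{j:02d}" for j in range(1, cfg.is_element_copies + 1)]
    is_len = int(rng_fam.integers(100, 201))
    is_seq = AA_BYTES[rng_fam.integers(0, 20, is_len)]

    strand_of = {fam: ("+" if rng_fam.random() < 0.5 else "-")
                 for fam in core_ids + [f for ms in fgi_members for f in ms]
                 + is_ids}

    slots = _pick_insertion_slots(cfg.n_core_genes,
                                  cfg.n_fgis + cfg.is_element_copies,
                                  rng_place)
    insert_at: dict[int, tuple[str, int]] = {}
    for j, slot in enumerate(slots[:cfg.n_fgis]):
        insert_at[slot] = ("fgi", j)
    for j, slot in enumerate(slots[cfg.n_fgis:]):
        insert_at[slot] = ("is", j)

    # evolve every non-IS family along the tree
    leaf_seqs: dict[str, dict[str, np.ndarray]] = {}
    for fam in core_ids + [f for ms in fgi_members for f in ms]:
        leaf_seqs[fam] = _evolve_family(ancestral[fam], branches, n_nodes,
                                        cfg.snp_rate, rng_evo)

    # per-strain circular gene lists
    per_strain_genes: dict[str, list[tuple[str, np.ndarray]]] = {}
    for strain in leaves:
        genes: list[tuple[str, np.ndarray]] = []
        for i, fam in enumerate(core_ids):
            genes.append((fam, leaf_seqs[fam][strain]))
            ins = insert_at.get(i)
            if ins is None:
                continue
            kind, j = ins
            if kind == "fgi" and strain in fgi_carriers[j]:
                for mfam in fgi_members[j]:
                    genes.append((mfam, leaf_seqs[mfam][strain]))
            elif kind == "is":
                genes.append((is_ids[j], is_seq))
        per_strain_genes[strain] = genes

    # truncations: prefix of the full-length leaf protein
    true_truncations: dict[tuple[str, str], float] = {}
    truncated_entries: dict[str, dict[str, tuple[np.ndarray, np.ndarray | None]]] = {}
    for strain in leaves:
        truncated_entries[strain] = {}
        for fam, seq in per_strain_genes[strain]:
            if fam.startswith("fam_is_"):
                continue
            if rng_trunc.random() < cfg.truncation_rate:
                frac = float(rng_trunc.uniform(0.15, 0.85))
                tlen = min(len(seq) - 1, max(10, int(round(frac * len(seq)))))
                downstream = None
                if cfg.emit_downstream_orf and len(seq) - tlen - 1 >= 10:
                    downstream = seq[tlen + 1:]
                truncated_entries[strain][fam] = (seq[:tlen], downstream)
                true_truncations[(strain, fam)] = tlen / len(seq)

    # function annotations on core families
    annotations: dict[str, str] = {fam: HYPOTHETICAL for fam in ancestral}
    for fam in is_ids:
        annotations[fam] = HYPOTHETICAL
    if cfg.annotate_functions:
        fn_ids = load_pathway_config().all_function_ids()
        for fam, fn in zip(core_ids, fn_ids):
            annotations[fam] = fn

    # layouts: rotate, break into contigs, assign coordinates
    layouts: dict[str, GenomeLayout] = {}
    proteins: dict[str, str] = {}
    orf_annotations: dict[str, str] = {}
    true_clusters: dict[str, str] = {}
    for strain in leaves:
        entries: list[tuple[str, np.ndarray, str]] = []   # (fam, seq, ann)
        for fam, seq in per_strain_genes[strain]:
            tr = truncated_entries[strain].get(fam)
            if tr is None:
                entries.append((fam, seq, annotations[fam]))
            else:
                prefix, downstream = tr
                entries.append((fam, prefix, annotations[fam]))
                if downstream is not None:
                    ds_fam = f"fam_ds_{fam[4:]}_{strain}"
                    entries.append((ds_fam, downstream, HYPOTHETICAL))
        rot = int(rng_layout.integers(len(entries)))
        entries = entries[rot:] + entries[:rot]
        n_breaks = min(int(rng_layout.poisson(cfg.contig_break_rate)),
                       len(entries) // 2 - 1)
        cuts: list[int] = []
        if n_breaks > 0:
            # breaks fall between genes and never isolate a single ORF:
            # every contig keeps at least 2 genes
            for _ in range(1000):
                cand = sorted(int(c) for c in
                              rng_layout.choice(
                                  np.arange(2, len(entries) - 1),
                                  size=n_breaks, replace=False))
                sizes = np.diff([0] + cand + [len(entries)])
                if (sizes >= 2).all():
                    cuts = cand
                    break
        bounds = [0] + cuts + [len(entries)]
        contigs: dict[str, list[str]] = {}
        meta: dict[str, OrfMeta] = {}
        k = 0
        for ci in range(len(bounds) - 1):
            contig_id = f"{strain}_ctg{ci + 1:02d}"
            segment = entries[bounds[ci]:bounds[ci + 1]]
            orf_list = []
            cursor = 1
            for idx, (fam, seq, ann) in enumerate(segment):
                k += 1
                orf_id = f"{strain}_orf{k:05d}"
                nt_len = 3 * (len(seq) + 1)
                start, end = cursor, cursor + nt_len - 1
                cursor = end + 1 + cfg.intergenic_gap
                orf_list.append(orf_id)
                meta[orf_id] = OrfMeta(
                    contig=contig_id, index=idx, start=start, end=end,
                    strand=strand_of.get(fam, "+"), length_aa=len(seq),
                    at_contig_edge=(idx == 0 or idx == len(segment) - 1))
                proteins[orf_id] = seq.tobytes().decode()
                orf_annotations[orf_id] = ann
                true_clusters[orf_id] = fam
            contigs[contig_id] = orf_list
        layouts[strain] = GenomeLayout(strain_tag=strain, contigs=contigs,
                                       orf_meta=meta)

    # nucleotide reference + SNPs along the tree
    L = cfg.genome_bp
    root_nt = NT_BYTES[rng_snp.integers(0, 4, L)]
    diffs: list[dict[int, int] | None] = [None] * n_nodes
    diffs[0] = {}
    leaf_diffs: dict[str, dict[int, int]] = {}
    snps_per_branch: dict[int, int] = {}
    for parent, child, bl, label in branches:
        d = dict(diffs[parent])
        m = int(rng_snp.poisson(cfg.snp_rate * bl * L))
        m = min(m, L)
        if m:
            pos = rng_snp.choice(L, size=m, replace=False)
            shift = rng_snp.integers(1, 4, size=m)
            for p, sh in zip(pos, shift):
                cur = d.get(int(p), int(root_nt[p]))
                cur_i = int(np.searchsorted(NT_BYTES, cur))
                d[int(p)] = int(NT_BYTES[(cur_i + int(sh)) % 4])
        snps_per_branch[child] = m
        diffs[child] = d
        if label is not None:
            leaf_diffs[label] = d
    reference_strain = leaves[0]
    ref_nt = root_nt.copy()
    for p, b in leaf_diffs[reference_strain].items():
        ref_nt[p] = b
    variants: dict[str, list[tuple[int, str, str]]] = {}
    ref_diff = leaf_diffs[reference_strain]
    for strain in leaves:
        d = leaf_diffs[strain]
        var = []
        for p in sorted(set(d) | set(ref_diff)):
            base_s = d.get(p, int(root_nt[p]))
            base_r = int(ref_nt[p])
            if base_s != base_r:
                var.append((p + 1, chr(base_r), chr(base_s)))
        variants[strain] = var

    gset = GenomeSet(strains=list(leaves), layouts=layouts,
                     proteins=proteins, annotations=orf_annotations,
                     reference_strain=reference_strain,
                     reference_genome=ref_nt.tobytes().decode(),
                     variants=variants)
    true_fgis = []
    for j in range(cfg.n_fgis):
        slot = slots[j]
        true_fgis.append(TrueFgi(
            fgi_id=f"fgi_{j + 1:02d}",
            left_anchor=core_ids[slot],
            right_anchor=core_ids[(slot + 1) % cfg.n_core_genes],
            members=tuple(fgi_members[j]),
            carriers=fgi_carriers[j]))
    truth = GroundTruth(
        true_clusters=true_clusters,
        true_core_ids=set(core_ids),
        true_core_order=list(core_ids),
        true_fgis=true_fgis,
        true_is_ids=list(is_ids),
        true_tree=tree,
        true_truncations=true_truncations,
        true_snps=variants,
        snps_per_branch=snps_per_branch,
        reference_strain=reference_strain,
        cluster_annotations=dict(annotations))
    return gset, truth


def cluster_set_from_truth(gset: GenomeSet, truth: GroundTruth,
                           params: ClusteringParams | None = None
                           ) -> OrthologClusterSet:
    """Assemble an :class:`OrthologClusterSet` directly from ground truth.

    Cluster ids are the true family ids; useful for exercising downstream
    stages (assembly, profiling) independently of clustering accuracy.
    """
    params = params or ClusteringParams()
    lengths = {orf: lay.orf_meta[orf].length_aa
               for lay in gset.layouts.values() for orf in lay.orf_ids()}
    strain_of = {orf: s for s, lay in gset.layouts.items()
                 for orf in lay.orf_ids()}
    groups: dict[str, list[str]] = {}
    for orf, fam in truth.true_clusters.items():
        groups.setdefault(fam, []).append(orf)
    clusters = []
    for fam in sorted(groups):
        members = sorted(groups[fam])
        centroid = min(members, key=lambda o: (-lengths[o], o))
        longest = lengths[centroid]
        clusters.append(Cluster(
            cluster_id=fam,
            members=[ClusterMember(orf_id=o, strain=strain_of[o],
                                   length_aa=lengths[o],
                                   percent_of_longest=100.0 * lengths[o] / longest)
                     for o in members],
            centroid=centroid))
    return OrthologClusterSet(clusters=clusters, params=params,
                              strains=list(gset.strains))


# ---------------------------------------------------------------- file IO

def write_genome_set(gset: GenomeSet, truth: GroundTruth, outdir) -> list[str]:
    """Emit the full file set; returns the manifest of relative paths."""
    outdir = str(outdir)
    manifest: list[str] = []

    def reg(relpath: str) -> str:
        manifest.append(relpath)
        return os.path.join(outdir, relpath)

    pio.ensure_dir(os.path.join(outdir, "proteins"))
    pio.ensure_dir(os.path.join(outdir, "vcf"))
    pio.ensure_dir(os.path.join(outdir, "truth"))
    att_rows = []
    for strain in gset.strains:
        lay = gset.layouts[strain]
        seqs = {o: gset.proteins[o] for o in lay.orf_ids()}
        descs = {o: gset.annotations.get(o, "") for o in seqs}
        pio.write_fasta(reg(f"proteins/{strain}.faa"), seqs, descs)
        for contig, orfs in lay.contigs.items():
            for orf in orfs:
                m = lay.orf_meta[orf]
                start, end = ((m.start, m.end) if m.strand == "+"
                              else (m.end, m.start))
                att_rows.append({
                    "contig_id": contig, "orf_id": orf, "start": start,
                    "end": end,
                    "annotation": gset.annotations.get(orf, ""),
                    "strain_tag": strain})
    pio.write_att_table(reg("att.tsv"), att_rows)
    pio.write_fasta(reg("reference.fasta"),
                    {gset.reference_strain: gset.reference_genome})
    for strain in gset.strains:
        pio.write_vcf(reg(f"vcf/{strain}.vcf"), strain,
                      gset.reference_strain, len(gset.reference_genome),
                      gset.variants.get(strain, []))
    truth.true_tree.write(reg("truth/tree.nwk"))
    pd.DataFrame(
        sorted(truth.true_clusters.items()),
        columns=["orf_id", "cluster_id"]).to_csv(
            reg("truth/clusters.tsv"), sep="\t", index=False)
    with open(reg("truth/core_order.txt"), "w") as fh:
        for fam in truth.true_core_order:
            fh.write(fam + "\n")
    pd.DataFrame(
        [{"fgi_id": f.fgi_id, "left_anchor": f.left_anchor,
          "right_anchor": f.right_anchor,
          "members": ";".join(f.members),
          "carriers": ";".join(sorted(f.carriers))}
         for f in truth.true_fgis]).to_csv(
            reg("truth/fgis.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"strain": s, "cluster_id": c, "fraction_of_full": round(fr, 6)}
         for (s, c), fr in sorted(truth.true_truncations.items())],
        columns=["strain", "cluster_id", "fraction_of_full"]).to_csv(
            reg("truth/truncations.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"child_node": k, "n_snps": v}
         for k, v in sorted(truth.snps_per_branch.items())],
        columns=["child_node", "n_snps"]).to_csv(
            reg("truth/branch_snps.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.cluster_annotations.items()),
        columns=["cluster_id", "annotation"]).to_csv(
            reg("truth/annotations.tsv"), sep="\t", index=False)
    with open(reg("truth/is_elements.txt"), "w") as fh:
        for fam in truth.true_is_ids:
            fh.write(fam + "\n")
    return manifest


def read_genome_set(outdir) -> GenomeSet:
    outdir = str(outdir)
    att = pio.read_att_table(os.path.join(outdir, "att.tsv"))
    strains = sorted(att["strain_tag"].unique())
    layouts = {s: layout_from_att(att, s) for s in strains}
    proteins: dict[str, str] = {}
    for strain in strains:
        proteins.update(pio.read_fasta(
            os.path.join(outdir, "proteins", f"{strain}.faa")))
    annotations = {row["orf_id"]: ("" if pd.isna(row["annotation"])
                                   else row["annotation"])
                   for _, row in att.iterrows()}
    ref = pio.read_fasta(os.path.join(outdir, "reference.fasta"))
    (ref_strain, ref_genome), = ref.items()
    variants = {}
    for strain in strains:
        path = os.path.join(outdir, "vcf", f"{strain}.vcf")
        variants[strain] = pio.read_vcf(path) if os.path.exists(path) else []
    return GenomeSet(strains=strains, layouts=layouts, proteins=proteins,
                     annotations=annotations, reference_strain=ref_strain,
                     reference_genome=ref_genome, variants=variants)


def read_ground_truth(outdir) -> dict:
    """Read the ground-truth TSVs back as plain structures."""
    outdir = str(outdir)
    clusters = pd.read_csv(os.path.join(outdir, "truth/clusters.tsv"),
                           sep="\t", dtype=str)
    fgis = pd.read_csv(os.path.join(outdir, "truth/fgis.tsv"), sep="\t",
                       dtype=str)
    with open(os.path.join(outdir, "truth/core_order.txt")) as fh:
        core_order = [line.strip() for line in fh if line.strip()]
    trunc = pd.read_csv(os.path.join(outdir, "truth/truncations.tsv"),
                        sep="\t")
    with open(os.path.join(outdir, "truth/is_elements.txt")) as fh:
        is_ids = [line.strip() for line in fh if line.strip()]
    return {
        "true_clusters": dict(zip(clusters["orf_id"], clusters["cluster_id"])),
        "true_core_order": core_order,
        "true_core_ids": set(core_order),
        "true_fgis": [
            TrueFgi(fgi_id=row["fgi_id"], left_anchor=row["left_anchor"],
                    right_anchor=row["right_anchor"],
                    members=tuple(row["members"].split(";")),
                    carriers=frozenset(row["carriers"].split(";")))
            for _, row in fgis.iterrows()],
        "true_is_ids": is_ids,
        "true_tree": StrainTree.read(os.path.join(outdir, "truth/tree.nwk")),
        "true_truncations": {
            (row["strain"], row["cluster_id"]): float(row["fraction_of_full"])
            for _, row in trunc.iterrows()},
    }
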