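"""End-to-end pipeline: simulate -> cluster -> rarefy -> assemble -> phylo
-> profile, with file-only contracts between stages.

Every stage consumes only on-disk outputs of earlier stages and writes its
own subdirectory, so steps can be toggled or rerun independently; one
global seed drives all stochastic steps through per-stage derived
sub-seeds, and rerunning with the same config reproduces byte-identical
outputs (the manifest lists every file with its SHA-256).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .assembly import build_pan_assembly, layout_heatmap
from .clustering import (Cluster, ClusterMember, ClusteringParams,
                         OrthologClusterSet, build_clusters,
                         classify_clusters, layout_from_att,
                         score_protein_pairs)
from .phylo import (VariantSet, group_strains, neighbor_joining,
                    snp_distance_matrix, apply_snps)
from .profiles import (FunctionMap, call_status, enzyme_strain_counts,
                       load_pathway_config, pathway_completeness,
                       subunit_set_completeness)
from .rarefaction import fit_exponential, openness_call, sample_curves
from .simulate import (GenomeSet, SimConfig, read_genome_set,
                       simulate_pangenome, simulate_tree, write_genome_set)
from .trees import StrainTree

__all__ = ["RunConfig", "run_all", "StageError", "DEFAULT_STEPS",
           "cluster_set_from_files"]

logger = logging.getLogger(__name__)

DEFAULT_STEPS = ["simulate", "cluster", "rarefy", "assemble", "phylo",
                 "profile"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial_manifest = manifest


@dataclass
class RunConfig:
    """One reproducible run.  The demo defaults describe a 12-strain,
    120-core-gene collection with 4 islands."""

    outdir: str
    seed: int = 0
    steps: list[str] = field(default_factory=lambda: list(DEFAULT_STEPS))
    simulate: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    rarefy: dict = field(default_factory=lambda: {"n_samples": 100})
    assemble: dict = field(default_factory=lambda: {"min_fgi_size": 3})
    phylo: dict = field(default_factory=lambda: {"k_groups": 2})
    profile: dict = field(default_factory=lambda: {"threshold": 0.9})

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"outdir", "seed", "steps", "simulate", "cluster", "rarefy",
                 "assemble", "phylo", "profile"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if outdir is not None:
            raw["outdir"] = outdir
        if seed is not None:
            raw["seed"] = seed
        if "outdir" not in raw:
            raise ValueError("config must define outdir")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        idx = DEFAULT_STEPS.index(stage)
        return int(np.random.SeedSequence([self.seed, idx])
                   .generate_state(1)[0] % (2 ** 31))


def cluster_set_from_files(cluster_dir) -> tuple[OrthologClusterSet, dict]:
    """Rebuild the cluster set and core/flexible classes from stage files."""
    members = pio.read_cluster_members(
        os.path.join(cluster_dir, "cluster_members.tsv"))
    strains = sorted(members["strain"].unique())
    clusters = []
    for cl_id, grp in members.groupby("cluster_id", sort=True):
        ms = [ClusterMember(orf_id=r["orf_id"], strain=r["strain"],
                            length_aa=int(r["length_aa"]),
                            percent_of_longest=float(r["percent_of_longest"]))
              for _, r in grp.iterrows()]
        centroid = grp[grp["is_centroid"] == 1]["orf_id"].iloc[0]
        clusters.append(Cluster(cluster_id=cl_id, members=ms,
                                centroid=centroid))
    cs = OrthologClusterSet(clusters=clusters, params=ClusteringParams(),
                            strains=strains)
    classes_path = os.path.join(cluster_dir, "cluster_classes.tsv")
    classes = {}
    if os.path.exists(classes_path):
        df = pd.read_csv(classes_path, sep="\t", dtype=str)
        classes = dict(zip(df["cluster_id"], df["class"]))
    return cs, classes


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: RunConfig, outdir: str) -> list[str]:
    params = dict(cfg.simulate)
    params.setdefault("seed", cfg.stage_seed("simulate"))
    sim = SimConfig(**params)
    tree = simulate_tree(sim.n_strains, sim.seed)
    gset, truth = simulate_pangenome(sim, tree)
    manifest = write_genome_set(gset, truth, outdir)
    logger.info("simulate: %d strains, %d ORFs total", len(gset.strains),
                len(gset.proteins))
    return manifest


def stage_cluster(cfg: RunConfig, sim_dir: str, outdir: str) -> list[str]:
    gset = read_genome_set(sim_dir)
    opts = dict(cfg.cluster)
    blast = opts.pop("external_table", None)
    params = ClusteringParams(**opts)
    matches = score_protein_pairs(
        gset, mode="external-table" if blast else "internal",
        external_table=blast,
        min_normalized_score=params.min_normalized_score)
    cs = build_clusters(matches, gset.layouts, params)
    classes = classify_clusters(cs)
    pio.ensure_dir(outdir)
    pio.write_matchtable(os.path.join(outdir, "matchtable.tsv"),
                         cs.clusters, cs.strains)
    pio.write_cluster_members(os.path.join(outdir, "cluster_members.tsv"),
                              cs.clusters)
    pd.DataFrame(sorted(classes.items()),
                 columns=["cluster_id", "class"]).to_csv(
        os.path.join(outdir, "cluster_classes.tsv"), sep="\t", index=False)
    pio.write_presence_matrix(os.path.join(outdir, "presence.tsv"),
                              cs.presence_matrix())
    logger.info("cluster: %d clusters (%d core)", len(cs.clusters),
                sum(1 for v in classes.values() if v == "core"))
    return ["matchtable.tsv", "cluster_members.tsv", "cluster_classes.tsv",
            "presence.tsv"]


def stage_rarefy(cfg: RunConfig, cluster_dir: str, outdir: str) -> list[str]:
    presence = pio.read_presence_matrix(
        os.path.join(cluster_dir, "presence.tsv"))
    opts = dict(cfg.rarefy)
    n_samples = int(opts.get("n_samples", 100))
    core_fraction = float(opts.get("core_fraction", 0.75))
    seed = int(opts.get("seed", cfg.stage_seed("rarefy")))
    res = sample_curves(presence, n_samples=n_samples, seed=seed,
                        core_fraction=core_fraction)
    pio.ensure_dir(outdir)
    res.to_frame().to_csv(os.path.join(outdir, "rarefaction.tsv"),
                          sep="\t", index=False)
    rows = []
    for name, medians in (("core", res.median_core), ("pan", res.median_pan)):
        fit = fit_exponential(medians)
        row = {"curve": name, "A": round(fit.A, 4), "B": round(fit.B, 4),
               "C": round(fit.C, 4), "rss": round(fit.rss, 4),
               "converged": fit.converged}
        if name == "pan":
            call = openness_call(fit, N=len(medians))
            row["openness"] = call.status
            row["new_genes_per_genome_at_N"] = round(call.rate_at_N, 4)
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "fits.tsv"), sep="\t",
                              index=False)
    files = ["rarefaction.tsv", "fits.tsv"]
    exclude = opts.get("exclude") or []
    subset_size = opts.get("subset_size")
    if exclude and subset_size:
        from .rarefaction import clade_exclusion_rerun
        pair = clade_exclusion_rerun(presence, exclude=set(exclude),
                                     n_samples=n_samples,
                                     subset_size=int(subset_size),
                                     seed=seed, core_fraction=core_fraction)
        pd.DataFrame([{
            "subset_size": pair.subset_size,
            "full_median_core": pair.full_core,
            "full_median_pan": pair.full_pan,
            "reduced_median_core": pair.reduced_core,
            "reduced_median_pan": pair.reduced_pan,
            "n_excluded": len(set(exclude)),
        }]).to_csv(os.path.join(outdir, "clade_exclusion.tsv"), sep="\t",
                   index=False)
        files.append("clade_exclusion.tsv")
    return files


def stage_assemble(cfg: RunConfig, sim_dir: str, cluster_dir: str,
                   outdir: str) -> list[str]:
    att = pio.read_att_table(os.path.join(sim_dir, "att.tsv"))
    strains = sorted(att["strain_tag"].unique())
    layouts = {s: layout_from_att(att, s) for s in strains}
    cs, classes = cluster_set_from_files(cluster_dir)
    core_ids = {c for c, k in classes.items() if k == "core"}
    opts = dict(cfg.assemble)
    assembly = build_pan_assembly(
        cs, layouts, core_ids,
        reference_strain=opts.get("reference_strain"),
        min_fgi_size=int(opts.get("min_fgi_size", 3)))
    pio.ensure_dir(outdir)
    pd.DataFrame({"position": range(1, len(assembly.core_order) + 1),
                  "cluster_id": assembly.core_order}).to_csv(
        os.path.join(outdir, "core_assembly.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "core_assembly_meta.tsv"), "w") as fh:
        fh.write("is_circular\t%s\n" % assembly.is_circular)
        fh.write("n_segments\t%d\n" % len(assembly.core.segment_starts))
    pd.DataFrame(
        [{"fgi_id": f.fgi_id, "left_anchor": f.left_anchor or "",
          "right_anchor": f.right_anchor or "",
          "n_members": len(f.members), "members": ";".join(f.members),
          "carriers": ";".join(sorted(f.carriers))}
         for f in assembly.fgis]).to_csv(
        os.path.join(outdir, "fgis.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"members": ";".join(d.members),
          "carriers": ";".join(sorted(d.carriers)), "reason": d.reason}
         for d in assembly.discarded_fgis],
        columns=["members", "carriers", "reason"]).to_csv(
        os.path.join(outdir, "discarded_fgis.tsv"), sep="\t", index=False)
    heat = layout_heatmap(assembly, cs, layouts)
    heat.values.round(4).to_csv(os.path.join(outdir, "heatmap.tsv"),
                                sep="\t", index_label="strain")
    heat.contig_break.astype(int).to_csv(
        os.path.join(outdir, "heatmap_contig_breaks.tsv"), sep="\t",
        index_label="strain")
    logger.info("assemble: %d core clusters (circular=%s), %d fGIs "
                "(%d discarded)", len(assembly.core_order),
                assembly.is_circular, len(assembly.fgis),
                len(assembly.discarded_fgis))
    return ["core_assembly.tsv", "core_assembly_meta.tsv", "fgis.tsv",
            "discarded_fgis.tsv", "heatmap.tsv", "heatmap_contig_breaks.tsv"]


def stage_phylo(cfg: RunConfig, sim_dir: str, outdir: str) -> list[str]:
    ref = pio.read_fasta(os.path.join(sim_dir, "reference.fasta"))
    (ref_strain, reference), = ref.items()
    vcf_dir = os.path.join(sim_dir, "vcf")
    pseudo = {}
    for fname in sorted(os.listdir(vcf_dir)):
        if not fname.endswith(".vcf"):
            continue
        strain = fname[:-4]
        vs = VariantSet(strain_tag=strain,
                        variants=pio.read_vcf(os.path.join(vcf_dir, fname)))
        pseudo[strain] = apply_snps(reference, vs)
    dm = snp_distance_matrix(pseudo)
    tree = neighbor_joining(dm)
    pio.ensure_dir(outdir)
    dm.to_phylip(os.path.join(outdir, "distances.phy"))
    tree.write(os.path.join(outdir, "nj_tree.nwk"))
    k = int(dict(cfg.phylo).get("k_groups", 2))
    groups = group_strains(tree, k)
    pd.DataFrame(sorted(groups.items()),
                 columns=["strain", "group"]).to_csv(
        os.path.join(outdir, "groups.tsv"), sep="\t", index=False)
    return ["distances.phy", "nj_tree.nwk", "groups.tsv"]


def stage_profile(cfg: RunConfig, sim_dir: str, cluster_dir: str,
                  phylo_dir: str | None, outdir: str) -> list[str]:
    att = pio.read_att_table(os.path.join(sim_dir, "att.tsv"))
    strains = sorted(att["strain_tag"].unique())
    layouts = {s: layout_from_att(att, s) for s in strains}
    cs, _classes = cluster_set_from_files(cluster_dir)
    annotations = {row["orf_id"]: ("" if pd.isna(row["annotation"])
                                   else row["annotation"])
                   for _, row in att.iterrows()}
    fmap = FunctionMap.from_annotations(cs, annotations)
    opts = dict(cfg.profile)
    pwcfg = load_pathway_config(opts.get("pathways"))
    sm = call_status(cs, fmap, layouts,
                     threshold=float(opts.get("threshold", 0.9)))
    # order rows by the NJ tree's leaves when a phylogeny is available
    tree_path = (os.path.join(phylo_dir, "nj_tree.nwk")
                 if phylo_dir else None)
    if tree_path and os.path.exists(tree_path):
        order = [lab for lab in
                 StrainTree.read(tree_path).leaf_labels if lab in sm.index]
        sm = sm.loc[order]
    pio.ensure_dir(outdir)
    sm.to_csv(os.path.join(outdir, "status.tsv"), sep="\t",
              index_label="strain")
    calls, caveat = pathway_completeness(sm, pwcfg.pathways,
                                         missing="absent")
    calls.to_csv(os.path.join(outdir, "pathway_completeness.tsv"), sep="\t",
                 index_label="strain")
    caveat.astype(int).to_csv(
        os.path.join(outdir, "pathway_contig_break_caveats.tsv"), sep="\t",
        index_label="strain")
    subunit_set_completeness(sm, pwcfg.subunit_systems,
                             missing="absent").to_csv(
        os.path.join(outdir, "subunit_completeness.tsv"), sep="\t",
        index_label="strain")
    enzyme_strain_counts(sm).round(4).to_csv(
        os.path.join(outdir, "enzyme_counts.tsv"), sep="\t")
    return ["status.tsv", "pathway_completeness.tsv",
            "pathway_contig_break_caveats.tsv", "subunit_completeness.tsv",
            "enzyme_counts.tsv"]


# ---------------------------------------------------------------- run_all

def run_all(cfg: RunConfig) -> dict:
    """Run the configured stages; returns (and writes) the manifest."""
    outdir = pio.ensure_dir(cfg.outdir)
    manifest: dict = {"seed": cfg.seed, "steps": [], "files": {}}
    subdir = {"simulate": "simulate", "cluster": "cluster",
              "rarefy": "rarefaction", "assemble": "assembly",
              "phylo": "phylogeny", "profile": "profile"}

    def record(stage: str, files: list[str]) -> None:
        manifest["steps"].append(stage)
        for rel in files:
            path = os.path.join(outdir, subdir[stage], rel)
            manifest["files"][os.path.join(subdir[stage], rel)] = \
                pio.sha256_of(path)

    def stage_dir(stage: str) -> str:
        return pio.ensure_dir(os.path.join(outdir, subdir[stage]))

    for stage in cfg.steps:
        if stage not in DEFAULT_STEPS:
            raise ValueError(f"unknown step {stage!r}")
        try:
            if stage == "simulate":
                files = stage_simulate(cfg, stage_dir(stage))
            elif stage == "cluster":
                files = stage_cluster(cfg, os.path.join(outdir, "simulate"),
                                      stage_dir(stage))
            elif stage == "rarefy":
                files = stage_rarefy(cfg, os.path.join(outdir, "cluster"),
                                     stage_dir(stage))
            elif stage == "assemble":
                files = stage_assemble(cfg, os.path.join(outdir, "simulate"),
                                       os.path.join(outdir, "cluster"),
                                       stage_dir(stage))
            elif stage == "phylo":
                files = stage_phylo(cfg, os.path.join(outdir, "simulate"),
                                    stage_dir(stage))
            elif stage == "profile":
                phylo_dir = os.path.join(outdir, "phylogeny")
                files = stage_profile(
                    cfg, os.path.join(outdir, "simulate"),
                    os.path.join(outdir, "cluster"),
                    phylo_dir if os.path.isdir(phylo_dir) else None,
                    stage_dir(stage))
        except Exception as exc:
            with open(os.path.join(outdir, "manifest.json"), "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
            raise StageError(stage, exc, manifest) from exc
        record(stage, files)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
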