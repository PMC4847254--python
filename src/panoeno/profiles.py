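"""Functional-ORF calling and pathway/subunit completeness profiling.

Each (strain, function) cell gets one status from the ordered lattice
``absent < contig_break < truncated < functional``:

* *functional* — some cluster member of that strain mapping to the
  function is strictly longer than ``threshold`` (default 0.9) times the
  function's reference length;
* *truncated* — members exist but none clears the length bar;
* *contig_break* — the best member sits at a contig edge, so its length
  (and hence its status) is unreliable;
* *absent* — no member in any mapped cluster.

Multi-gene capabilities are then assessed per strain: a biosynthesis
pathway is *complete* iff every required enzyme group has at least one
functional member; a multi-subunit transporter (PTS enzyme II) is
*complete* / *partial* / *absent* by how many of its subunits are
functional.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .clustering import GenomeLayout, OrthologClusterSet

__all__ = [
    "STATUS_ORDER", "FunctionMap", "PathwayDef", "SubunitSystem",
    "EnzymeSet", "PathwayConfig", "load_pathway_config", "call_status",
    "pathway_completeness", "subunit_set_completeness",
    "enzyme_strain_counts",
]

STATUS_ORDER = ["absent", "contig_break", "truncated", "functional"]
_RANK = {s: i for i, s in enumerate(STATUS_ORDER)}

HYPOTHETICAL = "hypothetical protein"


class ConfigError(ValueError):
    pass


# ----------------------------------------------------------------- inputs

@dataclass
class FunctionMap:
    """cluster id -> function ids, plus per-function reference lengths.

    ``reference_lengths`` defaults to the longest member across all
    clusters mapping to a function (``cluster-max`` source); user-supplied
    lengths override.
    """

    cluster_functions: dict[str, list[str]]
    reference_lengths: dict[str, int] = field(default_factory=dict)
    source: str = "cluster-max"

    def function_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for fns in self.cluster_functions.values():
            for fn in fns:
                seen.setdefault(fn, None)
        return list(seen)

    @classmethod
    def from_annotations(cls, cs: OrthologClusterSet,
                         orf_annotations: dict[str, str],
                         reference_lengths: dict[str, int] | None = None
                         ) -> "FunctionMap":
        """Derive the map from per-ORF annotation strings: any annotation
        other than 'hypothetical protein' (or empty) is taken as a
        function id carried by the member's cluster."""
        cf: dict[str, list[str]] = {}
        for cl in cs.clusters:
            fns: dict[str, None] = {}
            for m in cl.members:
                ann = (orf_annotations.get(m.orf_id) or "").strip()
                if ann and ann != HYPOTHETICAL:
                    fns.setdefault(ann, None)
            if fns:
                cf[cl.cluster_id] = list(fns)
        return cls(cluster_functions=cf,
                   reference_lengths=dict(reference_lengths or {}),
                   source="user-supplied" if reference_lengths else "cluster-max")

    @classmethod
    def read_tsv(cls, path) -> "FunctionMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cf: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            cf.setdefault(row["cluster_id"], []).append(row["function_id"])
        return cls(cluster_functions=cf)

    def write_tsv(self, path) -> None:
        rows = [{"cluster_id": cl, "function_id": fn}
                for cl in sorted(self.cluster_functions)
                for fn in self.cluster_functions[cl]]
        pd.DataFrame(rows, columns=["cluster_id", "function_id"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class PathwayDef:
    pathway_id: str
    label: str
    required: list[list[str]]     # groups; any member satisfies a group
    amino_acid: str = ""
    table: str = ""

    def __post_init__(self):
        if not self.required:
            raise ConfigError(f"pathway {self.pathway_id}: empty required list")


@dataclass
class SubunitSystem:
    system_id: str
    label: str
    subunits: list[str]


@dataclass
class EnzymeSet:
    set_id: str
    label: str
    functions: list[str]


@dataclass
class PathwayConfig:
    pathways: list[PathwayDef]
    subunit_systems: list[SubunitSystem]
    enzyme_sets: list[EnzymeSet]
    competence_genes: list[str]

    def all_function_ids(self) -> list[str]:
        """Every function id referenced anywhere, first-seen order."""
        seen: dict[str, None] = {}
        for pw in self.pathways:
            for group in pw.required:
                for fn in group:
                    seen.setdefault(fn, None)
        for sys_ in self.subunit_systems:
            for fn in sys_.subunits:
                seen.setdefault(fn, None)
        for es in self.enzyme_sets:
            for fn in es.functions:
                seen.setdefault(fn, None)
        for fn in self.competence_genes:
            seen.setdefault(fn, None)
        return list(seen)


def load_pathway_config(path=None) -> PathwayConfig:
    """Load a pathway-definition YAML; default is the shipped config."""
    if path is None:
        ref = importlib.resources.files("panoeno").joinpath("data/pathways.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    pathways = [PathwayDef(pathway_id=p["id"], label=p.get("label", p["id"]),
                           required=[list(g) for g in p["required"]],
                           amino_acid=p.get("amino_acid", ""),
                           table=p.get("table", ""))
                for p in raw.get("pathways", [])]
    systems = [SubunitSystem(system_id=s["id"], label=s.get("label", s["id"]),
                             subunits=list(s["subunits"]))
               for s in raw.get("subunit_systems", [])]
    esets = [EnzymeSet(set_id=e["id"], label=e.get("label", e["id"]),
                       functions=list(e["functions"]))
             for e in raw.get("enzyme_sets", [])]
    return PathwayConfig(pathways=pathways, subunit_systems=systems,
                         enzyme_sets=esets,
                         competence_genes=list(raw.get("competence_genes", [])))


# ----------------------------------------------------------------- status

def call_status(cs: OrthologClusterSet, fmap: FunctionMap,
                layouts: dict[str, GenomeLayout],
                threshold: float = 0.9) -> pd.DataFrame:
    """strain x function status matrix (best status wins per cell)."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    by_id = cs.by_id()
    functions = fmap.function_ids()
    # reference lengths
    ref_len: dict[str, int] = {}
    for fn in functions:
        if fn in fmap.reference_lengths:
            ref_len[fn] = int(fmap.reference_lengths[fn])
            continue
        longest = 0
        for cl_id, fns in fmap.cluster_functions.items():
            if fn in fns and cl_id in by_id:
                longest = max(longest,
                              max(m.length_aa for m in by_id[cl_id].members))
        if longest <= 0:
            raise ConfigError(f"no reference length derivable for function "
                              f"{fn}; supply one or map it to a cluster")
        ref_len[fn] = longest
    if fmap.source == "user-supplied":
        missing = [fn for fn in functions if fn not in fmap.reference_lengths]
        if missing:
            raise ConfigError(f"user-supplied reference lengths missing for: "
                              f"{missing[:5]}")
    strains = list(cs.strains)
    sm = pd.DataFrame("absent", index=strains, columns=functions)
    edge = {orf: lay.orf_meta[orf].at_contig_edge
            for lay in layouts.values() for orf in lay.orf_ids()}
    for cl_id, fns in fmap.cluster_functions.items():
        cl = by_id.get(cl_id)
        if cl is None:
            continue
        for fn in fns:
            bar = threshold * ref_len[fn]
            for m in cl.members:
                if edge.get(m.orf_id, False):
                    status = "contig_break"
                elif m.length_aa > bar:       # strictly greater than 90%
                    status = "functional"
                else:
                    status = "truncated"
                if _RANK[status] > _RANK[sm.at[m.strain, fn]]:
                    sm.at[m.strain, fn] = status
    return sm


def pathway_completeness(sm: pd.DataFrame, defs: list[PathwayDef],
                         missing: str = "error"
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strain pathway calls.

    Returns ``(calls, caveat)``: calls are ``complete``/``incomplete``;
    the caveat flag marks incomplete calls where some unsatisfied group's
    best status is ``contig_break`` (the call could flip if the break
    were resolved).  ``missing`` controls functions referenced by a
    definition but absent from the status matrix: ``error`` raises,
    ``absent`` treats them as absent.
    """
    strains = list(sm.index)
    calls = pd.DataFrame("incomplete", index=strains,
                         columns=[d.pathway_id for d in defs])
    caveat = pd.DataFrame(False, index=strains,
                          columns=[d.pathway_id for d in defs])
    for d in defs:
        for group in d.required:
            for fn in group:
                if fn not in sm.columns and missing == "error":
                    raise ConfigError(f"pathway {d.pathway_id} references "
                                      f"function {fn} not in status matrix")
        for strain in strains:
            complete = True
            broken = False
            for group in d.required:
                statuses = [sm.at[strain, fn] for fn in group
                            if fn in sm.columns] or ["absent"]
                best = max(statuses, key=lambda s: _RANK[s])
                if best != "functional":
                    complete = False
                    if best == "contig_break":
                        broken = True
            calls.at[strain, d.pathway_id] = ("complete" if complete
                                              else "incomplete")
            caveat.at[strain, d.pathway_id] = (not complete) and broken
    return calls, caveat


def subunit_set_completeness(sm: pd.DataFrame,
                             systems: list[SubunitSystem],
                             missing: str = "error") -> pd.DataFrame:
    """complete (all subunits functional) / partial (some) / absent (none)."""
    strains = list(sm.index)
    out = pd.DataFrame("absent", index=strains,
                       columns=[s.system_id for s in systems])
    for sys_ in systems:
        for fn in sys_.subunits:
            if fn not in sm.columns and missing == "error":
                raise ConfigError(f"system {sys_.system_id} references "
                                  f"function {fn} not in status matrix")
        for strain in strains:
            n_func = sum(1 for fn in sys_.subunits
                         if fn in sm.columns
                         and sm.at[strain, fn] == "functional")
            if n_func == len(sys_.subunits):
                out.at[strain, sys_.system_id] = "complete"
            elif n_func > 0:
                out.at[strain, sys_.system_id] = "partial"
    return out


def enzyme_strain_counts(sm: pd.DataFrame) -> pd.DataFrame:
    """Per function: count of strains with a functional copy, plus the
    square-root-scaled shading value used for relative display."""
    counts = (sm == "functional").sum(axis=0)
    return pd.DataFrame({
        "function_id": list(sm.columns),
        "n_strains_functional": [int(counts[fn]) for fn in sm.columns],
        "sqrt_shading": [math.sqrt(int(counts[fn])) for fn in sm.columns],
    }).set_index("function_id")
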