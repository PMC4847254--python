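"""Functional-ORF status calls and pathway/subunit completeness."""

from __future__ import annotations

import math

import pandas as pd
import pytest

import panoeno as p
from panoeno.profiles import (ConfigError, FunctionMap, PathwayDef,
                              SubunitSystem, load_pathway_config)
from conftest import make_genome_set, random_protein


def profile_fixture(rng, member_lengths: dict[str, int],
                    interior: bool = True):
    """One function F mapped to one cluster, one member per strain.

    ``interior=True`` pads each contig so the focal gene is never at a
    contig edge.
    """
    strains = {}
    assign = {}
    for strain, L in member_lengths.items():
        pad = [(f"{strain}_p{i}", random_protein(rng, 50)) for i in range(2)]
        focal = (f"{strain}_F", random_protein(rng, L))
        contig = [pad[0], focal, pad[1]] if interior else [focal] + pad
        strains[strain] = [contig]
        assign[focal[0]] = "CLF"
        for orf, _ in pad:
            assign[orf] = f"pad_{orf}"
    gset = make_genome_set(strains)
    from test_assembly import manual_cluster_set
    cs = manual_cluster_set(assign, gset)
    fmap = FunctionMap(cluster_functions={"CLF": ["F"]})
    return gset, cs, fmap


class TestCallStatus:
    def test_strictly_greater_than_threshold_is_functional(self, rng):
        gset, cs, fmap = profile_fixture(rng, {"s1": 100, "s2": 95,
                                               "s3": 90, "s4": 45})
        fmap.reference_lengths = {"F": 100}
        fmap.source = "user-supplied"
        sm = p.call_status(cs, fmap, gset.layouts, threshold=0.9)
        assert sm.at["s1", "F"] == "functional"
        assert sm.at["s2", "F"] == "functional"     # 95 > 90
        assert sm.at["s3", "F"] == "truncated"      # exactly 90% is not >90%
        assert sm.at["s4", "F"] == "truncated"

    def test_cluster_max_reference_defaults_to_longest_member(self, rng):
        gset, cs, fmap = profile_fixture(rng, {"s1": 120, "s2": 109})
        sm = p.call_status(cs, fmap, gset.layouts, threshold=0.9)
        assert sm.at["s1", "F"] == "functional"
        assert sm.at["s2", "F"] == "functional"     # 109 > 0.9*120 = 108
        gset2, cs2, fmap2 = profile_fixture(rng, {"s1": 120, "s2": 108})
        sm2 = p.call_status(cs2, fmap2, gset2.layouts, threshold=0.9)
        assert sm2.at["s2", "F"] == "truncated"

    def test_contig_edge_member_is_flagged_indeterminate(self, rng):
        gset, cs, fmap = profile_fixture(rng, {"s1": 100, "s2": 100},
                                         interior=False)
        sm = p.call_status(cs, fmap, gset.layouts)
        assert (sm["F"] == "contig_break").all()

    def test_best_status_wins_across_multiple_clusters(self, rng):
        gset, cs, fmap = profile_fixture(rng, {"s1": 100, "s2": 40})
        # map a second, truncated-only cluster to the same function
        fmap.cluster_functions["pad_s1_p0"] = ["F"]
        sm = p.call_status(cs, fmap, gset.layouts)
        assert sm.at["s1", "F"] == "functional"

    def test_unmapped_strain_is_absent(self, rng):
        gset, cs, fmap = profile_fixture(rng, {"s1": 100, "s2": 100})
        cl = cs.by_id()["CLF"]
        cl.members = [m for m in cl.members if m.strain != "s2"]
        sm = p.call_status(cs, fmap, gset.layouts)
        assert sm.at["s2", "F"] == "absent"

    def test_missing_reference_length_is_config_error(self, rng):
        gset, cs, fmap = profile_fixture(rng, {"s1": 100})
        fmap.cluster_functions["NO_SUCH_CLUSTER"] = ["orphan_fn"]
        with pytest.raises(ConfigError, match="orphan_fn"):
            p.call_status(cs, fmap, gset.layouts)

    def test_invalid_threshold_rejected(self, rng):
        gset, cs, fmap = profile_fixture(rng, {"s1": 100})
        with pytest.raises(ValueError):
            p.call_status(cs, fmap, gset.layouts, threshold=1.5)

    def test_lengthening_a_member_never_demotes_status(self, rng):
        order = []
        for L in (40, 80, 91, 100, 120):
            gset, cs, fmap = profile_fixture(rng, {"s1": 120, "s2": L})
            sm = p.call_status(cs, fmap, gset.layouts)
            order.append(sm.at["s2", "F"])
        ranks = [["absent", "contig_break", "truncated",
                  "functional"].index(s) for s in order]
        assert ranks == sorted(ranks)


def status_frame(data: dict[str, dict[str, str]]) -> pd.DataFrame:
    return pd.DataFrame(data).T


class TestPathwayCompleteness:
    def test_single_enzyme_pathway(self):
        sm = status_frame({"s1": {"K01915": "functional"},
                           "s2": {"K01915": "truncated"}})
        defs = [PathwayDef("gln", "Glutamate to Glutamine", [["K01915"]])]
        calls, caveat = p.pathway_completeness(sm, defs)
        assert calls.at["s1", "gln"] == "complete"
        assert calls.at["s2", "gln"] == "incomplete"
        assert not caveat.values.any()

    def test_truncated_kinase_breaks_threonine_pathway(self):
        defs = [PathwayDef("thr", "Aspartate to Threonine",
                           [["EC 2.7.2.4"], ["EC 2.7.1.39"]])]
        sm = status_frame({
            "ok": {"EC 2.7.2.4": "functional", "EC 2.7.1.39": "functional"},
            "aux": {"EC 2.7.2.4": "functional", "EC 2.7.1.39": "truncated"},
        })
        calls, _ = p.pathway_completeness(sm, defs)
        assert calls.at["ok", "thr"] == "complete"
        assert calls.at["aux", "thr"] == "incomplete"

    def test_alternative_enzymes_satisfy_a_group(self):
        defs = [PathwayDef("lys", "Aspartate to Lysine",
                           [["M00016", "M00525"]])]
        sm = status_frame({"s1": {"M00016": "absent", "M00525": "functional"}})
        calls, _ = p.pathway_completeness(sm, defs)
        assert calls.at["s1", "lys"] == "complete"

    def test_empty_strain_incomplete_everywhere(self):
        cfg = load_pathway_config()
        sm = pd.DataFrame("absent", index=["empty"],
                          columns=cfg.all_function_ids())
        calls, _ = p.pathway_completeness(sm, cfg.pathways)
        assert (calls.loc["empty"] == "incomplete").all()

    def test_contig_break_propagates_as_caveat_not_functional(self):
        defs = [PathwayDef("pw", "PW", [["f1"], ["f2"]])]
        sm = status_frame({"s1": {"f1": "functional", "f2": "contig_break"}})
        calls, caveat = p.pathway_completeness(sm, defs)
        assert calls.at["s1", "pw"] == "incomplete"
        assert bool(caveat.at["s1", "pw"])

    def test_missing_function_errors_unless_allowed(self):
        defs = [PathwayDef("pw", "PW", [["nowhere"]])]
        sm = status_frame({"s1": {"f1": "functional"}})
        with pytest.raises(ConfigError):
            p.pathway_completeness(sm, defs)
        calls, _ = p.pathway_completeness(sm, defs, missing="absent")
        assert calls.at["s1", "pw"] == "incomplete"


class TestSubunits:
    SYS = [SubunitSystem("pts_asc", "Ascorbate PTS II",
                         ["IIA", "IIB", "IIC"])]

    def test_missing_one_subunit_is_partial(self):
        sm = status_frame({"s1": {"IIA": "functional", "IIB": "absent",
                                  "IIC": "functional"}})
        out = p.subunit_set_completeness(sm, self.SYS)
        assert out.at["s1", "pts_asc"] == "partial"

    def test_all_subunits_functional_is_complete(self):
        sm = status_frame({"s1": {"IIA": "functional", "IIB": "functional",
                                  "IIC": "functional"}})
        assert p.subunit_set_completeness(sm, self.SYS).at[
            "s1", "pts_asc"] == "complete"

    def test_none_present_is_absent(self):
        sm = status_frame({"s1": {"IIA": "absent", "IIB": "absent",
                                  "IIC": "absent"}})
        assert p.subunit_set_completeness(sm, self.SYS).at[
            "s1", "pts_asc"] == "absent"


class TestEnzymeCounts:
    def test_counts_and_square_root_shading(self):
        sm = status_frame({
            f"s{i}": {"e4": "functional" if i < 4 else "absent",
                      "e16": "functional",
                      "e0": "truncated"}
            for i in range(16)})
        counts = p.enzyme_strain_counts(sm)
        assert counts.at["e0", "n_strains_functional"] == 0
        assert counts.at["e4", "n_strains_functional"] == 4
        assert counts.at["e16", "n_strains_functional"] == 16
        assert counts.at["e16", "sqrt_shading"] == pytest.approx(
            2 * counts.at["e4", "sqrt_shading"])

    def test_counts_equal_clade_sizes_on_simulation(self, demo_sim):
        _, _, gset, truth = demo_sim
        from panoeno.simulate import cluster_set_from_truth
        cs = cluster_set_from_truth(gset, truth)
        # plant one function on each island's first member cluster
        fmap = FunctionMap(cluster_functions={
            tf.members[0]: [f"fgi_fn_{i}"]
            for i, tf in enumerate(truth.true_fgis)})
        sm = p.call_status(cs, fmap, gset.layouts)
        counts = p.enzyme_strain_counts(sm)
        for i, tf in enumerate(truth.true_fgis):
            by_id = cs.by_id()[tf.members[0]]
            edge_members = sum(
                1 for m in by_id.members
                if gset.layouts[m.strain].orf_meta[m.orf_id].at_contig_edge)
            functional = counts.at[f"fgi_fn_{i}", "n_strains_functional"]
            # carriers minus any contig-edge (indeterminate) members
            assert functional >= len(tf.carriers) - edge_members
            assert functional <= len(tf.carriers)


class TestShippedConfig:
    def test_loads_and_references_are_consistent(self):
        cfg = load_pathway_config()
        assert len(cfg.pathways) == 23
        assert all(pw.required for pw in cfg.pathways)
        fns = cfg.all_function_ids()
        assert "K14454" in fns
        assert "K014454" not in fns        # corrected identifier
        aspartate = [pw for pw in cfg.pathways
                     if pw.amino_acid == "Aspartate"]
        assert len(aspartate) == 4          # one conversion + three routes
        assert {s.system_id for s in cfg.subunit_systems} >= {
            "pts_mannose", "pts_fructose", "pts_ascorbate", "pts_sucrose"}
        assert {e.set_id for e in cfg.enzyme_sets} == {
            "xylose", "arabinose", "xylulose"}
        assert cfg.competence_genes == ["ComEA", "ComEC", "ComGC",
                                        "ComFA", "ComG"]
        arab = next(e for e in cfg.enzyme_sets if e.set_id == "arabinose")
        assert "EC 2.7.1.16" in arab.functions
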