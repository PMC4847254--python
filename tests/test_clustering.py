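"""Ortholog clustering: scoring, neighborhood, greedy merge and oracle."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Align import substitution_matrices

import panoeno as p
from panoeno.clustering import (ClusteringParams, MatchTable,
                                exhaustive_best_partition)
from conftest import make_genome_set, random_protein

B62 = substitution_matrices.load("BLOSUM62")


def gotoh_local(a: str, b: str, gap_open: int = 11, gap_ext: int = 1):
    """Independent Smith-Waterman/Gotoh oracle.

    BLAST-style affine costs: a gap of length L costs gap_open + L*gap_ext.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)   # gap in b (vertical)
    Y = np.full((n + 1, m + 1), NEG)   # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i, j] = max(M[i - 1, j] - gap_open - gap_ext,
                          X[i - 1, j] - gap_ext)
            Y[i, j] = max(M[i, j - 1] - gap_open - gap_ext,
                          Y[i, j - 1] - gap_ext)
            s = B62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], X[i - 1, j - 1],
                                       Y[i - 1, j - 1]))
            best = max(best, M[i, j], X[i, j], Y[i, j])
    return best


def two_strain_set(order_a, order_b, seqs):
    return make_genome_set({
        "sA": [[(f"sA_{name}", seqs[name]) for name in order_a]],
        "sB": [[(f"sB_{name}", seqs[name]) for name in order_b]],
    })


@pytest.fixture(scope="module")
def synteny_pair(rng):
    """Two strains with identical 8-gene layouts."""
    names = [f"g{i}" for i in range(8)]
    seqs = {n: random_protein(rng, 120) for n in names}
    gset = two_strain_set(names, names, seqs)
    matches = p.score_protein_pairs(gset)
    return gset, matches


class TestScoring:
    def test_identical_sequences_normalize_to_one(self, synteny_pair):
        _, matches = synteny_pair
        for i in range(8):
            assert matches.normalized(f"sA_g{i}", f"sB_g{i}") == 1.0

    def test_scores_match_independent_alignment_oracle(self, rng):
        aligner_scores = []
        for _ in range(5):
            a = random_protein(rng, 40)
            b = list(a)
            for pos in rng.choice(40, size=8, replace=False):
                b[pos] = random_protein(rng, 1)
            b = "".join(b)
            seqs = {"x": a, "y": b}
            gset = two_strain_set(["x", "y"], ["x", "y"], seqs)
            matches = p.score_protein_pairs(gset, min_normalized_score=0.0,
                                            min_shared_kmers=1)
            raw, _ = matches.entries[("sA_x", "sB_y")]
            assert raw == pytest.approx(gotoh_local(a, b))
            aligner_scores.append(raw)
        assert aligner_scores

    def test_unrelated_and_reversed_sequences_fall_below_threshold(self, rng):
        a = random_protein(rng, 60)
        seqs = {"fwd": a, "rev": a[::-1], "rand": random_protein(rng, 60)}
        gset = make_genome_set({
            "sA": [[("sA_fwd", seqs["fwd"])]],
            "sB": [[("sB_rev", seqs["rev"]), ("sB_rand", seqs["rand"])]],
        })
        matches = p.score_protein_pairs(gset, min_normalized_score=0.0,
                                        min_shared_kmers=1)
        self_score = matches.entries[("sA_fwd", "sA_fwd")][0]
        for other in ("sB_rev", "sB_rand"):
            entry = matches.entries.get(("sA_fwd", other))
            norm = entry[1] if entry else 0.0
            assert norm < 0.35
            if entry:
                assert entry[0] == pytest.approx(
                    gotoh_local(seqs["fwd"], seqs[other[3:]]))
            assert self_score > 0

    def test_empty_second_genome_yields_no_cross_entries(self, rng):
        gset = make_genome_set({
            "sA": [[("sA_g0", random_protein(rng, 50))]],
            "sB": [],
        })
        matches = p.score_protein_pairs(gset)
        assert all(a == b for (a, b) in matches.entries)

    def test_prefix_truncation_scores_one(self, rng):
        a = random_protein(rng, 150)
        gset = two_strain_set(["x"], ["x"], {"x": a})
        gset.proteins["sB_x"] = a[:50]
        gset.layouts["sB"].orf_meta["sB_x"] = \
            gset.layouts["sB"].orf_meta["sB_x"].__class__(
                **{**gset.layouts["sB"].orf_meta["sB_x"].__dict__,
                   "length_aa": 50})
        matches = p.score_protein_pairs(gset)
        assert matches.normalized("sA_x", "sB_x") == 1.0

    def test_external_table_round_trip(self, synteny_pair, tmp_path):
        gset, internal = synteny_pair
        rows = []
        for (a, b), (raw, _) in internal.entries.items():
            rows.append(f"{a}\t{b}\t100.0\t120\t0\t0\t1\t120\t1\t120"
                        f"\t1e-50\t{raw}")
        table = tmp_path / "blast.tsv"
        table.write_text("\n".join(rows) + "\n")
        ext = p.score_protein_pairs(gset, mode="external-table",
                                    external_table=table)
        for i in range(8):
            assert ext.normalized(f"sA_g{i}", f"sB_g{i}") == 1.0

    def test_malformed_external_table_names_line(self, synteny_pair,
                                                 tmp_path):
        gset, _ = synteny_pair
        bad = tmp_path / "bad.tsv"
        bad.write_text("a\tb\tnot-enough-columns\n")
        from panoeno.io import ParseError
        with pytest.raises(ParseError, match="line 1"):
            p.score_protein_pairs(gset, mode="external-table",
                                  external_table=bad)


class TestNeighborhood:
    def test_perfect_synteny_scores_one(self, synteny_pair):
        gset, matches = synteny_pair
        assert p.neighborhood_score("sA_g4", "sB_g4", gset.layouts,
                                    matches, window=2) == 1.0

    def test_identical_is_protein_in_novel_context_scores_zero(self, rng):
        names = [f"g{i}" for i in range(9)]
        seqs = {n: random_protein(rng, 110) for n in names}
        seqs["IS"] = random_protein(rng, 110)
        order_a = names[:4] + ["IS"] + names[4:]
        order_b = names[:8] + ["IS"] + names[8:]
        gset = two_strain_set(order_a, order_b, seqs)
        matches = p.score_protein_pairs(gset)
        assert matches.normalized("sA_IS", "sB_IS") == 1.0
        assert p.neighborhood_score("sA_IS", "sB_IS", gset.layouts,
                                    matches, window=2) == 0.0

    def test_single_shared_flank_of_four_comparable_positions(self, rng):
        # window=2 around interior genes: 4 comparable positions, exactly
        # one of which (the immediate left neighbor) is shared
        shared = {f"c{i}": random_protein(rng, 110) for i in range(3)}
        only_a = {f"a{i}": random_protein(rng, 110) for i in range(4)}
        only_b = {f"b{i}": random_protein(rng, 110) for i in range(4)}
        seqs = {**shared, **only_a, **only_b}
        order_a = ["a0", "a1", "c0", "c1", "a2", "a3"]
        order_b = ["b0", "b1", "c0", "c1", "b2", "b3"]
        gset = two_strain_set(order_a, order_b, seqs)
        matches = p.score_protein_pairs(gset)
        # focal pair: c1 in both strains; flanks at -2,-1,+1,+2 are
        # (a1, c0, a2, a3) vs (b1, c0, b2, b3) -> only -1 matches
        assert p.neighborhood_score("sA_c1", "sB_c1", gset.layouts,
                                    matches, window=2) == 0.25

    def test_symmetric_under_swapping_for_reciprocal_best_matches(
            self, synteny_pair):
        gset, matches = synteny_pair
        for i in range(8):
            ab = p.neighborhood_score(f"sA_g{i}", f"sB_g{i}", gset.layouts,
                                      matches, window=3)
            ba = p.neighborhood_score(f"sB_g{i}", f"sA_g{i}", gset.layouts,
                                      matches, window=3)
            assert ab == ba

    def test_contig_edges_reduce_denominator_not_score(self, synteny_pair):
        gset, matches = synteny_pair
        # first gene has no left flank at all; right flank fully matches
        assert p.neighborhood_score("sA_g0", "sB_g0", gset.layouts,
                                    matches, window=3) == 1.0


class TestBuildClusters:
    def test_toy_families_recovered_exactly(self, rng):
        fams = {f"f{i}": random_protein(rng, 130) for i in range(5)}
        order = list(fams)
        gset = make_genome_set({
            s: [[(f"{s}_{name}", fams[name]) for name in order]]
            for s in ("s1", "s2", "s3")})
        matches = p.score_protein_pairs(gset)
        cs = p.build_clusters(matches, gset.layouts)
        assert len(cs.clusters) == 5
        expected = {frozenset({f"s1_{n}", f"s2_{n}", f"s3_{n}"})
                    for n in order}
        assert cs.partition() == expected
        assert exhaustive_best_partition(matches, gset.layouts) == expected

    def test_lambda_splits_identical_is_contexts(self, rng):
        names = [f"g{i}" for i in range(10)]
        seqs = {n: random_protein(rng, 110) for n in names}
        seqs["IS"] = random_protein(rng, 110)
        gset = two_strain_set(names[:5] + ["IS"] + names[5:],
                              ["IS"] + names, seqs)
        matches = p.score_protein_pairs(gset)
        with_cgn = p.build_clusters(
            matches, gset.layouts,
            ClusteringParams(neighborhood_weight=1.0))
        assert {frozenset({"sA_IS"}), frozenset({"sB_IS"})} <= \
            with_cgn.partition()
        without = p.build_clusters(
            matches, gset.layouts,
            ClusteringParams(neighborhood_weight=0.0))
        assert frozenset({"sA_IS", "sB_IS"}) in without.partition()

    def test_single_strain_gives_all_singletons(self, rng):
        gset = make_genome_set({
            "solo": [[(f"solo_g{i}", random_protein(rng, 80))
                      for i in range(6)]]})
        strain_of = {o: "solo" for o in gset.layouts["solo"].orf_ids()}
        matches = MatchTable(entries={(o, o): (1.0, 1.0) for o in strain_of},
                             strain_of=strain_of)
        cs = p.build_clusters(matches, gset.layouts)
        assert len(cs.clusters) == 6
        assert all(cl.size == 1 for cl in cs.clusters)

    def test_partition_and_percent_invariants(self, demo_sim):
        _, _, gset, _ = demo_sim
        matches = p.score_protein_pairs(gset)
        cs = p.build_clusters(matches, gset.layouts)
        all_orfs = sorted(o for lay in gset.layouts.values()
                          for o in lay.orf_ids())
        members = sorted(m.orf_id for cl in cs.clusters
                         for m in cl.members)
        assert members == all_orfs                   # partition property
        for cl in cs.clusters:
            strains = [m.strain for m in cl.members]
            assert len(strains) == len(set(strains))  # <=1 per strain
            assert max(m.percent_of_longest for m in cl.members) == 100.0
            assert cl.centroid in {m.orf_id for m in cl.members}

    def test_universe_mismatch_rejected(self, synteny_pair):
        gset, matches = synteny_pair
        layouts = dict(gset.layouts)
        layouts.pop("sB")
        with pytest.raises(ValueError, match="input-mismatch"):
            p.build_clusters(matches, layouts)


class TestClassifyClusters:
    @staticmethod
    def _fake_cluster_set(strain_counts):
        from panoeno.clustering import Cluster, ClusterMember
        clusters = []
        for idx, count in enumerate(strain_counts, start=1):
            members = [ClusterMember(orf_id=f"s{j:03d}_o{idx}",
                                     strain=f"s{j:03d}", length_aa=100,
                                     percent_of_longest=100.0)
                       for j in range(count)]
            clusters.append(Cluster(cluster_id=f"CL_{idx:05d}",
                                    members=members,
                                    centroid=members[0].orf_id))
        return p.OrthologClusterSet(
            clusters=clusters, params=ClusteringParams(),
            strains=[f"s{j:03d}" for j in range(max(strain_counts))])

    def test_75_percent_ceiling_on_191_strains(self):
        cs = self._fake_cluster_set([191, 144, 143])
        classes = p.classify_clusters(cs, n_strains=191, core_fraction=0.75)
        # ceil(0.75*191) = 144: 191 and 144 are core, 143 is flexible
        assert classes["CL_00001"] == "core"
        assert classes["CL_00002"] == "core"
        assert classes["CL_00003"] == "flexible"

    def test_strict_core_excludes_any_absence(self):
        cs = self._fake_cluster_set([20, 19])
        classes = p.classify_clusters(cs, n_strains=20, core_fraction=1.0)
        assert classes["CL_00001"] == "core"
        assert classes["CL_00002"] == "flexible"


class TestOracle:
    def test_greedy_matches_exhaustive_on_small_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            n = int(rng.integers(3, 5))
            tree = p.simulate_tree(n, int(rng.integers(2 ** 31)))
            cfg = p.SimConfig(
                n_strains=n, n_core_genes=int(rng.integers(10, 14)),
                n_fgis=int(rng.integers(0, 2)), fgi_size_range=(3, 4),
                truncation_rate=0.05,
                is_element_copies=int(rng.integers(0, 3)),
                contig_break_rate=1.0, seed=int(rng.integers(2 ** 31)))
            gset, _ = p.simulate_pangenome(cfg, tree)
            matches = p.score_protein_pairs(gset)
            greedy = p.build_clusters(matches, gset.layouts).partition()
            assert greedy == exhaustive_best_partition(matches, gset.layouts)

    def test_component_guard(self, rng):
        seq = random_protein(rng, 100)
        gset = make_genome_set({
            f"s{i}": [[(f"s{i}_g{j}", seq) for j in range(4)]]
            for i in range(4)})
        matches = p.score_protein_pairs(gset)
        with pytest.raises(ValueError, match="guard"):
            exhaustive_best_partition(matches, gset.layouts,
                                      max_component=4)
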