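"""Shared fixtures and builders for hand-constructed genome sets."""

from __future__ import annotations

import numpy as np
import pytest

from panoeno.clustering import GenomeLayout, OrfMeta
from panoeno.simulate import GenomeSet


def make_genome_set(strains: dict[str, list[list[tuple[str, str]]]]
                    ) -> GenomeSet:
    """Build a GenomeSet from explicit layouts.

    ``strains`` maps strain tag -> list of contigs, each contig a list of
    (orf_id, protein sequence) in gene order.
    """
    layouts = {}
    proteins = {}
    annotations = {}
    for strain, contigs in strains.items():
        cdict: dict[str, list[str]] = {}
        meta: dict[str, OrfMeta] = {}
        for ci, contig in enumerate(contigs):
            contig_id = f"{strain}_ctg{ci + 1:02d}"
            orf_ids = []
            cursor = 1
            for idx, (orf_id, seq) in enumerate(contig):
                nt_len = 3 * (len(seq) + 1)
                meta[orf_id] = OrfMeta(
                    contig=contig_id, index=idx, start=cursor,
                    end=cursor + nt_len - 1, strand="+",
                    length_aa=len(seq),
                    at_contig_edge=(idx == 0 or idx == len(contig) - 1))
                cursor += nt_len + 100
                orf_ids.append(orf_id)
                proteins[orf_id] = seq
                annotations[orf_id] = "hypothetical protein"
            cdict[contig_id] = orf_ids
        layouts[strain] = GenomeLayout(strain_tag=strain, contigs=cdict,
                                       orf_meta=meta)
    return GenomeSet(strains=sorted(strains), layouts=layouts,
                     proteins=proteins, annotations=annotations)


def random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160427)


@pytest.fixture(scope="session")
def demo_sim():
    """One 12-strain demonstration simulation, shared across tests."""
    import panoeno as p
    tree = p.simulate_tree(12, 5)
    cfg = p.SimConfig(seed=5)
    gset, truth = p.simulate_pangenome(cfg, tree)
    return cfg, tree, gset, truth
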