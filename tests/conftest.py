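"""Shared fixtures: tiny hand-built genomes and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from gnnpred import Contig, GeneRecord, GenomeAnnotation, SimConfig, simulate


def make_genome(
    genome_id: str,
    families_per_gene,
    circular: bool = False,
    phylum: str = "Phylum_T",
    contig_id: str | None = None,
):
    """Build a one-contig genome from a list of per-gene family collections.

    Each entry is an iterable of family ids (empty for unannotated genes).
    Protein ids are ``{genome_id}_p{ordinal}``.
    """
    contig_id = contig_id or f"{genome_id}_c1"
    genes = [
        GeneRecord(
            genome_id=genome_id,
            contig_id=contig_id,
            ordinal=i,
            strand="+",
            protein_id=f"{genome_id}_p{i}",
            family_ids=frozenset(fams),
        )
        for i, fams in enumerate(families_per_gene)
    ]
    return GenomeAnnotation(
        genome_id=genome_id,
        phylum=phylum,
        contigs=[Contig(contig_id=contig_id, genes=genes, circular=circular)],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240911)


@pytest.fixture(scope="session")
def small_sim():
    """A 50-genome synthetic pangenome used by several oracle tests."""
    cfg = SimConfig(
        n_genomes=50,
        n_phyla=5,
        genes_per_genome=150,
        n_complex_pairs=5,
        n_background_families=150,
        adjacency_prob=0.8,
        dispersal_window=4,
        rearrangement_rate=0.05,
        seed=4242,
    )
    genomes, truth, sims = simulate(cfg)
    return cfg, genomes, truth, sims
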