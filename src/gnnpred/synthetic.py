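"""Synthetic prokaryotic pangenomes with known interaction ground truth.

The generator emulates the evolutionary regime that makes neighborhood-
based partner prediction work — and the confounders that break it:

* genomes grouped into phyla, each phylum sharing a base gene order that
  individual genomes perturb at a configurable rearrangement rate
  (background gene-order divergence across, cohesion within, phyla);
* true hetero-dimer pairs encoded operon-like: adjacent with probability
  ``adjacency_prob``, otherwise a few genes apart, while a fraction
  ``p_far`` of pairs is *dispersed* — the partners sit half a replicon
  apart in every genome carrying them (the anthranilate-synthase
  pattern: a pair-level property, which is what caps achievable recall);
* a conserved monomer decoy gene sitting between the partners
  (``decoy_insert_prob``; the HisH–HisA–HisF motif);
* a second complex co-encoded in the same block upstream of the query
  (``cocluster_prob``; the Sox motif that produces false positives);
* whole-block horizontal transfer into random genomes
  (``hgt_block_prob``).

Family accessions are synthesized in Pfam style (PF9xxxx subunits,
PF8xxxx decoys, PF7xxxx co-cluster complexes, PF1xxxx background) so the
real parsers are exercised. Member-level similarities are emitted
directly by default (within-family ~90% identity, cross-family ~10%);
an optional mode evolves amino-acid sequences from per-family ancestors
and aligns them, exercising the alignment path end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .evaluation import GoldPair
from .genome_model import Contig, GeneRecord, GenomeAnnotation
from .ssn import SimilarityEdge, pairwise_identity

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

# genes inserted per pair and genome, at most: two co-cluster genes,
# subunit 1, decoy, subunit 2
_MAX_BLOCK = 5


@dataclass
class SimConfig:
    """Parameters of one synthetic pangenome.

    Defaults describe the benchmark conditions used throughout: 300
    genomes from 20 phyla, 30 hetero-dimer pairs, strong (90%) operon-like
    adjacency, no confounders, mild (5%) per-genome rearrangement.
    """

    n_genomes: int = 300
    n_phyla: int = 20
    genes_per_genome: int = 400
    n_complex_pairs: int = 30
    n_background_families: int = 400
    adjacency_prob: float = 0.9
    dispersal_window: int = 5
    p_far: float = 0.0
    decoy_insert_prob: float = 0.0
    cocluster_prob: float = 0.0
    rearrangement_rate: float = 0.05
    hgt_block_prob: float = 0.0
    seed: int = 0
    circular: bool = True
    emit_sequences: bool = False
    sequence_length: int = 120
    mutation_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "adjacency_prob",
            "p_far",
            "decoy_insert_prob",
            "cocluster_prob",
            "rearrangement_rate",
            "hgt_block_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_phyla > self.n_genomes:
            raise ConfigError("n_phyla must not exceed n_genomes")
        if min(self.n_genomes, self.n_phyla, self.n_complex_pairs,
               self.n_background_families, self.genes_per_genome) < 1:
            raise ConfigError("counts must be positive")
        if self.dispersal_window < 1:
            raise ConfigError("dispersal_window must be >= 1")
        if self.n_background_slots < max(50, 2 * self.dispersal_window + 4):
            raise ConfigError(
                f"genes_per_genome={self.genes_per_genome} is too small for "
                f"{self.n_complex_pairs} complex blocks"
            )

    @property
    def n_background_slots(self) -> int:
        return self.genes_per_genome - _MAX_BLOCK * self.n_complex_pairs


@dataclass
class Placement:
    """Realized gene distance of one pair in one genome (final layout)."""

    genome_id: str
    complex_id: str
    distance: int
    kind: str  # adjacent | dispersed | far


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic pangenome."""

    gold_pairs: list[GoldPair]
    placements: list[Placement]
    decoy_families: frozenset[str]
    sequences: dict[str, str] | None = None


def _pair_families(i: int) -> tuple[str, str, str, str, str]:
    """(su1, su2, decoy, companion1, companion2) accessions of pair i."""
    return (
        f"PF{90000 + 2 * i}",
        f"PF{90001 + 2 * i}",
        f"PF{80000 + i}",
        f"PF{70000 + 2 * i}",
        f"PF{70001 + 2 * i}",
    )


def simulate(config: SimConfig) -> tuple[list[GenomeAnnotation], SyntheticTruth, list[SimilarityEdge]]:
    """Generate genomes, ground truth and a member-level similarity table.

    Deterministic given ``config.seed``. Placement distances are measured
    from the final gene layout, so they recount exactly from the emitted
    gene tables.
    """
    rng = np.random.default_rng(config.seed)
    n_pairs = config.n_complex_pairs
    B = config.n_background_slots
    bg_families = np.array([f"PF{10000 + j}" for j in range(config.n_background_families)])
    pair_fams = [_pair_families(i) for i in range(n_pairs)]
    gold_pairs = [
        GoldPair(
            complex_id=f"CPX{i:04d}",
            su1_families=frozenset({pf[0]}),
            su2_families=frozenset({pf[1]}),
        )
        for i, pf in enumerate(pair_fams)
    ]

    # pair-level dispersal: a "far" pair sits on a distant locus in every genome
    far_pair = rng.random(n_pairs) < config.p_far

    # phylum-cohesive structure: shared background order and block anchors
    base_orders = [rng.choice(bg_families, size=B) for _ in range(config.n_phyla)]
    anchors = rng.integers(0, B, size=(config.n_phyla, n_pairs))

    genomes: list[GenomeAnnotation] = []
    placements: list[Placement] = []
    for g in range(config.n_genomes):
        genome_id = f"G{g:04d}"
        phylum_idx = g % config.n_phyla
        phylum = f"Phylum_{phylum_idx:02d}"

        order = base_orders[phylum_idx].copy()
        n_shuffled = rng.binomial(B, config.rearrangement_rate)
        if n_shuffled > 1:
            idx = rng.choice(B, size=n_shuffled, replace=False)
            order[idx] = order[idx[rng.permutation(n_shuffled)]]
        strands = np.where(rng.random(B) < 0.5, "+", "-")

        # atomic segments: complex blocks are inserted between segments and
        # can therefore never be split by later insertions
        segments: list[list[tuple[str, str]]] = [
            [(fam, strand)] for fam, strand in zip(order, strands)
        ]
        kinds: dict[int, str] = {}
        for i, (su1, su2, decoy, c1, c2) in enumerate(pair_fams):
            decoy_on = rng.random() < config.decoy_insert_prob
            cocluster_on = rng.random() < config.cocluster_prob
            head = [(c1, "+"), (c2, "+")] if cocluster_on else []
            head += [(su1, "+")]
            if decoy_on:
                head += [(decoy, "+")]
            ins = min(int(anchors[phylum_idx, i]), len(segments))
            if far_pair[i]:
                kinds[i] = "far"
                segments.insert(ins, head)
                jns = (ins + len(segments) // 2) % (len(segments) + 1)
                segments.insert(jns, [(su2, "+")])
            else:
                adjacent = rng.random() < config.adjacency_prob
                if adjacent:
                    kinds[i] = "adjacent"
                    segments.insert(ins, head + [(su2, "+")])
                else:
                    kinds[i] = "dispersed"
                    d = 2 + int(rng.integers(0, config.dispersal_window))
                    gap = d - 1 - (1 if decoy_on else 0)
                    # absorb the intervening genes into the atomic block so a
                    # later insertion can never stretch the realized distance
                    block = list(head)
                    filled = 0
                    while ins < len(segments) and filled + len(segments[ins]) <= gap:
                        seg = segments.pop(ins)
                        block.extend(seg)
                        filled += len(seg)
                    block.append((su2, "+"))
                    segments.insert(ins, block)
            if config.hgt_block_prob and rng.random() < config.hgt_block_prob:
                hgt_at = int(rng.integers(0, len(segments) + 1))
                segments.insert(hgt_at, [(su1, "+"), (su2, "+")])

        flat = [gene for seg in segments for gene in seg]
        genes = [
            GeneRecord(
                genome_id=genome_id,
                contig_id=f"{genome_id}_c1",
                ordinal=pos,
                strand=strand,
                protein_id=f"{genome_id}_{pos:05d}",
                family_ids=frozenset({fam}),
            )
            for pos, (fam, strand) in enumerate(flat)
        ]
        genomes.append(
            GenomeAnnotation(
                genome_id=genome_id,
                phylum=phylum,
                contigs=[Contig(contig_id=f"{genome_id}_c1", genes=genes, circular=config.circular)],
            )
        )

        # realized distances from the final layout
        length = len(flat)
        positions: dict[str, list[int]] = {}
        for pos, (fam, _s) in enumerate(flat):
            positions.setdefault(fam, []).append(pos)
        for i, (su1, su2, _d, _c1, _c2) in enumerate(pair_fams):
            dists = []
            for a in positions.get(su1, ()):
                for b in positions.get(su2, ()):
                    delta = abs(a - b)
                    dists.append(min(delta, length - delta) if config.circular else delta)
            placements.append(
                Placement(
                    genome_id=genome_id,
                    complex_id=f"CPX{i:04d}",
                    distance=min(dists),
                    kind=kinds[i],
                )
            )

    decoys = frozenset(
        fam for pf in pair_fams for fam in (pf[2], pf[3], pf[4])
    )
    sequences = _evolve_sequences(config, genomes, pair_fams, rng) if config.emit_sequences else None
    similarities = _emit_similarities(config, genomes, pair_fams, sequences, rng)
    truth = SyntheticTruth(
        gold_pairs=gold_pairs,
        placements=placements,
        decoy_families=decoys,
        sequences=sequences,
    )
    return genomes, truth, similarities


def _members_by_family(genomes: Iterable[GenomeAnnotation], families: set[str]) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {fam: [] for fam in families}
    for genome in genomes:
        for contig in genome.contigs:
            for gene in contig.genes:
                for fam in gene.family_ids:
                    if fam in members:
                        members[fam].append(gene.protein_id)
    return members


def _evolve_sequences(config, genomes, pair_fams, rng) -> dict[str, str]:
    """Mutate per-family ancestors into member sequences (optional mode)."""
    su_families = {fam for pf in pair_fams for fam in pf[:2]}
    members = _members_by_family(genomes, su_families)
    L = config.sequence_length
    sequences: dict[str, str] = {}
    for fam in sorted(su_families):
        ancestor = rng.choice(AMINO_ACIDS, size=L)
        for pid in members[fam]:
            seq = ancestor.copy()
            mask = rng.random(L) < config.mutation_rate
            seq[mask] = rng.choice(AMINO_ACIDS, size=int(mask.sum()))
            sequences[pid] = seq.tobytes().decode("ascii")
    return sequences


def _emit_similarities(config, genomes, pair_fams, sequences, rng) -> list[SimilarityEdge]:
    """Star-topology within-family edges plus sparse cross-family noise."""
    su_families = {fam for pf in pair_fams for fam in pf[:2]}
    members = _members_by_family(genomes, su_families)
    edges: list[SimilarityEdge] = []
    hubs: list[str] = []
    for fam in sorted(su_families):
        mems = members[fam]
        if not mems:
            continue
        hub = mems[0]
        hubs.append(hub)
        for other in mems[1:]:
            if sequences is not None:
                identity, score = pairwise_identity(sequences[hub], sequences[other])
                bit = float(max(score, 0)) * 2.0
            else:
                identity = float(np.clip(rng.normal(90.0, 3.0), 75.0, 100.0))
                bit = identity * 4.0
            edges.append(SimilarityEdge(id_a=hub, id_b=other, percent_identity=identity, bit_score=bit))
    for a in range(len(hubs)):
        for b in range(a + 1, min(a + 3, len(hubs))):  # sparse cross-family noise
            identity = float(np.clip(rng.normal(10.0, 3.0), 0.0, 30.0))
            edges.append(
                SimilarityEdge(id_a=hubs[a], id_b=hubs[b], percent_identity=identity, bit_score=identity)
            )
    return edges


# ---------------------------------------------------------------------------
# truth summaries and I/O
# ---------------------------------------------------------------------------

def summarize_truth(truth: SyntheticTruth, w: int) -> pd.DataFrame:
    """Per-pair fraction of genomes whose partner lies inside ±w."""
    rows = []
    by_pair: dict[str, list[Placement]] = {}
    for pl in truth.placements:
        by_pair.setdefault(pl.complex_id, []).append(pl)
    for complex_id in sorted(by_pair):
        pls = by_pair[complex_id]
        inside = sum(1 for pl in pls if pl.distance <= w)
        rows.append(
            {
                "complex_id": complex_id,
                "n_genomes": len(pls),
                "n_inside": inside,
                "fraction_inside": inside / len(pls),
            }
        )
    return pd.DataFrame(rows)


def overall_fraction_within(truth: SyntheticTruth, w: int) -> float:
    """Fraction of all placements with partner inside ±w."""
    if not truth.placements:
        raise ValueError("truth has no placements")
    return sum(1 for pl in truth.placements if pl.distance <= w) / len(truth.placements)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "gold_pairs": [
            {
                "complex_id": g.complex_id,
                "su1_families": sorted(g.su1_families),
                "su2_families": sorted(g.su2_families),
            }
            for g in truth.gold_pairs
        ],
        "placements": [
            {
                "genome_id": pl.genome_id,
                "complex_id": pl.complex_id,
                "distance": pl.distance,
                "kind": pl.kind,
            }
            for pl in truth.placements
        ],
        "decoy_families": sorted(truth.decoy_families),
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=1)


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    return SyntheticTruth(
        gold_pairs=[
            GoldPair(
                complex_id=g["complex_id"],
                su1_families=frozenset(g["su1_families"]),
                su2_families=frozenset(g["su2_families"]),
            )
            for g in payload["gold_pairs"]
        ],
        placements=[Placement(**pl) for pl in payload["placements"]],
        decoy_families=frozenset(payload["decoy_families"]),
    )
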