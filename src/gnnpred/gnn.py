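"""Genome-neighborhood extraction and refined neighborhood networks (rGNNs).

For every member sequence of a query family, the ±w gene-window around
its gene is collected (w = 10 by default: those 20 gene products encoded
in a ±10 window). Windows are truncated at linear contig ends and wrap
around circular contigs without revisiting a gene. Neighboring gene
products are aggregated as *pf_nodes*, one per protein family:

* ``seq_count`` — the number of distinct neighborhoods containing the
  family (presence/absence per window; a family found twice in one
  window counts once);
* ``coverage`` — seq_count divided by the number of neighborhoods;
* ``frequency_f`` — seq_count divided by the summed seq_count of all
  pf_nodes retained in the rGNN.

pf_nodes below a minimal coverage (default 20%) are removed before
frequencies are computed, focusing the network on the consistently
conserved neighbor functions; pass ``coverage_min=0`` to keep everything.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .exceptions import DegenerateInputError, EmptyNetworkError
from .genome_model import GenomeAnnotation, GenomeDataset, as_dataset
from .ssn import SSN, RepNode

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_W = 10
DEFAULT_COVERAGE_MIN = 0.20


@dataclass
class Neighborhood:
    """The ±w window of one query protein, as ordered family sets.

    ``neighbor_family_sets`` holds one (possibly empty) set of family
    accessions per neighboring gene, upstream genes first, excluding the
    query gene itself.
    """

    query_protein_id: str
    genome_id: str
    phylum: str
    neighbor_family_sets: list[frozenset[str]]
    window_halfwidth_w: int

    @property
    def family_union(self) -> frozenset[str]:
        out: set[str] = set()
        for fams in self.neighbor_family_sets:
            out |= fams
        return frozenset(out)


@dataclass
class PfNodeStat:
    """Aggregate statistics of one protein family across neighborhoods."""

    family_id: str
    seq_count: int
    coverage: float
    frequency_f: float = 0.0


@dataclass
class RGNN:
    """Refined genome-neighborhood network of one query family."""

    query_family_id: str
    rep_nodes: list[RepNode]
    pf_nodes: list[PfNodeStat]
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    n_neighborhoods: int = 0
    n_phyla: int = 0


def extract_neighborhood(
    genomes: Sequence[GenomeAnnotation] | GenomeDataset,
    protein_id: str,
    w: int = DEFAULT_WINDOW_W,
) -> Neighborhood:
    """Collect the ±w gene window around one protein.

    Linear contigs truncate the window at their ends; circular contigs
    wrap around but never revisit a gene, so at most
    ``min(2w, contig_size - 1)`` neighbors are returned. Strand is
    ignored. Raises ``KeyError`` for an unknown protein.
    """
    if w < 1:
        raise ValueError(f"window halfwidth w must be >= 1, got {w}")
    dataset = as_dataset(genomes)
    genome, contig, pos = dataset.locate(protein_id)
    n = len(contig)
    indices: list[int] = []
    if contig.circular:
        seen = {pos}
        for k in range(w, 0, -1):  # upstream, farthest first
            idx = (pos - k) % n
            if idx not in seen:
                seen.add(idx)
                indices.append(idx)
        for k in range(1, w + 1):
            idx = (pos + k) % n
            if idx not in seen:
                seen.add(idx)
                indices.append(idx)
    else:
        indices = list(range(max(0, pos - w), pos)) + list(range(pos + 1, min(n, pos + w + 1)))
    return Neighborhood(
        query_protein_id=protein_id,
        genome_id=genome.genome_id,
        phylum=genome.phylum,
        neighbor_family_sets=[contig.genes[i].family_ids for i in indices],
        window_halfwidth_w=w,
    )


def compute_frequencies(pf_nodes: Sequence[PfNodeStat]) -> list[PfNodeStat]:
    """Normalize seq_counts to relative frequencies f(pf_node).

    f = seq_count / sum of seq_counts over the supplied list; the
    frequencies of the returned list sum to 1.
    """
    total = sum(p.seq_count for p in pf_nodes)
    if total <= 0:
        raise DegenerateInputError("all pf_node seq_counts are zero")
    return [replace(p, frequency_f=p.seq_count / total) for p in pf_nodes]


def build_rgnn(
    ssn: SSN,
    genomes: Sequence[GenomeAnnotation] | GenomeDataset,
    w: int = DEFAULT_WINDOW_W,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    exclude_self_family: bool = False,
    count_mode: str = "member",
) -> RGNN:
    """Aggregate the ±w neighborhoods of all SSN members into an rGNN.

    ``count_mode`` is ``"member"`` (one neighborhood per member sequence,
    the default) or ``"rep_node"`` (one neighborhood per rep_node, taken
    from its representative sequence). Members absent from the gene-order
    dataset are skipped with a warning. ``exclude_self_family`` drops the
    query family itself from the neighbor sets; by default other members
    of the query family appearing as neighbors do count.
    """
    if not (0.0 <= coverage_min <= 1.0):
        raise ValueError(f"coverage_min must lie in [0, 1], got {coverage_min}")
    if count_mode not in ("member", "rep_node"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    dataset = as_dataset(genomes)
    if count_mode == "member":
        queries = [(m, rep.rep_id) for rep in ssn.rep_nodes for m in sorted(rep.member_ids)]
    else:
        queries = [(rep.representative_id, rep.rep_id) for rep in ssn.rep_nodes]

    neighborhoods: list[tuple[Neighborhood, str]] = []
    for protein_id, rep_id in queries:
        if protein_id not in dataset:
            logger.warning(
                "SSN member %r of family %r not found in gene-order dataset; skipped",
                protein_id,
                ssn.family_id,
            )
            continue
        neighborhoods.append((extract_neighborhood(dataset, protein_id, w), rep_id))
    if not neighborhoods:
        raise EmptyNetworkError(
            f"no usable neighborhoods for query family {ssn.family_id!r}"
        )

    n_nb = len(neighborhoods)
    seq_count: Counter[str] = Counter()
    per_rep_total: Counter[str] = Counter()
    per_rep_family: dict[tuple[str, str], int] = defaultdict(int)
    phyla: set[str] = set()
    for nb, rep_id in neighborhoods:
        phyla.add(nb.phylum)
        per_rep_total[rep_id] += 1
        families = nb.family_union
        if exclude_self_family:
            families = families - {ssn.family_id}
        for fam in families:
            seq_count[fam] += 1
            per_rep_family[(rep_id, fam)] += 1

    pf_nodes = [
        PfNodeStat(family_id=fam, seq_count=cnt, coverage=cnt / n_nb)
        for fam, cnt in sorted(seq_count.items())
    ]
    pf_nodes = [p for p in pf_nodes if p.coverage >= coverage_min]
    if pf_nodes:
        pf_nodes = compute_frequencies(pf_nodes)
    retained = {p.family_id for p in pf_nodes}
    edges = [
        (rep_id, fam, count / per_rep_total[rep_id])
        for (rep_id, fam), count in sorted(per_rep_family.items())
        if fam in retained
    ]
    return RGNN(
        query_family_id=ssn.family_id,
        rep_nodes=list(ssn.rep_nodes),
        pf_nodes=pf_nodes,
        edges=edges,
        n_neighborhoods=n_nb,
        n_phyla=len(phyla),
    )


def rgnn_table(rgnn: RGNN) -> "pd.DataFrame":
    """Tabular view of an rGNN's pf_nodes, ranked by descending frequency."""
    import pandas as pd

    from .classifier import pf_node_ranking

    ranked = pf_node_ranking(rgnn.pf_nodes)
    return pd.DataFrame(
        [
            {
                "family_id": p.family_id,
                "seq_count": p.seq_count,
                "coverage": p.coverage,
                "frequency_f": p.frequency_f,
                "rank": i + 1,
            }
            for i, p in enumerate(ranked)
        ]
    )
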