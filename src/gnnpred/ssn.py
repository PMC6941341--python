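"""Sequence-similarity networks and representative-node collapsing.

An SSN has one node per sequence, with edges weighted by an alignment
score. To keep large family networks tractable, sequences sharing at
least ``x``% identity are collapsed into one *representative node*
(rep_node x): the connected components of the thresholded identity graph
(single-linkage, deterministic and order-independent). Construction is
refused when the network would exceed an edge capacity, mirroring the
behaviour of large-scale SSN services; the conventional remedy is a
higher identity threshold (x = 80 falling back to x = 40).

Classification downstream depends only on rep_node membership, so the
SSN edge set is retained for export/inspection but carries no analytic
weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import CapacityError, FormatError

DEFAULT_EDGE_CAP = 10_000_000
DEFAULT_IDENTITY_X = 80.0
FALLBACK_IDENTITY_X = 40.0

SIMILARITY_COLUMNS = ["id_a", "id_b", "percent_identity", "bit_score"]


@dataclass(frozen=True)
class SimilarityEdge:
    """One unordered pair of proteins with identity and score."""

    id_a: str
    id_b: str
    bit_score: float
    percent_identity: float

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self-similarity record for {self.id_a!r}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent_identity outside [0, 100]: {self.percent_identity}")
        if self.bit_score < 0:
            raise ValueError(f"negative bit_score: {self.bit_score}")


@dataclass
class RepNode:
    """A representative node: a set of mutually linked member sequences."""

    rep_id: str
    member_ids: frozenset[str]
    representative_id: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("rep_node with empty member set")
        if self.representative_id not in self.member_ids:
            raise ValueError("representative_id must be a member")


@dataclass
class SSN:
    """A rep_node-collapsed sequence-similarity network for one family."""

    family_id: str
    rep_nodes: list[RepNode]
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    identity_threshold_x: float = DEFAULT_IDENTITY_X

    @property
    def member_ids(self) -> list[str]:
        out: list[str] = []
        for rep in self.rep_nodes:
            out.extend(sorted(rep.member_ids))
        return out


# ---------------------------------------------------------------------------
# pairwise identity (global alignment)
# ---------------------------------------------------------------------------

def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Percent identity and score of an optimal global alignment.

    Scoring: match +1, mismatch 0, linear gap -1 per gap column. Among
    alignments of optimal score, ties are broken by maximal match count,
    then by maximal number of aligned (non-gap) columns, which makes the
    reported identity canonical. Identity is identical columns divided by
    alignment length (aligned pairs plus gap columns), in percent.

    Returns ``(percent_identity, alignment_score)``; symmetric in its
    arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    la, lb = len(seq_a), len(seq_b)
    # lexicographic (score, matches, aligned_pairs) packed into one integer:
    # matches, aligned_pairs are both < A, so weights A^2 and A keep the order.
    A = la + lb + 1
    A2 = A * A
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    prev = np.arange(lb + 1, dtype=np.int64) * (-A2)
    for i in range(1, la + 1):
        cur = np.empty(lb + 1, dtype=np.int64)
        cur[0] = -A2 * i
        ai = ord(seq_a[i - 1])
        diag_gain = np.where(b == ai, A2 + A + 1, 1)  # match vs mismatch step
        diag = prev[:-1] + diag_gain
        up = prev[1:] - A2
        np.maximum(diag, up, out=diag)
        # left moves depend on cur itself: sequential scan
        run = cur[0]
        for j in range(1, lb + 1):
            run = max(diag[j - 1], run - A2)
            cur[j] = run
        prev = cur
    packed = int(prev[lb])
    score, rem = divmod(packed, A2)
    matches, aligned_pairs = divmod(rem, A)
    columns = la + lb - aligned_pairs
    identity = 100.0 * matches / columns if columns else 100.0
    return identity, int(score)


# ---------------------------------------------------------------------------
# rep_node collapsing
# ---------------------------------------------------------------------------

def collapse_rep_nodes(
    members: Sequence[str],
    similarities: Iterable[SimilarityEdge],
    x: float,
) -> list[RepNode]:
    """Collapse members into rep_nodes at identity threshold ``x``.

    Rep_nodes are the connected components of the graph whose edges are
    member pairs with percent identity >= x (a pair absent from
    ``similarities`` counts as identity 0). The representative — and the
    rep_id — is the lexicographically smallest member of each component.
    """
    if not (0.0 < x <= 100.0):
        raise ValueError(f"identity threshold x must lie in (0, 100], got {x}")
    graph = nx.Graph()
    graph.add_nodes_from(members)
    for edge in similarities:
        if edge.percent_identity >= x and edge.id_a in graph and edge.id_b in graph:
            graph.add_edge(edge.id_a, edge.id_b)
    reps = []
    for component in nx.connected_components(graph):
        representative = min(component)
        reps.append(
            RepNode(rep_id=representative, member_ids=frozenset(component), representative_id=representative)
        )
    reps.sort(key=lambda r: r.rep_id)
    return reps


def build_ssn(
    family_id: str,
    members: Sequence[str],
    similarities: Iterable[SimilarityEdge],
    x: float = DEFAULT_IDENTITY_X,
    edge_cap: int = DEFAULT_EDGE_CAP,
) -> SSN:
    """Build the rep_node-collapsed SSN of one query family.

    Two rep_nodes are linked if any member-level similarity record joins
    them; the edge weight is the maximal bit score over such records.
    Raises :class:`CapacityError` if the edge count would exceed
    ``edge_cap`` (default 10,000,000).
    """
    if not members:
        raise ValueError("members must be non-empty")
    similarities = list(similarities)
    reps = collapse_rep_nodes(members, similarities, x)
    member_to_rep = {m: rep.rep_id for rep in reps for m in rep.member_ids}
    best: dict[tuple[str, str], float] = {}
    for edge in similarities:
        ra = member_to_rep.get(edge.id_a)
        rb = member_to_rep.get(edge.id_b)
        if ra is None or rb is None or ra == rb:
            continue
        key = (ra, rb) if ra < rb else (rb, ra)
        if edge.bit_score > best.get(key, -1.0):
            best[key] = edge.bit_score
    if len(best) > edge_cap:
        raise CapacityError(
            f"SSN for {family_id!r} would contain {len(best)} edges "
            f"(cap {edge_cap}); retry with a larger identity threshold x"
        )
    edges = [(a, b, w) for (a, b), w in sorted(best.items())]
    return SSN(family_id=family_id, rep_nodes=reps, edges=edges, identity_threshold_x=x)


def build_ssn_auto(
    family_id: str,
    members: Sequence[str],
    similarities: Iterable[SimilarityEdge],
    x_primary: float = DEFAULT_IDENTITY_X,
    x_fallback: float = FALLBACK_IDENTITY_X,
    edge_cap: int = DEFAULT_EDGE_CAP,
) -> SSN:
    """Build at the primary threshold, falling back when capacity is hit.

    Mirrors the rep_node 80 → rep_node 40 convention: a network too dense
    at x = 80 is rebuilt at x = 40 (fewer, larger rep_nodes, fewer edges).
    """
    similarities = list(similarities)
    try:
        return build_ssn(family_id, members, similarities, x=x_primary, edge_cap=edge_cap)
    except CapacityError:
        return build_ssn(family_id, members, similarities, x=x_fallback, edge_cap=edge_cap)


# ---------------------------------------------------------------------------
# similarity-table I/O
# ---------------------------------------------------------------------------

def read_similarity_table(path: str | Path) -> list[SimilarityEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
    for col in SIMILARITY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return [
        SimilarityEdge(
            id_a=row.id_a,
            id_b=row.id_b,
            percent_identity=float(row.percent_identity),
            bit_score=float(row.bit_score),
        )
        for row in df.itertuples(index=False)
    ]


def write_similarity_table(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.id_a, e.id_b, e.percent_identity, e.bit_score) for e in edges],
        columns=SIMILARITY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
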