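"""Top-1 interaction-partner prediction from an rGNN.

The candidate partner of a query family is the pf_node with the highest
relative frequency f; it is called as the predicted partner iff
f_max >= f_min. Frequency ties are broken by higher seq_count, then by
lexicographically smallest family id — deterministic, so every rGNN
yields exactly zero or one positive prediction per threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .gnn import RGNN, PfNodeStat, build_rgnn
from .ssn import SSN

logger = logging.getLogger(__name__)

DEFAULT_F_MIN = 0.16


@dataclass
class Prediction:
    """The per-query outcome of the frequency classifier."""

    query_family_id: str
    predicted_family_id: str | None
    f_max: float
    f_min_used: float
    true_partner_rank: int | None = None


def _sort_key(p: PfNodeStat) -> tuple[float, int, str]:
    return (-p.frequency_f, -p.seq_count, p.family_id)


def pf_node_ranking(pf_nodes: Sequence[PfNodeStat]) -> list[PfNodeStat]:
    """pf_nodes in rank order: descending f, then seq_count, then id."""
    return sorted(pf_nodes, key=_sort_key)


def predict_partner(rgnn: RGNN, f_min: float = DEFAULT_F_MIN) -> Prediction:
    """Call the most frequent pf_node as partner if f_max >= f_min.

    An rGNN without pf_nodes yields a none-prediction with f_max = 0.
    """
    if not (0.0 <= f_min <= 1.0):
        raise ValueError(f"f_min must lie in [0, 1], got {f_min}")
    if not rgnn.pf_nodes:
        logger.info("rGNN of %r has no pf_nodes; predicting none", rgnn.query_family_id)
        return Prediction(rgnn.query_family_id, None, 0.0, f_min)
    top = min(rgnn.pf_nodes, key=_sort_key)
    predicted = top.family_id if top.frequency_f >= f_min else None
    return Prediction(rgnn.query_family_id, predicted, top.frequency_f, f_min)


def rank_true_partner(rgnn: RGNN, true_family_ids: Iterable[str]) -> int | None:
    """Rank (1 = most frequent) of the best-ranked true-partner family.

    Returns ``None`` when no true-partner family occurs among the
    pf_nodes at all.
    """
    truth = set(true_family_ids)
    if not truth:
        raise ValueError("true_family_ids must be non-empty")
    for rank, p in enumerate(pf_node_ranking(rgnn.pf_nodes), start=1):
        if p.family_id in truth:
            return rank
    return None


def rerank_in_smaller_window(
    ssn: SSN,
    genomes,
    true_family_ids: Iterable[str],
    w_small: int,
    w_default: int = 10,
    coverage_min: float = 0.20,
) -> tuple[int | None, int | None]:
    """True-partner rank before (±w_default) and after (±w_small) shrinking.

    Rebuilds the rGNN at both window sizes; the pair of ranks classifies
    the outcome as unaltered, improved or deteriorated.
    """
    if w_small > w_default:
        raise ValueError("w_small must not exceed the default window")
    truth = set(true_family_ids)
    before = rank_true_partner(build_rgnn(ssn, genomes, w=w_default, coverage_min=coverage_min), truth)
    after = rank_true_partner(build_rgnn(ssn, genomes, w=w_small, coverage_min=coverage_min), truth)
    return before, after
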