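"""Confusion-matrix accounting and MCC-optimized threshold selection.

Every query family of a gold-standard hetero-dimer pair is one positive
case P (its true partner is known); every other pf_node in its rGNN is
one negative case, and negatives are summed over all query families
without cross-rGNN deduplication. At a threshold f_min:

* TP — positive predictions matching a true-partner family;
* FP — positive predictions that do not;
* FN — P − TP, which deliberately includes positives whose partner never
  appears in the rGNN at all (those cap the achievable recall);
* TN — N − FP.

Metrics follow the textbook definitions FPR = FP/N, TPR = Recall = TP/P,
Precision = TP/(TP+FP) and the Matthews correlation coefficient
MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)), with MCC
defined as 0 when any denominator factor vanishes. The operating
threshold is chosen by sweeping f_min (default 1%..100% in 1% steps) and
maximizing MCC, ties resolved toward the smallest threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import Prediction, pf_node_ranking, predict_partner, rank_true_partner
from .exceptions import FormatError, ValidationError
from .gnn import RGNN

logger = logging.getLogger(__name__)

GOLD_COLUMNS = ["complex_id", "su1_families", "su2_families"]

DEFAULT_THRESHOLDS = [round(k / 100.0, 2) for k in range(1, 101)]


@dataclass(frozen=True)
class GoldPair:
    """A hetero-dimer: two subunits with disjoint family annotations."""

    complex_id: str
    su1_families: frozenset[str]
    su2_families: frozenset[str]

    def __post_init__(self) -> None:
        if not self.su1_families or not self.su2_families:
            raise ValidationError(f"gold pair {self.complex_id!r} with empty family set")
        if self.su1_families & self.su2_families:
            raise ValidationError(
                f"gold pair {self.complex_id!r}: subunit family sets overlap"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    p: int
    n: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn, self.p, self.n) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.tp + self.fn != self.p or self.fp + self.tn != self.n:
            raise ValidationError(
                f"inconsistent confusion counts: tp+fn={self.tp + self.fn} vs p={self.p}, "
                f"fp+tn={self.fp + self.tn} vs n={self.n}"
            )


@dataclass
class PerformancePoint:
    f_min: float
    counts: ConfusionCounts
    fpr: float
    tpr: float
    precision: float
    mcc: float
    precision_defined: bool = True


@dataclass
class LabeledPrediction:
    """A prediction paired with whether it names a true partner."""

    prediction: Prediction
    matches_truth: bool


# ---------------------------------------------------------------------------
# case accounting
# ---------------------------------------------------------------------------

def iter_query_instances(gold: Iterable[GoldPair]):
    """Yield (complex_id, query_family, true_family_set) for both subunits."""
    for pair in gold:
        for fam in sorted(pair.su1_families):
            yield pair.complex_id, fam, pair.su2_families
        for fam in sorted(pair.su2_families):
            yield pair.complex_id, fam, pair.su1_families


def count_cases(
    rgnns: Mapping[str, RGNN | None],
    gold: Sequence[GoldPair],
) -> tuple[int, int, pd.DataFrame]:
    """Tally positive and negative cases over all query-family instances.

    Each query-family instance contributes one positive case; its
    negatives are the pf_nodes of its rGNN that do not match a
    true-partner family. A query family without an rGNN still counts as a
    positive whose partner cannot be found (logged).
    """
    rows = []
    for complex_id, fam, truth in iter_query_instances(gold):
        rgnn = rgnns.get(fam)
        if rgnn is None:
            logger.warning("query family %r of %r has no rGNN", fam, complex_id)
            n_pf = 0
            n_neg = 0
        else:
            n_pf = len(rgnn.pf_nodes)
            n_neg = sum(1 for p in rgnn.pf_nodes if p.family_id not in truth)
        rows.append(
            {
                "complex_id": complex_id,
                "query_family": fam,
                "true_families": ";".join(sorted(truth)),
                "has_rgnn": rgnn is not None,
                "n_pf_nodes": n_pf,
                "n_negatives": n_neg,
            }
        )
    cases = pd.DataFrame(rows)
    p = len(cases)
    n = int(cases["n_negatives"].sum()) if p else 0
    return p, n, cases


def classify_at_threshold(
    labeled: Sequence[LabeledPrediction],
    p: int,
    n: int,
) -> ConfusionCounts:
    """Confusion counts from predictions generated at a single f_min."""
    tp = sum(1 for lp in labeled if lp.prediction.predicted_family_id is not None and lp.matches_truth)
    fp = sum(1 for lp in labeled if lp.prediction.predicted_family_id is not None and not lp.matches_truth)
    if tp > p or fp > n:
        raise ValidationError(f"tally exceeds case counts: tp={tp} p={p}, fp={fp} n={n}")
    return ConfusionCounts(tp=tp, fp=fp, tn=n - fp, fn=p - tp, p=p, n=n)


def compute_metrics(counts: ConfusionCounts, f_min: float = float("nan")) -> PerformancePoint:
    """Derive FPR, TPR, Precision and MCC from confusion counts.

    Requires p > 0 and n > 0. Precision with tp + fp = 0 is reported as 0
    and flagged via ``precision_defined``.
    """
    if counts.p <= 0 or counts.n <= 0:
        raise ValueError("compute_metrics requires p > 0 and n > 0")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    fpr = fp / counts.n
    tpr = tp / counts.p
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)  # exact integer product
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return PerformancePoint(
        f_min=f_min,
        counts=counts,
        fpr=fpr,
        tpr=tpr,
        precision=precision,
        mcc=mcc,
        precision_defined=precision_defined,
    )


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

def label_predictions(
    rgnns: Mapping[str, RGNN | None],
    gold: Sequence[GoldPair],
    f_min: float,
) -> list[LabeledPrediction]:
    """One labeled prediction per query-family instance at one threshold."""
    out = []
    for complex_id, fam, truth in iter_query_instances(gold):
        rgnn = rgnns.get(fam)
        if rgnn is None:
            pred = Prediction(fam, None, 0.0, f_min)
        else:
            pred = predict_partner(rgnn, f_min)
            pred.true_partner_rank = rank_true_partner(rgnn, truth)
        out.append(LabeledPrediction(pred, pred.predicted_family_id in truth))
    return out


def sweep_thresholds(
    rgnns: Mapping[str, RGNN | None],
    gold: Sequence[GoldPair],
    thresholds: Sequence[float] | None = None,
) -> tuple[list[PerformancePoint], PerformancePoint]:
    """Evaluate every threshold and return (points, MCC-argmax point).

    The per-query argmax pf_node does not depend on f_min, so it is
    computed once and only gated per threshold; the result is identical
    to reclassifying from scratch at each threshold.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    if len(thresholds) == 0:
        raise ValueError("threshold list must be non-empty")
    p, n, _cases = count_cases(rgnns, gold)
    f_max = []
    is_true = []
    has_pred = []
    for _complex_id, fam, truth in iter_query_instances(gold):
        rgnn = rgnns.get(fam)
        if rgnn is None or not rgnn.pf_nodes:
            f_max.append(0.0)
            is_true.append(False)
            has_pred.append(False)
            continue
        top = pf_node_ranking(rgnn.pf_nodes)[0]
        f_max.append(top.frequency_f)
        is_true.append(top.family_id in truth)
        has_pred.append(True)
    f_max = np.asarray(f_max)
    is_true = np.asarray(is_true)
    has_pred = np.asarray(has_pred)

    points = []
    for t in thresholds:
        positive = has_pred & (f_max >= t)
        tp = int(np.sum(positive & is_true))
        fp = int(np.sum(positive & ~is_true))
        counts = ConfusionCounts(tp=tp, fp=fp, tn=n - fp, fn=p - tp, p=p, n=n)
        points.append(compute_metrics(counts, f_min=float(t)))
    best = max(points, key=lambda pt: (pt.mcc, -pt.f_min))
    return points, best


def sweep_frame(points: Sequence[PerformancePoint]) -> pd.DataFrame:
    """ROC/PR-ready table of a threshold sweep."""
    return pd.DataFrame(
        [
            {
                "f_min": pt.f_min,
                "TP": pt.counts.tp,
                "FP": pt.counts.fp,
                "TN": pt.counts.tn,
                "FN": pt.counts.fn,
                "FPR": pt.fpr,
                "TPR": pt.tpr,
                "Precision": pt.precision,
                "MCC": pt.mcc,
            }
            for pt in points
        ]
    )


# ---------------------------------------------------------------------------
# window re-analysis bookkeeping
# ---------------------------------------------------------------------------

def classify_rank_shift(rank_before: int | None, rank_after: int | None) -> str:
    """Label a window-shrinking outcome: unaltered, improved, deteriorated.

    A partner that drops out of the smaller window entirely (rank None)
    counts as deteriorated.
    """
    if rank_before is None:
        raise ValueError("rank_before must be defined")
    if rank_after is None or rank_after > rank_before:
        return "deteriorated"
    if rank_after < rank_before:
        return "improved"
    return "unaltered"


def rank_shift_fractions(outcomes: Sequence[str]) -> dict[str, float]:
    """Percentage of unaltered / improved / deteriorated outcomes."""
    if not outcomes:
        raise ValueError("no outcomes supplied")
    total = len(outcomes)
    return {
        label: 100.0 * sum(1 for o in outcomes if o == label) / total
        for label in ("unaltered", "improved", "deteriorated")
    }


# ---------------------------------------------------------------------------
# gold-standard I/O
# ---------------------------------------------------------------------------

def read_gold_table(path: str | Path) -> list[GoldPair]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in GOLD_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return [
        GoldPair(
            complex_id=row.complex_id,
            su1_families=frozenset(row.su1_families.split(";")),
            su2_families=frozenset(row.su2_families.split(";")),
        )
        for row in df.itertuples(index=False)
    ]


def write_gold_table(gold: Iterable[GoldPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "complex_id": g.complex_id,
                "su1_families": ";".join(sorted(g.su1_families)),
                "su2_families": ";".join(sorted(g.su2_families)),
            }
            for g in gold
        ],
        columns=GOLD_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# end-to-end benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    rgnns: dict[str, RGNN | None]
    points: list[PerformancePoint]
    best: PerformancePoint
    p: int
    n: int
    cases: pd.DataFrame = field(repr=False, default=None)


def build_rgnns_for_gold(
    genomes,
    similarities,
    gold: Sequence[GoldPair],
    w: int = 10,
    x: float = 80.0,
    coverage_min: float = 0.20,
    edge_cap: int = 10_000_000,
) -> dict[str, RGNN | None]:
    """Build one rGNN per gold query family (None when it has no members)."""
    from .genome_model import as_dataset
    from .gnn import build_rgnn
    from .ssn import build_ssn_auto

    dataset = as_dataset(genomes)
    families = sorted({fam for _c, fam, _t in iter_query_instances(gold)})
    by_member: dict[str, list] = {}
    for edge in similarities:
        by_member.setdefault(edge.id_a, []).append(edge)
        by_member.setdefault(edge.id_b, []).append(edge)
    rgnns: dict[str, RGNN | None] = {}
    for fam in families:
        members = dataset.proteins_of_family(fam)
        if not members:
            logger.warning("gold family %r has no member proteins", fam)
            rgnns[fam] = None
            continue
        member_set = set(members)
        sims = []
        seen = set()
        for m in members:
            for edge in by_member.get(m, ()):
                if edge.id_a in member_set and edge.id_b in member_set:
                    key = (edge.id_a, edge.id_b)
                    if key not in seen:
                        seen.add(key)
                        sims.append(edge)
        ssn = build_ssn_auto(fam, members, sims, x_primary=x, edge_cap=edge_cap)
        rgnns[fam] = build_rgnn(ssn, dataset, w=w, coverage_min=coverage_min)
    return rgnns


def run_benchmark(
    genomes,
    similarities,
    gold: Sequence[GoldPair],
    w: int = 10,
    x: float = 80.0,
    coverage_min: float = 0.20,
    thresholds: Sequence[float] | None = None,
) -> BenchmarkResult:
    """Full pipeline: rGNNs for every gold family, then a threshold sweep."""
    rgnns = build_rgnns_for_gold(genomes, similarities, gold, w=w, x=x, coverage_min=coverage_min)
    p, n, cases = count_cases(rgnns, gold)
    points, best = sweep_thresholds(rgnns, gold, thresholds)
    return BenchmarkResult(rgnns=rgnns, points=points, best=best, p=p, n=n, cases=cases)
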