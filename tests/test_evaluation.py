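"""Case accounting, metric arithmetic and the threshold sweep."""

from __future__ import annotations

import numpy as np
import pytest

from gnnpred import (
    ConfusionCounts,
    GoldPair,
    LabeledPrediction,
    PfNodeStat,
    Prediction,
    RGNN,
    ValidationError,
    classify_at_threshold,
    classify_rank_shift,
    compute_frequencies,
    compute_metrics,
    count_cases,
    label_predictions,
    rank_shift_fractions,
    read_gold_table,
    run_benchmark,
    sweep_thresholds,
    write_gold_table,
)


def _rgnn(fam, seq_counts):
    stats = compute_frequencies([PfNodeStat(f, c, 0.0) for f, c in seq_counts.items()])
    return RGNN(fam, rep_nodes=[], pf_nodes=stats, n_neighborhoods=sum(seq_counts.values()), n_phyla=1)


def test_gold_pair_requires_disjoint_families():
    with pytest.raises(ValidationError):
        GoldPair("c1", frozenset({"A"}), frozenset({"A", "B"}))


def test_count_cases_one_query_with_partner_present():
    gold = [GoldPair("c1", frozenset({"QA"}), frozenset({"QB"}))]
    rgnns = {
        "QA": _rgnn("QA", {"QB": 5, "X1": 4, "X2": 3, "X3": 2, "X4": 1}),
        "QB": None,
    }
    p, n, cases = count_cases(rgnns, gold)
    assert p == 2  # both subunits are query instances
    # QA contributes 4 negatives; QB has no rGNN and contributes none
    assert n == 4
    assert cases.loc[cases.query_family == "QA", "n_negatives"].item() == 4


def test_count_cases_partner_absent_counts_all_pf_nodes_negative():
    gold = [GoldPair("c1", frozenset({"QA"}), frozenset({"QB"}))]
    rgnns = {"QA": _rgnn("QA", {"X1": 3, "X2": 2, "X3": 1, "X4": 1, "X5": 1}), "QB": None}
    _p, n, _cases = count_cases(rgnns, gold)
    assert n == 5


def test_count_cases_matches_enumeration_oracle(rng):
    for _ in range(20):
        gold = []
        rgnns = {}
        for i in range(int(rng.integers(1, 6))):
            a, b = f"A{i}", f"B{i}"
            gold.append(GoldPair(f"c{i}", frozenset({a}), frozenset({b})))
            for fam, partner in ((a, b), (b, a)):
                if rng.random() < 0.8:
                    others = {f"X{i}_{j}": int(rng.integers(1, 9)) for j in range(int(rng.integers(0, 6)))}
                    if rng.random() < 0.7:
                        others[partner] = int(rng.integers(1, 9))
                    rgnns[fam] = _rgnn(fam, others) if others else RGNN(fam, [], [])
                else:
                    rgnns[fam] = None
        p, n, _ = count_cases(rgnns, gold)
        # oracle: enumerate all (query, pf_node) pairs directly
        exp_p = 2 * len(gold)
        exp_n = 0
        for pair in gold:
            for fam, truth in ((next(iter(pair.su1_families)), pair.su2_families),
                               (next(iter(pair.su2_families)), pair.su1_families)):
                r = rgnns.get(fam)
                if r is not None:
                    exp_n += sum(1 for pf in r.pf_nodes if pf.family_id not in truth)
        assert (p, n) == (exp_p, exp_n)


# ---------------------------------------------------------------------------
# classification at a threshold
# ---------------------------------------------------------------------------

def _lp(fam, predicted, matches):
    return LabeledPrediction(Prediction(fam, predicted, 0.5 if predicted else 0.0, 0.16), matches)


def test_all_none_predictions_give_zero_tp_fp():
    labeled = [_lp(f"Q{i}", None, False) for i in range(4)]
    counts = classify_at_threshold(labeled, p=4, n=10)
    assert (counts.tp, counts.fp, counts.fn, counts.tn) == (0, 0, 4, 10)


def test_perfect_predictions_give_tp_equal_p():
    labeled = [_lp(f"Q{i}", f"P{i}", True) for i in range(5)]
    counts = classify_at_threshold(labeled, p=5, n=7)
    assert (counts.tp, counts.fp, counts.fn, counts.tn) == (5, 0, 0, 7)


def test_classification_matches_tally_oracle(rng):
    for _ in range(30):
        p = int(rng.integers(1, 20))
        n = int(rng.integers(p, 50))
        labeled = []
        exp_tp = exp_fp = 0
        for i in range(p):
            r = rng.random()
            if r < 0.4:
                labeled.append(_lp(f"Q{i}", "hit", True))
                exp_tp += 1
            elif r < 0.7:
                labeled.append(_lp(f"Q{i}", "miss", False))
                exp_fp += 1
            else:
                labeled.append(_lp(f"Q{i}", None, False))
        counts = classify_at_threshold(labeled, p=p, n=n)
        assert (counts.tp, counts.fp) == (exp_tp, exp_fp)
        assert counts.tp + counts.fn == p
        assert counts.fp + counts.tn == n


def test_inconsistent_tallies_rejected():
    labeled = [_lp("Q0", "hit", True), _lp("Q1", "hit", True)]
    with pytest.raises(ValidationError):
        classify_at_threshold(labeled, p=1, n=5)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_metrics_of_published_scale_confusion_matrix():
    counts = ConfusionCounts(tp=485, fp=389, tn=596378, fn=602, p=1087, n=596767)
    point = compute_metrics(counts)
    assert point.precision == pytest.approx(485 / 874)
    assert point.tpr == pytest.approx(485 / 1087)
    assert point.fpr == pytest.approx(389 / 596767)
    num = 485 * 596378 - 389 * 602
    den = (485 + 602) * (485 + 389) * (596378 + 389) * (596378 + 602)
    assert point.mcc == pytest.approx(num / np.sqrt(den))


def test_perfect_classifier_metrics():
    point = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=20, fn=0, p=10, n=20))
    assert (point.mcc, point.tpr, point.fpr, point.precision) == (1.0, 1.0, 0.0, 1.0)


def test_zero_positive_predictions_yield_zero_mcc_and_flagged_precision():
    point = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=20, fn=10, p=10, n=20))
    assert point.mcc == 0.0
    assert point.precision == 0.0
    assert not point.precision_defined


def test_metrics_require_positive_and_negative_cases():
    with pytest.raises(ValueError):
        compute_metrics(ConfusionCounts(tp=0, fp=0, tn=0, fn=0, p=0, n=0))


def test_random_confusion_matrices_match_sklearn(rng):
    from sklearn.metrics import matthews_corrcoef, precision_score, recall_score

    for _ in range(100):
        tp, fp, tn, fn = (int(x) for x in rng.integers(0, 30, size=4))
        p, n = tp + fn, fp + tn
        if p == 0 or n == 0:
            continue
        point = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, p=p, n=n))
        y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        assert point.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
        assert point.tpr == pytest.approx(recall_score(y_true, y_pred))
        if tp + fp:
            assert point.precision == pytest.approx(precision_score(y_true, y_pred))
        assert -1.0 <= point.mcc <= 1.0
        assert 0.0 <= point.fpr <= 1.0 and 0.0 <= point.tpr <= 1.0


# ---------------------------------------------------------------------------
# sweep
# ---------------------------------------------------------------------------

def _perfect_fixture():
    gold = [GoldPair("c1", frozenset({"QA"}), frozenset({"QB"}))]
    rgnns = {
        "QA": _rgnn("QA", {"QB": 9, "X": 1}),
        "QB": _rgnn("QB", {"QA": 9, "Y": 1}),
    }
    return rgnns, gold


def test_single_zero_threshold_on_perfect_fixture():
    rgnns, gold = _perfect_fixture()
    points, best = sweep_thresholds(rgnns, gold, thresholds=[0.0])
    assert best.f_min == 0.0
    assert best.mcc == 1.0
    assert points[0].counts.tp == 2 and points[0].counts.fp == 0


def test_empty_threshold_list_rejected():
    rgnns, gold = _perfect_fixture()
    with pytest.raises(ValueError):
        sweep_thresholds(rgnns, gold, thresholds=[])


def test_sweep_counts_match_per_threshold_reclassification(small_sim):
    """Dual route: the vectorized sweep must equal predicting and tallying
    from scratch at every threshold."""
    _cfg, genomes, truth, sims = small_sim
    result = run_benchmark(genomes, sims, truth.gold_pairs, coverage_min=0.0)
    for point in result.points[::7]:
        labeled = label_predictions(result.rgnns, truth.gold_pairs, point.f_min)
        counts = classify_at_threshold(labeled, result.p, result.n)
        assert counts == point.counts


def test_tp_and_fp_non_increasing_in_threshold(small_sim):
    _cfg, genomes, truth, sims = small_sim
    result = run_benchmark(genomes, sims, truth.gold_pairs)
    tps = [pt.counts.tp for pt in result.points]
    fps = [pt.counts.fp for pt in result.points]
    assert tps == sorted(tps, reverse=True)
    assert fps == sorted(fps, reverse=True)
    for pt in result.points:
        assert pt.counts.tp + pt.counts.fn == result.p
        assert pt.counts.fp + pt.counts.tn == result.n


# ---------------------------------------------------------------------------
# rank-shift bookkeeping and gold I/O
# ---------------------------------------------------------------------------

def test_rank_shift_classification():
    assert classify_rank_shift(2, 2) == "unaltered"
    assert classify_rank_shift(2, 1) == "improved"
    assert classify_rank_shift(2, 4) == "deteriorated"
    assert classify_rank_shift(2, None) == "deteriorated"
    with pytest.raises(ValueError):
        classify_rank_shift(None, 1)


def test_rank_shift_fractions():
    outcomes = ["unaltered"] * 12 + ["improved"] * 8 + ["deteriorated"] * 7
    fracs = rank_shift_fractions(outcomes)
    assert fracs["unaltered"] == pytest.approx(100 * 12 / 27)
    assert fracs["improved"] == pytest.approx(100 * 8 / 27)
    assert fracs["deteriorated"] == pytest.approx(100 * 7 / 27)


def test_gold_table_round_trip(tmp_path):
    gold = [
        GoldPair("c1", frozenset({"PF00001", "PF00002"}), frozenset({"PF00003"})),
        GoldPair("c2", frozenset({"PF00004"}), frozenset({"PF00005"})),
    ]
    path = tmp_path / "gold.tsv"
    write_gold_table(gold, path)
    assert read_gold_table(path) == gold
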