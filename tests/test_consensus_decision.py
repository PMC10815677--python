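"""Consensus intersection, or-rule classification and panel evaluation."""

import math

import numpy as np
import pytest

from methylpanel import published
from methylpanel.consensus_decision import (
    DecisionMatrix,
    PanelEvaluation,
    classify,
    consensus,
    enumerate_panels,
    evaluate_panel,
    rank_panels,
    select_best_panel,
)
from methylpanel.data_model import CpGUnitID


def two_cpg_ds(make_ds, values, groups, history=None):
    return make_ds(values, groups, columns=["02_CpG_6", "35_CpG_7"], history=history)


# -- consensus --------------------------------------------------------------

def test_consensus_identity_and_disjoint():
    a = {CpGUnitID("02", (6,)), CpGUnitID("35", (7,))}
    b = {CpGUnitID("42", (9,))}
    assert consensus([a]) == a
    assert consensus([a, b]) == set()


def test_consensus_order_invariant_and_idempotent():
    sets = published.selected_sets()
    base = consensus(sets)
    assert consensus(list(reversed(sets))) == base
    assert consensus(sets + [base]) == base


# -- classification ---------------------------------------------------------

def test_published_thresholds_call_positive(make_ds):
    matrix = DecisionMatrix((("02_CpG_6", 0.435), ("35_CpG_7", 0.465)))
    ds = two_cpg_ds(make_ds, [[0.50, 0.40]], ["case"])
    assert classify(matrix, ds).iloc[0]  # 0.50 > 0.435 suffices


def test_values_at_threshold_are_negative(make_ds):
    matrix = DecisionMatrix((("02_CpG_6", 0.435), ("35_CpG_7", 0.465)))
    ds = two_cpg_ds(make_ds, [[0.435, 0.465]], ["case"])
    assert not classify(matrix, ds).iloc[0]  # strict inequality


def test_classify_matches_brute_force(make_ds, rng):
    values = rng.uniform(0, 1, size=(4, 2))
    ds = two_cpg_ds(make_ds, values, ["case", "case", "control", "control"])
    thr = (0.3, 0.6)
    matrix = DecisionMatrix((("02_CpG_6", thr[0]), ("35_CpG_7", thr[1])))
    calls = classify(matrix, ds)
    for i in range(4):
        assert calls.iloc[i] == (values[i, 0] > thr[0] or values[i, 1] > thr[1])


def test_classify_rejects_missing_member(make_ds):
    values = np.array([[0.5, np.nan]])
    ds = two_cpg_ds(make_ds, values, ["case"])
    matrix = DecisionMatrix((("35_CpG_7", 0.4),))
    with pytest.raises(ValueError, match="missing"):
        classify(matrix, ds)


# -- panel evaluation -------------------------------------------------------

def test_single_member_panel_reduces_to_single_threshold(make_ds, rng):
    values = rng.uniform(0, 1, size=(20, 2))
    ds = two_cpg_ds(make_ds, values, ["case"] * 12 + ["control"] * 8)
    ev = evaluate_panel(DecisionMatrix((("02_CpG_6", 0.5),)), ds)
    pos = values[:, 0] > 0.5
    assert ev.sensitivity == pytest.approx(pos[:12].mean())
    assert ev.specificity == pytest.approx((~pos[12:]).mean())


def test_stratified_metrics_match_hand_counts(make_ds):
    values = np.array(
        [
            [0.9, 0.1],  # case, no history -> positive
            [0.1, 0.9],  # case, no history -> positive
            [0.1, 0.1],  # case, no history -> negative
            [0.9, 0.9],  # case, history    -> positive
            [0.1, 0.1],  # case, history    -> negative
            [0.1, 0.1],  # control, no history -> negative
            [0.9, 0.1],  # control, no history -> positive (false)
            [0.1, 0.1],  # control, history -> negative
            [0.1, 0.1],  # control, history -> negative
            [0.1, 0.9],  # control, history -> positive (false)
        ]
    )
    groups = ["case"] * 5 + ["control"] * 5
    history = [False, False, False, True, True, False, False, True, True, True]
    ds = two_cpg_ds(make_ds, values, groups, history=history)
    ev = evaluate_panel(DecisionMatrix((("02_CpG_6", 0.5), ("35_CpG_7", 0.5))), ds)
    assert ev.sensitivity == pytest.approx(3 / 5)
    assert ev.specificity == pytest.approx(3 / 5)
    assert ev.sensitivity_no_history == pytest.approx(2 / 3)
    assert ev.sensitivity_history == pytest.approx(1 / 2)
    assert ev.specificity_no_history == pytest.approx(1 / 2)
    assert ev.specificity_history == pytest.approx(2 / 3)
    # overall = stratum metrics recombined with stratum weights
    recombined_sens = (3 * ev.sensitivity_no_history + 2 * ev.sensitivity_history) / 5
    assert ev.sensitivity == pytest.approx(recombined_sens)


def test_empty_stratum_is_undefined_not_zero(make_ds):
    values = np.array([[0.9, 0.1], [0.1, 0.1]])
    ds = two_cpg_ds(make_ds, values, ["case", "control"], history=[False, False])
    ev = evaluate_panel(DecisionMatrix((("02_CpG_6", 0.5),)), ds)
    assert math.isnan(ev.sensitivity_history)
    assert math.isnan(ev.specificity_history)


# -- enumeration and best panel --------------------------------------------

def test_enumerate_three_candidates_yields_seven_consistent_panels(make_ds, rng):
    values = rng.uniform(0, 1, size=(30, 4))
    cols = ["02_CpG_6", "35_CpG_7", "78_CpG_2.3", "42_CpG_9"]
    ds = make_ds(values, ["case"] * 18 + ["control"] * 12, columns=cols)
    thresholds = {"02_CpG_6": 0.4, "35_CpG_7": 0.5, "78_CpG_2.3": 0.6}
    ranked = enumerate_panels(cols[:3], thresholds, ds, floor=0.8)
    assert len(ranked) == 7
    for ev in ranked:
        matrix = DecisionMatrix(tuple((m, thresholds[m]) for m in ev.members))
        direct = evaluate_panel(matrix, ds)
        assert ev.sensitivity == direct.sensitivity
        assert ev.specificity == direct.specificity
        assert ev.meets_floor == (ev.specificity >= 0.8)
    specs = [e.specificity for e in ranked]
    assert specs == sorted(specs, reverse=True) or all(
        (a > b) or (a == b) for a, b in zip(specs, specs[1:])
    )


def test_enumeration_cap():
    with pytest.raises(ValueError, match="refusing"):
        enumerate_panels([f"{i:02d}_CpG_1" for i in range(1, 23)], {}, None)


def test_select_best_panel_tie_breaks():
    rows = [
        PanelEvaluation(("a",), 0.60, 0.95, 0.6, 0.95, 0.6, 0.95),
        PanelEvaluation(("b",), 0.60, 0.97, 0.6, 0.97, 0.6, 0.97),
        PanelEvaluation(("c", "d"), 0.60, 0.97, 0.6, 0.97, 0.6, 0.97),
        PanelEvaluation(("e",), 0.70, 0.90, 0.7, 0.9, 0.7, 0.9),
    ]
    best = select_best_panel(rows, floor=0.95)
    assert best.members == ("b",)  # sens tie -> higher spec -> fewer members
    assert select_best_panel(rows, floor=0.99) is None


def test_published_report_ranking_and_best_panel():
    rows = published.published_panel_report()
    ranked = rank_panels(rows)
    assert [r.members for r in ranked] == [r.members for r in rows]
    best = select_best_panel(ranked, floor=0.95)
    assert best.members == ("02_CpG_6", "35_CpG_7")
    assert best.sensitivity == pytest.approx(0.61)
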