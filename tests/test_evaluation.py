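import numpy as np
import pandas as pd
import pytest

from beaconloc import (
    GroundTruthTrace,
    confusion,
    dwelling_agreement,
    dwelling_pairs,
    error_report,
    mark_transitions,
    stratified_agreement,
)
from beaconloc.evaluation import average_error_reports, icc_absolute_agreement


def truth_of(seq, epoch_s=10.0):
    return GroundTruthTrace(area_ids=list(seq), epoch_s=epoch_s)


# ---------------------------------------------------------------- transitions

def test_constant_truth_has_no_transitions():
    assert not mark_transitions(truth_of("AAAAA")).any()


def test_single_change_flags_three_epochs():
    mask = mark_transitions(truth_of("AAABBB"))
    assert np.flatnonzero(mask).tolist() == [2, 3, 4]


def test_boundary_change_clips_mask():
    mask = mark_transitions(truth_of("AB"))
    assert mask.tolist() == [True, True]


def test_wider_window():
    mask = mark_transitions(truth_of("AAAABBBB"), window=2)
    assert np.flatnonzero(mask).tolist() == [2, 3, 4, 5, 6]


# ---------------------------------------------------------------- error report

def test_perfect_prediction_zero_errors():
    truth = truth_of("AAABBB")
    rep = error_report(list(truth.area_ids), truth)
    assert rep.transition_error_pct == 0.0
    assert rep.nontransition_error_pct == 0.0
    assert rep.overall_error_pct == 0.0


def test_transition_error_direct_formula():
    # 10 transition epochs (100 s), 2-3 of which misclassified -> 25% needs
    # T_t=100 s with 25 s wrong: craft with window such that exactly holds
    truth = ["A"] * 10 + ["B"] * 10 + ["C"] * 10 + ["D"] * 10
    pred = list(truth)
    # changes at 10,20,30 -> mask = {9,10,11, 19,20,21, 29,30,31}: 90 s
    # misclassify 2 transition epochs and 0 others
    pred[9] = "B"
    pred[19] = "C"
    t = truth_of(truth)
    rep = error_report(pred, t)
    assert rep.transition_s == 90.0
    assert rep.misclassified_transition_s == 20.0
    assert rep.transition_error_pct == pytest.approx(100 * 20 / 90)
    assert rep.nontransition_error_pct == 0.0


def test_error_decomposition_hand_example():
    # T_l = 1000 s, T_nt = 500 s, e_hat_nt = 50 s, e_hat_t = 250 s
    truth = ["A"] * 50 + ["B"] * 50
    pred = list(truth)
    mask = mark_transitions(truth_of(truth))
    nt_idx = [i for i in range(100) if not mask[i]]
    t_idx = [i for i in range(100) if mask[i]]
    for i in nt_idx[:5]:
        pred[i] = "X"
    for i in t_idx[:2]:
        pred[i] = "X"
    rep = error_report(pred, truth_of(truth))
    assert rep.total_s == 1000.0
    assert rep.nontransition_error_pct == pytest.approx(100 * 50 / rep.nontransition_s)
    assert rep.transition_error_vs_total_pct == pytest.approx(100 * 20 / 1000)
    assert rep.overall_error_pct == pytest.approx(100 * (50 + 20) / 1000)


def test_zero_denominator_reported_as_undefined():
    rep = error_report(["A", "A"], truth_of("AA"))
    assert np.isnan(rep.transition_error_pct)
    assert rep.nontransition_error_pct == 0.0


def test_errors_invariant_to_relabeling():
    rng = np.random.default_rng(0)
    truth = ["ABC"[i] for i in rng.integers(0, 3, 60)]
    pred = ["ABC"[i] for i in rng.integers(0, 3, 60)]
    rep1 = error_report(pred, truth_of(truth))
    relabel = {"A": "Z", "B": "Y", "C": "X"}
    rep2 = error_report(
        [relabel[p] for p in pred], truth_of([relabel[t] for t in truth])
    )
    assert rep1.as_dict() == rep2.as_dict()


def test_min_dwell_filter_restricts_nontransition_tally():
    truth = ["A"] * 30 + ["B"] * 5 + ["C"] * 30  # B bout only 50 s
    pred = list(truth)
    pred[32] = "X"  # inside B, nontransition epoch
    rep_all = error_report(pred, truth_of(truth))
    rep_long = error_report(pred, truth_of(truth), min_dwell_s=100.0)
    assert rep_all.misclassified_nontransition_s == 10.0
    assert rep_long.misclassified_nontransition_s == 0.0


def test_average_over_trials_is_mean_of_relative_errors():
    truth = truth_of("AAAAABBBBB")
    perfect = error_report(list(truth.area_ids), truth)
    pred = list(truth.area_ids)
    pred[0] = "B"
    imperfect = error_report(pred, truth)
    avg = average_error_reports([perfect, imperfect])
    assert avg["nontransition_error_pct"] == pytest.approx(
        np.mean([0.0, imperfect.nontransition_error_pct])
    )


def test_longer_transition_bursts_never_decrease_transition_error():
    truth = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
    t = truth_of(truth)
    mask = np.flatnonzero(mark_transitions(t))
    last = -1.0
    for burst in range(len(mask) + 1):
        pred = list(truth)
        for i in mask[:burst]:
            pred[i] = "X"
        e_t = error_report(pred, t).transition_error_pct
        assert e_t >= last
        last = e_t


# ---------------------------------------------------------------- agreement

def test_perfect_agreement_closed_form():
    truth = truth_of(["A"] * 12 + ["B"] * 30 + ["A"] * 7 + ["C"] * 25)
    stats = dwelling_agreement(list(truth.area_ids), truth)
    assert stats.slope == pytest.approx(1.0)
    assert stats.intercept == pytest.approx(0.0, abs=1e-9)
    assert stats.r2 == pytest.approx(1.0)
    assert stats.icc == pytest.approx(1.0)
    assert stats.rmse == pytest.approx(0.0, abs=1e-9)
    assert stats.sse == pytest.approx(0.0, abs=1e-9)


def test_pairs_are_per_visit():
    truth = truth_of(["A"] * 5 + ["B"] * 3 + ["A"] * 4)
    pairs = dwelling_pairs(list(truth.area_ids), truth)
    assert len(pairs) == 3  # A revisited -> two separate bouts
    assert pairs["criterion_s"].tolist() == [50.0, 30.0, 40.0]


def test_icc_matches_published_two_way_formula():
    # independent oracle: direct ANOVA decomposition on a small hand table
    x = np.array([100.0, 200.0, 300.0, 150.0, 250.0, 80.0])
    y = np.array([110.0, 190.0, 310.0, 140.0, 260.0, 95.0])
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
    mse = ((data - data.mean(1, keepdims=True) - data.mean(0) + grand) ** 2).sum() / (
        (n - 1) * (k - 1)
    )
    expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
    assert icc_absolute_agreement(x, y) == pytest.approx(expected)


def test_icc_cross_checked_against_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(12)
    x = rng.uniform(50, 400, 10)
    y = x + rng.normal(0, 25, 10)
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(10), 2),
            "rater": ["c"] * 10 + ["p"] * 10,
            "score": np.concatenate([x, y]),
        }
    )
    table = pg.intraclass_corr(df, targets="target", raters="rater", ratings="score")
    ref = float(table.set_index("Type").loc["ICC(A,1)", "ICC"])
    assert icc_absolute_agreement(x, y) == pytest.approx(ref, abs=1e-10)


def test_constant_offset_keeps_fit_but_lowers_icc():
    truth = truth_of(["A"] * 12 + ["B"] * 30 + ["C"] * 19 + ["D"] * 25)
    pairs = dwelling_pairs(list(truth.area_ids), truth)
    pairs["predicted_s"] = pairs["criterion_s"] + 30.0
    stats = dwelling_agreement(None, truth, pairs=pairs)
    assert stats.slope == pytest.approx(1.0)
    assert stats.intercept == pytest.approx(30.0)
    assert stats.r2 == pytest.approx(1.0)
    assert stats.icc < 1.0


def test_stratification_splits_at_dwell_threshold():
    truth = truth_of(["A"] * 5 + ["B"] * 30 + ["C"] * 8 + ["D"] * 40 + ["E"] * 6)
    out = stratified_agreement(list(truth.area_ids), truth, threshold_s=100.0)
    assert out["under_threshold"].n_pairs == 3
    assert out["over_threshold"].n_pairs == 2
    assert out["all"].n_pairs == 5


def test_degenerate_variance_flagged_undefined():
    truth = truth_of(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
    stats = dwelling_agreement(list(truth.area_ids), truth)  # all dwells equal
    assert np.isnan(stats.slope)


# ---------------------------------------------------------------- confusion

def test_perfect_prediction_is_identity():
    truth = truth_of("AABBCC")
    cm = confusion(list(truth.area_ids), truth)
    assert np.array_equal(cm.to_numpy(), np.eye(3))


def test_row_fractions_count_time():
    truth = truth_of(["A"] * 10)
    pred = ["A"] * 9 + ["B"]
    cm = confusion(pred, truth)
    assert cm.loc["A", "A"] == pytest.approx(0.9)
    assert cm.loc["A", "B"] == pytest.approx(0.1)


def test_nontransition_variant_matches_subset_oracle():
    rng = np.random.default_rng(6)
    truth = ["AB"[i] for i in rng.integers(0, 2, 40)]
    pred = ["AB"[i] for i in rng.integers(0, 2, 40)]
    t = truth_of(truth)
    cm = confusion(pred, t, "nontransition")
    keep = ~mark_transitions(t)
    sub_truth = [a for a, k in zip(truth, keep) if k]
    sub_pred = [a for a, k in zip(pred, keep) if k]
    oracle = confusion(sub_pred, truth_of(sub_truth), "all", area_ids=["A", "B"])
    assert np.allclose(cm.to_numpy(), oracle.to_numpy())


def test_rows_sum_to_one_when_observed():
    rng = np.random.default_rng(3)
    truth = ["ABC"[i] for i in rng.integers(0, 3, 50)]
    pred = ["ABC"[i] for i in rng.integers(0, 3, 50)]
    cm = confusion(pred, truth_of(truth))
    assert np.allclose(cm.sum(axis=1), 1.0)


def test_diagonal_mean_complements_error_rate():
    rng = np.random.default_rng(14)
    truth = ["AB"[i] for i in rng.integers(0, 2, 200)]
    pred = ["AB"[i] for i in rng.integers(0, 2, 200)]
    t = truth_of(truth)
    cm = confusion(pred, t, "all")
    # time-weighted diagonal equals overall accuracy for the same epochs
    acc = np.mean([p == a for p, a in zip(pred, truth)])
    weights = pd.Series(truth).value_counts(normalize=True)
    diag = sum(cm.loc[a, a] * weights[a] for a in weights.index)
    assert diag == pytest.approx(acc)
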