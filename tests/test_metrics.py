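"""Confusion matrices, one-vs-rest metrics in both modes, macro aggregates,
and the Wilcoxon signed-rank test against brute-force enumeration."""

import itertools

import numpy as np
import pytest
import scipy.stats

from riboclass import (
    confusion_matrix,
    per_class_metrics,
    significance_stars,
    wilcoxon_signed_rank,
)


def test_confusion_matrix_hand_count():
    cm = confusion_matrix(list("AABC"), list("ABBB"), families=list("ABC"))
    assert cm.loc["A", "A"] == 1 and cm.loc["A", "B"] == 1
    assert cm.loc["B", "B"] == 1 and cm.loc["C", "B"] == 1
    assert cm.to_numpy().sum() == 4
    # diagonal for perfect predictions
    cm2 = confusion_matrix(list("ABC"), list("ABC"))
    assert np.array_equal(cm2.to_numpy(), np.eye(3, dtype=int))


def test_confusion_matrix_errors():
    with pytest.raises(ValueError, match="length"):
        confusion_matrix(["A"], ["A", "B"])
    with pytest.raises(ValueError, match="not in the family list"):
        confusion_matrix(["A"], ["Z"], families=["A", "B"])


def _binary_cm(tp, fp, fn, tn):
    """Two-family confusion matrix with the given one-vs-rest counts for 'pos'."""
    return confusion_matrix(
        ["pos"] * (tp + fn) + ["neg"] * (fp + tn),
        ["pos"] * tp + ["neg"] * fn + ["pos"] * fp + ["neg"] * tn,
        families=["pos", "neg"],
    )


def test_standard_mode_hand_arithmetic():
    table = per_class_metrics(_binary_cm(9, 1, 1, 89), mode="standard").table
    row = table.loc["pos"]
    assert (row["TP"], row["FP"], row["FN"], row["TN"]) == (9, 1, 1, 89)
    assert row["sensitivity"] == pytest.approx(0.9)
    assert row["specificity"] == pytest.approx(89 / 90)
    assert row["accuracy"] == pytest.approx(0.98)
    assert row["f_score"] == pytest.approx(0.9)


def test_one_vs_rest_counts_conserve_total(rng):
    y_true = rng.choice(list("ABCD"), 200)
    y_pred = rng.choice(list("ABCD"), 200)
    table = per_class_metrics(confusion_matrix(y_true, y_pred)).table
    assert ((table[["TP", "FP", "FN", "TN"]].sum(axis=1)) == 200).all()


def test_macro_f_is_arithmetic_mean():
    # family A: F=0.8 (TP=2, FP=FN=1 within a 3-family layout), contrived small case
    cm = confusion_matrix(
        ["A", "A", "A", "B", "B"], ["A", "A", "B", "B", "B"], families=["A", "B"]
    )
    mt = per_class_metrics(cm)
    per_f = mt.table["f_score"]
    assert mt.macro_f == pytest.approx(per_f.mean())


def test_perfect_predictions_all_ones():
    cm = confusion_matrix(list("AABBB"), list("AABBB"))
    mt = per_class_metrics(cm, mode="standard")
    assert (mt.table[["accuracy", "sensitivity", "specificity", "f_score"]] == 1.0).all().all()
    assert mt.macro_f == 1.0 and not mt.out_of_range
    # the verbatim-formula mode shares accuracy/sensitivity/F but its
    # specificity TN/(TP+FN) deviates from 1 whenever TN != TP+FN
    with pytest.warns(UserWarning):
        paper = per_class_metrics(cm, mode="paper")
    assert (paper.table[["accuracy", "sensitivity", "f_score"]] == 1.0).all().all()
    assert paper.table.loc["A", "specificity"] == pytest.approx(3 / 2)


def test_paper_mode_formulas_verbatim_and_flagged():
    # TP=9, FP=1, FN=1, TN=89: printed specificity TN/(TP+FN) = 8.9 > 1
    with pytest.warns(UserWarning, match="exceeded 1"):
        mt = per_class_metrics(_binary_cm(9, 1, 1, 89), mode="paper")
    row = mt.table.loc["pos"]
    assert row["sensitivity"] == pytest.approx(9 / 10)  # TP/(TP+FP)
    assert row["specificity"] == pytest.approx(89 / 10)  # TN/(TP+FN), unclipped
    assert "pos" in mt.out_of_range


def test_absent_family_zero_over_zero_is_zero():
    cm = confusion_matrix(["A", "A"], ["A", "A"], families=["A", "ghost"])
    row = per_class_metrics(cm).table.loc["ghost"]
    assert row["sensitivity"] == 0.0 and row["f_score"] == 0.0
    assert row["specificity"] == 1.0  # TN=2, FP=0


# -- Wilcoxon --

def brute_force_wilcoxon(d):
    """Enumerate all 2^n sign assignments of the ranked |d|."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p_le = (ws <= w_obs + 1e-9).mean()
    p_ge = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(p_le, p_ge))


def test_wilcoxon_all_positive_n5():
    stat, p = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
    assert stat == 0.0 and p == pytest.approx(1 / 16)


def test_wilcoxon_identical_vectors_degenerate():
    with pytest.warns(UserWarning, match="degenerate"):
        stat, p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (stat, p) == (0.0, 1.0)


@pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8, 9, 10])
def test_wilcoxon_matches_brute_force(n):
    rng = np.random.default_rng(n)
    for _ in range(5):
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(brute_force_wilcoxon(a - b), abs=1e-12)


def test_wilcoxon_symmetry_and_scipy_agreement(rng):
    a = rng.normal(size=12)
    b = rng.normal(size=12)
    _, p_ab = wilcoxon_signed_rank(a, b)
    _, p_ba = wilcoxon_signed_rank(b, a)
    assert p_ab == pytest.approx(p_ba)
    ref = scipy.stats.wilcoxon(a, b, method="exact")
    assert p_ab == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_large_n_normal_approximation(rng):
    a = rng.normal(size=60)
    b = a + rng.normal(loc=0.5, size=60)
    _, p = wilcoxon_signed_rank(a, b)
    ref = scipy.stats.wilcoxon(a, b, method="approx", correction=False)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_significance_stars():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.2) == "ns"
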