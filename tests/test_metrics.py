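"""Confusion-matrix metrics, including the published worked examples."""

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from csbnet.metrics import accuracy_from_correct_counts, confusion, score


def test_perfect_prediction_is_diagonal():
    y = np.repeat(np.arange(5), 2)
    cm = confusion(y, y, 5)
    assert np.array_equal(cm.counts, np.diag(np.bincount(y)))
    assert cm.total == 10
    rep = score(cm)
    assert rep.accuracy == 1.0
    assert np.allclose(rep.precision, 1.0) and np.allclose(rep.f1, 1.0)


def test_single_predicted_class_single_column():
    t = np.array([0, 1, 2, 1, 0])
    p = np.zeros(5, dtype=int)
    cm = confusion(t, p, 3)
    assert cm.counts[:, 0].sum() == 5
    assert cm.counts[:, 1:].sum() == 0


def test_three_class_hand_tally():
    t = [0, 0, 1, 2, 2, 1]
    p = [0, 1, 1, 2, 0, 1]
    cm = confusion(t, p, 3)
    expected = np.array([[1, 1, 0], [0, 2, 0], [1, 0, 1]])
    assert np.array_equal(cm.counts, expected)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion([0, 1], [0], 2)


def test_two_class_hand_arithmetic():
    cm = confusion(
        np.repeat([0, 1], 10),
        np.array([0] * 8 + [1] * 2 + [0] * 3 + [1] * 7),
        2,
    )
    assert np.array_equal(cm.counts, [[8, 2], [3, 7]])
    rep = score(cm)
    assert rep.accuracy == pytest.approx(0.75)
    assert rep.precision[0] == pytest.approx(8 / 11)
    assert rep.recall[0] == pytest.approx(0.8)


@pytest.mark.parametrize(
    "correct,total,expected_pct",
    [
        # per-class correct counts over the 816 validated samples
        ([103, 163, 232, 288], 816, 96.32),  # SE attention
        ([100, 157, 232, 288], 816, 95.22),  # ECA
        ([95, 164, 232, 288], 816, 95.47),  # CBAM
        ([38, 166, 231, 281], 816, 87.75),  # reference backbone + SE
        ([34, 172, 216, 267], 816, 84.44),  # reference backbone + ECA
        ([45, 164, 215, 280], 816, 86.27),  # reference backbone + CBAM
    ],
)
def test_published_worked_example_accuracies(correct, total, expected_pct):
    acc = accuracy_from_correct_counts(correct, total)
    assert round(acc * 100, 2) == expected_pct


def test_worked_example_through_confusion_matrix():
    # A full matrix with the published diagonal (103, 163, 232, 288) and the
    # remaining 30 of 816 samples placed off-diagonal; the accuracy must come
    # out at 96.32% regardless of where the errors land.
    diag = [103, 163, 232, 288]
    errors = [1, 20, 6, 3]
    counts = np.zeros((4, 4), dtype=int)
    for i, (d, e) in enumerate(zip(diag, errors)):
        counts[i, i] = d
        counts[i, (i + 1) % 4] = e
    from csbnet.metrics import ConfusionMatrix

    cm = ConfusionMatrix(counts, ["GLS", "NLB", "Rust", "Healthy"])
    assert cm.total == 816
    assert round(score(cm).accuracy * 100, 2) == 96.32


def test_zero_denominator_reports_zero_with_warning():
    cm = confusion([0, 0, 1], [0, 0, 0], 3)
    with pytest.warns(UserWarning):
        rep = score(cm)
    assert rep.precision[2] == 0.0 and rep.recall[2] == 0.0 and rep.f1[2] == 0.0


def test_agreement_with_sklearn_on_random_matrices():
    rng = np.random.default_rng(123)
    for _ in range(100):
        k = int(rng.integers(2, 6))
        n = int(rng.integers(5, 60))
        t = rng.integers(0, k, n)
        p = rng.integers(0, k, n)
        cm = confusion(t, p, k)
        assert np.array_equal(cm.counts, sk_confusion(t, p, labels=range(k)))
        rep = score(cm)
        prec, rec, f1, _ = precision_recall_fscore_support(
            t, p, labels=range(k), zero_division=0
        )
        assert np.allclose(rep.precision, prec)
        assert np.allclose(rep.recall, rec)
        assert np.allclose(rep.f1, f1)
        assert rep.accuracy == pytest.approx((t == p).mean())
        assert rep.macro_f1 == pytest.approx(f1.mean())


def test_class_permutation_invariance():
    rng = np.random.default_rng(5)
    t = rng.integers(0, 4, 50)
    p = rng.integers(0, 4, 50)
    perm = np.array([2, 0, 3, 1])
    rep = score(confusion(t, p, 4))
    rep_p = score(confusion(perm[t], perm[p], 4))
    assert rep_p.accuracy == pytest.approx(rep.accuracy)
    assert rep_p.macro_f1 == pytest.approx(rep.macro_f1)
    inv = np.argsort(perm)
    assert np.allclose(rep_p.precision[perm], rep.precision)


def test_f1_is_harmonic_mean():
    rng = np.random.default_rng(9)
    rep = score(confusion(rng.integers(0, 3, 60), rng.integers(0, 3, 60), 3))
    for p, r, f in zip(rep.precision, rep.recall, rep.f1):
        if p + r > 0:
            assert f == pytest.approx(2 * p * r / (p + r))


def test_report_writers(tmp_path):
    rep = score(confusion([0, 1, 1, 0], [0, 1, 0, 0], 2, ["x", "y"]))
    rep.to_csv(tmp_path / "m.csv")
    out = rep.to_json(tmp_path / "m.json")
    assert (tmp_path / "m.csv").exists()
    import json

    data = json.loads(out)
    assert data["accuracy"] == pytest.approx(0.75)
    assert set(data["per_class"]) == {"x", "y"}
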