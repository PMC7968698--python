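"""Confusion matrices and the accuracy/precision/recall/F1 formulas."""

import numpy as np
import pytest

from trapnet.evaluate import confusion, export_misclassified, metrics
from trapnet.labels import CATEGORIES_4, CATEGORIES_5, merge_label, reduce_confusion


def tally_oracle(true, pred, cats):
    table = {(a, b): 0 for a in cats for b in cats}
    for t, p in zip(true, pred):
        table[(t, p)] += 1
    out = np.zeros((len(cats), len(cats)), dtype=int)
    for i, a in enumerate(cats):
        for j, b in enumerate(cats):
            out[i, j] = table[(a, b)]
    return out


def metrics_oracle(c):
    """Independent per-cell arithmetic for the one-vs-rest metrics."""
    total = c.sum()
    out = {}
    for i in range(c.shape[0]):
        tp = c[i, i]
        fp = c[:, i].sum() - tp
        fn = c[i, :].sum() - tp
        tn = total - tp - fp - fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[i] = ((tp + tn) / total, prec, rec, f1)
    return out


def test_confusion_perfect_predictions_diagonal():
    labels = [c for c in CATEGORIES_5 for _ in range(3)]
    c = confusion(labels, labels, space=5)
    assert np.array_equal(c, np.eye(5, dtype=int) * 3)


def test_confusion_single_offdiagonal():
    c = confusion(["mC"], ["nC"], space=5)
    assert c.sum() == 1
    assert c[CATEGORIES_5.index("mC"), CATEGORIES_5.index("nC")] == 1


def test_confusion_matches_tally_oracle(rng):
    true = rng.choice(CATEGORIES_5, size=500)
    pred = rng.choice(CATEGORIES_5, size=500)
    np.testing.assert_array_equal(
        confusion(true, pred, space=5), tally_oracle(true, pred, CATEGORIES_5)
    )
    true4 = [merge_label(l) for l in true]
    pred4 = [merge_label(l) for l in pred]
    np.testing.assert_array_equal(
        confusion(true4, pred4, space=4), tally_oracle(true4, pred4, CATEGORIES_4)
    )


def test_confusion_rejects_bad_inputs():
    with pytest.raises(ValueError):
        confusion(["nC"], ["nC", "mC"], space=5)
    with pytest.raises(ValueError):
        confusion(["mdC"], ["mdC"], space=5)  # 4-space label in 5-space


def test_metrics_printed_recall_fraction():
    """TP = 354 of 360 mother-daughter traps recovered: recall 354/360."""
    c = np.zeros((4, 4), dtype=int)
    mdc = CATEGORIES_4.index("mdC")
    c[mdc, mdc] = 354
    c[mdc, CATEGORIES_4.index("mC")] = 6      # the 6 false negatives
    c[0, 0] = 100
    rep = metrics(c)
    assert rep.per_category.loc["mdC", "recall"] == pytest.approx(354 / 360, abs=1e-9)
    assert rep.per_category.loc["mdC", "recall"] == pytest.approx(0.9833, abs=5e-5)


def test_metrics_f1_from_precision_recall():
    # F1 of precision 0.71 / recall 0.66 is 2PR/(P+R) ~ 0.6841
    p, r = 0.71, 0.66
    assert 2 * p * r / (p + r) == pytest.approx(0.6841, abs=5e-5)
    # the same harmonic mean must come out of the report on a matching table
    c = np.zeros((4, 4), dtype=int)
    mc = CATEGORIES_4.index("mC")
    c[mc, mc] = 66          # recall 66/100
    c[mc, 0] = 34
    c[0, mc] = 27           # precision 66/93 ~ 0.7097
    c[0, 0] = 500
    rep = metrics(c)
    assert rep.per_category.loc["mC", "recall"] == pytest.approx(0.66, abs=1e-9)
    assert rep.per_category.loc["mC", "precision"] == pytest.approx(66 / 93, abs=1e-9)
    f1 = rep.per_category.loc["mC", "f1"]
    prec = 66 / 93
    assert f1 == pytest.approx(2 * prec * 0.66 / (prec + 0.66), abs=1e-9)


def test_metrics_diagonal_all_ones():
    rep = metrics(np.eye(5, dtype=int) * 7)
    assert rep.overall_accuracy == 1.0
    assert (rep.per_category == 1.0).all().all()


def test_metrics_match_oracle_on_random_matrices(rng):
    for _ in range(100):
        size = rng.choice([4, 5])
        c = rng.integers(0, 30, size=(size, size))
        if c.sum() == 0:
            continue
        rep = metrics(c)
        cats = CATEGORIES_5 if size == 5 else CATEGORIES_4
        oracle = metrics_oracle(c)
        for i, cat in enumerate(cats):
            acc, prec, rec, f1 = oracle[i]
            row = rep.per_category.loc[cat]
            assert row["accuracy"] == pytest.approx(acc, abs=1e-12)
            assert row["precision"] == pytest.approx(prec, abs=1e-12)
            assert row["recall"] == pytest.approx(rec, abs=1e-12)
            assert row["f1"] == pytest.approx(f1, abs=1e-12)
        assert rep.overall_accuracy == pytest.approx(np.trace(c) / c.sum(), abs=1e-12)


def test_metrics_zero_denominator_flagged():
    c = np.zeros((4, 4), dtype=int)
    c[0, 0] = 10  # categories 1-3 never occur and are never predicted
    rep = metrics(c)
    assert rep.per_category.loc["mC", "precision"] == 0.0
    assert ("mC", "precision") in rep.undefined


def test_metrics_rejects_empty():
    with pytest.raises(ValueError):
        metrics(np.zeros((4, 4), dtype=int))


def test_merge_then_metrics_end_to_end(rng):
    true = list(rng.choice(CATEGORIES_5, size=300))
    pred = list(rng.choice(CATEGORIES_5, size=300))
    c5 = confusion(true, pred, space=5)
    acc5 = metrics(c5).overall_accuracy
    acc4 = metrics(reduce_confusion(c5)).overall_accuracy
    assert acc4 >= acc5


def test_export_misclassified(tmp_path, small_easy_dataset):
    ds = small_easy_dataset.take(range(6))
    pred = list(ds.labels)
    pred[0] = "exC" if pred[0] != "exC" else "nC"        # one 4-space error
    swap = {"mduC": "mddC", "mddC": "mduC"}
    pred[1] = swap.get(pred[1], pred[1])                 # orientation-only: not an error
    man = export_misclassified(ds, pred, tmp_path)
    true4 = [merge_label(l) for l in ds.labels]
    pred4 = [merge_label(l) for l in pred]
    c4 = confusion(true4, pred4, space=4)
    off_diag = c4.sum() - np.trace(c4)
    assert len(man) == off_diag == 1
    assert (tmp_path / man.iloc[0]["path"]).exists()

    perfect = export_misclassified(ds, list(ds.labels), tmp_path / "none")
    assert len(perfect) == 0
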