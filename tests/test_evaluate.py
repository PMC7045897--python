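"""Metrics, cross-validation and rank-test oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from deuseg import (
    ConfusionCounts,
    confusion_counts,
    dsc,
    kfold_split,
    mann_whitney_u,
    precision,
    sensitivity,
)


# ---------------------------------------------------------------------------
# confusion counts


def test_identical_masks():
    gold = np.zeros((4, 5, 5), dtype=np.uint8)
    gold[1, 1:3, 1:6] = 1
    assert gold.sum() == 8
    c = confusion_counts(gold, gold)
    assert (c.tp, c.fp, c.fn, c.tn) == (8, 0, 0, 92)
    assert c.total == gold.size


def test_empty_prediction():
    gold = np.zeros((10, 10), dtype=np.uint8)
    gold.flat[:10] = 1
    c = confusion_counts(np.zeros_like(gold), gold)
    assert (c.tp, c.fn) == (0, 10)


def test_confusion_counts_match_per_voxel_loop():
    rng = np.random.default_rng(9)
    pred = (rng.random((4, 6, 6)) > 0.5).astype(np.uint8)
    gold = (rng.random((4, 6, 6)) > 0.5).astype(np.uint8)
    c = confusion_counts(pred, gold)
    tp = fp = fn = tn = 0
    for idx in np.ndindex(pred.shape):
        if pred[idx] and gold[idx]:
            tp += 1
        elif pred[idx]:
            fp += 1
        elif gold[idx]:
            fn += 1
        else:
            tn += 1
    assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)


def test_shape_and_binarity_validation():
    with pytest.raises(ValueError):
        confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ValueError):
        confusion_counts(np.full((2, 2), 2), np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# metric formulas


def test_dsc_direct_evaluation():
    assert dsc(ConfusionCounts(tp=3, fp=1, fn=1, tn=0)) == pytest.approx(0.75)


def test_dsc_extremes_and_empty_convention():
    assert dsc(ConfusionCounts(tp=5, fp=0, fn=0, tn=5)) == 1.0
    assert dsc(ConfusionCounts(tp=0, fp=3, fn=4, tn=0)) == 0.0
    assert dsc(ConfusionCounts(tp=0, fp=0, fn=0, tn=10)) == 1.0


def test_sensitivity_values():
    assert sensitivity(ConfusionCounts(tp=8, fp=0, fn=2, tn=0)) == pytest.approx(0.8)
    assert sensitivity(ConfusionCounts(tp=4, fp=0, fn=0, tn=0)) == 1.0
    assert sensitivity(ConfusionCounts(tp=0, fp=0, fn=5, tn=0)) == 0.0
    assert math.isnan(sensitivity(ConfusionCounts(tp=0, fp=2, fn=0, tn=2)))


def test_precision_values():
    assert precision(ConfusionCounts(tp=8, fp=2, fn=0, tn=0)) == pytest.approx(0.8)
    assert precision(ConfusionCounts(tp=4, fp=0, fn=0, tn=0)) == 1.0
    assert precision(ConfusionCounts(tp=0, fp=5, fn=0, tn=0)) == 0.0
    assert math.isnan(precision(ConfusionCounts(tp=0, fp=0, fn=3, tn=2)))


@given(tp=st.integers(1, 500), fp=st.integers(0, 500), fn=st.integers(0, 500))
@settings(deadline=None, max_examples=200)
def test_dsc_is_harmonic_mean_of_sensitivity_and_precision(tp, fp, fn):
    c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0)
    s, p = sensitivity(c), precision(c)
    assert dsc(c) == pytest.approx(2 * s * p / (s + p), abs=1e-12)


# ---------------------------------------------------------------------------
# cross-validation


def test_kfold_44_patients_10_folds_sizes():
    ids = [f"p{i:02d}" for i in range(44)]
    folds = kfold_split(ids, 10, seed=0)
    sizes = sorted(len(te) for _, te in folds)
    assert sizes == [4] * 6 + [5] * 4
    all_test = [pid for _, te in folds for pid in te]
    assert sorted(all_test) == sorted(ids)          # each patient exactly once
    for tr, te in folds:
        assert not set(tr) & set(te)                # patient-disjoint


def test_kfold_leave_one_out_and_determinism():
    ids = [f"p{i}" for i in range(6)]
    folds = kfold_split(ids, 6, seed=3)
    assert all(len(te) == 1 for _, te in folds)
    assert kfold_split(ids, 3, seed=7) == kfold_split(ids, 3, seed=7)
    assert kfold_split(ids, 3, seed=7) != kfold_split(ids, 3, seed=8)


def test_kfold_validation():
    with pytest.raises(ValueError):
        kfold_split(["a", "b"], 3, seed=0)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _exact_oracle(a, b):
    """Exhaustive enumeration over all group assignments of the pooled sample."""
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    obs = u_of(range(n1))
    us = np.array([u_of(c) for c in itertools.combinations(range(n1 + n2), n1)])
    p = min(1.0, 2 * min((us >= obs).mean(), (us <= obs).mean()))
    return obs, p


def test_identical_samples_give_p_one():
    _, p = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert p == pytest.approx(1.0, abs=0.05)


def test_extreme_separation_gives_u_zero():
    u, p = mann_whitney_u([1, 2, 3], [10, 11, 12])
    assert u == 0.0
    assert p < 0.2  # n=3 vs 3: the most extreme assignment, p = 0.1


def test_matches_exact_permutation_enumeration():
    rng = np.random.default_rng(17)
    for _ in range(10):
        a = rng.normal(size=int(rng.integers(3, 8)))
        b = rng.normal(size=int(rng.integers(3, 8)))
        u, p = mann_whitney_u(a, b)
        u_o, p_o = _exact_oracle(a, b)
        assert p == pytest.approx(p_o, abs=1e-9)
        assert u == min(u_o, len(a) * len(b) - u_o)


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])
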