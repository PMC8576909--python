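"""Losses and evaluation metrics against hand-computed and brute-force oracles."""

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lungnodule as ln
from lungnodule.losses import bce_loss, dice_loss, dice_loss_grad, dice_grad_reference, nll_loss
from lungnodule.metrics import ConfusionMatrix
from lungnodule import nn


def _mask_pair(overlap, p_only, t_only, shape=(4, 8, 8)):
    """Binary masks with the given overlap / exclusive voxel counts."""
    P = np.zeros(shape); T = np.zeros(shape)
    flat_p, flat_t = P.ravel(), T.ravel()
    flat_p[:overlap] = 1
    flat_t[:overlap] = 1
    flat_t[overlap:overlap + t_only] = 1
    flat_p[overlap + t_only:overlap + t_only + p_only] = 1
    return P, T


# -------------------------------------------------------------- Dice family

def test_dice_loss_hand_counted_cases():
    P, T = _mask_pair(overlap=50, p_only=0, t_only=50)   # |P|=50,|T|=100,∩=50
    assert dice_loss(P, T, smooth=0) == pytest.approx(1 / 3)
    same = np.zeros((3, 3, 3)); same[1] = 1
    assert dice_loss(same, same, smooth=0) == 0.0
    Pd, Td = _mask_pair(overlap=0, p_only=5, t_only=5)
    assert dice_loss(Pd, Td, smooth=0) == 1.0
    with pytest.raises(ValueError, match="empty"):
        dice_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)), smooth=0)


def test_dice_coefficient_precision_recall_hand_counts():
    P, T = _mask_pair(overlap=50, p_only=0, t_only=50)
    assert ln.dice_coefficient(P, T) == pytest.approx(2 / 3)
    P2, T2 = _mask_pair(overlap=40, p_only=10, t_only=60)  # |P|=50,|T|=100
    assert ln.precision(P2, T2) == pytest.approx(0.8)
    assert ln.recall(P2, T2) == pytest.approx(0.4)
    assert np.isnan(ln.precision(np.zeros((2, 2, 2)), T2[:2, :2, :2]))
    assert np.isnan(ln.recall(P2[:2, :2, :2], np.zeros((2, 2, 2))))


def test_dice_loss_gradient_matches_finite_differences(rng):
    P = rng.uniform(0.01, 0.99, size=(3, 4, 4))
    T = (rng.random((3, 4, 4)) < 0.3).astype(float)
    g = dice_loss_grad(P, T)
    for idx in [(0, 0, 0), (1, 2, 3), (2, 1, 1)]:
        eps = 1e-7
        Pp, Pm = P.copy(), P.copy()
        Pp[idx] += eps; Pm[idx] -= eps
        num = (dice_loss(Pp, T) - dice_loss(Pm, T)) / (2 * eps)
        assert g[idx] == pytest.approx(num, abs=1e-6)


def test_dice_grad_reference_printed_values():
    assert dice_grad_reference(np.array([0.5]), np.array([1.0]))[0] == pytest.approx(1.2)
    assert dice_grad_reference(np.array([1.0]), np.array([1.0]))[0] == 0.0
    assert dice_grad_reference(np.array([0.5]), np.array([0.0]))[0] == 0.0
    assert dice_grad_reference(np.array([0.0]), np.array([0.0]))[0] == 0.0  # limit


def test_dice_grad_reference_is_squared_denominator_derivative(rng):
    """The closed form equals d/dP of the voxelwise 2PT/(P^2+T^2) once the
    omitted denominator square is restored."""
    P = rng.uniform(0.05, 0.95, size=50)
    T = (rng.random(50) < 0.5).astype(float)
    ref = dice_grad_reference(P, T) / (P ** 2 + T ** 2)
    eps = 1e-7

    def soft_dice(p, t):
        return 2 * p * t / (p ** 2 + t ** 2) if (p or t) else 0.0

    num = np.array([(soft_dice(p + eps, t) - soft_dice(p - eps, t)) / (2 * eps)
                    for p, t in zip(P, T)])
    np.testing.assert_allclose(ref, num, atol=1e-6)


@given(st.integers(0, 2 ** 32 - 1))
def test_dice_identities_on_random_masks(seed):
    r = np.random.default_rng(seed)
    P = (r.random((4, 6, 6)) < 0.4).astype(np.uint8)
    T = (r.random((4, 6, 6)) < 0.4).astype(np.uint8)
    if not P.any() or not T.any():
        return
    d = ln.dice_coefficient(P, T)
    pr, rc = ln.precision(P, T), ln.recall(P, T)
    if pr + rc > 0:
        assert d == pytest.approx(2 * pr * rc / (pr + rc))
    assert dice_loss(P, T, smooth=0) + d == pytest.approx(1.0)


# ---------------------------------------------------------------------- BCE

def test_bce_single_voxel_value():
    assert bce_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(np.log(2))
    assert bce_loss(np.array([[0.3]]), np.array([[0.0]])) == pytest.approx(-np.log(0.7))
    assert bce_loss(np.array([1.0]), np.array([1.0])) == pytest.approx(0.0, abs=1e-5)


def test_bce_logit_gradient_is_p_minus_t(rng):
    z = rng.normal(size=20)
    T = (rng.random(20) < 0.5).astype(float)
    P = nn.sigmoid(z)
    analytic = ln.bce_grad_logits(P, T)
    eps = 1e-6
    num = np.array([
        (bce_loss(nn.sigmoid(np.array([zi + eps])), np.array([ti]))
         - bce_loss(nn.sigmoid(np.array([zi - eps])), np.array([ti]))) / (2 * eps)
        for zi, ti in zip(z, T)])
    np.testing.assert_allclose(analytic, num, atol=1e-6)
    # the printed example: P=0.7, T=1 -> gradient -0.3
    assert ln.bce_grad_logits(np.array([0.7]), np.array([1.0]))[0] == pytest.approx(-0.3)


# ---------------------------------------------------------------------- NLL

def test_nll_examples_and_batch_mean():
    assert nll_loss([[1.0, 0.0]], [[1, 0]]) == pytest.approx(0.0, abs=1e-9)
    assert nll_loss([[0.8, 0.2]], [[1, 0]]) == pytest.approx(-np.log(0.8))
    batch = nll_loss([[1.0, 0.0], [0.8, 0.2]], [[1, 0], [1, 0]])
    assert batch == pytest.approx(-np.log(0.8) / 2)


def test_nll_clips_zero_probability_with_warning():
    with pytest.warns(UserWarning, match="clip"):
        v = nll_loss([[0.0, 1.0]], [[1, 0]])
    assert np.isfinite(v)


# --------------------------------------------------- confusion-matrix ratios

def test_classification_metrics_published_test_set():
    """209 malignant / 191 benign with 41 false negatives and 10 false
    positives reproduces the published accuracy/recall/specificity row
    after half-up rounding to one decimal."""
    cm = ConfusionMatrix(tp=168, fp=10, tn=181, fn=41)
    acc, rec, spec = ln.classification_metrics(cm)
    assert acc == pytest.approx(0.8725)
    assert rec == pytest.approx(168 / 209)
    assert spec == pytest.approx(181 / 191)

    def pct(x):
        return float(Decimal(x * 100).quantize(Decimal("0.1"), ROUND_HALF_UP))

    assert pct(acc) == 87.3
    assert pct(rec) == 80.4
    assert pct(spec) == 94.8


def test_classification_metrics_degenerate_cases():
    assert ln.classification_metrics(ConfusionMatrix(1, 0, 1, 0)) == (1, 1, 1)
    acc, rec, spec = ln.classification_metrics(ConfusionMatrix(0, 1, 0, 1))
    assert (acc, rec, spec) == (0, 0, 0)
    with pytest.raises(ValueError):
        ConfusionMatrix(0, 0, 0, 0)
    with pytest.raises(ValueError):
        ConfusionMatrix(-1, 0, 1, 0)


# ----------------------------------------------------------------- ROC/AUC

def brute_force_auc(scores, labels):
    """Pairwise rank statistic with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_canonical_cases():
    assert ln.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])[2] == pytest.approx(1.0)
    assert ln.roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])[2] == pytest.approx(0.75)
    interleaved = ln.roc_auc([0.8, 0.7, 0.6, 0.5, 0.4, 0.3], [1, 0, 1, 0, 1, 0])[2]
    assert interleaved == pytest.approx(brute_force_auc(
        [0.8, 0.7, 0.6, 0.5, 0.4, 0.3], [1, 0, 1, 0, 1, 0]))
    with pytest.raises(ValueError, match="both classes"):
        ln.roc_auc([0.5, 0.6], [1, 1])


@given(st.integers(0, 2 ** 32 - 1), st.integers(2, 20))
def test_auc_equals_pairwise_oracle(seed, n):
    r = np.random.default_rng(seed)
    scores = np.round(r.random(n), 1)  # coarse grid forces ties
    labels = r.integers(0, 2, size=n)
    if labels.min() == labels.max():
        return
    _, _, auc = ln.roc_auc(scores, labels)
    assert auc == pytest.approx(brute_force_auc(scores, labels))


def test_auc_agrees_with_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    scores = rng.random(50)
    labels = rng.integers(0, 2, size=50)
    labels[0], labels[1] = 0, 1
    assert ln.roc_auc(scores, labels)[2] == pytest.approx(
        roc_auc_score(labels, scores))


def test_roc_curve_endpoints_and_monotonicity(rng):
    scores = rng.random(30)
    labels = rng.integers(0, 2, size=30)
    labels[:2] = [0, 1]
    fpr, tpr = ln.roc_curve(scores, labels)
    assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
    assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
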