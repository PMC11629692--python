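"""Bilinear classifier, adaptive-threshold loss, decoding, metrics."""

import numpy as np
import pytest

from htgrs import (
    ClassifierParams,
    PairLogits,
    TH,
    atl_loss,
    classify_pair,
    compute_metrics,
    decode,
)
from htgrs._tensor import Adam, Parameter, Tensor
from htgrs.head_loss_metrics import classify_pairs

from conftest import make_doc

LABELS = ("r1", "r2", "r3")


def make_params(d=6, seed=0):
    return ClassifierParams(LABELS, d).initialize(seed)


def make_logits(rows, pairs=None, labels=LABELS, grad=False):
    arr = np.asarray(rows, dtype=float)
    pairs = pairs or [(f"h{i}", f"t{i}") for i in range(arr.shape[0])]
    t = Parameter(arr) if grad else Tensor(arr)
    return PairLogits(pairs, labels, t)


# ---------------------------------------------------------------------------
# classifier


def test_zero_maps_give_bias_logits(rng):
    params = make_params()
    params.w_head = Parameter(np.zeros((6, 6)))
    params.w_tail = Parameter(np.zeros((6, 6)))
    params.bias = Parameter(rng.normal(size=4))
    out = classify_pair(Tensor(rng.normal(size=6)), Tensor(rng.normal(size=6)),
                        Tensor(np.zeros(6)), params)
    assert np.allclose(out.data, params.bias.data)


def test_zero_bilinear_equal_bias_gives_uniform_logits(rng):
    params = make_params()
    params.w_bil = Parameter(np.zeros((4, 6, 6)))
    params.bias = Parameter(np.full(4, 0.7))
    out = classify_pair(*(Tensor(rng.normal(size=6)) for _ in range(3)), params)
    assert np.allclose(out.data, 0.7)


def test_classifier_matches_per_label_loop(rng):
    params = make_params(seed=3)
    e_s, e_o, m_so = (rng.normal(size=6) for _ in range(3))
    out = classify_pair(Tensor(e_s), Tensor(e_o), Tensor(m_so), params)
    z_s = np.tanh(params.w_head.data @ e_s + m_so)
    z_o = np.tanh(params.w_tail.data @ e_o + m_so)
    for r in range(4):
        expect = z_s @ params.w_bil.data[r] @ z_o + params.bias.data[r]
        assert np.isclose(out.data[r], expect, atol=1e-6)


def test_classifier_probabilities_are_sigmoid(rng):
    params = make_params(seed=1)
    args = [Tensor(rng.normal(size=6)) for _ in range(3)]
    raw = classify_pair(*args, params).data
    prob = classify_pair(*args, params, probabilities=True).data
    assert np.allclose(prob, 1 / (1 + np.exp(-raw)))


def test_classifier_rejects_dimension_mismatch(rng):
    with pytest.raises(ValueError, match="d=6"):
        classify_pair(Tensor(np.zeros(5)), Tensor(np.zeros(6)),
                      Tensor(np.zeros(6)), make_params())


# ---------------------------------------------------------------------------
# adaptive-threshold loss


def test_atl_empty_positive_set_is_pure_l2():
    # P_T empty: L1 = 0 exactly; with all negatives far below TH, L2 -> 0
    lg = make_logits([[-50.0, -50.0, -50.0, 0.0]])
    loss = atl_loss(lg, {})
    assert np.isclose(loss.item(), 0.0, atol=1e-9)


def test_atl_two_way_tie_gives_log_two():
    # one positive with logit equal to TH, negatives at -inf mass
    lg = make_logits([[1.0, -1e30, -1e30, 1.0]])
    loss = atl_loss(lg, {("h0", "t0"): {"r1"}})
    assert np.isclose(loss.item(), np.log(2.0), atol=1e-9)


def naive_atl(rows, pos_sets, labels=LABELS):
    total = 0.0
    for row, pos in zip(rows, pos_sets):
        th = row[-1]
        l1 = 0.0
        for r in pos:
            idx = labels.index(r)
            denom = [row[labels.index(p)] for p in pos] + [th]
            l1 -= row[idx] - np.log(np.sum(np.exp(denom)))
        neg = [row[i] for i, lab in enumerate(labels) if lab not in pos]
        l2 = -(th - np.log(np.sum(np.exp(neg + [th]))))
        total += l1 + l2
    return total / len(rows)


def test_atl_matches_naive_softmax_oracle(rng):
    rows = rng.normal(size=(6, 4))
    pos_sets = [set(), {"r1"}, {"r2", "r3"}, {"r1", "r2", "r3"}, {"r3"}, set()]
    lg = make_logits(rows)
    gold = {pair: pos for pair, pos in zip(lg.pairs, pos_sets) if pos}
    assert np.isclose(atl_loss(lg, gold).item(),
                      naive_atl(rows, pos_sets), atol=1e-6)


def test_atl_decreases_when_positive_logit_raised(rng):
    rows = rng.normal(size=(3, 4))
    lg = make_logits(rows.copy())
    gold = {lg.pairs[0]: {"r2"}, lg.pairs[2]: {"r1"}}
    base = atl_loss(lg, gold).item()
    bumped = rows.copy()
    bumped[0, 1] += 0.05  # raise the positive logit of pair 0
    assert atl_loss(make_logits(bumped), gold).item() < base


def test_atl_rejects_th_in_gold():
    lg = make_logits([[0.0, 0.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="TH"):
        atl_loss(lg, {lg.pairs[0]: {TH}})


def test_atl_gradient_drives_decode_to_gold(rng):
    """Minimising the loss on a fixed batch makes decode reproduce the
    gold label sets exactly (loss/decode consistency).  A pair with k
    positives has an intrinsic loss floor of k log k (the positives
    share one softmax), so the reachable minimum is that floor averaged
    over pairs, not zero."""
    lg = make_logits(rng.normal(size=(4, 4)), grad=True)
    gold = {lg.pairs[0]: {"r1"}, lg.pairs[1]: {"r2", "r3"}}
    opt = Adam([lg.logits], lr=0.05)
    for _ in range(500):
        loss = atl_loss(lg, gold)
        opt.zero_grad()
        loss.backward()
        opt.step()
    floor = (0.0 + 2 * np.log(2.0)) / 4   # k log k per pair, mean over 4
    assert loss.item() < floor + 1e-2
    decoded = decode(lg)
    for pair in lg.pairs:
        assert decoded[pair] == gold.get(pair, set())


# ---------------------------------------------------------------------------
# decoding


def test_decode_threshold_rule():
    lg = make_logits([[2.0, 0.0, 0.5, 1.0]])
    assert decode(lg)[lg.pairs[0]] == {"r1"}


def test_decode_all_below_threshold_gives_empty_set():
    lg = make_logits([[0.2, -1.0, 0.9, 1.0]])
    assert decode(lg)[lg.pairs[0]] == set()


def test_decode_tie_not_predicted():
    lg = make_logits([[1.0, 1.0, 0.0, 1.0]])
    assert decode(lg)[lg.pairs[0]] == set()


def test_decode_matches_filter_oracle(rng):
    rows = rng.normal(size=(20, 4))
    lg = make_logits(rows)
    out = decode(lg)
    for i, pair in enumerate(lg.pairs):
        expect = {lab for j, lab in enumerate(LABELS)
                  if rows[i, j] > rows[i, 3]}
        assert out[pair] == expect


# ---------------------------------------------------------------------------
# metrics


def two_entity_docs(n):
    docs = []
    for i in range(n):
        docs.append(make_doc(
            doc_id=f"d{i}",
            sentences=[["x", "y", "."], ["z", "w", "."]],
            mentions=[("A", "gene", 0, 0, 1), ("B", "disease", 1, 0, 1)]))
    return docs


def test_metrics_perfect_predictions():
    docs = two_entity_docs(3)
    gold = {(f"d{i}", "A", "B"): {"r1"} for i in range(3)}
    rep = compute_metrics(gold, gold, docs)
    assert rep.precision == rep.recall == rep.f1 == 1.0
    assert rep.tnr == 1.0


def test_metrics_empty_predictions():
    docs = two_entity_docs(2)
    gold = {("d0", "A", "B"): {"r1"}}
    rep = compute_metrics({}, gold, docs)
    assert rep.recall == 0.0 and rep.f1 == 0.0
    assert rep.tnr == 1.0


def test_metrics_hand_counted_confusion_layout():
    """10 scored pairs: 3 TP, 1 FP, 2 FN, 4 TN ->
    P = 0.75, R = 0.6, F1 = harmonic mean, TNR = 0.8."""
    docs = two_entity_docs(5)               # 5 docs x 2 ordered pairs = 10
    gold, preds = {}, {}
    for key in [("d0", "A", "B"), ("d0", "B", "A"), ("d1", "A", "B")]:
        gold[key] = {"r1"}                  # 3 true positives
        preds[key] = {"r1"}
    preds[("d1", "B", "A")] = {"r1"}        # 1 false positive
    for key in [("d2", "A", "B"), ("d2", "B", "A")]:
        gold[key] = {"r1"}                  # 2 false negatives
    # d3, d4 untouched: 4 true-negative pairs
    rep = compute_metrics(preds, gold, docs)
    assert np.isclose(rep.precision, 0.75)
    assert np.isclose(rep.recall, 0.6)
    assert np.isclose(rep.f1, 2 * 0.75 * 0.6 / (0.75 + 0.6))
    assert np.isclose(rep.tnr, 0.8)         # 5 negative pairs, 1 predicted


def test_metrics_intra_inter_split():
    doc = make_doc(
        doc_id="d0",
        sentences=[["a", "b", "."], ["c", "."]],
        mentions=[("A", "gene", 0, 0, 1), ("B", "disease", 0, 1, 2),
                  ("C", "disease", 1, 0, 1)])
    gold = {("d0", "A", "B"): {"r1"},   # co-occur in sentence 0 -> intra
            ("d0", "A", "C"): {"r2"}}   # never co-occur -> inter
    preds = {("d0", "A", "B"): {"r1"}}  # only the intra instance found
    rep = compute_metrics(preds, gold, [doc])
    assert rep.intra_f1 == 1.0
    assert rep.inter_f1 == 0.0


def test_metrics_invariant_to_document_and_pair_order():
    docs = two_entity_docs(4)
    gold = {("d0", "A", "B"): {"r1"}, ("d2", "B", "A"): {"r2"}}
    preds = {("d2", "B", "A"): {"r2"}, ("d1", "A", "B"): {"r1"}}
    a = compute_metrics(preds, gold, docs)
    b = compute_metrics(dict(reversed(list(preds.items()))),
                        dict(reversed(list(gold.items()))),
                        list(reversed(docs)))
    assert a.to_dict() == b.to_dict()


def test_metrics_binary_single_label_equals_classical_f1(rng):
    """For single-label gold over one relation, micro-F1 equals the
    classical confusion-matrix F1."""
    docs = two_entity_docs(12)
    gold, preds = {}, {}
    truth = rng.integers(0, 2, 12).astype(bool)
    guess = rng.integers(0, 2, 12).astype(bool)
    for i in range(12):
        if truth[i]:
            gold[(f"d{i}", "A", "B")] = {"r1"}
        if guess[i]:
            preds[(f"d{i}", "A", "B")] = {"r1"}
    rep = compute_metrics(preds, gold, docs)
    tp = int(np.sum(truth & guess))
    fp = int(np.sum(~truth & guess))
    fn = int(np.sum(truth & ~guess))
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    assert np.isclose(rep.f1, f1)


def test_metrics_reject_unknown_pair():
    docs = two_entity_docs(1)
    with pytest.raises(ValueError, match="unknown pair"):
        compute_metrics({("d0", "A", "Z"): {"r1"}}, {}, docs)


def test_batched_classifier_agrees_with_single(rng):
    params = make_params(seed=9)
    e_s = rng.normal(size=(5, 6))
    e_o = rng.normal(size=(5, 6))
    m = rng.normal(size=(5, 6))
    batch = classify_pairs(Tensor(e_s), Tensor(e_o), Tensor(m), params).data
    for i in range(5):
        single = classify_pair(Tensor(e_s[i]), Tensor(e_o[i]), Tensor(m[i]),
                               params).data
        assert np.allclose(batch[i], single, atol=1e-12)
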