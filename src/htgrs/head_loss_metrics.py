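"""Stage 3: bilinear relation classification, adaptive-threshold loss,
decoding and evaluation metrics.

Each ordered entity pair (s, o) is scored over the relation vocabulary
plus a learnable threshold class TH.  The pair's head/tail hidden
vectors mix the entity embedding with the RS-refined pair cell through
a tanh feed-forward map, and a per-label bilinear form produces the
logit.  Training uses the adaptive-threshold objective: the positive
labels of a pair are pushed above TH (L1, a softmax over positives plus
TH) and TH is pushed above all negative labels (L2, a softmax over
negatives plus TH).  At decode time a label is predicted iff its logit
strictly exceeds the TH logit; the empty set means "no relation".

Metrics follow the evaluation conventions of document-level biomedical
relation extraction: micro precision/recall/F1 over (doc, head, tail,
label) instances, specificity (TNR) over relation-free entity pairs,
and the intra-/inter-sentence F1 split, where a gold instance is
*intra* iff some sentence contains a mention of both entities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._tensor import Parameter, Tensor, stack
from .corpus_io import Document

__all__ = [
    "TH",
    "ClassifierParams",
    "PairLogits",
    "MetricsReport",
    "classify_pair",
    "classify_pairs",
    "atl_loss",
    "decode",
    "compute_metrics",
    "is_intra",
]

TH = "[TH]"  # the adaptive threshold class

PairKey = tuple[str, str, str]  # (doc_id, head_entity_id, tail_entity_id)


@dataclass
class ClassifierParams:
    labels: tuple[str, ...]          # relation vocabulary, TH excluded
    d: int
    w_head: Parameter = None
    w_tail: Parameter = None
    w_bil: Parameter = None          # (R+1) x d x d, last index = TH
    bias: Parameter = None           # (R+1,)

    @property
    def all_labels(self) -> tuple[str, ...]:
        return self.labels + (TH,)

    def initialize(self, seed: int) -> "ClassifierParams":
        rng = np.random.default_rng(seed)
        d = self.d
        s = 1.0 / np.sqrt(d)
        self.w_head = Parameter(rng.normal(0, s, (d, d)))
        self.w_tail = Parameter(rng.normal(0, s, (d, d)))
        self.w_bil = Parameter(rng.normal(0, s, (len(self.labels) + 1, d, d)))
        self.bias = Parameter(np.zeros(len(self.labels) + 1))
        return self

    def parameters(self) -> list[Parameter]:
        return [self.w_head, self.w_tail, self.w_bil, self.bias]


@dataclass
class PairLogits:
    """Raw scores per valid ordered off-diagonal pair over R + {TH}."""

    pairs: list[tuple[str, str]]     # (head_entity_id, tail_entity_id)
    labels: tuple[str, ...]          # relation labels; TH is the last column
    logits: Tensor                   # n_pairs x (R+1)

    @property
    def th_index(self) -> int:
        return len(self.labels)


def classify_pairs(e_heads: Tensor, e_tails: Tensor, m_cells: Tensor,
                   params: ClassifierParams) -> Tensor:
    """Vectorized bilinear scoring of P pairs -> P x (R+1) logits.

    z_s = tanh(W_s e_s + M_so), z_o = tanh(W_o e_o + M_so),
    logit_r = z_s^T W_r z_o + b_r.
    """
    z_s = (e_heads @ params.w_head.T + m_cells).tanh()   # P x d
    z_o = (e_tails @ params.w_tail.T + m_cells).tanh()
    # t[r, p, :] = z_s[p] @ W_r ; logits[p, r] = t[r, p, :] . z_o[p]
    t = z_s.reshape(1, *z_s.shape) @ params.w_bil        # (R+1) x P x d
    lg = (t * z_o.reshape(1, *z_o.shape)).sum(axis=2)    # (R+1) x P
    return lg.transpose(1, 0) + params.bias


def classify_pair(e_s: Tensor, e_o: Tensor, m_so: Tensor,
                  params: ClassifierParams,
                  probabilities: bool = False) -> Tensor:
    """Score a single ordered pair; returns raw logits over R + {TH}
    (or sigmoid probabilities on request — losses and decoding always
    operate on raw logits)."""
    for v in (e_s, e_o, m_so):
        if v.shape != (params.d,):
            raise ValueError(f"expected d={params.d} vectors, got {v.shape}")
    lg = classify_pairs(e_s.reshape(1, -1), e_o.reshape(1, -1),
                        m_so.reshape(1, -1), params)[0]
    return lg.sigmoid() if probabilities else lg


def atl_loss(logits: PairLogits,
             gold: Mapping[tuple[str, str], set[str]]) -> Tensor:
    """Adaptive-threshold loss, mean of per-pair L1 + L2.

    L1 pushes each positive label above TH via a softmax over the
    positive set plus TH (empty positive set contributes exactly 0);
    L2 pushes TH above the negative labels via a softmax over the
    negative set plus TH.
    """
    R = len(logits.labels)
    P = len(logits.pairs)
    pos = np.zeros((P, R + 1), dtype=bool)
    for i, pair in enumerate(logits.pairs):
        for lab in gold.get(pair, ()):  # gold never contains TH
            if lab == TH:
                raise ValueError("gold label sets must not contain TH")
            if lab not in logits.labels:
                raise ValueError(f"unknown gold label {lab!r}")
            pos[i, logits.labels.index(lab)] = True
    neg = ~pos
    neg[:, R] = False
    th_col = np.zeros((P, R + 1), dtype=bool)
    th_col[:, R] = True

    lg = logits.logits
    # L1: -sum_{r in P_T} [logit_r - logsumexp over P_T u {TH}]
    denom1 = lg + np.where(pos | th_col, 0.0, _neg())
    lse1 = denom1.logsumexp(axis=1, keepdims=True)        # P x 1
    l1_terms = (lse1 - lg) * pos.astype(float)
    l1 = l1_terms.sum(axis=1)
    # L2: -(logit_TH - logsumexp over N_T u {TH})
    denom2 = lg + np.where(neg | th_col, 0.0, _neg())
    lse2 = denom2.logsumexp(axis=1)
    l2 = lse2 - lg[:, R]
    return (l1 + l2).mean()


def _neg() -> float:
    return -1e30  # exp underflows to exactly 0.0 in float64


def decode(logits: PairLogits) -> dict[tuple[str, str], set[str]]:
    """Predicted label set per pair: labels whose logit strictly exceeds
    the TH logit (ties are not predicted; empty set = no relation)."""
    out: dict[tuple[str, str], set[str]] = {}
    data = logits.logits.data
    th = data[:, logits.th_index]
    for i, pair in enumerate(logits.pairs):
        out[pair] = {lab for j, lab in enumerate(logits.labels)
                     if data[i, j] > th[i]}
    return out


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    tnr: float
    intra_f1: float
    inter_f1: float
    support: int = 0

    def to_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "f1": self.f1, "tnr": self.tnr, "intra_f1": self.intra_f1,
                "inter_f1": self.inter_f1, "support": self.support}

    def table(self) -> str:
        d = self.to_dict()
        rows = [f"{k:>10}: {v:.4f}" if isinstance(v, float) else
                f"{k:>10}: {v}" for k, v in d.items()]
        return "\n".join(rows)


def is_intra(doc: Document, head: str, tail: str) -> bool:
    """True iff some sentence contains a mention of both entities."""
    sents_h = {m.sentence_index for m in doc.mentions if m.entity_id == head}
    sents_t = {m.sentence_index for m in doc.mentions if m.entity_id == tail}
    return bool(sents_h & sents_t)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def compute_metrics(predictions: Mapping[PairKey, set[str]],
                    gold: Mapping[PairKey, set[str]],
                    docs: list[Document]) -> MetricsReport:
    """Micro P/R/F1 over (doc, head, tail, label) instances, pair-level
    TNR, and the intra-/inter-sentence F1 split.

    A pair is a TNR negative iff it has no gold label at all; intra vs
    inter is decided by sentence co-occurrence of the two entities'
    mentions, and predictions are credited to a class only for pairs of
    that class.
    """
    by_id = {d.doc_id: d for d in docs}
    valid_pairs: set[PairKey] = set()
    for d in docs:
        ids = d.entity_ids()
        for h in ids:
            for t in ids:
                if h != t:
                    valid_pairs.add((d.doc_id, h, t))
    for key in predictions:
        if key not in valid_pairs:
            raise ValueError(f"prediction references unknown pair {key}")
    for key in gold:
        if key not in valid_pairs:
            raise ValueError(f"gold references unknown pair {key}")

    pred_inst = {(k, lab) for k, labs in predictions.items() for lab in labs}
    gold_inst = {(k, lab) for k, labs in gold.items() for lab in labs}
    tp = len(pred_inst & gold_inst)
    fp = len(pred_inst - gold_inst)
    fn = len(gold_inst - pred_inst)
    p, r, f1 = _prf(tp, fp, fn)

    # TNR over all valid ordered pairs: negative = no gold label
    neg_pairs = {k for k in valid_pairs if not gold.get(k)}
    fp_pairs = {k for k in neg_pairs if predictions.get(k)}
    tnr = (len(neg_pairs) - len(fp_pairs)) / len(neg_pairs) if neg_pairs else 1.0

    def class_f1(want_intra: bool) -> float:
        keys = {k for k in valid_pairs
                if is_intra(by_id[k[0]], k[1], k[2]) == want_intra}
        g = {(k, lab) for k, lab in gold_inst if k in keys}
        pr = {(k, lab) for k, lab in pred_inst if k in keys}
        return _prf(len(pr & g), len(pr - g), len(g - pr))[2]

    return MetricsReport(p, r, f1, tnr, class_f1(True), class_f1(False),
                         support=len(gold_inst))
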