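"""End-to-end model assembly, training loop and evaluation.

The full pipeline per document: marked-sequence encoding -> HTG
construction and R-GCN reasoning (stage 1) -> logsumexp mention pooling
-> pair feature matrix -> relation segmentation (stage 2) -> bilinear
classification with the adaptive-threshold objective (stage 3).

Two ablation switches mirror the architecture study: ``use_htg=False``
takes mention vectors straight from the ``&`` marker embeddings
(skipping graph reasoning), and ``use_rs=False`` feeds the raw pair
matrix cells to the classifier.

Training is plain Adam, one document per step, with early stopping on
dev micro-F1; all randomness flows through one seeded generator and the
checkpoint records the seed, config and training log.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._tensor import Adam, Parameter, Tensor, stack
from .corpus_io import Document, MarkedSequence, insert_markers
from .encoding import EncoderParams, TokenEmbeddings, Vocabulary, build_vocabulary, encode
from .head_loss_metrics import (
    ClassifierParams,
    MetricsReport,
    PairLogits,
    atl_loss,
    compute_metrics,
    decode,
)
from .htg import RGCNParams, build_htg, readout_mentions, rgcn_forward
from .pair_reasoning import (
    EntityEmbeddings,
    PairMatrix,
    RSParams,
    build_pair_matrix,
    pool_entity,
    rs_forward,
)

__all__ = ["ModelConfig", "HTGRSModel", "Checkpoint", "train", "evaluate",
           "predictions_for", "export_predictions"]


@dataclass
class ModelConfig:
    labels: tuple[str, ...] = ("associates", "contributes", "causes", "resembles")
    d_emb: int = 64
    N: int = 16                 # pair-matrix size = max entities per document
    L_g: int = 2                # R-GCN depth
    L_rs: int = 2               # RS depth
    encoder_kind: str = "reference"
    encoder_window: int = 1
    use_htg: bool = True
    use_rs: bool = True
    cca_residual: bool = True
    rs_dropout: float = 0.25
    lr: float = 2e-3
    epochs: int = 100
    patience: int = 15
    seed: int = 0

    def validate(self) -> None:
        for name in ("d_emb", "N", "L_g", "L_rs", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.encoder_kind != "reference":
            raise ValueError("only the reference encoder ships with this "
                             "package; external encoders plug in via "
                             "htgrs.encoding.EncoderProtocol")


class HTGRSModel:
    """All parameter groups plus the end-to-end forward pass."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary):
        config.validate()
        self.config = config
        self.vocab = vocab
        root = np.random.default_rng(config.seed)
        seeds = root.integers(0, 2**31 - 1, size=4)
        self.encoder = EncoderParams(vocab, config.d_emb,
                                     window=config.encoder_window
                                     ).initialize(int(seeds[0]))
        self.rgcn = RGCNParams(config.d_emb, config.L_g).initialize(int(seeds[1]))
        self.rs = RSParams(config.d_emb, config.L_rs,
                           dropout=config.rs_dropout).initialize(
            int(seeds[2]), residual=config.cca_residual)
        self.classifier = ClassifierParams(tuple(config.labels),
                                           config.d_emb).initialize(int(seeds[3]))

    # -- parameters -------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        ps = self.encoder.parameters()
        if self.config.use_htg:
            ps += self.rgcn.parameters()
        if self.config.use_rs:
            ps += self.rs.parameters()
        return ps + self.classifier.parameters()

    # -- forward ----------------------------------------------------------
    def entity_vectors(self, doc: Document, seq: MarkedSequence,
                       H: TokenEmbeddings) -> EntityEmbeddings:
        """Stage-1 output: pooled entity embeddings, ordered by first
        mention position."""
        if self.config.use_htg:
            try:
                g = build_htg(doc, seq, H)
                node_feats = rgcn_forward(g, self.rgcn)
                per_entity = readout_mentions(g, node_feats)
            except Exception as exc:
                raise RuntimeError(f"[stage:htg] doc {doc.doc_id}: {exc}") from exc
        else:
            per_entity = {
                e.entity_id: [H.matrix[seq.mention_marker[m.mention_id]]
                              for m in doc.mentions_of(e.entity_id)]
                for e in doc.entities}
        order = sorted(doc.entity_ids(), key=lambda eid: (
            doc.mentions_of(eid)[0].sentence_index,
            doc.mentions_of(eid)[0].token_span[0]))
        vectors = stack([pool_entity(per_entity[eid]) for eid in order], axis=0)
        return EntityEmbeddings(vectors, order)

    def forward(self, doc: Document, training: bool = False) -> PairLogits:
        n_e = len(doc.entities)
        if not (2 <= n_e <= self.config.N):
            raise ValueError(f"doc {doc.doc_id}: entity count {n_e} outside "
                             f"[2, N={self.config.N}]")
        seq = insert_markers(doc)
        H = encode(seq, self.encoder)
        ents = self.entity_vectors(doc, seq, H)
        pm = build_pair_matrix(ents, self.config.N)
        if self.config.use_rs:
            try:
                pm = rs_forward(pm, self.rs, training=training)
            except Exception as exc:
                raise RuntimeError(f"[stage:rs] doc {doc.doc_id}: {exc}") from exc
        s_idx, o_idx = np.nonzero(~np.eye(n_e, dtype=bool))
        pairs = [(ents.entity_ids[s], ents.entity_ids[o])
                 for s, o in zip(s_idx, o_idx)]
        from .head_loss_metrics import classify_pairs
        logits = classify_pairs(ents.vectors[s_idx], ents.vectors[o_idx],
                                pm.cells[s_idx, o_idx], self.classifier)
        return PairLogits(pairs, tuple(self.config.labels), logits)

    # -- state ------------------------------------------------------------
    def _all_params(self) -> list[Parameter]:
        return (self.encoder.parameters() + self.rgcn.parameters()
                + self.rs.parameters() + self.classifier.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self._all_params()]
        for layer in self.rs.layers:
            arrays += [layer.bn.running_mean.copy(), layer.bn.running_var.copy()]
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self._all_params()
        for p, a in zip(params, arrays):
            p.data = a.copy()
        extra = arrays[len(params):]
        for i, layer in enumerate(self.rs.layers):
            layer.bn.running_mean = extra[2 * i].copy()
            layer.bn.running_var = extra[2 * i + 1].copy()


@dataclass
class Checkpoint:
    config: ModelConfig
    vocab: Vocabulary
    arrays: list[np.ndarray]
    log: list[dict] = field(default_factory=list)

    def build_model(self) -> HTGRSModel:
        model = HTGRSModel(self.config, self.vocab)
        model.load_state_arrays(self.arrays)
        return model

    def save(self, path: str) -> None:
        meta = {"config": asdict(self.config),
                "vocab": self.vocab.to_dict(), "log": self.log}
        np.savez(path, meta=np.array(json.dumps(meta)),
                 **{f"arr{i}": a for i, a in enumerate(self.arrays)})

    @classmethod
    def load(cls, path: str) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            arrays = [z[f"arr{i}"] for i in range(len(z.files) - 1)]
        cfg = meta["config"]
        cfg["labels"] = tuple(cfg["labels"])
        return cls(ModelConfig(**cfg), Vocabulary.from_dict(meta["vocab"]),
                   arrays, meta["log"])


def gold_for(doc: Document) -> dict[tuple[str, str], set[str]]:
    gold: dict[tuple[str, str], set[str]] = {}
    for r in doc.relations:
        gold.setdefault((r.head_entity_id, r.tail_entity_id), set()).add(r.label)
    return gold


def train(corpus: list[Document], config: ModelConfig,
          dev: list[Document] | None = None,
          verbose: bool = False) -> Checkpoint:
    """Train on ``corpus``; returns the best-dev checkpoint (best train
    loss if no dev set is given).

    One document per optimization step; early stopping when dev micro-F1
    has not improved for ``config.patience`` epochs.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    config.validate()
    vocab = build_vocabulary(corpus)
    model = HTGRSModel(config, vocab)
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []
    best = (-np.inf, None)   # (score, arrays)
    best_strict = -np.inf
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(corpus))
        total = 0.0
        for i in order:
            doc = corpus[i]
            logits = model.forward(doc, training=True)
            loss = atl_loss(logits, gold_for(doc))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}, doc {doc.doc_id}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
        entry = {"epoch": epoch, "train_loss": total / len(corpus)}
        if dev:
            report = evaluate_model(model, dev)
            entry["dev_f1"] = report.f1
            score = report.f1
        else:
            score = -entry["train_loss"]
        log.append(entry)
        if verbose:
            print("  " + json.dumps(entry))
        # ties (frequent on small dev sets) resolve to the later, more
        # converged checkpoint
        if score >= best[0]:
            best = (score, model.state_arrays())
            stale = 0 if score > best_strict else stale + 1
            best_strict = max(best_strict, score)
        else:
            stale += 1
            if dev and stale >= config.patience:
                break
    model.load_state_arrays(best[1])
    return Checkpoint(config, vocab, model.state_arrays(), log)


def predictions_for(model: HTGRSModel,
                    docs: list[Document]) -> dict[tuple[str, str, str], set[str]]:
    preds: dict[tuple[str, str, str], set[str]] = {}
    for doc in docs:
        logits = model.forward(doc, training=False)
        for (h, t), labs in decode(logits).items():
            preds[(doc.doc_id, h, t)] = labs
    return preds


def evaluate_model(model: HTGRSModel, docs: list[Document]) -> MetricsReport:
    preds = predictions_for(model, docs)
    gold = {(d.doc_id, h, t): labs
            for d in docs for (h, t), labs in gold_for(d).items()}
    return compute_metrics(preds, gold, docs)


def evaluate(checkpoint: Checkpoint, docs: list[Document]) -> MetricsReport:
    """Eval-mode forward + decode + metrics; deterministic."""
    model = checkpoint.build_model()
    labels = set()
    for d in docs:
        labels |= {r.label for r in d.relations}
    unknown = labels - set(checkpoint.config.labels)
    if unknown:
        raise ValueError(f"corpus labels {sorted(unknown)} missing from the "
                         f"checkpoint's label vocabulary")
    return evaluate_model(model, docs)


def export_predictions(preds: dict[tuple[str, str, str], set[str]]) -> str:
    """Render predictions as PubTator relation lines."""
    lines = []
    for (doc_id, h, t), labs in sorted(preds.items()):
        for lab in sorted(labs):
            lines.append("\t".join([doc_id, lab, h, t]))
    return "\n".join(lines)
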