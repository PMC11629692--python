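"""Hierarchical tree graph (HTG) construction and R-GCN reasoning.

Stage 1 of the pipeline.  A document becomes a typed graph with four
node kinds — one *document* node, one *sentence* node per sentence that
contains at least one mention, one *mention* node per mention, and one
*local-context* node per maximal run of non-mention tokens adjacent to
a mention — joined by three typed edges (document-sentence,
sentence-mention, mention-context).  Node features are pooled from the
token embeddings: sentence = its ``[CLS]`` row, document = mean of the
retained sentence features, mention = its leading ``&`` marker row,
context = elementwise max over the region's token rows.

A relational graph convolution (separate weight matrix per edge type
and direction, plus a self-connection, neighbour terms normalised by
neighbourhood size, ReLU) propagates information over the graph; the
per-layer hidden states are concatenated and projected back to d_emb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Parameter, Tensor, concatenate, stack
from .corpus_io import Document, MarkedSequence
from .encoding import TokenEmbeddings

__all__ = [
    "ContextRegion",
    "HTGNode",
    "HTG",
    "RGCNParams",
    "segment_local_contexts",
    "build_htg",
    "rgcn_layer",
    "rgcn_forward",
    "readout_mentions",
    "to_networkx",
]

NODE_TYPES = ("document", "sentence", "mention", "context")
EDGE_TYPES = ("D-S", "S-M", "M-C")


@dataclass(frozen=True)
class ContextRegion:
    """A maximal run of non-mention tokens adjacent to >= 1 mention.

    ``token_span`` is 0-based half-open in *original* sentence
    coordinates (control tokens are never part of a region).
    ``adjacent_mentions`` holds the ids (or ordinals) of the mention(s)
    the region borders: one for a leading/trailing region, two for a
    region between consecutive mentions.
    """

    sentence_index: int
    token_span: tuple[int, int]
    adjacent_mentions: tuple[str, ...]


@dataclass(frozen=True)
class HTGNode:
    node_id: str
    node_type: str  # one of NODE_TYPES
    provenance: dict = field(compare=False, hash=False, default_factory=dict)


@dataclass
class HTG:
    nodes: list[HTGNode]
    features: Tensor               # n_nodes x d_emb
    edges: list[tuple[int, int, str]]  # (src index, dst index, edge type)
    index: dict[str, int]          # node_id -> row
    mention_order: dict[str, list[str]]  # entity_id -> mention node ids, doc order


def segment_local_contexts(
    sentence_tokens: list[str],
    mention_spans: list[tuple[int, int]],
    sentence_index: int = 0,
    mention_ids: list[str] | None = None,
) -> list[ContextRegion]:
    """Split a sentence into the maximal non-mention runs around its
    mentions, left to right; empty runs (adjacent mentions, or a mention
    at the sentence edge) are omitted.

    A run between two mentions is adjacent to both; the run before the
    first (after the last) mention is adjacent to that mention only.
    """
    if not mention_spans:
        raise ValueError("at least one mention span is required")
    spans = sorted(mention_spans)
    n = len(sentence_tokens)
    for (a, b), (c, d) in zip(spans, spans[1:]):
        if c < b:
            raise ValueError(f"overlapping mention spans [{a},{b}) and [{c},{d})")
    for a, b in spans:
        if not (0 <= a < b <= n):
            raise ValueError(f"span [{a},{b}) out of bounds for length {n}")
    if mention_ids is None:
        ids = [str(i) for i in range(len(spans))]
    else:
        ids = [mid for _, mid in sorted(zip(mention_spans, mention_ids))]

    regions: list[ContextRegion] = []
    # leading run
    if spans[0][0] > 0:
        regions.append(ContextRegion(sentence_index, (0, spans[0][0]), (ids[0],)))
    # runs between consecutive mentions
    for i, ((_, b), (c, _)) in enumerate(zip(spans, spans[1:])):
        if c > b:
            regions.append(ContextRegion(sentence_index, (b, c),
                                         (ids[i], ids[i + 1])))
    # trailing run
    if spans[-1][1] < n:
        regions.append(ContextRegion(sentence_index, (spans[-1][1], n),
                                     (ids[-1],)))
    return regions


def build_htg(doc: Document, seq: MarkedSequence, H: TokenEmbeddings) -> HTG:
    """Assemble the typed document graph with pooled node features."""
    if not doc.mentions:
        raise ValueError(f"doc {doc.doc_id}: HTG undefined for a document "
                         f"with no mentions")
    if len(seq.tokens) != H.matrix.shape[0]:
        raise ValueError("token embeddings are not aligned with the marked "
                         "sequence")
    by_sent: dict[int, list] = {}
    for m in doc.mentions:
        by_sent.setdefault(m.sentence_index, []).append(m)
    retained = sorted(by_sent)  # sentences with >= 1 mention

    nodes: list[HTGNode] = [HTGNode("doc", "document",
                                    {"doc_id": doc.doc_id})]
    feats: list[Tensor] = [None]  # type: ignore  # document filled below
    edges: list[tuple[int, int, str]] = []
    index: dict[str, int] = {"doc": 0}

    def add(node: HTGNode, feat: Tensor) -> int:
        index[node.node_id] = len(nodes)
        nodes.append(node)
        feats.append(feat)
        return len(nodes) - 1

    sent_rows: list[Tensor] = []
    for si in retained:
        f = H.matrix[seq.cls_index[si]]
        sent_rows.append(f)
        i = add(HTGNode(f"sent:{si}", "sentence", {"sentence_index": si}), f)
        edges.append((0, i, "D-S"))

    mention_order: dict[str, list[str]] = {}
    for si in retained:
        ms = sorted(by_sent[si], key=lambda m: m.token_span)
        for m in ms:
            f = H.matrix[seq.mention_marker[m.mention_id]]
            i = add(HTGNode(f"mention:{m.mention_id}", "mention",
                            {"mention_id": m.mention_id,
                             "entity_id": m.entity_id}), f)
            edges.append((index[f"sent:{si}"], i, "S-M"))
        regions = segment_local_contexts(
            doc.sentences[si], [m.token_span for m in ms], si,
            [m.mention_id for m in ms])
        for k, reg in enumerate(regions):
            rows = H.matrix[np.array(
                [seq.alignment[(si, t)] for t in range(*reg.token_span)],
                dtype=np.intp)]
            f = rows.max(axis=0)
            i = add(HTGNode(f"ctx:{si}:{k}", "context",
                            {"sentence_index": si, "token_span": reg.token_span}),
                    f)
            for mid in reg.adjacent_mentions:
                edges.append((index[f"mention:{mid}"], i, "M-C"))

    # document feature: mean of retained sentence features
    feats[0] = stack(sent_rows, axis=0).mean(axis=0)
    for ent in doc.entities:
        order = [m.mention_id for m in doc.mentions_of(ent.entity_id)]
        mention_order[ent.entity_id] = order
    features = stack(feats, axis=0)
    return HTG(nodes, features, edges, index, mention_order)


# ---------------------------------------------------------------------------
# R-GCN


@dataclass
class RGCNParams:
    """Weights for L_g relational graph convolution layers.

    Each of the three edge types contributes two relations (one per
    direction), so every layer carries six neighbour matrices ``W_r``
    plus a self matrix ``W_o``.  After the final layer the initial and
    all hidden states are concatenated and linearly projected back to
    ``d_emb``.
    """

    d_emb: int
    n_layers: int = 2
    w_rel: list[list[Parameter]] = field(default_factory=list)
    w_self: list[Parameter] = field(default_factory=list)
    w_proj: Parameter | None = None
    b_proj: Parameter | None = None

    @property
    def relations(self) -> list[tuple[str, bool]]:
        return [(t, fwd) for t in EDGE_TYPES for fwd in (True, False)]

    def initialize(self, seed: int) -> "RGCNParams":
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        rng = np.random.default_rng(seed)
        d = self.d_emb
        s = 1.0 / np.sqrt(d)
        self.w_rel = [[Parameter(rng.normal(0, s, (d, d)))
                       for _ in self.relations] for _ in range(self.n_layers)]
        self.w_self = [Parameter(rng.normal(0, s, (d, d)))
                       for _ in range(self.n_layers)]
        self.w_proj = Parameter(
            rng.normal(0, 1.0 / np.sqrt((self.n_layers + 1) * d),
                       ((self.n_layers + 1) * d, d)))
        self.b_proj = Parameter(np.zeros(d))
        return self

    def parameters(self) -> list[Parameter]:
        ps = [w for layer in self.w_rel for w in layer] + list(self.w_self)
        return ps + [self.w_proj, self.b_proj]


def relation_adjacency(g: HTG) -> list[np.ndarray]:
    """Row-normalised neighbour matrices, one per (edge type, direction).

    ``A[n, u] = 1 / |N_n^r|`` when ``u`` is an r-neighbour of ``n``.
    """
    n = len(g.nodes)
    mats = []
    for etype in EDGE_TYPES:
        for fwd in (True, False):
            A = np.zeros((n, n))
            for s, d, t in g.edges:
                if t != etype:
                    continue
                if fwd:
                    A[d, s] = 1.0  # message from src to dst
                else:
                    A[s, d] = 1.0
            deg = A.sum(axis=1, keepdims=True)
            np.divide(A, deg, out=A, where=deg > 0)
            mats.append(A)
    return mats


def rgcn_layer(g: HTG, features: Tensor, w_rel: list[Parameter],
               w_self: Parameter,
               adjacency: list[np.ndarray] | None = None) -> Tensor:
    """One relational graph convolution step.

    ``h_n' = ReLU( sum_r sum_{u in N_n^r} W_r h_u / |N_n^r| + W_o h_n )``;
    relations with no neighbours contribute nothing.
    """
    if adjacency is None:
        adjacency = relation_adjacency(g)
    out = features @ w_self.T
    for A, W in zip(adjacency, w_rel):
        if A.any():
            out = out + (Tensor(A) @ features) @ W.T
    return out.relu()


def rgcn_forward(g: HTG, params: RGCNParams,
                 features: Tensor | None = None) -> Tensor:
    """Run all layers, concatenate [h^0; h^1; ...; h^L] per node and
    project the concatenation back to d_emb."""
    if not g.edges:
        raise ValueError("degenerate graph: no edges to propagate over")
    h = g.features if features is None else features
    adjacency = relation_adjacency(g)
    states = [h]
    for layer in range(params.n_layers):
        h = rgcn_layer(g, h, params.w_rel[layer], params.w_self[layer],
                       adjacency)
        states.append(h)
    cat = concatenate(states, axis=1)
    return cat @ params.w_proj + params.b_proj


def readout_mentions(g: HTG, node_features: Tensor) -> dict[str, list[Tensor]]:
    """Post-R-GCN mention vectors per entity, in document order."""
    out: dict[str, list[Tensor]] = {}
    for eid, mids in g.mention_order.items():
        if not mids:
            raise ValueError(f"entity {eid}: no mention nodes in the graph")
        out[eid] = [node_features[g.index[f"mention:{mid}"]] for mid in mids]
    return out


def to_networkx(g: HTG):
    """Export to a networkx graph (node/edge type attributes preserved)."""
    import networkx as nx

    G = nx.DiGraph()
    for i, node in enumerate(g.nodes):
        prov = {k: str(v) for k, v in node.provenance.items()}
        G.add_node(node.node_id, node_type=node.node_type, **prov)
    for s, d, t in g.edges:
        G.add_edge(g.nodes[s].node_id, g.nodes[d].node_id, edge_type=t)
    return G
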