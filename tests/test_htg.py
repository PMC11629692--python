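"""Hierarchical tree graph construction and R-GCN reasoning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htgrs import (
    build_vocabulary,
    build_htg,
    encode,
    insert_markers,
    rgcn_forward,
    rgcn_layer,
    readout_mentions,
    segment_local_contexts,
    to_networkx,
)
from htgrs.encoding import EncoderParams
from htgrs.htg import HTG, HTGNode, RGCNParams, relation_adjacency
from htgrs._tensor import Parameter, Tensor

from conftest import make_doc


# ---------------------------------------------------------------------------
# local-context segmentation


def test_segmentation_fourteen_token_worked_example():
    """A 14-token sentence with mentions covering (1-based) tokens 4-5 and
    10-11 splits into regions {1-3}, {6-9}, {12-14}."""
    sent = [f"c{i}" for i in range(1, 15)]
    regions = segment_local_contexts(sent, [(3, 5), (9, 11)])
    assert [r.token_span for r in regions] == [(0, 3), (5, 9), (11, 14)]
    assert [sent[a:b] for a, b in (r.token_span for r in regions)] == [
        ["c1", "c2", "c3"],
        ["c6", "c7", "c8", "c9"],
        ["c12", "c13", "c14"],
    ]
    # the middle region borders both mentions; the outer ones border one
    assert [len(r.adjacent_mentions) for r in regions] == [1, 2, 1]


def test_segmentation_full_sentence_mention_yields_nothing():
    assert segment_local_contexts(["a", "b"], [(0, 2)]) == []


def test_segmentation_rejects_overlap():
    with pytest.raises(ValueError, match="overlap"):
        segment_local_contexts(list("abcdef"), [(0, 3), (2, 4)])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(data=st.data())
def test_segmentation_complement_oracle(data):
    n = data.draw(st.integers(4, 20))
    k = data.draw(st.integers(1, max(1, n // 2 - 1)))
    cuts = sorted(data.draw(st.sets(st.integers(0, n), min_size=2 * k,
                                    max_size=2 * k)))
    spans = [(cuts[2 * i], cuts[2 * i + 1]) for i in range(k)]
    regions = segment_local_contexts([f"t{i}" for i in range(n)], spans)
    covered = [t for r in regions for t in range(*r.token_span)]
    mention_toks = {t for a, b in spans for t in range(a, b)}
    assert covered == sorted(set(range(n)) - mention_toks)


# ---------------------------------------------------------------------------
# graph construction


def build_graph(doc, d_emb=8, seed=0):
    seq = insert_markers(doc)
    params = EncoderParams(build_vocabulary([doc]), d_emb).initialize(seed)
    H = encode(seq, params)
    return build_htg(doc, seq, H), seq, H


def census(g):
    from collections import Counter
    return Counter(n.node_type for n in g.nodes), \
        sorted({t for _, _, t in g.edges})


def test_htg_census_and_types(small_corpus):
    for doc in small_corpus:
        g, _, _ = build_graph(doc)
        types, etypes = census(g)
        with_mentions = {m.sentence_index for m in doc.mentions}
        assert types["document"] == 1
        assert types["sentence"] == len(with_mentions)
        assert types["mention"] == len(doc.mentions)
        assert sum(1 for s, d, t in g.edges if t == "S-M") == len(doc.mentions)
        expected_regions = 0
        by_sent = {}
        for m in doc.mentions:
            by_sent.setdefault(m.sentence_index, []).append(m.token_span)
        for si, spans in by_sent.items():
            expected_regions += len(
                segment_local_contexts(doc.sentences[si], spans, si))
        assert types["context"] == expected_regions


def test_htg_four_node_types_three_edge_types(small_corpus):
    doc = next(d for d in small_corpus
               if any(m.token_span[0] > 0 for m in d.mentions))
    g, _, _ = build_graph(doc)
    types, etypes = census(g)
    assert set(types) == {"document", "sentence", "mention", "context"}
    assert etypes == ["D-S", "M-C", "S-M"]


def test_htg_is_tree_at_document_sentence_mention_level(small_corpus):
    for doc in small_corpus[:4]:
        g, _, _ = build_graph(doc)
        for i, node in enumerate(g.nodes):
            if node.node_type == "sentence":
                parents = [s for s, d, t in g.edges if d == i and t == "D-S"]
                assert parents == [0]
            if node.node_type == "mention":
                parents = [s for s, d, t in g.edges if d == i and t == "S-M"]
                assert len(parents) == 1


def test_mention_free_sentences_dropped_and_doc_feature_mean():
    doc = make_doc(sentences=[["a", "x", "b", "."], ["c", "d", "."]],
                   mentions=[("E1", "gene", 0, 1, 2)])
    g, seq, H = build_graph(doc)
    types, _ = census(g)
    assert types["sentence"] == 1
    # document feature = mean over one retained sentence = that sentence's [CLS]
    cls_row = H.matrix.data[seq.cls_index[0]]
    assert np.allclose(g.features.data[0], cls_row)


def test_node_features_match_pooling_rules(small_corpus):
    doc = small_corpus[1]
    g, seq, H = build_graph(doc)
    for i, node in enumerate(g.nodes):
        if node.node_type == "mention":
            pos = seq.mention_marker[node.provenance["mention_id"]]
            assert np.allclose(g.features.data[i], H.matrix.data[pos])
        if node.node_type == "context":
            si = node.provenance["sentence_index"]
            a, b = node.provenance["token_span"]
            rows = [H.matrix.data[seq.alignment[(si, t)]] for t in range(a, b)]
            assert np.allclose(g.features.data[i], np.max(rows, axis=0))


def test_htg_rejects_mention_free_document():
    with pytest.raises(ValueError, match="no mentions"):
        build_graph(make_doc(sentences=[["a", "b", "."]]))


def test_graphml_export_roundtrips_node_count(small_corpus):
    g, _, _ = build_graph(small_corpus[0])
    G = to_networkx(g)
    assert G.number_of_nodes() == len(g.nodes)
    assert G.number_of_edges() == len(g.edges)


# ---------------------------------------------------------------------------
# R-GCN


def tiny_graph(features, edges):
    nodes = [HTGNode(f"n{i}", "mention") for i in range(len(features))]
    return HTG(nodes, Tensor(np.asarray(features, dtype=float)),
               edges, {f"n{i}": i for i in range(len(features))}, {})


def test_rgcn_layer_self_identity():
    g = tiny_graph([[1.0, 2.0], [3.0, 0.5]], [(0, 1, "D-S")])
    d = 2
    w_rel = [Parameter(np.zeros((d, d))) for _ in range(6)]
    w_self = Parameter(np.eye(d))
    out = rgcn_layer(g, g.features, w_rel, w_self)
    assert np.allclose(out.data, g.features.data)


def test_rgcn_layer_star_graph_neighbor_mean():
    # hub node 0 with neighbours carrying (2,0) and (0,2): mean = (1,1)
    g = tiny_graph([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]],
                   [(1, 0, "S-M"), (2, 0, "S-M")])
    w_rel = [Parameter(np.zeros((2, 2))) for _ in range(6)]
    w_rel[2] = Parameter(np.eye(2))  # S-M forward direction
    w_self = Parameter(np.zeros((2, 2)))
    out = rgcn_layer(g, g.features, w_rel, w_self)
    assert np.allclose(out.data[0], [1.0, 1.0])


def rgcn_layer_loop_oracle(g, features, w_rel, w_self):
    """Per-node double loop over relations and neighbours (Eq.-style)."""
    relations = [(t, fwd) for t in ("D-S", "S-M", "M-C") for fwd in (True, False)]
    n, d = features.shape
    out = np.zeros((n, w_self.data.shape[0]))
    for i in range(n):
        acc = w_self.data @ features[i]
        for r, (etype, fwd) in enumerate(relations):
            nbrs = [s if fwd else dst
                    for s, dst, t in g.edges
                    if t == etype and (dst == i if fwd else s == i)]
            if not nbrs:
                continue
            for u in nbrs:
                acc = acc + (w_rel[r].data @ features[u]) / len(nbrs)
        out[i] = np.maximum(acc, 0.0)
    return out


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_rgcn_layer_matches_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    d = int(rng.integers(1, 6))
    feats = rng.normal(size=(n, d))
    edges = set()
    for _ in range(int(rng.integers(1, 3 * n))):
        s, t = rng.integers(0, n, 2)
        if s != t:
            edges.add((int(s), int(t),
                       ["D-S", "S-M", "M-C"][int(rng.integers(0, 3))]))
    edges = sorted(edges) or [(0, 1 % n, "D-S")]
    g = tiny_graph(feats, edges)
    w_rel = [Parameter(rng.normal(size=(d, d))) for _ in range(6)]
    w_self = Parameter(rng.normal(size=(d, d)))
    out = rgcn_layer(g, g.features, w_rel, w_self)
    expect = rgcn_layer_loop_oracle(g, feats, w_rel, w_self)
    assert np.allclose(out.data, expect, atol=1e-6)


def test_rgcn_forward_equals_stepwise_composition(small_corpus):
    doc = small_corpus[2]
    g, _, _ = build_graph(doc, d_emb=6, seed=4)
    params = RGCNParams(6, n_layers=2).initialize(7)
    out = rgcn_forward(g, params)
    assert out.shape == (len(g.nodes), 6)
    h = g.features
    states = [h.data]
    adj = relation_adjacency(g)
    for l in range(2):
        h = rgcn_layer(g, h, params.w_rel[l], params.w_self[l], adj)
        states.append(h.data)
    cat = np.concatenate(states, axis=1)  # (L+1) * d before projection
    assert cat.shape[1] == 3 * 6
    expect = cat @ params.w_proj.data + params.b_proj.data
    assert np.allclose(out.data, expect, atol=1e-9)


def test_rgcn_forward_concat_dim_single_layer(small_corpus):
    g, _, _ = build_graph(small_corpus[0], d_emb=5)
    params = RGCNParams(5, n_layers=1).initialize(0)
    assert params.w_proj.shape == (2 * 5, 5)
    assert rgcn_forward(g, params).shape == (len(g.nodes), 5)


def test_rgcn_forward_rejects_edge_free_graph():
    g = tiny_graph([[1.0, 0.0]], [])
    with pytest.raises(ValueError, match="degenerate"):
        rgcn_forward(g, RGCNParams(2, 1).initialize(0))


def test_readout_orders_mentions_by_document_position(small_corpus):
    doc = next(d for d in small_corpus
               if any(len(e.mentions) >= 2 for e in d.entities))
    g, _, _ = build_graph(doc)
    params = RGCNParams(8, 2).initialize(1)
    feats = rgcn_forward(g, params)
    out = readout_mentions(g, feats)
    ent = next(e for e in doc.entities if len(e.mentions) >= 2)
    vecs = out[ent.entity_id]
    assert len(vecs) == len(ent.mentions)
    expected = [feats.data[g.index[f"mention:{mid}"]]
                for mid in g.mention_order[ent.entity_id]]
    for v, e in zip(vecs, expected):
        assert np.allclose(v.data, e)
    # single-mention entity: one vector equal to that node's row
    single = next((e for e in doc.entities if len(e.mentions) == 1), None)
    if single:
        v, = out[single.entity_id]
        assert np.allclose(
            v.data, feats.data[g.index[f"mention:{single.mentions[0]}"]])
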