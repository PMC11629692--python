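import numpy as np
import pytest

from htgrs import (
    Document,
    Entity,
    Mention,
    RelationInstance,
    generate_corpus,
)
from htgrs.synthetic_corpus import default_config


def make_doc(doc_id="d1", sentences=None, mentions=None, relations=None):
    """Hand-built document helper: mentions as (entity_id, type, sent, start, end)."""
    sentences = sentences or [["a", "b", "c", "."]]
    mentions = mentions or []
    ms, ents = [], {}
    for k, (eid, etype, si, a, b) in enumerate(mentions):
        mid = f"{doc_id}.m{k}"
        ms.append(Mention(mid, eid, etype, si, (a, b),
                          tuple(sentences[si][a:b])))
        ents.setdefault(eid, (etype, []))[1].append(mid)
    entities = [Entity(eid, etype, tuple(mids))
                for eid, (etype, mids) in ents.items()]
    rels = [RelationInstance(h, t, lab) for h, t, lab in (relations or [])]
    return Document(doc_id, [list(s) for s in sentences], ms, entities, rels)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(default_config(n_docs=12, seed=5), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
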