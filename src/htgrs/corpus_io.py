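"""Document model and PubTator-style corpus I/O.

The canonical in-memory unit is :class:`Document`: tokenized sentences,
mentions with (sentence, token-span) coordinates, entities grouping the
mentions by concept identifier, and gold relation instances between
entity concept IDs.  Coordinates are 0-based with half-open spans
throughout.

The on-disk interchange format is PubTator: ``PMID|t|title`` and
``PMID|a|abstract`` text lines, tab-separated mention annotation lines
``PMID  start  end  text  type  conceptID`` with character offsets into
``title + " " + abstract``, and relation lines ``PMID  label  ID1  ID2``.
A JSON-lines serialization of the document model is also provided for
fixtures.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, TextIO

__all__ = [
    "Mention",
    "Entity",
    "RelationInstance",
    "Document",
    "MarkedSequence",
    "PubTatorParseError",
    "AlignmentError",
    "ValidationError",
    "tokenize",
    "split_sentences",
    "read_pubtator",
    "write_pubtator",
    "insert_markers",
    "validate_document",
    "docs_to_jsonl",
    "docs_from_jsonl",
]

CLS = "[CLS]"
SEP = "[SEP]"
MARKER = "&"
_SENT_END = {".", "!", "?"}


class PubTatorParseError(ValueError):
    """A PubTator line could not be parsed; the message names the line number."""


class AlignmentError(ValueError):
    """A mention's character span does not align with token/sentence boundaries."""


class ValidationError(ValueError):
    """A document violates the document-model invariants."""


@dataclass(frozen=True)
class Mention:
    """One textual occurrence of an entity concept.

    ``token_span`` is a 0-based half-open ``(start, end)`` within the
    mention's sentence; ``surface`` is the covered token list.
    """

    mention_id: str
    entity_id: str
    entity_type: str
    sentence_index: int
    token_span: tuple[int, int]
    surface: tuple[str, ...]


@dataclass(frozen=True)
class Entity:
    """An entity concept (e.g. a MeSH ID) with all its mentions."""

    entity_id: str
    entity_type: str
    mentions: tuple[str, ...]  # mention_ids, non-empty


@dataclass(frozen=True)
class RelationInstance:
    """A gold relation ``label`` between two distinct entity concepts."""

    head_entity_id: str
    tail_entity_id: str
    label: str


@dataclass
class Document:
    doc_id: str
    sentences: list[list[str]]
    mentions: list[Mention]
    entities: list[Entity]
    relations: list[RelationInstance]

    def entity(self, entity_id: str) -> Entity:
        for e in self.entities:
            if e.entity_id == entity_id:
                return e
        raise KeyError(entity_id)

    def mention(self, mention_id: str) -> Mention:
        for m in self.mentions:
            if m.mention_id == mention_id:
                return m
        raise KeyError(mention_id)

    def mentions_of(self, entity_id: str) -> list[Mention]:
        """Mentions of an entity in document order."""
        ms = [m for m in self.mentions if m.entity_id == entity_id]
        return sorted(ms, key=lambda m: (m.sentence_index, m.token_span[0]))

    def entity_ids(self) -> list[str]:
        return [e.entity_id for e in self.entities]


@dataclass
class MarkedSequence:
    """The marked token sequence fed to the encoder.

    Each sentence is wrapped ``[CLS] ... [SEP]`` and each mention is
    wrapped by a pair of ``&`` marker tokens; ``mention_marker`` points
    at each mention's *leading* ``&``, whose embedding later represents
    the mention.  ``alignment`` maps original ``(sentence, token)``
    coordinates to positions in ``tokens``.
    """

    tokens: list[str]
    cls_index: dict[int, int]
    sep_index: dict[int, int]
    mention_marker: dict[str, int]
    alignment: dict[tuple[int, int], int]


# ---------------------------------------------------------------------------
# tokenization


def tokenize(text: str) -> list[str]:
    """Deterministic reference tokenizer: word runs and single punctuation."""
    return re.findall(r"\w+|[^\w\s]", text)


def split_sentences(tokens: list[str]) -> list[list[str]]:
    """Split a token stream into sentences after ``.``, ``!`` or ``?``."""
    sentences: list[list[str]] = []
    cur: list[str] = []
    for tok in tokens:
        cur.append(tok)
        if tok in _SENT_END:
            sentences.append(cur)
            cur = []
    if cur:
        sentences.append(cur)
    return sentences


def _char_to_token_map(text: str) -> tuple[list[str], list[tuple[int, int]]]:
    """Tokens of ``text`` plus each token's character span."""
    spans = [(m.start(), m.end()) for m in re.finditer(r"\w+|[^\w\s]", text)]
    return [text[a:b] for a, b in spans], spans


# ---------------------------------------------------------------------------
# PubTator reading


def _group_entities(mentions: list[Mention]) -> list[Entity]:
    """Group mentions into entities by concept ID, first-appearance order."""
    order: dict[str, list[Mention]] = {}
    for m in sorted(mentions, key=lambda m: (m.sentence_index, m.token_span[0])):
        order.setdefault(m.entity_id, []).append(m)
    entities = []
    for eid, ms in order.items():
        types = {m.entity_type for m in ms}
        if len(types) != 1:
            raise ValidationError(
                f"entity {eid!r} has inconsistent types {sorted(types)}")
        entities.append(Entity(eid, ms[0].entity_type, tuple(m.mention_id for m in ms)))
    return entities


def _build_document(doc_id: str, title: str, abstract: str,
                    ann: list[tuple[int, int, str, str, str]],
                    rels: list[tuple[str, str, str]],
                    max_entities: int | None) -> Document:
    full = title + (" " + abstract if abstract else "")
    toks, char_spans = _char_to_token_map(full)
    sentences = split_sentences(toks)
    # map flat token index -> (sentence, token-in-sentence)
    flat_to_sent: list[tuple[int, int]] = []
    for si, sent in enumerate(sentences):
        for ti in range(len(sent)):
            flat_to_sent.append((si, ti))
    start_of = {a: i for i, (a, b) in enumerate(char_spans)}
    end_of = {b: i for i, (a, b) in enumerate(char_spans)}

    mentions: list[Mention] = []
    for k, (a, b, text, etype, eid) in enumerate(ann):
        if a not in start_of or b not in end_of:
            raise AlignmentError(
                f"doc {doc_id}: mention {text!r} at [{a},{b}) does not align "
                f"with token boundaries")
        t0, t1 = start_of[a], end_of[b]
        s0, s1 = flat_to_sent[t0], flat_to_sent[t1]
        if s0[0] != s1[0]:
            raise AlignmentError(
                f"doc {doc_id}: mention {text!r} at [{a},{b}) crosses a "
                f"sentence boundary")
        si = s0[0]
        span = (s0[1], s1[1] + 1)
        surface = tuple(sentences[si][span[0]:span[1]])
        mentions.append(Mention(f"{doc_id}.m{k}", eid, etype, si, span, surface))

    _check_overlaps(doc_id, mentions)
    entities = _group_entities(mentions)
    if max_entities is not None and len(entities) > max_entities:
        raise ValidationError(
            f"doc {doc_id}: {len(entities)} entities exceeds the configured "
            f"maximum N={max_entities}")
    known = {e.entity_id for e in entities}
    relations = []
    for label, h, t in rels:
        if h not in known or t not in known:
            raise ValidationError(
                f"doc {doc_id}: relation {label} references unknown entity "
                f"{h if h not in known else t!r}")
        relations.append(RelationInstance(h, t, label))
    return Document(doc_id, [list(s) for s in sentences], mentions, entities, relations)


def _check_overlaps(doc_id: str, mentions: list[Mention]) -> None:
    by_sent: dict[int, list[Mention]] = {}
    for m in mentions:
        by_sent.setdefault(m.sentence_index, []).append(m)
    for si, ms in by_sent.items():
        ms = sorted(ms, key=lambda m: m.token_span)
        for a, b in zip(ms, ms[1:]):
            if b.token_span[0] < a.token_span[1]:
                raise AlignmentError(
                    f"doc {doc_id}: overlapping mentions {a.mention_id}, "
                    f"{b.mention_id} in sentence {si}")


def read_pubtator(stream: TextIO | str, max_entities: int | None = None,
                  errors: str = "raise") -> list[Document]:
    """Parse a PubTator-format stream into :class:`Document` objects.

    ``errors='report'`` collects per-document alignment/validation
    failures and returns ``(documents, problems)`` instead of raising, so
    unusable documents are reported rather than silently dropped.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    blocks: list[list[tuple[int, str]]] = []
    cur: list[tuple[int, str]] = []
    for ln, line in enumerate(lines, start=1):
        if line.strip() == "":
            if cur:
                blocks.append(cur)
                cur = []
        else:
            cur.append((ln, line))
    if cur:
        blocks.append(cur)

    docs: list[Document] = []
    problems: list[str] = []
    for block in blocks:
        doc_id, title, abstract = None, "", ""
        ann: list[tuple[int, int, str, str, str]] = []
        rels: list[tuple[str, str, str]] = []
        for ln, line in block:
            if "|t|" in line:
                doc_id, title = line.split("|t|", 1)
            elif "|a|" in line:
                doc_id2, abstract = line.split("|a|", 1)
                doc_id = doc_id or doc_id2
            else:
                parts = line.split("\t")
                if len(parts) == 6:
                    pid, a, b, text, etype, eid = parts
                    try:
                        ann.append((int(a), int(b), text, etype, eid))
                    except ValueError:
                        raise PubTatorParseError(
                            f"line {ln}: non-integer offsets in annotation: {line!r}")
                elif len(parts) == 4:
                    pid, label, h, t = parts
                    rels.append((label, h, t))
                else:
                    raise PubTatorParseError(
                        f"line {ln}: malformed annotation line: {line!r}")
        if doc_id is None:
            raise PubTatorParseError(
                f"line {block[0][0]}: block without a title line")
        try:
            docs.append(_build_document(doc_id, title, abstract, ann, rels,
                                        max_entities))
        except (AlignmentError, ValidationError) as exc:
            if errors == "report":
                problems.append(str(exc))
            else:
                raise
    if errors == "report":
        return docs, problems  # type: ignore[return-value]
    return docs


# ---------------------------------------------------------------------------
# PubTator writing


def _detok(tokens: Iterable[str]) -> str:
    return " ".join(tokens)


def write_pubtator(docs: list[Document]) -> str:
    """Serialize documents to PubTator text; inverse of :func:`read_pubtator`."""
    out: list[str] = []
    for doc in docs:
        issues = validate_document(doc)
        if issues:
            raise ValidationError(
                f"doc {doc.doc_id}: invalid document: {issues[0]}")
        title = _detok(doc.sentences[0])
        abstract = _detok(tok for s in doc.sentences[1:] for tok in s)
        out.append(f"{doc.doc_id}|t|{title}")
        out.append(f"{doc.doc_id}|a|{abstract}")
        # character offset of each (sentence, token) in title + " " + abstract
        offsets: dict[tuple[int, int], tuple[int, int]] = {}
        pos = 0
        for si, sent in enumerate(doc.sentences):
            for ti, tok in enumerate(sent):
                offsets[(si, ti)] = (pos, pos + len(tok))
                pos += len(tok) + 1
        for m in sorted(doc.mentions,
                        key=lambda m: (m.sentence_index, m.token_span[0])):
            a = offsets[(m.sentence_index, m.token_span[0])][0]
            b = offsets[(m.sentence_index, m.token_span[1] - 1)][1]
            out.append("\t".join([doc.doc_id, str(a), str(b),
                                  _detok(m.surface), m.entity_type, m.entity_id]))
        for r in doc.relations:
            out.append("\t".join([doc.doc_id, r.label,
                                  r.head_entity_id, r.tail_entity_id]))
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# marker insertion


def insert_markers(doc: Document) -> MarkedSequence:
    """Produce the encoder input: per-sentence ``[CLS] ... [SEP]`` wrapping
    with each mention wrapped by a pair of ``&`` tokens.

    Total length is ``sum(len(s)) + 2 * n_sentences + 2 * n_mentions``.
    Overlapping mentions are rejected (the wrapping scheme is ill-defined
    for them).
    """
    _check_overlaps(doc.doc_id, doc.mentions)
    tokens: list[str] = []
    cls_index: dict[int, int] = {}
    sep_index: dict[int, int] = {}
    mention_marker: dict[str, int] = {}
    alignment: dict[tuple[int, int], int] = {}
    by_sent: dict[int, list[Mention]] = {}
    for m in doc.mentions:
        by_sent.setdefault(m.sentence_index, []).append(m)
    for si, sent in enumerate(doc.sentences):
        starts: dict[int, Mention] = {}
        ends: dict[int, Mention] = {}
        for m in sorted(by_sent.get(si, []), key=lambda m: m.token_span):
            starts[m.token_span[0]] = m
            ends[m.token_span[1]] = m
        cls_index[si] = len(tokens)
        tokens.append(CLS)
        for ti in range(len(sent) + 1):
            if ti in ends:
                tokens.append(MARKER)
            if ti in starts:
                mention_marker[starts[ti].mention_id] = len(tokens)
                tokens.append(MARKER)
            if ti < len(sent):
                alignment[(si, ti)] = len(tokens)
                tokens.append(sent[ti])
        sep_index[si] = len(tokens)
        tokens.append(SEP)
    return MarkedSequence(tokens, cls_index, sep_index, mention_marker, alignment)


# ---------------------------------------------------------------------------
# validation


def validate_document(doc: Document, max_entities: int | None = None) -> list[str]:
    """Check every document-model invariant; returns issues, raises nothing."""
    issues: list[str] = []
    mention_ids = {m.mention_id for m in doc.mentions}
    entity_ids = {e.entity_id for e in doc.entities}
    if len(mention_ids) != len(doc.mentions):
        issues.append("mentions: duplicate mention_id")
    if len(entity_ids) != len(doc.entities):
        issues.append("entities: duplicate entity_id")
    for m in doc.mentions:
        s, e = m.token_span
        if not (m.sentence_index < len(doc.sentences)):
            issues.append(f"mention {m.mention_id}: sentence_index out of range")
            continue
        sent = doc.sentences[m.sentence_index]
        if not (0 <= s < e <= len(sent)):
            issues.append(f"mention {m.mention_id}: span [{s},{e}) invalid for "
                          f"sentence of length {len(sent)}")
        elif tuple(sent[s:e]) != m.surface:
            issues.append(f"mention {m.mention_id}: surface does not match "
                          f"sentence tokens")
        if m.entity_id not in entity_ids:
            issues.append(f"mention {m.mention_id}: unknown entity {m.entity_id}")
    for ent in doc.entities:
        if not ent.mentions:
            issues.append(f"entity {ent.entity_id}: no mentions")
        for mid in ent.mentions:
            if mid not in mention_ids:
                issues.append(f"entity {ent.entity_id}: unknown mention {mid}")
            else:
                m = doc.mention(mid)
                if m.entity_id != ent.entity_id:
                    issues.append(f"entity {ent.entity_id}: mention {mid} "
                                  f"belongs to {m.entity_id}")
    for r in doc.relations:
        if r.head_entity_id == r.tail_entity_id:
            issues.append(f"relation {r.label}: head equals tail "
                          f"({r.head_entity_id})")
        for eid in (r.head_entity_id, r.tail_entity_id):
            if eid not in entity_ids:
                issues.append(f"relation {r.label}: unknown entity {eid}")
    if max_entities is not None and len(doc.entities) > max_entities:
        issues.append(f"document: entity count {len(doc.entities)} exceeds N="
                      f"{max_entities}")
    return issues


# ---------------------------------------------------------------------------
# JSON-lines serialization (fixture format)


def _doc_to_dict(doc: Document) -> dict:
    d = asdict(doc)
    return d


def _doc_from_dict(d: dict) -> Document:
    mentions = [Mention(m["mention_id"], m["entity_id"], m["entity_type"],
                        m["sentence_index"], tuple(m["token_span"]),
                        tuple(m["surface"])) for m in d["mentions"]]
    entities = [Entity(e["entity_id"], e["entity_type"], tuple(e["mentions"]))
                for e in d["entities"]]
    relations = [RelationInstance(r["head_entity_id"], r["tail_entity_id"],
                                  r["label"]) for r in d["relations"]]
    return Document(d["doc_id"], [list(s) for s in d["sentences"]],
                    mentions, entities, relations)


def docs_to_jsonl(docs: list[Document]) -> str:
    return "\n".join(json.dumps(_doc_to_dict(d)) for d in docs)


def docs_from_jsonl(text: str) -> list[Document]:
    return [_doc_from_dict(json.loads(line))
            for line in text.splitlines() if line.strip()]
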