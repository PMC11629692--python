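"""Synthetic corpora with the statistical structure of document-level
biomedical relation extraction.

Each generated document mimics a PubMed abstract annotated at the
concept level: several sentences, entities of typed concepts (variant /
gene / disease-like), entities surfacing as multiple (possibly aliased)
mentions, intra-sentence relations signalled by a trigger token between
two co-occurring mentions, and inter-sentence relations that exist only
because two intra-sentence facts compose through a shared bridge entity
(variant--gene plus gene--disease implies variant--disease).  The
conclusion label of a composition rule is never emitted by any trigger
rule, so inter-sentence instances cannot be recovered by a per-sentence
trigger heuristic; identifying them requires entity-pair-level
reasoning.

Generation is fully deterministic given ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corpus_io import (
    Document,
    Entity,
    Mention,
    RelationInstance,
    validate_document,
)

__all__ = [
    "TriggerRule",
    "CompositionRule",
    "SynthConfig",
    "default_config",
    "generate_corpus",
    "close_under_composition",
    "ConfigError",
]


class ConfigError(ValueError):
    """The generator configuration is inconsistent or unsatisfiable."""


@dataclass(frozen=True)
class TriggerRule:
    """An intra-sentence pattern: ``head TRIGGER tail`` emits ``label``."""

    head_type: str
    tail_type: str
    trigger_token: str
    label: str


@dataclass(frozen=True)
class CompositionRule:
    """(A, B, premise_1) and (B, C, premise_2) imply (A, C, conclusion)."""

    premise_label_1: str
    premise_label_2: str
    conclusion_label: str


@dataclass
class SynthConfig:
    n_docs: int = 64
    vocab_size: int = 40                  # filler token pool
    n_entity_types: int = 3
    relation_labels: tuple[str, ...] = (
        "associates", "contributes", "causes", "resembles")
    sentences_per_doc: tuple[int, int] = (3, 6)
    entities_per_doc: tuple[int, int] = (3, 6)
    mentions_per_entity: tuple[int, int] = (1, 3)
    trigger_rules: tuple[TriggerRule, ...] = ()
    composition_rules: tuple[CompositionRule, ...] = ()
    label_noise_rate: float = 0.0         # probability a gold relation is dropped
    alias_prob: float = 0.5               # chance a mention uses the alias surface
    max_entities: int = 8                 # hard cap N of the pair matrix
    seed: int = 0

    def validate(self) -> None:
        if not self.trigger_rules:
            raise ConfigError("at least one trigger rule is required")
        if self.entities_per_doc[1] > self.max_entities:
            raise ConfigError("entities_per_doc max exceeds max_entities N")
        if not (0.0 <= self.label_noise_rate <= 1.0):
            raise ConfigError("label_noise_rate must be a probability")
        if not (0.0 <= self.alias_prob <= 1.0):
            raise ConfigError("alias_prob must be a probability")
        labels = set(self.relation_labels)
        for tr in self.trigger_rules:
            if tr.label not in labels:
                raise ConfigError(f"trigger rule label {tr.label!r} not in "
                                  f"relation_labels")
        for cr in self.composition_rules:
            for lab in (cr.premise_label_1, cr.premise_label_2,
                        cr.conclusion_label):
                if lab not in labels:
                    raise ConfigError(f"composition rule label {lab!r} not in "
                                      f"relation_labels")
        for lo, hi in (self.sentences_per_doc, self.entities_per_doc,
                       self.mentions_per_entity):
            if lo < 1 or hi < lo:
                raise ConfigError("ranges must satisfy 1 <= lo <= hi")


# default study conditions: a variant -> gene -> disease reasoning chain
_TYPES = ("variant", "gene", "disease")


def default_config(**overrides) -> SynthConfig:
    """The packaged study conditions: 4 labels, 3 typed concept pools,
    trigger rules for three labels and one composition rule whose
    conclusion label ("causes") has no trigger of its own."""
    cfg = SynthConfig(
        trigger_rules=(
            TriggerRule("variant", "gene", "linkedto", "associates"),
            TriggerRule("gene", "disease", "implicatedin", "contributes"),
            TriggerRule("disease", "disease", "resembling", "resembles"),
        ),
        composition_rules=(
            CompositionRule("associates", "contributes", "causes"),
        ),
    )
    return replace(cfg, **overrides)


def close_under_composition(
    relations: set[RelationInstance],
    rules: list[CompositionRule] | tuple[CompositionRule, ...],
) -> set[RelationInstance]:
    """One-step composition closure.

    For every pair of facts (A,B,r1), (B,C,r2) matching a rule
    (r1, r2 -> r3) with A != C, the conclusion (A,C,r3) is added.  Exactly
    one step is applied; conclusions do not feed further conclusions.
    """
    out = set(relations)
    for rule in rules:
        for p1 in relations:
            if p1.label != rule.premise_label_1:
                continue
            for p2 in relations:
                if p2.label != rule.premise_label_2:
                    continue
                if p1.tail_entity_id != p2.head_entity_id:
                    continue
                if p1.head_entity_id == p2.tail_entity_id:
                    continue
                out.add(RelationInstance(p1.head_entity_id,
                                         p2.tail_entity_id,
                                         rule.conclusion_label))
    return out


# ---------------------------------------------------------------------------
# generation internals


@dataclass
class _EntitySpec:
    entity_id: str
    entity_type: str
    surfaces: tuple[str, str]  # base form and alias


def _sample_entities(rng: np.random.Generator, cfg: SynthConfig,
                     doc_idx: int) -> list[_EntitySpec]:
    n_ent = int(rng.integers(cfg.entities_per_doc[0],
                             cfg.entities_per_doc[1] + 1))
    type_names = [_TYPES[i] if i < len(_TYPES) else f"type{i}"
                  for i in range(cfg.n_entity_types)]
    # guarantee each type in the doc where possible so chains can form
    types = [type_names[i % len(type_names)] for i in range(n_ent)]
    rng.shuffle(types)
    specs = []
    counters: dict[str, int] = {}
    for t in types:
        k = counters.get(t, 0)
        counters[t] = k + 1
        eid = f"{t[0].upper()}{doc_idx:03d}{k}"
        # typed surface pools shared across documents
        base = f"{t}{int(rng.integers(0, 12))}x"
        alias = f"{t}{int(rng.integers(0, 12))}y"
        specs.append(_EntitySpec(eid, t, (base, alias)))
    return specs


def _co_occurs(sent_entities: set[str], pair: tuple[str, str]) -> bool:
    return pair[0] in sent_entities and pair[1] in sent_entities


def generate_corpus(config: SynthConfig, seed: int | None = None) -> list[Document]:
    """Generate ``config.n_docs`` labeled documents.

    Per document: entities are sampled with types and two surface forms;
    each sentence hosts at most one trigger fact (``head trigger tail``)
    between type-compatible entities, embedded in filler tokens; extra
    solo mentions are sprinkled subject to the constraint that both ends
    of a composed (inter-sentence) relation never co-occur in one
    sentence; the gold set is the trigger facts closed one step under the
    composition rules, with each instance then dropped with probability
    ``label_noise_rate``.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    docs: list[Document] = []
    for d in range(config.n_docs):
        rng = np.random.default_rng([seed, d])
        docs.append(_generate_doc(rng, config, d))
    return docs


def _generate_doc(rng: np.random.Generator, cfg: SynthConfig,
                  doc_idx: int) -> Document:
    for _ in range(40):  # resample until every entity is mentioned
        doc = _try_generate_doc(rng, cfg, doc_idx)
        if doc is not None:
            return doc
    raise ConfigError(
        f"could not generate a valid document for doc {doc_idx}; "
        f"config is likely unsatisfiable")


def _try_generate_doc(rng: np.random.Generator, cfg: SynthConfig,
                      doc_idx: int) -> Document | None:
    ents = _sample_entities(rng, cfg, doc_idx)
    by_type: dict[str, list[_EntitySpec]] = {}
    for e in ents:
        by_type.setdefault(e.entity_type, []).append(e)
    n_sent = int(rng.integers(cfg.sentences_per_doc[0],
                              cfg.sentences_per_doc[1] + 1))

    # choose one trigger fact per sentence (where a compatible pair exists)
    facts: list[tuple[int, TriggerRule, _EntitySpec, _EntitySpec]] = []
    fact_rels: set[RelationInstance] = set()
    for si in range(n_sent):
        usable = [tr for tr in cfg.trigger_rules
                  if by_type.get(tr.head_type) and by_type.get(tr.tail_type)]
        if not usable or rng.random() < 0.15:
            continue
        tr = usable[int(rng.integers(0, len(usable)))]
        heads = by_type[tr.head_type]
        tails = by_type[tr.tail_type]
        h = heads[int(rng.integers(0, len(heads)))]
        t = tails[int(rng.integers(0, len(tails)))]
        if h.entity_id == t.entity_id:
            continue
        facts.append((si, tr, h, t))
        fact_rels.add(RelationInstance(h.entity_id, t.entity_id, tr.label))

    gold = close_under_composition(fact_rels, cfg.composition_rules)
    inter_pairs = {(r.head_entity_id, r.tail_entity_id)
                   for r in gold - fact_rels}
    inter_pairs |= {(b, a) for a, b in inter_pairs}

    # build sentences: filler + fact pattern + optional solo mentions
    sentences: list[list[str]] = []
    mentions: list[Mention] = []
    mcount = 0
    mention_budget: dict[str, int] = {
        e.entity_id: int(rng.integers(cfg.mentions_per_entity[0],
                                      cfg.mentions_per_entity[1] + 1))
        for e in ents}
    used: dict[str, int] = {e.entity_id: 0 for e in ents}
    facts_by_sent = {si: (tr, h, t) for si, tr, h, t in facts}

    def surface(e: _EntitySpec) -> str:
        return e.surfaces[1] if rng.random() < cfg.alias_prob else e.surfaces[0]

    def filler(k: int) -> list[str]:
        return [f"w{int(rng.integers(0, cfg.vocab_size))}" for _ in range(k)]

    for si in range(n_sent):
        toks: list[str] = []
        sent_ents: set[str] = set()
        local: list[tuple[_EntitySpec, int, int]] = []  # (entity, start, end)

        def emit_mention(e: _EntitySpec) -> None:
            start = len(toks)
            toks.append(surface(e))
            local.append((e, start, start + 1))
            sent_ents.add(e.entity_id)

        toks.extend(filler(int(rng.integers(1, 4))))
        if si in facts_by_sent:
            tr, h, t = facts_by_sent[si]
            emit_mention(h)
            toks.append(tr.trigger_token)
            emit_mention(t)
            sent_ents.update({h.entity_id, t.entity_id})
        # solo mentions for under-mentioned entities, avoiding inter-pair
        # co-occurrence and accidental trigger adjacency
        candidates = [e for e in ents if used[e.entity_id] +
                      sum(1 for x, _, _ in local if x.entity_id == e.entity_id)
                      < mention_budget[e.entity_id]]
        rng.shuffle(candidates)
        for e in candidates[:2]:
            if e.entity_id in sent_ents:
                continue
            if any(_co_occurs(sent_ents | {e.entity_id}, p)
                   for p in inter_pairs):
                continue
            toks.extend(filler(int(rng.integers(1, 3))))
            emit_mention(e)
        toks.extend(filler(int(rng.integers(1, 3))))
        toks.append(".")
        for e, a, b in local:
            used[e.entity_id] += 1
            mentions.append(Mention(f"{doc_idx}.m{mcount}", e.entity_id,
                                    e.entity_type, si, (a, b),
                                    tuple(toks[a:b])))
            mcount += 1
        sentences.append(toks)

    if any(used[e.entity_id] == 0 for e in ents):
        return None  # some entity never surfaced; resample

    entities = []
    for e in ents:
        mids = tuple(m.mention_id for m in sorted(
            (m for m in mentions if m.entity_id == e.entity_id),
            key=lambda m: (m.sentence_index, m.token_span[0])))
        entities.append(Entity(e.entity_id, e.entity_type, mids))

    relations = sorted(gold, key=lambda r: (r.head_entity_id,
                                            r.tail_entity_id, r.label))
    if cfg.label_noise_rate > 0:
        relations = [r for r in relations
                     if rng.random() >= cfg.label_noise_rate]

    doc = Document(str(doc_idx), sentences, mentions, entities, relations)
    issues = validate_document(doc, max_entities=cfg.max_entities)
    if issues:  # pragma: no cover - generator bug guard
        raise AssertionError(f"generator produced invalid doc: {issues}")
    return doc
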