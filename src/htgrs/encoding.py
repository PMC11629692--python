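"""Token encoding: a tiny trainable reference encoder.

The contract is the one a pre-trained language model would fulfil: map
the marked token sequence (``[CLS]``/``[SEP]`` per sentence, ``&``
mention markers) to one d_emb row per token, differentiably.  The
reference encoder is an embedding lookup followed by a learnable local
mixing window (depth-1 averaging by default) and an optional layer
normalization — enough context sensitivity for ``[CLS]`` rows to learn
sentence summaries and for marker rows to absorb their neighbours,
while staying CPU-trivial.

An external pre-trained encoder can be slotted in through
:class:`EncoderProtocol`: anything callable on a
:class:`~htgrs.corpus_io.MarkedSequence` returning a row-aligned matrix
of matching width participates in the pipeline unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from ._tensor import Parameter, Tensor, concatenate, stack
from .corpus_io import CLS, MARKER, SEP, Document, MarkedSequence

__all__ = ["Vocabulary", "EncoderParams", "TokenEmbeddings", "encode",
           "build_vocabulary", "EncoderProtocol"]

UNK = "[UNK]"
_CONTROL = (UNK, CLS, SEP, MARKER)


@dataclass
class TokenEmbeddings:
    """L x d_emb matrix, rows aligned with ``MarkedSequence.tokens``."""

    matrix: Tensor

    @property
    def d_emb(self) -> int:
        return self.matrix.shape[1]


class Vocabulary:
    """Token -> index map with reserved control tokens and UNK fallback."""

    def __init__(self, tokens: list[str]):
        self.itos = list(_CONTROL) + [t for t in tokens if t not in _CONTROL]
        self.stoi = {t: i for i, t in enumerate(self.itos)}

    def __len__(self) -> int:
        return len(self.itos)

    def index(self, token: str) -> int:
        return self.stoi.get(token, 0)

    def encode(self, tokens: list[str]) -> np.ndarray:
        return np.array([self.index(t) for t in tokens], dtype=np.intp)

    def to_dict(self) -> dict:
        return {"itos": self.itos}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        v = cls.__new__(cls)
        v.itos = list(d["itos"])
        v.stoi = {t: i for i, t in enumerate(v.itos)}
        return v


def build_vocabulary(docs: list[Document]) -> Vocabulary:
    seen: dict[str, None] = {}
    for doc in docs:
        for sent in doc.sentences:
            for tok in sent:
                seen.setdefault(tok, None)
    return Vocabulary(list(seen))


class EncoderProtocol(Protocol):
    def __call__(self, seq: MarkedSequence) -> TokenEmbeddings: ...


@dataclass
class EncoderParams:
    """Reference encoder parameters.

    ``window`` is the half-width k of the mixing window: row i becomes a
    learnable weighted combination of the embedding-table rows of tokens
    i-k .. i+k (zero-padded at the edges).  With k = 0 and ``layer_norm``
    off, the encoder degenerates to a pure table lookup.
    """

    vocab: Vocabulary
    d_emb: int
    window: int = 1
    layer_norm: bool = True
    embedding: Parameter = field(init=False)
    mix: Parameter = field(init=False)          # 2k+1 scalar weights
    ln_gain: Parameter = field(init=False)
    ln_bias: Parameter = field(init=False)

    def __post_init__(self):
        if self.d_emb <= 0:
            raise ValueError("d_emb must be positive")
        self._rng = None

    def initialize(self, seed: int) -> "EncoderParams":
        rng = np.random.default_rng(seed)
        self.embedding = Parameter(
            rng.normal(0.0, 0.5, size=(len(self.vocab), self.d_emb)))
        k = self.window
        mix = np.full(2 * k + 1, 0.25)
        mix[k] = 1.0
        self.mix = Parameter(mix)
        self.ln_gain = Parameter(np.ones(self.d_emb))
        self.ln_bias = Parameter(np.zeros(self.d_emb))
        return self

    def parameters(self) -> list[Parameter]:
        return [self.embedding, self.mix, self.ln_gain, self.ln_bias]


def _layer_norm(x: Tensor, gain: Parameter, bias: Parameter,
                eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / ((var + eps) ** 0.5) * gain + bias


def encode(seq: MarkedSequence, params: EncoderParams) -> TokenEmbeddings:
    """Embed a marked sequence; deterministic given ``params``."""
    ids = params.vocab.encode(seq.tokens)
    rows = params.embedding[ids]                       # L x d
    k = params.window
    if k == 0:
        mixed = rows * params.mix[0]
    else:
        L = len(ids)
        zero = Tensor(np.zeros((k, params.d_emb)))
        padded = concatenate([zero, rows, zero], axis=0)
        shifted = [padded[j:j + L] * params.mix[j] for j in range(2 * k + 1)]
        mixed = shifted[0]
        for s in shifted[1:]:
            mixed = mixed + s
    if params.layer_norm:
        mixed = _layer_norm(mixed, params.ln_gain, params.ln_bias)
    if not np.all(np.isfinite(mixed.data)):
        raise FloatingPointError("non-finite token embeddings")
    return TokenEmbeddings(mixed)
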