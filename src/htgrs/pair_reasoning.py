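"""Stage 2: entity-pair feature matrix and the relation segmentation (RS)
module.

Mentions of an entity are pooled with logsumexp into one entity vector;
the ordered entity pair (s, o) gets the elementwise product e_s * e_o as
its cell in an N x N x D feature matrix (N the configured entity cap, D
the embedding width; cells beyond the document's entity count are
zero-masked padding).  The RS module treats the matrix as a D-channel
image and refines it with a stack of [5x5 same-padded convolution ->
BatchNorm -> ReLU -> criss-cross attention] layers, so each pair
repeatedly exchanges information with the pairs in its own row and
column — two stacked layers give every cell a path to every other cell.

``cc_attention_reference`` is a deliberately naive per-cell loop kept as
an independent oracle for the vectorized attention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Parameter, Tensor, concatenate, conv2d_same, stack

__all__ = [
    "EntityEmbeddings",
    "PairMatrix",
    "CCAParams",
    "RSParams",
    "pool_entity",
    "build_pair_matrix",
    "criss_cross_attention",
    "cc_attention_reference",
    "rs_forward",
]

_NEG = -1e9  # additive mask; exp underflows to exactly 0 in float64


@dataclass
class EntityEmbeddings:
    """One d_emb vector per entity, ordered by first mention position."""

    vectors: Tensor          # n_e x d_emb
    entity_ids: list[str]

    @property
    def n_e(self) -> int:
        return self.vectors.shape[0]


@dataclass
class PairMatrix:
    cells: Tensor            # N x N x D; padding cells zero
    mask: np.ndarray         # N x N bool; True iff both indices < n_e
    n_e: int
    N: int


def pool_entity(mention_vectors: list[Tensor]) -> Tensor:
    """Logsumexp pooling over an entity's mention vectors (max-shifted)."""
    if not mention_vectors:
        raise ValueError("cannot pool an entity with no mentions")
    if len(mention_vectors) == 1:
        return mention_vectors[0]
    return stack(mention_vectors, axis=0).logsumexp(axis=0)


def build_pair_matrix(ents: EntityEmbeddings, N: int) -> PairMatrix:
    """Cell (s, o) = e_s * e_o elementwise, for s, o < n_e; padding zero."""
    n_e = ents.n_e
    if n_e < 2:
        raise ValueError("need at least two entities to form pairs")
    if n_e > N:
        raise ValueError(f"entity count {n_e} exceeds matrix size N={N}")
    d = ents.vectors.shape[1]
    e = ents.vectors
    cells = e.reshape(n_e, 1, d) * e.reshape(1, n_e, d)
    if n_e < N:
        pad_r = Tensor(np.zeros((N - n_e, n_e, d)))
        pad_c = Tensor(np.zeros((N, N - n_e, d)))
        cells = concatenate([cells, pad_r], axis=0)
        cells = concatenate([cells, pad_c], axis=1)
    mask = np.zeros((N, N), dtype=bool)
    mask[:n_e, :n_e] = True
    return PairMatrix(cells, mask, n_e, N)


@dataclass
class CCAParams:
    """Criss-cross attention projections (query/key/value)."""

    d: int
    d_key: int
    w_q: Parameter
    w_k: Parameter
    w_v: Parameter
    residual: bool = True

    @classmethod
    def create(cls, d: int, rng: np.random.Generator, d_key: int | None = None,
               residual: bool = True) -> "CCAParams":
        d_key = d_key or max(d // 2, 1)
        s = 1.0 / np.sqrt(d)
        # value map starts small so the residual branch dominates at init
        return cls(d, d_key,
                   Parameter(rng.normal(0, s, (d, d_key))),
                   Parameter(rng.normal(0, s, (d, d_key))),
                   Parameter(rng.normal(0, 0.1 * s, (d, d))),
                   residual)

    def parameters(self) -> list[Parameter]:
        return [self.w_q, self.w_k, self.w_v]


def _apply_mask_output(cells: Tensor, mask: np.ndarray) -> Tensor:
    return cells * mask[:, :, None].astype(float)


def criss_cross_attention(m: PairMatrix, params: CCAParams) -> PairMatrix:
    """Vectorized criss-cross attention over the pair matrix.

    Each valid cell (s, o) attends, with scaled-dot-product weights, to
    the valid cells of row s and column o — its criss-cross set of
    2*n_e - 1 positions, the cell itself counted once.  Masked padding
    never attends nor is attended to.  The value-projected aggregate is
    added residually to the input (toggleable).
    """
    N, _, D = m.cells.shape
    n_e = m.n_e
    scale = 1.0 / np.sqrt(params.d_key)
    q = m.cells @ params.w_q          # N x N x dk
    k = m.cells @ params.w_k
    v = m.cells @ params.w_v          # N x N x D

    # row energies: E_row[s, o, i] = q[s,o] . k[s,i]
    e_row = q @ k.transpose(0, 2, 1) * scale              # N x N x N
    # column energies: E_col[s, o, i] = q[s,o] . k[i,o]
    e_col = (q.transpose(1, 0, 2) @ k.transpose(1, 2, 0)).transpose(1, 0, 2) * scale

    valid = np.arange(N) < n_e
    bias_row = np.where(valid, 0.0, _NEG)[None, None, :]
    # drop the duplicate self position (i = s) from the column side
    dup = np.zeros((N, N, N))
    dup[np.arange(N), :, np.arange(N)] = _NEG
    bias_col = np.where(valid, 0.0, _NEG)[None, None, :] + dup

    energy = concatenate([e_row + Tensor(np.broadcast_to(bias_row, (N, N, N)).copy()),
                          e_col + Tensor(bias_col + np.broadcast_to(bias_row, (N, N, N)))],
                         axis=2)                           # N x N x 2N
    att = energy.softmax(axis=2)
    a_row = att[:, :, :N]
    a_col = att[:, :, N:]
    out_row = a_row @ v                                   # N x N x D
    out_col = (a_col.transpose(1, 0, 2) @ v.transpose(1, 0, 2)).transpose(1, 0, 2)
    agg = out_row + out_col
    cells = m.cells + agg if params.residual else agg
    cells = _apply_mask_output(cells, m.mask)
    return PairMatrix(cells, m.mask, n_e, m.N)


def cc_attention_reference(m: PairMatrix, params: CCAParams) -> PairMatrix:
    """Per-cell loop oracle for :func:`criss_cross_attention` (numpy only)."""
    cells = m.cells.data
    N, _, D = cells.shape
    n_e = m.n_e
    scale = 1.0 / np.sqrt(params.d_key)
    wq, wk, wv = params.w_q.data, params.w_k.data, params.w_v.data
    out = np.zeros_like(cells)
    for s in range(N):
        for o in range(N):
            if not m.mask[s, o]:
                continue
            q = cells[s, o] @ wq
            positions = [("row", s, i) for i in range(n_e)]
            positions += [("col", i, o) for i in range(n_e) if i != s]
            energies = np.array([scale * np.dot(q, cells[a, b] @ wk)
                                 for _, a, b in positions])
            w = np.exp(energies - energies.max())
            w /= w.sum()
            agg = sum(wi * (cells[a, b] @ wv)
                      for wi, (_, a, b) in zip(w, positions))
            out[s, o] = agg
    result = cells * m.mask[:, :, None] + out if params.residual else out
    result = result * m.mask[:, :, None]
    return PairMatrix(Tensor(result), m.mask, n_e, m.N)


def cc_attention_weights(m: PairMatrix, params: CCAParams,
                         s: int, o: int) -> np.ndarray:
    """The softmax weights of one cell over its criss-cross set (oracle
    helper; length 2*n_e - 1)."""
    cells = m.cells.data
    n_e = m.n_e
    scale = 1.0 / np.sqrt(params.d_key)
    q = cells[s, o] @ params.w_q.data
    positions = [(s, i) for i in range(n_e)]
    positions += [(i, o) for i in range(n_e) if i != s]
    e = np.array([scale * np.dot(q, cells[a, b] @ params.w_k.data)
                  for a, b in positions])
    w = np.exp(e - e.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# RS module


@dataclass
class BatchNormParams:
    gamma: Parameter
    beta: Parameter
    running_mean: np.ndarray
    running_var: np.ndarray
    momentum: float = 0.1
    eps: float = 1e-5

    @classmethod
    def create(cls, d: int) -> "BatchNormParams":
        return cls(Parameter(np.ones(d)), Parameter(np.zeros(d)),
                   np.zeros(d), np.ones(d))

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


def _batch_norm(x: Tensor, bn: BatchNormParams, mask: np.ndarray,
                training: bool) -> Tensor:
    """Channel-wise normalisation treating the N x N cells as spatial
    positions.  Statistics are computed over the *valid* (masked-in)
    cells only, so padding never leaks into normalisation and outputs
    are invariant to enlarging N with extra padding; eval mode uses
    running statistics."""
    # x: N x N x D
    if training:
        mf = mask[:, :, None].astype(float)
        n_valid = float(mask.sum())
        mu = (x * mf).sum(axis=0, keepdims=True).sum(axis=1, keepdims=True) \
            * (1.0 / n_valid)
        xc = x - mu
        var = (xc * xc * mf).sum(axis=0, keepdims=True).sum(axis=1, keepdims=True) \
            * (1.0 / n_valid)
        bn.running_mean = ((1 - bn.momentum) * bn.running_mean
                           + bn.momentum * mu.data.reshape(-1))
        bn.running_var = ((1 - bn.momentum) * bn.running_var
                          + bn.momentum * var.data.reshape(-1))
        xn = xc / ((var + bn.eps) ** 0.5)
    else:
        xn = (x - bn.running_mean[None, None, :]) / np.sqrt(
            bn.running_var[None, None, :] + bn.eps)
    return xn * bn.gamma + bn.beta


@dataclass
class RSLayer:
    conv_w: Parameter        # D x D x 5 x 5
    conv_b: Parameter
    bn: BatchNormParams
    cca: CCAParams


@dataclass
class RSParams:
    """The relation-segmentation stack: input mixing ``W_M`` followed by
    ``n_layers`` blocks of [conv 5x5 -> BatchNorm -> ReLU -> criss-cross
    attention].  ``W_M`` is a D x D channel-mixing map.  ``dropout`` is
    applied to the post-ReLU features during training only (inverted
    scaling), a regularizer against pair-level memorisation at small
    corpus sizes."""

    d: int
    n_layers: int = 2
    kernel: int = 5
    dropout: float = 0.25
    w_m: Parameter | None = None
    layers: list[RSLayer] = field(default_factory=list)
    _drop_rng: np.random.Generator | None = None

    def initialize(self, seed: int, residual: bool = True) -> "RSParams":
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.kernel != 5:
            raise ValueError("the RS block uses a 5x5 kernel")
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng([seed, 1])
        d, k = self.d, self.kernel
        # identity-leaning init: W_M near the identity and conv kernels
        # near a centered delta, so the stack starts close to a
        # pass-through and training learns deviations from it
        self.w_m = Parameter(np.eye(d) + rng.normal(0, 0.1 / np.sqrt(d), (d, d)))
        self.layers = []
        for _ in range(self.n_layers):
            fan_in = d * k * k
            w = rng.normal(0, 0.1 / np.sqrt(fan_in), (d, d, k, k))
            w[:, :, k // 2, k // 2] += np.eye(d)
            self.layers.append(RSLayer(
                Parameter(w),
                Parameter(np.zeros(d)),
                BatchNormParams.create(d),
                CCAParams.create(d, rng, residual=residual)))
        return self

    def parameters(self) -> list[Parameter]:
        ps = [self.w_m]
        for layer in self.layers:
            ps += [layer.conv_w, layer.conv_b]
            ps += layer.bn.parameters()
            ps += layer.cca.parameters()
        return ps


def rs_forward(m: PairMatrix, params: RSParams,
               training: bool = False) -> PairMatrix:
    """Refine the pair matrix; output shape equals input shape and
    padding cells are re-zeroed after every block."""
    cells = _apply_mask_output(m.cells @ params.w_m, m.mask)
    cur = PairMatrix(cells, m.mask, m.n_e, m.N)
    for li, layer in enumerate(params.layers):
        x = cur.cells.transpose(2, 0, 1)          # D x N x N
        x = conv2d_same(x, layer.conv_w, layer.conv_b, params.kernel)
        x = x.transpose(1, 2, 0)                  # N x N x D
        x = _batch_norm(x, layer.bn, m.mask, training)
        x = x.relu()
        if training and params.dropout > 0:
            keep = ((params._drop_rng.random(x.shape) >= params.dropout)
                    / (1.0 - params.dropout))
            x = x * keep
        x = _apply_mask_output(x, m.mask)
        cur = criss_cross_attention(
            PairMatrix(x, m.mask, m.n_e, m.N), layer.cca)
        if not np.all(np.isfinite(cur.cells.data)):
            raise FloatingPointError(f"non-finite activations in RS layer {li}")
    return cur
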