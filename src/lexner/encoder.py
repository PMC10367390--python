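"""Character transformer encoder with directional relative positions and
entity-dictionary key/value fusion.

The stack follows the TENER lineage: attention logits are

    A(t, j) = [ q_t k_j^T  +  q_t R_{t-j}^T  +  u k_j^T  +  v R_{t-j}^T ] / sqrt(d_k)

where R is a *signed* sinusoidal table (sin slots are odd in the offset, so
left and right context score differently) and u, v are learnable per-head
bias vectors.  Keys and values are fused with the matched dictionary
entity's embedding: for a character whose entity tag e_t is nonzero,

    k_t = 1/2 (h_t W_hk + E_ent[e_t] W_ek),     v_t analogously,

while e_t = 0 positions use the plain projections.  With the position terms
off, the resulting attention row is exactly the normalised geometric mean
sqrt(s^c s^e) of the character-only and entity-only attention scores.

Heads are concatenated without an output projection; a GELU feed-forward
block (inner width 4 d_model) with residual + layer norm follows each
attention sublayer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor, einsum2, layer_norm, softmax


@dataclass
class EncoderConfig:
    d_model: int = 64            # H_c, character hidden width
    d_entity: int = 64           # H_e, entity embedding width
    n_layers: int = 2
    n_heads: int = 4
    dropout: float = 0.1
    max_len: int = 160
    use_entity_fusion: bool = True
    use_relative_position: bool = True
    use_absolute_position: bool = True

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


def relative_position(offset: int, d: int) -> np.ndarray:
    """Directional sinusoidal encoding of a signed offset.

    Slot 2i is sin(c_i * offset), slot 2i+1 is cos(c_i * offset) with
    c_i = 10000^(-2i/d).  Because sin is odd and cos is even, negating the
    offset negates exactly the sin slots.
    """
    if d % 2:
        raise ValueError("dimension must be even")
    i = np.arange(d // 2)
    c = 10000.0 ** (-2.0 * i / d)
    out = np.empty(d)
    out[0::2] = np.sin(c * offset)
    out[1::2] = np.cos(c * offset)
    return out


def relative_position_table(T: int, d: int) -> np.ndarray:
    """R[t, j] = encoding of offset (t - j); shape (T, T, d)."""
    offsets = np.arange(-(T - 1), T)
    i = np.arange(d // 2)
    c = 10000.0 ** (-2.0 * i / d)
    arg = offsets[:, None] * c[None, :]
    flat = np.empty((len(offsets), d))
    flat[:, 0::2] = np.sin(arg)
    flat[:, 1::2] = np.cos(arg)
    t = np.arange(T)
    return flat[(t[:, None] - t[None, :]) + (T - 1)]


def _normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return rng.normal(0.0, std, size=shape)


@dataclass
class EncoderParams:
    """All trainable encoder tables, built with ``init``."""

    E_c: Parameter
    E_p: Parameter
    E_ent: Parameter
    layers: list[dict] = field(default_factory=list)

    @staticmethod
    def init(cfg: EncoderConfig, vocab_size: int, n_entities: int,
             rng: np.random.Generator) -> "EncoderParams":
        d, de = cfg.d_model, cfg.d_entity
        layers = []
        for li in range(cfg.n_layers):
            layers.append({
                "W_hq": Parameter(_normal(rng, (d, d)), f"L{li}.W_hq"),
                "W_hk": Parameter(_normal(rng, (d, d)), f"L{li}.W_hk"),
                "W_hv": Parameter(_normal(rng, (d, d)), f"L{li}.W_hv"),
                "W_ek": Parameter(_normal(rng, (de, d)), f"L{li}.W_ek"),
                "W_ev": Parameter(_normal(rng, (de, d)), f"L{li}.W_ev"),
                "u": Parameter(np.zeros((cfg.n_heads, cfg.d_head)), f"L{li}.u"),
                "v": Parameter(np.zeros((cfg.n_heads, cfg.d_head)), f"L{li}.v"),
                "ln1_g": Parameter(np.ones(d), f"L{li}.ln1_g"),
                "ln1_b": Parameter(np.zeros(d), f"L{li}.ln1_b"),
                "ln2_g": Parameter(np.ones(d), f"L{li}.ln2_g"),
                "ln2_b": Parameter(np.zeros(d), f"L{li}.ln2_b"),
                "ffn_W1": Parameter(_normal(rng, (d, 4 * d)), f"L{li}.ffn_W1"),
                "ffn_b1": Parameter(np.zeros(4 * d), f"L{li}.ffn_b1"),
                "ffn_W2": Parameter(_normal(rng, (4 * d, d)), f"L{li}.ffn_W2"),
                "ffn_b2": Parameter(np.zeros(d), f"L{li}.ffn_b2"),
            })
        return EncoderParams(
            E_c=Parameter(_normal(rng, (vocab_size, d)), "E_c"),
            E_p=Parameter(_normal(rng, (cfg.max_len, d)), "E_p"),
            E_ent=Parameter(_normal(rng, (n_entities + 1, de)), "E_ent"),
            layers=layers,
        )

    def parameters(self) -> list[Parameter]:
        out = [self.E_c, self.E_p, self.E_ent]
        for layer in self.layers:
            out.extend(layer.values())
        return out


def embed(char_ids: np.ndarray, params: EncoderParams,
          cfg: EncoderConfig) -> Tensor:
    """Layer-1 states: character embedding plus absolute position embedding."""
    char_ids = np.atleast_2d(np.asarray(char_ids, dtype=np.intp))
    T = char_ids.shape[1]
    if T > cfg.max_len:
        raise ValueError(f"sequence length {T} exceeds max_len {cfg.max_len}")
    h = params.E_c[char_ids]
    if cfg.use_absolute_position:
        h = h + params.E_p[np.arange(T)].reshape(1, T, cfg.d_model)
    return h


def fuse_key_value(hidden: Tensor, ent_ids: np.ndarray, layer: dict,
                   params: EncoderParams, cfg: EncoderConfig) -> tuple[Tensor, Tensor]:
    """Entity-fused key/value projections (full width, before head split)."""
    ent_ids = np.atleast_2d(np.asarray(ent_ids, dtype=np.intp))
    if ent_ids.max(initial=0) >= params.E_ent.shape[0]:
        raise ValueError("entity id outside the entity embedding table")
    k = hidden @ layer["W_hk"]
    v = hidden @ layer["W_hv"]
    if cfg.use_entity_fusion:
        f = (ent_ids > 0).astype(np.float64)[..., None]
        e = params.E_ent[ent_ids]
        k = k * (1.0 - 0.5 * f) + (e @ layer["W_ek"]) * (0.5 * f)
        v = v * (1.0 - 0.5 * f) + (e @ layer["W_ev"]) * (0.5 * f)
    return k, v


def _split_heads(x: Tensor, cfg: EncoderConfig) -> Tensor:
    B, T = x.shape[0], x.shape[1]
    return x.reshape(B, T, cfg.n_heads, cfg.d_head).transpose(0, 2, 1, 3)


def attention_weights(q: Tensor, k: Tensor, layer: dict, cfg: EncoderConfig,
                      rel_table: np.ndarray | None,
                      pad_mask: np.ndarray | None = None) -> Tensor:
    """Per-head row-stochastic attention weights, shape (B, heads, T, T)."""
    qh = _split_heads(q, cfg)          # (B, H, T, dk)
    kh = _split_heads(k, cfg)
    T = qh.shape[2]
    logits = qh @ kh.swapaxes(-1, -2)  # content-content
    logits = logits + einsum2("hd,bhjd->bhj", layer["u"], kh) \
        .reshape(qh.shape[0], cfg.n_heads, 1, T)
    if cfg.use_relative_position:
        if rel_table is None:
            rel_table = relative_position_table(T, cfg.d_head)
        R = Tensor(rel_table)
        logits = logits + einsum2("bhtd,tjd->bhtj", qh, R)
        logits = logits + einsum2("hd,tjd->htj", layer["v"], R) \
            .reshape(1, cfg.n_heads, T, T)
    logits = logits * (1.0 / np.sqrt(cfg.d_head))
    if pad_mask is not None:
        bias = np.where(pad_mask[:, None, None, :] > 0, 0.0, -1e9)
        logits = logits + Tensor(bias)
    if not np.all(np.isfinite(logits.data)):
        raise FloatingPointError("non-finite attention logits")
    return softmax(logits, axis=-1)


def encode(char_ids: np.ndarray, ent_ids: np.ndarray, params: EncoderParams,
           cfg: EncoderConfig, pad_mask: np.ndarray | None = None,
           train_mode: bool = False,
           rng: np.random.Generator | None = None) -> Tensor:
    """Full encoder stack; returns final hidden states (B, T, d_model)."""
    char_ids = np.atleast_2d(np.asarray(char_ids, dtype=np.intp))
    B, T = char_ids.shape
    h = embed(char_ids, params, cfg)
    rel_table = relative_position_table(T, cfg.d_head) if cfg.use_relative_position else None

    def dropout(x: Tensor) -> Tensor:
        if not train_mode or cfg.dropout <= 0.0:
            return x
        keep = rng.random(x.shape) >= cfg.dropout
        return x * Tensor(keep / (1.0 - cfg.dropout))

    for li, layer in enumerate(params.layers):
        q = h @ layer["W_hq"]
        k, v = fuse_key_value(h, ent_ids, layer, params, cfg)
        attn = attention_weights(q, k, layer, cfg, rel_table, pad_mask)
        attn = dropout(attn)
        ctx = attn @ _split_heads(v, cfg)                      # (B,H,T,dk)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
        h = layer_norm(h + dropout(ctx), layer["ln1_g"], layer["ln1_b"])
        ff = (h @ layer["ffn_W1"] + layer["ffn_b1"]).gelu() @ layer["ffn_W2"] \
            + layer["ffn_b2"]
        h = layer_norm(h + dropout(ff), layer["ln2_g"], layer["ln2_b"])
        if not np.all(np.isfinite(h.data)):
            raise FloatingPointError(f"non-finite hidden states after layer {li}")
    return h
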