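"""A compact bidirectional transformer encoder for antibody MLM.

Pre-LayerNorm encoder blocks with switchable position encoding — rotary
(RoPE: queries and keys are rotated by position-dependent angles so that
attention logits depend only on relative offsets) or learned absolute
embeddings — plus a weight-tied MLM head and an attachable sequence
classification head pooled at the start token.

Two presets matter in practice: ``pilot`` mirrors the 55M-parameter
configuration (5 layers, 20 heads, hidden 960, intermediate 3840) and
``tiny`` (2 layers, 4 heads, hidden 64, intermediate 256) is the test-scale
workhorse.  The implementation runs on the package's numpy autodiff core, so
everything here is CPU-sized by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = ["EncoderConfig", "TransformerEncoder", "SequenceClassifier",
           "apply_rotary", "attach_classifier", "rotary_cos_sin",
           "save_checkpoint", "load_checkpoint"]

ROPE_BASE = 10000.0


@dataclass
class EncoderConfig:
    n_layers: int = 2
    n_heads: int = 4
    hidden_size: int = 64
    intermediate_size: int = 256
    pe_type: str = "rope"
    vocab_size: int = 33
    max_positions: int = 320

    def __post_init__(self):
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        if self.pe_type not in ("rope", "absolute"):
            raise ValueError(f"unknown pe_type {self.pe_type!r}")
        if self.pe_type == "rope" and (self.hidden_size // self.n_heads) % 2:
            raise ValueError("RoPE needs an even head dimension")

    @property
    def head_dim(self) -> int:
        return self.hidden_size // self.n_heads

    @classmethod
    def tiny(cls, pe_type: str = "rope") -> "EncoderConfig":
        return cls(2, 4, 64, 256, pe_type=pe_type)

    @classmethod
    def pilot(cls, pe_type: str = "rope") -> "EncoderConfig":
        """The 55M-parameter pilot dimensions (5 layers, 20 heads, 960/3840)."""
        return cls(5, 20, 960, 3840, pe_type=pe_type)

    def to_dict(self) -> dict:
        return asdict(self)


def rotary_cos_sin(positions: np.ndarray, head_dim: int):
    """Cosine/sine tables for rotary rotation at given absolute positions.

    Returns arrays of shape ``positions.shape + (head_dim,)`` laid out for
    the rotate-half convention (frequencies repeated over the two halves).
    """
    if head_dim % 2:
        raise ValueError("RoPE needs an even head dimension")
    half = head_dim // 2
    inv_freq = ROPE_BASE ** (-np.arange(half) / half)
    angles = np.asarray(positions, dtype=np.float64)[..., None] * inv_freq
    angles = np.concatenate([angles, angles], axis=-1)
    return np.cos(angles), np.sin(angles)


def apply_rotary(queries: np.ndarray, keys: np.ndarray,
                 positions: np.ndarray):
    """Rotate query/key arrays (..., T, head_dim) by their positions.

    The rotation makes the attention logit ``q_i · k_j`` a function of the
    relative offset ``i − j`` only; position 0 is the identity rotation.
    """
    head_dim = queries.shape[-1]
    cos, sin = rotary_cos_sin(positions, head_dim)
    half = head_dim // 2

    def rot(v):
        return np.concatenate([-v[..., half:], v[..., :half]], axis=-1)

    q = queries * cos + rot(queries) * sin
    k = keys * cos + rot(keys) * sin
    return q, k


def _init_params(cfg: EncoderConfig, rng: np.random.Generator) -> dict:
    h, i_sz, v = cfg.hidden_size, cfg.intermediate_size, cfg.vocab_size
    p = {}
    p["emb"] = ad.param((v, h), rng, scale=0.02)
    if cfg.pe_type == "absolute":
        p["pos_emb"] = ad.param((cfg.max_positions, h), rng, scale=0.02)
    for layer in range(cfg.n_layers):
        pre = f"l{layer}."
        for name in ("q", "k", "v", "o"):
            p[pre + f"attn_{name}_w"] = ad.param((h, h), rng)
            p[pre + f"attn_{name}_b"] = ad.param(np.zeros(h))
        p[pre + "ln1_g"] = ad.param(np.ones(h))
        p[pre + "ln1_b"] = ad.param(np.zeros(h))
        p[pre + "ln2_g"] = ad.param(np.ones(h))
        p[pre + "ln2_b"] = ad.param(np.zeros(h))
        p[pre + "mlp_w1"] = ad.param((h, i_sz), rng)
        p[pre + "mlp_b1"] = ad.param(np.zeros(i_sz))
        p[pre + "mlp_w2"] = ad.param((i_sz, h), rng)
        p[pre + "mlp_b2"] = ad.param(np.zeros(h))
    p["lnf_g"] = ad.param(np.ones(h))
    p["lnf_b"] = ad.param(np.zeros(h))
    # MLM head: dense -> gelu -> LN -> tied projection (+ output bias)
    p["mlm_w"] = ad.param((h, h), rng)
    p["mlm_b"] = ad.param(np.zeros(h))
    p["mlm_ln_g"] = ad.param(np.ones(h))
    p["mlm_ln_b"] = ad.param(np.zeros(h))
    p["mlm_out_b"] = ad.param(np.zeros(v))
    return p


class TransformerEncoder:
    """Bidirectional encoder with an MLM head (output weights tied to the
    input embedding)."""

    def __init__(self, config: EncoderConfig, seed: int = 0,
                 params: Optional[dict] = None):
        self.config = config
        self.params = params if params is not None else _init_params(
            config, np.random.default_rng(seed))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def _check_ids(self, ids: np.ndarray) -> np.ndarray:
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
        if ids.min() < 0 or ids.max() >= self.config.vocab_size:
            raise ValueError("token id out of vocabulary range")
        if ids.shape[1] > self.config.max_positions:
            raise ValueError(
                f"sequence length {ids.shape[1]} exceeds "
                f"max_positions={self.config.max_positions}")
        return ids

    def hidden_states(self, ids: np.ndarray,
                      attention_mask: Optional[np.ndarray] = None) -> Tensor:
        """Run the encoder stack; returns final-LN hidden states (B, T, H)."""
        cfg = self.config
        p = self.params
        ids = self._check_ids(ids)
        B, T = ids.shape
        if attention_mask is None:
            attention_mask = np.ones((B, T), dtype=bool)
        attention_mask = np.asarray(attention_mask, dtype=bool)
        if attention_mask.ndim == 1:
            attention_mask = attention_mask[None, :]
        key_bias = np.where(attention_mask, 0.0, -1e9)[:, None, None, :]
        positions = np.arange(T)

        x = ad.embedding(p["emb"], ids)
        if cfg.pe_type == "absolute":
            x = x + ad.embedding(p["pos_emb"], np.broadcast_to(positions, (B, T)))
        if cfg.pe_type == "rope":
            cos, sin = rotary_cos_sin(positions, cfg.head_dim)
        scale = 1.0 / np.sqrt(cfg.head_dim)

        for layer in range(cfg.n_layers):
            pre = f"l{layer}."
            h = ad.layer_norm(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
            q = ad.matmul(h, p[pre + "attn_q_w"]) + p[pre + "attn_q_b"]
            k = ad.matmul(h, p[pre + "attn_k_w"]) + p[pre + "attn_k_b"]
            v = ad.matmul(h, p[pre + "attn_v_w"]) + p[pre + "attn_v_b"]
            # (B, T, H) -> (B, heads, T, head_dim)
            def heads(t):
                return t.reshape(B, T, cfg.n_heads, cfg.head_dim).transpose(0, 2, 1, 3)
            q, k, v = heads(q), heads(k), heads(v)
            if cfg.pe_type == "rope":
                q = ad.rope_rotate(q, cos, sin)
                k = ad.rope_rotate(k, cos, sin)
            scores = ad.matmul(q, k.transpose(0, 1, 3, 2)) * scale
            probs = ad.softmax(scores, bias=key_bias)
            ctx = ad.matmul(probs, v)
            ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, cfg.hidden_size)
            x = x + (ad.matmul(ctx, p[pre + "attn_o_w"]) + p[pre + "attn_o_b"])
            h2 = ad.layer_norm(x, p[pre + "ln2_g"], p[pre + "ln2_b"])
            inner = ad.gelu(ad.matmul(h2, p[pre + "mlp_w1"]) + p[pre + "mlp_b1"])
            x = x + (ad.matmul(inner, p[pre + "mlp_w2"]) + p[pre + "mlp_b2"])
        return ad.layer_norm(x, p["lnf_g"], p["lnf_b"])

    def forward_mlm(self, ids: np.ndarray,
                    attention_mask: Optional[np.ndarray] = None) -> Tensor:
        """Per-position vocabulary logits (B, T, vocab)."""
        p = self.params
        h = self.hidden_states(ids, attention_mask)
        h = ad.gelu(ad.matmul(h, p["mlm_w"]) + p["mlm_b"])
        h = ad.layer_norm(h, p["mlm_ln_g"], p["mlm_ln_b"])
        emb_t = p["emb"].transpose(1, 0)
        return ad.matmul(h, emb_t) + p["mlm_out_b"]

    def mlm_loss(self, ids: np.ndarray, labels: np.ndarray,
                 attention_mask: Optional[np.ndarray] = None):
        """Mean cross-entropy over labelled positions; returns (loss, n)."""
        logits = self.forward_mlm(ids, attention_mask)
        return ad.cross_entropy_logits(logits, labels)


class SequenceClassifier:
    """Classification head over a (possibly frozen) encoder.

    Pooling takes the start-token position; the head is
    dense → tanh → projection, the convention of standard encoder
    classification heads.  With ``freeze_base`` the encoder output is
    detached, so encoder parameters receive no gradient and no updates.
    """

    def __init__(self, encoder: TransformerEncoder, n_classes: int,
                 freeze_base: bool = True, seed: int = 0):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.encoder = encoder
        self.n_classes = n_classes
        self.freeze_base = freeze_base
        h = encoder.config.hidden_size
        rng = np.random.default_rng(seed)
        self.head = {
            "w1": ad.param((h, h), rng),
            "b1": ad.param(np.zeros(h)),
            "w2": ad.param((h, n_classes), rng),
            "b2": ad.param(np.zeros(n_classes)),
        }

    def parameters(self) -> list[Tensor]:
        params = list(self.head.values())
        if not self.freeze_base:
            params += self.encoder.parameters()
        return params

    def pooled(self, ids: np.ndarray,
               attention_mask: Optional[np.ndarray] = None) -> Tensor:
        h = self.encoder.hidden_states(ids, attention_mask)
        if self.freeze_base:
            h = ad.const(h.data)
        return ad.select_position(h, 0)

    def forward(self, ids: np.ndarray,
                attention_mask: Optional[np.ndarray] = None) -> Tensor:
        return self.head_logits(self.pooled(ids, attention_mask))

    def head_logits(self, pooled: Tensor) -> Tensor:
        """Run only the head on pooled features (lets frozen-base training
        precompute embeddings once)."""
        h = ad.tanh(ad.matmul(pooled, self.head["w1"]) + self.head["b1"])
        return ad.matmul(h, self.head["w2"]) + self.head["b2"]

    def loss(self, ids: np.ndarray, labels: np.ndarray,
             attention_mask: Optional[np.ndarray] = None):
        logits = self.forward(ids, attention_mask)
        return ad.cross_entropy_logits(logits, labels)


def attach_classifier(encoder: TransformerEncoder, n_classes: int,
                      freeze_base: bool = True, seed: int = 0) -> SequenceClassifier:
    """Attach a sequence-classification head to an encoder."""
    return SequenceClassifier(encoder, n_classes, freeze_base, seed)


def save_checkpoint(encoder: TransformerEncoder, path: str | Path) -> None:
    """Save weights + config to an .npz checkpoint."""
    arrays = {name: t.data for name, t in encoder.params.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(encoder.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> TransformerEncoder:
    with np.load(path) as npz:
        cfg = EncoderConfig(**json.loads(bytes(npz["__config__"]).decode()))
        params = {name: ad.param(npz[name]) for name in npz.files
                  if name != "__config__"}
    return TransformerEncoder(cfg, params=params)
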