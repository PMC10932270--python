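"""Bidirectional transformer encoder with a fusion gate and classifier head.

The encoder follows the standard BERT layout: token + learned positional
embeddings with layer norm, then a stack of post-norm transformer layers
(multi-head self-attention -> add & norm -> GELU feed-forward -> add & norm).
The ``full`` preset mirrors the canonical 12-layer geometry; the ``tiny``
preset (2 layers, 64 hidden, 4 heads) is sized so the whole pipeline trains
in seconds on one CPU core.

Two tokenization scales are combined by a learned *fusion gate*::

    F   = sigmoid(W1 @ h_kmer1 + W2 @ h_kmer2)
    h_M = F * h_kmer1 + (1 - F) * h_kmer2      (elementwise)

so each fused component is a convex combination of the two scale
representations, with the mixing weight learned from both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .tokenization import (
    CLS_ID,
    MASK_ID,
    PAD_ID,
    SEP_ID,
    TokenizedSequence,
)

__all__ = [
    "EncoderConfig",
    "EncoderOutput",
    "FusionGateParams",
    "TransformerEncoder",
    "ClassifierHead",
    "SequenceClassifier",
    "fusion_gate",
    "classify",
    "masked_lm_step",
    "MaskedLMHead",
]

_NEG_INF = -1e9


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the transformer stack."""

    n_layers: int = 12
    n_heads: int = 12
    hidden_dim: int = 768
    intermediate_dim: int = 3072
    max_tokens: int = 512
    dropout: float = 0.1
    vocab_size: int = 69
    preset: str = "full"

    def __post_init__(self):
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")

    @staticmethod
    def full(vocab_size: int = 69) -> "EncoderConfig":
        """Canonical 12-layer BERT-base geometry."""
        return EncoderConfig(vocab_size=vocab_size, preset="full")

    @staticmethod
    def tiny(vocab_size: int = 69, max_tokens: int = 64) -> "EncoderConfig":
        """Desk-scale encoder: 2 layers, 64 hidden, 4 heads, no dropout."""
        return EncoderConfig(
            n_layers=2,
            n_heads=4,
            hidden_dim=64,
            intermediate_dim=128,
            max_tokens=max_tokens,
            dropout=0.0,
            vocab_size=vocab_size,
            preset="tiny",
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @staticmethod
    def from_json(path) -> "EncoderConfig":
        with open(path) as fh:
            return EncoderConfig(**json.load(fh))


@dataclass
class EncoderOutput:
    """Final-layer hidden states, pooled vector, and attention maps.

    ``attentions`` is a list (one entry per layer) of arrays shaped
    (batch, n_heads, T, T); each row is a softmax over unmasked key positions.
    """

    hidden_states: np.ndarray
    pooled: np.ndarray
    attentions: list[np.ndarray]


def _init(rng: np.random.Generator, *shape, scale: float = 0.02) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _ones(*shape) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


class TransformerEncoder:
    """BERT-style encoder over k-mer token ids (NumPy autodiff backend)."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        self.config = config
        c = config
        self.token_embedding = _init(rng, c.vocab_size, c.hidden_dim)
        self.position_embedding = _init(rng, c.max_tokens, c.hidden_dim)
        self.emb_ln_gain = _ones(c.hidden_dim)
        self.emb_ln_bias = _zeros(c.hidden_dim)
        self.layers = []
        for _ in range(c.n_layers):
            layer = {
                "Wq": _init(rng, c.hidden_dim, c.hidden_dim),
                "bq": _zeros(c.hidden_dim),
                "Wk": _init(rng, c.hidden_dim, c.hidden_dim),
                "bk": _zeros(c.hidden_dim),
                "Wv": _init(rng, c.hidden_dim, c.hidden_dim),
                "bv": _zeros(c.hidden_dim),
                "Wo": _init(rng, c.hidden_dim, c.hidden_dim),
                "bo": _zeros(c.hidden_dim),
                "ln1_gain": _ones(c.hidden_dim),
                "ln1_bias": _zeros(c.hidden_dim),
                "W_ff1": _init(rng, c.hidden_dim, c.intermediate_dim),
                "b_ff1": _zeros(c.intermediate_dim),
                "W_ff2": _init(rng, c.intermediate_dim, c.hidden_dim),
                "b_ff2": _zeros(c.hidden_dim),
                "ln2_gain": _ones(c.hidden_dim),
                "ln2_bias": _zeros(c.hidden_dim),
            }
            self.layers.append(layer)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def parameters(self) -> list[Tensor]:
        params = [
            self.token_embedding,
            self.position_embedding,
            self.emb_ln_gain,
            self.emb_ln_bias,
        ]
        for layer in self.layers:
            params.extend(layer.values())
        return params

    # -- forward ---------------------------------------------------------------
    def embed(self, ids: np.ndarray, perturbation: np.ndarray | None = None) -> Tensor:
        """Token + position embedding (pre-layer-norm); optionally perturbed.

        The returned tensor is the point where FGM adversarial noise enters:
        its gradient can be retained and a constant perturbation added.
        """
        B, T = ids.shape
        emb = self.token_embedding[ids] + self.position_embedding[np.arange(T)]
        if perturbation is not None:
            emb = emb + Tensor(perturbation)
        return emb

    def forward(
        self,
        ids: np.ndarray,
        attention_mask: np.ndarray,
        perturbation: np.ndarray | None = None,
        want_attentions: bool = False,
        retain_embedding_grad: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Run the encoder.

        Returns ``(hidden, pooled, attentions, emb)`` where ``hidden`` is a
        (B, T, H) tensor, ``pooled`` the [CLS] representation (B, H),
        ``attentions`` a list of (B, heads, T, T) arrays and ``emb`` the
        embedding-output tensor (for FGM gradients).
        """
        c = self.config
        ids = np.atleast_2d(ids)
        attention_mask = np.atleast_2d(attention_mask)
        if ids.max() >= c.vocab_size:
            raise ValueError(
                f"token id {int(ids.max())} out of range for vocab_size {c.vocab_size}"
            )
        B, T = ids.shape
        emb = self.embed(ids, perturbation)
        if retain_embedding_grad:
            emb.retain_grad()
        x = ad.layer_norm(emb, self.emb_ln_gain, self.emb_ln_bias)
        x = self._dropout(x, dropout_rng)

        # additive mask: -inf at padded key positions
        key_bias = np.where(attention_mask[:, None, None, :] > 0, 0.0, _NEG_INF)
        head_dim = c.hidden_dim // c.n_heads
        scale = 1.0 / np.sqrt(head_dim)
        attentions: list[np.ndarray] = []

        for layer in self.layers:
            def split_heads(t: Tensor) -> Tensor:
                return t.reshape(B, T, c.n_heads, head_dim).transpose((0, 2, 1, 3))

            q = split_heads(x @ layer["Wq"] + layer["bq"])
            k = split_heads(x @ layer["Wk"] + layer["bk"])
            v = split_heads(x @ layer["Wv"] + layer["bv"])
            scores = (q @ k.transpose((0, 1, 3, 2))) * scale + Tensor(key_bias)
            probs = ad.softmax(scores, axis=-1)
            if want_attentions:
                attentions.append(probs.data.copy())
            ctx = probs @ v  # (B, heads, T, head_dim)
            ctx = ctx.transpose((0, 2, 1, 3)).reshape(B, T, c.hidden_dim)
            attn_out = ctx @ layer["Wo"] + layer["bo"]
            attn_out = self._dropout(attn_out, dropout_rng)
            x = ad.layer_norm(x + attn_out, layer["ln1_gain"], layer["ln1_bias"])
            ff = ad.gelu(x @ layer["W_ff1"] + layer["b_ff1"]) @ layer["W_ff2"] + layer["b_ff2"]
            ff = self._dropout(ff, dropout_rng)
            x = ad.layer_norm(x + ff, layer["ln2_gain"], layer["ln2_bias"])

        pooled = x[:, 0, :]  # [CLS] position
        return x, pooled, attentions, emb

    def _dropout(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        if p <= 0.0 or rng is None:
            return x
        keep = (rng.random(x.shape) >= p).astype(float) / (1.0 - p)
        return x * Tensor(keep)

    def encode(
        self, tokens: TokenizedSequence, want_attentions: bool = True
    ) -> EncoderOutput:
        """Deterministic single-sequence forward pass (inference mode)."""
        with ad.no_grad():
            hidden, pooled, attentions, _ = self.forward(
                tokens.ids[None, :],
                tokens.attention_mask[None, :],
                want_attentions=want_attentions,
            )
        return EncoderOutput(
            hidden_states=hidden.data[0],
            pooled=pooled.data[0],
            attentions=[a[0] for a in attentions],
        )


@dataclass
class FusionGateParams:
    """Learned linear maps W1, W2 of the fusion gate.

    With ``scalar_gate`` the maps produce a single logit broadcast across all
    components; otherwise the gate is a full vector (the general case).
    """

    W1: Tensor
    W2: Tensor

    @staticmethod
    def init(dim: int, rng: np.random.Generator, scalar_gate: bool = False) -> "FusionGateParams":
        out_dim = 1 if scalar_gate else dim
        return FusionGateParams(
            W1=_init(rng, dim, out_dim),
            W2=_init(rng, dim, out_dim),
        )

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.W2]


def fusion_gate(h1, h2, params: FusionGateParams):
    """Blend two scale representations through a sigmoid gate.

    ``F = sigmoid(h1 W1 + h2 W2)``; ``h_M = F * h1 + (1 - F) * h2``. Accepts
    Tensors or plain arrays (vectors or batches); returns (F, h_M) of the
    input kind.
    """
    as_tensor = isinstance(h1, Tensor)
    t1 = h1 if as_tensor else Tensor(np.asarray(h1, dtype=float))
    t2 = h2 if isinstance(h2, Tensor) else Tensor(np.asarray(h2, dtype=float))
    if t1.shape != t2.shape:
        raise ValueError(f"shape mismatch: {t1.shape} vs {t2.shape}")
    if t1.shape[-1] != params.W1.shape[0]:
        raise ValueError(
            f"representation dim {t1.shape[-1]} does not match gate params "
            f"{params.W1.shape[0]}"
        )
    F = ad.sigmoid(t1 @ params.W1 + t2 @ params.W2)
    h_m = F * t1 + (1.0 - F) * t2
    if as_tensor:
        return F, h_m
    return F.data, h_m.data


class ClassifierHead:
    """Logistic head: p = sigmoid(w . h + b), probability of the positive class."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.w = _init(rng, dim, 1)
        self.b = _zeros(1)

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]

    def __call__(self, h: Tensor) -> Tensor:
        return ad.sigmoid(h @ self.w + self.b).reshape(-1)


def classify(pooled_or_fused, head: ClassifierHead) -> np.ndarray:
    """Predicted positive-class probability for a vector or batch."""
    x = np.atleast_2d(np.asarray(pooled_or_fused, dtype=float))
    return head(Tensor(x)).data


class MaskedLMHead:
    """Linear projection from hidden states to vocabulary logits."""

    def __init__(self, hidden_dim: int, vocab_size: int, rng: np.random.Generator):
        self.W = _init(rng, hidden_dim, vocab_size)
        self.b = _zeros(vocab_size)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]

    def __call__(self, hidden: Tensor) -> Tensor:
        return hidden @ self.W + self.b


def masked_lm_step(
    encoder: TransformerEncoder,
    head: MaskedLMHead,
    tokens: Sequence[TokenizedSequence],
    mask_prob: float = 0.15,
    seed: int = 0,
) -> Tensor:
    """One masked-language-model objective evaluation on a batch.

    A seeded subset of non-special tokens is selected per sequence (at least
    one is always forced); selected positions follow the 80/10/10 rule —
     80% become [MASK], 10% a random k-mer id, 10% keep the original token.
    Returns the mean cross-entropy over masked positions (a Tensor; call
    ``backward()`` on it to pretrain).
    """
    if not 0.0 < mask_prob < 1.0:
        raise ValueError("mask_prob must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.stack([t.ids for t in tokens])
    mask = np.stack([t.attention_mask for t in tokens])
    special = (ids == PAD_ID) | (ids == CLS_ID) | (ids == SEP_ID) | (ids == MASK_ID)
    maskable = (~special) & (mask > 0)
    if not maskable.any(axis=1).all():
        raise ValueError("a sequence in the batch has no maskable tokens")

    corrupted = ids.copy()
    targets_rows, targets_cols = [], []
    n_kmers = encoder.config.vocab_size - 5
    for b in range(ids.shape[0]):
        cand = np.flatnonzero(maskable[b])
        chosen = cand[rng.random(cand.size) < mask_prob]
        if chosen.size == 0:
            chosen = rng.choice(cand, size=1)  # guarantee >= 1 masked token
        for pos in chosen:
            u = rng.random()
            if u < 0.8:
                corrupted[b, pos] = MASK_ID
            elif u < 0.9:
                corrupted[b, pos] = 5 + rng.integers(n_kmers)
            # else: keep original token
            targets_rows.append(b)
            targets_cols.append(pos)

    hidden, _, _, _ = encoder.forward(corrupted, mask)
    logits = head(hidden)  # (B, T, V)
    rows = np.asarray(targets_rows)
    cols = np.asarray(targets_cols)
    sel = logits[rows, cols]  # (n_masked, V)
    # numerically stable log-softmax: logits - logsumexp
    shift = sel.data.max(axis=-1, keepdims=True)
    lse = ((sel - shift).exp().sum(axis=-1, keepdims=True)).log() + Tensor(shift)
    log_probs = sel - lse
    target_ids = ids[rows, cols]
    picked = log_probs[np.arange(len(rows)), target_ids]
    return -picked.mean()


class SequenceClassifier:
    """Encoder(+fusion gate)+head model for one or two tokenization scales.

    For a single scale the [CLS] pooled vector (or mean pooling) feeds the
    logistic head directly; for a scale pair the two pooled vectors pass
    through the fusion gate first. The two scales share one encoder by
    default (per-scale encoders available via ``shared_encoder=False``).
    """

    def __init__(
        self,
        config: EncoderConfig,
        n_scales: int = 1,
        shared_encoder: bool = True,
        scalar_gate: bool = False,
        pooling: str = "cls",
        seed: int = 0,
    ):
        if n_scales not in (1, 2):
            raise ValueError("n_scales must be 1 or 2")
        if pooling not in ("cls", "mean"):
            raise ValueError("pooling must be 'cls' or 'mean'")
        rng = np.random.default_rng(seed)
        self.config = config
        self.n_scales = n_scales
        self.shared_encoder = shared_encoder
        self.pooling = pooling
        if n_scales == 1 or shared_encoder:
            self.encoders = [TransformerEncoder(config, rng)]
        else:
            self.encoders = [TransformerEncoder(config, rng) for _ in range(2)]
        self.fusion = (
            FusionGateParams.init(config.hidden_dim, rng, scalar_gate=scalar_gate)
            if n_scales == 2
            else None
        )
        self.head = ClassifierHead(config.hidden_dim, rng)

    def encoder_for(self, scale_idx: int) -> TransformerEncoder:
        return self.encoders[0] if len(self.encoders) == 1 else self.encoders[scale_idx]

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for enc in self.encoders:
            params.extend(enc.parameters())
        if self.fusion is not None:
            params.extend(self.fusion.parameters())
        params.extend(self.head.parameters())
        return params

    def _pool(self, hidden: Tensor, pooled_cls: Tensor, mask: np.ndarray) -> Tensor:
        if self.pooling == "cls":
            return pooled_cls
        m = mask[:, :, None].astype(float)
        return (hidden * Tensor(m)).sum(axis=1) * Tensor(
            1.0 / mask.sum(axis=1, keepdims=True).astype(float)
        )

    def forward(
        self,
        batches: list[tuple[np.ndarray, np.ndarray]],
        perturbations: list[np.ndarray] | None = None,
        retain_embedding_grad: bool = False,
        want_attentions: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Forward over one (ids, mask) pair per scale.

        Returns ``(p, emb_leaves, attentions)``: positive-class probabilities
        (Tensor, shape (B,)), the per-scale embedding-output tensors (for
        FGM), and per-scale attention lists.
        """
        if len(batches) != self.n_scales:
            raise ValueError(f"expected {self.n_scales} scale batches, got {len(batches)}")
        pooled_vecs, embs, attns = [], [], []
        for i, (ids, mask) in enumerate(batches):
            enc = self.encoder_for(i)
            perturb = perturbations[i] if perturbations is not None else None
            hidden, pooled, attn, emb = enc.forward(
                ids,
                mask,
                perturbation=perturb,
                want_attentions=want_attentions,
                retain_embedding_grad=retain_embedding_grad,
                dropout_rng=dropout_rng,
            )
            pooled_vecs.append(self._pool(hidden, pooled, np.atleast_2d(mask)))
            embs.append(emb)
            attns.append(attn)
        if self.n_scales == 2:
            _, fused = fusion_gate(pooled_vecs[0], pooled_vecs[1], self.fusion)
        else:
            fused = pooled_vecs[0]
        p = self.head(fused)
        return p, embs, attns

    def predict_proba_tokens(self, batches) -> np.ndarray:
        with ad.no_grad():
            p, _, _ = self.forward(batches)
        return p.data

    # -- checkpointing ----------------------------------------------------------
    def save(self, weights_path, config_path) -> None:
        """Opaque binary weights + plain-text sidecar config."""
        arrays = {f"p{i}": t.data for i, t in enumerate(self.parameters())}
        np.savez(weights_path, **arrays)
        meta = dict(
            asdict(self.config),
            n_scales=self.n_scales,
            shared_encoder=self.shared_encoder,
            pooling=self.pooling,
            scalar_gate=self.fusion is not None and self.fusion.W1.shape[1] == 1,
        )
        with open(config_path, "w") as fh:
            json.dump(meta, fh, indent=2)

    @staticmethod
    def load(weights_path, config_path) -> "SequenceClassifier":
        with open(config_path) as fh:
            meta = json.load(fh)
        cfg = EncoderConfig(
            **{k: meta[k] for k in EncoderConfig.__dataclass_fields__}
        )
        model = SequenceClassifier(
            cfg,
            n_scales=meta["n_scales"],
            shared_encoder=meta["shared_encoder"],
            scalar_gate=meta["scalar_gate"],
            pooling=meta["pooling"],
        )
        data = np.load(weights_path)
        params = model.parameters()
        if len(data.files) != len(params):
            raise ValueError("checkpoint does not match model architecture")
        for i, t in enumerate(params):
            arr = data[f"p{i}"]
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            t.data = arr.astype(np.float64)
        return model
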