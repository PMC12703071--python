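"""The dual-stream cleavage-site network.

Two Transformer-based Encoder Units process the two input streams — the
s-nt cleavage pattern and the full-length pre-miRNA — each as joint
sequence+structure embeddings with sinusoidal positional encoding.  An
Encoder Unit is three standard Transformer encoder layers (multi-head
self-attention + feed-forward, post-layer-norm, padding masked), followed
by two convolutional blocks (1-D same-padding convolution + leaky ReLU),
each with a residual connection from the Transformer output, a masked mean
pool over positions and a linear projection to a fixed-width feature
vector.

The two stream features are fused either by attentional feature fusion

    Z = M(X (+) Y) (x) X + (1 - M(X (+) Y)) (x) Y

where M is a multi-scale channel attention block with sigmoid output in
[0, 1] ((+)/(x) elementwise add/multiply), or by plain concatenation.  A
fully connected head with softmax predicts the interval class in {0..s-1}.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import AdamW, Parameter, Tensor, cross_entropy, no_grad
from .encoding import EMBED_DIM, Vocabulary, build_vocab, sinusoidal_pe
from .io_formats import ValidationError

__all__ = [
    "EncoderUnitConfig",
    "ModelConfig",
    "EncoderUnit",
    "MSCAM",
    "aff_combine",
    "DualStreamClassifier",
    "predict_topk",
    "aff_weight_diagnostics",
    "save_checkpoint",
    "load_checkpoint",
]

NEG_INF = np.float32(-1e9)


@dataclasses.dataclass(frozen=True)
class EncoderUnitConfig:
    """Architecture of one Encoder Unit.

    ``d_model`` is fixed by the encoding (2 x 32 = 64).  ``residual_wiring``
    selects where the conv blocks take their residual from: "transformer"
    connects both blocks back to the Transformer output (default);
    "chained" connects each block to its immediate input.
    """

    n_transformer_layers: int = 3
    n_heads: int = 4
    d_model: int = 2 * EMBED_DIM
    ff_dim: int = 256
    conv_blocks: int = 2
    conv_kernel: int = 3
    out_dim: int = 256
    dropout: float = 0.1
    residual_wiring: str = "transformer"

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValidationError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}")
        if self.residual_wiring not in ("transformer", "chained"):
            raise ValidationError(f"unknown residual wiring {self.residual_wiring!r}")


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    n_classes: int = 14
    encoder: EncoderUnitConfig = EncoderUnitConfig()
    fusion: str = "aff"  # aff | concat
    fc_hidden: int = 128
    mscam_reduction: int = 4

    def __post_init__(self):
        if self.fusion not in ("aff", "concat"):
            raise ValidationError(f"unknown fusion {self.fusion!r}")


class Module:
    """Base class collecting :class:`Parameter` objects recursively."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(d_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim > 2:  # flatten leading dims into one BLAS call
            lead = x.shape[:-1]
            flat = x.reshape(int(np.prod(lead)), x.shape[-1])
            return (flat @ self.W + self.b).reshape(*lead, self.W.shape[1])
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * (var + self.eps).pow(-0.5)
        return xn * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float):
        self.p = p
        self.training = False
        self._rng = np.random.default_rng(0)

    def seed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self._rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_model, d_model, rng)
        self.v = Linear(d_model, d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)  # B,H,L,dh

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        # additive mask: padded key positions get -inf before the softmax
        bias = np.where(mask[:, None, None, :], np.float32(0.0), NEG_INF)
        attn = (scores + Tensor(bias)).softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    def __init__(self, cfg: EncoderUnitConfig, rng: np.random.Generator):
        self.attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ff1 = Linear(cfg.d_model, cfg.ff_dim, rng)
        self.ff2 = Linear(cfg.ff_dim, cfg.d_model, rng)
        self.ln1 = LayerNorm(cfg.d_model)
        self.ln2 = LayerNorm(cfg.d_model)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x, mask)))
        x = self.ln2(x + self.drop(self.ff2(self.ff1(x).relu())))
        return x


class Conv1dSame(Module):
    """1-D convolution with same padding, as a sum of shifted matmuls."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValidationError(f"conv kernel must be odd, got {kernel}")
        self.kernel = kernel
        scale = 1.0 / np.sqrt(channels * kernel)
        self.W = Parameter(rng.normal(0.0, scale, size=(kernel, channels, channels)))
        self.b = Parameter(np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        half = self.kernel // 2
        xp = x.pad_axis(1, half, half)
        out = None
        for tap in range(self.kernel):
            flat = xp[:, tap:tap + L, :].reshape(B * L, C)
            term = (flat @ self.W[tap]).reshape(B, L, C)
            out = term if out is None else out + term
        return out + self.b


class EncoderUnit(Module):
    """Transformer stack + conv refinement + masked-mean pool + projection."""

    def __init__(self, cfg: EncoderUnitConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.layers = [TransformerEncoderLayer(cfg, rng)
                       for _ in range(cfg.n_transformer_layers)]
        self.convs = [Conv1dSame(cfg.d_model, cfg.conv_kernel, rng)
                      for _ in range(cfg.conv_blocks)]
        self.proj = Linear(cfg.d_model, cfg.out_dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        if not mask.any(axis=-1).all():
            raise ValidationError("encoder received an all-padding input")
        for layer in self.layers:
            x = layer(x, mask)
        m = Tensor(mask[:, :, None].astype(np.float32))
        # zero the pad positions between stages: pad queries leave the
        # attention stack nonzero, and the same-padding convolutions would
        # otherwise leak them into the valid edge positions
        t = x * m
        h = t
        for conv in self.convs:
            residual = t if self.cfg.residual_wiring == "transformer" else h
            h = (conv(h).leaky_relu() + residual) * m
        pooled = (h * m).sum(axis=1) * Tensor(1.0 / mask.sum(axis=-1,
                                                             keepdims=True))
        return self.proj(pooled)


class MSCAM(Module):
    """Multi-scale channel attention: sigmoid(global ctx + local ctx).

    The global branch bottlenecks the channel-mean-pooled signal
    (broadcast back over channels); the local branch bottlenecks the
    feature vector directly.  Both use dim -> dim/r -> dim transforms.
    """

    def __init__(self, dim: int, reduction: int, rng: np.random.Generator):
        hidden = max(dim // reduction, 1)
        self.g1 = Linear(dim, hidden, rng)
        self.g2 = Linear(hidden, dim, rng)
        self.l1 = Linear(dim, hidden, rng)
        self.l2 = Linear(hidden, dim, rng)

    def __call__(self, joint: Tensor) -> Tensor:
        dim = joint.shape[-1]
        pooled = joint.mean(axis=-1, keepdims=True) * Tensor(np.ones(dim,
                                                                     dtype=np.float32))
        global_ctx = self.g2(self.g1(pooled).relu())
        local_ctx = self.l2(self.l1(joint).relu())
        return (global_ctx + local_ctx).sigmoid()


def aff_combine(X: Tensor, Y: Tensor, w: Tensor) -> Tensor:
    """Z = w (x) X + (1 - w) (x) Y, the attentional fusion rule."""
    if X.shape != Y.shape:
        raise ValidationError(f"fusion shape mismatch: {X.shape} vs {Y.shape}")
    return w * X + (1.0 - w) * Y


class DualStreamClassifier(Module):
    """Full network: two encoder units, AFF or concat fusion, FC head.

    The 3-mer embedding tables (sequence and structure, 32-dim each) are
    learned jointly with the network and shared between the pattern stream
    and the full-sequence stream.  Row 0 is the padding embedding; pad
    positions are zeroed by the mask, so row 0 receives no gradient.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        enc = cfg.encoder
        emb_scale = 1.0 / np.sqrt(EMBED_DIM)
        self.seq_vocab = build_vocab("sequence")
        self.struct_vocab = build_vocab("structure")
        self.seq_emb = Parameter(
            rng.normal(0.0, emb_scale, size=(self.seq_vocab.size + 1, EMBED_DIM)))
        self.struct_emb = Parameter(
            rng.normal(0.0, emb_scale, size=(self.struct_vocab.size + 1, EMBED_DIM)))
        self.pattern_encoder = EncoderUnit(enc, rng)
        self.sequence_encoder = EncoderUnit(enc, rng)
        if cfg.fusion == "aff":
            self.mscam = MSCAM(enc.out_dim, cfg.mscam_reduction, rng)
            fused_dim = enc.out_dim
        else:
            self.mscam = None
            fused_dim = 2 * enc.out_dim
        self.fc1 = Linear(fused_dim, cfg.fc_hidden, rng)
        self.fc2 = Linear(cfg.fc_hidden, cfg.n_classes, rng)
        self.drop = Dropout(enc.dropout)
        self._last_aff_weights: np.ndarray | None = None

    def train_mode(self, on: bool = True, seed: int = 0) -> None:
        for layer in self.pattern_encoder.layers + self.sequence_encoder.layers:
            layer.drop.training = on
            layer.drop.seed(seed)
        self.drop.training = on
        self.drop.seed(seed + 1)

    def fuse(self, X: Tensor, Y: Tensor) -> Tensor:
        if self.cfg.fusion == "aff":
            w = self.mscam(X + Y)
            self._last_aff_weights = w.numpy().copy()
            return aff_combine(X, Y, w)
        self._last_aff_weights = None
        return ad.concat([X, Y], axis=-1)

    def embed_stream(self, seq_ids: np.ndarray, struct_ids: np.ndarray,
                     mask: np.ndarray) -> Tensor:
        """Token ids -> joint embedding + positional encoding, pads zeroed.

        Embeddings are scaled by sqrt(embed_dim) before the positional
        encoding is added (the standard Transformer convention); without
        it the unit-amplitude sinusoids drown the token signal at
        fan-in-scaled initialization.
        """
        e = ad.concat([ad.embedding(self.seq_emb, seq_ids),
                       ad.embedding(self.struct_emb, struct_ids)], axis=-1)
        pe = sinusoidal_pe(seq_ids.shape[1], self.cfg.encoder.d_model)
        m = Tensor(mask[:, :, None].astype(np.float32))
        return (e * np.float32(np.sqrt(EMBED_DIM)) + Tensor(pe[None])) * m

    def _head(self, X: Tensor, Y: Tensor) -> Tensor:
        fused = self.fuse(X, Y)
        h = self.drop(self.fc1(fused).leaky_relu())
        return self.fc2(h)

    def forward(self, pattern_x: Tensor, pattern_mask: np.ndarray,
                seq_x: Tensor, seq_mask: np.ndarray) -> Tensor:
        """Return logits [batch x n_classes] from assembled streams."""
        X = self.pattern_encoder(pattern_x, pattern_mask)
        Y = self.sequence_encoder(seq_x, seq_mask)
        return self._head(X, Y)

    def forward_tokens(self, pat_seq: np.ndarray, pat_struct: np.ndarray,
                       pat_mask: np.ndarray, seq_seq: np.ndarray,
                       seq_struct: np.ndarray, seq_mask: np.ndarray,
                       seq_gather: np.ndarray | None = None) -> Tensor:
        """Logits straight from token-id arrays (training entry point).

        ``seq_gather`` supports hairpin deduplication: the sequence-stream
        arrays then hold one row per distinct hairpin and ``seq_gather[i]``
        maps sample i to its hairpin row.  Many overlapping patterns share
        one parent hairpin, so encoding each hairpin once per batch saves
        most of the sequence-stream compute; the result is identical.
        """
        px = self.embed_stream(pat_seq, pat_struct, pat_mask)
        sx = self.embed_stream(seq_seq, seq_struct, seq_mask)
        X = self.pattern_encoder(px, pat_mask)
        Y = self.sequence_encoder(sx, seq_mask)
        if seq_gather is not None:
            Y = Y[seq_gather]
        return self._head(X, Y)

    def predict_proba(self, pattern_x: Tensor, pattern_mask: np.ndarray,
                      seq_x: Tensor, seq_mask: np.ndarray) -> np.ndarray:
        with no_grad():
            logits = self.forward(pattern_x, pattern_mask, seq_x, seq_mask)
            return logits.softmax(axis=-1).numpy()


def predict_topk(probs: np.ndarray, k: int) -> np.ndarray:
    """Classes by descending probability; ties broken by ascending index."""
    probs = np.atleast_2d(probs)
    n_classes = probs.shape[-1]
    if not 1 <= k <= n_classes:
        raise ValidationError(f"k={k} outside [1, {n_classes}]")
    order = np.argsort(-probs, axis=-1, kind="stable")
    return order[:, :k]


def aff_weight_diagnostics(weights_per_sample: np.ndarray) -> dict:
    """Summarize the pattern-stream AFF weight distribution.

    Takes the per-sample weight vectors collected during prediction (the
    sigmoid output of the channel-attention block, used as the pattern
    stream's weight) and reports the mean/min/max of each sample's mean
    weight.  Diagnostic only — no assertion on the value.
    """
    if weights_per_sample is None:
        raise ValidationError("AFF diagnostics require an AFF-fusion model")
    per_sample = np.asarray(weights_per_sample).mean(axis=-1)
    return {
        "n": int(per_sample.shape[0]),
        "per_sample_mean": per_sample,
        "mean": float(per_sample.mean()),
        "min": float(per_sample.min()),
        "max": float(per_sample.max()),
    }


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: DualStreamClassifier, path: str | Path,
                    meta: dict | None = None) -> None:
    """Save weights (npz) plus a JSON sidecar with config and metadata."""
    path = Path(path)
    params = model.parameters()
    np.savez(path, **{f"p{i}": p.data for i, p in enumerate(params)})
    sidecar = {
        "model_config": dataclasses.asdict(model.cfg),
        "n_params": len(params),
        "vocabularies": {
            "sequence": list(model.seq_vocab.tokens),
            "structure": list(model.struct_vocab.tokens),
        },
        "meta": meta or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path, seed: int = 0) -> tuple[DualStreamClassifier, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = dict(sidecar["model_config"])
    cfg_d["encoder"] = EncoderUnitConfig(**cfg_d["encoder"])
    cfg = ModelConfig(**cfg_d)
    model = DualStreamClassifier(cfg, seed=seed)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"p{i}"]
    return model, sidecar["meta"]
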