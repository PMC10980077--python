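"""Transformer encoders with 1D/3D relative position embeddings.

The source model maps an amino-acid sequence to predictions for the named
biophysical score terms; the target model reuses its layers (the *backbone*)
under a single-output head for experimental functional scores.

Architecture (source): token embedding over the 20-letter alphabet plus a pad
token; a stack of pre-layer-norm encoder layers whose attention adds
learnable per-relative-distance key/value vectors (1D: signed sequence offset
clipped to ±8, 17 buckets; 3D: contact-graph shortest-path length clipped at
3, 4 buckets); a final layer norm; mean pooling over residues; a ReLU
fully-connected layer; and a linear multi-task output.  There is no absolute
positional encoding — the relative embeddings are the only positional signal.

Target models insert dropout 0.5 between backbone and a linear 1-output head.
For local (single-protein, 3D) backbones the head attaches after the final
fully-connected layer; for global (1D) backbones it attaches directly after
pooling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, relu
from .structures import (
    CLIP_1D,
    CLIP_3D,
    ProteinStructure,
    RelativeDistanceMap,
    relative_distances,
)
from .variants import AA_ALPHABET

PAD_TOKEN = 20
VOCAB_SIZE = 21  # 20 canonical amino acids + pad

_AA_TO_TOKEN = {a: i for i, a in enumerate(AA_ALPHABET)}


class ModelError(ValueError):
    pass


def encode_sequences(seqs: list[str]) -> np.ndarray:
    """Token-index matrix (n_seqs, L); all sequences must share one length."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ModelError(f"sequences of mixed lengths {sorted(lengths)}")
    try:
        return np.array([[_AA_TO_TOKEN[a] for a in s] for s in seqs], dtype=int)
    except KeyError as exc:
        raise ModelError(f"non-canonical amino acid {exc}") from exc


@dataclass
class ModelConfig:
    embed_dim: int = 256
    n_layers: int = 3
    n_heads: int = 4
    ff_dim: int = 1024
    dropout: float = 0.1
    rpe_mode: str = "3d"  # "1d" or "3d"
    rpe_clip: int = CLIP_3D
    n_tasks: int = 55
    head_hidden: int = 256
    pooling: str = "mean"

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ModelError("embed_dim must be divisible by n_heads")
        if self.rpe_mode not in ("1d", "3d"):
            raise ModelError(f"unknown rpe_mode {self.rpe_mode!r}")
        if self.pooling != "mean":
            raise ModelError("only mean pooling is supported")

    @property
    def n_distance_classes(self) -> int:
        return 2 * self.rpe_clip + 1 if self.rpe_mode == "1d" else self.rpe_clip + 1


def local_config(n_tasks: int = 55, rpe_mode: str = "3d") -> ModelConfig:
    """Single-protein source preset (~2.5M parameters)."""
    clip = CLIP_3D if rpe_mode == "3d" else CLIP_1D
    return ModelConfig(256, 3, 4, 1024, 0.1, rpe_mode, clip, n_tasks, 256)


def global_config(n_tasks: int = 55, rpe_mode: str = "1d") -> ModelConfig:
    """Multi-protein source preset (~19.2M parameters)."""
    clip = CLIP_3D if rpe_mode == "3d" else CLIP_1D
    return ModelConfig(512, 6, 8, 2048, 0.1, rpe_mode, clip, n_tasks, 512)


def global_xl_config(n_tasks: int = 55, rpe_mode: str = "1d") -> ModelConfig:
    """The enlarged multi-protein preset: global with 16 encoder layers."""
    cfg = global_config(n_tasks, rpe_mode)
    cfg.n_layers = 16
    return cfg


PRESETS = {"local": local_config, "global": global_config, "global-xl": global_xl_config}


class SourceModel(nn.Module):
    """Multi-task encoder; see module docstring for the layer layout."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.embed = nn.Embedding(VOCAB_SIZE, cfg.embed_dim, rng)
        self.layers = [
            nn.EncoderLayer(
                cfg.embed_dim, cfg.n_heads, cfg.ff_dim, cfg.dropout,
                cfg.n_distance_classes, rng,
            )
            for _ in range(cfg.n_layers)
        ]
        self.final_ln = nn.LayerNorm(cfg.embed_dim)
        self.fc = nn.Linear(cfg.embed_dim, cfg.head_hidden, rng)
        self.out = nn.Linear(cfg.head_hidden, cfg.n_tasks, rng)
        self._dist_idx: np.ndarray | None = None
        self.structure_id: str | None = None

    # -- structure / distance map ------------------------------------------
    def set_structure(self, structure: ProteinStructure) -> None:
        if self.cfg.rpe_mode != "3d":
            raise ModelError("set_structure is only meaningful for 3D RPE models")
        dmap = relative_distances(structure, "3d", clip=self.cfg.rpe_clip)
        self.set_distance_map(dmap, structure.id)

    def set_distance_map(self, dmap: RelativeDistanceMap, structure_id=None) -> None:
        if dmap.mode != self.cfg.rpe_mode:
            raise ModelError(f"distance map mode {dmap.mode} != model {self.cfg.rpe_mode}")
        self._dist_idx = dmap.index_map()
        self.structure_id = structure_id

    def _distance_indices(self, length: int) -> np.ndarray:
        if self.cfg.rpe_mode == "1d":
            return relative_distances(length, "1d", clip=self.cfg.rpe_clip).index_map()
        if self._dist_idx is None:
            raise ModelError("3D RPE model has no structure distance map set")
        if self._dist_idx.shape[0] != length:
            raise ModelError(
                f"sequence length {length} does not match structure "
                f"length {self._dist_idx.shape[0]}"
            )
        return self._dist_idx

    # -- forward ------------------------------------------------------------
    def encode(self, tokens, train=False, rng=None, collect_attn=None) -> Tensor:
        """Per-residue encodings after the post-encoder layer norm: (B, L, D)."""
        tokens = np.asarray(tokens, dtype=int)
        dist_idx = self._distance_indices(tokens.shape[1])
        x = self.embed(tokens)
        for layer in self.layers:
            x = layer(x, dist_idx, train=train, rng=rng, collect_attn=collect_attn)
        return self.final_ln(x)

    def pooled(self, tokens, train=False, rng=None) -> Tensor:
        return self.encode(tokens, train, rng).mean(axis=1)

    def fc_features(self, tokens, train=False, rng=None) -> Tensor:
        return relu(self.fc(self.pooled(tokens, train, rng)))

    def forward(self, tokens, train=False, rng=None) -> Tensor:
        """Multi-task predictions, shape (B, n_tasks)."""
        return self.out(self.fc_features(tokens, train, rng))

    __call__ = forward


class TargetModel(nn.Module):
    """Source backbone + dropout(0.5) + linear single-output head.

    ``attach`` selects the feature level: ``"fc"`` (after the final
    fully-connected layer; local convention) or ``"pool"`` (after mean
    pooling; global convention).  The source model's multi-task output layer
    is not part of the target model.
    """

    def __init__(self, backbone: SourceModel, attach: str | None = None,
                 dropout: float = 0.5, rng: np.random.Generator | None = None):
        if attach is None:
            attach = "fc" if backbone.cfg.rpe_mode == "3d" else "pool"
        if attach not in ("fc", "pool"):
            raise ModelError(f"unknown attach point {attach!r}")
        self.backbone = backbone
        self.attach = attach
        feat_dim = backbone.cfg.head_hidden if attach == "fc" else backbone.cfg.embed_dim
        self.drop = nn.Dropout(dropout)
        self.head = nn.Linear(feat_dim, 1, rng if rng is not None else np.random.default_rng(0))

    def named_parameters(self, prefix: str = ""):
        # the backbone's multi-task output layer is dropped from the target model
        for name, p in super().named_parameters(prefix):
            if ".backbone.out." not in f".{name}":
                yield name, p

    def backbone_parameters(self):
        for name, p in self.named_parameters():
            if name.startswith("backbone."):
                yield p

    def head_parameters(self):
        yield self.head.weight
        yield self.head.bias

    def features(self, tokens, train=False, rng=None) -> Tensor:
        if self.attach == "fc":
            return self.backbone.fc_features(tokens, train, rng)
        return self.backbone.pooled(tokens, train, rng)

    def forward(self, tokens, train=False, rng=None) -> Tensor:
        feats = self.drop(self.features(tokens, train, rng), train, rng)
        return self.head(feats).reshape(-1)

    __call__ = forward


def build_model(
    cfg: ModelConfig,
    structure: ProteinStructure | None = None,
    seed: int = 0,
) -> SourceModel:
    """Deterministically initialize a source model; 3D mode needs a structure."""
    rng = np.random.default_rng(seed)
    model = SourceModel(cfg, rng)
    if cfg.rpe_mode == "3d":
        if structure is None:
            raise ModelError("3D RPE mode requires a protein structure")
        model.set_structure(structure)
    return model


def count_parameters(m: nn.Module) -> int:
    """Exact trainable-parameter count."""
    return m.n_parameters()


def predict(m, seqs: list[str], batch_size: int = 256) -> np.ndarray:
    """Evaluation-mode predictions for raw sequences (dropout off)."""
    tokens = encode_sequences(seqs)
    chunks = [
        m(tokens[i : i + batch_size]).data for i in range(0, len(tokens), batch_size)
    ]
    return np.concatenate(chunks, axis=0)


def introspect(m: SourceModel, seq: str, batch_size: int = 64):
    """Attention map and amino-acid-averaged residue representations.

    Returns ``(attention, representations)`` where ``attention`` is the mean
    over all layers and heads of the row-normalized attention for ``seq``
    (n×n), and ``representations[i]`` is the encoder's residue-i output
    averaged over the 20 sequences placing each amino acid at position i
    (n × embed_dim).
    """
    tokens = encode_sequences([seq])
    maps: list[np.ndarray] = []
    m.encode(tokens, collect_attn=maps)
    attention = np.mean([a[0] for a in maps], axis=(0, 1))

    length = len(seq)
    reps = np.zeros((length, m.cfg.embed_dim))
    for i in range(length):
        block = np.repeat(tokens, 20, axis=0)
        block[:, i] = np.arange(20)
        enc = []
        for lo in range(0, 20, batch_size):
            enc.append(m.encode(block[lo : lo + batch_size]).data[:, i, :])
        reps[i] = np.concatenate(enc, axis=0).mean(axis=0)
    return attention, reps


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(path, model) -> None:
    """Single-archive checkpoint: config JSON + weights (+ distance map)."""
    if isinstance(model, TargetModel):
        meta = {
            "kind": "target",
            "attach": model.attach,
            "dropout": model.drop.p,
            "config": asdict(model.backbone.cfg),
            "structure_id": model.backbone.structure_id,
        }
        dist = model.backbone._dist_idx
    else:
        meta = {
            "kind": "source",
            "config": asdict(model.cfg),
            "structure_id": model.structure_id,
        }
        dist = model._dist_idx
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    if dist is not None:
        arrays["dist_idx"] = dist
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        cfg = ModelConfig(**meta["config"])
        source = SourceModel(cfg, np.random.default_rng(0))
        if "dist_idx" in archive:
            source._dist_idx = archive["dist_idx"]
            source.structure_id = meta.get("structure_id")
        if meta["kind"] == "source":
            model = source
        else:
            model = TargetModel(source, attach=meta["attach"], dropout=meta["dropout"])
        state = {
            k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")
        }
        model.load_state_dict(state)
    return model
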