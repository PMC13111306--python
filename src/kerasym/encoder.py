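"""Compact convolutional + transformer encoder for axial curvature maps.

Architecture (all sizes configurable): a two-layer strided convolutional
stem extracts local curvature gradients; the resulting feature grid is cut
into non-overlapping patches that become tokens; two transformer blocks
(pre-norm multi-head self-attention + MLP) model long-range spatial
structure; token mean-pooling and a linear projection give a unit-norm map
embedding.

Training aligns map embeddings with *learned embeddings of the two
diagnosis nodes* of the knowledge graph (normal cornea / early
keratoconus) using a symmetric InfoNCE objective at a fixed temperature:
maps are pulled toward their class node and pushed from the other, and
each node toward its maps.  Optimization is SGD with momentum under a
cosine learning-rate schedule, with early stopping on a held-out
validation split.  Everything is float64 numpy on the in-repo autodiff
engine and is bit-reproducible for a fixed seed in single-threaded mode.

The downstream neural score of a map is the softmax (over the two node
embeddings) of cosine similarities at the training temperature, reported
as the early-keratoconus component.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .graph import KnowledgeGraph
from .inference import KC_NODE
from .maps import CurvatureMap

__all__ = [
    "EncoderConfig",
    "TrainedEncoder",
    "train_encoder",
    "encode_map",
    "neural_score",
    "save_encoder",
    "load_encoder",
]

NORMAL_NODE = "normal_cornea"

# fixed affine input normalization: curvature maps live around 44 D
_NORM_CENTER_D = 44.0
_NORM_SCALE_D = 5.0

CHECKPOINT_VERSION = "1"


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the compact encoder (defaults train on a CPU in minutes)."""

    grid: int = 64
    conv_channels: tuple[int, int] = (8, 16)
    patch: int = 4
    depth: int = 2
    heads: int = 4
    dim: int = 64
    mlp_dim: int = 128
    temperature: float = 0.1
    lr: float = 0.05
    min_lr_factor: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 40
    patience: int = 8
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid", "patch", "depth", "heads", "dim", "mlp_dim", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dim % self.heads != 0:
            raise ValueError("dim must be divisible by heads")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _init_params(cfg: EncoderConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    c1, c2 = cfg.conv_channels
    feat = cfg.grid // 4  # two stride-2 convs
    if feat % cfg.patch != 0:
        raise ValueError(f"grid {cfg.grid} incompatible with patch size {cfg.patch}")
    n_tokens = (feat // cfg.patch) ** 2
    token_dim = c2 * cfg.patch**2

    def he(shape, fan_in):
        return ag.parameter(rng.standard_normal(shape) * np.sqrt(2.0 / fan_in))

    params: dict[str, Tensor] = {
        "conv1_w": he((c1, 1, 3, 3), 9),
        "conv1_b": ag.parameter(np.zeros(c1)),
        "conv2_w": he((c2, c1, 3, 3), 9 * c1),
        "conv2_b": ag.parameter(np.zeros(c2)),
        "patch_w": he((token_dim, cfg.dim), token_dim),
        "patch_b": ag.parameter(np.zeros(cfg.dim)),
        "pos": ag.parameter(rng.standard_normal((n_tokens, cfg.dim)) * 0.02),
        "head_w": he((cfg.dim, cfg.dim), cfg.dim),
        "head_b": ag.parameter(np.zeros(cfg.dim)),
        "nodes": ag.parameter(rng.standard_normal((2, cfg.dim)) * 0.1),  # [normal, kc]
    }
    for i in range(cfg.depth):
        params[f"blk{i}_ln1_g"] = ag.parameter(np.ones(cfg.dim))
        params[f"blk{i}_ln1_b"] = ag.parameter(np.zeros(cfg.dim))
        params[f"blk{i}_qkv_w"] = he((cfg.dim, 3 * cfg.dim), cfg.dim)
        params[f"blk{i}_qkv_b"] = ag.parameter(np.zeros(3 * cfg.dim))
        params[f"blk{i}_proj_w"] = he((cfg.dim, cfg.dim), cfg.dim)
        params[f"blk{i}_proj_b"] = ag.parameter(np.zeros(cfg.dim))
        params[f"blk{i}_ln2_g"] = ag.parameter(np.ones(cfg.dim))
        params[f"blk{i}_ln2_b"] = ag.parameter(np.zeros(cfg.dim))
        params[f"blk{i}_mlp1_w"] = he((cfg.dim, cfg.mlp_dim), cfg.dim)
        params[f"blk{i}_mlp1_b"] = ag.parameter(np.zeros(cfg.mlp_dim))
        params[f"blk{i}_mlp2_w"] = he((cfg.mlp_dim, cfg.dim), cfg.mlp_dim)
        params[f"blk{i}_mlp2_b"] = ag.parameter(np.zeros(cfg.dim))
    return params


def _layer_norm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * ((var + 1e-5) ** -0.5) * g + b


def _attention(x: Tensor, p: dict[str, Tensor], i: int, heads: int) -> Tensor:
    batch, n_tok, dim = x.shape
    dh = dim // heads
    qkv = x @ p[f"blk{i}_qkv_w"] + p[f"blk{i}_qkv_b"]  # (B, N, 3D)
    qkv = qkv.reshape(batch, n_tok, 3, heads, dh).transpose(2, 0, 3, 1, 4)  # (3, B, H, N, dh)
    qkv = qkv.reshape(3, batch * heads, n_tok, dh)
    q_t = _take_first(qkv, 0)
    k_t = _take_first(qkv, 1)
    v_t = _take_first(qkv, 2)
    scores = (q_t @ k_t.transpose(0, 2, 1)) * (dh**-0.5)  # (BH, N, N)
    attn = ag.softmax(scores, axis=-1)
    out = attn @ v_t  # (BH, N, dh)
    out = out.reshape(batch, heads, n_tok, dh).transpose(0, 2, 1, 3).reshape(batch, n_tok, dim)
    return out @ p[f"blk{i}_proj_w"] + p[f"blk{i}_proj_b"]


def _take_first(x: Tensor, index: int) -> Tensor:
    """Select x[index] along axis 0 (with gradient)."""

    def grad_fn(g):
        gx = np.zeros_like(x.data)
        gx[index] = g
        return (gx,)

    return Tensor(x.data[index], parents=(x,), grad_fn=grad_fn)


def _forward_embed(maps_array: np.ndarray, p: dict[str, Tensor], cfg: EncoderConfig) -> Tensor:
    """Map batch (B, H, W) of raw powers to unit-norm embeddings (B, dim)."""
    x = ag.constant((maps_array - _NORM_CENTER_D) / _NORM_SCALE_D)
    batch = x.shape[0]
    x = x.reshape(batch, 1, cfg.grid, cfg.grid)
    x = ag.conv2d(x, p["conv1_w"], p["conv1_b"], stride=2, pad=1).relu()
    x = ag.conv2d(x, p["conv2_w"], p["conv2_b"], stride=2, pad=1).relu()  # (B, C2, g/4, g/4)
    c2 = cfg.conv_channels[1]
    feat = cfg.grid // 4
    n_side = feat // cfg.patch
    # (B, C, n_side, patch, n_side, patch) -> tokens (B, n_side^2, C*patch^2)
    x = x.reshape(batch, c2, n_side, cfg.patch, n_side, cfg.patch)
    x = x.transpose(0, 2, 4, 1, 3, 5).reshape(batch, n_side * n_side, c2 * cfg.patch**2)
    x = x @ p["patch_w"] + p["patch_b"]
    x = x + p["pos"]
    for i in range(cfg.depth):
        x = x + _attention(_layer_norm(x, p[f"blk{i}_ln1_g"], p[f"blk{i}_ln1_b"]), p, i, cfg.heads)
        h = _layer_norm(x, p[f"blk{i}_ln2_g"], p[f"blk{i}_ln2_b"])
        h = (h @ p[f"blk{i}_mlp1_w"] + p[f"blk{i}_mlp1_b"]).relu()
        x = x + (h @ p[f"blk{i}_mlp2_w"] + p[f"blk{i}_mlp2_b"])
    x = x.mean(axis=1)  # (B, dim)
    x = x @ p["head_w"] + p["head_b"]
    return _l2_normalize(x)


def _l2_normalize(x: Tensor) -> Tensor:
    ss = (x * x).sum(axis=-1, keepdims=True)
    return x * ((ss + 1e-12) ** -0.5)


def _info_nce(z: Tensor, nodes: Tensor, labels01: np.ndarray, temperature: float) -> Tensor:
    """Symmetric InfoNCE between map embeddings and the two node embeddings."""
    e = _l2_normalize(nodes)
    sims = (z @ e.transpose(1, 0)) * (1.0 / temperature)  # (B, 2)
    n = labels01.shape[0]
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), labels01] = 1.0
    # map -> node
    lp_rows = ag.log_softmax(sims, axis=-1)
    loss_rows = -(lp_rows * ag.constant(onehot)).sum() * (1.0 / n)
    # node -> maps: for each class present, uniform target over its members
    lp_cols = ag.log_softmax(sims, axis=0)
    col_mask = np.zeros((n, 2))
    present = 0
    for c in (0, 1):
        members = labels01 == c
        if members.any():
            col_mask[members, c] = 1.0 / members.sum()
            present += 1
    loss_cols = -(lp_cols * ag.constant(col_mask)).sum() * (1.0 / max(present, 1))
    return (loss_rows + loss_cols) * 0.5


@dataclass
class TrainedEncoder:
    """Frozen training artifact: parameters, node embeddings, history, config."""

    params: dict[str, np.ndarray]
    config: EncoderConfig
    history: list[dict[str, float]] = field(default_factory=list)
    version: str = CHECKPOINT_VERSION

    def node_embeddings(self) -> np.ndarray:
        """Unit-norm embeddings of (normal_cornea, early_keratoconus)."""
        nodes = self.params["nodes"]
        return nodes / np.sqrt((nodes**2).sum(axis=-1, keepdims=True) + 1e-12)


def _labels_to01(labels: Sequence[str]) -> np.ndarray:
    mapping = {NORMAL_NODE: 0, "normal": 0, KC_NODE: 1, "early_kc": 1}
    try:
        return np.array([mapping[label] for label in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc}; expected normal/early_kc") from None


def train_encoder(
    maps: Sequence[CurvatureMap],
    labels: Sequence[str],
    graph: KnowledgeGraph,
    cfg: EncoderConfig,
) -> TrainedEncoder:
    """Train the encoder with contrastive feature-to-node alignment.

    Requires both classes in ``labels``.  A stratified ``val_fraction``
    split is held out; training stops once the validation loss has not
    improved for ``patience`` epochs and the best-validation parameters are
    returned.  Fully seeded and bit-reproducible in single-threaded mode.
    """
    for node_id in (NORMAL_NODE, KC_NODE):
        graph.node(node_id)  # raises KeyError if the diagnosis node is missing
    y = _labels_to01(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both diagnosis classes present")
    data = np.stack([m.values for m in maps])
    if data.shape[1] != cfg.grid or data.shape[2] != cfg.grid:
        raise ValueError(f"maps must match configured grid {cfg.grid}, got {data.shape[1:]}")

    rng = np.random.default_rng(cfg.seed)
    # stratified validation split
    val_idx: list[int] = []
    for c in (0, 1):
        members = np.flatnonzero(y == c)
        rng.shuffle(members)
        n_val = max(1, int(round(len(members) * cfg.val_fraction)))
        val_idx.extend(members[:n_val])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    train_idx = np.flatnonzero(~val_mask)
    val_idx = np.flatnonzero(val_mask)
    if len(train_idx) == 0:
        raise ValueError("no training samples left after validation split")

    params = _init_params(cfg, rng)
    velocity = {k: np.zeros_like(t.data) for k, t in params.items()}
    history: list[dict[str, float]] = []
    best_val = np.inf
    best_params: dict[str, np.ndarray] | None = None
    stale = 0

    for epoch in range(cfg.max_epochs):
        lr = cfg.lr * (
            cfg.min_lr_factor
            + (1 - cfg.min_lr_factor) * 0.5 * (1 + np.cos(np.pi * epoch / max(cfg.max_epochs - 1, 1)))
        )
        order = train_idx.copy()
        rng.shuffle(order)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            if len(batch) < 2 or len(np.unique(y[batch])) < 2:
                continue  # contrastive loss needs both classes in the batch
            for t in params.values():
                t.zero_grad()
            z = _forward_embed(data[batch], params, cfg)
            loss = _info_nce(z, params["nodes"], y[batch], cfg.temperature)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}: {loss.data!r}")
            loss.backward()
            for k, t in params.items():
                if t.grad is None:
                    continue
                velocity[k] = cfg.momentum * velocity[k] - lr * t.grad
                t.data = t.data + velocity[k]
            epoch_loss += float(loss.data)
            n_batches += 1
        z_val = _forward_embed(data[val_idx], params, cfg)
        val_loss = float(_info_nce(z_val, params["nodes"], y[val_idx], cfg.temperature).data)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append(
            {
                "epoch": epoch,
                "lr": float(lr),
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: t.data.copy() for k, t in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    assert best_params is not None
    return TrainedEncoder(params=best_params, config=cfg, history=history)


def _wrap(params: dict[str, np.ndarray]) -> dict[str, Tensor]:
    return {k: ag.constant(v) for k, v in params.items()}


def encode_map(cmap: CurvatureMap, enc: TrainedEncoder) -> np.ndarray:
    """Deterministic unit-norm embedding of one map."""
    if cmap.size != enc.config.grid:
        raise ValueError(
            f"map grid {cmap.size} does not match encoder grid {enc.config.grid}; resample first"
        )
    z = _forward_embed(cmap.values[None], _wrap(enc.params), enc.config)
    return z.data[0]


def encode_maps(maps: Sequence[CurvatureMap], enc: TrainedEncoder) -> np.ndarray:
    """Batch version of :func:`encode_map` (one row per map)."""
    data = np.stack([m.values for m in maps])
    if data.shape[1] != enc.config.grid:
        raise ValueError("map grid does not match encoder grid")
    return _forward_embed(data, _wrap(enc.params), enc.config).data


def neural_score(cmap: CurvatureMap, enc: TrainedEncoder) -> float:
    """Early-keratoconus probability-like score of one map.

    Softmax over cosine similarities to the two diagnosis-node embeddings
    at the training temperature; the normal-cornea component is its
    complement.
    """
    z = encode_map(cmap, enc)
    return _scores_from_embeddings(z[None], enc)[0]


def _scores_from_embeddings(z: np.ndarray, enc: TrainedEncoder) -> np.ndarray:
    e = enc.node_embeddings()
    sims = z @ e.T / enc.config.temperature
    sims = sims - sims.max(axis=-1, keepdims=True)
    p = np.exp(sims)
    p /= p.sum(axis=-1, keepdims=True)
    return p[:, 1]  # early_keratoconus component


def neural_scores(maps: Sequence[CurvatureMap], enc: TrainedEncoder) -> np.ndarray:
    return _scores_from_embeddings(encode_maps(maps, enc), enc)


# ---------------------------------------------------------------------------
# checkpoint IO


def save_encoder(enc: TrainedEncoder, path: str | Path) -> Path:
    """Versioned ``.npz`` checkpoint with the config and history embedded."""
    path = Path(path)
    meta = json.dumps(
        {"version": enc.version, "config": asdict(enc.config), "history": enc.history}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **enc.params)
    return path if path.suffix == ".npz" else path.parent / (path.name + ".npz")


def load_encoder(path: str | Path) -> TrainedEncoder:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']!r}")
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg_obj = meta["config"]
    cfg_obj["conv_channels"] = tuple(cfg_obj["conv_channels"])
    return TrainedEncoder(params=params, config=EncoderConfig(**cfg_obj), history=meta["history"])
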