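"""Modality encoders and the shared latent space.

Three encoders map the modalities to pooled embeddings:

* **sequence** — a transformer over amino-acid tokens; the pooled
  embedding is the output at the BOS position, which attends to every
  residue and so summarises the whole sequence.
* **structure** — a GVP-GNN stack over a k-nearest-neighbour residue
  graph (scalar channels rotation-invariant, vector channels
  rotation-equivariant), whose scalar features feed transformer layers;
  the pooled embedding is the mean over unmasked residues and is
  invariant to global rigid motion by construction.
* **text** — a transformer over word tokens; the pooled embedding is
  the output at the EOS position.

Each pooled embedding passes through a per-modality projection head
(LayerNorm + one affine map) into a shared latent space of equal
dimension across modalities; projected vectors are L2-normalised by
default so that temperature-scaled dot products are cosine
similarities (an unnormalised mode is available via config).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as onp
import autograd.numpy as np
import yaml

from . import nn
from .corpus_io import (
    BackboneStructure,
    TextVocab,
    TokenizedInput,
    PAD_ID,
    SEQ_VOCAB_SIZE,
)

__all__ = [
    "EncoderConfig",
    "desk_configs",
    "full_configs",
    "ResidueGraph",
    "PooledEmbedding",
    "build_residue_graph",
    "init_gvp",
    "gvp",
    "gvp_layer",
    "init_encoders",
    "encode_sequence_batch",
    "encode_text_batch",
    "encode_structure_batch",
    "encode_sequence",
    "encode_text",
    "encode_structure",
    "project",
    "pad_token_batch",
    "pad_graph_batch",
    "save_checkpoint",
    "load_checkpoint",
    "export_embeddings",
    "CHECKPOINT_FORMAT_VERSION",
]

CHECKPOINT_FORMAT_VERSION = 1

#: radial-basis expansion of CA-CA edge distances
RBF_CENTERS = onp.linspace(0.0, 20.0, 16)
RBF_SIGMA = float(RBF_CENTERS[1] - RBF_CENTERS[0])


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of one modality encoder.

    ``layers`` counts transformer layers; ``gvp_layers`` applies to the
    structure encoder only.  The documented full-scale configuration is
    33 layers x width 1280 (sequence), 4 GVP + 8 transformer layers
    (structure), and 8 transformer layers (text); desk scale defaults to
    2 layers x width 64 with 1 GVP layer.
    """

    modality: str
    layers: int
    width: int
    heads: int
    shared_dim: int
    gvp_layers: int = 0
    gvp_scalar: int = 32
    gvp_vector: int = 8
    knn: int = 30
    max_len: int = 512
    normalize_projection: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.modality not in ("sequence", "structure", "text"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.width % self.heads != 0:
            raise ValueError(f"width {self.width} not divisible by heads {self.heads}")


def desk_configs(shared_dim: int = 64, seed: int = 0) -> dict:
    """Desk-scale encoder configs (2 transformer layers, width 64, 1 GVP)."""
    return {
        "sequence": EncoderConfig("sequence", layers=2, width=64, heads=4, shared_dim=shared_dim, seed=seed),
        "structure": EncoderConfig(
            "structure", layers=2, width=64, heads=4, shared_dim=shared_dim, gvp_layers=1, knn=16, seed=seed
        ),
        "text": EncoderConfig("text", layers=2, width=64, heads=4, shared_dim=shared_dim, seed=seed),
    }


def full_configs(shared_dim: int = 512, seed: int = 0) -> dict:
    """Documented full-scale configuration (not exercised in tests)."""
    return {
        "sequence": EncoderConfig("sequence", layers=33, width=1280, heads=20, shared_dim=shared_dim, seed=seed),
        "structure": EncoderConfig(
            "structure", layers=8, width=512, heads=8, shared_dim=shared_dim, gvp_layers=4, seed=seed
        ),
        "text": EncoderConfig("text", layers=8, width=768, heads=12, shared_dim=shared_dim, seed=seed),
    }


@dataclass(frozen=True)
class PooledEmbedding:
    modality: str
    vector: onp.ndarray

    def __post_init__(self):
        v = onp.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", v)
        if not onp.isfinite(v).all():
            raise ValueError("non-finite pooled embedding")


# ---------------------------------------------------------------------------
# residue graphs


@dataclass(frozen=True)
class ResidueGraph:
    """k-NN graph over the unmasked residues of a backbone.

    node_s: (n, 6) sin/cos of the backbone dihedrals phi, psi, omega
    (zeroed at chain termini where undefined).
    node_v: (n, 3, 3) unit vectors: forward CA->CA, backward CA->CA,
    and the imputed side-chain direction (zero where undefined).
    nbr_idx: (n, k) neighbour indices, k = min(knn, n-1); self-edges
    excluded.  edge_s: (n, k, 16) RBF features of CA distance;
    edge_v: (n, k, 3) unit displacement vectors.
    """

    node_s: onp.ndarray
    node_v: onp.ndarray
    nbr_idx: onp.ndarray
    edge_s: onp.ndarray
    edge_v: onp.ndarray

    @property
    def n_nodes(self) -> int:
        return int(self.node_s.shape[0])

    @property
    def k(self) -> int:
        return int(self.nbr_idx.shape[1])


def _unit(v, eps=1e-8):
    n = onp.linalg.norm(v, axis=-1, keepdims=True)
    return onp.where(n > eps, v / onp.maximum(n, eps), 0.0)


def _dihedral(p0, p1, p2, p3):
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1u = b1 / onp.linalg.norm(b1)
    v = b0 - onp.dot(b0, b1u) * b1u
    w = b2 - onp.dot(b2, b1u) * b1u
    x = onp.dot(v, w)
    y = onp.dot(onp.cross(b1u, v), w)
    return onp.arctan2(y, x)


def rbf_expand(d):
    """exp(-(d - mu_j)^2 / (2 sigma^2)) over 16 centers spanning [0, 20] A."""
    d = onp.asarray(d)[..., None]
    return onp.exp(-((d - RBF_CENTERS) ** 2) / (2.0 * RBF_SIGMA**2))


def build_residue_graph(structure: BackboneStructure, k: int = 30) -> ResidueGraph:
    """Construct the GVP-GNN input graph from backbone coordinates."""
    idx = onp.flatnonzero(structure.mask)
    n = len(idx)
    if n == 0:
        raise ValueError("structure has no unmasked residues")
    X = structure.coords[idx]  # (n, 3, 3): N, CA, C
    N_at, CA, C_at = X[:, 0], X[:, 1], X[:, 2]

    # node scalars: backbone dihedrals (treating the unmasked residues as
    # a chain), zeroed where a flanking residue is missing
    phi = onp.zeros(n)
    psi = onp.zeros(n)
    omega = onp.zeros(n)
    defined = onp.zeros((n, 3), dtype=bool)
    for i in range(n):
        if i > 0:
            phi[i] = _dihedral(C_at[i - 1], N_at[i], CA[i], C_at[i])
            omega[i] = _dihedral(CA[i - 1], C_at[i - 1], N_at[i], CA[i])
            defined[i, 0] = defined[i, 2] = True
        if i < n - 1:
            psi[i] = _dihedral(N_at[i], CA[i], C_at[i], N_at[i + 1])
            defined[i, 1] = True
    ang = onp.stack([phi, psi, omega], axis=1)
    node_s = onp.concatenate([onp.sin(ang), onp.cos(ang)], axis=1)
    node_s = node_s * onp.concatenate([defined, defined], axis=1)

    # node vectors: forward / backward CA->CA and imputed side-chain direction
    fwd = onp.zeros((n, 3))
    bwd = onp.zeros((n, 3))
    if n > 1:
        fwd[:-1] = _unit(CA[1:] - CA[:-1])
        bwd[1:] = _unit(CA[:-1] - CA[1:])
    u1 = _unit(N_at - CA)
    u2 = _unit(C_at - CA)
    bisector = _unit(u1 + u2)
    perp = _unit(onp.cross(u1, u2))
    side = -bisector * onp.sqrt(1.0 / 3.0) - perp * onp.sqrt(2.0 / 3.0)
    node_v = onp.stack([fwd, bwd, side], axis=1)

    # k nearest neighbours by CA distance
    kk = min(k, n - 1)
    if kk == 0:
        nbr = onp.zeros((n, 1), dtype=int)
        edge_s = onp.zeros((n, 1, 16))
        edge_v = onp.zeros((n, 1, 3))
        return ResidueGraph(node_s, node_v, nbr, edge_s, edge_v)
    D = onp.linalg.norm(CA[:, None, :] - CA[None, :, :], axis=-1)
    onp.fill_diagonal(D, onp.inf)
    nbr = onp.argsort(D, axis=1, kind="stable")[:, :kk]
    dists = onp.take_along_axis(D, nbr, axis=1)
    edge_s = rbf_expand(dists)
    disp = CA[nbr] - CA[:, None, :]
    edge_v = _unit(disp)
    return ResidueGraph(node_s, node_v, nbr, edge_s, edge_v)


# ---------------------------------------------------------------------------
# geometric vector perceptron


def init_gvp(rng, s_in: int, v_in: int, s_out: int, v_out: int, v_hidden: int | None = None):
    v_hidden = v_hidden or max(v_in, v_out)
    return {
        "Wh": nn.trunc_normal(rng, (v_in, v_hidden), 0.1),
        "Wu": nn.trunc_normal(rng, (v_hidden, v_out), 0.1),
        "Ws": nn.init_linear(rng, s_in + v_hidden, s_out, std=0.1),
        "Wg": nn.init_linear(rng, s_in + v_hidden, v_out, std=0.1),
    }


def gvp(p, s, V, activate: bool = True, eps: float = 1e-8):
    """Geometric vector perceptron.

    s: (..., s_in) invariant scalars; V: (..., v_in, 3) equivariant
    vectors.  Scalars mix with vector norms (invariant); vectors pass
    through channel-linear maps gated by an invariant sigmoid, with no
    vector bias, so outputs rotate exactly with the inputs and zero
    vector inputs give zero vector outputs.
    """
    # channel-linear vector maps as matmul over the channel axis (the
    # spatial axis rides along), much faster than a general einsum
    Vt = np.swapaxes(V, -1, -2)  # (..., 3, v_in)
    Vht = Vt @ p["Wh"]  # (..., 3, h)
    vn = np.sqrt(np.sum(Vht * Vht, axis=-2) + eps)  # (..., h)
    sc = np.concatenate([s, vn], axis=-1)
    s_out = nn.linear(p["Ws"], sc)
    if activate:
        s_out = nn.relu(s_out)
    Vu = np.swapaxes(Vht @ p["Wu"], -1, -2)  # (..., v_out, 3)
    gate = nn.sigmoid(nn.linear(p["Wg"], sc))
    return s_out, Vu * gate[..., None]


def init_gvp_layer(rng, ns: int, nv: int, es: int = 16):
    return {
        "msg": init_gvp(rng, ns + es, nv + 1, ns, nv),
        "upd": init_gvp(rng, 2 * ns, 2 * nv, ns, nv),
    }


def gvp_layer(p, s, V, nbr_idx, edge_s, edge_v, nbr_mask=None):
    """One message-passing GVP-GNN layer with residual updates.

    s: (N, ns); V: (N, nv, 3); nbr_idx: (N, k) indices into the node
    axis; edge_s: (N, k, 16); edge_v: (N, k, 3); nbr_mask: (N, k) with
    1 for real neighbours (None means all real).
    """
    for arr in (s, V):
        if isinstance(arr, onp.ndarray) and not onp.isfinite(arr).all():
            raise ValueError("non-finite features passed to gvp_layer")
    sv = s[nbr_idx]  # (N, k, ns)
    Vv = V[nbr_idx]  # (N, k, nv, 3)
    m_s_in = np.concatenate([sv, edge_s], axis=-1)
    m_V_in = np.concatenate([Vv, edge_v[:, :, None, :]], axis=2)
    ms, mV = gvp(p["msg"], m_s_in, m_V_in)
    if nbr_mask is None:
        denom = float(nbr_idx.shape[1])
        agg_s = np.sum(ms, axis=1) / denom
        agg_V = np.sum(mV, axis=1) / denom
    else:
        w = nbr_mask
        denom = np.maximum(np.sum(w, axis=1), 1.0)
        agg_s = np.sum(ms * w[:, :, None], axis=1) / denom[:, None]
        agg_V = np.sum(mV * w[:, :, None, None], axis=1) / denom[:, None, None]
    us, uV = gvp(p["upd"], np.concatenate([s, agg_s], -1), np.concatenate([V, agg_V], 1), activate=False)
    return s + us, V + uV


# ---------------------------------------------------------------------------
# parameter initialisation


def _init_token_encoder(rng, cfg: EncoderConfig, vocab_size: int):
    return {
        "emb": nn.trunc_normal(rng, (vocab_size, cfg.width)),
        "pos": nn.trunc_normal(rng, (cfg.max_len, cfg.width)),
        "layers": [init_transformer(rng, cfg) for _ in range(cfg.layers)],
        "ln_f": nn.init_layer_norm(cfg.width),
    }


def init_transformer(rng, cfg: EncoderConfig):
    return nn.init_transformer_layer(rng, cfg.width, cfg.heads)


def _init_structure_encoder(rng, cfg: EncoderConfig):
    ns, nv = cfg.gvp_scalar, cfg.gvp_vector
    return {
        "embed_s": nn.init_linear(rng, 6, ns),
        "embed_v": nn.trunc_normal(rng, (3, nv), 0.1),
        "gvp_layers": [init_gvp_layer(rng, ns, nv) for _ in range(cfg.gvp_layers)],
        "to_width": nn.init_linear(rng, ns, cfg.width),
        "pos": nn.trunc_normal(rng, (cfg.max_len, cfg.width)),
        "layers": [init_transformer(rng, cfg) for _ in range(cfg.layers)],
        "ln_f": nn.init_layer_norm(cfg.width),
    }


def _init_projection(rng, cfg: EncoderConfig):
    return {"ln": nn.init_layer_norm(cfg.width), "out": nn.init_linear(rng, cfg.width, cfg.shared_dim)}


def init_encoders(cfgs: dict, text_vocab_size: int, seed: int = 0) -> dict:
    """Initialise all encoder and projection-head weights from one seed."""
    rng = onp.random.default_rng(seed)
    params = {
        "sequence": _init_token_encoder(rng, cfgs["sequence"], SEQ_VOCAB_SIZE),
        "structure": _init_structure_encoder(rng, cfgs["structure"]),
        "text": _init_token_encoder(rng, cfgs["text"], text_vocab_size),
        "projection": {m: _init_projection(rng, cfgs[m]) for m in ("sequence", "structure", "text")},
    }
    return params


# ---------------------------------------------------------------------------
# batched forward passes (differentiable)


def pad_token_batch(tokens: Sequence[TokenizedInput], pad_id: int = PAD_ID):
    """Stack variable-length token lists into (ids, mask, eos_idx) arrays."""
    L = max(len(t) for t in tokens)
    B = len(tokens)
    ids = onp.full((B, L), pad_id, dtype=int)
    mask = onp.zeros((B, L))
    eos = onp.zeros(B, dtype=int)
    for i, t in enumerate(tokens):
        ids[i, : len(t)] = t.token_ids
        mask[i, : len(t)] = 1.0
        eos[i] = t.eos_index
    return ids, mask, eos


def _token_forward(p, cfg: EncoderConfig, ids, mask):
    vocab = p["emb"].shape[0]
    if onp.max(ids) >= vocab or onp.min(ids) < 0:
        raise ValueError(f"token id out of range for vocabulary of size {vocab}")
    if ids.shape[1] > cfg.max_len:
        raise ValueError(f"input length {ids.shape[1]} exceeds max_len {cfg.max_len}")
    x = p["emb"][ids] + p["pos"][: ids.shape[1]]
    x = x * mask[:, :, None]
    x = nn.transformer_stack(p["layers"], x, mask, cfg.heads)
    return nn.layer_norm(p["ln_f"], x)


def encode_sequence_batch(p, cfg: EncoderConfig, ids, mask):
    """(B, L) token ids -> per-position embeddings (B, L, D) and BOS pooling (B, D)."""
    H = _token_forward(p, cfg, ids, mask)
    return H, H[:, 0, :]


def encode_text_batch(p, cfg: EncoderConfig, ids, mask, eos_idx):
    """(B, L) token ids -> EOS-pooled embeddings (B, D)."""
    H = _token_forward(p, cfg, ids, mask)
    B = ids.shape[0]
    return H[onp.arange(B), eos_idx, :]


def pad_graph_batch(graphs: Sequence[ResidueGraph]):
    """Pad residue graphs to common node/neighbour counts with masks."""
    B = len(graphs)
    n = max(g.n_nodes for g in graphs)
    k = max(g.k for g in graphs)
    node_s = onp.zeros((B, n, 6))
    node_v = onp.zeros((B, n, 3, 3))
    nbr = onp.zeros((B, n, k), dtype=int)
    edge_s = onp.zeros((B, n, k, 16))
    edge_v = onp.zeros((B, n, k, 3))
    nbr_mask = onp.zeros((B, n, k))
    node_mask = onp.zeros((B, n))
    for i, g in enumerate(graphs):
        ni, ki = g.n_nodes, g.k
        node_s[i, :ni] = g.node_s
        node_v[i, :ni] = g.node_v
        nbr[i, :ni, :ki] = g.nbr_idx
        edge_s[i, :ni, :ki] = g.edge_s
        edge_v[i, :ni, :ki] = g.edge_v
        nbr_mask[i, :ni, :ki] = 1.0
        node_mask[i, :ni] = 1.0
    return dict(
        node_s=node_s, node_v=node_v, nbr=nbr, edge_s=edge_s, edge_v=edge_v,
        nbr_mask=nbr_mask, node_mask=node_mask,
    )


def encode_structure_batch(p, cfg: EncoderConfig, batch: dict):
    """Padded graph batch -> per-residue embeddings (B, n, D) and mean pooling (B, D)."""
    node_s, node_v = batch["node_s"], batch["node_v"]
    B, n = node_s.shape[0], node_s.shape[1]
    k = batch["nbr"].shape[2]
    s = nn.linear(p["embed_s"], node_s).reshape((B * n, -1))
    V = np.swapaxes(np.swapaxes(node_v, -1, -2) @ p["embed_v"], -1, -2).reshape((B * n, -1, 3))
    glob_nbr = (batch["nbr"] + onp.arange(B)[:, None, None] * n).reshape(B * n, k)
    edge_s = batch["edge_s"].reshape(B * n, k, 16)
    edge_v = batch["edge_v"].reshape(B * n, k, 3)
    nbr_mask = batch["nbr_mask"].reshape(B * n, k)
    for lp in p["gvp_layers"]:
        s, V = gvp_layer(lp, s, V, glob_nbr, edge_s, edge_v, nbr_mask)
    x = nn.linear(p["to_width"], s).reshape((B, n, -1))
    if n > cfg.max_len:
        raise ValueError(f"structure length {n} exceeds max_len {cfg.max_len}")
    node_mask = batch["node_mask"]
    x = (x + p["pos"][:n]) * node_mask[:, :, None]
    x = nn.transformer_stack(p["layers"], x, node_mask, cfg.heads)
    x = nn.layer_norm(p["ln_f"], x)
    denom = np.sum(node_mask, axis=1)[:, None]
    pooled = np.sum(x * node_mask[:, :, None], axis=1) / denom
    return x, pooled


def project(p, pooled, normalize: bool = True, eps: float = 1e-12):
    """Projection head: LayerNorm + one affine map (+ L2 normalisation)."""
    z = nn.linear(p["out"], nn.layer_norm(p["ln"], pooled))
    if normalize:
        z = z / np.sqrt(np.sum(z * z, axis=-1, keepdims=True) + eps)
    return z


# ---------------------------------------------------------------------------
# single-record conveniences


def encode_sequence(tokens: TokenizedInput, cfg: EncoderConfig, params):
    if tokens.modality != "sequence":
        raise ValueError("expected sequence tokens")
    ids, mask, _ = pad_token_batch([tokens])
    H, pooled = encode_sequence_batch(params, cfg, ids, mask)
    return onp.asarray(H[0]), PooledEmbedding("sequence", onp.asarray(pooled[0]))


def encode_text(tokens: TokenizedInput, cfg: EncoderConfig, params) -> PooledEmbedding:
    if tokens.modality != "text":
        raise ValueError("expected text tokens")
    if int(tokens.token_ids[tokens.eos_index]) != 2:
        raise ValueError("text tokens missing EOS")
    ids, mask, eos = pad_token_batch([tokens])
    pooled = encode_text_batch(params, cfg, ids, mask, eos)
    return PooledEmbedding("text", onp.asarray(pooled[0]))


def encode_structure(structure: BackboneStructure, cfg: EncoderConfig, params):
    graph = build_residue_graph(structure, k=cfg.knn)
    batch = pad_graph_batch([graph])
    H, pooled = encode_structure_batch(params, cfg, batch)
    return onp.asarray(H[0]), PooledEmbedding("structure", onp.asarray(pooled[0]))


# ---------------------------------------------------------------------------
# checkpoints


def _tree_to_flat_dict(tree, prefix="", out=None):
    if out is None:
        out = {}
    if isinstance(tree, dict):
        for key, val in tree.items():
            _tree_to_flat_dict(val, f"{prefix}{key}/", out)
    elif isinstance(tree, (list, tuple)):
        for i, val in enumerate(tree):
            _tree_to_flat_dict(val, f"{prefix}{i}/", out)
    else:
        out[prefix[:-1]] = onp.asarray(tree)
    return out


def _fill_tree_from_flat(skeleton, flat, prefix=""):
    if isinstance(skeleton, dict):
        return {k: _fill_tree_from_flat(v, flat, f"{prefix}{k}/") for k, v in skeleton.items()}
    if isinstance(skeleton, (list, tuple)):
        return [_fill_tree_from_flat(v, flat, f"{prefix}{i}/") for i, v in enumerate(skeleton)]
    return flat[prefix[:-1]]


def config_digest(obj) -> str:
    """Stable SHA-256 digest of a JSON-serialisable configuration."""
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def save_checkpoint(path, params: dict, cfgs: dict, text_vocab: TextVocab, meta: dict | None = None) -> None:
    """Write weights + configs (+ vocabulary) to a checkpoint directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    flat = _tree_to_flat_dict(params)
    onp.savez(path / "weights.npz", **flat)
    cfg_doc = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "encoders": {m: asdict(cfgs[m]) for m in cfgs},
        "text_vocab_size": text_vocab.size,
        "meta": meta or {},
    }
    cfg_doc["config_digest"] = config_digest(cfg_doc["encoders"])
    (path / "config.yaml").write_text(yaml.safe_dump(cfg_doc, sort_keys=True))
    (path / "vocab.json").write_text(json.dumps(text_vocab.token_to_id, sort_keys=True))


def load_checkpoint(path):
    """Load (params, cfgs, text_vocab, meta) from a checkpoint directory."""
    path = Path(path)
    cfg_doc = yaml.safe_load((path / "config.yaml").read_text())
    if cfg_doc.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint format: {cfg_doc.get('format_version')}")
    cfgs = {m: EncoderConfig(**d) for m, d in cfg_doc["encoders"].items()}
    vocab = TextVocab(token_to_id=json.loads((path / "vocab.json").read_text()))
    skeleton = init_encoders(cfgs, vocab.size, seed=0)
    with onp.load(path / "weights.npz") as npz:
        flat = dict(npz)
    params = _fill_tree_from_flat(skeleton, flat)
    return params, cfgs, vocab, cfg_doc.get("meta", {})


def export_embeddings(path, ids: Sequence[str], matrix) -> None:
    """Write an (id x shared_dim) embedding matrix as a TSV file."""
    import pandas as pd

    matrix = onp.asarray(matrix)
    df = pd.DataFrame(matrix, index=list(ids))
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.8g")
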