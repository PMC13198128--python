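"""Sequence-anchored contrastive pretraining.

The sequence modality is the anchor: each training step draws a batch
of sequence-structure pairs and a batch of sequence-text pairs, encodes
and projects all modalities into the shared space, and minimises the
sum of two InfoNCE losses in which the sequence embedding is the query
and the structure/text embeddings are the keys.  Negatives come only
from within the same pair-type subset of the batch.  Structure and text
are never contrasted against each other directly; any structure-text
alignment that emerges is coupled through the shared anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as onp
import autograd.numpy as np
from autograd.tracer import getval

from . import nn
from .corpus_io import (
    CorpusManifest,
    ProteinRecord,
    TextVocab,
    build_manifest,
    build_text_vocab,
    tokenize_sequence,
    tokenize_text,
)
from .encoders import (
    EncoderConfig,
    build_residue_graph,
    desk_configs,
    encode_sequence_batch,
    encode_structure_batch,
    encode_text_batch,
    init_encoders,
    pad_graph_batch,
    pad_token_batch,
    project,
)

__all__ = [
    "AlignmentConfig",
    "TriModalBatch",
    "BatchPlan",
    "info_nce",
    "combined_loss",
    "sample_batch",
    "pretrain",
    "PretrainResult",
    "retrieve",
    "EncodedCorpus",
    "encode_corpus",
    "embed_records",
]


@dataclass(frozen=True)
class AlignmentConfig:
    """Hyperparameters of the contrastive pretraining run.

    Full-scale documented defaults: temperature 0.07; equal loss
    weights; 80 sequence-structure plus 80 sequence-text pairs per
    step; AdamW with learning rate 5e-6, weight decay 1e-4, betas
    (0.9, 0.95); cosine-annealed learning rate over 20 epochs.
    ``total_steps`` overrides the epoch-derived step count when set.
    ``loss_reduction`` selects the equal-weight sum (default) or the
    mean of the per-pair-type losses, which share an optimum up to a
    factor of two on the learning rate.
    """

    temperature: float = 0.07
    w_seq_struct: float = 1.0
    w_seq_text: float = 1.0
    sta_weight: float = 0.0
    batch_struct: int = 80
    batch_text: int = 80
    lr: float = 5e-6
    weight_decay: float = 1e-4
    betas: tuple = (0.9, 0.95)
    epochs: int = 20
    total_steps: int | None = None
    warmup: int = 0
    loss_reduction: str = "sum"
    bidirectional: bool = False
    with_replacement: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if min(self.w_seq_struct, self.w_seq_text, self.sta_weight) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.batch_struct < 2 or self.batch_text < 2:
            raise ValueError("batch sizes must be >= 2")
        if self.loss_reduction not in ("sum", "average"):
            raise ValueError("loss_reduction must be 'sum' or 'average'")


@dataclass(frozen=True)
class TriModalBatch:
    """Projected, matched embeddings for one step.

    Row i of each query matrix and row i of the corresponding key
    matrix come from the same record.  ``rt_pairs`` optionally holds
    matched (structure, text) rows for the direct structure-text loss.
    """

    seq_for_struct: onp.ndarray | None
    struct: onp.ndarray | None
    seq_for_text: onp.ndarray | None
    text: onp.ndarray | None
    struct_ids: tuple = ()
    text_ids: tuple = ()
    rt_struct: onp.ndarray | None = None
    rt_text: onp.ndarray | None = None


@dataclass(frozen=True)
class BatchPlan:
    struct_ids: tuple
    text_ids: tuple


def info_nce(queries, keys, temperature: float):
    """Mean InfoNCE loss over rows.

    For each row i the positive is key i and the negatives are every
    other key in the batch; the loss is the temperature-scaled softmax
    cross-entropy, computed with a numerically stable log-sum-exp.
    """
    q, k = queries, keys
    N = q.shape[0]
    if N < 2:
        raise ValueError("InfoNCE needs at least 2 rows (no negatives otherwise)")
    if k.shape[0] != N or q.shape[1] != k.shape[1]:
        raise ValueError(f"shape mismatch: queries {q.shape} vs keys {k.shape}")
    if isinstance(q, onp.ndarray) and isinstance(k, onp.ndarray):
        if not (onp.isfinite(q).all() and onp.isfinite(k).all()):
            raise ValueError("non-finite input to info_nce")
    logits = q @ k.T / temperature
    pos = np.diag(logits)
    return np.mean(nn.logsumexp(logits, axis=1) - pos)


def combined_loss(batch: TriModalBatch, cfg: AlignmentConfig):
    """Weighted combination of the per-pair-type InfoNCE losses.

    Returns (total, breakdown).  A missing subset contributes zero and
    is flagged in the breakdown; both subsets missing is an error.
    """
    has_struct = batch.seq_for_struct is not None and batch.struct is not None
    has_text = batch.seq_for_text is not None and batch.text is not None
    if not has_struct and not has_text:
        raise ValueError("batch has neither sequence-structure nor sequence-text pairs")

    def _pair_loss(q, k):
        loss = info_nce(q, k, cfg.temperature)
        if cfg.bidirectional:
            loss = 0.5 * (loss + info_nce(k, q, cfg.temperature))
        return loss

    breakdown = {"missing": []}
    terms = []
    if has_struct:
        l_sr = _pair_loss(batch.seq_for_struct, batch.struct)
        breakdown["seq_struct"] = l_sr
        terms.append(cfg.w_seq_struct * l_sr)
    else:
        breakdown["seq_struct"] = 0.0
        breakdown["missing"].append("seq_struct")
    if has_text:
        l_st = _pair_loss(batch.seq_for_text, batch.text)
        breakdown["seq_text"] = l_st
        terms.append(cfg.w_seq_text * l_st)
    else:
        breakdown["seq_text"] = 0.0
        breakdown["missing"].append("seq_text")
    if cfg.sta_weight > 0 and batch.rt_struct is not None and batch.rt_text is not None:
        l_rt = _pair_loss(batch.rt_struct, batch.rt_text)
        breakdown["struct_text"] = l_rt
        terms.append(cfg.sta_weight * l_rt)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    if cfg.loss_reduction == "average":
        total = total / len(terms)
    return total, breakdown


def sample_batch(
    manifest: CorpusManifest,
    cfg: AlignmentConfig,
    rng: onp.random.Generator,
    n_struct: int | None = None,
    n_text: int | None = None,
) -> BatchPlan:
    """Draw pair ids uniformly at random, without replacement by default.

    ``n_struct``/``n_text`` override the config batch sizes; an explicit
    0 skips that subset (the missing-modality case).
    """

    def _draw(ids, size, name):
        if size == 0:
            return ()
        ids = list(ids)
        if size > len(ids):
            if not cfg.with_replacement:
                raise ValueError(
                    f"requested {size} {name} pairs but only {len(ids)} available "
                    "(set with_replacement=True to allow resampling)"
                )
            picked = rng.choice(len(ids), size=size, replace=True)
        else:
            picked = rng.choice(len(ids), size=size, replace=False)
        return tuple(ids[i] for i in picked)

    ns = cfg.batch_struct if n_struct is None else n_struct
    nt = cfg.batch_text if n_text is None else n_text
    return BatchPlan(
        struct_ids=_draw(manifest.seq_struct_ids, ns, "sequence-structure"),
        text_ids=_draw(manifest.seq_text_ids, nt, "sequence-text"),
    )


# ---------------------------------------------------------------------------
# pretraining


@dataclass
class PretrainResult:
    params: dict
    cfgs: dict
    text_vocab: TextVocab
    history: list
    align_cfg: AlignmentConfig
    text_participation: dict
    struct_participation: dict
    state: dict | None = None


class _FeatureCache:
    """Tokenized sequences/texts and residue graphs, computed once."""

    def __init__(self, records: Sequence[ProteinRecord], vocab: TextVocab, knn: int):
        self.by_id = {r.id: r for r in records}
        self.seq_tok = {r.id: tokenize_sequence(r.sequence) for r in records}
        self.text_tok = {r.id: tokenize_text(r.text, vocab) for r in records if r.text is not None}
        self.graph = {
            r.id: build_residue_graph(r.structure, k=knn) for r in records if r.structure is not None
        }


def _forward_batch(params, cfgs, cache: _FeatureCache, plan: BatchPlan, align_cfg: AlignmentConfig):
    """Encode and project one step's records; shared sequences encoded once."""
    seq_ids = list(dict.fromkeys(list(plan.struct_ids) + list(plan.text_ids)))
    pos = {rid: i for i, rid in enumerate(seq_ids)}
    ids, mask, _ = pad_token_batch([cache.seq_tok[r] for r in seq_ids])
    graphs = pad_graph_batch([cache.graph[r] for r in plan.struct_ids]) if plan.struct_ids else None
    t_ids, t_mask, t_eos = (
        pad_token_batch([cache.text_tok[r] for r in plan.text_ids]) if plan.text_ids else (None, None, None)
    )
    idx_struct = onp.array([pos[r] for r in plan.struct_ids], dtype=int)
    idx_text = onp.array([pos[r] for r in plan.text_ids], dtype=int)
    norm = cfgs["sequence"].normalize_projection

    def batch_of(params):
        _, seq_pooled = encode_sequence_batch(params["sequence"], cfgs["sequence"], ids, mask)
        s_proj = project(params["projection"]["sequence"], seq_pooled, norm)
        kwargs = {}
        if plan.struct_ids:
            _, r_pooled = encode_structure_batch(params["structure"], cfgs["structure"], graphs)
            kwargs["seq_for_struct"] = s_proj[idx_struct]
            kwargs["struct"] = project(params["projection"]["structure"], r_pooled, norm)
        else:
            kwargs["seq_for_struct"] = kwargs["struct"] = None
        if plan.text_ids:
            t_pooled = encode_text_batch(params["text"], cfgs["text"], t_ids, t_mask, t_eos)
            kwargs["seq_for_text"] = s_proj[idx_text]
            kwargs["text"] = project(params["projection"]["text"], t_pooled, norm)
        else:
            kwargs["seq_for_text"] = kwargs["text"] = None
        if align_cfg.sta_weight > 0 and plan.struct_ids:
            both = [i for i, rid in enumerate(plan.struct_ids) if rid in cache.text_tok]
            if len(both) >= 2:
                bt_ids, bt_mask, bt_eos = pad_token_batch([cache.text_tok[plan.struct_ids[i]] for i in both])
                bt_pooled = encode_text_batch(params["text"], cfgs["text"], bt_ids, bt_mask, bt_eos)
                kwargs["rt_struct"] = kwargs["struct"][onp.array(both, dtype=int)]
                kwargs["rt_text"] = project(params["projection"]["text"], bt_pooled, norm)
        return TriModalBatch(struct_ids=plan.struct_ids, text_ids=plan.text_ids, **kwargs)

    return batch_of


def pretrain(
    records: Sequence[ProteinRecord],
    cfg: AlignmentConfig,
    enc_cfgs: dict | None = None,
    text_vocab: TextVocab | None = None,
    callback: Callable | None = None,
    checkpoint_dir=None,
    resume_state: dict | None = None,
    keep_state: bool = False,
    stop_after: int | None = None,
) -> PretrainResult:
    """Run the contrastive pretraining loop.

    Gradient flows into all three encoders and all projection heads
    (no frozen anchor).  Fully reproducible given the config seed; a
    captured ``resume_state`` continues a run with an identical
    trajectory.  Divergence (non-finite loss) aborts with the step
    index.
    """
    enc_cfgs = enc_cfgs or desk_configs(seed=cfg.seed)
    manifest = build_manifest(records)
    if text_vocab is None:
        text_vocab = build_text_vocab([r.text for r in records if r.text is not None])
    cache = _FeatureCache(records, text_vocab, knn=enc_cfgs["structure"].knn)

    n_text = manifest.n_seq_text
    steps_per_epoch = max(int(math.ceil(n_text / cfg.batch_text)), 1) if n_text else 1
    total_steps = cfg.total_steps if cfg.total_steps is not None else cfg.epochs * steps_per_epoch
    lr_at = nn.cosine_schedule(cfg.lr, total_steps, warmup=cfg.warmup)

    want_struct = cfg.batch_struct if manifest.n_seq_struct else 0
    want_text = cfg.batch_text if manifest.n_seq_text else 0
    if want_struct == 0 and want_text == 0:
        raise ValueError("corpus has neither structure nor text pairs")

    if resume_state is not None:
        params = resume_state["params"]
        rng = onp.random.default_rng()
        rng.bit_generator.state = resume_state["rng_state"]
        start_step = resume_state["step"]
        opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay, betas=cfg.betas)
        opt.m, opt.v, opt.t = resume_state["opt_m"].copy(), resume_state["opt_v"].copy(), resume_state["opt_t"]
        history = list(resume_state.get("history", []))
        text_part = dict(resume_state.get("text_participation", {}))
        struct_part = dict(resume_state.get("struct_participation", {}))
    else:
        params = init_encoders(enc_cfgs, text_vocab.size, seed=cfg.seed)
        rng = onp.random.default_rng(cfg.seed)
        start_step = 0
        opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay, betas=cfg.betas)
        history = []
        text_part: dict = {}
        struct_part: dict = {}

    end_step = total_steps if stop_after is None else min(stop_after, total_steps)
    best_loss, best_params, best_step = onp.inf, None, -1
    for step in range(start_step, end_step):
        plan = sample_batch(manifest, cfg, rng, n_struct=want_struct, n_text=want_text)
        for rid in plan.text_ids:
            text_part[rid] = text_part.get(rid, 0) + 1
        for rid in plan.struct_ids:
            struct_part[rid] = struct_part.get(rid, 0) + 1
        batch_of = _forward_batch(params, enc_cfgs, cache, plan, cfg)

        breakdown_holder = {}

        def objective(p):
            total, breakdown = combined_loss(batch_of(p), cfg)
            breakdown_holder.update(breakdown)
            return total

        loss, grads = nn.value_and_grad(objective)(params)
        if not onp.isfinite(loss):
            raise RuntimeError(f"non-finite loss at step {step}")
        lr = lr_at(step)
        params = opt.step(params, grads, lr=lr)
        rec = {
            "step": step,
            "loss_seq_struct": float(getval(breakdown_holder.get("seq_struct", 0.0))),
            "loss_seq_text": float(getval(breakdown_holder.get("seq_text", 0.0))),
            "total": float(loss),
            "lr": float(lr),
            "n_struct": len(plan.struct_ids),
            "n_text": len(plan.text_ids),
        }
        history.append(rec)
        if float(loss) < best_loss:
            best_loss, best_params, best_step = float(loss), params, step
        if callback is not None:
            callback(rec, params)
        if checkpoint_dir is not None and (step + 1) % steps_per_epoch == 0:
            from .encoders import save_checkpoint

            save_checkpoint(
                checkpoint_dir, params, enc_cfgs, text_vocab, meta={"step": step + 1, "loss": float(loss)}
            )
            if best_params is not None:
                save_checkpoint(
                    Path(checkpoint_dir) / "best", best_params, enc_cfgs, text_vocab,
                    meta={"step": best_step, "loss": best_loss},
                )

    state = None
    if keep_state:
        state = {
            "params": params,
            "rng_state": rng.bit_generator.state,
            "step": end_step,
            "opt_m": opt.m.copy(),
            "opt_v": opt.v.copy(),
            "opt_t": opt.t,
            "history": list(history),
            "text_participation": dict(text_part),
            "struct_participation": dict(struct_part),
        }
    return PretrainResult(
        params=params,
        cfgs=enc_cfgs,
        text_vocab=text_vocab,
        history=history,
        align_cfg=cfg,
        text_participation=text_part,
        struct_participation=struct_part,
        state=state,
    )


def capture_state(result: PretrainResult) -> dict:
    """The resumable training state of a run executed with keep_state=True."""
    if result.state is None:
        raise ValueError("run pretrain(..., keep_state=True) to capture state")
    return result.state


# ---------------------------------------------------------------------------
# evaluation: embedding and retrieval


@dataclass(frozen=True)
class EncodedCorpus:
    """Projected (shared-space) and pooled embeddings per modality."""

    ids: tuple
    projected: dict  # modality -> (n_subset, shared_dim), with subset ids
    pooled: dict  # modality -> (n_subset, width)
    subset_ids: dict  # modality -> tuple of record ids
    per_position: dict | None = None


def encode_corpus(
    params,
    cfgs,
    vocab: TextVocab,
    records: Sequence[ProteinRecord],
    batch_size: int = 64,
    keep_per_position: bool = False,
) -> EncodedCorpus:
    """Embed every record's available modalities (evaluation mode)."""
    norm = cfgs["sequence"].normalize_projection
    ids_all = tuple(r.id for r in records)
    projected: dict = {}
    pooled: dict = {}
    subset_ids: dict = {}
    per_position = {} if keep_per_position else None

    seq_tok = [tokenize_sequence(r.sequence) for r in records]
    pooled_rows, proj_rows = [], []
    for lo in range(0, len(records), batch_size):
        chunk = seq_tok[lo : lo + batch_size]
        ids, mask, _ = pad_token_batch(chunk)
        H, p = encode_sequence_batch(params["sequence"], cfgs["sequence"], ids, mask)
        pooled_rows.append(onp.asarray(p))
        proj_rows.append(onp.asarray(project(params["projection"]["sequence"], p, norm)))
        if keep_per_position:
            for j, t in enumerate(chunk):
                per_position[records[lo + j].id] = onp.asarray(H[j, : len(t)])
    pooled["sequence"] = onp.concatenate(pooled_rows) if pooled_rows else onp.zeros((0, 0))
    projected["sequence"] = onp.concatenate(proj_rows) if proj_rows else onp.zeros((0, 0))
    subset_ids["sequence"] = ids_all

    with_struct = [r for r in records if r.structure is not None]
    if with_struct:
        rows_p, rows_z = [], []
        for lo in range(0, len(with_struct), batch_size):
            chunk = with_struct[lo : lo + batch_size]
            graphs = pad_graph_batch(
                [build_residue_graph(r.structure, k=cfgs["structure"].knn) for r in chunk]
            )
            _, p = encode_structure_batch(params["structure"], cfgs["structure"], graphs)
            rows_p.append(onp.asarray(p))
            rows_z.append(onp.asarray(project(params["projection"]["structure"], p, norm)))
        pooled["structure"] = onp.concatenate(rows_p)
        projected["structure"] = onp.concatenate(rows_z)
        subset_ids["structure"] = tuple(r.id for r in with_struct)

    with_text = [r for r in records if r.text is not None]
    if with_text:
        rows_p, rows_z = [], []
        for lo in range(0, len(with_text), batch_size):
            chunk = with_text[lo : lo + batch_size]
            t_ids, t_mask, t_eos = pad_token_batch([tokenize_text(r.text, vocab) for r in chunk])
            p = encode_text_batch(params["text"], cfgs["text"], t_ids, t_mask, t_eos)
            rows_p.append(onp.asarray(p))
            rows_z.append(onp.asarray(project(params["projection"]["text"], p, norm)))
        pooled["text"] = onp.concatenate(rows_p)
        projected["text"] = onp.concatenate(rows_z)
        subset_ids["text"] = tuple(r.id for r in with_text)

    return EncodedCorpus(
        ids=ids_all, projected=projected, pooled=pooled, subset_ids=subset_ids, per_position=per_position
    )


def embed_records(result: PretrainResult, records: Sequence[ProteinRecord], **kw) -> EncodedCorpus:
    return encode_corpus(result.params, result.cfgs, result.text_vocab, records, **kw)


def retrieve(queries, gallery, ks=(1,), labels=None, query_labels=None):
    """Cosine-similarity retrieval of each query's true counterpart.

    Row i of ``queries`` corresponds to row i of ``gallery``.  Returns
    ranks (0-based), recall@k for each requested k, and — when gallery
    ``labels`` (and optionally distinct ``query_labels``) are given —
    the fraction of queries whose top hit shares their class label.
    """
    Q = onp.asarray(queries, dtype=float)
    G = onp.asarray(gallery, dtype=float)
    if Q.shape[1] != G.shape[1]:
        raise ValueError("dimension mismatch between queries and gallery")
    for k in ks:
        if k > G.shape[0]:
            raise ValueError(f"k={k} exceeds gallery size {G.shape[0]}")
    Qn = Q / onp.maximum(onp.linalg.norm(Q, axis=1, keepdims=True), 1e-12)
    Gn = G / onp.maximum(onp.linalg.norm(G, axis=1, keepdims=True), 1e-12)
    sim = Qn @ Gn.T
    order = onp.argsort(-sim, axis=1, kind="stable")
    n = Q.shape[0]
    ranks = onp.empty(n, dtype=int)
    if Q.shape[0] == G.shape[0]:
        for i in range(n):
            ranks[i] = int(onp.nonzero(order[i] == i)[0][0])
    else:
        ranks[:] = -1
    out = {"ranks": ranks}
    for k in ks:
        out[f"recall@{k}"] = float(onp.mean(ranks < k)) if ranks[0] >= 0 else float("nan")
    if labels is not None:
        labels = onp.asarray(labels)
        ql = onp.asarray(query_labels) if query_labels is not None else labels
        top = order[:, 0]
        out["class_top1"] = float(onp.mean(labels[top] == ql))
    return out
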