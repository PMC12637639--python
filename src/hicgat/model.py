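"""Locus encoders, graph-attention trunk, losses, two-stage training, metrics.

The architecture: every 5 kb locus is encoded into a d-vector by a shared
encoder (1-D CNN over one-hot sequence, optionally with an accessibility row,
or a two-layer perceptron over a precomputed dense vector).  Node embeddings
are propagated over the star subgraph by two multi-head graph-attention
layers (edge logits LeakyReLU(a^T [h'_v || h'_u]), softmax over in-neighbors,
weighted sum, head concatenation, then residual + dropout + layer norm).
The subgraph representation is z_s = [e_c || mean over nodes of the GAT
output], passed through a linear head to T per-assay logits.

Training is two-stage: (1) pretrain encoder + linear probe on center nodes
only, early-stopping on validation loss; (2) fine-tune end-to-end with early
conv blocks frozen, Adam (lr 3e-5, weight decay 1e-6) and plateau-based
learning-rate halving (factor 0.5, patience 1, floor 1e-7).  Data are split
by chromosome: chr9 test, chr8 validation, chrY excluded, the rest train.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .autograd import Tensor, concat
from .graph_builder import SignalSubgraph
from .io_formats import GenomicLocus, Track
from .nn import Adam, Conv1d, LayerNorm, Linear, Module, ReduceLROnPlateau, dropout

log = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SeqEncoder",
    "DenseProjector",
    "GatLayer",
    "GraphModel",
    "AttentionRecord",
    "one_hot_sequence",
    "locus_features",
    "masked_bce_loss",
    "chromosome_split",
    "pretrain_encoder",
    "finetune_graph",
    "evaluate",
    "paired_bootstrap_delta",
]

WINDOW_BP = 5000
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def one_hot_sequence(seq: str) -> np.ndarray:
    """4 x L one-hot; unknown bases (N) give all-zero columns."""
    out = np.zeros((4, len(seq)))
    for base, row in _BASE_INDEX.items():
        out[row] = np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)
    return out


def augment_windows(feats: np.ndarray, rng: np.random.Generator,
                    max_shift: int = 1000,
                    reverse_complement: bool = True) -> np.ndarray:
    """Training-time augmentation: circular shift + reverse complement.

    Both transformations preserve motif content, so they multiply the
    effective training set without touching the labels.  Rows 0-3 are the
    A/C/G/T one-hot; any extra rows (accessibility) are only reversed.
    """
    out = feats.copy()
    B = out.shape[0]
    shifts = rng.integers(-max_shift, max_shift + 1, size=B)
    flips = rng.random(B) < 0.5 if reverse_complement else np.zeros(B, bool)
    for b in range(B):
        if shifts[b]:
            out[b] = np.roll(out[b], shifts[b], axis=1)
        if flips[b]:
            out[b] = out[b, :, ::-1]
            out[b, :4] = out[b, [3, 2, 1, 0]]   # A<->T, C<->G
    return out


def locus_features(locus: GenomicLocus, genome: dict[str, str],
                   mode: str, track: Track | None = None,
                   embeddings: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Raw node features for one 5 kb locus in the requested encoder mode."""
    if mode == "dense":
        vec = embeddings[locus.key()]
        if vec.shape != (4096,):
            raise ValueError("dense embedding must be length 4096")
        return vec
    seq = genome[locus.chrom][locus.start : locus.end]
    if len(seq) < WINDOW_BP:  # clipped window at a chromosome edge
        seq = seq + "N" * (WINDOW_BP - len(seq))
    x = one_hot_sequence(seq)
    if mode == "seq":
        return x
    if mode == "seq_dnase":
        sig = track.values(locus.chrom, locus.start, locus.end)
        if sig.size < WINDOW_BP:
            sig = np.pad(sig, (0, WINDOW_BP - sig.size))
        return np.vstack([x, sig[None, :]])
    raise ValueError(f"unknown feature mode {mode!r}")


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    d: int = 128                 # embedding width
    heads: int = 4               # attention heads M
    layers: int = 2              # GAT depth (fixed by design)
    n_profiles: int = 8          # T
    feature_mode: str = "seq_dnase"     # seq | seq_dnase | dense
    conv_channels: tuple[int, ...] = (32, 32, 64)
    kernel: int = 9
    pool: int = 5
    dropout: float = 0.1
    leaky_slope: float = 0.2
    freeze_depth: int = 2        # conv blocks frozen in stage 2
    # Optional motif-informed initialization of first-layer filters (one
    # filter per motif plus its reverse complement), emulating the sequence
    # vocabulary a pretrained encoder brings; the filters stay trainable.
    pwm_init: tuple[str, ...] = ()

    @property
    def d_head(self) -> int:
        if self.d % self.heads:
            raise ValueError("d must be divisible by the number of heads")
        return self.d // self.heads

    @property
    def feature_rows(self) -> int:
        """Rows of the raw feature matrix handed to the encoder."""
        return {"seq": 4, "seq_dnase": 5, "dense": 4096}[self.feature_mode]


@dataclass
class TrainConfig:
    lr: float = 3e-5
    weight_decay: float = 1e-6
    epochs: int = 30
    batch_size: int = 32
    patience: int = 3            # early-stop patience (epochs), stage 1
    sched_factor: float = 0.5
    sched_patience: int = 1
    min_lr: float = 1e-7
    augment: bool = False        # shift/reverse-complement training windows
    max_shift: int = 1000
    seed: int = 0


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class SeqEncoder(Module):
    """Conv-relu-pool blocks over the one-hot sequence, global average+max
    pooling, linear projection to d.

    The accessibility row (seq_dnase mode) bypasses the convolutions and
    joins the pooled vector as mean/max summaries: motif filters then see
    pure sequence, and the max-pooling path keeps short-motif responses from
    being diluted by the window length.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c_prev = 4
        self.blocks: list[Conv1d] = []
        for i, c in enumerate(cfg.conv_channels):
            self.blocks.append(self.register(f"conv{i}", Conv1d(c_prev, c,
                                                                cfg.kernel, rng)))
            c_prev = c
        extra = 2 if cfg.feature_mode == "seq_dnase" else 0
        # multi-scale readout: every block contributes avg+max summaries,
        # so low-level (motif-scale) filter responses reach the projection
        # without passing through the deeper blocks
        width = 2 * sum(cfg.conv_channels) + extra
        self.proj = self.register("proj", Linear(width, cfg.d, rng))
        if cfg.pwm_init:
            self._seed_motif_filters(cfg.pwm_init)

    _COMPLEMENT = str.maketrans("ACGT", "TGCA")

    def _seed_motif_filters(self, motifs: tuple[str, ...]):
        """Overwrite leading first-layer filters with motif templates
        (forward and reverse complement): match +1, mismatch -1/3, so a
        perfect hit scores len(motif) and each substitution costs 4/3."""
        w = self.blocks[0].w.data
        k = w.shape[2]
        slot = 0
        for motif in motifs:
            rc = motif.translate(self._COMPLEMENT)[::-1]
            for m in (motif, rc):
                if slot >= w.shape[0] or len(m) > k:
                    break
                tmpl = np.full((4, k), 0.0)
                off = (k - len(m)) // 2
                for j, base in enumerate(m):
                    tmpl[:, off + j] = -1.0 / 3.0
                    tmpl[_BASE_INDEX[base], off + j] = 1.0
                w[slot] = tmpl * 0.3
                slot += 1

    def __call__(self, x: Tensor) -> Tensor:
        n_rows = x.shape[1]
        seq = x if n_rows == 4 else Tensor(x.data[:, :4])
        h = seq
        pooled = []
        for blk in self.blocks:
            h = blk(h).relu().max_pool1d(self.cfg.pool)
            pooled += [h.mean(axis=2), h.amax(axis=2)]
        if n_rows > 4:
            acc = Tensor(x.data[:, 4])
            pooled += [acc.mean(axis=1, keepdims=True),
                       acc.amax(axis=1).reshape(-1, 1)]
        return self.proj(concat(pooled, axis=1))

    def frozen_param_names(self, freeze_depth: int) -> set[str]:
        return {f"conv{i}.{p}" for i in range(min(freeze_depth, len(self.blocks)))
                for p in ("w", "b")}


class DenseProjector(Module):
    """Two-layer perceptron mapping a 4096 dense vector to d."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 hidden: int = 256):
        super().__init__()
        self.fc1 = self.register("fc1", Linear(4096, hidden, rng))
        self.fc2 = self.register("fc2", Linear(hidden, cfg.d, rng))

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def frozen_param_names(self, freeze_depth: int) -> set[str]:
        return {"fc1.w", "fc1.b"} if freeze_depth > 0 else set()


class GatLayer(Module):
    """One multi-head graph-attention layer with residual + dropout + norm."""

    def __init__(self, d_in: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d_out = cfg.heads * cfg.d_head
        scale = np.sqrt(2.0 / (d_in + cfg.d_head))
        self.w = self.register("w", rng.normal(0, scale, size=(d_in, d_out)))
        self.a_dst = self.register("a_dst",
                                   rng.normal(0, scale, size=(cfg.heads, cfg.d_head)))
        self.a_src = self.register("a_src",
                                   rng.normal(0, scale, size=(cfg.heads, cfg.d_head)))
        self.norm = self.register("norm", LayerNorm(d_out))
        if d_in != d_out:  # linear shortcut when widths differ
            self.shortcut = self.register("shortcut", Linear(d_in, d_out, rng))
        else:
            self.shortcut = None

    def __call__(self, h: Tensor, edges: np.ndarray, n_nodes: int,
                 rng: np.random.Generator):
        """h: (N, d_in); edges: (E, 2) src,dst rows.  Returns (out, alpha)."""
        cfg = self.cfg
        M, dh = cfg.heads, cfg.d_head
        hp = (h @ self.w).reshape(n_nodes, M, dh)           # projected, per head
        score_dst = (hp * self.a_dst).sum(axis=2)           # (N, M)
        score_src = (hp * self.a_src).sum(axis=2)
        if edges.shape[0] == 0:
            agg = Tensor(np.zeros((n_nodes, M * dh)))
            alpha = np.zeros((0, M))
        else:
            src, dst = edges[:, 0], edges[:, 1]
            logits = (score_dst.take_rows(dst)
                      + score_src.take_rows(src)).leaky_relu(cfg.leaky_slope)
            # softmax over in-edges grouped by destination (shift is constant)
            shift = np.zeros((n_nodes, M))
            np.maximum.at(shift, dst, logits.data)
            ex = (logits - Tensor(shift[dst])).exp()
            denom = ex.scatter_sum(dst, n_nodes)            # (N, M)
            alpha_t = ex / denom.take_rows(dst)             # (E, M)
            msg = alpha_t.reshape(-1, M, 1) * hp.take_rows(src)
            agg = msg.scatter_sum(dst, n_nodes).reshape(n_nodes, M * dh)
            alpha = alpha_t.data.copy()
        out = agg.elu()
        out = dropout(out, cfg.dropout, rng, self.training)
        res = h if self.shortcut is None else self.shortcut(h)
        return self.norm(res + out), alpha


@dataclass
class AttentionRecord:
    """Per-layer attention coefficients for the directed edges of a graph."""

    edges: np.ndarray                  # (E, 2) src,dst in graph-local indices
    alpha: list[np.ndarray]            # per layer: (E, M)

    def check_normalized(self, n_nodes: int, tol: float = 1e-6):
        for layer_alpha in self.alpha:
            sums = np.zeros((n_nodes, layer_alpha.shape[1]))
            np.add.at(sums, self.edges[:, 1], layer_alpha)
            has_in = np.zeros(n_nodes, dtype=bool)
            has_in[self.edges[:, 1]] = True
            if not np.allclose(sums[has_in], 1.0, atol=tol):
                raise AssertionError("attention coefficients do not sum to 1")


@dataclass
class ForwardResult:
    z: np.ndarray                      # (B, 2d)
    logits: np.ndarray                 # (B, T)
    probabilities: np.ndarray          # (B, T)
    records: list[AttentionRecord]
    loss: Tensor | None = None
    pooled: np.ndarray | None = None   # (B, d) mean GAT embedding per graph


class GraphModel(Module):
    """Shared locus encoder + two GAT layers + linear multi-label head."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        if cfg.layers != 2:
            warnings.warn("the published design fixes two attention layers",
                          stacklevel=2)
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        if cfg.feature_mode == "dense":
            self.encoder = self.register("encoder", DenseProjector(cfg, rng))
        else:
            self.encoder = self.register("encoder", SeqEncoder(cfg, rng))
        d_out = cfg.heads * cfg.d_head
        self.gats = [self.register(f"gat{i}",
                                   GatLayer(cfg.d if i == 0 else d_out, cfg, rng))
                     for i in range(cfg.layers)]
        self.head = self.register("head", Linear(cfg.d + d_out, cfg.n_profiles, rng))

    # -- encoding -----------------------------------------------------------
    def encode(self, features: np.ndarray) -> Tensor:
        """features: (N, C, 5000) for seq modes or (N, 4096) dense."""
        return self.encoder(Tensor(features))

    # -- full forward over a batch of star subgraphs ------------------------
    def forward_subgraphs(self, graphs: list[SignalSubgraph], feature_fn,
                          labels: np.ndarray | None = None,
                          mask: np.ndarray | None = None,
                          rng: np.random.Generator | None = None,
                          check_attention: bool = True,
                          augment_rng: np.random.Generator | None = None,
                          max_shift: int = 1000) -> ForwardResult:
        """feature_fn(locus, is_center) -> raw feature array.

        Nodes of all graphs are concatenated into one disjoint union; shared
        loci are featurized once through a cache and encoded in one batch.
        Inference passes (no labels, eval mode) skip tape construction.
        """
        from .autograd import no_grad

        if labels is None and not self.training:
            with no_grad():
                return self._forward_subgraphs(graphs, feature_fn, labels,
                                               mask, rng, check_attention,
                                               augment_rng, max_shift)
        return self._forward_subgraphs(graphs, feature_fn, labels, mask, rng,
                                       check_attention, augment_rng,
                                       max_shift)

    def _forward_subgraphs(self, graphs, feature_fn, labels, mask, rng,
                           check_attention, augment_rng, max_shift
                           ) -> ForwardResult:
        rng = rng or np.random.default_rng(0)
        cache: dict[tuple[str, bool], int] = {}
        feats: list[np.ndarray] = []

        def feat_index(locus: GenomicLocus, is_center: bool) -> int:
            k = (locus.key(), is_center)
            if k not in cache:
                cache[k] = len(feats)
                feats.append(feature_fn(locus, is_center))
            return cache[k]

        node_feat_idx: list[int] = []
        graph_slices: list[tuple[int, int]] = []
        edges: list[tuple[int, int]] = []
        center_nodes: list[int] = []
        for g in graphs:
            base = len(node_feat_idx)
            center_nodes.append(base)
            node_feat_idx.append(feat_index(g.center, True))
            for nb in g.neighbors:
                node_feat_idx.append(feat_index(nb, False))
            for k in range(len(g.neighbors)):
                edges.append((base + 1 + k, base))       # neighbor -> center
                edges.append((base, base + 1 + k))       # center -> neighbor
            graph_slices.append((base, len(node_feat_idx)))

        stacked = np.stack(feats, axis=0)
        if augment_rng is not None and stacked.ndim == 3:
            stacked = augment_windows(stacked, augment_rng, max_shift)
        unique = self.encode(stacked)                     # (U, d)
        h0 = unique.take_rows(np.asarray(node_feat_idx))  # (N_nodes, d)
        n_nodes = len(node_feat_idx)
        e = np.asarray(edges, dtype=np.intp).reshape(-1, 2)

        h = h0
        alphas: list[np.ndarray] = []
        for gat in self.gats:
            h, a = gat(h, e, n_nodes, rng)
            alphas.append(a)

        # per-graph mean pool over all nodes (center included)
        gid = np.concatenate([np.full(hi - lo, i)
                              for i, (lo, hi) in enumerate(graph_slices)])
        sizes = np.array([hi - lo for lo, hi in graph_slices], dtype=float)
        pooled = h.scatter_sum(gid, len(graphs)) * Tensor(1.0 / sizes[:, None])
        e_center = h0.take_rows(np.asarray(center_nodes))
        z = concat([e_center, pooled], axis=1)
        logits = self.head(z)
        probs = logits.sigmoid()

        records = []
        for i, (lo, hi) in enumerate(graph_slices):
            sel = (e[:, 1] >= lo) & (e[:, 1] < hi) if e.size else np.zeros(0, bool)
            rec = AttentionRecord(edges=e[sel] - lo if e.size else e,
                                  alpha=[a[sel] for a in alphas])
            if check_attention:
                rec.check_normalized(hi - lo)
            records.append(rec)

        loss = None
        if labels is not None:
            loss = masked_bce_loss(logits, labels, mask)
        return ForwardResult(z=z.data.copy(), logits=logits.data.copy(),
                             probabilities=probs.data.copy(), records=records,
                             loss=loss, pooled=pooled.data.copy())


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _softplus(x: Tensor) -> Tensor:
    # numerically stable log(1 + exp(x)) = relu(x) + log1p(exp(-|x|))
    ax = x.relu() + (-x).relu()
    return x.relu() + (1.0 + (-ax).exp()).log()


def masked_bce_loss(logits: Tensor, labels: np.ndarray,
                    mask: np.ndarray | None = None) -> Tensor:
    """Masked multi-label binary cross-entropy, computed in logit space.

    Per center: mean of -y log p - (1-y) log(1-p) over assays with mask 1;
    dataset loss is the mean over centers with at least one observed assay.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(labels)
    mask = np.asarray(mask, dtype=np.float64)
    # bce(x, y) = (1-y) x + softplus(-x)
    elem = (Tensor(1.0 - labels) * logits) + _softplus(-logits)
    msum = mask.sum(axis=1)
    valid = msum > 0
    if not valid.any():
        return Tensor(0.0)
    per_center = (elem * Tensor(mask)).sum(axis=1) * Tensor(
        np.where(valid, 1.0 / np.maximum(msum, 1.0), 0.0))
    return per_center.sum() * (1.0 / valid.sum())


# ---------------------------------------------------------------------------
# splits and training
# ---------------------------------------------------------------------------

TEST_CHROM, VAL_CHROM, EXCLUDED_CHROM = "chr9", "chr8", "chrY"


def chromosome_split(subgraphs: list[SignalSubgraph]):
    """chr9 -> test, chr8 -> validation, chrY dropped, the rest train."""
    train, val, test = [], [], []
    for g in subgraphs:
        chrom = g.center.chrom
        if chrom == EXCLUDED_CHROM:
            continue
        (test if chrom == TEST_CHROM else val if chrom == VAL_CHROM
         else train).append(g)
    return train, val, test


class _EncoderProbe(Module):
    """Stage-1 model: shared locus encoder + linear probe to T logits."""

    def __init__(self, cfg: ModelConfig, seed: int):
        super().__init__()
        rng = np.random.default_rng(seed)
        if cfg.feature_mode == "dense":
            self.encoder = self.register("encoder", DenseProjector(cfg, rng))
        else:
            self.encoder = self.register("encoder", SeqEncoder(cfg, rng))
        self.probe = self.register("probe", Linear(cfg.d, cfg.n_profiles, rng))

    def logits(self, feats: np.ndarray) -> Tensor:
        return self.probe(self.encoder(Tensor(feats)))


def _stack_center_data(graphs: list[SignalSubgraph], feature_fn):
    feats = np.stack([feature_fn(g.center, True) for g in graphs])
    labels = np.stack([g.labels for g in graphs])
    mask = np.stack([g.mask for g in graphs])
    return feats, labels, mask


def pretrain_encoder(graphs: list[SignalSubgraph], feature_fn,
                     cfg: ModelConfig, tc: TrainConfig):
    """Stage 1: fit encoder + probe on center nodes, early-stop on val loss.

    Returns (best_state_dict, history); the state dict holds ``encoder.*``
    and ``probe.*`` entries and the encoder part seeds stage 2.
    """
    train, val, _ = chromosome_split(graphs)
    if not train:
        raise ValueError("empty training split")
    model = _EncoderProbe(cfg, tc.seed)
    opt = Adam(model.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed)
    xv, yv, mv = _stack_center_data(val, feature_fn) if val else (None,) * 3
    xt, yt, mt = _stack_center_data(train, feature_fn)
    best = (np.inf, model.state_dict())
    history = []
    bad = 0
    for epoch in range(tc.epochs):
        order = rng.permutation(len(train))
        model.train()
        ep_loss = 0.0
        for lo in range(0, len(order), tc.batch_size):
            idx = order[lo : lo + tc.batch_size]
            xb = xt[idx]
            if tc.augment and xb.ndim == 3:
                xb = augment_windows(xb, rng, tc.max_shift)
            opt.zero_grad()
            loss = masked_bce_loss(model.logits(xb), yt[idx], mt[idx])
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
        model.eval()
        if xv is not None:
            vloss = float(masked_bce_loss(model.logits(xv), yv, mv).data)
        else:
            vloss = ep_loss / len(train)
        history.append({"epoch": epoch, "train_loss": ep_loss / len(train),
                        "val_loss": vloss})
        if vloss < best[0] - 1e-6:
            best = (vloss, model.state_dict())
            bad = 0
        else:
            bad += 1
            if bad >= tc.patience:
                log.info("stage-1 early stop at epoch %d", epoch)
                break
    return best[1], history


def finetune_graph(graphs: list[SignalSubgraph], feature_fn,
                   pretrained_state: dict[str, np.ndarray],
                   cfg: ModelConfig, tc: TrainConfig):
    """Stage 2: end-to-end fine-tuning with early encoder blocks frozen.

    Returns (model, history); the model carries the best-validation weights.
    """
    train, val, _ = chromosome_split(graphs)
    if not train:
        raise ValueError("empty training split")
    model = GraphModel(cfg, seed=tc.seed)
    enc_state = {k.removeprefix("encoder."): v for k, v in pretrained_state.items()
                 if k.startswith("encoder.")}
    model.encoder.load_state_dict(enc_state)
    frozen = {f"encoder.{n}"
              for n in model.encoder.frozen_param_names(cfg.freeze_depth)}
    trainable = {k: p for k, p in model.parameters().items() if k not in frozen}
    opt = Adam(trainable, lr=tc.lr, weight_decay=tc.weight_decay)
    sched = ReduceLROnPlateau(opt, factor=tc.sched_factor,
                              patience=tc.sched_patience, min_lr=tc.min_lr)
    rng = np.random.default_rng(tc.seed)
    best = (np.inf, model.state_dict())
    history = []
    for epoch in range(tc.epochs):
        order = rng.permutation(len(train))
        model.train()
        ep_loss = 0.0
        for lo in range(0, len(order), tc.batch_size):
            batch = [train[i] for i in order[lo : lo + tc.batch_size]]
            labels = np.stack([g.labels for g in batch])
            mask = np.stack([g.mask for g in batch])
            opt.zero_grad()
            res = model.forward_subgraphs(
                batch, feature_fn, labels, mask, rng=rng,
                check_attention=False,
                augment_rng=rng if tc.augment else None,
                max_shift=tc.max_shift)
            res.loss.backward()
            opt.step()
            ep_loss += float(res.loss.data) * len(batch)
        model.eval()
        if val:
            vres = model.forward_subgraphs(
                val, feature_fn, np.stack([g.labels for g in val]),
                np.stack([g.mask for g in val]), check_attention=False)
            vloss = float(vres.loss.data)
        else:
            vloss = ep_loss / len(train)
        history.append({"epoch": epoch, "train_loss": ep_loss / len(train),
                        "val_loss": vloss, "lr": opt.lr})
        sched.step(vloss)
        if vloss < best[0] - 1e-6:
            best = (vloss, model.state_dict())
    model.load_state_dict(best[1])
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _best_f1_threshold(y: np.ndarray, p: np.ndarray) -> float:
    order = np.argsort(-p)
    tp = np.cumsum(y[order])
    k = np.arange(1, len(y) + 1)
    prec = tp / k
    rec = tp / max(y.sum(), 1)
    with np.errstate(invalid="ignore"):
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return float(p[order][f1.argmax()])


def _f1_at(y: np.ndarray, p: np.ndarray, thr: float) -> float:
    yhat = p >= thr
    tp = float((yhat & (y == 1)).sum())
    denom = yhat.sum() + y.sum()
    return 2 * tp / denom if denom else 0.0


def evaluate(predictions: np.ndarray, labels: np.ndarray, mask: np.ndarray,
             val_predictions: np.ndarray | None = None,
             val_labels: np.ndarray | None = None,
             val_mask: np.ndarray | None = None,
             min_positives: int = 30) -> dict:
    """Per-class AUPR/AUROC/F1 and macro aggregates.

    F1 thresholds are optimized per class on the validation arrays (when
    given) and applied to the test arrays.  Macro aggregates cover classes
    with more than ``min_positives`` positive test examples; classes without
    both label values are excluded and logged.
    """
    T = labels.shape[1]
    per_class = []
    for t in range(T):
        sel = mask[:, t] > 0
        y, p = labels[sel, t], predictions[sel, t]
        if y.size == 0 or y.min() == y.max():
            log.info("class %d has a single label value; excluded", t)
            per_class.append(None)
            continue
        thr = 0.5
        if val_predictions is not None:
            vsel = val_mask[:, t] > 0
            yv, pv = val_labels[vsel, t], val_predictions[vsel, t]
            if yv.size and yv.sum() > 0:
                thr = _best_f1_threshold(yv, pv)
        per_class.append({
            "aupr": float(average_precision_score(y, p)),
            "auroc": float(roc_auc_score(y, p)),
            "f1": _f1_at(y, p, thr),
            "threshold": thr,
            "n_positives": int(y.sum()),
        })
    eligible = [c for c in per_class if c and c["n_positives"] > min_positives]
    macro = {f"macro_{k}": float(np.mean([c[k] for c in eligible]))
             for k in ("aupr", "auroc", "f1")} if eligible else {}
    return {"per_class": per_class, **macro,
            "n_eligible_classes": len(eligible)}


def paired_bootstrap_delta(pred_a: np.ndarray, pred_b: np.ndarray,
                           labels: np.ndarray, mask: np.ndarray,
                           metric: str = "aupr", n_boot: int = 200,
                           min_positives: int = 0, seed: int = 0) -> dict:
    """Bootstrap centers; report mean and 95% CI of macro metric(A) - (B)."""
    rng = np.random.default_rng(seed)
    n = labels.shape[0]
    deltas = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ma = evaluate(pred_a[idx], labels[idx], mask[idx],
                      min_positives=min_positives)
        mb = evaluate(pred_b[idx], labels[idx], mask[idx],
                      min_positives=min_positives)
        key = f"macro_{metric}"
        if key in ma and key in mb:
            deltas.append(ma[key] - mb[key])
    deltas = np.asarray(deltas)
    return {"mean": float(deltas.mean()),
            "ci_low": float(np.percentile(deltas, 2.5)),
            "ci_high": float(np.percentile(deltas, 97.5)),
            "n_boot": len(deltas)}
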