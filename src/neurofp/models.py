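"""Deep fingerprinting models: cross-entropy and triplet-loss variants.

Both share a feed-forward backbone (input -> 512 -> 256, each hidden layer
followed by batch normalization and ReLU).  The cross-entropy model
(DLM-CE) adds a linear softmax head with one output per training subject,
casting identification as multi-class classification; it can only rank
subjects seen during training.  The triplet-loss model (DLM-TL) instead
L2-normalizes the 256-unit backbone output and learns a metric space via

    L = sum_i [ ||f(a_i) - f(p_i)||^2 - ||f(a_i) - f(n_i)||^2 + alpha ]_+

over mined triplets (anchor, same-subject positive, different-subject
negative), which generalizes to subjects never seen in training.

Training inputs are generated on the fly: each step draws a fresh random
temporal crop of every selected run and computes its FC fingerprint, so
short segment lengths act as data augmentation.  Runs are bandpass-filtered
once, up front.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import nn
from .connectivity import bandpass, fingerprint
from .core import RoiTimeSeries

__all__ = [
    "ModelConfig",
    "Triplet",
    "EmbeddingSet",
    "CropFCSampler",
    "backbone_forward",
    "triplet_loss",
    "mine_semi_hard",
    "train_dlm_ce",
    "train_dlm_tl",
    "embed",
    "DlmCE",
    "DlmTL",
]

FULL = "full"


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``segment_length_s`` controls the augmentation crop in seconds
    (``"full"`` disables cropping).  ``crops_per_epoch`` is how many fresh
    crops of each training run are drawn per epoch; more crops mean more
    gradient steps per epoch and stronger augmentation.
    """

    input_dim: int
    hidden_1: int = 512
    hidden_2: int = 256
    n_classes: Optional[int] = None  # softmax head only
    margin_alpha: float = 0.2
    batch_size: int = 276
    epochs: int = 50
    learning_rate: float = 1e-3
    segment_length_s: Union[float, str] = FULL
    crops_per_epoch: int = 4
    binary_ce: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_1 < 1 or self.hidden_2 < 1:
            raise ValueError("hidden sizes must be positive")
        if self.margin_alpha <= 0:
            raise ValueError("margin_alpha must be positive")
        if self.n_classes is not None and self.n_classes < 2:
            raise ValueError("softmax head requires at least 2 classes")
        if self.batch_size < 2 or self.epochs < 1 or self.crops_per_epoch < 1:
            raise ValueError("batch_size, epochs, crops_per_epoch must be positive")
        if self.segment_length_s != FULL and float(self.segment_length_s) <= 0:
            raise ValueError("segment_length_s must be positive or 'full'")


@dataclass(frozen=True)
class Triplet:
    """Index triple into a labelled batch: anchor, positive (same label,
    different instance), negative (different label)."""

    anchor: int
    positive: int
    negative: int
    semi_hard: bool  # negative satisfied the strict margin band


@dataclass
class EmbeddingSet:
    """Unit-norm embeddings keyed by (subject_id, run_id[, crop_id])."""

    vectors: dict[tuple, np.ndarray]
    epoch: Optional[int] = None

    def __post_init__(self) -> None:
        for key, v in self.vectors.items():
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"embedding {key} is not unit-norm")

    def matrix(self) -> tuple[np.ndarray, list[str], list[tuple]]:
        keys = sorted(self.vectors.keys())
        mat = np.stack([self.vectors[k] for k in keys])
        subjects = [k[0] for k in keys]
        return mat, subjects, keys

    def __len__(self) -> int:
        return len(self.vectors)


def _build_backbone(cfg: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        [
            nn.Dense(cfg.input_dim, cfg.hidden_1, rng),
            nn.BatchNorm(cfg.hidden_1),
            nn.ReLU(),
            nn.Dense(cfg.hidden_1, cfg.hidden_2, rng),
            nn.BatchNorm(cfg.hidden_2),
            nn.ReLU(),
        ]
    )


def backbone_forward(
    x: np.ndarray, backbone: nn.Sequential, train: bool = False
) -> np.ndarray:
    """Hidden representation (batch, hidden_2) for a batch of FC vectors."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in model input")
    return backbone.forward(x, train=train)


def triplet_loss(
    a: np.ndarray, p: np.ndarray, n: np.ndarray, alpha: float
) -> float:
    """Summed hinge triplet loss over the batch.

    ``sum_i [ ||a_i-p_i||^2 - ||a_i-n_i||^2 + alpha ]_+`` — non-negative,
    zero when every negative is at least ``alpha`` farther (squared) than
    the positive.
    """
    a, p, n = (np.atleast_2d(np.asarray(v, dtype=float)) for v in (a, p, n))
    if not (a.shape == p.shape == n.shape):
        raise ValueError(f"shape mismatch: {a.shape}, {p.shape}, {n.shape}")
    d_ap = ((a - p) ** 2).sum(axis=1)
    d_an = ((a - n) ** 2).sum(axis=1)
    return float(np.maximum(d_ap - d_an + alpha, 0.0).sum())


def _triplet_loss_grads(
    a: np.ndarray, p: np.ndarray, n: np.ndarray, alpha: float
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    d_ap = ((a - p) ** 2).sum(axis=1)
    d_an = ((a - n) ** 2).sum(axis=1)
    hinge = d_ap - d_an + alpha
    active = (hinge > 0).astype(float)[:, None]
    loss = float(np.maximum(hinge, 0.0).sum())
    ga = 2.0 * (n - p) * active
    gp = -2.0 * (a - p) * active
    gn = 2.0 * (a - n) * active
    return loss, ga, gp, gn


def mine_semi_hard(
    embeddings: np.ndarray, labels: Sequence, alpha: float
) -> list[Triplet]:
    """Semi-hard triplet mining over a labelled batch.

    For every ordered same-label pair (a, p), prefer the closest negative
    strictly farther than the positive; when that negative also lies inside
    the margin band ``d_ap < d_an < d_ap + alpha`` it is a semi-hard pick.
    If no negative is farther than the positive, fall back to the hardest
    (closest) negative overall.
    """
    emb = np.atleast_2d(np.asarray(embeddings, dtype=float))
    labels = np.asarray(labels)
    if emb.shape[0] != labels.shape[0]:
        raise ValueError("labels do not match batch size")
    if np.unique(labels).size < 2:
        raise ValueError("mining requires at least 2 distinct labels in the batch")
    sq = (emb**2).sum(axis=1)
    dists = np.maximum(sq[:, None] + sq[None, :] - 2.0 * emb @ emb.T, 0.0)
    triplets: list[Triplet] = []
    for i in range(emb.shape[0]):
        pos_idx = np.flatnonzero((labels == labels[i]) & (np.arange(len(labels)) != i))
        neg_idx = np.flatnonzero(labels != labels[i])
        if pos_idx.size == 0 or neg_idx.size == 0:
            continue
        d_neg = dists[i, neg_idx]
        for j in pos_idx:
            d_ap = dists[i, j]
            farther = d_neg > d_ap
            if farther.any():
                cand = neg_idx[farther]
                k = int(cand[np.argmin(dists[i, cand])])
                semi = d_ap < dists[i, k] < d_ap + alpha
            else:
                k = int(neg_idx[np.argmin(d_neg)])
                semi = False
            triplets.append(Triplet(anchor=i, positive=int(j), negative=k, semi_hard=semi))
    return triplets


class CropFCSampler:
    """On-the-fly crop -> FC input pipeline.

    Holds bandpass-filtered runs; every ``draw`` returns one fresh random
    crop per run as a stacked FC-vector batch with integer labels.  With
    ``segment_length_s="full"`` the (precomputed) full-run fingerprints
    are returned instead.
    """

    def __init__(
        self,
        runs: list[RoiTimeSeries],
        segment_length_s: Union[float, str] = FULL,
        apply_bandpass: bool = True,
        band_hz: tuple[float, float] = (0.01, 0.1),
    ):
        if not runs:
            raise ValueError("no runs given")
        self.runs = [bandpass(ts, *band_hz) if apply_bandpass else ts for ts in runs]
        self.segment_length_s = segment_length_s
        self.subjects = sorted({ts.subject_id for ts in self.runs})
        self.label_of = {s: i for i, s in enumerate(self.subjects)}
        self.labels = np.array([self.label_of[ts.subject_id] for ts in self.runs])
        self._full: Optional[np.ndarray] = None
        if segment_length_s == FULL:
            self._full = np.stack([fingerprint(ts).values for ts in self.runs])

    @property
    def input_dim(self) -> int:
        p = self.runs[0].n_rois
        return p * (p - 1) // 2

    def draw(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        if self._full is not None:
            return self._full, self.labels
        from .connectivity import crop_segment

        batch = []
        for ts in self.runs:
            cropped, _ = crop_segment(ts, float(self.segment_length_s), rng)
            batch.append(fingerprint(cropped).values)
        return np.stack(batch), self.labels


@dataclass
class DlmCE:
    """Trained cross-entropy fingerprinting classifier."""

    backbone: nn.Sequential
    head: nn.Dense
    subjects: list[str]
    config: ModelConfig
    loss_trace: list[float] = field(default_factory=list)

    def logits(self, x: np.ndarray) -> np.ndarray:
        h = backbone_forward(x, self.backbone, train=False)
        return self.head.forward(h, train=False)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(x))

    def predict(self, x: np.ndarray) -> list[str]:
        idx = np.argmax(self.logits(x), axis=1)
        return [self.subjects[i] for i in idx]


@dataclass
class DlmTL:
    """Trained triplet-loss encoder."""

    backbone: nn.Sequential
    config: ModelConfig
    loss_trace: list[float] = field(default_factory=list)
    val_loss_trace: list[float] = field(default_factory=list)
    best_epoch: Optional[int] = None

    def encode(self, x: np.ndarray) -> np.ndarray:
        h = backbone_forward(x, self.backbone, train=False)
        norm = np.sqrt((h * h).sum(axis=1, keepdims=True))
        # a fully-rectified (all-zero) representation has no direction;
        # map it to a fixed point on the sphere instead of dividing by ~0
        dead = norm[:, 0] < 1e-8
        if dead.any():
            h = h.copy()
            h[dead, 0] = 1.0
            norm = np.sqrt((h * h).sum(axis=1, keepdims=True))
        return h / norm


def _batches(
    n: int, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def _subject_batches(
    labels: np.ndarray, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Batches that keep all instances of a subject together, so every
    subject in a batch has >= 2 instances (required by triplet mining)."""
    by_label: dict[int, np.ndarray] = {
        lab: np.flatnonzero(labels == lab) for lab in np.unique(labels)
    }
    if any(idx.size < 2 for idx in by_label.values()):
        bad = [lab for lab, idx in by_label.items() if idx.size < 2]
        raise ValueError(f"subjects {bad} have fewer than 2 instances in the batch pool")
    label_order = rng.permutation(list(by_label.keys()))
    batches: list[np.ndarray] = []
    current: list[np.ndarray] = []
    size = 0
    for lab in label_order:
        idx = by_label[lab]
        if current and size + idx.size > batch_size:
            batches.append(np.concatenate(current))
            current, size = [], 0
        current.append(idx)
        size += idx.size
    if current:
        # a trailing single-subject batch has no negatives; merge it back
        if len(current) == 1 and batches:
            batches[-1] = np.concatenate([batches[-1], current[0]])
        else:
            batches.append(np.concatenate(current))
    return batches


def train_dlm_ce(
    runs: list[RoiTimeSeries],
    cfg: ModelConfig,
    rng: np.random.Generator,
    apply_bandpass: bool = True,
) -> DlmCE:
    """Train the softmax classifier with on-the-fly crop augmentation.

    Every epoch draws ``crops_per_epoch`` fresh crops of each training run
    and performs mini-batch Adam steps on the categorical cross-entropy
    (per-class binary cross-entropy when ``cfg.binary_ce``).
    """
    sampler = CropFCSampler(runs, cfg.segment_length_s, apply_bandpass)
    n_classes = len(sampler.subjects)
    if cfg.n_classes is not None and cfg.n_classes != n_classes:
        raise ValueError(
            f"config says {cfg.n_classes} classes but data has {n_classes} subjects"
        )
    counts = np.bincount(sampler.labels, minlength=n_classes)
    if (counts == 0).any():
        raise ValueError("a class has no training samples")
    init_rng = np.random.default_rng(cfg.seed)
    backbone = _build_backbone(cfg, init_rng)
    head = nn.Dense(cfg.hidden_2, n_classes, init_rng)
    opt = nn.Adam(backbone.params() + head.params(), lr=cfg.learning_rate)
    trace: list[float] = []
    for _epoch in range(cfg.epochs):
        epoch_losses = []
        for _ in range(cfg.crops_per_epoch):
            x, y = sampler.draw(rng)
            for idx in _batches(len(y), cfg.batch_size, rng):
                h = backbone.forward(x[idx], train=True)
                logits = head.forward(h, train=True)
                loss, dlogits = nn.cross_entropy(logits, y[idx], binary=cfg.binary_ce)
                backbone.backward(head.backward(dlogits))
                opt.step(backbone.grads() + head.grads())
                epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))
    return DlmCE(
        backbone=backbone,
        head=head,
        subjects=sampler.subjects,
        config=cfg,
        loss_trace=trace,
    )


def _tl_epoch_loss(
    backbone: nn.Sequential,
    l2: nn.L2Normalize,
    x: np.ndarray,
    y: np.ndarray,
    alpha: float,
    train: bool,
) -> tuple[float, Optional[tuple]]:
    h = backbone.forward(x, train=train)
    emb = l2.forward(h, train=train)
    triplets = mine_semi_hard(emb, y, alpha)
    if not triplets:
        return 0.0, None
    ai = np.array([t.anchor for t in triplets])
    pi = np.array([t.positive for t in triplets])
    ni = np.array([t.negative for t in triplets])
    loss, ga, gp, gn = _triplet_loss_grads(emb[ai], emb[pi], emb[ni], alpha)
    loss /= len(triplets)
    if not train:
        return loss, None
    gemb = np.zeros_like(emb)
    np.add.at(gemb, ai, ga / len(triplets))
    np.add.at(gemb, pi, gp / len(triplets))
    np.add.at(gemb, ni, gn / len(triplets))
    return loss, (gemb,)


def train_dlm_tl(
    runs: list[RoiTimeSeries],
    cfg: ModelConfig,
    rng: np.random.Generator,
    val_runs: Optional[list[RoiTimeSeries]] = None,
    apply_bandpass: bool = True,
) -> DlmTL:
    """Train the triplet-loss encoder with semi-hard mining.

    Batches keep every subject's instances together so each anchor has a
    positive.  When ``val_runs`` is given, a validation triplet loss on
    full-length fingerprints is tracked per epoch and the weights from the
    best epoch are restored at the end.
    """
    sampler = CropFCSampler(runs, cfg.segment_length_s, apply_bandpass)
    if len(sampler.subjects) < 2:
        raise ValueError("triplet training requires at least 2 subjects")
    init_rng = np.random.default_rng(cfg.seed)
    backbone = _build_backbone(cfg, init_rng)
    l2 = nn.L2Normalize()
    opt = nn.Adam(backbone.params(), lr=cfg.learning_rate)
    val_sampler = (
        CropFCSampler(val_runs, FULL, apply_bandpass) if val_runs else None
    )
    trace: list[float] = []
    val_trace: list[float] = []
    best_epoch: Optional[int] = None
    best_state: Optional[list[np.ndarray]] = None
    best_val = np.inf
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for _ in range(cfg.crops_per_epoch):
            x, y = sampler.draw(rng)
            for idx in _subject_batches(y, cfg.batch_size, rng):
                if np.unique(y[idx]).size < 2:
                    continue
                loss, grads = _tl_epoch_loss(
                    backbone, l2, x[idx], y[idx], cfg.margin_alpha, train=True
                )
                if grads is None:
                    continue
                backbone.backward(l2.backward(grads[0]))
                opt.step(backbone.grads())
                epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)) if epoch_losses else 0.0)
        if val_sampler is not None:
            xv, yv = val_sampler.draw(rng)
            hv = backbone.forward(xv, train=False)
            ev = hv / (np.sqrt((hv * hv).sum(axis=1, keepdims=True)) + 1e-12)
            vt = mine_semi_hard(ev, yv, cfg.margin_alpha)
            if vt:
                ai = np.array([t.anchor for t in vt])
                pi = np.array([t.positive for t in vt])
                ni = np.array([t.negative for t in vt])
                vloss = triplet_loss(ev[ai], ev[pi], ev[ni], cfg.margin_alpha) / len(vt)
            else:
                vloss = 0.0
            val_trace.append(vloss)
            if vloss < best_val:
                best_val = vloss
                best_epoch = epoch
                best_state = [p.copy() for p in backbone.params()]
    model = DlmTL(
        backbone=backbone,
        config=cfg,
        loss_trace=trace,
        val_loss_trace=val_trace,
        best_epoch=best_epoch,
    )
    if best_state is not None:
        for p, saved in zip(backbone.params(), best_state):
            p[...] = saved
    return model


def embed(
    model: DlmTL,
    runs: list[RoiTimeSeries],
    segment_length_s: Union[float, str] = FULL,
    rng: Optional[np.random.Generator] = None,
    n_crops: int = 1,
    apply_bandpass: bool = True,
) -> EmbeddingSet:
    """Unit-norm embeddings per (subject, run[, crop]).

    Full-length fingerprints by default; with a finite segment length,
    ``n_crops`` random crops per run are embedded (keys gain a crop index)
    using the supplied ``rng``.
    """
    from .connectivity import crop_segment

    vectors: dict[tuple, np.ndarray] = {}
    prepared = [bandpass(ts) if apply_bandpass else ts for ts in runs]
    if segment_length_s == FULL:
        x = np.stack([fingerprint(ts).values for ts in prepared])
        emb = model.encode(x)
        for ts, e in zip(prepared, emb):
            vectors[(ts.subject_id, ts.run_id)] = e
    else:
        if rng is None:
            raise ValueError("cropped embedding needs an rng")
        batch, keys = [], []
        for ts in prepared:
            for c in range(n_crops):
                cropped, _ = crop_segment(ts, float(segment_length_s), rng)
                batch.append(fingerprint(cropped).values)
                keys.append((ts.subject_id, ts.run_id, c))
        emb = model.encode(np.stack(batch))
        vectors = dict(zip(keys, emb))
    return EmbeddingSet(vectors=vectors, epoch=model.best_epoch)


def clone_model(model: DlmTL) -> DlmTL:
    """Deep copy (useful for snapshotting weights across epochs)."""
    return copy.deepcopy(model)
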