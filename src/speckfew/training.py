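"""Triplet-loss training with mini-batch semi-hard negative mining.

A triplet is (anchor, positive, negative): anchor and positive share a hit
class, the negative does not. With unit-norm embeddings the squared L2
distance between any two embeddings lies in [0, 4], so the margin alpha is
bounded by 4. The loss per triplet is

    L = max(0, d(a,p) - d(a,n) + alpha)

with d the squared L2 distance. Negatives are classified by difficulty:
*hard* when d(a,n) <= d(a,p), *easy* when d(a,n) >= d(a,p) + alpha (zero
loss, zero gradient), and *semi-hard* in between. Training mines semi-hard
triplets within each mini-batch; when several single-particle samples are
present, the anchor and positive are drawn from the same sample (the
multi-sample scheme), while the negative may come from any sample with a
different label.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import Embedder
from .simulator import SpecklePattern

logger = logging.getLogger(__name__)

__all__ = [
    "Triplet",
    "TrainConfig",
    "pairwise_sq_dists",
    "triplet_loss",
    "classify_triplet_difficulty",
    "select_semihard_triplets",
    "fit",
]

EASY, SEMI_HARD, HARD = "easy", "semi_hard", "hard"


@dataclass(frozen=True)
class Triplet:
    anchor_idx: int
    positive_idx: int
    negative_idx: int

    def validate(self, labels: np.ndarray) -> None:
        if self.anchor_idx == self.positive_idx:
            raise ValueError("anchor and positive must be distinct examples")
        if labels[self.anchor_idx] != labels[self.positive_idx]:
            raise ValueError("anchor and positive must share a label")
        if labels[self.anchor_idx] == labels[self.negative_idx]:
            raise ValueError("negative must have a different label")


@dataclass
class TrainConfig:
    alpha: float = 0.2  # margin, squared-L2 units
    lr: float = 1e-3
    batch_size: int = 48
    epochs: int = 10
    triplets_per_batch: int = 48
    seed: int = 0
    sample_aware: bool = True  # anchor/positive from the same sample
    val_triplets: int = 256

    def __post_init__(self):
        if not 0 < self.alpha <= 4:
            raise ValueError("alpha must lie in (0, 4] (unit-sphere bound)")
        if self.lr < 0:
            raise ValueError("learning rate must be non-negative")


def pairwise_sq_dists(embeddings: np.ndarray) -> np.ndarray:
    """All-pairs squared L2 distances, shape (M, M); for unit vectors every
    entry lies in [0, 4]."""
    z = np.asarray(embeddings, dtype=np.float64)
    sq = (z * z).sum(axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (z @ z.T)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def triplet_loss(d_ap: float | np.ndarray, d_an: float | np.ndarray,
                 alpha: float) -> float | np.ndarray:
    """Hinge triplet loss max(0, d_ap - d_an + alpha) on squared distances."""
    return np.maximum(0.0, d_ap - d_an + alpha)


def classify_triplet_difficulty(d_ap: float, d_an: float, alpha: float) -> str:
    """Difficulty class of a negative. Boundary ties (d_an == d_ap or
    d_an == d_ap + alpha) are assigned to semi-hard, so the semi-hard band
    is the closed interval [d_ap, d_ap + alpha]."""
    if d_an < d_ap:
        return HARD
    if d_an > d_ap + alpha:
        return EASY
    return SEMI_HARD


def _candidate_pairs(labels: np.ndarray, sample_ids: np.ndarray | None,
                     sample_aware: bool) -> list[tuple[int, int]]:
    n = len(labels)
    pairs = []
    for a in range(n):
        for p in range(n):
            if a == p or labels[a] != labels[p]:
                continue
            if sample_aware and sample_ids is not None and \
                    sample_ids[a] != sample_ids[p]:
                continue
            pairs.append((a, p))
    return pairs


def select_semihard_triplets(
    embeddings: np.ndarray,
    labels: np.ndarray,
    sample_ids: np.ndarray | None,
    alpha: float,
    n_triplets: int,
    seed: int,
    sample_aware: bool = True,
) -> tuple[list[Triplet], int]:
    """Randomly select up to ``n_triplets`` semi-hard triplets in the batch.

    A triplet qualifies when d_ap < d_an < d_ap + alpha on the given
    embeddings, with the anchor/positive drawn from the same sample (when
    ``sample_aware``) and the negative from any sample of another label.
    When an anchor/positive pair has no semi-hard negative the fallback
    picks the easiest hard negative (largest d_an among d_an <= d_ap); a
    random valid-label negative is the last resort. Returns the triplets and
    the number of fallback events (logged).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("semi-hard selection needs at least two classes")
    if sample_ids is not None:
        sample_ids = np.asarray(sample_ids)
    rng = np.random.default_rng(seed)
    d = pairwise_sq_dists(embeddings)
    pairs = _candidate_pairs(labels, sample_ids, sample_aware)
    if not pairs:
        raise ValueError(
            "no anchor/positive pair satisfies the same-sample, same-label rule"
        )
    triplets: list[Triplet] = []
    n_fallback = 0
    pair_order = rng.integers(0, len(pairs), size=n_triplets)
    for k in pair_order:
        a, p = pairs[k]
        neg_mask = labels != labels[a]
        negs = np.flatnonzero(neg_mask)
        d_ap = d[a, p]
        d_an = d[a, negs]
        semi = negs[(d_an > d_ap) & (d_an < d_ap + alpha)]
        if len(semi):
            n = int(rng.choice(semi))
        else:
            n_fallback += 1
            hard = negs[d_an <= d_ap]
            if len(hard):
                n = int(hard[np.argmax(d[a, hard])])  # easiest hard negative
            else:
                n = int(rng.choice(negs))
        t = Triplet(a, p, n)
        t.validate(labels)
        triplets.append(t)
    if n_fallback:
        logger.debug("semi-hard fallback used for %d/%d triplets",
                     n_fallback, n_triplets)
    return triplets, n_fallback


def _triplet_loss_and_grad(z: np.ndarray, triplets: list[Triplet],
                           alpha: float) -> tuple[float, np.ndarray]:
    """Mean triplet loss over the batch and its gradient w.r.t. the
    (already normalized) embeddings."""
    grad = np.zeros_like(z)
    total = 0.0
    for t in triplets:
        za, zp, zn = z[t.anchor_idx], z[t.positive_idx], z[t.negative_idx]
        d_ap = float(((za - zp) ** 2).sum())
        d_an = float(((za - zn) ** 2).sum())
        loss = d_ap - d_an + alpha
        if loss > 0:
            total += loss
            grad[t.anchor_idx] += 2.0 * (zn - zp)
            grad[t.positive_idx] += -2.0 * (za - zp)
            grad[t.negative_idx] += 2.0 * (za - zn)
    m = max(len(triplets), 1)
    return total / m, (grad / m).astype(np.float32)


def _stack(patterns: list[SpecklePattern]):
    images = np.stack([p.image for p in patterns]).astype(np.float32)
    labels = np.array([p.label for p in patterns])
    samples = np.array([p.sample_id for p in patterns])
    return images, labels, samples


def _stratified_batches(labels: np.ndarray, sample_ids: np.ndarray,
                        batch_size: int, rng: np.random.Generator):
    """Batches stratified by (label, sample) so the same-sample
    anchor/positive rule is satisfiable in every batch."""
    groups: dict[tuple[str, str], list[int]] = {}
    for i, (lab, sid) in enumerate(zip(labels, sample_ids)):
        groups.setdefault((str(lab), str(sid)), []).append(i)
    keys = sorted(groups)
    for key in keys:
        rng.shuffle(groups[key])
    n = len(labels)
    per_group = max(2, batch_size // len(keys))
    cursors = {k: 0 for k in keys}
    n_batches = max(1, n // batch_size)
    for _ in range(n_batches):
        batch: list[int] = []
        for key in keys:
            g = groups[key]
            c = cursors[key]
            take = g[c: c + per_group]
            if len(take) < min(per_group, 2):  # wrap to keep pairs available
                cursors[key] = 0
                take = g[:per_group]
                cursors[key] = len(take)
            else:
                cursors[key] = c + len(take)
            batch.extend(take)
        yield np.array(batch)


def _random_val_triplets(labels: np.ndarray, n: int,
                         rng: np.random.Generator) -> list[Triplet]:
    """Random (selector-independent) triplets for validation loss."""
    classes = np.unique(labels)
    by_class = {c: np.flatnonzero(labels == c) for c in classes}
    usable = [c for c in classes if len(by_class[c]) >= 2]
    triplets = []
    for _ in range(n):
        c = rng.choice(usable)
        a, p = rng.choice(by_class[c], size=2, replace=False)
        others = np.flatnonzero(labels != c)
        neg = rng.choice(others)
        triplets.append(Triplet(int(a), int(p), int(neg)))
    return triplets


def fit(
    embedder: Embedder,
    train_patterns: list[SpecklePattern],
    val_patterns: list[SpecklePattern],
    config: TrainConfig | None = None,
    history_path: str | None = None,
) -> tuple[Embedder, list[dict]]:
    """Train the embedder with Adam on mined semi-hard triplets.

    Per batch: embeddings are computed in inference mode for triplet
    selection, then recomputed in training mode for the loss/backward pass.
    Validation uses random triplets so the metric is independent of the
    mining policy. The best-validation-loss parameters are restored at the
    end. Returns the embedder and a per-epoch history
    (epoch, train_loss, val_loss, n_fallbacks).
    """
    config = config or TrainConfig()
    train_images, train_labels, train_samples = _stack(train_patterns)
    val_images, val_labels, _ = _stack(val_patterns)
    train_classes = set(train_labels.tolist())
    if len(train_classes) < 2:
        raise ValueError("training set needs at least two classes")
    missing = train_classes - set(val_labels.tolist())
    if missing:
        raise ValueError(f"validation set missing classes: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(embedder.net, lr=config.lr)
    val_trip = _random_val_triplets(
        val_labels, config.val_triplets, np.random.default_rng(config.seed + 1)
    )
    history: list[dict] = []
    best_val = np.inf
    best_state = embedder.state()
    for epoch in range(config.epochs):
        epoch_losses = []
        n_fallbacks = 0
        for batch_idx in _stratified_batches(
            train_labels, train_samples, config.batch_size, rng
        ):
            x = train_images[batch_idx]
            z_sel = embedder.embed(x, train=False)
            triplets, nf = select_semihard_triplets(
                z_sel, train_labels[batch_idx], train_samples[batch_idx],
                config.alpha, config.triplets_per_batch,
                seed=int(rng.integers(0, 2**31 - 1)),
                sample_aware=config.sample_aware,
            )
            n_fallbacks += nf
            z = embedder.embed(x, train=True)
            loss, dz = _triplet_loss_and_grad(z, triplets, config.alpha)
            embedder.net.backward(dz)
            optimizer.step()
            epoch_losses.append(loss)
        z_val = embedder.embed(val_images, train=False)
        val_loss = float(np.mean([
            triplet_loss(
                ((z_val[t.anchor_idx] - z_val[t.positive_idx]) ** 2).sum(),
                ((z_val[t.anchor_idx] - z_val[t.negative_idx]) ** 2).sum(),
                config.alpha,
            )
            for t in val_trip
        ]))
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "n_fallbacks": n_fallbacks,
        }
        history.append(row)
        logger.info("epoch %d train %.4f val %.4f fallbacks %d",
                    epoch, row["train_loss"], val_loss, n_fallbacks)
        if val_loss < best_val:
            best_val = val_loss
            best_state = embedder.state()
    embedder.load_state(best_state)
    if history_path is not None:
        with open(history_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", "train_loss", "val_loss", "n_fallbacks"]
            )
            writer.writeheader()
            writer.writerows(history)
    return embedder, history


def fit_binary_baseline(
    baseline,
    train_patterns: list[SpecklePattern],
    val_patterns: list[SpecklePattern],
    epochs: int = 10,
    lr: float = 1e-3,
    batch_size: int = 48,
    seed: int = 0,
) -> tuple[object, list[dict]]:
    """Train the binary single-hit baseline with cross-entropy on relabeled
    (single vs non-single) targets."""
    from .evaluation import relabel_binary
    from .simulator import SINGLE_HIT

    images, labels, _ = _stack(train_patterns)
    y = (np.array(relabel_binary(list(labels))) == SINGLE_HIT).astype(np.float32)
    val_images, val_labels, _ = _stack(val_patterns)
    y_val = (np.array(relabel_binary(list(val_labels))) == SINGLE_HIT).astype(
        np.float32
    )
    rng = np.random.default_rng(seed)
    optimizer = nn.Adam(baseline.net, lr=lr)
    history = []
    best_val = np.inf
    best_state = baseline.state()
    for epoch in range(epochs):
        order = rng.permutation(len(images))
        losses = []
        for start in range(0, len(order) - 1, batch_size):
            idx = order[start: start + batch_size]
            if len(idx) < 2:
                continue
            logits = baseline.logits(images[idx], train=True)
            prob = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
            eps = 1e-7
            loss = float(np.mean(
                -(y[idx] * np.log(prob + eps) + (1 - y[idx]) * np.log(1 - prob + eps))
            ))
            dlogit = ((prob - y[idx]) / len(idx)).astype(np.float32)
            baseline.net.backward(dlogit[:, None])
            optimizer.step()
            losses.append(loss)
        prob_val = baseline.predict_proba(val_images)
        eps = 1e-7
        val_loss = float(np.mean(
            -(y_val * np.log(prob_val + eps) + (1 - y_val) * np.log(1 - prob_val + eps))
        ))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = baseline.state()
    baseline.load_state(best_state)
    return baseline, history
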