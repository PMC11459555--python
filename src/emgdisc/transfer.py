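"""Fine-tuning a cross-user temporal model to a new user.

Two procedures, both with the recurrent (temporal) block frozen so only the
linear head moves, tuned for 400 epochs with initial learning rate 1e-2 and a
step scheduler (step 25, gamma 0.9), keeping the best-validation iterate:

* **Traditional transfer** — tune the head with cross-entropy on the new
  user's labeled templates; the prediction interface is unchanged.
* **Contrastive transfer** — tune the head so the new user's embeddings move
  toward the *fixed* per-class centroids of the cross-user embedding space,
  minimizing  sum_i ||g_i - c_{label(i)}||_2 ; classification then happens in
  the embedding space with a k-nearest-neighbour vote over the transferred
  user's own templates (k = repetitions per gesture).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import DiscretePrediction
from .dataio import GestureTemplate
from .nn import Adam, StepLR, softmax_cross_entropy
from .temporal import TemporalNet, _pad_batch, embed_batch

__all__ = [
    "TransferConfig",
    "freeze_temporal",
    "transfer_traditional",
    "compute_centroids",
    "contrastive_loss",
    "transfer_contrastive",
    "CentroidKNN",
]


@dataclass(frozen=True)
class TransferConfig:
    """Head fine-tuning schedule (shared by both procedures)."""

    epochs: int = 400
    lr: float = 1e-2
    scheduler_step: int = 25
    scheduler_gamma: float = 0.9
    seed: int = 0


def freeze_temporal(net: TemporalNet) -> TemporalNet:
    """Mark the recurrent block immutable; only head parameters train."""
    if not net.trained:
        raise RuntimeError("model is not trained")
    net.frozen_temporal = True
    return net


def _clone(net: TemporalNet) -> TemporalNet:
    out = TemporalNet(net.config, net.classes, net.input_dim, net.pad_length)
    out.state_restore(net.state_copy())
    out.standardizer = net.standardizer
    out.trained = net.trained
    out.frozen_temporal = net.frozen_temporal
    return out


def _split_validation(
    templates: list[GestureTemplate],
) -> tuple[list[GestureTemplate], list[GestureTemplate]]:
    """Hold out a single repetition (the highest rep index) per class."""
    by_class: dict[str, list[GestureTemplate]] = {}
    for t in templates:
        by_class.setdefault(t.label, []).append(t)
    train, val = [], []
    for ts in by_class.values():
        ts = sorted(ts, key=lambda t: t.rep)
        if len(ts) > 1:
            train.extend(ts[:-1])
            val.append(ts[-1])
        else:
            train.extend(ts)
            val.extend(ts)
    return train, val


def transfer_traditional(
    net: TemporalNet,
    batch: list[GestureTemplate],
    config: TransferConfig = TransferConfig(),
) -> tuple[TemporalNet, dict]:
    """Cross-entropy head tuning on the new user's templates.

    Returns a tuned copy of the model (the input model is untouched) plus the
    tuning history; the best-validation-accuracy iterate is kept.
    """
    if not batch:
        raise ValueError("empty transfer batch")
    net = freeze_temporal(_clone(net))
    train, val = _split_validation(batch)
    idx_of = {c: i for i, c in enumerate(net.classes)}
    seqs = [net.prepare(t) for t in train]
    y = np.array([idx_of[t.label] for t in train])
    X, lengths = _pad_batch(seqs)
    val_seqs = [net.prepare(t) for t in val]
    Xv, lv = _pad_batch(val_seqs)
    yv = np.array([idx_of[t.label] for t in val])

    # the recurrent block is frozen: its states are computed once
    H = net.temporal_forward(X, lengths)
    Hv = net.temporal_forward(Xv, lv)
    opt = Adam(net.head_layers, lr=config.lr)
    sched = StepLR(opt, config.scheduler_step, config.scheduler_gamma)
    history = {"loss": [], "val_acc": []}
    best = (-1.0, None)
    for epoch in range(config.epochs):
        sched.at_epoch(epoch)
        logits, _ = net.head_forward(H)
        loss, dlogits = softmax_cross_entropy(logits, y)
        opt.zero_grad()
        net.head_backward(dlogits)
        opt.step()
        vlogits, _ = net.head_forward(Hv)
        val_acc = float(np.mean(np.argmax(vlogits, axis=1) == yv))
        history["loss"].append(loss)
        history["val_acc"].append(val_acc)
        if val_acc > best[0]:
            best = (val_acc, net.state_copy())
    if best[1] is not None:
        net.state_restore(best[1])
    return net, history


def compute_centroids(
    net: TemporalNet, templates: list[GestureTemplate]
) -> dict[str, np.ndarray]:
    """Per-class mean embedding over the cross-user training templates."""
    by_class: dict[str, list[GestureTemplate]] = {}
    for t in templates:
        by_class.setdefault(t.label, []).append(t)
    missing = set(net.classes) - set(by_class)
    if missing:
        raise ValueError(f"no templates for classes {sorted(missing)}")
    out = {}
    for label in sorted(by_class):
        embs = embed_batch(net, by_class[label])
        out[label] = embs.mean(axis=0)
    return out


def contrastive_loss(
    embeddings: np.ndarray,
    labels: list[str],
    centroids: dict[str, np.ndarray],
) -> float:
    """Sum over templates of the Euclidean distance to the class centroid."""
    missing = set(labels) - set(centroids)
    if missing:
        raise ValueError(f"missing centroids for {sorted(missing)}")
    total = 0.0
    for g, label in zip(np.atleast_2d(embeddings), labels):
        total += float(np.linalg.norm(g - centroids[label]))
    return total


class CentroidKNN:
    """kNN predictor in the transferred embedding space.

    Stores the transfer batch's embeddings; predicts by unweighted majority
    vote among the k nearest (Euclidean) stored embeddings, confidence =
    neighbour-vote fractions, ties toward the lowest class index.
    """

    def __init__(
        self,
        net: TemporalNet,
        templates: list[GestureTemplate],
        k: int,
    ):
        counts: dict[str, int] = {}
        for t in templates:
            counts[t.label] = counts.get(t.label, 0) + 1
        if k > min(counts.values()):
            raise ValueError(
                f"k={k} exceeds the available templates per class "
                f"(min {min(counts.values())})"
            )
        self.net = net
        self.k = k
        self.classes = net.classes
        self.embeddings = embed_batch(net, templates)
        self.labels = [t.label for t in templates]

    def predict(self, template: GestureTemplate) -> DiscretePrediction:
        g = embed_batch(self.net, [template])[0]
        d = np.linalg.norm(self.embeddings - g, axis=1)
        nearest = np.argsort(d, kind="stable")[: self.k]
        votes = np.array(
            [sum(1 for i in nearest if self.labels[i] == c)
             for c in self.classes],
            dtype=float,
        )
        label = self.classes[int(np.argmax(votes))]
        return DiscretePrediction(label, self.classes, votes / votes.sum())


def transfer_contrastive(
    net: TemporalNet,
    batch: list[GestureTemplate],
    centroids: dict[str, np.ndarray],
    k: int | None = None,
    config: TransferConfig = TransferConfig(),
) -> tuple[TemporalNet, CentroidKNN, dict]:
    """Head tuning toward fixed cross-user centroids, then kNN prediction.

    The centroids are anchors and are never updated.  ``k`` defaults to the
    number of repetitions per gesture in the batch.  Returns the tuned model,
    the kNN predictor over the transferred batch embeddings, and the history
    (per-epoch training loss and validation loss on the held-out repetition).
    """
    if not batch:
        raise ValueError("empty transfer batch")
    missing = {t.label for t in batch} - set(centroids)
    if missing:
        raise ValueError(f"missing centroids for {sorted(missing)}")
    net = freeze_temporal(_clone(net))
    train, val = _split_validation(batch)
    seqs = [net.prepare(t) for t in train]
    labels = [t.label for t in train]
    X, lengths = _pad_batch(seqs)
    C = np.stack([centroids[l] for l in labels])
    Xv, lv = _pad_batch([net.prepare(t) for t in val])
    Cv = np.stack([centroids[t.label] for t in val])

    # the recurrent block is frozen: its states are computed once
    H = net.temporal_forward(X, lengths)
    Hv = net.temporal_forward(Xv, lv)
    opt = Adam(net.head_layers, lr=config.lr)
    sched = StepLR(opt, config.scheduler_step, config.scheduler_gamma)
    history = {"loss": [], "val_loss": []}
    best = (np.inf, None)
    for epoch in range(config.epochs):
        sched.at_epoch(epoch)
        _, emb = net.head_forward(H)
        diff = emb - C
        dist = np.linalg.norm(diff, axis=1)
        loss = float(dist.sum())
        # d/dg ||g - c|| = (g - c) / ||g - c||
        demb = diff / np.maximum(dist, 1e-12)[:, None]
        opt.zero_grad()
        net.head_backward(None, demb=demb)
        opt.step()
        _, embv = net.head_forward(Hv)
        val_loss = float(np.linalg.norm(embv - Cv, axis=1).sum())
        history["loss"].append(loss)
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, net.state_copy())
    if best[1] is not None:
        net.state_restore(best[1])
    if k is None:
        counts: dict[str, int] = {}
        for t in batch:
            counts[t.label] = counts.get(t.label, 0) + 1
        k = min(counts.values())
    knn = CentroidKNN(net, batch, k)
    return net, knn, history
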