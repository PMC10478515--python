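"""N-way X-shot classification against a labeled support set.

Classification takes four steps: (1) embed the query and all support
patterns on the unit hypersphere, (2) compute the query-to-support
Euclidean distances, (3) average distances within each class, (4) predict
the class with the smallest average distance. Plain (unsquared) Euclidean
distance is the default for step 3; squared distance is available via
``squared=True`` (the two can rank classes differently once averaged).
Ties break to the lexicographically smallest label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Embedder
from .simulator import SpecklePattern

__all__ = ["SupportSet", "ClassificationResult", "classify", "batch_classify",
           "build_support"]


@dataclass
class SupportSet:
    """Per-class labeled support embeddings (X unit vectors per class)."""

    embeddings: dict[str, np.ndarray]  # label -> (X, d)
    provenance: dict[str, list[str]] | None = None

    def __post_init__(self):
        if len(self.embeddings) < 2:
            raise ValueError("support set needs at least two classes")
        for label, emb in self.embeddings.items():
            emb = np.atleast_2d(np.asarray(emb, dtype=np.float64))
            if emb.shape[0] < 1:
                raise ValueError(f"support class {label!r} is empty")
            norms = np.linalg.norm(emb, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-4):
                raise ValueError(f"support embeddings for {label!r} not unit norm")
            self.embeddings[label] = emb

    @property
    def classes(self) -> list[str]:
        return sorted(self.embeddings)


@dataclass
class ClassificationResult:
    predicted_label: str
    per_class_mean_distance: dict[str, float]
    per_support_distance: dict[str, np.ndarray]


def classify(query_embedding: np.ndarray, support: SupportSet,
             squared: bool = False) -> ClassificationResult:
    """Predict the class whose supports are closest on average to the query."""
    q = np.asarray(query_embedding, dtype=np.float64).ravel()
    if not np.isclose(np.linalg.norm(q), 1.0, atol=1e-4):
        raise ValueError("query embedding must be unit norm")
    per_support: dict[str, np.ndarray] = {}
    per_class: dict[str, float] = {}
    for label in support.classes:
        diffs = support.embeddings[label] - q
        d = (diffs**2).sum(axis=1)
        if not squared:
            d = np.sqrt(d)
        per_support[label] = d
        per_class[label] = float(d.mean())
    # argmin with lexicographic tie-break: sorted() orders labels, min is stable
    predicted = min(support.classes, key=lambda c: (per_class[c], c))
    return ClassificationResult(
        predicted_label=predicted,
        per_class_mean_distance=per_class,
        per_support_distance=per_support,
    )


def batch_classify(queries: np.ndarray, support: SupportSet,
                   squared: bool = False) -> list[ClassificationResult]:
    """Elementwise :func:`classify` over an (N, d) query array."""
    queries = np.atleast_2d(np.asarray(queries))
    if queries.size == 0:
        return []
    return [classify(q, support, squared=squared) for q in queries]


def build_support(patterns: list[SpecklePattern], x_shot: int,
                  embedder: Embedder, seed: int) -> tuple[SupportSet, set[int]]:
    """Sample ``x_shot`` patterns per class without replacement and embed
    them. Returns the support set and the indices of the chosen patterns
    (so callers can exclude them from the query pool)."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, p in enumerate(patterns):
        by_class.setdefault(p.label, []).append(i)
    embeddings: dict[str, np.ndarray] = {}
    provenance: dict[str, list[str]] = {}
    used: set[int] = set()
    for label in sorted(by_class):
        idxs = by_class[label]
        if len(idxs) < x_shot:
            raise ValueError(
                f"class {label!r} has {len(idxs)} patterns, fewer than the "
                f"requested {x_shot} shots"
            )
        chosen = rng.choice(idxs, size=x_shot, replace=False)
        images = np.stack([patterns[int(i)].image for i in chosen])
        embeddings[label] = embedder(images)
        provenance[label] = [patterns[int(i)].source_id for i in chosen]
        used.update(int(i) for i in chosen)
    return SupportSet(embeddings=embeddings, provenance=provenance), used
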