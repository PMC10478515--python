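"""Evaluation protocols: metrics, fluence scan, detector-area ablation.

The fluence scan rescales the noise-free test patterns by a grid of factors
(emulating shot-to-shot changes in delivered photons) before shot noise and
normalization, then measures N-way X-shot accuracy/F1 at each factor and
shot count. The detector ablation masks a contiguous region of every crop
(queries and supports alike) and compares the embedding few-shot classifier
against the probability-threshold binary baseline on the same masked
inputs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from . import fewshot
from .model import BinaryBaseline, Embedder
from .simulator import (
    SINGLE_HIT,
    DatasetConfig,
    SpecklePattern,
    ablation_mask,
    apply_masks,
    default_masks,
    process_image,
    LogNormalJitter,
)

__all__ = [
    "ConfusionMatrix",
    "ExperimentGrid",
    "confusion_and_scores",
    "relabel_binary",
    "fluence_scan",
    "detector_ablation",
    "tsne_export",
]

NON_SINGLE_HIT = "non_single_hit"


@dataclass
class ConfusionMatrix:
    """Counts with rows = truth, columns = prediction."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValueError("counts must be a KxK non-negative matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def f1_scores(self) -> dict[str, float]:
        """Per-class F1 = 2PR/(P+R), 0 when undefined."""
        out = {}
        for i, label in enumerate(self.labels):
            tp = self.counts[i, i]
            fp = self.counts[:, i].sum() - tp
            fn = self.counts[i, :].sum() - tp
            denom = 2 * tp + fp + fn
            out[label] = float(2 * tp / denom) if denom else 0.0
        return out

    @property
    def macro_f1(self) -> float:
        return float(np.mean(list(self.f1_scores().values())))


def confusion_and_scores(truth, predictions, labels=None):
    """Confusion matrix plus accuracy, per-class F1 and macro F1."""
    truth = list(truth)
    predictions = list(predictions)
    if not truth or len(truth) != len(predictions):
        raise ValueError("need equal-length, non-empty truth/prediction lists")
    if labels is None:
        labels = sorted(set(truth) | set(predictions))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), np.int64)
    for t, p in zip(truth, predictions):
        counts[index[t], index[p]] += 1
    cm = ConfusionMatrix(labels=list(labels), counts=counts)
    return cm, cm.accuracy, cm.f1_scores(), cm.macro_f1


def relabel_binary(labels: list[str]) -> list[str]:
    """Map multi-hit and non-sample-hit to a single non-single-hit class;
    single-hit is preserved. Idempotent."""
    return [lab if lab == SINGLE_HIT else NON_SINGLE_HIT for lab in labels]


@dataclass
class ExperimentGrid:
    fluence_factors: list[float] = field(
        default_factory=lambda: [10.0**e for e in np.arange(-2.0, 2.01, 0.5)]
    )
    shots: list[int] = field(default_factory=lambda: [1, 5, 20])
    detector_fraction: float = 1.0
    n_queries: int | None = None
    seed: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.fluence_factors):
            raise ValueError("fluence factors must be positive")
        if any(s < 1 for s in self.shots):
            raise ValueError("shot counts must be >= 1")
        if not 0 < self.detector_fraction <= 1:
            raise ValueError("detector_fraction must be in (0, 1]")


def _process_raw(raw_patterns: list[SpecklePattern], cfg: DatasetConfig,
                 intensity_factor: float, seed_offset: int) -> list[SpecklePattern]:
    masks = default_masks(cfg.geometry) if cfg.apply_masks else None
    jitter = LogNormalJitter(sigma=cfg.jitter_sigma) if cfg.use_jitter else None
    out = []
    for p in raw_patterns:
        img, mult = process_image(
            p.image.astype(np.float64), masks, p.rng_seed + seed_offset,
            jitter=jitter, gaussian_sigma=cfg.gaussian_sigma,
            crop_size=cfg.crop_size, intensity_factor=intensity_factor,
        )
        out.append(SpecklePattern(
            image=img, label=p.label, sample_id=p.sample_id,
            fluence_multiplier=mult * intensity_factor, rng_seed=p.rng_seed,
            source_id=p.source_id,
        ))
    return out


def fluence_scan(
    embedder: Embedder,
    raw_test_patterns: list[SpecklePattern],
    dataset_config: DatasetConfig,
    grid: ExperimentGrid,
) -> list[dict]:
    """X-shot classification accuracy/F1 across a fluence-factor grid.

    ``raw_test_patterns`` must hold noise-free detector images
    (``simulate_dataset(..., processed=False)``); each factor rescales them
    before shot noise and normalization, exactly as a brighter or dimmer
    pulse would. Supports are drawn (and embedded) from the same processed
    pool, disjoint from the queries. One row per (factor, shots) cell.
    """
    rows = []
    for fi, factor in enumerate(grid.fluence_factors):
        processed = _process_raw(
            raw_test_patterns, dataset_config, factor, seed_offset=7919 * fi
        )
        for shots in grid.shots:
            support, used = fewshot.build_support(
                processed, shots, embedder, seed=grid.seed + fi
            )
            pool = [i for i in range(len(processed)) if i not in used]
            if grid.n_queries is not None:
                rng = np.random.default_rng(grid.seed + 31 * fi + shots)
                pool = list(rng.choice(pool, size=min(grid.n_queries, len(pool)),
                                       replace=False))
            queries = np.stack([processed[i].image for i in pool])
            truth = [processed[i].label for i in pool]
            z = embedder(queries)
            preds = [r.predicted_label for r in fewshot.batch_classify(z, support)]
            _, acc, _, macro = confusion_and_scores(truth, preds)
            rows.append({
                "fluence_factor": factor, "shots": shots,
                "accuracy": acc, "macro_f1": macro, "n_queries": len(pool),
            })
    return rows


def _mask_crops(images: np.ndarray, fraction: float,
                mode: str = "topleft",
                rng: np.random.Generator | None = None) -> np.ndarray:
    if fraction == 1.0:
        return images
    mask = ablation_mask(images.shape[-2:], fraction, mode=mode, rng=rng)
    out = np.array(images, copy=True)
    out[..., mask.astype(bool)] = 0.0
    return out


def detector_ablation(
    embedder: Embedder,
    baseline: BinaryBaseline,
    test_patterns: list[SpecklePattern],
    fraction_available: float,
    shots: int = 5,
    seed: int = 0,
    mode: str = "topleft",
) -> dict:
    """Paired comparison of the few-shot embedding classifier and the
    threshold baseline on identically masked inputs.

    Both models see the same crops with everything outside a contiguous
    region of ``fraction_available`` of the area zeroed; supports are masked
    the same way as queries. The embedding classifier predicts among the
    dataset's hit classes and is then relabeled to single vs non-single for
    a confusion matrix compatible with the binary baseline.
    """
    images = np.stack([p.image for p in test_patterns])
    rng = np.random.default_rng(seed)
    masked = _mask_crops(images, fraction_available, mode=mode, rng=rng)
    masked_patterns = [
        SpecklePattern(image=m, label=p.label, sample_id=p.sample_id,
                       rng_seed=p.rng_seed, source_id=p.source_id)
        for m, p in zip(masked, test_patterns)
    ]
    support, used = fewshot.build_support(masked_patterns, shots, embedder,
                                          seed=seed)
    pool = [i for i in range(len(masked_patterns)) if i not in used]
    queries = masked[pool]
    truth3 = [masked_patterns[i].label for i in pool]
    z = embedder(queries)
    preds3 = [r.predicted_label for r in fewshot.batch_classify(z, support)]
    truth_bin = relabel_binary(truth3)
    embed_preds_bin = relabel_binary(preds3)
    base_preds_bin = [
        SINGLE_HIT if s else NON_SINGLE_HIT for s in baseline.predict(queries)
    ]
    bin_labels = [NON_SINGLE_HIT, SINGLE_HIT]
    _, acc_e, _, f1_e = confusion_and_scores(truth_bin, embed_preds_bin, bin_labels)
    _, acc_b, _, f1_b = confusion_and_scores(truth_bin, base_preds_bin, bin_labels)
    return {
        "fraction_available": fraction_available,
        "embedding_accuracy": acc_e, "embedding_macro_f1": f1_e,
        "baseline_accuracy": acc_b, "baseline_macro_f1": f1_b,
        "n_queries": len(pool),
    }


def tsne_export(embeddings: np.ndarray, labels, out_path: str,
                seed: int = 0) -> np.ndarray:
    """Project embeddings to 2-D with t-SNE and write a CSV of
    (x, y, label); a diagnostic, with no quantitative claims attached."""
    from sklearn.manifold import TSNE

    embeddings = np.atleast_2d(np.asarray(embeddings))
    if embeddings.shape[0] < 2:
        raise ValueError("t-SNE needs at least two points")
    perplexity = min(30.0, max(2.0, embeddings.shape[0] / 4.0))
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(embeddings)
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "label"])
        for (x, y), lab in zip(coords, labels):
            writer.writerow([f"{x:.6f}", f"{y:.6f}", lab])
    return coords


def write_rows_csv(rows: list[dict], path: str) -> None:
    if not rows:
        raise ValueError("no rows to write")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def write_summary_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
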