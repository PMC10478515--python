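"""Self-contained synthetic benchmark studies: simulate, split, train, score.

Two benchmark datasets are used, both at 200 patterns per class, 96x96,
with full detector realism (beam stop, panel gap, fluence jitter, shot
noise, Gaussian read-out noise) and a 50/20/30 source-level
train/validation/test split:

* the *hit study* (:func:`run_study`) emulates the online-training scenario
  on one sample of interest — a 50-atom toy particle with single-hit vs
  multi-hit classes — and trains both the embedding classifier and the
  binary threshold baseline on the same patterns, so missing-detector
  comparisons are paired. Hit classes overlap at unlucky fluence/geometry
  draws, which is realistic; accuracies saturate in the low 0.9s.
* the *fringe-spacing study* (:func:`run_size_study`) is the well-separated
  two-class benchmark used for the few-shot learning property: single hits
  of two toy particles whose radii differ by 2x, so the speckle fringe
  spacing (inversely proportional to particle size) is distinct class-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fewshot, training
from .augment import AugmentConfig, split_then_augment
from .evaluation import confusion_and_scores
from .model import BinaryBaseline, Embedder, ModelConfig
from .simulator import (
    MULTI_HIT,
    SINGLE_HIT,
    DatasetConfig,
    SpecklePattern,
    random_particle,
    simulate_dataset,
)

__all__ = ["StudyConfig", "SizeStudyConfig", "StudyResult", "run_study",
           "run_size_study", "fewshot_accuracy"]


@dataclass
class StudyConfig:
    n_per_class: int = 200
    classes: tuple[str, ...] = (SINGLE_HIT, MULTI_HIT)
    n_atoms: int = 50
    radius_A: float = 25.0
    fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    n_augment_per_source: int = 0
    embedder_epochs: int = 10
    baseline_epochs: int = 8
    alpha: float = 0.2
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    train_baseline: bool = True


@dataclass
class StudyResult:
    train: list[SpecklePattern]
    val: list[SpecklePattern]
    test: list[SpecklePattern]
    embedder: Embedder
    embedder_history: list[dict]
    baseline: BinaryBaseline | None
    baseline_history: list[dict] | None


def _subseed(seed: int, slot: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(slot,))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1))


def run_study(seed: int, config: StudyConfig | None = None) -> StudyResult:
    """Run the full benchmark pipeline, deterministic in ``seed``."""
    cfg = config or StudyConfig()
    particle = random_particle(cfg.n_atoms, cfg.radius_A, _subseed(seed, 0))
    patterns = simulate_dataset(
        cfg.n_per_class, list(cfg.classes), [particle],
        seed=_subseed(seed, 1), config=cfg.dataset,
    )
    train, val, test = split_then_augment(
        patterns, cfg.fractions, AugmentConfig(),
        cfg.n_augment_per_source, seed=_subseed(seed, 2),
    )
    model_cfg = ModelConfig(seed=_subseed(seed, 3))
    embedder = Embedder(model_cfg)
    embedder, emb_hist = training.fit(
        embedder, train, val,
        training.TrainConfig(alpha=cfg.alpha, epochs=cfg.embedder_epochs,
                             seed=_subseed(seed, 4)),
    )
    baseline = None
    base_hist = None
    if cfg.train_baseline:
        baseline = BinaryBaseline(ModelConfig(seed=_subseed(seed, 5)))
        baseline, base_hist = training.fit_binary_baseline(
            baseline, train, val, epochs=cfg.baseline_epochs,
            seed=_subseed(seed, 6),
        )
    return StudyResult(train=train, val=val, test=test, embedder=embedder,
                       embedder_history=emb_hist, baseline=baseline,
                       baseline_history=base_hist)


@dataclass
class SizeStudyConfig:
    """Two-class benchmark with class-wide distinct fringe spacings:
    single hits of a small and a large toy particle."""

    n_per_class: int = 200
    n_atoms: int = 50
    small_radius_A: float = 20.0
    large_radius_A: float = 40.0
    fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    n_augment_per_source: int = 0
    embedder_epochs: int = 10
    alpha: float = 0.2
    dataset: DatasetConfig = field(default_factory=DatasetConfig)


def run_size_study(seed: int, config: SizeStudyConfig | None = None) -> StudyResult:
    """Train the embedder to separate two particle sizes, deterministic in
    ``seed``. Labels are ``small_particle`` / ``large_particle``."""
    cfg = config or SizeStudyConfig()
    small = random_particle(cfg.n_atoms, cfg.small_radius_A, _subseed(seed, 0))
    large = random_particle(cfg.n_atoms, cfg.large_radius_A, _subseed(seed, 7))
    patterns = simulate_dataset(
        cfg.n_per_class, [SINGLE_HIT], [small, large],
        seed=_subseed(seed, 1), config=cfg.dataset,
    )
    for p in patterns:
        p.label = ("small_particle" if p.sample_id == small.particle_id
                   else "large_particle")
    train, val, test = split_then_augment(
        patterns, cfg.fractions, AugmentConfig(),
        cfg.n_augment_per_source, seed=_subseed(seed, 2),
    )
    embedder = Embedder(ModelConfig(seed=_subseed(seed, 3)))
    embedder, emb_hist = training.fit(
        embedder, train, val,
        training.TrainConfig(alpha=cfg.alpha, epochs=cfg.embedder_epochs,
                             seed=_subseed(seed, 4)),
    )
    return StudyResult(train=train, val=val, test=test, embedder=embedder,
                       embedder_history=emb_hist, baseline=None,
                       baseline_history=None)


def fewshot_accuracy(embedder: Embedder, patterns: list[SpecklePattern],
                     shots: int, support_seeds: list[int],
                     images: np.ndarray | None = None) -> list[float]:
    """Held-out X-shot accuracy, one value per support draw.

    Each draw samples a fresh support set; queries are all remaining
    patterns. ``images`` optionally overrides the pattern images (used for
    masked-detector evaluation) while labels come from ``patterns``.
    """
    if images is None:
        images = np.stack([p.image for p in patterns])
    accs = []
    for s in support_seeds:
        masked_patterns = [
            SpecklePattern(image=img, label=p.label, sample_id=p.sample_id,
                           rng_seed=p.rng_seed, source_id=p.source_id)
            for img, p in zip(images, patterns)
        ]
        support, used = fewshot.build_support(masked_patterns, shots, embedder,
                                              seed=s)
        pool = [i for i in range(len(patterns)) if i not in used]
        z = embedder(images[pool])
        preds = [r.predicted_label for r in fewshot.batch_classify(z, support)]
        truth = [patterns[i].label for i in pool]
        _, acc, _, _ = confusion_and_scores(truth, preds)
        accs.append(acc)
    return accs
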