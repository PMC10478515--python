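# speckfew

Few-shot classification of X-ray single-particle-imaging (SPI) speckle
patterns with a unit-hypersphere embedding network.

## The problem

At an X-ray free-electron laser, each pulse that hits the sample stream
produces one detector frame — a coherent-diffraction "speckle pattern".
Reconstruction pipelines need the frames sorted in near real time into
**single-hit** (exactly one particle), **multi-hit** (two or more particles,
showing inter-particle interference fringes) and **non-sample-hit**
(parasitic scattering). Labeled examples are scarce — labeling speckle
patterns is slow expert work — and large detector regions are routinely
masked or missing. Conventional CNN classifiers need hundreds of labels per
new sample and degrade badly with missing detector area.

`speckfew` instead learns a *metric*: a small CNN `f` maps a pattern `x` to
a point `f(x)` on the unit sphere in R^128, trained with the triplet loss

    L(a, p, n) = max(0, ‖f(a) − f(p)‖² − ‖f(a) − f(n)‖² + α),   α ∈ (0, 4]

with semi-hard negative mining at the mini-batch level (a negative is
*semi-hard* when `d(a,p) < d(a,n) < d(a,p) + α`). A new pattern is then
classified N-way X-shot: compute its Euclidean distances to X labeled
supports per class, average per class, and take the arg-min class. Because
only distances are compared, the classifier transfers to new samples with a
handful of labels and tolerates missing detector area far better than a
probability-threshold CNN baseline.

The package contains, as first-class tested code:

- `speckfew.simulator` — a flat-Ewald coherent diffraction simulator
  (point scatterers from toy particles or PDB files), with beam-stop/gap
  masks, fluence jitter, Poisson shot noise, cropping and normalization;
- `speckfew.augment` — rotation/masking/zoom/shift augmentation with a
  leakage-safe split-before-augment dataset builder and audit;
- `speckfew.model` / `speckfew.nn` — the embedding network and the binary
  threshold baseline, implemented as a numpy CNN with hand-written,
  gradient-checked backprop;
- `speckfew.training` — triplet loss, semi-hard mining with the
  multi-sample anchor/positive rule, Adam training loop;
- `speckfew.fewshot` — support sets and the 4-step N-way X-shot classifier;
- `speckfew.evaluation` — confusion/accuracy/F1, the fluence scan, the
  missing-detector-area ablation, optional t-SNE export;
- `speckfew.cli` — `speckfew simulate | train | classify | evaluate |
  audit-split`.

## Worked example

```python
import numpy as np
from speckfew.simulator import (DatasetConfig, SINGLE_HIT, MULTI_HIT,
                                random_particle, simulate_dataset)
from speckfew.augment import AugmentConfig, split_then_augment
from speckfew.model import Embedder, ModelConfig
from speckfew import training, fewshot

# 1. simulate a labeled dataset from one toy particle (50 atoms, 25 A)
particle = random_particle(50, 25.0, seed=7)
patterns = simulate_dataset(60, [SINGLE_HIT, MULTI_HIT], [particle],
                            seed=11, config=DatasetConfig())

# 2. leakage-safe split, then train the embedder with mined triplets
train, val, test = split_then_augment(patterns, (0.5, 0.2, 0.3),
                                      AugmentConfig(), 0, seed=3)
embedder = Embedder(ModelConfig(seed=5))
embedder, history = training.fit(embedder, train, val,
                                 training.TrainConfig(epochs=5, seed=5))
print(f"val loss {history[0]['val_loss']:.3f} -> {history[-1]['val_loss']:.3f}")

# 3. 2-way 5-shot classification of held-out patterns
support, used = fewshot.build_support(test, 5, embedder, seed=1)
pool = [i for i in range(len(test)) if i not in used]
z = embedder(np.stack([test[i].image for i in pool]))
preds = [r.predicted_label for r in fewshot.batch_classify(z, support)]
acc = np.mean([p == test[i].label for p, i in zip(preds, pool)])
print(f"5-shot accuracy on {len(pool)} held-out patterns: {acc:.3f}")
```

Output (a few minutes on one CPU):

```
val loss 0.175 -> 0.164
5-shot accuracy on 26 held-out patterns: 0.846
```

The validation triplet loss falls as the margin constraint is satisfied on
held-out triplets, and with only 5 labeled supports per class the embedding
classifier already sorts ~85% of unseen patterns correctly after 5 epochs
on 60 training patterns; the full benchmark below (200 patterns/class, 10
epochs) reaches ≥ 95%.

The same pipeline is available from the shell:

```bash
speckfew simulate --out ds.h5 --n-per-class 60 --classes single_hit,multi_hit --seed 11
speckfew train --dataset ds.h5 --out model.npz --epochs 5 --seed 5
speckfew evaluate --checkpoint model.npz --dataset ds.h5 --shots 1,5 --out-dir results/
```

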