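"""Data augmentation for speckle patterns and the leakage-safe split.

Four augmentations are used: random in-plane rotation (mimicking particle
rotation about the beam axis), random masking (bad pixels / parasitic
scattering), random zooming (detector-distance and wavelength changes) and
random shifting (beam-center drift).

Because augmented copies of one source pattern are highly correlated,
train/validation/test partitioning MUST happen before augmentation;
otherwise augmented siblings of a training pattern leak into the test set
and inflate measured performance. ``split_then_augment`` enforces this and
``audit_split`` re-checks it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .simulator import SpecklePattern

__all__ = [
    "AugmentConfig",
    "random_rotation",
    "random_masking",
    "random_zoom",
    "random_shift",
    "augment_image",
    "split_then_augment",
    "audit_split",
    "LeakageError",
]


class LeakageError(RuntimeError):
    """An augmented pattern was found in a different partition from its source."""


@dataclass
class AugmentConfig:
    rotation_range: tuple[float, float] = (0.0, 360.0)  # degrees
    n_mask_blocks: tuple[int, int] = (1, 3)
    mask_block_range: tuple[int, int] = (6, 20)  # block side, pixels
    zoom_range: tuple[float, float] = (0.85, 1.15)
    shift_range: tuple[int, int] = (-5, 5)  # pixels, both axes
    fill_value: float = 0.0

    def __post_init__(self):
        if self.rotation_range[0] > self.rotation_range[1]:
            raise ValueError("rotation_range must be well ordered")
        if self.zoom_range[0] <= 0 or self.zoom_range[0] > self.zoom_range[1]:
            raise ValueError("zoom factors must be positive and well ordered")
        if self.shift_range[0] > self.shift_range[1]:
            raise ValueError("shift_range must be well ordered")


def random_rotation(image: np.ndarray, angle_deg: float, fill: float = 0.0,
                    interpolation: str = "bilinear") -> np.ndarray:
    """Rotate about the image center, preserving shape.

    Exact multiples of 90 degrees use a lattice-preserving array rotation;
    other angles interpolate (bilinear by default) with ``fill`` outside the
    source footprint.
    """
    angle_deg = float(angle_deg) % 360.0
    if angle_deg == 0.0:
        return np.array(image, copy=True)
    if angle_deg % 90.0 == 0.0 and image.shape[0] == image.shape[1]:
        return np.ascontiguousarray(np.rot90(image, k=int(angle_deg // 90)))
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    return ndimage.rotate(
        image, angle_deg, reshape=False, order=order,
        mode="constant", cval=fill,
    )


def random_masking(image: np.ndarray, n_blocks: int,
                   block_size_range: tuple[int, int], fill: float,
                   seed: int) -> np.ndarray:
    """Cover ``n_blocks`` random rectangles with a constant fill value."""
    rng = np.random.default_rng(seed)
    out = np.array(image, copy=True)
    h, w = image.shape
    lo, hi = block_size_range
    for _ in range(n_blocks):
        bh = int(rng.integers(lo, hi + 1))
        bw = int(rng.integers(lo, hi + 1))
        r0 = int(rng.integers(0, h))
        c0 = int(rng.integers(0, w))
        out[r0: r0 + bh, c0: c0 + bw] = fill
    return out


def random_zoom(image: np.ndarray, factor: float, fill: float = 0.0) -> np.ndarray:
    """Zoom about the image center; output shape equals input shape
    (zooming in crops, zooming out pads with ``fill``)."""
    if factor <= 0:
        raise ValueError("zoom factor must be positive")
    if factor == 1.0:
        return np.array(image, copy=True)
    h, w = image.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    # output coord -> input coord: x_in = c + (x_out - c)/factor
    matrix = np.eye(2) / factor
    offset = center - matrix @ center
    return ndimage.affine_transform(
        image, matrix, offset=offset, output_shape=image.shape,
        order=1, mode="constant", cval=fill,
    )


def random_shift(image: np.ndarray, dx: float, dy: float,
                 fill: float = 0.0) -> np.ndarray:
    """Translate by (dx rows, dy cols); exposed pixels take ``fill``."""
    if dx == 0 and dy == 0:
        return np.array(image, copy=True)
    return ndimage.shift(image, (dx, dy), order=1, mode="constant", cval=fill)


def augment_image(image: np.ndarray, config: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply all four augmentations with parameters drawn from the config."""
    angle = rng.uniform(*config.rotation_range)
    out = random_rotation(image, angle, fill=config.fill_value)
    n_blocks = int(rng.integers(config.n_mask_blocks[0], config.n_mask_blocks[1] + 1))
    out = random_masking(
        out, n_blocks, config.mask_block_range, config.fill_value,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    out = random_zoom(out, rng.uniform(*config.zoom_range), fill=config.fill_value)
    dx = rng.integers(config.shift_range[0], config.shift_range[1] + 1)
    dy = rng.integers(config.shift_range[0], config.shift_range[1] + 1)
    return random_shift(out, int(dx), int(dy), fill=config.fill_value).astype(
        image.dtype
    )


def _partition_sources(patterns, fractions, rng):
    """Stratified-by-label partition of source patterns into train/val/test."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    by_label: dict[str, list[int]] = {}
    for i, p in enumerate(patterns):
        by_label.setdefault(p.label, []).append(i)
    parts: list[list[int]] = [[], [], []]
    for label, idxs in sorted(by_label.items()):
        idxs = np.array(idxs)
        rng.shuffle(idxs)
        n = len(idxs)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_val = min(n_val, n - n_train)
        splits = (idxs[:n_train], idxs[n_train: n_train + n_val],
                  idxs[n_train + n_val:])
        for part, chunk in zip(parts, splits):
            part.extend(int(i) for i in chunk)
        for name, frac, chunk in zip(("train", "val", "test"), fractions, splits):
            if frac > 0 and len(chunk) == 0:
                raise ValueError(
                    f"class {label!r} absent from the {name} partition at the "
                    f"requested fractions"
                )
    return parts


def split_then_augment(
    patterns: list[SpecklePattern],
    fractions: tuple[float, float, float],
    augment_config: AugmentConfig | None,
    n_augment_per_source: int,
    seed: int,
) -> tuple[list[SpecklePattern], list[SpecklePattern], list[SpecklePattern]]:
    """Partition source patterns first, then expand each partition with
    augmented copies; copies inherit the partition and ``source_id`` of
    their source, so no source ever spans two partitions.

    The split is stratified by label; within each class the train and val
    counts are ``round(fraction * n)`` (round-half-even) and the remainder
    goes to test.
    """
    if not patterns:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed)
    parts = _partition_sources(patterns, fractions, rng)
    out: list[list[SpecklePattern]] = []
    for part_indices in parts:
        expanded: list[SpecklePattern] = []
        for i in part_indices:
            src = patterns[i]
            expanded.append(src)
            for j in range(n_augment_per_source):
                aug_seed = int(rng.integers(0, 2**31 - 1))
                img = augment_image(
                    src.image, augment_config or AugmentConfig(),
                    np.random.default_rng(aug_seed),
                ) if n_augment_per_source else src.image
                expanded.append(
                    SpecklePattern(
                        image=img, label=src.label, sample_id=src.sample_id,
                        fluence_multiplier=src.fluence_multiplier,
                        rng_seed=aug_seed, is_augmented=True,
                        source_id=src.source_id,
                    )
                )
        out.append(expanded)
    audit_split({"train": out[0], "val": out[1], "test": out[2]})
    return out[0], out[1], out[2]


def audit_split(partitions: dict[str, list[SpecklePattern]]) -> None:
    """Raise :class:`LeakageError` if any source_id appears in more than one
    partition (the augmented-data leakage check)."""
    seen: dict[str, str] = {}
    for name, patterns in partitions.items():
        for p in patterns:
            prev = seen.get(p.source_id)
            if prev is not None and prev != name:
                raise LeakageError(
                    f"source {p.source_id!r} appears in partitions "
                    f"{prev!r} and {name!r}"
                )
            seen[p.source_id] = name
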