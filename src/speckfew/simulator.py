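"""Simulation of labeled X-ray single-particle-imaging speckle patterns.

A pulse outcome falls into one of three classes: a *single hit* (exactly one
particle in the beam), a *multi hit* (2-4 particles scattering coherently,
producing interference fringes on top of the single-particle speckle), or a
*non-sample hit* (parasitic scattering from something that is not the sample,
modeled here as smooth broad streaks).

The forward model is a far-field, small-angle (flat Ewald sphere) coherent
sum over point scatterers with unit form factors:

    I(q) = s * | sum_copies sum_atoms w * exp(i q . (R r + t)) |^2

with the per-pixel momentum transfer q taken from the detector geometry.
This keeps every tested invariant of coherent diffraction (Friedel symmetry,
k^2 scaling of the forward peak for k in-phase copies, interference fringes
for multi-hits) while staying desk-scale. Ewald curvature, element-specific
form factors and polarization/solid-angle corrections are out of scope.

Detector realism follows the standard pnCCD-like setup: a 172x172 pixel
grid, a 6x8 beam-stop mask at the beam center, a 4-column panel gap across
the detector midline, per-pattern fluence jitter, Poisson shot noise,
a 96x96 center crop, per-image intensity normalization and additive
Gaussian read-out noise on the normalized scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "DetectorGeometry",
    "BeamProfile",
    "Particle",
    "HitConfig",
    "MaskSet",
    "SpecklePattern",
    "LogNormalJitter",
    "EmpiricalJitter",
    "DatasetConfig",
    "HIT_CLASSES",
    "SINGLE_HIT",
    "MULTI_HIT",
    "NON_SAMPLE_HIT",
    "LABEL_TO_INT",
    "INT_TO_LABEL",
    "diffraction_intensity",
    "random_particle",
    "load_pdb_coordinates",
    "simulate_non_sample_hit",
    "apply_shot_noise",
    "apply_gaussian_noise",
    "apply_fluence_jitter",
    "default_masks",
    "ablation_mask",
    "apply_masks",
    "center_crop",
    "normalize_intensity",
    "random_hit_config",
    "render_hit",
    "process_image",
    "simulate_dataset",
]

SINGLE_HIT = "single_hit"
MULTI_HIT = "multi_hit"
NON_SAMPLE_HIT = "non_sample_hit"
HIT_CLASSES = (NON_SAMPLE_HIT, SINGLE_HIT, MULTI_HIT)
LABEL_TO_INT = {NON_SAMPLE_HIT: 0, SINGLE_HIT: 1, MULTI_HIT: 2}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}

#: hc in keV * Angstrom, for photon-energy -> wavelength conversion
HC_KEV_ANGSTROM = 12.398419


@dataclass(frozen=True)
class DetectorGeometry:
    """Square pixel-array detector in the far field.

    The default pixel-size / distance pair is chosen so that a ~50 Angstrom
    toy particle produces speckle fringes of roughly 3-10 pixel period at
    1.66 keV; both are configurable for other regimes.
    """

    n_rows: int = 172
    n_cols: int = 172
    pixel_size: float = 7.5e-5  # m
    detector_distance: float = 3.0e-3  # m
    beam_center: tuple[float, float] | None = None  # (row, col), default center
    photon_energy_kev: float = 1.66

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("detector dimensions must be positive")
        if self.pixel_size <= 0 or self.detector_distance <= 0:
            raise ValueError("pixel size and distance must be positive")
        if self.photon_energy_kev <= 0:
            raise ValueError("photon energy must be positive")
        if self.beam_center is None:
            object.__setattr__(
                self,
                "beam_center",
                ((self.n_rows - 1) / 2.0, (self.n_cols - 1) / 2.0),
            )
        r, c = self.beam_center
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise ValueError("beam center must lie on the detector")

    @property
    def wavelength(self) -> float:
        """X-ray wavelength in Angstrom."""
        return HC_KEV_ANGSTROM / self.photon_energy_kev

    def q_grid(self) -> np.ndarray:
        """Per-pixel transverse momentum transfer, shape (n_rows, n_cols, 2),
        in 1/Angstrom (flat-Ewald small-angle approximation)."""
        rows = np.arange(self.n_rows) - self.beam_center[0]
        cols = np.arange(self.n_cols) - self.beam_center[1]
        scale = 2.0 * math.pi / self.wavelength * self.pixel_size / self.detector_distance
        qr, qc = np.meshgrid(rows * scale, cols * scale, indexing="ij")
        return np.stack([qr, qc], axis=-1)


@dataclass(frozen=True)
class BeamProfile:
    photon_energy_kev: float = 1.66
    photons_per_pulse: float = 1e12
    beam_radius_um: float = 0.5
    fluence_multiplier: float = 1.0
    #: detector-scale factor; the default puts a ~50-atom single hit near
    #: 1e5 photons total before jitter
    intensity_scale: float = 6.7e-14

    def __post_init__(self):
        for name in ("photon_energy_kev", "photons_per_pulse", "beam_radius_um",
                     "fluence_multiplier", "intensity_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class Particle:
    """Point-scatterer model of a particle: N atom positions in Angstrom."""

    coords: np.ndarray  # (N, 3)
    weights: np.ndarray | None = None
    particle_id: str = "particle"

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coords, dtype=np.float64))
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coords must be an (N>=1, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        w = self.weights
        w = np.ones(len(coords)) if w is None else np.asarray(w, dtype=np.float64)
        if w.shape != (len(coords),) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per atom")
        object.__setattr__(self, "weights", w)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class HitConfig:
    """Number of particle copies with their orientations and displacements."""

    hit_class: str
    copies: int
    orientations: np.ndarray | None = None  # (copies, 4) unit quaternions
    displacements: np.ndarray | None = None  # (copies, 3) Angstrom

    def __post_init__(self):
        if self.hit_class not in HIT_CLASSES:
            raise ValueError(f"unknown hit class {self.hit_class!r}")
        if self.hit_class == SINGLE_HIT and self.copies != 1:
            raise ValueError("single_hit requires exactly one copy")
        if self.hit_class == MULTI_HIT and self.copies not in (2, 3, 4):
            raise ValueError("multi_hit requires 2-4 copies")
        if self.hit_class == NON_SAMPLE_HIT and self.copies != 0:
            raise ValueError("non_sample_hit carries no particle copies")
        if self.copies:
            q = np.asarray(self.orientations, dtype=np.float64)
            t = np.asarray(self.displacements, dtype=np.float64)
            if q.shape != (self.copies, 4):
                raise ValueError("need one quaternion per copy")
            if not np.allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-6):
                raise ValueError("orientation quaternions must be unit norm")
            if t.shape != (self.copies, 3):
                raise ValueError("need one displacement per copy")
            object.__setattr__(self, "orientations", q)
            object.__setattr__(self, "displacements", t)


@dataclass(frozen=True)
class MaskSet:
    """Binary detector masks (1 = masked). ``combined`` is the union."""

    beam_stop: np.ndarray
    gap: np.ndarray
    extra: np.ndarray | None = None

    def __post_init__(self):
        shapes = {self.beam_stop.shape, self.gap.shape}
        if self.extra is not None:
            shapes.add(self.extra.shape)
        if len(shapes) != 1:
            raise ValueError("all masks must share one shape")
        for m in (self.beam_stop, self.gap, self.extra):
            if m is not None and not np.isin(m, (0, 1)).all():
                raise ValueError("masks must be binary")

    @property
    def combined(self) -> np.ndarray:
        out = (self.beam_stop.astype(bool) | self.gap.astype(bool))
        if self.extra is not None:
            out |= self.extra.astype(bool)
        return out.astype(np.uint8)


@dataclass
class SpecklePattern:
    """One detector image with its class label and provenance.

    The canonical labels are the three hit classes, but any non-empty
    string is accepted so that benchmarks can classify along other axes
    (e.g. particle identity).
    """

    image: np.ndarray
    label: str
    sample_id: str
    fluence_multiplier: float = 1.0
    rng_seed: int = 0
    is_augmented: bool = False
    source_id: str | None = None

    def __post_init__(self):
        if not isinstance(self.label, str) or not self.label:
            raise ValueError(f"label must be a non-empty string, got {self.label!r}")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("pattern intensities must be finite")
        if self.source_id is None:
            self.source_id = f"{self.sample_id}/{self.rng_seed}"


# ---------------------------------------------------------------------------
# forward model


def _quat_to_matrix(quat: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(quat)
    if not math.isclose(n, 1.0, abs_tol=1e-6):
        raise ValueError(f"quaternion norm {n:.6f} != 1")
    # scipy uses (x, y, z, w) ordering; accept (w, x, y, z) input
    w, x, y, z = quat
    return Rotation.from_quat([x, y, z, w]).as_matrix()


def diffraction_intensity(
    particles: Sequence[tuple[Particle, np.ndarray, np.ndarray]],
    geometry: DetectorGeometry,
    beam: BeamProfile,
) -> np.ndarray:
    """Noise-free coherent diffraction image for one or more particle copies.

    Parameters
    ----------
    particles
        Sequence of ``(particle, quaternion_wxyz, displacement_A)`` tuples.
        All copies scatter coherently: amplitudes add before squaring, so
        multi-hits show interference fringes set by the copy displacements.
    """
    if len(particles) == 0:
        raise ValueError("at least one particle copy is required")
    q = geometry.q_grid()  # (H, W, 2)
    qflat = q.reshape(-1, 2)
    amplitude = np.zeros(qflat.shape[0], dtype=np.complex128)
    for particle, quat, disp in particles:
        rot = _quat_to_matrix(np.asarray(quat, dtype=np.float64))
        pos = particle.coords @ rot.T + np.asarray(disp, dtype=np.float64)
        phases = qflat @ pos[:, :2].T  # flat Ewald: transverse q only
        amplitude += (np.exp(1j * phases) * particle.weights).sum(axis=1)
    scale = beam.photons_per_pulse * beam.intensity_scale * beam.fluence_multiplier
    image = scale * np.abs(amplitude) ** 2
    return image.reshape(geometry.n_rows, geometry.n_cols)


def random_particle(n_atoms: int, radius_A: float, seed: int) -> Particle:
    """Toy particle: ``n_atoms`` unit scatterers uniform in a ball."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if radius_A <= 0:
        raise ValueError("radius_A must be positive")
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    while len(pts) < n_atoms:
        cand = rng.uniform(-radius_A, radius_A, size=(2 * n_atoms + 8, 3))
        cand = cand[np.linalg.norm(cand, axis=1) <= radius_A]
        pts = np.vstack([pts, cand])
    return Particle(
        coords=pts[:n_atoms], particle_id=f"toy-n{n_atoms}-r{radius_A:g}-s{seed}"
    )


def load_pdb_coordinates(path: str) -> Particle:
    """Read atom coordinates (ATOM + HETATM, first model) from a PDB file.

    All atoms get unit scattering weight; occupancy, B-factors and element
    identity are ignored.
    """
    import gemmi

    try:
        structure = gemmi.read_structure(str(path))
    except Exception as exc:  # noqa: BLE001 - gemmi raises various types
        raise ValueError(f"could not read PDB file {path}: {exc}") from exc
    coords = []
    if len(structure) > 0:
        for chain in structure[0]:
            for residue in chain:
                for atom in residue:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return Particle(coords=np.asarray(coords), particle_id=structure.name or str(path))


def simulate_non_sample_hit(
    geometry: DetectorGeometry,
    beam: BeamProfile,
    seed: int,
    total_intensity: float = 1e5,
) -> np.ndarray:
    """Smooth parasitic-scattering proxy: 1-3 broad anisotropic Gaussian
    streaks with random orientation, scaled to ``total_intensity`` photons.

    This is a functional stand-in: it matches the low-spatial-frequency,
    streaky character of beamline parasitic scattering, not its physics.
    """
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(
        np.arange(geometry.n_rows, dtype=float),
        np.arange(geometry.n_cols, dtype=float),
        indexing="ij",
    )
    image = np.zeros((geometry.n_rows, geometry.n_cols))
    for _ in range(rng.integers(1, 4)):
        cr = geometry.beam_center[0] + rng.normal(0, geometry.n_rows / 8)
        ccen = geometry.beam_center[1] + rng.normal(0, geometry.n_cols / 8)
        theta = rng.uniform(0, np.pi)
        s_major = rng.uniform(0.25, 0.6) * geometry.n_rows
        s_minor = rng.uniform(0.03, 0.12) * geometry.n_rows
        u = (rr - cr) * np.cos(theta) + (cc - ccen) * np.sin(theta)
        v = -(rr - cr) * np.sin(theta) + (cc - ccen) * np.cos(theta)
        image += rng.uniform(0.3, 1.0) * np.exp(
            -0.5 * ((u / s_major) ** 2 + (v / s_minor) ** 2)
        )
    total = image.sum()
    if total <= 0:  # pathological; keep a flat floor instead of dividing by 0
        return np.full_like(image, total_intensity / image.size)
    return image * (total_intensity * beam.fluence_multiplier / total)


# ---------------------------------------------------------------------------
# noise, masks, crop, normalization


def apply_shot_noise(image: np.ndarray, seed: int) -> np.ndarray:
    """Per-pixel independent Poisson draw with mean equal to the input."""
    if np.any(image < 0):
        raise ValueError("Poisson sampling requires non-negative intensities")
    rng = np.random.default_rng(seed)
    return rng.poisson(image).astype(np.float64)


def apply_gaussian_noise(image: np.ndarray, sigma: float = 0.15,
                         seed: int = 0) -> np.ndarray:
    """Additive i.i.d. zero-mean Gaussian noise (read-out noise proxy);
    meant for the intensity-normalized O(1) scale."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.array(image, copy=True)
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, sigma, size=image.shape)


class LogNormalJitter:
    """Log-normal pulse-fluence multiplier distribution, median 1 with a long
    right tail; a pluggable stand-in for an experimental shot-to-shot
    photon-count histogram."""

    def __init__(self, median: float = 1.0, sigma: float = 0.5):
        if median <= 0 or sigma < 0:
            raise ValueError("median must be positive, sigma non-negative")
        self.mu = math.log(median)
        self.sigma = sigma

    @property
    def mean(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2)

    def __call__(self, rng: np.random.Generator) -> float:
        return float(rng.lognormal(self.mu, self.sigma))


class EmpiricalJitter:
    """Fluence multipliers resampled from observed values (e.g. a measured
    per-pulse photon-count histogram divided by its mean)."""

    def __init__(self, samples: Sequence[float]):
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0 or np.any(~np.isfinite(samples)):
            raise ValueError("need a non-empty finite sample set")
        self.samples = samples

    def __call__(self, rng: np.random.Generator) -> float:
        return float(rng.choice(self.samples))


def apply_fluence_jitter(
    image: np.ndarray,
    multiplier_dist: Callable[[np.random.Generator], float],
    seed: int,
    max_redraws: int = 100,
) -> tuple[np.ndarray, float]:
    """Rescale the pattern by a random pulse-fluence multiplier.

    Non-positive draws are rejected and redrawn so the multiplier is always
    a valid intensity scale.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_redraws):
        multiplier = float(multiplier_dist(rng))
        if multiplier > 0:
            return image * multiplier, multiplier
    raise ValueError("fluence distribution failed to yield a positive multiplier")


def default_masks(geometry: DetectorGeometry,
                  extra: np.ndarray | None = None) -> MaskSet:
    """Beam-stop (6x8, centered on the beam center rounded to the nearest
    pixel) plus a 4-column panel gap centered on the detector midline."""
    shape = (geometry.n_rows, geometry.n_cols)
    beam_stop = np.zeros(shape, np.uint8)
    r0 = int(round(geometry.beam_center[0])) - 3
    c0 = int(round(geometry.beam_center[1])) - 4
    beam_stop[max(r0, 0): r0 + 6, max(c0, 0): c0 + 8] = 1
    gap = np.zeros(shape, np.uint8)
    g0 = geometry.n_cols // 2 - 2
    gap[:, g0: g0 + 4] = 1
    return MaskSet(beam_stop=beam_stop, gap=gap, extra=extra)


def ablation_mask(shape: tuple[int, int], fraction_available: float,
                  mode: str = "topleft",
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Mask mimicking lost detector panels: everything outside a contiguous
    square holding ``fraction_available`` of the area is masked (value 1).

    ``mode='topleft'`` keeps the top-left square (deterministic);
    ``mode='random'`` places the kept square at a random position.
    """
    if not 0 < fraction_available <= 1:
        raise ValueError("fraction_available must be in (0, 1]")
    h, w = shape
    mask = np.ones(shape, np.uint8)
    kh = int(round(math.sqrt(fraction_available) * h))
    kw = int(round(math.sqrt(fraction_available) * w))
    if mode == "topleft":
        r0, c0 = 0, 0
    elif mode == "random":
        rng = np.random.default_rng() if rng is None else rng
        r0 = int(rng.integers(0, h - kh + 1))
        c0 = int(rng.integers(0, w - kw + 1))
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")
    mask[r0: r0 + kh, c0: c0 + kw] = 0
    return mask


def apply_masks(image: np.ndarray, masks: MaskSet | np.ndarray,
                fill: float = 0.0) -> np.ndarray:
    combined = masks.combined if isinstance(masks, MaskSet) else np.asarray(masks)
    if combined.shape != image.shape:
        raise ValueError(
            f"mask shape {combined.shape} != image shape {image.shape}"
        )
    out = np.array(image, dtype=np.float64, copy=True)
    out[combined.astype(bool)] = fill
    return out


def center_crop(image: np.ndarray, size: int = 96) -> np.ndarray:
    """Central size x size window; the window starts at floor((dim-size)/2)."""
    h, w = image.shape
    if size > h or size > w:
        raise ValueError(f"crop {size} larger than image {h}x{w}")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return image[r0: r0 + size, c0: c0 + size]


def normalize_intensity(image: np.ndarray,
                        mask: np.ndarray | None = None) -> np.ndarray:
    """Per-image standardization: subtract the mean and divide by the standard
    deviation (over unmasked pixels when a mask is given).

    Scale invariant by construction: normalize(c*x) == normalize(x) for c>0.
    A constant image maps to all zeros.
    """
    image = np.asarray(image, dtype=np.float64)
    if mask is not None:
        valid = ~mask.astype(bool)
        mean = image[valid].mean()
        std = image[valid].std()
    else:
        mean = image.mean()
        std = image.std()
    if std == 0 or not np.isfinite(std):
        return np.zeros_like(image)
    return (image - mean) / std


# ---------------------------------------------------------------------------
# dataset assembly


def random_hit_config(hit_class: str, rng: np.random.Generator,
                      displacement_scale_A: float = 150.0,
                      copy_choices: Sequence[int] = (2, 3, 4)) -> HitConfig:
    """Random orientations/displacements for one pulse outcome.

    Multi-hit copy displacements are uniform in a ball of
    ``displacement_scale_A`` (a few particle diameters for the default toy
    particles), which sets the inter-particle fringe spacing.
    """
    if hit_class == NON_SAMPLE_HIT:
        return HitConfig(hit_class=hit_class, copies=0)
    copies = 1 if hit_class == SINGLE_HIT else int(rng.choice(copy_choices))
    quats = rng.normal(size=(copies, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    disps = np.zeros((copies, 3))
    if copies > 1:
        d = rng.normal(size=(copies, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        radii = displacement_scale_A * rng.uniform(0.3, 1.0, size=(copies, 1))
        disps = d * radii
    return HitConfig(
        hit_class=hit_class, copies=copies,
        orientations=quats if copies else None,
        displacements=disps if copies else None,
    )


def render_hit(particle: Particle, config: HitConfig,
               geometry: DetectorGeometry, beam: BeamProfile,
               seed: int) -> np.ndarray:
    """Noise-free detector image for one hit configuration."""
    if config.hit_class == NON_SAMPLE_HIT:
        return simulate_non_sample_hit(geometry, beam, seed)
    copies = [
        (particle, config.orientations[i], config.displacements[i])
        for i in range(config.copies)
    ]
    return diffraction_intensity(copies, geometry, beam)


def process_image(
    image: np.ndarray,
    masks: MaskSet | None,
    seed: int,
    jitter: Callable[[np.random.Generator], float] | None = None,
    gaussian_sigma: float = 0.15,
    crop_size: int = 96,
    intensity_factor: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Detector pipeline applied to a noise-free image.

    Order: fluence jitter -> Poisson shot noise -> masks -> center crop ->
    intensity normalization -> Gaussian noise. Returns the processed image
    and the fluence multiplier drawn.
    """
    multiplier = 1.0
    out = image * intensity_factor
    if jitter is not None:
        out, multiplier = apply_fluence_jitter(out, jitter, seed)
    out = apply_shot_noise(out, seed + 1)
    if masks is not None:
        out = apply_masks(out, masks)
        cropped_mask = center_crop(masks.combined.astype(float), crop_size)
        out = center_crop(out, crop_size)
        out = normalize_intensity(out, mask=cropped_mask)
    else:
        out = center_crop(out, crop_size)
        out = normalize_intensity(out)
    out = apply_gaussian_noise(out, gaussian_sigma, seed + 2)
    return out.astype(np.float32), multiplier


@dataclass
class DatasetConfig:
    """Study conditions for synthetic dataset generation."""

    geometry: DetectorGeometry = field(default_factory=DetectorGeometry)
    beam: BeamProfile = field(default_factory=BeamProfile)
    crop_size: int = 96
    gaussian_sigma: float = 0.15
    use_jitter: bool = True
    jitter_sigma: float = 0.5
    displacement_scale_A: float = 150.0
    multi_copy_choices: tuple[int, ...] = (2, 3, 4)
    apply_masks: bool = True


def simulate_dataset(
    n_per_class: int,
    classes: Sequence[str],
    particles: Sequence[Particle],
    seed: int,
    config: DatasetConfig | None = None,
    processed: bool = True,
) -> list[SpecklePattern]:
    """Balanced labeled dataset of simulated speckle patterns.

    ``n_per_class`` patterns are generated per hit class *per particle*
    (each particle is one sample, identified by ``sample_id``). Multi-hits
    pool 2-, 3- and 4-particle pulses with equal probability by default.
    With ``processed=False`` the raw noise-free detector images are returned
    (used by evaluation protocols that rescale fluence before noise).

    Deterministic for a fixed seed: each pattern derives its own seed from
    the master seed via ``SeedSequence``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    for cls in classes:
        if cls not in HIT_CLASSES:
            raise ValueError(f"unknown class name {cls!r}")
    if not particles:
        raise ValueError("need at least one particle")
    cfg = config or DatasetConfig()
    masks = default_masks(cfg.geometry) if cfg.apply_masks else None
    jitter = LogNormalJitter(sigma=cfg.jitter_sigma) if cfg.use_jitter else None
    patterns: list[SpecklePattern] = []
    root = np.random.SeedSequence(seed)
    for p_idx, particle in enumerate(particles):
        for cls in classes:
            for i in range(n_per_class):
                ss = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(p_idx, HIT_CLASSES.index(cls), i)
                )
                pattern_seed = int(ss.generate_state(1, np.uint32)[0] % (2**31 - 10))
                rng = np.random.default_rng(pattern_seed)
                hit = random_hit_config(
                    cls, rng,
                    displacement_scale_A=cfg.displacement_scale_A,
                    copy_choices=cfg.multi_copy_choices,
                )
                raw = render_hit(particle, hit, cfg.geometry, cfg.beam, pattern_seed)
                if processed:
                    img, mult = process_image(
                        raw, masks, pattern_seed,
                        jitter=jitter,
                        gaussian_sigma=cfg.gaussian_sigma,
                        crop_size=cfg.crop_size,
                    )
                else:
                    img, mult = raw.astype(np.float32), 1.0
                patterns.append(
                    SpecklePattern(
                        image=img, label=cls, sample_id=particle.particle_id,
                        fluence_multiplier=mult, rng_seed=pattern_seed,
                    )
                )
    return patterns
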