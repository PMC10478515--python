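"""Simulator correctness: forward-model oracle, physics invariants, noise
statistics, masks, crop and normalization, and dataset assembly."""

import numpy as np
import pytest

from speckfew import simulator as sim
from speckfew.simulator import (
    MULTI_HIT,
    NON_SAMPLE_HIT,
    SINGLE_HIT,
    BeamProfile,
    DatasetConfig,
    DetectorGeometry,
    HitConfig,
    LogNormalJitter,
    MaskSet,
    Particle,
)

IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


def brute_force_intensity(particles, geometry, beam):
    """Naive per-pixel, per-atom double loop over the coherent sum."""
    q = geometry.q_grid()
    out = np.zeros((geometry.n_rows, geometry.n_cols))
    scale = beam.photons_per_pulse * beam.intensity_scale * beam.fluence_multiplier
    from scipy.spatial.transform import Rotation

    for i in range(geometry.n_rows):
        for j in range(geometry.n_cols):
            amp = 0j
            for particle, quat, disp in particles:
                w, x, y, z = quat
                rot = Rotation.from_quat([x, y, z, w]).as_matrix()
                for atom, weight in zip(particle.coords, particle.weights):
                    r = rot @ atom + disp
                    amp += weight * np.exp(1j * (q[i, j, 0] * r[0] + q[i, j, 1] * r[1]))
            out[i, j] = scale * abs(amp) ** 2
    return out


class TestDiffractionIntensity:
    def test_single_atom_at_origin_gives_flat_image(self, small_geometry, beam):
        p = Particle(coords=np.zeros((1, 3)))
        img = sim.diffraction_intensity([(p, IDENTITY_Q, np.zeros(3))],
                                        small_geometry, beam)
        assert np.allclose(img, img.flat[0], rtol=1e-12)
        assert np.all(img >= 0)

    def test_two_atoms_quadruple_forward_intensity(self, beam):
        """Coherent sum: |1+1|^2 = 4x the single-atom value at q=0."""
        geo = DetectorGeometry(n_rows=33, n_cols=33)  # odd: beam center on a pixel
        one = Particle(coords=np.zeros((1, 3)))
        two = Particle(coords=np.array([[0.0, 0, 0], [30.0, 15.0, -4.0]]))
        i1 = sim.diffraction_intensity([(one, IDENTITY_Q, np.zeros(3))], geo, beam)
        i2 = sim.diffraction_intensity([(two, IDENTITY_Q, np.zeros(3))], geo, beam)
        assert np.isclose(i2[16, 16], 4.0 * i1[16, 16], rtol=1e-10)

    def test_vectorized_model_matches_brute_force_oracle(self, small_geometry,
                                                         beam, rng):
        particle = sim.random_particle(50, 25.0, seed=9)
        quat = rng.normal(size=4)
        quat /= np.linalg.norm(quat)
        disp = rng.normal(scale=20.0, size=3)
        args = [(particle, quat, disp)]
        fast = sim.diffraction_intensity(args, small_geometry, beam)
        slow = brute_force_intensity(args, small_geometry, beam)
        assert np.allclose(fast, slow, rtol=1e-8)

    def test_multi_copy_coherent_sum_matches_oracle(self, small_geometry, beam, rng):
        particle = sim.random_particle(10, 20.0, seed=3)
        copies = []
        for _ in range(3):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            copies.append((particle, q, rng.normal(scale=40.0, size=3)))
        fast = sim.diffraction_intensity(copies, small_geometry, beam)
        slow = brute_force_intensity(copies, small_geometry, beam)
        assert np.allclose(fast, slow, rtol=1e-8)

    def test_friedel_symmetry(self, beam):
        """I(q) = I(-q) for a real scatterer with the beam center on the
        array center (flat Ewald)."""
        geo = DetectorGeometry(n_rows=31, n_cols=31)
        particle = sim.random_particle(30, 25.0, seed=4)
        img = sim.diffraction_intensity([(particle, IDENTITY_Q, np.zeros(3))],
                                        geo, beam)
        flipped = img[::-1, ::-1]
        assert np.allclose(img, flipped, rtol=1e-8)

    def test_k_squared_scaling_of_in_phase_copies(self, beam):
        """k identical, unrotated, undisplaced copies scale I(0) by k^2."""
        geo = DetectorGeometry(n_rows=33, n_cols=33)
        particle = sim.random_particle(20, 25.0, seed=5)
        base = sim.diffraction_intensity(
            [(particle, IDENTITY_Q, np.zeros(3))], geo, beam)[16, 16]
        for k in (2, 3, 4):
            img = sim.diffraction_intensity(
                [(particle, IDENTITY_Q, np.zeros(3))] * k, geo, beam)
            assert np.isclose(img[16, 16], k**2 * base, rtol=1e-8)

    def test_empty_particle_list_rejected(self, small_geometry, beam):
        with pytest.raises(ValueError):
            sim.diffraction_intensity([], small_geometry, beam)

    def test_non_unit_quaternion_rejected(self, small_geometry, beam):
        p = Particle(coords=np.zeros((1, 3)))
        with pytest.raises(ValueError):
            sim.diffraction_intensity([(p, np.array([2.0, 0, 0, 0]), np.zeros(3))],
                                      small_geometry, beam)


class TestRandomParticle:
    def test_single_atom_inside_ball(self):
        p = sim.random_particle(1, 10.0, seed=0)
        assert p.n_atoms == 1
        assert np.linalg.norm(p.coords[0]) <= 10.0

    def test_deterministic_per_seed(self):
        a = sim.random_particle(100, 30.0, seed=7)
        b = sim.random_particle(100, 30.0, seed=7)
        assert np.array_equal(a.coords, b.coords)

    def test_rms_radius_matches_uniform_ball(self):
        """Uniform ball: RMS radius = R * sqrt(3/5)."""
        p = sim.random_particle(1000, 50.0, seed=11)
        radii = np.linalg.norm(p.coords, axis=1)
        assert radii.max() <= 50.0
        expected = 50.0 * np.sqrt(3.0 / 5.0)
        assert abs(np.sqrt((radii**2).mean()) - expected) < 0.2 * expected

    @pytest.mark.parametrize("n_atoms, radius", [(0, 10.0), (5, -1.0)])
    def test_invalid_arguments_rejected(self, n_atoms, radius):
        with pytest.raises(ValueError):
            sim.random_particle(n_atoms, radius, seed=0)


class TestLoadPdb:
    def test_reads_atom_and_hetatm_records(self, pdb_fixture):
        p = sim.load_pdb_coordinates(pdb_fixture)
        assert p.n_atoms == 4
        assert np.allclose(p.coords[0], [1.0, 2.0, 3.0])
        assert np.allclose(p.coords[3], [0.0, 0.0, -1.0])
        assert np.all(p.weights == 1.0)

    def test_header_only_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    NOTHING HERE\nEND\n")
        with pytest.raises(ValueError, match="empty.pdb"):
            sim.load_pdb_coordinates(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises((ValueError, FileNotFoundError)):
            sim.load_pdb_coordinates(tmp_path / "nope.pdb")


class TestNonSampleHit:
    def test_deterministic_and_positive(self, geometry, beam):
        a = sim.simulate_non_sample_hit(geometry, beam, seed=3)
        b = sim.simulate_non_sample_hit(geometry, beam, seed=3)
        assert np.array_equal(a, b)
        assert a.sum() > 0
        assert np.all(a >= 0)

    def test_smoother_than_particle_speckle(self, geometry, beam, toy_particle):
        """Mean power above half-Nyquist is lower than for single-hits at
        matched total intensity (parasitic scattering is low-frequency)."""
        def high_band_power(img):
            f = np.abs(np.fft.fftshift(np.fft.fft2(img / img.sum()))) ** 2
            h, w = img.shape
            yy, xx = np.meshgrid(np.arange(h) - h // 2, np.arange(w) - w // 2,
                                 indexing="ij")
            band = np.sqrt(yy**2 + xx**2) > h / 4  # above Nyquist/2
            return f[band].mean()

        rng = np.random.default_rng(0)
        bg, hits = [], []
        for seed in range(30):
            bg.append(high_band_power(
                sim.simulate_non_sample_hit(geometry, beam, seed=seed)))
            quat = rng.normal(size=4)
            quat /= np.linalg.norm(quat)
            hits.append(high_band_power(sim.diffraction_intensity(
                [(toy_particle, quat, np.zeros(3))], geometry, beam)))
        assert np.mean(bg) < np.mean(hits)


class TestNoise:
    def test_poisson_of_zero_is_zero(self):
        assert np.array_equal(sim.apply_shot_noise(np.zeros((8, 8)), seed=0),
                              np.zeros((8, 8)))

    def test_poisson_preserves_mean_within_clt_bound(self):
        img = np.full((172, 172), 1e6)
        out = sim.apply_shot_noise(img, seed=1)
        assert abs(out.mean() - 1e6) < 0.01 * 1e6

    def test_poisson_rejects_negative_and_is_reproducible(self):
        with pytest.raises(ValueError):
            sim.apply_shot_noise(np.array([[-1.0]]), seed=0)
        img = np.full((16, 16), 50.0)
        assert np.array_equal(sim.apply_shot_noise(img, seed=5),
                              sim.apply_shot_noise(img, seed=5))

    def test_gaussian_noise_sigma_and_identity(self):
        img = np.zeros((172, 172))
        out = sim.apply_gaussian_noise(img, sigma=0.15, seed=2)
        assert abs((out - img).std() - 0.15) < 0.05 * 0.15
        assert np.array_equal(sim.apply_gaussian_noise(img, sigma=0.0, seed=2), img)

    def test_fluence_jitter_degenerate_and_lognormal_mean(self):
        img = np.ones((8, 8))
        out, m = sim.apply_fluence_jitter(img, lambda rng: 1.0, seed=0)
        assert m == 1.0 and np.array_equal(out, img)
        out, m = sim.apply_fluence_jitter(img, lambda rng: 2.0, seed=0)
        assert m == 2.0 and np.array_equal(out, 2 * img)
        dist = LogNormalJitter(median=1.0, sigma=0.5)
        rng = np.random.default_rng(3)
        draws = [dist(rng) for _ in range(10_000)]
        assert abs(np.mean(draws) - dist.mean) < 0.05 * dist.mean


class TestMasksCropNormalize:
    def test_default_mask_union_matches_rectangle_count(self, geometry):
        """Zeroed-pixel count equals the brute-force union of the 6x8 beam
        stop and the 172x4 gap rectangles."""
        masks = sim.default_masks(geometry)
        out = sim.apply_masks(np.ones((172, 172)), masks)
        explicit = set()
        r0, c0 = 86 - 3, 86 - 4
        for r in range(r0, r0 + 6):
            for c in range(c0, c0 + 8):
                explicit.add((r, c))
        for r in range(172):
            for c in range(84, 88):
                explicit.add((r, c))
        assert int((out == 0).sum()) == len(explicit)

    def test_empty_and_full_masks(self):
        img = np.arange(16.0).reshape(4, 4)
        zeros = np.zeros((4, 4), np.uint8)
        ms = MaskSet(beam_stop=zeros, gap=zeros)
        assert np.array_equal(sim.apply_masks(img, ms), img)
        ones = MaskSet(beam_stop=np.ones((4, 4), np.uint8), gap=zeros)
        assert np.array_equal(sim.apply_masks(img, ones, fill=7.0),
                              np.full((4, 4), 7.0))

    def test_mask_shape_mismatch_rejected(self):
        ms = sim.default_masks(DetectorGeometry())
        with pytest.raises(ValueError):
            sim.apply_masks(np.ones((10, 10)), ms)

    def test_center_crop_convention(self):
        img = np.arange(16.0).reshape(4, 4)
        out = sim.center_crop(img, 2)
        # window starts at floor((4-2)/2) = 1
        assert np.array_equal(out, img[1:3, 1:3])
        assert sim.center_crop(img, 4) is not None
        assert np.array_equal(sim.center_crop(img, 4), img)
        assert sim.center_crop(np.zeros((172, 172)), 96).shape == (96, 96)
        with pytest.raises(ValueError):
            sim.center_crop(img, 5)

    def test_normalize_scale_invariance_and_fallback(self, rng):
        img = rng.normal(10, 3, size=(32, 32))
        assert np.allclose(sim.normalize_intensity(2 * img),
                           sim.normalize_intensity(img))
        out = sim.normalize_intensity(img)
        assert abs(out.mean()) < 1e-10 and abs(out.std() - 1) < 1e-10
        assert np.array_equal(sim.normalize_intensity(np.full((4, 4), 3.0)),
                              np.zeros((4, 4)))

    def test_normalize_with_mask_uses_unmasked_pixels(self, rng):
        img = rng.normal(size=(16, 16))
        mask = np.zeros((16, 16), np.uint8)
        mask[:4] = 1
        out = sim.normalize_intensity(img, mask=mask)
        valid = out[~mask.astype(bool)]
        assert abs(valid.mean()) < 1e-10 and abs(valid.std() - 1) < 1e-10

    def test_ablation_mask_pixel_count(self):
        mask = sim.ablation_mask((96, 96), 0.25)
        assert int(mask.sum()) == 96 * 96 - 48 * 48  # floor(0.75 * 96 * 96)
        assert int(sim.ablation_mask((96, 96), 1.0).sum()) == 0


@pytest.fixture(scope="module")
def tiny_config():
    return DatasetConfig(
        geometry=DetectorGeometry(n_rows=48, n_cols=48),
        crop_size=32,
    )


class TestSimulateDataset:
    def test_balanced_counts(self, toy_particle, tiny_config):
        pats = sim.simulate_dataset(2, [SINGLE_HIT, MULTI_HIT], [toy_particle],
                                    seed=0, config=tiny_config)
        assert len(pats) == 4
        labels = [p.label for p in pats]
        assert labels.count(SINGLE_HIT) == 2 and labels.count(MULTI_HIT) == 2

    def test_deterministic_for_fixed_seed(self, toy_particle, tiny_config):
        a = sim.simulate_dataset(2, [SINGLE_HIT, NON_SAMPLE_HIT], [toy_particle],
                                 seed=3, config=tiny_config)
        b = sim.simulate_dataset(2, [SINGLE_HIT, NON_SAMPLE_HIT], [toy_particle],
                                 seed=3, config=tiny_config)
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)
            assert x.rng_seed == y.rng_seed

    def test_unknown_class_rejected(self, toy_particle, tiny_config):
        with pytest.raises(ValueError):
            sim.simulate_dataset(1, ["mystery"], [toy_particle], seed=0,
                                 config=tiny_config)

    def test_multi_hit_copy_proportions(self):
        """2/3/4-copy multi-hits drawn with equal probability."""
        rng = np.random.default_rng(0)
        counts = {2: 0, 3: 0, 4: 0}
        for _ in range(300):
            hc = sim.random_hit_config(MULTI_HIT, rng)
            counts[hc.copies] += 1
        # binomial(300, 1/3): 3.5 sigma band is +-28.6 around 100
        for k in (2, 3, 4):
            assert 70 <= counts[k] <= 130

    def test_hit_config_invariants(self):
        with pytest.raises(ValueError):
            HitConfig(hit_class=SINGLE_HIT, copies=2,
                      orientations=np.tile(IDENTITY_Q, (2, 1)),
                      displacements=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            HitConfig(hit_class=NON_SAMPLE_HIT, copies=1,
                      orientations=IDENTITY_Q[None], displacements=np.zeros((1, 3)))
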