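import numpy as np
import pytest

from isosim import (
    KSpace,
    ParallelConfig,
    Phantom,
    RFPulse,
    SequenceEvent,
    SpinEchoConfig,
    TissueParams,
    acquire_sample,
    make_sphere_phantom,
    make_uniform_phantom,
    partition_isochromats,
    reconstruct,
    reduce_signals,
    run_events,
    simulate,
    spawn_isochromats,
)
from isosim.engine import IsochromatSet
from isosim.physics import GAMMA_HYDROGEN

B0 = 1.5


def make_iso(positions, m0=1.0, t1=np.inf, t2=np.inf, db=0.0):
    positions = np.atleast_2d(positions)
    n = len(positions)
    return IsochromatSet(
        positions, np.zeros(n, int), np.full(n, m0), np.full(n, t1),
        np.full(n, t2), np.full(n, db),
    )


class TestSpawn:
    def test_one_isochromat_per_voxel_tissue(self, gel_tissue):
        ph = make_uniform_phantom((2, 2, 1), 1e-3, [gel_tissue], [1.0])
        iso = spawn_isochromats(ph, 1)
        assert len(iso) == 4
        np.testing.assert_array_equal(iso.m[:, :2], 0)
        np.testing.assert_array_equal(iso.m[:, 2], iso.m0)

    def test_partial_volume_m0_ratio(self, gel_tissue):
        other = TissueParams("b", rho=1.0, t1=1.0, t2=0.1)
        fr = np.zeros((2, 1, 1, 1))
        fr[0], fr[1] = 0.3, 0.7
        ph = Phantom((1, 1, 1), (1e-3,) * 3, [gel_tissue, other], fr)
        iso = spawn_isochromats(ph, 1)
        assert len(iso) == 2
        m0 = sorted(iso.m0)
        assert m0[1] / m0[0] == pytest.approx(7 / 3, rel=1e-12)

    def test_subvoxel_split_conserves_equilibrium_magnetization(self, gel_tissue):
        ph = make_sphere_phantom((4, 4, 1), 1e-3, (1.5, 1.5, 0), 1.2, gel_tissue,
                                 supersample=2)
        total1 = spawn_isochromats(ph, 1).m0.sum()
        iso8 = spawn_isochromats(ph, 8)
        assert iso8.m0.sum() == pytest.approx(total1, rel=1e-12)
        assert len(iso8) == 8 * len(spawn_isochromats(ph, 1))

    def test_non_cube_subdivision_rejected(self, gel_tissue):
        ph = make_uniform_phantom((2, 2, 1), 1e-3, [gel_tissue], [1.0])
        with pytest.raises(ValueError):
            spawn_isochromats(ph, 3)


class TestAcquireSample:
    def test_sums_quadrature_components(self):
        iso = make_iso(np.zeros((3, 3)))
        iso.m[:] = [1.0, 0.0, 0.0]
        assert acquire_sample(iso) == 3 + 0j
        iso.m[0] = [1, 0, 0]
        iso.m[1] = [-1, 0, 0]
        iso.m[2] = [0, 0, 1]
        assert acquire_sample(iso) == 0j
        one = make_iso([[0, 0, 0]])
        one.m[0] = [0.5, -0.25, 0.0]
        assert acquire_sample(one) == 0.5 - 0.25j


class TestRunEvents:
    def _fid_events(self, n, dwell, gradients=(0.0, 0.0, 0.0)):
        return [
            SequenceEvent("rf", rf=RFPulse.hard(np.pi / 2, 1e-6, b_target=B0)),
            SequenceEvent("acquire", duration=n * dwell, gradients=gradients,
                          n_samples=n, dwell=dwell),
        ]

    def test_isocenter_fid_has_constant_magnitude(self):
        iso = make_iso([[0.0, 0.0, 0.0]], m0=0.7)
        rows = run_events(iso, self._fid_events(8, 1e-4), B0)
        np.testing.assert_allclose(np.abs(rows[0]), 0.7, rtol=1e-12)

    def test_fid_envelope_decays_with_t2(self):
        t2, dwell, n = 0.05, 1e-3, 16
        iso = make_iso([[0.0, 0.0, 0.0]], m0=1.0, t1=1.0, t2=t2)
        rows = run_events(iso, self._fid_events(n, dwell), B0)
        t = np.arange(n) * dwell  # sample k recorded after k dwells
        np.testing.assert_allclose(np.abs(rows[0]), np.exp(-t / t2), rtol=1e-10)

    def test_symmetric_pair_gives_real_cosine_readout(self):
        """Two spins at +/-x under a readout gradient beat as a cosine."""
        x0, g, dwell, n = 2e-3, 5e-3, 2e-5, 16
        iso = make_iso([[x0, 0, 0], [-x0, 0, 0]])
        rows = run_events(iso, self._fid_events(n, dwell, (g, 0.0, 0.0)), B0)
        total = rows.sum(axis=0)
        t = np.arange(n) * dwell
        expected = 2j * np.cos(GAMMA_HYDROGEN * g * x0 * t)
        np.testing.assert_allclose(total, expected, atol=1e-10)


class TestPartition:
    @pytest.mark.parametrize(
        "n,managers,workers,sizes",
        [
            (10, 1, 4, (3, 3, 2, 2)),
            (8, 2, 4, (2, 2, 2, 2)),
            (7, 1, 8, (1, 1, 1, 1, 1, 1, 1, 0)),
            (10, 2, 4, (3, 2, 3, 2)),
        ],
    )
    def test_even_split_rule(self, n, managers, workers, sizes):
        part = partition_isochromats(n, managers, workers)
        got = tuple(b - a for a, b in part.ranges)
        assert got == sizes
        # disjoint, covering, contiguous
        flat = [i for a, b in part.ranges for i in range(a, b)]
        assert flat == list(range(n))

    def test_non_divisible_worker_count_rejected(self):
        with pytest.raises(ValueError):
            partition_isochromats(10, 3, 4)


class TestReduce:
    def test_single_worker_identity(self):
        part = partition_isochromats(3, 1, 1)
        rows = np.arange(6, dtype=complex).reshape(3, 2)
        np.testing.assert_array_equal(reduce_signals([rows], part), rows.sum(axis=0))

    def test_linearity_across_workers(self):
        rng = np.random.default_rng(1)
        full = rng.standard_normal((8, 5)) + 1j * rng.standard_normal((8, 5))
        part = partition_isochromats(8, 2, 4)
        split = [full[a:b] for a, b in part.ranges]
        np.testing.assert_allclose(
            reduce_signals(split, part), full.sum(axis=0), rtol=1e-10
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reduce_signals([np.ones((2, 3)), np.ones((2, 4))])


class TestReconstruct:
    def test_zero_kspace_gives_zero_image(self):
        img, mag = reconstruct(np.zeros((8, 8), complex))
        assert np.all(mag == 0)

    def test_dc_delta_gives_constant_magnitude(self):
        k = np.zeros((8, 8), complex)
        k[4, 4] = 1.0  # DC at matrix center
        _, mag = reconstruct(k)
        np.testing.assert_allclose(mag, mag[0, 0], rtol=1e-12)

    def test_parseval(self):
        rng = np.random.default_rng(2)
        k = rng.standard_normal((8, 4)) + 1j * rng.standard_normal((8, 4))
        img, _ = reconstruct(k)
        assert np.sum(np.abs(k) ** 2) == pytest.approx(
            k.size * np.sum(np.abs(img) ** 2), rel=1e-12
        )


class TestSimulate:
    def test_empty_phantom_gives_zero_image(self, gel_tissue):
        ph = make_sphere_phantom((8, 8, 1), 1e-3, (4, 4, 0), 0, gel_tissue)
        cfg = SpinEchoConfig(te=0.01, tr=0.1, matrix=(8, 8), fov=0.008)
        res = simulate(ph, cfg)
        assert np.all(res.magnitude == 0)

    def test_parallel_runs_bit_identical(self, small_sphere_phantom):
        cfg = SpinEchoConfig(te=0.02, tr=0.2, matrix=(16, 16), fov=0.016)
        ref = simulate(small_sphere_phantom, cfg,
                       parallel=ParallelConfig(1, 1)).kspace.data
        for managers, workers in [(1, 4), (2, 4)]:
            k = simulate(small_sphere_phantom, cfg,
                         parallel=ParallelConfig(managers, workers)).kspace.data
            np.testing.assert_array_equal(ref, k)

    def test_isochromat_summation_is_additive(self, gel_tissue):
        """Disjoint objects simulate to the sum of their k-spaces."""
        other = TissueParams("b", rho=0.6, t1=0.9, t2=0.1)
        a = make_sphere_phantom((16, 16, 1), 1e-3, (4.5, 7.5, 0), 2.5, gel_tissue)
        b = make_sphere_phantom((16, 16, 1), 1e-3, (11.5, 7.5, 0), 2.5, other)
        fr = np.concatenate([a.fractions, b.fractions])
        union = Phantom((16, 16, 1), (1e-3,) * 3, [gel_tissue, other], fr)
        cfg = SpinEchoConfig(te=0.02, tr=0.2, matrix=(16, 16), fov=0.016)
        ka = simulate(a, cfg).kspace.data
        kb = simulate(b, cfg).kspace.data
        ku = simulate(union, cfg).kspace.data
        np.testing.assert_allclose(ku, ka + kb, rtol=1e-10, atol=1e-12)

    def test_seeded_noise_is_reproducible(self, small_sphere_phantom):
        cfg = SpinEchoConfig(te=0.02, tr=0.2, matrix=(16, 16), fov=0.016)
        a = simulate(small_sphere_phantom, cfg, noise_sigma=0.1, seed=5).kspace.data
        b = simulate(small_sphere_phantom, cfg, noise_sigma=0.1, seed=5).kspace.data
        c = simulate(small_sphere_phantom, cfg, noise_sigma=0.1, seed=6).kspace.data
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_kspace_validation_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            KSpace(np.array([[np.inf + 0j]]), (1.0,))
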