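"""Stokes conversion, noise estimation and noise-corrected DOPU."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import choromel as cm
from choromel import polarimetry as P

from conftest import uniform_block


def _single_voxel(h, v):
    return cm.JonesVolume(
        h=np.full((1, 1, 1), h, dtype=np.complex128),
        v=np.full((1, 1, 1), v, dtype=np.complex128),
        dz=1.0,
        dx=1.0,
        dy=1.0,
    )


class TestJonesToStokes:
    @pytest.mark.parametrize(
        "h,v,expected",
        [
            (1.0, 0.0, (1.0, 1.0, 0.0, 0.0)),  # horizontal linear
            (2**-0.5, 1j * 2**-0.5, (1.0, 0.0, 0.0, 1.0)),  # circular
            (2**-0.5, 2**-0.5, (1.0, 0.0, 1.0, 0.0)),  # 45° linear
        ],
    )
    def test_known_states(self, h, v, expected):
        s = P.jones_to_stokes(_single_voxel(h, v))
        got = (s.i[0, 0, 0], s.q[0, 0, 0], s.u[0, 0, 0], s.v[0, 0, 0])
        assert got == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_pure_state_identity(self, seed):
        """For any pure state, I² = Q² + U² + V² to floating precision."""
        rng = np.random.default_rng(seed)
        g = rng.standard_normal((4, 3, 3, 3))
        jones = cm.JonesVolume(
            h=g[0] + 1j * g[1], v=g[2] + 1j * g[3], dz=1.0, dx=1.0, dy=1.0
        )
        s = P.jones_to_stokes(jones)
        lhs = s.i**2
        rhs = s.q**2 + s.u**2 + s.v**2
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            _single_voxel(np.nan, 0.0)


class TestEstimateNoise:
    def test_zero_noise_volume(self):
        jones = uniform_block(power=None)
        zeros = cm.JonesVolume(
            h=np.zeros_like(jones.h), v=np.zeros_like(jones.v), dz=1, dx=1, dy=1
        )
        est = P.estimate_noise(zeros, region=(slice(None),) * 3)
        assert est.n_h == 0.0 and est.n_v == 0.0

    def test_recovers_known_powers(self):
        rng = np.random.default_rng(7)
        shape = (25, 20, 20)  # 10^4 voxels
        h = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * np.sqrt(1.0 / 2)
        v = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * np.sqrt(0.5 / 2)
        est = P.estimate_noise(
            cm.JonesVolume(h=h, v=v, dz=1, dx=1, dy=1), region=(slice(None),) * 3
        )
        assert est.n_h == pytest.approx(1.0, rel=0.05)
        assert est.n_v == pytest.approx(0.5, rel=0.05)

    def test_small_region_rejected(self):
        jones = uniform_block()
        with pytest.raises(ValueError, match="voxels"):
            P.estimate_noise(jones, region=(slice(0, 1), slice(0, 5), slice(0, 2)))


class TestComputeDopu:
    def test_uniform_pure_state_gives_exactly_one(self):
        """Spatially uniform pure states: DOPU is exactly 1 at every voxel."""
        d = P.compute_dopu(P.jones_to_stokes(uniform_block(state=(1, 0))))
        assert d.valid.all()
        assert (d.dopu == 1.0).all()

    def test_speckled_uniform_state_unity(self):
        """Fully developed speckle with a shared state still gives DOPU 1:
        per-voxel normalized Stokes vectors are identical."""
        d = P.compute_dopu(P.jones_to_stokes(uniform_block(state=(1, 0), power=0.5, seed=3)))
        assert np.allclose(d.dopu[d.valid], 1.0, atol=1e-6)

    def test_hand_computed_mixed_kernel(self):
        """3×3 kernel with 4 voxels at Q=+1 and 5 at Q=−1 → DOPU = 1/9."""
        h = np.zeros((3, 3, 1), dtype=np.complex128)
        v = np.zeros_like(h)
        flat = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float).reshape(3, 3, 1)
        h[flat == 1] = 1.0  # (I,Q,U,V) = (1,1,0,0)
        v[flat == 0] = 1.0  # (I,Q,U,V) = (1,-1,0,0)
        d = P.compute_dopu(P.jones_to_stokes(cm.JonesVolume(h=h, v=v, dz=1, dx=1, dy=1)))
        assert d.dopu[1, 1, 0] == pytest.approx(1 / 9, rel=1e-12)

    def test_noise_correction_beats_uncorrected_across_snr(self):
        """|E[corrected]−1| < |E[uncorrected]−1| at per-channel SNR 5..30."""
        for snr in (5, 10, 20, 30):
            jones = uniform_block(state=(1, 1), shape=(48, 48, 16), power=0.5, seed=100 + snr)
            n = 0.25 / snr
            rng = np.random.default_rng(200 + snr)
            g = rng.standard_normal((4,) + jones.shape)
            noisy = cm.JonesVolume(
                h=jones.h + (g[0] + 1j * g[1]) * np.sqrt(n / 2),
                v=jones.v + (g[2] + 1j * g[3]) * np.sqrt(n / 2),
                dz=1,
                dx=1,
                dy=1,
            )
            s = P.jones_to_stokes(noisy)
            bias_c = abs(P.compute_dopu(s, noise=P.NoiseEstimate(n, n)).dopu.mean() - 1)
            bias_u = abs(P.compute_dopu(s, noise=P.NoiseEstimate(0, 0)).dopu.mean() - 1)
            assert bias_c < bias_u
            if snr == 10:
                assert bias_u / bias_c >= 2.0

    def test_depolarizing_kernel_mean_decreases_with_kernel_size(self):
        """Independent random states: larger kernels average more states,
        so mean DOPU drops (Monte-Carlo, fixed seed)."""
        rng = np.random.default_rng(5)
        shape = (40, 40, 4)
        g = rng.standard_normal((4,) + shape)
        a, b = g[0] + 1j * g[1], g[2] + 1j * g[3]
        norm = np.sqrt(np.abs(a) ** 2 + np.abs(b) ** 2)
        jones = cm.JonesVolume(h=a / norm, v=b / norm, dz=1, dx=1, dy=1)
        s = P.jones_to_stokes(jones)
        m3 = P.compute_dopu(s, P.DOPUKernel(1, 1)).dopu.mean()
        m5 = P.compute_dopu(s, P.DOPUKernel(2, 2)).dopu.mean()
        assert m5 < m3 < 1.0

    def test_dopu_bounded_any_input(self):
        rng = np.random.default_rng(17)
        g = rng.standard_normal((4, 10, 10, 5)) * 10
        s = P.jones_to_stokes(cm.JonesVolume(h=g[0] + 1j * g[1], v=g[2] + 1j * g[3], dz=1, dx=1, dy=1))
        d = P.compute_dopu(s, noise=P.NoiseEstimate(0.5, 0.5))
        vals = d.dopu[d.valid]
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_bscan_permutation_equivariance(self):
        jones = uniform_block(state=(1, 1j), shape=(12, 12, 6), power=1.0, seed=9)
        s = P.jones_to_stokes(jones)
        d = P.compute_dopu(s).dopu
        perm = np.array([3, 1, 5, 0, 2, 4])
        s_perm = P.jones_to_stokes(
            cm.JonesVolume(h=jones.h[:, :, perm], v=jones.v[:, :, perm], dz=1, dx=1, dy=1)
        )
        d_perm = P.compute_dopu(s_perm).dopu
        np.testing.assert_array_equal(d_perm, d[:, :, perm])

    def test_kernel_larger_than_volume_rejected(self):
        s = P.jones_to_stokes(uniform_block(shape=(2, 2, 2)))
        with pytest.raises(ValueError, match="kernel"):
            P.compute_dopu(s, P.DOPUKernel(4, 4))


class TestBinarizeDopu:
    def test_threshold_is_strict(self):
        d = cm.DOPUVolume(
            dopu=np.array([[[0.79, 0.80, 0.81]]]),
            valid=np.array([[[True, True, True]]]),
            dz=1,
            dx=1,
            dy=1,
        )
        low = P.binarize_dopu(d, 0.8)
        assert low.tolist() == [[[True, False, False]]]

    def test_invalid_voxels_never_low(self):
        d = cm.DOPUVolume(
            dopu=np.array([[[0.1, 0.1]]]),
            valid=np.array([[[True, False]]]),
            dz=1,
            dx=1,
            dy=1,
        )
        assert P.binarize_dopu(d).tolist() == [[[True, False]]]

    def test_threshold_domain(self):
        d = cm.DOPUVolume(dopu=np.zeros((1, 1, 1)), valid=np.ones((1, 1, 1), bool), dz=1, dx=1, dy=1)
        with pytest.raises(ValueError):
            P.binarize_dopu(d, 0.0)
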