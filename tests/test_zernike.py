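import numpy as np
import pytest
from scipy.special import sph_harm_y

from affinet.synthetic import gen_structure_coords, random_rotation
from affinet.zernike import (
    VoxelGrid,
    compute_descriptors,
    radial_polynomial,
    valid_nl,
    voxelize,
    zernike_invariants,
    zernike_moments,
)


class TestBasis:
    @pytest.mark.parametrize("n_max,expected", [(0, 1), (1, 2), (2, 4), (20, 121)])
    def test_valid_pair_count(self, n_max, expected):
        pairs = valid_nl(n_max)
        assert len(pairs) == expected
        # closed form: sum over n of (floor(n/2) + 1)
        assert len(pairs) == sum(n // 2 + 1 for n in range(n_max + 1))
        for n, l in pairs:
            assert 0 <= l <= n and (n - l) % 2 == 0

    def test_radial_orthonormality(self):
        """integral_0^1 R_nl R_n'l r^2 dr = delta_nn' (Gauss quadrature)."""
        x, w = np.polynomial.legendre.leggauss(64)
        r = 0.5 * (x + 1)
        w = 0.5 * w
        for l in (0, 1, 2):
            for n1 in range(l, 9, 2):
                for n2 in range(l, 9, 2):
                    val = np.sum(
                        w
                        * radial_polynomial(n1, l, r)
                        * radial_polynomial(n2, l, r)
                        * r**2
                    )
                    assert val == pytest.approx(1.0 if n1 == n2 else 0.0, abs=1e-10)

    def test_invalid_nl_rejected(self):
        with pytest.raises(ValueError):
            radial_polynomial(3, 0, np.array([0.5]))  # n - l odd


class TestVoxelize:
    def test_single_atom_density_peaks_centrally(self):
        g = voxelize(np.array([[3.0, -1.0, 2.0]]), grid_size=16)
        peak = np.unravel_index(np.argmax(g.values), g.values.shape)
        center = (7, 7, 8)  # centroid maps to the grid middle
        assert all(abs(p - c) <= 1 for p, c in zip(peak, center))
        assert g.values.min() >= 0

    def test_translation_invariance_exact(self, helix_cloud):
        a = voxelize(helix_cloud, grid_size=16)
        b = voxelize(helix_cloud + np.array([12.0, -5.0, 3.0]), grid_size=16)
        np.testing.assert_allclose(a.values, b.values, rtol=0, atol=1e-12)

    def test_total_mass_positive(self, helix_cloud):
        g = voxelize(helix_cloud, grid_size=16)
        assert g.values.sum() > 0

    def test_parameter_validation(self):
        pts = np.zeros((2, 3))
        with pytest.raises(ValueError):
            voxelize(pts, grid_size=8)
        with pytest.raises(ValueError):
            voxelize(pts, gaussian_width=0)
        with pytest.raises(ValueError):
            voxelize(pts, scale_radius=1.5)


def _bruteforce_moments(grid: VoxelGrid, n_max: int):
    """Independent quadrature: plain loop over voxels, explicit Z_nlm."""
    G = grid.grid_size
    edges = np.linspace(-1.0, 1.0, G + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    dv = (mids[1] - mids[0]) ** 3
    out = {}
    for n, l in valid_nl(n_max):
        for m in range(-l, l + 1):
            acc = 0.0 + 0.0j
            for i in range(G):
                for j in range(G):
                    for k in range(G):
                        f = grid.values[i, j, k]
                        if f == 0.0:
                            continue
                        x, y, z = mids[i], mids[j], mids[k]
                        r = np.sqrt(x * x + y * y + z * z)
                        if r > 1.0:
                            continue
                        theta = np.arccos(z / r) if r > 0 else 0.0
                        phi = np.arctan2(y, x)
                        Z = radial_polynomial(n, l, r) * sph_harm_y(
                            l, m, theta, phi
                        )
                        acc += f * np.conj(Z)
            out[(n, l, m)] = acc * dv
    return out


class TestMoments:
    def test_agrees_with_bruteforce_oracle(self, helix_cloud):
        grid = voxelize(helix_cloud[:10], grid_size=16)
        n_max = 3
        fast = zernike_moments(grid, n_max)
        slow = _bruteforce_moments(grid, n_max)
        scale = max(abs(v) for v in slow.values())
        for (n, l, m), v in slow.items():
            assert abs(fast[(n, l, m)] - v) <= 1e-10 * scale

    def test_spherical_symmetry_kills_higher_harmonics(self):
        grid = voxelize(np.zeros((3, 3)), grid_size=24)  # one centred Gaussian
        mom = zernike_moments(grid, 6)
        c000 = abs(mom[(0, 0, 0)])
        for (n, l), arr in mom.moments.items():
            if l > 0:
                assert np.abs(arr).max() < 5e-2 * c000

    def test_zero_density_gives_zero_moments(self):
        grid = VoxelGrid(
            values=np.zeros((16, 16, 16)), center=np.zeros(3), scale=1.0,
            gaussian_width=1.0,
        )
        mom = zernike_moments(grid, 4)
        assert all(np.all(a == 0) for a in mom.moments.values())

    def test_conjugate_symmetry_of_real_density(self, helix_cloud):
        grid = voxelize(helix_cloud, grid_size=16)
        mom = zernike_moments(grid, 4, use_symmetry=False)
        for (n, l), arr in mom.moments.items():
            for m in range(l + 1):
                assert arr[l - m] == pytest.approx(
                    (-1) ** m * np.conj(arr[l + m]), abs=1e-12
                )


class TestInvariants:
    def test_vector_lengths(self, helix_cloud):
        assert len(compute_descriptors(helix_cloud, grid_size=16, n_max=20)) == 121
        assert len(compute_descriptors(helix_cloud, grid_size=16, n_max=0)) == 1

    def test_nonnegative(self, helix_cloud):
        d = compute_descriptors(helix_cloud, grid_size=16, n_max=8)
        assert (d >= 0).all()

    def test_rotation_invariance_over_100_rotations(self, helix_cloud):
        """Descriptors drift <= 1% relative under rigid rotation (grid bound)."""
        G = 64
        d0 = compute_descriptors(helix_cloud, grid_size=G)
        floor = 1e-3 * d0.max()
        mask = d0 > floor
        worst = 0.0
        for i in range(100):
            R = random_rotation(seed=1000 + i)
            d = compute_descriptors(helix_cloud @ R.T, grid_size=G)
            worst = max(worst, np.max(np.abs(d[mask] - d0[mask]) / d0[mask]))
        assert worst <= 1e-2

    def test_refinement_convergence(self, helix_cloud):
        """Descriptors at successive grid resolutions agree within 5%."""
        d32 = compute_descriptors(helix_cloud, grid_size=32)
        d64 = compute_descriptors(helix_cloud, grid_size=64)
        mask = d64 > 1e-3 * d64.max()
        assert np.max(np.abs(d32[mask] - d64[mask]) / d64[mask]) <= 0.05
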