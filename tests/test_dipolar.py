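"""hcp shell geometry, point-dipole energy sums and the mean-field sampler."""

import numpy as np
import pytest

from spasim import dipolar as dp
from spasim.core import MU0


def brute_force_pair_sum(center_m, positions, moments):
    """Independent oracle: explicit loop over the 12 pair energies."""
    total = 0.0
    for r, m in zip(positions, moments):
        dist = float(np.sqrt(r @ r))
        rhat = r / dist
        total += (
            MU0
            / (4 * np.pi)
            * (center_m @ m - 3 * (center_m @ rhat) * (m @ rhat))
            / dist**3
        )
    return total


def pair_energy_scale(moment, distance):
    """|E| of a head-to-tail pair: the natural scale for E_i."""
    return MU0 * moment**2 / (2 * np.pi * distance**3)


class TestHcpShell:
    def test_twelve_equidistant_neighbors(self):
        pos = dp.hcp_neighbor_positions(25e-9, 5e-9)
        assert pos.shape == (12, 3)
        dists = np.linalg.norm(pos, axis=1)
        np.testing.assert_allclose(dists, 30e-9, rtol=1e-12)

    def test_shell_vector_sum_vanishes(self):
        pos = dp.hcp_neighbor_positions(25e-9, 5e-9)
        np.testing.assert_allclose(pos.sum(axis=0), 0.0, atol=1e-22)

    def test_direction_tensor_is_isotropic(self):
        # sum of rhat rhat^T = 4 I is the geometric reason E_i = 0
        pos = dp.hcp_neighbor_positions(10e-9, 0.0)
        rhat = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        np.testing.assert_allclose(rhat.T @ rhat, 4 * np.eye(3), atol=1e-12)


class TestClusterEnergy:
    def test_head_to_tail_pair_matches_textbook_value(self):
        m = 2.2e-18
        r = 30e-9
        e = dp.dipole_pair_energy(
            np.array([0, 0, m]), np.array([0, 0, m]), np.array([0, 0, r])
        )
        assert e == pytest.approx(-MU0 * m**2 / (2 * np.pi * r**3), rel=1e-12)

    @pytest.mark.parametrize(
        "direction", [(0, 0, 1), (1, 0, 0), (0.3, -0.5, 0.81), (1, 1, 1)]
    )
    def test_ideal_hcp_parallel_moments_energy_vanishes(self, direction):
        geo = dp.build_cluster(
            25e-9, 5e-9, moment_magnitude=2.2e-18, moment_direction=direction
        )
        scale = pair_energy_scale(2.2e-18, 30e-9)
        assert abs(dp.cluster_energy(geo)) < 1e-6 * scale

    def test_matches_brute_force_oracle_on_random_clusters(self, rng):
        for _ in range(10):
            geo = dp.build_cluster(
                25e-9,
                5e-9,
                moment_magnitude=2.2e-18,
                moment_direction=rng.normal(size=3),
                distortion_sd=0.1,
                d_sd=5e-9,
                rng=rng,
            )
            expected = brute_force_pair_sum(
                geo.center_moment, geo.neighbor_positions, geo.neighbor_moments
            )
            assert dp.cluster_energy(geo) == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_global_rotation(self, rng):
        from scipy.spatial.transform import Rotation

        geo = dp.build_cluster(
            25e-9, 5e-9, moment_magnitude=2.2e-18, distortion_sd=0.05, rng=rng
        )
        e0 = dp.cluster_energy(geo)
        rot = Rotation.random(random_state=7).as_matrix()
        rotated = dp.ClusterGeometry(
            center_moment=rot @ geo.center_moment,
            neighbor_positions=geo.neighbor_positions @ rot.T,
            neighbor_moments=geo.neighbor_moments @ rot.T,
        )
        assert dp.cluster_energy(rotated) == pytest.approx(e0, rel=1e-9)

    def test_inverse_cube_dilation_scaling(self, rng):
        geo = dp.build_cluster(
            25e-9, 5e-9, moment_magnitude=2.2e-18, distortion_sd=0.05, rng=rng
        )
        dilated = dp.ClusterGeometry(
            center_moment=geo.center_moment,
            neighbor_positions=2.0 * geo.neighbor_positions,
            neighbor_moments=geo.neighbor_moments,
        )
        assert dp.cluster_energy(dilated) == pytest.approx(
            dp.cluster_energy(geo) / 8.0, rel=1e-12
        )

    def test_mean_abs_energy_grows_with_distortion(self):
        def mean_abs(distortion, n=200):
            rng = np.random.default_rng(11)
            return np.mean(
                [
                    abs(
                        dp.cluster_energy(
                            dp.build_cluster(
                                25e-9,
                                5e-9,
                                moment_magnitude=2.2e-18,
                                distortion_sd=distortion,
                                rng=rng,
                            )
                        )
                    )
                    for _ in range(n)
                ]
            )

        levels = [mean_abs(s) for s in (0.02, 0.05, 0.1)]
        assert levels[0] < levels[1] < levels[2]

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            dp.dipole_pair_energy(
                np.ones(3), np.ones(3), np.zeros(3)
            )


class TestInteractionFieldSampler:
    def test_zero_coupling_gives_zeros(self):
        cfg = dp.DipolarConfig(coupling_min=0.0, coupling_max=0.0, seed=1)
        np.testing.assert_array_equal(
            dp.sample_interaction_field(cfg, 20e3, 100), np.zeros(100)
        )

    def test_mean_magnitude_converges_to_coupling_fraction(self):
        cfg = dp.DipolarConfig(coupling_min=0.03, coupling_max=0.03, seed=2)
        samples = dp.sample_interaction_field(cfg, 20e3, 50_000)
        assert np.abs(samples).mean() == pytest.approx(0.6e3, rel=1e-6)
        # signs are balanced
        assert abs(np.sign(samples).mean()) < 0.02

    def test_default_range_mean(self):
        cfg = dp.DipolarConfig(seed=3)  # 2-5% of H0
        samples = np.abs(dp.sample_interaction_field(cfg, 20e3, 50_000))
        assert samples.mean() == pytest.approx(0.035 * 20e3, rel=2e-2)
        assert samples.min() >= 0.02 * 20e3
        assert samples.max() <= 0.05 * 20e3

    def test_seed_determinism(self):
        cfg = dp.DipolarConfig(seed=42)
        a = dp.sample_interaction_field(cfg, 20e3, 1000)
        b = dp.sample_interaction_field(cfg, 20e3, 1000)
        np.testing.assert_array_equal(a, b)

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError):
            dp.DipolarConfig(coupling_min=0.5, coupling_max=0.2)
        with pytest.raises(ValueError):
            dp.DipolarConfig(coupling_min=0.0, coupling_max=1.5)
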