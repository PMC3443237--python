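"""Sphere forward model and the group dipole simulator."""

import numpy as np
import pytest

from peakclust import (SimulationConfig, default_sensor_array, dipole_field,
                       mni_to_head_m, simulate_participant, sphere_leadfield)
from peakclust.simulate import MNI_OFFSET_MM, draw_source, head_m_to_mni

MU0_OVER_4PI = 1e-7


def radial_projection_oracle(loc_m, q, sensors):
    """Independent oracle: volume currents in a conducting sphere contribute no
    radial field, so a radial magnetometer sees exactly the primary-current
    (infinite-medium Biot-Savart) dipole field projected on the radial direction.
    """
    out = np.empty(sensors.n_channels)
    for s in range(sensors.n_channels):
        r = sensors.positions[s] - sensors.sphere_center
        a = r - (np.asarray(loc_m) - sensors.sphere_center)
        b_primary = MU0_OVER_4PI * np.cross(q, a) / np.linalg.norm(a) ** 3
        out[s] = b_primary @ sensors.orientations[s]
    return out


@pytest.fixture(scope="module")
def sensors():
    return default_sensor_array()


class TestSensorArray:
    def test_geometry(self, sensors):
        assert sensors.n_channels == 275
        np.testing.assert_allclose(np.linalg.norm(sensors.positions, axis=1),
                                   0.12, rtol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(sensors.orientations, axis=1),
                                   1.0, rtol=1e-9)
        # helmet-like cap: all sensors above the lower cutoff
        assert sensors.positions[:, 2].min() > -0.35 * 0.12 - 1e-9
        assert sensors.positions[:, 2].max() > 0.95 * 0.12


class TestSphereLeadfield:
    def test_central_dipole_is_silent(self, sensors):
        centre_mni = head_m_to_mni(sensors.sphere_center)
        field = dipole_field(centre_mni, [0.0, 1e-8, 0.0], sensors)
        np.testing.assert_allclose(field, 0.0, atol=1e-30)

    def test_radial_dipole_is_silent(self, sensors):
        loc_m = sensors.sphere_center + np.array([0.03, 0.02, 0.04])
        radial_moment = 1e-8 * (loc_m - sensors.sphere_center)
        radial_moment /= np.linalg.norm(loc_m - sensors.sphere_center)
        field = dipole_field(head_m_to_mni(loc_m), radial_moment, sensors)
        assert np.max(np.abs(field)) < 1e-25

    def test_location_outside_sphere_rejected(self, sensors):
        with pytest.raises(ValueError):
            sphere_leadfield(head_m_to_mni([0.2, 0.0, 0.0]), sensors)
        with pytest.raises(ValueError):
            sphere_leadfield(head_m_to_mni(sensors.sphere_center), sensors)

    @pytest.mark.parametrize("seed", range(5))
    def test_gains_match_independent_radial_formula(self, sensors, seed):
        rng = np.random.default_rng(seed)
        loc_m = rng.uniform(-0.04, 0.04, 3)
        gains, basis = sphere_leadfield(head_m_to_mni(loc_m), sensors)
        for j in range(2):
            oracle = radial_projection_oracle(loc_m, basis[j], sensors)
            np.testing.assert_allclose(gains[:, j], oracle, rtol=1e-10)

    def test_basis_tangential_and_orthonormal(self, sensors):
        loc_m = np.array([0.02, -0.01, 0.03])
        _, basis = sphere_leadfield(head_m_to_mni(loc_m), sensors)
        radial = loc_m - sensors.sphere_center
        np.testing.assert_allclose(basis @ radial, 0.0, atol=1e-12)
        np.testing.assert_allclose(basis @ basis.T, np.eye(2), atol=1e-12)

    def test_field_linear_in_moment(self, sensors):
        loc = head_m_to_mni([0.02, 0.01, 0.02])
        q = np.array([0.0, 1e-8, 1e-8])
        f1 = dipole_field(loc, q, sensors)
        f2 = dipole_field(loc, 2.0 * q, sensors)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)


class TestSimulateParticipant:
    def test_pure_noise_sample_sd_matches_density_times_root_bandwidth(self,
                                                                       sensors):
        cfg = SimulationConfig(moment_nam=0.0)
        data, _ = simulate_participant(cfg, np.random.default_rng(0), sensors)
        # 10 fT/sqrt(Hz) * sqrt(80 Hz) = 89.44 fT per sample
        sd = data.data.std()
        assert sd == pytest.approx(10e-15 * np.sqrt(80.0), rel=0.01)

    def test_epoch_structure(self, sensors):
        cfg = SimulationConfig()
        data, _ = simulate_participant(cfg, np.random.default_rng(1), sensors)
        assert data.data.shape == (60, 275, 40)
        assert data.active.sum() == 30

    def test_passive_epochs_are_pure_noise(self, sensors):
        # same seed with and without a source: passive epochs are identical
        silent, _ = simulate_participant(SimulationConfig(moment_nam=0.0),
                                         np.random.default_rng(7), sensors)
        loud, _ = simulate_participant(SimulationConfig(moment_nam=100.0),
                                       np.random.default_rng(7), sensors)
        passive = ~loud.active
        np.testing.assert_array_equal(loud.data[passive], silent.data[passive])
        assert np.abs(loud.data[loud.active] -
                      silent.data[loud.active]).max() > 0

    def test_deterministic_under_seed(self, sensors):
        cfg = SimulationConfig()
        d1, l1 = simulate_participant(cfg, np.random.default_rng(3), sensors)
        d2, l2 = simulate_participant(cfg, np.random.default_rng(3), sensors)
        np.testing.assert_array_equal(d1.data, d2.data)
        np.testing.assert_array_equal(l1, l2)

    def test_source_jitter_recovers_mean_and_sd(self, sensors):
        cfg = SimulationConfig()
        rng = np.random.default_rng(5)
        locs = np.array([draw_source(cfg, sensors, rng).location_mm
                         for _ in range(600)])
        np.testing.assert_allclose(locs.mean(axis=0), [52, -29, 13], atol=0.8)
        np.testing.assert_allclose(locs.std(axis=0), 5.0, atol=0.8)

    def test_orientation_tangential_unit(self, sensors):
        cfg = SimulationConfig()
        rng = np.random.default_rng(9)
        for _ in range(20):
            src = draw_source(cfg, sensors, rng)
            radial = mni_to_head_m(src.location_mm) - sensors.sphere_center
            assert np.linalg.norm(src.orientation) == pytest.approx(1.0)
            assert abs(src.orientation @ radial) < 1e-10


def test_config_yaml_round_trip(tmp_path):
    cfg = SimulationConfig(moment_nam=17.5, jitter_sd_mm=4.0)
    cfg.to_yaml(tmp_path / "sim.yaml")
    back = SimulationConfig.from_yaml(tmp_path / "sim.yaml")
    assert back == cfg
    assert back.noise_sd_t == pytest.approx(10e-15 * np.sqrt(80.0))
    assert back.samples_per_epoch == 40


def test_mni_head_transform_preserves_distances():
    a, b = np.array([52.0, -29.0, 13.0]), np.array([10.0, 0.0, -5.0])
    da = mni_to_head_m(a) - mni_to_head_m(b)
    assert np.linalg.norm(da) * 1000 == pytest.approx(np.linalg.norm(a - b))
    np.testing.assert_allclose(head_m_to_mni(mni_to_head_m(a)), a)
    np.testing.assert_allclose(MNI_OFFSET_MM, [0.0, -20.0, 20.0])
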