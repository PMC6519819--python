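import math

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.stats import kstest

from estreamlab.geometry import (
    BeamSetup,
    ExperimentCondition,
    PanelSetup,
    PhantomSetup,
)
from estreamlab.estream_simulator import (
    AIR_CSDA,
    PMMA_CSDA,
    ELECTRON_REST_MEV,
    PhysicsConfig,
    RangeTable,
    SimConfig,
    compton_kinematics,
    gyroradius_cm,
    helix_to_panel,
    klein_nishina_weight,
    propagate_electrons_to_surface,
    sample_compton,
    sample_interactions,
    sample_photons,
    simulate_condition,
)


def make_condition(tilt=20.0, fs=6.3, gantry=0.0, dist=10.0):
    return ExperimentCondition(
        beam=BeamSetup(gantry, fs),
        phantom=PhantomSetup(tilt_angle=tilt),
        panel=PanelSetup("front", dist),
    )


class TestPhotonSampling:
    def test_line_weights_recovered(self):
        rng = np.random.default_rng(1)
        _, _, e = sample_photons(BeamSetup(0, 6.3), PhysicsConfig(), rng, 100_000)
        frac = np.mean(np.isclose(e, 1.17))
        sigma = math.sqrt(0.25 / 100_000)
        assert abs(frac - 0.5) < 3 * sigma

    def test_isocenter_plane_points_within_half_side(self):
        rng = np.random.default_rng(2)
        o, d, _ = sample_photons(BeamSetup(0, 6.3), PhysicsConfig(), rng, 20_000)
        t = -o[:, 2] / d[:, 2]
        pts = o + t[:, None] * d
        assert np.all(np.abs(pts[:, 0]) <= 3.15 + 1e-9)
        assert np.all(np.abs(pts[:, 1]) <= 3.15 + 1e-9)

    def test_isocenter_plane_points_centered(self):
        rng = np.random.default_rng(3)
        n = 100_000
        o, d, _ = sample_photons(BeamSetup(0, 12.6), PhysicsConfig(), rng, n)
        t = -o[:, 2] / d[:, 2]
        pts = o + t[:, None] * d
        sigma = (12.6 / math.sqrt(12)) / math.sqrt(n)
        assert abs(pts[:, 0].mean()) < 3 * sigma
        assert abs(pts[:, 1].mean()) < 3 * sigma


class TestInteractionSampling:
    def test_vanishing_attenuation_always_passes_through(self):
        rng = np.random.default_rng(4)
        phys = PhysicsConfig(phantom_attenuation=(1e-9, 1e-9))
        beam = BeamSetup(0, 6.3)
        o, d, e = sample_photons(beam, phys, rng, 5_000)
        hit, _ = sample_interactions(o, d, e, PhantomSetup(), phys, rng)
        assert hit.sum() == 0

    def test_interaction_probability_closed_form(self):
        # vertical pencil-like beam through the untilted box: chord = 10 cm
        rng = np.random.default_rng(5)
        phys = PhysicsConfig()
        beam = BeamSetup(0, 0.01)
        n = 100_000
        o, d, e = sample_photons(beam, phys, rng, n)
        hit, _ = sample_interactions(o, d, e, PhantomSetup(tilt_angle=0.0), phys, rng)
        mu = np.mean(phys.phantom_attenuation)
        p = 1.0 - math.exp(-mu * 10.0)
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(hit.mean() - p) < 3.5 * sigma

    def test_interaction_points_inside_box(self):
        rng = np.random.default_rng(6)
        phys = PhysicsConfig()
        beam = BeamSetup(30, 6.3)
        phantom = PhantomSetup(tilt_angle=20.0)
        o, d, e = sample_photons(beam, phys, rng, 20_000)
        hit, pts = sample_interactions(o, d, e, phantom, phys, rng)
        assert phantom.contains(pts[hit], pad=1e-9).all()


class TestCompton:
    def test_forward_scatter_transfers_no_energy(self):
        t, phi = compton_kinematics(1.25, 1.0)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert phi == pytest.approx(math.pi / 2)

    def test_compton_edge_at_1p25_mev(self):
        t, phi = compton_kinematics(1.25, -1.0)
        alpha = 1.25 / ELECTRON_REST_MEV
        assert t == pytest.approx(1.25 * 2 * alpha / (1 + 2 * alpha), rel=1e-12)
        assert t == pytest.approx(1.0380, abs=2e-4)
        assert phi == pytest.approx(0.0, abs=1e-12)

    def test_sampled_angles_match_klein_nishina_cdf(self):
        rng = np.random.default_rng(7)
        n = 100_000
        energies = np.full(n, 1.25)
        cos_t, _, _ = sample_compton(energies, PhysicsConfig(), rng)
        grid = np.linspace(-1.0, 1.0, 4001)
        pdf = klein_nishina_weight(grid, 1.25 / ELECTRON_REST_MEV)
        cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
        cdf /= cdf[-1]
        stat = kstest(cos_t, lambda x: np.interp(x, grid, cdf)).statistic
        assert stat < 1.63 / math.sqrt(n)  # 1% critical value

    def test_energies_bounded_by_compton_edge(self):
        rng = np.random.default_rng(8)
        e = np.full(50_000, 1.33)
        _, t, _ = sample_compton(e, PhysicsConfig(), rng)
        alpha = 1.33 / ELECTRON_REST_MEV
        assert np.all(t <= 1.33 * 2 * alpha / (1 + 2 * alpha) + 1e-12)
        assert np.all(t >= 0)


class TestRangeTables:
    def test_log_log_interpolation_two_point_oracle(self):
        table = RangeTable((0.1, 1.0), (0.014, 0.437), density=1.0)
        e = 0.3
        # hand log-log interpolation between the two rows
        f = (math.log(e) - math.log(0.1)) / (math.log(1.0) - math.log(0.1))
        expected = math.exp(
            math.log(0.014) + f * (math.log(0.437) - math.log(0.014))
        )
        assert table.range_cm(e) == pytest.approx(expected, rel=1e-12)
        assert table.energy_from_range_cm(expected) == pytest.approx(e, rel=1e-9)

    def test_range_monotone_in_energy(self):
        e = np.linspace(0.02, 1.9, 200)
        assert np.all(np.diff(PMMA_CSDA.range_cm(e)) > 0)
        assert np.all(np.diff(AIR_CSDA.range_cm(e)) > 0)


class TestEscape:
    def test_surface_electron_moving_outward_escapes_with_full_energy(self):
        phantom = PhantomSetup(tilt_angle=0.0)
        pts = np.array([[0.0, 0.0, 5.0 - 1e-9]])
        dirs = np.array([[0.0, 0.0, 1.0]])
        e = np.array([0.8])
        esc, xp, xe, _ = propagate_electrons_to_surface(
            pts, dirs, e, phantom, PMMA_CSDA
        )
        assert esc[0]
        assert xe[0] == pytest.approx(0.8, rel=1e-3)

    def test_deep_electron_is_absorbed(self):
        phantom = PhantomSetup(tilt_angle=0.0)
        pts = np.array([[0.0, 0.0, 0.0]])  # 5 cm from every face
        dirs = np.array([[0.0, 0.0, 1.0]])
        e = np.array([1.0])  # CSDA range well under 1 cm in acrylic
        esc, _, _, _ = propagate_electrons_to_surface(pts, dirs, e, phantom, PMMA_CSDA)
        assert not esc[0]


class TestHelix:
    def test_axial_direction_goes_straight(self):
        panel = PanelSetup("front", 10.0)
        pos = np.array([[1.5, 0.0, -2.0]])
        d = np.array([[0.0, 1.0, 0.0]])
        ok, uv, e = helix_to_panel(pos, d, np.array([0.5]), panel, PhysicsConfig())
        assert ok[0]
        assert uv[0] == pytest.approx([1.5, -2.0], abs=1e-9)

    def test_zero_axial_velocity_is_a_miss(self):
        panel = PanelSetup("front", 10.0)
        pos = np.array([[0.0, 0.0, 0.0]])
        d = np.array([[1.0, 0.0, 0.0]])
        ok, _, _ = helix_to_panel(pos, d, np.array([0.5]), panel, PhysicsConfig())
        assert not ok[0]

    def test_wrong_panel_side_is_a_miss(self):
        panel = PanelSetup("end", 10.0)
        pos = np.array([[0.0, 0.0, 0.0]])
        d = np.array([[0.0, 1.0, 0.0]])
        ok, _, _ = helix_to_panel(pos, d, np.array([0.5]), panel, PhysicsConfig())
        assert not ok[0]

    def test_gyroradius_closed_form_1mev(self):
        pc = math.sqrt((1.0 + 0.511) ** 2 - 0.511**2)
        expected = pc / (299.792458 * 0.35) * 100.0
        assert gyroradius_cm(1.0, 0.35) == pytest.approx(expected, rel=1e-6)
        assert gyroradius_cm(1.0, 0.35) == pytest.approx(1.355, abs=2e-3)

    def test_patch_centroid_drift_bounded_by_gyroradius(self):
        rng = np.random.default_rng(9)
        n = 10_000
        phys = PhysicsConfig(air_interactions="none")
        panel = PanelSetup("front", 10.0)
        pos = np.column_stack(
            [rng.uniform(-1, 1, n), np.zeros(n), rng.uniform(-1, 1, n)]
        )
        # tilted upwards into +y with random azimuth
        psi = rng.uniform(0, 2 * np.pi, n)
        sin_a = 0.6
        d = np.column_stack(
            [sin_a * np.cos(psi), np.full(n, math.sqrt(1 - sin_a**2)),
             sin_a * np.sin(psi)]
        )
        e = np.full(n, 0.7)
        ok, uv, _ = helix_to_panel(pos, d, e, panel, phys)
        assert ok.all()
        r_g = float(gyroradius_cm(0.7, 0.35, sin_a))
        drift = np.linalg.norm(uv[ok].mean(axis=0) - [0.0, 0.0])
        assert drift <= r_g


class TestSimulateCondition:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(make_condition(), n_photons=30_000, seed=42)
        a = simulate_condition(cfg)
        b = simulate_condition(cfg)
        assert np.array_equal(a.front_map.values, b.front_map.values)
        assert np.array_equal(a.end_map.values, b.end_map.values)
        assert a.escaped_count == b.escaped_count
        assert a.isocenter_score == b.isocenter_score

    def test_energy_conservation_on_panels(self):
        res = simulate_condition(SimConfig(make_condition(), n_photons=200_000, seed=3))
        assert res.panel_energy_total <= res.compton_energy_total
        assert res.escaped_count >= max(res.panel_hit_counts)

    def test_maps_nonnegative_and_normalised(self):
        res = simulate_condition(SimConfig(make_condition(), n_photons=200_000, seed=5))
        assert np.all(res.front_map.values >= 0)
        assert np.all(res.end_map.values >= 0)
        assert res.isocenter_score > 0

    def test_single_spot_profile_monotone(self):
        from estreamlab.dosemap import drx_profile

        res = simulate_condition(
            SimConfig(make_condition(tilt=30.0), n_photons=400_000, seed=8)
        )
        prof = drx_profile(res.end_map)
        assert all(a >= b for a, b in zip(prof.values, prof.values[1:]))

    def test_zero_isocenter_score_raises(self):
        # with vanishing attenuation nothing interacts, so normalisation fails
        phys = PhysicsConfig(phantom_attenuation=(1e-12, 1e-12))
        with pytest.raises(ValueError, match="isocenter"):
            simulate_condition(
                SimConfig(make_condition(), n_photons=100, seed=1, physics=phys)
            )
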