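"""Condensed-history transport and dose tallies in water spheres."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

from augerdose.decay_model import EmittedParticle, isotropic_directions
from augerdose.transport_mc import (
    SphereWorld,
    TransportConfig,
    component_ratio,
    place_source,
    run_volume_sweep,
    transport_electron,
    transport_electrons_bulk,
    transport_photons_bulk,
)

CELL_VOLUME_UL = 1.4e-5  # 15 um radius, average tissue cell
NUCLEUS_VOLUME_UL = 4.2e-9  # 1 um radius


def containment_quadrature(e0_mev, world, table, n_r=160, n_mu=320):
    """Independent expectation of the energy a mono-energetic electron
    deposits inside the sphere: 2-D quadrature over source radius and
    direction cosine of the straight-ray exit distance, using only the
    range table (no stepping)."""
    R = world.radius_cm
    track = table.csda_range(e0_mev)
    u = (np.arange(n_r) + 0.5) / n_r  # r = u * R with weight 3u^2
    mu = -1.0 + 2.0 * (np.arange(n_mu) + 0.5) / n_mu
    uu, mm = np.meshgrid(u, mu, indexing="ij")
    r = uu * R
    s_exit = -r * mm + np.sqrt(R**2 - r**2 * (1 - mm**2))
    residual_range = np.clip(track - s_exit, 0.0, None)
    e_res = np.where(residual_range > 0, table.energy_at_range(residual_range), 0.0)
    dep = e0_mev - e_res
    w = 3.0 * uu**2
    return float(np.sum(dep * w) / np.sum(w))


class TestSourcePlacement:
    def test_positions_inside_sphere(self, rng):
        world = SphereWorld(1.0)
        pos = place_source(world, rng, 5000)
        assert np.all(np.linalg.norm(pos, axis=1) <= world.radius_cm)

    def test_volume_uniformity(self, rng):
        world = SphereWorld(10.0)
        pos = place_source(world, rng, 100_000)
        u = (np.linalg.norm(pos, axis=1) / world.radius_cm) ** 3
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_mean_radius_three_quarters(self, rng):
        world = SphereWorld(10.0)
        r = np.linalg.norm(place_source(world, rng, 100_000), axis=1)
        se = r.std() / np.sqrt(r.size)
        assert abs(r.mean() - 0.75 * world.radius_cm) < 3 * se


class TestElectronTransport:
    def test_auger_electron_fully_contained_in_cell(self, sp_table):
        """A 2 keV electron (range ~120 nm) launched at the centre of a
        15 um sphere deposits all of its energy inside."""
        world = SphereWorld(CELL_VOLUME_UL)
        p = EmittedParticle("electron", "auger", 2e-3, np.array([0.0, 0.0, 1.0]), np.zeros(3))
        rec = transport_electron(p, world, TransportConfig(), sp_table)
        assert rec["energy_inside_mev"] == pytest.approx(2e-3, rel=1e-9)
        assert rec["energy_escaped_mev"] == 0.0

    def test_energy_conservation(self, sp_table, rng):
        world = SphereWorld(1e-4)
        n = 400
        e0 = 10 ** rng.uniform(-5, -0.25, n)  # 10 eV .. 0.56 MeV
        pos = place_source(world, rng, n)
        dirs = isotropic_directions(rng, n)
        inside, escaped = transport_electrons_bulk(e0, pos, dirs, world, sp_table, TransportConfig())
        np.testing.assert_allclose(inside + escaped, e0, rtol=1e-6)

    def test_partial_containment_matches_1d_csda_oracle(self, sp_table):
        """0.573 MeV electron from the centre of a 0.5 mm sphere: the
        contained energy equals an independent ODE integration of
        dE/ds = -S(E) over the first 0.5 mm of the 2.1 mm track."""
        world_r = 0.05  # cm
        vol_ul = 4.0 / 3.0 * np.pi * world_r**3 / 1e-3
        world = SphereWorld(vol_ul)
        assert world.radius_cm == pytest.approx(world_r, rel=1e-9)
        sol = solve_ivp(
            lambda s, e: [-sp_table(max(e[0], 7.5e-6))],
            (0.0, world_r),
            [0.573],
            rtol=1e-9,
            atol=1e-12,
        )
        expected_inside = 0.573 - sol.y[0, -1]
        p = EmittedParticle("electron", "beta_minus", 0.573, np.array([0.0, 0.0, 1.0]), np.zeros(3))
        rec = transport_electron(p, world, TransportConfig(), sp_table)
        assert rec["energy_inside_mev"] == pytest.approx(expected_inside, rel=0.02)

    def test_uniform_source_containment_matches_quadrature(self, sp_table, rng):
        """MC containment of mono-energetic electrons from uniformly
        distributed sources agrees with the independent 2-D quadrature."""
        world = SphereWorld(10.0)
        n = 20_000
        e0 = np.full(n, 0.3)
        pos = place_source(world, rng, n)
        dirs = isotropic_directions(rng, n)
        inside, _ = transport_electrons_bulk(e0, pos, dirs, world, sp_table, TransportConfig())
        expected = containment_quadrature(0.3, world, sp_table)
        se = inside.std() / np.sqrt(n)
        assert abs(inside.mean() - expected) < max(3 * se, 0.02 * expected)

    def test_track_recording(self, sp_table):
        world = SphereWorld(1e-3)
        p = EmittedParticle("electron", "beta_minus", 0.1, np.array([1.0, 0.0, 0.0]), np.zeros(3))
        rec = transport_electron(p, world, TransportConfig(), sp_table, record_track=True)
        deposits = sum(de for _, de in rec["track"])
        assert deposits == pytest.approx(0.1, rel=1e-9)
        assert rec["energy_inside_mev"] + rec["energy_escaped_mev"] == pytest.approx(0.1, rel=1e-9)

    def test_energy_above_table_is_error(self, sp_table, rng):
        world = SphereWorld(1.0)
        with pytest.raises(ValueError, match="above"):
            transport_electrons_bulk(
                np.array([1.5]), np.zeros((1, 3)), np.array([[0.0, 0.0, 1.0]]), world, sp_table, TransportConfig()
            )


class TestPhotonTransport:
    def test_surface_outward_photon_escapes(self, att_table, rng):
        world = SphereWorld(1.0)
        pos = np.array([[0.0, 0.0, world.radius_cm]])
        d = np.array([[0.0, 0.0, 1.0]])
        inside, escaped = transport_photons_bulk(np.array([7.48e-3]), pos, d, world, att_table, rng)
        assert inside[0] == 0.0 and escaped[0] == pytest.approx(7.48e-3)

    def test_escape_fraction_one_attenuation_length(self, att_table, rng):
        """From the centre of a sphere whose radius equals the 7.5 keV
        attenuation length, exactly e^-1 of photons survive to escape."""
        lam = att_table.attenuation_length(7.5)
        vol_ul = 4.0 / 3.0 * np.pi * lam**3 / 1e-3
        world = SphereWorld(vol_ul)
        n = 100_000
        pos = np.zeros((n, 3))
        dirs = isotropic_directions(rng, n)
        _, escaped = transport_photons_bulk(np.full(n, 7.5e-3), pos, dirs, world, att_table, rng)
        f = np.mean(escaped > 0)
        p = np.exp(-1)
        assert abs(f - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_xrays_mostly_escape_cell_sized_sphere(self, att_table, rng):
        world = SphereWorld(CELL_VOLUME_UL)
        n = 20_000
        pos = place_source(world, rng, n)
        dirs = isotropic_directions(rng, n)
        _, escaped = transport_photons_bulk(np.full(n, 7.48e-3), pos, dirs, world, att_table, rng)
        assert np.mean(escaped > 0) > 0.95

    def test_annihilation_quanta_always_escape(self, att_table, rng):
        world = SphereWorld(1000.0)
        n = 100
        inside, escaped = transport_photons_bulk(
            np.full(n, 0.511), np.zeros((n, 3)), isotropic_directions(rng, n), world, att_table, rng,
            escape_only=np.ones(n, bool),
        )
        assert np.all(inside == 0.0)
        assert np.all(escaped == 0.511)


@pytest.fixture(scope="module")
def sweep(scheme):
    cfg = TransportConfig(seed=11, n_decays=20_000)
    volumes = [1e-7, 1e-5, 1e-3, 1e-1, 10.0, 1000.0]
    return volumes, run_volume_sweep(volumes, scheme, cfg)


class TestVolumeSweep:

    def test_energy_conservation_per_component(self, sweep, scheme):
        _, tallies = sweep
        for t in tallies:
            for c in t.components:
                total = t.energy_inside_mev[c] + t.energy_escaped_mev[c]
                assert total >= 0
            # total emitted electron energy per decay approximates the scheme mean
            emitted = sum(t.energy_emitted_mev(c) for c in ("beta", "auger")) / t.n_decays
            assert emitted == pytest.approx(scheme.mean_electron_energy_per_decay(), rel=0.05)

    def test_dose_additivity(self, sweep):
        _, tallies = sweep
        for t in tallies:
            assert t.dose_per_decay("total") == pytest.approx(
                sum(t.dose_per_decay(c) for c in t.components), rel=1e-12
            )

    def test_containment_monotone_in_volume(self, sweep):
        """The contained-energy fraction of every component, and so the
        dose per unit decay density, grows with the sphere volume."""
        _, tallies = sweep
        fractions = [t.inside_fraction() for t in tallies]
        assert all(b > a for a, b in zip(fractions, fractions[1:]))
        density_dose = [t.dose_per_decay_density() for t in tallies]
        assert all(b > a for a, b in zip(density_dose, density_dose[1:]))

    def test_auger_dose_constant_above_1e5_ul(self, sweep):
        """Auger electrons (range <~1.5 um) are fully contained from the
        cell scale upward: their specific dose plateaus above 1e-5 uL."""
        volumes, tallies = sweep
        plateau = [t for v, t in zip(volumes, tallies) if v >= 1e-5]
        values = np.array([t.dose_per_decay_density("auger") for t in plateau])
        errors = np.array([t.mc_error_density("auger") for t in plateau])
        ref = values[-1]
        assert np.all(np.abs(values - ref) < 3 * np.sqrt(errors**2 + errors[-1] ** 2))

    def test_full_absorption_limit_for_contained_components(self, sweep, scheme):
        """At 1000 uL the Auger component is fully absorbed: its dose
        matches the analytic per-decay Auger energy over the sphere mass."""
        volumes, tallies = sweep
        t = tallies[volumes.index(1000.0)]
        analytic = (
            scheme.p_auger_per_decay * scheme.auger_mean_kev * 1e-3 * 1.602176634e-13 / t.mass_kg
        )
        assert abs(t.dose_per_decay("auger") - analytic) < 3 * t.mc_error("auger")
        assert t.inside_fraction("auger") == pytest.approx(1.0, abs=1e-6)
        # betas are nearly but not exactly contained (straight 2.1-2.6 mm
        # tracks vs a 6.2 mm radius): >90% of all emitted energy stays in
        assert t.inside_fraction() > 0.90

    def test_beta_containment_matches_quadrature_at_1000ul(self, scheme, sp_table, rng):
        """Spectrum-averaged straight-ray containment oracle for the large
        sphere: MC beta deposition matches the independent quadrature."""
        world = SphereWorld(1000.0)
        cfg = TransportConfig(seed=13, n_decays=1)
        n = 30_000
        e0 = scheme.beta_spectrum("beta_minus").sample(rng, n)
        pos = place_source(world, rng, n)
        dirs = isotropic_directions(rng, n)
        inside, _ = transport_electrons_bulk(e0, pos, dirs, world, sp_table, cfg)
        # oracle: average the mono-energetic quadrature over a coarse spectrum grid
        grid = np.linspace(0.005, 0.570, 40)
        dens = scheme.beta_spectrum("beta_minus").density(grid)
        dep = np.array([containment_quadrature(e, world, sp_table, n_r=60, n_mu=120) for e in grid])
        expected = float(np.sum(dep * dens) / np.sum(dens))
        se = inside.std() / np.sqrt(n)
        assert abs(inside.mean() - expected) < max(3 * se, 0.02 * expected)

    def test_component_masking(self, scheme):
        cfg = TransportConfig(seed=17, n_decays=5_000)
        no_auger = run_volume_sweep([1e-3], scheme, cfg, components=("beta", "xray"))[0]
        assert "auger" not in no_auger.components
        assert no_auger.dose_per_decay("total") == pytest.approx(
            no_auger.dose_per_decay("beta") + no_auger.dose_per_decay("xray"), rel=1e-12
        )

    def test_seed_reproducibility(self, scheme):
        cfg = TransportConfig(seed=19, n_decays=2_000)
        a = run_volume_sweep([1e-4], scheme, cfg)[0]
        b = run_volume_sweep([1e-4], scheme, cfg)[0]
        assert a.energy_inside_mev == b.energy_inside_mev
        assert a.energy_escaped_mev == b.energy_escaped_mev


class TestComponentRatios:
    def test_auger_beta_parity_at_micron_scale(self, scheme):
        """In a 1 um-radius sphere the Auger and beta doses are of the
        same order (the micro-scale crossover)."""
        cfg = TransportConfig(seed=23, n_decays=30_000)
        t = run_volume_sweep([NUCLEUS_VOLUME_UL], scheme, cfg)[0]
        r = component_ratio(t, "auger", "beta")
        assert 0.5 <= r.value <= 2.0

    def test_beta_dominates_at_cell_scale(self, scheme):
        cfg = TransportConfig(seed=29, n_decays=30_000)
        t = run_volume_sweep([CELL_VOLUME_UL], scheme, cfg)[0]
        assert component_ratio(t, "beta", "auger").value > 2.0

    def test_identity_and_zero_denominator(self, scheme):
        cfg = TransportConfig(seed=31, n_decays=2_000)
        t = run_volume_sweep([1e-3], scheme, cfg)[0]
        assert component_ratio(t, "beta", "beta").value == 1.0
        t.energy_inside_mev["xray"] = 0.0
        with pytest.raises(ZeroDivisionError):
            component_ratio(t, "beta", "xray")


class TestWorldAndConfig:
    def test_radius_consistent_with_volume(self):
        w = SphereWorld(30.0)
        assert 4.0 / 3.0 * np.pi * w.radius_cm**3 == pytest.approx(w.volume_cm3, rel=1e-9)
        assert w.radius_cm * 10.0 == pytest.approx(1.93, abs=0.01)  # mm

    def test_volume_bounds_enforced(self):
        with pytest.raises(ValueError):
            SphereWorld(1e-12)
        with pytest.raises(ValueError):
            SphereWorld(1e4)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TransportConfig(step_fraction=0.5)
        with pytest.raises(ValueError):
            TransportConfig(detour_factor=0.0)
        with pytest.raises(ValueError):
            TransportConfig(electron_cutoff_mev=1e-6)
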