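"""Microdosimetry MC: sampling, geometry, registration, and tally physics.

The closed-form oracles used here are classical fluence results for
isotropic finite-range tracks from uniform emitters: one-sided plane
crossings per area n_v·R̄/4, expected hits on a convex body
n_v·(V + R̄·S/4) (Cauchy projection formula plus the emitters born
inside), and the charged-particle-equilibrium dose n_v·Ē/ρ, halved at a
non-emitting boundary.
"""

import math

import numpy as np
import pytest

from dartdose.mc import (
    GeometryConfig,
    RegistrationModel,
    TrackBatch,
    analytic_registered_depth_um,
    chord_through_nucleus,
    cr39_registers,
    dose_per_detected_pit,
    mean_alpha_energy_mev,
    mean_alpha_range_um,
    run_microdose,
    sample_decay_events,
    MEV_TO_J,
)

EQUILIBRIUM_DOSE_PER_NV = None  # filled lazily from the spectrum


def _equilibrium_dose_per_nv(inventory) -> float:
    """n_v·Ē/ρ for n_v = 1 decay/cm³, in Gy."""
    return mean_alpha_energy_mev(inventory.spectrum) * MEV_TO_J / 1e-3


class TestSampling:
    def test_positions_uniform_in_depth(self, spectrum_inventory, default_geometry, rng):
        batch = sample_decay_events(spectrum_inventory, default_geometry, 100_000, rng)
        z = batch.origin[:, 2]
        depth = z.max()  # sampling window top
        se = depth / math.sqrt(12 * len(z))
        assert abs(z.mean() - depth / 2) < 3 * se

    def test_directions_isotropic(self, spectrum_inventory, default_geometry, rng):
        batch = sample_decay_events(spectrum_inventory, default_geometry, 100_000, rng)
        cos_t = batch.direction[:, 2]
        assert abs(cos_t.mean()) < 3 / math.sqrt(3 * len(cos_t))
        norms = np.linalg.norm(batch.direction, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_energy_fractions_match_spectrum(
        self, spectrum_inventory, default_geometry, rng
    ):
        """The ²¹²Po/²¹²Bi line split reproduces the 0.64/0.36 branch
        fractions within 3 SE."""
        n = 100_000
        batch = sample_decay_events(spectrum_inventory, default_geometry, n, rng)
        for energy, frac in spectrum_inventory.spectrum:
            observed = np.mean(batch.e0_mev == energy)
            se = math.sqrt(frac * (1 - frac) / n)
            assert abs(observed - frac) < 3 * se

    def test_empty_spectrum_rejected(self, default_geometry, rng):
        from dartdose.decay import AlphaEmissionInventory

        with pytest.raises(ValueError):
            AlphaEmissionInventory(1.0, ())


class TestChord:
    def test_vertical_track_through_axis(self, default_geometry):
        h = default_geometry.nucleus_thickness_um
        batch = TrackBatch(
            origin=np.array([[0.0, 0.0, 50.0]]),
            direction=np.array([[0.0, 0.0, -1.0]]),
            e0_mev=np.array([8.785]),
            range_um=np.array([86.0]),
        )
        s_in, s_out, hit = chord_through_nucleus(batch, default_geometry)
        assert hit[0]
        assert s_out[0] - s_in[0] == pytest.approx(h, abs=1e-9)

    def test_lateral_miss(self, default_geometry):
        r = default_geometry.nucleus_radius_um
        batch = TrackBatch(
            origin=np.array([[r + 5.0, 0.0, 50.0]]),
            direction=np.array([[0.0, 0.0, -1.0]]),
            e0_mev=np.array([8.785]),
            range_um=np.array([86.0]),
        )
        _, _, hit = chord_through_nucleus(batch, default_geometry)
        assert not hit[0]

    def test_origin_inside_starts_at_zero(self, default_geometry):
        batch = TrackBatch(
            origin=np.array([[0.0, 0.0, 1.0]]),
            direction=np.array([[0.0, 0.0, 1.0]]),
            e0_mev=np.array([6.05]),
            range_um=np.array([47.0]),
        )
        s_in, s_out, hit = chord_through_nucleus(batch, default_geometry)
        assert hit[0] and s_in[0] == 0.0
        assert s_out[0] == pytest.approx(
            default_geometry.nucleus_thickness_um - 1.0, abs=1e-9
        )

    def test_against_ray_marching_oracle(
        self, spectrum_inventory, default_geometry, rng
    ):
        """Intersection decisions and chord endpoints agree with a
        brute-force 0.01 μm ray march to 0.05 μm."""
        geom = default_geometry
        batch = sample_decay_events(
            spectrum_inventory, geom, 1000, rng, lateral_halfwidth_um=15.0
        )
        s_in, s_out, hit = chord_through_nucleus(batch, geom)
        r2 = geom.nucleus_radius_um**2
        zb, zt = 0.0, geom.nucleus_thickness_um
        step = 0.01
        for i in range(len(batch)):
            s = np.arange(0.0, batch.range_um[i], step)
            pos = batch.origin[i] + s[:, None] * batch.direction[i]
            inside = (
                (pos[:, 0] ** 2 + pos[:, 1] ** 2 <= r2)
                & (pos[:, 2] >= zb)
                & (pos[:, 2] <= zt)
            )
            if inside.any():
                assert hit[i], f"oracle found a chord the solver missed (track {i})"
                o_in, o_out = s[inside][0], s[inside][-1]
                assert abs(o_in - s_in[i]) <= 0.05
                assert abs(o_out - s_out[i]) <= 0.05
            elif hit[i]:
                # only sub-step grazing chords may escape the march
                assert s_out[i] - s_in[i] < 0.05


class TestRegistration:
    def test_normal_incidence_registers(self):
        batch = TrackBatch(
            origin=np.array([[0.0, 0.0, 30.0]]),
            direction=np.array([[0.0, 0.0, -1.0]]),
            e0_mev=np.array([8.785]),
            range_um=np.array([86.0]),
        )
        arr = cr39_registers(batch, RegistrationModel())
        assert arr.reaches[0] and arr.registers[0]
        assert arr.dip_deg[0] == pytest.approx(90.0)

    def test_below_critical_dip_does_not_register(self):
        model = RegistrationModel(critical_dip_angle_deg=40.8)
        dip = math.radians(20.0)
        batch = TrackBatch(
            origin=np.array([[0.0, 0.0, 5.0]]),
            direction=np.array(
                [[math.cos(dip), 0.0, -math.sin(dip)]]
            ),
            e0_mev=np.array([8.785]),
            range_um=np.array([86.0]),
        )
        arr = cr39_registers(batch, model)
        assert arr.reaches[0] and not arr.registers[0]

    def test_out_of_range_track_does_not_reach(self):
        batch = TrackBatch(
            origin=np.array([[0.0, 0.0, 120.0]]),
            direction=np.array([[0.0, 0.0, -1.0]]),
            e0_mev=np.array([8.785]),
            range_um=np.array([86.0]),
        )
        arr = cr39_registers(batch, RegistrationModel())
        assert not arr.reaches[0]
        assert np.isnan(arr.arrival_e_mev[0])

    def test_energy_window(self):
        model = RegistrationModel(energy_window_mev=(0.5, 4.0))
        batch = TrackBatch(
            origin=np.array([[0.0, 0.0, 1.0]]),  # arrives with nearly full energy
            direction=np.array([[0.0, 0.0, -1.0]]),
            e0_mev=np.array([8.785]),
            range_um=np.array([86.0]),
        )
        arr = cr39_registers(batch, model)
        assert arr.reaches[0] and not arr.registers[0]

    def test_ensemble_efficiency_in_published_band(self, default_tally):
        """50–60% of plane-reaching alphas leave countable pits under the
        default calibrated criterion."""
        assert 0.50 <= default_tally.registration_efficiency <= 0.60


class TestFluenceOracles:
    def test_plane_crossing_density(self, spectrum_inventory, default_tally):
        """One-sided plane crossings per decay equal R̄/(4·depth)."""
        expected = mean_alpha_range_um(spectrum_inventory.spectrum) / 4.0 / (
            default_tally.sim_depth_cm / 1e-4
        )
        assert default_tally.reach_rate == pytest.approx(expected, rel=0.02)

    def test_registered_pit_density_closed_form(
        self, spectrum_inventory, default_registration, default_tally
    ):
        """Registered-pit areal density matches R̄(1−sin²θc)/4 within 2%."""
        depth_um = analytic_registered_depth_um(
            spectrum_inventory.spectrum, default_registration
        )
        expected_pits_per_nucleus_per_nv = depth_um * 1e-4 * default_tally.nucleus_area_cm2
        assert default_tally.pits_per_nucleus_per_nv == pytest.approx(
            expected_pits_per_nucleus_per_nv, rel=0.02
        )


@pytest.fixture(scope="module")
def midslab_tally(spectrum_inventory):
    """Nucleus buried mid-slab, farther than one range from any boundary:
    full charged-particle equilibrium."""
    geom = GeometryConfig(
        medium_depth_um=2000.0, nucleus_base_z_um=1000.0
    )
    return run_microdose(
        spectrum_inventory,
        geom,
        RegistrationModel(),
        n_decays=4_000_000,
        seed=777,
        z_range_um=(910.0, 1095.0),
    ), geom


def test_convex_body_hit_rate_cauchy(spectrum_inventory, midslab_tally):
    """Hits on the buried nucleus equal n_v·(V + R̄·S/4) within 2%."""
    tally, geom = midslab_tally
    r = geom.nucleus_radius_um
    h = geom.nucleus_thickness_um
    volume = geom.nucleus_area_um2 * h
    surface = 2 * geom.nucleus_area_um2 + 2 * math.pi * r * h
    rbar = mean_alpha_range_um(spectrum_inventory.spectrum)
    expected_um3 = volume + rbar * surface / 4.0
    observed_um3 = tally.hits_per_nucleus_per_nv / 1e-12  # cm³ → μm³
    assert observed_um3 == pytest.approx(expected_um3, rel=0.02)


def test_deep_medium_equilibrium_dose(spectrum_inventory, midslab_tally):
    """Dose to the buried nucleus reaches the equilibrium value n_v·Ē/ρ
    within 2%."""
    tally, _ = midslab_tally
    assert tally.dose_gy_per_nv == pytest.approx(
        _equilibrium_dose_per_nv(spectrum_inventory), rel=0.02
    )


def test_bottom_boundary_dose_half_equilibrium(spectrum_inventory):
    """A thin scoring layer on the non-emitting boundary receives half the
    equilibrium dose within 5%."""
    geom = GeometryConfig(nucleus_thickness_um=1.0)
    tally = run_microdose(
        spectrum_inventory, geom, RegistrationModel(), 2_000_000, seed=4242
    )
    assert tally.dose_gy_per_nv == pytest.approx(
        0.5 * _equilibrium_dose_per_nv(spectrum_inventory), rel=0.05
    )


def test_hits_per_nucleus_poisson_index(spectrum_inventory, default_geometry):
    """Independent uniform emitters give Poisson hit statistics:
    variance/mean of hits per nucleus within [0.9, 1.1]."""
    tally = run_microdose(
        spectrum_inventory, default_geometry, RegistrationModel(),
        1_000_000, seed=97531, decay_density_cm3=2.9e8,
    )
    counts = tally.hits_per_exposure
    assert counts is not None and len(counts) > 500
    index = counts.var(ddof=1) / counts.mean()
    assert 0.9 <= index <= 1.1


def test_linearity_of_per_decay_rates(spectrum_inventory, default_geometry,
                                      default_registration, default_tally):
    """Per-decay rates are invariant in n_decays within 3 SE; extensive
    tallies scale with it."""
    small = run_microdose(
        spectrum_inventory, default_geometry, default_registration,
        300_000, seed=13,
    )
    for attr in ("hit_rate", "pit_rate"):
        a, b = getattr(small, attr), getattr(default_tally, attr)
        se = math.hypot(getattr(small, attr + "_se"), getattr(default_tally, attr + "_se"))
        assert abs(a - b) < 3 * se


def test_density_free_ratios(spectrum_inventory, default_geometry,
                             default_registration):
    """Hit-to-pit and dose-per-pit do not depend on the decay density."""
    kw = dict(n_decays=200_000, seed=5)
    t1 = run_microdose(spectrum_inventory, default_geometry,
                       default_registration, decay_density_cm3=1e9, **kw)
    t2 = run_microdose(spectrum_inventory, default_geometry,
                       default_registration, decay_density_cm3=2e9, **kw)
    assert t1.hit_to_pit_ratio == t2.hit_to_pit_ratio
    assert dose_per_detected_pit(t1)[0][0] == dose_per_detected_pit(t2)[0][0]


def test_seed_determinism(spectrum_inventory, default_geometry,
                          default_registration):
    """Identical (config, seed) reproduce event counts bit-for-bit."""
    kw = dict(n_decays=200_000, seed=314159)
    t1 = run_microdose(spectrum_inventory, default_geometry,
                       default_registration, **kw)
    t2 = run_microdose(spectrum_inventory, default_geometry,
                       default_registration, **kw)
    assert t1.hit_rate == t2.hit_rate
    assert t1.pit_rate == t2.pit_rate
    assert t1.energy_per_nucleus_mev_per_nv == t2.energy_per_nucleus_mev_per_nv


def test_zero_decay_density_zero_tallies(spectrum_inventory, default_geometry,
                                         default_registration):
    tally = run_microdose(
        spectrum_inventory, default_geometry, default_registration,
        50_000, seed=8, decay_density_cm3=0.0,
    )
    assert tally.hits_per_nucleus == 0.0
    assert tally.pits_per_nucleus == 0.0
    assert tally.dose_gy == 0.0


def test_shallow_medium_warns(spectrum_inventory, default_registration):
    geom = GeometryConfig(medium_depth_um=50.0)
    with pytest.warns(UserWarning, match="medium depth"):
        tally = run_microdose(
            spectrum_inventory, geom, default_registration, 10_000, seed=3
        )
    assert tally.warnings


class TestTallyConsistency:
    def test_hit_to_pit_ratio_above_one(self, default_tally):
        assert default_tally.hit_to_pit_ratio >= 1.0

    def test_dose_energy_relation(self, default_tally):
        """dose = energy × 1.602e-13 J/MeV / (ρ·V) holds identically."""
        expected = (
            default_tally.energy_per_nucleus_mev_per_nv
            * MEV_TO_J
            / default_tally.nucleus_mass_kg
        )
        assert default_tally.dose_gy_per_nv == pytest.approx(expected, rel=1e-12)

    def test_footprint_crosscheck(self, default_tally):
        """Direct within-footprint pit tally agrees with areal density ×
        nucleus area within 3 SE."""
        direct = default_tally.pits_in_footprint_per_nv
        areal = default_tally.pits_per_nucleus_per_nv
        n_foot = direct / default_tally.sim_volume_cm3 * default_tally.n_decays
        se = areal / math.sqrt(max(n_foot, 1.0))
        assert abs(direct - areal) < 3 * se

    def test_absolute_tallies_at_half_dm_level(self, default_tally):
        """At the decay density implied by the measured pit count the
        absolute tallies sit at the published exposure level."""
        assert default_tally.pits_per_nucleus == pytest.approx(4.7, rel=0.1)
        assert 12.3 < default_tally.hits_per_nucleus < 18.9
        assert 0.87 < default_tally.dose_gy < 1.33

    def test_histogram_mean_matches_rate(self, default_tally):
        counts = default_tally.hits_per_exposure
        assert counts is not None
        assert counts.mean() == pytest.approx(
            default_tally.hits_per_nucleus, rel=0.1
        )

    def test_specific_energy_distribution(self, default_tally):
        z = default_tally.specific_energy_per_hit_gy
        assert len(z) > 0 and np.all(z >= 0)
        assert z.mean() * default_tally.hits_per_nucleus == pytest.approx(
            default_tally.dose_gy, rel=0.05
        )


class TestDosePerPit:
    def test_ratio_of_means(self, default_tally):
        (dpp, dpp_se), (hpp, hpp_se) = dose_per_detected_pit(default_tally)
        assert dpp == pytest.approx(
            default_tally.dose_gy_per_nv / default_tally.pits_per_nucleus_per_nv
        )
        assert hpp == pytest.approx(default_tally.hit_to_pit_ratio)
        assert dpp_se > 0 and hpp_se > 0

    def test_zero_pits_rejected(self, spectrum_inventory, default_geometry):
        # an impossible criterion leaves no registered pits
        model = RegistrationModel(critical_dip_angle_deg=89.9)
        tally = run_microdose(
            spectrum_inventory, default_geometry, model, 10_000, seed=2
        )
        with pytest.raises(ValueError):
            dose_per_detected_pit(tally)


def test_geometry_validation():
    with pytest.raises(ValueError):
        GeometryConfig(nucleus_area_um2=-1.0)
    with pytest.raises(ValueError):
        GeometryConfig(nucleus_thickness_um=0.0)
    with pytest.raises(ValueError):
        RegistrationModel(critical_dip_angle_deg=95.0)
    g = GeometryConfig()
    assert g.nucleus_radius_um == pytest.approx(math.sqrt(280.0 / math.pi))
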