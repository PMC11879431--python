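"""Generator contracts: geometry, determinism, and Boltzmann statistics."""

import numpy as np
import pytest
from scipy import stats

import poremech as pm
from poremech.moduli import spontaneous_curvature
from poremech.synthetic import largest_remainder_counts, synthetic_pmf_values
from poremech.units import KB, KJ_MOL_PER_PN_NM


class TestFlatMembrane:
    def test_dry_core_and_counts(self, flat_frame):
        # 100 lipids/leaflet -> 200 lipids; core |z| < 1.0 nm holds no polar particle
        assert len(flat_frame.lipid_molecules()) == 200
        flat_frame.validate_lipids()
        zc = flat_frame.box[2] / 2.0
        polar_z = flat_frame.positions[flat_frame.polar_mask, 2]
        assert np.sum(np.abs(polar_z - zc) < 1.0) == 0

    def test_species_counts_largest_remainder(self):
        frame = pm.make_flat_membrane(100, {"POPC": 0.7, "CHOL": 0.3}, seed=2)
        heads = frame.mask(role="head")
        sp = frame.species[heads].astype(str)
        assert np.sum(sp == "POPC") == 140
        assert np.sum(sp == "CHOL") == 60

    @pytest.mark.parametrize("fracs,n,expected", [
        ({"A": 0.5, "B": 0.5}, 5, {"A": 3, "B": 2}),
        ({"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}, 10, {"A": 4, "B": 3, "C": 3}),
    ])
    def test_largest_remainder(self, fracs, n, expected):
        assert largest_remainder_counts(fracs, n) == expected

    def test_determinism(self):
        a = pm.make_flat_membrane(50, {"POPC": 1.0}, seed=7)
        b = pm.make_flat_membrane(50, {"POPC": 1.0}, seed=7)
        c = pm.make_flat_membrane(50, {"POPC": 1.0}, seed=8)
        assert np.array_equal(a.positions, b.positions)
        assert not np.array_equal(a.positions, c.positions)

    def test_bad_fractions_raise(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pm.make_flat_membrane(50, {"POPC": 0.9}, seed=0)

    def test_too_small_box_raises(self):
        with pytest.raises(ValueError, match="spacing"):
            pm.make_flat_membrane(500, {"POPC": 1.0}, box_xy=4.0, seed=0)


class TestWaterWire:
    def test_spans_every_core_slab(self, wire_frame):
        zc = wire_frame.box[2] / 2.0
        polar = wire_frame.positions[wire_frame.polar_mask]
        core = polar[np.abs(polar[:, 2] - zc) < 1.4]
        edges = np.arange(zc - 1.4, zc + 1.4 + 0.05, 0.1)
        counts, _ = np.histogram(core[:, 2], bins=edges)
        assert np.all(counts >= 1)

    def test_without_wire_equals_flat(self, flat_frame, wire_frame):
        n = flat_frame.n_particles
        assert np.array_equal(wire_frame.positions[:n], flat_frame.positions)
        assert np.all(wire_frame.role[n:].astype(str) == "water")

    def test_offset_wire_translates_column(self):
        offset = (2.0, 3.0)
        frame = pm.make_water_wire(100, {"POPC": 1.0}, seed=1, center_xy=offset)
        zc = frame.box[2] / 2.0
        polar = frame.positions[frame.polar_mask]
        core = polar[np.abs(polar[:, 2] - zc) < 1.0]
        assert np.all(np.hypot(core[:, 0] - offset[0], core[:, 1] - offset[1]) < 0.2)

    def test_bad_radius_raises(self):
        with pytest.raises(ValueError):
            pm.make_water_wire(100, {"POPC": 1.0}, wire_radius=0.6)


class TestPoreMembrane:
    def test_interior_is_wet_at_all_core_heights(self, pore_frame):
        zc = pore_frame.box[2] / 2.0
        c = pore_frame.box[0] / 2.0
        polar = pore_frame.positions[pore_frame.polar_mask]
        inside = polar[np.hypot(polar[:, 0] - c, polar[:, 1] - c) < 0.8]
        z = inside[:, 2] - zc
        edges = np.arange(-1.4, 1.4 + 0.05, 0.2)
        counts, _ = np.histogram(z, bins=edges)
        assert np.all(counts >= 1)

    def test_rim_fraction_renormalization(self):
        # enrichment 2.0 at bulk fraction 0.2 -> rim fraction 2*0.2/(2*0.2+0.8)=1/3
        frames = [
            pm.make_pore_membrane(400, {"POPC": 0.8, "LPC": 0.2}, box_xy=12.0,
                                  seed=s, pore_radius=1.0,
                                  rim_enrichment={"LPC": 2.0})
            for s in range(20)
        ]
        n_lpc = n_rim = 0
        for frame in frames:
            c = frame.box[0] / 2.0
            zc = frame.box[2] / 2.0
            heads = frame.mask(role="head")
            pos = frame.positions[heads]
            sp = frame.species[heads].astype(str)
            r = np.hypot(pos[:, 0] - c, pos[:, 1] - c)
            # rim heads live inside the bulk exclusion radius
            rim = r < 1.0 + 1.4 + 0.25
            n_rim += int(np.sum(rim))
            n_lpc += int(np.sum(sp[rim] == "LPC"))
        frac = n_lpc / n_rim
        sigma = np.sqrt((1 / 3) * (2 / 3) / n_rim)
        assert abs(frac - 1.0 / 3.0) < 3.0 * sigma + 1e-9

    def test_zero_factor_excludes_species_from_rim(self):
        frame = pm.make_pore_membrane(200, {"POPC": 0.7, "CHOL": 0.3}, box_xy=10.0,
                                      seed=3, pore_radius=0.8,
                                      rim_enrichment={"CHOL": 0.0})
        c = frame.box[0] / 2.0
        heads = frame.mask(role="head", species="CHOL")
        pos = frame.positions[heads]
        r = np.hypot(pos[:, 0] - c, pos[:, 1] - c)
        # rim surface extends to r_ax = pore_radius + d_hc/2 = 2.2 nm
        assert np.all(r > 2.2 + 0.4)

    def test_geometry_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            pm.make_pore_membrane(100, {"POPC": 1.0}, box_xy=6.0, pore_radius=2.5)


class TestBoltzmannSamples:
    def test_tilt_variance_matches_equipartition(self):
        spec = pm.DirectorSampleSpec(kappa_theta_true=42.53, area_per_lipid=0.64,
                                     temperature=310.0, n_samples=100_000, seed=5)
        t = pm.sample_tilt_vectors(spec)
        expected = KB * 310.0 / (42.53 * 0.64)
        assert t.shape == (100_000, 2)
        assert np.var(t[:, 0]) == pytest.approx(expected, abs=1e-3)
        assert np.var(t[:, 1]) == pytest.approx(expected, abs=1e-3)

    def test_splay_variance_and_mean(self):
        spec = pm.DirectorSampleSpec(kappa_true=33.7, area_per_lipid=0.64,
                                     temperature=310.0, n_samples=100_000,
                                     J_s=0.227, seed=5)
        s = pm.sample_splay_values(spec)
        expected_var = KB * 310.0 / (33.7 * 0.64)
        se_mean = np.sqrt(expected_var / len(s))
        assert np.var(s) == pytest.approx(expected_var, abs=2e-3)
        assert np.mean(s) == pytest.approx(0.227, abs=3 * se_mean)

    def test_stiff_limit_shrinks_fluctuations(self):
        spec = pm.DirectorSampleSpec(kappa_theta_true=1e9, kappa_true=1e9,
                                     n_samples=100, J_s=0.1, seed=0)
        assert np.max(np.abs(pm.sample_tilt_vectors(spec))) < 1e-3
        assert np.allclose(pm.sample_splay_values(spec), 0.1, atol=1e-3)

    def test_samples_are_gaussian(self):
        spec = pm.DirectorSampleSpec(n_samples=10_000, seed=11)
        t = pm.sample_tilt_vectors(spec)[:, 0]
        s = pm.sample_splay_values(spec)
        sd_t = np.sqrt(KB * spec.temperature / (spec.kappa_theta_true * spec.area_per_lipid))
        sd_s = np.sqrt(KB * spec.temperature / (spec.kappa_true * spec.area_per_lipid))
        assert stats.kstest(t, "norm", args=(0.0, sd_t)).pvalue > 0.01
        assert stats.kstest(s, "norm", args=(spec.J_s, sd_s)).pvalue > 0.01

    def test_determinism(self):
        spec = pm.DirectorSampleSpec(n_samples=1000, seed=9)
        assert np.array_equal(pm.sample_tilt_vectors(spec), pm.sample_tilt_vectors(spec))


class TestSyntheticPMF:
    def test_linear_tail_slope(self):
        spec = pm.SyntheticPMFSpec(gamma_true=40.0, R0=0.4)
        g = synthetic_pmf_values(spec)
        xi = spec.xi_grid
        sel = xi >= 4.0
        slopes = np.diff(g[sel]) / np.diff(xi[sel])
        expected = 2.0 * np.pi * 40.0 * 0.4 * KJ_MOL_PER_PN_NM  # 60.54 kJ/mol per xi
        assert expected == pytest.approx(60.541, abs=5e-3)
        assert np.max(np.abs(slopes / expected - 1.0)) < 1e-9

    def test_nucleation_value_exact(self):
        p = pm.make_synthetic_pmf(pm.SyntheticPMFSpec(dG_nuc_true=90.0))
        assert pm.nucleation_free_energy(p) == pytest.approx(90.0, abs=1e-6)

    def test_metastable_dip_creates_local_minimum(self):
        p = pm.make_synthetic_pmf(pm.SyntheticPMFSpec(metastable_depth=5.0))
        hits = pm.detect_metastable(p)
        assert len(hits) == 1
        xi_min, depth = hits[0]
        assert 1.0 < xi_min < 3.5
        assert depth == pytest.approx(5.0, abs=0.1)

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="span"):
            pm.SyntheticPMFSpec(xi_grid=np.linspace(0.3, 6.5, 100))

    def test_noise_determinism(self):
        a = pm.make_synthetic_pmf(pm.SyntheticPMFSpec(noise_sd=2.0, seed=3))
        b = pm.make_synthetic_pmf(pm.SyntheticPMFSpec(noise_sd=2.0, seed=3))
        assert np.array_equal(a.G, b.G)


class TestStressProfile:
    def test_moment_matches_kappa_js(self):
        # POPI-like inputs: leaflet moment must equal kappa * J_s = 7.3616
        prof = pm.make_stress_profile(J_s=0.172, kappa=42.8)
        upper = prof.z >= 0
        moment = np.trapezoid(prof.z[upper] * prof.s[upper], prof.z[upper])
        assert moment == pytest.approx(42.8 * 0.172, abs=1e-9)
        assert spontaneous_curvature(prof, 42.8) == pytest.approx(0.172, abs=1e-3)

    def test_zero_curvature_zero_moment(self):
        prof = pm.make_stress_profile(J_s=0.0, kappa=40.0)
        upper = prof.z >= 0
        moment = np.trapezoid(prof.z[upper] * prof.s[upper], prof.z[upper])
        assert abs(moment) < 1e-9
        assert np.max(np.abs(prof.s)) > 0  # structured profile, not trivially zero

    def test_moment_linear_in_kappa(self):
        p1 = pm.make_stress_profile(J_s=0.1, kappa=30.0)
        p2 = pm.make_stress_profile(J_s=0.1, kappa=60.0)
        up = p1.z >= 0
        m1 = np.trapezoid(p1.z[up] * p1.s[up], p1.z[up])
        m2 = np.trapezoid(p2.z[up] * p2.s[up], p2.z[up])
        assert m2 == pytest.approx(2.0 * m1, rel=1e-9)

    def test_asymmetric_grid_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pm.make_stress_profile(0.1, 30.0, grid=np.linspace(-1.0, 2.0, 200))
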