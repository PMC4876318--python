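import numpy as np
import pytest
from scipy.integrate import quad

import fibretex as fx
from fibretex.model import ModelError, read_model_config, write_model_config


class TestWeight:
    def test_peak_value(self):
        d = fx.FibreDistribution(12.0, 30.0)
        assert fx.weight(12.0, d) == pytest.approx(1.0 / (30.0 * np.sqrt(np.pi)))

    def test_apolar_periodicity(self):
        d = fx.FibreDistribution(20.0, 40.0)
        g = np.array([-50.0, 3.0, 88.0])
        assert np.allclose(fx.weight(g, d), fx.weight(g + 180.0, d), rtol=1e-12)

    @pytest.mark.parametrize("dgamma0", [10.0, 50.0, 89.3])
    def test_normalized_over_one_period(self, dgamma0):
        d = fx.FibreDistribution(25.0, dgamma0)
        total, _ = quad(lambda g: fx.weight(g, d), 0.0, 180.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_about_centre(self):
        d = fx.FibreDistribution(-30.0, 55.0)
        off = np.array([5.0, 31.0, 77.0])
        assert np.allclose(fx.weight(-30.0 + off, d), fx.weight(-30.0 - off, d))

    def test_two_root_mode_close_to_wrapped(self):
        # unwrapped two-root density is periodic and near-normalized
        d = fx.FibreDistribution(0.0, 89.3, wrapped=False)
        g = np.linspace(0, 180, 3601)
        assert np.allclose(fx.weight(g, d), fx.weight(g + 180.0, d))
        total = np.trapezoid(fx.weight(g, d), g)
        assert total == pytest.approx(1.0, abs=1e-2)

    def test_invalid_width_rejected(self):
        with pytest.raises(ModelError):
            fx.FibreDistribution(0.0, 0.0)


class TestRingKernel:
    def test_shape_and_normalization(self):
        a_x = 0.03
        assert fx.ring_kernel(0.0, a_x) == pytest.approx(1.0 / (a_x * np.sqrt(np.pi)))
        total, _ = quad(lambda u: fx.ring_kernel(u, a_x), -1.0, 1.0)
        assert total == pytest.approx(1.0, rel=1e-9)
        assert fx.ring_kernel(0.0, a_x / 2) == pytest.approx(2 * fx.ring_kernel(0.0, a_x))

    def test_invalid_width_rejected(self):
        with pytest.raises(ModelError):
            fx.ring_kernel(0.0, -0.1)


class TestQSIntensity:
    def test_pole_is_global_maximum(self, geometry):
        # every fibril ring passes through the +-y poles: constructive sum
        dist = fx.FibreDistribution(0.0, 30.0)
        q = geometry.q_ring
        rng = np.random.default_rng(1)
        v = rng.normal(size=(200, 3))
        v = q * v / np.linalg.norm(v, axis=1)[:, None]
        sphere = fx.qs_intensity(v, dist, a_x=0.02, q_ring=q)
        pole = fx.qs_intensity(np.array([0.0, q, 0.0]), dist, a_x=0.02, q_ring=q)
        assert pole >= sphere.max()

    def test_beam_parallel_q_is_dark(self, geometry):
        # q along the fibril axis cannot satisfy an equatorial reflection
        dist = fx.FibreDistribution(0.0, 30.0)
        q = geometry.q_ring
        bright = fx.qs_intensity(np.array([0.0, q, 0.0]), dist, 0.005, q_ring=q)
        dark = fx.qs_intensity(np.array([q, 0.0, 0.0]), dist, 0.005, q_ring=q)
        assert dark < 1e-5 * bright

    def test_off_sphere_rejected(self, geometry):
        with pytest.raises(ModelError):
            fx.qs_intensity(
                np.array([0.0, 1.5 * geometry.q_ring, 0.0]),
                fx.FibreDistribution(0.0, 30.0),
                0.02,
                q_ring=geometry.q_ring,
            )

    @pytest.mark.parametrize("gamma0", [0.0, 25.0, -60.0])
    def test_total_spherical_power_gamma0_invariant(self, geometry, gamma0):
        # rotating the in-plane distribution conserves diffracted power
        dist = fx.FibreDistribution(gamma0, 40.0)
        theta = np.linspace(0, np.pi, 61)[1:-1]
        phi = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        q = geometry.q_ring * np.stack(
            [np.sin(tt) * np.sin(pp), np.cos(tt), np.sin(tt) * np.cos(pp)], axis=-1
        )
        inten = fx.qs_intensity(q, dist, 0.05, n_gamma=720)
        power = np.sum(inten * np.sin(tt))
        ref_power = getattr(self, "_ref", None)
        if ref_power is None:
            type(self)._ref = power
        else:
            assert power == pytest.approx(ref_power, rel=1e-3)


class TestQSMap:
    def test_untilted_maxima_at_vertical_poles(self, geometry):
        df = fx.qs_map(fx.FibreDistribution(0.0, 30.0), 0.0, 0.0, 0.05, 19, 24, geometry)
        top = df.loc[df.intensity.idxmax()]
        assert top.theta_deg in (0.0, 180.0)

    def test_beta_rigidly_rotates_map(self, geometry):
        # a 45 deg beta tilt moves the maxima 45 deg around the beam axis
        dist = fx.FibreDistribution(0.0, 30.0)
        base = fx.qs_map(dist, 0.0, 0.0, 0.05, 37, 8, geometry)
        tilted = fx.qs_map(dist, 0.0, 45.0, 0.05, 37, 8, geometry)
        phi0 = base[np.isclose(base.phi_deg, 0.0)].set_index("theta_deg").intensity
        phi0_tilted = tilted[np.isclose(tilted.phi_deg, 0.0)].set_index("theta_deg").intensity
        assert phi0.idxmax() in (0.0, 180.0)
        # the rotated band maxima sit 45 deg from the poles in this plane
        t_tilt = phi0_tilted.idxmax()
        assert min(abs(t_tilt - 45.0), abs(t_tilt - 135.0)) <= 5.0

    def test_gamma0_apolar_invariance(self, geometry):
        a = fx.qs_map(fx.FibreDistribution(30.0, 25.0), 0, 0, 0.05, 13, 12, geometry)
        b = fx.qs_map(fx.FibreDistribution(210.0, 25.0), 0, 0, 0.05, 13, 12, geometry)
        assert np.allclose(a.intensity, b.intensity, rtol=1e-10)

    def test_mesh_size_validated(self, geometry):
        with pytest.raises(ModelError):
            fx.qs_map(fx.FibreDistribution(0, 30), 0, 0, 0.05, 1, 12, geometry)


class TestProfiles:
    def test_untilted_lobes_centred_on_vertical(self, geometry, untilted):
        # lobe centres at chi = 90/270 (the sharp-ring notch splits the
        # maxima symmetrically about the vertical, so use circular means)
        chi = np.arange(0.0, 360.0, 0.25)
        inten = fx.profile_integral(chi, untilted, geometry, a_x=0.02)
        upper = (chi > 0) & (chi < 180)
        c = np.deg2rad(chi[upper])
        w = inten[upper]
        centre = np.degrees(np.arctan2(np.sum(w * np.sin(c)), np.sum(w * np.cos(c))))
        assert centre == pytest.approx(90.0, abs=0.5)
        assert fx.peak_separation(chi, inten) == pytest.approx(180.0, abs=0.3)

    def test_width_shrinks_as_spread_grows(self, geometry):
        chi = np.arange(0.0, 360.0, 0.25)
        widths = []
        for dg in (30.0, 60.0):
            lam = fx.LamellaModel(0, 0, fx.FibreDistribution(0, dg))
            widths.append(fx.halfmax_arc(chi, fx.profile_integral(chi, lam, geometry, 0.02)))
        assert widths[1] < widths[0]

    def test_zero_scale_is_dark(self, geometry, chi_coarse):
        lam = fx.LamellaModel(3, 7, fx.FibreDistribution(10, 40), scale=0.0)
        assert np.all(fx.profile_integral(chi_coarse, lam, geometry, 0.02) == 0.0)
        assert np.all(fx.profile_closed(chi_coarse, lam, geometry) == 0.0)

    def test_closed_untilted_equal_heights(self, geometry, untilted, chi_fine):
        inten = fx.profile_closed(chi_fine, untilted, geometry)
        upper = inten[(chi_fine > 0) & (chi_fine < 180)].max()
        lower = inten[(chi_fine > 180)].max()
        assert upper == pytest.approx(lower, rel=1e-12)

    def test_alpha_tilt_strengthens_upper_peak(self, geometry, chi_fine):
        lam = fx.LamellaModel(5.0, 0.0, fx.FibreDistribution(0.0, 30.0))
        inten = fx.profile_closed(chi_fine, lam, geometry)
        upper = inten[(chi_fine > 0) & (chi_fine < 180)].max()
        lower = inten[(chi_fine > 180)].max()
        assert upper > lower

    def test_degenerate_pole_flagged(self, geometry):
        # alpha chosen so the Ewald point at chi = 90 hits the body pole
        q = geometry.q_ring
        qx = -q * q / (2 * geometry.k)
        alpha_star = np.degrees(np.arctan2(-qx, np.sqrt(q * q - qx * qx)))
        lam = fx.LamellaModel(alpha_star, 0.0, fx.FibreDistribution(0.0, 30.0))
        inten, mask = fx.profile_closed(
            np.array([90.0, 45.0]), lam, geometry, return_mask=True
        )
        assert mask.tolist() == [True, False]
        assert np.all(np.isfinite(inten))

    def test_closed_matches_integral_oracle(self, geometry, untilted):
        # a_x -> 0 convergence of the quadrature model to the closed form
        chi = np.arange(0.0, 360.0, 0.25)
        closed = fx.profile_closed(chi, untilted, geometry)
        closed = closed / closed.max()
        errs = []
        for a_x in (0.08, 0.04, 0.02, 0.01, 0.005):
            integral = fx.profile_integral(chi, untilted, geometry, a_x)
            integral = integral / integral.max()
            errs.append(np.linalg.norm(closed - integral) / np.linalg.norm(integral))
        assert all(np.diff(errs) < 0)
        assert errs[-1] < 0.01


class TestBetaSmoothing:
    def test_narrow_kernel_recovers_closed_form(self, geometry, untilted, chi_coarse):
        closed = fx.profile_closed(chi_coarse, untilted, geometry)
        smoothed = fx.beta_smoothed_profile(chi_coarse, untilted, geometry, delta_beta=0.01)
        ok = closed > 0.01 * closed.max()  # away from the degenerate notch
        assert np.allclose(smoothed[ok], closed[ok], rtol=1e-3)

    def test_notch_removed_for_broad_distribution(self, geometry):
        # the a_x -> 0 artefact at chi = +-90 is filled by the beta kernel
        chi = np.arange(80.0, 100.01, 0.2)
        lam = fx.LamellaModel(0.0, 0.0, fx.FibreDistribution(0.0, 80.0))
        inten = fx.beta_smoothed_profile(chi, lam, geometry)
        sel = (chi >= 87.0) & (chi <= 93.0)
        interior = inten[sel]
        assert np.argmax(interior) not in (0, interior.size - 1)
        assert np.all(np.diff(inten[(chi >= 87.0) & (chi <= 90.0)]) >= 0)

    def test_kernel_parameters_validated(self, geometry, untilted, chi_coarse):
        with pytest.raises(ModelError):
            fx.beta_smoothed_profile(chi_coarse, untilted, geometry, delta_beta=-1.0)
        with pytest.raises(ModelError):
            fx.beta_smoothed_profile(chi_coarse, untilted, geometry, n_kernel=4)


class TestTwoFamily:
    def test_reduces_to_single_family(self, geometry, chi_coarse, make_single_family):
        model = make_single_family(alpha=2, beta=5, gamma0=15, dgamma0=35)
        combined = fx.two_family_profile(chi_coarse, model, geometry)
        alone = fx.beta_smoothed_profile(chi_coarse, model.ip, geometry)
        assert np.allclose(combined, alone)

    def test_pointwise_linearity(self, geometry, chi_coarse):
        m = fx.TELSON_CARINA["I"]
        doubled = fx.TwoFamilyModel(
            ip=m.ip.replace(scale=2 * m.ip.scale),
            op=m.op.replace(scale=2 * m.op.scale),
            background=2 * m.background + 2.0,
        )
        base = fx.two_family_profile(chi_coarse, m, geometry)
        twice = fx.two_family_profile(
            chi_coarse,
            fx.TwoFamilyModel(ip=m.ip, op=m.op, background=m.background + 1.0),
            geometry,
        )
        assert np.allclose(fx.two_family_profile(chi_coarse, doubled, geometry), 2 * twice)

    def test_config_file_round_trip(self, tmp_path):
        m = fx.TELSON_CARINA["III"]
        path = tmp_path / "model.cfg"
        write_model_config(m, path, extras={"a_x_invA": 0.02, "delta_beta_deg": 5.0})
        m2, extras = read_model_config(path)
        assert m2 == m
        assert extras["a_x_invA"] == 0.02


class TestSymmetries:
    """Exact invariances of the closed-form profile."""

    def test_beta_is_a_rigid_shift(self, geometry, chi_fine):
        beta0 = 25.0
        base = fx.LamellaModel(0.0, 0.0, fx.FibreDistribution(20.0, 40.0))
        tilted = base.replace(beta=beta0)
        # positive beta shifts the pattern toward larger chi: I_b(x) = I_0(x - b)
        i_base = fx.profile_closed(chi_fine, base, geometry)
        i_tilt = fx.profile_closed((chi_fine + beta0) % 360.0, tilted, geometry)
        assert np.allclose(i_base, i_tilt, rtol=1e-10)

    def test_alpha_mirror_symmetry(self, geometry, chi_fine):
        dist = fx.FibreDistribution(0.0, 35.0)
        plus = fx.profile_closed(chi_fine, fx.LamellaModel(7.0, 0.0, dist), geometry)
        minus = fx.profile_closed(-chi_fine, fx.LamellaModel(-7.0, 0.0, dist), geometry)
        assert np.allclose(plus, minus, rtol=1e-10)

    @pytest.mark.parametrize(
        "gamma0,comparison",
        [(0.0, "eq"), (15.0, "lt"), (45.0, "lt"), (-15.0, "gt"), (-40.0, "gt")],
    )
    def test_peak_separation_tracks_gamma0_sign(self, geometry, chi_fine, gamma0, comparison):
        lam = fx.LamellaModel(0.0, 0.0, fx.FibreDistribution(gamma0, 30.0))
        sep = fx.peak_separation(chi_fine, fx.profile_closed(chi_fine, lam, geometry))
        if comparison == "eq":
            assert sep == pytest.approx(180.0, abs=1e-6)
        elif comparison == "lt":
            assert sep < 180.0
        else:
            assert sep > 180.0

    def test_fwhm_monotone_in_spread(self, geometry):
        chi = np.arange(0.0, 360.0, 0.25)
        widths = []
        for dg in (20.0, 35.0, 50.0, 65.0, 80.0):
            lam = fx.LamellaModel(0.0, 0.0, fx.FibreDistribution(0.0, dg))
            widths.append(fx.halfmax_arc(chi, fx.beta_smoothed_profile(chi, lam, geometry)))
        assert all(np.diff(widths) < 0)


class TestSublamella:
    def test_peak_thickness(self):
        d = fx.FibreDistribution(30.0, 50.0)
        t = fx.sublamella_thickness(5.0, 30.0, 1.0, d)
        assert t == pytest.approx(5.0 / (50.0 * np.sqrt(np.pi)), rel=1e-4)

    def test_partition_conserves_total_thickness(self):
        d = fx.FibreDistribution(-20.0, 65.0)
        dg = 0.5
        gammas = np.arange(0.0, 180.0, dg) + dg / 2
        total = np.sum(fx.sublamella_thickness(5.0, gammas, dg, d))
        assert total == pytest.approx(5.0, abs=1e-3 * 5.0)

    def test_near_uniform_limit(self):
        # very broad distribution: all sublamellae approach equal thickness
        d = fx.FibreDistribution(0.0, 2000.0)
        vals = fx.sublamella_thickness(5.0, np.arange(0, 180, 15.0), 1.0, d)
        assert np.ptp(vals) / vals.mean() < 0.01

    def test_invalid_arguments_rejected(self):
        d = fx.FibreDistribution(0.0, 45.0)
        with pytest.raises(ModelError):
            fx.sublamella_thickness(-1.0, 0.0, 1.0, d)
        with pytest.raises(ModelError):
            fx.sublamella_thickness(1.0, 0.0, 0.0, d)
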