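import math

import numpy as np
import pytest

from uedindex.crystal import Reflection
from uedindex.geometry import DetectorGeometry, OrientationAngles, orientation_matrix
from uedindex.predict import predict_arrays
from uedindex.profiles import (BeamModel, MosaicityModel, ShapeTransform,
                               aniso_predict, effective_mosaic_cov,
                               effective_mosaic_sigma, local_frame,
                               shape_sigma_from_size, standard_predict,
                               tangent_covariance)

GEOM = DetectorGeometry(pixel_size_mm=0.05, camera_length_mm=500.0,
                        wavelength_A=0.037, beam_center=(256.0, 256.0))
K = 1.0 / GEOM.wavelength_A


def _refl(g, F2=1.0):
    g = np.asarray(g, float)
    h = float(np.linalg.norm(g))
    return Reflection(hkl=(1, 0, 0), h_vec_crystal=g, h_len=h, d=1 / h, F2=F2)


def _on_sphere(h, az=0.0):
    """Lab vector of length h exactly on the Ewald sphere."""
    gz = -h * h / (2 * K)
    gp = math.sqrt(h * h - gz * gz)
    return np.array([gp * math.cos(az), gp * math.sin(az), gz])


class TestShapeSigma:
    def test_plate_factor(self):
        sigma_z, sigma_q = shape_sigma_from_size("plate", 235.0)
        assert sigma_z == pytest.approx(100.0)
        assert sigma_q == pytest.approx(1 / (2 * math.pi * 100.0))

    def test_sphere_factor(self):
        sigma_z, _ = shape_sigma_from_size("sphere", 299.0)
        assert sigma_z == pytest.approx(100.0)

    def test_perfect_crystal_limit(self):
        _, sigma_q = shape_sigma_from_size("plate", 1e9)
        assert sigma_q < 1e-9

    def test_nonpositive_extent(self):
        with pytest.raises(ValueError):
            shape_sigma_from_size("plate", 0.0)


class TestEffectiveMosaic:
    def test_beam_terms_zero(self):
        mos = MosaicityModel(sigma_iso_deg=2.0)
        s = effective_mosaic_sigma(mos, BeamModel(), 0.5, 0.037)
        assert s == pytest.approx(math.radians(2.0))

    def test_3_4_5_quadrature(self):
        mos = MosaicityModel(sigma_iso_deg=math.degrees(3e-3))
        s = effective_mosaic_sigma(mos, BeamModel(sigma_divg=4e-3), 0.5, 0.037)
        assert s == pytest.approx(5e-3)

    def test_bandwidth_term_proportional_to_h(self):
        mos = MosaicityModel(sigma_iso_deg=0.0)
        beam = BeamModel(sigma_bwdth=1e-3)
        s1 = effective_mosaic_sigma(mos, beam, 0.3, 0.037)
        s2 = effective_mosaic_sigma(mos, beam, 0.6, 0.037)
        assert s2 / s1 == pytest.approx(2.0, rel=1e-12)

    def test_cov_divergence_rank2_update(self):
        mos = MosaicityModel(mode="anisotropic", sigmas_deg=(1.0, 1.0, 1.0))
        cov = effective_mosaic_cov(mos, BeamModel(sigma_divg=2e-3), 0.5, 0.037)
        s2 = math.radians(1.0) ** 2
        ev = np.sort(np.linalg.eigvalsh(cov))
        assert ev[0] == pytest.approx(s2)
        assert ev[1] == pytest.approx(s2 + 4e-6)
        assert ev[2] == pytest.approx(s2 + 4e-6)

    def test_cov_matches_scalar_marginal(self):
        # compare the tangent-plane variance along the excitation direction
        # for h perpendicular to the beam
        sig = 1.5
        mos_a = MosaicityModel(mode="anisotropic", sigmas_deg=(sig,) * 3)
        mos_i = MosaicityModel(sigma_iso_deg=sig)
        beam = BeamModel(sigma_divg=1e-3, sigma_bwdth=5e-4)
        h = 0.5
        cov = effective_mosaic_cov(mos_a, beam, h, 0.037)
        frame = local_frame(np.array([h, 0.0, 0.0]))
        Sh = tangent_covariance(cov, frame, h)
        scalar = effective_mosaic_sigma(mos_i, beam, h, 0.037)
        # rho2 (in-plane, e2) displacement variance = h^2 * Sigma11(omega)
        assert Sh[1, 1] == pytest.approx((h * scalar) ** 2, rel=1e-12)


class TestLocalFrame:
    def test_h_along_x(self):
        f = local_frame(np.array([1.0, 0.0, 0.0]))
        assert np.allclose(f.e3, [1, 0, 0])
        assert np.allclose(f.e1, [0, 1, 0])
        assert np.allclose(f.e2, [0, 0, 1])

    def test_orthonormality(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            f = local_frame(rng.normal(size=3))
            E = np.vstack([f.e1, f.e2, f.e3])
            assert np.allclose(E @ E.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(E) == pytest.approx(1.0)

    def test_degenerate_parallel_beam(self):
        f = local_frame(np.array([0.0, 0.0, 2.0]))
        assert np.allclose(f.e1, [1, 0, 0])

    def test_zero_vector_error(self):
        with pytest.raises(ValueError):
            local_frame(np.zeros(3))


class TestTangentCovariance:
    def test_block_swap_formula(self):
        a, b, c = 4.0, 1.2, 2.5
        cov = np.diag([a, c, 9.0])
        cov[0, 1] = cov[1, 0] = b
        f = local_frame(np.array([1.0, 0.0, 0.0]))
        # in this frame (e1=y, e2=z, e3=x): Sigma(12) entries are
        # [[cov_yy, cov_yz], [cov_zy, cov_zz]] of the rotated matrix;
        # build the omega covariance directly in frame coordinates instead
        E = np.vstack([f.e1, f.e2, f.e3])
        cov_lab = E.T @ np.array([[a, b, 0], [b, c, 0], [0, 0, 9.0]]) @ E
        Sh = tangent_covariance(cov_lab, f, 2.0)
        assert np.allclose(Sh, 4.0 * np.array([[c, -b], [-b, a]]), atol=1e-12)

    def test_isotropic_any_direction(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            h = rng.normal(size=3)
            hl = np.linalg.norm(h)
            Sh = tangent_covariance(np.eye(3) * 2.5, local_frame(h), hl)
            assert np.allclose(Sh, np.eye(2) * 2.5 * hl ** 2, atol=1e-12)

    def test_determinant_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            A = rng.normal(size=(3, 3))
            cov = A @ A.T
            h = rng.normal(size=3)
            hl = np.linalg.norm(h)
            f = local_frame(h)
            E = np.vstack([f.e1, f.e2])
            S12 = E @ cov @ E.T
            Sh = tangent_covariance(cov, f, hl)
            assert np.linalg.det(Sh) == pytest.approx(
                hl ** 4 * np.linalg.det(S12), rel=1e-9)


class TestAnisoPredict:
    MOS = MosaicityModel(sigma_iso_deg=2.0)
    NOSHAPE = ShapeTransform(sigma_shp=0.0)

    def test_on_sphere_maximizes_partiality_and_centroid(self):
        g = _on_sphere(0.4)
        refl = _refl(g)
        p0 = aniso_predict(refl, np.eye(3), GEOM, self.MOS, self.NOSHAPE,
                           BeamModel())
        assert p0.e_mos == pytest.approx(0.0, abs=1e-12)
        # the centroid equals the geometric projection of the RLP
        kf = g + np.array([0, 0, K])
        x_exp = 500 * kf[0] / kf[2] / 0.05 + 256
        assert p0.x == pytest.approx(x_exp, abs=1e-9)
        # any off-sphere version of the same RLP has lower partiality
        for a_deg in (0.5, -0.8, 2.0):
            a = math.radians(a_deg)
            Ry = np.array([[math.cos(a), 0, math.sin(a)], [0, 1, 0],
                           [-math.sin(a), 0, math.cos(a)]])
            p = aniso_predict(_refl(Ry @ g), np.eye(3), GEOM, self.MOS,
                              self.NOSHAPE, BeamModel())
            assert p.partiality < p0.partiality

    def test_closed_form_isotropic_ratio(self):
        sig = math.radians(2.0)
        h = 0.35
        g0 = _on_sphere(h)
        I0 = aniso_predict(_refl(g0), np.eye(3), GEOM, self.MOS, self.NOSHAPE,
                           BeamModel()).intensity
        for off_deg in (1.0, 2.5, 4.0):
            a = math.radians(off_deg)
            Ry = np.array([[math.cos(a), 0, math.sin(a)], [0, 1, 0],
                           [-math.sin(a), 0, math.cos(a)]])
            I = aniso_predict(_refl(Ry @ g0), np.eye(3), GEOM, self.MOS,
                              self.NOSHAPE, BeamModel()).intensity
            e = h * a
            assert I / I0 == pytest.approx(
                math.exp(-e * e / (2 * h * h * sig * sig)), rel=5e-3)

    def test_monte_carlo_oracle_small(self):
        # two randomized anisotropic cases against exact-rotation sampling
        rng = np.random.default_rng(10)
        for _ in range(2):
            sig = np.radians(rng.uniform(0.5, 2.0, 3))
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            cov = Q @ np.diag(sig ** 2) @ Q.T
            h = rng.uniform(0.2, 0.7)
            g = _on_sphere(h, az=rng.uniform(0, 2 * np.pi))
            a = rng.normal(0, np.mean(sig))
            Rx = np.array([[1, 0, 0], [0, math.cos(a), -math.sin(a)],
                           [0, math.sin(a), math.cos(a)]])
            g = Rx @ g

            class AnisoCov:
                mode = "anisotropic"
                def cov_omega(self):
                    return cov

            pred = predict_arrays(np.array([[1, 0, 0]]), g[None, :],
                                  np.array([h]), np.array([1.0]),
                                  R=np.eye(3), geom=GEOM, mos=AnisoCov(),
                                  shape=self.NOSHAPE, beam=BeamModel(),
                                  aniso=True, cutoff_sigma=np.inf)
            I_pred = pred.intensity[0] if len(pred) else 0.0
            n = 400_000
            w = rng.multivariate_normal(np.zeros(3), cov, size=n)
            ang = np.linalg.norm(w, axis=1)
            axis = w / np.maximum(ang, 1e-300)[:, None]
            ct, st = np.cos(ang), np.sin(ang)
            dotg = axis @ g
            gp = (ct[:, None] * g + st[:, None] * np.cross(axis, g)
                  + ((1 - ct) * dotg)[:, None] * axis)
            r = np.linalg.norm(gp + [0, 0, K], axis=1) - K
            delta = 2 * h * np.mean(sig) / 50
            cnt = np.sum(np.abs(r) < delta)
            dens = cnt / (n * 2 * delta)
            se = math.sqrt(max(cnt, 1)) / (n * 2 * delta)
            assert abs(I_pred - dens) < 3 * se + 0.01 * dens


class TestStandardPredict:
    def test_shape_dominated_is_pure_case_b(self):
        h = 0.4
        g = _on_sphere(h)
        a = math.radians(1.0)
        Ry = np.array([[math.cos(a), 0, math.sin(a)], [0, 1, 0],
                       [-math.sin(a), 0, math.cos(a)]])
        refl = _refl(Ry @ g)
        mos_tiny = MosaicityModel(sigma_iso_deg=1e-4)
        shape_big = ShapeTransform(sigma_shp=5e-3)
        p = standard_predict(refl, np.eye(3), GEOM, mos_tiny, shape_big,
                             BeamModel(), cutoff_sigma=np.inf)
        sstar = math.sqrt(shape_big.sigma_shp ** 2
                          + (h * math.radians(1e-4)) ** 2)
        dens_b = math.exp(-p.e_shp ** 2 / (2 * sstar ** 2)) / \
            (sstar * math.sqrt(2 * math.pi))
        assert p.intensity == pytest.approx(dens_b, rel=1e-3)

    def test_mosaic_dominated_is_pure_case_a(self):
        h = 0.4
        g = _on_sphere(h)
        a = math.radians(1.0)
        Ry = np.array([[math.cos(a), 0, math.sin(a)], [0, 1, 0],
                       [-math.sin(a), 0, math.cos(a)]])
        refl = _refl(Ry @ g)
        mos_big = MosaicityModel(sigma_iso_deg=2.0)
        shape_tiny = ShapeTransform(sigma_shp=1e-8)
        p = standard_predict(refl, np.eye(3), GEOM, mos_big, shape_tiny,
                             BeamModel(), cutoff_sigma=np.inf)
        sstar = math.sqrt(shape_tiny.sigma_shp ** 2
                          + (h * math.radians(2.0)) ** 2)
        dens_a = math.exp(-p.e_mos ** 2 / (2 * sstar ** 2)) / \
            (sstar * math.sqrt(2 * math.pi))
        assert p.intensity == pytest.approx(dens_a, rel=1e-3)

    def test_aniso_matches_standard_case_a_within_1pct(self):
        # isotropic mosaicity, no shape: the two modelings agree on a grid
        # of excitation errors out to 3 sigma
        mos = MosaicityModel(sigma_iso_deg=2.0)
        noshape = ShapeTransform(sigma_shp=0.0)
        h = 0.45
        g0 = _on_sphere(h)
        sig = math.radians(2.0)
        for frac in np.linspace(0, 3, 7):
            a = frac * sig
            Ry = np.array([[math.cos(a), 0, math.sin(a)], [0, 1, 0],
                           [-math.sin(a), 0, math.cos(a)]])
            refl = _refl(Ry @ g0)
            pa = aniso_predict(refl, np.eye(3), GEOM, mos, noshape,
                               BeamModel(), cutoff_sigma=np.inf)
            ps = standard_predict(refl, np.eye(3), GEOM, mos, noshape,
                                  BeamModel(), cutoff_sigma=np.inf)
            assert pa.intensity == pytest.approx(ps.intensity, rel=1e-2)


class TestEngineInvariants:
    def test_intensities_invariant_under_beam_rotation(self, cubic_carbon):
        from uedindex.crystal import reflection_table
        hkl, hv, hl, F2 = reflection_table(cubic_carbon, 2.0)
        mos = MosaicityModel(sigma_iso_deg=1.5)
        shape = ShapeTransform(sigma_shp=1e-3)
        kw = dict(geom=GEOM, mos=mos, shape=shape, beam=BeamModel(),
                  aniso=True)
        R = orientation_matrix(OrientationAngles(40.0, 10.0, 0.0))
        base = predict_arrays(hkl, hv, hl, F2, R=R, **kw)
        Rz = orientation_matrix(OrientationAngles(0.0, 0.0, 30.0))
        rot = predict_arrays(hkl, hv, hl, F2, R=Rz @ R, **kw)
        assert np.allclose(np.sort(base.intensity), np.sort(rot.intensity),
                           rtol=1e-9)

    def test_total_intensity_smooth_in_orientation(self, cubic_carbon):
        from uedindex.crystal import reflection_table
        hkl, hv, hl, F2 = reflection_table(cubic_carbon, 2.0)
        mos = MosaicityModel(sigma_iso_deg=2.0)
        kw = dict(geom=GEOM, mos=mos, shape=ShapeTransform(sigma_shp=1e-3),
                  beam=BeamModel(), aniso=True, cutoff_sigma=6.0)
        totals = []
        for dth in np.arange(0, 10) * 0.01:
            R = orientation_matrix(OrientationAngles(40.0 + dth, 10.0, 5.0))
            totals.append(predict_arrays(hkl, hv, hl, F2, R=R,
                                         **kw).intensity.sum())
        totals = np.array(totals)
        rel_step = np.abs(np.diff(totals)) / totals.max()
        assert np.all(rel_step < 0.01)
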