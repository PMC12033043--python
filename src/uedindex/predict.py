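"""Vectorized Bragg-spot prediction engine.

Given a reflection table (crystal-frame reciprocal vectors with |F|^2), an
orientation and the imperfection models, compute for every RLP its
excitation errors, Gaussian profile factor, integrated intensity and
detector centroid.  Both the anisotropic and the standard model share the
same geometric core; the orientation grid search uses the polar-coordinate
output so that the rotation of the crystal about the beam reduces to an
azimuth shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import DetectorGeometry, TiltState, apply_plane_rotation_and_distortion
from .profiles import (
    BeamModel,
    EXC_ERROR_FLOOR,
    MosaicityModel,
    ShapeTransform,
    SpotPrediction,
    bandwidth_constant,
    effective_mosaic_sigma,
)

__all__ = ["PredictionArrays", "predict_arrays", "predictions_to_spots"]

_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class PredictionArrays:
    """Columnar prediction result (only reflections above the cutoff)."""

    index: np.ndarray      # indices into the input reflection table
    hkl: np.ndarray        # (M, 3) int
    r_mm: np.ndarray       # gnomonic radius before image rotation/distortion
    az: np.ndarray         # gnomonic azimuth (rad) before rotation/distortion
    intensity: np.ndarray
    e_mos: np.ndarray
    e_shp: np.ndarray
    partiality: np.ndarray

    def __len__(self):
        return len(self.index)

    def detector_xy(self, geom: DetectorGeometry, psi_offset_rad: float = 0.0):
        """Pixel coordinates, optionally with an extra rotation about the
        beam (used by the orientation scan)."""
        x, y = apply_plane_rotation_and_distortion(
            self.r_mm, self.az + psi_offset_rad, geom)
        return np.stack([x, y], axis=-1)


def _local_frames(g, hlen):
    e3 = g / hlen[:, None]
    c = np.stack([-e3[:, 1], e3[:, 0], np.zeros(len(e3))], axis=1)  # z x e3
    cn = np.linalg.norm(c, axis=1)
    deg = cn < 1e-12
    e1 = np.empty_like(e3)
    e1[~deg] = c[~deg] / cn[~deg, None]
    e1[deg] = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e3, e1)
    return e1, e2, e3


def _arc_excitation(hlen, wavelength_A, c2, c3):
    """Signed arc-length excitation error on S_h (in the k_i-h plane).

    Solves sin(a) c2 + cos(a) c3 = -h lambda / 2 for the rotation angle a
    (about e1) that brings the RLP onto the Ewald sphere; e_mos = h * a of
    the smaller-|a| solution.  Where no solution exists (RLP sphere does not
    reach the Ewald sphere) the returned mask is False.
    """
    amp = np.hypot(c2, c3)
    t_req = -hlen * wavelength_A / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = t_req / amp
    solvable = (amp > 0) & (np.abs(ratio) <= 1.0)
    ratio = np.clip(ratio, -1.0, 1.0)
    phase = np.arctan2(c3, c2)
    base = np.arcsin(ratio)
    a1 = base - phase
    a2 = math.pi - base - phase
    wrap = lambda a: (a + math.pi) % (2.0 * math.pi) - math.pi
    a1, a2 = wrap(a1), wrap(a2)
    alpha = np.where(np.abs(a1) <= np.abs(a2), a1, a2)
    return hlen * alpha, solvable


def _relrod_excitation(rvec, rnorm, k, u):
    """Signed distance along direction u from the RLP to the Ewald sphere."""
    b = rvec @ u
    c0 = rnorm ** 2 - k ** 2
    disc = b * b - c0
    real = disc >= 0
    root = np.sqrt(np.abs(disc))
    s1 = -b + root
    s2 = -b - root
    s = np.where(np.abs(s1) <= np.abs(s2), s1, s2)
    # no intersection: report the distance of closest approach (for reports;
    # such reflections carry ~zero intensity anyway)
    s = np.where(real, s, np.sign(c0) * np.sqrt(np.maximum(c0 - b * b, 0.0)))
    return s, real


def predict_arrays(hkl, hvec_cryst, hlen, F2, *, R, geom: DetectorGeometry,
                   mos: MosaicityModel, shape: ShapeTransform,
                   beam: BeamModel, aniso: bool, scale: float = 1.0,
                   b_global: float = 0.0, tilt: TiltState | None = None,
                   image_index: int = 0, tilt_use: bool = False,
                   cutoff_sigma: float = 4.0) -> PredictionArrays:
    """Predict all reflections for one orientation; see module docstring.

    ``b_global`` attenuates intensities by exp(-B h^2 / 2).  ``tilt_use``
    rotates the standard-mode relrod direction with the sample tilt.
    """
    N = len(hlen)
    if N == 0:
        z = np.zeros(0)
        return PredictionArrays(z.astype(int), np.zeros((0, 3), int), z, z, z, z, z, z)
    lam = geom.wavelength_A
    k = 1.0 / lam
    R_total = R if tilt is None else tilt.rotation(image_index) @ R
    g = hvec_cryst @ R_total.T
    rvec = g + _Z * k
    rnorm = np.linalg.norm(rvec, axis=1)
    n = rvec / rnorm[:, None]
    d_rad = rnorm - k

    e1, e2, e3 = _local_frames(g, hlen)
    c2 = e2[:, 2]
    c3 = e3[:, 2]
    e_mos, arc_ok = _arc_excitation(hlen, lam, c2, c3)

    # relrod direction (lab): standard-mode direction, tilted with the
    # sample when requested; for an anisotropic shape, its major axis.
    if shape.mode == "standard":
        u = shape.relrod_direction()
        if tilt_use and tilt is not None:
            u = tilt.rotation(image_index) @ u
    else:
        cov_s_cryst = shape.cov()
        w, V = np.linalg.eigh(cov_s_cryst)
        u = R_total @ V[:, np.argmax(w)]
    e_shp, _ = _relrod_excitation(rvec, rnorm, k, u)

    scale_corr = 1.0
    if tilt is not None:
        scale_corr = tilt.scale_corrections[image_index]
    amp = scale * scale_corr * F2 * np.exp(-b_global * hlen ** 2 / 2.0)

    if aniso:
        # effective mosaic covariance, lab frame: base + beta h^2 I
        cov0 = mos.cov_omega().copy()
        cov0[0, 0] += beam.sigma_divg ** 2
        cov0[1, 1] += beam.sigma_divg ** 2
        beta = (bandwidth_constant(lam) * beam.sigma_bwdth) ** 2
        cov_s_lab = R_total @ shape.cov() @ R_total.T if shape.mode == "aniso" \
            else shape.cov()  # standard cov() is already lab-frame
        n_loc = np.stack([np.einsum("ni,ni->n", n, e1),
                          np.einsum("ni,ni->n", n, e2),
                          np.einsum("ni,ni->n", n, e3)], axis=1)
        nt = np.hypot(n_loc[:, 0], n_loc[:, 1])
        # arc-corrected offset of the Ewald surface from the RLP
        delta = np.where(arc_ok, np.sign(d_rad) * np.abs(e_mos) * nt, d_rad)
        # cheap prefilter: var_n <= h^2 lmax(mosaic) + lmax(shape)
        lmax_m = float(np.linalg.eigvalsh(cov0)[-1])
        lmax_s = float(np.linalg.eigvalsh(cov_s_lab)[-1])
        var_bound = hlen ** 2 * (lmax_m + beta * hlen ** 2) + lmax_s
        if math.isfinite(cutoff_sigma):
            pre = delta ** 2 <= cutoff_sigma ** 2 * var_bound
        else:
            pre = np.ones(N, dtype=bool)
        p_ix = np.flatnonzero(pre)
        e1p, e2p, e3p = e1[p_ix], e2[p_ix], e3[p_ix]
        hp = hlen[p_ix]
        E = np.stack([e1p, e2p], axis=1)                     # (M, 2, 3)
        A = np.einsum("nij,jk,nlk->nil", E, cov0, E)
        A[:, 0, 0] += beta * hp ** 2
        A[:, 1, 1] += beta * hp ** 2
        h2 = hp ** 2
        # tangent-plane displacement covariance (rho1, rho2) + local shape
        E3 = np.stack([e1p, e2p, e3p], axis=1)               # (M, 3, 3)
        T = np.einsum("nij,jk,nlk->nil", E3, cov_s_lab, E3)
        T[:, 0, 0] += h2 * A[:, 1, 1]
        T[:, 0, 1] -= h2 * A[:, 0, 1]
        T[:, 1, 0] -= h2 * A[:, 0, 1]
        T[:, 1, 1] += h2 * A[:, 0, 0]
        nl = n_loc[p_ix]
        var_n = np.einsum("ni,nij,nj->n", nl, T, nl)
        dp = delta[p_ix]
        with np.errstate(divide="ignore", invalid="ignore"):
            expo = dp ** 2 / (2.0 * var_n)
        keep = (var_n > 1e-30) & (expo < cutoff_sigma ** 2 / 2.0)
        sub = np.flatnonzero(keep)
        idx = p_ix[sub]
        var_k = var_n[sub]
        dens = np.exp(-expo[sub]) / np.sqrt(2.0 * math.pi * var_k)
        partiality = dens
        I = amp[idx] * dens
        # conditional mean on the Ewald surface: mu = -delta T n / var
        mu_loc = (-dp[sub] / var_k)[:, None] * \
            np.einsum("nij,nj->ni", T[sub], nl[sub])
        mu_lab = (mu_loc[:, 0, None] * e1[idx] + mu_loc[:, 1, None] * e2[idx]
                  + mu_loc[:, 2, None] * e3[idx])
        p = g[idx] + mu_lab
        v = p + _Z * k
        kf = v * (k / np.linalg.norm(v, axis=1))[:, None]
        em, es = e_mos[idx], e_shp[idx]
    else:
        sig_mos = effective_mosaic_sigma(mos, beam, hlen, lam)
        sig_shp = shape.sigma_shp
        sig_star = np.sqrt(sig_shp ** 2 + (hlen * sig_mos) ** 2)
        e_mos_eff = np.where(arc_ok, e_mos, np.sign(d_rad) * hlen * math.pi)
        keep = np.minimum(np.abs(e_mos_eff), np.abs(e_shp)) \
            < cutoff_sigma * sig_star
        keep &= sig_star > 0
        idx = np.flatnonzero(keep)
        ss = sig_star[idx]
        dens_a = np.exp(-e_mos_eff[idx] ** 2 / (2 * ss ** 2)) / (ss * math.sqrt(2 * math.pi))
        dens_b = np.exp(-e_shp[idx] ** 2 / (2 * ss ** 2)) / (ss * math.sqrt(2 * math.pi))
        wa = hlen[idx] * sig_mos[idx] / np.maximum(np.abs(e_mos_eff[idx]), EXC_ERROR_FLOOR)
        wb = sig_shp / np.maximum(np.abs(e_shp[idx]), EXC_ERROR_FLOOR)
        wsum = wa + wb
        flat = wsum <= 0
        wa = np.where(flat, 0.5, wa / np.where(wsum > 0, wsum, 1.0))
        wb = 1.0 - wa
        dens = wa * dens_a + wb * dens_b
        partiality = dens
        I = amp[idx] * dens
        # case-A point: on S_h at arc angle alpha in the (e2, e3) plane,
        # p(alpha) = h (sin(alpha) e2 + cos(alpha) e3), the solved root
        alpha = np.where(arc_ok, e_mos / np.where(hlen > 0, hlen, 1.0), 0.0)[idx]
        pa = hlen[idx, None] * (np.cos(alpha)[:, None] * e3[idx]
                                + np.sin(alpha)[:, None] * e2[idx])
        pb = g[idx] + e_shp[idx, None] * u
        va = pa + _Z * k
        vb = pb + _Z * k
        kfa = va * (k / np.linalg.norm(va, axis=1))[:, None]
        kfb = vb * (k / np.linalg.norm(vb, axis=1))[:, None]
        kf = wa[:, None] * kfa + wb[:, None] * kfb
        em, es = e_mos_eff[idx], e_shp[idx]

    ok = kf[:, 2] > 0
    idx, kf, I, em, es, partiality = (idx[ok], kf[ok], I[ok], em[ok], es[ok],
                                      partiality[ok])
    L = geom.camera_length_mm
    r_mm = L * np.hypot(kf[:, 0], kf[:, 1]) / kf[:, 2]
    az = np.arctan2(kf[:, 1], kf[:, 0])
    return PredictionArrays(index=idx, hkl=np.asarray(hkl)[idx], r_mm=r_mm,
                            az=az, intensity=I, e_mos=em, e_shp=es,
                            partiality=partiality)


def predictions_to_spots(pred: PredictionArrays,
                         geom: DetectorGeometry) -> list[SpotPrediction]:
    xy = pred.detector_xy(geom)
    return [
        SpotPrediction(hkl=tuple(int(v) for v in h), x=float(x), y=float(y),
                       intensity=float(i), e_mos=float(em), e_shp=float(es),
                       partiality=float(p))
        for h, (x, y), i, em, es, p in zip(pred.hkl, xy, pred.intensity,
                                           pred.e_mos, pred.e_shp,
                                           pred.partiality)
    ]
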