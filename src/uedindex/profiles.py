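"""Gaussian diffracting-power profiles of reciprocal lattice points.

Each RLP is broadened by four independent Gaussian effects — finite domain
size (shape transform), mosaicity (orientation spread of domains), beam
divergence and energy bandwidth — and its integrated intensity and centroid
follow from intersecting the combined distribution with the Ewald sphere.

Two prediction modes exist:

* anisotropic ("ANISO"): mosaicity is a trivariate normal of rotation
  vectors with full covariance; the shape transform is a trivariate normal
  in the crystal frame.  The intensity is the integral of the combined
  Gaussian over the locally planar Ewald surface, with the offset measured
  as arc length on the constant-|h| sphere (a curvature correction beyond
  the plain tangent-plane chord).
* standard: isotropic mosaicity plus a one-dimensional relrod profile; the
  mosaic-arc (case A) and relrod (case B) estimates are blended with
  weights proportional to h*sigma_MOS/e_mos and sigma_shp/e_shp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "PLATE_FACTOR",
    "SPHERE_FACTOR",
    "MosaicityModel",
    "ShapeTransform",
    "BeamModel",
    "LocalFrame",
    "SpotPrediction",
    "shape_sigma_from_size",
    "effective_mosaic_sigma",
    "effective_mosaic_cov",
    "local_frame",
    "tangent_covariance",
    "plate_profile",
    "sphere_profile",
    "minimax_gaussian_factor",
]

#: extent / sigma_z for a thin plate (minimax Gaussian fit to the sinc^2
#: relrod profile) and for a solid sphere (fit to the FT of the z-projected
#: autocorrelation); re-derivable with :func:`minimax_gaussian_factor`.
PLATE_FACTOR = 2.35
SPHERE_FACTOR = 2.99

#: regularization floor for excitation errors in the standard-model weights
EXC_ERROR_FLOOR = 1e-6  # 1/Angstrom

#: bandwidth coupling constant: an Ewald-radius spread k*sigma_bwdth shifts
#: the sphere near an RLP at resolution h by ~ (h^2 lambda / 2) sigma_bwdth,
#: i.e. an effective angular spread a*h*sigma_bwdth with a = lambda/2.
def bandwidth_constant(wavelength_A: float) -> float:
    return wavelength_A / 2.0


def _euler_zyz(alpha_deg, beta_deg, gamma_deg):
    a, b, g = (math.radians(x) for x in (alpha_deg, beta_deg, gamma_deg))
    ca, sa, cb, sb, cg, sg = (math.cos(a), math.sin(a), math.cos(b),
                              math.sin(b), math.cos(g), math.sin(g))
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    ry = np.array([[cb, 0, sb], [0, 1.0, 0], [-sb, 0, cb]])
    rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1.0]])
    return rz1 @ ry @ rz2


@dataclass(frozen=True)
class MosaicityModel:
    """Orientation spread of coherently diffracting domains.

    ``isotropic``: a single angle sigma_iso (degrees).  ``anisotropic``:
    standard deviations along three principal axes (degrees) plus ZYZ Euler
    angles orienting the axes in the lab frame; the covariance of rotation
    vectors (rad^2) follows.  Degenerate (zero) sigmas are allowed.
    """

    mode: str = "isotropic"
    sigma_iso_deg: float = 0.0
    sigmas_deg: tuple = (0.0, 0.0, 0.0)
    euler_deg: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.mode not in ("isotropic", "anisotropic"):
            raise ValueError(f"unknown mosaicity mode {self.mode!r}")
        if self.mode == "isotropic" and self.sigma_iso_deg < 0:
            raise ValueError("sigma_iso must be >= 0")
        if self.mode == "anisotropic" and any(s < 0 for s in self.sigmas_deg):
            raise ValueError("principal sigmas must be >= 0")

    def cov_omega(self) -> np.ndarray:
        """Covariance of rotation vectors, rad^2, lab frame."""
        if self.mode == "isotropic":
            s = math.radians(self.sigma_iso_deg)
            return np.eye(3) * s * s
        U = _euler_zyz(*self.euler_deg)
        D = np.diag([math.radians(s) ** 2 for s in self.sigmas_deg])
        return U @ D @ U.T


@dataclass(frozen=True)
class ShapeTransform:
    """Finite-size (shape-transform) profile of the RLPs.

    ``standard``: a single relrod of width sigma_shp (1/A) along a direction
    given by polar tilt from +Z and azimuth (degrees), lab frame of the
    untilted image.  ``aniso``: trivariate normal with principal sigmas
    (1/A) and ZYZ Euler angles, fixed in the crystal frame.
    """

    mode: str = "standard"
    sigma_shp: float = 0.0
    tilt_deg: float = 0.0
    azimuth_deg: float = 0.0
    sigmas: tuple = (0.0, 0.0, 0.0)
    euler_deg: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.mode not in ("standard", "aniso"):
            raise ValueError(f"unknown shape mode {self.mode!r}")
        if self.sigma_shp < 0 or any(s < 0 for s in self.sigmas):
            raise ValueError("shape sigmas must be >= 0")

    def relrod_direction(self) -> np.ndarray:
        t = math.radians(self.tilt_deg)
        a = math.radians(self.azimuth_deg)
        return np.array([math.sin(t) * math.cos(a),
                         math.sin(t) * math.sin(a),
                         math.cos(t)])

    def cov(self) -> np.ndarray:
        """3x3 covariance (1/A^2); for standard mode, rank-1 along the relrod."""
        if self.mode == "standard":
            u = self.relrod_direction()
            return self.sigma_shp ** 2 * np.outer(u, u)
        U = _euler_zyz(*self.euler_deg)
        return U @ np.diag(np.square(self.sigmas)) @ U.T


@dataclass(frozen=True)
class BeamModel:
    """Beam imperfections: divergence half-angle spread (rad, rotationally
    symmetric) and fractional energy bandwidth (dimensionless)."""

    sigma_divg: float = 0.0
    sigma_bwdth: float = 0.0

    def __post_init__(self):
        if self.sigma_divg < 0 or self.sigma_bwdth < 0:
            raise ValueError("beam sigmas must be >= 0")


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal triple with e3 || h and e1 || k_i x h."""

    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray


def shape_sigma_from_size(kind: str, extent: float) -> tuple[float, float]:
    """(sigma_z, sigma_q) of the Gaussian shape profile for a given size.

    ``kind`` is "plate" (extent = thickness t, factor 2.35) or "sphere"
    (extent = diameter D, factor 2.99): sigma_z = extent / c in real space,
    sigma_q = 1/(2 pi sigma_z) in reciprocal space (Fourier-pair widths).
    """
    if extent <= 0:
        raise ValueError("extent must be positive")
    try:
        c = {"plate": PLATE_FACTOR, "sphere": SPHERE_FACTOR}[kind]
    except KeyError:
        raise ValueError(f"kind must be 'plate' or 'sphere', got {kind!r}")
    sigma_z = extent / c
    return sigma_z, 1.0 / (2.0 * math.pi * sigma_z)


def effective_mosaic_sigma(mos: MosaicityModel, beam: BeamModel,
                           h_len, wavelength_A: float):
    """sigma_MOS (rad): quadrature sum of mosaicity, divergence and the
    resolution-dependent bandwidth term (a h sigma_bwdth, a = lambda/2)."""
    if mos.mode != "isotropic":
        raise ValueError("effective_mosaic_sigma needs isotropic mosaicity")
    a = bandwidth_constant(wavelength_A)
    s0 = math.radians(mos.sigma_iso_deg)
    return np.sqrt(s0 ** 2 + beam.sigma_divg ** 2
                   + (a * np.asarray(h_len) * beam.sigma_bwdth) ** 2)


def effective_mosaic_cov(mos: MosaicityModel, beam: BeamModel,
                         h_len: float, wavelength_A: float) -> np.ndarray:
    """Effective rotation-vector covariance (rad^2, lab frame).

    Divergence adds sigma_divg^2 on the two axes perpendicular to the beam
    (a rotation about Z does not change the beam direction); the bandwidth
    term is embedded isotropically.
    """
    cov = mos.cov_omega().copy()
    cov[0, 0] += beam.sigma_divg ** 2
    cov[1, 1] += beam.sigma_divg ** 2
    a = bandwidth_constant(wavelength_A)
    cov += np.eye(3) * (a * h_len * beam.sigma_bwdth) ** 2
    return cov


def local_frame(h_lab_vec, k_i=None) -> LocalFrame:
    """Local frame of one RLP: e3 || h, e1 || k_i x h, e2 = e3 x e1.

    Falls back to e1 = X when h is (anti)parallel to the beam.
    """
    h = np.asarray(h_lab_vec, dtype=float)
    hn = np.linalg.norm(h)
    if hn == 0:
        raise ValueError("local frame undefined for h = 0")
    e3 = h / hn
    ki = np.array([0.0, 0.0, 1.0]) if k_i is None else \
        np.asarray(k_i, dtype=float) / np.linalg.norm(k_i)
    c = np.cross(ki, e3)
    cn = np.linalg.norm(c)
    e1 = np.array([1.0, 0.0, 0.0]) if cn < 1e-12 else c / cn
    e2 = np.cross(e3, e1)
    return LocalFrame(e1=e1, e2=e2, e3=e3)


def tangent_covariance(cov_eff: np.ndarray, frame: LocalFrame,
                       h_len: float) -> np.ndarray:
    """2x2 covariance (1/A^2) of the RLP displacement in the tangent plane.

    The rotation-vector covariance is expressed in (omega_1, omega_2,
    omega_3) coordinates, marginalized over omega_3 (rotations about h do
    not move the RLP), and converted to displacements via
    (rho_1, rho_2) = h (omega_2, -omega_1):
    Sigma_h = h^2 [[S22, -S12], [-S12, S11]].
    """
    E = np.vstack([frame.e1, frame.e2])
    S = E @ np.asarray(cov_eff, dtype=float) @ E.T
    return h_len ** 2 * np.array([[S[1, 1], -S[0, 1]],
                                  [-S[0, 1], S[0, 0]]])


@dataclass(frozen=True)
class SpotPrediction:
    """One predicted reflection on the detector."""

    hkl: tuple
    x: float
    y: float
    intensity: float
    e_mos: float          # arc-length excitation error on S_h (1/A)
    e_shp: float          # excitation error along the relrod (1/A)
    partiality: float     # Gaussian profile factor (density value)
    projectable: bool = True


# ---------------------------------------------------------------------------
# Minimax Gaussian size factors (re-derivation of the 2.35 / 2.99 constants)
# ---------------------------------------------------------------------------

def plate_profile(q) -> np.ndarray:
    """Unit-peak relrod intensity profile of a thin plate of unit thickness:
    sinc^2(pi q) with q in units of 1/t."""
    q = np.asarray(q, dtype=float)
    return np.sinc(q) ** 2


def sphere_profile(q) -> np.ndarray:
    """Unit-peak reciprocal-space profile of a solid sphere of unit diameter.

    The 3-D autocorrelation of a ball of diameter D=1 depends only on r:
    A(r) = 1 - (3/2) r + (1/2) r^3 for r <= 1.  Its projection onto z is
    P_z(z) = 2 pi  int_{|z|}^{1} A(r) r dr  (closed form below); the profile
    is the 1-D Fourier transform of P_z, normalized to unit peak.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))

    def proj(z):
        z = abs(z)
        if z >= 1.0:
            return 0.0
        # int_z^1 (r - 1.5 r^2 + 0.5 r^4) dr
        F = lambda r: r ** 2 / 2.0 - r ** 3 / 2.0 + r ** 5 / 10.0
        return 2.0 * math.pi * (F(1.0) - F(z))

    zs = np.linspace(0.0, 1.0, 2001)
    pz = np.array([proj(z) for z in zs])
    # even function: FT reduces to a cosine transform
    out = np.trapezoid(pz * np.cos(2.0 * np.pi * np.outer(q, zs)), zs, axis=1)
    peak = np.trapezoid(pz, zs)
    return out / peak


def minimax_gaussian_factor(profile, q_max: float = 3.0,
                            n_grid: int = 6001) -> float:
    """Factor c such that a unit-peak Gaussian with sigma_q = c/(2 pi)
    minimizes the maximum absolute deviation from ``profile`` on [0, q_max].

    ``profile(q)`` must be the unit-peak reciprocal-space intensity profile
    for unit real-space extent; then sigma_z = extent / c.
    """
    q = np.linspace(0.0, q_max, n_grid)
    target = profile(q)

    def err(c):
        sq = c / (2.0 * math.pi)
        return np.max(np.abs(target - np.exp(-q ** 2 / (2.0 * sq ** 2))))

    res = optimize.minimize_scalar(err, bounds=(1.0, 6.0), method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


# ---------------------------------------------------------------------------
# Single-reflection convenience wrappers over the vectorized engine
# ---------------------------------------------------------------------------

def _predict_one(refl, R, geom, mos, shape, beam, *, aniso, scale=1.0,
                 b_global=0.0, tilt=None, image_index=0, tilt_use=False,
                 cutoff_sigma=math.inf) -> SpotPrediction:
    from .predict import predict_arrays, predictions_to_spots
    pred = predict_arrays(
        np.asarray([refl.hkl]), np.asarray([refl.h_vec_crystal]),
        np.asarray([refl.h_len]), np.asarray([refl.F2]), R=R, geom=geom,
        mos=mos, shape=shape, beam=beam, aniso=aniso, scale=scale,
        b_global=b_global, tilt=tilt, image_index=image_index,
        tilt_use=tilt_use, cutoff_sigma=cutoff_sigma)
    spots = predictions_to_spots(pred, geom)
    if not spots:
        return SpotPrediction(hkl=refl.hkl, x=math.nan, y=math.nan,
                              intensity=0.0, e_mos=math.nan, e_shp=math.nan,
                              partiality=0.0, projectable=False)
    return spots[0]


def aniso_predict(refl, R, geom, mos: MosaicityModel, shape: ShapeTransform,
                  beam: BeamModel, **kw) -> SpotPrediction:
    """Anisotropic-model prediction for a single reflection."""
    return _predict_one(refl, R, geom, mos, shape, beam, aniso=True, **kw)


def standard_predict(refl, R, geom, mos: MosaicityModel,
                     shape: ShapeTransform, beam: BeamModel,
                     **kw) -> SpotPrediction:
    """Standard-model (case A/B weighted) prediction for one reflection."""
    if shape.mode != "standard":
        raise ValueError("standard_predict needs a standard-mode shape")
    if mos.mode != "isotropic":
        raise ValueError("standard_predict needs isotropic mosaicity")
    return _predict_one(refl, R, geom, mos, shape, beam, aniso=False, **kw)
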