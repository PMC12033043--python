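"""Orientation, tilt-series and detector geometry.

Conventions (fixed here because every downstream number depends on them):

* Lab frame: right-handed X, Y, Z with Z along the incident beam; detector X
  right, Y down when viewing along the beam.  Pixel coordinates are 0-based,
  pixel-center.
* Orientation (crystal -> lab): ``R = Rz(psi) @ Ry(theta) @ Rz(phi)`` so that
  the lab +Z (beam) direction expressed in the crystal frame is
  ``(sin(theta) cos(phi), sin(theta) sin(phi), cos(theta))`` at psi = 0.
* Angles are degrees at every interface, radians internally.
* Image rotation (magnetic-lens rotation) is applied before the elliptical
  distortion ``r -> r * (1 + eps * cos 2(azimuth - phi0))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OrientationAngles",
    "DetectorGeometry",
    "TiltState",
    "orientation_matrix",
    "matrix_to_orientation",
    "rotation_about_axis",
    "h_lab",
    "project_to_detector",
    "electron_wavelength",
]

# CODATA-based constant for lambda[A] = K / sqrt(V (1 + V / (2 m c^2 / e)))
_LAMBDA_K = 12.264259  # A * sqrt(volt)
_TWO_M_C2_OVER_E = 1021998.0  # volt


def electron_wavelength(energy_kev: float) -> float:
    """Relativistic de Broglie wavelength (Angstrom) for energy in keV."""
    if energy_kev <= 0:
        raise ValueError("electron energy must be positive")
    v = energy_kev * 1e3
    return _LAMBDA_K / math.sqrt(v * (1.0 + v / _TWO_M_C2_OVER_E))


def electron_energy_kev(wavelength_A: float) -> float:
    """Inverse of :func:`electron_wavelength`."""
    if wavelength_A <= 0:
        raise ValueError("wavelength must be positive")
    c = (_LAMBDA_K / wavelength_A) ** 2
    # v (1 + v/T) = c  ->  v^2/T + v - c = 0
    T = _TWO_M_C2_OVER_E
    v = (-1.0 + math.sqrt(1.0 + 4.0 * c / T)) * T / 2.0
    return v / 1e3


@dataclass(frozen=True)
class OrientationAngles:
    """Beam direction in the crystal frame (theta, phi) plus rotation psi
    of the crystal about the beam; all degrees."""

    theta: float
    phi: float
    psi: float

    def __post_init__(self):
        if not 0 <= self.theta <= 180:
            raise ValueError(f"theta out of [0, 180]: {self.theta}")

    def normalized(self) -> "OrientationAngles":
        return OrientationAngles(self.theta, self.phi % 360.0, self.psi % 360.0)


def _rz(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def orientation_matrix(angles: OrientationAngles) -> np.ndarray:
    """Crystal -> lab rotation matrix, R = Rz(psi) Ry(-theta) Rz(-phi).

    ZYZ Euler convention fixed so that the lab +Z axis (beam) expressed in
    the crystal frame, R.T @ z_lab, equals
    (sin(theta) cos(phi), sin(theta) sin(phi), cos(theta)):
    (theta, phi) are the polar angles of the beam in the crystal frame and
    psi rotates the crystal about the beam.
    """
    t, p, s = (math.radians(x) for x in (angles.theta, angles.phi, angles.psi))
    return _rz(s) @ _ry(-t) @ _rz(-p)


def matrix_to_orientation(R: np.ndarray) -> OrientationAngles:
    """Inverse of :func:`orientation_matrix` (degenerate at theta in {0, 180})."""
    R = np.asarray(R, dtype=float)
    ct = min(1.0, max(-1.0, R[2, 2]))
    theta = math.acos(ct)
    if abs(abs(ct) - 1.0) < 1e-12:
        # gimbal locus: only psi-phi (theta=0) or psi+phi (theta=180) is
        # defined; put it in psi
        phi = 0.0
        if ct > 0:
            psi = math.atan2(R[1, 0], R[0, 0])
        else:
            psi = math.atan2(-R[1, 0], -R[0, 0])
    else:
        phi = math.atan2(R[2, 1], R[2, 0])
        psi = math.atan2(-R[1, 2], -R[0, 2])
    return OrientationAngles(math.degrees(theta), math.degrees(phi) % 360.0,
                             math.degrees(psi) % 360.0)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


@dataclass(frozen=True)
class TiltState:
    """Tilt-series geometry: a tilt axis in the lab XY plane (angle from +X,
    degrees) and per-image tilt angles with optional per-image corrections.

    Image 1 is the reference: its corrections are fixed at scale 1 / offset 0.
    """

    omega_axis_deg: float = 0.0
    omega_angles: tuple = (0.0,)
    scale_corrections: tuple = None
    omega_corrections: tuple = None

    def __post_init__(self):
        n = len(self.omega_angles)
        sc = self.scale_corrections if self.scale_corrections is not None \
            else tuple([1.0] * n)
        oc = self.omega_corrections if self.omega_corrections is not None \
            else tuple([0.0] * n)
        if len(sc) != n or len(oc) != n:
            raise ValueError("per-image correction lists must match image count")
        if abs(sc[0] - 1.0) > 0 or abs(oc[0]) > 0:
            raise ValueError("image 1 corrections are fixed (scale 1, offset 0)")
        object.__setattr__(self, "scale_corrections", tuple(sc))
        object.__setattr__(self, "omega_corrections", tuple(oc))

    @property
    def n_images(self) -> int:
        return len(self.omega_angles)

    def axis_vector(self) -> np.ndarray:
        a = math.radians(self.omega_axis_deg)
        return np.array([math.cos(a), math.sin(a), 0.0])

    def rotation(self, image_index: int) -> np.ndarray:
        """Lab-frame rotation applied on top of the crystal orientation."""
        ang = self.omega_angles[image_index] + self.omega_corrections[image_index]
        return rotation_about_axis(self.axis_vector(), ang)


def h_lab(h_vec_crystal, R: np.ndarray, tilt: TiltState | None = None,
          image_index: int = 0) -> np.ndarray:
    """Crystal-frame reciprocal vector(s) -> lab frame, including tilt."""
    h = np.asarray(h_vec_crystal, dtype=float)
    M = R if tilt is None else tilt.rotation(image_index) @ R
    return h @ M.T


@dataclass(frozen=True)
class DetectorGeometry:
    """Detector and beam parameters.

    ``camera_length_mm`` (L_eff) sets the gnomonic projection scale;
    ``detector_distance_mm`` (L) is the physical distance, so the
    magnification is L_eff / L.  Wavelength in Angstrom.
    """

    pixel_size_mm: float
    camera_length_mm: float
    wavelength_A: float
    beam_center: tuple = (0.0, 0.0)
    detector_distance_mm: float = None
    image_rotation_deg: float = 0.0
    distortion_eps: float = 0.0
    distortion_phi0_deg: float = 0.0

    def __post_init__(self):
        if self.pixel_size_mm <= 0 or self.camera_length_mm <= 0:
            raise ValueError("pixel size and camera length must be positive")
        if self.wavelength_A <= 0:
            raise ValueError("wavelength must be positive")
        if self.detector_distance_mm is None:
            object.__setattr__(self, "detector_distance_mm", self.camera_length_mm)

    @property
    def magnification(self) -> float:
        return self.camera_length_mm / self.detector_distance_mm

    @property
    def electron_energy_kev(self) -> float:
        return electron_energy_kev(self.wavelength_A)


def project_to_detector(points, geom: DetectorGeometry):
    """Map reciprocal-space position(s) near the Ewald sphere to pixels.

    ``points`` is (..., 3) in the lab frame (1/Angstrom).  Returns
    ``(xy, ok)`` where ``xy`` is (..., 2) pixel coordinates and ``ok`` marks
    projectable points (diffracted beam with positive Z component); entries
    with ``ok == False`` hold NaN.
    """
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    k = 1.0 / geom.wavelength_A
    kf = p + np.array([0.0, 0.0, k])
    ok = kf[:, 2] > 0
    x_mm = np.full(len(p), np.nan)
    y_mm = np.full(len(p), np.nan)
    L = geom.camera_length_mm
    x_mm[ok] = L * kf[ok, 0] / kf[ok, 2]
    y_mm[ok] = L * kf[ok, 1] / kf[ok, 2]
    # image rotation about the beam center (mm origin)
    rot = math.radians(geom.image_rotation_deg)
    if rot:
        c, s = math.cos(rot), math.sin(rot)
        x_mm, y_mm = c * x_mm - s * y_mm, s * x_mm + c * y_mm
    # elliptical distortion
    if geom.distortion_eps:
        r = np.hypot(x_mm, y_mm)
        az = np.arctan2(y_mm, x_mm)
        f = 1.0 + geom.distortion_eps * np.cos(
            2.0 * (az - math.radians(geom.distortion_phi0_deg)))
        x_mm = r * f * np.cos(az)
        y_mm = r * f * np.sin(az)
    xy = np.stack([x_mm / geom.pixel_size_mm + geom.beam_center[0],
                   y_mm / geom.pixel_size_mm + geom.beam_center[1]], axis=-1)
    if single:
        return xy[0], bool(ok[0])
    return xy, ok


def apply_plane_rotation_and_distortion(r_mm, az, geom: DetectorGeometry):
    """Detector mapping from polar gnomonic coordinates (helper for the
    orientation scan, where rotating the crystal about the beam shifts the
    azimuth without re-projecting)."""
    az = az + math.radians(geom.image_rotation_deg)
    f = 1.0
    if geom.distortion_eps:
        f = 1.0 + geom.distortion_eps * np.cos(
            2.0 * (az - math.radians(geom.distortion_phi0_deg)))
    x = r_mm * f * np.cos(az) / geom.pixel_size_mm + geom.beam_center[0]
    y = r_mm * f * np.sin(az) / geom.pixel_size_mm + geom.beam_center[1]
    return x, y
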